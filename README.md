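# turtlefarm

A bio-economic simulator of commercial freshwater turtle farming,
parameterised for red-eared slider (*Trachemys scripta elegans*) production
on a representative Louisiana farm.

US turtle farms currently sell only hatchlings (export pet/farm markets)
and yearling "4-inch" turtles (domestic pet market), while meat markets are
supplied by wild harvest of adults. This package models the farm as a
coupled biological and economic system, and asks what it would take for
*farmed* adults to compete with wild harvest: it projects the farm
population year by year, solves the operating parameters the farmer
actively manages, prices the output, and computes the break-even adult
price at which harvesting breeding stock for meat matches the profit of
traditional hatchling-and-yearling farming. It is intended for researchers
in wildlife economics and aquaculture management who want a transparent,
scriptable version of that analysis, or who want to re-parameterise it for
other species and farms.

## The model

**Biology.** A discrete annual-time-step, two-sex, age-structured cohort
projection. Females occupy classes F0 (hatchling), F1 (greenhouse
yearling), F2–F5 (juvenile stock) and F6 (adults, pooled); males mature a
year earlier, so M0–M1, M2–M4, M5. Each year:

1. last season's greenhouse cohort survives first-year mortality
   (1 − m_G = 0.85);
2. surviving yearlings are *head-started* into the stock ponds to fill the
   capacity deficit left by last year's losses (deficit-fill for females,
   males recruited in the stock sex proportion), and the surplus is sold;
3. the stock ages one class with survival s = 0.97; the adult pool loses
   natural mortality m_A = 1 − s plus the managed adult harvest h_A as
   competing outflows, F6(t) = F6(t−1)·(1 − m_A − h_A) + s·F5(t−1);
4. adult females nest: births = F6 · BR · min(1, SR/SR_o), with per-capita
   birth rate BR = CS·NC·HR·0.95 = 24.225 and fertility declining linearly
   when the adult sex ratio SR = M5/F6 falls below its optimum
   SR_o = 0.33. Because incubation is indoors and sex is
   temperature-determined, the managed split ADJ decides the fraction of
   eggs incubated female; the managed hatchling harvest h_H sells a
   fraction of the female hatchlings at emergence and the rest enter the
   greenhouse.

**Management controller.** For any adult harvest rate, `solve_policy`
finds h_H and ADJ such that at steady state the farm sells the yearling
target (~55,000/yr), incubates males only to cover male head-starting, and
keeps the stock at its 25,000-turtle capacity threshold.

**Economics.** Annual revenue H·p_h + Y·p_y and cost H·c_h + B·c_y (B =
yearlings produced, sold *plus* head-started; defaults $0.35/$7.50 prices,
$0.25/$4.50 costs). Expected total profit over an n-year cycle, with
discount rate d on costs and market appreciation m on revenue, both
compounding continuously:

    E(P) = Σ_{k=0}^{n−1} e^{(m−d)k} R − Σ_{k=0}^{n−1} e^{−dk} C

The break-even adult price for a harvest scenario is
P(a) = (P_tr − P_ntr)/A: the profit gap to traditional farming spread over
the adults harvested.

**Stochastic variant.** Seasonal clutch size as a truncated-normal draw
(10 ± 2.8, bounds [1, 22]) and warm-winter die-offs killing 10% of the
outdoor stock with probability 1/6 per year; Monte Carlo summaries over
replicates. Zero variance and zero event probability recover the
deterministic model exactly.

## Worked example

```python
import turtlefarm as tf

lh, stock, econ = tf.LifeHistory(), tf.StockConfig(), tf.EconParams()
sol = tf.solve_policy(lh, stock, h_A=0.0)          # traditional farming
rep = sol.steady_report
print(f"hatchlings sold {rep.H:,.0f}/yr, yearlings {rep.Y_sold:,.0f}/yr")
print(f"head-starts     {rep.g_F:.0f} female + {rep.g_M:.0f} male /yr")
print(f"annual profit   ${tf.annual_profit(rep, econ):,.0f}")

scen = tf.solve_policy(lh, stock, h_A=0.4)         # 40% adult harvest
price = tf.min_adult_price(tf.annual_profit(rep, econ),
                           tf.annual_profit(scen.steady_report, econ),
                           scen.steady_report.A_sold)
print(f"adults sold     {scen.steady_report.A_sold:,.0f}/yr")
print(f"break-even      ${price:.2f}/adult, "
      f"${tf.price_per_kg_meat(price, 1.6, 0.4):.2f}/kg meat")
```

prints

```
hatchlings sold 324,842/yr, yearlings 55,000/yr
head-starts     546 female + 182 male /yr
annual profit   $194,207
adults sold     3,015/yr
break-even      $12.89/adult, $20.14/kg meat
```

Traditional farming nets ~$194k/yr selling ~325k hatchlings and 55k
yearlings while replacing stock losses with ~728 head-starts. Harvesting
40% of the adults each year shrinks the nesting pool so badly that
hatchling exports fall to ~67k/yr; the 3,015 harvested adults would each
need to net ~$13 (≈$20/kg of meat) just to break even against not
harvesting them — far above current slider meat prices, which is the
paper-thin case for farmed slider meat.

The same analyses are available from the shell: `turtlefarm simulate`,
`sweep`, `npv-grid`, `break-even`, `monte-carlo`, `full-report`
(see `turtlefarm --help`; YAML config overrides any default).

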