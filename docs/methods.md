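# Methods

## Model structure and assumptions

The farm is modelled as three coupled compartments on an annual time step:
an indoor incubator (eggs laid April–August hatch the same year), heated
greenhouse ponds holding one cohort from hatching to yearling age, and
outdoor stock ponds holding the breeding population. State variables are
cohort abundances: females F0–F6 and males M0–M5, with all mature animals
pooled in the terminal class (females mature between five and six years,
males a year earlier — hence one fewer male class). Abundances are
continuous; whole-turtle rounding happens only in printed reports.

Assumptions inherited from the system being modelled:

- **No density dependence** in growth or survival as long as the stock is
  at or below the 12,500/ha threshold (farm feeds ad libitum); capacity is
  enforced as a hard ceiling by the head-start allocation, not by
  rate feedback.
- **Constant demand**: every hatchling and yearling produced for market is
  sold at the posted price.
- **Controlled sex at incubation** (temperature-dependent sex
  determination) and fertility governed by the adult sex ratio: the
  nesting fraction is 0.95 at or above the optimal ratio SR_o = 0.33
  (M:F), declining linearly below it — the multiplier is
  min(1, SR/SR_o).
- Hatchling harvest applies to the female hatchling share only; male eggs
  are incubated solely to replace male stock losses (pet markets have no
  sex preference, so the distinction costs nothing).

## Annual update order

Within year *t*, in order: (1) greenhouse cohort of year *t−1* passes
first-year mortality; (2) head-starts fill the stock deficit measured at
the census of *t−1*, surplus yearlings are sold; (3) the stock ages with
survival and adult harvest, head-starts entering the first stock class
(F2/M2) without an own-year survival decrement; (4) reproduction from the
post-update adult classes; (5) census. This is the ordering implied by the
model's year-(t−1) indices on head-start and aging terms, and it makes the
steady-state head-start requirement exactly

    g = max · (1 − s)/(2 − s)        (546.1 female, 182.0 male at baseline)

since the census always sits one year of attrition below the capacity
threshold that the deficit is measured against. A consequence worth
knowing: the realized census total is 25,000/(2 − s) ≈ 24,272, not 25,000
— the threshold is the ceiling the controller fills toward, not the
standing census.

### Adult-class update rule

Two formulations of the adult update are implemented (`update_rule`):

- `"concurrent"` (default): natural mortality and harvest are competing
  outflows from the standing pool within the year —
  F6(t) = F6(t−1)·(1 − m_A − h_A) + s·F5(t−1), harvest A = F6(t−1)·h_A.
  This is the Euler update of a stock-and-flow (systems-dynamics)
  formulation. If the combined outflow rate exceeds 1 the pool is split
  between the outflows in proportion to their rates.
- `"after_survival"`: survival first, then harvest of survivors —
  F6' = (F5+F6)·s, A = F6'·h_A.

The default was chosen by calibration against the full set of harvest-
scenario outcomes the model is expected to reproduce (adults sold across
h_A = 0.1–0.5, head-start requirements, hatchling production); the
concurrent rule reproduces them to within a fraction of a percent, the
alternative misses by 6–23%. Both rules coincide at h_A = 0.

### Head-start sex allocation

Female head-starts fill the female capacity deficit (bounded by supply).
Male head-starts are recruited in the stock sex proportion,
g_M = g_F·(1−p)/p (= g_F/3 at baseline), additionally bounded by the male
capacity deficit and male supply. At h_A = 0 this is identical to
filling the male deficit; under harvest it keeps recruitment — and hence
the standing sex ratio — at the configured proportion instead of
overstocking males. The resulting steady sex ratio is
SR = ((1−p)/p)/s ≈ 0.344 for every harvest rate: slightly above the 0.33
optimum (males being one survival step "younger" than their female
cohort-mates), so fertility is always at its full 95%. The controller
therefore checks SR ≥ SR_o rather than pinning SR to 0.33 exactly, which
the class structure cannot do while also filling female capacity.

## Management controller

`solve_policy(lh, cfg, h_A)` solves the two managed incubation/harvest
rates. Constraints at steady state: yearlings sold = target (55,000/yr,
relative tolerance 10⁻³), male yearling surplus ≈ 0 (males are incubated
only for head-starting), sex ratio fertile, capacity respected. The
closed-form stable stock (geometric ladder g·s^k over juvenile classes,
adult pool balancing inflow s·F5 against m_A + h_A) gives an analytic
first guess; each outer iteration simulates 100 years from the matching
equilibrium state, reads the steady report, and re-derives

    ADJ = 1 − (g_M /(1−m_G)) / births
    h_H = 1 − ((Y_target + g_F)/(1−m_G)) / (births·ADJ)

with damping 0.5 (cap 200 iterations). Because the stock side is
autonomous once yearling supply exceeds the deficit, the analytic guess is
already a fixed point and the loop typically certifies convergence on the
first pass. Infeasibility (e.g. births below greenhouse intake at high
h_A, or a male requirement exceeding total births) raises an error naming
the binding constraint; the harvest sweep records it per row and
continues.

Initial conditions default to the closed-form equilibrium; arbitrary
starts converge back to it (dominant transient eigenvalue ≈ 0.98/yr, so
simulations from distant states need several hundred years — the
`steady_state` check, span < 10⁻⁶ relative over a 10-year window, refuses
to average an unconverged tail rather than hiding oscillations).

## Economics

Revenue H·0.35 + Y·7.50 and cost H·0.25 + B·4.50 USD/yr, with B the full
greenhouse product (sold yearlings plus head-starts, which incur the same
heated-winter rearing cost). Accumulation over the n = 40-year cycle uses
continuous compounding with the year index k = 0…n−1; the market rate
appreciates revenue only, costs are discounted but not appreciated. The
zero-based index was fixed by verifying the accumulation against an
independent brute-force summation across the full discount × market grid;
the literal one-based variant is available (`convention="one_based"`) and
differs by one year's compounding. Break-even adult pricing takes the
scenario's hatchling+yearling profit and adults harvested from the solved
h_A = 0.4 steady state; no adult revenue or cost enters the scenario
profit — the computation *solves for* the required per-adult margin. The
per-kilogram figure divides by 1.6 kg mean adult mass × 40% meat yield.

## Stochastic variant

Two noise sources, both environmental (year-level):

- **Clutch size**: one truncated-normal draw per season
  (mean 10, sd 2.8, bounds [1, 22], mean not renormalised), scaling that
  year's birth rate. A single seasonal draw is deliberate: independent
  per-female draws across ~16,000 nesters would average to invisibility;
  the year-level draw represents shared environmental forcing. The raw
  observed clutch range (8–22) is inconsistent with the fitted
  distribution's lower tail, so the truncation floor is 1 egg,
  configurable.
- **Warm-winter die-off**: independent Bernoulli(1/6) per year; on an
  event every outdoor stock class loses 10% (optionally Uniform(0, 10%)),
  the heated greenhouse is spared. The event hits after aging, so it also
  depresses that year's nesting.

After a die-off the incubator split is re-managed for four seasons
(`adaptive_males` in `step`): if the fixed split would retain fewer male
hatchlings than the male capacity deficit requires, extra eggs are
incubated male at the expense of the female share. This mirrors actual
practice — the birth adjustment is an annually managed parameter — and is
structurally necessary: the solved fixed split produces males with zero
slack, so without re-management every die-off permanently erodes the male
stock until the sex ratio crosses the fertility threshold and production
collapses. The adaptation is a strict no-op when no event has occurred,
which is what makes the zero-variance/zero-probability limit reproduce
the deterministic model *bit-exactly*, not approximately.

Monte Carlo runs give each replicate a child stream of the seed
(`SeedSequence.spawn`), 100 years per replicate with a 50-year burn-in.
Under baseline stochasticity, mean hatchling production sits ~8% below the
deterministic steady state with ~5% coefficient of variation: the
deterministic value is the no-event upper envelope, since each die-off
drags the nesting pool below capacity for the several years the recruit
pipeline needs to refill it. Passing the degenerate-limit and
seed-reproducibility tests shows the machinery is consistent; it does not
validate the (unobserved) real-farm variance structure, for which only the
event frequency and magnitude anecdotes behind the defaults exist.

## Numerical conventions and problem sizes

- Simulations run 100 years (burn-in plus averaging window) per scenario;
  the economic horizon is 40 years; the Monte Carlo default is 200
  replicates. All headline quantities are deterministic and complete in
  seconds.
- Capacity and non-negativity are exact invariants of the update (head-
  starts are clipped to deficit and supply; outflow competition clips
  at pool exhaustion) and are asserted over randomized valid parameter
  sets in the property suite.
- Degenerate inputs: an empty farm is absorbing; F6 = 0 defines SR = 0;
  zero clutch size or hatch rate makes every management target infeasible
  and is reported as such rather than producing NaNs.

## Known limitations

- No individual growth, size structure, or density-dependent rates; no
  disease, no pond-failure catastrophes beyond the single die-off regime;
  no environmental autocorrelation (warm winters are independent).
- The economic layer has no inflation, tax, capital expenditure, itemized
  operating costs, or price–demand elasticity; prices and costs are flat
  per-turtle figures.
- Parameters describe one well-run farm; the model is a best-case
  envelope (capacity and sex ratio held at their managed optima every
  year), so realized farm output should undershoot it.
- The stochastic variant's adaptive incubation is a minimal recovery
  heuristic, not an optimal policy under uncertainty.
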