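# Methods

This note documents the model, its assumptions, the numerical choices, and
what the synthetic data do and do not establish.

## Hydrologic component

The basin is a directed tree of river reaches rooted at the mouth; each reach
has one downstream neighbor and confluences are expressed through tributary
reaches feeding the mainstem. The time step is annual and all volumes are in
Mm³/yr — seasonal storage, routing lags and reservoir operation are outside
the model's scope, which means within-year scarcity peaks are only
representable through the optional dry-season flow fraction (below).

Per reach, outflow follows the mass balance
`Wout = Win − loss − Div_IR − Div_URB + closure`, and continuity passes
outflow plus return flows (`r_IR`, `r_URB` of the withdrawing reach) to the
receiving reach. Demand units carry explicit withdrawal and return reaches;
a unit returning to its own reach contributes to that reach's inflow before
the outflow is taken, which is how the affine flow system
(`LinearFlowSystem`) treats it. Topological order is always computed from the
downstream links, never assumed from file order.

**Closure calibration.** Gauged outflows rarely match a network propagated
from observed diversions because of groundwater exchange, evaporation and
unmeasured returns. `calibrate_closure` places one signed closure constant at
each gauged reach; since a closure at reach d shifts every outflow at or
below d by the same amount, the gauge system is lower-triangular with unit
diagonal in topological order and has an exact solution (which is also the
minimum-norm exact solution). Closure terms are frozen constants afterwards;
they are not re-optimized in policy runs and are not scaled by drought
factors (they represent structural, not meteorological, imbalances).

## Irrigation component

Districts maximize profit over crop × technology acreages with linearly
declining yields `Y = β0 + β1 X` (β1 ≤ 0), the Ricardian representation of
heterogeneous land quality. Field crops irrigate by flood or sprinkler; fruit
trees and vegetables by drip or flood. Units are chosen to keep coefficients
O(1): acreage in 1,000 ha, water in Mm³, money in M€ (1 €/ha × 1,000 ha =
10⁻³ M€).

**PMP calibration** is the two-stage first-order-condition variant for linear
yield functions. Stage 1 solves a linear program at observed average yields
with calibration bounds `X ≤ X̄(1+ε)`, ε = 10⁻⁶, and reads the land/water/
labor duals λ from the LP (HiGHS marginals). Stage 2 sets, per observed
activity,

    μ  = max(margin − λᵀa, 0)        # calibration-bound dual
    β1 = −μ / (P X̄),  β0 = ȳ − β1 X̄

so that (i) the yield at X̄ equals the observed average yield and (ii) the
profit-maximization first-order condition holds at X̄ given λ. Re-solving the
district problem then returns X̄ exactly. Activities with zero observed
acreage, and activities pinned by a binding resource (μ = 0), keep a flat
yield and are held by their constraints. No quadratic-cost perturbation is
used: the curvature lives in the yield function, matching the linear-yield
formulation. Unprofitable observed activities (negative margin) are rejected
as a data error rather than silently calibrated.

District sub-problems are concave QPs solved with SLSQP (ftol 10⁻¹²); the
marginal value of water (the water constraint's dual) is recovered by a
forward-difference re-solve, which is robust to degenerate multiplier sets.

## Urban component

City surplus is `a_d Q_d − ½b_d Q_d² − a_s Q_s − ½b_s Q_s²` with supply ≥
demand. Because surplus strictly decreases in excess supply, supply equals
demand at the optimum and `Q* = (a_d − a_s)/(b_d + b_s)`. Urban supply is a
priority pre-allocation: `Q*` is computed once and held fixed in every policy
scenario, so urban ledger entries are identical across policies by
construction. In degenerate basins whose inflows cannot carry `Q*`, the urban
block is shrunk proportionally by bisection; ordinary instances never hit
this path.

## Environmental component

Habitat response is the saturating curve `WUA(X) = 1 − e^{βX}`, β < 0: zero
at zero flow, strictly increasing, concave, asymptoting to 1, with slope −β
at the origin. Ecosystem health is identified with WUA, and the reach benefit
is `VE·l·health` with tier values 0.072 / 0.180 / 0.450 M€/km (user-
overridable). The generic per-ha → per-km conversion is
`value_per_km(v, area, length) = v·area/length`.

Two deliberate degrees of freedom:

* **Flow-unit scale.** The β magnitudes reported in habitat studies span two
  orders of magnitude and their underlying flow units are study-specific.
  Each reach therefore carries a `wua_flow_scale` factor mapping annual Mm³
  to the curve's flow units. The fixture sets scales so baseline health lies
  in (0.55, 0.9) — mid-curve, where policy-induced flow changes move benefits
  measurably. An unscaled β of, say, −9.65 against flows of thousands of Mm³
  would pin health at 1.0 and silently delete the environmental trade-off.
* **Dry-season fraction.** Habitat stress is driven by low-water months; an
  optional multiplier (default 1.0) maps annual flow to the effective flow
  entering the curve.

The reach flow entering the benefit is the reach **outflow**, consistent with
the mouth minimum-flow constraint being an outflow constraint.

β is estimated by nonlinear least squares (`scipy.optimize.curve_fit`,
negative-bounded, data-driven start from inverting the curve at interior
points); the asymptotic SE comes from the fit covariance and t = β̂/SE. A
noise-free fit has zero residual variance and reports t = −∞.

## Policy optimization

The integrated objective is `Σ B_IR + Σ B_URB + Σ B_eco` (environmental terms
included only under the two environmental policies). Constraints: district
land/water/labor; per-district withdrawal caps `alloc·(1−drought)` under the
institutional policies, or the pooled sum of those caps under markets;
extraction ≤ net reach inflow at every withdrawal reach; minimum flows at
control points (drought-specific minimums where regulation differs);
nonnegative outflows and acreages. Drought scales every local inflow by
(1 − reduction); 0.3 and 0.4 correspond to moderate and severe events.

Because irrigation profit is concave quadratic, urban surplus fixed, the
environmental term concave in flows, and flows affine in acreage, the NLP is
a concave maximization over a polyhedron: SLSQP with analytic gradients from
a deterministic start (baseline acreage scaled by the drought factor) finds
the global optimum; a second start from zero covers rare line-search
failures. Solutions are validated post hoc against minimum flows and
nonnegativity, and solves are bit-deterministic for a fixed basin.

**Exchanges and pricing.** Sellers are districts using less than their
(reduced) allocation; buyers use more (markets only); the authority's
purchase is the remaining gap. Inter-district trades are priced at the pooled
cap's dual, obtained by a forward-difference re-solve of the whole NLP.
Purchases for the river are priced at each seller's marginal profit of water
at its final allocation — under environmental policies the pooled cap is
slack by exactly the purchased volume, so its dual is zero and the sellers'
duals are the economically meaningful price. Payments are pure transfers:
social welfare is production profit + urban surplus + environmental benefit,
and purchase expenditure appears in the ledger (`public_expenditure`,
`irrigation_env_income`) without entering welfare. The distributional view
(irrigation income including sale receipts, social net of public expense) is
recoverable from the same ledger fields.

## Synthetic data

`generate_basin` emulates the structural conditions the analysis assumes:
a mainstem-plus-tributaries tree carrying 14,600 Mm³/yr by default; habitat
coefficients drawn log-uniformly over the empirically observed range
[−16.39, −0.10]; three-tier valuation; districts whose observed baselines are
interior (endowments 5–20% slack, positive margins) so PMP calibration is
exact and well-posed; cities sized to a few percent of their reach's inflow;
and a mouth minimum flow set at half the severe-drought baseline mouth flow.
Feasibility at baseline and at every configured drought level is checked at
generation time. Seeds are explicit; identical seeds yield byte-identical
instances.

What the generator does **not** emulate: serially correlated hydrology,
within-year seasonality, heterogeneous per-crop price/cost data of any real
basin, conveyance losses on traded water, or groundwater stocks. Passing
tests therefore demonstrate the correctness of the machinery (calibration
exactness, optimality, orderings, conservation) — not predictive accuracy for
any real basin.

The frozen `toy_ebro` fixture uses the 14 published habitat coefficients and
the three control-point minimum flows (300; 945 normal / 640 drought; 3,000
at the mouth), 14,600 Mm³ inflow, a 402 Mm³ urban withdrawal, and synthetic
district/city economics calibrated so the baseline mouth flow is 8,895 Mm³
and baseline environmental benefits are 956 M€ — the published headline
aggregates — while the remaining monetary levels are intentionally not
matched (the original calibration dataset is unpublished). The fixture is
shipped as CSVs with a checksum manifest and never regenerated.

## Testing and problem sizes

The acceptance suite runs, single-CPU, in well under a minute: PMP exact
reproduction on 100 seeded districts (tolerance 10⁻⁶ relative); a 500-
replicate Monte Carlo of β recovery at the steepest studied design (n = 33,
σ = 0.05), comparing empirical 2-SE coverage against the nominal 95.45% minus
two binomial Monte-Carlo standard errors (asymptotic intervals at n = 33
undercover slightly; the tolerance is statistical, not a fudge); grid-search
equivalence of the NLP on a two-district basin at 0.01-acreage resolution
(10⁻³ relative on the objective); and policy-ordering, minimum-flow and
mass-conservation checks across 50 seeded basins × 4 policies (small
instances: 4 reaches, 2 districts, 1 city — the properties are
size-independent).

## Known limitations

* Static single-year model; no reservoirs, routing, or stock dynamics.
* Urban demand is aggregate and seasonal tariffs are not represented.
* A single habitat curve per reach; multi-species/life-stage aggregation
  rules are not modeled.
* Market clearing is frictionless and price-taking; the pooled-dual price is
  a competitive benchmark, not a bargaining outcome.
* Closure terms capture mean non-observed flows only and are invariant to
  drought scaling.
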