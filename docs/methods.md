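# Methods

## Model and scalarization

The optimizer treats one isomer campaign at a time. An observation is an
objective pair (conversion %, target-isomer selectivity %), both in
[0, 100]; the two isomer percentages of the condensation sum to 100, so the
N1 campaign's selectivity is 100 minus the N2 percentage and both campaigns
share one experiment table. The scalarized score is the weighted Euclidean
distance to an unreachable utopia point

d(y, u) = sqrt(w_sel²(u_sel − sel)² + w_conv²(u_conv − conv)²),  u_sel, u_conv > 100.

Unreachability is load-bearing: if an observation could pass u, points
beyond it would score worse than u itself and the scalar objective would no
longer be monotone in the underlying objectives. Strict unreachability also
guarantees that Pareto dominance implies distance ordering (strict under
strict dominance), which the suite property-tests on random pairs. The
quantity the surrogates fit and the acquisitions maximize is the inverse
distance 1/d, capped at 10⁶ purely to guard misconfigured (reachable)
utopia points; with a valid u the cap is unreachable. Default coordinates
are (110, 110) with equal weights — the method itself fixes no coordinates,
only unreachability — and both are configurable per campaign, since
placement is the intended weighting mechanism.

## Search space and encoding

Variables are Boolean switches, strictly increasing numeric grids, and one
solvent chosen from a descriptor table (four continuous descriptors per
solvent). Grids, not continuous ranges, are the native representation:
every proposal must be a condition a chemist can execute, and realized
campaign conditions are discrete. Acid and base loadings share one signed
axis (acid positive, base negative, never both). Model features are the
Booleans as 0/1, numerics min-max scaled to [0, 1] per variable (constants
stored on the space; raw values stay on the condition), and the solvent's
four descriptors, each min-max scaled over the table — so a GP length-scale
means the same thing on every axis. The shipped default space (3 Booleans ×
hydrazine 1–5 equiv × temperature 0–50 °C in 12.5 °C steps × a 13-level
acid/base grid × volumes 10–30 mL/g × 200 solvents) enumerates 2.6 million
conditions; enumeration is streaming (mixed-radix unranking), so counting
or subsampling it uses flat memory. Bounds are proposal constraints only:
observed data outside the current bounds is accepted on read and retained
for fitting, but flagged and never re-proposed. Mid-campaign interventions
(relaxing the hydrazine cap from 5 to 20 equiv, changing batch size from 5
to 8, switching the modeled target) are explicit API/CLI calls recorded in
the state's event log.

## Surrogates and acquisitions

Four families sit behind one mean/std interface: GPR (Matern-5/2 +
white-noise kernel, marginal-likelihood hyperparameters, posterior std),
RFR (500 trees; spread across trees), gradient boosting (300 estimators,
depth 3, row subsample 0.75) and MLP (two hidden layers 64/32; targets
standardized internally because inverse distances live on a ~0.01–0.07
scale). Boosting and networks have no native predictive variance, so each
is a 10-member seed-ensemble whose population standard deviation feeds the
acquisitions; the boosting subsample is what makes member seeds matter.
A constant target short-circuits every family to the exact constant with
zero spread. Acquisitions are UCB = mean + κ·std and expected improvement
with offset ξ over the incumbent best scalarized value; the strategy-label
tokens are read as κ = 2 (`ucb_2`) and ξ = 0.05 (`ei_05`), both
overridable, the tokens themselves fixing no semantics. EI maximizes
inverse distance (the plotted and modeled quantity) rather than minimizing
distance inside the acquisition.

Batch proposal: one surrogate per family per round (seeded deterministically
from campaign seed, round and family), each strategy claims its pool argmax
in configured order, duplicate winners fall to the earlier strategy, and any
shortfall is filled by globally descending score over unclaimed candidates.
The candidate pool is the whole unobserved space when small, otherwise a
seeded uniform subsample (default 50 000) — exhaustively scoring >10⁶
candidates per strategy per round buys nothing on these landscapes. In the
opening two-objective regime, conversion and selectivity are fitted
separately, each strategy scores both, and candidates are ranked by
successive nondominated fronts of the two acquisition scores (ties within a
front: descending rank-sum, then candidate index). Front extraction is an
O(n log n) two-dimensional sweep; the O(n²) dominance filter lives in the
tests as its independent oracle.

The final predictive stage cross-validates all four families (5-fold,
seeded; the validation scheme is this package's choice) and nominates the
lowest-RMSE family's predicted optimum over the unobserved space, ties
broken by the fixed order GPR, RFR, Grad, MLP.

## Synthetic data

The generator emulates the statistical structure of a finished condensation
campaign, not its mechanism. Solvent descriptors are a correlated
4-D Gaussian clipped to ±2.5 with d2 designated basicity-like. N2
selectivity and conversion are logistic-squashed linear models on the raw
variables; the planted hierarchy puts the acid/base axis first (±5 equiv ×
0.5 logit/equiv), the solvent block second, and adds a positive hydrazine
main effect with a hydrazine × basicity interaction — echoing the
campaign-level findings that excess hydrazine and basic solvents favor the
N2 isomer while strong base favors N1. The interaction is sized so N2
selectivity stays nondecreasing in hydrazine at every admissible basicity
(slope ≥ 0.06 − 0.015·2.5 > 0). N1% is exactly 100 − N2%. Observation
noise is truncated Gaussian, sd 3 percentage points per objective (typical
assay scatter), clipped to [0, 100]; draws are recorded so datasets can be
regenerated and audited exactly.

Campaign datasets (default 248 rows, the scale of a real two-isomer
campaign) are sampled from a seeded pool with weights favoring mid-range
conversion, then the top two conditions of each campaign's noiseless
landscape — found by exhaustive chunked scan of the full space — are
injected so lookup benchmarks contain a discoverable optimum, as a real
finished dataset does. What the generator does **not** reproduce: assay
failures, batch effects, solvent-availability censoring, heteroscedastic
noise, or any mechanistic coupling between the isomer pathways beyond the
shared linear drivers. Benchmarks passing on it show the optimizer exploits
smooth low-dimensional structure with planted interactions; they do not
certify performance on landscapes with discontinuities or strong
higher-order effects.

## Benchmarks and numerical choices

A finished table becomes a lookup oracle whose rows are the entire space.
Rounds-to-optimum is the first round whose running maximum of inverse
distance attains the space's true optimum within 10⁻⁹ (exact attainment —
the statistic is rediscovery, not approximation); seed observations count
toward round 1, so a lucky seed draw scores 1. Repeats that miss within
the budget are censored, reported separately, and counted at the budget
when averaging (a conservative bound, never silently dropped). The random
baseline draws uniformly without replacement with identical bookkeeping and
is implemented directly (a permutation position), which is what makes
10⁴-repeat comparisons against the hypergeometric closed form cheap. The
predicted-surface benchmark freezes the GPR/RFR/MLP ensemble-mean
prediction over a seeded subsample of the large space as a deterministic
oracle, mapping each predicted inverse distance to the objective pair on
the diagonal toward the utopia point at exactly that distance (values
outside the attainable band clip to the band edge).

Closed-loop benchmarks and the acceptance script use a scaled-down
surrogate preset — RFR 200 trees, boosting 100 estimators, MLP 32/16 with
300 iterations, 5-member ensembles — chosen once as the benchmark problem
size for single-CPU runs; library defaults are unchanged. Benchmark
defaults (5 seed observations, batch 8, 15-round budget, 20 repeats) are
this package's choices and are configurable. All derived seeds come from
`SeedSequence` over (campaign seed, round, role) and stay below 2³¹.

## Known limitations

Strategy allocation when strategies outnumber the batch follows configured
order — one of several defensible rules, and it matters in early rounds.
The solvent descriptor table is user-supplied or synthetic; the package
computes no descriptors from structure. No cost-aware or asynchronous
acquisition. Percent-scale objectives are assumed throughout; other scales
require re-placing the utopia point.
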