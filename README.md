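# upbo — utopia-point Bayesian optimization of reaction conditions

`upbo` is a batch, multi-model Bayesian optimizer for reaction development,
built for the situation a process chemist actually faces: two objectives
(conversion and isomer selectivity) that must be optimized *simultaneously*
over a mixed search space of Boolean choices (catalyst on/off, sieves
on/off), discrete numeric grids (reagent equivalents, temperature, solvent
volumes) and a categorical solvent choice described by four continuous
descriptors. The motivating application is the Knorr-type condensation of
methylhydrazine with a 1,3-dicarbonyl equivalent, where the N1- and
N2-methyl pyrazole constitutional isomers compete and each isomer campaign
needs its own selective conditions.

## The method

Each observation is a pair y = (selectivity %, conversion %) in
[0, 100]². A deliberately **unreachable utopia point** u = (u_sel, u_conv),
u > 100 on both axes, converts the two objectives into one scalar:

    d(y, u) = sqrt( w_sel² (u_sel − sel)² + w_conv² (u_conv − conv)² )

Pareto dominance implies distance ordering, so minimizing d (equivalently
maximizing 1/d, the quantity the surrogates model) never trades a dominated
point for a dominant one. Moving u outward along one axis, or raising that
axis's weight, re-weights the optimization toward that objective.

Per round, every configured **strategy** — a surrogate family crossed with
an acquisition function, labelled `GPR_ucb_2_n2`-style — fits the
observations and nominates its top unobserved candidate from a seeded pool;
duplicate winners fall to the earlier strategy and the batch is refilled by
global score. Families: Gaussian process (posterior std), random forest
(tree spread), gradient boosting and multilayer perceptron (seed-ensemble
spread). Acquisitions: UCB `mean + κ·std` (exploratory, κ = 2) and EI with
offset ξ = 0.05 (exploitative). An opening regime that models the two
objectives separately and Pareto-sorts the acquisition scores is also
provided, as is a final predictive stage that picks the family with the
lowest cross-validated RMSE and nominates its predicted optimum.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/04_lookup_benchmark.py` builds a 120-row synthetic
campaign dataset, treats its rows as the entire search space (a *lookup
oracle*) and races the optimizer against uniform random selection from
5 random seed observations:

```
lookup space: 120 conditions
UPBO rounds-to-optimum per repeat:   [2, 1, 1, 1, 1]
random rounds-to-optimum per repeat: [10, 11, 12, 5, 2]  (None = not found in 12 rounds)
mean rounds: UPBO 1.2 vs random 8.0
```

Each entry is the first round whose running-best inverse utopia distance
reaches the dataset's true optimum: model-guided selection needs a fraction
of the experiments random sampling needs. `examples/03_closed_loop_campaign.py`
shows the loop itself (running maxima per round ending at an N2-selective,
high-conversion condition), and `examples/05_feature_importance.py` prints
the grouped permutation importances, with the signed acid/base axis first
and the 4-descriptor solvent block second.

A thin CLI mirrors the lab loop (`upbo init / propose / observe /
predict-best / benchmark / simulate / importance`); state lives in a single
JSON document and all tables are plain CSV.

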