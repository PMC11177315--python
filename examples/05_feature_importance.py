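"""Which variables matter? Grouped permutation importance on synthetic data.

Fits a random forest to N2 selectivity on 400 noiseless synthetic rows and
measures the out-of-fold RMSE increase when each variable — or the joint
4-descriptor solvent block — is shuffled.
"""

import numpy as np

from upbo.surrogates import SurrogateSpec, feature_importance
from upbo.synthetic import DEFAULT_PARAMS, surface_values, synthetic_space

space = synthetic_space()
rng = np.random.default_rng(0)
idx = rng.choice(space.cardinality, size=400, replace=False)
n2, _ = surface_values(space, idx, DEFAULT_PARAMS)
X = space.encode_many([space.unrank(int(i)) for i in idx])

report = feature_importance(
    SurrogateSpec("RFR", {"n_estimators": 200}),
    X, n2, space.feature_groups(), n_permutations=5, seed=0,
)
for name, score, rank in sorted(
    zip(report.group_names, report.scores, report.ranks), key=lambda t: t[2]
):
    print(f"{rank}. {name:18s} dRMSE = {score:6.3f}")
# The signed acid/base axis dominates and the solvent descriptor block is
# second — the planted hierarchy of the generator, and the qualitative
# pattern seen in real condensation campaigns.
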