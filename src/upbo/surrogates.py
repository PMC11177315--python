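"""Surrogate model families with uncertainty, fit statistics and importance.

Four regressor families are registered, matching the campaign's strategy
labels:

* ``GPR`` — Gaussian process (Matern-5/2 + white noise, marginal-likelihood
  hyperparameters); posterior std is the native uncertainty.
* ``RFR`` — random forest; mean/std across the trees.
* ``Grad`` — gradient boosting; a seed-ensemble of boosters (row subsampling
  makes member seeds matter), mean/std across members.
* ``MLP`` — multilayer perceptron; a seed-ensemble of networks, mean/std
  across members.  Targets are standardized internally: inverse utopia
  distances live on a ~0.01–0.1 scale where raw-scale network training is
  poorly conditioned.

Gradient boosting and neural networks carry no native predictive variance,
so their seed-ensembles exist purely to feed UCB/EI acquisitions an honest
spread; the ensemble std is the population standard deviation of member
predictions.

Also here: k-fold cross-validated RMSE (used to pick the final predictive
family) and grouped permutation feature importance (the four solvent
descriptors are permuted jointly as one block, since they describe a single
categorical choice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

FAMILIES = ("GPR", "RFR", "Grad", "MLP")

MIN_OBSERVATIONS = 3


class InsufficientDataError(ValueError):
    """Fewer observations than a surrogate fit requires."""


@dataclass(frozen=True)
class SurrogateSpec:
    """Family name, family-specific hyperparameters, ensemble size, seed."""

    family: str
    params: dict = field(default_factory=dict)
    n_ensemble: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.n_ensemble < 1:
            raise ValueError("n_ensemble must be >= 1")

    def with_seed(self, seed: int) -> "SurrogateSpec":
        return SurrogateSpec(self.family, dict(self.params), self.n_ensemble, int(seed))


@dataclass(frozen=True)
class PredictionWithUncertainty:
    mean: float
    std: float


@dataclass(frozen=True)
class FitStatistics:
    rmse: float
    scheme: str


@dataclass(frozen=True)
class ImportanceReport:
    """Grouped permutation importances: mean out-of-fold RMSE increase."""

    group_names: tuple[str, ...]
    scores: tuple[float, ...]
    standard_errors: tuple[float, ...]
    ranks: tuple[int, ...]  # rank 1 = most important

    def rank_of(self, name: str) -> int:
        return self.ranks[self.group_names.index(name)]


def _default_kernel():
    return ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=1.0, length_scale_bounds=(1e-2, 1e2), nu=2.5
    ) + WhiteKernel(1e-4, (1e-10, 1e1))


def _build_gpr(params: dict, seed: int) -> GaussianProcessRegressor:
    kw = dict(
        kernel=_default_kernel(),
        normalize_y=True,
        n_restarts_optimizer=0,
        alpha=1e-10,
        random_state=seed,
    )
    kw.update(params)
    return GaussianProcessRegressor(**kw)


def _build_rfr(params: dict, seed: int) -> RandomForestRegressor:
    kw = dict(n_estimators=500, random_state=seed)
    kw.update(params)
    return RandomForestRegressor(**kw)


def _build_grad(params: dict, seed: int) -> GradientBoostingRegressor:
    kw = dict(n_estimators=300, max_depth=3, subsample=0.75, random_state=seed)
    kw.update(params)
    return GradientBoostingRegressor(**kw)


def _build_mlp(params: dict, seed: int) -> MLPRegressor:
    kw = dict(hidden_layer_sizes=(64, 32), max_iter=800, random_state=seed)
    kw.update(params)
    return MLPRegressor(**kw)


class FittedSurrogate:
    """A fitted family with a uniform mean/std prediction interface."""

    def __init__(self, spec: SurrogateSpec, members, y_loc=0.0, y_scale=1.0, const=None):
        self.spec = spec
        self._members = members
        self._y_loc = y_loc
        self._y_scale = y_scale
        self._const = const

    def member_predictions(self, X) -> np.ndarray:
        """(n_members, n_points) matrix of raw member predictions."""
        X = np.asarray(X, dtype=float)
        if self._const is not None:
            return np.full((1, X.shape[0]), self._const)
        if self.spec.family == "GPR":
            raise ValueError("GPR is not an ensemble; use predict_with_uncertainty")
        if self.spec.family == "RFR":
            members = self._members[0].estimators_
        else:
            members = self._members
        preds = np.array([m.predict(X) for m in members])
        return preds * self._y_scale + self._y_loc

    def predict_with_uncertainty(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Return (mean, std) arrays over the rows of X."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D encoded matrix")
        if self._const is not None:
            n = X.shape[0]
            return np.full(n, self._const), np.zeros(n)
        if self.spec.family == "GPR":
            mean, std = self._members[0].predict(X, return_std=True)
            return np.asarray(mean, dtype=float), np.asarray(std, dtype=float)
        preds = self.member_predictions(X)
        return preds.mean(axis=0), preds.std(axis=0)

    def predict(self, X) -> np.ndarray:
        return self.predict_with_uncertainty(X)[0]


_BUILDERS = {"GPR": _build_gpr, "RFR": _build_rfr, "Grad": _build_grad, "MLP": _build_mlp}


def fit(spec: SurrogateSpec, X, y) -> FittedSurrogate:
    """Fit one surrogate family; deterministic given ``spec.seed``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) and y (n,) with matching n")
    if X.shape[0] < MIN_OBSERVATIONS:
        raise InsufficientDataError(
            f"need at least {MIN_OBSERVATIONS} observations, got {X.shape[0]}"
        )
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite")
    if np.ptp(y) == 0.0:
        # Degenerate constant target: every family reduces to the constant,
        # with zero ensemble spread (the GP's noise floor is immaterial here).
        return FittedSurrogate(spec, [], const=float(y[0]))

    builder = _BUILDERS[spec.family]
    if spec.family in ("GPR", "RFR"):
        model = builder(spec.params, spec.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        return FittedSurrogate(spec, [model])

    # seed-ensemble families; standardize y for the MLP's sake
    y_loc, y_scale = (float(y.mean()), float(y.std())) if spec.family == "MLP" else (0.0, 1.0)
    if y_scale == 0.0:
        y_scale = 1.0
    yt = (y - y_loc) / y_scale
    members = []
    for k in range(spec.n_ensemble):
        model = builder(spec.params, spec.seed + k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, yt)
        members.append(model)
    return FittedSurrogate(spec, members, y_loc=y_loc, y_scale=y_scale)


def ensemble_mean_predict(models: dict, X) -> np.ndarray:
    """Unweighted mean of the GPR, RFR and MLP predicted means.

    This is the deterministic stand-in surface used to benchmark the
    optimizer over the full search space, where no lab measurement exists.
    """
    required = ("GPR", "RFR", "MLP")
    missing = [f for f in required if f not in models]
    if missing:
        raise KeyError(f"ensemble_mean_predict requires families {required}; missing {missing}")
    preds = [np.asarray(models[f].predict(X), dtype=float) for f in required]
    return np.mean(preds, axis=0)


def fit_statistics(spec: SurrogateSpec, X, y, k_folds: int = 5, seed: int = 0) -> FitStatistics:
    """Out-of-fold RMSE under seeded k-fold cross-validation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if X.shape[0] < k_folds:
        raise InsufficientDataError(f"need at least {k_folds} rows for {k_folds}-fold CV")
    oof = np.empty_like(y)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        model = fit(spec, X[train], y[train])
        oof[test] = model.predict(X[test])
    rmse = float(np.sqrt(np.mean((oof - y) ** 2)))
    return FitStatistics(rmse=rmse, scheme=f"{k_folds}-fold-cv(seed={seed})")


def feature_importance(
    spec: SurrogateSpec,
    X,
    y,
    groups: list[tuple[str, list[int]]],
    n_permutations: int = 10,
    seed: int = 0,
    k_folds: int = 3,
) -> ImportanceReport:
    """Grouped permutation importance on out-of-fold data.

    For each fold, each group's columns are shuffled *jointly* (one row
    permutation applied to the whole block) in the held-out rows and the
    increase in RMSE over the unshuffled baseline is recorded; scores are
    averaged over permutations and folds.  Joint permutation is what makes a
    block of correlated descriptors (the solvent block) register its combined
    effect instead of leaking through unshuffled partners.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    deltas: dict[str, list[float]] = {name: [] for name, _ in groups}
    for train, test in kf.split(X):
        model = fit(spec, X[train], y[train])
        base = np.sqrt(np.mean((model.predict(X[test]) - y[test]) ** 2))
        for name, cols in groups:
            for _ in range(n_permutations):
                Xp = X[test].copy()
                perm = rng.permutation(len(test))
                Xp[:, cols] = Xp[np.ix_(perm, cols)]
                rmse = np.sqrt(np.mean((model.predict(Xp) - y[test]) ** 2))
                deltas[name].append(float(rmse - base))
    names = tuple(name for name, _ in groups)
    scores = tuple(float(np.mean(deltas[n])) for n in names)
    ses = tuple(
        float(np.std(deltas[n], ddof=1) / np.sqrt(len(deltas[n]))) if len(deltas[n]) > 1 else 0.0
        for n in names
    )
    order = np.argsort([-s for s in scores], kind="stable")
    ranks = tuple(int(np.flatnonzero(order == i)[0]) + 1 for i in range(len(names)))
    return ImportanceReport(names, scores, ses, ranks)


def default_model_config(seed: int = 0) -> dict[str, SurrogateSpec]:
    """Library-default spec per family."""
    return {f: SurrogateSpec(f, seed=seed) for f in FAMILIES}


def fast_model_config(seed: int = 0) -> dict[str, SurrogateSpec]:
    """Scaled-down preset for closed-loop benchmarks on one CPU.

    Smaller forests/boosters and 5-member ensembles; chosen once as the
    benchmark problem size, not tuned per run.
    """
    return {
        "GPR": SurrogateSpec("GPR", seed=seed),
        "RFR": SurrogateSpec("RFR", {"n_estimators": 200}, seed=seed),
        "Grad": SurrogateSpec("Grad", {"n_estimators": 100}, n_ensemble=5, seed=seed),
        "MLP": SurrogateSpec(
            "MLP", {"hidden_layer_sizes": (32, 16), "max_iter": 300}, n_ensemble=5, seed=seed
        ),
    }
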