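"""Closed-loop campaign engine.

A campaign holds a search space, the observations so far (condition,
objectives, round, strategy label), an unreachable utopia point, and a list
of strategies.  Each round:

1. a seeded candidate pool of unobserved conditions is drawn (the whole
   unobserved space when small, a uniform subsample otherwise);
2. in ``upbo`` mode one surrogate per family is fitted to the inverse utopia
   distance of the observations; each strategy scores the pool with its
   acquisition and claims its argmax.  Duplicated winners fall to the first
   strategy in configured order; if fewer distinct winners than the batch
   size remain, the batch is filled with the next-best unclaimed candidates
   by descending score across all strategies;
3. in ``pareto_biobjective`` mode (the campaign's opening regime) conversion
   and selectivity are modeled separately, each strategy computes one
   acquisition score per objective, and candidates are ranked by successive
   nondominated fronts of the two scores;
4. measured outcomes are ingested, the round index advances, and the
   running maximum of inverse distance is extended.

Chemist interventions — relaxing a variable's allowed levels, changing the
batch size, switching the modeled target from the two separate objectives to
the scalarized distance — are explicit API calls recorded in the state's
event log.  Observations made out-of-bounds by a constraint stay in the
training data (they carry information) but are never proposed again.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import acquisition as acq_mod
from . import surrogates as sur
from .objectives import (
    ObjectivePair,
    UtopiaPoint,
    inverse_distance,
    pareto_sort_acquisition,
)
from .space import Condition, SearchSpace, flag_out_of_space

MODES = ("pareto_biobjective", "upbo")


class ExhaustedSpaceError(RuntimeError):
    """Every candidate condition has already been observed."""


def derive_seed(*parts: int) -> int:
    """Stable sub-seed from integer components, kept below 2**31."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31 - 1))


@dataclass(frozen=True)
class Observation:
    condition: Condition
    objectives: ObjectivePair
    round_index: int
    label: str  # strategy label string, or "seed"


@dataclass(frozen=True)
class Proposal:
    condition: Condition
    label: str
    score: float


@dataclass(frozen=True)
class ProposalBatch:
    proposals: tuple[Proposal, ...]
    round_index: int

    def conditions(self) -> list[Condition]:
        return [p.condition for p in self.proposals]

    def __len__(self) -> int:
        return len(self.proposals)


@dataclass(frozen=True)
class CampaignState:
    """The optimizer's persistent object for one isomer campaign."""

    space: SearchSpace
    utopia: UtopiaPoint
    strategies: tuple[acq_mod.StrategyLabel, ...]
    observations: tuple[Observation, ...] = ()
    round: int = 0
    mode: str = "upbo"
    rng_seed: int = 0
    model_config: dict = field(default_factory=sur.default_model_config)
    candidates: tuple[Condition, ...] | None = None  # finite pool override (lookup spaces)
    events: tuple[str, ...] = ()

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        conds = [o.condition for o in self.observations]
        if len(set(conds)) != len(conds):
            raise ValueError("observation conditions must be distinct")

    def observed_conditions(self) -> set[Condition]:
        return {o.condition for o in self.observations}

    def inverse_distances(self) -> np.ndarray:
        return np.array(
            [inverse_distance(o.objectives, self.utopia) for o in self.observations]
        )

    def best_inverse_distance(self) -> float:
        y = self.inverse_distances()
        return float(y.max()) if y.size else float("-inf")

    def with_mode(self, mode: str) -> "CampaignState":
        """Switch the modeled target (observations untouched)."""
        return replace(self, mode=mode, events=self.events + (f"mode -> {mode}",))

    def with_space(self, space: SearchSpace, note: str = "constraint change") -> "CampaignState":
        """Intervention: replace the space; out-of-space observations are
        flagged in the event log but retained for fitting."""
        flags = flag_out_of_space(space, [o.condition for o in self.observations])
        n_out = sum(flags)
        return replace(
            self, space=space, events=self.events + (f"{note} ({n_out} observations out-of-space)",)
        )


@dataclass
class RoundRecord:
    round_index: int
    batch: ProposalBatch
    observations: tuple[Observation, ...]
    best_so_far: float


@dataclass
class CampaignHistory:
    seed_observations: tuple[Observation, ...]
    rounds: list[RoundRecord] = field(default_factory=list)
    final_state: CampaignState | None = None

    def running_maximum(self) -> list[float]:
        return [r.best_so_far for r in self.rounds]


def _candidate_pool(state: CampaignState, pool_size: int) -> list[Condition]:
    observed = state.observed_conditions()
    if state.candidates is not None:
        pool = [c for c in state.candidates if c not in observed and state.space.contains(c)]
    else:
        card = state.space.cardinality
        if card <= max(pool_size, len(observed) + pool_size // 2):
            pool = [c for c in state.space.enumerate_candidates() if c not in observed]
        else:
            seed = derive_seed(state.rng_seed, state.round, 101)
            draw = state.space.enumerate_candidates(
                subsample=min(pool_size, card), seed=seed
            )
            pool = [c for c in draw if c not in observed]
    if not pool:
        raise ExhaustedSpaceError("all candidate conditions have been observed")
    return pool


def propose_from_pool(
    X_obs: np.ndarray,
    y_targets: dict[str, np.ndarray],
    pool: Sequence[Condition],
    X_pool: np.ndarray,
    strategies: Sequence[acq_mod.StrategyLabel],
    model_config: dict,
    seed: int,
    batch_size: int,
    mode: str = "upbo",
) -> list[Proposal]:
    """Core batch-proposal rule shared by campaigns and scalar benchmarks.

    ``y_targets`` maps target names to observation vectors: one entry
    (``"scalar"``) in upbo mode, two (``"selectivity"``, ``"conversion"``)
    in pareto mode.
    """
    families = []
    for s in strategies:
        if s.family not in families:
            families.append(s.family)
    fitted: dict[tuple[str, str], sur.FittedSurrogate] = {}
    for fam in families:
        spec = model_config[fam]
        for t_idx, (tname, y) in enumerate(sorted(y_targets.items())):
            fit_seed = derive_seed(seed, sur.FAMILIES.index(fam), t_idx)
            fitted[(fam, tname)] = sur.fit(spec.with_seed(fit_seed), X_obs, y)

    claimed: set[int] = set()
    proposals: list[Proposal] = []
    per_strategy_scores: list[np.ndarray] = []

    if mode == "upbo":
        y = y_targets["scalar"]
        best = float(np.max(y))
        for s in strategies:
            mean, std = fitted[(s.family, "scalar")].predict_with_uncertainty(X_pool)
            scores = acq_mod.score(s.acq_type, mean, std, s.parameter, best_observed=best)
            per_strategy_scores.append(np.asarray(scores, dtype=float))
        rankings = [np.argsort(-sc, kind="stable") for sc in per_strategy_scores]
    else:
        best = {t: float(np.max(y)) for t, y in y_targets.items()}
        rankings = []
        for s in strategies:
            two = []
            for tname in ("selectivity", "conversion"):
                mean, std = fitted[(s.family, tname)].predict_with_uncertainty(X_pool)
                two.append(
                    np.asarray(
                        acq_mod.score(s.acq_type, mean, std, s.parameter, best_observed=best[tname]),
                        dtype=float,
                    )
                )
            # the reported score is the pair sum; the ranking is Pareto-front order
            per_strategy_scores.append(two[0] + two[1])
            rankings.append(pareto_sort_acquisition(two[0], two[1], max_points=batch_size + len(strategies)))

    # one winner per strategy, in configured order
    for s_idx, s in enumerate(strategies):
        if len(proposals) >= batch_size:
            break
        for cand in rankings[s_idx]:
            if cand not in claimed:
                claimed.add(int(cand))
                proposals.append(
                    Proposal(pool[int(cand)], s.render(), float(per_strategy_scores[s_idx][cand]))
                )
                break

    # fill remaining slots by globally descending score among unclaimed candidates
    if len(proposals) < batch_size:
        flat = []
        for s_idx, sc in enumerate(per_strategy_scores):
            for cand in range(len(pool)):
                flat.append((-float(sc[cand]), s_idx, cand))
        flat.sort()
        for _, s_idx, cand in flat:
            if len(proposals) >= batch_size:
                break
            if cand in claimed:
                continue
            claimed.add(cand)
            proposals.append(
                Proposal(pool[cand], strategies[s_idx].render(), float(per_strategy_scores[s_idx][cand]))
            )
    return proposals


def propose_round(
    state: CampaignState, batch_size: int, pool_size: int = 50_000
) -> ProposalBatch:
    """Propose the next batch of conditions; deterministic given the state."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if len(state.observations) < sur.MIN_OBSERVATIONS:
        raise sur.InsufficientDataError(
            f"need at least {sur.MIN_OBSERVATIONS} seed observations before proposing; "
            "ingest seed data first"
        )
    pool = _candidate_pool(state, pool_size)
    X_pool = state.space.encode_many(pool)
    X_obs = state.space.encode_many([o.condition for o in state.observations])
    if state.mode == "upbo":
        y_targets = {"scalar": state.inverse_distances()}
    else:
        y_targets = {
            "selectivity": np.array([o.objectives.selectivity for o in state.observations]),
            "conversion": np.array([o.objectives.conversion for o in state.observations]),
        }
    seed = derive_seed(state.rng_seed, state.round, 7)
    proposals = propose_from_pool(
        X_obs,
        y_targets,
        pool,
        X_pool,
        state.strategies,
        state.model_config,
        seed,
        min(batch_size, len(pool)),
        mode=state.mode,
    )
    return ProposalBatch(tuple(proposals), round_index=state.round + 1)


def ingest(
    state: CampaignState, batch: ProposalBatch, measured: Sequence[ObjectivePair]
) -> CampaignState:
    """Append measured outcomes for a proposed batch; advances the round."""
    if len(measured) != len(batch):
        raise ValueError(
            f"measured outcomes ({len(measured)}) must align with batch ({len(batch)})"
        )
    observed = state.observed_conditions()
    new_obs = []
    seen_in_batch = set()
    for prop, obj in zip(batch.proposals, measured):
        if prop.condition in observed or prop.condition in seen_in_batch:
            raise ValueError(f"condition already observed: {prop.condition.as_dict()}")
        seen_in_batch.add(prop.condition)
        new_obs.append(
            Observation(prop.condition, obj, round_index=state.round + 1, label=prop.label)
        )
    return replace(
        state, observations=state.observations + tuple(new_obs), round=state.round + 1
    )


def seed_state(state: CampaignState, conditions, outcomes, label: str = "seed") -> CampaignState:
    """Load round-0 seed observations into a fresh state."""
    obs = tuple(
        Observation(c, o, round_index=0, label=label) for c, o in zip(conditions, outcomes)
    )
    return replace(state, observations=state.observations + obs)


def run_campaign(
    oracle: Callable[[Condition], ObjectivePair],
    state: CampaignState,
    n_rounds: int,
    batch_size: int,
    pool_size: int = 50_000,
    stop_at_inverse_distance: float | None = None,
) -> CampaignHistory:
    """Alternate propose/ingest for ``n_rounds`` against an oracle.

    Records the per-round running maximum of inverse distance; optionally
    stops early once the running maximum reaches a threshold (used by the
    rounds-to-optimum benchmarks).
    """
    history = CampaignHistory(seed_observations=state.observations)
    best = state.best_inverse_distance()
    for _ in range(n_rounds):
        if stop_at_inverse_distance is not None and best >= stop_at_inverse_distance:
            break
        try:
            batch = propose_round(state, batch_size, pool_size)
        except ExhaustedSpaceError:
            break
        measured = [oracle(c) for c in batch.conditions()]
        state = ingest(state, batch, measured)
        round_obs = state.observations[-len(batch):]
        best = max(best, max(inverse_distance(o.objectives, state.utopia) for o in round_obs))
        history.rounds.append(
            RoundRecord(state.round, batch, round_obs, best_so_far=best)
        )
    history.final_state = state
    return history


def running_maximum(history: CampaignHistory) -> list[float]:
    """Best-so-far inverse distance after each round (seed data included)."""
    if history.final_state is None:
        raise ValueError("history has no final state")
    u = history.final_state.utopia
    best = float("-inf")
    for o in history.seed_observations:
        best = max(best, inverse_distance(o.objectives, u))
    series = []
    for rec in history.rounds:
        for o in rec.observations:
            best = max(best, inverse_distance(o.objectives, u))
        series.append(best)
    return series


@dataclass(frozen=True)
class PredictBestResult:
    condition: Condition
    predicted_inverse_distance: float
    family: str
    rmse_by_family: dict
    all_observed: bool = False


def predict_best(
    state: CampaignState,
    k_folds: int = 5,
    pool_size: int = 50_000,
    model_config: dict | None = None,
) -> PredictBestResult:
    """Final predictive-model stage: pick the family with the lowest
    cross-validated RMSE on inverse distance, predict over the (sub)space,
    and return the unobserved condition with the best prediction.

    RMSE ties break by the fixed family order GPR, RFR, Grad, MLP.
    """
    if len(state.observations) < 10:
        raise sur.InsufficientDataError("predict_best requires at least 10 observations")
    config = model_config or state.model_config
    X = state.space.encode_many([o.condition for o in state.observations])
    y = state.inverse_distances()
    cv_seed = derive_seed(state.rng_seed, 999)
    rmse_by_family = {}
    for fam in sur.FAMILIES:
        spec = config[fam].with_seed(derive_seed(state.rng_seed, 17, sur.FAMILIES.index(fam)))
        rmse_by_family[fam] = sur.fit_statistics(spec, X, y, k_folds=k_folds, seed=cv_seed).rmse
    winner = min(sur.FAMILIES, key=lambda f: (rmse_by_family[f], sur.FAMILIES.index(f)))
    model = sur.fit(
        config[winner].with_seed(derive_seed(state.rng_seed, 23)), X, y
    )
    try:
        pool = _candidate_pool(state, pool_size)
    except ExhaustedSpaceError:
        # degenerate: everything observed; report the best observed condition
        idx = int(np.argmax(y))
        return PredictBestResult(
            state.observations[idx].condition,
            float(y[idx]),
            winner,
            rmse_by_family,
            all_observed=True,
        )
    preds = model.predict(state.space.encode_many(pool))
    idx = int(np.argmax(preds))
    return PredictBestResult(pool[idx], float(preds[idx]), winner, rmse_by_family)
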