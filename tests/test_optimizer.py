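import numpy as np
import pytest

from upbo import surrogates as sur
from upbo import synthetic as syn
from upbo.acquisition import StrategyLabel, default_acquisitions, strategy_grid
from upbo.objectives import ObjectivePair, UtopiaPoint, inverse_distance
from upbo.optimizer import (
    CampaignState,
    ExhaustedSpaceError,
    Observation,
    ProposalBatch,
    ingest,
    predict_best,
    propose_round,
    run_campaign,
    running_maximum,
    seed_state,
)
from upbo.space import apply_constraint

from conftest import make_tiny_space

FAST = sur.fast_model_config()
N2_STRATEGIES = tuple(strategy_grid(["GPR", "RFR"], default_acquisitions(), "n2"))
ALL_STRATEGIES = tuple(strategy_grid(sur.FAMILIES, default_acquisitions(), "n2"))


def surface_pair(space, cond):
    return syn.response_surface(cond, syn.DEFAULT_PARAMS, noisy=False, space=space)


def seeded_state(space, n_seed=5, seed=0, strategies=N2_STRATEGIES, **kw):
    rng = np.random.default_rng(seed)
    conds = list(space.enumerate_candidates(subsample=n_seed, seed=seed))
    outcomes = [surface_pair(space, c) for c in conds]
    state = CampaignState(
        space=space,
        utopia=UtopiaPoint(),
        strategies=strategies,
        rng_seed=seed,
        model_config=FAST,
        **kw,
    )
    return seed_state(state, conds, outcomes)


class TestProposeRound:
    def test_requires_seed_observations(self, tiny_space):
        state = CampaignState(
            space=tiny_space, utopia=UtopiaPoint(), strategies=N2_STRATEGIES, model_config=FAST
        )
        with pytest.raises(sur.InsufficientDataError):
            propose_round(state, batch_size=2)

    def test_forced_single_remaining_candidate(self):
        space = make_tiny_space(n_solvents=1)
        # restrict to a 3-condition space via the candidates override
        conds = [space.unrank(i) for i in (0, 1, 2)]
        state = CampaignState(
            space=space,
            utopia=UtopiaPoint(),
            strategies=N2_STRATEGIES,
            rng_seed=0,
            model_config=FAST,
            candidates=tuple(conds),
        )
        state = seed_state(state, conds[:2] + [space.unrank(5)],
                           [surface_pair(space, c) for c in conds[:2] + [space.unrank(5)]])
        batch = propose_round(state, batch_size=1)
        assert batch.conditions() == [conds[2]]

    def test_deterministic_given_state_and_seed(self, tiny_space):
        state = seeded_state(tiny_space, seed=3)
        b1 = propose_round(state, batch_size=4, pool_size=300)
        b2 = propose_round(state, batch_size=4, pool_size=300)
        assert b1 == b2

    def test_batch_is_distinct_and_disjoint_from_observed(self, tiny_space):
        state = seeded_state(tiny_space, seed=1)
        batch = propose_round(state, batch_size=6, pool_size=400)
        conds = batch.conditions()
        assert len(set(conds)) == len(conds) == 6
        assert not set(conds) & state.observed_conditions()

    def test_each_proposal_is_its_strategys_pool_argmax(self, tiny_space):
        # re-score the pool per strategy independently; whenever the
        # per-strategy argmaxes are distinct, the batch must equal them
        from upbo.optimizer import _candidate_pool, derive_seed, propose_from_pool

        state = seeded_state(tiny_space, seed=7, n_seed=8, strategies=ALL_STRATEGIES)
        batch = propose_round(state, batch_size=8, pool_size=500)
        pool = _candidate_pool(state, 500)
        X_pool = state.space.encode_many(pool)
        X_obs = state.space.encode_many([o.condition for o in state.observations])
        y = state.inverse_distances()
        seed = derive_seed(state.rng_seed, state.round, 7)
        from upbo import acquisition as acq_mod

        best = float(y.max())
        argmaxes = []
        for s_idx, s in enumerate(ALL_STRATEGIES):
            fit_seed = derive_seed(seed, sur.FAMILIES.index(s.family), 0)
            model = sur.fit(FAST[s.family].with_seed(fit_seed), X_obs, y)
            mean, std = model.predict_with_uncertainty(X_pool)
            scores = acq_mod.score(s.acq_type, mean, std, s.parameter, best_observed=best)
            argmaxes.append(pool[int(np.argmax(scores))])
        if len(set(argmaxes)) == len(argmaxes):
            assert batch.conditions() == argmaxes

    def test_pareto_mode_proposes_valid_batch(self, tiny_space):
        state = seeded_state(tiny_space, seed=2, mode="pareto_biobjective")
        batch = propose_round(state, batch_size=4, pool_size=200)
        assert len(batch) == 4
        assert not set(batch.conditions()) & state.observed_conditions()


class TestIngest:
    def test_bookkeeping(self, tiny_space):
        state = seeded_state(tiny_space, seed=4)
        batch = propose_round(state, batch_size=3, pool_size=200)
        outcomes = [surface_pair(tiny_space, c) for c in batch.conditions()]
        new = ingest(state, batch, outcomes)
        assert len(new.observations) == len(state.observations) + 3
        assert new.round == state.round + 1
        assert new.observations[-1].round_index == new.round

    def test_duplicate_reingestion_rejected(self, tiny_space):
        state = seeded_state(tiny_space, seed=4)
        batch = propose_round(state, batch_size=2, pool_size=200)
        outcomes = [surface_pair(tiny_space, c) for c in batch.conditions()]
        new = ingest(state, batch, outcomes)
        with pytest.raises(ValueError):
            ingest(new, batch, outcomes)

    def test_length_mismatch_rejected(self, tiny_space):
        state = seeded_state(tiny_space, seed=4)
        batch = propose_round(state, batch_size=2, pool_size=200)
        with pytest.raises(ValueError):
            ingest(state, batch, [])


class TestRunCampaign:
    def test_zero_rounds_keeps_only_seed_data(self, tiny_space):
        state = seeded_state(tiny_space, seed=5)
        hist = run_campaign(lambda c: surface_pair(tiny_space, c), state, 0, 2)
        assert hist.rounds == []
        assert len(hist.seed_observations) == 5

    def test_running_maximum_nondecreasing_and_matches_prefix_scan(self, tiny_space):
        state = seeded_state(tiny_space, seed=6)
        hist = run_campaign(lambda c: surface_pair(tiny_space, c), state, 3, 3, pool_size=150)
        series = running_maximum(hist)
        assert series == sorted(series)
        # prefix-scan oracle over all observations
        u = hist.final_state.utopia
        prefix_best = max(
            inverse_distance(o.objectives, u) for o in hist.seed_observations
        )
        expected = []
        for rec in hist.rounds:
            prefix_best = max(
                prefix_best, max(inverse_distance(o.objectives, u) for o in rec.observations)
            )
            expected.append(prefix_best)
        assert series == pytest.approx(expected)
        assert series == pytest.approx([r.best_so_far for r in hist.rounds])

    def test_identical_seeds_give_identical_histories(self, tiny_space):
        h = [
            run_campaign(
                lambda c: surface_pair(tiny_space, c),
                seeded_state(tiny_space, seed=8),
                2,
                3,
                pool_size=150,
            )
            for _ in range(2)
        ]
        assert [r.batch for r in h[0].rounds] == [r.batch for r in h[1].rounds]
        assert running_maximum(h[0]) == running_maximum(h[1])

    def test_final_best_improves_on_seed_best(self, tiny_space):
        improved = 0
        for seed in range(5):
            state = seeded_state(tiny_space, seed=seed)
            start = state.best_inverse_distance()
            hist = run_campaign(
                lambda c: surface_pair(tiny_space, c), state, 3, 4, pool_size=200
            )
            if running_maximum(hist)[-1] > start:
                improved += 1
        assert improved >= 4

    def test_proposals_never_repeat_observations_across_campaigns(self, tiny_space):
        for seed in range(10):
            state = seeded_state(tiny_space, seed=seed)
            seen = set(state.observed_conditions())
            for _ in range(2):
                batch = propose_round(state, batch_size=3, pool_size=100)
                assert not set(batch.conditions()) & seen
                outcomes = [surface_pair(tiny_space, c) for c in batch.conditions()]
                state = ingest(state, batch, outcomes)
                seen |= set(batch.conditions())


class TestInterventions:
    def test_mode_switch_preserves_observations(self, tiny_space):
        state = seeded_state(tiny_space, seed=9, mode="pareto_biobjective")
        switched = state.with_mode("upbo")
        assert switched.observations == state.observations
        assert switched.mode == "upbo"
        assert any("mode" in e for e in switched.events)

    def test_constraint_intervention_retains_out_of_space_data(self, tiny_space):
        state = seeded_state(tiny_space, seed=10)
        narrowed = apply_constraint(tiny_space, "menhnh2_equiv", (5.0,))
        new = state.with_space(narrowed, note="hydrazine cap")
        assert len(new.observations) == len(state.observations)
        batch = propose_round(new, batch_size=3, pool_size=150)
        for cond in batch.conditions():
            assert cond["menhnh2_equiv"] == 5.0


class TestPredictBest:
    def test_requires_ten_observations(self, tiny_space):
        state = seeded_state(tiny_space, n_seed=6, seed=11)
        with pytest.raises(sur.InsufficientDataError):
            predict_best(state)

    def test_recovers_lookup_optimum_when_interpolable(self):
        # 30-condition lookup space with a smooth target: the winning family
        # must nominate the true best unobserved condition
        space = make_tiny_space(n_solvents=2)
        conds = [space.unrank(i) for i in range(0, space.cardinality, 19)]
        pairs = [surface_pair(space, c) for c in conds]
        inv = [inverse_distance(p, UtopiaPoint()) for p in pairs]
        order = np.argsort(inv)
        observed_idx = [int(i) for i in order[:-1]]  # withhold the best row
        state = CampaignState(
            space=space,
            utopia=UtopiaPoint(),
            strategies=N2_STRATEGIES,
            rng_seed=1,
            model_config=FAST,
            candidates=tuple(conds),
        )
        state = seed_state(
            state, [conds[i] for i in observed_idx], [pairs[i] for i in observed_idx]
        )
        res = predict_best(state, k_folds=3)
        assert res.condition == conds[int(order[-1])]
        assert res.family in sur.FAMILIES

    def test_all_observed_flags_degenerate_case(self):
        space = make_tiny_space(n_solvents=1)
        conds = [space.unrank(i) for i in range(12)]
        pairs = [surface_pair(space, c) for c in conds]
        state = CampaignState(
            space=space,
            utopia=UtopiaPoint(),
            strategies=N2_STRATEGIES,
            rng_seed=2,
            model_config=FAST,
            candidates=tuple(conds),
        )
        state = seed_state(state, conds, pairs)
        res = predict_best(state, k_folds=3)
        assert res.all_observed
        inv = [inverse_distance(p, UtopiaPoint()) for p in pairs]
        assert res.condition == conds[int(np.argmax(inv))]
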