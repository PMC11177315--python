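"""Utopia-point Bayesian optimization of reaction conditions.

A batch, multi-model Bayesian optimizer for simultaneously maximizing
conversion and isomer selectivity of a reaction over a mixed
Boolean/numeric/solvent condition space, by minimizing the Euclidean
distance to a deliberately unreachable "utopia" point in objective space.
"""

from importlib import resources as _resources

import pandas as _pd

from .acquisition import AcquisitionSpec, StrategyLabel, default_acquisitions, ei, strategy_grid, ucb
from .benchmark import (
    BenchmarkResult,
    LookupOracle,
    benchmark_convergence,
    make_lookup_oracle,
    predicted_surface_benchmark,
    random_baseline,
)
from .objectives import (
    ObjectivePair,
    ScalarScore,
    UtopiaPoint,
    inverse_distance,
    pair_from_percents,
    pareto_front,
    pareto_sort_acquisition,
    utopia_distance,
)
from .optimizer import (
    CampaignHistory,
    CampaignState,
    Observation,
    PredictBestResult,
    Proposal,
    ProposalBatch,
    ingest,
    predict_best,
    propose_round,
    run_campaign,
    running_maximum,
    seed_state,
)
from .space import (
    Condition,
    SearchSpace,
    SolventRecord,
    VariableSpec,
    acid_base_axis,
    apply_constraint,
    define_space,
    flag_out_of_space,
    split_acid_base,
)
from .surrogates import (
    FitStatistics,
    ImportanceReport,
    SurrogateSpec,
    ensemble_mean_predict,
    fast_model_config,
    feature_importance,
    fit,
    fit_statistics,
)
from .synthetic import (
    DEFAULT_PARAMS,
    SurfaceParams,
    SyntheticDataset,
    default_space,
    generate_campaign_dataset,
    generate_solvent_table,
    ground_truth_optimum,
    knorr_like_fixture,
    response_surface,
    synthetic_space,
)
from .tables import (
    RunConfig,
    load_config,
    load_state,
    read_experiment_table,
    read_solvent_table,
    save_state,
    write_proposals,
)

__version__ = "0.1.0"


def load_reference_campaign() -> _pd.DataFrame:
    """The packaged 22-row table of round-best conditions from the
    N-methyl pyrazole condensation optimization campaign."""
    ref = _resources.files("upbo.data").joinpath("knorr_campaign_rounds.csv")
    with _resources.as_file(ref) as path:
        return read_experiment_table(path)
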