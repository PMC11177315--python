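"""Seeded synthetic chemistry: solvent tables, response surfaces, datasets.

Everything here emulates the *statistical structure* of a pyrazole-forming
condensation campaign — not its mechanism — so that every other module can
be exercised end-to-end with no external data:

* a solvent table of four correlated continuous descriptors per solvent,
  with the second descriptor designated "basicity-like";
* two correlated responses on the percent scale.  N2 selectivity is a
  logistic-squashed linear model whose dominant term is the signed acid/base
  axis, with the solvent block second, a positive methylhydrazine main
  effect and a planted hydrazine x solvent-basicity interaction (echoing the
  campaign findings that excess hydrazine and basic solvents drive the N2
  isomer while strong base drives N1).  Conversion is a second squashed
  linear model sharing some of the same drivers.  N1% is exactly
  100 - N2%;
* optional truncated Gaussian noise (default sd 3 percentage points per
  objective, typical of HPLC assay scatter);
* campaign datasets of a given row count sampled with a bias toward
  mid-range outcomes plus a couple of injected near-optimal rows per
  campaign, so lookup-oracle benchmarks have a discoverable optimum —
  mirroring the fact that a finished campaign dataset contains its own best
  conditions.

The generator's spaces and the shipped default space share the published
campaign's variable structure: three Booleans, four numeric grids
(methylhydrazine equivalents, temperature 0–50 °C, the signed acid/base
axis, solvent volume 10–30 mL/g) and one solvent choice over ~200
parametrized solvents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .objectives import ObjectivePair, UtopiaPoint, inverse_distance
from .space import (
    BOOLEAN,
    NUMERIC,
    SOLVENT,
    Condition,
    SearchSpace,
    SolventRecord,
    VariableSpec,
    grid,
    split_acid_base,
)

DESCRIPTOR_CLIP = 2.5
BASICITY_DESCRIPTOR = "d2"

ACID_BASE_LEVELS = (-5.0, -4.0, -3.0, -2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
HYDRAZINE_LEVELS_DEFAULT = (1.0, 2.0, 3.0, 4.0, 5.0)  # pre-intervention cap at 5 equiv
HYDRAZINE_LEVELS_EXTENDED = (1.0, 2.0, 3.0, 4.0, 5.0, 8.0, 10.0, 13.0, 16.0, 20.0)


@dataclass(frozen=True)
class SurfaceParams:
    """Coefficients of the two logistic-squashed linear response models.

    Units: logits per raw unit of each variable (equivalents, °C, mL/g,
    descriptor units); ``noise_sd`` in percentage points.
    """

    # N2-selectivity logit
    sel_intercept: float = -0.5
    sel_acid_base: float = 0.50
    sel_hydrazine: float = 0.06
    sel_solvent: tuple[float, float, float, float] = (0.10, 0.35, -0.08, 0.06)
    sel_hydrazine_x_basicity: float = 0.015
    sel_dsi2: float = 0.15
    sel_ptc: float = -0.25
    sel_ms: float = -0.10
    sel_temp: float = 0.004
    sel_volume: float = -0.006
    # conversion logit
    conv_intercept: float = 1.2
    conv_acid_base: float = 0.05
    conv_acid_base_sq: float = -0.012
    conv_hydrazine: float = 0.035
    conv_solvent: tuple[float, float, float, float] = (0.0, 0.10, 0.0, 0.25)
    conv_dsi2: float = 0.30
    conv_ms: float = -0.10
    conv_temp: float = 0.010
    conv_volume: float = -0.004
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


DEFAULT_PARAMS = SurfaceParams()


def generate_solvent_table(n_solvents: int, seed: int = 0) -> pd.DataFrame:
    """Seeded synthetic descriptor table: columns solvent, d1..d4.

    Descriptors are drawn from a correlated multivariate normal and clipped
    to ±2.5; d2 plays the basicity-like role that drives the planted
    hydrazine interaction.
    """
    if n_solvents < 1:
        raise ValueError("n_solvents must be >= 1")
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [1.0, 0.3, 0.0, 0.0],
            [0.3, 1.0, 0.2, 0.0],
            [0.0, 0.2, 1.0, 0.1],
            [0.0, 0.0, 0.1, 1.0],
        ]
    )
    desc = rng.multivariate_normal(np.zeros(4), cov, size=n_solvents)
    desc = np.clip(desc, -DESCRIPTOR_CLIP, DESCRIPTOR_CLIP)
    return pd.DataFrame(
        {
            "solvent": [f"solv_{i:03d}" for i in range(n_solvents)],
            "d1": desc[:, 0],
            "d2": desc[:, 1],
            "d3": desc[:, 2],
            "d4": desc[:, 3],
        }
    )


def solvent_records(table: pd.DataFrame) -> dict[str, SolventRecord]:
    return {
        str(r["solvent"]): SolventRecord(
            str(r["solvent"]), (r["d1"], r["d2"], r["d3"], r["d4"])
        )
        for _, r in table.iterrows()
    }


def synthetic_space(
    n_solvents: int = 200,
    solvent_seed: int = 0,
    hydrazine_levels=HYDRAZINE_LEVELS_DEFAULT,
    solvent_table: pd.DataFrame | None = None,
) -> SearchSpace:
    """The generator's (and the package's shipped default) search space."""
    table = solvent_table if solvent_table is not None else generate_solvent_table(n_solvents, solvent_seed)
    records = solvent_records(table)
    variables = (
        VariableSpec("acid_base_equiv", NUMERIC, ACID_BASE_LEVELS, unit="equiv"),
        VariableSpec("menhnh2_equiv", NUMERIC, tuple(hydrazine_levels), unit="equiv"),
        VariableSpec("dsi2", BOOLEAN, (0, 1)),
        VariableSpec("ptc", BOOLEAN, (0, 1)),
        VariableSpec("ms", BOOLEAN, (0, 1)),
        VariableSpec("temp_c", NUMERIC, grid(0.0, 50.0, 12.5), unit="degC"),
        VariableSpec("vol_ml_per_g", NUMERIC, grid(10.0, 30.0, 5.0), unit="mL/g"),
        VariableSpec("solvent", SOLVENT, tuple(records)),
    )
    return SearchSpace(variables, records)


def default_space(seed: int = 0) -> SearchSpace:
    """Shipped default configuration: > 1 million candidate conditions."""
    return synthetic_space(n_solvents=200, solvent_seed=seed)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _raw_arrays(space: SearchSpace, indices: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized mixed-radix unranking to raw per-variable value arrays."""
    idx = np.asarray(indices, dtype=np.int64).copy()
    out: dict[str, np.ndarray] = {}
    for v in reversed(space.variables):
        idx, digit = np.divmod(idx, v.n_levels)
        if v.kind == SOLVENT:
            out["_solvent_idx"] = digit
        else:
            out[v.name] = np.asarray(v.levels, dtype=float)[digit]
    return out


def _descriptor_matrix(space: SearchSpace) -> np.ndarray:
    names = space.solvent_variable.levels
    return np.array([space.solvent_record(n).descriptors for n in names])


def surface_values(
    space: SearchSpace, indices: np.ndarray, params: SurfaceParams
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless (N2 %, conversion %) arrays for the given condition indices."""
    raw = _raw_arrays(space, indices)
    d = _descriptor_matrix(space)[raw["_solvent_idx"]]
    ab = raw["acid_base_equiv"]
    hz = raw["menhnh2_equiv"] - 1.0
    T = raw["temp_c"] - 25.0
    vol = raw["vol_ml_per_g"] - 20.0
    p = params
    eta_sel = (
        p.sel_intercept
        + p.sel_acid_base * ab
        + p.sel_hydrazine * hz
        + d @ np.asarray(p.sel_solvent)
        + p.sel_hydrazine_x_basicity * hz * d[:, 1]
        + p.sel_dsi2 * raw["dsi2"]
        + p.sel_ptc * raw["ptc"]
        + p.sel_ms * raw["ms"]
        + p.sel_temp * T
        + p.sel_volume * vol
    )
    eta_conv = (
        p.conv_intercept
        + p.conv_acid_base * ab
        + p.conv_acid_base_sq * ab**2
        + p.conv_hydrazine * hz
        + d @ np.asarray(p.conv_solvent)
        + p.conv_dsi2 * raw["dsi2"]
        + p.conv_ms * raw["ms"]
        + p.conv_temp * T
        + p.conv_volume * vol
    )
    return 100.0 * _sigmoid(eta_sel), 100.0 * _sigmoid(eta_conv)


def _condition_index(space: SearchSpace, cond: Condition) -> int:
    idx = 0
    for v in space.variables:
        idx = idx * v.n_levels + v.levels.index(cond[v.name])
    return idx


def response_surface(
    cond: Condition,
    params: SurfaceParams = DEFAULT_PARAMS,
    noisy: bool = False,
    seed: int = 0,
    space: SearchSpace | None = None,
) -> ObjectivePair:
    """Evaluate one condition; returns the N2-campaign objective pair.

    Deterministic when ``noisy`` is false; with noise, truncated Gaussian
    perturbations (sd ``params.noise_sd``) are applied to each response and
    clipped to [0, 100].  N1% is always exactly 100 - N2%.
    """
    space = space or synthetic_space()
    n2, conv = surface_values(space, np.array([_condition_index(space, cond)]), params)
    n2, conv = float(n2[0]), float(conv[0])
    if noisy and params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        n2 = float(np.clip(n2 + rng.normal(0.0, params.noise_sd), 0.0, 100.0))
        conv = float(np.clip(conv + rng.normal(0.0, params.noise_sd), 0.0, 100.0))
    return ObjectivePair(conversion=conv, selectivity=n2)


def _campaign_inverse(n2, conv, isomer: str, utopia: UtopiaPoint) -> np.ndarray:
    sel = n2 if isomer == "n2" else 100.0 - n2
    dist = np.hypot(
        utopia.w_sel * (utopia.selectivity - sel), utopia.w_conv * (utopia.conversion - conv)
    )
    return 1.0 / dist


def scan_optimum(
    space: SearchSpace,
    params: SurfaceParams,
    isomer: str,
    utopia: UtopiaPoint | None = None,
    top_k: int = 1,
    chunk: int = 250_000,
) -> list[tuple[int, float]]:
    """Exhaustive chunked scan: top-k (index, inverse distance) on the
    noiseless surface, best first."""
    utopia = utopia or UtopiaPoint()
    card = space.cardinality
    if card > 10_000_000:
        raise ValueError("exhaustive scan limited to spaces of cardinality <= 1e7")
    best: list[tuple[float, int]] = []
    for start in range(0, card, chunk):
        idx = np.arange(start, min(start + chunk, card), dtype=np.int64)
        n2, conv = surface_values(space, idx, params)
        inv = _campaign_inverse(n2, conv, isomer, utopia)
        take = np.argsort(-inv)[: top_k]
        best.extend((float(inv[t]), int(idx[t])) for t in take)
        best.sort(key=lambda p: (-p[0], p[1]))
        best = best[:top_k]
    return [(i, v) for v, i in best]


def ground_truth_optimum(
    params: SurfaceParams,
    space: SearchSpace,
    isomer: str,
    utopia: UtopiaPoint | None = None,
) -> tuple[Condition, ObjectivePair]:
    """Exhaustive argmax of inverse utopia distance on the noiseless surface."""
    utopia = utopia or UtopiaPoint()
    (idx, _), = scan_optimum(space, params, isomer, utopia, top_k=1)
    cond = space.unrank(idx)
    n2, conv = surface_values(space, np.array([idx]), params)
    sel = float(n2[0]) if isomer == "n2" else 100.0 - float(n2[0])
    return cond, ObjectivePair(conversion=float(conv[0]), selectivity=sel)


@dataclass
class SyntheticDataset:
    """A generated campaign dataset plus its generating ground truth."""

    table: pd.DataFrame
    params: SurfaceParams
    space: SearchSpace
    seed: int
    condition_indices: np.ndarray
    noise_sel: np.ndarray
    noise_conv: np.ndarray
    true_optima: dict = field(default_factory=dict)  # isomer -> (Condition, ObjectivePair)

    def conditions(self) -> list[Condition]:
        return [self.space.unrank(int(i)) for i in self.condition_indices]


def generate_campaign_dataset(
    n_rows: int = 248,
    params: SurfaceParams = DEFAULT_PARAMS,
    seed: int = 7,
    space: SearchSpace | None = None,
    n_injected_per_campaign: int = 2,
    candidate_pool: int = 4000,
) -> SyntheticDataset:
    """Generate a campaign-scale dataset over the synthetic surface.

    Rows are drawn from a seeded candidate pool with weights favoring
    mid-range conversion (finished campaigns over-represent plausible but
    unexceptional conditions), then the top ``n_injected_per_campaign``
    conditions of each campaign's noiseless landscape are injected so the
    dataset contains discoverable optima.  Outcomes carry truncated Gaussian
    noise; the recorded draws allow exact regeneration audits.
    """
    space = space or synthetic_space(hydrazine_levels=HYDRAZINE_LEVELS_EXTENDED)
    if n_rows > space.cardinality:
        raise ValueError("n_rows exceeds the space cardinality")
    rng = np.random.default_rng(seed)
    utopia = UtopiaPoint()

    injected: list[int] = []
    true_optima = {}
    for isomer in ("n2", "n1"):
        top = scan_optimum(space, params, isomer, utopia, top_k=max(5, n_injected_per_campaign))
        kept = 0
        for idx, _ in top:
            if kept >= n_injected_per_campaign:
                break
            if idx not in injected:
                injected.append(idx)
                kept += 1
        opt_idx = top[0][0]
        n2, conv = surface_values(space, np.array([opt_idx]), params)
        sel = float(n2[0]) if isomer == "n2" else 100.0 - float(n2[0])
        true_optima[isomer] = (
            space.unrank(opt_idx),
            ObjectivePair(conversion=float(conv[0]), selectivity=sel),
        )

    pool = rng.choice(space.cardinality, size=min(candidate_pool, space.cardinality), replace=False)
    pool = np.array([i for i in pool if i not in set(injected)], dtype=np.int64)
    n2_pool, conv_pool = surface_values(space, pool, params)
    weights = np.exp(-(((conv_pool - 55.0) / 25.0) ** 2)) + 0.1
    weights /= weights.sum()
    n_sampled = n_rows - len(injected)
    chosen = rng.choice(pool, size=n_sampled, replace=False, p=weights)
    indices = np.concatenate([np.asarray(injected, dtype=np.int64), chosen])

    n2, conv = surface_values(space, indices, params)
    noise_sel = rng.normal(0.0, params.noise_sd, size=indices.size) if params.noise_sd else np.zeros(indices.size)
    noise_conv = rng.normal(0.0, params.noise_sd, size=indices.size) if params.noise_sd else np.zeros(indices.size)
    n2_obs = np.clip(n2 + noise_sel, 0.0, 100.0)
    conv_obs = np.clip(conv + noise_conv, 0.0, 100.0)

    raw = _raw_arrays(space, indices)
    solvent_names = np.asarray(space.solvent_variable.levels, dtype=object)[raw["_solvent_idx"]]
    acid = np.where(raw["acid_base_equiv"] > 0, raw["acid_base_equiv"], 0.0)
    base = np.where(raw["acid_base_equiv"] < 0, -raw["acid_base_equiv"], 0.0)
    table = pd.DataFrame(
        {
            "acoh_equiv": acid,
            "naoh_equiv": base,
            "menhnh2_equiv": raw["menhnh2_equiv"],
            "dsi2": raw["dsi2"].astype(int),
            "ptc": raw["ptc"].astype(int),
            "ms": raw["ms"].astype(int),
            "temp_c": raw["temp_c"],
            "vol_ml_per_g": raw["vol_ml_per_g"],
            "solvent": solvent_names,
            "n2_pct": n2_obs,
            "n1_pct": 100.0 - n2_obs,
            "conv_pct": conv_obs,
        }
    )
    return SyntheticDataset(
        table=table,
        params=params,
        space=space,
        seed=seed,
        condition_indices=indices,
        noise_sel=noise_sel,
        noise_conv=noise_conv,
        true_optima=true_optima,
    )


def knorr_like_fixture(seed: int = 7, n_rows: int = 248) -> SyntheticDataset:
    """The canonical campaign-scale benchmark fixture (deterministic per seed)."""
    return generate_campaign_dataset(n_rows=n_rows, params=DEFAULT_PARAMS, seed=seed)
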