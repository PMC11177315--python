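"""Two-objective bookkeeping and utopia-point scalarization.

The optimizer tracks two objectives per reaction, both on a 0–100 percent
scale: **conversion** (product formed) and **selectivity** (share of the
target isomer among the two isomeric products; the two isomer percentages sum
to 100, so selectivity for one campaign is 100 minus the other's).

Scalarization places a deliberately *unreachable* utopia point above the
attainable square — both coordinates exceed 100 % — and scores every
observation by its weighted Euclidean distance to that point.  Unreachability
matters: if any observation could pass the target, points beyond it would
look worse than the target itself and the scalarized objective would no
longer be monotone in the underlying objectives.  Moving the utopia point
further out along one axis up-weights that objective; per-axis weights do the
same thing explicitly.  The quantity the surrogate models actually fit and
maximize is the *inverse* distance, capped so a (mis)configured reachable
point cannot produce an infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

INVERSE_DISTANCE_CAP = 1e6


@dataclass(frozen=True)
class ObjectivePair:
    """(conversion %, target-isomer selectivity %) for one observation."""

    conversion: float
    selectivity: float

    def __post_init__(self):
        for label, v in (("conversion", self.conversion), ("selectivity", self.selectivity)):
            if not math.isfinite(v):
                raise ValueError(f"{label} must be finite, got {v!r}")
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{label} must be in [0, 100], got {v!r}")


def pair_from_percents(conv_pct: float, n1_pct: float, n2_pct: float, isomer: str) -> ObjectivePair:
    """Build an :class:`ObjectivePair` for one campaign from raw table columns."""
    isomer = isomer.lower()
    if isomer not in ("n1", "n2"):
        raise ValueError(f"isomer must be 'n1' or 'n2', got {isomer!r}")
    return ObjectivePair(conv_pct, n1_pct if isomer == "n1" else n2_pct)


@dataclass(frozen=True)
class UtopiaPoint:
    """Unreachable 2-D target; one per isomer campaign.

    Coordinates live on the percent scale and must strictly exceed 100.
    Weights multiply each axis inside the distance, default equal.
    """

    selectivity: float = 110.0
    conversion: float = 110.0
    w_sel: float = 1.0
    w_conv: float = 1.0

    def __post_init__(self):
        if not (self.selectivity > 100.0 and self.conversion > 100.0):
            raise ValueError("utopia coordinates must strictly exceed 100 (unreachable)")
        if not (self.w_sel > 0 and self.w_conv > 0):
            raise ValueError("utopia weights must be positive")


@dataclass(frozen=True)
class ScalarScore:
    distance: float
    inverse_distance: float


def utopia_distance(obj: ObjectivePair, u: UtopiaPoint) -> ScalarScore:
    """Weighted Euclidean distance to the utopia point, plus its capped inverse."""
    d = math.sqrt(
        (u.w_sel * (u.selectivity - obj.selectivity)) ** 2
        + (u.w_conv * (u.conversion - obj.conversion)) ** 2
    )
    inv = INVERSE_DISTANCE_CAP if d < 1.0 / INVERSE_DISTANCE_CAP else 1.0 / d
    return ScalarScore(distance=d, inverse_distance=inv)


def inverse_distance(obj: ObjectivePair, u: UtopiaPoint) -> float:
    return utopia_distance(obj, u).inverse_distance


def _first_front(scores: np.ndarray) -> np.ndarray:
    """Indices of weakly nondominated rows (both columns maximized).

    O(n log n) sweep: sort by first column descending, track the best second
    column over strictly better first columns; within a tie group on the
    first column, only the group's second-column maxima survive.  Duplicated
    points do not dominate each other and are all retained.
    """
    n = scores.shape[0]
    order = np.lexsort((-scores[:, 1], -scores[:, 0]))
    keep = np.zeros(n, dtype=bool)
    best_b = -np.inf  # max second coord among points with strictly greater first coord
    i = 0
    while i < n:
        j = i
        a0 = scores[order[i], 0]
        while j < n and scores[order[j], 0] == a0:
            j += 1
        group = order[i:j]
        group_max_b = scores[group, 1].max()
        for g in group:
            b = scores[g, 1]
            dominated = best_b >= b or b < group_max_b
            keep[g] = not dominated
        best_b = max(best_b, group_max_b)
        i = j
    return np.flatnonzero(keep)


def pareto_front(points) -> np.ndarray:
    """Indices of nondominated objective pairs (maximize both coordinates).

    Accepts an (n, 2) array or a list of :class:`ObjectivePair`.
    """
    if len(points) == 0:
        raise ValueError("pareto_front requires at least one point")
    if isinstance(points[0], ObjectivePair):
        arr = np.array([(p.selectivity, p.conversion) for p in points], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of objective values")
    return _first_front(arr)


def pareto_fronts(scores: np.ndarray, max_points: int | None = None) -> list[np.ndarray]:
    """Successive nondominated fronts; stops once ``max_points`` are ranked."""
    scores = np.asarray(scores, dtype=float)
    remaining = np.arange(scores.shape[0])
    fronts: list[np.ndarray] = []
    ranked = 0
    while remaining.size:
        f = remaining[_first_front(scores[remaining])]
        fronts.append(f)
        ranked += f.size
        if max_points is not None and ranked >= max_points:
            break
        remaining = remaining[np.isin(remaining, f, invert=True)]
    return fronts


def pareto_sort_acquisition(acq_a, acq_b, max_points: int | None = None) -> np.ndarray:
    """Rank candidates by successive nondominated fronts of two acquisition scores.

    Within a front, ties break by descending sum of per-objective ranks
    (average rank for exact ties), then by candidate index — a deterministic
    total order.
    """
    a = np.asarray(acq_a, dtype=float)
    b = np.asarray(acq_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("acquisition score lists must be 1-D and of equal length")
    scores = np.column_stack([a, b])
    ranksum = rankdata(a) + rankdata(b)
    out: list[int] = []
    for front in pareto_fronts(scores, max_points=max_points):
        ordered = sorted(front, key=lambda i: (-ranksum[i], i))
        out.extend(int(i) for i in ordered)
        if max_points is not None and len(out) >= max_points:
            break
    return np.array(out, dtype=int)
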