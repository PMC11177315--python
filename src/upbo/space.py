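"""Mixed reaction-condition search spaces.

A space is an ordered list of variables of three kinds:

* ``boolean`` — a 0/1 switch (e.g. use of an acid catalyst, a phase-transfer
  catalyst, or molecular sieves);
* ``numeric-grid`` — a finite, strictly increasing grid of executable lab
  values (reagent equivalents, temperature in °C, solvent volumes in mL/g).
  Grids rather than continuous ranges are the native representation: every
  proposal must be a condition a chemist can actually run, and realized
  campaign conditions are discrete;
* ``solvent`` — a categorical choice from a named solvent list.  Solvents
  never enter a model by identity: each is replaced by four continuous
  descriptors (COSMO-type parametrization supplied by the user or generated
  synthetically), so surrogate models can generalize across solvents.

Acid and base loadings are combined into one signed axis: excess acid
equivalents are positive, base equivalents negative, zero means neither.

Feature encoding is fixed-length: booleans as 0/1, numeric grids min-max
scaled to [0, 1] (scaling constants live on the space, raw values stay on the
condition), and the solvent replaced by its four descriptors, each min-max
scaled over the solvent table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

BOOLEAN = "boolean"
NUMERIC = "numeric-grid"
SOLVENT = "solvent"
_KINDS = (BOOLEAN, NUMERIC, SOLVENT)

N_SOLVENT_DESCRIPTORS = 4


class SpaceError(ValueError):
    """Invalid search-space definition or use."""


class SolventResolutionError(SpaceError):
    """A solvent name has no descriptor record."""


class EmptySpaceError(SpaceError):
    """A constraint or definition left a variable with no levels."""


def normalize_solvent_name(name: str) -> str:
    """Canonical solvent key: trimmed, case-folded, internal whitespace collapsed."""
    return " ".join(str(name).strip().split()).casefold()


@dataclass(frozen=True)
class VariableSpec:
    """One search variable: its kind and ordered allowed levels."""

    name: str
    kind: str
    levels: tuple
    unit: str | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise SpaceError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        object.__setattr__(self, "levels", tuple(self.levels))
        if not self.levels:
            raise EmptySpaceError(f"variable {self.name!r} has no levels")
        if self.kind == BOOLEAN:
            if not set(self.levels) <= {0, 1}:
                raise SpaceError(f"boolean variable {self.name!r} levels must be 0/1")
        if self.kind == NUMERIC:
            arr = [float(v) for v in self.levels]
            if any(not math.isfinite(v) for v in arr):
                raise SpaceError(f"non-finite level in {self.name!r}")
            if any(b <= a for a, b in zip(arr, arr[1:])):
                raise SpaceError(
                    f"numeric-grid levels of {self.name!r} must be strictly increasing"
                )
            object.__setattr__(self, "levels", tuple(arr))
        if len(set(self.levels)) != len(self.levels):
            raise SpaceError(f"duplicate levels in variable {self.name!r}")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class SolventRecord:
    """A solvent with its four continuous descriptors."""

    name: str
    descriptors: tuple[float, float, float, float]

    def __post_init__(self):
        desc = tuple(float(d) for d in self.descriptors)
        if len(desc) != N_SOLVENT_DESCRIPTORS:
            raise SpaceError(
                f"solvent {self.name!r} must have exactly {N_SOLVENT_DESCRIPTORS} "
                f"descriptors, got {len(desc)}"
            )
        if any(not math.isfinite(d) for d in desc):
            raise SpaceError(f"non-finite descriptor for solvent {self.name!r}")
        object.__setattr__(self, "descriptors", desc)


@dataclass(frozen=True)
class Condition:
    """One full assignment of all search variables, keyed by variable name.

    Hashable and canonical (items sorted by variable name) so conditions can
    be deduplicated and used as lookup-oracle keys regardless of how they
    were built.
    """

    items: tuple[tuple[str, object], ...]

    def __post_init__(self):
        object.__setattr__(
            self, "items", tuple(sorted(self.items, key=lambda kv: kv[0]))
        )

    @classmethod
    def from_dict(cls, values: Mapping[str, object]) -> "Condition":
        return cls(tuple(values.items()))

    def __getitem__(self, key: str):
        for k, v in self.items:
            if k == key:
                return v
        raise KeyError(key)

    def as_dict(self) -> dict:
        return dict(self.items)

    def replace_value(self, key: str, value) -> "Condition":
        return Condition(tuple((k, value if k == key else v) for k, v in self.items))


def acid_base_axis(acid_equiv: float, base_equiv: float) -> float:
    """Collapse acid/base loadings onto one signed axis.

    Excess acid equivalents are positive, base equivalents negative; a
    condition uses acid or base, never both.
    """
    acid_equiv = float(acid_equiv)
    base_equiv = float(base_equiv)
    if acid_equiv < 0 or base_equiv < 0:
        raise SpaceError("acid/base equivalents must be nonnegative")
    if acid_equiv > 0 and base_equiv > 0:
        raise SpaceError("condition cannot use both acid and base")
    return acid_equiv if acid_equiv > 0 else -base_equiv


def split_acid_base(axis: float) -> tuple[float, float]:
    """Inverse of :func:`acid_base_axis`: signed value -> (acid, base) pair."""
    axis = float(axis)
    return (axis, 0.0) if axis > 0 else (0.0, -axis)


def _minmax(levels: Sequence[float]) -> tuple[float, float]:
    lo, hi = min(levels), max(levels)
    return float(lo), float(hi)


@dataclass(frozen=True)
class SearchSpace:
    """An ordered set of variables plus the solvent descriptor table.

    Exactly one variable has kind ``solvent``; every one of its levels must
    resolve to a :class:`SolventRecord`.  The space owns the min-max scaling
    constants used by :meth:`encode`.
    """

    variables: tuple[VariableSpec, ...]
    solvent_table: Mapping[str, SolventRecord]

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        solvent_vars = [v for v in self.variables if v.kind == SOLVENT]
        if len(solvent_vars) != 1:
            raise SpaceError(
                f"space must contain exactly one solvent variable, got {len(solvent_vars)}"
            )
        table = {normalize_solvent_name(k): v for k, v in self.solvent_table.items()}
        object.__setattr__(self, "solvent_table", table)
        for name in solvent_vars[0].levels:
            if normalize_solvent_name(name) not in table:
                raise SolventResolutionError(f"solvent {name!r} has no descriptor record")
        # descriptor scaling constants over the table
        desc = np.array([r.descriptors for r in table.values()], dtype=float)
        object.__setattr__(self, "_desc_lo", desc.min(axis=0))
        object.__setattr__(self, "_desc_hi", desc.max(axis=0))

    # -- structure ---------------------------------------------------------

    @property
    def solvent_variable(self) -> VariableSpec:
        return next(v for v in self.variables if v.kind == SOLVENT)

    @property
    def cardinality(self) -> int:
        n = 1
        for v in self.variables:
            n *= v.n_levels
        return n

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise SpaceError(f"no variable named {name!r}")

    def solvent_record(self, name: str) -> SolventRecord:
        try:
            return self.solvent_table[normalize_solvent_name(name)]
        except KeyError:
            raise SolventResolutionError(f"solvent {name!r} has no descriptor record")

    def contains(self, cond: Condition) -> bool:
        try:
            for v in self.variables:
                if cond[v.name] not in v.levels:
                    return False
        except KeyError:
            return False
        return True

    # -- encoding ----------------------------------------------------------

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for v in self.variables:
            if v.kind == SOLVENT:
                names.extend(f"{v.name}_d{i + 1}" for i in range(N_SOLVENT_DESCRIPTORS))
            else:
                names.append(v.name)
        return names

    def feature_groups(self) -> list[tuple[str, list[int]]]:
        """Importance groups: each scalar feature alone, solvent block joint."""
        groups: list[tuple[str, list[int]]] = []
        col = 0
        for v in self.variables:
            if v.kind == SOLVENT:
                groups.append((v.name, list(range(col, col + N_SOLVENT_DESCRIPTORS))))
                col += N_SOLVENT_DESCRIPTORS
            else:
                groups.append((v.name, [col]))
                col += 1
        return groups

    @property
    def n_features(self) -> int:
        return len(self.variables) - 1 + N_SOLVENT_DESCRIPTORS

    def encode(self, cond: Condition) -> np.ndarray:
        """Fixed-length numeric feature vector for one condition."""
        out = np.empty(self.n_features, dtype=float)
        i = 0
        for v in self.variables:
            if v.kind == BOOLEAN:
                out[i] = float(cond[v.name])
                i += 1
            elif v.kind == NUMERIC:
                lo, hi = _minmax(v.levels)
                x = float(cond[v.name])
                out[i] = 0.0 if hi == lo else (x - lo) / (hi - lo)
                i += 1
            else:
                rec = self.solvent_record(cond[v.name])
                d = np.asarray(rec.descriptors, dtype=float)
                span = np.where(self._desc_hi > self._desc_lo, self._desc_hi - self._desc_lo, 1.0)
                out[i : i + N_SOLVENT_DESCRIPTORS] = (d - self._desc_lo) / span
                i += N_SOLVENT_DESCRIPTORS
        return out

    def encode_many(self, conds: Sequence[Condition]) -> np.ndarray:
        return np.array([self.encode(c) for c in conds], dtype=float)

    def decode(self, vec: np.ndarray) -> Condition:
        """Invert :meth:`encode`; numerics snap to the nearest grid level,
        the solvent resolves to the nearest descriptor record."""
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_features,):
            raise SpaceError(f"expected feature vector of length {self.n_features}")
        values: dict[str, object] = {}
        i = 0
        for v in self.variables:
            if v.kind == BOOLEAN:
                values[v.name] = int(round(vec[i]))
                i += 1
            elif v.kind == NUMERIC:
                lo, hi = _minmax(v.levels)
                raw = lo if hi == lo else lo + vec[i] * (hi - lo)
                values[v.name] = min(v.levels, key=lambda lv: abs(lv - raw))
                i += 1
            else:
                span = np.where(self._desc_hi > self._desc_lo, self._desc_hi - self._desc_lo, 1.0)
                d = vec[i : i + N_SOLVENT_DESCRIPTORS] * span + self._desc_lo
                best = None
                best_dist = math.inf
                for name in v.levels:
                    rec = self.solvent_record(name)
                    dist = float(np.sum((np.asarray(rec.descriptors) - d) ** 2))
                    if dist < best_dist:
                        best, best_dist = name, dist
                values[v.name] = best
                i += N_SOLVENT_DESCRIPTORS
        return Condition.from_dict(values)

    # -- enumeration -------------------------------------------------------

    def unrank(self, index: int) -> Condition:
        """Condition at a mixed-radix index (last variable varies fastest)."""
        if not 0 <= index < self.cardinality:
            raise SpaceError(f"index {index} out of range for cardinality {self.cardinality}")
        values: list[tuple[str, object]] = []
        for v in reversed(self.variables):
            index, digit = divmod(index, v.n_levels)
            values.append((v.name, v.levels[digit]))
        return Condition(tuple(reversed(values)))

    def enumerate_candidates(
        self, subsample: int | None = None, seed: int | None = None
    ) -> Iterator[Condition]:
        """Stream distinct conditions; memory use is flat in the cardinality.

        Without ``subsample`` every condition is yielded exactly once.  With
        ``subsample=n`` a seeded uniform sample of n distinct conditions is
        drawn (by sampling mixed-radix indices without replacement).
        """
        card = self.cardinality
        if card == 0:
            raise EmptySpaceError("cannot enumerate an empty space")
        if subsample is None:
            names = [v.name for v in self.variables]
            for combo in itertools.product(*(v.levels for v in self.variables)):
                yield Condition(tuple(zip(names, combo)))
            return
        if subsample > card:
            raise SpaceError(f"subsample {subsample} exceeds cardinality {card}")
        rng = np.random.default_rng(seed)
        if card <= 10_000_000:
            idx = rng.choice(card, size=subsample, replace=False)
        else:  # rejection sampling keeps memory flat for astronomically large spaces
            seen: set[int] = set()
            idx = []
            while len(idx) < subsample:
                j = int(rng.integers(card))
                if j not in seen:
                    seen.add(j)
                    idx.append(j)
        for j in idx:
            yield self.unrank(int(j))


def apply_constraint(
    space: SearchSpace, variable: str, new_levels: Sequence
) -> SearchSpace:
    """Replace one variable's levels, returning a new space.

    Used for mid-campaign interventions such as relaxing the hydrazine
    equivalents cap from 5 to 20.  Existing observations are never deleted:
    callers flag them with :func:`flag_out_of_space` and keep them for model
    fitting while excluding them as proposal candidates.
    """
    var = space.variable(variable)
    if not list(new_levels):
        raise EmptySpaceError(f"constraint leaves {variable!r} with no levels")
    new_var = VariableSpec(var.name, var.kind, tuple(new_levels), var.unit)
    variables = tuple(new_var if v.name == variable else v for v in space.variables)
    return SearchSpace(variables, space.solvent_table)


def flag_out_of_space(space: SearchSpace, conds: Iterable[Condition]) -> list[bool]:
    """True for each condition not representable in the (possibly constrained) space."""
    return [not space.contains(c) for c in conds]


def grid(lo: float, hi: float, step: float) -> tuple[float, ...]:
    """Inclusive numeric grid from lo to hi with the given step."""
    if step <= 0:
        raise SpaceError("grid step must be positive")
    n = int(round((hi - lo) / step))
    levels = tuple(float(lo + k * step) for k in range(n + 1))
    if levels[-1] > hi + 1e-9:
        levels = levels[:-1]
    return levels


def define_space(config: Mapping, solvent_table: Mapping[str, SolventRecord]) -> SearchSpace:
    """Build a :class:`SearchSpace` from a configuration fragment.

    ``config["variables"]`` is an ordered list of per-variable mappings with a
    ``kind`` and either explicit ``levels`` or ``min``/``max``/``step`` bounds;
    the solvent variable's levels default to every solvent in the table.
    """
    variables = []
    for spec in config["variables"]:
        kind = spec["kind"]
        name = spec["name"]
        unit = spec.get("unit")
        if kind == BOOLEAN:
            levels = tuple(spec.get("levels", (0, 1)))
        elif kind == NUMERIC:
            if "levels" in spec:
                levels = tuple(float(v) for v in spec["levels"])
            else:
                levels = grid(float(spec["min"]), float(spec["max"]), float(spec["step"]))
        elif kind == SOLVENT:
            levels = tuple(spec.get("levels") or (r.name for r in solvent_table.values()))
            for lv in levels:
                if normalize_solvent_name(lv) not in {
                    normalize_solvent_name(k) for k in solvent_table
                }:
                    raise SolventResolutionError(f"solvent {lv!r} has no descriptor record")
        else:
            raise SpaceError(f"unknown variable kind {kind!r}")
        if not levels:
            raise EmptySpaceError(f"variable {name!r} has no levels after bounding")
        variables.append(VariableSpec(name, kind, levels, unit))
    return SearchSpace(tuple(variables), dict(solvent_table))
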