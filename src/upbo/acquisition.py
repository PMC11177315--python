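"""Acquisition functions and strategy labels.

Two acquisition rules convert a surrogate's mean/uncertainty into a
candidate score:

* **UCB** (upper confidence bound), ``mean + kappa * std`` — exploratory,
  rewarding regions of high model uncertainty;
* **EI** (expected improvement), the expectation of ``max(0, Y - best - xi)``
  under ``Y ~ Normal(mean, std^2)`` — exploitative, rewarding predicted
  improvement over the incumbent with exploration offset ``xi``.

A strategy is a (surrogate family, acquisition, campaign isomer) triple
rendered as ``<family>_<acq>_<param>_<isomer>`` (e.g. ``GPR_ucb_2_n2``,
``RFR_ei_05_n1``): the label scheme used to tag each proposed condition with
the model/acquisition pair that claimed it.  The shipped parameter readings
are kappa = 2 for ``ucb_2`` and xi = 0.05 for ``ei_05``, both overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

ACQ_TYPES = ("ei", "ucb")
DEFAULT_KAPPA = 2.0
DEFAULT_XI = 0.05


def ucb(mean, std, kappa: float) -> np.ndarray:
    """Upper confidence bound score: mean + kappa * std (vectorized)."""
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    return np.asarray(mean, dtype=float) + kappa * np.asarray(std, dtype=float)


def ei(mean, std, best_observed: float, xi: float) -> np.ndarray:
    """Expected improvement over ``best_observed`` for maximization.

    With z = (mean - best - xi) / std:
    EI = (mean - best - xi) * Phi(z) + std * phi(z); the std -> 0 limit is
    max(0, mean - best - xi).
    """
    if xi < 0:
        raise ValueError("xi must be nonnegative")
    scalar = np.ndim(mean) == 0 and np.ndim(std) == 0
    mean, std = np.broadcast_arrays(
        np.atleast_1d(np.asarray(mean, dtype=float)),
        np.atleast_1d(np.asarray(std, dtype=float)),
    )
    if np.any(std < 0):
        raise ValueError("std must be nonnegative")
    delta = mean - best_observed - xi
    out = np.maximum(delta, 0.0)  # std == 0 limit
    pos = std > 0
    if np.any(pos):
        z = delta[pos] / std[pos]
        out = out.copy()
        out[pos] = delta[pos] * norm.cdf(z) + std[pos] * norm.pdf(z)
    return float(out[0]) if scalar else out


def score(acq_type: str, mean, std, parameter: float, best_observed: float | None = None):
    """Dispatch on acquisition type; EI requires ``best_observed``."""
    if acq_type == "ucb":
        return ucb(mean, std, parameter)
    if acq_type == "ei":
        if best_observed is None:
            raise ValueError("EI requires the incumbent best observed value")
        return ei(mean, std, best_observed, parameter)
    raise ValueError(f"unknown acquisition type {acq_type!r}")


def _param_token(p: float) -> str:
    if p == int(p):
        return str(int(p))
    s = f"{p:g}"
    # drop a leading "0." only when the remainder still starts with a zero,
    # so 0.05 -> "05" but 0.5 stays "0.5" (stripping would collide with 5)
    if s.startswith("0.") and s[2] == "0":
        return s[2:]
    return s


def _parse_param_token(tok: str) -> float:
    if "." in tok:
        return float(tok)
    if tok.startswith("0") and len(tok) > 1:
        return float("0." + tok)
    return float(int(tok))


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition type plus its tuning parameter (kappa for UCB, xi for EI)."""

    type: str
    parameter: float

    def __post_init__(self):
        if self.type not in ACQ_TYPES:
            raise ValueError(f"acquisition type must be one of {ACQ_TYPES}")
        if self.parameter < 0:
            raise ValueError("acquisition parameter must be nonnegative")


@dataclass(frozen=True)
class StrategyLabel:
    """(family, acquisition, parameter, isomer) rendered Table-style."""

    family: str
    acq_type: str
    parameter: float
    isomer: str

    def render(self) -> str:
        return f"{self.family}_{self.acq_type}_{_param_token(self.parameter)}_{self.isomer}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @property
    def acquisition(self) -> AcquisitionSpec:
        return AcquisitionSpec(self.acq_type, self.parameter)

    @classmethod
    def parse(cls, label: str) -> "StrategyLabel":
        parts = label.split("_")
        if len(parts) != 4:
            raise ValueError(f"cannot parse strategy label {label!r}")
        family, acq_type, tok, isomer = parts
        if acq_type not in ACQ_TYPES:
            raise ValueError(f"unknown acquisition type in label {label!r}")
        if isomer.lower() not in ("n1", "n2"):
            raise ValueError(f"unknown isomer in label {label!r}")
        return cls(family, acq_type, _parse_param_token(tok), isomer.lower())


def strategy_grid(families, acqs, isomer: str) -> list[StrategyLabel]:
    """Cartesian product of families and acquisition specs, families-major order."""
    families = list(families)
    acqs = list(acqs)
    if not families or not acqs:
        raise ValueError("families and acquisitions must be non-empty")
    return [
        StrategyLabel(fam, acq.type, acq.parameter, isomer)
        for fam in families
        for acq in acqs
    ]


def default_acquisitions() -> list[AcquisitionSpec]:
    """The campaign's exploit/explore pair: EI(xi=0.05) and UCB(kappa=2)."""
    return [AcquisitionSpec("ei", DEFAULT_XI), AcquisitionSpec("ucb", DEFAULT_KAPPA)]
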