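"""Incidence-frequency bookkeeping and sample-coverage estimation.

An assemblage sampled with ``T`` replicated units (here 8 collection times
x 2 size fractions = 16) is summarised by the incidence frequency ``Y_i`` of
each species: the number of units in which it was detected.  Sample coverage
-- the estimated fraction of all incidences in the assemblage attributable
to the detected species -- is the Good-Turing quantity that the singleton
(Q1) and doubleton (Q2) counts estimate, and is the yardstick on which all
between-plot comparisons in this package are standardised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _rarefy
from ._rarefy import freq_histogram

__all__ = [
    "IncidenceAssemblage",
    "EffortResult",
    "frequency_counts",
    "coverage_full",
    "coverage_rarefied",
    "coverage_extrapolated",
    "effort_for_coverage",
]


@dataclass(frozen=True)
class IncidenceAssemblage:
    """One assemblage's per-species incidence frequencies out of ``T`` units.

    Parameters
    ----------
    T : number of sampling units.
    Y : integer frequency vector, one entry per species, each in ``[0, T]``.
    """

    T: int
    Y: np.ndarray
    hist: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be a positive integer")
        Y = np.asarray(self.Y)
        if Y.size and not np.issubdtype(Y.dtype, np.integer):
            if not np.allclose(Y, np.round(Y)):
                raise ValueError("incidence frequencies must be integers")
            Y = np.round(Y).astype(int)
        object.__setattr__(self, "Y", Y.astype(int))
        object.__setattr__(self, "hist", freq_histogram(self.Y, self.T))

    @classmethod
    def from_units(cls, detections: np.ndarray) -> "IncidenceAssemblage":
        """Build from a species x units binary detection matrix."""
        det = np.asarray(detections)
        if det.ndim != 2:
            raise ValueError("detection matrix must be species x units")
        if np.any((det != 0) & (det != 1)):
            raise ValueError("detection matrix must be binary")
        return cls(T=det.shape[1], Y=det.sum(axis=1).astype(int))

    @property
    def S_obs(self) -> int:
        return int(np.count_nonzero(self.Y))

    @property
    def U(self) -> int:
        """Total number of incidences."""
        return int(self.Y.sum())

    def Q(self, k: int) -> int:
        """Number of species with incidence frequency exactly ``k``."""
        return int(self.hist[k]) if 1 <= k <= self.T else 0

    @property
    def relative_frequencies(self) -> np.ndarray:
        """pi_i = Y_i / U over detected species."""
        if self.U == 0:
            raise ValueError("relative frequencies undefined for U = 0")
        y = self.Y[self.Y > 0]
        return y / y.sum()


@dataclass(frozen=True)
class EffortResult:
    """Sampling effort matching a coverage target."""

    t: float
    side: str  # "rarefy" | "none" | "extrapolate"
    coverage: float


def frequency_counts(asm: IncidenceAssemblage) -> tuple[int, int, int, int]:
    """Return ``(S_obs, U, Q1, Q2)``."""
    return asm.S_obs, asm.U, asm.Q(1), asm.Q(2)


def _require_nonempty(asm: IncidenceAssemblage):
    if asm.U == 0:
        raise ValueError("sample coverage is undefined for an empty assemblage")


def coverage_full(asm: IncidenceAssemblage) -> float:
    """Good-Turing sample coverage of the full T-unit sample.

    ``C = 1 - (Q1/U) * (T-1)Q1 / ((T-1)Q1 + 2 Q2)``; 1 when there are no
    singletons.
    """
    _require_nonempty(asm)
    return float(_rarefy.coverage_at(asm.hist, asm.T, float(asm.T))[0])


def coverage_rarefied(asm: IncidenceAssemblage, t: float) -> float:
    """Expected coverage of a subsample of ``t < T`` units (real-valued)."""
    _require_nonempty(asm)
    if not (0 < t < asm.T):
        raise ValueError("rarefied coverage requires 0 < t < T")
    return float(_rarefy.coverage_at(asm.hist, asm.T, float(t))[0])


def coverage_extrapolated(asm: IncidenceAssemblage, t_star: float) -> float:
    """Coverage extrapolated to ``T + t_star`` units (``t_star >= 0``).

    ``t_star = 0`` reproduces :func:`coverage_full` exactly; the limit
    ``t_star -> inf`` is 1 (as long as doubletons support the rate).
    """
    _require_nonempty(asm)
    if t_star < 0:
        raise ValueError("t_star must be >= 0")
    return float(_rarefy.coverage_at(asm.hist, asm.T, asm.T + float(t_star))[0])


def effort_for_coverage(
    asm: IncidenceAssemblage, C_target: float, tol: float = 1e-6
) -> EffortResult:
    """Invert the (piecewise) coverage curve for a target in (0, 1).

    The curve is the rarefaction estimator below ``T`` and the geometric
    extrapolation above; it is monotone non-decreasing with an upward jump
    at ``T`` (from ``1 - Q1/U`` to the full-sample estimator).  Targets
    inside that jump are mapped to ``t = T`` with side ``"none"``.
    """
    _require_nonempty(asm)
    if not (0.0 < C_target < 1.0):
        raise ValueError(
            "coverage target must be in (0, 1); a target of 1 is unreachable "
            "whenever singletons remain"
        )
    t, side = _rarefy.effort_for_coverage_hist(asm.hist, asm.T, C_target, tol=tol)
    names = {-1: "rarefy", 0: "none", 1: "extrapolate"}
    cov = float(_rarefy.coverage_at(asm.hist, asm.T, t)[0])
    return EffortResult(t=float(t[0]), side=names[int(side[0])], coverage=cov)
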