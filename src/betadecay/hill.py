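"""Hill numbers for incidence data and coverage-standardised pair similarity.

The diversity of order q of an assemblage with relative incidence
frequencies pi_i = Y_i / U is

    qD = (sum_i pi_i^q)^(1/(1-q)),     1D = exp(-sum_i pi_i ln pi_i).

For a plot pair, gamma diversity comes from the pooled sample, alpha from
the concatenated per-plot frequencies normalised by the pooled number of
incidences, and beta = gamma/alpha in [1, 2] maps to a Sorensen-type
overlap C_qN (or Jaccard-type U_qN) in [0, 1].

Coverage standardisation evaluates gamma and alpha not at the observed
effort but at the effort where the pooled sample attains a common coverage
target, removing the detection-completeness bias that otherwise inflates
beta-diversity of under-sampled plots.  The pooled sample of a pair is the
unit-wise union of detections (the sampling-unit labels -- collection time
x size fraction -- are shared across plots), the alpha sample stacks the
two plots' frequency lists over the same units, and both are evaluated at
one common effort found on the pooled coverage curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _rarefy
from .dataset import UnitIncidence
from .incidence import IncidenceAssemblage

__all__ = [
    "hill_incidence",
    "hill_at_effort",
    "sorensen_transform",
    "PairDecomposition",
    "pair_decompose",
    "standardized_pair_similarity",
    "pairwise_similarity",
    "SimilarityMatrix",
    "similarity_matrices",
    "default_subsets",
]

logger = logging.getLogger(__name__)

_BETA_CLIP_WARN = 1e-6


def _hill_from_pi(pi: np.ndarray, q: float) -> float:
    pi = pi[pi > 0]
    if q == 0:
        return float(pi.size)
    if q == 1:
        return float(np.exp(-np.sum(pi * np.log(pi))))
    return float(np.sum(pi**q) ** (1.0 / (1.0 - q)))


def hill_incidence(asm: IncidenceAssemblage, q: float) -> float:
    """Incidence-based Hill number of order q (q = 0 gives S_obs)."""
    if asm.U == 0:
        raise ValueError("Hill number undefined for an empty assemblage")
    if q < 0:
        raise ValueError("diversity order must be non-negative")
    return _hill_from_pi(asm.relative_frequencies, q)


def hill_at_effort(asm: IncidenceAssemblage, q: float, t: float) -> float:
    """Rarefied (t <= T) or extrapolated (t > T) Hill number."""
    if asm.U == 0:
        raise ValueError("Hill number undefined for an empty assemblage")
    return float(_rarefy.hill_at_effort_hist(asm.hist, asm.T, float(t), q)[0])


def sorensen_transform(
    beta: float, q: float, N: int = 2, variant: str = "sorensen", tol: float = 1e-8
) -> float:
    """Map beta in [1, N] to a similarity in [0, 1].

    Sorensen-type: C_qN = [(1/beta)^(q-1) - (1/N)^(q-1)] / [1 - (1/N)^(q-1)]
    Jaccard-type:  U_qN = [(1/beta)^(1-q) - (1/N)^(1-q)] / [1 - (1/N)^(1-q)]
    with the shared q -> 1 limit 1 - ln(beta)/ln(N).
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if beta < 1.0 - tol or beta > N + tol:
        raise ValueError(f"beta = {beta} outside [1, {N}]")
    beta = min(max(beta, 1.0), float(N))
    if variant not in ("sorensen", "jaccard"):
        raise ValueError("variant must be 'sorensen' or 'jaccard'")
    if q == 1:
        return 1.0 - np.log(beta) / np.log(N)
    e = (q - 1.0) if variant == "sorensen" else (1.0 - q)
    return float(((1.0 / beta) ** e - (1.0 / N) ** e) / (1.0 - (1.0 / N) ** e))


@dataclass(frozen=True)
class PairDecomposition:
    q: float
    gamma: float
    alpha: float
    beta: float
    similarity: float
    N: int = 2


def pair_decompose(
    A: IncidenceAssemblage,
    B: IncidenceAssemblage,
    q: float,
    variant: str = "sorensen",
) -> PairDecomposition:
    """Gamma/alpha/beta decomposition of a plot pair at observed effort.

    Gamma is the Hill number of the pooled species x 2T incidence table
    (frequencies Y_A + Y_B); alpha is half the Hill number of the
    concatenated frequency list normalised by the pooled U.  The two
    frequency vectors must be aligned on a shared species universe.
    """
    if A.T != B.T:
        raise ValueError("assemblages must share the number of sampling units")
    if len(A.Y) != len(B.Y):
        raise ValueError("assemblages must share a species universe")
    U_pool = A.U + B.U
    if U_pool == 0:
        raise ValueError("both assemblages are empty")
    gamma = _hill_from_pi((A.Y + B.Y) / U_pool, q)
    alpha = _hill_from_pi(np.concatenate([A.Y, B.Y]) / U_pool, q) / 2.0
    beta = _clip_beta(gamma / alpha)
    return PairDecomposition(
        q=q,
        gamma=gamma,
        alpha=alpha,
        beta=beta,
        similarity=sorensen_transform(beta, q, 2, variant),
    )


def _clip_beta(beta, n: int = 2):
    b = np.asarray(beta, dtype=float)
    worst = max(np.max(1.0 - b, initial=0.0), np.max(b - n, initial=0.0))
    if worst > _BETA_CLIP_WARN:
        warnings.warn(
            f"beta outside [1, {n}] by {worst:.2e}; clipping", RuntimeWarning
        )
    clipped = np.clip(b, 1.0, float(n))
    return float(clipped) if np.isscalar(beta) else clipped


def _pair_hists(det_A: np.ndarray, det_B: np.ndarray, T: int):
    """(gamma_hist, alpha_hist) for one pair of species x T matrices."""
    Yu = (det_A | det_B).sum(axis=1)
    Ya, Yb = det_A.sum(axis=1), det_B.sum(axis=1)
    gh = _rarefy.freq_histogram(Yu, T)
    ah = _rarefy.freq_histogram(Ya, T) + _rarefy.freq_histogram(Yb, T)
    return gh, ah


def standardized_pair_similarity(
    det_A: np.ndarray,
    det_B: np.ndarray,
    q: float,
    C_target: float,
    variant: str = "sorensen",
) -> float:
    """Coverage-standardised pair similarity from unit-level detections.

    ``det_A`` and ``det_B`` are species x T binary matrices over the same
    species universe and the same (matched) sampling units.  Both gamma
    (unit-wise union) and alpha (stacked) components are evaluated at the
    effort where the pooled sample's coverage equals ``C_target``.
    """
    det_A = np.asarray(det_A, dtype=np.uint8)
    det_B = np.asarray(det_B, dtype=np.uint8)
    if det_A.shape != det_B.shape:
        raise ValueError("detection matrices must have identical shape")
    T = det_A.shape[1]
    gh, ah = _pair_hists(det_A.astype(bool), det_B.astype(bool), T)
    t, _ = _rarefy.effort_for_coverage_hist(gh, T, C_target)
    gamma = _rarefy.hill_at_effort_hist(gh, T, t, q)[0]
    alpha = 0.5 * _rarefy.hill_at_effort_hist(ah, T, t, q)[0]
    beta = _clip_beta(float(gamma / alpha))
    return sorensen_transform(beta, q, 2, variant)


def pairwise_similarity(
    inc: UnitIncidence,
    q_list=(0, 1, 2),
    C_target: float = 0.8,
    variant: str = "sorensen",
) -> dict[float, pd.DataFrame]:
    """All-pairs coverage-standardised similarity matrices, one per order.

    Vectorised over plot pairs: every estimator needed depends on a pair
    only through the gamma (union) and alpha (stacked) frequency
    histograms, so the pair loop reduces to histogram algebra.  All plots
    must be non-empty (see :func:`similarity_matrices` for the dropping
    logic).
    """
    X = inc.detections.astype(bool)  # (S, P, T)
    S, P, T = X.shape
    if P < 2:
        raise ValueError("need at least two plots")
    Y = X.sum(axis=2, dtype=np.int16)  # (S, P)
    if np.any(Y.sum(axis=0) == 0):
        raise ValueError("empty plots must be excluded before pairing")

    plot_hist = np.zeros((P, T + 1))
    for k in range(1, T + 1):
        plot_hist[:, k] = (Y == k).sum(axis=0)

    iu, ju = np.triu_indices(P, k=1)
    n_pairs = iu.size
    gamma_hist = np.zeros((n_pairs, T + 1))
    pos = 0
    for i in range(P - 1):
        block = slice(pos, pos + (P - 1 - i))
        inter = (X[:, i : i + 1, :] & X[:, i + 1 :, :]).sum(axis=2, dtype=np.int16)
        Yu = Y[:, i : i + 1] + Y[:, i + 1 :] - inter  # (S, P-1-i)
        for k in range(1, T + 1):
            gamma_hist[block, k] = (Yu == k).sum(axis=0)
        pos += P - 1 - i
    alpha_hist = plot_hist[iu] + plot_hist[ju]

    t, _ = _rarefy.effort_for_coverage_hist(gamma_hist, T, C_target)

    out = {}
    for q in q_list:
        gamma = _rarefy.hill_at_effort_hist(gamma_hist, T, t, q)
        alpha = 0.5 * _rarefy.hill_at_effort_hist(alpha_hist, T, t, q)
        beta = _clip_beta(gamma / alpha)
        if q == 1:
            sim = 1.0 - np.log(beta) / np.log(2.0)
        else:
            e = (q - 1.0) if variant == "sorensen" else (1.0 - q)
            sim = ((1.0 / beta) ** e - 0.5**e) / (1.0 - 0.5**e)
        M = np.eye(P)
        M[iu, ju] = sim
        M[ju, iu] = sim
        out[q] = pd.DataFrame(M, index=inc.plots, columns=inc.plots)
    return out


@dataclass
class SimilarityMatrix:
    """Symmetric plot x plot similarity matrix for one (subset, q)."""

    values: pd.DataFrame
    q: float
    C_target: float
    subset: str
    variant: str = "sorensen"
    dropped_plots: list = field(default_factory=list)

    def filename(self) -> str:
        return f"sim_{self.subset}_q{self.q:g}_C{self.C_target:g}.csv"

    def pairs(self) -> pd.DataFrame:
        """Upper-triangle long form: plot_a, plot_b, similarity."""
        m = self.values
        iu, ju = np.triu_indices(len(m), k=1)
        return pd.DataFrame(
            {
                "plot_a": m.index[iu],
                "plot_b": m.columns[ju],
                "similarity": m.to_numpy()[iu, ju],
            }
        )


def default_subsets(traits: pd.DataFrame | None) -> dict[str, pd.Index | None]:
    """The seven community subsets of the default analysis.

    'all' plus the three body-size classes and the three mobility classes;
    ``None`` marks the unrestricted community.
    """
    subsets: dict[str, pd.Index | None] = {"all": None}
    if traits is not None:
        for cls in ("small", "intermediate", "large"):
            subsets[f"size_{cls}"] = pd.Index(
                traits.loc[traits["size_class"] == cls, "species_id"]
            )
        for mob, label in ((1, "low"), (2, "medium"), (3, "high")):
            subsets[f"mobility_{label}"] = pd.Index(
                traits.loc[traits["mobility"] == mob, "species_id"]
            )
    return subsets


def similarity_matrices(
    inc: UnitIncidence,
    traits: pd.DataFrame | None = None,
    subsets: dict[str, pd.Index | None] | None = None,
    q_list=(0, 1, 2),
    C_all: float = 0.8,
    C_traits: float = 0.7,
    variant: str = "sorensen",
) -> list[SimilarityMatrix]:
    """One coverage-standardised similarity matrix per (subset, order).

    The default configuration (7 subsets x 3 orders) yields 21 matrices.
    Subsets with fewer than two non-empty plots are skipped with a logged
    warning; empty plots within a subset are dropped and recorded.
    """
    if subsets is None:
        subsets = default_subsets(traits)
    out: list[SimilarityMatrix] = []
    for label, species in subsets.items():
        sub = inc if species is None else inc.subset_species(
            inc.species.intersection(species)
        )
        C = C_all if label == "all" else C_traits
        keep = sub.nonempty_plots()
        dropped = [p for p in sub.plots if p not in set(keep)]
        if len(keep) < 2:
            logger.warning(
                "subset %s has %d non-empty plots; skipping", label, len(keep)
            )
            continue
        if dropped:
            logger.warning(
                "subset %s: dropping %d empty plots", label, len(dropped)
            )
            sub = sub.select_plots(keep)
        mats = pairwise_similarity(sub, q_list=q_list, C_target=C, variant=variant)
        for q in q_list:
            out.append(
                SimilarityMatrix(
                    values=mats[q],
                    q=q,
                    C_target=C,
                    subset=label,
                    variant=variant,
                    dropped_plots=dropped,
                )
            )
    return out
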