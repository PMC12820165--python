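"""Distance-decay regressions, permutation slope contrasts, landscape deltas.

A distance-decay relationship regresses pairwise community similarity on
pairwise geographic distance (km); the slope's magnitude measures spatial
heterogeneity (steep = heterogeneous, flat = homogenised).  Slopes of two
groups are compared with a randomisation test that re-partitions the
pooled (distance, similarity) pairs, and a land-use's slope inside one
regional landscape is compared with its overall slope via the delta
|slope_within| - |slope_overall| (positive = the landscape heterogenises).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "geo_distance_matrix",
    "decay_pairs",
    "DecayFit",
    "fit_decay",
    "SlopeContrast",
    "diffslope_permutation",
    "adjust_pvalues",
    "landscape_delta",
]

EARTH_RADIUS_KM = 6371.0


def geo_distance_matrix(metadata: pd.DataFrame) -> pd.DataFrame:
    """Great-circle plot x plot distances in km (haversine, R = 6371 km)."""
    lat = metadata["lat"].to_numpy(dtype=float)
    lon = metadata["lon"].to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates outside valid lat/lon ranges")
    la = np.deg2rad(lat)
    lo = np.deg2rad(lon)
    dla = la[:, None] - la[None, :]
    dlo = lo[:, None] - lo[None, :]
    h = (
        np.sin(dla / 2) ** 2
        + np.cos(la)[:, None] * np.cos(la)[None, :] * np.sin(dlo / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    ids = metadata["plot_id"]
    return pd.DataFrame(d, index=ids, columns=ids)


def decay_pairs(
    similarity: pd.DataFrame, distance: pd.DataFrame, plots=None
) -> np.ndarray:
    """Unique unordered (distance_km, similarity) pairs for a plot group.

    Returns an (n_pairs, 2) array from the upper triangle, NaN pairs
    dropped.
    """
    ids = pd.Index(plots) if plots is not None else similarity.index
    ids = ids.intersection(similarity.index)
    s = similarity.loc[ids, ids].to_numpy()
    d = distance.loc[ids, ids].to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    out = np.column_stack([d[iu, ju], s[iu, ju]])
    return out[~np.isnan(out).any(axis=1)]


@dataclass(frozen=True)
class DecayFit:
    """OLS fit of similarity on distance for one group of plots."""

    group: str
    slope: float  # similarity per km
    intercept: float
    slope_se: float
    n_pairs: int
    r_value: float = float("nan")

    @property
    def display_magnitude(self) -> float:
        """|slope| x 1000, the figure-display convention."""
        return abs(self.slope) * 1000.0


def _ols_slope(x: np.ndarray, y: np.ndarray):
    res = stats.linregress(x, y)
    return res


def fit_decay(
    similarity: pd.DataFrame,
    distance: pd.DataFrame,
    plots=None,
    group: str = "",
) -> DecayFit:
    """Distance-decay OLS over the unique plot pairs of a group.

    Requires at least 3 plots and non-degenerate distances.  Pairs are
    treated as independent observations (inference belongs to the
    permutation contrast, not to the OLS standard error).
    """
    ids = pd.Index(plots) if plots is not None else similarity.index
    ids = ids.intersection(similarity.index)
    if len(ids) < 3:
        raise ValueError("distance-decay fit requires at least 3 plots")
    pairs = decay_pairs(similarity, distance, ids)
    if len(pairs) < 3:
        raise ValueError("not enough valid pairs for a fit")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) <= 0:
        raise ValueError("zero distance variance in group")
    res = _ols_slope(x, y)
    return DecayFit(
        group=group,
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        n_pairs=len(pairs),
        r_value=float(res.rvalue),
    )


@dataclass(frozen=True)
class SlopeContrast:
    group_a: str
    group_b: str
    d_obs: float  # slope_a - slope_b
    p_value: float
    n_permutations: int
    p_adjusted: float | None = None


def _slopes_for_assignments(x, y, assign: np.ndarray):
    """Vectorised OLS slopes for many boolean pair-assignments.

    ``assign`` is (n_perm, n_pool); True = pair goes to group A.  Returns
    (slopes_A, slopes_B).
    """

    def batch(mask):
        n = mask.sum(axis=1)
        sx = mask @ x
        sy = mask @ y
        sxx = mask @ (x * x)
        sxy = mask @ (x * y)
        return (n * sxy - sx * sy) / (n * sxx - sx * sx)

    return batch(assign), batch(~assign)


def diffslope_permutation(
    pairs_a: np.ndarray,
    pairs_b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    group_a: str = "A",
    group_b: str = "B",
) -> SlopeContrast:
    """Randomisation test for the difference between two decay slopes.

    The observed statistic is d = slope_A - slope_B.  The null is built by
    randomly re-partitioning the pooled (distance, similarity) pairs into
    the original group sizes and recomputing d; the two-sided p-value uses
    the add-one convention p = (1 + #{|d_perm| >= |d_obs|}) / (1 + n_perm).
    """
    pairs_a = np.asarray(pairs_a, dtype=float)
    pairs_b = np.asarray(pairs_b, dtype=float)
    if len(pairs_a) < 3 or len(pairs_b) < 3:
        raise ValueError("each group needs at least 3 pairs")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    for p, name in ((pairs_a, "A"), (pairs_b, "B")):
        if np.ptp(p[:, 0]) <= 0:
            raise ValueError(f"group {name} has degenerate distances")
    sa = _ols_slope(pairs_a[:, 0], pairs_a[:, 1]).slope
    sb = _ols_slope(pairs_b[:, 0], pairs_b[:, 1]).slope
    d_obs = sa - sb

    pool = np.vstack([pairs_a, pairs_b])
    x, y = pool[:, 0], pool[:, 1]
    n_a, n_pool = len(pairs_a), len(pool)
    rng = np.random.default_rng(seed)
    # ranks of iid uniforms give uniformly random n_a-subsets per row
    u = rng.random((n_perm, n_pool))
    assign = u.argsort(axis=1).argsort(axis=1) < n_a
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes_a, slopes_b = _slopes_for_assignments(x, y, assign)
    d_perm = slopes_a - slopes_b
    d_perm = d_perm[np.isfinite(d_perm)]
    p = (1.0 + np.sum(np.abs(d_perm) >= abs(d_obs))) / (1.0 + len(d_perm))
    return SlopeContrast(
        group_a=group_a,
        group_b=group_b,
        d_obs=float(d_obs),
        p_value=float(p),
        n_permutations=int(len(d_perm)),
    )


def adjust_pvalues(p_values, method: str = "fdr_bh") -> np.ndarray:
    """Multiplicity adjustment: Benjamini-Hochberg (default) or Bonferroni."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError("method must be 'fdr_bh' or 'bonferroni'")
    return multipletests(p, method=method)[1]


def landscape_delta(
    fits_general: dict[str, DecayFit],
    fits_specific: dict[tuple[str, str], DecayFit],
) -> pd.DataFrame:
    """Regional-landscape slope deltas per (land-use, landscape) cell.

    delta = |slope of the land-use within the landscape| - |overall slope
    of the land-use|; positive values mean the landscape heterogenises
    (steeper decay), negative means it homogenises.  Missing cells are
    reported with NaN.
    """
    rows = []
    for (lu, scape), fit in fits_specific.items():
        gen = fits_general.get(lu)
        if gen is None or fit is None:
            rows.append(
                {"landuse": lu, "landscape": scape, "delta": float("nan"),
                 "direction": "missing"}
            )
            continue
        delta = abs(fit.slope) - abs(gen.slope)
        rows.append(
            {
                "landuse": lu,
                "landscape": scape,
                "delta": float(delta),
                "direction": (
                    "heterogenisation" if delta > 0
                    else "homogenisation" if delta < 0 else "none"
                ),
            }
        )
    return pd.DataFrame(rows)
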