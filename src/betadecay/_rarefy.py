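"""Vectorised estimator kernels for replicated incidence data.

Everything here operates on incidence *frequency histograms*: for an
assemblage sampled with ``T`` units, ``hist[k]`` is the number of species
detected in exactly ``k`` units (``k = 1..T``).  All diversity and coverage
estimators used by the package depend on the data only through this
histogram, which is what makes the pairwise similarity engine cheap: a batch
of assemblages is an ``(n, T+1)`` integer array.

Conventions
-----------
- ``U``: total number of incidences, ``sum k * hist[k]``.
- Rarefaction (effort ``t <= T``) uses exact hypergeometric expectations of
  the frequency counts; at integer ``t`` these match exhaustive enumeration
  of all ``C(T, t)`` unit subsets.
- Extrapolation (``t > T``) uses Good-Turing / Chao-type estimators for
  q = 0 and coverage, a closed-form moment estimator for q = 2, and a
  ratio-corrected binomial plug-in for q = 1 (see docs/methods.md).
- Non-integer effort: coverage, q = 0 and q = 2 have exact log-gamma
  continuations; q = 1 is linearly interpolated between adjacent integer
  efforts.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom as _binom

__all__ = [
    "freq_histogram",
    "coverage_at",
    "effort_for_coverage_hist",
    "hill_at_effort_hist",
    "EXTRAPOLATION_WARN_FACTOR",
]

#: efforts beyond this multiple of T trigger a reliability warning
EXTRAPOLATION_WARN_FACTOR = 2.0

_EPS = 1e-12


def freq_histogram(Y: np.ndarray, T: int) -> np.ndarray:
    """Histogram Q_k (k = 0..T) of an integer frequency vector."""
    Y = np.asarray(Y)
    if Y.ndim != 1:
        raise ValueError("frequency vector must be one-dimensional")
    if np.any((Y < 0) | (Y > T)):
        raise ValueError(f"incidence frequencies must lie in [0, {T}]")
    return np.bincount(Y.astype(int), minlength=T + 1).astype(float)


def _hist_stats(hist: np.ndarray, T: int):
    """(U, S_obs, Q1, Q2) row-wise for an (n, T+1) histogram array."""
    hist = np.atleast_2d(np.asarray(hist, dtype=float))
    k = np.arange(T + 1, dtype=float)
    U = hist[:, 1:] @ k[1:]
    S = hist[:, 1:].sum(axis=1)
    return U, S, hist[:, 1], hist[:, 2]


def _ratio_unseen(T: int, denom: int, t: np.ndarray) -> np.ndarray:
    """``C(T-k, t) / C(denom, t)`` for k = 1..T, real-valued ``t``.

    Returns an array of shape ``t.shape + (T,)`` (last axis is k).  Zero
    where ``t > T - k``; the k = 1, denom = T-1 lane is identically 1.
    """
    t = np.asarray(t, dtype=float)[..., None]
    k = np.arange(1, T + 1, dtype=float)
    a = T - k  # upper index of the numerator coefficient
    valid = t <= a + 1e-9
    tt = np.where(valid, t, 0.0)
    logr = (
        gammaln(a + 1)
        - gammaln(np.maximum(a - tt + 1, _EPS))
        - gammaln(denom + 1)
        + gammaln(np.maximum(denom - tt + 1, _EPS))
    )
    out = np.where(valid, np.exp(logr), 0.0)
    if denom == T - 1:
        out[..., 0] = 1.0  # C(T-1,t)/C(T-1,t)
    return out


def _gt_A(T: int, Q1: np.ndarray, Q2: np.ndarray) -> np.ndarray:
    """Good-Turing factor A for the incidence coverage estimator.

    A = (T-1)Q1 / ((T-1)Q1 + 2 Q2); when Q2 = 0 the modified form
    A = 2 / ((T-1)(Q1-1) + 2) avoids a degenerate (flat) extrapolation
    while still giving A = 1 when Q1 <= 1.
    """
    Q1 = np.asarray(Q1, dtype=float)
    Q2 = np.asarray(Q2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(
            Q2 > 0,
            (T - 1) * Q1 / ((T - 1) * Q1 + 2 * Q2),
            2.0 / ((T - 1) * np.maximum(Q1 - 1, 0) + 2.0),
        )
    return np.where(Q1 > 0, A, 1.0)


def coverage_at(hist: np.ndarray, T: int, t) -> np.ndarray:
    """Estimated sample coverage at effort ``t`` (piecewise curve).

    ``t < T``: hypergeometric rarefaction estimator;
    ``t == T``: full-sample Good-Turing estimator;
    ``t > T``: geometric extrapolation C(T+t*) = 1 - (Q1/U) A^(t*+1).
    """
    hist = np.atleast_2d(np.asarray(hist, dtype=float))
    U, _, Q1, Q2 = _hist_stats(hist, T)
    t = np.broadcast_to(np.asarray(t, dtype=float), U.shape).copy()
    if np.any(t < 0):
        raise ValueError("effort must be non-negative")
    if np.any(U <= 0):
        raise ValueError("coverage is undefined for an empty assemblage (U = 0)")
    k = np.arange(1, T + 1, dtype=float)
    out = np.empty_like(U)

    rare = t < T
    if np.any(rare):
        ratio = _ratio_unseen(T, T - 1, t[rare])
        w = hist[rare, 1:] * k / U[rare, None]
        out[rare] = 1.0 - (w * ratio).sum(axis=1)

    A = _gt_A(T, Q1, Q2)
    full = ~rare
    if np.any(full):
        tstar = t[full] - T
        out[full] = 1.0 - (Q1[full] / U[full]) * A[full] ** (tstar + 1.0)
    return np.clip(out, 0.0, 1.0)


def effort_for_coverage_hist(
    hist: np.ndarray, T: int, target: float, tol: float = 1e-6
):
    """Invert the coverage curve: effort whose coverage is ``target``.

    Returns ``(t, side)`` with ``side`` in {-1: rarefy, 0: none, +1:
    extrapolate} per row.  Targets that fall inside the upward jump of the
    piecewise curve at ``t = T`` (between the rarefaction limit 1 - Q1/U and
    the full-sample estimator) are mapped to ``t = T``.
    """
    if not (0.0 < target < 1.0):
        raise ValueError("coverage target must be in (0, 1)")
    hist = np.atleast_2d(np.asarray(hist, dtype=float))
    n = hist.shape[0]
    U, _, Q1, Q2 = _hist_stats(hist, T)
    if np.any(U <= 0):
        raise ValueError("coverage is undefined for an empty assemblage (U = 0)")
    A = _gt_A(T, Q1, Q2)
    c_full = 1.0 - (Q1 / U) * A
    jump_low = 1.0 - Q1 / U

    t = np.full(n, float(T))
    side = np.zeros(n, dtype=int)

    extrap = target > c_full + tol
    if np.any(extrap):
        unreachable = extrap & (A >= 1.0 - _EPS)
        if np.any(unreachable):
            raise ValueError(
                "coverage target is unreachable by extrapolation "
                "(no doubletons to support the Good-Turing rate)"
            )
        with np.errstate(divide="ignore"):
            tstar = (
                np.log((1.0 - target) * U[extrap] / np.maximum(Q1[extrap], _EPS))
                / np.log(A[extrap])
                - 1.0
            )
        t[extrap] = T + np.maximum(tstar, 0.0)
        side[extrap] = 1

    rare = target < jump_low - tol
    if np.any(rare):
        lo = np.full(rare.sum(), _EPS)
        hi = np.full(rare.sum(), float(T))
        sub = hist[rare]
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            c = coverage_at(sub, T, mid)
            go_up = c < target
            lo = np.where(go_up, mid, lo)
            hi = np.where(go_up, hi, mid)
        t[rare] = 0.5 * (lo + hi)
        side[rare] = -1
    # remaining rows (gap and |target - c_full| <= tol): t = T, side = 0
    return t, side


# ---------------------------------------------------------------------------
# Hill numbers at arbitrary effort
# ---------------------------------------------------------------------------


def _chao2_unseen(T: int, Q1, Q2):
    """Chao2-type estimate of the number of undetected species."""
    with np.errstate(divide="ignore", invalid="ignore"):
        q0 = np.where(
            Q2 > 0,
            (T - 1) / T * Q1 * Q1 / (2.0 * Q2),
            (T - 1) / T * Q1 * np.maximum(Q1 - 1, 0) / 2.0,
        )
    return q0


def _d0_at(hist, U, T, t):
    out = np.empty_like(U)
    rare = t <= T
    if np.any(rare):
        ratio = _ratio_unseen(T, T, t[rare])
        out[rare] = (hist[rare, 1:] * (1.0 - ratio)).sum(axis=1)
    ext = ~rare
    if np.any(ext):
        Q1, Q2 = hist[ext, 1], hist[ext, 2]
        S = hist[ext, 1:].sum(axis=1)
        q0 = _chao2_unseen(T, Q1, Q2)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(q0 > 0, Q1 / (Q1 + T * q0), 0.0)
        out[ext] = S + q0 * (1.0 - (1.0 - rate) ** (t[ext] - T))
    return out


def _d2_at(hist, U, T, t):
    # closed form, exact for hypergeometric rarefaction and equal to the
    # model-based estimator for extrapolation:
    #   D2(t) = (t U / T)^2 / [ t (U/T - G) + t^2 G ],
    #   G = sum_k Q_k k (k-1) / (T (T-1))
    k = np.arange(1, T + 1, dtype=float)
    G = (hist[:, 1:] * k * (k - 1.0)).sum(axis=1) / (T * (T - 1.0))
    num = (t * U / T) ** 2
    den = t * (U / T - G) + t * t * G
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, 0.0)


def _hyper_expected_counts(hist, T: int, m: int) -> np.ndarray:
    """E[Q_j(m)] (j = 1..min(m,T)) under subsampling m of T units."""
    J = min(m, T)
    j = np.arange(1, J + 1, dtype=float)[None, :]
    k = np.arange(1, T + 1, dtype=float)[:, None]
    with np.errstate(invalid="ignore"):
        logh = (
            gammaln(k + 1)
            - gammaln(j + 1)
            - gammaln(np.maximum(k - j + 1, _EPS))
            + gammaln(T - k + 1)
            - gammaln(np.maximum(m - j + 1, _EPS))
            - gammaln(np.maximum(T - k - (m - j) + 1, _EPS))
            - gammaln(T + 1)
            + gammaln(m + 1)
            + gammaln(T - m + 1)
        )
    valid = (j <= np.minimum(k, m)) & ((m - j) <= (T - k))
    H = np.where(valid, np.exp(logh), 0.0)  # (T, J)
    return hist[:, 1:] @ H


def _binom_expected_counts(hist, T: int, m: int) -> np.ndarray:
    """E[Q_j(m)] (j = 1..m) under a binomial model with p_k = k/T."""
    j = np.arange(1, m + 1)
    p = np.arange(1, T + 1, dtype=float) / T
    B = _binom.pmf(j[None, :], m, p[:, None])  # (T, m)
    return hist[:, 1:] @ B


def _entropy_of_counts(EQ: np.ndarray, Ut: np.ndarray) -> np.ndarray:
    """ln(Ut) - (1/Ut) sum_j j ln(j) E[Q_j]  (Shannon entropy of the
    expected incidence-frequency profile)."""
    j = np.arange(1, EQ.shape[1] + 1, dtype=float)
    s = EQ @ (j * np.log(j))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(Ut > 0, np.log(Ut) - s / Ut, 0.0)


def _d1_int(hist, U, T, m: int) -> np.ndarray:
    """q = 1 diversity at integer effort m <= T (expected-counts form)."""
    if m == 0:
        return np.zeros_like(U)
    EQ = _hyper_expected_counts(hist, T, m)
    Ut = m * U / T
    return np.exp(_entropy_of_counts(EQ, Ut))


def _d1_ext_entropy(hist, U, T, m: int) -> np.ndarray:
    """Binomial plug-in profile entropy Hb(m) for m >= T."""
    EQ = _binom_expected_counts(hist, T, m)
    Ut = m * U / T
    return _entropy_of_counts(EQ, Ut)


def _grouped_integer_eval(func, hist, U, t, lo_clip, hi_clip):
    """Evaluate an integer-effort function at floor/ceil of t and
    interpolate linearly.  ``func(rows_hist, rows_U, m) -> values``."""
    m_lo = np.clip(np.floor(t).astype(int), lo_clip, hi_clip)
    m_hi = np.clip(np.ceil(t).astype(int), lo_clip, hi_clip)
    vals_lo = np.empty_like(U)
    vals_hi = np.empty_like(U)
    for m in np.unique(np.concatenate([m_lo, m_hi])):
        sel_lo = m_lo == m
        sel_hi = m_hi == m
        sel = sel_lo | sel_hi
        v = func(hist[sel], U[sel], int(m))
        out_idx = np.flatnonzero(sel)
        vals_lo[out_idx[sel_lo[sel]]] = v[sel_lo[sel]]
        vals_hi[out_idx[sel_hi[sel]]] = v[sel_hi[sel]]
    frac = np.where(m_hi > m_lo, (t - m_lo) / np.maximum(m_hi - m_lo, 1), 0.0)
    return vals_lo * (1.0 - frac) + vals_hi * frac


def hill_at_effort_hist(hist: np.ndarray, T: int, t, q: float) -> np.ndarray:
    """Incidence-based Hill number of order q at sampling effort ``t``.

    Rarefaction (t <= T) reproduces the observed Hill number exactly at
    t = T.  Extrapolation uses Chao2 (q = 0), the closed-form moment
    estimator (q = 2) and a ratio-corrected binomial plug-in (q = 1).
    """
    hist = np.atleast_2d(np.asarray(hist, dtype=float))
    U, S, Q1, Q2 = _hist_stats(hist, T)
    t = np.broadcast_to(np.asarray(t, dtype=float), U.shape).astype(float).copy()
    if np.any(t <= 0):
        raise ValueError("effort must be positive")
    if np.any(U <= 0):
        raise ValueError("Hill numbers are undefined for an empty assemblage")
    if np.any(t > EXTRAPOLATION_WARN_FACTOR * T):
        warnings.warn(
            "extrapolating diversity beyond twice the reference effort; "
            "estimates may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    if q == 0:
        return _d0_at(hist, U, T, t)
    if q == 2:
        return _d2_at(hist, U, T, t)
    if q != 1:
        raise ValueError("only diversity orders q in {0, 1, 2} are supported")

    out = np.empty_like(U)
    rare = t <= T
    if np.any(rare):
        out[rare] = _grouped_integer_eval(
            lambda h, u, m: _d1_int(h, u, T, m), hist[rare], U[rare], t[rare], 0, T
        )
    ext = ~rare
    if np.any(ext):
        k = np.arange(1, T + 1, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            d1_obs = np.exp(
                np.log(U[ext]) - (hist[ext, 1:] @ (k * np.log(k))) / U[ext]
            )
        hb_T = _d1_ext_entropy(hist[ext], U[ext], T, T)
        hb_t = _grouped_integer_eval(
            lambda h, u, m: _d1_ext_entropy(h, u, T, m),
            hist[ext],
            U[ext],
            t[ext],
            T,
            10**9,
        )
        out[ext] = d1_obs * np.exp(hb_t - hb_T)
    return out
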