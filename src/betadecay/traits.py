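"""Trait classification, trait-subset communities and community-weighted means.

Body-size classes follow the study's data-driven thresholds: small <= 2.7
mm, intermediate strictly between 2.7 and 7 mm, large >= 7 mm.  Mobility is
an ordinal expert score: 1 = low, 2 = medium, 3 = high.  Community-weighted
means (CWM) use incidence frequency as the weight -- the only abundance
proxy a replicated-incidence design provides.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SIZE_THRESHOLD_SMALL",
    "SIZE_THRESHOLD_LARGE",
    "classify_body_size",
    "subset_incidence",
    "community_weighted_mean",
    "cwm_table",
    "MOBILITY_LABELS",
]

SIZE_THRESHOLD_SMALL = 2.7
SIZE_THRESHOLD_LARGE = 7.0
MOBILITY_LABELS = {1: "low", 2: "medium", 3: "high"}


def classify_body_size(
    size_mm: float,
    small_max: float = SIZE_THRESHOLD_SMALL,
    large_min: float = SIZE_THRESHOLD_LARGE,
) -> str:
    """'small' (<= 2.7 mm), 'intermediate', or 'large' (>= 7 mm)."""
    if not np.isfinite(size_mm) or size_mm <= 0:
        raise ValueError("body size must be a positive length in mm")
    if size_mm <= small_max:
        return "small"
    if size_mm >= large_min:
        return "large"
    return "intermediate"


def subset_incidence(
    freqs: pd.DataFrame, traits: pd.DataFrame, class_label: str
) -> pd.DataFrame:
    """Restrict a species x plots frequency matrix to one trait class.

    ``class_label`` is a size class name or a mobility label/score.
    Species absent from the trait table are dropped (logged).  Frequencies
    of retained species are unchanged; an empty result is returned as an
    empty frame for the caller to flag.
    """
    t = traits.set_index("species_id")
    covered = freqs.index.intersection(t.index)
    missing = len(freqs.index) - len(covered)
    if missing:
        logger.info("%d species lack traits; excluded from subset", missing)
    t = t.loc[covered]
    if class_label in ("small", "intermediate", "large"):
        keep = t.index[t["size_class"] == class_label]
    else:
        by_label = {v: k for k, v in MOBILITY_LABELS.items()}
        score = by_label.get(class_label, class_label)
        keep = t.index[t["mobility"] == int(score)]
    out = freqs.loc[keep]
    out.index.name = freqs.index.name
    return out


def community_weighted_mean(
    frequencies: pd.Series, traits: pd.DataFrame, trait_field: str
) -> float:
    """CWM = sum(Y_i x_i) / sum(Y_i) over detected, trait-covered species.

    Returns NaN when no detected species carries the trait.
    """
    t = traits.set_index("species_id")[trait_field].dropna()
    y = frequencies[frequencies > 0]
    shared = y.index.intersection(t.index)
    if len(shared) == 0:
        return float("nan")
    w = y.loc[shared].to_numpy(dtype=float)
    x = t.loc[shared].to_numpy(dtype=float)
    return float(np.sum(w * x) / np.sum(w))


def cwm_table(
    freqs: pd.DataFrame,
    traits: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    trait_fields=("body_size_mm", "mobility"),
) -> pd.DataFrame:
    """Per-plot CWMs for each trait field, with land-use attached if given."""
    rows = {
        plot: {f: community_weighted_mean(freqs[plot], traits, f) for f in trait_fields}
        for plot in freqs.columns
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "plot_id"
    if metadata is not None:
        out = out.join(metadata.set_index("plot_id")[["landuse", "landscape"]])
    return out.reset_index()
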