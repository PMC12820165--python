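"""CSV/TSV dialects for plot metadata, incidence and trait tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import UnitIncidence

__all__ = [
    "write_metadata",
    "read_metadata",
    "write_incidence_wide",
    "read_incidence_wide",
    "write_incidence_long",
    "read_incidence_long",
    "write_traits",
    "read_traits",
    "ValidationReport",
    "validate_inputs",
]

METADATA_COLS = ["plot_id", "region_id", "landscape", "landuse", "lat", "lon"]
TRAIT_COLS = ["species_id", "family", "body_size_mm", "mobility"]


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta[METADATA_COLS].to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_incidence_wide(freqs: pd.DataFrame, path) -> None:
    """Species x plots integer frequency matrix, species ids in column 1."""
    freqs.to_csv(path, index_label="species")


def read_incidence_wide(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_incidence_long(inc: UnitIncidence, path) -> None:
    inc.to_long().to_csv(path, sep="\t", index=False)


def read_incidence_long(path, T: int = 16) -> UnitIncidence:
    return UnitIncidence.from_long(pd.read_csv(path, sep="\t"), T=T)


def write_traits(traits: pd.DataFrame, path) -> None:
    cols = [c for c in TRAIT_COLS + ["size_class"] if c in traits.columns]
    traits[cols].to_csv(path, index=False)


def read_traits(path) -> pd.DataFrame:
    t = pd.read_csv(path)
    if "size_class" not in t.columns and "body_size_mm" in t.columns:
        from .traits import classify_body_size

        t["size_class"] = t["body_size_mm"].map(classify_body_size)
    return t


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)
    n_plots: int = 0
    n_species: int = 0
    trait_coverage_pct: float = float("nan")

    @property
    def ok(self) -> bool:
        return not self.violations

    def summary(self) -> str:
        head = (
            f"{self.n_plots} plots, {self.n_species} species, "
            f"trait coverage {self.trait_coverage_pct:.1f}%"
        )
        if self.ok:
            return f"OK: {head}"
        return f"FAILED ({len(self.violations)} violations): {head}\n" + "\n".join(
            f"  - {v}" for v in self.violations
        )


def validate_inputs(
    metadata_path, incidence_path, traits_path=None, T: int = 16
) -> ValidationReport:
    """Schema and range checks on the three input tables.

    Checks metadata columns and coordinate ranges, incidence frequency
    bounds 0..T and plot-id agreement, and trait columns; reports the
    percentage of incidence species covered by the trait table.
    """
    rep = ValidationReport()
    try:
        meta = read_metadata(metadata_path)
    except Exception as e:  # noqa: BLE001 - report, don't crash
        rep.violations.append(f"metadata unreadable: {e}")
        return rep
    for col in METADATA_COLS:
        if col not in meta.columns:
            rep.violations.append(f"metadata missing column '{col}'")
    if {"lat", "lon"}.issubset(meta.columns):
        if np.any(np.abs(meta["lat"]) > 90) or np.any(np.abs(meta["lon"]) > 180):
            rep.violations.append("metadata has coordinates outside valid ranges")
    if "plot_id" in meta.columns and meta["plot_id"].duplicated().any():
        rep.violations.append("duplicate plot ids in metadata")
    rep.n_plots = len(meta)

    try:
        if str(incidence_path).endswith((".tsv", ".txt")):
            freqs = read_incidence_long(incidence_path, T=T).frequencies()
        else:
            freqs = read_incidence_wide(incidence_path)
    except Exception as e:  # noqa: BLE001
        rep.violations.append(f"incidence unreadable: {e}")
        return rep
    rep.n_species = len(freqs)
    vals = freqs.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        rep.violations.append("incidence frequencies are not integers")
    bad = (vals < 0) | (vals > T)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        rep.violations.append(
            f"incidence frequency {vals[i, j]} outside [0, {T}] "
            f"(species {freqs.index[i]}, plot {freqs.columns[j]})"
        )
    if "plot_id" in meta.columns:
        unknown = set(freqs.columns) - set(meta["plot_id"])
        if unknown:
            rep.violations.append(
                f"{len(unknown)} incidence plot ids missing from metadata"
            )

    if traits_path is not None:
        try:
            traits = read_traits(traits_path)
        except Exception as e:  # noqa: BLE001
            rep.violations.append(f"traits unreadable: {e}")
            return rep
        for col in ("species_id", "body_size_mm", "mobility"):
            if col not in traits.columns:
                rep.violations.append(f"traits missing column '{col}'")
        if "mobility" in traits.columns:
            bad_mob = ~traits["mobility"].isin([1, 2, 3])
            if bad_mob.any():
                rep.violations.append("mobility scores outside {1, 2, 3}")
        if "body_size_mm" in traits.columns and (traits["body_size_mm"] <= 0).any():
            rep.violations.append("non-positive body sizes in traits")
        if "species_id" in traits.columns:
            covered = freqs.index.isin(traits["species_id"])
            rep.trait_coverage_pct = 100.0 * covered.mean() if len(covered) else 0.0
    return rep
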