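"""Unit-level incidence container: species x plots x sampling units.

The distance-decay pipeline needs detections resolved to individual
sampling units (collection time x size fraction), because the pooled
("gamma") sample of a plot pair is the unit-wise union of the two plots'
detections.  A plain frequency matrix is a lossy summary; this container
keeps the unit axis and derives frequencies on demand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .incidence import IncidenceAssemblage

__all__ = ["UnitIncidence"]


@dataclass
class UnitIncidence:
    detections: np.ndarray  # (n_species, n_plots, T), values in {0, 1}
    species: pd.Index
    plots: pd.Index

    def __post_init__(self):
        det = np.asarray(self.detections, dtype=np.uint8)
        if det.ndim != 3:
            raise ValueError("detections must be species x plots x units")
        if np.any(det > 1):
            raise ValueError("detections must be binary")
        if det.shape[0] != len(self.species) or det.shape[1] != len(self.plots):
            raise ValueError("axis lengths do not match species/plot labels")
        self.detections = det
        self.species = pd.Index(self.species, name="species")
        self.plots = pd.Index(self.plots, name="plot_id")

    @property
    def T(self) -> int:
        return self.detections.shape[2]

    @property
    def n_species(self) -> int:
        return self.detections.shape[0]

    @property
    def n_plots(self) -> int:
        return self.detections.shape[1]

    def frequencies(self) -> pd.DataFrame:
        """Species x plots incidence-frequency matrix (integers 0..T)."""
        return pd.DataFrame(
            self.detections.sum(axis=2, dtype=np.int64),
            index=self.species,
            columns=self.plots,
        )

    def assemblage(self, plot_id) -> IncidenceAssemblage:
        j = self.plots.get_loc(plot_id)
        return IncidenceAssemblage(
            T=self.T, Y=self.detections[:, j, :].sum(axis=1).astype(int)
        )

    def subset_species(self, species_ids) -> "UnitIncidence":
        idx = self.species.get_indexer(pd.Index(species_ids))
        if np.any(idx < 0):
            raise KeyError("unknown species in subset")
        return UnitIncidence(
            self.detections[idx], self.species[idx], self.plots
        )

    def select_plots(self, plot_ids) -> "UnitIncidence":
        idx = self.plots.get_indexer(pd.Index(plot_ids))
        if np.any(idx < 0):
            raise KeyError("unknown plot in selection")
        return UnitIncidence(
            self.detections[:, idx, :], self.species, self.plots[idx]
        )

    def nonempty_plots(self) -> pd.Index:
        """Plots with at least one detection."""
        mask = self.detections.sum(axis=(0, 2)) > 0
        return self.plots[mask]

    # -- construction -------------------------------------------------------

    @classmethod
    def from_frequencies(
        cls, freqs: pd.DataFrame, T: int, seed: int = 0
    ) -> "UnitIncidence":
        """Reconstruct unit-level data from a frequency matrix.

        Each species' Y detections at a plot are assigned to a seeded
        random subset of the T units.  This is a surrogate: real unit
        alignment (which collection/fraction a detection fell in) is lost
        in a frequency matrix, so pairwise unit-wise unions computed from
        the result carry no systematic co-detection structure.
        """
        Y = freqs.to_numpy()
        if np.any((Y < 0) | (Y > T)) or not np.allclose(Y, np.round(Y)):
            raise ValueError(f"frequencies must be integers in [0, {T}]")
        rng = np.random.default_rng(seed)
        # rank of a random uniform per unit < Y  <=>  Y random units chosen
        u = rng.random((Y.shape[0], Y.shape[1], T))
        order = np.argsort(u, axis=2).argsort(axis=2)
        det = (order < np.round(Y).astype(int)[:, :, None]).astype(np.uint8)
        return cls(det, pd.Index(freqs.index), pd.Index(freqs.columns))

    @classmethod
    def from_long(cls, df: pd.DataFrame, T: int | None = None) -> "UnitIncidence":
        """Build from long-form records (species, plot, unit, detected)."""
        req = {"species", "plot_id", "unit", "detected"}
        if not req.issubset(df.columns):
            raise ValueError(f"long-form table needs columns {sorted(req)}")
        species = pd.Index(sorted(df["species"].unique()))
        plots = pd.Index(pd.unique(df["plot_id"]))
        units = sorted(df["unit"].unique())
        T = T or len(units)
        det = np.zeros((len(species), len(plots), T), dtype=np.uint8)
        si = species.get_indexer(df["species"])
        pi = plots.get_indexer(df["plot_id"])
        ui = pd.Index(units).get_indexer(df["unit"])
        det[si, pi, ui] = (df["detected"].to_numpy() > 0).astype(np.uint8)
        return cls(det, species, plots)

    def to_long(self) -> pd.DataFrame:
        """Long-form records of positive detections only."""
        s, p, u = np.nonzero(self.detections)
        return pd.DataFrame(
            {
                "species": self.species[s],
                "plot_id": self.plots[p],
                "unit": u,
                "detected": 1,
            }
        )
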