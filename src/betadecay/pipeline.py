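"""End-to-end orchestration: simulate/load -> standardise -> similarity ->
decay -> contrasts -> landscape deltas, from a single config.

Every run is deterministic given its root seed: all child randomness
(design, pool, traits, incidence, permutations) is spawned from one
``numpy.random.SeedSequence``.  Outputs land under ``out_dir/run_id/`` with
a manifest recording versions, seed, config hash and object counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, decay, hill, io, simulate, traits as traits_mod
from .dataset import UnitIncidence

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration (simulation block or real-data paths)."""

    seed: int = 0
    output_dir: str = "out"
    simulation: dict | None = field(default_factory=dict)
    data: dict | None = None  # {"metadata": ..., "incidence": ..., "traits": ...}
    coverage: dict = field(
        default_factory=lambda: {"landuse": 0.8, "traits": 0.7}
    )
    q_list: tuple = (0, 1, 2)
    similarity_variant: str = "sorensen"
    n_permutations: int = 1000
    adjust_method: str = "fdr_bh"
    make_plots: bool = False

    def __post_init__(self):
        if self.data is None and self.simulation is None:
            raise ValueError("config needs a simulation block or data paths")
        for key, v in self.coverage.items():
            if not (0 < v < 1):
                raise ValueError(f"coverage target '{key}' must be in (0, 1)")
        self.q_list = tuple(self.q_list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:10]


@dataclass
class RunManifest:
    run_id: str
    seed: int
    config_hash: str
    versions: dict
    counts: dict
    files: list
    out_dir: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _build_simulation_objects(cfg: RunConfig):
    sim = cfg.simulation or {}
    design = simulate.StudyDesignConfig(**sim.get("design", {}))
    turnover_raw = sim.get("turnover")
    if turnover_raw:
        turnover = {
            lu: simulate.TurnoverParams(**p) for lu, p in turnover_raw.items()
        }
    else:
        turnover = simulate.default_turnover()
    trait_cfg = simulate.TraitConfig(**sim.get("traits", {}))
    meta, inc, _pool, trait_table = simulate.simulate_dataset(
        design, turnover, trait_cfg, seed=cfg.seed
    )
    return meta, inc, trait_table, design.T


def _load_data_objects(cfg: RunConfig):
    paths = cfg.data
    T = int(paths.get("T", 16))
    meta = io.read_metadata(paths["metadata"])
    inc_path = str(paths["incidence"])
    if inc_path.endswith((".tsv", ".txt")):
        inc = io.read_incidence_long(inc_path, T=T)
    else:
        freqs = io.read_incidence_wide(inc_path)
        inc = UnitIncidence.from_frequencies(freqs, T=T, seed=cfg.seed)
    trait_table = io.read_traits(paths["traits"]) if paths.get("traits") else None
    return meta, inc, trait_table, T


def _landuse_fits(mat: hill.SimilarityMatrix, dist, meta) -> dict[str, decay.DecayFit]:
    fits = {}
    by_lu = meta.groupby("landuse")["plot_id"]
    for lu, plots in by_lu:
        ids = pd.Index(plots).intersection(mat.values.index)
        if len(ids) < 3:
            logger.warning(
                "subset %s q=%g: land-use %s has %d plots; no fit",
                mat.subset, mat.q, lu, len(ids),
            )
            continue
        try:
            fits[lu] = decay.fit_decay(mat.values, dist, ids, group=lu)
        except ValueError as e:
            logger.warning("fit failed for %s (%s)", lu, e)
    return fits


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute the full analysis and write all outputs; returns the manifest."""
    run_id = f"run-seed{cfg.seed}-{cfg.config_hash()}"
    out = Path(cfg.output_dir) / run_id
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def _save(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, index=False, **kw)
        files.append(name)

    if cfg.data:
        meta, inc, trait_table, T = _load_data_objects(cfg)
        logger.info("loaded %d plots, %d species", len(meta), inc.n_species)
    else:
        meta, inc, trait_table, T = _build_simulation_objects(cfg)
        logger.info("simulated %d plots, %d species", len(meta), inc.n_species)
        io.write_metadata(meta, out / "plots.csv")
        io.write_incidence_wide(inc.frequencies(), out / "incidence_wide.csv")
        files += ["plots.csv", "incidence_wide.csv"]
        if trait_table is not None:
            io.write_traits(trait_table, out / "traits.csv")
            files.append("traits.csv")

    n_samples = len(meta) * (
        cfg.simulation.get("design", {}).get("n_collections", 8)
        if cfg.simulation is not None
        else 8
    )

    # --- similarity matrices -------------------------------------------
    mats = hill.similarity_matrices(
        inc,
        traits=trait_table,
        q_list=cfg.q_list,
        C_all=cfg.coverage.get("landuse", 0.8),
        C_traits=cfg.coverage.get("traits", 0.7),
        variant=cfg.similarity_variant,
    )
    for m in mats:
        m.values.to_csv(out / m.filename())
        files.append(m.filename())
    logger.info("computed %d similarity matrices", len(mats))

    # --- decay fits ----------------------------------------------------
    dist = decay.geo_distance_matrix(meta)
    fit_rows = []
    fits_by_key: dict[tuple, dict[str, decay.DecayFit]] = {}
    for m in mats:
        fits = _landuse_fits(m, dist, meta)
        fits_by_key[(m.subset, m.q)] = fits
        for lu, f in fits.items():
            fit_rows.append(
                {
                    "subset": m.subset,
                    "q": m.q,
                    "group": lu,
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "slope_se": f.slope_se,
                    "n_pairs": f.n_pairs,
                    "abs_slope_x1000": f.display_magnitude,
                }
            )
    _save(pd.DataFrame(fit_rows), "decay_fits.csv")

    # --- permutation contrasts between land-uses -----------------------
    seed_seq = np.random.SeedSequence(cfg.seed).spawn(1)[0]
    contrast_rows = []
    child_iter = iter(seed_seq.spawn(4096))
    for m in mats:
        fits = fits_by_key[(m.subset, m.q)]
        groups = sorted(fits)
        pairs = {
            lu: decay.decay_pairs(
                m.values, dist, meta.loc[meta["landuse"] == lu, "plot_id"]
            )
            for lu in groups
        }
        family = []
        for a, b in itertools.combinations(groups, 2):
            seed = int(next(child_iter).generate_state(1)[0] % 2**31)
            c = decay.diffslope_permutation(
                pairs[a], pairs[b], n_perm=cfg.n_permutations, seed=seed,
                group_a=a, group_b=b,
            )
            family.append(c)
        if not family:
            continue
        adj = decay.adjust_pvalues(
            [c.p_value for c in family], method=cfg.adjust_method
        )
        for c, pa in zip(family, adj):
            contrast_rows.append(
                {
                    "subset": m.subset,
                    "q": m.q,
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "slope_diff": c.d_obs,
                    "p_value": c.p_value,
                    "p_adjusted": pa,
                    "n_permutations": c.n_permutations,
                }
            )
    _save(pd.DataFrame(contrast_rows), "slope_contrasts.csv")

    # --- regional landscape deltas (all-species matrices) --------------
    delta_frames = []
    for m in mats:
        if m.subset != "all":
            continue
        general = fits_by_key[("all", m.q)]
        specific: dict[tuple[str, str], decay.DecayFit] = {}
        for (lu, scape), plots in meta.groupby(["landuse", "landscape"])["plot_id"]:
            ids = pd.Index(plots).intersection(m.values.index)
            if len(ids) < 3:
                continue
            try:
                specific[(lu, scape)] = decay.fit_decay(
                    m.values, dist, ids, group=f"{lu}|{scape}"
                )
            except ValueError:
                continue
        d = decay.landscape_delta(general, specific)
        d.insert(0, "q", m.q)
        delta_frames.append(d)
    deltas = (
        pd.concat(delta_frames, ignore_index=True)
        if delta_frames
        else pd.DataFrame(columns=["q", "landuse", "landscape", "delta", "direction"])
    )
    _save(deltas, "landscape_deltas.csv")

    # --- community-weighted means --------------------------------------
    if trait_table is not None:
        cwm = traits_mod.cwm_table(inc.frequencies(), trait_table, meta)
        _save(cwm, "cwm.csv")

    if cfg.make_plots:
        _decay_plots(mats, dist, meta, out, files)

    manifest = RunManifest(
        run_id=run_id,
        seed=cfg.seed,
        config_hash=cfg.config_hash(),
        versions={
            "betadecay": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        counts={
            "n_plots": int(len(meta)),
            "n_plot_collection_samples": int(n_samples),
            "n_species": int(inc.n_species),
            "n_similarity_matrices": len(mats),
            "n_decay_fits": len(fit_rows),
            "n_contrasts": len(contrast_rows),
            "n_landscape_deltas": int(deltas["delta"].notna().sum()),
        },
        files=sorted(files),
        out_dir=str(out),
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def _decay_plots(mats, dist, meta, out: Path, files: list):
    """Optional scatter + fitted-line plots (one per all-species matrix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for m in mats:
        if m.subset != "all":
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        for lu, plots in meta.groupby("landuse")["plot_id"]:
            pts = decay.decay_pairs(m.values, dist, plots)
            if len(pts) < 3:
                continue
            ax.scatter(pts[:, 0], pts[:, 1], s=4, alpha=0.3, label=lu)
            fit = decay.fit_decay(m.values, dist, plots, group=lu)
            xs = np.linspace(pts[:, 0].min(), pts[:, 0].max(), 10)
            ax.plot(xs, fit.intercept + fit.slope * xs)
        ax.set_xlabel("distance (km)")
        ax.set_ylabel(f"similarity (q={m.q:g})")
        ax.legend(fontsize=7)
        name = f"decay_all_q{m.q:g}.png"
        fig.savefig(out / name, dpi=120)
        plt.close(fig)
        files.append(name)
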