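# betadecay

Coverage-standardised Hill-number β-diversity and distance-decay analysis
for replicated incidence data, with a synthetic community generator for
testing the whole pipeline against planted spatial-turnover contrasts.

## The problem

Metabarcoding surveys of arthropod communities (e.g. Malaise-trap samples
clustered into Barcode Index Numbers) yield *replicated incidence data*:
for each plot, each species is detected in `Y ∈ {0..T}` of `T` sampling
units (here 8 collection times × 2 size fractions, `T = 16`).  Whether
land-use homogenises such communities is read off the **distance-decay**
of pairwise community similarity: a steep (more negative) slope of
similarity against geographic distance means spatially heterogeneous
communities, a flat slope means homogenisation.

Raw similarities are biased by incomplete sampling — under-sampled plots
look artificially dissimilar.  The package therefore standardises every
pairwise comparison to a common **sample coverage** before fitting decay
slopes.

## The statistics

For an assemblage with incidence frequencies `Y_i` and `U = Σ Y_i`
incidences, the Hill number of order `q` is

    qD = (Σ_i π_i^q)^(1/(1−q)),   π_i = Y_i / U,

with `q = 0` (richness, sensitive to infrequent species), `q = 1`
(Shannon-type, frequent species) and `q = 2` (highly frequent species).
Sample coverage is estimated from singletons and doubletons
(`Q1`, `Q2`) by the incidence Good–Turing formula

    Ĉ = 1 − (Q1/U) · (T−1)Q1 / ((T−1)Q1 + 2Q2),

and the coverage curve can be rarefied (hypergeometric, exact) or
extrapolated (geometric) to any effort `t`, then inverted to find the
effort that attains a target coverage (0.8 for land-use analyses, 0.7 for
trait subsets).

For a plot pair, γ-diversity comes from the pooled sample, α from the
concatenated frequency lists, and `β = γ/α ∈ [1, 2]` maps to a
Sørensen-type overlap `C_qN ∈ [0, 1]` (Jaccard-type `U_qN` available).
Both components are evaluated at the effort where the pooled pair reaches
the coverage target.  Decay slopes are OLS fits over unique plot pairs;
slopes of two groups are compared with a pair-exchanging randomisation
test ("diffslope"), Benjamini–Hochberg adjusted; and the regional-landscape
effect of a land-use is the delta `|slope within landscape| − |overall
slope|` (positive = heterogenisation).

## Worked example

Simulate a miniature of the study design (20 regions across three regional
landscapes, 60 plots in four local land-uses, `T = 16`), plant strong
turnover in arable land/settlement and weak turnover in grassland, then
recover it:

```python
import warnings
from betadecay import (
    StudyDesignConfig, simulate_dataset, similarity_matrices,
    geo_distance_matrix, fit_decay, diffslope_permutation,
)
from betadecay.simulate import TurnoverParams
from betadecay.decay import decay_pairs

meta, inc, pool, traits = simulate_dataset(
    StudyDesignConfig(n_regions=20, landscape_quotas=(7, 7, 6),
                      plots_per_landuse=(15, 15, 15, 15), rng_seed=0),
    {"forest": TurnoverParams(sigma_km=110, p_det=0.3, pool_size=150),
     "grassland": TurnoverParams(sigma_km=200, p_det=0.3, pool_size=150),
     "arable": TurnoverParams(sigma_km=70, p_det=0.3, pool_size=150),
     "settlement": TurnoverParams(sigma_km=70, p_det=0.3, pool_size=150)},
    seed=1,
)
mats = similarity_matrices(inc, traits=traits, q_list=(0,))
sim_q0 = next(m for m in mats if m.subset == "all")   # standardised to C = 0.8
dist = geo_distance_matrix(meta)
for landuse, plots in meta.groupby("landuse")["plot_id"]:
    f = fit_decay(sim_q0.values, dist, plots, group=landuse)
    print(f"{landuse:11s} slope = {f.slope:+.6f} /km  "
          f"|slope|x1000 = {f.display_magnitude:.3f}  (n_pairs = {f.n_pairs})")

pairs = {lu: decay_pairs(sim_q0.values, dist,
                         meta.loc[meta.landuse == lu, "plot_id"])
         for lu in ("grassland", "forest")}
c = diffslope_permutation(pairs["grassland"], pairs["forest"],
                          n_perm=999, seed=42,
                          group_a="grassland", group_b="forest")
print(f"grassland vs forest: d = {c.d_obs:+.6f}, p = {c.p_value:.4f}")
```

Output:

```
arable      slope = -0.000833 /km  |slope|x1000 = 0.833  (n_pairs = 105)
forest      slope = -0.000535 /km  |slope|x1000 = 0.535  (n_pairs = 105)
grassland   slope = -0.000210 /km  |slope|x1000 = 0.210  (n_pairs = 105)
settlement  slope = -0.000884 /km  |slope|x1000 = 0.884  (n_pairs = 105)
grassland vs forest: d = +0.000325, p = 0.0190
```

The planted ordering is recovered: grassland communities are the most
homogeneous in space (flattest decay), arable land and settlement the most
heterogeneous, and the grassland–forest slope difference is significant
under the randomisation test.  Slopes are in similarity units per km;
`|slope|×1000` is the display convention used throughout.

## Command line

```sh
betadecay simulate --out out/sim --seed 1      # synthetic dataset (CSV/TSV)
betadecay validate --metadata out/sim/plots.csv \
    --incidence out/sim/incidence_wide.csv --traits out/sim/traits.csv
betadecay all --config run.yaml                # full pipeline + manifest
```

The full pipeline writes, per run: 21 coverage-standardised similarity
matrices (`sim_{subset}_q{q}_C{C}.csv` for 7 community subsets — all
species, 3 body-size classes, 3 mobility classes — × 3 orders), decay fits
per land-use, permutation slope contrasts with adjusted p-values,
regional-landscape deltas, community-weighted trait means, and a JSON
manifest.  Reruns with the same config and seed are byte-identical.

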