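# Methods

This note documents the statistical machinery, the choices made where the
design was genuinely open, and what the synthetic-data experiments do and
do not demonstrate.

## Data model

An assemblage is a vector of incidence frequencies `Y_i ∈ {0..T}` over `T`
replicated sampling units (default `T = 16` = 8 collection times × 2 size
fractions).  All estimators in the package depend on the data only through
the frequency histogram `Q_k = #{i : Y_i = k}`; the pairwise similarity
engine exploits this to process thousands of plot pairs as histogram
algebra.  Unit-level detections (species × plot × unit) are retained in
`UnitIncidence` because the pooled sample of a plot pair is a *unit-wise
union*: unit labels (collection × fraction) are shared across plots.

## Coverage estimation

- **Full sample**: `Ĉ = 1 − (Q1/U)·A` with
  `A = (T−1)Q1 / ((T−1)Q1 + 2Q2)`.  When `Q2 = 0` this reduces to `A = 1`,
  which makes the extrapolated coverage curve flat and any higher target
  unreachable; we therefore use the modified factor
  `A = 2/((T−1)(Q1−1)+2)` in that case (it still gives `A = 1` when
  `Q1 ≤ 1`).
- **Rarefaction** (`t < T`): `Ĉ(t) = 1 − Σ_k (kQ_k/U)·C(T−k,t)/C(T−1,t)`,
  exact under hypergeometric subsampling; validated against exhaustive
  enumeration of all unit subsets for small `T`.
- **Extrapolation**: `Ĉ(T+t*) = 1 − (Q1/U)·A^(t*+1)`.
- The piecewise curve has a small upward jump at `t = T` (rarefaction
  limit `1 − Q1/U` vs. the full-sample estimator); it is monotone
  non-decreasing everywhere, and effort inversion maps targets inside the
  jump to `t = T`.  Continuity at `T` is exact precisely when `Q1 ≤ 1`.
- Inversion solves the rarefaction branch by bisection (coverage tolerance
  `1e−6`) and the extrapolation branch in closed form.  Real-valued effort
  is supported throughout (log-gamma continuation of the binomial
  coefficients) so coverage targets are hit exactly.
- Assemblages with `U = 0` are excluded from analysis with a logged
  warning, never imputed.

## Hill numbers at arbitrary effort

Rarefied diversity (`t ≤ T`) is the Hill number of the *expected*
frequency counts `E[Q_j(t)]` under hypergeometric subsampling — the
convention under which `t = T` reproduces the observed diversity exactly.
At non-integer `t`, orders 1 and 2 are linearly interpolated between
adjacent integer efforts (order 0 and coverage have exact continuations).
Extrapolation (`t > T`) uses:

- `q = 0`: Chao2-type asymptote,
  `S(T+t*) = S_obs + Q̂0·[1 − (1 − Q1/(Q1+T·Q̂0))^t*]` with
  `Q̂0 = ((T−1)/T)·Q1²/(2Q2)` (fallback `Q1(Q1−1)/2` when `Q2 = 0`).
- `q = 2`: the closed form `D2(t) = (tU/T)² / [t(U/T − G) + t²G]`,
  `G = ΣY(Y−1)/(T(T−1))`, which coincides with the hypergeometric
  expectation for `t ≤ T` and is the standard model-based estimator
  beyond.
- `q = 1`: a ratio-corrected binomial plug-in,
  `D1(T+t*) = D1_obs · exp(Hb(T+t*) − Hb(T))`, where `Hb` is the entropy
  of binomially smoothed (`p̂_i = Y_i/T`) expected counts.  This choice is
  exactly continuous at `t* = 0` and exactly invariant under duplicating
  an assemblage, which keeps the β-diversity identities below *exact*
  under standardisation.  It is conservative: it adds no
  undetected-species entropy, so long extrapolations understate `q = 1`
  diversity relative to asymptotic-entropy estimators.  Extrapolation
  beyond `2T` triggers a reliability warning.

## Pair β-diversity and coverage standardisation

Unstandardised decomposition (`pair_decompose`) works on frequency vectors
alone: γ is the Hill number of the summed frequencies over the stacked
`2T` units, α is half the Hill number of the concatenated frequency list
normalised by the pooled `U`, `β = γ/α` is clipped to `[1, 2]` (tolerance
warning at `1e−6`), and similarity is the Sørensen-type overlap

    C_qN = [(1/β)^(q−1) − (1/N)^(q−1)] / [1 − (1/N)^(q−1)],  N = 2,

with the Jaccard-type `U_qN` as a configurable alternative.  Which overlap
variant produced any particular published matrix is generally unknowable
from the matrix alone; Sørensen-type is the default here.

Standardised similarity works on unit-level data: the pooled (γ) sample is
the unit-wise union of the pair's detections (species × T), the α sample
stacks the two frequency lists over the same `T` units, and **both are
evaluated at the single common effort** at which the pooled sample attains
the coverage target (0.8 for land-use analyses, 0.7 for trait subsets —
chosen because trait subsets are sparser).  This construction makes two
identities exact at every reachable target and order: identical plots give
`S = 1`, disjoint plots give `S = 0`.  Anchoring the common effort on the
pooled sample (rather than standardising each plot separately) is a design
choice: β compares γ and α and must do so at one effort.  When the target
equals the pooled sample's own coverage, standardisation is a no-op and
the result equals the unstandardised decomposition (exactly so for pairs
without same-unit co-detections; with co-detections the union pooling and
the stacked pooling differ slightly at orders ≥ 1).

## Distance decay and inference

- Distances: haversine on a sphere of radius 6371 km.
- Decay fits: OLS of similarity on distance over unique unordered plot
  pairs (≥ 3 plots, non-degenerate distances).  Pairs are treated as
  independent observations in the fit; the non-independence of
  distance-matrix pairs is acknowledged and inference is delegated to the
  randomisation test.  Slope magnitudes are displayed ×1000.
- Slope contrast: the pooled (distance, similarity) pairs are randomly
  re-partitioned into the original group sizes; two-sided add-one p-value
  `p = (1 + #{|d_perm| ≥ |d_obs|})/(1 + n_perm)`, default
  `n_perm = 1000`, seeded.  Type-I error is verified by simulation
  (rejection rate 5% ± 3.5% over 200 null replicates).
- Multiplicity: Benjamini–Hochberg step-up by default (plain Bonferroni
  behind a flag), applied within each (subset, order) family of land-use
  contrasts.
- Landscape delta: `|slope of land-use within landscape| − |overall slope
  of land-use|`; positive = heterogenisation.  Cells with fewer than 3
  plots are reported missing.

## Synthetic community generator

The generator emulates the sampling design: 60 non-overlapping
5.8 × 5.8 km regions on a jittered grid over a 265 km square
(~70,500 km²), 20 regions per regional landscape (near-natural,
agricultural, urban), three plots per region in distinct local land-uses
with global quotas 55/46/43/35 (the alternative 55/45/44/35 split is a
config option; both sum to 179), plots at the region centre ± ≤ 2 km
jitter, coordinates reported as WGS84 decimal degrees.

Turnover is planted with a Gaussian occupancy kernel: species `s` of
land-use `l` occupies a matching plot at distance `d` from its range
centre with probability `p0·exp(−d²/2σ_l²)` (× a leakage factor `ε` at
non-matching plots), and is then detected in each of the `T` units
independently with probability `p_det`.  The kernel width σ (km) is the
turnover dial: small σ ⇒ strong distance-decay.  An optional
per-landscape multiplier on σ plants landscape-level contrasts for the
delta statistic.  Defaults — σ = 110 (forest), 200 (grassland), 70
(arable), 70 (settlement) km; `p0 = 0.6`; `p_det = 0.1`; `ε = 0.1`; 600
species per land-use pool — were fixed once so that (a) per-plot coverage
spans ≈ 0.73–0.86, inside the 0.6–0.9 band typical of such surveys and
straddling the 0.8 standardisation target, and (b) the qualitative slope
ordering (grassland flattest; arable/settlement steepest) expresses in the
fitted slopes rather than saturating at the zero-similarity floor.  The
species pool (~2,400) is a desk-scale stand-in for the ~11,000 species
units of a real campaign.

Traits are drawn at species level: body size lognormal (median 4.4 mm,
log-sd 0.9, giving roughly equal thirds across the ≤ 2.7 mm /
2.7–7 mm / ≥ 7 mm classes) and mobility categorical with probabilities
(0.12, 0.24, 0.64) mirroring the strong skew toward high-mobility taxa in
arthropod communities.  Family labels are cosmetic groupings; real
family-level trait structure is not simulated.

What the generator does *not* emulate: read-level noise (PCR/sequencing
artefacts, NUMTs), phenology and season-dependent detectability,
abundance structure, environmental gradients other than land-use, and
spatial autocorrelation beyond the occupancy kernel.  Passing the planted
-contrast tests therefore shows the *pipeline* recovers known spatial
structure from incidence data of this shape — not that any particular
field dataset satisfies the model.

## Numerical choices and degenerate inputs

- Real-valued binomial coefficients via `gammaln`, with explicit masks for
  out-of-support terms.
- β is clipped into `[1, N]`; violations beyond `1e−6` warn (estimator
  noise can push slightly outside, e.g. under long extrapolation).
- Empty plots are dropped from a subset's matrix (logged); subsets with
  < 2 non-empty plots are skipped.
- Degenerate simulation parameters yield empty matrices, not errors.
- All pipeline randomness is spawned from one root seed
  (`numpy.random.SeedSequence`); identical config + seed reproduces every
  output byte-for-byte.

## Known limitations

- The `q = 1` extrapolation is deliberately conservative (see above);
  matrices standardised far above the observed coverage should be read
  with care — the package warns beyond `2T`.
- OLS on similarity (not log-similarity) is assumed; no exponential or
  power-law decay models.
- Only pairwise (N = 2) similarity; no multiple-assemblage overlap, no
  confidence intervals on similarities or coverage.
- Frequency-only (wide CSV) input lacks unit alignment; surrogate random
  unit assignment is used, which erases systematic co-detection structure.
  Use the long-form TSV to preserve real unit-level data.
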