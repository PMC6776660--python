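# Methods

This note documents the models, numerical choices and defaults behind
`dichroma`, and what the synthetic-data tests do and do not demonstrate
about real spectrophotometric data.

## Spectra processing

Input spectra are wide CSV (first column `wl` in nm, one column per
spectrum) with a metadata table keyed by spectrum id (individual, sex
M/F, body region). Wavelengths must be strictly monotone; descending
spectrometer exports are flipped, anything else is rejected. Spectra are
linearly interpolated onto a common 1-nm grid clipped to 300–700 nm (the
span of lizard visual sensitivity and of typical field
spectrophotometry). Values whose maximum exceeds 1.5 are interpreted as
percent reflectance and divided by 100; the flag is kept on the data set.

Smoothing is LOESS with span 0.2: locally **linear** fits with tricube
weights, the span being the fraction of grid points in each window, and
no robustness iterations. This dialect matters — locally quadratic fits
or robustness iterations give visibly different curves — so the test
suite pins it against an independent transcription of the same kernel.
Smoothing is applied before any truncation of the wavelength range.
Negative reflectance (instrument noise around dark standards) is clamped
to zero after smoothing and the count logged.

## Visual model

Cone spectral sensitivities default to Govardovskii A1 visual-pigment
templates (alpha plus beta band, unit area) at λmax = 365/455/495/560 nm
for the UVS/SWS/MWS/LWS single cones — generic values for an iguanian
tetrachromat retina. Measured sensitivities can be supplied as CSV and
override the templates; the double cone defaults to the LWS curve.
Ocular-media transmission and oil droplets are not modelled.

Quantum catches are trapezoid integrals of reflectance × irradiance ×
sensitivity on the common grid. The packaged "bluesky" illuminant is a
Planck photon-flux curve at 20,000 K normalised to mean 1 — a smooth
synthetic stand-in with the blue-weighted shape of open-sky daylight
(any tabulated irradiance can be substituted via `file:`). Because both
dS and dL are built from log catch *ratios*, they are exactly invariant
to rescaling the illuminant or both spectra; only spectral shape enters.
The background is "ideal" (flat), under which von Kries normalisation is
a no-op, so it is off by default.

Receptor noise is `e_i = ω/√n_i` with ω = 0.10 the Weber fraction of a
unit-abundance channel and `n_i` the relative cone abundance. Three
abundance schemes are packaged: `lws_emphasis` (1, 1, 1, 4; double cone
4) — the reporting default, reflecting the LWS-dominated retinas of
diurnal lizards — `equal` (1, 1, 1, 1), and `split_ds_dl` (equal single
cones with a doubly abundant double cone for dL). Species-specific cone
proportions and Weber fractions for most lizards are unpublished; all
three schemes are stand-ins and fully configurable, and the pipeline's
regional dichromatism classification is tested to be identical across
them on the packaged fixture.

The chromatic distance is the receptor-noise-limited (Vorobyev–Osorio)
form on log contrasts `Δf_i = ln(Q_i^a/Q_i^b)`. The implementation uses
the general N-receptor quadratic form

    dS² = Σ_{i<j} (Π_{k≠i,j} e_k)² (Δf_i − Δf_j)² / Σ_i (Π_{k≠i} e_k)²

which reduces to the familiar tetrachromatic expression at N = 4 (the
test suite checks this against a literal transcription, and that the
N = 4 form collapses to the trichromatic one as one channel's noise
diverges). Pairwise matrices exploit that dS is a weighted Euclidean
distance in the 6-space of channel-pair log contrasts, so a region's
full matrix is one `pdist` call. The achromatic distance is
`dL = |ln(Q_D^a/Q_D^b)|/e_D` on the double cone; whether the double cone
or the LWS single cone drives luminance vision in lizards is not
settled, and the double cone is the configurable default.

## Tetrahedral color space and diversity indices

Relative catches `q = Q/ΣQ` over the four single cones map to

    x = ((1 − 2s − m − u)/2)·√(3/2),
    y = (−1 + 3m + u)/(2√2),
    z = u − 1/4,

placing the achromatic point at the origin and the pure-u vertex at
(0, 0, 0.75). Indices over a locus set: relative color volume is the
convex-hull volume divided by the full tetrahedron's volume (computed
from its vertices, not hard-coded); color span is the mean and variance
of pairwise Euclidean distances (chroma-sensitive); hue disparity is the
mean and variance of pairwise angles between origin-to-locus vectors
(chroma-free, and tested invariant to radial rescaling); the UV centroid
is the mean relative UVS catch, the probe for cryptic UV dichromatism.
Variances are population variances over the enumerated pairs — the
pair-level convention; at small n this differs from a sample variance,
so the choice is pinned here. Loci at the exact origin have no hue and
are excluded from hue-disparity pairs (counted and logged). Hulls with
volume below 1e-12, or fewer than 4 loci, score 0 with a degeneracy flag
rather than erroring, so group comparisons remain defined for tiny
groups.

## Dichromatism detection

Per body region, spectra are pooled across sexes and individuals and the
pairwise JND matrix (each channel separately) is clustered with UPGMA
(average linkage; merge heights are asserted non-decreasing, and
equality with a naive O(n³) agglomeration is part of the acceptance
suite). Cuts at k = 2..6 are examined. Any leaf forming a singleton
cluster at any examined cut is an outlier; outliers are removed in one
pass and the tree rebuilt once (iterating is available but off by
default). A cluster qualifies as a sex-specific patch when, inclusively,
pct_within ≥ 90 (share of its majority sex), pct_tot ≥ 10 (share of the
region's samples) and its mean JND to all non-members ≥ 2 (the
conservative discriminability threshold; the JND-to-rest average is
taken over member/non-member *pairs*, which equals the size-weighted
mean of between-cluster averages). The reported `tree_clust` is the
smallest qualifying k — the coarsest structure already showing
dichromatism — with every qualifying (k, cluster) retained; regions with
no qualifying cluster report 0 along with their best-scoring candidate.
`pct_males` counts male *individuals* contributing at least one spectrum
to the cluster, not male spectra. Threshold comparisons being inclusive
is a deliberate choice: a boundary case (e.g. pct_within exactly 90)
qualifies here, although reported analyses in the literature are
ambiguous on exactly-at-threshold cases.

The three-criterion rule has a known small-sample fragility: in a region
containing several well-separated shared patch classes, the JND-to-rest
criterion is dominated by the between-class distances, so with very few
samples a tiny single-sex noise subcluster can qualify by chance. At the
study's sampling depth (≥ 8 spectra/individual/region, i.e. ≥ 200 per
region) this is negligible; scaled-down fixtures therefore keep a floor
of 4 spectra per individual per region so that the 10 %-size criterion
never degenerates to a handful of points.

## Randomization inference

For each region, observed male − female differences in the six indices
are compared with nulls from randomly reassigning sex labels to loci
(group sizes preserved). All six indices are scored on the *same*
permutation stream, as in a single randomization of the labels. The
significance rule is two-sided: |observed| strictly greater than the
95th percentile (linear interpolation) of the |null| values, with the
direction (larger sex) reported — this reads the "larger than the 95 %
percentile" rule as magnitude-based, since either sex may carry the
larger index. An add-one empirical p-value (r+1)/(n+1) is reported
alongside. Default n_perm = 1000; below 100 a warning flags the unstable
percentile. Because loci within an individual are not independent,
locus-level permutation (the default, matching the standard design)
anticonservatively treats them as exchangeable; an individual-level
block permutation is available via `permutation_unit="individual"`. No
multiple-testing correction is applied by default (6 indices × 10
regions tested raw), matching common practice for this design.

## Synthetic study generator

The generator emulates the sampling design of a single-population field
study: 13 males and 12 females, ten body regions with per-individual
spectra counts (Abdomen 16, Chest 8, Throat 16, Cloaca 16, Dorsum 42,
Flanks 84, Head 20, Legs 16, Mouth 10, Head profile 20 — 248 per
individual, 6,200 total). Color-patch classes are parametric
archetypes: long-pass logistic edges for orange/red/yellow, Gaussian
bands for blue/green, a flat-high curve with a 350-nm shoulder for
UV-rich white, flat-low for black, and a shallow long-pass for brown.
Per spectrum, the archetype's spectral position is jittered (sd 3 nm)
and multiplicative lognormal noise (sd 0.02 per wavelength) applied,
then clamped to [0, 1] — keeping within-patch spread under ~2 JND while
distinct archetypes within any one region are separated by > 4 JND under
the default visual system (asserted at fixture-build time by
`check_archetype_separation`).

The default "paper_like" scenario plants male-specific patches in the
five display regions — orange abdomen/chest (with black chest scales),
red throat, yellow cloaca, blue/green/yellow flanks — against UV-white
or brown shared backgrounds, and leaves Dorsum, Head, Legs, Mouth and
Head profile null (identical mixtures in both sexes). The manifest
emitted with each simulation names the planted regions; detector
recovery is always scored against it. An optional outlier contamination (off by default; a rate of ~0.008
with the narrow-UV "spike" archetype mimics the handful of stray
measurements seen in field data) exercises singleton removal.

What the synthetic fixture does **not** emulate: correlated
within-individual patch structure, spatial adjacency of patches,
instrument wavelength-dependent noise, specular artefacts, and
continuous (rather than mixture-discrete) variation between patch
classes. Passing tests therefore demonstrate that the pipeline recovers
mixture-structured dichromatism of the planted magnitude and calibrates
its null rates — not that any particular species is dichromatic.

## Reproducibility and problem sizes

Every stochastic step takes a seed; the pipeline derives per-stage seeds
from one root seed via `SeedSequence`, records them in the run log, and
reruns are byte-identical. Report CSVs are written with a fixed float
format (`%.10g`).

Default problem sizes in the packaged checks: 1,000 random catch pairs
for formula equivalence; 200 random 8-leaf matrices for UPGMA
equivalence; 200 planted + 200 null regions (25 individuals × 16
spectra each) for detector power/false positives; 500 null datasets at
n_perm = 200 for randomization calibration; and a 0.2–0.25-scale fixture
(~1,400–1,550 spectra) for the cone-proportion robustness and
end-to-end runs. These sizes give binomial standard errors comfortably
inside the asserted bands while keeping a full run on one CPU in the
low minutes.
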