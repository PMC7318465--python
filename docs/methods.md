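# Methods

## Scope and analysis plane

The pipeline quantifies, per field: (1) the number of cells (DAPI-positive
nuclei passing size/shape gates), (2) the number of inclusion-channel foci
inside each nucleus, and (3) per-nucleus channel intensities, followed by
group-level aggregation and tests. Z-stacks are collapsed to 2-D before
segmentation, by per-pixel maximum by default: all masks in this workflow
are planar binary images, and maximum projection preserves punctate
structures that occupy a few focal planes. Mean projection is available via
`projection_method`; per-slice 3-D segmentation is out of scope.

Pixel convention: 0-based (row, col); areas are reported in μm² through
`pixel_size_um²` (reader default 0.102 μm/px, the acquisition sampling
interval). Intensities stay on their native scale until Z-scoring.
Shading correction requires reference flat-fields and is not implemented;
rolling-ball background subtraction (default radius 50 px) is available but
off by default, since the synthetic fields carry no shading.

## Nuclei segmentation

"Fixed intensity thresholding" is implemented as a fixed fraction of the
per-image dynamic range (default 0.25) rather than an absolute grey value,
so uint8/uint16/float inputs behave identically. Components are labelled
with 8-connectivity by default. Gates: area 40–300 μm² and circularity
0.3–1.0 (defaults near typical HEK293/granule-cell nuclear cross-sections;
the gates exist in the original workflow but their values were not
published, so all are configuration), border-touching nuclei excluded.
Circularity `4πA/P²` uses the scikit-image perimeter estimate and is
clamped to ≤ 1: digitised discs can exceed 1 through perimeter
underestimation, and the clamp keeps the statistic in its nominal range.
Touching nuclei are not split (no watershed); the generator places nuclei
with a minimum separation, and real fields where nuclei touch extensively
will undercount.

## RATS foci detection

The inclusion channel is masked to nuclear pixels and thresholded by Robust
Automatic Threshold Selection. Definitions used here:

- gradient magnitude `g` by central differences (one-sided at borders);
- weights `w = g^p` with `p = 2` (squared-gradient) by default, zeroed
  where `g ≤ λσ_g` (`λ = 3`, `σ_g = 5` by default — σ_g should be set near
  the image's gradient noise scale);
- quadtree recursion down to leaves of edge ≤ `min_leaf_px` (default 16);
  a region sets its own threshold `T = Σ wI / Σ w` only when its total
  weight exceeds `(λσ_g)^p · min_leaf_px` (roughly `min_leaf_px` pixels at
  the noise cut — there is no canonical closed form for this floor at
  arbitrary `p`; this is our operating definition), otherwise it inherits
  its parent's threshold;
- per-leaf thresholds are blended into a smooth surface by piecewise-linear
  (Delaunay) interpolation between leaf centres, nearest-neighbour outside
  their hull; the mask is `I > T(x)`. With a single leaf this reduces
  exactly to the weighted-mean formula, which is how the oracle tests pin
  the implementation.

An image with no gradient support above the floor (e.g. constant) yields an
empty mask with a logged warning rather than an error.

Particles are gated to 0.2–3.0 μm². The original workflow defers to
published NSB sizes (diameters roughly 0.3–3 μm) without printing its
bounds, so these defaults are calibration knobs, not published facts.
Assignment to nuclei is by pixel majority, ties to the lower nucleus id.

## Intensity and Z-scores

Per-nucleus mean and integrated (summed) intensity are measured through the
nuclear mask for every channel; integrated intensity is the default "total
nuclear signal" statistic for condition comparisons, matching the
total-signal framing of the underlying assay (mean intensity is also
emitted). Z-scores use sample sd (`ddof = 1`) and standardise each channel
over the pool of all nuclei in the table — a common scale is what makes
between-protein and between-condition comparisons meaningful. Z-scoring a
constant or singleton pool is a reported input error.

## Group statistics

- Mann–Whitney U: U from midrank sums; two-sided p by full enumeration of
  all C(n₁+n₂, n₁) group assignments when n₁+n₂ ≤ 12 (ties handled
  exactly), otherwise the tie-corrected normal approximation with
  continuity correction. The Bonferroni family is exactly the set of
  pairwise comparisons run (6 for four groups).
- One-way ANOVA with Tukey HSD post-hoc (studentized-range p values); the
  all-means-equal degenerate case returns F = 0, p = 1 explicitly.
- OLS regression (slope p from t with n−2 df) for the
  inclusion-count → reference-intensity relationship.
- Two-proportion comparison (cells with ≥ 1 nuclear vs ≥ 1 cytoplasmic
  inclusion): the source analysis does not name its test, so a pooled
  two-sided z test is used, with Fisher's exact test unless every pooled
  expected cell count exceeds 5, and results are labelled with the test
  actually applied. Cytoplasmic counts are never detected by the pipeline;
  they enter only as an externally supplied per-cell column, mirroring the
  original manual counting.
- Summary aggregation: total cells, mean/SEM cells per field (SEM over
  fields), mean/SEM inclusions per cell (SEM over cells). The published
  table does not state its SEM units; both denominators are recorded in the
  output metadata. Note the published FTLD dentate row's mean cells/field
  (40.92) is not exactly total/(subjects × 8) = 40.875, suggesting excluded
  fields in the original; the discrepancy is surfaced here rather than
  guessed at, and the arithmetic worked examples use the three rows that
  are exactly consistent.

## Synthetic generator

What it emulates: fields of ~40–52 non-overlapping elliptical nuclei
(area-preserving axis ratio ≤ 1.1, radius 4–6 μm, minimum edge separation
2 μm); per-nucleus inclusion counts from a zero-inflated Poisson capped at
17 (the observed per-cell range); group presets whose means track the
published per-cell burdens — control 0.44, AD 0.98, ALS 1.49, FTLD 2.38 —
via (π₀, λ) = (0.75, 1.76), (0.60, 2.45), (0.50, 2.98), (0.30, 3.40); foci
as isotropic Gaussian spots (FWHM drawn uniformly from 0.8–1.5 μm,
amplitude 150 over a diffuse nucleoplasmic level of 10); a reference
channel at `max(0, b₀ − β·k + ε)` with b₀ = 120, β = 10, ε ~ N(0, 8²); and
optics/detector effects as a 1-px Gaussian blur plus additive read noise
(σ = 4, spot SNR ≫ 5; Poisson shot noise optional). Subject-level
heterogeneity multiplies each subject's rate by a lognormal factor
(10 % sd). Studies follow the source design of 8 fields per subject.

Synthetic fields use 0.2 μm pixels on 768×768 grids (≈154 μm square) so
that ~50 nuclei of realistic size fit per field at desk scale; the 0.102 μm
acquisition calibration remains the reader default for real data.

Foci centres keep a 2.5 μm minimum separation and a 1 μm margin from the
nuclear rim. The separation is chosen so that distinct spots remain
optically resolvable after blur: closer pairs would fuse into a single
rendered blob and the recorded truth would no longer describe the image,
breaking the generator's contract that truth be consistent with the render
by construction. When a drawn count cannot be placed under these
constraints the truth records the placed count.

What it does not emulate: realistic PSFs, tissue autofluorescence,
lipofuscin, nucleolar/perinucleolar substructure, touching or overlapping
nuclei, cytoplasmic inclusions, or section-to-section staining variability.
Passing the validation bound on synthetic fields therefore demonstrates
correctness of the measurement chain at a favourable, well-specified
operating point — not segmentation robustness on real tissue, which must be
re-validated against manual counts (the harness exists for exactly that
comparison).

## Validation harness and determinism

`validate_run` generates ≥ 10 fields (20 by default), quantifies them with
the supplied configuration, and scores the fraction of fields whose
automated cell count *and* total focus count both exactly match truth,
against the 95 % agreement criterion used for the original pipeline's
manual-count validation. Falling short is a reported failure, not an
exception.

Determinism: every random draw descends from a single integer seed
(`numpy` Generator; spawned per-field seeds are < 2³¹); identical spec +
seed reproduce bit-identical images and truth, and identical config + input
reproduce byte-identical CSV/JSON outputs (fixed row order: group, subject,
field, nucleus; floats at 6 significant digits).

## Problem sizes used in the checks

Unit and property tests run on 256–448 px fields with 5–10 nuclei; the
validation bound uses 20 default 768 px fields; distribution-level checks
(four-group ordering, β recovery) use truth tables from `render=False`
studies of 3–5 subjects × 8 fields × ~50 nuclei per group, where the
Mann–Whitney and OLS power at the preset effect sizes is ample. These sizes
are the package's own desk-scale choices; all are parameters, not limits.

## Known limitations

- No watershed splitting: merged nuclei count as one.
- RATS has no spot-splitting; foci closer than the blur scale merge, and a
  merged particle exceeding the size gate is discarded (both counts lost).
- The exact Mann–Whitney enumerates C(n₁+n₂, n₁) assignments and is capped
  at n₁+n₂ = 12 by design.
- Rolling-ball background estimation climbs slightly (≈ R − √(R²−1)) into
  single-pixel spikes, so repeated subtraction is only approximately
  idempotent around such features.
- The two-proportion test treats cells as independent; no subject-level
  clustering correction is applied anywhere (none was used in the source
  analysis either).
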