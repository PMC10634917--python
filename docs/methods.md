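# Methods

This note documents the models, parameter choices and numerical decisions
behind `aznano`, and what the synthetic-data tests do and do not establish
about real data.

## Coordinate and unit conventions

All internal positions are in nm. Camera-pixel-denominated quantities (the
PSF-fit σ filter bounds, the linking radius, the nanocluster alpha radius) are
converted at the point of use through the table's `pixel_size_nm` (default
160 nm, i.e. a 20-nm rendering pixel at 8× magnification; always explicit,
never assumed silently). Frames are 0-based integers in `[0, n_frames)`.
Rendering pixels are half-open squares: pixel (i, j) covers
`[origin + i·p, origin + (i+1)·p)` per axis. Row order in a localization table
carries no meaning; all operations are permutation-invariant.

## Preprocessing

**Quality filters.** Localizations are removed when the PSF-fit σ is < 0.3 or
> 1.6 camera pixels, the localization error exceeds 20 nm, or the photon count
exceeds the upper edge of the modal bin of the photon histogram (the photon
rule discards likely multi-emitter events). The histogram binning is not
uniquely determined by the rule itself; this implementation uses fixed 50-photon
bins anchored at zero, ties broken toward the lower bin, and the *upper* edge
of the modal bin as the threshold — deterministic and insensitive to outliers;
both the bin width and the rule are configurable. The modal bin is computed on
rows that already passed the σ and precision rules. Removal causes are counted
with precedence σ → precision → photons; the surviving set is independent of
that precedence.

**Temporal linking.** Localizations of one binding event are merged greedily
in frame order: a localization joins the nearest active event whose running
photon-weighted mean position lies within 0.3 px and whose last appearance is
at most 5 dark frames in the past (ties toward the earlier event; same-frame
localizations never merge). Merged events keep the photon-weighted mean
position, summed photons, first frame, and — conservatively — the minimum
member precision; `last_frame`/`n_merged` columns make the operation
idempotent in its gap criterion.

**Drift correction.** Redundant cross-correlation: the acquisition is cut into
1000-frame segments, every segment pair is rendered as a 30-nm-pixel histogram
on a common grid and cross-correlated by FFT with sub-pixel quadratic peak
interpolation, and the per-segment drift is solved from all pairwise shifts by
least squares (first segment anchored at zero). Per-frame drift is linearly
interpolated between segment midpoints and linearly extrapolated at the ends.
A drift component constant over the whole acquisition is a gauge freedom —
cross-correlation only sees relative shifts — so estimates are reported
anchored to zero at frame 0 and compared to ground truth in the same gauge.

**Chromatic correction.** A degree-2 polynomial per axis (basis
1, x, y, x², xy, y²) is fitted by least squares from bead control-point pairs,
internally in centered/scaled coordinates for conditioning with the
coefficients expanded back to the raw basis. Six pairs are the minimum;
collinear configurations raise a conditioning warning. Because the planted
synthetic warp lives in the same model class, noise-free coefficient recovery
is exact to numerical precision (~1e-11).

**Residual offset.** Each remaining target is rigidly translated onto the
reference analysis target by the sub-pixel peak of the cross-correlation of
20-nm rendered images. Confidence is the ratio of the main correlation peak to
the best peak outside a 5-pixel exclusion zone (both above the median);
unrelated patterns give ratios near 1 and are flagged below a default
threshold of 2.

## Synapse selection

Scaffold (Bassoon-role) and postsynaptic (PSD-95-role) clusters come from
DBSCAN at ε = 48 nm, minPts = 10 (the point itself counts toward its
neighborhood), with clusters under 75 localizations discarded. Nonspecific
imager-binding clusters are short-lived, so clusters are removed when their
frame-number SD falls outside (2500, 11000) — a specific cluster sampled
uniformly over 30,000 frames has SD ≈ 30000/√12 ≈ 8660 — or when their mean
frame lies outside μ ± 2σ of a maximum-likelihood normal fit to all cluster
mean frames (skipped, with a warning, below three clusters). Note these
thresholds presuppose the 30,000-frame acquisition; shorter synthetic
acquisitions must scale them.

**Alpha shapes.** The alpha shape keeps every Delaunay triangle with
circumradius ≤ the alpha radius and unions them (convex hull in the large-alpha
limit; area is monotone in alpha). Nanocluster shapes use alpha radius
0.9375 camera px; with 160-nm pixels this is 150 nm, and the same physical
radius is used for synapse-scale shapes (configurable).

**En-face criterion.** The roundness constraint on the smoothed scaffold alpha
shape is implemented as the major/minor axis ratio of the second-moment
ellipse of the boundary-smoothed polygon (3-vertex cyclic moving average),
computed from exact polygon area moments; synapses with ratio ≤ 2 pass. This
is an *interpretation* of a constraint whose exact metric is not recoverable —
a dimensionless "≤ 2" reads most naturally as an aspect ratio for en-face
(round) footprints — so acceptance fractions should not be compared across
implementations. Area overlap between the two scaffold shapes is intersection
area over the smaller shape's area (nested shapes can reach 100%; a
scaffold-area denominator is available), thresholded at 70%. Analysis targets
are then restricted to the scaffold polygon (boundary-inclusive point-in-
polygon for determinism at edges) and the synapse is dropped if any required
target has fewer than 25 localizations inside.

## Nanoclusters and autocorrelation

Nanocluster DBSCAN parameters are deliberately explicit configuration
(defaults ε = 25 nm, minPts = 5, consistent with the ≥ 5-localization filter):
no principled values are fixed by the analysis itself, and results always
record them. Detected clusters below 5 localizations are dropped; then, across
the whole dataset (not per synapse), clusters whose alpha-shape area exceeds
the largest area not flagged as a high outlier (univariate ROUT, Q = 0.1%) are
removed. The centroid is the unweighted member mean (a density-peak reference
is a configurable alternative); the effective radius is √(area/π).

The within-synapse pair autocorrelation g(r) divides observed pair counts per
radial bin (10-nm bins to 200 nm by default) by the expectation for a
homogeneous pattern of the same intensity in the same polygon. The expectation
comes from the polygon's isotropized set covariance — the pair-distance
distribution of two uniform points — estimated on a 2-nm raster by FFT
autocorrelation of the polygon mask, with each displacement cell integrated
over a 2×2 subgrid to suppress lattice-circle quantization in the smallest
bins (residual bias < 2% against Monte-Carlo truth for a disc). CSR fields
give g ≈ 1 in every bin (the calibration test averages 200 synthetic
synapses).

## Cross-enrichment, classification, separation index

For each nanocluster of protein A, the density of protein B (count per in-ROI
annulus area, annuli clipped to the scaffold polygon with shapely so
near-edge centers are unbiased) is computed per radial bin and divided by the
same quantity averaged over 100 uniform randomizations of B inside the
polygon. Bins whose annulus lies entirely outside the polygon are missing, not
zero. For population curves, per-bin high outliers across nanoclusters are
replaced by the highest non-outlier value (ROUT, Q = 0.1%).

Classification compares the mean enrichment over bins with outer edge ≤ 60 nm
(unweighted) against the same statistic for 50 *independent* randomizations
(seeds derived from the master seed per synapse, protein and purpose):
enriched above mean + 1.96 SD, de-enriched below mean − 1.96 SD, strict
inequalities, otherwise indistinguishable. The envelope uses the SD across the
50 randomization statistics (not a pooled per-bin SD). Under a CSR opposite
protein the two-sided tail rate is a few percent (nominal 5%, mildly inflated
by the 50-sample SD estimate); the calibration test requires 2–10% over ≥ 500
nanoclusters.

The separation index of a nanocluster is computed against the *nearest*
opposite nanocluster by centroid distance (ties toward the lower cluster id):
SI = d/(r₁ + r₂) with r₁, r₂ the centroid-to-border distances along the
connecting line, measured on the actual alpha-shape polygons (first boundary
crossing along the ray). Coincident centroids give SI = 0, flagged degenerate,
with the effective radii reported. SI is symmetric for circle pairs and
scale-invariant.

## Synthetic data: what it emulates, what it does not

One simulated field contains a scaffold disc (default radius 200 nm, 500
binding events), a concentric postsynaptic disc (scale 0.9), and two analysis
targets drawn from K planted nanoclusters (defaults: 4 Gaussian clusters of
σ = 15 nm for the Munc13-1 role, 3 of σ = 20 nm for the CaV2.1 role, 60
events each, 10% uniform background — the Munc13-role clusters denser and
smaller, as at hippocampal synapses). Architectures: `co_organized` (B centers
coincide with A centers, optional offset), `segregated` (B centers ≥ 100 nm
from every A center), `independent`. Binding events arrive uniformly over
30,000 frames; run lengths are geometric (mean 3 frames) with occasional ≤ 5-
frame dark gaps; per-frame localizations are jittered by a per-row precision
(~7 ± 1.5 nm) and carry per-frame photon counts peaked at the imager
brightness (8% CV) with a partial-frame tail, so the photon-mode filter
behaves as on real data. A small fraction (2%) of rows violates the quality
bounds, and nonspecific binders are planted outside the synapse as tight
clusters confined to a 2000-frame window (frame SD ≈ 580 < 2500, so the
frame-statistics filter catches them). A `disc` cluster profile (uniform
within a planted radius) is used for radius-recovery tests because a uniform
disc has a well-defined planted effective radius, unlike a Gaussian cloud.

Not emulated: imager/docking kinetics and photophysics (no triplet states, no
concentration dependence), 3D structure and astigmatism, spatially varying
background, camera noise models, and multi-synapse interference within one
field. Passing the recovery tests therefore shows the chain is correct and
well-calibrated on its stated model, not that the defaults match any
particular microscope.

Auxiliary generators: `simulate_fiducial_field` (fixed sites revisited across
the acquisition — the structured field drift estimation needs; uniform
scatter carries no inter-segment correlation signal), `simulate_bead_pairs`
(control points under a planted warp), `simulate_side_view_images` (two-channel
Gaussian bars with a planted trans-synaptic offset).

## ROUT adaptation

The original ROUT procedure targets robust nonlinear regression. The
univariate reduction used here takes the median as the robust fit, the 68.27th
percentile of absolute residuals with an n/(n−1) small-sample factor as the
robust residual SD, converts residuals to t statistics (df = n−1, one- or
two-sided), and flags from the most extreme value inward with a
Benjamini–Hochberg-style threshold at rate Q, testing at most 30% of values;
when the robust scale is exactly zero, any nonzero residual on the tested side
is flagged. Correctness is defined by calibration, not by matching a
proprietary implementation: ≤ 1% average flags on clean N(0,1) samples at
Q = 0.1%, ≥ 95% sensitivity to 10-SD contaminants.

## STED side-view line profiles

Profiles are 750 nm long and 250 nm wide, sampled at the 22.7-nm acquisition
pixel with bilinear interpolation (intensity at each along-axis sample is the
mean over the across-axis samples). Smoothing is a centered 5-sample rolling
average with shrinking edge windows. Profiles are aligned by whole samples to
the postsynaptic-marker peak (ties toward the profile center, logged) and
averaged channel-wise with SEM across synapses on the common grid; averaging
jittered peaks attenuates the mean peak below individual peaks, which is why
averaged profiles top out below 100%. Peak intensities (maximum of the
smoothed profile) are normalized per culture to the mean of the comparison
condition, making that group's mean exactly 100% by construction. Profiles
are normalized before averaging when both are reported.

## Determinism and problem sizes

Every stochastic step takes a seed; pipeline randomizations derive per
(synapse, protein, purpose) from the master seed via `SeedSequence`, so adding
synapses does not perturb other synapses' draws. Two runs with equal
configurations and inputs are identical, and the run manifest echoes every
parameter plus per-stage counts.

Test and acceptance problem sizes are chosen as the smallest that give the
statistics adequate power: 200 random point sets for the DBSCAN oracle, 200
synapses for the g(r) null, 500 nanoclusters for the classification tails, 50
seeds for nanocluster-count recovery, 20 paired seeds for architecture
discrimination (fractions aggregated over seeds before comparison, since
per-seed fractions over a handful of nanoclusters are integer-granular), and a
~1600-row packaged fixture whose stage-by-stage counts are frozen as a
regression surface.

## Known limitations

* The en-face "≤ 2" roundness metric and the overlap denominator are
  interpretations; both are config-exposed and flagged above.
* Nanocluster DBSCAN parameters are unavoidably user-chosen; absolute
  nanocluster counts/areas depend on them and are not comparable across
  parameter choices.
* The chromatic model is a global degree-2 polynomial; field-dependent or
  time-varying aberrations and z-drift are out of scope.
* Enrichment bins near the ROI edge with tiny clipped annulus areas are noisy;
  they are excluded when empty but not variance-weighted.
* The linking greedy match is order-deterministic but not globally optimal;
  at realistic densities this is immaterial.
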