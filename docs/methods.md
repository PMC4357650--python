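# Methods

This note documents the models, numerical choices and limitations behind
`glycomsi`, in the spirit of the methods documentation of packages like
statsmodels or scanpy.

## Mass arithmetic

Glycan compositions are multisets over five residue classes with
monoisotopic dehydrated residue masses (Da): Hex 162.052824,
HexNAc 203.079373, dHex 146.057909, NeuAc 291.095417, NeuGc 307.090331;
water 18.010565.  The neutral mass is `Σ count·residue + H₂O`, so the
all-zero composition legally has the mass of one water.  The sodiated
adduct adds `Na − e⁻ = 22.989221 Da`: the electron-mass correction
(0.00055 Da) matters when masses are compared at four decimals.  The
glycosylamine form (PNGase F's initial release product, NH instead of OH
at the reducing-end HexNAc) sits 0.984016 Da below the free reducing
end — the source of an apparent ~1 Da discrepancy between measurement
modes when both forms co-exist.  Reduced alditol ions add 2.015650 Da
(ring opening + 2H) before deprotonation.  All ppm errors are signed,
`10⁶·(obs − calc)/calc`; summaries over sets use the mean of absolute
values.

The bundled murine-kidney reference table maps each reported
abundance-weighted-mean `[M+Na]⁺` value to a composition.  Those
assignments were made by exhaustive enumeration over
(Hex, HexNAc, dHex, NeuAc, NeuGc) within ±120 ppm of each observed
value; each has a unique biologically plausible solution (the
high-mannose series Man5–Man9 plus fucosylated complex glycans).  With
these assignments the mean |ppm| of the nine top-ranked species computes
to 34.6 ppm; the originally reported summary of the same comparison is
38.7 ppm, a figure we could not reproduce under any arithmetic
convention we tried (electron-mass inclusion or exclusion, neutral vs
sodiated denominator, rounding of calculated masses, signed vs absolute
averaging).  The package reports what it computes.

## Preprocessing

*TopHat baseline* is the residual after a grayscale morphological
opening (erosion then dilation) with a flat window, which by
construction is non-negative and preserves peaks narrower than the
window.  The window is expressed in points (default 101, configurable);
it should be wide enough to pass beneath glycan isotope envelopes at the
instrument's sampling density.  Edges replicate the boundary samples.

*Data reduction* resamples a profile onto n equal half-open m/z
intervals taking the per-interval **maximum** — a peak-preserving choice
(apexes are never lost) where the vendor's method is unspecified.

*Recalibration* fits `corrected = a·m² + b·m + c` by least squares from
calibrant pairs; each reference mass is matched to its nearest observed
peak within 500 ppm, ≥3 pairs are required, and exactly 3 interpolate
with zero residual.  When two calibrant spots are available the fit with
the lower maximum |residual| is the natural "best calibration" to copy
to all spots.  Application requires the model to be strictly increasing
over the acquisition m/z range so peak order is preserved.

*Binning* uses half-open `[lo, hi)` bins of fixed width (default
0.5 Da); a peak exactly on an edge belongs to the upper bin, and total
in-range intensity is conserved.  `occupancy_filter` is a data-reduction
step for the multivariate stages: it keeps only bins populated in at
least `min_spectra` spectra (default 100, the same screen applied to
peak groups before DIPPS), standing in for the peak pick/align step of
commercial MSI software.

Grid coordinates are 0-based, x rightward, y downward; these conventions
are stated once here and used everywhere.

## Peak grouping and occurrence

"Linkage distance" clustering is implemented as 1-D single linkage: all
peaks pooled, sorted by m/z, cut at consecutive gaps strictly greater
than the linkage distance (default 0.1 m/z).  This is the only
interpretation with a unique, order-independent 1-D result, and it is
verified against agglomerative single-linkage clustering on random
instances.  The AWM uses S/N as weights and never intensity; if every
member S/N is zero it falls back to the unweighted mean and flags the
group.  Occurrence counts **spots**, not peaks — a spot's duplicate
peaks in one group count once — which keeps occurrence proportions
bounded by 1.  All candidate-filter thresholds are inclusive
(≥2 treated, ≤1 control, AWM strictly > 1000 m/z; conservative variant
≥4; imaging screen ≥100 spectra).

## DIPPS

`DIPPS = p_treated − p_control` per peak group; ranking is descending
with ties broken by ascending AWM m/z for determinism.  Selection is
either user top-N or a data-dependent cutoff: every observed DIPPS value
is scanned as a candidate cutoff and scored by the mean per-group
occupancy contrast of the resulting DIPPS map between treated and
control spots, ties resolving to the larger cutoff (fewer groups).  The
original data-dependent heuristic in the field is unpublished; this rule
is one admissible choice, exposed beside top-N, not a reproduction.
Intensity maps use log1p so spots without signal remain at zero.
No multiple-testing calibration is attached to DIPPS values; they are a
ranking statistic, not a significance test.

## Multivariate summaries

*Bisecting k-means* repeatedly splits the leaf with the highest
correlation-distance inertia using 2-means (default 5 restarts, best
within-split inertia wins).  Rows are centred and scaled to unit norm so
squared Euclidean distance is an affine function of correlation
distance, letting standard Lloyd iterations minimise the correlation
objective.  Constant (zero-variance) rows are rejected — correlation is
undefined for them — so empty spots must be dropped first.  The
segmentation is deterministic given `random_state`.

*pLSA* fits the aspect model `P(s,b) = Σ_z P(z)P(s|z)P(b|z)` by EM from
random initialisation, recording the log-likelihood trace (guaranteed
non-decreasing).  Spots with zero total intensity are excluded from the
fit and surface as NaN in component maps.  `transform` folds new (or
training) rows in with the bin profiles fixed, yielding per-spot
component weights on the simplex.  Memory use is bounded by iterating
over components rather than materialising the n×m×k responsibility
tensor.

For the phantom acceptance analyses, segmentation runs on `log1p`
intensities of the occupancy-reduced matrix (log transformation
stabilises the heavy-tailed, log-normal peak intensities that otherwise
dominate the correlation structure) and pLSA on the TIC-normalised
reduced matrix.  Equivalence to commercial implementations is
qualitative (region discrimination), never bitwise; their smoothing and
inertia internals are undocumented, and the optional 3×3 median filter
offered for maps is not equivalent to "strong smoothing".

## The phantom generator

The default phantom is a 60×40 grid (2,400 spectra): an elliptical
treated tissue (~650 spots) whose inner ellipse (half the semi-axes) is
the medulla and whose annulus is the cortex, a smaller control tissue
(~370 spots), two calibrant spots carrying the GLY3 triplet, and
matrix-only background.  Twelve glycans are planted: six tissue-wide,
four cortex-restricted, two medulla-enriched.  Present-in-region
prevalence is 0.94 — the 15/16 occurrence level reported for in situ
profiling spots — with 0.06 for trace presence, and the buffer-control
tissue carries no glycans.  Presence is Bernoulli per spot and species;
a present species contributes one peak at its sodiated mass plus
N(0, 0.02 Da) jitter (kept below a quarter of the 0.1 m/z linkage so
each planted mass resolves into one group), log-normal intensity
(σ=0.7) and S/N of 3 plus an exponential excess, mirroring the S/N > 3
picking threshold.  Noise peaks are Poisson (mean 5 per spectrum),
uniform over the 1000–3000 m/z acquisition window, with low S/N — the
simplest model that stresses the occurrence filters.  Glycosylamine
satellite peaks at −0.984 Da can be planted at a configurable fraction
(default 0).  Everything derives from a single seed; identical seeds
give identical datasets.

What the phantom does **not** emulate: isotope envelopes and
deconvolution artefacts, matrix-cluster chemistry, detector saturation,
spatial intensity gradients, correlated (chemical) noise, and mass-drift
across the acquisition.  Passing tests therefore demonstrate the
correctness of the statistics and their implementations under the stated
generative model, not instrument-level robustness.

The expected DIPPS of a planted species is its area-weighted treated
prevalence minus its control prevalence.  The sampling band used in
acceptance checks, `2·√(p(1−p)/n)` with n the treated-region size, is a
per-species ~95% interval; across twelve species the checks therefore
allow misses at the nominal rate (at most two species outside the band)
with a hard cap at twice the band, rather than requiring all twelve
simultaneously — the latter would be stricter than the per-species
statement and fail a fixed seed roughly half the time by chance alone.

## Problem sizes

The test suite and acceptance script run the phantom at its default
2,400 spots, grouping oracles on 1,000 random instances of ≤100 peaks,
baseline oracles on 200 random profiles of ≤200 points, and 50 random
quadratic recalibration round-trips; the full suite completes in well
under a minute on one CPU.
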