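# Methods

This note documents the models, rules, and numerical choices behind each
stage of the pipeline, what the synthetic-data generators do and do not
emulate, and the known limitations.

## High-content image quantification

**Nucleus tracing.** The Hoechst channel is thresholded (Otsu by default;
an explicit threshold can be fixed) and 4-connected components are traced.
A nucleus is *accepted* iff its area is strictly greater than
`min_area_um2` (default 50 µm²) and its mean intensity is strictly below
the pyknotic brightness threshold. Pyknotic nuclei — condensed nuclei of
dying cells — are several-fold brighter than healthy ones; when no absolute
threshold is supplied, it is derived from the data as
`pyknotic_multiple` (default 2.5) × the median intensity of area-passing
nuclei. Both inequalities are strict, so an object of exactly 50 µm² is
rejected. Only an upper intensity bound is enforced; a lower bound for
dim/out-of-focus nuclei is not (the foreground threshold effectively plays
that role).

**Region expansion.** "Expanded by 50%" is read as +50% in *area*. Each
accepted nuclear mask grows by claiming background pixels in order of
Euclidean distance from the mask until its pixel count first reaches
⌈1.5 × area⌉; every background pixel can be claimed only by its nearest
nucleus (computed once by a Euclidean distance transform), so regions never
merge and adjacent cells tile their shared boundary. This is equivalent to
an isotropic dilation with sub-ring resolution. An interpretation of
"expanded by 50%" as +50% in radius would grow areas by 2.25×; the area
reading matches the phrase most directly and is the default.

**Marker positivity.** Intensity mode compares each expanded region's mean
intensity to a background-referenced threshold: image median (background
dominates the field area) + 25% of the range up to the brightest region.
Unlike a bimodality split (e.g. Otsu on region means), this behaves
correctly when none or all cells express the marker. A channel with no
contrast at all is called by signal presence (positive iff the flat level
exceeds zero). Granule mode calls a cell positive iff at least one detected
punctum of the marker lies inside its expanded region. Ratios
(βIII-tubulin⁺/Hoechst⁺, MAP2⁺/βIII-tubulin⁺, VGluT2⁺βIII⁺/βIII⁺, …)
are computed from the per-cell flags via `positivity_ratio`.

**Fiber morphometry.** The fiber channel is binarized and skeletonized
(`skimage.morphology.skeletonize`). Skeleton length sums 8-connected chain
steps with weight 1 (orthogonal) and √2 (diagonal); a diagonal link that
short-cuts an existing orthogonal corner is not double-counted. Components
shorter than `min_component_um` (default 10 µm) are discarded — they are
speckle or the stubby medial axes of cell bodies, not fibers. The field
metrics are total length *a*, component count *b*, and mean length *a*/*b*
(undefined when *b* = 0). Digitization biases (chain-code overestimation at
oblique angles, endpoint erosion by roughly half the fiber width) partially
cancel; measured recovery against known polyline arc lengths is ~2% mean
absolute error at 0.65 µm/px, and the estimate shifts < 3% when the same
geometry is rendered at twice the pixel density.

**Dendrite length** is the same skeleton measure on the MAP2 channel,
divided by the MAP2⁺ cell count from the positivity step (the per-field
total is also returned, since either normalization may be wanted). An
optional `exclude_mask` restricts the skeleton to MAP2 signal outside the
somata.

**Puncta.** Detection is difference-of-Gaussians filtering tuned to a
0.3–2 µm diameter band, local-maximum extraction above 3× the robust noise
of the DoG response, plus a raw-intensity gate of ≥ `background_k`
(default 3) × the local background (image median). Only puncta whose
centroid lies on the neuron (βIII-tubulin⁺) mask are counted when a mask
is given; shrinking the mask can therefore only decrease counts.
Colocalization forms candidate pre/post pairs within `max_distance_um`
(default 0.5 µm) and matches them greedily closest-first, each punctum
used at most once, so n_coloc ≤ min(n_pre, n_post) by construction.

**EB morphometrics.** Area is the pixel count of the largest connected
component; the perimeter comes from the sub-pixel marching-squares contour
simplified by Douglas–Peucker at 1 px tolerance, which removes the
digitization staircase while preserving real corners (error ~1% for both
smooth blobs and polygons — raw pixel-count perimeters cannot be accurate
for both). Form factor is 4πA/P²: 1 for a circle, π/4 for a square,
decreasing with elongation.

## MEA analysis

Filtering is a 3rd-order Butterworth bandpass (200–3000 Hz) applied
forward–backward (`sosfiltfilt`) for zero phase, per electrode. Baseline
noise SD is estimated robustly as median(|x|)/0.6745, which a spiking
trace does not inflate the way a raw SD would. Detection marks the
extremum sample of each excursion beyond `threshold_sd` (default 6.0) × SD;
excursions closer than the 1 ms refractory window merge into one event.
Detection is bipolar (±) by default with `polarity="positive"`/"negative"
modes, since extracellular spikes are predominantly negative while
plate-reader thresholds are quoted one-sided. An electrode is *active* iff
its rate is strictly > 5 spikes/min (25 spikes in a 300 s recording is
inactive); the well summary reports the active count and the mean rate in
spikes/s over active electrodes only, flagging wells with none. The drug
response is the per-well ratio of total spikes post/pre treatment; wells
with zero pre-treatment spikes are excluded with a warning, and mismatched
well sets raise.

## Calcium analysis

The endpoint photobleach correction subtracts a linear ramp running from 0
at the first frame to (F_last − F_first) at the last, so corrected first
and last frames are equal and a purely linear decay becomes exactly
constant; transients riding on the drift are untouched. (Subtracting the
endpoint difference as a constant offset would not flatten a drift; that
literal mode is available as `mode="constant"` for comparison.)
ΔF/F = (F − F₀)/F₀ with F₀ the first-frame value (default) or a
baseline-window mean; ROIs with F₀ ≤ 0 are excluded with a warning. ΔF/F
is invariant to rescaling the raw trace by any c > 0.

Event detection finds peaks on a 2-frame-Gaussian-smoothed copy of the
ΔF/F trace with minimum separation 10 frames and prominence ≥ k (default
3) × the robust noise SD of the *unsmoothed* trace (median absolute first
difference / (0.6745√2), insensitive to the transients). Because smoothing
shrinks the noise ~2.7×, this threshold sits ~8 noise SDs above the
smoothed trace, which is what keeps the false-event rate on a pure-noise
3500-frame trace near zero — a literal 3σ prominence cut on the raw trace
would fire on noise peaks over a hundred times per trace. Per-event
amplitude is the apex minus the median of a short pre-onset window
(frames apex−25…apex−8), both read from a minimally smoothed (σ=1) copy so
amplitudes stay calibrated; ΔFmax is the largest per-event amplitude of an
ROI, and since the per-well aggregation convention varies, the summary
reports all three (max over events, mean of ROI maxima, mean over events).
Measured ΔFmax mean absolute error is ~0.03 ΔF/F at the generator's
default noise and stays ≤ 0.05 for signal-to-noise ≥ 8.

## Statistics

**Dunnett.** With a shared control, the null vector of control-vs-group t
statistics is equicorrelated multivariate t: corr(Tᵢ,Tⱼ) = λᵢλⱼ with
λᵢ = √(nᵢ/(nᵢ+n₀)), which factorizes over one standard normal Z₀ (the
control mean) and the pooled-variance chi factor U = S/σ. The two-sided
adjusted p-value 1 − P(max|Tⱼ| ≤ |tᵢ|) is computed by numerical
integration: 96-node Gauss–Hermite in Z₀ × 64-node Gauss–Legendre in the
probability transform of U. The factorization is exact for unbalanced
designs as well, so no Monte-Carlo fallback is needed; k=1 reduces
analytically to the two-sided pooled t-test and is special-cased to the t
CDF. Agreement with 10⁶-draw Monte-Carlo nulls is ~3×10⁻⁴ in p, and the
derived critical values reproduce the classical tables (e.g. 2.44 for two
comparisons at df 15, α 0.05 two-sided). Variance homogeneity is assumed
(pooled estimator over all groups); Welch-type variants are out of scope.

**Tukey HSD** uses the studentized-range distribution with the
Tukey–Kramer standard error √(s²·(1/nᵢ+1/nⱼ)/2) for unequal sizes. t-tests
are the standard pooled two-sample and paired forms; degenerate
(zero-variance) inputs yield t=0, p=1 with a warning rather than NaN.

**ΔΔCt.** Per sample, ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the
calibrator group's mean ΔCt, making the calibrator's geometric mean RQ
exactly 1; RQ = 2^(−ΔΔCt). Group summaries are geometric mean and
geometric SD (sample SD of log₂RQ, exponentiated, ddof 1). Samples whose
target Ct is missing (below the detection limit) are dropped with a
warning; a missing reference Ct is an error. Adding any constant to every
Ct (instrument offset) leaves all RQ unchanged.

**DEG screening.** Fold change is the ratio of arithmetic group means on
linear-scale expression; a gene is differential iff fold > threshold or
fold < 1/threshold, strictly (a gene at exactly 2.0-fold is excluded).
Venn counts are set intersections of the per-contrast DEG lists. No
cross-family multiplicity correction is applied — adjustment is per
comparison family only.

## Synthetic data: what it emulates, and what it does not

Nuclei are ellipses (exact area πab), fibers are smooth random-walk
polylines (heading increments N(0, 0.12 rad) per 2 µm step; exact arc
length; each fiber confined to its own grid cell so components never
merge), puncta are Gaussian spots (σ 0.25 µm) placed on the dilated fiber
mask with ≥1.4 µm same-channel spacing; colocalized pairs are offset
0.2 µm, non-pairs kept ≥2.5× the 0.5 µm criterion apart. Pyknotic nuclei
are brighter than every normal nucleus by construction. Pixel size
defaults: 0.65 µm/px for 20×-style fields, 0.22 µm/px for 60×-style
synapse fields, 3.25 µm/px for EB wells — plausible stand-ins, since
instrument calibrations vary. MEA spikes are derivative-of-Gaussian
biphasic templates (~1.3 ms, spectral mass near 500 Hz, inside the
analysis band) at homogeneous-Poisson times; calcium transients rise in ~3
frames and decay with a 15-frame constant on a linear bleaching drift,
with the first-frame noise zeroed so F₀ is exact. Cohorts scale baselines
by per-group multiplicative factors and add lognormal between-replicate
variability (CV 15% default, the realistic scale of independent
differentiation experiments).

Deliberately not emulated: optics (no PSF convolution, no depth/defocus),
spatially varying background, cell crowding and touching nuclei, fiber
crossings and branching, spike waveform diversity and bursting, network
synchrony, calcium indicator saturation and nonlinear bleaching (an
exponential drift option exists for robustness checks only). Passing the
recovery tests therefore demonstrates the correctness of the measurement
chain on well-posed inputs, not robustness to every real-world imaging
pathology; thresholds are all config-exposed for real data.

## Orchestration and problem sizes

The pipeline aggregates field → well → replicate experiment → group and
takes the statistical n at the replicate-experiment level, mirroring the
"independent experiments" convention of such studies. Runs are
deterministic: replicate seeds derive from the single run seed via
seed-sequence spawning, and identical config+seed reproduce byte-identical
CSV outputs; the manifest records the package version, seed, and a hash of
the canonical config YAML. Default verification sizes — 20 scenes per
geometry class, 12+6 electrodes × 300 s for spike scoring, 10⁶ Monte-Carlo
draws per oracle comparison, 10,000 null datasets for the familywise-error
measurement, 1,000 cohorts per power/null arm (cohort power runs use the
measurement-level simulator; rendering a thousand image cohorts would add
nothing statistically) — were chosen to make Monte-Carlo uncertainty small
relative to every tolerance while keeping a full verification run in the
minutes range on one CPU.

## Known limitations

- Nuclei touching in dense fields are not split (no watershed); the
  generators enforce separation, real data may not.
- Skeleton length is slightly biased for oblique straight lines (chain-code
  effect, ≤ ~5% worst-case angle) and the min-component pruning hides
  genuinely short (<10 µm) fragments.
- Dunnett quadrature assumes the one-factor correlation structure of
  many-to-one contrasts with a pooled variance; it does not cover arbitrary
  contrast matrices.
- The ΔΔCt model assumes perfect (2.0) amplification efficiency for every
  primer pair.
- The calcium event detector reports merged events as one when transients
  overlap within the 10-frame separation window.
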