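# Methods

This note documents the models, estimators and numerical choices behind
`neuromat`, and what the synthetic generators do and do not emulate.

## Imaging features

**Nucleus segmentation.** DAPI is smoothed (Gaussian, σ = 1 px), thresholded
globally (Otsu), and touching nuclei are split by a watershed on the negated
Euclidean distance transform. Watershed seeds are h-maxima of the distance
map with suppression depth 2 px; the distance map is lightly smoothed
(σ = 1.5 px) first because the medial ridge of a rasterized ellipse carries
quantization bumps whose prominence exceeds 2 px, which would split single
nuclei. A contrast guard rejects segmentations whose foreground/background
mean separation is under 4 background noise s.d. — an Otsu split of a
signal-free raster otherwise yields phantom objects. Regions outside the
intact-nucleus gate (30–500 μm² by default) are discarded, which is also how
debris and clumps are kept out of viability counts.

**Morphometry.** Area is pixel count × pixel_size² (0.65 μm/px default,
typical for a ×20 sCMOS system). Roundness is 4πA/P² with the Crofton
perimeter estimate (4 directions), clipped to 1. Crofton is accurate to a
few percent at generic orientations but underestimates perimeters of shapes
aligned with its lattice directions (up to ~7% for axis-aligned rectangles);
the synthetic nuclei are ellipses at uniformly random orientation, and the
generator calibrates their axis ratio against the same 4πA/P² definition
(Ramanujan perimeter), so generator and measurement agree by construction.

**Neurite tracing.** MAP2 is thresholded (Otsu by default; a fixed AFU value
may be configured), somata are removed by masking the dilated nuclear
regions (disk radius 4 px), and the remainder is skeletonized to 1-px width.
Length sums 8-connected pixel steps at weight 1 (orthogonal) or √2
(diagonal) × pixel size. This chain-length estimator overestimates true
Euclidean length of oblique lines by up to ~8% (≈ +5% averaged over random
orientations); skeleton-merging where strands run within a pixel of each
other biases the other way. Net bias on the mature-reference preset is
about +10%, which the recovery tolerances absorb. A segment is a maximal
skeleton path between adjacent junction (degree ≥ 3) or end (degree 1)
nodes; isolated loops count as one segment. Per-nucleus values are field
totals divided by the nuclei count — no per-cell assignment is attempted,
the coarsest reading consistent with a per-nucleus length readout.

**IEG scoring.** The per-nucleus statistic is the mean intensity within the
nuclear mask (the plausible default where the original analysis software's
statistic is undocumented). Positivity is strictly above threshold
(defaults 800 AFU FOS, 1,000 AFU EGR-1); ties are negative. Double
positivity requires both.

**Puncta and apposition.** Puncta are Laplacian-of-Gaussian blobs between
σ = 1 and 3 px with an absolute response threshold of 2× the channel's
robust noise scale, restricted to the MAP2 mask dilated by 2 μm ("the area
surrounding neurites", a free choice where the assay specifies none). A
PSD95 punctum is apposed iff its centroid lies within 1 μm (default) of at
least one SYN1 centroid, counted at most once; density is appositions per
100 μm of total neurite length.

## Screen statistics

**Pairing.** Per replicate, stimulated and unstimulated plates are paired by
well address. Induced IEG fractions are stimulated − unstimulated (negative
values allowed); morphology is averaged across the pair. Viability is the
unstimulated plate's nuclei count: depolarization itself can perturb
counts, so the unstressed plate is the cleaner proxy.

**Normalization.** For each of the six maturity parameters (and the
double-IEG rescue parameter), per plate: two-way Tukey median polish
(rows first, overall term carried; max 100 iterations, tolerance 1e-6;
NaN-tolerant for empty wells), residuals divided by 1.4826 × median
absolute residual; a zero MAD yields all-zero b-scores. Then per replicate,
library-wide robust z ((x − median)/1.4826·MAD; classical moments are
config-switchable), then replicate averaging. Viability z is computed
directly on per-replicate counts against the library — the exclusion rule
is a plain z-score and needs no plate polish; the polish's row/column
median estimation error would only add noise to it.

**Hit selection.** Compounds with viability z < −2 (strict) are excluded.
PCA runs on the centered compound × 6 z-matrix via eigendecomposition of
its covariance (no further scaling — the columns are already z-scores).
Eigenvector signs are indeterminate; PC1 is oriented so the FOS-induction
loading is positive and every other component so its largest-magnitude
loading is positive, making reported scores invariant to sign flips.
Rank-deficient matrices proceed with near-zero-variance components flagged.
Hits are PC1 > 4 (strict). Cluster labels operationalize the phenotypic
groups: enhancing (PC1 > 4), inhibiting (PC1 < −4), non-neuronal
proliferation (viability z > 2 with negative neurite z), other.
Single-parameter rescue adds the top-5 z-scorers for neurite length and
double-IEG induction, excluding compounds already selected by PCA; ties
break by ascending compound id.

**Validation and dose–response.** Validation composite = mean of four
DMSO-normalized parameters (nucleus area, roundness, neurite length,
induced double-IEG fraction), using per-plate DMSO means so plate effects
cancel; a DMSO-like well scores 1.0. Dose trend = Spearman correlation of
well-level composites with log₁₀(dose) over the 30–10,000 nM series, with
a one-sided permutation p-value — exhaustive when the permutation count is
≤ 1e5, otherwise 10⁴ seeded Monte-Carlo draws — and a dose-dependent flag
at ρ > 0, p < 0.05.

## Activity quantification

**Spikes.** Noise σ per channel is median(|x|)/0.6745 (robust to the spikes
themselves); threshold 9σ on the negative-going phase; spike time at the
trough; 2-ms refractory. The threshold is σ-relative, so detection is
invariant to amplitude scaling. At 9σ the Gaussian false-positive rate is
negligible (< 0.1 per channel-minute is verified on pure-noise
simulations). This is a deliberate threshold-crossing detector; only the
9-s.d. criterion is inherited from the assay, not its proprietary
precise-timing algorithm.

**Network bursts.** Population rate per 0.1-s bin = total spikes /
(n_channels × bin), i.e. the 1 spike s⁻¹ array-wide threshold is read as a
mean per-channel rate (a total-rate mode is configurable); a burst is a
maximal run of bins at/above threshold, runs separated by < 0.2 s merged.
Bin width and merge gap are free choices. Burst frequency = bursts /
duration. Firing-rate summaries rank channels by spike count in a 60-s
window and select ⌈n/64⌉ per probe (64 of 4,096; 128 across two probes),
ties to lower channel ids.

**Calcium.** ΔF/F uses a running 10th-percentile baseline over 60 frames,
floored at a small positive constant. Events are upward crossings of 3× the
trace's robust σ sustained for ≥ 2 frames, with a 2-frame refractory. The
2-consecutive-frame rule suppresses single-frame noise but caps sensitivity:
with a 3-frame decay, transient peaks need roughly ≥ 8× noise for reliable
counting; at the default generator's SNR recovery is complete. The 240-frame
5-s/20-min schedule is validated on input.

## Synthetic generators

All generators are deterministic given their spec's seed, and every planted
object appears exactly once in the returned truth tables.

**Fields.** Nuclei are non-overlapping filled ellipses; per-nucleus area is
drawn around the preset mean (CV ~0.12) and the axis ratio is solved so the
4πA/P² index matches the per-nucleus roundness draw. Neurites are random
trees of 1-px polylines rooted at somata, grown in ~10-px steps with angular
jitter and branching calibrated to the preset's branch count, with
ground-truth Euclidean length tracked per neuron. IEG channels fill nuclear
masks at class-dependent intensities; one latent responder variable drives
both FOS and EGR-1 (activity-driven co-induction), so the double-positive
truth equals the smaller marginal fraction. Puncta are Gaussian spots along
the neurite paths; the configured apposed fraction of PSD95 spots is placed
within 0.7 μm of a SYN1 spot and the rest rejected away from all SYN1
(> 1.8 μm). Intensities are 16-bit AFU with Gaussian read noise; no
photobleaching, PSF, uneven illumination or out-of-focus light — threshold
based scoring needs none of them, so passing tests says nothing about
robustness to such artifacts. Presets: `rat_day14` (130 μm², 0.93
roundness, 2,800 μm neurite/neuron, ~98% stimulated IEG response) rendered
at 12 neurons per 1,024² field — at its very high per-cell neurite content
a denser field would rasterize into an untraceable mat, so the mature
reference is modeled as a sparse plating; `hpsc_day21` (90 μm², 0.82,
400 μm, 25%) and `hpsc_treated` (intermediate) at 60 neurons/field,
consistent with 5,000 cells/well sampled over four ×20 fields. The
immature-state parameter values are free choices; the source assay
quantifies the mature reference, not the immature distributions.

**Feature-level screen.** 2,688 compounds in duplicate across 16×24 plates
(DMSO controls in the outer columns, 352 compounds/plate, 8 plates per
replicate × condition). Well-level technical noise is uniform (bounded),
not Gaussian: planted effects are specified in robust z units of that
noise, so a −6 z toxic compound or +6 z hit is separated from the inert
background *deterministically* — no seed places an inert compound beyond
the viability threshold or a planted hit below it. Real screens have
heavier tails; recovery rates here certify the pipeline's bookkeeping, not
its behavior under outlier-laden data (the robust estimators are the
mitigation for that). Row/column plate artifacts are additive Gaussians
applied to the intensity-derived maturity features — they model staining
and illumination gradients — and not to nuclei counts, which are
threshold-based object counts robust to such gradients. Toxicity depresses
nuclei counts only; hits elevate all six parameters (IEG fractions in the
stimulated condition, so the effect appears as induced response).

**MEA.** Baseline spikes are per-channel Poisson processes (5-ms minimum
spacing enforced; truth is the post-thinning list). Bursts are placed on a
near-regular schedule (⌊rate × duration⌋ events, ±8% interval jitter) so
planted counts are exact; each burst is a 0.15-s window in which the
configured fraction of channels fires 1–2 spikes. Raw traces (Gaussian
noise + biphasic template, trough-normalized) are synthesized when the
sample count is desk-scale (≤ 4×10⁷); the 4,096-channel paths (bursts,
top-1/64 summaries) run on spike-time lists, which the recording container
supports directly.

**Calcium.** Traces are baseline + exponentially decaying transients
(3-frame decay, amplitudes ±20%) + Gaussian noise; events are placed with
≥ 6-decay-constant separation so they remain individually countable.

## Problem sizes and tolerances

Recovery of the mature-reference parameters is tested over 20 seeds × 17
fields (≥ 200 nuclei per seed) at 10% tolerance on area (130 μm²) and
roundness (0.93) and a 2,500 μm lower bound on per-neuron neurite length;
`scripts/acceptance.py` measures the same quantity over 100 fields
(~1,200 nuclei, ≈ 1 min). Median polish is verified against an
independently coded brute-force polish to 1e-6 on 100 random 16×24 plates,
apposition counting against an all-pairs oracle on 100 random fields, and
PCA against a second implementation (sklearn) to 1e-8. End-to-end screen
runs are byte-reproducible for a fixed config and seed; all randomness
flows from the single configured seed.

## Known limitations

* No per-cell neurite attribution; segment counts are per field.
* Chain-length tracing bias (~+10% on the dense mature preset) is
  documented rather than corrected; rotation invariance holds to < 1%.
* The bounded-noise screen tier makes planted-effect recovery exact by
  design; it does not stress outlier robustness.
* Calcium event counting requires ≥ 2 supra-threshold frames and therefore
  undercounts transients with peaks below ~8× noise.
* The imaging tier models 2-D monolayers only; organoid sections reuse the
  same nucleus/puncta operators on 2-D images.
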