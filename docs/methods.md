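# Methods

## The measurement model

Both assays reduce to counting and classifying diffraction-limited
fluorescent spots on a TIRF imaging surface, and (for fusion) to detecting a
stepwise intensity change in per-spot time traces.

**Spots.** Vesicles of ~80 nm are far below the diffraction limit, so every
docked vesicle or small cluster is modeled as an isotropic Gaussian of width
`psf_sigma_px` (default 1.3 px on a 512×512 field). A cluster of
multiplicity k carries k vesicles' worth of fluorophore, so its integrated
intensity is k× the single-vesicle intensity; this linearity is what makes
intensity-based single-vs-cluster classification possible.

**Content-mixing step.** The content dye is self-quenched; complete fusion
dilutes it ~twofold into the partner vesicle and the emission per molecule
rises. The trace model is a single upward step: baseline k·F before the
event, (k − 1 + g)·F after, with dequench factor g = 2.0 by default
(configurable; the twofold-dilution value is the simplest model consistent
with the assay) and F the single-vesicle flux (3000 counts/frame by
default).

**Event-time law.** Fusion times are drawn from the density proportional to
A₁·e^(−t/τ₁) + A₂·e^(−t/τ₂) truncated to the 50-s observation window.
The fitted offset y₀ of the published functions is a baseline artifact of
least-squares fitting, not probability mass, and is ignored when sampling
(a density must be non-negative). Component i is selected with probability
proportional to its truncated mass Aᵢτᵢ(1 − e^(−50/τᵢ)).

## The synthetic generator

Each `ConditionPreset` bundles: expected docked spots per field
(`n_docked`), fields per condition (`n_fields`, default 10), per-spot fusion
probability, kinetic parameters, a cluster-size law (truncated geometric on
k = 1..6; the very large aggregates seen with α-Syn are a separate rare
process rendered wider and brighter than any k ≤ 6 cluster), dequench
factor, optics and a noise model (constant background 100 counts/px,
Poisson shot noise, Gaussian read noise σ = 2).

Frame layout: 5 pre-trigger frames (docked spots are counted before Ca²⁺
injection) followed by observation frames at 1-s intervals covering
t = 0..50 s. The closing frame at t = 50 s exists so that an event sampled
anywhere in [0, 50) lands on at least one frame ("first frame at or after
the event time"); without it, events in the final second would be silently
invisible and planted event totals could not be recovered exactly.

Spots are placed uniformly at random with a minimum center separation of
4·psf_sigma (dart throwing; an over-full field raises). The fusion presets
use 6·psf_sigma so that aperture-photometry crosstalk between neighbors
stays far below the step-detection threshold. A 12-px border keep-out
guarantees photometry apertures never clip the frame.

The fusion presets split the published pooled populations over 10 fields of
view (200/field without α-Syn → 2000 docked; 130/field at 2 µM α-Syn →
1300), matching the experimental practice of pooling several fields. The
generic renderer draws the realized spot count Poisson(n_docked) and fuses
spots independently with probability p_fusion; the seeded fixtures
(`render_fusion_fixture`) instead plant exact totals — 166 events among
2000 spots, 84 among 1300 — by allocating the fusing spots uniformly
without replacement across fields.

Clustering presets encode each condition's expected *above-background*
docked DiI count per field (`clustering_efficiency`): wildtype 380 at 20 µM
and 150 at 2 µM over a 20-count nonspecific background; A30P exactly half
the wildtype efficiency; E46K/A53T at wildtype level; the
synaptobrevin-2-free, pure-PC and α-Syn[1-95] controls at background. The
saturated DiD surface preset places 2500 spots per field — above the
>1000-immobilized-vesicles scale reported for this surface preparation and
near the highest density at which individual spots remain countable by the
detector.

**What the generator does not emulate:** optical vignetting, stage drift,
evanescent-depth variation, photobleaching, dye blinking, non-uniform
backgrounds, or camera gain structure. Passing tests therefore demonstrate
correctness of the analysis chain under idealized but noisy image
formation, not robustness to every real-microscope artifact.

## Detection and photometry

Background is a moving-median (25-px window; frames with a wide count range
use a histogram-based rank filter on rounded counts — quantization error
≤ 0.5 count, negligible against shot noise). The residual is matched-
filtered with a Gaussian of the PSF width; local maxima above
`k_thresh` = 5 robust noise sigmas (MAD × 1.4826) survive non-maximum
suppression within `min_sep_px` = 3. Centers are refined by
intensity-weighted centroid in a (2·⌈3σ⌉+1)² window; integrated intensity
is a disc aperture of radius 3σ minus the local 4–6σ annulus median.

Intensities are normalized by the mode of the raw-intensity distribution
(kernel-density peak), anchoring the single-vesicle population at 1 a.u. so
the published thresholds apply directly: singles < 1.5 a.u., clusters
≥ 2 a.u. (spots in the [1.5, 2.0) gap are reported as a separate
intermediate class and pooled with clusters in summary totals), and
very-large exclusion above 6 a.u. or above 30 px of half-maximum footprint
(~4× the PSF half-max area). With fewer than 20 spots the mode is
unreliable and the median is used instead (with a warning).

## Step detection

A two-sided sliding-window detector: at each frame the difference between
the mean of the next w = 5 frames and the previous w = 5 frames is
computed (windows are clipped at the trace boundaries, so a step on the
final frame is still scored); the maximizing frame is the single candidate.
It is reported iff the difference exceeds k_step = 5 per-frame noise sigmas
(noise estimated robustly from first differences: MAD/√2 × 1.4826, immune
to the step itself), the elevation persists for m_sustain = 3 frames (or to
the trace end), and the post/pre mean ratio reaches min_ratio = 1.2. The
ratio guard reflects the physics — a genuine dequenching step is a ~2×
fractional rise — and suppresses the rare boundary-window noise excursions
that a pure k·σ threshold admits. At most one event is scored per spot
(complete-fusion semantics); later candidates are logged, not scored.

## Synchronization and fitting

Within each field of view the Ca²⁺-arrival time stamp is the field's first
content-mixing event; all events in the field are shifted so that event sits
at t = 0, then fields are pooled. This reproduces the experimental
procedure verbatim and carries a small left-edge bias: every field
contributes one event at exactly t = 0, so the first histogram bin is
slightly over-populated and the fitted fast component can partly absorb
that spike. The bias is documented rather than corrected.

Histograms use half-open 1-s bins over [0, 50) (50 bins), self-normalized
by the event total; synchronized times at or past 50 s are dropped with a
logged count (they still count as detected events). The bi-exponential fit
is least squares on (bin-center, probability) pairs with multi-start
initialization: 16 starts pairing time constants log-spaced in
[0.1, 100] s, amplitudes seeded from the first bin, y₀ = 0. Time constants
are optimized on a log scale (positivity); amplitudes and offset are free —
the offset may be negative, as in the published fits. The best-residual
solution is reported with the slow component first (τ₁ ≥ τ₂); fits with
τ₁/τ₂ < 1.2 or a vanishing amplitude are flagged degenerate.

A caution on precision: at realistic event counts (~166 events over 50
bins, ~3 events/bin) the slow time constant is weakly identifiable because
the free offset can absorb much of a slow decay over a 2τ window. The test
suite establishes the achievable envelope by Monte-Carlo simulation at the
fixture's event count and checks recovery against that envelope, not
against an optimistic fixed tolerance; the end-to-end pipeline is instead
held to exact fidelity (detected, synchronized event times must equal the
planted ones, so the pipeline fit coincides with the ground-truth fit).

## Clustering statistics

Per-location DiI counts are taken only after the DiD channel passes a
saturation/homogeneity check: coefficient of variation of block-summed
intensities (128-px blocks) below 0.2. Counts aggregate into mean and
sample standard deviation (denominator N − 1; undefined and flagged for a
single location). Condition contrasts use the classical pooled-variance
Student's t-test (two-tailed, df = N₁ + N₂ − 2) — the equal-variance
form, since that is the named test — with the star convention *** for
p < 0.001. The finite-volume depletion relation is the mass-balance form:
with a fixed vesicle budget, free particles = vesicles / E[k] under the
cluster-size law, strictly decreasing in the mean cluster size. The
clustering-vs-association anti-correlation is summarized by Spearman rank
correlation, since only ordinal structure is claimed.

## Problem sizes and determinism

Default problem sizes are those of the study conditions: 10 fields of view
per fusion condition (2000 and 1300 pooled docked vesicles), 10 imaging
locations per clustering condition, 512×512 fields, 56 frames. Every
stochastic operation takes an explicit numpy Generator; presets carry a
default seed, and with a fixed seed all generator outputs are
bit-reproducible. `scripts/acceptance.py` derives independent child seeds
from its single `--seed` argument.

## Known limitations

* Sub-second event localization is impossible at the 1-s frame interval;
  event times are frame-quantized (the generator equates frame interval
  with histogram bin width).
* The a.u. normalization assumes the single-vesicle population is the mode
  of the intensity distribution; under extreme clustering (singles a
  minority) the anchor would shift.
* Whether docked-vesicle denominators should be counted before or after
  large-spot exclusion is ambiguous in the assay description; this package
  counts after exclusion, consistent with the scoring rule used for spot
  counts.
* Detection merges spot pairs closer than the resolution limit; at the
  densities used here this affects ~1–2% of spots and is covered by the
  recall/precision tests.
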