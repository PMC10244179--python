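# Methods

This note documents the models and statistics `alloptical` implements, the
defaults it ships with and why, what the synthetic generators do and do not
emulate, and the numerical choices that matter for reproducing results.

## Trial response statistic and responder detection

Raw fluorescence is converted to ΔF/F against a rolling 10th-percentile
baseline (2,000-frame window for population recordings; 90 s for dendritic
recordings). The rolling percentile is evaluated on a stride and linearly
interpolated (exact at stride 1); the stride only smooths the already-slow
baseline and is a throughput choice, not a statistical one.

The per-trial statistic is `R_i = (S_i − B_i) / sd(B_{i−2..i})` with 500 ms
response (post-photostimulation-offset) and baseline (pre-visual-onset)
windows; window lengths are `ceil(0.5 · frame_rate)` frames. For the first
two trials the s.d. uses all available baselines; an exactly zero s.d. is
replaced by the session-median baseline s.d. For V trials the response window
is anchored where photostimulation would have ended.

Responders are detected per stimulation group: V trials are randomly
subsampled to match the V+P orientation proportions (one seeded draw by
default; averaging p over several draws is available), a two-sided
Mann–Whitney/Wilcoxon rank-sum test is run per neuron (exact for small
samples, tie-corrected normal approximation otherwise), and FDR is controlled
across neurons at q = 0.025 (Benjamini–Hochberg default; Storey positive-FDR
q-values as an option). A responder additionally requires a non-zero median
effect, whose sign labels it facilitated or suppressed.

**A property worth knowing:** the 3-trial rolling baseline s.d. in `R_i`
couples neighbouring trials (they share denominators), which makes the
rank-sum test *conservative* under the null — the realized false-discovery
proportion on calibration simulations is far below the nominal 2.5% (often
0), while power against embedded ~1 s.d. effects remains essentially
complete. This conservativeness is inherent to the statistic, not a bug in
the test.

## Response probability and point-spread

Each `R_i^{V+P}` is Z-scored against the mean and s.d. of all `R^V` for the
same neuron (the Z reference uses all V trials; orientation-matching the
reference is a plausible alternative the data format supports).
`P_response` is the fraction of trials with Z > 1.64 (one-sided 5%). The
lateral extent of photostimulation is summarized by fitting
`P(d) = floor + a·exp(−ln2·(d/HWHM)²)` to `P_response` versus lateral target
offset; the floor absorbs the 5% false-positive rate of the trial criterion
so the HWHM is estimated from the Gaussian component alone.

## Retinotopy

Deconvolution is non-negative least squares against a dictionary of
time-shifted calcium kernels (difference of exponentials; defaults rise
0.1 s, decay 1.5 s — GCaMP6s-like). Event traces are denoised by zeroing
amplitudes not strictly above mean + 2 sample s.d.; the strict comparison
means a constant trace is zeroed entirely (a warning is emitted on zero
variance). Receptive fields are event-triggered stimulus ensembles over a
2 s window, weighted by event size, Z-scored over all stimulus-frame ×
grid-position combinations per polarity, and median-filtered 3×3 within each
time bin (kernel size configurable; an isolated single-cell RF does not
survive a 3×3 median, so the filter assumes RFs span a few grid cells).
The preference is the peak within a 600 ms window centred on the temporal
peak; inclusion requires max Z ≥ 5 in either polarity, and when both pass the
preference is their max-Z-weighted average.

The retinotopic surface is a hand-rolled 2-D LOWESS: locally weighted linear
fits with tricube weights over the nearest ~20% of points and two bisquare
robustness iterations (the pre-installed lowess implementations are 1-D).
Queries outside the convex hull extrapolate from the nearest local fit and
are flagged. Signed distance to the border polyline assigns areas (left of
the polyline direction = A1); ROIs strictly within 75 µm of the border are
excluded.

## Topography of influence

Distances are Euclidean in (azimuth, elevation) degrees from each responder
to every locally facilitated responder (the sources). Histograms use 30 bins
of 1.2° spanning 0–36°, with larger distances pooled into the last bin. The
availability null draws 20,000 neurons with replacement from the readout
area, each contributing its full set of source distances (pooled
single-neuron draws; matching the responder count per draw is a variant the
estimator does not require). Responder and null histograms are normalized to
unit mass before the ratio; bins with empty null mass are undefined and
excluded from averages. Profiles are smoothed with a centred 5-bin moving
average (edge-truncated, NaN-aware) and averaged across groups with s.e.m.;
suppressed profiles are negated for display only.

Centroid displacement between facilitated and suppressed responders is a
rank-sum test across group centroids (exact enumeration when both n ≤ 10 and
untied, mid-rank asymptotics otherwise). The strength-matching control bins
groups by local-responder count (bin width 10), and per resample draws half
the smaller direction's group count from each direction in every shared bin,
5,000 times; the reported quantity is the fraction of resamples with a
negative facilitated-minus-suppressed displacement per direction. Within a
single dataset the resamples concentrate near that dataset's empirical
displacement; the 0.5 null level is a cross-dataset expectation.

## Spine connection mapping

ΔF/F for spine and branch ROIs uses the 90 s / 10th-percentile baseline, with
the percentile taken on a 1 s-smoothed copy of the trace (numerator raw). A
low quantile of a noisy trace sits systematically below the true baseline
(≈1.28 per-frame σ for the 10th percentile), which biases *ratio* statistics
like the boosting index; pre-smoothing the baseline source removes most of
that bias while leaving difference statistics (∆R) untouched.

∆R is the mean over 7 frames after stimulation offset minus the mean over 9
frames before onset; stimulation-artifact frames belong to neither window.
The candidate sweep tests ∆R thresholds mean + {0.5…3.0} s.d. (0.5 steps),
∆R_mean thresholds mean + {0.5…1.5} s.d., and reliability 10–20% (5% steps);
a spine's independent-event trials at a setting are those with ∆R above and
∆R_mean below threshold, and a target present on strictly more than the
reliability fraction of those trials is a candidate. The full sweep grid is
retained; candidates are deduplicated with their best reliability. The sweep
deliberately over-collects (the experimental procedure prunes candidates by
rank on reliability and response amplitude rather than by a human).

Confirmation is a two-sided signed-rank test on per-trial (post − pre) over
≥8 isolated stimulations (exact for n ≤ 25 without zeros), requiring
p < 0.01 and a positive mean response. The boosting index is the ratio of
post-stimulus ΔF/F means, stimulated-branch ROI (excluding the recipient
spine) over reference-branch ROI; trials with reference response below
0.01 ΔF/F are excluded, stim and blank BIs are compared within recording by
rank-sum, and across recordings the mean percentage increase is tested by a
one-sample t-test (signed-rank optional).

## Local dendritic events

Mask pixels are averaged into their nearest line-ROI pixel (ties to the
lowest index). Per-bin traces are smoothed with a 4 s moving average,
converted to ΔF/F (45 s / 10th-percentile baseline), normalized by **one
global s.d. of the whole space–time profile**, and smoothed across space with
a 2 µm moving average. A per-bin s.d. was considered and rejected: it
rescales each geodesic bin by its local event density and measurably widens
every event's spatial profile.

Event classification is rule-based (the experimental analogue is consensus
scoring by blinded raters): local = ≥2 active spines + active interposed
branch + quiet proximal 20% of geodesic length; global = whole branch active,
or a multi-spine event whose activity reaches the proximal end; single-spine
and none otherwise. This makes classification monotone — adding activity can
promote local to global but never demote it to none.

Event profiles are aligned to their spatial peaks, unit-normalized, resampled
to 0.5 µm, averaged, and fit with a sum of three Gaussians (initialized at
the peak and ±5 µm, widths 2 µm, non-negative amplitudes, 500-evaluation
budget; on failure the empirical FWHM is reported with a flag). The FWHM is
read from the fitted curve at half maximum. The prescribed 2 µm spatial
smoothing adds ≈0.3 µm² of variance, so a σ = 4.757 µm event (FWHM
11.2 µm) is recovered at ≈11.3–11.5 µm. Event rates per stimulus type are
compared with Kruskal–Wallis over per-branch rates plus Dunn's pairwise
post hoc z-tests (hand-rolled; unadjusted p-values reported).

## Soma–dendrite analyses

Pairing requires fluorescence correlation > 0.45 AND event-trace correlation
> 0.25 (strict; the stricter 0.55/0.35 setting is exposed as a robustness
check and always yields a subset). Population surfaces bin soma responses in
5%-of-peak bins from −40% to 100% (28 bins). The two-way ANOVA defaults to
unweighted bin-level cell means with the additive model — one observation per
cell leaves no replication for an interaction — and a trial-level mode
(`cells=False`) fits the full interaction model. Size tuning removes somatic
influence by a within-neuron least-squares line of dendritic on somatic
responses (trials with soma < 20% of peak excluded), followed by one-way
ANOVA of the residuals over stimulus size; the preferred size maximizes the
mean residual. The locomotion variant pools sizes as smaller/preferred/larger
around the preference computed on stationary trials and runs a two-way
(state × pooled size) ANOVA. The apical/basal test forms per-trial ratios
(basal > 0 and ≥ 20% of peak basal), pools Gabor stimuli as low-surround and
inverse/full-field as high-surround, and calls a neuron significant when the
observed class difference exceeds 95% of 3,000 label shuffles.

## Synthetic generators

`make_population_session` emulates one population recording: two areas on a
linear, border-mirrored retinotopic gradient (0.07 deg/µm) with a 150 µm
border zone; 100 V + 100 V+P trials per group at 3 s spacing, orientations
balanced within trial type; visual responses with von Mises-like orientation
tuning and log-normal trial gain; photostimulation groups of 10 targets whose
direct (within-area) responses attenuate in *probability* with the lateral
point-spread (HWHM 20.7 µm) at fixed amplitude — so the measured
`P_response` vs. offset profile carries the configured HWHM, mirroring how
photostimulation resolution is measured; across-area responders (10% of the
readout area by default, 1.0 ΔF/F effect ≈ 1 s.d. of single-trial responses)
placed with suppression probability Gaussian in retinotopic offset (σ = 8°)
and facilitation on an offset ring peaking at 12°; i.i.d. Gaussian frame
noise (σ = 0.2 ΔF/F).

`make_dendrite_recording` emulates sparse dendritic imaging: straight
branches with 1-px line and 5-px mask ROIs; spines on the stimulated branch
with independent spontaneous events, shared global events, and deterministic
connection-driven responses (0.5 ΔF/F, 90% reliability); a search block of
random target groups plus blanks followed by a confirmation block of isolated
stimulations of the connected targets, paced 15 s apart so the calcium signal
returns to baseline between trials; per-trial branch responses shared between
stimulated and reference branch, with the stimulated branch's post-stimulus
ΔF/F multiplied by the boosting factor (default 1.108) on stimulation trials.
Branch-ROI traces carry lower noise (σ = 0.05) than spine ROIs (σ = 0.2)
because they average hundreds of pixels. Local events are spatial Gaussians
(σ = 4.757 µm ⇒ FWHM 11.2 µm) injected into a rendered movie on a visual
stimulation timeline in which event probability scales with surround drive
(inverse > full-field > annulus > Gabors).

**What the generators do not emulate:** motion and its correction, neuropil
contamination and subtraction, photostimulation artifacts, shared (neuropil-
like) noise, curved dendrites, sag/bleaching, or across-session registration
(alignment is the identity; an affine from user-supplied point pairs is
available). Passing tests therefore validate the statistics and their
implementations under known truth — not robustness to those real-data
nuisances, which upstream preprocessing is assumed to have handled.

## Calibration studies and problem sizes

`alloptical.studies` (used by `scripts/acceptance.py` and the test suite)
runs: 200 sessions for the false-discovery calibration; 20 seeds × 20,000
null draws for the uniform-sampling level; 50 events on a 60 µm branch for
the event FWHM; 13 lateral offsets × 5 neurons × 100 trials for the
point-spread HWHM; and 25 recordings for the boosting increase. These sizes
keep each study to a few minutes on one CPU while leaving Monte-Carlo error
comfortably inside the tolerances stated in the tests.

## Known limitations

* Deconvolution solves a dense NNLS per trace (O(n²) memory in trace length);
  it is intended for the short traces RF mapping needs, not hour-long
  recordings.
* The 2-D LOWESS evaluates a local fit per query point; for very large ROI
  counts, fit once and cache interpolations.
* Exact rank-based tests switch to tie-corrected asymptotics when ties or
  larger samples appear; p-values near thresholds should not be compared
  across those regimes.
* The candidate sweep's reliability denominator is the spine's
  independent-event trial count at the current setting; with very few such
  trials single coincidences can pass the reliability fraction, which is why
  candidates are ranked, confirmed, and never reported as connections on
  their own.
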