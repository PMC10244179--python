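# alloptical

Analysis pipeline for **all-optical functional-connectivity mapping** between
retinotopically organized visual cortical areas (e.g. V1 and the lateromedial
area LM), and for the dendritic-imaging analyses that accompany such
experiments. The package is aimed at two-photon imaging labs that combine
holographic two-photon optogenetic stimulation of neuron groups in one area
with population calcium imaging — or sparse dendritic imaging — in the other.

It implements, as tested and reusable library code:

* **Responder detection.** Per trial *i*, the response of each neuron is the
  signal-to-background ratio
  `R_i = (S_i − B_i) / sd(B_{i−2}, B_{i−1}, B_i)`, where `S_i` is the mean
  ΔF/F in a 500 ms window after photostimulation offset and `B_i` the mean in
  a 500 ms window before visual onset. Facilitated and suppressed responders
  are detected per stimulation group by a two-sided Wilcoxon rank-sum test
  between visual-only (V) and visual+photostimulation (V+P) trials, after
  orientation-matched subsampling of the V trials, with Benjamini–Hochberg
  FDR control across neurons at q = 0.025 (Storey q-values available).
* **Response probability.** `P_response` = fraction of V+P trials whose
  Z-score against the V-trial reference exceeds the one-sided 5% critical
  value Z = 1.64; Gaussian fits of `P_response` vs. lateral target offset
  measure the photostimulation point-spread (HWHM).
* **Retinotopy.** Reverse-correlation receptive fields from deconvolved,
  denoised event traces (event-triggered stimulus ensembles, Z ≥ 5 inclusion);
  LOWESS (locally linear, bisquare-robust) azimuth/elevation surfaces over the
  field of view; exclusion of neurons within 75 µm of the area border.
* **Topography of influence.** Responder retinotopic distances to all locally
  facilitated "source" neurons, binned at 1.2° and divided by a
  20,000-draw availability null; 5-bin smoothing and group averaging;
  rank-sum tests on facilitated vs. suppressed centroid distributions; a
  5,000× stimulation-strength-matched resampling control.
* **Spine connection mapping.** Independent spine events (high per-spine ∆R,
  low across-spine ∆R_mean) under a threshold sweep identify candidate
  target→spine connections; confirmation by signed-rank test (p < 0.01) on
  isolated-stimulation trials; the branch **boosting index** (stimulated- /
  reference-branch post-stimulus ΔF/F) compared between stimulation and blank
  trials.
* **Local dendritic events.** Mask→line ROI projection, geodesic space–time
  profiles, local/global/single-spine classification, and a three-Gaussian
  fit of the average aligned event profile with its FWHM.
* **Soma–dendrite analyses.** Dual-threshold (r_F > 0.45, r_events > 0.25)
  soma–trunk pairing, soma-activity-binned population surfaces, within-neuron
  size-tuning residual ANOVAs, and an apical/basal ratio shuffle test (3,000
  permutations).
* **Synthetic data.** `alloptical.synth` generates fully ground-truthed
  population sessions and dendrite recordings (GCaMP-like kernels, configurable
  point-spread, responder placement profiles, true connections, boosting
  factors and local-event widths) so every stage can be validated against
  known truth.

## Worked example

```python
import alloptical as ao

# a synthetic session: 500 neurons in two areas, 100 V + 100 V+P trials,
# 10% embedded responders
session = ao.make_population_session(ao.GeneratorConfig(seed=1))
table = ao.pipeline.session_responders(session, rng=1)
found = table[table.sign != "none"]
truth = set(session.ground_truth.roi_id)
print(f"{len(found)} responders detected")
print(f"{len(set(found.roi_id) & truth)} of {len(truth)} true responders recovered")

import numpy as np
topo = ao.pipeline.session_topography(session, table, rng=1)
for sign in ("facilitated_profile", "suppressed_profile"):
    p = topo[sign]
    i = np.nanargmax(p["mean"].to_numpy())
    print(sign, "peak %.2f at %.1f deg" % (p["mean"][i], p["bin_centre_deg"][i]))
```

prints

```
28 responders detected
28 of 28 true responders recovered
facilitated_profile peak 1.28 at 17.4 deg
suppressed_profile peak 6.87 at 29.4 deg
```

— all 28 embedded responders are recovered with no false positives. The
weighted profiles are read against 1 (uniform spatial sampling): this
session's generator places across-area suppression at small retinotopic
offsets (its profile is ≈2× over-represented at the nearest bins, falling
below 1 past ~12°) and facilitation on a ~12° offset ring, where the
facilitated profile peaks. Far, sparsely populated bins can spike in a
single session — the 6.9 at 29.4° rests on a handful of null draws — which
is why profiles are averaged across stimulation groups in practice.

The same flow is available from the shell:

```bash
alloptical synth population --seed 1 --out session_dir
alloptical responders --session session_dir --out responders.csv
alloptical run --seed 1 --out pipeline_out   # synth → responders → topography
```

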