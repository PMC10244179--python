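"""Calibration studies run against the synthetic generators' ground truth.

Each study regenerates synthetic recordings at the generator defaults, runs
the corresponding analysis stage end to end, and measures how well the stage
recovers the embedded truth: the realized false-discovery proportion of
responder detection, the uniform-sampling level of the null-normalized
distance profile, the recovered local-event FWHM, the recovered lateral
photostimulation HWHM, and the recovered branch-boosting increase. These are
the package's reproducibility checks; `scripts/acceptance.py` reports them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import curve_fit

from .dendrites import event_spatial_profile, project_mask_to_line
from .pipeline import session_responders
from .responders import response_probability, trial_response_matrix
from .spines import boosting_index
from .synth import (
    GeneratorConfig,
    make_dendrite_recording,
    make_population_session,
    psf_lateral,
)
from .topography import weighted_distance_distribution
from .traces import dff, synthesize_fluorescence

__all__ = [
    "fdr_calibration",
    "uniform_sampling_level",
    "local_event_fwhm",
    "psf_hwhm_recovery",
    "boosting_recovery",
]


def fdr_calibration(
    n_sessions: int = 200,
    seed: int = 0,
    fdr_level: float = 0.025,
    config: GeneratorConfig | None = None,
) -> dict:
    """Realized false-discovery proportion of responder detection (percent).

    Simulates sessions at the generator defaults (500 neurons, 10% true
    responders, 100 V + 100 V+P trials), runs the full ΔF/F → R → rank-sum →
    FDR pipeline at the headline 2.5% control level, and averages the
    per-session false-discovery proportion (FP / max(discoveries, 1)) against
    the embedded truth.
    """
    base = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    fdps = []
    for i in range(n_sessions):
        s = int(rng.integers(0, 2**31 - 1))
        session = make_population_session(dataclasses.replace(base, seed=s))
        tab = session_responders(
            session, fdr_level=fdr_level, rng=s, f0_stride=100
        )
        fdp_session = []
        for grp in session.groups:
            sub = tab[(tab.group_id == grp.group_id) & (tab.sign != "none")]
            truth = set(
                session.ground_truth.roi_id[
                    session.ground_truth.group_id == grp.group_id
                ]
            )
            n_disc = len(sub)
            fp = sum(1 for r in sub.roi_id if r not in truth)
            fdp_session.append(fp / max(n_disc, 1))
        fdps.append(np.mean(fdp_session))
    return {"value": float(np.mean(fdps) * 100.0), "n": n_sessions}


def uniform_sampling_level(n_seeds: int = 20, seed: int = 0,
                           n_responders: int = 50, n_null: int = 20_000) -> dict:
    """Null-mass-weighted mean of the weighted profile for uniform responders.

    When the "responders" are a uniform random subsample of all available
    neurons the null-normalized distance profile should sit at 1 (uniform
    spatial sampling). Averaged over seeds.
    """
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31 - 1))
        cfg = dataclasses.replace(
            GeneratorConfig(), seed=s, n_v_trials=5, n_vp_trials=5
        )
        session = make_population_session(cfg)
        meta = session.roi_meta
        prefs = meta[["true_azimuth_deg", "true_elevation_deg"]].to_numpy(float)
        area = meta["area"].to_numpy()
        avail = np.flatnonzero(area == "A2")
        gt = session.ground_truth
        local_fac = gt.roi_id[
            (gt.group_id == 0) & (gt.label == "facilitated")
        ].to_numpy(int)
        local_fac = local_fac[area[local_fac] == "A1"]
        sub_rng = np.random.default_rng(s + 1)
        resp = sub_rng.choice(avail, size=min(n_responders, avail.size), replace=False)
        d = weighted_distance_distribution(
            prefs[resp], prefs[avail], prefs[local_fac], n_null=n_null, rng=sub_rng
        )
        ok = np.isfinite(d.weighted)
        vals.append(
            float(np.sum(d.null_prob[ok] * d.weighted[ok]) / np.sum(d.null_prob[ok]))
        )
    return {"value": float(np.mean(vals)), "n": n_seeds}


def local_event_fwhm(seed: int = 0, n_events: int = 50) -> dict:
    """FWHM (µm) of the mean local-event profile recovered by the pipeline.

    Renders a dendritic movie with Gaussian local events at the generator's
    default spatial width, projects the mask ROI onto the line ROI, averages
    each event over its frames, and fits the idealized profile with a sum of
    three Gaussians.
    """
    cfg = dataclasses.replace(
        GeneratorConfig(), seed=seed, render_movie=True, n_local_events=n_events,
        n_stim_trials=5, n_blank_trials=5,
    )
    rec = make_dendrite_recording(cfg)
    branch = rec.branches[0]
    prof, geo = project_mask_to_line(
        rec.movie, branch.mask_um, branch.line_um, cfg.um_per_px, rec.frame_rate
    )
    span = int(round(1.5 * rec.frame_rate))
    events = []
    for t0 in rec.ground_truth["local_event_frames"]:
        spatial = prof[:, t0 : t0 + span].mean(axis=1)
        events.append((geo, spatial))
    ep = event_spatial_profile(events)
    return {"value": float(ep.fwhm_um), "n": len(events)}


def psf_hwhm_recovery(
    seed: int = 0,
    offsets_um: np.ndarray | None = None,
    n_per_offset: int = 5,
    n_vp_trials: int = 100,
    n_v_trials: int = 30,
) -> dict:
    """Lateral HWHM (µm) of the photostimulation response-probability profile.

    Neurons at graded lateral offsets from a stimulation target respond on
    each trial with probability given by the generator's default lateral
    point-spread. P_response is estimated per neuron from the Z > 1.64
    criterion and a Gaussian (plus floor) is fit to P_response vs offset.
    """
    cfg = GeneratorConfig()
    if offsets_um is None:
        offsets_um = np.arange(0.0, 61.0, 5.0)
    rng = np.random.default_rng(seed)
    fr = cfg.frame_rate
    period = int(round(cfg.trial_period_s * fr))
    n_trials = n_vp_trials + n_v_trials
    onsets = int(2 * fr) + period * np.arange(n_trials)
    stim_end = onsets + int(np.ceil(cfg.photostim_dur_s * fr))
    ttype = np.array(["V+P"] * n_vp_trials + ["V"] * n_v_trials)
    rng.shuffle(ttype)
    import pandas as pd

    trials = pd.DataFrame(
        {"onset_frame": onsets, "stim_end_frame": stim_end, "type": ttype}
    )
    n_frames = int(onsets[-1] + period + 4 * fr)
    is_vp = ttype == "V+P"

    p_resp = []
    dist = []
    for d in offsets_um:
        p_hit = psf_lateral(float(d), cfg.psf_lateral_hwhm_um)
        for _ in range(n_per_offset):
            events = np.zeros(n_frames)
            hits = is_vp & (rng.random(n_trials) < p_hit)
            events[onsets[hits]] = 1.0
            trace = synthesize_fluorescence(
                events, fr, cfg.kernel_rise_s, cfg.kernel_decay_s,
                noise_sd=cfg.noise_sd, baseline=100.0, rng=rng,
            )
            dtr = dff(trace, window=2000, stride=100)
            _, _, R, kept = trial_response_matrix(dtr, trials, fr)
            kvp = kept["type"].to_numpy() == "V+P"
            p_resp.append(response_probability(R[0, kvp], R[0, ~kvp]))
            dist.append(float(d))

    dist = np.asarray(dist)
    p_resp = np.asarray(p_resp)

    def model(d, floor, amp, hwhm):
        return floor + amp * np.exp(-np.log(2.0) * (d / hwhm) ** 2)

    params, _ = curve_fit(
        model, dist, p_resp, p0=[0.05, 0.9, 20.0],
        bounds=([0.0, 0.0, 1.0], [0.5, 1.5, 100.0]),
    )
    return {"value": float(params[2]), "n": int(dist.size)}


def boosting_recovery(n_recordings: int = 25, seed: int = 0) -> dict:
    """Mean percentage increase of the boosting index on stimulation trials.

    Simulates recordings at the generator's default boosting factor, computes
    per-trial boosting indices for stimulation and blank trials, and averages
    the percentage increase across recordings.
    """
    rng = np.random.default_rng(seed)
    increases = []
    for _ in range(n_recordings):
        s = int(rng.integers(0, 2**31 - 1))
        cfg = dataclasses.replace(GeneratorConfig(), seed=s)
        rec = make_dendrite_recording(cfg)
        win = int(round(90.0 * rec.frame_rate))
        branch_dff = dff(
            rec.branch_traces, window=win, stride=50,
            presmooth=int(round(rec.frame_rate)),
        )
        res = boosting_index(
            branch_dff[0], branch_dff[1], rec.stim_log,
            rec.ground_truth["stim_trials"], rec.ground_truth["blank_trials"],
        )
        increases.append(res.mean_increase_pct)
    return {"value": float(np.mean(increases)), "n": n_recordings}
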