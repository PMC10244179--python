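"""Ground-truthed synthetic recordings for the all-optical feedback pipeline.

Two generators emulate the two experiment classes the pipeline analyses:

* :func:`make_population_session` — population two-photon imaging across two
  retinotopically organized areas (a V1-like and an LM-like field separated by
  a border zone), with interleaved visual-only (V) and visual+photostimulation
  (V+P) trials and known facilitated/suppressed responders placed according to
  a configurable retinotopic-offset profile.
* :func:`make_dendrite_recording` — sparse dendritic imaging of spiny branches
  during grid photostimulation of a source area, with known target→spine
  connections, a branch "boosting" effect on stimulation trials, and local
  dendritic events injected as Gaussian spatial profiles (optionally rendered
  as a pixel movie for spatial-profile analysis).

Every stochastic choice is drawn from a single seeded generator, so a config
plus seed reproduces a session bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import calcium_kernel, synthesize_fluorescence

__all__ = [
    "GeneratorConfig",
    "StimGroup",
    "PopulationSession",
    "BranchGeometry",
    "SpineRecording",
    "psf_lateral",
    "make_population_session",
    "make_dendrite_recording",
]

LN2 = np.log(2.0)


def psf_lateral(distance_um: np.ndarray | float, hwhm_um: float) -> np.ndarray | float:
    """Lateral photostimulation point-spread: Gaussian with the given HWHM."""
    d = np.asarray(distance_um, dtype=float)
    out = np.exp(-LN2 * (d / hwhm_um) ** 2)
    return float(out) if np.isscalar(distance_um) else out


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunable parameters of the synthetic generators.

    Population-session parameters come first, dendrite-recording parameters
    after. Widths are µm, angles visual degrees, times seconds, amplitudes
    ΔF/F. Defaults reproduce the study conditions the downstream stages are
    calibrated against.
    """

    seed: int = 0
    frame_rate: float = 10.0
    kernel_rise_s: float = 0.1
    kernel_decay_s: float = 1.5
    noise_sd: float = 0.2

    # --- population session -------------------------------------------------
    n_rois: int = 500
    fov_um: tuple[float, float] = (900.0, 450.0)
    border_zone_um: float = 150.0
    retinotopic_gradient_deg_per_um: float = 0.07
    n_v_trials: int = 100
    n_vp_trials: int = 100
    n_groups: int = 1
    targets_per_group: int = 10
    orientations_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    trial_period_s: float = 3.0
    visual_dur_s: float = 1.0
    photostim_dur_s: float = 0.5
    visual_amp_dff: float = 1.0
    visual_gain_sd: float = 0.4
    tuning_width_deg: float = 35.0
    spont_rate_hz: float = 0.02
    responder_fraction: float = 0.10
    responder_effect_dff: float = 1.0
    # probability that a responder's sign is suppressed follows a Gaussian of
    # retinotopic offset (centre-suppressed), facilitated an offset ring
    # (surround-facilitated); see methods note.
    suppressed_sigma_deg: float = 8.0
    facilitated_peak_deg: float = 12.0
    frac_running_trials: float = 0.3
    psf_lateral_hwhm_um: float = 20.7
    psf_axial_hwhm_um: float = 45.0

    # --- dendrite recording -------------------------------------------------
    n_branches: int = 2
    branch_length_um: float = 60.0
    um_per_px: float = 0.5
    n_spines: int = 8
    n_targets: int = 300
    targets_per_stim: int = 15
    n_stim_trials: int = 40
    n_blank_trials: int = 20
    # confirmation-style pacing: stimulations tens of seconds apart, so the
    # calcium signal fully returns to baseline between trials
    stim_period_s: float = 15.0
    n_connections: int = 1
    connection_amp_dff: float = 0.5
    connection_reliability: float = 0.9
    n_confirmation_trials: int = 25  # isolated stimulations of connected targets
    spine_event_prob: float = 0.15
    spine_event_amp_dff: float = 0.8
    global_event_prob: float = 0.3
    global_event_amp_dff: float = 0.6
    branch_response_amp_dff: float = 0.5
    branch_response_sd_dff: float = 0.15
    # branch mask ROIs average ~100s of pixels, so their trace noise is far
    # below the per-pixel / small-ROI level given by noise_sd
    branch_noise_sd: float = 0.05
    boosting_factor: float = 1.108
    local_event_sigma_um: float = 4.757  # FWHM 2*sqrt(2 ln 2)*sigma = 11.2 µm
    local_event_amp_dff: float = 2.0
    n_local_events: int = 50
    render_movie: bool = False
    # visual stimulus schedule of the movie timeline; local-event probability
    # scales with surround drive (inverse > full field > annulus > Gabors)
    stim_types: tuple[str, ...] = ("gabor8", "gabor16", "inverse", "fullfield",
                                   "annulus")
    local_event_type_weights: tuple[float, ...] = (0.10, 0.15, 0.40, 0.25, 0.10)

    def validate_population(self) -> None:
        if self.n_rois <= 0:
            raise ValueError("n_rois must be positive")
        if self.n_v_trials + self.n_vp_trials <= 0:
            raise ValueError("session must contain trials")
        if self.border_zone_um >= self.fov_um[0]:
            raise ValueError("border zone wider than FOV")
        if self.border_zone_um < 0 or self.noise_sd < 0:
            raise ValueError("widths and rates must be non-negative")
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise ValueError("responder_fraction must lie in [0, 1]")

    def validate_dendrite(self) -> None:
        if self.n_branches < 1 or self.n_spines < 2:
            raise ValueError("need >=1 branch and >=2 spines")
        if self.n_targets <= 0:
            raise ValueError("target grid is empty")
        if self.local_event_sigma_um <= 0 or self.um_per_px <= 0:
            raise ValueError("widths must be positive")


@dataclass(frozen=True)
class StimGroup:
    group_id: int
    target_roi_ids: np.ndarray
    target_positions_um: np.ndarray  # (n_targets, 3)


@dataclass
class PopulationSession:
    """One population recording: traces plus trial/ROI/ground-truth tables."""

    traces: np.ndarray  # rois × frames, raw fluorescence [a.u.]
    frame_rate: float
    roi_meta: pd.DataFrame  # roi_id, x_um, y_um, plane, area, true_az/el deg
    trials: pd.DataFrame  # onset_frame, stim_end_frame, type, group_id, ...
    groups: list[StimGroup]
    ground_truth: pd.DataFrame  # group_id, roi_id, label, effect_dff
    config: GeneratorConfig

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


@dataclass(frozen=True)
class BranchGeometry:
    """A dendritic branch as an ordered 1-px path; index 0 is the proximal end."""

    branch_id: int
    line_um: np.ndarray  # (n_px, 2) ordered pixel path, µm
    mask_um: np.ndarray  # (n_mask, 2) mask-ROI pixels, µm

    @property
    def geodesic_um(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.line_um, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class SpineRecording:
    """One dendritic recording: spine/branch traces, stimulation log, truth."""

    branches: list[BranchGeometry]
    spine_meta: pd.DataFrame  # spine_id, branch_id, position_um, x_um, y_um
    spine_traces: np.ndarray  # spines × frames, raw F
    branch_traces: np.ndarray  # branches × frames, raw F
    target_grid: np.ndarray  # (n_targets, 3) µm
    stim_log: pd.DataFrame  # stim_frame, stim_end_frame, target_ids (tuple)
    frame_rate: float
    ground_truth: dict
    config: GeneratorConfig
    movie: np.ndarray | None = None  # frames × y × x raw F (stim branch only)


# ---------------------------------------------------------------------------
# population sessions
# ---------------------------------------------------------------------------


def _orientation_tuning(orientation_deg, pref_deg, width_deg):
    d = np.abs(((orientation_deg - pref_deg) + 90.0) % 180.0 - 90.0)
    return np.exp(-(d**2) / (2.0 * width_deg**2))


def make_population_session(config: GeneratorConfig) -> PopulationSession:
    """Generate one population session with known responder ground truth."""
    config.validate_population()
    rng = np.random.default_rng(config.seed)
    fr = config.frame_rate
    fov_x, fov_y = config.fov_um
    border_x = fov_x / 2.0
    half_zone = config.border_zone_um / 2.0

    # ROI placement and retinotopy (mirrored linear gradient across the border)
    x = rng.uniform(0.0, fov_x, config.n_rois)
    y = rng.uniform(0.0, fov_y, config.n_rois)
    area = np.where(x < border_x, "A1", "A2")
    area = np.where(np.abs(x - border_x) < half_zone, "border", area)
    g = config.retinotopic_gradient_deg_per_um
    true_az = g * np.abs(x - border_x)
    true_el = g * (y - fov_y / 2.0)
    roi_meta = pd.DataFrame(
        {
            "roi_id": np.arange(config.n_rois),
            "x_um": x,
            "y_um": y,
            "plane": 0,
            "area": area,
            "true_azimuth_deg": true_az,
            "true_elevation_deg": true_el,
        }
    )
    pref_orient = rng.choice(config.orientations_deg, config.n_rois)

    # stimulation groups: targets in A1, outside the border zone
    groups: list[StimGroup] = []
    a1_ok = np.flatnonzero((area == "A1") & (x < border_x - half_zone))
    for gid in range(config.n_groups):
        centre = np.array(
            [
                rng.uniform(60.0, border_x - half_zone - 60.0),
                rng.uniform(60.0, fov_y - 60.0),
            ]
        )
        pos = centre + rng.normal(0.0, 40.0, size=(config.targets_per_group, 2))
        pos[:, 0] = np.clip(pos[:, 0], 0.0, border_x - half_zone - 1.0)
        pos[:, 1] = np.clip(pos[:, 1], 0.0, fov_y)
        d2 = (x[a1_ok, None] - pos[None, :, 0]) ** 2 + (
            y[a1_ok, None] - pos[None, :, 1]
        ) ** 2
        tgt_rois = a1_ok[np.argmin(d2, axis=0)]
        pos3 = np.column_stack([pos, np.zeros(len(pos))])
        groups.append(StimGroup(gid, tgt_rois, pos3))

    # ground-truth responders
    gt_rows = []
    for grp in groups:
        # local facilitated responders: neurons within ~1 lateral HWHM of a target
        d_lat = np.sqrt(
            (x[:, None] - grp.target_positions_um[None, :, 0]) ** 2
            + (y[:, None] - grp.target_positions_um[None, :, 1]) ** 2
        ).min(axis=1)
        local = (area == "A1") & (d_lat <= config.psf_lateral_hwhm_um)
        for rid in np.flatnonzero(local):
            gt_rows.append((grp.group_id, rid, "facilitated", config.responder_effect_dff))
        # across-area responders per the retinotopic-offset profile
        src = np.flatnonzero(local)
        if src.size:
            src_az = true_az[src].mean()
            src_el = true_el[src].mean()
        else:  # zero-effect configs still need a stimulated location
            src_az = float(g * half_zone)
            src_el = 0.0
        across = np.flatnonzero(area == "A2")
        n_resp = int(round(config.responder_fraction * across.size))
        if n_resp and config.responder_effect_dff != 0.0:
            offset = np.hypot(true_az[across] - src_az, true_el[across] - src_el)
            w_sup = np.exp(-(offset**2) / (2.0 * config.suppressed_sigma_deg**2))
            pk = config.facilitated_peak_deg
            w_fac = (offset / pk) * np.exp(0.5 * (1.0 - (offset / pk) ** 2))
            w_tot = w_sup + w_fac
            w_tot = w_tot / w_tot.sum()
            chosen = rng.choice(across, size=min(n_resp, across.size), replace=False,
                                p=w_tot)
            for rid in chosen:
                i = np.searchsorted(across, rid)
                p_sup = w_sup[i] / (w_sup[i] + w_fac[i])
                if rng.random() < p_sup:
                    gt_rows.append(
                        (grp.group_id, rid, "suppressed", -config.responder_effect_dff)
                    )
                else:
                    gt_rows.append(
                        (grp.group_id, rid, "facilitated", config.responder_effect_dff)
                    )
    if config.responder_effect_dff == 0.0:
        gt_rows = []
    ground_truth = pd.DataFrame(
        gt_rows, columns=["group_id", "roi_id", "label", "effect_dff"]
    )

    # trial table
    n_trials = config.n_v_trials + config.n_vp_trials * config.n_groups
    types = ["V"] * config.n_v_trials
    gids: list[int | float] = [np.nan] * config.n_v_trials
    for grp in groups:
        types += ["V+P"] * config.n_vp_trials
        gids += [grp.group_id] * config.n_vp_trials
    order = rng.permutation(n_trials)
    types = np.asarray(types)[order]
    gids = np.asarray(gids, dtype=float)[order]
    # orientations balanced within each trial type (as in the experiment)
    orients = np.empty(n_trials)
    for sel in [types == "V"] + [
        (types == "V+P") & (gids == g.group_id) for g in groups
    ]:
        n_sel = int(sel.sum())
        block = np.resize(config.orientations_deg, n_sel)
        orients[sel] = rng.permutation(block)
    period = int(round(config.trial_period_s * fr))
    warmup = int(round(2.0 * fr))
    onsets = warmup + period * np.arange(n_trials)
    stim_end = onsets + int(np.ceil(config.photostim_dur_s * fr))
    running = rng.random(n_trials) < config.frac_running_trials
    speed = np.where(running, rng.uniform(4.0, 15.0, n_trials), rng.uniform(0.0, 1.0, n_trials))
    trials = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "onset_frame": onsets,
            "stim_end_frame": stim_end,
            "type": types,
            "group_id": gids,
            "orientation_deg": orients,
            "run_speed_cm_s": speed,
        }
    )

    # per-ROI event trains
    n_frames = int(onsets[-1] + period + 4 * fr)
    events = np.zeros((config.n_rois, n_frames))
    gain = rng.lognormal(mean=0.0, sigma=config.visual_gain_sd, size=(config.n_rois, n_trials))
    tuning = _orientation_tuning(orients[None, :], pref_orient[:, None], config.tuning_width_deg)
    amp = config.visual_amp_dff * tuning * gain
    # photostimulation effects for ground-truth responders
    effect = np.zeros((config.n_rois, n_trials))
    if len(ground_truth):
        for grp in groups:
            gt_g = ground_truth[ground_truth.group_id == grp.group_id]
            mask_t = (types == "V+P") & (gids == grp.group_id)
            d_lat = np.sqrt(
                (x[:, None] - grp.target_positions_um[None, :, 0]) ** 2
                + (y[:, None] - grp.target_positions_um[None, :, 1]) ** 2
            ).min(axis=1)
            for _, row in gt_g.iterrows():
                rid = int(row.roi_id)
                if row.effect_dff > 0 and area[rid] == "A1":
                    # direct photoactivation: PSF attenuates the per-trial
                    # probability of a response, amplitude fixed
                    p = psf_lateral(d_lat[rid], config.psf_lateral_hwhm_um)
                    hit = mask_t & (rng.random(n_trials) < p)
                    effect[rid, hit] += row.effect_dff
                else:
                    effect[rid, mask_t] += row.effect_dff
    trial_amp = np.clip(amp + effect, 0.0, None)
    events[:, onsets] = trial_amp
    n_spont = rng.poisson(config.spont_rate_hz * n_frames / fr, size=config.n_rois)
    for i in range(config.n_rois):
        if n_spont[i]:
            t_sp = rng.integers(0, n_frames, n_spont[i])
            events[i, t_sp] += rng.exponential(0.5, n_spont[i])

    baseline = rng.lognormal(np.log(100.0), 0.2, size=(config.n_rois, 1))
    traces = synthesize_fluorescence(
        events,
        fr,
        config.kernel_rise_s,
        config.kernel_decay_s,
        noise_sd=config.noise_sd,
        baseline=baseline,
        rng=rng,
    )
    return PopulationSession(
        traces=traces.astype(np.float32),
        frame_rate=fr,
        roi_meta=roi_meta,
        trials=trials,
        groups=groups,
        ground_truth=ground_truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# dendrite recordings
# ---------------------------------------------------------------------------


def make_dendrite_recording(config: GeneratorConfig) -> SpineRecording:
    """Generate one dendritic recording with known connections and events.

    Branch 0 is the (potentially) stimulated branch carrying the connected
    spine(s); branch 1, when present, is the reference branch used by the
    boosting analysis. Branch ROIs carry a shared per-trial dendritic response
    whose amplitude on branch 0 is multiplied by ``boosting_factor`` on
    stimulation trials.
    """
    config.validate_dendrite()
    rng = np.random.default_rng(config.seed)
    fr = config.frame_rate

    # geometry: straight branches along x, 1-px line plus a 5-px-wide mask
    n_px = int(round(config.branch_length_um / config.um_per_px)) + 1
    branches = []
    for b in range(config.n_branches):
        y0 = (5.0 + 20.0 * b) * config.um_per_px  # branch 0 sits on movie row 5
        xs = np.arange(n_px) * config.um_per_px
        line = np.column_stack([xs, np.full(n_px, y0)])
        mask = np.concatenate(
            [np.column_stack([xs, np.full(n_px, y0 + dy * config.um_per_px)])
             for dy in (-2, -1, 0, 1, 2)]
        )
        branches.append(BranchGeometry(b, line, mask))

    spine_branch = np.zeros(config.n_spines, dtype=int)  # all spines on branch 0
    margin = 5.0
    spine_pos = rng.uniform(margin, config.branch_length_um - margin, config.n_spines)
    spine_pos.sort()
    spine_meta = pd.DataFrame(
        {
            "spine_id": np.arange(config.n_spines),
            "branch_id": spine_branch,
            "position_um": spine_pos,
            "x_um": spine_pos,
            "y_um": np.full(config.n_spines, 5.0 * config.um_per_px - 2.5),
        }
    )

    # target grid in the source area (arbitrary distant coordinates, 2 z-planes)
    grid = np.column_stack(
        [
            rng.uniform(0.0, 400.0, config.n_targets),
            rng.uniform(0.0, 400.0, config.n_targets),
            rng.choice([0.0, 30.0], config.n_targets),
        ]
    )

    # stimulation log: a search block of random groups plus blanks, then a
    # confirmation block of isolated stimulations of the connected targets
    n_search = config.n_stim_trials + config.n_blank_trials
    n_trials = n_search + config.n_confirmation_trials
    period = int(round(config.stim_period_s * fr))
    warmup = int(round(3.0 * fr))
    stim_frames = warmup + period * np.arange(n_trials)
    stim_dur = max(1, int(round(0.25 * fr)))
    is_blank = np.zeros(n_trials, dtype=bool)
    is_blank[rng.permutation(n_search)[: config.n_blank_trials]] = True

    # true connections: distinct targets onto distinct spines
    conn_targets = rng.choice(config.n_targets, config.n_connections, replace=False)
    conn_spines = rng.choice(config.n_spines, config.n_connections, replace=False)
    connections = list(zip(conn_targets.tolist(), conn_spines.tolist()))

    target_ids_per_trial: list[tuple[int, ...]] = []
    for t in range(n_trials):
        if is_blank[t]:
            target_ids_per_trial.append(())
        elif t >= n_search:
            target_ids_per_trial.append(tuple(int(i) for i in np.sort(conn_targets)))
        else:
            ids = rng.choice(config.n_targets, config.targets_per_stim, replace=False)
            target_ids_per_trial.append(tuple(int(i) for i in np.sort(ids)))
    stim_log = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "stim_frame": stim_frames,
            "stim_end_frame": stim_frames + stim_dur,
            "target_ids": target_ids_per_trial,
        }
    )

    n_frames = int(stim_frames[-1] + period + 4 * fr)
    spine_events = np.zeros((config.n_spines, n_frames))
    branch_events = np.zeros((config.n_branches, n_frames))

    # shared global events across all spines and branches
    glob = rng.random(n_trials) < config.global_event_prob
    glob_amp = rng.lognormal(np.log(config.global_event_amp_dff), 0.3, n_trials)
    # per-trial dendritic branch response (both branch ROIs, every trial)
    branch_amp = np.clip(
        rng.normal(config.branch_response_amp_dff, config.branch_response_sd_dff,
                   n_trials),
        0.05,
        None,
    )
    boost = np.where(~is_blank, config.boosting_factor, 1.0)

    for t in range(n_trials):
        f_resp = stim_frames[t] + stim_dur  # responses begin at stim offset
        if glob[t]:
            spine_events[:, f_resp] += glob_amp[t]
        g_t = glob_amp[t] if glob[t] else 0.0
        # the boosting factor multiplies the stimulated branch's entire
        # post-stimulus ΔF/F on stimulation trials
        branch_events[0, f_resp] += (branch_amp[t] + g_t) * boost[t]
        for b in range(1, config.n_branches):
            branch_events[b, f_resp] += branch_amp[t] + g_t
        # independent spontaneous spine events
        solo = rng.random(config.n_spines) < config.spine_event_prob
        spine_events[solo, f_resp] += rng.lognormal(
            np.log(config.spine_event_amp_dff), 0.2, int(solo.sum())
        )
        # connection-driven responses (amplitude × lateral PSF attenuation; the
        # direct target sits at distance 0 so attenuation is 1)
        if not is_blank[t]:
            stimulated = set(target_ids_per_trial[t])
            for tgt, sp in connections:
                if tgt in stimulated and rng.random() < config.connection_reliability:
                    spine_events[sp, f_resp] += config.connection_amp_dff

    baseline = 100.0
    spine_traces = synthesize_fluorescence(
        spine_events, fr, config.kernel_rise_s, config.kernel_decay_s,
        noise_sd=config.noise_sd, baseline=baseline, rng=rng,
    )
    branch_traces = synthesize_fluorescence(
        branch_events, fr, config.kernel_rise_s, config.kernel_decay_s,
        noise_sd=config.branch_noise_sd, baseline=baseline, rng=rng,
    )

    # local dendritic events on branch 0 (for the movie / spatial profiling);
    # the movie has its own visual-stimulation timeline, and events fall
    # preferentially on high-surround stimuli
    ev_margin = 3.0 * config.local_event_sigma_um
    event_times = np.array([], dtype=int)
    event_pos = np.array([])
    event_stimulus = np.array([], dtype=object)
    movie_trials = None
    movie = None
    if config.n_local_events > 0 and config.render_movie:
        ev_period = int(round(6.0 * fr))
        n_slots = 2 * config.n_local_events
        slot_frames = warmup + ev_period * np.arange(n_slots)
        slot_types = rng.choice(config.stim_types, n_slots)
        w = np.asarray(config.local_event_type_weights, dtype=float)
        slot_w = w[[config.stim_types.index(t) for t in slot_types]]
        chosen = rng.choice(
            n_slots, size=config.n_local_events, replace=False, p=slot_w / slot_w.sum()
        )
        chosen.sort()
        event_times = slot_frames[chosen]
        event_stimulus = slot_types[chosen]
        movie_trials = pd.DataFrame(
            {
                "trial": np.arange(n_slots),
                "onset_frame": slot_frames,
                "stimulus": slot_types,
                "n_events": np.isin(np.arange(n_slots), chosen).astype(int),
            }
        )
        movie_frames = int(slot_frames[-1] + ev_period + 4 * fr)
        event_pos = rng.uniform(
            ev_margin, config.branch_length_um - ev_margin, config.n_local_events
        )
        ny = 11
        nx = n_px
        xs = np.arange(nx) * config.um_per_px
        kern = calcium_kernel(fr, config.kernel_rise_s, config.kernel_decay_s)
        dff_px = np.zeros((movie_frames, nx))
        for t0, mu in zip(event_times, event_pos):
            prof = config.local_event_amp_dff * np.exp(
                -((xs - mu) ** 2) / (2.0 * config.local_event_sigma_um**2)
            )
            span = min(kern.size, movie_frames - t0)
            dff_px[t0 : t0 + span] += kern[:span, None] * prof[None, :]
        movie = np.empty((movie_frames, ny, nx), dtype=np.float32)
        strip = np.zeros(ny)
        strip[3:8] = 1.0  # branch occupies the central 5 rows
        clean = baseline * (1.0 + dff_px[:, None, :] * strip[None, :, None])
        movie[:] = clean + baseline * rng.normal(
            0.0, config.noise_sd, size=(movie_frames, ny, nx)
        )

    ground_truth = {
        "connections": connections,
        "connection_amp_dff": config.connection_amp_dff,
        "boosting_factor": config.boosting_factor,
        "stim_trials": np.flatnonzero(~is_blank),
        "blank_trials": np.flatnonzero(is_blank),
        "search_trials": np.arange(n_search),
        "confirmation_trials": np.arange(n_search, n_trials),
        "local_event_frames": event_times,
        "local_event_pos_um": event_pos,
        "local_event_stimulus": event_stimulus,
        "local_event_sigma_um": config.local_event_sigma_um,
        "movie_trials": movie_trials,
    }
    return SpineRecording(
        branches=branches,
        spine_meta=spine_meta,
        spine_traces=spine_traces.astype(np.float32),
        branch_traces=branch_traces.astype(np.float32),
        target_grid=grid,
        stim_log=stim_log,
        frame_rate=fr,
        ground_truth=ground_truth,
        config=config,
        movie=movie,
    )
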