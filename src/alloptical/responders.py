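"""Photostimulation responder detection and response quantification.

The per-trial response statistic R_i is a signal-to-background ratio: the mean
ΔF/F in a 500 ms window after photostimulation offset (S_i) minus the mean in
a 500 ms window before visual onset (B_i), divided by the s.d. of the baseline
values over the current and two preceding trials. Responders are neurons whose
R_i distributions differ between visual-only (V) and visual+photostimulation
(V+P) trials by a two-sided Wilcoxon rank-sum test after orientation matching,
with the false discovery rate controlled across neurons (headline level 2.5%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "trial_response_matrix",
    "trial_responses",
    "match_orientations",
    "detect_responders",
    "response_probability",
    "smooth_running_speed",
    "locomotion_modulation",
    "LocomotionModulation",
]

FDR_LEVEL = 0.025  # headline FDR control level
Z_CRIT = 1.64  # one-sided normal critical value at alpha = 0.05


def _window_frames(window_s: float, frame_rate: float) -> int:
    return max(1, int(np.ceil(window_s * frame_rate)))


def trial_response_matrix(
    dff_traces: np.ndarray,
    trials: pd.DataFrame,
    frame_rate: float,
    s_window_s: float = 0.5,
    b_window_s: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Compute S, B and R matrices (rois × trials) for a trial table.

    ``trials`` must carry ``onset_frame`` (visual onset) and ``stim_end_frame``
    (photostimulation offset; for V trials, the frame where photostimulation
    would have ended). Trials whose windows fall off the trace are dropped
    with a warning. For the first two trials the baseline s.d. uses all
    available preceding baselines; an exactly zero s.d. is replaced by the
    session-median baseline s.d.
    """
    dff_traces = np.atleast_2d(np.asarray(dff_traces, dtype=float))
    n_frames = dff_traces.shape[1]
    sw = _window_frames(s_window_s, frame_rate)
    bw = _window_frames(b_window_s, frame_rate)

    onset = trials["onset_frame"].to_numpy(int)
    stim_end = trials["stim_end_frame"].to_numpy(int)
    ok = (onset - bw >= 0) & (stim_end + sw <= n_frames)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} trial(s) with windows off the trace")
    trials = trials.loc[ok].reset_index(drop=True)
    onset, stim_end = onset[ok], stim_end[ok]
    n_trials = len(trials)

    S = np.stack([dff_traces[:, e : e + sw].mean(axis=1) for e in stim_end], axis=1)
    B = np.stack([dff_traces[:, o - bw : o].mean(axis=1) for o in onset], axis=1)

    sd = np.empty_like(B)
    for i in range(n_trials):
        lo = max(0, i - 2)
        sd[:, i] = B[:, lo : i + 1].std(axis=1, ddof=1) if i - lo >= 1 else 0.0
    med = np.median(sd[:, 2:], axis=1, keepdims=True) if n_trials > 2 else None
    degenerate = sd <= 0
    if med is not None:
        fallback = np.where(med > 0, med, 1.0)
        sd = np.where(degenerate, np.broadcast_to(fallback, sd.shape), sd)
    sd = np.where(sd <= 0, 1.0, sd)
    R = (S - B) / sd
    return S, B, R, trials


def trial_responses(
    dff_trace: np.ndarray,
    trials: pd.DataFrame,
    frame_rate: float,
    s_window_s: float = 0.5,
    b_window_s: float = 0.5,
) -> pd.DataFrame:
    """Per-trial responses of a single ROI as a tidy table."""
    S, B, R, kept = trial_response_matrix(
        dff_trace, trials, frame_rate, s_window_s, b_window_s
    )
    out = kept.copy()
    out["S"] = S[0]
    out["B"] = B[0]
    out["R"] = R[0]
    return out


def match_orientations(
    orients_v: np.ndarray,
    orients_vp: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of a V-trial subsample matching the V+P orientation proportions."""
    orients_v = np.asarray(orients_v)
    orients_vp = np.asarray(orients_vp)
    levels, counts_vp = np.unique(orients_vp, return_counts=True)
    prop = counts_vp / counts_vp.sum()
    counts_v = np.array([(orients_v == o).sum() for o in levels])
    if np.any(counts_v == 0):
        raise ValueError("an orientation present in V+P trials is absent from V trials")
    n_sub = int(np.floor((counts_v / prop).min()))
    keep: list[np.ndarray] = []
    for o, p in zip(levels, prop):
        k = max(1, int(round(p * n_sub)))
        idx = np.flatnonzero(orients_v == o)
        keep.append(rng.choice(idx, size=min(k, idx.size), replace=False))
    return np.sort(np.concatenate(keep))


def _storey_qvalues(p: np.ndarray) -> np.ndarray:
    """Storey positive-FDR q-values with the smoother-free pi0 at lambda=0.5."""
    p = np.asarray(p, dtype=float)
    m = p.size
    lam = 0.5
    pi0 = min(1.0, (p > lam).sum() / (m * (1.0 - lam)))
    pi0 = max(pi0, 1.0 / m)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        prev = min(prev, pi0 * m * p[i] / (rank + 1))
        q[i] = prev
    return q


def detect_responders(
    r_matrix: np.ndarray,
    trial_type: np.ndarray,
    orientations: np.ndarray,
    fdr_level: float = FDR_LEVEL,
    fdr_method: str = "bh",
    n_draws: int = 1,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Detect facilitated/suppressed responders for one stimulation group.

    Parameters
    ----------
    r_matrix : rois × trials R values (V and V+P trials of one group).
    trial_type : per-trial label, "V" or "V+P".
    orientations : per-trial grating orientation (deg).
    fdr_method : "bh" (Benjamini–Hochberg) or "storey" (positive-FDR q-values).
    n_draws : p-values are averaged over this many orientation-matched
        subsamples of the V trials (1 = a single seeded draw).

    Returns a table with one row per ROI: p, q, sign, median_effect. The sign
    (facilitated/suppressed) is assigned only when q < fdr_level and the median
    effect is non-zero.
    """
    rng = np.random.default_rng(rng)
    r_matrix = np.atleast_2d(np.asarray(r_matrix, dtype=float))
    trial_type = np.asarray(trial_type)
    is_vp = trial_type == "V+P"
    is_v = trial_type == "V"
    if not is_vp.any():
        raise ValueError("group has no V+P trials")
    if is_v.sum() < 5 or is_vp.sum() < 5:
        raise ValueError("need at least 5 trials of each type")

    r_vp = r_matrix[:, is_vp]
    r_v_all = r_matrix[:, is_v]
    or_v = np.asarray(orientations)[is_v]
    or_vp = np.asarray(orientations)[is_vp]

    n_rois = r_matrix.shape[0]
    pvals = np.zeros(n_rois)
    for _ in range(n_draws):
        sub = match_orientations(or_v, or_vp, rng)
        r_v = r_v_all[:, sub]
        with np.errstate(invalid="ignore"):
            res = stats.mannwhitneyu(
                r_vp, r_v, axis=1, alternative="two-sided",
                method="asymptotic" if min(r_vp.shape[1], r_v.shape[1]) > 20
                else "auto",
            )
        p = np.asarray(res.pvalue, dtype=float)
        # all-identical values across both samples: no evidence
        const = (np.ptp(r_vp, axis=1) == 0) & (np.ptp(r_v, axis=1) == 0) & (
            r_vp[:, 0] == r_v[:, 0]
        )
        p[const | ~np.isfinite(p)] = 1.0
        pvals += p
    pvals /= n_draws
    pvals = np.clip(pvals, 0.0, 1.0)

    if fdr_method == "bh":
        q = multipletests(pvals, method="fdr_bh")[1]
    elif fdr_method == "storey":
        q = _storey_qvalues(pvals)
    else:
        raise ValueError(f"unknown fdr_method {fdr_method!r}")

    med_effect = np.median(r_vp, axis=1) - np.median(r_v_all, axis=1)
    sign = np.full(n_rois, "none", dtype=object)
    hit = (q < fdr_level) & (med_effect != 0)
    sign[hit & (med_effect > 0)] = "facilitated"
    sign[hit & (med_effect < 0)] = "suppressed"
    return pd.DataFrame(
        {
            "roi_id": np.arange(n_rois),
            "p": pvals,
            "q": np.maximum(q, pvals),
            "sign": sign,
            "median_effect": med_effect,
        }
    )


def response_probability(
    r_vp: np.ndarray, r_v: np.ndarray, z_crit: float = Z_CRIT
) -> float:
    """Fraction of V+P trials whose Z-score against the V reference exceeds z_crit.

    Each R_i^{V+P} is Z-scored against the mean and s.d. of all R^V for the
    same neuron; the default critical value is the one-sided 5% normal
    quantile (Z = 1.64).
    """
    r_vp = np.asarray(r_vp, dtype=float)
    r_v = np.asarray(r_v, dtype=float)
    if r_vp.size < 1 or r_v.size < 2:
        raise ValueError("need >=1 V+P trial and >=2 V trials")
    sd = r_v.std(ddof=1)
    if sd == 0:
        return float("nan")
    z = (r_vp - r_v.mean()) / sd
    return float(np.mean(z > z_crit))


def smooth_running_speed(
    wheel_displacement: np.ndarray, frame_rate: float, smooth_s: float = 2.5
) -> np.ndarray:
    """Differentiate a wheel-displacement trace and apply a 2.5 s moving average."""
    speed = np.gradient(np.asarray(wheel_displacement, dtype=float)) * frame_rate
    w = max(1, int(round(smooth_s * frame_rate)))
    kern = np.ones(w) / w
    return np.convolve(speed, kern, mode="same")


@dataclass
class LocomotionModulation:
    r_run: float
    r_sit: float
    delta_response: float  # (R_run - R_sit) / R_sit; NaN when undefined
    n_run: int
    n_sit: int


def locomotion_modulation(
    responses: np.ndarray,
    trial_speeds: np.ndarray,
    threshold_cm_s: float = 3.0,
) -> LocomotionModulation:
    """Locomotion modulation of trial responses at a 3 cm/s speed threshold.

    ``responses`` are per-trial response values (S_i − B_i) for one ROI;
    ``trial_speeds`` the smoothed running speed during each trial. Δresponse is
    undefined (NaN) when either state has no trials or R_sit ≤ 0.
    """
    responses = np.asarray(responses, dtype=float)
    run = np.asarray(trial_speeds, dtype=float) > threshold_cm_s
    n_run, n_sit = int(run.sum()), int((~run).sum())
    r_run = responses[run].mean() if n_run else float("nan")
    r_sit = responses[~run].mean() if n_sit else float("nan")
    if n_run == 0 or n_sit == 0 or not np.isfinite(r_sit) or r_sit <= 0:
        delta = float("nan")
    else:
        delta = (r_run - r_sit) / r_sit
    return LocomotionModulation(r_run, r_sit, delta, n_run, n_sit)
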