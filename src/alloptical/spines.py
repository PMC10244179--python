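"""Detection of long-range target→spine connections and branch boosting.

The candidate search exploits *independent* spine activity: trials on which a
spine's response ∆R is high while the across-spine average ∆R_mean stays low
(ruling out global dendritic events). Targets over-represented among a spine's
independent-event trials, under a sweep of ∆R / ∆R_mean / reliability
thresholds, become candidate connections; candidates are confirmed by a
signed-rank test (pre vs post stimulation, P < 0.01) on dedicated
isolated-stimulation trials. The boosting index quantifies whether synaptic
stimulation elevates calcium in the stimulated branch beyond the recipient
spine, relative to a reference branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpineTrialResponse",
    "spine_delta_r",
    "find_candidate_connections",
    "ConfirmedConnection",
    "confirm_connection",
    "BoostingResult",
    "boosting_index",
    "boosting_increase_pct",
    "DEFAULT_DR_SDS",
    "DEFAULT_DRMEAN_SDS",
    "DEFAULT_RELIABILITY_PCTS",
]

PRE_FRAMES = 9
POST_FRAMES = 7
# sweep grids: ∆R mean + 0.5…3 s.d., ∆R_mean mean + 0.5…1.5 s.d.,
# reliability 10–20%, discretized at 0.5 s.d. / 5% steps
DEFAULT_DR_SDS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
DEFAULT_DRMEAN_SDS = (0.5, 1.0, 1.5)
DEFAULT_RELIABILITY_PCTS = (10.0, 15.0, 20.0)


@dataclass
class SpineTrialResponse:
    """∆R matrix (spines × trials) with the across-spine mean per trial."""

    delta_r: np.ndarray
    delta_r_mean: np.ndarray
    trials: pd.DataFrame  # surviving rows of the stimulation log


def spine_delta_r(
    spine_dff: np.ndarray,
    stim_log: pd.DataFrame,
    pre_frames: int = PRE_FRAMES,
    post_frames: int = POST_FRAMES,
) -> SpineTrialResponse:
    """Per-spine, per-trial stimulation response ∆R.

    ∆R = mean ΔF/F over ``post_frames`` frames starting at stimulation offset
    minus the mean over ``pre_frames`` frames ending at stimulation onset;
    frames during the stimulation (the artifact) belong to neither window.
    Trials clipped by the trace edges are dropped.
    """
    spine_dff = np.atleast_2d(np.asarray(spine_dff, dtype=float))
    n_frames = spine_dff.shape[1]
    start = stim_log["stim_frame"].to_numpy(int)
    end = stim_log["stim_end_frame"].to_numpy(int)
    ok = (start - pre_frames >= 0) & (end + post_frames <= n_frames)
    kept = stim_log.loc[ok].reset_index(drop=True)
    pre = np.stack(
        [spine_dff[:, s - pre_frames : s].mean(axis=1) for s in start[ok]], axis=1
    )
    post = np.stack(
        [spine_dff[:, e : e + post_frames].mean(axis=1) for e in end[ok]], axis=1
    )
    dr = post - pre
    return SpineTrialResponse(dr, dr.mean(axis=0), kept)


def find_candidate_connections(
    resp: SpineTrialResponse,
    dr_sds=DEFAULT_DR_SDS,
    drmean_sds=DEFAULT_DRMEAN_SDS,
    reliability_pcts=DEFAULT_RELIABILITY_PCTS,
) -> pd.DataFrame:
    """Sweep thresholds and collect candidate target→spine connections.

    For each spine and each sweep setting, the independent-event trials are
    those with ∆R above (mean + a·s.d. of that spine's ∆R) and ∆R_mean below
    (mean + b·s.d. of ∆R_mean). A target present on strictly more than the
    reliability fraction of those trials is a candidate. Candidates are
    deduplicated over the sweep, keeping the best reliability; the full sweep
    grid is retained in the output for audit.
    """
    dr = resp.delta_r
    drm = resp.delta_r_mean
    if dr.shape[1] < 10:
        raise ValueError("need at least 10 trials")
    target_sets = [set(t) for t in resp.trials["target_ids"]]
    mu_s, sd_s = dr.mean(axis=1), dr.std(axis=1, ddof=1)
    mu_m, sd_m = drm.mean(), drm.std(ddof=1)

    rows = []
    for a in dr_sds:
        hi = dr > (mu_s + a * sd_s)[:, None]
        for b in drmean_sds:
            quiet = drm < mu_m + b * sd_m
            indep = hi & quiet[None, :]
            for s in range(dr.shape[0]):
                trials_s = np.flatnonzero(indep[s])
                n_ind = trials_s.size
                if n_ind == 0:
                    continue
                counts: dict[int, int] = {}
                for t in trials_s:
                    for tgt in target_sets[t]:
                        counts[tgt] = counts.get(tgt, 0) + 1
                for rel in reliability_pcts:
                    for tgt, c in counts.items():
                        reliability = c / n_ind
                        if reliability > rel / 100.0:
                            rows.append(
                                (tgt, s, reliability, n_ind, a, b, rel)
                            )
    sweep = pd.DataFrame(
        rows,
        columns=[
            "target_id", "spine_id", "reliability", "n_independent_trials",
            "dr_sd", "drmean_sd", "reliability_pct",
        ],
    )
    if sweep.empty:
        return sweep.assign(best_reliability=pd.Series(dtype=float))
    best = (
        sweep.groupby(["target_id", "spine_id"])["reliability"].max()
        .rename("best_reliability").reset_index()
    )
    return sweep.merge(best, on=["target_id", "spine_id"])


@dataclass
class ConfirmedConnection:
    target_id: int
    spine_id: int
    p_value: float
    mean_response_dff: float
    confirmed: bool


def confirm_connection(
    pre: np.ndarray,
    post: np.ndarray,
    target_id: int = -1,
    spine_id: int = -1,
    alpha: float = 0.01,
) -> ConfirmedConnection:
    """Confirm a candidate with a signed-rank test on isolated-stim trials.

    ``pre``/``post`` are the per-trial window means of the spine's ΔF/F around
    isolated stimulations of the candidate target (≥8 trials). Confirmation
    requires two-sided signed-rank p < 0.01 and a positive mean response.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size or pre.size < 8:
        raise ValueError("need >=8 paired confirmation trials")
    diff = post - pre
    if np.all(diff == 0):
        return ConfirmedConnection(target_id, spine_id, 1.0, 0.0, False)
    mode = "exact" if diff.size <= 25 and not np.any(diff == 0) else "approx"
    res = stats.wilcoxon(diff, method=mode)
    mean_resp = float(diff.mean())
    p = float(res.pvalue)
    return ConfirmedConnection(
        target_id, spine_id, p, mean_resp, bool(p < alpha and mean_resp > 0)
    )


@dataclass
class BoostingResult:
    bi_stim: np.ndarray
    bi_blank: np.ndarray
    p_value: float  # within-recording rank-sum, stim vs blank BIs
    mean_increase_pct: float  # (mean BI stim / mean BI blank − 1) × 100
    n_excluded: int


def boosting_index(
    stim_branch_dff: np.ndarray,
    ref_branch_dff: np.ndarray,
    stim_log: pd.DataFrame,
    stim_trials: np.ndarray,
    blank_trials: np.ndarray,
    post_frames: int = POST_FRAMES,
    floor: float = 0.01,
) -> BoostingResult:
    """Per-trial boosting index and the stim-vs-blank comparison.

    BI = (post-stimulus mean ΔF/F of the stimulated-branch ROI, which excludes
    the recipient spine) / (same for the reference-branch ROI). Trials whose
    reference response falls below ``floor`` are excluded. Requires ≥5 trials
    per type after exclusion.
    """
    stim_branch_dff = np.asarray(stim_branch_dff, dtype=float)
    ref_branch_dff = np.asarray(ref_branch_dff, dtype=float)
    end = stim_log["stim_end_frame"].to_numpy(int)

    def _bi(trial_idx):
        vals, excluded = [], 0
        for t in np.asarray(trial_idx, int):
            e = end[t]
            s_post = stim_branch_dff[e : e + post_frames].mean()
            r_post = ref_branch_dff[e : e + post_frames].mean()
            if r_post < floor:
                excluded += 1
                continue
            vals.append(s_post / r_post)
        return np.asarray(vals), excluded

    bi_stim, ex1 = _bi(stim_trials)
    bi_blank, ex2 = _bi(blank_trials)
    if bi_stim.size < 5 or bi_blank.size < 5:
        raise ValueError("need >=5 usable trials per type")
    if np.array_equal(np.sort(bi_stim), np.sort(bi_blank)):
        p = 1.0
    else:
        p = float(
            stats.mannwhitneyu(bi_stim, bi_blank, alternative="two-sided").pvalue
        )
    inc = boosting_increase_pct(bi_stim, bi_blank)
    return BoostingResult(bi_stim, bi_blank, p, inc, ex1 + ex2)


def boosting_increase_pct(bi_stim: np.ndarray, bi_blank: np.ndarray) -> float:
    """Percentage increase of the mean boosting index on stimulation trials."""
    return float((np.mean(bi_stim) / np.mean(bi_blank) - 1.0) * 100.0)


def across_recording_test(increases_pct: np.ndarray, method: str = "ttest"):
    """Paired across-recording test of the BI increase against zero.

    ``method`` is "ttest" (paired t on stim−blank mean BIs, expressed here as
    a one-sample t on the per-recording increases) or "signrank".
    """
    x = np.asarray(increases_pct, dtype=float)
    if method == "ttest":
        return stats.ttest_1samp(x, 0.0)
    if method == "signrank":
        return stats.wilcoxon(x)
    raise ValueError(f"unknown method {method!r}")
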