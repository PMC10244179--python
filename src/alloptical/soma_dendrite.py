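"""Soma–apical-trunk pairing and dendritic surround preference.

Somata and trunk cross-sections recorded in separate planes are paired by dual
correlation thresholds on raw-fluorescence and deconvolved-event traces
(defaults 0.45 / 0.25). Dendritic stimulus-size preference is assessed after
removing somatic influence: a within-neuron linear fit of dendritic on somatic
responses, residuals tested across stimulus sizes by one-way ANOVA. Apical vs
basal surround preference uses a trial-shuffle permutation test (3,000
shuffles) on the apical/basal response ratio between low-surround (Gabor) and
high-surround (inverse / full-field) stimulus classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "SomaDendritePair",
    "pair_soma_dendrite",
    "binned_population_surface",
    "SizeTuningResult",
    "size_tuning_residuals",
    "ApicalBasalResult",
    "apical_basal_ratio_test",
]

R_F_THRESHOLD = 0.45
R_E_THRESHOLD = 0.25
SOMA_BIN_PCT = 5.0
SOMA_BIN_LO = -40.0
SOMA_BIN_HI = 100.0
ACTIVITY_FILTER = 0.20  # soma (or basal) must reach 20% of its peak
N_SHUFFLE = 3000


@dataclass
class SomaDendritePair:
    soma_id: int
    dendrite_id: int
    r_fluorescence: float
    r_events: float
    paired: bool


def pair_soma_dendrite(
    soma_f: np.ndarray,
    dend_f: np.ndarray,
    soma_e: np.ndarray,
    dend_e: np.ndarray,
    r_f_threshold: float = R_F_THRESHOLD,
    r_e_threshold: float = R_E_THRESHOLD,
) -> list[SomaDendritePair]:
    """All soma × dendrite pairings by dual Pearson-correlation thresholds.

    A pair is connected iff the fluorescence correlation exceeds
    ``r_f_threshold`` AND the event-trace correlation exceeds
    ``r_e_threshold`` (both strict). Zero-variance traces yield undefined
    correlations and are never paired. The stricter setting (0.55, 0.35) used
    as a robustness check is obtained by passing those thresholds.
    """
    soma_f, dend_f = np.atleast_2d(soma_f), np.atleast_2d(dend_f)
    soma_e, dend_e = np.atleast_2d(soma_e), np.atleast_2d(dend_e)
    out = []
    for i in range(soma_f.shape[0]):
        for j in range(dend_f.shape[0]):
            if (
                soma_f[i].std() == 0 or dend_f[j].std() == 0
                or soma_e[i].std() == 0 or dend_e[j].std() == 0
            ):
                out.append(SomaDendritePair(i, j, float("nan"), float("nan"), False))
                continue
            rf = float(np.corrcoef(soma_f[i], dend_f[j])[0, 1])
            re = float(np.corrcoef(soma_e[i], dend_e[j])[0, 1])
            out.append(
                SomaDendritePair(i, j, rf, re, rf > r_f_threshold and re > r_e_threshold)
            )
    return out


def binned_population_surface(
    table: pd.DataFrame,
    bin_pct: float = SOMA_BIN_PCT,
    lo_pct: float = SOMA_BIN_LO,
    hi_pct: float = SOMA_BIN_HI,
    cells: bool = True,
) -> dict:
    """Population soma-activity-binned dendritic responses with two-way ANOVA.

    ``table`` has per-trial rows with columns ``soma`` and ``dend`` (responses
    normalized to each ROI's peak, as fractions of peak) and ``factor``
    (stimulus size or locomotion state). Soma responses are binned in 5%-wide
    bins from −40% to 100% of peak (28 bins); empty bins are dropped.

    With ``cells=True`` (default) the ANOVA runs on the unweighted bin-level
    cell means with the additive model (one observation per cell leaves no
    replication for an interaction); with ``cells=False`` it runs on the
    trial-level data including the soma-bin × factor interaction.
    """
    edges = np.arange(lo_pct, hi_pct + bin_pct / 2, bin_pct) / 100.0
    df = table.copy()
    df = df[(df["soma"] >= edges[0]) & (df["soma"] <= edges[-1])]
    df["soma_bin"] = pd.cut(df["soma"], bins=edges, include_lowest=True)
    df = df.dropna(subset=["soma_bin"])
    df["soma_bin"] = df["soma_bin"].cat.remove_unused_categories()
    means = (
        df.groupby(["soma_bin", "factor"], observed=True)[["soma", "dend"]]
        .mean()
        .reset_index()
    )
    if cells:
        data = means.assign(bin_code=means["soma_bin"].astype(str))
        model = ols("dend ~ C(bin_code) + C(factor)", data=data).fit()
    else:
        data = df.assign(bin_code=df["soma_bin"].astype(str))
        model = ols("dend ~ C(bin_code) * C(factor)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    return {"bins": means, "anova": anova, "n_bins": len(edges) - 1}


@dataclass
class SizeTuningResult:
    residuals: pd.DataFrame  # per-trial residual dendritic response
    anova_p: float
    preferred_size: float | str
    slope: float
    intercept: float
    degenerate_soma: bool
    locomotion_anova: pd.DataFrame | None = None


def size_tuning_residuals(
    trials: pd.DataFrame,
    activity_filter: float = ACTIVITY_FILTER,
    min_trials_per_size: int = 3,
    locomotion: bool = False,
) -> SizeTuningResult:
    """Dendritic size preference of one neuron after removing somatic influence.

    ``trials`` has columns ``soma``, ``dend``, ``size`` (and ``state`` in
    {"run", "sit"} when ``locomotion``). Trials with soma below 20% of that
    neuron's peak are excluded; a least-squares line of dendrite on soma is
    fit across all remaining trials, and a one-way ANOVA asks whether stimulus
    size structures the residuals. The preferred size is the size with the
    largest mean residual.

    With ``locomotion=True`` a two-way ANOVA (locomotion × pooled size) runs
    on the residuals; sizes are pooled as smaller/preferred/larger with the
    preference computed on stationary trials only.
    """
    df = trials.copy()
    peak = df["soma"].max()
    df = df[df["soma"] >= activity_filter * peak].copy()
    counts = df.groupby("size")["dend"].count()
    if (counts < min_trials_per_size).any() or counts.size < 2:
        raise ValueError("need >=3 usable trials for every stimulus size")
    soma = df["soma"].to_numpy(float)
    dend = df["dend"].to_numpy(float)
    degenerate = soma.std() == 0
    if degenerate:
        slope, intercept = 0.0, float(dend.mean())
    else:
        slope, intercept = np.polyfit(soma, dend, 1)
    df["residual"] = dend - (slope * soma + intercept)
    groups = [g["residual"].to_numpy() for _, g in df.groupby("size")]
    anova_p = float(stats.f_oneway(*groups).pvalue)
    mean_resid = df.groupby("size")["residual"].mean()
    preferred = mean_resid.idxmax()

    loco = None
    if locomotion:
        if "state" not in df:
            raise ValueError("locomotion analysis needs a 'state' column")
        sit = df[df["state"] == "sit"]
        pref_sit = sit.groupby("size")["residual"].mean().idxmax()
        sizes = np.sort(df["size"].unique())
        rank = {s: i for i, s in enumerate(sizes)}

        def pool(s):
            if rank[s] < rank[pref_sit]:
                return "smaller"
            if rank[s] > rank[pref_sit]:
                return "larger"
            return "preferred"

        df["size_class"] = df["size"].map(pool)
        model = ols("residual ~ C(state) * C(size_class)", data=df).fit()
        loco = sm.stats.anova_lm(model, typ=2)
    return SizeTuningResult(df, anova_p, preferred, float(slope), float(intercept),
                            bool(degenerate), loco)


@dataclass
class ApicalBasalResult:
    ratios: np.ndarray
    classes: np.ndarray  # "low" or "high" surround per usable trial
    observed_difference: float  # mean high − mean low
    shuffle_differences: np.ndarray
    significant: bool  # observed > 95% of shuffles
    n_excluded: int


def apical_basal_ratio_test(
    apical: np.ndarray,
    basal: np.ndarray,
    stimulus: np.ndarray,
    low_surround: tuple = ("gabor8", "gabor16"),
    high_surround: tuple = ("inverse", "fullfield"),
    basal_filter: float = ACTIVITY_FILTER,
    n_shuffle: int = N_SHUFFLE,
    rng: np.random.Generator | int | None = None,
) -> ApicalBasalResult:
    """Permutation test of apical/basal response ratio vs surround class.

    Per-trial ratios are formed after excluding trials whose basal response is
    non-positive or below 20% of the neuron's peak basal response. The
    observed statistic is the mean ratio on high-surround trials minus the
    mean on low-surround trials; the null shuffles trials between the classes
    3,000 times preserving class sizes. Significant iff the observed
    difference exceeds 95% of shuffles.
    """
    rng = np.random.default_rng(rng)
    apical = np.asarray(apical, dtype=float)
    basal = np.asarray(basal, dtype=float)
    stimulus = np.asarray(stimulus)
    cls = np.full(stimulus.shape, "", dtype=object)
    cls[np.isin(stimulus, low_surround)] = "low"
    cls[np.isin(stimulus, high_surround)] = "high"
    usable = (cls != "") & (basal > 0) & (basal >= basal_filter * np.max(basal))
    n_excluded = int(((cls != "") & ~usable).sum())
    ratios = apical[usable] / basal[usable]
    cls = cls[usable]
    n_low, n_high = int((cls == "low").sum()), int((cls == "high").sum())
    if n_low < 5 or n_high < 5:
        raise ValueError("need >=5 usable trials per surround class")
    observed = ratios[cls == "high"].mean() - ratios[cls == "low"].mean()
    diffs = np.empty(n_shuffle)
    for s in range(n_shuffle):
        perm = rng.permutation(ratios.size)
        hi = perm[:n_high]
        lo = perm[n_high:]
        diffs[s] = ratios[hi].mean() - ratios[lo].mean()
    significant = observed > np.quantile(diffs, 0.95)
    return ApicalBasalResult(ratios, cls, float(observed), diffs, bool(significant),
                             n_excluded)
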