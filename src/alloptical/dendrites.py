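"""Local dendritic event classification and spatial profiling.

A local event is the simultaneous activation of at least two spines and the
branch segment between them while the proximal end of the branch stays quiet;
global events activate the entire branch. The spatial footprint of an event is
measured by projecting every mask-ROI pixel onto its nearest line-ROI pixel,
expressing the per-geodesic-bin fluorescence as ΔF/F, and averaging over the
event's frames; aligned, peak-normalized profiles are averaged across events
and fit with a sum of three Gaussians, from which the FWHM is read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist

from .traces import moving_average, rolling_percentile_baseline

__all__ = [
    "project_mask_to_line",
    "EventCall",
    "classify_event",
    "EventProfile",
    "event_spatial_profile",
    "fwhm_of_curve",
    "event_rate_by_stimulus",
    "dunns_test",
]

BASELINE_WINDOW_S = 45.0
TEMPORAL_SMOOTH_S = 4.0
SPATIAL_SMOOTH_UM = 2.0
PROXIMAL_FRACTION = 0.2
FIT_RESOLUTION_UM = 0.5


def project_mask_to_line(
    movie: np.ndarray,
    mask_um: np.ndarray,
    line_um: np.ndarray,
    um_per_px: float,
    frame_rate: float,
    baseline_window_s: float = BASELINE_WINDOW_S,
    temporal_smooth_s: float = TEMPORAL_SMOOTH_S,
    spatial_smooth_um: float = SPATIAL_SMOOTH_UM,
    normalize: bool = True,
    transform: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Project a branch movie onto the 1-px line ROI.

    Each mask pixel is assigned to its nearest line pixel (Euclidean; ties go
    to the lowest line-pixel index) and averaged per frame, yielding a
    space–time array (geodesic bins × frames). The per-bin trace is smoothed
    with a 4 s moving average, converted to ΔF/F against a 45 s rolling
    10th-percentile baseline, normalized to its s.d. over time (when
    ``normalize``), and smoothed across space with a 2 µm moving average.
    With ``transform=False`` the raw per-bin means are returned untouched
    (no smoothing, ΔF/F or normalization).

    Returns ``(profile, geodesic_um)``.
    """
    movie = np.asarray(movie, dtype=float)
    mask_um = np.atleast_2d(np.asarray(mask_um, dtype=float))
    line_um = np.atleast_2d(np.asarray(line_um, dtype=float))
    if mask_um.size == 0 or line_um.size == 0:
        raise ValueError("mask and line ROIs must be non-empty")
    # nearest line pixel per mask pixel; argmin returns the first (lowest
    # index) minimum, the documented tie-break
    assign = np.argmin(cdist(mask_um, line_um), axis=1)
    mask_px = np.round(mask_um / um_per_px).astype(int)  # (x, y) -> cols, rows
    vals = movie[:, mask_px[:, 1], mask_px[:, 0]]  # frames × mask pixels
    n_bins = line_um.shape[0]
    prof = np.zeros((n_bins, movie.shape[0]))
    counts = np.bincount(assign, minlength=n_bins).astype(float)
    for b in range(n_bins):
        sel = assign == b
        if sel.any():
            prof[b] = vals[:, sel].mean(axis=1)
    steps = np.linalg.norm(np.diff(line_um, axis=0), axis=1)
    geodesic = np.concatenate([[0.0], np.cumsum(steps)])
    if not transform:
        prof[counts == 0] = np.nan
        return prof, geodesic
    w_t = max(1, int(round(temporal_smooth_s * frame_rate)))
    prof = moving_average(prof, w_t, axis=1)
    f0 = rolling_percentile_baseline(
        prof, int(round(baseline_window_s * frame_rate)), 10.0
    )
    f0 = np.where(np.abs(f0) < 1e-12, 1.0, f0)
    prof = (prof - f0) / f0
    if normalize:
        # one scalar for the whole space-time profile: a per-bin s.d. would
        # rescale each geodesic bin by its local event density and distort
        # every event's spatial shape
        sd = prof.std()
        if sd > 0:
            prof = prof / sd
    w_s = max(1, int(round(spatial_smooth_um / um_per_px)))
    prof = moving_average(prof, w_s, axis=0)
    prof[counts == 0] = np.nan
    return prof, geodesic


@dataclass
class EventCall:
    event_class: str  # local | global | single-spine | none
    active_spines: np.ndarray
    active_interval_um: tuple[float, float] | None
    proximal_quiet: bool


def classify_event(
    spine_active: np.ndarray,
    branch_active: np.ndarray,
    geodesic_um: np.ndarray,
    spine_positions_um: np.ndarray,
    proximal_fraction: float = PROXIMAL_FRACTION,
) -> EventCall:
    """Classify one candidate event from simultaneous activity flags.

    * local: ≥2 active spines, the branch interval between them active, and
      the proximal end (nearest ``proximal_fraction`` of geodesic length)
      quiet;
    * global: the entire branch active, or a multi-spine event whose activity
      reaches the proximal end (spread beyond the local criteria);
    * single-spine: exactly one active spine without qualifying branch
      activity; * none: otherwise.
    """
    spine_active = np.asarray(spine_active, dtype=bool)
    branch_active = np.asarray(branch_active, dtype=bool)
    geodesic_um = np.asarray(geodesic_um, dtype=float)
    spine_positions_um = np.asarray(spine_positions_um, dtype=float)
    total = geodesic_um[-1]
    proximal = geodesic_um <= proximal_fraction * total
    proximal_quiet = not branch_active[proximal].any()

    if branch_active.all():
        return EventCall("global", np.flatnonzero(spine_active), (0.0, total), False)

    act = np.flatnonzero(spine_active)
    if act.size >= 2:
        lo = spine_positions_um[act].min()
        hi = spine_positions_um[act].max()
        between = (geodesic_um >= lo) & (geodesic_um <= hi)
        if branch_active[between].all():
            if proximal_quiet:
                return EventCall("local", act, (float(lo), float(hi)), True)
            return EventCall("global", act, (float(lo), float(hi)), False)
    if act.size == 1:
        return EventCall("single-spine", act, None, proximal_quiet)
    return EventCall("none", act, None, proximal_quiet)


@dataclass
class EventProfile:
    """Average aligned spatial profile of local events with its Gaussian fit."""

    offset_um: np.ndarray  # distance from the aligned peak
    mean_profile: np.ndarray  # unit peak
    fit_profile: np.ndarray
    fit_params: np.ndarray | None  # 3 × (amp, mu, sigma), flattened
    fwhm_um: float
    fit_converged: bool
    n_events: int


def _three_gaussians(x, a1, m1, s1, a2, m2, s2, a3, m3, s3):
    return (
        a1 * np.exp(-((x - m1) ** 2) / (2 * s1**2))
        + a2 * np.exp(-((x - m2) ** 2) / (2 * s2**2))
        + a3 * np.exp(-((x - m3) ** 2) / (2 * s3**2))
    )


def fwhm_of_curve(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum of a sampled curve, by linear interpolation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    i_pk = int(np.nanargmax(y))
    half = y[i_pk] / 2.0
    left = right = None
    for i in range(i_pk, 0, -1):
        if y[i - 1] <= half <= y[i]:
            left = np.interp(half, [y[i - 1], y[i]], [x[i - 1], x[i]])
            break
    for i in range(i_pk, len(y) - 1):
        if y[i + 1] <= half <= y[i]:
            right = np.interp(half, [y[i + 1], y[i]], [x[i + 1], x[i]])
            break
    if left is None or right is None:
        return float("nan")
    return float(right - left)


def event_spatial_profile(
    event_profiles: list[tuple[np.ndarray, np.ndarray]],
    resolution_um: float = FIT_RESOLUTION_UM,
) -> EventProfile:
    """Average aligned event profiles and fit a sum of three Gaussians.

    ``event_profiles`` is a list of ``(geodesic_um, profile)`` pairs, one per
    event (the profile already averaged over the event's frames). Profiles are
    aligned to their spatial peaks, normalized to unit peak, resampled to a
    common 0.5 µm grid and averaged; the FWHM is read from the fitted curve,
    falling back to the empirical profile (flagged) if the fit fails.
    """
    if not event_profiles:
        raise ValueError("need at least one event")
    half_spans = []
    aligned = []
    for g, p in event_profiles:
        g = np.asarray(g, dtype=float)
        p = np.asarray(p, dtype=float)
        fin = np.isfinite(p)
        g, p = g[fin], p[fin]
        pk = int(np.argmax(p))
        peak = p[pk]
        if peak <= 0:
            continue
        aligned.append((g - g[pk], p / peak))
        half_spans.append(min(g[pk] - g[0], g[-1] - g[pk]))
    if not aligned:
        raise ValueError("no event with a positive peak")
    span = max(half_spans)
    grid = np.arange(-span, span + resolution_um / 2, resolution_um)
    stack = np.full((len(aligned), grid.size), np.nan)
    for i, (g, p) in enumerate(aligned):
        inside = (grid >= g[0]) & (grid <= g[-1])
        stack[i, inside] = np.interp(grid[inside], g, p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_prof = np.nanmean(stack, axis=0)
    fin = np.isfinite(mean_prof)
    grid, mean_prof = grid[fin], mean_prof[fin]
    mean_prof = mean_prof / mean_prof.max()

    p0 = [1.0, 0.0, 2.0, 0.3, -5.0, 2.0, 0.3, 5.0, 2.0]
    lo = [0, grid[0], 0.1] * 3
    hi = [2.0, grid[-1], span] * 3
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params, _ = curve_fit(
                _three_gaussians, grid, mean_prof, p0=p0,
                bounds=(lo, hi), maxfev=500,
            )
        fit = _three_gaussians(grid, *params)
    except (RuntimeError, ValueError):
        converged = False
        params = None
        fit = mean_prof
    fine = np.arange(grid[0], grid[-1], 0.01)
    curve = _three_gaussians(fine, *params) if converged else np.interp(fine, grid, mean_prof)
    fwhm = fwhm_of_curve(fine, curve)
    return EventProfile(grid, mean_prof, fit, params, fwhm, converged, len(aligned))


def event_rate_by_stimulus(
    event_table: pd.DataFrame,
    trial_table: pd.DataFrame,
    trial_duration_s: float | None = None,
) -> dict:
    """Local-event rates per stimulus type with omnibus and post hoc tests.

    ``event_table`` has one row per (branch_id, trial) with an event count;
    ``trial_table`` one row per trial with a ``stimulus`` column. Rates are
    events per trial (and per minute when ``trial_duration_s`` is given),
    compared across stimulus types with a Kruskal–Wallis test over per-branch
    rates, followed by Dunn's pairwise post hoc test.
    """
    merged = event_table.merge(trial_table[["trial", "stimulus"]], on="trial")
    empty = set(trial_table["stimulus"].unique()) - set(merged["stimulus"].unique())
    if empty:
        warnings.warn(f"stimulus type(s) without trials excluded: {sorted(empty)}")
    rates = (
        merged.groupby(["branch_id", "stimulus"])["n_events"].mean().rename("per_trial")
        .reset_index()
    )
    if trial_duration_s:
        rates["per_minute"] = rates["per_trial"] * 60.0 / trial_duration_s
    groups = [g["per_trial"].to_numpy() for _, g in rates.groupby("stimulus")]
    if len(groups) < 2:
        raise ValueError("need >=2 stimulus types with trials")
    if np.ptp(np.concatenate(groups)) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    dunn = dunns_test(
        {s: g["per_trial"].to_numpy() for s, g in rates.groupby("stimulus")}
    )
    return {"rates": rates, "H": float(h), "p": float(p), "dunn": dunn}


def dunns_test(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on mean ranks with tie correction (unadjusted p)."""
    names = list(samples)
    values = np.concatenate([samples[k] for k in names])
    labels = np.concatenate([[k] * len(samples[k]) for k in names])
    ranks = stats.rankdata(values)
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            ra = ranks[labels == a].mean()
            rb = ranks[labels == b].mean()
            na, nb = (labels == a).sum(), (labels == b).sum()
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
            z = (ra - rb) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((a, b, z, p))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
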