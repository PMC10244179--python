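"""Reverse-correlation receptive-field mapping and retinotopic surface fitting.

Receptive fields are estimated from deconvolved event traces by collecting the
sparse-noise stimuli preceding each event in a 2 s window, weighting them by
event size, and Z-scoring the triggered average over all stimulus-frame ×
grid-position combinations (ON and OFF polarities separately). Included
neurons (max Z ≥ 5 in either polarity) seed a locally weighted linear (LOWESS)
surface of azimuth and elevation over the field of view, which interpolates a
retinotopic preference at every ROI position. ROIs within 75 µm of the area
border are excluded from responder analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.spatial import Delaunay
from shapely.geometry import LineString, Point

from .traces import deconvolve_trace, denoise_events  # re-exported pipeline steps

__all__ = [
    "deconvolve_trace",
    "denoise_events",
    "RFMap",
    "map_receptive_field",
    "RetinotopicMap",
    "fit_smooth_map",
    "assign_area_and_border",
]

Z_INCLUSION = 5.0  # max-Z threshold for photostimulation-experiment maps
PEAK_WINDOW_S = 0.6
TRIGGER_WINDOW_S = 2.0
BORDER_EXCLUSION_UM = 75.0


@dataclass
class RFMap:
    """ON/OFF Z-score maps and the derived retinotopic preference of one ROI."""

    z_on: np.ndarray  # lags × rows × cols
    z_off: np.ndarray
    max_z_on: float
    max_z_off: float
    included: bool
    peak_row_on: float | None = None
    peak_col_on: float | None = None
    peak_row_off: float | None = None
    peak_col_off: float | None = None
    preferred_azimuth_deg: float | None = None
    preferred_elevation_deg: float | None = None


def _polarity_map(events, stim, window_f, median_size):
    """Event-weighted triggered stimulus ensemble for one polarity."""
    eta = np.zeros((window_f,) + stim.shape[1:])
    total = 0.0
    for t in np.flatnonzero(events > 0):
        a = events[t]
        lo = max(0, t - window_f)
        seg = stim[lo:t][::-1]  # lag 0 = frame immediately preceding the event
        eta[: seg.shape[0]] += a * seg
        total += a
    if total > 0:
        eta /= total
    mu, sd = eta.mean(), eta.std()
    z = (eta - mu) / sd if sd > 0 else np.zeros_like(eta)
    if median_size and median_size > 1:
        z = median_filter(z, size=(1, median_size, median_size))
    return z


def map_receptive_field(
    events: np.ndarray,
    stimulus: np.ndarray,
    frame_rate: float,
    window_s: float = TRIGGER_WINDOW_S,
    peak_window_s: float = PEAK_WINDOW_S,
    z_threshold: float = Z_INCLUSION,
    median_size: int | None = 3,
    col_azimuth_deg: np.ndarray | None = None,
    row_elevation_deg: np.ndarray | None = None,
) -> RFMap:
    """Reverse-correlation RF map from a denoised event trace.

    ``stimulus`` is a boolean array (frames × rows × cols × 2) marking sparse
    noise occupancy; the last axis is (ON, OFF). The preferred location is the
    maximum-Z grid position within a 600 ms window centred on the peak of the
    event-triggered average over time; when both polarities pass threshold the
    preference is their max-Z-weighted average. ``col_azimuth_deg`` /
    ``row_elevation_deg`` map grid indices to visual degrees (default:
    index itself).
    """
    events = np.asarray(events, dtype=float)
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.ndim != 4 or stimulus.shape[3] != 2:
        raise ValueError("stimulus must be frames × rows × cols × 2")
    if stimulus.shape[1] == 0 or stimulus.shape[2] == 0:
        raise ValueError("stimulus grid is empty")
    n_rows, n_cols = stimulus.shape[1:3]
    if col_azimuth_deg is None:
        col_azimuth_deg = np.arange(n_cols, dtype=float)
    if row_elevation_deg is None:
        row_elevation_deg = np.arange(n_rows, dtype=float)

    if not np.any(events > 0):
        z0 = np.zeros((1, n_rows, n_cols))
        return RFMap(z0, z0, 0.0, 0.0, included=False)

    window_f = max(1, int(np.ceil(window_s * frame_rate)))
    peak_f = max(1, int(np.ceil(peak_window_s * frame_rate)))

    out: dict[str, tuple[np.ndarray, float, float, float]] = {}
    for pi, pol in enumerate(("on", "off")):
        z = _polarity_map(events, stimulus[..., pi], window_f, median_size)
        # temporal peak of the triggered average, then a centred 600 ms window
        t_peak = int(np.argmax(z.max(axis=(1, 2))))
        half = peak_f // 2
        lo = max(0, t_peak - half)
        hi = min(z.shape[0], lo + peak_f)
        win = z[lo:hi].max(axis=0)
        r, c = np.unravel_index(np.argmax(win), win.shape)
        out[pol] = (z, float(win[r, c]), float(r), float(c))

    z_on, mz_on, r_on, c_on = out["on"]
    z_off, mz_off, r_off, c_off = out["off"]
    included = (mz_on >= z_threshold) or (mz_off >= z_threshold)
    rf = RFMap(z_on, z_off, mz_on, mz_off, included,
               r_on, c_on, r_off, c_off)
    if included:
        if mz_on >= z_threshold and mz_off >= z_threshold:
            w_on, w_off = mz_on, mz_off
        elif mz_on >= z_threshold:
            w_on, w_off = 1.0, 0.0
        else:
            w_on, w_off = 0.0, 1.0
        wsum = w_on + w_off
        row = (w_on * r_on + w_off * r_off) / wsum
        col = (w_on * c_on + w_off * c_off) / wsum
        rf.preferred_azimuth_deg = float(np.interp(col, np.arange(n_cols), col_azimuth_deg))
        rf.preferred_elevation_deg = float(np.interp(row, np.arange(n_rows), row_elevation_deg))
    return rf


# ---------------------------------------------------------------------------
# LOWESS retinotopic surface
# ---------------------------------------------------------------------------


class _Lowess2D:
    """Locally weighted linear surface with tricube weights and bisquare
    robustness reweighting (2 iterations)."""

    def __init__(self, xy: np.ndarray, z: np.ndarray, span_frac: float,
                 robust_iter: int = 2):
        self.xy = np.asarray(xy, dtype=float)
        self.z = np.asarray(z, dtype=float)
        self.k = max(4, int(np.ceil(span_frac * len(self.z))))
        self.rw = np.ones(len(self.z))
        for _ in range(robust_iter):
            resid = self.z - self(self.xy)
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            u = resid / (6.0 * s)
            self.rw = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)

    def __call__(self, q: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(np.asarray(q, dtype=float))
        out = np.empty(len(q))
        for i, p in enumerate(q):
            d = np.hypot(self.xy[:, 0] - p[0], self.xy[:, 1] - p[1])
            idx = np.argsort(d)[: self.k]
            dmax = d[idx].max()
            w = (1 - (d[idx] / dmax) ** 3) ** 3 if dmax > 0 else np.ones(idx.size)
            w = w * self.rw[idx]
            if w.sum() <= 0:
                w = np.ones(idx.size)
            A = np.column_stack(
                [np.ones(idx.size), self.xy[idx, 0] - p[0], self.xy[idx, 1] - p[1]]
            )
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(A * sw[:, None], self.z[idx] * sw, rcond=None)
            out[i] = coef[0]
        return out


@dataclass
class RetinotopicMap:
    """Smooth azimuth/elevation surfaces over the FOV plus per-ROI estimates."""

    roi_positions_um: np.ndarray
    azimuth_deg: np.ndarray
    elevation_deg: np.ndarray
    extrapolated: np.ndarray  # per-ROI flag: outside the fitted hull
    _az_fit: _Lowess2D = field(repr=False, default=None)
    _el_fit: _Lowess2D = field(repr=False, default=None)
    _hull: Delaunay = field(repr=False, default=None)

    def interpolate(self, positions_um: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Azimuth, elevation and an extrapolation flag at arbitrary positions."""
        q = np.atleast_2d(np.asarray(positions_um, dtype=float))
        outside = self._hull.find_simplex(q) < 0
        return self._az_fit(q), self._el_fit(q), outside


def fit_smooth_map(
    roi_positions_um: np.ndarray,
    azimuth_deg: np.ndarray,
    elevation_deg: np.ndarray,
    span_frac: float = 0.2,
) -> RetinotopicMap:
    """Fit LOWESS surfaces (linear, ~20% span, bisquare-robust) to preferences.

    Requires at least 10 included ROIs. Queries outside the convex hull of the
    fitted points are served by the nearest local fit and flagged.
    """
    xy = np.atleast_2d(np.asarray(roi_positions_um, dtype=float))
    az = np.asarray(azimuth_deg, dtype=float)
    el = np.asarray(elevation_deg, dtype=float)
    if len(xy) < 10:
        raise ValueError("need at least 10 included ROIs to fit a surface")
    az_fit = _Lowess2D(xy, az, span_frac)
    el_fit = _Lowess2D(xy, el, span_frac)
    hull = Delaunay(xy)
    return RetinotopicMap(
        roi_positions_um=xy,
        azimuth_deg=az_fit(xy),
        elevation_deg=el_fit(xy),
        extrapolated=np.zeros(len(xy), dtype=bool),
        _az_fit=az_fit,
        _el_fit=el_fit,
        _hull=hull,
    )


def assign_area_and_border(
    roi_positions_um: np.ndarray,
    border_polyline_um: np.ndarray,
    exclusion_um: float = BORDER_EXCLUSION_UM,
) -> pd.DataFrame:
    """Signed distance to the area border and the 75 µm exclusion flag.

    The side of the (possibly curved) border polyline determines the area
    ("A1" on the left of the polyline direction, "A2" on the right); ROIs
    strictly within ``exclusion_um`` of the border are flagged excluded, and
    an ROI exactly on the border is assigned area "border".
    """
    poly = np.atleast_2d(np.asarray(border_polyline_um, dtype=float))
    if len(poly) < 2 or LineString(poly).length == 0:
        raise ValueError("degenerate border polyline")
    line = LineString(poly)
    pos = np.atleast_2d(np.asarray(roi_positions_um, dtype=float))
    rows = []
    for p in pos:
        pt = Point(p)
        d = line.distance(pt)
        # side via cross product on the nearest segment
        s = line.project(pt)
        a = np.asarray(line.interpolate(max(0.0, s - 1e-6)).coords[0])
        b = np.asarray(line.interpolate(min(line.length, s + 1e-6)).coords[0])
        tangent = b - a
        rel = p - a
        # positive cross product = point on the left of the polyline direction
        normal_side = tangent[0] * rel[1] - tangent[1] * rel[0]
        signed = d * np.sign(normal_side) if normal_side != 0 else 0.0
        if signed == 0.0 and d == 0.0:
            area = "border"
        else:
            area = "A1" if signed > 0 else "A2"
        rows.append((signed, area, abs(signed) < exclusion_um or d == 0.0))
    return pd.DataFrame(rows, columns=["signed_distance_um", "area", "excluded"])
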