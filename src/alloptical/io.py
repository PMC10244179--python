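"""Serialization of sessions and results (HDF5 traces + CSV tables)."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synth import GeneratorConfig, PopulationSession, StimGroup

__all__ = ["write_session", "read_session", "write_config", "read_config"]

_TRIAL_COLS = ["trial", "onset_frame", "stim_end_frame", "type", "group_id",
               "orientation_deg", "run_speed_cm_s"]
_ROI_COLS = ["roi_id", "x_um", "y_um", "plane", "area",
             "true_azimuth_deg", "true_elevation_deg"]


def write_session(session: PopulationSession, out_dir: str | Path) -> Path:
    """Write a session as traces.h5 plus CSV tables and a config YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / "traces.h5", "w") as f:
        d = f.create_dataset("traces", data=session.traces)
        d.attrs["frame_rate"] = session.frame_rate
    session.roi_meta.to_csv(out / "roi_meta.csv", index=False)
    session.trials.to_csv(out / "trials.csv", index=False)
    rows = []
    for g in session.groups:
        for rid, pos in zip(g.target_roi_ids, g.target_positions_um):
            rows.append((g.group_id, int(rid), pos[0], pos[1], pos[2]))
    pd.DataFrame(
        rows, columns=["group_id", "target_roi_id", "x_um", "y_um", "z_um"]
    ).to_csv(out / "groups.csv", index=False)
    session.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    write_config(session.config, out / "config.yaml")
    return out


def read_session(in_dir: str | Path) -> PopulationSession:
    """Read a session written by :func:`write_session`.

    Raises a schema error naming any missing file, dataset or column. ROIs
    whose traces contain NaN are loaded but flagged in ``roi_meta['has_nan']``.
    """
    src = Path(in_dir)
    missing = [
        n for n in ("traces.h5", "roi_meta.csv", "trials.csv", "groups.csv",
                    "ground_truth.csv")
        if not (src / n).exists()
    ]
    if missing:
        raise FileNotFoundError(f"session at {src} is missing: {', '.join(missing)}")
    with h5py.File(src / "traces.h5", "r") as f:
        if "traces" not in f:
            raise KeyError("traces.h5 lacks dataset 'traces'")
        traces = f["traces"][:]
        frame_rate = float(f["traces"].attrs["frame_rate"])
    roi_meta = pd.read_csv(src / "roi_meta.csv")
    trials = pd.read_csv(src / "trials.csv")
    for name, df, cols in (
        ("roi_meta.csv", roi_meta, _ROI_COLS),
        ("trials.csv", trials, _TRIAL_COLS),
    ):
        lack = [c for c in cols if c not in df.columns]
        if lack:
            raise KeyError(f"{name} is missing columns: {', '.join(lack)}")
    nan_rois = np.flatnonzero(np.isnan(traces).any(axis=1))
    roi_meta["has_nan"] = False
    if nan_rois.size:
        warnings.warn(f"{nan_rois.size} ROI trace(s) contain NaN; flagged")
        roi_meta.loc[roi_meta.index[nan_rois], "has_nan"] = True
    gdf = pd.read_csv(src / "groups.csv")
    groups = [
        StimGroup(
            int(gid),
            sub["target_roi_id"].to_numpy(int),
            sub[["x_um", "y_um", "z_um"]].to_numpy(float),
        )
        for gid, sub in gdf.groupby("group_id")
    ]
    ground_truth = pd.read_csv(src / "ground_truth.csv")
    config = read_config(src / "config.yaml") if (src / "config.yaml").exists() else GeneratorConfig()
    return PopulationSession(traces, frame_rate, roi_meta, trials, groups,
                             ground_truth, config)


def write_config(config: GeneratorConfig, path: str | Path) -> None:
    d = {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in config.__dict__.items()}
    path = Path(path)
    with open(path, "w") as f:
        if path.suffix == ".json":
            json.dump(d, f, indent=2)
        else:
            yaml.safe_dump(d, f)


def read_config(path: str | Path) -> GeneratorConfig:
    path = Path(path)
    with open(path) as f:
        d = json.load(f) if path.suffix == ".json" else yaml.safe_load(f)
    known = set(GeneratorConfig().__dict__)
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    for k, v in d.items():
        if isinstance(v, list):
            d[k] = tuple(v)
    return GeneratorConfig(**d)
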