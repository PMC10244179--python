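"""Session-level orchestration: responder detection and topography stages.

`run_pipeline` chains synth → responders → topography with a single global
seed; each stage draws from its own named substream so adding a stage never
perturbs another's random numbers. Every run writes a resolved copy of the
configuration and a JSON-lines log next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as session_io
from .responders import detect_responders, trial_response_matrix, FDR_LEVEL
from .synth import GeneratorConfig, PopulationSession, make_population_session
from .topography import (
    DistanceDistribution,
    average_profiles,
    centroid_displacement_test,
    retinotopic_distances,
    weighted_distance_distribution,
)
from .traces import dff

__all__ = [
    "stage_rng",
    "session_responders",
    "session_topography",
    "PipelineConfig",
    "run_pipeline",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent substream for a named pipeline stage."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


def session_responders(
    session: PopulationSession,
    fdr_level: float = FDR_LEVEL,
    fdr_method: str = "bh",
    rng: np.random.Generator | int | None = None,
    f0_stride: int | None = None,
) -> pd.DataFrame:
    """ΔF/F → per-trial R → responder table, per stimulation group.

    Returns one row per (group_id, roi_id) with p, q, sign and median effect.
    Border-zone ROIs are excluded (sign forced to "none", p/q retained).
    """
    rng = np.random.default_rng(rng)
    dff_traces = dff(session.traces, window=2000, stride=f0_stride)
    _, _, R, kept = trial_response_matrix(
        dff_traces, session.trials, session.frame_rate
    )
    ttype = kept["type"].to_numpy()
    gid = kept["group_id"].to_numpy(float)
    orient = kept["orientation_deg"].to_numpy(float)
    border = session.roi_meta["area"].to_numpy() == "border"
    out = []
    for grp in session.groups:
        sel = (ttype == "V") | ((ttype == "V+P") & (gid == grp.group_id))
        tab = detect_responders(
            R[:, sel], ttype[sel], orient[sel],
            fdr_level=fdr_level, fdr_method=fdr_method, rng=rng,
        )
        tab.insert(0, "group_id", grp.group_id)
        tab.loc[border, "sign"] = "none"
        tab["border_excluded"] = border
        out.append(tab)
    return pd.concat(out, ignore_index=True)


def session_topography(
    session: PopulationSession,
    responder_table: pd.DataFrame,
    n_null: int = 20_000,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Null-normalized distance profiles per group and sign, plus centroids.

    Preferences are the per-ROI retinotopic preferences in ``roi_meta``
    (ground truth for synthetic sessions; interpolated map values for real
    ones). Sources are the locally facilitated responders of each group; the
    readout population is the across-border area.
    """
    rng = np.random.default_rng(rng)
    meta = session.roi_meta
    prefs = meta[["true_azimuth_deg", "true_elevation_deg"]].to_numpy(float)
    area = meta["area"].to_numpy()
    distributions: list[DistanceDistribution] = []
    centroids = {"facilitated": [], "suppressed": []}
    for grp in session.groups:
        tab = responder_table[responder_table.group_id == grp.group_id]
        fac = tab.roi_id[(tab.sign == "facilitated")].to_numpy(int)
        local_fac = fac[area[fac] == "A1"]
        if local_fac.size == 0:
            continue
        src = prefs[local_fac]
        avail = prefs[area == "A2"]
        for sign in ("facilitated", "suppressed"):
            rids = tab.roi_id[(tab.sign == sign)].to_numpy(int)
            rids = rids[area[rids] == "A2"]
            if rids.size == 0:
                continue
            dist = weighted_distance_distribution(
                prefs[rids], avail, src, n_null=n_null, rng=rng,
                group_id=grp.group_id, sign=sign,
            )
            distributions.append(dist)
            centroids[sign].append(
                float(retinotopic_distances(prefs[rids], src).mean())
            )
    result = {"distributions": distributions, "centroids": centroids}
    if centroids["facilitated"] and centroids["suppressed"]:
        result["displacement"] = centroid_displacement_test(
            centroids["facilitated"], centroids["suppressed"]
        )
    fac_d = [d for d in distributions if d.sign == "facilitated"]
    sup_d = [d for d in distributions if d.sign == "suppressed"]
    if fac_d:
        result["facilitated_profile"] = average_profiles(fac_d)
    if sup_d:
        result["suppressed_profile"] = average_profiles(sup_d)
    return result


_STAGES = ("synth", "responders", "topography")


@dataclasses.dataclass
class PipelineConfig:
    """Resolved pipeline configuration: stages, parameters, seed, paths."""

    stages: tuple[str, ...] = _STAGES
    seed: int = 0
    out_dir: str = "pipeline_out"
    input_session: str | None = None  # read instead of synthesizing
    generator: GeneratorConfig = dataclasses.field(default_factory=GeneratorConfig)
    fdr_level: float = FDR_LEVEL
    fdr_method: str = "bh"
    n_null: int = 20_000
    f0_stride: int | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"generator"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        gen_known = set(GeneratorConfig().__dict__)
        gen_unknown = set(gen) - gen_known
        if gen_unknown:
            raise ValueError(
                f"unknown generator key(s): {', '.join(sorted(gen_unknown))}"
            )
        gen = {k: tuple(v) if isinstance(v, list) else v for k, v in gen.items()}
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(generator=GeneratorConfig(**gen), **d)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages, writing tables, logs and the resolved config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline_log.jsonl"
    resolved = dataclasses.asdict(config)
    resolved["generator"] = {
        k: list(v) if isinstance(v, tuple) else v
        for k, v in resolved["generator"].items()
    }
    resolved["stages"] = list(config.stages)
    with open(out / "resolved_config.json", "w") as f:
        json.dump(resolved, f, indent=2)

    session = None
    responder_table = None
    with open(log_path, "w") as log:
        for stage in config.stages:
            t0 = time.perf_counter()
            record = {"stage": stage, "seed": config.seed}
            try:
                if stage == "synth":
                    gen = dataclasses.replace(config.generator, seed=config.seed)
                    session = make_population_session(gen)
                    session_io.write_session(session, out / "session")
                    record["n_rois"] = session.n_rois
                    record["n_trials"] = len(session.trials)
                elif stage == "responders":
                    if session is None:
                        if config.input_session is None:
                            raise ValueError("responders stage needs a session")
                        session = session_io.read_session(config.input_session)
                    responder_table = session_responders(
                        session,
                        fdr_level=config.fdr_level,
                        fdr_method=config.fdr_method,
                        rng=stage_rng(config.seed, "responders"),
                        f0_stride=config.f0_stride,
                    )
                    responder_table.to_csv(out / "responders.csv", index=False)
                    record["n_responders"] = int((responder_table.sign != "none").sum())
                elif stage == "topography":
                    if responder_table is None:
                        raise ValueError("topography stage needs responder output")
                    topo = session_topography(
                        session, responder_table, n_null=config.n_null,
                        rng=stage_rng(config.seed, "topography"),
                    )
                    profiles = []
                    for d in topo["distributions"]:
                        profiles.append(
                            pd.DataFrame(
                                {
                                    "group_id": d.group_id,
                                    "sign": d.sign,
                                    "bin_centre_deg": d.bin_centres_deg,
                                    "responder_prob": d.responder_prob,
                                    "null_prob": d.null_prob,
                                    "weighted": d.weighted,
                                    "smoothed": d.smoothed,
                                }
                            )
                        )
                    if profiles:
                        pd.concat(profiles, ignore_index=True).to_csv(
                            out / "distance_profiles.csv", index=False
                        )
                    record["n_distributions"] = len(topo["distributions"])
                    if "displacement" in topo:
                        record["displacement_p"] = topo["displacement"].p_value
                else:
                    raise ValueError(f"unknown stage {stage!r}")
                record["status"] = "ok"
            except Exception as exc:  # noqa: BLE001 - logged and re-raised
                record["status"] = "error"
                record["error"] = f"{type(exc).__name__}: {exc}"
                record["wall_s"] = round(time.perf_counter() - t0, 3)
                log.write(json.dumps(record) + "\n")
                raise
            record["wall_s"] = round(time.perf_counter() - t0, 3)
            log.write(json.dumps(record) + "\n")
    return out
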