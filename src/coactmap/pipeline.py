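"""End-to-end study pipeline: load (or simulated) trials -> montages ->
RMS maps -> CAN under the three schemes -> spatial analysis -> descriptive
tables.

The pipeline is fully deterministic given a dataset and a configuration;
all randomness lives in the synthetic-data generator.  Reported summary
values are rounded to two decimals with round-half-up, the convention that
reconciles per-cell and pooled descriptive means.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amplitude import AmplitudeMap, rms_peak_epoch, rms_whole
from .can import CanMap, bip_can, cs_can, ov_can
from .grids import Direction, Effort, Knee, Montage, Muscle, TrialMeta
from .montage import monopolar_to_single_differential, simulate_bipolar
from .recording import EmgRecording
from .spatial import AponeurosisMask, analyze_can_map

logger = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Two-decimal reporting convention: 0.505 -> 0.51, never banker's
    rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pool_conditions(cells: list[float]) -> float:
    """Equal-weight arithmetic mean of condition-cell means, rounded to two
    decimals (round-half-up) for reporting."""
    if len(cells) == 0:
        raise ValueError("cannot pool an empty list of cells")
    return round_half_up(float(np.mean(cells)), 2)


@dataclass
class PipelineConfig:
    """Every decision parameter of one pipeline run."""

    dataset_dir: str
    out_dir: str
    sd_axis: str = "auto"
    threshold_frac: float = 0.70
    window_ms: float = 500.0
    #: aponeurosis bounds (proximal_row, distal_row) on the GM
    #: single-differential lattice; None = full lattice
    apo_rows: tuple[int, int] | None = None
    bipolar_groups: tuple | None = None  # None = default placement
    write_maps: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StudyResult:
    """Per-trial results plus pooled descriptive tables."""

    per_trial: pd.DataFrame  # long format: one row per subject/condition/scheme
    can_table: pd.DataFrame  # Table-2 style descriptive summary
    centroid_table: pd.DataFrame  # Table-3 style centroid summary
    segmentation: pd.DataFrame  # per subject/condition/scheme segmentation
    log: dict


def _amplitude(rec: EmgRecording, window_ms: float) -> AmplitudeMap:
    if rec.meta.effort is Effort.MAX_100:
        return rms_peak_epoch(rec, window_ms)
    return rms_whole(rec)


def _load_dataset(dataset_dir: Path) -> dict:
    """Map (subject, muscle, knee, effort, direction) -> recording path."""
    trials: dict = {}
    for sidecar in sorted(dataset_dir.glob("*.json")):
        if sidecar.name == "ground_truth.json" or sidecar.stem.endswith("_torque"):
            continue
        with open(sidecar) as fh:
            meta = json.load(fh).get("meta", {})
        key = (
            meta.get("subject_id"),
            meta.get("muscle"),
            meta.get("knee"),
            meta.get("effort"),
            meta.get("direction"),
        )
        trials[key] = sidecar.with_suffix("")
    return trials


def run_pipeline(config: PipelineConfig) -> StudyResult:
    """Run the full analysis over a dataset directory.

    For every subject, detection system, knee position and effort level the
    antagonist (dorsiflexion) trial is normalized by the knee-matched
    agonist-MVC (plantar-flexion, maximal) trial of the same system under
    the channel-specific and overall schemes; for the GM grid a simulated
    bipolar channel is analysed as well, and the channel-specific and
    overall CAN maps are segmented to locate the antagonist hotspot.

    Writes ``can_table.csv``, ``centroid_table.csv``, per-trial maps and a
    run log to ``config.out_dir``.  Deterministic: rerunning with the same
    dataset and configuration reproduces the outputs byte for byte.
    """
    dataset_dir = Path(config.dataset_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials = _load_dataset(dataset_dir)
    if not trials:
        raise ValueError(f"no trials found in dataset directory {dataset_dir}")

    subjects = sorted({k[0] for k in trials})
    rows: list[dict] = []
    seg_rows: list[dict] = []
    invalidation_counts: dict = {}
    maps_dir = out_dir / "maps"
    if config.write_maps:
        maps_dir.mkdir(exist_ok=True)

    for subject in subjects:
        for muscle in Muscle:
            for knee in Knee:
                mvc_key = (
                    subject, muscle.value, knee.value,
                    Effort.MAX_100.value, Direction.PLANTARFLEXION.value,
                )
                if mvc_key not in trials:
                    logger.warning(
                        "subject %s: missing agonist-MVC cell %s; conditions "
                        "excluded from pooled rows", subject, mvc_key[1:],
                    )
                    continue
                mvc_rec = EmgRecording.load(trials[mvc_key])
                mvc_sd = monopolar_to_single_differential(mvc_rec, config.sd_axis)
                mvc_amp = rms_peak_epoch(mvc_sd, config.window_ms)
                if muscle is Muscle.GM:
                    mvc_bip = simulate_bipolar(
                        mvc_rec, *(config.bipolar_groups or (None, None))
                    )
                    mvc_bip_amp = rms_peak_epoch(mvc_bip, config.window_ms)
                    apo = (
                        AponeurosisMask.from_rows(mvc_sd.grid, *config.apo_rows)
                        if config.apo_rows is not None
                        else AponeurosisMask.full(mvc_sd.grid)
                    )

                for effort in Effort:
                    key = (
                        subject, muscle.value, knee.value,
                        effort.value, Direction.DORSIFLEXION.value,
                    )
                    if key not in trials:
                        logger.warning(
                            "subject %s: missing antagonist cell %s", subject, key[1:]
                        )
                        continue
                    ant_rec = EmgRecording.load(trials[key])
                    ant_sd = monopolar_to_single_differential(ant_rec, config.sd_axis)
                    ant_amp = _amplitude(ant_sd, config.window_ms)
                    invalidation_counts[str(key)] = int((~ant_sd.valid).sum())

                    cmap_cs = cs_can(ant_amp, mvc_amp)
                    cmap_ov = ov_can(ant_amp, mvc_amp)
                    for cmap in (cmap_cs, cmap_ov):
                        rows.append(
                            {
                                "subject": subject,
                                "muscle": muscle.value,
                                "knee": knee.value,
                                "effort": effort.value,
                                "scheme": cmap.scheme,
                                "can": cmap.mean_valid(),
                                "n_channels": int(cmap.valid.sum()),
                            }
                        )
                        if config.write_maps:
                            _write_map(maps_dir, subject, cmap)
                        if muscle is Muscle.GM:
                            seg = analyze_can_map(cmap, apo, config.threshold_frac)
                            seg_rows.append(
                                {
                                    "subject": subject,
                                    "knee": knee.value,
                                    "effort": effort.value,
                                    "scheme": cmap.scheme,
                                    "n_segmented": seg.n_segmented,
                                    "relative_size": seg.relative_size,
                                    "centroid_row": seg.centroid_raw[0],
                                    "centroid_col": seg.centroid_raw[1],
                                    "centroid_pd": seg.centroid_norm[0],
                                    "centroid_ml": seg.centroid_norm[1],
                                }
                            )
                    if muscle is Muscle.GM:
                        ant_bip = simulate_bipolar(
                            ant_rec, *(config.bipolar_groups or (None, None))
                        )
                        ant_bip_amp = _amplitude(ant_bip, config.window_ms)
                        cmap_bip = bip_can(ant_bip_amp, mvc_bip_amp)
                        rows.append(
                            {
                                "subject": subject,
                                "muscle": muscle.value,
                                "knee": knee.value,
                                "effort": effort.value,
                                "scheme": "bip",
                                "can": cmap_bip.mean_valid(),
                                "n_channels": 1,
                            }
                        )

    if not rows:
        raise ValueError("dataset yielded no analysable condition cells")
    per_trial = pd.DataFrame(rows).sort_values(
        ["subject", "muscle", "knee", "effort", "scheme"]
    ).reset_index(drop=True)
    segmentation = pd.DataFrame(seg_rows)

    can_table = _summarize_can(per_trial)
    centroid_table = _summarize_centroids(segmentation)

    log = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_subjects": len(subjects),
        "n_trials": len(trials),
        "invalid_channel_counts": invalidation_counts,
    }
    can_table.to_csv(out_dir / "can_table.csv", index=False)
    centroid_table.to_csv(out_dir / "centroid_table.csv", index=False)
    per_trial.to_csv(out_dir / "per_trial.csv", index=False)
    if len(segmentation):
        segmentation.to_csv(out_dir / "segmentation.csv", index=False)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)

    return StudyResult(
        per_trial=per_trial,
        can_table=can_table,
        centroid_table=centroid_table,
        segmentation=segmentation,
        log=log,
    )


def _write_map(maps_dir: Path, subject: str, cmap: CanMap) -> None:
    rows = []
    for r in range(cmap.grid.n_rows):
        for c in range(cmap.grid.n_cols):
            rows.append(
                {
                    "row": r,
                    "col": c,
                    "value": cmap.values[r, c],
                    "valid": bool(cmap.valid[r, c]),
                    "scheme": cmap.scheme,
                }
            )
    name = "_".join([subject, *cmap.condition, cmap.scheme])
    pd.DataFrame(rows).to_csv(maps_dir / f"{name}.csv", index=False)


def _summarize_can(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Descriptive means ± SDs across subjects per muscle/knee/effort/scheme
    (the layout of a coactivation summary table)."""
    g = per_trial.groupby(["muscle", "knee", "effort", "scheme"])["can"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out = out.rename(columns={"std": "sd", "count": "n"})
    out["sd"] = out["sd"].fillna(0.0)
    out["mean_sd"] = [
        f"{round_half_up(m):.2f} ± {round_half_up(s):.2f}"
        for m, s in zip(out["mean"], out["sd"])
    ]
    return out


def _summarize_centroids(segmentation: pd.DataFrame) -> pd.DataFrame:
    if segmentation.empty:
        return pd.DataFrame(
            columns=["axis", "knee", "effort", "scheme", "mean", "sd", "n", "mean_sd"]
        )
    frames = []
    for axis, col in (("proximal_distal", "centroid_pd"), ("medial_lateral", "centroid_ml")):
        g = segmentation.groupby(["knee", "effort", "scheme"])[col]
        t = g.agg(["mean", "std", "count"]).reset_index()
        t = t.rename(columns={"std": "sd", "count": "n"})
        t["sd"] = t["sd"].fillna(0.0)
        t.insert(0, "axis", axis)
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    out["mean_sd"] = [
        f"{round_half_up(m):.2f} ± {round_half_up(s):.2f}"
        for m, s in zip(out["mean"], out["sd"])
    ]
    return out
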