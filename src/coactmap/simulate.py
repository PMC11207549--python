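"""Seeded synthetic monopolar HD-EMG (plus ankle torque) with planted
spatial ground truth.

The signal model is amplitude-modulated colored noise: each channel carries
an independent band-limited Gaussian process scaled to the planted RMS of a
spatial activation field, optionally plus a spatially uniform shared
crosstalk process and independent white sensor noise.  Everything
downstream (RMS maps, CAN ratios, segmentation, centroids) depends only on
the per-channel RMS structure, which this model controls exactly; no
motor-unit, conduction-velocity or volume-conductor realism is attempted.

Amplitudes are specified in microvolts; recordings are stored in millivolts.
All randomness flows from explicit integer seeds, and per-trial seeds are
derived deterministically from a study master seed and the condition tuple.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .grids import Direction, Effort, ElectrodeGrid, Knee, Montage, Muscle, TrialMeta, gm_grid, so_array
from .recording import EmgRecording

UV_PER_MV = 1000.0


@dataclass(frozen=True)
class ActivationField:
    """Spatial RMS amplitude field on a lattice, in microvolts.

    Evaluates to ``base_uv + sum of Gaussian blobs`` per channel; blobs are
    ``(center_row, center_col, sigma_row, sigma_col, peak_uv)`` tuples.
    """

    base_uv: float = 0.0
    blobs: tuple = ()

    def __post_init__(self) -> None:
        if self.base_uv < 0:
            raise ValueError("base amplitude must be non-negative")
        for b in self.blobs:
            if len(b) != 5:
                raise ValueError("each blob is (c_row, c_col, s_row, s_col, peak_uv)")
            if b[2] <= 0 or b[3] <= 0 or b[4] < 0:
                raise ValueError("blob sigmas must be positive and peak non-negative")

    def evaluate(self, grid: ElectrodeGrid) -> np.ndarray:
        """Planted RMS in µV on the full lattice, shape (n_rows, n_cols)."""
        rows, cols = np.meshgrid(
            np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij"
        )
        out = np.full((grid.n_rows, grid.n_cols), float(self.base_uv))
        for cr, cc, sr, sc, peak in self.blobs:
            out += peak * np.exp(
                -0.5 * (((rows - cr) / sr) ** 2 + ((cols - cc) / sc) ** 2)
            )
        return out

    def scaled(self, k: float) -> "ActivationField":
        return ActivationField(
            base_uv=self.base_uv * k,
            blobs=tuple((cr, cc, sr, sc, p * k) for cr, cc, sr, sc, p in self.blobs),
        )

    @property
    def hotspot(self) -> tuple[float, float] | None:
        """Centre of the highest-peak blob, if any."""
        if not self.blobs:
            return None
        cr, cc, _, _, _ = max(self.blobs, key=lambda b: b[4])
        return (float(cr), float(cc))

    def to_dict(self) -> dict:
        return {"base_uv": self.base_uv, "blobs": [list(b) for b in self.blobs]}

    @classmethod
    def from_dict(cls, d: dict) -> "ActivationField":
        return cls(base_uv=float(d["base_uv"]), blobs=tuple(tuple(b) for b in d["blobs"]))


@dataclass(frozen=True)
class TrialSpec:
    """Full description of one synthetic trial."""

    meta: TrialMeta
    field: ActivationField
    grid: ElectrodeGrid | None = None
    duration_s: float = 5.0
    fs_hz: float = 2048.0
    band_hz: tuple[float, float] = (20.0, 350.0)
    noise_uv: float = 0.0
    crosstalk_uv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ValueError("band edges must satisfy 0 < low < high")
        if hi >= self.fs_hz / 2:
            raise ValueError("band upper edge must lie below the Nyquist frequency")
        if self.noise_uv < 0 or self.crosstalk_uv < 0:
            raise ValueError("noise amplitudes must be non-negative")

    def resolved_grid(self) -> ElectrodeGrid:
        if self.grid is not None:
            return self.grid
        if self.meta.muscle is Muscle.GM:
            return gm_grid()
        return so_array("medial" if self.meta.muscle is Muscle.SO_MEDIAL else "lateral")


@dataclass
class GroundTruth:
    """Planted quantities for one trial (monopolar lattice)."""

    field_rms_uv: np.ndarray  # activation field only
    total_rms_uv: np.ndarray  # sqrt(field^2 + crosstalk^2 + noise^2)
    hotspot: tuple[float, float] | None


def _unit_rms_colored(
    rng: np.random.Generator, shape: tuple, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Band-limited Gaussian noise rescaled to exactly unit RMS per row."""
    white = rng.standard_normal(shape)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    col = sps.sosfiltfilt(sos, white, axis=-1)
    rms = np.sqrt(np.mean(col**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return col / rms


def generate_trial(spec: TrialSpec) -> tuple[EmgRecording, GroundTruth]:
    """Synthesize one monopolar trial and its exact planted ground truth.

    Identical specs (including the seed) yield bit-identical recordings.
    """
    grid = spec.resolved_grid()
    n_samples = int(round(spec.duration_s * spec.fs_hz))
    n_pos = grid.n_positions
    amp_uv = spec.field.evaluate(grid).ravel()

    rng = np.random.default_rng(spec.seed)
    sig = np.zeros((n_pos, n_samples))
    if np.any(amp_uv > 0):
        base = _unit_rms_colored(rng, (n_pos, n_samples), spec.fs_hz, spec.band_hz)
        sig = amp_uv[:, None] * base
    if spec.crosstalk_uv > 0:
        shared = _unit_rms_colored(rng, (1, n_samples), spec.fs_hz, spec.band_hz)
        sig = sig + spec.crosstalk_uv * shared
    if spec.noise_uv > 0:
        sig = sig + spec.noise_uv * rng.standard_normal((n_pos, n_samples))

    valid = np.ones(n_pos, dtype=bool)
    for r, c in grid.missing:
        valid[grid.channel_index(r, c)] = False
    sig[~valid] = 0.0

    rec = EmgRecording(
        grid=grid,
        samples=(sig / UV_PER_MV).astype(np.float32),
        fs_hz=spec.fs_hz,
        montage=Montage.MONOPOLAR,
        valid=valid,
        meta=spec.meta,
        extra={"seed": int(spec.seed), "band_hz": list(spec.band_hz)},
    )
    total = np.sqrt(amp_uv**2 + spec.crosstalk_uv**2 + spec.noise_uv**2)
    total[~valid] = 0.0
    gt = GroundTruth(
        field_rms_uv=amp_uv.reshape(grid.n_rows, grid.n_cols),
        total_rms_uv=total.reshape(grid.n_rows, grid.n_cols),
        hotspot=spec.field.hotspot,
    )
    return rec, gt


def generate_torque(
    meta: TrialMeta,
    mvc_nm: float,
    seed: int,
    duration_s: float = 5.0,
    fs_hz: float = 2048.0,
    noise_frac: float = 0.01,
) -> np.ndarray:
    """Plateau ankle-torque trace in N·m.

    Maximal trials plateau at 100% of ``mvc_nm``, submaximal at 30%; additive
    Gaussian noise is clipped to the ±5%-MVC target band, so submaximal
    traces lie in [0.25, 0.35] x MVC by construction.  ``noise_frac = 0``
    gives an exactly constant plateau.
    """
    if mvc_nm <= 0:
        raise ValueError("MVC torque must be positive")
    frac = 1.0 if meta.effort is Effort.MAX_100 else 0.30
    n = int(round(duration_s * fs_hz))
    target = frac * mvc_nm
    if noise_frac == 0:
        return np.full(n, target)
    rng = np.random.default_rng(seed)
    noise = np.clip(rng.standard_normal(n) * noise_frac * mvc_nm,
                    -0.05 * mvc_nm, 0.05 * mvc_nm)
    return target + noise


# ---------------------------------------------------------------------------
# Study-level generation (factorial design)
# ---------------------------------------------------------------------------

_MUSCLES = (Muscle.GM, Muscle.SO_MEDIAL, Muscle.SO_LATERAL)
_CONDITIONS = [
    (knee, effort, direction)
    for knee in Knee
    for effort in Effort
    for direction in Direction
]


@dataclass
class StudySpec:
    """Specification of a full synthetic study.

    ``fields`` maps ``(muscle, knee, effort, direction)`` value-tuples to
    activation fields; every cell of the 2 knee x 2 effort x 2 direction
    factorial must be present for each muscle.  All subjects share the
    fields; their trials differ through subject-specific seeds.
    """

    subjects: tuple[str, ...]
    fields: dict
    master_seed: int = 0
    duration_s: float = 5.0
    fs_hz: float = 2048.0
    band_hz: tuple[float, float] = (20.0, 350.0)
    noise_uv: float = 1.0
    crosstalk_uv: float = 0.0
    mvc_nm: float = 100.0

    def validate(self) -> None:
        absent = [
            (m.value, k.value, e.value, d.value)
            for m in _MUSCLES
            for (k, e, d) in _CONDITIONS
            if (m.value, k.value, e.value, d.value) not in self.fields
        ]
        if absent:
            raise ValueError(f"study spec is missing condition cells: {absent}")


def default_study_spec(
    n_subjects: int = 1,
    alpha: float = 0.4,
    agonist_peak_uv: float = 150.0,
    agonist_base_uv: float = 20.0,
    submax_frac: float = 0.3,
    antagonist_hotspot: tuple[float, float] | None = None,
    master_seed: int = 0,
    **kwargs,
) -> StudySpec:
    """Convenience factory: antagonist fields are ``alpha`` x the agonist-MVC
    field of the same condition (so the planted CAN field is constant
    ``alpha``); submaximal agonist efforts scale the MVC field by
    ``submax_frac``.  ``antagonist_hotspot`` optionally relocates the
    antagonist blob on the GM grid instead of scaling the agonist field.
    """
    fields: dict = {}
    for muscle in _MUSCLES:
        if muscle is Muscle.GM:
            ago = ActivationField(
                base_uv=agonist_base_uv, blobs=((6.0, 2.0, 2.5, 1.5, agonist_peak_uv),)
            )
        else:
            ago = ActivationField(base_uv=agonist_base_uv + agonist_peak_uv / 3.0)
        if antagonist_hotspot is not None and muscle is Muscle.GM:
            hr, hc = antagonist_hotspot
            ant = ActivationField(
                base_uv=alpha * agonist_base_uv,
                blobs=((hr, hc, 2.0, 1.2, alpha * agonist_peak_uv),),
            )
        else:
            ant = ago.scaled(alpha)
        for knee in Knee:
            for effort in Effort:
                sub = 1.0 if effort is Effort.MAX_100 else submax_frac
                fields[(muscle.value, knee.value, effort.value, Direction.PLANTARFLEXION.value)] = ago.scaled(sub)
                fields[(muscle.value, knee.value, effort.value, Direction.DORSIFLEXION.value)] = ant.scaled(sub)
    return StudySpec(
        subjects=tuple(f"S{i + 1:02d}" for i in range(n_subjects)),
        fields=fields,
        master_seed=master_seed,
        **kwargs,
    )


def trial_seed(master_seed: int, meta: TrialMeta) -> int:
    """Deterministic per-trial seed: stable hash of the condition tuple
    folded with the master seed, kept below 2^31."""
    key = "|".join(
        [
            meta.subject_id,
            meta.muscle.value,
            meta.knee.value,
            meta.effort.value,
            meta.direction.value,
        ]
    )
    h = int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "little")
    return (int(master_seed) * 1_000_003 + h) % (2**31)


def trial_name(meta: TrialMeta) -> str:
    return "_".join(
        [meta.subject_id, meta.muscle.value, meta.knee.value, meta.effort.value, meta.direction.value]
    )


def make_study(spec: StudySpec, out_dir: str | Path) -> Path:
    """Write every trial of the factorial design to ``out_dir``.

    Per subject and detection system the eight EMG trials (2 knee x 2 effort
    x 2 direction) and their eight synchronous torque traces are written in
    the binary+sidecar format, alongside a study-level ``ground_truth.json``
    holding the planted per-channel RMS, the planted CAN field
    (antagonist ÷ agonist-MVC, channel-wise) and the planted hotspots.
    Regeneration under the same spec is byte-identical.
    """
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gt: dict = {"spec": {"master_seed": spec.master_seed, "subjects": list(spec.subjects)},
                "trials": {}, "can_fields": {}}
    for subject in spec.subjects:
        for muscle in _MUSCLES:
            for knee, effort, direction in _CONDITIONS:
                meta = TrialMeta(
                    subject_id=subject,
                    muscle=muscle,
                    knee=knee,
                    effort=effort,
                    direction=direction,
                    trial_id=trial_name(
                        TrialMeta(subject, muscle, knee, effort, direction)
                    ),
                )
                field = spec.fields[(muscle.value, knee.value, effort.value, direction.value)]
                seed = trial_seed(spec.master_seed, meta)
                tspec = TrialSpec(
                    meta=meta,
                    field=field,
                    duration_s=spec.duration_s,
                    fs_hz=spec.fs_hz,
                    band_hz=spec.band_hz,
                    noise_uv=spec.noise_uv,
                    crosstalk_uv=spec.crosstalk_uv,
                    seed=seed,
                )
                rec, truth = generate_trial(tspec)
                name = trial_name(meta)
                rec.save(out / name)
                torque = generate_torque(
                    meta, spec.mvc_nm, seed=seed + 1,
                    duration_s=spec.duration_s, fs_hz=spec.fs_hz,
                )
                _save_torque(out / f"{name}_torque", torque, meta, spec.fs_hz)
                gt["trials"][name] = {
                    "seed": seed,
                    "field_rms_uv": truth.field_rms_uv.tolist(),
                    "total_rms_uv": truth.total_rms_uv.tolist(),
                    "hotspot": list(truth.hotspot) if truth.hotspot else None,
                }
            # planted CAN field per (muscle, knee, effort): antagonist field
            # over the agonist-MVC field of the same knee position
            for knee, effort, _ in _CONDITIONS:
                key = (muscle.value, knee.value, effort.value)
                if str(key) in gt["can_fields"]:
                    continue
                grid = gm_grid() if muscle is Muscle.GM else so_array(
                    "medial" if muscle is Muscle.SO_MEDIAL else "lateral"
                )
                ant = spec.fields[(muscle.value, knee.value, effort.value, Direction.DORSIFLEXION.value)].evaluate(grid)
                ago = spec.fields[(muscle.value, knee.value, Effort.MAX_100.value, Direction.PLANTARFLEXION.value)].evaluate(grid)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = np.where(ago > 0, ant / np.where(ago > 0, ago, 1.0), np.nan)
                gt["can_fields"][str(key)] = ratio.tolist()
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1, sort_keys=True)
    return out


def _save_torque(path: Path, torque: np.ndarray, meta: TrialMeta, fs_hz: float) -> None:
    data = np.ascontiguousarray(torque, dtype="<f4")
    data.tofile(path.with_suffix(".dat"))
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(
            {
                "kind": "torque",
                "units": "N.m",
                "fs_hz": fs_hz,
                "n_samples": int(data.size),
                "meta": meta.to_dict(),
            },
            fh,
            indent=1,
            sort_keys=True,
        )


def load_torque(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    data = np.fromfile(path.with_suffix(".dat"), dtype="<f4")
    return data, sidecar
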