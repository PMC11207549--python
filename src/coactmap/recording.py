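"""Multichannel EMG recording container and its on-disk format.

Channels are stored channel-major over the *full* derived-montage lattice in
row-major order, so channel ``k`` always maps to lattice position
``(k // n_cols, k % n_cols)``.  Positions without a physical electrode (or
derived channels touching one) are zero-filled and masked invalid; they are
excluded from every downstream map and statistic, never imputed.

On disk a trial is one little-endian float32 binary matrix (``.dat``,
channel-major) plus a JSON sidecar (``.json``) holding the grid geometry,
trial metadata, sampling rate, montage and validity mask.  The round trip is
bit-exact for float32 data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grids import ElectrodeGrid, Montage, TrialMeta

_SIDECAR_VERSION = 1


@dataclass
class EmgRecording:
    """Sample matrix ``[n_channels x n_samples]`` in mV at a fixed rate.

    ``grid`` describes the lattice of the *current* montage (e.g. 12 x 5 for
    single-differential signals derived from a 13 x 5 monopolar grid; 1 x 1
    for a simulated bipolar channel).
    """

    grid: ElectrodeGrid
    samples: np.ndarray
    fs_hz: float
    montage: Montage
    valid: np.ndarray
    meta: TrialMeta
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        self.valid = np.asarray(self.valid, dtype=bool).ravel()
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D [channels x samples] matrix")
        if self.samples.shape[0] != self.grid.n_positions:
            raise ValueError(
                f"sample matrix has {self.samples.shape[0]} channels but the "
                f"{self.grid.n_rows}x{self.grid.n_cols} lattice has {self.grid.n_positions}"
            )
        if self.valid.shape[0] != self.grid.n_positions:
            raise ValueError("validity mask length does not match the lattice")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        for r, c in self.grid.missing:
            self.valid[self.grid.channel_index(r, c)] = False

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def n_channels(self) -> int:
        """Total lattice channels of the montage (valid + invalid)."""
        return self.samples.shape[0]

    @property
    def n_valid_channels(self) -> int:
        return int(self.valid.sum())

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel(self, row: int, col: int) -> np.ndarray:
        return self.samples[self.grid.channel_index(row, col)]

    def valid_mask_2d(self) -> np.ndarray:
        return self.valid.reshape(self.grid.n_rows, self.grid.n_cols)

    # -- disk format ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write ``<path>.dat`` (little-endian float32, channel-major) and
        ``<path>.json``."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        data = np.ascontiguousarray(self.samples, dtype="<f4")
        data.tofile(path.with_suffix(".dat"))
        sidecar = {
            "version": _SIDECAR_VERSION,
            "grid": self.grid.to_dict(),
            "meta": self.meta.to_dict(),
            "fs_hz": self.fs_hz,
            "montage": self.montage.value,
            "n_channels": int(self.n_channels),
            "n_samples": int(self.n_samples),
            "valid": [bool(v) for v in self.valid],
            "extra": self.extra,
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "EmgRecording":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            sidecar = json.load(fh)
        n_ch = int(sidecar["n_channels"])
        n_s = int(sidecar["n_samples"])
        data = np.fromfile(path.with_suffix(".dat"), dtype="<f4")
        if data.size != n_ch * n_s:
            raise ValueError(
                f"{path.with_suffix('.dat')}: expected {n_ch * n_s} samples, found {data.size}"
            )
        return cls(
            grid=ElectrodeGrid.from_dict(sidecar["grid"]),
            samples=data.reshape(n_ch, n_s),
            fs_hz=float(sidecar["fs_hz"]),
            montage=Montage(sidecar["montage"]),
            valid=np.array(sidecar["valid"], dtype=bool),
            meta=TrialMeta.from_dict(sidecar["meta"]),
            extra=sidecar.get("extra", {}),
        )
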