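"""Per-channel RMS amplitude estimation.

Two epoching rules are provided, matching common practice for isometric
trials: the whole-recording RMS for steady submaximal contractions, and the
RMS over a 500-ms epoch centred at the peak of the rectified signal for
maximal efforts (where the plateau of true maximal drive may be brief).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import ElectrodeGrid, TrialMeta
from .recording import EmgRecording


@dataclass
class AmplitudeMap:
    """Per-channel RMS values (mV) on the derived-montage lattice."""

    grid: ElectrodeGrid
    values: np.ndarray  # shape (n_rows, n_cols)
    valid: np.ndarray  # boolean, same shape
    meta: TrialMeta
    epoch: str = "whole"  # "whole" or "peak_500ms"
    epoch_bounds: dict = field(default_factory=dict)  # channel index -> (start, stop) samples

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        shape = (self.grid.n_rows, self.grid.n_cols)
        if self.values.shape != shape or self.valid.shape != shape:
            raise ValueError("map shape does not match the grid lattice")
        if np.any(self.values[self.valid] < 0):
            raise ValueError("RMS values must be non-negative on valid channels")

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def max_valid(self) -> float:
        vals = self.valid_values()
        if vals.size == 0:
            raise ValueError("amplitude map has no valid channels")
        return float(vals.max())


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x, dtype=float))))


def rms_whole(rec: EmgRecording) -> AmplitudeMap:
    """RMS over the whole recording, per valid channel."""
    if rec.n_samples == 0:
        raise ValueError("cannot compute RMS of an empty recording")
    vals = np.sqrt(np.mean(np.square(rec.samples, dtype=float), axis=1))
    vals[~rec.valid] = 0.0
    return AmplitudeMap(
        grid=rec.grid,
        values=vals.reshape(rec.grid.n_rows, rec.grid.n_cols),
        valid=rec.valid_mask_2d().copy(),
        meta=rec.meta,
        epoch="whole",
        epoch_bounds={"all": (0, rec.n_samples)},
    )


def _peak_epoch_bounds(x: np.ndarray, half: int, window: int) -> tuple[int, int]:
    """Window of ``window`` samples centred on the rectified peak, clipped at
    the recording boundaries and re-extended inward to preserve length."""
    peak = int(np.argmax(np.abs(x)))
    start = peak - half
    stop = start + window
    n = x.shape[0]
    if start < 0:
        start, stop = 0, window
    elif stop > n:
        start, stop = n - window, n
    return start, stop


def rms_peak_epoch(rec: EmgRecording, window_ms: float = 500.0) -> AmplitudeMap:
    """RMS over a ``window_ms`` epoch centred at each channel's rectified
    peak.

    The peak is located independently per channel on the raw rectified
    signal (no envelope); epochs hitting a recording boundary are shifted
    inward so the window length is preserved.  The bounds actually used are
    recorded per channel.
    """
    window = int(round(window_ms / 1000.0 * rec.fs_hz))
    if window < 1:
        raise ValueError("epoch window must cover at least one sample")
    if rec.n_samples < window:
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than the "
            f"{window_ms}-ms epoch ({window} samples)"
        )
    half = window // 2
    vals = np.zeros(rec.n_channels)
    bounds: dict = {}
    for k in range(rec.n_channels):
        if not rec.valid[k]:
            continue
        start, stop = _peak_epoch_bounds(rec.samples[k], half, window)
        vals[k] = _rms(rec.samples[k, start:stop])
        bounds[k] = (start, stop)
    return AmplitudeMap(
        grid=rec.grid,
        values=vals.reshape(rec.grid.n_rows, rec.grid.n_cols),
        valid=rec.valid_mask_2d().copy(),
        meta=rec.meta,
        epoch="peak_500ms",
        epoch_bounds=bounds,
    )


def amplitude_map(rec: EmgRecording) -> AmplitudeMap:
    """Dispatch on the trial's effort level: whole-recording RMS for
    submaximal trials, peak-centred 500-ms epoch for maximal trials."""
    from .grids import Effort

    if rec.meta.effort is Effort.MAX_100:
        return rms_peak_epoch(rec)
    return rms_whole(rec)
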