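"""Spatial analysis of CAN maps: segmentation, weighted centroid,
anatomically normalized coordinates, and SO medial/lateral comparison.

Only channels over the muscle's superficial aponeurosis are analysed; the
aponeurosis mask is an explicit input (exactly known for synthetic data,
user-supplied for real recordings).  Segmentation keeps the channels within
70% of the map maximum and retains the largest 4-connected component; the
centroid is the CAN-weighted mean lattice position of the segmented
channels, reported both raw and normalized to [0, 1] along the
proximal–distal (aponeurosis span) and medial–lateral (column span) axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .can import CanMap
from .grids import ElectrodeGrid

logger = logging.getLogger(__name__)

#: 4-connectivity structuring element (no diagonals)
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class AponeurosisMask:
    """Channels located over the superficial aponeurosis.

    ``proximal_row``/``distal_row`` bound the included region along the row
    axis and define the span used to normalize centroid coordinates.
    """

    grid: ElectrodeGrid
    included: np.ndarray  # boolean (n_rows, n_cols)
    proximal_row: int
    distal_row: int

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool)
        if self.included.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("mask shape does not match the grid lattice")
        if not self.included.any():
            raise ValueError("aponeurosis mask includes no channel")
        if self.distal_row < self.proximal_row:
            raise ValueError("distal bound precedes proximal bound")

    @classmethod
    def full(cls, grid: ElectrodeGrid) -> "AponeurosisMask":
        """Whole-lattice mask (every channel assumed over the aponeurosis)."""
        return cls(
            grid=grid,
            included=np.ones((grid.n_rows, grid.n_cols), dtype=bool),
            proximal_row=0,
            distal_row=grid.n_rows - 1,
        )

    @classmethod
    def from_rows(cls, grid: ElectrodeGrid, proximal_row: int, distal_row: int) -> "AponeurosisMask":
        inc = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
        inc[proximal_row : distal_row + 1, :] = True
        return cls(grid=grid, included=inc, proximal_row=proximal_row, distal_row=distal_row)


@dataclass
class SegmentationResult:
    """Outcome of segmenting one CAN map."""

    mask: np.ndarray  # boolean (n_rows, n_cols), segmented channels
    n_segmented: int
    relative_size: float  # n_segmented / n_included, in (0, 1]
    centroid_raw: tuple[float, float]  # (row, col)
    centroid_norm: tuple[float, float]  # (pd, ml), each in [0, 1]


def segment_can_map(
    can_map: CanMap, apo: AponeurosisMask, threshold_frac: float = 0.70
) -> np.ndarray:
    """Segment the high-CAN region of a map.

    Channels (within the aponeurosis and valid) at or above
    ``threshold_frac`` x the map maximum are candidates; the largest
    4-connected candidate component is returned.  Ties between equal-sized
    components are broken by higher summed CAN, then by the most
    proximal-then-medial component.  The threshold is relative, so the
    segmentation is invariant to positive rescaling of the map.
    """
    if (can_map.grid.n_rows, can_map.grid.n_cols) != (apo.grid.n_rows, apo.grid.n_cols):
        raise ValueError("CAN map and aponeurosis mask are on different lattices")
    if not (0 < threshold_frac <= 1):
        raise ValueError("threshold fraction must lie in (0, 1]")
    eligible = can_map.valid & apo.included
    if not eligible.any():
        raise ValueError("no valid channel inside the aponeurosis mask")
    vmax = can_map.values[eligible].max()
    candidates = eligible & (can_map.values >= threshold_frac * vmax)
    labels, n_comp = ndimage.label(candidates, structure=_CROSS)
    if n_comp == 0:  # vmax == 0 edge case: all eligible channels are zero
        return eligible
    best = None
    for lab in range(1, n_comp + 1):
        comp = labels == lab
        rows, cols = np.nonzero(comp)
        key = (
            int(comp.sum()),
            float(can_map.values[comp].sum()),
            -int(rows.min()),
            -int(cols[rows == rows.min()].min()),
        )
        if best is None or key > best[0]:
            best = (key, comp)
    return best[1]


def can_centroid(can_map: CanMap, mask: np.ndarray) -> tuple[float, float]:
    """CAN-weighted mean lattice position of the masked channels.

    Falls back to the unweighted mean of the positions (with a log message)
    when all weights are zero.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("centroid of an empty mask is undefined")
    w = can_map.values[mask]
    wsum = w.sum()
    if wsum <= 0:
        logger.info("all-zero weights in centroid; using unweighted mean position")
        return (float(rows.mean()), float(cols.mean()))
    return (float((w * rows).sum() / wsum), float((w * cols).sum() / wsum))


def normalize_centroid(
    centroid_raw: tuple[float, float], apo: AponeurosisMask, grid: ElectrodeGrid
) -> tuple[float, float]:
    """Normalize a raw (row, col) centroid to [0, 1] coordinates.

    The proximal–distal coordinate is scaled to the aponeurosis span
    (0 = most proximal, 1 = most distal); the medial–lateral coordinate to
    the full column span (0 = most medial, 1 = most lateral).
    """
    row, col = centroid_raw
    span = apo.distal_row - apo.proximal_row
    if span == 0:
        raise ValueError("degenerate aponeurosis span: distal row equals proximal row")
    pd = (row - apo.proximal_row) / span
    ml = col / (grid.n_cols - 1) if grid.n_cols > 1 else 0.0
    return (float(np.clip(pd, 0.0, 1.0)), float(np.clip(ml, 0.0, 1.0)))


def analyze_can_map(
    can_map: CanMap, apo: AponeurosisMask, threshold_frac: float = 0.70
) -> SegmentationResult:
    """Segmentation + centroid in one step."""
    mask = segment_can_map(can_map, apo, threshold_frac)
    n_included = int((apo.included & can_map.valid).sum())
    raw = can_centroid(can_map, mask)
    norm = normalize_centroid(raw, apo, can_map.grid)
    return SegmentationResult(
        mask=mask,
        n_segmented=int(mask.sum()),
        relative_size=float(mask.sum() / n_included),
        centroid_raw=raw,
        centroid_norm=norm,
    )


def so_regional_can(medial: CanMap, lateral: CanMap) -> tuple[float, float]:
    """Mean CAN over valid channels of the medial and lateral SO arrays."""
    if medial.scheme != lateral.scheme:
        raise ValueError("medial and lateral maps use different schemes")
    if medial.condition[1:] != lateral.condition[1:]:
        raise ValueError("medial and lateral maps are from different conditions")
    return (medial.mean_valid(), lateral.mean_valid())
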