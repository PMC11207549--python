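"""Montage derivations: monopolar -> single-differential and simulated
large-electrode bipolar.

Single-differential (SD) signals are the algebraic difference between
monopolar potentials at consecutive rows within each column, the standard
spatial filter along the fibre (proximal–distal) direction.  For the 1-row
soleus arrays the only in-array option is the adjacent-electrode
differential along the array (``axis="cols"``).

A bipolar recording with large electrodes is simulated by averaging the
monopolar potentials under two disjoint 3 x 3 electrode groups and taking
the difference of the two averages, mimicking a pair of ~2 cm^2 electrodes.
"""

from __future__ import annotations

import numpy as np

from .grids import ElectrodeGrid, Montage
from .recording import EmgRecording

GROUP_SIZE = 3  # simulated bipolar electrodes are 3x3 blocks


def monopolar_to_single_differential(
    rec: EmgRecording, axis: str = "rows"
) -> EmgRecording:
    """Derive single-differential EMGs from a monopolar recording.

    Output channel ``(r, c)`` is ``monopolar(r+1, c) - monopolar(r, c)``
    (for ``axis="rows"``); a derived channel whose electrode pair includes a
    missing or invalid electrode is flagged invalid.

    Parameters
    ----------
    rec:
        Monopolar recording.
    axis:
        ``"rows"`` differentiates between consecutive rows (the default,
        valid for grids with >= 2 rows), ``"cols"`` between consecutive
        columns (the adjacent-electrode option for 1-row arrays), ``"auto"``
        picks ``"cols"`` for single-row grids and ``"rows"`` otherwise.
    """
    if rec.montage is not Montage.MONOPOLAR:
        raise ValueError("input recording must be monopolar")
    if axis == "auto":
        axis = "cols" if rec.grid.n_rows == 1 else "rows"
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows', 'cols' or 'auto'")
    g = rec.grid
    if axis == "rows" and g.n_rows < 2:
        raise ValueError(
            "differential along rows impossible: grid has a single row "
            "(use axis='cols' for linear arrays)"
        )
    if axis == "cols" and g.n_cols < 2:
        raise ValueError("differential along columns impossible: single-column grid")

    mono = rec.samples.reshape(g.n_rows, g.n_cols, -1)
    vmask = rec.valid_mask_2d()
    if axis == "rows":
        out = mono[1:, :, :] - mono[:-1, :, :]
        valid = vmask[1:, :] & vmask[:-1, :]
        new_grid = ElectrodeGrid(
            n_rows=g.n_rows - 1,
            n_cols=g.n_cols,
            missing=frozenset(),
            ied_mm=g.ied_mm,
            axis_row=g.axis_row,
            axis_col=g.axis_col,
            label=f"{g.label}_sd",
        )
    else:
        out = mono[:, 1:, :] - mono[:, :-1, :]
        valid = vmask[:, 1:] & vmask[:, :-1]
        new_grid = ElectrodeGrid(
            n_rows=g.n_rows,
            n_cols=g.n_cols - 1,
            missing=frozenset(),
            ied_mm=g.ied_mm,
            axis_row=g.axis_row,
            axis_col=g.axis_col,
            label=f"{g.label}_sd",
        )
    out = out.reshape(new_grid.n_positions, -1).copy()
    valid = valid.ravel()
    out[~valid] = 0.0
    return EmgRecording(
        grid=new_grid,
        samples=out,
        fs_hz=rec.fs_hz,
        montage=Montage.SINGLE_DIFFERENTIAL,
        valid=valid,
        meta=rec.meta,
        extra=dict(rec.extra, sd_axis=axis),
    )


def _check_group(grid: ElectrodeGrid, group: set, name: str) -> list[tuple[int, int]]:
    pos = sorted((int(r), int(c)) for r, c in group)
    if len(pos) != GROUP_SIZE * GROUP_SIZE:
        raise ValueError(f"{name} must contain exactly {GROUP_SIZE * GROUP_SIZE} electrodes")
    r0 = min(r for r, _ in pos)
    c0 = min(c for _, c in pos)
    expected = sorted((r0 + i, c0 + j) for i in range(GROUP_SIZE) for j in range(GROUP_SIZE))
    if pos != expected:
        raise ValueError(f"{name} is not a contiguous {GROUP_SIZE}x{GROUP_SIZE} block")
    for r, c in pos:
        if not grid.contains(r, c):
            raise ValueError(f"{name} extends off the lattice at {(r, c)}")
        if grid.is_missing(r, c):
            raise ValueError(f"{name} contains the missing electrode at {(r, c)}")
    return pos


def default_bipolar_groups(grid: ElectrodeGrid) -> tuple[set, set]:
    """Default placement of the two simulated electrodes on a GM-like grid:
    two 3x3 blocks centred on the middle column, upper block centred at row
    4 (0-based), one skipped row between the blocks."""
    mid = grid.n_cols // 2
    cols = range(mid - 1, mid + 2)
    upper = {(r, c) for r in range(3, 6) for c in cols}
    lower = {(r, c) for r in range(7, 10) for c in cols}
    return upper, lower


def simulate_bipolar(
    rec: EmgRecording,
    group_a: set | None = None,
    group_b: set | None = None,
) -> EmgRecording:
    """Simulate a classic bipolar recording from monopolar HD-EMG.

    Each virtual electrode is the average of the monopolar signals under a
    contiguous 3x3 block; the bipolar channel is
    ``mean(group_a) - mean(group_b)``.  The two groups must be disjoint and
    free of missing electrodes.  Group centres are recorded in the output's
    ``extra`` metadata.
    """
    if rec.montage is not Montage.MONOPOLAR:
        raise ValueError("input recording must be monopolar")
    if group_a is None and group_b is None:
        group_a, group_b = default_bipolar_groups(rec.grid)
    if group_a is None or group_b is None:
        raise ValueError("provide both electrode groups or neither")
    pos_a = _check_group(rec.grid, group_a, "group_a")
    pos_b = _check_group(rec.grid, group_b, "group_b")
    if set(pos_a) & set(pos_b):
        raise ValueError("bipolar electrode groups overlap")

    idx_a = [rec.grid.channel_index(r, c) for r, c in pos_a]
    idx_b = [rec.grid.channel_index(r, c) for r, c in pos_b]
    sig = rec.samples[idx_a].mean(axis=0) - rec.samples[idx_b].mean(axis=0)

    def _center(pos):
        return (
            float(np.mean([r for r, _ in pos])),
            float(np.mean([c for _, c in pos])),
        )

    bip_grid = ElectrodeGrid(
        n_rows=1, n_cols=1, ied_mm=rec.grid.ied_mm, label=f"{rec.grid.label}_bip"
    )
    return EmgRecording(
        grid=bip_grid,
        samples=sig[np.newaxis, :],
        fs_hz=rec.fs_hz,
        montage=Montage.BIPOLAR,
        valid=np.array([True]),
        meta=rec.meta,
        extra=dict(
            rec.extra,
            bipolar_center_a=_center(pos_a),
            bipolar_center_b=_center(pos_b),
        ),
    )
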