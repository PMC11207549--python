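"""Coefficient of antagonist activation (CAN).

CAN is the ratio of a muscle's EMG RMS amplitude while acting as antagonist
(dorsiflexion effort, for the triceps surae) to its RMS during its own
maximal agonist effort (plantar-flexion MVC).  Three estimation schemes are
implemented:

* ``bip`` — from a single (simulated) bipolar channel;
* ``cs``  — channel-specific normalization: each grid channel is divided by
  the agonist-MVC RMS of the *same* channel;
* ``ov``  — overall normalization: every channel is divided by the maximum
  agonist-MVC RMS across the detection system.

CAN values may exceed 1 (antagonist activation above the channel's own
agonist maximum) and are never clipped.  For every channel
``OvCAN <= CsCAN``, with equality everywhere only if the agonist map is
uniform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .amplitude import AmplitudeMap
from .grids import ElectrodeGrid, Knee, Muscle

logger = logging.getLogger(__name__)

SCHEMES = ("bip", "cs", "ov")


@dataclass
class CanMap:
    """Per-channel CAN values (dimensionless, >= 0, unclipped)."""

    grid: ElectrodeGrid
    values: np.ndarray  # (n_rows, n_cols)
    valid: np.ndarray
    scheme: str
    condition: tuple  # (muscle, knee, effort)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "bip" and self.valid.sum() != 1:
            raise ValueError("bipolar CAN carries exactly one channel")
        if np.any(self.values[self.valid] < 0):
            raise ValueError("CAN values must be non-negative")

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def mean_valid(self) -> float:
        vals = self.valid_values()
        if vals.size == 0:
            raise ValueError("CAN map has no valid channels")
        return float(vals.mean())


def _check_pair(antag: AmplitudeMap, agonist_mvc: AmplitudeMap) -> None:
    if (antag.grid.n_rows, antag.grid.n_cols) != (
        agonist_mvc.grid.n_rows,
        agonist_mvc.grid.n_cols,
    ):
        raise ValueError("antagonist and agonist maps are on different lattices")
    if antag.meta.muscle is not agonist_mvc.meta.muscle:
        raise ValueError("antagonist and agonist maps are from different muscles")
    if antag.meta.knee is not agonist_mvc.meta.knee:
        raise ValueError(
            "MVC reference must share the knee position of the antagonist trial"
        )


def _condition(antag: AmplitudeMap) -> tuple:
    m = antag.meta
    return (m.muscle.value, m.knee.value, m.effort.value)


def bip_can(antag: AmplitudeMap, agonist_mvc: AmplitudeMap) -> CanMap:
    """CAN from one simulated bipolar channel: antagonist RMS over the
    agonist-MVC RMS of the same channel."""
    _check_pair(antag, agonist_mvc)
    if antag.grid.n_positions != 1:
        raise ValueError("bipolar CAN expects single-channel amplitude maps")
    if not (antag.valid.all() and agonist_mvc.valid.all()):
        raise ValueError("degenerate MVC reference: invalid bipolar channel")
    denom = float(agonist_mvc.values.ravel()[0])
    if denom <= 0:
        raise ValueError("degenerate MVC reference: zero agonist amplitude")
    value = float(antag.values.ravel()[0]) / denom
    return CanMap(
        grid=antag.grid,
        values=np.array([[value]]),
        valid=np.array([[True]]),
        scheme="bip",
        condition=_condition(antag),
    )


def cs_can(antag: AmplitudeMap, agonist_mvc: AmplitudeMap) -> CanMap:
    """Channel-specific CAN: element-wise ratio on channels valid in both
    maps.  A zero agonist denominator invalidates that channel (with a
    warning) rather than failing the whole map."""
    _check_pair(antag, agonist_mvc)
    valid = antag.valid & agonist_mvc.valid
    zero_denom = valid & (agonist_mvc.values <= 0)
    if zero_denom.any():
        logger.warning(
            "channel-specific CAN: %d channel(s) with zero agonist-MVC RMS "
            "flagged invalid",
            int(zero_denom.sum()),
        )
        valid = valid & ~zero_denom
    values = np.zeros_like(antag.values)
    values[valid] = antag.values[valid] / agonist_mvc.values[valid]
    return CanMap(
        grid=antag.grid,
        values=values,
        valid=valid,
        scheme="cs",
        condition=_condition(antag),
    )


def ov_can(antag: AmplitudeMap, agonist_mvc: AmplitudeMap) -> CanMap:
    """Overall CAN: every channel divided by the maximum agonist-MVC RMS of
    the detection system (the GM grid, or each SO array separately)."""
    _check_pair(antag, agonist_mvc)
    denom = agonist_mvc.max_valid()  # raises if all-invalid
    if denom <= 0:
        raise ValueError("degenerate MVC reference: maximal agonist RMS is zero")
    valid = antag.valid & agonist_mvc.valid
    values = np.zeros_like(antag.values)
    values[valid] = antag.values[valid] / denom
    return CanMap(
        grid=antag.grid,
        values=values,
        valid=valid,
        scheme="ov",
        condition=_condition(antag),
    )
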