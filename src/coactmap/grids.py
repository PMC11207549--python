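"""Electrode-grid geometry and trial metadata.

The detection systems modelled here are the ones routinely used for the
triceps surae: a dense rectangular grid over gastrocnemius medialis (GM) and
short linear arrays over the medial and lateral exposed portions of soleus
(SO).  Every module in the package shares one coordinate convention:
0-based ``(row, col)`` lattice positions, row 0 most proximal, column 0 most
medial.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Montage(str, enum.Enum):
    """Spatial filter applied to the raw electrode potentials."""

    MONOPOLAR = "monopolar"
    SINGLE_DIFFERENTIAL = "single_differential"
    BIPOLAR = "bipolar"


class Muscle(str, enum.Enum):
    GM = "GM"
    SO_MEDIAL = "SO_medial"
    SO_LATERAL = "SO_lateral"


class Knee(str, enum.Enum):
    FLEXED_90 = "flexed_90"
    EXTENDED_0 = "extended_0"


class Effort(str, enum.Enum):
    SUBMAX_30 = "submax_30"
    MAX_100 = "max_100"


class Direction(str, enum.Enum):
    """Contraction direction.  For the triceps surae, plantar flexion is the
    agonist effort and dorsiflexion the antagonist effort."""

    DORSIFLEXION = "dorsiflexion"
    PLANTARFLEXION = "plantarflexion"


@dataclass(frozen=True)
class ElectrodeGrid:
    """Geometry of one detection system.

    Parameters
    ----------
    n_rows, n_cols:
        Lattice dimensions.  Rows run along the proximal–distal axis,
        columns along the medial–lateral axis.
    missing:
        Lattice positions without a physical electrode (e.g. the missing
        corner of the 64-electrode GM matrix).
    ied_mm:
        Inter-electrode distance in millimetres.
    axis_row, axis_col:
        Anatomical direction of increasing index; informational.
    label:
        Identifier such as ``"GM_grid"``.
    """

    n_rows: int
    n_cols: int
    missing: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    ied_mm: float = 8.0
    axis_row: str = "proximal_to_distal"
    axis_col: str = "medial_to_lateral"
    label: str = "grid"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.ied_mm <= 0:
            raise ValueError("inter-electrode distance must be positive")
        missing = frozenset((int(r), int(c)) for r, c in self.missing)
        object.__setattr__(self, "missing", missing)
        for r, c in missing:
            if not self.contains(r, c):
                raise ValueError(f"missing position {(r, c)} lies outside the lattice")

    # -- lattice bookkeeping -------------------------------------------------

    @property
    def n_positions(self) -> int:
        """Total lattice positions, missing included."""
        return self.n_rows * self.n_cols

    @property
    def n_electrodes(self) -> int:
        """Physical electrodes (lattice minus missing)."""
        return self.n_positions - len(self.missing)

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def is_missing(self, row: int, col: int) -> bool:
        return (row, col) in self.missing

    def channel_index(self, row: int, col: int) -> int:
        """Row-major flat index of a lattice position."""
        if not self.contains(row, col):
            raise IndexError(f"position {(row, col)} outside {self.n_rows}x{self.n_cols} lattice")
        return row * self.n_cols + col

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "missing": sorted(list(p) for p in self.missing),
            "ied_mm": self.ied_mm,
            "axis_row": self.axis_row,
            "axis_col": self.axis_col,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrodeGrid":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            missing=frozenset(tuple(p) for p in d.get("missing", [])),
            ied_mm=float(d.get("ied_mm", 8.0)),
            axis_row=d.get("axis_row", "proximal_to_distal"),
            axis_col=d.get("axis_col", "medial_to_lateral"),
            label=d.get("label", "grid"),
        )


def gm_grid() -> ElectrodeGrid:
    """Default GM detection system: 13 x 5 matrix, one missing corner
    electrode (64 electrodes total), 8-mm inter-electrode distance.

    The missing electrode sits at the proximal-medial corner (0, 0).
    """
    return ElectrodeGrid(
        n_rows=13,
        n_cols=5,
        missing=frozenset({(0, 0)}),
        ied_mm=8.0,
        label="GM_grid",
    )


def so_array(side: str = "medial") -> ElectrodeGrid:
    """Default SO detection system: linear array of 8 electrodes, 5-mm
    inter-electrode distance, one per muscle portion (medial / lateral)."""
    if side not in ("medial", "lateral"):
        raise ValueError("side must be 'medial' or 'lateral'")
    return ElectrodeGrid(
        n_rows=1,
        n_cols=8,
        missing=frozenset(),
        ied_mm=5.0,
        label=f"SO_{side}",
    )


@dataclass(frozen=True)
class TrialMeta:
    """Identity of one recorded trial within the factorial design."""

    subject_id: str
    muscle: Muscle
    knee: Knee
    effort: Effort
    direction: Direction
    trial_id: str = ""

    @property
    def is_antagonist_effort(self) -> bool:
        """Dorsiflexion is the antagonist effort for all plantar flexors."""
        return self.direction is Direction.DORSIFLEXION

    @property
    def is_agonist_effort(self) -> bool:
        return self.direction is Direction.PLANTARFLEXION

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "muscle": self.muscle.value,
            "knee": self.knee.value,
            "effort": self.effort.value,
            "direction": self.direction.value,
            "trial_id": self.trial_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialMeta":
        return cls(
            subject_id=d["subject_id"],
            muscle=Muscle(d["muscle"]),
            knee=Knee(d["knee"]),
            effort=Effort(d["effort"]),
            direction=Direction(d["direction"]),
            trial_id=d.get("trial_id", ""),
        )
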