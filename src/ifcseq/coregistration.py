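"""Cross-modality co-registration: marker normalization and rectangular gating.

The two experiments (SCT and IFC) measure the same surface markers on
different instruments and scales. Co-registration makes them comparable by
min-max normalizing each marker independently within each modality to [0,1].
Populations of interest are then defined by axis-aligned rectangular gates in
the 2-D normalized marker space; cells falling in no gate are labeled
"other".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import MarkerTable

__all__ = ["Gate", "GateSet", "PopulationLabels", "normalize_markers", "apply_gates",
           "OTHER_LABEL"]

OTHER_LABEL = "other"


@dataclass
class Gate:
    """Axis-aligned rectangle in normalized marker space.

    Intervals are half-open [lo, hi), except that hi == 1 (the normalized
    maximum) is closed so cells sitting exactly on the attained maximum are
    not lost. Boundary cells shared by overlapping gates resolve by gate
    precedence, never by double assignment.
    """

    marker_x: str
    marker_y: str
    x: tuple  # (lo, hi)
    y: tuple  # (lo, hi)

    def __post_init__(self) -> None:
        for lo, hi in (self.x, self.y):
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"gate bounds must satisfy 0 <= lo < hi <= 1, got ({lo}, {hi})")

    @staticmethod
    def _in_interval(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
        upper = v <= hi if hi >= 1.0 else v < hi
        return (v >= lo) & upper

    def contains(self, xv: np.ndarray, yv: np.ndarray) -> np.ndarray:
        return self._in_interval(np.asarray(xv, float), *self.x) & \
            self._in_interval(np.asarray(yv, float), *self.y)


@dataclass
class GateSet:
    gates: dict  # population name -> Gate
    precedence: list = field(default=None)

    def __post_init__(self) -> None:
        if self.precedence is None:
            self.precedence = list(self.gates)
        missing = set(self.gates) - set(self.precedence)
        if missing:
            raise ValueError(f"precedence missing gate names: {sorted(missing)}")
        unknown = set(self.precedence) - set(self.gates)
        if unknown:
            raise ValueError(f"precedence names without a gate: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "GateSet":
        """Build from a config mapping: name -> {marker_x, marker_y, x: [lo,hi], y: [lo,hi]}."""
        gates = {
            name: Gate(g["marker_x"], g["marker_y"], tuple(g["x"]), tuple(g["y"]))
            for name, g in d.get("gates", d).items()
        }
        return cls(gates, list(d["precedence"]) if "precedence" in d else None)


@dataclass
class PopulationLabels:
    labels: np.ndarray  # per-cell population name or "other"
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.labels) != len(self.cell_ids):
            raise ValueError("labels and cell_ids differ in length")

    def counts(self) -> dict:
        names, n = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(names.tolist(), n.tolist()))

    def populations(self, include_other: bool = True) -> list:
        pops = sorted(set(self.labels.tolist()))
        if not include_other and OTHER_LABEL in pops:
            pops.remove(OTHER_LABEL)
        return pops


def normalize_markers(markers: MarkerTable) -> MarkerTable:
    """Min-max normalize each marker column to [0,1] within this modality.

    The original per-marker (min, max) are stored on the result so the map
    can be inverted or reported in a run manifest. Each modality must be
    normalized with its own bounds — never reuse another modality's.
    """
    values = markers.values
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    constant = hi <= lo
    if constant.any():
        name = markers.marker_names[constant][0]
        raise ValueError(f"marker {name!r} is constant; cannot min-max normalize")
    out = (values - lo) / (hi - lo)
    bounds = {str(m): (float(l), float(h))
              for m, l, h in zip(markers.marker_names.tolist(), lo, hi)}
    return MarkerTable(out, markers.cell_ids, markers.marker_names,
                       normalized=True, norm_bounds=bounds)


def apply_gates(markers: MarkerTable, gates: GateSet) -> PopulationLabels:
    """Assign each cell to the first gate (in precedence order) containing it.

    Cells contained in no gate receive the reserved label ``"other"``.
    """
    if not markers.normalized:
        raise ValueError("markers must be normalized before gating")
    labels = np.full(markers.n_cells, OTHER_LABEL, dtype=object)
    unassigned = np.ones(markers.n_cells, dtype=bool)
    for name in gates.precedence:
        gate = gates.gates[name]
        inside = gate.contains(markers.column(gate.marker_x), markers.column(gate.marker_y))
        take = inside & unassigned
        labels[take] = name
        unassigned &= ~inside
    return PopulationLabels(labels, markers.cell_ids)
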