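"""Domain model for VMAT treatment plans.

A VMAT (volumetric modulated arc therapy) plan is delivered while the gantry
rotates; the record consists of one or more arcs, each an ordered sequence of
control points (CPs).  At every CP the multi-leaf collimator (MLC) bank
positions define the beam aperture and a meterset value ("dose", in MU or
cGy) defines the output delivered around that gantry angle.

Coordinate convention used throughout the package: the *position* axis (leaf
travel direction) is x in mm, isocenter-centred, with the left bank at
coordinates <= the right bank for a valid aperture; the *leaf-index* axis is
y in mm, isocenter-centred, with pair 0 at the most negative y.  Gantry
angles are stored as planned, in degrees; no IEC scale conversion is applied.
The per-CP dose is a per-segment meterset, never cumulative, and its unit is
metadata that is never converted.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "MachineSpec",
    "ControlPoint",
    "VMATPlan",
    "Violation",
    "ViolationReport",
    "SchemaError",
    "default_machine",
    "read_plan_json",
    "write_plan_json",
    "validate_plan",
    "LABELS",
]

LABELS = ("regular", "anomalous", "unknown")


class SchemaError(ValueError):
    """Raised when a plan document violates the interchange schema."""


@dataclass(frozen=True)
class MachineSpec:
    """Static MLC/linac geometry and delivery limits.

    Parameters
    ----------
    n_leaf_pairs
        Number of opposing leaf pairs in the MLC.
    leaf_widths
        Physical width of each pair (mm) along the leaf-index axis, ordered
        from the most negative y.
    field_width
        Total extent along the leaf-index axis (mm); must equal the sum of
        the leaf widths.
    field_height
        Maximum leaf-travel extent along the position axis (mm); leaves may
        occupy [-field_height/2, +field_height/2].
    max_leaf_speed
        Maximum leaf displacement per degree of gantry rotation (mm/deg).
        Gantry angle is the time proxy, since delivery time is absent from
        the plan record.
    min_gap
        Minimum allowed separation between opposing leaves (mm, >= 0).
    """

    n_leaf_pairs: int
    leaf_widths: tuple
    field_width: float
    field_height: float
    max_leaf_speed: float
    min_gap: float = 0.0

    def __post_init__(self):
        widths = tuple(float(w) for w in self.leaf_widths)
        object.__setattr__(self, "leaf_widths", widths)
        if self.n_leaf_pairs != len(widths):
            raise ValueError(
                f"n_leaf_pairs={self.n_leaf_pairs} but {len(widths)} leaf_widths given"
            )
        if any(w <= 0 for w in widths):
            raise ValueError("all leaf widths must be > 0")
        if not math.isclose(sum(widths), self.field_width, rel_tol=0, abs_tol=1e-6):
            raise ValueError(
                f"sum(leaf_widths)={sum(widths)} != field_width={self.field_width}"
            )
        if self.max_leaf_speed <= 0:
            raise ValueError("max_leaf_speed must be > 0")
        if self.min_gap < 0:
            raise ValueError("min_gap must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_leaf_pairs": self.n_leaf_pairs,
            "leaf_widths_mm": list(self.leaf_widths),
            "field_width_mm": self.field_width,
            "field_height_mm": self.field_height,
            "max_leaf_speed_mm_per_deg": self.max_leaf_speed,
            "min_gap_mm": self.min_gap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MachineSpec":
        try:
            return cls(
                n_leaf_pairs=int(d["n_leaf_pairs"]),
                leaf_widths=tuple(d["leaf_widths_mm"]),
                field_width=float(d["field_width_mm"]),
                field_height=float(d["field_height_mm"]),
                max_leaf_speed=float(d["max_leaf_speed_mm_per_deg"]),
                min_gap=float(d.get("min_gap_mm", 0.0)),
            )
        except KeyError as e:  # pragma: no cover - exercised via read_plan_json
            raise SchemaError(f"machine record missing field {e.args[0]!r}") from e


def default_machine() -> MachineSpec:
    """An Elekta-Synergy-like machine: 40 pairs of 10 mm leaves, 400 mm
    travel, 5 mm/deg leaf speed limit, 5 mm minimum dynamic gap."""
    return MachineSpec(
        n_leaf_pairs=40,
        leaf_widths=(10.0,) * 40,
        field_width=400.0,
        field_height=400.0,
        max_leaf_speed=5.0,
        min_gap=5.0,
    )


@dataclass
class ControlPoint:
    """One sampled machine state along an arc."""

    gantry_angle: float
    left_positions: np.ndarray
    right_positions: np.ndarray
    dose: float

    def __post_init__(self):
        self.left_positions = np.asarray(self.left_positions, dtype=float)
        self.right_positions = np.asarray(self.right_positions, dtype=float)
        if self.left_positions.shape != self.right_positions.shape:
            raise ValueError("left/right bank lengths differ")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")

    @property
    def n_pairs(self) -> int:
        return self.left_positions.shape[0]


@dataclass
class VMATPlan:
    """An ordered collection of arcs of control points plus a class label."""

    plan_id: str
    arcs: list  # list[list[ControlPoint]]
    label: str = "unknown"
    anomaly_meta: Optional[dict] = None
    machine: Optional[MachineSpec] = None

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.n_control_points < 1:
            raise ValueError("plan must contain at least one control point")

    @property
    def n_control_points(self) -> int:
        return sum(len(arc) for arc in self.arcs)

    def control_points(self) -> Iterator[ControlPoint]:
        """All CPs in arc order (arc-major, as delivered)."""
        for arc in self.arcs:
            yield from arc

    def doses(self) -> np.ndarray:
        return np.array([cp.dose for cp in self.control_points()], dtype=float)

    def copy(self) -> "VMATPlan":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class Violation:
    cp_index: int  # global arc-major CP index
    leaf_pair: int  # -1 for violations not tied to a single pair
    kind: str  # gap | travel | speed
    magnitude: float  # mm by which the constraint is exceeded


@dataclass
class ViolationReport:
    entries: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.entries)

    def count(self, kind: Optional[str] = None) -> int:
        if kind is None:
            return len(self.entries)
        return sum(1 for v in self.entries if v.kind == kind)

    @property
    def ok(self) -> bool:
        return not self.entries


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------

def _require(doc: dict, key: str, where: str):
    if key not in doc:
        raise SchemaError(f"missing field {key!r} in {where}")
    return doc[key]


def plan_to_dict(plan: VMATPlan) -> dict:
    doc = {
        "plan_id": plan.plan_id,
        "machine": plan.machine.to_dict() if plan.machine is not None else None,
        "arcs": [
            [
                {
                    "gantry_deg": cp.gantry_angle,
                    "left_mm": cp.left_positions.tolist(),
                    "right_mm": cp.right_positions.tolist(),
                    "dose": cp.dose,
                }
                for cp in arc
            ]
            for arc in plan.arcs
        ],
        "label": plan.label,
        "anomaly_meta": plan.anomaly_meta,
    }
    return doc


def plan_from_dict(doc: dict) -> VMATPlan:
    plan_id = str(_require(doc, "plan_id", "plan document"))
    machine_doc = doc.get("machine")
    machine = MachineSpec.from_dict(machine_doc) if machine_doc else None
    arcs_doc = _require(doc, "arcs", "plan document")
    if not isinstance(arcs_doc, list) or not arcs_doc:
        raise SchemaError("'arcs' must be a non-empty list of arcs")
    n_pairs = machine.n_leaf_pairs if machine is not None else None
    arcs = []
    for a, arc_doc in enumerate(arcs_doc):
        arc = []
        for k, cp_doc in enumerate(arc_doc):
            where = f"arc {a} control point {k}"
            left = _require(cp_doc, "left_mm", where)
            right = _require(cp_doc, "right_mm", where)
            if n_pairs is None:
                n_pairs = len(left)
            if len(left) != n_pairs:
                raise SchemaError(
                    f"field 'left_positions' has length {len(left)} "
                    f"but machine has {n_pairs} leaf pairs ({where})"
                )
            if len(right) != n_pairs:
                raise SchemaError(
                    f"field 'right_positions' has length {len(right)} "
                    f"but machine has {n_pairs} leaf pairs ({where})"
                )
            arc.append(
                ControlPoint(
                    gantry_angle=float(_require(cp_doc, "gantry_deg", where)),
                    left_positions=np.array(left, dtype=float),
                    right_positions=np.array(right, dtype=float),
                    dose=float(_require(cp_doc, "dose", where)),
                )
            )
        arcs.append(arc)
    label = doc.get("label", "unknown")
    if label not in LABELS:
        raise SchemaError(f"field 'label' must be one of {LABELS}, got {label!r}")
    return VMATPlan(
        plan_id=plan_id,
        arcs=arcs,
        label=label,
        anomaly_meta=doc.get("anomaly_meta"),
        machine=machine,
    )


def read_plan_json(path) -> VMATPlan:
    """Read a plan from the JSON interchange format.

    Units are preserved as mm / degrees / MU; no conversion is performed.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise SchemaError(f"{path}: not valid JSON ({e})") from e
    return plan_from_dict(doc)


def write_plan_json(plan: VMATPlan, path) -> None:
    """Write a plan to the JSON interchange format (lossless round-trip)."""
    if plan.n_control_points < 1:  # defensive; the constructor enforces this
        raise ValueError("refusing to serialize a plan with no control points")
    with open(path, "w") as fh:
        json.dump(plan_to_dict(plan), fh, indent=1)


# ---------------------------------------------------------------------------
# Physical-constraint validation
# ---------------------------------------------------------------------------

def validate_plan(plan: VMATPlan, machine: MachineSpec) -> ViolationReport:
    """Check every control point against the machine's physical limits.

    Three constraint families are checked, each reported per (CP, leaf pair)
    with the magnitude (mm) by which the limit is exceeded:

    gap
        opposing-leaf separation: right - left >= min_gap.
    travel
        both leaves inside [-field_height/2, +field_height/2].
    speed
        |position change| between consecutive CPs of the same arc must not
        exceed max_leaf_speed * |gantry change| (per bank; the larger excess
        of the two banks is reported).
    """
    report = ViolationReport()
    half = machine.field_height / 2.0
    offset = 0
    for arc in plan.arcs:
        for k, cp in enumerate(arc):
            if cp.n_pairs != machine.n_leaf_pairs:
                raise ValueError(
                    f"control point has {cp.n_pairs} leaf pairs, "
                    f"machine has {machine.n_leaf_pairs}"
                )
            gidx = offset + k
            gap = cp.right_positions - cp.left_positions
            for p in np.nonzero(gap < machine.min_gap - 1e-9)[0]:
                report.entries.append(
                    Violation(gidx, int(p), "gap", float(machine.min_gap - gap[p]))
                )
            for bank in (cp.left_positions, cp.right_positions):
                over = np.maximum(np.abs(bank) - half, 0.0)
                for p in np.nonzero(over > 1e-9)[0]:
                    report.entries.append(
                        Violation(gidx, int(p), "travel", float(over[p]))
                    )
            if k > 0:
                prev = arc[k - 1]
                allowed = machine.max_leaf_speed * abs(
                    cp.gantry_angle - prev.gantry_angle
                )
                excess = np.maximum(
                    np.abs(cp.left_positions - prev.left_positions),
                    np.abs(cp.right_positions - prev.right_positions),
                ) - allowed
                for p in np.nonzero(excess > 1e-9)[0]:
                    report.entries.append(
                        Violation(gidx, int(p), "speed", float(excess[p]))
                    )
        offset += len(arc)
    return report
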