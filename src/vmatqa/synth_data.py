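"""Synthetic VMAT plan generator with labeled fault injection.

Clinical plan databases are not shareable, so this module supplies plans
with the statistical structure the detector assumes: two full arcs of 90
control points each, smooth leaf-pair trajectories that respect the
machine's travel / gap / speed limits, and per-CP metersets drawn from a
truncated normal.  Anomalies are injected as labeled, kind-specific faults
so that detection performance can be measured exactly.

Trajectory model: each leaf pair carries a gap *centre* and *width* that
follow independent Gaussian random walks, smoothed with a moving average of
length ``smoothness`` (the correlation length in CPs), then projected CP by
CP onto the feasible set (travel range, minimum gap, leaf-speed limit).
This produces slowly varying, organ-shaped apertures without emulating a
treatment-plan optimizer.

Fault taxonomy (this package's invention; severities default to gross,
human-reviewable magnitudes and are config knobs):

==================  ======================================================
kind                effect
==================  ======================================================
leaf_jump           a few adjacent pairs displace by ``magnitude`` mm for a
                    window of CPs and snap back (speed violations at the
                    window edges, an aperture protrusion inside it)
crossed_leaves      right bank driven ``magnitude`` mm past the left bank
                    for a few pairs over a window (negative gap)
bank_swap           left and right banks exchanged over a window
                    (magnitude acts as an on/off switch)
aperture_collapse   the gap abruptly narrows by ``magnitude`` mm (floored
                    at the machine minimum gap) over a window
dose_spike          dose multiplied by (1 + magnitude) at one CP
dose_dropout        dose multiplied by max(0, 1 - magnitude) over a window
==================  ======================================================

The three leaf-position faults (and the abrupt collapse) violate the
machine constraints and are caught by ``validate_plan``; the dose faults
leave the geometry untouched and are detectable only from the dose record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .plan_model import (
    ControlPoint,
    MachineSpec,
    VMATPlan,
    default_machine,
)

__all__ = [
    "SimConfig",
    "AnomalySpec",
    "ANOMALY_KINDS",
    "GEOMETRIC_KINDS",
    "DOSE_KINDS",
    "simulate_regular_plan",
    "inject_anomaly",
    "make_dataset",
    "dataset_manifest",
]

ANOMALY_KINDS = (
    "leaf_jump",
    "crossed_leaves",
    "bank_swap",
    "dose_spike",
    "dose_dropout",
    "aperture_collapse",
)
#: kinds that break machine geometry constraints (validate_plan fails)
GEOMETRIC_KINDS = ("leaf_jump", "crossed_leaves", "bank_swap", "aperture_collapse")
#: kinds that only perturb the dose record (geometry checks pass)
DOSE_KINDS = ("dose_spike", "dose_dropout")

# Default severities are gross, human-reviewable faults: each one visibly
# corrupts a substantial fraction of the delivery (about a quarter to a
# whole arc), not a single control point that would vanish in plan-level
# averages.
_DEFAULT_MAGNITUDE = {
    "leaf_jump": 60.0,  # mm; 3x the per-CP travel allowed at 5 mm/deg, 4 deg steps
    "crossed_leaves": 20.0,  # mm of overlap past the opposing leaf
    "bank_swap": 1.0,  # on/off
    "aperture_collapse": 200.0,  # mm of gap reduction (collapses to min_gap)
    "dose_spike": 9.0,  # dose -> 10x
    "dose_dropout": 1.0,  # dose -> 0
}
_DEFAULT_WINDOW = {
    "leaf_jump": 60,
    "crossed_leaves": 60,
    "bank_swap": 90,
    "aperture_collapse": 60,
    "dose_spike": 5,
    "dose_dropout": 45,
}
_DEFAULT_PAIRS = {"leaf_jump": 4, "crossed_leaves": 6}


@dataclass
class AnomalySpec:
    """One injectable fault.  ``magnitude`` 0 is a no-op of any kind."""

    kind: str
    magnitude: Optional[float] = None
    cp_index: Optional[int] = None  # global arc-major index; None = random
    width: Optional[int] = None  # CPs affected; None = kind default

    def __post_init__(self):
        if self.kind not in ANOMALY_KINDS:
            raise ValueError(f"unknown anomaly kind {self.kind!r}")
        if self.magnitude is None:
            self.magnitude = _DEFAULT_MAGNITUDE[self.kind]
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.width is None:
            self.width = _DEFAULT_WINDOW[self.kind]


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a desk-scale cohort (200 regular + 20 anomalous plans,
    emulating the heavy regular:anomalous imbalance of clinical archives) of
    two-arc, 90-CP plans on the default 40-pair machine, with ~5 MU per CP.
    """

    n_regular: int = 200
    n_anomalous: int = 20
    arcs_per_plan: int = 2
    cps_per_arc: int = 90
    machine: MachineSpec = field(default_factory=default_machine)
    dose_mean: float = 5.0  # MU per CP
    dose_cv: float = 0.25  # coefficient of variation
    smoothness: int = 15  # trajectory correlation length, in CPs
    seed: int = 0
    anomaly_mix: dict = field(
        default_factory=lambda: {k: 1.0 for k in ANOMALY_KINDS}
    )

    def __post_init__(self):
        if self.n_regular < 0 or self.n_anomalous < 0:
            raise ValueError("plan counts must be >= 0")
        if self.cps_per_arc < 2:
            raise ValueError("cps_per_arc must be >= 2")
        if self.dose_mean <= 0:
            raise ValueError("dose_mean must be > 0")
        if self.smoothness < 1:
            raise ValueError("smoothness must be >= 1")
        bad = set(self.anomaly_mix) - set(ANOMALY_KINDS)
        if bad:
            raise ValueError(f"unknown anomaly kinds in mix: {sorted(bad)}")


def _smooth(x: np.ndarray, window: int, axis: int = 0) -> np.ndarray:
    """Moving average along one axis with edge padding."""
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    widths = [(0, 0)] * x.ndim
    widths[axis] = (pad, window - 1 - pad)
    xp = np.pad(x, widths, mode="edge")
    return np.apply_along_axis(
        lambda v: np.convolve(v, kernel, "valid"), axis, xp
    )


def _simulate_arc(
    config: SimConfig, rng: np.random.Generator, gantry: np.ndarray
) -> list:
    """One arc of smooth, constraint-respecting leaf trajectories."""
    m = config.machine
    n_cp = config.cps_per_arc
    n_p = m.n_leaf_pairs
    half = m.field_height / 2.0
    dg = np.abs(np.diff(gantry))

    # Organ-like base shape: an elliptical target silhouette per plan/arc,
    # perturbed by smoothed random walks on centre and width per pair.
    y = (np.arange(n_p) - (n_p - 1) / 2.0) / (n_p / 2.0)  # [-1, 1]
    target_half_width = np.maximum(
        0.0, rng.uniform(60.0, 120.0) * np.sqrt(np.maximum(0.0, 1.0 - y**2))
    )
    base_center = rng.uniform(-40.0, 40.0)

    # Random walks along the arc, then smoothed along BOTH the CP axis
    # (delivery is continuous) and the leaf-index axis (apertures conform to
    # smooth organ outlines, so adjacent leaf pairs are strongly correlated).
    pair_window = max(3, n_p // 5)
    center_walk = np.cumsum(rng.normal(0.0, 4.0, size=(n_cp, n_p)), axis=0)
    width_walk = np.cumsum(rng.normal(0.0, 4.0, size=(n_cp, n_p)), axis=0)
    center_walk = _smooth(_smooth(center_walk, config.smoothness), pair_window, axis=1)
    width_walk = _smooth(_smooth(width_walk, config.smoothness), pair_window, axis=1)
    center = base_center + center_walk
    half_width = target_half_width[None, :] + width_walk
    half_width = np.maximum(half_width, m.min_gap / 2.0)

    left_raw = center - half_width
    right_raw = center + half_width

    margin = 1.0  # keep clear of the hard travel limit
    left_raw = np.clip(left_raw, -half + margin, half - margin - m.min_gap)
    right_raw = np.clip(right_raw, left_raw + m.min_gap, half - margin)

    # Forward projection onto the speed-feasible set.
    left = np.empty_like(left_raw)
    right = np.empty_like(right_raw)
    left[0], right[0] = left_raw[0], right_raw[0]
    for k in range(1, n_cp):
        s = m.max_leaf_speed * dg[k - 1]
        l = np.clip(left_raw[k], left[k - 1] - s, left[k - 1] + s)
        r = np.clip(right_raw[k], right[k - 1] - s, right[k - 1] + s)
        # Restore any speed-clipping-induced gap deficit by pulling the
        # banks apart within both the speed window and the travel range;
        # feasible because the previous CP satisfies all constraints.
        deficit = np.maximum(m.min_gap - (r - l), 0.0)
        slack_l = l - np.maximum(left[k - 1] - s, -half)
        slack_r = np.minimum(right[k - 1] + s, half) - r
        dl = np.minimum(deficit / 2.0, slack_l)
        dr = deficit - dl
        over = np.maximum(dr - slack_r, 0.0)
        dr -= over
        dl += over
        left[k] = l - dl
        right[k] = r + dr
    doses = _truncated_normal_doses(config, rng, n_cp)
    return [
        ControlPoint(
            gantry_angle=float(gantry[k]),
            left_positions=left[k],
            right_positions=right[k],
            dose=float(doses[k]),
        )
        for k in range(n_cp)
    ]


def _truncated_normal_doses(
    config: SimConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    sd = config.dose_cv * config.dose_mean
    doses = rng.normal(config.dose_mean, sd, size=n)
    while True:  # redraw instead of clipping to keep the marginal smooth
        neg = doses < 0
        if not neg.any():
            return doses
        doses[neg] = rng.normal(config.dose_mean, sd, size=int(neg.sum()))


def simulate_regular_plan(
    config: SimConfig, rng: np.random.Generator, plan_id: str = "plan"
) -> VMATPlan:
    """One regular plan; its ViolationReport is empty by construction."""
    n_cp = config.cps_per_arc
    arcs = []
    for a in range(config.arcs_per_plan):
        # Full 360deg sweeps, alternating rotation direction (CW then CCW).
        angles = np.linspace(0.0, 360.0 * (n_cp - 1) / n_cp, n_cp)
        if a % 2 == 1:
            angles = angles[::-1].copy()
        arcs.append(_simulate_arc(config, rng, angles))
    return VMATPlan(
        plan_id=plan_id, arcs=arcs, label="regular", machine=config.machine
    )


def inject_anomaly(
    plan: VMATPlan, spec: AnomalySpec, rng: np.random.Generator
) -> VMATPlan:
    """Return a faulted copy of a regular plan; untouched CPs are identical."""
    if spec.kind not in ANOMALY_KINDS:
        raise ValueError(f"unknown anomaly kind {spec.kind!r}")
    out = plan.copy()
    cps = list(out.control_points())
    k_total = len(cps)
    width = max(1, int(spec.width))
    if spec.cp_index is None:
        start = int(rng.integers(0, max(1, k_total - width + 1)))
    else:
        start = int(spec.cp_index)
        if not 0 <= start < k_total:
            raise ValueError(f"cp_index {start} out of range (K={k_total})")
    window = cps[start : start + width]
    mag = float(spec.magnitude)

    if mag > 0:
        if spec.kind == "leaf_jump":
            n_pairs = cps[0].n_pairs
            span = _DEFAULT_PAIRS["leaf_jump"]
            p0 = int(rng.integers(0, max(1, n_pairs - span + 1)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            for cp in window:
                for p in range(p0, min(p0 + span, n_pairs)):
                    cp.left_positions[p] += sign * mag
                    cp.right_positions[p] += sign * mag
        elif spec.kind == "crossed_leaves":
            n_pairs = cps[0].n_pairs
            span = _DEFAULT_PAIRS["crossed_leaves"]
            p0 = int(rng.integers(0, max(1, n_pairs - span + 1)))
            for cp in window:
                for p in range(p0, min(p0 + span, n_pairs)):
                    cp.right_positions[p] = cp.left_positions[p] - mag
        elif spec.kind == "bank_swap":
            for cp in window:
                l = cp.left_positions.copy()
                cp.left_positions = cp.right_positions.copy()
                cp.right_positions = l
        elif spec.kind == "aperture_collapse":
            min_gap = out.machine.min_gap if out.machine else 0.0
            for cp in window:
                gap = cp.right_positions - cp.left_positions
                new_gap = np.maximum(gap - mag, min_gap)
                centre = (cp.right_positions + cp.left_positions) / 2.0
                cp.left_positions = centre - new_gap / 2.0
                cp.right_positions = centre + new_gap / 2.0
        elif spec.kind == "dose_spike":
            for cp in window:
                cp.dose *= 1.0 + mag
        elif spec.kind == "dose_dropout":
            for cp in window:
                cp.dose *= max(0.0, 1.0 - mag)

    out.label = "anomalous"
    out.anomaly_meta = {
        "kind": spec.kind,
        "magnitude": mag,
        "cp_index": start,
        "width": width,
    }
    return out


def make_dataset(config: SimConfig) -> list:
    """n_regular regular + n_anomalous faulted plans, pure in (config, seed)."""
    rng = np.random.default_rng(config.seed)
    plans = [
        simulate_regular_plan(config, rng, plan_id=f"reg{i:04d}")
        for i in range(config.n_regular)
    ]
    kinds = [k for k in ANOMALY_KINDS if config.anomaly_mix.get(k, 0.0) > 0]
    if config.n_anomalous > 0 and not kinds:
        raise ValueError("anomaly_mix has no positive weights")
    weights = np.array([config.anomaly_mix[k] for k in kinds], dtype=float)
    weights /= weights.sum()
    for i in range(config.n_anomalous):
        base = simulate_regular_plan(config, rng, plan_id=f"anom{i:04d}")
        kind = kinds[int(rng.choice(len(kinds), p=weights))]
        plans.append(inject_anomaly(base, AnomalySpec(kind=kind), rng))
    return plans


def dataset_manifest(plans: Sequence[VMATPlan]) -> list:
    """One row per plan: (plan_id, label, kind, magnitude, cp_index)."""
    rows = []
    for p in plans:
        meta = p.anomaly_meta or {}
        rows.append(
            {
                "plan_id": p.plan_id,
                "label": p.label,
                "kind": meta.get("kind", ""),
                "magnitude": meta.get("magnitude", ""),
                "cp_index": meta.get("cp_index", ""),
            }
        )
    return rows
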