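"""Per-control-point feature maps: binary aperture and fluence intensity.

Each control point is digitized on a uniform raster indexed by leaf index i
(rows, along the leaf-index axis) and position index j (columns, along the
leaf-travel axis).  The aperture map A_k(i, j) is 1 where the pixel centre
falls strictly between the left and right leaf of the pair owning row i, and
0 elsewhere; the intensity map is I_k(i, j) = D_k * A_k(i, j) with D_k the
per-CP meterset.  Physical leaf widths are resampled to the raster by row
replication (each pair owns a contiguous block of rows), so a map carries
both the beam geometry and the dosimetric weight of the CP.

Because a fine raster (e.g. 0.1 mm -> 3000 x 4000 px) is far larger than a
practical network input, maps are reduced to a fixed target shape with exact
area-overlap downsampling: the aperture by area-fraction coverage binarized
at >= 0.5, the intensity by area mean.  The downsampling is separable and
valid for non-integer factors, and conserves the map mean exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import h5py
import numpy as np

from .plan_model import ControlPoint, MachineSpec, VMATPlan

__all__ = [
    "RasterGrid",
    "ApertureMap",
    "IntensityMap",
    "FeatureTensor",
    "build_grid",
    "rasterize_aperture",
    "intensity_from_aperture",
    "overlap_matrix",
    "downsample_fraction",
    "featurize_plan",
    "save_feature_tensors",
    "load_feature_tensors",
]


@dataclass(frozen=True)
class RasterGrid:
    """Uniform digitization grid for one machine.

    ``n_leaf_index`` rows cover the field width (leaf-index axis) and
    ``n_position_index`` columns cover the field height (leaf-travel axis),
    both at ``resolution`` mm per pixel.  ``row_of_pair[p]`` is the
    half-open row range [lo, hi) owned by leaf pair p.
    """

    resolution: float
    n_leaf_index: int
    n_position_index: int
    row_of_pair: tuple  # tuple[(lo, hi), ...]
    field_height: float

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_leaf_index, self.n_position_index)

    def column_centers(self) -> np.ndarray:
        """Physical x (mm, isocentre-centred) of each column's pixel centre."""
        j = np.arange(self.n_position_index)
        return -self.field_height / 2.0 + (j + 0.5) * self.resolution


def build_grid(machine: MachineSpec, resolution: float) -> RasterGrid:
    """Digitize a machine's field onto a uniform grid.

    The number of leaf-index rows is field_width / resolution and the number
    of position columns is field_height / resolution (e.g. a 300 mm field at
    0.1 mm gives 3000 rows; a 400 mm travel range gives 4000 columns).  Each
    leaf pair is resampled to round(leaf_width / resolution) contiguous rows.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    n_l = machine.field_width / resolution
    n_p = machine.field_height / resolution
    if abs(n_l - round(n_l)) > 1e-6 or abs(n_p - round(n_p)) > 1e-6:
        raise ValueError(
            f"resolution {resolution} mm does not divide the field extents "
            f"({machine.field_width} x {machine.field_height} mm)"
        )
    rows = []
    lo = 0
    for w in machine.leaf_widths:
        cnt = int(round(w / resolution))
        rows.append((lo, lo + cnt))
        lo += cnt
    if lo != int(round(n_l)):
        raise ValueError(
            "leaf widths do not tile the field width at this resolution"
        )
    return RasterGrid(
        resolution=float(resolution),
        n_leaf_index=int(round(n_l)),
        n_position_index=int(round(n_p)),
        row_of_pair=tuple(rows),
        field_height=machine.field_height,
    )


@dataclass
class ApertureMap:
    """Binary beam-aperture indicator for one control point."""

    values: np.ndarray  # uint8, {0, 1}
    cp_index: int = 0


@dataclass
class IntensityMap:
    """Fluence map for one control point: dose * aperture, elementwise."""

    values: np.ndarray  # float32, >= 0
    cp_index: int = 0


def rasterize_aperture(cp: ControlPoint, grid: RasterGrid) -> ApertureMap:
    """Pixel (i, j) is 1 iff row i belongs to pair p and the pixel-centre x
    of column j lies in the open interval (left_p, right_p).

    A closed pair (left == right) therefore contributes no open pixels.
    """
    if cp.n_pairs != len(grid.row_of_pair):
        raise ValueError(
            f"control point has {cp.n_pairs} pairs, grid expects "
            f"{len(grid.row_of_pair)}"
        )
    x = grid.column_centers()
    out = np.zeros(grid.shape, dtype=np.uint8)
    for p, (lo, hi) in enumerate(grid.row_of_pair):
        row = (x > cp.left_positions[p]) & (x < cp.right_positions[p])
        out[lo:hi] = row.astype(np.uint8)
    return ApertureMap(values=out, cp_index=0)


def intensity_from_aperture(aperture: ApertureMap, dose: float) -> IntensityMap:
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return IntensityMap(
        values=aperture.values.astype(np.float32) * np.float32(dose),
        cp_index=aperture.cp_index,
    )


# ---------------------------------------------------------------------------
# Area-overlap downsampling
# ---------------------------------------------------------------------------

def overlap_matrix(n_src: int, n_tgt: int) -> np.ndarray:
    """Row-stochastic (n_tgt, n_src) matrix of fractional interval overlaps.

    Entry (t, s) is the fraction of target cell t covered by source cell s
    when [0, 1) is split uniformly into n_src and n_tgt cells.  Rows sum to
    1, and every source cell receives total weight n_tgt/n_src, so the map
    mean is conserved exactly for any (integer or not) resize factor.
    """
    if n_tgt > n_src:
        raise ValueError(f"cannot downsample {n_src} -> {n_tgt} (target larger)")
    src_edges = np.linspace(0.0, 1.0, n_src + 1)
    tgt_edges = np.linspace(0.0, 1.0, n_tgt + 1)
    lo = np.maximum.outer(tgt_edges[:-1], src_edges[:-1])
    hi = np.minimum.outer(tgt_edges[1:], src_edges[1:])
    return (np.maximum(hi - lo, 0.0) * n_tgt).astype(np.float64)


def downsample_fraction(values: np.ndarray, target_shape: Tuple[int, int]) -> np.ndarray:
    """Area-mean resize of a 2D (or stacked K x M x N) map."""
    m_src, n_src = values.shape[-2:]
    r = overlap_matrix(m_src, target_shape[0])
    c = overlap_matrix(n_src, target_shape[1])
    return np.einsum(
        "tm,...mn,sn->...ts", r, values.astype(np.float64), c, optimize=True
    )


@dataclass
class FeatureTensor:
    """Network-ready stack of per-CP maps for one plan."""

    apertures: np.ndarray  # (K, M, N) uint8
    intensities: np.ndarray  # (K, M, N) float32
    doses: np.ndarray  # (K,) float32
    plan_id: str = ""
    label: str = "unknown"

    @property
    def n_control_points(self) -> int:
        return self.apertures.shape[0]

    @property
    def map_shape(self) -> Tuple[int, int]:
        return self.apertures.shape[1:]


def featurize_plan(
    plan: VMATPlan,
    grid: RasterGrid,
    target_shape: Optional[Tuple[int, int]] = None,
) -> FeatureTensor:
    """Rasterize every CP of a plan and reduce to the network input shape.

    Equivalent to rasterize -> downsample per CP, but computed on the
    per-pair row structure (all rows of a leaf pair are identical on the
    fine raster), which avoids materializing the fine maps.  The aperture is
    binarized at area-fraction >= 0.5; the intensity is the area mean, i.e.
    dose times the fractional aperture coverage of each target pixel.
    """
    if plan.n_control_points < 1:
        raise ValueError("cannot featurize an empty plan")
    m_src, n_src = grid.shape
    if target_shape is None:
        target_shape = grid.shape
    m_tgt, n_tgt = target_shape
    if m_tgt > m_src or n_tgt > n_src:
        raise ValueError(
            f"target shape {target_shape} exceeds grid shape {grid.shape}"
        )

    cps = list(plan.control_points())
    k_total = len(cps)
    n_pairs = len(grid.row_of_pair)

    # Row-overlap matrix folded through the pair->rows replication: entry
    # (t, p) is the fraction of target row t covered by leaf pair p.
    r = overlap_matrix(m_src, m_tgt)
    pair_rows = np.zeros((m_src, n_pairs))
    for p, (lo, hi) in enumerate(grid.row_of_pair):
        pair_rows[lo:hi, p] = 1.0
    r_pair = r @ pair_rows  # (m_tgt, n_pairs)
    c = overlap_matrix(n_src, n_tgt)  # (n_tgt, n_src)

    x = grid.column_centers()
    left = np.array([cp.left_positions for cp in cps])  # (K, P)
    right = np.array([cp.right_positions for cp in cps])
    doses = np.array([cp.dose for cp in cps], dtype=np.float32)

    # (K, P, n_src) open-interval indicator, then column-overlap reduce.
    open_cols = (x[None, None, :] > left[:, :, None]) & (
        x[None, None, :] < right[:, :, None]
    )
    pair_cov = open_cols.astype(np.float64) @ c.T  # (K, P, n_tgt)
    coverage = np.einsum("tp,kps->kts", r_pair, pair_cov, optimize=True)

    apertures = (coverage >= 0.5).astype(np.uint8)
    intensities = (coverage * doses[:, None, None].astype(np.float64)).astype(
        np.float32
    )
    return FeatureTensor(
        apertures=apertures,
        intensities=intensities,
        doses=doses,
        plan_id=plan.plan_id,
        label=plan.label,
    )


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def save_feature_tensors(tensors: Sequence[FeatureTensor], path, grid_meta: Optional[dict] = None) -> None:
    """Store a dataset of feature tensors in one grouped HDF5 file."""
    with h5py.File(path, "w") as f:
        if grid_meta:
            for k, v in grid_meta.items():
                f.attrs[k] = v
        for t in tensors:
            g = f.create_group(t.plan_id)
            g.create_dataset("apertures", data=t.apertures, dtype="uint8")
            g.create_dataset("intensities", data=t.intensities, dtype="float32")
            g.create_dataset("doses", data=t.doses, dtype="float32")
            g.attrs["plan_id"] = t.plan_id
            g.attrs["label"] = t.label


def load_feature_tensors(path) -> list:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            out.append(
                FeatureTensor(
                    apertures=g["apertures"][()],
                    intensities=g["intensities"][()],
                    doses=g["doses"][()],
                    plan_id=str(g.attrs["plan_id"]),
                    label=str(g.attrs["label"]),
                )
            )
    return out
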