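"""Geometric and kinematic measures: Cobb / TLK angles, per-axis MAE against
reference coordinates, segmental range of motion, and grouped stress maxima.

Cobb is the coronal-plane angle between the superior-endplate line of the
upper end vertebra and the inferior-endplate line of the lower end vertebra;
TLK is the sagittal analogue (default T10 superior to L2 inferior).  Both
are computed on plane projections by default, with a 3D vector-angle mode
available for skew diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from spinefem import fe_solver
from spinefem.mesher import SpineMesh
from spinefem.parameterization import VertebraParams, rotation_matrix


# ---------------------------------------------------------------------------
# Geometry source
# ---------------------------------------------------------------------------


class SpineGeometry:
    """Per-level endplate sample points (A-D style corner points)."""

    def __init__(self, points: dict[str, dict[str, np.ndarray]], levels: list[str]):
        self.points = points
        self.levels = levels

    @classmethod
    def from_params(cls, params: list[VertebraParams]) -> "SpineGeometry":
        pts = {}
        for vp in params:
            lx, ly, lz = vp.lengths
            r = rotation_matrix(vp.beta_deg, vp.theta_deg, vp.phi_deg)
            p0 = np.asarray(vp.p_sup_post)

            def wedge(w_deg):
                w = math.radians(w_deg)
                return np.array(
                    [[math.cos(w), 0, math.sin(w)], [0, 1, 0], [-math.sin(w), 0, math.cos(w)]]
                )

            rs = wedge(vp.beta_sup_deg - vp.beta_deg)
            ri = wedge(vp.beta_inf_deg - vp.beta_deg)
            cs = np.array([0.0, ly / 2, 0.0])
            ci = np.array([0.0, ly / 2, -lz])
            half = np.array([lx / 2, 0.0, 0.0])
            local = {
                "sup_left": cs - rs @ half,
                "sup_right": cs + rs @ half,
                "sup_post": np.array([0.0, 0.0, 0.0]),
                "sup_ant": np.array([0.0, ly, 0.0]),
                "inf_left": ci - ri @ half,
                "inf_right": ci + ri @ half,
                "inf_post": np.array([0.0, 0.0, -lz]),
                "inf_ant": np.array([0.0, ly, -lz]),
            }
            pts[vp.level] = {k: p0 + r @ v for k, v in local.items()}
        return cls(pts, [vp.level for vp in params])

    @classmethod
    def from_mesh(
        cls, spine: SpineMesh, displacements: np.ndarray | None = None
    ) -> "SpineGeometry":
        pts = {}
        for level in spine.levels:
            c = spine.corner_points(level)
            if displacements is not None:
                g = spine.level_grids[level]
                nxp, nyp = g["sup"].shape
                iy, ixm = nyp // 2, nxp // 2
                ids = {
                    "sup_left": g["sup"][0, iy],
                    "sup_right": g["sup"][-1, iy],
                    "sup_post": g["sup"][ixm, 0],
                    "sup_ant": g["sup"][ixm, -1],
                    "inf_left": g["inf"][0, iy],
                    "inf_right": g["inf"][-1, iy],
                    "inf_post": g["inf"][ixm, 0],
                    "inf_ant": g["inf"][ixm, -1],
                }
                c = {k: spine.nodes[v] + displacements[v] for k, v in ids.items()}
            pts[level] = c
        return cls(pts, list(spine.levels))

    def endplate_line(self, level: str, which: str, direction: str) -> np.ndarray:
        pts = self.points[level]
        if direction == "ml":
            a, b = pts[f"{which}_left"], pts[f"{which}_right"]
        else:
            a, b = pts[f"{which}_post"], pts[f"{which}_ant"]
        d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
        if np.linalg.norm(d) < 1e-9:
            raise ValueError(f"coincident endplate points at {level}/{which}")
        return d


@dataclass
class AngleMeasurement:
    name: str
    upper_level: str
    lower_level: str
    plane: str
    value_deg: float
    mode: str = "projected"


def _line_angle_deg(a: np.ndarray, b: np.ndarray, keep: tuple[int, int] | None) -> float:
    if keep is not None:
        a = a[list(keep)]
        b = b[list(keep)]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-9 or nb < 1e-9:
        raise ValueError("endplate line nearly parallel to the projection direction")
    c = abs(float(np.dot(a, b)) / (na * nb))
    return math.degrees(math.acos(min(1.0, c)))


def cobb_angle(
    geometry: SpineGeometry,
    upper_level: str,
    lower_level: str,
    mode: str = "projected",
) -> AngleMeasurement:
    """Coronal Cobb angle between the named end vertebrae, in [0, 90] deg."""
    a = geometry.endplate_line(upper_level, "sup", "ml")
    b = geometry.endplate_line(lower_level, "inf", "ml")
    keep = (0, 2) if mode == "projected" else None  # coronal (X, Z) plane
    val = _line_angle_deg(a, b, keep)
    return AngleMeasurement("Cobb", upper_level, lower_level, "coronal", val, mode)


def tlk_angle(
    geometry: SpineGeometry,
    upper_level: str = "T10",
    lower_level: str = "L2",
    mode: str = "projected",
) -> AngleMeasurement:
    """Sagittal thoracolumbar-kyphosis angle (default T10 sup to L2 inf)."""
    a = geometry.endplate_line(upper_level, "sup", "ap")
    b = geometry.endplate_line(lower_level, "inf", "ap")
    keep = (1, 2) if mode == "projected" else None  # sagittal (Y, Z) plane
    val = _line_angle_deg(a, b, keep)
    return AngleMeasurement("TLK", upper_level, lower_level, "sagittal", val, mode)


def projection_skew_deg(
    geometry: SpineGeometry, upper_level: str, lower_level: str
) -> float:
    """Diagnostic: 3D vector angle minus the projected Cobb (>= 0 with
    axial rotation present; the 2D-vs-3D measurement discrepancy)."""
    v3 = cobb_angle(geometry, upper_level, lower_level, mode="vector3d").value_deg
    v2 = cobb_angle(geometry, upper_level, lower_level, mode="projected").value_deg
    return v3 - v2


# ---------------------------------------------------------------------------
# MAE vs reference coordinates
# ---------------------------------------------------------------------------


@dataclass
class MAEResult:
    mae_mm: tuple[float, float, float]  # (X, Y, Z)
    per_level: pd.DataFrame
    n_levels: int


def _coords_frame(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj[["level", "x_mm", "y_mm", "z_mm"]].copy()
    raise TypeError("expected a DataFrame with level/x_mm/y_mm/z_mm columns")


def mae(model_coords: pd.DataFrame, reference_coords: pd.DataFrame) -> MAEResult:
    """Per-axis mean absolute coordinate error over ordered levels.

    The sum of absolute differences is divided by the number of levels
    (mean), one comparison point per vertebra.
    """
    m = _coords_frame(model_coords)
    r = _coords_frame(reference_coords)
    if list(m["level"]) != list(r["level"]):
        raise ValueError(
            f"level mismatch: {list(m['level'])} vs {list(r['level'])}"
        )
    diff = np.abs(m[["x_mm", "y_mm", "z_mm"]].to_numpy() - r[["x_mm", "y_mm", "z_mm"]].to_numpy())
    per = pd.DataFrame(
        {"level": m["level"], "dx_mm": diff[:, 0], "dy_mm": diff[:, 1], "dz_mm": diff[:, 2]}
    )
    n = len(m)
    return MAEResult(tuple(diff.mean(axis=0)), per, n)


def mae_to_csv(res: MAEResult, path) -> None:
    """Per-level |dX| |dY| |dZ| table (LX/LY/LZ layout)."""
    res.per_level.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Segmental ROM
# ---------------------------------------------------------------------------


@dataclass
class SegmentROM:
    segment: str  # "UPPER-LOWER"
    rom_deg: float
    method: str = "rigid_lsq"


def segmental_rom(
    spine: SpineMesh,
    result: "fe_solver.SolveResult",
    upper_level: str,
    lower_level: str,
) -> SegmentROM:
    """Sagittal rotation of the upper level relative to the lower one
    (flexion positive), from per-vertebra rigid-body least-squares fits."""
    for lvl in (upper_level, lower_level):
        if lvl not in spine.levels:
            raise KeyError(f"level {lvl} not in model")
    ru = fe_solver.vertebra_flexion_deg(spine, result.displacements, upper_level)
    rl = fe_solver.vertebra_flexion_deg(spine, result.displacements, lower_level)
    return SegmentROM(f"{upper_level}-{lower_level}", ru - rl)


def rom_table(
    spine: SpineMesh, result: "fe_solver.SolveResult", segments: list[str]
) -> dict[str, float]:
    out = {}
    for seg in segments:
        upper, lower = seg.split("-")
        out[seg] = segmental_rom(spine, result, upper, lower).rom_deg
    return out


# ---------------------------------------------------------------------------
# Stress maxima
# ---------------------------------------------------------------------------


@dataclass
class StressMax:
    scope: str
    value_kpa: float
    element_kind: str  # "hex" | "truss"
    element_id: int
    side: str


def stress_maxima(
    spine: SpineMesh, result: "fe_solver.SolveResult", scope: str
) -> StressMax:
    """Max centroid von Mises (solids) / axial (trusses) stress over a named
    element group, with the argmax element and a ventral/dorsal side tag."""
    if scope not in spine.elem_groups:
        raise KeyError(f"unknown element group {scope!r}; have {sorted(spine.elem_groups)}")
    g = spine.elem_groups[scope]
    best = (-np.inf, "none", -1)
    hex_ids = np.asarray(g.get("hex", []), dtype=int)
    if hex_ids.size:
        vm = result.hex_vm_kpa[hex_ids]
        i = int(np.argmax(vm))
        best = max(best, (float(vm[i]), "hex", int(hex_ids[i])))
    truss_ids = np.asarray(g.get("truss", []), dtype=int)
    if truss_ids.size:
        ts = result.truss_stress_kpa[truss_ids]
        i = int(np.argmax(ts))
        best = max(best, (float(ts[i]), "truss", int(truss_ids[i])))
    if best[2] < 0:
        raise ValueError(f"element group {scope!r} is empty")
    value, kind, eid = best
    if kind == "hex":
        centroid = spine.nodes[spine.hexes[eid]].mean(axis=0)
        pool = np.vstack(
            [spine.nodes[spine.hexes[h]].mean(axis=0) for h in hex_ids]
        )
    else:
        centroid = spine.nodes[spine.trusses[eid]].mean(axis=0)
        pool = np.vstack(
            [spine.nodes[spine.trusses[t]].mean(axis=0) for t in truss_ids]
        )
    rel = centroid - pool.mean(axis=0)
    side = ("ventral" if rel[1] > 0 else "dorsal") + (
        "-left" if rel[0] < 0 else "-right"
    )
    return StressMax(scope, value, kind, eid, side)
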