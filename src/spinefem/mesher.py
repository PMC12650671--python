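"""Spine mesh construction.

A programmatic template vertebra (rounded-rectangle hex body + block
posterior elements) is morphed and placed per :class:`VertebraParams`;
discs (endplate layers, annulus ground ring, nucleus core, criss-cross
tension-only fibers), seven ligament sets, and optional pedicle-screw /
rod / connector instrumentation are assembled into a single
:class:`SpineMesh`.

Units: mm.  Hex connectivity uses the standard 8-node ordering (bottom
quad counter-clockwise about +z, then the top quad).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from spinefem.levels import is_lumbar, level_index
from spinefem.parameterization import VertebraParams, rotation_matrix

# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Material:
    E: float  # MPa
    nu: float | None = None
    area: float | None = None  # mm^2, line elements only


class MaterialTable(dict):
    """Material name -> properties; defaults follow a validated scoliotic lumbar-spine material card."""

    @classmethod
    def default(cls) -> "MaterialTable":
        t = cls()
        # bone / disc solids
        t["cortical"] = Material(12000.0, 0.3)
        t["cancellous"] = Material(100.0, 0.2)
        t["posterior"] = Material(3500.0, 0.25)
        t["nucleus"] = Material(1.0, 0.499)
        t["ground"] = Material(4.2, 0.46)
        t["endplate"] = Material(24.0, 0.4)
        # line elements (tension-only)
        t["fiber"] = Material(175.0, 0.4, area=0.76)  # area: config default
        t["ALL"] = Material(7.8, area=24.0)
        t["PLL"] = Material(10.0, area=14.4)
        t["TL"] = Material(10.0, area=3.6)
        t["LF"] = Material(15.0, area=40.0)
        t["ISL"] = Material(10.0, area=26.0)
        t["SSL"] = Material(8.0, area=23.0)
        t["CL"] = Material(7.5, area=30.0)
        # instrumentation (not part of the material card; titanium defaults)
        t["implant"] = Material(110000.0, 0.3)
        t["coupling"] = Material(210000.0, 0.3)
        return t

    def require(self, names) -> None:
        missing = [n for n in names if n not in self]
        if missing:
            raise KeyError(f"materials missing from table: {missing}")


LIGAMENT_TYPES = ("ALL", "PLL", "ISL", "SSL", "LF", "TL", "CL")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class DiscConfig:
    nucleus_area_fraction: float = 0.44
    nucleus_posterior_shift: float = 0.10  # fraction of depth toward posterior
    n_core_layers: int = 2
    endplate_fraction: float = 0.12  # of disc height, per endplate layer
    fiber_angle_deg: float = 30.0


@dataclass
class SpineConfig:
    resolution: tuple[int, int, int] = (4, 4, 3)
    disc: DiscConfig = field(default_factory=DiscConfig)
    materials: MaterialTable = field(default_factory=MaterialTable.default)
    ligaments: bool = True
    merge_tol_mm: float = 1e-6


@dataclass
class InstrumentationSpec:
    """Posterior construct layout: which levels carry screws and on which
    side(s), plus section diameters."""

    levels: dict[str, str]  # level -> "bilateral" | "left" | "right"
    screw_diameter_lumbar: float = 6.6
    screw_diameter_thoracic: float = 5.5
    rod_diameter: float = 5.5
    connector_diameter: float = 2.0
    connector_levels: tuple[str, ...] = ("T11", "L2", "L3")
    rod_offset_mm: float = 15.0

    def __post_init__(self):
        for lvl, mode in self.levels.items():
            if mode not in ("bilateral", "left", "right"):
                raise ValueError(
                    f"{lvl}: side must be 'bilateral', 'left' or 'right', got {mode!r}"
                    " (a bare 'unilateral' must specify the side)"
                )
        for d in (
            self.screw_diameter_lumbar,
            self.screw_diameter_thoracic,
            self.rod_diameter,
            self.connector_diameter,
        ):
            if d <= 0:
                raise ValueError("diameters must be > 0")

    @classmethod
    def default_construct(cls) -> "InstrumentationSpec":
        """Bilateral T10-T11 and L1-L4, unilateral T12, connectors at
        T11/L2/L3 (13 screws, 2 rods)."""
        levels = {lvl: "bilateral" for lvl in ("T10", "T11", "L1", "L2", "L3", "L4")}
        levels["T12"] = "left"
        return cls(levels=levels)

    def validate_contiguous(self, chain: list[str]) -> None:
        idx = sorted(level_index(chain, lvl) for lvl in self.levels)
        if idx and idx != list(range(idx[0], idx[-1] + 1)):
            raise ValueError(f"instrumented levels not contiguous: {sorted(self.levels)}")


# ---------------------------------------------------------------------------
# Template vertebra
# ---------------------------------------------------------------------------


def _round_xy(x: np.ndarray, y: np.ndarray, power: float = 4.0):
    """Square -> superellipse cross-section map (canonical frame)."""
    xi = x / 0.5
    eta = (y - 0.5) / 0.5
    m = np.maximum(np.abs(xi), np.abs(eta))
    p4 = (np.abs(xi) ** power + np.abs(eta) ** power) ** (1.0 / power)
    f = np.where(p4 > 1e-12, m / np.maximum(p4, 1e-12), 1.0)
    return 0.5 * xi * f, 0.5 * (eta * f) + 0.5


@dataclass
class TemplateVertebra:
    """Canonical-frame vertebra: body x in [-1/2, 1/2], y in [0, 1]
    (posterior wall at y=0), z in [-1, 0]; superior-posterior point at the
    origin.  Posterior elements hang off the y=0 face."""

    resolution: tuple[int, int, int]
    nodes: np.ndarray  # (N, 3)
    hexes: np.ndarray  # (H, 8)
    hex_tags: np.ndarray  # (H,) str
    sup_grid: np.ndarray  # (nx+1, ny+1) node ids at z=0
    inf_grid: np.ndarray  # node ids at z=-1
    grid_uv: np.ndarray  # (nx+1, ny+1, 2) canonical endplate (x, y)
    attachments: dict[str, int]
    node_sets: dict[str, np.ndarray]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def build_template(resolution: tuple[int, int, int] = (4, 4, 3)) -> TemplateVertebra:
    """Parametric template: extruded rounded-rectangle body grid plus coarse
    hex blocks for pedicles, lamina, spinous and transverse processes."""
    nx, ny, nz = resolution
    if min(nx, ny, nz) < 3:
        raise ValueError(
            f"resolution {resolution} too small: need >= 3 per axis so the "
            "1-element cortical shell encloses at least one cancellous element"
        )

    xs = np.linspace(-0.5, 0.5, nx + 1)
    ys = np.linspace(0.0, 1.0, ny + 1)
    zs = np.linspace(-1.0, 0.0, nz + 1)

    def nid(ix, iy, iz):
        return (ix * (ny + 1) + iy) * (nz + 1) + iz

    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    rx, ry = _round_xy(gx.ravel(), gy.ravel())
    nodes = [np.column_stack([rx, ry, gz.ravel()])]
    n_body = (nx + 1) * (ny + 1) * (nz + 1)

    hexes = []
    tags = []
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                hexes.append(
                    [
                        nid(ix, iy, iz),
                        nid(ix + 1, iy, iz),
                        nid(ix + 1, iy + 1, iz),
                        nid(ix, iy + 1, iz),
                        nid(ix, iy, iz + 1),
                        nid(ix + 1, iy, iz + 1),
                        nid(ix + 1, iy + 1, iz + 1),
                        nid(ix, iy + 1, iz + 1),
                    ]
                )
                shell = (
                    ix in (0, nx - 1) or iy in (0, ny - 1) or iz in (0, nz - 1)
                )
                tags.append("cortical" if shell else "cancellous")

    # ---- posterior elements (canonical block construction) --------------
    dp, dt, ds, tp = 0.30, 0.25, 0.45, 0.35  # pedicle/lamina/spinous/TP extents
    il = max(0, (nx - 3) // 2)
    ir = nx - 1 - il
    iz_p = nz - 1  # posterior structures occupy the top body cell in z
    z1, z2 = zs[iz_p], zs[nz]
    xl = [xs[il], xs[il + 1], xs[ir], xs[ir + 1]]

    extra: list[list[float]] = []

    def new_node(x, y, z) -> int:
        extra.append([x, y, z])
        return n_body + len(extra) - 1

    # lamina node grid: 4 x-lines x 2 y x 2 z
    lam = np.empty((4, 2, 2), dtype=int)  # [x-line, y(0=front,1=back), z(0=z1,1=z2)]
    for a, x in enumerate(xl):
        for b, y in enumerate((-dp, -dp - dt)):
            for c, z in enumerate((z1, z2)):
                lam[a, b, c] = new_node(x, y, z)

    def hex8(b00, b10, b11, b01, kind="posterior"):
        """Build a hex from a bottom quad (z=z1, CCW) and its z=z2 twin."""
        hexes.append([b00[0], b10[0], b11[0], b01[0], b00[1], b10[1], b11[1], b01[1]])
        tags.append(kind)

    def body_face(ixx, iz):
        return (nid(ixx, 0, iz), nid(ixx, 0, iz + 1))

    # pedicles: body face cell -> lamina front
    for side, (ia, ib) in (("L", (il, il + 1)), ("R", (ir, ir + 1))):
        la = 0 if side == "L" else 2
        hex8(
            (lam[la, 0, 0], lam[la, 0, 1]),
            (lam[la + 1, 0, 0], lam[la + 1, 0, 1]),
            body_face(ib, iz_p),
            body_face(ia, iz_p),
        )
    ped_l = len(hexes) - 2
    ped_r = len(hexes) - 1

    # lamina: 3 cells spanning the x-lines
    for a in range(3):
        hex8(
            (lam[a, 1, 0], lam[a, 1, 1]),
            (lam[a + 1, 1, 0], lam[a + 1, 1, 1]),
            (lam[a + 1, 0, 0], lam[a + 1, 0, 1]),
            (lam[a, 0, 0], lam[a, 0, 1]),
        )

    # spinous process off the lamina middle-cell back face
    yb = -dp - dt - ds
    sp = np.empty((2, 2), dtype=int)  # [x-line(1,2), z]
    for a, x in enumerate((xl[1], xl[2])):
        for c, z in enumerate((z1, z2)):
            sp[a, c] = new_node(x, yb, z)
    hex8(
        (sp[0, 0], sp[0, 1]),
        (sp[1, 0], sp[1, 1]),
        (lam[2, 1, 0], lam[2, 1, 1]),
        (lam[1, 1, 0], lam[1, 1, 1]),
    )

    # transverse processes off the pedicle outer faces
    tp_nodes = {}
    for side, ixx, x_out in (("L", il, -0.5 - tp), ("R", ir + 1, 0.5 + tp)):
        t_front = [new_node(x_out, 0.0, z) for z in (z1, z2)]
        t_back = [new_node(x_out, -dp, z) for z in (z1, z2)]
        la = 0 if side == "L" else 3
        if side == "L":
            hex8(
                (t_back[0], t_back[1]),
                (lam[0, 0, 0], lam[0, 0, 1]),
                body_face(il, iz_p),
                (t_front[0], t_front[1]),
            )
        else:
            hex8(
                (lam[3, 0, 0], lam[3, 0, 1]),
                (t_back[0], t_back[1]),
                (t_front[0], t_front[1]),
                body_face(ir + 1, iz_p),
            )
        tp_nodes[side] = t_back  # lateral tip nodes at y=-dp

    nodes.append(np.asarray(extra, dtype=float).reshape(-1, 3))
    all_nodes = np.vstack(nodes)
    hex_arr = np.asarray(hexes, dtype=int)
    tag_arr = np.asarray(tags, dtype=object)

    sup_grid = np.array(
        [[nid(ix, iy, nz) for iy in range(ny + 1)] for ix in range(nx + 1)]
    )
    inf_grid = np.array(
        [[nid(ix, iy, 0) for iy in range(ny + 1)] for ix in range(nx + 1)]
    )
    grid_uv = all_nodes[sup_grid][:, :, :2]

    ix_mid = nx // 2
    attachments = {
        "all_sup": nid(ix_mid, ny, nz),
        "all_inf": nid(ix_mid, ny, 0),
        "pll_sup": nid(ix_mid, 0, nz),
        "pll_inf": nid(ix_mid, 0, 0),
        "spinous_base_sup": int(lam[1, 1, 1]),
        "spinous_base_inf": int(lam[1, 1, 0]),
        "spinous_tip_sup": int(sp[0, 1]),
        "spinous_tip_inf": int(sp[0, 0]),
        "lamina_sup": int(lam[2, 0, 1]),
        "lamina_inf": int(lam[2, 0, 0]),
        "tp_left_sup": int(tp_nodes["L"][1]),
        "tp_left_inf": int(tp_nodes["L"][0]),
        "tp_right_sup": int(tp_nodes["R"][1]),
        "tp_right_inf": int(tp_nodes["R"][0]),
        "facet_left_sup": int(lam[0, 0, 1]),
        "facet_left_inf": int(lam[0, 0, 0]),
        "facet_right_sup": int(lam[3, 0, 1]),
        "facet_right_inf": int(lam[3, 0, 0]),
    }
    if len(set(attachments.values())) != len(attachments):
        raise RuntimeError("template attachment nodes are not unique")

    node_sets = {
        "pedicle_L": np.unique(hex_arr[ped_l]),
        "pedicle_R": np.unique(hex_arr[ped_r]),
    }

    tv = TemplateVertebra(
        resolution=(nx, ny, nz),
        nodes=all_nodes,
        hexes=hex_arr,
        hex_tags=tag_arr,
        sup_grid=sup_grid,
        inf_grid=inf_grid,
        grid_uv=grid_uv,
        attachments=attachments,
        node_sets=node_sets,
    )
    bad = np.flatnonzero(hex_jacobians(all_nodes, hex_arr) <= 0)
    if bad.size:
        raise RuntimeError(f"template has non-positive Jacobians in hexes {bad}")
    return tv


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

# trilinear shape-function derivatives at the element centre
_DN_CENTER = (
    np.array(
        [
            [-1, -1, -1],
            [1, -1, -1],
            [1, 1, -1],
            [-1, 1, -1],
            [-1, -1, 1],
            [1, -1, 1],
            [1, 1, 1],
            [-1, 1, 1],
        ],
        dtype=float,
    )
    / 8.0
)


def hex_jacobians(nodes: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    """Jacobian determinant at each hex centre."""
    coords = nodes[hexes]  # (H, 8, 3)
    jac = np.einsum("ai,haj->hij", _DN_CENTER, coords)
    return np.linalg.det(jac)


def hex_volumes(nodes: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    """Centre-Jacobian volume estimate (exact for parallelepipeds)."""
    return 8.0 * hex_jacobians(nodes, hexes)


# ---------------------------------------------------------------------------
# Morph and place
# ---------------------------------------------------------------------------


@dataclass
class PlacedVertebra:
    level: str
    nodes: np.ndarray
    hexes: np.ndarray
    hex_tags: np.ndarray
    sup_grid: np.ndarray
    inf_grid: np.ndarray
    grid_uv: np.ndarray
    attachments: dict[str, int]
    node_sets: dict[str, np.ndarray]
    params: VertebraParams


def morph_and_place(tpl: TemplateVertebra, vp: VertebraParams) -> PlacedVertebra:
    """Scale, wedge-taper, rotate and translate the template per params.

    The coronal wedge (beta_sup - beta at the top, beta_inf - beta at the
    bottom, linearly blended through the height) is applied about the
    x=0 line of each node layer, so after the whole-body Euler rotation the
    endplate coronal tilts equal beta_sup / beta_inf exactly.
    """
    lx, ly, lz = vp.lengths
    nodes = tpl.nodes * np.array([lx, ly, lz])

    d_sup = math.radians(vp.beta_sup_deg - vp.beta_deg)
    d_inf = math.radians(vp.beta_inf_deg - vp.beta_deg)
    if d_sup or d_inf:
        t = np.clip((nodes[:, 2] + lz) / lz, 0.0, 1.0)
        w = d_inf + (d_sup - d_inf) * t
        x = nodes[:, 0].copy()
        nodes[:, 0] = x * np.cos(w)
        nodes[:, 2] = nodes[:, 2] - x * np.sin(w)

    r = rotation_matrix(vp.beta_deg, vp.theta_deg, vp.phi_deg)
    nodes = nodes @ r.T + np.asarray(vp.p_sup_post)

    bad = np.flatnonzero(hex_jacobians(nodes, tpl.hexes) <= 0)
    if bad.size:
        raise ValueError(
            f"{vp.level}: wedge ({vp.beta_sup_deg - vp.beta_deg:+.1f}/"
            f"{vp.beta_inf_deg - vp.beta_deg:+.1f} deg) inverts hexes {bad[:5]}"
        )
    return PlacedVertebra(
        level=vp.level,
        nodes=nodes,
        hexes=tpl.hexes.copy(),
        hex_tags=tpl.hex_tags.copy(),
        sup_grid=tpl.sup_grid,
        inf_grid=tpl.inf_grid,
        grid_uv=tpl.grid_uv,
        attachments=dict(tpl.attachments),
        node_sets={k: v.copy() for k, v in tpl.node_sets.items()},
        params=vp,
    )


# ---------------------------------------------------------------------------
# Spine mesh container
# ---------------------------------------------------------------------------


@dataclass
class SpineMesh:
    """Assembled global mesh: hex solids, tension-only trusses, beams."""

    nodes: np.ndarray
    hexes: np.ndarray
    hex_tags: np.ndarray
    trusses: np.ndarray  # (T, 2)
    truss_types: np.ndarray  # (T,) str material names
    truss_areas: np.ndarray
    truss_tension_only: np.ndarray
    beams: np.ndarray  # (B, 2)
    beam_tags: np.ndarray
    beam_diameters: np.ndarray
    node_sets: dict[str, np.ndarray]
    elem_groups: dict[str, dict[str, np.ndarray]]
    levels: list[str]
    level_attachments: dict[str, dict[str, int]]
    level_grids: dict[str, dict[str, np.ndarray]]
    couplings: list[tuple[int, np.ndarray]] = field(default_factory=list)
    materials: MaterialTable = field(default_factory=MaterialTable.default)
    n_rods: int = 0

    def manifest(self) -> dict:
        m = {
            "n_nodes": int(len(self.nodes)),
            "n_hexes": int(len(self.hexes)),
            "n_trusses": int(len(self.trusses)),
            "n_beams": int(len(self.beams)),
            "n_levels": len(self.levels),
            "n_discs": sum(1 for g in self.elem_groups if g.startswith("disc:")),
            "hexes_by_tag": {
                t: int(np.sum(self.hex_tags == t)) for t in sorted(set(self.hex_tags))
            },
            "trusses_by_type": {
                t: int(np.sum(self.truss_types == t))
                for t in sorted(set(self.truss_types))
            },
            "beams_by_tag": {
                t: int(np.sum(self.beam_tags == t)) for t in sorted(set(self.beam_tags))
            },
        }
        return m

    def corner_points(self, level: str) -> dict[str, np.ndarray]:
        """Endplate line sample points (A-D style) from the mesh grids."""
        g = self.level_grids[level]
        nxp, nyp = g["sup"].shape
        iy = nyp // 2
        ixm = nxp // 2
        return {
            "sup_left": self.nodes[g["sup"][0, iy]],
            "sup_right": self.nodes[g["sup"][-1, iy]],
            "sup_post": self.nodes[g["sup"][ixm, 0]],
            "sup_ant": self.nodes[g["sup"][ixm, -1]],
            "inf_left": self.nodes[g["inf"][0, iy]],
            "inf_right": self.nodes[g["inf"][-1, iy]],
            "inf_post": self.nodes[g["inf"][ixm, 0]],
            "inf_ant": self.nodes[g["inf"][ixm, -1]],
        }


class _Builder:
    def __init__(self, materials: MaterialTable):
        self.nodes: list[np.ndarray] = []
        self.n_nodes = 0
        self.hexes: list[np.ndarray] = []
        self.hex_tags: list[np.ndarray] = []
        self.trusses: list[tuple[int, int, str, float, bool]] = []
        self.beams: list[tuple[int, int, str, float]] = []
        self.node_sets: dict[str, np.ndarray] = {}
        self.elem_groups: dict[str, dict[str, list[int]]] = {}
        self.materials = materials
        self.n_hexes = 0

    def add_nodes(self, arr: np.ndarray) -> int:
        off = self.n_nodes
        self.nodes.append(np.asarray(arr, dtype=float).reshape(-1, 3))
        self.n_nodes += len(self.nodes[-1])
        return off

    def add_hexes(self, conn: np.ndarray, tags: np.ndarray) -> np.ndarray:
        ids = np.arange(self.n_hexes, self.n_hexes + len(conn))
        self.hexes.append(np.asarray(conn, dtype=int))
        self.hex_tags.append(np.asarray(tags, dtype=object))
        self.n_hexes += len(conn)
        return ids

    def add_truss(self, a: int, b: int, mtype: str, tension_only: bool = True) -> int:
        area = self.materials[mtype].area
        if area is None:
            raise KeyError(f"material {mtype} has no cross-sectional area")
        self.trusses.append((a, b, mtype, area, tension_only))
        return len(self.trusses) - 1

    def add_beam(self, a: int, b: int, tag: str, diameter: float) -> int:
        self.beams.append((a, b, tag, diameter))
        return len(self.beams) - 1

    def group(self, name: str, kind: str, ids) -> None:
        g = self.elem_groups.setdefault(name, {"hex": [], "truss": [], "beam": []})
        g[kind].extend(int(i) for i in np.atleast_1d(ids))

    def all_nodes(self) -> np.ndarray:
        return (
            np.vstack(self.nodes) if self.nodes else np.zeros((0, 3))
        )


# ---------------------------------------------------------------------------
# Disc construction
# ---------------------------------------------------------------------------


def _perimeter_cycle(nxp: int, nyp: int) -> list[tuple[int, int]]:
    cyc = [(ix, 0) for ix in range(nxp)]
    cyc += [(nxp - 1, iy) for iy in range(1, nyp)]
    cyc += [(ix, nyp - 1) for ix in range(nxp - 2, -1, -1)]
    cyc += [(0, iy) for iy in range(nyp - 2, 0, -1)]
    return cyc


def _nucleus_cells(grid_uv: np.ndarray, cfg: DiscConfig) -> np.ndarray:
    """Boolean (nx, ny) mask of nucleus cells: greedily accumulate the cells
    closest to the (posteriorly shifted) centroid until the covered area
    fraction is nearest the target."""
    nxp, nyp, _ = grid_uv.shape
    nx, ny = nxp - 1, nyp - 1
    c00 = grid_uv[:-1, :-1]
    c10 = grid_uv[1:, :-1]
    c11 = grid_uv[1:, 1:]
    c01 = grid_uv[:-1, 1:]
    # shoelace quad areas and centres in the canonical endplate plane
    area = 0.5 * np.abs(
        (c10[..., 0] - c00[..., 0]) * (c01[..., 1] - c00[..., 1])
        - (c01[..., 0] - c00[..., 0]) * (c10[..., 1] - c00[..., 1])
    ) + 0.5 * np.abs(
        (c10[..., 0] - c11[..., 0]) * (c01[..., 1] - c11[..., 1])
        - (c01[..., 0] - c11[..., 0]) * (c10[..., 1] - c11[..., 1])
    )
    centers = 0.25 * (c00 + c10 + c11 + c01)
    total = float(area.sum())
    target = cfg.nucleus_area_fraction * total
    cx, cy = 0.0, 0.5 - cfg.nucleus_posterior_shift
    d = np.hypot((centers[..., 0] - cx) / 0.5, (centers[..., 1] - cy) / 0.5)
    order = np.argsort(d, axis=None, kind="stable")
    mask = np.zeros((nx, ny), dtype=bool)
    acc = 0.0
    for flat in order:
        a = float(area.ravel()[flat])
        if abs(acc + a - target) >= abs(acc - target):
            break
        mask.ravel()[flat] = True
        acc += a
    return mask


def _build_disc(
    b: _Builder,
    nodes_now: np.ndarray,
    lower_grid: np.ndarray,
    upper_grid: np.ndarray,
    grid_uv: np.ndarray,
    cfg: DiscConfig,
    seg_label: str,
    lower_level: str,
    upper_level: str,
) -> None:
    nxp, nyp = lower_grid.shape
    if upper_grid.shape != (nxp, nyp):
        raise ValueError("facing endplate rims have mismatched node layouts")
    lo = nodes_now[lower_grid.ravel()].reshape(nxp, nyp, 3)
    hi = nodes_now[upper_grid.ravel()].reshape(nxp, nyp, 3)
    gap = hi - lo
    # outward (cranial) normal of the lower endplate from its grid axes
    v1 = lo[-1].mean(axis=0) - lo[0].mean(axis=0)
    v2 = lo[:, -1].mean(axis=0) - lo[:, 0].mean(axis=0)
    axis = np.cross(v1, v2)
    axis = axis / np.linalg.norm(axis)
    h = gap.reshape(-1, 3) @ axis
    if np.any(h <= 0):
        raise ValueError(
            f"inverted disc at {seg_label}: negative height on "
            f"{int(np.sum(h <= 0))} node pairs"
        )

    ef = cfg.endplate_fraction
    ncore = cfg.n_core_layers
    fracs = np.concatenate(
        [[0.0, ef], ef + (1 - 2 * ef) * np.arange(1, ncore + 1) / ncore, [1.0]]
    )
    # interface node grids (first/last reuse the bony endplate grids)
    grids = [lower_grid]
    for t in fracs[1:-1]:
        pts = lo + t * gap
        off = b.add_nodes(pts.reshape(-1, 3))
        grids.append(off + np.arange(nxp * nyp).reshape(nxp, nyp))
    grids.append(upper_grid)

    nmask = _nucleus_cells(grid_uv, cfg)
    n_layers = len(grids) - 1
    for layer in range(n_layers):
        ga, gb = grids[layer], grids[layer + 1]
        conn = []
        tags = []
        for ix in range(nxp - 1):
            for iy in range(nyp - 1):
                conn.append(
                    [
                        ga[ix, iy],
                        ga[ix + 1, iy],
                        ga[ix + 1, iy + 1],
                        ga[ix, iy + 1],
                        gb[ix, iy],
                        gb[ix + 1, iy],
                        gb[ix + 1, iy + 1],
                        gb[ix, iy + 1],
                    ]
                )
                if layer == 0 or layer == n_layers - 1:
                    tags.append("endplate")
                elif nmask[ix, iy]:
                    tags.append("nucleus")
                else:
                    tags.append("ground")
        ids = b.add_hexes(np.asarray(conn), np.asarray(tags, dtype=object))
        tags = np.asarray(tags, dtype=object)
        b.group(f"disc:{seg_label}", "hex", ids)
        if layer == 0:
            b.group(f"endplate:{lower_level}:sup", "hex", ids)
        elif layer == n_layers - 1:
            b.group(f"endplate:{upper_level}:inf", "hex", ids)
        else:
            b.group(f"annulus:{seg_label}", "hex", ids[tags == "ground"])
            b.group(f"nucleus:{seg_label}", "hex", ids[tags == "nucleus"])

    # criss-cross fiber families on the annulus perimeter; each fiber picks
    # the ring offset whose inclination to the disc plane is closest to the
    # configured angle (perimeter nodes are discrete, so the angle is only
    # approximated; the per-family mean tracks the target)
    cyc = _perimeter_cycle(nxp, nyp)
    nper = len(cyc)
    all_nodes = b.all_nodes()
    fiber_ids = []
    kmax = max(1, nper // 8)
    target = math.radians(cfg.fiber_angle_deg)
    for layer in range(1, n_layers - 1):
        ga, gb = grids[layer], grids[layer + 1]
        ring_a = np.array([ga[ij] for ij in cyc])
        ring_b = np.array([gb[ij] for ij in cyc])
        pa = all_nodes[ring_a]
        pb = all_nodes[ring_b]
        for i in range(nper):
            for sgn in (+1, -1):
                best_j, best_err = None, np.inf
                for k in range(1, kmax + 1):
                    j = (i + sgn * k) % nper
                    d = pb[j] - pa[i]
                    ln = np.linalg.norm(d)
                    ang = math.asin(min(1.0, abs(d @ axis) / ln))
                    if abs(ang - target) < best_err:
                        best_err, best_j = abs(ang - target), j
                fiber_ids.append(
                    b.add_truss(int(ring_a[i]), int(ring_b[best_j]), "fiber", True)
                )
    b.group(f"annulus:{seg_label}", "truss", fiber_ids)
    b.group(f"disc:{seg_label}", "truss", fiber_ids)


def build_disc(
    lower: PlacedVertebra,
    upper: PlacedVertebra,
    cfg: DiscConfig | None = None,
    materials: MaterialTable | None = None,
) -> SpineMesh:
    """Standalone disc between two placed vertebrae (mostly for testing;
    :func:`assemble_spine` uses the same construction internally)."""
    cfg = cfg or DiscConfig()
    mats = materials or MaterialTable.default()
    b = _Builder(mats)
    off_lo = b.add_nodes(lower.nodes)
    off_hi = b.add_nodes(upper.nodes)
    seg = f"{upper.level}-{lower.level}"
    _build_disc(
        b,
        b.all_nodes(),
        lower.sup_grid + off_lo,
        upper.inf_grid + off_hi,
        lower.grid_uv,
        cfg,
        seg,
        lower.level,
        upper.level,
    )
    return _finalize(b, [lower.level, upper.level], {}, {})


# ---------------------------------------------------------------------------
# Ligaments
# ---------------------------------------------------------------------------

#: strand definitions: type -> list of (upper attachment, lower attachment)
LIGAMENT_STRANDS: dict[str, list[tuple[str, str]]] = {
    "ALL": [("all_inf", "all_sup")],
    "PLL": [("pll_inf", "pll_sup")],
    "ISL": [("spinous_base_inf", "spinous_base_sup")],
    "SSL": [("spinous_tip_inf", "spinous_tip_sup")],
    "LF": [("lamina_inf", "lamina_sup")],
    "TL": [("tp_left_inf", "tp_left_sup"), ("tp_right_inf", "tp_right_sup")],
    "CL": [("facet_left_inf", "facet_left_sup"), ("facet_right_inf", "facet_right_sup")],
}


def attach_ligaments(spine: SpineMesh) -> SpineMesh:
    """Add the seven tension-only ligament sets between adjacent vertebrae."""
    if len(spine.levels) < 2:
        raise ValueError("ligaments need at least two vertebrae")
    new_trusses = []
    groups: dict[str, list[int]] = {}
    t0 = len(spine.trusses)
    for i in range(len(spine.levels) - 1):
        low, up = spine.levels[i], spine.levels[i + 1]
        att_lo = spine.level_attachments[low]
        att_up = spine.level_attachments[up]
        for ltype, strands in LIGAMENT_STRANDS.items():
            area = spine.materials[ltype].area
            for name_up, name_lo in strands:
                for att, name, lvl in ((att_up, name_up, up), (att_lo, name_lo, low)):
                    if name not in att:
                        raise KeyError(
                            f"missing attachment node {name!r} at {lvl} for {ltype}"
                        )
                tid = t0 + len(new_trusses)
                new_trusses.append(
                    (att_up[name_up], att_lo[name_lo], ltype, area, True)
                )
                groups.setdefault(f"ligament:{ltype}", []).append(tid)
                groups.setdefault(f"ligament:{up}-{low}", []).append(tid)

    arr = np.array([(a, b) for a, b, *_ in new_trusses], dtype=int).reshape(-1, 2)
    spine.trusses = np.vstack([spine.trusses, arr]) if len(spine.trusses) else arr
    spine.truss_types = np.concatenate(
        [spine.truss_types, np.array([t for *_ab, t, _a, _t in new_trusses], dtype=object)]
    )
    spine.truss_areas = np.concatenate(
        [spine.truss_areas, np.array([a for *_x, a, _t in new_trusses], dtype=float)]
    )
    spine.truss_tension_only = np.concatenate(
        [spine.truss_tension_only, np.ones(len(new_trusses), dtype=bool)]
    )
    for name, ids in groups.items():
        g = spine.elem_groups.setdefault(name, {"hex": [], "truss": [], "beam": []})
        g["truss"] = np.concatenate(
            [np.asarray(g.get("truss", []), dtype=int), np.asarray(ids, dtype=int)]
        )
    return spine


# ---------------------------------------------------------------------------
# Instrumentation
# ---------------------------------------------------------------------------


def build_instrumentation(spine: SpineMesh, spec: InstrumentationSpec) -> SpineMesh:
    """Add pedicle screws, rods and transverse connectors as beam elements.

    Each screw anchor node sits at its pedicle centroid and is tied to the
    pedicle-region nodes by a stiff beam spider (rigid-coupling stand-in);
    the screw beam runs from the anchor to a rod-line head node offset
    posteriorly; rods chain ipsilateral heads caudal to cranial.
    """
    if not spec.levels:
        return spine  # empty construct: mesh unchanged
    spec.validate_contiguous(spine.levels)
    for lvl in spec.levels:
        if lvl not in spine.levels:
            raise KeyError(f"instrumented level {lvl} not present in spine")
    for lvl in spec.connector_levels:
        if lvl not in spec.levels:
            raise ValueError(f"connector level {lvl} has no screws")

    heads: dict[str, dict[str, int]] = {"left": {}, "right": {}}
    new_nodes: list[np.ndarray] = []
    nid0 = len(spine.nodes)

    def add_node(p: np.ndarray) -> int:
        new_nodes.append(p)
        return nid0 + len(new_nodes) - 1

    beams: list[tuple[int, int, str, float]] = []
    screw_ids, rod_ids, conn_ids = [], [], []

    ordered = sorted(spec.levels, key=lambda l: level_index(spine.levels, l))
    for lvl in ordered:
        mode = spec.levels[lvl]
        sides = ("left", "right") if mode == "bilateral" else (mode,)
        body_nodes = spine.node_sets[f"vertebra:{lvl}"]
        body_c = spine.nodes[body_nodes].mean(axis=0)
        for side in sides:
            ped_set = spine.node_sets[f"pedicle:{lvl}:{'L' if side == 'left' else 'R'}"]
            anchor_p = spine.nodes[ped_set].mean(axis=0)
            anchor = add_node(anchor_p)
            post = anchor_p - body_c
            post = post / np.linalg.norm(post)
            head = add_node(anchor_p + spec.rod_offset_mm * post)
            d = (
                spec.screw_diameter_lumbar
                if is_lumbar(lvl)
                else spec.screw_diameter_thoracic
            )
            screw_ids.append(len(beams))
            beams.append((anchor, head, "screw", d))
            # rigid-coupling spider into the pedicle region
            k = min(8, len(ped_set))
            near = ped_set[
                np.argsort(np.linalg.norm(spine.nodes[ped_set] - anchor_p, axis=1))[:k]
            ]
            spine.couplings.append((anchor, near))
            for nn in near:
                beams.append((anchor, int(nn), "coupling", 3.0))
            heads[side][lvl] = head

    for side in ("left", "right"):
        chain = [heads[side][l] for l in ordered if l in heads[side]]
        for a, b2 in zip(chain[:-1], chain[1:]):
            rod_ids.append(len(beams))
            beams.append((a, b2, "rod", spec.rod_diameter))

    for lvl in spec.connector_levels:
        if lvl not in heads["left"] or lvl not in heads["right"]:
            raise ValueError(f"connector at {lvl} needs screws on both sides")
        conn_ids.append(len(beams))
        beams.append(
            (heads["left"][lvl], heads["right"][lvl], "connector", spec.connector_diameter)
        )

    if new_nodes:
        spine.nodes = np.vstack([spine.nodes, np.asarray(new_nodes)])
    b0 = len(spine.beams)
    arr = np.array([(a, b2) for a, b2, *_ in beams], dtype=int).reshape(-1, 2)
    spine.beams = np.vstack([spine.beams, arr]) if len(spine.beams) else arr
    spine.beam_tags = np.concatenate(
        [spine.beam_tags, np.array([t for *_x, t, _d in beams], dtype=object)]
    )
    spine.beam_diameters = np.concatenate(
        [spine.beam_diameters, np.array([d for *_x, d in beams], dtype=float)]
    )
    for name, ids in (
        ("instrumentation:screws", screw_ids),
        ("instrumentation:rods", rod_ids),
        ("instrumentation:connectors", conn_ids),
    ):
        g = spine.elem_groups.setdefault(name, {"hex": [], "truss": [], "beam": []})
        g["beam"] = np.asarray(ids, dtype=int) + b0
    spine.n_rods = sum(1 for side in ("left", "right") if len(heads[side]) >= 2)
    return spine


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _finalize(
    b: _Builder,
    levels: list[str],
    level_attachments: dict[str, dict[str, int]],
    level_grids: dict[str, dict[str, np.ndarray]],
    node_sets: dict[str, np.ndarray] | None = None,
) -> SpineMesh:
    trusses = np.array([(a, bb) for a, bb, *_ in b.trusses], dtype=int).reshape(-1, 2)
    return SpineMesh(
        nodes=b.all_nodes(),
        hexes=np.vstack(b.hexes) if b.hexes else np.zeros((0, 8), dtype=int),
        hex_tags=(
            np.concatenate(b.hex_tags) if b.hex_tags else np.array([], dtype=object)
        ),
        trusses=trusses,
        truss_types=np.array([t for *_x, t, _a, _to in b.trusses], dtype=object),
        truss_areas=np.array([a for *_x, a, _to in b.trusses], dtype=float),
        truss_tension_only=np.array([to for *_x, to in b.trusses], dtype=bool),
        beams=np.array([(x, y) for x, y, *_ in b.beams], dtype=int).reshape(-1, 2),
        beam_tags=np.array([t for *_x, t, _d in b.beams], dtype=object),
        beam_diameters=np.array([d for *_x, d in b.beams], dtype=float),
        node_sets=node_sets or b.node_sets,
        elem_groups={
            k: {kk: np.asarray(vv, dtype=int) for kk, vv in v.items()}
            for k, v in b.elem_groups.items()
        },
        levels=levels,
        level_attachments=level_attachments,
        level_grids=level_grids,
        materials=b.materials,
    )


def assemble_spine(
    params: list[VertebraParams], config: SpineConfig | None = None
) -> SpineMesh:
    """Merge placed vertebrae and discs into one global mesh with node sets.

    Parameters must be ordered caudal to cranial; n vertebrae produce n-1
    discs.  Ligaments are attached unless ``config.ligaments`` is false.
    """
    if len(params) < 2:
        raise ValueError("need at least two vertebrae")
    config = config or SpineConfig()
    mats = config.materials
    tpl = build_template(config.resolution)
    b = _Builder(mats)

    placed: list[PlacedVertebra] = []
    level_attachments: dict[str, dict[str, int]] = {}
    level_grids: dict[str, dict[str, np.ndarray]] = {}
    node_sets: dict[str, np.ndarray] = {}
    levels = [vp.level for vp in params]
    if len(set(levels)) != len(levels):
        raise ValueError("duplicate level labels")

    for vp in params:
        pv = morph_and_place(tpl, vp)
        off = b.add_nodes(pv.nodes)
        ids = b.add_hexes(pv.hexes + off, pv.hex_tags)
        b.group(f"vertebra:{vp.level}", "hex", ids)
        node_sets[f"vertebra:{vp.level}"] = off + np.arange(len(pv.nodes))
        node_sets[f"pedicle:{vp.level}:L"] = pv.node_sets["pedicle_L"] + off
        node_sets[f"pedicle:{vp.level}:R"] = pv.node_sets["pedicle_R"] + off
        level_attachments[vp.level] = {k: v + off for k, v in pv.attachments.items()}
        level_grids[vp.level] = {
            "sup": pv.sup_grid + off,
            "inf": pv.inf_grid + off,
        }
        placed.append(pv)

    # interpenetration check, then discs
    for i in range(len(params) - 1):
        low, up = levels[i], levels[i + 1]
        nodes_now = b.all_nodes()
        lo_g = level_grids[low]["sup"]
        hi_g = level_grids[up]["inf"]
        gap = nodes_now[hi_g.ravel()] - nodes_now[lo_g.ravel()]
        lo_pts = nodes_now[lo_g.ravel()].reshape(lo_g.shape + (3,))
        v1 = lo_pts[-1].mean(axis=0) - lo_pts[0].mean(axis=0)
        v2 = lo_pts[:, -1].mean(axis=0) - lo_pts[:, 0].mean(axis=0)
        axis = np.cross(v1, v2)
        axis /= np.linalg.norm(axis)
        if np.any(gap @ axis <= 0):
            raise ValueError(f"vertebrae {low} and {up} interpenetrate")
        _build_disc(
            b,
            nodes_now,
            lo_g,
            hi_g,
            tpl.grid_uv,
            config.disc,
            f"{up}-{low}",
            low,
            up,
        )

    node_sets["inferior_fixed"] = level_grids[levels[0]]["inf"].ravel().copy()
    node_sets["load_top"] = level_grids[levels[-1]]["sup"].ravel().copy()

    spine = _finalize(b, levels, level_attachments, level_grids, node_sets)
    _check_no_duplicate_nodes(spine.nodes, config.merge_tol_mm)
    if config.ligaments:
        spine = attach_ligaments(spine)
    return spine


def _check_no_duplicate_nodes(nodes: np.ndarray, tol: float) -> None:
    from scipy.spatial import cKDTree

    tree = cKDTree(nodes)
    pairs = tree.query_pairs(tol)
    if pairs:
        raise ValueError(f"{len(pairs)} duplicate node pairs within {tol} mm")


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_VTK_HEX = 12
_VTK_LINE = 3


def export_mesh(spine: SpineMesh, fmt: str, path: str | Path) -> Path:
    """Write the mesh as VTK .vtu (ascii XML) or Abaqus .inp."""
    path = Path(path)
    if len(spine.hexes) + len(spine.trusses) + len(spine.beams) == 0:
        raise ValueError("refusing to export an empty mesh")
    if fmt == "vtu":
        _write_vtu(spine, path)
    elif fmt == "inp":
        _write_inp(spine, path)
    else:
        raise ValueError(f"unsupported export format {fmt!r} (use 'vtu' or 'inp')")
    return path


def write_manifest(spine: SpineMesh, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spine.manifest(), indent=1, sort_keys=True))


def _cell_tags(spine: SpineMesh) -> list[str]:
    return (
        [str(t) for t in spine.hex_tags]
        + [str(t) for t in spine.truss_types]
        + [f"beam:{t}" for t in spine.beam_tags]
    )


def _write_vtu(spine: SpineMesh, path: Path) -> None:
    tags = _cell_tags(spine)
    uniq = sorted(set(tags))
    tag_ids = {t: i for i, t in enumerate(uniq)}
    cells = (
        [list(h) for h in spine.hexes]
        + [list(t) for t in spine.trusses]
        + [list(bm) for bm in spine.beams]
    )
    types = [_VTK_HEX] * len(spine.hexes) + [_VTK_LINE] * (
        len(spine.trusses) + len(spine.beams)
    )
    offsets = np.cumsum([len(c) for c in cells])
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        fh.write(f"<!-- material tags: {json.dumps(uniq)} -->\n")
        fh.write("<UnstructuredGrid>\n")
        fh.write(f'<Piece NumberOfPoints="{len(spine.nodes)}" NumberOfCells="{len(cells)}">\n')
        fh.write('<Points>\n<DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
        for p in spine.nodes:
            fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        fh.write("</DataArray>\n</Points>\n<Cells>\n")
        fh.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        for c in cells:
            fh.write(" ".join(map(str, c)) + "\n")
        fh.write('</DataArray>\n<DataArray type="Int64" Name="offsets" format="ascii">\n')
        fh.write(" ".join(map(str, offsets)) + "\n")
        fh.write('</DataArray>\n<DataArray type="UInt8" Name="types" format="ascii">\n')
        fh.write(" ".join(map(str, types)) + "\n")
        fh.write("</DataArray>\n</Cells>\n<CellData>\n")
        fh.write('<DataArray type="Int32" Name="material" format="ascii">\n')
        fh.write(" ".join(str(tag_ids[t]) for t in tags) + "\n")
        fh.write("</DataArray>\n</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")


def import_vtu(path: str | Path) -> dict:
    """Re-import a .vtu written by :func:`export_mesh` (round-trip checks)."""
    import xml.etree.ElementTree as ET

    text = Path(path).read_text()
    m = re.search(r"<!-- material tags: (\[.*?\]) -->", text)
    tag_names = json.loads(m.group(1)) if m else []
    root = ET.fromstring(re.sub(r"<!--.*?-->", "", text, flags=re.S))
    piece = root.find(".//Piece")
    arrays = {da.get("Name"): da.text for da in piece.iter("DataArray")}
    pts_text = piece.find("Points/DataArray").text
    nodes = np.array(pts_text.split(), dtype=float).reshape(-1, 3)
    types = np.array(arrays["types"].split(), dtype=int)
    offsets = np.array(arrays["offsets"].split(), dtype=int)
    conn = np.array(arrays["connectivity"].split(), dtype=int)
    mat = np.array(arrays["material"].split(), dtype=int)
    cells = np.split(conn, offsets[:-1])
    tags = [tag_names[i] for i in mat]
    return {
        "nodes": nodes,
        "cells": cells,
        "types": types,
        "tags": tags,
        "counts_by_tag": {t: tags.count(t) for t in set(tags)},
    }


def _write_inp(spine: SpineMesh, path: Path) -> None:
    mats = spine.materials
    with open(path, "w") as fh:
        fh.write("*HEADING\nspinefem export\n*NODE\n")
        for i, p in enumerate(spine.nodes, start=1):
            fh.write(f"{i}, {p[0]:.10g}, {p[1]:.10g}, {p[2]:.10g}\n")
        eid = 1
        sections = []
        for tag in sorted(set(spine.hex_tags)):
            idx = np.flatnonzero(spine.hex_tags == tag)
            fh.write(f"*ELEMENT, TYPE=C3D8, ELSET={tag}\n")
            for h in spine.hexes[idx]:
                fh.write(f"{eid}, " + ", ".join(str(n + 1) for n in h) + "\n")
                eid += 1
            sections.append(("solid", tag))
        for tag in sorted(set(spine.truss_types)):
            idx = np.flatnonzero(spine.truss_types == tag)
            fh.write(f"*ELEMENT, TYPE=T3D2, ELSET={tag}\n")
            for t in spine.trusses[idx]:
                fh.write(f"{eid}, {t[0] + 1}, {t[1] + 1}\n")
                eid += 1
            sections.append(("truss", tag))
        for tag in sorted(set(spine.beam_tags)):
            idx = np.flatnonzero(spine.beam_tags == tag)
            fh.write(f"*ELEMENT, TYPE=B31, ELSET=beam_{tag}\n")
            for bm in spine.beams[idx]:
                fh.write(f"{eid}, {bm[0] + 1}, {bm[1] + 1}\n")
                eid += 1
            sections.append(("beam", tag))
        for kind, tag in sections:
            mat = tag if tag in mats else "implant"
            if kind == "solid":
                fh.write(f"*SOLID SECTION, ELSET={tag}, MATERIAL={mat}\n")
            elif kind == "truss":
                area = mats[mat].area if mats[mat].area else 1.0
                fh.write(f"*SOLID SECTION, ELSET={tag}, MATERIAL={mat}\n{area}\n")
            else:
                idx = np.flatnonzero(spine.beam_tags == tag)
                d = float(spine.beam_diameters[idx[0]])
                fh.write(
                    f"*BEAM SECTION, ELSET=beam_{tag}, MATERIAL={mat}, SECTION=CIRC\n{d / 2}\n"
                )
        for name in sorted(set(list(spine.materials))):
            m = spine.materials[name]
            fh.write(f"*MATERIAL, NAME={name}\n*ELASTIC\n{m.E}, {m.nu if m.nu is not None else 0.3}\n")


def import_inp(path: str | Path) -> dict:
    """Parse the .inp files written by :func:`export_mesh`."""
    counts: dict[str, int] = {}
    sections = []
    n_nodes = 0
    mode = None
    elset = None
    for line in Path(path).read_text().splitlines():
        ls = line.strip()
        if ls.upper().startswith("*NODE"):
            mode = "node"
            continue
        if ls.upper().startswith("*ELEMENT"):
            mode = "elem"
            m = re.search(r"ELSET=(\S+)", ls, re.I)
            elset = m.group(1) if m else "?"
            counts.setdefault(elset, 0)
            continue
        if ls.upper().startswith(("*SOLID SECTION", "*BEAM SECTION")):
            m = re.search(r"ELSET=(\S+?),", ls, re.I)
            sections.append(m.group(1) if m else "?")
            mode = None
            continue
        if ls.startswith("*"):
            mode = None
            continue
        if mode == "node" and ls:
            n_nodes += 1
        elif mode == "elem" and ls:
            counts[elset] += 1
    return {"n_nodes": n_nodes, "counts_by_elset": counts, "sections": sections}
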