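"""Linear-static spine solver.

Hex8 solids (selective reduced integration for near-incompressible
materials), tension-only axial trusses handled by an active-set loop, and
3D shear-deformable circular-section beams.  Units are N / mm / MPa
internally; stresses are reported in kPa at the boundary.

Flexion sign convention: +Y is anterior and +Z up, so a flexion (forward
bending) rotation carries anterior points downward; we report
``flexion = -omega_x`` in degrees so flexion is positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from spinefem.mesher import MaterialTable, SpineMesh

FLEXION_SIGN = -1.0  # flexion angle = FLEXION_SIGN * omega_x (deg)

# ---------------------------------------------------------------------------
# Element stiffness
# ---------------------------------------------------------------------------

_XI = np.array(
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


def _shape_grad(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape-function derivatives dN/dxi at one local point (8, 3)."""
    g = np.empty((8, 3))
    for a in range(8):
        xa, ya, za = _XI[a]
        g[a, 0] = xa * (1 + ya * xi[1]) * (1 + za * xi[2]) / 8.0
        g[a, 1] = ya * (1 + xa * xi[0]) * (1 + za * xi[2]) / 8.0
        g[a, 2] = za * (1 + xa * xi[0]) * (1 + ya * xi[1]) / 8.0
    return g


_GP = np.array(
    [(sx / math.sqrt(3), sy / math.sqrt(3), sz / math.sqrt(3))
     for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
)
_DN_GP = np.stack([_shape_grad(gp) for gp in _GP])  # (8gp, 8, 3)
_DN_0 = _shape_grad(np.zeros(3))


def _grad_det(dn: np.ndarray, coords: np.ndarray):
    """Physical shape gradients and |J| for a batch of elements."""
    jac = np.einsum("ai,eaj->eij", dn, coords)  # J_ij = dx_j/dxi_i
    det = np.linalg.det(jac)
    inv = np.linalg.inv(jac)
    grad = np.einsum("ai,eji->eaj", dn, inv)
    return grad, det


def hex8_stiffness_batch(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """Stiffness (n, 24, 24) for a batch of hex8 elements.

    Uses 2x2x2 Gauss quadrature; for nu > 0.49 the volumetric term is
    under-integrated at the element centre (selective reduced integration)
    to avoid locking.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 8, 3)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    sri = nu > 0.49
    kbulk = lam + 2 * mu / 3
    lam_eff = (lam - kbulk) if sri else lam

    n = len(coords)
    K = np.zeros((n, 8, 3, 8, 3))
    eye = np.eye(3)
    for dn in _DN_GP:
        grad, det = _grad_det(dn, coords)
        if np.any(det <= 0):
            raise ValueError("inverted hex element (non-positive Jacobian)")
        w = det  # unit Gauss weights
        dot = np.einsum("eak,ebk->eab", grad, grad)
        K += mu * np.einsum("e,eab,ij->eaibj", w, dot, eye)
        K += mu * np.einsum("e,ebi,eaj->eaibj", w, grad, grad)
        K += lam_eff * np.einsum("e,eai,ebj->eaibj", w, grad, grad)
    if sri:
        grad, det = _grad_det(_DN_0, coords)
        K += kbulk * np.einsum("e,eai,ebj->eaibj", 8.0 * det, grad, grad)
    return K.reshape(n, 24, 24)


def element_stiffness_hex8(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """24x24 stiffness of a single 8-node hexahedron."""
    return hex8_stiffness_batch(np.asarray(coords)[None], E, nu)[0]


def element_stiffness_truss(
    coords: np.ndarray, E: float, A: float, tension_only: bool = True
) -> np.ndarray:
    """6x6 axial stiffness EA/L along the element axis."""
    p = np.asarray(coords, dtype=float).reshape(2, 3)
    d = p[1] - p[0]
    L = float(np.linalg.norm(d))
    if L <= 0:
        raise ValueError("zero-length truss")
    n = d / L
    nn = np.outer(n, n) * (E * A / L)
    k = np.zeros((6, 6))
    k[:3, :3] = nn
    k[3:, 3:] = nn
    k[:3, 3:] = -nn
    k[3:, :3] = -nn
    return k


def _beam_local(E: float, nu: float, d: float, L: float) -> np.ndarray:
    A = math.pi * d**2 / 4
    I = math.pi * d**4 / 64
    J = math.pi * d**4 / 32
    G = E / (2 * (1 + nu))
    ks = 6 * (1 + nu) / (7 + 6 * nu)  # circular-section shear factor
    phi = 12 * E * I / (G * ks * A * L**2)
    k = np.zeros((12, 12))
    ea, gj = E * A / L, G * J / L
    a = 12 * E * I / (L**3 * (1 + phi))
    b = 6 * E * I / (L**2 * (1 + phi))
    c = (4 + phi) * E * I / (L * (1 + phi))
    e = (2 - phi) * E * I / (L * (1 + phi))
    k[0, 0] = k[6, 6] = ea
    k[0, 6] = k[6, 0] = -ea
    k[3, 3] = k[9, 9] = gj
    k[3, 9] = k[9, 3] = -gj
    # bending in the x-y plane (v, theta_z)
    for (i, j, v) in (
        (1, 1, a), (1, 5, b), (1, 7, -a), (1, 11, b),
        (5, 5, c), (5, 7, -b), (5, 11, e),
        (7, 7, a), (7, 11, -b),
        (11, 11, c),
    ):
        k[i, j] = k[j, i] = v
    # bending in the x-z plane (w, theta_y): mirrored signs
    for (i, j, v) in (
        (2, 2, a), (2, 4, -b), (2, 8, -a), (2, 10, -b),
        (4, 4, c), (4, 8, b), (4, 10, e),
        (8, 8, a), (8, 10, b),
        (10, 10, c),
    ):
        k[i, j] = k[j, i] = v
    return k


def beam_axes(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    dx = p1 - p0
    L = np.linalg.norm(dx)
    if L <= 0:
        raise ValueError("zero-length beam")
    ex = dx / L
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(ex @ ref)) > 0.95:
        ref = np.array([0.0, 1.0, 0.0])
    ey = np.cross(ref, ex)
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    return np.vstack([ex, ey, ez])


def element_stiffness_beam(
    coords: np.ndarray, E: float, nu: float, diameter: float
) -> np.ndarray:
    """12x12 global-frame stiffness of a circular-section Timoshenko beam."""
    if diameter <= 0:
        raise ValueError("beam diameter must be > 0")
    p = np.asarray(coords, dtype=float).reshape(2, 3)
    L = float(np.linalg.norm(p[1] - p[0]))
    lam = beam_axes(p[0], p[1])
    kl = _beam_local(E, nu, diameter, L)
    T = np.zeros((12, 12))
    for blk in range(4):
        T[3 * blk : 3 * blk + 3, 3 * blk : 3 * blk + 3] = lam
    return T.T @ kl @ T


# ---------------------------------------------------------------------------
# DOF bookkeeping
# ---------------------------------------------------------------------------


class DofMap:
    """3 translational DOFs per node; 6 for nodes touched by beams."""

    def __init__(self, n_nodes: int, beam_nodes: np.ndarray):
        self.has_rot = np.zeros(n_nodes, dtype=bool)
        if len(beam_nodes):
            self.has_rot[beam_nodes] = True
        counts = np.where(self.has_rot, 6, 3)
        self.offset = np.concatenate([[0], np.cumsum(counts)])
        self.ndof = int(self.offset[-1])

    def trans(self, nodes) -> np.ndarray:
        nodes = np.atleast_1d(np.asarray(nodes, dtype=int))
        return (self.offset[nodes][:, None] + np.arange(3)).reshape(-1)

    def all_dofs(self, node: int) -> np.ndarray:
        n = 6 if self.has_rot[node] else 3
        return self.offset[node] + np.arange(n)


# ---------------------------------------------------------------------------
# Load cases and results
# ---------------------------------------------------------------------------


@dataclass
class LoadCase:
    """Boundary conditions and applied load.

    ``magnitude`` is in Nm for moments, N for forces; a moment is realised
    as an equal-and-opposite vertical force couple on the anterior/posterior
    halves of the application node set (about the mediolateral X axis).
    """

    name: str = "flexion"
    fixed_set: str = "inferior_fixed"
    load_type: str = "moment"  # "moment" | "force"
    magnitude: float = 10.0
    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)  # force loads only
    apply_set: str = "load_top"
    match_target_deg: float | None = None
    tolerance_deg: float = 0.05

    def __post_init__(self):
        if self.magnitude < 0:
            raise ValueError("load magnitude must be >= 0")
        if self.load_type not in ("moment", "force"):
            raise ValueError(f"unknown load type {self.load_type!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LoadCase":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        if "direction" in d:
            d["direction"] = tuple(d["direction"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = {
            "name": self.name,
            "fixed_set": self.fixed_set,
            "load_type": self.load_type,
            "magnitude": self.magnitude,
            "direction": list(self.direction),
            "apply_set": self.apply_set,
            "match_target_deg": self.match_target_deg,
            "tolerance_deg": self.tolerance_deg,
        }
        Path(path).write_text(yaml.safe_dump(d))


@dataclass
class SolveResult:
    displacements: np.ndarray  # (N, 3) mm
    rotations: np.ndarray  # (N, 3) rad; zero rows for solid-only nodes
    hex_vm_kpa: np.ndarray
    truss_stress_kpa: np.ndarray  # axial, 0 for inactive
    truss_active: np.ndarray
    flexion_deg: float
    load_magnitude: float
    strain_energy: float
    external_work: float
    reactions: np.ndarray  # (n_fixed_dofs,)
    reaction_dofs: np.ndarray
    iterations: list[dict] = field(default_factory=list)

    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in (
                "displacements",
                "rotations",
                "hex_vm_kpa",
                "truss_stress_kpa",
                "truss_active",
                "reactions",
                "reaction_dofs",
            ):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["flexion_deg"] = self.flexion_deg
            f.attrs["load_magnitude"] = self.load_magnitude
            f.attrs["strain_energy"] = self.strain_energy
            f.attrs["external_work"] = self.external_work
            f.attrs["n_iterations"] = len(self.iterations)


class SolverError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _hex_entries(spine: SpineMesh, mats: MaterialTable, dofmap: DofMap):
    rows, cols, vals = [], [], []
    for tag in sorted(set(spine.hex_tags)):
        idx = np.flatnonzero(spine.hex_tags == tag)
        m = mats[tag]
        ke = hex8_stiffness_batch(spine.nodes[spine.hexes[idx]], m.E, m.nu)
        edofs = dofmap.trans(spine.hexes[idx].ravel()).reshape(len(idx), 24)
        rows.append(np.repeat(edofs, 24, axis=1).ravel())
        cols.append(np.tile(edofs, (1, 24)).ravel())
        vals.append(ke.ravel())
    return rows, cols, vals


def _beam_entries(spine: SpineMesh, mats: MaterialTable, dofmap: DofMap):
    rows, cols, vals = [], [], []
    for b in range(len(spine.beams)):
        n0, n1 = spine.beams[b]
        tag = spine.beam_tags[b]
        mname = tag if tag in mats else "implant"
        if tag in ("screw", "rod", "connector"):
            mname = "implant"
        m = mats[mname]
        ke = element_stiffness_beam(
            spine.nodes[[n0, n1]], m.E, m.nu, float(spine.beam_diameters[b])
        )
        ed = np.concatenate([dofmap.all_dofs(n0)[:6], dofmap.all_dofs(n1)[:6]])
        rows.append(np.repeat(ed, 12))
        cols.append(np.tile(ed, 12))
        vals.append(ke.ravel())
    return rows, cols, vals


def _truss_axes(spine: SpineMesh):
    d = spine.nodes[spine.trusses[:, 1]] - spine.nodes[spine.trusses[:, 0]]
    L = np.linalg.norm(d, axis=1)
    if np.any(L <= 0):
        raise ValueError("zero-length truss in mesh")
    return d / L[:, None], L


def _truss_entries(spine, mats, dofmap, active, axes, lengths):
    rows, cols, vals = [], [], []
    for t in np.flatnonzero(active):
        n0, n1 = spine.trusses[t]
        E = mats[spine.truss_types[t]].E
        kscale = E * spine.truss_areas[t] / lengths[t]
        nvec = axes[t]
        nn = kscale * np.outer(nvec, nvec)
        ed = np.concatenate([dofmap.trans(n0), dofmap.trans(n1)])
        ke = np.zeros((6, 6))
        ke[:3, :3] = nn
        ke[3:, 3:] = nn
        ke[:3, 3:] = -nn
        ke[3:, :3] = -nn
        rows.append(np.repeat(ed, 6))
        cols.append(np.tile(ed, 6))
        vals.append(ke.ravel())
    return rows, cols, vals


def build_load_vector(
    spine: SpineMesh, dofmap: DofMap, lc: LoadCase, magnitude: float | None = None
) -> np.ndarray:
    mag = lc.magnitude if magnitude is None else magnitude
    f = np.zeros(dofmap.ndof)
    nodes = spine.node_sets[lc.apply_set]
    if lc.load_type == "force":
        d = np.asarray(lc.direction, dtype=float)
        d = d / np.linalg.norm(d)
        per = mag / len(nodes) * d
        for n in nodes:
            f[dofmap.trans(n)] += per
        return f
    # moment about +X realised as a vertical force couple
    m_nmm = mag * 1000.0
    y = spine.nodes[nodes, 1]
    ant = nodes[y > y.mean()]
    post = nodes[y <= y.mean()]
    if len(ant) == 0 or len(post) == 0:
        raise SolverError("cannot split load node set into anterior/posterior halves")
    ya, yp = spine.nodes[ant, 1].mean(), spine.nodes[post, 1].mean()
    lever = ya - yp
    fz_ant = -m_nmm / lever / len(ant)  # anterior pushed down: flexion
    fz_post = m_nmm / lever / len(post)
    for n in ant:
        f[dofmap.trans(n)[2]] += fz_ant
    for n in post:
        f[dofmap.trans(n)[2]] += fz_post
    return f


def rigid_rotation(coords: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Small-rotation least-squares fit u ~ t + omega x r; returns omega (rad)."""
    r = coords - coords.mean(axis=0)
    du = disp - disp.mean(axis=0)
    rr = r.T @ r
    A = np.trace(rr) * np.eye(3) - rr
    b = np.cross(r, du).sum(axis=0)
    return np.linalg.solve(A, b)


def vertebra_flexion_deg(spine: SpineMesh, result_disp: np.ndarray, level: str) -> float:
    ns = spine.node_sets[f"vertebra:{level}"]
    omega = rigid_rotation(spine.nodes[ns], result_disp[ns])
    return FLEXION_SIGN * math.degrees(omega[0])


# ---------------------------------------------------------------------------
# Solve
# ---------------------------------------------------------------------------


def solve(
    spine: SpineMesh,
    mats: MaterialTable | None = None,
    lc: LoadCase | None = None,
    magnitude: float | None = None,
    max_active_set_iter: int = 50,
) -> SolveResult:
    """Linear-static solve with tension-only active-set iteration.

    Solves, deactivates compressed tension-only line elements, and repeats
    until the active set is stable; oscillating sets are damped by flipping
    only the worst offenders once an element has re-activated twice.
    """
    mats = mats or spine.materials
    lc = lc or LoadCase()
    beam_nodes = np.unique(spine.beams) if len(spine.beams) else np.array([], dtype=int)
    dofmap = DofMap(len(spine.nodes), beam_nodes)

    fixed_nodes = spine.node_sets[lc.fixed_set]
    if len(fixed_nodes) == 0:
        raise SolverError("empty fixed node set")
    fixed = np.concatenate([dofmap.all_dofs(n) for n in fixed_nodes])
    free_mask = np.ones(dofmap.ndof, dtype=bool)
    free_mask[fixed] = False
    free = np.flatnonzero(free_mask)
    perm = -np.ones(dofmap.ndof, dtype=int)
    perm[free] = np.arange(len(free))

    rows_c, cols_c, vals_c = _hex_entries(spine, mats, dofmap)
    br, bc, bv = _beam_entries(spine, mats, dofmap)
    rows_c += br
    cols_c += bc
    vals_c += bv

    f = build_load_vector(spine, dofmap, lc, magnitude)
    mag_used = lc.magnitude if magnitude is None else magnitude

    n_truss = len(spine.trusses)
    axes, lengths = _truss_axes(spine) if n_truss else (np.zeros((0, 3)), np.zeros(0))
    active = np.ones(n_truss, dtype=bool)
    tension_only = spine.truss_tension_only

    u = np.zeros(dofmap.ndof)
    history: set[frozenset] = set()
    reactivations = np.zeros(n_truss, dtype=int)
    prev_active = active.copy()
    iterations: list[dict] = []
    K = None

    for it in range(max_active_set_iter):
        tr_r, tr_c, tr_v = _truss_entries(spine, mats, dofmap, active, axes, lengths)
        rows = np.concatenate([np.concatenate(rows_c), *map(np.asarray, tr_r)]) if tr_r else np.concatenate(rows_c)
        cols = np.concatenate([np.concatenate(cols_c), *map(np.asarray, tr_c)]) if tr_c else np.concatenate(cols_c)
        vals = np.concatenate([np.concatenate(vals_c), *map(np.asarray, tr_v)]) if tr_v else np.concatenate(vals_c)
        K = sp.coo_matrix((vals, (rows, cols)), shape=(dofmap.ndof, dofmap.ndof)).tocsc()
        Kff = K[free][:, free]
        try:
            lu = spla.splu(Kff.tocsc())
        except RuntimeError as exc:
            raise SolverError(f"singular system (under-constrained?): {exc}") from exc
        u = np.zeros(dofmap.ndof)
        u[free] = lu.solve(f[free])
        if not np.all(np.isfinite(u)):
            raise SolverError("non-finite solution; system likely singular")

        if n_truss == 0:
            iterations.append({"iter": it, "n_active": 0, "changed": 0})
            break
        elong = np.einsum(
            "tj,tj->t",
            u_trans(u, dofmap, spine.trusses[:, 1]) - u_trans(u, dofmap, spine.trusses[:, 0]),
            axes,
        )
        want = ~tension_only | (elong > -1e-12)
        changed = np.flatnonzero(want != active)
        iterations.append(
            {"iter": it, "n_active": int(active.sum()), "changed": int(len(changed))}
        )
        if len(changed) == 0:
            break
        newly_on = changed[~active[changed]]
        reactivations[newly_on] += 1
        key = frozenset(np.flatnonzero(want).tolist())
        if key in history or np.any(reactivations[newly_on] >= 2):
            # damped update: flip only the half with the largest violation
            viol = np.abs(elong[changed])
            keep = changed[np.argsort(viol)[::-1][: max(1, len(changed) // 2)]]
            nxt = active.copy()
            nxt[keep] = want[keep]
            want = nxt
        history.add(key)
        prev_active = active
        active = want
    else:
        raise SolverError(
            f"active set did not stabilise in {max_active_set_iter} iterations"
        )

    disp = u_trans(u, dofmap, np.arange(len(spine.nodes))).reshape(-1, 3)
    rot = np.zeros_like(disp)
    rot_nodes = np.flatnonzero(dofmap.has_rot)
    for n in rot_nodes:
        rot[n] = u[dofmap.offset[n] + 3 : dofmap.offset[n] + 6]

    hex_vm, truss_sig = compute_stresses(spine, disp, mats, active, axes, lengths)

    r_full = K @ u - f
    strain_energy = 0.5 * float(u @ (K @ u))
    ext_work = 0.5 * float(f @ u)
    flex = (
        vertebra_flexion_deg(spine, disp, spine.levels[-1])
        - vertebra_flexion_deg(spine, disp, spine.levels[0])
        if spine.levels
        else 0.0
    )

    return SolveResult(
        displacements=disp,
        rotations=rot,
        hex_vm_kpa=hex_vm,
        truss_stress_kpa=truss_sig,
        truss_active=active,
        flexion_deg=flex,
        load_magnitude=mag_used,
        strain_energy=strain_energy,
        external_work=ext_work,
        reactions=r_full[fixed],
        reaction_dofs=fixed,
        iterations=iterations,
    )


def u_trans(u: np.ndarray, dofmap: DofMap, nodes) -> np.ndarray:
    nodes = np.atleast_1d(np.asarray(nodes, dtype=int))
    return u[(dofmap.offset[nodes][:, None] + np.arange(3))].reshape(len(nodes), 3)


# ---------------------------------------------------------------------------
# Stress recovery
# ---------------------------------------------------------------------------


def compute_stresses(
    spine: SpineMesh,
    displacements: np.ndarray,
    mats: MaterialTable | None = None,
    active: np.ndarray | None = None,
    axes: np.ndarray | None = None,
    lengths: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid von Mises stress per hex and axial stress per truss (kPa)."""
    mats = mats or spine.materials
    hex_vm = np.zeros(len(spine.hexes))
    for tag in sorted(set(spine.hex_tags)):
        idx = np.flatnonzero(spine.hex_tags == tag)
        m = mats[tag]
        lam = m.E * m.nu / ((1 + m.nu) * (1 - 2 * m.nu))
        mu = m.E / (2 * (1 + m.nu))
        coords = spine.nodes[spine.hexes[idx]]
        ue = displacements[spine.hexes[idx]]  # (e, 8, 3)
        grad, _ = _grad_det(_DN_0, coords)
        gu = np.einsum("eak,eai->eki", grad, ue)  # du_i/dx_k
        eps = 0.5 * (gu + np.transpose(gu, (0, 2, 1)))
        tr = np.trace(eps, axis1=1, axis2=2)
        sig = 2 * mu * eps + lam * tr[:, None, None] * np.eye(3)
        sd = sig - np.trace(sig, axis1=1, axis2=2)[:, None, None] / 3 * np.eye(3)
        vm = np.sqrt(1.5 * np.einsum("eij,eij->e", sd, sd))
        hex_vm[idx] = vm * 1000.0  # MPa -> kPa
    if len(spine.trusses) == 0:
        return hex_vm, np.zeros(0)
    if axes is None or lengths is None:
        axes, lengths = _truss_axes(spine)
    du = displacements[spine.trusses[:, 1]] - displacements[spine.trusses[:, 0]]
    strain = np.einsum("tj,tj->t", du, axes) / lengths
    E = np.array([mats[t].E for t in spine.truss_types])
    sig = E * strain * 1000.0
    if active is None:
        active = ~spine.truss_tension_only | (strain > -1e-12)
    sig[~active] = 0.0
    return hex_vm, sig


# ---------------------------------------------------------------------------
# Flexion-angle matching
# ---------------------------------------------------------------------------


def match_flexion_angle(
    spine: SpineMesh,
    mats: MaterialTable | None,
    target_deg: float,
    tol_deg: float = 0.05,
    lc: LoadCase | None = None,
    max_iter: int = 30,
) -> tuple[SolveResult, float]:
    """Secant iteration on load magnitude until total flexion hits target.

    Exact in <= 2 solves for a fully linear model; tension-only sets make a
    few more iterations necessary.
    """
    if target_deg < 0:
        raise ValueError("target flexion must be >= 0")
    lc = lc or LoadCase()
    if target_deg == 0:
        res = solve(spine, mats, lc, magnitude=0.0)
        return res, 0.0
    m1 = lc.magnitude if lc.magnitude > 0 else 1.0
    r1 = solve(spine, mats, lc, magnitude=m1)
    a1 = r1.flexion_deg
    if abs(a1 - target_deg) <= tol_deg:
        return r1, m1
    if abs(a1) < 1e-12:
        raise SolverError("model does not flex under load; cannot match angle")
    m2 = m1 * target_deg / a1
    for _ in range(max_iter):
        r2 = solve(spine, mats, lc, magnitude=m2)
        a2 = r2.flexion_deg
        if abs(a2 - target_deg) <= tol_deg:
            return r2, m2
        if abs(a2 - a1) < 1e-12:
            raise SolverError("flexion matching stalled")
        m1, a1, m2 = m2, a2, m2 + (target_deg - a2) * (m2 - m1) / (a2 - a1)
    raise SolverError(f"flexion matching did not converge in {max_iter} iterations")
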