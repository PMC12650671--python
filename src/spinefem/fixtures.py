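"""Synthetic scoliotic-spine fixtures with known ground truth.

Generates biplanar landmark sets (PA + lateral), per-vertebra placement
parameters, and CT-like reference coordinates so the whole pipeline is
testable without any external imaging data.  The coronal deformity is a
single-apex raised-cosine lateral offset whose amplitude is calibrated by
1D root-finding so the end-vertebra endplate tilts reproduce a requested
Cobb angle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from spinefem import parameterization as pz
from spinefem.levels import default_levels, is_lumbar, level_index
from spinefem.parameterization import LandmarkSet, NashMoeTable, VertebraParams, ViewLandmarks


@dataclass
class CoronalCurve:
    apex_level: str = "T12"
    target_cobb_deg: float = 52.0
    span: tuple[str, str] = ("L4", "T9")  # (caudal end, cranial end) of the bump

    def __post_init__(self):
        if self.target_cobb_deg < 0:
            raise ValueError("target_cobb_deg must be >= 0")


@dataclass
class SyntheticSpineSpec:
    """Recipe for one synthetic spine (defaults mimic a thoracolumbar,
    Lenke-5-like single curve over an 18-level L5..C7 stack)."""

    n_vertebrae: int = 18
    level_labels: list[str] | None = None
    vertebral_heights: np.ndarray | None = None  # mm per level
    disc_heights: np.ndarray | float = 8.0  # mm per gap (n-1)
    coronal_curve: CoronalCurve = field(default_factory=CoronalCurve)
    sagittal_profile: np.ndarray | None = None  # theta deg per level
    axial_rotation: np.ndarray | None = None  # phi deg per level
    endplate_wedge: np.ndarray | None = None  # (n, 2) extra (sup, inf) deg
    noise_sd_mm: float = 0.0
    seed: int = 0

    def resolved(self) -> "_ResolvedSpec":
        if self.n_vertebrae < 2:
            raise ValueError("n_vertebrae must be >= 2")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")
        levels = self.level_labels or default_levels(self.n_vertebrae)
        n = len(levels)
        if self.vertebral_heights is None:
            vh = np.array([22.0 if is_lumbar(l) else 18.0 for l in levels])
        else:
            vh = np.asarray(self.vertebral_heights, dtype=float)
        dh = np.asarray(self.disc_heights, dtype=float)
        if dh.ndim == 0:
            dh = np.full(n - 1, float(dh))
        if len(vh) != n or len(dh) != n - 1:
            raise ValueError("height arrays inconsistent with n_vertebrae")
        if np.any(vh <= 0) or np.any(dh <= 0):
            raise ValueError("all heights must be > 0")
        theta = (
            np.asarray(self.sagittal_profile, dtype=float)
            if self.sagittal_profile is not None
            else _default_sagittal(n)
        )
        phi = (
            np.asarray(self.axial_rotation, dtype=float)
            if self.axial_rotation is not None
            else np.zeros(n)
        )
        wedge = (
            np.asarray(self.endplate_wedge, dtype=float)
            if self.endplate_wedge is not None
            else np.zeros((n, 2))
        )
        for arr, name, shape in ((theta, "sagittal_profile", (n,)), (phi, "axial_rotation", (n,)), (wedge, "endplate_wedge", (n, 2))):
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
        widths = np.array([42.0 if is_lumbar(l) else 32.0 for l in levels])
        depths = np.array([34.0 if is_lumbar(l) else 26.0 for l in levels])
        return _ResolvedSpec(levels, vh, dh, theta, phi, wedge, widths, depths, self)


@dataclass
class _ResolvedSpec:
    levels: list[str]
    heights: np.ndarray
    disc_heights: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    wedge: np.ndarray
    widths: np.ndarray
    depths: np.ndarray
    spec: SyntheticSpineSpec


@dataclass
class GroundTruth:
    """Truth channel for round-trip tests."""

    params_per_vertebra: list[VertebraParams]
    true_cobb_deg: float
    true_tlk_deg: float | None
    cobb_levels: tuple[str, str]  # (cranial end vertebra, caudal end vertebra)
    tlk_levels: tuple[str, str] | None
    centerline_points: np.ndarray  # (n, 3) body centres, mm

    @property
    def levels(self) -> list[str]:
        return [vp.level for vp in self.params_per_vertebra]


def _default_sagittal(n: int) -> np.ndarray:
    """Mild lumbar-lordosis / thoracic-kyphosis tilt profile (deg)."""
    t = np.linspace(0.0, 1.0, n)
    return -8.0 * np.exp(-(((t - 0.10) / 0.16) ** 2)) + 9.0 * np.exp(
        -(((t - 0.62) / 0.24) ** 2)
    )


# --- fixtures-local rotation code: kept deliberately separate from the
# parameterization module so truth angles are computed on an independent path.
def _rot_yxz(beta_deg: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    b, t, p = map(math.radians, (beta_deg, theta_deg, phi_deg))
    m_y = np.array([[math.cos(b), 0, math.sin(b)], [0, 1, 0], [-math.sin(b), 0, math.cos(b)]])
    m_x = np.array([[1, 0, 0], [0, math.cos(t), -math.sin(t)], [0, math.sin(t), math.cos(t)]])
    m_z = np.array([[math.cos(p), -math.sin(p), 0], [math.sin(p), math.cos(p), 0], [0, 0, 1]])
    return m_z @ (m_x @ m_y)


def _coronal_line_angle(beta_deg, theta_deg, phi_deg) -> np.ndarray:
    """Coronal (X,Z) projection of the endplate line direction."""
    d = _rot_yxz(beta_deg, theta_deg, phi_deg) @ np.array([1.0, 0.0, 0.0])
    return np.array([d[0], d[2]])


def _angle_between_lines(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    c = abs(float(np.dot(a, b)) / (na * nb))
    return math.degrees(math.acos(min(1.0, c)))


def _bump_offset_and_slope(z: np.ndarray, z_lo: float, z_apex: float, z_hi: float):
    """Unit-amplitude raised-cosine bump x(z) and slope dx/dz."""
    x = np.zeros_like(z)
    s = np.zeros_like(z)
    lo = (z >= z_lo) & (z <= z_apex)
    hi = (z > z_apex) & (z <= z_hi)
    h1, h2 = z_apex - z_lo, z_hi - z_apex
    u = (z[lo] - z_lo) / h1
    x[lo] = 0.5 * (1 - np.cos(np.pi * u))
    s[lo] = 0.5 * np.pi / h1 * np.sin(np.pi * u)
    v = (z[hi] - z_apex) / h2
    x[hi] = 0.5 * (1 + np.cos(np.pi * v))
    s[hi] = -0.5 * np.pi / h2 * np.sin(np.pi * v)
    return x, s


class _Layout:
    """Vertical stacking plus the (amplitude-parametric) coronal bump."""

    def __init__(self, rs: _ResolvedSpec):
        self.rs = rs
        n = len(rs.levels)
        z_inf = np.concatenate(
            [[0.0], np.cumsum(rs.heights[:-1] + rs.disc_heights)]
        )
        self.z_center = z_inf + rs.heights / 2
        cc = rs.spec.coronal_curve
        try:
            i_lo = level_index(rs.levels, cc.span[0])
            i_hi = level_index(rs.levels, cc.span[1])
            i_ap = level_index(rs.levels, cc.apex_level)
        except KeyError as e:
            raise ValueError(f"curve span outside level range: {e}") from e
        if not i_lo < i_ap < i_hi:
            raise ValueError(
                f"curve apex {cc.apex_level} must lie strictly inside span {cc.span}"
            )
        self.z_lo, self.z_ap, self.z_hi = (
            self.z_center[i_lo],
            self.z_center[i_ap],
            self.z_center[i_hi],
        )
        _, self.unit_slope = _bump_offset_and_slope(
            self.z_center, self.z_lo, self.z_ap, self.z_hi
        )
        # clinical end vertebrae = most tilted levels (fixed for any amplitude)
        self.i_end_lo = int(np.argmax(self.unit_slope))
        self.i_end_hi = int(np.argmin(self.unit_slope))

    def beta_deg(self, amplitude: float) -> np.ndarray:
        return np.degrees(np.arctan(amplitude * self.unit_slope))

    def offsets(self, amplitude: float) -> np.ndarray:
        x, _ = _bump_offset_and_slope(self.z_center, self.z_lo, self.z_ap, self.z_hi)
        return amplitude * x

    def cobb_deg(self, amplitude: float) -> float:
        rs = self.rs
        beta = self.beta_deg(amplitude)
        iu, il = self.i_end_hi, self.i_end_lo
        a = _coronal_line_angle(
            beta[iu] + rs.wedge[iu, 0], rs.theta[iu], rs.phi[iu]
        )
        b = _coronal_line_angle(
            beta[il] + rs.wedge[il, 1], rs.theta[il], rs.phi[il]
        )
        return _angle_between_lines(a, b)


def _calibrate_amplitude(layout: _Layout, target_cobb: float) -> float:
    if target_cobb == 0:
        return 0.0
    base = layout.cobb_deg(0.0)
    if base >= target_cobb:
        raise ValueError(
            f"wedge/rotation baseline Cobb {base:.2f} already exceeds target {target_cobb}"
        )
    hi = 10.0
    while layout.cobb_deg(hi) < target_cobb and hi < 1e4:
        hi *= 2
    return float(brentq(lambda a: layout.cobb_deg(a) - target_cobb, 0.0, hi, xtol=1e-10))


def _sagittal_line_angle(beta_deg, theta_deg, phi_deg) -> np.ndarray:
    """Sagittal (Y,Z) projection of the endplate AP line direction."""
    d = _rot_yxz(beta_deg, theta_deg, phi_deg) @ np.array([0.0, 1.0, 0.0])
    return np.array([d[1], d[2]])


def _corner_points_local(lx, ly, lz, w_sup_deg, w_inf_deg) -> dict[str, np.ndarray]:
    """Named sampling points in the canonical vertebra frame.

    Origin at the superior-posterior point; body spans x in [-lx/2, lx/2],
    y in [0, ly] (posterior wall at y=0), z in [-lz, 0].  Endplate corner
    offsets are pre-tilted by the coronal wedge about the endplate centre.
    """

    def wedge_rot(w_deg):
        w = math.radians(w_deg)
        return np.array(
            [[math.cos(w), 0, math.sin(w)], [0, 1, 0], [-math.sin(w), 0, math.cos(w)]]
        )

    c_sup = np.array([0.0, ly / 2, 0.0])
    c_inf = np.array([0.0, ly / 2, -lz])
    r_s, r_i = wedge_rot(w_sup_deg), wedge_rot(w_inf_deg)
    half = np.array([lx / 2, 0.0, 0.0])
    return {
        "sup_post": np.array([0.0, 0.0, 0.0]),
        "sup_ant": np.array([0.0, ly, 0.0]),
        "inf_post": np.array([0.0, 0.0, -lz]),
        "sup_left": c_sup - r_s @ half,
        "sup_right": c_sup + r_s @ half,
        "inf_left": c_inf - r_i @ half,
        "inf_right": c_inf + r_i @ half,
        "waist_left": np.array([-lx / 2, ly / 2, -lz / 2]),
        "waist_right": np.array([lx / 2, ly / 2, -lz / 2]),
    }


def generate_spine(spec: SyntheticSpineSpec) -> tuple[LandmarkSet, GroundTruth]:
    """Build a synthetic spine; returns projected landmarks plus ground truth.

    Deterministic for a given (spec, seed).  The generator's reported Cobb
    and TLK angles are computed on a rotation code path local to this module.
    """
    rs = spec.resolved()
    layout = _Layout(rs)
    amp = _calibrate_amplitude(layout, rs.spec.coronal_curve.target_cobb_deg)
    beta = layout.beta_deg(amp)
    xoff = layout.offsets(amp)
    n = len(rs.levels)
    table = NashMoeTable()

    params: list[VertebraParams] = []
    centerline = np.zeros((n, 3))
    pa_pts: dict[str, dict[str, tuple[float, float]]] = {}
    lat_pts: dict[str, dict[str, tuple[float, float]]] = {}
    rng = np.random.default_rng(rs.spec.seed)
    sd = rs.spec.noise_sd_mm

    for i, level in enumerate(rs.levels):
        lx, ly, lz = rs.widths[i], rs.depths[i], rs.heights[i]
        t, p = float(rs.theta[i]), float(rs.phi[i])
        w_sup, w_inf = float(rs.wedge[i, 0]), float(rs.wedge[i, 1])
        # the body beta is the mean of the endplate tilts (the downstream
        # extraction convention); the residual wedge splits symmetrically
        b = float(beta[i]) + 0.5 * (w_sup + w_inf)
        w_sup, w_inf = w_sup - 0.5 * (w_sup + w_inf), w_inf - 0.5 * (w_sup + w_inf)
        r = _rot_yxz(b, t, p)
        center = np.array([xoff[i], 0.0, layout.z_center[i]])
        centerline[i] = center
        p_sp = center - r @ np.array([0.0, ly / 2, -lz / 2])
        params.append(
            VertebraParams(
                level=level,
                p_sup_post=tuple(float(c) for c in p_sp),
                lengths=(lx, ly, lz),
                theta_deg=t,
                phi_deg=p,
                beta_deg=b,
                beta_sup_deg=b + w_sup,
                beta_inf_deg=b + w_inf,
            )
        )
        local = _corner_points_local(lx, ly, lz, w_sup, w_inf)
        world = {name: p_sp + r @ q for name, q in local.items()}
        pa = {
            name: (float(w[0]), float(w[2]))
            for name, w in world.items()
            if name in pz.PA_POINTS
        }
        # pedicle shadow encodes the Nash-Moe offset ratio along the waist line
        ratio = table.offset_from_phi(p)
        u_wl, v_wl = pa["waist_left"]
        u_wr, v_wr = pa["waist_right"]
        pa["pedicle"] = (u_wl + ratio * (u_wr - u_wl), 0.5 * (v_wl + v_wr))
        lat = {
            name: (float(w[1]), float(w[2]))
            for name, w in world.items()
            if name in pz.LAT_POINTS
        }
        if sd > 0:
            pa = {k: tuple(np.array(v) + rng.normal(0, sd, 2)) for k, v in pa.items()}
            lat = {k: tuple(np.array(v) + rng.normal(0, sd, 2)) for k, v in lat.items()}
        pa_pts[level] = {k: (float(u), float(v)) for k, (u, v) in pa.items()}
        lat_pts[level] = {k: (float(u), float(v)) for k, (u, v) in lat.items()}

    lms = LandmarkSet(
        pa=ViewLandmarks(1.0, 0.0, pa_pts),
        lat=ViewLandmarks(1.0, 0.0, lat_pts),
        levels=list(rs.levels),
    )

    iu, il = layout.i_end_hi, layout.i_end_lo
    cobb = layout.cobb_deg(amp)
    tlk = None
    tlk_levels = None
    if "T10" in rs.levels and "L2" in rs.levels:
        ju, jl = level_index(rs.levels, "T10"), level_index(rs.levels, "L2")
        a = _sagittal_line_angle(beta[ju] + rs.wedge[ju, 0], rs.theta[ju], rs.phi[ju])
        c = _sagittal_line_angle(beta[jl] + rs.wedge[jl, 1], rs.theta[jl], rs.phi[jl])
        tlk = _angle_between_lines(a, c)
        tlk_levels = ("T10", "L2")

    truth = GroundTruth(
        params_per_vertebra=params,
        true_cobb_deg=float(cobb),
        true_tlk_deg=tlk,
        cobb_levels=(rs.levels[iu], rs.levels[il]),
        tlk_levels=tlk_levels,
        centerline_points=centerline,
    )
    return lms, truth


def generate_reference_coords(
    truth: GroundTruth,
    posture_shift: np.ndarray | tuple[float, float, float] | None = None,
    noise_sd_mm: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """CT-like per-vertebra reference coordinates (one point per level).

    The comparison point is the superior-posterior body point, offset by a
    per-level posture shift plus optional Gaussian noise.
    """
    n = len(truth.params_per_vertebra)
    pts = np.array([vp.p_sup_post for vp in truth.params_per_vertebra], dtype=float)
    if posture_shift is None:
        shift = np.zeros((n, 3))
    else:
        shift = np.asarray(posture_shift, dtype=float)
        if shift.shape == (3,):
            shift = np.broadcast_to(shift, (n, 3))
        if shift.shape != (n, 3):
            raise ValueError(f"posture_shift must have shape ({n}, 3) or (3,)")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd_mm, (n, 3)) if noise_sd_mm > 0 else 0.0
    out = pts + shift + noise
    return pd.DataFrame(
        {"level": truth.levels, "x_mm": out[:, 0], "y_mm": out[:, 1], "z_mm": out[:, 2]}
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "params": [
            {
                "level": vp.level,
                "p_sup_post": list(vp.p_sup_post),
                "lengths": list(vp.lengths),
                "theta_deg": vp.theta_deg,
                "phi_deg": vp.phi_deg,
                "beta_deg": vp.beta_deg,
                "beta_sup_deg": vp.beta_sup_deg,
                "beta_inf_deg": vp.beta_inf_deg,
            }
            for vp in truth.params_per_vertebra
        ],
        "true_cobb_deg": truth.true_cobb_deg,
        "true_tlk_deg": truth.true_tlk_deg,
        "cobb_levels": list(truth.cobb_levels),
        "tlk_levels": list(truth.tlk_levels) if truth.tlk_levels else None,
        "centerline_points": truth.centerline_points.tolist(),
    }


def truth_from_dict(d: dict) -> GroundTruth:
    params = [
        VertebraParams(
            level=p["level"],
            p_sup_post=tuple(p["p_sup_post"]),
            lengths=tuple(p["lengths"]),
            theta_deg=p["theta_deg"],
            phi_deg=p["phi_deg"],
            beta_deg=p["beta_deg"],
            beta_sup_deg=p["beta_sup_deg"],
            beta_inf_deg=p["beta_inf_deg"],
        )
        for p in d["params"]
    ]
    return GroundTruth(
        params_per_vertebra=params,
        true_cobb_deg=d["true_cobb_deg"],
        true_tlk_deg=d["true_tlk_deg"],
        cobb_levels=tuple(d["cobb_levels"]),
        tlk_levels=tuple(d["tlk_levels"]) if d["tlk_levels"] else None,
        centerline_points=np.asarray(d["centerline_points"], dtype=float),
    )


def write_fixture(
    lms: LandmarkSet, truth: GroundTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write landmarks (JSON + per-view CSVs) and ground truth (JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "landmarks": out / "landmarks.json",
        "pa_csv": out / "landmarks_pa.csv",
        "lat_csv": out / "landmarks_lat.csv",
        "truth": out / "ground_truth.json",
    }
    pz.write_landmarks(lms, paths["landmarks"])
    pz.write_view_csvs(lms, paths["pa_csv"], paths["lat_csv"])
    paths["truth"].write_text(json.dumps(truth_to_dict(truth), indent=1, sort_keys=True))
    return paths
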