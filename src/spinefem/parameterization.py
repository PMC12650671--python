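"""Landmark calibration and per-vertebra parameter extraction.

Axis convention (package-wide): X mediolateral, Y anterior-posterior
(+Y anterior), Z vertical, right-handed.  The PA view encodes (X, Z), the
lateral view encodes (Y, Z), both in mm after calibration.

Every vertebra is placed from a canonical template by the Y-X-Z Euler chain

    p_world = p_sup_post + Rz(phi) @ Rx(theta) @ Ry(beta) @ p_local

where beta is the frontal-plane (coronal) body rotation, theta the sagittal
tilt and phi the transverse (axial) rotation.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np


SCHEMA_VERSION = "spinefem-landmarks-1"

#: point names required per view for parameter extraction
PA_POINTS = (
    "sup_post",
    "sup_left",
    "sup_right",
    "inf_left",
    "inf_right",
    "waist_left",
    "waist_right",
    "pedicle",
)
LAT_POINTS = ("sup_post", "sup_ant", "inf_post")


# ---------------------------------------------------------------------------
# Euler transform
# ---------------------------------------------------------------------------


def rotation_matrix(beta_deg: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Composed rotation Rz(phi) @ Rx(theta) @ Ry(beta).

    The Ry factor uses the sign convention in which a positive beta maps
    (1,0,0) -> (cos b, 0, -sin b), i.e. tilts the +X side downward.
    """
    b, t, p = (math.radians(a) for a in (beta_deg, theta_deg, phi_deg))
    cb, sb = math.cos(b), math.sin(b)
    ct, st = math.cos(t), math.sin(t)
    cp, sp = math.cos(p), math.sin(p)
    ry = np.array([[cb, 0.0, sb], [0.0, 1.0, 0.0], [-sb, 0.0, cb]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, ct, -st], [0.0, st, ct]])
    rz = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    return rz @ rx @ ry


def euler_transform(
    points: np.ndarray, beta_deg: float, theta_deg: float, phi_deg: float
) -> np.ndarray:
    """Rotate points (..., 3) through the Y-X-Z Euler chain."""
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates")
    r = rotation_matrix(beta_deg, theta_deg, phi_deg)
    return pts @ r.T


# ---------------------------------------------------------------------------
# Nash-Moe axial-rotation grading
# ---------------------------------------------------------------------------

GRADE_NAMES = ("0", "I", "II", "III", "IV")


@dataclass(frozen=True)
class NashMoeTable:
    """Pedicle-offset-ratio to axial-rotation mapping.

    The grade-to-angle values are editable configuration defaults (they are
    not measured quantities); piecewise-linear between the bin knots.
    """

    offsets: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    phis_deg: tuple[float, ...] = (0.0, 5.0, 15.0, 25.0, 35.0)

    def phi_from_offset(self, ratio: float) -> float:
        if not 0.0 <= ratio <= 1.0:
            raise ValueError(f"pedicle offset ratio {ratio} outside [0, 1]")
        return float(np.interp(ratio, self.offsets, self.phis_deg))

    def offset_from_phi(self, phi_deg: float) -> float:
        if not self.phis_deg[0] <= phi_deg <= self.phis_deg[-1]:
            raise ValueError(
                f"phi {phi_deg} outside table range "
                f"[{self.phis_deg[0]}, {self.phis_deg[-1]}]"
            )
        return float(np.interp(phi_deg, self.phis_deg, self.offsets))

    def grade_from_offset(self, ratio: float) -> str:
        if not 0.0 <= ratio <= 1.0:
            raise ValueError(f"pedicle offset ratio {ratio} outside [0, 1]")
        # a ratio exactly on a bin boundary resolves to the lower bin
        idx = int(np.searchsorted(np.asarray(self.offsets[1:]), ratio, side="left"))
        return GRADE_NAMES[idx]


@dataclass(frozen=True)
class NashMoeGrade:
    grade: str
    offset_ratio: float

    def __post_init__(self):
        if self.grade not in GRADE_NAMES:
            raise ValueError(f"unknown Nash-Moe grade {self.grade!r}")


def nash_moe_to_phi(
    grade_or_offset: str | float, table: NashMoeTable | None = None
) -> float:
    """Axial rotation (deg) from a Nash-Moe grade or continuous offset ratio."""
    table = table or NashMoeTable()
    if isinstance(grade_or_offset, str):
        try:
            g = GRADE_NAMES.index(grade_or_offset)
        except ValueError:
            raise ValueError(f"unknown Nash-Moe grade {grade_or_offset!r}") from None
        return table.phis_deg[g]
    return table.phi_from_offset(float(grade_or_offset))


# ---------------------------------------------------------------------------
# Landmark container and IO
# ---------------------------------------------------------------------------


@dataclass
class ViewLandmarks:
    scale_mm_per_px: float
    v_offset_mm: float
    points: dict[str, dict[str, tuple[float, float]]]  # level -> name -> (u, v) px

    def calibrated(self, level: str, name: str) -> tuple[float, float]:
        u, v = self.points[level][name]
        s = self.scale_mm_per_px
        return u * s, v * s + self.v_offset_mm


@dataclass
class LandmarkSet:
    """Calibrated per-level, per-view named points from the two radiographs."""

    pa: ViewLandmarks
    lat: ViewLandmarks
    levels: list[str]

    def validate(self, z_tol_mm: float = 5.0) -> None:
        gaps = []
        for level in self.levels:
            for view_name, view, needed in (
                ("pa", self.pa, PA_POINTS),
                ("lat", self.lat, LAT_POINTS),
            ):
                pts = view.points.get(level)
                if pts is None:
                    gaps.append(f"{level}/{view_name}")
                    continue
                missing = [n for n in needed if n not in pts]
                gaps.extend(f"{level}/{view_name}:{n}" for n in missing)
        if gaps:
            raise ValueError("missing landmarks: " + ", ".join(gaps))
        for view in (self.pa, self.lat):
            if view.scale_mm_per_px <= 0:
                raise ValueError("non-positive view scale")
        for level in self.levels:
            _, z_pa = self.pa.calibrated(level, "sup_post")
            _, z_lat = self.lat.calibrated(level, "sup_post")
            if abs(z_pa - z_lat) > z_tol_mm:
                raise ValueError(
                    f"vertical registration mismatch at {level}: "
                    f"|{z_pa:.2f} - {z_lat:.2f}| > {z_tol_mm} mm"
                )

    def n_points(self) -> int:
        return sum(
            len(v.points.get(level, {})) for level in self.levels for v in (self.pa, self.lat)
        )


def landmarks_to_dict(lms: LandmarkSet) -> dict:
    def view(v: ViewLandmarks) -> dict:
        return {
            "scale_mm_per_px": v.scale_mm_per_px,
            "v_offset_mm": v.v_offset_mm,
            "points": {
                lvl: {name: [float(u), float(vv)] for name, (u, vv) in pts.items()}
                for lvl, pts in v.points.items()
            },
        }

    return {
        "schema": SCHEMA_VERSION,
        "levels": list(lms.levels),
        "views": {"pa": view(lms.pa), "lat": view(lms.lat)},
    }


def landmarks_from_dict(data: dict) -> LandmarkSet:
    if data.get("schema") != SCHEMA_VERSION:
        raise ValueError(f"unsupported landmark schema {data.get('schema')!r}")

    def view(d: dict) -> ViewLandmarks:
        return ViewLandmarks(
            scale_mm_per_px=float(d["scale_mm_per_px"]),
            v_offset_mm=float(d.get("v_offset_mm", 0.0)),
            points={
                lvl: {name: (float(p[0]), float(p[1])) for name, p in pts.items()}
                for lvl, pts in d["points"].items()
            },
        )

    return LandmarkSet(
        pa=view(data["views"]["pa"]),
        lat=view(data["views"]["lat"]),
        levels=list(data["levels"]),
    )


def write_landmarks(lms: LandmarkSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(landmarks_to_dict(lms), indent=1, sort_keys=True))


def read_landmarks(path: str | Path, z_tol_mm: float = 5.0) -> LandmarkSet:
    """Load, calibrate and validate a landmark JSON file."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    lms = landmarks_from_dict(json.loads(p.read_text()))
    lms.validate(z_tol_mm=z_tol_mm)
    return lms


def write_view_csvs(lms: LandmarkSet, pa_path: str | Path, lat_path: str | Path) -> None:
    """Per-view CSV export: level, point_id, u_mm, v_mm (calibrated)."""
    for view, path in ((lms.pa, pa_path), (lms.lat, lat_path)):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["level", "point_id", "u_mm", "v_mm"])
            for level in lms.levels:
                for name in sorted(view.points.get(level, {})):
                    u, v = view.calibrated(level, name)
                    w.writerow([level, name, f"{u:.9g}", f"{v:.9g}"])


# ---------------------------------------------------------------------------
# Vertebra parameters
# ---------------------------------------------------------------------------


@dataclass
class VertebraParams:
    """Placement and shape parameters of one vertebra.

    ``p_sup_post`` is the superior-posterior body point (world mm); lengths
    are the tri-axial body extents; angles in degrees.
    """

    level: str
    p_sup_post: tuple[float, float, float]
    lengths: tuple[float, float, float]  # (Lx, Ly, Lz)
    theta_deg: float = 0.0
    phi_deg: float = 0.0
    beta_deg: float = 0.0
    beta_sup_deg: float = 0.0
    beta_inf_deg: float = 0.0

    def __post_init__(self):
        if any(l <= 0 for l in self.lengths):
            raise ValueError(f"{self.level}: non-positive body length {self.lengths}")
        for name in ("theta_deg", "phi_deg", "beta_deg", "beta_sup_deg", "beta_inf_deg"):
            if abs(getattr(self, name)) >= 90.0:
                raise ValueError(f"{self.level}: |{name}| must be < 90 deg")

    @property
    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.beta_deg, self.theta_deg, self.phi_deg)


PARAM_COLUMNS = (
    "level",
    "px_mm",
    "py_mm",
    "pz_mm",
    "lx_mm",
    "ly_mm",
    "lz_mm",
    "theta_deg",
    "phi_deg",
    "beta_deg",
    "beta_sup_deg",
    "beta_inf_deg",
)


def params_to_csv(params: list[VertebraParams], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PARAM_COLUMNS)
        for vp in params:
            w.writerow(
                [vp.level]
                + [f"{x:.12g}" for x in (*vp.p_sup_post, *vp.lengths)]
                + [
                    f"{x:.12g}"
                    for x in (
                        vp.theta_deg,
                        vp.phi_deg,
                        vp.beta_deg,
                        vp.beta_sup_deg,
                        vp.beta_inf_deg,
                    )
                ]
            )


def params_from_csv(path: str | Path) -> list[VertebraParams]:
    out = []
    with open(path, newline="") as fh:
        rd = csv.DictReader(fh)
        for row in rd:
            out.append(
                VertebraParams(
                    level=row["level"],
                    p_sup_post=(float(row["px_mm"]), float(row["py_mm"]), float(row["pz_mm"])),
                    lengths=(float(row["lx_mm"]), float(row["ly_mm"]), float(row["lz_mm"])),
                    theta_deg=float(row["theta_deg"]),
                    phi_deg=float(row["phi_deg"]),
                    beta_deg=float(row["beta_deg"]),
                    beta_sup_deg=float(row["beta_sup_deg"]),
                    beta_inf_deg=float(row["beta_inf_deg"]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Parameter extraction
# ---------------------------------------------------------------------------


def _line(view: ViewLandmarks, level: str, a: str, b: str) -> tuple[np.ndarray, float]:
    pa = np.array(view.calibrated(level, a))
    pb = np.array(view.calibrated(level, b))
    d = pb - pa
    n = float(np.hypot(*d))
    if n < 1e-9:
        raise ValueError(f"degenerate landmark pair {a}/{b} at {level}")
    return d, n


def _invert_beta(beta_app: float, theta: float, phi: float) -> float:
    """Recover the true coronal tilt from its PA-projected apparent angle.

    For an endplate direction Rz(phi) Rx(theta) Ry(b) x_hat the PA projection
    satisfies tan(b_app) = cos(t) sin(b) / (cos(p) cos(b) - sin(p) sin(t) sin(b)).
    """
    tb = math.tan(beta_app)
    den = math.cos(theta) + tb * math.sin(phi) * math.sin(theta)
    return math.atan2(tb * math.cos(phi), den)


def extract_params(
    lms: LandmarkSet,
    nash_moe: NashMoeTable | None = None,
    phi_override_deg: dict[str, float] | None = None,
) -> list[VertebraParams]:
    """Per-level parameters from calibrated biplanar landmarks.

    View-wise apparent angles are corrected for the cross-talk introduced by
    the other two rotations, so the chain is an exact inverse of the forward
    projection at zero noise.  phi comes from the Nash-Moe pedicle-offset
    mapping unless overridden per level.
    """
    lms.validate()
    table = nash_moe or NashMoeTable()
    out: list[VertebraParams] = []
    for level in lms.levels:
        # --- transverse rotation from the pedicle shadow position
        if phi_override_deg and level in phi_override_deg:
            phi_deg = phi_override_deg[level]
        else:
            u_wl, _ = lms.pa.calibrated(level, "waist_left")
            u_wr, _ = lms.pa.calibrated(level, "waist_right")
            u_p, _ = lms.pa.calibrated(level, "pedicle")
            if abs(u_wr - u_wl) < 1e-9:
                raise ValueError(f"degenerate waist landmarks at {level}")
            ratio = (u_p - u_wl) / (u_wr - u_wl)
            phi_deg = nash_moe_to_phi(min(1.0, max(0.0, ratio)), table)
        phi = math.radians(phi_deg)

        # --- sagittal tilt from the lateral superior endplate line
        d_lat, len_sup_lat = _line(lms.lat, level, "sup_post", "sup_ant")
        theta_app = math.atan2(d_lat[1], d_lat[0])
        theta = math.atan(math.tan(theta_app) * math.cos(phi))

        # --- coronal endplate tilts from the PA endplate lines
        d_sup, len_sup_pa = _line(lms.pa, level, "sup_left", "sup_right")
        d_inf, _ = _line(lms.pa, level, "inf_left", "inf_right")
        beta_sup = _invert_beta(math.atan2(-d_sup[1], d_sup[0]), theta, phi)
        beta_inf = _invert_beta(math.atan2(-d_inf[1], d_inf[0]), theta, phi)
        beta = 0.5 * (beta_sup + beta_inf)

        # --- lengths, undoing projection foreshortening
        r_sup = rotation_matrix(math.degrees(beta_sup), math.degrees(theta), phi_deg)
        dx = r_sup @ np.array([1.0, 0.0, 0.0])
        lx = len_sup_pa / float(np.hypot(dx[0], dx[2]))

        ey, ez = math.cos(phi) * math.cos(theta), math.sin(theta)
        ly = len_sup_lat / float(np.hypot(ey, ez))

        r_body = rotation_matrix(math.degrees(beta), math.degrees(theta), phi_deg)
        fz = r_body @ np.array([0.0, 0.0, 1.0])
        _, len_post_lat = _line(lms.lat, level, "sup_post", "inf_post")
        lz = len_post_lat / float(np.hypot(fz[1], fz[2]))

        # --- superior-posterior point from the PA/lateral fusion
        x_pa, z_pa = lms.pa.calibrated(level, "sup_post")
        y_lat, z_lat = lms.lat.calibrated(level, "sup_post")
        p = (x_pa, y_lat, 0.5 * (z_pa + z_lat))

        out.append(
            VertebraParams(
                level=level,
                p_sup_post=p,
                lengths=(lx, ly, lz),
                theta_deg=math.degrees(theta),
                phi_deg=phi_deg,
                beta_deg=math.degrees(beta),
                beta_sup_deg=math.degrees(beta_sup),
                beta_inf_deg=math.degrees(beta_inf),
            )
        )
    return out
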