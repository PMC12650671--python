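"""End-to-end orchestration: synthetic (or loaded) landmarks -> parameters
-> pre/post meshes -> flexion solves -> measures -> comparison report."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass


from spinefem import fe_solver, fixtures, measure, mesher, report
from spinefem import parameterization as pz

DEFAULT_ROM_SEGMENTS = ("C7-T10", "T9-T10", "T10-L4", "L4-L5")
DEFAULT_STRESS_SCOPES = (
    "endplate:T10:sup",
    "endplate:L4:inf",
    "annulus:T9-T10",
    "annulus:L4-L5",
)


@dataclass
class FullRunConfig:
    seed: int = 0
    target_cobb_deg: float = 52.0
    noise_sd_mm: float = 0.0
    resolution: tuple[int, int, int] = (4, 4, 3)
    moment_nm: float = 10.0
    match_tol_deg: float = 0.05
    rom_segments: tuple[str, ...] = DEFAULT_ROM_SEGMENTS
    stress_scopes: tuple[str, ...] = DEFAULT_STRESS_SCOPES
    instrumentation: mesher.InstrumentationSpec | None = None  # default construct

    def hash(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "cobb": self.target_cobb_deg,
                "noise": self.noise_sd_mm,
                "res": list(self.resolution),
                "moment": self.moment_nm,
                "tol": self.match_tol_deg,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def summarize_solve(
    spine: mesher.SpineMesh,
    result: fe_solver.SolveResult,
    rom_segments,
    stress_scopes,
) -> dict:
    rom = measure.rom_table(spine, result, list(rom_segments))
    stress = {}
    for scope in stress_scopes:
        if scope in spine.elem_groups:
            stress[scope] = measure.stress_maxima(spine, result, scope).value_kpa
    return {
        "rom_deg": rom,
        "total_flexion_deg": result.flexion_deg,
        "stress_max_kpa": stress,
        "load_magnitude": result.load_magnitude,
    }


def full_run(cfg: FullRunConfig | None = None) -> dict:
    """Generate a synthetic scoliotic spine, solve pre-op flexion at the
    configured moment, solve the instrumented post-op model at the matched
    flexion angle, and build the comparison report."""
    cfg = cfg or FullRunConfig()
    spec = fixtures.SyntheticSpineSpec(
        coronal_curve=fixtures.CoronalCurve(target_cobb_deg=cfg.target_cobb_deg),
        noise_sd_mm=cfg.noise_sd_mm,
        seed=cfg.seed,
    )
    lms, truth = fixtures.generate_spine(spec)
    params = pz.extract_params(lms)

    geom = measure.SpineGeometry.from_params(params)
    angles = {
        "cobb": measure.cobb_angle(geom, *truth.cobb_levels).value_deg,
        "tlk": measure.tlk_angle(geom).value_deg,
    }

    mesh_cfg = mesher.SpineConfig(resolution=cfg.resolution)
    pre = mesher.assemble_spine(params, mesh_cfg)
    lc = fe_solver.LoadCase(magnitude=cfg.moment_nm)
    pre_res = fe_solver.solve(pre, None, lc)
    pre_summary = summarize_solve(pre, pre_res, cfg.rom_segments, cfg.stress_scopes)

    post = mesher.assemble_spine(params, mesh_cfg)
    instr = cfg.instrumentation or mesher.InstrumentationSpec.default_construct()
    post = mesher.build_instrumentation(post, instr)
    post_res, post_mag = fe_solver.match_flexion_angle(
        post, None, target_deg=pre_res.flexion_deg, tol_deg=cfg.match_tol_deg, lc=lc
    )
    post_summary = summarize_solve(post, post_res, cfg.rom_segments, cfg.stress_scopes)

    flat_pre = {**pre_summary["rom_deg"], **pre_summary["stress_max_kpa"]}
    flat_post = {**post_summary["rom_deg"], **post_summary["stress_max_kpa"]}
    rep = report.compare(flat_pre, flat_post)
    shares = {}
    block_rows_pre = {
        k: v for k, v in pre_summary["rom_deg"].items() if k in ("C7-T10", "T10-L4", "L4-L5")
    }
    block_rows_post = {
        k: v for k, v in post_summary["rom_deg"].items() if k in ("C7-T10", "T10-L4", "L4-L5")
    }
    if "C7-T10" in block_rows_pre:
        shares = {
            "pre": {"C7-T10": report.mobility_share(block_rows_pre, "C7-T10")},
            "post": {"C7-T10": report.mobility_share(block_rows_post, "C7-T10")},
        }
    rep.mobility_shares = shares
    rep.meta = {
        "seed": cfg.seed,
        "config_hash": cfg.hash(),
        "true_cobb_deg": truth.true_cobb_deg,
        "measured_cobb_deg": angles["cobb"],
        "measured_tlk_deg": angles["tlk"],
        "pre_total_flexion_deg": pre_res.flexion_deg,
        "post_total_flexion_deg": post_res.flexion_deg,
        "post_load_magnitude": post_mag,
        "mesh_manifest_pre": pre.manifest(),
    }
    return {
        "pre_summary": pre_summary,
        "post_summary": post_summary,
        "report": rep,
        "truth": truth,
        "params": params,
        "pre_spine": pre,
        "post_spine": post,
        "pre_result": pre_res,
        "post_result": post_res,
    }
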