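import numpy as np
import pytest

from spinefem import mesher as ms
from spinefem.parameterization import VertebraParams


def _vp(level, z, lx=40.0, ly=30.0, lz=22.0, **kw):
    return VertebraParams(level, (0.0, 0.0, z), (lx, ly, lz), **kw)


# ---------------------------------------------------------------------------
# Template
# ---------------------------------------------------------------------------


def test_template_333_counts():
    t = ms.build_template((3, 3, 3))
    body = np.isin(t.hex_tags, ["cortical", "cancellous"])
    assert body.sum() == 27  # enumerate 3*3*3 grid cells
    assert (t.hex_tags == "cortical").sum() == 26
    assert (t.hex_tags == "cancellous").sum() == 1


def test_template_positive_jacobians():
    for res in ((3, 3, 3), (4, 4, 3), (5, 4, 4)):
        t = ms.build_template(res)
        assert ms.hex_jacobians(t.nodes, t.hexes).min() > 0


def test_template_node_count_monotone():
    assert ms.build_template((4, 4, 4)).n_nodes > ms.build_template((3, 3, 3)).n_nodes


def test_template_too_small():
    with pytest.raises(ValueError, match="resolution"):
        ms.build_template((2, 3, 3))


def test_template_deterministic_counts():
    a = ms.build_template((4, 4, 3))
    b = ms.build_template((4, 4, 3))
    assert a.n_nodes == b.n_nodes and len(a.hexes) == len(b.hexes)
    assert np.array_equal(a.hexes, b.hexes)


def test_template_attachments_unique():
    t = ms.build_template((4, 4, 3))
    ids = list(t.attachments.values())
    assert len(set(ids)) == len(ids)
    assert all(0 <= i < t.n_nodes for i in ids)


# ---------------------------------------------------------------------------
# Morph and place
# ---------------------------------------------------------------------------


def test_morph_identity():
    t = ms.build_template((3, 3, 3))
    pv = ms.morph_and_place(t, VertebraParams("L5", (0, 0, 0), (1.0, 1.0, 1.0)))
    assert np.allclose(pv.nodes, t.nodes, atol=1e-12)


def test_morph_lz_doubles_volume():
    t = ms.build_template((4, 4, 3))
    v1 = ms.hex_volumes(
        ms.morph_and_place(t, _vp("L5", 0, lz=20)).nodes, t.hexes
    )
    v2 = ms.hex_volumes(
        ms.morph_and_place(t, _vp("L5", 0, lz=40)).nodes, t.hexes
    )
    assert np.allclose(v2, 2 * v1, rtol=1e-9)


def test_morph_wedge_plane_fit():
    """beta_sup=10, beta_inf=0: superior endplate normal tilts 10 deg in the
    coronal plane (least-squares plane fit oracle)."""
    t = ms.build_template((4, 4, 3))
    vp = _vp("L5", 0, beta_deg=5.0, beta_sup_deg=10.0, beta_inf_deg=0.0)
    pv = ms.morph_and_place(t, vp)
    pts = pv.nodes[pv.sup_grid.ravel()]
    # plane fit: normal = smallest singular vector of centred points
    c = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(c)
    n = vt[-1]
    n = n / np.linalg.norm(n) * np.sign(n[2])
    tilt = np.degrees(np.arctan2(abs(n[0]), n[2]))
    assert tilt == pytest.approx(10.0, abs=1e-6)
    # inferior endplate stays horizontal
    pts_i = pv.nodes[pv.inf_grid.ravel()]
    assert np.ptp(pts_i[:, 2]) < 1e-9


def test_morph_excessive_wedge_errors():
    t = ms.build_template((3, 3, 3))
    vp = _vp("L5", 0, lz=2.0, beta_sup_deg=80.0)
    with pytest.raises(ValueError, match="L5"):
        ms.morph_and_place(t, vp)


# ---------------------------------------------------------------------------
# Discs
# ---------------------------------------------------------------------------


def test_disc_parallel_endplates_uniform_height():
    spine = ms.assemble_spine(
        [_vp("L5", 22.0), _vp("L4", 52.0)], ms.SpineConfig(resolution=(4, 4, 3))
    )
    lo = spine.level_grids["L5"]["sup"].ravel()
    hi = spine.level_grids["L4"]["inf"].ravel()
    h = spine.nodes[hi, 2] - spine.nodes[lo, 2]
    assert np.allclose(h, 8.0, atol=1e-9)


def test_disc_fiber_angle_families():
    """Family-mean fiber inclination to the transverse plane ~ +-30 deg
    (arccos-of-direction oracle on the built mesh)."""
    spine = ms.assemble_spine(
        [_vp("L5", 22.0, ly=36.0), _vp("L4", 52.0, ly=36.0)],
        ms.SpineConfig(resolution=(8, 8, 3)),
    )
    fib = spine.elem_groups["annulus:L4-L5"]["truss"]
    d = spine.nodes[spine.trusses[fib][:, 1]] - spine.nodes[spine.trusses[fib][:, 0]]
    ang = np.degrees(np.arcsin(np.abs(d[:, 2]) / np.linalg.norm(d, axis=1)))
    assert ang.mean() == pytest.approx(30.0, abs=2.0)
    # criss-cross: both in-plane winding senses present
    phi = np.arctan2(d[:, 1], d[:, 0])
    assert (phi > 0).any() and (phi < 0).any()


def test_disc_nucleus_area_fraction():
    spine = ms.assemble_spine(
        [_vp("L5", 22.0), _vp("L4", 52.0)], ms.SpineConfig(resolution=(8, 8, 3))
    )
    vn = ms.hex_volumes(
        spine.nodes, spine.hexes[spine.elem_groups["nucleus:L4-L5"]["hex"]]
    ).sum()
    va = ms.hex_volumes(
        spine.nodes, spine.hexes[spine.elem_groups["annulus:L4-L5"]["hex"]]
    ).sum()
    assert vn / (vn + va) == pytest.approx(0.44, abs=0.02)


def test_disc_inverted_error():
    t = ms.build_template((3, 3, 3))
    lo = ms.morph_and_place(t, _vp("L5", 22.0))
    hi = ms.morph_and_place(t, _vp("L4", 20.0))  # overlaps the lower vertebra
    with pytest.raises(ValueError, match="inverted|interpenetrat"):
        ms.build_disc(lo, hi)


def test_standalone_build_disc_counts():
    t = ms.build_template((3, 3, 3))
    lo = ms.morph_and_place(t, _vp("L5", 22.0))
    hi = ms.morph_and_place(t, _vp("L4", 52.0))
    disc = ms.build_disc(lo, hi)
    # 3x3 cells x (2 endplate + 2 core) layers
    assert len(disc.hexes) == 9 * 4
    assert (disc.truss_types == "fiber").all()


# ---------------------------------------------------------------------------
# Ligaments
# ---------------------------------------------------------------------------


def test_ligament_counts_18(params18):
    spine = ms.assemble_spine(params18, ms.SpineConfig(resolution=(3, 3, 3)))
    lig = ~np.isin(spine.truss_types, ["fiber"])
    assert lig.sum() == 17 * 9  # 7 types, TL and CL bilateral
    assert lig.sum() >= 119
    for lt in ms.LIGAMENT_TYPES:
        n = (spine.truss_types == lt).sum()
        assert n == (34 if lt in ("TL", "CL") else 17)


def test_ligament_counts_two_level(spine2):
    for lt in ms.LIGAMENT_TYPES:
        n = (spine2.truss_types == lt).sum()
        assert n == (2 if lt in ("TL", "CL") else 1)
    assert spine2.truss_tension_only.all()


def test_ligaments_single_vertebra_error(two_level_params):
    spine = ms.assemble_spine(two_level_params, ms.SpineConfig(resolution=(3, 3, 3)))
    spine.levels = spine.levels[:1]
    with pytest.raises(ValueError):
        ms.attach_ligaments(spine)


def test_missing_attachment_error(two_level_params):
    spine = ms.assemble_spine(
        two_level_params, ms.SpineConfig(resolution=(3, 3, 3), ligaments=False)
    )
    del spine.level_attachments["L4"]["all_inf"]
    with pytest.raises(KeyError, match="all_inf"):
        ms.attach_ligaments(spine)


# ---------------------------------------------------------------------------
# Instrumentation
# ---------------------------------------------------------------------------


def test_default_construct_counts(params18):
    spine = ms.assemble_spine(params18, ms.SpineConfig(resolution=(3, 3, 3)))
    spine = ms.build_instrumentation(spine, ms.InstrumentationSpec.default_construct())
    m = spine.manifest()
    # 2*2 (T10, T11) + 1 (T12) + 2*4 (L1..L4) = 13 screws
    assert m["beams_by_tag"]["screw"] == 13
    assert m["beams_by_tag"]["connector"] == 3
    assert spine.n_rods == 2
    assert m["beams_by_tag"]["rod"] == 6 + 5  # left chain 7 heads, right 6


def test_screw_diameters(params18):
    spine = ms.assemble_spine(params18, ms.SpineConfig(resolution=(3, 3, 3)))
    spine = ms.build_instrumentation(spine, ms.InstrumentationSpec.default_construct())
    screws = spine.elem_groups["instrumentation:screws"]["beam"]
    d = spine.beam_diameters[screws]
    assert set(np.round(d, 3)) == {5.5, 6.6}
    rods = spine.elem_groups["instrumentation:rods"]["beam"]
    assert np.allclose(spine.beam_diameters[rods], 5.5)
    conns = spine.elem_groups["instrumentation:connectors"]["beam"]
    assert np.allclose(spine.beam_diameters[conns], 2.0)


def test_empty_instrumentation_noop(spine2):
    before = spine2.manifest()
    out = ms.build_instrumentation(
        ms.assemble_spine(
            [_vp("L5", 22.0), _vp("L4", 52.0)], ms.SpineConfig(resolution=(4, 4, 3))
        ),
        ms.InstrumentationSpec(levels={}),
    )
    assert out.manifest()["n_beams"] == 0
    assert out.manifest()["n_hexes"] == before["n_hexes"]


def test_unspecified_unilateral_side_error():
    with pytest.raises(ValueError, match="side"):
        ms.InstrumentationSpec(levels={"T12": "unilateral"})


def test_noncontiguous_levels_error(params18):
    spine = ms.assemble_spine(params18, ms.SpineConfig(resolution=(3, 3, 3)))
    with pytest.raises(ValueError, match="contiguous"):
        ms.build_instrumentation(
            spine, ms.InstrumentationSpec(levels={"T10": "bilateral", "L4": "bilateral"})
        )


def test_connector_needs_both_sides(params18):
    spine = ms.assemble_spine(params18, ms.SpineConfig(resolution=(3, 3, 3)))
    spec = ms.InstrumentationSpec(
        levels={"L2": "left", "L3": "bilateral"}, connector_levels=("L2",)
    )
    with pytest.raises(ValueError, match="both sides"):
        ms.build_instrumentation(spine, spec)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def test_18_levels_17_discs(params18):
    spine = ms.assemble_spine(params18, ms.SpineConfig(resolution=(3, 3, 3)))
    assert spine.manifest()["n_discs"] == 17
    assert len(spine.levels) == 18


def test_two_levels_one_disc(spine2):
    assert spine2.manifest()["n_discs"] == 1


def test_single_vertebra_rejected():
    with pytest.raises(ValueError):
        ms.assemble_spine([_vp("L5", 22.0)])


def test_straight_stack_mirror_symmetric(spine2):
    """Reflect-and-match oracle about the X=0 sagittal plane."""
    from scipy.spatial import cKDTree

    refl = spine2.nodes * np.array([-1.0, 1.0, 1.0])
    d, _ = cKDTree(spine2.nodes).query(refl)
    assert d.max() < 1e-9


def test_negated_coronal_params_reflect_mesh():
    def build(sign):
        params = [
            _vp("L5", 22.0),
            VertebraParams(
                "L4",
                (sign * 6.0, 0.0, 52.0),
                (40.0, 30.0, 22.0),
                beta_deg=sign * 8.0,
                beta_sup_deg=sign * 10.0,
                beta_inf_deg=sign * 6.0,
            ),
        ]
        return ms.assemble_spine(params, ms.SpineConfig(resolution=(4, 4, 3)))

    from scipy.spatial import cKDTree

    a, b = build(+1), build(-1)
    refl = b.nodes * np.array([-1.0, 1.0, 1.0])
    d, _ = cKDTree(a.nodes).query(refl)
    assert d.max() < 1e-9


def test_interpenetration_error():
    with pytest.raises(ValueError, match="interpenetrate"):
        ms.assemble_spine(
            [_vp("L5", 22.0), _vp("L4", 20.0)], ms.SpineConfig(resolution=(3, 3, 3))
        )


def test_counts_pure_function_of_config(params18):
    cfg = ms.SpineConfig(resolution=(3, 3, 3))
    m1 = ms.assemble_spine(params18, cfg).manifest()
    m2 = ms.assemble_spine(params18, cfg).manifest()
    assert m1 == m2
    # snapshot of the structural counts at this resolution
    assert m1["hexes_by_tag"]["cancellous"] == 18
    assert m1["hexes_by_tag"]["posterior"] == 18 * 8
    assert m1["trusses_by_type"]["fiber"] == 17 * 2 * 2 * 12


def test_jacobians_positive_with_moderate_wedge():
    t = ms.build_template((4, 4, 3))
    for wedge in (-15.0, 15.0):
        pv = ms.morph_and_place(
            t, _vp("L5", 0, beta_sup_deg=wedge, beta_inf_deg=-wedge / 2)
        )
        assert ms.hex_jacobians(pv.nodes, pv.hexes).min() > 0


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def test_vtu_round_trip(tmp_path, spine2):
    p = ms.export_mesh(spine2, "vtu", tmp_path / "s.vtu")
    imp = ms.import_vtu(p)
    m = spine2.manifest()
    assert len(imp["nodes"]) == m["n_nodes"]
    for tag, count in m["hexes_by_tag"].items():
        assert imp["counts_by_tag"][tag] == count
    assert (imp["types"] == 12).sum() == m["n_hexes"]


def test_inp_round_trip(tmp_path, spine2):
    p = ms.export_mesh(spine2, "inp", tmp_path / "s.inp")
    imp = ms.import_inp(p)
    m = spine2.manifest()
    assert imp["n_nodes"] == m["n_nodes"]
    for tag, count in m["hexes_by_tag"].items():
        assert imp["counts_by_elset"][tag] == count
    # one section block per material tag in the mesh
    used = set(m["hexes_by_tag"]) | set(m["trusses_by_type"])
    assert used <= set(imp["sections"])


def test_export_unsupported_format(spine2, tmp_path):
    with pytest.raises(ValueError, match="format"):
        ms.export_mesh(spine2, "stl", tmp_path / "s.stl")


def test_export_empty_mesh_error(tmp_path):
    empty = ms.SpineMesh(
        nodes=np.zeros((0, 3)),
        hexes=np.zeros((0, 8), dtype=int),
        hex_tags=np.array([], dtype=object),
        trusses=np.zeros((0, 2), dtype=int),
        truss_types=np.array([], dtype=object),
        truss_areas=np.zeros(0),
        truss_tension_only=np.zeros(0, dtype=bool),
        beams=np.zeros((0, 2), dtype=int),
        beam_tags=np.array([], dtype=object),
        beam_diameters=np.zeros(0),
        node_sets={},
        elem_groups={},
        levels=[],
        level_attachments={},
        level_grids={},
    )
    with pytest.raises(ValueError, match="empty"):
        ms.export_mesh(empty, "vtu", tmp_path / "e.vtu")


def test_material_table_defaults():
    t = ms.MaterialTable.default()
    assert t["cortical"].E == 12000.0 and t["cortical"].nu == 0.3
    assert t["nucleus"].E == 1.0 and t["nucleus"].nu == 0.499
    assert t["fiber"].E == 175.0
    assert t["ALL"].area == 24.0 and t["CL"].area == 30.0
    assert t["ISL"].E == 10.0 and t["ISL"].area == 26.0
    with pytest.raises(KeyError):
        t.require(["cortical", "unobtainium"])
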