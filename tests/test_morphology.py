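"""Simulator ground truth: soma geometry, arbors, Poisson placement, sectioning."""
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stereoglia as sg
from stereoglia.errors import ParameterError
from stereoglia.geometry import clip_polyline_to_box, polyline_length
from stereoglia.morphology import Segment, _length_scale, sample_soma, to_swc


def make_arbor(*segment_specs):
    segs = [Segment(parent, np.asarray(pts, float), np.full(len(pts), 0.1)) for parent, pts in segment_specs]
    return sg.ProcessArbor(segs)


class TestSoma:
    def test_volume_matches_ellipsoid_formula(self, rng):
        for _ in range(20):
            soma = sample_soma(rng, sg.CONTROL, rng.uniform(0, 100, 3))
            a, b, c = soma.semi_axes
            assert soma.volume == pytest.approx(4 / 3 * np.pi * a * b * c, rel=1e-9)

    def test_surface_point_lies_on_quadric(self, rng):
        soma = sample_soma(rng, sg.CONTROL, np.zeros(3))
        for _ in range(10):
            d = rng.normal(size=3)
            p = soma.surface_point(d) - soma.center
            assert p @ soma.quadric() @ p == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_axes_rejected(self):
        with pytest.raises(ParameterError):
            sg.SomaModel(np.zeros(3), np.array([1.0, -1.0, 1.0]), np.eye(3))


class TestArborLength:
    def test_straight_segment(self):
        arbor = make_arbor((-1, [[0, 0, 0], [0, 0, 100]]))
        assert sg.arbor_total_length(arbor) == pytest.approx(100.0)

    def test_additivity(self):
        arbor = make_arbor(
            (-1, [[0, 0, 0], [60, 0, 0]]),
            (0, [[60, 0, 0], [60, 40, 0]]),
        )
        assert sg.arbor_total_length(arbor) == pytest.approx(100.0)

    def test_calibrated_mean_length_hits_target(self, rng):
        scale = _length_scale(sg.CONTROL)
        soma = sample_soma(rng, sg.CONTROL, np.zeros(3))
        lens = [
            sg.grow_arbor(rng, sg.CONTROL, soma, scale).total_length()
            for _ in range(500)
        ]
        assert np.mean(lens) == pytest.approx(
            sg.CONTROL.length_per_cell_um, rel=0.05
        )

    def test_tree_invariants_hold_for_grown_arbors(self, rng):
        soma = sample_soma(rng, sg.DEAFFERENTED, np.zeros(3))
        for _ in range(20):
            arbor = sg.grow_arbor(rng, sg.DEAFFERENTED, soma, 1.0)
            arbor.validate(soma)

    @pytest.mark.parametrize(
        "params,expected",
        [(sg.CONTROL, 4.1), (sg.DEAFFERENTED, 9.0)],
        ids=["control", "deafferented"],
    )
    def test_primary_count_means(self, rng, params, expected):
        soma = sample_soma(rng, params, np.zeros(3))
        counts = [
            sg.grow_arbor(rng, params, soma, 1.0).primary_count for _ in range(400)
        ]
        assert np.mean(counts) == pytest.approx(expected, rel=0.08)


class TestBuildTissue:
    def test_zero_intensity_gives_empty_block(self):
        empty = sg.ConditionParams(**{**sg.CONTROL.__dict__, "nv_per_mm3": 0.0})
        block = sg.build_tissue(empty, (100, 100, 100), 0)
        assert block.n_cells == 0
        assert block.nv_per_mm3() == 0.0
        assert block.lv_mm_per_mm3() == 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            sg.build_tissue(sg.CONTROL, (100, -5, 100), 0)
        bad = sg.ConditionParams(**{**sg.CONTROL.__dict__, "nv_per_mm3": -1.0})
        with pytest.raises(ParameterError):
            sg.build_tissue(bad, (100, 100, 100), 0)

    def test_poisson_count_recovery(self):
        """Mean cell count over many replicates matches lambda*V within 2%."""
        lam_v = 5e4 * 1e-9 * 1e6  # 50 expected cells in a (100 um)^3 block
        params = sg.ConditionParams(**{**sg.DEAFFERENTED.__dict__, "nv_per_mm3": 5e4})
        counts = [
            sg.build_tissue(params, (100, 100, 100), s, with_arbors=False).n_cells
            for s in range(500)
        ]
        assert abs(np.mean(counts) - lam_v) / lam_v < 0.02

    def test_seeded_determinism(self):
        a = sg.build_tissue(sg.CONTROL, (120, 120, 60), 7)
        b = sg.build_tissue(sg.CONTROL, (120, 120, 60), 7)
        assert a.n_cells == b.n_cells
        for ca, cb in zip(a.cells, b.cells):
            assert np.array_equal(ca.soma.center, cb.soma.center)
            for sa, sb in zip(ca.arbor.segments, cb.arbor.segments):
                assert np.array_equal(sa.points, sb.points)
                assert np.array_equal(sa.radii, sb.radii)

    def test_expected_count_in_control_regime(self):
        """A 10^6 um^3 block at the control density holds ~10 cells on average."""
        counts = [
            sg.build_tissue(sg.CONTROL, (100, 100, 100), s, with_arbors=False).n_cells
            for s in range(300)
        ]
        expected = sg.CONTROL.nv_per_mm3 * 1e-3  # 10 cells per 10^6 um^3
        assert np.mean(counts) == pytest.approx(expected, rel=0.1)


class TestCutSections:
    def test_every_fifth_section_sampled(self):
        block = sg.build_tissue(sg.CONTROL, (80, 80, 400), 3, with_arbors=False)
        secs = sg.cut_sections(block, thickness=40, period=5)
        assert len(secs) == 2

    def test_shrinkage_identity(self, control_block):
        secs = sg.cut_sections(control_block, 40, period=1, z_shrinkage=1.0)
        total = sum(s.total_curve_length() for s in secs)
        assert total == pytest.approx(control_block.clipped_total_length(), rel=1e-6)

    def test_z_parallel_segment_halves_under_half_shrinkage(self):
        block = sg.TissueBlock(
            np.array([50.0, 50.0, 40.0]),
            [
                sg.Cell(
                    sg.SomaModel(np.array([25.0, 25.0, 20.0]), np.ones(3), np.eye(3)),
                    make_arbor((-1, [[25, 25, 0], [25, 25, 40]])),
                )
            ],
            sg.CONTROL,
            0,
        )
        secs = sg.cut_sections(block, 40, period=1, z_shrinkage=0.5)
        assert secs[0].total_curve_length() == pytest.approx(20.0)

    def test_slab_partition_conserves_length(self, control_block):
        """Cutting into disjoint slabs neither creates nor destroys length."""
        secs = sg.cut_sections(control_block, 20, period=1, z_shrinkage=1.0)
        total = sum(s.total_curve_length() for s in secs)
        assert total == pytest.approx(control_block.clipped_total_length(), rel=1e-6)

    def test_invalid_period_rejected(self, control_block):
        with pytest.raises(ParameterError):
            sg.cut_sections(control_block, 40, period=0)
        with pytest.raises(ParameterError):
            sg.cut_sections(control_block, 40, z_shrinkage=0.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    pts=st.lists(
        st.tuples(
            st.floats(-50, 150), st.floats(-50, 150), st.floats(-50, 150)
        ),
        min_size=2,
        max_size=8,
    ),
    split=st.floats(10, 90),
)
def test_clip_partition_is_additive(pts, split):
    """Clipping to two abutting half-boxes conserves the clipped length."""
    poly = np.asarray(pts, float)
    lo, hi = np.zeros(3), np.full(3, 100.0)
    full = sum(polyline_length(r) for r, _ in clip_polyline_to_box(poly, lo, hi))
    mid_lo = np.array([100.0, 100.0, split])
    mid_hi = np.array([0.0, 0.0, split])
    lower = sum(
        polyline_length(r) for r, _ in clip_polyline_to_box(poly, lo, mid_lo)
    )
    upper = sum(
        polyline_length(r) for r, _ in clip_polyline_to_box(poly, mid_hi, hi)
    )
    assert lower + upper == pytest.approx(full, rel=1e-6, abs=1e-6)


class TestExport:
    def test_swc_parents_are_consistent(self, rng):
        soma = sample_soma(rng, sg.CONTROL, np.array([10.0, 10.0, 10.0]))
        cell = sg.Cell(soma, sg.grow_arbor(rng, sg.CONTROL, soma, 1.0))
        text = to_swc(cell)
        rows = [l.split() for l in text.splitlines() if not l.startswith("#")]
        ids = {int(r[0]) for r in rows}
        for r in rows:
            parent = int(r[6])
            assert parent == -1 or parent in ids

    def test_ground_truth_roundtrip(self, tmp_path):
        block = sg.build_tissue(sg.CONTROL, (100, 100, 50), 9)
        jpath, cpath = tmp_path / "gt.json", tmp_path / "gt.csv"
        block.export_ground_truth(jpath, cpath)
        gt = json.loads(jpath.read_text())
        assert gt["n_cells"] == block.n_cells
        assert gt["lv_mm_per_mm3"] == pytest.approx(block.lv_mm_per_mm3())
        assert len(cpath.read_text().splitlines()) == block.n_cells + 1
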