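"""Structured quad meshing: determinism, quality, seams, closure plan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atflap.geometry import design_flap
from atflap.mesh import (
    build_domain,
    closure_plan,
    generate_mesh,
    quality_report,
    rectangle_mesh,
    reference_jacobians,
    suture_pairs,
)


def _default_mesh(size=3.0):
    return generate_mesh(build_domain(design_flap(10.0, 60.0)), size)


class TestRectangle:
    def test_counts(self):
        m = rectangle_mesh(6.0, 6.0, 3.0)
        assert m.n_elements == 4
        assert m.n_nodes == 9

    def test_all_unit_quality(self):
        m = rectangle_mesh(12.0, 12.0, 3.0, origin=(0.0, -6.0))
        q = quality_report(m)
        assert q.n_inverted == 0
        assert q.n_distorted == 0
        assert q.n_bad_aspect == 0

    def test_positive_jacobians(self):
        m = rectangle_mesh(10.0, 7.0, 2.0)
        assert (reference_jacobians(m) > 0.0).all()


class TestDomain:
    def test_reference_domain(self):
        dom = build_domain(design_flap(10.0, 60.0))
        assert dom.half_base == pytest.approx(17.3205, rel=1e-5)
        assert dom.flap_length == 30.0
        assert dom.waist_length == pytest.approx(34.6410, rel=1e-5)
        assert dom.half_span == 30.0  # 3 r extension rule

    def test_flap_must_fit(self):
        with pytest.raises(ValueError):
            build_domain(design_flap(10.0, 60.0), width=50.0, height=100.0)


class TestGenerate:
    def test_reference_counts(self):
        m = _default_mesh()
        # within the published 3 mm model's ballpark (1068 / 1161)
        assert 800 <= m.n_elements <= 1350
        assert m.n_nodes > m.n_elements

    def test_determinism(self):
        a, b = _default_mesh(), _default_mesh()
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.quads, b.quads)

    def test_refinement_quadruples_elements(self):
        n2 = _default_mesh(2.0).n_elements
        n1 = _default_mesh(1.0).n_elements
        assert 0.8 * 4 <= n1 / n2 <= 1.2 * 4

    @pytest.mark.parametrize("size", [4.0, 3.0, 2.0, 1.0])
    def test_no_inverted_elements(self, size):
        assert quality_report(_default_mesh(size)).n_inverted == 0

    def test_size_limits(self):
        dom = build_domain(design_flap(10.0, 60.0))
        with pytest.raises(ValueError):
            generate_mesh(dom, 0.2)
        with pytest.raises(ValueError):
            generate_mesh(dom, 20.0)

    def test_node_set_mirror_symmetric(self):
        m = _default_mesh()
        left = {(round(-x, 6), round(y, 6)) for x, y in m.nodes}
        right = {(round(x, 6), round(y, 6)) for x, y in m.nodes}
        assert left == right

    def test_cut_pairs_coincident_and_distinct(self):
        m = _default_mesh()
        a, b = m.cut_pairs[:, 0], m.cut_pairs[:, 1]
        assert (a != b).all()
        assert np.linalg.norm(m.nodes[a] - m.nodes[b], axis=1).max() < 1e-9

    def test_seam_chains(self):
        m = _default_mesh()
        dom = m.domain
        for side in ("left", "right"):
            lower = m.seams[f"lower_{side}"]
            upper = m.seams[f"upper_{side}"]
            waist = m.seams[f"waist_upper_{side}"]
            assert lower.size == upper.size  # zip pairing needs 1:1 chains
            # lower margin runs tip -> base centre along y = 0
            assert np.allclose(m.nodes[lower][:, 1], 0.0, atol=1e-12)
            assert m.nodes[lower][0, 0] == pytest.approx(
                -dom.half_span if side == "left" else dom.half_span
            )
            assert lower[-1] == m.center_node
            # waist chain ends at the shared apex node
            assert waist[-1] == m.apex_node
        assert m.nodes[m.apex_node][1] == pytest.approx(dom.flap_length)

    def test_landmarks(self):
        m = _default_mesh()
        assert np.allclose(m.nodes[m.center_node], [0.0, 0.0])
        assert len(m.tip_nodes) >= 2
        assert len(m.corner_nodes) == 4


class TestClosurePlan:
    def test_joint_height_reference(self):
        plan = closure_plan(_default_mesh())
        assert plan.joint_height == pytest.approx(10.0, rel=1e-12)

    def test_max_prescribed_displacement(self):
        m = _default_mesh()
        plan = closure_plan(m)
        assert plan.max_prescribed_displacement(m.nodes) == pytest.approx(
            10.0, rel=1e-9
        )

    def test_paired_targets_agree(self):
        m = _default_mesh()
        for a, b, target in suture_pairs(m):
            assert a != b
            assert np.isfinite(target).all()

    def test_pairing_mirror_symmetric(self):
        m = _default_mesh()
        plan = closure_plan(m)
        # reflecting a target node's reference position across x = 0 finds
        # another target node with the mirrored target position
        coords = {
            (round(m.nodes[n][0], 6), round(m.nodes[n][1], 6)): t
            for n, t in plan.targets.items()
        }
        for (x, y), t in coords.items():
            mirrored = coords[(round(-x, 6), y)]
            assert mirrored[0] == pytest.approx(-t[0], abs=1e-9)
            assert mirrored[1] == pytest.approx(t[1], abs=1e-9)

    def test_arc_length_preserved_on_lateral_seam(self):
        # consecutive targets along the lower margin are spaced by the limb
        # length over the margin length: tangential stretch is uniform and
        # close to one (no intrinsic seam mismatch)
        m = _default_mesh()
        plan = closure_plan(m)
        dom = m.domain
        lower = m.seams["lower_left"]
        t = np.array([plan.targets[n] for n in lower])
        seam_len = np.linalg.norm(np.diff(t, axis=0), axis=1).sum()
        limb = np.hypot(dom.half_span, plan.joint_height)
        assert seam_len == pytest.approx(limb, rel=1e-9)
        assert limb / dom.half_span == pytest.approx(1.054, abs=0.001)

    def test_ties_cover_margins(self):
        m = _default_mesh()
        plan = closure_plan(m)
        tied = {n for pair in plan.ties for n in pair}
        for side in ("left", "right"):
            assert set(m.seams[f"lower_{side}"][1:]) <= tied
            assert set(m.seams[f"upper_{side}"][1:]) <= tied


@settings(max_examples=8, deadline=None)
@given(size=st.floats(1.2, 6.0))
def test_any_size_meshes_cleanly(size):
    m = _default_mesh(size)
    assert quality_report(m).n_inverted == 0
    plan = closure_plan(m)
    assert plan.joint_height == pytest.approx(10.0, rel=1e-12)
    for a, b, _ in suture_pairs(m):
        assert a != b
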