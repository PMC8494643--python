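"""SWC parsing, validation and geometric transforms."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from axonmap.swc import (
    LandmarkWarp,
    SWCParseError,
    flip_to_left,
    parse_swc,
    prune_terminal_branches,
    resample,
    sort_tree,
    tps_warp,
    validate,
    write_swc,
)
from conftest import chain_neuron, random_tree

SIMPLE = """# brain_id: test-01
1 1 0 0 0 5 -1
2 2 10 0 0 1 1
3 3 0 10 0 1 1
"""


class TestParse:
    def test_three_line_file(self):
        neuron = parse_swc(SIMPLE)
        assert len(neuron) == 3
        assert neuron.nodes["id"].tolist() == [1, 2, 3]
        assert neuron.nodes["parent"].tolist() == [-1, 1, 1]
        assert neuron.metadata["brain_id"] == "test-01"

    def test_write_parse_roundtrip_lossless(self):
        first = parse_swc(SIMPLE)
        second = parse_swc(write_swc(first))
        pd.testing.assert_frame_equal(first.nodes, second.nodes)

    def test_six_columns_raises_with_line_number(self):
        bad = "1 1 0 0 0 5 -1\n2 2 10 0 0 1\n"
        with pytest.raises(SWCParseError, match="line 2"):
            parse_swc(bad)

    def test_non_numeric_field_raises(self):
        with pytest.raises(SWCParseError, match="line 1"):
            parse_swc("a 1 0 0 0 5 -1\n")

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 7),
                st.floats(-1e5, 1e5).map(lambda v: round(v, 6)),
                st.floats(-1e5, 1e5).map(lambda v: round(v, 6)),
                st.floats(-1e5, 1e5).map(lambda v: round(v, 6)),
                st.floats(0, 50).map(lambda v: round(v, 6)),
            ),
            min_size=1,
            max_size=15,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_roundtrip_lossless_on_arbitrary_chains(self, rows):
        text = "".join(
            f"{i + 1} {t} {x} {y} {z} {r} {i if i else -1}\n"
            for i, (t, x, y, z, r) in enumerate(rows)
        )
        first = parse_swc(text)
        second = parse_swc(write_swc(first))
        pd.testing.assert_frame_equal(first.nodes, second.nodes)


class TestValidate:
    def test_orphan_parent_is_error(self):
        neuron = parse_swc("1 1 0 0 0 5 -1\n2 2 1 0 0 1 99\n")
        report = validate(neuron)
        assert not report.is_valid
        assert "orphan-parent" in report.codes()

    def test_multiple_roots_is_error(self):
        neuron = parse_swc("1 1 0 0 0 5 -1\n2 2 1 0 0 1 -1\n")
        assert "multiple-roots" in validate(neuron).codes()

    def test_loop_is_error(self):
        neuron = parse_swc(
            "1 1 0 0 0 5 -1\n2 2 1 0 0 1 3\n3 2 2 0 0 1 2\n"
        )
        report = validate(neuron)
        assert "loop" in report.codes()
        assert not report.is_valid

    def test_duplicate_id_is_error(self):
        neuron = parse_swc("1 1 0 0 0 5 -1\n1 2 1 0 0 1 1\n")
        assert "duplicate-id" in validate(neuron).codes()

    def test_multifurcation_is_warning_only(self):
        text = "1 1 0 0 0 5 -1\n" + "".join(
            f"{i} 2 {i} 0 0 1 1\n" for i in (2, 3, 4)
        )
        report = validate(parse_swc(text))
        assert "multifurcation" in report.codes()
        assert report.is_valid

    def test_child_before_parent_is_warning(self):
        neuron = parse_swc("2 2 1 0 0 1 1\n1 1 0 0 0 5 -1\n")
        report = validate(neuron)
        assert "not-sorted" in report.codes()
        assert report.is_valid


class TestSortTree:
    def test_preorder_renumbering_from_root(self):
        neuron = parse_swc("5 2 1 0 0 1 9\n9 1 0 0 0 5 -1\n")
        out = sort_tree(neuron)
        assert out.nodes["id"].tolist() == [1, 2]
        assert out.nodes["parent"].tolist() == [-1, 1]
        assert out.nodes.iloc[0]["type"] == 1

    def test_idempotent_on_sorted_tree(self):
        neuron = sort_tree(random_tree(1))
        again = sort_tree(neuron)
        pd.testing.assert_frame_equal(neuron.nodes, again.nodes)

    @pytest.mark.parametrize("seed", range(5))
    def test_cable_length_invariant(self, seed):
        neuron = random_tree(seed)
        assert sort_tree(neuron).total_length() == pytest.approx(
            neuron.total_length(), abs=1e-9
        )


class TestPrune:
    def _y_neuron(self, branch_len):
        # stem of 20 plus one long and one adjustable daughter branch
        return parse_swc(
            "1 1 0 0 0 1 -1\n"
            "2 2 20 0 0 1 1\n"
            "3 2 50 0 0 1 2\n"
            f"4 2 20 {branch_len} 0 1 2\n"
        )

    def test_short_terminal_branch_removed(self):
        out = prune_terminal_branches(self._y_neuron(5.0), min_length=10)
        assert len(out) == 3
        assert 4 not in out.nodes["id"].tolist()

    def test_exactly_threshold_branch_retained(self):
        out = prune_terminal_branches(self._y_neuron(10.0), min_length=10)
        assert len(out) == 4

    def test_identity_when_all_branches_long(self):
        neuron = self._y_neuron(25.0)
        out = prune_terminal_branches(neuron, min_length=10)
        pd.testing.assert_frame_equal(out.nodes, neuron.nodes)

    def test_single_pass_does_not_cascade(self):
        # both short daughters of node 2 go in pass one, turning node 2
        # into a tip on a 5-long branch: only a cascade removes it too
        neuron = parse_swc(
            "1 1 0 0 0 1 -1\n"
            "2 2 5 0 0 1 1\n"
            "3 2 8 0 0 1 2\n"
            "4 2 5 4 0 1 2\n"
        )
        once = prune_terminal_branches(neuron, min_length=10)
        assert once.nodes["id"].tolist() == [1, 2]
        cascaded = prune_terminal_branches(neuron, min_length=10, cascade=True)
        assert cascaded.nodes["id"].tolist() == [1]

    @pytest.mark.parametrize("seed", range(5))
    def test_result_stays_valid(self, seed):
        out = prune_terminal_branches(random_tree(seed), min_length=6)
        assert validate(out).is_valid


class TestResample:
    def test_straight_segment_node_count(self):
        neuron = chain_neuron([[0, 0, 0], [100, 0, 0]])
        out = resample(neuron, 10.0)
        assert len(out) == 11
        assert out.total_length() == pytest.approx(100.0)

    def test_large_step_keeps_anchors_only(self):
        pts = [[0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0]]
        out = resample(chain_neuron(pts), 1000.0)
        assert len(out) == 2  # root and tip survive
        np.testing.assert_allclose(out.coords()[-1], [30, 0, 0])

    def test_branch_points_and_tips_preserved(self):
        neuron = parse_swc(
            "1 1 0 0 0 1 -1\n2 2 40 0 0 1 1\n"
            "3 2 80 0 0 1 2\n4 2 40 40 0 1 2\n"
        )
        out = resample(neuron, 7.0)
        got = {tuple(c) for c in np.round(out.coords(), 6)}
        for anchor in [(0, 0, 0), (40, 0, 0), (80, 0, 0), (40, 40, 0)]:
            assert tuple(float(v) for v in anchor) in got

    def test_length_error_shrinks_with_step(self):
        # smooth helix-like neurite: finer resampling converges in length
        t = np.linspace(0, 4 * np.pi, 200)
        pts = np.column_stack([30 * np.cos(t), 30 * np.sin(t), 10 * t])
        neuron = chain_neuron(pts)
        ref = neuron.total_length()
        errors = [
            abs(resample(neuron, s).total_length() - ref) for s in (16, 8, 4)
        ]
        assert errors[0] >= errors[1] >= errors[2]
        assert errors[2] / ref < 0.01

    def test_non_positive_step_rejected(self):
        with pytest.raises(ValueError):
            resample(chain_neuron([[0, 0, 0], [1, 0, 0]]), 0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_result_stays_valid(self, seed):
        out = resample(random_tree(seed), 3.0)
        assert validate(out).is_valid


class TestFlip:
    def test_right_soma_mirrored_and_involutive(self):
        neuron = chain_neuron([[0, 0, 800], [10, 0, 900]])
        out = flip_to_left(neuron, midline=500.0)
        assert out.coords()[0, 2] == pytest.approx(200.0)
        again = flip_to_left(out, midline=500.0)
        np.testing.assert_allclose(again.coords(), out.coords())

    def test_left_soma_unchanged(self):
        neuron = chain_neuron([[0, 0, 100], [10, 0, 900]])
        out = flip_to_left(neuron, midline=500.0)
        np.testing.assert_allclose(out.coords(), neuron.coords())

    def test_isometry(self):
        neuron = random_tree(3)
        shifted = neuron.with_coords(neuron.coords() + [0, 0, 1000])
        out = flip_to_left(shifted, midline=500.0)
        np.testing.assert_allclose(
            pdist(out.coords()), pdist(shifted.coords()), atol=1e-9
        )

    def test_missing_axis_convention_raises(self):
        neuron = chain_neuron([[0, 0, 800], [1, 0, 900]])
        neuron.metadata.pop("lr_axis")
        with pytest.raises(ValueError, match="axis"):
            flip_to_left(neuron, midline=500.0)


class TestTPS:
    def _landmarks(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        return rng.uniform(0, 100, size=(n, 3))

    def test_identity_landmarks_identity_map(self):
        src = self._landmarks()
        warp = LandmarkWarp(src, src.copy())
        pts = self._landmarks(seed=1)
        np.testing.assert_allclose(tps_warp(pts, warp), pts, atol=1e-8)

    def test_translation_reproduced_everywhere(self):
        src = self._landmarks()
        t = np.array([5.0, -3.0, 12.0])
        warp = LandmarkWarp(src, src + t)
        pts = self._landmarks(seed=2)
        np.testing.assert_allclose(tps_warp(pts, warp), pts + t, atol=1e-8)

    def test_affine_map_reproduced_to_1e6(self):
        rng = np.random.default_rng(7)
        A = np.eye(3) + 0.2 * rng.normal(size=(3, 3))
        b = rng.normal(scale=10, size=3)
        src = self._landmarks()
        warp = LandmarkWarp(src, src @ A.T + b)
        pts = self._landmarks(seed=3)
        np.testing.assert_allclose(tps_warp(pts, warp), pts @ A.T + b, atol=1e-6)

    def test_coplanar_landmarks_rejected(self):
        src = self._landmarks()
        src[:, 2] = 0.0
        with pytest.raises(ValueError, match="coplanar"):
            LandmarkWarp(src, src.copy())

    def test_duplicate_landmarks_rejected(self):
        src = self._landmarks()
        src[1] = src[0]
        with pytest.raises(ValueError, match="duplicated"):
            LandmarkWarp(src, src.copy())

    def test_too_few_landmarks_rejected(self):
        src = self._landmarks(n=3)
        with pytest.raises(ValueError, match="4 landmark"):
            LandmarkWarp(src, src.copy())
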