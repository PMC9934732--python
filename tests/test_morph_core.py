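"""Vertex correspondence, morphing, snapping and the distance criterion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seegmorph as sm
from seegmorph._exceptions import CorrespondenceError, InconsistencyError
from seegmorph.morph_core import _nearest_many

from conftest import brute_nearest, random_mesh


def _mesh(vertices, faces=((0, 1, 2),), hemisphere="unknown"):
    return sm.SurfaceMesh(np.asarray(vertices, float), np.asarray(faces), hemisphere)


class TestValidatePair:
    def test_identical_mesh_twice_is_valid(self, tetrahedron):
        pair = sm.validate_pair(tetrahedron, tetrahedron)
        assert pair.n_vertices == 4

    def test_vertex_count_mismatch_reports_both_counts(self):
        a = random_mesh(1000, seed=0)
        b = random_mesh(999, seed=1)
        with pytest.raises(CorrespondenceError, match="1000 vs 999"):
            sm.validate_pair(a, b)

    def test_face_mismatch_reports_first_differing_face(self):
        v = np.eye(4, 3) * 10
        a = _mesh(v, [[0, 1, 2], [1, 2, 3]])
        b = _mesh(v, [[0, 1, 2], [1, 3, 2]])
        with pytest.raises(CorrespondenceError, match="face 1"):
            sm.validate_pair(a, b)

    def test_hemisphere_mismatch_rejected(self):
        v = np.eye(4, 3)
        with pytest.raises(CorrespondenceError, match="hemisphere"):
            sm.validate_pair(_mesh(v, hemisphere="left"), _mesh(v, hemisphere="right"))

    def test_fixture_pair_is_valid(self, pair):
        assert sm.validate_pair(pair.folded, pair.inflated).n_vertices == 2500


class TestMorphVertices:
    def test_endpoints_are_bitwise(self, pair):
        np.testing.assert_array_equal(
            sm.morph_vertices(pair, 0.0), pair.folded.vertices
        )
        np.testing.assert_array_equal(
            sm.morph_vertices(pair, 1.0), pair.inflated.vertices
        )

    def test_midpoint_of_stated_formula(self):
        folded = _mesh([[0, 0, 0], [0, 0, 0], [0, 0, 0]])
        inflated = _mesh([[2, 4, -6], [0, 0, 0], [0, 0, 0]])
        pair = sm.validate_pair(folded, inflated)
        np.testing.assert_array_equal(
            sm.morph_vertices(pair, 0.5)[0], [1.0, 2.0, -3.0]
        )

    @pytest.mark.parametrize("sigma", [-0.1, 1.1, np.nan, np.inf])
    def test_sigma_outside_unit_interval_rejected(self, pair, sigma):
        with pytest.raises(ValueError):
            sm.morph_vertices(pair, sigma)


class TestNearestVertex:
    def test_point_on_vertex_returns_zero_distance(self, pair):
        idx, dist = sm.nearest_vertex(pair.folded, pair.folded.vertices[7])
        assert (idx, dist) == (7, 0.0)

    @pytest.mark.parametrize("method", ["brute", "kdtree"])
    def test_matches_exhaustive_scan(self, method):
        mesh = random_mesh(200, seed=42)
        rng = np.random.default_rng(7)
        for point in rng.uniform(-60, 60, (25, 3)):
            i, d = sm.nearest_vertex(mesh, point, method=method)
            oi, od = brute_nearest(mesh.vertices, point)
            assert i == oi
            assert d == pytest.approx(od, abs=1e-9)

    @pytest.mark.parametrize("method", ["brute", "kdtree"])
    def test_tie_breaks_to_lowest_index(self, method):
        # vertices 2 and 5 both sit 1 mm from the origin query point
        v = np.array(
            [[9, 9, 9], [8, 8, 8], [1, 0, 0], [7, 7, 7], [6, 6, 6], [-1, 0, 0]],
            dtype=float,
        )
        mesh = _mesh(v)
        idx, dist = sm.nearest_vertex(mesh, [0.0, 0.0, 0.0], method=method)
        assert idx == 2 and dist == 1.0

    def test_brute_and_kdtree_paths_agree(self):
        mesh = random_mesh(3000, seed=3)
        rng = np.random.default_rng(11)
        points = rng.uniform(-60, 60, (50, 3))
        ib, db = _nearest_many(mesh.vertices, points, "brute")
        ik, dk = _nearest_many(mesh.vertices, points, "kdtree")
        np.testing.assert_array_equal(ib, ik)
        np.testing.assert_allclose(db, dk, atol=1e-9)

    def test_non_finite_point_rejected(self, pair):
        with pytest.raises(ValueError):
            sm.nearest_vertex(pair.folded, [0.0, np.nan, 0.0])


class TestMapContacts:
    def test_contact_on_vertex_included(self, pair):
        es = sm.ElectrodeSet(("A",), pair.folded.vertices[[100]])
        (m,) = sm.map_contacts(pair, es, 4.0)
        assert m.distance_mm == 0.0 and m.included and m.vertex_index == 100

    def test_strict_inequality_at_threshold(self, tetrahedron):
        # contacts straight below the origin vertex: nearest distance is exact
        es = sm.ElectrodeSet(
            ("d0", "d4"), np.array([[0.0, 0.0, 0.0], [0.0, 0.0, -4.0]])
        )
        pair = sm.validate_pair(tetrahedron, tetrahedron)
        flags = [m.included for m in sm.map_contacts(pair, es, 4.0)]
        assert flags == [True, False]

    def test_empty_electrode_set_returns_empty_list(self, pair):
        es = sm.ElectrodeSet((), np.empty((0, 3)))
        assert sm.map_contacts(pair, es, 4.0) == []

    def test_inclusion_matches_brute_force(self, pair, trajectory):
        maps = sm.map_contacts(pair, trajectory, 4.0)
        for m in maps:
            oi, od = brute_nearest(pair.folded.vertices, trajectory.positions[m.electrode_index])
            assert m.vertex_index == oi
            assert m.included == (od < 4.0)

    def test_monotone_in_threshold(self, pair, trajectory):
        prev: set = set()
        for thr in (0.5, 1, 2, 4, 8, 1e9):
            inc = {
                m.electrode_index
                for m in sm.map_contacts(pair, trajectory, thr)
                if m.included
            }
            assert prev <= inc
            prev = inc
        assert prev == set(range(len(trajectory)))  # threshold -> inf keeps all

    def test_nonpositive_threshold_rejected(self, pair, trajectory):
        with pytest.raises(ValueError):
            sm.map_contacts(pair, trajectory, 0.0)


class TestMorphElectrodes:
    def test_endpoints(self, pair, trajectory, mappings):
        included = [m.electrode_index for m in mappings if m.included]
        at0 = sm.morph_electrodes(pair, mappings, trajectory, 0.0)
        np.testing.assert_array_equal(at0, trajectory.positions[included])
        at1 = sm.morph_electrodes(pair, mappings, trajectory, 1.0)
        snapped = [m.vertex_index for m in mappings if m.included]
        np.testing.assert_array_equal(at1, pair.inflated.vertices[snapped])

    def test_quarter_morph_of_stated_formula(self):
        folded = _mesh([[1, 1, 1], [50, 50, 50], [60, 60, 60]])
        inflated = _mesh([[3, 3, 3], [50, 50, 50], [60, 60, 60]])
        pair = sm.validate_pair(folded, inflated)
        es = sm.ElectrodeSet(("E",), np.array([[1.0, 1.0, 1.0]]))
        maps = sm.map_contacts(pair, es, 4.0)
        out = sm.morph_electrodes(pair, maps, es, 0.25)
        np.testing.assert_array_equal(out, [[1.5, 1.5, 1.5]])

    def test_excluded_contacts_are_dropped(self, pair, trajectory, mappings):
        out = sm.morph_electrodes(pair, mappings, trajectory, 0.5)
        assert out.shape == (sum(m.included for m in mappings), 3)

    def test_stale_mapping_rejected(self, pair, trajectory):
        bad = [sm.ContactMapping(0, pair.n_vertices + 5, 1.0, True)]
        with pytest.raises(InconsistencyError, match="stale"):
            sm.morph_electrodes(pair, bad, trajectory, 0.5)


class TestMakeFrame:
    def test_sigma_zero_frame_is_folded(self, pair, trajectory, mappings):
        frame = sm.make_frame(pair, trajectory, mappings, 0.0)
        np.testing.assert_array_equal(frame.vertices, pair.folded.vertices)
        included = [m.electrode_index for m in mappings if m.included]
        np.testing.assert_array_equal(
            frame.electrode_positions, trajectory.positions[included]
        )
        assert frame.electrode_names == tuple(
            trajectory.names[j] for j in included
        )

    def test_midpoint_frame_is_mean_of_endpoints(self, pair, trajectory, mappings):
        f0 = sm.make_frame(pair, trajectory, mappings, 0.0)
        f1 = sm.make_frame(pair, trajectory, mappings, 1.0)
        fm = sm.make_frame(pair, trajectory, mappings, 0.5)
        np.testing.assert_allclose(
            fm.vertices, (f0.vertices + f1.vertices) / 2, atol=1e-9
        )
        np.testing.assert_allclose(
            fm.electrode_positions,
            (f0.electrode_positions + f1.electrode_positions) / 2,
            atol=1e-9,
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(sigma=st.floats(0.0, 1.0))
    def test_linearity_for_any_sigma(self, pair, trajectory, mappings, sigma):
        f0 = sm.make_frame(pair, trajectory, mappings, 0.0)
        f1 = sm.make_frame(pair, trajectory, mappings, 1.0)
        fs = sm.make_frame(pair, trajectory, mappings, sigma)
        np.testing.assert_allclose(
            fs.vertices,
            (1 - sigma) * f0.vertices + sigma * f1.vertices,
            atol=1e-9,
        )
        np.testing.assert_allclose(
            fs.electrode_positions,
            (1 - sigma) * f0.electrode_positions + sigma * f1.electrode_positions,
            atol=1e-9,
        )


class TestSplitByHemisphere:
    def test_contacts_assigned_to_closer_hemisphere_tie_to_left(self):
        left = _mesh([[-10, 0, 0], [-10, 1, 0], [-10, 0, 1]], hemisphere="left")
        right = _mesh([[10, 0, 0], [10, 1, 0], [10, 0, 1]], hemisphere="right")
        lp = sm.validate_pair(left, left)
        rp = sm.validate_pair(right, right)
        es = sm.ElectrodeSet(
            ("L", "R", "MID"),
            np.array([[-8.0, 0, 0], [8.0, 0, 0], [0.0, 0, 0]]),
        )
        ls, rs = sm.split_by_hemisphere(lp, rp, es)
        assert ls.names == ("L", "MID")  # exact tie goes left
        assert rs.names == ("R",)
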