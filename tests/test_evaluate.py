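import numpy as np
import pytest
from scipy.spatial.distance import pdist

from hicstruct import synthetic
from hicstruct.evaluate import (
    call_compartments,
    drmsd,
    dscc,
    interpolate_structure,
    region_distance_compare,
)
from hicstruct.io import ContactMap, Structure
from hicstruct.preprocess import WishDistances, wish_distances


def brute_force_spearman(x, y):
    """Independent rank-and-correlate oracle (average ranks for ties)."""

    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        r[order] = np.arange(1, len(v) + 1)
        # average tied ranks
        for val in np.unique(v):
            idx = np.flatnonzero(v == val)
            if len(idx) > 1:
                r[idx] = r[idx].mean()
        return r

    rx, ry = ranks(np.asarray(x)), ranks(np.asarray(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def wd_from_pairs(n, pairs):
    """WishDistances with explicit per-pair targets."""
    d = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for (i, j), v in pairs.items():
        d[i, j] = d[j, i] = v
        mask[i, j] = mask[j, i] = True
    return WishDistances(gamma=1.0, d=d, mask=mask)


class TestDscc:
    def test_perfect_agreement(self):
        # wish distances built to equal the structure distances exactly
        s = synthetic.make_structure(25, "random_walk", seed=8)
        dm = s.pairwise_distances()
        mask = ~np.eye(25, dtype=bool)
        wd = WishDistances(gamma=1.0, d=dm, mask=mask)
        assert dscc(s, wd) == pytest.approx(1.0)

    def test_reversed_ranks(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]])
        s = Structure(coords)
        dist = pdist(coords)
        # wish distances strictly decreasing in the structure distances
        vals = 10.0 - dist
        wd = wd_from_pairs(4, {p: v for p, v in zip([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], vals)})
        assert dscc(s, wd) == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            n = 8
            coords = rng.standard_normal((n, 3))
            s = Structure(coords)
            cf = rng.random((n, n)) + 0.1
            cf = (cf + cf.T) / 2
            np.fill_diagonal(cf, 0.0)
            wd = wish_distances(cf, 1.0)
            iu, ju, d = wd.condensed()
            dist = np.linalg.norm(coords[iu] - coords[ju], axis=1)
            assert dscc(s, wd) == pytest.approx(brute_force_spearman(dist, d), abs=1e-12)

    def test_rigid_motion_and_scale_invariance(self, rng):
        # generic point cloud: all pairwise distances distinct, so ranks are
        # stable under the float error of the motion
        s = Structure(rng.standard_normal((25, 3)) * 2.0)
        m = synthetic.structure_to_map(s, gamma=1.0)
        wd = wish_distances(m, 1.0)
        base = dscc(s, wd)
        from scipy.linalg import qr

        q, r = qr(rng.standard_normal((3, 3)))
        q = q * np.sign(np.diag(r))
        moved = Structure(3.7 * (s.coords @ q.T) + np.array([5.0, -2.0, 1.0]))
        assert dscc(moved, wd) == pytest.approx(base, abs=1e-12)

    def test_constant_vector_errors(self):
        s = Structure(np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]]))
        wd = wd_from_pairs(4, {(0, 1): 1.0, (1, 2): 1.0, (2, 3): 1.0})
        with pytest.raises(ValueError, match="constant"):
            dscc(s, wd)

    def test_too_few_pairs_errors(self):
        s = Structure(np.zeros((3, 3)))
        wd = wd_from_pairs(3, {(0, 1): 1.0, (1, 2): 2.0})
        with pytest.raises(ValueError, match="3"):
            dscc(s, wd)


class TestDrmsd:
    def test_perfect_structure_zero(self, helix30):
        s, m = helix30
        assert drmsd(s, wish_distances(m, 1.0)) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_hand_value(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        wd = wd_from_pairs(3, {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0})
        assert drmsd(Structure(coords), wd) == pytest.approx(np.sqrt(1 / 3), rel=1e-12)

    def test_rescale_never_larger(self, rng, helix30):
        s, m = helix30
        wd = wish_distances(m, 1.0)
        scaled = Structure(s.coords * rng.uniform(0.1, 5.0))
        assert drmsd(scaled, wd, rescale=True) <= drmsd(scaled, wd, rescale=False) + 1e-12

    def test_rescale_undoes_uniform_scaling(self, helix30):
        s, m = helix30
        wd = wish_distances(m, 1.0)
        assert drmsd(Structure(s.coords * 4.2), wd, rescale=True) == pytest.approx(0.0, abs=1e-9)


class TestInterpolateStructure:
    def test_midpoint_insertion(self):
        s = Structure(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        out = interpolate_structure(s, 2)
        np.testing.assert_allclose(out.coords, [[0, 0, 0], [1, 0, 0], [2, 0, 0]])

    def test_identity_for_k1(self, helix30):
        s, _ = helix30
        np.testing.assert_array_equal(interpolate_structure(s, 1).coords, s.coords)

    def test_k4_equal_spacing(self):
        s = Structure(np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        out = interpolate_structure(s, 4)
        assert len(out.coords) == 5
        gaps = np.linalg.norm(np.diff(out.coords, axis=0), axis=1)
        np.testing.assert_allclose(gaps, 1.0, atol=1e-12)

    def test_point_count_formula(self, helix30):
        s, _ = helix30
        out = interpolate_structure(s, 2)
        assert len(out.coords) == 2 * (s.n_loci - 1) + 1

    def test_padding_to_target(self, helix30):
        s, _ = helix30
        out = interpolate_structure(s, 2, target_n=60)
        assert len(out.coords) == 60
        np.testing.assert_array_equal(out.coords[-1], out.coords[-2])

    def test_invalid_k_rejected(self, helix30):
        s, _ = helix30
        with pytest.raises(ValueError):
            interpolate_structure(s, 0)


class TestCallCompartments:
    @pytest.fixture()
    def two_block_map(self):
        # planted two-community contact map: strong within, weak between
        rng = np.random.default_rng(5)
        n1, n2 = 12, 8
        n = n1 + n2
        c = np.full((n, n), 0.2) + rng.random((n, n)) * 0.05
        c[:n1, :n1] += 2.0
        c[n1:, n1:] += 2.0
        c = (c + c.T) / 2
        np.fill_diagonal(c, 0.0)
        return ContactMap(c), n1, n2

    def test_recovers_planted_partition(self, two_block_map):
        m, n1, n2 = two_block_map
        calls = call_compartments(m)
        labels = calls.labels
        assert len(set(labels[:n1])) == 1
        assert len(set(labels[n1:])) == 1
        assert labels[0] != labels[-1]

    def test_larger_compartment_labeled_a(self, two_block_map):
        m, n1, n2 = two_block_map
        calls = call_compartments(m)
        assert (calls.labels == "A").sum() >= (calls.labels == "B").sum()
        assert calls.labels[0] == "A"  # block 1 is larger

    def test_label_count_matches_retained_loci(self, two_block_map):
        m, _, _ = two_block_map
        calls = call_compartments(m)
        assert len(calls.labels) == len(calls.kept_indices) == m.n_loci

    def test_partition_independent_of_eigenvector_sign(self, two_block_map):
        # the convention fix makes the labeling deterministic: recomputing
        # after permuting block order still splits on the planted blocks
        m, n1, n2 = two_block_map
        perm = np.roll(np.arange(m.n_loci), n2)
        m2 = ContactMap(m.counts[np.ix_(perm, perm)])
        calls = call_compartments(m2)
        assert len(np.unique(calls.labels[:n2])) == 1
        assert len(np.unique(calls.labels[n2:])) == 1

    def test_intra_closer_than_inter_on_planted_structure(self):
        s = synthetic.make_structure(24, "two_domain", seed=2)
        m = synthetic.structure_to_map(s, gamma=1.0)
        calls = call_compartments(m)
        a = np.flatnonzero(calls.labels == "A")
        b = np.flatnonzero(calls.labels == "B")
        dm = s.pairwise_distances()
        intra = np.concatenate(
            [dm[np.ix_(a, a)][np.triu_indices(len(a), 1)], dm[np.ix_(b, b)][np.triu_indices(len(b), 1)]]
        )
        inter = dm[np.ix_(a, b)].ravel()
        assert intra.mean() < inter.mean()


class TestRegionDistanceCompare:
    def test_adjacent_closer_than_distant_on_line(self):
        coords = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        s = Structure(coords)
        near = [(i, i + 1) for i in range(9)]
        far = [(i, i + 5) for i in range(5)]
        (m1, m2), p = region_distance_compare(s, near, far)
        assert m1 < m2
        assert p < 0.05

    def test_identical_sets_equal_means(self, helix30):
        s, _ = helix30
        pairs = [(0, 5), (3, 9), (10, 20)]
        (m1, m2), p = region_distance_compare(s, pairs, pairs)
        assert m1 == m2
        assert p == 1.0

    def test_empty_set_rejected(self, helix30):
        s, _ = helix30
        with pytest.raises(ValueError):
            region_distance_compare(s, [], [(0, 1)])

    def test_planted_loops_significantly_closer(self):
        rng = np.random.default_rng(9)
        s = synthetic.make_structure(40, "random_walk", seed=4)
        coords = s.coords.copy()
        loops = [(3, 30), (8, 35), (12, 28), (5, 25)]
        for i, j in loops:  # pull loop anchors together
            mid = (coords[i] + coords[j]) / 2
            coords[i] = mid + rng.standard_normal(3) * 0.05
            coords[j] = mid - rng.standard_normal(3) * 0.05
        planted = Structure(coords)
        nonloops = [(2, 27), (7, 33), (11, 31), (6, 24), (4, 29), (9, 36)]
        (m1, m2), p = region_distance_compare(planted, loops, nonloops)
        assert m1 < m2
        assert p < 0.05
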