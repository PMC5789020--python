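"""Minimum-image distances, neighbour tables, rank histograms, RDF, coordination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import hydroshell as hs
from hydroshell.neighbors import oo_distance_matrix

from conftest import brute_min_image, brute_neighbor_lists, cluster_frame


def sc_lattice_frame(m=4, a=3.0):
    """Simple-cubic oxygen lattice, m³ sites, spacing a, periodic box m·a."""
    pts = a * np.array([[i, j, k] for i in range(m) for j in range(m) for k in range(m)], float)
    return hs.BoxedFrame(pts, np.empty((0, 3)), box=np.full(3, m * a))


class TestMinimumImage:
    @pytest.mark.parametrize(
        "a,b,box,expected",
        [
            ((0, 0, 0), (9, 0, 0), (10, 10, 10), 1.0),
            ((3, 4, 5), (3, 4, 5), (10, 10, 10), 0.0),
            # half-box corner: nearest image of (5,5,5) from the origin
            ((0, 0, 0), (5, 5, 5), (10, 10, 10), np.sqrt(75.0)),
        ],
    )
    def test_examples(self, a, b, box, expected):
        assert hs.minimum_image_distance(a, b, box) == pytest.approx(expected, abs=1e-9)
        assert brute_min_image(a, b, box) == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_27_image_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        box = rng.uniform(4, 15, 3)
        # within 1.5 box lengths of each other: the 27-image search is exact
        a = rng.uniform(0, 1, 3) * box
        b = rng.uniform(0, 1, 3) * 1.5 * box - 0.5 * box
        assert hs.minimum_image_distance(a, b, box) == pytest.approx(
            brute_min_image(a, b, box), abs=1e-10
        )


class TestNeighborTable:
    def test_two_molecules(self):
        f = hs.BoxedFrame([[1, 1, 1], [4, 1, 1]], np.empty((0, 3)), box=[20, 20, 20])
        t = hs.build_neighbor_table(f, max_rank=1)
        np.testing.assert_allclose(t.distances, [[3.0], [3.0]])
        np.testing.assert_array_equal(t.indices, [[1], [0]])

    def test_simple_cubic_first_six_ranks(self):
        f = sc_lattice_frame(m=4, a=3.0)
        t = hs.build_neighbor_table(f, max_rank=6)
        np.testing.assert_allclose(t.distances, 3.0, atol=1e-10)

    def test_max_rank_must_be_below_n(self):
        f = hs.BoxedFrame([[0, 0, 0], [1, 0, 0]], np.empty((0, 3)), box=[10, 10, 10])
        with pytest.raises(ValueError, match="max_rank"):
            hs.build_neighbor_table(f, max_rank=2)

    def test_matches_brute_force_on_random_frame(self, rng):
        f = hs.BoxedFrame(
            rng.uniform(0, 12, (40, 3)), np.empty((0, 3)), box=[12.0, 12.0, 12.0]
        )
        t = hs.build_neighbor_table(f, max_rank=8)
        ref = brute_neighbor_lists(f.oxygen_positions, f.box, max_rank=8)
        for i, row in enumerate(ref):
            np.testing.assert_allclose(t.distances[i], [d for d, _ in row], atol=1e-9)
            assert list(t.indices[i]) == [j for _, j in row]

    def test_symmetric_consistency(self, rng):
        f = hs.BoxedFrame(rng.uniform(0, 10, (30, 3)), np.empty((0, 3)), box=[10] * 3)
        t = hs.build_neighbor_table(f, max_rank=29)
        dist = {(i, j): d for i in range(30) for d, j in zip(t.distances[i], t.indices[i])}
        j0 = t.indices[0, 0]
        assert dist[(j0, 0)] == pytest.approx(t.distances[0, 0], abs=1e-12)

    def test_translation_and_relabel_invariance(self, rng):
        o = rng.uniform(0, 10, (20, 3))
        box = np.array([10.0, 10.0, 10.0])
        f1 = hs.BoxedFrame(o, np.empty((0, 3)), box=box)
        f2 = hs.wrap(hs.BoxedFrame(o + [3.3, -7.1, 12.9], np.empty((0, 3)), box=box))
        t1 = hs.build_neighbor_table(f1, 5)
        t2 = hs.build_neighbor_table(f2, 5)
        np.testing.assert_allclose(t1.distances, t2.distances, atol=1e-9)
        perm = rng.permutation(20)
        f3 = hs.BoxedFrame(o[perm], np.empty((0, 3)), box=box)
        t3 = hs.build_neighbor_table(f3, 5)
        np.testing.assert_allclose(np.sort(t3.distances, axis=0), np.sort(t1.distances, axis=0), atol=1e-9)


class TestRankDistribution:
    def test_single_occupied_bin(self):
        f = sc_lattice_frame(m=3, a=3.0)
        rd = hs.rank_distribution([f], k=1, bins=np.arange(0, 5, 0.5))
        assert rd.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert rd.probabilities[np.digitize(3.0, rd.bin_edges) - 1] == pytest.approx(1.0)

    def test_hand_placed_fifth_neighbour(self):
        offsets = [
            [2.7, 0, 0], [0, 2.8, 0], [0, 0, 2.9], [-3.0, 0, 0], [0, -3.4, 0],
        ]
        f = cluster_frame([20, 20, 20], offsets)
        rd = hs.rank_distribution([f], k=5, bins=np.arange(0, 6, 0.1))
        # the central molecule's rank-5 distance is 3.4 Å by construction, so
        # the bin containing 3.4 must carry mass
        bin_34 = np.digitize(3.4, rd.bin_edges) - 1
        assert rd.probabilities[bin_34] > 0

    def test_overflow_flagged(self):
        f = hs.BoxedFrame([[0, 0, 0], [0, 0, 9]], np.empty((0, 3)), box=[20] * 3)
        rd = hs.rank_distribution([f], k=1, bins=np.arange(0, 5, 0.5))
        assert rd.overflow == pytest.approx(1.0)

    def test_requires_valid_rank_and_frames(self):
        f = sc_lattice_frame(2)
        with pytest.raises(ValueError):
            hs.rank_distribution([f], k=0, bins=np.arange(0, 5, 0.5))
        with pytest.raises(ValueError):
            hs.rank_distribution([], k=1, bins=np.arange(0, 5, 0.5))

    def test_ideal_gas_matches_poisson_law(self):
        """r_k of a uniform gas follows the kth-nearest-neighbour law of a
        Poisson process: P(r_k > r) = P(Poisson(4/3 πρ r³) < k)."""
        frames = [hs.ideal_gas(300, 55.3173, seed=s) for s in range(8)]
        k = 3
        samples = np.concatenate(
            [hs.build_neighbor_table(f, k).rank(k) for f in frames]
        )
        rho = frames[0].number_density

        def cdf(r):
            lam = 4.0 / 3.0 * np.pi * rho * np.asarray(r) ** 3
            return stats.gamma.cdf(lam, a=k)  # P(r_k <= r)

        stat = stats.ks_1samp(samples, cdf).statistic
        # molecules share neighbours so samples are weakly dependent; the
        # bound is loose but excludes any systematically wrong law
        assert stat < 0.03


class TestRDF:
    def test_ideal_gas_is_flat(self):
        frames = [hs.ideal_gas(200, 55.3173, seed=s) for s in range(10)]
        res = hs.rdf(frames, bin_width=0.2)
        n, rho = 200, res.number_density
        shell = 4.0 / 3.0 * np.pi * np.diff(res.bin_edges**3)
        lam = len(frames) * n * rho * shell / 2.0  # expected pair count per bin
        sel = res.bin_centers > 1.0
        # per-bin Poisson sampling error: |g-1| within 5 relative sigma
        assert np.all(np.abs(res.g[sel] - 1.0) < 5.0 / np.sqrt(lam[sel]))
        assert abs(res.g[sel].mean() - 1.0) < 0.02

    def test_two_molecules_single_peak(self):
        f = hs.BoxedFrame([[1, 1, 1], [1, 1, 3.8]], np.empty((0, 3)), box=[10] * 3)
        res = hs.rdf([f], bin_width=0.1)
        occupied = np.nonzero(res.g)[0]
        assert len(occupied) == 1
        assert res.bin_edges[occupied[0]] <= 2.8 < res.bin_edges[occupied[0] + 1]

    def test_lattice_peaks_at_shell_radii(self):
        f = sc_lattice_frame(m=5, a=3.0)
        res = hs.rdf([f], bin_width=0.05)
        occupied = res.bin_centers[res.g > 0]
        # sc shells: a, a√2, a√3, 2a ... below L/2 = 7.5
        for shell in (3.0, 3.0 * np.sqrt(2), 3.0 * np.sqrt(3), 6.0):
            assert np.min(np.abs(occupied - shell)) < 0.05
        for r in occupied:
            shells = 3.0 * np.sqrt(np.array([1, 2, 3, 4, 5, 6]))
            assert np.min(np.abs(shells - r)) < 0.05

    def test_r_max_beyond_half_box_rejected(self):
        f = sc_lattice_frame(m=3, a=3.0)
        with pytest.raises(ValueError, match="half"):
            hs.rdf([f], r_max=5.0)


class TestCoordination:
    def test_ideal_gas_closed_form(self):
        frames = [hs.ideal_gas(200, 55.3173, seed=100 + s) for s in range(10)]
        res = hs.rdf(frames, bin_width=0.05)
        rho = res.number_density
        for r_cut in (2.0, 3.0, 4.0):
            expected = 4.0 / 3.0 * np.pi * rho * r_cut**3
            # Poisson sampling error of the total pair count inside r_cut
            n_pairs = len(frames) * 200 * expected / 2.0
            tol = max(4.0 / np.sqrt(n_pairs), 0.01)
            assert hs.coordination_number(res, r_cut) == pytest.approx(expected, rel=tol)

    def test_zero_cutoff(self):
        f = sc_lattice_frame(m=3)
        res = hs.rdf([f])
        assert hs.coordination_number(res, 0.0) == 0.0

    def test_monotone_in_cutoff(self):
        frames = [hs.ideal_gas(100, 55.3173, seed=5)]
        res = hs.rdf(frames)
        cuts = np.linspace(0, res.bin_edges[-1], 40)
        vals = [hs.coordination_number(res, c) for c in cuts]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_neighbour_conservation_two_molecules(self):
        # all pairs inside the integration sphere: n(r_max) recovers N-1
        f = hs.BoxedFrame([[1, 1, 1], [1, 1, 3]], np.empty((0, 3)), box=[10] * 3)
        res = hs.rdf([f], bin_width=0.05)
        assert hs.coordination_number(res, 4.9) == pytest.approx(1.0, rel=0.02)
        assert hs.coordination_count([f], 4.9) == pytest.approx(1.0)

    def test_rdf_integral_matches_direct_count(self):
        frames = [hs.ideal_gas(150, 55.3173, seed=40 + s) for s in range(5)]
        res = hs.rdf(frames, bin_width=0.02)
        for r_cut in (2.5, 3.5):
            assert hs.coordination_number(res, r_cut) == pytest.approx(
                hs.coordination_count(frames, r_cut), rel=0.03, abs=0.02
            )
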