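"""Histogramming, KLD, windowed divergence and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trajdiverge import (
    BinningSpec,
    ConfigurationError,
    GeometryError,
    build_distribution,
    divergence_profile,
    joint_geometry,
    kld,
    normalize_maps,
    resolve_selection,
    symmetrized_kld,
    window_bounds,
    windowed_divergence,
)
from trajdiverge.divergence import BinGeometry, ResidueDistribution
from trajdiverge.synthetic import generate_reference_chain

from conftest import make_chain


def dist_from_counts(counts, pseudocount=0.5, shape=None):
    counts = np.asarray(counts, dtype=float)
    if shape is None:
        shape = (counts.size, 1, 1)
    geom = BinGeometry((0.0, 0.0, 0.0), 0.1, shape)
    return ResidueDistribution(
        residue_index=1,
        counts=counts.ravel(),
        n=int(counts.sum()),
        geometry=geom,
        pseudocount=pseudocount,
    )


def kld_oracle(P, Q):
    """Direct summation over bins, plain Python loop."""
    p = P.probabilities
    q = Q.probabilities
    total = 0.0
    for k in range(len(p)):
        total += q[k] * np.log(q[k] / p[k])
    return total


class TestBuildDistribution:
    def test_point_mass_lands_in_one_bin(self):
        traj = make_chain(3, n_frames=50)
        spec = BinningSpec()
        box = joint_geometry(traj.coords[:, 0], traj.coords[:, 0], spec.bin_width)
        d = build_distribution(traj, 1, None, spec, box)
        assert d.n == 50
        assert d.counts.max() == 50
        assert (d.counts > 0).sum() == 1
        assert abs(d.probabilities.sum() - 1.0) < 1e-12

    def test_uniform_over_eight_bin_centers(self):
        # frames cycle over the 8 corners of a cube, one bin apart
        corners = 0.25 * np.array(
            [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
        )
        coords = np.tile(corners, (100, 1))[:, None, :]
        traj = make_chain(1, n_frames=800).with_coords(coords)
        spec = BinningSpec(bin_width=0.25)
        box = joint_geometry(coords[:, 0], coords[:, 0], spec.bin_width)
        d = build_distribution(traj, 1, None, spec, box)
        occupied = d.counts[d.counts > 0]
        assert len(occupied) == 8
        np.testing.assert_allclose(occupied, 100)

    def test_matches_histogramdd_counting_oracle(self, rng):
        # positions kept strictly interior to bins so that the floor-based
        # binning and the edge-comparison oracle cannot disagree on FP ties
        bw = 0.05
        pos = bw * (
            rng.integers(-10, 10, size=(1000, 1, 3))
            + rng.uniform(0.25, 0.75, size=(1000, 1, 3))
        )
        traj = make_chain(1, n_frames=1000).with_coords(pos)
        spec = BinningSpec(bin_width=bw)
        geom = joint_geometry(pos[:, 0], pos[:, 0], spec.bin_width)
        d = build_distribution(traj, 1, None, spec, geom)
        edges = [
            geom.origin[a] + spec.bin_width * np.arange(geom.shape[a] + 1)
            for a in range(3)
        ]
        oracle, _ = np.histogramdd(pos[:, 0], bins=edges)
        np.testing.assert_array_equal(
            d.counts.reshape(geom.shape), oracle
        )

    def test_empty_frame_range_rejected(self):
        from trajdiverge import EmptyWindowError

        traj = make_chain(3, n_frames=10)
        spec = BinningSpec()
        box = joint_geometry(traj.coords[:, 0], traj.coords[:, 0], spec.bin_width)
        with pytest.raises(EmptyWindowError):
            build_distribution(traj, 1, slice(5, 5), spec, box)


class TestKld:
    def test_identity_is_zero(self):
        P = dist_from_counts([10, 20, 30])
        assert kld(P, P) == pytest.approx(0.0, abs=1e-12)
        assert symmetrized_kld(P, P) == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_direct_summation_oracle(self):
        # q = (0.9, 0.1), p = (0.5, 0.5) exactly, via large counts and a
        # vanishing pseudocount contribution handled identically both ways
        P = dist_from_counts([500, 500], pseudocount=1e-9)
        Q = dist_from_counts([900, 100], pseudocount=1e-9)
        expected = 0.9 * np.log(0.9 / 0.5) + 0.1 * np.log(0.1 / 0.5)
        assert kld(P, Q) == pytest.approx(expected, rel=1e-6)
        sym = symmetrized_kld(P, Q)
        rev = 0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1)
        assert sym == pytest.approx(0.5 * (expected + rev), rel=1e-6)

    def test_concentrated_mass_grows_as_pseudocount_shrinks(self):
        values = []
        for pc in (1.0, 0.1, 0.01):
            P = dist_from_counts([100, 0], pseudocount=pc)
            Q = dist_from_counts([0, 100], pseudocount=pc)
            values.append(kld(P, Q))
        assert values[0] < values[1] < values[2]
        assert np.isfinite(values[-1])

    def test_geometry_mismatch_rejected(self):
        P = dist_from_counts([1, 2, 3])
        Q = dist_from_counts([1, 2, 3, 4])
        with pytest.raises(GeometryError):
            kld(P, Q)

    def test_symmetry_to_machine_precision(self, rng):
        for _ in range(20):
            cP = rng.integers(0, 50, size=27)
            cQ = rng.integers(0, 50, size=27)
            P = dist_from_counts(cP, shape=(3, 3, 3))
            Q = dist_from_counts(cQ, shape=(3, 3, 3))
            assert symmetrized_kld(P, Q) == pytest.approx(
                symmetrized_kld(Q, P), abs=1e-12
            )

    def test_matches_loop_oracle_on_random_histograms(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 65))
            P = dist_from_counts(rng.integers(0, 100, size=k))
            Q = dist_from_counts(rng.integers(0, 100, size=k))
            assert kld(P, Q) == pytest.approx(kld_oracle(P, Q), abs=1e-12)
            expected_sym = 0.5 * (kld_oracle(P, Q) + kld_oracle(Q, P))
            assert symmetrized_kld(P, Q) == pytest.approx(expected_sym, abs=1e-12)

    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 200), st.integers(0, 200)),
            min_size=2, max_size=32,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_nonnegative_and_zero_iff_identical(self, counts):
        cP = [c[0] for c in counts]
        cQ = [c[1] for c in counts]
        P = dist_from_counts(cP)
        Q = dist_from_counts(cQ)
        v = symmetrized_kld(P, Q)
        assert v >= 0
        if cP == cQ:
            assert v == pytest.approx(0.0, abs=1e-12)
        # scaling both identically keeps the value symmetric
        assert v == pytest.approx(symmetrized_kld(Q, P), abs=1e-12)


class TestProfile:
    def test_self_comparison_is_zero(self, rng):
        traj = make_chain(5, n_frames=100).with_coords(
            rng.normal(size=(100, 5, 3))
        )
        sel = resolve_selection(traj, "backbone")
        prof = divergence_profile(traj, traj, sel)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)
        assert (prof.values >= 0).all()

    def test_planted_mean_shift_ranks_top(self, rng):
        n_res, n_frames = 40, 1500
        ref = generate_reference_chain(n_res)
        base = ref.coords[0]
        shift = np.zeros((n_res, 3))
        shift[19:24, 0] = 0.5  # residues 20-24
        A = ref.with_coords(base + rng.normal(scale=0.1, size=(n_frames, n_res, 3)))
        B = ref.with_coords(
            base + shift + rng.normal(scale=0.1, size=(n_frames, n_res, 3))
        )
        sel = resolve_selection(ref, "backbone")
        prof = divergence_profile(A, B, sel)
        assert sorted(prof.top_residues(5)) == [20, 21, 22, 23, 24]

    def test_similar_high_motility_gives_low_divergence(self, rng):
        # both trajectories highly mobile at one residue but identically
        # distributed there -> divergence stays near the estimator floor
        n_res, n_frames = 20, 2000
        ref = generate_reference_chain(n_res)
        base = ref.coords[0]
        sigma = np.full((n_res, 1), 0.05)
        sigma[9] = 0.5  # residue 10: 10x motility in both
        A = ref.with_coords(base + rng.normal(size=(n_frames, n_res, 3)) * sigma)
        B = ref.with_coords(base + rng.normal(size=(n_frames, n_res, 3)) * sigma)
        shift = np.zeros((n_res, 3))
        shift[14, 0] = 0.3  # residue 15: genuinely different mean
        C = ref.with_coords(
            base + shift + rng.normal(size=(n_frames, n_res, 3)) * sigma
        )
        sel = resolve_selection(ref, "backbone")
        same_motion = divergence_profile(A, B, sel).values[9]
        different_mean = divergence_profile(A, C, sel).values[14]
        assert same_motion < 0.5 * different_mean


class TestWindows:
    def test_quoted_window_indexing(self):
        starts, stops = window_bounds(200, 50)
        # windows are 1-based: window 49 covers snapshots 1-49
        assert (starts[48], stops[48]) == (1, 49)
        assert (starts[49], stops[49]) == (1, 50)
        assert (starts[50], stops[50]) == (2, 51)
        # trailing windows shrink from the left down to one snapshot
        assert (starts[-1], stops[-1]) == (200, 200)
        assert len(starts) == 200 + 50 - 1

    def test_small_max_window_rejected(self):
        with pytest.raises(ConfigurationError):
            window_bounds(100, 1)

    def test_window_at_n_with_large_w_equals_full_profile(self, rng):
        n_frames = 120
        traj_a = make_chain(6, n_frames=n_frames).with_coords(
            rng.normal(scale=0.1, size=(n_frames, 6, 3))
        )
        traj_b = make_chain(6, n_frames=n_frames).with_coords(
            rng.normal(scale=0.1, size=(n_frames, 6, 3))
        )
        sel = resolve_selection(traj_a, "backbone")
        wmap = windowed_divergence(traj_a, traj_b, sel, max_window=150)
        prof = divergence_profile(traj_a, traj_b, sel)
        row = np.where(wmap.window_stops - wmap.window_starts + 1 == n_frames)[0]
        np.testing.assert_array_equal(
            wmap.values[row[0]], prof.values
        )

    def test_identical_pair_windows_are_zero(self):
        traj = make_chain(4, n_frames=100)
        sel = resolve_selection(traj, "backbone")
        wmap = windowed_divergence(traj, traj, sel, max_window=20)
        np.testing.assert_allclose(wmap.values, 0.0, atol=1e-12)

    def test_change_point_recovered_within_one_window(self, rng):
        # windowed estimates need coarse enough bins that a 50-snapshot
        # window populates the histogram (occupied bins << window size)
        n_frames, switch = 400, 200
        shift = np.zeros((n_frames, 1, 3))
        shift[switch:, 0, 0] = 0.6
        noise = lambda: rng.normal(scale=0.1, size=(n_frames, 1, 3))
        traj_a = make_chain(1, n_frames=n_frames).with_coords(noise())
        traj_b = make_chain(1, n_frames=n_frames).with_coords(noise() + shift)
        sel = resolve_selection(traj_a, "backbone")
        wmap = windowed_divergence(
            traj_a, traj_b, sel, BinningSpec(bin_width=0.2), max_window=50
        )
        series = wmap.values[:, 0]
        plateau = series[(wmap.window_starts > switch + 60) & (wmap.window_stops <= n_frames)].mean()
        first = np.argmax(series > 0.5 * plateau)
        assert abs(wmap.window_stops[first] - (switch + 1)) <= 50

    def test_unequal_lengths_truncated_with_warning(self, rng, caplog):
        traj_a = make_chain(2, n_frames=80).with_coords(
            rng.normal(size=(80, 2, 3))
        )
        traj_b = make_chain(2, n_frames=100).with_coords(
            rng.normal(size=(100, 2, 3))
        )
        sel = resolve_selection(traj_a, "backbone")
        with caplog.at_level("WARNING"):
            wmap = windowed_divergence(traj_a, traj_b, sel, max_window=30)
        assert wmap.window_stops.max() == 80
        assert any("truncat" in r.message for r in caplog.records)


class TestNormalization:
    def _map_with(self, values):
        from trajdiverge.divergence import WindowedDivergenceMap

        values = np.asarray(values, dtype=float)
        n = values.shape[0]
        return WindowedDivergenceMap(
            values=values,
            window_starts=np.arange(1, n + 1),
            window_stops=np.arange(1, n + 1),
            residue_indices=np.arange(1, values.shape[1] + 1),
            max_window=50,
            labels=("a", "b"),
            spec=BinningSpec(),
        )

    def test_single_map_scaled_by_its_max(self):
        m = self._map_with([[2.0, 1.0], [0.5, 0.0]])
        out = normalize_maps([m])[0]
        assert out.values.max() == 1.0
        np.testing.assert_allclose(out.values, [[1.0, 0.5], [0.25, 0.0]])
        assert out.normalization == 2.0

    def test_joint_scaling_across_maps(self):
        m1 = self._map_with([[1.0, 0.5]])
        m2 = self._map_with([[4.0, 2.0]])
        o1, o2 = normalize_maps([m1, m2])
        assert o1.values.max() == 0.25
        assert o2.values.max() == 1.0

    def test_argmax_locations_preserved(self, rng):
        m1 = self._map_with(rng.uniform(size=(6, 4)))
        m2 = self._map_with(rng.uniform(size=(6, 4)))
        o1, o2 = normalize_maps([m1, m2])
        assert np.argmax(o1.values) == np.argmax(m1.values)
        assert np.argmax(o2.values) == np.argmax(m2.values)

    def test_all_zero_maps_returned_unchanged(self, caplog):
        m = self._map_with(np.zeros((3, 2)))
        with caplog.at_level("WARNING"):
            out = normalize_maps([m])
        assert out[0] is m
        assert out[0].normalization is None
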