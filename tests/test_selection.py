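"""Per-band scoring criteria, window scoring/selection and the random baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hsiband import (
    BandScores,
    Hypercube,
    LabeledDataset,
    SelectionConfig,
    WavelengthAxis,
    band_std_scores,
    cumulative_window_scores,
    entropy_scores,
    mi_scores,
    mutual_information,
    random_window,
    select_for_dataset,
    select_window,
    shannon_entropy,
    spatial_mean,
)
from conftest import random_cube
from oracles import best_window_loops, entropy_loops, mi_loops, std_scores_loops, \
    window_scores_loops


class TestSpatialMean:
    def test_hand_example(self, small_axis):
        v = np.zeros((2, 2, 10))
        v[:, :, 0] = [[0, 0], [2, 2]]
        assert spatial_mean(Hypercube(v, small_axis), 0) == pytest.approx(1.0)

    def test_constant_cube(self, small_axis):
        cube = Hypercube(np.full((3, 3, 10), 4.5), small_axis)
        assert all(spatial_mean(cube, l) == 4.5 for l in range(10))

    def test_out_of_range_channel(self, small_cube):
        with pytest.raises(IndexError):
            spatial_mean(small_cube, 10)


class TestStdScores:
    def test_constant_cube_scores_zero(self, small_axis):
        cube = Hypercube(np.full((3, 3, 10), 2.0), small_axis)
        np.testing.assert_array_equal(band_std_scores(cube).scores, 0.0)

    def test_hand_example_population_std(self, small_axis):
        """Band {0,0,2,2}: mean 1, every squared deviation 1, sigma = 1."""
        v = np.ones((2, 2, 10))
        v[:, :, 3] = [[0, 0], [2, 2]]
        assert band_std_scores(Hypercube(v, small_axis)).scores[3] == pytest.approx(1.0)

    def test_matches_two_pass_loop_oracle(self, rng):
        cube = random_cube(rng, y=5, x=5, n=8)
        np.testing.assert_allclose(band_std_scores(cube).scores,
                                   std_scores_loops(cube.values), rtol=1e-12)

    def test_scaling_and_pixel_permutation_invariance(self, rng):
        cube = random_cube(rng)
        base = band_std_scores(cube).scores
        scaled = Hypercube(3.0 * cube.values, cube.axis)
        np.testing.assert_allclose(band_std_scores(scaled).scores, 3.0 * base,
                                   rtol=1e-12)
        perm = rng.permutation(16)
        shuffled = Hypercube(
            cube.values.reshape(16, -1)[perm].reshape(cube.shape), cube.axis)
        np.testing.assert_allclose(band_std_scores(shuffled).scores, base, rtol=1e-12)


class TestMutualInformation:
    def test_constant_band_gives_zero(self, rng, small_axis):
        v = rng.random((4, 4, 10))
        v[:, :, 2] = 1.0
        scores = mi_scores(Hypercube(v, small_axis), n_bins=8).scores
        assert scores[2] == 0.0

    def test_identical_binary_variables_give_one_bit(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        assert mutual_information(x, x, 2) == pytest.approx(1.0)

    def test_frozen_joint_table_value(self):
        """Joint bin frequencies [[0.5, 0], [0.25, 0.25]] carry 0.3113 bits."""
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([0.0, 0.0, 0.0, 1.0])
        assert mutual_information(x, y, 2) == pytest.approx(0.311278, abs=1e-5)

    def test_matches_counting_oracle(self, rng):
        for _ in range(20):
            x = rng.random(50)
            y = x + 0.3 * rng.random(50)
            got = mutual_information(x, y, 6)
            assert got == pytest.approx(mi_loops(x, y, 6), abs=1e-10)

    def test_bounded_by_min_marginal_entropy(self, rng):
        cube = random_cube(rng, y=6, x=6, n=10)
        flat = cube.values.reshape(-1, 10)
        mu = flat.mean(axis=1)
        h_mu = shannon_entropy(mu, 8)
        for l, i_l in enumerate(mi_scores(cube, n_bins=8).scores):
            h_l = shannon_entropy(flat[:, l], 8)
            assert -1e-12 <= i_l <= min(h_l, h_mu) + 1e-9


class TestEntropyScores:
    def test_constant_band_zero_bits(self, small_axis):
        cube = Hypercube(np.full((4, 4, 10), 3.0), small_axis)
        np.testing.assert_array_equal(entropy_scores(cube, 8).scores, 0.0)

    def test_uniform_over_four_bins_is_two_bits(self):
        v = np.repeat([0.0, 1.0, 2.0, 3.0], 4)
        assert shannon_entropy(v, 4) == pytest.approx(2.0)

    def test_frozen_occupancy_value(self):
        """Occupancies {1/2, 1/4, 1/4} give 1.5 bits."""
        v = np.array([0.0, 0.0, 1.0, 2.9])  # bins 0,0,1,2 with 3 bins over [0,3)
        assert shannon_entropy(v, 3) == pytest.approx(1.5)

    def test_matches_counting_oracle(self, rng):
        cube = random_cube(rng, y=5, x=5, n=6)
        flat = cube.values.reshape(-1, 6)
        got = entropy_scores(cube, 5).scores
        want = [entropy_loops(flat[:, l], 5) for l in range(6)]
        np.testing.assert_allclose(got, want, atol=1e-10)

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 10_000), n_bins=st.integers(2, 32))
    def test_bounds_and_affine_invariance(self, seed, n_bins):
        """0 <= H <= log2(B); H and I unchanged by increasing affine rescaling."""
        v = np.random.default_rng(seed).random(64)
        h = shannon_entropy(v, n_bins)
        assert 0.0 <= h <= np.log2(n_bins) + 1e-12
        assert shannon_entropy(2.5 * v + 1.0, n_bins) == pytest.approx(h, abs=1e-12)
        w = np.random.default_rng(seed + 1).random(64)
        assert mutual_information(2.5 * v + 1.0, w, n_bins) == pytest.approx(
            mutual_information(v, w, n_bins), abs=1e-12)


class TestWindowScoring:
    def test_constant_scores(self):
        s = BandScores(np.ones(12), "std")
        np.testing.assert_allclose(cumulative_window_scores(s, 5), 5.0)

    def test_hand_example(self):
        s = BandScores(np.array([1.0, 2, 3, 4, 5]), "std")
        np.testing.assert_allclose(cumulative_window_scores(s, 2), [3, 5, 7, 9])

    def test_full_width_conserves_total(self, rng):
        vec = rng.random(30)
        s = BandScores(vec, "std")
        out = cumulative_window_scores(s, 30)
        assert out.shape == (1,)
        assert out[0] == pytest.approx(vec.sum())

    @pytest.mark.parametrize("w", [0, 13])
    def test_width_out_of_range(self, w):
        with pytest.raises(ValueError):
            cumulative_window_scores(BandScores(np.ones(12), "std"), w)

    def test_conservation_against_direct_summation(self, rng):
        vec = rng.random(40)
        got = cumulative_window_scores(BandScores(vec, "std"), 7)
        np.testing.assert_allclose(got, window_scores_loops(vec, 7), rtol=1e-12)


class TestSelectWindow:
    def test_hand_example_argmax(self):
        win = select_window(BandScores(np.array([1.0, 2, 3, 4, 5]), "std"), 2)
        assert (win.s, win.e, win.score) == (3, 5, pytest.approx(9.0))

    def test_tie_breaks_to_smallest_start(self):
        win = select_window(BandScores(np.ones(10), "entropy"), 4)
        assert (win.s, win.e) == (0, 4)
        assert win.method == "entropy"

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            n = int(rng.integers(5, 60))
            w = int(rng.integers(1, n + 1))
            vec = rng.random(n)
            win = select_window(BandScores(vec, "std"), w)
            s_ref, score_ref = best_window_loops(vec, w)
            assert win.s == s_ref and win.e == s_ref + w
            assert win.score == pytest.approx(score_ref, rel=1e-12)


class TestRandomWindow:
    def test_full_width_single_start(self):
        win = random_window(10, 10, seed=3)
        assert (win.s, win.e) == (0, 10)

    def test_deterministic_given_seed(self):
        assert random_window(100, 20, seed=42) == random_window(100, 20, seed=42)

    def test_score_filled_from_supplied_scores(self, rng):
        vec = rng.random(50)
        win = random_window(50, 10, seed=5, scores=BandScores(vec, "std"))
        assert win.score == pytest.approx(vec[win.s:win.e].sum())
        assert random_window(50, 10, seed=5).score == 0.0

    def test_starts_uniform_chi_square(self):
        """10^4 draws over 81 admissible starts pass a goodness-of-fit test."""
        starts = [random_window(100, 20, seed=s).s for s in range(10_000)]
        counts = np.bincount(starts, minlength=81)
        assert counts.size == 81
        _, p = stats.chisquare(counts)
        assert p > 0.01


class TestDatasetSelection:
    def _dataset(self, cubes):
        return LabeledDataset(cubes, [0] * len(cubes), ["only"])

    def test_identical_cubes_match_single_cube_selection(self, rng):
        cube = random_cube(rng, n=12)
        ds = self._dataset([cube, Hypercube(cube.values.copy(), cube.axis)])
        cfg = SelectionConfig(method="std", window_nm=3.0)
        got = select_for_dataset(ds, cfg)
        solo = select_window(band_std_scores(cube), 3)
        assert (got.s, got.e) == (solo.s, solo.e)

    def test_mean_of_score_vectors_drives_argmax(self, rng, small_axis):
        """Two cubes whose std vectors average to [1..5] select window [3,5)."""
        axis = WavelengthAxis(400.0, 1.0, 5)

        def cube_with_stds(stds):
            # band values {m - s, m + s} have population std s
            v = np.empty((2, 2, 5))
            for l, s in enumerate(stds):
                v[:, :, l] = [[10 - s, 10 - s], [10 + s, 10 + s]]
            return Hypercube(v, axis)

        ds = self._dataset([cube_with_stds([0.5, 1, 1.5, 2, 2.5]),
                            cube_with_stds([1.5, 3, 4.5, 6, 7.5])])
        win = select_for_dataset(ds, SelectionConfig(method="std", window_nm=2.0))
        assert (win.s, win.e) == (3, 5)

    def test_window_wider_than_axis_rejected(self, rng):
        ds = self._dataset([random_cube(rng, n=8)])
        with pytest.raises(ValueError):
            select_for_dataset(ds, SelectionConfig(method="std", window_nm=50.0))

    def test_random_method_is_seeded(self, rng):
        ds = self._dataset([random_cube(rng, n=30)])
        cfg = SelectionConfig(method="random", window_nm=5.0, seed=11)
        assert select_for_dataset(ds, cfg) == select_for_dataset(ds, cfg)
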