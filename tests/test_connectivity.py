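"""Phase/power connectivity, statistical thresholding, degree maps."""

import numpy as np
import pytest
from scipy import stats

from phrasal import connectivity, tfr
from phrasal.connectivity import ConnectivityStack


def _stack_from_values(vals, kind="phase"):
    return ConnectivityStack(vals, kind)


class TestISPC:
    def test_fixed_phase_delay_gives_one(self):
        rng = np.random.default_rng(0)
        phases = rng.uniform(-np.pi, np.pi, size=(8, 1, 2, 10))
        a = np.exp(1j * phases)
        b = np.exp(1j * (phases + 0.7))  # constant lag
        coeffs = np.concatenate([a, b], axis=1)
        tf = tfr.TFRTensor(coeffs, np.ones(2), np.zeros(10), 100.0)
        vals = connectivity.ispc(tf).values
        np.testing.assert_allclose(vals[0, 1], 1.0, atol=1e-12)

    def test_symmetry(self, rng):
        coeffs = rng.normal(size=(6, 4, 2, 3)) + 1j * rng.normal(size=(6, 4, 2, 3))
        vals = connectivity.ispc(
            tfr.TFRTensor(coeffs, np.ones(2), np.zeros(3), 1.0)
        ).values
        np.testing.assert_allclose(vals, np.swapaxes(vals, 0, 1), atol=1e-12)

    def test_matches_resultant_oracle(self, rng):
        coeffs = rng.normal(size=(7, 3, 1, 2)) + 1j * rng.normal(size=(7, 3, 1, 2))
        tf = tfr.TFRTensor(coeffs, np.ones(1), np.zeros(2), 1.0)
        got = connectivity.ispc(tf).values
        # oracle: resultant length of the phase differences across trials
        for a in range(3):
            for b in range(3):
                dphi = np.angle(coeffs[:, a]) - np.angle(coeffs[:, b])
                want = np.abs(np.mean(np.exp(1j * dphi), axis=0))
                np.testing.assert_allclose(got[a, b], want, atol=1e-12)

    def test_uniform_phase_expectation(self, rng):
        # independent phases, n=10 trials: mean ISPC matches the Monte Carlo
        # resultant-length expectation within 3 SE
        reps = 10000
        coeffs = np.exp(1j * rng.uniform(-np.pi, np.pi, size=(10, 2, 1, reps)))
        got = connectivity.ispc(
            tfr.TFRTensor(coeffs, np.ones(1), np.zeros(reps), 1.0)
        ).values[0, 1, 0]
        mc = np.abs(np.mean(np.exp(
            1j * rng.uniform(-np.pi, np.pi, size=(10, reps))), axis=0))
        se = (got.std() + mc.std()) / np.sqrt(reps)
        assert abs(got.mean() - mc.mean()) < 3 * se


class TestPowerConnectivity:
    def test_identical_and_reversed_ranks(self):
        up = np.arange(5.0)
        power = np.stack([up, up, up[::-1]], axis=1).reshape(5, 3, 1, 1)
        vals = connectivity.power_connectivity(power).values
        assert vals[0, 1, 0, 0] == pytest.approx(1.0)
        assert vals[0, 2, 0, 0] == pytest.approx(-1.0)

    def test_toy_vectors_match_bruteforce_oracle(self):
        a = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        b = np.array([2.0, 7.0, 1.0, 8.0, 2.0])
        power = np.stack([a, b], axis=1).reshape(5, 2, 1, 1)
        got = connectivity.power_connectivity(power).values[0, 1, 0, 0]

        def avg_ranks(x):
            order = np.argsort(x, kind="stable")
            ranks = np.empty(len(x))
            ranks[order] = np.arange(1, len(x) + 1)
            for v in np.unique(x):
                ranks[x == v] = ranks[x == v].mean()
            return ranks

        ra, rb = avg_ranks(a), avg_ranks(b)
        want = np.corrcoef(ra, rb)[0, 1]
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(stats.spearmanr(a, b).statistic, abs=1e-12)

    def test_constant_power_flagged_missing(self):
        power = np.ones((4, 2, 1, 1))
        power[:, 0, 0, 0] = [1, 2, 3, 4]
        vals = connectivity.power_connectivity(power).values
        assert np.isnan(vals[0, 1, 0, 0])


class TestThresholdDegree:
    def test_all_equal_values_count_zero(self):
        vals = np.full((3, 3, 1, 2), 0.5)
        a = _stack_from_values(vals.copy())
        b = _stack_from_values(vals.copy())
        times = np.array([-0.5, 0.5])
        da, db = connectivity.threshold_degree(a, b, times)
        assert da.counts.sum() == 0 and db.counts.sum() == 0

    def test_toy_case_matches_hand_enumeration(self):
        # 4 channels -> 6 pairs; pooled values 0.1..1.2 across 2 conditions
        pool = np.arange(0.1, 1.25, 0.1)
        va = pool[:6]
        vb = pool[6:]
        n = 4
        iu = np.triu_indices(n, k=1)

        def mat(pairvals):
            m = np.zeros((n, n, 1, 1))
            m[iu] = pairvals.reshape(-1, 1, 1)
            m[iu[1], iu[0]] = pairvals.reshape(-1, 1, 1)
            return m

        a, b = _stack_from_values(mat(va)), _stack_from_values(mat(vb))
        times = np.zeros(1)
        da, db = connectivity.threshold_degree(
            a, b, times, baseline=(-1.0, 1.0))
        thr = np.median(pool) + 0.5 * np.std(pool)
        assert da.threshold[0, 0] == pytest.approx(thr)
        assert da.counts[0, 0] == np.sum(va > thr)
        assert db.counts[0, 0] == np.sum(vb > thr)

    def test_translation_invariance_of_binary_matrices(self, rng):
        vals_a = rng.uniform(size=(5, 5, 2, 3))
        vals_a = (vals_a + vals_a.swapaxes(0, 1)) / 2
        vals_b = rng.uniform(size=(5, 5, 2, 3))
        vals_b = (vals_b + vals_b.swapaxes(0, 1)) / 2
        times = np.array([-0.5, 0.0, 0.5])
        da1, db1 = connectivity.threshold_degree(
            _stack_from_values(vals_a), _stack_from_values(vals_b), times)
        da2, db2 = connectivity.threshold_degree(
            _stack_from_values(vals_a + 3.0), _stack_from_values(vals_b + 3.0),
            times)
        np.testing.assert_array_equal(da1.binary, da2.binary)
        np.testing.assert_array_equal(db1.binary, db2.binary)

    def test_degree_conservation(self, rng):
        vals = rng.uniform(size=(6, 6, 1, 4))
        vals = (vals + vals.swapaxes(0, 1)) / 2
        times = np.linspace(-0.5, 0.5, 4)
        da, _ = connectivity.threshold_degree(
            _stack_from_values(vals), _stack_from_values(vals[..., ::-1]), times)
        iu = np.triu_indices(6, k=1)
        np.testing.assert_array_equal(da.counts, da.binary[iu].sum(axis=0))
        assert da.counts.max() <= 6 * 5 // 2


class TestSeedExport:
    def test_all_ones_matrix(self):
        binary = np.ones((4, 4, 2))
        prof = connectivity.seed_connectivity_export(binary, [0, 2])
        np.testing.assert_array_equal(prof, np.ones((4, 2)))

    def test_isolated_seed(self):
        binary = np.zeros((3, 3))
        prof = connectivity.seed_connectivity_export(binary, [1])
        np.testing.assert_array_equal(prof, np.zeros(3))

    def test_profile_is_mean_of_seed_rows(self, rng):
        binary = rng.integers(0, 2, size=(5, 5)).astype(float)
        seeds = [0, 3]
        got = connectivity.seed_connectivity_export(binary, seeds)
        np.testing.assert_allclose(got, binary[seeds].mean(axis=0))

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError):
            connectivity.seed_connectivity_export(np.ones((3, 3)), [])


class TestTopChannels:
    def test_per_hemisphere_selection(self):
        metric = np.array([0.1, 0.9, 0.5, 0.7, 0.2, 0.8])
        hemi = np.array(["L", "L", "L", "R", "R", "R"])
        sel = connectivity.select_top_channels(metric, 2, hemi)
        assert list(sel["L"]) == [1, 2]
        assert list(sel["R"]) == [5, 3]
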