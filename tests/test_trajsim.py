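"""Statistical and contract tests of the trajectory simulator."""

import numpy as np
import pytest
from scipy import stats

from dlmss import trajsim as ts
from dlmss.exceptions import ParameterError, ValidationError

EQ_PI = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])


class TestTrackLength:
    def test_floor_enforced(self, rng):
        lengths = [ts.sample_track_length(1 / 50, 5, rng) for _ in range(2000)]
        assert min(lengths) >= 5

    def test_huge_rate_collapses_to_floor(self, rng):
        lengths = [ts.sample_track_length(1e3, 5, rng) for _ in range(200)]
        assert set(lengths) == {5}

    def test_mean_matches_truncated_exponential_oracle(self, rng):
        # oracle: brute-force rejection sampling of the same truncated law
        oracle_rng = np.random.default_rng(999)
        draws = np.ceil(oracle_rng.exponential(50.0, size=400_000))
        oracle_mean = draws[draws >= 5].mean()
        sample = [ts.sample_track_length(1 / 50, 5, rng) for _ in range(100_000)]
        assert np.mean(sample) == pytest.approx(oracle_mean, rel=0.05)

    def test_nonpositive_rate_rejected(self, rng):
        with pytest.raises(ParameterError):
            ts.sample_track_length(0.0, 5, rng)


class TestStateSequence:
    def test_identity_matrix_is_absorbing(self, rng):
        seq = ts.sample_state_sequence(np.eye(3), 500, rng, init=2)
        assert np.all(seq == 2)

    def test_self_transition_frequency_matches_matrix(self, rng):
        seq = ts.sample_state_sequence(EQ_PI, 1_000_000, rng)
        for k in range(3):
            at_k = seq[:-1] == k
            stay = np.mean(seq[1:][at_k] == k)
            assert stay == pytest.approx(0.8, abs=0.01)

    def test_dwell_times_geometric(self, rng):
        """Dwell-length histogram consistent with Geometric(p=0.2)."""
        seq = ts.sample_state_sequence(EQ_PI, 200_000, rng)
        bounds = np.flatnonzero(np.diff(seq)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [len(seq)]])
        dwells = np.array([e - s for s, e, in zip(starts, ends) if seq[s] == 0])
        kmax = 25
        observed = np.bincount(np.minimum(dwells, kmax), minlength=kmax + 1)[1:]
        p = 0.2
        probs = np.array([(1 - p) ** (k - 1) * p for k in range(1, kmax)])
        probs = np.append(probs, (1 - p) ** (kmax - 1))  # tail bin
        chi2 = stats.chisquare(observed, probs * observed.sum())
        assert chi2.pvalue > 0.01

    def test_empirical_transition_matrix_entrywise(self, rng):
        seq = ts.sample_state_sequence(EQ_PI, 1_000_000, rng)
        counts = np.zeros((3, 3))
        np.add.at(counts, (seq[:-1], seq[1:]), 1)
        emp = counts / counts.sum(axis=1, keepdims=True)
        assert np.all(np.abs(emp - EQ_PI) < 0.01)

    def test_non_stochastic_matrix_rejected(self, rng):
        with pytest.raises(ValidationError):
            ts.sample_state_sequence(np.array([[0.5, 0.4], [0.1, 0.9]]), 10, rng)


class TestBrownian:
    def test_zero_diffusion_is_frozen(self, rng):
        steps = ts.simulate_brownian_steps(0.0, 0.032, 100, rng)
        assert np.all(steps == 0.0)

    def test_variance_closed_form(self, rng):
        steps = ts.simulate_brownian_steps(1.0, 0.032, 100_000, rng)
        for c in range(2):
            assert steps[:, c].var() == pytest.approx(0.064, rel=0.02)

    def test_steps_uncorrelated(self, rng):
        steps = ts.simulate_brownian_steps(1.0, 0.032, 100_000, rng)
        r = np.corrcoef(steps[:-1, 0], steps[1:, 0])[0, 1]
        assert abs(r) < 0.01

    def test_negative_d_rejected(self, rng):
        with pytest.raises(ParameterError):
            ts.simulate_brownian_steps(-1.0, 0.032, 10, rng)


class TestFbm:
    @pytest.mark.parametrize("method", ["exact", "ma"])
    def test_zero_noise_gives_zero_displacements(self, rng, method):
        fbm = ts.FbmParams(method=method)
        n = 20
        need = 10_000  # generous stream for either construction
        steps = ts.simulate_fbm_steps(
            0.3, fbm, 1.0, n, rng, xi_x=np.zeros(need), xi_y=np.zeros(need)
        )
        assert np.all(steps == 0.0)

    def test_h_half_is_plain_gaussian(self, rng):
        """At H = 0.5 increments must match an i.i.d. normal sample (KS)."""
        fbm = ts.FbmParams()
        steps = ts.simulate_fbm_steps(0.5, fbm, 1.0, 2000, rng)
        dx = steps[:, 0] / steps[:, 0].std()
        ref = rng.standard_normal(10_000)
        assert stats.ks_2samp(dx, ref / ref.std()).pvalue > 0.01

    @pytest.mark.parametrize("method", ["exact", "ma"])
    def test_subdiffusive_anticorrelation(self, rng, method):
        fbm = ts.FbmParams(method=method)
        steps = ts.simulate_fbm_steps(0.1, fbm, 1.0, 2000, rng)
        dx = steps[:, 0]
        r = np.corrcoef(dx[:-1], dx[1:])[0, 1]
        assert r < -0.05

    def test_exact_matches_theoretical_autocovariance(self, rng):
        steps = ts.simulate_fbm_steps(0.1, ts.FbmParams(), 1.0, 2000, rng)
        dx = steps[:, 0]
        r = np.corrcoef(dx[:-1], dx[1:])[0, 1]
        theory = 0.5 * (2**0.2 - 2)
        assert r == pytest.approx(theory, abs=0.06)

    def test_invalid_hurst_rejected(self, rng):
        with pytest.raises(ParameterError):
            ts.simulate_fbm_steps(1.5, ts.FbmParams(), 1.0, 10, rng)

    def test_long_sequence_uses_same_law(self, rng):
        # Hosking path (beyond the Cholesky cache cap) has the same variance
        long = ts.simulate_fbm_steps(0.3, ts.FbmParams(), 1.0, 3000, rng)
        short = ts.simulate_fbm_steps(0.3, ts.FbmParams(), 1.0, 1000, rng)
        assert long[:, 0].std() == pytest.approx(short[:, 0].std(), rel=0.1)


class TestDataset:
    def test_zero_tracks(self, three_state, fbm_params, rng):
        assert ts.simulate_dataset(three_state, fbm_params, 0, rng) == []

    def test_labels_align_with_positions(self, three_state, fbm_params, rng):
        for tr in ts.simulate_dataset(three_state, fbm_params, 20, rng):
            assert len(tr.labels) == len(tr.positions)
            assert set(np.unique(tr.labels)) <= {0, 1, 2}
            assert len(tr) >= three_state.min_len

    def test_label_marginal_near_uniform(self, three_state, fbm_params, rng):
        """The symmetric chain's stationary distribution is uniform."""
        data = ts.simulate_dataset(three_state, fbm_params, 1000, rng)
        lab = np.concatenate([t.labels for t in data])
        marg = np.bincount(lab, minlength=3) / len(lab)
        # brute-force stationary distribution of the transition matrix
        w, v = np.linalg.eig(EQ_PI.T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi /= pi.sum()
        assert np.all(np.abs(marg - pi) < 0.02)

    def test_same_seed_same_dataset(self, three_state, fbm_params):
        a = ts.simulate_dataset(three_state, fbm_params, 30, np.random.default_rng(7))
        b = ts.simulate_dataset(three_state, fbm_params, 30, np.random.default_rng(7))
        assert len(a) == len(b)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.positions, y.positions)
            np.testing.assert_array_equal(x.labels, y.labels)

    def test_single_state_brownian_diffuses(self, rng, fbm_params):
        """A no-switching Brownian model produces MSS slope ~0.5 downstream."""
        from dlmss.mss import estimate_mss

        model = ts.SwitchingModel(
            states=(ts.MotionState(label=0, kind="brownian", D=1.0),),
            Pi=np.array([[1.0]]),
            min_len=300,
        )
        vals = [
            estimate_mss(ts.simulate_track(model, fbm_params, rng, n_frames=300).positions).S_mss
            for _ in range(30)
        ]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)
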