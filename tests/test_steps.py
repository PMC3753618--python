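"""Step statistics: drift, effective diffusion, tails, memory."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import locusdrift as ld
from locusdrift.tracks import COLUMNS, TrackEnsemble


def _free_ensemble(tracks, dt=1.0):
    rows = []
    for i, xs in enumerate(tracks):
        for k, x in enumerate(xs):
            rows.append([f"c{i}", k, k * dt, "locus", 0, x, np.nan])
    return TrackEnsemble(data=pd.DataFrame(rows, columns=list(COLUMNS)), dt=dt)


class TestComputeSteps:
    def test_simple_track(self):
        se = ld.compute_steps(_free_ensemble([[0.0, 0.1, 0.2]]))
        np.testing.assert_allclose(sorted(se.steps), [0.1, 0.1])

    def test_lag_three_on_five_frames_gives_two_steps(self):
        se = ld.compute_steps(_free_ensemble([[0.0, 0.1, 0.2, 0.3, 0.4]]), lag=3)
        assert len(se) == 2
        np.testing.assert_allclose(se.steps, [0.3, 0.3])
        assert se.dt_eff == 3.0

    def test_post_split_selection_rules(self, split_synced):
        right = ld.compute_steps(split_synced, "Post-Segregation", selection="right")
        left = ld.compute_steps(split_synced, "Post-Segregation", selection="left")
        both = ld.compute_steps(split_synced, "Post-Segregation", selection="both")
        mirrored = ld.compute_steps(split_synced, "Post-Segregation", selection="mirror")
        assert set(right.table["focus_id"]) == {1}
        assert set(left.table["focus_id"]) == {0}
        assert len(both) == len(right) + len(left) == len(mirrored)

    def test_mirror_pool_matches_right_only_mean(self, split_synced):
        """Left/right symmetry of the generator: mirror-pooling doubles n
        without shifting the mean drift."""
        right = ld.summarize_steps(
            ld.compute_steps(split_synced, "Rapid-Translocation", selection="right")
        )
        mirrored = ld.summarize_steps(
            ld.compute_steps(split_synced, "Rapid-Translocation", selection="mirror")
        )
        assert mirrored.n == 2 * right.n
        assert mirrored.v == pytest.approx(
            right.v, abs=3 * math.hypot(right.v_se, mirrored.v_se)
        )


class TestSummarizeSteps:
    def test_deterministic_steps(self):
        xs = list(np.arange(0, 0.2001, 0.02))
        s = ld.summarize_steps(ld.compute_steps(_free_ensemble([xs])))
        assert s.v == pytest.approx(0.02)
        assert s.d_eff == pytest.approx(0.0, abs=1e-18)

    def test_gaussian_steps_effective_diffusion(self):
        rng = np.random.default_rng(10)
        sigma2 = 5e-4
        xs = np.cumsum(rng.normal(0, math.sqrt(sigma2), (50, 400)), axis=1)
        s = ld.summarize_steps(ld.compute_steps(_free_ensemble(list(xs))))
        assert s.d_eff == pytest.approx(sigma2 / 2, rel=0.05)
        assert s.v == pytest.approx(0.0, abs=3 * s.v_se)

    def test_requires_two_steps(self):
        with pytest.raises(ValueError):
            ld.summarize_steps(ld.compute_steps(_free_ensemble([[0.0, 0.1]])))

    def test_mirror_antisymmetry(self, split_synced):
        """Negating all positions negates the drift and leaves diffusion,
        tails and memory untouched."""
        for interval in ("Pre-Replication", "Rapid-Translocation"):
            a = ld.summarize_steps(
                ld.compute_steps(split_synced, interval, selection="both")
            )
            b = ld.summarize_steps(
                ld.compute_steps(ld.mirror(split_synced), interval, selection="both")
            )
            assert b.v == pytest.approx(-a.v, abs=1e-15)
            assert b.d_eff == pytest.approx(a.d_eff, rel=1e-12)
            assert b.excess_tail == pytest.approx(a.excess_tail, abs=1e-12)
            assert b.lag1_autocorr == pytest.approx(a.lag1_autocorr, abs=1e-9)


class TestGaussianExcess:
    def test_null_gaussian_sample(self):
        rng = np.random.default_rng(11)
        g = ld.gaussian_excess(rng.normal(0, 1, 20000), seed=0)
        assert g.ci_low <= 0.0 <= g.ci_high or abs(g.excess) < 0.005

    def test_mixture_with_large_steps_closed_form(self):
        # 95% standard normal, 5% spikes at +/-4; threshold 2.5 mixture-sigma
        rng = np.random.default_rng(12)
        n = 40000
        spikes = 4.0 * rng.choice([-1, 1], size=int(0.05 * n))
        x = np.concatenate([rng.normal(0, 1, n - len(spikes)), spikes])
        sigma_mix = math.sqrt(0.95 * 1.0 + 0.05 * 16.0)
        cut = 2.5 * sigma_mix
        expected = (
            0.05 * (4.0 > cut)
            + 0.95 * 2 * stats.norm.sf(cut)
            - 2 * stats.norm.sf(2.5)
        )
        g = ld.gaussian_excess(x, threshold_sd=2.5, seed=0)
        assert g.excess == pytest.approx(expected, abs=0.006)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ld.gaussian_excess(np.full(300, 0.1))

    def test_small_sample_warns(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="steps"):
            ld.gaussian_excess(rng.normal(size=50))

    def test_unbiased_over_gaussian_replicates(self):
        """Mean excess over 50 Gaussian replicates is compatible with 0."""
        rng = np.random.default_rng(13)
        vals = [
            ld.gaussian_excess(rng.normal(0, 1, 2000), n_boot=0, seed=0).excess
            for _ in range(50)
        ]
        se = np.std(vals, ddof=1) / math.sqrt(50)
        assert abs(np.mean(vals)) < 3 * se + 1e-4


class TestStepAutocorrelation:
    def test_white_noise_uncorrelated(self):
        rng = np.random.default_rng(14)
        xs = np.cumsum(rng.normal(0, 0.02, (100, 100)), axis=1)
        ac = ld.step_autocorrelation(_free_ensemble(list(xs)), max_lag=3)
        np.testing.assert_allclose(ac.corr, 0.0, atol=0.02)

    def test_fbm_lag1_matches_closed_form(self):
        alpha = 0.38
        ens = ld.simulate_fbm_tracks(alpha=alpha, n_tracks=300, n_frames=100, seed=15)
        ac = ld.step_autocorrelation(ens, max_lag=1)
        assert ac.corr[0] == pytest.approx(2 ** (alpha - 1) - 1, abs=0.02)

    def test_ou_lag1_closed_form(self):
        # stationary OU increments: rho(1) = -(1 - exp(-dt/tau)) / 2
        ens = ld.simulate_ou_tracks(n_tracks=300, n_frames=120, tau=10.0,
                                    D=2.5e-4, seed=16)
        ac = ld.step_autocorrelation(ens, max_lag=1)
        expected = -(1 - math.exp(-0.1)) / 2
        assert ac.corr[0] == pytest.approx(expected, abs=0.02)

    def test_tracks_too_short_rejected(self):
        with pytest.raises(ValueError):
            ld.step_autocorrelation(_free_ensemble([[0.0, 0.1]]), max_lag=1)


class TestDeffConsistency:
    def test_brownian_d_eff_within_five_percent(self):
        D = 2.5e-4
        ens = ld.simulate_ou_tracks(n_tracks=200, n_frames=100, tau=1e7, D=D,
                                    x0=0.0, seed=17)
        s = ld.summarize_steps(ld.compute_steps(ens))
        assert s.n >= 10_000
        assert s.d_eff == pytest.approx(D, rel=0.05)
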