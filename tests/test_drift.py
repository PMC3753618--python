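"""Drift-velocity profiles, equilibria, relaxation time, occupancy."""
import math

import numpy as np
import pandas as pd
import pytest

import locusdrift as ld
from locusdrift.drift import DriftProfile, _count_modes
from locusdrift.tracks import COLUMNS, TrackEnsemble


def _profile_from_line(slope, x=None, se=0.001):
    """Synthetic DriftProfile with v = slope * x."""
    x = np.asarray(x if x is not None else np.arange(-0.2, 0.21, 0.05))
    return DriftProfile(
        x_center=x, x_mean=x, v=slope * x, se=np.full_like(x, se),
        n=np.full(len(x), 1000), bin_width=0.05, min_count=25,
        interval=None, dt_eff=1.0, selection="both",
    )


class TestDriftProfile:
    def test_drift_free_random_walk_is_flat(self):
        ens = ld.simulate_fbm_tracks(alpha=1.0, n_tracks=400, n_frames=100, seed=20)
        prof = ld.compute_drift_profile(ens, bin_width=0.05, min_count=25)
        ok = prof.populated
        z = prof.v[ok] / prof.se[ok]
        # per-bin velocities are pure noise: z-scores ~ N(0, 1) and the
        # fitted spatial slope of v(x) is compatible with zero
        assert np.mean(np.abs(z) < 2) >= 0.75
        assert abs(z.mean()) < 3 / np.sqrt(ok.sum())
        from locusdrift.drift import _weighted_slope

        slope, slope_se = _weighted_slope(prof.x_mean[ok], prof.v[ok], prof.se[ok])
        assert abs(slope) < 3 * slope_se

    def test_ou_bins_match_conditional_mean(self):
        """Every populated bin agrees with the exact Ornstein-Uhlenbeck
        conditional step mean -(x - x_eq)(1 - e^(-dt/tau))/dt."""
        tau = 10.0
        ens = ld.simulate_ou_tracks(n_tracks=400, n_frames=100, tau=tau,
                                    D=2.5e-4, seed=21)
        prof = ld.compute_drift_profile(ens, bin_width=0.05, min_count=25)
        ok = prof.populated
        pred = -(prof.x_mean[ok]) * (1 - math.exp(-1 / tau))
        z = np.abs(prof.v[ok] - pred / prof.dt_eff) / prof.se[ok]
        assert np.mean(z < 2) >= 0.95

    def test_example_bin_value(self):
        # at x = 0.2, tau = 10, dt = 1: v = -0.2 * (1 - e^-0.1) = -0.0190
        ens = ld.simulate_ou_tracks(n_tracks=3000, n_frames=40, tau=10.0,
                                    D=2.5e-4, x0=0.2, seed=22)
        prof = ld.compute_drift_profile(ens, bin_width=0.05, min_count=25)
        i = np.argmin(np.abs(prof.x_mean - 0.2))
        assert prof.v[i] == pytest.approx(
            -(prof.x_mean[i]) * (1 - math.exp(-0.1)), abs=3 * prof.se[i]
        )

    def test_insufficient_occupancy_raises(self):
        ens = ld.simulate_ou_tracks(n_tracks=2, n_frames=5, tau=10.0,
                                    D=2.5e-4, seed=23)
        with pytest.raises(ValueError, match="insufficient occupancy"):
            ld.compute_drift_profile(ens, min_count=1000)

    def test_mirror_negates_profile(self, split_synced):
        a = ld.compute_drift_profile(split_synced, "Pre-Replication")
        b = ld.compute_drift_profile(ld.mirror(split_synced), "Pre-Replication")
        # mirrored bins run in reverse order with negated centres/velocities
        np.testing.assert_allclose(b.x_mean, -a.x_mean[::-1], atol=1e-12)
        np.testing.assert_allclose(b.v, -a.v[::-1], atol=1e-12)


class TestEquilibria:
    def test_pre_split_single_stable_equilibrium_at_midcell(self):
        ens = ld.simulate_ou_tracks(n_tracks=300, n_frames=100, tau=10.0,
                                    D=2.5e-4, seed=24)
        eq = ld.find_equilibria(ld.compute_drift_profile(ens))
        stable = eq.stable
        assert len(stable) == 1
        assert stable[0].position == pytest.approx(0.0, abs=0.02)
        assert stable[0].tau == pytest.approx(10.0, rel=0.25)

    def test_post_split_equilibrium_at_quarter_cell(self):
        ens = ld.simulate_ou_tracks(n_tracks=300, n_frames=100, tau=10.0,
                                    D=2.5e-4, x_eq=0.25, seed=25)
        eq = ld.find_equilibria(ld.compute_drift_profile(ens))
        assert len(eq.stable) == 1
        assert eq.stable[0].position == pytest.approx(0.25, abs=0.02)

    def test_positive_slope_crossing_is_unstable(self):
        eq = ld.find_equilibria(_profile_from_line(+0.1))
        assert len(eq) == 1
        assert not eq.equilibria[0].stable
        assert eq.equilibria[0].position == pytest.approx(0.0, abs=1e-9)

    def test_no_sign_change_is_empty_set(self):
        prof = _profile_from_line(-0.1)
        prof.v[:] = prof.v + 1.0  # all positive
        assert len(ld.find_equilibria(prof)) == 0


class TestRelaxationTime:
    def test_exact_discrete_line_inverts_to_tau(self):
        tau, dt = 10.0, 1.0
        slope = -(1 - math.exp(-dt / tau)) / dt
        fit = ld.fit_relaxation_time(_profile_from_line(slope), x_eq=0.0)
        assert fit.tau == pytest.approx(tau, rel=1e-9)

    def test_ou_recovery_within_fifteen_percent(self):
        ens = ld.simulate_ou_tracks(n_tracks=400, n_frames=100, tau=10.0,
                                    D=2.5e-4, seed=26)
        fit = ld.fit_relaxation_time(ld.compute_drift_profile(ens), x_eq=0.0)
        assert fit.tau == pytest.approx(10.0, rel=0.15)

    def test_binning_robustness(self):
        ens = ld.simulate_ou_tracks(n_tracks=400, n_frames=100, tau=10.0,
                                    D=2.5e-4, seed=27)
        coarse = ld.fit_relaxation_time(
            ld.compute_drift_profile(ens, bin_width=0.05), x_eq=0.0
        )
        fine = ld.fit_relaxation_time(
            ld.compute_drift_profile(ens, bin_width=0.025, min_count=13), x_eq=0.0
        )
        assert abs(fine.tau - coarse.tau) < max(coarse.tau_se, fine.tau_se) * 2

    def test_non_restoring_profile_rejected(self):
        with pytest.raises(ValueError, match="not a restoring"):
            ld.fit_relaxation_time(_profile_from_line(+0.05), x_eq=0.0)


class TestTemporalStationarity:
    def test_late_interval_profile_is_stationary(self, split_synced):
        """Splitting the late interval in half yields statistically
        indistinguishable drift profiles (the drift field changes little
        after segregation)."""
        scheme = ld.IntervalScheme(
            names=("early", "mid", "late1", "late2"),
            inner_edges=(-10.0, 15.0, 38.0),
        )
        a = ld.compute_drift_profile(split_synced, "late1", scheme=scheme,
                                     selection="right", min_count=15)
        b = ld.compute_drift_profile(split_synced, "late2", scheme=scheme,
                                     selection="right", min_count=15)
        shared_a = np.isin(prof_round(a.x_center), prof_round(b.x_center))
        common = prof_round(a.x_center)[shared_a & a.populated]
        z = []
        for c in common:
            ia = np.where(prof_round(a.x_center) == c)[0][0]
            ib = np.where(prof_round(b.x_center) == c)[0][0]
            if not b.populated[ib]:
                continue
            z.append(abs(a.v[ia] - b.v[ib]) / math.hypot(a.se[ia], b.se[ib]))
        assert len(z) >= 4
        assert np.mean(np.asarray(z) < 3) >= 0.9


def prof_round(x):
    return np.round(np.asarray(x), 6)


class TestOccupancy:
    def test_static_track_point_mass(self):
        rows = []
        for k in range(20):
            rows.append(["c0", k, float(k - 10), "locus", 0, 0.1, np.nan])
        ens = TrackEnsemble(
            data=pd.DataFrame(rows, columns=list(COLUMNS)), dt=1.0,
            synchronized=True, t_split={"c0": 10.0},
        )
        occ = ld.occupancy_map(ens, time_bin=5.0, pos_bin=0.05)
        rows_with_data = ~np.isnan(occ.occupancy).all(axis=1)
        assert (np.nanmax(occ.occupancy[rows_with_data], axis=1) == 1.0).all()
        assert np.allclose(occ.mean_traj["mean_x"], 0.1)

    def test_rows_sum_to_one(self, split_synced):
        occ = ld.occupancy_map(split_synced)
        sums = np.nansum(occ.occupancy, axis=1)
        has_data = ~np.isnan(occ.occupancy).all(axis=1)
        np.testing.assert_allclose(sums[has_data], 1.0)

    def test_split_cycle_unimodal_per_focus(self, split_synced):
        occ = ld.occupancy_map(split_synced)
        assert (occ.mode_counts["n_modes"] == 1).all()

    def test_mean_trajectory_relaxes_to_quarter_positions(self, split_synced):
        mt = ld.occupancy_map(split_synced).mean_traj
        late = mt[mt["time_center"] > 30]
        f1 = late[late["group"] == "focus1"]["mean_x"]
        f0 = late[late["group"] == "focus0"]["mean_x"]
        assert (f1 > 0.2).all() and (f0 < -0.2).all()

    def test_requires_synchronized(self, split_raw):
        with pytest.raises(ValueError, match="synchronized"):
            ld.occupancy_map(split_raw)


class TestModeCounting:
    @pytest.mark.parametrize(
        "hist, expected",
        [
            ([0, 1, 5, 9, 5, 1, 0], 1),
            ([0, 8, 2, 1, 2, 8, 0], 2),
            ([0, 0, 0], 0),
            ([5, 5, 5], 1),
        ],
    )
    def test_local_maxima(self, hist, expected):
        assert _count_modes(np.asarray(hist, float)) == expected
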