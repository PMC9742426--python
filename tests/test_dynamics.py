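import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import residence_spec
from helpers import make_trajectory, protein_atom, static_trajectory, water_atom
from hydrashell.dynamics import (
    HBondCriteria,
    OccupancyTrace,
    ResidenceTime,
    SurvivalCurve,
    build_occupancy_trace,
    fit_residence_time,
    hbond_lifetimes,
    shell_residence_summary,
    survival_function,
)
from hydrashell.errors import (
    ParameterError,
    SelectionError,
    UndefinedCurveError,
)
from hydrashell.structure import HydrationSite
from hydrashell.synthetic import generate_system, sample_occupancy


def _site(pos, sid=0):
    return HydrationSite(id=sid, position=np.asarray(pos, float),
                         peak_density=5.0, surface_distance=1.9)


def _trace(occupants, dt=2.0):
    return OccupancyTrace(site_id=0, occupants=np.asarray(occupants),
                          capture_radius=1.4, dt=dt)


class TestOccupancyTrace:
    def test_frozen_occupant(self):
        top = [protein_atom(0), water_atom(1, 1), water_atom(2, 2)]
        xyz = [[18.0, 18, 18], [25.0, 18, 18], [10.0, 10, 10]]
        traj = static_trajectory(xyz, top, box=36.0, dt=2.0)
        trace = build_occupancy_trace(traj, _site([25.0, 18.0, 18.0]))
        assert np.all(trace.occupants == 1)

    def test_never_occupied(self):
        top = [protein_atom(0), water_atom(1, 1)]
        traj = static_trajectory([[18.0, 18, 18], [30.0, 30, 30]], top,
                                 box=36.0)
        trace = build_occupancy_trace(traj, _site([25.0, 18.0, 18.0]))
        assert np.all(trace.occupants == -1)

    def test_nearest_wins_brute_force(self, rng):
        n_w, n_f = 8, 60
        top = [protein_atom(0)] + [water_atom(1 + i, 1 + i)
                                   for i in range(n_w)]
        site_pos = np.array([20.0, 18.0, 18.0])
        frames = []
        for _ in range(n_f):
            wat = site_pos + rng.uniform(-2.0, 2.0, size=(n_w, 3))
            frames.append(np.vstack([[[18.0, 18, 18]], wat]))
        traj = make_trajectory(frames, top, box=36.0)
        trace = build_occupancy_trace(traj, _site(site_pos),
                                      capture_radius=1.4)
        for f, xyz in enumerate(frames):
            d = np.linalg.norm(xyz[1:] - site_pos, axis=1)
            j = int(np.argmin(d))
            expected = 1 + j if d[j] <= 1.4 else -1
            assert trace.occupants[f] == expected

    def test_bad_radius(self):
        top = [protein_atom(0), water_atom(1, 1)]
        traj = static_trajectory([[0.0, 0, 0], [1.0, 0, 0]], top)
        with pytest.raises(ParameterError):
            build_occupancy_trace(traj, _site([1.0, 0, 0]), capture_radius=0)


class TestSurvivalFunction:
    def test_frozen_p_one(self):
        tr = _trace([5] * 50)
        for mode in ("continuous", "intermittent"):
            c = survival_function(tr, mode)
            np.testing.assert_allclose(c.p, 1.0)

    def test_perfect_turnover(self):
        tr = _trace(np.arange(50))  # always occupied, new water each frame
        for mode in ("continuous", "intermittent"):
            c = survival_function(tr, mode)
            assert c.p[0] == 1.0
            np.testing.assert_allclose(c.p[1:], 0.0)

    def test_p0_is_one_and_bounds(self):
        rng = np.random.default_rng(1)
        tr = _trace(rng.integers(-1, 4, size=300))
        for mode in ("continuous", "intermittent"):
            c = survival_function(tr, mode)
            assert c.p[0] == 1.0
            assert np.all((c.p >= 0) & (c.p <= 1))

    def test_continuous_monotone(self):
        rng = np.random.default_rng(2)
        tr = _trace(rng.integers(-1, 3, size=500))
        c = survival_function(tr, "continuous")
        assert np.all(np.diff(c.p) <= 1e-12)

    def test_never_occupied_raises(self):
        with pytest.raises(UndefinedCurveError):
            survival_function(_trace([-1] * 20))

    def test_markov_closed_form(self):
        # two-state Markov site: continuous survival is geometric,
        # (1 - dt/dwell)^(tau/dt)
        dwell, dt, n = 50.0, 2.0, 50_000
        rng = np.random.default_rng(3)
        p_exit = dt / dwell
        occ, runs = sample_occupancy(rng, n, p_exit, p_exit)  # occupancy 0.5
        occupants = np.full(n, -1)
        for state, start, length in runs:
            if state:
                occupants[start:start + length] = rng.integers(100)
        c = survival_function(_trace(occupants, dt=dt), "continuous",
                              max_lag=150.0)
        expected = (1 - p_exit) ** (c.taus / dt)
        n_events = occ.sum() * p_exit  # independent dwells, not origins
        sigma = np.sqrt(np.maximum(expected * (1 - expected), 1e-12)
                        / n_events)
        dev = np.abs(c.p - expected)
        assert np.all(dev <= 3 * sigma + 0.01)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(-1, 3), min_size=10, max_size=120))
    def test_continuous_le_intermittent(self, occupants):
        if all(o < 0 for o in occupants):
            return
        tr = _trace(occupants)
        c = survival_function(tr, "continuous")
        i = survival_function(tr, "intermittent")
        assert np.all(c.p <= i.p + 1e-12)

    def test_reentry_makes_modes_differ(self):
        # occupant leaves and the same water returns after a gap
        tr = _trace([7, 7, -1, 7, 7, -1, 7, 7, -1, 7, 7, 7])
        c = survival_function(tr, "continuous")
        i = survival_function(tr, "intermittent")
        assert np.any(i.p > c.p + 1e-9)


class TestFitResidenceTime:
    def _curve(self, tau, n=50, dt=2.0, n_origins=1000):
        taus = np.arange(n) * dt
        return SurvivalCurve(taus=taus, p=np.exp(-taus / tau),
                             mode="continuous",
                             n_origins=np.full(n, n_origins))

    def test_exact_recovery(self):
        rt = fit_residence_time(self._curve(100.0))
        assert rt.tau == pytest.approx(100.0, abs=1e-6)
        assert not rt.superstructured

    def test_superstructured_flag(self):
        taus = np.arange(200) * 50.0
        curve = SurvivalCurve(taus=taus, p=np.exp(-taus / 2000.0),
                              mode="continuous",
                              n_origins=np.full(200, 1000))
        rt = fit_residence_time(curve)
        assert rt.tau == pytest.approx(2000.0, rel=1e-6)
        assert rt.superstructured

    def test_scale_equivariance(self):
        rt1 = fit_residence_time(self._curve(100.0, dt=2.0))
        rt2 = fit_residence_time(self._curve(300.0, dt=6.0))
        assert rt2.tau == pytest.approx(3.0 * rt1.tau, rel=1e-9)

    def test_nondecaying_flagged(self):
        taus = np.arange(20) * 2.0
        curve = SurvivalCurve(taus=taus, p=np.exp(-taus / 1e5),
                              mode="continuous",
                              n_origins=np.full(20, 1000))
        rt = fit_residence_time(curve)
        assert not rt.reliable

    def test_too_few_points(self):
        curve = SurvivalCurve(taus=np.arange(3) * 2.0,
                              p=np.array([1.0, 0.5, 0.25]),
                              mode="continuous",
                              n_origins=np.full(3, 100))
        with pytest.raises(ParameterError):
            fit_residence_time(curve)

    def test_synthetic_recovery_median(self):
        # planted dwell 80 ps; median fitted tau over 8 seeds within 15 %
        taus = []
        for seed in range(8):
            spec, positions = residence_spec(seed, dwell_times=(80.0,),
                                             n_frames=20_000)
            traj, _ = generate_system(spec)
            trace = build_occupancy_trace(traj, _site(positions[0]),
                                          capture_radius=1.4)
            curve = survival_function(trace, "continuous", max_lag=400.0)
            taus.append(fit_residence_time(curve).tau)
        assert abs(np.median(taus) - 80.0) / 80.0 < 0.15

    def test_estimator_consistency(self):
        # median |bias| decreases with trajectory length
        biases = {}
        for n_frames in (2000, 8000, 32000):
            errs = []
            for seed in range(7):
                spec, positions = residence_spec(
                    1000 + seed, dwell_times=(80.0,), n_frames=n_frames)
                traj, _ = generate_system(spec)
                trace = build_occupancy_trace(traj, _site(positions[0]))
                curve = survival_function(trace, "continuous", max_lag=400.0)
                errs.append(abs(fit_residence_time(curve).tau - 80.0))
            biases[n_frames] = float(np.median(errs))
        assert biases[32000] <= biases[8000] <= biases[2000]


class TestShellSummary:
    def _rt(self, tau, shell="first"):
        return ResidenceTime(tau=tau, fit_rss=0.0,
                             superstructured=tau > 1000.0, shell=shell)

    def test_mean_sd(self):
        times = [self._rt(t) for t in (50.0, 60.0, 70.0)]
        table = shell_residence_summary(times)
        row = table[table["shell"] == "first"].iloc[0]
        assert row["mean_tau_ps"] == pytest.approx(60.0)
        assert row["sd_tau_ps"] == pytest.approx(10.0)
        assert row["n"] == 3 and row["n_excluded"] == 0

    def test_superstructured_excluded(self):
        times = [self._rt(t) for t in (50.0, 60.0, 70.0, 4000.0)]
        table = shell_residence_summary(times)
        row = table[table["shell"] == "first"].iloc[0]
        assert row["mean_tau_ps"] == pytest.approx(60.0)
        assert row["n_excluded"] == 1

    def test_exclusion_invariance(self):
        base = [self._rt(t) for t in (40.0, 80.0)]
        t1 = shell_residence_summary(base)
        t2 = shell_residence_summary(base + [self._rt(2500.0)])
        m1 = t1[t1["shell"] == "first"]["mean_tau_ps"].iloc[0]
        m2 = t2[t2["shell"] == "first"]["mean_tau_ps"].iloc[0]
        assert m1 == m2

    def test_empty_shell_no_crash(self):
        table = shell_residence_summary([self._rt(50.0)])
        row = table[table["shell"] == "second"].iloc[0]
        assert row["n"] == 0
        assert np.isnan(row["mean_tau_ps"])

    def test_recomputation_oracle(self, rng):
        taus = rng.uniform(10, 2000, size=30)
        shells = rng.choice(["first", "second"], size=30)
        times = [self._rt(t, s) for t, s in zip(taus, shells)]
        table = shell_residence_summary(times)
        for shell in ("first", "second"):
            keep = [t for t, s in zip(taus, shells)
                    if s == shell and t <= 1000.0]
            row = table[table["shell"] == shell].iloc[0]
            assert row["mean_tau_ps"] == pytest.approx(np.mean(keep))
            assert row["n"] == len(keep)


def _hbond_top():
    return [
        protein_atom(0, 0, name="N", element="N", residue_name="ALA",
                     mass=14.007),
        protein_atom(1, 0, name="H", element="H", residue_name="ALA",
                     mass=1.008),
        water_atom(2, 1),
    ]


class TestHBondLifetimes:
    def test_permanent_bond_one_event(self):
        n = 20
        xyz = [[10.0, 10, 10], [11.0, 10, 10], [12.9, 10, 10]]
        traj = static_trajectory(xyz, _hbond_top(), box=36.0, dt=2.0)
        assert traj.n_frames == 3
        events, overall = hbond_lifetimes(traj)
        assert len(events) == 1
        assert events[0].n_events == 1
        assert events[0].mean_lifetime == pytest.approx((3 - 1) * 2.0)
        assert overall == pytest.approx(4.0)

    def test_distance_cutoff(self):
        xyz = [[10.0, 10, 10], [11.0, 10, 10], [13.6, 10, 10]]
        traj = static_trajectory(xyz, _hbond_top(), box=36.0)
        events, overall = hbond_lifetimes(traj)
        assert events == []
        assert overall == 0.0

    def test_angle_cutoff(self):
        # acceptor at 90 deg from the N-H axis, within distance
        xyz = [[10.0, 10, 10], [11.0, 10, 10], [10.0, 12.9, 10]]
        traj = static_trajectory(xyz, _hbond_top(), box=36.0)
        events, _ = hbond_lifetimes(traj)
        assert events == []

    def test_no_polar_atoms(self):
        top = [protein_atom(0, 0, name="CA", element="C"), water_atom(1, 1)]
        traj = static_trajectory([[0.0, 0, 0], [3.0, 0, 0]], top, box=36.0)
        with pytest.raises(SelectionError):
            hbond_lifetimes(traj)

    def test_sticky_partner_lifetime(self):
        # a water bonds to the donor in exponential runs of mean 100 ps
        dwell, dt, n = 100.0, 2.0, 30_000
        lifetimes = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            occ, _ = sample_occupancy(rng, n, dt / dwell, dt / dwell)
            frames = []
            near = np.array([12.9, 10.0, 10.0])
            far = np.array([30.0, 30.0, 30.0])
            wpos = np.where(occ[:, None], near, far)
            base = np.array([[10.0, 10, 10], [11.0, 10, 10]])
            frames = [np.vstack([base, wpos[k][None]]) for k in range(n)]
            traj = make_trajectory(frames, _hbond_top(), box=72.0, dt=dt)
            events, overall = hbond_lifetimes(traj)
            lifetimes.append(overall)
        # mean event duration of a geometric run of mean 50 frames is
        # (50 - 1) * dt = 98 ps
        assert abs(np.mean(lifetimes) - 98.0) / 98.0 < 0.2
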