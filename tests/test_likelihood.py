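import numpy as np
import pytest

from tcphoton import (
    BlinkParams,
    KineticModel,
    LifetimeScan,
    TCParams,
    TwoStateParams,
    delta_lnL_scan,
    endpoint_vectors,
    estimate_pB_from_start,
    find_lifetime_or_bound,
    fit_two_state,
    log_likelihood_endpoint,
    log_likelihood_eq,
    make_six_state_tc,
    make_four_state,
    make_three_state_tc,
    make_two_state,
    simulate_ctmc_photons,
    simulate_transition_segments,
    SimConfig,
    PhotonTrajectory,
)
from tcphoton.likelihood import EndpointVectors
from tcphoton.segmentation import TransitionSegment

from conftest import MODEL_KINDS, oracle_loglik, random_model, random_trajectory


def one_state(E: float) -> KineticModel:
    return KineticModel(("S",), np.zeros((1, 1)), np.array([E]), np.array([1.0]))


def make_traj(times, colors, tid="t") -> PhotonTrajectory:
    return PhotonTrajectory(tid, np.asarray(times, float), np.asarray(colors), {})


class TestEquilibriumLikelihood:
    def test_single_acceptor_photon(self):
        m = one_state(0.6)
        assert log_likelihood_eq(make_traj([0.0], [1]), m) == pytest.approx(np.log(0.6))

    def test_single_donor_photon_two_state(self, idp_two):
        m = make_two_state(idp_two)
        expected = np.log(0.4 * 0.75 + 0.75 * 0.25)  # 1^T (I-E) p_eq
        assert log_likelihood_eq(make_traj([0.0], [0]), m) == pytest.approx(expected)

    def test_one_state_binomial_closed_form(self, rng):
        E = 0.37
        m = one_state(E)
        for _ in range(5):
            times, colors = random_trajectory(rng, 200)
            n_a = int(colors.sum())
            expected = n_a * np.log(E) + (200 - n_a) * np.log(1 - E)
            assert log_likelihood_eq(make_traj(times, colors), m) == pytest.approx(expected)

    def test_one_state_time_independence(self, rng):
        m = one_state(0.5)
        colors = rng.integers(0, 2, 50)
        t1 = np.sort(rng.uniform(0, 1e-3, 50))
        t2 = np.sort(rng.uniform(0, 10.0, 50))
        assert log_likelihood_eq(make_traj(t1, colors), m) == pytest.approx(
            log_likelihood_eq(make_traj(t2, colors), m)
        )

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_oracle_equivalence(self, kind, rng):
        for _ in range(10):
            m = random_model(rng, kind)
            times, colors = random_trajectory(rng, int(rng.integers(2, 11)))
            got = log_likelihood_eq(make_traj(times, colors), m)
            want = oracle_loglik(times, colors, m.K, m.E_diag, m.p_eq, np.ones(m.n_states))
            assert got == pytest.approx(want, rel=1e-8)

    def test_additivity_and_order_invariance(self, rng, idp_two):
        m = make_two_state(idp_two)
        trajs = [make_traj(*random_trajectory(rng, 30), tid=str(i)) for i in range(6)]
        individual = [log_likelihood_eq(t, m) for t in trajs]
        assert sum(individual) == pytest.approx(sum(sorted(individual)))

    def test_zero_probability_flagged(self):
        m = one_state(0.0)
        assert log_likelihood_eq(make_traj([0.0, 1e-4], [0, 1]), m) == -np.inf

    def test_long_trajectory_no_underflow(self, idp_two):
        cfg = SimConfig(two=idp_two, rate_ms=100.0, duration_s=2.0, n_traj=1, seed=3)
        (tr,) = simulate_ctmc_photons(cfg)
        assert len(tr) > 150_000
        ll = log_likelihood_eq(tr, make_two_state(idp_two))
        assert np.isfinite(ll)


class TestEndpointLikelihood:
    def test_reduces_to_equilibrium(self, rng, idp_two):
        m = make_two_state(idp_two)
        times, colors = random_trajectory(rng, 40)
        ev = EndpointVectors(m.p_eq, np.ones(2))
        seg = TransitionSegment("x", times, colors, "binding", 5e-4, (0.0, 1e-3))
        assert log_likelihood_endpoint(seg, m, ev) == pytest.approx(
            log_likelihood_eq(make_traj(times, colors), m)
        )

    def test_three_state_binding_vectors(self):
        ev = endpoint_vectors("binding", 3)
        assert ev.v_ini.tolist() == [0.0, 0.0, 1.0]
        assert ev.v_fin.tolist() == [1.0, 0.0, 0.0]

    def test_six_state_binding_vectors(self):
        ev = endpoint_vectors("binding", 6, p_b=0.8)
        assert ev.v_ini.tolist() == [0.0, 0.0, 0.8, 0.0, 0.0, pytest.approx(0.2)]
        assert ev.v_fin.tolist() == [1.0, 0.0, 0.0, 1.0, 0.0, 0.0]

    def test_dissociation_vectors_mirror(self):
        ev = endpoint_vectors("dissociation", 3)
        assert ev.v_ini.tolist() == [1.0, 0.0, 0.0]
        assert ev.v_fin.tolist() == [0.0, 0.0, 1.0]

    @pytest.mark.parametrize("kind", ["three", "six"])
    def test_oracle_equivalence(self, kind, rng):
        for _ in range(8):
            m = random_model(rng, kind)
            times, colors = random_trajectory(rng, int(rng.integers(2, 11)))
            ev = endpoint_vectors("binding", m.n_states, p_b=0.9)
            seg = TransitionSegment("x", times, colors, "binding", 5e-4, (0.0, 1e-3))
            got = log_likelihood_endpoint(seg, m, ev)
            want = oracle_loglik(times, colors, m.K, m.E_diag, ev.v_ini, ev.v_fin)
            if np.isfinite(want):
                assert got == pytest.approx(want, rel=1e-8)
            else:
                assert got == -np.inf


class TestNesting:
    """As t_TC -> 0 the intermediate branches back with probability 1/2, so
    the TC models converge to the instantaneous models at half the rates."""

    def test_three_to_two(self, rng, idp_two):
        halved = TwoStateParams(idp_two.E_B, idp_two.E_U,
                                idp_two.k_A_app / 2, idp_two.k_D / 2)
        m2 = make_two_state(halved)
        tc = TCParams.from_lifetime(1e-9, 0.425, rate_reduction=1.0)
        m3 = make_three_state_tc(idp_two, tc)
        times, colors = random_trajectory(rng, 200)
        seg = TransitionSegment("x", times, colors, "binding", 5e-4, (0.0, 1e-3))
        ll3 = log_likelihood_endpoint(seg, m3)
        ll2 = log_likelihood_endpoint(seg, m2)
        assert ll3 == pytest.approx(ll2, rel=1e-3)

    def test_six_to_four(self, rng, idp_two):
        blink = BlinkParams(E_d=0.06, k_b=3000.0, k_0=500.0)
        halved = TwoStateParams(idp_two.E_B, idp_two.E_U,
                                idp_two.k_A_app / 2, idp_two.k_D / 2)
        m4 = make_four_state(halved, blink, 500.0)
        tc = TCParams.from_lifetime(1e-9, 0.425, rate_reduction=1.0)
        m6 = make_six_state_tc(idp_two, tc, blink, 500.0)
        times, colors = random_trajectory(rng, 200)
        p_b = blink.p_b(500.0)
        seg = TransitionSegment("x", times, colors, "binding", 5e-4, (0.0, 1e-3))
        ll6 = log_likelihood_endpoint(seg, m6, endpoint_vectors("binding", 6, p_b))
        ll4 = log_likelihood_endpoint(seg, m4, endpoint_vectors("binding", 4, p_b))
        assert ll6 == pytest.approx(ll4, rel=1e-3)


class TestScan:
    def test_delta_vanishes_at_tiny_lifetime(self, idp_two):
        segs = simulate_transition_segments(
            30, 1e-3, 300.0, idp_two.E_B, idp_two.E_U, None, 0.0, seed=4
        )
        scan = delta_lnL_scan(segs, idp_two, t_grid=np.array([1e-8, 1e-6, 1e-4]))
        assert abs(scan.delta_lnL[0]) < 0.5

    def test_free_mode_not_below_fixed(self, idp_two):
        segs = simulate_transition_segments(
            20, 1e-3, 300.0, idp_two.E_B, idp_two.E_U, None, 100e-6, seed=6
        )
        grid = np.geomspace(1e-5, 1e-3, 5)
        fixed = delta_lnL_scan(segs, idp_two, t_grid=grid)
        free = delta_lnL_scan(segs, idp_two, t_grid=grid, E_TC_mode="free")
        assert np.all(free.delta_lnL >= fixed.delta_lnL - 1e-3)
        assert free.E_TC_opt is not None

    def test_bad_grid_rejected(self, idp_two):
        segs = simulate_transition_segments(3, 1e-3, 300.0, 0.6, 0.25, None, 0.0, seed=1)
        with pytest.raises(ValueError):
            delta_lnL_scan(segs, idp_two, t_grid=np.array([1e-4, 1e-5]))
        with pytest.raises(ValueError):
            delta_lnL_scan([], idp_two)


def _scan_of(t_grid, delta):
    return LifetimeScan(np.asarray(t_grid, float), np.asarray(delta, float), "fixed-midpoint")


class TestFindLifetimeOrBound:
    def test_peak_extraction(self):
        t = np.geomspace(1e-5, 1e-3, 21)
        # quadratic in log t peaking at 183 us with height 10
        x = np.log(t / 183e-6)
        scan = _scan_of(t, 10.0 - 8.0 * x**2)
        r = find_lifetime_or_bound(scan)
        assert r.significant
        assert r.t_hat == pytest.approx(183e-6, rel=1e-6)
        assert r.t_stderr == pytest.approx(183e-6 / 4.0, rel=1e-6)

    def test_upper_bound_interpolation(self):
        # monotone decreasing curve crossing -3 between 1.8 and 2.2 us
        t = np.array([1.0e-6, 1.4e-6, 1.8e-6, 2.2e-6, 3.0e-6])
        d = np.array([0.0, -1.0, -2.0, -4.0, -8.0])
        r = find_lifetime_or_bound(_scan_of(t, d))
        assert not r.significant
        assert r.t_hat is None
        assert r.upper_bound == pytest.approx(2.0e-6, rel=0.05)

    def test_unbounded_grid_reported(self):
        t = np.geomspace(1e-6, 1e-3, 10)
        r = find_lifetime_or_bound(_scan_of(t, np.linspace(0, -2.5, 10)))
        assert r.upper_bound is None and "unbounded" in r.note

    def test_tie_breaks_toward_smaller_lifetime(self):
        t = np.geomspace(1e-6, 1e-3, 5)
        d = np.array([0.0, 5.0, 4.0, 5.0, 0.0])
        r = find_lifetime_or_bound(_scan_of(t, d))
        assert r.t_hat <= t[2]


class TestStartStateEstimate:
    def _traj(self, e, tid):
        times = np.arange(100) * 1e-4
        colors = (np.arange(100) % 10 < e * 10).astype(np.int8)
        return PhotonTrajectory(tid, times, colors, {})

    def test_counting(self):
        trajs = [self._traj(0.8, f"b{i}") for i in range(6)]
        trajs += [self._traj(0.1, f"u{i}") for i in range(4)]
        assert estimate_pB_from_start(trajs, 0.75, 0.06) == pytest.approx(0.6)

    def test_all_bound(self):
        trajs = [self._traj(0.9, str(i)) for i in range(5)]
        assert estimate_pB_from_start(trajs, 0.75, 0.06) == 1.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            estimate_pB_from_start([], 0.75, 0.06)


@pytest.fixture(scope="module")
def small_data():
    two = TwoStateParams(0.6, 0.25, 300.0, 100.0)
    cfg = SimConfig(two=two, rate_ms=50.0, duration_s=0.4, n_traj=2, seed=12)
    return simulate_ctmc_photons(cfg), two


class TestTwoStateFitContracts:
    def test_fix_pB_constraint_exact(self, small_data):
        trajs, two = small_data
        fit = fit_two_state(trajs, init=two, fix_pB=0.75, n_starts=1)
        k_a, k_d = fit.params["k_A_app"], fit.params["k_D"]
        assert k_a / (k_a + k_d) == pytest.approx(0.75, abs=1e-12)

    def test_duplication_shrinks_stderr(self, small_data):
        trajs, two = small_data
        fit1 = fit_two_state(trajs, init=two, n_starts=1)
        fit2 = fit_two_state(trajs + trajs, init=two, n_starts=1)
        for name in ("k_A_app", "k_D"):
            assert fit2.params[name] == pytest.approx(fit1.params[name], rel=1e-3)
            assert fit2.stderr[name] == pytest.approx(fit1.stderr[name] / np.sqrt(2), rel=0.05)
        assert fit2.lnL == pytest.approx(2 * fit1.lnL, rel=1e-6)

    def test_requires_data(self):
        with pytest.raises(ValueError):
            fit_two_state([])
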