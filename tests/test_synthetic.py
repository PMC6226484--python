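import numpy as np
import pytest
from scipy import stats

from tcphoton import (
    BlinkParams,
    SimConfig,
    TwoStateParams,
    delta_lnL_scan,
    fit_two_state,
    generate_condition_series,
    make_two_state,
    recolor_trajectory,
    simulate_ctmc_photons,
    simulate_transition_segments,
)
from tcphoton.synthetic import _gillespie
from tcphoton.trajectory import PhotonTrajectory


@pytest.fixture(scope="module")
def idp_cfg():
    two = TwoStateParams(0.6, 0.25, 300.0, 100.0)
    return SimConfig(two=two, rate_ms=100.0, duration_s=0.5, n_traj=4, seed=99)


class TestCTMCSimulator:
    def test_seed_determinism(self, idp_cfg):
        a = simulate_ctmc_photons(idp_cfg)
        b = simulate_ctmc_photons(idp_cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.times, y.times)
            assert np.array_equal(x.colors, y.colors)

    def test_uniform_efficiency_iid_colors(self):
        two = TwoStateParams(0.4, 0.4, 300.0, 100.0)
        cfg = SimConfig(two=two, rate_ms=100.0, duration_s=1.0, n_traj=1, seed=5)
        (tr,) = simulate_ctmc_photons(cfg)
        n = len(tr)
        f = tr.colors.mean()
        assert abs(f - 0.4) < 4 * np.sqrt(0.4 * 0.6 / n)
        # neighbor colors uncorrelated when dwell structure is invisible
        r = np.corrcoef(tr.colors[:-1], tr.colors[1:])[0, 1]
        assert abs(r) < 4 / np.sqrt(n)

    def test_stationary_bound_fraction(self):
        # E_B=1, E_U=0 makes the photon colors an exact state readout
        two = TwoStateParams(1.0, 0.0, 300.0, 100.0)
        cfg = SimConfig(two=two, rate_ms=50.0, duration_s=0.2, n_traj=100, seed=17)
        trajs = simulate_ctmc_photons(cfg)
        frac = np.mean(np.concatenate([t.colors for t in trajs]))
        assert frac == pytest.approx(0.75, abs=0.02)

    def test_dwell_times_exponential(self):
        two = TwoStateParams(0.6, 0.25, 300.0, 100.0)
        m = make_two_state(two)
        rng = np.random.default_rng(7)
        jump_t, jump_s = _gillespie(m.K, m.p_eq, 400.0, rng)
        dwells = np.diff(jump_t)
        states = jump_s[:-1]
        for s, rate in ((0, 100.0), (1, 300.0)):
            d = dwells[states == s]
            assert d.size > 1e4
            _, p = stats.kstest(d, "expon", args=(0, 1 / rate))
            assert p > 0.01

    def test_occupancy_converges_to_p_eq(self):
        two = TwoStateParams(0.6, 0.25, 300.0, 100.0)
        m = make_two_state(two)
        rng = np.random.default_rng(3)
        jump_t, jump_s = _gillespie(m.K, m.p_eq, 100.0, rng)
        edges = np.append(jump_t, 100.0)
        occ = np.zeros(2)
        np.add.at(occ, jump_s, np.diff(edges))
        occ /= occ.sum()
        # binomial-ish error over ~#transitions independent dwells
        assert occ[0] == pytest.approx(m.p_eq[0], abs=0.01)

    def test_acceptor_bleach_goes_to_donor_leak(self):
        two = TwoStateParams(0.9, 0.9, 300.0, 100.0)
        cfg = SimConfig(two=two, rate_ms=100.0, duration_s=1.0, n_traj=1, seed=11,
                        k_bleach_acceptor=50.0)
        (tr,) = simulate_ctmc_photons(cfg)
        t_bleach = tr.meta["acceptor_bleach_s"]
        assert t_bleach is not None and t_bleach < 1.0
        late = tr.colors[tr.times > t_bleach]
        assert late.mean() < 0.15  # E drops from 0.9 to ~0.06

    def test_donor_bleach_truncates(self):
        two = TwoStateParams(0.6, 0.25, 300.0, 100.0)
        cfg = SimConfig(two=two, rate_ms=100.0, duration_s=10.0, n_traj=1, seed=13,
                        k_bleach_donor=10.0)
        (tr,) = simulate_ctmc_photons(cfg)
        assert tr.meta["duration_s"] < 10.0
        assert tr.times[-1] <= tr.meta["duration_s"]

    def test_zero_rate_warns_empty(self, idp_cfg):
        import dataclasses

        cfg = dataclasses.replace(idp_cfg, rate_ms=0.0)
        with pytest.warns(UserWarning):
            trajs = simulate_ctmc_photons(cfg)
        assert all(len(t) == 0 for t in trajs)


class TestRecoloring:
    def _base(self, rng, n=1000, window=2e-3):
        times = np.sort(rng.uniform(0, window, n))
        return PhotonTrajectory("b", times, np.zeros(n, dtype=np.int8), {})

    def test_times_preserved_bitwise(self):
        rng = np.random.default_rng(2)
        tr = self._base(rng)
        rec = recolor_trajectory(tr, (1e-3, 1.001e-3), 200e-6, 0.6, 0.425, 0.25, seed=4)
        assert np.array_equal(rec.times, tr.times)
        assert len(rec) == len(tr)

    def test_tc_acceptor_fraction_binomial(self):
        rng = np.random.default_rng(9)
        tr = self._base(rng, n=2000)
        e_tc = 0.425
        n_tot = 0
        n_acc = 0
        for seed in range(300):
            rec = recolor_trajectory(tr, 1e-3, 400e-6, 0.9, e_tc, 0.05, seed=seed)
            lo = 1e-3 - rec.meta["tc_duration_drawn_s"] / 2
            hi = 1e-3 + rec.meta["tc_duration_drawn_s"] / 2
            sel = (tr.times >= lo) & (tr.times < hi)
            n_tot += sel.sum()
            n_acc += rec.colors[sel].sum()
        assert n_tot > 1e4
        assert abs(n_acc / n_tot - e_tc) < 3 * np.sqrt(e_tc * (1 - e_tc) / n_tot)

    def test_zero_lifetime_sharp_transition(self):
        rng = np.random.default_rng(4)
        tr = self._base(rng)
        rec = recolor_trajectory(tr, 1e-3, 0.0, 1.0, 0.5, 0.0, seed=1, direction="binding")
        pre = rec.colors[tr.times < 1e-3]
        post = rec.colors[tr.times >= 1e-3]
        assert pre.sum() == 0 and post.min() == 1  # E_U=0 then E_B=1

    def test_dark_intervals_recolored(self):
        rng = np.random.default_rng(6)
        tr = self._base(rng, n=5000, window=10e-3)
        blink = BlinkParams(E_d=0.06, k_b=2000.0, k_0=2000.0)
        rec = recolor_trajectory(tr, 5e-3, 0.0, 0.95, 0.5, 0.95, blink=blink, seed=3)
        # dark periods at ~E=0.06 pull the acceptor fraction below 0.95
        assert rec.colors.mean() < 0.9

    def test_missing_interval_raises(self):
        rng = np.random.default_rng(1)
        tr = self._base(rng)
        with pytest.raises(ValueError):
            recolor_trajectory(tr, None, 1e-4, 0.6, 0.4, 0.2)

    def test_null_recoloring_shows_no_tc_signal(self):
        two = TwoStateParams(0.6, 0.25, 300.0, 100.0)
        hits = 0
        for seed in range(5):
            segs = simulate_transition_segments(
                100, 2e-3, 500.0, two.E_B, two.E_U, None, 0.0, seed=seed
            )
            scan = delta_lnL_scan(segs, two, t_grid=np.geomspace(1e-6, 1e-3, 15))
            if scan.result.significant:
                hits += 1
        assert hits == 0


class TestTransitionSegments:
    def test_counts_and_window(self):
        segs = simulate_transition_segments(20, 2e-3, 500.0, 0.6, 0.25, None, 0.0, seed=3)
        assert len(segs) == 20
        counts = [len(s) for s in segs]
        assert abs(np.mean(counts) - 1000) < 3 * np.sqrt(1000 / 20)
        for s in segs:
            assert s.window == (0.0, 2e-3)
            assert 0 < s.t_transition < 2e-3

    def test_directions_alternate(self):
        segs = simulate_transition_segments(4, 1e-3, 300.0, 0.6, 0.25, None, 0.0, seed=3)
        assert [s.direction for s in segs] == [
            "binding", "dissociation", "binding", "dissociation"
        ]

    def test_determinism(self):
        a = simulate_transition_segments(5, 1e-3, 300.0, 0.6, 0.25, None, 1e-4, seed=8)
        b = simulate_transition_segments(5, 1e-3, 300.0, 0.6, 0.25, None, 1e-4, seed=8)
        for x, y in zip(a, b):
            assert np.array_equal(x.times, y.times)
            assert np.array_equal(x.colors, y.colors)


class TestConditionSeries:
    def test_manifest_monotone_and_recovery(self):
        base = SimConfig(
            two=TwoStateParams(0.6, 0.25, 300.0, 100.0),
            rate_ms=50.0, duration_s=0.5, n_traj=2, seed=40,
        )
        series = [
            {"label": "low", "E_U": 0.25, "k_D": 100.0, "partner_conc_M": 1e-9},
            {"label": "mid", "E_U": 0.30, "k_D": 200.0, "partner_conc_M": 2e-9},
            {"label": "high", "E_U": 0.35, "k_D": 400.0, "partner_conc_M": 4e-9},
        ]
        out = generate_condition_series(base, series)
        truths = out["manifest"]["conditions"]
        k_ds = [c["k_D"] for c in truths]
        e_us = [c["E_U"] for c in truths]
        assert k_ds == sorted(k_ds) and e_us == sorted(e_us)
        # end-to-end: fitted k_D reproduces the monotone trend
        fitted = []
        for cond, truth in zip(out["conditions"], truths):
            fit = fit_two_state(
                cond["trajectories"],
                init=TwoStateParams(0.6, truth["E_U"], 300.0, truth["k_D"]),
                n_starts=1,
            )
            fitted.append(fit.params["k_D"])
        assert fitted == sorted(fitted)
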