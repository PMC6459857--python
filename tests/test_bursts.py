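"""Burst search, time windows and MFD observable estimators."""

import numpy as np
import pytest

import mfdlab as m
from mfdlab import bursts


def synthetic_stream(transits, background_khz=0.1, duration=10.0, seed=0,
                     period=15.625):
    """Hand-built stream: list of (t0_s, dur_ms, n_photons) transits on
    uniform background, channels split evenly green/red."""
    rng = np.random.default_rng(seed)
    mt, ch = [], []
    for t0, dur_ms, n in transits:
        t = np.sort(rng.uniform(t0, t0 + dur_ms * 1e-3, n))
        mt.append(t)
        ch.append(rng.integers(0, 4, n).astype(np.uint8))
    nb = rng.poisson(background_khz * 4e3 * duration)
    mt.append(rng.uniform(0, duration, nb))
    ch.append(rng.integers(0, 4, nb).astype(np.uint8))
    mt = np.concatenate(mt)
    order = np.argsort(mt)
    ch = np.concatenate(ch)[order]
    micro = rng.exponential(2.0, mt.size) % period
    meta = {"duration": duration, "background_khz": [background_khz] * 4,
            "period_ns": period, "irf_mu": 0.0, "irf_sigma": 0.25}
    return m.PhotonStream(mt[order], micro, ch, meta)


class TestBurstSearch:
    def test_background_only_yields_no_bursts(self):
        s = synthetic_stream([], background_khz=0.25, duration=100.0, seed=1)
        found = m.find_bursts(s, min_photons=60)
        assert len(found) <= 1

    def test_single_transit_found_with_most_photons(self):
        s = synthetic_stream([(5.0, 2.0, 150)], background_khz=0.1, seed=2)
        found = m.find_bursts(s, min_photons=60)
        assert len(found) == 1
        b = found[0]
        in_transit = np.sum((s.macro_times >= 5.0)
                            & (s.macro_times <= 5.0 + 2e-3))
        got = np.sum((s.macro_times[b.start_index:b.stop_index + 1] >= 5.0)
                     & (s.macro_times[b.start_index:b.stop_index + 1] <= 5.002))
        assert got >= 0.9 * in_transit

    def test_two_separated_transits_give_two_bursts(self):
        s = synthetic_stream([(3.0, 2.0, 150), (3.05, 2.0, 150)], seed=3)
        assert len(m.find_bursts(s, min_photons=60)) == 2

    def test_empty_stream(self):
        s = m.PhotonStream(np.empty(0), np.empty(0), np.empty(0, np.uint8),
                           {"duration": 1.0})
        assert m.find_bursts(s) == []

    def test_invalid_thresholds_rejected(self):
        s = synthetic_stream([(1.0, 2.0, 100)])
        with pytest.raises(ValueError):
            m.find_bursts(s, min_photons=0)


class TestTimeWindows:
    def _burst(self, stream):
        return m.find_bursts(stream, min_photons=60)[0]

    def test_window_count_from_burst_duration(self):
        s = synthetic_stream([(2.0, 3.2, 400)], background_khz=0.0)
        b = self._burst(s)
        assert len(m.time_windows(s, b, 1.0)) == int(b.duration // 1.0) >= 3
        assert m.time_windows(s, b, 2.0 * b.duration) == []

    def test_short_burst_yields_no_windows(self):
        s = synthetic_stream([(2.0, 0.8, 120)], background_khz=0.0)
        b = self._burst(s)
        assert m.time_windows(s, b, 2.0) == []

    def test_photon_count_conservation(self):
        s = synthetic_stream([(2.0, 3.0, 600)], background_khz=0.0)
        b = self._burst(s)
        wins = m.time_windows(s, b, 1.0)
        win_total = sum(w.counts.sum() for w in wins)
        assert win_total <= b.n_photons
        # windows tile the burst without overlap
        idx = np.concatenate([np.arange(w.start_index, w.stop_index)
                              for w in wins])
        assert idx.size == np.unique(idx).size


class TestObservables:
    def _count_stream(self, n_green, n_red, duration_ms=2.0):
        """Deterministic counts in one 'burst': green then red photons."""
        n = n_green + n_red
        t = np.linspace(0.0, duration_ms * 1e-3, n)
        ch = np.r_[np.zeros(n_green), np.full(n_red, 2)].astype(np.uint8)
        micro = np.full(n, 2.0)
        meta = {"duration": duration_ms * 1e-3, "background_khz": [0.0] * 4,
                "period_ns": 15.625, "irf_mu": 0.0, "irf_sigma": 0.25}
        s = m.PhotonStream(t, micro, ch, meta)
        b = m.Burst(0, n - 1, 0.0, duration_ms * 1e-3,
                    np.bincount(ch, minlength=4))
        return s, b

    def test_distance_at_half_efficiency_is_r0(self):
        s, b = self._count_stream(500, 500)
        obs = m.mfd_observables(s, b, m.Calibration(R0=53.0),
                                min_lifetime_photons=10 ** 9)
        assert obs.rda_e == pytest.approx(53.0, abs=1e-9)

    def test_distance_inverts_forster_relation(self):
        # E = 0.727 -> R = 45.0 with R0 = 53
        s, b = self._count_stream(273, 727)
        obs = m.mfd_observables(s, b, m.Calibration(R0=53.0),
                                min_lifetime_photons=10 ** 9)
        assert obs.rda_e == pytest.approx(45.0, abs=0.1)

    def test_zero_acceptor_is_right_censored(self):
        s, b = self._count_stream(300, 0)
        obs = m.mfd_observables(s, b, m.Calibration(R0=53.0),
                                min_lifetime_photons=10 ** 9)
        assert obs.censored and obs.rda_e == 150.0

    def test_rigid_dye_anisotropy_approaches_r0(self):
        """ρ → ∞: r_D → r0 = 0.38 within counting noise (Perrin limit)."""
        st = m.DyeState("s", R_DA=np.inf, sigma_DA=0.0, tau_D=4.0, rho=1e6)
        model = m.ExchangeModel((st,), np.zeros((1, 1)))
        conf = m.ConfocalModel(mean_occupancy=0.02, brightness=150.0,
                               background=0.0)
        s = m.simulate_photon_stream(model, conf, 20.0, seed=8)
        found = m.find_bursts(s)
        assert len(found) > 50
        obs = [m.mfd_observables(s, b, m.Calibration(),
                                 min_lifetime_photons=10 ** 9) for b in found]
        r_mean = np.mean([o.r_d for o in obs])
        assert abs(r_mean - 0.38) < 0.01

    def test_lifetime_mle_recovers_simulated_lifetime(self,
                                                      single_state_stream):
        """⟨τ⟩ MLE on ≥100-photon segments within 5% of the simulated
        FRET-shortened lifetime (4 ns × 0.5 = 2 ns)."""
        s = single_state_stream
        found = [b for b in m.find_bursts(s) if b.counts[:2].sum() >= 100]
        assert len(found) > 20
        calib = m.Calibration(R0=53.0, background=s.metadata["background_khz"])
        taus = [m.mfd_observables(s, b, calib).tau_da_f for b in found[:60]]
        assert abs(np.mean(taus) - 2.0) / 2.0 < 0.05

    def test_burstwise_efficiency_unbiased(self, single_state_stream):
        """Mean burst-wise proximity-derived E within 0.01 of the
        Förster prediction for a static state at R0."""
        s = single_state_stream
        found = m.find_bursts(s)
        g = np.array([b.counts[0] + b.counts[1] for b in found], float)
        r = np.array([b.counts[2] + b.counts[3] for b in found], float)
        e = r / (r + g)
        assert abs(e.mean() - 0.5) < 0.01


class TestHistogram2D:
    def test_single_record_single_cell(self):
        o = bursts.MFDObservables(1.0, 45.0, 2.0, 0.2, 50, 50, 1.0)
        h = m.mfd_histogram2d([o], "rda_e", "tau_da_f", bins=10)
        assert h.counts.sum() == 1 and (h.counts > 0).sum() == 1

    def test_marginals_are_projections(self):
        rng = np.random.default_rng(0)
        obs = [bursts.MFDObservables(1.0, r, t, 0.1, 50, 50, 1.0)
               for r, t in zip(rng.uniform(30, 80, 500),
                               rng.uniform(0.5, 4, 500))]
        h = m.mfd_histogram2d(obs, "rda_e", "tau_da_f", bins=15)
        assert np.array_equal(h.marginal_x, h.counts.sum(axis=1))
        assert np.array_equal(h.marginal_y, h.counts.sum(axis=0))
        assert h.marginal_x.sum() == 500

    def test_all_missing_raises_with_observable_name(self):
        o = bursts.MFDObservables(1.0, 45.0, np.nan, 0.2, 50, 50, 1.0)
        with pytest.raises(ValueError, match="tau_da_f"):
            m.mfd_histogram2d([o], "rda_e", "tau_da_f")

    def test_two_slow_states_give_bimodal_distance_marginal(self):
        from conftest import two_state_exchange
        model = two_state_exchange(5.0, 5.0, r_h=40.0, r_l=60.0, sigma=0.5)
        s = m.simulate_photon_stream(
            model, m.ConfocalModel(mean_occupancy=0.02, brightness=120.0,
                                   background=0.2), 60.0, seed=17)
        calib = m.Calibration(R0=53.0, background=s.metadata["background_khz"])
        found = m.find_bursts(s)
        wins = []
        for i, b in enumerate(found):
            wins += m.time_windows(s, b, 2.0, i)
        obs = [o for o in bursts.window_observables(
            s, wins, calib, min_lifetime_photons=10 ** 9) if not o.censored]
        h = m.mfd_histogram2d(obs, "rda_e", "fd_fa", bins=[
            np.linspace(30, 75, 31), np.linspace(0, 100, 10)])
        marg = h.marginal_x
        centers = 0.5 * (h.x_edges[:-1] + h.x_edges[1:])
        # the two most populated, well-separated modes sit at the state means
        main = centers[np.argmax(marg)]
        far = marg.copy()
        far[np.abs(centers - main) < 8.0] = 0
        second = centers[np.argmax(far)]
        lo, hi = sorted([main, second])
        bw = centers[1] - centers[0]
        assert abs(lo - 40.0) <= bw
        assert abs(hi - 60.0) <= bw
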