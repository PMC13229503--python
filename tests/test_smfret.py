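"""Burst searches vs brute-force oracles, E*/S* statistics, BVA and titration fits."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from bindkin.simulate import SimConfig, simulate_photon_stream
from bindkin.smfret import (
    Burst,
    PhotonStream,
    PopulationFit,
    accurate_fret,
    all_photon_burst_search,
    burst_proximity,
    bva,
    bva_semicircle,
    dual_channel_burst_search,
    fit_population_gaussian,
    fraction_outside,
    hill_titration_fit,
    lifetime_fret,
    lifetime_from_fret,
)
from conftest import brute_force_apbs, runs_of

CLOCK = 100e-9


def make_stream(times_s, labels, background=None):
    order = np.argsort(times_s, kind="stable")
    return PhotonStream(
        timestamps=np.round(np.asarray(times_s)[order] / CLOCK).astype(np.int64),
        stream=np.asarray(labels, dtype=object)[order],
        clock=CLOCK,
        background=background or {},
    )


class TestAllPhotonBurstSearch:
    def test_single_dense_cluster_detected(self):
        """200 photons at 10 µs spacing inside 2 ms on a 1/ms background give one burst."""
        rng = np.random.default_rng(0)
        bg = np.sort(rng.uniform(0, 1.0, 1000))  # 1 photon/ms over 1 s
        cluster = 0.5 + np.arange(200) * 10e-6
        times = np.concatenate([bg, cluster])
        labels = ["DD"] * times.size
        stream = make_stream(times, labels)
        bursts = all_photon_burst_search(stream)
        assert len(bursts) == 1
        assert bursts[0].total >= 200

    def test_sparse_background_yields_no_bursts(self):
        rng = np.random.default_rng(1)
        times = np.sort(rng.uniform(0, 1.0, 2000))  # 2 photons/ms
        stream = make_stream(times, ["DD"] * 2000)
        assert all_photon_burst_search(stream) == []

    def test_min_total_edge(self):
        """A cluster of 149 photons is rejected by the minimum-total filter."""
        cluster = 0.1 + np.arange(149) * 10e-6
        stream = make_stream(cluster, ["DD"] * 149)
        assert all_photon_burst_search(stream, min_total=150) == []
        cluster = 0.1 + np.arange(150) * 10e-6
        stream = make_stream(cluster, ["DD"] * 150)
        assert len(all_photon_burst_search(stream, min_total=150)) == 1

    def test_matches_brute_force_on_simulated_stream(self):
        """Sliding-window search equals exhaustive criterion evaluation."""
        cfg = SimConfig(seed=7, E1=0.5, E2=0.5, background={"DD": 800.0, "DA": 400.0, "AA": 600.0})
        stream = simulate_photon_stream(cfg, 1.2)
        assert len(stream) < 10_000
        sel = brute_force_apbs(stream.timestamps, CLOCK, 500e-6, 15)
        expected = [
            (a, b)
            for a, b in runs_of(sel)
            if b - a + 1 >= 150
        ]
        bursts = all_photon_burst_search(stream)
        got = [(b.indices[0], b.indices[-1]) for b in bursts]
        assert got == expected

    def test_empty_stream(self):
        stream = PhotonStream(
            timestamps=np.array([], dtype=np.int64), stream=np.array([], dtype=object)
        )
        assert all_photon_burst_search(stream) == []


class TestDualChannelBurstSearch:
    BG = {"DD": 1000.0, "DA": 500.0, "AA": 800.0}

    def test_donor_only_stream_rejected_by_and_gate(self):
        cfg = SimConfig(seed=3, donor_only_fraction=1.0, background=self.BG)
        stream = simulate_photon_stream(cfg, 2.0)
        assert dual_channel_burst_search(stream) == []
        # same stream passes the all-photon search: the AND-gate is the difference
        assert len(all_photon_burst_search(stream)) > 0

    def test_matches_brute_force_on_small_stream(self):
        cfg = SimConfig(seed=4, E1=0.5, E2=0.5, background=self.BG)
        stream = simulate_photon_stream(cfg, 1.0)
        bursts = dual_channel_burst_search(stream, m=10, F=6.0)
        got = {(b.indices[0], b.indices[-1]) for b in bursts}
        expected = self._brute_force(stream, m=10, F=6.0, min_D=50, min_A=50)
        assert got == expected

    def _brute_force(self, stream, m, F, min_D, min_A):
        ts = stream.timestamps
        d_mask = np.isin(stream.stream, ("DD", "DA"))
        a_mask = stream.stream == "AA"
        windows = {}
        for mask, bg in ((d_mask, self.BG["DD"] + self.BG["DA"]), (a_mask, self.BG["AA"])):
            sub = ts[mask]
            sel = np.zeros(sub.size, dtype=bool)
            span_max = (m - 1) / (F * bg) / stream.clock
            for i in range(sub.size):
                j0 = max(0, min(i - m // 2, sub.size - m))
                if sub.size >= m and sub[j0 + m - 1] - sub[j0] <= span_max:
                    sel[i] = True
            iv = []
            for a, b in runs_of(sel):
                iv.append((sub[a], sub[b]))
            windows[bg] = iv
        (iv_d, iv_a) = windows.values()
        selected = np.zeros(ts.size, dtype=bool)
        for lo_d, hi_d in iv_d:
            for lo_a, hi_a in iv_a:
                lo, hi = max(lo_d, lo_a), min(hi_d, hi_a)
                if lo <= hi:
                    selected |= (ts >= lo) & (ts <= hi)
        out = set()
        for a, b in runs_of(selected):
            labels = stream.stream[a : b + 1]
            n_d = int(np.isin(labels, ("DD", "DA")).sum())
            n_a = int((labels == "AA").sum())
            if n_d >= min_D and n_a >= min_A:
                out.add((a, b))
        return out

    def test_acceptor_count_edge(self):
        """A burst carrying 49 acceptor-excitation photons is filtered out."""
        d_times = 0.1 + np.arange(100) * 4e-6
        a_times = 0.1 + 2e-6 + np.arange(49) * 8e-6
        times = np.concatenate([d_times, a_times])
        labels = ["DD"] * 100 + ["AA"] * 49
        stream = make_stream(times, labels, background=self.BG)
        assert dual_channel_burst_search(stream, min_A=50) == []
        assert len(dual_channel_burst_search(stream, min_A=49)) == 1

    def test_requires_background_rates(self):
        stream = make_stream([0.1, 0.2], ["DD", "AA"])
        with pytest.raises(ValueError):
            dual_channel_burst_search(stream)


class TestProximityAndCorrections:
    def test_direct_arithmetic(self):
        b = Burst(start=0, stop=100, F_DD=60, F_DA=40, F_AA=100, duration=1e-3)
        E, S = burst_proximity(b)
        assert E == pytest.approx(0.4) and S == pytest.approx(0.5)

    def test_donor_only_signature(self):
        b = Burst(start=0, stop=1, F_DD=80, F_DA=0, F_AA=0, duration=1e-3)
        E, S = burst_proximity(b)
        assert E == 0.0 and S == 1.0

    def test_acceptor_only_flagged_undefined(self):
        b = Burst(start=0, stop=1, F_DD=0, F_DA=0, F_AA=120, duration=1e-3)
        E, S = burst_proximity(b)
        assert math.isnan(E) and S == pytest.approx(0.0)

    def test_accurate_fret_reduces_to_proximity(self):
        assert accurate_fret(60, 40, 100, 0.0, 0.0, 1.0) == pytest.approx(0.4)

    def test_accurate_fret_direct_excitation_correction(self):
        assert accurate_fret(60, 40, 100, 0.1, 0.0, 1.0) == pytest.approx(30 / 90)

    def test_accurate_fret_recovers_generator_truth(self):
        """Mean corrected E over bursts equals the generator E within its SE."""
        cfg = SimConfig(
            seed=5, E1=0.6, E2=0.6, alpha=0.08, beta=0.05, gamma=1.3,
            burst_duration_median=2e-3,
        )
        stream = simulate_photon_stream(cfg, 20.0)
        bursts = all_photon_burst_search(stream)
        assert len(bursts) >= 50
        Es = []
        for b in bursts:
            Es.append(accurate_fret(b.F_DD, b.F_DA, b.F_AA, cfg.alpha, cfg.beta, cfg.gamma))
        Es = np.asarray(Es)
        se = Es.std(ddof=1) / np.sqrt(Es.size)
        assert abs(Es.mean() - 0.6) < 3 * se + 0.005

    def test_lifetime_relation(self):
        assert lifetime_fret(4.0, 4.0) == 0.0
        assert lifetime_fret(2.0, 4.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            lifetime_fret(5.0, 4.0)

    def test_lifetime_round_trip(self):
        rng = np.random.default_rng(6)
        for E in rng.uniform(0, 0.99, 20):
            tau = lifetime_from_fret(E, 4.1)
            assert lifetime_fret(tau, 4.1) == pytest.approx(E, abs=1e-12)


class TestPopulationFit:
    def test_single_gaussian_recovery(self):
        rng = np.random.default_rng(8)
        E = rng.normal(0.5, 0.05, 5000)
        fit = fit_population_gaussian(E, 1)
        assert fit.means[0] == pytest.approx(0.5, abs=0.01)
        assert fit.sigmas[0] == pytest.approx(0.05, rel=0.2)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(9)
        E = np.concatenate([rng.normal(0.51, 0.06, 3000), rng.normal(0.68, 0.05, 2000)])
        fit = fit_population_gaussian(E, 2)
        assert fit.means[0] == pytest.approx(0.51, abs=0.02)
        assert fit.means[1] == pytest.approx(0.68, abs=0.02)

    def test_histogram_mode_agrees(self):
        rng = np.random.default_rng(10)
        E = rng.normal(0.47, 0.07, 4000)
        fit = fit_population_gaussian(E, 1, method="histogram")
        assert fit.means[0] == pytest.approx(0.47, abs=0.02)

    def test_degenerate_constant_sample_flagged(self):
        fit = fit_population_gaussian(np.full(100, 0.5), 1)
        assert fit.degenerate and fit.sigmas[0] == pytest.approx(0.02)

    def test_outside_fraction_pure_gaussian(self):
        """At +-1 sigma a pure Gaussian leaves 2 Phi(-1) ~ 31.7% outside."""
        rng = np.random.default_rng(11)
        E = rng.normal(0.5, 0.05, 20_000)
        fit = PopulationFit(means=[0.5], sigmas=[0.05], weights=[1.0])
        expect = 2 * norm.cdf(-1)
        assert fraction_outside(E, fit, 1.0) == pytest.approx(expect, abs=0.02)

    def test_outside_fraction_all_inside(self):
        fit = PopulationFit(means=[0.5], sigmas=[0.3], weights=[1.0])
        assert fraction_outside(np.full(200, 0.5), fit, 1.0) == 0.0

    def test_outside_fraction_planted_outliers(self):
        """An 8% outlier population adds to the Gaussian tail mass."""
        rng = np.random.default_rng(12)
        main = rng.normal(0.47, 0.05, 9200)
        outl = rng.normal(0.9, 0.02, 800)
        E = np.concatenate([main, outl])
        fit = PopulationFit(means=[0.47], sigmas=[0.05], weights=[1.0])
        expect = 0.92 * 2 * norm.cdf(-1) + 0.08
        assert fraction_outside(E, fit, 1.0) == pytest.approx(expect, abs=0.02)


class TestBVA:
    def test_semicircle_value(self):
        assert bva_semicircle(np.array([0.5]), 100)[0] == pytest.approx(0.05)

    def test_static_bursts_on_semicircle(self, static_stream, static_bursts):
        """Static molecules: mean within-burst SD deviates from sqrt(E(1-E)/n)
        by less than 2 Monte-Carlo SE."""
        res = bva(static_stream, static_bursts, n=5)
        dev = res.sd_E - res.semicircle()
        se = dev.std(ddof=1) / np.sqrt(dev.size)
        # default 1 ms bursts carry a small finite-window bias; allow it on top of 2 SE
        assert abs(dev.mean()) < 2 * se + 0.01

    def test_dynamic_bursts_exceed_semicircle(self):
        """Two-state switching at 1 ms^-1, dE = 0.2: SD above semicircle by > 3 SE."""
        cfg = SimConfig(
            seed=2, E1=0.4, E2=0.6, k_12=1000.0, k_21=1000.0,
            burst_duration_median=3e-3,
        )
        stream = simulate_photon_stream(cfg, 30.0)
        bursts = all_photon_burst_search(stream)
        res = bva(stream, bursts, n=5)
        exc = res.sd_E - res.semicircle()
        se = exc.std(ddof=1) / np.sqrt(exc.size)
        assert exc.mean() > 3 * se

    def test_short_bursts_skipped(self, static_stream, static_bursts):
        res = bva(static_stream, static_bursts, n=200)
        assert res.E_star.size + res.n_skipped == len(static_bursts)


class TestHillTitration:
    CONCS = np.array([5, 10, 20, 40, 80, 160, 320, 640]) * 1e-9

    def test_half_saturation_point(self):
        kd = 35e-9
        f = self.CONCS / (kd + self.CONCS)
        i = np.argmin(np.abs(self.CONCS - kd))
        assert f[i] == pytest.approx(self.CONCS[i] / (kd + self.CONCS[i]))
        fit = hill_titration_fit(self.CONCS, f)
        assert fit["K_d"] == pytest.approx(kd, rel=1e-6)

    def test_recovery_with_noise(self):
        rng = np.random.default_rng(13)
        kd = 35e-9
        f = self.CONCS / (kd + self.CONCS)
        fit = hill_titration_fit(self.CONCS, f * (1 + rng.normal(0, 0.03, f.size)))
        assert fit["K_d"] == pytest.approx(kd, rel=0.15)

    def test_requires_three_concentrations(self):
        with pytest.raises(ValueError):
            hill_titration_fit(np.array([1e-8, 1e-8]), np.array([0.5, 0.5]))
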