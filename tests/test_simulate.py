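"""Stochastic integrator and first-passage event extraction.

The analytic oracle throughout: for an uncoupled phase with period T and
diffusion sigma, the interval between successive events is
inverse-Gaussian with mean T and shape (2*pi/sigma)^2, hence
SD = sigma * T^(3/2) / (2*pi).
"""

import math

import numpy as np
import pytest
from scipy import stats

from cellclock.model import ModelParams
from cellclock.simulate import (EventSequence, PhasePath, extract_events,
                                simulate_cohort, simulate_sde)

TWO_PI = 2 * math.pi


def long_intervals(T, sigma, n_cells=60, duration=600.0, seed=3, dt=0.02):
    """Pooled p->p intervals from long traces (negligible window censoring)."""
    params = ModelParams(T1=T, T2=math.inf, sigma1=sigma, sigma2=0.0)
    events = simulate_cohort(params, n_cells, duration=duration, dt=dt,
                             seed=seed, burn_in=0.0)
    out = []
    for ev in events:
        t = ev.times_of("p")
        out.append(np.diff(t))
    return np.concatenate(out)


class TestSimulateSde:
    def test_zero_noise_linear_drift_exact(self):
        p = ModelParams(T1=24.0, T2=math.inf, sigma1=0.0, sigma2=0.0)
        path = simulate_sde(p, x0=(0.3, 0.0), t_end=72.0, dt=0.02, seed=0)
        expected = 0.3 + TWO_PI * path.times / 24.0
        assert np.allclose(path.theta, expected, atol=1e-10)

    def test_same_seed_bit_identical(self):
        p = ModelParams(T1=24.0, T2=20.0, sigma1=0.2, sigma2=0.3)
        a = simulate_sde(p, t_end=24.0, seed=42)
        b = simulate_sde(p, t_end=24.0, seed=42)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.phi, b.phi)
        c = simulate_sde(p, t_end=24.0, seed=43)
        assert not np.array_equal(a.theta, c.theta)

    def test_brownian_variance_growth(self):
        p = ModelParams(T1=24.0, T2=24.0, sigma1=0.3, sigma2=0.0)
        t_end = 10.0
        finals = np.array([
            simulate_sde(p, t_end=t_end, dt=0.05, seed=s).theta[-1]
            for s in range(2000)
        ])
        resid = finals - TWO_PI * t_end / 24.0
        assert resid.var() == pytest.approx(0.3 ** 2 * t_end, rel=0.08)

    def test_invalid_arguments(self):
        p = ModelParams(T1=24.0, T2=24.0, sigma1=0.1, sigma2=0.1)
        with pytest.raises(ValueError):
            simulate_sde(p, t_end=-1.0)
        with pytest.raises(ValueError):
            simulate_sde(p, t_end=10.0, dt=0.2)


class TestExtractEvents:
    def test_linear_phase_peak_times(self):
        times = np.arange(0, 72.0 + 1e-9, 0.02)
        theta = TWO_PI * times / 24.0
        path = PhasePath(times=times, theta=theta, phi=np.zeros_like(times),
                         dt=0.02)
        ev = extract_events(path)
        assert np.allclose(ev.times_of("p"), [24.0, 48.0, 72.0], atol=1e-9)
        assert len(ev.times_of("d")) == 0

    def test_interpolated_time_strictly_inside_step(self):
        times = np.array([0.0, 1.0, 2.0])
        theta = np.array([5.9, 6.1, 6.5])  # crosses 2*pi between samples 1,2
        path = PhasePath(times=times, theta=theta, phi=np.zeros(3), dt=1.0)
        t = extract_events(path).times_of("p")
        assert len(t) == 1 and 1.0 < t[0] < 2.0

    def test_noise_recrossings_not_double_counted(self):
        # a diffusing phase wiggling across a level must yield one event
        times = np.arange(0, 3.0 + 1e-9, 0.5)
        theta = np.array([6.0, 6.4, 6.2, 6.5, 6.1, 6.6, 6.9])
        path = PhasePath(times=times, theta=theta, phi=np.zeros_like(times),
                         dt=0.5)
        assert len(extract_events(path).times_of("p")) == 1

    def test_uncoupled_interval_mean_matches_first_passage(self):
        iv = long_intervals(24.0, 0.17, n_cells=40, duration=500.0)
        assert len(iv) > 500
        assert iv.mean() == pytest.approx(24.0, abs=0.15)

    def test_inverse_gaussian_distribution_ks(self):
        T, sigma = 24.0, 0.17
        iv = long_intervals(T, sigma, n_cells=100, duration=600.0, seed=5)
        lam = (TWO_PI / sigma) ** 2  # shape parameter
        mu = T
        d, _ = stats.kstest(iv, stats.invgauss(mu / lam, scale=lam).cdf)
        assert len(iv) >= 2000
        assert d < 0.02

    def test_interval_sd_matches_diffusion_inversion(self):
        T, sigma = 23.7, 3.1 * TWO_PI / 23.7 ** 1.5
        iv = long_intervals(T, sigma, n_cells=80, duration=600.0, seed=9)
        assert iv.std(ddof=1) == pytest.approx(3.1, abs=0.15)


class TestSimulateCohort:
    def test_window_bounds_event_count(self, free37_cohort):
        for ev in free37_cohort:
            assert len(ev.times_of("p")) <= 5
            for t, _ in ev.events:
                assert 0.0 <= t <= 72.0

    def test_reproducible_and_chunk_invariant(self, free37):
        params, _ = free37
        a = simulate_cohort(params, 12, duration=48.0, seed=7, burn_in=0.0)
        b = simulate_cohort(params, 12, duration=48.0, seed=7, burn_in=0.0,
                            chunk=5)
        for ea, eb in zip(a, b):
            assert ea.events == eb.events

    def test_cell_streams_independent_of_cohort_size(self, free37):
        params, _ = free37
        small = simulate_cohort(params, 3, duration=48.0, seed=7, burn_in=0.0)
        big = simulate_cohort(params, 8, duration=48.0, seed=7, burn_in=0.0)
        for ea, eb in zip(small, big[:3]):
            assert ea.events == eb.events

    def test_event_counts_scale_with_duration(self, free37):
        params, _ = free37
        short = simulate_cohort(params, 80, duration=100.0, seed=11, burn_in=0.0)
        long_ = simulate_cohort(params, 80, duration=200.0, seed=11, burn_in=0.0)
        n_s = sum(len(e) for e in short)
        n_l = sum(len(e) for e in long_)
        assert n_l / n_s == pytest.approx(200.0 / 100.0, rel=0.1)

    def test_halving_dt_leaves_interval_mean(self, free37):
        params, _ = free37
        means = []
        for dt in (0.04, 0.02):
            evs = simulate_cohort(params, 150, duration=300.0, dt=dt, seed=13,
                                  burn_in=0.0)
            iv = np.concatenate([np.diff(e.times_of("p")) for e in evs])
            means.append(iv.mean())
        assert abs(means[0] - means[1]) < 0.05

    def test_locked_intervals_shorter_than_free_running(self, a37, free37):
        pa, _ = a37
        evs = simulate_cohort(pa, 150, duration=72.0, seed=17)
        pdp = []
        for e in evs:
            seq = e.events
            peaks = [(i, t) for i, (t, k) in enumerate(seq) if k == "p"]
            for (i1, t1), (i2, t2) in zip(peaks[:-1], peaks[1:]):
                n_div = sum(1 for t, k in seq[i1 + 1:i2] if k == "d")
                if n_div == 1:
                    pdp.append(t2 - t1)
        assert len(pdp) > 100
        assert np.mean(pdp) < 23.7 - 0.5


class TestEventSequenceInvariants:
    def test_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            EventSequence("c", [(1.0, "p"), (1.0, "d")])

    def test_window_containment_enforced(self):
        with pytest.raises(ValueError):
            EventSequence("c", [(5.0, "p")], t_start=0.0, t_end=4.0)
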