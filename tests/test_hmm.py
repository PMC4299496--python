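"""Viterbi phase decoding and velocity profiles."""

import math

import numpy as np
import pytest

from cellclock.hmm import (DecodedPath, HMMSpec, instantaneous_velocity,
                           velocity_profile, viterbi_decode)
from cellclock.synth import generate_dataset

TWO_PI = 2 * math.pi


def clean_cosine(T=24.0, duration=72.0, dt=0.5, b=50.0, A=100.0):
    t = np.arange(0, duration + 1e-9, dt)
    return t, b + A * (1 + np.cos(TWO_PI * t / T)) / 2


@pytest.fixture(scope="module")
def decoded_free37():
    ds = generate_dataset("REF-FREE37", 20, seed=41)
    spec = HMMSpec(period=23.7, sigma=ds.params.sigma1)
    out = []
    for i in range(ds.n_cells):
        out.append((viterbi_decode(ds.yfp[i], ds.times, spec), ds.paths[i],
                    ds.events[i]))
    return ds, out


class TestViterbiDecode:
    def test_phase_zero_at_signal_maxima(self):
        t, y = clean_cosine()
        dec = viterbi_decode(y, t, HMMSpec())
        bin_w = TWO_PI / dec.spec.n_theta
        for tm in (0.0, 24.0, 48.0):
            i = int(tm / 0.5)
            wrapped = dec.theta_hat[i] % TWO_PI
            d = min(wrapped, TWO_PI - wrapped)
            assert d <= bin_w + 1e-9

    def test_mean_velocity_on_clean_cosine(self):
        t, y = clean_cosine(T=24.0)
        dec = viterbi_decode(y, t, HMMSpec(period=24.0))
        v = instantaneous_velocity(dec)
        bin_per_step = (TWO_PI / dec.spec.n_theta) / 0.5
        assert np.mean(v[2:-2]) == pytest.approx(TWO_PI / 24.0,
                                                 abs=bin_per_step)

    def test_decoding_rmse_on_rendered_traces(self, decoded_free37):
        _, decs = decoded_free37
        errs = []
        for dec, path, _ in decs:
            true_theta = path.theta[::25]  # 0.5 h grid
            d = (dec.theta_hat - true_theta + math.pi) % TWO_PI - math.pi
            errs.append(d)
        rmse = float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))
        assert rmse < 0.3

    def test_decoded_period_matches_true_path(self, decoded_free37):
        """Decoded rotation rate tracks the generating path's rate (cohort
        sampling noise cancels by comparing cell for cell)."""
        _, decs = decoded_free37
        rates = [np.polyfit(dec.times, dec.theta_hat, 1)[0]
                 for dec, _, _ in decs]
        true_rates = [np.polyfit(path.times, path.theta, 1)[0]
                      for _, path, _ in decs]
        period = TWO_PI / np.mean(rates)
        true_period = TWO_PI / np.mean(true_rates)
        assert period == pytest.approx(true_period, abs=0.5)

    def test_bin_refinement_convergence(self, decoded_free37):
        ds, decs = decoded_free37

        def rmse(spec):
            errs = []
            for i in range(5):
                dec = viterbi_decode(ds.yfp[i], ds.times, spec)
                d = (dec.theta_hat - ds.paths[i].theta[::25]
                     + math.pi) % TWO_PI - math.pi
                errs.append(d)
            return float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))

        base = HMMSpec(period=23.7, sigma=ds.params.sigma1)
        fine = HMMSpec(period=23.7, sigma=ds.params.sigma1, n_theta=96)
        r1, r2 = rmse(base), rmse(fine)
        assert abs(r2 - r1) < 0.2 * r1 + 0.02

    def test_affine_equivariance(self):
        t, y = clean_cosine()
        a, c = 2.5, 30.0
        s1 = HMMSpec()
        s2 = HMMSpec(baseline=s1.baseline * a + c, amp_mean=s1.amp_mean * a,
                     amp_noise=s1.amp_noise * a, obs_noise=s1.obs_noise * a)
        d1 = viterbi_decode(y, t, s1)
        d2 = viterbi_decode(a * y + c, t, s2)
        assert np.array_equal(d1.theta_hat, d2.theta_hat)


class TestVelocity:
    def test_linear_phase_constant_velocity(self):
        t = np.arange(0, 48.0 + 1e-9, 0.5)
        dec = DecodedPath(times=t, theta_hat=TWO_PI * t / 24.0,
                          amp_hat=np.ones_like(t), logp=np.zeros_like(t))
        assert np.allclose(instantaneous_velocity(dec), TWO_PI / 24.0)

    def test_constant_phase_zero_velocity(self):
        t = np.arange(0, 48.0 + 1e-9, 0.5)
        dec = DecodedPath(times=t, theta_hat=np.full_like(t, 1.0),
                          amp_hat=np.ones_like(t), logp=np.zeros_like(t))
        assert np.allclose(instantaneous_velocity(dec), 0.0)

    def test_flat_profile_division_free(self, decoded_free37):
        _, decs = decoded_free37
        prof = velocity_profile([d for d, _, _ in decs],
                                [e for _, _, e in decs])
        free = prof["free"]
        sel = free["n"] >= 30
        dev = np.abs(free["mean"][sel] - TWO_PI / 23.7)
        # flat profile: small systematic wiggles near the waveform maximum
        # (flat emission gradient) are the only structure expected
        assert np.all(dev <= 0.15)
        assert np.mean(dev) <= 0.05

    def test_centering_makes_free_profile_zero(self, decoded_free37):
        _, decs = decoded_free37
        prof = velocity_profile([d for d, _, _ in decs],
                                [e for _, _, e in decs])
        assert np.allclose(prof["free"]["mean_centered"][prof["free"]["n"] > 0]
                           [~np.isnan(prof["free"]["mean_centered"]
                                      [prof["free"]["n"] > 0])], 0.0)

    def test_coupling_sign_visible_in_normalized_profiles(self):
        """The generator's coupling must surface in the centered velocity
        profiles of division-containing intervals: positive in the
        acceleration's phase range for the locked fixture, negative in the
        slowdown's range for a dilution-like fixture.  Division-free
        baseline intervals come from a non-dividing cohort decoded the same
        way, as in a culture containing both dividing and resting cells."""
        from cellclock.model import CouplingBump, CouplingFunction, ModelParams
        from cellclock.simulate import simulate_cohort
        from cellclock.synth import RenderSpec, render_yfp, make_fixture

        def decode_cohort(params, seed, n):
            rspec = RenderSpec()
            evs, paths = simulate_cohort(params, n, seed=seed,
                                         return_paths=True)
            spec = HMMSpec(period=24.0, sigma=0.17)
            decs = [viterbi_decode(render_yfp(p, e, rspec, seed=1000 + i),
                                   p.times[::25], spec,
                                   mask_times=e.times_of("d"))
                    for i, (p, e) in enumerate(zip(paths, evs))]
            return decs, evs

        def range_mean(prof, lo, hi):
            vals = []
            for cohort in ("early", "late"):
                if cohort in prof and "mean_centered" in prof[cohort]:
                    c = prof[cohort]["bin_centers"]
                    sel = (prof[cohort]["n"] >= 10) & (c >= lo) & (c <= hi)
                    vals.extend(prof[cohort]["mean_centered"][sel])
            return float(np.nanmean(vals))

        free_p, _ = make_fixture("REF-FREE37")
        base_d, base_e = decode_cohort(free_p, 99, 15)

        accel, _ = make_fixture("REF-A37")
        dc, ec = decode_cohort(accel, 43, 25)
        prof = velocity_profile(dc + base_d, ec + base_e, n_bins=12)
        # on the locked path the acceleration acts past the trough on the
        # approach to division (theta ~ 3-4.3)
        assert range_mean(prof, 2.9, 4.3) > 0.02

        slow = ModelParams(
            T1=24.0, T2=21.5, sigma1=free_p.sigma1, sigma2=0.25,
            F1=CouplingFunction((CouplingBump(-2.0, (5.5, 1.0), (0.8, 0.8)),)))
        dc, ec = decode_cohort(slow, 47, 25)
        prof = velocity_profile(dc + base_d, ec + base_e, n_bins=12)
        assert range_mean(prof, 4.7, 6.3) < -0.01
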