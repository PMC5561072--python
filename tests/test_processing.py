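"""Curve processing: detection, WLC fitting, filtering, spectrum building."""
import numpy as np
import pytest

from polydfs import (
    AllEventsFilteredError,
    DomainError,
    EmptySpectrumError,
    EventFlaggedError,
    FilterConfig,
    ForceCurve,
    GeneratorConfig,
    RuptureEvent,
    SimConfig,
    WindowError,
    WLCParams,
    build_spectrum,
    detect_last_rupture,
    filter_events,
    fit_last_event_wlc,
    generate_curve,
    loading_rate,
    numerical_loading_rate,
    run_simulation,
    wlc_force,
)

VELOCITY = 500.0


def make_curve(f, dt=1e-3, velocity=VELOCITY, **kw):
    f = np.asarray(f, dtype=float)
    t = dt * np.arange(len(f))
    return ForceCurve(t=t, x=velocity * t, f=f, velocity=velocity, **kw)


def wlc_pull_curve(l_app=0.4, L=150.0, n=200, n_tail=40, noise=0.0, x_stop=0.97,
                   rng=None, velocity=VELOCITY):
    """Single WLC loaded to x_stop·L then released to baseline."""
    wlc = WLCParams(l_app=l_app, L=L)
    x = np.linspace(0.0, x_stop * L, n)
    f = wlc_force(x, wlc)
    dt = (x[1] - x[0]) / velocity
    t = np.arange(n + n_tail) * dt
    ff = np.concatenate([f, np.zeros(n_tail)])
    if noise > 0:
        ff = ff + (rng or np.random.default_rng(0)).normal(0.0, noise, len(ff))
    return ForceCurve(t=t, x=velocity * t, f=ff, velocity=velocity), n - 1


class TestForceCurveValidation:
    def test_rejects_short_and_unequal_arrays(self):
        with pytest.raises(DomainError):
            make_curve(np.zeros(8))
        with pytest.raises(DomainError):
            ForceCurve(t=np.arange(20.0), x=np.arange(20.0), f=np.zeros(19),
                       velocity=1.0)

    def test_rejects_nonmonotonic_time(self):
        t = np.arange(20.0)
        t[5] = t[4]
        with pytest.raises(DomainError):
            ForceCurve(t=t, x=np.arange(20.0), f=np.zeros(20), velocity=1.0)


class TestDetection:
    def test_flat_curve_has_no_rupture(self, rng):
        det = detect_last_rupture(make_curve(rng.normal(0, 2, 400)))
        assert not det.ok
        assert det.reason == "no_rupture"

    def test_detects_single_rupture(self):
        curve, k = wlc_pull_curve()
        det = detect_last_rupture(curve)
        assert det.ok
        assert det.index == k

    def test_two_ruptures_returns_later(self, rng):
        # staircase: 60 pN plateau, drop to 35, then final drop to baseline
        f = np.concatenate([
            np.linspace(0, 60, 120), np.full(40, 35.0), np.zeros(80)
        ]) + rng.normal(0, 2, 240)
        det = detect_last_rupture(make_curve(f))
        assert det.ok
        assert 155 <= det.index <= 162
        assert det.f_r == pytest.approx(35.0, abs=3 * 5 * det.noise_sigma)

    def test_generator_truth_recovered(self):
        cfg = GeneratorConfig(n_polymers_distribution={1: 1.0}, seed=0)
        n_hit = 0
        for i in range(20):
            rng = np.random.default_rng(100 + i)
            curve, truth = generate_curve(1000.0, cfg, rng)
            det = detect_last_rupture(curve)
            if not det.ok:
                continue
            assert abs(det.index - truth["last_event"]["index"]) <= 2
            assert det.f_r == pytest.approx(
                truth["last_event"]["f_pN"], abs=3 * det.noise_sigma
            )
            n_hit += 1
        assert n_hit >= 15


class TestWLCFitting:
    def test_noiseless_recovery(self):
        curve, k = wlc_pull_curve(l_app=0.4, L=150.0)
        fit = fit_last_event_wlc(curve, k)
        assert fit.converged
        assert fit.l_app == pytest.approx(0.4, rel=5e-3)
        assert fit.L == pytest.approx(150.0, rel=5e-3)

    def test_noisy_recovery_median(self):
        """5 pN noise, 200-sample segment: median l_app error over 100
        replicates stays within 15%."""
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(100):
            curve, k = wlc_pull_curve(noise=5.0, rng=rng)
            det = detect_last_rupture(curve)
            if not det.ok:
                continue
            try:
                fit = fit_last_event_wlc(curve, det.index, detection=det)
            except WindowError:
                continue
            if fit.converged:
                errs.append(abs(fit.l_app - 0.4) / 0.4)
        assert len(errs) >= 90
        assert np.median(errs) < 0.15

    def test_short_window_raises(self):
        curve, _ = wlc_pull_curve()
        with pytest.raises(WindowError):
            fit_last_event_wlc(curve, 5)


class TestFilter:
    @staticmethod
    def event(l_app, velocity=460.0):
        return RuptureEvent(f_r=50.0, r=1e3, t_r=0.1, velocity=velocity,
                            l_app=l_app, L=150.0)

    def test_no_op_filter_keeps_all(self):
        events = [self.event(x) for x in (0.04, 0.2, 0.4, 0.8)]
        cfg = FilterConfig(l_p=0.4, threshold_fraction=1e-9, max_fraction=1e9)
        kept, report = filter_events(events, cfg)
        assert len(kept) == 4
        assert report["n_kept"] == 4

    def test_threshold_rule(self):
        l_p = 0.4
        events = [self.event(frac * l_p) for frac in (0.1, 0.35, 0.45, 0.9)]
        kept, report = filter_events(events, FilterConfig(l_p=l_p, threshold_fraction=0.7))
        assert len(kept) == 1
        assert kept[0].l_app == pytest.approx(0.9 * l_p)
        assert report["n_below_threshold"] == 3

    def test_mixed_n_separation(self, rng):
        """l_app = l_p/N with 10% scatter: the 0.7·l_p cut keeps >90% of
        single-chain events and <5% of multi-chain events."""
        l_p = 0.4
        events, labels = [], []
        for n_chains, count in ((1, 400), (2, 300), (3, 300)):
            l_apps = (l_p / n_chains) * (1 + 0.1 * rng.standard_normal(count))
            events += [self.event(max(la, 1e-3)) for la in l_apps]
            labels += [n_chains] * count
        kept, _ = filter_events(events, FilterConfig(l_p=l_p, threshold_fraction=0.7))
        kept_ids = {id(e) for e in kept}
        frac1 = np.mean([id(e) in kept_ids for e, n in zip(events, labels) if n == 1])
        frac_multi = np.mean([id(e) in kept_ids for e, n in zip(events, labels) if n >= 2])
        assert frac1 > 0.90
        assert frac_multi < 0.05

    def test_all_filtered_raises(self):
        events = [self.event(0.01)]
        with pytest.raises(AllEventsFilteredError):
            filter_events(events, FilterConfig(l_p=0.4))

    def test_invalid_config(self):
        with pytest.raises(DomainError):
            FilterConfig(l_p=0.4, threshold_fraction=1.5)


class TestNumericalLoadingRate:
    def test_linear_ramp_exact(self):
        c = 250.0  # pN/s
        t = 1e-3 * np.arange(200)
        curve = ForceCurve(t=t, x=VELOCITY * t, f=c * t, velocity=VELOCITY)
        assert numerical_loading_rate(curve, 150) == pytest.approx(c, rel=1e-9)

    def test_constant_force_flagged(self):
        curve = make_curve(np.full(100, 30.0))
        with pytest.raises(EventFlaggedError):
            numerical_loading_rate(curve, 80)

    def test_too_few_samples(self):
        curve, _ = wlc_pull_curve()
        with pytest.raises(WindowError):
            numerical_loading_rate(curve, 4)

    def test_matches_analytic_on_noiseless_wlc(self):
        # the 10%-of-samples window averages the stiffness over the
        # final stretch, so agreement with the instantaneous rate is
        # close only while the stiffness varies mildly across the
        # window; at larger extensions the same window reads low
        wlc = WLCParams(l_app=0.4, L=150.0)
        curve, k = wlc_pull_curve(n=2000, x_stop=0.2)
        r_num = numerical_loading_rate(curve, k)
        r_ana = loading_rate(float(curve.f[k]), VELOCITY, wlc)
        assert r_num == pytest.approx(r_ana, rel=0.05)

        curve_hi, k_hi = wlc_pull_curve(n=2000, x_stop=0.8)
        r_num_hi = numerical_loading_rate(curve_hi, k_hi)
        r_ana_hi = loading_rate(float(curve_hi.f[k_hi]), VELOCITY, wlc)
        assert r_num_hi < r_ana_hi


class TestBuildSpectrum:
    def test_single_velocity_arithmetic(self):
        events = [
            RuptureEvent(f_r=f, r=r, t_r=0.1, velocity=460.0, l_app=0.4, L=150.0)
            for f, r in zip((10.0, 20.0, 30.0), (100.0, 200.0, 300.0))
        ]
        points, report = build_spectrum(events)
        (pt,) = points
        assert pt.mean_r == pytest.approx(200.0)
        assert pt.mean_f == pytest.approx(20.0)
        assert pt.sem_f == pytest.approx(5.7735, abs=1e-4)
        assert pt.n_events == 3
        assert report["sparse_velocities"] == [460.0]

    def test_empty_raises(self):
        with pytest.raises(EmptySpectrumError):
            build_spectrum([])

    def test_mc_ensemble_gives_ordered_points(self, wlc, bond):
        cfg = SimConfig(wlc=wlc, bond=bond, n_events_per_velocity=50, seed=2)
        points, _ = build_spectrum(run_simulation(cfg))
        assert len(points) == 4
        forces = [p.mean_f for p in points]
        assert np.all(np.diff(forces) > 0)
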