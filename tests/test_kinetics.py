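"""Bell kinetics, the E1 kernel, and the single-bond spectrum fit."""
import math

import numpy as np
import pytest
from scipy.integrate import quad

from polydfs import (
    BondParams,
    DomainError,
    FitError,
    MeanForcePoint,
    OverflowGuardError,
    SimConfig,
    bell_rate,
    build_spectrum,
    exp1,
    exp_scaled_e1,
    fit_single_bond_model,
    mean_rupture_force,
    run_simulation,
)

EULER_GAMMA = 0.5772156649015329


def quad_exp1(z: float) -> float:
    """Independent oracle: E1(z) = e^{-z} ∫_0^∞ e^{-u}/(z+u) du."""
    val, _ = quad(lambda u: math.exp(-u) / (z + u), 0.0, np.inf, epsrel=1e-12)
    return math.exp(-z) * val


def series_exp1(z: float, terms: int = 60) -> float:
    """Convergent series oracle for small z."""
    s = 0.0
    for k in range(1, terms + 1):
        s += (-1) ** (k + 1) * z**k / (k * math.factorial(k))
    return -EULER_GAMMA - math.log(z) + s


class TestBellRate:
    def test_zero_force_gives_k_off(self, bond, kBT):
        assert bell_rate(0.0, bond, kBT) == bond.k_off

    def test_e_fold_at_f_beta(self, bond, kBT):
        fb = bond.f_beta(kBT)
        assert bell_rate(fb, bond, kBT) == pytest.approx(bond.k_off * math.e, rel=1e-12)
        assert bell_rate(2 * fb, bond, kBT) == pytest.approx(
            bond.k_off * math.e**2, rel=1e-12
        )

    def test_overflow_guard(self, bond, kBT):
        with pytest.raises(OverflowGuardError):
            bell_rate(800.0 * bond.f_beta(kBT), bond, kBT)

    def test_invariants(self, bond, kBT):
        assert bond.f_beta(kBT) * bond.x_t == pytest.approx(kBT, rel=1e-15)
        with pytest.raises(DomainError):
            bell_rate(-1.0, bond, kBT)


class TestExp1:
    def test_unit_argument(self):
        assert exp1(1.0) == pytest.approx(0.219384, abs=1e-6)

    def test_small_argument_series_oracle(self):
        assert exp1(0.1) == pytest.approx(series_exp1(0.1), rel=1e-10)
        assert exp1(0.1) == pytest.approx(1.82292, abs=1e-5)

    def test_leading_asymptotics(self):
        z = 50.0
        assert exp1(z) * z * math.exp(z) == pytest.approx(1.0, rel=0.03)

    def test_bounds_and_monotonicity(self):
        zs = np.geomspace(1e-3, 30.0, 40)
        vals = exp1(zs)
        assert np.all(np.diff(vals) < 0)
        assert np.all(vals > 0)
        assert np.all(vals < np.exp(-zs) / zs)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            exp1(0.0)


class TestScaledKernel:
    def test_agrees_with_direct_product_midrange(self):
        for z in (0.01, 0.5, 5.0, 25.0):
            assert exp_scaled_e1(z) == pytest.approx(
                math.exp(z) * quad_exp1(z), rel=1e-10
            )

    def test_branches_agree_at_switch_point(self):
        from polydfs.kinetics import _e1_scaled_cf

        product = exp_scaled_e1(30.0)  # direct-product branch
        cf = _e1_scaled_cf(np.array([30.0]))[0]
        assert cf == pytest.approx(product, rel=1e-12)

    def test_large_argument_asymptote(self):
        # e^z E1(z) ~ 1/z − 1/z² for large z
        for z in (1e3, 1e6, 1e9):
            assert exp_scaled_e1(z) == pytest.approx(1.0 / z - 1.0 / z**2, rel=1e-3)


class TestMeanRuptureForce:
    def test_equilibrium_plateau(self, kBT):
        bond = BondParams(k_off=0.5, x_t=0.3, f_eq=20.0)
        fb = bond.f_beta(kBT)
        r = 1e-6 * bell_rate(bond.f_eq, bond, kBT) * fb
        assert mean_rupture_force(r, bond, kBT) - bond.f_eq < 1e-4 * fb

    def test_kinetic_asymptote(self, kBT):
        bond = BondParams(k_off=0.5, x_t=0.3, f_eq=20.0)
        fb = bond.f_beta(kBT)
        R = 1e4
        r = R * bell_rate(bond.f_eq, bond, kBT) * fb
        expected = bond.f_eq + fb * (math.log(R) - EULER_GAMMA)
        assert mean_rupture_force(r, bond, kBT) == pytest.approx(expected, rel=1e-3)

    def test_monotone_and_asymptotically_linear_in_log_rate(self, bond, kBT):
        # <f>(ln r) rises from the r-linear regime toward the Bell
        # asymptote f_beta·(ln R − γ): curvature in ln r is positive and
        # decays to zero as the slope settles at f_beta
        r = np.geomspace(1.0, 1e6, 60)
        f = mean_rupture_force(r, bond, kBT)
        assert np.all(np.diff(f) > 0)
        d2 = np.diff(f, 2)
        assert np.all(d2 > 0)
        assert d2[-1] < 1e-3 * d2.max()  # curvature dies off at high rates
        dlnr = math.log(r[1] / r[0])
        assert np.diff(f)[-1] / dlnr == pytest.approx(bond.f_beta(kBT), rel=0.02)

    def test_tenfold_rate_increases_force(self, bond, kBT):
        for r in (10.0, 1e3, 1e5):
            assert mean_rupture_force(10 * r, bond, kBT) > mean_rupture_force(
                r, bond, kBT
            )


def spectrum_from_model(params, kBT, rates, sem=0.5):
    return [
        MeanForcePoint(
            mean_r=r,
            mean_f=float(mean_rupture_force(r, params, kBT)),
            sem_f=sem,
            n_events=100,
            velocity=float(i + 1),
        )
        for i, r in enumerate(rates)
    ]


class TestSpectrumFit:
    def test_noiseless_self_consistency(self, kBT):
        truth = BondParams(k_off=0.5, x_t=0.3, f_eq=20.0)
        pts = spectrum_from_model(truth, kBT, np.geomspace(10.0, 1e5, 8))
        fit = fit_single_bond_model(pts, kBT)
        assert fit.converged
        assert fit.params.f_eq == pytest.approx(truth.f_eq, rel=1e-3)
        assert fit.params.x_t == pytest.approx(truth.x_t, rel=1e-3)
        assert fit.params.k_off == pytest.approx(truth.k_off, rel=1e-3)

    def test_plateau_consistency(self, kBT):
        # near-equilibrium rates included: fitted f_eq stays within the
        # observed force range and near the low-rate plateau
        truth = BondParams(k_off=2.0, x_t=0.5, f_eq=15.0)
        pts = spectrum_from_model(truth, kBT, np.geomspace(0.01, 1e4, 10))
        fit = fit_single_bond_model(pts, kBT)
        forces = [p.mean_f for p in pts]
        assert min(forces) * 0.9 <= fit.params.f_eq <= min(forces) * 1.1

    def test_underdetermined_raises(self, kBT):
        truth = BondParams(k_off=0.5, x_t=0.3, f_eq=20.0)
        pts = spectrum_from_model(truth, kBT, [10.0, 100.0, 1000.0])
        with pytest.raises(FitError):
            fit_single_bond_model(pts, kBT)

    def test_narrow_span_warns(self, kBT):
        truth = BondParams(k_off=0.5, x_t=0.3, f_eq=20.0)
        pts = spectrum_from_model(truth, kBT, np.geomspace(100.0, 1000.0, 5))
        with pytest.warns(UserWarning, match="decades"):
            fit_single_bond_model(pts, kBT)

    def test_mc_ensemble_recovery_characterisation(self, kBT):
        """Fit to simulated ensembles: x_t recovers closely; k_off carries
        the known systematic from the loading rate varying along the
        tether (the constant-rate model sees an effective rate below the
        at-rupture rate), so it is only order-of-magnitude accurate."""
        truth = BondParams(k_off=0.5, x_t=0.3)
        cfg = SimConfig(
            bond=truth,
            velocities=tuple(float(v) for v in np.geomspace(100.0, 10000.0, 6)),
            n_events_per_velocity=300,
            seed=3,
        )
        events = run_simulation(cfg)
        pts, _ = build_spectrum(events)
        fit = fit_single_bond_model(pts, kBT)
        assert fit.converged
        assert fit.params.x_t == pytest.approx(truth.x_t, rel=0.15)
        assert truth.k_off / 4.0 < fit.params.k_off < truth.k_off * 4.0
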