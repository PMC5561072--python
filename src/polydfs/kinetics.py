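"""Bell unbinding kinetics and the single-bond mean-rupture-force model.

A slip bond loaded at rate r ruptures at a mean force

    <f>(r) ≈ f_eq + f_beta · e^{1/R} · E1(1/R),     R = r / (k_u(f_eq) · f_beta)

with the Bell rate k_u(f) = k_off · exp(f / f_beta), the thermal force
scale f_beta = k_B·T / x_t, and E1 the exponential integral.  At slow
loading (R → 0) the mean force plateaus at the equilibrium force f_eq;
at fast loading it grows as f_beta·(ln R − γ_Euler), the familiar
force-vs-log-rate kinetic regime.

The module provides the rate law, a numerically stable evaluation of
the kernel g(z) = e^z·E1(z) over the full range of loading rates, and a
weighted least-squares fit of (f_eq, x_t, k_off) to a mean-force
spectrum.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.optimize import least_squares

from .exceptions import DomainError, FitError, NumericalError, OverflowGuardError

#: Largest exponent passed to exp() before the overflow guard trips.
_EXP_GUARD = 700.0


@dataclass(frozen=True)
class BondParams:
    """Kinetic and thermodynamic parameters of a single bond.

    Parameters
    ----------
    k_off:
        Intrinsic (zero-force) unbinding rate in 1/s.
    x_t:
        Distance to the transition state in nm.
    f_eq:
        Equilibrium rupture force in pN (0 for a bond with no
        near-equilibrium plateau, e.g. the irreversible simulator).
    """

    k_off: float
    x_t: float
    f_eq: float = 0.0

    def __post_init__(self) -> None:
        if self.k_off <= 0:
            raise DomainError(f"k_off must be positive, got {self.k_off} 1/s")
        if self.x_t <= 0:
            raise DomainError(f"x_t must be positive, got {self.x_t} nm")
        if self.f_eq < 0:
            raise DomainError(f"f_eq must be non-negative, got {self.f_eq} pN")

    def f_beta(self, kBT: float) -> float:
        """Thermal force scale f_beta = kBT / x_t in pN."""
        return kBT / self.x_t


def bell_rate(f, params: BondParams, kBT: float):
    """Bell unbinding rate k_u(f) = k_off·exp(f/f_beta) in 1/s.

    Raises :class:`OverflowGuardError` when f/f_beta exceeds 700 rather
    than silently returning inf.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0):
        raise DomainError("force must be non-negative in bell_rate")
    z = f_arr / params.f_beta(kBT)
    if np.any(z > _EXP_GUARD):
        raise OverflowGuardError(
            f"f/f_beta = {float(np.max(z)):g} exceeds the overflow guard ({_EXP_GUARD:g})"
        )
    out = params.k_off * np.exp(z)
    return out if np.ndim(f) else float(out)


def exp1(z):
    """Exponential integral E1(z) = ∫_z^∞ e^{-s}/s ds for z > 0."""
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr <= 0):
        raise DomainError("exp1 requires z > 0")
    out = special.exp1(z_arr)
    return out if np.ndim(z) else float(out)


def _e1_scaled_cf(x, tol=1e-15, max_iter=300):
    """e^x·E1(x) via the modified Lentz continued fraction (large x)."""
    x = np.asarray(x, dtype=float)
    tiny = 1e-300
    b = x + 1.0
    C = np.full_like(b, 1.0 / tiny)
    D = 1.0 / b
    h = D.copy()
    for k in range(2, max_iter + 1):
        a = -float((k - 1) ** 2)
        b = x + (2.0 * k - 1.0)
        D = 1.0 / (b + a * D)
        C = b + a / C
        delta = C * D
        h *= delta
        if np.all(np.abs(delta - 1.0) < tol):
            return h
    raise NumericalError("continued fraction for e^x·E1(x) did not converge")


def exp_scaled_e1(z):
    """Numerically stable g(z) = e^z · E1(z) for z > 0.

    Direct product for z <= 30 (both factors representable), Lentz
    continued fraction beyond, where exp() overflows / E1 underflows.
    """
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    if np.any(z_arr <= 0):
        raise DomainError("exp_scaled_e1 requires z > 0")
    out = np.empty_like(z_arr)
    small = z_arr <= 30.0
    if np.any(small):
        out[small] = np.exp(z_arr[small]) * special.exp1(z_arr[small])
    if np.any(~small):
        out[~small] = _e1_scaled_cf(z_arr[~small])
    return out if np.ndim(z) else float(out[0])


def mean_rupture_force(r, params: BondParams, kBT: float):
    """Mean rupture force <f>(r) in pN at loading rate ``r`` (pN/s).

    Covers both regimes: <f> → f_eq as r → 0 and
    <f> → f_eq + f_beta·(ln R − γ_Euler) in the kinetic regime,
    R = r/(k_u(f_eq)·f_beta).
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise DomainError("loading rate must be positive")
    f_beta = params.f_beta(kBT)
    R = r_arr / (bell_rate(params.f_eq, params, kBT) * f_beta)
    out = params.f_eq + f_beta * exp_scaled_e1(1.0 / R)
    return out if np.ndim(r) else float(out)


@dataclass(frozen=True)
class MeanForcePoint:
    """One velocity group of the mean-force spectrum."""

    mean_r: float  # pN/s
    mean_f: float  # pN
    sem_f: float  # pN
    n_events: int
    velocity: float  # nm/s

    def __post_init__(self) -> None:
        if self.mean_r <= 0:
            raise DomainError(f"mean_r must be positive, got {self.mean_r}")
        if self.n_events < 1:
            raise DomainError(f"n_events must be >= 1, got {self.n_events}")
        if self.sem_f < 0:
            raise DomainError(f"sem_f must be >= 0, got {self.sem_f}")


@dataclass
class BondFitResult:
    """Result of fitting the single-bond model to a mean-force spectrum."""

    params: BondParams
    stderr: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    residual_norm: float = float("nan")
    n_points: int = 0
    converged: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "f_eq_pN": self.params.f_eq,
                "x_t_nm": self.params.x_t,
                "k_off_per_s": self.params.k_off,
                "ci95": self.ci95,
                "residual": self.residual_norm,
                "n_points": self.n_points,
                "converged": self.converged,
            }
        )


def _spectrum_model(r, f_eq, x_t, k_off, kBT):
    f_beta = kBT / x_t
    z = min(f_eq / f_beta, _EXP_GUARD)
    R = r / (k_off * math.exp(z) * f_beta)
    return f_eq + f_beta * exp_scaled_e1(1.0 / R)


def fit_single_bond_model(
    points,
    kBT: float,
    init: BondParams | None = None,
    n_bootstrap: int = 0,
    rng: np.random.Generator | None = None,
) -> BondFitResult:
    """Fit (f_eq, x_t, k_off) to mean rupture force vs mean loading rate.

    Weighted least squares with weights 1/sem_f² when every point
    carries a positive SEM, unweighted otherwise.  Multi-start
    initialisation: f_eq from the smallest mean force, x_t from the
    slope of force vs ln(rate) over the upper half of rates, and k_off
    over a log grid — the model is stiff in k_off and a single start is
    unreliable.

    Parameter uncertainties come from the Jacobian-based covariance at
    the optimum; with ``n_bootstrap > 0`` the 95% intervals are instead
    taken from a bootstrap over spectrum points.

    Raises :class:`FitError` with fewer than 4 points; warns when the
    rates span less than 1.5 decades.
    """
    points = list(points)
    n = len(points)
    if n < 4:
        raise FitError(f"need at least 4 spectrum points to fit 3 parameters, got {n}")
    r = np.array([p.mean_r for p in points], dtype=float)
    fbar = np.array([p.mean_f for p in points], dtype=float)
    sem = np.array([p.sem_f for p in points], dtype=float)
    span = math.log10(r.max() / r.min())
    if span < 1.5:
        warnings.warn(
            f"loading rates span only {span:.2f} decades (< 1.5); "
            "fitted parameters may be poorly constrained",
            stacklevel=2,
        )
    if np.all(sem > 0):
        w = 1.0 / sem
    else:
        w = np.ones_like(sem)

    f_max = float(fbar.max())
    f_min = float(fbar.min())

    # slope of f vs ln r over the upper half of rates -> x_t seed
    order = np.argsort(r)
    upper = order[n // 2:]
    x_t0 = 0.3
    if len(upper) >= 2:
        slope = np.polyfit(np.log(r[upper]), fbar[upper], 1)[0]
        if slope > 0:
            x_t0 = float(np.clip(kBT / slope, 1e-3, 100.0))

    # theta = (f_eq, log10 x_t, log10 k_off)
    lo = np.array([0.0, -3.0, -8.0])
    hi = np.array([f_max, 2.0, 4.0])

    def residuals(theta):
        f_eq, lx, lk = theta
        model = _spectrum_model(r, f_eq, 10.0 ** lx, 10.0 ** lk, kBT)
        return w * (model - fbar)

    starts = []
    if init is not None:
        starts.append((init.f_eq, math.log10(init.x_t), math.log10(init.k_off)))
    for f_eq0 in (0.9 * f_min, 0.3 * f_min, 0.0):
        for lk0 in (-3.0, -2.0, -1.0, 0.0, 1.0):
            starts.append((f_eq0, math.log10(x_t0), lk0))

    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lo, hi)
        try:
            res = least_squares(residuals, theta0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("single-bond model fit did not converge from any start")

    f_eq, lx, lk = best.x
    x_t = 10.0 ** lx
    k_off = 10.0 ** lk
    fitted = BondParams(k_off=k_off, x_t=x_t, f_eq=f_eq)

    stderr: dict = {}
    ci95: dict = {}
    dof = n - 3
    if dof > 0:
        s2 = 2.0 * best.cost / dof
        try:
            cov = s2 * np.linalg.pinv(best.jac.T @ best.jac)
            sd = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            ln10 = math.log(10.0)
            stderr = {
                "f_eq_pN": float(sd[0]),
                "x_t_nm": float(x_t * ln10 * sd[1]),
                "k_off_per_s": float(k_off * ln10 * sd[2]),
            }
            ci95 = {k: 1.96 * v for k, v in stderr.items()}
        except np.linalg.LinAlgError:  # pragma: no cover
            pass

    if n_bootstrap > 0:
        rng = rng or np.random.default_rng()
        samples = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(r[idx])) < 4:
                continue

            def boot_res(theta, idx=idx):
                f_eq_b, lx_b, lk_b = theta
                model = _spectrum_model(r[idx], f_eq_b, 10.0 ** lx_b, 10.0 ** lk_b, kBT)
                return w[idx] * (model - fbar[idx])

            try:
                res_b = least_squares(boot_res, best.x, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if res_b.success:
                samples.append(res_b.x)
        if len(samples) >= 10:
            arr = np.array(samples)
            half_width = {
                "f_eq_pN": arr[:, 0],
                "x_t_nm": 10.0 ** arr[:, 1],
                "k_off_per_s": 10.0 ** arr[:, 2],
            }
            ci95 = {
                k: float((np.percentile(v, 97.5) - np.percentile(v, 2.5)) / 2.0)
                for k, v in half_width.items()
            }

    return BondFitResult(
        params=fitted,
        stderr=stderr,
        ci95=ci95,
        residual_norm=float(math.sqrt(2.0 * best.cost)),
        n_points=n,
        converged=True,
    )
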