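"""Monte Carlo simulation of single-bond rupture under WLC loading.

A bond tethered through a worm-like chain is pulled at constant
retraction velocity v.  Time advances in steps of dt; at step i the
extension is x = v·t, the tether force f = f_WLC(x), and the rupture
probability over the step is

    P_u = k_u(f) · dt

with k_u the Bell rate.  A uniform variate xi on [0, 1) is drawn each
step and the bond ruptures when P_u > xi (first-order Euler thinning of
the inhomogeneous Poisson process).  A dt-robust variant
P_u = 1 − exp(−k_u·dt) is available behind ``robust_probability`` and
is off by default.

The default configuration mirrors the validation setup: four retraction
velocities (0.1, 0.21, 0.46, 1.0 μm/s), dt = 1 μs, and 300 rupture
events recorded per velocity.

The module also provides a first-passage oracle — deterministic
integration of the survival equation dS/dt = −k_u(f(t))·S — used to
validate the stochastic ensembles, and the exact mean of the discrete
per-step rule for dt-convergence checks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .exceptions import DomainError, ExtensionOverflowError, NumericalError
from .kinetics import BondParams, _EXP_GUARD
from .wlc import WLCParams, _force_raw, loading_rate, wlc_extension, wlc_stiffness

#: Fraction of the contour length at which the simulation aborts.
_X_MAX_FRACTION = 0.9999

#: Per-event chunk of uniform draws scanned at a time.
_CHUNK = 1 << 16


@dataclass(frozen=True)
class RuptureEvent:
    """One terminal rupture event.

    ``l_app`` and ``L`` are the tether parameters — known exactly for
    simulated events, fitted for experimental ones.
    """

    f_r: float  # pN
    r: float  # pN/s, loading rate at rupture
    t_r: float  # s
    velocity: float  # nm/s
    l_app: float  # nm
    L: float  # nm

    def __post_init__(self) -> None:
        if self.f_r < 0:
            raise DomainError(f"f_r must be non-negative, got {self.f_r}")
        if self.r <= 0:
            raise DomainError(f"loading rate must be positive, got {self.r}")
        if self.t_r <= 0:
            raise DomainError(f"t_r must be positive, got {self.t_r}")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a rupture-ensemble simulation.

    Defaults reproduce the standard validation setup: velocities
    (0.1, 0.21, 0.46, 1.0) μm/s, dt = 1 μs, 300 events per velocity.
    ``bond.f_eq`` is ignored: the simulator is irreversible (no
    rebinding), so simulated spectra have no equilibrium plateau.
    """

    wlc: WLCParams = field(default_factory=lambda: WLCParams(l_app=0.4, L=150.0))
    bond: BondParams = field(default_factory=lambda: BondParams(k_off=0.5, x_t=0.3))
    velocities: tuple = (100.0, 210.0, 460.0, 1000.0)  # nm/s
    dt: float = 1e-6  # s
    n_events_per_velocity: int = 300
    seed: int = 0
    robust_probability: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise DomainError(f"dt must be positive, got {self.dt} s")
        if any(v <= 0 for v in self.velocities):
            raise DomainError("all velocities must be positive")
        if self.n_events_per_velocity < 1:
            raise DomainError("n_events_per_velocity must be >= 1")


def _step_probabilities(velocity, wlc, bond, dt, robust_probability):
    """Per-step rupture probabilities along the retraction trajectory.

    Step i (1-based) has t = i·dt, x = v·t; the table ends just before
    x reaches 0.9999·L.
    """
    n_max = int(_X_MAX_FRACTION * wlc.L / (velocity * dt))
    if n_max < 1:
        raise DomainError("dt too large: tether fully extends within one step")
    if n_max > 200_000_000:
        raise NumericalError(
            f"trajectory table of {n_max} steps is too large; increase dt"
        )
    kBT = wlc.kBT
    f_beta = bond.f_beta(kBT)
    x = velocity * dt * np.arange(1, n_max + 1)
    f = _force_raw(x, wlc.l_app, wlc.L, kBT)
    hazard = bond.k_off * np.exp(np.minimum(f / f_beta, _EXP_GUARD))
    if robust_probability:
        p = -np.expm1(-hazard * dt)
    else:
        p = hazard * dt
    return f, p


def simulate_rupture(
    velocity: float,
    wlc: WLCParams,
    bond: BondParams,
    dt: float,
    rng: np.random.Generator,
    robust_probability: bool = False,
    _table=None,
) -> RuptureEvent:
    """Simulate one pull to rupture; returns the terminal event.

    The per-step uniforms are drawn from ``rng`` in chunks and compared
    against the precomputed probability table; the first step with
    P_u > xi is the rupture step.  Raises
    :class:`ExtensionOverflowError` if the tether reaches 0.9999·L
    without rupturing, and warns when the per-step probability at the
    rupture step exceeds 0.1 (dt too coarse for the sampled forces).
    """
    if _table is None:
        _table = _step_probabilities(velocity, wlc, bond, dt, robust_probability)
    f, p = _table
    n_max = len(p)
    pos = 0
    step = -1
    while pos < n_max:
        m = min(_CHUNK, n_max - pos)
        xi = rng.random(m)
        hit = p[pos:pos + m] > xi
        idx = int(np.argmax(hit))
        if hit[idx]:
            step = pos + idx
            break
        pos += m
    if step < 0:
        raise ExtensionOverflowError(
            f"no rupture before x = {_X_MAX_FRACTION}·L at v = {velocity} nm/s; "
            "bond parameters are inconsistent with the tether length"
        )
    if p[step] > 0.1:
        warnings.warn(
            f"per-step rupture probability {p[step]:.3g} > 0.1 at rupture; "
            "decrease dt for accurate statistics",
            stacklevel=2,
        )
    f_r = float(f[step])
    t_r = dt * (step + 1)
    r = loading_rate(f_r, velocity, wlc)
    return RuptureEvent(
        f_r=f_r, r=r, t_r=t_r, velocity=velocity, l_app=wlc.l_app, L=wlc.L
    )


def run_simulation(config: SimConfig) -> list[RuptureEvent]:
    """Run the full ensemble: n events per velocity, reproducible by seed.

    Each velocity uses an independent spawned RNG substream, so adding
    a velocity to the list does not perturb the events of the others.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(config.velocities))
    events: list[RuptureEvent] = []
    for velocity, stream in zip(config.velocities, streams):
        rng = np.random.default_rng(stream)
        table = _step_probabilities(
            velocity, config.wlc, config.bond, config.dt, config.robust_probability
        )
        for _ in range(config.n_events_per_velocity):
            try:
                events.append(
                    simulate_rupture(
                        velocity,
                        config.wlc,
                        config.bond,
                        config.dt,
                        rng,
                        config.robust_probability,
                        _table=table,
                    )
                )
            except ExtensionOverflowError as exc:
                raise ExtensionOverflowError(
                    f"at velocity {velocity} nm/s: {exc}"
                ) from exc
    return events


def ensemble_mean_rupture_force(
    velocity: float,
    wlc: WLCParams,
    bond: BondParams,
    dt: float,
    robust_probability: bool = False,
) -> float:
    """Exact mean rupture force of the discrete per-step rule (no sampling).

    The rupture step follows P(step = i) = P_i · Π_{j<i}(1 − P_j); the
    mean force is computed deterministically from the probability
    table.  Useful for dt-convergence checks free of Monte Carlo noise.
    """
    f, p = _step_probabilities(velocity, wlc, bond, dt, robust_probability)
    p = np.clip(p, 0.0, 1.0)
    log_s = np.concatenate(([0.0], np.cumsum(np.log1p(-np.minimum(p[:-1], 1 - 1e-16)))))
    w = p * np.exp(log_s)
    total = w.sum()
    if total <= 0:
        raise NumericalError("degenerate rupture distribution")
    return float((f * w).sum() / total)


@dataclass(frozen=True)
class RuptureForceDistribution:
    """First-passage rupture-force density along a WLC pull."""

    f: np.ndarray  # pN grid
    pdf: np.ndarray  # 1/pN
    cdf: np.ndarray

    def cdf_at(self, values):
        """CDF interpolated at arbitrary forces (0/1 outside the grid)."""
        return np.interp(values, self.f, self.cdf, left=0.0, right=1.0)

    @property
    def mean(self) -> float:
        return float(np.trapezoid(self.f * self.pdf, self.f) / np.trapezoid(self.pdf, self.f))


def rupture_force_distribution_oracle(
    velocity: float,
    wlc: WLCParams,
    bond: BondParams,
    f_grid,
) -> RuptureForceDistribution:
    """Analytic-numerical rupture-force density (first-passage oracle).

    Integrates the survival equation dS/dt = −k_u(f(t))·S along the
    deterministic WLC trajectory, changing variables to force:
    S(f) = exp(−∫_0^f k_u(f')/(v·κ(f')) df') with κ the tether
    stiffness, so pdf(f) = k_u(f)·S(f)/(v·κ(f)).  Warns when the grid
    misses more than 1e-3 of the probability mass.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    if f_grid.ndim != 1 or len(f_grid) < 8 or np.any(np.diff(f_grid) <= 0):
        raise DomainError("f_grid must be an increasing 1-D array with >= 8 points")
    if f_grid[0] < 0:
        raise DomainError("f_grid must be non-negative")
    kBT = wlc.kBT
    f_beta = bond.f_beta(kBT)

    # extend the grid down to f = 0 so no hazard below f_grid[0] is missed
    if f_grid[0] > 0:
        head = np.linspace(0.0, f_grid[0], 65)[:-1]
        full = np.concatenate([head, f_grid])
    else:
        full = f_grid

    x = wlc_extension(full, wlc)
    kappa = wlc_stiffness(x, wlc)
    hazard = bond.k_off * np.exp(np.minimum(full / f_beta, _EXP_GUARD))
    integrand = hazard / (velocity * kappa)
    Lam = cumulative_trapezoid(integrand, full, initial=0.0)
    S = np.exp(-Lam)
    pdf_full = integrand * S
    cdf_full = 1.0 - S

    keep = slice(len(full) - len(f_grid), None)
    pdf = pdf_full[keep]
    cdf = cdf_full[keep]
    covered = cdf[-1] - cdf[0]
    if 1.0 - covered > 1e-3:
        warnings.warn(
            f"f_grid covers only {covered:.4f} of the rupture probability mass",
            stacklevel=2,
        )
    return RuptureForceDistribution(f=f_grid, pdf=pdf, cdf=cdf)
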