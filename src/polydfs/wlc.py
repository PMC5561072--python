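"""Worm-like chain (WLC) force–extension mechanics.

The WLC interpolation formula relates the entropic restoring force of a
semiflexible polymer to its end-to-end extension::

    f(x) = (k_B T / l_app) * [ x/L + 1/(4 (1 - x/L)^2) - 1/4 ]

where ``l_app`` is the apparent persistence length of the loaded tether
(``l_app = l_p / N`` for N identical chains sharing the load), ``L`` the
contour length and ``x`` the tip–surface separation.  The module also
provides the analytic stiffness df/dx, the numerical inversion x(f), and
the loading rate r = v * df/dx experienced by a bond pulled through the
tether at constant retraction velocity v.

Units are fixed package-wide: pN, nm, s, pN·nm (energy), K.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .exceptions import DomainError, NumericalError

#: Boltzmann constant in pN·nm/K (exact, CODATA).
BOLTZMANN_PN_NM = 0.01380649

#: Default bath temperature (20 °C) used when metadata omits it.
DEFAULT_TEMPERATURE_K = 293.15


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy k_B·T in pN·nm at the given temperature in kelvin."""
    if temperature <= 0:
        raise DomainError(f"temperature must be positive, got {temperature} K")
    return BOLTZMANN_PN_NM * temperature


@dataclass(frozen=True)
class WLCParams:
    """Polymer-mechanics parameters of one loaded tether.

    Parameters
    ----------
    l_app:
        Apparent persistence length in nm.  For a single chain this is
        the persistence length l_p; for N equal chains loaded in
        parallel it is l_p / N.
    L:
        Contour length in nm.
    temperature:
        Bath temperature in kelvin (default 20 °C).
    """

    l_app: float
    L: float
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.l_app <= 0:
            raise DomainError(f"l_app must be positive, got {self.l_app} nm")
        if self.L <= 0:
            raise DomainError(f"L must be positive, got {self.L} nm")
        if self.temperature <= 0:
            raise DomainError(
                f"temperature must be positive, got {self.temperature} K"
            )

    @property
    def kBT(self) -> float:
        """Thermal energy in pN·nm."""
        return thermal_energy(self.temperature)


def _marko_siggia(u):
    """Dimensionless WLC force f·l_app/kBT as a function of u = x/L."""
    return u + 0.25 / (1.0 - u) ** 2 - 0.25


def _force_raw(x, l_app, L, kBT, u_max=1.0 - 1e-12):
    """WLC force without domain checks; clips x/L just below 1.

    Used internally by fitting and simulation code where the optimiser
    or a recorded sample may graze the x -> L singularity.
    """
    u = np.minimum(np.asarray(x, dtype=float) / L, u_max)
    return (kBT / l_app) * _marko_siggia(u)


def wlc_force(x, params: WLCParams):
    """Tether force in pN at extension ``x`` (nm).

    Accepts a scalar or array extension; valid for 0 <= x < L and
    strictly increasing in x, diverging as x -> L.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or np.any(x_arr >= params.L):
        bad = x_arr[(x_arr < 0) | (x_arr >= params.L)]
        raise DomainError(
            f"extension {np.atleast_1d(bad)[0]:g} nm outside [0, L={params.L:g} nm)"
        )
    out = (params.kBT / params.l_app) * _marko_siggia(x_arr / params.L)
    return out if np.ndim(x) else float(out)


def wlc_stiffness(x, params: WLCParams):
    """Analytic tether stiffness df/dx in pN/nm at extension ``x`` (nm)."""
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or np.any(x_arr >= params.L):
        bad = x_arr[(x_arr < 0) | (x_arr >= params.L)]
        raise DomainError(
            f"extension {np.atleast_1d(bad)[0]:g} nm outside [0, L={params.L:g} nm)"
        )
    u = x_arr / params.L
    out = (params.kBT / params.l_app) * (
        1.0 / params.L + 0.5 / (params.L * (1.0 - u) ** 3)
    )
    return out if np.ndim(x) else float(out)


def wlc_extension(f, params: WLCParams):
    """Invert the force–extension relation: extension x(f) in nm.

    Bisection-based root bracketing (Brent) on [0, (1-1e-12)·L] with
    absolute tolerance 1e-10·L; guaranteed to converge because the
    force is strictly monotone on the bracket.
    """
    def _invert(fi: float) -> float:
        if fi < 0:
            raise DomainError(f"force must be non-negative, got {fi} pN")
        if fi == 0.0:
            return 0.0
        hi = (1.0 - 1e-12) * params.L
        f_hi = _force_raw(hi, params.l_app, params.L, params.kBT)
        if fi >= f_hi:
            raise NumericalError(
                f"force {fi:g} pN unreachable below full extension for {params}"
            )
        try:
            return brentq(
                lambda xx: _force_raw(xx, params.l_app, params.L, params.kBT) - fi,
                0.0,
                hi,
                xtol=1e-10 * params.L,
                rtol=8.9e-16,
            )
        except RuntimeError as exc:  # pragma: no cover - brentq is robust here
            raise NumericalError(
                f"WLC inversion did not converge for f={fi:g} pN, {params}"
            ) from exc

    if np.ndim(f) == 0:
        return _invert(float(f))
    return np.array([_invert(float(fi)) for fi in np.asarray(f, dtype=float)])


def loading_rate(f, velocity: float, params: WLCParams):
    """Loading rate r = dF/dt in pN/s at force ``f`` for retraction velocity ``velocity``.

    For a constant-velocity pull through a WLC tether the loading rate
    is the tether stiffness at the current force times the velocity:
    r(f) = v · k(x(f)).  At fixed velocity this is a single curve in
    (f, r) independent of any bond parameters.
    """
    if velocity <= 0:
        raise DomainError(f"velocity must be positive, got {velocity} nm/s")
    x = wlc_extension(f, params)
    return velocity * wlc_stiffness(x, params)


def estimate_n(l_app: float, l_p: float) -> float:
    """Number of chains sharing the load, N = l_p / l_app.

    Returned as a real number; values below 1 indicate a fitted
    apparent persistence length stiffer than a single chain and are
    left to the filtering stage to interpret.
    """
    if l_app <= 0:
        raise DomainError(f"l_app must be positive, got {l_app} nm")
    if l_p <= 0:
        raise DomainError(f"l_p must be positive, got {l_p} nm")
    return l_p / l_app
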