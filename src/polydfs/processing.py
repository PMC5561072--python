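"""From raw force curves to the velocity-averaged mean-force spectrum.

The single-bond protocol: detect the last rupture of each retraction
curve, fit the preceding force-extension segment to the WLC model to
obtain the apparent persistence length l_app and contour length L,
keep only events whose l_app is near the single-polymer persistence
length (single-molecule selection, since l_app = l_p/N for N chains
loaded in parallel), measure the loading rate r = dF/dt just before
rupture, group events by retraction velocity, and average (r, f_r)
within each group to one spectrum point per velocity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    AllEventsFilteredError,
    DomainError,
    EmptySpectrumError,
    EventFlaggedError,
    NumericalError,
    WindowError,
)
from .kinetics import MeanForcePoint
from .montecarlo import RuptureEvent
from .wlc import DEFAULT_TEMPERATURE_K, WLCParams, _force_raw, loading_rate, thermal_energy


@dataclass
class ForceCurve:
    """One retraction trajectory with its acquisition metadata."""

    t: np.ndarray  # s, strictly increasing
    x: np.ndarray  # nm, tip-surface separation, non-decreasing
    f: np.ndarray  # pN, adhesion force positive after baseline correction
    velocity: float  # nm/s
    temperature: float = DEFAULT_TEMPERATURE_K
    curve_id: str | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.f) == n):
            raise DomainError("t, x, f must have equal length")
        if n < 16:
            raise DomainError(f"curve needs >= 16 samples, got {n}")
        if np.any(np.diff(self.t) <= 0):
            raise DomainError("time must be strictly increasing")
        tol = 1e-9 * max(1.0, float(np.ptp(self.x)))
        if np.any(np.diff(self.x) < -tol):
            raise DomainError("separation must be non-decreasing on retraction")
        if self.velocity <= 0:
            raise DomainError(f"velocity must be positive, got {self.velocity}")


@dataclass(frozen=True)
class RuptureDetection:
    """Outcome of last-rupture detection on one curve."""

    ok: bool
    index: int | None
    f_r: float | None
    noise_sigma: float
    baseline: float
    reason: str | None = None


def _tail_stats(f: np.ndarray):
    """Baseline offset and robust noise scale from the post-rupture tail."""
    n = len(f)
    n_tail = max(8, n // 10)
    tail = f[-n_tail:]
    baseline = float(np.median(tail))
    mad = float(np.median(np.abs(tail - baseline)))
    sigma = 1.4826 * mad
    return baseline, sigma, n_tail


def _drop_candidates(fc: np.ndarray, sigma: float) -> np.ndarray:
    """Indices of sustained force drops >= 5*sigma within <= 3 samples.

    Beyond the bare drop criterion, a candidate must start from a force
    at least 5*sigma above baseline (for a terminal rupture the drop
    magnitude is the rupture force, so this rejects only noise) and the
    median of the 5 following samples must stay 4*sigma below the
    pre-drop force — together these keep the per-curve false-positive
    rate of the pair-difference test negligible in noisy baselines.
    """
    n = len(fc)
    drop = np.full(n, -np.inf)
    for k in (1, 2, 3):
        d = fc[:-k] - fc[k:]
        drop[: n - k] = np.maximum(drop[: n - k], d)
    cand = np.zeros(n, dtype=bool)
    limit = n - 6
    idx = np.nonzero(drop[:limit] >= 5.0 * sigma)[0]
    for i in idx:
        if fc[i] < 5.0 * sigma:
            continue
        if np.median(fc[i + 1 : i + 6]) <= fc[i] - 4.0 * sigma:
            cand[i] = True
    return np.nonzero(cand)[0]


def detect_last_rupture(
    curve: ForceCurve, noise_sigma: float | None = None
) -> RuptureDetection:
    """Locate the final rupture of a retraction curve.

    The baseline is the median of the final 10% of samples (assumed
    post-rupture); the noise scale is 1.4826·MAD of that tail unless
    ``noise_sigma`` is given.  Returns a non-ok detection (reason
    ``"no_rupture"`` or ``"unstable_baseline"``) instead of raising, so
    batch processing can count rejections.
    """
    f = curve.f
    baseline, sigma_auto, n_tail = _tail_stats(f)
    sigma = noise_sigma if noise_sigma is not None else sigma_auto
    sigma = max(sigma, 1e-9 * max(1.0, float(np.ptp(f))))
    fc = f - baseline

    tail = fc[-n_tail:]
    if np.mean(np.abs(tail) > 5.0 * sigma) > 0.2:
        return RuptureDetection(False, None, None, sigma, baseline, "unstable_baseline")

    cand = _drop_candidates(fc, sigma)
    if len(cand) == 0:
        return RuptureDetection(False, None, None, sigma, baseline, "no_rupture")
    i = int(cand[-1])
    return RuptureDetection(True, i, float(fc[i]), sigma, baseline, None)


@dataclass(frozen=True)
class WLCFit:
    """Result of fitting the WLC model to a last-event segment."""

    l_app: float  # nm
    L: float  # nm
    residual_rms: float  # pN
    window: tuple  # (start, stop) sample indices, stop exclusive
    converged: bool


def _fit_window(fc: np.ndarray, rupture_index: int, sigma: float) -> int:
    """Start index of the last-event segment: after the previous rupture
    or at the force onset, whichever is later."""
    start_prev = 0
    prev = _drop_candidates(fc[:rupture_index], sigma)
    prev = prev[prev < rupture_index - 3]
    if len(prev) > 0:
        start_prev = int(prev[-1]) + 4
    onset = start_prev
    below = np.nonzero(fc[start_prev : rupture_index + 1] <= 3.0 * sigma)[0]
    if len(below) > 0:
        onset = start_prev + int(below[-1])
    return max(start_prev, onset)


def fit_last_event_wlc(
    curve: ForceCurve,
    rupture_index: int,
    detection: RuptureDetection | None = None,
) -> WLCFit:
    """Fit the WLC model to the segment ending at ``rupture_index``.

    Free parameters (l_app, L) with bounds l_app in [0.01, 100] nm and
    L in (x_max, 1e4·x_max]; multi-start over L seeds.  Returns
    ``converged=False`` rather than raising on poor fits; raises
    :class:`WindowError` only when the segment holds fewer than 8
    samples.
    """
    if detection is None:
        detection = detect_last_rupture(curve)
        if not detection.ok:
            raise WindowError(f"no usable rupture detection: {detection.reason}")
    sigma = detection.noise_sigma
    fc = curve.f - detection.baseline
    start = _fit_window(fc, rupture_index, sigma)
    stop = rupture_index + 1
    if stop - start < 8:
        raise WindowError(
            f"fit window [{start}, {stop}) holds {stop - start} samples (< 8)"
        )
    xw = curve.x[start:stop]
    fw = fc[start:stop]
    kBT = thermal_energy(curve.temperature)
    x_max = float(xw.max())
    if x_max <= 0:
        raise WindowError("fit window has no positive extension")
    f_end = max(float(np.median(fw[-3:])), 1e-3)

    lo = np.array([0.01, x_max * (1.0 + 1e-7)])
    hi = np.array([100.0, 1e4 * x_max])

    def residuals(theta):
        l_app, L = theta
        return _force_raw(xw, l_app, L, kBT) - fw

    best = None
    for scale in (1.05, 1.2, 1.5, 3.0):
        L0 = scale * x_max
        phi = x_max / L0 + 0.25 / (1.0 - x_max / L0) ** 2 - 0.25
        l_app0 = float(np.clip(kBT * phi / f_end, 0.011, 99.0))
        theta0 = np.clip([l_app0, L0], lo, hi)
        try:
            res = least_squares(residuals, theta0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return WLCFit(np.nan, np.nan, np.nan, (start, stop), False)
    l_app, L = best.x
    rms = float(np.sqrt(2.0 * best.cost / (stop - start)))
    converged = bool(np.isfinite(best.cost)) and L > x_max
    return WLCFit(float(l_app), float(L), rms, (start, stop), converged)


def numerical_loading_rate(
    curve: ForceCurve,
    rupture_index: int,
    window_fraction: float = 0.1,
    min_samples: int = 8,
) -> float:
    """Loading rate dF/dt (pN/s) from the force-time trace before rupture.

    Slope of a linear fit over the final pre-rupture window (last 10%
    of pre-rupture samples, at least 8).  Raises
    :class:`EventFlaggedError` for non-positive slopes and
    :class:`WindowError` when fewer than ``min_samples`` samples
    precede the rupture.
    """
    n_pre = rupture_index + 1
    if n_pre < min_samples:
        raise WindowError(f"only {n_pre} samples before rupture (< {min_samples})")
    w = max(min_samples, int(round(window_fraction * n_pre)))
    sl = slice(rupture_index + 1 - w, rupture_index + 1)
    tw, fw = curve.t[sl], curve.f[sl]
    slope = float(np.polyfit(tw, fw, 1)[0])
    # floor guards against a numerically-zero slope on flat segments
    floor = 1e-9 * (float(np.ptp(fw)) + 1.0) / (tw[-1] - tw[0])
    if slope <= floor:
        raise EventFlaggedError(
            f"non-positive loading rate ({slope:g} pN/s) before rupture"
        )
    return slope


@dataclass(frozen=True)
class FilterConfig:
    """Single-molecule selection by apparent persistence length.

    Events are kept when threshold_fraction·l_p <= l_app <=
    max_fraction·l_p.  The lower cut rejects multi-chain clusters
    (l_app = l_p/N); the upper cut rejects nonphysically steep fits.
    """

    l_p: float  # nm, single-polymer persistence length
    threshold_fraction: float = 0.7
    max_fraction: float = 2.0

    def __post_init__(self) -> None:
        if self.l_p <= 0:
            raise DomainError(f"l_p must be positive, got {self.l_p} nm")
        if not (0.0 < self.threshold_fraction <= 1.0 <= self.max_fraction):
            raise DomainError(
                "require 0 < threshold_fraction <= 1 <= max_fraction, got "
                f"{self.threshold_fraction}, {self.max_fraction}"
            )


def filter_events(events, cfg: FilterConfig):
    """Keep events whose fitted l_app is consistent with a single chain.

    Returns ``(kept_events, report)`` where the report counts events in
    and out and histograms the implied chain count N = l_p/l_app
    (rounded to the nearest integer).  Raises
    :class:`AllEventsFilteredError` when nothing survives.
    """
    events = list(events)
    lo = cfg.threshold_fraction * cfg.l_p
    hi = cfg.max_fraction * cfg.l_p
    kept, n_below, n_above = [], 0, 0
    n_hist: dict[int, int] = {}
    for ev in events:
        n_implied = int(round(cfg.l_p / ev.l_app)) if ev.l_app > 0 else -1
        n_hist[n_implied] = n_hist.get(n_implied, 0) + 1
        if ev.l_app < lo:
            n_below += 1
        elif ev.l_app > hi:
            n_above += 1
        else:
            kept.append(ev)
    report = {
        "n_in": len(events),
        "n_kept": len(kept),
        "n_below_threshold": n_below,
        "n_above_max": n_above,
        "implied_N_histogram": dict(sorted(n_hist.items())),
    }
    if events and not kept:
        raise AllEventsFilteredError(
            "all events removed by the l_app filter; review threshold_fraction "
            f"({cfg.threshold_fraction}) and l_p ({cfg.l_p} nm)"
        )
    return kept, report


def build_spectrum(events):
    """Average (r, f_r) within each velocity group.

    Returns ``(points, report)``: one :class:`MeanForcePoint` per
    velocity (arithmetic means, SEM of f_r), sorted by mean loading
    rate; the report flags velocities with fewer than 5 events.
    """
    events = list(events)
    if not events:
        raise EmptySpectrumError("no events to build a spectrum from")
    groups: dict[float, list] = {}
    for ev in events:
        groups.setdefault(ev.velocity, []).append(ev)
    points = []
    sparse = []
    for velocity, evs in groups.items():
        f_r = np.array([e.f_r for e in evs])
        r = np.array([e.r for e in evs])
        n = len(evs)
        sem = float(np.std(f_r, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        points.append(
            MeanForcePoint(
                mean_r=float(r.mean()),
                mean_f=float(f_r.mean()),
                sem_f=sem,
                n_events=n,
                velocity=velocity,
            )
        )
        if n < 5:
            sparse.append(velocity)
    points.sort(key=lambda p: p.mean_r)
    report = {
        "n_velocities": len(points),
        "sparse_velocities": sorted(sparse),
    }
    return points, report


@dataclass
class ExtractionResult:
    """Per-curve pipeline output: events with fits, plus QC counts."""

    events: list  # RuptureEvent, l_app/L from the WLC fit
    fits: list  # WLCFit, parallel to events
    qc: dict = field(default_factory=dict)


def extract_events(
    curves,
    noise_sigma: float | None = None,
    rate_method: str = "numerical",
) -> ExtractionResult:
    """Run detection, WLC fitting and loading-rate measurement per curve.

    ``rate_method`` is ``"numerical"`` (slope of f(t), the protocol's
    definition) or ``"analytic"`` (WLC stiffness at the rupture force
    using the fitted tether, exact for simulated curves).  Curves
    failing any stage are counted in the QC report, not raised.
    """
    if rate_method not in ("numerical", "analytic"):
        raise DomainError(f"unknown rate_method {rate_method!r}")
    events: list[RuptureEvent] = []
    fits: list[WLCFit] = []
    reasons: dict[str, int] = {}

    def _count(reason: str) -> None:
        reasons[reason] = reasons.get(reason, 0) + 1

    n_curves = n_ruptures = n_converged = 0
    for curve in curves:
        n_curves += 1
        det = detect_last_rupture(curve, noise_sigma)
        if not det.ok:
            _count(det.reason or "detection_failed")
            continue
        n_ruptures += 1
        try:
            fit = fit_last_event_wlc(curve, det.index, detection=det)
        except WindowError:
            _count("window_too_short")
            continue
        if not fit.converged:
            _count("wlc_fit_not_converged")
            continue
        n_converged += 1
        try:
            if rate_method == "numerical":
                r = numerical_loading_rate(curve, det.index)
            else:
                wlc = WLCParams(fit.l_app, fit.L, curve.temperature)
                r = loading_rate(det.f_r, curve.velocity, wlc)
        except (EventFlaggedError, WindowError, NumericalError):
            _count("loading_rate_rejected")
            continue
        events.append(
            RuptureEvent(
                f_r=det.f_r,
                r=r,
                t_r=float(curve.t[det.index]),
                velocity=curve.velocity,
                l_app=fit.l_app,
                L=fit.L,
            )
        )
        fits.append(fit)
    qc = {
        "n_curves": n_curves,
        "n_ruptures": n_ruptures,
        "n_converged_fits": n_converged,
        "n_events": len(events),
        "reasons": reasons,
    }
    return ExtractionResult(events=events, fits=fits, qc=qc)
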