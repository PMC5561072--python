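"""Ground-truthed synthetic force-curve generator.

Emulates a polymer-tethered retraction experiment: each curve carries N
chains attached in parallel (N drawn from a configurable distribution),
each chain an independent WLC with its own contour length, rupturing
stochastically under the Bell hazard as the tip retracts at constant
velocity.  Gaussian force noise and a linear baseline drift are added.
Every curve comes with a truth record (per-chain rupture times and
forces, segment-wise apparent persistence lengths, the last-event
index), so each pipeline stage can be validated without real AFM data.

Chain rupture times are sampled by inverting the continuous cumulative
Bell hazard along the retraction (the small-time-step limit of per-step
thinning), which keeps slow pulls exact without micro-second stepping.
Curves are recorded at the configured sample rate, decimated so no
curve exceeds ``max_samples`` points — mimicking an instrument's fixed
points-per-curve rather than a fixed clock.

The default acquisition schedule emulates the standard protocol:
seven retraction speeds spanning 5 nm/s to 10 μm/s, changed every five
curves, with 100 curves per speed (at least 700 curves per dataset).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .exceptions import DomainError
from .io import write_force_curve
from .kinetics import BondParams, _EXP_GUARD
from .processing import ForceCurve
from .wlc import DEFAULT_TEMPERATURE_K, _force_raw, thermal_energy

#: Default seven-speed protocol, nm/s (log-spaced 5 nm/s .. 10 um/s).
DEFAULT_VELOCITIES = tuple(float(v) for v in np.geomspace(5.0, 1.0e4, 7))

#: Fraction of the contour length where a surviving chain is forcibly released.
_X_TRUNC = 0.999


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of a synthetic dataset.

    ``n_polymers_distribution`` maps chain count N to probability;
    ``L_distribution`` is ``("constant", value)``,
    ``("uniform", lo, hi)`` or ``("lognormal", median, sigma_ln)`` in
    nm.  Defaults: mostly single-chain contacts with occasional
    clusters, lognormal contour lengths around 150 nm, 5 pN white
    noise, 10 kHz sampling capped at 4096 points per curve, 2 pN linear
    baseline drift.
    """

    velocities: tuple = DEFAULT_VELOCITIES  # nm/s
    curves_per_velocity: int = 100
    n_polymers_distribution: dict = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.15, 4: 0.04, 5: 0.01}
    )
    l_p: float = 0.4  # nm, single-chain persistence length
    L_distribution: tuple = ("lognormal", 150.0, 0.3)
    bond: BondParams = field(default_factory=lambda: BondParams(k_off=0.5, x_t=0.3))
    noise_sigma: float = 5.0  # pN
    sample_rate: float = 1.0e4  # Hz
    max_samples: int = 4096
    baseline_drift: float = 2.0  # pN over the curve
    temperature: float = DEFAULT_TEMPERATURE_K
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.velocities):
            raise DomainError("all velocities must be positive")
        if self.curves_per_velocity < 1:
            raise DomainError("curves_per_velocity must be >= 1")
        if self.l_p <= 0 or self.sample_rate <= 0 or self.noise_sigma < 0:
            raise DomainError("l_p, sample_rate must be positive; noise_sigma >= 0")
        total = sum(self.n_polymers_distribution.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise DomainError(f"N probabilities must sum to 1, got {total}")
        if any(p < 0 for p in self.n_polymers_distribution.values()):
            raise DomainError("N probabilities must be non-negative")
        if any(n < 1 for n in self.n_polymers_distribution):
            raise DomainError("chain counts must be >= 1")


def _sample_contour_length(dist: tuple, rng: np.random.Generator) -> float:
    kind = dist[0]
    if kind == "constant":
        return float(dist[1])
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    if kind == "lognormal":
        median, sigma = dist[1], dist[2]
        return float(median * math.exp(sigma * rng.standard_normal()))
    raise DomainError(f"unknown L_distribution kind {kind!r}")


def _chain_rupture_time(velocity, L, l_p, bond, kBT, rng, grid=2048):
    """Rupture time of one chain by inverse cumulative-hazard sampling."""
    t_end = _X_TRUNC * L / velocity
    t = np.linspace(0.0, t_end, grid)
    f = _force_raw(velocity * t, l_p, L, kBT)
    hazard = bond.k_off * np.exp(np.minimum(f / bond.f_beta(kBT), _EXP_GUARD))
    Lam = cumulative_trapezoid(hazard, t, initial=0.0)
    target = -math.log(max(rng.random(), 1e-300))
    if target >= Lam[-1]:
        return t_end, True  # forced release at near-full extension
    return float(np.interp(target, Lam, t)), False


def generate_curve(velocity: float, cfg: GeneratorConfig, rng: np.random.Generator):
    """Generate one retraction curve and its ground-truth record.

    Returns ``(curve, truth)``.  The truth dict carries N, per-chain
    (L, rupture time/force), segment-wise apparent persistence lengths
    (l_p/k while k equal-length chains survive, None for mixed
    lengths), the last-event sample index, and the pre-rupture total
    force at that sample.
    """
    if velocity <= 0:
        raise DomainError(f"velocity must be positive, got {velocity}")
    kBT = thermal_energy(cfg.temperature)
    ns = sorted(cfg.n_polymers_distribution)
    probs = [cfg.n_polymers_distribution[n] for n in ns]
    N = int(rng.choice(ns, p=probs))
    chains = []
    for _ in range(N):
        L = _sample_contour_length(cfg.L_distribution, rng)
        t_rup, truncated = _chain_rupture_time(
            velocity, L, cfg.l_p, cfg.bond, kBT, rng
        )
        chains.append({"L_nm": L, "t_rupture_s": t_rup, "truncated": truncated})
    for c in chains:
        c["f_rupture_pN"] = float(
            _force_raw(velocity * c["t_rupture_s"], cfg.l_p, c["L_nm"], kBT)
        )

    t_last = max(c["t_rupture_s"] for c in chains)
    T = 1.25 * t_last
    dt = 1.0 / cfg.sample_rate
    n_samples = int(math.ceil(T / dt))
    if n_samples > cfg.max_samples:
        dt = T / cfg.max_samples
        n_samples = cfg.max_samples
    if n_samples < 64:
        n_samples = 256
        dt = T / n_samples
    t = dt * np.arange(n_samples)
    x = velocity * t

    f = np.zeros(n_samples)
    for c in chains:
        attached = t < c["t_rupture_s"]
        xi = np.minimum(x[attached], _X_TRUNC * c["L_nm"])
        f[attached] += _force_raw(xi, cfg.l_p, c["L_nm"], kBT)
    f += cfg.baseline_drift * (t / T)
    if cfg.noise_sigma > 0:
        f += rng.normal(0.0, cfg.noise_sigma, n_samples)

    # segment bookkeeping: chains surviving between consecutive ruptures
    order = np.argsort([c["t_rupture_s"] for c in chains])
    times = [chains[i]["t_rupture_s"] for i in order]
    segments = []
    prev = 0.0
    for k, t_r in enumerate(times):
        surviving = [chains[i] for i in order[k:]]
        Ls = [c["L_nm"] for c in surviving]
        equal = max(Ls) - min(Ls) < 1e-9 * max(Ls)
        segments.append(
            {
                "t_start_s": prev,
                "t_end_s": t_r,
                "n_chains": len(surviving),
                "l_app_nm": cfg.l_p / len(surviving) if equal else None,
            }
        )
        prev = t_r

    last_index = int(np.searchsorted(t, t_last) - 1)
    last_chain = chains[order[-1]]
    truth = {
        "N": N,
        "velocity_nm_s": velocity,
        "l_p_nm": cfg.l_p,
        "chains": chains,
        "segments": segments,
        "last_event": {
            "t_s": t_last,
            "f_pN": last_chain["f_rupture_pN"],
            "l_app_nm": cfg.l_p,
            "L_nm": last_chain["L_nm"],
            "index": last_index,
        },
    }
    curve = ForceCurve(t=t, x=x, f=f, velocity=velocity, temperature=cfg.temperature)
    return curve, truth


def generate_dataset(cfg: GeneratorConfig, outdir):
    """Write a full synthetic dataset plus its truth manifest.

    Curves are written in the package CSV format, interleaving
    velocities in blocks of five curves (the heterogeneity-averaging
    schedule), until each velocity reaches its quota.  Returns the
    manifest dict (also written to ``manifest.json``), keyed by
    curve_id.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_total = len(cfg.velocities) * cfg.curves_per_velocity
    streams = np.random.SeedSequence(cfg.seed).spawn(n_total)
    manifest = {}
    quota = {v: 0 for v in cfg.velocities}
    idx = 0
    n_cycles = math.ceil(cfg.curves_per_velocity / 5)
    for _cycle in range(n_cycles):
        for velocity in cfg.velocities:
            for _ in range(5):
                if quota[velocity] >= cfg.curves_per_velocity:
                    break
                rng = np.random.default_rng(streams[idx])
                curve, truth = generate_curve(velocity, cfg, rng)
                curve_id = f"curve_{idx:05d}"
                curve.curve_id = curve_id
                write_force_curve(curve, outdir / f"{curve_id}.csv")
                manifest[curve_id] = truth
                quota[velocity] += 1
                idx += 1
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def generate_curves(cfg: GeneratorConfig):
    """Generate the dataset's curves in memory (no files).

    Yields ``(curve, truth)`` pairs in the same five-curve interleaved
    schedule as :func:`generate_dataset`; convenient for tests and
    pipelines that do not need the CSV round-trip.
    """
    n_total = len(cfg.velocities) * cfg.curves_per_velocity
    streams = np.random.SeedSequence(cfg.seed).spawn(n_total)
    quota = {v: 0 for v in cfg.velocities}
    idx = 0
    n_cycles = math.ceil(cfg.curves_per_velocity / 5)
    for _cycle in range(n_cycles):
        for velocity in cfg.velocities:
            for _ in range(5):
                if quota[velocity] >= cfg.curves_per_velocity:
                    break
                rng = np.random.default_rng(streams[idx])
                curve, truth = generate_curve(velocity, cfg, rng)
                curve.curve_id = f"curve_{idx:05d}"
                quota[velocity] += 1
                idx += 1
                yield curve, truth
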