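"""End-to-end protocol: curves in, bond parameters and free energy out."""
from __future__ import annotations

from dataclasses import dataclass, field

from .energy import DEFAULT_MONOMER_LENGTH_NM, EnergyLandscape, summarize_landscape
from .kinetics import BondFitResult, fit_single_bond_model
from .processing import (
    FilterConfig,
    build_spectrum,
    extract_events,
    filter_events,
)
from .wlc import thermal_energy


@dataclass
class ProtocolResult:
    """Everything the single-bond protocol produces for one dataset."""

    fit: BondFitResult
    landscape: EnergyLandscape
    spectrum: list
    events: list
    qc: dict = field(default_factory=dict)


def run_protocol(
    curves,
    l_p: float,
    threshold_fraction: float = 0.7,
    max_fraction: float = 2.0,
    l_mono: float = DEFAULT_MONOMER_LENGTH_NM,
    rate_method: str = "numerical",
    noise_sigma: float | None = None,
    temperature: float | None = None,
) -> ProtocolResult:
    """Run the full analysis on an iterable of :class:`ForceCurve`.

    Stages: last-rupture detection → last-event WLC fit → l_app filter
    at ``threshold_fraction``·l_p → per-velocity mean-force spectrum →
    single-bond model fit → energy-landscape summary.  The QC dict
    aggregates per-stage counts and rejection reasons.
    """
    curves = list(curves)
    extraction = extract_events(curves, noise_sigma=noise_sigma, rate_method=rate_method)
    kept, filter_report = filter_events(
        extraction.events,
        FilterConfig(
            l_p=l_p,
            threshold_fraction=threshold_fraction,
            max_fraction=max_fraction,
        ),
    )
    spectrum, spectrum_report = build_spectrum(kept)
    if temperature is None:
        temperature = curves[0].temperature if curves else None
    kBT = thermal_energy(temperature) if temperature else thermal_energy()
    fit = fit_single_bond_model(spectrum, kBT)
    landscape = summarize_landscape(fit, l_p=l_p, l_mono=l_mono, kBT=kBT)
    qc = dict(extraction.qc)
    qc["n_passed_filter"] = filter_report["n_kept"]
    qc["filter"] = filter_report
    qc["spectrum"] = spectrum_report
    return ProtocolResult(
        fit=fit, landscape=landscape, spectrum=spectrum, events=kept, qc=qc
    )
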