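"""Plain-text I/O for force curves and rupture-event tables.

Force-curve format: CSV with a commented metadata header::

    # velocity_nm_s=460.0
    # temperature_K=293.15
    # curve_id=curve_00012
    time_s,separation_nm,force_pN
    0,0,0.12
    ...

A directory of such files is a dataset.  Rupture-event ensembles are
CSV with columns velocity_nm_s, f_r_pN, r_pN_s, t_r_s, l_app_nm, L_nm,
with the generating seed recorded in a header comment.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DomainError

_CURVE_COLUMNS = ["time_s", "separation_nm", "force_pN"]
_EVENT_COLUMNS = ["velocity_nm_s", "f_r_pN", "r_pN_s", "t_r_s", "l_app_nm", "L_nm"]


def write_force_curve(curve, path) -> None:
    """Write one curve in the package CSV format."""
    path = Path(path)
    header = [f"# velocity_nm_s={curve.velocity!r}",
              f"# temperature_K={curve.temperature!r}"]
    if curve.curve_id is not None:
        header.append(f"# curve_id={curve.curve_id}")
    header.append(",".join(_CURVE_COLUMNS))
    np.savetxt(
        path,
        np.column_stack([curve.t, curve.x, curve.f]),
        delimiter=",",
        fmt="%.9g",
        header="\n".join(header),
        comments="",
    )


def _parse_metadata(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_force_curve(path):
    """Read one curve written by :func:`write_force_curve`."""
    from .processing import ForceCurve

    path = Path(path)
    meta = _parse_metadata(path)
    if "velocity_nm_s" not in meta:
        raise DomainError(f"{path}: missing '# velocity_nm_s=' metadata line")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: missing columns {missing}")
    return ForceCurve(
        t=df["time_s"].to_numpy(),
        x=df["separation_nm"].to_numpy(),
        f=df["force_pN"].to_numpy(),
        velocity=float(meta["velocity_nm_s"]),
        temperature=float(meta.get("temperature_K", 293.15)),
        curve_id=meta.get("curve_id"),
    )


def read_dataset(directory):
    """Read every ``*.csv`` curve in a dataset directory, sorted by name."""
    directory = Path(directory)
    paths = sorted(p for p in directory.glob("*.csv"))
    if not paths:
        raise DomainError(f"no .csv curves found in {directory}")
    return [read_force_curve(p) for p in paths]


def write_events_csv(events, path, seed: int | None = None) -> None:
    """Write a rupture-event ensemble, recording the seed as a comment."""
    path = Path(path)
    rows = [
        (e.velocity, e.f_r, e.r, e.t_r, e.l_app, e.L) for e in events
    ]
    lines = []
    if seed is not None:
        lines.append(f"# seed={seed}")
    lines.append(",".join(_EVENT_COLUMNS))
    np.savetxt(
        path,
        np.array(rows, dtype=float),
        delimiter=",",
        fmt="%.17g",
        header="\n".join(lines),
        comments="",
    )


def read_events_csv(path):
    """Read a rupture-event ensemble written by :func:`write_events_csv`."""
    from .montecarlo import RuptureEvent

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: missing columns {missing}")
    return [
        RuptureEvent(
            f_r=row.f_r_pN,
            r=row.r_pN_s,
            t_r=row.t_r_s,
            velocity=row.velocity_nm_s,
            l_app=row.l_app_nm,
            L=row.L_nm,
        )
        for row in df.itertuples()
    ]
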