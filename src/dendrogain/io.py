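"""Plain-text containers: voltage traces, gain curves and cohort tables.

The trace container is a CSV with ``#``-prefixed header lines carrying the
sampling step, units and recording site, followed by ``time_s,voltage_mV``
(plus ``current_pA`` when an injected current is stored).  Gain curves are
a CSV of per-frequency readouts with a JSON sidecar for the scalar
metadata (F0, threshold, cutoff, seeds).  Cohort tables are ordinary CSV,
one row per subject.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .biophysics import VoltageTrace
from .transfer_gain import CutoffResult, GainCurve

__all__ = [
    "write_trace",
    "read_trace",
    "write_gain_curve",
    "read_gain_curve",
]


def write_trace(trace: VoltageTrace, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# dt_s = {trace.dt:.17g}\n")
        fh.write(f"# site = {trace.site}\n")
        fh.write("# units: time s, voltage mV, current pA\n")
        if trace.current is not None:
            fh.write("time_s,voltage_mV,current_pA\n")
            for i, (v, c) in enumerate(zip(trace.voltage, trace.current)):
                fh.write(f"{i * trace.dt:.9g},{v:.9g},{c:.9g}\n")
        else:
            fh.write("time_s,voltage_mV\n")
            for i, v in enumerate(trace.voltage):
                fh.write(f"{i * trace.dt:.9g},{v:.9g}\n")


def read_trace(path) -> VoltageTrace:
    path = Path(path)
    dt = None
    site = "soma"
    with open(path, "r", encoding="utf-8") as fh:
        header_lines = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if body.startswith("dt_s"):
                dt = float(body.split("=")[1])
            elif body.startswith("site"):
                site = body.split("=")[1].strip()
    df = pd.read_csv(path, comment="#")
    if dt is None:
        t = df["time_s"].to_numpy()
        dt = float(t[1] - t[0])
    current = df["current_pA"].to_numpy() if "current_pA" in df else None
    return VoltageTrace(dt=dt, voltage=df["voltage_mV"].to_numpy(), current=current, site=site)


def write_gain_curve(curve: GainCurve, path, cutoff: CutoffResult | None = None) -> None:
    """CSV of (F, N, r1, g, unreliable) plus a ``.json`` metadata sidecar."""
    path = Path(path)
    pd.DataFrame(
        {
            "frequency_hz": curve.frequencies,
            "n_spikes": curve.n_spikes,
            "r1": curve.r1,
            "g": curve.g,
            "unreliable": curve.unreliable.astype(int),
        }
    ).to_csv(path, index=False)
    meta = {
        "f0_hz": curve.f0,
        "threshold": curve.threshold,
        "seeds": None if curve.seeds is None else [int(s) for s in curve.seeds],
    }
    if cutoff is None:
        cutoff = curve.cutoff()
    meta["cutoff"] = asdict(cutoff)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_gain_curve(path) -> GainCurve:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return GainCurve(
        frequencies=df["frequency_hz"].to_numpy(),
        r1=df["r1"].to_numpy(),
        n_spikes=df["n_spikes"].to_numpy(),
        f0=meta["f0_hz"],
        threshold=meta["threshold"],
        unreliable=df["unreliable"].to_numpy().astype(bool),
        seeds=None if meta["seeds"] is None else np.array(meta["seeds"]),
    )
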