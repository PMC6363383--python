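"""Figures for the standard readouts: AP phase plane, gain curve, cohort
regression scatter (the latter lives on
:meth:`~dendrogain.cohort_stats.CohortAssociationResults.plot`)."""

from __future__ import annotations

import numpy as np

from .biophysics import VoltageTrace
from .transfer_gain import GainCurve

__all__ = ["plot_phase_plane", "plot_gain_curve"]


def plot_phase_plane(trace: VoltageTrace, ax=None, eval_speed: float = 10.0):
    """dV/dt against V with the onset-rapidity evaluation level marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    dvdt = np.gradient(trace.voltage, trace.dt * 1e3)
    ax.plot(trace.voltage, dvdt, lw=0.5)
    ax.axhline(eval_speed, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("V (mV)")
    ax.set_ylabel("dV/dt (mV/ms)")
    return ax


def plot_gain_curve(curve: GainCurve, ax=None, show_cutoff: bool = True):
    """Normalized transfer gain against modulation frequency (log-log)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.loglog(curve.frequencies, curve.g, "o-")
    ax.axhline(curve.threshold, ls="--", color="grey", lw=0.8)
    if show_cutoff:
        co = curve.cutoff()
        ax.axvline(co.fc, ls=":", color="red", lw=0.8,
                   label=f"Fc = {co.fc:.0f} Hz" + (" (censored)" if co.censored else ""))
        ax.legend()
    ax.set_xlabel("modulation frequency (Hz)")
    ax.set_ylabel("normalized gain r1(F)/r1(F0)")
    return ax
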