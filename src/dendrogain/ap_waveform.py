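"""Action-potential waveform analysis of current-step voltage sweeps.

APs are extracted from step-protocol recordings (10-50 kHz sampling),
sorted by instantaneous firing frequency (1 / time to the previous AP in
the same sweep), and their rise speed — the peak of dV/dt on the upstroke —
is averaged inside 10 Hz-wide frequency bins, with the first AP of every
sweep isolated in its own bin.  Relative rise speed divides each bin mean
by the first-AP mean and quantifies activity-dependent AP fatigue; the
20-40 Hz aggregate averages the (20,30] and (30,40] bins.  Per-neuron
metrics are averaged, unweighted, across the neurons of one subject.

Bin edges are half-open, (10·(k−1), 10·k], matching the conventional
"1–10 Hz, 11–20 Hz, ..." labels.  dV/dt uses centred differences at the
native sampling rate; events whose derivative peak spans fewer than three
samples, or whose waveform is clipped, carry a quality flag and are
excluded from the bin means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biophysics import VoltageTrace, detect_spikes

__all__ = [
    "APEvent",
    "FrequencyBinnedRiseSpeed",
    "SamplingRateError",
    "NormalizationError",
    "extract_aps",
    "max_rise_speed",
    "bin_by_frequency",
    "aggregate_subject",
    "BIN_WIDTH_HZ",
]

BIN_WIDTH_HZ = 10.0
WINDOW_S = 5e-3  # extracted half-window around the upstroke


class SamplingRateError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass
class APEvent:
    """One detected action potential and its waveform metrics."""

    time: float  # s, within its sweep
    sweep: int
    waveform: np.ndarray  # mV, ±5 ms around the threshold crossing
    dt: float  # s
    max_rise_speed: float  # mV/ms, peak of dV/dt on the upstroke
    instantaneous_frequency: float | None  # Hz; None for the first AP
    is_first_in_train: bool
    quality_ok: bool = True


def max_rise_speed(ap: APEvent | np.ndarray, dt: float | None = None) -> float:
    """Peak of centred-difference dV/dt (mV/ms) on the AP rising phase.

    Accepts an :class:`APEvent` or a raw waveform window with its ``dt``.
    The search is restricted to samples at or before the voltage peak.
    """
    if isinstance(ap, APEvent):
        w, dt = ap.waveform, ap.dt
    else:
        w = np.asarray(ap, dtype=float)
        if dt is None:
            raise ValueError("dt required with a raw waveform")
    dvdt = np.gradient(w, dt * 1e3)
    peak = int(np.argmax(w))
    if peak < 1:
        return float("nan")
    return float(np.max(dvdt[: peak + 1]))


def _quality(w: np.ndarray, dt: float) -> bool:
    """False for clipped waveforms or derivative peaks thinner than 3 samples."""
    peak = int(np.argmax(w))
    at_max = np.flatnonzero(w == w[peak])
    if len(at_max) >= 3 and np.any(np.diff(at_max)[:2] == 1):
        run = 1
        for d in np.diff(at_max):
            run = run + 1 if d == 1 else 1
            if run >= 3:
                return False  # flat-topped / clipped
    dvdt = np.gradient(w, dt * 1e3)
    rise = dvdt[: peak + 1]
    if len(rise) < 3:
        return False
    k = int(np.argmax(rise))
    half = rise[k] / 2.0
    span = np.flatnonzero(rise >= half)
    return len(span) >= 3


def extract_aps(
    sweeps: list[VoltageTrace],
    include_mask: list[bool] | None = None,
    threshold: float = 0.0,
    refractory: float = 2e-3,
) -> list[APEvent]:
    """Detect APs in a set of sweeps and attach instantaneous frequencies.

    ``include_mask`` mirrors upstream experimental exclusion criteria
    (bridge balance, epileptiform activity): masked-out sweeps are skipped.
    Sampling outside 10-50 kHz raises :class:`SamplingRateError`.
    """
    events: list[APEvent] = []
    for si, sweep in enumerate(sweeps):
        if include_mask is not None and not include_mask[si]:
            continue
        fs = sweep.sampling_rate
        if fs < 10_000 or fs > 50_000:
            raise SamplingRateError(
                f"sweep {si}: sampling rate {fs:.0f} Hz outside the 10-50 kHz range"
            )
        spikes = detect_spikes(sweep, threshold=threshold, refractory=refractory)
        half = int(round(WINDOW_S / sweep.dt))
        prev_t = None
        for k, t in enumerate(spikes.times):
            c = int(round(t / sweep.dt))
            lo, hi = max(c - half, 0), min(c + half, len(sweep.voltage))
            w = sweep.voltage[lo:hi].copy()
            ev = APEvent(
                time=float(t),
                sweep=si,
                waveform=w,
                dt=sweep.dt,
                max_rise_speed=float("nan"),
                instantaneous_frequency=None if k == 0 else 1.0 / (t - prev_t),
                is_first_in_train=(k == 0),
            )
            ev.max_rise_speed = max_rise_speed(ev)
            ev.quality_ok = _quality(w, sweep.dt) and math.isfinite(ev.max_rise_speed)
            events.append(ev)
            prev_t = t
    return events


@dataclass
class FrequencyBinnedRiseSpeed:
    """Per-bin mean rise speeds for one neuron.

    ``bin_means[k]`` covers instantaneous frequencies in (10·k, 10·(k+1)];
    empty bins are NaN.  Relative values divide by the first-AP mean.
    """

    bin_means: np.ndarray  # mV/ms
    bin_counts: np.ndarray
    first_ap_mean: float  # mV/ms
    first_ap_count: int
    bin_width: float = BIN_WIDTH_HZ

    @property
    def relative(self) -> np.ndarray:
        return self.bin_means / self.first_ap_mean

    def _band(self, arr: np.ndarray, lo_bin: int, hi_bin: int) -> float:
        vals = arr[lo_bin : hi_bin + 1]
        vals = vals[np.isfinite(vals)]
        return float(np.mean(vals)) if len(vals) else float("nan")

    @property
    def rise_20_40(self) -> float:
        """Mean of the (20,30] and (30,40] bin means (mV/ms)."""
        return self._band(self.bin_means, 2, 3)

    @property
    def relative_20_40(self) -> float:
        return self._band(self.relative, 2, 3)


def bin_by_frequency(aps: list[APEvent], n_bins: int = 10) -> FrequencyBinnedRiseSpeed:
    """Average rise speed inside 10 Hz instantaneous-frequency bins.

    First-in-train APs form their own bin (the normalization reference);
    an input without any first AP raises :class:`NormalizationError`.
    Flagged (low-quality) events are ignored.
    """
    good = [a for a in aps if a.quality_ok]
    firsts = [a.max_rise_speed for a in good if a.is_first_in_train]
    if not firsts:
        raise NormalizationError("no first-in-train AP available for normalization")
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for a in good:
        f = a.instantaneous_frequency
        if f is None:
            continue
        k = int(math.ceil(f / BIN_WIDTH_HZ)) - 1  # f in (10k, 10(k+1)]
        if 0 <= k < n_bins:
            sums[k] += a.max_rise_speed
            counts[k] += 1
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return FrequencyBinnedRiseSpeed(
        bin_means=means,
        bin_counts=counts,
        first_ap_mean=float(np.mean(firsts)),
        first_ap_count=len(firsts),
    )


def aggregate_subject(neurons: list[FrequencyBinnedRiseSpeed], subject_id) -> pd.Series:
    """Unweighted mean of per-neuron metrics across the neurons of a subject.

    Per-bin means (absolute and relative) are averaged across neurons
    ignoring missing bins; the 20-40 Hz aggregates then average the two
    subject-level bins.
    """
    if not neurons:
        raise ValueError("need at least one neuron")
    n_bins = len(neurons[0].bin_means)
    abs_mat = np.vstack([n.bin_means for n in neurons])
    rel_mat = np.vstack([n.relative for n in neurons])
    counts = np.sum(np.isfinite(abs_mat), axis=0)
    with np.errstate(invalid="ignore"):
        abs_bins = np.where(counts > 0, np.nansum(abs_mat, axis=0) / np.maximum(counts, 1), np.nan)
        rel_bins = np.where(counts > 0, np.nansum(rel_mat, axis=0) / np.maximum(counts, 1), np.nan)
    first = float(np.mean([n.first_ap_mean for n in neurons]))

    def band(arr):
        vals = arr[2:4]
        vals = vals[np.isfinite(vals)]
        return float(np.mean(vals)) if len(vals) else float("nan")

    out = {
        "subject": subject_id,
        "n_neurons": len(neurons),
        "first_ap_rise_speed": first,
        "rise_speed_20_40": band(abs_bins),
        "relative_rise_speed_20_40": band(rel_bins),
    }
    for k in range(n_bins):
        out[f"rise_speed_bin_{10 * k}_{10 * (k + 1)}"] = abs_bins[k]
        out[f"relative_bin_{10 * k}_{10 * (k + 1)}"] = rel_bins[k]
    return pd.Series(out)
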