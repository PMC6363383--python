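"""Dynamic input-output transfer gain, cutoff frequency and AP onset rapidity.

The transfer gain at a modulation frequency F is the vector strength of the
somatic spike train,

    r1(F) = | (1/N) Σ_k exp(i·2πF·t_k) |,

estimated from a long sinusoid-plus-noise injection at each probe frequency
and normalized to its value at F0 = 3 Hz.  The normalized curve behaves
like a low-pass filter; the cutoff frequency Fc is the highest frequency at
which the normalized gain still reaches 1/√2 (the −3 dB convention, the
plotted "0.7 response magnitude" line), located by log-linear interpolation
between probe points.

AP onset rapidity is the slope of the phase-plane trajectory (dV/dt against
V) on the action-potential rising phase, evaluated where dV/dt = 10 mV/ms
and averaged across the APs of a train.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import biophysics as bp
from .stimulus import StimulusSpec, sinusoid_stimulus

__all__ = [
    "GainCurve",
    "CutoffResult",
    "OnsetRapidity",
    "vector_strength",
    "gain_curve",
    "cutoff_frequency",
    "onset_rapidity",
    "DEFAULT_PROBE_FREQUENCIES",
    "GAIN_THRESHOLD",
]

GAIN_THRESHOLD = 1.0 / np.sqrt(2.0)
F0_DEFAULT = 3.0
#: 16 log-spaced probe frequencies spanning 1-1000 Hz (plus the 3 Hz reference)
DEFAULT_PROBE_FREQUENCIES = np.unique(
    np.concatenate([np.round(np.geomspace(1.0, 1000.0, 16), 1), [3.0]])
)


def vector_strength(spikes, F: float) -> float:
    """Modulus of the mean unit phasor of spike times at frequency F.

    ``spikes`` is a :class:`~dendrogain.biophysics.SpikeTrain` or an array
    of times in seconds; the result lies in [0, 1].  An empty train raises
    ``ValueError``.
    """
    times = spikes.times if hasattr(spikes, "times") else np.asarray(spikes, dtype=float)
    if len(times) == 0:
        raise ValueError("vector strength is undefined for an empty spike train")
    return float(np.abs(np.mean(np.exp(2j * np.pi * F * times))))


@dataclass
class GainCurve:
    """Transfer gain r1 at each probe frequency, normalized at F0."""

    frequencies: np.ndarray
    r1: np.ndarray
    n_spikes: np.ndarray
    f0: float = F0_DEFAULT
    threshold: float = GAIN_THRESHOLD
    unreliable: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    seeds: np.ndarray | None = None  # noise seed used at each probe frequency

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.r1 = np.asarray(self.r1, dtype=float)
        if len(self.unreliable) == 0:
            self.unreliable = np.zeros(len(self.frequencies), dtype=bool)

    @property
    def r1_f0(self) -> float:
        i = np.argmin(np.abs(self.frequencies - self.f0))
        if abs(self.frequencies[i] - self.f0) > 1e-9:
            raise ValueError(f"normalization frequency {self.f0} Hz not in probe set")
        return float(self.r1[i])

    @property
    def g(self) -> np.ndarray:
        """Normalized gain r1(F) / r1(F0)."""
        return self.r1 / self.r1_f0

    def cutoff(self) -> "CutoffResult":
        return cutoff_frequency(self)


@dataclass(frozen=True)
class CutoffResult:
    """Cutoff frequency with censoring information.

    ``censored`` means the gain never fell below threshold inside the probed
    range; ``degenerate`` means it was below threshold everywhere above F0.
    """

    fc: float
    censored: bool = False
    degenerate: bool = False


def cutoff_frequency(curve: GainCurve) -> CutoffResult:
    """Highest frequency at which the normalized gain is >= the threshold,
    log-linearly interpolated between the bracketing probe points."""
    order = np.argsort(curve.frequencies)
    f = curve.frequencies[order]
    g = curve.g[order]
    if len(f) < 5:
        raise ValueError("need at least 5 probe points to locate a cutoff")
    thr = curve.threshold
    above = np.flatnonzero(g >= thr)
    if len(above) == 0:
        return CutoffResult(fc=float(f[0]), degenerate=True)
    j = above[-1]
    if j == len(f) - 1:
        return CutoffResult(fc=float(f[-1]), censored=True)
    i0_f0 = np.argmin(np.abs(f - curve.f0))
    if j <= i0_f0:
        return CutoffResult(fc=float(curve.f0), degenerate=True)
    lf = np.log(f)
    frac = (thr - g[j]) / (g[j + 1] - g[j])
    return CutoffResult(fc=float(np.exp(lf[j] + frac * (lf[j + 1] - lf[j]))))


def gain_curve(
    model: bp.CompartmentModel,
    template: StimulusSpec,
    probe_frequencies=None,
    seconds_per_freq: float | dict | None = None,
    transient_discard: float = 0.5,
    min_rate: float = 2.0,
    state: bp.ModelState | None = None,
    f0_oversample: float = 4.0,
    theta: float = 1.0,
) -> GainCurve:
    """Measure r1(F) over a probe set with the calibrated stimulus template.

    Each probe frequency gets an independent noise realization (seed =
    template.seed + probe index, recorded on the curve); F0 = 3 Hz is added
    to the probe set if absent.  Probe points where the firing rate falls
    below ``min_rate`` spike/s are flagged unreliable.

    ``seconds_per_freq`` may be a scalar, or a mapping from probe frequency
    to duration (missing probes fall back to the mapping's ``"default"``
    entry) — cutoff estimation benefits from spending integration time on
    the probes that bracket the threshold crossing rather than uniformly.

    The F0 reference point is integrated ``f0_oversample`` times longer
    than its base duration: its estimation error propagates coherently into
    every normalized gain value (and hence the cutoff), so extra averaging
    there is the cheapest way to stabilise the whole curve.
    """
    if probe_frequencies is None:
        probe_frequencies = DEFAULT_PROBE_FREQUENCIES
    freqs = np.unique(np.concatenate([np.asarray(probe_frequencies, float), [F0_DEFAULT]]))
    if np.any((freqs < 1.0 - 1e-9) | (freqs > 1000.0 + 1e-9)):
        raise ValueError("probe frequencies must lie within [1, 1000] Hz")
    if seconds_per_freq is None:
        seconds_per_freq = template.duration

    def _base_duration(f: float) -> float:
        if isinstance(seconds_per_freq, dict):
            return float(seconds_per_freq.get(f, seconds_per_freq.get("default",
                                                                      template.duration)))
        return float(seconds_per_freq)

    if state is None:
        _, state = bp.equilibrate(model, dt=template.dt)

    r1 = np.empty(len(freqs))
    n_spikes = np.zeros(len(freqs), dtype=int)
    unreliable = np.zeros(len(freqs), dtype=bool)
    seeds = np.empty(len(freqs), dtype=np.int64)
    for i, f in enumerate(freqs):
        seeds[i] = template.seed + i
        dur_i = _base_duration(f)
        if abs(f - F0_DEFAULT) < 1e-9:
            dur_i *= f0_oversample
        spec = replace(template, F=float(f), duration=dur_i, seed=int(seeds[i]))
        current = sinusoid_stimulus(spec)
        trace = bp.simulate(model, current=current, dt=spec.dt, state=state, theta=theta)
        spikes = bp.detect_spikes(trace)
        times = spikes.times[spikes.times >= transient_discard]
        n_spikes[i] = len(times)
        if len(times) / (dur_i - transient_discard) < min_rate:
            unreliable[i] = True
            r1[i] = np.nan if len(times) == 0 else vector_strength(times, f)
        else:
            r1[i] = vector_strength(times, f)
    return GainCurve(
        frequencies=freqs, r1=r1, n_spikes=n_spikes, unreliable=unreliable, seeds=seeds
    )


# ---------------------------------------------------------------------------
# Onset rapidity


@dataclass
class OnsetRapidity:
    """Phase-plane slope at the 10 mV/ms evaluation speed (units 1/ms)."""

    value: float  # train mean
    per_ap: np.ndarray
    eval_speed: float = 10.0


def onset_rapidity(
    trace: bp.VoltageTrace,
    spike_times: np.ndarray | None = None,
    eval_speed: float = 10.0,
    fit_window: tuple[float, float] = (5.0, 15.0),
    pre_window: float = 5e-3,
) -> OnsetRapidity:
    """Slope of dV/dt against V on the AP rising phase at ``eval_speed``.

    For each AP, dV/dt is computed by centred differences and a local line
    is fitted to (V, dV/dt) over rising-phase samples with dV/dt inside
    ``fit_window`` (mV/ms); an AP whose upstroke never reaches
    ``eval_speed`` is excluded with a warning.  Returns per-AP slopes and
    their mean (1/ms).
    """
    if trace.sampling_rate < 10_000:
        raise ValueError("onset rapidity requires sampling of at least 10 kHz")
    if spike_times is None:
        spike_times = bp.detect_spikes(trace).times
    spike_times = np.asarray(spike_times, dtype=float)
    if len(spike_times) == 0:
        raise ValueError("trace contains no action potentials")
    v = trace.voltage
    dt_ms = trace.dt * 1e3
    dvdt = np.gradient(v, dt_ms)
    lo, hi = fit_window
    slopes = []
    n_excluded = 0
    for t in spike_times:
        k = int(round(t / trace.dt))
        i0 = max(k - int(round(pre_window / trace.dt)), 1)
        seg_v = v[i0 : k + 1]
        seg_d = dvdt[i0 : k + 1]
        if len(seg_d) < 3 or np.max(seg_d) < eval_speed:
            n_excluded += 1
            continue
        # rising flank: walk back from the threshold crossing while dV/dt
        # stays above the window floor, then keep samples inside the window
        sel = np.flatnonzero((seg_d >= lo) & (seg_d <= hi))
        if len(sel) >= 2:
            slope = np.polyfit(seg_v[sel], seg_d[sel], 1)[0]
        else:
            j = np.flatnonzero(seg_d >= eval_speed)
            if len(j) == 0 or j[0] == 0:
                n_excluded += 1
                continue
            j = j[0]
            dv = seg_v[j] - seg_v[j - 1]
            if dv == 0:
                n_excluded += 1
                continue
            slope = (seg_d[j] - seg_d[j - 1]) / dv
        slopes.append(slope)
    if n_excluded:
        warnings.warn(
            f"{n_excluded} AP(s) excluded from onset-rapidity estimate", stacklevel=2
        )
    if not slopes:
        raise ValueError("no AP reached the evaluation speed")
    per_ap = np.array(slopes)
    return OnsetRapidity(value=float(per_ap.mean()), per_ap=per_ap, eval_speed=eval_speed)
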