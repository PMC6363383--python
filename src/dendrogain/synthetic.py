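"""Synthetic cohorts: morphologies, current-step sweeps and planted effects.

Emulates everything the real study measured, so the full analysis chain is
testable without any recordings: a cohort of subjects with WAIS-scale IQ
scores (normal, mean 90, SD 17, truncated to [60, 130]); per-subject total
dendritic length and AP-speed latents correlated with IQ at stated effect
sizes (defaults R² = 0.26 for IQ-TDL and 0.14 for IQ-relative rise speed);
1-11 neurons per subject (median 3); branched morphologies matching each
neuron's TDL; and step-protocol voltage sweeps whose AP upstrokes follow a
planted fatigue model — per-AP peak dV/dt declines linearly with
instantaneous firing frequency.

Correlated subject latents are drawn from a bivariate-normal construction:
latent = mean + SD·(ρ·z + sqrt(1−ρ²)·ε) with z the standardized (truncated)
IQ score and ρ² the requested R², which makes the population correlation
exactly ρ.  Synthetic AP upstrokes are parametric sigmoids, not simulated
membrane potential, so the waveform analysis is tested independently of
the biophysics; the logistic time constant is chosen per AP such that the
centred-difference derivative at the native sampling rate peaks exactly at
the planted rise speed.  Every latent draw is recorded in a ground-truth
ledger.  Fixed seed ⇒ byte-identical bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .biophysics import VoltageTrace
from .morphology import Morphology, SyntheticTreeSpec, generate_branched_tree
from .stimulus import ou_noise

__all__ = [
    "FatigueModel",
    "CohortSpec",
    "NeuronRecord",
    "CohortBundle",
    "CohortSpecError",
    "generate_recording_sweeps",
    "generate_cohort",
]

BRANCH_POINTS_PER_UM = 64.0 / 14670.0  # cohort-calibrated branch density


class CohortSpecError(ValueError):
    pass


@dataclass(frozen=True)
class FatigueModel:
    """Planted AP-fatigue mechanism for one neuron.

    ``slowing_coefficient`` is the fractional rise-speed decline per Hz of
    instantaneous frequency: speed(f) = first_ap_rise_speed·(1 − c·f).
    A relative 20-40 Hz rise speed of ``r`` corresponds to c = (1 − r)/30
    (the band centre is 30 Hz).
    """

    first_ap_rise_speed: float  # mV/ms
    slowing_coefficient: float  # 1/Hz
    within_noise_sd: float = 8.0  # mV/ms, per-AP speed jitter

    def __post_init__(self) -> None:
        if self.first_ap_rise_speed <= 0:
            raise ValueError("first_ap_rise_speed must be positive")
        if self.slowing_coefficient < 0:
            raise ValueError("slowing_coefficient must be >= 0")

    def speed_at(self, f_inst: float | None) -> float:
        if f_inst is None:
            return self.first_ap_rise_speed
        return self.first_ap_rise_speed * max(1.0 - self.slowing_coefficient * f_inst, 0.2)


@dataclass(frozen=True)
class CohortSpec:
    """Study-scale cohort with planted IQ associations."""

    n_subjects: int = 31
    iq_mean: float = 90.0
    iq_sd: float = 17.0
    iq_range: tuple[float, float] = (60.0, 130.0)
    neurons_median: int = 3
    neurons_max: int = 11
    r2_iq_tdl: float = 0.26
    r2_iq_relrise: float = 0.14
    r2_iq_first: float = 0.17
    tdl_mean: float = 14670.0  # µm
    tdl_sd: float = 4000.0
    first_speed_mean: float = 300.0  # mV/ms
    first_speed_sd: float = 38.0
    relrise_mean: float = 0.79
    relrise_sd: float = 0.09
    within_noise_sd: float = 8.0
    n_sweeps: int = 5
    sampling_rate: float = 25_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 5:
            raise CohortSpecError("n_subjects must be >= 5")
        for name in ("r2_iq_tdl", "r2_iq_relrise", "r2_iq_first"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise CohortSpecError(f"{name} must lie in [0, 1)")


@dataclass
class NeuronRecord:
    subject: int
    neuron: int
    tdl: float  # µm, planted (equals the morphology's measured TDL)
    fatigue: FatigueModel
    morphology: Morphology | None
    sweeps: list[VoltageTrace]


@dataclass
class CohortBundle:
    """Everything a cohort analysis consumes, plus the ground truth."""

    spec: CohortSpec
    subjects: pd.DataFrame  # subject, iq, n_neurons
    neurons: list[NeuronRecord]
    ground_truth: dict


# ---------------------------------------------------------------------------
# Sweep synthesis


def _logistic_tau(amplitude: float, target_dvdt: float, h_ms: float) -> float:
    """Logistic time constant whose centred-difference derivative at the
    sample spacing ``h_ms`` peaks exactly at ``target_dvdt``."""
    x = 2.0 * h_ms * target_dvdt / amplitude
    x = min(x, 0.995)
    return h_ms / (2.0 * math.atanh(x))


def _insert_ap(v: np.ndarray, k0: int, fs: float, base: float, peak: float, target_dvdt: float):
    """Overwrite samples around ``k0`` with a sigmoidal AP waveform."""
    h_ms = 1e3 / fs
    amp = peak - base
    tau = _logistic_tau(amp, target_dvdt, h_ms)
    n_pre = int(round(1.2 / h_ms))
    n_rise_post = max(int(round(6 * tau / h_ms)), 2)
    n_decay = int(round(3.0 / h_ms))
    n_rec = int(round(2.0 / h_ms))
    lo = max(k0 - n_pre, 0)
    t_ms = (np.arange(lo, min(k0 + n_rise_post + 1, len(v))) - k0) * h_ms
    v[lo : lo + len(t_ms)] = base + amp / (1.0 + np.exp(-t_ms / tau))
    j0 = lo + len(t_ms)
    v_end = v[j0 - 1]
    trough = base - 3.0
    j1 = min(j0 + n_decay, len(v))
    td = (np.arange(j0, j1) - (j0 - 1)) * h_ms
    v[j0:j1] = trough + (v_end - trough) * np.exp(-td / 0.8)
    j2 = min(j1 + n_rec, len(v))
    if j2 > j1 and j1 > 0:
        v[j1:j2] = np.linspace(v[j1 - 1], base, j2 - j1)


def generate_recording_sweeps(
    fatigue: FatigueModel,
    n_sweeps: int = 5,
    sampling_rate: float = 25_000.0,
    seed: int = 0,
    sweep_duration: float = 0.65,
    step_onset: float = 0.1,
    step_offset: float = 0.6,
    baseline: float = -70.0,
    step_depolarization: float = 8.0,
    noise_sd: float = 0.3,
    noise_tau: float = 1e-3,
    ap_peak: float = 30.0,
    return_truth: bool = False,
):
    """Step-protocol sweeps containing AP trains with planted fatigue.

    Sweep k fires at a nominal instantaneous frequency ramping from ~5 to
    ~38 Hz across sweeps (emulating increasing current steps); ISIs are
    jittered by 8%.  The membrane baseline is −70 mV with 0.3 mV SD of
    exponentially correlated noise (τ = 1 ms), depolarized during the step.

    With ``return_truth`` the planted per-sweep spike times and target rise
    speeds are returned alongside the sweeps.
    """
    rng = np.random.default_rng(seed)
    n = int(round(sweep_duration * sampling_rate))
    dt = 1.0 / sampling_rate
    nominal = np.linspace(5.0, 38.0, n_sweeps)
    sweeps = []
    truth = []
    for si in range(n_sweeps):
        v = np.full(n, baseline)
        k_on, k_off = int(step_onset / dt), int(step_offset / dt)
        v[k_on:k_off] += step_depolarization
        v += ou_noise(sweep_duration, dt, noise_sd * math.sqrt(2.0), noise_tau,
                      seed=int(rng.integers(2**31)))
        t = step_onset + 0.015 + 0.005 * rng.random()
        prev = None
        planted = []
        while t < step_offset - 0.01:
            f_inst = None if prev is None else 1.0 / (t - prev)
            target = fatigue.speed_at(f_inst) + fatigue.within_noise_sd * rng.standard_normal()
            target = max(target, 30.0)
            k0 = int(round(t * sampling_rate))
            base_here = baseline + step_depolarization
            _insert_ap(v, k0, sampling_rate, base_here, ap_peak, target)
            planted.append({"time": t, "target_rise_speed": target, "f_inst": f_inst})
            prev = t
            isi = (1.0 / nominal[si]) * (1.0 + 0.08 * rng.standard_normal())
            t += max(isi, 0.004)
        sweeps.append(VoltageTrace(dt=dt, voltage=v))
        truth.append(planted)
    if return_truth:
        return sweeps, truth
    return sweeps


# ---------------------------------------------------------------------------
# Cohort synthesis


def _mix(z: np.ndarray, rho: float, eps: np.ndarray) -> np.ndarray:
    return rho * z + math.sqrt(1.0 - rho * rho) * eps


def generate_cohort(
    spec: CohortSpec,
    include_sweeps: bool = True,
    include_morphologies: bool = True,
) -> CohortBundle:
    """Draw a full synthetic cohort; deterministic for a fixed spec seed.

    Subject latents (TDL, first-AP rise speed, relative 20-40 Hz rise
    speed) are correlated with the standardized IQ score at the planted
    effect sizes; each neuron perturbs its subject's latents slightly.  The
    ground-truth ledger records every draw.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.iq_range
    a, b = (lo - spec.iq_mean) / spec.iq_sd, (hi - spec.iq_mean) / spec.iq_sd
    tn = sps.truncnorm(a, b, loc=spec.iq_mean, scale=spec.iq_sd)
    t_mean, t_var = tn.stats(moments="mv")
    iq = tn.ppf(rng.random(spec.n_subjects))
    z = (iq - float(t_mean)) / math.sqrt(float(t_var))

    rho_tdl = math.sqrt(spec.r2_iq_tdl)
    rho_rel = math.sqrt(spec.r2_iq_relrise)
    rho_first = math.sqrt(spec.r2_iq_first)
    tdl_s = spec.tdl_mean + spec.tdl_sd * _mix(z, rho_tdl, rng.standard_normal(spec.n_subjects))
    tdl_s = np.clip(tdl_s, 2000.0, 32000.0)
    first_s = spec.first_speed_mean + spec.first_speed_sd * _mix(
        z, rho_first, rng.standard_normal(spec.n_subjects)
    )
    first_s = np.clip(first_s, 120.0, 600.0)
    rel_s = spec.relrise_mean + spec.relrise_sd * _mix(
        z, rho_rel, rng.standard_normal(spec.n_subjects)
    )
    rel_s = np.clip(rel_s, 0.35, 0.99)
    n_neurons = np.minimum(1 + rng.poisson(spec.neurons_median - 1, spec.n_subjects),
                           spec.neurons_max)

    neurons: list[NeuronRecord] = []
    gt_neurons = []
    for s in range(spec.n_subjects):
        for j in range(n_neurons[s]):
            tdl_n = float(np.clip(tdl_s[s] * math.exp(0.08 * rng.standard_normal()),
                                  1500.0, 34000.0))
            first_n = max(first_s[s] + 10.0 * rng.standard_normal(), 100.0)
            rel_n = float(np.clip(rel_s[s] + 0.03 * rng.standard_normal(), 0.3, 1.0))
            fat = FatigueModel(
                first_ap_rise_speed=first_n,
                slowing_coefficient=(1.0 - rel_n) / 30.0,
                within_noise_sd=spec.within_noise_sd,
            )
            child_seed = int(rng.integers(2**31))
            morph = None
            if include_morphologies:
                morph = generate_branched_tree(
                    SyntheticTreeSpec(
                        target_tdl=tdl_n,
                        target_branch_points=max(1, round(tdl_n * BRANCH_POINTS_PER_UM)),
                        seed=child_seed,
                    )
                )
            sweeps: list[VoltageTrace] = []
            if include_sweeps:
                sweeps = generate_recording_sweeps(
                    fat,
                    n_sweeps=spec.n_sweeps,
                    sampling_rate=spec.sampling_rate,
                    seed=child_seed + 1,
                )
            neurons.append(
                NeuronRecord(subject=s, neuron=j, tdl=tdl_n, fatigue=fat,
                             morphology=morph, sweeps=sweeps)
            )
            gt_neurons.append(
                {"subject": s, "neuron": j, "tdl": tdl_n,
                 "first_ap_rise_speed": first_n, "relative_rise_20_40": rel_n,
                 "slowing_coefficient": fat.slowing_coefficient, "seed": child_seed}
            )

    subjects = pd.DataFrame({"subject": np.arange(spec.n_subjects), "iq": iq,
                             "n_neurons": n_neurons})
    ground_truth = {
        "planted": {
            "r2_iq_tdl": spec.r2_iq_tdl,
            "r2_iq_relrise": spec.r2_iq_relrise,
            "r2_iq_first": spec.r2_iq_first,
            "rho_iq_tdl": rho_tdl,
            "rho_iq_relrise": rho_rel,
            "rho_iq_first": rho_first,
        },
        "subjects": {
            "iq": iq.tolist(),
            "z": z.tolist(),
            "tdl": tdl_s.tolist(),
            "first_ap_rise_speed": first_s.tolist(),
            "relative_rise_20_40": rel_s.tolist(),
        },
        "neurons": gt_neurons,
    }
    return CohortBundle(spec=spec, subjects=subjects, neurons=neurons,
                        ground_truth=ground_truth)
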