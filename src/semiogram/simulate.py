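"""Synthetic three-sensor IMU walking trials with exact ground truth.

The generator emulates the 10-m out-and-back walking protocol: two
straight bouts separated by a half-revolution U-turn, recorded by foot
sensors and a lower-back sensor at 100 Hz.  It is a *timing* model, not a
biomechanical one: event times (IC/FC per foot) are laid out first from
the commanded stride time, double-stance fraction and swing asymmetry,
and minimal signal shapes are then painted around them —

* foot ML angular velocity: one raised-cosine lobe per swing (FC -> IC),
  amplitude scaled per side by ``amplitude_asymmetry``;
* foot accelerations: damped 15 Hz transient at each IC;
* trunk accelerations: stride-locked harmonic series whose even/odd mix
  per axis is chosen to produce healthy-like harmonic ratios, the ML axis
  scaled to a commanded RMS, the AP axis carrying an adjustable
  high-frequency "roughness" component;
* trunk craniocaudal angular velocity: optional constant drift plus one
  smooth pulse integrating to +-180 degrees at the trial midpoint.

Step count and cadence are laid out so that the commanded walking speed
(``step_length / (stride_time / 2)``), step length, double-stance
percentage and swing-time ratio are recovered by the analysis pipeline up
to discretisation of the 10-m path into whole steps.  Every trial is a
deterministic function of its spec (including the seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy import signal as sps

from .exceptions import GaitError
from .imu import ImuTrial, SensorStream
from .segmentation import FEET, GaitEvents

FOOT_SWING_AMPLITUDE_DPS = 300.0
FOOT_EVENT_DIP_DPS = 150.0  # negative trough at each FC/IC
FOOT_EVENT_DIP_WIDTH_S = 0.10
IC_TRANSIENT_AMPLITUDE = 8.0  # m/s^2
IC_TRANSIENT_FREQ_HZ = 15.0
IC_TRANSIENT_TAU_S = 0.05

# trunk harmonic amplitudes (m/s^2); even harmonics carry the step-locked
# biphasic content of AP/CC, odd harmonics the side-alternating ML content
TRUNK_CC_EVEN = {2: 1.50, 4: 0.45}
TRUNK_CC_ODD = {1: 0.33, 3: 0.15}
TRUNK_AP_EVEN = {2: 1.20, 4: 0.60, 6: 0.80, 8: 0.80, 10: 0.70}
TRUNK_AP_ODD = {1: 0.24, 3: 0.12}
TRUNK_ML_ODD_FRACTION = 0.868  # odd-harmonic power share of the ML axis
TRUNK_ACC_NOISE = 0.05
TRUNK_GYR_OSC = {1: 4.0, 2: 3.0, 3: 2.5, 4: 2.0}  # deg/s, all gyro axes
TRUNK_GYR_NOISE = 0.6
GYR_ROUGHNESS_SCALE = 4.0  # deg/s of gyro intermittency per m/s^2 of acc
TREMOR_HZ = 6.5
FOOT_GYR_NOISE = 1.2
FOOT_ACC_NOISE = 0.15

LEAD_S = 2.0  # quiet standing before/after the walk


@dataclass
class WalkerSpec:
    """Commanded gait of one synthetic trial.

    Defaults describe a healthy adult walking the 20-m out-and-back test:
    1.10 s strides of 0.68 m steps (1.24 m/s), 2.3% stride-time
    variability, 23.3% of the cycle in double stance, symmetric swings,
    trunk sway of 1.28 m/s^2 RMS and a 2.6 s U-turn.
    """

    stride_time_s: float = 1.10
    stride_time_cv: float = 0.023
    step_length_m: float = 0.68
    double_stance_fraction: float = 0.2334
    swing_asymmetry: float = 1.0
    amplitude_asymmetry: float = 1.0
    trunk_ml_rms_target: float = 1.28
    smoothness_noise: float = 0.15  # m/s^2 RMS of high-frequency AP jerkiness
    uturn_duration_s: float = 2.62
    turn_direction: int = 1  # +1 right turn, -1 left turn
    gyro_drift_dps: float = 0.0
    path_length_m: float = 20.0
    sample_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stride_time_s <= 0:
            raise GaitError("stride_time_s must be positive")
        if not 0.0 < self.double_stance_fraction < 0.5:
            raise GaitError("double_stance_fraction must be in (0, 0.5)")
        if not 0.0 < self.swing_asymmetry <= 1.0:
            raise GaitError("swing_asymmetry must be in (0, 1]")
        if self.swing_asymmetry < 1.0 - 2.0 * self.double_stance_fraction:
            raise GaitError(
                "infeasible spec: double stance plus swings exceed the cycle"
            )
        if self.turn_direction not in (1, -1):
            raise GaitError("turn_direction must be +1 or -1")

    @property
    def commanded_speed(self) -> float:
        """Walking speed implied by step length and cadence (m/s)."""
        return self.step_length_m / (self.stride_time_s / 2.0)


@dataclass
class GroundTruth:
    """Exact event times and commanded parameter targets of one trial."""

    events: GaitEvents
    uturn_start: float
    uturn_end: float
    stride_times: dict  # foot -> realized stride-time series
    double_stance_pct: np.ndarray  # realized per-cycle series (straight bouts)
    commanded: dict  # ParameterSet-style targets where defined

    @property
    def uturn_duration(self) -> float:
        return self.uturn_end - self.uturn_start

    def swing_ratio(self) -> float:
        means = [
            float(np.mean(self.events.ic[f][1:] - self.events.fc[f][1:]))
            for f in FEET
        ]
        return min(means) / max(means)

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "uturn": [self.uturn_start, self.uturn_end],
            "commanded": self.commanded,
            "ic": {f: self.events.ic[f].tolist() for f in FEET},
            "fc": {f: self.events.fc[f].tolist() for f in FEET},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _swing_times(spec: WalkerSpec) -> tuple:
    """Per-side swing durations meeting the asymmetry and stance targets."""
    total_swing = spec.stride_time_s * (1.0 - spec.double_stance_fraction)
    s_long = total_swing / (1.0 + spec.swing_asymmetry)
    s_short = spec.swing_asymmetry * s_long
    # left gets the shorter swing when asymmetric
    return s_short, s_long  # (left, right)


def _event_times(spec: WalkerSpec, rng: np.random.Generator) -> tuple:
    """Lay out merged IC grid, per-foot IC/FC arrays and the turn interval."""
    T = spec.stride_time_s
    q = T / 2.0
    s_left, s_right = _swing_times(spec)
    sw_mean = 0.5 * (s_left + s_right)

    n_straight = max(8, int(round(spec.path_length_m / spec.step_length_m)))
    k_turn = max(1, int(round((spec.uturn_duration_s - sw_mean) / q)) + 1)
    m_total = n_straight + k_turn

    # step-interval jitter; stride CV = step CV / sqrt(2) for summed steps
    cv_step = spec.stride_time_cv * np.sqrt(2.0)
    eps = np.clip(rng.standard_normal(m_total - 1), -3.0, 3.0)
    gaps = q * (1.0 + cv_step * eps)
    gaps = np.maximum(gaps, 0.3 * q)
    t0 = LEAD_S + s_right
    merged = t0 + np.concatenate([[0.0], np.cumsum(gaps)])

    ic = {FEET[0]: merged[0::2], FEET[1]: merged[1::2]}
    fc = {
        FEET[0]: ic[FEET[0]] - s_left,
        FEET[1]: ic[FEET[1]] - s_right,
    }
    i0 = n_straight // 2
    ts = merged[i0] - sw_mean / 2.0
    te = merged[i0 + k_turn - 1] + sw_mean / 2.0
    return GaitEvents(ic=ic, fc=fc), float(ts), float(te), n_straight


def _raised_cosine(t: np.ndarray, start: float, width: float) -> np.ndarray:
    u = (t - start) / width
    lobe = np.zeros_like(t)
    m = (u >= 0) & (u <= 1)
    lobe[m] = 0.5 * (1.0 - np.cos(2.0 * np.pi * u[m]))
    return lobe


def _stride_phase(t: np.ndarray, left_ic: np.ndarray, T: float) -> np.ndarray:
    """Piecewise-linear stride phase: 2*pi per left-foot stride."""
    phase_at_ic = 2.0 * np.pi * np.arange(left_ic.size)
    phi = np.interp(t, left_ic, phase_at_ic)
    before = t < left_ic[0]
    after = t > left_ic[-1]
    phi[before] = phase_at_ic[0] - 2.0 * np.pi * (left_ic[0] - t[before]) / T
    phi[after] = phase_at_ic[-1] + 2.0 * np.pi * (t[after] - left_ic[-1]) / T
    return phi


def _envelope(t: np.ndarray, on: float, off: float, ramp: float = 1.0) -> np.ndarray:
    env = np.clip((t - (on - ramp)) / ramp, 0.0, 1.0)
    env *= np.clip(((off + ramp) - t) / ramp, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * env))


def _harmonic_series(phase: np.ndarray, amplitudes: dict,
                     phases: dict | None = None) -> np.ndarray:
    out = np.zeros_like(phase)
    for k, a in amplitudes.items():
        out += a * np.cos(k * phase + (phases or {}).get(k, 0.4 * k))
    return out


def _bandpass_noise(rng: np.random.Generator, n: int, fs: float,
                    lo: float, hi: float, rms: float) -> np.ndarray:
    if rms <= 0:
        return np.zeros(n)
    x = rng.standard_normal(n)
    sos = sps.butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band",
                     output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y * (rms / np.sqrt(np.mean(y ** 2)))


def generate_trial(spec: WalkerSpec) -> tuple:
    """Synthesize one trial; returns (ImuTrial, GroundTruth)."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    events, ts, te, n_straight = _event_times(spec, rng)

    last_event = float(events.all_times()[-1])
    duration = last_event + LEAD_S
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    first_event = float(events.all_times()[0])
    env = _envelope(t, first_event, last_event)

    T = spec.stride_time_s
    phase = _stride_phase(t, events.ic[FEET[0]], T)

    sensors = {}
    # ---- feet ----------------------------------------------------------
    amp = {FEET[0]: FOOT_SWING_AMPLITUDE_DPS * spec.amplitude_asymmetry,
           FEET[1]: FOOT_SWING_AMPLITUDE_DPS}
    for foot in FEET:
        gyr = np.zeros((n, 3))
        acc = np.zeros((n, 3))
        for f, i in zip(events.fc[foot], events.ic[foot]):
            gyr[:, 1] += amp[foot] * _raised_cosine(t, f, i - f)
            # physiological negative troughs centred on the events
            for ev in (f, i):
                gyr[:, 1] -= FOOT_EVENT_DIP_DPS * _raised_cosine(
                    t, ev - FOOT_EVENT_DIP_WIDTH_S / 2, FOOT_EVENT_DIP_WIDTH_S
                )
            dt = t - i
            m = (dt >= 0) & (dt < 0.3)
            acc[m, 0] += (IC_TRANSIENT_AMPLITUDE
                          * np.exp(-dt[m] / IC_TRANSIENT_TAU_S)
                          * np.sin(2 * np.pi * IC_TRANSIENT_FREQ_HZ * dt[m]))
            acc[m, 2] += (0.6 * IC_TRANSIENT_AMPLITUDE
                          * np.exp(-dt[m] / IC_TRANSIENT_TAU_S)
                          * np.cos(2 * np.pi * IC_TRANSIENT_FREQ_HZ * dt[m]))
        gyr += FOOT_GYR_NOISE * rng.standard_normal((n, 3))
        acc += FOOT_ACC_NOISE * rng.standard_normal((n, 3))
        sensors[foot] = SensorStream(acc=acc, gyr=gyr)

    # ---- trunk ---------------------------------------------------------
    acc = np.zeros((n, 3))
    acc[:, 0] = env * _harmonic_series(phase, TRUNK_AP_EVEN | TRUNK_AP_ODD)
    acc[:, 0] += _bandpass_noise(rng, n, fs, 4.0, 9.0,
                                 spec.smoothness_noise) * env
    acc[:, 2] = env * _harmonic_series(phase, TRUNK_CC_EVEN | TRUNK_CC_ODD)

    # ML axis: odd-dominant mix rescaled to the commanded RMS
    noise_var = TRUNK_ACC_NOISE ** 2
    target_power = max(spec.trunk_ml_rms_target ** 2 - noise_var, 1e-6)
    odd_amp = np.sqrt(2.0 * target_power * TRUNK_ML_ODD_FRACTION)
    even_amp = np.sqrt(2.0 * target_power * (1.0 - TRUNK_ML_ODD_FRACTION))
    acc[:, 1] = env * _harmonic_series(
        phase, {1: odd_amp, 2: even_amp}, phases={1: 0.0, 2: 0.9}
    )
    acc += TRUNK_ACC_NOISE * rng.standard_normal((n, 3))

    gyr = np.zeros((n, 3))
    for ax in range(3):
        gyr[:, ax] = env * _harmonic_series(
            phase, TRUNK_GYR_OSC, phases={1: 0.3 * ax, 2: 0.8 + 0.3 * ax}
        )
        # movement intermittency shared with the AP-acceleration roughness:
        # a tremor-like narrowband oscillation around 6.5 Hz
        amp = GYR_ROUGHNESS_SCALE * spec.smoothness_noise
        gyr[:, ax] += (env * amp * np.sqrt(2.0)
                       * np.cos(2 * np.pi * TREMOR_HZ * t + 1.1 * ax))
    gyr += TRUNK_GYR_NOISE * rng.standard_normal((n, 3))
    # U-turn pulse integrating to +-180 deg, plus constant sensor drift
    turn_amp = 2.0 * 180.0 / (te - ts)
    gyr[:, 2] += (spec.turn_direction * turn_amp * _raised_cosine(t, ts, te - ts)
                  + spec.gyro_drift_dps)
    sensors["lower_back"] = SensorStream(acc=acc, gyr=gyr)

    trial = ImuTrial(
        sample_rate=fs,
        sensors=sensors,
        meta={"generator": "semiogram.simulate", "seed": spec.seed,
              "spec": {k: getattr(spec, k) for k in spec.__dataclass_fields__}},
    )

    stride_times = {f: np.diff(events.ic[f]) for f in FEET}
    ds = _realized_double_stance(events, ts, te)
    commanded = {
        "V": spec.path_length_m / (n_straight * T / 2.0),
        "StrT": T,
        "CV_StrT": 100.0 * spec.stride_time_cv,
        "SteL": spec.path_length_m / n_straight,
        "dstT": 100.0 * spec.double_stance_fraction,
        "swTr": spec.swing_asymmetry,
        "UtrT": te - ts,
        "RMS_aML": spec.trunk_ml_rms_target,
    }
    truth = GroundTruth(
        events=events, uturn_start=ts, uturn_end=te,
        stride_times=stride_times, double_stance_pct=ds, commanded=commanded,
    )
    return trial, truth


def _realized_double_stance(events: GaitEvents, ts: float, te: float) -> np.ndarray:
    other = {FEET[0]: FEET[1], FEET[1]: FEET[0]}
    out = []
    for foot in FEET:
        ics = events.ic[foot]
        for a, b in zip(ics[:-1], ics[1:]):
            if not (b <= ts or a >= te):
                continue
            contra = other[foot]
            fc_c = events.fc[contra][events.fc[contra] > a]
            ic_c = events.ic[contra][(events.ic[contra] > a)
                                     & (events.ic[contra] < b)]
            fc_o = events.fc[foot][events.fc[foot] > a]
            if fc_c.size and ic_c.size and fc_o.size:
                ds = (fc_c[0] - a) + (fc_o[0] - ic_c[0])
                out.append(100.0 * ds / (b - a))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SimulatedTrial:
    subject: str
    session: str
    trial: int
    imu: ImuTrial
    truth: GroundTruth
    spec: WalkerSpec


def cohort(
    specs: Iterable[WalkerSpec],
    trials_per_session: int = 2,
    sessions: int = 2,
    seed: int = 0,
    within_subject_noise: float = 0.0,
) -> list:
    """Generate a labelled cohort: subjects x sessions x repeated trials.

    ``within_subject_noise`` is the relative SD applied to each subject's
    stride time and step length independently per trial, emulating
    test-retest variability; 0 makes the repeated trials of a visit
    bit-identical (no repeat noise of any kind).
    """
    specs = list(specs)
    if not specs:
        raise GaitError("cohort needs at least one subject spec")
    out = []
    for si, spec in enumerate(specs):
        for sess in range(sessions):
            for tr in range(trials_per_session):
                key = [seed, si, sess] if within_subject_noise == 0 else \
                    [seed, si, sess, tr]
                ss = np.random.SeedSequence(key)
                child = int(ss.generate_state(1)[0] % (2 ** 31))
                rng = np.random.default_rng(child)
                factor_t = 1.0 + within_subject_noise * rng.standard_normal()
                factor_l = 1.0 + within_subject_noise * rng.standard_normal()
                variant = replace(
                    spec,
                    stride_time_s=spec.stride_time_s * max(factor_t, 0.5),
                    step_length_m=spec.step_length_m * max(factor_l, 0.5),
                    seed=child,
                )
                imu, truth = generate_trial(variant)
                imu.meta.update(
                    subject=f"S{si:02d}", session=f"M{6 * sess}", trial=tr
                )
                out.append(
                    SimulatedTrial(
                        subject=f"S{si:02d}", session=f"M{6 * sess}",
                        trial=tr, imu=imu, truth=truth, spec=variant,
                    )
                )
    return out
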