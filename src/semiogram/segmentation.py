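"""Gait-event detection, U-turn delineation and trial segmentation.

The out-and-back 10-m walking test is segmented into

* per-foot Initial Contact (IC) / Final Contact (FC) events detected from
  the foot-mounted gyroscopes,
* the U-turn interval found by integrating the trunk craniocaudal angular
  velocity into an angular position and correcting its linear drift under
  the assumption that the turn starts at 0 deg and ends at 180 deg,
* the set of valid strides and the two straight-walking windows that every
  downstream parameter consumes (U-turn, initiation stride and terminal
  stride excluded).

Event detector model: during swing the foot rotates rapidly in the sagittal
plane, producing one prominent lobe per stride in the mediolateral angular
velocity.  FC is taken as the last local minimum before the swing peak and
IC as the first local minimum after it, on a 10 Hz zero-phase low-passed
signal.  The prominence threshold adapts to the signal so that heavily
degraded, low-amplitude gait is still segmented.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, signal

from .exceptions import (
    DegenerateSegmentationError,
    InsufficientGaitError,
    NoUTurnError,
)
from .imu import ImuTrial

logger = logging.getLogger(__name__)

FEET = ("left_foot", "right_foot")

# event-detector constants
LOWPASS_HZ = 10.0
PROMINENCE_DPS = 50.0  # absolute swing-peak prominence, deg/s
ADAPTIVE_FRACTION = 0.4  # fallback: 0.4 x max prominence
MIN_PEAK_SEPARATION_S = 0.45  # strides are >= 0.9 s apart per foot
MERGE_TOLERANCE_S = 0.2
MIN_STRIDES_PER_FOOT = 4

# U-turn constants
TURN_ANGLE_MIN_DEG = 120.0
ANGLE_SMOOTH_HZ = 0.5
RATE_BOUNDARY_FRACTION = 0.02  # boundary: angular rate falls to 2% of peak
MAX_UTURN_TRIAL_FRACTION = 0.8


@dataclass
class GaitEvents:
    """Per-foot ordered Initial/Final Contact times in seconds."""

    ic: dict  # foot -> np.ndarray of times
    fc: dict  # foot -> np.ndarray of times

    def all_times(self) -> np.ndarray:
        return np.sort(
            np.concatenate(
                [self.ic[f] for f in FEET] + [self.fc[f] for f in FEET]
            )
        )

    def shifted(self, dt: float) -> "GaitEvents":
        return GaitEvents(
            ic={f: self.ic[f] + dt for f in FEET},
            fc={f: self.fc[f] + dt for f in FEET},
        )

    def mirrored(self) -> "GaitEvents":
        """Relabel left as right and vice versa."""
        swap = {FEET[0]: FEET[1], FEET[1]: FEET[0]}
        return GaitEvents(
            ic={swap[f]: self.ic[f] for f in FEET},
            fc={swap[f]: self.fc[f] for f in FEET},
        )


@dataclass
class UTurnInterval:
    """U-turn boundaries plus the drift-corrected trunk yaw trace (deg)."""

    start: float
    end: float
    time: np.ndarray
    angle_trace: np.ndarray  # drift-corrected, sign-folded so the turn is +180

    @property
    def duration(self) -> float:
        return self.end - self.start

    def angle_at(self, t: float) -> float:
        return float(np.interp(t, self.time, self.angle_trace))

    @property
    def displacement(self) -> float:
        """Angular displacement between the detected boundaries (deg)."""
        return abs(self.angle_at(self.end) - self.angle_at(self.start))


@dataclass
class TrialSegmentation:
    """Valid strides, straight-walk windows and steps of one trial."""

    uturn: UTurnInterval
    straight_windows: list  # [(t0, t1), ...], 1 or 2 windows
    strides: list  # [(foot, ic_start, ic_end), ...] sorted by start
    steps: np.ndarray  # merged IC times of both feet outside the U-turn
    events: GaitEvents | None = field(default=None, repr=False)

    def stride_times(self) -> np.ndarray:
        return np.array([e - s for _, s, e in self.strides])

    def strides_of(self, foot: str) -> list:
        return [(f, s, e) for f, s, e in self.strides if f == foot]


def _local_min_before(x: np.ndarray, peak: int, lo: int) -> int | None:
    """First strict local minimum met while walking left from ``peak``."""
    for i in range(peak - 1, max(lo, 1), -1):
        if x[i] <= x[i - 1] and x[i] <= x[i + 1]:
            return i
    return None


def _local_min_after(x: np.ndarray, peak: int, hi: int) -> int | None:
    for i in range(peak + 1, min(hi, x.size - 1)):
        if x[i] <= x[i - 1] and x[i] <= x[i + 1]:
            return i
    return None


def _lowpass(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        return x
    sos = signal.butter(4, cutoff_hz / nyq, output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_gait_events(trial: ImuTrial) -> GaitEvents:
    """Detect per-foot IC/FC times from the foot mediolateral gyroscopes."""
    fs = trial.sample_rate
    t = trial.time
    ic, fc = {}, {}
    for foot in FEET:
        raw = trial.sensor(foot).axis("gyr", "ML")
        x = _lowpass(raw, LOWPASS_HZ, fs)
        # orient so swing lobes are positive
        if np.max(x, initial=0.0) < np.max(-x, initial=0.0):
            x = -x
        distance = max(1, int(MIN_PEAK_SEPARATION_S * fs))
        peaks, props = signal.find_peaks(
            x, prominence=PROMINENCE_DPS, height=PROMINENCE_DPS,
            distance=distance,
        )
        if peaks.size < MIN_STRIDES_PER_FOOT + 1 and x.max(initial=0.0) > 0:
            adaptive = ADAPTIVE_FRACTION * float(x.max())
            if adaptive > 0:
                peaks, props = signal.find_peaks(
                    x, prominence=adaptive, height=adaptive, distance=distance
                )
        peaks = _merge_close_peaks(peaks, props.get("prominences"), fs)
        if peaks.size - 1 < MIN_STRIDES_PER_FOOT:
            raise InsufficientGaitError(
                f"insufficient gait: {max(peaks.size - 1, 0)} strides on {foot}"
            )
        half = int(np.median(np.diff(peaks)) / 2) if peaks.size > 1 else x.size
        ic_i, fc_i = [], []
        for p in peaks:
            j = _local_min_before(x, p, p - half)
            k = _local_min_after(x, p, p + half)
            if j is None or k is None:
                continue
            fc_i.append(j)
            ic_i.append(k)
        ic[foot] = t[np.asarray(ic_i, dtype=int)]
        fc[foot] = t[np.asarray(fc_i, dtype=int)]
        if ic[foot].size - 1 < MIN_STRIDES_PER_FOOT:
            raise InsufficientGaitError(
                f"insufficient gait: {max(ic[foot].size - 1, 0)} strides on {foot}"
            )
    return GaitEvents(ic=ic, fc=fc)


def _merge_close_peaks(
    peaks: np.ndarray, prominences: np.ndarray | None, fs: float
) -> np.ndarray:
    """Merge same-foot peaks closer than the tolerance, keeping the taller."""
    if peaks.size < 2 or prominences is None:
        return peaks
    tol = MERGE_TOLERANCE_S * fs
    keep = []
    i = 0
    while i < peaks.size:
        j = i
        while j + 1 < peaks.size and peaks[j + 1] - peaks[j] < tol:
            j += 1
        group = slice(i, j + 1)
        keep.append(peaks[group][np.argmax(prominences[group])])
        i = j + 1
    return np.asarray(keep)


def detect_uturn(trial: ImuTrial) -> UTurnInterval:
    """Delineate the half-revolution U-turn from the trunk yaw rate.

    The craniocaudal angular velocity of the lower-back sensor is
    integrated (trapezoidal rule) into an angular position.  Linear
    gyroscope drift is removed by fitting the line through the pre- and
    post-turn plateaus under the assumption that the turn begins at 0 deg
    and ends at 180 deg.  Boundaries are placed where the smoothed angular
    rate decays to 5% of its turn-peak value, i.e. the inflection of the
    yaw trace out of / back into its plateaus.
    """
    fs = trial.sample_rate
    t = trial.time
    gz = trial.sensor("lower_back").axis("gyr", "CC")
    angle = integrate.cumulative_trapezoid(gz, t, initial=0.0)
    if np.max(np.abs(angle)) < TURN_ANGLE_MIN_DEG:
        raise NoUTurnError(
            f"no U-turn: max |angle| = {np.max(np.abs(angle)):.0f} deg < "
            f"{TURN_ANGLE_MIN_DEG:.0f} deg"
        )

    # coarse turn region from the smoothed, baseline-free yaw rate
    rate_s = _lowpass(gz - np.median(gz), ANGLE_SMOOTH_HZ, fs)
    pk = int(np.argmax(np.abs(rate_s)))
    sgn = np.sign(rate_s[pk]) or 1.0
    thresh = 0.25 * abs(rate_s[pk])
    i0 = pk
    while i0 > 0 and abs(rate_s[i0 - 1]) > thresh:
        i0 -= 1
    i1 = pk
    while i1 < rate_s.size - 1 and abs(rate_s[i1 + 1]) > thresh:
        i1 += 1

    # plateau means before/after the coarse region
    margin = int(0.5 * fs)
    pre = slice(0, max(i0 - margin, 2))
    post = slice(min(i1 + margin, gz.size - 2), gz.size)
    a_pre, t_pre = float(np.mean(angle[pre])), float(np.mean(t[pre]))
    a_post, t_post = float(np.mean(angle[post])), float(np.mean(t[post]))

    # drift line through (t_pre, a_pre) and (t_post, a_post - 180*sign)
    slope = (a_post - 180.0 * sgn - a_pre) / (t_post - t_pre)
    corrected = angle - (a_pre + slope * (t - t_pre))
    folded = corrected * sgn  # left turns folded onto +180

    smooth = _lowpass(folded, ANGLE_SMOOTH_HZ, fs)
    vel = np.gradient(smooth, t)
    pk = i0 + int(np.argmax(vel[i0 : i1 + 1])) if i1 > i0 else pk
    vth = RATE_BOUNDARY_FRACTION * vel[pk]
    s = pk
    while s > 0 and vel[s - 1] > vth:
        s -= 1
    e = pk
    while e < vel.size - 1 and vel[e + 1] > vth:
        e += 1
    return UTurnInterval(
        start=float(t[s]), end=float(t[e]), time=t, angle_trace=folded
    )


def segment_trial(
    events: GaitEvents, uturn: UTurnInterval, trial_span: tuple
) -> TrialSegmentation:
    """Assemble valid strides, straight windows and steps.

    Excluded from ``strides``: any stride overlapping the U-turn interval
    and the first (initiation) stride of each foot.  ``straight_windows``
    additionally exclude the terminal stride of each foot, because the
    trunk-signal parameters should not see gait termination.
    """
    t0, t1 = trial_span
    span = t1 - t0
    if span <= 0:
        raise DegenerateSegmentationError("empty trial span")
    if uturn.duration > MAX_UTURN_TRIAL_FRACTION * span:
        raise DegenerateSegmentationError(
            "degenerate segmentation: U-turn covers "
            f"{100 * uturn.duration / span:.0f}% of the trial"
        )

    strides = []
    for foot in FEET:
        ics = events.ic[foot]
        for a, b in zip(ics[:-1], ics[1:]):
            if b <= uturn.start or a >= uturn.end:
                strides.append((foot, float(a), float(b)))
    # drop the initiation stride of each foot
    for foot in FEET:
        own = [s for s in strides if s[0] == foot]
        if own:
            strides.remove(min(own, key=lambda s: s[1]))
    strides.sort(key=lambda s: s[1])
    if not strides:
        raise DegenerateSegmentationError(
            "degenerate segmentation: no valid strides outside the U-turn"
        )

    merged_ic = np.sort(np.concatenate([events.ic[f] for f in FEET]))
    steps = merged_ic[(merged_ic < uturn.start) | (merged_ic > uturn.end)]
    if steps.size < 4:
        raise DegenerateSegmentationError(
            f"degenerate segmentation: only {steps.size} steps outside the U-turn"
        )

    windows = []
    pre = [s for s in strides if s[2] <= uturn.start]
    post = [s for s in strides if s[1] >= uturn.end]
    if pre:
        windows.append((min(s[1] for s in pre), uturn.start))
    if post:
        # exclude the terminal stride of each foot from the trunk window
        end = t1
        for foot in FEET:
            own = [s for s in post if s[0] == foot]
            if len(own) > 1:
                end = min(end, max(own, key=lambda s: s[2])[1])
        start = min(s[1] for s in post)
        if end > start:
            windows.append((uturn.end, end))
    if len(windows) < 2:
        warnings.warn(
            "only one straight-walking window available", stacklevel=2
        )
    if not windows:
        raise DegenerateSegmentationError(
            "degenerate segmentation: no straight-walking window"
        )
    return TrialSegmentation(
        uturn=uturn,
        straight_windows=windows,
        strides=strides,
        steps=steps,
        events=events,
    )


def segment(trial: ImuTrial) -> TrialSegmentation:
    """Full segmentation pipeline for one trial."""
    events = detect_gait_events(trial)
    uturn = detect_uturn(trial)
    return segment_trial(events, uturn, (0.0, trial.duration))


def write_events(events: GaitEvents, path: str) -> None:
    """Export events as a 3-column delimited file: time_s, foot, event_type."""
    rows = []
    for foot in FEET:
        rows += [(t, foot, "IC") for t in events.ic[foot]]
        rows += [(t, foot, "FC") for t in events.fc[foot]]
    rows.sort()
    with open(path, "w") as fh:
        fh.write("time_s\tfoot\tevent_type\n")
        for t, foot, kind in rows:
            fh.write(f"{t:.4f}\t{foot}\t{kind}\n")
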