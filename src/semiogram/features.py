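"""The 17 gait parameters computed from a segmented trial.

Eight families of measures are derived from the three-sensor recording of a
10-m out-and-back walk:

=============== ==========================================================
V               average speed: path length / walking time excluding U-turn
StrT, UtrT      springiness: mean stride time, U-turn duration
SPARC_G, LDLJ_A smoothness: spectral arc length of the trunk gyration
                magnitude; log dimensionless jerk of the trunk AP
                acceleration
CV_StrT, CV_dstT, P1_aCC, P2_aCC
                steadiness: stride-time and double-stance-time variation
                coefficients; step/stride autocorrelation peaks of the
                trunk craniocaudal acceleration
SteL            sturdiness: path length / number of steps
RMS_aML         stability: zero-referenced RMS of the trunk ML acceleration
iHR_aAP/ML/CC, P1P2_aCC, swTr
                symmetry: improved harmonic ratios per axis, P1/P2 ratio,
                min/max swing-time ratio
dstT            synchronization: double-stance percentage of the cycle
=============== ==========================================================

Trunk measures use only the straight-walking windows (U-turn, initiation
and terminal strides excluded).  All signals are assumed anatomically
aligned, accelerations in m/s^2, angular velocities in deg/s.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from . import segmentation as seg_mod
from .exceptions import (
    DegenerateSignalError,
    GaitError,
    InsufficientDataError,
)
from .imu import ImuTrial
from .segmentation import FEET, GaitEvents, TrialSegmentation, UTurnInterval

PARAMETER_NAMES = (
    "V", "StrT", "UtrT", "SPARC_G", "LDLJ_A", "CV_StrT", "CV_dstT",
    "P1_aCC", "P2_aCC", "SteL", "RMS_aML", "iHR_aAP", "iHR_aML", "iHR_aCC",
    "P1P2_aCC", "swTr", "dstT",
)

PARAMETER_UNITS = {
    "V": "m/s", "StrT": "s", "UtrT": "s", "SPARC_G": "-", "LDLJ_A": "-",
    "CV_StrT": "%", "CV_dstT": "%", "P1_aCC": "-", "P2_aCC": "-",
    "SteL": "m", "RMS_aML": "m/s^2", "iHR_aAP": "%", "iHR_aML": "%",
    "iHR_aCC": "%", "P1P2_aCC": "-", "swTr": "-", "dstT": "%",
}

# SPARC defaults: zero-padded spectrum, 20 Hz ceiling, 5% amplitude floor
SPARC_PADLEVEL = 4
SPARC_FC_HZ = 20.0
SPARC_AMP_THRESHOLD = 0.05

IHR_N_HARMONICS = 20
JERK_LOWPASS_HZ = 10.0


@dataclass
class ParameterSet:
    """The 17 named gait parameters of one trial (native units)."""

    V: float
    StrT: float
    UtrT: float
    SPARC_G: float
    LDLJ_A: float
    CV_StrT: float
    CV_dstT: float
    P1_aCC: float
    P2_aCC: float
    SteL: float
    RMS_aML: float
    iHR_aAP: float
    iHR_aML: float
    iHR_aCC: float
    P1P2_aCC: float
    swTr: float
    dstT: float

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_dict(), name="value")

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_csv_row(self) -> pd.DataFrame:
        """One wide row with columns exactly the 17 parameter names."""
        return pd.DataFrame([self.to_dict()], columns=list(PARAMETER_NAMES))

    @classmethod
    def from_dict(cls, values: dict) -> "ParameterSet":
        missing = set(PARAMETER_NAMES) - set(values)
        if missing:
            raise GaitError(f"incomplete parameter set: missing {sorted(missing)}")
        return cls(**{k: float(values[k]) for k in PARAMETER_NAMES})


# ---------------------------------------------------------------------------
# spatio-temporal parameters


def velocity(seg: TrialSegmentation, path_length: float = 20.0) -> float:
    """Average speed: path length over walking time, U-turn excluded.

    The walking time runs from the first to the last detected gait event,
    minus the U-turn duration.
    """
    if path_length <= 0:
        raise GaitError("path_length must be positive")
    times = seg.events.all_times() if seg.events is not None else seg.steps
    effective = (times[-1] - times[0]) - seg.uturn.duration
    if effective <= 0:
        raise GaitError("invalid segmentation: non-positive walking time")
    return path_length / effective


def stride_time(seg: TrialSegmentation) -> float:
    """Mean IC-to-next-IC duration, both feet pooled, valid strides only."""
    st = seg.stride_times()
    if st.size < 2:
        raise InsufficientDataError("insufficient strides for stride time")
    return float(np.mean(st))


def uturn_time(uturn: UTurnInterval) -> float:
    return float(uturn.duration)


def step_length(seg: TrialSegmentation, path_length: float = 20.0) -> float:
    """Path length divided by the step count outside the U-turn."""
    n = int(seg.steps.size)
    if n == 0:
        raise InsufficientDataError("no steps outside the U-turn")
    return path_length / n


def variation_coefficient(values: np.ndarray) -> float:
    """Coefficient of variation in percent (sample SD over mean)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InsufficientDataError("insufficient data for CV (need >= 3)")
    mean = values.mean()
    if mean <= 0:
        raise GaitError("CV undefined for non-positive mean")
    return float(100.0 * values.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# smoothness


def sparc(x: np.ndarray, fs: float,
          padlevel: int = SPARC_PADLEVEL,
          fc: float = SPARC_FC_HZ,
          amp_threshold: float = SPARC_AMP_THRESHOLD) -> float:
    """Spectral arc length of one movement-speed profile.

    The magnitude spectrum is normalised by its zero-frequency value and an
    adaptive cutoff is chosen as the last frequency below ``fc`` at which
    the normalised spectrum still exceeds ``amp_threshold``; the arc length
    of the spectrum over the (normalised) band is returned, negated, so
    that more negative values mean a less smooth movement.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 or not np.any(x):
        raise DegenerateSignalError("degenerate spectrum: all-zero signal")
    nfft = int(2 ** np.ceil(np.log2(x.size) + padlevel))
    freq = np.arange(nfft) * fs / nfft
    mag = np.abs(np.fft.fft(x, nfft))
    sel = freq <= fc
    f_sel, m_sel = freq[sel], mag[sel] / mag[sel].max()
    above = np.nonzero(m_sel >= amp_threshold)[0]
    f_cut, m_cut = f_sel[: above[-1] + 1], m_sel[: above[-1] + 1]
    df = np.diff(f_cut) / (f_cut[-1] - f_cut[0])
    dm = np.diff(m_cut)
    return float(-np.sum(np.sqrt(df ** 2 + dm ** 2)))


def sparc_windows(trunk_gyr: np.ndarray, windows_idx: list, fs: float) -> float:
    """Duration-weighted SPARC of the trunk gyration magnitude per window."""
    vals, weights = [], []
    for i0, i1 in windows_idx:
        if (i1 - i0) / fs < 2.0:
            continue
        mag = np.linalg.norm(trunk_gyr[i0:i1], axis=1)
        vals.append(sparc(mag, fs))
        weights.append(i1 - i0)
    if not vals:
        raise InsufficientDataError("no straight window >= 2 s for SPARC")
    return float(np.average(vals, weights=weights))


def ldlj(a: np.ndarray, fs: float,
         lowpass: float | None = JERK_LOWPASS_HZ) -> float:
    """Log dimensionless jerk of one acceleration window.

    ``-ln( (T / a_peak^2) * integral(jerk^2) )`` with the jerk obtained by
    centred finite differences on the low-passed signal (differentiation
    amplifies noise; pass ``lowpass=None`` to skip the filter).
    """
    a = np.asarray(a, dtype=float)
    if a.size < 5:
        raise InsufficientDataError("window too short for LDLJ")
    a_f = seg_mod._lowpass(a, lowpass, fs) if lowpass else a
    peak = np.max(np.abs(a_f))
    if peak == 0:
        raise DegenerateSignalError("degenerate signal: zero peak acceleration")
    jerk = np.gradient(a_f, 1.0 / fs)
    T = a.size / fs
    integral = np.trapezoid(jerk ** 2, dx=1.0 / fs)
    return float(-np.log(T * integral / peak ** 2))


def ldlj_windows(trunk_ap: np.ndarray, windows_idx: list, fs: float) -> float:
    vals, weights = [], []
    for i0, i1 in windows_idx:
        if (i1 - i0) / fs < 2.0:
            continue
        vals.append(ldlj(trunk_ap[i0:i1], fs))
        weights.append(i1 - i0)
    if not vals:
        raise InsufficientDataError("no straight window >= 2 s for LDLJ")
    return float(np.average(vals, weights=weights))


# ---------------------------------------------------------------------------
# regularity and symmetry of the trunk signal


def unbiased_autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Unbiased, normalised autocorrelation coefficients for lags 0..max_lag."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    denom = np.dot(x, x) / n
    if denom == 0:
        raise DegenerateSignalError("degenerate signal: zero variance")
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        out[k] = np.dot(x[: n - k], x[k:]) / (n - k) / denom
    return out


def autocorr_peaks(
    x: np.ndarray, fs: float, step_lag: float, stride_lag: float
) -> tuple:
    """First (step) and second (stride) autocorrelation peaks of one window.

    P1 is the maximum coefficient for lags in ``step_lag * [0.5, 1.5]``, P2
    in ``stride_lag * [0.75, 1.25]``.
    """
    n = np.asarray(x).size
    hi = int(round(1.25 * stride_lag * fs))
    if n < 2 * stride_lag * fs:
        raise InsufficientDataError(
            "insufficient window for autocorrelation peaks"
        )
    rho = unbiased_autocorrelation(x, min(hi, n - 2))
    lags = np.arange(rho.size) / fs

    def peak(lo_t, hi_t):
        m = (lags >= lo_t) & (lags <= hi_t)
        if not m.any():
            raise InsufficientDataError("empty autocorrelation search window")
        return float(rho[m].max())

    p1 = peak(0.5 * step_lag, 1.5 * step_lag)
    p2 = peak(0.75 * stride_lag, 1.25 * stride_lag)
    return p1, p2


def autocorr_peaks_windows(
    trunk_cc: np.ndarray, windows_idx: list, fs: float,
    step_lag: float, stride_lag: float,
) -> tuple:
    p1s, p2s, weights = [], [], []
    for i0, i1 in windows_idx:
        if (i1 - i0) < 2 * stride_lag * fs:
            continue
        p1, p2 = autocorr_peaks(trunk_cc[i0:i1], fs, step_lag, stride_lag)
        p1s.append(p1)
        p2s.append(p2)
        weights.append(i1 - i0)
    if not p1s:
        raise InsufficientDataError("no window long enough for autocorrelation")
    return (
        float(np.average(p1s, weights=weights)),
        float(np.average(p2s, weights=weights)),
    )


def rms_ml(trunk_ml: np.ndarray, windows_idx: list) -> float:
    """Zero-referenced RMS of the trunk ML acceleration over the windows."""
    chunks = [trunk_ml[i0:i1] for i0, i1 in windows_idx]
    samples = np.concatenate(chunks) if chunks else np.array([])
    if samples.size == 0:
        raise InsufficientDataError("no straight-window samples for RMS")
    return float(np.sqrt(np.mean(samples ** 2)))


def ihr(
    x: np.ndarray, fs: float, strides: list, axis: str,
    n_harmonics: int = IHR_N_HARMONICS,
) -> float:
    """Improved harmonic ratio of one trunk acceleration axis, in percent.

    For each valid stride the signal segment between consecutive
    ipsilateral ICs is expanded into its stride-locked Fourier series
    (harmonics 1..``n_harmonics``); the index is the power in the intrinsic
    harmonics (even for AP/CC, odd for ML) over the total harmonic power,
    averaged across strides.
    """
    if axis not in ("AP", "ML", "CC"):
        raise GaitError(f"unknown axis {axis!r}")
    intrinsic_even = axis in ("AP", "CC")
    usable = []
    for _, a, b in strides:
        i0, i1 = int(round(a * fs)), int(round(b * fs))
        if i1 - i0 < 2 * n_harmonics:
            warnings.warn("stride too short for harmonic analysis; skipped",
                          stacklevel=2)
            continue
        seg = np.asarray(x[i0:i1], dtype=float)
        seg = seg - seg.mean()
        spec = np.fft.rfft(seg)
        k = np.arange(1, min(n_harmonics, spec.size - 1) + 1)
        power = np.abs(spec[k]) ** 2
        total = power.sum()
        if total == 0:
            continue
        mask = (k % 2 == 0) if intrinsic_even else (k % 2 == 1)
        usable.append(100.0 * power[mask].sum() / total)
    if len(usable) < 3:
        raise InsufficientDataError(
            "insufficient strides for harmonic ratio (need >= 3)"
        )
    return float(np.mean(usable))


# ---------------------------------------------------------------------------
# bilateral timing


def swing_times(events: GaitEvents, seg: TrialSegmentation) -> dict:
    """Per-foot FC -> next-IC durations for swings inside valid strides."""
    out = {}
    for foot in FEET:
        valid = seg.strides_of(foot)
        spans = [(a, b) for _, a, b in valid]
        sw = []
        for f in events.fc[foot]:
            nxt = events.ic[foot][events.ic[foot] > f]
            if nxt.size == 0:
                continue
            i = float(nxt[0])
            if any(a < i <= b + 1e-9 for a, b in spans):
                sw.append(i - f)
        out[foot] = np.asarray(sw)
    return out


def symmetry_ratios(
    events: GaitEvents, seg: TrialSegmentation, p1: float, p2: float
) -> tuple:
    """(swTr, P1P2_aCC): min/max mean swing-time ratio and P1/P2."""
    sw = swing_times(events, seg)
    means = []
    for foot in FEET:
        if sw[foot].size < 2:
            raise InsufficientDataError(f"fewer than 2 swings on {foot}")
        means.append(float(np.mean(sw[foot])))
    sw_ratio = min(means) / max(means)
    if p2 == 0:
        raise GaitError("undefined ratio: P2 = 0")
    return sw_ratio, p1 / p2


def double_stance(events: GaitEvents, seg: TrialSegmentation) -> tuple:
    """(dstT %, per-cycle %-series) from the valid stride cycles.

    Each gait cycle contains two double-support periods, each spanning from
    the IC of one foot to the FC of the contralateral foot; their summed
    duration over the cycle time gives the cycle's double-stance
    percentage.
    """
    other = {FEET[0]: FEET[1], FEET[1]: FEET[0]}
    per_cycle = []
    n_discarded = 0
    for foot, a, b in seg.strides:
        # double support 1: own IC (a) -> contralateral FC
        # double support 2: contralateral IC -> own FC
        contra = other[foot]
        fc_c = events.fc[contra][events.fc[contra] > a]
        ic_c = events.ic[contra][(events.ic[contra] > a) & (events.ic[contra] < b)]
        fc_o = events.fc[foot][events.fc[foot] > a]
        if fc_c.size == 0 or ic_c.size == 0 or fc_o.size == 0:
            n_discarded += 1
            continue
        ds1 = float(fc_c[0]) - a
        ds2 = float(fc_o[0]) - float(ic_c[0])
        if ds1 < 0 or ds2 < 0 or ds1 + ds2 >= (b - a):
            n_discarded += 1
            continue
        per_cycle.append(100.0 * (ds1 + ds2) / (b - a))
    if n_discarded:
        warnings.warn(
            f"{n_discarded} cycle(s) discarded from double-stance computation",
            stacklevel=2,
        )
    if not per_cycle:
        raise InsufficientDataError("no usable cycles for double stance")
    series = np.asarray(per_cycle)
    return float(series.mean()), series


# ---------------------------------------------------------------------------
# whole-trial driver


def _window_indices(windows: list, fs: float, n: int) -> list:
    out = []
    for t0, t1 in windows:
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        out.append((max(i0, 0), min(i1, n)))
    return out


def compute_all(
    trial: ImuTrial, path_length: float = 20.0,
    segmentation: TrialSegmentation | None = None,
) -> tuple:
    """Run segmentation and every parameter; returns (ParameterSet, qc dict)."""
    qc: dict = {"warnings": []}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        seg = segmentation or seg_mod.segment(trial)
        events = seg.events
        fs = trial.sample_rate
        trunk = trial.sensor("lower_back")
        win_idx = _window_indices(seg.straight_windows, fs, trial.n_samples)

        v = velocity(seg, path_length)
        strt = stride_time(seg)
        utrt = uturn_time(seg.uturn)
        stel = step_length(seg, path_length)

        stride_series = seg.stride_times()
        cv_strt = variation_coefficient(stride_series)

        dstt, ds_series = double_stance(events, seg)
        cv_dstt = variation_coefficient(ds_series)

        steps_sorted = np.sort(seg.steps)
        step_gaps = np.diff(steps_sorted)
        step_lag = float(np.median(step_gaps[step_gaps < 0.9 * strt]) if
                         np.any(step_gaps < 0.9 * strt) else strt / 2)
        p1, p2 = autocorr_peaks_windows(
            trunk.axis("acc", "CC"), win_idx, fs, step_lag, strt
        )

        sparc_g = sparc_windows(trunk.gyr, win_idx, fs)
        ldlj_a = ldlj_windows(trunk.axis("acc", "AP"), win_idx, fs)
        rms = rms_ml(trunk.axis("acc", "ML"), win_idx)

        ihrs = {
            ax: ihr(trunk.axis("acc", ax), fs, seg.strides, ax)
            for ax in ("AP", "ML", "CC")
        }
        swtr, p1p2 = symmetry_ratios(events, seg, p1, p2)

    qc["warnings"] = [str(w.message) for w in caught]
    qc["n_strides"] = len(seg.strides)
    qc["n_steps"] = int(seg.steps.size)
    qc["n_windows"] = len(seg.straight_windows)

    params = ParameterSet(
        V=v, StrT=strt, UtrT=utrt, SPARC_G=sparc_g, LDLJ_A=ldlj_a,
        CV_StrT=cv_strt, CV_dstT=cv_dstt, P1_aCC=p1, P2_aCC=p2, SteL=stel,
        RMS_aML=rms, iHR_aAP=ihrs["AP"], iHR_aML=ihrs["ML"],
        iHR_aCC=ihrs["CC"], P1P2_aCC=p1p2, swTr=swtr, dstT=dstt,
    )
    return params, qc
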