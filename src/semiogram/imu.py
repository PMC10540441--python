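"""IMU trial data model and plain-text I/O.

A walking trial is recorded by three inertial sensors (left foot dorsum,
right foot dorsum, lower back at L4-L5), each providing tri-axial
acceleration and angular velocity at a nominal 100 Hz.  Internally every
stream is stored in an anatomically aligned frame with axes

* ``AP`` - anteroposterior (forward positive),
* ``ML`` - mediolateral,
* ``CC`` - craniocaudal (upward positive),

with accelerations in m/s^2 and angular velocities in deg/s.  Files are
per-site CSVs with columns ``t, acc_AP, acc_ML, acc_CC, gyr_AP, gyr_ML,
gyr_CC`` (``t`` in seconds, ``#`` comments allowed); a :class:`Dialect`
describes deviations from that convention (sample rate, gyro units, axis
remapping per site).
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    CorruptStreamError,
    GaitError,
    IncompleteSensorSetError,
    UnorderedSamplesError,
)

logger = logging.getLogger(__name__)

SITES = ("left_foot", "right_foot", "lower_back")
AXES = ("AP", "ML", "CC")
COLUMNS = ["t"] + [f"{kind}_{ax}" for kind in ("acc", "gyr") for ax in AXES]

#: index of each anatomical axis in the (n, 3) sample arrays
AXIS_INDEX = {ax: i for i, ax in enumerate(AXES)}

MIN_DURATION_S = 5.0
MAX_NONFINITE_FRACTION = 0.01


@dataclass
class SensorStream:
    """Synchronised tri-axial accelerometer + gyroscope samples of one site.

    ``acc`` is (n, 3) in m/s^2 and ``gyr`` (n, 3) in deg/s, columns ordered
    (AP, ML, CC).
    """

    acc: np.ndarray
    gyr: np.ndarray

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise GaitError("acc must be an (n, 3) array")
        if self.gyr.shape != self.acc.shape:
            raise GaitError("acc and gyr must have the same shape")
        if not (np.isfinite(self.acc).all() and np.isfinite(self.gyr).all()):
            raise CorruptStreamError("non-finite samples in sensor stream")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    def axis(self, kind: str, ax: str) -> np.ndarray:
        """Return one channel, e.g. ``axis('acc', 'ML')``."""
        data = self.acc if kind == "acc" else self.gyr
        return data[:, AXIS_INDEX[ax]]


@dataclass
class ImuTrial:
    """One out-and-back walking trial recorded by the three sensors."""

    sample_rate: float
    sensors: Mapping[str, SensorStream]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise GaitError("sample_rate must be positive")
        missing = set(SITES) - set(self.sensors)
        if missing:
            raise IncompleteSensorSetError(
                f"incomplete sensor set: missing {sorted(missing)}"
            )
        extra = set(self.sensors) - set(SITES)
        if extra:
            raise GaitError(f"unknown sensor sites {sorted(extra)}")
        lengths = {s.n_samples for s in self.sensors.values()}
        if len(lengths) != 1:
            raise GaitError("sensor streams have unequal lengths")
        if self.duration < MIN_DURATION_S:
            raise GaitError(
                f"trial too short ({self.duration:.2f} s < {MIN_DURATION_S} s); "
                "not a walking trial"
            )

    @property
    def n_samples(self) -> int:
        return next(iter(self.sensors.values())).n_samples

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def sensor(self, site: str) -> SensorStream:
        return self.sensors[site]


@dataclass
class Dialect:
    """How to interpret a set of on-disk trial files.

    ``axis_map`` maps each site to a mapping from anatomical axis to a signed
    file axis, e.g. ``{"AP": "-ML", "ML": "+AP", "CC": "+CC"}`` for a sensor
    mounted rotated by 90 degrees.  The default is the identity for every
    site (mounting with the trunk CC axis vertical).
    """

    sample_rate: float = 100.0
    gyro_unit: str = "deg/s"  # or "rad/s"
    axis_map: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "Dialect":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            sample_rate=float(raw.get("sample_rate", 100.0)),
            gyro_unit=str(raw.get("gyro_unit", "deg/s")),
            axis_map=raw.get("axis_map", {}) or {},
        )


def _apply_axis_map(arr: np.ndarray, site_map: Mapping[str, str]) -> np.ndarray:
    out = np.empty_like(arr)
    for i, ax in enumerate(AXES):
        spec = site_map.get(ax, f"+{ax}")
        sign = -1.0 if spec.startswith("-") else 1.0
        src = spec.lstrip("+-")
        out[:, i] = sign * arr[:, AXIS_INDEX[src]]
    return out


def _repair_nonfinite(values: np.ndarray, label: str) -> np.ndarray:
    """Linearly interpolate isolated non-finite samples (<=1% tolerated)."""
    bad = ~np.isfinite(values)
    if not bad.any():
        return values
    frac = bad.mean()
    if frac > MAX_NONFINITE_FRACTION:
        raise CorruptStreamError(
            f"corrupt stream: {100 * frac:.1f}% non-finite samples in {label}"
        )
    idx = np.arange(values.size)
    values = values.copy()
    values[bad] = np.interp(idx[bad], idx[~bad], values[~bad])
    logger.warning(
        "interpolated %d non-finite sample(s) in %s", int(bad.sum()), label
    )
    return values


def _load_site(path: str, dialect: Dialect, target_rate: float) -> SensorStream:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise GaitError(f"{path}: missing columns {missing}")
    t = df["t"].to_numpy(dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise UnorderedSamplesError(f"{path}: unordered samples")

    channels = {}
    for col in COLUMNS[1:]:
        channels[col] = _repair_nonfinite(
            df[col].to_numpy(dtype=float), f"{os.path.basename(path)}:{col}"
        )

    # uniform grid at the target rate
    grid = np.arange(t[0], t[-1] + 0.5 / target_rate, 1.0 / target_rate)
    data = {c: np.interp(grid, t, v) for c, v in channels.items()}

    acc = np.column_stack([data[f"acc_{ax}"] for ax in AXES])
    gyr = np.column_stack([data[f"gyr_{ax}"] for ax in AXES])
    if dialect.gyro_unit == "rad/s":
        gyr = gyr * (180.0 / math.pi)
    elif dialect.gyro_unit != "deg/s":
        raise GaitError(f"unknown gyro unit {dialect.gyro_unit!r}")
    return SensorStream(acc=acc, gyr=gyr)


def load_trial(
    paths: Mapping[str, str],
    dialect: Dialect | None = None,
    meta: dict | None = None,
) -> ImuTrial:
    """Load one trial from per-site CSV files.

    Parameters
    ----------
    paths
        Mapping site name -> file path; all of ``left_foot``, ``right_foot``
        and ``lower_back`` must be present.
    dialect
        File-format description; defaults to the native convention
        (100 Hz, deg/s, identity axis mapping).
    """
    dialect = dialect or Dialect()
    missing = set(SITES) - set(paths)
    if missing:
        raise IncompleteSensorSetError(
            f"incomplete sensor set: missing {sorted(missing)}"
        )
    streams = {}
    for site in SITES:
        stream = _load_site(paths[site], dialect, dialect.sample_rate)
        site_map = dialect.axis_map.get(site, {})
        if site_map:
            stream = SensorStream(
                acc=_apply_axis_map(stream.acc, site_map),
                gyr=_apply_axis_map(stream.gyr, site_map),
            )
        streams[site] = stream
    n = min(s.n_samples for s in streams.values())
    streams = {
        k: SensorStream(acc=s.acc[:n], gyr=s.gyr[:n]) for k, s in streams.items()
    }
    return ImuTrial(
        sample_rate=dialect.sample_rate, sensors=streams, meta=dict(meta or {})
    )


def write_trial(trial: ImuTrial, directory: str) -> dict:
    """Write a trial as one CSV per site under ``directory``.

    Returns the mapping of site -> written path.  Metadata is stored as a
    JSON payload in a ``#`` comment line so that a load/write round trip
    preserves it bit for bit.
    """
    os.makedirs(directory, exist_ok=True)
    t = trial.time
    paths = {}
    for site in SITES:
        stream = trial.sensor(site)
        path = os.path.join(directory, f"{site}.csv")
        df = pd.DataFrame({"t": t})
        for i, ax in enumerate(AXES):
            df[f"acc_{ax}"] = stream.acc[:, i]
        for i, ax in enumerate(AXES):
            df[f"gyr_{ax}"] = stream.gyr[:, i]
        with open(path, "w") as fh:
            fh.write(f"# site: {site}\n")
            fh.write(f"# sample_rate: {trial.sample_rate!r}\n")
            fh.write(f"# meta: {json.dumps(trial.meta, sort_keys=True)}\n")
            df.to_csv(fh, index=False, float_format="%.12g")
        paths[site] = path
    return paths


def read_meta(path: str) -> dict:
    """Recover the metadata comment written by :func:`write_trial`."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("# meta: "):
                return json.loads(line[len("# meta: "):])
            if not line.startswith("#"):
                break
    return {}


def trial_paths(directory: str) -> dict:
    """Convenience: the standard per-site file layout under ``directory``."""
    return {site: os.path.join(directory, f"{site}.csv") for site in SITES}
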