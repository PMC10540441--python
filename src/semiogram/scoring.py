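"""Z-normalisation against a reference population and criterion scores.

Each of the 17 gait parameters is turned into a signed z-score

    z_p = c_p * (x_p - mean_p) / sd_p

where ``c_p`` (+1/-1) declares whether an increase of the parameter is
beneficial or pathological, so that *positive always means better than the
reference*.  The seven semiological criterion scores are arithmetic means
of their member parameters' z-scores; walking speed stays on its own axis
(it drives the colour of the chart, not a spoke):

    sturdiness      <- SteL
    springiness     <- StrT, UtrT
    steadiness      <- CV_StrT, CV_dstT, P1_aCC, P2_aCC
    stability       <- RMS_aML
    smoothness      <- LDLJ_A, SPARC_G
    synchronization <- dstT
    symmetry        <- iHR_aAP, iHR_aML, iHR_aCC, P1P2_aCC, swTr
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import GaitError
from .features import PARAMETER_NAMES, ParameterSet

logger = logging.getLogger(__name__)

#: fixed axis order used throughout plots and reports
CRITERIA_ORDER = (
    "sturdiness", "springiness", "steadiness", "stability",
    "smoothness", "synchronization", "symmetry",
)

CRITERIA_MEMBERS = {
    "sturdiness": ("SteL",),
    "springiness": ("StrT", "UtrT"),
    "steadiness": ("CV_StrT", "CV_dstT", "P1_aCC", "P2_aCC"),
    "stability": ("RMS_aML",),
    "smoothness": ("LDLJ_A", "SPARC_G"),
    "synchronization": ("dstT",),
    "symmetry": ("iHR_aAP", "iHR_aML", "iHR_aCC", "P1P2_aCC", "swTr"),
}

SPEED_PARAMETER = "V"


@dataclass
class ReferenceStats:
    """Per-parameter reference mean, SD and z-coefficient."""

    mean: dict
    sd: dict
    z_coefficient: dict
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for table in (self.mean, self.sd, self.z_coefficient):
            missing = set(PARAMETER_NAMES) - set(table)
            if missing:
                raise GaitError(
                    f"reference stats incomplete: missing {sorted(missing)}"
                )
        if any(self.sd[p] <= 0 for p in PARAMETER_NAMES):
            raise GaitError("reference SDs must be positive")
        if any(self.z_coefficient[p] not in (1, -1) for p in PARAMETER_NAMES):
            raise GaitError("z-coefficients must be +1 or -1")

    @classmethod
    def default(cls) -> "ReferenceStats":
        """The packaged healthy-adult normative table."""
        ref = importlib.resources.files("semiogram").joinpath(
            "data/reference_healthy.yaml"
        )
        with ref.open() as fh:
            return cls._from_mapping(yaml.safe_load(fh))

    @classmethod
    def from_yaml(cls, path: str) -> "ReferenceStats":
        with open(path) as fh:
            return cls._from_mapping(yaml.safe_load(fh))

    @classmethod
    def _from_mapping(cls, raw: dict) -> "ReferenceStats":
        params = raw["parameters"]
        return cls(
            mean={k: float(v["mean"]) for k, v in params.items()},
            sd={k: float(v["sd"]) for k, v in params.items()},
            z_coefficient={k: int(v["z_coefficient"]) for k, v in params.items()},
            provenance=str(raw.get("provenance", "unspecified")),
        )

    @classmethod
    def from_parameter_sets(
        cls, sets: list, provenance: str = "derived cohort"
    ) -> "ReferenceStats":
        """Re-derive reference means/SDs from a cohort of ParameterSets.

        The z-coefficients are copied from the packaged default (they
        encode a clinical judgement, not a sample statistic).
        """
        frame = pd.DataFrame([s.to_dict() for s in sets])
        base = cls.default()
        mean = frame.mean().to_dict()
        sd = frame.std(ddof=1).to_dict()
        for p, v in sd.items():
            if v <= 0:  # e.g. a count-derived parameter identical across trials
                sd[p] = max(1e-6, 1e-6 * abs(mean[p]))
                logger.warning(
                    "parameter %s has zero variance in the cohort; "
                    "SD floored at %g", p, sd[p],
                )
        return cls(
            mean=mean,
            sd=sd,
            z_coefficient=dict(base.z_coefficient),
            provenance=provenance,
        )

    def to_yaml(self, path: str) -> None:
        payload = {
            "provenance": self.provenance,
            "parameters": {
                p: {
                    "mean": float(self.mean[p]),
                    "sd": float(self.sd[p]),
                    "z_coefficient": int(self.z_coefficient[p]),
                }
                for p in PARAMETER_NAMES
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": [self.mean[p] for p in PARAMETER_NAMES],
                "sd": [self.sd[p] for p in PARAMETER_NAMES],
                "z_coefficient": [self.z_coefficient[p] for p in PARAMETER_NAMES],
            },
            index=list(PARAMETER_NAMES),
        )


@dataclass
class Semiogram:
    """Speed z-score plus the seven criterion partial scores of one trial."""

    speed_z: float
    criteria: dict  # criterion name -> z-score (SD units)
    parameter_z: dict  # parameter name -> signed z-score
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "speed_z": self.speed_z,
            "criteria": {k: self.criteria[k] for k in CRITERIA_ORDER},
            "parameter_z": dict(self.parameter_z),
            "meta": dict(self.meta),
        }

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, raw: dict) -> "Semiogram":
        return cls(
            speed_z=float(raw["speed_z"]),
            criteria={k: float(v) for k, v in raw["criteria"].items()},
            parameter_z={k: float(v) for k, v in raw.get("parameter_z", {}).items()},
            meta=dict(raw.get("meta", {})),
        )


@dataclass
class SessionSummary:
    """Mean and min-max band of the criterion scores over a session."""

    label: str
    mean: Semiogram
    low: dict  # criterion -> min
    high: dict  # criterion -> max
    n_trials: int = 1

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_trials": self.n_trials,
            "speed_z": self.mean.speed_z,
            "criteria": {
                k: {
                    "mean": self.mean.criteria[k],
                    "min": self.low[k],
                    "max": self.high[k],
                }
                for k in CRITERIA_ORDER
            },
        }

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, raw: dict) -> "SessionSummary":
        crit = raw["criteria"]
        mean = Semiogram(
            speed_z=float(raw["speed_z"]),
            criteria={k: float(v["mean"]) for k, v in crit.items()},
            parameter_z={},
            meta={"label": raw.get("label", "")},
        )
        return cls(
            label=str(raw.get("label", "")),
            mean=mean,
            low={k: float(v["min"]) for k, v in crit.items()},
            high={k: float(v["max"]) for k, v in crit.items()},
            n_trials=int(raw.get("n_trials", 1)),
        )


def zscore(params: ParameterSet, ref: ReferenceStats) -> dict:
    """Signed per-parameter z-scores (positive = better than reference)."""
    values = params.to_dict()
    return {
        p: ref.z_coefficient[p] * (values[p] - ref.mean[p]) / ref.sd[p]
        for p in PARAMETER_NAMES
    }


def criterion_scores(parameter_z: dict, meta: dict | None = None) -> Semiogram:
    """Assemble the semiogram from the per-parameter z-scores."""
    missing = set(PARAMETER_NAMES) - set(parameter_z)
    if missing:
        raise GaitError(f"incomplete parameter set: missing {sorted(missing)}")
    criteria = {
        name: float(np.mean([parameter_z[p] for p in members]))
        for name, members in CRITERIA_MEMBERS.items()
    }
    return Semiogram(
        speed_z=float(parameter_z[SPEED_PARAMETER]),
        criteria=criteria,
        parameter_z=dict(parameter_z),
        meta=dict(meta or {}),
    )


def score(params: ParameterSet, ref: ReferenceStats | None = None,
          meta: dict | None = None) -> Semiogram:
    """Z-score a ParameterSet and build its semiogram in one call."""
    ref = ref or ReferenceStats.default()
    return criterion_scores(zscore(params, ref), meta=meta)


def session_summary(
    semiograms: list, label: str = "session"
) -> SessionSummary:
    """Mean line and min-max band over the trials of one session."""
    if not semiograms:
        raise GaitError("session_summary needs at least one semiogram")
    crit = {
        k: np.array([s.criteria[k] for s in semiograms]) for k in CRITERIA_ORDER
    }
    mean = Semiogram(
        speed_z=float(np.mean([s.speed_z for s in semiograms])),
        criteria={k: float(v.mean()) for k, v in crit.items()},
        parameter_z={},
        meta={"label": label, "n_trials": len(semiograms)},
    )
    return SessionSummary(
        label=label,
        mean=mean,
        low={k: float(v.min()) for k, v in crit.items()},
        high={k: float(v.max()) for k, v in crit.items()},
        n_trials=len(semiograms),
    )
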