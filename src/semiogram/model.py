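"""Model/Results facade over the gait-analysis pipeline.

:class:`GaitTrialModel` is built from an :class:`~semiogram.imu.ImuTrial`
(or the per-site CSV files) and a normative reference; ``fit()`` runs
segmentation, the 17 parameters and the z-scored criterion scores, and
returns a :class:`GaitTrialResults` carrying the estimates, quality flags
and a ``summary()`` table.  Plotting hangs off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from . import features, imu, plotting, scoring, segmentation
from .features import PARAMETER_NAMES, PARAMETER_UNITS, ParameterSet
from .imu import ImuTrial
from .scoring import CRITERIA_ORDER, ReferenceStats, Semiogram, SessionSummary


class GaitTrialModel:
    """One 10-m out-and-back walking trial awaiting analysis.

    Parameters
    ----------
    trial
        The synchronised three-sensor recording.
    path_length
        Total walked distance in metres (default 20: 10 m out and back).
    reference
        Normative statistics used for z-scoring; defaults to the packaged
        healthy-adult table.
    """

    def __init__(
        self,
        trial: ImuTrial,
        path_length: float = 20.0,
        reference: ReferenceStats | None = None,
    ):
        self.trial = trial
        self.path_length = path_length
        self.reference = reference or ReferenceStats.default()

    @classmethod
    def from_csv(
        cls,
        paths: Mapping[str, str] | str,
        dialect: imu.Dialect | None = None,
        **kwargs,
    ) -> "GaitTrialModel":
        """Build from per-site CSVs (a mapping or a directory)."""
        if isinstance(paths, str):
            paths = imu.trial_paths(paths)
        return cls(imu.load_trial(paths, dialect=dialect), **kwargs)

    def fit(self) -> "GaitTrialResults":
        seg = segmentation.segment(self.trial)
        params, qc = features.compute_all(
            self.trial, self.path_length, segmentation=seg
        )
        parameter_z = scoring.zscore(params, self.reference)
        semio = scoring.criterion_scores(parameter_z, meta=dict(self.trial.meta))
        return GaitTrialResults(
            model=self, segmentation=seg, params=params, qc=qc,
            parameter_z=parameter_z, semiogram=semio,
        )


@dataclass
class GaitTrialResults:
    """Fitted gait parameters and scores of one trial."""

    model: GaitTrialModel
    segmentation: segmentation.TrialSegmentation
    params: ParameterSet
    qc: dict
    parameter_z: dict
    semiogram: Semiogram

    @property
    def events(self) -> segmentation.GaitEvents:
        return self.segmentation.events

    @property
    def criteria(self) -> dict:
        return self.semiogram.criteria

    @property
    def speed_z(self) -> float:
        return self.semiogram.speed_z

    def to_frame(self) -> pd.DataFrame:
        ref = self.model.reference
        values = self.params.to_dict()
        return pd.DataFrame(
            {
                "value": [values[p] for p in PARAMETER_NAMES],
                "unit": [PARAMETER_UNITS[p] for p in PARAMETER_NAMES],
                "ref_mean": [ref.mean[p] for p in PARAMETER_NAMES],
                "ref_sd": [ref.sd[p] for p in PARAMETER_NAMES],
                "z": [self.parameter_z[p] for p in PARAMETER_NAMES],
            },
            index=list(PARAMETER_NAMES),
        )

    def summary(self) -> str:
        """Human-readable parameter and criterion tables."""
        lines = ["Gait trial summary", "=" * 66]
        frame = self.to_frame()
        lines.append(
            f"{'parameter':<10}{'value':>10}  {'unit':<6}"
            f"{'ref mean':>9}{'ref sd':>8}{'z':>8}"
        )
        lines.append("-" * 66)
        for p, row in frame.iterrows():
            lines.append(
                f"{p:<10}{row['value']:>10.3f}  {row['unit']:<6}"
                f"{row['ref_mean']:>9.2f}{row['ref_sd']:>8.2f}{row['z']:>8.2f}"
            )
        lines.append("-" * 66)
        lines.append(f"{'speed z-score':<24}{self.speed_z:>8.2f}")
        for c in CRITERIA_ORDER:
            lines.append(f"{c:<24}{self.criteria[c]:>8.2f}")
        lines.append("=" * 66)
        nw = len(self.qc.get("warnings", []))
        lines.append(
            f"strides: {self.qc.get('n_strides')}  steps: {self.qc.get('n_steps')}"
            f"  straight windows: {self.qc.get('n_windows')}  warnings: {nw}"
        )
        return "\n".join(lines)

    def plot(self, out: str | None = None, label: str = "trial",
             spec: plotting.RenderSpec | None = None):
        """Radar chart of this single trial (band collapsed to the line)."""
        sess = scoring.session_summary([self.semiogram], label=label)
        return plotting.render([sess], spec=spec, out=out)


def session_results(
    results: list, label: str = "session"
) -> SessionSummary:
    """Pool several fitted trials of one session into a mean + band."""
    return scoring.session_summary([r.semiogram for r in results], label=label)
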