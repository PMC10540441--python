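"""Test-retest reliability statistics: ICC, SEM and validity tests.

Two single-measure intraclass correlation models are implemented from
their ANOVA mean squares (n subjects, k repeats):

* ``ICC(1,1)`` (one-way random): all within-subject variability counts as
  measurement error,
  ``(BMS - WMS) / (BMS + (k-1) WMS)``;
* ``ICC(3,1)`` (two-way mixed, consistency): systematic shifts between
  repeats are removed before assessing agreement,
  ``(BMS - EMS) / (BMS + (k-1) EMS)``.

Absolute reliability is the standard error of measurement
``SEM = pooled SD * sqrt(1 - ICC)``; heteroskedasticity is screened with
the Pearson correlation between absolute test-retest differences and
subject means.  Group differences use the Mann-Whitney U test with
Bonferroni adjustment; correlations with clinical scales use Pearson's r
tested through the Fisher z-transformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import GaitError, InsufficientDataError

logger = logging.getLogger(__name__)

#: agreement bands for ICC values (boundaries inclusive downward:
#: 0.75 counts as excellent, 0.4 as moderate-to-high)
BAND_EXCELLENT = 0.75
BAND_MODERATE = 0.4

EXACT_MW_MAX_N = 8


@dataclass
class RepeatedMeasures:
    """subjects x repeats matrix of one parameter or criterion score."""

    values: np.ndarray
    label: str = ""
    repeat_semantics: str = "intra-session"  # or "inter-session"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise GaitError("repeated measures must be a 2-D matrix")
        keep = np.isfinite(arr).all(axis=1)
        if not keep.all():
            logger.warning(
                "dropping %d row(s) with missing repeats", int((~keep).sum())
            )
            arr = arr[keep]
        if arr.shape[0] < 3 or arr.shape[1] < 2:
            raise InsufficientDataError(
                "need >= 3 subjects and >= 2 repeats for reliability"
            )
        self.values = arr

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "",
                   repeat_semantics: str = "intra-session") -> "RepeatedMeasures":
        """Wide layout: one row per subject, one column per repeat."""
        return cls(frame.to_numpy(dtype=float), label=label,
                   repeat_semantics=repeat_semantics)


@dataclass
class ReliabilityReport:
    """Reliability summary of one parameter/criterion."""

    label: str
    icc11: float
    icc31: float
    sem: float
    hetero_r: float
    hetero_p: float
    band: str
    degenerate: bool = False


def _anova_mean_squares(m: np.ndarray) -> tuple:
    """(BMS, WMS, EMS, k) from the subjects x repeats matrix."""
    n, k = m.shape
    grand = m.mean()
    rows = m.mean(axis=1)
    cols = m.mean(axis=0)
    bms = k * np.sum((rows - grand) ** 2) / (n - 1)
    wms = np.sum((m - rows[:, None]) ** 2) / (n * (k - 1))
    sse = np.sum((m - rows[:, None] - cols[None, :] + grand) ** 2)
    ems = sse / ((n - 1) * (k - 1))
    return bms, wms, ems, k


def icc(measures: RepeatedMeasures, model: str = "one_way") -> float:
    """Single-measure intraclass correlation.

    ``model``: ``"one_way"`` for ICC(1,1), ``"two_way_mixed"`` for ICC(3,1).
    A matrix with no between-subject spread yields a defined (non-positive)
    value; callers may flag it via :func:`is_degenerate`.
    """
    bms, wms, ems, k = _anova_mean_squares(measures.values)
    if model == "one_way":
        denom = bms + (k - 1) * wms
        num = bms - wms
    elif model == "two_way_mixed":
        denom = bms + (k - 1) * ems
        num = bms - ems
    else:
        raise GaitError(f"unknown ICC model {model!r}")
    if denom == 0:
        return 1.0  # all values identical: perfect (trivial) agreement
    return float(num / denom)


def is_degenerate(measures: RepeatedMeasures) -> bool:
    """True when there is no between-subject spread to resolve."""
    rows = measures.values.mean(axis=1)
    return bool(np.allclose(rows, rows[0]))


def sem(measures: RepeatedMeasures, icc_value: float) -> float:
    """Standard error of measurement: pooled SD * sqrt(1 - ICC)."""
    if icc_value > 1:
        raise GaitError("ICC cannot exceed 1")
    pooled_sd = float(np.std(measures.values, ddof=1))
    return pooled_sd * float(np.sqrt(max(1.0 - icc_value, 0.0)))


def heteroskedasticity(measures: RepeatedMeasures) -> tuple:
    """Pearson r (and two-sided p) of |x1 - x2| against subject means.

    Defined for two repeats.  Degenerate inputs (constant differences or
    constant means) are reported as r = 0, p = 1.
    """
    m = measures.values
    if m.shape[1] != 2:
        raise GaitError("heteroskedasticity screen needs exactly 2 repeats")
    diffs = np.abs(m[:, 0] - m[:, 1])
    means = m.mean(axis=1)
    if np.allclose(diffs, diffs[0]) or np.allclose(means, means[0]):
        logger.warning("degenerate heteroskedasticity screen (constant input)")
        return 0.0, 1.0
    r, p = stats.pearsonr(diffs, means)
    return float(r), float(p)


def agreement_band(icc_value: float) -> str:
    """Classify an ICC: >= 0.75 excellent, 0.4-0.75 moderate-to-high, else low."""
    if icc_value >= BAND_EXCELLENT:
        return "excellent"
    if icc_value >= BAND_MODERATE:
        return "moderate-to-high"
    return "low"


def reliability_report(measures: RepeatedMeasures) -> ReliabilityReport:
    icc11 = icc(measures, "one_way")
    icc31 = icc(measures, "two_way_mixed")
    if measures.n_repeats == 2:
        hr, hp = heteroskedasticity(measures)
    else:
        hr, hp = float("nan"), float("nan")
    return ReliabilityReport(
        label=measures.label,
        icc11=icc11,
        icc31=icc31,
        sem=sem(measures, icc11),
        hetero_r=hr,
        hetero_p=hp,
        band=agreement_band(icc11),
        degenerate=is_degenerate(measures),
    )


def reliability_table(
    intra: dict, inter: dict | None = None
) -> pd.DataFrame:
    """Assemble the per-parameter reliability table.

    ``intra``/``inter`` map a label to a :class:`RepeatedMeasures`; columns
    mirror the conventional report: ICC(1,1), ICC(3,1) and SEM for each
    repeat design.
    """
    rows = {}
    for label, meas in intra.items():
        rep = reliability_report(meas)
        rows[label] = {
            "intra_ICC11": rep.icc11, "intra_ICC31": rep.icc31,
            "intra_SEM": rep.sem, "intra_band": rep.band,
        }
    for label, meas in (inter or {}).items():
        rep = reliability_report(meas)
        rows.setdefault(label, {}).update({
            "inter_ICC11": rep.icc11, "inter_ICC31": rep.icc31,
            "inter_SEM": rep.sem, "inter_band": rep.band,
        })
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# group differences and clinical correlations


def _mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of group a via midranks."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def group_difference(
    a: np.ndarray, b: np.ndarray, n_tests: int = 8
) -> tuple:
    """Two-sided Mann-Whitney U test with Bonferroni adjustment.

    Returns ``(U, p_adjusted)``.  The normal approximation with tie
    correction is used, switching to the exact permutation distribution
    when both groups have at most 8 observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each group needs >= 3 observations")
    n1, n2 = a.size, b.size
    u = _mann_whitney_u(a, b)

    if n1 <= EXACT_MW_MAX_N and n2 <= EXACT_MW_MAX_N:
        pooled = np.concatenate([a, b])
        idx = np.arange(n1 + n2)
        mean_u = n1 * n2 / 2.0
        count = 0
        total = 0
        for comb in combinations(idx, n1):
            total += 1
            u_perm = _mann_whitney_u(pooled[list(comb)],
                                     np.delete(pooled, list(comb)))
            if abs(u_perm - mean_u) >= abs(u - mean_u) - 1e-12:
                count += 1
        p = count / total
    else:
        mean_u = n1 * n2 / 2.0
        pooled = np.concatenate([a, b])
        _, tie_counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_u == 0:
            p = 1.0
        else:
            z = (u - mean_u - 0.5 * np.sign(u - mean_u)) / np.sqrt(var_u)
            p = 2.0 * stats.norm.sf(abs(z))
    return u, float(min(1.0, p * n_tests))


def clinical_correlation(
    scores: np.ndarray, clinical: np.ndarray, n_tests: int = 1
) -> tuple:
    """Pearson r between gait scores and a clinical scale.

    The p-value comes from the two-sided Fisher z-transformation test and
    is Bonferroni-multiplied by ``n_tests``.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(clinical, dtype=float)
    if x.size != y.size:
        raise GaitError("paired vectors required")
    if x.size < 4:
        raise InsufficientDataError("need >= 4 pairs for correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise GaitError("zero variance in correlation input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        z = np.arctanh(r) * np.sqrt(x.size - 3)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return r, float(min(1.0, p * n_tests))
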