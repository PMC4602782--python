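"""Neuropsychological diagnosis, score correlations, and ROC analysis.

MHE labeling follows the psychometric convention: a cirrhotic patient is
MHE when at least one of two tests (number connection test A, digit symbol
test) is abnormal, i.e. beyond 2 SD of the healthy-control distribution in
the impaired direction (longer NCT-A time, lower DST score).

ROC analysis discriminates MHE from non-HE patients from a regional
connectivity value; the default orientation is "lower connectivity
indicates disease", matching reduced DMN coupling in MHE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError
from .types import SubjectRecord


@dataclass(frozen=True)
class NormativeReference:
    """Healthy-control normative statistics for the two psychometric tests.

    A score is abnormal beyond ``sd_multiplier`` control SDs in the impaired
    direction.
    """

    nct_a_mean: float
    nct_a_sd: float
    dst_mean: float
    dst_sd: float
    sd_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.nct_a_sd <= 0 or self.dst_sd <= 0:
            raise ValueError("normative SDs must be positive")

    @classmethod
    def from_controls(
        cls, records: list[SubjectRecord], sd_multiplier: float = 2.0
    ) -> "NormativeReference":
        hc = [r for r in records if r.group == "HC"]
        if len(hc) < 2:
            raise DegenerateDataError("need at least 2 healthy controls for norms")
        nct = np.array([r.nct_a_seconds for r in hc], float)
        dst = np.array([r.dst_score for r in hc], float)
        return cls(
            nct_a_mean=float(nct.mean()),
            nct_a_sd=float(nct.std(ddof=1)),
            dst_mean=float(dst.mean()),
            dst_sd=float(dst.std(ddof=1)),
            sd_multiplier=sd_multiplier,
        )


def diagnose_mhe(record: SubjectRecord, norms: NormativeReference) -> str:
    """Label a cirrhotic patient MHE or nonHE from the two test scores.

    MHE iff NCT-A time exceeds control mean + k*SD (longer is worse) or DST
    score falls below control mean - k*SD (lower is worse); one abnormal
    test suffices.
    """
    k = norms.sd_multiplier
    nct_abnormal = record.nct_a_seconds > norms.nct_a_mean + k * norms.nct_a_sd
    dst_abnormal = record.dst_score < norms.dst_mean - k * norms.dst_sd
    return "MHE" if (nct_abnormal or dst_abnormal) else "nonHE"


def pearson_with_scores(
    roi_values: np.ndarray, scores: np.ndarray
) -> tuple[float, float]:
    """Sample Pearson r between regional connectivity and test scores, with
    the two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(roi_values, float)
    y = np.asarray(scores, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("roi_values and scores must be 1-D and paired")
    if x.size < 3:
        raise DegenerateDataError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input to Pearson correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class RocResult:
    """Full ROC curve for one regional connectivity marker.

    ``thresholds`` are the sweep points; a subject is called diseased when
    the value falls strictly below the threshold (orientation "lower") or
    at/above it (orientation "higher"). ``auc`` equals the normalized count
    of concordant case-control pairs with ties counted 1/2.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    orientation: str  # "lower" or "higher" indicates disease


def roc_curve(
    values: np.ndarray, labels: list[str], orientation: str = "lower"
) -> RocResult:
    """ROC curve for discriminating MHE from nonHE by a scalar marker.

    With orientation "lower", sensitivity at threshold t is the fraction of
    MHE values < t and specificity the fraction of nonHE values >= t.
    Thresholds sweep the sorted unique observed values plus one point above
    the maximum, so the curve runs from (0, 0) to (1, 1). AUC by the
    trapezoidal rule.
    """
    if orientation not in ("lower", "higher"):
        raise ValueError(f"orientation must be 'lower' or 'higher', got {orientation!r}")
    v = np.asarray(values, float)
    lab = np.asarray(labels)
    cases = v[lab == "MHE"]
    controls = v[lab == "nonHE"]
    if cases.size == 0 or controls.size == 0:
        raise DegenerateDataError("both MHE and nonHE values are required")
    if orientation == "higher":
        # reuse the "lower" machinery on negated values
        res = roc_curve(-v, labels, orientation="lower")
        return RocResult(
            thresholds=-res.thresholds,
            sensitivity=res.sensitivity,
            specificity=res.specificity,
            auc=res.auc,
            optimal_cutoff=-res.optimal_cutoff,
            sens_at_cutoff=res.sens_at_cutoff,
            spec_at_cutoff=res.spec_at_cutoff,
            orientation="higher",
        )
    uniq = np.unique(v)
    step = max(np.ptp(uniq), 1.0)
    thresholds = np.concatenate([uniq, [uniq[-1] + 0.01 * step]])
    sens = (cases[None, :] < thresholds[:, None]).mean(axis=1)
    spec = (controls[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(np.concatenate([[0.0], sens[order], [1.0]]),
                             np.concatenate([[0.0], fpr[order], [1.0]])))
    cutoff, s, sp = _youden(thresholds, sens, spec)
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_cutoff=cutoff,
        sens_at_cutoff=s,
        spec_at_cutoff=sp,
        orientation="lower",
    )


def _youden(thresholds: np.ndarray, sens: np.ndarray, spec: np.ndarray):
    youden = sens + spec - 1.0
    best = youden.max()
    tied = np.flatnonzero(youden >= best - 1e-12)
    # break ties toward higher specificity, then toward the lower threshold
    tied = tied[np.lexsort((thresholds[tied], -spec[tied]))]
    i = tied[0]
    return float(thresholds[i]), float(sens[i]), float(spec[i])


def youden_cutoff(roc: RocResult) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties break toward higher specificity; returns (cutoff, sensitivity,
    specificity) at that threshold.
    """
    return _youden(roc.thresholds, roc.sensitivity, roc.specificity)


def prevalence(labels: list[str], positive: str = "MHE") -> tuple[int, int, float]:
    """Count of positive labels, total count, and percent to one decimal."""
    if len(labels) == 0:
        raise DegenerateDataError("empty label sequence")
    count = sum(1 for l in labels if l == positive)
    total = len(labels)
    return count, total, round(100.0 * count / total, 1)
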