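"""Diagnostic-performance statistics for case-control biomarker cohorts.

Implements the evaluation stack used for MSLN(+)CTC / CTC counts and the
serum markers CA125 and HE4: group summaries with a normal-approximation 95%
CI, detection rates, the Mann-Whitney U test, empirical ROC curves with
Youden-index cutoff selection, and combined multi-marker scoring models
(binarize each marker at its cutoff, sum to a total score, run ROC analysis
on the score).

Conventions
-----------
* Cases are labelled ``EOC`` and controls ``BENIGN`` in the ``group`` column;
  higher marker values indicate disease.
* ROC candidate thresholds are midpoints between consecutive distinct pooled
  values plus -inf/+inf sentinels; a subject is test-positive when its value
  is strictly greater than the threshold.  For display, count and serum
  cutoffs are additionally reported as the smallest observed value called
  positive (so a midpoint of 0.5 cells prints as "1 cell").
* Missing marker values are handled complete-case, per marker and per
  combined model.
* CIs use z = 1.96 (normal approximation), matching the reporting convention
  of the source tables; report-layer rounding is half-up to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .reconstruct import round_half_up

__all__ = [
    "GroupSummary", "TestResult", "RocCurve", "CutoffResult", "MarkerReport",
    "CombinedModel", "normal_ci", "group_summary", "detection_rate",
    "mann_whitney", "roc_curve", "youden_cutoff", "evaluate_marker",
    "binarize", "combined_model", "compare_models", "cohort_report",
    "CASE_LABEL", "CONTROL_LABEL",
]

CASE_LABEL = "EOC"
CONTROL_LABEL = "BENIGN"
Z_95 = 1.96


# ---------------------------------------------------------------------------
# group summaries

@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    mean: float
    sd: float
    vmin: float
    vmax: float
    ci_lo: float
    ci_hi: float

    def rounded(self, decimals: int = 1) -> dict:
        """Report-layer view: half-up rounding, the table convention."""
        r = lambda x: round_half_up(x, decimals)
        return {"n": self.n, "median": r(self.median), "mean": r(self.mean),
                "sd": r(self.sd), "min": r(self.vmin), "max": r(self.vmax),
                "ci_lo": r(self.ci_lo), "ci_hi": r(self.ci_hi)}


def normal_ci(mean: float, sd: float, n: int) -> tuple[float, float]:
    """95% CI for the mean under the normal approximation, mean ± 1.96·SD/√n."""
    if n < 2:
        raise ValueError("normal_ci requires n >= 2")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    half = Z_95 * sd / math.sqrt(n)
    return mean - half, mean + half


def group_summary(values: Sequence[float]) -> GroupSummary:
    """Descriptive statistics (sample SD, n-1) with a normal 95% CI."""
    arr = np.asarray([v for v in values if v is not None and not np.isnan(v)], dtype=float)
    if arr.size < 2:
        raise ValueError("group_summary requires >= 2 non-missing values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    lo, hi = normal_ci(mean, sd, arr.size)
    return GroupSummary(n=int(arr.size), median=float(np.median(arr)), mean=mean,
                        sd=sd, vmin=float(arr.min()), vmax=float(arr.max()),
                        ci_lo=lo, ci_hi=hi)


def detection_rate(counts: Sequence[int]) -> float:
    """Percent of subjects with at least one called cell."""
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("detection_rate requires a non-empty list")
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    return 100.0 * float(np.count_nonzero(arr >= 1)) / arr.size


# ---------------------------------------------------------------------------
# Mann-Whitney U

@dataclass(frozen=True)
class TestResult:
    u: float
    p: float
    method: str  # "exact" or "normal-tie-corrected"


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    U is computed from midranks.  With n1+n2 <= 12 and no ties the two-sided
    p-value is exact by full enumeration of all group assignments; otherwise
    the normal approximation with tie correction and continuity correction
    is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    has_ties = len(np.unique(pooled)) < n1 + n2
    if n1 + n2 <= 12 and not has_ties:
        # enumerate every C(n1+n2, n1) assignment of the pooled values
        order = np.sort(pooled)
        total = 0
        extreme = 0
        obs_dev = abs(u1 - mu)
        for idx in combinations(range(n1 + n2), n1):
            rsum = sum(i + 1 for i in idx)  # ranks are 1..n since no ties
            u = rsum - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                extreme += 1
        return TestResult(u=float(u1), p=extreme / total, method="exact")

    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return TestResult(u=float(u1), p=1.0, method="normal-tie-corrected")
    z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return TestResult(u=float(u1), p=p, method="normal-tie-corrected")


# ---------------------------------------------------------------------------
# ROC / Youden

@dataclass
class RocCurve:
    """Empirical ROC over midpoint thresholds (``value > threshold`` is
    test-positive). Sentinels at ±inf give the (1,1) and (0,0) corners."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cases: np.ndarray = field(repr=False, default=None)
    controls: np.ndarray = field(repr=False, default=None)


def roc_curve(cases: Sequence[float], controls: Sequence[float]) -> RocCurve:
    """Empirical ROC curve; AUC by trapezoid, which for midpoint thresholds
    equals the tie-corrected rank statistic U/(n1*n2)."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size < 1 or controls.size < 1:
        raise ValueError("need at least one case and one control")
    pooled = np.unique(np.concatenate([cases, controls]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if pooled.size > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(cases > t).mean() for t in thresholds])
    spec = np.array([(controls <= t).mean() for t in thresholds])
    fpr = 1.0 - spec
    # thresholds ascend => the ROC path runs from (1,1) down to (0,0);
    # reversing gives the path in ascending-fpr order (tie diagonals intact)
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec,
                    auc=auc, cases=cases, controls=controls)


@dataclass(frozen=True)
class CutoffResult:
    threshold: float          # midpoint candidate threshold
    cutoff_observed: float    # smallest observed value called positive (>= rule)
    j: float                  # Youden index, sensitivity + specificity - 1
    sensitivity: float        # fraction in [0, 1]
    specificity: float


def youden_cutoff(curve: RocCurve) -> CutoffResult:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity, then toward the higher
    threshold.  The observed-value cutoff is the smallest pooled value
    strictly above the winning midpoint (i.e. the smallest value that the
    ``>= cutoff`` rule calls positive).
    """
    j = curve.sensitivity + curve.specificity - 1.0
    best = max(range(len(j)), key=lambda i: (j[i], curve.specificity[i], curve.thresholds[i]))
    thr = float(curve.thresholds[best])
    pooled = np.unique(np.concatenate([curve.cases, curve.controls]))
    above = pooled[pooled > thr]
    observed = float(above[0]) if above.size else math.inf
    return CutoffResult(threshold=thr, cutoff_observed=observed, j=float(j[best]),
                        sensitivity=float(curve.sensitivity[best]),
                        specificity=float(curve.specificity[best]))


# ---------------------------------------------------------------------------
# marker-level and model-level evaluation

@dataclass
class MarkerReport:
    marker: str
    n_cases: int
    n_controls: int
    curve: RocCurve
    cutoff: CutoffResult

    def to_dict(self) -> dict:
        return _report_block(self.marker, self.n_cases, self.n_controls,
                             self.curve, self.cutoff)


def _split_groups(cohort: pd.DataFrame, column: str) -> tuple[np.ndarray, np.ndarray]:
    if column not in cohort.columns:
        raise KeyError(f"marker column '{column}' not found")
    sub = cohort[cohort[column].notna()]
    cases = sub.loc[sub["group"] == CASE_LABEL, column].to_numpy(dtype=float)
    controls = sub.loc[sub["group"] == CONTROL_LABEL, column].to_numpy(dtype=float)
    return cases, controls


def evaluate_marker(cohort: pd.DataFrame, marker: str) -> MarkerReport:
    """Single-marker ROC/Youden analysis under the complete-case convention
    (patients missing this marker are excluded)."""
    cases, controls = _split_groups(cohort, marker)
    if cases.size < 1 or controls.size < 1:
        raise ValueError(f"marker '{marker}': need >= 1 case and control after "
                         f"complete-case filtering (got {cases.size}/{controls.size})")
    curve = roc_curve(cases, controls)
    return MarkerReport(marker=marker, n_cases=int(cases.size),
                        n_controls=int(controls.size), curve=curve,
                        cutoff=youden_cutoff(curve))


def binarize(value: float, cutoff: float) -> Optional[int]:
    """Score 1 when value >= cutoff (observed-value convention), else 0;
    missing propagates as None so the patient drops from a combined model."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return 1 if value >= cutoff else 0


@dataclass
class CombinedModel:
    """Multi-marker scoring model: each marker is binarized at its cutoff and
    the per-patient total score (0..n_markers) is evaluated by ROC/Youden."""

    markers: tuple[str, ...]
    cutoffs: dict
    scores: pd.DataFrame  # patient_id, group, score (complete cases only)
    n_cases: int
    n_controls: int
    curve: RocCurve
    cutoff: CutoffResult

    @property
    def name(self) -> str:
        return "+".join(self.markers)

    def to_dict(self) -> dict:
        block = _report_block(self.name, self.n_cases, self.n_controls,
                              self.curve, self.cutoff)
        block["markers"] = list(self.markers)
        block["marker_cutoffs"] = {m: float(c) for m, c in self.cutoffs.items()}
        return block


def combined_model(cohort: pd.DataFrame, markers: Sequence[str],
                   cutoffs: Optional[dict] = None) -> CombinedModel:
    """Build a combined scoring model over ``markers``.

    Per-marker cutoffs default to each marker's own Youden-optimal
    observed-value cutoff (computed complete-case per marker).  Only patients
    with every marker observed are scored.
    """
    markers = tuple(markers)
    if len(markers) < 2:
        raise ValueError("a combined model needs >= 2 markers")
    if cutoffs is None:
        cutoffs = {m: evaluate_marker(cohort, m).cutoff.cutoff_observed for m in markers}
    complete = cohort.dropna(subset=list(markers))
    if complete.empty:
        raise ValueError("no complete cases across " + ", ".join(markers))
    score = sum((complete[m] >= cutoffs[m]).astype(int) for m in markers)
    scores = pd.DataFrame({"patient_id": complete["patient_id"],
                           "group": complete["group"], "score": score})
    cases = scores.loc[scores["group"] == CASE_LABEL, "score"].to_numpy(dtype=float)
    controls = scores.loc[scores["group"] == CONTROL_LABEL, "score"].to_numpy(dtype=float)
    if cases.size < 1 or controls.size < 1:
        raise ValueError("no complete cases in one of the groups")
    curve = roc_curve(cases, controls)
    return CombinedModel(markers=markers, cutoffs=dict(cutoffs), scores=scores,
                         n_cases=int(cases.size), n_controls=int(controls.size),
                         curve=curve, cutoff=youden_cutoff(curve))


def compare_models(models: Sequence) -> pd.DataFrame:
    """Tabulate AUC / sensitivity / specificity / cutoff per model, flagging
    models whose sensitivity and specificity both exceed 90%."""
    if len(models) < 1:
        raise ValueError("need at least one model")
    rows = []
    for m in models:
        name = m.name if hasattr(m, "name") else m.marker
        sens = 100.0 * m.cutoff.sensitivity
        spec = 100.0 * m.cutoff.specificity
        rows.append({"model": name, "auc": m.curve.auc,
                     "cutoff_midpoint": m.cutoff.threshold,
                     "cutoff_observed": m.cutoff.cutoff_observed,
                     "sensitivity_pct": sens, "specificity_pct": spec,
                     "youden_j": m.cutoff.j,
                     "both_above_90": bool(sens > 90.0 and spec > 90.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# JSON report

def _report_block(name: str, n_cases: int, n_controls: int,
                  curve: RocCurve, cut: CutoffResult) -> dict:
    return {
        "name": name,
        "n_cases": n_cases,
        "n_controls": n_controls,
        "auc": round(curve.auc, 6),
        "cutoff_midpoint": round(cut.threshold, 6) if math.isfinite(cut.threshold) else None,
        "cutoff_observed": round(cut.cutoff_observed, 6) if math.isfinite(cut.cutoff_observed) else None,
        "sensitivity_pct": round(100.0 * cut.sensitivity, 6),
        "specificity_pct": round(100.0 * cut.specificity, 6),
        "youden_j": round(cut.j, 6),
    }


DEFAULT_MARKERS = ("msln_ctc_count", "ctc_count", "ca125_u_ml", "he4_pmol_l")
DEFAULT_MODELS = (
    ("msln_ctc_count", "ca125_u_ml"),
    ("msln_ctc_count", "he4_pmol_l"),
    ("ctc_count", "ca125_u_ml"),
    ("ctc_count", "he4_pmol_l"),
    ("msln_ctc_count", "ca125_u_ml", "he4_pmol_l"),
    ("ctc_count", "ca125_u_ml", "he4_pmol_l"),
)


def cohort_report(cohort: pd.DataFrame,
                  markers: Sequence[str] = DEFAULT_MARKERS,
                  models: Sequence[Sequence[str]] = DEFAULT_MODELS) -> dict:
    """Full diagnostic report: group summaries, detection rates, group
    comparisons, single-marker blocks and combined-model blocks."""
    report: dict = {"markers": {}, "models": {}, "summaries": {}, "tests": {}}
    for marker in markers:
        cases, controls = _split_groups(cohort, marker)
        mr = evaluate_marker(cohort, marker)
        report["markers"][marker] = mr.to_dict()
        report["summaries"][marker] = {
            CASE_LABEL: group_summary(cases).rounded(),
            CONTROL_LABEL: group_summary(controls).rounded(),
        }
        if marker.endswith("_count"):
            report["markers"][marker]["detection_rate_cases_pct"] = round(
                detection_rate(cases.astype(int)), 6)
        t = mann_whitney(cases, controls)
        report["tests"][marker] = {"u": t.u, "p": round(t.p, 8), "method": t.method}
    built = []
    for spec_markers in models:
        model = combined_model(cohort, spec_markers)
        report["models"][model.name] = model.to_dict()
        built.append(model)
    report["comparison"] = compare_models(
        [evaluate_marker(cohort, m) for m in markers] + built
    ).to_dict(orient="records")
    return report
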