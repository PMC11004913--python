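"""Cross-validated screening evaluation: ROC/AUC, sensitivity at fixed
specificity, paired permutation tests, screening horizons, lead time and
case contingency tables.

The outer evaluation plan is repeated stratified k-fold cross-validation
(default 5 folds, 2 repetitions, i.e. 10 train/test pairs).  Performance is
summarised per fold and aggregated as mean with a normal-approximation 95%
confidence interval across folds (bootstrap optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import RepeatedStratifiedKFold

from .cohort import Cohort, VisitSeries

__all__ = [
    "FoldPlan", "FoldResult", "LeadTimeStats", "make_folds", "auc",
    "sensitivity_at_specificity", "permutation_test_paired", "screen_horizon",
    "lead_time", "contingency", "summarize_metric", "lead_time_summary",
]


# ------------------------------------------------------------------ fold plan

@dataclass
class FoldPlan:
    """Outer train/test splits preserving the case/control proportion."""

    folds: list                      # list of (train_ids, test_ids) tuples
    k: int
    reps: int
    seed: int

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def make_folds(cohort: Cohort, k: int = 5, reps: int = 2,
               seed: int = 0) -> FoldPlan:
    """Repeated stratified k-fold split of a cohort by patient."""
    if cohort.n_cases < k or cohort.n_controls < k:
        raise ValueError(f"need at least {k} cases and {k} controls")
    ids = np.array(cohort.ids)
    labels = cohort.labels
    splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=reps,
                                       random_state=seed)
    folds = [(list(ids[tr]), list(ids[te]))
             for tr, te in splitter.split(ids, labels)]
    return FoldPlan(folds=folds, k=k, reps=reps, seed=seed)


# ------------------------------------------------------------------- metrics

def auc(labels, scores) -> float:
    """Area under the ROC curve via the Mann-Whitney U normalisation.

    Ties between a case and a control score count one half.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def sensitivity_at_specificity(labels, scores,
                               specificity: float = 0.90) -> tuple[float, float]:
    """Sensitivity at the smallest threshold keeping the requested fraction
    of controls below it; scores at the threshold count as abnormal.

    Returns (sensitivity, threshold).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    ctrl = scores[labels == 0]
    case = scores[labels == 1]
    if ctrl.size == 0 or case.size == 0:
        raise ValueError("both classes must be present")
    # candidate cutoffs: every observed score plus one above the maximum
    candidates = np.unique(scores)
    candidates = np.append(candidates, candidates[-1] + 1.0)
    spec = (ctrl[None, :] < candidates[:, None]).mean(axis=1)
    ok = np.nonzero(spec >= specificity)[0]
    threshold = float(candidates[ok[0]])
    sensitivity = float((case >= threshold).mean())
    return sensitivity, threshold


def permutation_test_paired(metric_a, metric_b, n_perm: int = 10_000,
                            seed: int = 0) -> float:
    """One-sided sign-flip permutation p-value for mean(a - b) > 0.

    With ``n_perm >= 2^n`` all sign patterns are enumerated exactly
    (p = #{permuted mean >= observed}/2^n); otherwise ``n_perm`` random
    flips are drawn and p = (#{>= observed} + 1)/(n_perm + 1).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("paired metric vectors must be non-empty, equal length")
    d = a - b
    n = d.size
    observed = d.mean()
    tol = 1e-12
    if n <= 30 and n_perm >= 2**n:
        signs = np.array([[1 if (i >> j) & 1 else -1 for j in range(n)]
                          for i in range(2**n)], dtype=float)
        means = signs @ d / n
        return float((means >= observed - tol).mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = signs @ d / n
    return float(((means >= observed - tol).sum() + 1) / (n_perm + 1))


# ---------------------------------------------------------- screening horizon

def screen_horizon(cohort: Cohort, horizon) -> dict:
    """Evaluated visit index per patient for one screening horizon.

    ``horizon`` is ``"all"`` (last visit) or a number of years h: a case's
    evaluated visit is the last one at least h years before diagnosis;
    controls are truncated by the same calendar span before their last
    visit.  Patients with no qualifying visit are omitted.
    """
    out = {}
    h = 0.0 if horizon in ("all", 0, 0.0) else float(horizon)
    for p in cohort.patients:
        ref = p.diagnosis_age if p.status == 1 else p.d
        eligible = np.nonzero(ref - p.ages >= h - 1e-9)[0]
        if eligible.size:
            out[p.patient_id] = int(eligible[-1])
    return out


def lead_time(ages, risks, threshold: float,
              diagnosis_age: float) -> float | None:
    """Years from the earliest abnormal screen (risk >= threshold) to
    diagnosis; ``None`` if no screen is abnormal."""
    ages = np.asarray(ages, dtype=float)
    risks = np.asarray(risks, dtype=float)
    abnormal = np.nonzero(risks >= threshold)[0]
    if abnormal.size == 0:
        return None
    return float(diagnosis_age - ages[abnormal[0]])


def contingency(detected_a: dict, detected_b: dict) -> dict:
    """2x2 diagnosed/missed case counts for two models on the same cases.

    Inputs map case id -> bool (detected).  Returns the four cells keyed
    ``a_diagnosed_b_diagnosed`` etc.
    """
    if set(detected_a) != set(detected_b):
        raise ValueError("both models must score the same case set")
    cells = {"a_diagnosed_b_diagnosed": 0, "a_diagnosed_b_missed": 0,
             "a_missed_b_diagnosed": 0, "a_missed_b_missed": 0}
    for cid in detected_a:
        key = (f"a_{'diagnosed' if detected_a[cid] else 'missed'}"
               f"_b_{'diagnosed' if detected_b[cid] else 'missed'}")
        cells[key] += 1
    return cells


# ---------------------------------------------------------------- aggregation

@dataclass
class FoldResult:
    """Per-fold metrics for one model/scenario/horizon."""

    model: str
    scenario: str
    horizon: str
    fold: int
    auc: float
    sensitivity: float
    threshold: float

    def as_dict(self):
        return {"model": self.model, "scenario": self.scenario,
                "horizon": self.horizon, "fold": self.fold, "auc": self.auc,
                "sensitivity": self.sensitivity, "threshold": self.threshold}


@dataclass
class LeadTimeStats:
    """Across-fold summaries of lead time (years) with 95% CIs."""

    mean: tuple
    median: tuple
    min: tuple
    max: tuple

    def as_dict(self):
        out = {}
        for name in ("mean", "median", "min", "max"):
            est, lo, hi = getattr(self, name)
            out[f"{name}_lead_time"] = est
            out[f"{name}_ci_lo"] = lo
            out[f"{name}_ci_hi"] = hi
        return out


def _ci(values, method: str = "normal", seed: int = 0,
        n_boot: int = 2000) -> tuple[float, float, float]:
    values = np.asarray(values, dtype=float)
    est = float(values.mean())
    if values.size < 2:
        return est, est, est
    if method == "normal":
        se = values.std(ddof=1) / np.sqrt(values.size)
        return est, est - 1.96 * se, est + 1.96 * se
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = rng.choice(values, size=(n_boot, values.size)).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        return est, float(lo), float(hi)
    raise ValueError(f"unknown CI method {method}")


def summarize_metric(fold_values, method: str = "normal",
                     seed: int = 0) -> tuple[float, float, float]:
    """(mean, ci_lo, ci_hi) across fold-level metric values."""
    return _ci(fold_values, method=method, seed=seed)


def lead_time_summary(per_fold_lead_times: list, method: str = "normal",
                      seed: int = 0) -> LeadTimeStats:
    """Summaries across folds of per-fold lead-time lists.

    Each element of ``per_fold_lead_times`` is the list of detected-case
    lead times in one fold; folds with no detection are skipped.
    """
    stats = {"mean": [], "median": [], "min": [], "max": []}
    for fold in per_fold_lead_times:
        arr = np.asarray([v for v in fold if v is not None], dtype=float)
        if arr.size == 0:
            continue
        stats["mean"].append(arr.mean())
        stats["median"].append(np.median(arr))
        stats["min"].append(arr.min())
        stats["max"].append(arr.max())
    if not stats["mean"]:
        raise ValueError("no fold produced a detected case")
    return LeadTimeStats(
        mean=_ci(stats["mean"], method, seed),
        median=_ci(stats["median"], method, seed),
        min=_ci(stats["min"], method, seed),
        max=_ci(stats["max"], method, seed),
    )
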