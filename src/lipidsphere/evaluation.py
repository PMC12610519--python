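"""Risk-marker evaluation: ROC/AUROC, confusion metrics, cost-sensitive
cutoff optimisation, quantile stratification, Kaplan-Meier curves and the
log-rank test.

Conventions (all deterministic):

* a positive call is ``score >= cutoff``;
* AUROC is the Mann-Whitney concordance probability with ties counted 1/2;
* quantile bins assign boundary ties to the lower bin;
* cutoff optimisation minimises ``fn_weight * FN + FP`` on held-out folds
  and aggregates fold-optimal cutoffs by their mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, FitError

logger = logging.getLogger(__name__)


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise DomainError("labels must be binary 0/1")
    return y


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney concordance, ties = 1/2)."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if not (0 < y.sum() < len(y)):
        raise DomainError("AUROC needs both outcome classes present")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, s))


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and derived metrics at one cutoff.

    Ratios with a zero denominator are NaN and their names appear in
    ``undefined``.
    """

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    undefined: frozenset[str] = frozenset()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_metrics(scores, labels, cutoff: float) -> ConfusionMetrics:
    """Confusion metrics with positive calls at ``score >= cutoff``."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    calls = s >= cutoff
    tp = int(np.sum(calls & (y == 1)))
    fp = int(np.sum(calls & (y == 0)))
    fn = int(np.sum(~calls & (y == 1)))
    tn = int(np.sum(~calls & (y == 0)))
    undefined: set[str] = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return float("nan")
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    ppv = ratio(tp, tp + fp, "ppv")
    npv = ratio(tn, tn + fn, "npv")
    if np.isnan(ppv) or np.isnan(sens) or (ppv + sens) == 0:
        undefined.add("f1")
        f1 = float("nan")
    else:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    return ConfusionMetrics(
        cutoff=float(cutoff),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        f1=f1,
        undefined=frozenset(undefined),
    )


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    """Distinct-score midpoints plus the minimum score (all-positive call)."""
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[distinct[0]], mids])


def _fold_cost(scores, y, cutoffs, fn_weight) -> np.ndarray:
    # cost(c) = fn_weight * FN(c) + FP(c), vectorised over candidate cutoffs
    calls = scores[None, :] >= cutoffs[:, None]
    fn = np.sum(~calls & (y == 1)[None, :], axis=1)
    fp = np.sum(calls & (y == 0)[None, :], axis=1)
    return fn_weight * fn + fp


def optimize_cutoff(
    scores,
    labels,
    fn_weight: float = 2.0,
    k_folds: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated cost-sensitive cutoff.

    Candidate cutoffs are the observed-score midpoints. Within each
    stratified fold the candidate minimising ``fn_weight * FN + FP`` on
    the held-out fold is selected (ties favour the lower cutoff, i.e.
    higher sensitivity); the returned cutoff is the mean of the
    fold-optimal values. Deterministic for a given seed.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if not (0 < y.sum() < len(y)):
        raise DomainError("cutoff optimisation needs both classes present")
    if fn_weight < 1:
        raise DomainError("fn_weight must be >= 1")
    if k_folds < 2:
        raise DomainError("k_folds must be >= 2")
    if len(y) < k_folds:
        raise DomainError("need at least k_folds observations")
    n_min_class = int(min(y.sum(), len(y) - y.sum()))
    if n_min_class < 2:
        raise FitError(
            "cannot form cross-validation folds: minority class has < 2 members"
        )
    k = min(k_folds, n_min_class)
    if k < k_folds:
        logger.warning(
            "reducing folds from %d to %d to keep both classes in every fold",
            k_folds, k,
        )
    from sklearn.model_selection import StratifiedKFold

    cutoffs = _candidate_cutoffs(s)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_best: list[float] = []
    for _, test_idx in skf.split(s.reshape(-1, 1), y):
        cost = _fold_cost(s[test_idx], y[test_idx], cutoffs, fn_weight)
        # argmin takes the first (lowest) cutoff on ties
        fold_best.append(float(cutoffs[int(np.argmin(cost))]))
    return float(np.mean(fold_best))


def quantile_bins(values, q: int) -> np.ndarray:
    """Assign each value a 0-based quantile-bin index.

    Boundaries are the 1/q ... (q-1)/q empirical quantiles; values equal
    to a boundary go to the lower bin, so a tie group never straddles a
    boundary. Massive ties that collapse boundaries are logged.
    """
    v = np.asarray(values, dtype=float)
    if q < 1:
        raise DomainError("q must be >= 1")
    if len(v) < q:
        raise DomainError(f"need at least q={q} values, got {len(v)}")
    boundaries = np.quantile(v, np.arange(1, q) / q)
    if len(boundaries) != len(np.unique(boundaries)):
        logger.warning("tied values collapse quantile boundaries; bins are unequal")
    return np.searchsorted(boundaries, v, side="left")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit (Kaplan-Meier) estimate at the distinct observed times."""

    times: np.ndarray  # ordered distinct observed times
    at_risk: np.ndarray  # risk-set size just before each time
    events: np.ndarray  # events at each time
    censored: np.ndarray  # censorings at each time
    survival: np.ndarray  # S(t) just after each time

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator; censored subjects leave the risk set after
    their recorded time."""
    t = np.asarray(times, dtype=float)
    e = _as_binary(events)
    if len(t) == 0:
        raise DomainError("empty survival input")
    if np.any(t < 0):
        raise DomainError("survival times must be >= 0")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    # keep only rows for observed times (lifelines inserts a t=0 anchor row)
    table = kmf.event_table
    table = table[(table["observed"] + table["censored"]) > 0]
    sf = kmf.survival_function_["KM_estimate"]
    out_times = table.index.to_numpy(dtype=float)
    return SurvivalCurve(
        times=out_times,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        censored=table["censored"].to_numpy(dtype=int),
        survival=np.array([float(sf.loc[tt]) for tt in out_times]),
    )


def logrank_chisq(groups: list[tuple[np.ndarray, np.ndarray]]) -> tuple[float, int]:
    """Log-rank chi-square over two or more groups.

    ``groups`` is a list of (times, events) pairs. Returns (chi_square,
    degrees of freedom = n_groups - 1).
    """
    if len(groups) < 2:
        raise DomainError("log-rank needs at least 2 groups")
    all_t, all_e, all_g = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = _as_binary(e)
        if len(t) == 0:
            raise DomainError(f"group {gi} is empty")
        all_t.append(t)
        all_e.append(e)
        all_g.append(np.full(len(t), gi))
    t = np.concatenate(all_t)
    e = np.concatenate(all_e)
    g = np.concatenate(all_g)
    if e.sum() == 0:
        raise DomainError("no events in any group; log-rank undefined")
    from lifelines.statistics import multivariate_logrank_test

    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), len(groups) - 1


def evaluate_marker(
    scores,
    labels,
    times=None,
    n_quantiles: int = 5,
    fn_weight: float = 2.0,
    k_folds: int = 5,
    seed: int = 0,
    extra_cutoffs: dict[str, float] | None = None,
) -> dict:
    """One-stop marker report: AUROC, optimised-cutoff confusion metrics,
    and (when follow-up times are given) quantile Kaplan-Meier curves with
    the log-rank chi-square. Returns a plain dict of results."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    report: dict = {"n": len(y), "prevalence": float(y.mean())}
    report["auroc"] = roc_auc(s, y)
    cut = optimize_cutoff(s, y, fn_weight=fn_weight, k_folds=k_folds, seed=seed)
    report["optimized_cutoff"] = cut
    report["metrics_at_optimized"] = confusion_metrics(s, y, cut)
    for label, c in (extra_cutoffs or {}).items():
        report[f"metrics_at_{label}"] = confusion_metrics(s, y, c)
    if times is not None:
        t = np.asarray(times, dtype=float)
        bins = quantile_bins(s, n_quantiles)
        groups = [
            (t[bins == b], y[bins == b])
            for b in range(n_quantiles)
            if np.any(bins == b)
        ]
        report["km_by_quantile"] = [
            kaplan_meier(gt, ge) for gt, ge in groups
        ]
        chi2, df = logrank_chisq(groups)
        report["logrank_chisq"] = chi2
        report["logrank_df"] = df
    return report
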