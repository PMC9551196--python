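"""Candidate evaluation statistics.

ROC AUC via the Mann-Whitney midrank identity (with one-vs-rest "Stage-AUC"),
combined logistic models, Kaplan-Meier / log-rank survival, mean- or
median-split group comparisons for drug response, Spearman correlation, and a
generic hypergeometric over-representation test for user-supplied gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .errors import DegenerateStatisticError, InputError
from .exprde import HEALTHY, ExpressionStudy, GroupTestResult, bh_adjust


@dataclass
class ROCResult:
    name: str
    contrast: str
    auc: float
    direction: str  # "high_in_cases" or "low_in_cases"


def auc_rank(values, labels, auto_direction: bool = True,
             name: str = "", contrast: str = "") -> ROCResult:
    """AUC = U / (n1 * n2) from midranks (Mann-Whitney identity).

    ``labels`` is boolean-like, True marking cases. With ``auto_direction``
    the reported AUC is max(auc, 1 - auc) and the favoured direction recorded.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n2 = int((~labels).sum())
    if n1 == 0 or n2 == 0:
        raise InputError("both classes must be nonempty for AUC")
    ranks = stats.rankdata(values)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n2))
    direction = "high_in_cases"
    if auto_direction and auc < 0.5:
        auc = 1.0 - auc
        direction = "low_in_cases"
    return ROCResult(name=name, contrast=contrast, auc=auc, direction=direction)


def crc_auc(study: ExpressionStudy, feature: str) -> ROCResult:
    """AUC of one feature separating tumor samples (any stage) from healthy."""
    samples = list(study.matrix.columns)
    groups = study.sample_sheet.loc[samples, "group"]
    labels = (groups != HEALTHY).to_numpy()
    return auc_rank(study.matrix.loc[feature, samples].to_numpy(dtype=float),
                    labels, name=feature, contrast="CRC-vs-healthy")


def stage_auc(study: ExpressionStudy, feature: str, stage: str) -> ROCResult:
    """One-vs-rest AUC for one stage, computed among tumor samples only."""
    samples = list(study.matrix.columns)
    groups = study.sample_sheet.loc[samples, "group"]
    tumor = groups != HEALTHY
    tumor_groups = groups[tumor]
    if stage not in set(tumor_groups):
        raise InputError(f"stage {stage!r} absent among tumor samples")
    vals = study.matrix.loc[feature, tumor_groups.index].to_numpy(dtype=float)
    labels = (tumor_groups == stage).to_numpy()
    return auc_rank(vals, labels, name=feature, contrast=f"{stage}-vs-rest")


def fit_logistic_combined(
    study: ExpressionStudy,
    features: list[str],
    case,
    control=None,
    ridge_lambda: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[LogisticRegression, ROCResult]:
    """Multivariate logistic model over the given features, scored in-sample.

    ``case`` is a group label or set of labels; ``control`` likewise (defaults
    to every other group). A small L2 penalty keeps the fit defined under
    complete separation.
    """
    if not features:
        raise InputError("need at least one feature")
    case = {case} if isinstance(case, str) else set(case)
    samples = list(study.matrix.columns)
    groups = study.sample_sheet.loc[samples, "group"]
    if control is None:
        mask = np.ones(len(samples), dtype=bool)
    else:
        control = {control} if isinstance(control, str) else set(control)
        mask = groups.isin(case | control).to_numpy()
    X = study.matrix.loc[features, samples].to_numpy(dtype=float).T[mask]
    y = groups.isin(case).to_numpy()[mask]
    if y.all() or not y.any():
        raise InputError("both classes must be nonempty for the combined model")
    model = LogisticRegression(C=1.0 / ridge_lambda, solver="lbfgs",
                               max_iter=max_iter)
    model.fit(X, y)
    if model.n_iter_[0] >= max_iter:
        raise InputError(f"logistic fit did not converge in {max_iter} iterations")
    probs = model.predict_proba(X)[:, 1]
    roc = auc_rank(probs, y, name="+".join(features),
                   contrast="combined:" + "|".join(sorted(case)))
    return model, roc


@dataclass
class KMCurve:
    times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi_sq: float
    df: int
    p: float


def km_curve(times, events) -> KMCurve:
    """Product-limit (Kaplan-Meier) survival estimate with right censoring."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise InputError("survival times must be nonnegative")
    if not np.isin(events, (0, 1)).all():
        raise InputError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.unique(times[events == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    at_risk = np.array([(times >= t).sum() for t in event_times])
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk)


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-group log-rank test: chi-square = (sum(O-E))^2 / sum(V), 1 df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise InputError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    g0 = groups == labels[0]
    if g0.all() or not g0.any():
        raise InputError("each group needs at least one subject")
    res = _ll_logrank(times[g0], times[~g0], event_observed_A=events[g0],
                      event_observed_B=events[~g0])
    chi = float(res.test_statistic)
    if not np.isfinite(chi):  # no events at all -> no information
        return LogRankResult(chi_sq=0.0, df=1, p=1.0)
    return LogRankResult(chi_sq=chi, df=1, p=float(res.p_value))


def expression_split(values, rule: str = "mean") -> np.ndarray:
    """Boolean high/low assignment: high means strictly above the cutpoint."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InputError("need at least 2 samples to split")
    if np.all(values == values[0]):
        raise DegenerateStatisticError("all values identical; split undefined")
    if rule == "mean":
        cut = values.mean()
    elif rule == "median":
        cut = np.median(values)
    else:
        raise InputError(f"unknown split rule {rule!r}")
    high = values > cut
    if high.all() or not high.any():
        raise DegenerateStatisticError(f"{rule} split puts all samples on one side")
    return high


def drug_response_test(
    ic50, gene_expr, rule: str = "median", welch: bool = True
) -> GroupTestResult:
    """Two-sided t-test of IC50 between high/low expression cell-line groups.

    Welch (unequal variance) by default. Direction reports which expression
    group is more resistant (higher mean IC50).
    """
    ic50 = np.asarray(ic50, dtype=float)
    gene_expr = np.asarray(gene_expr, dtype=float)
    if ic50.shape != gene_expr.shape:
        raise InputError("ic50 and expression vectors must align")
    high = expression_split(gene_expr, rule=rule)
    a, b = ic50[high], ic50[~high]
    if len(a) < 2 or len(b) < 2:
        raise InputError("each split group needs >=2 cell lines")
    if np.all(ic50 == ic50[0]):
        t, p, df = 0.0, 1.0, float(len(ic50) - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df) if hasattr(res, "df") else float(len(ic50) - 2)
    means = {"high": float(a.mean()), "low": float(b.mean())}
    direction = "high_expression_resistant" if means["high"] >= means["low"] \
        else "low_expression_resistant"
    return GroupTestResult(statistic=t, df=df, p=p, group_summary=means,
                           direction=direction)


def spearman_test(x, y) -> tuple[float, float]:
    """Midrank Spearman rho with t-approximation p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InputError("need equal-length vectors of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateStatisticError("constant vector; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class OraResult:
    set_id: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    adj_p: float


def hypergeom_ora(query: set, sets: dict[str, set], universe: set) -> list[OraResult]:
    """Upper-tail hypergeometric over-representation of the query in each set."""
    query, universe = set(query), set(universe)
    if not query <= universe:
        raise InputError("query must be a subset of the universe")
    results = []
    for sid in sorted(sets):
        s = set(sets[sid])
        if not s <= universe:
            raise InputError(f"gene set {sid!r} not contained in the universe")
        k = len(query & s)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(s), len(query)))
        results.append([sid, k, len(s), min(p, 1.0)])
    adj = bh_adjust([r[3] for r in results]) if results else []
    return [
        OraResult(set_id=sid, overlap=k, set_size=n, query_size=len(query),
                  universe_size=len(universe), p=p, adj_p=float(a))
        for (sid, k, n, p), a in zip(results, adj)
    ]
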