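"""Expression preprocessing and differential expression.

The differential test is an empirical-Bayes moderated t: per-feature pooled
variances are shrunk toward a common prior fitted by method of moments on the
log sample variances (digamma/trigamma inversion), and the moderated statistic
is referenced to a t distribution with augmented degrees of freedom. This
stabilises variance estimates for the small group sizes typical of exosome
microarray cohorts (11-20 samples per arm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.impute import KNNImputer
from statsmodels.stats.multitest import multipletests

from .errors import InputError

logger = logging.getLogger(__name__)

#: canonical tumor stage labels, ordered
STAGES = ("I", "II", "IIIA", "IIIB", "IV")
HEALTHY = "healthy"
GROUP_LABELS = (HEALTHY,) + STAGES


@dataclass
class ExpressionStudy:
    """A log2 feature x sample expression matrix with per-sample annotations.

    Parameters
    ----------
    matrix : DataFrame
        Features (rows) by samples (columns), log2 scale, no missing values.
    sample_sheet : DataFrame
        Indexed by sample id, with a ``group`` column (healthy/I/II/IIIA/IIIB/IV)
        and optional ``time`` (days) and ``event`` (0/1) survival columns.
    """

    matrix: pd.DataFrame
    sample_sheet: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            raise InputError("duplicate feature ids in expression matrix")
        if self.matrix.columns.has_duplicates:
            raise InputError("duplicate sample ids in expression matrix")
        missing = set(self.matrix.columns) - set(self.sample_sheet.index)
        if missing:
            raise InputError(f"samples without group label: {sorted(missing)[:5]}")
        if self.matrix.isna().any().any():
            raise InputError("expression matrix contains missing values; preprocess first")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.matrix.index)

    def samples_in_group(self, group: str) -> list[str]:
        sheet = self.sample_sheet.loc[list(self.matrix.columns)]
        return list(sheet.index[sheet["group"] == group])

    def values(self, feature: str, samples) -> np.ndarray:
        return self.matrix.loc[feature, samples].to_numpy(dtype=float)


def preprocess_matrix(
    raw: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    already_log2: bool = False,
    k: int = 5,
) -> ExpressionStudy:
    """Clean a raw intensity matrix into an :class:`ExpressionStudy`.

    Negative and missing cells are masked and imputed from the ``k`` nearest
    feature profiles (Euclidean distance over shared samples, mean of the
    neighbours' values; falls back to the feature median when no neighbour has
    the value). Features missing everywhere are dropped with a warning.
    Unless ``already_log2``, log2(x + 1) is applied after imputation.
    """
    mat = raw.astype(float).copy()
    mat = mat.mask(mat < 0)
    all_missing = mat.isna().all(axis=1)
    if all_missing.any():
        dropped = list(mat.index[all_missing])
        logger.warning("dropping %d all-missing features: %s", len(dropped), dropped[:5])
        mat = mat.loc[~all_missing]
    if mat.isna().any().any():
        # features are rows, so row-neighbour imputation = nearest feature profiles
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        imputed = imputer.fit_transform(mat.to_numpy())
        mat = pd.DataFrame(imputed, index=mat.index, columns=mat.columns)
    if not already_log2:
        mat = np.log2(mat + 1.0)
    return ExpressionStudy(matrix=mat, sample_sheet=sample_sheet)


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) for the scaled inverse-chi^2 prior.

    Moments are matched on z = log(s2): E z and Var z involve digamma and
    trigamma terms of the residual and prior degrees of freedom.
    """
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess dispersion in log s^2: infinite prior df; the geometric
        # mean keeps the identical-variance case identical to the pooled t
        d0 = np.inf
        s0_sq = float(np.exp(z.mean()))
    return d0, s0_sq


def moderated_t_test(study: ExpressionStudy, case: str, control: str) -> pd.DataFrame:
    """Moderated two-group t-test for every feature, case minus control.

    Returns a table with columns feature, log2fc, t, p, adj_p, direction.
    """
    case_samples = study.samples_in_group(case)
    ctrl_samples = study.samples_in_group(control)
    n1, n0 = len(case_samples), len(ctrl_samples)
    if n1 < 2 or n0 < 2:
        raise InputError(
            f"moderated t needs >=2 samples per group; got {case}={n1}, {control}={n0}"
        )
    x1 = study.matrix[case_samples].to_numpy(dtype=float)
    x0 = study.matrix[ctrl_samples].to_numpy(dtype=float)
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    df_resid = float(n1 + n0 - 2)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x0.var(axis=1, ddof=1) * (n0 - 1)
    s2 = ss / df_resid

    d0, s0_sq = _fit_variance_prior(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    log2fc = m1 - m0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 0.0, 1.0)

    table = pd.DataFrame(
        {
            "feature": study.feature_ids,
            "log2fc": log2fc,
            "t": t_mod,
            "p": p,
            "adj_p": bh_adjust(p),
            "direction": np.where(log2fc >= 0, "up", "down"),
        }
    )
    table.attrs["d0"] = d0
    table.attrs["s0_sq"] = s0_sq
    return table


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def threshold_de(
    table: pd.DataFrame,
    p_max: float = 0.05,
    lfc_min: float = 1.0,
    use_adjusted: bool = False,
) -> set[tuple[str, str]]:
    """Features passing p < p_max (strict) and |log2fc| > lfc_min (strict)."""
    pcol = "adj_p" if use_adjusted else "p"
    keep = (table[pcol] < p_max) & (table["log2fc"].abs() > lfc_min)
    return set(zip(table.loc[keep, "feature"], table.loc[keep, "direction"]))


@dataclass
class GroupTestResult:
    statistic: float
    df: float
    p: float
    group_summary: dict
    direction: str | None = None


def nonparam_stage_test(study: ExpressionStudy, feature: str, groups) -> GroupTestResult:
    """Rank-based comparison of a feature across sample groups.

    Two groups: Wilcoxon rank-sum (midranks, normal approximation with tie
    correction). More than two: Kruskal-Wallis chi-square.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    samples = [study.samples_in_group(g) for g in groups]
    for g, s in zip(groups, samples):
        if not s:
            raise InputError(f"group {g!r} has no samples")
    vals = [study.values(feature, s) for s in samples]
    medians = {g: float(np.median(v)) for g, v in zip(groups, vals)}
    pooled = np.concatenate(vals)
    if np.all(pooled == pooled[0]):
        return GroupTestResult(0.0, float(len(groups) - 1), 1.0, medians)
    if len(groups) == 2:
        res = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided",
                                 method="asymptotic")
        return GroupTestResult(float(res.statistic), 1.0, float(res.pvalue), medians)
    res = stats.kruskal(*vals)
    return GroupTestResult(float(res.statistic), float(len(groups) - 1),
                           float(res.pvalue), medians)
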