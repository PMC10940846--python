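"""Nonparametric cohort statistics for flow-index group comparisons.

Implements the statistical layer used to compare flow indices between
study groups: Mann-Whitney U for two groups, Kruskal-Wallis for three or
more with Conover-Iman rank post-hoc tests, partial correlation via
multiple regression, empirical ROC curves with Youden-index cut-offs,
and the within-subject coefficient of variation for method agreement.

All tests are two-sided. Group summaries are median and IQR with
quantiles by linear interpolation between order statistics (numpy's
default rule); the choice matters because median +/- IQR summaries are
not invariant to the quantile rule. No multiplicity adjustment is
applied by default; Holm is available by flag on the post-hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupComparison:
    """Result of one two- or k-group rank test."""

    groups: tuple[str, ...]
    statistic: float
    p_value: float
    summaries: dict[str, tuple[float, float]]  # group -> (median, iqr)
    test: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class ROCResult:
    """Empirical ROC curve with the Youden-index operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float


def summarize_group(values: Sequence[float]) -> tuple[float, float]:
    """(median, IQR) with linear-interpolation quantiles."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return np.nan, np.nan
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return float(q50), float(q75 - q25)


def _clean(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) == 0:
        raise ValueError(f"group '{name}' is empty")
    return arr


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    names: tuple[str, str] = ("x", "y"),
) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when the pooled sample is small (n1 + n2 <= 12)
    and tie-free, and the tie-corrected normal approximation otherwise.
    """
    xa, ya = _clean(x, names[0]), _clean(y, names[1])
    pooled = np.concatenate([xa, ya])
    small = len(pooled) <= 12 and len(np.unique(pooled)) == len(pooled)
    method = "exact" if small else "asymptotic"
    res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return GroupComparison(
        groups=names,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        summaries={names[0]: summarize_group(xa), names[1]: summarize_group(ya)},
        test=f"mann-whitney ({method})",
    )


def kruskal_wallis(groups: dict[str, Sequence[float]]) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with a chi-square reference (df=k-1)."""
    if len(groups) < 3:
        raise ValueError("kruskal_wallis needs >= 3 groups; use mann_whitney for two")
    arrays = {k: _clean(v, k) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group '{k}' needs n >= 2")
    h, p = stats.kruskal(*arrays.values())
    return GroupComparison(
        groups=tuple(arrays),
        statistic=float(h),
        p_value=float(p),
        summaries={k: summarize_group(v) for k, v in arrays.items()},
        test="kruskal-wallis",
    )


def conover_posthoc(
    groups: dict[str, Sequence[float]],
    adjust: Optional[str] = None,
) -> list[GroupComparison]:
    """Conover-Iman pairwise rank tests following Kruskal-Wallis.

    The t statistic compares mean pooled ranks with the pooled rank
    variance scaled by ``(N - 1 - H) / (N - k)`` and df = N - k; midranks
    handle ties, and the scaling makes the test consistent with the H
    statistic computed on the same data. p-values are unadjusted by
    default; ``adjust='holm'`` applies the Holm step-down correction.
    """
    arrays = {k: _clean(v, k) for k, v in groups.items()}
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(list(arrays.values()))
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # split ranks back into groups
    rank_groups: dict[str, np.ndarray] = {}
    start = 0
    for name, arr in arrays.items():
        rank_groups[name] = ranks[start : start + len(arr)]
        start += len(arr)

    degenerate = len(np.unique(pooled)) == 1
    if degenerate:
        h = 0.0
        s2 = 0.0
    else:
        h, _ = stats.kruskal(*arrays.values())
        s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1)

    df = n_total - k
    names = list(arrays)
    results = []
    pvals = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            if degenerate or s2 <= 0 or df <= 0:
                t, p = 0.0, 1.0
            else:
                var = s2 * ((n_total - 1 - h) / df) * (
                    1.0 / len(rank_groups[a]) + 1.0 / len(rank_groups[b])
                )
                if var <= 0:
                    t, p = np.inf, 0.0
                else:
                    t = (rank_groups[a].mean() - rank_groups[b].mean()) / np.sqrt(var)
                    p = 2.0 * stats.t.sf(abs(t), df)
            pvals.append(min(p, 1.0))
            results.append(
                GroupComparison(
                    groups=(a, b),
                    statistic=float(t),
                    p_value=float(min(p, 1.0)),
                    summaries={a: summarize_group(arrays[a]), b: summarize_group(arrays[b])},
                    test="conover",
                )
            )
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(pvals, method="holm")
        for res, p in zip(results, adj):
            res.p_value = float(p)
            res.test = "conover (holm)"
    elif adjust is not None:
        raise ValueError(f"unknown adjustment '{adjust}'")
    return results


def partial_correlation(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: Sequence[str] = (),
) -> tuple[float, float]:
    """Partial correlation of outcome and predictor given covariates.

    Fits the outcome on predictor + covariates by ordinary least squares
    and converts the predictor's t statistic: r = t / sqrt(t^2 + df).
    With no covariates this reduces to the Pearson correlation.
    """
    import statsmodels.api as sm

    cols = [outcome, predictor, *covariates]
    sub = data[cols].dropna()
    n = len(sub)
    if n <= len(covariates) + 2:
        raise ValueError(f"n={n} too small for {len(covariates)} covariates")
    design = sub[[predictor, *covariates]].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), design]))
    if rank < design.shape[1] + 1:
        bad = _collinear_columns(design, [predictor, *covariates])
        raise ValueError(f"collinear design columns: {bad}")
    model = sm.OLS(sub[outcome].to_numpy(dtype=float), sm.add_constant(design)).fit()
    t = model.tvalues[1]  # predictor is first after the constant
    df = model.df_resid
    r = t / np.sqrt(t**2 + df)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(r), float(p)


def _collinear_columns(design: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name columns that are linear combinations of the preceding ones."""
    bad = []
    n = design.shape[0]
    kept = [np.ones(n)]
    for j, name in enumerate(names):
        candidate = np.column_stack(kept + [design[:, j]])
        if np.linalg.matrix_rank(candidate) < candidate.shape[1]:
            bad.append(name)
        else:
            kept.append(design[:, j])
    return bad


def roc_youden(
    values: Sequence[float],
    labels: Sequence[int],
    positive_direction: str = ">",
) -> ROCResult:
    """Empirical ROC with the Youden-index cut-off.

    Thresholds are the midpoints between adjacent sorted unique values
    plus -inf/+inf sentinels, so a strict-inequality rule like
    "positive when value > c" is representable for every achievable
    confusion matrix. The AUC uses the rank (Mann-Whitney) identity with
    midranks for ties. The Youden cut-off maximises sensitivity +
    specificity - 1, ties broken toward the smaller threshold.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape:
        raise ValueError("values and labels must align")
    keep = np.isfinite(v)
    v, y = v[keep], y[keep]
    if positive_direction == "<":
        return _flip_roc(roc_youden(-v, y, ">"))
    if positive_direction != ">":
        raise ValueError("positive_direction must be '>' or '<'")
    cases, controls = v[y == 1], v[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")

    uniq = np.unique(v)
    mid = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mid, [np.inf]])
    sens = np.array([(cases > t).mean() for t in thresholds])
    spec = np.array([(controls <= t).mean() for t in thresholds])

    # AUC via the rank identity: U / (n1 n2) with midranks
    ranks = stats.rankdata(v)
    u = ranks[y == 1].sum() - len(cases) * (len(cases) + 1) / 2.0
    auc = u / (len(cases) * len(controls))

    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (smallest threshold) on ties
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        youden_cutoff=float(thresholds[best]),
        sens_at_cutoff=float(sens[best]),
        spec_at_cutoff=float(spec[best]),
    )


def _flip_roc(res: ROCResult) -> ROCResult:
    return ROCResult(
        thresholds=-res.thresholds[::-1],
        sensitivity=res.sensitivity[::-1],
        specificity=res.specificity[::-1],
        auc=res.auc,
        youden_cutoff=-res.youden_cutoff,
        sens_at_cutoff=res.sens_at_cutoff,
        spec_at_cutoff=res.spec_at_cutoff,
    )


def cov_within_subject(method_a: Sequence[float], method_b: Sequence[float]) -> float:
    """Within-subject coefficient of variation between paired methods, %.

    Root-mean-square form: 100 * sqrt(mean(d_i^2 / 2)) / grand mean, with
    d_i the paired differences. Scale-invariant; undefined (NaN) when the
    grand mean is not positive.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired inputs must be equal-length 1D arrays")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    grand = np.concatenate([a, b]).mean()
    if grand <= 0:
        return np.nan
    d = a - b
    return float(100.0 * np.sqrt(np.mean(d**2 / 2.0)) / grand)


def match_age_sex(
    table: pd.DataFrame,
    case_group: str,
    control_group: str,
    caliper_years: float = 10.0,
) -> pd.DataFrame:
    """Greedy 1:1 exact-sex, nearest-age matching within a caliper.

    Returns the matched subset of ``table`` (both groups). This is a
    labelled approximation of an age/sex-matched sub-group design, not a
    claim about any particular study's pairing procedure.
    """
    cases = table[table["group"] == case_group].copy()
    controls = table[table["group"] == control_group].copy()
    used: set = set()
    keep_cases = []
    for _, ctrl in controls.iterrows():
        cand = cases[(cases["sex"] == ctrl["sex"]) & (~cases.index.isin(used))]
        if cand.empty:
            continue
        gaps = (cand["age"] - ctrl["age"]).abs()
        best = gaps.idxmin()
        if gaps[best] <= caliper_years:
            used.add(best)
            keep_cases.append(best)
    matched = pd.concat([controls, cases.loc[keep_cases]])
    return matched.sort_index()
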