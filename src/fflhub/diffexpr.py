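"""Two-group differential expression screening on log2 expression matrices.

The screening stage emulates a GEO2R-style contrast between two patient
groups (here: sepsis with acute lung injury vs sepsis only).  A gene is
called differentially expressed (DEG) when its two-sided p-value is
strictly below ``alpha`` (default 0.05); DEGs are split into up- and
down-regulated by the sign of log2 fold change (case mean − control mean).

Two per-gene tests are available:

``welch``
    Welch's unequal-variance t-test with Satterthwaite degrees of freedom —
    the default, as it makes no equal-variance assumption.
``geo2r-compat``
    An empirical-Bayes moderated t-test in the style of limma (which GEO2R
    runs): per-gene pooled variances are shrunk toward a common prior whose
    hyperparameters (prior df ``d0`` and prior variance ``s0²``) are
    estimated from the log-variance moments across genes, and the
    moderated statistic is referred to a t distribution with
    ``d0 + n − 2`` degrees of freedom.

The module also provides the presentation-layer statistics used around the
DEG table: per-row z-scoring for heatmaps, hierarchical clustering with
Pearson distance and complete linkage, and the Wilcoxon rank-sum test used
to compare hub-gene expression between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import (
    DegenerateVarianceError,
    InputMismatchError,
    InvalidConfigError,
    ValidationError,
)

__all__ = [
    "welch_t",
    "moderated_t",
    "run_deg",
    "deg_summary",
    "row_zscore",
    "hclust_pearson_complete",
    "Dendrogram",
    "wilcoxon_ranksum",
]


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's t-test; returns ``(statistic, df, p_value)``.

    The statistic is ``(mean(x) − mean(y)) / sqrt(s²_x/n_x + s²_y/n_y)``
    with Satterthwaite degrees of freedom, two-sided p from the t
    distribution.  If both groups are constant and equal the difference is
    exactly zero and ``(0.0, n_x+n_y−2, 1.0)`` is returned; if both are
    constant but unequal the test is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidConfigError("welch_t needs at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise DegenerateVarianceError(
            "both groups constant with unequal means: Welch statistic undefined"
        )
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration, limma-style)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _group_split(matrix: pd.DataFrame, phenotype: pd.Series, case: str | None):
    """Column indices for (case, control) after validating the pairing."""
    unknown = set(phenotype.index) - set(matrix.columns)
    if unknown:
        raise InputMismatchError(f"phenotype samples not in matrix: {sorted(unknown)}")
    unlabeled = set(matrix.columns) - set(phenotype.index)
    if unlabeled:
        raise InputMismatchError(f"matrix samples without phenotype: {sorted(unlabeled)}")
    groups = sorted(phenotype.unique())
    if len(groups) != 2:
        raise ValidationError(f"phenotype must have exactly 2 groups, got {groups}")
    if case is None:
        case = "case" if "case" in groups else groups[0]
    if case not in groups:
        raise ValidationError(f"case label {case!r} not among groups {groups}")
    control = next(g for g in groups if g != case)
    case_cols = [s for s in matrix.columns if phenotype[s] == case]
    ctrl_cols = [s for s in matrix.columns if phenotype[s] == control]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValidationError("each group needs at least 2 samples")
    return case_cols, ctrl_cols


def moderated_t(
    matrix: pd.DataFrame,
    phenotype: pd.Series,
    case: str | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test per gene (limma-style shrinkage).

    Pooled per-gene variances ``s²_g`` (df ``d = n − 2``) are modelled as
    scaled F draws around a prior variance ``s0²`` with prior df ``d0``;
    the hyperparameters are estimated by matching the mean and variance of
    ``log s²_g`` (method of moments on the log scale).  Each gene is then
    tested with the shrunken variance ``(d0·s0² + d·s²_g)/(d0 + d)`` and
    ``d0 + d`` degrees of freedom.  ``prior_df`` overrides the estimated
    ``d0`` (``prior_df=0`` recovers the ordinary pooled-variance t-test).
    """
    if matrix.shape[0] < 10 and prior_df is None:
        raise InvalidConfigError("moderated_t needs >= 10 genes to estimate the prior")
    case_cols, ctrl_cols = _group_split(matrix, phenotype, case)
    a = matrix[case_cols].to_numpy(float)
    b = matrix[ctrl_cols].to_numpy(float)
    n1, n2 = a.shape[1], b.shape[1]
    d = n1 + n2 - 2
    diff = a.mean(axis=1) - b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d
    if np.all(s2 == 0):
        raise DegenerateVarianceError("all genes have zero pooled variance")

    if prior_df is None:
        ok = s2 > 0
        z = np.log(s2[ok])
        e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
        evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
        if evar > 0:
            half_d0 = _trigamma_inverse(float(evar))
            d0 = 2.0 * half_d0
            s0_sq = float(
                np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0))
            )
        else:
            d0, s0_sq = np.inf, float(np.exp(e.mean()))
    else:
        d0 = float(prior_df)
        s0_sq = float(np.median(s2[s2 > 0])) if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, diff / se, 0.0)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    pvals = np.where((se == 0) & (diff == 0), 1.0, pvals)
    return pd.DataFrame(
        {"statistic": tstat, "df": df_total, "p_value": pvals},
        index=matrix.index,
    )


def run_deg(
    matrix: pd.DataFrame,
    phenotype: pd.Series,
    alpha: float = 0.05,
    case: str | None = None,
    method: str = "welch",
) -> pd.DataFrame:
    """Screen every gene for differential expression between two groups.

    Returns one row per gene (same order as the matrix) with columns
    ``log2fc`` (case − control means, log2 units), ``statistic``, ``df``,
    ``p_value`` and ``direction`` ∈ {``up``, ``down``, ``none``}.
    Direction is ``up``/``down`` only for genes with ``p < alpha`` (strict)
    and a non-zero log2 fold change; a significant gene with log2fc exactly
    0 keeps direction ``none``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0,1], got {alpha}")
    if method not in ("welch", "geo2r-compat"):
        raise ValidationError(f"unknown method {method!r}")
    case_cols, ctrl_cols = _group_split(matrix, phenotype, case)
    a = matrix[case_cols].to_numpy(float)
    b = matrix[ctrl_cols].to_numpy(float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    if method == "welch":
        stat_df_p = [welch_t(a[i], b[i]) for i in range(matrix.shape[0])]
        table = pd.DataFrame(
            stat_df_p, columns=["statistic", "df", "p_value"], index=matrix.index
        )
    else:
        table = moderated_t(matrix, phenotype, case=case)
    table.insert(0, "log2fc", log2fc)
    sig = table["p_value"] < alpha
    direction = np.where(
        sig & (table["log2fc"] > 0),
        "up",
        np.where(sig & (table["log2fc"] < 0), "down", "none"),
    )
    table["direction"] = direction
    table.index.name = "gene_id"
    return table


def deg_summary(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Counts reported alongside the DEG table."""
    sig = table["p_value"] < alpha
    return {
        "n_total": int(len(table)),
        "n_deg": int(sig.sum()),
        "n_up": int((table["direction"] == "up").sum()),
        "n_down": int((table["direction"] == "down").sum()),
    }


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardise each gene (row) to mean 0, sd 1 (ddof=1, as in R's scale).

    Constant rows cannot be standardised; they are returned as all-zero
    rows with a warning.
    """
    values = matrix.to_numpy(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant row(s) z-scored to zeros", stacklevel=2
        )
    sd[sd == 0] = 1.0
    out = (values - mean) / sd
    out[flat, :] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class Dendrogram:
    """Agglomeration result: scipy-style linkage matrix plus leaf order."""

    linkage: np.ndarray  # (n-1, 4): cluster i, cluster j, height, size
    leaf_order: list  # row labels in dendrogram order
    labels: list


def hclust_pearson_complete(matrix: pd.DataFrame) -> Dendrogram:
    """Hierarchical clustering of rows: Pearson distance, complete linkage.

    Distance is ``1 − r`` (Pearson correlation across columns).  At each
    step the two active clusters at minimal complete-linkage distance are
    merged; exact distance ties are broken by the smallest (i, j) cluster
    index pair, making the merge sequence deterministic.  Cluster indexing
    follows scipy: leaves are 0..n−1, the merge at step t creates cluster
    n+t.
    """
    if matrix.shape[0] < 2:
        raise InvalidConfigError("need at least 2 rows to cluster")
    values = matrix.to_numpy(float)
    if np.any(values.std(axis=1) == 0):
        raise DegenerateVarianceError("constant row: Pearson correlation undefined")
    corr = np.corrcoef(values)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)

    n = values.shape[0]
    # complete-linkage distances between active clusters, updated in place
    active: dict[int, None] = {i: None for i in range(n)}
    dmat = {
        (i, j): dist[i, j] for i, j in combinations(range(n), 2)
    }
    members = {i: [i] for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    linkage = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        (i, j) = min(dmat, key=lambda p: (dmat[p], p))
        height = dmat[(i, j)]
        linkage[step] = (i, j, height, len(members[i]) + len(members[j]))
        children[next_id] = (i, j)
        members[next_id] = members[i] + members[j]
        del active[i], active[j]
        for other in active:
            a, b = (min(i, other), max(i, other)), (min(j, other), max(j, other))
            dmat[(other, next_id)] = max(dmat[a], dmat[b])
            del dmat[a], dmat[b]
        del dmat[(i, j)]
        active[next_id] = None
        next_id += 1

    def _leaves(cluster: int) -> list:
        if cluster < n:
            return [cluster]
        left, right = children[cluster]
        return _leaves(left) + _leaves(right)

    order = _leaves(next_id - 1) if n > 1 else [0]
    labels = list(matrix.index)
    return Dendrogram(
        linkage=linkage, leaf_order=[labels[i] for i in order], labels=labels
    )


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    For pooled sample sizes up to 12 the p-value is exact: every assignment
    of the pooled observations to the two groups is enumerated and the
    rank-sum statistic (midranks under ties) compared with the observed
    one.  Larger samples use the normal approximation with tie correction
    and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("wilcoxon_ranksum needs non-empty groups")
    n, m = x.size, y.size
    if n + m <= 12:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        w_obs = ranks[:n].sum()
        mu = n * (n + m + 1) / 2.0
        dev = abs(w_obs - mu)
        total = 0
        hits = 0
        for idx in combinations(range(n + m), n):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-12:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)
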