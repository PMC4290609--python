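"""Baseline and validation statistics.

These are the conventional analyses the probe-space PCA approach is compared
against: per-probe t-tests between metastasis groups with Benjamini-Hochberg
adjustment, per-gene paired expression-methylation correlations over the
four design-category means, and directional two-sample Kolmogorov-Smirnov
tests for validation on independent tissue data.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data_io import CATEGORY_LABELS, OmicsMatrix
from .integrate import pearson_df2

logger = logging.getLogger(__name__)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order.

    Sorted ascending, q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def per_probe_ttest(
    matrix: OmicsMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    equal_var: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided t-test per probe between two sample groups, BH-adjusted.

    Welch's unequal-variance statistic by default (``equal_var=True`` gives
    the pooled Student variant). Probes with zero variance in both groups get
    p = 1 and are flagged. Returns a TestTable DataFrame indexed by probe
    with columns statistic, p_raw, p_adj, direction, zero_variance,
    significant.
    """
    group_a, group_b = list(group_a), list(group_b)
    for g, name in ((group_a, "A"), (group_b, "B")):
        if len(g) < 2:
            raise ValueError(f"group {name} needs >= 2 samples, got {len(g)}")
        missing = [s for s in g if s not in matrix.sample_ids]
        if missing:
            raise ValueError(f"samples {missing} not in matrix")
    a = matrix.values[group_a].to_numpy(float)
    b = matrix.values[group_b].to_numpy(float)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(a, b, axis=1, equal_var=equal_var)
    stat = np.asarray(res.statistic, float)
    p = np.asarray(res.pvalue, float)
    stat[degenerate] = 0.0
    p[degenerate] = 1.0
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning("%d probes with zero variance in both groups: p set to 1", n_deg)
    bad = ~np.isfinite(p)
    p[bad] = 1.0
    stat[bad & ~degenerate] = 0.0
    out = pd.DataFrame(
        {
            "statistic": stat,
            "p_raw": p,
            "p_adj": bh_adjust(p),
            "direction": np.sign(a.mean(axis=1) - b.mean(axis=1)),
            "zero_variance": degenerate,
        },
        index=matrix.probe_ids,
    )
    out["significant"] = out["p_adj"] < alpha
    return out


def _category_mean_matrix(matrix: OmicsMatrix) -> pd.DataFrame:
    """Probe x 4 matrix of within-category replicate means."""
    cols = {}
    for label in CATEGORY_LABELS:
        members = [s for s in matrix.sample_ids if matrix.category_of(s) == label]
        if not members:
            raise ValueError(f"category {label} has no samples")
        cols[label] = matrix.values[members].mean(axis=1)
    return pd.DataFrame(cols)


def paired_probe_correlation(
    expr: OmicsMatrix,
    meth: OmicsMatrix,
    annot_expr: Mapping[str, frozenset[str]],
    annot_meth: Mapping[str, frozenset[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate expression and methylation probes sharing a RefSeq ID.

    Replicates are first averaged within the four design categories on each
    platform (the replicate counts differ across platforms, so raw samples
    cannot be paired), then the Pearson correlation over the 4 paired means
    is computed per probe pair, its P-value on 2 degrees of freedom, and BH
    adjustment over all pairs. Pairs where either side has fewer than 3
    distinct category means are skipped (correlation too degenerate) and
    counted in the log.
    """
    cm_e = _category_mean_matrix(expr)
    cm_m = _category_mean_matrix(meth)

    by_gene_m: dict[str, list[str]] = {}
    for probe, genes in annot_meth.items():
        if probe not in meth.probe_ids:
            continue
        for g in genes:
            by_gene_m.setdefault(g, []).append(probe)
    pairs: list[tuple[str, str, str]] = []
    for probe_e, genes in annot_expr.items():
        if probe_e not in expr.probe_ids:
            continue
        for g in genes:
            for probe_m in by_gene_m.get(g, ()):
                pairs.append((g, probe_e, probe_m))
    if not pairs:
        return pd.DataFrame(
            columns=["refseq_id", "expr_probe", "meth_probe", "r", "p_raw", "p_adj", "significant"]
        )

    xe = cm_e.loc[[p[1] for p in pairs]].to_numpy(float)
    xm = cm_m.loc[[p[2] for p in pairs]].to_numpy(float)

    def distinct(a):
        return np.array([len(np.unique(row)) for row in a])

    ok = (distinct(xe) >= 3) & (distinct(xm) >= 3)
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info("%d probe pairs skipped (<3 distinct category means)", n_skip)

    xe, xm = xe[ok], xm[ok]
    kept = [p for p, k in zip(pairs, ok) if k]
    xc = xe - xe.mean(axis=1, keepdims=True)
    yc = xm - xm.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    r = np.clip((xc * yc).sum(axis=1) / denom, -1.0, 1.0)
    df = xe.shape[1] - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = np.where(np.abs(r) == 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t), df))
    out = pd.DataFrame(
        {
            "refseq_id": [k[0] for k in kept],
            "expr_probe": [k[1] for k in kept],
            "meth_probe": [k[2] for k in kept],
            "r": r,
            "p_raw": p,
            "p_adj": bh_adjust(p),
        }
    )
    out["significant"] = out["p_adj"] < alpha
    return out


def ks_onesided(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "asymp",
) -> tuple[float, float]:
    """Two directional two-sample Kolmogorov-Smirnov P-values.

    Returns ``(p_a_greater, p_b_greater)``: evidence that A is stochastically
    greater than B, and the reverse. Asymptotic P-values by default (ties are
    then handled by the asymptotic formula and a warning is logged when more
    than 10% of the pooled values are tied); ``method="exact"`` switches to
    the exact small-sample distribution.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    tie_frac = 1.0 - len(np.unique(pooled)) / len(pooled)
    if tie_frac > 0.10:
        logger.warning("KS test: %.0f%% of pooled values tied", 100 * tie_frac)
    # alternative="less": empirical CDF of the first sample lies below the
    # second, i.e. the first sample is stochastically greater.
    p_a_greater = float(sps.ks_2samp(a, b, alternative="less", method=method).pvalue)
    p_b_greater = float(sps.ks_2samp(a, b, alternative="greater", method=method).pvalue)
    return p_a_greater, p_b_greater


def ks_table(
    values: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    method: str = "asymp",
) -> pd.DataFrame:
    """Directional KS tests per row of a gene x sample table (the tissue
    validation layout: one row per gene, columns split into metastasis and
    non-metastasis samples)."""
    rows = []
    for gene, row in values.iterrows():
        pa, pb = ks_onesided(
            row[list(group_a)].dropna(), row[list(group_b)].dropna(), method=method
        )
        rows.append({"gene": gene, "p_a_greater": pa, "p_b_greater": pb})
    return pd.DataFrame(rows).set_index("gene")
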