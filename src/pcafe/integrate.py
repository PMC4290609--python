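"""Cross-platform integration of probe-space PCA decompositions.

The integration step pairs expression and methylation components whose
category-averaged sample contributions correlate, extracts the top-100
outlier probes from each tail of each paired component, intersects the
implied RefSeq gene sets with a sign-aware tail-pairing rule, and scores the
overlap with an upper-tail binomial statistic: the chance that two random
100-probe selections from a universe of y probes share at least x entries,
with per-draw success probability 100/y.

The tail-pairing rule encodes the expected anticorrelation of expression and
promoter methylation: when the two components' sample contributions
correlate positively, high-expression tails are intersected with
low-methylation tails (and vice versa); when they correlate negatively, the
same tails are intersected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pca import PCDecomposition, category_means, characterize_all

logger = logging.getLogger(__name__)

TAIL_HIGH = "high"
TAIL_LOW = "low"

#: tail pairings, written expr-tail <-> meth-tail
TP_HIGH_LOW = "expr_high<->meth_low"
TP_LOW_HIGH = "expr_low<->meth_high"
TP_HIGH_HIGH = "expr_high<->meth_high"
TP_LOW_LOW = "expr_low<->meth_low"


@dataclass(frozen=True)
class PCPairing:
    """A matched (expression PC, methylation PC) pair.

    ``r`` and ``p`` are the Pearson correlation of the two 4-long
    category-mean contribution vectors and its two-sided P-value on 2
    degrees of freedom. ``sign`` is "positive" iff r > 0.
    """

    expr_pc: int
    meth_pc: int
    r: float
    p: float
    label: str = ""

    @property
    def sign(self) -> str:
        return "positive" if self.r > 0 else "negative"


@dataclass
class SelectionResult:
    """Outcome of one tail pairing of one PC pairing.

    ``x`` counts RefSeq genes common to the two top-100 outlier probe sets
    (overlap is counted at gene level, as gene lists are the reported unit),
    while the universe sizes ``y_expr``/``y_meth`` are the per-platform probe
    counts the binomial formula calls for; one overlap P-value is reported
    per universe.
    """

    pairing: PCPairing
    tail_pairing: str
    expr_probes: tuple[str, ...]
    meth_probes: tuple[str, ...]
    expr_genes: frozenset[str]
    meth_genes: frozenset[str]
    common_genes: frozenset[str]
    x: int
    y_expr: int
    y_meth: int
    p_expr: float
    p_meth: float
    n_top: int = 100
    tie_expanded: bool = False


def pearson_df2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r of two length-4 vectors with its two-sided P-value from the
    t transform on n - 2 = 2 degrees of freedom."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    n = len(x)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return r, p


def correlate_pcs(cm_expr: Sequence[float], cm_meth: Sequence[float]) -> tuple[float, float]:
    """Correlation between two components' category-averaged contributions
    (4 categories, hence df = 2)."""
    return pearson_df2(cm_expr, cm_meth)


def match_pcs(
    dec_expr: PCDecomposition,
    dec_meth: PCDecomposition,
    design_expr,
    design_meth,
    max_pc: int = 6,
    alpha: float = 0.05,
    z_threshold: float = 2.0,
    flat_cv: float = 0.1,
) -> tuple[list[PCPairing], pd.DataFrame]:
    """Pair components across platforms by category-mean correlation.

    All (k, l) with k, l <= max_pc are scored; candidates need p < alpha and
    identical characterization labels on the two platforms. Each PC is used
    at most once, assigned greedily by decreasing |r| (ties broken by PC
    index). Returns the pairings plus the full candidate-correlation table
    for audit.
    """
    kmax = min(max_pc, dec_expr.K)
    lmax = min(max_pc, dec_meth.K)
    cm_e = category_means(dec_expr, design_expr)
    cm_m = category_means(dec_meth, design_meth)
    chars_e = {c.pc: c for c in characterize_all(dec_expr, design_expr, z_threshold, flat_cv)}
    chars_m = {c.pc: c for c in characterize_all(dec_meth, design_meth, z_threshold, flat_cv)}

    records = []
    for k in range(1, kmax + 1):
        for l in range(1, lmax + 1):
            try:
                r, p = correlate_pcs(cm_e.loc[f"PC{k}"], cm_m.loc[f"PC{l}"])
            except ValueError:
                records.append((k, l, np.nan, np.nan, chars_e[k].label, chars_m[l].label, False))
                continue
            ok = p < alpha and chars_e[k].label == chars_m[l].label
            records.append((k, l, r, p, chars_e[k].label, chars_m[l].label, ok))
    audit = pd.DataFrame(
        records,
        columns=["expr_pc", "meth_pc", "r", "p", "expr_label", "meth_label", "candidate"],
    )

    cands = audit[audit["candidate"]].copy()
    cands = cands.sort_values(
        by=["r", "expr_pc", "meth_pc"],
        key=lambda col: -col.abs() if col.name == "r" else col,
        kind="mergesort",
    )
    used_e: set[int] = set()
    used_m: set[int] = set()
    pairings: list[PCPairing] = []
    for _, row in cands.iterrows():
        k, l = int(row["expr_pc"]), int(row["meth_pc"])
        if k in used_e or l in used_m:
            continue
        used_e.add(k)
        used_m.add(l)
        pairings.append(
            PCPairing(expr_pc=k, meth_pc=l, r=float(row["r"]), p=float(row["p"]),
                      label=str(row["expr_label"]))
        )
    pairings.sort(key=lambda pr: (pr.expr_pc, pr.meth_pc))
    return pairings, audit


def select_outliers(
    dec: PCDecomposition, pc: int, tail: str, n_top: int = 100
) -> tuple[tuple[str, ...], bool]:
    """The n_top probes with the largest (tail="high") or smallest
    (tail="low") scores on a component; ties at the cutoff expand the set.

    Returns the probe IDs (sorted by extremity) and a tie-expansion flag.
    """
    if not 1 <= pc <= dec.K:
        raise ValueError(f"pc={pc} out of range 1..{dec.K}")
    if tail not in (TAIL_HIGH, TAIL_LOW):
        raise ValueError(f"tail must be 'high' or 'low', got {tail!r}")
    scores = dec.probe_scores[f"PC{pc}"]
    if n_top > len(scores) or n_top < 1:
        raise ValueError(f"n_top={n_top} not in [1, {len(scores)}]")
    signed = -scores if tail == TAIL_HIGH else scores
    order = signed.sort_values(kind="mergesort")
    cutoff = order.iloc[n_top - 1]
    selected = order[order <= cutoff]
    expanded = len(selected) > n_top
    if expanded:
        logger.info(
            "platform %s PC%d %s tail: cutoff tie expands selection to %d probes",
            dec.platform_id, pc, tail, len(selected),
        )
    return tuple(selected.index), expanded


def tail_pairings(sign: str) -> list[str]:
    """Tail combinations to intersect for a pairing of the given sign.

    Positively correlated components pair opposite tails (expression up with
    methylation down and vice versa — the expected anticorrelation); negatively
    correlated components pair the same tails.
    """
    if sign == "positive":
        return [TP_HIGH_LOW, TP_LOW_HIGH]
    if sign == "negative":
        return [TP_HIGH_HIGH, TP_LOW_LOW]
    raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")


def genes_of(probes, annotation: Mapping[str, frozenset[str]]) -> frozenset[str]:
    """Union of RefSeq IDs of the given probes; unannotated probes contribute
    nothing, multi-gene probes contribute every ID."""
    out: set[str] = set()
    for p in probes:
        out.update(annotation.get(p, ()))
    return frozenset(out)


def gene_intersection(
    expr_probes, meth_probes,
    annot_expr: Mapping[str, frozenset[str]],
    annot_meth: Mapping[str, frozenset[str]],
) -> tuple[frozenset[str], int]:
    """Genes selected on both platforms, and their count x."""
    common = genes_of(expr_probes, annot_expr) & genes_of(meth_probes, annot_meth)
    return common, len(common)


def overlap_pvalue(x: int, n: int = 100, y: int = 0, variant: str = "inclusive") -> float:
    """Upper-tail binomial probability of an overlap of at least x.

    The overlap of two top-n outlier sets from a universe of y probes is
    modelled as X ~ Binomial(n, n/y); the reported value is P[X >= x]
    (``variant="inclusive"``, the default: the observed overlap belongs to
    its own tail), i.e. 1 - CDF(x - 1), which is 1 when x = 0. The literal
    1 - CDF(x) is available as ``variant="literal"``.
    """
    if x < 0 or n < 1:
        raise ValueError("x must be >= 0 and n >= 1")
    if x > n:
        raise ValueError(f"x={x} exceeds n={n}")
    if y <= n:
        raise ValueError(f"universe y={y} must exceed n={n}")
    p = n / y
    if variant == "inclusive":
        if x == 0:
            return 1.0
        return float(stats.binom.sf(x - 1, n, p))
    if variant == "literal":
        return float(stats.binom.sf(x, n, p))
    raise ValueError(f"unknown variant {variant!r}")


def run_selection(
    pairing: PCPairing,
    dec_expr: PCDecomposition,
    dec_meth: PCDecomposition,
    annot_expr: Mapping[str, frozenset[str]],
    annot_meth: Mapping[str, frozenset[str]],
    n_top: int = 100,
    variant: str = "inclusive",
) -> list[SelectionResult]:
    """Both tail pairings of one PC pairing, fully scored.

    The universe size y is taken per platform (the number of probes on each
    array), giving two overlap P-values per tail pairing.
    """
    results = []
    for tp in tail_pairings(pairing.sign):
        expr_tail, meth_tail = (
            part.split("_")[1] for part in tp.split("<->")
        )
        expr_probes, exp_e = select_outliers(dec_expr, pairing.expr_pc, expr_tail, n_top)
        meth_probes, exp_m = select_outliers(dec_meth, pairing.meth_pc, meth_tail, n_top)
        common, x = gene_intersection(expr_probes, meth_probes, annot_expr, annot_meth)
        y_e, y_m = dec_expr.n_probes, dec_meth.n_probes
        results.append(
            SelectionResult(
                pairing=pairing,
                tail_pairing=tp,
                expr_probes=expr_probes,
                meth_probes=meth_probes,
                expr_genes=genes_of(expr_probes, annot_expr),
                meth_genes=genes_of(meth_probes, annot_meth),
                common_genes=common,
                x=x,
                y_expr=y_e,
                y_meth=y_m,
                p_expr=overlap_pvalue(x, n_top, y_e, variant),
                p_meth=overlap_pvalue(x, n_top, y_m, variant),
                n_top=n_top,
                tie_expanded=exp_e or exp_m,
            )
        )
    return results
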