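"""Gene-level promoter methylation from site-level calls.

The promoter of a RefSeq transcript is the strand-aware window from 1500 bp
upstream to 500 bp downstream of its transcription start site. Site-level
beta values falling inside the window are averaged (unweighted, per-site)
into a single gene-level promoter beta per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_io import GeneModel

logger = logging.getLogger(__name__)

UPSTREAM_DEFAULT = 1500
DOWNSTREAM_DEFAULT = 500


@dataclass(frozen=True)
class PromoterWindow:
    """1-based inclusive genomic window around a transcription start site."""

    refseq_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid window [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1


def promoter_window(
    gene: GeneModel,
    upstream: int = UPSTREAM_DEFAULT,
    downstream: int = DOWNSTREAM_DEFAULT,
) -> PromoterWindow:
    """Strand-aware promoter window of a gene, 1-based inclusive.

    For a + strand gene the TSS is ``tx_start`` (0-based), i.e. 1-based
    ``t = tx_start + 1`` and the window is ``[t - upstream, t + downstream]``.
    For a - strand gene the TSS is the last transcribed base, 1-based
    ``t = tx_end``, and the window mirrors to ``[t - downstream, t + upstream]``.
    The window is clipped at the chromosome start (position 1); with the
    default bounds an unclipped window spans 2001 bp.
    """
    if gene.strand == "+":
        t = gene.tx_start + 1
        start, end = t - upstream, t + downstream
    else:
        t = gene.tx_end
        start, end = t - downstream, t + upstream
    return PromoterWindow(gene.refseq_id, gene.chrom, max(start, 1), end)


def promoter_windows(
    genes: Iterable[GeneModel],
    upstream: int = UPSTREAM_DEFAULT,
    downstream: int = DOWNSTREAM_DEFAULT,
) -> list[PromoterWindow]:
    return [promoter_window(g, upstream, downstream) for g in genes]


def mean_promoter_beta(
    sites: pd.DataFrame,
    windows: Iterable[PromoterWindow],
    pooled: bool = False,
) -> pd.DataFrame:
    """Aggregate site-level beta values into per-gene promoter means.

    Parameters
    ----------
    sites
        Site table as returned by :func:`pcafe.data_io.read_site_table`
        (columns chrom, position, beta and optionally
        methylated_count/total_count). Positions are 1-based.
    windows
        Promoter windows; several windows may share a ``refseq_id``
        (multi-locus genes), in which case the gene-level beta is the mean
        over loci that contain at least one site.
    pooled
        If True and count columns are present, aggregate as the pooled ratio
        sum(methylated)/sum(total) instead of the default unweighted mean of
        per-site beta values. The two differ whenever site coverages differ.

    Returns
    -------
    DataFrame indexed by refseq_id with columns ``beta`` (NaN when no site
    falls in any of the gene's windows) and ``site_count``.
    """
    windows = list(windows)
    by_chrom: dict[str, pd.DataFrame] = {
        str(chrom): grp.sort_values("position")
        for chrom, grp in sites.groupby("chrom")
    }
    has_counts = {"methylated_count", "total_count"}.issubset(sites.columns)
    if pooled and not has_counts:
        raise ValueError("pooled aggregation requires methylated_count/total_count")

    # per-locus sums, then combined per gene
    acc: dict[str, dict[str, float]] = {}
    for w in windows:
        rec = acc.setdefault(
            w.refseq_id,
            {"beta_sum": 0.0, "m_sum": 0.0, "t_sum": 0.0, "n": 0, "locus_means": []},
        )
        grp = by_chrom.get(str(w.chrom))
        if grp is None:
            continue
        pos = grp["position"].to_numpy()
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        if hi <= lo:
            continue
        sub = grp.iloc[lo:hi]
        rec["n"] += len(sub)
        if pooled:
            rec["m_sum"] += float(sub["methylated_count"].sum())
            rec["t_sum"] += float(sub["total_count"].sum())
            rec["locus_means"].append(
                float(sub["methylated_count"].sum()) / float(sub["total_count"].sum())
            )
        else:
            # summing in sorted order makes the mean exactly invariant to
            # site ordering (and hence to coordinate reflection)
            rec["locus_means"].append(float(np.sort(sub["beta"].to_numpy()).mean()))

    rows = []
    seen: set[str] = set()
    for w in windows:
        if w.refseq_id in seen:
            continue
        seen.add(w.refseq_id)
        rec = acc[w.refseq_id]
        if rec["n"] == 0:
            beta = np.nan
        elif pooled:
            beta = rec["m_sum"] / rec["t_sum"]
        else:
            beta = float(np.mean(rec["locus_means"]))
        rows.append({"refseq_id": w.refseq_id, "beta": beta, "site_count": rec["n"]})
    out = pd.DataFrame(rows).set_index("refseq_id")
    out["site_count"] = out["site_count"].astype(int)
    return out


def mean_promoter_beta_per_sample(
    site_tables: Mapping[str, pd.DataFrame],
    windows: Iterable[PromoterWindow],
    pooled: bool = False,
) -> pd.DataFrame:
    """Gene x sample promoter-beta table from per-sample site tables.

    Whether replicate sequencing runs should be pooled before aggregation is
    left to the caller; this function keeps samples separate.
    """
    windows = list(windows)
    cols = {}
    counts = None
    for sample, sites in site_tables.items():
        tab = mean_promoter_beta(sites, windows, pooled=pooled)
        cols[sample] = tab["beta"]
        counts = tab["site_count"] if counts is None else counts
    out = pd.DataFrame(cols)
    out.index.name = "refseq_id"
    return out
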