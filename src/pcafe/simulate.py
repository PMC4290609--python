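"""Synthetic paired expression/methylation data with known ground truth.

The generator emulates the structure of the cell-line study the analysis is
built for: two NSCLC cell lines (A549, HTB56), each profiled with and
without in-vivo-selected metastatic ability; three expression replicates and
two methylation replicates per condition; a dominant sample-independent
baseline; a cell-line gene set; an HTB56-only and an A549-only metastasis
gene set whose expression and promoter methylation effects are
anticorrelated across platforms. All randomness flows from a single integer
seed through one generator.

A site-level companion (:func:`generate_site_fixture`) lays the same genes
onto a toy genome, scatters noisy beta calls inside each promoter window
plus out-of-window decoys, and records the per-gene truth, so the promoter
aggregation can be exercised end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import CATEGORIES, GeneModel, OmicsMatrix, SampleDesign
from .promoter import promoter_window

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study conditions of the simulated experiment.

    Expression values are on a log-intensity scale, methylation values are
    beta fractions clipped to [0, 1]. Effect sizes are additive shifts
    applied to the affected conditions; metastasis effects have opposite
    signs on the two platforms when ``anticorrelated`` (the default,
    reflecting the expected repression of expression by promoter
    methylation).
    """

    n_genes: int = 2000
    expr_probes_per_gene: tuple[int, int] = (1, 2)  # uniform over this range
    meth_probes_per_gene: int = 1
    expr_replicates: int = 3
    meth_replicates: int = 2
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 2.0
    meth_baseline_mean: float = 0.5
    meth_baseline_sd: float = 0.15
    n_cellline_genes: int = 150
    cellline_effect_expr: float = 2.0
    cellline_effect_meth: float = 0.15
    n_metH_genes: int = 30
    n_metA_genes: int = 20
    met_effect_expr: float = 1.5
    met_effect_meth: float = 0.15   # magnitude; sign set by `anticorrelated`
    expr_noise_sd: float = 0.3
    meth_noise_sd: float = 0.05
    anticorrelated: bool = True
    seed: int = 0

    def __post_init__(self):
        n_planted = self.n_cellline_genes + self.n_metH_genes + self.n_metA_genes
        if n_planted > self.n_genes:
            raise ValueError(
                f"planted gene sets ({n_planted}) exceed n_genes ({self.n_genes})"
            )
        lo, hi = self.expr_probes_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("expr_probes_per_gene must be an increasing range >= 1")


@dataclass
class GroundTruth:
    """Planted gene sets and per-platform effect signs."""

    cellline_genes: tuple[str, ...]
    metH_genes: tuple[str, ...]
    metA_genes: tuple[str, ...]
    effect_sign_expr: int
    effect_sign_meth: int

    @property
    def metastasis_genes(self) -> frozenset[str]:
        return frozenset(self.metH_genes) | frozenset(self.metA_genes)

    @property
    def all_planted(self) -> frozenset[str]:
        return (
            frozenset(self.cellline_genes)
            | frozenset(self.metH_genes)
            | frozenset(self.metA_genes)
        )

    def to_dict(self) -> dict:
        return {
            "cellline_genes": list(self.cellline_genes),
            "metH_genes": list(self.metH_genes),
            "metA_genes": list(self.metA_genes),
            "effect_sign_expr": self.effect_sign_expr,
            "effect_sign_meth": self.effect_sign_meth,
        }


@dataclass
class SimData:
    expr: OmicsMatrix
    meth: OmicsMatrix
    annot_expr: dict[str, frozenset[str]]
    annot_meth: dict[str, frozenset[str]]
    truth: GroundTruth
    config: SimConfig


def _gene_ids(n: int) -> list[str]:
    return [f"NM_{i + 1:06d}" for i in range(n)]


def _design(prefix: str, replicates: int) -> dict[str, SampleDesign]:
    out = {}
    for cell, met in CATEGORIES:
        for r in range(1, replicates + 1):
            tag = "met" if met == "with" else "ctl"
            out[f"{prefix}_{cell}_{tag}_{r}"] = SampleDesign(cell, met, r)
    return out


def _condition_signal(base, cell_eff, metH_eff, metA_eff, cell, met):
    h = cell == "HTB56"
    w = met == "with"
    sig = base.copy()
    if h:
        sig = sig + cell_eff
        if w:
            sig = sig + metH_eff
    elif w:
        sig = sig + metA_eff
    return sig


def generate(config: SimConfig | None = None) -> SimData:
    """Generate one paired expression/methylation dataset.

    Deterministic given ``config.seed``. Per-gene signal per condition is
    baseline + cell-line shift (HTB56 samples) + HTB56-metastasis shift
    (HTB56 with metastasis) + A549-metastasis shift (A549 with metastasis);
    every probe of a gene shares the gene signal and receives independent
    Gaussian noise. Methylation values are clipped to [0, 1] (logged when
    clipping occurs — rare at the default effect and noise sizes).
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    genes = _gene_ids(n)

    lo, hi = cfg.expr_probes_per_gene
    ppg = rng.integers(lo, hi + 1, n)
    base_e = rng.normal(cfg.expr_baseline_mean, cfg.expr_baseline_sd, n)
    base_m = rng.normal(cfg.meth_baseline_mean, cfg.meth_baseline_sd, n)
    perm = rng.permutation(n)
    i_cell = perm[: cfg.n_cellline_genes]
    i_metH = perm[cfg.n_cellline_genes: cfg.n_cellline_genes + cfg.n_metH_genes]
    i_metA = perm[
        cfg.n_cellline_genes + cfg.n_metH_genes:
        cfg.n_cellline_genes + cfg.n_metH_genes + cfg.n_metA_genes
    ]

    sign_e = 1
    sign_m = -1 if cfg.anticorrelated else 1
    cell_e = np.zeros(n); cell_m = np.zeros(n)
    metH_e = np.zeros(n); metH_m = np.zeros(n)
    metA_e = np.zeros(n); metA_m = np.zeros(n)
    cell_e[i_cell] = cfg.cellline_effect_expr
    cell_m[i_cell] = cfg.cellline_effect_meth
    metH_e[i_metH] = sign_e * cfg.met_effect_expr
    metH_m[i_metH] = sign_m * cfg.met_effect_meth
    metA_e[i_metA] = sign_e * cfg.met_effect_expr
    metA_m[i_metA] = sign_m * cfg.met_effect_meth

    design_e = _design("E", cfg.expr_replicates)
    design_m = _design("M", cfg.meth_replicates)

    cols_e, cols_m = [], []
    for cell, met in CATEGORIES:
        sig_e = _condition_signal(base_e, cell_e, metH_e, metA_e, cell, met)
        sig_m = _condition_signal(base_m, cell_m, metH_m, metA_m, cell, met)
        cols_e.extend([sig_e] * cfg.expr_replicates)
        cols_m.extend([sig_m] * cfg.meth_replicates)

    gene_of_row = np.repeat(np.arange(n), ppg)
    E = np.stack(cols_e, axis=1)[gene_of_row]
    E = E + rng.normal(0.0, cfg.expr_noise_sd, E.shape)
    M = np.stack(cols_m, axis=1)
    if cfg.meth_probes_per_gene != 1:
        M = np.repeat(M, cfg.meth_probes_per_gene, axis=0)
    M = M + rng.normal(0.0, cfg.meth_noise_sd, M.shape)
    n_clip = int(((M < 0) | (M > 1)).sum())
    if n_clip:
        logger.info("methylation clipping applied to %d values", n_clip)
    M = np.clip(M, 0.0, 1.0)

    probe_counter: dict[int, int] = {}
    expr_probes = []
    for gi in gene_of_row:
        k = probe_counter.get(gi, 0)
        probe_counter[gi] = k + 1
        expr_probes.append(f"EXPR_{gi + 1:06d}_{chr(ord('a') + k)}")
    meth_gene_of_row = np.repeat(np.arange(n), cfg.meth_probes_per_gene)
    meth_probes = []
    probe_counter.clear()
    for gi in meth_gene_of_row:
        k = probe_counter.get(gi, 0)
        probe_counter[gi] = k + 1
        meth_probes.append(f"METH_{gi + 1:06d}_{chr(ord('a') + k)}")

    expr = OmicsMatrix(
        platform_id="sim_expression",
        values=pd.DataFrame(E, index=pd.Index(expr_probes, name="probe_id"),
                            columns=list(design_e)),
        design=design_e,
    )
    meth = OmicsMatrix(
        platform_id="sim_methylation",
        values=pd.DataFrame(M, index=pd.Index(meth_probes, name="probe_id"),
                            columns=list(design_m)),
        design=design_m,
        is_beta=True,
    )
    annot_e = {p: frozenset({genes[g]}) for p, g in zip(expr_probes, gene_of_row)}
    annot_m = {p: frozenset({genes[g]}) for p, g in zip(meth_probes, meth_gene_of_row)}
    truth = GroundTruth(
        cellline_genes=tuple(genes[i] for i in i_cell),
        metH_genes=tuple(genes[i] for i in i_metH),
        metA_genes=tuple(genes[i] for i in i_metA),
        effect_sign_expr=sign_e,
        effect_sign_meth=sign_m,
    )
    return SimData(expr, meth, annot_e, annot_m, truth, cfg)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A configuration with all planted effects set to zero (pure noise plus
    baseline) — the null for calibration runs."""
    return SimConfig(
        cellline_effect_expr=0.0, cellline_effect_meth=0.0,
        met_effect_expr=0.0, met_effect_meth=0.0,
        seed=seed, **overrides,
    )


# ---------------------------------------------------------------------------
# site-level fixture


@dataclass
class SiteFixture:
    site_tables: dict[str, pd.DataFrame]
    genes: list[GeneModel]
    truth_beta: pd.DataFrame  # gene x sample planted promoter beta


def generate_site_fixture(
    config: SimConfig | None = None,
    sites_per_promoter: int = 20,
    site_noise_sd: float = 0.1,
    decoys_per_gene: int = 5,
    emit_counts: bool = False,
    count_depth: int = 30,
) -> SiteFixture:
    """Site-level methylation calls on a toy genome with known truth.

    Genes are laid out on two chromosomes with alternating strands, 20 kb
    apart, transcripts 5 kb long. For each gene and sample,
    ``sites_per_promoter`` sites are placed uniformly inside the gene's
    promoter window with beta = planted gene-level beta + Gaussian site noise
    (clipped to [0, 1]); ``decoys_per_gene`` decoy sites land well outside
    every promoter window. With ``emit_counts`` the per-site calls are
    emitted as methylated/total read counts drawn binomially at
    ``count_depth`` reads.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from generate()
    n = cfg.n_genes
    gene_names = _gene_ids(n)

    base_m = rng.normal(cfg.meth_baseline_mean, cfg.meth_baseline_sd, n)
    perm = rng.permutation(n)
    i_cell = perm[: cfg.n_cellline_genes]
    i_metH = perm[cfg.n_cellline_genes: cfg.n_cellline_genes + cfg.n_metH_genes]
    i_metA = perm[
        cfg.n_cellline_genes + cfg.n_metH_genes:
        cfg.n_cellline_genes + cfg.n_metH_genes + cfg.n_metA_genes
    ]
    sign_m = -1 if cfg.anticorrelated else 1
    cell_m = np.zeros(n); cell_m[i_cell] = cfg.cellline_effect_meth
    metH_m = np.zeros(n); metH_m[i_metH] = sign_m * cfg.met_effect_meth
    metA_m = np.zeros(n); metA_m[i_metA] = sign_m * cfg.met_effect_meth

    spacing, tx_len = 20_000, 5_000
    genes: list[GeneModel] = []
    for i, name in enumerate(gene_names):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        slot = i // 2
        start = 10_000 + slot * spacing
        strand = "+" if slot % 2 == 0 else "-"
        genes.append(GeneModel(name, chrom, strand, start, start + tx_len))
    windows = {g.refseq_id: promoter_window(g) for g in genes}

    design = _design("S", cfg.meth_replicates)
    truth_cols = {}
    site_tables: dict[str, pd.DataFrame] = {}
    for sample, d in design.items():
        planted = np.clip(
            _condition_signal(base_m, cell_m, metH_m, metA_m, d.cell_line, d.metastasis),
            0.0, 1.0,
        )
        truth_cols[sample] = planted
        chroms, positions, betas = [], [], []
        for i, g in enumerate(genes):
            w = windows[g.refseq_id]
            pos = rng.integers(w.start, w.end + 1, sites_per_promoter)
            beta = np.clip(
                planted[i] + rng.normal(0.0, site_noise_sd, sites_per_promoter), 0.0, 1.0
            )
            chroms.extend([g.chrom] * sites_per_promoter)
            positions.extend(pos.tolist())
            betas.extend(beta.tolist())
            # decoys: inside the transcript body, beyond any promoter window
            decoy_pos = rng.integers(
                g.tx_start + 3_000, g.tx_end - 1_000, decoys_per_gene
            )
            chroms.extend([g.chrom] * decoys_per_gene)
            positions.extend(decoy_pos.tolist())
            betas.extend(rng.uniform(0, 1, decoys_per_gene).tolist())
        tab = pd.DataFrame({"chrom": chroms, "position": positions, "beta": betas})
        if emit_counts:
            m = rng.binomial(count_depth, np.asarray(betas))
            tab["methylated_count"] = m
            tab["total_count"] = count_depth
            tab["beta"] = m / count_depth
        site_tables[sample] = tab.sort_values(["chrom", "position"]).reset_index(drop=True)

    truth = pd.DataFrame(truth_cols, index=pd.Index(gene_names, name="refseq_id"))
    return SiteFixture(site_tables=site_tables, genes=genes, truth_beta=truth)
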