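"""End-to-end orchestration: load -> decompose -> characterize -> pair ->
select -> intersect -> score -> report.

The library entry point is :func:`integrated_analysis`, which works on
in-memory objects; :func:`run_pipeline` wraps it with file input/output and
a YAML-configurable :class:`RunConfig`. Identical inputs and configuration
give identical numeric outputs: every threshold and decision taken (tie
expansions, dropped probes, tail conventions) is captured in the JSON run
summary, from which every reported overlap P-value can be recomputed from
its stored (x, n, y).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import data_io
from .data_io import OmicsMatrix
from .integrate import PCPairing, SelectionResult, match_pcs, overlap_pvalue, run_selection
from .pca import (
    LABEL_CELL, LABEL_MET_A549, LABEL_MET_HTB56,
    category_means, characterization_table, characterize_all, decompose,
)

logger = logging.getLogger(__name__)

#: labels whose pairings contribute genes to the final list
BIOLOGICAL_LABELS = (LABEL_CELL, LABEL_MET_A549, LABEL_MET_HTB56)


@dataclass
class RunConfig:
    """Every tunable of the integrated analysis.

    Defaults follow the method's published values where one exists (100 top
    outliers per tail, significance threshold 0.05); the characterization
    thresholds are this package's own formalization and are reported in the
    run summary.
    """

    expr_path: str = ""
    meth_path: str = ""
    design_path: str = ""
    annot_expr_path: str = ""
    annot_meth_path: str = ""
    out_dir: str = "pcafe_out"
    center: str = "none"
    K: int | None = None
    max_pc: int = 6
    n_top: int = 100
    alpha: float = 0.05
    z_threshold: float = 2.0
    flat_cv: float = 0.1
    overlap_variant: str = "inclusive"  # tail convention of the overlap P
    seed: int = 0

    def __post_init__(self):
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.center not in ("none", "probe"):
            raise ValueError("center must be 'none' or 'probe'")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunSummary:
    config: dict
    dropped_probes: dict[str, int]
    contribution_fractions: dict[str, list[float]]
    characterizations: dict[str, list[dict]]
    pairings: list[dict]
    selections: list[SelectionResult]
    final_genes: tuple[str, ...]

    def to_jsonable(self) -> dict:
        return {
            "config": self.config,
            "dropped_probes": self.dropped_probes,
            "contribution_fractions": self.contribution_fractions,
            "characterizations": self.characterizations,
            "pairings": self.pairings,
            "selections": [
                {
                    "expr_pc": s.pairing.expr_pc,
                    "meth_pc": s.pairing.meth_pc,
                    "label": s.pairing.label,
                    "r": s.pairing.r,
                    "p": s.pairing.p,
                    "sign": s.pairing.sign,
                    "tail_pairing": s.tail_pairing,
                    "x": s.x,
                    "n_top": s.n_top,
                    "y_expr": s.y_expr,
                    "y_meth": s.y_meth,
                    "p_overlap_expr": s.p_expr,
                    "p_overlap_meth": s.p_meth,
                    "tie_expanded": s.tie_expanded,
                    "common_genes": sorted(s.common_genes),
                }
                for s in self.selections
            ],
            "final_genes": sorted(self.final_genes),
        }


def integrated_analysis(
    expr: OmicsMatrix,
    meth: OmicsMatrix,
    annot_expr,
    annot_meth,
    config: RunConfig | None = None,
) -> RunSummary:
    """Run the full probe-space PCA feature-extraction analysis in memory.

    Probes with missing values are dropped per platform before
    decomposition. Gene selection is performed for every matched PC pairing
    carrying a biological label (cell line or one of the metastasis
    contrasts); both tail pairings of each are scored and their gene sets
    unioned into the final gene list.
    """
    cfg = config or RunConfig()
    expr, dropped_e = expr.drop_missing_probes()
    meth, dropped_m = meth.drop_missing_probes()

    dec_e = decompose(expr, K=cfg.K, center=cfg.center)
    dec_m = decompose(meth, K=cfg.K, center=cfg.center)
    chars_e = characterize_all(dec_e, expr.design, cfg.z_threshold, cfg.flat_cv)
    chars_m = characterize_all(dec_m, meth.design, cfg.z_threshold, cfg.flat_cv)

    pairings, audit = match_pcs(
        dec_e, dec_m, expr.design, meth.design,
        max_pc=cfg.max_pc, alpha=cfg.alpha,
        z_threshold=cfg.z_threshold, flat_cv=cfg.flat_cv,
    )

    selections: list[SelectionResult] = []
    final: set[str] = set()
    for pairing in pairings:
        if pairing.label not in BIOLOGICAL_LABELS:
            continue
        res = run_selection(
            pairing, dec_e, dec_m, annot_expr, annot_meth,
            n_top=cfg.n_top, variant=cfg.overlap_variant,
        )
        selections.extend(res)
        for r in res:
            final.update(r.common_genes)

    summary = RunSummary(
        config=dataclasses.asdict(cfg),
        dropped_probes={"expression": dropped_e, "methylation": dropped_m},
        contribution_fractions={
            "expression": [float(v) for v in dec_e.contribution_fraction],
            "methylation": [float(v) for v in dec_m.contribution_fraction],
        },
        characterizations={
            "expression": [dataclasses.asdict(c) for c in chars_e],
            "methylation": [dataclasses.asdict(c) for c in chars_m],
        },
        pairings=[
            {"expr_pc": p.expr_pc, "meth_pc": p.meth_pc, "r": p.r, "p": p.p,
             "sign": p.sign, "label": p.label}
            for p in pairings
        ],
        selections=selections,
        final_genes=tuple(sorted(final)),
    )
    summary._audit = audit  # full candidate-correlation table, for export
    summary._decompositions = (dec_e, dec_m)
    summary._category_means = (
        category_means(dec_e, expr.design), category_means(dec_m, meth.design)
    )
    return summary


def run_pipeline(config: RunConfig) -> RunSummary:
    """File-based wrapper around :func:`integrated_analysis`.

    Writes per-PC characterization tables, the full pairwise PC correlation
    table, one selection TSV per tail pairing, the final unioned gene list
    and a JSON run summary into ``config.out_dir``.
    """
    design = data_io.read_design_table(config.design_path)
    expr = data_io.read_series_matrix(config.expr_path, design, platform_id="expression")
    meth = data_io.read_series_matrix(
        config.meth_path, design, platform_id="methylation", is_beta=True
    )
    annot_e = data_io.read_probe_annotation(config.annot_expr_path)
    annot_m = data_io.read_probe_annotation(config.annot_meth_path)

    summary = integrated_analysis(expr, meth, annot_e, annot_m, config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dec_e, dec_m = summary._decompositions
    cm_e, cm_m = summary._category_means
    for name, dec, chars, cm in (
        ("expression", dec_e, summary.characterizations["expression"], cm_e),
        ("methylation", dec_m, summary.characterizations["methylation"], cm_m),
    ):
        from .pca import PCCharacterization
        chs = [PCCharacterization(**c) for c in chars]
        characterization_table(dec, chs, cm).to_csv(
            out / f"characterization_{name}.tsv", sep="\t"
        )
    summary._audit.to_csv(out / "pc_correlations.tsv", sep="\t", index=False)
    data_io.write_results(summary.selections, out, summary=summary.to_jsonable())
    (out / "final_genes.txt").write_text("\n".join(sorted(summary.final_genes)) + "\n")
    logger.info(
        "pipeline finished: %d pairings, %d selections, %d final genes",
        len(summary.pairings), len(summary.selections), len(summary.final_genes),
    )
    return summary


def verify_summary(summary_json: dict) -> bool:
    """Recompute every stored overlap P-value from its (x, n, y); True when
    all match exactly (the run summary is self-verifying)."""
    variant = summary_json["config"]["overlap_variant"]
    for sel in summary_json["selections"]:
        for y_key, p_key in (("y_expr", "p_overlap_expr"), ("y_meth", "p_overlap_meth")):
            p = overlap_pvalue(sel["x"], sel["n_top"], sel[y_key], variant)
            if p != sel[p_key]:
                return False
    return True
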