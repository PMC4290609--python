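"""Readers and writers for the standard formats the pipeline touches.

Supported inputs
----------------
* GEO Series Matrix files (tab-separated, ``!``-prefixed metadata lines, data
  table delimited by ``!series_matrix_table_begin`` / ``!series_matrix_table_end``),
* refGene-style gene tables (``name  chrom  strand  txStart  txEnd``, 0-based
  half-open coordinates),
* probe -> RefSeq mRNA annotation tables,
* BED-derived site-level methylation call tables (beta values or
  methylated/total counts),
* sample-design tables mapping sample IDs onto the 2x2 cell-line x metastasis
  layout.

All readers accept plain text or gzip-compressed files. Coordinate
conventions are normalised at the reader boundary: gene tables stay 0-based
half-open as in refGene, site tables are 1-based on return (a 0-based
``start`` column is shifted on read). No statistics live in this module.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

logger = logging.getLogger(__name__)

CELL_LINES = ("A549", "HTB56")
METASTASIS = ("without", "with")

#: The four design categories in their fixed reporting order.
CATEGORIES = (
    ("A549", "without"),
    ("A549", "with"),
    ("HTB56", "without"),
    ("HTB56", "with"),
)

CATEGORY_LABELS = ("A549-", "A549+", "HTB56-", "HTB56+")

_REFSEQ_RE = re.compile(r"^[NX][MR]_\d+")


@dataclass(frozen=True)
class SampleDesign:
    """Experimental condition of one sample."""

    cell_line: str
    metastasis: str
    replicate: int

    def __post_init__(self):
        if self.cell_line not in CELL_LINES:
            raise DesignError(f"unknown cell line {self.cell_line!r}")
        if self.metastasis not in METASTASIS:
            raise DesignError(f"metastasis must be 'with'/'without', got {self.metastasis!r}")
        if self.replicate < 1:
            raise DesignError("replicate must be a positive integer")

    @property
    def category(self) -> str:
        return CATEGORY_LABELS[CATEGORIES.index((self.cell_line, self.metastasis))]


@dataclass
class OmicsMatrix:
    """A probe x sample matrix with per-sample design labels.

    ``values`` holds log-intensities for expression platforms and beta values
    in [0, 1] for methylation microarrays (``is_beta=True``). Rows are probes
    in file order, columns are samples in file order.
    """

    platform_id: str
    values: pd.DataFrame
    design: Mapping[str, SampleDesign]
    is_beta: bool = False
    metadata: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate probe ID {dup!r}")
        missing = [s for s in self.values.columns if s not in self.design]
        if missing:
            raise DesignError(
                f"sample(s) {missing} of platform {self.platform_id!r} "
                "have no design record"
            )
        if self.is_beta:
            vals = self.values.to_numpy(float)
            finite = vals[np.isfinite(vals)]
            n_out = int(((finite < 0) | (finite > 1)).sum())
            if n_out:
                logger.warning(
                    "platform %s: clipping %d beta values outside [0, 1]",
                    self.platform_id, n_out,
                )
                self.values = self.values.clip(0.0, 1.0)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def category_of(self, sample_id: str) -> str:
        return self.design[sample_id].category

    def samples_in(self, cell_line: str, metastasis: str) -> list[str]:
        return [
            s for s in self.sample_ids
            if self.design[s].cell_line == cell_line
            and self.design[s].metastasis == metastasis
        ]

    def drop_missing_probes(self) -> tuple["OmicsMatrix", int]:
        """Drop probes with any missing value (PCA has no missing-data
        mechanism); returns the filtered matrix and the number dropped."""
        keep = ~self.values.isna().any(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "platform %s: dropped %d/%d probes with missing values",
                self.platform_id, n_dropped, len(keep),
            )
        out = OmicsMatrix(
            platform_id=self.platform_id,
            values=self.values.loc[keep],
            design=self.design,
            is_beta=self.is_beta,
            metadata=list(self.metadata),
        )
        return out, n_dropped


@dataclass(frozen=True)
class GeneModel:
    """A RefSeq transcript with the coordinates needed to place its promoter.

    Coordinates follow the refGene dialect: 0-based ``tx_start``, exclusive
    ``tx_end``. ``duplicated`` flags RefSeq IDs that map to several loci.
    """

    refseq_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    duplicated: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise ValueError(
                f"{self.refseq_id}: tx_start {self.tx_start} >= tx_end {self.tx_end}"
            )


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _strip_quotes(s: str) -> str:
    s = s.strip()
    if len(s) >= 2 and s[0] == '"' and s[-1] == '"':
        return s[1:-1]
    return s


# ---------------------------------------------------------------------------
# design tables


def read_design_table(path) -> dict[str, SampleDesign]:
    """Read a TSV with columns sample_id, cell_line, metastasis, replicate.

    The sample -> design mapping is always supplied explicitly; it is never
    inferred from GEO sample titles, whose naming is idiosyncratic.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    required = {"sample_id", "cell_line", "metastasis", "replicate"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"design table {path} must have columns {sorted(required)}"
        )
    out: dict[str, SampleDesign] = {}
    for i, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in out:
            raise FormatError(f"duplicate sample_id {sid!r}", line=i + 2)
        out[sid] = SampleDesign(
            cell_line=str(row["cell_line"]),
            metastasis=str(row["metastasis"]),
            replicate=int(row["replicate"]),
        )
    return out


def write_design_table(design: Mapping[str, SampleDesign], path) -> None:
    rows = [
        {"sample_id": s, "cell_line": d.cell_line,
         "metastasis": d.metastasis, "replicate": d.replicate}
        for s, d in design.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GEO series matrix

_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def read_series_matrix(
    path,
    design_map: Mapping[str, SampleDesign],
    platform_id: str | None = None,
    is_beta: bool = False,
) -> OmicsMatrix:
    """Parse a GEO Series Matrix file into an :class:`OmicsMatrix`.

    Metadata (``!``-prefixed) lines are preserved verbatim in
    ``OmicsMatrix.metadata``. Cells written as ``null`` or left empty become
    missing values. Probe and sample order follow the file.
    """
    metadata: list[str] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with _open_text(path) as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            low = stripped.strip().lower()
            if low == _TABLE_BEGIN:
                saw_begin, in_table = True, True
                continue
            if low == _TABLE_END:
                saw_end, in_table = True, False
                continue
            if in_table:
                if stripped:
                    table_lines.append(stripped)
            elif stripped.startswith("!"):
                metadata.append(stripped)
    if not (saw_begin and saw_end):
        raise FormatError(
            f"{path}: missing {_TABLE_BEGIN}/{_TABLE_END} delimiters"
        )
    if not table_lines:
        raise FormatError(f"{path}: empty data table")
    header = [_strip_quotes(c) for c in table_lines[0].split("\t")]
    if not header or header[0].upper() != "ID_REF":
        raise FormatError(f"{path}: first table column must be ID_REF")
    df = pd.read_csv(
        io.StringIO("\n".join(table_lines[1:])),
        sep="\t", header=None, names=header,
        na_values=["null", "NULL", "Null", ""],
        keep_default_na=True,
    )
    df["ID_REF"] = df["ID_REF"].map(lambda v: _strip_quotes(str(v)))
    values = df.set_index("ID_REF")
    values.index.name = "probe_id"
    values = values.astype(float)
    for sid in values.columns:
        if sid not in design_map:
            raise DesignError(
                f"sample {sid!r} in {path} is absent from the design table"
            )
    if platform_id is None:
        platform_id = Path(path).name
    return OmicsMatrix(
        platform_id=platform_id,
        values=values,
        design={s: design_map[s] for s in values.columns},
        is_beta=is_beta,
        metadata=metadata,
    )


def write_series_matrix(matrix: OmicsMatrix, path, float_format: str = "%.6g") -> None:
    """Write an OmicsMatrix in Series Matrix layout (round-trips through
    :func:`read_series_matrix` to 6 significant digits)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", encoding="utf-8") as fh:
        meta = matrix.metadata or [f"!Series_title\t\"{matrix.platform_id}\""]
        for line in meta:
            fh.write(line + "\n")
        fh.write(_TABLE_BEGIN + "\n")
        fh.write("\t".join(["\"ID_REF\""] + [f"\"{s}\"" for s in matrix.sample_ids]) + "\n")
        fmt = lambda v: "null" if not np.isfinite(v) else float_format % v
        arr = matrix.values.to_numpy(float)
        for pid, row in zip(matrix.probe_ids, arr):
            fh.write("\t".join([f"\"{pid}\""] + [fmt(v) for v in row]) + "\n")
        fh.write(_TABLE_END + "\n")


# ---------------------------------------------------------------------------
# gene tables


def read_gene_table(path) -> list[GeneModel]:
    """Read a refGene-style TSV (columns name, chrom, strand, txStart, txEnd).

    Rows with an invalid strand or with txStart >= txEnd are record-level
    errors: they are skipped with a logged warning. Duplicate RefSeq IDs
    (multi-locus genes) are retained with ``duplicated=True``.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    required = {"name", "chrom", "strand", "txStart", "txEnd"}
    if not required.issubset(df.columns):
        raise FormatError(f"gene table {path} must have columns {sorted(required)}")
    rows: list[dict] = []
    for i, row in df.iterrows():
        lineno = i + 2
        strand = str(row["strand"]).strip()
        if strand not in ("+", "-"):
            logger.warning("%s line %d: invalid strand %r, row skipped", path, lineno, strand)
            continue
        try:
            start, end = int(row["txStart"]), int(row["txEnd"])
        except (TypeError, ValueError):
            raise FormatError(f"{path}: non-integer coordinates", line=lineno)
        if start >= end:
            logger.warning(
                "%s line %d: txStart %d >= txEnd %d, row skipped", path, lineno, start, end
            )
            continue
        rows.append(dict(
            refseq_id=str(row["name"]).strip(), chrom=str(row["chrom"]).strip(),
            strand=strand, tx_start=start, tx_end=end,
        ))
    counts: dict[str, int] = {}
    for r in rows:
        counts[r["refseq_id"]] = counts.get(r["refseq_id"], 0) + 1
    return [GeneModel(**r, duplicated=counts[r["refseq_id"]] > 1) for r in rows]


def write_gene_table(genes: Iterable[GeneModel], path) -> None:
    pd.DataFrame(
        [
            {"name": g.refseq_id, "chrom": g.chrom, "strand": g.strand,
             "txStart": g.tx_start, "txEnd": g.tx_end}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# probe annotations


def read_probe_annotation(path) -> dict[str, frozenset[str]]:
    """Read a probe -> RefSeq mRNA annotation TSV.

    Two dialects are accepted and may be mixed: one row per (probe, RefSeq)
    pair, or a single row per probe with RefSeq IDs separated by ``,`` or
    ``;``. Probes may map to zero (empty field) or several RefSeq IDs.
    """
    mapping: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        header = fh.readline()
        if not header:
            return {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: expected 2 tab-separated columns, got {len(parts)}",
                    line=lineno,
                )
            probe = _strip_quotes(parts[0])
            ids = {
                t.strip() for t in re.split(r"[,;]", parts[1]) if t.strip()
            }
            for rid in ids:
                if not _REFSEQ_RE.match(rid):
                    logger.warning(
                        "%s line %d: %r does not look like a RefSeq ID", path, lineno, rid
                    )
            mapping.setdefault(probe, set()).update(ids)
    return {p: frozenset(v) for p, v in mapping.items()}


def write_probe_annotation(annotation: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\trefseq_ids\n")
        for probe, ids in annotation.items():
            fh.write(f"{probe}\t{';'.join(sorted(ids))}\n")


# ---------------------------------------------------------------------------
# site-level methylation calls


def read_site_table(path) -> pd.DataFrame:
    """Read BED-like site-level methylation calls.

    Accepted headers: ``chrom, position, beta`` or
    ``chrom, position, methylated_count, total_count``; a 0-based ``start``
    column may replace ``position`` and is shifted to 1-based on read.
    Returns a DataFrame with columns chrom, position (1-based), beta and,
    for count data, methylated_count / total_count.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    if "start" in df.columns and "position" not in df.columns:
        df = df.rename(columns={"start": "position"})
        df["position"] = df["position"].astype(int) + 1
    if "chrom" not in df.columns or "position" not in df.columns:
        raise FormatError(f"site table {path} needs chrom and position/start columns")
    df["position"] = df["position"].astype(int)
    if "beta" in df.columns:
        beta = df["beta"].astype(float)
        bad = beta.index[(beta < 0) | (beta > 1)]
        if len(bad):
            raise FormatError(f"{path}: beta outside [0, 1]", line=int(bad[0]) + 2)
        df["beta"] = beta
    elif {"methylated_count", "total_count"}.issubset(df.columns):
        m = df["methylated_count"].astype(int)
        t = df["total_count"].astype(int)
        bad = df.index[(t <= 0) | (m < 0) | (m > t)]
        if len(bad):
            raise FormatError(
                f"{path}: methylated_count/total_count out of range",
                line=int(bad[0]) + 2,
            )
        df["methylated_count"], df["total_count"] = m, t
        df["beta"] = m / t
    else:
        raise FormatError(
            f"site table {path} needs a beta column or methylated_count/total_count"
        )
    return df[[c for c in
               ("chrom", "position", "beta", "methylated_count", "total_count")
               if c in df.columns]]


def write_site_table(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# results


def write_results(results, out_dir, summary: dict | None = None) -> list[Path]:
    """Write one TSV per tail-pairing selection plus an optional JSON summary.

    ``results`` is an iterable of :class:`pcafe.integrate.SelectionResult`.
    Each TSV lists the common genes with the tails, PC indices, overlap count
    x, both per-platform universe sizes y and the overlap P-values.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for res in results:
        name = (
            f"selection_expr_pc{res.pairing.expr_pc}_meth_pc{res.pairing.meth_pc}"
            f"_{res.tail_pairing.replace('<->', '__')}.tsv"
        )
        fp = out_dir / name
        df = pd.DataFrame({"gene": sorted(res.common_genes)})
        df["expr_pc"] = res.pairing.expr_pc
        df["meth_pc"] = res.pairing.meth_pc
        df["tail_pairing"] = res.tail_pairing
        df["x"] = res.x
        df["y_expr"] = res.y_expr
        df["y_meth"] = res.y_meth
        df["p_overlap_expr"] = res.p_expr
        df["p_overlap_meth"] = res.p_meth
        df.to_csv(fp, sep="\t", index=False)
        written.append(fp)
    if summary is not None:
        fp = out_dir / "run_summary.json"
        fp.write_text(json.dumps(summary, indent=2, sort_keys=True))
        written.append(fp)
    return written


def read_results(path) -> pd.DataFrame:
    """Round-trip reader for a selection TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
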