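"""Probe-space principal component analysis and component characterization.

In this analysis PCA embeds *probes*, not samples: the left singular vectors
(scaled by the singular values) give each probe a score per component, while
the right singular vectors are the per-sample weight vectors — the
"contributions of samples" whose pattern across the 2x2 cell-line x
metastasis design tells what each component distinguishes. By default the
matrix is decomposed uncentered: on array data the leading component is then
the near-constant sample-independent profile carrying the bulk of the
variance, and the biologically interesting contrasts live in later, small
components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CATEGORIES, CATEGORY_LABELS, OmicsMatrix
from .errors import DesignError

logger = logging.getLogger(__name__)

#: Possible characterization labels of a component.
LABEL_FLAT = "flat"
LABEL_CELL = "cell_line"
LABEL_MET_A549 = "metastasis:A549"
LABEL_MET_HTB56 = "metastasis:HTB56"
LABEL_OTHER = "other"


@dataclass
class PCDecomposition:
    """Thin SVD of a probe x sample matrix.

    probe_scores
        probes x K DataFrame; column ``PCk`` is the k-th left singular vector
        scaled by its singular value (the probe embedding).
    sample_contributions
        K x samples DataFrame of right singular vectors (unit norm rows).
    contribution_fraction
        Fraction of total variance per component for *all* components of the
        thin decomposition (sums to 1), not only the K retained.
    """

    platform_id: str
    probe_scores: pd.DataFrame
    sample_contributions: pd.DataFrame
    contribution_fraction: np.ndarray
    K: int
    center: str = "none"

    @property
    def sample_ids(self) -> pd.Index:
        return self.sample_contributions.columns

    @property
    def probe_ids(self) -> pd.Index:
        return self.probe_scores.index

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass
class PCCharacterization:
    """What one component distinguishes across the 2x2 design."""

    pc: int
    label: str
    e_flat: float   # coefficient of variation of the sample contributions
    e_cell: float   # |mean(A549) - mean(HTB56)| / pooled within-category sd
    e_metA: float   # |A549- minus A549+| / s
    e_metH: float   # |HTB56- minus HTB56+| / s
    fallback_ranking: bool = False  # True when no within-category spread existed


def decompose(matrix: OmicsMatrix, K: int | None = None, center: str = "none") -> PCDecomposition:
    """Singular-value decomposition of the (optionally probe-centered) matrix.

    Parameters
    ----------
    matrix
        Probe x sample matrix without missing values (drop them first with
        :meth:`OmicsMatrix.drop_missing_probes`).
    K
        Number of components to retain; defaults to the full thin
        decomposition (the number of samples whenever probes outnumber
        samples, as they do on array data).
    center
        ``"none"`` (default — required to reproduce the near-constant
        dominant component) or ``"probe"`` to subtract each probe's mean.

    The sign of each component is fixed so the mean of its sample-contribution
    vector is >= 0 (tie broken by the first nonzero element >= 0), making
    output reproducible across linear-algebra backends.
    """
    X = matrix.values.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError(
            "matrix contains missing values; call drop_missing_probes() first"
        )
    n_probes, n_samples = X.shape
    k_max = min(n_probes, n_samples)
    if K is None:
        K = k_max
    if not 1 <= K <= n_samples:
        raise ValueError(f"K={K} must be in [1, {n_samples}]")
    if K > k_max:
        raise ValueError(
            f"K={K} exceeds the {k_max} components of a {n_probes}x{n_samples} matrix"
        )
    if center not in ("none", "probe"):
        raise ValueError(f"center must be 'none' or 'probe', got {center!r}")
    if center == "probe":
        logger.warning(
            "platform %s: probe-centered PCA requested; the dominant "
            "sample-independent component will be removed", matrix.platform_id,
        )
        X = X - X.mean(axis=1, keepdims=True)

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    ss = s ** 2
    total = ss.sum()
    fractions = ss / total if total > 0 else np.full_like(ss, 1.0 / len(ss))

    for k in range(Vt.shape[0]):
        m = Vt[k].mean()
        flip = m < 0
        if m == 0:
            nz = Vt[k][Vt[k] != 0]
            flip = len(nz) > 0 and nz[0] < 0
        if flip:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]

    pc_names = [f"PC{k + 1}" for k in range(K)]
    probe_scores = pd.DataFrame(
        U[:, :K] * s[:K], index=matrix.probe_ids, columns=pc_names
    )
    sample_contributions = pd.DataFrame(
        Vt[:K], index=pc_names, columns=matrix.sample_ids
    )
    return PCDecomposition(
        platform_id=matrix.platform_id,
        probe_scores=probe_scores,
        sample_contributions=sample_contributions,
        contribution_fraction=fractions,
        K=K,
        center=center,
    )


def category_means(dec: PCDecomposition, design) -> pd.DataFrame:
    """Average sample contributions within the four design categories.

    Returns a K x 4 DataFrame with columns in the fixed order
    ``A549-``, ``A549+``, ``HTB56-``, ``HTB56+``.
    """
    cols = {}
    for (cell, met), label in zip(CATEGORIES, CATEGORY_LABELS):
        members = [
            s for s in dec.sample_ids
            if design[s].cell_line == cell and design[s].metastasis == met
        ]
        if not members:
            raise DesignError(f"design category {label} has no samples")
        cols[label] = dec.sample_contributions[members].mean(axis=1)
    return pd.DataFrame(cols)


def _category_members(dec: PCDecomposition, design) -> dict[str, list[str]]:
    return {
        label: [
            s for s in dec.sample_ids
            if design[s].cell_line == cell and design[s].metastasis == met
        ]
        for (cell, met), label in zip(CATEGORIES, CATEGORY_LABELS)
    }


def characterize_pc(
    cm: pd.Series,
    dec: PCDecomposition,
    design,
    pc: int,
    z_threshold: float = 2.0,
    flat_cv: float = 0.1,
) -> PCCharacterization:
    """Assign a design label to one component from its contribution pattern.

    This formalizes the by-eye reading of sample-contribution plots: a
    component whose contributions are nearly constant (coefficient of
    variation below ``flat_cv``) is ``flat``; otherwise between-category
    differences are scaled by the pooled within-category standard deviation
    of replicate contributions and the largest effect exceeding
    ``z_threshold`` wins (``cell_line`` beats the metastasis labels only when
    its effect is the largest). Ties and no exceedance give ``other``. The
    thresholds are reported in output and configurable; there is no canonical
    numeric rule for this call.
    """
    c = dec.sample_contributions.loc[f"PC{pc}"].to_numpy(float)
    mean_all = c.mean()
    cv = float(np.std(c)) / abs(mean_all) if mean_all != 0 else np.inf

    members = _category_members(dec, design)
    m = {lab: float(cm[lab]) for lab in CATEGORY_LABELS}
    sq, dof = 0.0, 0
    for lab, ids in members.items():
        vals = dec.sample_contributions.loc[f"PC{pc}", ids].to_numpy(float)
        if len(vals) >= 2:
            sq += float(((vals - vals.mean()) ** 2).sum())
            dof += len(vals) - 1
    fallback = dof == 0
    s = np.sqrt(sq / dof) if dof > 0 else np.nan

    d_cell = abs((m["A549-"] + m["A549+"]) / 2 - (m["HTB56-"] + m["HTB56+"]) / 2)
    d_metA = abs(m["A549-"] - m["A549+"])
    d_metH = abs(m["HTB56-"] - m["HTB56+"])

    if fallback or s == 0:
        if not fallback:
            fallback = True
        logger.warning(
            "platform %s PC%d: no within-category spread; falling back to "
            "between-category ranking", dec.platform_id, pc,
        )
        effects = {LABEL_CELL: d_cell, LABEL_MET_A549: d_metA, LABEL_MET_HTB56: d_metH}
        exceed = {k: v for k, v in effects.items() if v > 0}
    else:
        effects = {
            LABEL_CELL: d_cell / s,
            LABEL_MET_A549: d_metA / s,
            LABEL_MET_HTB56: d_metH / s,
        }
        exceed = {k: v for k, v in effects.items() if v > z_threshold}

    if cv < flat_cv:
        label = LABEL_FLAT
    elif not exceed:
        label = LABEL_OTHER
    else:
        best = max(exceed.values())
        winners = [k for k, v in exceed.items() if v == best]
        label = winners[0] if len(winners) == 1 else LABEL_OTHER

    return PCCharacterization(
        pc=pc, label=label, e_flat=cv,
        e_cell=float(effects[LABEL_CELL]),
        e_metA=float(effects[LABEL_MET_A549]),
        e_metH=float(effects[LABEL_MET_HTB56]),
        fallback_ranking=fallback,
    )


def characterize_all(
    dec: PCDecomposition,
    design,
    z_threshold: float = 2.0,
    flat_cv: float = 0.1,
) -> list[PCCharacterization]:
    cm = category_means(dec, design)
    return [
        characterize_pc(cm.loc[f"PC{k}"], dec, design, k, z_threshold, flat_cv)
        for k in range(1, dec.K + 1)
    ]


def characterization_table(
    dec: PCDecomposition, chars: list[PCCharacterization], cm: pd.DataFrame
) -> pd.DataFrame:
    """One row per component: variance fraction, label, effect sizes and the
    four category means (the exportable summary of the embedding)."""
    rows = []
    for ch in chars:
        row = {
            "pc": ch.pc,
            "contribution_fraction": float(dec.contribution_fraction[ch.pc - 1]),
            "label": ch.label,
            "e_flat_cv": ch.e_flat,
            "e_cell": ch.e_cell,
            "e_metA": ch.e_metA,
            "e_metH": ch.e_metH,
            "fallback_ranking": ch.fallback_ranking,
        }
        row.update({lab: float(cm.loc[f"PC{ch.pc}", lab]) for lab in CATEGORY_LABELS})
        rows.append(row)
    return pd.DataFrame(rows).set_index("pc")
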