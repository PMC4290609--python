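import math

import numpy as np
import pytest

import pcafe
from pcafe import (
    correlate_pcs, decompose, gene_intersection, match_pcs, overlap_pvalue,
    run_selection, select_outliers, tail_pairings,
)
from pcafe.integrate import PCPairing

from conftest import balanced_specs, make_matrix


# ---------------------------------------------------------------------------
# correlate_pcs


def test_correlate_identical_and_reversed():
    r, p = correlate_pcs([1, 2, 3, 4], [1, 2, 3, 4])
    assert (r, p) == (1.0, 0.0)
    r, p = correlate_pcs([1, 2, 3, 4], [4, 3, 2, 1])
    assert (r, p) == (-1.0, 0.0)


def test_correlate_matches_t_transform_oracle():
    """(1,2,3,4) vs (1,2,3,5): r from the explicit covariance formula and p
    from the df=2 t tail computed via the incomplete-beta closed form."""
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 2.0, 3.0, 5.0])
    xc, yc = x - x.mean(), y - y.mean()
    r_expect = float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
    t = r_expect * math.sqrt(2 / (1 - r_expect ** 2))
    # two-sided t tail, df=2, closed form: p = 1 - t/sqrt(t^2 + 2)  (times 2/2)
    p_expect = 1.0 - t / math.sqrt(t * t + 2.0)
    r, p = correlate_pcs(x, y)
    assert r == pytest.approx(r_expect, abs=1e-12)
    assert p == pytest.approx(p_expect, rel=1e-10)


def test_correlate_zero_variance_is_error():
    with pytest.raises(ValueError, match="zero variance"):
        correlate_pcs([1, 1, 1, 1], [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# match_pcs


def test_identical_platforms_pair_diagonally(matrix_2x2):
    dec = decompose(matrix_2x2)
    pairings, audit = match_pcs(dec, dec, matrix_2x2.design, matrix_2x2.design,
                                max_pc=6)
    diag = {(p.expr_pc, p.meth_pc) for p in pairings}
    assert {(k, k) for k in range(1, 7)} <= diag
    assert all(p.r == pytest.approx(1.0) for p in pairings if p.expr_pc == p.meth_pc)
    assert len(audit) == 36  # every candidate correlation exported for audit


def test_planted_metastasis_pcs_pair_with_high_r(sim_default):
    d = sim_default
    dec_e = decompose(d.expr)
    dec_m = decompose(d.meth)
    pairings, _ = match_pcs(dec_e, dec_m, d.expr.design, d.meth.design)
    met = [p for p in pairings if p.label == "metastasis:HTB56"]
    assert len(met) == 1
    assert abs(met[0].r) > 0.9


def test_white_noise_platforms_pair_at_false_positive_rate():
    """Uncorrelated noise platforms pair only at the false-positive level of
    the alpha = 0.05 gate over the 36 candidate correlations, and almost
    never with a metastasis label on both sides."""
    counts, met_counts = [], []
    for seed in range(30):
        rng = np.random.default_rng(seed)
        me = make_matrix(rng.normal(0, 1, (80, 12)), balanced_specs(3), platform="e")
        mm = make_matrix(rng.normal(0, 1, (80, 8)), balanced_specs(2), platform="m")
        prs, _ = match_pcs(decompose(me), decompose(mm), me.design, mm.design)
        counts.append(len(prs))
        met_counts.append(sum(p.label.startswith("metastasis") for p in prs))
    assert np.mean(counts) <= 36 * 0.05  # the multiple-candidate FP budget
    assert np.mean(met_counts) < 0.35


# ---------------------------------------------------------------------------
# select_outliers


@pytest.fixture
def dec_scores():
    m = make_matrix(
        np.array([[5.0], [4.0], [3.0], [2.0], [1.0]]) * [1.0],
        [("A549", "without", 1)],
    )
    return decompose(m, K=1)


def test_select_all_probes(dec_scores):
    probes, expanded = select_outliers(dec_scores, 1, "high", n_top=5)
    assert set(probes) == {"P1", "P2", "P3", "P4", "P5"}
    assert not expanded


def test_select_top_two(dec_scores):
    probes, _ = select_outliers(dec_scores, 1, "high", n_top=2)
    assert list(probes) == ["P1", "P2"]
    probes, _ = select_outliers(dec_scores, 1, "low", n_top=2)
    assert list(probes) == ["P5", "P4"]


def test_select_ties_expand():
    m = make_matrix(np.array([[3.0], [2.0], [2.0], [1.0]]), [("A549", "without", 1)])
    dec = decompose(m, K=1)
    probes, expanded = select_outliers(dec, 1, "high", n_top=2)
    assert set(probes) == {"P1", "P2", "P3"}
    assert expanded


def test_select_argument_errors(dec_scores):
    with pytest.raises(ValueError):
        select_outliers(dec_scores, 1, "high", n_top=6)
    with pytest.raises(ValueError):
        select_outliers(dec_scores, 2, "high", n_top=2)
    with pytest.raises(ValueError):
        select_outliers(dec_scores, 1, "up", n_top=2)


# ---------------------------------------------------------------------------
# tail pairings and gene intersection


def test_tail_pairings_sign_rule():
    assert tail_pairings("positive") == ["expr_high<->meth_low", "expr_low<->meth_high"]
    assert tail_pairings("negative") == ["expr_high<->meth_high", "expr_low<->meth_low"]
    for sign in ("positive", "negative"):
        assert len(tail_pairings(sign)) == 2
    with pytest.raises(ValueError):
        tail_pairings("zero")


def test_gene_intersection_cases():
    annot_e = {"e1": frozenset({"NM_1"}), "e2": frozenset({"NM_2"})}
    annot_m = {"m1": frozenset({"NM_2"}), "m2": frozenset({"NM_3"})}
    common, x = gene_intersection(["e1", "e2"], ["m1", "m2"], annot_e, annot_m)
    assert (common, x) == (frozenset({"NM_2"}), 1)

    common, x = gene_intersection(["e1"], ["m2"], annot_e, annot_m)
    assert (common, x) == (frozenset(), 0)

    # a probe with two RefSeq IDs contributes both genes
    annot_e2 = {"e1": frozenset({"NM_1", "NM_3"})}
    common, x = gene_intersection(["e1"], ["m2"], annot_e2, annot_m)
    assert (common, x) == (frozenset({"NM_3"}), 1)

    # unannotated probes contribute nothing
    common, x = gene_intersection(["e9"], ["m1"], annot_e, annot_m)
    assert x == 0


# ---------------------------------------------------------------------------
# overlap_pvalue


def test_overlap_zero_is_one():
    assert overlap_pvalue(0, 100, 20000) == 1.0


def test_overlap_closed_form_x1():
    for y in (10_000, 30_000):
        expected = 1.0 - (1.0 - 100 / y) ** 100
        assert overlap_pvalue(1, 100, y) == pytest.approx(expected, rel=1e-12)


def test_overlap_matches_pmf_summation():
    """P[X >= x] for X ~ Binomial(100, 100/y) by explicit pmf summation with
    math.comb — an oracle independent of the scipy survival function."""
    n = 100
    for y in (10_000, 30_000):
        p = n / y
        for x in range(0, 21):
            tail = sum(
                math.comb(n, k) * p ** k * (1 - p) ** (n - k) for k in range(x, n + 1)
            )
            assert overlap_pvalue(x, n, y) == pytest.approx(tail, rel=1e-9)


def test_overlap_literal_variant():
    assert pcafe.overlap_pvalue(0, 100, 10_000, variant="literal") == pytest.approx(
        1.0 - (1.0 - 100 / 10_000) ** 100, rel=1e-12
    )


def test_overlap_monotonicity():
    n, y = 100, 10_000
    ps = [overlap_pvalue(x, n, y) for x in range(0, 15)]
    assert all(a > b for a, b in zip(ps, ps[1:]))  # strictly decreasing in x
    for x in (1, 5, 10):
        assert overlap_pvalue(x, n, 5_000) > overlap_pvalue(x, n, 20_000)


def test_overlap_argument_errors():
    with pytest.raises(ValueError):
        overlap_pvalue(101, 100, 10_000)
    with pytest.raises(ValueError):
        overlap_pvalue(1, 100, 100)
    with pytest.raises(ValueError):
        overlap_pvalue(-1, 100, 10_000)


# ---------------------------------------------------------------------------
# run_selection


def _toy_platforms(seed=0):
    rng = np.random.default_rng(seed)
    ne, nm = 150, 120
    me = make_matrix(rng.normal(0, 1, (ne, 8)), balanced_specs(2), platform="e",
                     probe_prefix="E")
    mm = make_matrix(rng.normal(0, 1, (nm, 8)), balanced_specs(2), platform="m",
                     probe_prefix="M")
    annot_e = {f"E{i + 1}": frozenset({f"NM_{i + 1:04d}"}) for i in range(ne)}
    annot_m = {f"M{i + 1}": frozenset({f"NM_{i + 1:04d}"}) for i in range(nm)}
    return me, mm, annot_e, annot_m


def test_selection_pvalues_recomputable():
    me, mm, annot_e, annot_m = _toy_platforms()
    dec_e, dec_m = decompose(me), decompose(mm)
    pairing = PCPairing(expr_pc=2, meth_pc=2, r=0.95, p=0.01, label="other")
    for res in run_selection(pairing, dec_e, dec_m, annot_e, annot_m, n_top=20):
        assert res.x == len(res.common_genes)
        assert res.p_expr == overlap_pvalue(res.x, res.n_top, res.y_expr)
        assert res.p_meth == overlap_pvalue(res.x, res.n_top, res.y_meth)
        assert res.y_expr == 150 and res.y_meth == 120


def test_swapping_platforms_swaps_tails_keeps_overlap():
    """Using methylation as 'expression' and vice versa relabels the tails
    but leaves the common genes and overlap count unchanged."""
    me, mm, annot_e, annot_m = _toy_platforms(3)
    dec_e, dec_m = decompose(me), decompose(mm)
    pairing = PCPairing(expr_pc=2, meth_pc=3, r=0.9, p=0.01, label="other")
    swapped = PCPairing(expr_pc=3, meth_pc=2, r=0.9, p=0.01, label="other")
    fwd = run_selection(pairing, dec_e, dec_m, annot_e, annot_m, n_top=20)
    rev = run_selection(swapped, dec_m, dec_e, annot_m, annot_e, n_top=20)

    def key(res):  # tails as an unordered platform-agnostic pair
        te, tm = (part.split("_")[1] for part in res.tail_pairing.split("<->"))
        return frozenset([("a", te), ("b", tm)])

    fwd_map = {key(r): r for r in fwd}
    for r in rev:
        te, tm = (part.split("_")[1] for part in r.tail_pairing.split("<->"))
        mirror = frozenset([("a", tm), ("b", te)])
        match = fwd_map[mirror]
        assert r.common_genes == match.common_genes
        assert r.x == match.x
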