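import itertools

import numpy as np
import pandas as pd
import pytest

import pcafe
from pcafe import bh_adjust, ks_onesided, paired_probe_correlation, per_probe_ttest

from conftest import balanced_specs, make_matrix


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_oracle(pvals):
    """Brute-force step-up: q_i = min over thresholds t in {p_j : p_j >= p_i}
    of m * t / #{k : p_k <= t}, capped at 1."""
    p = list(pvals)
    m = len(p)
    out = []
    for pi in p:
        qs = []
        for t in p:
            if t >= pi:
                rank = sum(1 for pk in p if pk <= t)
                qs.append(min(1.0, m * t / rank))
        out.append(min(qs))
    return out


def test_bh_hand_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_single_and_degenerate():
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_bh_matches_bruteforce_on_grid():
    grid = [0.01, 0.05, 0.2, 0.5, 1.0]
    for length in (2, 3, 4):
        for combo in itertools.product(grid, repeat=length):
            np.testing.assert_allclose(
                bh_adjust(list(combo)), bh_oracle(combo), atol=1e-12,
                err_msg=f"combo={combo}",
            )


def test_bh_matches_bruteforce_random_longer_lists():
    rng = np.random.default_rng(0)
    grid = np.arange(0, 21) * 0.05
    for _ in range(100):
        p = rng.choice(grid, size=8).tolist()
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


def test_bh_order_equivariance():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=10)
    perm = rng.permutation(10)
    np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


# ---------------------------------------------------------------------------
# per-probe t-tests


def _groups(matrix, cell):
    return matrix.samples_in(cell, "with"), matrix.samples_in(cell, "without")


def test_ttest_identical_groups_near_one():
    rng = np.random.default_rng(0)
    base = rng.normal(8, 1, (30, 3))
    X = np.hstack([base, base])  # the two HTB56 groups are identical
    specs = ([("HTB56", "with", r) for r in (1, 2, 3)]
             + [("HTB56", "without", r) for r in (1, 2, 3)])
    m = make_matrix(X, specs)
    tab = per_probe_ttest(m, *_groups(m, "HTB56"))
    assert (tab["zero_variance"] | (tab["p_raw"] > 0.9)).all()


def test_ttest_planted_shift_is_most_significant():
    rng = np.random.default_rng(2)
    X = rng.normal(0, 1, (50, 6))
    X[7, :3] += 10.0  # ~10 pooled SDs between 3-vs-3 groups
    specs = ([("A549", "with", r) for r in (1, 2, 3)]
             + [("A549", "without", r) for r in (1, 2, 3)])
    m = make_matrix(X, specs)
    tab = per_probe_ttest(m, *_groups(m, "A549"))
    assert tab["p_raw"].idxmin() == "P8"
    assert tab.loc["P8", "direction"] == 1.0
    assert tab.loc["P8", "p_raw"] < 1e-2  # Welch df is tiny at 3 vs 3


def test_ttest_zero_variance_flagged():
    X = np.ones((3, 4))
    X[1] = [0.0, 1.0, 5.0, 6.0]
    specs = [("A549", "with", 1), ("A549", "with", 2),
             ("A549", "without", 1), ("A549", "without", 2)]
    m = make_matrix(X, specs)
    tab = per_probe_ttest(m, *_groups(m, "A549"))
    assert tab.loc["P1", "zero_variance"]
    assert tab.loc["P1", "p_raw"] == 1.0
    assert not tab.loc["P2", "zero_variance"]


def test_ttest_label_permutation_controls_significance(sim_default):
    """Comparing a scrambled split of the HTB56 expression samples (one with-
    and one without-metastasis replicate per group) should leave ~no probe
    significant after adjustment."""
    expr = sim_default.expr
    with_met = expr.samples_in("HTB56", "with")
    without = expr.samples_in("HTB56", "without")
    mixed_a = [with_met[0], without[0], with_met[1]]
    mixed_b = [without[1], with_met[2], without[2]]
    tab = per_probe_ttest(expr, mixed_a, mixed_b)
    assert int(tab["significant"].sum()) <= 2


def test_ttest_ranks_planted_metastasis_probes_first(sim_default):
    """With 3-vs-3 replicates the planted HTB56-metastasis probes dominate
    the smallest raw P-values even though few survive BH adjustment (the
    small-replicate power problem the probe-space PCA approach works
    around)."""
    expr = sim_default.expr
    tab = per_probe_ttest(expr, *_groups(expr, "HTB56"))
    metH = set(sim_default.truth.metH_genes)
    top30 = tab["p_raw"].nsmallest(30).index
    hits = sum(bool(sim_default.annot_expr[p] & metH) for p in top30)
    # ~1.4% of probes are planted; under the null the top-30 would hold < 1
    assert hits >= 15
    # all significant calls (if any) are planted metastasis genes
    for p in tab.index[tab["significant"]]:
        assert sim_default.annot_expr[p] & metH


def test_ttest_argument_errors(matrix_2x2):
    a = matrix_2x2.samples_in("A549", "with")
    with pytest.raises(ValueError):
        per_probe_ttest(matrix_2x2, a, [a[0]])
    with pytest.raises(ValueError):
        per_probe_ttest(matrix_2x2, a, ["nope", "nah"])


# ---------------------------------------------------------------------------
# paired probe correlations


def _paired_platforms(r_sign=-1.0, seed=0, n=40):
    """Expression/methylation pair where gene NM_0001's category means are
    exactly (anti)correlated across platforms."""
    rng = np.random.default_rng(seed)
    Xe = rng.normal(8, 1, (n, 12))
    Xm = rng.normal(0.5, 0.1, (n, 8))
    cat_pattern = np.array([1.0, 2.0, 3.0, 4.0])
    Xe[0] = np.repeat(cat_pattern, 3)
    Xm[0] = np.repeat(0.5 + 0.05 * r_sign * cat_pattern, 2)
    me = make_matrix(Xe, balanced_specs(3), platform="e", probe_prefix="E")
    mm = make_matrix(Xm, balanced_specs(2), platform="m", probe_prefix="M",
                     is_beta=True)
    annot_e = {f"E{i + 1}": frozenset({f"NM_{i + 1:04d}"}) for i in range(n)}
    annot_m = {f"M{i + 1}": frozenset({f"NM_{i + 1:04d}"}) for i in range(n)}
    return me, mm, annot_e, annot_m


def test_paired_correlation_planted_anticorrelated_pair():
    me, mm, annot_e, annot_m = _paired_platforms(r_sign=-1.0)
    tab = paired_probe_correlation(me, mm, annot_e, annot_m)
    row = tab[tab["refseq_id"] == "NM_0001"].iloc[0]
    assert row["r"] == pytest.approx(-1.0)
    assert row["p_raw"] == 0.0


def test_paired_correlation_category_permutation_invariant():
    """Relabelling the four categories consistently on both platforms leaves
    each pair's correlation unchanged."""
    me, mm, annot_e, annot_m = _paired_platforms(seed=4)
    tab = paired_probe_correlation(me, mm, annot_e, annot_m)

    swap = {"A549": "HTB56", "HTB56": "A549"}
    def relabel(mat):
        new_design = {
            s: pcafe.SampleDesign(swap[d.cell_line], d.metastasis, d.replicate)
            for s, d in mat.design.items()
        }
        return pcafe.OmicsMatrix(mat.platform_id, mat.values, new_design,
                                 is_beta=mat.is_beta)

    tab2 = paired_probe_correlation(relabel(me), relabel(mm), annot_e, annot_m)
    merged = tab.merge(tab2, on=["expr_probe", "meth_probe"], suffixes=("", "_2"))
    np.testing.assert_allclose(merged["r"], merged["r_2"], atol=1e-12)


def test_paired_correlation_null_calibration():
    """On null data the raw P-value of the df=2 correlation test is uniform:
    the fraction below 0.05 stays near 0.05 over many independent pairs."""
    fracs = []
    for seed in range(4):
        me, mm, annot_e, annot_m = _paired_platforms(seed=10 + seed, n=500)
        tab = paired_probe_correlation(me, mm, annot_e, annot_m)
        null_rows = tab[tab["refseq_id"] != "NM_0001"]
        fracs.append((null_rows["p_raw"] < 0.05).mean())
    # 1996 null pairs: 3 binomial SDs ~ 0.015
    assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)


def test_paired_correlation_skips_degenerate_pairs():
    me, mm, annot_e, annot_m = _paired_platforms()
    vals = mm.values.copy()
    vals.iloc[1] = 0.5  # constant probe: < 3 distinct category means
    mm2 = pcafe.OmicsMatrix(mm.platform_id, vals, mm.design, is_beta=True)
    tab = paired_probe_correlation(me, mm2, annot_e, annot_m)
    assert "NM_0002" not in set(tab["refseq_id"])


# ---------------------------------------------------------------------------
# one-sided KS


def test_ks_identical_samples_near_one():
    x = np.linspace(0, 1, 20)
    pa, pb = ks_onesided(x, x)
    assert pa > 0.95 and pb > 0.95


def test_ks_swap_symmetry():
    rng = np.random.default_rng(0)
    a = rng.normal(0.5, 1, 15)
    b = rng.normal(0, 1, 25)
    pa, pb = ks_onesided(a, b)
    pb2, pa2 = ks_onesided(b, a)
    assert (pa, pb) == (pa2, pb2)


def test_ks_shifted_direction():
    rng = np.random.default_rng(1)
    b = rng.normal(0, 1, 20)
    a = b + 3.0
    pa, pb = ks_onesided(a, b)
    assert pa < 1e-4
    assert pb > 0.9


def test_ks_table_layout():
    values = pd.DataFrame(
        np.random.default_rng(2).normal(size=(3, 10)),
        index=["g1", "g2", "g3"],
        columns=[f"s{i}" for i in range(10)],
    )
    tab = pcafe.ks_table(values, [f"s{i}" for i in range(5)],
                         [f"s{i}" for i in range(5, 10)])
    assert list(tab.columns) == ["p_a_greater", "p_b_greater"]
    assert len(tab) == 3
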