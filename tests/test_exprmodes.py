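"""Normalization, NB testing, mode classification, ASE rules, reporting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from triohap import exprmodes, simdata
from triohap.exprmodes import (
    MODE_CATEGORIES,
    ase_model_test,
    ase_ratio_call,
    average_across_references,
    classify_mode,
    decide_mode,
    expressed_filter,
    fpkm,
    mpv_comparison,
    nb_two_group_test,
    pathway_report,
    percent,
    size_factors,
    sum_gene_copies,
)


def _nb(rng, mu, phi, n):
    size = 1.0 / phi
    return pd.DataFrame(
        {f"r{i}": rng.negative_binomial(size, size / (size + np.asarray(mu))) for i in range(n)}
    )


def test_fpkm_formula_and_scaling():
    counts = pd.DataFrame({"s1": [100, 10**6 - 100]}, index=["g1", "g2"])
    lengths = pd.Series([1000, 10**6], index=["g1", "g2"])
    mat = fpkm(counts, lengths)
    assert mat.loc["g1", "s1"] == pytest.approx(100.0)
    doubled = counts * 2
    assert np.allclose(fpkm(doubled, lengths), mat)  # FPKM is depth-invariant
    assert fpkm(counts.assign(s1=[0, 10**6]), lengths).loc["g1", "s1"] == 0.0
    with pytest.raises(ValueError):
        fpkm(counts.assign(s1=0), lengths)


def test_size_factors_median_of_ratios():
    """Oracle: direct median-of-ratios arithmetic for exact 2x scaling."""
    rng = np.random.default_rng(0)
    base = rng.poisson(100, 50) + 1
    counts = pd.DataFrame({"s1": base, "s2": 2 * base})
    sf = size_factors(counts)
    assert sf["s1"] == pytest.approx(1 / np.sqrt(2), rel=1e-9)
    assert sf["s2"] == pytest.approx(np.sqrt(2), rel=1e-9)
    assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)
    identical = pd.DataFrame({"a": base, "b": base})
    assert np.allclose(size_factors(identical), 1.0)
    with pytest.raises(ValueError):
        size_factors(pd.DataFrame({"a": [0, 1], "b": [1, 0]}))


def test_equal_groups_give_null_result():
    counts = pd.DataFrame({"r1": [100, 50], "r2": [120, 60], "r3": [80, 40]})
    res = nb_two_group_test(counts, counts.copy(), size_factors_=(np.ones(3), np.ones(3)))
    assert np.allclose(res["log2FC"], 0.0)
    assert np.allclose(res["pvalue"], 1.0)


def test_all_zero_gene_flagged_untestable():
    a = pd.DataFrame({"r1": [0, 100], "r2": [0, 110], "r3": [0, 90]})
    b = pd.DataFrame({"r1": [0, 400], "r2": [0, 380], "r3": [0, 420]})
    res = nb_two_group_test(a, b, size_factors_=(np.ones(3), np.ones(3)))
    assert bool(res["untestable"].iloc[0]) and np.isnan(res["pvalue"].iloc[0])
    assert not res["untestable"].iloc[1]


def test_null_calibration_and_power():
    """Type-I error at the NB null within 3 binomial SDs of alpha, and near-
    complete power for a planted 8-fold change at species thresholds."""
    rng = np.random.default_rng(42)
    n_genes = 2000
    mu = np.exp(rng.uniform(np.log(20), np.log(2000), n_genes))
    res = nb_two_group_test(_nb(rng, mu, 0.05, 3), _nb(rng, mu, 0.05, 3))
    for alpha in (0.05, 0.01):
        rate = (res["pvalue"] < alpha).mean()
        sd = np.sqrt(alpha * (1 - alpha) / n_genes)
        assert abs(rate - alpha) <= 3 * sd, f"alpha={alpha}: {rate}"
    muA = np.full(1000, 50.0)
    resp = nb_two_group_test(
        _nb(rng, muA, 0.05, 3), _nb(rng, muA * 8, 0.05, 3),
        size_factors_=(np.ones(3), np.ones(3)),
    )
    power = ((resp["pvalue"] < 0.01) & (resp["log2FC"].abs() > 2)).mean()
    assert power >= 0.95


def test_expressed_filter_summed_counts():
    p1 = pd.DataFrame({"r1": [5, 5, 0], "r2": [7, 4, 0]}, index=["a", "b", "c"])
    p2 = pd.DataFrame({"r1": [8, 2, 9], "r2": [7, 2, 8]}, index=["a", "b", "c"])
    kept = expressed_filter(p1, p2)
    assert list(kept) == ["a"]  # b: parent2 sum 4 < 10; c: parent1 sum 0
    assert len(expressed_filter(p1, p2, min_total=0)) == 3


def test_mpv_additive_and_planted_nonadditive_fraction():
    """70% of genes at the mid-parent, 30% deviating four-fold: the additive
    calls recover the planted split within 5 percentage points."""
    rng = np.random.default_rng(1)
    n = 1000
    mu1 = np.exp(rng.uniform(np.log(50), np.log(500), n))
    mu2 = mu1 * rng.choice([1.0, 3.0], n)
    mpv_mu = (mu1 + mu2) / 2
    nonadd = rng.random(n) < 0.30
    h_mu = np.where(nonadd, np.where(rng.random(n) < 0.5, 4.0, 0.25) * mpv_mu, mpv_mu)
    p1, p2 = _nb(rng, mu1, 0.05, 3), _nb(rng, mu2, 0.05, 3)
    res = mpv_comparison(p1, p2, _nb(rng, h_mu, 0.05, 3))
    measured_nonadd = (res["call"] != "additive").mean()
    assert abs(measured_nonadd - 0.30) <= 0.05
    assert (res["call"][nonadd] != "additive").mean() >= 0.9
    assert (res["call"][~nonadd] == "additive").mean() >= 0.9
    with pytest.raises(ValueError):
        mpv_comparison(p1, p2.iloc[:, :2], p1)


def test_decision_table_is_total_and_consistent():
    """Every combination of the three test outcomes maps to exactly one
    category, and over/underdominance always reflect both signs."""
    for s12, sh1, sh2 in itertools.product((-1, 0, 1), repeat=3):
        cat = decide_mode(s12, sh1, sh2)
        assert cat in MODE_CATEGORIES
        if sh1 > 0 and sh2 > 0:
            assert cat == "overdominance"
        if sh1 < 0 and sh2 < 0:
            assert cat == "underdominance"
        if s12 == 0 and sh1 == 0 and sh2 == 0:
            assert cat == "conserved"
        if s12 != 0 and sh1 == 0 and sh2 == 0:
            assert cat == "additive"


def _fake_test(lfc, p):
    return pd.DataFrame({"log2FC": lfc, "pvalue": p, "padj": p})


def test_classify_mode_worked_examples():
    # P1=100, P2=400 different; H equals the higher parent
    t12 = _fake_test([2.0], [1e-6])
    th1 = _fake_test([2.0], [1e-6])  # H vs P1: up
    th2 = _fake_test([0.0], [0.9])  # H vs P2: same
    assert classify_mode(t12, th1, th2)["category"].iloc[0] == "high_parent_dominance"
    # H above both parents
    th2_up = _fake_test([2.0], [1e-6])
    assert classify_mode(t12, _fake_test([4.0], [1e-9]), th2_up)["category"].iloc[0] == (
        "overdominance"
    )
    # nothing significant anywhere
    null = _fake_test([0.1], [0.8])
    assert classify_mode(null, null, null)["category"].iloc[0] == "conserved"
    # missing test -> ambiguous
    nan_test = _fake_test([np.nan], [np.nan])
    out = classify_mode(t12, nan_test, th2)
    assert out["category"].iloc[0] == "ambiguous" and out["reason"].iloc[0] == "missing_test"


def _allelic_frame(m, p):
    genes = [f"g{i}" for i in range(len(m))]
    rows = []
    for r in range(m.shape[1]):
        for i, g in enumerate(genes):
            rows.append(
                {"gene_id": g, "replicate": f"rep{r+1}", "maternal": m[i, r], "paternal": p[i, r]}
            )
    return pd.DataFrame(rows)


def test_ase_model_symmetry_and_balance():
    rng = np.random.default_rng(2)
    m = rng.poisson(200, (100, 3))
    allelic = _allelic_frame(m, m.copy())
    res = ase_model_test(allelic)
    assert (res["label"] == "balanced").all()

    m2 = rng.poisson(400, (100, 3))
    p2 = rng.poisson(100, (100, 3))
    fwd = ase_model_test(_allelic_frame(m2, p2))
    rev = ase_model_test(_allelic_frame(p2, m2))
    swap = {"maternal": "paternal", "paternal": "maternal", "balanced": "balanced"}
    assert list(fwd["label"].map(swap)) == list(rev["label"])


def test_ase_model_detects_strong_imbalance():
    rng = np.random.default_rng(3)
    totals = _nb(rng, np.full(300, 500.0), 0.05, 3).to_numpy()
    m = rng.binomial(totals, 0.8)
    res = ase_model_test(_allelic_frame(m, totals - m))
    assert (res["label"] == "maternal").mean() >= 0.95


def test_ase_ratio_worked_rule():
    """The published rule: ratios (0.80, 0.75, 0.50) are maternal because
    two of three replicates exceed 0.7."""
    m = pd.DataFrame([[80.0, 75.0, 50.0]], index=["g1"], columns=["r1", "r2", "r3"])
    p = pd.DataFrame([[20.0, 25.0, 50.0]], index=["g1"], columns=["r1", "r2", "r3"])
    assert ase_ratio_call(m, p)["label"].iloc[0] == "maternal"
    assert ase_ratio_call(p, m)["label"].iloc[0] == "paternal"  # (0.20, 0.25, 0.50)
    m2 = pd.DataFrame([[20.0, 25.0, 80.0]], index=["g1"], columns=["r1", "r2", "r3"])
    p2 = pd.DataFrame([[80.0, 75.0, 20.0]], index=["g1"], columns=["r1", "r2", "r3"])
    assert ase_ratio_call(m2, p2)["label"].iloc[0] == "paternal"


def test_ase_ratio_zero_totals_flagged():
    m = pd.DataFrame([[0.0, 0.0, 10.0]], index=["g1"], columns=["r1", "r2", "r3"])
    p = pd.DataFrame([[0.0, 0.0, 0.0]], index=["g1"], columns=["r1", "r2", "r3"])
    res = ase_ratio_call(m, p)
    assert res["n_excluded"].iloc[0] == 2
    assert bool(res["insufficient_data"].iloc[0])
    assert res["label"].iloc[0] == "balanced"


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=1000), st.integers(min_value=0, max_value=1000)
        ),
        min_size=3,
        max_size=3,
    )
)
def test_ase_ratio_symmetry_property(reps):
    """r(m, p) = 1 - r(p, m) for every replicate with nonzero total."""
    m = pd.DataFrame([[a for a, _ in reps]], index=["g"], columns=["r1", "r2", "r3"], dtype=float)
    p = pd.DataFrame([[b for _, b in reps]], index=["g"], columns=["r1", "r2", "r3"], dtype=float)
    fwd = ase_ratio_call(m, p)
    rev = ase_ratio_call(p, m)
    for c in ("r1", "r2", "r3"):
        a, b = fwd[f"ratio_{c}"].iloc[0], rev[f"ratio_{c}"].iloc[0]
        if not np.isnan(a):
            assert a == pytest.approx(1.0 - b)


def test_average_across_references():
    fa = pd.DataFrame({"s1": [10.0, 5.0]}, index=["a1", "a2"])
    fb = pd.DataFrame({"s1": [20.0, 7.0]}, index=["b1", "b2"])
    out = average_across_references(fa, fb, {"a1": "b1"})
    assert out.loc["a1", "s1"] == 15.0 and not out.loc["a1", "single_source"]
    assert out.loc["a2", "s1"] == 5.0 and out.loc["a2", "single_source"]
    assert out.loc["b2", "s1"] == 7.0 and out.loc["b2", "single_source"]
    # commutative up to index naming
    rev = average_across_references(fb, fa, {"b1": "a1"})
    assert rev.loc["b1", "s1"] == 15.0
    with pytest.raises(ValueError):
        average_across_references(fa, fb, {"a1": "b1", "a2": "b1"})


def test_sum_gene_copies_linearity():
    mat = pd.DataFrame({"s1": [10.0, 5.0, 2.0]}, index=["c1", "c2", "c3"])
    cmap = pd.DataFrame({"copy": ["c1", "c2", "c3"], "family": ["F1", "F1", "F2"]})
    fam = sum_gene_copies(mat, cmap)
    assert fam.loc["F1", "s1"] == 15.0 and fam.loc["F2", "s1"] == 2.0
    # summing after averaging equals averaging after summing
    mat2 = mat * 3
    avg_then_sum = sum_gene_copies((mat + mat2) / 2, cmap)
    sum_then_avg = (sum_gene_copies(mat, cmap) + sum_gene_copies(mat2, cmap)) / 2
    assert np.allclose(avg_then_sum, sum_then_avg)
    with pytest.raises(ValueError):
        sum_gene_copies(mat, pd.DataFrame({"copy": ["c1", "c1"], "family": ["F1", "F2"]}))
    with pytest.warns(UserWarning):
        fam = sum_gene_copies(mat, cmap, families=["F3"])
    assert fam.loc["F3", "s1"] == 0.0


def test_percent_rounds_half_up():
    assert percent(13, 58) == 22.41
    assert percent(17, 27) == 62.96
    assert percent(1, 8) == 12.5
    assert percent(1, 16) == 6.25
    assert np.isnan(percent(0, 0))


def test_pathway_report_percentages_recompute_from_counts():
    genes = [f"g{i}" for i in range(58)]
    cats = ["high_parent_dominance"] * 13 + ["conserved"] * 45
    mode_calls = pd.DataFrame({"category": cats}, index=genes)
    labels = ["maternal"] * 10 + ["paternal"] * 7 + ["balanced"] * 41
    ase_calls = pd.DataFrame({"label": labels}, index=genes)
    table = pathway_report(
        mode_calls, ase_calls, {"pw": genes, "sub": genes[:27], "empty": []}
    )
    t = table.set_index("pathway")
    assert t.loc["pw", "pct_high_parent_dominance"] == 22.41
    assert t.loc["sub", "pct_aseg"] == 62.96  # 10 maternal + 7 paternal of 27
    assert np.isnan(t.loc["empty", "pct_aseg"])
    # every printed percentage recomputes exactly from its printed counts
    for pw in ("pw", "sub"):
        row = t.loc[pw]
        for cat in MODE_CATEGORIES:
            assert row[f"pct_{cat}"] == percent(int(row[f"n_{cat}"]), int(row["n_genes"]))
        assert row["pct_aseg"] == percent(int(row["n_aseg"]), int(row["n_genes"]))


def test_mode_recovery_on_planted_simulation():
    """Planted four-fold modes at the default replicate design are recovered:
    the dominance and overdominance categories via the three-test decision
    table, additivity via the mid-parent comparison."""
    cfg = simdata.SimConfig(genome_length=100_000, n_genes=1000, seed=30)
    p1, p2, allelic, truth = simdata.simulate_rnaseq_counts(cfg)
    hyb = (
        allelic.assign(total=lambda d: d.maternal + d.paternal)
        .pivot(index="gene_id", columns="replicate", values="total")
        .loc[p1.index]
    )
    t12 = nb_two_group_test(p1, p2)
    th1 = nb_two_group_test(p1, hyb)
    th2 = nb_two_group_test(p2, hyb)
    calls = classify_mode(t12, th1, th2)
    truth_modes = truth.genes.set_index("gene_id")["mode"]
    for mode in ("high_parent_dominance", "overdominance"):
        planted = truth_modes[truth_modes == mode].index
        recall = (calls.loc[planted, "category"] == mode).mean()
        assert recall >= 0.9, f"{mode}: {recall}"
    mpv = mpv_comparison(p1, p2, hyb)
    planted_add = truth_modes[truth_modes == "additive"].index
    assert (mpv.loc[planted_add, "call"] == "additive").mean() >= 0.9
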