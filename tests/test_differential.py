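"""Permutation tests, BH adjustment and the DE calls, checked against
brute-force oracles and null simulations."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from pamuslink import differential as de


# ---------------------------------------------------------------- oracles

def oracle_permutation_p(a, b):
    """Exhaustive enumeration of all group assignments (independent of the
    implementation's vectorised path)."""
    pooled = list(a) + list(b)
    n, n_a = len(pooled), len(a)
    obs = abs(np.mean(a) - np.mean(b))
    count = 0
    total = 0
    for idx in combinations(range(n), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        total += 1
        if abs(np.mean(ga) - np.mean(gb)) >= obs - 1e-12:
            count += 1
    return (1 + count) / (1 + total)


def oracle_bh(p):
    """Hand step-up: p(i) * m / i then cumulative minimum from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------- fold change

def test_log2_fold_change_closed_forms():
    assert de.log2_fold_change([1, 2, 3], [1, 2, 3]) == 0
    assert de.log2_fold_change([4.0], [2.0]) == pytest.approx(1.0)
    assert de.log2_fold_change([0.9], [1.2]) == pytest.approx(np.log2(0.75))
    with pytest.raises(ValueError):
        de.log2_fold_change([], [1.0])
    with pytest.raises(ValueError):
        de.log2_fold_change([0.0, 0.0], [1.0])


# ----------------------------------------------------- permutation test

def test_permutation_constant_equal_groups_gives_p_one():
    assert de.permutation_test([1.0] * 4, [1.0] * 4) == 1.0


def test_permutation_symmetric_under_label_swap():
    a, b = [0.1, 0.9, 0.4, 0.7], [1.2, 1.5, 0.8, 1.9]
    assert de.permutation_test(a, b) == de.permutation_test(b, a)


@pytest.mark.parametrize("a,b", [
    ([0.1, 0.9, 0.4, 0.7], [1.2, 1.5, 0.8, 1.9]),       # 4v4 -> C(8,4)=70
    ([2.0, 2.2], [1.0, 1.1, 1.3, 0.9]),                  # 2v4 -> C(6,2)=15
    ([0.5, 0.1, 0.8], [0.4, 0.2, 0.9]),
])
def test_permutation_matches_exhaustive_enumeration(a, b):
    assert de.permutation_test(a, b) == pytest.approx(oracle_permutation_p(a, b))


def test_permutation_matrix_agrees_with_scalar_path():
    rng = np.random.default_rng(4)
    av = rng.normal(0, 1, (20, 4))
    bv = rng.normal(0.5, 1, (20, 4))
    ps = de.permutation_test_matrix(av, bv)
    for i in range(20):
        assert ps[i] == pytest.approx(de.permutation_test(av[i], bv[i]))


def test_permutation_rejects_tiny_groups():
    with pytest.raises(ValueError):
        de.permutation_test([1.0], [1.0, 2.0])


def test_sampled_permutation_path_is_seeded():
    rng = np.random.default_rng(8)
    a = rng.normal(0, 1, 10)
    b = rng.normal(1, 1, 10)  # C(20,10) = 184756 > exact cap
    p1 = de.permutation_test(a, b, n_perm=500, seed=42)
    p2 = de.permutation_test(a, b, n_perm=500, seed=42)
    assert p1 == p2
    assert 0 < p1 <= 1


def test_min_attainable_p_for_small_designs():
    assert de.min_attainable_p(4, 4) == pytest.approx(2 / 71)
    assert de.min_attainable_p(2, 4) == pytest.approx(2 / 16)


# ------------------------------------------------------------ BH / cutoff

def test_bh_worked_example_and_oracle():
    np.testing.assert_allclose(de.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    assert de.bh_adjust([0.37])[0] == pytest.approx(0.37)
    np.testing.assert_allclose(de.bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)
    rng = np.random.default_rng(1)
    p = rng.uniform(0, 1, 200)
    np.testing.assert_allclose(de.bh_adjust(p), oracle_bh(p), atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        de.bh_adjust([0.5, 1.2])


def test_corrected_raw_threshold_rank_scan():
    # boundaries at alpha=0.05, m=5: 0.01, 0.02, 0.03, 0.04, 0.05
    assert de.corrected_raw_threshold(
        [0.001, 0.01, 0.02, 0.1, 0.9], 0.05) == pytest.approx(0.02)
    p_small = [0.001, 0.002, 0.003]
    assert de.corrected_raw_threshold(p_small, 0.05) == pytest.approx(0.003)
    assert de.corrected_raw_threshold([0.5, 0.6, 0.9], 0.05) == 0.0


def test_corrected_threshold_consistent_with_bh():
    rng = np.random.default_rng(2)
    p = np.concatenate([rng.uniform(0, 0.01, 50), rng.uniform(0, 1, 500)])
    cutoff = de.corrected_raw_threshold(p, 0.05)
    adj = de.bh_adjust(p)
    np.testing.assert_array_equal(p <= cutoff, adj <= 0.05)


# ------------------------------------------------------------ protein DE

def _molpct_design(n_treat=4, n_ctrl=4, group="N-"):
    rows = []
    for i in range(n_ctrl):
        rows.append({"sample": f"c{i}", "group": "C", "day": 3,
                     "replicate": f"C{i}", "tmt_label": f"l{i}"})
    for i in range(n_treat):
        rows.append({"sample": f"t{i}", "group": group, "day": 3,
                     "replicate": f"{group}{i}", "tmt_label": f"l{9 - i}"})
    return pd.DataFrame(rows)


def test_protein_de_underpowered_contrast_warns():
    design = _molpct_design(n_treat=2, group="P-")
    rng = np.random.default_rng(0)
    molpct = pd.DataFrame(rng.lognormal(0, 0.2, (30, 6)),
                          index=[f"p{i}" for i in range(30)],
                          columns=[f"c{i}" for i in range(4)] + ["t0", "t1"])
    with pytest.warns(UserWarning, match="under-powered"):
        de.protein_de(molpct, design, contrast=("P-", "C"))


def test_protein_de_flags_and_reports_both_tiers():
    design = _molpct_design()
    rng = np.random.default_rng(3)
    base = rng.lognormal(0, 0.05, (40, 8))
    base[:8, 4:] *= 4.0  # strong effects in the treatment samples
    molpct = pd.DataFrame(base, index=[f"p{i}" for i in range(40)],
                          columns=[f"c{i}" for i in range(4)]
                          + [f"t{i}" for i in range(4)])
    table = de.protein_de(molpct, design, p_threshold=0.05, seed=0)
    assert set(table.columns) >= {"feature", "contrast", "l2fc", "p_raw",
                                  "p_adj", "significant"}
    assert (table["p_adj"] >= table["p_raw"] - 1e-15).all()
    strong = table.set_index("feature").loc[[f"p{i}" for i in range(8)]]
    assert strong["significant"].all()
    assert (strong["l2fc"] > 1.5).all()


# --------------------------------------------------------- transcript DE

def _counts_design(n_per_group=7):
    rows = []
    for g, prefix in (("C", "c"), ("N-", "n")):
        for i in range(n_per_group):
            rows.append({"sample": f"{prefix}{i}", "group": g, "day": 3,
                         "replicate": f"{prefix}{i}", "tmt_label": ""})
    return pd.DataFrame(rows)


def test_transcript_de_calls_require_both_thresholds():
    """A strong fold change with small p is DE; an equally significant but
    small fold change is not (|L2fc| must exceed 1)."""
    rng = np.random.default_rng(6)
    design = _counts_design(7)
    samples = [f"c{i}" for i in range(7)] + [f"n{i}" for i in range(7)]
    base = rng.poisson(1000, (30, 14)).astype(float)
    base[0, 7:] = rng.poisson(4000, 7)   # L2fc ~ 2
    base[1, 7:] = rng.poisson(1500, 7)   # L2fc ~ 0.58, strongly significant
    counts = pd.DataFrame(base, index=[f"g{i}" for i in range(30)],
                          columns=samples)
    table = de.transcript_de(counts, design, contrast=("N-", "C"), day=3,
                             seed=1).set_index("feature")
    assert table.loc["g0", "significant"]
    assert table.loc["g0", "l2fc"] > 1
    assert table.loc["g1", "p_adj"] < 0.05
    assert not table.loc["g1", "significant"]


def test_size_factors_median_of_ratios():
    counts = pd.DataFrame({"a": [100, 200, 300], "b": [200, 400, 600]},
                          index=["g1", "g2", "g3"]).astype(float)
    sf = de.size_factors(counts)
    # a doubled everywhere in b -> factors in ratio 1:2, geometric centre
    assert sf["b"] / sf["a"] == pytest.approx(2.0)


def test_transcript_null_type_one_error_near_nominal():
    """Global null: raw permutation p-values reject at close to the nominal
    0.05 level (7v7 design, where the discrete null is fine-grained)."""
    rng = np.random.default_rng(12)
    design = _counts_design(7)
    samples = [f"c{i}" for i in range(7)] + [f"n{i}" for i in range(7)]
    counts = pd.DataFrame(rng.poisson(500, (2500, 14)).astype(float),
                          index=[f"g{i}" for i in range(2500)],
                          columns=samples)
    table = de.transcript_de(counts, design, contrast=("N-", "C"), day=3,
                             seed=2)
    frac = (table["p_raw"] < 0.05).mean()
    assert frac == pytest.approx(0.05, abs=0.01)


def test_empirical_fdr_controlled_on_mixture():
    """10% true effects at |L2fc| = 2: the BH 0.05 cut keeps the realised
    false-discovery proportion near or below the target."""
    n_genes, n_true = 1000, 100
    fdps = []
    any_tp = False
    for seed in range(10):
        rngs = np.random.default_rng(100 + seed)
        base = rngs.lognormal(np.log(300), 0.1, (n_genes, 14))
        truth = np.zeros(n_genes, bool)
        truth[:n_true] = True
        base[:n_true, 7:] *= 4.0
        a = np.log2(base[:, 7:])
        b = np.log2(base[:, :7])
        p = de.permutation_test_matrix(a, b, seed=seed)
        rej = de.bh_adjust(p) < 0.05
        fp = int((rej & ~truth).sum())
        tp = int((rej & truth).sum())
        any_tp |= tp > 0
        fdps.append(fp / max(fp + tp, 1))
    assert any_tp
    assert np.mean(fdps) <= 0.08


def test_power_at_unit_fold_change_low_noise():
    """4v4, |L2fc| = 1, reporter-level CV 0.1: essentially every true
    effect reaches the permutation floor and survives BH."""
    rng = np.random.default_rng(10)
    n = 400
    sd = np.sqrt(np.log1p(0.1 ** 2)) / np.log(2)  # lognormal cv -> log2 sd
    ctrl = rng.normal(0.0, sd, (n, 4))
    treat = rng.normal(1.0, sd, (n, 4))
    p = de.permutation_test_matrix(treat, ctrl, seed=3)
    detected = de.bh_adjust(p) < 0.05
    assert detected.mean() >= 0.90
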