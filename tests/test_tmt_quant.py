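"""Unit tests for digestion, emPAI, isotope correction and PAMUS Mol%."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pamuslink import tmt_quant as tq
from pamuslink.simulate import SimConfig, simulate_study

# ---------------------------------------------------------------- oracles

# Monoisotopic residue masses, independent of the implementation's mass
# backend.
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.01056


def oracle_mass(peptide: str) -> float:
    return sum(RESIDUE_MASS[a] for a in peptide) + WATER


def oracle_digest(sequence: str, missed: int = 0) -> set:
    """Exhaustive left-to-right scan applying the KR-not-before-P rule."""
    cuts = [0]
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            cuts.append(i + 1)
    if cuts[-1] != len(sequence):
        cuts.append(len(sequence))
    fragments = [sequence[a:b] for a, b in zip(cuts, cuts[1:])]
    out = set()
    for m in range(missed + 1):
        for i in range(len(fragments) - m):
            out.add("".join(fragments[i:i + m + 1]))
    return out


# ------------------------------------------------------------- digestion

@pytest.mark.parametrize("seq,missed,expected", [
    ("AAAK", 0, {"AAAK"}),
    ("MKRAAAKPDER", 0, {"MK", "R", "AAAKPDER"}),
    ("MKRAAAK", 1, {"MK", "R", "AAAK", "MKR", "RAAAK"}),
])
def test_digest_worked_examples(seq, missed, expected):
    assert set(tq.digest_protein(seq, missed)) == expected


@pytest.mark.parametrize("bad", ["", "AAKBB", "AAK1"])
def test_digest_rejects_invalid_sequences(bad):
    with pytest.raises(ValueError):
        tq.digest_protein(bad)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60),
       missed=st.integers(min_value=0, max_value=2))
def test_digest_matches_exhaustive_scan(seq, missed):
    assert set(tq.digest_protein(seq, missed)) == oracle_digest(seq, missed)


# ------------------------------------------------- observable peptides

def test_observable_window_against_mass_oracle():
    # mass(AAAK) = 3*71.03711 + 128.09496 + water ~ 359.22 -> inside
    # mass(G) ~ 75.03 -> outside; mass(AAAKAAAK) ~ 700.4 -> outside
    peptides = ["G", "AAAK", "AAAKAAAK"]
    inside = [p for p in peptides if 350 <= oracle_mass(p) <= 700]
    assert inside == ["AAAK"]
    assert tq.count_observable_peptides(peptides, (350, 700)) == 1
    assert abs(tq.peptide_mass("AAAK") - oracle_mass("AAAK")) < 1e-3


def test_observable_counts_trivial_cases():
    assert tq.count_observable_peptides(["AAAK"], (0, np.inf)) == 1
    assert tq.count_observable_peptides([], (0, np.inf)) == 0
    # duplicates collapse
    assert tq.count_observable_peptides(["AAAK", "AAAK"], (0, np.inf)) == 1


# ------------------------------------------------------------------ emPAI

@pytest.mark.parametrize("n_obs,n_able,pai,empai", [
    (0, 10, 0.0, 0.0),
    (10, 10, 1.0, 9.0),
    (3, 12, 0.25, 10 ** 0.25 - 1),   # ~0.77828
])
def test_empai_closed_form(n_obs, n_able, pai, empai):
    got_pai, got_empai = tq.compute_empai(n_obs, n_able)
    assert got_pai == pytest.approx(pai)
    assert got_empai == pytest.approx(empai, abs=1e-9)


def test_empai_rejects_zero_observable():
    with pytest.raises(ValueError):
        tq.compute_empai(3, 0)


def test_empai_monotone_in_observed_count():
    values = [tq.compute_empai(k, 15)[1] for k in range(16)]
    assert all(b > a for a, b in zip(values, values[1:]))


# -------------------------------------------------- isotope correction

def test_isotope_identity_is_noop():
    raw = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    out = tq.correct_isotope_impurities(raw, np.eye(3))
    np.testing.assert_allclose(out, raw)


def test_isotope_round_trip_recovers_original():
    impurity = np.array([[0.95, 0.03], [0.05, 0.97]])
    truth = np.array([123.4, 56.7])
    mixed = impurity @ truth
    out = tq.correct_isotope_impurities(mixed, impurity)
    np.testing.assert_allclose(out, truth, atol=1e-10)


def test_isotope_correction_matches_closed_form_inverse():
    impurity = np.array([[0.95, 0.03], [0.05, 0.97]])
    raw = np.array([100.0, 0.0])
    a, b, c, d = impurity.ravel()
    det = a * d - b * c
    inv = np.array([[d, -b], [-c, a]]) / det
    expected = np.clip(inv @ raw, 0, None)  # the (2,1) solution is negative
    out = tq.correct_isotope_impurities(raw, impurity)
    np.testing.assert_allclose(out, expected, atol=1e-10)


def test_isotope_singular_matrix_errors():
    with pytest.raises(ValueError):
        tq.correct_isotope_impurities(np.ones(2), np.ones((2, 2)))
    with pytest.raises(ValueError):
        tq.correct_isotope_impurities(np.ones(3), np.ones((2, 2)))


# ------------------------------------------------ identification filter

def _toy_psms(unique_counts, prob=1.0):
    rows = []
    for i, k in enumerate(unique_counts):
        for j in range(k):
            rows.append({"spectrum_id": f"s{i}_{j}", "peptide": f"PEP{i}X{j}K",
                         "accession": f"prot{i}", "peptide_prob": prob,
                         "protein_prob": prob, "ch126": 1.0, "ch127N": 1.0})
    return pd.DataFrame(rows)


def test_filter_min_unique_peptides_rule():
    psms = _toy_psms([1, 2, 2, 3, 1])
    kept = tq.filter_identifications(psms)
    assert kept["accession"].nunique() == 3
    assert "prot0" not in set(kept["accession"])


def test_filter_keeps_confident_multi_peptide_table_unchanged():
    psms = _toy_psms([2, 3, 4])
    kept = tq.filter_identifications(psms)
    assert len(kept) == len(psms)


def test_filter_removes_low_confidence_decoys(small_study):
    kept = tq.filter_identifications(small_study.psms)
    assert not kept["is_decoy"].any()
    assert (kept.groupby("accession")["peptide"].nunique() >= 2).all()


# ----------------------------------------------------- PAMUS quantification

def _design(labels_to_samples):
    return pd.DataFrame({"sample": list(labels_to_samples.values()),
                         "tmt_label": list(labels_to_samples.keys())})


def test_pamus_single_protein_is_100_percent_everywhere():
    psms = pd.DataFrame({
        "spectrum_id": ["s1"], "peptide": ["AAAK"], "accession": ["p1"],
        "ch126": [5.0], "ch127N": [1.0], "ch127C": [2.0]})
    design = _design({"126": "a", "127N": "b", "127C": "c"})
    quant = tq.pamus_quantify(psms, {"p1": "AAAKGGGR"}, design,
                              tq.QuantOptions(mass_window=(0, 1e5)))
    for col in ("molpct_a", "molpct_b", "molpct_c"):
        assert quant[col].iloc[0] == pytest.approx(100.0)


def test_pamus_shares_are_proportional_split_of_empai():
    # sequence digests to {AAAK, GGGR}; both observable in a wide window;
    # one observed peptide -> PAI 0.5, emPAI 10^0.5 - 1
    psms = pd.DataFrame({
        "spectrum_id": ["s1"], "peptide": ["AAAK"], "accession": ["p1"],
        "ch126": [0.5], "ch127N": [0.3], "ch127C": [0.2]})
    design = _design({"126": "a", "127N": "b", "127C": "c"})
    quant = tq.pamus_quantify(psms, {"p1": "AAAKGGGR"}, design,
                              tq.QuantOptions(mass_window=(0, 1e5)))
    empai = 10 ** 0.5 - 1
    assert quant["empai"].iloc[0] == pytest.approx(empai)
    for col, frac in (("share_ch126", 0.5), ("share_ch127N", 0.3),
                      ("share_ch127C", 0.2)):
        assert quant[col].iloc[0] == pytest.approx(empai * frac)


def test_pamus_equal_proteins_split_50_50():
    psms = pd.DataFrame({
        "spectrum_id": ["s1", "s2"], "peptide": ["AAAK", "VVVK"],
        "accession": ["p1", "p2"],
        "ch126": [3.0, 3.0], "ch127N": [7.0, 7.0]})
    design = _design({"126": "a", "127N": "b"})
    quant = tq.pamus_quantify(psms, {"p1": "AAAKGGGR", "p2": "VVVKGGGR"},
                              design, tq.QuantOptions(mass_window=(0, 1e5)))
    assert quant["molpct_a"].tolist() == pytest.approx([50.0, 50.0])
    assert quant["molpct_b"].tolist() == pytest.approx([50.0, 50.0])


def test_pamus_psm_row_order_invariance(small_study):
    kept = tq.filter_identifications(small_study.psms)
    design = small_study.design
    seqs = small_study.truth.sequences
    q1 = tq.pamus_quantify(kept, seqs, design)
    shuffled = kept.sample(frac=1.0, random_state=5).reset_index(drop=True)
    q2 = tq.pamus_quantify(shuffled, seqs, design)
    pd.testing.assert_frame_equal(q1, q2)


def test_molpct_sums_to_100_per_sample(small_study):
    kept = tq.filter_identifications(small_study.psms)
    quant = tq.pamus_quantify(kept, small_study.truth.sequences,
                              small_study.design)
    molpct = tq.molpct_matrix(quant)
    np.testing.assert_allclose(molpct.sum(axis=0), 100.0, atol=1e-9)


def test_noiseless_quantification_tracks_true_abundance():
    """Zero reporter noise + identity impurities: within-protein channel
    shares are exactly proportional to true abundance, and between-protein
    Mol% ranks track true ranks (up to emPAI discretisation)."""
    cfg = SimConfig(n_genes=120, seed=21, reporter_noise_cv=0.0,
                    isotope_impurity_matrix=np.eye(10),
                    deterministic_pai=True, frac_decoy=0.0,
                    missingness=0.0)
    study = simulate_study(cfg)
    quant = tq.pamus_quantify(study.psms, study.truth.sequences, study.design)
    truth_ab = np.power(2.0, study.truth.protein_log2)

    share_cols = [c for c in quant.columns if c.startswith("share_")]
    shares = quant.set_index("accession")[share_cols]
    for acc in shares.index[:30]:
        s = shares.loc[acc].to_numpy(float)
        t = truth_ab.loc[acc].to_numpy(float)
        np.testing.assert_allclose(s / s.sum(), t / t.sum(), rtol=1e-9)

    molpct = tq.molpct_matrix(quant)
    for col in molpct.columns:
        rho = stats.spearmanr(molpct[col],
                              truth_ab.loc[molpct.index, col]).statistic
        assert rho > 0.9
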