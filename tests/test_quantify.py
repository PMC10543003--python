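"""Quantification arithmetic: digestion, correction factors, ppm, normalisations."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from brewtime.containers import (
    AbundanceMatrix,
    ConfigurationError,
    PeptideCountMatrix,
    SampleMetadata,
    ValidationError,
)
from brewtime.quantify import (
    CorrectionFactor,
    PeptideSet,
    UndefinedFactorError,
    correction_factor,
    detection_filter,
    digest_fasta,
    digest_protein,
    log2_median_center,
    peptide_filter,
    psm_to_ppm,
    row_mean_normalize,
    sum_replicates,
)


def regex_digest(sequence: str) -> list[str]:
    """Independent cleavage oracle: split after K/R not followed by P."""
    return [p for p in re.split(r"(?<=[KR])(?!P)", sequence) if p]


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "sequence,expected",
    [
        ("AAAA", ["AAAA"]),
        ("KKK", ["K", "K", "K"]),
        ("MKWVTFRPK", ["MK", "WVTFRPK"]),  # R-P bond is not cleaved
        ("AKPGR", ["AKPGR"]),  # K-P suppressed, trailing R at C-terminus
    ],
)
def test_digest_examples(sequence, expected):
    assert digest_protein("X", sequence).peptides == expected


def test_digest_rejects_nonstandard_residue():
    with pytest.raises(ValidationError, match="position 3"):
        digest_protein("X", "AAXA")
    with pytest.raises(ValidationError, match="empty"):
        digest_protein("X", "")


@settings(max_examples=300, derandomize=True)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=120))
def test_digest_reconstructs_and_matches_regex_oracle(sequence):
    ps = digest_protein("X", sequence)
    assert "".join(ps.peptides) == sequence
    assert ps.peptides == regex_digest(sequence)
    for pep, flag in zip(ps.peptides, ps.in_range):
        assert flag == (7 <= len(pep) <= 40)


# ---------------------------------------------------------------------------
# Peptide filter & correction factor
# ---------------------------------------------------------------------------

def _pepset(peps):
    return PeptideSet("X", list(peps), [7 <= len(p) <= 40 for p in peps])


def test_peptide_filter_window_inclusive():
    lens = {6: "A" * 6, 7: "A" * 7, 40: "A" * 40, 41: "A" * 41}
    filtered = peptide_filter(_pepset(lens.values()))
    assert sorted(len(p) for p in filtered.peptides) == [7, 40]
    assert peptide_filter(_pepset(["MK", "WVTFRPK"])).peptides == ["WVTFRPK"]
    assert peptide_filter(_pepset([])).peptides == []


def test_peptide_filter_bad_bounds():
    with pytest.raises(ConfigurationError):
        peptide_filter(_pepset(["AAAAAAA"]), min_len=10, max_len=5)


def test_correction_factor_sums_in_range_lengths():
    cf = correction_factor(_pepset(["A" * 7, "A" * 10]))
    assert cf.detectable_length == 17
    assert cf.factor == pytest.approx(1 / 17)
    assert correction_factor(_pepset(["A" * 10])).factor == pytest.approx(0.1)
    with pytest.raises(UndefinedFactorError):
        correction_factor(_pepset(["AAA"]))


def test_digest_fasta_excludes_undigestible():
    seqs = {"GOOD": "AAAAAAAAAA", "BAD": "KKKKK"}  # BAD digests to 1-mers only
    _, factors = digest_fasta(seqs)
    assert set(factors) == {"GOOD"}


# ---------------------------------------------------------------------------
# ppm conversion
# ---------------------------------------------------------------------------

def _counts(rows: dict, proteins: dict, lengths: dict, samples):
    idx = pd.Index(list(rows), name="peptide")
    return PeptideCountMatrix(
        data=pd.DataFrame(rows, index=samples).T,
        assignments=pd.Series(proteins),
        lengths=pd.Series(lengths),
    )


def test_ppm_hand_example():
    # A: one peptide of length 10, 3 PSMs -> weight 3; B: length 30, 1 PSM -> weight 1
    counts = _counts(
        {"pA": [3], "pB": [1]}, {"pA": "A", "pB": "B"}, {"pA": 10, "pB": 30}, ["s1"]
    )
    factors = {"A": CorrectionFactor("A", 10), "B": CorrectionFactor("B", 30)}
    ppm = psm_to_ppm(counts, factors)
    assert ppm.data.loc["A", "s1"] == pytest.approx(750_000)
    assert ppm.data.loc["B", "s1"] == pytest.approx(250_000)
    assert ppm.state == "ppm"


def test_ppm_single_protein_self_normalizes():
    counts = _counts({"p0": [17, 1]}, {"p0": "A"}, {"p0": 12}, ["s1", "s2"])
    ppm = psm_to_ppm(counts, {"A": CorrectionFactor("A", 12)})
    np.testing.assert_allclose(ppm.data.loc["A"], 1_000_000, rtol=1e-12)


def test_ppm_zero_count_protein_zero_ppm():
    counts = _counts(
        {"pA": [5], "pB": [0]}, {"pA": "A", "pB": "B"}, {"pA": 10, "pB": 10}, ["s1"]
    )
    factors = {p: CorrectionFactor(p, 10) for p in "AB"}
    ppm = psm_to_ppm(counts, factors)
    assert ppm.data.loc["B", "s1"] == 0.0


def test_ppm_scale_invariance(rng):
    n_pep = 30
    peps = {f"p{i}": rng.integers(1, 50) for i in range(n_pep)}
    prots = {f"p{i}": f"P{i % 7}" for i in range(n_pep)}
    lens = {f"p{i}": int(rng.integers(7, 41)) for i in range(n_pep)}
    counts = _counts({k: [v] for k, v in peps.items()}, prots, lens, ["s1"])
    factors = {
        p: CorrectionFactor(p, sum(lens[k] for k in lens if prots[k] == p))
        for p in set(prots.values())
    }
    ppm1 = psm_to_ppm(counts, factors)
    scaled = PeptideCountMatrix(counts.data * 5, counts.assignments, counts.lengths)
    ppm2 = psm_to_ppm(scaled, factors)
    pd.testing.assert_frame_equal(ppm1.data, ppm2.data)


def test_ppm_zero_weight_sample_flagged_missing():
    counts = _counts({"pA": [0, 3]}, {"pA": "A"}, {"pA": 10}, ["empty", "s2"])
    with pytest.warns(UserWarning, match="zero total weight"):
        ppm = psm_to_ppm(counts, {"A": CorrectionFactor("A", 10)})
    assert np.isnan(ppm.data.loc["A", "empty"])
    assert ppm.data.loc["A", "s2"] == pytest.approx(1_000_000)


def test_ppm_requires_factors_for_all_counted_proteins():
    counts = _counts({"pA": [1]}, {"pA": "A"}, {"pA": 10}, ["s1"])
    with pytest.raises(ValidationError, match="without a correction factor"):
        psm_to_ppm(counts, {})


def test_ppm_round_trip_recovers_true_abundance(rng):
    """At high sequencing depth, ppm rank-correlates with planted abundance."""
    from scipy.stats import spearmanr

    from brewtime.synthetic import simulate_protein_fasta, simulate_psm_counts

    seqs = simulate_protein_fasta(150, rng=5)
    peptide_sets, factors = digest_fasta(seqs)
    quantifiable = sorted(factors)
    true = pd.DataFrame(
        {"s1": np.exp2(rng.normal(10, 2, size=len(quantifiable)))}, index=quantifiable
    )
    ab = AbundanceMatrix(true, state="raw")
    lens = {p: peptide_sets[p].in_range_lengths() for p in quantifiable}
    counts = simulate_psm_counts(ab, lens, depth=10**5, rng=rng)
    ppm = psm_to_ppm(counts, factors)
    rho = spearmanr(true["s1"], ppm.data["s1"]).statistic
    assert rho >= 0.99


# ---------------------------------------------------------------------------
# Detection filter, replicate summing, normalisations
# ---------------------------------------------------------------------------

def _matrix(values, samples, proteins, state="raw"):
    return AbundanceMatrix(pd.DataFrame(values, index=proteins, columns=samples), state=state)


def test_detection_filter_unique_peptides_and_both_replicates(two_tp_metadata):
    samples = list(two_tp_metadata.samples)
    values = [[1.0, 2.0, 3.0, 4.0], [1.0, np.nan, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]]
    m = _matrix(values, samples, ["A", "B", "C"])
    uniq = pd.Series({"A": 3, "B": 2, "C": 1})
    out = detection_filter(m, two_tp_metadata, uniq)
    assert list(out.data.index) == ["A", "B"]  # C dropped: 1 unique peptide
    assert out.data.loc["B", samples[:2]].isna().all()  # masked at 0h
    assert not out.data.loc["B", samples[2:]].isna().any()  # kept at 6h


def test_detection_filter_fully_observed_unchanged(two_tp_metadata):
    m = _matrix([[1.0, 2, 3, 4]], list(two_tp_metadata.samples), ["A"])
    out = detection_filter(m, two_tp_metadata)
    pd.testing.assert_frame_equal(out.data, m.data)


def test_sum_replicates_cases(two_tp_metadata):
    samples = list(two_tp_metadata.samples)
    m = _matrix([[5.0, 7.0, 5.0, np.nan], [np.nan, np.nan, 1.0, 2.0]], samples, ["A", "B"])
    out = sum_replicates(m, two_tp_metadata)
    assert out.state == "replicate_summed"
    assert out.data.loc["A", "B1:0h"] == 12.0
    assert out.data.loc["A", "B1:6h"] == 5.0  # single replicate stands alone
    assert np.isnan(out.data.loc["B", "B1:0h"])  # missing in all replicates


def test_log2_median_center_example():
    m = _matrix([[2.0], [8.0], [32.0]], ["s1"], ["A", "B", "C"])
    out = log2_median_center(m)
    np.testing.assert_allclose(out.data["s1"], [-2.0, 0.0, 2.0])
    assert out.state == "log2_centered"


def test_log2_median_center_column_medians_zero(rng):
    m = _matrix(np.exp2(rng.normal(10, 2, size=(50, 4))), list("abcd"), range(50))
    out = log2_median_center(m)
    np.testing.assert_allclose(out.data.median(axis=0), 0.0, atol=1e-9)


def test_log2_median_center_zeros_become_missing_negatives_raise():
    m = _matrix([[0.0], [4.0], [8.0]], ["s1"], ["A", "B", "C"])
    out = log2_median_center(m)
    assert np.isnan(out.data.loc["A", "s1"])
    with pytest.raises(ValidationError):
        log2_median_center(_matrix([[-1.0]], ["s1"], ["A"]))


def test_row_mean_normalize_examples():
    m = _matrix([[4.0, 4.0, 4.0], [2.0, 4.0, 8.0]], list("abc"), ["A", "B"])
    out = row_mean_normalize(m)
    np.testing.assert_allclose(out.data.loc["A"], 0.0)
    np.testing.assert_allclose(
        out.data.loc["B"], np.log2(np.array([2, 4, 8]) / (14 / 3)), rtol=1e-12
    )
    assert out.state == "row_mean_normalized"


def test_row_mean_normalize_scale_invariance(rng):
    vals = np.exp2(rng.normal(8, 1, size=(10, 5)))
    m1 = _matrix(vals, list("abcde"), range(10))
    m2 = _matrix(vals * 16, list("abcde"), range(10))  # +4 in log2 space
    out1, out2 = row_mean_normalize(m1), row_mean_normalize(m2)
    pd.testing.assert_frame_equal(out1.data, out2.data)


def test_row_mean_normalize_drops_all_missing_rows():
    m = _matrix([[np.nan, np.nan], [1.0, 2.0]], ["a", "b"], ["A", "B"])
    with pytest.warns(UserWarning, match="all-missing"):
        out = row_mean_normalize(m)
    assert list(out.data.index) == ["B"]
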