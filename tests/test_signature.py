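"""Unit and property tests for k-mer counting, DRA, and TS."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dinusig import (
    SequenceRecord,
    cg_enrichment_percent,
    count_kmers,
    dra_profile,
    genome_baseline,
    load_baseline,
    save_baseline,
    transcript_signature,
)
from dinusig.signature import (
    DINUCLEOTIDES,
    EmptyProfileError,
    GenomeBaseline,
    rho_matrix,
    ts_matrix,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


def _nonzero(d):
    return {k: v for k, v in d.items() if v}


@pytest.mark.parametrize(
    "seq,k,expected",
    [
        ("ACGT", 2, {"AC": 1, "CG": 1, "GT": 1}),
        ("ACNGT", 2, {"AC": 1, "GT": 1}),  # windows spanning N dropped
        ("A", 2, {}),
        ("ACGT", 1, {"A": 1, "C": 1, "G": 1, "T": 1}),
        ("", 2, {}),
        ("acgu", 2, {"AC": 1, "CG": 1, "GT": 1}),  # RNA/lowercase normalised
    ],
)
def test_count_kmers_examples(seq, k, expected):
    assert _nonzero(count_kmers(SequenceRecord("x", residues=seq), k)) == expected


def test_count_kmers_rejects_bad_k():
    with pytest.raises(ValueError):
        count_kmers("ACGT", 3)


def test_dra_profile_hand_enumeration_cgcg():
    prof = dra_profile("CGCG")
    assert prof.nucleotide_freqs["C"] == 0.5
    assert prof.dinucleotide_freqs["CG"] == pytest.approx(2 / 3)
    assert prof.rho["CG"] == 8 / 3
    assert prof.rho["GC"] == pytest.approx(4 / 3)


def test_dra_profile_degenerate_composition():
    prof = dra_profile("AAAA")
    assert prof.rho["AA"] == 1.0
    assert prof.rho["AC"] is None  # f_C = 0 -> undefined, not 0


def test_dra_profile_empty_sequence_errors():
    with pytest.raises(EmptyProfileError):
        dra_profile("")


def test_pooling_sums_counts_without_junction_windows():
    pool = dra_profile(["ACGT", "ACGT"])
    assert pool.n_dinucleotides == 6
    assert pool.dinucleotide_freqs["CG"] == pytest.approx(2 / 6)
    # no TA window from the junction T|A
    assert pool.dinucleotide_counts["TA"] == 0


def test_genome_baseline_matches_pooled_profile_and_order_invariance(tmp_path):
    a = tmp_path / "a.fa"
    b = tmp_path / "b.fa"
    a.write_text(">chr1\nACGTACGT\n")
    b.write_text(">chr2\nGGCCNNTT\n")
    b1 = genome_baseline([a, b], build_label="toy")
    b2 = genome_baseline([b, a])
    assert b1.profile.dinucleotide_counts == b2.profile.dinucleotide_counts
    single = genome_baseline([a])
    assert single.profile.rho == dra_profile("ACGTACGT").rho
    assert b1.profile.n_nucleotides >= b1.profile.n_dinucleotides


def test_transcript_signature_identity_and_arithmetic():
    seq = SequenceRecord("t1", residues="ACGTACGTGGCC" * 5)
    self_baseline = GenomeBaseline(profile=dra_profile(seq))
    ts = transcript_signature(seq, self_baseline)
    for d, v in ts.ts.items():
        if v is not None:
            assert v == pytest.approx(1.0)
    assert ts.source_id == "t1"


def test_ts_undefined_propagates_not_zero():
    baseline = GenomeBaseline(profile=dra_profile("AAAA"))  # rho defined only for AA
    ts = transcript_signature(SequenceRecord("x", residues="ACGTACGT"), baseline)
    assert ts.ts["CG"] is None
    assert ts.ts["AA"] is not None


@pytest.mark.parametrize(
    "value,expected",
    [(2.0, 100.0), (1.0, 0.0), (0.8, pytest.approx(-20.0)), (None, None)],
)
def test_cg_enrichment_percent(value, expected):
    assert cg_enrichment_percent(value) == expected


def test_iid_rho_near_one_moderate_length():
    rng = np.random.default_rng(5)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200_000)])
    prof = dra_profile(seq)
    for d in DINUCLEOTIDES:
        assert prof.rho[d] == pytest.approx(1.0, abs=0.05)


@given(dna)
def test_conservation_of_counts(seq):
    """Unambiguous sequences: k-mer counts sum to L and L-1."""
    assert sum(count_kmers(seq, 1).values()) == len(seq)
    assert sum(count_kmers(seq, 2).values()) == max(len(seq) - 1, 0)


_RC = str.maketrans("ACGT", "TGCA")


@given(dna.filter(lambda s: len(s) >= 10))
def test_self_complementary_rho_strand_symmetric(seq):
    """rho*_CG and rho*_TA are invariant under reverse complement."""
    fwd = dra_profile(seq)
    rev = dra_profile(seq.translate(_RC)[::-1])
    for d in ("CG", "TA"):
        if fwd.rho[d] is None:
            assert rev.rho[d] is None
        else:
            assert rev.rho[d] == pytest.approx(fwd.rho[d], rel=1e-12)


def test_rho_matrix_matches_scalar_path():
    recs = [SequenceRecord(f"s{i}", residues=s) for i, s in enumerate(["ACGTACGT", "CGCG", "AAAA"])]
    mat = rho_matrix(recs)
    for i, rec in enumerate(recs):
        prof = dra_profile(rec)
        for k, d in enumerate(DINUCLEOTIDES):
            if prof.rho[d] is None:
                assert math.isnan(mat[i, k])
            else:
                assert mat[i, k] == pytest.approx(prof.rho[d], rel=1e-12)


def test_baseline_json_round_trip(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">chr1\nACGTACGTGGCCNNACGT\n")
    bl = genome_baseline([fa], build_label="toy-build")
    path = tmp_path / "baseline.json"
    save_baseline(bl, path)
    loaded = load_baseline(path)
    assert loaded.build_label == "toy-build"
    assert loaded.profile.rho == bl.profile.rho
    assert loaded.profile.nucleotide_counts == bl.profile.nucleotide_counts


def test_ts_matrix_against_transcript_signature(genome_baseline_analytic):
    recs = [SequenceRecord("a", residues="ACGTACGTCCGG" * 20)]
    mat = ts_matrix(recs, genome_baseline_analytic)
    ts = transcript_signature(recs[0], genome_baseline_analytic)
    for k, d in enumerate(DINUCLEOTIDES):
        assert mat[0, k] == pytest.approx(ts.ts[d], rel=1e-12)
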