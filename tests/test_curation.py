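"""Tests for RefSeq header parsing and curation filters."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dinusig import (
    SequenceRecord,
    bona_fide_prefilter,
    filter_lncrna,
    filter_mrna,
    load_curated_lncrna_table,
    longest_isoform,
    parse_header,
)


def rec(accession, desc, seq="ACGTACGT"):
    return SequenceRecord(id=accession, description=desc, residues=seq)


@pytest.mark.parametrize(
    "header,prefix,flags,variant",
    [
        ("NM_000518.4 Homo sapiens hemoglobin subunit beta (HBB), mRNA", "NM_", set(), None),
        ("XM_012345.1 PREDICTED: ... transcript variant 2, mRNA", "XM_", {"predicted"}, 2),
        ("NR_026690.1 Homo sapiens ... non-coding RNA", "NR_", set(), None),
        ("ENST0001 some other dialect", "other", set(), None),
        ("NM_1.1 partial cds RIKEN clone", "NM_", {"partial", "riken"}, None),
    ],
)
def test_parse_header(header, prefix, flags, variant):
    ann = parse_header(header)
    assert ann.accession_prefix == prefix
    assert set(ann.flags) == flags
    assert ann.variant_number == variant


def _toy_corpus():
    return [
        rec("NM_000001.1", "plain mRNA"),
        rec("NM_000002.1", "something, transcript variant 1, mRNA"),
        rec("NM_000003.1", "something, transcript variant 2, mRNA"),
        rec("NR_000004.1", "plain non-coding RNA"),
        rec("NM_000005.1", "partial cds"),
    ]


def test_filter_mrna_rule_table():
    kept, report = filter_mrna(_toy_corpus())
    assert [r.id for r in kept] == ["NM_000001.1", "NM_000002.1"]
    assert report.n_input == 5 and report.n_kept == 2
    assert report.n_dropped_by_rule == {"variant": 1, "prefix": 1, "partial": 1}


def test_filter_mrna_all_nr_attributed_to_prefix():
    records = [rec(f"NR_{i:06d}.1", "non-coding RNA") for i in range(4)]
    kept, report = filter_mrna(records)
    assert kept == []
    assert report.n_dropped_by_rule == {"prefix": 4}


def test_filters_idempotent_and_disjoint():
    corpus = _toy_corpus()
    mrna, _ = filter_mrna(corpus)
    again, _ = filter_mrna(mrna)
    assert [r.id for r in again] == [r.id for r in mrna]
    lnc, _ = filter_lncrna(corpus)
    cross, _ = filter_mrna(lnc)
    assert cross == []


def test_filter_lncrna_counts():
    corpus = [rec(f"NR_{i}.1", "x") for i in range(4)] + [rec(f"NM_{i}.1", "x") for i in range(6)]
    kept, report = filter_lncrna(corpus)
    assert len(kept) == 4
    assert report.n_kept == 4 and report.n_dropped_by_rule["prefix"] == 6
    empty_kept, empty_report = filter_lncrna([])
    assert empty_kept == [] and empty_report.n_input == 0


_FLAG_WORDS = ["", "partial", "PREDICTED:", "RIKEN", "transcript variant 1", "transcript variant 3"]
_PREFIXES = ["NM_", "NR_", "XM_", "XR_", "ZZ"]
header_strategy = st.builds(
    lambda p, i, w: rec(f"{p}{i:06d}.1", f"Homo sapiens gene, {w} mRNA"),
    st.sampled_from(_PREFIXES),
    st.integers(0, 999999),
    st.sampled_from(_FLAG_WORDS),
)


@given(st.lists(header_strategy, max_size=60))
def test_report_conservation_on_random_corpora(records):
    """n_input decomposes exactly into kept + per-rule drops."""
    for filt in (filter_mrna, filter_lncrna):
        kept, report = filt(records)
        assert report.n_input == report.n_kept + sum(report.n_dropped_by_rule.values())
        assert report.n_kept == len(kept)
        # order-stable: reversing the input keeps the same set
        kept_rev, _ = filt(records[::-1])
        assert {r.id for r in kept_rev} == {r.id for r in kept}


def test_bona_fide_prefilter_keyword_rules():
    corpus = [
        rec("NR_100001.1", "long non-coding RNA candidate A"),
        rec("NR_100002.1", "snoRNA host gene B"),
        rec("NR_100003.1", "ribosomal pseudogene C"),
        rec("NR_100004.1", "antisense RNA D"),
        rec("NM_100005.1", "plain mRNA E"),
    ]
    kept, report = bona_fide_prefilter(corpus)
    assert [r.id for r in kept] == ["NR_100001.1"]
    assert sum(report.n_dropped_by_rule.values()) == 4
    # empty keyword config leaves the keyword step inert
    kept2, _ = bona_fide_prefilter(corpus, class_keywords=())
    assert [r.id for r in kept2] == ["NR_100001.1", "NR_100002.1", "NR_100003.1", "NR_100004.1"]


def test_bona_fide_confirmation_against_packaged_table():
    table = load_curated_lncrna_table()
    assert len(table) == 52
    assert table["refseq_accession"].is_unique
    records = [rec(acc, "curated long non-coding RNA") for acc in table["refseq_accession"]]
    records.append(rec("NR_999999.1", "uncurated long non-coding RNA"))
    kept, report = bona_fide_prefilter(records, confirm=True, whitelist=table)
    assert len(kept) == 52
    assert report.n_dropped_by_rule == {"not_confirmed": 1}


def test_bona_fide_confirmation_requires_whitelist():
    with pytest.raises(ValueError):
        bona_fide_prefilter([rec("NR_1.1", "x")], confirm=True)


def test_longest_isoform_rules():
    records = [
        rec("NR_2.1", "geneA isoform short", "A" * 900),
        rec("NR_1.1", "geneA isoform long", "A" * 1500),
        rec("NR_4.1", "geneB tie", "A" * 1000),
        rec("NR_3.1", "geneB tie", "A" * 1000),
        rec("NR_5.1", "geneC singleton", "A" * 100),
    ]
    groups = {"NR_1.1": "A", "NR_2.1": "A", "NR_3.1": "B", "NR_4.1": "B", "NR_5.1": "C"}
    kept = longest_isoform(records, groups)
    assert [r.id for r in kept] == ["NR_1.1", "NR_3.1", "NR_5.1"]
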