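"""RefSeq transcript curation: keyword/accession filters and the
automatable part of the "bona fide" lncRNA workflow.

The mRNA dataset is built from RefSeq ``*.rna.fna`` headers by discarding
everything that is not an unambiguous curated protein-coding transcript:
non-NM_ accessions, "partial", "predicted" (incl. "PREDICTED:"), "RIKEN",
and transcript variants numbered above 1 (variant 1 and un-numbered
records are kept, so each gene contributes at most its reference isoform).
The lncRNA dataset is simply the NR_ accession class.

The bona-fide prefilter additionally removes infrastructural RNAs, small
RNAs, pseudogene transcripts and antisense records by keyword, and can
confirm candidates against a curated whitelist table; the literature-
confirmation step itself is inherently manual and is represented by that
table, not automated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .records import SequenceRecord

__all__ = [
    "HeaderAnnotation",
    "FilterReport",
    "parse_header",
    "filter_mrna",
    "filter_lncrna",
    "bona_fide_prefilter",
    "longest_isoform",
    "load_curated_lncrna_table",
    "DEFAULT_CONTAMINANT_KEYWORDS",
]

KNOWN_PREFIXES = ("NM_", "NR_", "XM_", "XR_")

# Reconstructed contaminant classes: infrastructural RNAs, small RNAs,
# pseudogenes, antisense records.
DEFAULT_CONTAMINANT_KEYWORDS: tuple[str, ...] = (
    "tRNA",
    "rRNA",
    "snoRNA",
    "snRNA",
    "miRNA",
    "microRNA",
    "piRNA",
    "pseudogene",
    "antisense",
)

_VARIANT_RE = re.compile(r"transcript variant (\d+)", re.IGNORECASE)


@dataclass(frozen=True)
class HeaderAnnotation:
    """Parsed RefSeq-style FASTA header."""

    accession_prefix: str  # one of NM_, NR_, XM_, XR_, other
    variant_number: int | None
    flags: frozenset[str]  # subset of {partial, predicted, riken}
    organism_tag: str


@dataclass
class FilterReport:
    """Accounting for a filter pass: n_input = n_kept + sum(dropped)."""

    n_input: int
    n_kept: int
    n_dropped_by_rule: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        assert self.n_input == self.n_kept + sum(self.n_dropped_by_rule.values())


def parse_header(raw_header: str) -> HeaderAnnotation:
    """Parse accession prefix, flags and transcript-variant number.

    The prefix is taken from the first whitespace token; flags are matched
    case-insensitively as substrings of the whole header; the variant
    number is captured from the literal pattern "transcript variant <n>".
    Unrecognised headers get prefix "other" and no flags.
    """
    header = raw_header.lstrip(">").strip()
    first = header.split(None, 1)
    accession = first[0] if first else ""
    rest = first[1] if len(first) > 1 else ""
    prefix = next((p for p in KNOWN_PREFIXES if accession.startswith(p)), "other")
    lower = header.lower()
    flags = frozenset(f for f in ("partial", "predicted", "riken") if f in lower)
    m = _VARIANT_RE.search(header)
    variant = int(m.group(1)) if m else None
    return HeaderAnnotation(
        accession_prefix=prefix, variant_number=variant, flags=flags, organism_tag=rest
    )


def _first_matching_rule_mrna(ann: HeaderAnnotation) -> str | None:
    """Fixed rule order: prefix -> partial -> predicted -> riken -> variant."""
    if ann.accession_prefix != "NM_":
        return "prefix"
    if "partial" in ann.flags:
        return "partial"
    if "predicted" in ann.flags:
        return "predicted"
    if "riken" in ann.flags:
        return "riken"
    if ann.variant_number is not None and ann.variant_number > 1:
        return "variant"
    return None


def filter_mrna(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], FilterReport]:
    """Keep curated protein-coding transcripts (NM_, no contaminant flag,
    variant 1 or un-numbered); drops are attributed to the first matching
    rule."""
    kept: list[SequenceRecord] = []
    dropped: dict[str, int] = {}
    for rec in records:
        rule = _first_matching_rule_mrna(parse_header(rec.header))
        if rule is None:
            kept.append(rec)
        else:
            dropped[rule] = dropped.get(rule, 0) + 1
    report = FilterReport(n_input=len(records), n_kept=len(kept), n_dropped_by_rule=dropped)
    report.check()
    return kept, report


def filter_lncrna(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], FilterReport]:
    """Keep transcripts with the NR_ RefSeq accession prefix."""
    kept: list[SequenceRecord] = []
    dropped: dict[str, int] = {}
    for rec in records:
        if parse_header(rec.header).accession_prefix == "NR_":
            kept.append(rec)
        else:
            dropped["prefix"] = dropped.get("prefix", 0) + 1
    report = FilterReport(n_input=len(records), n_kept=len(kept), n_dropped_by_rule=dropped)
    report.check()
    return kept, report


def _strip_version(accession: str) -> str:
    return accession.split(".", 1)[0]


def bona_fide_prefilter(
    records: Sequence[SequenceRecord],
    class_keywords: Iterable[str] | None = DEFAULT_CONTAMINANT_KEYWORDS,
    annotation: pd.DataFrame | None = None,
    confirm: bool = False,
    whitelist: pd.DataFrame | None = None,
) -> tuple[list[SequenceRecord], FilterReport]:
    """Automatable steps of the bona-fide lncRNA workflow.

    Step 1 drops records whose description (or annotated class) matches a
    contaminant keyword.  Step 2 keeps RefSeq NR_ entries and, when an
    annotation table with a ``refseq_status`` column is supplied, requires
    the "validated" status.  Step 3 (literature confirmation) is not
    automated: with ``confirm=True`` records are checked against a
    user-supplied whitelist table carrying a ``refseq_accession`` column
    (version-insensitive match).

    An empty ``class_keywords`` leaves step 1 as a no-op.
    """
    if confirm and whitelist is None:
        raise ValueError("confirmation requested but no whitelist table supplied")
    keywords = [k.lower() for k in (class_keywords or [])]
    classes: Mapping[str, str] = {}
    statuses: Mapping[str, str] = {}
    if annotation is not None:
        acc = annotation["accession"].map(_strip_version)
        if "class" in annotation.columns:
            classes = dict(zip(acc, annotation["class"].astype(str)))
        if "refseq_status" in annotation.columns:
            statuses = dict(zip(acc, annotation["refseq_status"].astype(str)))
    allowed: set[str] | None = None
    if confirm and whitelist is not None:
        allowed = set(whitelist["refseq_accession"].map(_strip_version))

    kept: list[SequenceRecord] = []
    dropped: dict[str, int] = {}

    def drop(rule: str) -> None:
        dropped[rule] = dropped.get(rule, 0) + 1

    for rec in records:
        ann = parse_header(rec.header)
        accession = _strip_version(rec.id)
        text = rec.header.lower()
        cls = classes.get(accession, "").lower()
        hit = next((k for k in keywords if k in text or k in cls), None)
        if hit is not None:
            drop(f"contaminant:{hit}")
            continue
        if ann.accession_prefix != "NR_":
            drop("prefix")
            continue
        if statuses and statuses.get(accession, "").lower() != "validated":
            drop("refseq_status")
            continue
        if allowed is not None and accession not in allowed:
            drop("not_confirmed")
            continue
        kept.append(rec)
    report = FilterReport(n_input=len(records), n_kept=len(kept), n_dropped_by_rule=dropped)
    report.check()
    return kept, report


def longest_isoform(
    records: Sequence[SequenceRecord],
    group_key: Callable[[SequenceRecord], str] | Mapping[str, str],
) -> list[SequenceRecord]:
    """Keep exactly one record per gene/alias group: the longest isoform.

    Length ties are broken by the lexicographically smallest accession.
    ``group_key`` maps a record (or its accession) to its group label;
    singleton groups pass through unchanged.
    """
    if isinstance(group_key, Mapping):
        mapping = {k: v for k, v in group_key.items()}

        def key(rec: SequenceRecord) -> str:
            return mapping.get(rec.id, mapping.get(_strip_version(rec.id), rec.id))

    else:
        key = group_key
    best: dict[str, SequenceRecord] = {}
    order: list[str] = []
    for rec in records:
        g = key(rec)
        cur = best.get(g)
        if cur is None:
            best[g] = rec
            order.append(g)
        elif rec.length > cur.length or (rec.length == cur.length and rec.id < cur.id):
            best[g] = rec
    return [best[g] for g in order]


def load_curated_lncrna_table() -> pd.DataFrame:
    """Packaged curated-lncRNA whitelist table (52 entries).

    This is a synthetic stand-in assembled to the published schema
    (name/alias, RefSeq accession, chromosome, exon count, transcript
    length, longest ORF, disease link); only the WBSCR26/NR_026690 entry
    reflects a real transcript, the rest carry placeholder accessions for
    pipeline testing.  Replace with a real curated table for production
    analyses.
    """
    with resources.files("dinusig.data").joinpath("curated_lncrna_synthetic.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
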