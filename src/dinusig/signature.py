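"""Dinucleotide relative abundance (DRA) and the transcript signature (TS).

The dinucleotide relative abundance of a dinucleotide XY in a sequence is

    rho*_XY = f*_XY / (f_X * f_Y)

where f_X is the frequency of nucleotide X and f*_XY the frequency of the
overlapping dinucleotide XY.  rho* measures how abundant a dinucleotide is
relative to the expectation under independence of its component bases;
rho* - 1 is the dinucleotide bias.  The transcript signature normalises a
transcript's rho* to a whole-genome baseline:

    TS_XY = rho*_XY(transcript) / rho*_XY(genome)

so TS = 1 means genome-like.  The CG component of TS is the headline
statistic: mRNAs carry a markedly higher CG signature than long
non-coding RNAs, because CpG-island-driven CG enrichment of coding
transcripts stands out against the methylation-driven CG suppression of
the genome at large.

Conventions (fixed across the package):

* frequencies are computed on the given strand only, no reverse-complement
  symmetrisation — transcripts are directional;
* windows are overlapping, linear (no circular wrap-around), 1-based;
* any window containing a non-ACGT symbol is skipped and excluded from
  both the numerator and the denominator totals;
* zero-denominator rho* or TS entries are *undefined* (``None`` in maps,
  ``NaN`` in matrices, ``NA`` on disk), never silently 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import SequenceRecord, iter_fasta

__all__ = [
    "NUCLEOTIDES",
    "DINUCLEOTIDES",
    "DRAProfile",
    "GenomeBaseline",
    "TranscriptSignature",
    "count_kmers",
    "dra_profile",
    "genome_baseline",
    "transcript_signature",
    "cg_enrichment_percent",
    "rho_matrix",
    "ts_matrix",
    "score_table",
    "save_baseline",
    "load_baseline",
]

logger = logging.getLogger(__name__)

NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "T")
DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)

# 256-entry code lookup: A,C,G,T -> 0..3, everything else -> 4 (ambiguous).
_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _LUT[_b] = _i
_LUT[ord("U")] = 3
_LUT[ord("u")] = 3


class EmptyProfileError(ValueError):
    """Raised when a profile is requested over zero countable nucleotides."""


def encode(residues: str) -> np.ndarray:
    """Residue string -> int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _LUT[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def _count_codes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (nucleotide counts[4], dinucleotide counts[16]) skipping
    windows that contain an ambiguous base."""
    valid = codes < 4
    nuc = np.bincount(codes[valid], minlength=5)[:4].astype(np.int64)
    if codes.size >= 2:
        a = codes[:-1]
        b = codes[1:]
        ok = (a < 4) & (b < 4)
        di = np.bincount(
            (a[ok].astype(np.int64) * 4 + b[ok]), minlength=16
        )[:16]
    else:
        di = np.zeros(16, dtype=np.int64)
    return nuc, di


def count_kmers(seq: SequenceRecord | str, k: int) -> dict[str, int]:
    """Count overlapping k-mers (k = 1 or 2) over unambiguous windows.

    Windows containing any non-ACGT symbol are dropped; an empty sequence
    yields an all-zero map.
    """
    if k not in (1, 2):
        raise ValueError(f"k must be 1 or 2, got {k}")
    residues = seq.residues if isinstance(seq, SequenceRecord) else SequenceRecord("x", residues=str(seq)).residues
    codes = encode(residues)
    nuc, di = _count_codes(codes)
    if k == 1:
        return {b: int(c) for b, c in zip(NUCLEOTIDES, nuc)}
    return {d: int(c) for d, c in zip(DINUCLEOTIDES, di)}


@dataclass
class DRAProfile:
    """Nucleotide/dinucleotide frequencies and the 16 rho* values.

    Undefined rho* entries (zero base-frequency denominator, or no
    countable dinucleotide window) are stored as ``None``.
    """

    nucleotide_counts: dict[str, int]
    dinucleotide_counts: dict[str, int]
    nucleotide_freqs: dict[str, float]
    dinucleotide_freqs: dict[str, float]
    rho: dict[str, float | None]
    n_nucleotides: int
    n_dinucleotides: int

    @classmethod
    def from_counts(cls, nuc: np.ndarray, di: np.ndarray) -> "DRAProfile":
        n_nuc = int(nuc.sum())
        n_di = int(di.sum())
        if n_nuc == 0:
            raise EmptyProfileError("zero countable nucleotides")
        f = nuc / n_nuc
        fstar = di / n_di if n_di > 0 else np.zeros(16)
        rho: dict[str, float | None] = {}
        for idx, d in enumerate(DINUCLEOTIDES):
            denom = f[NUCLEOTIDES.index(d[0])] * f[NUCLEOTIDES.index(d[1])]
            if n_di > 0 and denom > 0:
                rho[d] = float(fstar[idx] / denom)
            else:
                rho[d] = None
        return cls(
            nucleotide_counts={b: int(c) for b, c in zip(NUCLEOTIDES, nuc)},
            dinucleotide_counts={d: int(c) for d, c in zip(DINUCLEOTIDES, di)},
            nucleotide_freqs={b: float(x) for b, x in zip(NUCLEOTIDES, f)},
            dinucleotide_freqs={d: float(x) for d, x in zip(DINUCLEOTIDES, fstar)},
            rho=rho,
            n_nucleotides=n_nuc,
            n_dinucleotides=n_di,
        )

    @classmethod
    def from_frequencies(
        cls, nucleotide_freqs: Mapping[str, float], dinucleotide_freqs: Mapping[str, float]
    ) -> "DRAProfile":
        """Analytic profile from exact expected frequencies (counts zero).

        Used for model-derived baselines where frequencies are known in
        closed form rather than estimated from a finite sequence.
        """
        rho: dict[str, float | None] = {}
        for d in DINUCLEOTIDES:
            denom = nucleotide_freqs[d[0]] * nucleotide_freqs[d[1]]
            rho[d] = float(dinucleotide_freqs[d] / denom) if denom > 0 else None
        return cls(
            nucleotide_counts={b: 0 for b in NUCLEOTIDES},
            dinucleotide_counts={d: 0 for d in DINUCLEOTIDES},
            nucleotide_freqs={b: float(nucleotide_freqs[b]) for b in NUCLEOTIDES},
            dinucleotide_freqs={d: float(dinucleotide_freqs[d]) for d in DINUCLEOTIDES},
            rho=rho,
            n_nucleotides=0,
            n_dinucleotides=0,
        )


@dataclass
class GenomeBaseline:
    """Pooled-genome DRA profile used as the TS normalisation denominator."""

    profile: DRAProfile
    build_label: str = ""


@dataclass
class TranscriptSignature:
    """The 16 TS ratios (transcript rho* / genome rho*) for one transcript."""

    ts: dict[str, float | None]
    source_id: str


def _pool_counts(seqs: Iterable[SequenceRecord | str]) -> tuple[np.ndarray, np.ndarray]:
    nuc = np.zeros(4, dtype=np.int64)
    di = np.zeros(16, dtype=np.int64)
    n_seen = 0
    for s in seqs:
        residues = s.residues if isinstance(s, SequenceRecord) else SequenceRecord("x", residues=str(s)).residues
        a, b = _count_codes(encode(residues))
        nuc += a
        di += b
        n_seen += 1
    if n_seen == 0:
        raise EmptyProfileError("no sequences supplied")
    return nuc, di


def dra_profile(seq_or_pool: SequenceRecord | str | Iterable[SequenceRecord | str]) -> DRAProfile:
    """DRA profile of one sequence, or of a pool.

    Pooling sums raw counts across sequences before computing frequencies:
    each sequence contributes its own L-1 dinucleotide windows and no
    inter-sequence junction windows.
    """
    if isinstance(seq_or_pool, (SequenceRecord, str)):
        seq_or_pool = [seq_or_pool]
    nuc, di = _pool_counts(seq_or_pool)
    return DRAProfile.from_counts(nuc, di)


def genome_baseline(
    chromosome_fastas: Sequence[str | Path], build_label: str = ""
) -> GenomeBaseline:
    """Pooled DRA profile over all chromosome sequences of the given FASTAs.

    One strand only, no reverse-complement symmetrisation; N-spanning
    windows skipped.  Pooled counts are invariant to file order.
    """
    nuc = np.zeros(4, dtype=np.int64)
    di = np.zeros(16, dtype=np.int64)
    n_seqs = 0
    for path in chromosome_fastas:
        for rec in iter_fasta(path):
            a, b = _count_codes(encode(rec.residues))
            nuc += a
            di += b
            n_seqs += 1
    if n_seqs == 0:
        raise EmptyProfileError("no parsable chromosome sequence")
    return GenomeBaseline(profile=DRAProfile.from_counts(nuc, di), build_label=build_label)


def transcript_signature(
    seq: SequenceRecord | str, baseline: GenomeBaseline
) -> TranscriptSignature:
    """TS_XY = rho*_XY(transcript) / rho*_XY(genome).

    Entries where either rho* is undefined, or the genome rho* is zero,
    propagate as undefined — never as 0.
    """
    prof = dra_profile(seq)
    ts: dict[str, float | None] = {}
    for d in DINUCLEOTIDES:
        rt = prof.rho[d]
        rg = baseline.profile.rho[d]
        ts[d] = float(rt / rg) if (rt is not None and rg is not None and rg > 0) else None
    source = seq.id if isinstance(seq, SequenceRecord) else ""
    return TranscriptSignature(ts=ts, source_id=source)


def cg_enrichment_percent(ts: TranscriptSignature | float | None) -> float | None:
    """CG enrichment over the genome, in percent: (TS_CG - 1) x 100.

    0% means genome-like; negative values mean under-representation.
    Accepts a TranscriptSignature or a scalar TS value (e.g. a dataset
    mean); undefined input yields ``None``.
    """
    value = ts.ts["CG"] if isinstance(ts, TranscriptSignature) else ts
    if value is None:
        return None
    return (float(value) - 1.0) * 100.0


# --- vectorised helpers -------------------------------------------------

def rho_matrix(records: Sequence[SequenceRecord | str]) -> np.ndarray:
    """Per-transcript rho* values, shape (n, 16), NaN where undefined.

    Column order follows ``DINUCLEOTIDES``.
    """
    out = np.full((len(records), 16), np.nan)
    for i, rec in enumerate(records):
        residues = rec.residues if isinstance(rec, SequenceRecord) else str(rec)
        nuc, di = _count_codes(encode(residues))
        n_nuc = nuc.sum()
        n_di = di.sum()
        if n_nuc == 0 or n_di == 0:
            continue
        f = nuc / n_nuc
        fstar = di / n_di
        denom = np.outer(f, f).ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            row = fstar / denom
        row[denom == 0] = np.nan
        out[i] = row
    return out


def ts_matrix(records: Sequence[SequenceRecord | str], baseline: GenomeBaseline) -> np.ndarray:
    """Per-transcript TS values, shape (n, 16), NaN where undefined."""
    g = np.array(
        [np.nan if baseline.profile.rho[d] in (None, 0) else baseline.profile.rho[d] for d in DINUCLEOTIDES]
    )
    return rho_matrix(records) / g


def score_table(records: Sequence[SequenceRecord], baseline: GenomeBaseline | None = None) -> pd.DataFrame:
    """Per-transcript score table: id, length, base freqs, rho*, and TS.

    TS columns are included only when a baseline is given.  Undefined
    entries are NaN in memory and serialise as ``NA``.
    """
    rows = []
    for rec in records:
        prof = dra_profile(rec)
        row: dict[str, object] = {"id": rec.id, "length": rec.length}
        for b in NUCLEOTIDES:
            row[f"f_{b}"] = prof.nucleotide_freqs[b]
        for d in DINUCLEOTIDES:
            r = prof.rho[d]
            row[f"rho_{d}"] = np.nan if r is None else r
        if baseline is not None:
            ts = transcript_signature(rec, baseline)
            for d in DINUCLEOTIDES:
                v = ts.ts[d]
                row[f"ts_{d}"] = np.nan if v is None else v
        rows.append(row)
    return pd.DataFrame(rows)


def save_baseline(baseline: GenomeBaseline, path: str | Path) -> None:
    """Serialise a baseline as JSON (counts + frequencies + rho + label)
    so the genome never has to be re-read."""
    p = baseline.profile
    payload = {
        "build_label": baseline.build_label,
        "n_nucleotides": p.n_nucleotides,
        "n_dinucleotides": p.n_dinucleotides,
        "nucleotide_counts": p.nucleotide_counts,
        "dinucleotide_counts": p.dinucleotide_counts,
        "nucleotide_freqs": p.nucleotide_freqs,
        "dinucleotide_freqs": p.dinucleotide_freqs,
        "rho": p.rho,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_baseline(path: str | Path) -> GenomeBaseline:
    payload = json.loads(Path(path).read_text())
    profile = DRAProfile(
        nucleotide_counts=payload["nucleotide_counts"],
        dinucleotide_counts=payload["dinucleotide_counts"],
        nucleotide_freqs=payload["nucleotide_freqs"],
        dinucleotide_freqs=payload["dinucleotide_freqs"],
        rho={d: payload["rho"][d] for d in DINUCLEOTIDES},
        n_nucleotides=payload["n_nucleotides"],
        n_dinucleotides=payload["n_dinucleotides"],
    )
    return GenomeBaseline(profile=profile, build_label=payload.get("build_label", ""))
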