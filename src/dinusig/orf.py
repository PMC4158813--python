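"""Longest-ORF detection, stop-codon statistics, and the uniform random
sequence null model.

An open reading frame runs from an ATG through the last sense codon
before an in-frame stop (TAA/TAG/TGA); its nucleotide length excludes
the stop codon, so an 80-codon ORF is 240 nt and 80 aa.  Transcripts are
directional: only the three sense-strand frames are scanned.  ORFs that
reach the end of the sequence without an in-frame stop are not counted
by default (truncated 3' ends cannot be distinguished from genuinely
open-ended spans); pass ``include_open_ended=True`` to count them.

Stop-codon statistics follow the codon-usage-table convention: frame-1
non-overlapping codons, trailing 1-2 bases ignored.  Under the uniform
i.i.d. null, 3 of the 64 codons are stops, i.e. 4.6875% of codons —
the benchmark against which the stop-codon content of non-coding
transcripts is judged "random-like".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import SequenceRecord
from .signature import encode

__all__ = [
    "ORFResult",
    "StopCodonStats",
    "longest_orf",
    "stop_codon_stats",
    "random_sequences",
    "STOP_CODONS",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
# codon codes under A=0,C=1,G=2,T=3: 16*a + 4*b + c
_STOP_CODES = frozenset((48, 50, 56))  # TAA, TAG, TGA
_ATG_CODE = 16 * 0 + 4 * 3 + 2  # == 14


@dataclass(frozen=True)
class ORFResult:
    """Longest ORF of a transcript.

    ``start`` is the 1-based position of the A of the ATG; ``frame`` in
    {1,2,3}; ``nt_length`` counts codons from the ATG through the last
    sense codon (stop excluded) and is divisible by 3.
    """

    start: int
    frame: int
    nt_length: int

    @property
    def aa_length(self) -> int:
        return self.nt_length // 3


@dataclass(frozen=True)
class StopCodonStats:
    """Frame-1 stop-codon content of a transcript."""

    n_codons: int
    n_stops: int
    length: int

    @property
    def percent_stops(self) -> float:
        return 100.0 * self.n_stops / self.n_codons if self.n_codons else 0.0

    @property
    def per_kb(self) -> float:
        """Stops per 1,000 bases (the figure-axis variant of the same count)."""
        return 1000.0 * self.n_stops / self.length if self.length else 0.0


def _codon_codes(codes: np.ndarray, frame0: int) -> np.ndarray:
    """Non-overlapping codon codes for 0-based frame offset; codons
    containing an ambiguous base get code -1."""
    usable = (codes.size - frame0) // 3
    if usable <= 0:
        return np.zeros(0, dtype=np.int64)
    c = codes[frame0 : frame0 + 3 * usable].reshape(usable, 3).astype(np.int64)
    out = 16 * c[:, 0] + 4 * c[:, 1] + c[:, 2]
    out[(c >= 4).any(axis=1)] = -1
    return out


def longest_orf(
    seq: SequenceRecord | str, include_open_ended: bool = False
) -> ORFResult | None:
    """Longest ATG..stop span over the three sense frames.

    Ties are broken by smallest start position, then smallest frame.
    Returns ``None`` when no ORF exists.  Ambiguous-base codons are
    treated as unknown sense codons (neither start nor stop).
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else SequenceRecord("x", residues=str(seq)).residues
    codes = encode(residues)
    best: ORFResult | None = None

    def consider(start0: int, frame0: int, n_sense_codons: int) -> None:
        nonlocal best
        if n_sense_codons <= 0:
            return
        cand = ORFResult(start=start0 + 1, frame=frame0 + 1, nt_length=3 * n_sense_codons)
        if (
            best is None
            or cand.nt_length > best.nt_length
            or (cand.nt_length == best.nt_length and cand.start < best.start)
            or (
                cand.nt_length == best.nt_length
                and cand.start == best.start
                and cand.frame < best.frame
            )
        ):
            best = cand

    for frame0 in range(3):
        codons = _codon_codes(codes, frame0)
        open_idx: int | None = None  # earliest ATG since last stop
        for i, code in enumerate(codons):
            if code in _STOP_CODES:
                if open_idx is not None:
                    consider(frame0 + 3 * open_idx, frame0, i - open_idx)
                    open_idx = None
            elif code == _ATG_CODE and open_idx is None:
                open_idx = i
        if include_open_ended and open_idx is not None:
            consider(frame0 + 3 * open_idx, frame0, len(codons) - open_idx)
    return best


def stop_codon_stats(seq: SequenceRecord | str) -> StopCodonStats:
    """Frame-1 stop-codon count, percentage, and per-kilobase rate.

    Codons containing ambiguous bases are excluded from both counts.
    Raises ``ValueError`` for sequences shorter than one codon.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else SequenceRecord("x", residues=str(seq)).residues
    if len(residues) < 3:
        raise ValueError("sequence shorter than one codon")
    codons = _codon_codes(encode(residues), 0)
    valid = codons >= 0
    n_codons = int(valid.sum())
    n_stops = int(np.isin(codons[valid], list(_STOP_CODES)).sum())
    return StopCodonStats(n_codons=n_codons, n_stops=n_stops, length=len(residues))


def stop_codon_stats_all_frames(seq: SequenceRecord | str) -> float:
    """Mean stop-codon percentage over the three sense frames."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else str(seq)
    codes = encode(SequenceRecord("x", residues=residues).residues)
    pcts = []
    for frame0 in range(3):
        codons = _codon_codes(codes, frame0)
        valid = codons >= 0
        n = int(valid.sum())
        if n:
            pcts.append(100.0 * np.isin(codons[valid], list(_STOP_CODES)).sum() / n)
    if not pcts:
        raise ValueError("no complete codon in any frame")
    return float(np.mean(pcts))


def random_sequences(
    n: int,
    lengths: int | Sequence[int],
    seed: int,
    prefix: str = "RND",
) -> list[SequenceRecord]:
    """i.i.d. uniform ACGT sequences; deterministic for a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if np.isscalar(lengths):
        lens = [int(lengths)] * n
    else:
        lens = [int(x) for x in lengths]
        if len(lens) != n:
            raise ValueError("lengths must match n")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = []
    for i, L in enumerate(lens):
        codes = rng.integers(0, 4, size=L)
        residues = bases[codes].tobytes().decode("ascii")
        out.append(
            SequenceRecord(id=f"{prefix}_{i:06d}", description="uniform random", residues=residues)
        )
    return out
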