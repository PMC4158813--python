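"""Synthetic transcript populations with controlled dinucleotide
relative abundance.

Sequences are drawn from a first-order Markov chain whose transition
matrix encodes a target composition: given base frequencies f and target
abundances rho, the implied dinucleotide matrix is p_XY = rho_XY f_X f_Y
and the chain's transitions are P(Y|X) = p_XY / sum_Y' p_XY'.  The first
base is drawn from the chain's stationary distribution.  Because row
renormalisation (and the stationary distribution differing from f) can
shift the chain's long-run composition away from the requested targets,
the module reports *realized* abundances computed in closed form from
the chain, and provides a fixed-point calibration that adjusts the
requested rho until the realized values hit a desired target exactly.

The shipped presets emulate three transcript populations against a
synthetic CG-suppressed genome (rho*_CG = 0.25, rho*_TA = 0.78, GC 41%,
i.e. human-like bulk values):

* ``mrna``      — TS_CG 2.29, GC 52% (CpG-island-rich coding transcripts)
* ``pseudo``    — TS_CG 2.12, GC 46% (intermediate, decayed gene copies)
* ``lncrna``    — TS_CG 1.96, GC 44%

with TS_TA = 0.80 for all three, and a right-skewed log-normal length
model (median 1.5 kb, mean 3.1 kb, minimum 200 nt).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import SequenceRecord, write_fasta
from .signature import (
    DINUCLEOTIDES,
    NUCLEOTIDES,
    DRAProfile,
    GenomeBaseline,
)

__all__ = [
    "FixedLength",
    "LogNormalLength",
    "GeneratorSpec",
    "build_transition_matrix",
    "stationary_distribution",
    "realized_rho",
    "analytic_profile",
    "calibrate_target_rho",
    "generate_population",
    "preset_spec",
    "genome_spec",
    "synthetic_genome",
    "analytic_genome_baseline",
    "write_population",
    "PRESET_TS",
]

_BASES_U8 = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixedLength:
    length: int

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(n, int(self.length), dtype=np.int64)


@dataclass(frozen=True)
class LogNormalLength:
    """Log-normal transcript lengths parameterised by median and mean.

    sigma = sqrt(2 ln(mean/median)), mu = ln(median); draws below
    ``min_length`` are redrawn (long non-coding RNAs are >200 nt by
    definition, and sub-codon transcripts are not meaningful).
    """

    median: float = 1500.0
    mean: float = 3100.0
    min_length: int = 200

    def _params(self) -> tuple[float, float]:
        """(mu, sigma) of the underlying log-normal such that the
        *truncated* distribution has the requested median and mean."""
        from scipy import optimize, stats as sps

        if self.mean <= self.median:
            raise ValueError("log-normal requires mean > median")
        ln_a = np.log(self.min_length)
        ln_m = np.log(self.median)

        def equations(x):
            mu, sigma = x
            z_a = (ln_a - mu) / sigma
            tail = sps.norm.sf(z_a)
            med = sps.norm.cdf((ln_m - mu) / sigma) - 0.5 * (1 + sps.norm.cdf(z_a))
            mean = np.exp(mu + sigma**2 / 2) * sps.norm.sf(z_a - sigma) / tail - self.mean
            return [med, mean / self.mean]

        sigma0 = float(np.sqrt(2.0 * np.log(self.mean / self.median)))
        sol = optimize.fsolve(equations, [ln_m, sigma0], full_output=False)
        return float(sol[0]), float(sol[1])

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        mu, sigma = self._params()
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = rng.lognormal(mu, sigma, size=n - filled).astype(np.int64)
            ok = draw[draw >= self.min_length]
            out[filled : filled + ok.size] = ok
            filled += ok.size
        return out


@dataclass
class GeneratorSpec:
    """Population recipe: base frequencies, target rho*, length model."""

    base_freqs: dict[str, float]
    target_rho: dict[str, float] = field(default_factory=dict)
    length_model: FixedLength | LogNormalLength = field(
        default_factory=lambda: LogNormalLength()
    )
    n: int = 100
    seed: int = 0
    label: str = "custom"

    def rho_vector(self) -> np.ndarray:
        return np.array([self.target_rho.get(d, 1.0) for d in DINUCLEOTIDES]).reshape(4, 4)

    def freq_vector(self) -> np.ndarray:
        f = np.array([self.base_freqs[b] for b in NUCLEOTIDES], dtype=float)
        if not np.isclose(f.sum(), 1.0, atol=1e-9):
            raise ValueError("base_freqs must sum to 1")
        if (f < 0).any():
            raise ValueError("base_freqs must be non-negative")
        return f


def build_transition_matrix(spec: GeneratorSpec) -> np.ndarray:
    """P(Y|X) = p_XY / sum_Y' p_XY' with p_XY = rho_XY f_X f_Y."""
    f = spec.freq_vector()
    p = spec.rho_vector() * np.outer(f, f)
    if (p < 0).any():
        raise ValueError("implied dinucleotide matrix has negative entries")
    rows = p.sum(axis=1)
    if (rows <= 0).any():
        raise ValueError("invalid spec: zero transition row")
    return p / rows[:, None]


def stationary_distribution(P: np.ndarray, tol: float = 1e-12, max_iter: int = 100000) -> np.ndarray:
    """Leading left eigenvector by power iteration (tolerance 1e-12)."""
    pi = np.full(4, 0.25)
    for _ in range(max_iter):
        nxt = pi @ P
        nxt /= nxt.sum()
        if np.abs(nxt - pi).max() < tol:
            return nxt
        pi = nxt
    return pi


def _expected_dinucleotide_freqs(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pi = stationary_distribution(P)
    return pi, pi[:, None] * P


def realized_rho(spec: GeneratorSpec) -> dict[str, float]:
    """Closed-form long-run rho* of the chain (what generated sequences
    converge to), which can differ slightly from ``target_rho``."""
    pi, p = _expected_dinucleotide_freqs(build_transition_matrix(spec))
    rho = p / np.outer(pi, pi)
    return {d: float(rho[i // 4, i % 4]) for i, d in enumerate(DINUCLEOTIDES)}


def analytic_profile(spec: GeneratorSpec) -> DRAProfile:
    """Exact expected DRA profile of the chain (counts are zero; the
    frequencies are model expectations, not estimates)."""
    pi, p = _expected_dinucleotide_freqs(build_transition_matrix(spec))
    return DRAProfile.from_frequencies(
        {b: float(pi[i]) for i, b in enumerate(NUCLEOTIDES)},
        {d: float(p[i // 4, i % 4]) for i, d in enumerate(DINUCLEOTIDES)},
    )


def calibrate_target_rho(
    base_freqs: Mapping[str, float],
    desired_rho: Mapping[str, float],
    max_iter: int = 200,
    tol: float = 1e-10,
) -> dict[str, float]:
    """Find target_rho such that the chain's *realized* rho* equals
    ``desired_rho`` for the listed dinucleotides (others stay free).

    Multiplicative fixed-point iteration; raises if it fails to converge.
    """
    target = dict(desired_rho)
    spec = GeneratorSpec(base_freqs=dict(base_freqs), target_rho=target, n=1, seed=0)
    for _ in range(max_iter):
        spec.target_rho = target
        real = realized_rho(spec)
        err = max(abs(real[d] - desired_rho[d]) for d in desired_rho)
        if err < tol:
            return target
        target = {d: target[d] * desired_rho[d] / real[d] for d in desired_rho}
    raise RuntimeError(f"calibration did not converge (residual {err:.3g})")


def _sample_codes(
    P: np.ndarray, pi: np.ndarray, lengths: np.ndarray, rng: np.random.Generator
) -> list[np.ndarray]:
    """Vectorised batch sampling of Markov sequences of given lengths."""
    n = lengths.size
    order = np.argsort(-lengths, kind="stable")
    lsort = lengths[order]
    max_len = int(lsort[0]) if n else 0
    out = np.empty((n, max_len), dtype=np.int8)
    cum = P.cumsum(axis=1)
    cum[:, -1] = 1.0
    state = np.searchsorted(pi.cumsum(), rng.random(n), side="right").astype(np.int8)
    state = np.minimum(state, 3)
    out[:, 0] = state
    # sequences sorted longest-first: the active set at step t is a prefix
    active = n - np.searchsorted(lsort[::-1], np.arange(1, max_len), side="right")
    for t in range(1, max_len):
        k = int(active[t - 1])
        if k == 0:
            break
        u = rng.random(k)
        nxt = (u[:, None] < cum[out[:k, t - 1]]).argmax(axis=1).astype(np.int8)
        out[:k, t] = nxt
    seqs: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    for rank, idx in enumerate(order):
        seqs[idx] = out[rank, : lengths[idx]].copy()
    return seqs


def generate_population(
    spec: GeneratorSpec, rng: np.random.Generator | None = None
) -> list[SequenceRecord]:
    """Generate ``spec.n`` transcripts; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    P = build_transition_matrix(spec)
    pi = stationary_distribution(P)
    lengths = spec.length_model.sample(spec.n, rng)
    codes = _sample_codes(P, pi, lengths, rng)
    records = []
    for i, c in enumerate(codes):
        residues = _BASES_U8[c].tobytes().decode("ascii")
        records.append(
            SequenceRecord(
                id=f"{spec.label}_{i:06d}",
                description=f"synthetic {spec.label} transcript",
                residues=residues,
                source="dinusig.simulate",
            )
        )
    return records


# --- presets ------------------------------------------------------------

GENOME_BASE_FREQS = {"A": 0.295, "C": 0.205, "G": 0.205, "T": 0.295}
GENOME_DESIRED_RHO = {"CG": 0.25, "TA": 0.78}

PRESET_TS = {
    "mrna": {"CG": 2.29, "TA": 0.80},
    "pseudo": {"CG": 2.12, "TA": 0.80},
    "lncrna": {"CG": 1.96, "TA": 0.80},
}
PRESET_GC = {"mrna": 0.52, "pseudo": 0.46, "lncrna": 0.44}


def genome_spec(n: int = 4, seed: int = 0, length: int = 500_000) -> GeneratorSpec:
    """Synthetic genome 'chromosomes': CG-suppressed, TA-depleted, GC 41%."""
    target = calibrate_target_rho(GENOME_BASE_FREQS, GENOME_DESIRED_RHO)
    return GeneratorSpec(
        base_freqs=dict(GENOME_BASE_FREQS),
        target_rho=target,
        length_model=FixedLength(length),
        n=n,
        seed=seed,
        label="chr",
    )


def synthetic_genome(n: int = 4, seed: int = 0, length: int = 500_000) -> list[SequenceRecord]:
    return generate_population(genome_spec(n=n, seed=seed, length=length))


def analytic_genome_baseline() -> GenomeBaseline:
    """Exact expected baseline of the synthetic genome model."""
    return GenomeBaseline(profile=analytic_profile(genome_spec()), build_label="synthetic-genome")


def preset_spec(
    kind: str,
    n: int,
    seed: int,
    length_model: FixedLength | LogNormalLength | None = None,
) -> GeneratorSpec:
    """Population spec whose realized TS (against the synthetic-genome
    baseline) equals the preset targets exactly at the model level."""
    if kind not in PRESET_TS:
        raise ValueError(f"unknown preset {kind!r}; choose from {sorted(PRESET_TS)}")
    genome_rho = realized_rho(genome_spec())
    desired = {d: ts * genome_rho[d] for d, ts in PRESET_TS[kind].items()}
    gc = PRESET_GC[kind]
    base = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    target = calibrate_target_rho(base, desired)
    return GeneratorSpec(
        base_freqs=base,
        target_rho=target,
        length_model=length_model or LogNormalLength(),
        n=n,
        seed=seed,
        label=f"{kind}-like",
    )


def write_population(records: Sequence[SequenceRecord], spec: GeneratorSpec, path: str | Path) -> None:
    """FASTA plus a JSON sidecar recording the spec, seed, and realized
    composition of the chain."""
    path = Path(path)
    write_fasta(records, path)
    sidecar = {
        "label": spec.label,
        "n": spec.n,
        "seed": spec.seed,
        "base_freqs": spec.base_freqs,
        "target_rho": spec.target_rho,
        "length_model": asdict(spec.length_model) | {"kind": type(spec.length_model).__name__},
        "realized_rho": realized_rho(spec),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
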