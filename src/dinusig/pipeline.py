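"""End-to-end orchestration: curate -> datasets -> cross-validate ->
signatures -> summaries -> comparisons -> ORF/stop statistics.

Configuration lives in a small dataclass (loadable from YAML); the same
config and seed always produce a byte-identical report bundle.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curation import bona_fide_prefilter, filter_lncrna, filter_mrna
from .orf import longest_orf, stop_codon_stats
from .records import SequenceRecord, read_fasta
from .signature import GenomeBaseline, load_baseline, score_table
from .validation import (
    compare_groups,
    cross_validate,
    make_datasets,
    summarize,
    summary_table,
    ts_values,
)

__all__ = ["PipelineConfig", "PipelineError", "run_full_analysis"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name, partial outputs preserved."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs and knobs for a full run.

    ``groups`` maps a label (e.g. "mrna") to a transcript FASTA path;
    ``curate`` optionally maps labels to a curation mode in
    {none, mrna, lncrna, bonafide}.
    """

    groups: dict[str, str]
    baseline: str
    outdir: str
    curate: dict[str, str] = field(default_factory=dict)
    dataset_size: int = 50
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def to_dict(self) -> dict:
        return {
            "groups": dict(self.groups),
            "baseline": str(self.baseline),
            "outdir": str(self.outdir),
            "curate": dict(self.curate),
            "dataset_size": self.dataset_size,
            "alpha": self.alpha,
            "seed": self.seed,
        }


def _curate(label: str, records: list[SequenceRecord], mode: str):
    if mode in ("none", "", None):
        return records, None
    if mode == "mrna":
        return filter_mrna(records)
    if mode == "lncrna":
        return filter_lncrna(records)
    if mode == "bonafide":
        return bona_fide_prefilter(records)
    raise PipelineError("curate", f"unknown curation mode {mode!r} for group {label!r}")


def run_full_analysis(config: PipelineConfig) -> dict[str, object]:
    """Run the whole pipeline and write the TSV/JSON report bundle.

    Inputs are read and validated before any output file is written, so
    an empty or unreadable input aborts cleanly without partial TSVs.
    """
    # -- stage: load (no outputs yet) ----------------------------------
    try:
        baseline: GenomeBaseline = load_baseline(config.baseline)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("load-baseline", str(exc)) from exc
    raw: dict[str, list[SequenceRecord]] = {}
    for label, path in config.groups.items():
        try:
            raw[label] = read_fasta(path)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("load-input", f"group {label!r}: {exc}") from exc
    if not raw:
        raise PipelineError("load-input", "no input groups configured")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, object] = {}

    # -- stage: curate -------------------------------------------------
    curated: dict[str, list[SequenceRecord]] = {}
    reports = {}
    for label, records in raw.items():
        kept, report = _curate(label, records, config.curate.get(label, "none"))
        if not kept:
            raise PipelineError("curate", f"group {label!r} empty after curation")
        curated[label] = kept
        if report is not None:
            reports[label] = {
                "n_input": report.n_input,
                "n_kept": report.n_kept,
                "n_dropped_by_rule": report.n_dropped_by_rule,
            }
    if reports:
        (outdir / "curation_reports.json").write_text(json.dumps(reports, indent=1, sort_keys=True))
        bundle["curation_reports"] = reports

    # -- stage: datasets + cross-validation ----------------------------
    try:
        xval_rows = []
        for label, records in curated.items():
            if len(records) < 2 * config.dataset_size:
                continue
            datasets = make_datasets(records, size=config.dataset_size, seed=config.seed)
            kept_idx, results = cross_validate(
                datasets, alpha=config.alpha, labels=[f"{label}/ds{i}" for i in range(len(datasets))]
            )
            for r in results:
                xval_rows.append(
                    {
                        "group": label,
                        "pair": f"{r.groups[0]}|{r.groups[1]}",
                        "dinucleotide": r.dinucleotide,
                        "t": r.statistic,
                        "p": r.p_value,
                        "kept_datasets": ",".join(str(i) for i in kept_idx),
                    }
                )
        if xval_rows:
            df = pd.DataFrame(xval_rows)
            df.to_csv(outdir / "cross_validation.tsv", sep="\t", index=False, na_rep="NA")
            bundle["cross_validation"] = df
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cross-validate", str(exc)) from exc

    # -- stage: signatures + summaries ---------------------------------
    try:
        summaries = []
        for label, records in curated.items():
            scores = score_table(records, baseline)
            scores.to_csv(outdir / f"scores_{label}.tsv", sep="\t", index=False, na_rep="NA")
            bundle[f"scores_{label}"] = scores
            summaries.append(summarize(records, baseline, label=label))
        stable = summary_table(summaries)
        stable.to_csv(outdir / "summary.tsv", sep="\t", index=False, na_rep="NA")
        bundle["summary"] = stable
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("summarize", str(exc)) from exc

    # -- stage: group comparisons --------------------------------------
    try:
        comp_rows = []
        for (la, ra), (lb, rb) in itertools.combinations(curated.items(), 2):
            for d in ("CG", "TA"):
                res = compare_groups(
                    ts_values(ra, baseline, d),
                    ts_values(rb, baseline, d),
                    dinucleotide=d,
                    groups=(la, lb),
                )
                comp_rows.append(
                    {"group_a": la, "group_b": lb, "dinucleotide": d, "t": res.statistic, "p": res.p_value}
                )
        if comp_rows:
            comps = pd.DataFrame(comp_rows)
            comps.to_csv(outdir / "comparisons.tsv", sep="\t", index=False, na_rep="NA")
            bundle["comparisons"] = comps
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("compare", str(exc)) from exc

    # -- stage: ORF / stop-codon statistics ----------------------------
    try:
        orf_rows = []
        for label, records in curated.items():
            for rec in records:
                orf = longest_orf(rec)
                st = stop_codon_stats(rec) if rec.length >= 3 else None
                orf_rows.append(
                    {
                        "group": label,
                        "accession": rec.id,
                        "length": rec.length,
                        "orf_start": orf.start if orf else np.nan,
                        "orf_frame": orf.frame if orf else np.nan,
                        "orf_nt": orf.nt_length if orf else np.nan,
                        "orf_aa": orf.aa_length if orf else np.nan,
                        "stops_per_kb": st.per_kb if st else np.nan,
                        "percent_stops": st.percent_stops if st else np.nan,
                    }
                )
        orfs = pd.DataFrame(orf_rows)
        orfs.to_csv(outdir / "orf_stats.tsv", sep="\t", index=False, na_rep="NA")
        bundle["orf_stats"] = orfs
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("orfstats", str(exc)) from exc

    run_log = {"config": config.to_dict(), "seed": config.seed, "version": __version__}
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True))
    bundle["run_log"] = run_log
    return bundle
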