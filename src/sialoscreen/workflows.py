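"""End-to-end orchestration and report I/O for the full screen.

``run_genome_workflow`` chains profile-HMM search, architecture calling,
cluster detection, pathway classification and the genome-level summary;
``run_metagenome_workflow`` runs the cohort prevalence analysis in either
sequence-level or count-level mode.  All intermediate tables are written as
TSV (1-based inclusive coordinates throughout), the final reports as JSON
with both raw and display-rounded percentages, and runs are deterministic
given the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .profile_hmm import ProfileHMM, calibrate, search_domains, hits_to_table, read_fasta
from .domain_architecture import classify_proteome, calls_to_table
from .genome_screen import (
    GeneLocus, StrainScreenResult, classify_pathway, summarize_genome_screen,
    results_to_table,
)
from .metagenome_screen import (
    CohortError, CohortSummary, count_sample_hits, summarize_cohort, compare_groups,
    samples_from_count_table, samples_to_count_table, format_prevalence_table,
    COUNT_COLUMNS,
)

logger = logging.getLogger(__name__)

MODEL_SLOTS = ("NanA", "NanK", "NanE1", "NanE2", "sialidase", "I-domain", "CBM40")
REPORT_SCHEMA_VERSION = 1


class WorkflowError(ValueError):
    pass


@dataclass
class ScreenConfig:
    """Configuration for a screen run.

    ``models`` maps slot names (NanA, NanK, NanE1, NanE2, sialidase,
    I-domain, CBM40; RokA optional) to ProfileHMM objects or JSON profile
    paths.  Missing RokA downgrades the Bacteroides-type call with a warning
    rather than failing.
    """

    models: dict[str, ProfileHMM | str] = field(default_factory=dict)
    max_evalue: float = 1e-4
    window: int = 15
    calibration_n_random: int = 1000
    calibration_length: int | None = None  # default 2 x model length
    seed: int = 421
    outdir: str | Path | None = None

    def __post_init__(self):
        if self.max_evalue <= 0:
            raise WorkflowError("max_evalue must be > 0")
        if self.window < 3:
            raise WorkflowError("cluster window must be >= 3")
        loaded = {}
        for name, m in self.models.items():
            loaded[name] = m if isinstance(m, ProfileHMM) else ProfileHMM.from_json(Path(m))
        self.models = loaded

    def require(self, slots: Sequence[str]) -> None:
        missing = [s for s in slots if s not in self.models]
        if missing:
            raise WorkflowError(f"missing model slots: {missing}")

    def ensure_calibrated(self) -> None:
        """Calibrate any uncalibrated model, deterministically from the seed."""
        for i, name in enumerate(sorted(self.models)):
            model = self.models[name]
            if model.calibration is None:
                calibrate(model, n_random=self.calibration_n_random,
                          random_length=self.calibration_length,
                          seed=(self.seed + 1009 * i) % (2 ** 31))
            logger.info("model %s length=%d checksum=%s mu=%.3f lambda=%.3f",
                        name, model.length, model_checksum(model),
                        model.calibration.mu, model.calibration.lam)


def model_checksum(model: ProfileHMM) -> str:
    return hashlib.sha256(model.to_json().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Genome workflow
# ---------------------------------------------------------------------------

def run_genome_workflow(
    config: ScreenConfig,
    gene_tables: Mapping[str, Sequence[GeneLocus]],
    proteomes: Mapping[str, Sequence[tuple[str, str]]],
    species: Mapping[str, str] | None = None,
) -> tuple[list[StrainScreenResult], dict]:
    """Search -> architecture -> cluster -> pathway -> summary, per strain.

    ``gene_tables`` and ``proteomes`` are keyed by strain id; protein ids in
    the gene tables must match the proteome record ids.
    """
    config.require(["sialidase", "I-domain"])
    config.ensure_calibrated()
    roka_available = "RokA" in config.models
    species = species or {}

    results: list[StrainScreenResult] = []
    all_hits = []
    all_calls = {}
    for strain in sorted(proteomes):
        prots = list(proteomes[strain])
        loci = list(gene_tables.get(strain, []))
        hits = []
        for name in sorted(config.models):
            hits.extend(search_domains(config.models[name], prots,
                                       max_evalue=config.max_evalue))
        all_hits.extend(hits)
        protein_roles: dict[str, set[str]] = {}
        for h in hits:
            protein_roles.setdefault(h.target_id, set()).add(h.model_name)
        calls = classify_proteome(hits, all_target_ids=[pid for pid, _ in prots])
        all_calls.update(calls)
        results.append(classify_pathway(
            strain_id=strain, protein_roles=protein_roles, loci=loci,
            architecture_calls=calls, window=config.window,
            species=species.get(strain, ""), roka_available=roka_available))

    summary = summarize_genome_screen(results)
    summary["schema_version"] = REPORT_SCHEMA_VERSION

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        hits_to_table(all_hits).to_csv(out / "domain_hits.tsv", sep="\t", index=False)
        calls_to_table(all_calls).to_csv(out / "architecture.tsv", sep="\t", index=False)
        results_to_table(results).to_csv(out / "strain_screen.tsv", sep="\t", index=False)
        (out / "genome_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return results, summary


# ---------------------------------------------------------------------------
# Metagenome workflow
# ---------------------------------------------------------------------------

def run_metagenome_workflow(
    config: ScreenConfig,
    sample_sheet: pd.DataFrame | str | Path,
) -> tuple[CohortSummary, dict]:
    """Cohort prevalence analysis from a sample sheet.

    Count-level mode: columns sample_id, group, n_sequences, mean_bp,
    sialidase_hits, idomain_hits.  Sequence-level mode: columns sample_id,
    group, path (protein FASTA per sample).  Mixing modes in one sheet is an
    error.
    """
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = pd.read_csv(sample_sheet, sep="\t")
    has_counts = all(c in sample_sheet.columns for c in COUNT_COLUMNS)
    has_paths = "path" in sample_sheet.columns
    count_like = {"n_sequences", "sialidase_hits", "idomain_hits"} & set(sample_sheet.columns)
    if has_paths and count_like:
        raise WorkflowError("mixed-mode sample sheet: both FASTA paths and hit counts present")
    if has_counts:
        samples = samples_from_count_table(sample_sheet)
    elif has_paths:
        config.require(["sialidase", "I-domain"])
        config.ensure_calibrated()
        models = [config.models["sialidase"], config.models["I-domain"]]
        samples = []
        for _, row in sample_sheet.iterrows():
            seqs = read_fasta(row["path"])
            samples.append(count_sample_hits(str(row["sample_id"]), str(row["group"]),
                                             seqs, models, max_evalue=config.max_evalue))
    else:
        raise WorkflowError("sample sheet must carry either count columns "
                            f"{COUNT_COLUMNS} or a 'path' column")

    cohort = summarize_cohort(samples)
    try:
        contrast = compare_groups(cohort)
    except CohortError:  # single-group cohorts have no contrast
        contrast = None
    report = cohort_report(cohort, contrast)

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        samples_to_count_table(samples).to_csv(out / "sample_counts.tsv", sep="\t", index=False)
        format_prevalence_table(cohort).to_csv(out / "prevalence_table.tsv",
                                               sep="\t", index=False)
        (out / "cohort_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return cohort, report


def _round_or_none(x, nd):
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return round(x, nd)


def cohort_report(cohort: CohortSummary, contrast: dict | None = None) -> dict:
    """JSON-ready cohort report: raw values plus display-rounded views."""
    d = cohort.derived
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "table": cohort.table.to_dict(orient="records"),
        "table_display": format_prevalence_table(cohort).to_dict(orient="records"),
        "derived": {
            **{k: v for k, v in d.items() if k != "sequences_per_hit_by_group"},
            "sequences_per_hit_by_group": {
                k: (None if (isinstance(v, float) and math.isnan(v)) else v)
                for k, v in d["sequences_per_hit_by_group"].items()},
        },
        "derived_display": {
            "overall_pct_positive_subjects": _round_or_none(
                d["overall_pct_positive_subjects"], 1),
            "mean_hits_per_positive_subject": _round_or_none(
                d["mean_hits_per_positive_subject"], 1),
            "sequences_per_hit": _round_or_none(d["sequences_per_hit"], 0),
        },
    }
    if contrast is not None:
        report["group_contrast"] = {
            **contrast,
            "risk_ratio": None if math.isnan(contrast["risk_ratio"]) else contrast["risk_ratio"],
        }
    return report
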