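"""Cohort prevalence statistics for sialidase / I-domain hits in metagenomes.

Each sample is one subject's set of translated coding sequences; a sample is
*positive* for a model when at least one of its sequences carries a domain
hit at the E-value threshold.  Two execution modes are supported: a
sequence-level mode that runs the real profile-HMM search (used at reduced
scale) and a count-level mode that consumes precomputed per-sample hit
counts (the published screens pooled 14.1 million coding sequences, which is
not desk-scale; the arithmetic is).  Percent-hit-sequences is one pooled
ratio per group, not a mean of per-sample ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .profile_hmm import ProfileHMM, search_domains

GROUPS = ("IBD_N", "IBD_Y")
DEFAULT_MODELS = ("sialidase", "I-domain")
# the IT-sialidase marker: a sequence hit by the I-domain model
IT_MARKER = "I-domain"


class CohortError(ValueError):
    pass


@dataclass
class SampleSummary:
    sample_id: str
    group: str
    n_sequences: float  # float so count-level tables may carry group means
    mean_bp: float
    hits: dict[str, float] = field(default_factory=dict)  # model -> hit-sequence count

    def __post_init__(self):
        if self.n_sequences < 0:
            raise CohortError("negative sequence count")
        for m, h in self.hits.items():
            if h > self.n_sequences:
                raise CohortError(f"more hit sequences than sequences for model {m}")

    def positive(self, model: str) -> bool:
        return self.hits.get(model, 0) >= 1


@dataclass
class CohortSummary:
    table: pd.DataFrame              # per (group, model) Table-style rows
    derived: dict                    # pooled statistics
    samples: list[SampleSummary]


def count_sample_hits(
    sample_id: str,
    group: str,
    sequences: Sequence[tuple[str, str]],
    models: Sequence[ProfileHMM],
    max_evalue: float = 1e-4,
    search_space: int | None = None,
) -> SampleSummary:
    """Search every model over one sample's protein sequences.

    Counts distinct sequences with >=1 hit per model (a sequence with two
    hits of the same model counts once).  An empty sample yields zero counts
    rather than an error.  ``mean_bp`` is 3 x mean protein length, the
    coding-sequence length the proteins translate from.
    """
    sequences = list(sequences)
    hits: dict[str, float] = {}
    for model in models:
        found = search_domains(model, sequences, max_evalue=max_evalue,
                               search_space=search_space)
        hits[model.name] = float(len({h.target_id for h in found}))
    mean_bp = 3.0 * float(np.mean([len(s) for _, s in sequences])) if sequences else 0.0
    return SampleSummary(sample_id=sample_id, group=group,
                         n_sequences=float(len(sequences)), mean_bp=mean_bp, hits=hits)


def summarize_cohort(
    samples: Sequence[SampleSummary],
    models: Sequence[str] = DEFAULT_MODELS,
    it_marker: str = IT_MARKER,
    groups: Sequence[str] = GROUPS,
) -> CohortSummary:
    """Per-group, per-model prevalence table plus pooled derived statistics.

    Table columns per (group, model): number of samples, mean sequences per
    sample, mean bp per sequence, pooled percent hit sequences, positive
    samples and their percentage, mean hit sequences per sample.  Derived
    statistics pool both groups on the IT marker model: overall subject
    prevalence, mean hits per positive subject, sequences-per-hit (the
    "1 in N" figure, per group and pooled) and the pooled sequence total.
    """
    samples = list(samples)
    if not samples:
        raise CohortError("empty cohort")
    known = set(groups)
    for s in samples:
        if s.group not in known:
            raise CohortError(f"unknown group label {s.group!r} (expected one of {sorted(known)})")

    rows = []
    for group in groups:
        gs = [s for s in samples if s.group == group]
        if not gs:
            continue
        n = len(gs)
        tot_seq = math.fsum(s.n_sequences for s in gs)
        mean_seq = tot_seq / n
        mean_bp = float(np.average([s.mean_bp for s in gs],
                                   weights=[max(s.n_sequences, 1e-300) for s in gs]))
        for model in models:
            tot_hits = math.fsum(s.hits.get(model, 0) for s in gs)
            n_pos = sum(1 for s in gs if s.positive(model))
            rows.append({
                "group": group,
                "model": model,
                "n_samples": n,
                "mean_sequences_per_sample": mean_seq,
                "mean_bp_per_sequence": mean_bp,
                "pct_hit_sequences": 100.0 * tot_hits / tot_seq if tot_seq else 0.0,
                "n_positive_samples": n_pos,
                "pct_positive_samples": 100.0 * n_pos / n,
                "mean_hits_per_sample": tot_hits / n,
                "total_hits": tot_hits,
                "total_sequences": tot_seq,
            })
    table = pd.DataFrame(rows)

    total_sequences = math.fsum(s.n_sequences for s in samples)
    marker_hits = math.fsum(s.hits.get(it_marker, 0) for s in samples)
    n_pos = sum(1 for s in samples if s.positive(it_marker))
    per_group_spH = {}
    for group in groups:
        gs = [s for s in samples if s.group == group]
        gh = math.fsum(s.hits.get(it_marker, 0) for s in gs)
        gseq = math.fsum(s.n_sequences for s in gs)
        per_group_spH[group] = gseq / gh if gh > 0 else math.nan
    derived = {
        "it_marker_model": it_marker,
        "n_samples": len(samples),
        "total_sequences": total_sequences,
        "n_positive_subjects": n_pos,
        "overall_pct_positive_subjects": 100.0 * n_pos / len(samples),
        "mean_hits_per_positive_subject": marker_hits / n_pos if n_pos else math.nan,
        "sequences_per_hit": total_sequences / marker_hits if marker_hits else math.nan,
        "sequences_per_hit_by_group": per_group_spH,
    }
    return CohortSummary(table=table, derived=derived, samples=samples)


def compare_groups(
    cohort: CohortSummary,
    model: str = IT_MARKER,
    groups: Sequence[str] = GROUPS,
) -> dict:
    """Prevalence contrast between the two groups on one model.

    Reports the positive fractions, the risk ratio of positivity, and a
    two-sided Fisher exact p-value on the 2x2 positivity table (descriptive).
    The risk ratio is NaN (flagged degenerate) when the reference group has
    zero positives.
    """
    counts = {}
    for group in groups:
        gs = [s for s in cohort.samples if s.group == group]
        if not gs:
            raise CohortError(f"group {group!r} has no samples")
        counts[group] = (sum(1 for s in gs if s.positive(model)), len(gs))
    (a, n1), (b, n2) = counts[groups[0]], counts[groups[1]]
    tab = [[a, n1 - a], [b, n2 - b]]
    _, p = sstats.fisher_exact(tab, alternative="two-sided")
    p1, p2 = a / n1, b / n2
    degenerate = p1 == 0
    rr = (p2 / p1) if p1 > 0 else math.nan
    return {
        "model": model,
        "groups": tuple(groups),
        "prevalence": {groups[0]: 100.0 * p1, groups[1]: 100.0 * p2},
        "risk_ratio": rr,
        "degenerate": degenerate or (p1 == 0 and p2 == 0),
        "fisher_p": float(p),
    }


# ---------------------------------------------------------------------------
# Count-table I/O
# ---------------------------------------------------------------------------

COUNT_COLUMNS = ["sample_id", "group", "n_sequences", "mean_bp",
                 "sialidase_hits", "idomain_hits"]


def samples_from_count_table(df: pd.DataFrame) -> list[SampleSummary]:
    """Build SampleSummaries from a count-level table.

    Expects columns sample_id, group, n_sequences, mean_bp, sialidase_hits,
    idomain_hits.
    """
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"count table missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(SampleSummary(
            sample_id=str(row["sample_id"]),
            group=str(row["group"]),
            n_sequences=float(row["n_sequences"]),
            mean_bp=float(row["mean_bp"]),
            hits={"sialidase": float(row["sialidase_hits"]),
                  "I-domain": float(row["idomain_hits"])},
        ))
    return out


def samples_to_count_table(samples: Sequence[SampleSummary]) -> pd.DataFrame:
    rows = []
    for s in samples:
        rows.append({"sample_id": s.sample_id, "group": s.group,
                     "n_sequences": s.n_sequences, "mean_bp": s.mean_bp,
                     "sialidase_hits": s.hits.get("sialidase", 0.0),
                     "idomain_hits": s.hits.get("I-domain", 0.0)})
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def format_prevalence_table(cohort: CohortSummary) -> pd.DataFrame:
    """Display-rounded view of the cohort table (means to 2 dp, pooled
    percent-hit-sequences to 4 dp); raw values stay in ``cohort.table``."""
    t = cohort.table.copy()
    t["mean_sequences_per_sample"] = t["mean_sequences_per_sample"].round(2)
    t["mean_bp_per_sequence"] = t["mean_bp_per_sequence"].round(2)
    t["pct_hit_sequences"] = t["pct_hit_sequences"].round(4)
    t["pct_positive_samples"] = t["pct_positive_samples"].round(1)
    t["mean_hits_per_sample"] = t["mean_hits_per_sample"].round(2)
    return t[["group", "model", "n_samples", "mean_sequences_per_sample",
              "mean_bp_per_sequence", "pct_hit_sequences", "n_positive_samples",
              "pct_positive_samples", "mean_hits_per_sample"]]
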