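"""Per-strain genome screening: Nan genes, gene clusters, pathway calls.

Sialic-acid catabolism (Nan) genes are located on per-genome gene tables
(ordered loci per replicon).  The canonical pathway needs NanA (lyase),
NanK (kinase) and NanE1 (ManNAc-6-P epimerase); a *cluster* is called when
all three fall within a window of 15 consecutive loci on one replicon,
intervening genes permitted.  The Bacteroides-type alternative pathway is
called from NanA-model hits (the model also covers B. fragilis NanL) plus
NanE2 and RokA.  Windows never span replicon boundaries, because contig
order in draft genomes is arbitrary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .domain_architecture import Call

logger = logging.getLogger(__name__)

CANONICAL_ROLES = frozenset({"NanA", "NanK", "NanE1"})
BACTEROIDES_ROLES = frozenset({"NanA", "NanE2", "RokA"})


class GeneTableError(ValueError):
    pass


class ClusterError(ValueError):
    pass


@dataclass(frozen=True)
class GeneLocus:
    strain_id: str
    replicon_id: str
    locus_index: int  # 1-based ordinal position along the replicon
    protein_id: str
    strand: str = "unknown"


@dataclass
class StrainScreenResult:
    strain_id: str
    species: str = ""
    domain_hits: dict[str, set[str]] = field(default_factory=dict)  # role -> protein ids
    has_it_sialidase: bool = False
    canonical_clustered: bool = False
    canonical_unclustered: bool = False
    bacteroides_type: bool = False
    cluster_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    it_cbm40_flags: list[bool] = field(default_factory=list)  # per IT-sialidase protein
    n_sialidase_proteins: int = 0

    @property
    def any_pathway(self) -> bool:
        """Positive for either Nan gene set, cluster required for the canonical one."""
        return self.canonical_clustered or self.bacteroides_type

    @property
    def any_pathway_relaxed(self) -> bool:
        """As any_pathway but accepting unclustered canonical genes."""
        return self.canonical_unclustered or self.bacteroides_type


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

TSV_COLUMNS = ["strain", "replicon", "locus_index", "protein_id", "strand"]


def load_gene_table(path: str | Path, fmt: str | None = None,
                    strain_id: str | None = None) -> list[GeneLocus]:
    """Load a gene table from TSV or GFF3 and normalise locus indices.

    TSV needs the header columns strain, replicon, locus_index, protein_id,
    strand.  For GFF3, CDS features are ranked by start coordinate per seqid
    and ``locus_index`` assigned by rank (``strain_id`` then names the
    strain).  After loading, indices are consecutive 1-based per replicon.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in TSV_COLUMNS if c not in df.columns]
        if missing:
            raise GeneTableError(f"gene table missing columns: {missing}")
        df["locus_index"] = df["locus_index"].astype(int)
        dup = df.duplicated(subset=["strain", "replicon", "locus_index"])
        if dup.any():
            raise GeneTableError("duplicate (replicon, locus_index) in gene table")
        df = df.sort_values(["strain", "replicon", "locus_index"], kind="mergesort")
    elif fmt == "gff3":
        rows = []
        for line in path.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            attrs = f[8]
            m = re.search(r"(?:protein_id|ID)=([^;]+)", attrs)
            pid = m.group(1) if m else f"{f[0]}:{f[3]}"
            rows.append({"strain": strain_id or path.stem, "replicon": f[0],
                         "locus_index": int(f[3]), "protein_id": pid, "strand": f[6]})
        if not rows:
            raise GeneTableError(f"no CDS features in {path}")
        df = pd.DataFrame(rows).sort_values(["strain", "replicon", "locus_index"],
                                            kind="mergesort")
    else:
        raise GeneTableError(f"unknown gene-table format {fmt!r}")

    loci = []
    for (strain, replicon), grp in df.groupby(["strain", "replicon"], sort=True):
        for rank, (_, row) in enumerate(grp.iterrows(), start=1):
            loci.append(GeneLocus(strain_id=strain, replicon_id=replicon,
                                  locus_index=rank, protein_id=row["protein_id"],
                                  strand=row.get("strand", "unknown")))
    return loci


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------

def detect_gene_cluster(
    loci_with_roles: Iterable[tuple[str, int, frozenset | set]],
    required_roles: frozenset = CANONICAL_ROLES,
    window: int = 15,
) -> list[tuple[str, int, int]]:
    """Minimal same-replicon intervals of span <= window covering all roles.

    ``loci_with_roles`` yields ``(replicon_id, locus_index, roles)``.  An
    interval's span counts both endpoints and any intervening genes
    (``max - min + 1``).  Minimal means no proper sub-interval also covers
    every required role.  Returns ``(replicon, start_index, end_index)``
    triples; empty list when no window qualifies.
    """
    required_roles = frozenset(required_roles)
    if window < len(required_roles):
        raise ClusterError(f"window {window} smaller than number of required roles")
    by_rep: dict[str, list[tuple[int, frozenset]]] = {}
    for rep, idx, roles in loci_with_roles:
        r = frozenset(roles) & required_roles
        if r:
            by_rep.setdefault(rep, []).append((idx, r))

    out = []
    for rep in sorted(by_rep):
        marks = sorted(by_rep[rep])
        m = len(marks)

        def covers(i: int, j: int) -> bool:
            got = set()
            for idx, r in marks[i:j + 1]:
                got |= r
            return required_roles <= got

        for i in range(m):
            for j in range(i, m):
                span = marks[j][0] - marks[i][0] + 1
                if span > window:
                    break
                if not covers(i, j):
                    continue
                if (i < j and (covers(i + 1, j) or covers(i, j - 1))):
                    continue  # not minimal
                out.append((rep, marks[i][0], marks[j][0]))
    return sorted(set(out))


# ---------------------------------------------------------------------------
# Pathway classification and aggregation
# ---------------------------------------------------------------------------

def classify_pathway(
    strain_id: str,
    protein_roles: Mapping[str, set[str]],
    loci: Sequence[GeneLocus],
    architecture_calls: Mapping[str, "object"] | None = None,
    window: int = 15,
    species: str = "",
    roka_available: bool = True,
) -> StrainScreenResult:
    """Flag one strain's Nan pathway content and IT-sialidase status.

    ``protein_roles`` maps protein_id to the set of roles whose models hit
    it (NanA, NanK, NanE1, NanE2, RokA, sialidase, I-domain, CBM40).
    ``architecture_calls`` maps protein_id to an ArchitectureCall.  When no
    RokA model was available, ``roka_available=False`` downgrades the
    Bacteroides-type rule to NanA-model + NanE2 with a logged warning.
    """
    roles_present: dict[str, set[str]] = {}
    for pid, roles in protein_roles.items():
        for role in roles:
            roles_present.setdefault(role, set()).add(pid)

    loci_roles = []
    for l in loci:
        roles = protein_roles.get(l.protein_id, set())
        loci_roles.append((l.replicon_id, l.locus_index, frozenset(roles)))
    clusters = detect_gene_cluster(loci_roles, CANONICAL_ROLES, window=window)

    canonical_unclustered = CANONICAL_ROLES <= roles_present.keys()
    canonical_clustered = bool(clusters)

    bact_required = set(BACTEROIDES_ROLES)
    if not roka_available:
        bact_required.discard("RokA")
        logger.warning("strain %s: no RokA model; Bacteroides-type call uses the "
                       "two-component rule (NanA-model + NanE2)", strain_id)
    bacteroides = bact_required <= roles_present.keys()

    it_flags = []
    has_it = False
    n_sial = 0
    if architecture_calls:
        for pid, call in architecture_calls.items():
            if call.call is Call.IT_SIALIDASE:
                has_it = True
                it_flags.append(call.has_cbm40)
            if call.has_sialidase:
                n_sial += 1

    return StrainScreenResult(
        strain_id=strain_id,
        species=species,
        domain_hits=roles_present,
        has_it_sialidase=has_it,
        canonical_clustered=canonical_clustered,
        canonical_unclustered=canonical_unclustered,
        bacteroides_type=bacteroides,
        cluster_intervals=clusters,
        it_cbm40_flags=it_flags,
        n_sialidase_proteins=n_sial,
    )


def _pct(num: float, den: float, ndigits: int = 0) -> float:
    if den == 0:
        return 0.0
    v = 100.0 * num / den
    return round(v, ndigits) if ndigits else float(round(v))


def summarize_genome_screen(results: Sequence[StrainScreenResult]) -> dict:
    """Aggregate per-strain calls into the screen-level report.

    Returns raw counts plus display-rounded percentages (integer percent,
    matching the precision the screen's headline numbers are reported at):
    IT-positive strains and their share of all strains, the share of
    IT-positives carrying the canonical cluster, pathway-positive strains
    (cluster-required and relaxed), the IT share among pathway-positive
    strains, the CBM40 fraction among IT-sialidase proteins, NanE1
    co-occurrence violations among Bacteroides-type strains, and a
    species-level roll-up.
    """
    results = list(results)
    if not results:
        raise ValueError("summarize_genome_screen needs at least one strain")
    n = len(results)
    it = [r for r in results if r.has_it_sialidase]
    n_it = len(it)
    it_clustered = sum(1 for r in it if r.canonical_clustered)
    pathway = [r for r in results if r.any_pathway]
    pathway_relaxed = [r for r in results if r.any_pathway_relaxed]
    pathway_it = sum(1 for r in pathway if r.has_it_sialidase)
    cbm_flags = [f for r in it for f in r.it_cbm40_flags]
    bact = [r for r in results if r.bacteroides_type]
    nane1_violations = sum(1 for r in bact if "NanE1" in r.domain_hits)
    species_it: dict[str, int] = {}
    for r in it:
        species_it[r.species or r.strain_id] = species_it.get(r.species or r.strain_id, 0) + 1
    # sialidase-positive strains that also carry a Nan pathway, and the IT share of them
    sial_pathway = [r for r in results if r.n_sialidase_proteins > 0 and r.any_pathway_relaxed]
    it_of_sial_pathway = sum(1 for r in sial_pathway if r.has_it_sialidase)

    return {
        "n_strains": n,
        "n_it_positive": n_it,
        "pct_it_positive": _pct(n_it, n),
        "pct_it_positive_raw": 100.0 * n_it / n,
        "n_it_with_cluster": it_clustered,
        "pct_it_with_cluster": _pct(it_clustered, n_it),
        "pct_it_with_cluster_raw": 100.0 * it_clustered / n_it if n_it else 0.0,
        "n_pathway_positive": len(pathway),
        "n_pathway_positive_relaxed": len(pathway_relaxed),
        "n_pathway_it_positive": pathway_it,
        "pct_pathway_it_positive": _pct(pathway_it, len(pathway)),
        "pct_pathway_it_positive_raw": 100.0 * pathway_it / len(pathway) if pathway else 0.0,
        "n_it_proteins": len(cbm_flags),
        "pct_it_with_cbm40": _pct(sum(cbm_flags), len(cbm_flags)),
        "n_bacteroides_type": len(bact),
        "n_nane1_violations": nane1_violations,
        "n_sialidase_and_pathway": len(sial_pathway),
        "pct_sialidase_pathway_it": _pct(it_of_sial_pathway, len(sial_pathway)),
        "species_it_positive": dict(sorted(species_it.items())),
    }


def results_to_table(results: Sequence[StrainScreenResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "strain_id": r.strain_id,
            "species": r.species,
            "has_it_sialidase": r.has_it_sialidase,
            "canonical_clustered": r.canonical_clustered,
            "canonical_unclustered": r.canonical_unclustered,
            "bacteroides_type": r.bacteroides_type,
            "n_clusters": len(r.cluster_intervals),
            "clusters": ";".join(f"{rep}:{a}-{b}" for rep, a, b in r.cluster_intervals),
        })
    return pd.DataFrame(rows)
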