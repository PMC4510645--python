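"""Seeded generators for every input the screening pipeline consumes.

Proteomes with planted hydrolytic sialidases (contiguous GH33 emission),
IT-sialidases (GH33 emission split by an inserted I-domain, optionally with
an N-terminal CBM40), and background decoys; per-genome gene tables with
planted Nan gene sets at controlled spans; cohorts of metagenome samples
with specified positivity and hit intensities; and kinetic datasets drawn
from the stated rate laws with Gaussian noise.  Every generator is
bit-reproducible for a given seed and emits truth labels alongside the data.

The hit-count model for cohorts is the simplest zero-inflated scheme
consistent with "positive sample = at least one hit sequence": positivity is
Bernoulli(p) and hits given positivity are 1 + Poisson(lambda).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profile_hmm import AMINO_ACIDS, ProfileHMM
from .metagenome_screen import SampleSummary
from .genome_screen import GeneLocus
from .kinetics import (
    RateDataset, ProgressCurve, substrate_inhibition_rate, michaelis_menten_rate,
)


class SyntheticDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Profiles and sequences
# ---------------------------------------------------------------------------

def make_profile(
    name: str,
    length: int,
    seed: int,
    conservation: float = 0.9,
    mm: float = 0.97, mi: float = 0.01, md: float = 0.02,
    im: float = 0.9, ii: float = 0.1,
    dm: float = 0.8, dd: float = 0.2,
) -> ProfileHMM:
    """An informative synthetic profile with a random conserved consensus.

    Each match state puts ``conservation`` probability on one residue and
    spreads the rest uniformly; at the 0.9 default that is about 3.4 bits of
    information per state against a uniform background.  Insert emissions
    equal the background, so unaligned insertions score zero bits and pay
    only transition costs.
    """
    rng = np.random.default_rng(seed)
    cons = rng.integers(0, 20, size=length)
    memit = np.full((length, 20), (1.0 - conservation) / 19.0)
    memit[np.arange(length), cons] = conservation
    bg = np.full(20, 1.0 / 20)
    iemit = np.tile(bg, (length, 1))
    trans = {
        "MM": np.full(length, mm), "MI": np.full(length, mi), "MD": np.full(length, md),
        "IM": np.full(length, im), "II": np.full(length, ii),
        "DM": np.full(length, dm), "DD": np.full(length, dd),
    }
    return ProfileHMM(name=name, match_emissions=memit, insert_emissions=iemit,
                      transitions=trans, background=bg)


def default_models(seed: int = 7) -> dict[str, ProfileHMM]:
    """The eight-slot synthetic model set used throughout tests and demos."""
    spec = [("sialidase", 60), ("I-domain", 45), ("CBM40", 30),
            ("NanA", 28), ("NanK", 26), ("NanE1", 24), ("NanE2", 27), ("RokA", 25)]
    return {name: make_profile(name, L, seed=seed + i)
            for i, (name, L) in enumerate(spec)}


def _walk_segment(model: ProfileHMM, rng: np.random.Generator,
                  k_start: int, k_end: int) -> str:
    """Emit residues by walking match states k_start..k_end of the profile."""
    out = []
    k = k_start
    state = "M"
    while True:
        if state == "M":
            out.append(AMINO_ACIDS[rng.choice(20, p=model.match_emissions[k - 1])])
            if k == k_end:
                break
            p = [model.transitions[t][k - 1] for t in ("MM", "MI", "MD")]
            state = ("M", "I", "D")[rng.choice(3, p=np.asarray(p) / sum(p))]
            if state != "I":
                k += 1
        elif state == "I":
            out.append(AMINO_ACIDS[rng.choice(20, p=model.insert_emissions[k - 1])])
            p = [model.transitions[t][k - 1] for t in ("IM", "II")]
            state = ("M", "I")[rng.choice(2, p=np.asarray(p) / sum(p))]
            if state == "M":
                k += 1
        else:  # D
            if k == k_end:
                break  # degenerate: end node deleted; stop without emission
            p = [model.transitions[t][k - 1] for t in ("DM", "DD")]
            state = ("M", "D")[rng.choice(2, p=np.asarray(p) / sum(p))]
            k += 1
    return "".join(out)


def random_background(rng: np.random.Generator, length: int,
                      background: np.ndarray | None = None) -> str:
    p = background if background is not None else np.full(20, 1 / 20)
    return "".join(AMINO_ACIDS[i] for i in rng.choice(20, size=length, p=p))


def sample_sequence_from_profile(
    model: ProfileHMM,
    seed: int | np.random.Generator,
    flank_range: tuple[int, int] = (20, 80),
) -> tuple[str, tuple[int, int]]:
    """A full-length domain emission with background flanks.

    Returns the sequence and the 1-based inclusive true span of the domain.
    Deterministic for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    left = int(rng.integers(flank_range[0], flank_range[1] + 1))
    right = int(rng.integers(flank_range[0], flank_range[1] + 1))
    core = _walk_segment(model, rng, 1, model.length)
    seq = random_background(rng, left) + core + random_background(rng, right)
    return seq, (left + 1, left + len(core))


# ---------------------------------------------------------------------------
# Proteomes
# ---------------------------------------------------------------------------

@dataclass
class ProteomeSpec:
    n_background: int = 180
    n_hydrolytic: int = 20
    n_it: int = 20
    cbm40_fraction_among_it: float = 0.75
    background_length: tuple[int, int] = (150, 500)
    flank_range: tuple[int, int] = (20, 80)
    split_col: int | None = None  # sialidase model column ending the N-segment
    seed: int = 0

    def __post_init__(self):
        if min(self.n_background, self.n_hydrolytic, self.n_it) < 0:
            raise SyntheticDataError("counts must be >= 0")
        if not 0.0 <= self.cbm40_fraction_among_it <= 1.0:
            raise SyntheticDataError("cbm40 fraction must be in [0, 1]")


def make_it_protein(
    models: dict[str, ProfileHMM],
    rng: np.random.Generator,
    with_cbm40: bool,
    split_col: int | None = None,
    flank_range: tuple[int, int] = (20, 80),
) -> tuple[str, dict]:
    """One IT-sialidase construct: GH33 N-segment + I-domain + GH33 C-segment.

    The split point defaults to the sialidase model's middle column.  An
    optional CBM40 emission is prepended ahead of the catalytic region.
    """
    sial = models["sialidase"]
    split = split_col if split_col is not None else sial.length // 2
    if not 1 <= split < sial.length:
        raise SyntheticDataError("split column must be inside the sialidase model")
    left = int(rng.integers(flank_range[0], flank_range[1] + 1))
    right = int(rng.integers(flank_range[0], flank_range[1] + 1))
    parts = []
    spans = {}
    pos = 0
    if with_cbm40:
        cbm = _walk_segment(models["CBM40"], rng, 1, models["CBM40"].length)
        parts.append(random_background(rng, 10) + cbm + random_background(rng, 10))
        spans["cbm40"] = (11, 10 + len(cbm))
        pos = len(parts[0])
    parts.append(random_background(rng, left))
    pos += left
    nseg = _walk_segment(sial, rng, 1, split)
    spans["sialidase_n"] = (pos + 1, pos + len(nseg))
    parts.append(nseg)
    pos += len(nseg)
    ido = _walk_segment(models["I-domain"], rng, 1, models["I-domain"].length)
    spans["idomain"] = (pos + 1, pos + len(ido))
    parts.append(ido)
    pos += len(ido)
    cseg = _walk_segment(sial, rng, split + 1, sial.length)
    spans["sialidase_c"] = (pos + 1, pos + len(cseg))
    parts.append(cseg)
    parts.append(random_background(rng, right))
    return "".join(parts), spans


def make_proteome(
    spec: ProteomeSpec,
    models: dict[str, ProfileHMM] | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """A labelled synthetic proteome: decoys + planted sialidase architectures.

    Returns FASTA-ready ``(id, sequence)`` records and a truth table with
    per-protein labels (NONE / HYDROLYTIC_TYPE / IT_SIALIDASE) and CBM40
    flags.  Record order is deterministic for a given spec.
    """
    models = models if models is not None else default_models()
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str]] = []
    truth_rows = []

    n_cbm = int(round(spec.cbm40_fraction_among_it * spec.n_it))
    cbm_flags = np.zeros(spec.n_it, dtype=bool)
    cbm_flags[:n_cbm] = True
    rng.shuffle(cbm_flags)

    for i in range(spec.n_it):
        pid = f"it_{i:04d}"
        seq, spans = make_it_protein(models, rng, with_cbm40=bool(cbm_flags[i]),
                                     split_col=spec.split_col,
                                     flank_range=spec.flank_range)
        records.append((pid, seq))
        truth_rows.append({"protein_id": pid, "label": "IT_SIALIDASE",
                           "has_cbm40": bool(cbm_flags[i]),
                           "idomain_start": spans["idomain"][0],
                           "idomain_end": spans["idomain"][1]})
    for i in range(spec.n_hydrolytic):
        pid = f"hyd_{i:04d}"
        seq, span = sample_sequence_from_profile(models["sialidase"], rng,
                                                 flank_range=spec.flank_range)
        records.append((pid, seq))
        truth_rows.append({"protein_id": pid, "label": "HYDROLYTIC_TYPE",
                           "has_cbm40": False,
                           "idomain_start": 0, "idomain_end": 0})
    for i in range(spec.n_background):
        pid = f"bg_{i:04d}"
        length = int(rng.integers(spec.background_length[0], spec.background_length[1] + 1))
        records.append((pid, random_background(rng, length)))
        truth_rows.append({"protein_id": pid, "label": "NONE", "has_cbm40": False,
                           "idomain_start": 0, "idomain_end": 0})
    truth = pd.DataFrame(truth_rows)
    return records, truth


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

@dataclass
class GenomeTableSpec:
    """Counts of strains per planted category.

    clustered: NanA/K/E1 within a window span <= 15 (IT protein planted);
    wide: the triplet at span > 15 (unclustered only); scattered: the
    triplet across two replicons; bacteroides: NanA + NanE2 + RokA; empty:
    decoy genes only.
    """

    n_clustered: int = 6
    n_wide: int = 4
    n_scattered: int = 3
    n_bacteroides: int = 4
    n_empty: int = 3
    n_decoy_genes: int = 30
    it_fraction_clustered: float = 1.0
    it_fraction_other: float = 0.0
    window: int = 15
    seed: int = 0


def make_genome_table(
    spec: GenomeTableSpec,
    seed: int | None = None,
) -> tuple[list[GeneLocus], dict[str, dict[str, set[str]]], pd.DataFrame]:
    """Gene tables with planted Nan gene sets and per-strain truth flags.

    Returns all loci, per-strain protein-role truth (protein_id -> roles),
    and a truth table with the expected pathway flags per strain.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    loci: list[GeneLocus] = []
    roles: dict[str, dict[str, set[str]]] = {}
    rows = []

    plan = ([("clustered", spec.it_fraction_clustered)] * spec.n_clustered
            + [("wide", spec.it_fraction_other)] * spec.n_wide
            + [("scattered", spec.it_fraction_other)] * spec.n_scattered
            + [("bacteroides", spec.it_fraction_other)] * spec.n_bacteroides
            + [("empty", spec.it_fraction_other)] * spec.n_empty)

    for si, (category, it_p) in enumerate(plan):
        strain = f"strain_{si:03d}"
        sroles: dict[str, set[str]] = {}
        n = spec.n_decoy_genes
        it_positive = bool(rng.random() < it_p)

        def pid(rep, idx):
            return f"{strain}_{rep}_g{idx:03d}"

        reps = {"r1": n, "r2": max(6, n // 3)}
        placements: dict[tuple[str, int], set[str]] = {}
        if category in ("clustered", "wide"):
            span = int(rng.integers(3, spec.window + 1)) if category == "clustered" \
                else int(rng.integers(spec.window + 1, spec.window + 8))
            start = int(rng.integers(1, n - span))
            mid = int(rng.integers(start + 1, start + span - 1))
            placements[("r1", start)] = {"NanA"}
            placements[("r1", mid)] = {"NanK"}
            placements[("r1", start + span - 1)] = {"NanE1"}
            expected = {"canonical_clustered": category == "clustered",
                        "canonical_unclustered": True, "bacteroides_type": False}
        elif category == "scattered":
            placements[("r1", int(rng.integers(1, n // 2)))] = {"NanA"}
            placements[("r1", int(rng.integers(n // 2 + 1, n + 1)))] = {"NanK"}
            placements[("r2", int(rng.integers(1, reps["r2"] + 1)))] = {"NanE1"}
            expected = {"canonical_clustered": False,
                        "canonical_unclustered": True, "bacteroides_type": False}
        elif category == "bacteroides":
            idxs = rng.choice(np.arange(1, n + 1), size=3, replace=False)
            for idx, role in zip(idxs, ("NanA", "NanE2", "RokA")):
                placements[("r1", int(idx))] = {role}
            expected = {"canonical_clustered": False,
                        "canonical_unclustered": False, "bacteroides_type": True}
        else:
            expected = {"canonical_clustered": False,
                        "canonical_unclustered": False, "bacteroides_type": False}

        if it_positive:
            placements.setdefault(("r2", int(rng.integers(1, reps["r2"] + 1))), set()).update(
                {"sialidase", "I-domain"})

        for rep, count in reps.items():
            for idx in range(1, count + 1):
                p = pid(rep, idx)
                loci.append(GeneLocus(strain_id=strain, replicon_id=rep,
                                      locus_index=idx, protein_id=p,
                                      strand="+" if rng.random() < 0.5 else "-"))
                r = placements.get((rep, idx))
                if r:
                    sroles[p] = set(r)
        roles[strain] = sroles
        rows.append({"strain_id": strain, "category": category,
                     "it_positive": it_positive, **expected})

    return loci, roles, pd.DataFrame(rows)


def make_strain_proteomes(
    loci: list[GeneLocus],
    roles: dict[str, dict[str, set[str]]],
    models: dict[str, ProfileHMM] | None = None,
    seed: int = 0,
    decoy_length: tuple[int, int] = (100, 300),
) -> dict[str, list[tuple[str, str]]]:
    """Protein sequences for every gene in a synthetic gene table.

    Role-carrying genes are emitted from the matching profile (a gene with
    both sialidase and I-domain roles becomes an IT construct, with a CBM40
    module when that role is also present); other genes are background
    decoys.  Keyed by strain id, record ids match the gene table.
    """
    models = models if models is not None else default_models()
    rng = np.random.default_rng(seed)
    out: dict[str, list[tuple[str, str]]] = {}
    for locus in loci:
        sroles = roles.get(locus.strain_id, {}).get(locus.protein_id, set())
        if {"sialidase", "I-domain"} <= sroles:
            seq, _ = make_it_protein(models, rng, with_cbm40="CBM40" in sroles)
        elif sroles:
            parts = []
            for role in sorted(sroles):
                if role in models:
                    parts.append(_walk_segment(models[role], rng, 1, models[role].length))
            seq = (random_background(rng, 20) + random_background(rng, 5).join(parts)
                   + random_background(rng, 20)) if parts \
                else random_background(rng, int(rng.integers(*decoy_length)))
        else:
            seq = random_background(rng, int(rng.integers(decoy_length[0],
                                                          decoy_length[1] + 1)))
        out.setdefault(locus.strain_id, []).append((locus.protein_id, seq))
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    n_samples: int
    mean_sequences: float
    p_positive: float            # per-sample probability of >=1 IT hit
    hit_lambda: float = 0.5      # hits | positive ~ 1 + Poisson(hit_lambda)
    sialidase_rate: float = 25.0  # extra sialidase-only hits ~ Poisson(rate)
    sequence_dispersion: float = 0.1  # CV of per-sample sequence counts
    mean_protein_length: float = 212.0  # -> ~637 bp coding sequences

    def __post_init__(self):
        if not 0.0 <= self.p_positive <= 1.0:
            raise SyntheticDataError("p_positive must be in [0, 1]")
        if self.n_samples < 1:
            raise SyntheticDataError("need n_samples >= 1")


@dataclass
class CohortSpec:
    groups: dict[str, GroupSpec] = field(default_factory=dict)
    seed: int = 0


def make_cohort(
    spec: CohortSpec,
    sequence_level: bool = False,
    models: dict[str, ProfileHMM] | None = None,
) -> tuple[list[SampleSummary], dict[str, list[tuple[str, str]]] | None]:
    """Cohort samples with planted hit counts (and optionally sequences).

    Count-level output is always produced.  With ``sequence_level=True`` a
    per-sample protein FASTA is also generated — planted IT constructs for
    I-domain hits and hydrolytic constructs for the remaining sialidase hits
    — refused above 10,000 sequences per sample (use count-level mode for
    larger cohorts).
    """
    rng = np.random.default_rng(spec.seed)
    samples: list[SampleSummary] = []
    fastas: dict[str, list[tuple[str, str]]] | None = {} if sequence_level else None
    if sequence_level and models is None:
        models = default_models()

    for group, g in spec.groups.items():
        for i in range(g.n_samples):
            sid = f"{group}_s{i:04d}"
            n_seq = max(1, int(round(rng.normal(g.mean_sequences,
                                                g.sequence_dispersion * g.mean_sequences))))
            positive = rng.random() < g.p_positive
            ido = int(1 + rng.poisson(g.hit_lambda)) if positive else 0
            sial = ido + int(rng.poisson(g.sialidase_rate))
            sial = min(sial, n_seq)
            ido = min(ido, sial)
            mean_bp = 3.0 * g.mean_protein_length
            samples.append(SampleSummary(sample_id=sid, group=group,
                                         n_sequences=float(n_seq), mean_bp=mean_bp,
                                         hits={"sialidase": float(sial),
                                               "I-domain": float(ido)}))
            if sequence_level:
                if n_seq > 10_000:
                    raise SyntheticDataError(
                        "sequence-level cohorts are limited to 10,000 sequences per "
                        "sample; use count-level mode for larger cohorts")
                recs: list[tuple[str, str]] = []
                for j in range(ido):
                    seq, _ = make_it_protein(models, rng, with_cbm40=rng.random() < 0.75)
                    recs.append((f"{sid}_it{j}", seq))
                for j in range(sial - ido):
                    seq, _ = sample_sequence_from_profile(models["sialidase"], rng)
                    recs.append((f"{sid}_hyd{j}", seq))
                mean_len = int(round(g.mean_protein_length))
                for j in range(n_seq - sial):
                    length = max(30, int(rng.normal(mean_len, 0.3 * mean_len)))
                    recs.append((f"{sid}_bg{j}", random_background(rng, length)))
                fastas[sid] = recs
    return samples, fastas


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def make_kinetic_dataset(
    model: str,
    true_params: dict,
    design: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_mode: str = "absolute",
):
    """Evaluate a named kinetic model at the design points plus Gaussian noise.

    ``model`` is one of substrate_inhibition, michaelis_menten, progress,
    ic50.  With ``noise_mode="absolute"`` the noise sd is in response units
    (relative to S0 for the progress model); with ``"relative"`` it is a
    coefficient of variation, i.e. sd proportional to the true response.
    Returns the dataset object the corresponding fitter consumes.
    """
    if noise_sd < 0:
        raise SyntheticDataError("noise_sd must be >= 0")
    if noise_mode not in ("absolute", "relative"):
        raise SyntheticDataError(f"unknown noise mode {noise_mode!r}")
    rng = np.random.default_rng(seed)
    design = np.asarray(design, dtype=float)

    def _noisy(y):
        if not noise_sd:
            return y
        sd = noise_sd * np.abs(y) if noise_mode == "relative" else noise_sd
        return y + rng.normal(0, 1, size=y.shape) * sd

    if model == "substrate_inhibition":
        v = _noisy(substrate_inhibition_rate(design, true_params["vmax"],
                                             true_params["km"], true_params["ki"]))
        return RateDataset(substrate_conc=design, rate=v,
                           enzyme_conc=true_params.get("enzyme_conc"),
                           enzyme_conc_unit=true_params.get("enzyme_conc_unit", "nM"))
    if model == "michaelis_menten":
        v = _noisy(michaelis_menten_rate(design, true_params["vmax"], true_params["km"]))
        return RateDataset(substrate_conc=design, rate=v,
                           enzyme_conc=true_params.get("enzyme_conc"),
                           enzyme_conc_unit=true_params.get("enzyme_conc_unit", "nM"))
    if model == "progress":
        S0 = float(true_params["S0"])
        k = float(true_params["k"])
        St = S0 * np.exp(-k * design)
        if noise_sd:
            St = np.clip(St + rng.normal(0, noise_sd * S0, size=St.shape), 1e-12, None)
        return ProgressCurve(time=design, substrate_remaining=St, S0=S0,
                             enzyme_conc=true_params.get("enzyme_conc"),
                             enzyme_conc_unit=true_params.get("enzyme_conc_unit", "nM"))
    if model == "ic50":
        logic50 = float(true_params["log_ic50"])
        with np.errstate(divide="ignore"):
            y = np.where(design > 0,
                         100.0 / (1.0 + 10.0 ** (np.log10(np.where(design > 0, design, 1.0))
                                                 - logic50)),
                         100.0)
        if noise_sd:
            y = y + rng.normal(0, noise_sd, size=y.shape)
        return design, y
    raise SyntheticDataError(f"unknown kinetic model {model!r}")
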