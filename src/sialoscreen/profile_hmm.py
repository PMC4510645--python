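"""Profile hidden Markov models for protein domains.

A small Plan7-style engine: models are built from seed alignments, scored
against targets with local-mode Viterbi (uniform entry/exit over match
states, unaligned flanks emitted from the background and contributing zero
bits), calibrated against random background sequences to obtain Gumbel
E-value statistics, and searched iteratively with envelope masking so that a
single target can carry several non-overlapping domain hits.  The masked,
multi-hit search is what lets a GH33 sialidase domain interrupted by an
inserted I-domain show up as a *segmented* match (two sub-hits bracketing
the insertion) instead of one contiguous alignment.

Scores are log-odds in bits.  The per-domain E-value of a hit with bit score
``s`` against a search space of ``N`` sequences is ``N * SF(s)`` where SF is
the survival function of the calibrated Gumbel law; hits with E-value
strictly greater than the configured threshold (default 1e-4) are discarded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP_CHARS = set("-.")

_NEG = -np.inf


class ProfileHMMError(ValueError):
    """Invalid model, alignment or search input."""


class AlignmentError(ProfileHMMError):
    """Seed alignment cannot be turned into a profile."""


class CalibrationError(ProfileHMMError):
    """E-value calibration failed or is missing."""


@dataclass(frozen=True)
class GumbelParams:
    """Gumbel (EVD type I) bit-score statistics: SF(s) = 1 - exp(-exp(-lambda*(s-mu)))."""

    mu: float
    lam: float
    n_random: int
    random_length: int
    seed: int

    def __post_init__(self):
        if self.lam <= 0:
            raise CalibrationError("Gumbel lambda must be > 0")
        if self.n_random < 100:
            raise CalibrationError("calibration needs n_random >= 100")

    def survival(self, bit_score: float | np.ndarray) -> float | np.ndarray:
        return stats.gumbel_r.sf(bit_score, loc=self.mu, scale=1.0 / self.lam)


@dataclass(frozen=True)
class DomainHit:
    """One scored local match of a profile on a target protein.

    Coordinates are 1-based inclusive: ``target_start..target_end`` on the
    protein, ``model_start..model_end`` over match states.
    """

    model_name: str
    target_id: str
    target_start: int
    target_end: int
    model_start: int
    model_end: int
    bit_score: float
    evalue: float

    def __post_init__(self):
        if self.target_start > self.target_end:
            raise ProfileHMMError("target_start > target_end")
        if self.model_start > self.model_end:
            raise ProfileHMMError("model_start > model_end")
        if self.evalue < 0:
            raise ProfileHMMError("negative E-value")

    @property
    def target_span(self) -> tuple[int, int]:
        return (self.target_start, self.target_end)


@dataclass(eq=False)
class ProfileHMM:
    """A match/insert/delete profile over the 20 standard amino acids.

    ``match_emissions`` and ``insert_emissions`` have shape (length, 20),
    row ``k-1`` belonging to node ``k`` (nodes are 1-based).  ``transitions``
    maps each of the seven Plan7 core transitions ('MM','MI','MD','IM','II',
    'DM','DD') to a vector of length ``length`` whose entry ``k-1`` is the
    probability of moving from node ``k`` to node ``k+1`` (the last row is
    unused: node L only exits).
    """

    name: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: dict[str, np.ndarray]
    background: np.ndarray
    calibration: GumbelParams | None = None

    TRANSITION_KEYS = ("MM", "MI", "MD", "IM", "II", "DM", "DD")

    def __post_init__(self):
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.transitions = {k: np.asarray(v, dtype=float) for k, v in self.transitions.items()}
        self.validate()
        self._cache: dict | None = None

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        L = self.match_emissions.shape[0]
        if L < 1:
            raise ProfileHMMError("model length must be >= 1")
        for arr, nm in ((self.match_emissions, "match"), (self.insert_emissions, "insert")):
            if arr.shape != (L, 20):
                raise ProfileHMMError(f"{nm} emissions must have shape ({L}, 20)")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ProfileHMMError(f"{nm} emissions must sum to 1")
            if (arr < 0).any():
                raise ProfileHMMError(f"negative {nm} emission")
        if self.background.shape != (20,) or not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ProfileHMMError("background must be a distribution over 20 residues")
        for key in self.TRANSITION_KEYS:
            if key not in self.transitions or self.transitions[key].shape != (L,):
                raise ProfileHMMError(f"missing or malformed transition vector {key}")
        if L > 1:
            core = slice(0, L - 1)
            for group in (("MM", "MI", "MD"), ("IM", "II"), ("DM", "DD")):
                tot = sum(self.transitions[k][core] for k in group)
                if not np.allclose(tot, 1.0, atol=1e-9):
                    raise ProfileHMMError(f"outgoing transitions {group} must sum to 1")

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))

    def _scoring(self) -> dict:
        """Cached log2-odds emissions and log2 transitions."""
        if self._cache is None:
            with np.errstate(divide="ignore"):
                lodM = np.log2(self.match_emissions) - np.log2(self.background)
                lodI = np.log2(self.insert_emissions) - np.log2(self.background)
                lt = {k: np.log2(v) for k, v in self.transitions.items()}
            self._cache = {"lodM": lodM, "lodI": lodI, "lt": lt,
                           "entry": -math.log2(self.length)}
        return self._cache

    # -- serialization -------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format": "sialoscreen-profile-1",
            "name": self.name,
            "alphabet": AMINO_ACIDS,
            "length": self.length,
            "log_match_emissions": _safe_log(self.match_emissions).tolist(),
            "log_insert_emissions": _safe_log(self.insert_emissions).tolist(),
            "log_transitions": {k: _safe_log(v).tolist() for k, v in self.transitions.items()},
            "log_background": _safe_log(self.background).tolist(),
            "calibration": asdict(self.calibration) if self.calibration else None,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ProfileHMM":
        text = Path(source).read_text() if isinstance(source, Path) or "\n" not in str(source) and Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        cal = doc.get("calibration")
        return cls(
            name=doc["name"],
            match_emissions=np.exp(np.asarray(doc["log_match_emissions"])),
            insert_emissions=np.exp(np.asarray(doc["log_insert_emissions"])),
            transitions={k: np.exp(np.asarray(v)) for k, v in doc["log_transitions"].items()},
            background=np.exp(np.asarray(doc["log_background"])),
            calibration=GumbelParams(**cal) if cal else None,
        )


def _safe_log(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(np.asarray(p, dtype=float))


def encode_sequence(seq: str) -> np.ndarray:
    try:
        return np.fromiter((AA_INDEX[c] for c in seq.upper()), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ProfileHMMError(f"non-standard residue {exc} in sequence") from None


# ---------------------------------------------------------------------------
# Model building
# ---------------------------------------------------------------------------

def build_profile(
    msa: Sequence[tuple[str, str]] | Sequence[str],
    gap_threshold: float = 0.5,
    pseudocount_mass: float = 1.0,
    name: str = "profile",
    background: np.ndarray | str | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from an aligned set of protein sequences.

    Columns whose gap fraction is <= ``gap_threshold`` become match states,
    in order.  Emissions are smoothed column frequencies,
    ``(counts + pseudocount_mass * background) / (total + pseudocount_mass)``;
    transitions are estimated from per-row state paths with the analogous
    uniform-prior smoothing.  ``background`` may be a 20-vector, the string
    ``"alignment"`` (observed residue frequencies), or None (uniform 1/20).
    """
    rows = [s if isinstance(s, str) else s[1] for s in msa]
    if len(rows) < 2:
        raise AlignmentError("alignment needs at least 2 rows")
    ncol = len(rows[0])
    if ncol == 0 or any(len(r) != ncol for r in rows):
        raise AlignmentError("alignment rows must be non-empty and equal length")
    rows = [r.upper() for r in rows]
    for r in rows:
        bad = set(r) - set(AMINO_ACIDS) - GAP_CHARS
        if bad:
            raise AlignmentError(f"non-amino-acid symbols in alignment: {sorted(bad)}")

    mat = np.array([[(-1 if c in GAP_CHARS else AA_INDEX[c]) for c in r] for r in rows])
    gap_frac = (mat < 0).mean(axis=0)
    is_match = gap_frac <= gap_threshold
    match_cols = np.flatnonzero(is_match)
    L = len(match_cols)
    if L == 0:
        raise AlignmentError("alignment has no match columns at this gap threshold")

    if background is None:
        bg = np.full(20, 1.0 / 20)
    elif isinstance(background, str) and background == "alignment":
        counts = np.bincount(mat[mat >= 0].ravel(), minlength=20).astype(float)
        if counts.sum() == 0:
            raise AlignmentError("alignment has no residues")
        bg = counts / counts.sum()
    else:
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()

    # emissions
    memit = np.empty((L, 20))
    for j, col in enumerate(match_cols):
        colv = mat[:, col]
        counts = np.bincount(colv[colv >= 0], minlength=20).astype(float)
        memit[j] = (counts + pseudocount_mass * bg) / (counts.sum() + pseudocount_mass)

    # node of each insert column = number of match columns to its left
    node_of_col = np.cumsum(is_match)
    iemit = np.tile(bg, (L, 1)).copy()
    icounts = np.zeros((L, 20))
    for col in np.flatnonzero(~is_match):
        k = node_of_col[col]
        if 1 <= k <= L - 1:
            colv = mat[:, col]
            icounts[k - 1] += np.bincount(colv[colv >= 0], minlength=20)
    for k in range(L - 1):
        tot = icounts[k].sum()
        if tot > 0:
            iemit[k] = (icounts[k] + pseudocount_mass * bg) / (tot + pseudocount_mass)

    # transitions from per-row state paths
    tcount = {k: np.zeros(L) for k in ProfileHMM.TRANSITION_KEYS}
    for r in range(len(rows)):
        path = []  # (state, node) with node 1..L; inserts before node 1/after node L dropped
        for col in range(ncol):
            v = mat[r, col]
            if is_match[col]:
                k = node_of_col[col]
                path.append(("M" if v >= 0 else "D", k))
            elif v >= 0:
                k = node_of_col[col]
                if 1 <= k <= L - 1:
                    path.append(("I", k))
        for (s1, k1), (s2, k2) in zip(path, path[1:]):
            if s1 == "I":
                if s2 == "I" and k1 == k2:
                    tcount["II"][k1 - 1] += 1
                elif k2 == k1 + 1:  # I->D is not in the Plan7 core; fold into I->M
                    tcount["IM"][k1 - 1] += 1
            elif s2 == "I" and k2 == k1:
                if s1 == "M":
                    tcount["MI"][k1 - 1] += 1
                # D->I is not modelled; dropped
            elif k2 == k1 + 1 and s1 in "MD" and s2 in "MD":
                tcount[s1 + s2][k1 - 1] += 1

    trans = {k: np.zeros(L) for k in ProfileHMM.TRANSITION_KEYS}
    groups = (("MM", "MI", "MD"), ("IM", "II"), ("DM", "DD"))
    for k in range(L - 1):
        for group in groups:
            tot = sum(tcount[g][k] for g in group)
            for g in group:
                trans[g][k] = (tcount[g][k] + pseudocount_mass / len(group)) / (tot + pseudocount_mass)
    # node L rows are unused; keep them normalised for tidiness
    for group in groups:
        for g in group:
            trans[g][L - 1] = 1.0 / len(group)

    return ProfileHMM(name=name, match_emissions=memit, insert_emissions=iemit,
                      transitions=trans, background=bg)


# ---------------------------------------------------------------------------
# Viterbi scoring
# ---------------------------------------------------------------------------

def _viterbi_fill(model: ProfileHMM, x: np.ndarray, mask: np.ndarray | None):
    """Fill local-mode Viterbi matrices.  Returns (VM, VI, VD, best, i*, k*)."""
    sc = model._scoring()
    L = model.length
    n = len(x)
    lodM, lodI, lt, entry = sc["lodM"], sc["lodI"], sc["lt"], sc["entry"]
    tMM, tMI, tMD = lt["MM"], lt["MI"], lt["MD"]
    tIM, tII = lt["IM"], lt["II"]
    tDM, tDD = lt["DM"], lt["DD"]
    # cumulative log tDD for the in-row delete scan: C[k] = sum_{m<=k} tDD[m-1], C[0]=0
    C = np.concatenate(([0.0], np.cumsum(tDD)))  # length L+1; C[k]-C[j] = tDD chain j+1..k

    VM = np.full((n + 1, L + 1), _NEG)
    VI = np.full((n + 1, L + 1), _NEG)
    VD = np.full((n + 1, L + 1), _NEG)
    best = _NEG
    bi = bk = -1
    for i in range(1, n + 1):
        xi = x[i - 1]
        if mask is not None and mask[i - 1]:
            continue  # masked residue: no emitting state may use it
        em = lodM[:, xi]  # node k -> em[k-1]
        prevM, prevI, prevD = VM[i - 1], VI[i - 1], VD[i - 1]
        # M: from M/I/D at node k-1, or fresh local entry
        cont = np.maximum(prevM[:L] + np.concatenate(([_NEG], tMM[: L - 1])),
                          np.maximum(prevI[:L] + np.concatenate(([_NEG], tIM[: L - 1])),
                                     prevD[:L] + np.concatenate(([_NEG], tDM[: L - 1]))))
        VM[i, 1:] = em + np.maximum(cont, entry)
        # I: node k = 1..L-1
        if L > 1:
            emI = lodI[: L - 1, xi]
            VI[i, 1:L] = emI + np.maximum(prevM[1:L] + tMI[: L - 1], prevI[1:L] + tII[: L - 1])
        # D within the same row: VD[i,k] = C[k-1] + cummax_j<=k-1 (VM[i,j]+tMD[j-1]-C[j])
        if L > 1:
            A = VM[i, 1:L] + tMD[: L - 1] - C[1:L]
            VD[i, 2:] = C[1:L] + np.maximum.accumulate(A)
        rowbest = VM[i, 1:].max()
        if rowbest > best:
            best = rowbest
            bi, bk = i, int(VM[i, 1:].argmax()) + 1
    return VM, VI, VD, best, bi, bk


_TOL = 1e-9


def _traceback(model: ProfileHMM, x: np.ndarray, VM, VI, VD, i: int, k: int):
    """Recover one optimal path ending at M_k consuming residue i.

    Tie-breaking prefers M over D over I over a fresh entry at equal score.
    Returns a list of (state, node, 1-based residue position or None).
    """
    sc = model._scoring()
    lt, entry = sc["lt"], sc["entry"]
    lodM, lodI = sc["lodM"], sc["lodI"]
    path = []
    state = "M"
    while True:
        if state == "M":
            path.append(("M", k, i))
            target = VM[i, k] - lodM[k - 1, x[i - 1]]
            if k > 1:
                cands = [("M", VM[i - 1, k - 1] + lt["MM"][k - 2]),
                         ("D", VD[i - 1, k - 1] + lt["DM"][k - 2]),
                         ("I", VI[i - 1, k - 1] + lt["IM"][k - 2])]
            else:
                cands = []
            cands.append(("^", entry))
            statep = _pick(cands, target)
            if statep == "^":
                break
            state = statep
            i, k = i - 1, k - 1  # all predecessors of M_k sit at node k-1, row i-1
        elif state == "I":
            path.append(("I", k, i))
            target = VI[i, k] - lodI[k - 1, x[i - 1]]
            cands = [("M", VM[i - 1, k] + lt["MI"][k - 1]),
                     ("I", VI[i - 1, k] + lt["II"][k - 1])]
            state = _pick(cands, target)
            i = i - 1
        else:  # D
            path.append(("D", k, None))
            target = VD[i, k]
            cands = [("M", VM[i, k - 1] + lt["MD"][k - 2]),
                     ("D", VD[i, k - 1] + lt["DD"][k - 2])]
            state = _pick(cands, target)
            k = k - 1
    path.reverse()
    return path


def _pick(cands, target):
    """Choose the candidate matching the DP cell value, preferring M > D > I > entry."""
    order = {"M": 0, "D": 1, "I": 2, "^": 3}
    best_val = max(v for _, v in cands)
    # guard against drift between the vectorised fill and scalar recomputation
    ok = [s for s, v in cands if v >= best_val - _TOL and v >= target - 1e-6]
    if not ok:
        ok = [s for s, v in cands if v >= best_val - _TOL]
    return min(ok, key=order.__getitem__)


def viterbi_score(
    model: ProfileHMM,
    seq: str,
    mask: np.ndarray | None = None,
    with_path: bool = True,
):
    """Best local log-odds alignment of ``seq`` to ``model``.

    Returns ``(bit_score, path)`` where ``path`` is a list of
    ``(state, node, residue_position)`` triples (position is 1-based, None
    for delete states), or ``(bit_score, None)`` when ``with_path=False``.
    A score of ``-inf`` means no residue may align (fully masked sequence).
    """
    if len(seq) == 0:
        raise ProfileHMMError("cannot score an empty sequence")
    x = encode_sequence(seq) if isinstance(seq, str) else np.asarray(seq)
    VM, VI, VD, best, bi, bk = _viterbi_fill(model, x, mask)
    if not with_path or not np.isfinite(best):
        return best, None
    # deterministic end cell: smallest i, then smallest k, achieving the max
    finite = np.argwhere(VM[:, 1:] >= best - _TOL)
    bi, bk = int(finite[0][0]), int(finite[0][1]) + 1
    path = _traceback(model, x, VM, VI, VD, bi, bk)
    return best, path


def path_envelope(path) -> tuple[int, int, int, int]:
    """(target_start, target_end, model_start, model_end) of an alignment path."""
    pos = [p for _, _, p in path if p is not None]
    nodes = [k for s, k, _ in path if s in "MD"]
    return min(pos), max(pos), min(nodes), max(nodes)


# ---------------------------------------------------------------------------
# Calibration and search
# ---------------------------------------------------------------------------

def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (mu, lambda = 1/scale)."""
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) < 1e-12:
        raise CalibrationError("degenerate score distribution: all scores equal")
    loc, scale = stats.gumbel_r.fit(scores)
    return float(loc), float(1.0 / scale)


def calibrate(
    model: ProfileHMM,
    n_random: int = 1000,
    random_length: int | None = None,
    seed: int = 421,
) -> GumbelParams:
    """Fit Gumbel bit-score statistics on i.i.d. background sequences.

    Scores ``n_random`` random sequences of ``random_length`` residues drawn
    from the model background and fits a Gumbel law by maximum likelihood.
    Deterministic given ``seed``; the parameters are stored on the model.
    """
    if n_random < 100:
        raise CalibrationError("calibration needs n_random >= 100")
    if random_length is None:
        random_length = 2 * model.length
    rng = np.random.default_rng(seed)
    draws = rng.choice(20, size=(n_random, random_length), p=model.background)
    scores = np.array([viterbi_score(model, row, with_path=False)[0] for row in draws])
    mu, lam = fit_gumbel(scores)
    params = GumbelParams(mu=mu, lam=lam,
                          n_random=n_random, random_length=random_length, seed=seed)
    model.calibration = params
    return params


def evalue_of(model: ProfileHMM, bit_score: float, search_space: int) -> float:
    if model.calibration is None:
        raise CalibrationError(f"model {model.name!r} is not calibrated")
    return float(search_space * model.calibration.survival(bit_score))


def search_domains(
    model: ProfileHMM,
    targets: Iterable[tuple[str, str]],
    max_evalue: float = 1e-4,
    search_space: int | None = None,
    max_rounds: int = 10,
) -> list[DomainHit]:
    """All domain hits of ``model`` in ``targets`` with E-value <= ``max_evalue``.

    Per target the best local Viterbi alignment is found, its envelope
    masked, and the search repeated (at most ``max_rounds`` times) until the
    score no longer passes the threshold, so tandem copies and segmented
    (insertion-split) domains yield multiple disjoint hits.  ``search_space``
    defaults to the number of target sequences.  Hits are sorted by E-value.
    """
    if model.calibration is None:
        raise CalibrationError(f"model {model.name!r} is not calibrated; run calibrate() first")
    targets = list(targets)
    N = search_space if search_space is not None else max(1, len(targets))
    if N < 1:
        raise ProfileHMMError("search_space must be >= 1")
    hits: list[DomainHit] = []
    for target_id, seq in targets:
        if len(seq) == 0:
            continue
        x = encode_sequence(seq)
        mask = np.zeros(len(seq), dtype=bool)
        for _ in range(max_rounds):
            bits, path = viterbi_score(model, x, mask=mask)
            if path is None:
                break
            ev = evalue_of(model, bits, N)
            if ev > max_evalue:
                break
            ts, te, ms, me = path_envelope(path)
            hits.append(DomainHit(model_name=model.name, target_id=target_id,
                                  target_start=ts, target_end=te,
                                  model_start=ms, model_end=me,
                                  bit_score=float(bits), evalue=ev))
            mask[ts - 1:te] = True
            if mask.all():
                break
    hits.sort(key=lambda h: (h.evalue, h.target_id, h.target_start))
    return hits


# ---------------------------------------------------------------------------
# File I/O: alignments, FASTA targets, HMMER3 ASCII import, hit tables
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, fmt: str | None = None) -> list[tuple[str, str]]:
    """Read a seed alignment (aligned FASTA or Stockholm) as (id, row) pairs."""
    from Bio import AlignIO

    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in {".sto", ".stk", ".stockholm"} else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return [(rec.id, str(rec.seq)) for rec in aln]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read protein FASTA; record ids are truncated at the first whitespace."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_hmmer3(path: str | Path) -> ProfileHMM:
    """Import a HMMER3/f ASCII profile (emissions and core transitions only).

    Values in the file are negative natural logs of probabilities ('*' is
    probability zero).  A ``STATS LOCAL VITERBI`` line, when present, seeds
    the Gumbel calibration (mu, lambda in bit units, as HMMER writes them).
    """
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    name, L, stats_line = "hmmer_profile", None, None
    alpha_order = None
    for line in it:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "NAME":
            name = tok[1]
        elif tok[0] == "LENG":
            L = int(tok[1])
        elif tok[0] == "ALPH" and tok[1].lower() != "amino":
            raise ProfileHMMError("only amino-acid HMMER profiles are supported")
        elif tok[0] == "STATS" and len(tok) >= 5 and tok[2] == "VITERBI":
            stats_line = (float(tok[3]), float(tok[4]))
        elif tok[0] == "HMM":
            alpha_order = tok[1:21]
            next(it)  # transition header line
            break
    if L is None or alpha_order is None:
        raise ProfileHMMError("not a HMMER3 ASCII profile")
    perm = [AA_INDEX[a] for a in alpha_order]

    def probs(fields):
        out = np.zeros(len(fields))
        for i, f in enumerate(fields):
            out[i] = 0.0 if f == "*" else math.exp(-float(f))
        return out

    memit = np.zeros((L, 20))
    iemit = np.zeros((L, 20))
    trans = {k: np.zeros(L) for k in ProfileHMM.TRANSITION_KEYS}
    compo = None
    rows = [ln.split() for ln in it if ln.split()]
    i = 0
    if rows[i][0] == "COMPO":
        compo = probs(rows[i][1:21])
        i += 1
    i += 2  # node-0 insert emission and transition lines
    for k in range(1, L + 1):
        m = rows[i]; ins = rows[i + 1]; tr = rows[i + 2]
        i += 3
        p = probs(m[1:21])
        memit[k - 1][perm] = p
        memit[k - 1] /= memit[k - 1].sum()
        p = probs(ins[:20])
        iemit[k - 1][perm] = p
        iemit[k - 1] /= iemit[k - 1].sum()
        tv = probs(tr[:7])  # MM MI MD IM II DM DD
        for j, key in enumerate(ProfileHMM.TRANSITION_KEYS):
            trans[key][k - 1] = tv[j]
    # renormalise core transitions; last node keeps placeholders
    for k in range(L - 1):
        for group in (("MM", "MI", "MD"), ("IM", "II"), ("DM", "DD")):
            tot = sum(trans[g][k] for g in group)
            if tot > 0:
                for g in group:
                    trans[g][k] /= tot
    for group in (("MM", "MI", "MD"), ("IM", "II"), ("DM", "DD")):
        for g in group:
            trans[g][L - 1] = 1.0 / len(group)
    bg = compo / compo.sum() if compo is not None else np.full(20, 1 / 20)
    bg_full = np.zeros(20)
    if compo is not None:
        bg_full[perm] = compo
        bg = bg_full / bg_full.sum()
    model = ProfileHMM(name=name, match_emissions=memit, insert_emissions=iemit,
                       transitions=trans, background=bg)
    if stats_line is not None:
        model.calibration = GumbelParams(mu=stats_line[0], lam=stats_line[1],
                                         n_random=100, random_length=0, seed=0)
    return model


HIT_COLUMNS = ["model_name", "target_id", "target_start", "target_end",
               "model_start", "model_end", "bit_score", "evalue"]


def hits_to_table(hits: Sequence[DomainHit]):
    import pandas as pd

    return pd.DataFrame([asdict(h) for h in hits], columns=HIT_COLUMNS)


def hits_from_table(df) -> list[DomainHit]:
    return [DomainHit(**{c: row[c] for c in HIT_COLUMNS}) for _, row in df.iterrows()]
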