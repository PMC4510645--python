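"""Per-protein sialidase architecture calls.

Hydrolytic-type sialidases carry a contiguous GH33 catalytic domain;
intramolecular trans-sialidases (IT-sialidases) carry a GH33 domain split
around an inserted I-domain.  The primary IT criterion is the co-occurrence
of a sialidase-domain hit and an I-domain hit on the same protein; a
*segmented* sialidase match (two sub-hits whose model coordinates are in
order, separated by a target gap that houses the I-domain) is recorded as
corroborating evidence but is not required — fragmentary coding sequences in
draft genomes can truncate one sub-hit.  A CBM40 (sialic-acid-binding
module) hit is annotated independently and never makes a sialidase on its
own.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

from .profile_hmm import DomainHit

SIALIDASE_MODEL = "sialidase"
IDOMAIN_MODEL = "I-domain"
CBM40_MODEL = "CBM40"


class Call(str, enum.Enum):
    NONE = "NONE"
    HYDROLYTIC_TYPE = "HYDROLYTIC_TYPE"
    IT_SIALIDASE = "IT_SIALIDASE"


class ArchitectureError(ValueError):
    pass


@dataclass
class ArchitectureCall:
    target_id: str
    call: Call
    has_sialidase: bool
    has_idomain: bool
    has_cbm40: bool
    segmented: bool
    gap_interval: tuple[int, int] | None
    evidence: list[DomainHit] = field(default_factory=list)

    def __post_init__(self):
        if self.call is Call.IT_SIALIDASE and not (self.has_sialidase and self.has_idomain):
            raise ArchitectureError("IT call requires sialidase and I-domain hits")
        if self.call is Call.HYDROLYTIC_TYPE and not (self.has_sialidase and not self.has_idomain):
            raise ArchitectureError("hydrolytic call requires sialidase without I-domain")
        if self.segmented and self.gap_interval is None:
            raise ArchitectureError("segmented call requires a gap interval")


def _overlap_fraction(span: tuple[int, int], interval: tuple[int, int]) -> float:
    """Fraction of 1-based inclusive ``span`` lying inside ``interval``."""
    lo = max(span[0], interval[0])
    hi = min(span[1], interval[1])
    if hi < lo:
        return 0.0
    return (hi - lo + 1) / (span[1] - span[0] + 1)


def detect_segmented_match(
    sialidase_hits: Sequence[DomainHit],
    idomain_hits: Sequence[DomainHit],
    gap_min: int = 30,
    idomain_overlap: float = 0.5,
) -> tuple[bool, tuple[int, int] | None]:
    """Detect a GH33 match split around an inserted I-domain.

    Segmented is true iff some pair of sialidase sub-hits has model
    coordinates in order (``first.model_end < second.model_start``), a
    target-side gap of at least ``gap_min`` residues between their
    envelopes, and at least ``idomain_overlap`` of some I-domain hit's
    envelope inside that gap.  Returns ``(flag, gap_interval)``; the gap is
    ``(first.target_end + 1, second.target_start - 1)``.
    """
    sial = sorted(sialidase_hits, key=lambda h: (h.target_start, h.target_end))
    for a in sial:
        for b in sial:
            if a is b or a.model_end >= b.model_start:
                continue
            gap = (a.target_end + 1, b.target_start - 1)
            if gap[1] - gap[0] + 1 < gap_min:
                continue
            for ido in idomain_hits:
                if _overlap_fraction(ido.target_span, gap) >= idomain_overlap:
                    return True, gap
    return False, None


def classify_architecture(
    hits: Sequence[DomainHit],
    sialidase_model: str = SIALIDASE_MODEL,
    idomain_model: str = IDOMAIN_MODEL,
    cbm40_model: str = CBM40_MODEL,
    gap_min: int = 30,
    idomain_overlap: float = 0.5,
    target_id: str | None = None,
) -> ArchitectureCall:
    """Classify one protein from its (already E-value-filtered) domain hits.

    IT_SIALIDASE iff the protein has >=1 sialidase hit and >=1 I-domain hit;
    HYDROLYTIC_TYPE iff it has sialidase hit(s) only; NONE otherwise.  The
    call is invariant to the ordering of ``hits``.  ``target_id`` is only
    needed for an empty hit list.
    """
    hits = sorted(hits, key=lambda h: (h.target_start, h.target_end, h.model_name))
    tids = {h.target_id for h in hits}
    if len(tids) > 1:
        raise ArchitectureError(f"hits span multiple targets: {sorted(tids)}")
    if not hits and target_id is None:
        raise ArchitectureError("no hits and no target_id given")
    tid = hits[0].target_id if hits else target_id

    sial = [h for h in hits if h.model_name == sialidase_model]
    ido = [h for h in hits if h.model_name == idomain_model]
    cbm = [h for h in hits if h.model_name == cbm40_model]

    if sial and ido:
        call = Call.IT_SIALIDASE
    elif sial:
        call = Call.HYDROLYTIC_TYPE
    else:
        call = Call.NONE

    segmented, gap = detect_segmented_match(sial, ido, gap_min=gap_min,
                                            idomain_overlap=idomain_overlap)
    return ArchitectureCall(
        target_id=tid,
        call=call,
        has_sialidase=bool(sial),
        has_idomain=bool(ido),
        has_cbm40=bool(cbm),
        segmented=segmented,
        gap_interval=gap,
        evidence=list(hits),
    )


def classify_proteome(
    hits: Sequence[DomainHit],
    all_target_ids: Sequence[str] | None = None,
    **kwargs,
) -> dict[str, ArchitectureCall]:
    """Group hits by target and classify each protein.

    Targets listed in ``all_target_ids`` but carrying no hits receive an
    explicit NONE call.
    """
    by_target: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_target.setdefault(h.target_id, []).append(h)
    calls = {tid: classify_architecture(hs, **kwargs) for tid, hs in by_target.items()}
    if all_target_ids is not None:
        for tid in all_target_ids:
            if tid not in calls:
                calls[tid] = classify_architecture([], target_id=tid, **kwargs)
    return calls


def calls_to_table(calls: dict[str, ArchitectureCall]):
    import pandas as pd

    rows = []
    for tid in sorted(calls):
        c = calls[tid]
        rows.append({
            "target_id": tid,
            "call": c.call.value,
            "has_sialidase": c.has_sialidase,
            "has_idomain": c.has_idomain,
            "has_cbm40": c.has_cbm40,
            "segmented": c.segmented,
            "gap_start": c.gap_interval[0] if c.gap_interval else "",
            "gap_end": c.gap_interval[1] if c.gap_interval else "",
        })
    return pd.DataFrame(rows, columns=["target_id", "call", "has_sialidase", "has_idomain",
                                       "has_cbm40", "segmented", "gap_start", "gap_end"])
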