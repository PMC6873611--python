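"""Per-protein domain architectures and native RING zinc-finger typing.

A domain architecture is the ordered, non-overlapping list of domains on one
protein, resolved from (possibly conflicting) external hits.  RING fingers
are the one domain detected natively, by matching the eight metal-ligand
grammar

    M1-x(2)-M2-x(9..39)-M3-x(1..3)-M4-x(2..3)-M5-x(2)-M6-x(4..48)-M7-x(2)-M8

where M1, M2, M3, M6, M7, M8 are cysteines, M4 may be C/H/G and M5 may be
C/H/S/T/G.  The residues at the 4th and 5th ligand positions (plus any
glycine substitution) decide the RING type: RING-HC (C3HC4), RING-H2
(C3H2C3), RING-C2, RING-v (swapped C/H), RING-S/T and RING-G.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .io_formats import DomainHit

logger = logging.getLogger(__name__)

RING_TYPES = ("RING-C2", "RING-G", "RING-HC", "RING-H2", "RING-S/T", "RING-v")

#: Allowed inter-ligand gap lengths (number of x residues between
#: consecutive ligands), M1-M2 through M7-M8.
RING_GAP_BOUNDS: tuple[tuple[int, int], ...] = (
    (2, 2), (9, 39), (1, 3), (2, 3), (2, 2), (4, 48), (2, 2)
)
M4_RESIDUES = frozenset("CHG")
M5_RESIDUES = frozenset("CHSTG")
#: Canonical M4-M5 spacing for the RING-HC call (configurable).
HC_CANONICAL_M4_M5 = (2, 3)

UNCLASSIFIED = "unclassified"


@dataclass
class DomainArchitecture:
    """Ordered, non-overlapping domains of one protein."""

    protein_id: str
    domains: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def domain_names(self) -> list[str]:
        return [d for d, _, _ in self.domains]

    def domain_string(self) -> str:
        return "+".join(self.domain_names)

    def __len__(self) -> int:
        return len(self.domains)


@dataclass
class RingDomainCall:
    """One RING grammar match: 8 ligand positions (1-based aa indices),
    their residues, the 7 inter-ligand spacings, and the type decision."""

    protein_id: str
    ligand_positions: tuple[int, ...]
    ligand_residues: str
    spacings: tuple[int, ...]
    ring_type: str = ""

    def __post_init__(self) -> None:
        if len(self.ligand_positions) != 8 or len(self.ligand_residues) != 8:
            raise ValueError("a RING call carries exactly 8 metal ligands")
        gaps = tuple(
            self.ligand_positions[i + 1] - self.ligand_positions[i] - 1
            for i in range(7)
        )
        if tuple(self.spacings) != gaps:
            raise ValueError("spacings inconsistent with ligand positions")
        if any(b <= a for a, b in zip(self.ligand_positions, self.ligand_positions[1:])):
            raise ValueError("ligand positions must be strictly increasing")

    @property
    def start(self) -> int:
        return self.ligand_positions[0]

    @property
    def end(self) -> int:
        return self.ligand_positions[-1]


# ---------------------------------------------------------------------------
# architecture resolution
# ---------------------------------------------------------------------------

def _hit_priority(h: DomainHit) -> tuple:
    # ascending E-value; ties: longer hit, then lexicographic name, then
    # position for full determinism
    return (h.evalue, -h.length, h.domain_name, h.start, h.end)


def build_architecture(hits: list[DomainHit]) -> DomainArchitecture:
    """Resolve overlapping hits of one protein into an architecture.

    Hits are admitted greedily in order of ascending E-value (ties: longer
    hit, then lexicographic domain name); a hit overlapping an already
    admitted hit is discarded.  Survivors are sorted by start.
    """
    if not hits:
        return DomainArchitecture(protein_id="")
    pids = {h.protein_id for h in hits}
    if len(pids) != 1:
        raise ValueError(f"hits span multiple proteins: {sorted(pids)}")
    kept: list[DomainHit] = []
    for h in sorted(hits, key=_hit_priority):
        if all(h.end < k.start or h.start > k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.end))
    return DomainArchitecture(
        protein_id=next(iter(pids)),
        domains=[(h.domain_name, h.start, h.end) for h in kept],
    )


# ---------------------------------------------------------------------------
# RING scanning
# ---------------------------------------------------------------------------

def _ring_regex() -> re.Pattern:
    (g1, g2, g3, g4, g5, g6, g7) = RING_GAP_BOUNDS
    m4 = "[" + "".join(sorted(M4_RESIDUES)) + "]"
    m5 = "[" + "".join(sorted(M5_RESIDUES)) + "]"
    # lazy quantifiers: the leftmost feasible decomposition at each start
    return re.compile(
        f"C(.{{{g1[0]},{g1[1]}}})C(.{{{g2[0]},{g2[1]}}}?)C(.{{{g3[0]},{g3[1]}}}?)"
        f"({m4})(.{{{g4[0]},{g4[1]}}}?)({m5})(.{{{g5[0]},{g5[1]}}})"
        f"C(.{{{g6[0]},{g6[1]}}}?)C(.{{{g7[0]},{g7[1]}}})C"
    )


_RING_RE = _ring_regex()


def _match_at(sequence: str, i: int) -> RingDomainCall | None:
    m = _RING_RE.match(sequence, i)
    if m is None:
        return None
    gaps = [len(m.group(k)) for k in (1, 2, 3, 5, 7, 8, 9)]
    positions = [i + 1]  # 1-based
    for g in gaps:
        positions.append(positions[-1] + g + 1)
    residues = "".join(sequence[p - 1] for p in positions)
    return RingDomainCall(
        protein_id="",
        ligand_positions=tuple(positions),
        ligand_residues=residues,
        spacings=tuple(gaps),
    )


def scan_ring_ligands(sequence: str, protein_id: str = "") -> list[RingDomainCall]:
    """Find all non-overlapping RING grammar matches in a protein sequence.

    Candidate matches are generated at every cysteine; at one start the
    leftmost feasible gap decomposition is taken.  Overlaps between
    candidates are resolved leftmost-first, ties by shorter match.  Each
    surviving match is typed via :func:`classify_ring_type`.
    """
    if sequence != sequence.upper():
        raise ValueError("sequence must be uppercase")
    candidates: list[RingDomainCall] = []
    for i, aa in enumerate(sequence):
        if aa != "C":
            continue
        call = _match_at(sequence, i)
        if call is not None:
            candidates.append(call)
    candidates.sort(key=lambda c: (c.start, c.end))
    accepted: list[RingDomainCall] = []
    for c in candidates:
        if all(c.start > a.end or c.end < a.start for a in accepted):
            c.protein_id = protein_id
            c.ring_type = classify_ring_type(c)
            accepted.append(c)
    return accepted


def classify_ring_type(call: RingDomainCall) -> str:
    """Type one RING grammar match from its ligand residues and spacings.

    Decision order: glycine substitution at any ligand -> RING-G; serine or
    threonine at M5 -> RING-S/T; (M4, M5) = (H, H) -> RING-H2; (H, C) with
    canonical M4-M5 spacing -> RING-HC; (C, H) -> RING-v; (C, C) -> RING-C2.
    Combinations outside the table fall to the "unclassified" sentinel.
    """
    res = call.ligand_residues
    m4, m5 = res[3], res[4]
    if "G" in res:
        return "RING-G"
    if m5 in {"S", "T"}:
        return "RING-S/T"
    if (m4, m5) == ("H", "H"):
        return "RING-H2"
    if (m4, m5) == ("H", "C"):
        lo, hi = HC_CANONICAL_M4_M5
        if lo <= call.spacings[3] <= hi:
            return "RING-HC"
        logger.warning(
            "H/C ligands with non-canonical M4-M5 spacing %d on %s",
            call.spacings[3], call.protein_id or "<anon>",
        )
        return UNCLASSIFIED
    if (m4, m5) == ("C", "H"):
        return "RING-v"
    if (m4, m5) == ("C", "C"):
        return "RING-C2"
    logger.warning(
        "unclassifiable ligand residues %s on %s", res, call.protein_id or "<anon>"
    )
    return UNCLASSIFIED
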