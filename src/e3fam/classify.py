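"""Subfamily and subgroup assignment for E3 ubiquitin ligase proteins.

Eight subfamilies are recognized by their diagnostic domain (RING finger,
F-box, BTB/POZ, U-box, HECT, Cullin, SKP, DDB); proteins carrying none of
them get the NONE label and are excluded from the family, mirroring the
removal of candidates that lack an indispensable E3 domain.  Within the
BTB, F-box, U-box and HECT subfamilies, subgroups are decided by an
explicit, priority-ordered rule table over the additional domains; the
table is data, not code, and can be replaced from a TSV.  RING subgroups
are the six RING types produced by the native scanner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .architecture import DomainArchitecture, RingDomainCall, UNCLASSIFIED
from .io_formats import GeneModel

logger = logging.getLogger(__name__)

SUBFAMILIES = ("RING", "F-box", "BTB", "U-box", "SKP", "Cullin", "HECT", "DDB")
NONE_LABEL = "NONE"

#: Conflict precedence when a protein carries several diagnostic domains.
SUBFAMILY_PRECEDENCE = (
    "Cullin", "HECT", "U-box", "RING", "F-box", "BTB", "SKP", "DDB"
)

INTRON_BINS = ("0", "1-5", "6-10", "11-20", ">20")


@dataclass(frozen=True)
class SubgroupRule:
    """One row of the subgroup rule table.

    A rule matches when its required domains are all present and none of its
    forbidden domains is; ``requires_extra`` marks "other extra domain"
    catch-alls that need at least one domain besides the diagnostic one.
    Rules of a subfamily are tried in ascending priority; each subfamily
    ends in a catch-all, so assignment is total.
    """

    subfamily: str
    name: str
    required: frozenset
    forbidden: frozenset = frozenset()
    priority: int = 0
    requires_extra: bool = False


def _r(subfamily, name, required, forbidden=(), priority=0, extra=False):
    return SubgroupRule(
        subfamily, name, frozenset(required), frozenset(forbidden), priority, extra
    )


def default_rules() -> list[SubgroupRule]:
    """The shipped subgroup rule table (BTB 14, F-box 10, U-box 7, HECT 3)."""
    rules: list[SubgroupRule] = []
    btb = [
        ("BTBN", {"BTB", "NPH3"}, ()),
        ("BTBAND", {"BTB", "ANK", "NPR", "DUF"}, ()),
        ("BTBAN", {"BTB", "ANK", "NPR"}, {"DUF"}),
        ("BTBBL", {"BTB", "BACK", "LRR"}, ()),
        ("BTBP", {"BTB", "Pentapeptide"}, ()),
        ("BTBM", {"BTB", "MATH"}, ()),
        ("BTBZ", {"BTB", "TAZ"}, ()),
        ("BTBB", {"BTB", "BACK"}, {"LRR"}),
        ("BTBA", {"BTB", "ANK"}, {"NPR"}),
        ("BTBT", {"BTB", "TPR"}, ()),
        ("BTBW", {"BTB", "WD40"}, ()),
        ("BTBD", {"BTB", "DUF"}, ()),
    ]
    for i, (name, req, forb) in enumerate(btb):
        rules.append(_r("BTB", name, req, forb, i))
    rules.append(_r("BTB", "BTBO", {"BTB"}, (), len(btb), extra=True))
    rules.append(_r("BTB", "BTB", {"BTB"}, (), len(btb) + 1))

    fbox = [
        ("FBDL", {"F-box", "FBD", "LRR"}, ()),
        ("FBA", {"F-box", "FBA"}, ()),
        ("FBD", {"F-box", "FBD"}, ()),
        ("FBL", {"F-box", "LRR"}, ()),
        ("FBK", {"F-box", "Kelch"}, ()),
        ("FBP", {"F-box", "Pentapeptide"}, ()),
        ("FBW", {"F-box", "WD40"}, ()),
        ("FBDUF", {"F-box", "DUF"}, ()),
    ]
    for i, (name, req, forb) in enumerate(fbox):
        rules.append(_r("F-box", name, req, forb, i))
    rules.append(_r("F-box", "FBO", {"F-box"}, (), len(fbox), extra=True))
    rules.append(_r("F-box", "FBX", {"F-box"}, (), len(fbox) + 1))

    ubox = [
        ("ARM", {"U-box", "ARM"}),
        ("Pkinase", {"U-box", "Pkinase"}),
        ("TPR", {"U-box", "TPR"}),
        ("UFD2", {"U-box", "UFD2"}),
        ("KAP", {"U-box", "KAP"}),
        ("WD40", {"U-box", "WD40"}),
    ]
    for i, (name, req) in enumerate(ubox):
        rules.append(_r("U-box", name, req, (), i))
    rules.append(_r("U-box", "U-box-only", {"U-box"}, (), len(ubox)))

    rules.append(_r("HECT", "II", {"HECT", "UBA", "UIM", "DUF"}, (), 0))
    rules.append(_r("HECT", "III", {"HECT", "UBQ"}, (), 1))
    rules.append(_r("HECT", "I", {"HECT"}, (), 2))
    return rules


def rules_to_tsv(rules: list[SubgroupRule], path) -> None:
    pd.DataFrame(
        [
            (
                r.subfamily,
                r.name,
                ",".join(sorted(r.required)),
                ",".join(sorted(r.forbidden)),
                r.priority,
                int(r.requires_extra),
            )
            for r in rules
        ],
        columns=["subfamily", "subgroup", "required", "forbidden", "priority",
                 "requires_extra"],
    ).to_csv(path, sep="\t", index=False)


def rules_from_tsv(path) -> list[SubgroupRule]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    rules = []
    for row in df.itertuples(index=False):
        rules.append(
            SubgroupRule(
                subfamily=row.subfamily,
                name=row.subgroup,
                required=frozenset(x for x in str(row.required).split(",") if x),
                forbidden=frozenset(x for x in str(row.forbidden).split(",") if x),
                priority=int(row.priority),
                requires_extra=bool(
                    int(getattr(row, "requires_extra", 0) or 0)
                ),
            )
        )
    return rules


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def assign_subfamily(
    arch: DomainArchitecture, ring_calls: list[RingDomainCall] = ()
) -> str:
    """Assign the subfamily by presence of a diagnostic domain.

    RING presence is satisfied either by an external RING hit or by a native
    scanner call.  When several diagnostic domains co-occur the fixed
    precedence order decides, with a logged conflict; no diagnostic domain
    gives NONE (the protein is excluded from the family).
    """
    present = set(arch.domain_names)
    matched = [
        sf
        for sf in SUBFAMILY_PRECEDENCE
        if sf in present or (sf == "RING" and ring_calls)
    ]
    if not matched:
        return NONE_LABEL
    if len(matched) > 1:
        logger.info(
            "protein %s carries several diagnostic domains %s; keeping %s",
            arch.protein_id, matched, matched[0],
        )
    return matched[0]


def assign_subgroup(
    subfamily: str,
    arch: DomainArchitecture,
    rules: list[SubgroupRule] | None = None,
    ring_calls: list[RingDomainCall] = (),
) -> str:
    """Assign the subgroup within a subfamily.

    BTB / F-box / U-box / HECT use the rule table (first matching rule by
    priority); RING proteins take the type of their first scanner call;
    Cullin, SKP and DDB have no subgroups and return the subfamily name.
    """
    if subfamily == NONE_LABEL:
        raise ValueError("cannot assign a subgroup to a NONE-labelled protein")
    if subfamily == "RING":
        if ring_calls:
            return ring_calls[0].ring_type
        return UNCLASSIFIED
    if subfamily in {"Cullin", "SKP", "DDB"}:
        return subfamily
    if rules is None:
        rules = default_rules()
    present = set(arch.domain_names)
    diagnostic = {subfamily}
    for rule in sorted(
        (r for r in rules if r.subfamily == subfamily),
        key=lambda r: (r.priority, r.name),
    ):
        if not rule.required <= present:
            continue
        if rule.forbidden & present:
            continue
        if rule.requires_extra and not (present - diagnostic):
            continue
        return rule.name
    raise ValueError(
        f"no subgroup rule matched {arch.domain_string()!r} in {subfamily} "
        "(rule table lacks a catch-all)"
    )


# ---------------------------------------------------------------------------
# intron groups and chromosome distribution
# ---------------------------------------------------------------------------

@dataclass
class IntronGroupHistogram:
    """Gene counts over the five intron-number groups."""

    counts: dict

    @property
    def n_over_20(self) -> int:
        return self.counts[">20"]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def intron_bin(n_introns: int) -> str:
    if n_introns == 0:
        return "0"
    if n_introns <= 5:
        return "1-5"
    if n_introns <= 10:
        return "6-10"
    if n_introns <= 20:
        return "11-20"
    return ">20"


def group_by_intron_count(genes: list[GeneModel]) -> IntronGroupHistogram:
    counts = {b: 0 for b in INTRON_BINS}
    for g in genes:
        counts[intron_bin(g.n_introns)] += 1
    return IntronGroupHistogram(counts)


def chromosome_distribution(
    genes: list[GeneModel], labels: dict[str, str]
) -> pd.DataFrame:
    """Contingency table of chromosome x subfamily counts with margins.

    Only genes with a non-NONE label are counted; every labelled gene must
    be present in ``genes``.
    """
    gene_chrom = {g.gene_id: g.chrom for g in genes}
    rows = []
    for gid, sf in labels.items():
        if sf == NONE_LABEL:
            continue
        if gid not in gene_chrom:
            raise ValueError(f"labelled gene {gid!r} has no gene model")
        rows.append((gene_chrom[gid], sf))
    df = pd.DataFrame(rows, columns=["chrom", "subfamily"])
    if df.empty:
        return pd.DataFrame()
    table = pd.crosstab(df["chrom"], df["subfamily"], margins=True,
                        margins_name="Total")
    return table
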