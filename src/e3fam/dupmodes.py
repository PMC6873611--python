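"""Gene duplication mode dissection: SINGLETON / DSD / PD / TD / WGD.

Follows the duplicate-gene-classifier convention: rank genes along each
chromosome, chain homolog pairs into collinear (syntenic) blocks by
dynamic-programming longest chains, then classify each gene by the best
evidence among its pairs with priority WGD > TD > PD > DSD > SINGLETON.
A pair inside a collinear block marks both genes as retained from
whole-genome/segmental duplication; adjacent homologs are tandem; homologs
within a short rank window are proximal; any other homology is dispersed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .io_formats import GeneModel
from .report import percentage

MODES = ("DSD", "TD", "WGD", "PD", "SINGLETON")
MODE_PRIORITY = ("WGD", "TD", "PD", "DSD")


@dataclass(frozen=True)
class HomologPair:
    """Unordered homolog pair, canonicalized so gene_a < gene_b."""

    gene_a: str
    gene_b: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair for {self.gene_a}")
        if self.gene_a > self.gene_b:
            object.__setattr__(self, "gene_a", self.gene_b)
            object.__setattr__(self, "gene_b", self.gene_a)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class CollinearBlock:
    """A chain of homolog pairs with conserved gene order between two
    chromosome segments (orientation ``same`` or ``inverted``)."""

    pairs: list[HomologPair]
    chroms: tuple[str, str]
    orientation: str

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    mode: str
    evidence: str = "-"


def rank_genes(genes: list[GeneModel]) -> list[GeneModel]:
    """Return genes with ``rank`` set: 1..n by ascending start within each
    chromosome.  Duplicate (chrom, start) coordinates are an error."""
    seen = {}
    for g in genes:
        key = (g.chrom, g.start)
        if key in seen:
            raise ValueError(
                f"duplicate coordinates {key} for {seen[key]} and {g.gene_id}"
            )
        seen[key] = g.gene_id
    ranked = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        for i, g in enumerate(sorted(by_chrom[chrom], key=lambda x: x.start), 1):
            ranked.append(replace(g, rank=i))
    return ranked


# ---------------------------------------------------------------------------
# collinear block detection
# ---------------------------------------------------------------------------

def _oriented_pairs(
    pairs: list[HomologPair], loc: dict[str, tuple[str, int]]
) -> dict[tuple[str, str], list[tuple[int, int, HomologPair]]]:
    """Group pairs by unordered chromosome pair; each entry is (rank on axis
    A, rank on axis B, pair), axis A being the lexicographically smaller
    chromosome (smaller rank for intra-chromosome pairs)."""
    groups: dict[tuple[str, str], list[tuple[int, int, HomologPair]]] = {}
    for p in pairs:
        ca, ra = loc[p.gene_a]
        cb, rb = loc[p.gene_b]
        if (cb, rb) < (ca, ra):
            ca, ra, cb, rb = cb, rb, ca, ra
        groups.setdefault((ca, cb), []).append((ra, rb, p))
    return groups


def _longest_chain(
    entries: list[tuple[int, int, HomologPair]], max_gap: int, orientation: str
) -> list[int]:
    """Longest chain (indices into ``entries``) with strictly increasing
    A-ranks, strictly increasing (same) or decreasing (inverted) B-ranks,
    and rank gaps <= max_gap on both axes.  Deterministic: ties prefer the
    smaller predecessor index and the smaller chain end index."""
    n = len(entries)
    order = sorted(range(n), key=lambda i: (entries[i][0], entries[i][1]))
    best_len = [1] * n
    prev = [-1] * n
    sign = 1 if orientation == "same" else -1
    for oi in range(n):
        i = order[oi]
        ra_i, rb_i, _ = entries[i]
        for oj in range(oi):
            j = order[oj]
            ra_j, rb_j, _ = entries[j]
            if ra_i <= ra_j or ra_i - ra_j > max_gap:
                continue
            db = sign * (rb_i - rb_j)
            if db <= 0 or db > max_gap:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: (best_len[i], -entries[i][0], -entries[i][1]))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def detect_collinear_blocks(
    pairs: list[HomologPair],
    genes: list[GeneModel],
    min_pairs: int = 5,
    max_gap: int = 25,
    exclude_self_within: int = 10,
) -> list[CollinearBlock]:
    """Chain homolog pairs into collinear blocks.

    For each chromosome pair, chains are extracted greedily: the longest
    chain (either orientation) is accepted if it has >= min_pairs pairs, its
    pairs are removed, and the search repeats.  Ties between equally long
    chains prefer the leftmost anchor (smallest A-rank), then orientation
    ``same``.  Each pair belongs to at most one block.

    Intra-chromosome pairs closer than ``exclude_self_within`` ranks are
    tandem/proximal evidence, not synteny, and are excluded from chaining
    (runs of tandem arrays would otherwise read as self-collinearity).
    """
    loc = {g.gene_id: (g.chrom, g.rank) for g in genes}
    for p in pairs:
        for gid in (p.gene_a, p.gene_b):
            if gid not in loc:
                raise ValueError(f"pair references unknown gene {gid!r}")
            if loc[gid][1] < 1:
                raise ValueError("genes must be ranked before block detection")
    pairs = [
        p
        for p in pairs
        if loc[p.gene_a][0] != loc[p.gene_b][0]
        or abs(loc[p.gene_a][1] - loc[p.gene_b][1]) > exclude_self_within
    ]
    if not pairs:
        return []
    blocks: list[CollinearBlock] = []
    groups = _oriented_pairs(pairs, loc)
    for chroms in sorted(groups):
        entries = groups[chroms]
        remaining = list(range(len(entries)))
        while remaining:
            sub = [entries[i] for i in remaining]
            best = None
            for orientation in ("same", "inverted"):
                chain = _longest_chain(sub, max_gap, orientation)
                anchor = sub[chain[0]][:2]
                cand = (len(chain), anchor, orientation, chain)
                if best is None or (
                    cand[0] > best[0]
                    or (cand[0] == best[0] and cand[1] < best[1])
                    or (cand[0] == best[0] and cand[1] == best[1]
                        and cand[2] == "same" and best[2] == "inverted")
                ):
                    best = cand
            length, _, orientation, chain = best
            if length < min_pairs:
                break
            chain_entries = [sub[i] for i in chain]
            blocks.append(
                CollinearBlock(
                    pairs=[e[2] for e in chain_entries],
                    chroms=chroms,
                    orientation=orientation,
                )
            )
            used = {id(sub[i]) for i in chain}
            remaining = [i for i in remaining if id(entries[i]) not in used]
    return blocks


# ---------------------------------------------------------------------------
# mode classification
# ---------------------------------------------------------------------------

def classify_duplication(
    genes: list[GeneModel],
    pairs: list[HomologPair],
    blocks: list[CollinearBlock],
    tandem_max_gap: int = 1,
    proximal_max_gap: int = 10,
) -> list[DuplicationCall]:
    """Assign exactly one duplication mode per gene.

    Candidate modes from a gene's pairs: WGD if any pair lies in a collinear
    block; TD if any same-chromosome pair with rank difference <=
    tandem_max_gap; PD for rank differences in (tandem_max_gap,
    proximal_max_gap]; DSD for any other pair; SINGLETON with no pair.
    The final mode is the highest-priority candidate (WGD > TD > PD > DSD).
    """
    loc = {g.gene_id: (g.chrom, g.rank) for g in genes}
    block_pairs: dict[tuple[str, str], int] = {}
    for bi, b in enumerate(blocks):
        for p in b.pairs:
            block_pairs.setdefault(p.key, bi)
    by_gene: dict[str, list[HomologPair]] = {g.gene_id: [] for g in genes}
    for p in pairs:
        for gid in (p.gene_a, p.gene_b):
            if gid not in by_gene:
                raise ValueError(f"pair references unknown gene {gid!r}")
            by_gene[gid].append(p)
    calls = []
    for g in genes:
        evidence = {m: None for m in MODE_PRIORITY}
        for p in by_gene[g.gene_id]:
            partner = p.gene_b if p.gene_a == g.gene_id else p.gene_a
            if p.key in block_pairs:
                evidence["WGD"] = evidence["WGD"] or f"block{block_pairs[p.key]}"
            (ca, ra), (cb, rb) = loc[g.gene_id], loc[partner]
            if ca == cb:
                d = abs(ra - rb)
                if d <= tandem_max_gap:
                    evidence["TD"] = evidence["TD"] or partner
                elif d <= proximal_max_gap:
                    evidence["PD"] = evidence["PD"] or partner
                else:
                    evidence["DSD"] = evidence["DSD"] or partner
            else:
                evidence["DSD"] = evidence["DSD"] or partner
        mode = next((m for m in MODE_PRIORITY if evidence[m]), "SINGLETON")
        calls.append(
            DuplicationCall(
                gene_id=g.gene_id,
                mode=mode,
                evidence=evidence.get(mode) or "-",
            )
        )
    return calls


@dataclass
class ModeSummary:
    """Subfamily x mode counts with half-up integer percentages."""

    counts: pd.DataFrame
    pct_of_subfamily: pd.DataFrame
    pct_of_total: pd.DataFrame


def summarize_modes(
    calls: list[DuplicationCall], labels: dict[str, str]
) -> ModeSummary:
    """Tabulate duplication modes per subfamily (labels map gene ->
    subfamily); percentages are rounded half-up to integer, matching the
    printed convention."""
    rows = []
    for c in calls:
        if c.gene_id not in labels:
            raise ValueError(f"gene {c.gene_id!r} has no subfamily label")
        rows.append((labels[c.gene_id], c.mode))
    df = pd.DataFrame(rows, columns=["subfamily", "mode"])
    counts = pd.crosstab(df["subfamily"], df["mode"]).reindex(
        columns=list(MODES), fill_value=0
    )
    counts["Total"] = counts.sum(axis=1)
    counts.loc["Total"] = counts.sum(axis=0)
    grand = int(counts.at["Total", "Total"])
    pct_sub = counts.copy().astype(float)
    pct_tot = counts.copy().astype(float)
    for sf in counts.index:
        for m in counts.columns:
            n = int(counts.at[sf, m])
            denom = int(counts.at[sf, "Total"])
            pct_sub.at[sf, m] = percentage(n, denom, 0) if denom else 0.0
            pct_tot.at[sf, m] = percentage(n, grand, 0) if grand else 0.0
    return ModeSummary(counts=counts, pct_of_subfamily=pct_sub,
                       pct_of_total=pct_tot)
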