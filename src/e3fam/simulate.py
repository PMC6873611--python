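"""Synthetic proteomes, genome layouts and FPKM matrices with known truth.

The generator emulates the statistical structure the downstream analysis
assumes: proteins carrying planted E3 domain architectures (with genuine
RING metal-ligand motifs realized from the scanner's grammar), chromosome
layouts with planted tandem arrays, proximal pairs, collinear (WGD-like)
blocks, dispersed pairs and singletons, and log-normal-noise FPKM matrices
with planted differential-expression effects following the eight pattern-
cluster prototypes.  Every planted fact is recorded in a truth table so
each pipeline stage can be scored against ground truth.

A single integer seed determines every output byte; independent sub-streams
are derived per component (proteome / layout / expression), so regenerating
one block does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io_formats as io
from .architecture import (
    M4_RESIDUES,
    M5_RESIDUES,
    RING_GAP_BOUNDS,
    RING_TYPES,
)
from .expression import CLUSTER_PROTOTYPES, CLUSTERS
from .io_formats import DomainHit, ExpressionMatrix, GeneModel, ProteinRecord

#: Background residues for simulated protein sequence: every amino acid
#: except cysteine and histidine, so no spurious RING ligands can arise.
BACKGROUND_AA = "ADEFGIKLMNPQRSTVWY"
#: Stricter background for the gaps inside a RING motif: also excludes
#: G/S/T, which are legal at the 4th/5th ligand positions and would make
#: the motif's ligand decomposition ambiguous to the scanner.
MOTIF_GAP_AA = "ADEFIKLMNPQRVWY"

#: Peach-scale subfamily counts used as the default mixing proportions.
SUBFAMILY_COUNTS = {
    "RING": 338, "F-box": 267, "BTB": 67, "U-box": 54,
    "SKP": 16, "Cullin": 13, "HECT": 7, "DDB": 3,
}

#: Default subgroup counts within each rule-based subfamily (F-box, U-box
#: and HECT follow the reported subgroup sizes; the seven unnamed BTB
#: subgroups receive invented counts summing to the subfamily total).
SUBGROUP_COUNTS = {
    "BTB": {
        "BTBN": 21, "BTBM": 5, "BTBZ": 5, "BTBT": 3, "BTBW": 2, "BTBA": 4,
        "BTBB": 3, "BTBD": 3, "BTBP": 2, "BTBBL": 3, "BTBAND": 2,
        "BTBAN": 2, "BTBO": 6, "BTB": 6,
    },
    "F-box": {
        "FBX": 128, "FBA": 64, "FBD": 19, "FBDL": 2, "FBL": 14, "FBK": 12,
        "FBP": 6, "FBW": 2, "FBDUF": 8, "FBO": 12,
    },
    "U-box": {
        "U-box-only": 15, "ARM": 25, "Pkinase": 8, "TPR": 1, "UFD2": 1,
        "KAP": 1, "WD40": 3,
    },
    "HECT": {"I": 4, "II": 2, "III": 1},
}

RING_TYPE_COUNTS = {
    "RING-HC": 198, "RING-H2": 109, "RING-v": 20, "RING-C2": 18,
    "RING-S/T": 4, "RING-G": 3,
}

#: Domain architecture planted for each subgroup (ordered hit lists).
SUBGROUP_ARCHITECTURES = {
    ("BTB", "BTBN"): ["BTB", "NPH3"],
    ("BTB", "BTBAND"): ["BTB", "ANK", "NPR", "DUF"],
    ("BTB", "BTBAN"): ["BTB", "ANK", "NPR"],
    ("BTB", "BTBBL"): ["BTB", "BACK", "LRR"],
    ("BTB", "BTBP"): ["BTB", "Pentapeptide"],
    ("BTB", "BTBM"): ["BTB", "MATH"],
    ("BTB", "BTBZ"): ["BTB", "TAZ"],
    ("BTB", "BTBB"): ["BTB", "BACK"],
    ("BTB", "BTBA"): ["BTB", "ANK"],
    ("BTB", "BTBT"): ["BTB", "TPR"],
    ("BTB", "BTBW"): ["BTB", "WD40"],
    ("BTB", "BTBD"): ["BTB", "DUF"],
    ("BTB", "BTBO"): ["BTB", "Kelch"],
    ("BTB", "BTB"): ["BTB"],
    ("F-box", "FBX"): ["F-box"],
    ("F-box", "FBA"): ["F-box", "FBA"],
    ("F-box", "FBD"): ["F-box", "FBD"],
    ("F-box", "FBDL"): ["F-box", "FBD", "LRR"],
    ("F-box", "FBL"): ["F-box", "LRR"],
    ("F-box", "FBK"): ["F-box", "Kelch"],
    ("F-box", "FBP"): ["F-box", "Pentapeptide"],
    ("F-box", "FBW"): ["F-box", "WD40"],
    ("F-box", "FBDUF"): ["F-box", "DUF"],
    ("F-box", "FBO"): ["F-box", "ARM"],
    ("U-box", "U-box-only"): ["U-box"],
    ("U-box", "ARM"): ["U-box", "ARM"],
    ("U-box", "Pkinase"): ["U-box", "Pkinase"],
    ("U-box", "TPR"): ["U-box", "TPR"],
    ("U-box", "UFD2"): ["U-box", "UFD2"],
    ("U-box", "KAP"): ["U-box", "KAP"],
    ("U-box", "WD40"): ["U-box", "WD40"],
    ("HECT", "I"): ["HECT"],
    ("HECT", "II"): ["HECT", "UBA", "UIM", "DUF"],
    ("HECT", "III"): ["HECT", "UBQ"],
    ("Cullin", "Cullin"): ["Cullin"],
    ("SKP", "SKP"): ["SKP"],
    ("DDB", "DDB"): ["DDB"],
}

#: Decoy architectures: no diagnostic E3 domain (one variant has no hits).
DECOY_ARCHITECTURES = [["Pkinase"], ["LRR"], ["ANK"], ["WD40"], ["MATH"], []]


class ConfigError(ValueError):
    """The simulation configuration is inconsistent or infeasible."""


def _normalize(counts: dict) -> dict:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass
class SimulationConfig:
    """Study-condition parameters of one synthetic dataset."""

    seed: int = 0
    n_genes: int = 300
    n_chromosomes: int = 2
    subfamily_mix: dict = field(
        default_factory=lambda: _normalize(SUBFAMILY_COUNTS)
    )
    subgroup_mix: dict = field(
        default_factory=lambda: {
            sf: _normalize(c) for sf, c in SUBGROUP_COUNTS.items()
        }
    )
    ring_type_mix: dict = field(
        default_factory=lambda: _normalize(RING_TYPE_COUNTS)
    )
    decoy_fraction: float = 0.10
    multi_ring_fraction: float = 14 / 338  # 352 domains on 338 proteins
    n_tandem_arrays: int = 6
    tandem_array_size: int = 3
    n_proximal_pairs: int = 8
    n_collinear_blocks: int = 2
    block_size: int = 6
    n_dispersed_pairs: int = 15
    fpkm_log2_sd: float = 0.2
    planted_effect: float = 2.0
    silenced_fraction: float = 0.33  # mirrors 515/765 expressed
    deg_fraction: float = 231 / 515  # DEGs among expressed genes
    pseudocount: float = 0.01
    cluster_mix: dict = field(
        default_factory=lambda: _normalize(
            {"I": 47, "II": 20, "III": 18, "IV": 42,
             "V": 33, "VI": 20, "VII": 29, "VIII": 22}
        )
    )

    def __post_init__(self) -> None:
        for name, mix in [
            ("subfamily_mix", self.subfamily_mix),
            ("ring_type_mix", self.ring_type_mix),
            ("cluster_mix", self.cluster_mix),
            *[(f"subgroup_mix[{sf}]", m) for sf, m in self.subgroup_mix.items()],
        ]:
            if mix and abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} proportions must sum to 1")
        needed = (
            self.n_collinear_blocks * 2 * self.block_size
            + self.n_tandem_arrays * self.tandem_array_size
            + self.n_proximal_pairs * 3  # pair + at least one filler
            + self.n_dispersed_pairs * 2
        )
        if needed > self.n_genes:
            raise ConfigError(
                f"layout needs at least {needed} genes, n_genes={self.n_genes}"
            )
        if self.n_collinear_blocks > 0 and self.n_chromosomes < 2:
            raise ConfigError("collinear blocks need at least 2 chromosomes")
        if self.n_dispersed_pairs > 0 and self.n_chromosomes < 2:
            raise ConfigError("dispersed pairs need at least 2 chromosomes")
        if not 0 <= self.decoy_fraction < 1:
            raise ConfigError("decoy_fraction must be in [0, 1)")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("proteome", "layout", "expression")
    return {
        name: np.random.Generator(np.random.PCG64(child))
        for name, child in zip(names, root.spawn(len(names)))
    }


def _apportion(mix: dict, n: int) -> dict:
    """Largest-remainder apportionment of n items over mix proportions."""
    keys = sorted(mix)
    quotas = {k: n * mix[k] for k in keys}
    counts = {k: int(np.floor(quotas[k])) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), k))[:short]:
        counts[k] += 1
    return counts


def _bg(rng: np.random.Generator, n: int, alphabet: str = BACKGROUND_AA) -> str:
    return "".join(
        np.asarray(list(alphabet))[rng.integers(0, len(alphabet), n)]
    )


# ---------------------------------------------------------------------------
# RING motif generation
# ---------------------------------------------------------------------------

def simulate_ring_domain(
    ring_type: str, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    """Realize one RING motif of the requested type.

    Ligand spacings are drawn uniformly from the grammar's allowed ranges;
    the residues at the 4th/5th ligand positions are set so the type
    decision recovers ``ring_type``; non-ligand positions come from the
    background distribution (no C or H).  Returns the motif sequence and
    the eight 1-based ligand positions within it.
    """
    if ring_type not in RING_TYPES:
        raise ConfigError(f"unknown RING type {ring_type!r}")
    gaps = [int(rng.integers(lo, hi + 1)) for lo, hi in RING_GAP_BOUNDS]
    if ring_type == "RING-HC":
        m4, m5 = "H", "C"
    elif ring_type == "RING-H2":
        m4, m5 = "H", "H"
    elif ring_type == "RING-C2":
        m4, m5 = "C", "C"
    elif ring_type == "RING-v":
        m4, m5 = "C", "H"
    elif ring_type == "RING-S/T":
        m4 = str(rng.choice(["C", "H"]))
        m5 = str(rng.choice(["S", "T"]))
    else:  # RING-G: glycine substitution at the 4th or 5th ligand
        if rng.random() < 0.5:
            m4, m5 = "G", str(rng.choice(["C", "H"]))
        else:
            m4, m5 = str(rng.choice(["C", "H"])), "G"
    assert m4 in M4_RESIDUES and m5 in M5_RESIDUES
    ligands = ["C", "C", "C", m4, m5, "C", "C", "C"]
    seq = []
    positions = []
    pos = 1
    for i, lig in enumerate(ligands):
        seq.append(lig)
        positions.append(pos)
        if i < 7:
            seq.append(_bg(rng, gaps[i], MOTIF_GAP_AA))
            pos += gaps[i] + 1
    return "".join(seq), tuple(positions)


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def simulate_proteome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], list[DomainHit], pd.DataFrame]:
    """Generate proteins, their domain-hit table and the proteome truth.

    Each non-decoy gene draws a subfamily from ``subfamily_mix`` and a
    subgroup architecture from the shipped rule table's archetypes; RING
    genes carry a genuine RING motif (two for the multi-RING fraction)
    embedded in sequence alongside an external RING hit.  Decoy genes carry
    no diagnostic E3 domain.
    """
    if rng is None:
        rng = _streams(config.seed)["proteome"]
    n_decoys = int(round(config.decoy_fraction * config.n_genes))
    n_e3 = config.n_genes - n_decoys
    sf_counts = _apportion(config.subfamily_mix, n_e3)

    assignments: list[tuple[str, str]] = []  # (subfamily, subgroup)
    for sf in sorted(sf_counts):
        n_sf = sf_counts[sf]
        if sf == "RING":
            sg_counts = _apportion(config.ring_type_mix, n_sf)
        elif sf in config.subgroup_mix:
            sg_counts = _apportion(config.subgroup_mix[sf], n_sf)
        else:
            sg_counts = {sf: n_sf}
        for sg in sorted(sg_counts):
            assignments += [(sf, sg)] * sg_counts[sg]
    assignments += [("NONE", "-")] * n_decoys
    order = rng.permutation(len(assignments))
    assignments = [assignments[i] for i in order]

    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    truth_rows = []
    for i, (sf, sg) in enumerate(assignments, 1):
        gene_id = f"g{i:04d}"
        protein_id = f"{gene_id}.1"
        if sf == "NONE":
            domains = DECOY_ARCHITECTURES[
                int(rng.integers(0, len(DECOY_ARCHITECTURES)))
            ]
        elif sf == "RING":
            n_motifs = 2 if rng.random() < config.multi_ring_fraction else 1
            domains = ["RING"] * n_motifs
        else:
            domains = SUBGROUP_ARCHITECTURES[(sf, sg)]
        seq_parts = [_bg(rng, int(rng.integers(20, 60)))]
        pos = len(seq_parts[0])
        ring_types = []
        for dom in domains:
            if dom == "RING":
                motif, _ = simulate_ring_domain(sg, rng)
                seg = motif
                ring_types.append(sg)
            else:
                seg = _bg(rng, int(rng.integers(40, 120)))
            start = pos + 1
            end = pos + len(seg)
            hits.append(
                DomainHit(
                    protein_id=protein_id,
                    domain_name=dom,
                    start=start,
                    end=end,
                    evalue=float(10.0 ** -rng.uniform(4, 30)),
                )
            )
            seq_parts.append(seg)
            spacer = _bg(rng, int(rng.integers(10, 30)))
            seq_parts.append(spacer)
            pos = end + len(spacer)
        seq_parts.append(_bg(rng, int(rng.integers(10, 40))))
        proteins.append(
            ProteinRecord(protein_id, gene_id, "".join(seq_parts))
        )
        truth_rows.append(
            {
                "gene_id": gene_id,
                "subfamily": sf,
                "subgroup": sg,
                "ring_types": ";".join(ring_types),
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return proteins, hits, truth


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def _intron_count(rng: np.random.Generator) -> int:
    # five intron groups with most genes in 1-5, a thin >20 tail
    u = rng.random()
    if u < 0.25:
        return 0
    if u < 0.80:
        return int(rng.integers(1, 6))
    if u < 0.93:
        return int(rng.integers(6, 11))
    if u < 0.985:
        return int(rng.integers(11, 21))
    return int(rng.integers(21, 31))


def simulate_genome_layout(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    gene_ids: list[str] | None = None,
    min_pairs: int = 5,
    max_gap: int = 25,
) -> tuple[list[GeneModel], list[tuple[str, str, float]], pd.DataFrame]:
    """Place genes on chromosomes with planted duplication structures.

    Tandem arrays are runs of adjacent homologs; proximal pairs are homologs
    with rank difference 2..10 (singleton fillers in between); collinear
    blocks are two ``block_size`` segments with order-preserving pairs;
    dispersed pairs sit on different chromosomes away from any block (their
    placement is re-drawn if it falls inside a block's chaining window or
    would complete a >= min_pairs chain among dispersed pairs); everything
    else is a singleton.
    """
    if rng is None:
        rng = _streams(config.seed)["layout"]
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]
    if len(gene_ids) != config.n_genes:
        raise ConfigError("gene_ids length must equal n_genes")
    queue = [gene_ids[i] for i in rng.permutation(len(gene_ids))]
    chroms = [f"chr{c + 1}" for c in range(config.n_chromosomes)]

    def take(n: int) -> list[str]:
        if len(queue) < n:
            raise ConfigError("gene placement infeasible: ran out of genes")
        out = queue[:n]
        del queue[:n]
        return out

    mode: dict[str, str] = {}
    pairs: list[tuple[str, str, float]] = []
    # segments[c] is a list of gene runs; runs are later shuffled per chrom
    segments: dict[str, list[list[str]]] = {c: [] for c in chroms}
    block_members: list[tuple[tuple[str, str], list[str], list[str]]] = []

    def score() -> float:
        return float(np.round(rng.uniform(50.0, 300.0), 2))

    for _ in range(config.n_collinear_blocks):
        ca, cb = rng.choice(len(chroms), size=2, replace=False)
        ca, cb = sorted((chroms[ca], chroms[cb]))
        seg_a = take(config.block_size)
        seg_b = take(config.block_size)
        inverted = rng.random() < 0.3
        partners = seg_b[::-1] if inverted else seg_b
        for ga, gb in zip(seg_a, partners):
            pairs.append((ga, gb, score()))
            mode[ga] = mode[gb] = "WGD"
        segments[ca].append(seg_a)
        segments[cb].append(seg_b)
        block_members.append(((ca, cb), seg_a, seg_b))

    for _ in range(config.n_tandem_arrays):
        seg = take(config.tandem_array_size)
        for ga, gb in zip(seg, seg[1:]):
            pairs.append((ga, gb, score()))
        for g in seg:
            mode[g] = "TD"
        segments[chroms[int(rng.integers(0, len(chroms)))]].append(seg)

    for i in range(config.n_proximal_pairs):
        remaining_prox = config.n_proximal_pairs - i - 1
        reserve = 2 * config.n_dispersed_pairs + 3 * remaining_prox
        gap = int(rng.integers(2, 11))
        n_fillers = max(1, min(gap - 1, len(queue) - 2 - reserve))
        ga, gb = take(2)
        fillers = take(n_fillers)
        pairs.append((ga, gb, score()))
        mode[ga] = mode[gb] = "PD"
        for f in fillers:
            mode[f] = "SINGLETON"
        segments[chroms[int(rng.integers(0, len(chroms)))]].append(
            [ga, *fillers, gb]
        )

    # all remaining genes are placed as single-gene segments; dispersed
    # pairs are later drawn from this pool, the rest stay singletons
    pool = take(len(queue))
    for g in pool:
        mode[g] = "SINGLETON"
        segments[chroms[int(rng.integers(0, len(chroms)))]].append([g])

    # assemble chromosome orders and ranks
    layout: dict[str, list[str]] = {}
    for c in chroms:
        segs = segments[c]
        order = rng.permutation(len(segs))
        layout[c] = [g for i in order for g in segs[i]]
    rank = {
        g: (c, r + 1) for c in chroms for r, g in enumerate(layout[c])
    }

    # choose dispersed pairings that cannot masquerade as collinearity
    block_windows = []
    for (ca, cb), seg_a, seg_b in block_members:
        ra = [rank[g][1] for g in seg_a]
        rb = [rank[g][1] for g in seg_b]
        block_windows.append(
            ((ca, cb),
             (min(ra) - max_gap, max(ra) + max_gap),
             (min(rb) - max_gap, max(rb) + max_gap))
        )

    def near_block(g1: str, g2: str) -> bool:
        (c1, r1), (c2, r2) = rank[g1], rank[g2]
        if (c2, r2) < (c1, r1):
            c1, r1, c2, r2 = c2, r2, c1, r1
        for (ca, cb), (a_lo, a_hi), (b_lo, b_hi) in block_windows:
            if (c1, c2) == (ca, cb) and a_lo <= r1 <= a_hi and b_lo <= r2 <= b_hi:
                return True
        return False

    chosen: list[tuple[str, int, str, int]] = []

    def longest_disp_chain(cands: list[tuple[str, int, str, int]]) -> int:
        best = 1
        n = len(cands)
        for sign in (1, -1):
            lengths = [1] * n
            order = sorted(range(n), key=lambda i: (cands[i][1], cands[i][3]))
            for oi in range(n):
                i = order[oi]
                for oj in range(oi):
                    j = order[oj]
                    if cands[i][0] != cands[j][0] or cands[i][2] != cands[j][2]:
                        continue
                    da = cands[i][1] - cands[j][1]
                    db = sign * (cands[i][3] - cands[j][3])
                    if 0 < da <= max_gap and 0 < db <= max_gap:
                        lengths[i] = max(lengths[i], lengths[j] + 1)
            best = max(best, max(lengths, default=1))
        return best

    pool = list(pool)
    for _ in range(config.n_dispersed_pairs):
        placed = False
        for _attempt in range(200):
            idx = rng.permutation(len(pool))[:2]
            ga, gb = pool[int(idx[0])], pool[int(idx[1])]
            if ga == gb or rank[ga][0] == rank[gb][0]:
                continue
            if near_block(ga, gb):
                continue
            (c1, r1), (c2, r2) = rank[ga], rank[gb]
            if (c2, r2) < (c1, r1):
                c1, r1, c2, r2 = c2, r2, c1, r1
            cand = chosen + [(c1, r1, c2, r2)]
            if longest_disp_chain(cand) >= min_pairs:
                continue
            chosen.append((c1, r1, c2, r2))
            pairs.append((ga, gb, score()))
            mode[ga] = mode[gb] = "DSD"
            pool.remove(ga)
            pool.remove(gb)
            placed = True
            break
        if not placed:
            raise ConfigError(
                "could not place a dispersed pair outside block windows"
            )
    # unpaired pool genes stay singletons

    # coordinates and gene models
    genes: list[GeneModel] = []
    for c in chroms:
        pos = int(rng.integers(1, 5000))
        for g in layout[c]:
            length = int(rng.integers(800, 5000))
            n_introns = _intron_count(rng)
            genes.append(
                GeneModel(
                    gene_id=g,
                    chrom=c,
                    start=pos,
                    end=pos + length - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    n_exons=n_introns + 1,
                    n_introns=n_introns,
                )
            )
            pos += length + int(rng.integers(1000, 8000))

    canonical = [
        (min(a, b), max(a, b), s) for a, b, s in pairs
    ]
    canonical.sort()
    truth = pd.DataFrame(
        {"gene_id": gene_ids,
         "duplication_mode": [mode[g] for g in gene_ids]}
    ).set_index("gene_id")
    return genes, canonical, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    gene_ids: list[str],
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate the FPKM matrix with planted DEG effects.

    Expressed genes draw a baseline log2 FPKM uniformly from [1, 8]; SH
    values add Normal(0, fpkm_log2_sd) noise.  For a planted DEG, the MF
    value at each stage is derived from the realized SH value so that the
    pseudocounted log2 fold change equals prototype * planted_effect plus
    Normal(0, sd) noise exactly; non-DEG genes get independent MF noise.
    Silenced genes stay below FPKM 1 in all eight samples.
    """
    if rng is None:
        rng = _streams(config.seed)["expression"]
    n = len(gene_ids)
    ids = list(gene_ids)
    silenced_n = int(round(config.silenced_fraction * n))
    perm = rng.permutation(n)
    silenced = {ids[i] for i in perm[:silenced_n]}
    expressed = [ids[i] for i in perm[silenced_n:]]
    deg_n = int(round(config.deg_fraction * len(expressed)))
    deg_genes = expressed[:deg_n]
    cluster_counts = _apportion(config.cluster_mix, deg_n)
    cluster_of: dict[str, str] = {}
    k = 0
    for cl in CLUSTERS:
        for _ in range(cluster_counts.get(cl, 0)):
            cluster_of[deg_genes[k]] = cl
            k += 1

    sd = config.fpkm_log2_sd
    eff = config.planted_effect
    p = config.pseudocount
    rows = []
    truth_rows = []
    stages = list(io.STAGES)
    for g in ids:
        if g in silenced:
            vals = rng.uniform(0.0, 0.9, size=8)
            rows.append(vals)
            truth_rows.append(
                {"gene_id": g, "is_expressed": False, "cluster": "",
                 **{f"dir_{s}": "ns" for s in stages}}
            )
            continue
        b = rng.uniform(1.0, 8.0)
        sh = 2.0 ** (b + rng.normal(0.0, sd, size=4))
        if g in cluster_of:
            proto = CLUSTER_PROTOTYPES[cluster_of[g]]
            delta = np.array(proto) * eff + rng.normal(0.0, sd, size=4)
            mf = np.maximum((sh + p) * 2.0 ** delta - p, 0.0)
            dirs = {
                f"dir_{s}": ("up" if v > 0 else "down" if v < 0 else "ns")
                for s, v in zip(stages, proto)
            }
        else:
            mf = 2.0 ** (b + rng.normal(0.0, sd, size=4))
            dirs = {f"dir_{s}": "ns" for s in stages}
        rows.append(np.concatenate([mf, sh]))
        truth_rows.append(
            {"gene_id": g, "is_expressed": True,
             "cluster": cluster_of.get(g, ""), **dirs}
        )
    matrix = ExpressionMatrix(
        pd.DataFrame(rows, index=pd.Index(ids, name="gene_id"),
                     columns=list(io.SAMPLES))
    )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return matrix, truth


# ---------------------------------------------------------------------------
# whole-dataset orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """One simulated study: all input files plus the merged truth table."""

    config: SimulationConfig
    proteins: list[ProteinRecord]
    hits: list[DomainHit]
    genes: list[GeneModel]
    pairs: list[tuple[str, str, float]]
    matrix: ExpressionMatrix
    truth: pd.DataFrame


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Run the three generator components on independent sub-streams."""
    streams = _streams(config.seed)
    proteins, hits, prot_truth = simulate_proteome(config, streams["proteome"])
    gene_ids = [p.gene_id for p in proteins]
    gene_ids_sorted = sorted(gene_ids)
    genes, pairs, layout_truth = simulate_genome_layout(
        config, streams["layout"], gene_ids_sorted
    )
    matrix, expr_truth = simulate_expression(
        config, gene_ids_sorted, streams["expression"]
    )
    truth = prot_truth.join(layout_truth, how="left").join(
        expr_truth, how="left"
    )
    return SimulatedDataset(
        config=config,
        proteins=proteins,
        hits=hits,
        genes=genes,
        pairs=pairs,
        matrix=matrix,
        truth=truth.sort_index(),
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> None:
    """Write proteins.fasta, genes.gff3, domains.tsv, pairs.tsv, fpkm.tsv
    and truth.tsv to a directory."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(ds.proteins, out_dir / "proteins.fasta")
    io.write_gff3(ds.genes, out_dir / "genes.gff3")
    io.write_domain_hits(ds.hits, out_dir / "domains.tsv")
    io.write_pairs(ds.pairs, out_dir / "pairs.tsv")
    io.write_expression(ds.matrix, out_dir / "fpkm.tsv")
    out = ds.truth.reset_index()
    out.to_csv(out_dir / "truth.tsv", sep="\t", index=False)


def audit(ds: SimulatedDataset) -> None:
    """Check that the truth table is self-consistent with the emitted data.

    Structural checks only: diagnostic domains present in the hit table,
    RING motifs present in sequence, tandem genes adjacent in rank,
    proximal rank windows respected, silenced genes below FPKM 1.  Raises
    AssertionError on the first inconsistency.
    """
    from .dupmodes import rank_genes

    hit_doms: dict[str, set] = {}
    for h in ds.hits:
        hit_doms.setdefault(h.protein_id, set()).add(h.domain_name)
    for p in ds.proteins:
        sf = ds.truth.at[p.gene_id, "subfamily"]
        doms = hit_doms.get(p.protein_id, set())
        if sf == "NONE":
            assert not doms & set(SUBFAMILY_COUNTS), (
                f"decoy {p.gene_id} carries a diagnostic domain"
            )
        else:
            assert sf in doms, f"{p.gene_id}: {sf} domain missing from hits"

    ranked = rank_genes(ds.genes)
    loc = {g.gene_id: (g.chrom, g.rank) for g in ranked}
    partners: dict[str, list[str]] = {}
    for a, b, _ in ds.pairs:
        partners.setdefault(a, []).append(b)
        partners.setdefault(b, []).append(a)
    for g in ds.truth.index:
        m = ds.truth.at[g, "duplication_mode"]
        ps = partners.get(g, [])
        if m == "SINGLETON":
            assert not ps, f"singleton {g} has a homolog pair"
        elif m == "TD":
            assert any(
                loc[q][0] == loc[g][0] and abs(loc[q][1] - loc[g][1]) == 1
                for q in ps
            ), f"tandem gene {g} has no adjacent homolog"
        elif m == "PD":
            assert any(
                loc[q][0] == loc[g][0] and 2 <= abs(loc[q][1] - loc[g][1]) <= 10
                for q in ps
            ), f"proximal gene {g} has no homolog in the rank window"
        elif m == "DSD":
            assert any(loc[q][0] != loc[g][0] for q in ps), (
                f"dispersed gene {g} has no cross-chromosome homolog"
            )
        elif m == "WGD":
            assert ps, f"WGD gene {g} has no homolog pair"

    silenced = ds.truth.index[~ds.truth["is_expressed"].astype(bool)]
    assert (ds.matrix.values.loc[silenced] < 1.0).all().all(), (
        "silenced gene exceeds the expression threshold"
    )

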