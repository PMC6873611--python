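"""MF-vs-SH expression profiling across four ripening stages.

The pipeline follows a pure fold-change design (no count model): a gene is
*expressed* if its FPKM exceeds 1 in at least one of the eight samples;
between the melting-flesh (MF) and stony-hard (SH) cultivars at the same
stage, a gene is differentially expressed when |log2 FPKM ratio| reaches a
threshold (default 2.0).  Differentially expressed genes are assigned to
one of eight canonical expression-pattern clusters by nearest signed
stage-profile prototype; a data-driven hierarchical clustering (average
linkage on 1 - uncentered correlation, the Cluster 3.0 convention) is
provided as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .io_formats import ExpressionMatrix, STAGES
from .report import percentage

CLUSTERS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

#: Signed per-stage (S3, S4I, S4II, S4III) prototype of each pattern
#: cluster: +1 higher in MF, -1 lower in MF, 0 comparable.
CLUSTER_PROTOTYPES: dict[str, tuple[int, int, int, int]] = {
    "I": (0, 0, 0, -1),
    "II": (+1, +1, +1, +1),
    "III": (-1, 0, 0, +1),
    "IV": (-1, 0, 0, 0),
    "V": (-1, +1, -1, -1),
    "VI": (-1, -1, +1, +1),
    "VII": (-1, -1, -1, -1),
    "VIII": (0, 0, 0, +1),
}


@dataclass(frozen=True)
class DEGRecord:
    """Per-gene, per-stage differential-expression call (MF over SH)."""

    gene_id: str
    stage: str
    log2fc: float
    direction: str  # up / down / ns


def expressed_set(m: ExpressionMatrix, fpkm_min: float = 1.0) -> set[str]:
    """Genes with FPKM > fpkm_min in at least one of the 8 samples."""
    mask = (m.values > fpkm_min).any(axis=1)
    return set(m.values.index[mask])


def log2_fold_change(
    m: ExpressionMatrix, gene: str, stage: str, pseudocount: float = 0.01
) -> float:
    """log2((FPKM_MF + pseudocount) / (FPKM_SH + pseudocount)) at one stage."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    mf = m.fpkm(gene, "MF", stage)
    sh = m.fpkm(gene, "SH", stage)
    return math.log2((mf + pseudocount) / (sh + pseudocount))


def call_degs(
    m: ExpressionMatrix,
    theta: float = 2.0,
    fpkm_min: float = 1.0,
    pseudocount: float = 0.01,
) -> list[DEGRecord]:
    """Call per-stage differential expression for every expressed gene.

    direction = up if log2fc >= theta, down if <= -theta, else ns.  One
    record per expressed gene and stage; non-expressed genes yield none, so
    DEG ⊆ expressed by construction.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    expressed = expressed_set(m, fpkm_min)
    records = []
    for gene in m.gene_ids:
        if gene not in expressed:
            continue
        for stage in STAGES:
            fc = log2_fold_change(m, gene, stage, pseudocount)
            if fc >= theta:
                direction = "up"
            elif fc <= -theta:
                direction = "down"
            else:
                direction = "ns"
            records.append(DEGRecord(gene, stage, fc, direction))
    return records


def deg_genes(records: list[DEGRecord]) -> set[str]:
    """Genes differentially expressed in at least one stage."""
    return {r.gene_id for r in records if r.direction != "ns"}


def fold_change_matrix(
    m: ExpressionMatrix, genes=None, pseudocount: float = 0.01
) -> pd.DataFrame:
    """log2 fold-change (MF over SH) matrix, genes x stages."""
    if genes is None:
        genes = m.gene_ids
    data = {
        s: [log2_fold_change(m, g, s, pseudocount) for g in genes]
        for s in STAGES
    }
    return pd.DataFrame(data, index=list(genes))


def assign_pattern_cluster(
    log2fc: "np.ndarray | list[float]",
    delta: float = 0.5,
    theta: float = 2.0,
) -> str:
    """Assign a DEG's 4-stage fold-change vector to the nearest pattern
    cluster.

    Stage signs use the looser threshold delta (default 0.5): +1 if
    log2fc >= delta, -1 if <= -delta, else 0.  The label is the prototype at
    minimum Hamming distance; ties resolve in cluster order I -> VIII.  A
    vector with no stage at |log2fc| >= theta is not a DEG and is rejected.
    """
    fc = np.asarray(log2fc, dtype=float)
    if fc.shape != (4,):
        raise ValueError("expected one log2 fold change per stage (4 values)")
    if not (np.abs(fc) >= theta).any():
        raise ValueError("not a DEG: no stage reaches the threshold")
    signs = np.where(fc >= delta, 1, np.where(fc <= -delta, -1, 0))
    best = None
    for name in CLUSTERS:
        proto = np.asarray(CLUSTER_PROTOTYPES[name])
        dist = int((signs != proto).sum())
        if best is None or dist < best[0]:
            best = (dist, name)
    return best[1]


def hierarchical_cluster(fc_matrix: pd.DataFrame, k: int = 8) -> pd.Series:
    """Agglomerative clustering of DEG fold-change profiles.

    Average linkage on distance 1 - uncentered correlation (cosine), cut to
    k clusters; deterministic for a fixed input order.  Returns a Series of
    integer cluster ids (1..k) indexed by gene.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(fc_matrix) < k:
        raise ValueError(f"need at least k={k} profiles, got {len(fc_matrix)}")
    X = fc_matrix.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError("all-zero profile cannot be clustered")
    dist = pdist(X, metric="cosine")
    Z = linkage(dist, method="average")
    ids = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(ids, index=fc_matrix.index, name="cluster")


def stage_summary(
    m: ExpressionMatrix,
    labels: dict[str, str],
    theta: float = 2.0,
    fpkm_min: float = 1.0,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-subfamily, per-stage expressed-gene (EG) and DEG counts.

    For each subfamily and stage: the number of genes with FPKM > fpkm_min
    in MF or SH at that stage, the number of DEGs at that stage, and the
    count of genes differentially expressed in at least one stage; each with
    its share of the subfamily size (two decimals, half-up).  A Total row
    sums across subfamilies.
    """
    genes = [g for g in m.gene_ids if labels.get(g, "NONE") != "NONE"]
    missing = [g for g in m.gene_ids if g not in labels]
    if missing:
        raise ValueError(f"{len(missing)} matrix gene(s) lack a label")
    records = call_degs(
        ExpressionMatrix(m.values.loc[genes]), theta, fpkm_min, pseudocount
    )
    deg_at = {s: set() for s in STAGES}
    for r in records:
        if r.direction != "ns":
            deg_at[r.stage].add(r.gene_id)
    ever_deg = deg_genes(records)

    subfamilies = sorted(
        {labels[g] for g in genes},
        key=lambda sf: (-sum(labels[g] == sf for g in genes), sf),
    )
    rows = []
    for sf in subfamilies + ["Total"]:
        members = genes if sf == "Total" else [g for g in genes if labels[g] == sf]
        size = len(members)
        row = {"subfamily": sf, "size": size}
        for s in STAGES:
            cols = [f"MF_{s}", f"SH_{s}"]
            eg = int((m.values.loc[members, cols] > fpkm_min).any(axis=1).sum())
            dg = sum(g in deg_at[s] for g in members)
            row[f"EG_{s}"] = eg
            row[f"EG_{s}_pct"] = percentage(eg, size, 2) if size else 0.0
            row[f"DEG_{s}"] = dg
            row[f"DEG_{s}_pct"] = percentage(dg, size, 2) if size else 0.0
        any_deg = sum(g in ever_deg for g in members)
        row["DEG_any"] = any_deg
        row["DEG_any_pct"] = percentage(any_deg, size, 2) if size else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("subfamily")
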