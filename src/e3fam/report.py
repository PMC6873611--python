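"""Report assembly: printed-style percentages, family count tables, and the
end-to-end pipeline driver.

All percentages are rounded half-up at the printed precision (integer for
duplication-mode shares, two decimals for expression tables) — round-half-
even would disagree with the printed anchors.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


def percentage(count: int, total: int, ndigits: int = 0) -> float:
    """100 * count / total, rounded half-up to ndigits decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    q = Decimal(1).scaleb(-ndigits)
    value = (Decimal(count) * 100 / Decimal(total)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass
class FamilyReport:
    """Per-subfamily gene counts with derived shares of the family total."""

    counts: dict
    total: int
    none_count: int
    pct: dict

    def combined_pct(self, subfamilies, ndigits: int = 0) -> float:
        """Share of the total held jointly by several subfamilies."""
        return percentage(
            sum(self.counts.get(sf, 0) for sf in subfamilies), self.total, ndigits
        )


def family_count_table(labels: dict[str, str]) -> FamilyReport:
    """Count genes per subfamily; NONE-labelled genes are excluded from the
    family and reported separately."""
    counts: dict[str, int] = {}
    none_count = 0
    for sf in labels.values():
        if sf == "NONE":
            none_count += 1
        else:
            counts[sf] = counts.get(sf, 0) + 1
    total = sum(counts.values())
    pct = {sf: percentage(n, total, 1) for sf, n in counts.items()} if total else {}
    return FamilyReport(
        counts=dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))),
        total=total,
        none_count=none_count,
        pct=pct,
    )


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    in_dir: str | Path,
    out_dir: str | Path,
    theta: float = 2.0,
    fpkm_min: float = 1.0,
    pseudocount: float = 0.01,
    min_pairs: int = 5,
    max_gap: int = 25,
    tandem_max_gap: int = 1,
    proximal_max_gap: int = 10,
    evalue_cutoff: float = 1.0,
    seed: int | None = None,
) -> dict:
    """Run annotate -> classify -> dupmode -> express -> report.

    Consumes proteins.fasta, genes.gff3, domains.tsv, pairs.tsv and fpkm.tsv
    from ``in_dir``; writes architecture, classification, duplication-mode,
    DEG, cluster and summary TSVs plus a key:value run manifest to
    ``out_dir``.  Output is a pure function of the inputs and parameters, so
    reruns are byte-identical.  Any stage failure aborts with the stage name.
    """
    from . import classify as _classify
    from . import dupmodes as _dup
    from . import expression as _expr
    from . import io_formats as _io
    from .architecture import build_architecture, scan_ring_ligands

    in_dir = Path(in_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(name, exc) from exc
        return wrap

    # --- annotate ---------------------------------------------------------
    def annotate():
        proteins = _io.read_fasta(in_dir / "proteins.fasta")
        hits = _io.read_domain_hits(in_dir / "domains.tsv", evalue_cutoff)
        by_protein: dict[str, list] = {p.protein_id: [] for p in proteins}
        for h in hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        archs, ring_calls = {}, {}
        for p in proteins:
            arch = build_architecture(by_protein.get(p.protein_id, []))
            arch.protein_id = p.protein_id
            archs[p.protein_id] = arch
            ring_calls[p.protein_id] = scan_ring_ligands(p.sequence, p.protein_id)
        rows = []
        for p in proteins:
            calls = ring_calls[p.protein_id]
            rows.append(
                (
                    p.protein_id,
                    p.gene_id,
                    archs[p.protein_id].domain_string(),
                    ";".join(
                        f"{c.ring_type}@"
                        + ",".join(map(str, c.ligand_positions))
                        for c in calls
                    ),
                )
            )
        pd.DataFrame(
            rows, columns=["protein_id", "gene_id", "architecture", "ring_calls"]
        ).to_csv(out_dir / "arch.tsv", sep="\t", index=False)
        return proteins, archs, ring_calls

    proteins, archs, ring_calls = _stage("annotate")(annotate)

    # --- classify ---------------------------------------------------------
    def do_classify():
        genes = _io.read_gff3(in_dir / "genes.gff3")
        rules = _classify.default_rules()
        labels, subgroups = {}, {}
        for p in proteins:
            sf = _classify.assign_subfamily(
                archs[p.protein_id], ring_calls[p.protein_id]
            )
            labels[p.gene_id] = sf
            if sf != "NONE":
                subgroups[p.gene_id] = _classify.assign_subgroup(
                    sf, archs[p.protein_id], rules, ring_calls[p.protein_id]
                )
        cls = pd.DataFrame(
            [
                (g, labels[g], subgroups.get(g, "-"))
                for g in sorted(labels)
            ],
            columns=["gene_id", "subfamily", "subgroup"],
        )
        cls[cls["subfamily"] != "NONE"].to_csv(
            out_dir / "class.tsv", sep="\t", index=False
        )
        cls[cls["subfamily"] == "NONE"].to_csv(
            out_dir / "excluded.tsv", sep="\t", index=False
        )
        hist = _classify.group_by_intron_count(genes)
        pd.DataFrame(
            [(b, n) for b, n in hist.counts.items()],
            columns=["intron_group", "n_genes"],
        ).to_csv(out_dir / "intron_groups.tsv", sep="\t", index=False)
        chrom_tab = _classify.chromosome_distribution(genes, labels)
        chrom_tab.to_csv(out_dir / "chrom_distribution.tsv", sep="\t")
        return genes, labels, subgroups

    genes, labels, subgroups = _stage("classify")(do_classify)

    # --- dupmode ----------------------------------------------------------
    def dupmode():
        raw_pairs = _io.read_pairs(in_dir / "pairs.tsv")
        pairs = [_dup.HomologPair(a, b, s) for a, b, s in raw_pairs]
        ranked = _dup.rank_genes(genes)
        blocks = _dup.detect_collinear_blocks(pairs, ranked, min_pairs, max_gap)
        calls = _dup.classify_duplication(
            ranked, pairs, blocks, tandem_max_gap, proximal_max_gap
        )
        pd.DataFrame(
            [(c.gene_id, c.mode, c.evidence) for c in calls],
            columns=["gene_id", "mode", "evidence"],
        ).to_csv(out_dir / "modes.tsv", sep="\t", index=False)
        e3_calls = [c for c in calls if labels.get(c.gene_id, "NONE") != "NONE"]
        summary = _dup.summarize_modes(
            e3_calls, {g: sf for g, sf in labels.items() if sf != "NONE"}
        )
        summary.counts.to_csv(out_dir / "mode_counts.tsv", sep="\t")
        summary.pct_of_subfamily.to_csv(out_dir / "mode_pct.tsv", sep="\t")
        return calls, summary

    dup_calls, mode_summary = _stage("dupmode")(dupmode)

    # --- express ----------------------------------------------------------
    def express():
        matrix = _io.read_expression(in_dir / "fpkm.tsv")
        records = _expr.call_degs(matrix, theta, fpkm_min, pseudocount)
        degs = _expr.deg_genes(records)
        pd.DataFrame(
            [(r.gene_id, r.stage, r.log2fc, r.direction) for r in records],
            columns=["gene_id", "stage", "log2fc", "direction"],
        ).to_csv(out_dir / "degs.tsv", sep="\t", index=False, float_format="%.6g")
        fc = _expr.fold_change_matrix(matrix, sorted(degs), pseudocount)
        clusters = {
            g: _expr.assign_pattern_cluster(fc.loc[g].to_numpy(), theta=theta)
            for g in fc.index
        }
        rows = [(g, clusters[g], "prototype") for g in fc.index]
        if len(fc) >= 8:
            hier = _expr.hierarchical_cluster(fc, k=8)
            rows += [(g, str(hier[g]), "hierarchical") for g in fc.index]
        pd.DataFrame(rows, columns=["gene_id", "cluster", "method"]).to_csv(
            out_dir / "clusters.tsv", sep="\t", index=False
        )
        summary = _expr.stage_summary(matrix, labels, theta, fpkm_min, pseudocount)
        summary.to_csv(out_dir / "summary.tsv", sep="\t")
        # set-inclusion audits
        expressed = _expr.expressed_set(matrix, fpkm_min)
        assert degs <= expressed, "DEG set escapes the expressed set"
        assert set(clusters) <= degs, "cluster-labelled gene is not a DEG"
        return matrix, records, clusters, summary

    matrix, deg_records, clusters, expr_summary = _stage("express")(express)

    # --- report -----------------------------------------------------------
    def do_report():
        fam = family_count_table(labels)
        pd.DataFrame(
            [(sf, n, fam.pct[sf]) for sf, n in fam.counts.items()]
            + [("Total", fam.total, 100.0), ("NONE", fam.none_count, float("nan"))],
            columns=["subfamily", "n_genes", "pct_of_total"],
        ).to_csv(out_dir / "family_counts.tsv", sep="\t", index=False)
        params = {
            "theta": theta,
            "fpkm_min": fpkm_min,
            "pseudocount": pseudocount,
            "min_pairs": min_pairs,
            "max_gap": max_gap,
            "tandem_max_gap": tandem_max_gap,
            "proximal_max_gap": proximal_max_gap,
            "evalue_cutoff": evalue_cutoff,
            "seed": seed if seed is not None else "-",
        }
        manifest = [f"input.{p.name}: {_sha256(p)}" for p in sorted(in_dir.glob("*"))
                    if p.name in {"proteins.fasta", "genes.gff3", "domains.tsv",
                                  "pairs.tsv", "fpkm.tsv"}]
        manifest += [f"param.{k}: {v}" for k, v in params.items()]
        from .classify import default_rules as _dr
        rule_digest = hashlib.sha256(
            repr(sorted((r.subfamily, r.name, tuple(sorted(r.required)),
                         tuple(sorted(r.forbidden)), r.priority)
                        for r in _dr())).encode()
        ).hexdigest()[:12]
        manifest.append(f"rules.version: {rule_digest}")
        (out_dir / "manifest.txt").write_text("\n".join(manifest) + "\n")
        return fam

    fam = _stage("report")(do_report)

    # conservation audit: subfamily counts sum to total, one mode per gene
    assert sum(fam.counts.values()) == fam.total
    assert len(dup_calls) == len({c.gene_id for c in dup_calls})

    results.update(
        family=fam,
        labels=labels,
        subgroups=subgroups,
        dup_calls=dup_calls,
        mode_summary=mode_summary,
        deg_records=deg_records,
        clusters=clusters,
        stage_summary=expr_summary,
    )
    return results


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]
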