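"""Readers and writers for the plain-text formats the pipeline touches.

All genomic coordinates are 1-based and inclusive (the GFF3 convention);
``validate_interval`` enforces this everywhere.  Protein/gene tables travel
as headered TSV, sequences as FASTA, gene models as GFF3.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Domain-name tokens the subgroup rule engine knows about.  Unknown tokens
#: are kept verbatim (with a warning) and treated as "other" by the rules.
DOMAIN_VOCAB = frozenset(
    {
        "BTB", "F-box", "U-box", "HECT", "RING", "Cullin", "SKP", "DDB",
        "NPH3", "ANK", "NPR", "DUF", "BACK", "LRR", "Pentapeptide", "MATH",
        "TAZ", "Kelch", "WD40", "ARM", "Pkinase", "TPR", "UFD2", "KAP",
        "FBA", "FBD", "UBA", "UIM", "UBQ",
    }
)

CULTIVARS = ("MF", "SH")
STAGES = ("S3", "S4I", "S4II", "S4III")
#: Canonical sample order of the 2-cultivar x 4-stage expression matrix.
SAMPLES = tuple(f"{c}_{s}" for c in CULTIVARS for s in STAGES)


class ParseError(ValueError):
    """A file violated the format contract (message names the location)."""


def validate_interval(start: int, end: int, context: str = "") -> None:
    """Assert the shared 1-based inclusive coordinate convention."""
    if start < 1 or end < start:
        raise ParseError(
            f"invalid 1-based inclusive interval [{start}, {end}] {context}"
        )


# ---------------------------------------------------------------------------
# core record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein: primary transcript translation of one gene."""

    protein_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"empty sequence for {self.protein_id}")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ParseError(
                f"illegal residue(s) {sorted(bad)} in {self.protein_id}"
            )


@dataclass
class GeneModel:
    """One gene locus; ``rank`` is its order index along the chromosome
    (1-based, assigned by :func:`e3fam.dupmodes.rank_genes`)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_exons: int
    n_introns: int
    rank: int = 0

    def __post_init__(self) -> None:
        validate_interval(self.start, self.end, f"for gene {self.gene_id}")
        if self.strand not in {"+", "-"}:
            raise ParseError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.n_exons < 1 or self.n_introns != self.n_exons - 1:
            raise ParseError(
                f"{self.gene_id}: n_introns ({self.n_introns}) must equal "
                f"n_exons ({self.n_exons}) - 1"
            )


@dataclass(frozen=True)
class DomainHit:
    """One domain interval on one protein (aa coordinates, 1-based incl.)."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    evalue: float
    source: str = "external"

    def __post_init__(self) -> None:
        validate_interval(self.start, self.end, f"for hit on {self.protein_id}")
        if self.evalue < 0:
            raise ParseError(f"negative E-value for {self.protein_id}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class ExpressionMatrix:
    """FPKM values for (MF, SH) x (S3, S4I, S4II, S4III), genes as rows.

    Thin wrapper over a pandas DataFrame with the canonical sample order.
    """

    def __init__(self, values: pd.DataFrame):
        missing = set(SAMPLES) - set(values.columns)
        if missing:
            raise ParseError(f"missing sample columns: {sorted(missing)}")
        extra = set(values.columns) - set(SAMPLES)
        if extra:
            raise ParseError(f"unexpected columns: {sorted(extra)}")
        df = values.loc[:, list(SAMPLES)].astype(float)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene_id(s): {dups}")
        if df.isna().any().any():
            raise ParseError("missing FPKM value(s)")
        if (df.to_numpy() < 0).any():
            raise ParseError("negative FPKM value(s)")
        self.values = df

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def fpkm(self, gene: str, cultivar: str, stage: str) -> float:
        return float(self.values.at[gene, f"{cultivar}_{stage}"])

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self.values.equals(
            other.values
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_ISOFORM_SUFFIX = re.compile(r"\.\d+$")


def gene_id_from_protein_id(protein_id: str) -> str:
    """Strip a trailing numeric isoform suffix (``g1.1`` -> ``g1``)."""
    return _ISOFORM_SUFFIX.sub("", protein_id)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    gene_id is the header token with any trailing ``.N`` isoform suffix
    removed; a malformed header or an illegal residue raises
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ParseError(
                f"{path}:{_line_of(path, '>')}: FASTA header without identifier"
            )
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate protein_id {rec.id!r}")
        seen.add(rec.id)
        bad = set(seq) - AA_ALPHABET
        if bad or not seq:
            lineno = _line_of_sequence_error(path, rec.id, bad)
            raise ParseError(
                f"{path}:{lineno}: illegal residue(s) {sorted(bad)} "
                f"in record {rec.id!r}"
                if bad
                else f"{path}:{lineno}: empty sequence for {rec.id!r}"
            )
        records.append(
            ProteinRecord(rec.id, gene_id_from_protein_id(rec.id), seq)
        )
    return records


def _line_of(path: Path, prefix: str) -> int:
    for i, line in enumerate(path.read_text().splitlines(), 1):
        if line.startswith(prefix):
            return i
    return 0


def _line_of_sequence_error(path: Path, protein_id: str, bad: set[str]) -> int:
    # Only walked on the error path; locates the first offending line.
    in_rec = False
    header_line = 0
    for i, line in enumerate(path.read_text().splitlines(), 1):
        if line.startswith(">"):
            if in_rec and not bad:
                return header_line  # empty sequence: blame its header
            in_rec = bool(line[1:]) and line[1:].split()[0] == protein_id
            if in_rec:
                header_line = i
        elif in_rec and bad and set(line.strip().upper()) & bad:
            return i
    return header_line


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene / mRNA / exon features only).

    Exon structure is taken from the gene's primary mRNA — the first mRNA by
    coordinate when several are annotated.  A gene without exon children gets
    ``n_exons = 1`` with a warning; an exon outside its gene's bounds is a
    validation error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        mrnas = sorted(
            db.children(g, featuretype="mRNA"),
            key=lambda f: (f.start, f.end, f.id),
        )
        if mrnas:
            exons = list(db.children(mrnas[0], featuretype="exon"))
        else:
            exons = list(db.children(g, featuretype="exon"))
        for e in exons:
            if e.start < g.start or e.end > g.end:
                raise ParseError(
                    f"exon [{e.start}, {e.end}] outside gene "
                    f"{g.id} bounds [{g.start}, {g.end}]"
                )
        n_exons = len(exons)
        if n_exons == 0:
            logger.warning("gene %s has no exon children; assuming 1 exon", g.id)
            n_exons = 1
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand if g.strand in {"+", "-"} else "+",
                n_exons=n_exons,
                n_introns=n_exons - 1,
            )
        )
    return genes


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + one mRNA + evenly spread exons).

    The exon layout is synthetic but consistent: the first exon starts at the
    gene start, the last ends at the gene end, so a read/write cycle
    preserves every :class:`GeneModel` field.
    """
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda x: (x.chrom, x.start, x.gene_id)):
        lines.append(
            "\t".join(
                [g.chrom, "e3fam", "gene", str(g.start), str(g.end), ".",
                 g.strand, ".", f"ID={g.gene_id}"]
            )
        )
        mrna_id = f"{g.gene_id}.1"
        lines.append(
            "\t".join(
                [g.chrom, "e3fam", "mRNA", str(g.start), str(g.end), ".",
                 g.strand, ".", f"ID={mrna_id};Parent={g.gene_id}"]
            )
        )
        for i, (es, ee) in enumerate(_spread_exons(g.start, g.end, g.n_exons)):
            lines.append(
                "\t".join(
                    [g.chrom, "e3fam", "exon", str(es), str(ee), ".",
                     g.strand, ".", f"ID={mrna_id}.exon{i + 1};Parent={mrna_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _spread_exons(start: int, end: int, n: int) -> list[tuple[int, int]]:
    span = end - start + 1
    if n == 1 or span < 2 * n:
        return [(start, end)]
    # n exons separated by n-1 one-bp gaps, remainder absorbed by the last.
    exon_len = max((span - (n - 1)) // n, 1)
    exons = []
    pos = start
    for i in range(n - 1):
        exons.append((pos, pos + exon_len - 1))
        pos += exon_len + 1
    exons.append((pos, end))
    return exons


# ---------------------------------------------------------------------------
# domain-hit tables
# ---------------------------------------------------------------------------

_HIT_COLUMNS = ["protein_id", "domain_name", "start", "end", "evalue"]


def read_domain_hits(
    path: str | Path, evalue_cutoff: float = 1.0
) -> list[DomainHit]:
    """Read the 5-column domain-hit TSV, dropping hits above the E-value
    cutoff (default 1.0) with a logged count.  Unknown domain tokens are kept
    verbatim with a warning; the rule engine treats them as "other".
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str},
                     float_precision="round_trip")
    unknown_cols = set(df.columns) - set(_HIT_COLUMNS)
    missing_cols = set(_HIT_COLUMNS) - set(df.columns)
    if unknown_cols or missing_cols:
        raise ParseError(
            f"{path}: expected columns {_HIT_COLUMNS}, got {list(df.columns)}"
        )
    hits: list[DomainHit] = []
    n_dropped = 0
    unknown_tokens: set[str] = set()
    for row in df.itertuples(index=False):
        if row.evalue > evalue_cutoff:
            n_dropped += 1
            continue
        if row.domain_name not in DOMAIN_VOCAB:
            unknown_tokens.add(row.domain_name)
        hits.append(
            DomainHit(
                protein_id=row.protein_id,
                domain_name=row.domain_name,
                start=int(row.start),
                end=int(row.end),
                evalue=float(row.evalue),
                source="external",
            )
        )
    if n_dropped:
        logger.info(
            "dropped %d domain hit(s) with E-value > %g", n_dropped, evalue_cutoff
        )
    for tok in sorted(unknown_tokens):
        logger.warning("unknown domain token %r kept verbatim", tok)
    return hits


def write_domain_hits(hits: list[DomainHit], path: str | Path) -> None:
    # evalues written with repr for a lossless text round trip
    pd.DataFrame(
        [(h.protein_id, h.domain_name, h.start, h.end, repr(h.evalue))
         for h in hits],
        columns=_HIT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_interproscan_tsv(
    path: str | Path, evalue_cutoff: float = 1.0
) -> list[DomainHit]:
    """Adapter for headerless InterProScan TSV output.

    Maps protein accession, signature accession, start, stop and score onto
    :class:`DomainHit`; remaining columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 9:
        raise ParseError(f"{path}: InterProScan TSV needs >= 9 columns")
    hits = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        evalue = float(row[8]) if row[8] not in {"-", None} else 0.0
        if evalue > evalue_cutoff:
            n_dropped += 1
            continue
        hits.append(
            DomainHit(
                protein_id=row[0],
                domain_name=row[4],
                start=int(row[6]),
                end=int(row[7]),
                evalue=evalue,
            )
        )
    if n_dropped:
        logger.info("dropped %d InterProScan hit(s) above cutoff", n_dropped)
    return hits


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read the FPKM TSV (first column gene_id, the 8 sample columns in any
    order) into an :class:`ExpressionMatrix` with canonical sample order."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                     float_precision="round_trip")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: first column must be gene_id")
    df = df.set_index("gene_id")
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# homolog-pair tables
# ---------------------------------------------------------------------------

def read_pairs(path: str | Path) -> list[tuple[str, str, float]]:
    """Read the homolog-pair TSV (gene_a, gene_b, score); canonicalizes each
    pair to gene_a < gene_b, drops self-pairs and exact duplicates."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str},
                     float_precision="round_trip")
    for col in ("gene_a", "gene_b", "score"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    pairs: dict[tuple[str, str], float] = {}
    n_self = 0
    for row in df.itertuples(index=False):
        if row.gene_a == row.gene_b:
            n_self += 1
            continue
        key = tuple(sorted((row.gene_a, row.gene_b)))
        pairs.setdefault(key, float(row.score))
    if n_self:
        logger.info("dropped %d self-pair(s)", n_self)
    return [(a, b, s) for (a, b), s in sorted(pairs.items())]


def write_pairs(pairs: list[tuple[str, str, float]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["gene_a", "gene_b", "score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    """Read a YAML-style key: value config file into a flat dict."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a key: value mapping")
    return data
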