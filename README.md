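# e3fam

Gene-family analysis for plant **E3 ubiquitin ligases** — the substrate-
selecting enzymes of the ubiquitin/26S-proteasome pathway.  The package
re-implements, as a tested and reusable pipeline, the three stages of a
genome-wide E3 family study in peach (*Prunus persica*):

1. **Domain-architecture classification.**  Proteins are assigned to eight
   subfamilies (RING, F-box, BTB, U-box, SKP, Cullin, HECT, DDB) by their
   diagnostic domain, and to subgroups within BTB (14), F-box (10),
   U-box (7) and HECT (3) by an explicit, user-overridable rule table over
   the additional domains.  RING fingers are detected natively from
   sequence by matching the eight metal-ligand grammar
   `C-x2-C-x(9..39)-C-x(1..3)-M4-x(2..3)-M5-x2-C-x(4..48)-C-x2-C` and typed
   into RING-HC (C3HC4), RING-H2 (C3H2C3), RING-C2, RING-v, RING-S/T and
   RING-G from the residues at the 4th/5th ligand positions and the
   inter-ligand spacing.
2. **Duplication-mode dissection.**  From gene ranks and homolog pairs,
   every gene receives exactly one mode with priority
   WGD > TD > PD > DSD > singleton: pairs chained into collinear
   (syntenic) blocks by dynamic programming mark whole-genome/segmental
   duplicates; adjacent homologs are tandem; homologs within a 10-rank
   window are proximal; any other homology is dispersed.
3. **Expression profiling (MF vs SH).**  FPKM matrices over two cultivars
   (melting flesh, stony hard) and four ripening stages (S3, S4I, S4II,
   S4III) pass an expressed filter (FPKM > 1 in any sample), per-stage
   fold-change DEG calling (|log2 MF/SH| ≥ 2), assignment of DEGs to eight
   canonical expression-pattern clusters by nearest signed stage-profile
   prototype, and an agglomerative cross-check (average linkage on
   1 − uncentered correlation).

Because the original genome and RNA-seq reads are not needed to test the
*method*, a first-class synthetic-data generator plants known domain
architectures, RING motifs, duplication structures and expression effects,
and every stage is scored against that planted truth.

## Worked example

```python
from e3fam import SimulationConfig, simulate_all, write_dataset, run_pipeline

cfg = SimulationConfig(seed=1, n_genes=200)
ds = simulate_all(cfg)                      # proteins, GFF3, hits, pairs, FPKM
write_dataset(ds, "demo/inputs")
results = run_pipeline("demo/inputs", "demo/out", seed=1)

fam = results["family"]
print("family counts:", fam.counts, "total:", fam.total,
      "excluded:", fam.none_count)
```

prints

```
family counts: {'RING': 79, 'F-box': 63, 'BTB': 16, 'U-box': 13, 'SKP': 4,
'Cullin': 3, 'DDB': 1, 'HECT': 1} total: 180 excluded: 20
```

i.e. of 200 simulated genes, 180 carry a diagnostic E3 domain (RING and
F-box dominating, as in real proteomes) and 20 decoys were excluded for
lacking one.  The duplication summary for the same run,

```
mode       DSD  TD  WGD  PD  SINGLETON  Total
BTB          1   1    0   1         13     16
...
Total       25  16   22  13        104    180
```

recovers exactly the planted tandem arrays (16 TD genes), collinear blocks
(22 WGD genes among labelled families), proximal and dispersed pairs, and
the expression stage reports 45 DEGs, all assigned to pattern clusters
I–VIII (`{'I': 6, 'II': 5, 'III': 4, 'IV': 6, 'V': 8, 'VI': 5, 'VII': 7,
'VIII': 4}`).

The same stages are available from a shell:

```bash
e3fam simulate --seed 1 --out-dir demo/inputs
e3fam report --in-dir demo/inputs --out demo/out
```

## Layout

```
src/e3fam/
  io_formats.py    FASTA / GFF3 / TSV readers and writers, coordinate checks
  simulate.py      synthetic proteome, genome layout, FPKM generator + truth
  architecture.py  hit resolution, RING ligand scanner and typer
  classify.py      subfamily/subgroup rule engine, intron groups, chrom table
  dupmodes.py      gene ranking, collinearity chaining, mode classification
  expression.py    expressed filter, DEG calling, pattern + hierarchical clusters
  report.py        percentages, family tables, end-to-end pipeline driver
  cli.py           the e3fam command
```

See `docs/methods.md` for the model conventions, parameter defaults and
known limitations.
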