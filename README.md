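# tpsfam

Genome-wide characterization of a plant **terpene synthase (TPS) gene family**,
packaged as a reusable, tested pipeline with a synthetic-genome generator that
plants every feature the analysis must recover.

Plant TPS families are large (dozens of loci, heavily tandem-duplicated) and
are annotated by a standard recipe: screen predicted proteins against known
TPS enzymes, keep products of at least 400 residues as putative functional
genes, read the exon/intron architecture (class I: 11–14 introns, class II: 9,
class III: 6 — the mono-/sesquiterpene synthase architecture), scan for the
conserved catalytic motifs (RRX8W, RDR, DDXXD, NSE/DTE; DXDD in class II-type
cyclases), compute molecular weight and isoelectric point, detect tandem
clusters along the chromosomes, build a neighbor-joining tree with bootstrap
against subfamily reference proteins (TPS-a, -b, -c, -e/f, -g), and summarize
RPKM expression per tissue. `tpsfam` implements each of those steps as an
importable module and chains them into one reproducible run.

Because the original genome-scale counts depend on a specific genome release,
correctness here is demonstrated on **synthetic genomes with planted ground
truth**: the generator emits FASTA + GFF3 + references + expression matrices
whose subfamily sizes, gene architectures, motif positions, cluster layout,
pseudogenes and tissue-specific genes are all known, and the pipeline must
recover them exactly.

## Library layout

| module | what it does |
| --- | --- |
| `tpsfam.genome_io` | FASTA/GFF3 read/write, spliced CDS assembly, ORF finding, translation |
| `tpsfam.architecture` | intron phases, class assignment, exon/intron stats, splice-site consensus |
| `tpsfam.protein_props` | ≥400-aa functionality filter, average MW, pI by bisection, mono/sesqui hints |
| `tpsfam.motifs` | degenerate motif notation compiler + overlapping scanner, completeness calls |
| `tpsfam.homology` | BLOSUM62 global alignment, percent identity, paralog pairs, reference search |
| `tpsfam.phylogeny` | p-distances, neighbor joining, bootstrap supports, subfamily assignment, progressive MSA |
| `tpsfam.clusters` | tandem-cluster chaining (<67 kb gaps), chromosome/strand census |
| `tpsfam.expression` | RPKM categories, tissue specificity, heatmap-ready clustering |
| `tpsfam.simulate` | the synthetic-genome generator (`FamilySpec`, `assemble_genome`, ...) |
| `tpsfam.pipeline` / `tpsfam.cli` | orchestration + `tpsfam simulate\|run\|report` CLI |

## Worked example

```bash
python analysis/01_simulate_genome.py
python analysis/02_characterize_family.py
python analysis/03_figures.py
```

The first script prints (default family, fixed seed):

```
simulated 95 genes on 30 sequences
  functional: 55, pseudogenes: 40
  functional subfamily counts: {'tps-a': 28, 'tps-b': 18, 'tps-g': 5, 'tps-ef': 2, 'tps-c': 2}
  planted clusters: 19 (61 member genes)
  unplaced scaffolds: 24
```

i.e. a family of 95 loci, 55 of them with full-length products split
28/18/2/2/5 across the five angiosperm subfamilies, 61 genes arranged in 19
tandem clusters and 24 genes on unplaced scaffolds. The second script runs
the pipeline on those files and ends with:

```
recovery vs planted truth:
  subfamily counts recovered exactly: True
  pseudogene filter errors: 0
  clusters detected: 19
```

meaning every planted pseudogene was caught by the 400-residue filter, all 19
clusters were re-detected at the 67 kb gap threshold, and the NJ tree anchored
on the reference proteins reassigned every functional gene to its true
subfamily. Per-stage tables (dispositions, architecture, motif completeness,
properties, identity matrix, paralogs, Newick tree, expression categories)
land under `results/pipeline/`.

The same run is available through the CLI:

```bash
tpsfam simulate --seed 1 --outdir sim/
tpsfam run --genome sim/genome.fasta --gff3 sim/genes.gff3 \
    --references sim/references.fasta --reference-labels sim/reference_labels.tsv \
    --expression sim/expression.tsv --outdir out/ --seed 7
```

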