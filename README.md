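# ucescan

Discovery and characterization of ultraconserved elements (UCEs) in
multi-species whole-genome alignments.

`ucescan` scans a MAF alignment for maximal runs of columns that are
present and identical in every required species (≥ 18 bp by default),
lifts them to reference coordinates, flags repeat (multi-mapping)
sequences, and then characterizes the resulting elements by:

- **genomic location** — exon / UTR / intron / RNA-gene / intergenic
  composition against a GFF3 annotation, AT content, and mod-3 length
  periodicity;
- **matched random controls** — N independent control interval sets
  matched for number and length (drawn from the alignment coverage mask)
  or additionally for genic/intergenic location (drawn genome-wide);
- **motif content** — JASPAR PFM scanning with exact DP-computed null
  p-values and joint BH q-values, plus a Cas9 target-site search
  (18 bp + NGG / CCN + 18 bp, fully internal);
- **population diversity** — per-region segregating sites, nucleotide
  diversity π, and Tajima's D from a many-sample VCF, with paired
  UCE-vs-control contrasts and a SNP-free element count;
- **GO enrichment** — length-bias-corrected over-representation using an
  isotonic-regression probability weighting function and Wallenius
  noncentral hypergeometric tails (with an uncorrected Fisher mode for
  comparison);
- **synteny** — cross-species positional conservation through orthology
  of containing genes (genic UCEs) or nearest flanking genes (intergenic
  UCEs), with the six-way flank-category split;
- **target report** — a per-gene ranking of gene-drive target
  suitability (SNP-free Cas9-compatible UCE count, then total invariant
  bases), with an optional phenotype-table join.

A first-class synthetic-data module generates MAF / FASTA / GFF3 / VCF /
JASPAR / ortholog / GO fixtures with planted ground truth (invariant
elements, motif occurrences, orthology mismatch rates, length-biased GO
terms), so the entire pipeline runs and is validated without any
genome-scale downloads.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes per-module unit tests, property tests
(hypothesis), independent brute-force oracles (per-column alignment
scans, all-pairs diversity, exhaustive 4^w motif enumeration, biased-urn
Monte Carlo), and `tests/test_acceptance.py` with the binding desk-scale
acceptance criteria (planted-truth recovery on a 1 Mb / 21-species
simulation, oracle equivalence, Wallenius exactness, null calibration of
every comparison statistic).

## CLI

```bash
uce-scan simulate --config sim.yaml --outdir data/
uce-scan discover --maf data/alignment.maf --ref data/reference.fa \
    --out-prefix out/uces
uce-scan annotate --uces out/uces.tsv --gff data/genes.gff3 --out out/annot.json
uce-scan controls --uces out/uces.tsv --maf data/alignment.maf --mode maf \
    --n 10 --seed 1 --outdir out/controls
uce-scan motifs  --seqs out/uces.tsv --pfms data/motifs.jaspar --q 0.05 \
    --out-prefix out/motifs
uce-scan popgen  --vcf data/variants.vcf --uces out/uces.tsv \
    --controls out/controls --out-prefix out/popgen
uce-scan enrich  --uces out/uces.tsv --gff data/genes.gff3 \
    --go data/go_terms.tsv --alpha 0.05 --out out/enrichment.tsv
uce-scan synteny --uces out/uces.tsv --maf data/alignment.maf \
    --gff-a data/genes.gff3 --gff-b data/genes_b.gff3 \
    --orthologs-a data/orthologs_a.tsv --orthologs-b data/orthologs_b.tsv \
    --species-b sp01 --out out/synteny.json
uce-scan all --config pipeline.yaml     # full pipeline, deterministic
```

`pipeline.yaml` lists input paths plus thresholds and a seed; see
`ucescan.pipeline.PipelineConfig` for all keys. Optional inputs (VCF,
PFMs, orthologs, GO table, phenotype table) switch their stages off with
a warning.

## Layout

```
src/ucescan/
  simulate.py    synthetic fixtures with planted truth
  mafio.py       MAF block model + streaming reader/writer
  discovery.py   invariant-run scan, repeat flagging, BED/TSV output
  annotation.py  GFF3 feature index, per-base classification, composition
  controls.py    coverage mask + matched control-set sampler
  motifs.py      PWM scan with exact p-values, BH q-values, Cas9 search
  popgen.py      S / π / Tajima's D per region, UCE-vs-control contrasts
  goenrich.py    PWF + Wallenius noncentral hypergeometric enrichment
  synteny.py     MAF-based lift, genic/flanking orthology categories
  pipeline.py    end-to-end orchestration + target report
  cli.py         `uce-scan` entry point
```
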