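# decontax

Host-read decontamination for metagenomics, plus the statistics to benchmark it.

Metagenomic sequencing data — stool, saliva, sputum, environmental samples —
carries substantial host (typically human) sequence. Because even a handful of
human reads can leak identifiable genetic information, such reads must be
removed before data are shared or published; at the same time, microbial reads
must survive the filter unbiased. `decontax` implements the computational core
of that task for read pairs:

* **Cutoff model over Kraken2 per-read output** — Kraken2 assigns every k-mer
  of a read to the lowest common ancestor (LCA) of the genomes containing it.
  Given a filter target (a taxon name, e.g. *Homo sapiens*, expanded to its
  whole taxonomic subtree), each read pair's k-mers are tallied into `T`
  (target subtree), `O` (other classified taxa) and `U` (unclassified), and
  the pair is labeled as contamination iff

  1. `T > cutoff_tax2filter`,
  2. `T / (O + T) > cutoff_tax2keep`, and
  3. `T / (U + T) > cutoff_unclassified`.

  With all cutoffs at 0 (the benchmark default) a pair is labeled exactly when
  at least one k-mer hits the target subtree; raising any cutoff only shrinks
  the labeled set.

* **Canonical k-mer membership classifier** (bbduk-style) — a reference FASTA
  is decomposed into canonical k-mers (default `k = 27`); a read pair is
  labeled when either mate shares at least one k-mer with the reference.

* **Union merge and filtering** — the union of both classifiers' labeled
  read-pair IDs is final; labeled pairs are removed from the paired FASTQ
  files (optionally also written to a removed-reads output).

* **Benchmark evaluation** — with host pairs as the positive class
  (TP/FP removed, TN/FN retained):
  `recall = TP/(TP+FN)` measures decontamination thoroughness,
  `precision = TP/(TP+FP)` measures microbial retention. Composition bias in
  removed/retained microbial reads is tested with a 2×2 Pearson χ² test of
  independence (df = 1, no continuity correction), and cross-method FN
  intersections / FP unions quantify what chaining methods buys and costs.

* **Synthetic fixtures** — a taxonomy with a host and several microbes, random
  genomes with controllable k-mer sharing, error-bearing paired reads with a
  truth manifest, and Kraken2-format per-read output from a miniature LCA
  emulator, so the full pipeline runs and is testable with no downloads.

## Worked example

Simulate a community (32% host read pairs, disjoint genomes, error-free reads)
and run the full pipeline — both classifiers, merge, filter, evaluation:

```bash
decontax simulate --outdir sim --n-pairs 150 --seed 3
decontax all --samplesheet sim/samplesheet.csv \
    --nodes sim/taxonomy/nodes.dmp --names sim/taxonomy/names.dmp \
    --classification-bbduk --fasta-bbduk sim/taxonomy/taxon_9606.fasta \
    --output-removed-reads --outdir run
cat run/summary.tsv run/sim/evaluation.tsv
```

prints

```
sample	tool	labeled	fraction
sim	kraken_model	45	0.3
sim	kmer_classifier	45	0.3
sim	merged	45	0.3
method	tp	fp	tn	fn	recall	precision
kraken_model	45	0	105	0	1.0	1.0
kmer_classifier	45	0	105	0	1.0	1.0
merged	45	0	105	0	1.0	1.0
```

Of 150 simulated pairs, 45 came from the host genome; both classifiers label
exactly those 45 (the realized draw at this seed), the merged union is
identical, and filtering removes them — recall and precision are both 1.0
because the synthetic genomes share no k-mers and the reads carry no errors.
`run/sim/` also holds the kept/removed FASTQ files and per-tool label lists.

The same machinery scores any external decontamination run: give `decontax
evaluate` a truth manifest and one or more removed-ID lists and it writes the
metrics table plus, for multiple methods, FN-intersection and FP-union tables
suitable for upset-style plots.

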