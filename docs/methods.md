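# Methods

## The labeling model

Decontamination here is a per-read-pair classification problem: given
sequencing evidence, decide whether a pair originates from an unwanted
("host") taxon. Two classifiers with complementary failure modes are
implemented, because exact k-mer membership and LCA-resolved k-mer
classification disagree precisely on sequence shared between the host and
other taxa.

**Cutoff model (Kraken2 evidence).** Kraken2 reports, per read, an ordered
run-length encoding of k-mer assignments: a taxon ID (the LCA of all database
genomes containing that k-mer), `0` for k-mers absent from the database, or
`A` for windows spanning ambiguous bases. The filter target is a scientific
name resolved against a taxdump-dialect taxonomy and expanded to its full
subtree. Pooling both mates, k-mers are tallied into `T` (assigned within the
target subtree), `O` (any other classified taxon) and `U` (unclassified), and
a pair is labeled iff

    T > cutoff_tax2filter            (count, default 0)
    T / (O + T) > cutoff_tax2keep    (ratio in [0,1], default 0)
    T / (U + T) > cutoff_unclassified(ratio in [0,1], default 0)

Choices made where the interface description leaves room:

* **Strict inequalities** on all three conditions. At the all-zero defaults
  this gives the intended semantics "label iff at least one target k-mer",
  and it makes the boundary case ratio == cutoff unlabeled, which keeps the
  label set monotone non-increasing in every cutoff.
* **Ambiguous (`A`) k-mers are excluded from all three counts.** Including
  them in `U` would penalize low-complexity reads through condition (iii)
  for reasons unrelated to taxonomy; excluding them keeps both ratios
  interpretable as fractions of informative k-mers.
* **Ancestors of the target count as `O`, not `T`.** Only the subtree is the
  filter target; a k-mer whose LCA is, say, "cellular organisms" is evidence
  shared with non-target taxa, not evidence for the target. This is the
  conservative reading (fewer labels) and is what makes the combination of
  classifiers informative — see the synthetic shared-segment experiment.
* **Mates are pooled before the conditions.** A pair is labeled (and later
  removed) as a unit; labeling on either-mate-alone would differ only in
  making condition (ii)/(iii) denominators smaller and is not what pair-level
  removal semantics suggest.

**Canonical k-mer classifier (bbduk-style).** The reference FASTA is indexed
as the set of canonical k-mers — `min(kmer, revcomp(kmer))` under A<C<G<T —
of every length-k window; windows containing non-ACGT characters are skipped
and case is folded (masked lower-case reference is still indexed). A read
hits if any of its valid windows is in the set; a pair is labeled if either
mate hits. Default `k = 27`. Exact membership only: no Hamming-distance
neighborhoods, no middle-base masking. k-mers are stored as Python strings
in a set; at reference scales up to megabases this is well within memory,
and the contract is set membership, so a 2-bit-packed representation could
be swapped in without interface change (k ≤ 31 is supported regardless).

**Merge and filter.** The union of the classifiers' label sets is final.
IDs are normalized (first-whitespace token, leading `@` dropped, one
trailing `/1`/`/2` stripped) so Kraken-side and FASTQ-side spellings agree;
this rule set is a documented convention of this package, since ID dialects
drift between tools. Filtering preserves record order, removes both mates of
a labeled pair together, mirrors gzip compression (detected by magic bytes,
not extension), and treats labeled IDs absent from the FASTQ as a reported
count rather than an error.

## Evaluation

Host pairs are the positive class: TP and FP are removed pairs (host and
microbial respectively), FN and TN appear in the decontaminated output.
Recall `TP/(TP+FN)` measures thoroughness of removal; precision `TP/(TP+FP)`
measures microbial retention. The ID universe is taken from the truth
manifest, not from the FASTQ, so evaluation is independent of filtering
dialects. Metrics are reported at 5 decimals; raw doubles are kept
internally.

Composition bias between two microbial source categories among removed (FP)
versus retained (TN) reads is tested with a 2×2 Pearson χ² test of
independence, df = 1, **no continuity correction**: at the intended-use
counts (≥ 10⁴ per cell) the correction is negligible, but users testing
small tables should be aware the uncorrected statistic is anti-conservative.
A table with a zero row or column total is rejected as degenerate.

Cross-method set algebra reports, for every non-empty subset of methods, the
size of the intersection of their FN sets (2^k − 1 entries, antitone in
subset inclusion), and the size of the FP union together with each method's
incremental FP over the first (base) method. A tidy table for upset-style
plotting is emitted instead of rendered figures.

## Synthetic data

The generator emulates the structure of a decontamination benchmark with a
known ground truth, not any particular instrument:

* **Community**: a small taxonomy (host species under Eukaryota, microbes
  under Bacteria, joined at "cellular organisms") and i.i.d.-uniform random
  genomes — host 20 kb, microbes 12 kb by default. Random 12–20 kb genomes
  share no 27-mers in practice (collision probability ≈ 10⁻⁸ per pair of
  genomes), giving a clean separability baseline. Optional shared segments
  are copied verbatim between two genomes; a segment of length k+m−1
  contributes exactly m shared k-mers.
* **Reads**: paired-end, default 150 bp, normal insert (mean 350, sd 35)
  clipped to [read length, genome length], uniform start positions, R1 the
  forward strand of the fragment start and R2 the reverse complement strand
  of the fragment end. Substitution errors i.i.d. per base; **no indels**
  and no quality-dependent error profile — sufficient to exercise k-mer
  mismatch behavior, not a platform simulator. Default host abundance 0.32
  mirrors a host-heavy benchmark mixture (~10M host in ~31M pairs).
* **Kraken-format output**: a map from canonical k-mer to the LCA of all
  taxa whose genomes contain it (default k = 31, Kraken2's default k-mer
  length) drives per-read run-length-encoded assignment tokens; misses are
  `0`, non-ACGT windows are `A`, mates join with `|:|`. The consensus column
  carries the plurality assigned taxon; the cutoff model never reads it.

Because genomes are random and error models simplistic, passing end-to-end
tests demonstrates correctness of the algebra and the classifiers' contracts
— perfect recall/precision on disjoint genomes, the shared-segment
FP/LCA dissociation between the two classifiers — not performance on real
human-microbial data, where divergence from the reference, low-complexity
sequence and true shared biology dominate the error budget.

All outputs are pure functions of (spec, parameters, seed); label lists and
tables are written in sorted order so identical runs are byte-identical.

## Numerical and interface choices

* Taxonomy parsing accepts both tab-pipe-padded and bare `|` dmp delimiters,
  ignores fields beyond rank, takes only "scientific name" class entries,
  detects the root as the unique self-parent node, and rejects missing
  parents and cycles with the offending taxon named. Name resolution is
  exact-match first, case-insensitive fallback, with ambiguity an error —
  synonym classes are deliberately unsupported.
* The χ² statistic and p-value come from `scipy.stats.chi2_contingency`
  (correction disabled); the test suite cross-checks it against the
  closed-form Σ(obs−exp)²/exp.
* Problem sizes in the test suite and acceptance script (hundreds to a few
  thousand read pairs, 12–20 kb genomes) were chosen as the smallest scales
  at which every pipeline path — both classifiers, merge, filter,
  evaluation — is exercised with non-trivial realized draws.

## Known limitations

* The k-mer classifier is exact-membership only; bbduk's mismatch and
  masking modes are out of scope, so agreement with bbduk is at the level of
  the default at-least-one-k-mer contract, not bit-for-bit.
* The cutoff model consumes Kraken2 *output*; it does not reimplement
  Kraken2's classifier or confidence scoring, and it assumes the database's
  taxonomy matches the taxdump given for subtree expansion.
* Single-end data flow through all interfaces, but the evaluation convention
  counts read pairs; mixing single- and paired-end in one sample sheet is
  untested territory.
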