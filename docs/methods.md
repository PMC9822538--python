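# Methods

`snphase` implements a progressive, haplotype-aware SNP caller for
low-coverage long-read alignments, together with the diploid read simulator
that makes every stage trainable and testable at desk scale.  This note
records the model, its assumptions, the tunable parameters, and the design
choices made where the design was genuinely open.

## The calling model

**Candidate search.** For every reference position `b` with reference base
`B_r`, the pileup records per-strand counts over `{A, C, G, T, I, D}` (an
insertion is counted once at its anchor, the aligned base immediately to the
left; every reference position under a deletion contributes one `D`).  The
alternative-allele frequency is

    f_b = max{ count of symbol B at b : B in {A,C,G,T,I,D} \ {B_r} } / depth_b ,

with counts pooled over strands and depth counting every read whose
alignment spans `b`, including reads with `D` there (so `f_b <= 1` always).
`b` is a candidate iff `depth_b > d` and `f_b > e`, both strict; defaults
`d = 6`, `e = 0.12`.  Reads that are unmapped, secondary, supplementary or
below MAPQ 1 are excluded from pileups (standard pileup hygiene; the
filter is exposed in `CandidateConfig.min_mapq`).

**Round one — pileup model.** Each candidate becomes a `(2w+1) x 16` image
(`w = 16`): one row per position of `[b-w, b+w]`, eight forward-strand
features `(C[A], C[C], C[G], C[T], C[I], C[D], IMAX, DMAX)` then the same
eight from reverse reads only; IMAX/DMAX are per-strand maxima.  Rows
outside the contig are zero so shapes are fixed.  The network is two
stacked bidirectional LSTM layers; the middle time step of the
tanh-activated recurrent output feeds one dense layer and two softmax
heads: 21 genotype classes (unordered symbol pairs, `AA ... ID`) and 3
zygosity classes (hom-ref 0/0, hom-alt 1/1, het 0/1).

**Phasing and haplotagging.** Het calls with quality >= 14 and two distinct
base alleles are phased by a built-in minimum-error-correction heuristic
(below); each read is then assigned to the haplotype whose alleles it
matches at strictly more phased sites, ties and uninformative reads staying
unphased.  This yields the four alignment subsets (original, hap1, hap2,
unphased).

**Round two — haplotype model.** At each position `j` and for each subset,
the combined feature `T_j` (length 26) stacks nucleotide counts `C_j^B` and
frequencies `F_j^B` over `{A,C,G,T,D}`, base-quality sums `Q_j^B` and means
`U_j^B`, and mapping-quality sums `M_j^B` and means `V_j^B` over `{A,C,G,T}`;
mean terms are 0 where the count is 0, and `F` normalises by the all-five
symbol total exactly as defined.  Insertions are invisible to `T_j`.  The
short-range image stacks `T_j` over `[b-w, b+w]` (`33 x 104` after
concatenating the four subsets); the long-range image stacks `T_j` at the
`t = 5` nearest quality->=14 het sites on each side of `b` plus `b` itself
(`11 x 104`), zero-padding (with a validity mask) when a side has fewer
than `t` sites.  The het-site list is computed once per contig.  Two
recurrent branches with the round-one architecture (one per image, each
reduced at its middle time step) are joined by a dense combining layer and
feed 10-class genotype and 3-class zygosity heads.

**Quality and merging.** Per head, the Phred-like score is
`q(P) = (10/ln 10) ln(P/(1-P))`, clipped to `[0, 60]`; a record's quality is
the smaller of its genotype and zygosity scores.  The log-odds form is the
convention of earlier deep-learning genotypers and is the only reading
under which a min-of-two-scores rule behaves sensibly; the clip cap of 60
is this package's choice.
At each candidate the merge rule is: haplotype-model quality > delta (=14)
-> its decision stands (a variant pair is emitted; a confident hom-ref
yields no record and shadows round one); otherwise pileup-model quality >
delta -> its call is emitted (unless its pair involves I/D — the final VCF
is SNP-only); otherwise the site is discarded.  Both comparisons are strict,
so a quality of exactly delta discards (the keep branch requires "greater
than" and the discard branch "less than", leaving equality to the discard
side by construction).  Output is an unphased VCF v4.2 with GT and GQ; het calls with
two non-reference alleles are written as `1/2` with two ALTs.

## Probability calibration

Training uses label smoothing `s = 0.1` on both heads.  Smoothing pins the
optimum softmax maximum at `1 - s + s/K` (0.905 for `K = 21`, 0.933 for
`K = 3`), and under the log-odds transform those caps correspond to
qualities of ~9.8 and ~11.5 — *below* the het-selection and merge
thresholds of 14.  Taken literally, the three constants (smoothing 0.1,
threshold 14, log-odds quality) cannot coexist: every call would be
discarded.  The package resolves this with standard temperature
scaling: after training, a single scalar `T` per model is fitted by
minimising the unsmoothed negative log-likelihood of the training
candidates under `logits / T` (grid search over `[0.05, 3]`,
deterministic), and inference probabilities are `softmax(logits / T)`.
Typical fitted values are `T ~ 0.5` (sharpening), which restores
high-confidence probabilities for clear-cut sites while leaving ambiguous
sites below threshold.  `quality_score` itself remains the pure log-odds
law (`q(0.5) = 0`, strictly monotone, antisymmetric before clipping).

## Phasing heuristic

Sites sharing at least one informative read form a phase block (connected
component).  Within a block, orientations are initialised greedily left to
right (each site oriented by the current leaning of the reads covering it),
then refined by single-site flips and suffix flips — the classic
switch-error move — until neither lowers the MEC cost, i.e. the number of
read-allele conflicts after every read is assigned to its better haplotype.
Blocks with at most 12 sites are additionally solved exactly by enumerating
orientations with the first site fixed (the global hap1/hap2 swap is a
symmetry), so small blocks are provably optimal and large blocks inherit a
strong local optimum.  The hap1/hap2 labelling of each block is fixed by
the tie-break "first site's first (canonically ordered) allele -> hap1";
blocks are never stitched across connectivity gaps.  An external phaser
(e.g. WhatsHap) can be substituted by constructing a `PhasedSiteSet` from
its output; nothing downstream distinguishes the source.

## The simulator

`generate_diploid` plants SNPs (default rate 1e-3 per base — roughly the
density of a human genome against its reference), short 1-5 bp indels
(default 2e-4), with 2/3 of variants heterozygous (the familiar ~2:1
het:hom ratio); variants are kept >= 2 bp apart so alleles never overlap.
Haplotype sequences and hap->reference coordinate maps are materialised
explicitly.  `simulate_reads` draws reads alternately from the two
haplotypes (gamma-distributed lengths, mean 5 kb; ~50/50 strands; MAPQ
uniform in [40, 60]), injects substitution/insertion/deletion errors per
base (defaults 4%/1%/1%, the scale of modern long-read error profiles),
and emits each read at its true coordinates with an exact CIGAR — no
external aligner, which makes feature-extractor oracles exact.  Reads may
overhang contig ends and are clipped; the read count compensates so mean
depth matches the target.  Base qualities are drawn from two Beta-scaled
Phred bands (correct bases ~Q5-30 centred near Q22, erroneous and inserted
bases ~Q2-17 centred near Q7) so quality features carry learnable signal.
Truth artifacts are a FASTA (+ .fai), a coordinate-sorted indexed BAM with
the true haplotype in the `XH` tag, a truth VCF (1-based, GT per zygosity)
and a whole-contig confident-region BED; a FASTQ export exists for optional
re-alignment.

What the simulator does *not* emulate — and hence what passing tests do not
show about real data: pore-level signal, homopolymer- and context-dependent
error structure, chimeric/split or clipped mappings, mappability artifacts,
reference bias, structural variants, and coverage biases beyond binomial
fluctuation.

## Training profiles

The **full profile** is the full-scale schedule (hidden 128, dense 512,
Adam + Lookahead(k=5, alpha=0.5), batch 2000 / lr 1e-4 / 200 epochs for
round one; batch 512 / lr 1e-5 / 30 epochs for round two) and exists for
completeness; it assumes far more labelled data than a desk experiment has.
The **desk profile** — the default for the bundled tests, examples and
acceptance script — keeps every calling threshold and image geometry
unchanged but trains hidden-48 networks with plain Adam (batch 128,
lr 3e-3, 60 epochs round one / 40 round two, label smoothing 0.1); at
desk-scale step counts Lookahead's slow-weight averaging measurably delays
convergence, so the wrapper stays available but off.  Three desk-specific
choices:

- **Class rebalancing.** At 4% substitution error ~4% of positions pass the
  candidate filter, so hom-ref examples outnumber variants ~25:1; a seeded
  subsample caps the ratio at 8:1 (all variant examples are kept).
- **Base-permutation augmentation.** The feature images are exactly
  equivariant under relabellings of `{A, C, G, T}` (and, for the
  strand-split pileup image, strand swap): permuting the base channels and
  mapping genotype labels through the same permutation yields an equally
  likely example.  Each training batch applies one random such transform.
  This multiplies the effective variety of variant examples ~50-fold and is
  what lets a 200 kb training contig (~350 variant examples) generalise.
- **Symmetrized inference.** For the same reason, head logits are averaged
  at inference over a fixed set of these transforms (four base relabellings,
  crossed with strand swap for the pileup image), with the genotype axis
  mapped back through each permutation.  This enforces the exact task
  symmetry on the predictor and reduces prediction variance; it is applied
  before temperature calibration so the fitted temperature matches the
  distribution actually used for calling.

Networks compute in float32 (a float64 mode exists and is used by the
finite-difference gradient checks); feature values are `log1p`-compressed
inside the forward pass so count and Phred-sum channels share an O(1)
scale.  All randomness flows through explicit seeded generators: same seed,
same data, bit-identical weights and VCF output.

Indel handling is internal only: the 21-class round-one space carries I/D
pairs so deletion/insertion evidence is modelled, candidates whose truth is
an indel are excluded from round-two training (the 10-class space has no
I/D), and I/D genotypes are suppressed at the merge.  By design the final
VCF contains SNPs only.

## Problem sizes and the bundled experiment

`run_experiment` simulates a 200 kb training contig and a 50 kb held-out
contig at 16x coverage with 4%/1%/1% errors, trains both models at the desk
profile, runs the full two-round pipeline on the held-out contig, and
scores each round and the merged output against the planted SNPs (site and
genotype must both match; truth indels are out of scope).  Those sizes keep
the whole experiment within a few minutes on one CPU core while leaving
~200 planted SNPs for training and ~60 for evaluation.  The second round
re-genotypes **all** candidates by default (`merge.second_round = "all"`),
which the merge rule requires to have two scores per site; a
`low-qual-only` mode restricts round two to sites the pileup model scored
below delta, treating the missing record as quality 0 at the merge.

## Known limitations

- Desk-scale scores are not comparable to whole-genome GPU-trained results;
  they demonstrate the pipeline's mechanics and internal consistency, not
  clinical-grade accuracy.
- The built-in truth classifier matches sites and genotypes exactly, with
  no haplotype-aware normalisation of representations.
- The MEC phaser is heuristic above 12-site blocks.
- Multi-allelic sites are only representable as het non-ref pairs (`1/2`);
  the candidate search itself follows the single max-alt-frequency rule.
- The unphased-read subset and zero-padded flank rows are encoded as
  all-zero feature blocks; the networks must learn that zero means absent.
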