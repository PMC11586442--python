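# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind each module, in the order data flows through the
pipeline.

## Synthetic data

**Genomes.**  `generate_genome_pair` draws an i.i.d. sequence at a chosen
GC fraction and derives the second genome by independent per-site
substitutions at the requested expected divergence (uniform over the three
alternative bases, no indels).  The true substitution positions are
returned, so realized identity is exactly `1 − n_subs/length` and every
downstream detector can be scored against a known truth.  `annotate_orfs`
tiles forward-strand genes of a fixed length at a fixed spacing, rewriting
each gene to start ATG and to contain no in-frame stop.  Substitution-only
divergence keeps coordinates shared across a genome family, which is what
lets reads be placed without an aligner.

**Damage model.**  Terminal deamination is geometric:
`rate(i) = d0·decay^i` for read positions `i < extent` from the relevant
end, C→T from 5′ and G→A from 3′, applied in read orientation and stored
back in reference orientation for reverse-strand reads.  Defaults:

| profile  | d0   | decay | extent | emulates                     |
|----------|------|-------|--------|------------------------------|
| non_udg  | 0.30 | 0.70  | 15 bp  | untreated library            |
| half     | 0.05 | 0.50  | 2 bp   | partial-UDG library          |
| none     | 0    | —     | 0      | full UDG / modern DNA        |

Two parameters reproduce the feature that matters for masking — high
terminal rates decaying over ~10 bp — without fitting empirical damage
tables.  No indels and no sequencing error beyond deamination are
simulated: the simulations isolate the damage effect that masking is
calibrated to remove.  Consequences: passing tests say nothing about indel
robustness or about quality-score–correlated error, and pileups of
undamaged simulated reads are error-free, which real data never is.

**Reads.**  Fragments are uniform over the genome; the leftmost mate is
forward, its mate reverse; template length is uniform on
`[read_length, 2·read_length]` by default, so mates overlap about half the
time — deliberately exercising the mate-overlap deduplication that matters
at a minimum insert of 12.  Base qualities are constant Q37 by default;
low-quality behavior is tested with explicit per-base quality fixtures.
SAM output (via pysam) is byte-identical for identical config and seed.

**Taxon tables.**  Per sample, Dirichlet(0.5) compositions are drawn
separately for oral and environmental taxa and scaled to the requested
expected oral mass; counts are multinomial.  60% of taxa form the oral
reference set, reflecting that curated oral references cover most taxa
detectable in calculus; at moderate sequencing depth the minor source's
taxa partially drop out, giving well- and poorly-preserved samples the
different *presence* structure that decay-curve screening keys on.  The
generator does not emulate shared contaminant profiles across samples or
batch effects, so screening tests exercise the classifier, not
decontamination.

## Preservation screening

The decay curve at rank k is `100·|oral among top-k by abundance|/k`,
counting taxa (not abundance mass), ties broken lexicographically.  A
sample passes when the curve is at or above the cutoff (default 50%) at
every rank from the burn-in rank on.  The adaptive burn-in is the first
rank after the last rank-to-rank jump exceeding 5 percentage points; the
head of the curve, where single taxa swing the percentage by tens of
points, is thereby excluded.  This rule is a deterministic stand-in for
the adaptive mode of the cuperdec R package, whose exact criterion is
unpublished; a fixed-rank burn-in is available
(`burn_in=<rank>` / `--burnin rank:N`).  Caveat: with an adaptive burn-in
the monotone-response property (adding top-ranked oral taxa never flips
pass → fail) is only guaranteed under a fixed burn-in, because added taxa
can move the burn-in earlier and expose previously skipped ranks.

## FAVA

Unweighted form only: with row compositions `p(i)` and column mean `p̄`,
`H_T = 1 − Σ p̄²`, `H_S(i) = 1 − Σ p(i)²`,
`FAVA = (H_T − mean_i H_S(i))/H_T`.  Counts are closed to compositions by
row-sum division; zero-sum rows are rejected.  Undefined results (fewer
than two samples, or `H_T = 0` when all mass sits on one shared taxon)
carry a reason code and propagate as NA — a one-sample island is NA, not
0.  Weighted variants (non-uniform sample weights or taxon similarity) are
out of scope and would change none of the module's interfaces.

## Strain comparison (popANI/conANI)

Masking flags the first and last N aligned bases of each read as
non-contributing without shortening the read; the protocol values are 1
base per end for UDG-half libraries and 11 for untreated ones.  Pileups
then drop pairs with template length below the minimum insert (default
12), drop bases below quality 30, and count mate-overlap positions once —
the mate with the higher base quality wins, ties to the leftmost mate —
so short-insert pairs cannot double-count, which matters precisely at
min-insert 12.

At positions covered ≥ min_cov (default 5) in both samples: alleles are
bases with count ≥ 2 and frequency ≥ 0.05 (the referenced strain-comparison
tool's defaults; treat both as tunable, since protocols rarely state them
explicitly); a popANI substitution needs disjoint allele sets, a conANI
substitution a consensus difference (consensus ties break toward A<C<G<T).
`coverage_overlap` is the Jaccard overlap of the two samples' ≥min_cov
position sets; whether to gate comparisons on it is left to the caller.

The calibration sweep evaluates the full mask {0,1,9,11,13,15} ×
min-insert {12,24,36,48} grid and selects the smallest (mask, then insert)
whose popANI is within 10⁻⁴ percentage points of the grid maximum — an
explicit encoding of "maximum popANI with minimal loss of coverage"; the
tolerance is a parameter.

## Polymorphic-rate dN/dS

Classification is pileup-only: dominant allele by count (tie →
alphabetical), polymorphic iff dominant frequency < 0.8 at coverage ≥ 5,
effect from substituting the secondary allele into the codon formed of
dominant alleles (standard genetic code; a stop translates as `*`).  When
two sites of one codon are polymorphic each is classified holding the
other at its dominant allele; when a codon's other positions are not all
covered the effect is `not-applicable` and excluded from both counts.
Reverse-strand genes are complemented into coding orientation before codon
assembly.  The ratio is a count ratio over polymorphic sites, not
normalized by synonymous/nonsynonymous site opportunity — matching the
referenced ad-hoc polymorphic-rate method, so values are comparable to
that tool's output, not to codon-model dN/dS estimates.  Base quality is
enforced once, at pileup construction, which is why the classification
functions take no quality argument.

**Wrong-reference experiment.**  The elevated dN/dS observed when a
sample's reads are mapped to a close but incorrect reference arises, in
real genomes, from reads of near-identical paralogous loci cross-mapping
onto a single reference locus and mixing their alleles.  The synthetic
experiment builds that mechanism in directly: the genome family shares a
duplicated segment (default two 4.5 kb copies at 2% internal divergence
inside a 30 kb genome; family members at 5% pairwise divergence), and
"mapping" places each read at its best-matching homologous candidate
locus — own locus, plus the other paralog copy when the read lies wholly
inside one — by Hamming distance, random tie-break, and a mismatch cap
(default 8% of read length), emulating an aligner's mismatch tolerance.
On the correct reference a read matches its own locus exactly and never
beats it with a paralog, so pileups stay clean; on an incorrect reference
the copies are nearly equidistant and reads cross-map, producing
polymorphic sites at paralog-divergent positions whose dN/dS sits near
the random-substitution expectation (≈ 2–3.5 in the default grid),
independent of deamination level.  Shorter reads cross-map more, which is
why the 50 bp cells carry the summary.  The absolute ratio for real
assemblies depends on their true repeat structure, so calibrating a
flagging threshold against specific species requires supplying those
assemblies (FASTA/GFF/SAM); the synthetic family establishes the
mechanism and its qualitative behavior only.

## Phylogeny

Majority-allele calls at coverage ≥ 5; homozygous means major-allele
frequency strictly > 0.9; sample QC thresholds (≥ 1000 SNPs, mean coverage
≥ 2× or 5× depending on the species' heterozygosity) are inclusive.  The
SNP alignment's columns are the union of positions where any sample has a
homozygous non-reference allele; a sample's state is its homozygous call
(which covers confident reference) or N.  Requiring the same coverage and
frequency thresholds for reference fill as for SNPs is the conservative
reading of the upstream multi-VCF combiner's behavior and is the
documented choice here.

TN93 distances use the closed form with empirical base frequencies
estimated per pair from shared non-N columns.  Saturation — a log of a
non-positive argument — marks the pair undefined with a reason, and trees
refuse undefined inputs.  A hard bound worth knowing: for *any* base
composition and substitution-class mix, the TN93 form is undefined once
the pairwise difference proportion reaches 3/4 (the three log arguments
cannot all stay positive).  SNP-only alignments with few samples and
strongly unbalanced divergence can exceed that bound even when the true
per-site divergence is tiny: with two clusters at between:within branch
ratio R and n samples, between-cluster pairs differ at roughly
`(B+2w)/(B+nw)` of columns with `B/w = 2R`, so at R = 10 and n = 8 the
proportion is ≈ 0.79 — saturated regardless of model.  Tests of
cluster recovery therefore use a milder ratio (within-island pairwise
0.08%, between 0.2%), where the transversion log argument sits several
standard errors above zero and the two-clade structure is recovered
exactly.  The "+G4" gamma correction used as a model label in distance
contexts is under-determined; the default is no gamma correction, with an
optional shape parameter (`gamma_alpha`) applying
`d = Σ k·α(w^(−1/α)−1)`.

Neighbour joining is scikit-bio's implementation (negative branch lengths
clamped to zero — the standard convention; clamping affects midpoint
placement on near-degenerate trees).  Midpoint rooting special-cases
two-tip trees, where the root is placed equidistant from both tips.
Bootstrap resamples columns with replacement, rebuilds TN93+NJ, and
reports bipartition frequencies on the full-data tree; replicates with
undefined distances are skipped and the effective replicate count is
returned.  Concordance is Kendall's W over rank-transformed unfolded
distance upper triangles with tie correction; the permutation null
relabels tips of every matrix but the first, and
`p = (1+hits)/(permutations+1)`, so 99 permutations floor p at 0.01.

## Pipeline

Stages run preservation → FAVA → strain comparison → dN/dS → phylogeny;
samples excluded by the preservation gate or phylogeny QC are written out
with the failing criterion, never silently dropped.  TSV artifacts carry a
`# calcstrain <version> config=<hash> seed=<seed>` header; FASTA and
Newick outputs stay comment-free (comments are not part of those formats)
and the run's full configuration is snapshotted in `run.json`.  A dataset
with no variant columns records a skipped phylogeny stage instead of
failing the run.  Reruns with identical inputs, config and seed are
byte-identical.

## Problem sizes

Simulation-backed tests use 100 kb genomes at ~30× (strain identity and
divergence), ~6× (calibration sweep), and ~10× over eight samples
(island-cluster recovery); the wrong-reference grid uses 30 kb genomes at
20× and 50 bp reads.  These sizes put binomial sampling error well inside
the asserted tolerances for every statistic tested while the full suite
stays interactive.

## Known limitations

- No indels, recombination, contamination, or sequencing error beyond
  deamination in the simulator; no empirical damage-profile fitting.
- The adaptive burn-in rule approximates an unpublished criterion; results
  at the 50% cutoff can differ from the R implementation for samples whose
  curves hover at the cutoff.
- dN/dS is a polymorphic-site count ratio; it is not comparable to
  codon-substitution-model estimates.
- TN93 on SNP-only columns inflates distances relative to whole-genome
  divergence (invariant sites are absent by construction); trees remain
  valid for clustering, branch lengths should not be read as per-site
  rates, and the saturation bound above applies.
- BAM reading works where pysam can read the input, but only all-match
  CIGARs are accepted; the pipeline consumes alignments, it never maps.
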