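# Methods

## The discovery model

A-to-I editing deaminates adenosine to inosine in mRNA; sequencers and
ribosomes read inosine as guanosine, so an edited position shows a
mixture of A (unedited transcript copies) and G (edited copies) in
RNA-seq reads mapped against the genomic sequence. Discovery therefore
reduces to finding positions whose read pile contains a reproducible
minority (or majority) alternative base that cannot be explained by
sequencing error or by the reference sequence being wrong.

All coordinates are **gene space**: 1-based positions along each gene's
unspliced sense-strand sequence (5'UTR, CDS exons, introns, 3'UTR).
Reads are assumed mapped to these gene sequences rather than to
chromosomes. This is deliberate: on a genome, A→G on a reverse-strand
gene appears as T→C, and the 12-type substitution spectrum would
conflate the editing signature with its alias. Read trimming and
mapping are upstream of this package and out of scope.

## Detection thresholds

A position in one sample becomes a candidate variant iff

* depth ≥ `min_depth` (default 5), where depth counts A/C/G/T calls
  only — N calls, deletions (`*`) and reference skips (`>`/`<`) in the
  pileup carry no base evidence;
* exactly one alternative base has ≥ `min_alt_reads` (default 2) reads;
  if two or more distinct alternatives each reach that threshold the
  position is discarded outright (a single stray error read below the
  threshold does **not** void a deep position; the literal reading, any
  second alternative read kills the position, is available as
  `strict_single_alt`);
* that base's fraction of depth is ≥ `min_alt_fraction` (default 3%);
* indel evidence at the column is below `min_alt_reads` (the indel veto
  reuses the same threshold for symmetry; positions, not reads, are
  vetoed).

One non-obvious consequence of the single-alternative rule: detection
is *not* monotone in `min_alt_reads` (raising it can disqualify a
competing second alternative and thereby resurrect a previously
discarded position). It is monotone in `min_depth` and
`min_alt_fraction`; the property tests assert exactly this.

**Genome-error screen.** A position where *every* sample with depth ≥
`min_depth` shows the same alternative base at ≥ 95% is a strain
difference or an error in the reference, not editing; such positions
are excluded from all calls. Samples not covering the position abstain
— requiring coverage in literally all samples would make the screen
untestable on sparse data.

## Replicates, normalisation, specificity

Each condition has exactly two independent biological replicates; a
site is **reproducible** iff the identical (gene, position, ref, alt)
key is called in both. Counts are normalised to events per million
covered bases (positions with depth ≥ 5); per-replicate counts use the
replicate's own denominator, the intersection count uses the mean of
the two, and the summary percentage is
`100 · norm_both / mean(norm_rep1, norm_rep2)` — which is why the
statistic can exceed 100 when the replicates' covered-base counts
differ, and is bounded by 100 when they are equal. Published table
values are printed at 1 decimal; internal arithmetic is unrounded.

A reproducible site is **specific** to a condition iff its key appears
in no other condition's reproducible set ("not in the other samples" is
read at the reproducible-set level; a stricter mode also vetoes keys
seen in any other condition's single-replicate raw calls).

## Codon consequences and read-through

CDS positions are mapped through the spliced CDS (CDS segments
concatenated, introns excised) to a codon index and within-codon
position; the reference and edited codons are translated with the
standard nuclear genetic code (table 1). Categories: synonymous,
nonsynonymous, stop_loss (stop → amino-acid codon), stop_retained
(TAA→TAG-type edits; counted with synonymous in "product unchanged"
summaries, exposed separately so either convention is derivable), and
stop_gain, which a single A→G can never produce — an exhaustive codon
enumeration in the test suite proves this — but which other
substitution types can.

After stop loss, translation continues **through the literal unspliced
downstream gene sequence** until the next in-frame stop (or the
transcript end, which is flagged). Annotation beyond the annotated stop
is deliberately not trusted: the biologically interesting read-through
cases in these fungi run into regions mis-annotated as introns, so
excising annotated downstream introns would be wrong exactly where it
matters. The extension length counts residues gained beyond the
annotated CDS; the recoded stop itself is not counted.

## Ortholog comparison

Given an ortholog-pair table with protein sequences, genes edited under
the filters (amino-acid-changing consequence, pooled replicate editing
fraction ≥ 10%; pooling is alt reads over depth summed across the two
replicates) are compared between species. For site pairs with the same
amino-acid substitution, the two proteins are globally aligned
(Gotoh/affine Needleman–Wunsch; BLOSUM62; a gap of length k costs
−10 − (k−1)·1) and the edited residues are called positionally
orthologous iff they occupy the same alignment column. The aligner is
implemented in-package because position mapping needs a deterministic
tie-break (diagonal over gap-in-a over gap-in-b); its scores are
cross-checked in the tests against both a brute-force enumeration of
all alignments and Biopython's PairwiseAligner.

## Clone co-editing

A clone matrix holds one row per sequenced cDNA clone and one 0/1 entry
per editing site. Under per-site independence the edits-per-clone count
follows the Poisson-binomial distribution of the observed per-site
frequencies, computed exactly by dynamic programming (verified against
2^k enumeration). The test statistic is the total-variation distance
between the observed and expected histograms; its null distribution is
sampled by Monte Carlo at the observed marginals, and the p-value uses
the (r+1)/(n_mc+1) estimator so it is never zero. The histogram (rather
than the full joint pattern table) is the default statistic because
realistic clone counts are 8–14; the full-pattern statistic is
available (`statistic="pattern"`). With such clone counts the test is
descriptive — reports should not over-read a non-significant result.

## Expression groups

Genes are grouped as: *any* (any reproducible site anywhere), *specific*
(an A→G site specific to the focal condition), *aa* (such a site with a
product-changing consequence at ≥ 10% pooled editing fraction); the
groups are nested by construction. Per-group ratio distributions use
`(numerator + pseudocount)/(denominator + pseudocount)` with a default
pseudocount of 1 abundance unit (tolerates zero denominators; the
upstream quantification and its units are taken as given), and
quartiles use linear interpolation between order statistics (type 7) —
a fixed, testable convention. Ratios are linear; a log2 option exists
for plotting.

## Synthetic data: what it emulates, what it does not

The generator produces the full study design with known truth: genes of
~600–1000 bases (5'UTR 40–120, 80–200 internal codons, optional single
50–90-base intron, 3'UTR 80–200; CDS starts ATG, ends with a stop,
internal codons never stops), three conditions × two replicates,
negative-binomial depth (dispersion parameter 20) around a smooth
sinusoidal coverage profile (amplitude 0.3, phase a property of the
gene) with an optional linear 3'-bias ramp emulating linearly amplified
libraries, and a strand-symmetric, base-uniform error model (each wrong
base at e/3; quality strings are a constant placeholder).

The reference study plants 100 sites: 20 condition-specific A→G sites
(fractions uniform on 0.15–0.9, five of them on TGA/TAG stop codons to
guarantee stop-loss cases, consequence categories recorded from the
generator's own codon bookkeeping as a cross-module oracle for the
classifier) and 80 background variants cycling through the 12
substitution types, present in every condition at fractions 0.10–0.50 —
mirroring the empirically observed flat cross-type background with an
A→G excess confined to sexual tissue. Three reference errors are
planted at ~100% alternative in all samples. Seed discipline: one
master seed; every stochastic step derives a child seed from (master,
purpose, condition, replicate) by hashing, so replicates differ only by
derivation and every output is reproducible byte-for-byte.

Under these conditions the pipeline recovers, in expectation, all but
~0.4 of the 20 specific sites per study: a site with fraction near 0.15
occasionally draws ≤ 1 alternative read in one replicate, and ~1% of
sites lose their position to two stray error reads of a third base.
At the documented reference seed recovery is 20/20 with zero false
discoveries; the false-discovery proportion is measured over all
reproducible calls in the focal condition after reference-error
exclusion. The null-calibration study (no planted sites) raises the
error rate to 2% so that enough error-driven reproducible sites exist
(~100 across conditions) to test spectrum flatness at all; its
chi-square expectation accounts for the reference-base composition
(each ref base feeds three substitution types).

What the generator does **not** emulate: read-level artefacts (mapping
bias, soft-clipping, strand bias), base-quality variation, splicing
noise, real coverage autocorrelation beyond the smooth profile,
polymorphism between strains beyond the planted near-fixed errors, and
any sequence-context preference of the editing machinery. Passing tests
therefore demonstrate the *arithmetic and logic* of the pipeline, not
robustness to alignment artefacts on real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script use the 50-gene reference
study (~32 kb of transcript, six samples at 50×), a 20-gene null study,
1000 random models for the classifier/translation-diff equivalence,
exhaustive codon and small-column enumerations, alignment oracles on
all short sequence pairs, and 60–120 Monte-Carlo calibration runs at
n_mc = 300; together they run in well under a minute. Larger studies
only change runtimes, not code paths. Floating-point comparisons in the
Monte-Carlo test use a 1e-12 slack so ties count as at-least-as-extreme;
table output rounds to 1 decimal to match the published precision.
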