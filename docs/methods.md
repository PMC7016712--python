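# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `mthet`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The experimental design being modeled

A mutation-accumulation (MA) experiment propagates replicate nematode
lines through single-individual bottlenecks so that genetic drift, not
selection, dominates the fate of new mutations. For mtDNA this means a
heteroplasmic variant at frequency *p* in one generation is transmitted
through a small effective number of mtDNA copies, and over ≤ 50
generations it can fix, be lost, or remain heteroplasmic. Total-DNA
shotgun sequencing of each line and its progenitor yields a few
hundred-fold mtDNA coverage and single-digit nuclear coverage, from which
the pipeline estimates variant frequencies, class-specific mutation
rates, and the mtDNA:nDNA copy ratio.

## Genome model (`mito_model`)

Coordinates are 1-based inclusive in every user-visible structure;
0-based half-open indices are used internally and never serialized.
Circular genomes are handled by operating on the doubled sequence and
deduplicating wrapped hits; origin-spanning features carry an explicit
wrap flag.

* **Homopolymer census.** Maximal A/T mononucleotide runs are found by a
  vectorized boundary scan; a run qualifies when its length is at least
  `min_run` (default 8, the length at which replication slippage is
  treated as the dominant indel mechanism in nematode mtDNA). `n_sites`
  counts only bases outside the excluded feature (default the AT-rich
  control region): for a run straddling the boundary, inside bases never
  count. The census is validated against an independent
  position-by-position scan in the test suite.

* **Direct repeats.** `find_direct_repeats` enumerates diagonal shifts
  between two disjoint windows and reports every maximal pair with at
  most `max_mismatch` internal mismatches, ends always on matches, with
  the decomposition into exact sub-repeats at the mismatch offsets. For
  the default synthetic genome this yields the 36 bp pair at
  12,473/13,343 with one mismatch at offset 5 (sub-repeats of 5 and
  30 bp), hence the 870 bp deletion between repeat-copy starts.

* **Protein effects.** Genes are translated with NCBI table 5
  (invertebrate mitochondrial). Indels with length not divisible by 3
  inside a gene body are frameshifts; in-frame indels are reported as
  such and never as frameshifts. Variants beyond a gene's first stop
  codon have no effect. A large deletion that removes a gene's 5′ end
  but not its 3′ end is annotated alternative-start + truncation.

## Synthetic data (`synthetic_data`)

The generator's defaults define the study conditions used throughout the
tests and the acceptance script:

| parameter | default | rationale |
|---|---|---|
| genome length | 14,420 bp | nematode mtgenome scale |
| AT-rich region | 600 bp at 94% AT | low-complexity control region |
| planted A/T runs | 5–13 bp (six runs ≥ 8 bp) | slippage hotspots spanning the census threshold |
| direct repeat | 36 bp, C/T mismatch at base 6, copies 870 bp apart | substrate of the repeat-mediated deletion |
| read length / fragment | 250 bp / 330 ± 30 bp | 250 bp paired-end libraries with overlapping mates |
| mtDNA coverage | 300× (200–360× in examples) | observed mtDNA depth range |
| nuclear coverage | 5.5× | observed single-copy locus depth |
| per-base error | 0.002 raw; 5 × 10⁻⁴ for merged-consensus libraries | overlap merging corrects most errors in the overlap |
| duplicate fraction | 0.05 | exact PCR duplicates removed upstream |
| bottleneck N_eff | 100 | effective mtDNA copies per generation (free parameter; the germline bottleneck size is not identified by the design) |

**Drift model.** One Wright–Fisher resampling event per host generation:
each segregating variant's copy count among `n_eff` transmitted genomes
is binomial with success probability p·b/(p·b + (1 − p)), where *b* is a
multiplicative transmission bias (b = 1 neutral; b > 1 a selfish
element). Variants are unlinked — each is resampled independently — so
genetic hitchhiking is *not* modeled. The closed-form neutral variance
Var_t = p(1−p)(1−(1−1/N)^t) is used as the oracle in tests.

**Mutational input.** De-novo rates are per site per generation per
mtDNA copy: arrivals are Poisson with mean rate·n_sites·n_eff per
generation, each seeded at frequency 1/n_eff. Under this convention the
expected summed final frequency per line is rate·n·T (the per-arrival
expected frequency is the 1/n_eff martingale value), which is exactly
what the frequency-difference rate estimator consumes — making the
estimator's calibration a meaningful end-to-end check rather than a
tautology.

**Read simulation.** Fragments are drawn uniformly from the circular
genome (or the deletion haplotype, chosen per fragment with probability
equal to the deletion frequency); point variants are applied per
fragment with probability equal to their frequency, with coordinates
mapped across the deletion. Errors are i.i.d. substitutions on the reads;
qualities are constant (no quality model); the stated duplicate fraction
of read pairs is emitted as exact copies. All randomness flows from one
seed; identical seeds give byte-identical FASTQ.

What the generator does **not** emulate: indel sequencing errors, GC or
coverage bias, quality-score structure, chimeric fragments, nuclear
mitochondrial insertions (NUMTs), or linkage between variants. Passing
tests therefore demonstrate correctness of the analysis under an
idealized error model, not robustness to every artifact of real
libraries.

## Preprocessing (`preprocess`)

Order is trim → merge → dedupe. Adapter trimming removes the longest
read suffix matching an adapter prefix with ≤ 1 mismatch per 10 bases,
with a 5 bp minimum overlap so a single coincidental terminal base is not
treated as adapter. Merging reverse-complements the mate, finds the best
suffix/prefix overlap ≥ `min_overlap` (default 20) with mismatch rate
≤ 5%, and resolves overlap disagreements to the higher-quality base;
pairs that do not merge are discarded (a `keep_unmerged` flag exists,
off by default). Deduplication keeps the first occurrence of each exact
sequence; containment is deliberately not absorbed, and identity is by
sequence only — the purpose is removing PCR duplicates so each surviving
read can be treated as an independent source molecule.

## Mapping (`align`)

A small-genome seed-and-extend design: exact k-mer index (default k = 8)
over the doubled circular sequence; diagonal voting from a handful of
spread seeds; vectorized Hamming scoring of candidate placements
(match +1, mismatch −3 in score units). Reads scoring poorly ungapped
are rescued two ways: a banded gapped alignment (edlib, ±24 bp window)
for small indels, and a two-diagonal split alignment for a single long
deletion of ≤ `maxindel` (default 2000) bp, charged a flat gap-open cost
of 6 independent of gap length — one biological deletion event, not a
per-base penalty. The split point on the read is chosen by a prefix-sum
minimization, which in a flanking repeat lands on the leftmost
equivalent breakpoint. Placements tying for best score are discarded
(ambiguous); best identity below `minratio` (default 0.8) is unmapped.

**Realignment around candidate deletions.** Reads ending a little past a
deletion breakpoint initially align ungapped with a mismatching tail
inside the deleted interval. Given a candidate deletion,
`realign_indels` rescores each overlapping read against the deletion
haplotype at both possible anchors and converts it to a split alignment
when strictly better, using a lighter gap cost (2): with the deletion
supplied as a hypothesis, a read overhanging a flanking 36 bp repeat
copy differs from the ungapped placement by a single diagnostic
mismatch and must still convert.

**Reference extension.** For a linear reference truncated inside a
low-complexity flank, `extend_reference` iteratively (default 10
rounds) maps reads ungapped (≤ 5% mismatch, ≥ 25 bp anchor), takes a
majority-rule consensus including overhanging bases (coverage ≥ 2), and
grows the sequence; after the last round, extended positions with
coverage below mean − 2 SD (computed over the whole final sequence) are
trimmed back. With uniform fragment starts the outermost tip of an
extension always sits on a coverage ramp, so the trim removes the last
few dozen bases; recovery of "up to" the full missing flank is the
expected behavior, not recovery of every base.

## Calling (`caller`)

The pileup stores per-position, per-strand base counts plus insertion,
deletion and split-read events. The calling reference is the majority
base of the progenitor library at each position (ties and zero-coverage
positions fall back to the FASTA base and are flagged); the same
reference vector is applied to the progenitor and every MA line.

Gates (defaults): coverage ≥ 100, support ≥ 4, exact binomial
p < 10⁻⁶, strand-bias rule. The p-value is the upper tail of
Binomial(coverage, error_rate) at the observed support — an explicit,
reproducible null in place of proprietary callers' undocumented
approximate p-values; `error_rate` defaults to 0.002 and should be set
to the library's effective per-base error (≈ 5 × 10⁻⁴ after overlap
merging). Published p-values of other tools are consequently not
reproduced exactly. A permissive mode emits every non-reference
observation without gates; it implements the "present at any frequency"
screen used to flag de-novo variants (an MA-line call is de novo iff the
progenitor permissive screen has zero supporting reads for it).
Multi-allelic sites produce separate records. No multiple-testing
correction is applied; thresholds are per site.

Indels are left-aligned (insertions rotated to the leftmost equivalent
placement) and aggregated after canonicalization; single-base indels in
runs are reported as `(B)n → (B)n±1` with the reference run length.

**Large deletions.** Split events are canonicalized by left-alignment
and clustered by (start, length); clusters with support ≥ 4 are
reported. The boundary-ambiguity interval is the exact-repeat shift
extent. Frequency is support / (support + reference-spanning reads) at
each breakpoint, reported as a range over the two breakpoints. The
spanning-read denominator is probed just inside the deletion but
*beyond* the flanking-repeat extent: at the breakpoint itself, junction
reads overhanging into a repeat copy are indistinguishable from
reference-spanning reads, which would inflate the denominator. This
convention is a documented choice — the two printed breakpoints of a
repeat-mediated deletion are inherently ambiguous, and alternative
boundary clusters are merged only when their canonical representation is
identical, preserving genuinely distinct +6-shifted deletion variants.

## Rates (`rates`)

μ = m/(L·n·T) with SE = √(μ/(L·n·T)). The default *m* bookkeeping sums,
per MA line, |f_MA − f_prog| over the **union** of that line's and the
progenitor's variant sites of the class: loss of a progenitor
heteroplasmy contributes |0 − f_prog| and fixation contributes
|1 − f_prog|. `include_progenitor_only=False` restricts to sites
observed in the MA line — both conventions are defensible readings of
frequency-difference bookkeeping, and published rate tables in this
design cannot generally be reproduced to the printed digit without
knowing which was used, so rates computed from transcribed survey tables
should be read as order-of-magnitude anchored. For base substitutions
n = genome length minus the AT-rich region; for homopolymer indels
n = the census of A/T bases in runs ≥ 8 bp outside the AT-rich region
(caller output in shorter runs is reported but excluded from rates).

## Copy number (`copy_number`)

Per-site mtDNA depth (AT-rich region dropped) divided by the mean of the
three nuclear loci's average depths. Group tests treat positions as
exchangeable observations — positional autocorrelation along the genome
is ignored by design, so p-values are anti-conservative for long-range
coverage waves; this mirrors common practice for such coverage tracks
and is the main caveat on the inferential output. Dunn's post-hoc z uses
pooled tie-corrected rank variance with Bonferroni adjustment over the
MA-vs-progenitor contrasts (adjusted p never below unadjusted).
Significance is assessed at 0.05.

## Problem sizes and determinism

The test suite and acceptance script run desk-scale versions of every
experiment: one 14.4 kb genome, 300× libraries (~13,000 fragments),
20 seeded null libraries for the specificity check, 50 replicate 5-line
× 50-generation experiments for rate calibration, and 1,500–2,000
replicate lineages for drift moments. These sizes put Monte-Carlo error
well below the assertion tolerances while keeping a full run in minutes
on one CPU. Every stochastic component takes an explicit integer seed;
the acceptance script derives all sub-seeds from its single `--seed`
argument.

## Known limitations

* Variants are unlinked in both the simulator and the caller; haplotype
  phasing and hitchhiking are out of scope.
* The mapper targets ≤ ~20 kb references; it is not a general-purpose
  aligner and has no FM-index scalability.
* At most one large deletion per simulated lineage/library.
* The binomial error null ignores position-specific error structure.
* Copy-number inference treats positions as independent (see above).
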