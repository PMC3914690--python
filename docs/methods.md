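# Methods

This note documents the models, rules and numerical choices behind each
analysis, what the synthetic-data generator does and does not emulate, and
the known limitations. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Reference-anchored pseudogene classification

The central assumption is that the derived genome diverged recently from a
close free-living relative (a few percent nucleotide divergence), so the
reference ortholog is an adequate model of each derived gene's ancestral
state. Classification proceeds in three tiers:

1. **Fast path.** A derived CDS with protein identity > 0.90 and aligned
   reference coverage > 0.80 (strict inequalities) and no inactivating
   mutation is intact.
2. **Extended search.** Otherwise the derived sequence is re-extracted with
   `context_nt` = 2,500 nt of flanking genome on each side (wrapping the
   circular origin when needed) and re-scanned; this recovers genes whose
   annotated boundary moved because of a truncation or frameshift.
3. **Span rule.** After the extended scan, a gene is intact only if its
   well-aligned span exceeds 99% of the reference ORF (90% for reference
   ORFs shorter than 300 nt) and no inactivating mutation was found;
   otherwise it is a pseudogene. A derived CDS with no reciprocal ortholog
   is `unresolved` and excluded from the intact/pseudogene totals.

Mutation typing works on the nucleotide alignment (edlib, edit distance)
of the reference ORF against the derived sequence, projected into the
reference reading frame:

* indel runs of length ≢ 0 (mod 3) → `frameshift_indel`, positioned at the
  first affected reference codon; compensating pairs within 30 nt are
  reported as two frameshifts (the gene is still inactivated);
* reference-frame stop codons ahead of the reference stop →
  `premature_stop`;
* a long terminal run of codons with collapsed identity → `truncation`;
* an IS-library match inside the ORF → `is_interruption`.

Numerical choices that matter:

* **Alignment-path normalization.** An optimal edit-distance path can
  represent two nearby substitutions as an insertion/deletion pair of equal
  cost, and can leave a terminal query gap where a mismatch would do. Both
  forms are rewritten (I/D pairs within 30 columns collapse to mismatch
  columns when the columnwise cost is no higher; terminal query gaps are
  absorbed against the free target flank). Without this, equal-cost tie
  breaking inside the aligner produces spurious frameshift calls on clean
  genes. Genuine compensating indel pairs survive because their columnwise
  cost is far higher.
* **Divergence changepoint.** Truncation (and the aligned span) is defined
  by the argmax of the cumulative per-codon drift `identity − 0.75`: the
  prefix score rises through well-conserved sequence and falls through
  scrambled or unrelated sequence, so the argmax marks the boundary. A
  windowed threshold is not used because random sequence locally exceeds
  any fixed identity cutoff. A diverged suffix shorter than 10 codons is
  treated as boundary noise, not truncation.
* **Stop-adjacent suppression.** Premature-stop and frameshift calls within
  the final three sense codons are suppressed (alternative stop usage and
  ORF-boundary alignment ties, not inactivation).
* **IS excision before alignment.** A kilobase-scale IS insertion is
  cheaper for an edit-distance aligner to thread through as noise than to
  open as one gap, so IS-library matches (identity ≥ 0.8 over ≥ 80% of a
  consensus) are excised from the derived sequence first and reported as
  `is_interruption` at the codon where they sat.

## Orthology

Reciprocal best hits. Candidates are shortlisted by shared 12-mers
(inverted index; candidates need at least 30% of the top candidate's seed
count — a mobile-element insertion inflates edit distance but barely dents
the seed count), ranked by length-normalized global edit distance on the
nucleotide CDS, and made reciprocal. Protein identity and reference
coverage for each pair come from a BLOSUM62 global alignment (gap open −11,
extend −1) of the translations and feed the `min_identity`/`min_coverage`
filter (defaults 0.9/0.8 for selection analyses; the classifier anchors
pairs with both at 0, because severely frameshifted genes have
uninformative translations yet still need their reference anchor).
Ties break deterministically (smaller normalized distance, then
lexicographic locus tag).

## dN/dS (Nei–Gojobori counting)

Sites: for each codon position, the site value is the fraction of the
three single-nucleotide changes that are synonymous among those not
creating a stop; site totals are averaged over the two sequences, so
`S + N = 3 × n_codons` exactly. Differences: per codon pair, averaged over
all orderings of the differing positions, excluding orderings that pass
through a stop codon (if all do, all are used). Proportions are corrected
with Jukes–Cantor, `d = −(3/4)·ln(1 − (4/3)p)`, undefined for `p ≥ 3/4`.
`omega = dN/dS` is +∞ when `dS = 0 < dN` and undefined when both are zero;
infinite and undefined values are excluded from means. Codon alignments
are built from the nucleotide alignment with in-frame gap codons dropped;
frameshifted pairs are excluded from selection analysis entirely, as are
pseudogenes, IS elements and phage. Codon-bootstrap standard errors
(1,000 seeded resamples) are available because close-relative estimates of
per-gene rates carry large sampling error. The cryptic-pseudogene screen
partitions genes at `omega ≥ 0.3` and labels genes at `≥ 0.4`, reporting
the mean ORF length of each set.

The estimator's neutral limit is validated on codon pairs evolved under a
syn/nonsyn acceptance dial at ≈ 0.2 proposed substitutions per site. That
depth is chosen because the per-gene omega is a ratio of counts: at very
low divergence the handful of synonymous differences makes the mean of
per-gene ratios biased upward (Jensen effect), which is a property of the
summary statistic, not the estimator.

## Synteny and replichore symmetry

After masking IS elements, phage and rRNA, every k-mer (k = 20) occurring
exactly once in each genome (both strands counted, canonical form) yields
a match. Matches are chained greedily in reference order: same strand,
reference gap ≤ 1,000 nt, diagonal drift ≤ 20 nt. Against supplied ori/ter
positions a block is *symmetric* if it keeps strand and replichore or
inverts both, *violating* otherwise, *indeterminate* if it straddles
ori/ter; the violation fraction ignores indeterminate blocks. Block
boundaries localize rearrangement breakpoints to within k nt because the
first/last unique k-mers abut the true junction.

## Chromosome architecture

GC skew `(G−C)/(G+C)` per window (default 10 kb window / 5 kb step —
smooth at whole-chromosome scale; windows with `G+C = 0` are flagged and
contribute 0); ori at the cumulative-skew global minimum and ter at the
maximum. The polarization index is the fraction of non-flagged windows
whose skew sign follows the two-replichore model, orientation chosen to
maximize agreement (0.5 = no signal, 1.0 = perfect). KOPS sites are
overlapping IUPAC matches of GGGNAGGG on both strands; polarity is the
fraction oriented ori→ter on their replichore's leading strand. The dif
search is ungapped mismatch counting of the 28-nt query at every position
on both strands (vectorized sliding window; default budget 4 mismatches,
ties to the leftmost position, + strand first). Skew-estimated ori/ter can
be overridden by the caller — necessary for genomes whose skew is already
disrupted, where the reference-homologous positions are the meaningful
axis.

## Mobile elements

IS annotation is library-driven (consensus sequences with transposase ORF
coordinates): exact 16-mer seeding, cluster, then infix edit-distance
refinement; hits need identity ≥ 0.94 over ≥ 80% of the consensus, and the
transposase is typed intact/disrupted with the pseudogene mutation
scanner. The intergenic clustering test compares the observed fraction of
IS midpoints in intergenic space (complement of CDS/rRNA/tRNA) with a
uniform-placement null holding the element count fixed; elements are
placed independently (no overlap exclusion — a documented simplification).
It returns both the add-one p-value `(1+b)/(B+1)` for inference and the
raw exceedance proportion `b/B`, the unbiased Monte-Carlo estimate used
when comparing against closed-form tail probabilities (the add-one
estimator cannot go below `1/(B+1)`). Because the observed statistic takes
only `n+1` values, the attainable test level is quantized; calibration
checks use 120 elements on a ~20% intergenic genome, where binomial tail
arithmetic puts the attainable level at α = 0.05 near 0.047.

Duplication detection chains k-mers occurring exactly twice (IS sequence
masked) on a consistent diagonal; any open chain may be extended, since
pairs from unrelated repeats interleave in position order, and the chain
gap (2,000 nt) must bridge interior multi-copy sequence such as rRNA
operons, whose k-mers occur more than twice and contribute no seeds.
Candidate pairs are extended outward over exactly matching unmasked bases
— for IS-bounded duplications the masked flanks pin the true boundaries —
then globally aligned to count substitutions and indel events and filtered
at ≥ 2,500 nt and ≥ 0.98 identity. `bounded_by_is` requires same-family IS
annotations within 2 kb of all four flanks.

## 16S rRNA mutations

Substitutions (from the global alignment, indel-pair normalization
applied; gapped positions counted separately, never silently dropped) are
classified against a stem pairing map: at a paired position the realized
query pair — using the partner's query state, because the realized
molecule is what folds — is conservative if Watson–Crick or G·U wobble
(G·T in DNA representation), disruptive otherwise; unpaired positions are
loop. The treatment of non-canonical pairs such as A·G as disruptive is
this package's explicit operationalization. A per-position variability map
(ordinal classes 1–6) bins the same substitutions into rare-site (classes
1–2 by default) versus common-site counts. Both maps are plain TSV inputs;
the simulator fabricates internally consistent toy maps, and no external
structure or variability database is shipped.

## Synthetic data: what it emulates, and what it does not

`generate_ancestor` builds a gene-dense circular chromosome with ori at 0
and ter at L/2. Composition is biased per replichore: the leading strand
carries a G−C excess `b` (default 0.05 — strong enough that a 10-kb-window
skew track is cleanly polarized at the 200-kb scale used in tests, within
the range of real bacterial skew amplitudes). Genes (default mean 900 nt,
sd 200, 70% co-oriented with the fork) sample sense codons weighted by the
local strand composition, so genic sequence carries the skew too. Chance
GGGNAGGG occurrences are scrubbed (synonymous codon swaps inside genes) so
that KOPS polarity is exactly the configured value; the 28-nt dif sequence
is written at the terminus; rRNA operons embed a toy 16S whose helices are
forced complementary and whose variability map marks stems conserved.

`degenerate` applies events in a fixed order — background substitutions,
gene inactivations, duplications, IS insertions, inversions,
translocations, deletions — recording every primitive edit so that
replaying the ledger reproduces the derived sequence byte-exactly (a
tested invariant). Default degeneration conditions for recovery scoring:
40% of genes inactivated (frameshift/stop/truncation at 0.4/0.3/0.3),
IS insertions 85% intergenic, and one 13,476-nt duplication carrying 13
substitutions and 4 single-base indels bounded by IS256-family copies —
the scale of a recently duplicated chaperonin region in a degenerating
symbiont. Choices that keep the ground truth crisp:

* background substitutions never create in-frame stops, and nonsynonymous
  ones are accepted with probability `background_omega` (default 0.2, the
  upper range of purifying selection in bacteria), so unperturbed genes
  stay classifiable as intact and genome-wide omega is realistic;
* inactivating mutations sit ≥ 9 nt from ORF ends; truncations write a
  premature stop and scramble the downstream sequence, exercising both the
  extension search and the span rule;
* rearrangement breakpoints are confined to feature-free positions, and
  inversions are sampled disjoint, so each maps to one expected violating
  block; ori/ter are tracked through every edit into the ledger;
* duplicated segments are inserted as unannotated sequence (their genes
  are not duplicated as features), and later events avoid the tracked
  duplication intervals.

What the simulator does **not** emulate — and hence what passing recovery
tests do not show about real data: codon-usage and amino-acid composition
realism; transition/transversion bias; rate heterogeneity among genes and
sites; overlapping genes and operon structure; partial IS copies and
target-site duplications; gene conversion between repeats; assembly error.
Real annotation pipelines also disagree about gene boundaries in ways the
locus-tag-preserving simulation cannot capture, so real-data ortholog
anchoring is harder than the simulated task.

## Problem sizes

Defaults used by the test suite and acceptance script: 500-gene (~560 kb)
pairs for classifier scoring (three seeds), 200 × 500-codon genes for the
neutral dN/dS limit, 100–200-kb genomes for synteny and architecture
properties (10 seeds), 1,000 simulations × 1,000 permutations for test
calibration, and a 120-kb genome for the duplication round trip. These
sizes give stable statistics while keeping a full run around a minute on
one CPU; all scale linearly if larger studies are wanted.

## Known limitations

* Orthology is one-to-one; recent paralog families resolve to a single
  reciprocal pair and the rest stay unpaired (`unresolved`).
* The dif and KOPS searches are ungapped; a motif split by an insertion is
  missed.
* The clustering test measures intergenic *enrichment*, not spatial
  clustering per se; a nearest-neighbor statistic was deliberately left
  out.
* Duplication detection requires both copies on the same strand; an
  inverted duplication is not chained.
* Partial IS elements (below 80% of consensus length) are neither
  annotated nor excised before classification.
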