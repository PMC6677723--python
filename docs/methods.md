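# Methods

This note documents the models, conventions, parameters and numerical
choices behind `retronest`, and what its synthetic benchmarks do and do not
demonstrate about real data.

## Coordinates and conventions

All internal arithmetic is 0-based half-open; everything printed or written
(GFF, TSV, reports) is 1-based inclusive.  `core_io.to_one_based` /
`from_one_based` are the only crossing points.  Element-local positions are
always expressed in the element's own 5′→3′ sense, regardless of the
genomic strand it occupies.  `N` matches nothing in any repeat, TSD or
motif comparison.

An insertion position `p` (1-based) means the element sits between host
bases `p` and `p+1`, with the target site duplication copied from host
bases `p−k+1..p` onto the element's downstream side.  The equivalent
"first interrupted base" convention is `p+1`; the decomposition logs both.

## Target site duplications

A TSD is reported only as a maximal *exact* duplication immediately
flanking the element (k from 25 downward; k = 0 is valid).  Near-matches
are deliberately not reported: integration biology produces exact
duplications, and admitting mismatches would trade a crisp invariant
(reported k admits no extension) for an arbitrary similarity threshold.

## Terminal repeats (seed and extend)

Word matches (default 12-mers) between element positions `i` and `i+d`
vote for repeat-pair offsets.  An end-anchored pair of length
`L = len − d` spans `[0, L)` and `[d, len)`; the longest candidate whose
ungapped identity is ≥ 0.80 (default) is reported.  Requiring candidates
to arise from word seeds is what makes "longest above an identity floor"
well-posed: without seeds, padding a true 522-bp repeat with random
sequence keeps identity above 0.80 for hundreds of extra bases.

## Nested decomposition and its identifiability limit

Candidate inner elements are seeded from the self-comparison's
off-diagonal repeat pairs: for each offset `d`, runs of word seeds locate
a putative inner 5′ repeat copy at `a0` with length `rep_len`, implying an
inner element `[a0, a0 + d + rep_len)`.  Boundaries are then refined over
a ±30 bp grid and must be flanked by an exact internal duplication of
≥ 4 bp (the inner TSD).  Candidates are ranked by joint duplication
evidence:

    score = (2·repeat_matches − repeat_columns) + tsd_len − boundary_shift

where the repeat copies are compared aligned at offset `d` (so the score
is comparable across candidate boundaries), random columns cost on
average, each exact TSD base adds one, and moving away from the word
seeds is penalised per base.  Non-overlapping accepted candidates are
returned ranked by inner repeat length; the host is reconstructed by
excising the inner element plus one TSD copy.

**Identifiability.**  When a host base flanking the integration site
equals the element base adjacent to a terminal-repeat copy, the composite
string admits several equally supported readings: the element can absorb
or shed a base while the TSD shrinks or grows correspondingly, with
identical host reconstructions.  Roughly 40% of uniform-random builds are
affected at ≥ 1 bp.  No decomposer can recover "the" truth in those cases
— the truth is underdetermined.  The generator therefore provides
`build_nested_allele`, which rejection-samples insertion sites until the
four boundary-coincidence conditions are excluded and the planted TSD is
the maximal flanking duplication; on such instances decomposition is exact
(validated over hundreds of seeded replicates, and at 1% LTR divergence
boundaries are recovered within ≤ 5 bp in ≥ 95% of replicates).  Real
nested integrants can be ambiguous in exactly the same way, in which case
any single reported reading is one of several equivalent ones.

## PBS, PPT and LTR motifs

The PBS search slides the reverse complement of each tRNA's 3′-terminal 18
nt (default) over a 30-nt window downstream of the 5′ LTR; fewest
mismatches wins, ties to the hit nearest the LTR.  The PPT is the longest
purine-delimited run within 20 nt upstream of the 3′ LTR with purine
fraction ≥ 0.9; requiring purine endpoints keeps a planted pure tract
maximal instead of letting runs absorb a leading pyrimidine at the 0.9
threshold.  Motif scans report all AATAAA and TATAWA (W ∈ {A,T}) hexamer
starts; the annotated pair is the most 3′ TATA that still has an upstream
polyA — the promoter expected at the 3′ end of U3.

## U3 | R | U5 partition

Given a transcription start site and termination site (1-based LTR
offsets), U3 = `[1, tss−1]`, R = `[tss, term]`, U5 = `[term+1, L]`; U3/U5
may be empty at the boundaries and the three lengths always sum to L.
Transcript-end evidence should come from homologous transcripts when
available.  Without evidence, a heuristic places the start site 8 nt after
the TATA hexamer start and gives R a default length of 22 nt — the short
repeated region typical of betaretroviral LTRs; both constants are module
attributes and should be treated as rough defaults, not measurements.

## ORF discovery and synteny labelling

Six-frame scan for ATG-initiated ORFs of ≥ 100 aa (default; the threshold
is a free parameter), longest-per-stop: the first ATG after the previous
in-frame stop opens the reported ORF.  ORFs running off the element end
are flagged partial and never gene-labelled.  Genes are labelled purely by
synteny — the ≤ 4 longest non-partial sense-strand ORFs between the LTRs,
ranked by start coordinate, get *gag*, *pro*, *pol*, *env* — because
homology search against external protein databases is outside this
package's scope; `label_genes` accepts externally determined labels when
the caller has them.  Classification: full-length provirus iff all four
genes and both LTRs; solo LTR for a repeat-less element of single-LTR
scale carrying both promoter motifs; otherwise truncated/ambiguous.

## Phylogenetics

Conserved polymerase regions are extracted by one global alignment of the
query against an anchor and concatenation of the query residues falling in
eight anchor-coordinate intervals spanning reverse-transcriptase residues
23–266.  Only the overall span is established; the shipped sub-interval
boundaries (`DEFAULT_POL_REGIONS`) are **provisional** and user-editable.
Regions with < 50% alignment coverage are skipped with a warning.

Distances are closed-form ML estimators over ungapped column pairs: JC69
`d = −¾ ln(1 − 4p/3)` (pairs with p ≥ ¾ are flagged saturated and capped
at 5 substitutions/site) and K80 from transition/transversion proportions.
Neighbor joining is the canonical Saitou–Nei algorithm; Q-ties are broken
toward the lexicographically first active pair so runs are deterministic,
and negative branch-length estimates are clamped to zero (additive inputs
never produce them; NJ recovers any additive matrix's topology and path
lengths to 1e−9, which the tests check against an exhaustive least-squares
topology search at five taxa and scikit-bio's NJ).  Bootstrap support is
column resampling with replacement; supports are the percentage of
replicate trees containing each internal bipartition of the reference
tree, whose zero-length internal branches are collapsed first so a
signal-free alignment reports no bipartition.  The default is 1,000
replicates (10,000 by flag) — supports are percentages whose Monte Carlo
error at 1,000 replicates (≤ ~1.6 points) is far below the 70% display
threshold customarily applied when rendering.  Rooting places the root at
the midpoint of the outgroup's pendant edge.

A small center-star progressive aligner is included for toy panels;
curated alignments should be supplied for real analyses.

## Depth genotyping and copy number

Presence calls label each empty-site flank *tail* iff its mean depth is at
or below the lower q-quantile (default q = 0.05, nearest-rank, one-sided —
deletions and spanning failures reduce depth) of unmasked genome-wide
depth; both tails ⇒ the site is interrupted in that strain.  The genome
coverage denominator is a 5%-trimmed mean of unmasked depth; the trimming
fraction, the one- vs two-sided tail and the quantile are configuration,
not facts.  Copy number is mean depth in the low copy-number region
(recruitment profile < 4 copies) divided by genome coverage; ploidy is the
value rounded half away from zero.  At 30× over 10-kb regions the mean's
standard error is ≤ 0.05 copies, so integer ploidies 0–6 are recovered
essentially always — the benchmark checks ≥ 95/100 replicates.

## Splice classification

Junction TSVs carry 1-based first/last intronic bases.  Donor context is
the innermost annotated feature covering the exonic base upstream of the
intron (acceptor downstream; swapped on minus strand); innermost means
smallest interval, ties broken by a specificity rank (U3/R/U5/PBS/PPT
before LTR/ORF before element).  A junction is *normal* iff both contexts
are exons (optionally restricted to an annotated pairing set),
*element-hijacked* iff either context lies in an element feature, else
*unannotated*.  Chains are matched to a transcript catalogue by exact
junction-set equality; otherwise the nearest model by Jaccard similarity
is reported with the similarity value.  Read counts are taken as given —
multi-mapping ambiguity inside repeated LTRs (a real problem at such loci)
is not modelled or down-weighted.

## The synthetic generator: what it emulates, what it does not

Elements are built as `5′LTR | gap(2) | PBS | spacers+ORFs | PPT | 3′LTR`
with uniform-ACGT background (motif false-positive rates are then
quantifiable), planted AATAAA/TATA hexamers (chance occurrences scrubbed
outside the planted spans), PBS as the reverse complement of a synthetic
tRNA 3′ end, an all-purine PPT preceded by pyrimidines, and stop-wall
spacers (stops in all three frames, no ATG) so planted ORFs are recovered
at exactly their planted coordinates.  Defaults mirror the nested *agouti*
insertion: 522-bp identical LTRs (divergence configurable), 8,300-bp
inter-LTR span (9,344 bp total), polyA/TATA/TSS/termination at LTR offsets
328/396/404/425, Lys-tRNA PBS, and a 686-codon *env*; the host element is
VL30-like (5,357 bp, no ORFs) and the nest sits at position 2,914 with a
6-bp TSD behind a 4-bp genomic TSD.  Depth is per-base
Poisson(copies × coverage) with optional uniform contamination — exactly
the estimator's assumptions.  Not modelled: GC bias, mappability, indels,
sequencing error, read pairing.  Passing benchmarks therefore demonstrate
correctness of the inference logic under its stated model, not robustness
to alignment artefacts of real short-read data.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use: 100 clean and 100
1%-diverged nested-allele builds (~12.5-kb composites); 50 random additive
matrices of 5–8 taxa (plus exhaustive 15-topology least-squares checks at
5 taxa); 100 Poisson depth replicates at 30× with 10-kb regions for
ploidies 0–6; 100 presence-call junctions; and a 13-model transcript
catalogue.  The full suite runs in well under a minute of CPU.
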