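# retronest

Structural analysis of nested LTR-retroelement insertions: the computational
chain of evidence that resolves one retrovirus integrated inside another.

The motivating case is the classic *nonagouti* (*a*) allele of the mouse
*agouti* locus: a 14.7-kb insertion that turns out to be a β4-family
endogenous retrovirus (9,344 bp, identical 522-bp LTRs) nested inside a
VL30 retroelement (5,357 bp) at VL30 position 2,914, each integrant flanked
by its own target site duplication (6 bp and 4 bp).  The insertion hijacks
host splicing (hair-cycle exons splice into the U5 region of the inner
element's 5′ LTR), and homologous recombination between the two identical
LTRs leaves a solo LTR — the *black-and-tan* allele.  `retronest`
implements every analytical step of that characterisation as a tested,
reusable library with a synthetic-data generator carrying known ground
truth, so the whole pipeline runs and validates without any downloads.

## What it computes

- **anatomy** — target site duplications (maximal exact flanking
  duplication), direct terminal repeats by seed-and-extend
  (`L = len − d` for end-anchored word-match offset `d`), nested
  decomposition with host reconstruction, PBS (tRNA 3′-end complement) and
  PPT detection, AATAAA/TATAWA motif scans, the U3 | R | U5 partition of an
  LTR from transcription start/termination sites, solo-LTR recombination
  products, dotplots, and Needleman–Wunsch percent identity.
- **orf_annot** — six-frame ATG-initiated ORF discovery
  (longest-per-stop) and synteny labelling *gag* < *pro* < *pol* < *env*,
  with full-length / truncated / solo-LTR classification.
- **phylo** — conserved reverse-transcriptase region extraction against an
  anchor, closed-form ML distances (JC69: `d = −¾ ln(1 − 4p/3)`; K80),
  canonical Saitou–Nei neighbor joining with deterministic tie-breaking,
  nonparametric bootstrap supports, outgroup rooting.
- **depth_cn** — presence/absence of an insertion from the depth of the
  empty-site flanks against the lower 5%-tail of genome coverage;
  recruitment profiles; low copy-number regions (profile < 4); copy number
  = mean region depth / genome coverage, ploidy = rounded value.
- **splice_class** — splice-junction donor/acceptor annotation by the
  innermost feature (so a hit in U5 reports U5, not "LTR"), normal /
  element-hijacked classification, and junction-chain matching against an
  enumerated transcript catalogue (Jaccard-nearest reporting for novel
  chains).
- **synthetic_data** — generators for all of the above with known truth:
  betaretrovirus-like elements (planted LTR motifs, PBS, PPT, ORFs),
  nested insertion with TSD, per-base Poisson(copy × coverage) depth, and
  junction tables; includes a replica of the nested *agouti* insertion
  built from the published structural parameters.

## Worked example

Simulate the nested insertion allele and annotate it:

```bash
retronest --seed 5 --out-dir demo simulate allele
retronest --seed 5 --out-dir demo anatomy \
    --allele demo/allele.fa --element-start 1501 --element-end 16207
```

prints

```json
{
  "tsd_length": 4,
  "tsd_sequence": "GCTG",
  "classification": "full_length_provirus",
  "terminal_repeat_length": 350,
  "terminal_repeat_identity": 1.0,
  "nested": [
    {
      "inner_length": 9344,
      "host_length": 5357,
      "insertion_pos_in_host": 2914,
      "tsd": "CCTATA"
    }
  ]
}
```

Reading: the 14,707-bp insertion sits behind a 4-bp target site duplication
and carries an identical terminal-repeat pair (the host element's LTRs, 350
bp in the simulation).  Inside it, the decomposition finds a 9,344-bp inner
element flanked by a 6-bp internal TSD, inserted after position 2,914 of
the reconstructed 5,357-bp host element — the nested-retrovirus anatomy the
package exists to recover.  The same operations are available as library
calls (`retronest.anatomy.decompose_nested`, …), which is the intended
interface for analysis scripts.

## Caveats

Synthetic data is uniform-random outside planted features: no GC bias, no
mapping noise by default, no indels.  See `docs/methods.md` for the model
assumptions, the identifiability conditions of nested decomposition, and
known limitations.
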