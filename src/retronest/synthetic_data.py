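"""Ground-truth generators for nested LTR-retroelement analyses.

Everything downstream of this module (structural anatomy, ORF annotation,
depth genotyping, splice classification) is exercised against sequences and
tracks built here, where the truth — TSD string, LTR boundaries, motif
offsets, copy numbers, junction counts — is known by construction.

The element generator emulates a betaretrovirus-like provirus:

    5'LTR | gap | PBS | spacer | gag | pro | pol | env | spacer | PPT | 3'LTR

with a polyadenylation signal (AATAAA) and a TATA box planted inside each
LTR at configurable offsets.  Defaults reproduce the anatomy of the murine
β4 provirus nested inside VL30 at the *agouti* locus: 522-bp identical LTRs,
an 8,300-bp inter-LTR span (9,344 bp total), an 18-nt Lys-tRNA primer
binding site, a polypurine tract abutting the 3' LTR, and a 686-codon env.

Design notes
------------
* Background composition is uniform over ACGT, so motif false-positive rates
  are quantifiable.
* Each inter-ORF spacer ends in a "stop wall" (stop codons in all three
  forward frames, no ATG), which guarantees that an ORF finder using the
  first-ATG-after-stop rule recovers planted ORFs at exactly their planted
  coordinates.
* Read depth is Poisson(copy_number x mean coverage) per base — the
  assumption the copy-number estimator makes; an optional contamination rate
  adds uniform mapping noise for robustness tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import (
    FeatureRecord,
    GenomicInterval,
    SequenceRecord,
    get_logger,
    revcomp,
)

log = get_logger("synthetic_data")

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOP_CODONS
)
#: Stop codons in all three forward frames, no ATG anywhere.
STOP_WALL = "TAAATAAATAA"

#: Small synthetic tRNA panel (76 nt each, invented sequences — these are
#: stand-ins with realistic length, not database tRNAs).  The PBS of a
#: generated element is the reverse complement of the 3'-terminal bases of
#: the named tRNA.
SYNTHETIC_TRNA_PANEL = [
    SequenceRecord("tRNA-Lys", "GCCCGGCTAGCTCAGTCGGTAGAGCATGGGACTTTTAATCCCAGGGTCGTGGGTTCGAGCCCCACGTTGGGCGCCA"),
    SequenceRecord("tRNA-Gly", "GCATTGGTGGTTCAGTGGTAGAATTCTCGCCTGCCACGCGGGAGGCCCGGGTTCGATTCCCGGCCAATGCACCTGG"),
    SequenceRecord("tRNA-Pro", "GGCTCGTTGGTCTAGGGGTATGATTCTCGCTTAGGGTGCGAGAGGTCCCGGGTTCAAATCCCGGACGAGCCCACCA"),
    SequenceRecord("tRNA-Phe", "GCCGAAATAGCTCAGTTGGGAGAGCGTTAGACTGAAGATCTAAAGGTCCCTGGTTCGATCCCGGGTTTCGGCACCA"),
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


_BASE_ARR = np.array(list(BASES))
_CODON_ARR = np.array(_SENSE_CODONS)


def random_seq(length: int, rng) -> str:
    if length == 0:
        return ""
    rng = _rng(rng)
    return "".join(_BASE_ARR[rng.integers(0, 4, size=length)])


# --------------------------------------------------------------------------
# specifications and truth containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementSpec:
    """Blueprint of a synthetic LTR retroelement.

    Offsets inside the LTR are 1-based, matching how LTR positions are
    printed in the literature.  ``internal_length`` is the full inter-LTR
    span (PBS gap + PBS + ORFs + spacers + PPT), so the total element length
    is ``2 * ltr_length + internal_length``; the defaults give 9,344 bp.
    """

    ltr_length: int = 522
    internal_length: int = 8300
    polyA_offset: int = 328   # AATAAA start, 1-based within LTR
    tata_offset: int = 396    # TATAWA start
    tss_offset: int = 404     # transcription start: U3|R boundary
    term_offset: int = 425    # transcription termination: R|U5 boundary
    pbs_trna_id: str = "tRNA-Lys"
    pbs_len: int = 18
    pbs_gap: int = 2          # bases between 5' LTR and PBS
    ppt_len: int = 12
    orf_plan: tuple[tuple[str, int], ...] = (
        ("gag", 600), ("pro", 300), ("pol", 900), ("env", 686),
    )
    ltr_divergence: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.polyA_offset < self.tata_offset < self.tss_offset
                <= self.term_offset <= self.ltr_length):
            raise ValueError(
                "require 1 <= polyA_offset < tata_offset < tss_offset "
                "<= term_offset <= ltr_length")
        if not 0.0 <= self.ltr_divergence <= 0.25:
            raise ValueError("ltr_divergence must lie in [0, 0.25]")
        order = {"gag": 0, "pro": 1, "pol": 2, "env": 3}
        ranks = [order[name] for name, _ in self.orf_plan if name in order]
        if ranks != sorted(ranks):
            raise ValueError("orf_plan must keep gag < pro < pol < env order")

    @property
    def total_length(self) -> int:
        return 2 * self.ltr_length + self.internal_length


@dataclass
class AlleleTruth:
    """Ground truth for a generated sequence.

    ``features`` is a non-overlapping chain that tiles the sequence exactly;
    ``extra_features`` carries nested annotations (U3/R/U5) that overlap the
    LTR features.  For insertion alleles, ``tsd`` is the duplicated target
    string and ``insertion_pos_in_host`` the 1-based host position after
    which the element sits.
    """

    sequence: SequenceRecord
    features: list[FeatureRecord]
    tsd: str = ""
    insertion_pos_in_host: int | None = None
    extra_features: list[FeatureRecord] = field(default_factory=list)
    spec: ElementSpec | None = None

    def tiling_sequence(self) -> str:
        parts = sorted(self.features, key=lambda f: f.interval.start)
        return "".join(
            self.sequence.seq[f.interval.start:f.interval.end] for f in parts)

    def feature(self, kind: str, label: str | None = None) -> FeatureRecord:
        for f in list(self.features) + list(self.extra_features):
            if f.kind == kind and (label is None or f.label == label):
                return f
        raise KeyError(f"no truth feature kind={kind!r} label={label!r}")


# --------------------------------------------------------------------------
# element construction
# --------------------------------------------------------------------------

def _scrub_motifs(ltr: list[str], spec: ElementSpec, rng) -> None:
    """Remove chance AATAAA / TATAWA occurrences so the planted pair is the
    only annotatable one (mutates ``ltr`` in place).  The disrupting base is
    always chosen outside the planted hexamers, so overlapping chance
    occurrences cannot take the planted motifs down with them."""
    planted_starts = {spec.polyA_offset - 1, spec.tata_offset - 1}
    protected = set()
    for p in planted_starts:
        protected.update(range(p, p + 6))
    changed = True
    while changed:
        changed = False
        s = "".join(ltr)
        for i in range(len(s) - 5):
            if i in planted_starts:
                continue
            word = s[i:i + 6]
            if word == "AATAAA" or (word[:4] == "TATA" and word[4] in "AT" and word[5] == "A"):
                j = next((j for j in range(i, i + 6) if j not in protected), None)
                if j is None:
                    continue  # occurrence inseparable from a planted motif
                ltr[j] = "C"
                changed = True
                break


def _build_ltr(spec: ElementSpec, rng) -> str:
    ltr = list(random_seq(spec.ltr_length, rng))
    ltr[spec.polyA_offset - 1:spec.polyA_offset + 5] = "AATAAA"
    ltr[spec.tata_offset - 1:spec.tata_offset + 5] = "TATAAA"
    _scrub_motifs(ltr, spec, rng)
    return "".join(ltr)


def _orf_seq(aa_len: int, rng) -> str:
    """ATG + (aa_len - 1) sense codons + one stop: translates to aa_len aa."""
    rng = _rng(rng)
    body = "".join(_CODON_ARR[rng.integers(0, len(_CODON_ARR), size=aa_len - 1)])
    stop = STOP_CODONS[int(rng.integers(0, 3))]
    return "ATG" + body + stop


def _ltr_subregions(spec: ElementSpec, ltr_start: int, which: str, chrom: str) -> list[FeatureRecord]:
    u3 = GenomicInterval(chrom, ltr_start, ltr_start + spec.tss_offset - 1)
    r = GenomicInterval(chrom, ltr_start + spec.tss_offset - 1, ltr_start + spec.term_offset)
    u5 = GenomicInterval(chrom, ltr_start + spec.term_offset, ltr_start + spec.ltr_length)
    return [
        FeatureRecord(u3, "U3", f"U3_{which}"),
        FeatureRecord(r, "R", f"R_{which}"),
        FeatureRecord(u5, "U5", f"U5_{which}"),
    ]


def build_element(
    spec: ElementSpec,
    seed,
    element_id: str = "element",
    trnas: Sequence[SequenceRecord] = tuple(SYNTHETIC_TRNA_PANEL),
) -> tuple[SequenceRecord, AlleleTruth]:
    """Generate one LTR retroelement and its full ground-truth annotation."""
    rng = _rng(seed)
    trna = {t.id: t for t in trnas}.get(spec.pbs_trna_id)
    if trna is None:
        raise ValueError(f"tRNA {spec.pbs_trna_id!r} not in panel")

    orf_seqs = [(name, _orf_seq(aa, rng)) for name, aa in spec.orf_plan]
    orf_nt = sum(len(s) for _, s in orf_seqs)
    n_spacers = len(orf_seqs) + 1
    spacer_total = (spec.internal_length - spec.pbs_gap - spec.pbs_len
                    - spec.ppt_len - orf_nt)
    min_needed = n_spacers * (len(STOP_WALL) + 1)
    if spacer_total < min_needed:
        raise ValueError(
            f"orf_plan too long for internal_length: needs at least "
            f"{spec.internal_length - spacer_total + min_needed} bp")
    base = spacer_total // n_spacers
    spacer_lens = [base] * n_spacers
    spacer_lens[-1] += spacer_total - base * n_spacers

    ltr5 = _build_ltr(spec, rng)
    ltr3 = mutate_seq(SequenceRecord("ltr", ltr5), spec.ltr_divergence, rng).seq
    pbs = revcomp(trna.seq[-spec.pbs_len:])

    chrom = element_id
    parts: list[tuple[str, str, str]] = [("LTR5", "LTR5", ltr5)]
    parts.append(("element", "pbs_gap", random_seq(spec.pbs_gap, rng)))
    parts.append(("PBS", spec.pbs_trna_id, pbs))
    for i, (name, oseq) in enumerate(orf_seqs):
        spacer = random_seq(spacer_lens[i] - len(STOP_WALL), rng) + STOP_WALL
        parts.append(("element", f"spacer_{i}", spacer))
        parts.append(("ORF", name, oseq))
    # final spacer: last bases forced pyrimidine so the planted PPT run is
    # maximal (a purine-delimited run cannot extend across them)
    if spacer_lens[-1] > 0:
        last = list(random_seq(spacer_lens[-1], rng))
        for k in range(1, min(3, len(last)) + 1):
            last[-k] = str(rng.choice(["C", "T"]))
        parts.append(("element", f"spacer_{n_spacers - 1}", "".join(last)))
    ppt = "".join(_rng(rng).choice(["A", "G"], size=spec.ppt_len))
    parts.append(("PPT", "ppt", ppt))
    parts.append(("LTR3", "LTR3", ltr3))

    seq = "".join(p[2] for p in parts)
    assert len(seq) == spec.total_length, (len(seq), spec.total_length)

    features: list[FeatureRecord] = []
    pos = 0
    extra: list[FeatureRecord] = []
    for kind, label, sub in parts:
        iv = GenomicInterval(chrom, pos, pos + len(sub), "+")
        features.append(FeatureRecord(iv, kind, label))
        if kind == "LTR5":
            extra.extend(_ltr_subregions(spec, pos, "5p", chrom))
        elif kind == "LTR3":
            extra.extend(_ltr_subregions(spec, pos, "3p", chrom))
        pos += len(sub)

    record = SequenceRecord(element_id, seq)
    truth = AlleleTruth(sequence=record, features=features,
                        extra_features=extra, spec=spec)
    log.debug("built element %s: %d bp, %d ORFs", element_id, len(seq), len(orf_seqs))
    return record, truth


# --------------------------------------------------------------------------
# insertion with target site duplication
# --------------------------------------------------------------------------

def insert_with_tsd(
    host: SequenceRecord,
    element: SequenceRecord,
    pos: int,
    tsd_len: int,
    seed=None,
    allele_id: str | None = None,
) -> AlleleTruth:
    """Insert ``element`` into ``host`` after 1-based position ``pos``,
    duplicating the ``tsd_len`` host bases immediately upstream of the
    insertion point on the element's downstream side (the integration-site
    duplication a retroviral integrase leaves behind)."""
    if not 1 <= pos <= len(host):
        raise ValueError(f"pos must lie in [1, {len(host)}], got {pos}")
    if not 0 <= tsd_len <= 25:
        raise ValueError("tsd_len must lie in [0, 25]")
    if tsd_len > pos:
        raise ValueError(f"tsd_len {tsd_len} exceeds upstream host sequence ({pos} bp)")
    tsd = host.seq[pos - tsd_len:pos]
    seq = host.seq[:pos] + element.seq + tsd + host.seq[pos:]
    chrom = allele_id or f"{host.id}+{element.id}"
    record = SequenceRecord(chrom, seq)

    features: list[FeatureRecord] = []
    if pos - tsd_len > 0:
        features.append(FeatureRecord(GenomicInterval(chrom, 0, pos - tsd_len), "flank", "host_left"))
    if tsd_len:
        features.append(FeatureRecord(GenomicInterval(chrom, pos - tsd_len, pos), "TSD", "tsd_left"))
    el_iv = GenomicInterval(chrom, pos, pos + len(element), "+")
    features.append(FeatureRecord(el_iv, "element", element.id))
    if tsd_len:
        features.append(FeatureRecord(
            GenomicInterval(chrom, el_iv.end, el_iv.end + tsd_len), "TSD", "tsd_right"))
    if pos < len(host):
        features.append(FeatureRecord(
            GenomicInterval(chrom, el_iv.end + tsd_len, len(seq)), "flank", "host_right"))

    return AlleleTruth(sequence=record, features=features, tsd=tsd,
                       insertion_pos_in_host=pos)


def build_nested_allele(
    seed,
    host_len: int = 3000,
    spec: ElementSpec | None = None,
    tsd_range: tuple[int, int] = (4, 8),
    margin: int = 300,
    max_tries: int = 100,
) -> tuple[SequenceRecord, SequenceRecord, AlleleTruth]:
    """A nested-allele instance whose decomposition is identifiable.

    When the host base flanking an integration site happens to equal the
    element base adjacent to a terminal-repeat copy, the composite string
    admits several equally supported (element, TSD) readings shifted by a
    base or more — the ground truth is then mathematically underdetermined.
    This builder rejection-samples the insertion position and TSD length
    until the four boundary-coincidence conditions are all excluded, so the
    planted structure is the unique maximal-evidence reading.

    Returns (host, element, allele truth).
    """
    rng = _rng(seed)
    spec = spec or ElementSpec()
    element, _ = build_element(spec, rng, element_id="inner")
    host = SequenceRecord("host", random_seq(host_len, rng))
    el, n, L = element.seq, len(element), spec.ltr_length
    for _ in range(max_tries):
        pos = int(rng.integers(margin, host_len - margin))
        k = int(rng.integers(tsd_range[0], tsd_range[1] + 1))
        identifiable = (
            host.seq[pos] != el[0]               # element cannot shed its first base
            and host.seq[pos - 1] != el[n - L - 1]   # nor absorb the upstream TSD base
            and host.seq[pos - k] != el[L]           # nor absorb the downstream TSD base
            and host.seq[pos - k - 1] != el[n - 1]   # nor shed its last base
        )
        if identifiable:
            truth = insert_with_tsd(host, element, pos=pos, tsd_len=k)
            # the planted TSD must also be the maximal flanking duplication
            # (a shorter TSD planted inside a homopolymer run is ill-posed)
            if _max_flanking_dup(truth.sequence.seq, pos, pos + len(element)) == k:
                return host, element, truth
    raise RuntimeError("no identifiable insertion site found")  # pragma: no cover


# --------------------------------------------------------------------------
# sequence mutation
# --------------------------------------------------------------------------

def mutate_seq(seq: SequenceRecord, sub_rate: float, seed) -> SequenceRecord:
    """Apply i.i.d. substitutions (always to a different base) at the given
    per-site rate; N bases are left untouched."""
    if not 0.0 <= sub_rate <= 0.5:
        raise ValueError("sub_rate must lie in [0, 0.5]")
    rng = _rng(seed)
    chars = np.array(list(seq.seq))
    hit = rng.random(len(chars)) < sub_rate
    hit &= chars != "N"
    idx = np.flatnonzero(hit)
    if idx.size:
        base_index = {b: i for i, b in enumerate(BASES)}
        cur = np.array([base_index[c] for c in chars[idx]])
        shift = rng.integers(1, 4, size=idx.size)
        chars[idx] = [BASES[(c + s) % 4] for c, s in zip(cur, shift)]
    return SequenceRecord(seq.id, "".join(chars), seq.alphabet)


# --------------------------------------------------------------------------
# depth and junction simulation
# --------------------------------------------------------------------------

def simulate_depth(
    loci: Sequence[tuple[GenomicInterval, float]],
    mean_cov: float,
    seed,
    contamination: float = 0.0,
):
    """Per-base depth ~ Poisson(copy_number x mean_cov) over the given loci.

    Positions covered by no locus get depth 0; callers include single-copy
    background loci explicitly so the genome-coverage denominator is part of
    the track.  ``contamination`` adds Poisson(contamination x mean_cov)
    everywhere, emulating uniform mis-mapping noise.
    """
    from .depth_cn import DepthTrack

    if mean_cov <= 0:
        raise ValueError("mean_cov must be positive")
    rng = _rng(seed)
    chroms = {iv.chrom for iv, _ in loci}
    if len(chroms) != 1:
        raise ValueError("all loci must share one chromosome per track")
    length = max(iv.end for iv, _ in loci)
    depth = np.zeros(length, dtype=np.int64)
    for iv, cn in loci:
        if cn < 0:
            raise ValueError("copy number must be >= 0")
        if cn > 0:
            depth[iv.start:iv.end] += rng.poisson(cn * mean_cov, size=iv.length)
    if contamination > 0:
        depth += rng.poisson(contamination * mean_cov, size=length)
    return DepthTrack(chrom=chroms.pop(), depth=depth)


def simulate_junctions(
    models,
    counts: Sequence[int],
    noise_junctions: int = 0,
    seed=None,
    chrom_length: int | None = None,
):
    """Emit the junction table implied by transcript models.

    Each model contributes every junction in its chain at the model's read
    count; a junction shared by several models accumulates their counts.
    Noise junctions are placed at random unannotated positions.
    Returns a list of :class:`retronest.splice_class.JunctionRecord`.
    """
    from .splice_class import JunctionRecord

    if len(models) != len(counts):
        raise ValueError("need one count per transcript model")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be >= 0")
    rng = _rng(seed)
    acc: dict[tuple[str, int, int, str], int] = {}
    for model, count in zip(models, counts):
        if count == 0:
            continue
        for iv in model.junctions:
            key = (iv.chrom, iv.start, iv.end, iv.strand if iv.strand != "." else "+")
            acc[key] = acc.get(key, 0) + count
    if noise_junctions:
        if chrom_length is None:
            raise ValueError("chrom_length required to place noise junctions")
        chrom = models[0].junctions[0].chrom if models else "locus"
        annotated = set(acc)
        placed = 0
        while placed < noise_junctions:
            start = int(rng.integers(0, chrom_length - 120))
            end = start + int(rng.integers(40, 120))
            key = (chrom, start, end, "+")
            if key in annotated or key in acc:
                continue
            acc[key] = int(rng.integers(1, 6))
            placed += 1
    out = [
        JunctionRecord(intron=GenomicInterval(c, s, e, st), strand=st, read_count=n)
        for (c, s, e, st), n in sorted(acc.items())
    ]
    return out


# --------------------------------------------------------------------------
# replica of the nonagouti nested-insertion locus (synthetic throughout)
# --------------------------------------------------------------------------

#: Reference-genome (GRCm38) coordinates of the insertion-allele interval.
NONAGOUTI_INTERVAL = GenomicInterval.from_one_based("chr2", 155_014_951, 155_029_655)

#: Structural parameters of the nested insertion at the *agouti* locus:
#: a β4-family provirus (522-bp identical LTRs, 9,344 bp total, Lys-tRNA PBS,
#: polyA 328 / TATA 396 / TSS 404 / termination 425 inside the LTR, 686-aa
#: env) nested at position 2,914 of a 5,357-bp VL30 with a 6-bp TSD; the
#: composite sits in the host genome behind a 4-bp TSD.
BETA4_SPEC = ElementSpec()
VL30_SPEC = ElementSpec(
    ltr_length=350, internal_length=5357 - 2 * 350,
    polyA_offset=200, tata_offset=280, tss_offset=288, term_offset=310,
    pbs_trna_id="tRNA-Gly", orf_plan=(),
)
BETA4_POS_IN_VL30 = 2914
BETA4_TSD_LEN = 6
VL30_TSD_LEN = 4


@dataclass
class ReplicaLocus:
    """Synthetic stand-in for the nested nonagouti insertion allele."""

    beta4: SequenceRecord
    beta4_truth: AlleleTruth
    vl30: SequenceRecord
    vl30_truth: AlleleTruth
    composite_truth: AlleleTruth      # β4 nested in VL30 (+ inner TSD)
    allele_truth: AlleleTruth         # composite inserted in genomic flanks
    trnas: list[SequenceRecord]

    @property
    def composite(self) -> SequenceRecord:
        return self.composite_truth.sequence

    @property
    def allele(self) -> SequenceRecord:
        return self.allele_truth.sequence

    @property
    def composite_interval(self) -> GenomicInterval:
        return self.allele_truth.feature("element").interval

    @property
    def inner_interval(self) -> GenomicInterval:
        return self.composite_truth.feature("element").interval


def _max_flanking_dup(seq: str, s: int, e: int, max_len: int = 25) -> int:
    """Longest exact duplication immediately flanking ``[s, e)`` (local
    string check used to verify that a planted TSD is maximal)."""
    for k in range(max_len, 0, -1):
        if s - k >= 0 and e + k <= len(seq) and seq[s - k:s] == seq[e:e + k]:
            return k
    return 0


def nonagouti_replica(seed, flank_len: int = 1500, max_tries: int = 20) -> ReplicaLocus:
    """Build the synthetic nested-insertion locus with the reference anatomy.

    Rebuilds until the planted boundaries are identifiable (no chance
    boundary coincidence extends or shifts the TSDs), so the locus anatomy
    is exactly recoverable for any seed.
    """
    rng = _rng(seed)
    pos, k_in, k_out = BETA4_POS_IN_VL30, BETA4_TSD_LEN, VL30_TSD_LEN
    for _ in range(max_tries):
        beta4, beta4_truth = build_element(BETA4_SPEC, rng, element_id="beta4")
        vl30, vl30_truth = build_element(VL30_SPEC, rng, element_id="VL30")
        b4, n, L = beta4.seq, len(beta4), BETA4_SPEC.ltr_length
        identifiable = (
            vl30.seq[pos] != b4[0]
            and vl30.seq[pos - 1] != b4[n - L - 1]
            and vl30.seq[pos - k_in] != b4[L]
            and vl30.seq[pos - k_in - 1] != b4[n - 1]
        )
        if not identifiable:
            continue
        composite_truth = insert_with_tsd(
            vl30, beta4, pos, k_in, allele_id="VL30_nested")
        host = SequenceRecord("agouti_flanks", random_seq(2 * flank_len, rng))
        allele_truth = insert_with_tsd(
            host, composite_truth.sequence, flank_len, k_out, allele_id="a_allele")
        inner_iv = composite_truth.feature("element").interval
        outer_iv = allele_truth.feature("element").interval
        if (_max_flanking_dup(composite_truth.sequence.seq, inner_iv.start, inner_iv.end) != k_in
                or _max_flanking_dup(allele_truth.sequence.seq, outer_iv.start, outer_iv.end) != k_out):
            continue
        return ReplicaLocus(
            beta4=beta4, beta4_truth=beta4_truth,
            vl30=vl30, vl30_truth=vl30_truth,
            composite_truth=composite_truth, allele_truth=allele_truth,
            trnas=list(SYNTHETIC_TRNA_PANEL),
        )
    raise RuntimeError("no identifiable replica build found")  # pragma: no cover


@dataclass
class SpliceLocus:
    """Annotation + transcript catalogue for the replica insertion allele."""

    features: list[FeatureRecord]
    catalog: list            # 13 TranscriptModel entries
    exon_pairs: set[tuple[str, str]]
    hijack_exon_model: object     # exon 1C donor -> β4 5' LTR U5 acceptor
    hijack_vl30_model: object     # VL30 LTR donor -> β4 internal acceptor


def replica_splice_locus(replica: ReplicaLocus) -> SpliceLocus:
    """Build the splice annotation mirroring the disrupted locus: host-gene
    exons in the flanks, the nested elements with their LTR subregions in
    between, and a 13-entry transcript catalogue mixing normally spliced and
    element-hijacked structures (including the exon-1C -> β4-U5 and
    VL30-LTR -> β4 junctions)."""
    from .splice_class import TranscriptModel

    chrom = replica.allele.id
    comp = replica.composite_interval                      # composite in allele
    c0, c1 = comp.start, comp.end
    b0 = c0 + replica.inner_interval.start                 # β4 start in allele
    b1 = c0 + replica.inner_interval.end
    beta4_spec, vl30_spec = replica.beta4_truth.spec, replica.vl30_truth.spec
    left_flank = replica.allele_truth.feature("flank", "host_left").interval
    right_flank = replica.allele_truth.feature("flank", "host_right").interval
    if left_flank.length < 1000 or right_flank.length < 1000:
        raise ValueError("replica flanks too short for the splice locus")

    def exon(name: str, start: int, end: int) -> FeatureRecord:
        return FeatureRecord(GenomicInterval(chrom, start, end, "+"), "exon", name)

    r0 = right_flank.start
    exons = [
        exon("exon1A", left_flank.start + 100, left_flank.start + 180),
        exon("exon1A'", left_flank.start + 250, left_flank.start + 330),
        exon("exon1B", left_flank.start + 500, left_flank.start + 580),
        exon("exon1C", left_flank.start + 700, left_flank.start + 780),
        exon("exon2", r0 + 200, r0 + 280),
        exon("exon3", r0 + 500, r0 + 580),
        exon("exon4", r0 + 800, r0 + 880),
    ]
    L_b, L_v = beta4_spec.ltr_length, vl30_spec.ltr_length
    elements = [
        FeatureRecord(GenomicInterval(chrom, c0, c1, "+"), "element", "VL30"),
        FeatureRecord(GenomicInterval(chrom, c0, c0 + L_v, "+"), "LTR5", "VL30_LTR5"),
        FeatureRecord(GenomicInterval(chrom, c1 - L_v, c1, "+"), "LTR3", "VL30_LTR3"),
        FeatureRecord(GenomicInterval(chrom, b0, b1, "+"), "element", "beta4"),
        FeatureRecord(GenomicInterval(chrom, b0, b0 + L_b, "+"), "LTR5", "beta4_LTR5"),
        FeatureRecord(GenomicInterval(chrom, b0 + beta4_spec.term_offset,
                                      b0 + L_b, "+"), "U5", "beta4_LTR5_U5"),
        FeatureRecord(GenomicInterval(chrom, b1 - L_b, b1, "+"), "LTR3", "beta4_LTR3"),
    ]
    features = exons + elements
    by_name = {f.label: f.interval for f in exons}

    def intron(donor_end: int, acceptor_start: int) -> GenomicInterval:
        return GenomicInterval(chrom, donor_end, acceptor_start, "+")

    u5_acc = b0 + beta4_spec.term_offset + 30       # inside β4 5' LTR U5
    vl30_ltr3_acc = c1 - L_v + 50                   # inside VL30 3' LTR
    beta4_internal_acc = b0 + L_b + 80              # inside β4, past the 5' LTR
    n23 = intron(by_name["exon2"].end, by_name["exon3"].start)
    n34 = intron(by_name["exon3"].end, by_name["exon4"].start)

    catalog: list[TranscriptModel] = []
    donors = ["exon1A", "exon1A'", "exon1B", "exon1C"]
    for i, name in enumerate(donors, start=1):
        catalog.append(TranscriptModel(
            id=str(i),
            junctions=(intron(by_name[name].end, by_name["exon2"].start), n23, n34),
            klass="normal"))
    for i, name in enumerate(donors, start=5):
        catalog.append(TranscriptModel(
            id=str(i), junctions=(intron(by_name[name].end, u5_acc),),
            klass="element_hijacked"))
    for i, name in enumerate(donors, start=9):
        catalog.append(TranscriptModel(
            id=str(i), junctions=(intron(by_name[name].end, vl30_ltr3_acc),),
            klass="element_hijacked"))
    catalog.append(TranscriptModel(
        id="13", junctions=(intron(c0 + 100, beta4_internal_acc),),
        klass="element_hijacked"))

    exon_pairs = {
        (f"exon:{d}", "exon:exon2") for d in donors
    } | {("exon:exon2", "exon:exon3"), ("exon:exon3", "exon:exon4")}

    return SpliceLocus(
        features=features, catalog=catalog, exon_pairs=exon_pairs,
        hijack_exon_model=catalog[7],    # id "8": exon1C -> β4 U5
        hijack_vl30_model=catalog[12],   # id "13": VL30 LTR -> β4
    )
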