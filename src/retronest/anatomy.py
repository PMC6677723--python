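"""Structural anatomy of (nested) LTR-retroelement insertions.

This is the analytical heart of the package: given an insertion allele it
finds the target site duplication (TSD) the integrase left behind, the
element's direct terminal repeats (LTRs), the primer binding site and
polypurine tract, the promoter/polyadenylation motifs inside the LTR and the
U3-R-U5 partition they imply, and — for composite integrants — decomposes a
nested insertion into its inner element and reconstructed host, exactly the
chain of evidence used to resolve a retrovirus inserted inside another
retroelement.

Conventions: element-local positions are reported in the element's own
5'->3' sense (1-based when printed), regardless of which genomic strand the
element occupies.  N matches nothing in repeat/TSD comparisons.  TSDs are
exact duplications only; near-duplications are deliberately not reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .core_io import (
    FeatureRecord,
    GenomicInterval,
    SequenceRecord,
    get_logger,
    revcomp,
)
from . import orf_annot

log = get_logger("anatomy")

PURINES = frozenset("AG")

__all__ = [
    "TSDReport", "TerminalRepeat", "LTRPartition", "PBSHit", "PPTHit",
    "NestedDecomposition", "ElementAnnotation", "MotifScan",
    "detect_tsd", "detect_terminal_repeats", "decompose_nested",
    "find_pbs", "find_ppt", "scan_ltr_motifs", "partition_ltr",
    "annotate_element", "predict_solo_ltr", "dotplot", "pairwise_identity",
]


# --------------------------------------------------------------------------
# result types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TSDReport:
    """An exact direct duplication flanking an element (length 0 = none)."""

    length: int
    sequence: str
    left_interval: GenomicInterval | None
    right_interval: GenomicInterval | None


@dataclass(frozen=True)
class TerminalRepeat:
    """End-anchored direct repeat pair (the two LTR copies of a provirus)."""

    five_prime: GenomicInterval
    three_prime: GenomicInterval
    length: int
    identity: float


@dataclass(frozen=True)
class LTRPartition:
    """U3 / R / U5 partition of an LTR (R = transcribed repeat, from the
    transcription start site to the termination site)."""

    u3: GenomicInterval
    r: GenomicInterval
    u5: GenomicInterval
    polyA_site: int | None = None   # 1-based LTR offsets when known
    tata_site: int | None = None


@dataclass(frozen=True)
class PBSHit:
    interval: GenomicInterval
    matched_trna_id: str
    mismatches: int


@dataclass(frozen=True)
class PPTHit:
    interval: GenomicInterval
    purine_fraction: float


@dataclass(frozen=True)
class MotifScan:
    """All AATAAA / TATAWA hits in an LTR plus the annotated (polyA, TATA)
    pair: polyA upstream of TATA, TATA maximal (closest to the U3 3' end)."""

    polyA_sites: tuple[int, ...]    # 1-based start offsets
    tata_sites: tuple[int, ...]
    polyA_site: int | None
    tata_site: int | None


@dataclass
class ElementAnnotation:
    terminal_repeat: TerminalRepeat | None
    partition5: LTRPartition | None
    partition3: LTRPartition | None
    pbs: PBSHit | None
    ppt: PPTHit | None
    orfs: list
    gene_model: object | None
    classification: str  # full_length_provirus | truncated | solo_ltr | non_ltr
    motifs5: MotifScan | None = None


@dataclass
class NestedDecomposition:
    inner_element: SequenceRecord
    inner_annotation: ElementAnnotation | None
    host_reconstructed: SequenceRecord
    insertion_pos_in_host: int       # 1-based, host sense
    tsd: TSDReport


# --------------------------------------------------------------------------
# target site duplication
# --------------------------------------------------------------------------

def detect_tsd(
    allele: SequenceRecord,
    element_interval: GenomicInterval,
    max_len: int = 25,
) -> TSDReport:
    """Longest exact duplication immediately flanking the element.

    Compares the k-mers abutting the element on both sides for k from
    ``max_len`` down to 1 (Ns never match); k = 0 is a valid outcome.
    """
    s, e = element_interval.start, element_interval.end
    if s < max_len or e + max_len > len(allele):
        raise ValueError(
            f"need >= {max_len} bp of flank on both sides of {element_interval}")
    seq = allele.seq
    for k in range(max_len, 0, -1):
        left = seq[s - k:s]
        right = seq[e:e + k]
        if left == right and "N" not in left:
            return TSDReport(
                length=k, sequence=left,
                left_interval=GenomicInterval(allele.id, s - k, s),
                right_interval=GenomicInterval(allele.id, e, e + k),
            )
    return TSDReport(length=0, sequence="", left_interval=None, right_interval=None)


# --------------------------------------------------------------------------
# terminal repeats (seed and extend)
# --------------------------------------------------------------------------

def _ungapped_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    m = sum(1 for x, y in zip(a, b) if x == y and x != "N")
    return m / n


def _word_offsets(seq: str, word: int, min_offset: int = 1) -> dict[int, list[int]]:
    """Self-match offsets: for every pair of identical words at positions
    (i, i+d), collect i under offset d (d >= min_offset, forward sense)."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - word + 1):
        w = seq[i:i + word]
        if "N" in w:
            continue
        index.setdefault(w, []).append(i)
    offsets: dict[int, list[int]] = {}
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                d = positions[bi] - positions[ai]
                if d >= min_offset:
                    offsets.setdefault(d, []).append(positions[ai])
    return offsets


def detect_terminal_repeats(
    element: SequenceRecord,
    min_len: int = 50,
    min_identity: float = 0.80,
    word: int = 12,
) -> TerminalRepeat | None:
    """Find the element's direct terminal repeat pair by seed-and-extend.

    Word matches between the two ends vote for an offset d; an end-anchored
    repeat of length L = len - d spans ``[0, L)`` and ``[d, len)``.  The
    longest candidate with ungapped identity >= ``min_identity`` wins.
    Returns None when no qualifying repeat exists.
    """
    n = len(element)
    if n < 2 * min_len:
        raise ValueError(f"element shorter than 2 x min_len ({n} < {2 * min_len})")
    seq = element.seq
    offsets = _word_offsets(seq, word, min_offset=min_len)
    best: TerminalRepeat | None = None
    for d, starts in offsets.items():
        length = n - d
        if length < min_len or length > n // 2:
            continue
        # seeds must actually touch the repeat pair, not an interior repeat
        if min(starts) > length:
            continue
        ident = _ungapped_identity(seq[:length], seq[d:])
        if ident >= min_identity and (best is None or length > best.length):
            best = TerminalRepeat(
                five_prime=GenomicInterval(element.id, 0, length),
                three_prime=GenomicInterval(element.id, d, n),
                length=length, identity=ident,
            )
    return best


# --------------------------------------------------------------------------
# nested decomposition
# --------------------------------------------------------------------------

def _refine_boundaries(seq: str, a0: int, b0: int, d: int, min_rep: int,
                       slack: int = 30, min_tsd: int = 4,
                       max_tsd: int = 25) -> tuple[int, int, int]:
    """Search boundary pairs near the seeded (a0, b0) for the pair best
    explained as an integrant.

    For a candidate (a, b) the implied terminal-repeat length is
    L = b - a - d (the two repeat copies sit ``d`` apart), so the copies
    ``seq[a:a+L]`` and ``seq[a+d:b]`` stay aligned for every candidate.
    Candidates must be flanked by an exact duplication of >= ``min_tsd`` bp
    (the internal TSD) and are ranked by repeat-copy matches, then TSD
    length, then closeness to the seeds.  Returns (a, b, tsd_len);
    tsd_len 0 means no qualifying pair exists nearby."""
    best = (a0, b0, 0)
    best_score = (-1, -1, 0)
    for a in range(max(a0 - slack, min_tsd), a0 + slack + 1):
        for b in range(max(b0 - slack, a + d + min_rep),
                       min(b0 + slack + 1, len(seq) - min_tsd + 1)):
            k = 0
            for kk in range(min(max_tsd, a, len(seq) - b), min_tsd - 1, -1):
                left = seq[a - kk:a]
                if left == seq[b:b + kk] and "N" not in left:
                    k = kk
                    break
            if k < min_tsd:
                continue
            rep_matches = sum(
                1 for x, y in zip(seq[a:b - d], seq[a + d:b])
                if x == y and x != "N")
            # joint evidence: net repeat matches (random columns cost), the
            # exact TSD pairs, and a penalty for moving away from the word
            # seeds — so neither a partial repeat extension nor a chance
            # nearby duplication can outbid the planted boundaries
            net = 2 * rep_matches - (b - d - a)
            dist = abs(a - a0) + abs(b - b0)
            score = (net + k - dist, k, -dist)
            if score > best_score:
                best_score = score
                best = (a, b, k)
    return best


def decompose_nested(
    composite: SequenceRecord,
    min_inner_len: int = 500,
    min_tsd: int = 4,
    min_repeat_len: int = 50,
    min_identity: float = 0.80,
    word: int = 12,
    annotate_inner: bool = True,
) -> list[NestedDecomposition]:
    """Resolve a nested insertion: an inner LTR element, bearing its own
    end-anchored repeat pair and flanked by an internal TSD, buried inside a
    composite element.

    Candidate inner boundaries are seeded from the self-comparison's
    off-diagonal repeat pairs (the inner element's two LTR copies), then
    validated and refined by the internal-TSD check.  On success the inner
    element plus one TSD copy is excised and the host reconstructed.
    Returns all non-overlapping candidates ranked by inner terminal-repeat
    length (empty list when none qualifies).
    """
    n = len(composite)
    if n <= min_inner_len:
        raise ValueError("composite shorter than min_inner_len")
    seq = composite.seq
    offsets = _word_offsets(seq, word, min_offset=min_repeat_len)

    candidates: list[tuple[int, int, int, int]] = []  # (a, b, tsd_len, repeat_len)
    for d, starts in offsets.items():
        starts = sorted(set(starts))
        # cluster seed starts into runs (gap tolerance absorbs divergence)
        runs: list[list[int]] = [[starts[0]]]
        for i in starts[1:]:
            if i - runs[-1][-1] <= 3 * word:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            a0 = run[0]
            rep_len = run[-1] + word - run[0]
            if rep_len < min_repeat_len:
                continue
            inner_len = d + rep_len
            if inner_len < min_inner_len or inner_len > n - 2 * min_tsd:
                continue
            b0 = a0 + inner_len
            if a0 < min_tsd or b0 > n - min_tsd:
                continue  # the composite's own terminal repeats, not a nest
            if _ungapped_identity(seq[a0:a0 + rep_len], seq[a0 + d:a0 + d + rep_len]) < min_identity:
                continue
            a, b, tsd_len = _refine_boundaries(
                seq, a0, b0, d, min_rep=min_repeat_len, min_tsd=min_tsd)
            if tsd_len < min_tsd:
                continue
            candidates.append((a, b, tsd_len, rep_len))

    # de-duplicate overlapping candidates, keep longest repeat per locus
    candidates.sort(key=lambda c: (-c[3], c[0]))
    chosen: list[tuple[int, int, int, int]] = []
    for cand in candidates:
        if all(cand[1] <= c[0] or cand[0] >= c[1] for c in chosen):
            chosen.append(cand)

    results: list[NestedDecomposition] = []
    for a, b, tsd_len, _rep in chosen:
        inner = SequenceRecord(f"{composite.id}_inner", seq[a:b])
        host = SequenceRecord(f"{composite.id}_host", seq[:a] + seq[b + tsd_len:])
        tsd = TSDReport(
            length=tsd_len, sequence=seq[a - tsd_len:a],
            left_interval=GenomicInterval(composite.id, a - tsd_len, a),
            right_interval=GenomicInterval(composite.id, b, b + tsd_len),
        )
        ann = annotate_element(inner) if annotate_inner else None
        log.info(
            "nested decomposition of %s: inner [%d, %d) (%d bp), host %d bp, "
            "insertion after host position %d (1-based, host sense; the first "
            "interrupted base is %d), TSD %s",
            composite.id, a, b, b - a, len(host), a, a + 1, tsd.sequence)
        results.append(NestedDecomposition(
            inner_element=inner, inner_annotation=ann,
            host_reconstructed=host, insertion_pos_in_host=a, tsd=tsd))
    return results


# --------------------------------------------------------------------------
# PBS / PPT
# --------------------------------------------------------------------------

def find_pbs(
    element: SequenceRecord,
    repeat: TerminalRepeat,
    trnas: Sequence[SequenceRecord],
    window: int = 30,
    pbs_len: int = 18,
    max_mismatch: int = 2,
) -> PBSHit | None:
    """Primer binding site: the reverse complement of a tRNA 3' end, within
    ``window`` bases downstream of the 5' LTR.  Best hit by fewest
    mismatches; ties go to the hit closest to the LTR."""
    if not trnas:
        raise ValueError("empty tRNA set")
    start0 = repeat.five_prime.end
    region = element.seq[start0:start0 + window + pbs_len]
    best: tuple[int, int, str] | None = None  # (mismatches, offset, trna_id)
    for trna in trnas:
        target = revcomp(trna.seq[-pbs_len:])
        for off in range(0, min(window, len(region) - pbs_len) + 1):
            sub = region[off:off + pbs_len]
            if len(sub) < pbs_len:
                break
            mm = sum(1 for x, y in zip(sub, target) if x != y or x == "N")
            if best is None or (mm, off) < (best[0], best[1]):
                best = (mm, off, trna.id)
    if best is None or best[0] > max_mismatch:
        return None
    mm, off, trna_id = best
    iv = GenomicInterval(element.id, start0 + off, start0 + off + pbs_len, "+")
    return PBSHit(interval=iv, matched_trna_id=trna_id, mismatches=mm)


def find_ppt(
    element: SequenceRecord,
    repeat: TerminalRepeat,
    window: int = 20,
    min_len: int = 9,
    min_purine: float = 0.9,
) -> PPTHit | None:
    """Polypurine tract: the longest run within ``window`` bases upstream of
    the 3' LTR whose purine fraction is >= ``min_purine``.  Runs must begin
    and end on a purine (a tract is delimited by purines); ties prefer the
    run closest to the LTR."""
    end0 = repeat.three_prime.start
    lo = max(0, end0 - window)
    region = element.seq[lo:end0]
    best: tuple[int, int, float] | None = None  # (length, start, fraction)
    for i in range(len(region)):
        if region[i] not in PURINES:
            continue
        purines = 0
        for j in range(i, len(region)):
            is_purine = region[j] in PURINES
            purines += is_purine
            if not is_purine:
                continue  # runs may span pyrimidines but must end on a purine
            length = j - i + 1
            frac = purines / length
            if length >= min_len and frac >= min_purine:
                if best is None or length > best[0] or (length == best[0] and i > best[1]):
                    best = (length, i, frac)
    if best is None:
        return None
    length, i, frac = best
    iv = GenomicInterval(element.id, lo + i, lo + i + length, "+")
    return PPTHit(interval=iv, purine_fraction=frac)


# --------------------------------------------------------------------------
# LTR motifs and U3-R-U5 partition
# --------------------------------------------------------------------------

def scan_ltr_motifs(ltr: SequenceRecord) -> MotifScan:
    """Scan an LTR for polyadenylation signals (AATAAA) and TATA boxes
    (TATAWA, W in {A, T}); offsets are 1-based hexamer starts.

    The annotated pair is the (polyA, TATA) with polyA < TATA and TATA
    maximal — the promoter closest to the 3' end of U3 — with the nearest
    upstream polyA.  All raw hits are returned alongside.
    """
    seq = ltr.seq
    polya, tata = [], []
    for i in range(len(seq) - 5):
        w = seq[i:i + 6]
        if w == "AATAAA":
            polya.append(i + 1)
        if w[:4] == "TATA" and w[4] in "AT" and w[5] == "A":
            tata.append(i + 1)
    polyA_site = tata_site = None
    for t in sorted(tata, reverse=True):
        ups = [p for p in polya if p < t]
        if ups:
            tata_site, polyA_site = t, max(ups)
            break
    return MotifScan(tuple(polya), tuple(tata), polyA_site, tata_site)


def partition_ltr(
    ltr_length: int,
    tss_pos: int,
    term_pos: int,
    chrom: str = "LTR",
    polyA_site: int | None = None,
    tata_site: int | None = None,
) -> LTRPartition:
    """Partition an LTR into U3 | R | U5 (all positions 1-based).

    U3 runs from the 5' end to just before the transcription start site, R
    from the start site through the termination site, U5 from there to the
    LTR 3' end.  U3 and/or U5 may be empty at the boundaries.
    """
    if not (1 <= tss_pos <= term_pos <= ltr_length):
        raise ValueError(
            f"require 1 <= tss ({tss_pos}) <= term ({term_pos}) <= length ({ltr_length})")

    def iv(first: int, last: int) -> GenomicInterval | None:
        if last < first:
            return None
        return GenomicInterval.from_one_based(chrom, first, last)

    return LTRPartition(
        u3=iv(1, tss_pos - 1),
        r=iv(tss_pos, term_pos),
        u5=iv(term_pos + 1, ltr_length),
        polyA_site=polyA_site, tata_site=tata_site,
    )


# --------------------------------------------------------------------------
# whole-element annotation and solo-LTR prediction
# --------------------------------------------------------------------------

#: Heuristic U3|R boundary: transcription initiates ~8 bp downstream of the
#: last TATA base pair group under the canonical ~25-30 bp TATA-to-TSS
#: spacing measured from the hexamer start; R length defaults to the short
#: repeated region typical of betaretroviral LTRs.
TSS_OFFSET_FROM_TATA = 8
DEFAULT_R_LENGTH = 22
SOLO_LTR_MAX_LEN = 1200


def annotate_element(
    element: SequenceRecord,
    trnas: Sequence[SequenceRecord] | None = None,
    min_repeat_len: int = 50,
    min_repeat_identity: float = 0.80,
    min_orf_aa: int = 100,
    tss_pos: int | None = None,
    term_pos: int | None = None,
) -> ElementAnnotation:
    """Full structural annotation: terminal repeats, LTR motifs, U3-R-U5,
    PBS/PPT, ORFs + gene labels, and an overall classification.

    When no transcript-end evidence is supplied, the U3|R boundary is placed
    ``TSS_OFFSET_FROM_TATA`` bases after the TATA hexamer start and R spans
    ``DEFAULT_R_LENGTH`` bases (heuristic, logged).
    """
    repeat = None
    if len(element) >= 2 * min_repeat_len:
        repeat = detect_terminal_repeats(
            element, min_len=min_repeat_len, min_identity=min_repeat_identity)

    orfs = orf_annot.find_orfs(element, min_aa=min_orf_aa)
    gene_model = orf_annot.label_genes(orfs, len(element), repeat)

    pbs = ppt = None
    partition5 = partition3 = None
    motifs5 = None
    if repeat is not None:
        if trnas:
            pbs = find_pbs(element, repeat, trnas)
        ppt = find_ppt(element, repeat)
        ltr5 = element.slice(repeat.five_prime.start, repeat.five_prime.end, "LTR5")
        motifs5 = scan_ltr_motifs(ltr5)
        partition5 = _partition_from_evidence(
            repeat.length, motifs5, tss_pos, term_pos, chrom=f"{element.id}_LTR5")
        ltr3 = element.slice(repeat.three_prime.start, repeat.three_prime.end, "LTR3")
        motifs3 = scan_ltr_motifs(ltr3)
        partition3 = _partition_from_evidence(
            repeat.three_prime.length, motifs3, tss_pos, term_pos,
            chrom=f"{element.id}_LTR3")

    if repeat is not None and gene_model.classification == "full_length_provirus":
        classification = "full_length_provirus"
    elif repeat is None and len(element) <= SOLO_LTR_MAX_LEN:
        # a lone LTR: no repeat pair, single-LTR scale, own promoter/polyA
        motifs_solo = scan_ltr_motifs(element)
        classification = ("solo_ltr" if motifs_solo.tata_site and motifs_solo.polyA_site
                          else "non_ltr")
        motifs5 = motifs_solo
        if classification == "solo_ltr":
            partition5 = _partition_from_evidence(
                len(element), motifs_solo, tss_pos, term_pos, chrom=element.id)
    elif repeat is not None:
        classification = "truncated"
    else:
        classification = "non_ltr"

    return ElementAnnotation(
        terminal_repeat=repeat, partition5=partition5, partition3=partition3,
        pbs=pbs, ppt=ppt, orfs=orfs, gene_model=gene_model,
        classification=classification, motifs5=motifs5,
    )


def _partition_from_evidence(ltr_length, motifs, tss_pos, term_pos, chrom):
    if tss_pos is None:
        if motifs.tata_site is None:
            return None
        tss_pos = motifs.tata_site + TSS_OFFSET_FROM_TATA
    if term_pos is None:
        term_pos = min(tss_pos + DEFAULT_R_LENGTH - 1, ltr_length)
    if not 1 <= tss_pos <= term_pos <= ltr_length:
        return None
    return partition_ltr(ltr_length, tss_pos, term_pos, chrom=chrom,
                         polyA_site=motifs.polyA_site, tata_site=motifs.tata_site)


def predict_solo_ltr(
    element: SequenceRecord,
    annotation: ElementAnnotation,
    tsd: TSDReport | None = None,
    min_identity: float = 0.95,
) -> SequenceRecord:
    """Product of homologous recombination between the two LTR copies of a
    provirus: one LTR (the 5' copy, by convention) stays in place, the
    internal sequence and second LTR are lost, and the flanking TSD is
    untouched — the allelic change that converts a full-length insertion
    into a solo-LTR allele."""
    if annotation.classification == "solo_ltr":
        raise ValueError("element is already a solo LTR")
    repeat = annotation.terminal_repeat
    if repeat is None or annotation.classification != "full_length_provirus":
        raise ValueError("solo-LTR prediction requires a full-length provirus")
    if repeat.identity < min_identity:
        raise ValueError(
            f"LTR identity {repeat.identity:.3f} below {min_identity}; direct-repeat "
            "recombination between diverged LTRs needs manual review")
    return element.slice(repeat.five_prime.start, repeat.five_prime.end,
                         f"{element.id}_soloLTR")


# --------------------------------------------------------------------------
# dotplot and pairwise identity
# --------------------------------------------------------------------------

def dotplot(
    seq_a: SequenceRecord,
    seq_b: SequenceRecord,
    word: int = 12,
) -> list[tuple[int, int, str]]:
    """Exact word matches between two sequences, forward ('+') and
    reverse-complement ('-') orientation; coordinates are 0-based word start
    positions (x in ``seq_a``, y in ``seq_b``)."""
    if word < 4:
        raise ValueError("word size must be >= 4")
    index: dict[str, list[int]] = {}
    b = seq_b.seq
    for j in range(len(b) - word + 1):
        w = b[j:j + word]
        if "N" not in w:
            index.setdefault(w, []).append(j)
    points: list[tuple[int, int, str]] = []
    a = seq_a.seq
    for i in range(len(a) - word + 1):
        w = a[i:i + word]
        if "N" in w:
            continue
        for j in index.get(w, ()):
            points.append((i, j, "+"))
        for j in index.get(revcomp(w), ()):
            points.append((i, j, "-"))
    return points


_aligner_cache: dict[tuple[float, float, float], Align.PairwiseAligner] = {}


def _global_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    key = (match, mismatch, gap)
    if key not in _aligner_cache:
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.match_score = match
        al.mismatch_score = mismatch
        al.open_gap_score = gap
        al.extend_gap_score = gap
        _aligner_cache[key] = al
    return _aligner_cache[key]


def pairwise_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    mode: str = "global",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Percent identity between two sequences.

    ``global``: Needleman-Wunsch (unit-cost scheme by default), identity =
    matching columns / alignment columns x 100.  ``ungapped``: positionwise
    matches / length of the shorter sequence x 100.
    """
    if mode == "ungapped":
        n = min(len(a), len(b))
        m = sum(1 for x, y in zip(a.seq, b.seq) if x == y and x != "N")
        return 100.0 * m / n
    if mode != "global":
        raise ValueError("mode must be 'global' or 'ungapped'")
    aligner = _global_aligner(match, mismatch, gap)
    aln = aligner.align(a.seq, b.seq)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-" and x != "N")
    return 100.0 * matches / len(sa)
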