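"""ORF discovery and synteny-based retroviral gene labelling.

A replication-competent retroviral integrant carries gag, pro, pol and env
in that order on the element's sense strand.  Because homology searches
against external protein databases are out of scope here, genes are labelled
purely by synteny: the longest internal ORFs are ranked by start coordinate
and assigned gag -> env.  A hook accepts externally determined labels when
the caller has them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

from Bio.Seq import Seq

from .core_io import GenomicInterval, SequenceRecord, get_logger, revcomp

if TYPE_CHECKING:  # pragma: no cover
    from .anatomy import TerminalRepeat

log = get_logger("orf_annot")

GENE_ORDER = ("gag", "pro", "pol", "env")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ORFRecord:
    """One open reading frame in element coordinates.

    ``interval`` covers ATG through the stop codon inclusive (or the element
    end for ``partial`` ORFs).  ``aa_length`` counts codons excluding the
    stop; ``frame`` is the start position modulo 3 on the given strand.
    """

    interval: GenomicInterval
    strand: str
    frame: int
    aa_length: int
    protein: str
    partial: bool = False


@dataclass
class GeneModel:
    labeled_orfs: list[tuple[str, ORFRecord]]
    classification: str  # full_length_provirus | truncated | solo_ltr | ambiguous


def find_orfs(
    seq: SequenceRecord,
    min_aa: int = 100,
    strands: str = "both",
    table: int = 1,
) -> list[ORFRecord]:
    """All ATG-initiated ORFs of >= ``min_aa`` codons in the requested
    frames, longest-per-stop (the first ATG after the previous in-frame stop
    opens the reported ORF).  ORFs running off the element end are flagged
    partial.  Sorted by start coordinate."""
    out: list[ORFRecord] = []
    n = len(seq)
    strand_list = {"both": ("+", "-"), "+": ("+",), "-": ("-",)}[strands]
    for strand in strand_list:
        s = seq.seq if strand == "+" else revcomp(seq.seq)
        for frame in range(3):
            start_codon: int | None = None
            i = frame
            while i + 3 <= n:
                codon = s[i:i + 3]
                if codon in _STOPS:
                    if start_codon is not None:
                        out.extend(_make_orf(seq, s, strand, frame, start_codon,
                                             i + 3, False, min_aa, table))
                        start_codon = None
                elif codon == "ATG" and start_codon is None:
                    start_codon = i
                i += 3
            if start_codon is not None:  # ran off the end without a stop
                out.extend(_make_orf(seq, s, strand, frame, start_codon,
                                     i, True, min_aa, table))
    out.sort(key=lambda o: (o.interval.start, o.interval.end, o.strand))
    return out


def _make_orf(seq, stranded, strand, frame, start, end, partial, min_aa, table):
    aa_len = (end - start) // 3 - (0 if partial else 1)
    if aa_len < min_aa:
        return []
    nt = stranded[start:end if partial else end - 3]
    protein = str(Seq(nt).translate(table=table))
    n = len(seq)
    if strand == "+":
        iv = GenomicInterval(seq.id, start, end, "+")
    else:  # map back to forward coordinates
        iv = GenomicInterval(seq.id, n - end, n - start, "-")
    return [ORFRecord(interval=iv, strand=strand, frame=frame,
                      aa_length=aa_len, protein=protein, partial=partial)]


def label_genes(
    orfs: Sequence[ORFRecord],
    element_length: int,
    ltr: "TerminalRepeat | None",
    external_labels: Sequence[str] | None = None,
) -> GeneModel:
    """Assign gag/pro/pol/env by positional rank among the longest internal
    sense-strand ORFs.

    Internal means strictly between the two LTR copies when a terminal
    repeat is supplied.  Partial ORFs are never labelled.  Classification is
    ``full_length_provirus`` iff all four genes are assigned and both LTRs
    are present; ``solo_ltr`` iff the element is about one LTR long with no
    internal ORFs; otherwise ``truncated`` (or ``ambiguous`` when there is
    nothing to rank).
    """
    lo = ltr.five_prime.end if ltr else 0
    hi = ltr.three_prime.start if ltr else element_length
    internal = [o for o in orfs
                if o.strand == "+" and not o.partial
                and o.interval.start >= lo and o.interval.end <= hi]
    ranked = sorted(internal, key=lambda o: -o.aa_length)[:4]
    ranked.sort(key=lambda o: o.interval.start)
    if external_labels is not None:
        if len(external_labels) != len(ranked):
            raise ValueError("need one external label per labelled ORF")
        labels = list(external_labels)
    else:
        labels = list(GENE_ORDER[:len(ranked)])
    labeled = list(zip(labels, ranked))

    if ltr is not None and len(labeled) == 4:
        classification = "full_length_provirus"
    elif ltr is None and not internal and element_length <= 1200:
        classification = "solo_ltr"
    elif labeled:
        classification = "truncated"
    else:
        classification = "ambiguous"
    return GeneModel(labeled_orfs=labeled, classification=classification)
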