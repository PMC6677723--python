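"""Classification of splice junctions around an element insertion.

When a retroelement lands inside a gene, splicing is re-routed: donors from
upstream exons join acceptors inside the element (its LTR — often the U5
region — or internal sequence), or element-internal donors splice onward
into the gene.  This module labels each junction's donor and acceptor with
the innermost annotated feature (so a hit inside U5 reports "U5", not
"LTR5" or "element"), classifies the junction, and matches whole junction
chains against an enumerated transcript catalogue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .core_io import FeatureRecord, GenomicInterval, get_logger

log = get_logger("splice_class")

#: Feature kinds that belong to the inserted element.
ELEMENT_KINDS = {"LTR5", "LTR3", "U3", "R", "U5", "PBS", "PPT", "ORF", "element", "TSD"}

#: Specificity rank for breaking ties between equally small features.
_SPECIFICITY = {"U3": 0, "R": 0, "U5": 0, "PBS": 0, "PPT": 0, "TSD": 0,
                "ORF": 1, "LTR5": 2, "LTR3": 2, "exon": 2, "element": 3, "flank": 4}

MIN_INTRON = 20


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction: the intron it removes plus its read support.

    ``donor_context`` / ``acceptor_context`` are filled by
    :func:`classify_junction`; ``klass`` is one of normal,
    element_hijacked, unannotated.
    """

    intron: GenomicInterval
    strand: str
    read_count: int
    donor_context: str | None = None
    acceptor_context: str | None = None
    klass: str | None = None

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")
        if self.intron.length < MIN_INTRON:
            raise ValueError(
                f"intron {self.intron} shorter than {MIN_INTRON} bp floor")


@dataclass(frozen=True)
class TranscriptModel:
    """An enumerated transcript structure: an ordered chain of introns."""

    id: str
    junctions: tuple[GenomicInterval, ...]
    klass: str = "normal"  # normal | element_hijacked | element_exonized

    def __post_init__(self) -> None:
        ordered = all(a.end <= b.start for a, b in zip(self.junctions, self.junctions[1:]))
        if not ordered:
            raise ValueError(f"transcript {self.id}: junctions must be ordered and disjoint")

    def key(self) -> frozenset:
        return frozenset((j.start, j.end) for j in self.junctions)


# --------------------------------------------------------------------------
# junction classification
# --------------------------------------------------------------------------

def _innermost(features: Sequence[FeatureRecord], pos: int, chrom: str) -> FeatureRecord | None:
    hits = [f for f in features
            if f.interval.chrom == chrom and f.interval.contains(pos)]
    if not hits:
        return None
    return min(hits, key=lambda f: (f.interval.length, _SPECIFICITY.get(f.kind, 5)))


def classify_junction(
    j: JunctionRecord,
    features: Sequence[FeatureRecord],
    exon_pairs: set[tuple[str, str]] | None = None,
) -> JunctionRecord:
    """Assign donor/acceptor contexts and a class.

    The donor context is the innermost feature covering the exonic base just
    upstream of the intron, the acceptor context the base just downstream
    (swapped on the minus strand).  Class is ``normal`` iff both contexts
    are exons (and, when ``exon_pairs`` is given, an annotated pairing);
    ``element_hijacked`` iff either side lies in an element feature;
    otherwise ``unannotated``.
    """
    left, right = j.intron.start - 1, j.intron.end
    if j.strand == "-":
        donor_pos, acceptor_pos = right, left
    else:
        donor_pos, acceptor_pos = left, right
    donor = _innermost(features, donor_pos, j.intron.chrom)
    acceptor = _innermost(features, acceptor_pos, j.intron.chrom)
    dlab = f"{donor.kind}:{donor.label}" if donor else None
    alab = f"{acceptor.kind}:{acceptor.label}" if acceptor else None

    if donor is None and acceptor is None:
        warnings.warn(f"junction {j.intron} outside the annotated locus")
        klass = "unannotated"
    elif (donor and donor.kind in ELEMENT_KINDS) or (acceptor and acceptor.kind in ELEMENT_KINDS):
        klass = "element_hijacked"
    elif donor and acceptor and donor.kind == "exon" and acceptor.kind == "exon":
        if exon_pairs is None or (donor.label, acceptor.label) in exon_pairs:
            klass = "normal"
        else:
            klass = "unannotated"
    else:
        klass = "unannotated"
    return replace(j, donor_context=dlab, acceptor_context=alab, klass=klass)


# --------------------------------------------------------------------------
# transcript catalogue matching
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptMatch:
    model_id: str            # catalogue id or "novel"
    nearest_id: str | None   # closest model when novel
    similarity: float        # Jaccard of junction sets vs nearest/exact model


def match_transcript(
    chain: Sequence[JunctionRecord],
    catalog: Sequence[TranscriptModel],
) -> TranscriptMatch:
    """Match an observed junction chain against the transcript catalogue.

    Exact junction-set equality returns that model's id; otherwise the chain
    is ``novel`` and the nearest catalogue model by Jaccard similarity of
    junction sets is reported alongside the similarity value.
    """
    if not chain:
        raise ValueError("empty junction chain")
    if not catalog:
        raise ValueError("empty transcript catalogue")
    observed = frozenset((j.intron.start, j.intron.end) for j in chain)
    best_id, best_sim = None, -1.0
    for model in catalog:
        key = model.key()
        if key == observed:
            return TranscriptMatch(model_id=model.id, nearest_id=model.id, similarity=1.0)
        union = len(observed | key)
        sim = len(observed & key) / union if union else 0.0
        if sim > best_sim:
            best_id, best_sim = model.id, sim
    return TranscriptMatch(model_id="novel", nearest_id=best_id, similarity=best_sim)


# --------------------------------------------------------------------------
# summary table
# --------------------------------------------------------------------------

def junction_summary(junctions: Sequence[JunctionRecord]) -> pd.DataFrame:
    """Read counts per (donor_context, acceptor_context, class); total read
    count is conserved."""
    rows = [
        {
            "donor_context": j.donor_context or "none",
            "acceptor_context": j.acceptor_context or "none",
            "class": j.klass or "unclassified",
            "read_count": j.read_count,
        }
        for j in junctions
    ]
    if not rows:
        return pd.DataFrame(columns=["donor_context", "acceptor_context", "class", "read_count"])
    df = pd.DataFrame(rows)
    out = (df.groupby(["donor_context", "acceptor_context", "class"], as_index=False)
             ["read_count"].sum()
             .sort_values("read_count", ascending=False, kind="stable")
             .reset_index(drop=True))
    return out
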