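"""Read-depth genotyping of transposable-element insertions.

Presence/absence of an insertion in a strain is read off the depth of the
two empty-site flanks: a flank whose mean depth falls within the lower tail
of the genome-wide coverage distribution signals that no read spans the
junction in that strain (the site is interrupted by an insertion there).
Copy number of a repeated element is estimated from a recruitment profile
(how many genomic copies cover each element base): positions covered by few
copies define the element's low copy-number region, and the mean read depth
there divided by the genome coverage gives copies per haploid genome; its
rounded value is the working ploidy for haplotype analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import GenomicInterval, get_logger

log = get_logger("depth_cn")

__all__ = [
    "DepthTrack", "PresenceCall", "CopyNumberEstimate",
    "coverage_tail_threshold", "call_presence", "recruitment_profile",
    "low_cn_region", "estimate_copy_number", "genome_coverage",
    "word_match_hits",
]


@dataclass
class DepthTrack:
    """Per-base depth over one chromosome, with optional masked intervals
    (e.g. annotated repeats) excluded from all statistics."""

    chrom: str
    depth: np.ndarray
    mask: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if np.any(self.depth < 0):
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return len(self.depth)

    def mask_array(self) -> np.ndarray:
        m = np.zeros(len(self.depth), dtype=bool)
        for iv in self.mask:
            m[iv.start:min(iv.end, len(self.depth))] = True
        return m

    def unmasked_depths(self) -> np.ndarray:
        return self.depth[~self.mask_array()]

    def region_mean(self, region: GenomicInterval) -> float:
        if region.end > len(self.depth):
            raise ValueError(f"region {region} beyond track end {len(self.depth)}")
        sel = ~self.mask_array()[region.start:region.end]
        vals = self.depth[region.start:region.end][sel]
        if vals.size == 0:
            return math.nan
        return float(vals.mean())


@dataclass(frozen=True)
class PresenceCall:
    element_id: str
    strain_id: str
    left_side: str   # covered | tail
    right_side: str
    verdict: str     # present | absent | ambiguous


@dataclass(frozen=True)
class CopyNumberEstimate:
    region: GenomicInterval
    mean_region_depth: float
    genome_coverage: float
    copy_number: float
    ploidy: int


# --------------------------------------------------------------------------
# tail threshold and presence calling
# --------------------------------------------------------------------------

def coverage_tail_threshold(track: DepthTrack, q: float = 0.05) -> int:
    """Lower-tail depth threshold: the empirical q-quantile of unmasked
    per-base depth, nearest-rank definition (k = max(1, ceil(q*n)); q = 0
    returns the minimum).  Deletions are annotated as depths at or below
    this threshold."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    vals = np.sort(track.unmasked_depths())
    if vals.size == 0:
        raise ValueError("no unmasked positions in track")
    if vals.size < 1000:
        warnings.warn(f"only {vals.size} unmasked positions; tail threshold is noisy")
    k = max(1, math.ceil(q * vals.size))
    return int(vals[k - 1])


def call_presence(
    track: DepthTrack,
    element_flanks: tuple[GenomicInterval, GenomicInterval],
    threshold: float,
    element_id: str = "element",
    strain_id: str = "strain",
) -> PresenceCall:
    """Label each empty-site flank `tail` (mean depth <= threshold) or
    `covered`, and call the site: both tails -> absent (the empty site is
    interrupted, i.e. the strain carries the insertion); both covered ->
    present (site intact); one of each -> ambiguous.  A fully masked flank
    makes the call ambiguous with a warning."""
    left_iv, right_iv = element_flanks
    sides = []
    for iv in (left_iv, right_iv):
        mean = track.region_mean(iv)
        if math.isnan(mean):
            warnings.warn(f"flank {iv} fully masked; presence call ambiguous")
            sides.append("masked")
        else:
            sides.append("tail" if mean <= threshold else "covered")
    if "masked" in sides:
        verdict = "ambiguous"
        sides = [s if s != "masked" else "tail" for s in sides]
    elif sides == ["tail", "tail"]:
        verdict = "absent"
    elif sides == ["covered", "covered"]:
        verdict = "present"
    else:
        verdict = "ambiguous"
    return PresenceCall(element_id=element_id, strain_id=strain_id,
                        left_side=sides[0], right_side=sides[1], verdict=verdict)


# --------------------------------------------------------------------------
# recruitment profile and copy number
# --------------------------------------------------------------------------

def recruitment_profile(
    hits: Sequence[GenomicInterval],
    element_length: int,
) -> np.ndarray:
    """profile[i] = number of homologous genomic copies covering element
    position i (hits are intervals in element coordinates)."""
    profile = np.zeros(element_length, dtype=np.int64)
    for iv in hits:
        if iv.end > element_length:
            raise ValueError(f"hit {iv} outside element (length {element_length})")
        profile[iv.start:iv.end] += 1
    return profile


def low_cn_region(
    profile: np.ndarray,
    cutoff: int = 4,
    merge_gap: int = 0,
    chrom: str = "element",
) -> list[GenomicInterval]:
    """Maximal runs of positions with profile < cutoff (the element interval
    private enough for haplotype work), optionally merged across short gaps."""
    profile = np.asarray(profile)
    if profile.size == 0:
        raise ValueError("empty profile")
    low = profile < cutoff
    regions: list[list[int]] = []
    start = None
    for i, flag in enumerate(low):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            regions.append([start, i])
            start = None
    if start is not None:
        regions.append([start, len(low)])
    merged: list[list[int]] = []
    for reg in regions:
        if merged and reg[0] - merged[-1][1] <= merge_gap:
            merged[-1][1] = reg[1]
        else:
            merged.append(reg)
    return [GenomicInterval(chrom, s, e) for s, e in merged]


def genome_coverage(track: DepthTrack, trim: float = 0.05) -> float:
    """Genome-wide coverage denominator: trimmed mean (``trim`` fraction cut
    from each side) of unmasked per-base depth."""
    vals = track.unmasked_depths()
    if vals.size == 0:
        raise ValueError("no unmasked positions in track")
    return float(stats.trim_mean(vals, trim))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def estimate_copy_number(
    track: DepthTrack,
    region: GenomicInterval,
    genome_cov: float,
) -> CopyNumberEstimate:
    """Copies per haploid genome = mean depth in ``region`` / genome
    coverage; ploidy is the rounded value (half away from zero)."""
    if genome_cov <= 0:
        raise ValueError("genome coverage must be positive")
    mean_depth = track.region_mean(region)
    if math.isnan(mean_depth):
        raise ValueError(f"region {region} fully masked")
    cn = mean_depth / genome_cov
    return CopyNumberEstimate(
        region=region, mean_region_depth=mean_depth, genome_coverage=genome_cov,
        copy_number=cn, ploidy=_round_half_away(cn),
    )


# --------------------------------------------------------------------------
# exact word-match homology scanner (synthetic-genome stand-in for external
# homology search hits)
# --------------------------------------------------------------------------

def word_match_hits(
    genome_seq: str,
    element_seq: str,
    word: int = 30,
    chrom: str = "element",
) -> list[GenomicInterval]:
    """Exact-match homology hits of a genome against an element, as merged
    intervals in element coordinates.

    Consecutive word matches on the same diagonal are merged into one hit,
    so each genomic copy of (part of) the element contributes one interval.
    Intended for synthetic genomes; real analyses should supply precomputed
    homology intervals instead.
    """
    if word < 30:
        raise ValueError("word must be >= 30 to keep chance hits negligible")
    index: dict[str, list[int]] = {}
    for i in range(len(element_seq) - word + 1):
        index.setdefault(element_seq[i:i + word], []).append(i)
    # diagonal -> list of element start positions
    by_diag: dict[int, list[int]] = {}
    for g in range(len(genome_seq) - word + 1):
        for e in index.get(genome_seq[g:g + word], ()):
            by_diag.setdefault(g - e, []).append(e)
    hits: list[GenomicInterval] = []
    for diag, starts in sorted(by_diag.items()):
        starts.sort()
        run_start, prev = starts[0], starts[0]
        for s in starts[1:]:
            if s - prev <= word:
                prev = s
            else:
                hits.append(GenomicInterval(chrom, run_start, prev + word))
                run_start = prev = s
        hits.append(GenomicInterval(chrom, run_start, prev + word))
    return hits
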