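"""Distance-based phylogeny of retroelement pol regions.

The pipeline mirrors the classic desk workflow for placing an unknown
retroviral element: extract the conserved polymerase (reverse transcriptase)
regions against an anchor, compute maximum-likelihood pairwise distances
under a closed-form substitution model (JC69 or K80), build a
neighbor-joining tree, attach nonparametric bootstrap supports, and root on
a designated outgroup.

Full tree-likelihood optimisation and substitution-model selection are
deliberately not part of this module; NJ on ML distances is the reproducible
core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from Bio import Align

from .core_io import SequenceRecord, get_logger

log = get_logger("phylo")

__all__ = [
    "MsAlignment", "DistanceMatrix", "DEFAULT_POL_REGIONS", "SATURATION_CAP",
    "extract_conserved_pol", "align_center_star", "ml_distance", "nj_tree",
    "bootstrap_support", "root_tree", "random_tree", "tree_distance_matrix",
]

#: Conserved reverse-transcriptase polymerisation-domain regions, in anchor
#: (HIV-1 RT) amino-acid coordinates, 1-based inclusive.  Only the overall
#: span (residues 23-266) is established; these eight sub-intervals are
#: PROVISIONAL defaults and should be overridden with curated boundaries.
DEFAULT_POL_REGIONS: tuple[tuple[int, int], ...] = (
    (23, 43), (57, 82), (94, 118), (123, 150),
    (155, 178), (183, 210), (218, 239), (244, 266),
)

#: Distance assigned to saturated pairs (substitutions/site).
SATURATION_CAP = 5.0

_NT = set("ACGT")


@dataclass
class MsAlignment:
    """A gapped multiple sequence alignment (rows all the same length)."""

    taxa: list[str]
    seqs: list[str]
    alphabet: str = "nt"

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.seqs):
            raise ValueError("one sequence per taxon required")
        if len({len(s) for s in self.seqs}) > 1:
            raise ValueError("alignment rows differ in length")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def ncols(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def resample_columns(self, rng: np.random.Generator) -> "MsAlignment":
        cols = rng.integers(0, self.ncols, size=self.ncols)
        seqs = ["".join(s[c] for c in cols) for s in self.seqs]
        return MsAlignment(list(self.taxa), seqs, self.alphabet)

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord], alphabet: str = "nt"):
        return cls([r.id for r in records], [r.seq for r in records], alphabet)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances (substitutions/site)."""

    taxa: list[str]
    matrix: np.ndarray
    saturated: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("distances must be finite and non-negative")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])


# --------------------------------------------------------------------------
# conserved-region extraction
# --------------------------------------------------------------------------

def _simple_aligner(alphabet: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 2.0
    al.mismatch_score = -1.0
    al.open_gap_score = -5.0
    al.extend_gap_score = -1.0
    return al


def extract_conserved_pol(
    query_pol: SequenceRecord,
    anchor: SequenceRecord,
    regions: Sequence[tuple[int, int]] = DEFAULT_POL_REGIONS,
    min_coverage: float = 0.5,
) -> SequenceRecord:
    """Concatenate the query residues that align within the conserved anchor
    regions (anchor coordinates, 1-based inclusive).

    The query is globally aligned to the anchor once; for each region the
    query residues aligned to anchor positions inside it are collected.  A
    region with alignment coverage below ``min_coverage`` is skipped with a
    warning.
    """
    if query_pol.alphabet != anchor.alphabet:
        raise ValueError("query and anchor must share an alphabet")
    for first, last in regions:
        if not 1 <= first <= last <= len(anchor):
            raise ValueError(f"region {first}-{last} outside anchor (1-{len(anchor)})")
    aligner = _simple_aligner(anchor.alphabet)
    aln = aligner.align(anchor.seq, query_pol.seq)[0]
    # anchor position (0-based) -> query position, None where query is gapped
    a2q: dict[int, int] = {}
    for (a_blk, q_blk) in zip(*aln.aligned):
        for off in range(a_blk[1] - a_blk[0]):
            a2q[a_blk[0] + off] = q_blk[0] + off
    pieces: list[str] = []
    for first, last in regions:
        idx = [a2q[p] for p in range(first - 1, last) if p in a2q]
        coverage = len(idx) / (last - first + 1)
        if coverage < min_coverage:
            log.warning("region %d-%d coverage %.0f%% < %.0f%%; skipped",
                        first, last, 100 * coverage, 100 * min_coverage)
            continue
        pieces.append("".join(query_pol.seq[i] for i in idx))
    return SequenceRecord(query_pol.id, "".join(pieces) or "N",
                          query_pol.alphabet if "".join(pieces) else query_pol.alphabet)


# --------------------------------------------------------------------------
# small center-star progressive aligner (for small panels only; published
# alignments are preferred as input)
# --------------------------------------------------------------------------

def align_center_star(records: Sequence[SequenceRecord]) -> MsAlignment:
    """Center-star progressive alignment: the sequence most similar to all
    others anchors pairwise alignments that are merged column-wise
    ("once a gap, always a gap")."""
    if not records:
        raise ValueError("no sequences to align")
    if len(records) == 1:
        return MsAlignment.from_records(records, records[0].alphabet)
    from .anatomy import pairwise_identity

    n = len(records)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = pairwise_identity(records[i], records[j])
    center = int(np.argmax(sim.sum(axis=1)))
    c = records[center]
    aligner = _simple_aligner(c.alphabet)

    gapped: list[tuple[int, str, str]] = []  # (record index, gapped center, gapped other)
    for i, rec in enumerate(records):
        if i == center:
            continue
        aln = aligner.align(c.seq, rec.seq)[0]
        gapped.append((i, str(aln[0]), str(aln[1])))

    # insertion counts relative to center positions (index k = before center
    # residue k; index len(c) = after the last residue)
    ins = np.zeros(len(c) + 1, dtype=int)
    per_aln_ins: list[np.ndarray] = []
    for _, gc, _go in gapped:
        counts = np.zeros(len(c) + 1, dtype=int)
        k = 0
        for ch in gc:
            if ch == "-":
                counts[k] += 1
            else:
                k += 1
        per_aln_ins.append(counts)
        np.maximum(ins, counts, out=ins)

    def pad_center() -> str:
        out = []
        for k, ch in enumerate(c.seq):
            out.append("-" * ins[k])
            out.append(ch)
        out.append("-" * ins[len(c)])
        return "".join(out)

    rows: dict[int, str] = {center: pad_center()}
    for (i, gc, go), counts in zip(gapped, per_aln_ins):
        out = []
        k = 0          # center residue index
        buf = []       # other-row chars in the current insertion block
        for cch, och in zip(gc, go):
            if cch == "-":
                buf.append(och)
            else:
                out.append("-" * (ins[k] - counts[k]) + "".join(buf))
                buf = []
                out.append(och)
                k += 1
        out.append("-" * (ins[len(c)] - counts[len(c)]) + "".join(buf))
        rows[i] = "".join(out)

    ordered = [rows[i] for i in range(n)]
    return MsAlignment([r.id for r in records], ordered, c.alphabet)


# --------------------------------------------------------------------------
# ML pairwise distances
# --------------------------------------------------------------------------

def _jc69(p: float) -> float:
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _k80(P: float, Q: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("saturated")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def ml_distance(aln: MsAlignment, model: str = "JC69") -> DistanceMatrix:
    """Closed-form maximum-likelihood pairwise distances over ungapped
    column pairs.

    JC69: d = -(3/4) ln(1 - 4p/3); pairs with p >= 3/4 are saturated and
    capped at :data:`SATURATION_CAP` (and flagged).  K80 separates
    transition/transversion proportions.
    """
    if model not in ("JC69", "K80"):
        raise ValueError("model must be 'JC69' or 'K80'")
    n = len(aln.taxa)
    if n < 2:
        raise ValueError("need at least two taxa")
    m = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = aln.seqs[i], aln.seqs[j]
            pairs = [(x, y) for x, y in zip(si, sj) if x in _NT and y in _NT]
            if not pairs:
                raise ValueError(
                    f"no comparable columns between {aln.taxa[i]} and {aln.taxa[j]}")
            total = len(pairs)
            if model == "JC69":
                p = sum(1 for x, y in pairs if x != y) / total
                if p >= 0.75:
                    d = SATURATION_CAP
                    saturated.add((aln.taxa[i], aln.taxa[j]))
                else:
                    d = _jc69(p)
            else:
                P = sum(1 for x, y in pairs
                        if x != y and frozenset((x, y)) in _TRANSITIONS) / total
                Q = sum(1 for x, y in pairs
                        if x != y and frozenset((x, y)) not in _TRANSITIONS) / total
                try:
                    d = _k80(P, Q)
                except ValueError:
                    d = SATURATION_CAP
                    saturated.add((aln.taxa[i], aln.taxa[j]))
            m[i, j] = m[j, i] = d
    return DistanceMatrix(list(aln.taxa), m, saturated)


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------

def nj_tree(D: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining (Saitou-Nei Q criterion).

    Ties in the Q matrix are broken deterministically in favour of the
    lexicographically first active pair (by taxon input order).  Negative
    branch-length estimates are clamped to zero.  Returns an unrooted
    dendropy tree (trifurcating seed node).
    """
    taxa = D.taxa
    r = len(taxa)
    if r < 3:
        raise ValueError("need at least three taxa for a tree")
    tns = dendropy.TaxonNamespace(taxa)
    nodes: dict[int, dendropy.Node] = {
        i: dendropy.Node(taxon=tns.get_taxon(t)) for i, t in enumerate(taxa)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(r):
        for j in range(i + 1, r):
            dist[(i, j)] = float(D.matrix[i, j])

    def d(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    active = list(range(r))
    next_id = r
    while len(active) > 3:
        m = len(active)
        row_sum = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best_q, best_pair = None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - row_sum[i] - row_sum[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best_pair = q, (i, j)
        i, j = best_pair
        li = 0.5 * d(i, j) + (row_sum[i] - row_sum[j]) / (2.0 * (m - 2))
        lj = d(i, j) - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(0.0, li)
        nodes[j].edge.length = max(0.0, lj)
        for k in active:
            if k in (i, j):
                continue
            dist[(k, next_id) if k < next_id else (next_id, k)] = \
                0.5 * (d(i, k) + d(j, k) - d(i, j))
        nodes[next_id] = parent
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    center = dendropy.Node()
    for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
        length = 0.5 * (d(a, b) + d(a, c) - d(b, c))
        center.add_child(nodes[a])
        nodes[a].edge.length = max(0.0, length)

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# --------------------------------------------------------------------------
# bootstrap and rooting
# --------------------------------------------------------------------------

def _internal_bipartitions(tree: dendropy.Tree) -> dict[int, dendropy.Edge]:
    tree.encode_bipartitions()
    out: dict[int, dendropy.Edge] = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.head_node.is_leaf():
            continue
        out[edge.bipartition.split_bitmask] = edge
    return out


def bootstrap_support(
    aln: MsAlignment,
    n_reps: int,
    seed,
    model: str = "JC69",
) -> dendropy.Tree:
    """Nonparametric bootstrap: resample alignment columns with replacement,
    rebuild NJ trees, and report for each internal branch of the reference
    tree the percentage of replicates containing the same bipartition
    (stored as internal-node labels and in ``tree.bootstrap_supports``).

    Zero-length internal branches of the reference tree are collapsed first,
    so an alignment with no signal reports no internal bipartition.  Any
    display threshold (e.g. hiding supports below 70%) is a rendering
    choice, applied downstream.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ref = nj_tree(ml_distance(aln, model))
    for edge in list(ref.preorder_edge_iter()):
        if (edge.head_node is not ref.seed_node and not edge.head_node.is_leaf()
                and (edge.length or 0.0) <= 0.0):
            edge.collapse()
    ref_bips = _internal_bipartitions(ref)

    counts: dict[int, int] = {mask: 0 for mask in ref_bips}
    for _ in range(n_reps):
        rep = nj_tree(ml_distance(aln.resample_columns(rng), model))
        rep_masks = set(_internal_bipartitions(rep))
        for mask in counts:
            if mask in rep_masks:
                counts[mask] += 1

    supports: dict[int, float] = {}
    for mask, edge in ref_bips.items():
        pct = 100.0 * counts[mask] / n_reps
        supports[mask] = pct
        edge.head_node.label = f"{pct:g}"
    ref.bootstrap_supports = supports
    log.info("bootstrap: %d replicates, %d internal branches", n_reps, len(supports))
    return ref


def root_tree(tree: dendropy.Tree, outgroup_taxon: str) -> dendropy.Tree:
    """Root on the outgroup's pendant edge, at its midpoint; node labels
    (bootstrap supports) are preserved."""
    rooted = tree.clone(depth=1)
    node = rooted.find_node_with_taxon_label(outgroup_taxon)
    if node is None:
        raise ValueError(f"outgroup {outgroup_taxon!r} not among leaves")
    edge = node.edge
    half = (edge.length or 0.0) / 2.0
    rooted.reroot_at_edge(edge, length1=half, length2=half)
    rooted.is_rooted = True
    return rooted


# --------------------------------------------------------------------------
# tree utilities (random additive trees and their path-length matrices)
# --------------------------------------------------------------------------

def random_tree(
    taxa: Sequence[str],
    rng,
    min_branch: float = 0.05,
    max_branch: float = 1.0,
) -> dendropy.Tree:
    """Random unrooted binary tree over ``taxa`` with uniform branch lengths
    — a generator of additive distance structures."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if len(taxa) < 3:
        raise ValueError("need at least three taxa")
    tns = dendropy.TaxonNamespace(list(taxa))

    def blen() -> float:
        return float(rng.uniform(min_branch, max_branch))

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False
    center = tree.seed_node
    edges_pool: list[dendropy.Edge] = []
    for t in taxa[:3]:
        leaf = dendropy.Node(taxon=tns.get_taxon(t))
        center.add_child(leaf)
        leaf.edge.length = blen()
        edges_pool.append(leaf.edge)
    for t in taxa[3:]:
        edge = edges_pool[int(rng.integers(0, len(edges_pool)))]
        old_head, tail = edge.head_node, edge.tail_node
        split = dendropy.Node()
        tail.remove_child(old_head)
        tail.add_child(split)
        keep = edge.length
        split.edge.length = keep / 2.0
        split.add_child(old_head)
        old_head.edge.length = keep / 2.0
        leaf = dendropy.Node(taxon=tns.get_taxon(t))
        split.add_child(leaf)
        leaf.edge.length = blen()
        edges_pool = [n.edge for n in tree.preorder_node_iter() if n is not tree.seed_node]
    return tree


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distance matrix of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.patristic_distance(lookup[taxa[i]], lookup[taxa[j]])
    return DistanceMatrix(taxa, m)
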