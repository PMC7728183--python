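"""Marker extraction, concatenated alignments and neighbor-joining trees.

Supports the two marker strategies used for phylogenomic placement of
novel isolates: a large single-copy core-gene (SCG) panel concatenated at
the protein level, and a small multilocus (MLSA) panel of housekeeping
genes concatenated after codon-aware gap removal.  Trees are built by
neighbor joining (Saitou-Nei) on pairwise distances with bootstrap
supports from column resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from skbio import TreeNode

from . import align as ak
from .io import Proteome, SeqEntry

#: the seven housekeeping genes of the MLSA panel
MLSA_GENES = ("atpA", "dnaK", "glyA", "gyrB", "metG", "pheS", "tkt")
#: size of the single-copy core-gene panel used for phylogenomics
SCG_PANEL_SIZE = 139

GAP = "-"


# ---------------------------------------------------------------------------
# Marker sets and extraction
# ---------------------------------------------------------------------------


@dataclass
class MarkerSet:
    """Named markers, each with one or more exemplar (seed) proteins."""

    name: str
    markers: list[tuple[str, list[SeqEntry]]]

    def __post_init__(self):
        ids = [m for m, _ in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids must be unique")
        for m, seeds in self.markers:
            if not seeds:
                raise ValueError(f"marker {m!r} has no seed sequence")

    @property
    def marker_ids(self) -> list[str]:
        return [m for m, _ in self.markers]

    @classmethod
    def from_seed_entries(cls, name: str, seeds: Sequence[SeqEntry]) -> "MarkerSet":
        """One exemplar per marker; marker id = sequence id."""
        return cls(name=name, markers=[(s.id, [s]) for s in seeds])


@dataclass
class MarkerExtraction:
    """Best-matching protein per marker; absence is data, not an error."""

    found: dict[str, SeqEntry]
    missing: list[str]
    hits: dict[str, ak.AlignmentHit] = field(default_factory=dict)


def extract_markers(proteome: Proteome, marker_set: MarkerSet,
                    min_identity: float = 30.0, min_coverage: float = 0.7,
                    scoring: ak.ScoringScheme = ak.PROTEIN_SCORING
                    ) -> MarkerExtraction:
    """For each marker, the highest-scoring proteome protein whose
    alignment to a seed passes identity >= 30% and seed coverage >= 70%."""
    if len(proteome) == 0 or not marker_set.markers:
        raise ValueError("proteome and marker set must be non-empty")
    idx = ak.ProteomeKmerIndex(proteome)
    by_id = {p.id: p for p in proteome.proteins}
    found: dict[str, SeqEntry] = {}
    hits: dict[str, ak.AlignmentHit] = {}
    missing: list[str] = []
    for marker_id, seeds in marker_set.markers:
        best: ak.AlignmentHit | None = None
        seed_proteome = Proteome("seeds", tuple(seeds))
        for h in ak.search(seed_proteome, proteome, scoring, index=idx):
            if h.percent_identity < min_identity or h.query_coverage < min_coverage:
                continue
            if best is None or (
                (-h.score, -h.percent_identity, h.subject_id)
                < (-best.score, -best.percent_identity, best.subject_id)
            ):
                best = h
        if best is None:
            missing.append(marker_id)
        else:
            found[marker_id] = by_id[best.subject_id]
            hits[marker_id] = best
    return MarkerExtraction(found=found, missing=missing, hits=hits)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass
class Msa:
    """A multiple sequence alignment (equal-length gapped strings)."""

    ids: list[str]
    seqs: list[str]
    alphabet: str = "protein"

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate taxon in alignment")
        if self.seqs and len({len(s) for s in self.seqs}) != 1:
            raise ValueError("aligned sequences must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0


def align_marker(entries: Sequence[SeqEntry],
                 scoring: ak.ScoringScheme = ak.PROTEIN_SCORING) -> Msa:
    """Progressive multiple alignment on a guide tree of pairwise distances
    (biotite's progressive aligner); a single sequence is returned unchanged,
    two sequences reduce to the optimal pairwise global alignment."""
    alphabet = scoring.alphabet
    if len(entries) == 0:
        raise ValueError("no sequences to align")
    if len(entries) == 1:
        return Msa([entries[0].id], [entries[0].seq], alphabet)
    import biotite.sequence.align as bioalign

    seqs = [scoring.to_biotite_seq(e.seq) for e in entries]
    if len(entries) == 2:
        aln = bioalign.align_optimal(seqs[0], seqs[1], scoring.matrix(),
                                     gap_penalty=scoring.biotite_gap(),
                                     local=False, max_number=1)[0]
        gapped = aln.get_gapped_sequences()
    else:
        aln, _, _, _ = bioalign.align_multiple(seqs, scoring.matrix(),
                                               gap_penalty=scoring.biotite_gap())
        gapped = aln.get_gapped_sequences()
    return Msa([e.id for e in entries], [str(g) for g in gapped], alphabet)


def strip_gap_codons(msa: Msa) -> Msa:
    """Remove every codon column-triple containing a gap in any taxon.

    Reading-frame-aware gap removal for nucleotide alignments whose columns
    group into codons; the output length is a multiple of 3 and gap-free.
    """
    if msa.n_columns % 3 != 0:
        raise ValueError("alignment length is not a multiple of 3")
    keep: list[int] = []
    for c in range(0, msa.n_columns, 3):
        if not any(GAP in s[c:c + 3] for s in msa.seqs):
            keep.extend((c, c + 1, c + 2))
    new_seqs = ["".join(s[i] for i in keep) for s in msa.seqs]
    return Msa(list(msa.ids), new_seqs, msa.alphabet)


@dataclass
class ConcatenatedAlignment:
    """Multi-marker supermatrix with recorded per-marker partitions."""

    taxa: list[str]
    sequences: list[str]
    partitions: dict[str, tuple[int, int]]   # marker -> [start, stop)
    alphabet: str = "protein"

    def __post_init__(self):
        if self.sequences and len({len(s) for s in self.sequences}) != 1:
            raise ValueError("concatenated sequences must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_msa(self) -> Msa:
        return Msa(list(self.taxa), list(self.sequences), self.alphabet)


def concatenate(msas: Mapping[str, Msa], taxa_universe: Sequence[str],
                marker_order: Sequence[str] | None = None
                ) -> ConcatenatedAlignment:
    """Concatenate per-marker alignments in a fixed marker order.

    Taxa missing from a marker receive an all-gap block for that partition;
    the declared ``marker_order`` (default: sorted marker ids) makes the
    output independent of mapping order.
    """
    order = list(marker_order) if marker_order is not None else sorted(msas)
    taxa = list(taxa_universe)
    for m in order:
        extra = set(msas[m].ids) - set(taxa)
        if extra:
            raise ValueError(f"marker {m!r} contains taxa outside the universe: {sorted(extra)}")
    parts: dict[str, tuple[int, int]] = {}
    rows = {t: [] for t in taxa}
    offset = 0
    alphabet = msas[order[0]].alphabet if order else "protein"
    for m in order:
        msa = msas[m]
        width = msa.n_columns
        by_taxon = dict(zip(msa.ids, msa.seqs))
        for t in taxa:
            rows[t].append(by_taxon.get(t, GAP * width))
        parts[m] = (offset, offset + width)
        offset += width
    return ConcatenatedAlignment(taxa=taxa,
                                 sequences=["".join(rows[t]) for t in taxa],
                                 partitions=parts, alphabet=alphabet)


def write_partitions(aln: ConcatenatedAlignment, path) -> None:
    """RAxML-style partition file (1-based inclusive column ranges)."""
    kind = "WAG" if aln.alphabet == "protein" else "DNA"
    with open(path, "w") as fh:
        for m, (a, b) in aln.partitions.items():
            fh.write(f"{kind}, {m} = {a + 1}-{b}\n")


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix; ``inf`` flags saturation."""

    ids: list[str]
    values: np.ndarray


def _pair_distance(s1: str, s2: str, model: str, alphabet: str) -> float:
    """Distance between two aligned rows under pairwise deletion."""
    a = np.frombuffer(s1.encode(), dtype=np.uint8)
    b = np.frombuffer(s2.encode(), dtype=np.uint8)
    gap = ord(GAP)
    use = (a != gap) & (b != gap)
    n = int(use.sum())
    if n == 0:
        return float("inf")
    diff = a[use] != b[use]
    p = float(diff.mean())
    if model == "p-distance":
        return p
    if model == "poisson":
        return float("inf") if p >= 1.0 else -math.log(1.0 - p)
    if model == "jc69":
        if alphabet != "dna":
            raise ValueError("JC69 requires a nucleotide alignment")
        arg = 1.0 - 4.0 * p / 3.0
        return float("inf") if arg <= 0 else -0.75 * math.log(arg)
    if model == "k2p":
        if alphabet != "dna":
            raise ValueError("K2P requires a nucleotide alignment")
        purine = {ord("A"), ord("G")}
        ts = tv = 0
        aa, bb = a[use], b[use]
        for x, y in zip(aa[diff], bb[diff]):
            if ((x in purine) and (y in purine)) or ((x not in purine) and (y not in purine)):
                ts += 1
            else:
                tv += 1
        P, Q = ts / n, tv / n
        arg1 = 1.0 - 2.0 * P - Q
        arg2 = 1.0 - 2.0 * Q
        if arg1 <= 0 or arg2 <= 0:
            return float("inf")
        return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    raise ValueError(f"unknown model {model!r}")


def distance_matrix(aln: Msa | ConcatenatedAlignment,
                    model: str = "p-distance") -> DistanceMatrix:
    """Pairwise distances over an alignment, ignoring per-pair gap sites."""
    ids = aln.ids if isinstance(aln, Msa) else aln.taxa
    seqs = aln.seqs if isinstance(aln, Msa) else aln.sequences
    alphabet = aln.alphabet
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_distance(seqs[i], seqs[j], model, alphabet)
    return DistanceMatrix(ids=list(ids), values=d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix, saturation_cap: float = 10.0) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie handling.

    Agglomeration ties break on the lowest (i, j) index pair; negative
    branch estimates are clamped to zero with the deficit shifted to the
    sibling edge.  Saturated (infinite) distances are capped at
    ``saturation_cap`` before agglomeration.  Returns an unrooted tree
    (trifurcating root) as a TreeNode.
    """
    d = np.array(dm.values, dtype=float)
    n = len(dm.ids)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if not np.allclose(np.where(np.isfinite(d), d, 0),
                       np.where(np.isfinite(d.T), d.T, 0), atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = np.where(np.isinf(d), saturation_cap, d)
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        q[np.tril_indices(m)] = np.inf
        # lowest (i, j) index pair among minimal q (deterministic ties)
        qmin = q.min()
        cand = np.argwhere(q <= qmin + 1e-12)
        i, j = min(map(tuple, cand))
        dij = sub[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ni, nj_ = nodes[active[i]], nodes[active[j]]
        ni.length, nj_.length = float(li), float(lj)
        parent = TreeNode(children=[ni, nj_])
        # distances from the new node to the remaining ones
        new_d = np.zeros(len(d))
        gi, gj = active[i], active[j]
        for k in active:
            if k in (gi, gj):
                continue
            new_d[k] = max(0.0, (d[gi, k] + d[gj, k] - dij) / 2.0)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_d
        d[:-1, -1] = new_d
        nodes.append(parent)
        active = [k for k in active if k not in (gi, gj)] + [len(d) - 1]
    # terminal join of the last three nodes onto a central node
    a, b, c = active
    la = max(0.0, (d[a, b] + d[a, c] - d[b, c]) / 2.0)
    lb = max(0.0, (d[a, b] + d[b, c] - d[a, c]) / 2.0)
    lc = max(0.0, (d[a, c] + d[b, c] - d[a, b]) / 2.0)
    for k, l in zip((a, b, c), (la, lb, lc)):
        nodes[k].length = float(l)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap
# ---------------------------------------------------------------------------


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each encoded as the
    side not containing the lexicographically first taxon."""
    taxa = sorted(t.name for t in tree.tips())
    ref = taxa[0]
    full = frozenset(taxa)
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        side = below if ref not in below else full - below
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(side)
    return out


def same_topology(t1: TreeNode, t2: TreeNode) -> bool:
    """True when two unrooted trees share all non-trivial bipartitions."""
    return bipartitions(t1) == bipartitions(t2)


def bootstrap_support(aln: Msa | ConcatenatedAlignment, n_replicates: int,
                      seed: int, model: str = "p-distance",
                      tree_builder: Callable[[DistanceMatrix], TreeNode] = nj_tree
                      ) -> tuple[TreeNode, dict[frozenset, float]]:
    """Column-resampling bootstrap supports on the point-estimate NJ tree.

    Returns the point tree with internal node names set to the support
    percentage (2 decimals) and the bipartition -> support mapping.
    """
    ids = aln.ids if isinstance(aln, Msa) else aln.taxa
    seqs = aln.seqs if isinstance(aln, Msa) else aln.sequences
    if len(ids) < 4:
        raise ValueError("bootstrap needs >= 4 taxa")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    point = tree_builder(distance_matrix(
        Msa(list(ids), list(seqs), aln.alphabet), model))
    target = bipartitions(point)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    ncol = len(seqs[0])
    mat = np.array([list(s) for s in seqs])
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        res = ["".join(row) for row in mat[:, cols]]
        rep_tree = tree_builder(distance_matrix(
            Msa(list(ids), res, aln.alphabet), model))
        rep_bp = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bp:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    # annotate the point tree
    taxa = sorted(ids)
    ref, full = taxa[0], frozenset(taxa)
    for node in point.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        side = below if ref not in below else full - below
        if side in supports:
            node.name = f"{supports[side]:.2f}"
    return point, supports


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
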