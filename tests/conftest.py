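"""Shared fixtures and independent oracles for the test suite.

The Smith-Waterman oracle below is a plain quadratic-space Gotoh DP kept
deliberately separate from the package's alignment engine; tests compare
engine scores against it.
"""

from __future__ import annotations

import numpy as np
import pytest

from gbtax.synthetic import PairSpec, evolve_pair, evolve_markers_on_tree


# ---------------------------------------------------------------------------
# Independent affine-gap Smith-Waterman oracle (BLAST gap convention:
# a gap of length L costs open + L * extend)
# ---------------------------------------------------------------------------

def sw_oracle_score(a: str, b: str, score_fn, gap_open: int, gap_extend: int) -> int:
    n, m = len(a), len(b)
    NEG = -10 ** 9
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    go = gap_open + gap_extend
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - gap_extend)
            H[i][j] = max(0, E[i][j], F[i][j],
                          H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1]))
            best = max(best, H[i][j])
    return int(best)


def blosum62_score_fn():
    import biotite.sequence as bioseq
    import biotite.sequence.align as bioalign

    mat = bioalign.SubstitutionMatrix.std_protein_matrix()
    alph = mat.get_alphabet1()

    def fn(x, y):
        return int(mat.get_score(
            bioseq.ProteinSequence(x)[0], bioseq.ProteinSequence(y)[0]))

    # faster: direct matrix lookup via alphabet encoding
    arr = mat.score_matrix()

    def fast(x, y):
        return int(arr[alph.encode(x), alph.encode(y)])

    return fast


# ---------------------------------------------------------------------------
# Hamming identity oracle over a recorded ortholog map
# ---------------------------------------------------------------------------

def hamming_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def mean_ortholog_identity(bundle_a, bundle_b, truth) -> float:
    pa = {p.id: p.seq for p in bundle_a.proteome.proteins}
    pb = {p.id: p.seq for p in bundle_b.proteome.proteins}
    return float(np.mean([hamming_identity(pa[x], pb[y])
                          for x, y in truth.ortholog_map]))


# ---------------------------------------------------------------------------
# Random additive trees (path-length metric oracle for NJ)
# ---------------------------------------------------------------------------

def random_additive_tree(n_taxa, rng):
    """Random binary tree with strictly positive branch lengths and its
    path-length (additive) distance matrix."""
    import itertools as it

    from skbio import TreeNode

    from gbtax.phylo import DistanceMatrix

    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        parent = TreeNode(children=[b, a])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    for x in nodes:
        x.length = float(rng.uniform(0.05, 1.0))
    tree = TreeNode(children=nodes)
    tips = sorted(t.name for t in tree.tips())
    td = tree.tip_tip_distances()
    mat = np.zeros((len(tips), len(tips)))
    for x, y in it.combinations(range(len(tips)), 2):
        mat[x, y] = mat[y, x] = td[tips[x], tips[y]]
    return tree, DistanceMatrix(tips, mat)


# ---------------------------------------------------------------------------
# Session fixtures (reused across modules to keep the suite fast)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def pair_mid():
    """Medium pair: 120 genes, 60% shared, planted 0.8/0.8 identity."""
    spec = PairSpec(n_genes=120, gene_length_mean=150, shared_fraction=0.6,
                    target_protein_identity=0.8, target_nucleotide_identity=0.8,
                    seed=42)
    return evolve_pair(spec)


@pytest.fixture(scope="session")
def quartet_markers():
    """20 markers evolved on an unambiguous 4-taxon tree."""
    nwk = "((T1:0.05,T2:0.05):0.30,(T3:0.06,T4:0.04):0.30);"
    return evolve_markers_on_tree(nwk, marker_count=20, seed=7)
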