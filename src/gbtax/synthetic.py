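"""Synthetic genomes, proteomes and marker sets with planted divergence.

Every downstream stage is tested against ground truth produced here: pairs
of proteomes with a planted mean amino-acid identity among orthologs and a
planted shared-gene fraction, nucleotide genomes with planted identity, and
marker genes evolved along a known tree.

Mutation accounting
-------------------
To plant a pairwise identity ``p`` between two lineages descending from a
common ancestor, each lineage substitutes sites independently at rate ``q``
under a uniform replacement model over an alphabet of size ``A``.  Two
descendant sites then agree with probability ``(1-q)^2 + q^2/(A-1)``;
inverting for ``q``:

    q = (A-1)/A * (1 - sqrt(1 - A*(1-p)/(A-1)))

valid for ``p > 1/A`` (the random-agreement floor).  Protein identity uses
A = 20, nucleotide identity A = 4.

Non-orthologous genes are drawn from the same length distribution but with
independent random composition, so they fail any sensible reciprocal-best-
hit cutoff.  Codon choice is uniform over synonymous codons; genome-level
nucleotide identity is planted directly on the genome sequence (not via
back-translation), because the whole-genome indices (ANI, dDDH) read only
that view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from skbio import TreeNode

from .io import GeneSet, GenomeRecord, Proteome, SeqEntry, translate_cds

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

_TABLE = unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)
_STOP_CODONS = sorted(_TABLE.stop_codons)


class ParameterError(ValueError):
    """Invalid simulation parameters."""


def two_lineage_rate(target_identity: float, alphabet_size: int) -> float:
    """Per-lineage substitution probability planting a pairwise identity.

    Solves ``(1-q)^2 + q^2/(A-1) = p`` for ``q`` (see module docstring).
    """
    p, a = target_identity, alphabet_size
    if not (0.0 < p <= 1.0):
        raise ParameterError("target identity must be in (0, 1]")
    floor = 1.0 / a
    if p <= floor:
        raise ParameterError(
            f"target identity {p} is at or below the random floor {floor}")
    disc = 1.0 - a * (1.0 - p) / (a - 1.0)
    return (a - 1.0) / a * (1.0 - math.sqrt(disc))


@dataclass(frozen=True)
class PairSpec:
    """Parameters of one synthetic genome pair."""

    n_genes: int = 300
    gene_length_mean: int = 220          # amino acids
    shared_fraction: float = 1.0
    target_protein_identity: float = 0.7
    target_nucleotide_identity: float = 0.8
    indel_rate: float = 0.0              # events per aa site per lineage
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if self.gene_length_mean < 30:
            raise ParameterError("gene_length_mean must be >= 30")
        for name in ("shared_fraction", "target_protein_identity",
                     "target_nucleotide_identity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.target_protein_identity == 0 or self.target_nucleotide_identity == 0:
            raise ParameterError("target identities must be > 0")
        if self.indel_rate < 0:
            raise ParameterError("indel_rate must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generators."""

    expected_mean_ortholog_identity: float
    expected_shared_fraction: float
    ortholog_map: list[tuple[str, str]] = field(default_factory=list)
    tree: TreeNode | None = None


@dataclass(frozen=True)
class GenomeBundle:
    """The three sequence views of one synthetic organism."""

    genome: GenomeRecord
    proteome: Proteome
    genes: GeneSet


# ---------------------------------------------------------------------------
# Ancestor
# ---------------------------------------------------------------------------


def _gene_lengths(rng: np.random.Generator, n: int, mean: int) -> np.ndarray:
    lengths = rng.normal(mean, 0.2 * mean, size=n)
    return np.maximum(30, np.round(lengths)).astype(int)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def _backtranslate(rng: np.random.Generator, protein: str) -> str:
    codons = [_CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein]
    codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def generate_ancestor(n_genes: int, gene_length_mean: int, seed: int,
                      genome_id: str = "ancestor") -> GenomeBundle:
    """Random ancestral organism: proteins, CDSs, and a one-contig genome.

    Every protein is the standard-code translation of its CDS; CDS lengths
    are ``3 * (protein length + 1)`` (terminal stop codon included).  The
    genome is the CDS concatenation interleaved with short random intergenic
    spacers.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    if gene_length_mean < 30:
        raise ParameterError("gene_length_mean must be >= 30")
    rng = np.random.default_rng(seed)
    lengths = _gene_lengths(rng, n_genes, gene_length_mean)
    width = len(str(n_genes))
    proteins, genes, genome_parts = [], [], []
    for i, L in enumerate(lengths):
        gid = f"{genome_id}_g{i + 1:0{width}d}"
        prot = _random_protein(rng, int(L))
        cds = _backtranslate(rng, prot)
        proteins.append(SeqEntry(gid, prot))
        genes.append(SeqEntry(gid, cds))
        spacer = "".join(rng.choice(list(_NT), size=int(rng.integers(20, 120))))
        genome_parts.append(cds)
        genome_parts.append(spacer)
    genome = GenomeRecord(genome_id,
                          (SeqEntry(f"{genome_id}_contig1", "".join(genome_parts)),))
    return GenomeBundle(genome=genome,
                        proteome=Proteome(genome_id, tuple(proteins)),
                        genes=GeneSet(genome_id, tuple(genes)))


# ---------------------------------------------------------------------------
# Pair evolution
# ---------------------------------------------------------------------------


_AA_ARR = np.array(list(_AA))
_AA_IDX = {a: i for i, a in enumerate(_AA)}


def _substitute(rng: np.random.Generator, seq: str, mask: np.ndarray,
                alphabet: np.ndarray, index: dict[str, int]) -> str:
    """Replace masked sites by a uniform draw over the other letters
    (implemented as a nonzero cyclic offset, which is uniform over the
    alternatives)."""
    codes = np.array([index[c] for c in seq], dtype=np.int64)
    a = len(alphabet)
    k = int(mask.sum())
    if k:
        codes[mask] = (codes[mask] + rng.integers(1, a, size=k)) % a
    return "".join(alphabet[codes])


def _mutate_protein(rng: np.random.Generator, protein: str, q: float,
                    indel_rate: float) -> tuple[str, np.ndarray]:
    """Substitute sites at rate q (uniform over the 19 alternatives), then
    apply single-residue indels at ``indel_rate`` events/site.

    Returns the mutated protein and the boolean substitution mask (before
    indels), used to keep unchanged codons identical in the CDS.
    """
    mask = rng.random(len(protein)) < q
    out = _substitute(rng, protein, mask, _AA_ARR, _AA_IDX)
    n_events = 0
    if indel_rate > 0:
        n_events = rng.poisson(indel_rate * len(out))
        for _ in range(n_events):
            pos = int(rng.integers(max(len(out), 1)))
            if rng.random() < 0.5 and len(out) > 30:
                out = out[:pos] + out[pos + 1:]
            else:
                out = out[:pos] + _AA[rng.integers(20)] + out[pos:]
    return out, mask, n_events


def _lineage_cds(rng: np.random.Generator, ancestor_cds: str, mutated: str,
                 mask: np.ndarray, had_indels: bool) -> str:
    """CDS of a mutated protein: unchanged positions keep the ancestral
    codon, substituted positions get a random synonymous codon of the new
    residue.  After indels the correspondence is lost and the protein is
    back-translated afresh."""
    if had_indels:
        return _backtranslate(rng, mutated)
    codons = [ancestor_cds[3 * i:3 * i + 3] for i in range(len(mask))]
    for i in np.nonzero(mask)[0]:
        aa = mutated[i]
        codons[i] = _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))]
    return "".join(codons) + ancestor_cds[-3:]


_NT_ARR = np.array(list(_NT))
_NT_IDX = {c: i for i, c in enumerate(_NT)}


def _mutate_dna(rng: np.random.Generator, seq: str, q: float) -> str:
    mask = rng.random(len(seq)) < q
    return _substitute(rng, seq, mask, _NT_ARR, _NT_IDX)


def evolve_pair(spec: PairSpec) -> tuple[GenomeBundle, GenomeBundle, PlantedTruth]:
    """Two organisms diverged from a common ancestor per ``spec``.

    The first ``round(shared_fraction * n_genes)`` ancestral genes are
    orthologous between the lineages (recorded in the truth map); the
    remainder are replaced by lineage-unique random genes.  Genome
    sequences are mutated directly at the nucleotide level to plant
    ``target_nucleotide_identity``.
    """
    rng = np.random.default_rng(spec.seed)
    anc = generate_ancestor(spec.n_genes, spec.gene_length_mean,
                            seed=int(rng.integers(2 ** 31)), genome_id="anc")
    n_shared = round(spec.shared_fraction * spec.n_genes)
    q_p = two_lineage_rate(spec.target_protein_identity, 20)
    q_n = two_lineage_rate(spec.target_nucleotide_identity, 4)
    width = len(str(spec.n_genes))
    bundles = []
    for label in ("A", "B"):
        proteins, genes = [], []
        for i in range(spec.n_genes):
            gid = f"{label}_g{i + 1:0{width}d}"
            if i < n_shared:
                mutated, mask, n_indels = _mutate_protein(
                    rng, anc.proteome.proteins[i].seq, q_p, spec.indel_rate)
                cds = _lineage_cds(rng, anc.genes.genes[i].seq, mutated, mask,
                                   had_indels=n_indels > 0)
            else:
                length = int(_gene_lengths(rng, 1, spec.gene_length_mean)[0])
                mutated = _random_protein(rng, length)
                cds = _backtranslate(rng, mutated)
            proteins.append(SeqEntry(gid, mutated))
            genes.append(SeqEntry(gid, cds))
        genome_seq = _mutate_dna(rng, anc.genome.contigs[0].seq, q_n)
        genome = GenomeRecord(label, (SeqEntry(f"{label}_contig1", genome_seq),))
        bundles.append(GenomeBundle(genome=genome,
                                    proteome=Proteome(label, tuple(proteins)),
                                    genes=GeneSet(label, tuple(genes))))
    truth = PlantedTruth(
        expected_mean_ortholog_identity=spec.target_protein_identity,
        expected_shared_fraction=n_shared / spec.n_genes,
        ortholog_map=[(f"A_g{i + 1:0{width}d}", f"B_g{i + 1:0{width}d}")
                      for i in range(n_shared)],
    )
    return bundles[0], bundles[1], truth


# ---------------------------------------------------------------------------
# Marker evolution on a tree
# ---------------------------------------------------------------------------


@dataclass
class MarkerEvolution:
    """Markers evolved along a known tree."""

    taxa_markers: dict[str, Proteome]          # taxon -> markers (ids shared)
    seed_markers: list[SeqEntry]               # root-state exemplars
    truth: PlantedTruth


def _p_substituted(branch_length: float) -> float:
    """Probability a protein site differs from its parent after ``t``
    expected substitutions/site under uniform replacement (A=20)."""
    return (19.0 / 20.0) * (1.0 - math.exp(-20.0 / 19.0 * branch_length))


def evolve_markers_on_tree(tree_spec: str | TreeNode, marker_count: int,
                           seed: int, marker_length_mean: int = 180
                           ) -> MarkerEvolution:
    """Evolve ``marker_count`` protein markers independently along a tree.

    ``tree_spec`` is a Newick string (or TreeNode) with branch lengths in
    expected substitutions/site.  Marker sequences are substitution-only, so
    the per-taxon sets are concatenation-ready without realignment.
    """
    tree = (TreeNode.read([tree_spec]) if isinstance(tree_spec, str)
            else tree_spec.copy())
    leaves = [t.name for t in tree.tips()]
    if len(leaves) < 4:
        raise ParameterError("tree must have at least 4 leaves")
    if len(set(leaves)) != len(leaves):
        raise ParameterError("leaf labels must be unique")
    if marker_count < 1:
        raise ParameterError("marker_count must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = _gene_lengths(rng, marker_count, marker_length_mean)
    width = len(str(marker_count))
    marker_ids = [f"m{i + 1:0{width}d}" for i in range(marker_count)]
    taxa_seqs: dict[str, list[SeqEntry]] = {t: [] for t in leaves}
    seeds: list[SeqEntry] = []
    for mid, L in zip(marker_ids, lengths):
        root_seq = _random_protein(rng, int(L))
        seeds.append(SeqEntry(mid, root_seq))
        # pre-order walk carrying parent state
        states = {id(tree): root_seq}
        for node in tree.preorder(include_self=False):
            parent_state = states[id(node.parent)]
            t = node.length or 0.0
            p = _p_substituted(t)
            mask = rng.random(len(parent_state)) < p
            state = _substitute(rng, parent_state, mask, _AA_ARR, _AA_IDX)
            states[id(node)] = state
            if node.is_tip():
                taxa_seqs[node.name].append(SeqEntry(mid, state))
    taxa_markers = {t: Proteome(t, tuple(s)) for t, s in taxa_seqs.items()}
    truth = PlantedTruth(expected_mean_ortholog_identity=float("nan"),
                         expected_shared_fraction=1.0, tree=tree)
    return MarkerEvolution(taxa_markers=taxa_markers, seed_markers=seeds,
                           truth=truth)


def write_truth_tsv(truth: PlantedTruth, path) -> None:
    """Truth table: geneA, geneB, planted_identity."""
    from .io import write_tsv

    rows = [{"geneA": a, "geneB": b,
             "planted_identity": truth.expected_mean_ortholog_identity}
            for a, b in truth.ortholog_map]
    write_tsv(rows, path, columns=["geneA", "geneB", "planted_identity"])


def verify_translation(bundle: GenomeBundle) -> bool:
    """True when every protein equals the translation of its CDS."""
    cds_by_id = {g.id: g.seq for g in bundle.genes.genes}
    return all(translate_cds(cds_by_id[p.id]) == p.seq
               for p in bundle.proteome.proteins)
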