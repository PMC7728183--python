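"""Local-alignment and best-hit machinery underlying every relatedness index.

Protein searches run exact affine-gap Smith-Waterman (biotite's C kernel) on
candidate pairs nominated by a shared-k-mer prefilter (k=4).  Nucleotide
genome fragments are mapped by 6-mer diagonal voting followed by an exact
gapless sliding scan with a placement-significance floor; plain local
alignment is deliberately avoided there because at low identity (<~60%) a
positive-score-only local alignment collapses onto short high-identity
islands and overstates fragment identity, while free-end edit-distance
alignment inflates it through gap abuse.

Scoring conventions
-------------------
Gap costs follow the BLAST convention: a gap of length L costs
``gap_open + L * gap_extend``.  Protein default BLOSUM62 / 11,1; nucleotide
default match +2, mismatch -3, gap 5,2.  Identity is matches over aligned
columns, gap columns included.  Ties everywhere break by
(score desc, identity desc, subject_id asc).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp
from typing import Sequence

import numpy as np
import biotite.sequence as bioseq
import biotite.sequence.align as bioalign

from .io import Proteome, SeqEntry

# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

_PROTEIN_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_CODE = {a: i for i, a in enumerate(_PROTEIN_ORDER)}
_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

_BLOSUM62 = bioalign.SubstitutionMatrix.std_protein_matrix()

_NT_ALPH = bioseq.NucleotideSequence.alphabet_unamb


def _nt_matrix(match: int = 2, mismatch: int = -3) -> bioalign.SubstitutionMatrix:
    m = np.full((4, 4), mismatch, dtype=np.int32)
    np.fill_diagonal(m, match)
    return bioalign.SubstitutionMatrix(_NT_ALPH, _NT_ALPH, m)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (BLAST convention)."""

    alphabet: str = "protein"  # "protein" | "dna"
    gap_open: int = 11
    gap_extend: int = 1
    match: int = 2       # used for dna only
    mismatch: int = -3   # used for dna only
    # Karlin-Altschul parameters for the e-value approximation (gapped
    # BLOSUM62 11/1 defaults); only load-bearing for the POCP criterion.
    ka_lambda: float = 0.267
    ka_k: float = 0.041

    def matrix(self) -> bioalign.SubstitutionMatrix:
        if self.alphabet == "protein":
            return _BLOSUM62
        if self.alphabet == "dna":
            return _nt_matrix(self.match, self.mismatch)
        raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def biotite_gap(self) -> tuple[int, int]:
        # biotite charges open + (L-1)*extend; BLAST charges open + L*extend
        return (-(self.gap_open + self.gap_extend), -self.gap_extend)

    def to_biotite_seq(self, s: str):
        if self.alphabet == "protein":
            return bioseq.ProteinSequence(s)
        return bioseq.NucleotideSequence(s)


PROTEIN_SCORING = ScoringScheme()
DNA_SCORING = ScoringScheme(alphabet="dna", gap_open=5, gap_extend=2)


def karlin_altschul_evalue(score: float, query_len: int, db_len: int,
                           scoring: ScoringScheme = PROTEIN_SCORING) -> float:
    """Karlin-Altschul-style expectation value, E = K m n exp(-lambda S)."""
    return scoring.ka_k * query_len * db_len * exp(-scoring.ka_lambda * score)


# ---------------------------------------------------------------------------
# Hits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between two sequences."""

    query_id: str
    subject_id: str
    percent_identity: float      # matches / aligned columns * 100
    aligned_length: int          # columns, gap columns included
    query_coverage: float        # aligned query span / query length
    subject_coverage: float
    score: float
    evalue: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity out of range")
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")


@dataclass(frozen=True)
class RBHPair:
    """A reciprocal-best-hit gene pair with both directed hits."""

    gene_a: str
    gene_b: str
    hit_ab: AlignmentHit
    hit_ba: AlignmentHit


def local_align(seq_a: str, seq_b: str,
                scoring: ScoringScheme = PROTEIN_SCORING,
                query_id: str = "query", subject_id: str = "subject",
                with_evalue: bool = False,
                db_len: int | None = None) -> AlignmentHit | None:
    """Optimal affine-gap local alignment; ``None`` when no positive score.

    Raises ``ValueError`` for empty sequences or characters outside the
    declared alphabet.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    try:
        a = scoring.to_biotite_seq(seq_a)
        b = scoring.to_biotite_seq(seq_b)
    except Exception as err:
        raise ValueError(f"sequence incompatible with {scoring.alphabet} alphabet: {err}")
    alns = bioalign.align_optimal(a, b, scoring.matrix(),
                                  gap_penalty=scoring.biotite_gap(),
                                  local=True, max_number=1)
    aln = alns[0]
    if aln.score <= 0 or len(aln.trace) == 0:
        return None
    ident = bioalign.get_sequence_identity(aln, mode="all")
    tr = aln.trace
    qa = tr[:, 0][tr[:, 0] >= 0]
    sa = tr[:, 1][tr[:, 1] >= 0]
    qcov = (qa.max() - qa.min() + 1) / len(seq_a)
    scov = (sa.max() - sa.min() + 1) / len(seq_b)
    ev = None
    if with_evalue:
        ev = karlin_altschul_evalue(aln.score, len(seq_a),
                                    db_len if db_len is not None else len(seq_b),
                                    scoring)
    return AlignmentHit(query_id=query_id, subject_id=subject_id,
                        percent_identity=100.0 * ident,
                        aligned_length=len(tr),
                        query_coverage=float(qcov), subject_coverage=float(scov),
                        score=float(aln.score), evalue=ev)


# ---------------------------------------------------------------------------
# Protein k-mer prefilter + search
# ---------------------------------------------------------------------------


def _encode_protein(seq: str) -> np.ndarray:
    return np.array([_AA_CODE.get(c, -1) for c in seq], dtype=np.int64)


def _protein_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(kmer code, start position) for every window free of non-standard aa."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    mult = 20 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    km = (win * mult).sum(axis=1)
    pos = np.arange(n)
    return km[valid], pos[valid]


class ProteomeKmerIndex:
    """Sorted-array index of all protein k-mers of a proteome."""

    def __init__(self, proteome: Proteome, k: int = 4):
        self.k = k
        self.ids = [p.id for p in proteome.proteins]
        self.lengths = np.array([len(p.seq) for p in proteome.proteins])
        kms, genes = [], []
        for gi, p in enumerate(proteome.proteins):
            km, _ = _protein_kmers(_encode_protein(p.seq), k)
            kms.append(km)
            genes.append(np.full(len(km), gi, dtype=np.int64))
        self._kmers = np.concatenate(kms) if kms else np.empty(0, dtype=np.int64)
        self._genes = np.concatenate(genes) if genes else np.empty(0, dtype=np.int64)
        order = np.argsort(self._kmers, kind="stable")
        self._kmers = self._kmers[order]
        self._genes = self._genes[order]

    def candidate_counts(self, query_seq: str) -> np.ndarray:
        """Shared-k-mer occurrence count against every subject gene."""
        km, _ = _protein_kmers(_encode_protein(query_seq), self.k)
        counts = np.zeros(len(self.ids), dtype=np.int64)
        if len(km) == 0 or len(self._kmers) == 0:
            return counts
        km = np.unique(km)
        lo = np.searchsorted(self._kmers, km, side="left")
        hi = np.searchsorted(self._kmers, km, side="right")
        cnt = hi - lo
        sel = cnt > 0
        if not sel.any():
            return counts
        lo, cnt = lo[sel], cnt[sel]
        total = int(cnt.sum())
        offs = np.repeat(np.cumsum(cnt) - cnt, cnt)
        idx = np.arange(total) - offs + np.repeat(lo, cnt)
        np.add.at(counts, self._genes[idx], 1)
        return counts


def search(query_proteome: Proteome, subject_proteome: Proteome,
           scoring: ScoringScheme = PROTEIN_SCORING,
           k: int = 4, min_kmer_matches: int = 1, max_candidates: int = 5,
           min_score: float = 0.0,
           with_evalue: bool = False,
           index: ProteomeKmerIndex | None = None) -> list[AlignmentHit]:
    """Best subject hit per query (queries with no candidate are omitted).

    The prefilter nominates the ``max_candidates`` subjects sharing the most
    k-mers with the query (at least ``min_kmer_matches``); each nominee is
    aligned by exact Smith-Waterman.  Candidate nomination and the final
    choice are invariant to the order of genes in either proteome.
    """
    if len(query_proteome) == 0 or len(subject_proteome) == 0:
        raise ValueError("proteomes must be non-empty")
    idx = index if index is not None else ProteomeKmerIndex(subject_proteome, k=k)
    db_len = sum(len(p.seq) for p in subject_proteome.proteins)
    hits: list[AlignmentHit] = []
    for q in query_proteome.proteins:
        counts = idx.candidate_counts(q.seq)
        cand = np.nonzero(counts >= min_kmer_matches)[0]
        if len(cand) == 0:
            continue
        # order-invariant nomination: by count desc, then subject id asc
        cand = sorted(cand, key=lambda g: (-counts[g], idx.ids[g]))[:max_candidates]
        best: AlignmentHit | None = None
        for gi in cand:
            s = subject_proteome.proteins[gi]
            hit = local_align(q.seq, s.seq, scoring, query_id=q.id,
                              subject_id=s.id, with_evalue=with_evalue,
                              db_len=db_len)
            if hit is None or hit.score <= min_score:
                continue
            if best is None or (
                (-hit.score, -hit.percent_identity, hit.subject_id)
                < (-best.score, -best.percent_identity, best.subject_id)
            ):
                best = hit
        if best is not None:
            hits.append(best)
    return hits


def reciprocal_best_hits(hits_ab: Sequence[AlignmentHit],
                         hits_ba: Sequence[AlignmentHit]) -> list[RBHPair]:
    """Mutually-best pairs; each gene occurs in at most one pair."""
    best_ab = {h.query_id: h for h in hits_ab}
    best_ba = {h.query_id: h for h in hits_ba}
    pairs = []
    for a, hab in best_ab.items():
        b = hab.subject_id
        hba = best_ba.get(b)
        if hba is not None and hba.subject_id == a:
            pairs.append(RBHPair(gene_a=a, gene_b=b, hit_ab=hab, hit_ba=hba))
    pairs.sort(key=lambda p: p.gene_a)
    return pairs


# ---------------------------------------------------------------------------
# Nucleotide fragment mapping (ANI / dDDH substrate)
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode_dna(seq: str) -> np.ndarray:
    out = np.full(len(seq), 4, dtype=np.int64)
    for c, v in _NT_CODE.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(c)] = v
    return out


def _dna_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    mult = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    km = (win * mult).sum(axis=1)
    return km[valid], np.arange(n)[valid]


@dataclass(frozen=True)
class FragmentHit:
    """Placement of one genome fragment on a subject genome."""

    identity: float          # matches / aligned columns, fraction
    aligned_columns: int
    coverage: float          # aligned query fraction (query-global: 1.0)
    matches: int
    strand: str              # "+" | "-"
    subject_start: int


class GenomeMapper:
    """Maps query fragments onto one subject genome.

    Seeds with 6-mers on both strands (short enough that a fragment at 50%
    identity still yields ~16 conserved seeds, >5 sd above the per-bucket
    background), votes on diagonal buckets, evaluates
    the top buckets by an exact gapless sliding scan, then refines the best
    placement with a banded query-global affine alignment so that small
    indels are absorbed without letting free end-gaps inflate identity.
    """

    SPACER = 1100  # N-run between contigs, longer than any fragment

    def __init__(self, contigs: Sequence[str], k: int = 6, bucket: int = 16):
        self.k = k
        self.bucket = bucket
        joined = ("N" * self.SPACER).join(c.upper() for c in contigs)
        self.strands = {"+": joined, "-": revcomp(joined)}
        self._codes = {s: _encode_dna(t) for s, t in self.strands.items()}
        self._index = {}
        nk = 4 ** k
        for s, codes in self._codes.items():
            km, pos = _dna_kmers(codes, k)
            order = np.argsort(km, kind="stable")
            km_sorted = km[order]
            starts = np.searchsorted(km_sorted, np.arange(nk + 1))
            self._index[s] = (starts, pos[order])

    # -- seeding -----------------------------------------------------------

    def _candidate_buckets(self, qkm: np.ndarray, qpos: np.ndarray, strand: str,
                           qlen: int, top: int) -> list[int]:
        starts, pos_sorted = self._index[strand]
        cnt = starts[qkm + 1] - starts[qkm]
        total = int(cnt.sum())
        if total == 0:
            return []
        offs = np.repeat(np.cumsum(cnt) - cnt, cnt)
        idx = np.arange(total) - offs + np.repeat(starts[qkm], cnt)
        spos = pos_sorted[idx]
        diag = spos - np.repeat(qpos, cnt) + qlen  # shift >= -qlen
        b = diag // self.bucket
        nb = (len(self._codes[strand]) + qlen) // self.bucket + 2
        votes = np.bincount(b, minlength=nb)
        votes = votes + np.concatenate([votes[1:], [0]])  # smear over boundary
        order = np.lexsort((np.arange(nb), -votes))
        out = []
        for bi in order[:top]:
            if votes[bi] < 2:
                break
            out.append(int(bi))
        return out

    def _gapless_best(self, qcodes: np.ndarray, strand: str,
                      buckets: list[int]) -> tuple[int, int] | None:
        """Best (matches, shift) over all shifts covered by the buckets."""
        tcodes = self._codes[strand]
        qlen = len(qcodes)
        best = None
        for bi in buckets:
            base = bi * self.bucket - qlen
            for s in range(base, base + 2 * self.bucket):
                if s < 0 or s + qlen > len(tcodes):
                    continue
                m = int(np.count_nonzero(qcodes == tcodes[s:s + qlen]))
                if best is None or m > best[0] or (m == best[0] and s < best[1]):
                    best = (m, s)
        return best

    # -- public ------------------------------------------------------------

    def map_fragment(self, fragment: str, top_buckets: int = 80,
                     min_identity: float = 0.35) -> FragmentHit | None:
        """Place one fragment; ``None`` when no placement is significant.

        The reported identity is the exact gapless maximum over the
        evaluated diagonals (substitution divergence is the model the
        synthetic genomes plant; indel divergence degrades the reported
        identity like any gapless estimator).  ``min_identity`` is the
        placement-significance floor: the best spurious placement of an
        unrelated fragment reaches ~0.30 identity (the best of ~10^3
        evaluated shifts over a 0.25 background), so placements below 0.35
        are indistinguishable from noise and rejected.
        """
        qcodes = _encode_dna(fragment.upper())
        qkm, qpos = _dna_kmers(qcodes, self.k)
        if len(qkm) == 0:
            return None
        best = None  # (key, matches, shift, strand)
        for rank, strand in enumerate("+-"):
            buckets = self._candidate_buckets(qkm, qpos, strand, len(qcodes),
                                              top_buckets)
            got = self._gapless_best(qcodes, strand, buckets)
            if got is None:
                continue
            m, s = got
            key = (-m, rank, s)
            if best is None or key < best[0]:
                best = (key, m, s, strand)
        if best is None:
            return None
        _, m, s, strand = best
        cols = len(qcodes)
        if m / cols < min_identity:
            return None
        return FragmentHit(identity=m / cols, aligned_columns=cols,
                           coverage=1.0, strand=strand,
                           matches=m, subject_start=s)


# ---------------------------------------------------------------------------
# Nucleotide gene-vs-gene search (gANI/AF substrate)
# ---------------------------------------------------------------------------


def _edlib_identity(a: str, b: str) -> tuple[int, int]:
    """(matches, columns) of the global edit-distance alignment of a and b."""
    import edlib

    r = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(r, a, b)
    bars = nice["matched_aligned"]
    return bars.count("|"), len(bars)


class GeneKmerIndex:
    """Sorted-array index of nucleotide k-mers over a gene set."""

    def __init__(self, genes: Sequence[SeqEntry], k: int = 11):
        self.k = k
        self.ids = [g.id for g in genes]
        kms, gidx = [], []
        for gi, g in enumerate(genes):
            km, _ = _dna_kmers(_encode_dna(g.seq.upper()), k)
            kms.append(km)
            gidx.append(np.full(len(km), gi, dtype=np.int64))
        self._kmers = np.concatenate(kms) if kms else np.empty(0, dtype=np.int64)
        self._genes = np.concatenate(gidx) if gidx else np.empty(0, dtype=np.int64)
        order = np.argsort(self._kmers, kind="stable")
        self._kmers = self._kmers[order]
        self._genes = self._genes[order]

    def candidate_counts(self, seq: str) -> np.ndarray:
        km, _ = _dna_kmers(_encode_dna(seq.upper()), self.k)
        counts = np.zeros(len(self.ids), dtype=np.int64)
        if len(km) == 0 or len(self._kmers) == 0:
            return counts
        km = np.unique(km)
        lo = np.searchsorted(self._kmers, km, side="left")
        hi = np.searchsorted(self._kmers, km, side="right")
        cnt = hi - lo
        sel = cnt > 0
        if not sel.any():
            return counts
        lo, cnt = lo[sel], cnt[sel]
        total = int(cnt.sum())
        offs = np.repeat(np.cumsum(cnt) - cnt, cnt)
        idx = np.arange(total) - offs + np.repeat(lo, cnt)
        np.add.at(counts, self._genes[idx], 1)
        return counts


def search_genes(query_genes: Sequence[SeqEntry], subject_genes: Sequence[SeqEntry],
                 k: int = 11, min_kmer_matches: int = 2,
                 max_candidates: int = 5,
                 index: GeneKmerIndex | None = None) -> list[AlignmentHit]:
    """Best-hit nucleotide gene search by global edit-distance alignment.

    The stated score ordering for this search is identity (then subject id);
    coverage is 1 by construction of the global alignment.
    """
    idx = index if index is not None else GeneKmerIndex(subject_genes, k=k)
    hits: list[AlignmentHit] = []
    for q in query_genes:
        counts = idx.candidate_counts(q.seq)
        cand = np.nonzero(counts >= min_kmer_matches)[0]
        if len(cand) == 0:
            continue
        cand = sorted(cand, key=lambda g: (-counts[g], idx.ids[g]))[:max_candidates]
        best = None
        for gi in cand:
            s = subject_genes[gi]
            matches, cols = _edlib_identity(q.seq.upper(), s.seq.upper())
            hit = AlignmentHit(query_id=q.id, subject_id=s.id,
                               percent_identity=100.0 * matches / cols,
                               aligned_length=cols, query_coverage=1.0,
                               subject_coverage=1.0, score=float(matches))
            if best is None or (
                (-hit.score, -hit.percent_identity, hit.subject_id)
                < (-best.score, -best.percent_identity, best.subject_id)
            ):
                best = hit
        if best is not None:
            hits.append(best)
    return hits
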