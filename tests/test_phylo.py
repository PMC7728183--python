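"""Marker phylogenomics: extraction, alignment, concatenation, distances,
neighbor joining and bootstrap."""

import itertools
import math

import numpy as np
import pytest
from skbio import TreeNode

from gbtax.align import PROTEIN_SCORING, local_align
from gbtax.io import Proteome, SeqEntry
from gbtax.phylo import (ConcatenatedAlignment, DistanceMatrix, MarkerSet,
                         Msa, align_marker, bipartitions, bootstrap_support,
                         concatenate, distance_matrix, extract_markers,
                         nj_tree, same_topology, strip_gap_codons)

RNG = np.random.default_rng(90)
AA = "ACDEFGHIKLMNPQRSTVWY"


def rand_prot(n, rng=RNG):
    return "".join(rng.choice(list(AA), size=n))


class TestExtractMarkers:
    def test_seed_itself_is_found(self):
        seeds = [SeqEntry("m1", rand_prot(80)), SeqEntry("m2", rand_prot(70))]
        prot = Proteome("X", (SeqEntry("p1", seeds[0].seq),
                              SeqEntry("p2", seeds[1].seq),
                              SeqEntry("p3", rand_prot(60))))
        ms = MarkerSet.from_seed_entries("s", seeds)
        ext = extract_markers(prot, ms)
        assert ext.found["m1"].id == "p1"
        assert ext.found["m2"].id == "p2"
        assert ext.missing == []

    def test_decoy_proteome_reports_all_missing(self):
        rng = np.random.default_rng(3)
        seeds = [SeqEntry("m1", rand_prot(80, rng))]
        prot = Proteome("X", tuple(SeqEntry(f"d{i}", rand_prot(80, rng))
                                   for i in range(5)))
        ext = extract_markers(prot, MarkerSet.from_seed_entries("s", seeds))
        assert ext.found == {}
        assert ext.missing == ["m1"]

    def test_tree_evolved_markers_fully_recovered(self, quartet_markers):
        me = quartet_markers
        ms = MarkerSet.from_seed_entries("seeds", me.seed_markers)
        for taxon, prot in me.taxa_markers.items():
            ext = extract_markers(prot, ms)
            assert ext.missing == []
            # planted mapping: marker id == protein id within each taxon
            assert all(ext.found[mid].id == mid for mid in ext.found)

    def test_duplicate_marker_ids_rejected(self):
        s = SeqEntry("m1", rand_prot(50))
        with pytest.raises(ValueError):
            MarkerSet("bad", [("m1", [s]), ("m1", [s])])


class TestAlignMarker:
    def test_identical_sequences_align_gap_free(self):
        s = rand_prot(60)
        msa = align_marker([SeqEntry(f"t{i}", s) for i in range(4)])
        assert all(seq == s for seq in msa.seqs)

    def test_two_sequences_reduce_to_pairwise_global(self):
        a, b = rand_prot(50), rand_prot(45)
        msa = align_marker([SeqEntry("x", a), SeqEntry("y", b)])
        assert msa.seqs[0].replace("-", "") == a
        assert msa.seqs[1].replace("-", "") == b
        assert len(msa.seqs[0]) == len(msa.seqs[1])

    def test_single_indel_matches_bruteforce_sum_of_pairs(self):
        """Three sequences, one with a single-residue deletion: the
        progressive alignment must reach the optimum found by brute force
        over all single-gap placements."""
        base = "MKVAHEWLDRAG"
        entries = [SeqEntry("a", base), SeqEntry("b", base),
                   SeqEntry("c", base[:5] + base[6:])]
        msa = align_marker(entries)
        assert msa.n_columns == len(base)

        def sp_score(rows):
            total = 0
            for r1, r2 in itertools.combinations(rows, 2):
                s1 = r1.replace("-", "")
                s2 = r2.replace("-", "")
                hit = local_align(s1, s2) if s1 and s2 else None
                total += 0 if hit is None else hit.score
            return total

        # brute force: gap in every possible position of sequence c
        best = None
        for g in range(len(base)):
            rows = [base, base, base[:5] + base[6:]]
            gapped_c = rows[2][:g] + "-" + rows[2][g:]
            cols = list(zip(base, base, gapped_c))
            pair_sum = 0
            mat = PROTEIN_SCORING.matrix()
            import biotite.sequence as bs

            def sc(x, y):
                if "-" in (x, y):
                    return -PROTEIN_SCORING.gap_open
                return mat.get_score(bs.ProteinSequence(x)[0],
                                     bs.ProteinSequence(y)[0])

            for col in cols:
                for x, y in itertools.combinations(col, 2):
                    pair_sum += sc(x, y)
            if best is None or pair_sum > best[0]:
                best = (pair_sum, g)
        # the aligned gap must sit at the deleted position (5) for the
        # sum-of-pairs optimum
        assert best[1] == 5
        gap_cols = [i for i in range(msa.n_columns) if msa.seqs[2][i] == "-"]
        assert gap_cols == [5]


class TestStripGapCodons:
    def test_gap_free_input_unchanged(self):
        m = Msa(["a", "b"], ["ATGAAA", "ATGCCC"], "dna")
        assert strip_gap_codons(m).seqs == m.seqs

    def test_single_codon_gap_removes_one_triple_everywhere(self):
        m = Msa(["a", "b"], ["ATG---AAA", "ATGCCCAAA"], "dna")
        out = strip_gap_codons(m)
        assert out.seqs == ["ATGAAA", "ATGAAA"]

    def test_random_gap_mask_equals_columnwise_oracle(self):
        rng = np.random.default_rng(17)
        n_codons = 40
        rows = []
        for _ in range(4):
            codons = []
            for _ in range(n_codons):
                if rng.random() < 0.15:
                    codons.append("---")
                else:
                    codons.append("".join(rng.choice(list("ACGT"), 3)))
            rows.append("".join(codons))
        m = Msa([f"t{i}" for i in range(4)], rows, "dna")
        out = strip_gap_codons(m)
        # independent oracle: scan codon columns, keep those without gaps
        keep = [c for c in range(n_codons)
                if all("-" not in r[3 * c:3 * c + 3] for r in rows)]
        expected = ["".join(r[3 * c:3 * c + 3] for c in keep) for r in rows]
        assert out.seqs == expected
        assert "-" not in "".join(out.seqs)
        assert out.n_columns % 3 == 0

    def test_idempotent(self):
        m = Msa(["a", "b"], ["ATG---AAA", "ATGCCCAAA"], "dna")
        once = strip_gap_codons(m)
        assert strip_gap_codons(once).seqs == once.seqs

    def test_non_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            strip_gap_codons(Msa(["a"], ["ATGA"], "dna"))


class TestConcatenate:
    def test_two_msas_tile_partitions(self):
        m1 = Msa(["a", "b"], ["K" * 10, "R" * 10])
        m2 = Msa(["a", "b"], ["D" * 10, "E" * 10])
        cat = concatenate({"x": m1, "y": m2}, ["a", "b"], ["x", "y"])
        assert cat.n_columns == 20
        assert cat.partitions == {"x": (0, 10), "y": (10, 20)}

    def test_missing_taxon_gets_gap_block(self):
        m1 = Msa(["a", "b"], ["K" * 10, "R" * 10])
        m2 = Msa(["a"], ["D" * 10])
        cat = concatenate({"x": m1, "y": m2}, ["a", "b"], ["x", "y"])
        assert cat.sequences[cat.taxa.index("b")][10:] == "-" * 10

    def test_declared_order_makes_input_order_irrelevant(self):
        m1 = Msa(["a"], ["KKK"])
        m2 = Msa(["a"], ["DDD"])
        c1 = concatenate({"x": m1, "y": m2}, ["a"], ["x", "y"])
        c2 = concatenate({"y": m2, "x": m1}, ["a"], ["x", "y"])
        assert c1.sequences == c2.sequences
        assert c1.partitions == c2.partitions

    def test_residue_conservation(self):
        m1 = Msa(["a", "b"], ["KK-K", "RRRR"])
        m2 = Msa(["a"], ["DD"])
        cat = concatenate({"x": m1, "y": m2}, ["a", "b"], ["x", "y"])
        total_in = sum(len(s.replace("-", "")) for s in m1.seqs + m2.seqs)
        total_out = sum(len(s.replace("-", "")) for s in cat.sequences)
        assert total_in == total_out

    def test_duplicate_taxon_rejected(self):
        with pytest.raises(ValueError):
            Msa(["a", "a"], ["KK", "RR"])


class TestDistances:
    def test_identical_rows_distance_zero(self):
        m = Msa(["a", "b"], ["ACGTACGTAC", "ACGTACGTAC"], "dna")
        assert distance_matrix(m, "p-distance").values[0, 1] == 0.0

    def test_jc69_closed_form(self):
        # 10% differing sites
        a = "A" * 90 + "C" * 10
        b = "A" * 90 + "G" * 10
        d = distance_matrix(Msa(["x", "y"], [a, b], "dna"), "jc69").values[0, 1]
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * 0.1 / 3), abs=1e-12)

    def test_pairwise_deletion_ignores_gap_sites(self):
        a = "AC-TACGT"
        b = "ACGTACG-"
        d = distance_matrix(Msa(["x", "y"], [a, b], "dna"), "p-distance")
        assert d.values[0, 1] == 0.0  # 6 comparable sites, all equal

    def test_matrix_equals_per_pair_oracle(self):
        rng = np.random.default_rng(7)
        rows = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(4)]
        m = Msa([f"t{i}" for i in range(4)], rows, "dna")
        got = distance_matrix(m, "p-distance").values
        for i in range(4):
            for j in range(4):
                exp = np.mean([x != y for x, y in zip(rows[i], rows[j])])
                assert got[i, j] == pytest.approx(exp, abs=1e-12)

    def test_saturation_flagged_infinite(self):
        a = "A" * 100
        b = "C" * 100
        d = distance_matrix(Msa(["x", "y"], [a, b], "dna"), "jc69")
        assert math.isinf(d.values[0, 1])


from conftest import random_additive_tree  # noqa: E402  (shared oracle)


class TestNJ:
    def test_additive_quartet_recovered_exactly(self):
        # hand-drawn tree ((A:1,B:2):3,(C:4,D:5)) -> path-length matrix
        D = np.array([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]],
                     dtype=float)
        t = nj_tree(DistanceMatrix(["A", "B", "C", "D"], D))
        td = t.tip_tip_distances()
        for (x, y), exp in zip([("A", "B"), ("A", "C"), ("A", "D"),
                                ("B", "C"), ("B", "D"), ("C", "D")],
                               [3, 8, 9, 9, 10, 9]):
            assert td[x, y] == pytest.approx(exp, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_additive_trees_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        tree, dm = random_additive_tree(n, rng)
        rec = nj_tree(dm)
        assert same_topology(rec, tree)
        td = rec.tip_tip_distances()
        for i, x in enumerate(dm.ids):
            for j in range(i + 1, len(dm.ids)):
                assert td[x, dm.ids[j]] == pytest.approx(dm.values[i, j], abs=1e-9)

    def test_three_taxa_star_resolution(self):
        D = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(["a", "b", "c"], D))
        assert len(list(t.tips())) == 3
        assert all(tip.length == pytest.approx(1.0) for tip in t.tips())

    def test_label_invariance_under_permutation(self):
        rng = np.random.default_rng(12)
        tree, dm = random_additive_tree(7, rng)
        perm = rng.permutation(len(dm.ids))
        dm2 = DistanceMatrix([dm.ids[i] for i in perm],
                             dm.values[np.ix_(perm, perm)])
        t1, t2 = nj_tree(dm), nj_tree(dm2)
        assert same_topology(t1, t2)
        td1, td2 = t1.tip_tip_distances(), t2.tip_tip_distances()
        for i, x in enumerate(dm.ids):
            for y in dm.ids[i + 1:]:
                assert td1[x, y] == pytest.approx(td2[x, y], abs=1e-9)

    def test_agrees_with_independent_nj_implementation(self):
        """Cross-check against scikit-bio's neighbor joining on a random
        non-additive (noisy) matrix: same unrooted topology."""
        import skbio

        rng = np.random.default_rng(21)
        tree, dm = random_additive_tree(8, rng)
        noisy = dm.values + rng.uniform(0, 0.01, dm.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        mine = nj_tree(DistanceMatrix(dm.ids, noisy))
        ref = skbio.tree.nj(skbio.DistanceMatrix(noisy, dm.ids))
        assert bipartitions(mine) == bipartitions(ref)

    def test_non_symmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b", "c"], D))


class TestBootstrap:
    def test_strong_signal_gives_high_support(self, quartet_markers):
        me = quartet_markers
        taxa = sorted(me.taxa_markers)
        msas = {s.id: Msa(taxa, [me.taxa_markers[t].proteins[i].seq
                                 for t in taxa])
                for i, s in enumerate(me.seed_markers)}
        cat = concatenate(msas, taxa)
        _, supports = bootstrap_support(cat, 100, seed=5)
        assert supports and all(v >= 95 for v in supports.values())

    def test_single_replicate_supports_are_binary(self, quartet_markers):
        me = quartet_markers
        taxa = sorted(me.taxa_markers)
        msas = {s.id: Msa(taxa, [me.taxa_markers[t].proteins[i].seq
                                 for t in taxa])
                for i, s in enumerate(me.seed_markers)}
        cat = concatenate(msas, taxa)
        _, supports = bootstrap_support(cat, 1, seed=3)
        assert all(v in (0.0, 100.0) for v in supports.values())

    def test_fixed_seed_reproducible(self, quartet_markers):
        me = quartet_markers
        taxa = sorted(me.taxa_markers)
        msas = {s.id: Msa(taxa, [me.taxa_markers[t].proteins[i].seq
                                 for t in taxa])
                for i, s in enumerate(me.seed_markers)}
        cat = concatenate(msas, taxa)
        _, s1 = bootstrap_support(cat, 20, seed=8)
        _, s2 = bootstrap_support(cat, 20, seed=8)
        assert s1 == s2


def test_mlsa_small_panel_matches_large_panel_topology():
    """The MLSA-sized panel (7 markers) recovers the same NJ topology as
    the full SCG-sized panel on taxa evolved along one tree."""
    from gbtax.synthetic import evolve_markers_on_tree

    nwk = ("(((T1:0.04,T2:0.04):0.12,(T3:0.04,T4:0.05):0.10):0.08,"
           "((T5:0.05,T6:0.04):0.15,(T7:0.04,T8:0.06):0.11):0.05);")
    me = evolve_markers_on_tree(nwk, marker_count=139, seed=10)
    taxa = sorted(me.taxa_markers)

    def tree_from(k):
        msas = {s.id: Msa(taxa, [me.taxa_markers[t].proteins[i].seq
                                 for t in taxa])
                for i, s in enumerate(me.seed_markers[:k])}
        cat = concatenate(msas, taxa)
        return nj_tree(distance_matrix(cat, "p-distance"))

    assert same_topology(tree_from(7), tree_from(139))
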