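"""Relatedness indices: identity invariants, planted-parameter recovery,
symmetry, monotone response, undefined-result handling."""

import numpy as np
import pytest

from gbtax.align import GenomeMapper
from gbtax.indices import (IndexMatrix, POCPComponents, build_index_matrix,
                           compute_aai, compute_ani_fragment, compute_ddh_f2,
                           compute_gani_af, compute_pocp, compute_ssu_identity,
                           DdhTransform)
from gbtax.io import GeneSet, GenomeRecord, Proteome, SeqEntry
from gbtax.synthetic import PairSpec, evolve_pair, generate_ancestor

RNG = np.random.default_rng(77)


def _identical_proteomes(n=12, length=90):
    prots = tuple(SeqEntry(f"g{i}", "".join(RNG.choice(list("ACDEFGHIKLMNPQRSTVWY"), length)))
                  for i in range(n))
    return Proteome("A", prots), Proteome("B", prots)


class TestAAI:
    def test_identical_proteomes_give_100(self):
        pa, pb = _identical_proteomes()
        res = compute_aai(pa, pb)
        assert res.value == pytest.approx(100.0)
        assert res.n_components == len(pa)

    def test_recovers_planted_identity(self, pair_mid):
        a, b, _ = pair_mid
        res = compute_aai(a.proteome, b.proteome)
        assert res.value == pytest.approx(80.0, abs=2.0)

    def test_symmetric_under_argument_swap(self, pair_mid):
        a, b, _ = pair_mid
        r1 = compute_aai(a.proteome, b.proteome)
        r2 = compute_aai(b.proteome, a.proteome)
        assert r1.value == pytest.approx(r2.value, abs=1e-9)
        assert r1.n_components == r2.n_components

    def test_no_rbh_flags_undefined_not_zero(self):
        rng = np.random.default_rng(1)
        pa = Proteome("A", (SeqEntry("a1", "".join(rng.choice(list("ACDE"), 60))),))
        pb = Proteome("B", (SeqEntry("b1", "".join(rng.choice(list("KLMN"), 60))),))
        res = compute_aai(pa, pb)
        assert res.value is None
        assert not res.defined


class TestPOCP:
    def test_identical_proteomes_give_100(self):
        pa, pb = _identical_proteomes()
        assert compute_pocp(pa, pb).value == pytest.approx(100.0)

    def test_component_formula(self):
        comp = POCPComponents(C1=100, C2=120, T1=200, T2=200)
        assert comp.pocp == pytest.approx(55.0)
        with pytest.raises(ValueError):
            POCPComponents(C1=300, C2=0, T1=200, T2=200)

    def test_recovers_planted_shared_fraction(self, pair_mid):
        a, b, _ = pair_mid  # shared_fraction 0.6, identity 0.8
        res = compute_pocp(a.proteome, b.proteome)
        assert res.value == pytest.approx(60.0, abs=5.0)

    def test_empty_proteome_rejected(self):
        pa, _ = _identical_proteomes()
        with pytest.raises(ValueError):
            compute_pocp(pa, Proteome("B", ()))


class TestANI:
    def test_genome_vs_itself_is_100(self):
        anc = generate_ancestor(40, 120, seed=5)
        res = compute_ani_fragment(anc.genome, anc.genome)
        assert res.value == pytest.approx(100.0)

    def test_reverse_complement_is_100(self):
        from gbtax.align import revcomp

        anc = generate_ancestor(40, 120, seed=6)
        g = anc.genome
        rc = GenomeRecord("rc", (SeqEntry("c1", revcomp(g.contigs[0].seq)),))
        res = compute_ani_fragment(g, rc)
        assert res.value == pytest.approx(100.0)

    def test_recovers_planted_identity(self, pair_mid):
        a, b, _ = pair_mid  # nucleotide identity 0.8
        res = compute_ani_fragment(a.genome, b.genome)
        assert res.value == pytest.approx(80.0, abs=2.0)
        assert res.components["a->b"] == pytest.approx(res.components["b->a"], abs=1.0)

    def test_unrelated_genomes_flagged_undefined(self):
        rng = np.random.default_rng(8)
        ga = GenomeRecord("A", (SeqEntry("c", "".join(rng.choice(list("ACGT"), 5000))),))
        gb = GenomeRecord("B", (SeqEntry("c", "".join(rng.choice(list("ACGT"), 5000))),))
        res = compute_ani_fragment(ga, gb)
        assert res.value is None or res.value < 60


class TestDDH:
    def test_self_comparison_sits_at_plateau(self):
        anc = generate_ancestor(40, 120, seed=9)
        res = compute_ddh_f2(anc.genome, anc.genome)
        assert res.components["raw_identity"] == pytest.approx(1.0)
        assert res.value > 99.0

    def test_raw_statistic_monotone_in_planted_identity(self):
        raws = []
        for ident in (0.7, 0.9):
            a, b, _ = evolve_pair(PairSpec(
                n_genes=40, gene_length_mean=150, shared_fraction=1.0,
                target_protein_identity=0.8, target_nucleotide_identity=ident,
                seed=21))
            raws.append(compute_ddh_f2(a.genome, b.genome).components["raw_identity"])
        assert raws[0] < raws[1]

    def test_transform_monotone_decreasing_in_distance(self):
        tr = DdhTransform()
        vals = [tr.ddh_percent(s) for s in (1.0, 0.97, 0.9, 0.8)]
        assert vals == sorted(vals, reverse=True)


class TestGaniAf:
    def test_identical_gene_sets(self):
        anc = generate_ancestor(30, 100, seed=12)
        gani, af = compute_gani_af(anc.genes, anc.genes)
        assert gani.value == pytest.approx(100.0)
        assert af.value == pytest.approx(1.0)

    def test_single_shared_gene_arithmetic(self):
        anc = generate_ancestor(2, 100, seed=13)
        shared, unique = anc.genes.genes
        other = generate_ancestor(1, 100, seed=14).genes.genes[0]
        a = GeneSet("A", (shared, unique))
        b = GeneSet("B", (SeqEntry("x", shared.seq), SeqEntry("y", other.seq)))
        gani, af = compute_gani_af(a, b)
        # one perfect BBH pair out of two genes of equal mean length
        assert gani.value == pytest.approx(100.0)
        expected_af = np.mean([len(shared.seq) / a.total_length,
                               len(shared.seq) / b.total_length])
        assert af.value == pytest.approx(expected_af, abs=1e-6)

    def test_recovers_planted_shared_fraction(self, pair_mid):
        a, b, _ = pair_mid  # shared_fraction 0.6
        _, af = compute_gani_af(a.genes, b.genes)
        assert af.value == pytest.approx(0.6, abs=0.05)


class TestSSU:
    def test_identical_sequences_100(self):
        rng = np.random.default_rng(31)
        s = "".join(rng.choice(list("ACGT"), 1200))
        assert compute_ssu_identity(s, s).value == pytest.approx(100.0)

    def test_substitution_only_identity_exact(self):
        rng = np.random.default_rng(32)
        s = list("".join(rng.choice(list("ACGT"), 1000)))
        t = list(s)
        for i in rng.choice(1000, size=5, replace=False):
            t[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[t[i]]
        res = compute_ssu_identity("".join(s), "".join(t))
        assert res.value == pytest.approx(99.5)

    def test_matches_hamming_oracle_at_planted_identity(self):
        from gbtax.synthetic import _mutate_dna, two_lineage_rate

        rng = np.random.default_rng(33)
        anc = "".join(rng.choice(list("ACGT"), 1400))
        q = two_lineage_rate(0.95, 4)
        sa, sb = _mutate_dna(rng, anc, q), _mutate_dna(rng, anc, q)
        truth = 100.0 * sum(x == y for x, y in zip(sa, sb)) / len(sa)
        res = compute_ssu_identity(sa, sb)
        assert res.value == pytest.approx(truth, abs=1e-9)
        assert res.value == pytest.approx(95.0, abs=1.5)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_ssu_identity("ACGT" * 10, "ACGT" * 100)


class TestMonotoneResponse:
    def test_aai_and_gani_increase_with_planted_identity(self):
        """AAI and gANI respond monotonically across planted protein
        identities (ANI/dDDH monotonicity is covered in acceptance)."""
        aais, ganis = [], []
        for ident in (0.5, 0.7, 0.9):
            a, b, _ = evolve_pair(PairSpec(
                n_genes=60, gene_length_mean=120, shared_fraction=1.0,
                target_protein_identity=ident, target_nucleotide_identity=0.8,
                seed=55))
            aais.append(compute_aai(a.proteome, b.proteome).value)
            ganis.append(compute_gani_af(a.genes, b.genes)[0].value)
        assert aais == sorted(aais)
        assert ganis == sorted(ganis)


class TestIndexMatrix:
    def test_identical_genomes_off_diagonal_100(self):
        anc = generate_ancestor(15, 80, seed=41)
        pool = {g: Proteome(g, anc.proteome.proteins) for g in ("a", "b", "c")}
        m = build_index_matrix(pool, "AAI")
        off = m.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 100.0)
        assert np.allclose(m.values, m.values.T)

    def test_two_clade_structure_preserved(self):
        """Four tree-evolved proteomes in two clades: every within-clade AAI
        exceeds every between-clade AAI."""
        from gbtax.synthetic import evolve_markers_on_tree

        me = evolve_markers_on_tree(
            "((a1:0.05,a2:0.05):0.2,(b1:0.05,b2:0.05):0.2);", 40, seed=63)
        pool = {t: p for t, p in me.taxa_markers.items()}
        m = build_index_matrix(pool, "AAI")
        within = [m.value("a1", "a2"), m.value("b1", "b2")]
        between = [m.value(x, y) for x in ("a1", "a2") for y in ("b1", "b2")]
        assert min(within) > max(between)

    def test_missing_input_reported_not_silent(self):
        anc = generate_ancestor(10, 80, seed=43)
        pool = {"a": anc.proteome, "b": anc.proteome, "c": None}
        m = build_index_matrix(pool, "AAI")
        assert ("c", "missing input") in m.skipped
        assert np.isnan(m.value("a", "c"))
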