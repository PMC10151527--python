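import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heterosim.populations import two_locus_genotype_freqs
from heterosim.trait_model import (
    EPISTASIS_TYPES,
    F2_RATIOS,
    TraitModel,
    assign_gene_effects,
    build_epistasis_table,
    composite_aa,
    composite_dd,
    epistatic_variance_target,
    f2_class_ratio,
    genotypic_value,
    kempthorne_decompose,
    pair_epistatic_genes,
    phenotype,
)

from conftest import two_gene_trait


# ---------------------------------------------------------------------------
# gene effects
# ---------------------------------------------------------------------------

class TestGeneEffects:
    def test_homozygote_totals(self):
        genes = assign_gene_effects(400, 30.0, 160.0, seed=0)
        lo = sum(g.m - g.a for g in genes)
        hi = sum(g.m + g.a for g in genes)
        assert lo == pytest.approx(30.0, abs=1e-9)
        assert hi == pytest.approx(160.0, abs=1e-9)
        assert all(g.a > 0 for g in genes)
        assert all(g.d >= 0 for g in genes)

    def test_degenerate_dominance_range(self):
        genes = assign_gene_effects(50, 0.0, 100.0, dom_mean=0.6, dom_range=(0.6, 0.6), seed=1)
        assert all(g.d == pytest.approx(0.6 * g.a) for g in genes)

    def test_dominance_degree_distribution(self):
        genes = assign_gene_effects(100_000, 0.0, 100.0, dom_mean=0.6,
                                    dom_range=(0.1, 1.2), seed=2)
        deg = np.array([g.degree for g in genes])
        assert np.all((deg >= 0.1) & (deg <= 1.2))
        # scaled beta has mean exactly 0.6; sd is bounded by the range
        assert abs(deg.mean() - 0.6) < 3 * 1.1 / np.sqrt(100_000) * 0.5

    def test_inconsistent_range_rejected(self):
        with pytest.raises(ValueError):
            assign_gene_effects(10, 100.0, 30.0)


class TestPairing:
    def test_full_fraction(self):
        pairs = pair_epistatic_genes(np.arange(400), 1.0, seed=0)
        assert len(pairs) == 200
        flat = [g for p in pairs for g in p]
        assert sorted(flat) == list(range(400))

    def test_quarter_fraction(self):
        pairs = pair_epistatic_genes(np.arange(400), 0.25, seed=1)
        assert len(pairs) == 50
        flat = [g for p in pairs for g in p]
        assert len(set(flat)) == 100

    def test_zero_fraction(self):
        assert pair_epistatic_genes(np.arange(10), 0.0) == []

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError):
            pair_epistatic_genes(np.arange(10), 0.5)  # 5 genes


class TestVarianceTarget:
    def test_textbook_case(self):
        genes = two_gene_trait(a=(1.0, 1.0), d=(0.0, 0.0)).genes
        # V(A) = 2pq a^2 per locus = 0.5 each at p = 0.5; V(D) = 0
        assert epistatic_variance_target(genes[0], genes[1], 0.5, 0.5, 1.0) == pytest.approx(1.0)
        assert epistatic_variance_target(genes[0], genes[1], 0.5, 0.5, 10.0) == pytest.approx(10.0)
        assert epistatic_variance_target(genes[0], genes[1], 0.5, 0.5, 0.0) == 0.0

    def test_matches_enumerated_variances(self):
        """V(A)+V(D) equals the genetic variance of the additive-dominance table."""
        trait = two_gene_trait(a=(1.3, 0.8), d=(0.6, 0.9))
        ga, gb = trait.genes
        pa, pb = 0.3, 0.6
        total = 0.0
        for g, p in [(ga, pa), (gb, pb)]:
            w = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
            vals = g.locus_values
            var = w @ vals**2 - (w @ vals) ** 2
            # single-locus genetic variance = V(A) + V(D) at that locus
            total += var
        assert epistatic_variance_target(ga, gb, pa, pb, 1.0) == pytest.approx(total, rel=1e-12)


# ---------------------------------------------------------------------------
# epistasis tables
# ---------------------------------------------------------------------------

class TestEpistasisTables:
    @pytest.mark.parametrize("etype", EPISTASIS_TYPES)
    def test_f2_ratio(self, etype):
        """Dihybrid F2 enumeration reproduces the classical segregation ratio."""
        trait = two_gene_trait()
        pair = build_epistasis_table(etype, trait.genes[0], trait.genes[1],
                                     ratio=1.0, seed=7)
        G = trait.genes[0].locus_values[:, None] + trait.genes[1].locus_values[None, :] + pair.I
        got = f2_class_ratio(G)
        expected = F2_RATIOS[etype]
        assert got[0] == expected[0]
        assert sorted(got) == sorted(expected)
        assert sum(got) == 16

    @pytest.mark.parametrize("etype", EPISTASIS_TYPES)
    def test_equality_pattern_exact(self, etype):
        from heterosim.trait_model import _P

        trait = two_gene_trait()
        pair = build_epistasis_table(etype, trait.genes[0], trait.genes[1],
                                     ratio=10.0, seed=3)
        G = trait.pair_table(pair)
        for cells in _P[etype]:
            vals = [G[i, k] for (i, k) in cells]
            assert np.ptp(vals) < 1e-12

    def test_i22_distribution(self):
        """I22 draws have the target variance V(I)."""
        trait = two_gene_trait()
        ga, gb = trait.genes
        v_i = epistatic_variance_target(ga, gb, 0.5, 0.5, 1.0)
        rng = np.random.default_rng(11)
        draws = np.array([
            build_epistasis_table("complementary", ga, gb, ratio=1.0, seed=rng).I[2, 2]
            for _ in range(3000)
        ])
        assert abs(draws.mean()) < 3 * np.sqrt(v_i / 3000)
        # sample variance of a normal: SE ~ sqrt(2/n) * V
        assert abs(draws.var() - v_i) < 4 * np.sqrt(2 / 3000) * v_i

    def test_zero_ratio_degenerate(self):
        """With V(I) = 0 no table exists unless the baseline fits the pattern."""
        trait = two_gene_trait()
        with pytest.raises(ValueError):
            build_epistasis_table("complementary", trait.genes[0], trait.genes[1],
                                  ratio=0.0, seed=0)

    def test_unknown_type_rejected(self):
        trait = two_gene_trait()
        with pytest.raises(ValueError):
            build_epistasis_table("triplicate", trait.genes[0], trait.genes[1])


# ---------------------------------------------------------------------------
# orthogonal decomposition
# ---------------------------------------------------------------------------

def _projection_oracle(G, pa, pb):
    """Independent weighted-least-squares projection onto explicit contrasts."""
    qa, qb = 1 - pa, 1 - pb
    wa = np.array([qa * qa, 2 * pa * qa, pa * pa])
    wb = np.array([qb * qb, 2 * pb * qb, pb * pb])
    xa = np.array([-2 * pa, 1 - 2 * pa, 2 - 2 * pa])
    xb = np.array([-2 * pb, 1 - 2 * pb, 2 - 2 * pb])
    za = np.array([-2 * pa * pa, 2 * pa * qa, -2 * qa * qa])
    zb = np.array([-2 * pb * pb, 2 * pb * qb, -2 * qb * qb])
    one = np.ones(3)
    basis = [
        np.outer(u, v)
        for u in (one, xa, za)
        for v in (one, xb, zb)
    ]
    W = np.outer(wa, wb).ravel()
    X = np.stack([b.ravel() for b in basis], axis=1)
    # weighted normal equations
    A = X.T @ (W[:, None] * X)
    beta = np.linalg.solve(A, X.T @ (W * G.ravel()))
    surfaces = [beta[i] * basis[i] for i in range(9)]
    return beta, surfaces


class TestDecomposition:
    @given(
        g=st.lists(st.floats(-10, 10), min_size=9, max_size=9),
        pa=st.floats(0.05, 0.95),
        pb=st.floats(0.05, 0.95),
    )
    def test_round_trip_identity(self, g, pa, pb):
        G = np.array(g).reshape(3, 3)
        dec = kempthorne_decompose(G, pa, pb)
        assert np.allclose(dec.reconstruct(), G, atol=1e-10)

    def test_additive_table_has_no_higher_effects(self):
        G = np.add.outer(np.array([0.0, 1.0, 2.0]), np.array([0.0, 3.0, 6.0]))
        dec = kempthorne_decompose(G, 0.4, 0.7)
        assert np.allclose(dec.dominance_a, 0, atol=1e-12)
        assert np.allclose(dec.dominance_b, 0, atol=1e-12)
        for s in (dec.aa_surface, dec.ad_surface, dec.da_surface, dec.dd_surface):
            assert np.allclose(s, 0, atol=1e-12)
        assert dec.aa == pytest.approx(0.0, abs=1e-12)
        assert dec.dd == pytest.approx(0.0, abs=1e-12)

    @given(
        g=st.lists(st.floats(-5, 5), min_size=9, max_size=9),
        pa=st.floats(0.1, 0.9),
        pb=st.floats(0.1, 0.9),
    )
    def test_epistatic_marginal_restrictions(self, g, pa, pb):
        """Frequency-weighted row and column sums of every epistatic surface vanish."""
        G = np.array(g).reshape(3, 3)
        dec = kempthorne_decompose(G, pa, pb)
        qa, qb = 1 - pa, 1 - pb
        wa = np.array([qa * qa, 2 * pa * qa, pa * pa])
        wb = np.array([qb * qb, 2 * pb * qb, pb * pb])
        for s in (dec.aa_surface, dec.ad_surface, dec.da_surface, dec.dd_surface):
            assert np.allclose(wa @ s, 0, atol=1e-10)
            assert np.allclose(s @ wb, 0, atol=1e-10)

    @pytest.mark.parametrize("seed,pa,pb", [(0, 0.5, 0.5), (1, 0.3, 0.8), (2, 0.65, 0.2)])
    def test_matches_projection_oracle(self, seed, pa, pb):
        rng = np.random.default_rng(seed)
        G = rng.normal(size=(3, 3))
        dec = kempthorne_decompose(G, pa, pb)
        _, surfaces = _projection_oracle(G, pa, pb)
        # basis order: 1x1, 1xX, 1xZ, Xx1, XxX, XxZ, Zx1, ZxX, ZxZ
        assert np.allclose(dec.aa_surface, surfaces[4], atol=1e-10)
        assert np.allclose(dec.ad_surface, surfaces[5], atol=1e-10)
        assert np.allclose(dec.da_surface, surfaces[7], atol=1e-10)
        assert np.allclose(dec.dd_surface, surfaces[8], atol=1e-10)

    def test_complementary_table_has_aa_and_dd(self):
        trait = two_gene_trait()
        pair = build_epistasis_table("complementary", trait.genes[0], trait.genes[1],
                                     ratio=1.0, seed=5)
        dec = kempthorne_decompose(pair.I, 0.5, 0.5)
        assert abs(dec.aa) > 1e-6
        assert abs(dec.dd) > 1e-6

    def test_cumulative_equal_spacing_has_no_aa(self):
        """The canonical 9:6:1 table with equally spaced class values is
        additive-by-additive free at p = q = 0.5 (the corner double
        difference cancels by symmetry)."""
        G = np.array([[0.0, 1.0, 1.0], [1.0, 2.0, 2.0], [1.0, 2.0, 2.0]])
        dec = kempthorne_decompose(G, 0.5, 0.5)
        assert dec.aa == pytest.approx(0.0, abs=1e-12)

    @given(
        g=st.lists(st.floats(-5, 5), min_size=9, max_size=9),
        pa=st.floats(0.1, 0.9),
        pb=st.floats(0.1, 0.9),
        t=st.floats(-1, 1),
    )
    def test_ad_da_expectation_zero_under_any_ld(self, g, pa, pb, t):
        """E over any Hardy-Weinberg-with-LD table of the AD and DA surfaces is 0."""
        G = np.array(g).reshape(3, 3)
        dec = kempthorne_decompose(G, pa, pb)
        lo = max(-pa * pb, -(1 - pa) * (1 - pb))
        hi = min(pa * (1 - pb), (1 - pa) * pb)
        delta = lo + (t + 1) / 2 * (hi - lo)
        f = two_locus_genotype_freqs(pa, pb, delta)
        assert (f * dec.ad_surface).sum() == pytest.approx(0.0, abs=1e-10)
        assert (f * dec.da_surface).sum() == pytest.approx(0.0, abs=1e-10)

    def test_composite_aa_identity(self):
        """E(AA) computed as 2 Delta (aa) equals the enumeration over f."""
        rng = np.random.default_rng(3)
        G = rng.normal(size=(3, 3))
        pa, pb, delta = 0.35, 0.55, 0.06
        dec = kempthorne_decompose(G, pa, pb)
        f = two_locus_genotype_freqs(pa, pb, delta)
        assert (f * dec.aa_surface).sum() == pytest.approx(2 * delta * composite_aa(dec), abs=1e-12)
        assert (f * dec.dd_surface).sum() == pytest.approx(delta**2 * composite_dd(dec), abs=1e-12)


# ---------------------------------------------------------------------------
# genotypic and phenotypic values
# ---------------------------------------------------------------------------

class TestGenotypicValue:
    def test_all_heterozygous_no_epistasis(self):
        genes = assign_gene_effects(20, 30.0, 160.0, seed=0)
        trait = TraitModel(genes)
        dos = np.ones((1, 20), dtype=int)
        expected = sum(g.m + g.d for g in genes)
        assert genotypic_value(dos, trait)[0] == pytest.approx(expected, rel=1e-12)

    def test_best_homozygote_hits_range_maximum(self):
        genes = assign_gene_effects(400, 30.0, 160.0, seed=1)
        trait = TraitModel(genes)
        dos = np.full((1, 400), 2, dtype=int)
        assert genotypic_value(dos, trait)[0] == pytest.approx(160.0, abs=1e-8)
        dos0 = np.zeros((1, 400), dtype=int)
        assert genotypic_value(dos0, trait)[0] == pytest.approx(30.0, abs=1e-8)

    def test_matches_bruteforce_pair_lookup(self):
        rng = np.random.default_rng(4)
        genes = assign_gene_effects(10, 10.0, 50.0, seed=2)
        pairs = [
            build_epistasis_table("dominant", genes[0], genes[3], ratio=1.0, seed=5),
            build_epistasis_table("recessive", genes[7], genes[2], ratio=10.0, seed=6),
        ]
        trait = TraitModel(genes, pairs)
        dos = rng.integers(0, 3, size=(50, 10))
        G = genotypic_value(dos, trait)
        for row, g in zip(dos, G):
            expected = sum(genes[i].locus_values[row[i]] for i in range(10))
            for p in pairs:
                expected += p.I[row[p.gene_a], row[p.gene_b]]
            assert g == pytest.approx(expected, rel=1e-12)


class TestPhenotype:
    def test_full_heritability_is_identity(self):
        G = np.linspace(30, 160, 100)
        assert np.array_equal(phenotype(G, 1.0, bounds=None, seed=0), G)

    def test_variance_ratio(self):
        rng = np.random.default_rng(5)
        G = rng.normal(100, 10, 200_000)
        P = phenotype(G, 0.1, bounds=None, seed=1)
        ratio = (P - G).var() / P.var()
        assert ratio == pytest.approx(0.9, abs=0.01)

    def test_bounds_applied(self):
        rng = np.random.default_rng(6)
        G = rng.normal(95, 30, 10_000)
        P = phenotype(G, 0.1, bounds=(10.0, 180.0), seed=2)
        assert P.min() >= 10.0 and P.max() <= 180.0

    def test_zero_heritability_rejected(self):
        with pytest.raises(ValueError):
            phenotype(np.ones(10), 0.0)


def test_trait_serialisation_round_trip(tmp_path):
    genes = assign_gene_effects(8, 10.0, 60.0, seed=3)
    pairs = [build_epistasis_table("duplicate", genes[1], genes[5], ratio=1.0, seed=9)]
    trait = TraitModel(genes, pairs)
    gp, pp = tmp_path / "genes.tsv", tmp_path / "pairs.tsv"
    trait.write(gp, pp)
    back = TraitModel.read(gp, pp)
    assert np.array_equal(back.m_vec, trait.m_vec)
    assert np.array_equal(back.a_vec, trait.a_vec)
    assert np.array_equal(back.d_vec, trait.d_vec)
    assert np.array_equal(back.pairs[0].I, trait.pairs[0].I)
    assert back.pairs[0].type == "duplicate"
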