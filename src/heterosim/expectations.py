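"""Closed-form parametric means under linkage disequilibrium and epistasis.

The genotypic mean of a non-inbred population decomposes as

    M_j = m + v_j + E(AA)_j + E(DD)_j

where ``m`` is the summed homozygote midpoint, ``v_j`` collects the
per-locus (variety) contributions, and the epistatic components are the
expectations of the additive x additive and dominance x dominance effect
surfaces: per pair of interacting genes E(AA) = 2 Delta (aa) and
E(DD) = Delta^2 (dd), with Delta the gametic LD of the pool that formed
the population.  The additive x dominance and dominance x additive
expectations vanish in any non-inbred population because the effect
surfaces have zero frequency-weighted marginal sums.

For an interpopulation F1 each parental pool contributes one further
meiosis, Delta(0) = (1 - r) Delta(-1), giving

    E(AA)_jj' = Delta_j(0) (aa) + Delta_j'(0) (aa)
    E(DD)_jj' = Delta_j(0) Delta_j'(0) (dd)

Selfed populations are handled by exact recursion of the phased two-locus
genotype distribution under selfing; the printed closed forms (the ``c1``
coefficient and the probability ``p1``) serve as cross-checks of the
recursion, and all four epistatic components are generally non-zero under
LD once the population is inbred.

All means are exact expectations of the genotypic value, which Monte-Carlo
simulation of individuals reproduces within sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeMap
from .populations import PopulationSpec, haplotype_freqs, selfing_recursion, zygote_table
from .trait_model import TraitModel, decompose_tables

__all__ = [
    "MeanComponents",
    "population_mean",
    "cross_mean",
    "selfed_mean",
    "heterosis",
    "selfing_c1",
    "selfing_c",
]


@dataclass(frozen=True)
class MeanComponents:
    """Genotypic mean of a population/cross/selfed population (g/plant).

    ``M = m + v + d + E_AA + E_AD + E_DA + E_DD`` exactly; ``d`` is the
    change due to inbreeding (zero for non-inbred populations) and ``v``
    the variety effect (per-locus contributions plus the reference-weighted
    mean of the epistatic tables).
    """

    M: float
    m: float
    v: float
    E_AA: float = 0.0
    E_AD: float = 0.0
    E_DA: float = 0.0
    E_DD: float = 0.0
    d: float = 0.0
    F: float = 0.0

    @property
    def total(self) -> float:
        return self.m + self.v + self.d + self.E_AA + self.E_AD + self.E_DA + self.E_DD


def selfing_c1(r: float, n: int) -> float:
    """Coefficient c1 = 2{1 - [(1 - 2r)/2]^n} / (1 + 2r) of selfed-mean theory."""
    return 2.0 * (1.0 - ((1.0 - 2.0 * r) / 2.0) ** n) / (1.0 + 2.0 * r)


def selfing_c(r: float) -> float:
    """Coefficient c = 1 - 2r(1 - r) of selfed-mean theory."""
    return 1.0 - 2.0 * r * (1.0 - r)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _locus_means(trait: TraitModel, pm: np.ndarray, pf: np.ndarray) -> float:
    """Sum over genes of the per-locus mean for maternal/paternal freqs."""
    P2 = pm * pf
    P0 = (1.0 - pm) * (1.0 - pf)
    P1 = 1.0 - P2 - P0
    lv = trait.locus_values
    return float((lv[:, 0] * P0 + lv[:, 1] * P1 + lv[:, 2] * P2).sum())


def _pair_arrays(trait: TraitModel):
    ia = np.array([p.gene_a for p in trait.pairs], dtype=np.int64)
    ib = np.array([p.gene_b for p in trait.pairs], dtype=np.int64)
    I = np.stack([p.I for p in trait.pairs])
    return ia, ib, I


def _zygote_tables(Hm: np.ndarray, Hf: np.ndarray) -> np.ndarray:
    """Batched 3x3 genotype tables from batched 2x2 gamete-pool tables."""
    n = Hm.shape[0]
    f = np.zeros((n, 3, 3))
    for ca in range(2):
        for cb in range(2):
            for da in range(2):
                for db in range(2):
                    f[:, ca + da, cb + db] += Hm[:, ca, cb] * Hf[:, da, db]
    return f


def _haplotype_tables(pa, pb, delta) -> np.ndarray:
    qa, qb = 1.0 - pa, 1.0 - pb
    H = np.empty((pa.size, 2, 2))
    H[:, 0, 0] = qa * qb + delta
    H[:, 0, 1] = qa * pb - delta
    H[:, 1, 0] = pa * qb - delta
    H[:, 1, 1] = pa * pb + delta
    if np.any(H < -1e-12):
        raise ValueError("an LD value violates its admissible bounds")
    return np.clip(H, 0.0, None)


def _ordered_moment_coefs(I, pm_a, pf_a, pm_b, pf_b):
    """Pool-specific epistatic regression coefficients of the I tables.

    Treating each locus genotype as an ordered (maternal, paternal) allele
    pair with pool-specific Bernoulli measures, returns the coefficients
    of the maternal-maternal and paternal-paternal additive x additive
    score products and of the dominance x dominance product.  With equal
    pool frequencies these reduce to the composites (aa) and (dd).
    """
    n = I.shape[0]
    # scores s(c) = c - p per pool and locus, c in {0, 1}
    def scores(p):
        return np.stack([-p, 1.0 - p], axis=-1)  # (n, 2)

    def measure(p):
        return np.stack([1.0 - p, p], axis=-1)

    sma, sfa = scores(pm_a), scores(pf_a)
    smb, sfb = scores(pm_b), scores(pf_b)
    wma, wfa = measure(pm_a), measure(pf_a)
    wmb, wfb = measure(pm_b), measure(pf_b)
    vma, vfa = pm_a * (1 - pm_a), pf_a * (1 - pf_a)
    vmb, vfb = pm_b * (1 - pm_b), pf_b * (1 - pf_b)

    # expand I to the ordered representation J[c_ma, c_fa, c_mb, c_fb]
    idx = np.array([0, 1])
    J = I[:, idx[:, None, None, None] + idx[None, :, None, None],
          idx[None, None, :, None] + idx[None, None, None, :]]

    c_mm = np.einsum("nabcd,na,nb,nc,nd,na,nc->n", J, wma, wfa, wmb, wfb,
                     sma / vma[:, None], smb / vmb[:, None])
    c_ff = np.einsum("nabcd,na,nb,nc,nd,nb,nd->n", J, wma, wfa, wmb, wfb,
                     sfa / vfa[:, None], sfb / vfb[:, None])
    e_dd = np.einsum("nabcd,na,nb,nc,nd->n", J,
                     wma * sma / vma[:, None], wfa * sfa / vfa[:, None],
                     wmb * smb / vmb[:, None], wfb * sfb / vfb[:, None])
    return c_mm, c_ff, e_dd


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def population_mean(pop: PopulationSpec, trait: TraitModel, genome: GenomeMap) -> MeanComponents:
    """Parametric mean components of a non-inbred population (or F1 cross).

    The total mean is the exact expectation of the genotypic value over
    the population's two-locus genotype distribution; the epistatic
    components are the expectations of the epistatic effect surfaces, so
    that for a panmictic population E(AA) = sum over pairs of
    2 Delta (aa), E(DD) of Delta^2 (dd), and E(AD) = E(DA) = 0.
    """
    if pop.selfing_generations:
        raise ValueError("population is inbred; use selfed_mean")
    pm, pf = pop.pool_m.p, pop.pool_f.p
    M = _locus_means(trait, pm, pf)
    E_AA = E_AD = E_DA = E_DD = 0.0
    if trait.pairs:
        ia, ib, I = _pair_arrays(trait)
        dm = np.atleast_1d(pop.pool_m.delta(ia, ib, genome))
        df = np.atleast_1d(pop.pool_f.delta(ia, ib, genome))
        Hm = _haplotype_tables(pm[ia], pm[ib], dm)
        Hf = _haplotype_tables(pf[ia], pf[ib], df)
        f = _zygote_tables(Hm, Hf)
        M += float(np.einsum("nik,nik->", f, I))
        if pop.is_panmictic:
            dec = decompose_tables(I, pm[ia], pm[ib])
            E_AA = float(np.einsum("nik,nik->", f, dec["aa_surface"]))
            E_AD = float(np.einsum("nik,nik->", f, dec["ad_surface"]))
            E_DA = float(np.einsum("nik,nik->", f, dec["da_surface"]))
            E_DD = float(np.einsum("nik,nik->", f, dec["dd_surface"]))
        else:
            c_mm, c_ff, e_dd = _ordered_moment_coefs(I, pm[ia], pf[ia], pm[ib], pf[ib])
            E_AA = float((c_mm * dm + c_ff * df).sum())
            E_DD = float((e_dd * dm * df).sum())
            # AD/DA vanish exactly: every score product leaves one factor
            # centred at its own pool frequency with independent pools.
            E_AD = E_DA = 0.0
    m = trait.m_total
    v = M - m - E_AA - E_AD - E_DA - E_DD
    return MeanComponents(M=M, m=m, v=v, E_AA=E_AA, E_AD=E_AD, E_DA=E_DA, E_DD=E_DD)


def cross_mean(popA: PopulationSpec, popB: PopulationSpec, trait: TraitModel,
               genome: GenomeMap) -> MeanComponents:
    """Parametric mean components of the interpopulation F1.

    Each parent contributes a gamete pool with one further meiosis, so its
    LD is Delta(0) = (1 - r) Delta(-1).
    """
    from .populations import cross_populations

    return population_mean(cross_populations(popA, popB, genome), trait, genome)


def selfed_mean(pop: PopulationSpec, trait: TraitModel, genome: GenomeMap,
                n_gen: int = 1) -> MeanComponents:
    """Parametric mean components after ``n_gen`` selfing generations.

    Computed by exact recursion of the phased two-locus genotype
    distribution under selfing; the epistatic components are expectations
    of the effect surfaces (defined at the base population's frequencies)
    over the selfed genotype distribution.  ``d`` is the change of the
    mean due to inbreeding net of the epistatic components, and
    ``d* = M_s - M`` overall.
    """
    if n_gen < 1:
        raise ValueError("n_gen must be >= 1")
    if pop.selfing_generations:
        raise ValueError("base population must be non-inbred")
    if not pop.is_panmictic:
        raise ValueError("selfing is defined for panmictic base populations")
    base = population_mean(pop, trait, genome)
    p = pop.p
    F = 1.0 - 0.5 ** n_gen
    # single-locus means under selfing
    P2 = p**2 + F * p * (1 - p)
    P0 = (1 - p) ** 2 + F * p * (1 - p)
    P1 = 2 * p * (1 - p) * (1 - F)
    lv = trait.locus_values
    M_s = float((lv[:, 0] * P0 + lv[:, 1] * P1 + lv[:, 2] * P2).sum())
    E_AA = E_AD = E_DA = E_DD = 0.0
    if trait.pairs:
        ia, ib, I = _pair_arrays(trait)
        delta = np.atleast_1d(pop.pool_m.delta(ia, ib, genome))
        r = genome.r_pairs(ia, ib)
        dec = decompose_tables(I, p[ia], p[ib])
        for k in range(len(trait.pairs)):
            H = haplotype_freqs(p[ia[k]], p[ib[k]], delta[k])
            fn = selfing_recursion(H, r[k], n_gen)
            M_s += float(np.einsum("ik,ik->", fn, I[k]))
            E_AA += float(np.einsum("ik,ik->", fn, dec["aa_surface"][k]))
            E_AD += float(np.einsum("ik,ik->", fn, dec["ad_surface"][k]))
            E_DA += float(np.einsum("ik,ik->", fn, dec["da_surface"][k]))
            E_DD += float(np.einsum("ik,ik->", fn, dec["dd_surface"][k]))
    m = trait.m_total
    d = M_s - m - base.v - E_AA - E_AD - E_DA - E_DD
    return MeanComponents(M=M_s, m=m, v=base.v, E_AA=E_AA, E_AD=E_AD, E_DA=E_DA,
                          E_DD=E_DD, d=d, F=F)


def heterosis(popA: PopulationSpec, popB: PopulationSpec, trait: TraitModel,
              genome: GenomeMap) -> float:
    """Heterosis H*_jj' = M_jj' - (M_j + M_j') / 2 from parametric means."""
    MA = population_mean(popA, trait, genome).M
    MB = population_mean(popB, trait, genome).M
    Mx = cross_mean(popA, popB, trait, genome).M
    return Mx - 0.5 * (MA + MB)
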