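"""Populations with target allele frequencies and linkage disequilibrium.

A population is described parametrically by the gamete pools that form its
individuals.  A pool carries the per-gene frequency of the trait-increasing
allele and, when the population was built by crossing two linkage-
equilibrium founders, the founder frequency difference from which every
pairwise gametic LD value follows:

    Delta_ab(-1) = [(1 - 2 r_ab) / 4] (p_a1 - p_a2)(p_b1 - p_b2)

Each extra round of meiosis (producing gametes from the current
individuals) decays the LD by the factor (1 - r_ab).  Individuals are
always formed by random union of one gamete from each pool; selfing is
tracked as a number of selfing generations applied to that base and is
resolved either by exact two-locus recursion (parametric work) or by
simulated selfing (individual sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .genome import GenomeMap

__all__ = [
    "GametePool",
    "PopulationSpec",
    "GenotypeMatrix",
    "DHLine",
    "sample_allele_freqs",
    "le_population",
    "make_ld_population",
    "two_locus_genotype_freqs",
    "sample_individuals",
    "cross_populations",
    "self_population",
    "derive_dh",
    "haplotype_freqs",
    "zygote_table",
    "selfing_recursion",
]


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def sample_allele_freqs(target_mean, concentration, n_genes, seed=None):
    """Draw per-gene allele frequencies from a beta distribution.

    The beta parameters are ``alpha = mean * concentration`` and
    ``beta = (1 - mean) * concentration`` so that the expectation equals
    ``target_mean``; the concentration controls the spread around it.
    """
    if not 0.0 < target_mean < 1.0:
        raise ValueError("target_mean must be strictly inside (0, 1)")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    return rng.beta(target_mean * concentration, (1.0 - target_mean) * concentration, n_genes)


# ---------------------------------------------------------------------------
# parametric specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GametePool:
    """A gamete pool: per-gene frequencies plus the LD bookkeeping.

    ``meioses`` counts rounds of meiosis since the founder F1: the pool
    that forms generation 0 of an LD population has ``meioses = 1`` and
    LD ``Delta(-1)``; gametes produced by generation-0 individuals have
    ``meioses = 2`` and LD ``Delta(0) = (1 - r) Delta(-1)``.
    """

    p: np.ndarray
    founder_diff: Optional[np.ndarray] = None  # p1 - p2, None => linkage equilibrium
    meioses: int = 1

    def delta(self, i, j, genome: GenomeMap):
        """Parametric gametic LD between genes ``i`` and ``j``."""
        if self.founder_diff is None:
            return np.zeros(np.broadcast(np.asarray(i), np.asarray(j)).shape) if np.ndim(i) else 0.0
        r = genome.r_pairs(np.atleast_1d(i), np.atleast_1d(j))
        u = self.founder_diff
        d = (1.0 - 2.0 * r) / 4.0 * u[np.atleast_1d(i)] * u[np.atleast_1d(j)]
        d *= (1.0 - r) ** (self.meioses - 1)
        return d if np.ndim(i) else float(d[0])

    def advanced(self) -> "GametePool":
        """The pool of gametes produced by individuals formed from this pool."""
        return replace(self, meioses=self.meioses + 1)


@dataclass(frozen=True)
class PopulationSpec:
    """Parametric description of a population.

    Individuals are the random union of one gamete from ``pool_m`` and one
    from ``pool_f`` (identical pools for a panmictic population, distinct
    pools for an interpopulation F1), followed by ``selfing_generations``
    rounds of selfing.
    """

    pool_m: GametePool
    pool_f: GametePool
    selfing_generations: int = 0

    @property
    def p(self) -> np.ndarray:
        """Per-gene frequency of the trait-increasing allele."""
        return 0.5 * (self.pool_m.p + self.pool_f.p)

    @property
    def n_genes(self) -> int:
        return self.pool_m.p.size

    @property
    def F(self) -> float:
        """Inbreeding coefficient, 1 - (1/2)^n after n selfing generations."""
        return 1.0 - 0.5 ** self.selfing_generations

    @property
    def is_panmictic(self) -> bool:
        return self.pool_m is self.pool_f or (
            self.pool_m.meioses == self.pool_f.meioses
            and np.array_equal(self.pool_m.p, self.pool_f.p)
            and (
                (self.pool_m.founder_diff is None and self.pool_f.founder_diff is None)
                or (
                    self.pool_m.founder_diff is not None
                    and self.pool_f.founder_diff is not None
                    and np.array_equal(self.pool_m.founder_diff, self.pool_f.founder_diff)
                )
            )
        )

    def delta(self, i, j, genome: GenomeMap):
        """Gametic LD of the pools that formed the population.

        For a panmictic population this is the single pool value
        ``Delta(-1)``; for a cross it is the average of the two pools.
        """
        return 0.5 * (self.pool_m.delta(i, j, genome) + self.pool_f.delta(i, j, genome))

    def output_pool(self, genome: GenomeMap = None) -> GametePool:
        """The gamete pool produced by this population's individuals."""
        if self.selfing_generations:
            raise NotImplementedError("gamete pool of a selfed population is not parametrised")
        if not self.is_panmictic:
            raise NotImplementedError("gamete pool of a non-panmictic population is not parametrised")
        return self.pool_m.advanced()


def le_population(p) -> PopulationSpec:
    """Population in Hardy-Weinberg and linkage equilibrium."""
    pool = GametePool(np.asarray(p, dtype=float))
    return PopulationSpec(pool, pool)


def make_ld_population(p1, p2, genome: GenomeMap = None) -> PopulationSpec:
    """Population in LD built by crossing two LE founders and one random cross.

    The resulting allele frequencies are ``(p1 + p2) / 2`` and the gametic
    LD is ``[(1 - 2 r) / 4](p1_i - p2_i)(p1_j - p2_j)``.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("founder frequency vectors must have the same length")
    pool = GametePool(0.5 * (p1 + p2), founder_diff=p1 - p2, meioses=1)
    return PopulationSpec(pool, pool)


# ---------------------------------------------------------------------------
# two-locus machinery
# ---------------------------------------------------------------------------

def haplotype_freqs(pa, pb, delta) -> np.ndarray:
    """2x2 haplotype frequency table ``H[c_a, c_b]`` (c = allele count).

    ``H[1, 1]`` is the coupling haplotype carrying both trait-increasing
    alleles.  Raises if ``delta`` violates the Lewontin bounds.
    """
    qa, qb = 1.0 - pa, 1.0 - pb
    H = np.array(
        [
            [qa * qb + delta, qa * pb - delta],
            [pa * qb - delta, pa * pb + delta],
        ]
    )
    if np.any(H < -1e-12):
        raise ValueError(f"LD value {delta} outside the admissible bounds for ({pa}, {pb})")
    return np.clip(H, 0.0, None)


def zygote_table(H1: np.ndarray, H2: np.ndarray) -> np.ndarray:
    """3x3 genotype probabilities from the random union of two gamete pools.

    ``f[i, k]`` is the probability of carrying ``i`` trait-increasing
    alleles at the first gene and ``k`` at the second.
    """
    f = np.zeros((3, 3))
    for ca in range(2):
        for cb in range(2):
            for da in range(2):
                for db in range(2):
                    f[ca + da, cb + db] += H1[ca, cb] * H2[da, db]
    return f


def two_locus_genotype_freqs(pa, pb, delta) -> np.ndarray:
    """3x3 genotype table of a panmictic population with gametic LD ``delta``.

    For example ``f[2, 2] = pa^2 pb^2 + 2 pa pb delta + delta^2``.
    """
    H = haplotype_freqs(pa, pb, delta)
    return zygote_table(H, H)


# Haplotypes indexed 0..3 as (c_a, c_b) = (h >> 1, h & 1).
_HAP_CA = np.array([0, 0, 1, 1])
_HAP_CB = np.array([0, 1, 0, 1])


def _selfing_gamete_kernel(r: float) -> np.ndarray:
    """``g[h1, h2, h]``: gamete distribution of an individual ``(h1, h2)``."""
    g = np.zeros((4, 4, 4))
    for h1 in range(4):
        for h2 in range(4):
            g[h1, h2, h1] += (1.0 - r) / 2.0
            g[h1, h2, h2] += (1.0 - r) / 2.0
            rec1 = (_HAP_CA[h1] << 1) | _HAP_CB[h2]
            rec2 = (_HAP_CA[h2] << 1) | _HAP_CB[h1]
            g[h1, h2, rec1] += r / 2.0
            g[h1, h2, rec2] += r / 2.0
    return g


def selfing_recursion(H: np.ndarray, r: float, n_gen: int) -> np.ndarray:
    """Exact 3x3 genotype table after ``n_gen`` selfing generations.

    Starts from the random union of two gametes from pool ``H`` (2x2
    haplotype table) and iterates the phased two-locus genotype
    distribution (ordered haplotype pairs, 16 states) under selfing with
    recombination fraction ``r``.
    """
    if n_gen < 0:
        raise ValueError("n_gen must be >= 0")
    hvec = np.array([H[_HAP_CA[h], _HAP_CB[h]] for h in range(4)])
    S = np.outer(hvec, hvec)  # ordered pairs
    g = _selfing_gamete_kernel(r)
    for _ in range(n_gen):
        S = np.einsum("ij,ijk,ijl->kl", S, g, g)
    f = np.zeros((3, 3))
    for h1 in range(4):
        for h2 in range(4):
            f[_HAP_CA[h1] + _HAP_CA[h2], _HAP_CB[h1] + _HAP_CB[h2]] += S[h1, h2]
    return f


# ---------------------------------------------------------------------------
# individual sampling
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Phased genotypes: ``haplotypes[individual, gene, 0|1]`` in {0, 1}."""

    haplotypes: np.ndarray

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[2] != 2:
            raise ValueError("haplotypes must have shape (n, n_genes, 2)")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_genes(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def dosage(self) -> np.ndarray:
        """Allele dosage in {0, 1, 2}, shape (n, n_genes)."""
        return self.haplotypes.sum(axis=2, dtype=np.int8)

    def allele_freqs(self) -> np.ndarray:
        return self.dosage.mean(axis=0) / 2.0

    def write(self, path, genome_file=None, seed=None, phased=False) -> None:
        """Write a delimited dosage table (individuals x genes).

        A '#'-prefixed header records the genome file and seed when given.
        With ``phased=True`` two columns per gene are written instead.
        """
        import pandas as pd

        if phased:
            n, g, _ = self.haplotypes.shape
            data = self.haplotypes.reshape(n, 2 * g)  # two adjacent columns per gene
        else:
            data = self.dosage
        with open(path, "w") as fh:
            if genome_file is not None:
                fh.write(f"# genome={genome_file}\n")
            if seed is not None:
                fh.write(f"# seed={seed}\n")
            fh.write(f"# phased={phased}\n")
            pd.DataFrame(data).to_csv(fh, sep="\t", index=False, header=False)

    @classmethod
    def read(cls, path) -> "GenotypeMatrix":
        """Read a phased genotype table written with ``write(phased=True)``."""
        import pandas as pd

        data = pd.read_csv(path, sep="\t", comment="#", header=None).to_numpy(dtype=np.int8)
        n, two_g = data.shape
        return cls(data.reshape(n, two_g // 2, 2))


@dataclass(frozen=True)
class DHLine:
    """A doubled haploid: one gamete doubled into a fully homozygous line."""

    haplotype: np.ndarray

    @property
    def dosage(self) -> np.ndarray:
        return 2 * np.asarray(self.haplotype, dtype=np.int8)


def meiosis(h1: np.ndarray, h2: np.ndarray, genome: GenomeMap, rng) -> np.ndarray:
    """Vectorised meiosis: one gamete per row of the haplotype pair.

    The parental origin switches between consecutive genes with the
    adjacent recombination fraction (two-state Markov chain, equivalent to
    Poisson-distributed crossovers with uniform positions).
    """
    n = h1.shape[0]
    out = np.empty_like(h1)
    for sl, adj in genome.chromosome_slices():
        nloc = sl.stop - sl.start
        bits = np.empty((n, nloc), dtype=bool)
        bits[:, 0] = rng.random(n) < 0.5
        if nloc > 1:
            bits[:, 1:] = rng.random((n, nloc - 1)) < adj
        origin = np.bitwise_xor.accumulate(bits, axis=1)
        out[:, sl] = np.where(origin, h1[:, sl], h2[:, sl])
    return out


def _sample_pool_gametes(pool: GametePool, genome: GenomeMap, n: int, rng) -> np.ndarray:
    """Sample ``n`` gametes (n, n_genes) from a parametric gamete pool."""
    if pool.founder_diff is None:
        return (rng.random((n, pool.p.size)) < pool.p).astype(np.int8)
    if pool.meioses == 1:
        p1 = np.clip(pool.p + 0.5 * pool.founder_diff, 0.0, 1.0)
        p2 = np.clip(pool.p - 0.5 * pool.founder_diff, 0.0, 1.0)
        h1 = (rng.random((n, pool.p.size)) < p1).astype(np.int8)
        h2 = (rng.random((n, pool.p.size)) < p2).astype(np.int8)
        return meiosis(h1, h2, genome, rng)
    sub = replace(pool, meioses=pool.meioses - 1)
    g1 = _sample_pool_gametes(sub, genome, n, rng)
    g2 = _sample_pool_gametes(sub, genome, n, rng)
    return meiosis(g1, g2, genome, rng)


def sample_individuals(pop: PopulationSpec, genome: GenomeMap, n: int, seed=None) -> GenotypeMatrix:
    """Sample ``n`` individuals by random union of gametes (plus selfing).

    Realised per-gene frequencies and pairwise LD converge to the
    parametric values of the specification as ``n`` grows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    g1 = _sample_pool_gametes(pop.pool_m, genome, n, rng)
    g2 = _sample_pool_gametes(pop.pool_f, genome, n, rng)
    for _ in range(pop.selfing_generations):
        new1 = meiosis(g1, g2, genome, rng)
        new2 = meiosis(g1, g2, genome, rng)
        g1, g2 = new1, new2
    return GenotypeMatrix(np.stack([g1, g2], axis=2))


def cross_populations(popA: PopulationSpec, popB: PopulationSpec, genome: GenomeMap = None) -> PopulationSpec:
    """The interpopulation F1: one gamete from each parent population.

    Each parental gamete pool reflects one further meiosis, so its LD is
    ``Delta(0) = (1 - r) Delta(-1)``.
    """
    return PopulationSpec(popA.output_pool(genome), popB.output_pool(genome))


def self_population(pop: PopulationSpec, n_gen: int = 1) -> PopulationSpec:
    """The population after ``n_gen`` additional selfing generations."""
    if n_gen < 1:
        raise ValueError("n_gen must be >= 1")
    return replace(pop, selfing_generations=pop.selfing_generations + n_gen)


def derive_dh(pop: PopulationSpec, genome: GenomeMap, n_dh: int, seed=None) -> list:
    """Derive doubled haploids: one random gamete per random individual.

    Each DH doubles a single meiotic product of an individual sampled from
    the population, so it is fully homozygous and its expected allele
    frequency at every gene equals the population frequency.
    """
    if n_dh < 1:
        raise ValueError("n_dh must be >= 1")
    rng = np.random.default_rng(seed)
    inds = sample_individuals(pop, genome, n_dh, rng)
    gam = meiosis(inds.haplotypes[:, :, 0], inds.haplotypes[:, :, 1], genome, rng)
    return [DHLine(gam[i].copy()) for i in range(n_dh)]
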