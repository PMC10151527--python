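"""Trait architecture: additive/dominance gene effects and digenic epistasis.

Each gene contributes a midpoint value ``m``, a homozygote deviation ``a``
(value of the favourable homozygote above the midpoint) and a dominance
deviation ``d``; the per-gene values are scaled so that the worst and best
full homozygotes hit a configured range (e.g. 30 and 160 g/plant).

Digenic epistasis is specified by classical two-locus patterns named after
their F2 segregation ratios (complementary 9:7, duplicate 15:1, dominant
12:3:1, recessive 9:3:4, dominant-and-recessive 13:3, duplicate genes with
cumulative effects 9:6:1, non-epistatic genic interaction 9:3:3:1).  For a
pair of interacting genes the joint genotypic value is

    G_ik = locus_value_A(i) + locus_value_B(k) + I_ik

where ``I_ik`` is the epistatic deviation for ``i`` and ``k`` copies of the
trait-increasing alleles.  The magnitude of the epistasis is controlled by
the ratio V(I)/(V(A) + V(D)): the deviation of the double homozygote,
``I22``, is drawn from N(0, V(I)), and the remaining deviations are the
minimum-norm solution consistent with the type's equality pattern.

The module also provides the frequency-weighted orthogonal (Kempthorne
style) decomposition of a 3x3 genotypic table into mean, additive,
dominance, and the four epistatic effect surfaces (additive x additive,
additive x dominance, dominance x additive, dominance x dominance), whose
frequency-weighted marginal sums vanish, making the expectation of the
AD and DA effects zero in any non-inbred population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EPISTASIS_TYPES",
    "F2_RATIOS",
    "GeneEffect",
    "EpistaticPair",
    "TraitModel",
    "PairEffects",
    "assign_gene_effects",
    "pair_epistatic_genes",
    "epistatic_variance_target",
    "build_epistasis_table",
    "kempthorne_decompose",
    "composite_aa",
    "composite_dd",
    "genotypic_value",
    "phenotype",
    "f2_class_ratio",
]


# Equality classes of the 3x3 genotypic table, keyed by (i, k) dosage pairs.
# The first class always contains the double homozygote (2, 2).
_P = {
    "complementary": [
        {(2, 2), (2, 1), (1, 2), (1, 1)},
        {(2, 0), (1, 0), (0, 2), (0, 1), (0, 0)},
    ],
    "duplicate": [
        {(2, 2), (2, 1), (2, 0), (1, 2), (1, 1), (1, 0), (0, 2), (0, 1)},
        {(0, 0)},
    ],
    "dominant": [
        {(2, 2), (2, 1), (2, 0), (1, 2), (1, 1), (1, 0)},
        {(0, 2), (0, 1)},
        {(0, 0)},
    ],
    "recessive": [
        {(2, 2), (2, 1), (1, 2), (1, 1)},
        {(0, 2), (0, 1)},
        {(2, 0), (1, 0), (0, 0)},
    ],
    "dominant_and_recessive": [
        {(2, 2), (2, 1), (1, 2), (1, 1), (2, 0), (1, 0), (0, 0)},
        {(0, 2), (0, 1)},
    ],
    "duplicate_cumulative": [
        {(2, 2), (2, 1), (1, 2), (1, 1)},
        {(2, 0), (1, 0), (0, 2), (0, 1)},
        {(0, 0)},
    ],
    "non_epistatic_interaction": [
        {(2, 2), (2, 1), (1, 2), (1, 1)},
        {(2, 0), (1, 0)},
        {(0, 2), (0, 1)},
        {(0, 0)},
    ],
}

EPISTASIS_TYPES = tuple(_P)

#: Expected F2 phenotypic-class ratio (in sixteenths) of a dihybrid self at
#: r = 0.5, ordered with the class containing the double homozygote first.
F2_RATIOS = {
    "complementary": (9, 7),
    "duplicate": (15, 1),
    "dominant": (12, 3, 1),
    "recessive": (9, 3, 4),
    "dominant_and_recessive": (13, 3),
    "duplicate_cumulative": (9, 6, 1),
    "non_epistatic_interaction": (9, 3, 3, 1),
}


@dataclass(frozen=True)
class GeneEffect:
    """Single-gene genotypic parameters (g/plant)."""

    gene_id: int
    m: float
    a: float
    d: float

    @property
    def degree(self) -> float:
        """Degree of dominance d/a."""
        return self.d / self.a

    @property
    def locus_values(self) -> np.ndarray:
        """Genotypic value by dosage (0, 1, 2): (m - a, m + d, m + a)."""
        return np.array([self.m - self.a, self.m + self.d, self.m + self.a])


@dataclass
class EpistaticPair:
    """A pair of interacting genes with its 3x3 epistatic deviation table."""

    gene_a: int
    gene_b: int
    type: str
    I: np.ndarray  # (3, 3), [dosage_a, dosage_b]
    ratio: float
    v_i: float  # the epistatic variance target V(I) used for the I22 draw

    def __post_init__(self):
        self.I = np.asarray(self.I, dtype=float)
        if self.I.shape != (3, 3):
            raise ValueError("I table must be 3x3")


@dataclass
class TraitModel:
    """Per-gene effects plus disjoint epistatic pair assignments."""

    genes: Sequence[GeneEffect]
    pairs: Sequence[EpistaticPair] = field(default_factory=list)

    def __post_init__(self):
        used = [g for p in self.pairs for g in (p.gene_a, p.gene_b)]
        if len(used) != len(set(used)):
            raise ValueError("epistatic pairs must be disjoint")
        self.m_vec = np.array([g.m for g in self.genes])
        self.a_vec = np.array([g.a for g in self.genes])
        self.d_vec = np.array([g.d for g in self.genes])
        # locus value lookup, shape (n_genes, 3) indexed by dosage
        self.locus_values = np.stack([g.locus_values for g in self.genes])
        paired = set(used)
        self.unpaired = np.array(
            [g.gene_id for g in self.genes if g.gene_id not in paired], dtype=np.int64
        )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def m_total(self) -> float:
        """Sum of homozygote midpoints over genes."""
        return float(self.m_vec.sum())

    def pair_table(self, pair: EpistaticPair) -> np.ndarray:
        """Joint genotypic value table of a pair (locus values + I)."""
        la = self.locus_values[pair.gene_a]
        lb = self.locus_values[pair.gene_b]
        return la[:, None] + lb[None, :] + pair.I

    # -- serialisation -----------------------------------------------------
    def write(self, genes_path, pairs_path) -> None:
        ge = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "m": self.m_vec,
                "a": self.a_vec,
                "d": self.d_vec,
            }
        )
        ge.to_csv(genes_path, sep="\t", index=False, float_format="%.17g")
        rows = []
        for p in self.pairs:
            row = {"gene_a": p.gene_a, "gene_b": p.gene_b, "type": p.type,
                   "ratio": p.ratio, "v_i": p.v_i}
            for i in range(3):
                for k in range(3):
                    row[f"I{i}{k}"] = p.I[i, k]
            rows.append(row)
        cols = ["gene_a", "gene_b", "type", "ratio", "v_i"] + [
            f"I{i}{k}" for i in range(3) for k in range(3)
        ]
        pd.DataFrame(rows, columns=cols).to_csv(
            pairs_path, sep="\t", index=False, float_format="%.17g"
        )

    @classmethod
    def read(cls, genes_path, pairs_path) -> "TraitModel":
        ge = pd.read_csv(genes_path, sep="\t", float_precision="round_trip")
        genes = [
            GeneEffect(int(r.gene_id), float(r.m), float(r.a), float(r.d))
            for r in ge.itertuples()
        ]
        pe = pd.read_csv(pairs_path, sep="\t", float_precision="round_trip")
        pairs = []
        for r in pe.itertuples():
            I = np.array([[getattr(r, f"I{i}{k}") for k in range(3)] for i in range(3)])
            pairs.append(
                EpistaticPair(int(r.gene_a), int(r.gene_b), str(r.type), I,
                              float(r.ratio), float(r.v_i))
            )
        return cls(genes, pairs)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def assign_gene_effects(
    n_genes: int,
    min_hom: float,
    max_hom: float,
    dom_mean: float = 0.6,
    dom_range=(0.1, 1.2),
    direction: str = "positive",
    seed=None,
    a_distribution: str = "equal",
) -> list:
    """Assign per-gene m, a, d such that the homozygote totals match.

    The worst full homozygote sums to ``min_hom`` and the best to
    ``max_hom``: per gene, sum(m - a) = min_hom and sum(m + a) = max_hom.
    Degrees of dominance d/a are drawn from a beta distribution rescaled
    to ``dom_range`` with mean exactly ``dom_mean``; under positive
    dominance every d is non-negative.
    """
    if min_hom >= max_hom:
        raise ValueError("min_hom must be < max_hom")
    lo, hi = dom_range
    if hi < lo or lo < 0:
        raise ValueError("dominance range must be non-negative and ordered")
    if not lo <= dom_mean <= hi:
        raise ValueError("dom_mean must lie within dom_range")
    rng = np.random.default_rng(seed)

    m_i = np.full(n_genes, (max_hom + min_hom) / (2.0 * n_genes))
    if a_distribution == "equal":
        a_i = np.full(n_genes, (max_hom - min_hom) / (2.0 * n_genes))
    elif a_distribution == "gamma":
        raw = rng.gamma(2.0, 1.0, n_genes)
        a_i = raw / raw.sum() * (max_hom - min_hom) / 2.0
    else:
        raise ValueError(f"unknown a_distribution {a_distribution!r}")

    if hi == lo:
        deg = np.full(n_genes, lo)
    else:
        mu = (dom_mean - lo) / (hi - lo)
        conc = 2.0  # mildly informative: keeps the whole range reachable
        deg = lo + (hi - lo) * rng.beta(mu * conc, (1.0 - mu) * conc, n_genes)
    d_i = deg * a_i
    if direction == "negative":
        d_i = -d_i
    elif direction != "positive":
        raise ValueError("direction must be 'positive' or 'negative'")
    return [GeneEffect(i, m_i[i], a_i[i], d_i[i]) for i in range(n_genes)]


def pair_epistatic_genes(gene_ids, fraction: float, seed=None) -> list:
    """Pair a random ``fraction`` of the genes into disjoint epistatic pairs."""
    gene_ids = np.asarray(gene_ids)
    n_sel = int(round(fraction * gene_ids.size))
    if n_sel % 2:
        raise ValueError("fraction * n_genes must be an even count of genes")
    if n_sel == 0:
        return []
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(gene_ids)[:n_sel]
    return [(int(chosen[2 * i]), int(chosen[2 * i + 1])) for i in range(n_sel // 2)]


def _single_locus_variances(a, d, p):
    q = 1.0 - p
    alpha = a + (q - p) * d
    va = 2.0 * p * q * alpha**2
    vd = (2.0 * p * q * d) ** 2
    return va, vd


def epistatic_variance_target(gene_a: GeneEffect, gene_b: GeneEffect,
                              pa: float, pb: float, ratio: float) -> float:
    """Target epistatic variance V(I) = ratio * (V(A) + V(D)) for a pair.

    V(A) and V(D) are the two-locus additive and dominance variances at the
    reference frequencies assuming linkage equilibrium (single-locus
    formulas summed over the pair).
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    va1, vd1 = _single_locus_variances(gene_a.a, gene_a.d, pa)
    va2, vd2 = _single_locus_variances(gene_b.a, gene_b.d, pb)
    return ratio * (va1 + vd1 + va2 + vd2)


def build_epistasis_table(
    type: str,
    gene_a: GeneEffect,
    gene_b: GeneEffect,
    pa: float = 0.5,
    pb: float = 0.5,
    ratio: float = 1.0,
    seed=None,
    max_retries: int = 100,
) -> EpistaticPair:
    """Build the epistatic deviation table of a pair for a given type.

    Draws ``I22 ~ N(0, V(I))`` with ``V(I)`` from
    :func:`epistatic_variance_target`, then fills in the remaining
    deviations as the minimum-norm table satisfying the type's equality
    pattern: the class containing the double homozygote takes the value
    ``N22 + I22`` and every other class takes the mean of the
    additive-dominance baseline ``N_ik`` over its cells, which minimises
    the sum of squared deviations.  A draw that collapses two classes onto
    the same genotypic value (destroying the type's F2 ratio) is
    resampled.
    """
    if type not in _P:
        raise ValueError(f"unknown epistasis type {type!r}")
    rng = np.random.default_rng(seed)
    v_i = epistatic_variance_target(gene_a, gene_b, pa, pb, ratio)
    N = gene_a.locus_values[:, None] + gene_b.locus_values[None, :]
    classes = _P[type]
    scale = max(abs(N).max(), 1.0)
    free = [float(np.mean([N[i, k] for (i, k) in cells]))
            for cells in classes if (2, 2) not in cells]
    if v_i == 0.0:
        # a forced zero draw is admissible only if the baseline already
        # satisfies the pattern (all I_ik = 0)
        ok = all(
            np.ptp([N[i, k] for (i, k) in cells]) < 1e-12 * scale for cells in classes
        )
        if not ok:
            raise ValueError(
                "V(I) = 0 but the additive-dominance baseline does not satisfy "
                f"the {type} pattern; no epistatic table exists"
            )
    for _ in range(max_retries):
        i22 = rng.normal(0.0, np.sqrt(v_i)) if v_i > 0 else 0.0
        anchored = N[2, 2] + i22
        # only a collision of the anchored class with a free class can be
        # resolved by resampling; coinciding free classes reflect the gene
        # parameters themselves (e.g. 9:3:3:1 with identical gene effects)
        if any(abs(anchored - v) < 1e-9 * scale for v in free) and v_i > 0:
            continue
        values = []
        it = iter(free)
        for cells in classes:
            values.append(anchored if (2, 2) in cells else next(it))
        G = np.empty((3, 3))
        for c, cells in enumerate(classes):
            for (i, k) in cells:
                G[i, k] = values[c]
        return EpistaticPair(gene_a.gene_id, gene_b.gene_id, type, G - N, ratio, v_i)
    raise RuntimeError(
        f"could not build a non-degenerate {type} table after {max_retries} draws"
    )


def f2_class_ratio(G: np.ndarray, decimals: int = 9):
    """Phenotypic-class frequencies (sixteenths) of a dihybrid F2.

    Enumerates the self of a double heterozygote under independent
    assortment (dosage probabilities 1:2:1 at each locus), groups the nine
    genotypes by distinct value of ``G``, and returns the sixteenths per
    class ordered with the class containing the double homozygote (2, 2)
    first, then by decreasing count.
    """
    w = np.array([1, 2, 1])
    weight = np.outer(w, w)  # sums to 16
    scale = max(np.abs(G).max(), 1.0)
    key = np.round(G / scale, decimals)
    classes = {}
    for i in range(3):
        for k in range(3):
            classes.setdefault(key[i, k], 0)
            classes[key[i, k]] += int(weight[i, k])
    top = key[2, 2]
    rest = sorted((v for k, v in classes.items() if k != top), reverse=True)
    return tuple([classes[top]] + rest)


# ---------------------------------------------------------------------------
# orthogonal decomposition
# ---------------------------------------------------------------------------

@dataclass
class PairEffects:
    """Frequency-weighted orthogonal decomposition of a 3x3 table.

    Surfaces are indexed by dosage (axis 0: gene A, axis 1: gene B) and
    reconstruct the table exactly:

        G = mu + additive_a + dominance_a + additive_b + dominance_b
            + aa_surface + ad_surface + da_surface + dd_surface

    ``aa`` and ``dd`` are the composite scalars entering the closed-form
    mean components E(AA) = 2 Delta (aa) and E(DD) = Delta^2 (dd).
    """

    pa: float
    pb: float
    mu: float
    additive_a: np.ndarray  # (3,), c_A * x_A by dosage
    dominance_a: np.ndarray  # (3,), dominance deviations at A
    additive_b: np.ndarray
    dominance_b: np.ndarray
    aa_surface: np.ndarray  # (3, 3)
    ad_surface: np.ndarray
    da_surface: np.ndarray
    dd_surface: np.ndarray
    aa: float
    dd: float

    def reconstruct(self) -> np.ndarray:
        one = np.ones(3)
        return (
            self.mu
            + np.outer(self.additive_a + self.dominance_a, one)
            + np.outer(one, self.additive_b + self.dominance_b)
            + self.aa_surface
            + self.ad_surface
            + self.da_surface
            + self.dd_surface
        )


def _hwe_weights(p):
    q = 1.0 - p
    return np.stack([q * q, 2.0 * p * q, p * p], axis=-1)


def _additive_contrast(p):
    # dosage minus its mean 2p
    return np.stack([-2.0 * p, 1.0 - 2.0 * p, 2.0 - 2.0 * p], axis=-1)


def _dominance_contrast(p):
    # orthogonal to {1, x} under HWE weights
    q = 1.0 - p
    return np.stack([-2.0 * p * p, 2.0 * p * q, -2.0 * q * q], axis=-1)


_DD_COMB = np.array([[1.0, -2.0, 1.0], [-2.0, 4.0, -2.0], [1.0, -2.0, 1.0]])


def decompose_tables(G: np.ndarray, pa: np.ndarray, pb: np.ndarray) -> dict:
    """Batched orthogonal decomposition of tables ``G`` (n, 3, 3).

    Returns a dict of arrays; see :class:`PairEffects` for the meaning of
    each entry.  Used internally by the closed-form mean machinery, where
    every epistatic pair is decomposed at its population's frequencies in
    one shot.
    """
    G = np.asarray(G, dtype=float)
    pa = np.atleast_1d(np.asarray(pa, dtype=float))
    pb = np.atleast_1d(np.asarray(pb, dtype=float))
    if np.any((pa <= 0) | (pa >= 1)) or np.any((pb <= 0) | (pb >= 1)):
        raise ValueError("frequencies must be strictly inside (0, 1)")
    wa, wb = _hwe_weights(pa), _hwe_weights(pb)
    xa, xb = _additive_contrast(pa), _additive_contrast(pb)
    va = 2.0 * pa * (1.0 - pa)  # = sum w x^2
    vb = 2.0 * pb * (1.0 - pb)

    mu = np.einsum("ni,nk,nik->n", wa, wb, G)
    rowm = np.einsum("nk,nik->ni", wb, G) - mu[:, None]
    colm = np.einsum("ni,nik->nk", wa, G) - mu[:, None]
    ca = np.einsum("ni,ni,ni->n", wa, xa, rowm) / va
    cb = np.einsum("nk,nk,nk->n", wb, xb, colm) / vb
    add_a = ca[:, None] * xa
    add_b = cb[:, None] * xb
    dom_a = rowm - add_a
    dom_b = colm - add_b

    R = G - mu[:, None, None] - rowm[:, :, None] - colm[:, None, :]
    aa = np.einsum("ni,ni,nk,nk,nik->n", wa, xa, wb, xb, R) / (va * vb)
    ha = np.einsum("ni,ni,nik->nk", wa, xa, R) / va[:, None] - aa[:, None] * xb
    hb = np.einsum("nk,nk,nik->ni", wb, xb, R) / vb[:, None] - aa[:, None] * xa
    aa_surface = aa[:, None, None] * xa[:, :, None] * xb[:, None, :]
    ad_surface = xa[:, :, None] * ha[:, None, :]
    da_surface = hb[:, :, None] * xb[:, None, :]
    dd_surface = R - aa_surface - ad_surface - da_surface
    dd = np.einsum("ik,nik->n", _DD_COMB, dd_surface)
    return {
        "mu": mu,
        "additive_a": add_a,
        "dominance_a": dom_a,
        "additive_b": add_b,
        "dominance_b": dom_b,
        "aa_surface": aa_surface,
        "ad_surface": ad_surface,
        "da_surface": da_surface,
        "dd_surface": dd_surface,
        "aa": aa,
        "dd": dd,
    }


def kempthorne_decompose(G: np.ndarray, pa: float, pb: float) -> PairEffects:
    """Orthogonal decomposition of one 3x3 genotypic table.

    The weights are the Hardy-Weinberg, linkage-equilibrium genotype
    probabilities at ``(pa, pb)``; the epistatic surfaces carry 4 degrees
    of freedom and have zero frequency-weighted marginal sums, and the
    decomposition is an exact re-parameterisation of the table.
    """
    d = decompose_tables(np.asarray(G)[None], [pa], [pb])
    return PairEffects(
        pa=pa,
        pb=pb,
        mu=float(d["mu"][0]),
        additive_a=d["additive_a"][0],
        dominance_a=d["dominance_a"][0],
        additive_b=d["additive_b"][0],
        dominance_b=d["dominance_b"][0],
        aa_surface=d["aa_surface"][0],
        ad_surface=d["ad_surface"][0],
        da_surface=d["da_surface"][0],
        dd_surface=d["dd_surface"][0],
        aa=float(d["aa"][0]),
        dd=float(d["dd"][0]),
    )


def composite_aa(effects: PairEffects) -> float:
    """The additive x additive composite (aa) of a decomposed pair."""
    return effects.aa


def composite_dd(effects: PairEffects) -> float:
    """The dominance x dominance composite (dd) of a decomposed pair."""
    return effects.dd


# ---------------------------------------------------------------------------
# genotypic and phenotypic values
# ---------------------------------------------------------------------------

def genotypic_value(dosages: np.ndarray, trait: TraitModel) -> np.ndarray:
    """Genotypic values G of individuals from their dosage rows.

    G is the sum of per-locus values plus the epistatic deviation of every
    declared pair at the individual's two-locus genotype.
    """
    dos = np.atleast_2d(np.asarray(dosages, dtype=np.int64))
    if dos.shape[1] != trait.n_genes:
        raise ValueError("dosage width must equal the number of genes")
    gene_idx = np.arange(trait.n_genes)
    G = trait.locus_values[gene_idx, dos].sum(axis=1)
    if trait.pairs:
        ia = np.array([p.gene_a for p in trait.pairs])
        ib = np.array([p.gene_b for p in trait.pairs])
        I = np.stack([p.I for p in trait.pairs])  # (P, 3, 3)
        G = G + I[np.arange(len(trait.pairs))[None, :], dos[:, ia], dos[:, ib]].sum(axis=1)
    return G if np.ndim(dosages) > 1 else float(G[0])


def phenotype(G: np.ndarray, heritability: float, bounds=(10.0, 180.0), seed=None) -> np.ndarray:
    """Phenotypes P = G + E with E ~ N(0, V_E) and truncation to bounds.

    The error variance is set from the realised genotypic variance so that
    V(G) / (V(G) + V_E) equals the requested broad-sense heritability.
    """
    if not 0.0 < heritability <= 1.0:
        raise ValueError("heritability must be in (0, 1]")
    G = np.asarray(G, dtype=float)
    rng = np.random.default_rng(seed)
    var_g = G.var()
    var_e = var_g * (1.0 - heritability) / heritability
    P = G + rng.normal(0.0, np.sqrt(var_e), G.shape)
    if bounds is not None:
        P = np.clip(P, bounds[0], bounds[1])
    return P
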