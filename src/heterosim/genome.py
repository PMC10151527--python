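"""Simulated genome layout and recombination.

Genes are abstract biallelic loci placed at map positions (centimorgans, cM)
on chromosomes.  Map distance is converted to a recombination fraction with
the Haldane mapping function, i.e. crossovers form a Poisson process along
the chromosome with no interference.  The same model drives meiosis
sampling: the parental origin of consecutive genes is a two-state Markov
chain whose switch probability is the recombination fraction of the
adjacent-gene interval, which is distributionally identical to drawing a
Poisson number of crossovers with uniform positions and reading the genome
off at the gene positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeMap", "build_genome", "recomb_fraction"]


def recomb_fraction(distance_cM):
    """Haldane mapping function r = (1 - exp(-2 d / 100)) / 2.

    Parameters
    ----------
    distance_cM : float or array-like
        Map distance in centimorgans, >= 0.

    Returns
    -------
    Recombination fraction in [0, 0.5), same shape as the input.
    """
    d = np.asarray(distance_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return r if r.ndim else float(r)


@dataclass(frozen=True)
class GenomeMap:
    """Gene positions on chromosomes plus pairwise recombination fractions.

    Attributes
    ----------
    chrom_lengths : tuple of float
        Chromosome map lengths in cM.
    chrom_index : ndarray of int, shape (n_genes,)
        Chromosome of each gene (0-based), non-decreasing.
    positions : ndarray of float, shape (n_genes,)
        Map position of each gene within its chromosome, strictly
        increasing inside a chromosome and within [0, length].
    """

    chrom_lengths: tuple
    chrom_index: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)

    def __post_init__(self):
        chrom_index = np.asarray(self.chrom_index, dtype=np.int64)
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "chrom_index", chrom_index)
        object.__setattr__(self, "positions", positions)
        if chrom_index.shape != positions.shape or chrom_index.ndim != 1:
            raise ValueError("chrom_index and positions must be conformal 1-d arrays")
        if np.any(np.diff(chrom_index) < 0):
            raise ValueError("genes must be ordered by chromosome")
        for c, length in enumerate(self.chrom_lengths):
            pos = positions[chrom_index == c]
            if pos.size == 0:
                continue
            if np.any(pos < 0) or np.any(pos > length):
                raise ValueError(f"positions on chromosome {c} outside [0, {length}]")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions on chromosome {c} not strictly increasing")

    @property
    def n_genes(self) -> int:
        return self.positions.size

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths)

    def r(self, i: int, j: int) -> float:
        """Recombination fraction between genes ``i`` and ``j``.

        Zero for a gene with itself, 0.5 for genes on different
        chromosomes, Haldane of the map distance otherwise.
        """
        return float(self.r_pairs([i], [j])[0])

    def r_pairs(self, ii, jj) -> np.ndarray:
        """Vectorised :meth:`r` for index arrays ``ii`` and ``jj``."""
        ii = np.asarray(ii, dtype=np.int64)
        jj = np.asarray(jj, dtype=np.int64)
        same_chrom = self.chrom_index[ii] == self.chrom_index[jj]
        dist = np.abs(self.positions[ii] - self.positions[jj])
        r = np.where(same_chrom, recomb_fraction(dist), 0.5)
        r[ii == jj] = 0.0
        return r

    def chromosome_slices(self):
        """Yield ``(slice, adjacent_r)`` per chromosome.

        ``adjacent_r`` is the recombination-fraction vector between
        consecutive genes of the chromosome (length ``n_c - 1``).
        """
        out = []
        for c in range(self.n_chromosomes):
            idx = np.flatnonzero(self.chrom_index == c)
            if idx.size == 0:
                continue
            sl = slice(idx[0], idx[-1] + 1)
            adj = recomb_fraction(np.diff(self.positions[sl]))
            out.append((sl, np.atleast_1d(adj)))
        return out

    # -- serialisation -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chrom_index,
                "gene_id": np.arange(self.n_genes),
                "position_cM": self.positions,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, chrom_lengths=None) -> "GenomeMap":
        df = pd.read_csv(path, sep="\t")
        chrom = df["chromosome"].to_numpy()
        pos = df["position_cM"].to_numpy(dtype=float)
        if chrom_lengths is None:
            # infer: length of a chromosome is the largest observed position
            chrom_lengths = tuple(
                float(pos[chrom == c].max()) for c in range(int(chrom.max()) + 1)
            )
        return cls(tuple(chrom_lengths), chrom, pos)


def build_genome(n_chrom: int, chrom_length: float, genes_per_chrom: int) -> GenomeMap:
    """Build a genome with equally spaced genes on identical chromosomes.

    Genes are placed at ``linspace(0, chrom_length, genes_per_chrom)``
    (endpoints included); a single gene sits at position 0.

    Examples
    --------
    >>> g = build_genome(10, 200.0, 40)
    >>> g.n_genes
    400
    """
    if n_chrom < 1 or genes_per_chrom < 1:
        raise ValueError("n_chrom and genes_per_chrom must be >= 1")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    if genes_per_chrom == 1:
        pos_c = np.array([0.0])
    else:
        pos_c = np.linspace(0.0, chrom_length, genes_per_chrom)
    positions = np.tile(pos_c, n_chrom)
    chrom_index = np.repeat(np.arange(n_chrom), genes_per_chrom)
    return GenomeMap(tuple([float(chrom_length)] * n_chrom), chrom_index, positions)
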