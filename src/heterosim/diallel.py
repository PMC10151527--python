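"""Diallel decompositions: Gardner-Eberhart heterosis and Griffing combining ability.

All analyses operate on parametric genotypic-mean tables (no error term):

* Gardner-Eberhart (analysis II): the heterosis of each cross,
  H_jj' = M_jj' - (M_j + M_j')/2, is partitioned into average heterosis
  H*, variety heteroses H_j* (zero-sum) and specific heteroses S_jj'*
  (zero row sums), an exact re-parameterisation of the half-diallel.
* Griffing method 2 (parents + crosses): M_jj' = M.. + g_j* + g_j'* +
  s_jj'* with M.. the full-table mean; the restrictions sum g* = 0,
  per-row sum of SCA = 0, and sum s_jj* + 2 sum_pairs s_jj'* = 0 hold
  exactly.
* Griffing method 4 (crosses only, e.g. DH or inbred lines):
  least-squares GCA/SCA under sum g = 0; fitted plus residual reproduces
  every cross mean exactly.

The correlation metrics quantify how faithfully the decomposition effects
track the underlying allele frequencies: with purely additive-dominant
gene action the variety and GCA effects are perfectly correlated with the
mean frequency of the trait-increasing alleles, and epistasis can degrade
or invert those correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "DiallelMeans",
    "DecompositionReport",
    "GardnerEberhartResult",
    "GriffingResult",
    "gardner_eberhart",
    "griffing_method2",
    "griffing_method4",
    "correlation_metrics",
    "average_heterosis_percent",
]


@dataclass
class DiallelMeans:
    """Half-diallel mean table: parents, crosses and optional selfed parents."""

    crosses: np.ndarray  # (N, N) symmetric; diagonal ignored unless parents absent
    parents: Optional[np.ndarray] = None  # (N,) parent per-se means
    selfed: Optional[np.ndarray] = None  # (N,) selfed-parent means
    parent_ids: Optional[list] = None

    def __post_init__(self):
        self.crosses = np.asarray(self.crosses, dtype=float)
        n = self.crosses.shape[0]
        if self.crosses.shape != (n, n):
            raise ValueError("cross table must be square")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(self.crosses[off], self.crosses.T[off], equal_nan=True):
            raise ValueError("cross table must be symmetric")
        if self.parents is not None:
            self.parents = np.asarray(self.parents, dtype=float)
            if self.parents.shape != (n,):
                raise ValueError("parent means must have length N")
        if self.selfed is not None:
            self.selfed = np.asarray(self.selfed, dtype=float)
        if self.parent_ids is None:
            self.parent_ids = list(range(n))

    @property
    def n_parents(self) -> int:
        return self.crosses.shape[0]

    def full_table(self) -> np.ndarray:
        """Cross table with the diagonal filled by the parent means."""
        if self.parents is None:
            raise ValueError("parent means are required")
        T = self.crosses.copy()
        np.fill_diagonal(T, self.parents)
        return T

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.crosses, index=self.parent_ids, columns=self.parent_ids)
        return df

    @classmethod
    def read(cls, path) -> "DiallelMeans":
        """Read a delimited mean table (parents on the diagonal if present)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        T = df.to_numpy(dtype=float)
        diag = np.diag(T)
        parents = None if np.any(np.isnan(diag)) else diag.copy()
        return cls(T, parents=parents, parent_ids=list(df.index))


@dataclass
class GardnerEberhartResult:
    """Gardner-Eberhart heterosis components of a population diallel."""

    grand_parent_mean: float
    variety_effects: np.ndarray  # v*_j = M_j - mean of parents
    heterosis: np.ndarray  # (N, N) H_jj'*, nan diagonal
    average_heterosis: float  # H*
    variety_heterosis: np.ndarray  # H_j*, zero-sum
    specific_heterosis: np.ndarray  # (N, N) S_jj'*, zero row sums
    variety_heterosis_row_mean: np.ndarray  # plain row means of H_jj'* minus H*
    inbreeding_change: Optional[np.ndarray] = None  # d*_j = M_js - M_j

    def reconstruct(self) -> np.ndarray:
        """H* + H_j* + H_j'* + S_jj'* (equals the heterosis table)."""
        n = self.variety_heterosis.size
        H = (
            self.average_heterosis
            + self.variety_heterosis[:, None]
            + self.variety_heterosis[None, :]
            + self.specific_heterosis
        )
        np.fill_diagonal(H, np.nan)
        return H


@dataclass
class GriffingResult:
    """Combining-ability effects of a diallel (method 2 or method 4)."""

    method: str
    grand_mean: float
    gca: np.ndarray  # g*_j, zero-sum
    sca: np.ndarray  # (N, N); diagonal s_jj* for method 2, nan for method 4

    def reconstruct(self) -> np.ndarray:
        return self.grand_mean + self.gca[:, None] + self.gca[None, :] + self.sca

    @property
    def sca_self(self) -> np.ndarray:
        return np.diag(self.sca)


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def gardner_eberhart(means: DiallelMeans) -> GardnerEberhartResult:
    """Gardner-Eberhart analysis II of a population half-diallel.

    Requires parent means and at least three parents (the variety
    heterosis is otherwise unidentifiable).  The partition
    H_jj'* = H* + H_j* + H_j'* + S_jj'* is enforced with the zero-sum
    restrictions sum_j H_j* = 0 and sum_{j' != j} S_jj'* = 0 for every j,
    which makes the reconstruction exact.
    """
    if means.parents is None:
        raise ValueError("Gardner-Eberhart analysis requires parent means")
    n = means.n_parents
    if n < 3:
        raise ValueError("at least 3 parents are required")
    M = means.crosses
    P = means.parents
    off = _offdiag_mask(n)
    H = M - 0.5 * (P[:, None] + P[None, :])
    np.fill_diagonal(H, 0.0)
    row_sums = H.sum(axis=1)
    h_avg = row_sums.sum() / (n * (n - 1))  # mean over ordered (= unordered) pairs
    row_means = row_sums / (n - 1)
    h_j = (n - 1) / (n - 2) * (row_means - h_avg)
    S = H - h_avg - h_j[:, None] - h_j[None, :]
    np.fill_diagonal(S, np.nan)
    Hnan = H.copy()
    np.fill_diagonal(Hnan, np.nan)
    d_star = None if means.selfed is None else means.selfed - P
    return GardnerEberhartResult(
        grand_parent_mean=float(P.mean()),
        variety_effects=P - P.mean(),
        heterosis=Hnan,
        average_heterosis=float(h_avg),
        variety_heterosis=h_j,
        specific_heterosis=S,
        variety_heterosis_row_mean=row_means - h_avg,
        inbreeding_change=d_star,
    )


def griffing_method2(means: DiallelMeans) -> GriffingResult:
    """Griffing method 2 (parents and crosses, no reciprocals), model I.

    g_j* is the deviation of the row mean (diagonal included) from the
    full-table mean; the SCA table, including the parent-with-itself
    effects s_jj*, is the residual.
    """
    T = means.full_table()
    n = means.n_parents
    grand = T.mean()
    g = T.mean(axis=1) - grand
    s = T - grand - g[:, None] - g[None, :]
    return GriffingResult(method="2", grand_mean=float(grand), gca=g, sca=s)


def griffing_method4(crosses, n_parents: Optional[int] = None) -> GriffingResult:
    """Griffing method 4 (crosses only), model I, by least squares.

    Fits M_jj' = mu + g_j + g_j' + s_jj' to the C(N, 2) cross means under
    sum g = 0.  The solution of the normal equations is
    mu = mean of crosses and g_j = (N - 1)(rowmean_j - mu)/(N - 2); the
    SCA residuals then have zero row sums and reproduce the table exactly.
    """
    if isinstance(crosses, DiallelMeans):
        crosses = crosses.crosses
    T = np.asarray(crosses, dtype=float)
    n = T.shape[0] if n_parents is None else n_parents
    if n < 3:
        raise ValueError("at least 3 lines are required")
    off = _offdiag_mask(n)
    if np.any(np.isnan(T[off])):
        raise ValueError("all C(N,2) crosses must be present")
    mu = T[off].mean()
    row_means = T[off].reshape(n, n - 1).mean(axis=1)
    g = (n - 1) / (n - 2) * (row_means - mu)
    s = T - mu - g[:, None] - g[None, :]
    np.fill_diagonal(s, np.nan)
    return GriffingResult(method="4", grand_mean=float(mu), gca=g, sca=s)


# ---------------------------------------------------------------------------
# correlation metrics
# ---------------------------------------------------------------------------

@dataclass
class DecompositionReport:
    """Bundle of decomposition effects feeding the correlation metrics."""

    variety_effects: Optional[np.ndarray] = None
    heterosis: Optional[np.ndarray] = None  # (N, N)
    average_heterosis: Optional[float] = None
    variety_heterosis: Optional[np.ndarray] = None
    specific_heterosis: Optional[np.ndarray] = None  # (N, N)
    gca: Optional[np.ndarray] = None
    sca: Optional[np.ndarray] = None  # (N, N), diagonal used when present
    sca_self: Optional[np.ndarray] = None
    inbreeding_change: Optional[np.ndarray] = None

    @classmethod
    def from_results(cls, ge: Optional[GardnerEberhartResult] = None,
                     griffing: Optional[GriffingResult] = None) -> "DecompositionReport":
        rep = cls()
        if ge is not None:
            rep.variety_effects = ge.variety_effects
            rep.heterosis = ge.heterosis
            rep.average_heterosis = ge.average_heterosis
            rep.variety_heterosis = ge.variety_heterosis
            rep.specific_heterosis = ge.specific_heterosis
            rep.inbreeding_change = ge.inbreeding_change
        if griffing is not None:
            rep.gca = griffing.gca
            rep.sca = griffing.sca
            if griffing.method == "2":
                rep.sca_self = griffing.sca_self
        return rep


def _pearson(x: np.ndarray, y: np.ndarray):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        return np.nan, False
    return float(np.corrcoef(x, y)[0, 1]), True


def correlation_metrics(report: DecompositionReport, freqs: np.ndarray) -> pd.DataFrame:
    """Correlations between allele-frequency summaries and diallel effects.

    ``freqs`` holds the per-gene frequency of the trait-increasing allele
    for each parent (N x n_genes).  Four families are computed, where
    available in ``report``:

    1. mean frequency vs variety effect / GCA effect;
    2. mean absolute pairwise frequency difference vs heterosis,
       specific heterosis and SCA effect (off-diagonal pairs);
    3. mean absolute difference between a parent and the average of the
       other parents vs variety heterosis and |SCA of a parent with
       itself|;
    4. |mean frequency - 0.5| vs the inbreeding change d*.

    Pairs with zero variance on either side are flagged as undefined
    (NaN correlation).
    """
    freqs = np.asarray(freqs, dtype=float)
    n = freqs.shape[0]
    pbar = freqs.mean(axis=1)
    pair_diff = np.abs(freqs[:, None, :] - freqs[None, :, :]).mean(axis=2)
    others = (freqs.sum(axis=0)[None, :] - freqs) / (n - 1)
    others_diff = np.abs(freqs - others).mean(axis=1)
    half_dev = np.abs(pbar - 0.5)
    off = _offdiag_mask(n)
    iu = np.triu_indices(n, k=1)

    rows = []

    def add(family, x_name, x, effect, y):
        if y is None:
            return
        r, ok = _pearson(x, y)
        if not ok:
            warnings.warn(f"correlation of {effect} with {x_name} is undefined "
                          "(zero variance)", stacklevel=2)
        rows.append({"family": family, "x": x_name, "effect": effect,
                     "correlation": r, "n": len(np.atleast_1d(x)), "defined": ok})

    add("superiority", "mean_freq", pbar, "variety_effect", report.variety_effects)
    add("superiority", "mean_freq", pbar, "gca", report.gca)
    for name, tab in [("heterosis", report.heterosis),
                      ("specific_heterosis", report.specific_heterosis),
                      ("sca", report.sca)]:
        if tab is not None:
            add("divergence", "mean_abs_freq_diff", pair_diff[iu], name, tab[iu])
    add("parent_vs_rest", "mean_abs_diff_to_others", others_diff,
        "variety_heterosis", report.variety_heterosis)
    if report.sca_self is not None:
        add("parent_vs_rest", "mean_abs_diff_to_others", others_diff,
            "abs_sca_self", np.abs(report.sca_self))
    add("variability", "abs_mean_freq_minus_half", half_dev,
        "inbreeding_change", report.inbreeding_change)
    return pd.DataFrame(rows, columns=["family", "x", "effect", "correlation", "n", "defined"])


def average_heterosis_percent(h_star: float, parent_means) -> float:
    """Average heterosis as a percentage of the mean of the parents."""
    pm = float(np.mean(parent_means))
    if pm == 0.0:
        raise ValueError("parent mean is zero; percent heterosis undefined")
    return 100.0 * h_star / pm
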