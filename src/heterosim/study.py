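"""End-to-end study orchestration.

Two experiments are wired together here, mirroring a maize-style breeding
design:

* **Population diallel** — nine panmictic populations in LD (identified by
  their average allele frequency), their selfed versions and all 36
  interpopulation crosses.  Parametric means are decomposed with
  Gardner-Eberhart analysis II and Griffing method 2, and the correlation
  metrics quantify how epistasis distorts the identification of superior
  and divergent populations.
* **DH diallel** — 20 doubled haploids sampled per population (180 lines)
  and their 16,110 single crosses, analysed with Griffing method 4, plus a
  resampling analysis of 100 random subsets of 20 DHs (190 crosses each).

Each scenario of the grid combines an epistasis type (none, one of the
seven digenic types, or an admixture), a fraction of epistatic genes and a
ratio V(I)/(V(A)+V(D)).  The full run is deterministic given the master
seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diallel import (
    DecompositionReport,
    DiallelMeans,
    average_heterosis_percent,
    correlation_metrics,
    gardner_eberhart,
    griffing_method2,
    griffing_method4,
)
from .expectations import cross_mean, population_mean, selfed_mean
from .genome import GenomeMap, build_genome
from .populations import derive_dh, make_ld_population, sample_allele_freqs
from .trait_model import (
    EPISTASIS_TYPES,
    GeneEffect,
    TraitModel,
    assign_gene_effects,
    build_epistasis_table,
    genotypic_value,
    pair_epistatic_genes,
)

__all__ = [
    "StudyConfig",
    "Scenario",
    "ScenarioResult",
    "scenario_grid",
    "build_study_populations",
    "build_scenario_trait",
    "run_population_study",
    "run_dh_study",
    "resample_dh_subsets",
]


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the simulation study.

    The defaults reproduce the reference design: 400 genes on 10
    chromosomes of 200 cM, nine populations (the two with mean frequency
    0.5 differing in founder divergence, hence LD level), homozygote
    genotypic range 30-160 g/plant, positive dominance with mean degree
    0.6 in [0.1, 1.2], 20 DHs per population and 100 subsets of 20 DHs.
    """

    n_chrom: int = 10
    chrom_length: float = 200.0
    genes_per_chrom: int = 40
    pop_means: Sequence[float] = (0.1, 0.2, 0.3, 0.5, 0.6, 0.5, 0.7, 0.8, 0.9)
    founder_divergence: Sequence[float] = (0.25, 0.25, 0.25, 0.5, 0.25, 0.1, 0.25, 0.25, 0.25)
    beta_concentration: float = 4.0
    min_hom: float = 30.0
    max_hom: float = 160.0
    dom_mean: float = 0.6
    dom_range: Sequence[float] = (0.1, 1.2)
    epistasis_types: Sequence[str] = EPISTASIS_TYPES + ("all",)
    fractions: Sequence[float] = (0.25, 1.0)
    ratios: Sequence[float] = (1.0, 10.0)
    include_no_dominance: bool = False
    selfing_generations: int = 1
    dh_per_population: int = 20
    subset_size: int = 20
    n_subsets: int = 100
    seed: int = 2023

    @property
    def n_genes(self) -> int:
        return self.n_chrom * self.genes_per_chrom

    @property
    def n_populations(self) -> int:
        return len(self.pop_means)

    def genome(self) -> GenomeMap:
        return build_genome(self.n_chrom, self.chrom_length, self.genes_per_chrom)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class Scenario:
    """One cell of the study grid."""

    epistasis: Optional[str]  # None, one of the seven types, or "all"
    fraction: float = 0.0
    ratio: float = 0.0
    dominance: bool = True

    @property
    def label(self) -> str:
        if self.epistasis is None:
            base = "none"
        else:
            base = f"{self.epistasis}_f{int(round(100 * self.fraction))}_r{self.ratio:g}"
        return base if self.dominance else base + "_nodom"


def scenario_grid(config: StudyConfig):
    """The scenario grid: no-epistasis baseline plus types x fractions x ratios."""
    doms = (True, False) if config.include_no_dominance else (True,)
    out = []
    for dom in doms:
        out.append(Scenario(None, dominance=dom))
        for t, f, r in itertools.product(config.epistasis_types, config.fractions, config.ratios):
            out.append(Scenario(t, f, r, dominance=dom))
    return out


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def build_study_populations(config: StudyConfig, seed=None):
    """The study populations and their per-gene frequency matrix.

    Each population is built from two linkage-equilibrium founders whose
    per-gene frequencies straddle a beta-sampled target, so that the
    average frequency hits the configured mean and the founder divergence
    sets the LD level.
    """
    seed = config.seed if seed is None else seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pops = []
    freqs = np.empty((config.n_populations, config.n_genes))
    for j, child in enumerate(ss.spawn(config.n_populations)):
        p = sample_allele_freqs(config.pop_means[j], config.beta_concentration,
                                config.n_genes, seed=child)
        p = np.clip(p, 1e-4, 1.0 - 1e-4)
        half = np.minimum(config.founder_divergence[j] / 2.0, np.minimum(p, 1.0 - p))
        pops.append(make_ld_population(p + half, p - half))
        freqs[j] = p
    return pops, freqs


def build_scenario_trait(config: StudyConfig, scenario: Scenario, seed=None) -> TraitModel:
    """Trait model for one scenario (gene effects plus epistatic pairs)."""
    seed = config.seed if seed is None else seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_genes, s_pairs, s_tables = ss.spawn(3)
    genes = assign_gene_effects(
        config.n_genes, config.min_hom, config.max_hom, config.dom_mean,
        tuple(config.dom_range), seed=s_genes,
    )
    if not scenario.dominance:
        genes = [GeneEffect(g.gene_id, g.m, g.a, 0.0) for g in genes]
    pairs = []
    if scenario.epistasis is not None and scenario.fraction > 0:
        idx_pairs = pair_epistatic_genes(np.arange(config.n_genes), scenario.fraction,
                                         seed=s_pairs)
        rng = np.random.default_rng(s_tables)
        for (i, k) in idx_pairs:
            etype = (scenario.epistasis if scenario.epistasis != "all"
                     else str(rng.choice(EPISTASIS_TYPES)))
            pairs.append(
                build_epistasis_table(etype, genes[i], genes[k],
                                      ratio=scenario.ratio, seed=rng)
            )
    return TraitModel(genes, pairs)


@dataclass
class ScenarioResult:
    """Per-scenario tables of a study run."""

    means: pd.DataFrame
    correlations: pd.DataFrame
    summary: pd.DataFrame


def _concat(results):
    return ScenarioResult(
        means=pd.concat([r.means for r in results], ignore_index=True),
        correlations=pd.concat([r.correlations for r in results], ignore_index=True),
        summary=pd.concat([r.summary for r in results], ignore_index=True),
    )


# ---------------------------------------------------------------------------
# population experiment
# ---------------------------------------------------------------------------

def _population_scenario(config, scenario, genome, pops, freqs, trait) -> ScenarioResult:
    n = len(pops)
    comp_rows = []
    parent_M = np.empty(n)
    selfed_M = np.empty(n)
    crosses = np.full((n, n), np.nan)
    for j, pop in enumerate(pops):
        mc = population_mean(pop, trait, genome)
        parent_M[j] = mc.M
        comp_rows.append(("population", j, j, mc))
        ms = selfed_mean(pop, trait, genome, config.selfing_generations)
        selfed_M[j] = ms.M
        comp_rows.append(("selfed", j, j, ms))
    for j in range(n - 1):
        for k in range(j + 1, n):
            mx = cross_mean(pops[j], pops[k], trait, genome)
            crosses[j, k] = crosses[k, j] = mx.M
            comp_rows.append(("cross", j, k, mx))

    dm = DiallelMeans(crosses, parents=parent_M, selfed=selfed_M)
    ge = gardner_eberhart(dm)
    g2 = griffing_method2(dm)
    report = DecompositionReport.from_results(ge, g2)
    corr = correlation_metrics(report, freqs)
    corr.insert(0, "scenario", scenario.label)

    means = pd.DataFrame(
        [
            {
                "scenario": scenario.label, "kind": kind, "parent_1": j, "parent_2": k,
                "M": mc.M, "m": mc.m, "v": mc.v, "E_AA": mc.E_AA, "E_AD": mc.E_AD,
                "E_DA": mc.E_DA, "E_DD": mc.E_DD, "d": mc.d, "F": mc.F,
            }
            for kind, j, k, mc in comp_rows
        ]
    )
    summary = pd.DataFrame(
        [
            {
                "scenario": scenario.label,
                "average_heterosis": ge.average_heterosis,
                "average_heterosis_pct": average_heterosis_percent(
                    ge.average_heterosis, parent_M),
                "mean_parent": parent_M.mean(),
                "mean_cross": crosses[np.triu_indices(n, 1)].mean(),
                "mean_inbreeding_change": float((selfed_M - parent_M).mean()),
            }
        ]
    )
    return ScenarioResult(means, corr, summary)


def run_population_study(config: StudyConfig, seed=None) -> ScenarioResult:
    """Heterosis and combining-ability analysis of the population diallel.

    For every scenario: parametric means of the populations, their selfed
    versions and all crosses; Gardner-Eberhart and Griffing method 2
    decompositions; the four correlation families; average heterosis.
    """
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    s_pops, s_traits = ss.spawn(2)
    genome = config.genome()
    pops, freqs = build_study_populations(config, s_pops)
    scenarios = scenario_grid(config)
    trait_seeds = s_traits.spawn(len(scenarios))
    results = []
    for scenario, s_t in zip(scenarios, trait_seeds):
        trait = build_scenario_trait(config, scenario, s_t)
        results.append(_population_scenario(config, scenario, genome, pops, freqs, trait))
    return _concat(results)


# ---------------------------------------------------------------------------
# DH experiment
# ---------------------------------------------------------------------------

def sample_study_dhs(config: StudyConfig, genome, pops, seed):
    """Allele matrix (n_lines x n_genes) of the DHs, ``dh_per_population`` each."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    blocks = []
    for pop, child in zip(pops, ss.spawn(len(pops))):
        dhs = derive_dh(pop, genome, config.dh_per_population, child)
        blocks.append(np.stack([dh.haplotype for dh in dhs]))
    return np.concatenate(blocks, axis=0)


def dh_cross_table(alleles: np.ndarray, trait: TraitModel):
    """Parametric genotypic values of all DH single crosses and per-se lines.

    Crossing two fully homozygous lines fixes the F1 genotype, so the
    cross genotypic value is deterministic: dosage = allele_j + allele_j'.
    Returns ``(per_se, table)`` with a NaN diagonal.
    """
    n = alleles.shape[0]
    per_se = genotypic_value(2 * alleles.astype(np.int64), trait)
    iu = np.triu_indices(n, k=1)
    dos = alleles[iu[0]] + alleles[iu[1]]
    vals = genotypic_value(dos.astype(np.int64), trait)
    T = np.full((n, n), np.nan)
    T[iu] = vals
    T[(iu[1], iu[0])] = vals
    return per_se, T


def _dh_scenario(scenario, alleles, trait) -> ScenarioResult:
    n = alleles.shape[0]
    per_se, T = dh_cross_table(alleles, trait)
    g4 = griffing_method4(T)
    report = DecompositionReport.from_results(griffing=g4)
    corr = correlation_metrics(report, alleles.astype(float))
    corr.insert(0, "scenario", scenario.label)
    iu = np.triu_indices(n, k=1)
    h = T[iu] - 0.5 * (per_se[iu[0]] + per_se[iu[1]])
    h_star = float(h.mean())
    means = pd.DataFrame(
        {
            "scenario": scenario.label,
            "line": np.arange(n),
            "per_se": per_se,
            "gca": g4.gca,
            "mean_freq": alleles.mean(axis=1),
        }
    )
    summary = pd.DataFrame(
        [
            {
                "scenario": scenario.label,
                "n_lines": n,
                "n_crosses": iu[0].size,
                "average_heterosis": h_star,
                "average_heterosis_pct": average_heterosis_percent(h_star, per_se),
                "mean_cross": float(T[iu].mean()),
                "mean_per_se": float(per_se.mean()),
            }
        ]
    )
    return ScenarioResult(means, corr, summary)


def run_dh_study(config: StudyConfig, seed=None) -> ScenarioResult:
    """Combining-ability analysis of the full DH diallel (method 4)."""
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    s_pops, s_traits, s_dh = ss.spawn(3)
    genome = config.genome()
    pops, _ = build_study_populations(config, s_pops)
    alleles = sample_study_dhs(config, genome, pops, s_dh)
    scenarios = scenario_grid(config)
    trait_seeds = s_traits.spawn(len(scenarios))
    results = []
    for scenario, s_t in zip(scenarios, trait_seeds):
        trait = build_scenario_trait(config, scenario, s_t)
        results.append(_dh_scenario(scenario, alleles, trait))
    return _concat(results)


def resample_dh_subsets(config: StudyConfig, seed=None) -> pd.DataFrame:
    """Method-4 analyses of random DH subsets: correlation spread per scenario.

    Draws ``n_subsets`` independent subsets of ``subset_size`` DHs, fits
    Griffing method 4 on each subset's crosses, computes the GCA and SCA
    correlations with the allele-frequency summaries, and reports the
    minimum, mean and maximum across subsets.
    """
    if config.subset_size < 3:
        raise ValueError("subset_size must be >= 3")
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    s_pops, s_traits, s_dh, s_sub = ss.spawn(4)
    genome = config.genome()
    pops, _ = build_study_populations(config, s_pops)
    alleles = sample_study_dhs(config, genome, pops, s_dh)
    n = alleles.shape[0]
    if config.subset_size > n:
        raise ValueError("subset_size exceeds the number of DHs")
    rng = np.random.default_rng(s_sub)
    subsets = [rng.choice(n, size=config.subset_size, replace=False)
               for _ in range(config.n_subsets)]
    scenarios = scenario_grid(config)
    trait_seeds = s_traits.spawn(len(scenarios))
    rows = []
    for scenario, s_t in zip(scenarios, trait_seeds):
        trait = build_scenario_trait(config, scenario, s_t)
        _, T = dh_cross_table(alleles, trait)
        rs = {"gca": [], "sca": []}
        for sub in subsets:
            Ts = T[np.ix_(sub, sub)]
            g4 = griffing_method4(Ts)
            report = DecompositionReport.from_results(griffing=g4)
            corr = correlation_metrics(report, alleles[sub].astype(float))
            rs["gca"].append(
                float(corr.loc[corr.effect == "gca", "correlation"].iloc[0]))
            rs["sca"].append(
                float(corr.loc[corr.effect == "sca", "correlation"].iloc[0]))
        for effect, vals in rs.items():
            vals = np.array(vals)
            rows.append({
                "scenario": scenario.label, "effect": effect,
                "min": vals.min(), "mean": vals.mean(), "max": vals.max(),
                "n_subsets": len(vals), "subset_size": config.subset_size,
            })
    return pd.DataFrame(rows)
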