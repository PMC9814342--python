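"""Synthetic populations for exercising the reliability pipeline.

Generates a discrete-generation random-mating population with gene-dropped
marker genotypes, a residual polygenic component matching the covariance
structure the single-step model assumes (G_omega = (1-omega) ZZ' + omega
A22), phenotypes with contemporary-group effects, and a partially genotyped,
partially recorded sampling pattern with genotyping biased toward recent
generations, as in practical dairy populations.

All randomness flows from one integer seed through named
``numpy.random.default_rng`` streams, so every artefact is reproducible
per-seed and the separate simulate_* operations agree with each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic import GenotypeSet
from .pedigree import UNKNOWN, Pedigree, inbreeding_coefficients

_PED_STREAM, _GENO_STREAM, _TRAIT_STREAM = 11, 13, 17


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of a synthetic population.

    Total phenotypic variance is 1, so ``h2`` fixes sigma2_u = h2 and
    sigma2_e = 1 - h2.  ``omega`` is the residual polygenic proportion of
    the additive variance.
    """

    n_founders: int = 120
    n_generations: int = 5
    offspring_per_mating: int = 6
    m_markers: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2: float = 0.4
    omega: float = 0.3
    prop_genotyped: float = 0.2
    prop_recorded: float = 0.5
    n_fixed_levels: int = 20
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("maf_range must be inside (0, 1)")
        for prop in (self.prop_genotyped, self.prop_recorded):
            if not 0.0 <= prop <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")

    @property
    def sigma2_u(self) -> float:
        return self.h2

    @property
    def sigma2_e(self) -> float:
        return 1.0 - self.h2

    @property
    def n_animals(self) -> int:
        """Closed-form pedigree size: founders + generations x matings x litter."""
        return (
            self.n_founders
            + self.n_generations * (self.n_founders // 2) * self.offspring_per_mating
        )


def _rng(sc: SimulationScenario, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, sc.seed])


def simulate_pedigree(sc: SimulationScenario) -> Pedigree:
    """Discrete-generation pedigree with random mating and no selfing.

    Sexes alternate by birth order within each generation, so both sexes are
    always available for mating; sires and dams are drawn with replacement
    from the previous generation only.
    """
    rng = _rng(sc, _PED_STREAM)
    n_matings = sc.n_founders // 2
    sire = []
    dam = []
    prev = list(range(sc.n_founders))
    sire.extend([UNKNOWN] * sc.n_founders)
    dam.extend([UNKNOWN] * sc.n_founders)
    next_id = sc.n_founders
    for _gen in range(sc.n_generations):
        males = prev[0::2]
        females = prev[1::2]
        cur: list[int] = []
        s_choice = rng.choice(males, size=n_matings, replace=True)
        d_choice = rng.choice(females, size=n_matings, replace=True)
        for s, d in zip(s_choice, d_choice):
            for _ in range(sc.offspring_per_mating):
                sire.append(int(s))
                dam.append(int(d))
                cur.append(next_id)
                next_id += 1
        prev = cur
    ids = [f"A{i + 1}" for i in range(next_id)]
    return Pedigree(ids=ids, sire=np.array(sire), dam=np.array(dam))


def generation_numbers(ped: Pedigree) -> np.ndarray:
    """Generation of each animal: 0 for founders, else 1 + max(parent gen)."""
    gen = np.zeros(ped.n_animals, dtype=np.int64)
    for i in range(ped.n_animals):
        parents = [x for x in (ped.sire[i], ped.dam[i]) if x != UNKNOWN]
        if parents:
            gen[i] = 1 + max(gen[x] for x in parents)
    return gen


def gene_drop(ped: Pedigree, sc: SimulationScenario) -> tuple[np.ndarray, np.ndarray]:
    """Dosages (p x m) for every pedigree animal, plus founder frequencies.

    Founder alleles are Bernoulli draws at per-marker frequencies uniform on
    ``maf_range``; each descendant inherits one allele sampled at random
    from each parent's pair (an unknown parent contributes a fresh
    founder-population allele).
    """
    rng = _rng(sc, _GENO_STREAM)
    p, m = ped.n_animals, sc.m_markers
    freqs = rng.uniform(*sc.maf_range, size=m)
    # paternal/maternal allele per animal per marker
    pat = np.zeros((p, m), dtype=np.int8)
    mat = np.zeros((p, m), dtype=np.int8)
    for i in range(p):
        for alleles, parent in ((pat, ped.sire[i]), (mat, ped.dam[i])):
            if parent == UNKNOWN:
                alleles[i] = rng.random(m) < freqs
            else:
                pick = rng.random(m) < 0.5
                alleles[i] = np.where(pick, pat[parent], mat[parent])
    return (pat + mat).astype(np.int8), freqs


def select_genotyped(ped: Pedigree, sc: SimulationScenario) -> np.ndarray:
    """Sample the genotyped subset, biased toward recent generations."""
    rng = _rng(sc, _GENO_STREAM).spawn(1)[0]
    p = ped.n_animals
    n_gen = int(round(sc.prop_genotyped * p))
    gen = generation_numbers(ped)
    w = (gen + 1.0) ** 2
    idx = rng.choice(p, size=n_gen, replace=False, p=w / w.sum())
    return np.sort(idx)


def simulate_genotypes(
    ped: Pedigree, sc: SimulationScenario
) -> tuple[GenotypeSet, np.ndarray, np.ndarray, np.ndarray]:
    """Observed genotypes of the sampled genotyped animals.

    Returns the :class:`GenotypeSet` (allele frequencies observed in the
    genotyped animals), the genotyped pedigree indices, the full p x m
    dosage matrix, and the true founder frequencies.
    """
    dosages, freqs = gene_drop(ped, sc)
    genotyped = select_genotyped(ped, sc)
    geno = GenotypeSet(
        animal_ids=[ped.ids[i] for i in genotyped],
        dosages=dosages[genotyped].astype(float),
    )
    return geno, genotyped, dosages, freqs


def true_breeding_values(
    ped: Pedigree,
    dosages: np.ndarray,
    freqs: np.ndarray,
    sc: SimulationScenario,
    rng: np.random.Generator,
) -> np.ndarray:
    """Additive genetic values u = sqrt(1-omega) Z g + RPG component.

    Marker effects g ~ N(0, sigma2_u I_m) act through the centered and
    scaled true-frequency covariates, so var(u_marker) ~ (1-omega) sigma2_u;
    the residual polygenic part is gene-dropped down the pedigree with
    founder variance omega sigma2_u and inbreeding-adjusted Mendelian
    sampling variance, matching cov = omega sigma2_u A.
    """
    p = ped.n_animals
    scale = np.sqrt(2.0 * np.sum(freqs * (1.0 - freqs)))
    Z = (dosages - 2.0 * freqs) / scale
    g = rng.normal(0.0, np.sqrt(sc.sigma2_u), size=sc.m_markers)
    u = np.sqrt(1.0 - sc.omega) * (Z @ g)

    var_rpg = sc.omega * sc.sigma2_u
    if var_rpg > 0:
        F = inbreeding_coefficients(ped)
        a = np.zeros(p)
        for i in range(p):
            s, d = ped.sire[i], ped.dam[i]
            if s != UNKNOWN and d != UNKNOWN:
                mean = 0.5 * (a[s] + a[d])
                mvar = var_rpg * (0.5 - 0.25 * (F[s] + F[d]))
            elif s != UNKNOWN or d != UNKNOWN:
                known = s if s != UNKNOWN else d
                mean = 0.5 * a[known]
                mvar = var_rpg * (0.75 - 0.25 * F[known])
            else:
                mean, mvar = 0.0, var_rpg
            a[i] = mean + rng.normal(0.0, np.sqrt(mvar))
        u = u + a
    return u


def simulate_records(
    ped: Pedigree,
    dosages: np.ndarray,
    freqs: np.ndarray,
    sc: SimulationScenario,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Phenotype table, true record weights, and true breeding values.

    A random subset of animals receives one record each (weight 1):
    y = contemporary-group effect + u + e with e ~ N(0, sigma2_e).
    """
    rng = _rng(sc, _TRAIT_STREAM)
    p = ped.n_animals
    u = true_breeding_values(ped, dosages, freqs, sc, rng)
    n_rec = int(round(sc.prop_recorded * p))
    recorded = np.sort(rng.choice(p, size=n_rec, replace=False))
    levels = rng.integers(0, sc.n_fixed_levels, size=n_rec)
    level_effects = rng.normal(0.0, 1.0, size=sc.n_fixed_levels)
    e = rng.normal(0.0, np.sqrt(sc.sigma2_e), size=n_rec)
    y = level_effects[levels] + u[recorded] + e
    records = pd.DataFrame(
        {
            "animal": [ped.ids[i] for i in recorded],
            "value": y,
            "level": [f"L{v + 1}" for v in levels],
        }
    )
    weights = np.zeros(p)
    weights[recorded] = 1.0
    return records, weights, u


@dataclass
class SyntheticPopulation:
    """Everything the pipeline consumes, plus simulation truth."""

    scenario: SimulationScenario
    ped: Pedigree
    geno: GenotypeSet
    genotyped: np.ndarray
    records: pd.DataFrame
    true_weights: np.ndarray
    true_bv: np.ndarray
    dosages: np.ndarray
    founder_freqs: np.ndarray


def simulate_population(sc: SimulationScenario) -> SyntheticPopulation:
    """Generate a complete scenario: pedigree, genotypes, records, truth."""
    ped = simulate_pedigree(sc)
    geno, genotyped, dosages, freqs = simulate_genotypes(ped, sc)
    records, weights, u = simulate_records(ped, dosages, freqs, sc)
    return SyntheticPopulation(
        scenario=sc,
        ped=ped,
        geno=geno,
        genotyped=genotyped,
        records=records,
        true_weights=weights,
        true_bv=u,
        dosages=dosages,
        founder_freqs=freqs,
    )
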