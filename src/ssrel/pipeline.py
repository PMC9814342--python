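"""Seven-step approximation of single-step GEBV reliabilities.

The approximation splits the work between the genotyped and non-genotyped
parts of the pedigree:

1. pedigree-only (PBLUP) reliabilities for every animal, from the full
   animal model with fixed effects;
2. reverse those of the genotyped animals into weights ERC_g;
3. genomic reliabilities of the genotyped animals, by a SNPBLUP/GBLUP model
   that carries the residual polygenic (RPG) effect either explicitly (the
   "direct" method) or through an index with the PBLUP reliabilities (the
   "blended" method);
4. reverse the Step-1 reliabilities of all animals into weights ERC_f;
5. convert the genomic reliabilities into weights for the genotyped animals
   by one of schemes A-E;
6. stack the non-genotyped ERC_f with the scheme weights and floor at 0.01;
7. reliabilities for the non-genotyped animals from a weighted animal model
   with the Step-6 weights.

The exact single-step reliabilities, obtained by inverting the coefficient
matrix of the ssGBLUP animal model built on H^{-1}, serve as the validation
oracle for the whole chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import erc as erc_mod
from .genomic import GenotypeSet, MarkerMatrix, build_G, build_G_omega, center_scale
from .mme import (
    MMEFactor,
    ModelError,
    VarianceComponents,
    assemble_gblup,
    assemble_snpblup,
    assemble_snpblup_direct,
    assemble_ssgblup_exact,
    assemble_weighted_pblup,
    reliability_from_factor,
)
from .pedigree import Pedigree, RelationshipMatrix, build_A, build_A_inverse, extract_A22

logger = logging.getLogger(__name__)

SCHEMES = ("A", "B", "C", "D", "E")
METHODS = ("direct", "blended")


@dataclass
class ReliabilityVector:
    """Reliabilities for a set of animals, tagged by the producing step."""

    values: np.ndarray
    animals: np.ndarray  # pedigree indices the values refer to
    tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.animals = np.asarray(self.animals, dtype=np.int64)
        if self.values.shape != self.animals.shape:
            raise ValueError("values and animals must align")
        if ((self.values < 0) | (self.values >= 1)).any():
            raise ValueError("reliabilities must lie in [0, 1)")


@dataclass
class ComparisonReport:
    """Agreement statistics between exact and approximate reliabilities."""

    group: str
    n: int
    pearson_r: float
    intercept: float
    slope: float
    mse: float

    def as_dict(self) -> dict:
        return {
            "group": self.group,
            "n": self.n,
            "pearson_r": self.pearson_r,
            "intercept": self.intercept,
            "slope": self.slope,
            "mse": self.mse,
        }


# ---------------------------------------------------------------------------
# Step 1
# ---------------------------------------------------------------------------

def _records_design(ped: Pedigree, records: pd.DataFrame):
    """Map a phenotype table to (animal index, level index) per record."""
    if records.empty:
        return np.zeros(0, np.int64), np.zeros(0, np.int64), []
    animal_idx = ped.index_of(records["animal"].astype(str).tolist())
    levels, level_idx = np.unique(records["level"].to_numpy(), return_inverse=True)
    return animal_idx, level_idx.astype(np.int64), list(levels)


def step1_pblup_reliabilities(
    ped: Pedigree,
    records: pd.DataFrame,
    vc: VarianceComponents,
    A_inverse: sp.spmatrix | None = None,
    inbreeding: np.ndarray | None = None,
) -> ReliabilityVector:
    """Exact PBLUP reliabilities from the full animal model with fixed levels.

    The model is y = Xb + a + e with one fixed effect per contemporary-group
    level (cell-means coding, no separate general mean) and unit weight per
    record.  Reliabilities are 1 - lambda * C^aa_ii / (1 + F_i) from the
    inverse coefficient matrix.
    """
    from .pedigree import inbreeding_coefficients

    p = ped.n_animals
    if A_inverse is None:
        A_inverse = build_A_inverse(ped, inbreeding)
    if inbreeding is None:
        inbreeding = inbreeding_coefficients(ped)
    if records.empty:
        return ReliabilityVector(np.zeros(p), np.arange(p), "step1_pblup")
    animal_idx, level_idx, levels = _records_design(ped, records)
    nlev = len(levels)
    n_eq = nlev + p
    lhs = np.zeros((n_eq, n_eq))
    np.add.at(lhs, (level_idx, level_idx), 1.0)  # X'X
    np.add.at(lhs, (level_idx, nlev + animal_idx), 1.0)  # X'T
    np.add.at(lhs, (nlev + animal_idx, level_idx), 1.0)
    np.add.at(lhs, (nlev + animal_idx, nlev + animal_idx), 1.0)  # T'T
    lhs[nlev:, nlev:] += vc.lambda_ * A_inverse.toarray()
    try:
        factor = MMEFactor("pblup_full", lhs, n_fixed=nlev)
        r2 = reliability_from_factor(factor, 1.0 + inbreeding, vc)
    except ModelError as exc:
        raise ModelError(f"Step 1 fixed effects are confounded: {exc}") from exc
    return ReliabilityVector(r2, np.arange(p), "step1_pblup")


def step1_reduced_reliabilities(
    ped: Pedigree,
    records: pd.DataFrame,
    genotyped: np.ndarray,
    vc: VarianceComponents,
    A_inverse: sp.spmatrix,
    inbreeding: np.ndarray,
) -> np.ndarray:
    """Step-1 reliabilities with genotyped-progeny records removed.

    Removes the records of every genotyped animal that has a genotyped
    parent, refits the Step-1 model once, and for each such animal restores
    its own records by a low-rank (Woodbury) update of its own diagonal so
    that only *other* animals lose that information.  Used by the scheme-C
    progeny-contribution proxy.
    """
    p = ped.n_animals
    genotyped = np.asarray(genotyped, dtype=np.int64)
    gmask = np.zeros(p, dtype=bool)
    gmask[genotyped] = True
    has_gen_parent = np.zeros(p, dtype=bool)
    for arr in (ped.sire, ped.dam):
        known = arr >= 0
        has_gen_parent[known] |= gmask[arr[known]]
    Q = np.where(gmask & has_gen_parent)[0]
    qmask = np.zeros(p, dtype=bool)
    qmask[Q] = True

    if records.empty:
        return np.zeros(p)
    animal_idx, level_idx, levels = _records_design(ped, records)
    drop = qmask[animal_idx]
    reduced = records.loc[~drop]
    base = step1_pblup_reliabilities(
        ped, reduced, vc, A_inverse=A_inverse, inbreeding=inbreeding
    )
    r2 = base.values.copy()
    if not drop.any():
        return r2

    # rebuild the reduced factor once to perform the per-animal restorations
    red_animal, red_level, red_levels = _records_design(ped, reduced)
    nlev = len(red_levels)
    # level codes of dropped records, in the reduced model's level coding
    lev_map = {lv: i for i, lv in enumerate(red_levels)}
    n_eq = nlev + p
    lhs = np.zeros((n_eq, n_eq))
    np.add.at(lhs, (red_level, red_level), 1.0)
    np.add.at(lhs, (red_level, nlev + red_animal), 1.0)
    np.add.at(lhs, (nlev + red_animal, red_level), 1.0)
    np.add.at(lhs, (nlev + red_animal, nlev + red_animal), 1.0)
    lhs[nlev:, nlev:] += vc.lambda_ * A_inverse.toarray()
    factor = MMEFactor("pblup_reduced", lhs, n_fixed=nlev)

    dropped = records.loc[drop]
    lam = vc.lambda_
    for i in Q:
        own = dropped.loc[dropped["animal"].astype(str) == ped.ids[i]]
        if own.empty:
            # genotyped progeny without own records: reduced value stands
            continue
        k = len(own)
        V = np.zeros((n_eq, k))
        for col, (_, rec) in enumerate(own.iterrows()):
            lv = lev_map.get(rec["level"])
            if lv is not None:
                V[lv, col] = 1.0
            # a level that vanished entirely from the reduced model acts as
            # a new cell absorbed exactly by the record itself; its design
            # column is outside the reduced system, so the animal part alone
            # carries the restored information
            V[nlev + i, col] = 1.0
        Y = factor.solve_columns(V)
        M = np.eye(k) + V.T @ Y
        row = nlev + i
        c_ii = factor.inverse_diag(np.array([i]))[0]
        y_i = Y[row, :]
        c_new = c_ii - y_i @ np.linalg.solve(M, y_i)
        r2[i] = min(max(1.0 - lam * c_new / (1.0 + inbreeding[i]), 0.0), 1 - 1e-12)
    return r2


# ---------------------------------------------------------------------------
# Step 3: genotyped animals
# ---------------------------------------------------------------------------

def _choose_model(model: str, default: str) -> str:
    """Route "auto" to the model family with the smaller MME.

    The direct method is cheapest as GBLUP on G_omega (n+1 equations, and
    G_omega is nonsingular for omega > 0); the blended method is cheapest as
    marker-effect SNPBLUP (m+1 equations regardless of n, and it does not
    require inverting the possibly singular ZZ').
    """
    return default if model == "auto" else model


def step3_direct(
    Zm: MarkerMatrix,
    A22: RelationshipMatrix,
    erc_g: np.ndarray,
    vc: VarianceComponents,
    genotyped: np.ndarray | None = None,
    model: str = "auto",
) -> ReliabilityVector:
    """Genomic reliabilities with the RPG effect carried in the model.

    Either the SNPBLUP with explicit marker and RPG effects or the
    equivalent GBLUP on G_omega = (1-omega) ZZ' + omega A22 is solved; both
    give r2_i = 1 - lambda * PEV_i / (sigma2_u * (G_omega)_ii).
    """
    G = build_G(Zm)
    Gw = build_G_omega(G, A22, vc.omega)
    route = _choose_model(model, "gblup")
    if route == "gblup":
        factor = assemble_gblup(Gw, erc_g, vc)
        r2 = reliability_from_factor(factor, np.diag(Gw), vc)
    else:
        factor = assemble_snpblup_direct(Zm, A22, erc_g, vc)
        r2 = reliability_from_factor(factor, np.diag(Gw), vc)
    animals = (
        np.arange(Zm.n_animals) if genotyped is None else np.asarray(genotyped)
    )
    return ReliabilityVector(r2, animals, "step3_direct")


def blend_reliabilities(
    r_star: np.ndarray,
    r2_pg: np.ndarray,
    g_ii: np.ndarray,
    a22_ii: np.ndarray,
    omega: float,
) -> np.ndarray:
    """Index-blend marker-model and pedigree reliabilities.

    r2 = [(1-omega) G_ii r*2 + omega A22_ii r2_p] /
         [(1-omega) G_ii + omega A22_ii]
    """
    r_star = np.asarray(r_star, dtype=float)
    r2_pg = np.asarray(r2_pg, dtype=float)
    g_ii = np.asarray(g_ii, dtype=float)
    a22_ii = np.asarray(a22_ii, dtype=float)
    denom = (1.0 - omega) * g_ii + omega * a22_ii
    if (denom <= 0).any():
        raise ModelError("blending denominator (1-omega)G_ii + omega A22_ii <= 0")
    return ((1.0 - omega) * g_ii * r_star + omega * a22_ii * r2_pg) / denom


def step3_blended(
    Zm: MarkerMatrix,
    A22: RelationshipMatrix,
    erc_g: np.ndarray,
    r2_pg: np.ndarray,
    vc: VarianceComponents,
    genotyped: np.ndarray | None = None,
    model: str = "auto",
) -> ReliabilityVector:
    """Genomic reliabilities via the no-RPG model blended with PBLUP.

    First r*2 from the marker-only model (no RPG), then the index

        r2 = [(1-omega) G_ii r*2 + omega A22_ii r2_p] /
             [(1-omega) G_ii + omega A22_ii],

    which weights the genomic and pedigree reliabilities by their variance
    contributions.
    """
    G = build_G(Zm)
    route = _choose_model(model, "snpblup")
    if route == "gblup":
        factor = assemble_gblup(G, erc_g, vc, allow_ridge=True)
        r_star = reliability_from_factor(factor, np.diag(G), vc)
    else:
        factor = assemble_snpblup(Zm, erc_g, vc)
        r_star = reliability_from_factor(factor, np.diag(G), vc)
    r2 = blend_reliabilities(r_star, r2_pg, np.diag(G), np.diag(A22.values), vc.omega)
    animals = (
        np.arange(Zm.n_animals) if genotyped is None else np.asarray(genotyped)
    )
    return ReliabilityVector(r2, animals, "step3_blended")


# ---------------------------------------------------------------------------
# Step 7 and the exact oracle
# ---------------------------------------------------------------------------

def step7_nongenotyped(
    A_inverse: sp.spmatrix,
    inbreeding: np.ndarray,
    erc_ss: np.ndarray,
    vc: VarianceComponents,
) -> ReliabilityVector:
    """Weighted animal-model reliabilities for all animals under ERC_ss."""
    factor = assemble_weighted_pblup(A_inverse, erc_ss, vc)
    r2 = reliability_from_factor(factor, 1.0 + np.asarray(inbreeding), vc)
    return ReliabilityVector(r2, np.arange(A_inverse.shape[0]), "step7")


def exact_ssgblup_reliabilities(
    A_inverse: sp.spmatrix,
    inbreeding: np.ndarray,
    A22: RelationshipMatrix,
    G_omega: np.ndarray,
    genotyped: np.ndarray,
    weights_all: np.ndarray,
    vc: VarianceComponents,
) -> ReliabilityVector:
    """Exact single-step reliabilities by inverting the ssGBLUP MME.

    Denominators follow the relationship diagonal of the model:
    (G_omega)_ii for genotyped animals, 1 + F_i otherwise, so exact and
    approximate reliabilities are on the same scale.
    """
    p = A_inverse.shape[0]
    factor = assemble_ssgblup_exact(A_inverse, A22, G_omega, genotyped, weights_all, vc)
    den = 1.0 + np.asarray(inbreeding, dtype=float)
    genotyped = np.asarray(genotyped, dtype=np.int64)
    if genotyped.size:
        den = den.copy()
        den[genotyped] = np.diag(G_omega)
    r2 = reliability_from_factor(factor, den, vc)
    return ReliabilityVector(r2, np.arange(p), "exact_ssgblup")


# ---------------------------------------------------------------------------
# Comparison statistics
# ---------------------------------------------------------------------------

def compare(
    exact: np.ndarray, approx: np.ndarray, group: str = "all"
) -> ComparisonReport:
    """Pearson r, regression of exact on approximate, and MSE."""
    exact = np.asarray(exact, dtype=float)
    approx = np.asarray(approx, dtype=float)
    if exact.shape != approx.shape or exact.size == 0:
        raise ValueError("exact and approximate vectors must align and be non-empty")
    if np.std(exact) == 0 or np.std(approx) == 0:
        raise ValueError("correlation undefined: zero variance in a vector")
    r = float(np.corrcoef(approx, exact)[0, 1])
    slope, intercept = np.polyfit(approx, exact, 1)
    mse = float(np.mean((exact - approx) ** 2))
    return ComparisonReport(
        group=group,
        n=exact.size,
        pearson_r=r,
        intercept=float(intercept),
        slope=float(slope),
        mse=mse,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """All per-step reliability vectors, weights, and comparison reports."""

    ped: Pedigree
    genotyped: np.ndarray
    r2_step1: ReliabilityVector
    r2_step3: ReliabilityVector
    r2_step7: ReliabilityVector
    r2_single_step: ReliabilityVector  # step3 for genotyped, step7 otherwise
    erc: dict = field(default_factory=dict)
    r2_exact: ReliabilityVector | None = None
    reports: dict = field(default_factory=dict)
    young: np.ndarray | None = None


def young_genotyped(
    ped: Pedigree, genotyped: np.ndarray, recorded: np.ndarray
) -> np.ndarray:
    """Genotyped animals without own records and without progeny."""
    p = ped.n_animals
    has_progeny = np.zeros(p, dtype=bool)
    for arr in (ped.sire, ped.dam):
        known = arr[arr >= 0]
        has_progeny[known] = True
    rec_mask = np.zeros(p, dtype=bool)
    rec_mask[np.asarray(recorded, dtype=np.int64)] = True
    gen = np.asarray(genotyped, dtype=np.int64)
    keep = ~has_progeny[gen] & ~rec_mask[gen]
    return gen[keep]


def run_pipeline(
    ped: Pedigree,
    geno: GenotypeSet,
    records: pd.DataFrame,
    vc: VarianceComponents,
    method: str = "blended",
    scheme: str = "E",
    erc_floor: float = erc_mod.DEFAULT_FLOOR,
    reverse_tol: float = 1e-5,
    reverse_max_iter: int = 100,
    compute_exact: bool = True,
    model: str = "auto",
) -> PipelineResult:
    """Execute Steps 1-7 and (optionally) the exact single-step oracle.

    ``records`` is a phenotype table with columns animal, value, level; each
    record carries unit weight in both the Step-1 model and the exact model.
    The pipeline is fully deterministic given its inputs.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")

    p = ped.n_animals
    A = build_A(ped)
    F = A.inbreeding
    Ainv = build_A_inverse(ped, F)
    genotyped = ped.index_of(geno.animal_ids)
    nongenotyped = np.setdiff1d(np.arange(p), genotyped)
    A22 = extract_A22(A, genotyped)
    geno_poly = geno.drop_monomorphic()
    Zm = center_scale(geno_poly)
    rev_kw = dict(tol=reverse_tol, max_iter=reverse_max_iter)

    logger.info("step 1: PBLUP reliabilities (%d animals)", p)
    r2_p = step1_pblup_reliabilities(ped, records, vc, A_inverse=Ainv, inbreeding=F)
    r2_pg = r2_p.values[genotyped]

    logger.info("step 2: reverse reliabilities for %d genotyped", genotyped.size)
    erc_g_full = erc_mod.reverse_reliability(
        r2_pg, genotyped, Ainv, F, vc, **rev_kw
    )
    erc_g = erc_g_full[genotyped]

    logger.info("step 3: genomic reliabilities (%s method)", method)
    if method == "direct":
        r2_step3 = step3_direct(Zm, A22, erc_g, vc, genotyped=genotyped, model=model)
    else:
        r2_step3 = step3_blended(
            Zm, A22, erc_g, r2_pg, vc, genotyped=genotyped, model=model
        )
    r2_gg = r2_step3.values

    logger.info("step 4: reverse reliabilities for all animals")
    erc_f = erc_mod.reverse_reliability(
        r2_p.values, np.arange(p), Ainv, F, vc, **rev_kw
    )
    erc_f_g = erc_f[genotyped]

    logger.info("step 5: scheme %s weights", scheme)
    if scheme == "A":
        erc_gg = erc_mod.scheme_A(r2_gg, vc)
    elif scheme == "B":
        erc_gg = erc_mod.scheme_B(erc_f_g, r2_gg, r2_pg, vc)
    elif scheme == "C":
        r2_reduced = step1_reduced_reliabilities(
            ped, records, genotyped, vc, Ainv, F
        )
        erc_i_g = erc_mod.interbull_progeny_erc(
            r2_p.values, r2_reduced, genotyped, Ainv, F, vc, **rev_kw
        )
        erc_gg = erc_mod.scheme_C(erc_f_g, r2_gg, erc_i_g, vc)
    elif scheme == "D":
        erc_gg = erc_mod.scheme_D(erc_f_g, r2_gg, erc_g, vc)
    else:  # E
        erc_gg_rev_full = erc_mod.reverse_reliability(
            r2_gg, genotyped, Ainv, F, vc, **rev_kw
        )
        erc_gg = erc_mod.scheme_E(erc_f_g, erc_gg_rev_full[genotyped], erc_g)

    logger.info("step 6: combine and floor at %.3g", erc_floor)
    erc_ss = erc_mod.combine_and_floor(
        erc_f[nongenotyped], erc_gg, nongenotyped, genotyped, p, floor=erc_floor
    )

    logger.info("step 7: weighted PBLUP for non-genotyped animals")
    r2_step7 = step7_nongenotyped(Ainv, F, erc_ss, vc)

    single = r2_step7.values.copy()
    single[genotyped] = r2_gg
    r2_single = ReliabilityVector(single, np.arange(p), f"approx_{method}_{scheme}")

    result = PipelineResult(
        ped=ped,
        genotyped=genotyped,
        r2_step1=r2_p,
        r2_step3=r2_step3,
        r2_step7=r2_step7,
        r2_single_step=r2_single,
        erc={
            "ERC_g": erc_g,
            "ERC_f": erc_f,
            "ERC_gg": erc_gg,
            "ERC_ss": erc_ss,
        },
    )

    recorded = (
        ped.index_of(records["animal"].astype(str).tolist())
        if not records.empty
        else np.zeros(0, np.int64)
    )
    result.young = young_genotyped(ped, genotyped, recorded)

    if compute_exact:
        logger.info("exact oracle: inverting the single-step MME")
        weights_all = np.zeros(p)
        np.add.at(weights_all, recorded, 1.0)
        Gw = build_G_omega(build_G(Zm), A22, vc.omega)
        r2_exact = exact_ssgblup_reliabilities(
            Ainv, F, A22, Gw, genotyped, weights_all, vc
        )
        result.r2_exact = r2_exact
        ex = r2_exact.values
        ap = r2_single.values
        result.reports["genotyped"] = compare(
            ex[genotyped], ap[genotyped], "genotyped"
        )
        if nongenotyped.size > 1:
            result.reports["non_genotyped"] = compare(
                ex[nongenotyped], ap[nongenotyped], "non_genotyped"
            )
        if result.young.size > 1:
            result.reports["young_genotyped"] = compare(
                ex[result.young], ap[result.young], "young_genotyped"
            )
    return result
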