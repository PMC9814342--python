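"""Effective record contributions (ERC) and genomic-information weights.

An ERC expresses the information available on an animal as a number of
effective own records on the residual-precision scale: an animal with ERC d
in the weighted animal model y = 1*mu + a + e, e ~ N(0, D^{-1} sigma2_e) has,
in isolation, reliability d / (d + lambda).

The reverse-reliability operation inverts this map: given target
reliabilities for a subset of animals it finds the nonnegative per-animal
weights under which the weighted animal model over the full pedigree
reproduces those reliabilities.  Five schemes (A-E) then convert genomic
reliabilities into additional weights for the genotyped animals while trying
to avoid double-counting the pedigree information that genomic reliabilities
already contain.
"""

from __future__ import annotations

import logging

import numpy as np

from .mme import (
    VarianceComponents,
    assemble_weighted_pblup,
    reliability_from_factor,
)

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 0.01


class ConvergenceError(RuntimeError):
    pass


class PartitionError(ValueError):
    pass


def _odds(r2: np.ndarray) -> np.ndarray:
    r2 = np.asarray(r2, dtype=float)
    if (r2 >= 1.0).any():
        raise ValueError("reliability of 1 implies infinite information")
    if (r2 < 0.0).any():
        raise ValueError("reliabilities must be nonnegative")
    return r2 / (1.0 - r2)


def erc_from_r2(r2: np.ndarray, vc: VarianceComponents) -> np.ndarray:
    """Deregress reliabilities to effective records: ERC = lambda r2/(1-r2)."""
    return vc.lambda_ * _odds(r2)


def reverse_reliability(
    targets: np.ndarray,
    subset: np.ndarray,
    A_inverse,
    inbreeding: np.ndarray,
    vc: VarianceComponents,
    *,
    tol: float = 1e-5,
    max_iter: int = 100,
    damping: float = 0.8,
    include_mean: bool = True,
) -> np.ndarray:
    """Weights for a subset of animals that reproduce target reliabilities.

    Because weights are constrained nonnegative, the problem is a
    complementarity one: for every subset animal either its reliability
    under the weighted animal model equals the target, or its weight is
    zero and relatives alone already push the reliability above the target
    (the target carries no information beyond the pedigree).

    Each sweep factorizes the weighted-PBLUP MME and extracts the subset
    block of its inverse, which yields both the exact current reliabilities
    and the exact Jacobian

        dr2_i / dd_j = lambda * (C_{i,mu} + C_{ij})^2 / (1 + F_i),

    where C is the inverse coefficient matrix (the mean-column term appears
    because a weight enters the mean equations too).  Far from the solution
    a damped diagonal (Jacobi) Newton step is taken; once the worst residual
    is below 1e-3 full Newton steps with a backtracking line search finish
    quadratically.  Updates are projected onto d >= 0 with an active set.
    The scalar case inverts d/(d + lambda) exactly at the starting value
    lambda * r2 / (1 - r2).

    Returns a full-length weight vector (zeros outside ``subset``).

    Raises
    ------
    ConvergenceError
        If the complementarity residual still exceeds ``tol`` after
        ``max_iter`` sweeps.
    """
    p = A_inverse.shape[0]
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size == 0:
        raise ValueError("subset is empty")
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (subset.size,):
        raise ValueError("targets must align with subset")
    odds_t = _odds(targets)  # validates range

    erc_sub = vc.lambda_ * odds_t  # exact for an isolated animal
    if not (targets > 0).any():
        return np.zeros(p)
    den = 1.0 + np.asarray(inbreeding, dtype=float)[subset]
    lam = vc.lambda_
    newton_switch = 1e-3

    def evaluate(erc):
        """Current reliabilities and inverse entries (B block, mean column)."""
        w = np.zeros(p)
        w[subset] = erc
        factor = assemble_weighted_pblup(
            A_inverse, w, vc, include_mean=include_mean
        )
        nf = factor.n_fixed
        rows = nf + subset
        cols = np.concatenate([np.arange(nf), rows])
        E = np.zeros((factor.n_equations, cols.size))
        E[cols, np.arange(cols.size)] = 1.0
        Y = factor.solve_columns(E)
        c_mu = Y[rows, 0] if nf else np.zeros(subset.size)
        B = Y[rows, nf:]
        r2 = np.clip(1.0 - lam * np.diag(B) / den, 0.0, 1.0 - 1e-12)
        return r2, B, c_mu

    def comp_resid(erc, r2):
        # mismatch where the weight is positive, one-sided shortfall on bound
        return np.where(
            erc > 0.0, np.abs(r2 - targets), np.maximum(targets - r2, 0.0)
        )

    r2_cur, B, c_mu = evaluate(erc_sub)
    for it in range(1, max_iter + 1):
        resid = comp_resid(erc_sub, r2_cur)
        worst = resid.max()
        if worst <= tol:
            n_bound = int(((erc_sub == 0.0) & (targets > 0.0)).sum())
            if n_bound:
                logger.info(
                    "reverse reliability: %d targets already exceeded by "
                    "relatives alone (weight 0)",
                    n_bound,
                )
            logger.debug("reverse reliability converged in %d sweeps", it)
            out = np.zeros(p)
            out[subset] = erc_sub
            return out
        free = (erc_sub > 0.0) | (r2_cur < targets)
        M = c_mu[:, None] + B
        rhs = targets[free] - r2_cur[free]
        # trust bound: a target that saturates (derivative -> 0 while still
        # short) must not drive its weight to overflow; growth is capped so
        # an infeasible target ends in a clean ConvergenceError
        cap = 10.0 * (erc_sub + lam)
        if worst >= newton_switch:
            deriv = lam * np.diag(M)[free] ** 2 / den[free]
            new = erc_sub.copy()
            new[free] = np.maximum(
                erc_sub[free] + damping * rhs / np.maximum(deriv, 1e-300), 0.0
            )
            new[~free] = 0.0
            erc_sub = np.minimum(new, cap)
            r2_cur, B, c_mu = evaluate(erc_sub)
        else:
            jac = lam * (M[np.ix_(free, free)] ** 2) / den[free, None]
            try:
                delta = np.linalg.solve(jac, rhs)
            except np.linalg.LinAlgError:  # near-singular coupling
                delta, *_ = np.linalg.lstsq(jac, rhs, rcond=None)
            s = 1.0
            for _ in range(8):  # backtracking on the residual norm
                trial = erc_sub.copy()
                trial[free] = np.maximum(erc_sub[free] + s * delta, 0.0)
                trial[~free] = 0.0
                trial = np.minimum(trial, cap)
                r2_t, B_t, c_t = evaluate(trial)
                if comp_resid(trial, r2_t).max() < worst:
                    break
                s *= 0.5
            erc_sub, r2_cur, B, c_mu = trial, r2_t, B_t, c_t

    iworst = int(np.argmax(resid))
    raise ConvergenceError(
        f"reverse reliability did not converge in {max_iter} sweeps; "
        f"worst residual {worst:.3e} at subset position {iworst} "
        f"(animal index {int(subset[iworst])})"
    )


# ---------------------------------------------------------------------------
# Schemes A-E: weights carrying genomic information for genotyped animals
# ---------------------------------------------------------------------------

def scheme_A(r2_gg: np.ndarray, vc: VarianceComponents) -> np.ndarray:
    """Deregressed genomic reliabilities; ignores the pedigree part of r2_gg."""
    return erc_from_r2(r2_gg, vc)


def scheme_B(
    erc_f_g: np.ndarray, r2_gg: np.ndarray, r2_pg: np.ndarray, vc: VarianceComponents
) -> np.ndarray:
    """Pedigree ERC plus the genomic-minus-pedigree information difference."""
    return np.asarray(erc_f_g, dtype=float) + vc.lambda_ * (_odds(r2_gg) - _odds(r2_pg))


def scheme_C(
    erc_f_g: np.ndarray, r2_gg: np.ndarray, erc_i_g: np.ndarray, vc: VarianceComponents
) -> np.ndarray:
    """Like scheme D but subtracting the genotyped-progeny contribution."""
    return (
        np.asarray(erc_f_g, dtype=float)
        + vc.lambda_ * _odds(r2_gg)
        - np.asarray(erc_i_g, dtype=float)
    )


def scheme_D(
    erc_f_g: np.ndarray, r2_gg: np.ndarray, erc_g: np.ndarray, vc: VarianceComponents
) -> np.ndarray:
    """Pedigree ERC plus deregressed genomic reliability minus own-info ERC."""
    return (
        np.asarray(erc_f_g, dtype=float)
        + vc.lambda_ * _odds(r2_gg)
        - np.asarray(erc_g, dtype=float)
    )


def scheme_E(
    erc_f_g: np.ndarray, erc_gg_rev: np.ndarray, erc_g: np.ndarray
) -> np.ndarray:
    """All-reverse-reliability scheme: ERC_f,g + ERC_gg,rev - ERC_g."""
    return (
        np.asarray(erc_f_g, dtype=float)
        + np.asarray(erc_gg_rev, dtype=float)
        - np.asarray(erc_g, dtype=float)
    )


def interbull_progeny_erc(
    r2_full: np.ndarray,
    r2_reduced: np.ndarray,
    genotyped: np.ndarray,
    A_inverse,
    inbreeding: np.ndarray,
    vc: VarianceComponents,
    **reverse_kwargs,
) -> np.ndarray:
    """Per-animal ERC attributable to genotyped progeny (differencing proxy).

    ``r2_full`` are the Step-1 reliabilities of all animals; ``r2_reduced``
    the same quantity recomputed after removing the records of genotyped
    progeny (each such animal's own record restored for its own value).
    Both vectors are reversed to weights under the *no-mean* weighted animal
    model -- measuring information against a known mean keeps unrelated
    animals exactly decoupled -- and differenced; the genotyped part of the
    difference is returned.

    This is a synthetic stand-in for the Interbull effective daughter
    contribution convention: information that reaches an animal through the
    removed records but not through its own progeny is still attributed to
    progeny, so values are approximate and may be slightly negative.
    """
    p = A_inverse.shape[0]
    kwargs = {**reverse_kwargs, "include_mean": False}
    erc_full = reverse_reliability(
        np.asarray(r2_full, dtype=float),
        np.arange(p),
        A_inverse,
        inbreeding,
        vc,
        **kwargs,
    )
    erc_reduced = reverse_reliability(
        np.asarray(r2_reduced, dtype=float),
        np.arange(p),
        A_inverse,
        inbreeding,
        vc,
        **kwargs,
    )
    diff = erc_full - erc_reduced
    return diff[np.asarray(genotyped, dtype=np.int64)]


def combine_and_floor(
    erc_f_n: np.ndarray,
    erc_gg: np.ndarray,
    nongenotyped: np.ndarray,
    genotyped: np.ndarray,
    n_animals: int,
    floor: float = DEFAULT_FLOOR,
) -> np.ndarray:
    """Stack non-genotyped and genotyped weights and apply the lower floor.

    The two index sets must partition all pedigree animals exactly once.
    Weights below ``floor`` (including negative scheme outputs) are raised to
    ``floor`` to avoid extreme weights in the final weighted animal model.
    """
    nongenotyped = np.asarray(nongenotyped, dtype=np.int64)
    genotyped = np.asarray(genotyped, dtype=np.int64)
    combined_idx = np.concatenate([nongenotyped, genotyped])
    if not np.array_equal(np.sort(combined_idx), np.arange(n_animals)):
        raise PartitionError(
            "genotyped and non-genotyped sets must partition the pedigree"
        )
    out = np.empty(n_animals)
    out[nongenotyped] = np.asarray(erc_f_n, dtype=float)
    out[genotyped] = np.asarray(erc_gg, dtype=float)
    n_floored = int((out < floor).sum())
    if n_floored:
        logger.info("floored %d ERC values to %.3g", n_floored, floor)
    return np.maximum(out, floor)
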