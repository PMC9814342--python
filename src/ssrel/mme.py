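"""Assembly and inversion of weighted mixed-model equations (MME).

All reliability computations in this package reduce to elements of the
inverse of an MME coefficient matrix.  Every model used here has the same
shape: a general mean (optionally omitted for closed-form checks) plus one
random-effect block with a known covariance structure, and a diagonal
residual weight matrix D whose entries are effective record contributions:

    LHS = [[1'D1, 1'D X_r],
           [X_r'D1, X_r'D X_r + lambda * Omega^{-1}]]

where ``X_r`` is the incidence of the random effects on the observations
(identity for animal-effect models, the marker matrix for SNP models) and
``lambda = sigma2_e / sigma2_u``.  Prediction error variances come from the
random-effect block of ``LHS^{-1}``; no right-hand side is ever needed.

Reliability of an estimated effect with relationship diagonal ``K_ii`` is
``r2_i = 1 - lambda * C_ii / K_ii`` for animal-effect models, or
``r2_i = 1 - lambda * (W_i C^{uu} W_i') / K_ii`` for marker-effect models,
with ``W_i`` the covariate row of animal i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .genomic import MarkerMatrix
from .pedigree import RelationshipMatrix

logger = logging.getLogger(__name__)

#: dense factorization is used up to this many equations
DEFAULT_DENSE_LIMIT = 5000

#: ridge added to a numerically singular relationship matrix when permitted
RIDGE = 1e-8


class ModelError(ValueError):
    pass


class NumericalError(RuntimeError):
    """A reliability fell below zero beyond round-off: ill-conditioned MME."""


@dataclass(frozen=True)
class VarianceComponents:
    """Additive genetic variance, residual variance, and RPG proportion.

    ``omega`` is the fraction of additive variance assigned to the residual
    polygenic effect (pedigree-based) rather than the markers.
    """

    sigma2_u: float
    sigma2_e: float
    omega: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2_u <= 0 or self.sigma2_e <= 0:
            raise ValueError("variances must be strictly positive")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must be in [0, 1], got {self.omega}")

    @property
    def lambda_(self) -> float:
        """Variance ratio sigma2_e / sigma2_u."""
        return self.sigma2_e / self.sigma2_u


def _check_weights(weights: np.ndarray, n: int, what: str = "weights") -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ModelError(f"{what} must have length {n}, got shape {w.shape}")
    if not np.isfinite(w).all() or (w < 0).any():
        raise ModelError(f"{what} must be finite and nonnegative")
    return w


def invert_psd(K: np.ndarray, allow_ridge: bool = False, what: str = "matrix") -> np.ndarray:
    """Invert a symmetric PSD matrix by Cholesky, optionally with a ridge.

    A ridge of ``RIDGE`` on the diagonal is used (and logged) only when
    ``allow_ridge`` is set and the plain factorization fails; otherwise a
    singular matrix raises :class:`ModelError`.
    """
    K = np.asarray(K, dtype=float)
    try:
        c = sla.cho_factor(K, lower=True)
        return sla.cho_solve(c, np.eye(K.shape[0]))
    except sla.LinAlgError:
        if not allow_ridge:
            raise ModelError(f"{what} is singular; no ridge permitted") from None
        logger.warning("%s singular; adding ridge %.1e to its diagonal", what, RIDGE)
        c = sla.cho_factor(K + RIDGE * np.eye(K.shape[0]), lower=True)
        return sla.cho_solve(c, np.eye(K.shape[0]))


class MMEFactor:
    """Factorized MME coefficient matrix with access to inverse blocks.

    Equations are ordered fixed effects first (the general mean when
    present), then the random effects.  ``inverse_diag`` and
    ``quadratic_forms`` both address the random-effect block of the inverse.
    """

    def __init__(
        self,
        model_kind: str,
        lhs,
        n_fixed: int,
        row_covariates: np.ndarray | None = None,
        dense_limit: int = DEFAULT_DENSE_LIMIT,
    ) -> None:
        self.model_kind = model_kind
        self.n_fixed = n_fixed
        self.row_covariates = row_covariates
        n = lhs.shape[0]
        self.n_equations = n
        self.n_random = n - n_fixed
        self._dense = not sp.issparse(lhs) or n <= dense_limit
        if self._dense:
            self.lhs = lhs.toarray() if sp.issparse(lhs) else np.asarray(lhs)
            self._chol = None
        else:
            self.lhs = sp.csc_matrix(lhs)
            self._lu = None
        self._inv_cache: np.ndarray | None = None

    # -- factorization ----------------------------------------------------
    def _factorize(self):
        if self._dense:
            if self._chol is None:
                try:
                    self._chol = sla.cho_factor(self.lhs, lower=True)
                except sla.LinAlgError as exc:
                    raise ModelError(
                        f"{self.model_kind} MME coefficient matrix is singular"
                    ) from exc
            return self._chol
        if self._lu is None:
            self._lu = spla.splu(self.lhs)
        return self._lu

    def solve_columns(self, cols: np.ndarray) -> np.ndarray:
        """Columns of ``LHS^{-1} B`` for a dense right-hand side block B."""
        fac = self._factorize()
        if self._dense:
            return sla.cho_solve(fac, cols)
        return fac.solve(cols)

    def _full_inverse(self) -> np.ndarray:
        if self._inv_cache is None:
            self._inv_cache = self.solve_columns(np.eye(self.n_equations))
        return self._inv_cache

    # -- inverse access ----------------------------------------------------
    def inverse_block(self, idx: np.ndarray) -> np.ndarray:
        """Block of the inverse over the given random-effect rows/columns."""
        idx = np.asarray(idx, dtype=np.int64)
        rows = self.n_fixed + idx
        if idx.size > self.n_equations // 2 and self._dense:
            return self._full_inverse()[np.ix_(rows, rows)]
        E = np.zeros((self.n_equations, idx.size))
        E[rows, np.arange(idx.size)] = 1.0
        return self.solve_columns(E)[rows, :]

    def inverse_diag(self, idx: np.ndarray | None = None) -> np.ndarray:
        """Diagonal of the random-effect block of the inverse (the PEV/sigma2_e)."""
        if idx is None:
            idx = np.arange(self.n_random)
        idx = np.asarray(idx, dtype=np.int64)
        rows = self.n_fixed + idx
        if idx.size > self.n_equations // 2 and self._dense:
            return np.diag(self._full_inverse())[rows]
        E = np.zeros((self.n_equations, idx.size))
        E[rows, np.arange(idx.size)] = 1.0
        sol = self.solve_columns(E)
        return sol[rows, np.arange(idx.size)]

    def quadratic_forms(self, V: np.ndarray) -> np.ndarray:
        """diag(V C^{uu} V') for rows ``V`` over the random-effect coordinates."""
        V = np.atleast_2d(np.asarray(V, dtype=float))
        if V.shape[1] != self.n_random:
            raise ModelError("covariate rows must span the random-effect block")
        B = np.zeros((self.n_equations, V.shape[0]))
        B[self.n_fixed :, :] = V.T
        sol = self.solve_columns(B)
        return np.einsum("ij,ji->i", V, sol[self.n_fixed :, :])


def _bordered(D: np.ndarray, penalty, include_mean: bool) -> np.ndarray:
    """Assemble [[1'D1, 1'D], [D1, D + penalty]] (mean row optional)."""
    n = D.size
    core = penalty.toarray() if sp.issparse(penalty) else np.array(penalty, dtype=float)
    core[np.diag_indices(n)] += D
    if not include_mean:
        return core
    lhs = np.empty((n + 1, n + 1))
    lhs[0, 0] = D.sum()
    lhs[0, 1:] = D
    lhs[1:, 0] = D
    lhs[1:, 1:] = core
    return lhs


def assemble_weighted_pblup(
    A_inverse: sp.spmatrix,
    weights: np.ndarray,
    vc: VarianceComponents,
    include_mean: bool = True,
    dense_limit: int = DEFAULT_DENSE_LIMIT,
) -> MMEFactor:
    """MME of the weighted animal model y = 1*mu + a + e, e ~ N(0, D^{-1} s2e).

    The model used to propagate information through the pedigree: only a
    general mean and additive genetic effects, with per-animal weights
    (effective record contributions) on the residual precision.
    """
    p = A_inverse.shape[0]
    w = _check_weights(weights, p)
    if include_mean and w.sum() == 0:
        raise ModelError("all weights are zero: model for the mean is singular")
    lam = vc.lambda_
    p_big = p + (1 if include_mean else 0) > dense_limit
    if p_big:
        n = p + (1 if include_mean else 0)
        core = lam * sp.csc_matrix(A_inverse) + sp.diags(w)
        if include_mean:
            ws = sp.csc_matrix(w.reshape(1, -1))
            lhs = sp.bmat(
                [[sp.csc_matrix([[w.sum()]]), ws], [ws.T, core]], format="csc"
            )
        else:
            lhs = core
        return MMEFactor("weighted_pblup", lhs, int(include_mean), dense_limit=dense_limit)
    lhs = _bordered(w, lam * sp.csc_matrix(A_inverse), include_mean)
    return MMEFactor("weighted_pblup", lhs, int(include_mean), dense_limit=dense_limit)


def assemble_snpblup_direct(
    Zm: MarkerMatrix,
    A22: RelationshipMatrix,
    weights: np.ndarray,
    vc: VarianceComponents,
    include_mean: bool = True,
) -> MMEFactor:
    """SNPBLUP with an explicit residual polygenic effect.

    Covariates are W = [sqrt(1-omega) Z, sqrt(omega) I_n]; the random effects
    u = (marker effects, RPG effects) have prior covariance
    blockdiag(I_m, A22) * sigma2_u.  ``row_covariates`` on the returned factor
    holds W for the reliability quadratic forms.
    """
    n, m = Zm.n_animals, Zm.n_markers
    w = _check_weights(weights, n)
    omega = vc.omega
    W = np.hstack([np.sqrt(1.0 - omega) * Zm.Z, np.sqrt(omega) * np.eye(n)])
    A22_inv = invert_psd(A22.values, what="A22")
    omega_inv = sla.block_diag(np.eye(m), A22_inv)
    DW = w[:, None] * W
    lhs_core = W.T @ DW + vc.lambda_ * omega_inv
    if include_mean:
        k = m + n
        lhs = np.empty((k + 1, k + 1))
        lhs[0, 0] = w.sum()
        lhs[0, 1:] = DW.sum(axis=0)
        lhs[1:, 0] = lhs[0, 1:]
        lhs[1:, 1:] = lhs_core
    else:
        lhs = lhs_core
    return MMEFactor("snpblup_rpg", lhs, int(include_mean), row_covariates=W)


def assemble_snpblup(
    Zm: MarkerMatrix,
    weights: np.ndarray,
    vc: VarianceComponents,
    include_mean: bool = True,
) -> MMEFactor:
    """SNPBLUP without the residual polygenic effect (marker effects only)."""
    n, m = Zm.n_animals, Zm.n_markers
    w = _check_weights(weights, n)
    Z = Zm.Z
    DZ = w[:, None] * Z
    lhs_core = Z.T @ DZ + vc.lambda_ * np.eye(m)
    if include_mean:
        lhs = np.empty((m + 1, m + 1))
        lhs[0, 0] = w.sum()
        lhs[0, 1:] = DZ.sum(axis=0)
        lhs[1:, 0] = lhs[0, 1:]
        lhs[1:, 1:] = lhs_core
    else:
        lhs = lhs_core
    return MMEFactor("snpblup", lhs, int(include_mean), row_covariates=Z)


def assemble_gblup(
    K: np.ndarray,
    weights: np.ndarray,
    vc: VarianceComponents,
    include_mean: bool = True,
    allow_ridge: bool = False,
) -> MMEFactor:
    """Animal-effect model on the genotyped set with relationship matrix K.

    ``K`` is either G = ZZ' (no RPG) or G_omega; a pure ZZ' with more animals
    than markers is rank-deficient, in which case a logged ridge may be
    permitted.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    w = _check_weights(weights, n)
    Kinv = invert_psd(K, allow_ridge=allow_ridge, what="GBLUP relationship matrix")
    lhs = _bordered(w, vc.lambda_ * Kinv, include_mean)
    kind = "gblup_rpg" if vc.omega > 0 else "gblup"
    return MMEFactor(kind, lhs, int(include_mean))


def build_H_inverse(
    A_inverse: sp.spmatrix,
    A22: RelationshipMatrix,
    G_omega: np.ndarray,
    genotyped: np.ndarray,
) -> np.ndarray:
    """Single-step relationship inverse H^{-1} = A^{-1} + [0; Gw^{-1} - A22^{-1}]."""
    genotyped = np.asarray(genotyped, dtype=np.int64)
    Hinv = A_inverse.toarray() if sp.issparse(A_inverse) else np.array(A_inverse)
    if genotyped.size == 0:
        return Hinv
    if A22.n != genotyped.size or G_omega.shape[0] != genotyped.size:
        raise ModelError("genotyped set, A22 and G_omega dimensions disagree")
    Gw_inv = invert_psd(G_omega, what="G_omega")
    A22_inv = invert_psd(A22.values, what="A22")
    Hinv[np.ix_(genotyped, genotyped)] += Gw_inv - A22_inv
    return Hinv


def assemble_ssgblup_exact(
    A_inverse: sp.spmatrix,
    A22: RelationshipMatrix,
    G_omega: np.ndarray,
    genotyped: np.ndarray,
    weights_all: np.ndarray,
    vc: VarianceComponents,
    include_mean: bool = True,
) -> MMEFactor:
    """Single-step animal model over the full pedigree (the exact oracle)."""
    p = A_inverse.shape[0]
    w = _check_weights(weights_all, p, "weights_all")
    Hinv = build_H_inverse(A_inverse, A22, G_omega, genotyped)
    lhs = _bordered(w, vc.lambda_ * Hinv, include_mean)
    return MMEFactor("ssgblup", lhs, int(include_mean))


def reliability_from_factor(
    factor: MMEFactor,
    denominators: np.ndarray,
    vc: VarianceComponents,
    effect_indices: np.ndarray | None = None,
    row_covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Per-animal reliabilities 1 - lambda * PEV_i / (sigma2_u * K_ii).

    For animal-effect models the PEV element is the diagonal of the inverse
    random-effect block (select rows with ``effect_indices``).  For marker
    models pass the covariate rows ``W_i`` (defaults to the factor's stored
    ``row_covariates``) and the quadratic form W_i C^{uu} W_i' is used.

    ``denominators`` are the relationship diagonal of the model: 1 + F_i for
    pedigree models, G_ii or (G_omega)_ii for genomic models.
    """
    den = np.asarray(denominators, dtype=float)
    if (den <= 0).any():
        raise ModelError("relationship diagonal (denominators) must be positive")
    if row_covariates is None and factor.row_covariates is not None:
        row_covariates = factor.row_covariates
        if effect_indices is not None:
            row_covariates = row_covariates[np.asarray(effect_indices, dtype=np.int64)]
    if row_covariates is not None:
        quad = factor.quadratic_forms(row_covariates)
    else:
        quad = factor.inverse_diag(effect_indices)
    r2 = 1.0 - vc.lambda_ * quad / den
    if (r2 < -1e-10).any():
        worst = float(r2.min())
        raise NumericalError(
            f"reliability {worst:.3e} below zero: ill-conditioned {factor.model_kind} system"
        )
    n_clip = int(((r2 < 0) | (r2 > 1 - 1e-12)).sum())
    if n_clip:
        logger.info("clipped %d reliabilities into [0, 1)", n_clip)
    return np.clip(r2, 0.0, 1.0 - 1e-12)
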