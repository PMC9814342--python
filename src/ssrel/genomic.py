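"""Marker matrices and genomic relationship matrices.

Centering and scaling follow VanRaden's first method: dosages are centered by
twice the allele frequency and the whole matrix is divided by the single
scalar sqrt(2 * sum_i p_i (1 - p_i)), so that G = Z Z' has average diagonal
near 1 + f in an unselected population.  The combined matrix used when a
residual polygenic (RPG) proportion ``omega`` is modelled is
G_omega = (1 - omega) * Z Z' + omega * A22.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .pedigree import RelationshipMatrix

logger = logging.getLogger(__name__)


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeSet:
    """Allele dosages (0/1/2) for genotyped animals, with allele frequencies.

    ``allele_freq`` defaults to frequencies observed in these animals; an
    external base-population frequency file may override it.  Missing dosages
    (NaN) are mean-imputed to 2p at centering time.
    """

    animal_ids: list[str]
    dosages: np.ndarray
    allele_freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise GenotypeError("dosages must be a 2-D animals x markers array")
        if len(self.animal_ids) != self.dosages.shape[0]:
            raise GenotypeError("animal_ids and dosage rows differ in length")
        obs = self.dosages[~np.isnan(self.dosages)]
        if not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise GenotypeError("dosages must be 0, 1 or 2 (NaN for missing)")
        if self.allele_freq is None:
            self.allele_freq = observed_frequencies(self.dosages)
        else:
            self.allele_freq = np.asarray(self.allele_freq, dtype=float)
            if self.allele_freq.size != self.n_markers:
                raise GenotypeError("allele_freq length must equal marker count")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def drop_monomorphic(self, eps: float = 0.0) -> "GenotypeSet":
        """Return a copy without markers whose frequency is <= eps or >= 1-eps."""
        p = self.allele_freq
        keep = (p > eps) & (p < 1.0 - eps)
        if not keep.all():
            logger.info("dropping %d monomorphic markers", int((~keep).sum()))
        return GenotypeSet(
            animal_ids=list(self.animal_ids),
            dosages=self.dosages[:, keep],
            allele_freq=p[keep],
        )


@dataclass
class MarkerMatrix:
    """Centered and scaled marker covariates ``Z`` (n animals x m markers)."""

    Z: np.ndarray
    scale_constant: float
    animal_ids: list[str] = field(default_factory=list)

    @property
    def n_animals(self) -> int:
        return self.Z.shape[0]

    @property
    def n_markers(self) -> int:
        return self.Z.shape[1]


def observed_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Per-marker allele frequencies observed in the dosage matrix."""
    return np.nanmean(np.asarray(dosages, dtype=float), axis=0) / 2.0


def center_scale(geno: GenotypeSet) -> MarkerMatrix:
    """Center dosages by 2p and divide by the global scalar sqrt(2 sum p(1-p)).

    Raises
    ------
    GenotypeError
        If any marker is monomorphic (p = 0 or 1); remove such markers with
        :meth:`GenotypeSet.drop_monomorphic` first.
    """
    p = geno.allele_freq
    if (p <= 0.0).any() or (p >= 1.0).any():
        bad = int(((p <= 0.0) | (p >= 1.0)).sum())
        raise GenotypeError(
            f"{bad} monomorphic marker(s) present; remove them before scaling"
        )
    scale = 2.0 * np.sum(p * (1.0 - p))
    M = geno.dosages.copy()
    nan_mask = np.isnan(M)
    if nan_mask.any():
        M[nan_mask] = np.broadcast_to(2.0 * p, M.shape)[nan_mask]
        logger.info("mean-imputed %d missing dosages", int(nan_mask.sum()))
    Z = (M - 2.0 * p) / np.sqrt(scale)
    return MarkerMatrix(Z=Z, scale_constant=scale, animal_ids=list(geno.animal_ids))


def build_G(Zm: MarkerMatrix) -> np.ndarray:
    """Genomic relationship matrix G = Z Z'."""
    return Zm.Z @ Zm.Z.T


def build_G_omega(
    G: np.ndarray, A22: RelationshipMatrix | np.ndarray, omega: float
) -> np.ndarray:
    """RPG-combined relationship matrix (1 - omega) G + omega A22."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must be in [0, 1], got {omega}")
    A22v = A22.values if isinstance(A22, RelationshipMatrix) else np.asarray(A22)
    if A22v.shape != np.asarray(G).shape:
        raise ValueError("G and A22 must be conformable")
    return (1.0 - omega) * np.asarray(G) + omega * A22v
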