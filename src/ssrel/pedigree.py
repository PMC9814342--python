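"""Pedigree parsing, ordering, and numerator relationship matrices.

A pedigree is a list of (animal, sire, dam) triples.  Internally animals are
mapped to dense 0-based indices in a topological order, i.e. every parent
precedes all of its offspring.  Unknown parents are treated as unrelated,
non-inbred founders (no genetic groups).

The additive (numerator) relationship matrix ``A`` is built by the tabular
method; its sparse inverse comes from Henderson's rules with inbreeding
accounted for, where the per-animal inbreeding coefficients are obtained with
the Meuwissen & Luo algorithm so that no dense matrix is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = -1

#: strings interpreted as "parent unknown" in pedigree files
MISSING_CODES = {"0", "NA", "na", ".", ""}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate, bad reference)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Attributes
    ----------
    ids : list of str
        Animal identifiers in internal order (parents before offspring).
    sire, dam : ndarray of int
        Parent indices per animal; ``UNKNOWN`` (-1) for missing parents.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if not (len(self.ids) == self.sire.size == self.dam.size):
            raise PedigreeError("ids, sire and dam must have equal length")
        self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise PedigreeError("duplicate animal identifiers")
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            bad = (par != UNKNOWN) & ((par < 0) | (par >= self.n_animals))
            if bad.any():
                raise PedigreeError(f"{name} index out of range")
        idx = np.arange(self.n_animals)
        known_s = self.sire != UNKNOWN
        known_d = self.dam != UNKNOWN
        if (self.sire[known_s] >= idx[known_s]).any() or (
            self.dam[known_d] >= idx[known_d]
        ).any():
            raise PedigreeError("pedigree is not topologically sorted")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        """Map external identifiers to internal indices."""
        try:
            return np.array([self._index[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise PedigreeError(f"unknown animal id {exc.args[0]!r}") from exc


@dataclass
class RelationshipMatrix:
    """Symmetric additive relationship matrix with inbreeding coefficients.

    ``values[i, i] == 1 + inbreeding[i]`` for every animal.
    """

    values: np.ndarray
    inbreeding: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _looks_like_header(fields: list[str]) -> bool:
    names = {"animal", "animal_id", "id", "sire", "dam", "father", "mother"}
    return any(f.strip().lower() in names for f in fields)


def read_pedigree(path) -> Pedigree:
    """Read a three-column pedigree file and return it topologically sorted.

    Columns are animal, sire, dam separated by whitespace or commas; "0" or
    "NA" denote an unknown parent.  A header line is auto-detected.  Parents
    that appear only as parents are added as founders.
    """
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 3:
                raise PedigreeError(
                    f"line {lineno}: expected 3 columns (animal sire dam)"
                )
            rows.append((fields[0], fields[1], fields[2]))
    return pedigree_from_records(rows)


def pedigree_from_records(rows) -> Pedigree:
    """Build a sorted :class:`Pedigree` from (animal, sire, dam) id triples."""
    parents: dict[str, tuple[str | None, str | None]] = {}
    order_seen: list[str] = []
    for animal, sire, dam in rows:
        s = None if sire in MISSING_CODES else sire
        d = None if dam in MISSING_CODES else dam
        if animal in MISSING_CODES:
            raise PedigreeError("animal id is a missing-value code")
        if animal in parents:
            raise PedigreeError(f"duplicate animal id {animal!r}")
        if animal in (s, d):
            raise PedigreeError(f"animal {animal!r} is its own parent")
        parents[animal] = (s, d)
        order_seen.append(animal)
    # parents that never appear as animals become founders
    for animal in list(parents):
        for par in parents[animal]:
            if par is not None and par not in parents:
                parents[par] = (None, None)
                order_seen.append(par)

    # Kahn's algorithm: parent precedes offspring
    children: dict[str, list[str]] = {a: [] for a in parents}
    indeg = {a: 0 for a in parents}
    for animal, (s, d) in parents.items():
        for par in {s, d} - {None}:
            children[par].append(animal)
            indeg[animal] += 1
    queue = [a for a in order_seen if indeg[a] == 0]
    topo: list[str] = []
    while queue:
        a = queue.pop(0)
        topo.append(a)
        for ch in children[a]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                queue.append(ch)
    if len(topo) != len(parents):
        cyc = sorted(a for a in parents if indeg[a] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving {cyc[0]!r}")

    pos = {a: i for i, a in enumerate(topo)}
    sire = np.full(len(topo), UNKNOWN, dtype=np.int64)
    dam = np.full(len(topo), UNKNOWN, dtype=np.int64)
    for a, (s, d) in parents.items():
        i = pos[a]
        if s is not None:
            sire[i] = pos[s]
        if d is not None:
            dam[i] = pos[d]
    return Pedigree(ids=topo, sire=sire, dam=dam)


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Full numerator relationship matrix by the tabular method.

    Diagonal is ``1 + F_i`` with ``F_i = 0.5 * A[sire_i, dam_i]``; an animal
    with one or both parents unknown receives no inbreeding contribution from
    the unknown side.
    """
    p = ped.n_animals
    A = np.zeros((p, p))
    for i in range(p):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        f_i = 0.5 * A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[i, i] = 1.0 + f_i
    return RelationshipMatrix(values=A, inbreeding=np.diag(A) - 1.0)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo L'DL traversal.

    Computes each F_i from the ancestor decomposition A_ii = sum_j L_ij^2 d_j
    without building any dense matrix; O(p * ancestors) time.
    """
    p = ped.n_animals
    F = np.zeros(p)
    # within-family (Mendelian sampling) variances, filled as we go
    dvar = np.zeros(p)
    for i in range(p):
        s, d = ped.sire[i], ped.dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            dvar[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s != UNKNOWN or d != UNKNOWN:
            known = s if s != UNKNOWN else d
            dvar[i] = 0.75 - 0.25 * F[known]
        else:
            dvar[i] = 1.0
        if s == UNKNOWN or d == UNKNOWN:
            F[i] = 0.0
            continue
        # accumulate L row of animal i over its ancestors
        L: dict[int, float] = {i: 1.0}
        aii = 0.0
        for j in range(i, -1, -1):
            lij = L.pop(j, 0.0)
            if lij == 0.0:
                continue
            aii += lij * lij * dvar[j]
            for par in (ped.sire[j], ped.dam[j]):
                if par != UNKNOWN:
                    L[par] = L.get(par, 0.0) + 0.5 * lij
        F[i] = aii - 1.0
    return F


def extract_A22(A: RelationshipMatrix, genotyped: np.ndarray) -> RelationshipMatrix:
    """Principal submatrix of ``A`` for the genotyped animals."""
    genotyped = np.asarray(genotyped, dtype=np.int64)
    if genotyped.size == 0:
        raise PedigreeError("genotyped set is empty")
    if genotyped.min() < 0 or genotyped.max() >= A.n:
        raise PedigreeError("genotyped index out of range")
    if np.unique(genotyped).size != genotyped.size:
        raise PedigreeError("genotyped indices must be unique")
    sub = A.values[np.ix_(genotyped, genotyped)]
    return RelationshipMatrix(values=sub, inbreeding=A.inbreeding[genotyped])


def build_A_inverse(ped: Pedigree, inbreeding: np.ndarray | None = None) -> sp.csc_matrix:
    """Sparse inverse of the numerator relationship matrix (Henderson's rules).

    Uses the exact within-family variances 0.5 - 0.25 (F_s + F_d) so the
    result is the true inverse of the tabular A, including for inbred
    pedigrees.
    """
    p = ped.n_animals
    F = inbreeding_coefficients(ped) if inbreeding is None else np.asarray(inbreeding)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(p):
        s, d = ped.sire[i], ped.dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            dvar = 0.5 - 0.25 * (F[s] + F[d])
        elif s != UNKNOWN or d != UNKNOWN:
            known = s if s != UNKNOWN else d
            dvar = 0.75 - 0.25 * F[known]
        else:
            dvar = 1.0
        alpha = 1.0 / dvar
        add(i, i, alpha)
        for par in (s, d):
            if par != UNKNOWN:
                add(i, par, -alpha / 2.0)
                add(par, i, -alpha / 2.0)
        known_parents = [x for x in (s, d) if x != UNKNOWN]
        for a in known_parents:
            for b in known_parents:
                add(a, b, alpha / 4.0)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(p, p)).tocsc()
    return Ainv
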