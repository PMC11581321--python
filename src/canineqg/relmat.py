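"""Relationship matrices for pedigree and genomic evaluation.

Builds the pedigree numerator relationship matrix A (tabular method, with
inbreeding), its sparse-rule inverse (Henderson's rules accounting for
inbreeding), the genotyped-block A22, the VanRaden genomic relationship
matrix G, the column-centered GRM used by mixed-model association, and the
single-step blended inverse

    H^-1 = A^-1 + [0 0; 0 (w_g G + w_a A22)^-1 - A22^-1]

with default blend weights w_g = 0.95, w_a = 0.05. Dense linear algebra
throughout: the target scale is at most a few thousand animals.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import IntegrityError, NumericalError
from .formats import GenotypeMatrix
from .pedigree import (
    Pedigree,
    inbreeding_coefficients,
    mendelian_sampling_variances,
)

#: diagonal ridge applied to G before inversion inside the single-step blend
G_RIDGE = 1e-8


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix keyed by animal identifiers."""

    kind: str  # A, A_INV, A22, G_VANRADEN, G_CENTERED, H_INV
    ids: list[str]
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = list(map(str, self.ids))
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise IntegrityError("relationship matrix shape does not match id count")
        if n and np.max(np.abs(self.values - self.values.T)) > 1e-8:
            raise IntegrityError(f"{self.kind} matrix is not symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        pos = {a: i for i, a in enumerate(self.ids)}
        try:
            idx = np.array([pos[str(a)] for a in ids], dtype=np.int64)
        except KeyError as exc:
            raise IntegrityError(f"unknown animal id {exc.args[0]!r}") from exc
        return RelationshipMatrix(
            self.kind, [str(a) for a in ids], self.values[np.ix_(idx, idx)],
            dict(self.metadata),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class PedigreeSummary:
    n_animals: int
    n_sires: int
    n_dams: int
    n_fullsib_families: int
    mean_fullsib_family_size: float
    n_inbred: int
    mean_F_all: float
    mean_F_inbred: float
    max_F: float


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ij = (a_{j,sire(i)} + a_{j,dam(i)}) / 2 for j < i and
    a_ii = 1 + a_{sire(i),dam(i)} / 2; the diagonal is cross-checked against
    the Meuwissen-Luo inbreeding coefficients.
    """
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if i:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    F = inbreeding_coefficients(pedigree)
    if n and np.max(np.abs(np.diag(A) - 1.0 - F)) > 1e-10:
        raise NumericalError("tabular diagonal disagrees with Meuwissen-Luo inbreeding")
    return RelationshipMatrix("A", pedigree.ids, A, {"inbreeding": F})


def build_A_inverse(pedigree: Pedigree) -> RelationshipMatrix:
    """A^-1 by Henderson's rules with inbreeding.

    Each animal contributes alpha_i = 1/d_i to the mixed-model structure,
    where d_i is its Mendelian-sampling variance computed from parental
    inbreeding coefficients.
    """
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    F = inbreeding_coefficients(pedigree)
    d = mendelian_sampling_variances(pedigree, F)
    Ainv = np.zeros((n, n))
    for i in range(n):
        alpha = 1.0 / d[i]
        parents = [p for p in (sire[i], dam[i]) if p >= 0]
        Ainv[i, i] += alpha
        for p in parents:
            Ainv[i, p] -= alpha / 2.0
            Ainv[p, i] -= alpha / 2.0
        for p in parents:
            for q in parents:
                Ainv[p, q] += alpha / 4.0
    return RelationshipMatrix("A_INV", pedigree.ids, Ainv, {"inbreeding": F})


def extract_A22(A: RelationshipMatrix, genotyped_ids: Sequence[str]) -> RelationshipMatrix:
    """Principal submatrix of A for the genotyped animals, in the given order."""
    sub = A.submatrix(genotyped_ids)
    sub.kind = "A22"
    return sub


def _genomic_cross_product(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    X = gm.dosage
    if np.isnan(X).any():
        raise NumericalError("missing dosages present; impute before building a GRM")
    p = X.mean(axis=0) / 2.0
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        bad = [gm.snp_ids[j] for j in np.flatnonzero(mono)[:5]]
        raise NumericalError(
            f"monomorphic SNPs have zero variance (e.g. {bad}); remove them in QC"
        )
    return X, p


def build_G_vanraden(gm: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden method-1 GRM: G = MM' / (2 * sum_i p_i (1 - p_i)).

    M holds dosages centered by twice the observed allele frequency of the
    counted (minor) allele; the scaling makes the mean diagonal ~1 in an
    unrelated, non-inbred sample.
    """
    X, p = _genomic_cross_product(gm)
    M = X - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (M @ M.T) / denom
    return RelationshipMatrix(
        "G_VANRADEN", gm.animal_ids, G,
        {"allele_freq": p, "denominator": denom},
    )


def build_G_centered(gm: GenotypeMatrix) -> RelationshipMatrix:
    """Column-centered GRM, K = (1/p) sum_i (x_i - xbar_i)(x_i - xbar_i)'.

    This is the kinship standardization used by mixed-model association
    software; rows/columns sum to zero (K 1 = 0).
    """
    X, p = _genomic_cross_product(gm)
    M = X - X.mean(axis=0)
    G = (M @ M.T) / gm.n_snps
    return RelationshipMatrix("G_CENTERED", gm.animal_ids, G, {"allele_freq": p})


def build_H_inverse(
    A_inv: RelationshipMatrix,
    A22: RelationshipMatrix,
    G: RelationshipMatrix,
    tau_g: float = 0.95,
    tau_a: float = 0.05,
) -> RelationshipMatrix:
    """Single-step H^-1 from A^-1 plus the genotyped-block correction.

    The genomic block uses the blend tau_g * G + tau_a * A22 (weights must
    sum to 1). A tiny ridge is added to G's diagonal before inversion and
    recorded in metadata when applied.
    """
    if abs(tau_g + tau_a - 1.0) > 1e-12:
        raise NumericalError(f"blend weights must sum to 1, got {tau_g} + {tau_a}")
    if A22.ids != G.ids:
        raise IntegrityError("A22 and G must be indexed by the same ids in the same order")
    pos = {a: i for i, a in enumerate(A_inv.ids)}
    try:
        gidx = np.array([pos[a] for a in G.ids], dtype=np.int64)
    except KeyError as exc:
        raise IntegrityError(f"genotyped id {exc.args[0]!r} absent from A^-1") from exc
    n_g = len(G.ids)
    Hinv = A_inv.values.copy()
    meta = {"tau_g": tau_g, "tau_a": tau_a, "ridge": 0.0}
    if n_g:
        Gv = G.values + G_RIDGE * np.eye(n_g)
        meta["ridge"] = G_RIDGE
        blend = tau_g * Gv + tau_a * A22.values
        evals = scipy.linalg.eigvalsh(blend)
        if evals[0] <= 0:
            raise NumericalError(
                f"blended genomic matrix is singular (smallest eigenvalue {evals[0]:.3e})"
            )
        correction = np.linalg.inv(blend) - np.linalg.inv(A22.values)
        Hinv[np.ix_(gidx, gidx)] += correction
    return RelationshipMatrix("H_INV", A_inv.ids, Hinv, meta)


def pedigree_summary(pedigree: Pedigree, A: RelationshipMatrix) -> PedigreeSummary:
    """Structure summary: parent counts, full-sib families, inbreeding.

    A full-sib family is a maximal set of >= 2 animals sharing both (known)
    parents; inbred means F > 0 where F = diag(A) - 1.
    """
    if A.ids != pedigree.ids:
        raise IntegrityError("A matrix was not built from this pedigree")
    sires = {r.sire_id for r in pedigree.records if r.sire_id is not None}
    dams = {r.dam_id for r in pedigree.records if r.dam_id is not None}
    fams: dict[tuple[str, str], int] = {}
    for r in pedigree.records:
        if r.sire_id is not None and r.dam_id is not None:
            fams[(r.sire_id, r.dam_id)] = fams.get((r.sire_id, r.dam_id), 0) + 1
    sizes = [c for c in fams.values() if c >= 2]
    F = np.diag(A.values) - 1.0
    inbred = F > 0
    return PedigreeSummary(
        n_animals=len(pedigree),
        n_sires=len(sires),
        n_dams=len(dams),
        n_fullsib_families=len(sizes),
        mean_fullsib_family_size=float(np.mean(sizes)) if sizes else 0.0,
        n_inbred=int(inbred.sum()),
        mean_F_all=float(F.mean()) if len(F) else 0.0,
        mean_F_inbred=float(F[inbred].mean()) if inbred.any() else 0.0,
        max_F=float(F.max()) if len(F) else 0.0,
    )


def write_relationship_tsv(rm: RelationshipMatrix, path) -> None:
    rm.to_frame().to_csv(path, sep="\t")


def read_relationship_tsv(path, kind: str) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(kind, [str(c) for c in df.columns], df.to_numpy())
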