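"""Relationship matrices: pedigree A, genomic G (VanRaden), and the ssGBLUP H inverse.

A is built by the tabular method with inbreeding on the diagonal (1 + F_i).
G follows VanRaden's first method, G = ZZ' / (2 sum p_i (1 - p_i)) with
Z = M - 2p and p the observed allele frequencies of the genotyped set;
monomorphic markers contribute zero and are excluded from the denominator.
The single-step blend adds G^-1 - A22^-1 on the genotyped block of A^-1:

    H^-1 = A^-1 + [[0, 0], [0, G^-1 - A22^-1]]

Inverses are taken directly at desk scale; G is regularized as
G* = (1 - w) G + w I (default w = 0.01) before inversion because duplicated
animals or n > m make the raw G singular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genio import GenotypeMatrix
from .simdata import Pedigree, UNKNOWN

DEFAULT_G_REG = 0.01


@dataclass
class RelationshipMatrix:
    """Square symmetric relationship matrix indexed by individual ids."""

    values: np.ndarray
    ids: list
    kind: str  # one of A, G, A22, A_inv, G_inv, H_inv
    regularization: float = 0.0
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def loc(self, a, b) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def subset(self, ids, kind: str | None = None) -> "RelationshipMatrix":
        rows = np.array([self._index[i] for i in ids], dtype=int)
        return RelationshipMatrix(self.values[np.ix_(rows, rows)], list(ids),
                                  kind or self.kind, self.regularization)

    def write(self, path: str) -> None:
        """Labeled delimited text for inspection."""
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Diagonals are 1 + F_i with F_i the inbreeding coefficient; the Pedigree
    container already guarantees parents precede offspring (cyclic pedigrees
    are rejected at construction, naming the offending id).
    """
    ids = ped.ids
    n = len(ids)
    index = {v: k for k, v in enumerate(ids)}
    A = np.zeros((n, n))
    for i, (ind, sire, dam) in enumerate(ped.records):
        s = index[sire] if sire != UNKNOWN else -1
        d = index[dam] if dam != UNKNOWN else -1
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
    return RelationshipMatrix(A, ids, "A")


def build_G(g: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from observed allele frequencies."""
    if g.n_individuals < 2:
        raise ValueError("need at least two genotyped individuals")
    p = g.allele_frequency()
    het = 2.0 * p * (1.0 - p)
    poly = np.nan_to_num(het) > 0
    if not poly.any():
        raise ValueError("no polymorphic markers; G undefined")
    Z = g.dosage()[:, poly] - 2.0 * p[poly]
    denom = float(het[poly].sum())
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(G, list(g.individual_ids), "G")


def regularize(K: RelationshipMatrix, weight: float = DEFAULT_G_REG) -> RelationshipMatrix:
    """Blend toward the identity, K* = (1 - w) K + w I, recording w."""
    if weight == 0.0:
        return K
    V = (1.0 - weight) * K.values + weight * np.eye(len(K.ids))
    return RelationshipMatrix(V, K.ids, K.kind, regularization=weight)


def invert(K: RelationshipMatrix) -> RelationshipMatrix:
    inv = np.linalg.inv(K.values)
    inv = 0.5 * (inv + inv.T)
    return RelationshipMatrix(inv, K.ids, K.kind + "_inv", K.regularization)


def build_H_inverse(
    A_inv: RelationshipMatrix,
    G_inv: RelationshipMatrix,
    A22_inv: RelationshipMatrix,
    genotyped_ids=None,
) -> RelationshipMatrix:
    """Single-step blended inverse, ordered like A^-1.

    The correction G^-1 - A22^-1 is added only on the genotyped block; with
    an empty genotyped set H^-1 = A^-1, and with everyone genotyped
    H^-1 = G^-1 (A^-1 and A22^-1 cancel).
    """
    genotyped_ids = list(G_inv.ids if genotyped_ids is None else genotyped_ids)
    missing = [i for i in genotyped_ids if i not in A_inv._index]
    if missing:
        raise ValueError(f"genotyped ids absent from pedigree: {missing[:5]}")
    H = A_inv.values.copy()
    if genotyped_ids:
        rows = np.array([A_inv._index[i] for i in genotyped_ids], dtype=int)
        Gm = G_inv.subset(genotyped_ids).values
        Am = A22_inv.subset(genotyped_ids).values
        H[np.ix_(rows, rows)] += Gm - Am
    return RelationshipMatrix(0.5 * (H + H.T), list(A_inv.ids), "H_inv",
                              regularization=G_inv.regularization)


def build_H_inverse_from(
    ped: Pedigree,
    G: RelationshipMatrix,
    g_reg: float = DEFAULT_G_REG,
) -> RelationshipMatrix:
    """Convenience assembly of H^-1 from a pedigree and a (raw) G."""
    A = build_A(ped)
    A22 = A.subset(G.ids, kind="A22")
    return build_H_inverse(invert(A), invert(regularize(G, g_reg)), invert(A22),
                           list(G.ids))
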