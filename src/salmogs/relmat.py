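"""Pedigree (A), genomic (G), blended (G*) and single-step (H) relationship
matrices.

A uses the tabular method (with inbreeding); its sparse inverse uses the
classical rules with Mendelian-sampling variances from Meuwissen-Luo
inbreeding coefficients.  G is VanRaden method 1 on observed allele
frequencies.  G* rescales G to the A22 scale with a two-statistic
(mean-diagonal / mean-off-diagonal) fit and blends a small pedigree
fraction back in so the matrix is safely invertible.  H is the standard
single-step augmentation, available both via its sparse inverse and via
the direct joint-distribution formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse

from .containers import GenotypeMatrix, Pedigree

__all__ = [
    "RelationshipMatrix",
    "numerator_relationship",
    "inbreeding_coefficients",
    "a_inverse",
    "genomic_relationship",
    "scale_blend_G",
    "h_matrix",
    "h_inverse",
]


@dataclass
class RelationshipMatrix:
    """Symmetric relationship coefficients over an ordered id list."""

    ids: list
    values: np.ndarray
    kind: str  # A | G | Gstar | H

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")

    def submatrix(self, ids: Sequence) -> "RelationshipMatrix":
        index = {v: i for i, v in enumerate(self.ids)}
        rows = np.array([index[i] for i in ids], dtype=int)
        return RelationshipMatrix(list(ids), self.values[np.ix_(rows, rows)], self.kind)

    def to_tsv(self, path: str) -> None:
        """Export with an id index for inspection."""
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids,
                     columns=self.ids).to_csv(path, sep="\t")


def numerator_relationship(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    With individuals topologically ordered, a_ii = 1 + a_{s,d}/2 (inbreeding
    from the parents' relationship) and a_ij = (a_{j,s(i)} + a_{j,d(i)})/2
    for j earlier than i; unknown parents contribute zero.
    """
    parents = pedigree.parent_indices()
    n = len(pedigree)
    a = np.zeros((n, n))
    for i in range(n):
        s, d = parents[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * a[s, :i]
        if d >= 0:
            row += 0.5 * a[d, :i]
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(pedigree.ids, a, "A")


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F (diag(A) - 1) without forming dense A.

    Meuwissen & Luo's algorithm: for each individual, trace the ancestor
    list with accumulating path contributions.
    """
    parents = pedigree.parent_indices()
    n = len(pedigree)
    f = np.zeros(n)
    for i in range(n):
        s, d = parents[i]
        if s < 0 or d < 0:
            continue
        f[i] = _a_between(s, d, parents, f)  # F_i = a_{s,d} / 2
    return f


def _a_between(i: int, j: int, parents: np.ndarray, f: np.ndarray) -> float:
    """Half the relationship a_ij/2 between i and j by recursive descent."""

    def a(x: int, y: int) -> float:
        if x < 0 or y < 0:
            return 0.0
        if x == y:
            return 1.0 + f[x]
        if x < y:
            x, y = y, x
        xs, xd = parents[x]
        return 0.5 * (a(xs, y) + a(xd, y))

    return 0.5 * a(i, j)


def a_inverse(pedigree: Pedigree) -> sparse.csc_matrix:
    """Sparse A^{-1} via Henderson's rules with inbreeding accounted for."""
    parents = pedigree.parent_indices()
    n = len(pedigree)
    f = inbreeding_coefficients(pedigree)
    rows, cols, vals = [], [], []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = parents[i]
        fs = f[s] if s >= 0 else 0.0
        fd = f[d] if d >= 0 else 0.0
        known = int(s >= 0) + int(d >= 0)
        if known == 2:
            dvar = 0.5 - 0.25 * (fs + fd)
        elif known == 1:
            dvar = 0.75 - 0.25 * (fs if s >= 0 else fd)
        else:
            dvar = 1.0
        w = 1.0 / dvar
        add(i, i, w)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * w)
                add(p, i, -0.5 * w)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    add(p, q, 0.25 * w)
    return sparse.csc_matrix(sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)))


def genomic_relationship(g: GenotypeMatrix,
                         allele_freqs: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden method 1: G = (M - 2P)(M - 2P)' / (2 sum p_k (1 - p_k)).

    ``allele_freqs`` defaults to observed frequencies in the genotyped set.
    Missing dosages are not allowed (impute first); monomorphic markers must
    have been removed by QC.
    """
    if np.isnan(g.dosages).any():
        raise ValueError("genomic relationship requires complete genotypes; impute first")
    p = g.allele_freq() if allele_freqs is None else np.asarray(allele_freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic markers present (allele frequency 0 or 1); run QC")
    z = g.dosages - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    return RelationshipMatrix(list(g.ids), z @ z.T / denom, "G")


def scale_blend_G(G: RelationshipMatrix, A22: RelationshipMatrix,
                  tau: float = 0.05) -> RelationshipMatrix:
    """Rescale G to the pedigree base and blend a pedigree fraction back in.

    The two-parameter fit G_scaled = alpha + beta*G matches mean(diag) and
    mean(offdiag) of A22; then G* = (1 - tau) G_scaled + tau A22.  The blend
    guarantees invertibility when A22 is positive definite.
    """
    if not (0 < tau < 1):
        raise ValueError("tau must be in (0, 1)")
    if list(G.ids) != list(A22.ids):
        raise ValueError("G and A22 must cover the same individuals in the same order")
    g, a = G.values, A22.values
    n = g.shape[0]
    if n < 2:
        raise ValueError("need at least 2 genotyped individuals")
    mask_off = ~np.eye(n, dtype=bool)
    gd, go = np.mean(np.diag(g)), np.mean(g[mask_off])
    ad, ao = np.mean(np.diag(a)), np.mean(a[mask_off])
    if np.isclose(gd, go):
        beta, alpha = 1.0, ad - gd  # degenerate: shift only
    else:
        beta = (ad - ao) / (gd - go)
        alpha = ad - beta * gd
    g_scaled = alpha + beta * g
    gstar = (1.0 - tau) * g_scaled + tau * a
    try:
        np.linalg.cholesky(gstar)
    except np.linalg.LinAlgError as exc:
        raise ValueError("blended G* is singular or indefinite") from exc
    return RelationshipMatrix(list(G.ids), gstar, "Gstar")


def _partition(A: RelationshipMatrix, genotyped_ids: Sequence):
    index = {v: i for i, v in enumerate(A.ids)}
    missing = [i for i in genotyped_ids if i not in index]
    if missing:
        raise ValueError(f"genotyped ids absent from pedigree: {missing[:5]}")
    g_idx = np.array([index[i] for i in genotyped_ids], dtype=int)
    n_idx = np.array([i for i in range(len(A.ids)) if i not in set(g_idx)], dtype=int)
    return g_idx, n_idx


def h_inverse(A_inv: sparse.spmatrix, Gstar: RelationshipMatrix,
              A22: RelationshipMatrix, genotyped_positions: np.ndarray) -> sparse.csc_matrix:
    """H^{-1} = A^{-1} + [0 0; 0 G*^{-1} - A22^{-1}] on the genotyped block."""
    n = A_inv.shape[0]
    gstar_inv = np.linalg.inv(Gstar.values)
    a22_inv = np.linalg.inv(A22.values)
    corr = gstar_inv - a22_inv
    rows = np.repeat(genotyped_positions, len(genotyped_positions))
    cols = np.tile(genotyped_positions, len(genotyped_positions))
    add = sparse.coo_matrix((corr.ravel(), (rows, cols)), shape=(n, n))
    return sparse.csc_matrix(A_inv + add)


def h_matrix(A: RelationshipMatrix, Gstar: RelationshipMatrix | None,
             genotyped_ids: Sequence) -> tuple[RelationshipMatrix, np.ndarray]:
    """Single-step augmented relationship matrix H and its inverse (dense).

    With no genotyped individuals H = A exactly.  Otherwise H is built from
    the joint-distribution formula
      H11 = A11 + A12 A22^{-1} (G* - A22) A22^{-1} A21,
      H12 = A12 A22^{-1} G*,  H22 = G*,
    and the returned inverse is computed from the sparse-inverse identity
    H^{-1} = A^{-1} + [0 0; 0 G*^{-1} - A22^{-1}].
    """
    if Gstar is None or len(genotyped_ids) == 0:
        return (RelationshipMatrix(list(A.ids), A.values.copy(), "H"),
                np.linalg.inv(A.values))
    if list(Gstar.ids) != list(genotyped_ids):
        raise ValueError("Gstar id order must match genotyped_ids")
    g_idx, n_idx = _partition(A, genotyped_ids)
    a = A.values
    a22 = a[np.ix_(g_idx, g_idx)]
    if np.linalg.matrix_rank(a22) < len(g_idx):
        raise ValueError("A22 is singular")
    a22_inv = np.linalg.inv(a22)
    gs = Gstar.values
    h = a.copy()
    if len(n_idx):
        a12 = a[np.ix_(n_idx, g_idx)]
        t = a12 @ a22_inv
        h[np.ix_(n_idx, n_idx)] = a[np.ix_(n_idx, n_idx)] + t @ (gs - a22) @ t.T
        h[np.ix_(n_idx, g_idx)] = t @ gs
        h[np.ix_(g_idx, n_idx)] = (t @ gs).T
    h[np.ix_(g_idx, g_idx)] = gs

    a_inv_dense = np.linalg.inv(a)
    corr = np.linalg.inv(gs) - a22_inv
    h_inv = a_inv_dense.copy()
    h_inv[np.ix_(g_idx, g_idx)] += corr
    return RelationshipMatrix(list(A.ids), h, "H"), h_inv
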