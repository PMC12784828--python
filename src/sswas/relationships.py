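"""Pedigree, genomic and combined relationship matrices.

This module builds the three relationship structures single-step GBLUP
needs:

* the sparse inverse numerator relationship matrix A^-1 over all pedigree
  animals, from Henderson's rules with inbreeding coefficients computed by
  the Meuwissen-Luo recursion;
* A22, the pedigree relationship block for the genotyped animals (tabular
  recursion);
* the (optionally SNP-weighted) genomic relationship matrix
  G = Z D Z' / sum_i 2 p_i (1 - p_i), with Z the gene-content matrix
  column-centered by twice the counted-allele frequency;
* the single-step H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1], held as a sparse
  matrix plus a dense correction block on the genotyped animals.

G is blended with A22 (G* = (1-beta) G + beta A22, beta = 0.05 by default)
before inversion; with allele frequencies estimated from the genotyped set
itself, raw G is exactly singular (its rows sum to zero), so some blending
is not optional in practice.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError

from .io import UNKNOWN, GenotypePanel, Pedigree


# ---------------------------------------------------------------------------
# pedigree side


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficient per animal by the Meuwissen-Luo algorithm.

    For each animal i the self-relationship a_ii = 1 + F_i is accumulated as
    sum_j L_j^2 D_j over its ancestors j, where L is filled by halving path
    coefficients down the pedigree and D_j is the Mendelian-sampling
    variance of j given its parents' inbreeding.
    """
    if not ped.is_topological():
        raise ValueError("pedigree must be topologically sorted")
    n = ped.n
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    D = np.zeros(n)  # Mendelian sampling variance, filled in order
    for i in range(n):
        s, d = sire[i], dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            D[i] = 1.0
        elif s == UNKNOWN or d == UNKNOWN:
            k = s if s != UNKNOWN else d
            D[i] = 0.75 - 0.25 * F[k]
        else:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        if s == UNKNOWN or d == UNKNOWN:
            F[i] = 0.0
            continue
        # trace ancestors of i from i downward (max-heap on index)
        L = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j, 0.0)
            if lj == 0.0:
                continue
            aii += lj * lj * D[j]
            for p in (sire[j], dam[j]):
                if p != UNKNOWN:
                    if p not in L:
                        heapq.heappush(heap, -p)
                        L[p] = 0.0
                    L[p] += 0.5 * lj
        F[i] = aii - 1.0
    return F


def tabular_A(ped: Pedigree) -> np.ndarray:
    """Full numerator relationship matrix by the tabular method (dense)."""
    if not ped.is_topological():
        raise ValueError("pedigree must be topologically sorted")
    n = ped.n
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s != UNKNOWN:
                row += A[s, :i]
            if d != UNKNOWN:
                row += A[d, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s != UNKNOWN and d != UNKNOWN else 0.0)
    return A


def build_A_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse A^-1 by Henderson's rules with Meuwissen-Luo inbreeding.

    Each animal contributes at most 9 nonzeros (itself and its known
    parents).
    """
    F = inbreeding_coefficients(ped)
    n = ped.n
    sire, dam = ped.sire, ped.dam
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            mend = 0.5 - 0.25 * (F[s] + F[d])
        elif s != UNKNOWN or d != UNKNOWN:
            k = s if s != UNKNOWN else d
            mend = 0.75 - 0.25 * F[k]
        else:
            mend = 1.0
        alpha = 1.0 / mend
        add(i, i, alpha)
        for p in (s, d):
            if p != UNKNOWN:
                add(i, p, -alpha / 2)
                add(p, i, -alpha / 2)
                add(p, p, alpha / 4)
        if s != UNKNOWN and d != UNKNOWN:
            add(s, d, alpha / 4)
            add(d, s, alpha / 4)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def build_A22(ped: Pedigree, genotyped_ids: list[str]) -> np.ndarray:
    """Pedigree relationship matrix restricted to the genotyped animals."""
    if len(genotyped_ids) == 0:
        raise ValueError("empty genotyped set")
    idx = np.array([ped.index[a] for a in genotyped_ids])
    A = tabular_A(ped)
    return A[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# genomic side


@dataclass
class SNPWeights:
    """Diagonal SNP weights D with the trace of the first iteration kept as
    the normalization reference (trace conservation keeps the implied total
    genetic variance constant across re-weighting iterations)."""

    d: np.ndarray
    trace_ref: float

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        if np.any(self.d <= 0):
            raise ValueError("SNP weights must be positive")

    @classmethod
    def identity(cls, n_snps: int) -> "SNPWeights":
        return cls(np.ones(n_snps), float(n_snps))

    def normalized(self) -> "SNPWeights":
        d = self.d * (self.trace_ref / self.d.sum())
        return SNPWeights(d, self.trace_ref)


def center_gene_content(panel: GenotypePanel, p: np.ndarray | None = None) -> np.ndarray:
    """Z = gene content minus 2 p_i per column (requires a complete panel)."""
    g = panel.gene_content
    if np.any(np.isnan(g)):
        raise ValueError("panel has missing genotypes; impute first")
    if p is None:
        p = panel.freqs
    return g - 2.0 * p[None, :]


def lambda_scale(p: np.ndarray) -> float:
    """lambda = 1 / sum_i 2 p_i (1 - p_i)."""
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: zero heterozygosity")
    return 1.0 / denom


def build_G(
    panel: GenotypePanel,
    weights: SNPWeights | None = None,
    p: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted genomic relationship matrix G = Z D Z' * lambda."""
    if p is None:
        p = panel.freqs
    Z = center_gene_content(panel, p)
    lam = lambda_scale(p)
    if weights is None:
        G = Z @ Z.T
    else:
        G = (Z * weights.d[None, :]) @ Z.T
    G *= lam
    return G


def blend_G(G: np.ndarray, A22: np.ndarray, beta: float = 0.05) -> np.ndarray:
    """G* = (1 - beta) G + beta A22, verified positive definite by Cholesky."""
    if G.shape != A22.shape:
        raise ValueError("G and A22 shapes differ")
    G_star = (1.0 - beta) * G + beta * A22
    try:
        cholesky(G_star, lower=True)
    except LinAlgError as exc:
        raise ValueError(
            f"blended G is not positive definite at beta={beta}; "
            "increase beta"
        ) from exc
    return G_star


# ---------------------------------------------------------------------------
# combined


class HInverse:
    """H^-1 as sparse A^-1 plus a dense correction on the genotyped block.

    The correction is G*^-1 - A22^-1 placed at the genotyped animals'
    pedigree positions.  Supports matrix-vector products, a diagonal for
    Jacobi preconditioning, and full materialization for small problems.
    """

    def __init__(
        self,
        A_inv: sparse.spmatrix,
        correction: np.ndarray,
        genotyped_index: np.ndarray,
    ) -> None:
        self.A_inv = sparse.csr_matrix(A_inv)
        self.correction = np.asarray(correction, dtype=np.float64)
        self.genotyped_index = np.asarray(genotyped_index, dtype=np.int64)
        self.n = self.A_inv.shape[0]

    def matvec(self, x: np.ndarray) -> np.ndarray:
        y = self.A_inv @ x
        if self.genotyped_index.size:
            y[self.genotyped_index] += self.correction @ x[self.genotyped_index]
        return y

    def __matmul__(self, x: np.ndarray) -> np.ndarray:
        return self.matvec(x)

    def diagonal(self) -> np.ndarray:
        d = np.asarray(self.A_inv.diagonal()).copy()
        if self.genotyped_index.size:
            d[self.genotyped_index] += np.diag(self.correction)
        return d

    def materialize(self) -> np.ndarray:
        H_inv = self.A_inv.toarray()
        if self.genotyped_index.size:
            ix = np.ix_(self.genotyped_index, self.genotyped_index)
            H_inv[ix] += self.correction
        return H_inv

    def relationship(self) -> np.ndarray:
        """Dense H = inv(H^-1); intended for small/medium problems."""
        c, low = cho_factor(self.materialize(), lower=True)
        return cho_solve((c, low), np.eye(self.n))


def spd_inverse(M: np.ndarray) -> np.ndarray:
    c, low = cho_factor(M, lower=True)
    return cho_solve((c, low), np.eye(M.shape[0]))


def build_H_inverse(
    A_inv: sparse.spmatrix,
    G_star: np.ndarray | None,
    A22: np.ndarray | None,
    genotyped_index: np.ndarray | list[int],
) -> HInverse:
    """Assemble H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1].

    With an empty genotyped set H^-1 is exactly A^-1.
    """
    genotyped_index = np.asarray(genotyped_index, dtype=np.int64)
    if genotyped_index.size == 0:
        return HInverse(A_inv, np.zeros((0, 0)), genotyped_index)
    if np.unique(genotyped_index).size != genotyped_index.size:
        raise ValueError("duplicate genotyped animals")
    try:
        A22_inv = spd_inverse(A22)
    except LinAlgError as exc:
        raise ValueError("A22 is singular (duplicate genotyped identity?)") from exc
    try:
        G_inv = spd_inverse(G_star)
    except LinAlgError as exc:
        raise ValueError("G* is singular; blend with larger beta") from exc
    return HInverse(A_inv, G_inv - A22_inv, genotyped_index)
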