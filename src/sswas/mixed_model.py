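"""Single-trait animal model: y = X b + Z a + e with a ~ N(0, H sigma2_a).

Provides the design-matrix assembly (contemporary group and sex as factors,
slaughter age as a centered covariate), a preconditioned conjugate-gradient
solver for Henderson's mixed model equations under any H^-1 operator, and
average-information REML for the two variance components.

AIREML here works in the eigenbasis of the genetic covariance kernel
K = Z H Z': after rotating y and X by the eigenvectors of K, the phenotypic
covariance V = sigma2_a K + sigma2_e I is diagonal, so each AI round costs
O(n p^2) instead of a fresh Cholesky of V.  The eigendecomposition is paid
once per data set.  Negative AI proposals fall back to a positive
fixed-point (EM-flavoured) update whose fixed points are the REML score
zeros; standard errors come from the inverse AI matrix, with se(h2) by the
delta method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import eigh, solve

from .io import Pedigree
from .relationships import HInverse

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    trait: str
    fixed_factors: list[str] = field(
        default_factory=lambda: ["contemporary_group", "sex"]
    )
    covariates: list[str] = field(default_factory=lambda: ["slaughter_age"])


@dataclass
class VarianceComponents:
    """Additive and residual variances; h2 is always the exact ratio."""

    sigma2_a: float
    sigma2_e: float
    se_h2: float = float("nan")
    converged: bool = True
    boundary: bool = False

    @property
    def h2(self) -> float:
        return heritability(self.sigma2_a, self.sigma2_e)


@dataclass
class Solutions:
    b_hat: np.ndarray
    a_hat: np.ndarray
    converged: bool
    iterations: int
    genotyped_index: np.ndarray | None = None

    @property
    def a_hat_g(self) -> np.ndarray:
        if self.genotyped_index is None:
            raise ValueError("no genotyped index attached")
        return self.a_hat[self.genotyped_index]


def heritability(sigma2_a: float, sigma2_e: float) -> float:
    """h2 = sigma2_a / (sigma2_a + sigma2_e)."""
    tot = sigma2_a + sigma2_e
    if tot <= 0:
        raise ValueError("non-positive total variance")
    return sigma2_a / tot


# ---------------------------------------------------------------------------
# design


def build_design(
    phenos: pd.DataFrame, spec: ModelSpec, ped: Pedigree
) -> tuple[np.ndarray, np.ndarray, sparse.csr_matrix]:
    """Assemble (y, X, Z) for the animal model.

    X carries an explicit intercept, drop-first dummy columns per factor and
    centered covariates; Z is the 0/1 record-to-pedigree incidence.  Records
    for animals absent from the pedigree are an error; X must have full
    column rank after the drop-first constraint.
    """
    missing = [a for a in phenos["animal_id"] if a not in ped.index]
    if missing:
        raise ValueError(
            f"{len(missing)} phenotype records for animals absent from the "
            f"pedigree (first: {missing[:5]})"
        )
    n = len(phenos)
    y = phenos[spec.trait].to_numpy(dtype=np.float64)

    cols = [np.ones((n, 1))]
    names = ["intercept"]
    for f in spec.fixed_factors:
        if f not in phenos.columns:
            raise ValueError(f"factor {f!r} not in phenotype table")
        dummies = pd.get_dummies(phenos[f].astype("category"), drop_first=True)
        cols.append(dummies.to_numpy(dtype=np.float64))
        names += [f"{f}={lv}" for lv in dummies.columns]
    for c in spec.covariates:
        if c not in phenos.columns:
            raise ValueError(f"covariate {c!r} not in phenotype table")
        v = phenos[c].to_numpy(dtype=np.float64)
        cols.append((v - v.mean())[:, None])
        names.append(c)
    X = np.hstack(cols)

    rank = np.linalg.matrix_rank(X.T @ X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"confounded terms among {names}"
        )

    rec_idx = np.array([ped.index[a] for a in phenos["animal_id"]])
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), rec_idx)), shape=(n, ped.n)
    )
    return y, X, Z


# ---------------------------------------------------------------------------
# MME solver


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z: sparse.spmatrix,
    H_inv: HInverse,
    vc: VarianceComponents,
    tol: float = 1e-10,
    max_iter: int = 5000,
    genotyped_index: np.ndarray | None = None,
) -> Solutions:
    """Solve Henderson's MME by Jacobi-preconditioned conjugate gradients.

    The coefficient matrix [X'X, X'Z; Z'X, Z'Z + k H^-1] with
    k = sigma2_e/sigma2_a is applied matrix-free.  Convergence is declared
    at relative residual < tol.
    """
    if vc.sigma2_e <= 0:
        raise ValueError("sigma2_e must be positive")
    if vc.sigma2_a <= 0:
        # infinite shrinkage limit: breeding values are identically zero
        b_hat = solve(X.T @ X, X.T @ y, assume_a="sym")
        return Solutions(b_hat, np.zeros(H_inv.n), True, 0, genotyped_index)
    k = vc.sigma2_e / vc.sigma2_a
    p = X.shape[1]
    N = H_inv.n
    Zc = sparse.csr_matrix(Z)

    def matvec(v: np.ndarray) -> np.ndarray:
        vb, va = v[:p], v[p:]
        w = X @ vb + Zc @ va
        top = X.T @ w
        bot = Zc.T @ w + k * H_inv.matvec(va)
        return np.concatenate([top, bot])

    rhs = np.concatenate([X.T @ y, Zc.T @ y])
    diag = np.concatenate(
        [np.einsum("ij,ij->j", X, X),
         np.asarray(Zc.multiply(Zc).sum(axis=0)).ravel() + k * H_inv.diagonal()]
    )
    diag[diag <= 0] = 1.0

    x = np.zeros(p + N)
    r = rhs - matvec(x)
    z = r / diag
    pdir = z.copy()
    rz = float(r @ z)
    bnorm = float(np.linalg.norm(rhs))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Ap = matvec(pdir)
        alpha = rz / float(pdir @ Ap)
        x += alpha * pdir
        r -= alpha * Ap
        if np.linalg.norm(r) <= tol * bnorm:
            converged = True
            break
        z = r / diag
        rz_new = float(r @ z)
        pdir = z + (rz_new / rz) * pdir
        rz = rz_new
    if not converged:
        logger.warning("PCG did not converge in %d iterations", max_iter)
    return Solutions(x[:p], x[p:], converged, it, genotyped_index)


# ---------------------------------------------------------------------------
# AIREML


class AIREMLError(RuntimeError):
    pass


def _kernel_matrix(Z: sparse.spmatrix, H_inv: HInverse) -> np.ndarray:
    """K = Z H Z' (dense): the genetic covariance of the records."""
    H = H_inv.relationship()
    Zc = sparse.csr_matrix(Z)
    return np.asarray(Zc @ (Zc @ H).T)


def estimate_aireml(
    y: np.ndarray,
    X: np.ndarray,
    Z: sparse.spmatrix,
    H_inv: HInverse,
    init: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_rounds: int = 200,
) -> VarianceComponents:
    """AIREML estimates of (sigma2_a, sigma2_e) under the animal model."""
    n, p = X.shape
    if n <= p:
        raise ValueError("need more records than fixed-effect columns")
    K = _kernel_matrix(Z, H_inv)
    lam, U = eigh(K)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    vy = float(np.var(y))
    floor = 1e-10 * vy
    if init is None:
        theta = np.array([0.5 * vy, 0.5 * vy])
    else:
        theta = np.array([max(init.sigma2_a, floor), max(init.sigma2_e, floor)])

    trajectory = []
    AI = np.eye(2)
    converged = False
    for rnd in range(1, max_rounds + 1):
        v = theta[0] * lam + theta[1]
        w = 1.0 / v
        WX = Xt * w[:, None]
        B = np.linalg.inv(Xt.T @ WX)

        def apply_P(u: np.ndarray) -> np.ndarray:
            wu = w * u
            return wu - w * (Xt @ (B @ (WX.T @ u)))

        Py = apply_P(yt)
        qa = lam * Py          # V_a P y (rotated)
        qe = Py                # V_e P y
        # traces of P V_j
        tr_a = float(np.sum(w * lam)) - float(
            np.einsum("ij,ji->", B, Xt.T @ (Xt * (w * w * lam)[:, None]))
        )
        tr_e = float(np.sum(w)) - float(
            np.einsum("ij,ji->", B, Xt.T @ (Xt * (w * w)[:, None]))
        )
        yPVaPy = float(qa @ Py)  # y'P Va P y

        yPVePy = float(Py @ Py)
        grad = -0.5 * np.array([tr_a - yPVaPy, tr_e - yPVePy])

        Pqa = apply_P(qa)
        Pqe = apply_P(qe)
        AI = 0.5 * np.array(
            [[float(qa @ Pqa), float(qa @ Pqe)],
             [float(qe @ Pqa), float(qe @ Pqe)]]
        )
        try:
            step = np.linalg.solve(AI, grad)
        except np.linalg.LinAlgError:
            step = grad / np.maximum(np.diag(AI), 1e-12)
        proposal = theta + step
        if np.any(proposal <= 0):
            # EM-flavoured positive fixed point: theta * (y'PVPy / tr(PV))
            ratios = np.array(
                [yPVaPy / max(tr_a, 1e-300), yPVePy / max(tr_e, 1e-300)]
            )
            proposal = theta * np.clip(ratios, 0.1, 10.0)
        proposal = np.maximum(proposal, floor)
        rel = np.max(np.abs(proposal - theta) / np.maximum(theta, floor))
        trajectory.append((rnd, *theta, rel))
        theta = proposal
        if rel < tol:
            converged = True
            break
    if not converged:
        raise AIREMLError(
            "AIREML did not converge in "
            f"{max_rounds} rounds; trajectory tail: {trajectory[-5:]}"
        )

    boundary = bool(theta[0] <= floor * 1.01)
    if boundary:
        logger.warning("sigma2_a estimate at boundary (~0)")
    # se(h2) by the delta method from the inverse AI matrix
    try:
        C = np.linalg.inv(AI)
        a, e = theta
        g = np.array([e, -a]) / (a + e) ** 2
        se_h2 = float(np.sqrt(max(g @ C @ g, 0.0)))
    except np.linalg.LinAlgError:
        se_h2 = float("nan")
    return VarianceComponents(
        float(theta[0]), float(theta[1]), se_h2, True, boundary
    )
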