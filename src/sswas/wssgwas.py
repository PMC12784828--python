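"""Iterative SNP re-weighting (weighted single-step GWAS).

Starting from unit weights, each iteration (i) builds the weighted genomic
matrix G(t) = Z D(t) Z' lambda, (ii) solves ssGBLUP under the resulting
H^-1 for GEBVs, (iii) back-solves SNP effects from the genotyped animals'
GEBVs as u_hat = lambda D(t) Z' G(t)^-1 a_hat_g, (iv) sets the next weights
d_i = u_hat_i^2 * 2 p_i (1 - p_i), and (v) rescales them so tr(D) stays at
its iteration-1 value, keeping the implied total genetic variance constant.
Three iterations is the conventional default.

Variance components are estimated once from the unweighted (D = I) fit and
held fixed across iterations; allele frequencies and lambda likewise stay
at their initial values so all iterations share one scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .io import GenotypePanel, Pedigree
from .mixed_model import (
    ModelSpec,
    Solutions,
    VarianceComponents,
    build_design,
    estimate_aireml,
    solve_mme,
)
from .relationships import (
    SNPWeights,
    blend_G,
    build_A22,
    build_A_inverse,
    build_G,
    build_H_inverse,
    center_gene_content,
    lambda_scale,
)

logger = logging.getLogger(__name__)


@dataclass
class IterationState:
    """Audit record of one re-weighting iteration."""

    t: int
    weights: SNPWeights  # weights used to build G at this iteration
    u_hat: np.ndarray
    a_hat_g: np.ndarray
    G_t: np.ndarray
    solutions: Solutions

    def effects_frame(self, panel: GenotypePanel) -> pd.DataFrame:
        p = panel.freqs
        return pd.DataFrame(
            {
                "snp": panel.snp_ids,
                "chrom": panel.chrom,
                "bp": panel.pos,
                "u_hat": self.u_hat,
                "d": self.weights.d,
                "u2_2pq": self.u_hat**2 * 2 * p * (1 - p),
            }
        )


def backsolve_snp_effects(
    a_hat_g: np.ndarray,
    G_used: np.ndarray,
    Z_centered: np.ndarray,
    weights: SNPWeights,
    lam: float,
) -> np.ndarray:
    """u_hat = lambda D Z' G^-1 a_hat_g (G is the matrix actually inverted
    in H^-1, i.e. the blended G*)."""
    try:
        c, low = cho_factor(G_used, lower=True)
    except Exception as exc:  # singular G
        raise ValueError("G is singular; blend before back-solving") from exc
    v = cho_solve((c, low), a_hat_g)
    return lam * weights.d * (Z_centered.T @ v)


def update_weights(
    u_hat: np.ndarray,
    p: np.ndarray,
    trace_ref: float,
    floor_rel: float = 1e-8,
) -> SNPWeights:
    """Next-iteration weights d_i = u_i^2 * 2 p_i (1 - p_i), floored and
    rescaled to tr(D) = trace_ref.

    The relative floor keeps a SNP with an exactly-zero effect estimate from
    being permanently removed from G.
    """
    d = u_hat**2 * 2.0 * p * (1.0 - p)
    mean_d = d.mean()
    if mean_d <= 0:
        raise ValueError(
            "all SNP effects are zero; stop at the previous iteration"
        )
    d = np.maximum(d, floor_rel * mean_d)
    return SNPWeights(d, trace_ref).normalized()


def run_wssgwas(
    ped: Pedigree,
    panel: GenotypePanel,
    phenos: pd.DataFrame,
    spec: ModelSpec,
    vc: VarianceComponents | None = None,
    n_iter: int = 3,
    beta: float = 0.05,
    pcg_tol: float = 1e-10,
) -> tuple[list[IterationState], VarianceComponents]:
    """Run the full re-weighting loop; returns all iteration states.

    ``panel`` must be the QC'd, imputed panel of genotyped animals.  If
    ``vc`` is None, variance components are estimated by AIREML under the
    unweighted H^-1 and then held fixed.
    """
    y, X, Z = build_design(phenos, spec, ped)
    gen_idx = np.array([ped.index[a] for a in panel.animal_ids])
    A_inv = build_A_inverse(ped)
    A22 = build_A22(ped, panel.animal_ids)
    p = panel.freqs
    Zc = center_gene_content(panel, p)
    lam = lambda_scale(p)

    states: list[IterationState] = []
    weights = SNPWeights.identity(panel.n_snps)
    for t in range(1, n_iter + 1):
        G_t = build_G(panel, weights, p)
        G_star = blend_G(G_t, A22, beta)
        H_inv = build_H_inverse(A_inv, G_star, A22, gen_idx)
        if t == 1 and vc is None:
            vc = estimate_aireml(y, X, Z, H_inv)
            logger.info(
                "AIREML: sigma2_a=%.4g sigma2_e=%.4g h2=%.3f",
                vc.sigma2_a, vc.sigma2_e, vc.h2,
            )
        sol = solve_mme(y, X, Z, H_inv, vc, tol=pcg_tol,
                        genotyped_index=gen_idx)
        a_hat_g = sol.a_hat[gen_idx]
        u_hat = backsolve_snp_effects(a_hat_g, G_star, Zc, weights, lam)
        states.append(IterationState(t, weights, u_hat, a_hat_g, G_t, sol))
        logger.info(
            "iteration %d: tr(D)=%.6f |u|=%.4g PCG iters=%d",
            t, weights.d.sum(), float(np.linalg.norm(u_hat)), sol.iterations,
        )
        if t < n_iter:
            weights = update_weights(u_hat, p, weights.trace_ref)
    assert vc is not None
    return states, vc
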