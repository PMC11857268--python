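"""Closed-form bilinear least squares and Wald-type inference.

The model is Y = X B Zᵀ + E for an n x m response Y, sample design
X (n x p), metabolite design Z (m x q), and coefficient matrix B (p x q);
rows of E are independent with mean zero and a shared m x m covariance Σ.
The least-squares solution is

    B̂ = (XᵀX)⁻¹ Xᵀ Y Z (ZᵀZ)⁻¹,

with coefficient covariance Var(vec(B̂ᵀ)) = (XᵀX)⁻¹ ⊗ (ZᵀZ)⁻¹ZᵀΣZ(ZᵀZ)⁻¹.
Only the p·q diagonal entries of that Kronecker product are ever
materialized.  Σ is estimated as RᵀR/(n − p) from the residuals R, the
divisor chosen so that the Z = I case reproduces classical per-metabolite
OLS variances.  Coefficient t-statistics are referred to the standard
normal by default (``df`` substitutes a Student-t reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .design import DesignMatrixX, DesignMatrixZ
from .io_tables import AbundanceMatrix, ValidationError

__all__ = ["MLMFit", "fit_mlm", "wald_inference"]

logger = logging.getLogger("matlm")


@dataclass
class MLMFit:
    """Fitted matrix linear model: coefficients, residuals, Σ̂ and the
    cached cross-product inverses needed for Wald inference."""

    B_hat: np.ndarray
    residuals: np.ndarray
    sigma_hat: np.ndarray
    xtx_inv: np.ndarray
    ztz_inv: np.ndarray
    dof_resid: int
    X: np.ndarray
    Z: np.ndarray
    x_labels: list[str]
    z_labels: list[str]


def _as_values(A, what: str) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(A, AbundanceMatrix):
        if A.missing_mask.any():
            raise ValidationError(
                "Y contains missing values; run preprocess.impute first"
            )
        return A.values, None
    if isinstance(A, DesignMatrixX):
        return A.values, A.column_labels
    if isinstance(A, DesignMatrixZ):
        return A.values, A.column_labels
    M = np.asarray(A, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    return M, None


def _chol_inverse(G: np.ndarray, name: str):
    """Cholesky factor + inverse of a Gram matrix, with a helpful error."""
    try:
        c = linalg.cho_factor(G, lower=True)
    except linalg.LinAlgError:
        rank = np.linalg.matrix_rank(G)
        raise ValidationError(
            f"{name} is singular (rank {rank} < {G.shape[0]}); "
            "remove collinear design columns"
        ) from None
    return c, linalg.cho_solve(c, np.eye(G.shape[0]))


def fit_mlm(Y, X, Z, ridge: float = 0.0) -> MLMFit:
    """Fit Y = X B Zᵀ + E by least squares.

    ``Y`` may be an :class:`AbundanceMatrix` or array (no missing values);
    ``X``/``Z`` may be design-matrix objects or plain arrays.  ``ridge``
    adds ε·I to Σ̂ to guard near-singularity when m approaches n.
    """
    Yv, _ = _as_values(Y, "Y")
    Xv, x_labels = _as_values(X, "X")
    Zv, z_labels = _as_values(Z, "Z")
    if not np.all(np.isfinite(Yv)):
        raise ValidationError("Y contains non-finite values; run preprocessing first")
    n, m = Yv.shape
    if Xv.shape[0] != n:
        raise ValidationError(f"X has {Xv.shape[0]} rows but Y has {n} samples")
    if Zv.shape[0] != m:
        raise ValidationError(f"Z has {Zv.shape[0]} rows but Y has {m} metabolites")
    p, q = Xv.shape[1], Zv.shape[1]
    if n <= p:
        raise ValidationError(f"need n > p for residual degrees of freedom (n={n}, p={p})")

    cx, xtx_inv = _chol_inverse(Xv.T @ Xv, "XᵀX")
    cz, ztz_inv = _chol_inverse(Zv.T @ Zv, "ZᵀZ")
    # B̂ = (XᵀX)⁻¹ Xᵀ Y Z (ZᵀZ)⁻¹ via two triangular solves
    T = linalg.cho_solve(cx, Xv.T @ Yv) @ Zv          # p x q
    B_hat = linalg.cho_solve(cz, T.T).T               # p x q
    R = Yv - Xv @ B_hat @ Zv.T
    dof = n - p
    sigma_hat = R.T @ R / dof
    if ridge:
        sigma_hat = sigma_hat + ridge * np.eye(m)
    sigma_hat = 0.5 * (sigma_hat + sigma_hat.T)
    return MLMFit(
        B_hat=B_hat,
        residuals=R,
        sigma_hat=sigma_hat,
        xtx_inv=xtx_inv,
        ztz_inv=ztz_inv,
        dof_resid=dof,
        X=Xv,
        Z=Zv,
        x_labels=x_labels or [f"x{k}" for k in range(p)],
        z_labels=z_labels or [f"z{l}" for l in range(q)],
    )


def coefficient_variances(fit: MLMFit) -> np.ndarray:
    """The p x q matrix of Var(b̂_kl): the diagonal of
    (XᵀX)⁻¹ ⊗ (ZᵀZ)⁻¹ZᵀΣ̂Z(ZᵀZ)⁻¹ without forming the Kronecker product."""
    G = fit.ztz_inv @ (fit.Z.T @ fit.sigma_hat @ fit.Z) @ fit.ztz_inv
    return np.outer(np.diag(fit.xtx_inv), np.diag(G))


def wald_inference(
    fit: MLMFit,
    level: float = 0.95,
    fdr: str = "adaptive_bh",
    df: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-coefficient effects, standard errors, t, p, CI and FDR q.

    ``fdr`` is ``adaptive_bh`` (default), ``bh`` or ``none``; q-values are
    computed over all reported coefficients of the fit.  ``df`` switches
    the normal reference to Student-t with that many degrees of freedom.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must be in (0, 1)")
    var = coefficient_variances(fit)
    se = np.sqrt(var)
    B = fit.B_hat
    t = np.zeros_like(B)
    pos = se > 0
    t[pos] = B[pos] / se[pos]
    degenerate = (~pos) & (B != 0)
    if degenerate.any():
        logger.warning(
            "%d coefficient(s) have zero standard error with nonzero effect",
            int(degenerate.sum()),
        )
        t[degenerate] = np.inf * np.sign(B[degenerate])
    dist = stats.norm if df is None else stats.t(df)
    pvals = np.where(np.isinf(t), 0.0, 2.0 * dist.sf(np.abs(np.where(np.isinf(t), 0.0, t))))
    pvals = np.where(degenerate, 0.0, pvals)
    crit = dist.ppf(0.5 + level / 2.0)
    ci_lo = B - crit * se
    ci_hi = B + crit * se

    p, q = B.shape
    table = pd.DataFrame(
        {
            "x_label": np.repeat(fit.x_labels, q),
            "z_label": np.tile(fit.z_labels, p),
            "effect": B.ravel(),
            "se": se.ravel(),
            "t": t.ravel(),
            "p": pvals.ravel(),
            "ci_lo": ci_lo.ravel(),
            "ci_hi": ci_hi.ravel(),
        }
    )
    if fdr == "none":
        table["q"] = np.nan
    else:
        from .inference import adaptive_bh

        variant = "adaptive" if fdr == "adaptive_bh" else "standard"
        qvals, _ = adaptive_bh(table["p"].to_numpy(), alpha=alpha, variant=variant)
        table["q"] = qvals
    table.attrs["level"] = level
    table.attrs["fdr"] = fdr
    return table
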