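"""Multiple testing, permutation p-values and cross-study contrasts.

``adaptive_bh`` implements the Benjamini–Hochberg linear step-up and its
adaptive two-stage variant in which the number of true nulls m0 is first
estimated by the lowest-slope method and the step-up is then applied at
the correspondingly relaxed level.  ``permutation_pvalues`` permutes the
rows of Y against a fixed X — a joint test of the global null for all X
covariates — and uses the add-one estimator so p is never exactly zero.
``contrast_studies`` combines two independently fitted studies into
differences or averages of identically labeled coefficients.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .core import coefficient_variances, fit_mlm
from .io_tables import ValidationError

__all__ = [
    "adaptive_bh",
    "estimate_m0_lowest_slope",
    "permutation_pvalues",
    "contrast_studies",
]

logger = logging.getLogger("matlm")


def estimate_m0_lowest_slope(pvalues: np.ndarray) -> int:
    """Lowest-slope estimate of the number of true null hypotheses.

    With p sorted ascending, the slopes S_i = (1 − p_(i)) / (m + 1 − i)
    are scanned until they first decrease; m0 is then min(m,
    ceil(1/S_i) + 1) at the stopping index (m if the slopes never
    decrease or the stopping slope is zero).
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    m = p.size
    slopes = (1.0 - p) / (m + 1 - np.arange(1, m + 1))
    stop = None
    for i in range(1, m):
        if slopes[i] < slopes[i - 1]:
            stop = i
            break
    if stop is None or slopes[stop] <= 0:
        return m
    return int(min(m, math.ceil(1.0 / slopes[stop]) + 1))


def _bh_qvalues(p: np.ndarray, scale: float) -> np.ndarray:
    """Monotone step-up adjusted p-values with multiplier ``scale``
    (m for standard BH, m̂0 for the adaptive variant)."""
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * scale / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def adaptive_bh(
    pvalues, alpha: float = 0.05, variant: str = "adaptive"
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg q-values and rejection flags.

    ``variant="standard"`` is the linear step-up at level ``alpha``;
    ``variant="adaptive"`` first estimates m0 by the lowest-slope method
    and steps up at level alpha·m/m̂0.  Whenever m̂0 ≤ m the adaptive
    rejection set contains the standard one.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("pvalues must be a nonempty 1-D vector")
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must be finite and in [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    if variant not in ("adaptive", "standard"):
        raise ValidationError(f"variant must be adaptive|standard, got {variant!r}")
    m = p.size
    scale = float(m if variant == "standard" else estimate_m0_lowest_slope(p))
    q = _bh_qvalues(p, scale)
    return q, q <= alpha


def permutation_pvalues(
    Y, X, Z, n_perm: int, seed: int
) -> np.ndarray:
    """Permutation p-values for every coefficient of the bilinear fit.

    Rows of Y are shuffled against the fixed X (equivalently, X rows are
    permuted), the model is refit, and p_kl = (1 + #{|t*| ≥ |t|}) /
    (1 + n_perm).  Deterministic given ``seed``.  Because whole samples
    are permuted, this tests the global null of no X effect; it does not
    preserve nuisance covariates.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    fit = fit_mlm(Y, X, Z)
    Yv, Xv, Zv = (fit.X @ fit.B_hat @ fit.Z.T + fit.residuals), fit.X, fit.Z
    abs_t_obs = _abs_t(fit)
    counts = np.zeros_like(abs_t_obs)
    n = Yv.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        fstar = fit_mlm(Yv[perm], Xv, Zv)
        counts += _abs_t(fstar) >= abs_t_obs
    return (1.0 + counts) / (1.0 + n_perm)


def _abs_t(fit) -> np.ndarray:
    se = np.sqrt(coefficient_variances(fit))
    t = np.zeros_like(fit.B_hat)
    pos = se > 0
    t[pos] = fit.B_hat[pos] / se[pos]
    t[(~pos) & (fit.B_hat != 0)] = np.inf
    return np.abs(t)


def contrast_studies(
    fitA: pd.DataFrame,
    fitB: pd.DataFrame,
    mode: str = "difference",
    level: float = 0.95,
    fdr: str = "adaptive_bh",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differences or averages of coefficients shared by two studies.

    The two inference tables are matched on (x_label, z_label); studies
    are assumed independent, so the difference has se = √(seA² + seB²)
    and the average se = ½√(seA² + seB²).  Unmatched labels are reported
    in ``result.attrs["unmatched"]`` and excluded.
    """
    if mode not in ("difference", "average"):
        raise ValidationError(f"mode must be difference|average, got {mode!r}")
    keyA = list(zip(fitA["x_label"], fitA["z_label"]))
    keyB = list(zip(fitB["x_label"], fitB["z_label"]))
    merged = pd.merge(
        fitA.assign(_key=keyA)[["_key", "x_label", "z_label", "effect", "se"]],
        fitB.assign(_key=keyB)[["_key", "effect", "se"]],
        on="_key",
        suffixes=("_a", "_b"),
    )
    unmatched = sorted(set(keyA).symmetric_difference(keyB))
    if merged.empty:
        raise ValidationError("the two studies share no coefficient labels")
    if unmatched:
        logger.warning("excluding %d unmatched coefficient label(s)", len(unmatched))

    se = np.sqrt(merged["se_a"] ** 2 + merged["se_b"] ** 2)
    if mode == "difference":
        effect = merged["effect_a"] - merged["effect_b"]
    else:
        effect = 0.5 * (merged["effect_a"] + merged["effect_b"])
        se = 0.5 * se
    se = se.to_numpy()
    effect = effect.to_numpy()
    t = np.zeros_like(effect)
    pos = se > 0
    t[pos] = effect[pos] / se[pos]
    p = 2.0 * stats.norm.sf(np.abs(t))
    crit = stats.norm.ppf(0.5 + level / 2.0)
    out = pd.DataFrame(
        {
            "x_label": merged["x_label"],
            "z_label": merged["z_label"],
            "effect": effect,
            "se": se,
            "t": t,
            "p": p,
            "ci_lo": effect - crit * se,
            "ci_hi": effect + crit * se,
        }
    )
    if fdr == "none":
        out["q"] = np.nan
    else:
        variant = "adaptive" if fdr == "adaptive_bh" else "standard"
        out["q"] = adaptive_bh(out["p"].to_numpy(), alpha=alpha, variant=variant)[0]
    out.attrs["mode"] = mode
    out.attrs["unmatched"] = unmatched
    return out
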