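"""Preprocessing chain for abundance matrices: impute -> PQN -> log.

Imputation offers half-minimum substitution and a deterministic KNN
averager.  Probabilistic quotient normalization (PQN) removes per-sample
dilution by dividing each sample by the median of its metabolite-wise
quotients against the median reference spectrum.  The default pipeline
order (impute, then PQN on raw positive abundances, then log) follows
standard metabolomics practice; the CLI lets the user reorder explicitly.
"""

from __future__ import annotations

import math

import numpy as np

from .io_tables import AbundanceMatrix, ValidationError

__all__ = ["impute", "pqn_normalize", "log_transform"]


def impute(
    A: AbundanceMatrix,
    method: str = "half_min",
    k: int = 5,
    seed: int = 0,
) -> AbundanceMatrix:
    """Fill missing cells; observed cells are never altered.

    ``half_min`` fills a missing cell with half the minimum observed value
    of that metabolite.  ``knn`` fills it with the mean of the metabolite's
    values in the ``k`` nearest samples (Euclidean distance over
    co-observed metabolites, each metabolite standardized; distance ties
    broken by sample order).  ``seed`` is accepted for interface
    uniformity; both methods are deterministic.
    """
    if method not in ("half_min", "knn"):
        raise ValidationError(f"unknown imputation method {method!r}")
    out = A.copy()
    if not out.missing_mask.any():
        out.missing_mask[:] = False
        return out
    V, M = out.values, out.missing_mask
    n, m = V.shape

    fully_missing = np.where(M.all(axis=0))[0]
    if fully_missing.size:
        names = [out.metabolite_ids[j] for j in fully_missing]
        raise ValidationError(f"metabolite(s) with no observed values: {names}")

    if method == "half_min":
        for j in range(m):
            miss = M[:, j]
            if miss.any():
                V[miss, j] = 0.5 * np.nanmin(np.where(miss, np.nan, V[:, j]))
    else:
        if k < 1:
            raise ValidationError("k must be a positive integer")
        if k >= n:
            raise ValidationError(f"k={k} must be smaller than the sample count n={n}")
        # standardize per metabolite over observed entries
        obs = ~M
        Vn = np.where(obs, V, np.nan)
        mu = np.nanmean(Vn, axis=0)
        sd = np.nanstd(Vn, axis=0)
        sd[sd == 0] = 1.0
        S = (Vn - mu) / sd  # NaN at missing cells
        for i in range(n):
            miss_j = np.where(M[i])[0]
            if miss_j.size == 0:
                continue
            # mean squared std-difference over co-observed metabolites,
            # so samples with different overlap sizes are comparable
            diff = S - S[i]
            co = np.isfinite(diff)
            counts = co.sum(axis=1)
            with np.errstate(invalid="ignore"):
                d2 = np.nansum(np.where(co, diff**2, 0.0), axis=1) / np.where(
                    counts > 0, counts, 1
                )
            d2[counts == 0] = np.inf
            d2[i] = np.inf
            order = np.argsort(d2, kind="stable")  # stable => ties by sample order
            for j in miss_j:
                donors = [h for h in order if obs[h, j] and math.isfinite(d2[h])]
                if not donors:
                    raise ValidationError(
                        f"no neighbor with an observed value for metabolite "
                        f"{out.metabolite_ids[j]!r} when imputing sample "
                        f"{out.sample_ids[i]!r}"
                    )
                V[i, j] = float(np.mean(V[donors[:k], j]))
    out.missing_mask[:] = False
    return out


def pqn_normalize(A: AbundanceMatrix) -> AbundanceMatrix:
    """Probabilistic quotient normalization.

    Follows the full quotient-normalization recipe: spectra are first
    brought to a common integral (each row divided by its total), the
    reference spectrum r_j is the per-metabolite median of those
    integral-normalized spectra, each sample's dilution factor d_i is the
    median over metabolites of A[i, j] / r_j, and the output is
    A[i, j] / d_i.  Computing the reference on integral-normalized
    spectra makes the result exactly invariant to per-sample dilution
    (PQN(diag(s) A) == PQN(A)) and exactly idempotent; a reference taken
    on raw columns would satisfy neither.  Requires a complete, strictly
    positive matrix (impute and/or shift first).
    """
    if A.missing_mask.any():
        raise ValidationError("PQN requires a complete matrix; impute first")
    V = A.values
    if np.any(V <= 0):
        i, j = map(int, np.argwhere(V <= 0)[0])
        raise ValidationError(
            f"PQN requires strictly positive values; found {V[i, j]!r} at "
            f"sample {A.sample_ids[i]!r}, metabolite {A.metabolite_ids[j]!r}"
        )
    T = V / V.sum(axis=1, keepdims=True)
    r = np.median(T, axis=0)
    if np.any(r == 0):
        raise ValidationError("reference spectrum contains a zero median")
    d = np.median(V / r, axis=1)
    out = A.copy()
    out.values = V / d[:, None]
    return out


_LOG = {"2": math.log(2.0), "e": 1.0, "10": math.log(10.0)}


def log_transform(A: AbundanceMatrix, base="2", offset: float = 0.0) -> AbundanceMatrix:
    """Elementwise log_base(value + offset); base in {2, e, 10}."""
    key = str(base)
    if key not in _LOG:
        raise ValidationError(f"base must be one of 2, e, 10; got {base!r}")
    if offset < 0:
        raise ValidationError("offset must be nonnegative")
    if A.missing_mask.any():
        raise ValidationError("log transform requires a complete matrix; impute first")
    shifted = A.values + offset
    if np.any(shifted <= 0):
        i, j = map(int, np.argwhere(shifted <= 0)[0])
        raise ValidationError(
            f"value + offset <= 0 at sample {A.sample_ids[i]!r}, "
            f"metabolite {A.metabolite_ids[j]!r}"
        )
    out = A.copy()
    out.values = np.log(shifted) / _LOG[key]
    return out
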