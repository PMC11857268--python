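"""The conventional two-step comparator and contingency-table utilities.

The two-step pipeline first fits one linear model per metabolite
(``univariate_stats``: the bilinear model with Z = I), then asks whether
significant metabolites are overrepresented in an annotation category
(``ora_test``: upper-tail hypergeometric).  ``chi2_2x2`` is the Pearson
chi-square test (no continuity correction) used for categorical
cohort-demographics comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import fit_mlm, wald_inference
from .design import DesignMatrixZ
from .inference import adaptive_bh
from .io_tables import AbundanceMatrix, ValidationError

__all__ = ["univariate_stats", "ora_test", "chi2_2x2", "two_step_enrichment"]


def univariate_stats(
    Y, X, focus: str, level: float = 0.95, fdr: str = "adaptive_bh"
) -> pd.DataFrame:
    """Per-metabolite effect/se/t/p/q for one X covariate (Z = identity).

    Equivalent to running an ordinary least-squares regression for each
    metabolite separately and keeping the ``focus`` coefficient; q-values
    are computed over the m focus p-values.
    """
    if isinstance(Y, AbundanceMatrix):
        ids = Y.metabolite_ids
    else:
        ids = [f"m{j}" for j in range(np.asarray(Y).shape[1])]
    fit = fit_mlm(Y, X, DesignMatrixZ.identity(ids))
    if focus not in fit.x_labels:
        raise ValidationError(
            f"unknown focus covariate {focus!r}; available: {fit.x_labels}"
        )
    table = wald_inference(fit, level=level, fdr="none")
    table = table[table["x_label"] == focus].reset_index(drop=True)
    table = table.rename(columns={"z_label": "metabolite_id"}).drop(columns=["q"])
    if fdr != "none":
        variant = "adaptive" if fdr == "adaptive_bh" else "standard"
        table["q"] = adaptive_bh(table["p"].to_numpy(), variant=variant)[0]
    else:
        table["q"] = np.nan
    return table


def ora_test(significant, membership) -> pd.DataFrame:
    """Overrepresentation analysis: one hypergeometric upper tail per category.

    With m metabolites of which K are significant, a category of size m_g
    containing k_g significant metabolites gets
    p_g = P(X ≥ k_g), X ~ Hypergeom(m, m_g, K).
    """
    flags = np.asarray(significant, dtype=bool)
    labels = np.asarray(membership, dtype=object)
    if flags.size == 0 or labels.size == 0:
        raise ValidationError("empty input to ora_test")
    if flags.size != labels.size:
        raise ValidationError("significance flags and category labels differ in length")
    m = flags.size
    K = int(flags.sum())
    rows = []
    for cat in dict.fromkeys(labels):  # first-appearance order
        in_cat = labels == cat
        m_g = int(in_cat.sum())
        k_g = int((flags & in_cat).sum())
        p = float(stats.hypergeom(m, K, m_g).sf(k_g - 1))
        rows.append({"category": cat, "m_g": m_g, "k_g": k_g, "p": min(p, 1.0)})
    return pd.DataFrame(rows)


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    X² = N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)) with N = a+b+c+d, referred
    to the chi-square distribution with 1 degree of freedom.
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValidationError("cell counts must be nonnegative integers")
    a, b, c, d = (int(x) for x in counts)
    margins = (a + b, c + d, a + c, b + d)
    if any(mgn == 0 for mgn in margins):
        raise ValidationError("every row and column margin must be positive")
    N = a + b + c + d
    x2 = N * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(x2), float(stats.chi2.sf(x2, df=1))


def two_step_enrichment(
    Y,
    X,
    focus: str,
    membership,
    alpha: float = 0.05,
    fdr: str = "adaptive_bh",
) -> pd.DataFrame:
    """Univariate tests at FDR ``alpha`` followed by ORA per category."""
    uni = univariate_stats(Y, X, focus, fdr=fdr)
    significant = uni["q"].to_numpy() < alpha
    return ora_test(significant, membership)
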