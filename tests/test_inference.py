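import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matlm import (
    ValidationError,
    adaptive_bh,
    contrast_studies,
    permutation_pvalues,
)
from matlm.inference import estimate_m0_lowest_slope


def brute_force_bh(p, alpha):
    """O(m^2) literal step-up: largest i with p_(i) <= i*alpha/m rejected."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * alpha / m:
            k = i
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return reject


class TestAdaptiveBH:
    def test_all_ones_never_reject(self):
        q, rej = adaptive_bh(np.ones(7), variant="adaptive")
        assert not rej.any()
        np.testing.assert_array_equal(q, 1.0)

    def test_worked_stepup_example(self):
        p = np.array([0.001, 0.01, 0.02, 0.8, 0.9])
        _, rej = adaptive_bh(p, alpha=0.05, variant="standard")
        assert rej.tolist() == [True, True, True, False, False]

    def test_single_small_p_rejected_by_both_variants(self):
        for variant in ("standard", "adaptive"):
            _, rej = adaptive_bh(np.array([0.04]), alpha=0.05, variant=variant)
            assert rej.all()

    def test_standard_matches_brute_force_stepup(self, rng):
        for _ in range(300):
            m = int(rng.integers(1, 51))
            p = rng.uniform(size=m)
            alpha = float(rng.uniform(0.01, 0.2))
            _, rej = adaptive_bh(p, alpha=alpha, variant="standard")
            np.testing.assert_array_equal(rej, brute_force_bh(p, alpha))

    def test_standard_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            q, rej = adaptive_bh(p, alpha=0.05, variant="standard")
            sm_rej, sm_q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(q, sm_q, atol=1e-12)
            np.testing.assert_array_equal(rej, sm_rej)

    def test_adaptive_rejections_contain_standard_when_m0_below_m(self, rng):
        for _ in range(200):
            m = int(rng.integers(2, 60))
            # mixture: some signal so m0 < m is common
            p = np.concatenate(
                [rng.uniform(size=m // 2), rng.beta(0.2, 5.0, size=m - m // 2)]
            )
            m0 = estimate_m0_lowest_slope(p)
            _, rej_std = adaptive_bh(p, variant="standard")
            _, rej_ada = adaptive_bh(p, variant="adaptive")
            if m0 <= m:
                assert np.all(rej_ada | ~rej_std)

    def test_appending_p_one_only_raises_qvalues(self, rng):
        # Appending a null p = 1 scales every step-up threshold by
        # m/(m+1), so q-values weakly increase and no new rejection can
        # appear (rejections can only shrink, never grow).
        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 30)))
            q, rej = adaptive_bh(p, variant="standard")
            q_aug, rej_aug = adaptive_bh(np.append(p, 1.0), variant="standard")
            assert np.all(q_aug[:-1] >= q - 1e-12)
            assert np.all(rej | ~rej_aug[:-1])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_qvalues_bounded_and_monotone_in_p(self, pvals):
        p = np.asarray(pvals)
        q, _ = adaptive_bh(p, variant="standard")
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValidationError):
            adaptive_bh(np.array([0.5, 1.2]))
        with pytest.raises(ValidationError):
            adaptive_bh(np.array([0.5]), alpha=1.5)


class TestPermutation:
    def test_identical_rows_give_p_one(self):
        Y = np.tile([[1.0, 2.0, 3.0]], (8, 1))
        X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        P = permutation_pvalues(Y, X, np.eye(3), n_perm=30, seed=1)
        np.testing.assert_array_equal(P, 1.0)

    def test_minimum_attainable_p_is_one_over_nperm_plus_one(self, rng):
        n = 20
        x = np.repeat([0.0, 1.0], n // 2)
        Y = rng.standard_normal((n, 2))
        Y[:, 0] += 50 * x  # overwhelming effect
        X = np.column_stack([np.ones(n), x])
        P = permutation_pvalues(Y, X, np.eye(2), n_perm=99, seed=2)
        assert P.min() == pytest.approx(1 / 100)
        assert np.all(P >= 1 / 100)

    def test_bitwise_reproducible_for_fixed_seed(self, rng):
        Y = rng.standard_normal((15, 4))
        X = np.column_stack([np.ones(15), rng.standard_normal(15)])
        Z = rng.standard_normal((4, 2))
        P1 = permutation_pvalues(Y, X, Z, n_perm=50, seed=123)
        P2 = permutation_pvalues(Y, X, Z, n_perm=50, seed=123)
        np.testing.assert_array_equal(P1, P2)
        assert not np.array_equal(P1, permutation_pvalues(Y, X, Z, n_perm=50, seed=124))

    def test_rejects_bad_nperm(self, rng):
        with pytest.raises(ValidationError):
            permutation_pvalues(rng.standard_normal((6, 2)), np.ones((6, 1)),
                                np.eye(2), n_perm=0, seed=0)


def _table(effects, ses):
    k = len(effects)
    return pd.DataFrame(
        {
            "x_label": ["fish_oil:yes"] * k,
            "z_label": [f"c{i}" for i in range(k)],
            "effect": effects,
            "se": ses,
        }
    )


class TestContrastStudies:
    def test_self_contrast_identities(self):
        A = _table([0.3, -0.1], [0.1, 0.2])
        diff = contrast_studies(A, A, mode="difference", fdr="none")
        np.testing.assert_allclose(diff.effect, 0.0, atol=1e-12)
        avg = contrast_studies(A, A, mode="average", fdr="none")
        np.testing.assert_allclose(avg.effect, A.effect)
        np.testing.assert_allclose(avg.se, A.se / np.sqrt(2))

    def test_difference_is_antisymmetric(self):
        A = _table([0.3, -0.1], [0.1, 0.2])
        B = _table([0.1, 0.4], [0.15, 0.05])
        ab = contrast_studies(A, B, mode="difference", fdr="none")
        ba = contrast_studies(B, A, mode="difference", fdr="none")
        np.testing.assert_allclose(ab.effect, -ba.effect)
        np.testing.assert_allclose(ab.se, ba.se)

    def test_hand_computed_difference(self):
        A = _table([0.3], [0.1])
        B = _table([0.1], [0.1])
        out = contrast_studies(A, B, mode="difference", fdr="none")
        assert out.effect[0] == pytest.approx(0.2)
        assert out.se[0] == pytest.approx(np.sqrt(0.02), abs=1e-6)
        assert out.t[0] == pytest.approx(0.2 / np.sqrt(0.02), abs=1e-6)

    def test_ci_excludes_zero_iff_z_exceeds_critical(self, rng):
        A = _table(rng.standard_normal(20), rng.uniform(0.05, 0.3, 20))
        B = _table(rng.standard_normal(20), rng.uniform(0.05, 0.3, 20))
        out = contrast_studies(A, B, mode="difference", level=0.95, fdr="none")
        from scipy.stats import norm

        crit = norm.ppf(0.975)
        excl = (out.ci_lo > 0) | (out.ci_hi < 0)
        np.testing.assert_array_equal(excl, np.abs(out.effect) > crit * out.se)

    def test_unmatched_labels_reported_and_excluded(self):
        A = _table([0.3, -0.1], [0.1, 0.2])
        B = _table([0.1], [0.15])
        out = contrast_studies(A, B, mode="difference", fdr="none")
        assert len(out) == 1
        assert out.attrs["unmatched"] == [("fish_oil:yes", "c1")]

    def test_zero_shared_labels_is_an_error(self):
        A = _table([0.3], [0.1])
        B = _table([0.1], [0.1]).assign(z_label=["other"])
        with pytest.raises(ValidationError, match="share"):
            contrast_studies(A, B)
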