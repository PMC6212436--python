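"""Correlations, collinearity screen, the Gaussian log-link GLM (with
independent-oracle cross-checks) and tie-corrected Kruskal-Wallis."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from nistrace.stats import (
    collinearity_screen,
    correlation,
    glm_normal_log,
    kruskal_wallis,
)


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-12 and res.df == 8

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=5)
        y = rng.permutation(x)
        manual = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert correlation(x, y).r == pytest.approx(manual)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert correlation(x, y).r == pytest.approx(correlation(y, x).r)

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r1 = correlation(x, y, "spearman").r
        r2 = correlation(np.exp(x), y ** 3, "spearman").r
        assert r1 == pytest.approx(r2)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_fixture_natives_correlation_direction(self, table1):
        pct = [r.pct for r in table1]
        nat = [r.natives for r in table1]
        res = correlation(pct, nat)
        assert res.r < -0.5 and res.p < 0.01  # biotic resistance signal


class TestCollinearityScreen:
    def test_identical_columns_drop_second(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        kept, dropped = collinearity_screen(df)
        assert kept == ["a"]
        assert dropped[0][:2] == ("a", "b")

    def test_all_weakly_correlated_retained(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        kept, dropped = collinearity_screen(df)
        assert kept == ["a", "b", "c"] and not dropped

    def test_only_flagged_pair_dropped(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=60)
        df = pd.DataFrame({"a": a, "b": a + rng.normal(scale=0.1, size=60),
                           "c": rng.normal(size=60)})
        kept, _ = collinearity_screen(df)
        assert kept == ["a", "c"]


class TestGLMNormalLog:
    def test_noiseless_recovery(self):
        x = np.arange(10.0)
        y = np.exp(1.0 + 0.5 * x)
        res = glm_normal_log(y, x)
        assert res.slope == pytest.approx(0.5, abs=1e-8)
        assert res.intercept == pytest.approx(1.0, abs=1e-8)
        assert res.G > 1e6 and res.p_slope < 1e-50

    def test_agrees_with_statsmodels_irls(self):
        """Cross-implementation oracle: statsmodels Gaussian/log GLM."""
        rng = np.random.default_rng(17)
        worst = 0.0
        for _ in range(20):
            n = int(rng.integers(8, 30))
            x = rng.uniform(0, 2, n)
            y = np.exp(0.5 + 0.4 * x) + rng.normal(0, 0.3, n)
            res = glm_normal_log(y, x)
            fit = sm.GLM(y, sm.add_constant(x),
                         family=sm.families.Gaussian(sm.families.links.Log())).fit()
            worst = max(worst, abs(res.slope - fit.params[1]),
                        abs(res.intercept - fit.params[0]))
            assert res.phi == pytest.approx(fit.scale, rel=1e-6)
        assert worst < 1e-6

    def test_g_invariant_to_affine_rescaling_of_x(self):
        rng = np.random.default_rng(19)
        x = rng.uniform(0, 5, 25)
        y = np.exp(0.2 + 0.3 * x) + rng.normal(0, 0.5, 25)
        res1 = glm_normal_log(y, x)
        res2 = glm_normal_log(y, 10 * x + 3)
        assert res2.G == pytest.approx(res1.G, rel=1e-6)
        assert res2.slope == pytest.approx(res1.slope / 10, rel=1e-6)

    def test_zero_responses_admitted(self):
        y = np.array([0.0, 0.1, 0.5, 1.0, 2.0, 3.0])
        x = np.arange(6.0)
        res = glm_normal_log(y, x)
        assert res.converged and np.isfinite(res.slope)

    def test_dw_within_bounds_and_bp_valid(self):
        rng = np.random.default_rng(23)
        x = rng.uniform(0, 2, 30)
        y = np.exp(1 + 0.2 * x) + rng.normal(0, 0.4, 30)
        res = glm_normal_log(y, x)
        assert 0.0 <= res.dw <= 4.0
        assert 0.0 <= res.bp_p <= 1.0

    def test_type_one_error_calibrated_small_sample(self):
        """Null rejection rate of the G test ~5% at n=20 (quick check; the
        full 2000-replicate calibration lives in the acceptance suite)."""
        rng = np.random.default_rng(29)
        rejections = 0
        reps = 400
        for _ in range(reps):
            x = rng.uniform(0, 1, 20)
            y = rng.normal(5, 1, 20)
            rejections += glm_normal_log(y, x).p_slope < 0.05
        assert 0.02 < rejections / reps < 0.08

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            glm_normal_log([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


def brute_force_kw(groups):
    """Hand-rank H and the tie-correction factor computed from first
    principles (sorted pooled values, explicit average ranks)."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    values = [v for v, _ in pooled]
    ranks = []
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and values[j] == values[i]:
            j += 1
        avg = (i + 1 + j) / 2.0
        ranks.extend([avg] * (j - i))
        i = j
    N = len(values)
    rsums = {}
    counts = {}
    for (v, gi), rk in zip(pooled, ranks):
        rsums[gi] = rsums.get(gi, 0.0) + rk
        counts[gi] = counts.get(gi, 0) + 1
    H = 12.0 / (N * (N + 1)) * sum(rsums[g] ** 2 / counts[g] for g in rsums) - 3 * (N + 1)
    ties = {}
    for v in values:
        ties[v] = ties.get(v, 0) + 1
    corr = 1.0 - sum(t ** 3 - t for t in ties.values()) / (N ** 3 - N)
    return H, (H / corr if corr > 0 else 0.0)


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.H == pytest.approx(0.0, abs=1e-12)

    def test_hand_rank_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.H == pytest.approx(3.857, abs=5e-4)

    def test_tie_correction_inflates_h(self):
        res = kruskal_wallis([[1, 1, 2, 2], [2, 3, 3, 4]])
        assert res.Hc > res.H

    def test_all_values_identical(self):
        res = kruskal_wallis([[2, 2], [2, 2, 2]])
        assert res.H == 0.0 and res.p == 1.0

    @pytest.mark.parametrize("groups", [
        [[1, 2, 3], [4, 5, 6]],
        [[1, 1, 2, 5], [2, 3, 3], [4, 4, 4, 9]],
        [[0.5, 0.5], [0.5, 1.5], [2.5]],
    ])
    def test_matches_brute_force_and_scipy(self, groups):
        res = kruskal_wallis(groups)
        H_bf, Hc_bf = brute_force_kw(groups)
        assert res.H == pytest.approx(H_bf, abs=1e-10)
        assert res.Hc == pytest.approx(Hc_bf, abs=1e-10)
        stat, p = sps.kruskal(*groups)  # scipy reports the tie-corrected form
        assert res.Hc == pytest.approx(stat, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
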