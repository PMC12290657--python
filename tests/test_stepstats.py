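import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cbgrad.errors import DegenerateInputError
from cbgrad.stepstats import (
    holm_adjust,
    holm_posthoc,
    mean_gm_z,
    overlap_counts,
    paired_t,
    rm_anova,
    step_profile,
)


# ---------------------------------------------------------------------------
# independent brute-force oracle for the repeated-measures ANOVA

def rm_anova_oracle(X):
    """From-first-principles sums of squares, Mauchly W and GG epsilon,
    computed with explicit loops (no reuse of the package implementation)."""
    n, K = X.shape
    grand = sum(X[i][j] for i in range(n) for j in range(K)) / (n * K)
    ss_total = sum((X[i][j] - grand) ** 2 for i in range(n) for j in range(K))
    ss_subj = sum(K * (sum(X[i]) / K - grand) ** 2 for i in range(n))
    ss_steps = sum(n * (sum(X[i][j] for i in range(n)) / n - grand) ** 2 for j in range(K))
    ss_err = ss_total - ss_subj - ss_steps
    F = (ss_steps / (K - 1)) / (ss_err / ((K - 1) * (n - 1)))

    # sample covariance, explicit loops
    col_means = [sum(X[i][j] for i in range(n)) / n for j in range(K)]
    S = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            S[a, b] = sum((X[i][a] - col_means[a]) * (X[i][b] - col_means[b])
                          for i in range(n)) / (n - 1)

    # GG epsilon from the eigenvalues of the double-centred covariance
    H = np.eye(K) - np.ones((K, K)) / K
    lam = np.linalg.eigvalsh(H @ S @ H)
    lam = [max(v, 0.0) for v in lam]
    eps = sum(lam) ** 2 / ((K - 1) * sum(v * v for v in lam))
    eps = min(max(eps, 1.0 / (K - 1)), 1.0)

    # Mauchly's W on an orthonormal contrast basis
    C = np.linalg.qr(H)[0][:, : K - 1]
    Sc = C.T @ S @ C
    lam_c = np.linalg.eigvalsh(Sc)
    W = float(np.prod(lam_c) / (np.mean(lam_c) ** (K - 1)))
    return dict(F=F, ss=(ss_total, ss_subj, ss_steps, ss_err), eps=eps, W=W)


class _FakeStepMap:
    def __init__(self, steps, n_steps):
        self.steps = steps
        self.n_steps = n_steps
        self.lobule = 2
        self.hemisphere = "left"
        self.direction = "fissure_depth"


class TestStepProfile:
    def _stepmap(self):
        steps = np.zeros((7, 3, 3), dtype=np.int16)
        for s in range(1, 8):
            steps[s - 1] = s
        return _FakeStepMap(steps, 7)

    def test_constant_field(self):
        sm = self._stepmap()
        z = np.full(sm.steps.shape, 5.0)
        prof = step_profile(z, sm, np.ones_like(z, dtype=bool))
        np.testing.assert_allclose(prof.mean_z, 5.0)

    def test_planted_step_index(self):
        sm = self._stepmap()
        z = sm.steps.astype(float)
        prof = step_profile(z, sm, np.ones_like(z, dtype=bool))
        np.testing.assert_allclose(prof.mean_z, np.arange(1.0, 8.0))
        assert prof.voxel_counts.tolist() == [9] * 7

    def test_empty_step_is_missing_not_zero(self):
        sm = self._stepmap()
        sm.steps[sm.steps == 4] = 0
        z = np.full(sm.steps.shape, 2.0)
        prof = step_profile(z, sm, np.ones_like(z, dtype=bool))
        assert math.isnan(prof.mean_z[3])
        assert prof.voxel_counts[3] == 0
        assert prof.mean_z[0] == 2.0

    def test_gm_mask_restriction(self):
        sm = self._stepmap()
        z = np.ones(sm.steps.shape)
        z[:, 0, :] = 100.0
        gm = np.ones_like(z, dtype=bool)
        gm[:, 0, :] = False
        prof = step_profile(z, sm, gm)
        np.testing.assert_allclose(prof.mean_z, 1.0)


class TestMeanGmZ:
    def test_constant(self):
        z = np.full((4, 4, 4), 2.0)
        assert mean_gm_z(z, np.ones_like(z, dtype=bool)) == 2.0

    def test_half_and_half(self):
        z = np.zeros((2, 2, 2))
        z[0] = 4.0
        assert mean_gm_z(z, np.ones_like(z, dtype=bool)) == 2.0

    def test_matches_full_scan(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(6, 6, 6))
        gm = rng.random((6, 6, 6)) > 0.5
        expected = sum(z[i] for i in map(tuple, np.argwhere(gm))) / gm.sum()
        assert mean_gm_z(z, gm) == pytest.approx(expected)


class TestOverlapCounts:
    def test_partial_overlap(self):
        a = np.zeros((1, 1, 3), dtype=bool)
        b = np.zeros_like(a)
        a[0, 0, :2] = True      # {v1, v2}
        b[0, 0, 1:] = True      # {v2, v3}
        oc = overlap_counts(a, b)
        assert (oc.only_a, oc.only_b, oc.both) == (1, 1, 1)

    def test_identical_masks(self):
        a = np.ones((2, 2, 2), dtype=bool)
        oc = overlap_counts(a, a)
        assert (oc.only_a, oc.only_b, oc.both) == (0, 0, 8)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        a = rng.random((5, 5, 5)) > 0.5
        b = rng.random((5, 5, 5)) > 0.5
        roi = rng.random((5, 5, 5)) > 0.3
        oc = overlap_counts(a, b, roi)
        oa = ob = both = 0
        for v in map(tuple, np.argwhere(roi)):
            if a[v] and b[v]:
                both += 1
            elif a[v]:
                oa += 1
            elif b[v]:
                ob += 1
        assert (oc.only_a, oc.only_b, oc.both) == (oa, ob, both)
        assert oc.only_a + oc.both == int((a & roi).sum())


class TestPairedT:
    def test_identical_vectors(self):
        r = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 1.0

    def test_closed_form(self):
        r = paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert r.t == pytest.approx(2.0 / (1.0 / math.sqrt(3)), rel=1e-9)
        assert r.t == pytest.approx(3.4641, abs=1e-4)
        assert r.df == 2

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(size=8)
        r1 = paired_t(a, b)
        r2 = paired_t(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=10), rng.normal(size=10)
        r = paired_t(a, b)
        ref = stats.ttest_rel(a, b)
        assert r.t == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            paired_t([1.0], [0.0])
        with pytest.raises(DegenerateInputError):
            paired_t([1.0, 1.0], [0.0, 0.0])


class TestRmAnova:
    def test_all_columns_identical(self):
        X = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 5))
        res = rm_anova(X)
        assert res.F == 0.0 and res.p == 1.0

    def test_k2_equals_paired_t_squared(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(9, 2))
        res = rm_anova(X)
        t = paired_t(X[:, 0], X[:, 1])
        assert res.F == pytest.approx(t.t ** 2, rel=1e-10)
        assert res.p == pytest.approx(t.p, rel=1e-10)
        assert not res.corrected

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 7)) + rng.normal(size=(8, 1))
        res = rm_anova(X)
        ref = rm_anova_oracle(X)
        assert res.F == pytest.approx(ref["F"], rel=1e-8)
        assert res.gg_epsilon == pytest.approx(ref["eps"], rel=1e-8)
        assert res.mauchly_W == pytest.approx(ref["W"], rel=1e-8)
        if res.corrected:
            assert res.df1 == pytest.approx(ref["eps"] * 6, rel=1e-8)
            assert res.df2 == pytest.approx(ref["eps"] * 6 * 7, rel=1e-8)

    def test_ss_conservation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 5))
        ref = rm_anova_oracle(X)
        ss_total, ss_subj, ss_steps, ss_err = ref["ss"]
        assert ss_subj + ss_steps + ss_err == pytest.approx(ss_total, rel=1e-8)

    def test_epsilon_bounds_and_compound_symmetry(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            X = rng.normal(size=(10, 6))
            eps = rm_anova(X).gg_epsilon
            assert 1.0 / 5.0 - 1e-12 <= eps <= 1.0 + 1e-12
        # compound-symmetric covariance: shared subject effect + iid noise
        K = 5
        S = 0.7 * np.ones((K, K)) + 0.9 * np.eye(K)
        from cbgrad.stepstats import _gg_epsilon

        assert _gg_epsilon(S) == pytest.approx(1.0)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 7))
        res = rm_anova(X)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 7),
            "step": np.tile(np.arange(7), 8),
            "y": X.ravel(),
        })
        ref = pg.rm_anova(data=long, dv="y", within="step", subject="subject", correction=True)
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert res.p_uncorrected == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)
        assert res.gg_epsilon == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-6)
        spher = pg.sphericity(long, dv="y", within="step", subject="subject")
        assert res.mauchly_W == pytest.approx(float(spher.W), rel=1e-6)
        # our p uses the classical first-order chi-square approximation
        # (pingouin adds a second-order term); check against the formula
        n, K = 8, 7
        f = 1.0 - (2 * 6 * 6 + 6 + 2) / (6.0 * 6 * (n - 1))
        chi2_stat = -(n - 1) * f * np.log(res.mauchly_W)
        assert chi2_stat == pytest.approx(float(spher.chi2), rel=1e-6)
        assert res.mauchly_p == pytest.approx(float(stats.chi2.sf(chi2_stat, 20)), rel=1e-9)

    def test_missing_subject_dropped_with_warning(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 4))
        X[2, 1] = np.nan
        with pytest.warns(UserWarning, match="missing steps"):
            res = rm_anova(X)
        assert res.n_subjects == 5

    def test_argument_errors(self):
        with pytest.raises(DegenerateInputError):
            rm_anova(np.zeros((1, 4)))
        with pytest.raises(DegenerateInputError):
            rm_anova(np.zeros((4, 1)))


class TestHolm:
    def test_hand_applied_formula(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        # sorted raw: 0.01, 0.03, 0.04 -> 0.03, 0.06, max(0.06, 0.04) = 0.06
        np.testing.assert_allclose(np.sort(adj), [0.03, 0.06, 0.06])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])

    def test_single_comparison_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(9)
        p = rng.random(15)
        adj = holm_adjust(p)
        assert (adj >= p).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_dominated_by_bonferroni(self):
        rng = np.random.default_rng(10)
        p = rng.random(12)
        adj = holm_adjust(p)
        assert (adj <= np.minimum(1.0, len(p) * p) + 1e-15).all()

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(11)
        p = rng.random(21)
        _, ref, _, _ = sm.multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), ref, rtol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_holm_properties_hold_for_arbitrary_p_sets(self, p):
        adj = holm_adjust(p)
        p = np.asarray(p)
        assert (adj <= 1.0).all() and (adj >= 0.0).all()
        assert (adj >= p - 1e-15).all()
        assert (adj <= np.minimum(1.0, len(p) * p) + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_posthoc_family_size_and_pairs(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(8, 7))
        results = holm_posthoc(X)
        assert len(results) == 21
        assert results[0].pair == (1, 2)
        assert results[-1].pair == (6, 7)
        for r in results:
            assert r.p_adjusted >= r.p - 1e-15
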