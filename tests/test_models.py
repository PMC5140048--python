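"""Dual regression models: R^2, folds, OLS, penalized fits, nested CV."""

import numpy as np
import pandas as pd
import pytest

from rbpreg import models, synthdata
from rbpreg.models import (
    DegenerateFitError,
    compute_improvement,
    default_lambda_grid,
    fit_panel,
    fit_rbp_plus,
    fit_rna_only,
    make_folds,
    r_squared,
)


class TestRSquared:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 5.0])
        assert r_squared(y, y) == 1.0

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_anticorrelated_predictions_are_negative(self):
        assert r_squared([0, 1, 2], [2, 1, 0]) == pytest.approx(-3.0)

    def test_constant_observations_rejected(self):
        with pytest.raises(DegenerateFitError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMakeFolds:
    def test_twelve_into_five_near_equal(self):
        folds = make_folds(12, 5, seed=0)
        sizes = sorted(np.bincount(folds, minlength=5))
        assert sizes == [2, 2, 2, 3, 3]

    def test_ten_into_five_equal(self):
        sizes = np.bincount(make_folds(10, 5, seed=1))
        assert (sizes == 2).all()

    def test_deterministic_and_seed_sensitive(self):
        a = make_folds(30, 5, seed=4)
        b = make_folds(30, 5, seed=4)
        c = make_folds(30, 5, seed=5)
        assert (a == b).all()
        assert not (a == c).all()

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            make_folds(4, 5)


class TestFitRnaOnly:
    def test_noiseless_linear_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = 2.0 * x
        fit = fit_rna_only(y, x, make_folds(20, 5, seed=0), gene_id="g")
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.beta_mrna == pytest.approx(2.0, abs=1e-12)

    def test_per_fold_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        y = 1.0 + 0.7 * x + rng.normal(scale=0.3, size=25)
        folds = make_folds(25, 5, seed=1)
        fit = fit_rna_only(y, x, folds, gene_id="g")
        for f in range(5):
            tr = folds != f
            X = np.column_stack([np.ones(tr.sum()), x[tr]])
            beta = np.linalg.solve(X.T @ X, X.T @ y[tr])
            pred = beta[0] + beta[1] * x[~tr]
            np.testing.assert_allclose(fit.cv_predictions.values[~tr], pred, rtol=1e-10)

    def test_uninformative_predictor_has_nonpositive_mean_heldout_r2(self):
        """Out-of-sample R^2 of pure noise regressions is negatively biased."""
        rng = np.random.default_rng(2)
        r2s = []
        for rep in range(150):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            fit = fit_rna_only(y, x, make_folds(30, 5, seed=rep), gene_id="g")
            r2s.append(fit.r2)
        assert np.mean(r2s) < 0


class TestFitRbpPlus:
    def _toy(self, n=40, k=3, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        X = rng.normal(size=(n, k))
        beta = np.array([1.0, -0.8, 0.5])[:k]
        y = 1.0 + 0.5 * x + X @ beta + noise * rng.normal(size=n)
        return y, x, X, beta

    def test_infinite_penalty_matches_rna_only_exactly(self):
        y, x, X, _ = self._toy(noise=0.5)
        folds = make_folds(len(y), 5, seed=3)
        grid = np.array([np.inf])
        fit_inf = fit_rbp_plus(y, x, X, folds, penalty="ridge", lambda_grid=grid, gene_id="g")
        fit_rna = fit_rna_only(y, x, folds, gene_id="g")
        np.testing.assert_allclose(
            fit_inf.cv_predictions.values, fit_rna.cv_predictions.values, atol=1e-6
        )
        assert (fit_inf.beta_rbp == 0).all()

    def test_noiseless_truth_recovered_at_tiny_lambda(self):
        y, x, X, beta = self._toy(noise=0.0)
        folds = make_folds(len(y), 5, seed=4)
        fit = fit_rbp_plus(y, x, X, folds, penalty="ridge",
                           lambda_grid=np.array([1e-8]), gene_id="g")
        np.testing.assert_allclose(fit.beta_rbp.values, beta, atol=1e-3)
        assert fit.beta_mrna == pytest.approx(0.5, abs=1e-3)
        assert fit.beta0 == pytest.approx(1.0, abs=1e-3)

    def test_lasso_at_grid_maximum_zeroes_all_rbps(self):
        y, x, X, _ = self._toy(noise=0.3, seed=5)
        folds = make_folds(len(y), 5, seed=5)
        fit = fit_rbp_plus(y, x, X, folds, penalty="lasso",
                           lambda_grid=np.array([np.inf]), gene_id="g")
        assert (fit.beta_rbp.values == 0).all()

    def test_lasso_solution_satisfies_kkt_conditions(self):
        """Independent optimality check of the lasso path on the
        residualized problem: |grad| <= lambda off-support, = lambda with
        matching sign on the support."""
        y, x, X, _ = self._toy(n=60, noise=0.5, seed=6)
        lam = 5.0
        U = np.column_stack([np.ones(len(y)), x])
        Q, _ = np.linalg.qr(U)
        My = y - Q @ (Q.T @ y)
        MX = X - Q @ (Q.T @ X)
        B = models._lasso_path(My, MX, np.array([lam]))
        b = B[:, 0]
        grad = -2.0 * MX.T @ (My - MX @ b)
        for j in range(len(b)):
            if b[j] == 0:
                assert abs(grad[j]) <= lam * (1 + 1e-4)
            else:
                assert grad[j] + lam * np.sign(b[j]) == pytest.approx(0.0, abs=lam * 1e-3)

    def test_ridge_matches_sklearn_on_residualized_block(self):
        from sklearn.linear_model import Ridge

        y, x, X, _ = self._toy(n=50, noise=0.4, seed=7)
        lam = 2.5
        U = np.column_stack([np.ones(len(y)), x])
        Q, _ = np.linalg.qr(U)
        My = y - Q @ (Q.T @ y)
        MX = X - Q @ (Q.T @ X)
        ours = models._ridge_path(My, MX, np.array([lam]))[:, 0]
        ref = Ridge(alpha=lam, fit_intercept=False).fit(MX, My).coef_
        np.testing.assert_allclose(ours, ref, rtol=1e-8)

    def test_empty_rbp_block_falls_back_to_rna_only(self):
        y, x, _, _ = self._toy(noise=0.2, seed=8)
        folds = make_folds(len(y), 5, seed=8)
        fit = fit_rbp_plus(y, x, np.empty((len(y), 0)), folds, gene_id="g")
        assert fit.penalty == "none"
        assert any("fallback" in w for w in fit.warnings)

    def test_no_leakage_between_outer_folds(self, monkeypatch):
        """Inner-CV tuning must only ever see training-split samples."""
        y, x, X, _ = self._toy(n=30, noise=0.5, seed=9)
        folds = make_folds(30, 5, seed=9)
        seen = []
        orig = models._residualize

        def spy(U, yy, XX):
            seen.append(len(yy))
            return orig(U, yy, XX)

        monkeypatch.setattr(models, "_residualize", spy)
        fit_rbp_plus(y, x, X, folds, gene_id="g")
        # outer training splits have 24 samples; inner splits at most 24*4/5;
        # only the final full-data fit may see all 30
        outer_sizes = {24}
        for size in seen:
            assert size <= 30
            assert size not in range(25, 30)

    def test_ridge_predictions_converge_to_rna_only_along_grid(self):
        """On null genes the held-out prediction gap to RNA-only shrinks as
        lambda grows beyond the optimum (checked at grid points)."""
        rng = np.random.default_rng(10)
        x = rng.normal(size=40)
        y = 0.8 * x + rng.normal(scale=0.5, size=40)  # RBPs irrelevant
        X = rng.normal(size=(40, 4))
        folds = make_folds(40, 5, seed=10)
        rna = fit_rna_only(y, x, folds, gene_id="g").cv_predictions.values
        gaps = []
        for lam in [1e0, 1e2, 1e4, 1e6, np.inf]:
            fit = fit_rbp_plus(y, x, X, folds, penalty="ridge",
                               lambda_grid=np.array([lam]), gene_id="g")
            gaps.append(np.abs(fit.cv_predictions.values - rna).max())
        assert all(g2 <= g1 + 1e-12 for g1, g2 in zip(gaps, gaps[1:]))
        assert gaps[-1] == 0.0


class TestImprovementAndPanel:
    def test_identical_predictions_zero_improvement(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=20)
        y = x + rng.normal(scale=0.2, size=20)
        folds = make_folds(20, 5, seed=11)
        a = fit_rna_only(y, x, folds, gene_id="g")
        b = fit_rbp_plus(y, x, np.empty((20, 0)), folds, gene_id="g")
        pair = compute_improvement(a, b)
        assert pair.improvement == pytest.approx(0.0, abs=1e-12)

    def test_improvement_is_r2_difference(self):
        pair = models.AccuracyPair("g", 0.3, 0.5)
        assert pair.improvement == pytest.approx(0.2)

    def test_mismatched_folds_rejected(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        a = fit_rna_only(y, x, make_folds(20, 5, seed=1), gene_id="g")
        b = fit_rna_only(y, x, make_folds(20, 5, seed=2), gene_id="g")
        with pytest.raises(ValueError, match="fold"):
            compute_improvement(a, b)

    def test_fit_panel_one_pair_per_mapped_gene(self, centered_fixture):
        panel, imap, _ = centered_fixture
        pairs, fits = fit_panel(panel, imap, penalty="ridge", seed=3)
        mapped = [g for g in imap.transcripts() if g in panel.protein.columns]
        assert set(pairs["gene"]) <= set(mapped)
        assert len(pairs) == len(fits)
        # genes absent from the map are absent from the table
        unmapped = set(panel.gene_ids) - set(imap.transcripts())
        assert not (set(pairs["gene"]) & unmapped)

    def test_fit_panel_rerun_identical(self, centered_fixture):
        panel, imap, _ = centered_fixture
        p1, _ = fit_panel(panel, imap, penalty="ridge", seed=3)
        p2, _ = fit_panel(panel, imap, penalty="ridge", seed=3)
        pd.testing.assert_frame_equal(p1, p2)

    def test_regulated_genes_show_positive_median_improvement(self, fixture_data, centered_fixture):
        panel, imap, _ = centered_fixture
        pairs, _ = fit_panel(panel, imap, penalty="ridge", seed=3)
        truth = fixture_data["truth"]
        reg = [g for g in pairs["gene"] if truth.regulated.get(g, False)]
        assert len(reg) >= 10
        med = pairs.set_index("gene").loc[reg, "improvement"].median()
        assert med > 0

    def test_r2_recomputation_for_stored_fits(self, centered_fixture):
        panel, imap, _ = centered_fixture
        pairs, fits = fit_panel(panel, imap, penalty="ridge", seed=3)
        for gene, (f_rna, f_rbp) in list(fits.items())[:10]:
            rbps = [r for r in imap.rbps_for(gene) if r != gene]
            y, x, X, ok = models.complete_cases(panel, gene, rbps)
            for fit in (f_rna, f_rbp):
                preds = fit.cv_predictions.values
                mask = np.isfinite(preds)
                sse = ((y[ok][mask] - preds[mask]) ** 2).sum()
                sst = ((y[ok][mask] - y[ok][mask].mean()) ** 2).sum()
                assert fit.r2 == pytest.approx(1 - sse / sst, rel=1e-9)
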