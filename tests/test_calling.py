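"""Empty-droplet thresholding and damaged-cell mixture calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import nfqc
from nfqc.calling import (
    CallConfig,
    DamagedCellDetector,
    DiagonalGaussianMixture,
    EmptyDropletDetector,
)
from nfqc.counting import STATUS_CELL, STATUS_DAMAGED, STATUS_EMPTY

from conftest import simulate_mixture


def bimodal_nf(n=5000, seed=0, w=0.3, m1=0.05, s1=0.01, m2=0.5, s2=0.05):
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < w
    x = np.where(comp, rng.normal(m1, s1, n), rng.normal(m2, s2, n))
    return np.clip(x, 0, 1)


def direct_loglik(X, means, variances, weights):
    """Brute-force mixture log-likelihood, summed in log space."""
    X = np.asarray(X)
    per_comp = np.stack([
        np.log(w) + norm.logpdf(X, m, np.sqrt(v)).sum(axis=1)
        for m, v, w in zip(means, variances, weights)
    ], axis=1)
    mx = per_comp.max(axis=1, keepdims=True)
    return float((mx[:, 0] + np.log(np.exp(per_comp - mx).sum(axis=1))).sum())


class TestEmptyThreshold:
    def test_bimodal_cutoff_separates_the_modes(self):
        nf = bimodal_nf(seed=3)
        thr = nfqc.estimate_empty_threshold(nf)
        assert thr.cutoff is not None
        assert 0.1 < thr.cutoff < 0.35  # between the planted modes
        assert thr.peak_position < thr.valley_position
        grid_at = lambda p: thr.density[np.argmin(np.abs(thr.grid - p))]
        assert grid_at(thr.valley_position) <= grid_at(thr.peak_position)

    def test_unimodal_gives_no_cutoff(self):
        rng = np.random.default_rng(1)
        nf = np.clip(rng.normal(0.5, 0.05, 5000), 0, 1)
        thr = nfqc.estimate_empty_threshold(nf)
        assert thr.cutoff is None and thr.valley_position is None

    def test_order_invariance(self):
        nf = bimodal_nf(seed=5)
        thr1 = nfqc.estimate_empty_threshold(nf)
        rng = np.random.default_rng(0)
        thr2 = nfqc.estimate_empty_threshold(rng.permutation(nf))
        assert thr1.cutoff == thr2.cutoff
        np.testing.assert_array_equal(thr1.density, thr2.density)

    def test_density_integrates_to_one(self):
        for nf in (bimodal_nf(seed=2), np.clip(np.random.default_rng(3).normal(0.5, 0.05, 5000), 0, 1)):
            thr = nfqc.estimate_empty_threshold(nf)
            assert np.trapezoid(thr.density, thr.grid) == pytest.approx(1.0, abs=1e-3)

    def test_too_few_values_directs_to_manual_threshold(self):
        with pytest.raises(ValueError, match="nf_rescue"):
            nfqc.estimate_empty_threshold(np.linspace(0, 1, 20))

    def test_detector_is_sklearn_compatible(self):
        det = EmptyDropletDetector(umi_rescue=1000.0)
        params = det.get_params()
        assert params["umi_rescue"] == 1000.0
        det.set_params(prominence=0.1)
        assert det.prominence == 0.1


class TestFlagEmpty:
    @pytest.fixture()
    def table(self):
        return pd.DataFrame({
            "barcode": ["a", "b", "c", "d"],
            "nuclear_fraction": [0.05, 0.05, 0.5, np.nan],
            "umi_count": [800, 30_000, 2000, 100],
            "cell_type": [pd.NA] * 4,
            "qc_status": ["unassigned"] * 4,
        })

    def test_below_cutoff_is_empty(self, table):
        out = nfqc.flag_empty(table, None, CallConfig(nf_rescue=0.2))
        assert out.set_index("barcode")["qc_status"].to_dict() == {
            "a": STATUS_EMPTY, "b": STATUS_EMPTY, "c": STATUS_CELL,
            "d": "unassigned"}

    def test_umi_rescue_overrides_empty_call(self, table):
        out = nfqc.flag_empty(table, None,
                              CallConfig(nf_rescue=0.2, umi_rescue=20_000))
        assert out.set_index("barcode")["qc_status"]["b"] == STATUS_CELL
        assert out.set_index("barcode")["qc_status"]["a"] == STATUS_EMPTY

    def test_no_cutoff_available_is_an_error(self, table):
        with pytest.raises(ValueError, match="cutoff"):
            nfqc.flag_empty(table, None, CallConfig())

    def test_fixture_population_empty_fraction_recovered(self, population):
        """Oracle: the generator's truth labels; within 2 percentage points."""
        _, table, labels = population
        thr = nfqc.estimate_empty_threshold(table["nuclear_fraction"].dropna())
        out = nfqc.flag_empty(table, thr)
        recovered = (out["qc_status"] == STATUS_EMPTY).mean()
        planted = (labels["true_class"] == "empty").mean()
        assert abs(recovered - planted) < 0.02


class TestMixtureEM:
    def test_single_component_closed_form(self):
        """k=1 EM is one M-step: sample mean, biased variance, BIC in closed form."""
        X, _ = simulate_mixture(500, [[3.0, 0.4]], [[0.04, 0.01]], [1.0], seed=8)
        fit = nfqc.fit_mixture(X, k=1)
        np.testing.assert_allclose(fit.means[0], X.mean(axis=0), atol=1e-9)
        np.testing.assert_allclose(fit.variances[0], X.var(axis=0), atol=1e-9)
        np.testing.assert_allclose(fit.weights, [1.0])
        ll = direct_loglik(X, fit.means, fit.variances, fit.weights)
        assert fit.bic == pytest.approx(-2 * ll + 4 * np.log(len(X)), rel=1e-9)

    def test_loglik_matches_independent_evaluation(self):
        for seed in range(5):
            X, _ = simulate_mixture(
                800, [[3.5, 0.4], [3.0, 0.75]], [[0.04, 0.0036], [0.04, 0.0025]],
                [0.8, 0.2], seed=seed)
            fit = nfqc.fit_mixture(X, k=2)
            oracle = direct_loglik(X, fit.means, fit.variances, fit.weights)
            assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_loglik_path_is_monotone(self):
        X, _ = simulate_mixture(
            1000, [[3.5, 0.4], [3.0, 0.7]], [[0.04, 0.004], [0.04, 0.003]],
            [0.7, 0.3], seed=2)
        fit = nfqc.fit_mixture(X, k=2)
        diffs = np.diff(fit.loglik_path)
        assert (diffs >= -1e-9).all()
        assert fit.converged

    def test_responsibilities_are_posteriors(self):
        X, _ = simulate_mixture(
            600, [[3.5, 0.4], [3.0, 0.7]], [[0.04, 0.004], [0.04, 0.003]],
            [0.7, 0.3], seed=4)
        fit = nfqc.fit_mixture(X, k=2)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-9)
        assert (fit.weights >= 0).all()
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_parameter_recovery_on_separated_mixture(self):
        """Oracle: the simulation's generating parameters (separation > 4 sd)."""
        true_means = np.array([[3.5, 0.40], [2.98, 0.75]])
        true_vars = np.array([[0.04, 0.0036], [0.04, 0.0025]])
        X, _ = simulate_mixture(2000, true_means, true_vars, [0.8, 0.2], seed=6)
        fit = nfqc.fit_mixture(X, k=2)
        order = np.argsort(fit.means[:, 1])
        means = fit.means[order]
        weights = fit.weights[order]
        assert abs(means[0, 1] - 0.40) < 0.02 and abs(means[1, 1] - 0.75) < 0.02
        assert abs(weights[0] - 0.8) < 0.05 and abs(weights[1] - 0.2) < 0.05

    def test_agrees_with_sklearn_reference(self):
        """Independent EM implementation (sklearn, diag covariance) reaches
        the same optimum on well-separated data."""
        from sklearn.mixture import GaussianMixture
        X, _ = simulate_mixture(
            1500, [[3.5, 0.4], [3.0, 0.75]], [[0.04, 0.0036], [0.04, 0.0025]],
            [0.75, 0.25], seed=12)
        fit = nfqc.fit_mixture(X, k=2)
        ref = GaussianMixture(2, covariance_type="diag", tol=1e-8,
                              n_init=3, random_state=0).fit(X)
        assert fit.loglik == pytest.approx(ref.score(X) * len(X), rel=1e-3)
        order = np.argsort(fit.means[:, 1])
        ref_order = np.argsort(ref.means_[:, 1])
        np.testing.assert_allclose(fit.means[order], ref.means_[ref_order], atol=0.01)

    def test_bic_prefers_true_model_order(self):
        X1, _ = simulate_mixture(1000, [[3.5, 0.4]], [[0.04, 0.004]], [1.0], seed=9)
        assert nfqc.fit_mixture(X1, 1).bic < nfqc.fit_mixture(X1, 2).bic
        X2, _ = simulate_mixture(
            1000, [[3.5, 0.4], [3.0, 0.75]], [[0.04, 0.0036], [0.04, 0.0025]],
            [0.7, 0.3], seed=9)
        assert nfqc.fit_mixture(X2, 2).bic < nfqc.fit_mixture(X2, 1).bic

    def test_determinism(self):
        X, _ = simulate_mixture(
            700, [[3.5, 0.4], [3.0, 0.7]], [[0.04, 0.004], [0.04, 0.003]],
            [0.7, 0.3], seed=5)
        f1, f2 = nfqc.fit_mixture(X, 2), nfqc.fit_mixture(X, 2)
        np.testing.assert_array_equal(f1.means, f2.means)
        np.testing.assert_array_equal(f1.responsibilities, f2.responsibilities)

    def test_invalid_k_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            DiagonalGaussianMixture(n_components=3).fit(X)


class TestIdentifyDamaged:
    @staticmethod
    def make_table(n_intact, n_damaged, nf_i, nf_d, umi_i, umi_d, seed=0):
        rng = np.random.default_rng(seed)
        nf = np.concatenate([
            rng.normal(nf_i, 0.05, n_intact), rng.normal(nf_d, 0.05, n_damaged)])
        umi = np.concatenate([
            10 ** rng.normal(umi_i, 0.2, n_intact),
            10 ** rng.normal(umi_d, 0.2, n_damaged)]).round().astype(int)
        return pd.DataFrame({
            "barcode": [f"b{i}" for i in range(n_intact + n_damaged)],
            "nuclear_fraction": np.clip(nf, 0, 1),
            "umi_count": np.maximum(umi, 1),
            "cell_type": "T",
            "qc_status": STATUS_CELL,
            "truth": [False] * n_intact + [True] * n_damaged,
        })

    def test_small_nf_separation_flags_nothing(self):
        """Separation below delta_nf (0.15) must yield zero damaged flags."""
        table = self.make_table(1600, 400, 0.40, 0.45, 3.5, 2.98, seed=1)
        out = nfqc.identify_damaged(table, "T")
        assert (out["qc_status"] == STATUS_DAMAGED).sum() == 0

    def test_higher_umi_in_high_nf_cluster_flags_nothing(self):
        """Damaged phenotype requires high NF AND low UMI, jointly."""
        table = self.make_table(1600, 400, 0.40, 0.75, 3.0, 3.6, seed=2)
        out = nfqc.identify_damaged(table, "T")
        assert (out["qc_status"] == STATUS_DAMAGED).sum() == 0

    def test_planted_damaged_cluster_recovered(self):
        """NF 0.75 vs 0.40, UMI at 30%, 20% prevalence: >= 90% balanced accuracy."""
        from sklearn.metrics import balanced_accuracy_score
        table = self.make_table(1600, 400, 0.40, 0.75, 3.5, 3.5 + np.log10(0.3),
                                seed=3)
        out = nfqc.identify_damaged(table, "T")
        called = out["qc_status"] == STATUS_DAMAGED
        assert balanced_accuracy_score(table["truth"], called) >= 0.90

    def test_group_below_min_droplets_is_skipped(self, caplog):
        table = self.make_table(30, 10, 0.40, 0.75, 3.5, 3.0)
        with caplog.at_level("WARNING", logger="nfqc.calling"):
            out = nfqc.identify_damaged(table, "T")
        assert (out["qc_status"] == STATUS_DAMAGED).sum() == 0
        assert "min_droplets" in caplog.text

    def test_empty_droplets_excluded_from_fit(self):
        table = self.make_table(1600, 400, 0.40, 0.75, 3.5, 2.98, seed=4)
        table.loc[:200, "qc_status"] = STATUS_EMPTY
        out = nfqc.identify_damaged(table, "T")
        assert ((out["qc_status"] == STATUS_EMPTY)
                == (table["qc_status"] == STATUS_EMPTY)).all()

    def test_detector_requires_positive_umi(self):
        det = DamagedCellDetector()
        with pytest.raises(ValueError, match="positive"):
            det.fit(np.array([[0.4, 0], [0.5, 10]]))


class TestCallAll:
    def test_statuses_without_cell_types(self, population):
        _, table, _ = population
        t = table.copy()
        t["cell_type"] = pd.NA
        out, report = nfqc.call_all(t)
        assert set(out["qc_status"]) <= {STATUS_CELL, STATUS_EMPTY}
        assert report["cell_types"] == {}

    def test_full_population_damaged_fractions(self, population):
        """Oracle: planted per-type damaged fractions, within 3 points."""
        _, table, labels = population
        out, _ = nfqc.call_all(table, CallConfig(seed=7))
        merged = out.merge(labels, on="barcode", suffixes=("", "_true"))
        for ct in ("type_A", "type_B", "type_C"):
            grp = merged[merged["cell_type"] == ct]
            planted = (grp["true_class"] == "damaged").mean()
            called = (grp["qc_status"] == STATUS_DAMAGED).mean()
            assert abs(called - planted) < 0.03, ct

    def test_no_droplet_is_both_empty_and_damaged(self, population):
        _, table, _ = population
        out, _ = nfqc.call_all(table)
        assert out["qc_status"].isin(
            [STATUS_CELL, STATUS_EMPTY, STATUS_DAMAGED, "unassigned"]).all()

    def test_idempotent_and_preserves_rows(self, population):
        """Flags only, never removes; rerunning resets and reproduces."""
        _, table, _ = population
        out1, rep1 = nfqc.call_all(table, CallConfig(seed=1))
        out2, rep2 = nfqc.call_all(out1, CallConfig(seed=1))
        assert len(out1) == len(table)
        pd.testing.assert_frame_equal(out1, out2)
        assert rep1["empty_threshold"] == rep2["empty_threshold"]

    def test_manual_nf_threshold_overrides_automatic(self, population):
        _, table, _ = population
        out, report = nfqc.call_all(table, CallConfig(nf_rescue=0.01))
        assert report["empty_threshold"]["effective"] == 0.01
        auto, _ = nfqc.call_all(table)
        assert (out["qc_status"] == STATUS_EMPTY).sum() < (
            (auto["qc_status"] == STATUS_EMPTY).sum())


def test_call_config_validates_gates():
    with pytest.raises(ValueError):
        CallConfig(delta_nf=1.5)
    with pytest.raises(ValueError):
        CallConfig(umi_ratio=0.0)
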