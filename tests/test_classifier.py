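"""GMM labeling, logistic callability model, precision map, VCF filter."""

import numpy as np
import pytest
from sklearn.metrics import f1_score, roc_auc_score

from abbscore.classifier import (
    CallabilityModel,
    RecurrentDeviationLabeler,
    confidence_level,
    f1_scan,
    filter_variants,
    gmm_label,
    score_position,
)
from abbscore.io import VcfSiteRow
from abbscore.site import SiteDeviationSummary


def _noisy_features(rng, n=4000, pos_rate=0.3):
    y = (rng.random(n) < pos_rate).astype(int)
    r1 = np.clip(0.04 + 0.10 * y + rng.normal(0, 0.03, n), 0, 0.5)
    r2 = np.clip(0.05 + 0.25 * y + rng.normal(0, 0.08, n), 0, 1)
    r3 = np.clip(0.4 + 2.5 * y + rng.normal(0, 0.8, n), 0, None)
    return np.column_stack([r1, r2, r3]), y


class TestGmmLabel:
    def test_simulate_then_label_accuracy(self, rng):
        truth = rng.random(5000) < 0.10
        x = np.where(truth, rng.normal(0.20, 0.03, 5000), rng.normal(0.03, 0.01, 5000))
        labels = gmm_label(x, random_state=0)
        assert (labels == truth).mean() >= 0.98

    def test_degenerate_constant_input(self):
        with pytest.warns(RuntimeWarning):
            labels = gmm_label(np.full(200, 0.07))
        assert not labels.any()

    def test_larger_mean_component_is_class_one(self):
        x = np.r_[np.full(50, 0.01), np.full(50, 0.40)]
        labels = gmm_label(x + np.linspace(0, 1e-4, 100))
        assert not labels[:50].any()
        assert labels[50:].all()


class TestCallabilityModel:
    def test_separable_features_reach_f1_one(self, rng):
        y = (rng.random(2000) < 0.3).astype(int)
        X = np.column_stack([0.03 + 0.2 * y, 0.05 + 0.5 * y, 0.3 + 3.0 * y])
        X += rng.normal(0, 1e-3, X.shape)
        model = CallabilityModel(random_state=0).fit(X, y)
        assert model.f1_ == pytest.approx(1.0)

    def test_null_features_give_chance_auc(self, rng):
        X, y = _noisy_features(rng, n=10_000)
        y = rng.permutation(y)  # break any feature-label association
        model = CallabilityModel(random_state=0).fit(X, y)
        resp = model.predict_response(X)
        assert roc_auc_score(y, resp) == pytest.approx(0.5, abs=0.03)

    def test_f1_scan_matches_brute_force(self, rng):
        resp = rng.random(300)
        y = (rng.random(300) < 0.4).astype(int)
        thr, f1 = f1_scan(resp, y)
        for t, f in zip(thr[::17], f1[::17]):
            brute = f1_score(y, (resp >= t).astype(int), zero_division=0)
            assert f == pytest.approx(brute, abs=1e-12)

    def test_coefficients_match_statsmodels_mle(self, rng):
        """Unpenalized logistic fit cross-checked against an independent
        Newton IRLS implementation on a well-conditioned problem."""
        import statsmodels.api as sm

        n = 3000
        y = (rng.random(n) < 0.4).astype(int)
        # heavily overlapping classes: well-identified, finite MLE
        X = np.column_stack(
            [
                0.05 + 0.03 * y + rng.normal(0, 0.05, n),
                0.10 + 0.08 * y + rng.normal(0, 0.15, n),
                0.50 + 0.50 * y + rng.normal(0, 0.80, n),
            ]
        )
        D = np.column_stack([X, X[:, 1] * X[:, 2]])
        model = CallabilityModel(random_state=0).fit(X, y)
        # refit with statsmodels on the same training split
        from sklearn.model_selection import train_test_split

        D_tr, _, y_tr, _ = train_test_split(
            D, y, test_size=1 / 3, stratify=y, random_state=0
        )
        ref = sm.Logit(y_tr, sm.add_constant(D_tr)).fit(disp=0, method="lbfgs", maxiter=2000)
        np.testing.assert_allclose(model.coef_, ref.params, rtol=1e-2, atol=5e-2)

    def test_response_monotone_in_each_feature(self, rng):
        X, y = _noisy_features(rng)
        model = CallabilityModel(random_state=1).fit(X, y)
        base = np.array([[0.05, 0.2, 1.0]])
        r0 = model.predict_response(base)[0]
        for j in range(3):
            bumped = base.copy()
            bumped[0, j] += 0.01
            r1 = model.predict_response(bumped)[0]
            # moves in the direction of the effective coefficient sign
            eff = model.coef_[1 + j]
            if j in (1, 2):  # interaction contributes to rdab2/rdab3
                eff += model.coef_[4] * base[0, 2 if j == 1 else 1]
            assert np.sign(r1 - r0) == np.sign(eff)

    def test_precision_map_is_monotone(self, rng):
        X, y = _noisy_features(rng)
        model = CallabilityModel(random_state=2).fit(X, y)
        grid = np.linspace(0, 1, 101)
        mapped = model.precision_map(grid)
        assert (np.diff(mapped) >= -1e-12).all()
        assert ((mapped >= 0) & (mapped <= 1)).all()

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError):
            CallabilityModel().fit(np.random.rand(50, 3), np.zeros(50))

    def test_json_roundtrip(self, rng, tmp_path):
        X, y = _noisy_features(rng)
        model = CallabilityModel(random_state=0).fit(X, y)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = CallabilityModel.from_json(path)
        np.testing.assert_allclose(loaded.coef_, model.coef_)
        np.testing.assert_allclose(
            loaded.transform(X[:20]), model.transform(X[:20]), atol=1e-12
        )


class TestScorePosition:
    @pytest.mark.parametrize(
        "abb, expected",
        [(0.0, "high"), (0.15, "high"), (0.16, "medium"), (0.75, "medium"),
         (0.76, "low"), (0.90, "low"), (0.91, "very_low"), (1.0, "very_low")],
    )
    def test_confidence_bins(self, abb, expected):
        assert confidence_level(abb) == expected

    def test_identity_precision_map_passes_response_through(self):
        model = CallabilityModel()
        model.coef_ = np.array([0.0, 1.0, 1.0, 1.0, 1.0])
        model.cutoff_ = 0.5
        model.f1_ = 1.0
        model.precision_x_ = np.array([0.0, 1.0])
        model.precision_y_ = np.array([0.0, 1.0])
        s = SiteDeviationSummary("chr1", 100, 90, 0.2, 0.3, 1.0)
        rec = score_position(s, model)
        assert rec.abb == pytest.approx(rec.lr_response)
        assert rec.confidence == confidence_level(rec.abb)

    def test_clean_summary_scores_high_confidence(self, rng):
        X, y = _noisy_features(rng)
        model = CallabilityModel(random_state=0).fit(X, y)
        s = SiteDeviationSummary("chr1", 1, 100, 0.0, 0.0, 0.0)
        assert score_position(s, model).confidence == "high"


class TestFilterVariants:
    def _rows(self):
        return [
            VcfSiteRow("chr1", 100, "A", "G", ("het",)),
            VcfSiteRow("chr1", 200, "C", "T", ("het",)),
            VcfSiteRow("chr1", 300, "G", "A", ("het",)),
        ]

    def test_strict_threshold_and_unscored_kept(self):
        scores = {("chr1", 100): 0.95, ("chr1", 200): 0.90}
        kept, removed, n_unscored = filter_variants(self._rows(), scores, max_abb=0.9)
        assert [r.pos for r in removed] == [100]  # 0.95 > 0.9 removed
        assert [r.pos for r in kept] == [200, 300]  # 0.90 kept (strict >)
        assert n_unscored == 1
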