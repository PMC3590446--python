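import numpy as np
import pytest
from scipy.stats import norm

from nodtemplate import (
    CandidateRecord,
    LCGDensity,
    NoduleBayesModel,
    TemplateSpec,
    TrainingSet,
    Volume,
    build_template,
    classify,
    fit_lcg,
    gray_features,
    make_feature_training_set,
    radial_distances,
    radial_nonuniformity,
    train_classifier,
)


class TestRadialDistances:
    def test_disk_is_isotropic(self):
        from skimage.draw import disk

        m = np.zeros((64, 64))
        rr, cc = disk((32, 32), 10.5)
        m[rr, cc] = 1
        d = radial_distances(m, (32, 32))
        assert len(d) == 8
        assert all(abs(x - 10) <= 0.5 for x in d)

    def test_square_axis_vs_diagonal(self):
        m = np.zeros((64, 64))
        m[20:45, 20:45] = 1  # half-width 12.5 around (32, 32)
        d = radial_distances(m, (32, 32))
        axes, diags = d[0::2], d[1::2]
        assert all(abs(x - 12.5) <= 1.0 for x in axes)
        assert all(abs(x - 12.5 * np.sqrt(2)) <= 1.0 for x in diags)

    def test_ellipse_max_min_semi_axes(self):
        from skimage.draw import ellipse

        m = np.zeros((64, 64))
        rr, cc = ellipse(32, 32, 20, 10)
        m[rr, cc] = 1
        d = radial_distances(m, (32, 32))
        assert max(d) == pytest.approx(20, abs=1.0)
        assert min(d) == pytest.approx(10, abs=1.0)

    def test_center_on_background_rejected(self):
        m = np.zeros((16, 16))
        m[2:5, 2:5] = 1
        with pytest.raises(ValueError):
            radial_distances(m, (10, 10))


class TestRadialNonuniformity:
    def test_perfect_disk_is_zero(self):
        assert radial_nonuniformity([10.0] * 8) == 0.0

    def test_max_minus_min(self):
        assert radial_nonuniformity([3, 5, 4, 7, 3, 4, 5, 6]) == 4.0

    def test_needs_two_directions(self):
        with pytest.raises(ValueError):
            radial_nonuniformity([5.0])


class TestGrayFeatures:
    def test_uniform_support(self):
        vol = Volume(data=np.full((24, 24, 3), 100.0))
        cand = CandidateRecord(center=(12, 12, 1), shape="circle", R=5.0, similarity=1.0)
        assert gray_features(vol, cand) == (100.0, 100.0)

    def test_percentile_uses_lower_interpolation(self):
        spec = TemplateSpec("circle", R=5.0)
        img = build_template(spec)
        n = int(img.support.sum())
        data = np.full((24, 24, 3), 0.0)
        offs = np.argwhere(img.support) - np.array(img.center)
        vals = np.arange(n, dtype=float)
        data[offs[:, 0] + 12, offs[:, 1] + 12, 1] = vals
        cand = CandidateRecord(center=(12, 12, 1), shape="circle", R=5.0, similarity=1.0)
        q_ave, q_10 = gray_features(Volume(data=data), cand)
        assert q_ave == pytest.approx(vals.mean())
        assert q_10 == np.sort(vals)[int(0.1 * (n - 1))]  # lower data point

    def test_rendered_template_mean(self):
        spec = TemplateSpec("circle", R=10.0)
        img = build_template(spec)
        data = np.full((32, 32, 3), 20.0)
        offs = np.argwhere(img.support) - np.array(img.center)
        data[offs[:, 0] + 16, offs[:, 1] + 16, 1] = img.values[img.support]
        cand = CandidateRecord(center=(16, 16, 1), shape="circle", R=10.0, similarity=1.0)
        q_ave, _ = gray_features(Volume(data=data), cand)
        assert q_ave == pytest.approx(img.values[img.support].mean())

    def test_support_outside_volume_rejected(self):
        vol = Volume(data=np.zeros((10, 10, 3)))
        cand = CandidateRecord(center=(1, 1, 1), shape="circle", R=5.0, similarity=1.0)
        with pytest.raises(ValueError):
            gray_features(vol, cand)


class TestFitLCG:
    def test_single_gaussian_recovery(self):
        x = np.random.default_rng(5).normal(5, 1, 2000)
        m = fit_lcg(x, n_pos=1, n_neg=0)
        assert abs(m.means[0] - 5) < 0.1
        assert abs(m.sigmas[0] - 1) < 0.1
        assert m.weights[0] == pytest.approx(1.0)

    def test_bimodal_mean_recovery(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(2, 1, 2000), rng.normal(8, 1, 2000)])
        m = fit_lcg(x, n_pos=2, n_neg=0)
        assert sorted(m.means) == pytest.approx([2, 8], abs=0.2)

    def test_positive_phase_loglik_non_decreasing(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(4, 1, 500)])
        m = fit_lcg(x, n_pos=2, n_neg=0)
        ll = np.asarray(m.positive_phase_loglik)
        assert np.all(np.diff(ll) >= -1e-8)

    def test_density_invariants_with_negative_component(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(2, 1, 1500), rng.normal(8, 1, 1500)])
        m = fit_lcg(x, n_pos=2, n_neg=1)
        assert m.weights.sum() == pytest.approx(1.0)
        grid = np.linspace(*m.eval_range, 4001)
        pdf = m.pdf(grid)
        assert pdf.min() >= -1e-6
        assert np.trapezoid(pdf, grid) == pytest.approx(1.0, abs=0.02)

    def test_matches_reference_mixture_em(self):
        """With no negative components the fit coincides with a standard
        Gaussian-mixture EM (sklearn as independent reference)."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(2, 1, 1000), rng.normal(8, 1, 1000)])
        mine = fit_lcg(x, n_pos=2, n_neg=0)
        ref = GaussianMixture(
            2,
            means_init=np.quantile(x, [0.25, 0.75]).reshape(-1, 1),
            weights_init=[0.5, 0.5],
            precisions_init=[[[1 / x.var()]], [[1 / x.var()]]],
            tol=1e-8, max_iter=1000, reg_covar=1e-10,
        ).fit(x.reshape(-1, 1))
        assert mine.positive_phase_loglik[-1] / len(x) == pytest.approx(
            ref.score(x.reshape(-1, 1)), abs=1e-3
        )

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_lcg(np.full(100, 3.0), n_pos=1, n_neg=0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_lcg([1.0, 2.0, 3.0], n_pos=2, n_neg=1)


def _delta_density(value_at_point, point):
    """Single Gaussian whose pdf at ``point`` (its mean) equals ``value_at_point``."""
    sigma = 1.0 / (value_at_point * np.sqrt(2 * np.pi))
    return LCGDensity(weights=np.array([1.0]), means=np.array([point]),
                      sigmas=np.array([sigma]), n_pos=1, n_neg=0,
                      eval_range=(point - 5 * sigma, point + 5 * sigma))


class TestClassify:
    def test_hand_computed_posterior(self):
        # TPN density 0.2 and FPN density 0.05 on each of three features
        pt = {"U": 1.0, "q_ave": 100.0, "q_10": 50.0}
        model = NoduleBayesModel(densities={
            "TPN_lung": {f: _delta_density(0.2, v) for f, v in pt.items()},
            "FPN": {f: _delta_density(0.05, v) for f, v in pt.items()},
        })
        label, post = classify((1.0, 100.0, 50.0), model)
        assert label == "TPN"
        assert post == pytest.approx(0.2**3 / (0.2**3 + 0.05**3), abs=1e-9)
        assert post == pytest.approx(0.9846, abs=1e-3)

    def test_tie_resolves_to_fpn(self):
        pt = {"U": 1.0, "q_ave": 100.0, "q_10": 50.0}
        model = NoduleBayesModel(densities={
            "TPN_lung": {f: _delta_density(0.1, v) for f, v in pt.items()},
            "FPN": {f: _delta_density(0.1, v) for f, v in pt.items()},
        })
        label, post = classify((1.0, 100.0, 50.0), model)
        assert post == pytest.approx(0.5)
        assert label == "FPN"

    def test_label_swap_flips_posterior(self):
        train = make_feature_training_set(20, seed=1)
        lung = train.labels != "TPN_wall"
        ts = TrainingSet(samples=train.samples[lung], labels=train.labels[lung])
        swapped_labels = np.where(ts.labels == "FPN", "TPN_lung", "FPN")
        ts_swap = TrainingSet(samples=ts.samples, labels=swapped_labels)
        m1 = train_classifier(ts, seed=2)
        m2 = train_classifier(ts_swap, seed=2)
        for feats in [(1.5, 120.0, 70.0), (9.0, 80.0, 30.0), (5.0, 100.0, 50.0)]:
            _, p1 = classify(feats, m1)
            _, p2 = classify(feats, m2)
            assert p1 == pytest.approx(1 - p2, abs=1e-6)

    def test_posterior_bounded(self):
        model = train_classifier(make_feature_training_set(20, seed=3), seed=3)
        rng = np.random.default_rng(4)
        for _ in range(50):
            feats = (rng.uniform(0, 20), rng.uniform(0, 255), rng.uniform(0, 255))
            _, post = classify(feats, model, wall_nodule=bool(rng.integers(2)))
            assert 0.0 <= post <= 1.0


class TestTrainClassifier:
    def test_wall_class_uses_exactly_two_features(self):
        model = train_classifier(make_feature_training_set(20, seed=3), seed=3)
        assert set(model.densities["TPN_wall"]) == {"q_ave", "q_10"}
        assert set(model.densities["TPN_lung"]) == {"U", "q_ave", "q_10"}
        assert set(model.densities["FPN"]) == {"U", "q_ave", "q_10"}

    def test_deterministic_per_seed(self):
        train = make_feature_training_set(20, seed=3)
        m1 = train_classifier(train, seed=5)
        m2 = train_classifier(train, seed=5)
        for cls in m1.densities:
            for feat in m1.densities[cls]:
                assert np.array_equal(m1.densities[cls][feat].weights,
                                      m2.densities[cls][feat].weights)

    def test_undersized_class_rejected(self):
        ts = TrainingSet(samples=np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]]),
                         labels=np.array(["FPN", "TPN_lung"], dtype=object))
        with pytest.raises(ValueError):
            train_classifier(ts)

    def test_json_round_trip(self, tmp_path):
        model = train_classifier(make_feature_training_set(20, seed=3), seed=3)
        p = tmp_path / "model.json"
        model.to_json(p)
        back = NoduleBayesModel.from_json(p)
        x = np.linspace(0, 255, 100)
        for cls in model.densities:
            for feat in model.densities[cls]:
                assert model.densities[cls][feat].pdf(x) == pytest.approx(
                    back.densities[cls][feat].pdf(x)
                )
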