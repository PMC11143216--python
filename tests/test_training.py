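"""Joint ML training: objective, exact gradients, determinism, ablation."""

import numpy as np
import pytest

from tavrisk.core import complete_log_joint, fit_prior
from tavrisk.evaluation import auroc
from tavrisk.synthetic import (MissingnessSpec, generate_cohort,
                               impose_missingness, make_true_params)
from tavrisk.training import (
    ParamPacker,
    TrainConfig,
    fit_model,
    fit_without_auxiliary,
    objective_and_grad,
    prepare_data,
    training_objective,
)

FAST = dict(lr=0.05, batch_size=10**6, max_epochs=120, patience=15)


class TestObjective:
    def test_single_complete_row_is_negative_complete_log_joint(
            self, masked_cohort):
        truth, complete, _ = masked_cohort
        one = complete.subset([0])
        obj = training_objective(one, truth.params, truth.prior)
        assert obj == pytest.approx(
            -complete_log_joint(complete.row(0), truth.params, truth.prior,
                                truth.schema), abs=1e-12)

    def test_duplicating_the_batch_leaves_the_mean_unchanged(
            self, masked_cohort):
        truth, _, masked = masked_cohort
        batch = masked.subset(np.arange(30))
        twice = masked.subset(np.concatenate([np.arange(30), np.arange(30)]))
        prior = truth.prior
        a = training_objective(batch, truth.params, prior)
        b = training_objective(twice, truth.params, prior)
        assert a == pytest.approx(b, abs=1e-12)

    def test_complex_step_gradient_matches_central_differences(
            self, masked_cohort):
        """Exactness of the complex-step gradient on a mixed-missingness
        batch, every probabilistic parameter."""
        truth, _, masked = masked_cohort
        batch = masked.subset(np.arange(14))
        prior = fit_prior(batch.A, batch.A_mask, truth.schema)
        data = prepare_data(batch, True, prior)
        packer = ParamPacker(4, 3, 3, include_aux=True)
        theta = packer.pack(truth.params)
        _, grad = objective_and_grad(theta, packer, prior, data)
        h = 1e-5
        for p in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[p] += h
            tm[p] -= h
            vp = training_objective(data, packer.unpack(tp), prior)
            vm = training_objective(data, packer.unpack(tm), prior)
            fd = (vp - vm) / (2 * h)
            assert grad[p] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_likelihood_dominance_at_the_generative_truth(self):
        """On a large complete sample, the truth parameters beat 20 random
        perturbations of themselves."""
        truth = make_true_params(4, 3, 2, effect_scale=1.0, seed=21)
        cohort = generate_cohort(truth, 4000, seed=22)
        base = training_objective(cohort, truth.params, truth.prior)
        rng = np.random.default_rng(23)
        packer = ParamPacker(4, 3, 2, include_aux=True)
        theta = packer.pack(truth.params)
        for _ in range(20):
            pert = theta + rng.normal(0, 0.15, theta.size)
            assert training_objective(cohort, packer.unpack(pert),
                                      truth.prior) > base


class TestFitModel:
    def test_best_so_far_training_objective_is_monotone(self, masked_cohort):
        truth, _, masked = masked_cohort
        tr = masked.subset(np.arange(250))
        va = masked.subset(np.arange(250, 330))
        res = fit_model(tr, va, TrainConfig(seed=0, **FAST))
        best = np.minimum.accumulate(res.train_trace)
        assert np.all(np.diff(best) <= 1e-12)

    def test_same_seed_gives_bitwise_identical_traces(self, masked_cohort):
        truth, _, masked = masked_cohort
        tr = masked.subset(np.arange(200))
        va = masked.subset(np.arange(200, 260))
        r1 = fit_model(tr, va, TrainConfig(seed=7, **FAST))
        r2 = fit_model(tr, va, TrainConfig(seed=7, **FAST))
        np.testing.assert_array_equal(r1.train_trace, r2.train_trace)
        np.testing.assert_array_equal(r1.val_trace, r2.val_trace)
        np.testing.assert_array_equal(r1.params.beta, r2.params.beta)

    def test_non_finite_objective_reports_offending_rows(self, masked_cohort):
        truth, _, masked = masked_cohort
        tr = masked.subset(np.arange(50)).copy()
        # a corrupt feature vector (features are not rescaled) blows up the
        # Gaussian term and must be reported by row id
        img_row = int(np.where(tr.has_image)[0][0])
        tr.F[img_row, :] = 1e200
        va = masked.subset(np.arange(50, 80))
        with pytest.raises(FloatingPointError, match="row ids"):
            fit_model(tr, va, TrainConfig(seed=0, **FAST))

    def test_scaler_and_prior_never_see_validation_rows(self, masked_cohort):
        """Leakage check: permuting validation covariates must leave the
        training trace unchanged."""
        truth, _, masked = masked_cohort
        tr = masked.subset(np.arange(200))
        va = masked.subset(np.arange(200, 260))
        r1 = fit_model(tr, va, TrainConfig(seed=1, **FAST))
        va2 = va.copy()
        rng = np.random.default_rng(0)
        va2.A = va2.A[rng.permutation(va2.n)]
        va2.A_mask = np.ones_like(va2.A_mask)
        va2.A = np.nan_to_num(va2.A)
        r2 = fit_model(tr, va2, TrainConfig(seed=1, **FAST))
        n = min(len(r1.train_trace), len(r2.train_trace))
        np.testing.assert_array_equal(r1.train_trace[:2], r2.train_trace[:2])


class TestAblation:
    def test_ablated_model_never_consults_measurements(self, masked_cohort):
        """Predictions are invariant to J even for missing-image rows."""
        truth, _, masked = masked_cohort
        tr = masked.subset(np.arange(250))
        va = masked.subset(np.arange(250, 330))
        res = fit_without_auxiliary(tr, va, TrainConfig(seed=2, **FAST))
        te = masked.subset(np.arange(330, 400))
        p1 = res.predict(te)
        te2 = te.copy()
        te2.J = np.nan_to_num(te2.J) + 3.0
        p2 = res.predict(te2)
        np.testing.assert_array_equal(p1, p2)

    def test_zero_measurement_dims_make_ablation_vacuous(self):
        truth = make_true_params(4, 2, 0, effect_scale=1.0, seed=30)
        cohort = generate_cohort(truth, 200, seed=31)
        masked = impose_missingness(cohort,
                                    MissingnessSpec(image_rate=0.4), seed=32)
        tr = masked.subset(np.arange(150))
        va = masked.subset(np.arange(150, 200))
        cfg = TrainConfig(seed=3, **FAST)
        full = fit_model(tr, va, cfg)
        ablat = fit_without_auxiliary(tr, va, cfg)
        np.testing.assert_array_equal(full.train_trace, ablat.train_trace)
        np.testing.assert_allclose(full.params.beta, ablat.params.beta)


class TestJointBackboneTraining:
    def test_planted_image_signal_improves_heldout_auroc(self):
        """End to end: tube phantoms whose band radii encode outcome-relevant
        features; training the tiny backbone jointly lifts held-out AUROC
        over the tabular-only fit (single demonstrative seed, scaled small)."""
        from tavrisk.backbone import TinyBackbone, ChunkCompressor
        from tavrisk.roi import extract_roi, ROIConfig
        from tavrisk.synthetic import PhantomConfig, link_features_to_phantom
        from tavrisk.backbone import preprocess_intensities

        rng = np.random.default_rng(40)
        n, d_A, d_f = 360, 2, 16
        truth = make_true_params(d_A, d_f, 1, effect_scale=0.0, seed=41)
        A = rng.normal(size=(n, d_A))
        f_true = rng.uniform(-2.0, 2.0, size=(n, d_f))
        alpha_I = np.zeros(d_f)
        alpha_I[:4] = 1.2  # outcome driven by the first four radii bands
        logits = f_true @ alpha_I - 0.3 * A[:, 0]
        y = rng.binomial(1, 1 / (1 + np.exp(-logits)))

        cfg_ph = PhantomConfig(shape=(48, 48, 64), spacing=1.0, noise_sd=5.0,
                               base_radius_mm=8.0, radius_scale_mm=1.5,
                               feature_range=2.5)
        rois = []
        for i in range(n):
            vol, lms, _ = link_features_to_phantom(f_true[i], cfg_ph, seed=i)
            roi = extract_roi(vol, lms, ROIConfig(in_plane_spacing_mm=0.75))
            rois.append(roi.intensities)

        from tavrisk.schema import Cohort
        J = np.zeros((n, 0))
        cohort = Cohort(truth.schema, A, np.ones_like(A, bool), J,
                        np.ones((n, 0), bool), np.ones(n, bool), None, y)
        idx = rng.permutation(n)
        tr, va, te = idx[:250], idx[250:290], idx[290:]

        bb = TinyBackbone(embed_dim=32, seed=42, scale=0.3)
        comp = ChunkCompressor.init(32, d_f, scale=0.3, seed=43)
        cfg = TrainConfig(lr=0.05, lr_backbone=0.05, batch_size=10**6,
                          max_epochs=250, patience=40, seed=44)
        res_img = fit_model(cohort.subset(tr), cohort.subset(va), cfg,
                            backbone=bb, compressor=comp,
                            images_train=[rois[i] for i in tr],
                            images_val=[rois[i] for i in va])
        # tabular-only reference
        res_tab = fit_model(cohort.without_images().subset(tr),
                            cohort.without_images().subset(va),
                            TrainConfig(lr=0.05, batch_size=10**6,
                                        max_epochs=150, patience=20,
                                        seed=44), d_f=2)
        # score the test rows
        te_cohort = cohort.subset(te)
        from tavrisk.backbone import chunk_compress
        pooled = np.stack([TinyBackbone.pool(preprocess_intensities(rois[i]))
                           for i in te])
        F_te = chunk_compress(pooled @ res_img.backbone.W.T,
                              res_img.compressor)
        te_img = te_cohort.copy()
        te_img.F = F_te
        a_img = auroc(res_img.predict(te_img), te_cohort.y)
        a_tab = auroc(res_tab.predict(te_cohort.without_images()),
                      te_cohort.y)
        assert a_img > a_tab
        assert a_img > 0.6
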