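import numpy as np
import pytest

from protonsct.volume import ImageVolume
from protonsct.mi import MIConfig
from protonsct.gan import (
    GeneratorConfig, DiscriminatorConfig, TrainConfig,
    normalize, denormalize, HU_OFFSET,
    build_generator, build_discriminator,
    discriminator_loss, generator_loss,
    MISynthesisGAN, crossval_split,
)


class TestNormalization:
    def test_ct_offset_and_scale(self):
        ct = ImageVolume(np.array([[[-1000.0, 0.0, 2000.0]]]))
        unit, scale = normalize(ct, offset=HU_OFFSET)
        assert scale == pytest.approx(3000.0)
        assert unit.min() == 0.0 and unit.max() == 1.0

    def test_mri_divides_by_max(self):
        mri = ImageVolume(np.array([[[0.0, 400.0, 800.0]]]))
        unit, scale = normalize(mri)
        assert scale == pytest.approx(800.0)
        assert np.allclose(unit, [[[0.0, 0.5, 1.0]]])

    def test_roundtrip_on_phantom_ct(self, sample):
        unit, scale = normalize(sample.ct, offset=HU_OFFSET)
        back = denormalize(unit, scale, offset=HU_OFFSET)
        assert np.abs(back - sample.ct.data).max() < 1e-3

    def test_zeros_denormalize_to_air(self):
        assert denormalize(np.zeros(3), 3000.0, offset=HU_OFFSET).max() == pytest.approx(-1000.0)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="dynamic range"):
            normalize(ImageVolume(np.full((1, 2, 2), 5.0)))

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            denormalize(np.zeros(3), 0.0)


class TestGeneratorNetwork:
    def test_output_shape_matches_input(self, rng):
        gen = build_generator(GeneratorConfig(input_size=64, depth=3), rng=rng)
        x = rng.random((2, 1, 64, 64))
        assert gen.forward(x).shape == x.shape

    def test_output_in_unit_interval(self, rng):
        gen = build_generator(GeneratorConfig(), rng=rng)
        y = gen.forward(rng.normal(0, 10, (1, 1, 64, 64)))
        assert y.min() >= 0.0 and y.max() <= 1.0

    def test_parameter_count_increases_with_base_filters(self):
        def count(bf):
            gen = build_generator(GeneratorConfig(base_filters=bf))
            return sum(p.v.size for p in gen.params())
        assert count(8) > count(4)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            GeneratorConfig(input_size=60, depth=3).validate()


class TestDiscriminatorNetwork:
    def test_scalar_output_in_unit_interval(self, rng):
        disc = build_discriminator(DiscriminatorConfig(), rng=rng)
        y = disc.forward(rng.random((3, 1, 64, 64)))
        assert y.shape == (3, 1)
        assert (y >= 0).all() and (y <= 1).all()

    def test_paper_scale_input_accepted(self, rng):
        disc = build_discriminator(DiscriminatorConfig(input_size=352), rng=rng)
        y = disc.forward(rng.random((1, 1, 352, 352)))
        assert y.shape == (1, 1)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            DiscriminatorConfig(input_size=32).validate()


class TestLosses:
    def test_perfect_discriminator_loss_near_zero(self):
        eps = 1e-9
        assert discriminator_loss(np.array([1 - eps]), np.array([eps])) < 1e-6

    def test_uninformative_discriminator_analytic(self):
        val = discriminator_loss(np.array([0.5]), np.array([0.5]))
        assert val == pytest.approx(2 * np.log(2), abs=1e-9)

    def test_batch_mean_equals_per_item_mean(self, rng):
        dr = rng.uniform(0.1, 0.9, 8)
        df = rng.uniform(0.1, 0.9, 8)
        per_item = [discriminator_loss(np.array([a]), np.array([b])) for a, b in zip(dr, df)]
        assert discriminator_loss(dr, df) == pytest.approx(np.mean(per_item))

    def test_generator_loss_identity_pure_mi(self, rng):
        cfg = TrainConfig(adversarial_weight=0.0)
        a = rng.uniform(0.05, 0.95, (1, 32, 32))
        val = generator_loss(a, a, np.array([0.5]), cfg)
        from protonsct.mi import mi_training_loss
        assert val == pytest.approx(mi_training_loss(a[0], a[0], MIConfig()))
        assert val < 0  # -MI of a self-matched pair

    def test_generator_loss_pure_adversarial_analytic(self, rng):
        cfg = TrainConfig(mi_weight=1e-12, adversarial_weight=1.0)
        a = rng.uniform(0, 1, (1, 16, 16))
        val = generator_loss(a, a, np.array([0.5]), cfg)
        assert val == pytest.approx(np.log(2), abs=1e-6)

    def test_weighted_terms_additive(self, rng):
        a = rng.uniform(0.05, 0.95, (1, 16, 16))
        b = rng.uniform(0.05, 0.95, (1, 16, 16))
        d = np.array([0.3])
        both = generator_loss(a, b, d, TrainConfig(mi_weight=2.0, adversarial_weight=3.0))
        mi_only = generator_loss(a, b, d, TrainConfig(mi_weight=2.0, adversarial_weight=0.0))
        adv_only = generator_loss(a, b, d, TrainConfig(mi_weight=1e-300, adversarial_weight=3.0))
        assert both == pytest.approx(mi_only + adv_only, rel=1e-9)


class TestCrossValidationProtocol:
    def test_77_subject_split_counts(self):
        """The clinical protocol: 77 subjects -> 66 development + 11 held
        out; each fold trains on 54 and validates on 12."""
        split = crossval_split(77, k=5, holdout_fraction=0.15, train_fraction=0.70, seed=0)
        assert len(split.holdout) == 11
        assert split.n_development == 66
        for trn, val in split.folds:
            assert len(trn) == 54
            assert len(val) == 12

    def test_validation_folds_disjoint(self):
        split = crossval_split(77, seed=3)
        seen = set()
        for _, val in split.folds:
            vs = set(val.tolist())
            assert not vs & seen
            seen |= vs

    def test_holdout_isolated_from_folds(self):
        split = crossval_split(77, seed=1)
        hold = set(split.holdout.tolist())
        for trn, val in split.folds:
            assert not hold & set(trn.tolist())
            assert not hold & set(val.tolist())

    def test_too_small_cohort_raises(self):
        with pytest.raises(ValueError, match="small"):
            crossval_split(6, k=5)

    def test_seeded_and_deterministic(self):
        a = crossval_split(40, k=2, seed=9)
        b = crossval_split(40, k=2, seed=9)
        assert np.array_equal(a.holdout, b.holdout)


class TestTrainingMechanics:
    """Cheap training contracts; the full learning property lives in the
    acceptance suite."""

    @pytest.fixture(scope="class")
    def tiny_cohort(self, spec):
        from protonsct.phantom import make_cohort
        return make_cohort(spec, 4, seed=55)

    def test_same_seed_identical_history(self, tiny_cohort):
        cfg = TrainConfig.phantom_scale(epochs=2, seed=3)
        mi_cfg = MIConfig(n_bins=16)
        h1 = MISynthesisGAN(tiny_cohort, mi_cfg=mi_cfg).fit(cfg).loss_history
        h2 = MISynthesisGAN(tiny_cohort, mi_cfg=mi_cfg).fit(cfg).loss_history
        assert h1 == h2

    def test_pure_mi_mode_runs_without_divergence(self, tiny_cohort):
        cfg = TrainConfig.phantom_scale(epochs=2, seed=1, adversarial_weight=0.0)
        res = MISynthesisGAN(tiny_cohort, mi_cfg=MIConfig(n_bins=16)).fit(cfg)
        assert all(np.isfinite(v) for v in res.loss_history["g_loss"])
        assert all(v == 0.0 for v in res.loss_history["g_adv"])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            MISynthesisGAN([])

    def test_prediction_properties(self, tiny_cohort):
        cfg = TrainConfig.phantom_scale(epochs=1, seed=2)
        res = MISynthesisGAN(tiny_cohort, mi_cfg=MIConfig(n_bins=16)).fit(cfg)
        mri = tiny_cohort[0].mri
        sct1 = res.predict_sct(mri)
        sct2 = res.predict_sct(mri)
        assert np.array_equal(sct1.data, sct2.data)  # no dropout at inference
        assert sct1.data.min() >= -1000.0
        assert sct1.data.max() <= res.normalization_scale - 1000.0

    def test_results_roundtrip_via_disk(self, tiny_cohort, tmp_path):
        from protonsct.gan import SynthesisResults
        cfg = TrainConfig.phantom_scale(epochs=1, seed=4)
        res = MISynthesisGAN(tiny_cohort, mi_cfg=MIConfig(n_bins=16)).fit(cfg)
        res.save(tmp_path / "model")
        again = SynthesisResults.load(tmp_path / "model")
        mri = tiny_cohort[0].mri
        assert np.allclose(again.predict_sct(mri).data, res.predict_sct(mri).data)
        assert again.normalization_scale == res.normalization_scale

    def test_crossvalidate_selects_lowest_validation_loss(self, spec):
        from protonsct.phantom import make_cohort
        from protonsct.gan import crossvalidate
        cohort = make_cohort(spec, 12, seed=77)
        cv = crossvalidate(cohort, k=2, train_cfg=TrainConfig.phantom_scale(epochs=1, seed=5),
                           mi_cfg=MIConfig(n_bins=16))
        assert len(cv.fold_results) == 2
        assert cv.selected_fold == int(np.argmin(cv.fold_val_losses))
        assert cv.selected is cv.fold_results[cv.selected_fold]
        assert "fold" in cv.summary()

    def test_summary_mentions_configuration(self, tiny_cohort):
        cfg = TrainConfig.phantom_scale(epochs=1, seed=0)
        res = MISynthesisGAN(tiny_cohort, mi_cfg=MIConfig(n_bins=16)).fit(cfg)
        text = res.summary()
        assert "U-Net" in text and "normalization scale" in text
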