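import json
import math

import numpy as np
import pytest

from fundusvqa.core_types import AnswerLabel, QuestionType, validate_manifest
from fundusvqa.synthgen import (
    BACKGROUND,
    RETINA_BASE,
    BalanceError,
    Lesion,
    SynthConfig,
    SynthScene,
    derive_answer,
    disk_mask,
    generate_dataset,
    preset,
    question_text,
    render_image,
    sample_scene,
)


def make_scene(lesions, fovea_radius=4.0, macula_radius=9.0, noise_sd=0.0, gain=1.0):
    return SynthScene(
        image_size=(64, 64),
        retina_center=(32.0, 32.0),
        retina_radius=29.0,
        disc_center=(32.0, 14.0),
        disc_radius=4.0,
        fovea_center=(32.0, 40.0),
        fovea_radius=fovea_radius,
        macula_radius=macula_radius,
        lesions=lesions,
        noise_sd=noise_sd,
        illumination_gain=gain,
        noise_seed=99,
    )


class TestSceneSampling:
    def test_same_seed_gives_identical_scenes(self):
        cfg = SynthConfig(seed=5)
        s1 = sample_scene(cfg, np.random.Generator(np.random.PCG64(11)))
        s2 = sample_scene(cfg, np.random.Generator(np.random.PCG64(11)))
        assert s1.to_dict() == s2.to_dict()

    def test_scene_invariants_hold(self):
        cfg = SynthConfig()
        rng = np.random.Generator(np.random.PCG64(3))
        for _ in range(200):
            s = sample_scene(cfg, rng)
            assert s.fovea_radius <= s.macula_radius < s.retina_radius
            for les in s.lesions:
                d = math.hypot(
                    les.center[0] - s.retina_center[0],
                    les.center[1] - s.retina_center[1],
                )
                assert d <= s.retina_radius

    def test_zero_lesion_count_distribution(self):
        cfg = SynthConfig(lesion_count={"kind": "fixed", "n": 0})
        s = sample_scene(cfg, np.random.Generator(np.random.PCG64(0)))
        assert s.lesions == []

    def test_lesion_count_mean_matches_configured_distribution(self):
        cfg = SynthConfig(lesion_count={"kind": "poisson", "mean": 2.0})
        rng = np.random.Generator(np.random.PCG64(42))
        counts = [len(sample_scene(cfg, rng).lesions) for _ in range(10_000)]
        se = math.sqrt(2.0 / len(counts))  # Poisson variance = mean
        assert abs(np.mean(counts) - 2.0) < 3 * se

    def test_infeasible_geometry_is_a_configuration_error(self):
        cfg = SynthConfig(fovea_radius_frac=(0.5, 0.6), macula_scale=(2.0, 2.4))
        with pytest.raises(ValueError, match="infeasible"):
            sample_scene(cfg, np.random.Generator(np.random.PCG64(0)))


class TestRendering:
    def test_image_stays_in_unit_interval(self):
        cfg = SynthConfig()
        rng = np.random.Generator(np.random.PCG64(8))
        for _ in range(10):
            img, masks = render_image(sample_scene(cfg, rng))
            assert img.min() >= 0.0 and img.max() <= 1.0
            for m in masks:
                assert set(np.unique(m)) <= {0, 1}

    def test_clean_render_levels(self):
        scene = make_scene([], noise_sd=0.0, gain=1.0)
        img, _ = render_image(scene)
        img = img[:, :, 0]
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        outside = (rr - 32) ** 2 + (cc - 32) ** 2 > 29.0**2
        np.testing.assert_allclose(img[outside], BACKGROUND)
        # away from the disc and fovea, the retina sits at its base level
        assert abs(img[10, 32] - RETINA_BASE) < 0.02

    def test_lesion_center_at_least_retina_base(self):
        scene = make_scene([Lesion((20.0, 32.0), 3.0, 0.9)], noise_sd=0.0)
        img, _ = render_image(scene)
        assert img[20, 32, 0] >= RETINA_BASE
        assert img[20, 32, 0] == pytest.approx(0.9, abs=0.05)

    def test_render_is_deterministic_with_noise(self):
        scene = make_scene([Lesion((20.0, 32.0), 3.0, 0.9)], noise_sd=0.02)
        img1, _ = render_image(scene)
        img2, _ = render_image(scene)
        np.testing.assert_array_equal(img1, img2)


class TestAnswerDerivation:
    def test_empty_scene(self):
        s = make_scene([])
        assert derive_answer(s, QuestionType.WHOLE) is AnswerLabel.NO
        assert derive_answer(s, QuestionType.GRADE) is AnswerLabel.GRADE_0
        assert derive_answer(s, QuestionType.FOVEA) is AnswerLabel.NO

    def test_lesion_at_fovea_center_is_grade_2(self):
        s = make_scene([Lesion((32.0, 40.0), 2.0, 0.9)])
        assert derive_answer(s, QuestionType.GRADE) is AnswerLabel.GRADE_2
        assert derive_answer(s, QuestionType.FOVEA) is AnswerLabel.YES

    def test_peripheral_lesion_is_grade_1(self):
        # strictly outside the macula disk (center (32,40), radius 9)
        s = make_scene([Lesion((32.0, 12.0), 2.0, 0.9)])
        assert derive_answer(s, QuestionType.GRADE) is AnswerLabel.GRADE_1
        assert derive_answer(s, QuestionType.FOVEA) is AnswerLabel.NO

    def test_region_answers_follow_mask_overlap(self):
        s = make_scene([Lesion((20.0, 20.0), 2.0, 0.9)])
        hit = disk_mask((64, 64), (20.0, 20.0), 5.0).astype(np.uint8)
        miss = disk_mask((64, 64), (45.0, 45.0), 5.0).astype(np.uint8)
        assert derive_answer(s, QuestionType.REGION, hit) is AnswerLabel.YES
        assert derive_answer(s, QuestionType.REGION, miss) is AnswerLabel.NO

    def test_region_without_mask_is_a_contract_error(self):
        with pytest.raises(ValueError):
            derive_answer(make_scene([]), QuestionType.REGION)
        with pytest.raises(ValueError):
            derive_answer(make_scene([]), QuestionType.WHOLE, np.ones((64, 64)))

    def test_macula_covering_retina_forces_grade_2(self):
        # degenerate limit: any lesion-bearing scene must grade 2
        rng = np.random.Generator(np.random.PCG64(21))
        cfg = SynthConfig()
        for _ in range(50):
            s = sample_scene(cfg, rng)
            s.macula_radius = s.retina_radius - 1e-6
            if s.lesions:
                assert derive_answer(s, QuestionType.GRADE) is AnswerLabel.GRADE_2


class TestQuestionTemplates:
    @pytest.mark.parametrize(
        "qtype,text",
        [
            (QuestionType.WHOLE, "Are there hard exudates in this image?"),
            (QuestionType.REGION, "Are there hard exudates in the region?"),
            (QuestionType.FOVEA, "Are there hard exudates in the fovea?"),
            (QuestionType.GRADE, "What is the diabetic macular edema grade for this image?"),
        ],
    )
    def test_templates(self, qtype, text):
        assert question_text(qtype) == text


class TestDatasetGeneration:
    def test_counts_match_config_exactly(self, tiny_dataset):
        manifest = tiny_dataset["manifest"]
        counts = manifest.counts()
        assert counts["train"]["n"]["total"] == 80
        assert counts["val"]["n"]["total"] == 20
        # uniform type mix: 20 per type in the 80-sample train split
        assert all(v == 20 for v in counts["train"]["question_type"].values())

    def test_same_config_and_seed_byte_identical(self, tmp_path):
        cfg = SynthConfig(
            n_samples={"train": 24, "val": 8, "test": 8}, image_size=(32, 32), seed=13
        )
        generate_dataset(cfg, tmp_path / "a")
        generate_dataset(cfg, tmp_path / "b")
        for name in ("manifest.jsonl", "scenes.jsonl"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        img = next((tmp_path / "a" / "images").glob("*.png")).name
        assert (tmp_path / "a" / "images" / img).read_bytes() == (
            tmp_path / "b" / "images" / img
        ).read_bytes()

    def test_generated_manifest_validates(self, tiny_dataset):
        assert validate_manifest(tiny_dataset["manifest"]) == []

    def test_answers_reproducible_from_stored_scenes(self, tiny_dataset):
        """Re-deriving every answer from the scene sidecar matches the manifest."""
        scenes = {}
        with open(tiny_dataset["dir"] / "scenes.jsonl") as fh:
            for line in fh:
                entry = json.loads(line)
                scenes[entry["id"]] = SynthScene.from_dict(entry["scene"])
        from fundusvqa.core_types import read_mask

        for rec in tiny_dataset["manifest"].records:
            scene = scenes[rec.id]
            mask = None
            if rec.mask_path is not None:
                mask = read_mask(tiny_dataset["dir"] / rec.mask_path)
            assert derive_answer(scene, rec.question_type, mask) is rec.answer

    def test_answer_balance_converges_to_targets(self, tmp_path):
        cfg = SynthConfig(
            n_samples={"train": 2000, "val": 0, "test": 0}, image_size=(32, 32), seed=3
        )
        manifest = generate_dataset(cfg, tmp_path / "bal")
        rows = manifest.split("train")
        for qtype, targets in cfg.answer_balance.items():
            sub = [r for r in rows if r.question_type is qtype]
            for answer, target in targets.items():
                freq = sum(r.answer is answer for r in sub) / len(sub)
                assert abs(freq - target) <= 0.03

    def test_dme_like_train_region_share(self, tmp_path):
        cfg = preset("dme-like", seed=9, n_samples={"train": 700, "val": 0, "test": 0})
        cfg.image_size = (32, 32)
        manifest = generate_dataset(cfg, tmp_path / "dme")
        rows = manifest.split("train")
        share = sum(r.question_type is QuestionType.REGION for r in rows) / len(rows)
        assert abs(share - 8498 / 9779) <= 0.01

    def test_infeasible_balance_raises_named_error(self, tmp_path):
        cfg = SynthConfig(
            n_samples={"train": 8, "val": 0, "test": 0},
            type_mix={QuestionType.FOVEA: 1.0},
            answer_balance={
                QuestionType.FOVEA: {AnswerLabel.YES: 1.0, AnswerLabel.NO: 0.0}
            },
            lesion_count={"kind": "fixed", "n": 0},  # no lesions -> YES impossible
            image_size=(32, 32),
            max_attempts=5,
            seed=1,
        )
        with pytest.raises(BalanceError, match="fovea"):
            generate_dataset(cfg, tmp_path / "bad")
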