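"""Pseudo-population decoding: construction counts, SVM behavior, controls,
ablation, and determinism."""

import dataclasses

import numpy as np
import pytest

from mbondecode.config import DecodingConfig, GeneratorConfig
from mbondecode.decoding import (
    AnimalSample,
    DecodingError,
    ablate_and_decode,
    bootstrap_training_vectors,
    build_animal_samples,
    draw_test_split,
    fit_predict_model,
    relabel_control,
    run_decoding,
)
from mbondecode.pipeline import quantified_experiment
from tests.helpers import replicate_decoding_means, trained_samples

MBONS = ("g1", "g2", "g3", "g4", "g5")


def make_samples(rng, n_per_type=10, g1_gap=0.0):
    """Samples with iid standard-normal features; optionally separate the
    two classes on the γ1 feature by ``g1_gap``."""
    out = []
    for m in MBONS:
        for i in range(n_per_type):
            plus = rng.normal() - (g1_gap if m == "g1" else 0.0)
            out.append(
                AnimalSample(f"{m}_f{i}", m, plus, rng.normal(), "post", "paired")
            )
    return out


class TestSampleConstruction:
    def test_default_experiment_yields_50_samples(self, default_aucs):
        samples = build_animal_samples(default_aucs, "post", "paired")
        assert len(samples) == 50
        assert all(np.isfinite([s.auc_csplus, s.auc_csminus]).all()
                   for s in samples)

    def test_fly_missing_one_role_excluded(self, default_aucs, caplog):
        trimmed = default_aucs[
            ~(
                (default_aucs.fly_id == "paired_g1_f000")
                & (default_aucs.cs_role == "CSminus")
                & (default_aucs.phase == "post")
            )
        ]
        with caplog.at_level("WARNING"):
            samples = build_animal_samples(trimmed, "post", "paired")
        assert len(samples) == 49
        assert "excluded" in caplog.text

    def test_nonresponder_g5_flies_are_kept(self, default_aucs):
        samples = build_animal_samples(default_aucs, "post", "paired")
        assert sum(s.mbon_type == "g5" for s in samples) == 10

    def test_missing_mbon_type_errors(self, default_aucs):
        no_g3 = default_aucs[
            ~((default_aucs.mbon_type == "g3") & (default_aucs.phase == "post"))
        ]
        with pytest.raises(DecodingError, match="g3"):
            build_animal_samples(no_g3, "post", "paired")


class TestSplitAndBootstrap:
    def test_split_leaves_45_of_50(self):
        samples = make_samples(np.random.default_rng(0))
        (tp, tm), pool = draw_test_split(samples, np.random.default_rng(1))
        assert len(pool) == 45
        assert tp.shape == tm.shape == (5,)

    def test_split_with_two_per_type(self):
        samples = make_samples(np.random.default_rng(0), n_per_type=2)
        _, pool = draw_test_split(samples, np.random.default_rng(1))
        assert len(pool) == 5

    def test_split_deterministic(self):
        samples = make_samples(np.random.default_rng(0))
        a = draw_test_split(samples, np.random.default_rng(3))
        b = draw_test_split(samples, np.random.default_rng(3))
        assert np.array_equal(a[0][0], b[0][0])
        assert [s.fly_id for s in a[1]] == [s.fly_id for s in b[1]]

    def test_bootstrap_vector_count(self):
        samples = make_samples(np.random.default_rng(0))
        _, pool = draw_test_split(samples, np.random.default_rng(1))
        X, y = bootstrap_training_vectors(pool, 1000, np.random.default_rng(2))
        assert X.shape == (2000, 5)
        assert (y == 1).sum() == (y == -1).sum() == 1000

    def test_single_draw(self):
        samples = make_samples(np.random.default_rng(0))
        X, y = bootstrap_training_vectors(samples, 1, np.random.default_rng(2))
        assert X.shape == (2, 5) and set(y) == {1, -1}

    def test_degenerate_pool_of_one_per_type(self):
        samples = make_samples(np.random.default_rng(0), n_per_type=1)
        X, _ = bootstrap_training_vectors(samples, 50, np.random.default_rng(2))
        assert np.allclose(X[:50], X[0])  # every CS+ vector identical

    def test_missing_type_in_pool_errors(self):
        samples = [s for s in make_samples(np.random.default_rng(0))
                   if s.mbon_type != "g2"]
        with pytest.raises(DecodingError, match="g2"):
            bootstrap_training_vectors(samples, 10, np.random.default_rng(2))


class TestFitPredict:
    def test_separable_feature_matches_centroid_oracle(self):
        # γ1 feature 0 for CS+ and 1 for CS−, everything else identical:
        # both the SVM and a nearest-centroid oracle must score 100%
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, (10, 5))
        X = np.vstack([base.copy(), base.copy()])
        X[:10, 0] = 0.0
        X[10:, 0] = 1.0
        y = np.array([1] * 10 + [-1] * 10)
        test_pair = (np.array([0.0, 0, 0, 0, 0]), np.array([1.0, 0, 0, 0, 0]))
        acc = fit_predict_model(X, y, test_pair)
        centroid_plus = X[:10].mean(axis=0)
        centroid_minus = X[10:].mean(axis=0)

        def centroid_label(v):
            return (1 if np.linalg.norm(v - centroid_plus)
                    < np.linalg.norm(v - centroid_minus) else -1)

        oracle = 50 * (int(centroid_label(test_pair[0]) == 1)
                       + int(centroid_label(test_pair[1]) == -1))
        assert acc == oracle == 100

    def test_random_labels_score_at_chance(self):
        # 400 fresh single models on label-free features: binomial mean 50%
        rng = np.random.default_rng(1)
        accs = []
        for _ in range(400):
            X = rng.normal(0, 1, (40, 5))
            y = np.array([1] * 20 + [-1] * 20)
            test_pair = (rng.normal(0, 1, 5), rng.normal(0, 1, 5))
            accs.append(fit_predict_model(X, y, test_pair))
        assert set(accs) <= {0, 50, 100}
        assert abs(np.mean(accs) - 50) <= 5

    def test_single_class_training_errors(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        with pytest.raises(DecodingError, match="single class"):
            fit_predict_model(X, np.ones(10, int),
                              (np.zeros(5), np.zeros(5)))


class TestRunDecoding:
    def test_fixed_seed_reproducible(self):
        samples = make_samples(np.random.default_rng(0), g1_gap=1.0)
        cfg = DecodingConfig(seed=11, n_models=10, n_bootstrap_draws=50)
        a = run_decoding(samples, cfg)
        b = run_decoding(samples, cfg)
        assert a.per_model_accuracy == b.per_model_accuracy
        assert a.mean_accuracy == b.mean_accuracy
        assert a.chance_test_p == b.chance_test_p

    def test_extending_n_models_preserves_prefix(self):
        samples = make_samples(np.random.default_rng(0), g1_gap=1.0)
        short = run_decoding(
            samples, DecodingConfig(seed=11, n_models=5, n_bootstrap_draws=50)
        )
        long = run_decoding(
            samples, DecodingConfig(seed=11, n_models=10, n_bootstrap_draws=50)
        )
        assert long.per_model_accuracy[:5] == short.per_model_accuracy

    def test_accuracy_support(self):
        samples = make_samples(np.random.default_rng(2))
        res = run_decoding(
            samples, DecodingConfig(seed=0, n_models=20, n_bootstrap_draws=30)
        )
        assert set(res.per_model_accuracy) <= {0, 50, 100}
        assert 0 <= res.mean_accuracy <= 100

    def test_trained_condition_beats_chance(self):
        means = replicate_decoding_means(
            4, 400, trained_samples, n_models=50, n_draws=300
        )
        assert means.mean() > 58

    def test_null_generator_decodes_at_chance(self):
        # all plasticity ratios 1: grand mean over 20 replicate experiments
        def null_samples(aucs, seed):
            return build_animal_samples(aucs, "post", "paired")

        means = []
        for i in range(20):
            cfg = GeneratorConfig(seed=600 + i, plasticity={})
            aucs = quantified_experiment(cfg)
            dcfg = DecodingConfig(seed=600 + i, n_models=25,
                                  n_bootstrap_draws=200)
            means.append(run_decoding(null_samples(aucs, 0), dcfg).mean_accuracy)
        assert 45 <= np.mean(means) <= 55

    def test_label_permutation_destroys_accuracy(self):
        # swapping each fly's CS+/CS− assignment at random is the
        # label-symmetry null: grand mean at chance despite real plasticity
        def permuted(aucs, seed):
            rng = np.random.default_rng(10_000 + seed)
            out = []
            for s in build_animal_samples(aucs, "post", "paired"):
                if rng.random() < 0.5:
                    s = dataclasses.replace(
                        s, auc_csplus=s.auc_csminus, auc_csminus=s.auc_csplus
                    )
                out.append(s)
            return out

        means = replicate_decoding_means(
            20, 700, permuted, n_models=25, n_draws=200
        )
        assert 45 <= means.mean() <= 55

    def test_stronger_suppression_never_hurts(self):
        # expected accuracy is non-decreasing in the distance of the γ1
        # CS+ ratio from 1 (small slack for sampling error)
        grand = {}
        for mult in (1.0, 0.7, 0.4):
            means = []
            for i in range(50):
                cfg = GeneratorConfig(
                    seed=2000 + i,
                    plasticity={("paired", "g1", "CSplus"): mult},
                )
                aucs = quantified_experiment(cfg)
                dcfg = DecodingConfig(seed=2000 + i, n_models=25,
                                      n_bootstrap_draws=200)
                samples = build_animal_samples(aucs, "post", "paired")
                means.append(run_decoding(samples, dcfg).mean_accuracy)
            grand[mult] = np.mean(means)
        assert grand[0.7] >= grand[1.0] - 4
        assert grand[0.4] >= grand[0.7] - 4
        assert grand[0.4] > grand[1.0]


class TestRelabelControl:
    def test_pretraining_requires_pre_phase(self, default_aucs):
        post = build_animal_samples(default_aucs, "post", "paired")
        with pytest.raises(DecodingError, match="pre-phase"):
            relabel_control(post, "pretraining")

    def test_mode_protocol_mismatch_errors(self, default_aucs):
        paired = build_animal_samples(default_aucs, "post", "paired")
        with pytest.raises(DecodingError, match="odor_only"):
            relabel_control(paired, "odor_only", np.random.default_rng(0))

    def test_random_relabel_reproducible(self, default_aucs):
        ctrl = build_animal_samples(default_aucs, "post", "odor_only")
        a = relabel_control(ctrl, "odor_only", np.random.default_rng(5))
        b = relabel_control(ctrl, "odor_only", np.random.default_rng(5))
        assert a == b
        # some pairs swapped, some not
        swapped = [x.auc_csplus != y.auc_csplus for x, y in zip(a, ctrl)]
        assert any(swapped) and not all(swapped)


class TestAblation:
    def test_five_results_with_four_features(self, default_aucs):
        samples = build_animal_samples(default_aucs, "post", "paired")
        cfg = DecodingConfig(seed=1, n_models=5, n_bootstrap_draws=30)
        results = ablate_and_decode(samples, cfg)
        assert set(results) == set(MBONS)
        for excluded, res in results.items():
            assert len(res.config.included_mbons) == 4
            assert excluded not in res.config.included_mbons

    def test_ablation_deterministic(self, default_aucs):
        samples = build_animal_samples(default_aucs, "post", "paired")
        cfg = DecodingConfig(seed=1, n_models=5, n_bootstrap_draws=30)
        a = ablate_and_decode(samples, cfg)
        b = ablate_and_decode(samples, cfg)
        assert all(a[m].per_model_accuracy == b[m].per_model_accuracy
                   for m in MBONS)

    def test_too_few_types_errors(self):
        samples = make_samples(np.random.default_rng(0))
        cfg = DecodingConfig(seed=0, included_mbons=("g1", "g2"))
        with pytest.raises(DecodingError, match=">= 2"):
            ablate_and_decode(samples, cfg)
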