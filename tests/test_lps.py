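import math

import numpy as np
import pandas as pd
import pytest

from suvarness.io import ExpressionMatrix
from suvarness.lps import (
    LPSModel,
    MulticlassLPSModel,
    UNCLASSIFIED,
    band_tis_scores,
    classify,
    classify_tis_responders,
    fit_lps,
    fit_lps_multiclass,
    lps_score,
    posterior,
    tenfold_cv,
)
from suvarness.simulate import CohortConfig, generate_cohort


def make_model(mu1=0.0, mu2=4.0, sd1=1.0, sd2=1.0, priors=(0.5, 0.5), cut=0.9):
    return LPSModel(
        classifier_genes=("g1",),
        weights=np.array([1.0]),
        classes=("pos", "neg"),
        means={"pos": mu1, "neg": mu2},
        sds={"pos": sd1, "neg": sd2},
        priors={"pos": priors[0], "neg": priors[1]},
        confidence_cut=cut,
    )


def bayes_oracle(model, s):
    """Direct density evaluation of Bayes' rule, independent of the
    log-space implementation."""
    dens = {}
    for k in model.classes:
        mu, sd, pi = model.means[k], model.sds[k], model.priors[k]
        dens[k] = pi * math.exp(-((s - mu) ** 2) / (2 * sd**2)) / (sd * math.sqrt(2 * math.pi))
    total = sum(dens.values())
    return {k: v / total for k, v in dens.items()}


def three_class_cohort(effect=3.0, n_per=15, seed=5, n_genes=90):
    """Three groups, each with its own planted up-block."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    groups = ["C1"] * n_per + ["C2"] * n_per + ["C3"] * n_per
    samples = [f"s{i}" for i in range(len(groups))]
    values = rng.normal(0, 1, size=(n_genes, len(groups)))
    block = n_genes // 9
    for ci, g in enumerate(("C1", "C2", "C3")):
        rows = slice(ci * block, (ci + 1) * block)
        cols = [j for j, lab in enumerate(groups) if lab == g]
        values[rows, :][:, cols] += effect
    m = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    return m, pd.Series(groups, index=samples)


class TestPosterior:
    def test_matches_bayes_oracle_on_random_models(self, rng):
        for _ in range(1000):
            mu1, gap = rng.normal(0, 5), rng.uniform(0.2, 6)
            sd1, sd2 = rng.uniform(0.3, 3, size=2)
            pi = rng.uniform(0.1, 0.9)
            model = make_model(mu1, mu1 + gap, sd1, sd2, (pi, 1 - pi))
            s = rng.normal(mu1 + gap / 2, 3 * max(sd1, sd2))
            got = posterior(model, s)
            want = bayes_oracle(model, s)
            for k in model.classes:
                assert got[k] == pytest.approx(want[k], abs=1e-12)

    def test_midpoint_symmetry(self):
        model = make_model(0.0, 4.0)
        p = posterior(model, 2.0)
        assert p["pos"] == pytest.approx(0.5, abs=1e-12)

    def test_four_sigma_separation_value(self):
        # s = mu1 with mu2 = mu1 + 4 sd: P = phi(0) / (phi(0) + phi(4))
        from scipy.stats import norm

        model = make_model(0.0, 4.0)
        expected = norm.pdf(0) / (norm.pdf(0) + norm.pdf(4))
        assert posterior(model, 0.0)["pos"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9996646, abs=1e-7)

    def test_probabilities_sum_to_one(self, rng):
        model = make_model(1.0, 3.0, 0.7, 1.5, (0.3, 0.7))
        s = rng.normal(2, 10, size=10_000)
        frame = posterior(model, s)
        assert np.allclose(frame.sum(axis=1), 1.0, atol=1e-12)

    def test_extreme_scores_stay_finite(self):
        model = make_model(0.0, 4.0)
        p = posterior(model, 1e4)
        assert p["neg"] == pytest.approx(1.0)


class TestLpsScore:
    def test_linearity_and_zero_weights(self):
        m = ExpressionMatrix(pd.DataFrame([[1.5, 3.0]], index=["g1"], columns=["a", "b"]))
        model = make_model()
        model.weights = np.array([2.0])
        s = lps_score(model, m)
        assert np.array_equal(s.to_numpy(), [3.0, 6.0])  # weight*expr; doubling doubles
        model.weights = np.array([0.0])
        assert np.array_equal(lps_score(model, m).to_numpy(), [0.0, 0.0])

    def test_missing_gene_errors_unless_imputed(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0]], index=["other"], columns=["a"]))
        model = make_model()
        model.gene_means = {"g1": 5.0}
        with pytest.raises(KeyError):
            lps_score(model, m)
        s = lps_score(model, m, impute_missing=True)
        assert s.to_numpy()[0] == 5.0

    def test_zero_weight_gene_leaves_scores_unchanged(self, two_group_cohort):
        m = two_group_cohort.expression
        labels = two_group_cohort.annotation["outcome_group"]
        model = fit_lps(m, labels, n_genes=10)
        base = lps_score(model, m)
        extended = LPSModel(
            classifier_genes=model.classifier_genes + (m.gene_ids[-1],),
            weights=np.append(model.weights, 0.0),
            classes=model.classes,
            means=model.means,
            sds=model.sds,
            priors=model.priors,
            confidence_cut=model.confidence_cut,
        )
        assert np.allclose(lps_score(extended, m).to_numpy(), base.to_numpy())


class TestFitLps:
    def test_separated_classes_training_accuracy(self, two_group_cohort):
        m = two_group_cohort.expression
        labels = two_group_cohort.annotation["outcome_group"]
        model = fit_lps(m, labels, n_genes=15)
        calls = classify(model, m, confidence_cut=0.5001)["call"]
        accuracy = (calls == labels).mean()
        assert accuracy >= 0.95

    def test_refit_is_deterministic(self, two_group_cohort):
        m = two_group_cohort.expression
        labels = two_group_cohort.annotation["outcome_group"]
        m1 = fit_lps(m, labels, n_genes=10)
        m2 = fit_lps(m, labels, n_genes=10)
        assert m1.to_dict() == m2.to_dict()

    def test_small_class_rejected(self):
        m = ExpressionMatrix(
            pd.DataFrame(np.random.default_rng(0).normal(size=(5, 5)),
                         index=list("abcde"), columns=[f"s{i}" for i in range(5)])
        )
        labels = pd.Series(["A", "A", "B", "B", "B"], index=m.sample_ids)
        with pytest.raises(ValueError, match="at least 3"):
            fit_lps(m, labels, n_genes=2)

    def test_serialization_round_trip(self, two_group_cohort, tmp_path):
        m = two_group_cohort.expression
        model = fit_lps(m, two_group_cohort.annotation["outcome_group"], n_genes=8)
        path = tmp_path / "model.json"
        model.save(path)
        back = LPSModel.load(path)
        assert back.to_dict() == model.to_dict()
        assert np.allclose(lps_score(back, m), lps_score(model, m))


class TestClassify:
    def test_confidence_band(self):
        model = make_model(0.0, 4.0, cut=0.9)
        m = ExpressionMatrix(
            pd.DataFrame([[0.0, 2.0]], index=["g1"], columns=["sure", "middle"])
        )
        calls = classify(model, m)
        assert calls.loc["sure", "call"] == "pos"
        assert calls.loc["middle", "call"] == UNCLASSIFIED

    def test_argmax_cut_never_unclassifies_two_class(self, rng):
        model = make_model(0.0, 1.0, cut=0.9)
        m = ExpressionMatrix(
            pd.DataFrame(rng.normal(0.5, 2, size=(1, 50)), index=["g1"],
                         columns=[f"s{i}" for i in range(50)])
        )
        calls = classify(model, m, confidence_cut=0.5)
        assert (calls["call"] != UNCLASSIFIED).all()

    def test_posterior_calibration_on_model_draws(self, rng):
        # draw scores from the fitted two-Gaussian mixture; within each
        # posterior decile the empirical class-1 fraction tracks the midpoint
        model = make_model(0.0, 2.0)
        n = 40_000
        z = rng.random(n) < 0.5
        s = np.where(z, rng.normal(0.0, 1.0, n), rng.normal(2.0, 1.0, n))
        p = posterior(model, s)["pos"].to_numpy()
        for lo in np.arange(0.0, 1.0, 0.1):
            mask = (p >= lo) & (p < lo + 0.1)
            if mask.sum() < 200:
                continue
            assert abs(z[mask].mean() - p[mask].mean()) < 0.05


class TestMulticlass:
    def test_separated_three_classes_recovered(self):
        m, labels = three_class_cohort(effect=3.0)
        model = fit_lps_multiclass(m, labels, n_genes_per_class=10)
        calls = classify(model, m, confidence_cut=0.34)["call"]
        assert (calls == labels).mean() >= 0.9

    def test_permuted_labels_held_out_accuracy_near_chance(self):
        m, labels = three_class_cohort(effect=3.0, seed=6, n_per=30)
        rng = np.random.default_rng(0)
        perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        train = rng.random(len(perm)) < 2 / 3
        model = fit_lps_multiclass(
            m.subset_samples(np.asarray(m.sample_ids)[train]),
            perm[train], n_genes_per_class=10,
        )
        test_ids = np.asarray(m.sample_ids)[~train]
        calls = classify(model, m.subset_samples(test_ids), confidence_cut=0.34)["call"]
        acc = (calls.to_numpy() == perm[~train].to_numpy()).mean()
        assert abs(acc - 1 / 3) < 0.25

    def test_class_centroid_sample_wins(self):
        m, labels = three_class_cohort(effect=4.0, seed=8)
        model = fit_lps_multiclass(m, labels, n_genes_per_class=10)
        centroid = m.data.loc[:, (labels == "C2").to_numpy()].mean(axis=1)
        probe = ExpressionMatrix(centroid.to_frame("probe"))
        calls = classify(model, probe, confidence_cut=0.34)
        assert calls.loc["probe", "call"] == "C2"

    def test_serialization_round_trip(self, tmp_path):
        m, labels = three_class_cohort()
        model = fit_lps_multiclass(m, labels, n_genes_per_class=5)
        path = tmp_path / "mc.json"
        model.save(path)
        assert MulticlassLPSModel.load(path).to_dict() == model.to_dict()


class TestTenfoldCv:
    def test_separable_data_perfect_accuracy(self, two_group_cohort):
        acc, table = tenfold_cv(
            two_group_cohort.expression,
            two_group_cohort.annotation["outcome_group"],
            n_genes=15, seed=1,
        )
        assert acc == 1.0
        assert table["n_test"].sum() == 40

    def test_same_seed_reproduces_folds_and_accuracy(self, two_group_cohort):
        args = (two_group_cohort.expression, two_group_cohort.annotation["outcome_group"])
        acc1, t1 = tenfold_cv(*args, n_genes=10, seed=3)
        acc2, t2 = tenfold_cv(*args, n_genes=10, seed=3)
        assert acc1 == acc2
        assert t1.equals(t2)

    def test_small_class_shrinks_fold_count(self, caplog):
        cohort = generate_cohort(
            CohortConfig(n_genes=40, n_samples_per_group={"A": 6, "B": 6},
                         n_signature_genes=10, effect_size=3.0, seed=2)
        )
        with caplog.at_level("WARNING"):
            _, table = tenfold_cv(
                cohort.expression, cohort.annotation["outcome_group"],
                n_genes=5, folds=10, seed=1,
            )
        assert len(table) == 6
        assert "folds" in caplog.text


class TestTisBanding:
    def test_band_rules_including_exact_boundaries(self):
        calls = band_tis_scores(np.array([0.85, 0.5, 0.8, 0.2, 0.15]))
        assert list(calls) == [
            "responder", UNCLASSIFIED, UNCLASSIFIED, UNCLASSIFIED, "non_responder"
        ]

    def test_classifier_scores_banded(self, two_group_cohort):
        m = two_group_cohort.expression
        labels = two_group_cohort.annotation["outcome_group"]
        model = fit_lps(m, labels, n_genes=15)
        calls = classify_tis_responders(model, m)
        # group A is the first class -> its samples should be responders
        in_a = (labels == "A").to_numpy()
        assert (calls.loc[in_a, "call"] == "responder").mean() > 0.9
        assert (calls.loc[~in_a, "call"] == "non_responder").mean() > 0.9
        assert calls["tis_score"].between(0, 1).all()
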