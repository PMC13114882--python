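"""Gated fusion, loss, stratified folds, training loop and site baseline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fmrifuse import nn
from fmrifuse.backbone import BackboneConfig
from fmrifuse.dfc_encoder import DfcEncoderConfig
from fmrifuse.fusion import (
    GatedFusionClassifier,
    classification_loss,
    evaluate_predictions,
    fold_balance_report,
    gated_fuse,
    site_only_baseline,
    stratified_subject_folds,
)


class TestGate:
    def test_beta_zero_is_bitwise_half_half(self, rng):
        for _ in range(100):
            zv, zd = rng.normal(size=(2, 2)) * 10
            fused = gated_fuse(zv, zd, beta=0.0)
            fixed = 0.5 * zv + 0.5 * zd
            np.testing.assert_array_equal(fused, fixed)

    def test_large_beta_saturates_to_voxel_branch(self, rng):
        zv, zd = rng.normal(size=(2, 4))
        np.testing.assert_allclose(gated_fuse(zv, zd, beta=30.0), zv, atol=1e-9)

    def test_beta_ln3_gives_three_quarter_weight(self):
        zv, zd = np.array([4.0, 0.0]), np.array([0.0, 4.0])
        np.testing.assert_allclose(gated_fuse(zv, zd, np.log(3.0)),
                                   [3.0, 1.0], atol=1e-12)

    def test_gate_monotone_and_bounded(self):
        betas = np.linspace(-20, 20, 101)
        alphas = 1.0 / (1.0 + np.exp(-betas))
        assert np.all((alphas > 0) & (alphas < 1))
        assert np.all(np.diff(alphas) > 0)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shapes differ"):
            gated_fuse(np.zeros(2), np.zeros(3), 0.0)


class TestLoss:
    def test_uninformative_logits_give_ln2(self):
        assert classification_loss([0.0, 0.0], [1.0, 0.0]) == pytest.approx(
            np.log(2.0), abs=1e-12)

    def test_saturated_logits_near_zero_loss(self):
        assert classification_loss([30.0, -30.0], [1.0, 0.0]) < 1e-12

    def test_closed_form_value(self):
        # -ln(e / (e + 1))
        expected = -np.log(np.e / (np.e + 1.0))
        assert classification_loss([1.0, 0.0], [1.0, 0.0]) == pytest.approx(
            expected, abs=1e-12)

    def test_positivity_and_batch_mean(self, rng):
        z = rng.normal(size=(8, 2))
        y = np.eye(2)[rng.integers(0, 2, 8)]
        total = classification_loss(z, y)
        assert total > 0
        per = np.mean([classification_loss(z[i], y[i]) for i in range(8)])
        assert total == pytest.approx(per, rel=1e-12)


class TestBranchLogits:
    def test_hand_set_weights(self):
        head = nn.Linear(2, 2, np.random.default_rng(0))
        head.weight.data = np.array([[1.0, 3.0], [2.0, 4.0]])  # x @ W
        head.bias.data[:] = 0.0
        z = head(nn.Tensor([[1.0, 1.0]])).data
        np.testing.assert_array_equal(z, [[3.0, 7.0]])

    def test_zero_weights_zero_logits(self):
        head = nn.Linear(3, 2, np.random.default_rng(0))
        head.weight.data[:] = 0.0
        head.bias.data[:] = 0.0
        np.testing.assert_array_equal(head(nn.Tensor([[1.0, -2.0, 5.0]])).data,
                                      [[0.0, 0.0]])


def make_pheno(n_per_stratum: dict[tuple[str, str], int]) -> pd.DataFrame:
    rows = []
    i = 0
    for (dx, site), n in n_per_stratum.items():
        for _ in range(n):
            rows.append({"subject_id": f"s{i:03d}", "diagnosis": dx,
                         "site_id": site, "sex": "M", "age": 10.0 + i,
                         "fiq": 100.0 + i, "eye_status": "Open"})
            i += 1
    return pd.DataFrame(rows).set_index("subject_id")


class TestFolds:
    def test_balanced_strata_deal_one_each(self):
        pheno = make_pheno({("ASD", "A"): 5, ("ASD", "B"): 5,
                            ("TC", "A"): 5, ("TC", "B"): 5})
        folds = stratified_subject_folds(pheno, 5, seed=3)
        table = pheno.assign(fold=[folds.fold_of_subject[s] for s in pheno.index])
        counts = table.groupby(["diagnosis", "site_id", "fold"]).size()
        assert set(counts.values) == {1}

    def test_round_robin_sizes_for_stratum_of_seven(self):
        pheno = make_pheno({("ASD", "A"): 7})
        folds = stratified_subject_folds(pheno, 5, seed=0)
        sizes = sorted(np.bincount(list(folds.fold_of_subject.values()),
                                   minlength=5), reverse=True)
        assert sizes == [2, 2, 1, 1, 1]

    def test_k_equals_one_puts_all_in_fold_zero(self):
        pheno = make_pheno({("ASD", "A"): 3, ("TC", "A"): 3})
        folds = stratified_subject_folds(pheno, 1, seed=0)
        assert set(folds.fold_of_subject.values()) == {0}

    def test_subject_disjointness_and_seed_determinism(self):
        pheno = make_pheno({("ASD", "A"): 9, ("TC", "B"): 8, ("TC", "A"): 7})
        f1 = stratified_subject_folds(pheno, 4, seed=11)
        f2 = stratified_subject_folds(pheno, 4, seed=11)
        assert f1.fold_of_subject == f2.fold_of_subject
        all_subjects = [s for k in range(4) for s in f1.subjects(k)]
        assert sorted(all_subjects) == sorted(pheno.index)

    def test_k_larger_than_cohort_errors(self):
        with pytest.raises(ValueError, match="invalid"):
            stratified_subject_folds(make_pheno({("ASD", "A"): 2}), 5)


class TestBalanceReport:
    def test_row_sums_conserve_cohort(self):
        pheno = make_pheno({("ASD", "A"): 6, ("TC", "A"): 5, ("TC", "B"): 7})
        folds = stratified_subject_folds(pheno, 3, seed=0)
        report = fold_balance_report(pheno, folds)
        assert report["N"].sum() == len(pheno)
        assert report["ASD"].sum() == 6
        assert report["TC"].sum() == 12
        assert (report["M"] + report["F"]).sum() == len(pheno)

    def test_fiq_validity_filter(self):
        pheno = make_pheno({("ASD", "A"): 4})
        pheno.loc["s000", "fiq"] = -999.0
        pheno.loc["s001", "fiq"] = np.nan
        folds = stratified_subject_folds(pheno, 1, seed=0)
        report = fold_balance_report(pheno, folds)
        assert report.loc[0, "fiq_n"] == 2

    def test_single_fold_equals_cohort_summary(self):
        pheno = make_pheno({("ASD", "A"): 3, ("TC", "B"): 3})
        report = fold_balance_report(pheno, stratified_subject_folds(pheno, 1))
        assert len(report) == 1
        assert report.loc[0, "N"] == 6
        assert report.loc[0, "age_mean"] == pytest.approx(pheno["age"].mean())


class TestMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        m = evaluate_predictions(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert m["Acc"] == 1.0 and m["AUC"] == 1.0

    def test_hand_contingency(self):
        # TP=1, FP=1, TN=1, FN=1
        y = np.array([1, 0, 0, 1])
        prob = np.array([0.9, 0.8, 0.1, 0.2])
        m = evaluate_predictions(y, prob)
        assert m["Acc"] == 0.5 and m["Prec"] == 0.5 and m["F1"] == 0.5

    def test_shuffled_predictions_near_chance(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 2000)
        prob = rng.random(2000)
        m = evaluate_predictions(y, prob)
        assert abs(m["AUC"] - 0.5) < 0.05

    def test_single_class_fold_auc_nan(self):
        with pytest.warns(UserWarning, match="single-class"):
            m = evaluate_predictions(np.ones(4, dtype=int),
                                     np.array([0.6, 0.7, 0.8, 0.9]))
        assert np.isnan(m["AUC"])

    def test_auc_matches_mann_whitney_rank_formula(self, rng):
        """sklearn AUC vs an independent midrank U-statistic."""
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        prob = np.round(rng.random(60), 1)  # ties on purpose
        from scipy.stats import rankdata
        ranks = rankdata(prob)
        n1, n0 = y.sum(), (1 - y).sum()
        u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
        assert evaluate_predictions(y, prob)["AUC"] == pytest.approx(
            u / (n1 * n0), abs=1e-12)


class TestSiteBaseline:
    @staticmethod
    def ratio_pheno(ratios: dict[str, tuple[int, int]]) -> pd.DataFrame:
        strata = {}
        for site, (n_asd, n_tc) in ratios.items():
            strata[("ASD", site)] = n_asd
            strata[("TC", site)] = n_tc
        return make_pheno(strata)

    def test_uninformative_sites_near_chance(self):
        pheno = self.ratio_pheno({"A": (10, 10), "B": (10, 10)})
        folds = stratified_subject_folds(pheno, 4, seed=0)
        metrics = site_only_baseline(pheno, folds, seed=0)
        assert abs(metrics["AUC"].mean() - 0.5) < 0.05
        assert abs(metrics["Acc"].mean() - 0.5) < 0.15

    def test_perfect_site_confound(self):
        pheno = self.ratio_pheno({"A": (12, 0), "B": (0, 12)})
        folds = stratified_subject_folds(pheno, 4, seed=0)
        metrics = site_only_baseline(pheno, folds, seed=0)
        assert metrics["Acc"].mean() > 0.95

    def test_matches_closed_form_rank_auc(self):
        """Site rates 0.8/0.2 vs 0.4/0.6: the classifier's test AUC equals
        the analytic rank AUC of the two-valued site score."""
        pheno = self.ratio_pheno({"A": (24, 6), "B": (12, 18)})
        folds = stratified_subject_folds(pheno, 5, seed=2)
        metrics = site_only_baseline(pheno, folds, seed=0)
        fold_series = pd.Series(folds.fold_of_subject)
        for fold in range(5):
            sub = pheno.loc[fold_series[fold_series == fold].index]
            pos = (sub["diagnosis"] == "ASD")
            a_pos = int((pos & (sub["site_id"] == "A")).sum())
            a_neg = int((~pos & (sub["site_id"] == "A")).sum())
            b_pos = int((pos & (sub["site_id"] == "B")).sum())
            b_neg = int((~pos & (sub["site_id"] == "B")).sum())
            n1, n0 = a_pos + b_pos, a_neg + b_neg
            # score(A) > score(B); same-site pairs tie at 1/2
            closed = (a_pos * b_neg + 0.5 * (a_pos * a_neg + b_pos * b_neg)) / (n1 * n0)
            assert metrics.loc[fold, "AUC"] == pytest.approx(closed, abs=0.02)


@pytest.fixture(scope="module")
def smoke_classifier():
    return GatedFusionClassifier(
        backbone_cfg=BackboneConfig(spatial_patch=(8, 8, 8), temporal_patch=2,
                                    embed_dim=16, depth=2, heads=2,
                                    window_size=(2, 2, 2, 2)),
        dfc_cfg=DfcEncoderConfig(embed_dim=16, fused_dim=16, heads=2),
        clip_side=16, clip_length=8, max_epochs=2, patience=5, lr=1e-3,
        batch_size=4, seed=0)


class TestTraining:
    def test_smoke_run_records_history(self, tiny_dataset, smoke_classifier):
        import copy
        clf = copy.deepcopy(smoke_classifier)
        clf.fit(tiny_dataset.records[:8])
        assert list(clf.history_.columns) == ["epoch", "train_loss", "val_loss"]
        assert len(clf.history_) == 2
        assert np.isfinite(clf.history_.to_numpy()).all()

    def test_fixed_fusion_excludes_beta_from_optimizer(self, tiny_dataset,
                                                       smoke_classifier):
        import copy
        clf = copy.deepcopy(smoke_classifier)
        clf.set_params(mode="fixed_fusion", max_epochs=1)
        clf.fit(tiny_dataset.records[:8])
        assert clf.beta_.data == 0.0 and clf.alpha_ == 0.5
        assert not any(p is clf.beta_ for m in clf._modules()
                       for p in m.parameters())

    def test_zero_lr_leaves_parameters_unchanged(self, tiny_dataset,
                                                 smoke_classifier):
        import copy
        clf = copy.deepcopy(smoke_classifier)
        clf.set_params(lr=0.0, max_epochs=1)
        clf.fit(tiny_dataset.records[:8])
        fresh = copy.deepcopy(smoke_classifier)
        fresh.set_params(lr=0.0, max_epochs=1)
        fresh._build(tiny_dataset.records[:8],
                     np.random.default_rng(np.random.SeedSequence(0).spawn(3)[0]))
        for p, q in zip(clf._trainable(), fresh._trainable()):
            np.testing.assert_array_equal(p.data, q.data)

    def test_single_branch_modes_fit_and_predict(self, tiny_dataset,
                                                 smoke_classifier):
        import copy
        for mode in ("dfc_only", "voxel_only"):
            clf = copy.deepcopy(smoke_classifier)
            clf.set_params(mode=mode, max_epochs=1)
            clf.fit(tiny_dataset.records[:8])
            probs = clf.predict_proba(tiny_dataset.records[8:10])
            assert probs.shape == (2, 2)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_training_is_deterministic_given_seed(self, tiny_dataset,
                                                  smoke_classifier):
        import copy
        outs = []
        for _ in range(2):
            clf = copy.deepcopy(smoke_classifier)
            clf.set_params(max_epochs=1)
            clf.fit(tiny_dataset.records[:8])
            outs.append(clf.predict_proba(tiny_dataset.records[8:10]))
        np.testing.assert_array_equal(outs[0], outs[1])


class TestPrediction:
    def test_subject_aggregation_is_mean_of_clip_logits(self, tiny_dataset,
                                                        smoke_classifier):
        import copy
        clf = copy.deepcopy(smoke_classifier)
        clf.fit(tiny_dataset.records[:8])
        rec = tiny_dataset.records[10]
        probs, per_clip = clf.predict_subject(rec)
        mean_logits = per_clip.mean(axis=0)
        e = np.exp(mean_logits - mean_logits.max())
        np.testing.assert_allclose(probs, e / e.sum(), atol=1e-12)

    def test_hand_averaged_logits(self):
        from fmrifuse.fusion import softmax_probs
        per_clip = np.array([[1.0, 0.0], [0.0, 1.0]])
        probs = softmax_probs(per_clip.mean(axis=0))
        np.testing.assert_allclose(probs, [0.5, 0.5])
        per3 = np.array([[2.0, 0.0], [1.0, 1.0], [0.0, 2.0]])
        np.testing.assert_allclose(softmax_probs(per3.mean(axis=0)),
                                   softmax_probs(np.array([1.0, 1.0])))

    def test_checkpoint_round_trip(self, tmp_path, tiny_dataset,
                                   smoke_classifier):
        import copy
        clf = copy.deepcopy(smoke_classifier)
        clf.fit(tiny_dataset.records[:8])
        clf.save(tmp_path / "model")
        loaded = GatedFusionClassifier.load(tmp_path / "model",
                                            tiny_dataset.records[:8])
        p1 = clf.predict_proba(tiny_dataset.records[8:10])
        p2 = loaded.predict_proba(tiny_dataset.records[8:10])
        np.testing.assert_allclose(p1, p2, atol=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(beta=st.floats(-15, 15), seed=st.integers(0, 10**6))
def test_gate_blend_property(beta, seed):
    """Fused logits always lie between the two branch logits, elementwise."""
    rng = np.random.default_rng(seed)
    zv, zd = rng.normal(size=(2, 2))
    z = gated_fuse(zv, zd, beta)
    lo, hi = np.minimum(zv, zd), np.maximum(zv, zd)
    assert np.all(z >= lo - 1e-12) and np.all(z <= hi + 1e-12)
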