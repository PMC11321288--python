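"""Stage-cluster probabilities, linear probe, review panels, summary table."""

import numpy as np
import pandas as pd
import pytest

from octopheno.annotation import (GRADING_LABELS, cluster_summary_table,
                                  fit_linear_probe, sample_review_panels,
                                  stage_cluster_matrix)


class TestStageClusterMatrix:
    def test_counting_example(self):
        assignments = np.array([1] * 10)
        labels = ["mnv"] * 8 + ["healthy"] * 2
        mat, flagged = stage_cluster_matrix(assignments, labels)
        assert mat.loc[1, "mnv"] == pytest.approx(0.8)
        assert mat.loc[1, "healthy"] == pytest.approx(0.2)
        assert mat.loc[1].drop(["mnv", "healthy"]).sum() == 0
        assert flagged == []

    def test_rows_sum_to_one(self, rng):
        assignments = rng.integers(1, 5, size=200)
        labels = rng.choice(GRADING_LABELS, size=200)
        mat, _ = stage_cluster_matrix(assignments, labels)
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)

    def test_unlabelled_cluster_flagged_not_zero(self):
        assignments = np.array([1, 1, 2, 2])
        labels = ["mnv", "healthy", None, None]
        mat, flagged = stage_cluster_matrix(assignments, labels)
        assert flagged == [2]
        assert mat.loc[2].isna().all()

    def test_unknown_label_rejected_with_value(self):
        with pytest.raises(ValueError, match="not_a_stage"):
            stage_cluster_matrix(np.array([1]), ["not_a_stage"])

    def test_shuffled_labels_converge_to_marginal(self, rng):
        n = 10_000
        marginal = np.array([0.3, 0.3, 0.2, 0.1, 0.1])
        labels = rng.choice(GRADING_LABELS, size=n, p=marginal)
        assignments = rng.integers(1, 5, size=n)  # independent of labels
        mat, _ = stage_cluster_matrix(assignments, labels)
        assert np.all(np.abs(mat.to_numpy(float) - marginal) < 0.05)


class TestLinearProbe:
    def test_separable_blobs_reach_full_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (30, 3)), rng.normal(5, 0.3, (30, 3))])
        y = np.repeat([1, 2], 30)
        probe = fit_linear_probe(X, y)
        assert probe.train_accuracy == 1.0
        assert np.array_equal(probe.predict(X), y)

    def test_permuted_labels_give_chance_accuracy(self, rng):
        k = 4
        X = rng.normal(size=(400, 5))
        y = rng.integers(1, k + 1, size=400)  # labels independent of X
        probe = fit_linear_probe(X, y)
        assert probe.train_accuracy < 1.0 / k + 0.15

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_linear_probe(rng.normal(size=(10, 2)), np.ones(10))


class TestGradCAM:
    @pytest.fixture(scope="class")
    def trained(self):
        from octopheno.augment import AugmentationPolicy
        from octopheno.byol import TrainConfig, extract_features, train_byol
        from octopheno.clustering import assign, kmeans_fit, order_clusters_by_va
        from octopheno.synthetic import CohortConfig, generate_cohort

        cfg = CohortConfig(n_patients=40, visits_per_eye=1, seed=31,
                           classes=("healthy", "atrophy_complete", "scarring"))
        images, visits, truth = generate_cohort(cfg)
        state = train_byol(images, AugmentationPolicy(),
                           TrainConfig(steps=60, batch_size=16, seed=2))
        feats = extract_features(state, images)
        model = kmeans_fit(feats, k=3, seed=0)
        order_clusters_by_va(model, visits["letters"].to_numpy(float))
        ids = assign(feats, model)
        probe = fit_linear_probe(model.transform(feats), ids,
                                 mean=model.mean, sd=model.sd)
        return images, ids, state, probe

    def test_map_contract_shape_range(self, trained):
        from octopheno.annotation import gradcam_attribution

        images, ids, state, probe = trained
        att = gradcam_attribution(state, probe, images[0], int(ids[0]))
        assert att.map.shape == images[0].shape
        assert att.map.min() >= 0.0
        assert att.degenerate or att.map.max() == pytest.approx(1.0)

    def test_zero_probe_row_gives_zero_map(self, trained):
        from octopheno.annotation import gradcam_attribution

        images, ids, state, probe = trained
        import copy

        p0 = copy.deepcopy(probe)
        j = int(np.where(p0.classes == ids[0])[0][0])
        p0.coef[j, :] = 0.0
        with pytest.warns(UserWarning, match="zero"):
            att = gradcam_attribution(state, p0, images[0], int(ids[0]))
        assert att.degenerate and not att.map.any()

    def test_unknown_cluster_rejected(self, trained):
        from octopheno.annotation import gradcam_attribution

        images, _, state, probe = trained
        with pytest.raises(ValueError):
            gradcam_attribution(state, probe, images[0], 999)


class TestPanels:
    def _cohort(self, n_patients, images_per_patient=2):
        pids = np.repeat([f"P{i}" for i in range(n_patients)], images_per_patient)
        return np.ones(len(pids), dtype=int), pids

    def test_twenty_distinct_patients_selected(self):
        assignments, pids = self._cohort(25)
        panels = sample_review_panels(assignments, pids, np.random.default_rng(0))
        p = panels[1]
        chosen = [pids[i] for i in p.seen + p.unseen]
        assert len(chosen) == 20 and len(set(chosen)) == 20
        assert not (set(p.seen) & set(p.unseen))
        assert not p.truncated

    def test_truncation_with_warning(self):
        assignments, pids = self._cohort(12)
        with pytest.warns(UserWarning, match="truncated"):
            panels = sample_review_panels(assignments, pids, np.random.default_rng(0))
        p = panels[1]
        assert len(p.seen) + len(p.unseen) == 12 and p.truncated

    def test_deterministic_given_seed(self):
        assignments, pids = self._cohort(30)
        a = sample_review_panels(assignments, pids, np.random.default_rng(5))
        b = sample_review_panels(assignments, pids, np.random.default_rng(5))
        assert a[1].seen == b[1].seen and a[1].unseen == b[1].unseen


class TestSummaryTable:
    def test_published_style_ratios(self):
        # 310 images / 196 patients -> 1.6 ; 235 / 55 -> 4.3
        assignments = np.array([1] * 310 + [2] * 235)
        pids = ([f"A{i % 196}" for i in range(310)] +
                [f"B{i % 55}" for i in range(235)])
        table = cluster_summary_table(assignments, pids).set_index("cluster")
        assert table.loc[1, "ratio"] == pytest.approx(1.6)
        assert table.loc[2, "ratio"] == pytest.approx(4.3)

    def test_identity_ratio_and_totals(self):
        assignments = np.array([1, 1, 2])
        pids = ["a", "b", "c"]
        table = cluster_summary_table(assignments, pids)
        total = table[table["cluster"] == "total"].iloc[0]
        assert total["n_images"] == 3 and total["n_patients"] == 3
        assert total["ratio"] == pytest.approx(1.0)
        assert table[table["cluster"] != "total"]["n_images"].sum() == 3

    def test_missing_patient_id_rejected(self):
        with pytest.raises(ValueError):
            cluster_summary_table(np.array([1, 1]), pd.Series(["a", None]))
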