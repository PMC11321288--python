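"""Generator contracts: geometry ordering, physical sizes, rendering, cohorts."""

import numpy as np
import pytest

from octopheno.synthetic import (ALL_CLASSES, CLASS_ORDER, VA_BASE, BiomarkerSpec,
                                 CohortConfig, generate_cohort,
                                 generate_retina_layers, plant_biomarker,
                                 render_bscan, um_to_cols)


def geom(seed=0, **kw):
    return generate_retina_layers(64, 64, rng=np.random.default_rng(seed), **kw)


class TestLayers:
    @pytest.mark.parametrize("seed", range(8))
    def test_boundary_ordering_every_column(self, seed):
        g = geom(seed)
        assert np.all(g.ilm < g.rpe) and np.all(g.rpe < g.bm) and np.all(g.bm < g.csi)
        assert g.csi.max() <= g.height

    def test_zero_pit_depth_gives_flat_ilm_offset(self):
        g = generate_retina_layers(64, 64, pit_depth=0.0, undulation=0.0,
                                   rng=np.random.default_rng(0))
        # no pit and no undulation: ILM is a straight (possibly tilted) line
        second_diff = np.diff(g.ilm, 2)
        assert np.allclose(second_diff, 0.0, atol=1e-9)

    def test_determinism(self):
        a = geom(3)
        b = geom(3)
        assert np.array_equal(a.ilm, b.ilm) and np.array_equal(a.csi, b.csi)

    def test_rejects_small_frames(self):
        with pytest.raises(ValueError):
            generate_retina_layers(32, 64)

    def test_physical_width_of_full_scale_frame(self):
        # 256 columns at 23.4 um mediolateral pitch
        assert 256 * 23.4 == pytest.approx(5990.4)


class TestPlanting:
    def test_drusen_63um_mask_is_3_columns(self):
        g = geom(1)
        _, mask = plant_biomarker(g, BiomarkerSpec("drusen_large", 63.0),
                                  np.random.default_rng(0))
        assert mask.any(axis=0).sum() == um_to_cols(63.0) == 3

    def test_healthy_leaves_geometry_unchanged(self):
        g = geom(2)
        g2, mask = plant_biomarker(g, BiomarkerSpec("healthy"), np.random.default_rng(0))
        assert not mask.any()
        assert np.array_equal(g.rpe, g2.rpe) and np.array_equal(g.ilm, g2.ilm)

    def test_atrophy_complete_thins_retina_and_sets_hypertransmission(self):
        g = geom(3)
        g2, mask = plant_biomarker(g, BiomarkerSpec("atrophy_complete", 1000.0),
                                   np.random.default_rng(0))
        cols = mask.any(axis=0)
        assert cols.sum() == um_to_cols(1000.0) == 43
        # RPE elevated (smaller depth) exactly over the lesion columns
        assert np.all(g2.rpe[cols] < g.rpe[cols])
        assert np.array_equal(g2.rpe[~cols], g.rpe[~cols])
        assert np.array_equal(g2.hyper_cols, cols)

    @pytest.mark.parametrize("label", [c for c in ALL_CLASSES if c != "healthy"])
    def test_every_class_preserves_ordering_and_mask_contract(self, label):
        g = geom(4)
        g2, mask = plant_biomarker(g, BiomarkerSpec(label), np.random.default_rng(5))
        g2.validate()
        expect_empty = label in ("healthy", "poor_quality")
        assert mask.any() != expect_empty

    def test_mask_width_roundtrip_exact(self):
        for w_um in (63.0, 250.0, 500.0, 1000.0):
            g = geom(5)
            _, mask = plant_biomarker(g, BiomarkerSpec("atrophy_complete", max(w_um, 250.0)),
                                      np.random.default_rng(1))
            assert mask.any(axis=0).sum() == um_to_cols(max(w_um, 250.0))

    def test_oversized_lesion_rejected(self):
        g = geom(6)
        with pytest.raises(ValueError, match="wider"):
            plant_biomarker(g, BiomarkerSpec("PED", 3000.0), np.random.default_rng(0))

    def test_small_drusen_large_rejected(self):
        with pytest.raises(ValueError, match="63"):
            BiomarkerSpec("drusen_large", 50.0).validate(64)


class TestRender:
    def test_noiseless_render_is_piecewise_constant_at_reflectivities(self):
        g = generate_retina_layers(64, 64, pit_depth=0.0, undulation=0.0,
                                   rng=np.random.default_rng(0))
        img = render_bscan(g, noise=0.0)
        assert set(np.round(np.unique(img), 6)) <= {0.05, 0.45, 0.85, 0.25, 0.12}

    def test_hypertransmission_brightens_choroid_band(self):
        g = geom(7)
        g2, _ = plant_biomarker(g, BiomarkerSpec("atrophy_complete", 800.0),
                                np.random.default_rng(2))
        img = render_bscan(g2, noise=0.0)
        rows = np.arange(g2.height)[:, None]
        band = (rows >= g2.bm[None, :]) & (rows < g2.csi[None, :])
        hyp = g2.hyper_cols[None, :]
        assert img[band & hyp].mean() > img[band & ~hyp].mean()

    def test_fixed_seed_bit_identical(self):
        g = geom(8)
        a = render_bscan(g, noise=0.15, rng=np.random.default_rng(9))
        b = render_bscan(g, noise=0.15, rng=np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_intensity_bounds_under_noise(self):
        g = geom(9)
        img = render_bscan(g, noise=0.5, rng=np.random.default_rng(0),
                           gain_jitter=(0.7, 1.3), offset_jitter=0.1)
        assert img.min() >= 0.0 and img.max() <= 1.0


class TestCohort:
    def test_counts_one_image_per_visit(self):
        cfg = CohortConfig(n_patients=10, eyes_per_patient=1, visits_per_eye=3, seed=0)
        images, visits, truth = generate_cohort(cfg)
        assert images.shape[0] == len(visits) == len(truth.class_labels) == 30

    def test_same_seed_identical_metadata(self):
        cfg = CohortConfig(n_patients=8, seed=5)
        _, v1, _ = generate_cohort(cfg)
        _, v2, _ = generate_cohort(cfg)
        assert v1.equals(v2)

    def test_class_proportions_match_mixture(self):
        # eye-level multinomial check at n = 2000 eyes (one visit to stay fast)
        cfg = CohortConfig(n_patients=2000, visits_per_eye=1, seed=2,
                           image_size=(64, 64))
        _, _, truth = generate_cohort(cfg)
        freq = (np.array([(truth.class_labels == c).mean() for c in cfg.classes]))
        assert np.all(np.abs(freq - 1.0 / len(cfg.classes)) < 0.05)

    def test_mixture_must_sum_to_one(self):
        cfg = CohortConfig(n_patients=5, mixture=(0.5, 0.1, 0.1, 0.1, 0.1, 0.2))
        cfg.mixture = (0.5, 0.1, 0.1, 0.1, 0.1, 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()

    def test_va_bases_strictly_ordered_by_severity(self):
        bases = [VA_BASE[c] for c in CLASS_ORDER]
        assert all(a > b for a, b in zip(bases, bases[1:]))

    def test_mask_nonzero_iff_lesion_class(self, small_cohort):
        _, _, _, truth = small_cohort
        for lbl, mask in zip(truth.class_labels, truth.masks):
            assert mask.any() == (lbl not in ("healthy", "poor_quality"))

    def test_conversion_times_nonnegative(self, small_cohort):
        _, _, _, truth = small_cohort
        assert (truth.conversions[["time_to_mnv", "time_to_crora"]] >= 0).all().all()

    def test_noiseless_nearest_centroid_separates_classes(self):
        # recoverability oracle: class means in pixel space classify perfectly
        cfg = CohortConfig(n_patients=36, visits_per_eye=1, noise=0.0,
                           gain_jitter=(1.0, 1.0), offset_jitter=0.0, seed=3)
        images, _, truth = generate_cohort(cfg)
        X = images.reshape(len(images), -1)
        labels = truth.class_labels
        cents = {c: X[labels == c].mean(axis=0) for c in np.unique(labels)}
        names = list(cents)
        C = np.stack([cents[c] for c in names])
        pred = [names[np.argmin(((C - x) ** 2).sum(axis=1))] for x in X]
        assert (np.array(pred) == labels).mean() == 1.0
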