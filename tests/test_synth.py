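"""Synthetic study generator: determinism, geometry, planted structure."""

import itertools

import numpy as np
import pytest

from lesionfactors.synth import (
    SynthConfig,
    make_atlas,
    make_template,
    sample_cognition,
    sample_disconnection_corpus,
    sample_lesions,
)


class TestTemplate:
    def test_deterministic(self):
        a = make_template(grid_shape=(24, 28, 24), seed=5)
        b = make_template(grid_shape=(24, 28, 24), seed=5)
        np.testing.assert_array_equal(a.brain_mask, b.brain_mask)
        np.testing.assert_array_equal(a.territory_labels, b.territory_labels)
        np.testing.assert_array_equal(a.affine, b.affine)

    def test_ten_territories_nine_lobes(self, template):
        terr = np.unique(template.territory_labels[template.brain_mask])
        lobes = np.unique(template.lobe_labels[template.brain_mask])
        assert set(terr) == set(range(1, 11))
        assert set(lobes) == set(range(1, 10))

    def test_territories_partition_brain(self, template):
        assert np.all((template.territory_labels > 0) == template.brain_mask)

    def test_masks_disjoint(self, template):
        assert not (template.ventricle_mask & template.cortex_mask).any()

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_template(grid_shape=(8, 8, 8))


class TestAtlas:
    def test_cardinality(self, template):
        atlas = make_atlas(template, n_tracts=5, streamlines_per_tract=20, seed=2)
        assert len(atlas) == 5
        assert all(len(t.streamlines) == 20 for t in atlas.tracts)

    def test_points_inside_grid_bbox(self, atlas, template):
        inv = np.linalg.inv(template.affine)
        hi = np.asarray(template.shape) - 1
        for t in atlas.tracts:
            for sl in t.streamlines:
                v = sl.points @ inv[:3, :3].T + inv[:3, 3]
                assert np.all(v >= -1e-9) and np.all(v <= hi + 1e-9)

    def test_deterministic(self, template):
        a = make_atlas(template, 4, 6, seed=3)
        b = make_atlas(template, 4, 6, seed=3)
        for ta, tb in zip(a.tracts, b.tracts):
            assert ta.name == tb.name
            for sa, sb in zip(ta.streamlines, tb.streamlines):
                np.testing.assert_array_equal(sa.points, sb.points)

    def test_too_few_tracts_rejected(self, template):
        with pytest.raises(ValueError):
            make_atlas(template, n_tracts=1)


def _mean_pairwise_dice(masks):
    grids = [m.grid.astype(bool) for m in masks]
    vals = []
    for a, b in itertools.combinations(grids, 2):
        s = a.sum() + b.sum()
        vals.append(2 * (a & b).sum() / s if s else 0.0)
    return float(np.mean(vals))


class TestLesions:
    def test_infarct_overlap_below_wmh_overlap(self, template):
        inf = sample_lesions(template, "infarct", 30, seed=10)
        wmh = sample_lesions(template, "wmh", 30, seed=11)
        assert _mean_pairwise_dice(inf) < _mean_pairwise_dice(wmh)

    def test_wmh_within_rim_distance(self, template):
        from scipy import ndimage

        wmh = sample_lesions(template, "wmh", 10, seed=12, rim_mm=(1.5, 6.0))
        dv = ndimage.distance_transform_edt(~template.ventricle_mask, sampling=template.voxel_mm)
        for m in wmh:
            sel = m.grid.astype(bool)
            assert dv[sel].max() <= 6.0 * 1.3 + 1e-9  # anterior rim widening included

    def test_infarct_avoids_ventricle(self, template):
        inf = sample_lesions(template, "infarct", 20, seed=13)
        for m in inf:
            assert not (m.grid.astype(bool) & template.ventricle_mask).any()

    def test_deterministic(self, template):
        a = sample_lesions(template, "infarct", 5, seed=14)
        b = sample_lesions(template, "infarct", 5, seed=14)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.grid, mb.grid)

    def test_unknown_kind_rejected(self, template):
        with pytest.raises(ValueError):
            sample_lesions(template, "tumour", 3)


class TestCorpus:
    def test_single_factor_degenerate(self):
        cfg = SynthConfig(n_subjects=20, k_true=1, seed=0)
        _, truth = sample_disconnection_corpus(cfg)
        np.testing.assert_allclose(truth.theta_true, 1.0)

    def test_rows_on_simplex(self):
        cfg = SynthConfig(n_subjects=50, seed=1)
        counts, truth = sample_disconnection_corpus(cfg)
        np.testing.assert_allclose(truth.beta_true.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(truth.theta_true.sum(axis=1), 1.0, atol=1e-9)
        assert np.issubdtype(counts.dtype, np.integer)
        assert counts.min() >= 0
        assert np.all(counts.sum(axis=1) == cfg.total_pseudocount)

    def test_column_sums_match_mixture(self):
        """Monte-Carlo: corpus column masses converge to mean mixture rates."""
        cfg = SynthConfig(n_subjects=2000, seed=2)
        counts, truth = sample_disconnection_corpus(cfg)
        expected = (truth.theta_true @ truth.beta_true).mean(axis=0)
        observed = counts.sum(axis=0) / counts.sum()
        # multinomial error at this corpus size is well below 0.01 per tract
        np.testing.assert_allclose(observed, expected, atol=5e-3)

    def test_deterministic(self):
        cfg = SynthConfig(n_subjects=30, seed=3)
        c1, t1 = sample_disconnection_corpus(cfg)
        c2, t2 = sample_disconnection_corpus(cfg)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(t1.theta_true, t2.theta_true)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(k_true=30, n_tracts=24)
        with pytest.raises(ValueError):
            SynthConfig(dirichlet_alpha=0.0)


class TestCognition:
    def test_null_effect_gives_null_slope(self):
        """With no planted effect and no confounds, status is independent
        of the causal loading (logistic slope compatible with zero)."""
        from lesionfactors.association_stats import fit_logistic

        cfg = SynthConfig(
            n_subjects=4000, effect_beta=1e-12, confound_coeffs=(0.0, 0.0), seed=4
        )
        rng = np.random.default_rng(5)
        theta = rng.dirichlet([cfg.dirichlet_alpha] * 3, cfg.n_subjects)
        coh = sample_cognition(theta, cfg, seed=6)
        y = coh["psci_m6"].to_numpy()
        X = np.column_stack([np.ones(len(y)), theta[:, 1]])
        fit = fit_logistic(y, X)
        assert abs(fit.coef[1]) < 3 * fit.se[1]

    def test_planted_effect_raises_top_tertile_rate(self):
        cfg = SynthConfig(n_subjects=2000, seed=7)
        rng = np.random.default_rng(8)
        theta = rng.dirichlet([cfg.dirichlet_alpha] * 3, cfg.n_subjects)
        coh = sample_cognition(theta, cfg, seed=9)
        x = theta[:, cfg.causal_factor_index]
        lo, hi = np.quantile(x, [1 / 3, 2 / 3])
        rate_bottom = coh.loc[x <= lo, "psci_m6"].mean()
        rate_top = coh.loc[x >= hi, "psci_m6"].mean()
        assert rate_top > rate_bottom + 0.1

    def test_prevalence_near_cohort_rates(self):
        cfg = SynthConfig(n_subjects=6000, seed=10)
        rng = np.random.default_rng(11)
        theta = rng.dirichlet([cfg.dirichlet_alpha] * 3, cfg.n_subjects)
        coh = sample_cognition(theta, cfg, seed=12)
        assert coh["psci_m6"].mean() == pytest.approx(0.52, abs=0.05)
        assert coh["psci_m36"].mean() == pytest.approx(0.38, abs=0.05)

    def test_deterministic(self):
        cfg = SynthConfig(n_subjects=40, seed=13)
        rng = np.random.default_rng(14)
        theta = rng.dirichlet([cfg.dirichlet_alpha] * 3, cfg.n_subjects)
        a = sample_cognition(theta, cfg, seed=15)
        b = sample_cognition(theta, cfg, seed=15)
        assert a.equals(b)

    def test_moca_tracks_cognition(self):
        cfg = SynthConfig(n_subjects=3000, seed=16)
        rng = np.random.default_rng(17)
        theta = rng.dirichlet([cfg.dirichlet_alpha] * 3, cfg.n_subjects)
        coh = sample_cognition(theta, cfg, seed=18)
        zbar = coh[[c for c in coh.columns if c.startswith("z_") and c.endswith("m6")]].mean(axis=1)
        assert np.corrcoef(coh["moca"], zbar)[0, 1] > 0.4
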