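import math

import numpy as np
import pytest
from scipy import integrate, stats

from npcgold import (
    AnalysisConfig,
    InsufficientDataError,
    RingModel,
    SimParams,
    bootstrap_interval,
    classify_symmetry,
    estimate_axial,
    estimate_radial,
    fit_ring_model,
    projected_ring_density,
    simulate_gold_particles,
    summarize_localizations,
)
from npcgold.localize import radial_peak, silverman_bandwidth

from conftest import make_set


class TestProjectedRingDensity:
    def test_closed_form_at_center(self):
        assert projected_ring_density(0.0, RingModel(50.0)) == pytest.approx(
            1.0 / (50.0 * math.pi), abs=1e-12
        )

    def test_even_function(self):
        rng = np.random.default_rng(2)
        xs = rng.uniform(-60, 60, 20)
        for model in (RingModel(40.0, 0.0), RingModel(40.0, 7.0)):
            f_pos = projected_ring_density(xs, model)
            f_neg = projected_ring_density(-xs, model)
            np.testing.assert_allclose(f_pos, f_neg, rtol=1e-12)

    def test_unit_mass_vs_quadrature_oracle(self):
        # oracle: scipy adaptive quadrature, independent of the fixed-order
        # Gauss-Legendre evaluation inside the density
        model = RingModel(40.0, 7.0)
        mass, err = integrate.quad(
            lambda x: projected_ring_density(x, model), -150, 150, limit=200
        )
        assert mass == pytest.approx(1.0, abs=1e-6)
        # and the noiseless arcsine integrates to 1 in closed form
        mass0, _ = integrate.quad(
            lambda x: projected_ring_density(x, RingModel(40.0)),
            -40, 40, points=[-40, 40], limit=200,
        )
        assert mass0 == pytest.approx(1.0, abs=1e-6)

    def test_mode_approaches_ring_radius_as_blur_vanishes(self):
        x = np.linspace(0, 60, 6001)
        modes = [
            x[np.argmax(projected_ring_density(x, RingModel(40.0, sd)))]
            for sd in (8.0, 4.0, 2.0, 1.0, 0.25)
        ]
        assert np.all(np.diff(modes) > 0)
        assert modes[-1] == pytest.approx(40.0, abs=0.5)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            RingModel(-1.0)

    def test_degenerate_point_mass_rejected(self):
        with pytest.raises(ValueError):
            projected_ring_density(0.0, RingModel(0.0, 0.0))

    def test_zero_radius_reduces_to_normal(self):
        f = projected_ring_density(3.0, RingModel(0.0, 7.0))
        assert f == pytest.approx(stats.norm.pdf(3.0, scale=7.0), rel=1e-12)


class TestRadialEstimation:
    def test_degenerate_identical_sample(self, fast_cfg):
        ps = make_set([(25.0, 0.0)] * 12 + [(-25.0, 0.0)] * 12)
        r = estimate_radial(ps, fast_cfg)
        assert r == (25.0, 0.0, 24)

    def test_noiseless_ring_peak_vs_histogram_mode_oracle(self, fast_cfg):
        # 50k noiseless projections of a ring R=40; oracle = mode of a
        # 0.5-nm fine histogram of |x|
        ps = simulate_gold_particles(
            SimParams(
                R0_nm=40.0, Z0_nm=0.0, symmetric=True, n_npcs=50,
                epitopes_per_npc=1000, linkage_max_nm=0.0,
                alignment_jitter_sd_nm=0.0, section_thickness_nm=math.inf,
                seed=7,
            ),
            label="ring",
        )
        u = np.abs(ps.x())
        edges = np.arange(0, 45.5, 0.5)
        counts, _ = np.histogram(u, bins=edges)
        oracle_mode = edges[np.argmax(counts)] + 0.25
        peak = radial_peak(u, fast_cfg)
        assert peak == pytest.approx(40.0, abs=2.0)
        assert peak == pytest.approx(oracle_mode, abs=2.0)

    def test_ml_refinement_recovers_radius(self):
        # spec'd recovery: 500 particles, R0=40, blur sd 7, 20 seeds
        errs = []
        for seed in range(20):
            ps = simulate_gold_particles(
                SimParams(
                    R0_nm=40.0, Z0_nm=0.0, symmetric=True,
                    displacement_model="isotropic-normal", displacement_sd_nm=7.0,
                    alignment_jitter_sd_nm=0.0, seed=seed,
                ),
                label="r",
            )
            errs.append(fit_ring_model(ps.x()).R_nm - 40.0)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse <= 3.0

    def test_insufficient_data_carries_count(self, fast_cfg):
        ps = make_set([(10.0, 0.0)] * 4)
        with pytest.raises(InsufficientDataError) as err:
            estimate_radial(ps, fast_cfg)
        assert err.value.count == 4

    def test_radial_window_excludes_far_axial_particles(self, fast_cfg):
        ps = make_set([(30.0, 0.0)] * 12 + [(200.0, 200.0)] * 5)
        r = estimate_radial(ps, fast_cfg)
        assert r.n_r == 12 and r.r_ave_nm == 30.0


class TestSymmetryClassification:
    def test_all_negative_is_nucleoplasmic(self):
        assert classify_symmetry([-1.0] * 20) == "nucleoplasmic"

    def test_balanced_is_symmetric(self):
        assert classify_symmetry([-1.0] * 10 + [1.0] * 10) == "symmetric"

    def test_all_positive_is_cytoplasmic(self):
        assert classify_symmetry([1.0] * 20) == "cytoplasmic"

    def test_all_zero_is_symmetric(self):
        assert classify_symmetry([0.0] * 10) == "symmetric"

    def test_monte_carlo_calibration(self):
        rng = np.random.default_rng(5)
        asym_correct = sum(
            classify_symmetry(-np.abs(rng.normal(40, 7, 30))) == "nucleoplasmic"
            for _ in range(500)
        )
        assert asym_correct == 500
        sym_wrong = sum(
            classify_symmetry(rng.normal(0, 20, 30)) != "symmetric"
            for _ in range(500)
        )
        assert sym_wrong / 500 <= 0.05 + 0.03


class TestAxialEstimation:
    def test_constant_nucleoplasmic_sample(self, fast_cfg):
        # n must be large enough for the exact sign test to be able to
        # reject at alpha=0.05 (the smallest two-sided p at n=3 is 0.25)
        cfg = AnalysisConfig(bootstrap_B=200, min_particles=3)
        ps = make_set([(0.0, -40.0)] * 12)
        z = estimate_axial(ps, cfg)
        assert z.z_ave_nm == -40.0
        assert z.z_err_nm == 0.0
        assert z.symmetry_class == "nucleoplasmic"

    def test_balanced_pair_folds(self):
        cfg = AnalysisConfig(bootstrap_B=200, min_particles=3)
        ps = make_set([(0.0, -30.0), (0.0, 30.0), (0.0, -30.0), (0.0, 30.0)])
        z = estimate_axial(ps, cfg)
        assert z.symmetry_class == "symmetric"
        assert z.z_ave_nm == pytest.approx(30.0)

    def test_folded_mean_identity(self, fast_cfg):
        # for a sample exactly symmetric under z -> -z the folded estimate
        # equals the one-sided mean of the positive half
        pos = np.array([5.0, 12.0, 33.0, 41.0, 27.0, 8.0])
        ps = make_set([(0.0, z) for z in np.concatenate([pos, -pos])])
        z = estimate_axial(ps, fast_cfg, with_error=False)
        assert z.symmetry_class == "symmetric"
        assert z.z_ave_nm == pytest.approx(pos.mean(), rel=1e-12)

    def test_symmetric_offset_recovery(self):
        # folded Z within 3 nm of the true 25 nm offset across 20 seeds
        cfg = AnalysisConfig()
        errs = []
        for seed in range(20):
            ps = simulate_gold_particles(
                SimParams(
                    R0_nm=40.0, Z0_nm=25.0, symmetric=True,
                    displacement_model="isotropic-normal",
                    displacement_sd_nm=7.0, seed=seed,
                ),
                label="s",
            )
            z = estimate_axial(ps, cfg, with_error=False)
            errs.append(z.z_ave_nm - 25.0)
        assert float(np.sqrt(np.mean(np.square(errs)))) <= 3.0


class TestBootstrap:
    def test_constant_sample_zero_width(self):
        lo, hi = bootstrap_interval(np.mean, [4.0] * 30, B=200)
        assert lo == hi == 4.0

    def test_seed_determinism(self):
        sample = np.random.default_rng(3).normal(size=40)
        a = bootstrap_interval(np.mean, sample, B=300, seed=42)
        b = bootstrap_interval(np.mean, sample, B=300, seed=42)
        assert a == b

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_interval(np.mean, [], B=200)

    def test_interval_contains_plug_in_mean(self):
        rng = np.random.default_rng(9)
        for seed in range(10):
            sample = rng.normal(2.0, 1.0, 60)
            lo, hi = bootstrap_interval(np.mean, sample, B=400, seed=seed)
            assert lo <= sample.mean() <= hi


class TestSummaries:
    def test_degenerate_single_protein_row(self, fast_cfg):
        ps = make_set([(25.0, -40.0)] * 15, label="NupX")
        (est,) = summarize_localizations([ps], fast_cfg)
        assert est.nup_label == "NupX"
        assert (est.z_ave_nm, est.z_err_nm) == (-40.0, 0.0)
        assert (est.r_ave_nm, est.r_err_nm) == (25.0, 0.0)
        assert est.n_r == est.n_z == 15
        assert est.symmetry_class == "nucleoplasmic"

    def test_two_protein_study_classes(self, fast_cfg, basket_set, channel_set):
        rows = summarize_localizations([basket_set, channel_set], fast_cfg,
                                       with_error=False)
        by_label = {r.nup_label: r for r in rows}
        assert by_label["basket"].symmetry_class == "nucleoplasmic"
        assert by_label["basket"].z_ave_nm < -30
        assert by_label["channel"].symmetry_class == "symmetric"

    def test_small_set_skipped_with_warning(self, fast_cfg, caplog):
        import logging

        tiny = make_set([(10.0, 5.0)] * 4, label="tiny")
        ok = make_set([(25.0, -40.0)] * 15, label="ok")
        with caplog.at_level(logging.WARNING):
            rows = summarize_localizations([tiny, ok], fast_cfg)
        assert [r.nup_label for r in rows] == ["ok"]
        assert any("tiny" in r.message for r in caplog.records)

    def test_row_metadata_records_estimator_settings(self, fast_cfg, basket_set):
        (est,) = summarize_localizations([basket_set], fast_cfg, with_error=False)
        assert est.meta["bootstrap_B"] == fast_cfg.bootstrap_B
        assert est.meta["bandwidth_rule"] == "silverman"
        assert est.n_npcs == 25


class TestKdeAgainstScipy:
    def test_unfolded_peak_matches_gaussian_kde_cross_check(self):
        # same bandwidth fed to scipy's independent KDE implementation
        rng = np.random.default_rng(8)
        u = np.abs(rng.normal(40, 6, 400))
        bw = silverman_bandwidth(u)
        grid = np.linspace(0, 80, 2001)
        from npcgold.localize import folded_kde

        mine = grid[np.argmax(folded_kde(u, grid, bw))]
        refl = np.concatenate([u, -u])
        kde = stats.gaussian_kde(refl, bw_method=bw / refl.std(ddof=1))
        theirs = grid[np.argmax(kde(grid))]
        assert mine == pytest.approx(theirs, abs=0.5)
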