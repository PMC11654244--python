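"""Generators: planted truth, determinism, and distributional calibration."""

import numpy as np
import pandas as pd
import pytest

from degronscreen import synthetic_data as sim


class TestGenPlatePair:
    def test_no_noise_no_effect_gives_identical_grids(self):
        cfg = sim.ScreenSimConfig(
            layout=(8, 12), n_strains=96, lethal_fraction=0.0,
            noise_cv=0.0, edge_boost=1.0, seed=0,
        )
        ind, unind, truth = sim.gen_plate_pair(cfg)
        np.testing.assert_array_equal(ind.sizes, unind.sizes)
        assert not truth.any()

    def test_planted_lethals_have_zero_induced_size(self):
        cfg = sim.ScreenSimConfig(
            layout=(16, 24), n_strains=100, lethal_fraction=0.1, effect_size=0.0, seed=3
        )
        ind, unind, truth = sim.gen_plate_pair(cfg)
        assert truth.sum() == 10  # brute-force count of planted flags
        sizes = ind.strain_sizes()
        assert all(sizes[s] == 0.0 for s in truth.index[truth])
        assert all(sizes[s] > 0.0 for s in truth.index[~truth])

    def test_same_seed_is_bit_identical(self):
        cfg = sim.ScreenSimConfig(seed=42)
        a = sim.gen_plate_pair(cfg)
        b = sim.gen_plate_pair(cfg)
        np.testing.assert_array_equal(a[0].sizes, b[0].sizes)
        np.testing.assert_array_equal(a[1].sizes, b[1].sizes)
        pd.testing.assert_series_equal(a[2], b[2])

    def test_replicates_share_truth_but_not_noise(self):
        cfg = sim.ScreenSimConfig(seed=5, noise_cv=0.1)
        _, u1, t1 = sim.gen_plate_pair(cfg, replicate=1)
        _, u2, t2 = sim.gen_plate_pair(cfg, replicate=2)
        pd.testing.assert_series_equal(t1, t2)
        assert not np.array_equal(u1.sizes, u2.sizes)

    def test_edge_boost_scales_border_ring_both_conditions(self):
        base = sim.ScreenSimConfig(
            layout=(6, 8), n_strains=48, lethal_fraction=0.0, noise_cv=0.0,
            edge_boost=1.0, seed=0,
        )
        boosted = sim.ScreenSimConfig(
            layout=(6, 8), n_strains=48, lethal_fraction=0.0, noise_cv=0.0,
            edge_boost=2.0, seed=0,
        )
        i0, u0, _ = sim.gen_plate_pair(base)
        i2, u2, _ = sim.gen_plate_pair(boosted)
        for plain, big in ((i0, i2), (u0, u2)):
            np.testing.assert_allclose(big.sizes[0, :], 2.0 * plain.sizes[0, :])
            np.testing.assert_allclose(big.sizes[1:-1, 1:-1], plain.sizes[1:-1, 1:-1])

    def test_capacity_overflow_raises(self):
        with pytest.raises(ValueError, match="cannot place"):
            sim.gen_plate_pair(sim.ScreenSimConfig(layout=(4, 4), n_strains=17))


class TestGenCellPopulation:
    def test_no_depletion_shares_distribution(self):
        cfg = sim.CellSimConfig(n_cells=5000, depletion_factor=1.0, seed=1)
        before = sim.gen_cell_population(cfg, induced=False)
        after = sim.gen_cell_population(cfg, induced=True)
        # same generating law: geometric means agree within sampling error
        assert after.summary.geo_mean == pytest.approx(before.summary.geo_mean, rel=0.05)

    def test_degenerate_config_gives_constant_cells(self):
        cfg = sim.CellSimConfig(
            n_cells=10, log_mean=np.log(500.0), log_sd=0.0,
            autofluorescence_mean=100.0, autofluorescence_sd=0.0, seed=0,
        )
        pop = sim.gen_cell_population(cfg, induced=False)
        np.testing.assert_allclose(pop.intensities, 600.0)
        assert pop.summary.geo_mean == pytest.approx(600.0)

    def test_depletion_ratio_matches_closed_form(self):
        # E[induced]/E[uninduced] = (AF + d*S) / (AF + S) with S = exp(mu+sd^2/2)
        cfg = sim.CellSimConfig(n_cells=500, depletion_factor=0.1, seed=9)
        before = sim.gen_cell_population(cfg, induced=False)
        after = sim.gen_cell_population(cfg, induced=True)
        S = np.exp(cfg.log_mean + cfg.log_sd**2 / 2)
        expected = (cfg.autofluorescence_mean + 0.1 * S) / (cfg.autofluorescence_mean + S)
        ratio = after.summary.geo_mean / before.summary.geo_mean
        assert ratio == pytest.approx(expected, rel=0.10)

    def test_intensities_strictly_positive(self):
        cfg = sim.CellSimConfig(
            n_cells=2000, autofluorescence_mean=5.0, autofluorescence_sd=20.0, seed=2
        )
        pop = sim.gen_cell_population(cfg, induced=True)
        assert np.all(pop.intensities > 0)

    def test_geometric_mean_converges_to_signal_location(self):
        # pure signal (no AF): sample geometric mean -> exp(log_mean) at n=1e5
        cfg = sim.CellSimConfig(
            n_cells=100_000, log_sd=0.5, autofluorescence_mean=0.0,
            autofluorescence_sd=0.0, seed=4,
        )
        rng_pop = sim.gen_cell_population(cfg, induced=False)
        # the additive AF floor is clipped at ~0 here, so intensities ~ signal
        geo = np.exp(np.mean(np.log(rng_pop.intensities)))
        assert geo == pytest.approx(np.exp(cfg.log_mean), rel=0.01)


class TestGenTimecourse:
    def test_noiseless_closed_form(self):
        t, y = sim.gen_timecourse(30.0, 0.0, [0, 30, 60], noise_cv=0.0, n_rep=1, seed=0)
        np.testing.assert_allclose(y[0], [1.0, 0.5, 0.25])

    def test_plateau_asymptote(self):
        t, y = sim.gen_timecourse(30.0, 0.2, [0, 30_000], noise_cv=0.0, n_rep=1, seed=0)
        assert y[0, -1] == pytest.approx(0.2, abs=1e-6)

    def test_invalid_t50_raises(self):
        with pytest.raises(ValueError):
            sim.gen_timecourse(0.0, 0.0, [0, 10], 0.0)

    def test_missing_t0_raises(self):
        with pytest.raises(ValueError, match="include 0"):
            sim.gen_timecourse(30.0, 0.0, [10, 20], 0.0)


class TestGenAnnotationTable:
    def test_single_full_size_term_covers_every_gene(self):
        df = sim.gen_annotation_table(20, [("T", 20)], seed=0)
        assert set(df["gene_id"]) == {f"G{i + 1:02d}" for i in range(20)}

    def test_term_sizes_are_exact(self):
        df = sim.gen_annotation_table(6000, [("GO:BIG", 151), ("GO:SMALL", 7)], seed=1)
        counts = df["term_id"].value_counts()
        assert counts["GO:BIG"] == 151 and counts["GO:SMALL"] == 7

    def test_seed_determinism_and_oversize_error(self):
        a = sim.gen_annotation_table(100, [("T", 10)], seed=5)
        b = sim.gen_annotation_table(100, [("T", 10)], seed=5)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            sim.gen_annotation_table(5, [("T", 6)], seed=0)


class TestGenCellImage:
    def test_empty_image(self):
        img, cents = sim.gen_cell_image(0, seed=0)
        assert img.sum() == 0 and len(cents) == 0

    def test_disks_non_overlapping_and_inside_frame(self):
        img, cents = sim.gen_cell_image(30, image_size=(256, 256), cell_radius=8, seed=1)
        assert img.dtype == np.uint16
        r = 8
        xy = cents[["y", "x"]].to_numpy()
        assert (xy >= r).all() and (xy[:, 0] < 256 - r).all() and (xy[:, 1] < 256 - r).all()
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1).astype(float)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= (2 * r + 1) ** 2

    def test_centroid_pixel_carries_disk_intensity(self):
        img, cents = sim.gen_cell_image(5, intensity=4321, seed=2)
        for _, row in cents.iterrows():
            assert img[int(row["y"]), int(row["x"])] == 4321

    def test_seed_determinism(self):
        a, ca = sim.gen_cell_image(10, seed=3)
        b, cb = sim.gen_cell_image(10, seed=3)
        np.testing.assert_array_equal(a, b)
        pd.testing.assert_frame_equal(ca, cb)

    def test_impossible_packing_raises(self):
        with pytest.raises(RuntimeError):
            sim.gen_cell_image(50, image_size=(64, 64), cell_radius=15, seed=0)
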