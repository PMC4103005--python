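"""Tests for the synthetic-data generators and their ground-truth contracts."""

import numpy as np
import pandas as pd
import pytest

from myxphen.core import REPLICATE_TRAITS, TRAITS, WILDTYPE
from myxphen.synthetic import (
    Blob,
    ImageSpec,
    SimulationConfig,
    default_trait_correlation,
    simulate_development_image,
    simulate_expression_matrix,
    simulate_trait_table,
)


class TestTraitTable:
    def test_null_configuration_has_no_effects(self):
        cfg = SimulationConfig(n_strains=41, effect_fraction=0.0, rng_seed=3)
        table, truth = simulate_trait_table(cfg)
        assert not truth.affected.to_numpy().any()
        assert (truth.planted_shifts.to_numpy() == 0).all()
        # replicate means sit at the wild-type baseline for every strain
        for trait in REPLICATE_TRAITS:
            vals = table.df.loc[table.df["trait"] == trait, "value"]
            baseline = cfg.baseline_means[trait]
            sd = cfg.baseline_cvs[trait] * baseline
            assert abs(vals.mean() - baseline) < 5 * sd / np.sqrt(len(vals))

    def test_zero_effect_size_sets_flags_but_no_shifts(self):
        cfg = SimulationConfig(n_strains=61, effect_fraction=0.5,
                               effect_size_sd=0.0, rng_seed=2)
        _, truth = simulate_trait_table(cfg)
        assert truth.affected.to_numpy().any()
        assert (truth.planted_shifts.to_numpy() == 0).all()

    def test_determinism_byte_identical(self):
        cfg = SimulationConfig(n_strains=25, rng_seed=42)
        t1, g1 = simulate_trait_table(cfg)
        t2, g2 = simulate_trait_table(SimulationConfig(n_strains=25, rng_seed=42))
        assert t1.df.to_csv() == t2.df.to_csv()
        pd.testing.assert_frame_equal(g1.planted_shifts, g2.planted_shifts)

    def test_non_psd_correlation_rejected(self):
        bad = np.eye(8)
        bad[0, 1] = bad[1, 0] = 0.9
        bad[0, 2] = bad[2, 0] = 0.9
        bad[1, 2] = bad[2, 1] = -0.9
        with pytest.raises(ValueError, match="positive semidefinite"):
            simulate_trait_table(SimulationConfig(trait_correlation=bad))

    @pytest.mark.parametrize("seed", [0, 7, 99])
    def test_ground_truth_invariants(self, seed):
        cfg = SimulationConfig(n_strains=31, rng_seed=seed,
                               group_separation_sd=1.5)
        table, truth = simulate_trait_table(cfg)
        assert not truth.affected.loc[WILDTYPE].any()
        unaffected = ~truth.affected.to_numpy()
        assert (truth.planted_shifts.to_numpy()[unaffected] == 0).all()
        # emission contracts: timing ordinal 1..5, count non-negative integer,
        # sporulation floored at zero
        timing = table.df.loc[table.df["trait"] == "timing", "value"]
        assert timing.isin([1, 2, 3, 4, 5]).all()
        assert timing.groupby(table.df["strain"]).size().eq(1).all()
        count = table.df.loc[table.df["trait"] == "count", "value"]
        assert (count >= 0).all() and (count == count.round()).all()
        sporulation = table.df.loc[table.df["trait"] == "sporulation", "value"]
        assert (sporulation >= 0).all()

    def test_effect_fraction_calibration_and_correlation_recovery(self):
        # fraction of mutants with >=1 planted effect tracks the configured
        # value despite trait correlation
        cfg = SimulationConfig(n_strains=2001, rng_seed=7)
        _, truth = simulate_trait_table(cfg)
        frac = (truth.affected.drop(index=WILDTYPE).sum(axis=1) >= 1).mean()
        assert abs(frac - cfg.effect_fraction) < 0.03
        # with every strain affected, the observed Spearman structure
        # converges to the latent trait correlation
        from scipy.stats import spearmanr

        cfg_all = SimulationConfig(n_strains=2001, effect_fraction=1.0,
                                   rng_seed=3)
        table, _ = simulate_trait_table(cfg_all)
        summ = table.summary_matrix(include_wildtype=False)[list(TRAITS)]
        rho = spearmanr(summ.to_numpy())[0]
        assert np.abs(rho - default_trait_correlation()).max() < 0.1


class TestDevelopmentImage:
    def test_single_disk_ground_truth_is_rasterized_mask(self):
        from skimage.draw import ellipse as draw_ellipse

        spec = ImageSpec(width=128, height=128, noise_sd=0.0,
                         blobs=[Blob(center=(64, 64), axes=(20, 20))])
        img, truth = simulate_development_image(spec)
        assert truth.count == 1
        rr, cc = draw_ellipse(64, 64, 20, 20, shape=(128, 128))
        assert truth.records[0].area == len(rr)
        assert not truth.records[0].touches_edge
        assert (img[rr, cc] == 80).all()

    def test_empty_blob_list_gives_count_zero(self):
        img, truth = simulate_development_image(ImageSpec(width=64, height=64))
        assert truth.count == 0
        assert (img == 200).all() or img.std() > 0  # background +- noise only

    def test_border_blob_flagged_edge_overlapping(self):
        spec = ImageSpec(width=128, height=128, noise_sd=0.0,
                         blobs=[Blob(center=(0, 64), axes=(15, 15))])
        _, truth = simulate_development_image(spec)
        assert truth.records[0].touches_edge

    def test_zero_area_blob_rejected(self):
        spec = ImageSpec(blobs=[Blob(center=(50, 50), axes=(0, 10))])
        with pytest.raises(ValueError, match="[Zz]ero-area"):
            simulate_development_image(spec)

    def test_separability_guarantee_enforced(self):
        spec = ImageSpec(noise_sd=30.0,
                         blobs=[Blob(center=(50, 50), axes=(10, 10),
                                     intensity=150.0)])
        with pytest.raises(ValueError, match="separability"):
            simulate_development_image(spec)


class TestExpressionMatrix:
    def test_zero_noise_reproduces_cluster_curves(self):
        expr, labels = simulate_expression_matrix(n_genes=20, noise_sd=0.0,
                                                  rng_seed=1)
        from myxphen.synthetic import default_cluster_profiles

        profiles = default_cluster_profiles()
        for gene in expr.index:
            np.testing.assert_allclose(expr.loc[gene].to_numpy(),
                                       profiles[labels[gene]])

    def test_orthogonal_step_profiles_recovered_downstream(self):
        t = np.array([0.0, 6.0, 12.0, 18.0, 24.0, 30.0])
        profiles = {"up": np.where(t >= 15, 2.0, 0.0),
                    "down": np.where(t >= 15, 0.0, 2.0)}
        expr, labels = simulate_expression_matrix(
            n_genes=40, timepoints=t, cluster_profiles=profiles,
            noise_sd=0.05, rng_seed=0)
        from sklearn.metrics import adjusted_rand_score

        from myxphen.expression import average_linkage_cluster

        cl = average_linkage_cluster(expr, k=2)
        assert adjusted_rand_score(labels[cl.labels.index], cl.labels) == 1.0

    def test_reproducible_for_fixed_seed(self):
        a, _ = simulate_expression_matrix(n_genes=15, rng_seed=9)
        b, _ = simulate_expression_matrix(n_genes=15, rng_seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="fewer genes"):
            simulate_expression_matrix(n_genes=2)
        with pytest.raises(ValueError, match="timepoints"):
            simulate_expression_matrix(n_genes=10, timepoints=[0, 12])
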