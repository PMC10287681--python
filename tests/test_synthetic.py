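import numpy as np
import pandas as pd
import pytest

from soilnet.clustering import ClusterPartition, cluster_abundances, order_clusters
from soilnet.coupling import coupling_scores
from soilnet.errors import ConfigError, DataError
from soilnet.plants import community_time_series
from soilnet.prep import clr_transform, rarefy, specialisation_index
from soilnet.synthetic import (
    SyntheticConfig,
    generate_dataset,
    generate_otu_counts,
    generate_plant_series,
)


def truth_abundances(table, labels, n_pairs=9):
    weights = table.relative().sum(axis=0)
    part = order_clusters(ClusterPartition(dict(labels), 0.0), weights)
    return cluster_abundances(part, table)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("n_mesocosms_per_soil", 0),
            ("specialist_fraction", 1.5),
            ("specialist_fold_change", 0.5),
            ("invasion_onset_year", 2050),
            ("coupling_rho_per_soil", {"natural": 1.4, "abandoned": 0.0}),
            ("nb_dispersion", -1.0),
        ],
    )
    def test_invalid_field_names_it(self, field, value):
        cfg = SyntheticConfig(**{field: value})
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            cfg.validate()


class TestDataset:
    def test_shapes_and_determinism(self):
        cfg = SyntheticConfig(n_mesocosms_per_soil=5, n_prok_otus=50,
                              n_fungal_otus=50, seed=1)
        plant, chem, prok, fung, truth = generate_dataset(cfg)
        assert plant["mesocosm_id"].nunique() == 10
        assert prok.n_otus == 50 and fung.n_otus == 50
        assert prok.n_samples == 10
        plant2, chem2, prok2, fung2, _ = generate_dataset(cfg)
        pd.testing.assert_frame_equal(plant, plant2)
        pd.testing.assert_frame_equal(chem, chem2)
        pd.testing.assert_frame_equal(prok.counts, prok2.counts)
        pd.testing.assert_frame_equal(fung.counts, fung2.counts)

    def test_invaders_absent_before_onset(self, small_dataset):
        plant, *_ = small_dataset
        pre = plant[(plant["year"] < 2012) & plant["invader_flag"]]
        assert (pre["biomass_g"] == 0).all() or pre.empty

    def test_truth_covers_all_otus(self, small_dataset, small_config):
        *_, prok, fung, truth = small_dataset
        assert set(truth.prok_clusters) == set(prok.otu_ids)
        assert set(truth.prok_clusters.values()) == set(
            range(1, small_config.n_prok_clusters + 1)
        )

    def test_coupling_rho_raises_downstream_beta(self):
        """Mean coupling beta across replicate datasets is higher under
        rho = 0.9 than rho = 0."""
        def mean_beta(rho, seed):
            cfg = SyntheticConfig(
                n_mesocosms_per_soil=8, n_prok_otus=40, n_fungal_otus=40,
                coupling_rho_per_soil={"natural": rho, "abandoned": rho},
                depth_mean=3000, seed=seed,
            )
            _, _, prok, fung, truth = generate_dataset(cfg)
            pa = truth_abundances(prok, truth.prok_clusters)
            fa = truth_abundances(fung, truth.fungal_clusters)
            return coupling_scores(pa, fa, transform="none")["beta"].mean()

        lo = [mean_beta(0.0, s) for s in range(20)]
        hi = [mean_beta(0.9, s) for s in range(20)]
        assert np.mean(hi) > np.mean(lo)
        assert np.mean([h > l for h, l in zip(hi, lo)]) >= 0.9

    def test_no_fold_change_no_si_separation(self):
        cfg = SyntheticConfig(
            n_mesocosms_per_soil=8, n_prok_otus=60, n_fungal_otus=30,
            specialist_fold_change=1.0, depth_mean=3000, seed=11,
        )
        _, _, prok, _, truth = generate_dataset(cfg)
        res = specialisation_index(rarefy(prok, seed=0), k_habitats=2)
        flags = pd.Series(truth.prok_specialists).reindex(res.per_otu.index)
        spec = res.per_otu.si[flags.fillna(False)]
        gen = res.per_otu.si[~flags.fillna(False)]
        # "specialists" are unlabelled noise: interquartile ranges overlap
        assert spec.quantile(0.25) < gen.quantile(0.75)
        assert gen.quantile(0.25) < spec.quantile(0.75)

    def test_specialist_recovery_with_strong_fold_change(self):
        hits = 0
        for s in range(10):
            cfg = SyntheticConfig(
                n_mesocosms_per_soil=8, n_prok_otus=60, n_fungal_otus=30,
                specialist_fold_change=8.0, depth_mean=3000, seed=100 + s,
            )
            _, _, prok, _, truth = generate_dataset(cfg)
            res = specialisation_index(rarefy(prok, seed=s), k_habitats=2)
            flags = pd.Series(truth.prok_specialists).reindex(res.per_otu.index)
            spec = res.per_otu.si[flags.fillna(False)]
            gen = res.per_otu.si[~flags.fillna(False)]
            hits += spec.median() > gen.median()
        assert hits >= 10 * 0.95


class TestPlantSeries:
    def test_no_invaders_configured(self):
        cfg = SyntheticConfig(n_mesocosms_per_soil=3, n_invader_species=0, seed=2)
        plant, _ = generate_plant_series(cfg)
        assert not plant["invader_flag"].any()

    def test_shannon_jump_at_onset(self):
        diffs = []
        for s in range(20):
            cfg = SyntheticConfig(n_mesocosms_per_soil=3, seed=s)
            plant, _ = generate_plant_series(cfg)
            ts = community_time_series(plant)
            diffs.append(
                ts[ts.year == 2013]["shannon"].mean()
                - ts[ts.year == 2011]["shannon"].mean()
            )
        assert np.mean(diffs) > 0
        assert np.mean([d > 0 for d in diffs]) > 0.9

    def test_productivity_stationary(self, small_dataset):
        plant, *_ = small_dataset
        ts = community_time_series(plant)
        by_year = ts.groupby("year")["productivity"].mean()
        assert by_year.max() / by_year.min() < 1.5  # no trend beyond noise

    def test_deterministic(self):
        cfg = SyntheticConfig(n_mesocosms_per_soil=3, seed=9)
        a, ax_a = generate_plant_series(cfg)
        b, ax_b = generate_plant_series(cfg)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ax_a, ax_b)


class TestOtuCounts:
    def test_row_sums_equal_drawn_depth(self):
        lat = pd.DataFrame(np.ones((6, 2)), columns=["c1", "c2"])
        counts = generate_otu_counts(lat, [1, 1, 2, 2], depth_mean=500, seed=0)
        # totals are the NB depth draw; multinomial conditions on it exactly
        assert (counts.sum(axis=1) >= 1).all()
        counts2 = generate_otu_counts(lat, [1, 1, 2, 2], depth_mean=500, seed=0)
        pd.testing.assert_frame_equal(counts, counts2)

    def test_uniform_limit(self):
        lat = pd.DataFrame(np.ones((4, 2)), columns=["c1", "c2"])
        counts = generate_otu_counts(
            lat, [1, 1, 2, 2], depth_mean=40_000, depth_dispersion=0,
            nb_dispersion=0.0, seed=1,
        )
        frac = counts.div(counts.sum(axis=1), axis=0)
        assert np.all(np.abs(frac - 0.25) < 0.02)

    def test_zero_mass_cluster_gets_zero_counts(self):
        lat = pd.DataFrame({"c1": [1.0, 1.0], "c2": [0.0, 0.0]})
        counts = generate_otu_counts(lat, [1, 1, 2, 2], depth_mean=1000, seed=2)
        assert (counts.iloc[:, 2:] == 0).all().all()

    def test_nonfinite_latent_raises(self):
        lat = pd.DataFrame({"c1": [1.0, np.nan]})
        with pytest.raises(DataError):
            generate_otu_counts(lat, [1, 1], depth_mean=100)

    def test_block_structure_in_clr(self):
        rng = np.random.default_rng(3)
        n, k = 40, 3
        lat = pd.DataFrame(np.exp(rng.normal(0, 1.5, size=(n, k))),
                           columns=list("abc"))
        labels = [1, 1, 1, 2, 2, 2, 3, 3, 3]
        counts = generate_otu_counts(
            lat, labels, depth_mean=5000, nb_dispersion=0.5, seed=4
        )
        from soilnet.otutable import OtuTable

        t = OtuTable(counts, pd.Series(["x"] * n, index=counts.index), "prokaryote")
        clr = clr_transform(t).to_numpy()
        corr = np.corrcoef(clr.T)
        lab = np.array(labels)
        same = corr[np.equal.outer(lab, lab) & ~np.eye(len(lab), dtype=bool)]
        diff = corr[~np.equal.outer(lab, lab)]
        assert same.mean() > diff.mean()
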