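import numpy as np
import pandas as pd
import pytest

from soilnet.errors import DataError, EmptyResultError
from soilnet.otutable import OtuTable, read_otu_tsv, write_otu_tsv
from soilnet.prep import (
    classify_cluster_specialisation,
    clr_transform,
    cwm_si,
    enrichment_ratio_and_classify,
    filter_otus,
    multi_rarefied_shannon,
    otu_overlap,
    rarefy,
    specialisation_index,
)


def table_from(counts: dict, habitats=None) -> OtuTable:
    df = pd.DataFrame(counts)
    df.index = [f"s{i}" for i in range(len(df))]
    hab = habitats or ["natural"] * (len(df) // 2) + ["abandoned"] * (len(df) - len(df) // 2)
    return OtuTable(df, pd.Series(hab, index=df.index), "prokaryote")


class TestFilter:
    def test_boundary_retained(self):
        # exactly 100 reads over exactly 5 samples survives both rules
        t = table_from({"keep": [20] * 5 + [0], "drop": [150, 0, 0, 0, 0, 0]})
        out = filter_otus(t, 100, 5)
        assert out.otu_ids == ["keep"]

    def test_presence_rule_removes(self):
        t = table_from({"a": [50, 50, 50, 0, 0, 0], "b": [30] * 6})
        out = filter_otus(t, 100, 5)
        assert out.otu_ids == ["b"]

    def test_zero_thresholds_identity(self, toy_table):
        out = filter_otus(toy_table, 0, 0)
        assert out.otu_ids == toy_table.otu_ids

    def test_empty_result_raises(self, toy_table):
        with pytest.raises(EmptyResultError):
            filter_otus(toy_table, 10_000, 1)


class TestRarefy:
    def test_totals_equal_depth(self, toy_table):
        out = rarefy(toy_table, depth=10, seed=1)
        assert (out.sample_totals() == 10).all()

    def test_sample_at_depth_unchanged(self):
        t = table_from({"a": [6, 50], "b": [4, 50]})
        out = rarefy(t, depth=10, seed=0)
        assert out.counts.loc["s0"].tolist() == [6, 4]

    def test_shallow_samples_dropped(self):
        t = table_from({"a": [2, 50], "b": [1, 50]})
        out = rarefy(t, depth=10, seed=0)
        assert out.sample_ids == ["s1"]

    def test_depth_unreachable_raises(self, toy_table):
        with pytest.raises(EmptyResultError):
            rarefy(toy_table, depth=10_000)

    def test_hypergeometric_mean(self):
        # E[count] = depth * count/total for sampling without replacement
        t = table_from({"a": [60, 60], "b": [30, 30], "c": [10, 10]})
        depth, n_iter = 20, 1000
        draws = np.array(
            [rarefy(t, depth, seed=s).counts.loc["s0"].to_numpy()
             for s in range(n_iter)]
        )
        expected = depth * np.array([0.6, 0.3, 0.1])
        # hypergeometric variance for 3-SE band
        n_total = 100
        var = depth * np.array([0.6, 0.3, 0.1]) * (1 - np.array([0.6, 0.3, 0.1]))
        var *= (n_total - depth) / (n_total - 1)
        se = np.sqrt(var / n_iter)
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se)

    def test_seeded_reproducible(self, toy_table):
        a = rarefy(toy_table, 10, seed=5).counts
        b = rarefy(toy_table, 10, seed=5).counts
        pd.testing.assert_frame_equal(a, b)


class TestMultiRarefiedShannon:
    def test_even_sample_near_log_richness(self):
        t = table_from({f"o{i}": [100, 100] for i in range(5)})
        h = multi_rarefied_shannon(t, depth=100, iterations=20, seed=0)
        assert np.all(np.abs(h - np.log(5)) < 0.1)

    def test_single_otu_zero(self):
        t = table_from({"only": [500, 400]})
        h = multi_rarefied_shannon(t, depth=100, iterations=5, seed=0)
        assert np.allclose(h, 0.0)

    def test_one_iteration_matches_single_rarefy(self, toy_table):
        from soilnet.plants import shannon_diversity

        h = multi_rarefied_shannon(toy_table, depth=10, iterations=1, seed=3)
        r = rarefy(toy_table, depth=10, seed=3)
        manual = r.counts.apply(lambda row: shannon_diversity(row.to_numpy()), axis=1)
        pd.testing.assert_series_equal(h, manual)


class TestClr:
    def test_hand_computed(self):
        t = table_from({"a": [1, 1], "b": [1, 1], "c": [8, 8]})
        clr = clr_transform(t, pseudocount=0)
        g = np.log(8) / 3
        np.testing.assert_allclose(
            clr.iloc[0].to_numpy(), [-g, -g, 2 * g], atol=1e-12
        )

    def test_rows_sum_to_zero(self, toy_table):
        clr = clr_transform(toy_table, pseudocount=1)
        assert np.all(np.abs(clr.sum(axis=1)) < 1e-9)

    def test_equal_counts_give_zero_row(self):
        t = table_from({"a": [5, 7], "b": [5, 7], "c": [5, 7]})
        assert np.allclose(clr_transform(t, pseudocount=0), 0.0)

    def test_scale_invariance_without_pseudocount(self):
        t1 = table_from({"a": [2, 4], "b": [6, 8], "c": [10, 2]})
        t2 = OtuTable(t1.counts * 10, t1.habitat, "prokaryote")
        pd.testing.assert_frame_equal(
            clr_transform(t1, 0), clr_transform(t2, 0), atol=1e-12
        )

    def test_zero_counts_need_pseudocount(self, toy_table):
        with pytest.raises(DataError):
            clr_transform(toy_table, pseudocount=0)


class TestSpecialisationIndex:
    def test_constant_otu(self):
        # 5 reads in each of 4 samples, K=2: sigma=0, N=20 -> -sqrt(0.1)
        t = table_from({"a": [5, 5, 5, 5]})
        res = specialisation_index(t, k_habitats=2)
        assert res.per_otu.loc["a", "si"] == pytest.approx(-np.sqrt(0.1))

    def test_concentrated_otu(self):
        # reads (10,0,0,0): mu=2.5, sigma=5 (ddof=1), N=10 -> 2 - sqrt(0.2)
        t = table_from({"a": [10, 0, 0, 0], "b": [1, 1, 1, 1]})
        res = specialisation_index(t, k_habitats=2)
        assert res.per_otu.loc["a", "si"] == pytest.approx(2 - np.sqrt(0.2))

    def test_k_zero_reduces_to_cv(self):
        t = table_from({"a": [10, 0, 0, 0]})
        res = specialisation_index(t, k_habitats=0)
        assert res.per_otu.loc["a", "si"] == pytest.approx(2.0)

    def test_identity_holds_for_all_otus(self, small_dataset):
        _, _, prok, _, _ = small_dataset
        r = rarefy(prok, seed=2)
        res = specialisation_index(r, k_habitats=2)
        recomputed = (
            res.per_otu["sigma"] / res.per_otu["mu"]
            - np.sqrt(res.k_habitats / res.per_otu["n_reads"])
        )
        assert np.all(np.abs(res.per_otu["si"] - recomputed) < 1e-12)

    def test_absent_otus_excluded(self):
        t = table_from({"a": [1, 2, 3, 4], "gone": [0, 0, 0, 0]})
        res = specialisation_index(t, k_habitats=2)
        assert res.excluded_otus == ["gone"]
        assert "gone" not in res.per_otu.index

    def test_even_increment_monotone(self):
        # adding reads evenly shrinks sigma/mu and the correction
        base = np.array([4, 0, 0, 0])
        sis = []
        for inc in (0, 2, 8):
            t = table_from({"a": (base + inc).tolist()})
            sis.append(specialisation_index(t, k_habitats=2).per_otu.loc["a", "si"])
        assert sis[0] > sis[1] > sis[2]


class TestCwmAndClassification:
    @pytest.mark.parametrize(
        "si, w, expected",
        [([2.0], [5.0], 2.0), ([1, 3], [1, 1], 2.0), ([1, 3], [3, 1], 1.5)],
    )
    def test_weighted_mean(self, si, w, expected):
        assert cwm_si(si, w) == pytest.approx(expected)

    def test_zero_weight_raises(self):
        with pytest.raises(DataError):
            cwm_si([1.0], [0.0])

    def test_identical_distributions_intermediate(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4])
        out = classify_cluster_specialisation({1: vals, 2: vals}, vals.mean())
        assert (out["label"] == "intermediate").all()

    def test_point_mass_below_mean_is_generalist(self):
        out = classify_cluster_specialisation({1: np.full(4, -2.0)}, 0.0)
        assert out.loc[1, "label"] == "generalist"

    def test_point_mass_above_mean_is_specialist(self):
        out = classify_cluster_specialisation({1: np.full(4, 2.0)}, 0.0)
        assert out.loc[1, "label"] == "specialist"


class TestEnrichment:
    def test_equal_reads_neutral(self):
        t = table_from({"a": [50, 50, 50, 50]},
                       ["natural", "natural", "abandoned", "abandoned"])
        res = enrichment_ratio_and_classify(t, {"a": 1}, pseudocount=0)
        assert res.per_otu_ratio["a"] == pytest.approx(0.0)
        assert res.cluster_labels[1] == "neutral"

    def test_hand_ratio(self):
        t = table_from({"a": [100, 100, 50, 50]},
                       ["natural", "natural", "abandoned", "abandoned"])
        res = enrichment_ratio_and_classify(
            t, {"a": 1}, pseudocount=0, habitats=("natural", "abandoned")
        )
        assert res.per_otu_ratio["a"] == pytest.approx(np.log(2))

    def test_cluster_with_all_positive_ratios_enriched(self):
        counts = {f"o{i}": [40 * (i + 1), 40 * (i + 1), 10, 10] for i in range(4)}
        t = table_from(counts, ["natural", "natural", "abandoned", "abandoned"])
        res = enrichment_ratio_and_classify(
            t, {f"o{i}": 1 for i in range(4)}, habitats=("natural", "abandoned")
        )
        assert res.cluster_labels[1] == "enriched-natural"


class TestOverlapAndIO:
    def test_overlap_counts(self):
        a = table_from({"x": [1, 1], "y": [1, 1], "z": [1, 1]})
        b = table_from({"y": [1, 1], "z": [1, 1], "w": [1, 1]})
        assert otu_overlap(a, b) == (2, 1, 1)
        assert otu_overlap(a, a) == (3, 0, 0)

    def test_disjoint(self):
        a = table_from({"x": [1, 1]})
        b = table_from({"y": [1, 1]})
        assert otu_overlap(a, b) == (0, 1, 1)

    def test_tsv_round_trip(self, toy_table, tmp_path):
        p = tmp_path / "otus.tsv"
        write_otu_tsv(toy_table, p)
        back = read_otu_tsv(p, toy_table.habitat, "prokaryote")
        pd.testing.assert_frame_equal(back.counts, toy_table.counts)
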