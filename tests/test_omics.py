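"""Expression preprocessing, hypergeometric enrichment, growth-rate
classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from retentostat.omics import (
    ExpressionPreprocessor,
    GrowthCorrelationClassifier,
    average_normalize,
    classify_growth_correlation,
    floor_and_filter,
    housekeeping_cv,
    hypergeometric_enrichment,
    scale_arrays,
    venn_partition,
)
from retentostat.synthetic import generate_expression_dataset


@pytest.fixture
def toy_matrix() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "a1": [100.0, 5.0, 30.0, 400.0],
            "a2": [300.0, 5.0, 25.0, 500.0],
            "a3": [200.0, 5.0, 35.0, 450.0],
        },
        index=["ACT1", "low", "mid", "high"],
    )


class TestPreprocessing:
    def test_scale_arrays_sets_every_column_mean_to_target(self, toy_matrix):
        scaled = scale_arrays(toy_matrix, target=240.0)
        np.testing.assert_allclose(scaled.mean(axis=0), 240.0)

    def test_scale_is_identity_at_target(self):
        m = pd.DataFrame({"a": [240.0, 240.0], "b": [200.0, 280.0]},
                         index=["g1", "g2"])
        np.testing.assert_allclose(scale_arrays(m).to_numpy(), m.to_numpy())

    def test_scale_two_gene_example(self):
        m = pd.DataFrame({"a": [100.0, 300.0]}, index=["g1", "g2"])
        out = scale_arrays(m)
        np.testing.assert_allclose(out["a"], [120.0, 360.0])

    def test_floor_then_filter_discards_dim_genes(self):
        m = pd.DataFrame(
            {
                "a": [5.0, 25.0, 10.0, 18.0],
                "b": [5.0, 26.0, 14.0, 30.0],
                "c": [5.0, 24.0, 11.0, 19.0],
            },
            index=["allfive", "bright", "dim", "borderline"],
        )
        out, discarded = floor_and_filter(m, floor=12.0, min_mean=20.0)
        # all-5 gene floors to 12 everywhere -> mean 12 < 20 -> discarded
        assert "allfive" in discarded and "dim" in discarded
        assert list(out.index) == ["bright", "borderline"]
        assert (out >= 12.0).all().all()

    def test_exact_discard_count_on_fixture(self):
        m = pd.DataFrame(
            {
                "a": [100.0, 3.0, 15.0, 50.0],
                "b": [100.0, 3.0, 16.0, 50.0],
                "c": [100.0, 3.0, 17.0, 50.0],
            },
            index=["g1", "g2", "g3", "g4"],
        )
        out, discarded = floor_and_filter(m)
        assert len(discarded) == 2
        assert set(discarded) == {"g2", "g3"}

    def test_average_normalize(self):
        m = pd.DataFrame({"a": [10.0], "b": [20.0], "c": [30.0]}, index=["g"])
        out = average_normalize(m)
        np.testing.assert_allclose(out.loc["g"], [0.5, 1.0, 1.5])
        np.testing.assert_allclose(out.mean(axis=1), 1.0)

    def test_average_normalize_idempotent(self, toy_matrix):
        once = average_normalize(toy_matrix)
        twice = average_normalize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy())

    def test_preprocessor_pipeline_idempotent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(
            rng.lognormal(5.0, 1.0, size=(50, 4)),
            index=[f"g{i}" for i in range(50)],
            columns=list("abcd"),
        )
        pre = ExpressionPreprocessor()
        once = pre.fit_transform(m)
        twice = pre.fit_transform(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_array_rejected(self):
        m = pd.DataFrame({"a": [0.0, 0.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            scale_arrays(m)


class TestHousekeepingCV:
    def test_constant_gene_has_zero_cv(self):
        m = pd.DataFrame({"a": [7.0], "b": [7.0], "c": [7.0]}, index=["ACT1"])
        cv, avg, missing = housekeeping_cv(m, genes=("ACT1",))
        assert cv["ACT1"] == 0.0 and avg == 0.0 and missing == []

    def test_hand_computed_cv(self):
        m = pd.DataFrame(
            {"a": [100.0], "b": [100.0], "c": [200.0]}, index=["PDA1"]
        )
        cv, _, _ = housekeeping_cv(m, genes=("PDA1",))
        assert cv["PDA1"] == pytest.approx(np.std([100, 100, 200], ddof=1) / (400 / 3))
        assert cv["PDA1"] == pytest.approx(0.433, abs=1e-3)

    def test_stable_set_at_ten_percent_noise(self):
        m, _, _ = generate_expression_dataset(
            n_genes=300, frac_up=0.0, frac_down=0.0, noise_cv=0.10, seed=5
        )
        genes = list(m.index[:6])
        cv, avg, missing = housekeeping_cv(m, genes=genes)
        assert missing == []
        assert avg == pytest.approx(0.10, abs=0.03)

    def test_missing_genes_reported_not_fatal(self, toy_matrix):
        cv, avg, missing = housekeeping_cv(toy_matrix)
        assert "ACT1" in cv.index
        assert set(missing) == {"HHT2", "SHR3", "PDA1", "TPI", "TFC1"}


class TestHypergeometricEnrichment:
    def test_matches_exhaustive_enumeration_small_universes(self):
        """Upper-tail p agrees with brute-force enumeration of all
        C(N, n) cluster draws for every small (N, K, n, k)."""
        from retentostat.omics import _log_hypergeom_sf

        for n_bg in range(2, 11):
            universe = list(range(n_bg))
            for n_cat in range(0, n_bg + 1):
                cat = set(range(n_cat))
                for n_cl in range(1, n_bg + 1):
                    draws = list(itertools.combinations(universe, n_cl))
                    overlaps = np.array([len(cat & set(d)) for d in draws])
                    for k in range(0, min(n_cat, n_cl) + 1):
                        brute = np.mean(overlaps >= k)
                        ours = np.exp(_log_hypergeom_sf(k, n_bg, n_cat, n_cl))
                        assert ours == pytest.approx(brute, abs=1e-12), (
                            n_bg, n_cat, n_cl, k,
                        )

    def test_worked_example(self):
        res = hypergeometric_enrichment(
            cluster=[0, 1, 2, 3, 4],
            categories={"cat": [0, 1, 2, 9]},
            background=list(range(10)),
        )[0]
        assert res.overlap == 3
        assert res.p_value == pytest.approx(66 / 252, rel=1e-12)

    def test_degenerate_cases_give_p_one(self):
        bg = list(range(20))
        res = hypergeometric_enrichment(
            cluster=bg[:5],
            categories={"empty_overlap": bg[10:], "whole_bg": bg},
            background=bg,
        )
        assert all(r.p_value == 1.0 for r in res)

    def test_symmetry_in_cluster_and_category(self):
        bg = list(range(40))
        a, b = bg[:12], bg[5:20]
        p1 = hypergeometric_enrichment(a, {"s": b}, bg)[0].p_value
        p2 = hypergeometric_enrichment(b, {"s": a}, bg)[0].p_value
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_bonferroni_correction_and_sorting(self):
        bg = [f"g{i}" for i in range(100)]
        cluster = bg[:20]
        cats = {
            "enriched": bg[:15],       # overlaps cluster heavily
            "null1": bg[40:60],
            "null2": bg[60:80],
        }
        res = hypergeometric_enrichment(cluster, cats, bg)
        assert res[0].category == "enriched"
        for r in res:
            assert r.p_corrected == pytest.approx(min(1.0, r.p_value * 3))
        assert res[0].significant

    def test_large_overlap_is_vanishingly_improbable(self):
        """55 hits from a 166-gene category in a 775-gene cluster of a
        6383-gene background is far beyond chance (p < 1e-10)."""
        bg = [f"g{i}" for i in range(6383)]
        cat = set(bg[:166])
        cluster = bg[:55] + bg[200:920]  # 775 genes, 55 in the category
        res = hypergeometric_enrichment(cluster, {"tf_targets": cat}, bg)[0]
        assert res.overlap == 55
        assert res.p_value < 1e-10

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment([], {"c": [1]}, [1, 2])
        with pytest.raises(ValueError):
            hypergeometric_enrichment([1], {"c": [1]}, [])
        with pytest.raises(ValueError):
            hypergeometric_enrichment([99], {"c": [1]}, [1, 2])


class TestGrowthCorrelationClassifier:
    def test_recovers_planted_direction(self):
        m, rates, truth = generate_expression_dataset(
            n_genes=400, frac_up=0.1, frac_down=0.12, effect_size=2.0, seed=1
        )
        up, down, non, table = classify_growth_correlation(
            m, rates, n_permutations=300, random_state=0
        )
        tu, td = truth["up_genes"], truth["down_genes"]
        assert len(up & tu) / len(tu) >= 0.95
        assert len(down & td) / len(td) >= 0.95

    def test_full_scale_recovery_with_planted_enrichment(self):
        """Full 6383-gene x 13-array dataset: planted up/down genes are
        recovered and the planted categories surface as the top
        enrichments of the corresponding clusters."""
        m, rates, truth = generate_expression_dataset(effect_size=2.0, seed=6)
        assert m.shape == (6383, 13)
        up, down, _, _ = classify_growth_correlation(
            m, rates, n_permutations=300, random_state=0
        )
        tu, td = truth["up_genes"], truth["down_genes"]
        assert len(up & tu) / len(tu) >= 0.95
        assert len(down & td) / len(td) >= 0.95
        res = hypergeometric_enrichment(up, truth["categories"], m.index)
        assert res[0].category == "planted_up" and res[0].significant
        res = hypergeometric_enrichment(down, truth["categories"], m.index)
        assert res[0].category == "planted_down" and res[0].significant

    def test_type_one_error_near_nominal_under_null(self):
        m, rates, _ = generate_expression_dataset(
            n_genes=600, frac_up=0.0, frac_down=0.0, noise_cv=0.10, seed=4
        )
        clf = GrowthCorrelationClassifier(
            alpha=0.05, n_permutations=400, random_state=0
        ).fit(m, rates.to_numpy())
        responsive_frac = (clf.labels_ != 0).mean()
        assert responsive_frac == pytest.approx(0.05, abs=0.03)

    def test_seeded_determinism(self):
        m, rates, _ = generate_expression_dataset(n_genes=100, seed=8)
        a = GrowthCorrelationClassifier(random_state=3).fit(m, rates)
        b = GrowthCorrelationClassifier(random_state=3).fit(m, rates)
        pd.testing.assert_series_equal(a.p_values_, b.p_values_)

    def test_needs_distinct_growth_rates(self):
        m = pd.DataFrame(np.ones((5, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            GrowthCorrelationClassifier().fit(m, [0.1, 0.1, 0.1, 0.1])


class TestVennPartition:
    def test_identical_sets(self):
        out = venn_partition({1, 2, 3}, {1, 2, 3})
        assert out["n_shared"] == 3
        assert out["n_only_a"] == out["n_only_b"] == 0

    def test_counts_are_exact_set_arithmetic(self):
        out = venn_partition({1, 2, 3, 4}, {3, 4, 5})
        assert out["only_a"] == {1, 2}
        assert out["only_b"] == {5}
        assert out["shared"] == {3, 4}
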