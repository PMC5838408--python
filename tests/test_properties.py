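"""Gene-set characterization: the essentiality rule, rank tests on
constraint scores, Fisher proportion tests against an enumeration
oracle, and exact recovery of population-level planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import small_config
from evsets.enrichment import EVSets
from evsets.properties import (
    classify_essential,
    compare_score_across_sets,
    count_constrained,
    detect_class_switches,
    disease_overlap_summary,
    essentiality_summary,
    mann_whitney,
    population_specificity,
    proportion_test,
)
from evsets.simulate import simulate_dataset
from oracles import fisher_two_sided_oracle


def evsets_of(disease=(), rare=(), common=()):
    return EVSets(
        disease=frozenset(disease),
        rare=frozenset(rare),
        common=frozenset(common),
        alpha=0.05,
        overlap={},
    )


class TestEssentiality:
    @pytest.mark.parametrize(
        "mgi, ogee, expected",
        [
            (True, False, True),
            (False, True, True),
            (True, True, True),
            (False, False, False),
            (float("nan"), float("nan"), False),
            (None, True, True),
        ],
    )
    def test_disjunctive_rule(self, mgi, ogee, expected):
        assert classify_essential(mgi, ogee) is expected

    def test_monotone_in_evidence(self):
        for mgi in (False, True):
            for ogee in (False, True):
                if classify_essential(mgi, ogee):
                    assert classify_essential(True, ogee)
                    assert classify_essential(mgi, True)

    @pytest.mark.parametrize(
        "n_essential, n_total, pct",
        [(511, 800, 64), (17, 32, 53), (30, 282, 11)],
    )
    def test_summary_percentages(self, annotations_factory, n_essential, n_total, pct):
        genes = [f"G{i}" for i in range(n_total)]
        ann = annotations_factory(genes, essential_mgi=[i < n_essential for i in range(n_total)])
        assert essentiality_summary(set(genes), ann) == (n_essential, pct)

    def test_percentage_scale_free(self, annotations_factory):
        genes = [f"G{i}" for i in range(40)]
        ann = annotations_factory(genes, essential_ogee=[i < 13 for i in range(40)])
        _, pct = essentiality_summary(set(genes), ann, precision=3)
        doubled = pd.concat(
            [ann, ann.assign(gene=[g + "_copy" for g in genes])], ignore_index=True
        )
        big_set = set(doubled["gene"])
        _, pct2 = essentiality_summary(big_set, doubled, precision=3)
        assert pct == pct2

    def test_empty_set_rejected(self, annotations_factory):
        with pytest.raises(ValueError):
            essentiality_summary(set(), annotations_factory(["G1"]))


class TestCountConstrained:
    def test_boundary_inclusive(self, annotations_factory):
        pli = [0.95, 0.9, 0.89, 0.5, 0.91, 0.1, 0.97, 0.3, float("nan"), 0.88]
        genes = [f"G{i}" for i in range(10)]
        ann = annotations_factory(genes, pli=pli)
        count, n_missing = count_constrained(set(genes), ann)
        assert count == 4  # 0.95, 0.9 (inclusive), 0.91, 0.97
        assert n_missing == 1

    def test_all_scored_at_one(self, annotations_factory):
        genes = [f"G{i}" for i in range(5)]
        ann = annotations_factory(genes, pli=1.0)
        assert count_constrained(set(genes), ann) == (5, 0)

    def test_all_missing(self, annotations_factory):
        genes = [f"G{i}" for i in range(6)]
        ann = annotations_factory(genes)
        assert count_constrained(set(genes), ann) == (0, 6)


class TestRankTests:
    def test_identical_samples_give_p_one(self):
        assert mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_fully_separated_groups_closed_form_statistic(self, annotations_factory):
        """For {1,1,1} vs {0,0,0} vs {0,0,0} the tie-corrected
        Kruskal-Wallis statistic is 5.4 / 0.675 = 8 (hand-computed from
        mid-ranks 8 and 3.5)."""
        h = stats.kruskal([1, 1, 1], [0, 0, 0], [0, 0, 0]).statistic
        assert h == pytest.approx(8.0, abs=1e-12)
        genes = [f"G{i}" for i in range(9)]
        ann = annotations_factory(genes, pli=[1, 1, 1, 0, 0, 0, 0, 0, 0])
        sets = {"a": set(genes[:3]), "b": set(genes[3:6]), "c": set(genes[6:])}
        report = compare_score_across_sets(sets, ann, "pli")
        assert stats.chi2.sf(8.0, 2) == pytest.approx(report.omnibus_p)

    def test_omnibus_type_one_error_calibrated(self, annotations_factory):
        """Three same-distribution sets: the omnibus p is uniform, so
        over 200 seeded replicates the rejection fraction at 0.05 sits
        in 0.05 +/- 0.04."""
        rng = np.random.default_rng(2024)
        genes = [f"G{i}" for i in range(90)]
        sets = {"a": set(genes[:30]), "b": set(genes[30:60]), "c": set(genes[60:])}
        rejections = 0
        for _ in range(200):
            ann = annotations_factory(genes, dn_ds=rng.lognormal(0, 0.5, 90))
            report = compare_score_across_sets(sets, ann, "dn_ds")
            rejections += report.omnibus_p < 0.05
        assert 0.01 <= rejections / 200 <= 0.09

    def test_missing_scores_dropped_and_reported(self, annotations_factory):
        genes = [f"G{i}" for i in range(8)]
        pli = [0.1, 0.2, float("nan"), 0.4, 0.5, 0.6, float("nan"), 0.8]
        ann = annotations_factory(genes, pli=pli)
        sets = {"a": set(genes[:4]), "b": set(genes[4:])}
        report = compare_score_across_sets(sets, ann, "pli")
        assert report.per_set["a"]["n_missing"] == 1
        assert report.per_set["b"]["n_scored"] == 3

    def test_underpowered_set_marked_unavailable(self, annotations_factory):
        genes = ["G0", "G1", "G2", "G3"]
        ann = annotations_factory(genes, pli=[0.5, 0.6, float("nan"), float("nan")])
        sets = {"a": {"G0", "G1"}, "b": {"G2", "G3"}}
        report = compare_score_across_sets(sets, ann, "pli")
        assert "a|b" in report.unavailable
        assert "omnibus" in report.unavailable


class TestProportionTest:
    def test_printed_tables_below_bound(self):
        assert proportion_test(17, 32, 30, 282) < 0.001
        assert proportion_test(23, 32, 94, 282) < 0.001

    def test_matches_enumeration_oracle_small_tables(self):
        for n in range(2, 11):
            for r1 in range(1, n):
                r2 = n - r1
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        p = proportion_test(a, r1, c, r2)
                        oracle = fisher_two_sided_oracle(a, r1 - a, c, r2 - c)
                        assert p == pytest.approx(oracle, abs=1e-12)

    def test_symmetries(self):
        p = proportion_test(5, 20, 12, 30)
        assert proportion_test(12, 30, 5, 20) == pytest.approx(p)
        # swapping yes/no in both groups jointly leaves p unchanged
        assert proportion_test(15, 20, 18, 30) == pytest.approx(p)

    def test_null_rejection_rate_conservative(self):
        """Fisher on equal-proportion tables rejects at 0.05 in at most
        5% + 3 SE of replicates (discreteness makes it conservative)."""
        rng = np.random.default_rng(7)
        n_reps, n = 400, 30
        rejections = sum(
            proportion_test(rng.binomial(n, 0.3), n, rng.binomial(n, 0.3), n) < 0.05
            for _ in range(n_reps)
        )
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_reps)
        assert rejections / n_reps <= bound

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            proportion_test(5, 3, 1, 10)
        with pytest.raises(ValueError):
            proportion_test(0, 0, 1, 10)


class TestDiseaseOverlap:
    def test_printed_percentages(self, annotations_factory):
        rare_genes = [f"R{i}" for i in range(32)]
        common_genes = [f"C{i}" for i in range(282)]
        ann = annotations_factory(
            rare_genes + common_genes,
            disease_annotated=[i < 20 for i in range(32)] + [i < 91 for i in range(282)],
        )
        ev = evsets_of(disease=["D0"], rare=rare_genes, common=common_genes)
        out = disease_overlap_summary(ev, ann)
        assert out["per_set"]["rare"]["percent"] == 62.5
        assert out["per_set"]["common"]["percent"] == 32.3
        # Fisher's exact test on this 32-vs-282 table: agreement with the
        # margin-conditional enumeration oracle (p ~ 0.0014)
        assert out["rare_vs_common_p"] == pytest.approx(
            fisher_two_sided_oracle(20, 12, 91, 191), abs=1e-9
        )

    def test_gwas_counts_as_disease_linked(self, annotations_factory):
        genes = ["A", "B", "C", "D"]
        ann = annotations_factory(genes, gwas_associated=[True, False, False, False])
        out = disease_overlap_summary(evsets_of(rare=genes, common=["C"]), ann)
        assert out["per_set"]["rare"]["n_disease_linked"] == 1

    def test_empty_annotations_give_zero(self, annotations_factory):
        ann = annotations_factory([])
        out = disease_overlap_summary(evsets_of(rare=["X"], common=["Y"]), ann)
        assert out["per_set"]["rare"]["percent"] == 0.0


class TestPopulationAnalysis:
    @staticmethod
    def pop_table(rows):
        """rows: (variant_id, allele counts across populations)"""
        records = []
        for vid, counts in rows:
            for i, ac in enumerate(counts):
                records.append((vid, f"P{i}", ac, 1000))
        return pd.DataFrame(
            records, columns=["variant_id", "population", "allele_count", "allele_number"]
        )

    def test_specificity_calls(self):
        table = self.pop_table([("v1", (5, 0, 0)), ("v2", (5, 1, 0)), ("v3", (0, 0, 0))])
        per_variant, summary = population_specificity(table)
        flags = per_variant.set_index("variant_id")
        assert bool(flags.loc["v1", "population_specific"])
        assert not bool(flags.loc["v2", "population_specific"])
        assert bool(flags.loc["v3", "unobserved"])
        assert summary["n_unobserved"] == 1
        # among observed variants, only v2 of (v1, v2) is non-specific
        assert summary["fraction_not_population_specific"] == pytest.approx(0.5)

    def test_switch_detection_rules(self):
        table = self.pop_table([("v1", (2, 50)), ("v2", (2, 3))])
        assert detect_class_switches(table) == ["v1"]

    def test_allele_count_bounded_by_allele_number(self):
        bad = self.pop_table([("v1", (2000, 0))])
        with pytest.raises(ValueError):
            population_specificity(bad)

    def test_generator_truth_recovered_exactly(self):
        ds = simulate_dataset(small_config(seed=77, population_max_variants=800))
        per_variant, _ = population_specificity(ds.populations)
        found = set(per_variant.loc[per_variant["population_specific"], "variant_id"])
        assert found == ds.truth.population_specific
        assert set(detect_class_switches(ds.populations)) == ds.truth.class_switch

    def test_per_gene_summary_uses_gene_map(self):
        table = self.pop_table([("v1", (5, 0)), ("v2", (5, 3)), ("v3", (1, 2))])
        gene_map = pd.Series({"v1": "G1", "v2": "G1", "v3": "G2"})
        _, summary = population_specificity(table, gene_map)
        per_gene = summary["fraction_not_population_specific_per_gene"]
        assert per_gene == {"G1": 0.5, "G2": 1.0}
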