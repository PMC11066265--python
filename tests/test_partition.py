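import numpy as np
import pandas as pd
import pytest

import estasm
from estasm import CountTable, ValidationError


def table_with_fractions(fracs, total=200_000):
    """Two-sample table whose dataset-wide taxon fractions are ``fracs``."""
    col = np.array([round(f * total) for f in fracs], dtype=np.int64)
    half = col // 2
    return CountTable(["S1", "S2"],
                      [f"T{i}" for i in range(len(fracs))],
                      np.vstack([half, col - half]))


class TestClassifyTaxa:
    def test_threshold_definition(self):
        t = table_with_fractions([0.5 - 0.00055, 0.499, 0.0005, 0.00005])
        part = estasm.classify_taxa(t)
        assert list(part.labels) == ["abundant", "abundant", "intermediate",
                                     "rare"]

    def test_boundaries_are_intermediate(self):
        # taxa sitting exactly at 0.1% and 0.01% of 10,000 reads
        t = CountTable(["S1", "S2"], ["big", "at_01pct", "at_001pct"],
                       np.array([[9989, 10, 1], [0, 0, 0]]))
        part = estasm.classify_taxa(t)
        assert part.labels["at_01pct"] == "intermediate"
        assert part.labels["at_001pct"] == "intermediate"

    def test_bad_thresholds(self, toy_table):
        with pytest.raises(ValidationError):
            estasm.classify_taxa(toy_table, abundant_threshold=0.0001,
                                 rare_threshold=0.001)

    def test_all_zero_taxon_rare_with_warning(self):
        t = CountTable(["S1", "S2"], ["A", "B", "Z"],
                       np.array([[10, 5, 0], [10, 5, 0]]))
        with pytest.warns(UserWarning, match="all-zero"):
            part = estasm.classify_taxa(t)
        assert part.labels["Z"] == "rare"

    def test_bruteforce_scan_on_lognormal_table(self):
        """Labels agree with a one-line threshold scan on 2,000 taxa."""
        rng = np.random.default_rng(8)
        col = np.maximum(1, rng.lognormal(2, 2, size=2000)).astype(np.int64)
        t = CountTable(["S1", "S2"], [f"T{i}" for i in range(2000)],
                       np.vstack([col, col]))
        part = estasm.classify_taxa(t)
        frac = 2 * col / (2 * col.sum())
        oracle = np.where(frac > 0.001, "abundant",
                          np.where(frac < 0.0001, "rare", "intermediate"))
        assert (part.labels.to_numpy() == oracle).all()

    def test_per_sample_mean_basis(self):
        counts = np.array([[99, 1], [1, 99]])
        t = CountTable(["S1", "S2"], ["A", "B"], counts)
        part = estasm.classify_taxa(t, basis="per_sample_mean")
        assert np.allclose(part.rel_abundance, [0.5, 0.5])

    @pytest.mark.parametrize("a_thr", [0.0005, 0.001, 0.005, 0.02])
    def test_monotone_in_abundant_threshold(self, bundle, a_thr):
        base = estasm.classify_taxa(bundle.table, abundant_threshold=0.0004)
        part = estasm.classify_taxa(bundle.table, abundant_threshold=a_thr)
        assert len(part.taxa("abundant")) <= len(base.taxa("abundant"))


class TestPartitionSummary:
    def test_exhaustive_and_exclusive(self, bundle):
        part = estasm.classify_taxa(bundle.table)
        summary = estasm.partition_summary(part, bundle.table)
        assert summary["n_taxa"].sum() == bundle.table.n_taxa
        assert summary["n_sequences"].sum() == bundle.table.total
        assert summary["pct_taxa_exact"].sum() == pytest.approx(100.0)
        assert summary["pct_sequences_exact"].sum() == pytest.approx(100.0)

    def test_percentages_recompute_within_rounding(self, bundle):
        part = estasm.classify_taxa(bundle.table)
        summary = estasm.partition_summary(part, bundle.table)
        for _, row in summary.iterrows():
            assert abs(row["pct_taxa"]
                       - 100 * row["n_taxa"] / bundle.table.n_taxa) <= 0.005

    def test_degenerate_single_class(self):
        summary = estasm.summarize_partition_counts(
            {"abundant": 7}, {"abundant": 1234})
        assert summary.loc["abundant", "pct_taxa"] == 100.00
        assert summary.loc["abundant", "pct_sequences"] == 100.00


class TestSubcommunityTable:
    def test_single_column_subset(self):
        t = table_with_fractions([0.9989, 0.001, 0.0001])
        part = estasm.classify_taxa(t)
        sub = estasm.subcommunity_table(t, part, "abundant")
        assert sub.taxon_ids == ["T0"]
        assert sub.sample_ids == t.sample_ids

    def test_union_reconstitutes_table(self, bundle):
        part = estasm.classify_taxa(bundle.table)
        cols = []
        for which in ("abundant", "intermediate", "rare"):
            if part.taxa(which):
                cols += estasm.subcommunity_table(
                    bundle.table, part, which).taxon_ids
        assert sorted(cols) == sorted(bundle.table.taxon_ids)

    def test_row_sums_match_class_columns(self, bundle):
        part = estasm.classify_taxa(bundle.table)
        sub = estasm.subcommunity_table(bundle.table, part, "rare")
        df = bundle.table.to_dataframe()
        np.testing.assert_array_equal(
            sub.depth, df[part.taxa("rare")].sum(axis=1).to_numpy())

    def test_empty_class_error(self):
        t = table_with_fractions([0.6, 0.4])
        part = estasm.classify_taxa(t)
        with pytest.raises(ValidationError, match="empty"):
            estasm.subcommunity_table(t, part, "rare")


class TestComposition:
    def test_single_phylum(self, bundle):
        tax = pd.DataFrame({"phylum": "OnlyOne", "class": "C"},
                           index=bundle.table.taxon_ids)
        comp = estasm.composition_by_group(bundle.table, tax, bundle.frame)
        assert np.allclose(comp["mean_rel_abundance"], 1.0)

    def test_two_equal_phyla(self):
        counts = np.full((4, 4), 5)
        t = CountTable(list("WXYZ"), list("ABCD"), counts)
        tax = pd.DataFrame({"phylum": ["P1", "P1", "P2", "P2"],
                            "class": ["c"] * 4}, index=list("ABCD"))
        frame = pd.DataFrame({"salinity_group": ["LS", "LS", "HS", "HS"]},
                             index=list("WXYZ"))
        comp = estasm.composition_by_group(t, tax, frame)
        assert np.allclose(comp["mean_rel_abundance"], 0.5)

    def test_matches_group_then_sum_oracle(self, bundle):
        comp = estasm.composition_by_group(bundle.table, bundle.taxonomy,
                                           bundle.frame)
        # independent route: melt, join, aggregate
        rel = pd.DataFrame(bundle.table.relative(),
                           index=bundle.table.sample_ids,
                           columns=bundle.table.taxon_ids)
        long = rel.reset_index(names="sample").melt(
            id_vars="sample", var_name="taxon", value_name="rel")
        long["phylum"] = long["taxon"].map(bundle.taxonomy["phylum"])
        long["group"] = long["sample"].map(bundle.frame["salinity_group"])
        oracle = (long.groupby(["group", "sample", "phylum"])["rel"].sum()
                  .groupby(["group", "phylum"]).mean())
        for _, row in comp.iterrows():
            assert row["mean_rel_abundance"] == pytest.approx(
                oracle.loc[(row["group"], row["phylum"])], abs=1e-12)
        sums = comp.groupby("group")["mean_rel_abundance"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)
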