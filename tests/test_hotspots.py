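import numpy as np
import pandas as pd
import pytest

from ptmfp.hotspots import (
    call_hotspots,
    derive_hotspot_threshold,
    enrichment_vs_random,
    hotspot_summary,
    join_variants,
    pathogenic_benign_summary,
)
from ptmfp.maps import MAP, assign_labels
from ptmfp.types import FamilyAlignment, VariantRecord
from conftest import make_obs


def scored_map(score, kfsc=0, column=1, family="F", known=None):
    m = MAP(family, column, [make_obs("P", 1, "S", known=kfsc > 0, sources=kfsc)])
    assign_labels([m])
    if known is not None:
        m.known_function = known
    m.score = score
    return m


class TestThresholdDerivation:
    def test_ten_equally_spaced_scores(self):
        maps = [scored_map(s / 10, kfsc=12, column=s) for s in range(1, 11)]
        assert derive_hotspot_threshold(maps) == pytest.approx(0.2)

    def test_point_mass(self):
        maps = [scored_map(0.37, kfsc=15, column=i) for i in range(12)]
        assert derive_hotspot_threshold(maps) == pytest.approx(0.37)

    def test_too_few_high_kfsc_errors(self):
        maps = [scored_map(0.5, kfsc=12, column=i) for i in range(5)]
        with pytest.raises(ValueError, match="explicit threshold"):
            derive_hotspot_threshold(maps)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_coverage_contract_holds(self, seed):
        """>= 90% of high-KFSC MAPs score at or above the derived threshold."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 500))
        scores = rng.beta(2, 5, n)
        maps = [scored_map(s, kfsc=11 + int(rng.integers(0, 50)), column=i)
                for i, s in enumerate(scores)]
        t = derive_hotspot_threshold(maps)
        assert (scores >= t).mean() >= 0.90


class TestCallHotspots:
    def make_maps(self):
        return [scored_map(s, column=i, known=(i % 3 == 0))
                for i, s in enumerate([0.1, 0.3, 0.5, 0.7, 0.9])]

    def test_zero_threshold_all_hotspots(self):
        calls = call_hotspots(self.make_maps(), 0.0)
        assert all(c.is_hotspot for c in calls)

    def test_threshold_above_max_none(self):
        calls = call_hotspots(self.make_maps(), 0.95)
        assert not any(c.is_hotspot for c in calls)

    def test_counts_partition_known_plus_unknown(self):
        calls = call_hotspots(self.make_maps(), 0.4)
        summary = hotspot_summary(calls).set_index("label")
        assert (
            summary.loc["all", "n_hotspots"]
            == summary.loc["known", "n_hotspots"] + summary.loc["unknown", "n_hotspots"]
        )

    def test_unscored_map_errors(self):
        m = scored_map(0.5)
        m.score = None
        with pytest.raises(ValueError):
            call_hotspots([m], 0.1)


class TestEnrichment:
    def test_full_set_subset_ratio_exactly_one(self):
        rng = np.random.default_rng(0)
        scores = rng.random(500)
        table = enrichment_vs_random(scores, np.ones(500, bool))
        assert (table["ratio"] == 1.0).all()

    def test_independent_subset_ratio_near_one(self):
        rng = np.random.default_rng(1)
        n = 10_000
        scores = rng.random(n)
        subset = rng.random(n) < 0.3
        table = enrichment_vs_random(scores, subset)
        assert ((table["ratio"] > 0.85) & (table["ratio"] < 1.15)).all()

    def test_top_decile_subset_ratio_ten(self):
        rng = np.random.default_rng(2)
        n = 10_000
        scores = rng.permutation(np.linspace(0, 1, n))
        decile = np.quantile(scores, 0.9)
        subset = scores >= decile
        table = enrichment_vs_random(scores, subset, thresholds=(decile,))
        assert table.loc[0, "ratio"] == pytest.approx(10, rel=0.01)

    def test_pathogenic_like_increases_benign_like_decreases(self):
        """Score-biased subsets reproduce opposite enrichment trends."""
        rng = np.random.default_rng(3)
        n = 10_000
        scores = rng.random(n)
        z = (scores - scores.mean()) / scores.std()
        pathogenic_like = rng.random(n) < 0.05 * np.exp(1.5 * z) / np.exp(1.5 * z).mean()
        benign_like = rng.random(n) < 0.05 * np.exp(-1.5 * z) / np.exp(-1.5 * z).mean()
        tp = enrichment_vs_random(scores, pathogenic_like)["ratio"].to_numpy()
        tb = enrichment_vs_random(scores, benign_like)["ratio"].to_numpy()
        assert (np.diff(tp) > 0).all()
        assert (np.diff(tb) < 0).all()

    def test_empty_subset_errors(self):
        with pytest.raises(ValueError):
            enrichment_vs_random(np.random.default_rng(0).random(10), np.zeros(10, bool))


class TestJoinVariants:
    @pytest.fixture
    def family(self):
        aln = FamilyAlignment("F", [("H1", "AKS-D"), ("M1", "AKSTD")])
        maps = [MAP("F", 3, [make_obs("M1", 3, "S")])]
        return aln, maps

    def test_variant_on_ptm_site_is_type1(self, family):
        aln, maps = family
        records, _ = join_variants(
            maps, [VariantRecord("M1", 3, "S", "A", "pathogenic")], {"F": aln}
        )
        assert len(records) == 1 and records[0].type == 1

    def test_variant_on_aligned_column_is_type2(self, family):
        aln, maps = family
        records, _ = join_variants(
            maps, [VariantRecord("H1", 3, "S", "F", "benign")], {"F": aln}
        )
        assert len(records) == 1 and records[0].type == 2

    def test_variant_off_map_column_dropped(self, family):
        aln, maps = family
        records, report = join_variants(
            maps, [VariantRecord("H1", 1, "A", "V", "benign")], {"F": aln}
        )
        assert records == []
        assert report.iloc[0]["reason"] == "no_map_at_column"

    def test_unknown_uid_dropped_with_reason(self, family):
        aln, maps = family
        records, report = join_variants(
            maps, [VariantRecord("ZZ", 1, "A", "V", "benign")], {"F": aln}
        )
        assert records == [] and report.iloc[0]["reason"] == "uid_not_in_families"

    def test_type1_type2_disjoint_and_exhaustive(self, demo_dataset, demo_run):
        _, result = demo_run
        records = result.variant_records
        assert records, "demo run should join some variants"
        assert all(r.type in (1, 2) for r in records)
        # Type-1 records really sit on observed PTM sites; Type-2 never do
        for r in records:
            on_site = any(
                o.uid == r.variant.uid and o.native_position == r.variant.native_position
                for o in r.map.observations
            )
            assert on_site == (r.type == 1)

    def test_join_invariant_to_family_order(self, family):
        aln, maps = family
        aln2 = FamilyAlignment("G", [("X1", "MMKK"), ("X2", "MMKK")])
        maps2 = maps + [MAP("G", 2, [make_obs("X1", 2, "M")])]
        variants = [
            VariantRecord("M1", 3, "S", "A", "pathogenic"),
            VariantRecord("X2", 2, "M", "T", "benign"),
        ]
        r1, _ = join_variants(maps2, variants, {"F": aln, "G": aln2})
        r2, _ = join_variants(maps2[::-1], variants, {"G": aln2, "F": aln})
        key = lambda rs: sorted((r.variant.uid, r.map.column, r.type) for r in rs)
        assert key(r1) == key(r2)


class TestPathogenicBenignSummary:
    def test_empty_records_all_zero(self):
        table = pathogenic_benign_summary([], threshold=0.196)
        assert (table["n_records"] == 0).all() and (table["n_hotspot"] == 0).all()

    def test_three_to_nine_type_ratio(self, family_records):
        table = pathogenic_benign_summary(family_records, threshold=0.0)
        by_type = table.groupby("type")["n_records"].sum()
        assert by_type[1] == 3 and by_type[2] == 9

    def test_likely_pathogenic_pooled_with_pathogenic(self, family_records):
        table = pathogenic_benign_summary(family_records, threshold=0.0)
        pathogenic_total = table[table.significance == "pathogenic"]["n_records"].sum()
        assert pathogenic_total == 8  # 4 pathogenic + 4 likely_pathogenic


@pytest.fixture
def family_records():
    """3 Type-1 and 9 Type-2 records, mixed significance classes."""
    from ptmfp.hotspots import CoincidenceRecord

    records = []
    sigs = ["pathogenic", "likely_pathogenic"] * 4 + ["benign", "likely_benign"] * 2
    for i in range(12):
        m = MAP("F", i + 1, [make_obs("P", 1, "S")])
        m.score = 0.5
        v = VariantRecord("P", i + 1, "S", "A", sigs[i])
        records.append(CoincidenceRecord(v, m, 1 if i < 3 else 2))
    return records
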