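import numpy as np
import pandas as pd
import pytest

from pleioscan.loci import (HLA_REGION, Locus, apply_novelty_filter,
                            apply_pleiotropy_filters, define_locus,
                            discover_loci, find_sentinels,
                            merge_independent_loci)
from pleioscan.multitrait import MultiTraitResult, ScanDefinition
from pleioscan.significance import z_to_p
from pleioscan.sumstats import KnownAssociation, LDTable


def make_result(rows, traits=("A", "B")):
    """rows: (variant_id, chrom, pos, p_multi [, pA, pB])."""
    recs = []
    for row in rows:
        vid, chrom, pos, p_multi = row[:4]
        rec = {"variant_id": vid, "chrom": str(chrom), "pos": pos, "eaf": 0.3,
               "effect_allele": "C", "other_allele": "A",
               "p_multi": p_multi, "z_multi": 1.0, "direction": "+/+"}
        for k, t in enumerate(traits):
            p = row[4 + k] if len(row) > 4 else 0.5
            rec[f"p_{t}"] = p
            rec[f"z_{t}"] = 1.0
        recs.append(rec)
    return MultiTraitResult(scan=ScanDefinition(tuple(traits)),
                            df=pd.DataFrame(recs))


def greedy_reference(result, p_threshold, ld, window_bp, r2_min):
    """Naive re-implementation: repeated linear scans, no sorting."""
    df = result.df
    claimed, sentinels = set(), []
    while True:
        best = None
        for row in df.itertuples(index=False):
            if row.variant_id in claimed or row.p_multi >= p_threshold:
                continue
            key = (row.p_multi, str(row.chrom), row.pos)
            if best is None or key < best[0]:
                best = (key, row)
        if best is None:
            return sentinels
        sent = best[1]
        sentinels.append(sent.variant_id)
        for row in df.itertuples(index=False):
            same_chrom = str(row.chrom) == str(sent.chrom)
            if (same_chrom and abs(row.pos - sent.pos) <= window_bp) or \
                    ld.r2(row.variant_id, sent.variant_id) > r2_min:
                claimed.add(row.variant_id)


class TestSentinels:
    def test_nearby_significant_variant_absorbed(self):
        result = make_result([("a", 1, 1_000_000, 1e-10),
                              ("b", 1, 1_200_000, 1e-9)])
        assert find_sentinels(result, 5e-8, LDTable()) == ["a"]

    def test_no_significant_variants(self):
        result = make_result([("a", 1, 100, 1e-3)])
        assert find_sentinels(result, 5e-8, LDTable()) == []

    def test_different_chromosomes_stay_separate(self):
        result = make_result([("a", 1, 100, 1e-10), ("b", 2, 100, 1e-9)])
        assert find_sentinels(result, 5e-8, LDTable()) == ["a", "b"]

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_matches_naive_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        rows = [(f"v{i}", "1", int(pos), float(p))
                for i, (pos, p) in enumerate(zip(
                    np.sort(rng.integers(1, 6_000_000, n)),
                    10.0 ** rng.uniform(-12, -4, n)))]
        ld = LDTable()
        for _ in range(10):
            i, j = rng.integers(0, n, 2)
            if i != j:
                ld.add(f"v{i}", f"v{j}", float(rng.uniform(0, 1)))
        result = make_result(rows)
        got = find_sentinels(result, 5e-8, ld)
        want = greedy_reference(result, 5e-8, ld, 1_000_000, 0.2)
        assert got == want


class TestDefineLocus:
    def setup_method(self):
        self.result = make_result([("s", 1, 2_000_000, 1e-10),
                                   ("near", 1, 2_900_000, 0.5),
                                   ("far_ld", 1, 3_500_000, 0.5),
                                   ("far_no_ld", 1, 3_600_000, 0.5)])
        self.ld = LDTable()
        self.ld.add("s", "far_ld", 0.3)
        self.ld.add("s", "far_no_ld", 0.1)

    def test_window_and_ld_rules(self):
        locus = define_locus("s", self.result, self.ld)
        assert "near" in locus.members          # 0.9 Mb, no LD
        assert "far_ld" in locus.members        # 1.5 Mb, r2 = 0.3
        assert "far_no_ld" not in locus.members  # 1.5 Mb, r2 = 0.1
        assert locus.sentinel_id in locus.members
        assert locus.window[1] <= locus.pos <= locus.window[2]


class TestPleiotropyFilters:
    def make_locus(self, chrom="15", pos=101_906_737):
        return Locus(scan=ScanDefinition(("PAD", "LDL")), sentinel_id="s",
                     chrom=chrom, pos=pos, p_multi=3.15e-10, members={"s"},
                     window=(chrom, pos - 1000, pos + 1000))

    def test_published_sentinel_passes_both_verdicts(self):
        # PAD/LDL sentinel: both traits nominal but neither genome-wide
        locus = apply_pleiotropy_filters(
            self.make_locus(), {"PAD": 4.72e-4, "LDL": 6.48e-8})
        assert locus.verdicts["pleiotropy_pass"]
        assert locus.verdicts["not_gw_single"]
        assert locus.verdicts["outside_hla"]

    def test_weak_single_trait_association_fails_pleiotropy(self):
        locus = apply_pleiotropy_filters(
            self.make_locus(), {"PAD": 0.01, "LDL": 1e-4})
        assert not locus.verdicts["pleiotropy_pass"]

    def test_genome_wide_single_trait_fails_novel_filter(self):
        locus = apply_pleiotropy_filters(
            self.make_locus(), {"PAD": 1e-9, "LDL": 1e-4})
        assert not locus.verdicts["not_gw_single"]

    def test_hla_window_excluded(self):
        locus = apply_pleiotropy_filters(
            self.make_locus(chrom="6", pos=30_000_000),
            {"PAD": 1e-4, "LDL": 1e-4})
        assert not locus.verdicts["outside_hla"]
        assert HLA_REGION[0] == "6"

    def test_missing_trait_p_raises(self):
        with pytest.raises(ValueError, match="missing single-trait p"):
            apply_pleiotropy_filters(self.make_locus(), {"PAD": 1e-4})

    def test_reapplication_idempotent(self):
        locus = self.make_locus()
        apply_pleiotropy_filters(locus, {"PAD": 4.72e-4, "LDL": 6.48e-8})
        first = dict(locus.verdicts)
        apply_pleiotropy_filters(locus, {"PAD": 4.72e-4, "LDL": 6.48e-8})
        assert locus.verdicts == first


class TestNoveltyFilter:
    def make_locus(self):
        return Locus(scan=ScanDefinition(("PAD", "LDL")), sentinel_id="s",
                     chrom="1", pos=5_000_000, p_multi=1e-9,
                     members={"s", "m1"}, window=("1", 4_900_000, 5_100_000))

    def test_catalog_hit_at_sentinel_position(self):
        catalog = [KnownAssociation(trait="PAD", variant_id="rsX",
                                    chrom="1", pos=5_000_000)]
        locus = apply_novelty_filter(self.make_locus(), catalog, LDTable(),
                                     member_pos={"s": ("1", 5_000_000),
                                                 "m1": ("1", 5_050_000)})
        assert not locus.verdicts["novel_vs_catalog"]

    def test_distant_unlinked_catalog_entry_is_ignored(self):
        catalog = [KnownAssociation(trait="PAD", variant_id="rsX",
                                    chrom="1", pos=5_600_001)]
        locus = apply_novelty_filter(self.make_locus(), catalog, LDTable(),
                                     member_pos={"s": ("1", 5_000_000),
                                                 "m1": ("1", 5_050_000)})
        assert locus.verdicts["novel_vs_catalog"]

    def test_trait_scoping(self):
        catalog = [KnownAssociation(trait="BMI", variant_id="rsX",
                                    chrom="1", pos=5_000_000)]
        locus = apply_novelty_filter(self.make_locus(), catalog, LDTable(),
                                     member_pos={"s": ("1", 5_000_000),
                                                 "m1": ("1", 5_050_000)})
        assert locus.verdicts["novel_vs_catalog"]

    def test_ld_with_catalog_entry_breaks_novelty(self):
        catalog = [KnownAssociation(trait="LDL", variant_id="rsX",
                                    chrom="2", pos=9_000_000)]
        ld = LDTable()
        ld.add("m1", "rsX", 0.5)
        locus = apply_novelty_filter(self.make_locus(), catalog, ld,
                                     member_pos={"s": ("1", 5_000_000),
                                                 "m1": ("1", 5_050_000)})
        assert not locus.verdicts["novel_vs_catalog"]


class _Item:
    def __init__(self, sid, chrom, pos, p):
        self.sentinel_id, self.chrom, self.pos, self.p_multi = sid, chrom, pos, p


class TestMerging:
    def test_same_chromosome_within_1mb_merges(self):
        items = [_Item("a", "1", 1_000_000, 1e-10),
                 _Item("b", "1", 1_900_000, 1e-9)]
        clusters = merge_independent_loci(items)
        assert len(clusters) == 1
        assert clusters[0][0].sentinel_id == "a"  # representative = lowest p

    def test_transitive_chain_merges(self):
        items = [_Item("a", "1", 1_000_000, 1e-9),
                 _Item("b", "1", 1_900_000, 1e-10),
                 _Item("c", "1", 2_800_000, 1e-8)]
        assert len(merge_independent_loci(items)) == 1

    def test_identical_sentinels_collapse(self):
        items = [_Item("a", "1", 1_000_000, 1e-9),
                 _Item("a", "1", 1_000_000, 1e-8)]
        assert len(merge_independent_loci(items)) == 1

    def test_beyond_1mb_stays_separate(self):
        items = [_Item("a", "1", 1_000_000, 1e-9),
                 _Item("b", "1", 2_100_000, 1e-8)]
        assert len(merge_independent_loci(items)) == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        items = [_Item(f"v{i}", str(rng.integers(1, 4)),
                       int(rng.integers(1, 20_000_000)),
                       float(10.0 ** rng.uniform(-12, -8)))
                 for i in range(25)]
        base = merge_independent_loci(items)
        perm = list(items)
        rng.shuffle(perm)
        shuffled = merge_independent_loci(perm)
        as_sets = lambda cl: sorted(tuple(sorted(x.sentinel_id for x in c)) for c in cl)
        assert as_sets(base) == as_sets(shuffled)


class TestPlantedPanelFiltering:
    def test_only_pleiotropic_locus_survives(self, planted_panel):
        from pleioscan.multitrait import estimate_z_correlation, run_scan
        from pleioscan.sumstats import harmonize_panel
        panel = harmonize_panel(planted_panel.scans)
        R = estimate_z_correlation(panel)
        result = run_scan(panel, ScanDefinition(("PAD", "CAD")), R)
        shared_pos = planted_panel.truth.loci[0]["pos"]
        single_pos = planted_panel.truth.loci[1]["pos"]
        loci = discover_loci(result, 1e-4, planted_panel.ld)
        survivors = []
        for locus in loci:
            apply_pleiotropy_filters(locus, result.trait_p_at(locus.sentinel_id),
                                     nominal_p=5e-3)
            if locus.verdicts["pleiotropy_pass"]:
                survivors.append(locus)
        assert any(abs(l.pos - shared_pos) < 200_000 for l in survivors)
        assert not any(abs(l.pos - single_pos) < 200_000 for l in survivors)
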