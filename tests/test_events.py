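import numpy as np
import pandas as pd
import pytest

from triodel import (
    AnnotationTables,
    DeletionEvent,
    GeneDeletionRecord,
    GeneFlags,
    Region,
    RegionSet,
    Trio,
    annotate_events,
    apply_size_filter,
    merge_contiguous_calls,
    morbid_enrichment,
)
from triodel.trio import PATTERN_INHERITED, SingletonCall, TrioCall


def trio_call(proband: str, region_id: str) -> TrioCall:
    return TrioCall(
        Trio(proband, f"{proband}.f", f"{proband}.m"), region_id, 0, 1, 1, PATTERN_INHERITED
    )


def grid_regions(n: int, chrom: str = "1", length: int = 10_000, gap: int = 2_000) -> RegionSet:
    return RegionSet(
        [
            Region(f"g{j}", chrom, j * (length + gap), j * (length + gap) + length)
            for j in range(n)
        ]
    )


class TestMergeContiguousCalls:
    def test_three_adjacent_regions_one_event(self):
        regions = grid_regions(3, gap=2_500)
        calls = [trio_call("P1", f"g{j}") for j in range(3)]
        events = merge_contiguous_calls(calls, regions)
        assert len(events) == 1
        ev = events[0]
        assert ev.region_ids == ("g0", "g1", "g2")
        assert (ev.start, ev.end) == (regions[0].start, regions[2].end)
        assert ev.sample_ids == ("P1",)

    def test_distant_regions_stay_separate(self):
        regions = RegionSet(
            [Region("a", "1", 0, 10_000), Region("b", "1", 510_000, 520_000)]
        )
        events = merge_contiguous_calls(
            [trio_call("P1", "a"), trio_call("P1", "b")], regions
        )
        assert len(events) == 2

    def test_intervening_uncalled_region_breaks_chain(self):
        regions = grid_regions(3)
        events = merge_contiguous_calls(
            [trio_call("P1", "g0"), trio_call("P1", "g2")], regions
        )
        assert len(events) == 2

    def test_intervening_masked_region_does_not_break_chain(self):
        regions = grid_regions(3)
        mask = [False, True, False]
        events = merge_contiguous_calls(
            [trio_call("P1", "g0"), trio_call("P1", "g2")], regions, region_mask=mask
        )
        assert len(events) == 1
        assert events[0].region_ids == ("g0", "g2")

    def test_chromosome_boundary_breaks_chain(self):
        regions = RegionSet(
            [Region("a", "1", 0, 10_000), Region("b", "2", 2_000, 12_000)]
        )
        events = merge_contiguous_calls(
            [trio_call("P1", "a"), trio_call("P1", "b")], regions
        )
        assert len(events) == 2

    def test_identical_spans_consolidated_across_samples(self):
        regions = grid_regions(2)
        calls = [trio_call(p, g) for p in ("P1", "P2") for g in ("g0", "g1")]
        events = merge_contiguous_calls(calls, regions)
        assert len(events) == 1
        assert events[0].sample_ids == ("P1", "P2")

    def test_different_spans_stay_distinct(self):
        regions = grid_regions(2)
        calls = [trio_call("P1", "g0"), trio_call("P1", "g1"), trio_call("P2", "g0")]
        events = merge_contiguous_calls(calls, regions)
        assert len(events) == 2

    def test_fdel_max_over_member_regions(self):
        from triodel import FdelEntry, FdelTable

        regions = grid_regions(2)
        fdel = FdelTable(
            {
                "g0": FdelEntry(0.001, 1, 0, 1000),
                "g1": FdelEntry(0.003, 3, 0, 1000),
            }
        )
        events = merge_contiguous_calls(
            [trio_call("P1", "g0"), trio_call("P1", "g1")], regions, fdel=fdel
        )
        assert events[0].fdel_max == 0.003

    def test_unknown_region_errors(self):
        with pytest.raises(KeyError):
            merge_contiguous_calls([trio_call("P1", "zz")], grid_regions(2))

    def test_singleton_calls_merge_too(self):
        regions = grid_regions(2)
        events = merge_contiguous_calls(
            [SingletonCall("S1", "g0"), SingletonCall("S1", "g1")], regions
        )
        assert len(events) == 1
        assert events[0].pattern == "singleton"

    @staticmethod
    def brute_force_chains(called_idx, regions, region_mask, max_gap):
        """Independent gap-walk: for each pair of neighbours decide chain/break."""
        chains = []
        for idx in sorted(called_idx):
            if not chains:
                chains.append([idx])
                continue
            prev = chains[-1][-1]
            a, b = regions[prev], regions[idx]
            joinable = (
                a.chrom == b.chrom
                and b.start - a.end <= max_gap
                and all(
                    (k in called_idx) or region_mask[k]
                    for k in range(prev + 1, idx)
                    if regions[k].chrom == a.chrom
                )
            )
            if joinable:
                chains[-1].append(idx)
            else:
                chains.append([idx])
        return chains

    @pytest.mark.parametrize("seed", range(15))
    def test_randomized_against_gap_walk_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # 30 regions over 2 chromosomes with irregular gaps
        regions_list = []
        for chrom in ("1", "2"):
            pos = 0
            for j in range(15):
                length = int(rng.integers(2_000, 30_000))
                regions_list.append(
                    Region(f"c{chrom}g{j}", chrom, pos, pos + length)
                )
                pos += length + int(rng.integers(500, 200_000))
        regions = RegionSet(regions_list)
        region_mask = rng.random(len(regions)) < 0.15
        max_gap = 100_000

        called = {
            i for i in range(len(regions)) if rng.random() < 0.4 and not region_mask[i]
        }
        if not called:
            return
        calls = [trio_call("P1", regions[i].region_id) for i in sorted(called)]
        events = merge_contiguous_calls(
            calls, regions, max_gap=max_gap, region_mask=region_mask
        )
        expected = self.brute_force_chains(called, regions, region_mask, max_gap)
        got = [tuple(regions.index_of(r) for r in ev.region_ids) for ev in events]
        assert sorted(got) == sorted(tuple(c) for c in expected)
        # per-sample events pairwise non-overlapping and sorted
        for e1, e2 in zip(events, events[1:]):
            assert e1.sort_key() <= e2.sort_key()
            if e1.chrom == e2.chrom:
                assert e1.end <= e2.start or e2.end <= e1.start
        # union conservation: bases covered by events == bases of called regions
        called_bases = {
            (regions[i].chrom, b)
            for i in called
            for b in range(regions[i].start, regions[i].end)
        }
        event_bases = set()
        for ev in events:
            for rid in ev.region_ids:
                r = regions.get(rid)
                event_bases |= {(r.chrom, b) for b in range(r.start, r.end)}
        assert event_bases == called_bases


class TestApplySizeFilter:
    def ev(self, size: int) -> DeletionEvent:
        return DeletionEvent("1", 0, size, ("g0",), ("P1",), PATTERN_INHERITED)

    @pytest.mark.parametrize(
        "size,kept", [(21_000, True), (7_999, False), (8_000, True), (750_000, True)]
    )
    def test_boundaries(self, size, kept):
        assert (apply_size_filter([self.ev(size)]) != []) is kept

    def test_monotone_in_min_size(self):
        events = [self.ev(s) for s in (5_000, 8_000, 21_000, 750_000)]
        prev = len(events)
        for min_size in (1, 6_000, 8_000, 100_000, 10**6):
            n = len(apply_size_filter(events, min_size=min_size))
            assert n <= prev
            prev = n

    def test_bad_min_size(self):
        with pytest.raises(ValueError):
            apply_size_filter([], min_size=0)


class TestAnnotateEvents:
    @pytest.fixture
    def regions(self) -> RegionSet:
        return RegionSet(
            [
                Region("g0", "1", 100_000, 150_000, "GENEX"),
                Region("g1", "1", 160_000, 200_000, "GENEY"),
            ]
        )

    def ev(self, samples=("P1",), region_ids=("g0", "g1")) -> DeletionEvent:
        return DeletionEvent("1", 100_000, 200_000, tuple(region_ids), tuple(samples),
                             PATTERN_INHERITED)

    def test_segdup_intersection(self, regions):
        annot = AnnotationTables(segdups=[("1", 150_000, 160_000)])
        (out,) = annotate_events([self.ev()], annot, regions)
        assert out.segdup_overlap is True

    def test_segdup_touching_only_no_overlap(self, regions):
        annot = AnnotationTables(segdups=[("1", 200_000, 210_000)])  # abuts, half-open
        (out,) = annotate_events([self.ev()], annot, regions)
        assert out.segdup_overlap is False

    def test_roh_containment(self, regions):
        annot = AnnotationTables(roh={"P1": [("1", 0, 3_000_000)]})
        (out,) = annotate_events([self.ev()], annot, regions)
        assert out.roh_overlap is True

    def test_short_roh_run_ignored(self, regions):
        annot = AnnotationTables(roh={"P1": [("1", 90_000, 250_000)]})  # < 2 Mb
        (out,) = annotate_events([self.ev()], annot, regions)
        assert out.roh_overlap is False

    def test_partial_roh_overlap_is_not_containment(self, regions):
        annot = AnnotationTables(roh={"P1": [("1", 150_000, 4_000_000)]})
        (out,) = annotate_events([self.ev()], annot, regions)
        assert out.roh_overlap is False

    def test_missing_roh_data_unknown_not_false(self, regions):
        annot = AnnotationTables(roh={})
        (out,) = annotate_events([self.ev()], annot, regions)
        assert out.roh_overlap is None

    def test_mixed_known_unknown_stays_unknown(self, regions):
        annot = AnnotationTables(roh={"P1": []})
        (out,) = annotate_events([self.ev(samples=("P1", "P2"))], annot, regions)
        assert out.roh_overlap is None

    def test_gene_and_omim_flags(self, regions):
        annot = AnnotationTables(
            gene_flags={"GENEY": GeneFlags(omim_morbid=True, omim_ar=True)}
        )
        (out,) = annotate_events([self.ev()], annot, regions)
        assert out.genes == ("GENEX", "GENEY")
        assert out.omim_morbid is True and out.omim_ar is True

    def test_unflagged_genes(self, regions):
        (out,) = annotate_events([self.ev()], AnnotationTables(), regions)
        assert out.omim_morbid is False and out.omim_ar is False


class TestMorbidEnrichment:
    def annot(self) -> AnnotationTables:
        return AnnotationTables(
            gene_flags={
                "M1": GeneFlags(omim_morbid=True, omim_ar=True),
                "M2": GeneFlags(omim_morbid=True, omim_ar=False),
                "N1": GeneFlags(omim_morbid=False, omim_ar=False),
            }
        )

    def test_all_morbid_proportion_one(self):
        records = [GeneDeletionRecord("M1", 0.001, 10_000) for _ in range(5)]
        table = morbid_enrichment(records, self.annot(), [0, 0.005, 0.05], [0, 8_000, 10**6])
        nonempty = table[table["n_morbid"] + table["n_non_morbid"] > 0]
        assert (nonempty["proportion_morbid"] == 1.0).all()

    def test_construction_by_design_enrichment(self):
        # morbid genes only in the (rare, large) stratum; non-morbid spread evenly
        rng = np.random.default_rng(2)
        records = [
            GeneDeletionRecord("M1", float(rng.uniform(0, 0.005)), int(rng.integers(8_000, 500_000)))
            for _ in range(30)
        ]
        for fdel_lo, fdel_hi, size_lo, size_hi in [
            (0, 0.005, 100, 8_000), (0.005, 0.05, 100, 8_000), (0.005, 0.05, 8_000, 500_000),
            (0, 0.005, 8_000, 500_000),
        ]:
            records += [
                GeneDeletionRecord("N1", float(rng.uniform(fdel_lo, fdel_hi)),
                                   int(rng.integers(size_lo, size_hi)))
                for _ in range(10)
            ]
        table = morbid_enrichment(records, self.annot(), [0, 0.005, 0.05], [0, 8_000, 10**6])
        # direct tabulation oracle
        def cell(fdel_rare: bool, large: bool):
            m = n = 0
            for r in records:
                if (r.fdel < 0.005) == fdel_rare and (r.size >= 8_000) == large:
                    if r.gene_symbol.startswith("M"):
                        m += 1
                    else:
                        n += 1
            return m, n, (m / (m + n) if m + n else np.nan)

        props = table["proportion_morbid"].to_numpy().reshape(2, 2)
        for i, rare in enumerate([True, False]):
            for j, large in enumerate([False, True]):
                m, n, p = cell(rare, large)
                row = table.iloc[i * 2 + j]
                assert (row["n_morbid"], row["n_non_morbid"]) == (m, n)
        # maximal proportion in the (rare, large) cell
        assert np.nanargmax(props) == 1  # row 0 (rare), col 1 (large)

    def test_empty_records(self):
        table = morbid_enrichment([], self.annot(), [0, 1], [0, 100])
        assert (table["n_morbid"] == 0).all()
        assert table["proportion_morbid"].isna().all()

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            morbid_enrichment([], self.annot(), [0.5, 0.1], [0, 100])
        with pytest.raises(ValueError):
            morbid_enrichment([], self.annot(), [0, 1], [100, 0])
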