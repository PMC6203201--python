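import numpy as np
import pandas as pd
import pytest

from apakit.apa import (
    AtlasOverlapError,
    GeneAPAResult,
    SHIFT_LENGTHENED,
    SHIFT_SHORTENED,
    SHIFT_UNCHANGED,
    UR_APA,
    UTR_APA,
    aggregate_gene_counts,
    assign_read_ends,
    call_apa_cohort,
    call_apa_shift,
    classify_apa_type,
    compute_rud,
    filter_sites,
    overlap_shift_sets,
    relative_site_usage,
    summarize_cohort,
)
from apakit.io import GeneSiteMap, PolyASite, SiteCountMatrix, build_gene_site_maps


class TestAssignReadEnds:
    def test_cluster_boundaries_inclusive(self, two_site_atlas):
        reads = pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "strand": ["+"] * 4,
                "pos": [95, 115, 94, 116],  # both edges in, both neighbours out
            }
        )
        res = assign_read_ends(reads, two_site_atlas)
        assert res.matrix.counts.loc["gA_s1"].sum() == 2
        assert res.n_unassigned == 2

    def test_strand_mismatch_unassigned(self, two_site_atlas):
        reads = pd.DataFrame({"chrom": ["chr1"], "strand": ["-"], "pos": [100]})
        res = assign_read_ends(reads, two_site_atlas)
        assert res.n_assigned == 0 and res.n_unassigned == 1

    def test_matches_brute_force_interval_scan(self, two_site_atlas):
        rng = np.random.default_rng(7)
        reads = pd.DataFrame(
            {
                "chrom": "chr1",
                "strand": rng.choice(["+", "-"], size=1000),
                "pos": rng.integers(1, 1000, size=1000),
            }
        )
        res = assign_read_ends(reads, two_site_atlas)
        # oracle: per-read linear scan over all clusters
        expected = {s.site_id: 0 for s in two_site_atlas}
        unassigned = 0
        for _, r in reads.iterrows():
            hits = [
                s.site_id
                for s in two_site_atlas
                if s.chrom == r["chrom"]
                and s.strand == r["strand"]
                and s.cluster_start <= r["pos"] <= s.cluster_end
            ]
            if hits:
                expected[hits[0]] += 1
            else:
                unassigned += 1
        for sid, n in expected.items():
            assert res.matrix.counts.loc[sid].sum() == n
        assert res.n_unassigned == unassigned

    def test_overlapping_clusters_rejected(self):
        atlas = [
            PolyASite("a", "g", "chr1", "+", 100, 200, 150, "TE"),
            PolyASite("b", "g", "chr1", "+", 150, 250, 200, "TE"),
        ]
        with pytest.raises(AtlasOverlapError):
            assign_read_ends(pd.DataFrame({"chrom": [], "strand": [], "pos": []}), atlas)


class TestFilterSites:
    def test_count_threshold_boundary(self, two_site_atlas, sample_sheet):
        counts = pd.DataFrame(
            {"P_r1": [9, 10, 3, 100], "P_r2": 0, "Q_r1": 0, "Q_r2": 0},
            index=pd.Index([s.site_id for s in two_site_atlas], name="site_id"),
        )
        m = SiteCountMatrix(counts, sample_sheet)
        kept = filter_sites(m, two_site_atlas, min_total=10)
        assert kept.site_ids == ["gA_s2", "gB_s2"]  # 9 dropped, 10 kept (inclusive)

    def test_all_pass_is_identity(self, two_site_matrix, two_site_atlas):
        kept = filter_sites(two_site_matrix, two_site_atlas)
        pd.testing.assert_frame_equal(kept.counts, two_site_matrix.counts)

    def test_single_site_gene_excluded_from_calling_kept_in_aggregation(
        self, two_site_atlas, sample_sheet
    ):
        counts = pd.DataFrame(
            {"P_r1": [100, 100, 5, 100], "P_r2": 100, "Q_r1": 100, "Q_r2": 100},
            index=pd.Index([s.site_id for s in two_site_atlas], name="site_id"),
        )
        counts.loc["gB_s1"] = [5, 0, 0, 0]  # gB proximal fails the gate
        m = SiteCountMatrix(counts, sample_sheet)
        maps = build_gene_site_maps(two_site_atlas)
        kept = filter_sites(m, two_site_atlas)
        results = call_apa_cohort(kept, maps, "P", "Q")
        assert {r.gene_id for r in results} == {"gA"}
        agg = aggregate_gene_counts(m, maps)  # pre-filter counts
        assert "gB" in agg.index


class TestRUD:
    def test_direct_formula(self, two_site_matrix, two_site_atlas):
        maps = build_gene_site_maps(two_site_atlas)
        rud = compute_rud(two_site_matrix, maps["gA"])
        assert rud["P_r1"] == pytest.approx(70 / 100)

    def test_zero_distal_gives_zero(self, two_site_atlas, sample_sheet):
        counts = pd.DataFrame(
            {"P_r1": [50, 0, 1, 1], "P_r2": 1, "Q_r1": 1, "Q_r2": 1},
            index=pd.Index([s.site_id for s in two_site_atlas], name="site_id"),
        )
        m = SiteCountMatrix(counts, sample_sheet)
        maps = build_gene_site_maps(two_site_atlas)
        assert compute_rud(m, maps["gA"])["P_r1"] == 0.0

    def test_zero_total_is_missing_not_zero(self, two_site_atlas, sample_sheet):
        counts = pd.DataFrame(
            {"P_r1": [0, 0, 1, 1], "P_r2": [10, 30, 1, 1], "Q_r1": 1, "Q_r2": 1},
            index=pd.Index([s.site_id for s in two_site_atlas], name="site_id"),
        )
        m = SiteCountMatrix(counts, sample_sheet)
        maps = build_gene_site_maps(two_site_atlas)
        rud = compute_rud(m, maps["gA"])
        assert np.isnan(rud["P_r1"]) and rud["P_r2"] == pytest.approx(0.75)

    def test_minus_strand_distal_is_genomic_leftmost(self, two_site_atlas, sample_sheet):
        # gB on minus strand: distal = gB_s2 at rep 600 (leftmost)
        counts = pd.DataFrame(
            {"P_r1": [1, 1, 20, 80], "P_r2": 1, "Q_r1": 1, "Q_r2": 1},
            index=pd.Index([s.site_id for s in two_site_atlas], name="site_id"),
        )
        m = SiteCountMatrix(counts, sample_sheet)
        maps = build_gene_site_maps(two_site_atlas)
        rud = compute_rud(m, maps["gB"])
        # oracle: transcript order by brute-force strand-aware sort
        ordered = sorted(
            [s for s in two_site_atlas if s.gene_id == "gB"],
            key=lambda s: s.rep_pos,
            reverse=True,
        )
        distal = counts.loc[ordered[-1].site_id, "P_r1"]
        total = counts.loc[[s.site_id for s in ordered], "P_r1"].sum()
        assert rud["P_r1"] == pytest.approx(distal / total) == pytest.approx(0.8)


class TestCallShift:
    def _series(self, vals):
        return pd.Series(vals, index=["P_r1", "P_r2", "Q_r1", "Q_r2"])

    def test_threshold_arithmetic(self, sample_sheet):
        rud = self._series([0.50, 0.50, 0.56, 0.56])
        mean, delta, call = call_apa_shift(rud, sample_sheet, "P", "Q")
        assert delta == pytest.approx(0.06)
        assert call == SHIFT_LENGTHENED

    def test_threshold_is_strict(self, sample_sheet):
        rud = self._series([0.50, 0.50, 0.55, 0.55])
        _, delta, call = call_apa_shift(rud, sample_sheet, "P", "Q")
        assert delta == pytest.approx(0.05)
        assert call == SHIFT_UNCHANGED

    def test_replicates_averaged_before_differencing(self, sample_sheet):
        rud = self._series([0.4, 0.6, 0.5, 0.5])
        mean, delta, call = call_apa_shift(rud, sample_sheet, "P", "Q")
        assert mean["P"] == pytest.approx(0.5)
        assert call == SHIFT_UNCHANGED

    def test_condition_with_no_defined_rud_skipped(self, sample_sheet):
        rud = self._series([np.nan, np.nan, 0.5, 0.5])
        assert call_apa_shift(rud, sample_sheet, "P", "Q") is None


class TestClassifyAPAType:
    @pytest.mark.parametrize("annot,expected", [("TE", UTR_APA), ("IN", UR_APA), ("EX", UR_APA)])
    def test_proximal_class_drives_call(self, annot, expected):
        gm = GeneSiteMap(
            "g",
            (
                PolyASite("p", "g", "chr1", "+", 95, 105, 100, annot),
                PolyASite("d", "g", "chr1", "+", 195, 205, 200, "TE"),
            ),
        )
        assert classify_apa_type(gm) == expected


class TestRelativeSiteUsage:
    def _three_site(self):
        sites = tuple(
            PolyASite(f"s{i}", "g", "chr1", "+", 100 * i - 5, 100 * i + 5, 100 * i, "TE")
            for i in (1, 2, 3)
        )
        return GeneSiteMap("g", sites)

    def test_direct_normalization(self):
        gm = self._three_site()
        samples = pd.DataFrame(
            {"condition": ["P"], "replicate": [1], "timepoint_h": [np.nan]},
            index=pd.Index(["P_r1"], name="sample_id"),
        )
        counts = pd.DataFrame({"P_r1": [10, 20, 70]}, index=["s1", "s2", "s3"])
        m = SiteCountMatrix(counts, samples)
        usage = relative_site_usage(m, gm, ["P"])
        assert usage["P"] == pytest.approx([0.1, 0.2, 0.7])

    def test_replicate_average_matches_oracle_mean(self):
        gm = self._three_site()
        samples = pd.DataFrame(
            {"condition": ["P", "P"], "replicate": [1, 2], "timepoint_h": np.nan},
            index=pd.Index(["P_r1", "P_r2"], name="sample_id"),
        )
        counts = pd.DataFrame(
            {"P_r1": [10, 20, 70], "P_r2": [50, 25, 25]}, index=["s1", "s2", "s3"]
        )
        m = SiteCountMatrix(counts, samples)
        usage = relative_site_usage(m, gm, ["P"])["P"]
        oracle = (np.array([0.1, 0.2, 0.7]) + np.array([0.5, 0.25, 0.25])) / 2
        assert usage == pytest.approx(oracle)
        assert usage.sum() == pytest.approx(1.0, abs=1e-9)


class TestAggregation:
    def test_column_sums_conserved(self, two_site_matrix, two_site_atlas):
        maps = build_gene_site_maps(two_site_atlas)
        agg = aggregate_gene_counts(two_site_matrix, maps)
        assert agg.loc["gA", "P_r1"] == 100
        pd.testing.assert_series_equal(
            agg.sum(axis=0), two_site_matrix.counts.sum(axis=0), check_names=False
        )


def _result(gene, call, apa_class=UTR_APA):
    return GeneAPAResult(gene, 2, call, 0.1 if call == SHIFT_LENGTHENED else -0.1,
                         apa_class=apa_class)


class TestSummarizeCohort:
    def test_published_style_ratios(self):
        results = (
            [_result(f"L{i}", SHIFT_LENGTHENED, UTR_APA) for i in range(572)]
            + [_result(f"U{i}", SHIFT_LENGTHENED, UR_APA) for i in range(56)]
            + [_result(f"S{i}", SHIFT_SHORTENED) for i in range(86)]
        )
        s = summarize_cohort(results)
        assert (s.n_significant, s.n_lengthened) == (714, 628)
        assert s.pct_lengthened == 88
        assert s.pct_utr_apa == 91

    def test_no_significant_gives_na(self):
        s = summarize_cohort([_result("g", SHIFT_UNCHANGED)])
        assert s.n_significant == 0
        assert s.pct_lengthened is None and s.pct_utr_apa is None


class TestOverlap:
    def test_reported_fractions(self):
        universe = {f"g{i}" for i in range(2000)}
        set_a = {f"g{i}" for i in range(626)}
        set_b = {f"g{i}" for i in range(400, 800)}  # intersection 226
        res = overlap_shift_sets(set_a, set_b, universe)
        assert res.n_intersection == 226
        assert round(100 * res.fraction_a) == 36

    def test_identity_overlap(self):
        universe = {f"g{i}" for i in range(50)}
        s = {f"g{i}" for i in range(10)}
        res = overlap_shift_sets(s, s, universe)
        assert res.fraction_a == 1.0
        assert 0 < res.p_enrich < 1e-8

    def test_subset_of_universe_enforced(self):
        with pytest.raises(ValueError):
            overlap_shift_sets({"x"}, set(), {"y"})
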