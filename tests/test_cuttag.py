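"""Genome tiling, region categorization, normalization and NB testing."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasequant.cuttag import (
    categorize_regions,
    compute_size_factors,
    median_of_ratios,
    merge_intervals,
    nb_differential,
    summarize_categories,
    tile_genome,
)
from phasequant.synthetic import CountSimSpec, generate_counts


def intervals(rows):
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


def brute_force_categorize(wt_rows, kd_rows, bin_rows):
    """O(n^2) oracle: merge pooled peaks by pairwise sweeps, then label by
    pairwise overlap against the raw condition peak lists."""

    def overlaps(a, b):
        return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]

    pooled = [list(r) for r in wt_rows + kd_rows]
    merged: list[list] = []
    for iv in sorted(pooled):
        placed = False
        for m in merged:
            if m[0] == iv[0] and iv[1] < m[2] and m[1] < iv[2]:
                m[1], m[2] = min(m[1], iv[1]), max(m[2], iv[2])
                placed = True
                break
        if not placed:
            merged.append(iv)
    # iterate merging until stable (chained strict overlaps)
    changed = True
    while changed:
        changed = False
        out = []
        for m in sorted(merged):
            if out and out[-1][0] == m[0] and m[1] < out[-1][2]:
                out[-1][2] = max(out[-1][2], m[2])
                changed = True
            else:
                out.append(m)
        merged = out
    results = []
    for m in merged:
        in_wt = any(overlaps(m, w) for w in wt_rows)
        in_kd = any(overlaps(m, k) for k in kd_rows)
        cat = "shared" if (in_wt and in_kd) else ("unique_wt" if in_wt else "unique_kd")
        results.append((m[0], m[1], m[2], cat))
    for b in bin_rows:
        if not any(overlaps(b, p) for p in wt_rows + kd_rows):
            results.append((b[0], b[1], b[2], "no_peak_bin"))
    return sorted(results)


class TestTileGenome:
    def test_truncated_terminal_bin(self):
        bins = tile_genome({"chr1": 1250}, bin_size=500)
        assert bins[["start", "end"]].values.tolist() == [[0, 500], [500, 1000], [1000, 1250]]

    def test_single_bin_chromosome(self):
        bins = tile_genome({"chr1": 500}, bin_size=500)
        assert len(bins) == 1 and bins.iloc[0]["end"] == 500

    def test_total_coverage_equals_genome_length(self, rng):
        sizes = {f"chr{i}": int(rng.integers(1, 10_000)) for i in range(8)}
        bins = tile_genome(sizes, bin_size=int(rng.integers(100, 700)))
        assert (bins["end"] - bins["start"]).sum() == sum(sizes.values())

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tile_genome({"chr1": 100}, bin_size=0)
        with pytest.raises(ValueError):
            tile_genome({"chr1": 0})


class TestCategorizeRegions:
    def test_overlapping_peaks_merge_to_shared(self):
        out = categorize_regions(
            intervals([("chr1", 100, 200)]), intervals([("chr1", 150, 250)])
        )
        assert out.values.tolist() == [["chr1", 100, 250, "shared"]]

    def test_disjoint_peaks_stay_unique(self):
        out = categorize_regions(
            intervals([("chr1", 100, 200)]), intervals([("chr1", 300, 400)])
        )
        assert sorted(out["category"]) == ["unique_kd", "unique_wt"]

    def test_bookended_peaks_do_not_share(self):
        """[100,200) and [200,300) overlap by zero bp: not shared."""
        out = categorize_regions(
            intervals([("chr1", 100, 200)]), intervals([("chr1", 200, 300)])
        )
        assert sorted(out["category"]) == ["unique_kd", "unique_wt"]

    def test_no_peak_bins_only_where_no_overlap(self):
        bins = tile_genome({"chr1": 2000}, 500)
        out = categorize_regions(
            intervals([("chr1", 100, 200)]), intervals([("chr1", 600, 650)]), bins
        )
        no_peak = out.query("category == 'no_peak_bin'")
        assert no_peak["start"].tolist() == [1000, 1500]

    def test_malformed_intervals_rejected(self):
        with pytest.raises(ValueError):
            categorize_regions(
                intervals([("chr1", 200, 100)]), intervals([("chr1", 0, 10)])
            )

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        def random_peaks(n):
            rows = []
            for _ in range(n):
                chrom = f"chr{rng.integers(1, 4)}"
                start = int(rng.integers(0, 5000))
                rows.append((chrom, start, start + int(rng.integers(1, 400))))
            return rows
        wt = random_peaks(int(rng.integers(0, 30)))
        kd = random_peaks(int(rng.integers(0, 30)))
        if not wt and not kd:
            wt = random_peaks(1)
        bins = [(f"chr{c}", s, s + 500) for c in (1, 2, 3) for s in range(0, 5500, 500)]
        got = categorize_regions(
            intervals(wt), intervals(kd), intervals(bins)
        )
        expect = brute_force_categorize(wt, kd, bins)
        assert sorted(map(tuple, got.values.tolist())) == expect


class TestSizeFactors:
    def test_symmetric_design_gives_unit_factors(self):
        h3 = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf = compute_size_factors({"a": 1000.0, "b": 1000.0}, h3)
        assert sf.combined == pytest.approx([1.0, 1.0])

    def test_geometric_mean_centering_of_spikein(self):
        h3 = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf = compute_size_factors({"a": 1000.0, "b": 2000.0}, h3)
        assert sf.spikein_factor == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])
        assert sf.combined == pytest.approx(sf.spikein_factor * sf.h3_factor)

    def test_median_of_ratios_recovers_depth(self, rng):
        base = rng.gamma(4, 50, 500)
        mat = np.column_stack([base, base * 2.0, base * 0.5])
        f = median_of_ratios(mat)
        f = f / np.exp(np.mean(np.log(f)))
        assert f == pytest.approx([1.0, 2.0, 0.5], rel=1e-6)

    def test_zero_rows_excluded_from_reference(self):
        mat = np.array([[0, 5], [10, 10], [20, 20], [30, 30]])
        f = median_of_ratios(mat)
        assert f == pytest.approx([1.0, 1.0])

    def test_recovers_generating_depths(self):
        spec = CountSimSpec(seed=6)
        table, sheet, h3 = generate_counts(spec)
        sf = compute_size_factors(
            pd.Series(sheet["spikein_total"].to_numpy(), index=sheet["sample"]),
            h3,
            h3_of=dict(zip(sheet["sample"], sheet["h3_sample"])),
        )
        spike = np.asarray(spec.spikein_depths)
        h3d = np.asarray(spec.h3_depths)
        truth = (spike / np.exp(np.mean(np.log(spike)))) * (
            h3d / np.exp(np.mean(np.log(h3d)))
        )
        assert np.abs(sf.combined / truth - 1).max() < 0.02

    def test_invalid_totals_rejected(self):
        h3 = pd.DataFrame({"a": [1, 2], "b": [1, 2]})
        with pytest.raises(ValueError):
            compute_size_factors({"a": 0.0, "b": 10.0}, h3)

    def test_depth_rescaling_invariance(self):
        """Scaling one sample's counts and spike-in total by c leaves its
        normalized counts unchanged under a fixed reference depth."""
        spec = CountSimSpec(seed=8)
        table, sheet, h3 = generate_counts(spec)
        totals = pd.Series(sheet["spikein_total"].to_numpy(), index=sheet["sample"])
        h3_of = dict(zip(sheet["sample"], sheet["h3_sample"]))
        sf = compute_size_factors(totals, h3, h3_of=h3_of)
        for c in (0.1, 10.0):
            t2 = totals.copy()
            t2.iloc[0] *= c
            sf2 = compute_size_factors(
                t2, h3, h3_of=h3_of, spikein_reference=sf.spikein_reference
            )
            n1 = table["wt_rep1"].to_numpy() / sf.combined[0]
            n2 = (table["wt_rep1"].to_numpy() * c) / sf2.combined[0]
            assert np.abs(n2 / n1 - 1).max() < 1e-9


def toy_sample_sheet():
    return pd.DataFrame(
        {
            "sample": ["wt_rep1", "wt_rep2", "kd_rep1", "kd_rep2"],
            "condition": ["wt", "wt", "kd", "kd"],
            "replicate": [1, 2, 1, 2],
        }
    )


def unit_factors():
    from phasequant.cuttag import SizeFactors

    return SizeFactors(
        samples=["wt_rep1", "wt_rep2", "kd_rep1", "kd_rep2"],
        spikein_factor=np.ones(4),
        h3_factor=np.ones(4),
        spikein_reference=1.0,
    )


class TestNbDifferential:
    def test_identical_counts_give_null_result(self):
        counts = pd.DataFrame(
            {"name": ["r1"], "wt_rep1": [100], "wt_rep2": [100],
             "kd_rep1": [100], "kd_rep2": [100]}
        )
        res = nb_differential(counts, toy_sample_sheet(), unit_factors())
        row = res.table.iloc[0]
        assert row["log2fc_raw"] == pytest.approx(0.0, abs=1e-8)
        assert row["pvalue"] == pytest.approx(1.0, abs=1e-6)
        assert not row["pass_filter"]

    def test_exact_fourfold_change(self):
        counts = pd.DataFrame(
            {"name": ["r1"], "wt_rep1": [100], "wt_rep2": [100],
             "kd_rep1": [400], "kd_rep2": [400]}
        )
        res = nb_differential(counts, toy_sample_sheet(), unit_factors())
        assert res.table.iloc[0]["log2fc_raw"] == pytest.approx(2.0, abs=1e-6)

    def test_basemean_filter_discards_low_regions(self):
        counts = pd.DataFrame(
            {"name": ["lo", "hi"], "wt_rep1": [10, 100], "wt_rep2": [12, 100],
             "kd_rep1": [11, 400], "kd_rep2": [9, 400]}
        )
        res = nb_differential(counts, toy_sample_sheet(), unit_factors())
        assert res.table["tested"].tolist() == [False, True]
        assert np.isnan(res.table.iloc[0]["pvalue"])

    def test_padj_monotone_and_bounded_by_p(self):
        spec = CountSimSpec(seed=10, n_regions={"shared": 200, "unique_wt": 0,
                                                "unique_kd": 0, "no_peak_bin": 0})
        table, sheet, h3 = generate_counts(spec)
        sf = compute_size_factors(
            pd.Series(sheet["spikein_total"].to_numpy(), index=sheet["sample"]),
            h3, h3_of=dict(zip(sheet["sample"], sheet["h3_sample"])),
        )
        res = nb_differential(table.drop(columns="true_lfc"), sheet, sf)
        ok = res.table["tested"] & res.table["pvalue"].notna()
        assert (res.table.loc[ok, "padj"] >= res.table.loc[ok, "pvalue"] - 1e-12).all()

    def test_shrinkage_never_increases_magnitude(self):
        spec = CountSimSpec(
            seed=11, true_lfc={"shared": 1.0},
            n_regions={"shared": 150, "unique_wt": 50, "unique_kd": 0, "no_peak_bin": 100},
        )
        table, sheet, h3 = generate_counts(spec)
        sf = compute_size_factors(
            pd.Series(sheet["spikein_total"].to_numpy(), index=sheet["sample"]),
            h3, h3_of=dict(zip(sheet["sample"], sheet["h3_sample"])),
        )
        res = nb_differential(table.drop(columns="true_lfc"), sheet, sf)
        t = res.table[res.table["tested"]]
        assert (t["log2fc_shrunk"].abs() <= t["log2fc_raw"].abs() + 1e-12).all()

    def test_single_condition_rejected(self):
        counts = pd.DataFrame({"name": ["r"], "a": [5], "b": [6]})
        sheet = pd.DataFrame(
            {"sample": ["a", "b"], "condition": ["wt", "wt"], "replicate": [1, 2]}
        )
        from phasequant.cuttag import SizeFactors

        sf = SizeFactors(["a", "b"], np.ones(2), np.ones(2), 1.0)
        with pytest.raises(ValueError):
            nb_differential(counts, sheet, sf)

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame(
            {"name": ["r"], "wt_rep1": [-1], "wt_rep2": [1],
             "kd_rep1": [1], "kd_rep2": [1]}
        )
        with pytest.raises(ValueError):
            nb_differential(counts, toy_sample_sheet(), unit_factors())


class TestSummarizeCategories:
    def make_result_table(self, rows):
        df = pd.DataFrame(
            rows, columns=["category", "log2fc_raw", "tested", "pass_filter"]
        )
        return df

    def test_all_up_and_none_significant(self):
        all_up = self.make_result_table(
            [("shared", 1.0, True, True), ("shared", 2.0, True, True)]
        )
        s = summarize_categories(all_up)
        assert s.iloc[0]["pct_up"] == 100.0 and s.iloc[0]["pct_down"] == 0.0
        none = self.make_result_table(
            [("shared", 1.0, True, False), ("shared", -1.0, True, False)]
        )
        s = summarize_categories(none)
        assert s.iloc[0]["pct_up"] == 0.0 and s.iloc[0]["pct_down"] == 0.0

    def test_percentages_bounded(self):
        mixed = self.make_result_table(
            [("shared", 1.0, True, True), ("shared", -1.0, True, True),
             ("shared", 0.5, True, False)]
        )
        s = summarize_categories(mixed)
        assert s.iloc[0]["n_tested"] == 3
        assert s.iloc[0]["pct_up"] + s.iloc[0]["pct_down"] <= 100.0

    def test_enriched_category_exceeds_null_category(self):
        """With a true +1 LFC in shared regions only, the shared up% must
        exceed the no-peak-bin up%."""
        spec = CountSimSpec(seed=12, true_lfc={"shared": 1.0})
        table, sheet, h3 = generate_counts(spec)
        sf = compute_size_factors(
            pd.Series(sheet["spikein_total"].to_numpy(), index=sheet["sample"]),
            h3, h3_of=dict(zip(sheet["sample"], sheet["h3_sample"])),
        )
        res = nb_differential(table.drop(columns="true_lfc"), sheet, sf)
        s = summarize_categories(res).set_index("category")
        assert s.loc["shared", "pct_up"] > s.loc["no_peak_bin", "pct_up"]
        assert s.loc["shared", "pct_up"] > 50.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 100_000))
def test_merge_intervals_property(seed):
    """Merged intervals are disjoint, sorted and cover the same bp set."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(rng.integers(1, 40)):
        s = int(rng.integers(0, 2000))
        rows.append(("chr1", s, s + int(rng.integers(1, 300))))
    merged = merge_intervals(intervals(rows))
    starts = merged["start"].to_numpy()
    ends = merged["end"].to_numpy()
    assert (starts[1:] >= ends[:-1]).all()  # disjoint (bookending allowed)
    covered = np.zeros(3000, bool)
    for _, s, e in rows:
        covered[s:e] = True
    merged_cov = np.zeros(3000, bool)
    for s, e in zip(starts, ends):
        merged_cov[s:e] = True
    assert np.array_equal(covered, merged_cov)


class TestAgainstReferenceImplementation:
    def test_raw_lfc_matches_pydeseq2_on_mostly_null_data(self):
        """Per-region raw log2 fold changes agree with an independent NB
        differential implementation (pyDESeq2) when its internally
        re-estimated size factors are unbiased (mostly-null dataset;
        size factors then match the fixed external ones)."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        from phasequant.cuttag import SizeFactors

        spec = CountSimSpec(
            seed=33,
            true_lfc={"shared": 1.0},
            n_regions={"shared": 20, "unique_wt": 0, "unique_kd": 0,
                       "no_peak_bin": 180},
            spikein_depths=(1e6,) * 4,
            h3_depths=(1e6,) * 4,
        )
        table, sheet, _ = generate_counts(spec)
        samples = list(sheet["sample"])
        sf = SizeFactors(samples, np.ones(4), np.ones(4), 1.0)
        mine = nb_differential(table.drop(columns="true_lfc"), sheet, sf).table

        counts = table[samples].T
        counts.index = samples
        counts.columns = table["name"]
        meta = pd.DataFrame(
            {
                "condition": sheet["condition"].values,
                "replicate": sheet["replicate"].astype(str).values,
            },
            index=samples,
        )
        dds = DeseqDataSet(
            counts=counts, metadata=meta, design="~replicate + condition",
            quiet=True,
        )
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "kd", "wt"], quiet=True)
        stats.summary()
        ref = stats.results_df["log2FoldChange"].to_numpy()
        got = mine["log2fc_raw"].to_numpy()
        ok = np.isfinite(ref) & np.isfinite(got)
        assert ok.sum() > 150
        assert np.corrcoef(ref[ok], got[ok])[0, 1] > 0.99
        # the two runs differ only by the normalization gauge (pyDESeq2
        # re-derives size factors internally; ours are fixed externally):
        # after removing that constant offset agreement is per-region tight
        diff = ref[ok] - got[ok]
        assert np.abs(diff - np.median(diff)).mean() < 0.01
        assert np.abs(np.median(diff)) < 0.1


class TestPowerRegression:
    def test_power_at_unit_lfc(self):
        """Regression value: at baseline mean 200, dispersion 0.05, 2 vs 2
        and |true lfc| = 1, a stable majority (~3/4, recorded from the
        first calibration run) of non-null regions pass padj < 0.1."""
        spec = CountSimSpec(seed=77, true_lfc={"shared": 1.0})
        table, sheet, h3 = generate_counts(spec)
        sf = compute_size_factors(
            pd.Series(sheet["spikein_total"].to_numpy(), index=sheet["sample"]),
            h3, h3_of=dict(zip(sheet["sample"], sheet["h3_sample"])),
        )
        res = nb_differential(table.drop(columns="true_lfc"), sheet, sf)
        shared = res.table[res.table["category"] == "shared"]
        assert shared["pass_filter"].mean() >= 0.70
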