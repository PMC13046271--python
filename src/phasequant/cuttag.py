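"""CUT&Tag region quantification: categorization, dual normalization and
negative-binomial differential testing.

The analysis compares histone-modification CUT&Tag signal between a
wild-type (WT) and a knockdown (KD) condition over four region
categories: peaks shared by both conditions, peaks unique to either
condition, and 500-bp genome bins containing no called peak. Counts are
normalized by the product of two per-sample factors — a spike-in factor
(exogenous lambda-phage reads, capturing absolute library scale) and a
histone-H3 factor (median-of-ratios on the matched total-H3 library,
capturing input chromatin) — and tested per region with a negative-
binomial GLM (``~ replicate + condition``, Wald test on the condition
coefficient), Benjamini-Hochberg adjustment, and normal-prior shrinkage
of log2 fold changes. Regions with basemean <= 25 normalized counts are
discarded before testing; significance is adjusted p < 0.1.

Coordinates are BED-style 0-based half-open throughout. Dispersion is
estimated per region by a floored method-of-moments estimator; the
trend/shrinkage machinery of reference differential tools is deliberately
not replicated — the conclusions drawn from this analysis rest on
direction and aggregate behaviour, not on exact dispersion values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SizeFactors",
    "DifferentialResult",
    "tile_genome",
    "merge_intervals",
    "categorize_regions",
    "compute_size_factors",
    "nb_differential",
    "summarize_categories",
]

DISPERSION_FLOOR = 1e-8
DEFAULT_BASEMEAN_MIN = 25.0
DEFAULT_ALPHA = 0.1


def _check_intervals(df: pd.DataFrame, what: str) -> pd.DataFrame:
    df = df.copy()
    required = {"chromosome", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"{what} must have columns {sorted(required)}")
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        raise ValueError(f"{what} contains malformed intervals (need 0 <= start < end)")
    return df.sort_values(["chromosome", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def tile_genome(
    chrom_sizes: Mapping[str, int] | pd.Series | pd.DataFrame,
    bin_size: int = 500,
) -> pd.DataFrame:
    """Tile the genome into non-overlapping half-open bins of ``bin_size`` bp.

    The terminal bin of each chromosome is truncated at the chromosome
    end, so the bins cover the genome exactly.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    if isinstance(chrom_sizes, pd.DataFrame):
        chrom_sizes = dict(zip(chrom_sizes.iloc[:, 0], chrom_sizes.iloc[:, 1]))
    elif isinstance(chrom_sizes, pd.Series):
        chrom_sizes = chrom_sizes.to_dict()
    rows = []
    for chrom, size in chrom_sizes.items():
        size = int(size)
        if size < 1:
            raise ValueError(f"invalid size {size} for chromosome {chrom}")
        starts = np.arange(0, size, bin_size)
        ends = np.minimum(starts + bin_size, size)
        rows.append(
            pd.DataFrame({"chromosome": chrom, "start": starts, "end": ends})
        )
    return pd.concat(rows, ignore_index=True)


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge strictly overlapping (>= 1 bp) intervals per chromosome.

    Bookended intervals ([a, b) and [b, c)) share zero bases and are kept
    separate, consistent with the >= 1 bp overlap rule used for peak
    sharing.
    """
    intervals = _check_intervals(intervals, "intervals")
    out = []
    for chrom, grp in intervals.groupby("chromosome", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s < cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chromosome", "start", "end"])


def _overlaps_any(
    chrom: str, start: int, end: int, by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]
) -> bool:
    """Whether [start, end) overlaps any interval of a sorted, merged set."""
    if chrom not in by_chrom:
        return False
    starts, ends = by_chrom[chrom]
    i = int(np.searchsorted(starts, end, side="left"))
    if i == 0:
        return False
    return bool(ends[i - 1] > start)


def _index_by_chrom(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in df.groupby("chromosome", sort=False)
    }


def categorize_regions(
    peaks_wt: pd.DataFrame,
    peaks_kd: pd.DataFrame,
    bins: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Label genomic regions as shared / unique_wt / unique_kd / no_peak_bin.

    The WT and KD peak sets are pooled and merged; each merged peak is
    ``shared`` when it overlaps (>= 1 bp) at least one peak from each
    condition, otherwise unique to the condition that contributed it.
    When ``bins`` is given (typically 500-bp genome tiles), bins that
    overlap no peak from either condition are appended with category
    ``no_peak_bin``. The returned categories are mutually exclusive.
    """
    peaks_wt = _check_intervals(peaks_wt, "peaks_wt")
    peaks_kd = _check_intervals(peaks_kd, "peaks_kd")
    pooled = pd.concat(
        [peaks_wt[["chromosome", "start", "end"]], peaks_kd[["chromosome", "start", "end"]]],
        ignore_index=True,
    )
    wt_idx = _index_by_chrom(merge_intervals(peaks_wt)) if len(peaks_wt) else {}
    kd_idx = _index_by_chrom(merge_intervals(peaks_kd)) if len(peaks_kd) else {}

    rows = []
    if len(pooled):
        merged = merge_intervals(pooled)
        for chrom, start, end in merged.itertuples(index=False):
            in_wt = _overlaps_any(chrom, start, end, wt_idx)
            in_kd = _overlaps_any(chrom, start, end, kd_idx)
            category = "shared" if (in_wt and in_kd) else (
                "unique_wt" if in_wt else "unique_kd"
            )
            rows.append((chrom, int(start), int(end), category))
    if bins is not None:
        bins = _check_intervals(bins, "bins")
        for chrom, start, end in bins[["chromosome", "start", "end"]].itertuples(
            index=False
        ):
            if not _overlaps_any(chrom, start, end, wt_idx) and not _overlaps_any(
                chrom, start, end, kd_idx
            ):
                rows.append((chrom, int(start), int(end), "no_peak_bin"))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "category"])


@dataclass
class SizeFactors:
    """Per-sample normalization factors.

    ``spikein_factor`` scales by the exogenous spike-in total relative to
    ``spikein_reference`` (by default the geometric mean of the observed
    totals); ``h3_factor`` is the median-of-ratios factor of the matched
    total-H3 library; ``combined`` is their product and is the size
    factor supplied (fixed) to the differential test.

    The reference depth is a constant of the analysis: re-using the same
    reference makes normalized counts invariant to rescaling any single
    sample's counts and spike-in total.
    """

    samples: list[str]
    spikein_factor: np.ndarray
    h3_factor: np.ndarray
    spikein_reference: float

    def __post_init__(self) -> None:
        self.spikein_factor = np.asarray(self.spikein_factor, float)
        self.h3_factor = np.asarray(self.h3_factor, float)
        if (self.spikein_factor <= 0).any() or (self.h3_factor <= 0).any():
            raise ValueError("size factors must be positive")

    @property
    def combined(self) -> np.ndarray:
        return self.spikein_factor * self.h3_factor

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "spikein_factor": self.spikein_factor,
                "h3_factor": self.h3_factor,
                "combined": self.combined,
            }
        )


def median_of_ratios(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (regions x samples matrix).

    Each sample's factor is the median across regions of its counts
    divided by the per-region geometric mean across samples; regions with
    a zero count in any sample are excluded from the reference.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2 or mat.shape[0] == 0:
        raise ValueError("counts must be a non-empty regions x samples matrix")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no region has positive counts in every sample")
    logs = np.log(mat[positive])
    log_ref = logs.mean(axis=1, keepdims=True)
    return np.exp(np.median(logs - log_ref, axis=0))


def compute_size_factors(
    spikein_totals: Mapping[str, float] | pd.Series,
    h3_counts: pd.DataFrame,
    h3_of: Mapping[str, str] | None = None,
    spikein_reference: float | None = None,
) -> SizeFactors:
    """Combine spike-in and H3 normalization into per-sample size factors.

    Parameters
    ----------
    spikein_totals
        Spike-in (exogenous genome) read totals per sample.
    h3_counts
        Per-region counts of the total-H3 libraries (regions x H3 samples).
    h3_of
        Maps each sample to its matched H3 library column; identity
        mapping by default (columns named like the samples).
    spikein_reference
        Fixed reference depth dividing the spike-in totals. Defaults to
        the geometric mean of the supplied totals; pass the value from a
        previous run to keep the normalization gauge fixed.
    """
    totals = pd.Series(spikein_totals, dtype=float)
    if (totals <= 0).any():
        raise ValueError("spike-in totals must be positive")
    samples = list(totals.index)
    if spikein_reference is None:
        spikein_reference = float(np.exp(np.mean(np.log(totals.to_numpy()))))
    if spikein_reference <= 0:
        raise ValueError("spikein_reference must be positive")
    spike_f = totals.to_numpy() / spikein_reference

    h3_f_by_col = pd.Series(
        median_of_ratios(h3_counts), index=list(h3_counts.columns)
    )
    if h3_of is None:
        missing = [s for s in samples if s not in h3_f_by_col.index]
        if missing:
            raise ValueError(
                f"h3_counts has no column for samples {missing}; pass h3_of"
            )
        h3_f = h3_f_by_col.loc[samples].to_numpy()
    else:
        h3_f = h3_f_by_col.loc[[h3_of[s] for s in samples]].to_numpy()
    return SizeFactors(
        samples=samples,
        spikein_factor=spike_f,
        h3_factor=h3_f,
        spikein_reference=spikein_reference,
    )


@dataclass
class DifferentialResult:
    """Per-region differential test results.

    ``table`` columns: ``basemean`` (mean normalized count across
    samples), ``log2fc_raw``, ``lfc_se``, ``log2fc_shrunk``, ``pvalue``,
    ``padj`` (BH across tested regions), ``tested`` (basemean filter) and
    ``pass_filter`` (tested and padj < alpha). Any metadata columns of
    the input (coordinates, ``category``, ``true_lfc``) are carried
    through.
    """

    table: pd.DataFrame
    alpha: float
    basemean_min: float
    prior_sd: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["pass_filter"]]


def _moment_dispersion(norm_counts: np.ndarray, condition: np.ndarray) -> float:
    """Raw per-region method-of-moments NB dispersion.

    Within each condition, alpha is estimated as (s^2 - m) / m^2 on the
    normalized counts and the estimates are averaged over conditions.
    Can be negative (sample variance below the mean); callers floor it.
    """
    alphas = []
    for c in np.unique(condition):
        x = norm_counts[condition == c]
        if len(x) < 2:
            continue
        m = x.mean()
        if m <= 0:
            continue
        v = x.var(ddof=1)
        alphas.append((v - m) / m**2)
    if not alphas:
        return 0.0
    return float(np.mean(alphas))


def _design_matrix(sample_info: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix for ``~ replicate + condition`` (condition last)."""
    cond = sample_info["condition"].to_numpy()
    levels = pd.unique(cond)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {list(levels)}")
    ref, alt = levels[0], levels[1]
    is_alt = (cond == alt).astype(float)
    rep = sample_info["replicate"].to_numpy()
    rep_levels = pd.unique(rep)
    cols = [np.ones(len(sample_info))]
    for r in rep_levels[1:]:
        cols.append((rep == r).astype(float))
    cols.append(is_alt)
    X = np.column_stack(cols)
    return X, is_alt.astype(bool)


def nb_differential(
    counts: pd.DataFrame,
    sample_info: pd.DataFrame,
    factors: SizeFactors,
    basemean_min: float = DEFAULT_BASEMEAN_MIN,
    alpha: float = DEFAULT_ALPHA,
) -> DifferentialResult:
    """Negative-binomial differential test per region.

    Parameters
    ----------
    counts
        Raw counts with one column per sample (columns matching
        ``factors.samples``); other columns are treated as region
        metadata and carried into the result.
    sample_info
        One row per sample with ``sample``, ``condition`` and
        ``replicate`` columns. The first condition encountered is the
        reference; the log2 fold change is alt vs reference.
    factors
        Fixed size factors (not re-estimated here).
    basemean_min, alpha
        Regions with basemean <= ``basemean_min`` are discarded before
        testing; significance requires BH-adjusted p < ``alpha``.

    The model is a NB GLM with log link, design ``~ replicate +
    condition`` and ``log(combined factor)`` offsets; p-values are
    two-sided Wald tests on the condition coefficient. The per-region
    dispersion is a method-of-moments estimate on normalized counts,
    floored at the dataset median of the per-region estimates (and at
    ``DISPERSION_FLOOR``): with few replicates the raw moment estimate
    collapses toward zero for regions whose replicates agree by chance,
    which would inflate Wald statistics; the median floor removes that
    anti-conservative failure mode without modelling a dispersion trend.
    Shrunk log2 fold changes apply a zero-centred normal prior whose sd
    is the upper (95%) quantile of |raw LFC| over tested regions, via
    the ridge factor prior_var / (prior_var + se^2).
    """
    samples = factors.samples
    missing = [s for s in samples if s not in counts.columns]
    if missing:
        raise ValueError(f"counts is missing sample columns {missing}")
    info = sample_info.set_index("sample").loc[samples].reset_index()
    X, _ = _design_matrix(info)
    sf = factors.combined
    offset = np.log(sf)

    raw = counts[samples].to_numpy(dtype=float)
    if (raw < 0).any():
        raise ValueError("counts must be non-negative")
    norm = raw / sf[None, :]
    basemean = norm.mean(axis=1)
    tested = basemean > basemean_min

    n = len(counts)
    lfc = np.full(n, np.nan)
    se = np.full(n, np.nan)
    pval = np.full(n, np.nan)
    condition = info["condition"].to_numpy()
    ln2 = np.log(2.0)
    test_idx = np.nonzero(tested)[0]
    moments = np.array([_moment_dispersion(norm[i], condition) for i in test_idx])
    global_floor = float(np.median(moments)) if len(moments) else 0.0
    global_floor = max(global_floor, 0.0)
    for i, mom in zip(test_idx, moments):
        disp = max(mom, global_floor, DISPERSION_FLOOR)
        try:
            fit = sm.GLM(
                raw[i],
                X,
                family=sm.families.NegativeBinomial(alpha=disp),
                offset=offset,
            ).fit()
            lfc[i] = fit.params[-1] / ln2
            se[i] = fit.bse[-1] / ln2
            z = fit.params[-1] / fit.bse[-1] if fit.bse[-1] > 0 else 0.0
            pval[i] = 2.0 * stats.norm.sf(abs(z))
        except Exception:  # noqa: BLE001 - degenerate fits stay NaN
            pass

    padj = np.full(n, np.nan)
    ok = tested & np.isfinite(pval)
    if ok.any():
        padj[ok] = multipletests(pval[ok], method="fdr_bh")[1]

    finite_lfc = np.abs(lfc[np.isfinite(lfc)])
    prior_sd = float(np.quantile(finite_lfc, 0.95)) if len(finite_lfc) else 0.0
    prior_sd = max(prior_sd, 1e-6)
    shrink = prior_sd**2 / (prior_sd**2 + se**2)
    lfc_shrunk = lfc * shrink

    meta = counts.drop(columns=samples)
    table = meta.copy()
    table["basemean"] = basemean
    table["log2fc_raw"] = lfc
    table["lfc_se"] = se
    table["log2fc_shrunk"] = lfc_shrunk
    table["pvalue"] = pval
    table["padj"] = padj
    table["tested"] = tested
    table["pass_filter"] = tested & (padj < alpha)
    return DifferentialResult(
        table=table, alpha=alpha, basemean_min=basemean_min, prior_sd=prior_sd
    )


def summarize_categories(
    result: DifferentialResult | pd.DataFrame,
    category_col: str = "category",
) -> pd.DataFrame:
    """Per-category counts of tested regions and % significantly up / down.

    A region counts as up when it passes the filters with log2fc_raw > 0
    and down when < 0; percentages are relative to the number of tested
    regions in the category, so up% + down% <= 100.
    """
    table = result.table if isinstance(result, DifferentialResult) else result
    if len(table) == 0:
        raise ValueError("empty differential result")
    if category_col not in table.columns:
        raise ValueError(f"no {category_col!r} column in result")
    rows = []
    for cat, grp in table.groupby(category_col, sort=False):
        tested = grp[grp["tested"]]
        sig = tested[tested["pass_filter"]]
        n_tested = len(tested)
        n_up = int((sig["log2fc_raw"] > 0).sum())
        n_down = int((sig["log2fc_raw"] < 0).sum())
        rows.append(
            {
                "category": cat,
                "n_tested": n_tested,
                "n_up": n_up,
                "n_down": n_down,
                "pct_up": 100.0 * n_up / n_tested if n_tested else 0.0,
                "pct_down": 100.0 * n_down / n_tested if n_tested else 0.0,
            }
        )
    return pd.DataFrame(rows)
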