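"""Genomic-feature enrichment of extreme-IPD loci.

For each region class the fraction of eligible bases that are feature loci
is compared with the genome-wide fraction: fold change = (k/n) / p0 with a
two-sided binomial test (number of trials n = eligible bases in the region,
success probability p0 = genome-wide locus fraction, successes k = loci in
the region).  Eligibility means passing the per-strand valid-IPD coverage
filter, so region "size" counts eligible bases, not raw length (a raw-length
mode is available).  High- and low-IPD loci are tested separately;
q-values are Benjamini-Hochberg across region labels within a class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .extremes import ExtremeLociSet
from .siteagg import SITE_KEY


@dataclass(frozen=True)
class GenomicRegionSet:
    """Labelled intervals (0-based half-open) on the reference."""

    label: str
    intervals: pd.DataFrame  # columns contig, start, end

    def __post_init__(self) -> None:
        iv = self.intervals
        if len(iv) and not (iv["start"] < iv["end"]).all():
            raise ValueError(f"region set {self.label!r} has start >= end")

    def total_length(self) -> int:
        merged = _merge_intervals(self.intervals)
        return int((merged["end"] - merged["start"]).sum())


def regions_from_table(table: pd.DataFrame,
                       label_column: str) -> list[GenomicRegionSet]:
    """Split a BED/GFF3 interval table into one region set per label."""
    return [GenomicRegionSet(str(label),
                             grp[["contig", "start", "end"]].reset_index(drop=True))
            for label, grp in table.groupby(label_column, sort=True)]


def _merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for contig, grp in intervals.groupby("contig", sort=True):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((contig, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((contig, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def points_in_regions(points: pd.DataFrame,
                      intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask of which (contig, pos) points fall inside the intervals."""
    merged = _merge_intervals(intervals)
    mask = np.zeros(len(points), dtype=bool)
    pos_all = points["pos"].to_numpy(np.int64)
    for contig, grp in merged.groupby("contig", sort=False):
        sel = (points["contig"] == contig).to_numpy()
        if not sel.any():
            continue
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        pos = pos_all[sel]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        mask[sel] = ok
    return mask


def binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Two-sided binomial p by the minimum-likelihood rule: the sum of all
    Binomial(n, p0) point masses not exceeding pmf(k)."""
    return float(stats.binomtest(k, n, p0).pvalue)


def region_enrichment(
    loci: ExtremeLociSet | pd.DataFrame,
    regions: list[GenomicRegionSet],
    eligible_sites: pd.DataFrame,
    use_eligible_size: bool = True,
) -> pd.DataFrame:
    """Fold change and two-sided binomial test of locus density per region.

    Returns one row per (label, class) with columns label, class, n, k, p0,
    fold, p, q, testable.  Rows with p0 = 0 or n = 0 are flagged not
    testable and excluded from the BH adjustment.
    """
    table = loci.loci if isinstance(loci, ExtremeLociSet) else loci
    if "class" not in table.columns:
        table = table.assign(**{"class": "all"})
    eligible = eligible_sites[SITE_KEY].drop_duplicates().reset_index(drop=True)
    total_eligible = len(eligible)
    if total_eligible == 0:
        raise ValueError("no eligible sites")

    region_masks = {rs.label: points_in_regions(eligible, rs.intervals)
                    for rs in regions}
    region_raw_sizes = {rs.label: rs.total_length() for rs in regions}

    rows = []
    for cls, cls_loci in table.groupby("class", sort=True):
        cls_pts = cls_loci[SITE_KEY].drop_duplicates().reset_index(drop=True)
        p0 = len(cls_pts) / total_eligible
        for rs in regions:
            if use_eligible_size:
                n = int(region_masks[rs.label].sum())
            else:
                n = 2 * region_raw_sizes[rs.label]  # both strands
            k = int(points_in_regions(cls_pts, rs.intervals).sum())
            testable = n > 0 and p0 > 0
            if testable:
                fold = (k / n) / p0
                p = binomial_two_sided(k, n, p0)
            else:
                fold, p = np.nan, np.nan
            rows.append((rs.label, cls, n, k, p0, fold, p, testable))
    out = pd.DataFrame(rows, columns=["label", "class", "n", "k", "p0",
                                      "fold", "p", "testable"])
    out["q"] = np.nan
    for cls in out["class"].unique():
        sel = (out["class"] == cls) & out["testable"]
        if sel.any():
            out.loc[sel, "q"] = stats.false_discovery_control(
                out.loc[sel, "p"].to_numpy(), method="bh")
    return out


def fold_change_correlation(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
) -> tuple[float, float]:
    """Pearson correlation of log2 fold changes over shared region labels.

    The p-value comes from the t transform with n - 2 degrees of freedom.
    Labels with non-positive or missing fold in either table are dropped.
    """
    keys = ["label"]
    if "class" in results_a.columns and "class" in results_b.columns:
        keys = ["label", "class"]
    merged = results_a.merge(results_b, on=keys, suffixes=("_a", "_b"))
    fa = merged["fold_a"].to_numpy(float)
    fb = merged["fold_b"].to_numpy(float)
    ok = np.isfinite(fa) & np.isfinite(fb) & (fa > 0) & (fb > 0)
    if ok.sum() < 3:
        raise ValueError("need at least 3 shared labels with positive folds")
    res = stats.pearsonr(np.log2(fa[ok]), np.log2(fb[ok]))
    return float(res.statistic), float(res.pvalue)
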