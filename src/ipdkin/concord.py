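"""Concordance statistics between kinetics datasets.

Covers three comparisons: motif-profile correlation across datasets,
observed-versus-predicted site IPD agreement (Pearson r, R², RMSE), and the
replicate log2-ratio-versus-coverage table that shows how per-site IPD
estimates stabilise as read coverage grows.

All metrics are computed on log2 IPDs by default (kinetic effects are
multiplicative, and heavy right tails otherwise dominate least-squares
summaries); a linear-scale option is provided.  R² is the coefficient of
determination of the identity-line prediction, 1 - SSres/SStot with the
predicted values taken as given — not the square of r; the two differ
whenever the prediction is biased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .motifkin import MotifProfile
from .siteagg import SITE_KEY


@dataclass(frozen=True)
class ConcordanceStat:
    """Paired-comparison summary: Pearson r with p, R² and RMSE."""

    n: int
    pearson_r: float
    p_r: float
    r2: float
    rmse: float


def _concordance(x: np.ndarray, y: np.ndarray) -> ConcordanceStat:
    """x observed, y predicted/other; values already on the analysis scale."""
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        r, p = np.nan, np.nan
    else:
        res = stats.pearsonr(x, y)
        r, p = float(res.statistic), float(res.pvalue)
    resid = x - y
    sstot = float(((x - x.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / sstot if sstot > 0 else np.nan
    rmse = float(np.sqrt((resid ** 2).mean()))
    return ConcordanceStat(n=int(x.size), pearson_r=r, p_r=p, r2=r2, rmse=rmse)


def profile_correlation(
    profile_a: MotifProfile,
    profile_b: MotifProfile,
    include_upstream: int = 10,
) -> ConcordanceStat:
    """Concordance of two motif profiles over the motif positions plus
    *include_upstream* upstream positions, on mean log2 IPDs.

    Upstream means 5' of the motif on the motif strand (negative relative
    positions).  Positions missing from either profile are skipped.
    """
    if len(profile_a.motif) != len(profile_b.motif):
        raise ValueError("profiles are for motifs of different lengths")
    m = len(profile_a.motif)
    lo = -min(include_upstream, profile_a.flank, profile_b.flank)
    merged = profile_a.table.merge(profile_b.table, on="rel_pos",
                                   suffixes=("_a", "_b"))
    merged = merged[(merged["rel_pos"] >= lo) & (merged["rel_pos"] < m)]
    merged = merged.dropna(subset=["mean_ipd_a", "mean_ipd_b"])
    merged = merged[(merged["n_sites_a"] > 0) & (merged["n_sites_b"] > 0)]
    if len(merged) < 3:
        raise ValueError("fewer than 3 usable paired positions")
    return _concordance(np.log2(merged["mean_ipd_a"].to_numpy()),
                        np.log2(merged["mean_ipd_b"].to_numpy()))


def observed_vs_predicted(
    sites: pd.DataFrame,
    predicted: pd.DataFrame,
    by_base: bool = True,
    log_scale: bool = True,
) -> dict[str, ConcordanceStat]:
    """Agreement between observed site IPDs and a model-predicted table.

    *predicted* is keyed by (contig, pos, strand) and provides either a
    ``model_prediction`` or ``mean_ipd`` column.  Metrics are computed on
    log2 values per base identity (plus ``"all"``); unmatched sites are
    skipped and reported in the ``"all"`` n only implicitly.
    """
    pred_col = ("model_prediction" if "model_prediction" in predicted.columns
                else "mean_ipd")
    pred = predicted[SITE_KEY + [pred_col]].rename(
        columns={pred_col: "predicted"})
    merged = sites[SITE_KEY + ["ref_base", "mean_ipd"]].merge(
        pred, on=SITE_KEY, how="inner")
    if not len(merged):
        raise ValueError("no sites shared between observed and predicted")
    obs = merged["mean_ipd"].to_numpy(float)
    prd = merged["predicted"].to_numpy(float)
    if log_scale:
        obs, prd = np.log2(obs), np.log2(prd)
    out = {"all": _concordance(obs, prd)}
    if by_base:
        base_arr = merged["ref_base"].to_numpy()
        for base in np.unique(base_arr):
            sel = base_arr == base
            if sel.sum() >= 3:
                out[str(base)] = _concordance(obs[sel], prd[sel])
    return out


def replicate_ratio_by_coverage(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    coverage_grid,
) -> pd.DataFrame:
    """Distribution of per-site log2(IPD_b / IPD_a) as a function of the
    minimum valid-IPD coverage required in both datasets.

    For each grid value c the comparison is restricted to sites with
    valid_count >= c in BOTH tables.  Returns one row per grid value with
    n, mean, sd and the quartiles of the log2 ratios; an empty intersection
    gives a row with n = 0.
    """
    grid = sorted(int(c) for c in coverage_grid)
    if not grid:
        raise ValueError("empty coverage grid")
    merged = sites_a[SITE_KEY + ["valid_count", "mean_ipd"]].merge(
        sites_b[SITE_KEY + ["valid_count", "mean_ipd"]],
        on=SITE_KEY, suffixes=("_a", "_b"))
    log_ratio = np.log2(merged["mean_ipd_b"].to_numpy()
                        / merged["mean_ipd_a"].to_numpy())
    cov_min = np.minimum(merged["valid_count_a"].to_numpy(),
                         merged["valid_count_b"].to_numpy())
    rows = []
    for c in grid:
        r = log_ratio[cov_min >= c]
        if r.size == 0:
            rows.append((c, 0, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        q25, q50, q75 = np.percentile(r, [25, 50, 75])
        sd = float(r.std(ddof=1)) if r.size > 1 else np.nan
        rows.append((c, int(r.size), float(r.mean()), sd,
                     float(q25), float(q50), float(q75)))
    return pd.DataFrame(rows, columns=["min_coverage", "n", "mean", "sd",
                                       "q25", "median", "q75"])
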