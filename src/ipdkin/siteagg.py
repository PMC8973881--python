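"""Per-site kinetics: alignment-quality filtering, outlier trimming,
coverage filtering, per-base genome means and log2 IPD histograms.

An observation contributes to a site mean only if it is *valid*: its read
matched the reference at the neighbouring bases and its IPD was not an
outlier of the IPDs at the same locus.  Sites are kept only when at least
``min_valid`` (default 25) valid IPDs remain on the strand, following the
per-strand coverage threshold used throughout the analysis.

Outlier trimming is two-sided Tukey fencing (k = 1.5) on log2 IPDs with
linearly interpolated quartiles.  The rule is deterministic and robust to
the heavy right tail of polymerase pausing; percentile capping can be
substituted through the ``trim`` argument of :func:`aggregate_sites`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .util import BASES

logger = logging.getLogger(__name__)

#: Per-strand valid-IPD coverage threshold applied throughout the analysis.
MIN_VALID_DEFAULT = 25

#: Mapping-quality threshold (Phred scale); alignments must exceed it.
MIN_MAPQ_DEFAULT = 127.0

SITE_KEY = ["contig", "pos", "strand"]


@dataclass(frozen=True)
class AlignmentRecord:
    """One read alignment with its probability of being misplaced."""

    read_id: str
    error_prob: float
    mapq: float

    @classmethod
    def from_error_prob(cls, read_id: str, error_prob: float) -> "AlignmentRecord":
        return cls(read_id, error_prob, mapq_from_error_prob(error_prob))


@dataclass(frozen=True)
class Log2Histogram:
    """Histogram of per-site mean IPDs on the log2 scale."""

    bin_edges: np.ndarray
    counts: np.ndarray
    base_label: str


def mapq_from_error_prob(p: float) -> float:
    """Phred-scaled mapping quality, MapQ = -10 * log10(p).

    *p* is the estimated probability that the alignment is incorrect;
    p = 10**-12.7 gives MapQ 127.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"error probability must be in (0, 1], got {p}")
    return -10.0 * math.log10(p)


def filter_alignments(records, min_mapq: float = MIN_MAPQ_DEFAULT):
    """Keep alignments whose MapQ strictly exceeds *min_mapq*.

    Accepts a DataFrame with a ``mapq`` column or an iterable of objects
    with a ``mapq`` attribute; returns the same kind.
    """
    if isinstance(records, pd.DataFrame):
        return records[records["mapq"] > min_mapq]
    return [r for r in records if r.mapq > min_mapq]


def trim_outliers(values) -> np.ndarray:
    """Drop values outside the Tukey fences of the log2 distribution.

    Fences are [Q1 - 1.5*IQR, Q3 + 1.5*IQR] of log2(values), with quartiles
    by linear interpolation on the sorted sample.  The result is always a
    sub-multiset of the input.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot trim an empty collection")
    lv = np.log2(v)
    q1, q3 = np.percentile(lv, [25.0, 75.0])
    iqr = q3 - q1
    keep = (lv >= q1 - 1.5 * iqr) & (lv <= q3 + 1.5 * iqr)
    return v[keep]


def aggregate_sites(
    observations: pd.DataFrame,
    min_valid: int = MIN_VALID_DEFAULT,
    trim: str = "tukey_log2",
) -> pd.DataFrame:
    """Collapse read-level observations into filtered per-site kinetics.

    Per (contig, pos, strand): observations whose neighbouring bases
    mismatched the reference are dropped, outliers are trimmed, and the
    site is emitted only if at least *min_valid* valid IPDs remain.  Sites
    on reference N are excluded.  Strands are kept separate.

    ``trim`` is ``"tukey_log2"`` (default), ``"none"``, or a callable
    mapping an IPD array to its retained subset (applied per site).

    Returns a DataFrame with columns contig, pos, strand, ref_base,
    valid_count, mean_ipd, ipd_err (standard error of the site mean).
    """
    cols = SITE_KEY + ["ref_base", "ipd"]
    obs = observations.loc[
        observations["neighbors_match"] & (observations["ref_base"] != "N"),
        cols,
    ].copy()

    if len(obs) and trim != "none":
        if callable(trim):
            obs = (obs.groupby(SITE_KEY, group_keys=False, sort=False)
                   .apply(lambda g: g[np.isin(g["ipd"].to_numpy(),
                                              trim(g["ipd"].to_numpy()))],
                          include_groups=True))
        elif trim == "tukey_log2":
            obs = _tukey_trim_vectorized(obs)
        else:
            raise ValueError(f"unknown trim strategy {trim!r}")

    if not len(obs):
        return _empty_sites()
    agg = (obs.groupby(SITE_KEY, sort=True, as_index=False)
           .agg(ref_base=("ref_base", "first"),
                valid_count=("ipd", "size"),
                mean_ipd=("ipd", "mean"),
                ipd_sd=("ipd", "std")))
    agg["ipd_err"] = (agg["ipd_sd"].fillna(0.0)
                      / np.sqrt(agg["valid_count"])).astype(float)
    agg = agg.drop(columns="ipd_sd")
    kept = agg[agg["valid_count"] >= min_valid].reset_index(drop=True)
    logger.info("aggregate_sites: %d/%d sites pass the >=%d valid-IPD filter",
                len(kept), len(agg), min_valid)
    return kept


def _tukey_trim_vectorized(obs: pd.DataFrame) -> pd.DataFrame:
    """Apply per-site log2 Tukey fences without per-group Python calls."""
    log2 = np.log2(obs["ipd"].to_numpy())
    obs = obs.assign(_log2=log2)
    q = (obs.groupby(SITE_KEY, sort=False)["_log2"]
         .quantile([0.25, 0.75]).unstack())
    iqr = q[0.75] - q[0.25]
    fences = pd.DataFrame({"_lo": q[0.25] - 1.5 * iqr,
                           "_hi": q[0.75] + 1.5 * iqr}).reset_index()
    obs = obs.merge(fences, on=SITE_KEY, how="left", copy=False)
    keep = (obs["_log2"] >= obs["_lo"]) & (obs["_log2"] <= obs["_hi"])
    return obs.loc[keep, SITE_KEY + ["ref_base", "ipd"]]


def _empty_sites() -> pd.DataFrame:
    return pd.DataFrame({
        "contig": pd.Series(dtype=str),
        "pos": pd.Series(dtype=np.int64),
        "strand": pd.Series(dtype=str),
        "ref_base": pd.Series(dtype=str),
        "valid_count": pd.Series(dtype=np.int64),
        "mean_ipd": pd.Series(dtype=float),
        "ipd_err": pd.Series(dtype=float),
    })


def genome_base_means(sites: pd.DataFrame) -> pd.DataFrame:
    """Unweighted genome-wide average of per-site mean IPDs by base.

    Strands are pooled.  Returns a DataFrame indexed by base with columns
    ``mean_ipd`` and ``n_sites``; a base with no sites appears with
    n_sites 0 and NaN mean.
    """
    if not len(sites):
        raise ValueError("no sites to average")
    g = sites.groupby("ref_base")["mean_ipd"].agg(["mean", "size"])
    out = g.reindex(list(BASES))
    out.columns = ["mean_ipd", "n_sites"]
    out["n_sites"] = out["n_sites"].fillna(0).astype(np.int64)
    out.index.name = "base"
    return out


def ipd_log2_histogram(
    sites: pd.DataFrame,
    bin_width: float = 0.1,
    by_base: bool = False,
) -> list[Log2Histogram]:
    """Histogram per-site mean IPDs on the log2 scale.

    Bin edges are aligned to multiples of *bin_width* and shared across the
    returned histograms, so with ``by_base`` the per-base counts partition
    the "all" counts bin-wise.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not len(sites):
        raise ValueError("no sites to histogram")
    log2 = np.log2(sites["mean_ipd"].to_numpy())
    lo = math.floor(log2.min() / bin_width)
    hi = math.ceil(log2.max() / bin_width)
    if hi == lo:
        hi += 1
    edges = np.arange(lo, hi + 1) * bin_width
    out = [Log2Histogram(edges, np.histogram(log2, bins=edges)[0], "all")]
    if by_base:
        for base in BASES:
            sel = log2[(sites["ref_base"] == base).to_numpy()]
            out.append(Log2Histogram(edges, np.histogram(sel, bins=edges)[0],
                                     base))
    return out
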