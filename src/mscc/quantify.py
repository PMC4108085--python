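"""Spike-in normalized methylation calls and summaries.

For each sample the two libraries get scale factors f_L = K / spike_in(L)
(the constant K cancels in the ratio); the methylation level of a site is

    level = m * f_inverse / (m * f_inverse + u * f_hpaii)

where u is the HpaII-library count (unmethylated evidence) and m the
inverse-library count (methylated evidence). Sites with fewer than
``min_depth`` raw reads (u + m, default 30) are excluded: sampling noise is
governed by raw read numbers, so the filter applies before scaling.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NormalizationError

logger = logging.getLogger(__name__)


def normalize_and_call(
    counts: pd.DataFrame,
    spike_ins: pd.DataFrame,
    min_depth: int = 30,
    scale_constant: float = 1e6,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-site methylation calls after spike-in normalization and depth filter.

    Parameters
    ----------
    counts
        Columns sample, site_id, u, m (raw reads).
    spike_ins
        Columns sample, library, count; must be positive for every (sample,
        library) appearing in *counts*, else :class:`NormalizationError`.
    min_depth
        Minimum raw depth u + m; a site with depth exactly ``min_depth`` is
        retained (>= convention, the "30+ reads" filter).
    sites
        Optional site table (site_id, chrom, pos) to join coordinates in.

    Returns
    -------
    DataFrame with sample, site_id, [chrom, pos,] u, m, depth, level.
    """
    spike = spike_ins.set_index(["sample", "library"])["count"]
    needed = pd.unique(counts["sample"])
    for sample in needed:
        for lib in ("hpaii", "inverse"):
            val = spike.get((sample, lib), 0)
            if val <= 0:
                raise NormalizationError(
                    f"spike-in count for sample={sample!r} library={lib!r} is "
                    f"{val}; cannot compute a scale factor"
                )
    f_h = scale_constant / counts["sample"].map(lambda s: spike[(s, "hpaii")])
    f_i = scale_constant / counts["sample"].map(lambda s: spike[(s, "inverse")])

    out = counts.copy()
    out["depth"] = out["u"] + out["m"]
    num = out["m"] * f_i
    den = num + out["u"] * f_h
    with np.errstate(invalid="ignore"):
        out["level"] = np.where(den > 0, num / den, np.nan)
    out = out[out["depth"] >= min_depth].reset_index(drop=True)
    if sites is not None:
        out = out.merge(sites[["site_id", "chrom", "pos"]], on="site_id", how="left")
        out = out[["sample", "site_id", "chrom", "pos", "u", "m", "depth", "level"]]
    return out


def depth_accuracy_curve(
    calls_rep1: pd.DataFrame,
    calls_rep2: pd.DataFrame,
    depth_thresholds: list[int] = (10, 30, 50, 100),
    min_shared: int = 10,
) -> pd.DataFrame:
    """Replicate-pair Pearson correlation as a function of a depth threshold.

    Both call tables must come from independent sequencing of the same
    methylome (single sample each). For each threshold t the correlation is
    computed over sites with depth >= t in *both* replicates; thresholds with
    fewer than *min_shared* shared sites are skipped and logged.
    """
    a = calls_rep1.set_index("site_id")[["level", "depth"]]
    b = calls_rep2.set_index("site_id")[["level", "depth"]]
    shared = a.join(b, lsuffix="_1", rsuffix="_2", how="inner")
    rows = []
    for t in depth_thresholds:
        sub = shared[(shared["depth_1"] >= t) & (shared["depth_2"] >= t)]
        if len(sub) < min_shared:
            logger.warning(
                "depth_accuracy_curve: threshold %d skipped (%d shared sites < %d)",
                t, len(sub), min_shared,
            )
            continue
        r = float(stats.pearsonr(sub["level_1"], sub["level_2"]).statistic)
        rows.append((t, len(sub), r))
    return pd.DataFrame(rows, columns=["threshold", "n", "pearson_r"])


def chromosome_summary(calls: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-chromosome mean level and site count, plus an overall row.

    Chromosomes present in *sites* but with no surviving calls are reported
    with a null mean rather than dropped.
    """
    df = calls
    if "chrom" not in df.columns:
        df = df.merge(sites[["site_id", "chrom"]], on="site_id", how="left")
    per = df.groupby("chrom")["level"].agg(["mean", "count"])
    all_chroms = pd.unique(sites["chrom"])
    per = per.reindex(all_chroms)
    per["count"] = per["count"].fillna(0).astype(int)
    per = per.reset_index().rename(columns={"mean": "mean_level", "count": "n"})
    overall = pd.DataFrame(
        [{"chrom": "overall", "mean_level": per["mean_level"].mean(), "n": int(per["n"].sum())}]
    )
    return pd.concat([per, overall], ignore_index=True)
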