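"""Descriptive genome-context profiles of the methylome.

Metagene frame: each quantified site is placed in its nearest gene's
coordinate system, strand-aware, as a fraction of gene length — 0 at the
TSS, 1 at the TES, negative upstream, with flanks of half a gene length per
side, so the axis runs -0.5 .. 1.5. Bin means are unweighted; a moving
average (default 11 bins, boundary-truncated) gives the smoothed line.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .annotate import GeneModel, interval_membership

logger = logging.getLogger(__name__)

TERTILES = ("low", "mid", "high")


# ---------------------------------------------------------------------------
# metagene machinery
# ---------------------------------------------------------------------------

def _relative_positions(calls: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Nearest-gene assignment and strand-aware relative coordinate per site.

    Sites farther than half a gene length from their nearest gene fall
    outside the -0.5..1.5 axis and are dropped here. Zero-length gene-like
    records are skipped with a log line.
    """
    usable = []
    for g in genes:
        if g.length <= 0:
            logger.warning("metagene: skipping zero-length gene %s", g.name)
            continue
        usable.append(g)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in usable:
        by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    for row in calls.itertuples(index=False):
        best: GeneModel | None = None
        best_dist = np.inf
        for g in by_chrom.get(row.chrom, []):
            if g.tx_start <= row.pos < g.tx_end:
                d = 0
            else:
                d = min(abs(row.pos - g.tx_start), abs(row.pos - (g.tx_end - 1)))
            if d < best_dist:
                best, best_dist = g, d
        if best is None:
            continue
        if best.strand == "+":
            rel = (row.pos - best.tx_start) / best.length
        else:
            rel = (best.tx_end - 1 - row.pos) / best.length
        if -0.5 <= rel <= 1.5:
            rows.append((row.site_id, row.pos, row.level, best.name, rel))
    return pd.DataFrame(rows, columns=["site_id", "pos", "level", "gene", "rel"])


def _bin_index(rel: np.ndarray, body_bins: int, flank_bins: int) -> np.ndarray:
    """Map relative coordinates to bin indices 0 .. 2*flank_bins+body_bins-1."""
    total = 2 * flank_bins + body_bins
    idx = np.empty(len(rel), dtype=int)
    up = rel < 0
    body = (rel >= 0) & (rel < 1)
    down = rel >= 1
    idx[up] = np.floor((rel[up] + 0.5) * 2 * flank_bins).astype(int)
    idx[body] = flank_bins + np.floor(rel[body] * body_bins).astype(int)
    idx[down] = flank_bins + body_bins + np.floor((rel[down] - 1.0) * 2 * flank_bins).astype(int)
    return np.clip(idx, 0, total - 1)


def bin_axis(body_bins: int = 40, flank_bins: int = 20) -> np.ndarray:
    """Bin-center coordinates on the -0.5 .. 1.5 metagene axis."""
    up = -0.5 + (np.arange(flank_bins) + 0.5) / (2 * flank_bins)
    body = (np.arange(body_bins) + 0.5) / body_bins
    down = 1.0 + (np.arange(flank_bins) + 0.5) / (2 * flank_bins)
    return np.concatenate([up, body, down])


def moving_average(series, window: int = 11) -> np.ndarray:
    """Centered moving average, window truncated at the boundaries.

    *window* must be odd; window >= length collapses to the whole-series
    mean at every position. NaN entries are skipped within each window.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    x = pd.Series(np.asarray(series, dtype=float))
    if window >= len(x):
        return np.full(len(x), float(x.mean()))
    return x.rolling(window, center=True, min_periods=1).mean().to_numpy()


def metagene_profile(
    calls: pd.DataFrame,
    genes: list[GeneModel],
    body_bins: int = 40,
    flank_bins: int = 20,
    ma_window: int | None = 11,
    gene_subset: set[str] | None = None,
) -> pd.DataFrame:
    """Mean methylation level along the metagene axis.

    *calls* is a single-sample call table with site_id, chrom, pos, level.
    With *gene_subset*, sites are still assigned to their nearest gene among
    all *genes* and then restricted to those whose assigned gene is in the
    subset. Returns one row per bin: bin, axis, n, mean_level[, smoothed].
    """
    assigned = _relative_positions(calls, genes)
    if gene_subset is not None:
        assigned = assigned[assigned["gene"].isin(gene_subset)]
    total = 2 * flank_bins + body_bins
    if len(assigned):
        idx = _bin_index(assigned["rel"].to_numpy(), body_bins, flank_bins)
        grouped = pd.DataFrame({"bin": idx, "level": assigned["level"].to_numpy()}).groupby("bin")[
            "level"
        ].agg(["mean", "count"])
    else:
        grouped = pd.DataFrame(columns=["mean", "count"])
    out = pd.DataFrame({"bin": np.arange(total), "axis": bin_axis(body_bins, flank_bins)})
    out["n"] = out["bin"].map(grouped["count"]).fillna(0).astype(int) if len(grouped) else 0
    out["mean_level"] = out["bin"].map(grouped["mean"]) if len(grouped) else np.nan
    if ma_window is not None:
        out["smoothed"] = moving_average(out["mean_level"], ma_window)
    return out


# ---------------------------------------------------------------------------
# expression tertiles
# ---------------------------------------------------------------------------

def assign_tertiles(expression: pd.DataFrame) -> dict[str, int]:
    """gene -> tertile index (0 low, 1 mid, 2 high), near-equal thirds.

    Rank-based nearest-rank split: genes are stably sorted by (expression,
    gene id) and cut into thirds, so boundary ties resolve to the lower
    group and equal-expression inputs still yield thirds of near-equal size.
    """
    ordered = expression.sort_values(["expression", "gene"], kind="mergesort")["gene"].tolist()
    n = len(ordered)
    out: dict[str, int] = {}
    for t, chunk in enumerate(np.array_split(np.array(ordered, dtype=object), 3)):
        for gene in chunk:
            out[gene] = t
    return out if n else {}


def expression_tertile_profiles(
    calls: pd.DataFrame,
    genes: list[GeneModel],
    expression: pd.DataFrame,
    body_bins: int = 40,
    flank_bins: int = 20,
    ma_window: int | None = 11,
    tss_halfwidth: int = 1000,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Metagene profile per expression tertile plus a TSS / latter-body contrast.

    Genes missing from the expression table are excluded (and counted in a
    log line). The contrast table reports, per tertile, the mean level of
    sites within +-tss_halfwidth of their assigned gene's TSS and of sites
    in the latter half of the gene body (relative position 0.5-1).
    """
    have_expr = set(expression["gene"])
    missing = [g.name for g in genes if g.name not in have_expr]
    if missing:
        logger.warning("expression_tertile_profiles: %d genes without expression excluded", len(missing))
    usable = [g for g in genes if g.name in have_expr]
    expr = expression[expression["gene"].isin({g.name for g in usable})]
    tert = assign_tertiles(expr)
    genes_by_name = {g.name: g for g in usable}

    profiles: dict[str, pd.DataFrame] = {}
    contrast_rows = []
    assigned = _relative_positions(calls, usable)
    for t, label in enumerate(TERTILES):
        subset = {name for name, ti in tert.items() if ti == t}
        profiles[label] = metagene_profile(
            calls, usable, body_bins, flank_bins, ma_window, gene_subset=subset
        )
        sub = assigned[assigned["gene"].isin(subset)]
        tss_of = sub["gene"].map(lambda name: genes_by_name[name].tss)
        tss_mask = ((sub["pos"] - tss_of).abs() <= tss_halfwidth).to_numpy()
        body_mask = ((sub["rel"] >= 0.5) & (sub["rel"] < 1.0)).to_numpy()
        contrast_rows.append(
            (label, len(subset),
             float(sub.loc[tss_mask, "level"].mean()) if tss_mask.any() else np.nan,
             int(tss_mask.sum()),
             float(sub.loc[body_mask, "level"].mean()) if body_mask.any() else np.nan,
             int(body_mask.sum()))
        )
    contrast = pd.DataFrame(
        contrast_rows,
        columns=["tertile", "n_genes", "tss_mean", "tss_n", "latter_body_mean", "latter_body_n"],
    )
    return profiles, contrast


# ---------------------------------------------------------------------------
# interval-stratum summaries
# ---------------------------------------------------------------------------

def peak_overlap_summary(calls: pd.DataFrame, peaks: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Mean level within vs without each histone mark's (merged) peaks."""
    rows = []
    for mark, intervals in peaks.items():
        inside, _ = interval_membership(calls, intervals)
        for stratum, mask in (("within", inside), ("without", ~inside)):
            n = int(mask.sum())
            rows.append((mark, stratum, n, float(calls.loc[mask, "level"].mean()) if n else np.nan))
    return pd.DataFrame(rows, columns=["mark", "stratum", "n", "mean_level"])


def shortrna_proximity_summary(
    calls: pd.DataFrame, shortrna: pd.DataFrame, flank: int = 2000
) -> pd.DataFrame:
    """Fraction and mean level of sites within / near / without short-RNA loci.

    near = outside every locus but within *flank* bp of one (boundary
    inclusive). Fractions are over all quantified sites and sum to 1.
    """
    inside, dist = interval_membership(calls, shortrna)
    near = ~inside & (dist <= flank)
    without = ~inside & ~near
    total = len(calls)
    rows = []
    for label, mask in (("within", inside), ("near", near), ("without", without)):
        n = int(mask.sum())
        rows.append(
            (label, n, n / total if total else np.nan,
             float(calls.loc[mask, "level"].mean()) if n else np.nan)
        )
    return pd.DataFrame(rows, columns=["class", "n", "fraction", "mean_level"])
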