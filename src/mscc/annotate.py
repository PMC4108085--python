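"""Genomic-context annotation of quantified CCGG sites.

Two independent axes are assigned per site:

* gene context — one of ``tss_region, exon, intron, upstream, downstream,
  intergenic``, resolved with that precedence when a site touches several
  genes (strand-aware upstream/downstream);
* CGI context — ``cgi`` inside a CpG island, ``shore`` within ``shore_width``
  bp of one (2 kb by convention), else ``open_sea``.

All coordinates are 0-based half-open. Distance from a position outside an
interval to the interval is counted to its nearest contained base, so a site
exactly ``width`` bp beyond an edge is still within reach of a ``width``
flank (inclusive boundary).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

GENE_CONTEXTS = ["tss_region", "exon", "intron", "upstream", "downstream", "intergenic"]
CGI_CONTEXTS = ["cgi", "shore", "open_sea"]

_PRECEDENCE = {label: rank for rank, label in enumerate(GENE_CONTEXTS)}


@dataclass
class GeneModel:
    """A transcript model: 0-based half-open bounds, sorted non-overlapping exons."""

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.name}: strand must be + or -, got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"gene {self.name}: empty interval [{self.tx_start},{self.tx_end})")
        last = self.tx_start
        for s, e in self.exons:
            if s < last or e > self.tx_end or s >= e:
                raise ValueError(f"gene {self.name}: bad exon ({s},{e})")
            last = e

    @property
    def tss(self) -> int:
        """Transcription start site: first transcribed base (strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome (BED-style)."""
    rows = []
    for chrom, grp in intervals.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def interval_membership(
    sites: pd.DataFrame, intervals: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Per site: (inside, distance) relative to merged *intervals*.

    ``inside`` is True when the position lies in an interval (half-open);
    ``distance`` is 0 inside, otherwise base count to the nearest contained
    base, inf when the chromosome carries no interval.
    """
    inside = np.zeros(len(sites), dtype=bool)
    dist = np.full(len(sites), np.inf)
    if len(intervals) == 0:
        return inside, dist
    merged = merge_intervals(intervals)
    chroms = sites["chrom"].to_numpy()
    positions = sites["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        ivs = merged[merged["chrom"] == chrom]
        if ivs.empty:
            continue
        starts = ivs["start"].to_numpy()
        ends = ivs["end"].to_numpy()
        mask = chroms == chrom
        pos = positions[mask]
        idx = np.searchsorted(starts, pos, side="right") - 1
        idxc = np.clip(idx, 0, None)
        has_left = idx >= 0
        ins = has_left & (pos < ends[idxc])
        d_left = np.where(has_left, pos - ends[idxc] + 1, np.inf)
        has_right = idx + 1 < len(starts)
        nxt = np.clip(idx + 1, 0, len(starts) - 1)
        d_right = np.where(has_right, starts[nxt] - pos, np.inf)
        inside[mask] = ins
        dist[mask] = np.where(ins, 0.0, np.minimum(d_left, d_right))
    return inside, dist


def _context_for_gene(pos: int, gene: GeneModel, tss_halfwidth: int, flank: int) -> str | None:
    """Label of *pos* relative to one gene, or None if out of reach."""
    if abs(pos - gene.tss) <= tss_halfwidth:
        return "tss_region"
    if gene.tx_start <= pos < gene.tx_end:
        for s, e in gene.exons:
            if s <= pos < e:
                return "exon"
        return "intron"
    if gene.strand == "+":
        upstream = gene.tx_start - flank <= pos < gene.tx_start
        downstream = gene.tx_end <= pos < gene.tx_end + flank
    else:
        upstream = gene.tx_end <= pos < gene.tx_end + flank
        downstream = gene.tx_start - flank <= pos < gene.tx_start
    if upstream:
        return "upstream"
    if downstream:
        return "downstream"
    return None


def _gene_trees(genes: list[GeneModel], reach: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(max(0, g.tx_start - reach), g.tx_end + reach, g)
    return trees


def classify_gene_context(
    sites: pd.DataFrame,
    genes: list[GeneModel],
    tss_halfwidth: int = 1000,
    flank: int = 2000,
) -> pd.Series:
    """Assign each site one gene-context label, best label winning by precedence.

    ``sites`` needs ``chrom`` and ``pos`` columns; result indexed like ``sites``.
    """
    reach = max(tss_halfwidth, flank)
    trees = _gene_trees(genes, reach)
    labels = []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        best = "intergenic"
        tree = trees.get(chrom)
        if tree is not None:
            for iv in tree.at(pos):
                label = _context_for_gene(pos, iv.data, tss_halfwidth, flank)
                if label is not None and _PRECEDENCE[label] < _PRECEDENCE[best]:
                    best = label
        labels.append(best)
    return pd.Series(labels, index=sites.index, name="gene_context")


def classify_cgi_context(
    sites: pd.DataFrame, cgis: pd.DataFrame, shore_width: int = 2000
) -> pd.Series:
    """cgi / shore / open_sea per site; CGI intervals merged first."""
    inside, dist = interval_membership(sites, cgis)
    labels = np.where(inside, "cgi", np.where(dist <= shore_width, "shore", "open_sea"))
    return pd.Series(labels, index=sites.index, name="cgi_context")


def nearest_gene(sites: pd.DataFrame, genes: list[GeneModel]) -> pd.DataFrame:
    """Nearest gene name and distance (0 if inside, -1 if no gene on chromosome)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    names, dists = [], []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        best_name, best_dist = ".", np.inf
        for g in by_chrom.get(chrom, []):
            if g.tx_start <= pos < g.tx_end:
                d = 0
            else:
                d = min(abs(pos - g.tx_start), abs(pos - (g.tx_end - 1)))
            if d < best_dist:
                best_name, best_dist = g.name, d
        names.append(best_name)
        dists.append(int(best_dist) if np.isfinite(best_dist) else -1)
    return pd.DataFrame({"nearest_gene": names, "distance": dists}, index=sites.index)


def annotate_sites(
    sites: pd.DataFrame,
    genes: list[GeneModel],
    cgis: pd.DataFrame,
    tss_halfwidth: int = 1000,
    flank: int = 2000,
    shore_width: int = 2000,
) -> pd.DataFrame:
    """Full per-site annotation table (site_id, contexts, nearest gene, distance)."""
    out = sites[["site_id", "chrom", "pos"]].copy()
    out["gene_context"] = classify_gene_context(sites, genes, tss_halfwidth, flank)
    out["cgi_context"] = classify_cgi_context(sites, cgis, shore_width)
    out = out.join(nearest_gene(sites, genes))
    return out


def stratum_means(calls: pd.DataFrame, annotation: pd.DataFrame, axis: str = "cgi_context") -> pd.DataFrame:
    """Unweighted mean methylation level and site count per annotation class.

    Classes with no quantified sites appear with count 0 and a null mean.
    """
    if axis not in {"gene_context", "cgi_context"}:
        raise ValueError(f"axis must be gene_context or cgi_context, got {axis!r}")
    merged = calls.merge(annotation[["site_id", axis]], on="site_id", how="inner")
    grouped = merged.groupby(axis)["level"].agg(["mean", "count"])
    all_classes = GENE_CONTEXTS if axis == "gene_context" else CGI_CONTEXTS
    grouped = grouped.reindex(all_classes)
    grouped["count"] = grouped["count"].fillna(0).astype(int)
    return grouped.reset_index().rename(columns={axis: "stratum", "mean": "mean_level", "count": "n"})
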