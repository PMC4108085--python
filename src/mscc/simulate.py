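"""Synthetic genomes, methylomes and MSCC sequencing libraries.

The generator builds toy data with the statistical structure the downstream
analyses assume, so every estimator has a recovery target:

* a multi-chromosome genome with CCGG sites planted at a controlled spacing,
  CpG islands with >=3x the background CCGG density, gene models with strand
  and exons, per-mark histone peak tracks, short-RNA loci, and a positive
  expression value per gene;
* a ground-truth methylome per sample: bimodal background
  (0.7*Beta(8,2) + 0.3*Beta(2,8)), hypomethylated CGIs (Beta(1,12)),
  intermediate shores (Beta(2,6)), a multiplicative dip around each TSS,
  hypermethylation under repressive histone peaks, hypomethylated short-RNA
  neighborhoods, and (optionally) expression-coupled gene-body levels or
  planted differentially methylated regions;
* dual-library counts: per site, depth ~ Poisson(mean_depth) and the
  methylated-library count m ~ Binomial(depth, q) with
  q = p*e_I / (p*e_I + (1-p)*e_H), plus spike-in standard counts that carry
  the per-library efficiency scale;
* FASTQ reads of the form index + 18-bp tag with substitution errors.

Identical config and seed reproduce identical output byte for byte.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneModel, interval_membership
from .config import ACTIVE_MARKS, REPRESSIVE_MARKS, SimulationConfig
from .digest import CCGGSite, TagLibrary, sites_to_frame
from .errors import ConfigurationError, PlacementError, SizingError
from .io import write_bed, write_fastq, write_fasta, write_genes_bed12, write_tsv

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)

SCENARIOS = ("null", "planted_dmr", "expression_coupled")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Annotations:
    """Everything the genome generator emits besides the sequence itself."""

    genes: list[GeneModel]
    cgis: pd.DataFrame                 # chrom, start, end, name
    peaks: dict[str, pd.DataFrame]     # mark -> chrom, start, end
    shortrna: pd.DataFrame             # chrom, start, end, name
    expression: pd.DataFrame           # gene, expression

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["genes"] = outdir / "genes.bed12"
        write_genes_bed12(self.genes, paths["genes"])
        paths["cgis"] = outdir / "cgis.bed"
        write_bed(self.cgis, paths["cgis"])
        for mark, df in self.peaks.items():
            p = outdir / f"peaks_{mark}.bed"
            write_bed(df, p)
            paths[f"peaks_{mark}"] = p
        paths["shortrna"] = outdir / "shortrna.bed"
        write_bed(self.shortrna, paths["shortrna"])
        paths["expression"] = outdir / "expression.tsv"
        write_tsv(self.expression, paths["expression"])
        return paths


@dataclass
class MethylomeTruth:
    """Ground-truth methylation level per (sample, site)."""

    sites: pd.DataFrame           # site_id, chrom, pos
    levels: pd.DataFrame          # index = site_id, one column per sample

    @property
    def samples(self) -> list[str]:
        return list(self.levels.columns)

    def copy(self) -> "MethylomeTruth":
        return MethylomeTruth(self.sites.copy(), self.levels.copy())

    def to_long(self) -> pd.DataFrame:
        long = self.levels.reset_index(names="site_id").melt(
            id_vars="site_id", var_name="sample", value_name="level"
        )
        return long.merge(self.sites, on="site_id")[["sample", "site_id", "chrom", "pos", "level"]]

    def write(self, path: str | Path) -> None:
        write_tsv(self.to_long(), path)

    @classmethod
    def read(cls, path: str | Path) -> "MethylomeTruth":
        long = pd.read_csv(path, sep="\t")
        sites = long[["site_id", "chrom", "pos"]].drop_duplicates().sort_values("site_id")
        levels = long.pivot(index="site_id", columns="sample", values="level")
        # preserve the sample order of first appearance
        order = list(dict.fromkeys(long["sample"]))
        return cls(sites.reset_index(drop=True), levels[order])


@dataclass(frozen=True)
class DMRTruth:
    """A planted differentially methylated region and the shift applied."""

    chrom: str
    start: int
    end: int
    delta: float
    samples: tuple[str, ...]


# ---------------------------------------------------------------------------
# genome + annotations
# ---------------------------------------------------------------------------

def _distribute(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _make_exons(start: int, end: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Split [start, end) into 2-5 exons separated by introns, each >=100 bp."""
    n_exons = int(rng.integers(2, 6))
    n_seg = 2 * n_exons - 1
    length = end - start
    if length < 100 * n_seg:
        n_exons, n_seg = 2, 3
    weights = rng.random(n_seg) + 0.3
    sizes = np.maximum(100, (weights / weights.sum() * (length - 100 * n_seg)).astype(int) + 100)
    sizes[-1] = length - sizes[:-1].sum()
    bounds = start + np.concatenate([[0], np.cumsum(sizes)])
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_seg, 2)]


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], Annotations]:
    """Generate the toy genome and its full annotation set.

    Raises :class:`SizingError` when the configured features cannot be placed
    on chromosomes of the configured length.
    """
    rng = np.random.default_rng([1, config.seed])
    L = config.chrom_length
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    cgi_rows: list[tuple] = []
    short_rows: list[tuple] = []
    rep_rows: dict[str, list[tuple]] = {m: [] for m in config.marks if m in REPRESSIVE_MARKS}

    genes_per = _distribute(config.gene_count, config.n_chroms)
    cgis_per = _distribute(config.cgi_count, config.n_chroms)
    srna_per = _distribute(config.shortrna_count, config.n_chroms)

    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        codes = rng.choice(4, size=L, p=[0.3, 0.2, 0.2, 0.3])

        # --- genes laid out left to right with intergenic gaps
        chrom_genes: list[GeneModel] = []
        gaps: list[tuple[int, int]] = []
        cursor, prev_end = 3000, 2000
        for gi in range(genes_per[ci]):
            glen = int(rng.integers(2500, 6001))
            gap_after = int(rng.integers(2000, 5001))
            if cursor + glen > L - 3000:
                raise SizingError(
                    f"chrom_length={L} too small to place {genes_per[ci]} genes on {chrom} "
                    f"(ran out of room at gene {gi})"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"gene_{chrom}_{gi}"
            exons = _make_exons(cursor, cursor + glen, rng)
            chrom_genes.append(GeneModel(name, chrom, strand, cursor, cursor + glen, exons))
            gaps.append((prev_end, cursor))
            prev_end = cursor + glen
            cursor = prev_end + gap_after
        gaps.append((prev_end, L - 2000))
        genes.extend(chrom_genes)

        # --- CGIs: ~60% anchored at TSSs, the rest intergenic
        free_gaps = [g for g in gaps if g[1] - g[0] >= config.cgi_width + 800]
        order = rng.permutation(len(free_gaps))
        free_iter = iter(order)
        n_cgi = cgis_per[ci]
        n_tss = min(int(round(0.6 * n_cgi)), len(chrom_genes))
        if n_tss:
            for gidx in rng.choice(len(chrom_genes), size=n_tss, replace=False):
                g = chrom_genes[int(gidx)]
                s = max(0, g.tss - config.cgi_width // 2)
                cgi_rows.append((chrom, s, s + config.cgi_width, f"cgi_{len(cgi_rows)}"))
        for _ in range(n_cgi - n_tss):
            try:
                gs, ge = free_gaps[next(free_iter)]
            except StopIteration:
                raise SizingError(
                    f"chrom_length={L}: not enough intergenic gaps on {chrom} for "
                    f"{n_cgi - n_tss} intergenic CGIs of width {config.cgi_width}"
                ) from None
            mid = (gs + ge) // 2
            cgi_rows.append((chrom, mid - config.cgi_width // 2,
                             mid + config.cgi_width - config.cgi_width // 2, f"cgi_{len(cgi_rows)}"))

        # --- short-RNA loci and repressive-mark peaks in the remaining gaps
        def _pop_gap(need: int, what: str) -> tuple[int, int]:
            try:
                gs, ge = free_gaps[next(free_iter)]
            except StopIteration:
                raise SizingError(
                    f"chrom_length={L}: not enough intergenic gaps on {chrom} for {what}"
                ) from None
            if ge - gs < need:
                return _pop_gap(need, what)
            return gs, ge

        for si in range(srna_per[ci]):
            gs, ge = _pop_gap(config.shortrna_width + 400, "short-RNA loci")
            mid = (gs + ge) // 2
            short_rows.append((chrom, mid - config.shortrna_width // 2,
                               mid + config.shortrna_width - config.shortrna_width // 2,
                               f"srna_{len(short_rows)}"))
        for mark in rep_rows:
            for _ in range(config.repressive_peaks_per_chrom):
                gs, ge = _pop_gap(1900, f"{mark} peaks")
                mid = (gs + ge) // 2
                rep_rows[mark].append((chrom, mid - 750, mid + 750))

        # --- CpG-enrich CGI sequence, then plant CCGG motifs
        chrom_cgis = [(s, e) for c, s, e, _ in cgi_rows if c == chrom]
        for s, e in chrom_cgis:
            codes[s:e] = rng.choice(4, size=e - s, p=[0.15, 0.35, 0.35, 0.15])

        motif = np.array([1, 1, 2, 2])  # C C G G
        cgi_starts = np.array(sorted(s for s, _ in chrom_cgis)) if chrom_cgis else np.empty(0)
        cgi_ends = np.array(sorted(e for _, e in chrom_cgis)) if chrom_cgis else np.empty(0)

        def _in_cgi(p: int) -> bool:
            if not len(cgi_starts):
                return False
            i = int(np.searchsorted(cgi_starts, p, side="right")) - 1
            return i >= 0 and p < cgi_ends[i] + 6

        pos = 50
        hi = 2 * config.ccgg_spacing - 23
        while pos < L - 30:
            if not _in_cgi(pos):
                codes[pos : pos + 4] = motif
            pos += int(rng.integers(24, hi))
        cgi_step_hi = max(9, int(2 * config.ccgg_spacing / config.cgi_ccgg_multiplier) - 7)
        for s, e in chrom_cgis:
            pos = s + 4
            while pos < e - 6:
                codes[pos : pos + 4] = motif
                pos += int(rng.integers(8, cgi_step_hi + 1))

        genome[chrom] = _ASCII[codes].tobytes().decode("ascii")

    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "name"])
    shortrna = pd.DataFrame(short_rows, columns=["chrom", "start", "end", "name"])

    peaks: dict[str, pd.DataFrame] = {}
    for mark in config.marks:
        if mark in REPRESSIVE_MARKS:
            peaks[mark] = pd.DataFrame(rep_rows.get(mark, []), columns=["chrom", "start", "end"])
        else:
            # active marks sit over (a random 70% subset of) CGIs, widened a little
            if len(cgis):
                take = rng.random(len(cgis)) < 0.7
                sub = cgis[take]
            else:
                sub = cgis
            peaks[mark] = pd.DataFrame(
                {"chrom": sub["chrom"],
                 "start": (sub["start"] - 200).clip(lower=0),
                 "end": sub["end"] + 200}
            ).reset_index(drop=True)

    expression = pd.DataFrame(
        {"gene": [g.name for g in genes],
         "expression": rng.lognormal(mean=2.0, sigma=1.2, size=len(genes))}
    )
    return genome, Annotations(genes, cgis, peaks, shortrna, expression)


# ---------------------------------------------------------------------------
# truth methylome
# ---------------------------------------------------------------------------

def _tss_context(sites: pd.DataFrame, genes: list[GeneModel]) -> tuple[np.ndarray, np.ndarray]:
    """Per site: distance to the nearest TSS and the index of that gene (-1 if none)."""
    dist = np.full(len(sites), np.inf)
    gene_idx = np.full(len(sites), -1)
    by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append(i)
    chroms = sites["chrom"].to_numpy()
    positions = sites["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        idxs = by_chrom.get(chrom)
        if not idxs:
            continue
        tss = np.array([genes[i].tss for i in idxs])
        order = np.argsort(tss)
        tss_sorted = tss[order]
        idx_sorted = np.array(idxs)[order]
        mask = chroms == chrom
        pos = positions[mask]
        j = np.clip(np.searchsorted(tss_sorted, pos), 0, len(tss_sorted) - 1)
        jm = np.clip(j - 1, 0, len(tss_sorted) - 1)
        d_right = np.abs(tss_sorted[j] - pos)
        d_left = np.abs(tss_sorted[jm] - pos)
        pick = np.where(d_left <= d_right, jm, j)
        dist[mask] = np.minimum(d_left, d_right)
        gene_idx[mask] = idx_sorted[pick]
    return dist, gene_idx


def _body_context(sites: pd.DataFrame, genes: list[GeneModel]) -> tuple[np.ndarray, np.ndarray]:
    """Per site: host gene index (-1 if intergenic) and strand-aware body fraction."""
    gene_idx = np.full(len(sites), -1)
    frac = np.full(len(sites), np.nan)
    by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append(i)
    chroms = sites["chrom"].to_numpy()
    positions = sites["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        idxs = by_chrom.get(chrom)
        if not idxs:
            continue
        starts = np.array([genes[i].tx_start for i in idxs])
        ends = np.array([genes[i].tx_end for i in idxs])
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        idx_sorted = np.array(idxs)[order]
        mask = chroms == chrom
        pos = positions[mask]
        j = np.searchsorted(starts, pos, side="right") - 1
        jc = np.clip(j, 0, None)
        inside = (j >= 0) & (pos < ends[jc])
        host = np.where(inside, idx_sorted[jc], -1)
        gene_idx[mask] = host
        f = np.full(len(pos), np.nan)
        for k in np.nonzero(inside)[0]:
            g = genes[host[k]]
            if g.strand == "+":
                f[k] = (pos[k] - g.tx_start) / g.length
            else:
                f[k] = (g.tx_end - 1 - pos[k]) / g.length
        frac[mask] = f
    return gene_idx, frac


def generate_methylome(
    sites: list[CCGGSite] | pd.DataFrame,
    annotations: Annotations,
    scenario: str,
    seed: int,
    samples: tuple[str, ...] = ("S0h", "S4h", "S12h", "S24h", "S96h"),
    *,
    tss_halfwidth: int = 1000,
    shore_width: int = 2000,
    shortrna_flank: int = 2000,
    expression_offset: float = 0.2,
) -> MethylomeTruth:
    """Draw a ground-truth methylome over *sites*.

    Scenarios: ``null`` (all samples identical), ``planted_dmr`` (identical;
    shifts are added afterwards by :func:`plant_dmrs`), ``expression_coupled``
    (latter gene-body levels offset by expression tertile and the TSS dip
    deepened for highly expressed genes).
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    sites_df = sites if isinstance(sites, pd.DataFrame) else sites_to_frame(sites)
    rng = np.random.default_rng([2, seed])
    n = len(sites_df)

    in_cgi, _ = interval_membership(sites_df, annotations.cgis)
    _, cgi_dist = interval_membership(sites_df, annotations.cgis)
    in_shore = ~in_cgi & (cgi_dist <= shore_width)
    rep_frames = [annotations.peaks[m] for m in annotations.peaks if m in REPRESSIVE_MARKS]
    if rep_frames:
        rep_all = pd.concat(rep_frames, ignore_index=True)
        in_rep, _ = interval_membership(sites_df, rep_all)
    else:
        in_rep = np.zeros(n, dtype=bool)
    in_srna, srna_dist = interval_membership(sites_df, annotations.shortrna)
    near_srna = ~in_srna & (srna_dist <= shortrna_flank)
    tss_dist, tss_gene = _tss_context(sites_df, annotations.genes)

    # background: bimodal mixture, then stratum overrides
    high = rng.random(n) < 0.7
    base = np.where(high, rng.beta(8, 2, n), rng.beta(2, 8, n))
    base[in_rep] = rng.beta(8, 2, n)[in_rep]
    base[in_shore] = rng.beta(2, 6, n)[in_shore]
    base[in_cgi] = rng.beta(1, 12, n)[in_cgi]

    tss_factor = np.ones(n)
    if scenario == "expression_coupled":
        from .profiles import assign_tertiles

        tertile = assign_tertiles(annotations.expression)  # gene -> 0 (low) / 1 / 2 (high)
        tert_by_idx = np.array(
            [tertile.get(g.name, 1) for g in annotations.genes], dtype=int
        ) if annotations.genes else np.empty(0, dtype=int)

        host, frac = _body_context(sites_df, annotations.genes)
        latter = (host >= 0) & (frac >= 0.5) & ~in_cgi & ~in_shore
        body_draw = rng.beta(4, 4, n)
        weights = np.array([0.0, 0.5, 1.0])
        off = np.zeros(n)
        off[latter] = expression_offset * weights[tert_by_idx[host[latter]]]
        base[latter] = np.clip(body_draw[latter] + off[latter], 0, 1)

        dips = np.array([0.6, 0.3, 0.1])  # low, mid, high expression
        near_tss = tss_dist <= tss_halfwidth
        factors = np.where(tss_gene >= 0, dips[tert_by_idx[np.clip(tss_gene, 0, None)]], 0.2)
        tss_factor[near_tss] = factors[near_tss]
    else:
        tss_factor[tss_dist <= tss_halfwidth] = 0.2

    srna_factor = np.ones(n)
    srna_factor[near_srna] = 0.6
    srna_factor[in_srna] = 0.25

    level = np.clip(base * srna_factor * tss_factor, 0.0, 1.0)
    levels = pd.DataFrame(
        {s: level for s in samples}, index=pd.Index(sites_df["site_id"], name="site_id")
    )
    return MethylomeTruth(sites_df[["site_id", "chrom", "pos"]].copy(), levels)


def plant_dmrs(
    truth: MethylomeTruth,
    n_dmrs: int,
    delta: float,
    width_bp: int = 200,
    seed: int = 0,
    treated: tuple[str, ...] | None = None,
    min_sites: int = 4,
    auto_sign: bool = True,
) -> tuple[MethylomeTruth, list[DMRTruth]]:
    """Shift treated samples by *delta* (clipped to [0,1]) in planted regions.

    Regions are width_bp-grid-aligned windows containing >= min_sites CCGG
    sites, chosen non-overlapping; the baseline (first) sample is untouched.
    With ``auto_sign`` the shift direction per region is the one with more
    dynamic range (ties broken toward the sign of *delta*), and the signed
    shift actually applied is recorded in the returned truth list.
    """
    if abs(delta) > 1:
        raise ValueError("|delta| must be <= 1")
    out = truth.copy()
    if treated is None:
        treated = tuple(out.samples[1:])
    baseline = out.samples[0]

    sites = out.sites
    win = pd.DataFrame(
        {"chrom": sites["chrom"], "wstart": (sites["pos"] // width_bp) * width_bp}
    )
    grouped = win.groupby(["chrom", "wstart"]).size()
    eligible = [key for key, cnt in grouped.items() if cnt >= min_sites]
    if len(eligible) < n_dmrs:
        raise PlacementError(
            f"cannot place {n_dmrs} non-overlapping regions with >= {min_sites} CCGG sites; "
            f"only {len(eligible)} eligible {width_bp}-bp windows"
        )
    eligible.sort()
    rng = np.random.default_rng([5, seed])
    chosen = [eligible[i] for i in rng.choice(len(eligible), size=n_dmrs, replace=False)]

    mag = abs(delta)
    dmrs: list[DMRTruth] = []
    pos = sites["pos"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    base_levels = out.levels[baseline].to_numpy()
    for chrom, wstart in chosen:
        mask = (chroms == chrom) & (pos >= wstart) & (pos < wstart + width_bp)
        lv = base_levels[mask]
        up = np.mean(np.clip(lv + mag, 0, 1) - lv)
        down = np.mean(lv - np.clip(lv - mag, 0, 1))
        if not auto_sign or abs(up - down) < 1e-12:
            sign = 1.0 if delta >= 0 else -1.0
        else:
            sign = 1.0 if up > down else -1.0
        applied = sign * mag
        ids = sites.loc[mask, "site_id"].to_numpy()
        out.levels.loc[ids, list(treated)] = np.clip(
            out.levels.loc[ids, list(treated)].to_numpy() + applied, 0, 1
        )
        dmrs.append(DMRTruth(str(chrom), int(wstart), int(wstart + width_bp), float(applied), tuple(treated)))
    return out, dmrs


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def draw_depth_means(n_sites: int, config: SimulationConfig, seed: int) -> np.ndarray:
    """Per-site expected depths: gamma-mixed when depth_dispersion > 0."""
    rng = np.random.default_rng([6, seed])
    if config.depth_dispersion > 0:
        shape = 1.0 / config.depth_dispersion
        return rng.gamma(shape, config.mean_depth / shape, size=n_sites)
    return np.full(n_sites, config.mean_depth)


def simulate_counts(
    truth: MethylomeTruth,
    config: SimulationConfig,
    seed: int,
    depth_means: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the dual-library count table and spike-in standard counts.

    Returns (counts, spike_ins): counts has columns sample, site_id, u, m;
    spike_ins has sample, library, count. Zero-depth sites are kept (they
    simply fail the downstream depth filter).
    """
    rng = np.random.default_rng([3, seed])
    samples = truth.samples
    n = len(truth.sites)
    if depth_means is None:
        depth_means = draw_depth_means(n, config, seed)
    e_h, e_i = config.hpaii_efficiency, config.inverse_efficiency
    p = truth.levels[samples].to_numpy()
    depth = rng.poisson(np.broadcast_to(depth_means[:, None], p.shape))
    q = p * e_i / (p * e_i + (1.0 - p) * e_h)
    m = rng.binomial(depth, q)
    u = depth - m

    site_ids = truth.sites["site_id"].to_numpy()
    frames = [
        pd.DataFrame({"sample": s, "site_id": site_ids, "u": u[:, j], "m": m[:, j]})
        for j, s in enumerate(samples)
    ]
    counts = pd.concat(frames, ignore_index=True)

    spike_rows = []
    for s in samples:
        spike_rows.append((s, "hpaii", int(rng.poisson(config.spike_in_mean * e_h))))
        spike_rows.append((s, "inverse", int(rng.poisson(config.spike_in_mean * e_i))))
    spike = pd.DataFrame(spike_rows, columns=["sample", "library", "count"])
    return counts, spike


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def make_index_table(
    samples: tuple[str, ...], index_length: int = 6, seed: int = 0
) -> pd.DataFrame:
    """Unique fixed-length index per (sample, library), like a demux sheet."""
    rng = np.random.default_rng([4, seed])
    seen: set[str] = set()
    rows = []
    for s in samples:
        for lib in ("hpaii", "inverse"):
            while True:
                idx = "".join(_BASES[c] for c in rng.integers(0, 4, size=index_length))
                if idx not in seen:
                    seen.add(idx)
                    break
            rows.append((idx, s, lib))
    return pd.DataFrame(rows, columns=["index", "sample", "library"])


def make_standard_tags(
    tag_length: int = 18, n_per_library: int = 4, seed: int = 0
) -> dict[str, str]:
    """Dedicated spike-in standard tags, one set per library.

    Prefixes AAT / TTA keep every standard >=3 mismatches away from genomic
    tags (which all begin CGG) and from the other library's standards.
    """
    rng = np.random.default_rng([7, seed])
    tags: dict[str, str] = {}
    for prefix, lib in (("AAT", "hpaii"), ("TTA", "inverse")):
        made = 0
        while made < n_per_library:
            suffix = "".join(_BASES[c] for c in rng.integers(0, 4, size=tag_length - 3))
            tag = prefix + suffix
            if tag not in tags:
                tags[tag] = lib
                made += 1
    return tags


def _apply_substitution_errors(
    tags: list[str], rate: float, rng: np.random.Generator
) -> list[str]:
    """Per-base substitutions at *rate*; never substitutes a base for itself."""
    if rate <= 0 or not tags:
        return tags
    tag_len = len(tags[0])
    arr = np.frombuffer("".join(tags).encode("ascii"), dtype=np.uint8).reshape(len(tags), tag_len).copy()
    code = np.zeros(256, dtype=np.uint8)
    for k, b in enumerate(b"ACGT"):
        code[b] = k
    hits = rng.random(arr.shape) < rate
    n_hits = int(hits.sum())
    if n_hits:
        shift = rng.integers(1, 4, size=n_hits)
        arr[hits] = _ASCII[(code[arr[hits]] + shift) % 4]
    flat = arr.tobytes().decode("ascii")
    return [flat[i * tag_len : (i + 1) * tag_len] for i in range(len(tags))]


def simulate_reads(
    counts: pd.DataFrame,
    spike_ins: pd.DataFrame,
    tag_library: TagLibrary,
    index_table: pd.DataFrame,
    seq_error_rate: float,
    seed: int,
    path: str | Path,
) -> dict:
    """Emit one FASTQ read (index + tag) per counted molecule.

    Genomic reads draw uniformly from their site's usable tags; spike-in
    reads use the library's dedicated standard tags. Substitution errors hit
    the tag portion only. Sites with zero usable tags are excluded and their
    dropped read counts logged and returned in the ledger.
    """
    rng = np.random.default_rng([8, seed])
    idx_lookup = {
        (row.sample, row.library): row.index_seq
        for row in index_table.rename(columns={"index": "index_seq"}).itertuples(index=False)
    }
    site_tags = tag_library.site_tag_map()
    std_by_lib: dict[str, list[str]] = {}
    for tag, lib in tag_library.standard_tags.items():
        std_by_lib.setdefault(lib, []).append(tag)
    for lib in std_by_lib:
        std_by_lib[lib].sort()

    streams: dict[tuple[str, str], int] = {}
    dropped_reads = 0
    dropped_sites: set[int] = set()
    indices: list[str] = []
    tags: list[str] = []

    ordered = counts.sort_values(["sample", "site_id"], kind="mergesort")
    for row in ordered.itertuples(index=False):
        choices = site_tags.get(row.site_id)
        if not choices:
            dropped_reads += int(row.u) + int(row.m)
            dropped_sites.add(int(row.site_id))
            continue
        choices = sorted(choices)
        for lib, cnt in (("hpaii", int(row.u)), ("inverse", int(row.m))):
            if cnt == 0:
                continue
            index_seq = idx_lookup[(row.sample, lib)]
            picks = rng.integers(0, len(choices), size=cnt)
            indices.extend([index_seq] * cnt)
            tags.extend(choices[k] for k in picks)
            streams[(row.sample, lib)] = streams.get((row.sample, lib), 0) + cnt

    spike_emitted: dict[tuple[str, str], int] = {}
    for row in spike_ins.sort_values(["sample", "library"], kind="mergesort").itertuples(index=False):
        stds = std_by_lib.get(row.library)
        if not stds or row.count == 0:
            continue
        index_seq = idx_lookup[(row.sample, row.library)]
        picks = rng.integers(0, len(stds), size=int(row.count))
        indices.extend([index_seq] * int(row.count))
        tags.extend(stds[k] for k in picks)
        key = (row.sample, row.library)
        spike_emitted[key] = spike_emitted.get(key, 0) + int(row.count)
        streams[key] = streams.get(key, 0) + int(row.count)

    tags = _apply_substitution_errors(tags, seq_error_rate, rng)
    n = write_fastq(
        ((f"r{i}", idx + tag) for i, (idx, tag) in enumerate(zip(indices, tags))), path
    )
    if dropped_reads:
        logger.warning(
            "simulate_reads: dropped %d reads from %d sites with no usable tags",
            dropped_reads, len(dropped_sites),
        )
    return {
        "total_reads": n,
        "streams": streams,
        "spike_reads": spike_emitted,
        "dropped_reads": dropped_reads,
        "dropped_sites": sorted(dropped_sites),
    }


# ---------------------------------------------------------------------------
# convenience: full scenario emission
# ---------------------------------------------------------------------------

def write_simulation(
    config: SimulationConfig,
    scenario: str,
    outdir: str | Path,
    n_dmrs: int = 50,
    dmr_delta: float = 0.4,
    dmr_width: int = 200,
    expression_offset: float = 0.2,
    with_reads: bool = True,
) -> dict[str, Path]:
    """Generate and write a complete synthetic dataset; returns output paths."""
    from .digest import build_tag_library, find_ccgg_sites, write_sites, write_tag_library

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, ann = generate_genome(config)
    paths: dict[str, Path] = {"genome": outdir / "genome.fa"}
    write_fasta(genome, paths["genome"])
    paths.update(ann.write(outdir))

    sites = find_ccgg_sites(genome)
    truth = generate_methylome(
        sites, ann, scenario, config.seed, config.samples,
        expression_offset=expression_offset,
    )
    dmr_truth: list[DMRTruth] = []
    if scenario == "planted_dmr":
        truth, dmr_truth = plant_dmrs(
            truth, n_dmrs, dmr_delta, dmr_width, seed=config.seed
        )
    paths["truth"] = outdir / "truth.tsv"
    truth.write(paths["truth"])
    if dmr_truth:
        paths["dmr_truth"] = outdir / "dmr_truth.tsv"
        write_tsv(
            pd.DataFrame(
                [(d.chrom, d.start, d.end, d.delta, ",".join(d.samples)) for d in dmr_truth],
                columns=["chrom", "start", "end", "delta", "samples"],
            ),
            paths["dmr_truth"],
        )

    counts, spike = simulate_counts(truth, config, config.seed)
    paths["counts"] = outdir / "true_counts.tsv"
    write_tsv(counts, paths["counts"])
    paths["spike"] = outdir / "true_spike.tsv"
    write_tsv(spike, paths["spike"])

    if with_reads:
        library = build_tag_library(genome, sites, config.tag_length)
        library.standard_tags = make_standard_tags(config.tag_length, seed=config.seed)
        paths["sites"] = outdir / "sites.tsv"
        write_sites(sites, paths["sites"])
        paths["tags"] = outdir / "tags.tsv"
        write_tag_library(library, paths["tags"], outdir / "ambiguous_tags.txt")
        index_table = make_index_table(config.samples, config.index_length, config.seed)
        paths["index_table"] = outdir / "index_table.tsv"
        write_tsv(index_table, paths["index_table"])
        write_tsv(
            pd.DataFrame(
                sorted(library.standard_tags.items()), columns=["tag", "library"]
            ),
            outdir / "standard_tags.tsv",
        )
        paths["standard_tags"] = outdir / "standard_tags.tsv"
        paths["reads"] = outdir / "reads.fastq"
        simulate_reads(
            counts, spike, library, index_table, config.seq_error_rate,
            config.seed, paths["reads"],
        )
    return paths
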