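"""Windowed differential-methylation testing.

Analysis units are 200-bp non-overlapping genome windows and known CGIs.
A unit enters a comparison only with >= min_sites (default 4, the ">3
sequenced CpGs" rule) member sites quantified in *both* samples; its means
are unweighted averages over that shared site set and its 2x2 table pools
the raw (not spike-in-scaled) m and u counts over the same set — the exact
test's sampling model is count-based, and within one comparison the scale
factors are near-constant.

A unit is a DMR in one comparison when |delta| > 25% and BH q < 0.05 (the
25% cutoff alone is available via ``delta_only``), and a *consistent* DMR
when it passes in every treated-vs-baseline comparison.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

_REL_TOL = 1e-7


def make_windows(chrom_lengths: dict[str, int], width: int = 200) -> pd.DataFrame:
    """Tile every chromosome into non-overlapping windows; trailing partial kept."""
    rows = []
    uid = 0
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, width):
            rows.append((f"win_{uid}", "window", chrom, start, min(start + width, length)))
            uid += 1
    return pd.DataFrame(rows, columns=["unit_id", "kind", "chrom", "start", "end"])


def make_cgi_units(cgis: pd.DataFrame) -> pd.DataFrame:
    """One analysis unit per (merged) CGI."""
    from .annotate import merge_intervals

    merged = merge_intervals(cgis) if len(cgis) else pd.DataFrame(columns=["chrom", "start", "end"])
    merged = merged.reset_index(drop=True)
    return pd.DataFrame(
        {"unit_id": [f"cgi_{i}" for i in range(len(merged))],
         "kind": "cgi",
         "chrom": merged["chrom"],
         "start": merged["start"],
         "end": merged["end"]}
    )


def unit_site_map(units: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Long (unit_id, site_id) membership table by position containment."""
    rows_unit: list[str] = []
    rows_site: list[int] = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos)
        pos_sorted = pos[order]
        ids_sorted = grp["site_id"].to_numpy()[order]
        uchr = units[units["chrom"] == chrom]
        for row in uchr.itertuples(index=False):
            lo = np.searchsorted(pos_sorted, row.start, side="left")
            hi = np.searchsorted(pos_sorted, row.end, side="left")
            if hi > lo:
                rows_unit.extend([row.unit_id] * (hi - lo))
                rows_site.extend(ids_sorted[lo:hi])
    return pd.DataFrame({"unit_id": rows_unit, "site_id": rows_site})


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher's exact test for a 2x2 table of non-negative counts.

    The conditional (hypergeometric) formulation: p is the total probability
    of all tables with the observed margins whose probability does not exceed
    the observed table's, the comparison made with relative tolerance 1e-7
    to absorb floating-point ties. A zero margin gives p = 1 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    # canonical orientation: p is invariant under row and column swaps, so
    # order rows/columns deterministically to make that invariance bit-exact
    if (a + b, a) > (c + d, c):
        (a, b), (c, d) = (c, d), (a, b)
    if (a + c, a) > (b + d, b):
        (a, c), (b, d) = (b, d), (a, c)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(support + 1) - gammaln(r1 - support + 1)
        + gammaln(r2 + 1) - gammaln(c1 - support + 1) - gammaln(r2 - c1 + support + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    log_obs = logpmf[a - lo]
    keep = logpmf <= log_obs + math.log1p(_REL_TOL)
    if keep.all():  # the observed table is modal: total conditional mass is 1
        return 1.0
    # fsum: the sum is exact to rounding, hence invariant under row/column swaps
    p = math.fsum(np.exp(logpmf[keep]))
    return min(1.0, p)


def unit_stats(
    member_ids: np.ndarray,
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    min_sites: int = 4,
) -> dict | None:
    """Means and pooled 2x2 table of one unit for one sample pair.

    *calls_a*/*calls_b* are single-sample call tables. Returns None when
    fewer than *min_sites* member sites are quantified in both samples
    (ineligibility is a value, not an error).
    """
    a = calls_a.set_index("site_id") if calls_a.index.name != "site_id" else calls_a
    b = calls_b.set_index("site_id") if calls_b.index.name != "site_id" else calls_b
    shared = [s for s in member_ids if s in a.index and s in b.index]
    if len(shared) < min_sites:
        return None
    sa, sb = a.loc[shared], b.loc[shared]
    return {
        "n_sites": len(shared),
        "mean_a": float(sa["level"].mean()),
        "mean_b": float(sb["level"].mean()),
        "table": (int(sa["m"].sum()), int(sa["u"].sum()), int(sb["m"].sum()), int(sb["u"].sum())),
    }


def compare_all_units(
    units: pd.DataFrame,
    calls_by_sample: dict[str, pd.DataFrame],
    baseline: str = "S0h",
    delta_cutoff: float = 0.25,
    q_cutoff: float = 0.05,
    min_sites: int = 4,
    delta_only: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Every eligible unit, every treated sample vs the baseline.

    Returns (comparisons, dmr_calls). BH adjustment is applied within each
    comparison across units. ``dmr_calls.consistent`` is True when the unit
    passes the joint delta+q criterion in all treated comparisons (or the
    delta-only criterion when *delta_only*); ``consistent_delta_only`` always
    reports the headline 25%-change-alone reading.
    """
    if baseline not in calls_by_sample:
        raise ConfigurationError(f"baseline sample {baseline!r} missing from calls")
    treated = [s for s in calls_by_sample if s != baseline]
    if not treated:
        raise ConfigurationError("need at least one treated sample besides the baseline")

    sites = pd.concat(
        [c[["site_id", "chrom", "pos"]] for c in calls_by_sample.values()]
    ).drop_duplicates("site_id")
    usm = unit_site_map(units, sites)
    base = calls_by_sample[baseline][["site_id", "level", "u", "m"]]

    comp_frames = []
    for sample_b in treated:
        tr = calls_by_sample[sample_b][["site_id", "level", "u", "m"]]
        merged = base.merge(tr, on="site_id", suffixes=("_a", "_b"))
        j = usm.merge(merged, on="site_id")
        g = j.groupby("unit_id").agg(
            n_sites=("site_id", "size"),
            mean_a=("level_a", "mean"),
            mean_b=("level_b", "mean"),
            m_a=("m_a", "sum"),
            u_a=("u_a", "sum"),
            m_b=("m_b", "sum"),
            u_b=("u_b", "sum"),
        )
        g = g[g["n_sites"] >= min_sites].reset_index()
        g["delta"] = g["mean_b"] - g["mean_a"]
        g["p"] = [
            fisher_exact_two_sided([[row.m_a, row.u_a], [row.m_b, row.u_b]])
            for row in g.itertuples(index=False)
        ]
        g["q"] = multipletests(g["p"], method="fdr_bh")[1] if len(g) else []
        g["passes_delta"] = g["delta"].abs() > delta_cutoff
        if delta_only:
            g["passes"] = g["passes_delta"]
        else:
            g["passes"] = g["passes_delta"] & (g["q"] < q_cutoff)
        g.insert(1, "sample_a", baseline)
        g.insert(2, "sample_b", sample_b)
        comp_frames.append(g)

    comparisons = pd.concat(comp_frames, ignore_index=True)
    comparisons = comparisons.merge(
        units[["unit_id", "kind", "chrom", "start", "end"]], on="unit_id", how="left"
    )
    front = ["unit_id", "kind", "chrom", "start", "end", "sample_a", "sample_b"]
    comparisons = comparisons[
        front + [c for c in comparisons.columns if c not in front]
    ]

    per_unit = comparisons.groupby("unit_id").agg(
        n_comparisons=("sample_b", "size"),
        all_pass=("passes", "all"),
        all_pass_delta=("passes_delta", "all"),
        max_abs_delta=("delta", lambda d: float(np.abs(d).max())),
    )
    per_unit["consistent"] = per_unit["all_pass"] & (per_unit["n_comparisons"] == len(treated))
    per_unit["consistent_delta_only"] = per_unit["all_pass_delta"] & (
        per_unit["n_comparisons"] == len(treated)
    )
    dmr = per_unit.drop(columns=["all_pass", "all_pass_delta"]).reset_index()
    dmr = dmr.merge(units[["unit_id", "kind", "chrom", "start", "end"]], on="unit_id", how="left")
    return comparisons, dmr


def site_level_consistency(
    calls_by_sample: dict[str, pd.DataFrame],
    baseline: str = "S0h",
    delta_cutoff: float = 0.25,
    strict_sign: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-site consistent-change flags across all treated-vs-baseline pairs.

    A site is eligible only when quantified in every sample; it is flagged
    when every treated sample differs from the baseline by more than
    *delta_cutoff* in absolute level (additionally with one common sign when
    *strict_sign*). Returns (flags, summary) where summary reports the
    flagged / eligible fraction and the excluded-site count.
    """
    if baseline not in calls_by_sample:
        raise ConfigurationError(f"baseline sample {baseline!r} missing from calls")
    samples = list(calls_by_sample)
    wide = None
    for s in samples:
        col = calls_by_sample[s][["site_id", "level"]].rename(columns={"level": s})
        wide = col if wide is None else wide.merge(col, on="site_id", how="outer")
    total = len(wide)
    eligible = wide.dropna().reset_index(drop=True)
    treated = [s for s in samples if s != baseline]
    deltas = eligible[treated].to_numpy() - eligible[[baseline]].to_numpy()
    exceed = np.abs(deltas) > delta_cutoff
    flags = exceed.all(axis=1)
    if strict_sign:
        same_sign = (deltas > 0).all(axis=1) | (deltas < 0).all(axis=1)
        flags = flags & same_sign
    out = eligible[["site_id"]].copy()
    out["consistent_change"] = flags
    summary = {
        "eligible": len(eligible),
        "excluded": total - len(eligible),
        "flagged": int(flags.sum()),
        "fraction": float(flags.mean()) if len(eligible) else float("nan"),
    }
    return out, summary
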