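"""Demultiplexing and mismatch-tolerant tag matching.

Reads are ``index + 18-bp tag``. The index must match a demux-sheet entry
exactly; the tag is matched against the tag library in mismatch tiers
0..max_mismatch, lowest non-empty tier wins, and a hit is accepted only when
exactly one library entry (genomic or spike-in standard) sits at that tier.
"less than 2 mismatches" is read literally as at most one (the default);
``max_mismatch=2`` restores the inclusive reading. Exhaustive neighborhood
lookup replaces a genome-scale aligner — at toy scale correctness dominates
speed and the hash lookups are exact.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable

import pandas as pd

from .digest import TagLibrary
from .errors import ConfigurationError

_BASES = "ACGT"


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one tag.

    kind: 'site' (genomic hit: site_id, side), 'standard' (spike-in hit:
    label), or 'reject' (reason 'no_hit' or 'ambiguous'). ``mismatches`` is
    the tier at which the decision was made (None for no_hit).
    """

    kind: str
    site_id: int | None = None
    side: str | None = None
    label: str | None = None
    reason: str | None = None
    mismatches: int | None = None


def _hits_at_tier(tag: str, library: TagLibrary, tier: int) -> set[tuple]:
    """Distinct library identities at exactly Hamming distance *tier*.

    Tier 0 is a direct lookup; tier k enumerates all candidates with exactly
    k substituted positions. Non-ACGT bases never match and so behave as a
    mismatch at their position.
    """
    hits: set[tuple] = set()

    def _lookup(candidate: str) -> None:
        entry = library.tags.get(candidate)
        if entry is not None:
            hits.add(("site",) + entry)
        label = library.standard_tags.get(candidate)
        if label is not None:
            hits.add(("standard", label))

    if tier == 0:
        _lookup(tag)
        return hits
    n = len(tag)
    for positions in combinations(range(n), tier):
        originals = [tag[p] for p in positions]
        for subs in product(_BASES, repeat=tier):
            if any(s == o for s, o in zip(subs, originals)):
                continue  # exact distance: every chosen position must change
            cand = list(tag)
            for p, s in zip(positions, subs):
                cand[p] = s
            _lookup("".join(cand))
    return hits


def match_tag(read_tag: str, tag_library: TagLibrary, max_mismatch: int = 1) -> MatchResult:
    """Match one tag; accept only a unique hit at the lowest non-empty tier."""
    read_tag = read_tag.upper()
    for tier in range(max_mismatch + 1):
        hits = _hits_at_tier(read_tag, tag_library, tier)
        if not hits:
            continue
        if len(hits) > 1:
            return MatchResult(kind="reject", reason="ambiguous", mismatches=tier)
        (hit,) = hits
        if hit[0] == "site":
            return MatchResult(kind="site", site_id=hit[1], side=hit[2], mismatches=tier)
        return MatchResult(kind="standard", label=hit[1], mismatches=tier)
    return MatchResult(kind="reject", reason="no_hit")


def demultiplex(
    reads: Iterable[tuple[str, str, str] | tuple[str, str]],
    index_table: pd.DataFrame,
) -> tuple[dict[tuple[str, str], list[str]], int]:
    """Split reads into per-(sample, library) tag streams by exact index match.

    *reads* yields FASTQ tuples (name, seq[, qual]). Returns ({stream: tags},
    unassigned count); stream sizes plus unassigned always equal the input
    size. Every stream in the demux sheet is present, possibly empty.
    """
    lengths = index_table["index"].str.len().unique()
    if len(lengths) != 1:
        raise ConfigurationError(f"ragged index lengths in table: {sorted(lengths)}")
    index_len = int(lengths[0])
    lookup = {
        row["index"]: (row["sample"], row["library"]) for _, row in index_table.iterrows()
    }
    streams: dict[tuple[str, str], list[str]] = {key: [] for key in lookup.values()}
    unassigned = 0
    for read in reads:
        seq = read[1].upper()
        key = lookup.get(seq[:index_len])
        if key is None:
            unassigned += 1
        else:
            streams[key].append(seq[index_len:])
    return streams, unassigned


def count_tags(
    streams: dict[tuple[str, str], list[str]],
    tag_library: TagLibrary,
    max_mismatch: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tally stream hits into the per-site dual-library count table.

    Returns (counts, spike_ins, report): counts has columns
    sample/site_id/u/m covering every site with a usable tag (zero-filled);
    spike_ins has sample/library/count; the report partitions every stream
    into mapped / standard / no_hit / ambiguous.
    """
    if not tag_library.tags and not tag_library.standard_tags:
        raise ConfigurationError("empty tag library")
    all_sites = sorted({sid for sid, _ in tag_library.tags.values()})
    samples = sorted({sample for sample, _ in streams})

    u: dict[tuple[str, int], int] = {}
    m: dict[tuple[str, int], int] = {}
    spike: dict[tuple[str, str], int] = {}
    report_rows = []
    for (sample, lib), tags in sorted(streams.items()):
        mapped = standard = no_hit = ambiguous = 0
        counter = u if lib == "hpaii" else m
        for tag in tags:
            res = match_tag(tag, tag_library, max_mismatch)
            if res.kind == "site":
                counter[(sample, res.site_id)] = counter.get((sample, res.site_id), 0) + 1
                mapped += 1
            elif res.kind == "standard":
                spike[(sample, lib)] = spike.get((sample, lib), 0) + 1
                standard += 1
            elif res.reason == "no_hit":
                no_hit += 1
            else:
                ambiguous += 1
        report_rows.append((sample, lib, len(tags), mapped, standard, no_hit, ambiguous))

    count_rows = [
        (sample, sid, u.get((sample, sid), 0), m.get((sample, sid), 0))
        for sample in samples
        for sid in all_sites
    ]
    counts = pd.DataFrame(count_rows, columns=["sample", "site_id", "u", "m"])
    spike_rows = [
        (sample, lib, spike.get((sample, lib), 0))
        for sample in samples
        for lib in ("hpaii", "inverse")
    ]
    spike_df = pd.DataFrame(spike_rows, columns=["sample", "library", "count"])
    report = pd.DataFrame(
        report_rows,
        columns=["sample", "library", "total", "mapped", "standard", "no_hit", "ambiguous"],
    )
    return counts, spike_df, report


def map_reads(
    reads: Iterable[tuple[str, str, str] | tuple[str, str]],
    tag_library: TagLibrary,
    index_table: pd.DataFrame,
    max_mismatch: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, int]:
    """demultiplex + count_tags in one call; returns (..., unassigned)."""
    streams, unassigned = demultiplex(reads, index_table)
    counts, spike, report = count_tags(streams, tag_library, max_mismatch)
    return counts, spike, report, unassigned
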