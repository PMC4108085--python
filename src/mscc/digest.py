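"""Virtual HpaII/MspI digestion: CCGG site discovery and the MmeI tag library.

Both HpaII and MspI recognize CCGG; HpaII is blocked by CpG methylation while
MspI cuts regardless. MmeI, cutting at a fixed distance from its site in the
ligated adaptor, releases an 18-bp genomic "tag" from each cut end. Because
CCGG is palindromic, each site yields two tags, one per side of the cut, and
every tag begins with CGG.

Coordinate convention (fixed here, used consistently by simulator and mapper):
the enzymes cut C^CGG, so for a site whose first C is at 0-based position *p*,

* forward-side tag = ``genome[p+1 : p+19]``
* reverse-side tag = reverse-complement of ``genome[p-15 : p+3]``

Tags running past a chromosome end are omitted for that side; tags that occur
at more than one (site, side) cannot identify their origin and are quarantined
in ``ambiguous_tags`` (both occurrences discarded, mirroring a unique-mapping
acceptance rule).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import write_tsv

CCGG = re.compile(r"(?=CCGG)")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

TAG_LENGTH = 18


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CCGGSite:
    """One CCGG occurrence: *pos* is the 0-based coordinate of its first C."""

    site_id: int
    chrom: str
    pos: int


@dataclass
class TagLibrary:
    """The dataset of all expected 18-bp tags.

    ``tags`` maps tag sequence -> (site_id, side); ``ambiguous_tags`` holds
    sequences seen at >1 (site, side); ``standard_tags`` maps spike-in
    standard tags -> library label ("hpaii" / "inverse").
    """

    tags: dict[str, tuple[int, str]]
    ambiguous_tags: set[str]
    standard_tags: dict[str, str] = field(default_factory=dict)
    tag_length: int = TAG_LENGTH

    def tags_for_site(self, site_id: int) -> list[str]:
        """Usable (unambiguous) tags of one site. O(n); fine at toy scale."""
        return [t for t, (sid, _) in self.tags.items() if sid == site_id]

    def site_tag_map(self) -> dict[int, list[str]]:
        """site_id -> list of usable tags, one pass over the library."""
        out: dict[int, list[str]] = {}
        for tag, (sid, _side) in self.tags.items():
            out.setdefault(sid, []).append(tag)
        return out


def find_ccgg_sites(genome: dict[str, str]) -> list[CCGGSite]:
    """Enumerate every CCGG occurrence, in genome order, with dense site ids.

    Overlapping occurrences are impossible for this motif but the scan uses a
    zero-width lookahead so the guarantee does not depend on that fact.
    """
    sites: list[CCGGSite] = []
    for chrom, seq in genome.items():
        for match in CCGG.finditer(seq.upper()):
            sites.append(CCGGSite(site_id=len(sites), chrom=chrom, pos=match.start()))
    return sites


def build_tag_library(
    genome: dict[str, str], sites: list[CCGGSite], tag_length: int = TAG_LENGTH
) -> TagLibrary:
    """Derive both MmeI tags of every site and classify ambiguous ones."""
    emitted: dict[str, list[tuple[int, str]]] = {}
    for site in sites:
        seq = genome[site.chrom]
        p = site.pos
        if p + 1 + tag_length <= len(seq):
            fwd = seq[p + 1 : p + 1 + tag_length].upper()
            emitted.setdefault(fwd, []).append((site.site_id, "fwd"))
        if p - (tag_length - 3) >= 0:
            rev = reverse_complement(seq[p - (tag_length - 3) : p + 3]).upper()
            emitted.setdefault(rev, []).append((site.site_id, "rev"))

    tags: dict[str, tuple[int, str]] = {}
    ambiguous: set[str] = set()
    for tag, origins in emitted.items():
        if len(set(origins)) == 1:
            tags[tag] = origins[0]
        else:
            ambiguous.add(tag)
    return TagLibrary(tags=tags, ambiguous_tags=ambiguous, tag_length=tag_length)


# -- external interfaces ----------------------------------------------------

def sites_to_frame(sites: list[CCGGSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {"site_id": [s.site_id for s in sites],
         "chrom": [s.chrom for s in sites],
         "pos": [s.pos for s in sites]}
    )


def write_sites(sites: list[CCGGSite], path: str | Path) -> None:
    write_tsv(sites_to_frame(sites), path)


def write_tag_library(library: TagLibrary, path: str | Path, ambiguous_path: str | Path | None = None) -> None:
    rows = sorted((tag, sid, side) for tag, (sid, side) in library.tags.items())
    write_tsv(pd.DataFrame(rows, columns=["tag", "site_id", "side"]), path)
    if ambiguous_path is not None:
        with open(ambiguous_path, "w") as fh:
            for tag in sorted(library.ambiguous_tags):
                fh.write(tag + "\n")
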