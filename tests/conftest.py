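"""Shared synthetic worlds for the test suite.

Everything is generated at test time from fixed seeds; nothing is read from
disk except what the tests themselves write into tmp paths.
"""
from __future__ import annotations

from types import SimpleNamespace

import pytest

from mscc.config import SimulationConfig
from mscc.digest import build_tag_library, find_ccgg_sites, sites_to_frame
from mscc.quantify import normalize_and_call
from mscc.simulate import (
    generate_genome,
    generate_methylome,
    make_index_table,
    make_standard_tags,
    simulate_counts,
)

TINY = dict(
    n_chroms=1, chrom_length=60_000, cgi_count=4, gene_count=6,
    shortrna_count=2, repressive_peaks_per_chrom=1, mean_depth=20.0,
    seq_error_rate=0.0,
)


def make_world(cfg: SimulationConfig, scenario: str = "null", seed: int | None = None) -> SimpleNamespace:
    """Genome + annotations + truth + counts + calls bundle for one config."""
    seed = cfg.seed if seed is None else seed
    genome, ann = generate_genome(cfg)
    sites = find_ccgg_sites(genome)
    sf = sites_to_frame(sites)
    truth = generate_methylome(sites, ann, scenario, seed, cfg.samples)
    counts, spike = simulate_counts(truth, cfg, seed)
    calls = normalize_and_call(counts, spike, sites=sf)
    return SimpleNamespace(
        cfg=cfg, genome=genome, ann=ann, sites=sites, sf=sf, truth=truth,
        counts=counts, spike=spike, calls=calls,
    )


@pytest.fixture(scope="session")
def tiny_world() -> SimpleNamespace:
    cfg = SimulationConfig(seed=3, **TINY)
    w = make_world(cfg)
    w.library = build_tag_library(w.genome, w.sites)
    w.library.standard_tags = make_standard_tags(seed=3)
    w.index_table = make_index_table(cfg.samples, cfg.index_length, 3)
    return w


@pytest.fixture(scope="session")
def coupled_world() -> SimpleNamespace:
    """Full-scale expression-coupled scenario shared by annotation/profile tests."""
    return make_world(SimulationConfig(seed=31), scenario="expression_coupled")
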