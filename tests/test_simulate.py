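"""Synthetic-data generator: determinism, planted structure, count model."""
import numpy as np
import pandas as pd
import pytest

from mscc.annotate import interval_membership
from mscc.config import SimulationConfig
from mscc.digest import find_ccgg_sites, sites_to_frame
from mscc.errors import ConfigurationError, PlacementError, SizingError
from mscc.profiles import assign_tertiles
from mscc.simulate import (
    MethylomeTruth,
    generate_genome,
    generate_methylome,
    plant_dmrs,
    simulate_counts,
    simulate_reads,
    make_index_table,
    make_standard_tags,
)

from conftest import TINY


def test_generate_genome_deterministic():
    cfg = SimulationConfig(seed=7, n_chroms=2, chrom_length=50_000, cgi_count=4,
                           gene_count=8, shortrna_count=2, repressive_peaks_per_chrom=1)
    g1, a1 = generate_genome(cfg)
    g2, a2 = generate_genome(cfg)
    assert g1 == g2
    assert list(g1) == ["chr1", "chr2"]
    assert all(len(s) == 50_000 for s in g1.values())
    assert a1.expression.equals(a2.expression)
    assert a1.cgis.equals(a2.cgis)


def test_genome_feature_contracts():
    cfg = SimulationConfig(seed=9, **TINY)
    genome, ann = generate_genome(cfg)
    assert set("".join(genome.values())) <= set("ACGT")
    assert (ann.expression["expression"] > 0).all()
    for g in ann.genes:
        assert g.strand in "+-" and g.tx_start < g.tx_end and g.exons
    assert set(ann.peaks) == set(cfg.marks)
    assert (ann.cgis["start"] < ann.cgis["end"]).all()


def test_cgi_ccgg_enrichment():
    """CCGG density inside CGIs at least 3x the outside density."""
    cfg = SimulationConfig(seed=7)
    genome, ann = generate_genome(cfg)
    sf = sites_to_frame(find_ccgg_sites(genome))
    inside, _ = interval_membership(sf, ann.cgis)
    cgi_bp = int((ann.cgis["end"] - ann.cgis["start"]).sum())
    total_bp = sum(len(s) for s in genome.values())
    ratio = (inside.sum() / cgi_bp) / ((~inside).sum() / (total_bp - cgi_bp))
    assert ratio >= 3


def test_zero_cgis_still_runs():
    cfg = SimulationConfig(seed=1, n_chroms=1, chrom_length=60_000, cgi_count=0,
                           gene_count=3, shortrna_count=1, repressive_peaks_per_chrom=1)
    genome, ann = generate_genome(cfg)
    assert len(ann.cgis) == 0
    sites = find_ccgg_sites(genome)
    truth = generate_methylome(sites, ann, "null", 1, cfg.samples)
    counts, spike = simulate_counts(truth, cfg, 1)
    assert len(counts) == len(sites) * len(cfg.samples)


def test_sizing_error_names_constraint():
    cfg = SimulationConfig(seed=0, n_chroms=1, chrom_length=10_000, gene_count=40)
    with pytest.raises(SizingError, match="chrom_length"):
        generate_genome(cfg)


def test_methylome_null_identical_and_bounded(tiny_world):
    truth = tiny_world.truth
    lv = truth.levels
    assert ((lv >= 0) & (lv <= 1)).all().all()
    for s in lv.columns[1:]:
        assert (lv[s] == lv[lv.columns[0]]).all()


def test_methylome_cgi_hypomethylation(coupled_world):
    w = coupled_world
    in_cgi, _ = interval_membership(w.sf, w.ann.cgis)
    lv = w.truth.levels["S0h"].to_numpy()
    assert lv[in_cgi].mean() < 0.15
    assert lv[in_cgi].mean() < lv[~in_cgi].mean()


def test_methylome_unknown_scenario(tiny_world):
    with pytest.raises(ConfigurationError, match="scenario"):
        generate_methylome(tiny_world.sites, tiny_world.ann, "bogus", 0, tiny_world.cfg.samples)


def test_expression_coupled_truth_offset(coupled_world):
    """Latter-gene-body truth difference between tertiles matches the offset."""
    w = coupled_world
    tert = assign_tertiles(w.ann.expression)
    lv = w.truth.levels["S0h"]
    pos = w.sf.set_index("site_id")
    means = {}
    for t in (0, 2):
        vals = []
        for g in w.ann.genes:
            if tert[g.name] != t:
                continue
            sub = pos[(pos["chrom"] == g.chrom) & (pos["pos"] >= g.tx_start) & (pos["pos"] < g.tx_end)]
            if g.strand == "+":
                frac = (sub["pos"] - g.tx_start) / g.length
            else:
                frac = (g.tx_end - 1 - sub["pos"]) / g.length
            vals.extend(lv.loc[sub.index[(frac >= 0.5)]].tolist())
        means[t] = np.mean(vals)
    assert means[2] - means[0] == pytest.approx(0.2, abs=0.03)


def _flat_truth(n=200, level=0.2, spacing=30, samples=("S0h", "S4h")):
    sites = pd.DataFrame({"site_id": range(n), "chrom": "chr1", "pos": np.arange(n) * spacing})
    levels = pd.DataFrame({s: np.full(n, level) for s in samples},
                          index=pd.Index(sites["site_id"], name="site_id"))
    return MethylomeTruth(sites, levels)


def test_plant_dmrs_shifts_and_clipping():
    truth = _flat_truth(level=0.2)
    shifted, dmrs = plant_dmrs(truth, n_dmrs=3, delta=0.4, width_bp=200, seed=1)
    assert len(dmrs) == 3
    # baseline untouched
    assert (shifted.levels["S0h"] == 0.2).all()
    for d in dmrs:
        in_region = (truth.sites["pos"] >= d.start) & (truth.sites["pos"] < d.end)
        ids = truth.sites.loc[in_region, "site_id"]
        assert len(ids) >= 4
        assert np.allclose(shifted.levels.loc[ids, "S4h"], 0.6)
        assert d.delta == pytest.approx(0.4)

    clipped, dmrs2 = plant_dmrs(_flat_truth(level=0.5), n_dmrs=1, delta=0.9, seed=2)
    d = dmrs2[0]
    in_region = (clipped.sites["pos"] >= d.start) & (clipped.sites["pos"] < d.end)
    ids = clipped.sites.loc[in_region, "site_id"]
    assert np.allclose(clipped.levels.loc[ids, "S4h"], 1.0)


def test_plant_dmrs_disjoint_and_eligible():
    truth = _flat_truth(n=400, level=0.3)
    _, dmrs = plant_dmrs(truth, n_dmrs=10, delta=0.4, seed=3)
    intervals = sorted((d.start, d.end) for d in dmrs)
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        assert e1 <= s2
    pos = truth.sites["pos"].to_numpy()
    for d in dmrs:
        assert ((pos >= d.start) & (pos < d.end)).sum() >= 4


def test_plant_dmrs_placement_error():
    truth = _flat_truth(n=20, spacing=500)  # one site per window: nothing eligible
    with pytest.raises(PlacementError, match="eligible"):
        plant_dmrs(truth, n_dmrs=1, delta=0.4, seed=0)


@pytest.mark.parametrize("level,lib_zero", [(0.0, "m"), (1.0, "u")])
def test_counts_degenerate_levels(level, lib_zero):
    truth = _flat_truth(n=500, level=level, samples=("S0h",))
    cfg = SimulationConfig(seed=0, samples=("S0h", "SX"), mean_depth=30.0)
    counts, _ = simulate_counts(truth, cfg, 5)
    assert (counts[lib_zero] == 0).all()
    assert (counts["u"] + counts["m"] > 0).any()


def test_counts_binomial_mean():
    """p=0.5 with equal efficiencies: raw fraction averages 0.5 +- 0.01."""
    truth = _flat_truth(n=2000, level=0.5, samples=("S0h",))
    cfg = SimulationConfig(seed=0, samples=("S0h", "SX"), mean_depth=100.0)
    counts, _ = simulate_counts(truth, cfg, 9)
    frac = counts["m"] / (counts["m"] + counts["u"])
    assert frac.mean() == pytest.approx(0.5, abs=0.01)


def test_reads_error_free_membership_and_conservation(tiny_world, tmp_path):
    w = tiny_world
    one = w.counts[(w.counts["sample"] == "S0h")].head(200)
    spike = w.spike[w.spike["sample"] == "S0h"]
    ledger = simulate_reads(one, spike, w.library, w.index_table, 0.0, 4, tmp_path / "r.fastq")
    from mscc.io import read_fastq

    idx_len = w.cfg.index_length
    known = set(w.library.tags) | set(w.library.standard_tags)
    n = 0
    for _, seq, _ in read_fastq(tmp_path / "r.fastq"):
        assert seq[idx_len:] in known
        n += 1
    expected = int(one["u"].sum() + one["m"].sum()) - ledger["dropped_reads"] + int(spike["count"].sum())
    assert n == ledger["total_reads"] == expected
    assert sum(ledger["streams"].values()) == n


def test_reads_single_site_index_routing(tmp_path):
    """u=3 for one site in one library: exactly 3 reads carry that index."""
    seq = "ATGCATGCATGCATGCATG" + "CCGG" + "TACGTACGTACGTACGTACG"
    genome = {"c": seq}
    sites = find_ccgg_sites(genome)
    from mscc.digest import build_tag_library

    lib = build_tag_library(genome, sites)
    lib.standard_tags = make_standard_tags(seed=0)
    index_table = make_index_table(("S0h", "S4h"), 6, 0)
    counts = pd.DataFrame([{"sample": "S0h", "site_id": 0, "u": 3, "m": 0}])
    spike = pd.DataFrame(columns=["sample", "library", "count"])
    simulate_reads(counts, spike, lib, index_table, 0.0, 0, tmp_path / "r.fastq")
    from mscc.io import read_fastq

    target = index_table.set_index(["sample", "library"])["index"][("S0h", "hpaii")]
    reads = list(read_fastq(tmp_path / "r.fastq"))
    assert len(reads) == 3
    assert all(seq.startswith(target) for _, seq, _ in reads)


def test_fastq_byte_determinism(tiny_world, tmp_path):
    w = tiny_world
    sub = w.counts[w.counts["sample"] == "S0h"].head(100)
    spike = w.spike[w.spike["sample"] == "S0h"]
    for name in ("a.fastq", "b.fastq"):
        simulate_reads(sub, spike, w.library, w.index_table, 0.01, 6, tmp_path / name)
    assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
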