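"""Windowed DMR machinery: units, Fisher's exact test, consistency rules."""
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from mscc.differential import (
    compare_all_units,
    fisher_exact_two_sided,
    make_cgi_units,
    make_windows,
    site_level_consistency,
    unit_site_map,
    unit_stats,
)
from mscc.errors import ConfigurationError


def enumeration_oracle(a, b, c, d):
    """Exact-integer hypergeometric enumeration of the two-sided p value."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    return sum(v for v in nums if v <= obs) / comb(n, c1)


# -- windows ----------------------------------------------------------------

def test_make_windows_tiling():
    w = make_windows({"c": 1000}, width=200)
    assert len(w) == 5
    assert (w["end"] - w["start"] == 200).all()
    w2 = make_windows({"c": 1050}, width=200)
    assert len(w2) == 6
    last = w2.iloc[-1]
    assert (last["start"], last["end"]) == (1000, 1050)


def test_windows_partition_sites(tiny_world):
    w = tiny_world
    units = make_windows({c: len(s) for c, s in w.genome.items()}, 200)
    usm = unit_site_map(units, w.sf)
    counts = usm.groupby("site_id").size()
    assert (counts == 1).all()
    assert set(usm["site_id"]) == set(w.sf["site_id"])


def test_cgi_units_cover_members(coupled_world):
    w = coupled_world
    units = make_cgi_units(w.ann.cgis)
    usm = unit_site_map(units, w.sf)
    lookup = units.set_index("unit_id")
    merged = usm.merge(w.sf, on="site_id")
    for row in merged.itertuples(index=False):
        u = lookup.loc[row.unit_id]
        assert u["start"] <= row.pos < u["end"]


# -- unit stats ---------------------------------------------------------------

def _calls(levels, u=None, m=None, sample="A"):
    n = len(levels)
    return pd.DataFrame(
        {"sample": sample, "site_id": range(n),
         "level": levels, "u": u if u is not None else [10] * n,
         "m": m if m is not None else [10] * n}
    )


def test_unit_stats_mean_and_threshold():
    a = _calls([0.2, 0.4, 0.6, 0.8])
    b = _calls([0.1, 0.2, 0.3, 0.4], sample="B")
    st_ = unit_stats(np.arange(4), a, b, min_sites=4)
    assert st_["mean_a"] == pytest.approx(0.5)
    assert st_["n_sites"] == 4
    assert unit_stats(np.arange(3), a, b, min_sites=4) is None  # ">3" means >=4


def test_unit_stats_pooled_table_oracle():
    rng = np.random.default_rng(0)
    u1, m1 = rng.integers(0, 40, 6), rng.integers(0, 40, 6)
    u2, m2 = rng.integers(0, 40, 6), rng.integers(0, 40, 6)
    a = _calls(rng.random(6), u1, m1)
    b = _calls(rng.random(6), u2, m2, sample="B")
    st_ = unit_stats(np.arange(6), a, b)
    assert st_["table"] == (m1.sum(), u1.sum(), m2.sum(), u2.sum())


# -- Fisher -------------------------------------------------------------------

@pytest.mark.parametrize(
    "table,expected",
    [
        ([[5, 5], [5, 5]], 1.0),
        ([[3, 1], [1, 3]], 34 / 70),
        ([[0, 0], [3, 4]], 1.0),   # zero margin convention
        ([[10, 0], [0, 10]], 2 / comb(20, 10)),
    ],
)
def test_fisher_known_values(table, expected):
    assert fisher_exact_two_sided(table) == pytest.approx(expected, abs=1e-12)


@given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
@settings(deadline=None, max_examples=300)
def test_fisher_equals_enumeration_oracle(cells):
    a, b, c, d = cells
    p = fisher_exact_two_sided([[a, b], [c, d]])
    assert p == pytest.approx(enumeration_oracle(a, b, c, d), abs=1e-10)
    assert 0 < p <= 1


@given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
@settings(deadline=None, max_examples=200)
def test_fisher_matches_scipy_and_symmetry(cells):
    a, b, c, d = cells
    p = fisher_exact_two_sided([[a, b], [c, d]])
    assert p == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], abs=1e-9)
    # swapping the samples (rows) leaves p unchanged exactly
    assert fisher_exact_two_sided([[c, d], [a, b]]) == p


# -- comparisons --------------------------------------------------------------

def _world_units(world):
    return pd.concat(
        [make_windows({c: len(s) for c, s in world.genome.items()}, 200),
         make_cgi_units(world.ann.cgis)],
        ignore_index=True,
    )


def test_identical_samples_not_passing(tiny_world):
    w = tiny_world
    base = w.calls[w.calls["sample"] == "S0h"].reset_index(drop=True)
    twin = base.assign(sample="S4h")
    comp, dmr = compare_all_units(_world_units(w), {"S0h": base, "S4h": twin})
    assert (comp["delta"] == 0).all()
    assert (comp["p"] == 1.0).all()
    assert not comp["passes"].any()
    assert not dmr["consistent"].any()


def test_sample_swap_negates_delta(tiny_world):
    w = tiny_world
    c = w.calls
    a = c[c["sample"] == "S0h"].reset_index(drop=True)
    b = c[c["sample"] == "S4h"].reset_index(drop=True)
    units = _world_units(w)
    fwd, _ = compare_all_units(units, {"S0h": a, "S4h": b}, baseline="S0h")
    rev, _ = compare_all_units(
        units, {"S0h": a, "S4h": b}, baseline="S4h"
    )
    m = fwd.set_index("unit_id")[["delta", "p"]].join(
        rev.set_index("unit_id")[["delta", "p"]], lsuffix="_f", rsuffix="_r", how="inner"
    )
    assert np.allclose(m["delta_f"], -m["delta_r"])
    assert (m["p_f"] == m["p_r"]).all()


def test_missing_baseline_errors(tiny_world):
    w = tiny_world
    base = w.calls[w.calls["sample"] == "S0h"].reset_index(drop=True)
    with pytest.raises(ConfigurationError, match="baseline"):
        compare_all_units(_world_units(w), {"S4h": base}, baseline="S0h")


def test_min_sites_monotone_eligibility(tiny_world):
    w = tiny_world
    by = {s: g.reset_index(drop=True) for s, g in w.calls.groupby("sample")}
    units = _world_units(w)
    sizes = []
    for ms in (2, 4, 6, 8):
        comp, _ = compare_all_units(units, by, min_sites=ms)
        sizes.append(len(comp))
    assert sizes == sorted(sizes, reverse=True)


# -- site-level consistency ----------------------------------------------------

def _sample_calls(levels_by_sample):
    out = {}
    for s, lv in levels_by_sample.items():
        out[s] = pd.DataFrame(
            {"sample": s, "site_id": range(len(lv)), "level": lv,
             "u": 50, "m": 50, "chrom": "c", "pos": range(len(lv))}
        )
    return out


def test_site_consistency_flags_and_impossible_cutoff():
    calls = _sample_calls(
        {"S0h": [0.1, 0.5], "S4h": [0.6, 0.5], "S12h": [0.7, 0.9], "S24h": [0.8, 0.5], "S96h": [0.9, 0.5]}
    )
    flags, summary = site_level_consistency(calls)
    assert flags.set_index("site_id")["consistent_change"].tolist() == [True, False]
    assert summary == {"eligible": 2, "excluded": 0, "flagged": 1, "fraction": 0.5}
    _, s2 = site_level_consistency(calls, delta_cutoff=1.0)
    assert s2["flagged"] == 0


def test_site_consistency_strict_sign():
    calls = _sample_calls(
        {"S0h": [0.5], "S4h": [0.9], "S12h": [0.1], "S24h": [0.9], "S96h": [0.1]}
    )
    _, loose = site_level_consistency(calls, strict_sign=False)
    _, strict = site_level_consistency(calls, strict_sign=True)
    assert loose["flagged"] == 1
    assert strict["flagged"] == 0


def test_site_consistency_excludes_partial_sites():
    calls = _sample_calls({"S0h": [0.1, 0.2], "S4h": [0.6, 0.7]})
    calls["S4h"] = calls["S4h"].iloc[:1]  # second site missing in S4h
    _, summary = site_level_consistency(calls)
    assert summary["eligible"] == 1 and summary["excluded"] == 1
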