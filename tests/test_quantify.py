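"""Spike-in normalization, depth filtering and summaries."""
import numpy as np
import pandas as pd
import pytest

from mscc.config import SimulationConfig
from mscc.errors import NormalizationError
from mscc.quantify import chromosome_summary, depth_accuracy_curve, normalize_and_call
from mscc.simulate import MethylomeTruth, draw_depth_means, simulate_counts


def _counts(rows):
    return pd.DataFrame(rows, columns=["sample", "site_id", "u", "m"])


def _spike(values):
    return pd.DataFrame(values, columns=["sample", "library", "count"])


EQUAL_SPIKE = _spike([("A", "hpaii", 1000), ("A", "inverse", 1000)])


def test_level_arithmetic_and_endpoints():
    counts = _counts([("A", 0, 10, 30), ("A", 1, 40, 0), ("A", 2, 0, 40)])
    calls = normalize_and_call(counts, EQUAL_SPIKE, min_depth=30)
    by = calls.set_index("site_id")["level"]
    assert by[0] == pytest.approx(0.75)
    assert by[1] == 0.0
    assert by[2] == 1.0


def test_spike_in_scaling_hand_example():
    """u=50, m=50 with spike_H=1000, spike_I=2000 (f_H = 2 f_I) gives 1/3."""
    counts = _counts([("A", 0, 50, 50)])
    spike = _spike([("A", "hpaii", 1000), ("A", "inverse", 2000)])
    calls = normalize_and_call(counts, spike, min_depth=30)
    assert calls["level"].iloc[0] == pytest.approx(1 / 3)


def test_scale_constant_cancels():
    counts = _counts([("A", 0, 17, 55)])
    spike = _spike([("A", "hpaii", 700), ("A", "inverse", 1300)])
    a = normalize_and_call(counts, spike, min_depth=1, scale_constant=1e6)
    b = normalize_and_call(counts, spike, min_depth=1, scale_constant=37.0)
    assert a["level"].iloc[0] == pytest.approx(b["level"].iloc[0], rel=1e-12)


def test_depth_filter_boundary():
    """Depth exactly 30 retained (the 30+ convention); 29 dropped; 0+0 dropped."""
    counts = _counts([("A", 0, 15, 15), ("A", 1, 15, 14), ("A", 2, 0, 0)])
    calls = normalize_and_call(counts, EQUAL_SPIKE, min_depth=30)
    assert set(calls["site_id"]) == {0}


def test_zero_spike_raises():
    counts = _counts([("A", 0, 50, 50)])
    spike = _spike([("A", "hpaii", 1000), ("A", "inverse", 0)])
    with pytest.raises(NormalizationError, match="inverse"):
        normalize_and_call(counts, spike)


def test_estimator_unbiased_and_binomial_rmse():
    """With equal efficiencies at depth d the call is Binomial(d, p)/d."""
    rng = np.random.default_rng(2)
    n, d = 4000, 100
    p = rng.beta(2, 2, n)
    sites = pd.DataFrame({"site_id": range(n), "chrom": "chr1", "pos": np.arange(n) * 40})
    truth = MethylomeTruth(sites, pd.DataFrame({"S0h": p}, index=pd.Index(sites["site_id"], name="site_id")))
    cfg = SimulationConfig(seed=0, samples=("S0h", "SX"), mean_depth=float(d))
    counts, _ = simulate_counts(truth, cfg, 3)
    # equal spike counts: scale factors cancel and the call is the raw fraction
    spike = _spike([("S0h", "hpaii", 1000), ("S0h", "inverse", 1000)])
    calls = normalize_and_call(counts, spike, min_depth=30).set_index("site_id")
    tr = pd.Series(p, index=sites["site_id"]).reindex(calls.index)
    err = calls["level"] - tr
    assert abs(err.mean()) < 0.005
    expected_rmse = np.sqrt(np.mean(tr * (1 - tr) / d))
    assert np.sqrt((err ** 2).mean()) == pytest.approx(expected_rmse, rel=0.15)


def test_normalization_corrects_efficiency_bias():
    """Biased libraries (e_H=1, e_I=0.8): spike-in scaling removes the bias."""
    rng = np.random.default_rng(4)
    n = 2000
    p = np.where(rng.random(n) < 0.7, rng.beta(8, 2, n), rng.beta(2, 8, n))
    sites = pd.DataFrame({"site_id": range(n), "chrom": "chr1", "pos": np.arange(n) * 40})
    truth = MethylomeTruth(sites, pd.DataFrame({"S0h": p}, index=pd.Index(sites["site_id"], name="site_id")))
    cfg = SimulationConfig(seed=0, samples=("S0h", "SX"), mean_depth=200.0, inverse_efficiency=0.8)
    counts, spike = simulate_counts(truth, cfg, 7)
    calls = normalize_and_call(counts, spike, min_depth=30).set_index("site_id")
    tr = pd.Series(p, index=sites["site_id"]).reindex(calls.index)
    norm_bias = float((calls["level"] - tr).mean())
    naive_bias = float((calls["m"] / (calls["m"] + calls["u"]) - tr).mean())
    assert abs(norm_bias) < 0.02
    assert abs(naive_bias) > 2 * abs(norm_bias)


def test_depth_curve_identical_and_shuffled():
    rng = np.random.default_rng(8)
    calls = pd.DataFrame(
        {"site_id": range(500), "level": rng.random(500), "depth": rng.integers(10, 200, 500)}
    )
    same = depth_accuracy_curve(calls, calls, [10, 50])
    assert np.allclose(same["pearson_r"], 1.0)
    shuffled = calls.copy()
    shuffled["level"] = rng.permutation(shuffled["level"].to_numpy())
    r = depth_accuracy_curve(calls, shuffled, [10])["pearson_r"].iloc[0]
    assert abs(r) < 0.15


def test_depth_curve_monotone_on_replicates():
    """Replicate correlation at depth threshold 100 beats threshold 10."""
    rng = np.random.default_rng(1)
    n = 3000
    p = np.where(rng.random(n) < 0.7, rng.beta(8, 2, n), rng.beta(2, 8, n))
    sites = pd.DataFrame({"site_id": range(n), "chrom": "chr1", "pos": np.arange(n) * 40})
    truth = MethylomeTruth(sites, pd.DataFrame({"R": p}, index=pd.Index(sites["site_id"], name="site_id")))
    cfg = SimulationConfig(seed=0, samples=("R", "X"), mean_depth=60.0, depth_dispersion=0.5)
    means = draw_depth_means(n, cfg, 5)
    c1, s1 = simulate_counts(truth, cfg, 6, depth_means=means)
    c2, s2 = simulate_counts(truth, cfg, 7, depth_means=means)
    r1 = normalize_and_call(c1, s1, min_depth=1)
    r2 = normalize_and_call(c2, s2, min_depth=1)
    curve = depth_accuracy_curve(r1, r2, [10, 100]).set_index("threshold")["pearson_r"]
    assert curve[100] > curve[10]


def test_depth_curve_skips_thin_thresholds(caplog):
    calls = pd.DataFrame({"site_id": range(20), "level": np.linspace(0, 1, 20), "depth": 15})
    curve = depth_accuracy_curve(calls, calls, [10, 100])
    assert list(curve["threshold"]) == [10]


def test_chromosome_summary_constant_and_oracle():
    rng = np.random.default_rng(3)
    sites = pd.DataFrame(
        {"site_id": range(300),
         "chrom": ["chr1"] * 100 + ["chr2"] * 100 + ["chr3"] * 100,
         "pos": list(range(100)) * 3}
    )
    calls = pd.DataFrame({"sample": "A", "site_id": range(200), "level": rng.random(200)})
    summ = chromosome_summary(calls, sites).set_index("chrom")
    merged = calls.merge(sites, on="site_id")
    for chrom, grp in merged.groupby("chrom"):
        assert summ.loc[chrom, "mean_level"] == pytest.approx(grp["level"].mean())
        assert summ.loc[chrom, "n"] == len(grp)
    # chromosome with no calls present with null mean
    assert summ.loc["chr3", "n"] == 0 and np.isnan(summ.loc["chr3", "mean_level"])
    const = calls.assign(level=0.2)
    s2 = chromosome_summary(const, sites).set_index("chrom")
    assert s2.loc["chr1", "mean_level"] == pytest.approx(0.2)
    assert s2.loc["overall", "mean_level"] == pytest.approx(0.2)


def test_planted_hypermethylated_chromosome_recovered():
    rng = np.random.default_rng(9)
    n = 400
    sites = pd.DataFrame(
        {"site_id": range(n), "chrom": ["chrHi"] * 200 + ["chrLo"] * 200,
         "pos": (list(range(200)) * 2)}
    )
    p = np.concatenate([np.full(200, 0.9), np.full(200, 0.2)])
    truth = MethylomeTruth(sites, pd.DataFrame({"S0h": p}, index=pd.Index(sites["site_id"], name="site_id")))
    cfg = SimulationConfig(seed=0, samples=("S0h", "SX"), mean_depth=60.0)
    counts, spike = simulate_counts(truth, cfg, 10)
    calls = normalize_and_call(counts, spike)
    summ = chromosome_summary(calls, sites).set_index("chrom")
    assert summ.loc["chrHi", "mean_level"] >= 0.8
    assert summ.loc["chrLo", "mean_level"] <= 0.3
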