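import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transporter_traits import (
    composition_stability,
    mg_mt_correlation,
    spearman_env_screen,
    spearman_exact_p,
    spearman_rho,
    spearman_test,
    succession_summary,
)


def tensor_from(data: dict, samples: list[str]) -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(data.keys(), names=["taxon", "category"])
    return pd.DataFrame(list(data.values()), index=idx, columns=samples)


# ---------------------------------------------------------------------------
# composition stability

def test_two_point_flip_has_sd_of_one_over_sqrt_two():
    tensor = tensor_from(
        {("T", "cation"): [10.0, 0.0], ("T", "anion"): [0.0, 10.0]}, ["s1", "s2"]
    )
    _, sd, score = composition_stability(tensor)
    assert sd.loc["T", "cation"] == pytest.approx(math.sqrt(0.5))
    assert score["T"] == pytest.approx(math.sqrt(0.5))


def test_constant_composition_has_zero_stability_score():
    tensor = tensor_from(
        {("T", "cation"): [8.0, 4.0, 2.0], ("T", "anion"): [8.0, 4.0, 2.0]},
        ["s1", "s2", "s3"],
    )
    mean, _, score = composition_stability(tensor)
    assert score["T"] == pytest.approx(0.0)
    assert mean.loc["T"].sum() == pytest.approx(1.0)


def test_taxon_in_single_sample_is_omitted():
    tensor = tensor_from(
        {("A", "cation"): [1.0, 0.0], ("B", "cation"): [1.0, 2.0]}, ["s1", "s2"]
    )
    with pytest.warns(UserWarning):
        mean, _, score = composition_stability(tensor, min_total=0.5)
    assert "A" not in score.index and "B" in score.index


def test_deep_run_profiles_are_stable(deep_run):
    """Planted profiles are season-constant, so the per-category s.d. over
    well-populated samples stays small at depth 10^6."""
    _, _, res = deep_run
    totals = res.tensor_mg.groupby(level="taxon").sum()
    floor = float(totals.values.max()) * 0.05
    _, _, score = composition_stability(res.tensor_mg, min_total=floor)
    assert (score < 0.05).all()


# ---------------------------------------------------------------------------
# MG–MT coupling

def panel_for(mg_samples, mt_samples, dates):
    rows = [{"sample_id": s, "date": d, "dataset": "MG"} for s, d in zip(mg_samples, dates)]
    rows += [{"sample_id": s, "date": d, "dataset": "MT"} for s, d in zip(mt_samples, dates)]
    return pd.DataFrame(rows)


def test_perfectly_coupled_expression_correlates_at_one():
    mg = tensor_from(
        {("T", "cation"): [1.0, 2.0, 3.0, 4.0], ("T", "anion"): [4.0, 3.0, 2.0, 1.0]},
        ["g1", "g2", "g3", "g4"],
    )
    mt = 2 * mg
    mt.columns = ["t1", "t2", "t3", "t4"]
    panel = panel_for(mg.columns, mt.columns, pd.date_range("2012-05-01", periods=4, freq="30D"))
    out = mg_mt_correlation(mg, mt, panel)
    assert np.allclose(out["coefficient"], 1.0)
    assert out["passes_filter"].all()


def test_constant_series_reported_missing():
    mg = tensor_from({("T", "cation"): [1.0, 1.0, 1.0]}, ["g1", "g2", "g3"])
    mt = tensor_from({("T", "cation"): [1.0, 2.0, 3.0]}, ["t1", "t2", "t3"])
    panel = panel_for(mg.columns, mt.columns, pd.date_range("2012-05-01", periods=3, freq="30D"))
    out = mg_mt_correlation(mg, mt, panel)
    assert out["coefficient"].isna().all()
    assert not out["passes_filter"].any()


def test_requires_matched_dates():
    mg = tensor_from({("T", "cation"): [1.0]}, ["g1"])
    mt = tensor_from({("T", "cation"): [1.0]}, ["t1"])
    panel = pd.DataFrame([
        {"sample_id": "g1", "date": "2012-05-01", "dataset": "MG"},
        {"sample_id": "t1", "date": "2012-06-01", "dataset": "MT"},
    ])
    with pytest.raises(ValueError):
        mg_mt_correlation(mg, mt, panel)


def test_independent_mg_mt_noise_is_centered_at_zero():
    """Null Monte-Carlo: with independent MG and MT values the mean
    coefficient over a 100-seed suite is near 0."""
    rng = np.random.default_rng(99)
    dates = pd.date_range("2012-05-01", periods=4, freq="30D")
    coefs = []
    for _ in range(100):
        mg = tensor_from({("T", "cation"): rng.random(4), ("T", "anion"): rng.random(4)},
                         ["g1", "g2", "g3", "g4"])
        mt = tensor_from({("T", "cation"): rng.random(4), ("T", "anion"): rng.random(4)},
                         ["t1", "t2", "t3", "t4"])
        out = mg_mt_correlation(mg, mt, panel_for(mg.columns, mt.columns, dates))
        coefs.extend(out["coefficient"].dropna())
    n_pairs = len(coefs)
    assert abs(np.mean(coefs)) < 3 / math.sqrt(n_pairs * (4 - 1))


# ---------------------------------------------------------------------------
# Spearman rank statistics

def bruteforce_spearman(x, y):
    """Exhaustive oracle: average ranks by sorting, Pearson on ranks, and
    a two-sided permutation p over all orderings of y's ranks."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    def pearson(a, b):
        ma, mb = np.mean(a), np.mean(b)
        da, db = np.array(a) - ma, np.array(b) - mb
        denom = math.sqrt((da @ da) * (db @ db))
        return float(da @ db) / denom if denom else math.nan

    rx, ry = ranks(list(x)), ranks(list(y))
    rho = pearson(rx, ry)
    hits = total = 0
    for perm in permutations(ry):
        total += 1
        if abs(pearson(rx, list(perm))) >= abs(rho) - 1e-12:
            hits += 1
    return rho, hits / total


def test_perfect_monotone_series():
    x = np.arange(5.0)
    assert spearman_rho(x, x * 3 + 1) == pytest.approx(1.0)
    assert spearman_rho(x, -x) == pytest.approx(-1.0)


def test_rho_and_exact_p_match_exhaustive_enumeration():
    rng = np.random.default_rng(8)
    cases = [
        ([1, 2, 2, 3], [1, 1, 2, 3]),          # ties on both sides
        ([1, 2, 3, 4, 5], [5, 3, 4, 1, 2]),
        ([2, 2, 2, 1, 3], [1, 2, 3, 4, 5]),
    ]
    cases += [
        (rng.integers(0, 4, size=n).tolist(), rng.integers(0, 4, size=n).tolist())
        for n in (4, 5, 6, 7) for _ in range(3)
    ]
    for x, y in cases:
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho, p = spearman_test(np.array(x, float), np.array(y, float))
        orho, op = bruteforce_spearman(x, y)
        assert rho == pytest.approx(orho, abs=1e-12)
        assert p == pytest.approx(op, abs=1e-12)


def test_spearman_equals_pearson_on_ranks():
    rng = np.random.default_rng(4)
    x, y = rng.random(20), rng.random(20)
    assert spearman_rho(x, y) == pytest.approx(
        stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
    )
    assert spearman_rho(x, y) == pytest.approx(stats.spearmanr(x, y).statistic)


def test_permutation_p_is_symmetric_under_sign_flip():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
    assert spearman_exact_p(x, y) == pytest.approx(spearman_exact_p(x, -y))


def test_t_approximation_for_larger_samples():
    rng = np.random.default_rng(10)
    x, y = rng.random(30), rng.random(30)
    rho, p = spearman_test(x, y)
    ref = stats.spearmanr(x, y)
    assert rho == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# environment screen

def screen_inputs():
    samples = [f"s{i}" for i in range(6)]
    rel = pd.DataFrame(
        {s: [i, 5 - i] for i, s in enumerate(samples)},
        index=["up", "down"], dtype=float,
    )
    env = pd.DataFrame({"temperature": np.arange(6.0)}, index=samples)
    return rel, env


def test_monotone_pairs_hit_plus_minus_one():
    rel, env = screen_inputs()
    out = spearman_env_screen(rel, env)
    rho = out.set_index("cluster_id")["rho"]
    assert rho["up"] == pytest.approx(1.0)
    assert rho["down"] == pytest.approx(-1.0)
    assert out.set_index("cluster_id")["passes"].all()


def test_signed_screen_drops_negative_correlations():
    rel, env = screen_inputs()
    out = spearman_env_screen(rel, env, use_absolute=False)
    passes = out.set_index("cluster_id")["passes"]
    assert bool(passes["up"]) and not bool(passes["down"])


def test_constant_series_excluded():
    samples = [f"s{i}" for i in range(5)]
    rel = pd.DataFrame({s: [1.0] for s in samples}, index=["flat"])
    env = pd.DataFrame({"temperature": np.arange(5.0)}, index=samples)
    out = spearman_env_screen(rel, env)
    assert out.empty


def test_missing_env_values_dropped_pairwise():
    samples = [f"s{i}" for i in range(6)]
    rel = pd.DataFrame({s: [float(i)] for i, s in enumerate(samples)}, index=["up"])
    env = pd.DataFrame({"temperature": [0.0, 1, np.nan, 3, 4, 5]}, index=samples)
    out = spearman_env_screen(rel, env)
    assert out.loc[0, "n"] == 5 and out.loc[0, "rho"] == pytest.approx(1.0)


def test_tightening_filters_never_adds_pairs():
    rng = np.random.default_rng(12)
    samples = [f"s{i}" for i in range(10)]
    rel = pd.DataFrame(rng.random((6, 10)), index=[f"c{i}" for i in range(6)],
                       columns=samples)
    env = pd.DataFrame(rng.random((10, 3)), index=samples, columns=["a", "b", "c"])
    base = spearman_env_screen(rel, env, rho_threshold=0.3, alpha=0.2)
    key = ["cluster_id", "variable"]
    passed = set(map(tuple, base.loc[base["passes"], key].values))
    for rho_t, alpha in [(0.5, 0.2), (0.3, 0.05), (0.7, 0.01)]:
        tighter = spearman_env_screen(rel, env, rho_threshold=rho_t, alpha=alpha)
        sub = set(map(tuple, tighter.loc[tighter["passes"], key].values))
        assert sub <= passed


# ---------------------------------------------------------------------------
# succession

def test_flat_series_peaks_at_first_sample():
    tensor = tensor_from({("T", "cation"): [2.0, 2.0, 2.0]}, ["s1", "s2", "s3"])
    panel = pd.DataFrame([
        {"sample_id": f"s{i+1}", "date": d, "dataset": "MG"}
        for i, d in enumerate(pd.date_range("2012-04-01", periods=3, freq="9D"))
    ])
    out = succession_summary(tensor, panel)
    assert out.loc[0, "peak_sample"] == "s1"


def test_single_taxon_gives_singleton_sequence():
    tensor = tensor_from({("T", "cation"): [1.0, 3.0, 2.0]}, ["s1", "s2", "s3"])
    panel = pd.DataFrame([
        {"sample_id": f"s{i+1}", "date": d, "dataset": "MG"}
        for i, d in enumerate(pd.date_range("2012-04-01", periods=3, freq="9D"))
    ])
    out = succession_summary(tensor, panel)
    assert len(out) == 1 and out.loc[0, "peak_sample"] == "s2"


def test_succession_order_matches_planted_peaks(deep_run):
    _, com, res = deep_run
    from transporter_traits.synthetic_data import DEFAULT_TAXA
    planted = [t.label for t in sorted(DEFAULT_TAXA, key=lambda t: t.peak_day)]
    tensor = res.tensor_mg.drop(index="Unclassified", level="taxon", errors="ignore")
    out = succession_summary(tensor, com.samples)
    assert list(out["taxon"]) == planted
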