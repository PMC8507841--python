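"""Seasonal trait statistics.

Covers four analyses run on the taxon × category × sample tensors and the
cluster abundance tables:

* **composition stability** — how constant each taxon's substrate-category
  composition stays across the year (per-category s.d. over samples; the
  stability score is the worst category);
* **MG–MT correlation** — per (taxon, category), correlation between
  metagenome relative abundance and metatranscriptome relative expression
  across the dates sampled in both datasets;
* **Spearman environment screen** — rank correlation of every transporter
  cluster against every environmental variable, with an exact permutation
  p-value at small n and the t approximation otherwise;
* **succession summary** — per-taxon peak timing and the resulting
  succession order.
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

ENV_VARIABLES = (
    "temperature", "salinity", "chla", "doc", "nh4", "no3", "po4", "sio4", "totn",
)


# ---------------------------------------------------------------------------
# composition stability

def composition_stability(
    tensor: pd.DataFrame,
    min_total: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-taxon mean composition, per-category s.d., and stability score.

    Compositions are computed only in samples where the taxon's total
    abundance exceeds ``min_total`` (avoids 0/0 compositions); taxa with
    fewer than two qualifying samples are omitted with a warning. The
    stability score is the maximum across categories of the s.d. over
    samples (0 = perfectly stable).
    """
    means, sds, scores = {}, {}, {}
    for taxon, block in tensor.groupby(level="taxon"):
        block = block.droplevel("taxon")
        totals = block.sum(axis=0)
        keep = totals > min_total
        if keep.sum() < 2:
            warnings.warn(f"taxon {taxon!r}: <2 samples above floor, omitted")
            continue
        comp = block.loc[:, keep].div(totals[keep], axis=1)
        means[taxon] = comp.mean(axis=1)
        sds[taxon] = comp.std(axis=1, ddof=1)
        scores[taxon] = float(sds[taxon].max())
    mean_df = pd.DataFrame(means).T
    sd_df = pd.DataFrame(sds).T
    mean_df.index.name = sd_df.index.name = "taxon"
    return mean_df, sd_df, pd.Series(scores, name="stability")


# ---------------------------------------------------------------------------
# MG–MT coupling

def mg_mt_correlation(
    mg_tensor: pd.DataFrame,
    mt_tensor: pd.DataFrame,
    panel: pd.DataFrame,
    method: str = "pearson",
    flag_threshold: float = 0.6,
) -> pd.DataFrame:
    """Correlate MG abundance with MT expression per (taxon, category).

    Samples are paired by date using ``panel`` (columns sample_id, date,
    dataset). Values are per-sample relative abundances (each dataset
    normalized to its own transporter total). Pairs with zero variance on
    either side are reported with a missing coefficient. ``passes_filter``
    flags coefficients strictly above ``flag_threshold``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    panel = panel.copy()
    panel["date"] = pd.to_datetime(panel["date"])
    mg_dates = panel.loc[panel["dataset"] == "MG"].set_index("date")["sample_id"]
    mt_dates = panel.loc[panel["dataset"] == "MT"].set_index("date")["sample_id"]
    matched = mg_dates.index.intersection(mt_dates.index).sort_values()
    if len(matched) < 2:
        raise ValueError("need >=2 dates sampled in both MG and MT")

    mg_rel = mg_tensor.div(mg_tensor.sum(axis=0), axis=1)
    mt_rel = mt_tensor.div(mt_tensor.sum(axis=0), axis=1)
    mg_cols = [mg_dates[d] for d in matched]
    mt_cols = [mt_dates[d] for d in matched]

    rows = []
    pairs = mg_rel.index.intersection(mt_rel.index)
    for taxon, category in pairs:
        x = mg_rel.loc[(taxon, category), mg_cols].to_numpy(dtype=float)
        y = mt_rel.loc[(taxon, category), mt_cols].to_numpy(dtype=float)
        n = len(matched)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            coef, p = np.nan, np.nan
        elif method == "pearson":
            coef, p = stats.pearsonr(x, y)
        else:
            coef, p = stats.spearmanr(x, y)
        rows.append({
            "taxon": taxon, "category": category,
            "coefficient": coef, "n": n, "p_value": p,
            "passes_filter": bool(coef > flag_threshold) if not np.isnan(coef) else False,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spearman environment screen

def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation on average-ranked data (ties averaged)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return math.nan
    return float(rx @ ry) / denom


def spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman's rho.

    Enumerates all n! orderings of one ranking (ties kept as a multiset),
    so it is only used for small n (<= 8 in the screen).
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = spearman_rho(x, y)
    if math.isnan(obs):
        return math.nan
    perms = np.array(list(permutations(ry)), dtype=float)
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt(float(rxc @ rxc) * (pc * pc).sum(axis=1))
    rhos = (pc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(obs) - 1e-12))


def spearman_test(x: np.ndarray, y: np.ndarray, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Exact permutation enumeration for n <= ``exact_max_n``; otherwise the t
    approximation with n − 2 degrees of freedom.
    """
    n = len(x)
    rho = spearman_rho(x, y)
    if math.isnan(rho) or n < 3:
        return rho, math.nan
    if n <= exact_max_n:
        return rho, spearman_exact_p(x, y)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return rho, 2 * float(stats.t.sf(abs(t), df=n - 2))


def spearman_env_screen(
    rel_abund: pd.DataFrame,
    env: pd.DataFrame,
    rho_threshold: float = 0.5,
    alpha: float = 0.05,
    use_absolute: bool = True,
    bh_correct: bool = False,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Screen transporter clusters against environmental variables.

    ``rel_abund`` is cluster × sample; ``env`` is sample × variable.
    Missing environmental values are dropped pairwise; pairs with fewer
    than 3 complete observations, or an all-constant series, are excluded.
    A pair passes when |rho| (or rho, with ``use_absolute=False``) exceeds
    ``rho_threshold`` and p < ``alpha``; a cluster is *retained* when any
    of its variables passes. Benjamini–Hochberg correction across all
    tested pairs is available but off by default.

    Returns a long table: cluster, variable, rho, n, p_value, passes,
    retained.
    """
    samples = rel_abund.columns.intersection(env.index)
    rows = []
    for cluster in rel_abund.index:
        xs = rel_abund.loc[cluster, samples].to_numpy(dtype=float)
        for var in env.columns:
            ys = env.loc[samples, var].to_numpy(dtype=float)
            ok = ~(np.isnan(xs) | np.isnan(ys))
            x, y = xs[ok], ys[ok]
            if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = spearman_test(x, y, exact_max_n=exact_max_n)
            rows.append({
                "cluster_id": cluster, "variable": var,
                "rho": rho, "n": len(x), "p_value": p,
            })
    out = pd.DataFrame(rows, columns=["cluster_id", "variable", "rho", "n", "p_value"])
    if out.empty:
        out["passes"] = out["retained"] = pd.Series(dtype=bool)
        return out
    if bh_correct:
        out["p_value"] = stats.false_discovery_control(out["p_value"], method="bh")
    strength = out["rho"].abs() if use_absolute else out["rho"]
    out["passes"] = (strength > rho_threshold) & (out["p_value"] < alpha)
    retained = set(out.loc[out["passes"], "cluster_id"])
    out["retained"] = out["cluster_id"].isin(retained)
    return out


# ---------------------------------------------------------------------------
# succession

def succession_summary(tensor: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon peak date and magnitude, ordered as a succession sequence.

    The peak is the argmax over samples of the taxon's total abundance;
    ties are broken by the earlier date. Rows are sorted by peak date
    (then taxon name), giving the succession order.
    """
    dates = panel.set_index("sample_id")["date"]
    dates = pd.to_datetime(dates)
    totals = tensor.groupby(level="taxon").sum()
    cols = sorted(totals.columns, key=lambda s: dates[s])
    totals = totals[cols]
    rows = []
    for taxon, series in totals.iterrows():
        peak_sample = series.idxmax()  # first occurrence wins ties (date order)
        rows.append({
            "taxon": taxon,
            "peak_sample": peak_sample,
            "peak_date": dates[peak_sample],
            "peak_value": float(series[peak_sample]),
        })
    out = pd.DataFrame(rows).sort_values(["peak_date", "taxon"]).reset_index(drop=True)
    out["succession_rank"] = np.arange(1, len(out) + 1)
    return out
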