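"""Which hotspot holds the fastest-evolving lineage?  A two-level
Monte-Carlo answer, plus an exact enumeration oracle for small tables.

One *sampling step* draws k lineages (default 5) without replacement
from each hotspot's pool of per-lineage net diversification rates, pools
the draws, ranks them by rate (descending) and records (a) the hotspot
of the top-ranked lineage and (b) how many of the top-ranked lineages
come from that hotspot before another hotspot appears (the "run" of
consecutive fastest lineages from one region).  A *process* repeats the
step n_samples times (default 1000) and reports, per hotspot, the
proportion of steps it was fastest and the maximum run length it
achieved.  The outer level repeats the whole process n_iterations times
(default 1000) with independent random streams and summarizes both
statistics with a mean and a 2.5–97.5 percentile interval.

Lineages are replaced between steps (the within-hotspot pools are small,
5–13 lineages); "without replacement" applies within one step.  Rate
ties are broken lexicographically by lineage id, a documented and
reproducible convention — with real-valued rates ties have measure zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from math import comb
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class ResamplingConfig:
    per_hotspot_k: int = 5
    n_samples: int = 1000
    n_iterations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.per_hotspot_k < 1:
            raise ValidationError("per_hotspot_k must be >= 1")
        if self.n_samples < 1 or self.n_iterations < 1:
            raise ValidationError("n_samples and n_iterations must be >= 1")


class RatePools:
    """Per-hotspot rate pools with the lexicographic tie rank precomputed.

    Built from a table with columns ``lineage_id``, ``hotspot`` and a
    rate column (``rate`` or ``r_mean_age``).
    """

    def __init__(self, table: pd.DataFrame):
        cols = set(table.columns)
        rate_col = "rate" if "rate" in cols else "r_mean_age"
        if not {"lineage_id", "hotspot", rate_col} <= cols:
            raise ValidationError(
                "rate table needs columns lineage_id, hotspot and rate/r_mean_age"
            )
        df = table[["lineage_id", "hotspot", rate_col]].rename(
            columns={rate_col: "rate"}
        )
        df = df.dropna(subset=["rate"])
        if not np.all(np.isfinite(df["rate"])):
            raise ValidationError("rates must be finite")
        if df["lineage_id"].duplicated().any():
            dupes = df.loc[df["lineage_id"].duplicated(), "lineage_id"].tolist()
            raise ValidationError(f"duplicate lineage ids: {dupes}")
        # ties break toward the alphabetically first lineage id
        df = df.sort_values("lineage_id").reset_index(drop=True)
        df["tie_rank"] = np.arange(len(df))
        self.hotspots: list[str] = sorted(df["hotspot"].unique())
        self._rates: Dict[str, np.ndarray] = {}
        self._ranks: Dict[str, np.ndarray] = {}
        for h in self.hotspots:
            sub = df[df["hotspot"] == h]
            self._rates[h] = sub["rate"].to_numpy(dtype=float)
            self._ranks[h] = sub["tie_rank"].to_numpy(dtype=np.int64)
        self._df = df

    def pool_size(self, hotspot: str) -> int:
        return len(self._rates[hotspot])

    def require_k(self, k: int) -> None:
        for h in self.hotspots:
            if self.pool_size(h) < k:
                raise ValidationError(
                    f"hotspot {h!r} has {self.pool_size(h)} lineages, needs >= {k}"
                )

    def rates(self, hotspot: str) -> np.ndarray:
        return self._rates[hotspot]

    def tie_ranks(self, hotspot: str) -> np.ndarray:
        return self._ranks[hotspot]


def _as_pools(table) -> RatePools:
    return table if isinstance(table, RatePools) else RatePools(table)


# ----------------------------------------------------------------------
# single step


def sample_once(
    table, k: int, rng: np.random.Generator
) -> Tuple[str, int]:
    """One sampling step: draw k per hotspot, rank the pool, return the
    fastest lineage's hotspot and the top-of-ranking run length."""
    pools = _as_pools(table)
    pools.require_k(k)
    rates, ranks, owners = [], [], []
    for i, h in enumerate(pools.hotspots):
        idx = rng.choice(pools.pool_size(h), size=k, replace=False)
        rates.append(pools.rates(h)[idx])
        ranks.append(pools.tie_ranks(h)[idx])
        owners.append(np.full(k, i))
    rates = np.concatenate(rates)
    ranks = np.concatenate(ranks)
    owners = np.concatenate(owners)
    order = np.lexsort((ranks, -rates))  # primary: rate desc; ties: lexicographic
    sorted_owner = owners[order]
    top = sorted_owner[0]
    run = 1
    while run < len(sorted_owner) and sorted_owner[run] == top:
        run += 1
    return pools.hotspots[top], run


# ----------------------------------------------------------------------
# one process of n_samples steps (vectorized)


def _sample_matrix(
    pools: RatePools, k: int, n_samples: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized draws: returns (rates, tie_ranks, owners), each of shape
    (n_samples, k * n_hotspots)."""
    rate_blocks, rank_blocks, owner_blocks = [], [], []
    for i, h in enumerate(pools.hotspots):
        m = pools.pool_size(h)
        # k-without-replacement per row: permute row-wise, take first k
        perm = rng.permuted(
            np.broadcast_to(np.arange(m), (n_samples, m)).copy(), axis=1
        )[:, :k]
        rate_blocks.append(pools.rates(h)[perm])
        rank_blocks.append(pools.tie_ranks(h)[perm])
        owner_blocks.append(np.full((n_samples, k), i, dtype=np.int64))
    return (
        np.concatenate(rate_blocks, axis=1),
        np.concatenate(rank_blocks, axis=1),
        np.concatenate(owner_blocks, axis=1),
    )


def run_process(
    table, k: int, n_samples: int, rng: np.random.Generator
) -> pd.DataFrame:
    """n_samples independent steps; per hotspot, the fraction of steps it
    held the fastest lineage and the maximum top-of-ranking run length
    (0 for a hotspot that was never fastest).

    Also reports ``max_step_run`` — the longest run of *consecutive
    steps* won by the hotspot — as a secondary statistic under the
    alternative reading of "consecutive fastest lineages".
    """
    pools = _as_pools(table)
    pools.require_k(k)
    rates, ranks, owners = _sample_matrix(pools, k, n_samples, rng)
    order = np.lexsort((ranks, -rates), axis=1)
    sorted_owner = np.take_along_axis(owners, order, axis=1)
    top = sorted_owner[:, 0]
    # run length: first column where the owner differs from the top owner
    differs = sorted_owner != top[:, None]
    any_diff = differs.any(axis=1)
    run = np.where(any_diff, differs.argmax(axis=1), sorted_owner.shape[1])
    n_hot = len(pools.hotspots)
    prop = np.bincount(top, minlength=n_hot) / n_samples
    max_run = np.zeros(n_hot, dtype=int)
    for i in range(n_hot):
        mask = top == i
        if mask.any():
            max_run[i] = int(run[mask].max())
    return pd.DataFrame(
        {
            "hotspot": pools.hotspots,
            "prop_fastest": prop,
            "max_run": max_run,
            "max_step_run": _max_step_runs(top, n_hot),
        }
    )


def _max_step_runs(top: np.ndarray, n_hot: int) -> np.ndarray:
    """Longest streak of consecutive steps won by each hotspot."""
    out = np.zeros(n_hot, dtype=int)
    streak_owner, streak = -1, 0
    for t in top:
        if t == streak_owner:
            streak += 1
        else:
            streak_owner, streak = t, 1
        if streak > out[t]:
            out[t] = streak
    return out


# ----------------------------------------------------------------------
# outer level


@dataclass(frozen=True)
class ResamplingSummary:
    """Per-hotspot means and percentile CIs of both statistics across
    iterations, plus the full per-iteration arrays."""

    table: pd.DataFrame  # one row per hotspot
    per_iteration_prop: pd.DataFrame  # iterations x hotspots
    per_iteration_max_run: pd.DataFrame
    config: ResamplingConfig


def summarize(table, config: ResamplingConfig) -> ResamplingSummary:
    """Run ``n_iterations`` independent processes and summarize.

    Each iteration draws its random stream from
    ``SeedSequence([seed, iteration])`` — a documented counter scheme, so
    iterations are independent and reproducible (and could run in
    parallel without changing the result).
    """
    pools = _as_pools(table)
    pools.require_k(config.per_hotspot_k)
    props, max_runs = [], []
    for it in range(config.n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, it]))
        res = run_process(pools, config.per_hotspot_k, config.n_samples, rng)
        props.append(res["prop_fastest"].to_numpy())
        max_runs.append(res["max_run"].to_numpy())
    props = np.asarray(props)
    max_runs = np.asarray(max_runs)
    rows = []
    for i, h in enumerate(pools.hotspots):
        p_lo, p_hi = np.percentile(props[:, i], [2.5, 97.5])
        r_lo, r_hi = np.percentile(max_runs[:, i], [2.5, 97.5])
        rows.append(
            {
                "hotspot": h,
                "prob_fastest_mean": props[:, i].mean(),
                "prob_fastest_ci_low": p_lo,
                "prob_fastest_ci_high": p_hi,
                "max_run_mean": max_runs[:, i].mean(),
                "max_run_ci_low": r_lo,
                "max_run_ci_high": r_hi,
            }
        )
    return ResamplingSummary(
        table=pd.DataFrame(rows),
        per_iteration_prop=pd.DataFrame(props, columns=pools.hotspots),
        per_iteration_max_run=pd.DataFrame(max_runs, columns=pools.hotspots),
        config=config,
    )


# ----------------------------------------------------------------------
# exact oracle


def exact_fastest_probability(
    table, k: int, max_combinations: int = 10**6
) -> Dict[str, float]:
    """Exact per-hotspot probability of holding the fastest lineage.

    Enumerates the product of all per-hotspot k-subsets (equiprobable)
    and tallies which hotspot supplies the top-ranked lineage under the
    same descending-rate, lexicographic-tie ordering the sampler uses.
    Intended as a validation oracle for small tables.
    """
    pools = _as_pools(table)
    pools.require_k(k)
    total = 1
    for h in pools.hotspots:
        total *= comb(pools.pool_size(h), k)
        if total > max_combinations:
            raise ValidationError(
                f"enumeration would exceed {max_combinations} joint draws"
            )
    per_hotspot_subsets = []
    for h in pools.hotspots:
        rates, ranks = pools.rates(h), pools.tie_ranks(h)
        subsets = []
        for combo in combinations(range(len(rates)), k):
            # best lineage of the subset under the ordering
            best = min(combo, key=lambda j: (-rates[j], ranks[j]))
            subsets.append((rates[best], ranks[best]))
        per_hotspot_subsets.append(subsets)
    counts = {h: 0 for h in pools.hotspots}
    for joint in product(*per_hotspot_subsets):
        winner = max(
            range(len(joint)), key=lambda i: (joint[i][0], -joint[i][1])
        )
        counts[pools.hotspots[winner]] += 1
    return {h: c / total for h, c in counts.items()}
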