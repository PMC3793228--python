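"""Per-hotspot summaries: mean rates with bootstrap CIs and density metrics.

Each biodiversity hotspot contributes a set of per-lineage net
diversification rates; the hotspot's rate is their arithmetic mean, with
a 95% percentile-bootstrap confidence interval (resample the lineages
with replacement, recompute the mean).  Two per-area metrics put
richness and tempo on a common footing: species per km², and speciation
events per Myr per km² (mean rate / area, using the unrounded mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class HotspotMeta:
    """Static attributes of one hotspot (area, richness)."""

    hotspot: str
    area_km2: float
    species_total: int
    species_endemic: Optional[int] = None
    #: published species/km² cell, when reproducing a printed table
    species_per_km2_printed: Optional[float] = None
    #: published hotspot mean rate, usable when per-lineage rates are not
    mean_rate_printed: Optional[float] = None
    speciation_density_printed: Optional[float] = None

    def __post_init__(self):
        if self.area_km2 <= 0:
            raise ValidationError(f"{self.hotspot}: area must be > 0 km²")
        if (
            self.species_endemic is not None
            and self.species_endemic > self.species_total
        ):
            raise ValidationError(
                f"{self.hotspot}: endemic species exceed total species"
            )


@dataclass(frozen=True)
class HotspotSummary:
    hotspot: str
    n_lineages: int
    mean_rate: float
    ci_low: float
    ci_high: float
    species_density: float  # species per km²
    speciation_density: float  # events per Myr per km²


def hotspot_mean_rate(rates: Sequence[float]) -> float:
    """Arithmetic mean of unrounded per-lineage rates."""
    arr = np.asarray(list(rates), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot average an empty set of rates")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("rates must all be finite")
    return float(arr.mean())


def bootstrap_mean_ci(
    values: Sequence[float],
    n_boot: int = 1000,
    conf: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> Tuple[float, float, float]:
    """Percentile bootstrap of the mean.

    Resamples ``len(values)`` items with replacement ``n_boot`` times and
    reads the CI off the (alpha/2, 1-alpha/2) empirical percentiles of the
    resampled means.  Deterministic for a given seed.

    Returns ``(mean, ci_low, ci_high)``.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot bootstrap an empty set of values")
    if n_boot < 1:
        raise ValidationError(f"n_boot must be >= 1, got {n_boot}")
    mean = float(arr.mean())
    if arr.size == 1:
        warnings.warn(
            "bootstrap CI of a single value is degenerate", stacklevel=2
        )
        return mean, mean, mean
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    boot_means = arr[idx].mean(axis=1)
    alpha = (1.0 - conf) / 2.0
    lo, hi = np.quantile(boot_means, [alpha, 1.0 - alpha])
    return mean, float(lo), float(hi)


def species_density(species_total: int, area_km2: float) -> float:
    """Species per km²."""
    if area_km2 <= 0:
        raise ValidationError(f"area must be > 0 km², got {area_km2}")
    return species_total / area_km2


def speciation_density(mean_rate: float, area_km2: float) -> float:
    """Speciation events per Myr per km² (unrounded mean rate / area)."""
    if area_km2 <= 0:
        raise ValidationError(f"area must be > 0 km², got {area_km2}")
    if mean_rate < 0:
        raise ValidationError(f"mean rate must be >= 0, got {mean_rate}")
    return mean_rate / area_km2


def _consistent_with_printed(computed: float, printed: float) -> bool:
    """A printed cell is accepted when it equals the computed value either
    rounded or truncated to the precision it was printed at.

    Published tables mix the two conventions; a cell that matches neither
    is internally inconsistent with its own row.
    """
    s = f"{printed:.10f}".rstrip("0")
    ndec = len(s.split(".")[1]) if "." in s else 0
    ndec = max(ndec, 1)
    scale = 10**ndec
    rounded = round(computed, ndec)
    truncated = np.floor(computed * scale) / scale
    return np.isclose(printed, rounded, atol=0.51 / scale) or np.isclose(
        printed, truncated, atol=0.51 / scale
    )


def validate_density_cells(metas: Iterable[HotspotMeta]) -> pd.DataFrame:
    """Check each hotspot's printed species/km² cell against its own
    area and richness columns; rows that match neither the rounded nor
    the truncated recomputation are flagged inconsistent."""
    rows = []
    for m in metas:
        computed = species_density(m.species_total, m.area_km2)
        printed = m.species_per_km2_printed
        rows.append(
            {
                "hotspot": m.hotspot,
                "species_per_km2_computed": computed,
                "species_per_km2_printed": printed,
                "consistent": (
                    None
                    if printed is None
                    else _consistent_with_printed(computed, printed)
                ),
            }
        )
    return pd.DataFrame(rows)


def assemble_summary(
    rate_df: pd.DataFrame,
    metas: Iterable[HotspotMeta],
    n_boot: int = 1000,
    conf: float = 0.95,
    seed: int | None = None,
) -> List[HotspotSummary]:
    """Join per-lineage mean-age rates with hotspot metadata.

    ``rate_df`` needs columns ``hotspot`` and ``r_mean_age`` (the output
    of :func:`paramodiv.rates.rate_table`, or any table of per-lineage
    rates).  One summary per hotspot present in the rate table, sorted
    by hotspot name; every such hotspot must have metadata.  Bootstrap
    seeds are derived per hotspot from ``seed`` so the output does not
    depend on input ordering.
    """
    meta_by_name = {m.hotspot: m for m in metas}
    summaries = []
    for hotspot in sorted(rate_df["hotspot"].unique()):
        if hotspot not in meta_by_name:
            raise ValidationError(f"no metadata for hotspot {hotspot!r}")
        meta = meta_by_name[hotspot]
        rates = (
            rate_df.loc[rate_df["hotspot"] == hotspot]
            .sort_values("lineage_id")["r_mean_age"]
            .dropna()
            .to_numpy()
        )
        sub_seed = (
            None
            if seed is None
            else np.random.SeedSequence([seed, _stable_hash(hotspot)])
        )
        rng = np.random.default_rng(sub_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean, lo, hi = bootstrap_mean_ci(rates, n_boot=n_boot, conf=conf, seed=rng)
        summaries.append(
            HotspotSummary(
                hotspot=hotspot,
                n_lineages=len(rates),
                mean_rate=mean,
                ci_low=lo,
                ci_high=hi,
                species_density=species_density(meta.species_total, meta.area_km2),
                speciation_density=speciation_density(mean, meta.area_km2),
            )
        )
    return summaries


def _stable_hash(name: str) -> int:
    # deterministic across processes, unlike hash()
    h = 2166136261
    for byte in name.encode("utf-8"):
        h = ((h ^ byte) * 16777619) % (2**31)
    return h


def summary_frame(summaries: Iterable[HotspotSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
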