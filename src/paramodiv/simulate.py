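"""Constant-rate Yule and birth–death chronogram simulators, and synthetic
per-hotspot lineage-rate tables.

These generators stand in for the study system when exercising the
estimation, comparison and resampling machinery with known ground truth:

* :func:`simulate_yule` — pure-birth (no extinction) trees from a
  two-lineage crown start, exponential waiting times, stopped either at
  a fixed height (crown age) or at a fixed number of tips.
* :func:`simulate_birth_death` — full birth–death process with the
  extinct lineages pruned away (the reconstructed tree of the extant
  sample), optionally rejection-sampled until >= 2 lineages survive.
* :func:`generate_lineage_table` — per-hotspot lineage rates drawn from
  a log-normal, mirroring the statistical shape of published rate
  tables: positive, right-skewed, with a controllable per-hotspot
  location and spread.

All randomness flows through a single integer seed; the same seed yields
byte-identical serialized trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SimulationError, ValidationError
from .trees import Chronogram, chronogram_from_string

_MAX_REJECTIONS = 10**5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one birth–death simulation.

    ``birth_rate`` (lambda) and ``death_rate`` (mu) are per lineage per
    Myr; the net diversification rate is lambda - mu and the relative
    extinction fraction eps = mu/lambda must be < 1.  Exactly one of
    ``stop_time`` (tree height, Myr) or ``stop_tips`` must be set.
    ``crown_start`` starts from the two daughters of a crown node (the
    convention matching crown-age tables); stem start begins from one.
    """

    birth_rate: float
    death_rate: float = 0.0
    stop_time: Optional[float] = None
    stop_tips: Optional[int] = None
    condition_on_survival: bool = False
    crown_start: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.birth_rate <= 0:
            raise ValidationError("birth_rate must be > 0")
        if not 0 <= self.death_rate < self.birth_rate:
            raise ValidationError("need 0 <= death_rate < birth_rate")
        if (self.stop_time is None) == (self.stop_tips is None):
            raise ValidationError("set exactly one of stop_time / stop_tips")
        if self.stop_time is not None and self.stop_time <= 0:
            raise ValidationError("stop_time must be > 0")
        if self.stop_tips is not None and self.stop_tips < 2:
            raise ValidationError("stop_tips must be >= 2")


class _Lineage:
    __slots__ = ("birth", "death", "children", "index")

    def __init__(self, birth: float, index: int):
        self.birth = birth
        self.death: Optional[float] = None
        self.children: List["_Lineage"] = []
        self.index = index  # creation order, used for tip labels


def _gillespie(config: SimulationConfig, rng: np.random.Generator):
    """One realization.  Returns (roots, extant, stop_time, event_times)
    or None if the process died out before satisfying the stop rule."""
    lam, mu = config.birth_rate, config.death_rate
    total_rate = lam + mu
    counter = 0

    def new(birth):
        nonlocal counter
        counter += 1
        return _Lineage(birth, counter)

    if config.crown_start:
        roots = [new(0.0), new(0.0)]
    else:
        roots = [new(0.0)]
    active = list(roots)
    t = 0.0
    event_times = [0.0] if config.crown_start else []
    if config.stop_tips is not None and len(active) >= config.stop_tips:
        t = rng.exponential(1.0 / (len(active) * total_rate))
        return roots, active, t, event_times
    while True:
        wait = rng.exponential(1.0 / (len(active) * total_rate))
        if config.stop_time is not None and t + wait > config.stop_time:
            t = config.stop_time
            break
        t += wait
        lineage = active[rng.integers(len(active))]
        if rng.random() < lam / total_rate:
            lineage.children = [new(t), new(t)]
            active.remove(lineage)
            active.extend(lineage.children)
            event_times.append(t)
            if config.stop_tips is not None and len(active) == config.stop_tips:
                # stop just before the next event so pendant edges have length
                t += rng.exponential(1.0 / (len(active) * total_rate))
                break
        else:
            lineage.death = t
            active.remove(lineage)
            if not active:
                return None
    return roots, active, t, event_times


def _reconstruct(lineage: _Lineage, stop: float):
    """Collapse extinct subtrees; returns (newick_fragment, node_time) or
    None if no extant descendant.  node_time is ``stop`` for a tip and
    the split time for an internal node."""
    if lineage.children:
        subs = [_reconstruct(c, stop) for c in lineage.children]
        subs = [s for s in subs if s is not None]
        if not subs:
            return None
        if len(subs) == 1:
            return subs[0]
        split = lineage.children[0].birth
        parts = ",".join(
            f"{frag}:{time - split:.12f}" for frag, time in subs
        )
        return f"({parts})", split
    if lineage.death is not None:
        return None
    return f"T{lineage.index}", stop


def _to_chronogram(roots, stop: float, event_times) -> Optional[Chronogram]:
    subs = [_reconstruct(r, stop) for r in roots]
    subs = [s for s in subs if s is not None]
    if not subs:
        return None
    if len(subs) == 1:
        frag, time = subs[0]
        if not frag.startswith("("):
            return None  # single surviving tip: no crown group
        newick = frag + ";"
    else:
        parts = ",".join(f"{frag}:{time - 0.0:.12f}" for frag, time in subs)
        newick = f"({parts});"
    chron = chronogram_from_string(newick)
    chron.event_times = sorted(event_times)
    return chron


def simulate_yule(config: SimulationConfig) -> Chronogram:
    """Pure-birth chronogram; ``death_rate`` must be 0.

    Stopped at ``stop_time`` the tree's crown age equals it exactly;
    stopped at ``stop_tips`` the tree has exactly that many tips.
    Speciation event times are recorded on ``Chronogram.event_times``.
    """
    if config.death_rate != 0.0:
        raise ValidationError("simulate_yule requires death_rate = 0")
    rng = np.random.default_rng(config.seed)
    out = _gillespie(config, rng)
    assert out is not None  # pure birth cannot die out
    roots, _, stop, event_times = out
    chron = _to_chronogram(roots, stop, event_times)
    assert chron is not None
    return chron


def simulate_birth_death(config: SimulationConfig) -> Chronogram:
    """Reconstructed (extant-only) birth–death chronogram.

    With ``condition_on_survival`` the process is rejection-sampled until
    at least two lineages survive to the present (so a crown group
    exists); note the reconstructed crown age can be younger than
    ``stop_time`` when one of the two founding lineages died out.
    Without conditioning, a realization with < 2 extant lineages raises
    :class:`SimulationError`.
    """
    rng = np.random.default_rng(config.seed)
    attempts = _MAX_REJECTIONS if config.condition_on_survival else 1
    for _ in range(attempts):
        out = _gillespie(config, rng)
        if out is None:
            continue
        roots, active, stop, event_times = out
        if len(active) < 2:
            continue
        chron = _to_chronogram(roots, stop, event_times)
        if chron is not None:
            return chron
    raise SimulationError(
        "no realization with >= 2 surviving lineages within "
        f"{attempts} attempt(s)"
    )


# ----------------------------------------------------------------------
# synthetic rate tables


@dataclass(frozen=True)
class HotspotSpec:
    """Log-normal rate distribution for one synthetic hotspot.

    ``rate_location`` and ``rate_spread`` are the log-scale mean and
    standard deviation; lineage rates are ``exp(Normal(location, spread))``
    so the hotspot's median rate is ``exp(rate_location)``.
    """

    hotspot: str
    n_lineages: int
    rate_location: float
    rate_spread: float

    def __post_init__(self):
        if self.n_lineages < 1:
            raise ValidationError("n_lineages must be >= 1")
        if self.rate_spread < 0:
            raise ValidationError("rate_spread must be >= 0")


def generate_lineage_table(
    specs: Sequence[HotspotSpec], seed: int = 0
) -> pd.DataFrame:
    """Sample a ``lineage_id,hotspot,rate`` table from per-hotspot
    log-normals.  Each hotspot draws from its own counter-derived
    substream, so adding a hotspot does not disturb the others."""
    if not specs:
        raise ValidationError("no hotspot specs supplied")
    rows = []
    for i, spec in enumerate(specs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        rates = np.exp(
            rng.normal(spec.rate_location, spec.rate_spread, size=spec.n_lineages)
        )
        for j, r in enumerate(rates):
            rows.append(
                {
                    "lineage_id": f"{spec.hotspot}_L{j:03d}",
                    "hotspot": spec.hotspot,
                    "rate": float(r),
                }
            )
    return pd.DataFrame(rows)
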