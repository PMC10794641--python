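"""Growth kinetics: per-plant time series, daily growth rates, and
stress-response classification per organ.

Rates are raw forward finite differences (no smoothing); smoothing is
left to downstream users. The "victim" classification captures an organ
that fails to resume growth after a stress window while its siblings on
the same plant do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rootct.segmentation import LabelMatch
from rootct.traits import TraitRecord

__all__ = [
    "OrganObservation",
    "PlantTimeSeries",
    "GrowthRate",
    "StressResponse",
    "build_time_series",
    "growth_per_day",
    "stress_response_summary",
]


@dataclass
class OrganObservation:
    """One organ at one scan day."""

    day: float
    volume_mm3: float
    mean_gray: float = math.nan
    dry_weight_g: float = math.nan


@dataclass
class PlantTimeSeries:
    """Date-ordered per-scan records and per-organ observation chains
    for one plant, with optional stress windows (days after sowing when
    the manifest provides a sowing date, else days after first scan)."""

    plant_id: str
    records: list[tuple[float, TraitRecord]]
    organs: dict[str, list[OrganObservation]]
    stress_windows: list[tuple[float, float, str]] = field(default_factory=list)
    climate: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        days = [d for d, _ in self.records]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("record days must be strictly increasing")


@dataclass
class GrowthRate:
    """Per-interval growth rate: (day_a, day_b, rate units/day).
    ``spanning`` flags intervals that bridge a missing observation."""

    day_a: float
    day_b: float
    rate: float
    spanning: bool = False


@dataclass
class StressResponse:
    """Mean growth rate per phase and the stress-response class:
    'resumed', 'stalled', 'victim', or 'undefined'."""

    organ: str
    rate_pre: float
    rate_during: float
    rate_post: float
    klass: str


def build_time_series(
    records: Sequence[tuple[float, TraitRecord]],
    label_volumes: Sequence[Mapping[int, float]] | None = None,
    label_matches: Sequence[LabelMatch] | None = None,
    stress_windows: Sequence[tuple[float, float, str]] = (),
    plant_id: str | None = None,
) -> PlantTimeSeries:
    """Assemble a plant's time series, chaining organ identity through
    pairwise label matches.

    ``label_volumes[i]`` maps the label ids of scan i to volumes (mm^3);
    ``label_matches[i]`` matches scan i to scan i+1. Organs lost at one
    scan and re-found later keep their chain with the middle missing —
    gaps are carried, never interpolated. Duplicate (plant, day) pairs
    are rejected.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 time points")
    recs = sorted(records, key=lambda r: r[0])
    days = [d for d, _ in recs]
    if len(set(days)) != len(days):
        dup = next(d for i, d in enumerate(days) if d in days[:i])
        raise ValueError(f"duplicate scan day {dup} for plant {plant_id!r}")
    pid = plant_id or (recs[0][1].plant_id or "plant")

    organs: dict[str, list[OrganObservation]] = {}
    if label_volumes is not None:
        if label_matches is None or len(label_matches) != len(label_volumes) - 1:
            raise ValueError("label_matches must have one entry per consecutive scan pair")
        # chain ids: organ identity = first-scan label, propagated forward
        chain_of: dict[tuple[int, int], str] = {}
        next_organ = 1
        for i, volumes in enumerate(label_volumes):
            for lbl in sorted(volumes):
                if (i, lbl) not in chain_of:
                    chain_of[(i, lbl)] = f"organ_{next_organ}"
                    next_organ += 1
                name = chain_of[(i, lbl)]
                organs.setdefault(name, []).append(
                    OrganObservation(day=days[i], volume_mm3=float(volumes[lbl]))
                )
                if i < len(label_matches) and lbl in label_matches[i].mapping:
                    chain_of[(i + 1, label_matches[i].mapping[lbl])] = name
    return PlantTimeSeries(
        plant_id=pid,
        records=list(zip(days, [r for _, r in recs])),
        organs=organs,
        stress_windows=list(stress_windows),
    )


def _observations(series: PlantTimeSeries, organ: str, quantity: str) -> list[tuple[float, float]]:
    attr = {"volume": "volume_mm3", "dry_weight": "dry_weight_g"}[quantity]
    obs = [(o.day, getattr(o, attr)) for o in series.organs[organ]]
    return [(d, v) for d, v in sorted(obs) if math.isfinite(v)]


def growth_per_day(series: PlantTimeSeries, quantity: str = "volume") -> dict[str, list[GrowthRate]]:
    """Forward finite-difference growth rates per organ, units per day.

    A missing middle observation produces one rate over the spanning
    interval, flagged ``spanning``. Organs with a single observation get
    an empty rate list.
    """
    all_days = [d for d, _ in series.records]
    out: dict[str, list[GrowthRate]] = {}
    for organ in sorted(series.organs):
        obs = _observations(series, organ, quantity)
        rates = []
        for (d0, v0), (d1, v1) in zip(obs[:-1], obs[1:]):
            dt = d1 - d0
            if dt <= 0:
                continue
            n_between = sum(1 for d in all_days if d0 < d < d1)
            rates.append(GrowthRate(d0, d1, (v1 - v0) / dt, spanning=n_between > 0))
        out[organ] = rates
    return out


def plant_total_rates(series: PlantTimeSeries, quantity: str = "volume") -> list[GrowthRate]:
    """Plant-level total growth rate: finite differences of the summed
    organ quantity at days where every chained organ is observed, else
    of the per-scan sums of whatever is observed."""
    sums: dict[float, float] = {}
    attr = {"volume": "volume_mm3", "dry_weight": "dry_weight_g"}[quantity]
    for organ, obs in series.organs.items():
        for o in obs:
            v = getattr(o, attr)
            if math.isfinite(v):
                sums[o.day] = sums.get(o.day, 0.0) + v
    days = sorted(sums)
    return [
        GrowthRate(d0, d1, (sums[d1] - sums[d0]) / (d1 - d0))
        for d0, d1 in zip(days[:-1], days[1:])
        if d1 > d0
    ]


def _phase_mean(rates: Sequence[GrowthRate], lo: float, hi: float) -> float:
    vals = [r.rate for r in rates if lo <= 0.5 * (r.day_a + r.day_b) < hi]
    return float(np.mean(vals)) if vals else math.nan


def stress_response_summary(
    series: PlantTimeSeries,
    quantity: str = "volume",
    rho: float = 0.5,
) -> dict[str, StressResponse]:
    """Classify each organ's response to the (first) stress window.

    Mean finite-difference rates are computed per phase (interval
    midpoints before / inside / after the window). Classes:
    'resumed' if rate_post >= rho x rate_pre; 'stalled' if
    0 < rate_post < rho x rate_pre; 'victim' if rate_post <= 0 while the
    plant-level total post-stress rate is positive. Without a stress
    window, rates over the whole series are reported with class
    'undefined'. Raises when the window leaves a phase with no data.
    """
    rates = growth_per_day(series, quantity)
    if not series.stress_windows:
        return {
            organ: StressResponse(
                organ,
                rate_pre=_phase_mean(rs, -math.inf, math.inf),
                rate_during=math.nan,
                rate_post=math.nan,
                klass="undefined",
            )
            for organ, rs in rates.items()
        }
    d0, d1, _kind = series.stress_windows[0]
    days = [d for d, _ in series.records]
    for phase, lo, hi in (("pre-stress", min(days) - 1, d0), ("during-stress", d0, d1), ("post-stress", d1, max(days) + 1)):
        if not any(lo <= d < hi for d in days):
            raise ValueError(f"stress window ({d0}, {d1}) leaves no observation in the {phase} phase")

    total_rates = plant_total_rates(series, quantity)
    total_post = _phase_mean(total_rates, d1, math.inf)

    out: dict[str, StressResponse] = {}
    for organ, rs in rates.items():
        pre = _phase_mean(rs, -math.inf, d0)
        during = _phase_mean(rs, d0, d1)
        post = _phase_mean(rs, d1, math.inf)
        if not math.isfinite(post):
            klass = "undefined"
        elif post <= 0 and math.isfinite(total_post) and total_post > 0:
            klass = "victim"
        elif math.isfinite(pre) and post >= rho * pre:
            klass = "resumed"
        elif post > 0:
            klass = "stalled"
        elif post <= 0:
            klass = "victim" if math.isfinite(total_post) and total_post > 0 else "stalled"
        else:
            klass = "undefined"
        out[organ] = StressResponse(organ, pre, during, post, klass)
    return out
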