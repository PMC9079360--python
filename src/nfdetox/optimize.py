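"""Constrained grid multi-objective optimization of the diafiltration
operating point (j_v, t).

A uniform grid over flux and time is evaluated exhaustively; nodes meeting
the removal constraints (total inhibitor removal above a floor, total
monosaccharide removal below a cap) form the feasible set, from which the
minimum-EC, maximum-Pr and maximum-Y_sugar points are extracted.  Rejections
depend on flux but not on time, so they are computed once per flux column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .process import (
    FeedState,
    OperatingPoint,
    ProcessMetrics,
    evaluate_operating_point,
)
from .properties import ChannelGeometry, SolutionConditions, flux_si
from .rejection import mixture_rejection

__all__ = [
    "OptimizationConfig",
    "FeasibleSet",
    "ExtremePoints",
    "grid_scan",
    "select_extrema",
    "export_surface",
    "read_surface",
]


@dataclass(frozen=True)
class OptimizationConfig:
    """Grid bounds, shape and feasibility constraints.

    The lower bounds exclude zero (metrics are undefined at zero flux or
    time): the default 100x100 grid spans j_v in (0, 2.4] with step 0.024 and
    t in (0, 40] with step 0.4, endpoints inclusive on the upper bounds.
    """

    flux_bounds: tuple[float, float] = (0.024, 2.4)
    time_bounds: tuple[float, float] = (0.4, 40.0)
    grid_shape: tuple[int, int] = (100, 100)
    min_inhibitor_removal: float = 0.90
    max_monosaccharide_removal: float = 0.35

    def __post_init__(self) -> None:
        if self.flux_bounds[1] <= self.flux_bounds[0] or self.flux_bounds[0] <= 0:
            raise ValueError("flux bounds must satisfy 0 < low < high")
        if self.time_bounds[1] <= self.time_bounds[0] or self.time_bounds[0] <= 0:
            raise ValueError("time bounds must satisfy 0 < low < high")
        if min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be positive")

    def flux_grid(self) -> np.ndarray:
        return np.linspace(*self.flux_bounds, self.grid_shape[0])

    def time_grid(self) -> np.ndarray:
        return np.linspace(*self.time_bounds, self.grid_shape[1])


@dataclass(frozen=True)
class FeasibleSet:
    """Every evaluated grid node with its metrics and feasibility flag."""

    points: tuple[OperatingPoint, ...]
    metrics: tuple[ProcessMetrics, ...]
    feasible: np.ndarray
    config: OptimizationConfig

    @property
    def total(self) -> int:
        return len(self.points)

    @property
    def n_feasible(self) -> int:
        return int(np.sum(self.feasible))

    def feasible_items(self) -> list[tuple[OperatingPoint, ProcessMetrics]]:
        return [
            (p, m) for p, m, ok in zip(self.points, self.metrics, self.feasible) if ok
        ]


@dataclass(frozen=True)
class ExtremePoints:
    """The three reported operating points of the feasible set."""

    min_EC: tuple[OperatingPoint, ProcessMetrics]
    max_Pr: tuple[OperatingPoint, ProcessMetrics]
    max_Ysugar: tuple[OperatingPoint, ProcessMetrics]


def grid_scan(
    feed: FeedState,
    config: OptimizationConfig,
    membrane,
    conditions: SolutionConditions | None = None,
    geometry: ChannelGeometry | None = None,
) -> FeasibleSet:
    """Evaluate the metrics at every grid node and flag feasibility.

    The rejection engine runs once per flux column; within a column the
    analytic washout makes the time sweep a cheap vectorized evaluation.
    """
    points: list[OperatingPoint] = []
    metrics: list[ProcessMetrics] = []
    feas: list[bool] = []
    for jv in config.flux_grid():
        mix = mixture_rejection(feed, flux_si(jv), membrane, conditions, geometry)
        rej = mix.observed_rejections()
        for t in config.time_grid():
            point = OperatingPoint(permeate_flux=float(jv), duration=float(t))
            m = evaluate_operating_point(feed, point, membrane, conditions, geometry, rejections=rej)
            points.append(point)
            metrics.append(m)
            feas.append(
                m.total_inhibitor_removal >= config.min_inhibitor_removal
                and m.total_monosaccharide_removal <= config.max_monosaccharide_removal
            )
    return FeasibleSet(
        points=tuple(points),
        metrics=tuple(metrics),
        feasible=np.asarray(feas, dtype=bool),
        config=config,
    )


def _argbest(
    items: Sequence[tuple[OperatingPoint, ProcessMetrics]],
    key,
    maximize: bool,
) -> tuple[OperatingPoint, ProcessMetrics]:
    # ties broken by smaller duration, then smaller flux
    sign = -1.0 if maximize else 1.0
    return min(items, key=lambda pm: (sign * key(pm[1]), pm[0].duration, pm[0].permeate_flux))


def select_extrema(feasible: FeasibleSet) -> ExtremePoints:
    """Min-EC, max-Pr and max-Y_sugar points of the feasible set."""
    items = feasible.feasible_items()
    if not items:
        raise ValueError("feasible set is empty")
    return ExtremePoints(
        min_EC=_argbest(items, lambda m: m.water_consumption, maximize=False),
        max_Pr=_argbest(items, lambda m: m.inhibitor_removal_rate, maximize=True),
        max_Ysugar=_argbest(items, lambda m: m.sugar_recovery, maximize=True),
    )


def export_surface(feasible: FeasibleSet) -> pd.DataFrame:
    """The full evaluated surface as a tidy table (one row per grid node)."""
    return pd.DataFrame(
        {
            "j_v": [p.permeate_flux for p in feasible.points],
            "t": [p.duration for p in feasible.points],
            "EC": [m.water_consumption for m in feasible.metrics],
            "Pr": [m.inhibitor_removal_rate for m in feasible.metrics],
            "Y_sugar": [m.sugar_recovery for m in feasible.metrics],
            "RM_inhibitor": [m.total_inhibitor_removal for m in feasible.metrics],
            "RM_monosaccharides": [m.total_monosaccharide_removal for m in feasible.metrics],
            "feasible": feasible.feasible,
        }
    )


def read_surface(path) -> pd.DataFrame:
    """Re-read an exported surface table."""
    return pd.read_csv(path, float_precision="round_trip")
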