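"""Batch concentration and constant-volume diananofiltration simulation with
the process performance metrics.

With per-solute rejection R_i held constant over a step (quasi-steady
assumption), both operations have exact solutions:

* batch concentration V0 -> V:   C_i(V) = C_i(0) (V0/V)^{R_i}
* constant-volume diafiltration: C_i(t) = C_i(0) exp(-J_v A_m (1-R_i) t / V_f)

Performance metrics for one operating point (j_v, t):

* G_i, per-solute removal = 1 - C_i(t)/C_i(0)
* RM_inhibitor / RM_monosaccharides, class removals weighted by initial mass
  fractions within the class
* EC, diafiltration water consumed per gram of inhibitor removed (L/g)
* Pr_inhibitor, inhibitor mass removed per minute (g/min)
* Y_sugar = 1 - RM_monosaccharides

EC * Pr_inhibitor == j_v * A_m is an algebraic identity of the definitions
and is preserved to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .properties import (
    ChannelGeometry,
    SolutionConditions,
    flux_si,
    solute_catalogue,
)
from .rejection import mixture_rejection

__all__ = [
    "FeedState",
    "OperatingPoint",
    "ProcessMetrics",
    "Trajectory",
    "INHIBITOR_CLASSES",
    "MONOSACCHARIDE_CLASSES",
    "simulate_concentration",
    "simulate_diafiltration",
    "compute_metrics",
    "evaluate_operating_point",
    "average_relative_deviation",
]

#: solute classes counted as fermentation inhibitors in the class metrics;
#: sulfate/sulfuric acid is tracked but belongs to neither class.
INHIBITOR_CLASSES = frozenset({"carboxylic_acid", "phenolic_acid", "furan"})
MONOSACCHARIDE_CLASSES = frozenset({"sugar"})


@dataclass(frozen=True)
class FeedState:
    """Tank contents at one time point: volume (L) and g/L concentrations."""

    volume: float
    concentrations: Mapping[str, float]
    pH: float = 3.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name!r}")

    def mass(self, name: str) -> float:
        """Mass of one solute in the tank (g)."""
        return self.volume * self.concentrations[name]

    def class_mass(self, classes: frozenset[str]) -> float:
        cat = solute_catalogue()
        return sum(
            self.mass(n) for n in self.concentrations if cat[n].solute_class in classes
        )


@dataclass(frozen=True)
class OperatingPoint:
    """Diafiltration decision variables: flux (L m^-2 min^-1) and time (min)."""

    permeate_flux: float
    duration: float

    def __post_init__(self) -> None:
        if self.permeate_flux <= 0:
            raise ValueError("permeate_flux must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class ProcessMetrics:
    """Performance of one diafiltration operating point."""

    removal_per_solute: Mapping[str, float]      # G_i
    total_inhibitor_removal: float               # RM_inhibitor
    total_monosaccharide_removal: float          # RM_monosaccharides
    water_consumption: float                     # EC, L/g
    inhibitor_removal_rate: float                # Pr_inhibitor, g/min
    sugar_recovery: float                        # Y_sugar
    water_volume: float                          # L
    inhibitor_mass_removed: float                # g


@dataclass(frozen=True)
class Trajectory:
    """Sampled tank state over a constant-volume diafiltration run."""

    times: np.ndarray                       # min
    concentrations: Mapping[str, np.ndarray]  # g/L, per solute
    volume: float                           # L (constant)
    rejections: Mapping[str, float]         # the per-solute R used
    initial: FeedState

    def final_feed(self) -> FeedState:
        return FeedState(
            volume=self.volume,
            concentrations={n: float(c[-1]) for n, c in self.concentrations.items()},
            pH=self.initial.pH,
            label=self.initial.label + " (diafiltered)",
        )

    def cumulative_permeate_mass(self, name: str) -> np.ndarray:
        """Permeate mass (g) collected up to each sample time."""
        c0 = self.initial.concentrations[name]
        return self.volume * (c0 - self.concentrations[name])


def _resolve_rejections(
    feed: FeedState,
    flux_lmm: float,
    membrane,
    conditions: SolutionConditions | None,
    geometry: ChannelGeometry | None,
    rejection_mode: str,
    rejections: Mapping[str, float] | None,
) -> dict[str, float]:
    """Observed per-solute rejections driving the bulk mass balance."""
    if rejection_mode == "fixed":
        if rejections is None:
            raise ValueError("rejection_mode='fixed' requires explicit rejections")
        missing = set(feed.concentrations) - set(rejections)
        if missing:
            raise ValueError(f"missing rejections for: {sorted(missing)}")
        return {n: float(rejections[n]) for n in feed.concentrations}
    if rejection_mode != "model":
        raise ValueError("rejection_mode must be 'model' or 'fixed'")
    mix = mixture_rejection(feed, flux_si(flux_lmm), membrane, conditions, geometry)
    return mix.observed_rejections()


def simulate_concentration(
    feed: FeedState,
    final_volume: float,
    flux: float,
    membrane,
    conditions: SolutionConditions | None = None,
    geometry: ChannelGeometry | None = None,
    rejection_mode: str = "model",
    rejections: Mapping[str, float] | None = None,
) -> FeedState:
    """Batch-concentrate a feed from its volume down to ``final_volume`` (L).

    Rejections are evaluated once at the given flux (L m^-2 min^-1) and held
    constant, giving the closed form C_end = C_0 (V_0/V_end)^{R_i}.
    """
    if final_volume <= 0:
        raise ValueError("final_volume must be positive")
    if final_volume >= feed.volume:
        raise ValueError("final_volume must be smaller than the feed volume")
    r = _resolve_rejections(feed, flux, membrane, conditions, geometry, rejection_mode, rejections)
    vcr = feed.volume / final_volume
    conc = {n: c0 * vcr ** r[n] for n, c0 in feed.concentrations.items()}
    return FeedState(volume=final_volume, concentrations=conc, pH=feed.pH, label=feed.label + " (concentrated)")


def simulate_diafiltration(
    feed: FeedState,
    point: OperatingPoint,
    membrane,
    conditions: SolutionConditions | None = None,
    geometry: ChannelGeometry | None = None,
    rejection_mode: str = "model",
    rejections: Mapping[str, float] | None = None,
    n_samples: int = 121,
) -> Trajectory:
    """Constant-volume diafiltration of a feed at one operating point.

    In ``model`` mode the observed rejections are computed once per solute at
    the operating flux on the given feed composition and held constant;
    ``fixed`` mode takes them from ``rejections``.  The analytic washout
    C_i(t) = C_i(0) exp(-J_v A_m (1-R_i) t / V_f) is sampled on a uniform
    time grid.
    """
    r = _resolve_rejections(feed, point.permeate_flux, membrane, conditions, geometry, rejection_mode, rejections)
    times = np.linspace(0.0, point.duration, n_samples)
    rate = point.permeate_flux * membrane.area / feed.volume  # 1/min
    conc = {
        n: c0 * np.exp(-rate * (1.0 - r[n]) * times)
        for n, c0 in feed.concentrations.items()
    }
    return Trajectory(times=times, concentrations=conc, volume=feed.volume, rejections=r, initial=feed)


def compute_metrics(
    trajectory: Trajectory,
    point: OperatingPoint,
    membrane,
) -> ProcessMetrics:
    """Performance metrics of a completed diafiltration trajectory."""
    cat = solute_catalogue()
    feed = trajectory.initial
    removal = {
        n: float(1.0 - trajectory.concentrations[n][-1] / feed.concentrations[n])
        if feed.concentrations[n] > 0
        else 0.0
        for n in feed.concentrations
    }

    def class_stats(classes: frozenset[str]) -> tuple[float, float, float]:
        names = [n for n in feed.concentrations if cat[n].solute_class in classes]
        m0 = {n: feed.mass(n) for n in names}
        total = sum(m0.values())
        if total == 0.0:
            return 0.0, 0.0, 0.0
        rm = sum(m0[n] / total * removal[n] for n in names)
        removed = sum(m0[n] * removal[n] for n in names)
        return rm, removed, total

    rm_inh, removed_inh, total_inh = class_stats(INHIBITOR_CLASSES)
    rm_mono, _, _ = class_stats(MONOSACCHARIDE_CLASSES)
    if total_inh == 0.0:
        raise ValueError("feed contains no inhibitor mass: EC is undefined")

    water = point.permeate_flux * membrane.area * point.duration  # L
    if removed_inh <= 0.0:
        raise ValueError("no inhibitor mass removed: EC is undefined")
    ec = water / removed_inh
    pr = removed_inh / point.duration
    return ProcessMetrics(
        removal_per_solute=removal,
        total_inhibitor_removal=rm_inh,
        total_monosaccharide_removal=rm_mono,
        water_consumption=ec,
        inhibitor_removal_rate=pr,
        sugar_recovery=1.0 - rm_mono,
        water_volume=water,
        inhibitor_mass_removed=removed_inh,
    )


def evaluate_operating_point(
    feed: FeedState,
    point: OperatingPoint,
    membrane,
    conditions: SolutionConditions | None = None,
    geometry: ChannelGeometry | None = None,
    rejections: Mapping[str, float] | None = None,
) -> ProcessMetrics:
    """Diafilter ``feed`` at ``point`` and return the metrics.

    ``rejections`` may carry precomputed observed rejections (e.g. reused
    across operating times at one flux); otherwise they are computed from the
    rejection engine at the operating flux.
    """
    mode = "fixed" if rejections is not None else "model"
    traj = simulate_diafiltration(
        feed, point, membrane, conditions, geometry,
        rejection_mode=mode, rejections=rejections, n_samples=2,
    )
    return compute_metrics(traj, point, membrane)


def average_relative_deviation(
    experimental: Sequence[float], predicted: Sequence[float]
) -> float:
    """ARD% = (100/N) sum |R_exp - R_pred| / |R_exp|."""
    if len(experimental) != len(predicted) or len(experimental) == 0:
        raise ValueError("need equal-length, non-empty vectors")
    exp = np.asarray(experimental, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if np.any(exp == 0):
        raise ValueError("experimental entries must be nonzero")
    return float(100.0 * np.mean(np.abs(exp - pred) / np.abs(exp)))
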