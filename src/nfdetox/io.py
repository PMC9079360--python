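"""Tabular I/O and pipeline configuration.

File dialects:

* ``solutes.csv`` -- the solute catalogue, mirroring the property-table
  layout (diameters in nm, diffusivities in 1e-6 cm^2/s).
* feed CSV -- header ``solute,concentration_g_L`` with metadata rows
  ``volume_L`` and ``pH``.
* ``rejections.csv`` -- ``solute,flux_L_m2_min,observed_rejection``.
* ``membrane.yaml`` / ``conditions:`` YAML blocks for parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import pandas as pd
import yaml

from .membrane import MembraneParams
from .process import FeedState, OperatingPoint, compute_metrics, simulate_concentration, simulate_diafiltration
from .properties import SoluteSpec, SolutionConditions, solute_catalogue

__all__ = [
    "write_solute_table",
    "read_solute_table",
    "read_feed",
    "write_feed",
    "read_membrane",
    "write_membrane",
    "read_conditions",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("nfdetox")

_FEED_META = ("volume_L", "pH")


def _diffusivity_scaled(d: float) -> float:
    """d (m^2/s) in 1e-6 cm^2/s units, chosen so that scaled * 1e-10 == d.

    Scaling by a power of ten can be off by one ulp; nudge the stored value
    until the reader's inverse multiplication reproduces the input bitwise.
    """
    import math

    w = d * 1e10
    if w * 1e-10 == d:
        return w
    for k in range(1, 4):
        for direction in (math.inf, -math.inf):
            w2 = w
            for _ in range(k):
                w2 = math.nextafter(w2, direction)
            if w2 * 1e-10 == d:
                return w2
    raise ValueError(f"cannot represent diffusivity {d!r} in scaled units")


def write_solute_table(solutes: list[SoluteSpec], path) -> None:
    rows = [
        {
            "name": s.name,
            "formula": s.molecular_formula,
            "molar_mass_g_mol": s.molar_mass,
            "stokes_diameter_nm": 2.0 * s.stokes_radius,
            "diffusivity_1e6_cm2_s": _diffusivity_scaled(s.diffusivity),
            "pKa": "" if s.pKa is None else s.pKa,
            "valence": s.ion_valence_when_dissociated,
            "class": s.solute_class,
        }
        for s in solutes
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_solute_table(path) -> list[SoluteSpec]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        pka = row["pKa"]
        out.append(
            SoluteSpec(
                name=row["name"],
                molecular_formula=row["formula"],
                molar_mass=float(row["molar_mass_g_mol"]),
                stokes_radius=float(row["stokes_diameter_nm"]) / 2.0,
                diffusivity=float(row["diffusivity_1e6_cm2_s"]) * 1e-10,  # inverse of _diffusivity_scaled
                pKa=None if pd.isna(pka) or pka == "" else float(pka),
                ion_valence_when_dissociated=int(row["valence"]),
                solute_class=row["class"],
            )
        )
    return out


def write_feed(state: FeedState, path) -> None:
    rows = [{"solute": "volume_L", "concentration_g_L": state.volume},
            {"solute": "pH", "concentration_g_L": state.pH}]
    rows += [{"solute": n, "concentration_g_L": c} for n, c in state.concentrations.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feed(path) -> FeedState:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty feed file")
    missing_cols = {"solute", "concentration_g_L"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    meta: dict[str, float] = {}
    conc: dict[str, float] = {}
    cat = solute_catalogue()
    for i, row in df.iterrows():
        name = str(row["solute"])
        value = float(row["concentration_g_L"])
        if name in _FEED_META:
            meta[name] = value
        elif name in cat:
            if value < 0:
                raise ValueError(f"{path} row {i}: negative concentration for {name!r}")
            conc[name] = value
        else:
            raise ValueError(f"{path} row {i}: unknown solute {name!r}")
    if "volume_L" not in meta:
        raise ValueError(f"{path}: missing volume_L metadata row")
    return FeedState(
        volume=meta["volume_L"], concentrations=conc, pH=meta.get("pH", 3.0), label=path.stem
    )


def write_membrane(membrane: MembraneParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"membrane": dataclasses.asdict(membrane)}, fh, sort_keys=False)


def read_membrane(path) -> MembraneParams:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return MembraneParams(**data["membrane"])


def read_conditions(path) -> SolutionConditions:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    block = data.get("conditions", data)
    kwargs = {}
    if "temperature_C" in block:
        kwargs["temperature"] = 273.15 + float(block["temperature_C"])
    for src, dst in (("pH", "pH"), ("viscosity_Pa_s", "viscosity"), ("density_kg_m3", "density")):
        if src in block:
            kwargs[dst] = float(block[src])
    return SolutionConditions(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one end-to-end pipeline run."""

    feed_path: str
    output_dir: str
    membrane_path: str | None = None
    conditions_path: str | None = None
    concentrate_to: float | None = None      # L; None skips the step
    concentration_flux: float = 1.35         # L m^-2 min^-1
    operating_point: OperatingPoint | None = None
    flux_bounds: tuple[float, float] = (0.024, 2.4)
    time_bounds: tuple[float, float] = (0.4, 40.0)
    grid_shape: tuple[int, int] = (100, 100)
    min_inhibitor_removal: float = 0.90
    max_monosaccharide_removal: float = 0.35
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.flux_bounds[1] <= 0 or self.time_bounds[1] <= 0:
            raise ValueError("upper bounds must be positive")


def _metrics_dict(point: OperatingPoint, m) -> dict:
    return {
        "j_v": point.permeate_flux,
        "t": point.duration,
        "EC": m.water_consumption,
        "Pr_inhibitor": m.inhibitor_removal_rate,
        "Y_sugar": m.sugar_recovery,
        "RM_inhibitor": m.total_inhibitor_removal,
        "RM_monosaccharides": m.total_monosaccharide_removal,
        "water_L": m.water_volume,
        "removal_per_solute": dict(m.removal_per_solute),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute reject -> (concentrate) -> diafilter -> optimize as configured.

    Writes ``surface.csv``, ``extrema.json`` and ``metrics.json`` into the
    output directory along with a log of the resolved parameters; returns a
    summary dict of the produced artifacts.
    """
    from .membrane import canonical_membrane
    from .optimize import OptimizationConfig, export_surface, grid_scan, select_extrema

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        membrane = read_membrane(config.membrane_path) if config.membrane_path else canonical_membrane()
        conditions = read_conditions(config.conditions_path) if config.conditions_path else SolutionConditions()
        stage = "read-feed"
        feed = read_feed(config.feed_path)
        artifacts: dict = {"config": dataclasses.asdict(config) | {
            "operating_point": None if config.operating_point is None else dataclasses.asdict(config.operating_point)
        }}
        if config.concentrate_to is not None:
            stage = "concentrate"
            feed = simulate_concentration(feed, config.concentrate_to, config.concentration_flux, membrane, conditions)
            artifacts["concentrated_feed"] = {"volume_L": feed.volume, "concentrations": dict(feed.concentrations)}
        if config.operating_point is not None:
            stage = "diafilter"
            traj = simulate_diafiltration(feed, config.operating_point, membrane, conditions)
            metrics = compute_metrics(traj, config.operating_point, membrane)
            with open(out / "metrics.json", "w") as fh:
                json.dump(_metrics_dict(config.operating_point, metrics), fh, indent=2)
            artifacts["metrics"] = str(out / "metrics.json")
        stage = "optimize"
        opt = OptimizationConfig(
            flux_bounds=config.flux_bounds,
            time_bounds=config.time_bounds,
            grid_shape=config.grid_shape,
            min_inhibitor_removal=config.min_inhibitor_removal,
            max_monosaccharide_removal=config.max_monosaccharide_removal,
        )
        feasible = grid_scan(feed, opt, membrane, conditions)
        export_surface(feasible).to_csv(out / "surface.csv", index=False)
        extrema = select_extrema(feasible)
        with open(out / "extrema.json", "w") as fh:
            json.dump(
                {
                    "min_EC": _metrics_dict(*extrema.min_EC),
                    "max_Pr": _metrics_dict(*extrema.max_Pr),
                    "max_Ysugar": _metrics_dict(*extrema.max_Ysugar),
                    "n_feasible": feasible.n_feasible,
                    "n_total": feasible.total,
                },
                fh,
                indent=2,
            )
        artifacts["surface"] = str(out / "surface.csv")
        artifacts["extrema"] = str(out / "extrema.json")
        with open(out / "run_log.json", "w") as fh:
            json.dump(artifacts, fh, indent=2, default=str)
        return artifacts
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
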