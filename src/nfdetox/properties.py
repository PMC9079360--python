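"""Physicochemical constants, the solute catalogue, weak-acid speciation and
concentration-polarization corrections.

Units are SI internally (m, s, mol/m^3, Pa·s).  The two deliberate exceptions,
chosen because they match how membrane data are reported, are Stokes radii in
nanometres and permeate fluxes at I/O boundaries in L·m^-2·min^-1 (converted
with :func:`flux_si`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "SoluteSpec",
    "SolutionConditions",
    "ChannelGeometry",
    "builtin_solute_table",
    "solute_catalogue",
    "lookup",
    "dissociation_fraction",
    "speciate",
    "mass_transfer_coefficient",
    "observed_from_real",
    "real_from_observed",
    "stokes_einstein_radius",
    "flux_si",
    "flux_lmm",
]

#: pKa at or above this value is treated as "never dissociates" in the pH
#: range relevant to hydrolysate processing (sugars, furans).
ALWAYS_NEUTRAL_PKA = 12.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants (SI).  Faraday's constant is kept at the slightly
    rounded 96487 C/mol conventional in the membrane-transport literature."""

    faraday_constant: float = 96487.0            # C/mol
    gas_constant: float = 8.314                  # J/(mol K)
    boltzmann_constant: float = 1.380649e-23     # J/K
    vacuum_permittivity: float = 8.85419e-12     # C/(V m) == C^2/(J m)
    elementary_charge: float = 1.602176634e-19   # C

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"physical constant {name!r} must be positive")


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class SoluteSpec:
    """Physicochemical identity of one solute.

    Parameters
    ----------
    stokes_radius : float
        Stokes radius in nm (half the Stokes diameter).
    diffusivity : float
        Bulk diffusion coefficient in m^2/s.
    pKa : float or None
        Acid dissociation constant; ``None`` (or >= 12) means the solute is
        treated as permanently neutral at process pH.
    ion_valence_when_dissociated : int
        Charge of the dissociated form (0 for permanently neutral solutes,
        -1 for carboxylates, -2 for sulfate, +1 for Na+/H+).
    solute_class : str
        One of ``sugar``, ``furan``, ``carboxylic_acid``, ``phenolic_acid``,
        ``inorganic_ion``.
    """

    name: str
    molecular_formula: str
    molar_mass: float            # g/mol
    stokes_radius: float         # nm
    diffusivity: float           # m^2/s
    pKa: Optional[float]
    ion_valence_when_dissociated: int
    solute_class: str

    def __post_init__(self) -> None:
        if self.stokes_radius <= 0:
            raise ValueError(f"{self.name}: stokes_radius must be positive")
        if self.diffusivity <= 0:
            raise ValueError(f"{self.name}: diffusivity must be positive")
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar_mass must be positive")
        if self.solute_class in ("sugar", "furan") and self.is_ionizable:
            raise ValueError(
                f"{self.name}: sugars/furans must not have a finite pKa below "
                f"{ALWAYS_NEUTRAL_PKA}"
            )

    @property
    def is_ionizable(self) -> bool:
        """True when a dissociated (charged) sub-species exists at process pH."""
        return self.pKa is not None and self.pKa < ALWAYS_NEUTRAL_PKA

    @property
    def is_strong_ion(self) -> bool:
        """True for species that are always fully charged (Na+, H+, SO4^2-)."""
        return self.solute_class == "inorganic_ion" and self.ion_valence_when_dissociated != 0


@dataclass(frozen=True)
class SolutionConditions:
    """Bulk solution state: 25 degC water properties by default, pH 3."""

    temperature: float = 298.15   # K
    pH: float = 3.0
    viscosity: float = 8.9e-4     # Pa s
    density: float = 997.0        # kg/m^3

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError("pH must lie in [0, 14]")


@dataclass(frozen=True)
class ChannelGeometry:
    """Feed-channel geometry for the film-model mass-transfer correlation.

    Defaults describe a narrow spacer-filled module channel (1 mm hydraulic
    diameter) at 1 m/s crossflow with a spiral-wound Sherwood correlation
    Sh = 0.065 Re^0.875 Sc^0.25.
    """

    hydraulic_diameter: float = 1.0e-3   # m
    crossflow_velocity: float = 1.0      # m/s
    sherwood_coefficients: tuple[float, float, float] = (0.065, 0.875, 0.25)

    def __post_init__(self) -> None:
        if self.hydraulic_diameter <= 0:
            raise ValueError("hydraulic_diameter must be positive")
        if self.crossflow_velocity < 0:
            raise ValueError("crossflow_velocity must be non-negative")


def flux_si(flux_lmm: float) -> float:
    """Convert a permeate flux from L m^-2 min^-1 to m/s."""
    return flux_lmm * 1.0e-3 / 60.0


def flux_lmm(flux_si: float) -> float:
    """Convert a permeate flux from m/s to L m^-2 min^-1."""
    return flux_si * 60.0e3


def stokes_einstein_radius(
    diffusivity: float,
    conditions: SolutionConditions | None = None,
) -> float:
    """Stokes-Einstein radius (nm) from a bulk diffusivity.

    r = kT / (6 pi mu D).  Used for the small ions whose Stokes diameters the
    catalogue does not list directly.
    """
    cond = conditions or SolutionConditions()
    r_m = CONSTANTS.boltzmann_constant * cond.temperature / (
        6.0 * math.pi * cond.viscosity * diffusivity
    )
    return r_m * 1e9


# --- the built-in solute catalogue ------------------------------------------
# Stokes diameters (nm) and diffusivities (1e-6 cm^2/s) for the nine organic
# solutes of a dilute-acid corncob hydrolysate; diameters are halved to radii
# and diffusivities converted to m^2/s.  Sulfate, sodium and hydrogen carry
# literature diffusivities and Stokes-Einstein radii.

_ORGANICS: list[tuple[str, str, float, float, float, Optional[float], int, str]] = [
    # name, formula, molar mass, Stokes diameter nm, D 1e-6 cm2/s, pKa, z(diss), class
    ("Xylose", "C5H10O5", 150.13, 0.638, 6.76, 12.28, 0, "sugar"),
    ("Glucose", "C6H12O6", 180.16, 0.730, 7.69, 12.15, 0, "sugar"),
    ("Arabinose", "C5H10O5", 150.13, 0.635, 7.73, 12.34, 0, "sugar"),
    ("Furfural", "C5H4O2", 96.08, 0.412, 11.2, None, 0, "furan"),
    ("HMF", "C6H6O3", 126.11, 0.463, 10.6, None, 0, "furan"),
    ("Acetic acid", "C2H4O2", 60.05, 0.412, 11.9, 4.756, -1, "carboxylic_acid"),
    ("Formic acid", "CH2O2", 46.03, 0.323, 15.2, 3.751, -1, "carboxylic_acid"),
    ("Ferulic acid", "C10H10O4", 194.18, 0.580, 8.1, 4.27, -1, "phenolic_acid"),
    ("Vanillic acid", "C8H8O4", 168.15, 0.480, 10.1, 4.08, -1, "phenolic_acid"),
]

#: default diffusivities for the background ions, m^2/s
ION_DIFFUSIVITIES = {"Sulfate": 1.06e-9, "Sodium": 1.33e-9, "Hydrogen": 9.3e-9}
_ION_ROWS = [
    ("Sulfate", "SO4^2-", 96.06, "Sulfate", -2),
    ("Sodium", "Na+", 22.99, "Sodium", 1),
    ("Hydrogen", "H+", 1.008, "Hydrogen", 1),
]


def builtin_solute_table(conditions: SolutionConditions | None = None) -> list[SoluteSpec]:
    """The built-in solute catalogue: nine hydrolysate organics plus the
    sulfate/sodium/hydrogen background ions.

    Ion radii are derived by Stokes-Einstein from their diffusivities at the
    given (default 25 degC) conditions.
    """
    table = [
        SoluteSpec(
            name=name,
            molecular_formula=formula,
            molar_mass=mm,
            stokes_radius=diam / 2.0,
            diffusivity=diff * 1e-10,   # 1e-6 cm^2/s -> m^2/s
            pKa=pka,
            ion_valence_when_dissociated=z,
            solute_class=cls,
        )
        for name, formula, mm, diam, diff, pka, z, cls in _ORGANICS
    ]
    for name, formula, mm, key, z in _ION_ROWS:
        d = ION_DIFFUSIVITIES[key]
        table.append(
            SoluteSpec(
                name=name,
                molecular_formula=formula,
                molar_mass=mm,
                stokes_radius=stokes_einstein_radius(d, conditions),
                diffusivity=d,
                pKa=None,
                ion_valence_when_dissociated=z,
                solute_class="inorganic_ion",
            )
        )
    return table


def solute_catalogue(conditions: SolutionConditions | None = None) -> dict[str, SoluteSpec]:
    """The built-in table keyed by solute name."""
    return {s.name: s for s in builtin_solute_table(conditions)}


def lookup(name: str, conditions: SolutionConditions | None = None) -> SoluteSpec:
    """Fetch one solute from the built-in catalogue by name (case-sensitive)."""
    cat = solute_catalogue(conditions)
    try:
        return cat[name]
    except KeyError:
        known = ", ".join(sorted(cat))
        raise KeyError(f"unknown solute {name!r}; catalogue has: {known}") from None


def dissociation_fraction(pKa: float, pH: float) -> float:
    """Henderson-Hasselbalch dissociated fraction of a monoprotic acid.

    f = 1 / (1 + 10^(pKa - pH)); strictly increasing in pH with f = 1/2 at
    pH = pKa.
    """
    if not math.isfinite(pKa):
        raise ValueError("pKa must be finite")
    return 1.0 / (1.0 + 10.0 ** (pKa - pH))


def speciate(
    solute: SoluteSpec,
    total_concentration: float,
    conditions: SolutionConditions,
) -> tuple[float, float]:
    """Split a total molar concentration into (neutral, anion) sub-species.

    Permanently neutral classes return ``(total, 0)``; strong ions return
    ``(0, total)``.  Mass is conserved exactly.
    """
    if total_concentration < 0:
        raise ValueError("total_concentration must be non-negative")
    if solute.is_strong_ion:
        return 0.0, total_concentration
    if not solute.is_ionizable:
        return total_concentration, 0.0
    f = dissociation_fraction(solute.pKa, conditions.pH)
    anion = f * total_concentration
    return total_concentration - anion, anion


def mass_transfer_coefficient(
    solute: SoluteSpec,
    geometry: ChannelGeometry | None = None,
    conditions: SolutionConditions | None = None,
) -> float:
    """Film-model mass-transfer coefficient K (m/s) from a Sherwood correlation.

    Sh = A Re^a Sc^b with Re = rho u d_c / mu and Sc = mu / (rho D);
    K = Sh D / d_c.
    """
    geom = geometry or ChannelGeometry()
    cond = conditions or SolutionConditions()
    if geom.hydraulic_diameter <= 0:
        raise ValueError("invalid geometry: hydraulic_diameter must be positive")
    pref, a, b = geom.sherwood_coefficients
    re = cond.density * geom.crossflow_velocity * geom.hydraulic_diameter / cond.viscosity
    sc = cond.viscosity / (cond.density * solute.diffusivity)
    sh = pref * re**a * sc**b
    return sh * solute.diffusivity / geom.hydraulic_diameter


def observed_from_real(real_rejection: float, permeate_flux: float, k: float) -> float:
    """Observed rejection from real rejection via the stagnant-film model.

    R_obs/(1-R_obs) = R_real/(1-R_real) * exp(-J_v/K).  R_real = 1 maps to 1
    for any finite flux.  Negative real rejections are legal and map to
    negative observed rejections.
    """
    if k <= 0:
        raise ValueError("mass-transfer coefficient must be positive")
    if real_rejection >= 1.0:
        return 1.0
    odds = real_rejection / (1.0 - real_rejection) * math.exp(-permeate_flux / k)
    return odds / (1.0 + odds)


def real_from_observed(observed_rejection: float, permeate_flux: float, k: float) -> float:
    """Inverse of :func:`observed_from_real`."""
    if k <= 0:
        raise ValueError("mass-transfer coefficient must be positive")
    if observed_rejection >= 1.0:
        return 1.0
    odds = observed_rejection / (1.0 - observed_rejection) * math.exp(permeate_flux / k)
    return odds / (1.0 + odds)
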