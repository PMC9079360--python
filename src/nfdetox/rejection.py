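"""DSPM-DE rejection engine.

Two transport paths share the hindered-transport factors:

* neutral solutes use the closed-form real rejection
  R = 1 - Phi K_c / (1 - (1 - Phi K_c) e^{-Pe}),
* charged species are solved jointly as a steady-state extended
  Nernst-Planck boundary-value problem across the active layer, with
  Donnan + steric + Born (dielectric) partitioning at both faces and pore
  electroneutrality against the fixed charge X_d.

``mixture_rejection`` ties the two together for a realistic feed: weak acids
are speciated at the feed pH, the neutral sub-species and neutral solutes go
through the closed form, all ions (acid anions, Na+, H+, SO4^2-) through the
ENP solver, and per-solute rejections recombine sub-species by mole fraction
before the film-model polarization correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

from . import membrane as membrane_mod
from .properties import (
    CONSTANTS,
    ChannelGeometry,
    PhysicalConstants,
    SoluteSpec,
    SolutionConditions,
    mass_transfer_coefficient,
    observed_from_real,
    solute_catalogue,
    speciate,
)

if TYPE_CHECKING:  # pragma: no cover
    from .membrane import MembraneParams
    from .process import FeedState

__all__ = [
    "HindranceFactors",
    "hindrance_factors",
    "peclet_number",
    "neutral_real_rejection",
    "ChargedSpecies",
    "IonSystem",
    "SolverSettings",
    "RejectionResult",
    "ConvergenceError",
    "solve_charged_system",
    "SoluteRejection",
    "MixtureRejection",
    "mixture_rejection",
]

_EXP_CLIP = 700.0  # largest safe argument for exp()


def _exp(x):
    return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))


@dataclass(frozen=True)
class HindranceFactors:
    """Hydrodynamic hindrance of a finite solute in a cylindrical pore."""

    lambda_ratio: float
    steric_partition: float   # Phi
    convection_factor: float  # K_c
    diffusion_factor: float   # K_d


def hindrance_factors(stokes_radius: float, pore_radius: float) -> HindranceFactors:
    """Steric partition and hindrance polynomials for lambda = r_s/r_p.

    Phi = (1 - lambda)^2
    K_d = 1 - 2.3 lambda + 1.154 lambda^2 + 0.224 lambda^3
    K_c = (2 - Phi)(1 + 0.054 lambda - 0.988 lambda^2 + 0.441 lambda^3)
    """
    if stokes_radius < 0 or pore_radius <= 0:
        raise ValueError("radii must be positive")
    lam = stokes_radius / pore_radius
    if lam > 1.0:
        raise ValueError(
            f"solute radius {stokes_radius} nm exceeds pore radius {pore_radius} nm: "
            "full steric exclusion (rejection is 1 by definition upstream)"
        )
    phi = (1.0 - lam) ** 2
    kd = 1.0 - 2.3 * lam + 1.154 * lam**2 + 0.224 * lam**3
    kc = (2.0 - phi) * (1.0 + 0.054 * lam - 0.988 * lam**2 + 0.441 * lam**3)
    return HindranceFactors(lambda_ratio=lam, steric_partition=phi, convection_factor=kc, diffusion_factor=kd)


def peclet_number(
    factors: HindranceFactors,
    flux: float,
    diffusivity: float,
    thickness_over_porosity: float,
) -> float:
    """Membrane Peclet number Pe = (K_c J_v / (K_d D)) (dX/A_k), SI units."""
    if diffusivity <= 0:
        raise ValueError("diffusivity must be positive")
    if factors.diffusion_factor <= 0:
        raise ValueError("K_d = 0: solute does not transport through the pore")
    return factors.convection_factor * flux * thickness_over_porosity / (factors.diffusion_factor * diffusivity)


def neutral_real_rejection(solute: SoluteSpec, flux: float, membrane: "MembraneParams") -> float:
    """Closed-form real rejection of a neutral solute (flux in m/s).

    Returns 1.0 when the solute is sterically excluded (r_s >= r_p).
    """
    if solute.stokes_radius >= membrane.pore_radius:
        return 1.0
    h = hindrance_factors(solute.stokes_radius, membrane.pore_radius)
    if flux == 0.0:
        return 0.0
    pe = peclet_number(h, flux, solute.diffusivity, membrane.thickness_m)
    phikc = h.steric_partition * h.convection_factor
    return 1.0 - phikc / (1.0 - (1.0 - phikc) * math.exp(-pe))


# --- charged-system BVP ------------------------------------------------------


@dataclass(frozen=True)
class ChargedSpecies:
    """One species of the ENP system (a strong ion or an acid anion)."""

    name: str
    valence: int
    stokes_radius: float        # nm
    diffusivity: float          # m^2/s
    bulk_concentration: float   # mol/m^3

    def __post_init__(self) -> None:
        if self.bulk_concentration < 0:
            raise ValueError(f"{self.name}: bulk concentration must be non-negative")


@dataclass(frozen=True)
class IonSystem:
    """A bulk-electroneutral set of charged species facing the membrane."""

    species: Sequence[ChargedSpecies]
    charge_density: float        # X_d, signed, mol/m^3
    membrane: "MembraneParams"
    permeate_flux: float         # m/s

    def __post_init__(self) -> None:
        if self.permeate_flux <= 0:
            raise ValueError("permeate flux must be positive")
        z = np.array([s.valence for s in self.species], dtype=float)
        c = np.array([s.bulk_concentration for s in self.species], dtype=float)
        scale = float(np.sum(np.abs(z) * c))
        if scale > 0 and abs(float(z @ c)) > 1e-8 * scale:
            raise ValueError(
                f"ion system is not electroneutral: sum z_i C_i = {float(z @ c):.3e} "
                f"(scale {scale:.3e})"
            )


@dataclass(frozen=True)
class SolverSettings:
    """Numerics of the ENP boundary-value solver."""

    n_slices: int = 200
    tolerance: float = 1e-8
    max_iterations: int = 800
    damping: float = 0.7
    continuation_steps: int = 10
    donnan_tolerance: float = 1e-13


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last residual {residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class RejectionResult:
    """Converged ENP solution for one ion system."""

    names: tuple[str, ...]
    real_rejection: np.ndarray
    permeate_concentrations: np.ndarray   # mol/m^3
    peclet: np.ndarray
    donnan_potential_feed: float          # V
    donnan_potential_permeate: float      # V
    positions: np.ndarray                 # normalized x in [0, 1]
    pore_concentrations: np.ndarray       # (n_slices+1, n_species)
    pore_potential: np.ndarray            # V, relative to feed solution
    iterations: int
    residual: float

    def rejection_of(self, name: str) -> float:
        return float(self.real_rejection[self.names.index(name)])


def _donnan_root(z: np.ndarray, a: np.ndarray, target: float, tol: float) -> float:
    """Solve sum_i z_i a_i exp(-z_i u) = target for u (dimensionless potential).

    The left side is strictly decreasing in u wherever any a_i > 0, so the
    root is unique; found by bracket expansion + bisection with Newton
    acceleration.
    """
    active = a > 0
    if not np.any(active & (z != 0)):
        if abs(target) > 0:
            raise ConvergenceError("no charged species available to satisfy electroneutrality", abs(target))
        return 0.0

    def g(u: float) -> float:
        return float(np.sum(z * a * _exp(-z * u))) - target

    lo, hi = -1.0, 1.0
    glo, ghi = g(lo), g(hi)
    # g decreasing: want g(lo) >= 0 >= g(hi)
    it = 0
    while glo < 0.0 and it < 60:
        lo *= 2.0
        glo = g(lo)
        it += 1
    it = 0
    while ghi > 0.0 and it < 60:
        hi *= 2.0
        ghi = g(hi)
        it += 1
    if glo < 0.0 or ghi > 0.0:
        raise ConvergenceError("Donnan potential bracket expansion failed", max(abs(glo), abs(ghi)))
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        gm = g(mid)
        if gm >= 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, abs(mid)):
            break
    return 0.5 * (lo + hi)


def _integrate_pore(
    c_start: np.ndarray,
    cp: np.ndarray,
    alpha: np.ndarray,
    kc: np.ndarray,
    z: np.ndarray,
    n: int,
    backward: bool = False,
    keep_profile: bool = False,
):
    """Classical RK4 integration of the normalized ENP pore ODEs.

    dc/dxi  = alpha (K_c c - C_p) - z c dpsi/dxi
    dpsi/dxi = sum z alpha (K_c c - C_p) / sum z^2 c

    xi in [0, 1]; alpha_i = J_v L / (K_d,i D_i); psi in units of RT/F.
    ``backward`` integrates from the permeate face (xi = 1) to the feed face.
    """
    h = (-1.0 if backward else 1.0) / n
    c = c_start.astype(float).copy()
    psi = 0.0
    prof_c = [c.copy()] if keep_profile else None
    prof_psi = [0.0] if keep_profile else None

    def deriv(ci: np.ndarray):
        gi = alpha * (kc * ci - cp)
        denom = float(np.sum(z * z * ci))
        dpsi = float(np.sum(z * gi)) / denom if denom > 1e-300 else 0.0
        return gi - z * ci * dpsi, dpsi

    for _ in range(n):
        k1, p1 = deriv(c)
        k2, p2 = deriv(c + 0.5 * h * k1)
        k3, p3 = deriv(c + 0.5 * h * k2)
        k4, p4 = deriv(c + h * k3)
        c = c + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        psi += (h / 6.0) * (p1 + 2.0 * p2 + 2.0 * p3 + p4)
        c = np.maximum(c, 0.0)
        if keep_profile:
            prof_c.append(c.copy())
            prof_psi.append(psi)
    if keep_profile:
        return c, psi, np.asarray(prof_c), np.asarray(prof_psi)
    return c, psi, None, None


def _project_electroneutral(cp: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Rescale cations/anions symmetrically so that sum z cp = 0."""
    pos = float(np.sum(np.where(z > 0, z * cp, 0.0)))
    neg = float(-np.sum(np.where(z < 0, z * cp, 0.0)))
    if pos > 0.0 and neg > 0.0:
        s = math.sqrt(neg / pos)
        return np.where(z > 0, cp * s, np.where(z < 0, cp / s, cp))
    if pos > 0.0 or neg > 0.0:
        # charge of one sign only: the electroneutral permeate carries none
        return np.where(z != 0, 0.0, cp)
    return cp


def _solve_fixed_xd(
    z: np.ndarray,
    cb: np.ndarray,
    b: np.ndarray,
    alpha: np.ndarray,
    kc: np.ndarray,
    xd: float,
    cp0: np.ndarray,
    settings: SolverSettings,
):
    """Damped fixed-point iteration on the permeate concentrations.

    Shooting runs from the permeate side: a guess C_p fixes the pore-exit
    state through the exit-face partitioning (the exit Donnan potential
    follows from pore electroneutrality against X_d), backward integration
    recovers the feed-face pore state, and the feed-face partitioning maps it
    to an *implied* external feed.  The update multiplies C_p by
    (C_b/C_implied)^damping, which keeps concentrations positive and handles
    the many-orders-of-magnitude partitioning of strongly excluded ions;
    permeate electroneutrality is restored after every step.
    """
    cp = np.where(cp0 > 0, cp0, np.maximum(cb, np.max(cb) * 1e-8) if cb.size else cp0)
    cp = _project_electroneutral(cp.astype(float), z)
    # species with charge of one sign only cannot reach an electroneutral
    # permeate; seed them at a tiny level so the ratio update can act
    cp = np.where(cp <= 0, np.max(cb) * 1e-12 if cb.size else 0.0, cp)
    resid = math.inf
    u0 = u1 = 0.0
    for it in range(1, settings.max_iterations + 1):
        # exit face: pore electroneutrality sum z cp b e^{-z u1} = -X_d
        u1 = _donnan_root(z, cp * b, -xd, settings.donnan_tolerance)
        c_exit = cp * b * _exp(-z * u1)
        c_feed_pore, _, _, _ = _integrate_pore(
            c_exit, cp, alpha, kc, z, settings.n_slices, backward=True
        )
        # feed face: implied external concentrations, with u0 from external
        # electroneutrality sum z C_implied = 0
        a_feed = c_feed_pore / b
        u0 = _donnan_root(-z, a_feed, 0.0, settings.donnan_tolerance)
        c_implied = a_feed * _exp(z * u0)
        ratio = np.where(
            (c_implied > 0) & (cb > 0),
            cb / np.maximum(c_implied, 1e-300),
            np.where(cb > 0, 1e4, 1.0),
        )
        ratio = np.clip(ratio, 1e-4, 1e4)
        resid = float(np.max(np.abs(np.log(ratio))))
        if resid < settings.tolerance:
            return cp, u0, u1, it, resid
        cp = _project_electroneutral(cp * ratio**settings.damping, z)
    raise ConvergenceError("ENP fixed-point iteration did not converge", resid)


def solve_charged_system(
    system: IonSystem,
    conditions: SolutionConditions | None = None,
    constants: PhysicalConstants = CONSTANTS,
    settings: SolverSettings | None = None,
) -> RejectionResult:
    """Steady-state DSPM-DE solution of a multi-ion system.

    Boundary partitioning at both membrane faces combines the steric factor
    Phi, the Donnan factor exp(-z F dpsi / RT) and the Born factor
    exp(-dW/kT); the pore interior satisfies the ENP flux equations with
    j_i = J_v C_i,p and pore electroneutrality sum(z c) + X_d = 0.  A damped
    fixed-point iteration on the permeate concentrations is used, with
    geometric continuation in X_d when direct iteration stalls.
    """
    cond = conditions or SolutionConditions()
    settings = settings or SolverSettings()
    if len(system.species) < 1:
        raise ValueError("empty ion system")

    memb = system.membrane
    z = np.array([s.valence for s in system.species], dtype=float)
    cb = np.array([s.bulk_concentration for s in system.species], dtype=float)
    d = np.array([s.diffusivity for s in system.species], dtype=float)
    names = tuple(s.name for s in system.species)

    hf = [hindrance_factors(s.stokes_radius, memb.pore_radius) for s in system.species]
    phi = np.array([h.steric_partition for h in hf])
    kc = np.array([h.convection_factor for h in hf])
    kd = np.array([h.diffusion_factor for h in hf])

    eps_p = membrane_mod.pore_dielectric_constant(memb)
    dw = np.array(
        [
            membrane_mod.born_energy(s.valence, s.stokes_radius, eps_p, memb.bulk_dielectric, constants)
            for s in system.species
        ]
    )
    kt = constants.boltzmann_constant * cond.temperature
    b = phi * _exp(-dw / kt)  # flux-independent part of the partition factor

    jv = system.permeate_flux
    length = memb.thickness_m
    alpha = jv * length / (kd * d)
    pe = kc * jv * length / (kd * d)

    xd = system.charge_density
    cp0 = cb.copy()
    try:
        cp, u0, u1, its, resid = _solve_fixed_xd(z, cb, b, alpha, kc, xd, cp0, settings)
    except ConvergenceError:
        # continuation: ramp |X_d| geometrically up to the target
        steps = np.geomspace(max(abs(xd) * 1e-2, 1e-6), abs(xd), settings.continuation_steps) * np.sign(xd)
        cp = cp0
        for xk in steps:
            cp, u0, u1, its, resid = _solve_fixed_xd(z, cb, b, alpha, kc, float(xk), cp, settings)

    # final profile at the converged permeate concentrations
    u0 = _donnan_root(z, cb * b, -xd, settings.donnan_tolerance)
    c0 = cb * b * _exp(-z * u0)
    c_end, psi_end, prof_c, prof_psi = _integrate_pore(c0, cp, alpha, kc, z, settings.n_slices, keep_profile=True)

    rt_over_f = constants.gas_constant * cond.temperature / constants.faraday_constant
    with np.errstate(divide="ignore", invalid="ignore"):
        rej = np.where(cb > 0, 1.0 - cp / np.where(cb > 0, cb, 1.0), 0.0)

    return RejectionResult(
        names=names,
        real_rejection=rej,
        permeate_concentrations=cp,
        peclet=pe,
        donnan_potential_feed=u0 * rt_over_f,
        donnan_potential_permeate=u1 * rt_over_f,
        positions=np.linspace(0.0, 1.0, settings.n_slices + 1),
        pore_concentrations=prof_c,
        pore_potential=(u0 + prof_psi) * rt_over_f,
        iterations=its,
        residual=resid,
    )


# --- full mixture ------------------------------------------------------------


@dataclass(frozen=True)
class SoluteRejection:
    """Per-solute rejection with its sub-species decomposition."""

    name: str
    real_rejection: float
    observed_rejection: float
    neutral_fraction: float
    neutral_real_rejection: float | None
    anion_real_rejection: float | None
    mass_transfer_coefficient: float


@dataclass(frozen=True)
class MixtureRejection:
    """Rejections of every solute of a feed at one permeate flux."""

    flux: float  # m/s
    solutes: Mapping[str, SoluteRejection]
    ion_result: RejectionResult | None

    def real(self, name: str) -> float:
        return self.solutes[name].real_rejection

    def observed(self, name: str) -> float:
        return self.solutes[name].observed_rejection

    def observed_rejections(self) -> dict[str, float]:
        return {k: v.observed_rejection for k, v in self.solutes.items()}


def _grams_per_litre_to_molar(conc_g_l: float, molar_mass: float) -> float:
    """g/L -> mol/m^3."""
    return conc_g_l * 1000.0 / molar_mass


def mixture_rejection(
    feed: "FeedState",
    flux: float,
    membrane: "MembraneParams",
    conditions: SolutionConditions | None = None,
    geometry: ChannelGeometry | None = None,
    constants: PhysicalConstants = CONSTANTS,
    settings: SolverSettings | None = None,
) -> MixtureRejection:
    """Rejection of every solute in a feed at one permeate flux (m/s).

    Weak acids are speciated at the feed pH.  Neutral solutes and neutral
    acid sub-species use the closed-form model; all ionic species are solved
    jointly through the ENP system, with the fixed charge X_d taken from the
    Freundlich isotherm at the feed sulfate molarity and H+ closing the feed
    charge balance.  Per-solute real rejections recombine sub-species by mole
    fraction; observed rejections follow from the film model.
    """
    cond = conditions or SolutionConditions()
    if not feed.concentrations:
        raise ValueError("empty feed")
    cat = solute_catalogue(cond)
    feed_cond = SolutionConditions(
        temperature=cond.temperature, pH=feed.pH, viscosity=cond.viscosity, density=cond.density
    )

    neutral_r: dict[str, float] = {}
    anion_species: list[ChargedSpecies] = []
    anion_parent: dict[str, str] = {}
    fractions: dict[str, float] = {}
    sodium_molar = 0.0
    sulfate_molar = 0.0

    for name, conc in feed.concentrations.items():
        if name not in cat:
            raise KeyError(f"unknown solute {name!r} in feed")
        sol = cat[name]
        molar = _grams_per_litre_to_molar(conc, sol.molar_mass)
        neutral_c, anion_c = speciate(sol, molar, feed_cond)
        frac_anion = anion_c / molar if molar > 0 else 0.0
        fractions[name] = frac_anion
        if sol.name == "Sodium":
            sodium_molar = molar
            continue
        if sol.name == "Sulfate":
            sulfate_molar = molar
            continue
        if neutral_c > 0 or not sol.is_ionizable:
            neutral_r[name] = neutral_real_rejection(sol, flux, membrane)
        if sol.is_ionizable and anion_c > 0:
            anion_name = f"{name} (anion)"
            anion_parent[anion_name] = name
            anion_species.append(
                ChargedSpecies(
                    name=anion_name,
                    valence=sol.ion_valence_when_dissociated,
                    stokes_radius=sol.stokes_radius,
                    diffusivity=sol.diffusivity,
                    bulk_concentration=anion_c,
                )
            )

    ion_result: RejectionResult | None = None
    anion_rej: dict[str, float] = {}
    have_ions = sulfate_molar > 0 or sodium_molar > 0 or anion_species
    if have_ions:
        anion_charge = sum(-s.valence * s.bulk_concentration for s in anion_species)
        hydrogen = 2.0 * sulfate_molar + anion_charge - sodium_molar
        if hydrogen < -1e-9 * max(sodium_molar, 1.0):
            raise ValueError(
                "feed charge balance requires negative [H+]: sodium exceeds "
                "the available anion charge"
            )
        hydrogen = max(hydrogen, 0.0)
        species = list(anion_species)
        sulf, na, h = cat["Sulfate"], cat["Sodium"], cat["Hydrogen"]
        if sulfate_molar > 0:
            species.append(ChargedSpecies("Sulfate", -2, sulf.stokes_radius, sulf.diffusivity, sulfate_molar))
        if sodium_molar > 0:
            species.append(ChargedSpecies("Sodium", 1, na.stokes_radius, na.diffusivity, sodium_molar))
        if hydrogen > 0:
            species.append(ChargedSpecies("Hydrogen", 1, h.stokes_radius, h.diffusivity, hydrogen))
        xd = membrane_mod.charge_density(membrane, sulfate_molar / 1000.0)
        system = IonSystem(species=species, charge_density=xd, membrane=membrane, permeate_flux=flux)
        ion_result = solve_charged_system(system, cond, constants, settings)
        for nm, r in zip(ion_result.names, ion_result.real_rejection):
            anion_rej[nm] = float(r)

    solutes: dict[str, SoluteRejection] = {}
    for name, conc in feed.concentrations.items():
        sol = cat[name]
        k = mass_transfer_coefficient(sol, geometry, cond)
        f_anion = fractions[name]
        if name == "Sulfate":
            r_real = anion_rej.get("Sulfate", 0.0)
            r_n, r_a = None, r_real
        elif name == "Sodium":
            r_real = anion_rej.get("Sodium", 0.0)
            r_n, r_a = None, r_real
        else:
            r_n = neutral_r.get(name)
            r_a = anion_rej.get(f"{name} (anion)")
            if r_a is None:
                r_real = r_n if r_n is not None else 0.0
                f_anion = 0.0
            elif r_n is None:
                r_real = r_a
            else:
                r_real = (1.0 - f_anion) * r_n + f_anion * r_a
        solutes[name] = SoluteRejection(
            name=name,
            real_rejection=r_real,
            observed_rejection=observed_from_real(r_real, flux, k),
            neutral_fraction=1.0 - f_anion,
            neutral_real_rejection=r_n,
            anion_real_rejection=r_a,
            mass_transfer_coefficient=k,
        )
    return MixtureRejection(flux=flux, solutes=solutes, ion_result=ion_result)
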