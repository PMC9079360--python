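"""Independent oracles for the transport solvers, built on scipy's adaptive
integrators and root finders.

These deliberately re-derive the physics from the raw formulas (hindrance
polynomials, dielectric model, Born energy) rather than calling the package's
helpers, so that agreement between the package solver and the oracle checks
the whole computational path, not just the outer iteration.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

FARADAY = 96487.0
GAS = 8.314
KB = 1.380649e-23
EPS0 = 8.85419e-12
ECHARGE = 1.602176634e-19


def _clip_exp(x):
    return np.exp(np.clip(x, -700.0, 700.0))


def donnan_u(z, a, target):
    """Root of sum z a exp(-z u) = target via brentq on an expanded bracket."""
    z = np.asarray(z, float)
    a = np.asarray(a, float)

    def g(u):
        return float(np.sum(z * a * _clip_exp(-z * u))) - target

    lo, hi = -1.0, 1.0
    while g(lo) < 0.0 and lo > -600.0:
        lo *= 2.0
    while g(hi) > 0.0 and hi < 600.0:
        hi *= 2.0
    return brentq(g, lo, hi, xtol=1e-14, maxiter=300)


def solve_enp_dense(system, temperature=298.15, n_slices=2000, damping=0.6,
                    tol=1e-10, max_iter=4000):
    """Dense-grid steady-state solution of the charged-transport BVP.

    Same physics as the package solver, independently coded: hindrance and
    partition factors evaluated from the literal polynomials, pore ODEs
    integrated with scipy's adaptive RK45 at a dense maximum step (1/n_slices
    of the membrane), Donnan potentials via brentq.  Returns a dict of real
    rejections by species name.
    """
    memb = system.membrane
    rp = memb.pore_radius
    z = np.array([s.valence for s in system.species], float)
    cb = np.array([s.bulk_concentration for s in system.species], float)
    rs = np.array([s.stokes_radius for s in system.species], float)
    d = np.array([s.diffusivity for s in system.species], float)

    lam = rs / rp
    phi = (1.0 - lam) ** 2
    kd = 1.0 - 2.3 * lam + 1.154 * lam**2 + 0.224 * lam**3
    kc = (2.0 - phi) * (1.0 + 0.054 * lam - 0.988 * lam**2 + 0.441 * lam**3)

    ratio = memb.oriented_layer_thickness / rp
    eps_p = memb.bulk_dielectric - (memb.bulk_dielectric - memb.oriented_layer_dielectric) * (2.0 * ratio - ratio**2)
    dw = z**2 * ECHARGE**2 / (8.0 * math.pi * EPS0 * rs * 1e-9) * (1.0 / eps_p - 1.0 / memb.bulk_dielectric)
    b = phi * _clip_exp(-dw / (KB * temperature))

    jv = system.permeate_flux
    alpha = jv * memb.thickness_m / (kd * d)
    xd = system.charge_density

    def rhs(_, c):
        g = alpha * (kc * c - cp)
        den = float(np.sum(z * z * c))
        dpsi = float(np.sum(z * g)) / den if den > 0 else 0.0
        return g - z * c * dpsi

    cp = np.maximum(cb * 0.5, np.max(cb) * 1e-12)
    for _ in range(max_iter):
        u1 = donnan_u(z, cp * b, -xd)
        c_exit = cp * b * _clip_exp(-z * u1)
        sol = solve_ivp(rhs, (1.0, 0.0), c_exit, method="RK45",
                        max_step=1.0 / n_slices, rtol=1e-10, atol=1e-300)
        c0 = np.maximum(sol.y[:, -1], 0.0)
        u0 = donnan_u(-z, c0 / b, 0.0)
        c_implied = (c0 / b) * _clip_exp(z * u0)
        ratio_upd = np.where(
            (c_implied > 0) & (cb > 0), cb / np.maximum(c_implied, 1e-300),
            np.where(cb > 0, 1e4, 1.0),
        )
        ratio_upd = np.clip(ratio_upd, 1e-4, 1e4)
        if float(np.max(np.abs(np.log(ratio_upd)))) < tol:
            break
        cp = cp * ratio_upd**damping
        pos = float(np.sum(np.where(z > 0, z * cp, 0.0)))
        neg = float(-np.sum(np.where(z < 0, z * cp, 0.0)))
        if pos > 0 and neg > 0:
            s = math.sqrt(neg / pos)
            cp = np.where(z > 0, cp * s, np.where(z < 0, cp / s, cp))
    names = [s.name for s in system.species]
    return {n: 1.0 - p / c if c > 0 else 0.0 for n, p, c in zip(names, cp, cb)}


def diafiltration_ode(c0_map, rejections, flux_lmm, area, volume, duration, n_eval=121):
    """Adaptive-stepper solution of dC_i/dt = -(j A / V)(1 - R_i) C_i."""
    names = sorted(c0_map)
    c0 = np.array([c0_map[n] for n in names], float)
    r = np.array([rejections[n] for n in names], float)
    rate = flux_lmm * area / volume

    def rhs(_, c):
        return -rate * (1.0 - r) * c

    t_eval = np.linspace(0.0, duration, n_eval)
    sol = solve_ivp(rhs, (0.0, duration), c0, t_eval=t_eval, rtol=1e-12, atol=1e-14)
    return {n: sol.y[i] for i, n in enumerate(names)}, t_eval


def concentration_ode(c0_map, rejections, flux_lmm, area, v0, v_end):
    """Adaptive solution of d(VC)/dt = -jA(1-R)C with dV/dt = -jA."""
    names = sorted(c0_map)
    c0 = np.array([c0_map[n] for n in names], float)
    r = np.array([rejections[n] for n in names], float)
    ja = flux_lmm * area
    t_end = (v0 - v_end) / ja

    def rhs(t, c):
        v = v0 - ja * t
        return ja * r * c / v

    sol = solve_ivp(rhs, (0.0, t_end), c0, rtol=1e-12, atol=1e-14)
    return {n: float(sol.y[i, -1]) for i, n in enumerate(names)}
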