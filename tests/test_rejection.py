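"""Hindrance factors, neutral closed form, and the charged ENP solver."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from enp_oracle import solve_enp_dense
from nfdetox.membrane import charge_density
from nfdetox.process import FeedState
from nfdetox.properties import SolutionConditions, flux_si, lookup
from nfdetox.rejection import (
    ChargedSpecies,
    IonSystem,
    SolverSettings,
    hindrance_factors,
    mixture_rejection,
    neutral_real_rejection,
    peclet_number,
    solve_charged_system,
)


class TestHindranceFactors:
    def test_point_solute(self):
        h = hindrance_factors(0.0, 0.395)
        assert (h.steric_partition, h.diffusion_factor, h.convection_factor) == (1.0, 1.0, 1.0)

    def test_half_lambda_polynomials(self):
        h = hindrance_factors(0.5, 1.0)
        assert h.steric_partition == pytest.approx(0.25)
        assert h.diffusion_factor == pytest.approx(0.1665)
        assert h.convection_factor == pytest.approx(1.4615, abs=2e-4)

    def test_glucose_in_characterized_pore(self):
        h = hindrance_factors(0.365, 0.395)
        assert h.lambda_ratio == pytest.approx(0.924051, abs=1e-6)
        assert h.steric_partition == pytest.approx(0.005768, abs=2e-6)
        assert h.diffusion_factor == pytest.approx(0.036789, abs=2e-6)
        assert h.convection_factor == pytest.approx(1.105269, abs=2e-6)

    def test_oversized_solute_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            hindrance_factors(0.5, 0.395)

    @given(lam=st.floats(0.0, 0.999))
    def test_factor_bounds(self, lam):
        h = hindrance_factors(lam, 1.0)
        assert 0.0 <= h.steric_partition <= 1.0
        assert 0.0 < h.diffusion_factor <= 1.0
        assert np.isfinite(h.convection_factor)


class TestPeclet:
    def test_zero_flux(self):
        h = hindrance_factors(0.365, 0.395)
        assert peclet_number(h, 0.0, 7.69e-10, 1.661e-6) == 0.0

    def test_glucose_value(self):
        h = hindrance_factors(0.365, 0.395)
        assert peclet_number(h, 2.25e-5, 7.69e-10, 1.661e-6) == pytest.approx(1.4601, abs=2e-4)

    def test_linear_in_flux(self):
        h = hindrance_factors(0.365, 0.395)
        pe1 = peclet_number(h, 1e-5, 7.69e-10, 1.661e-6)
        assert peclet_number(h, 3e-5, 7.69e-10, 1.661e-6) == pytest.approx(3 * pe1)


class TestNeutralRejection:
    def test_vanishes_at_zero_flux_limit(self, membrane):
        assert neutral_real_rejection(lookup("Glucose"), 0.0, membrane) == 0.0
        assert 0.0 < neutral_real_rejection(lookup("Glucose"), 1e-12, membrane) < 1e-4

    def test_convective_limit(self, membrane):
        h = hindrance_factors(0.365, membrane.pore_radius)
        r = neutral_real_rejection(lookup("Glucose"), 1.0, membrane)  # huge flux
        assert r == pytest.approx(1.0 - h.steric_partition * h.convection_factor, rel=1e-9)

    def test_glucose_at_reference_flux(self, membrane):
        assert neutral_real_rejection(lookup("Glucose"), flux_si(1.35), membrane) == pytest.approx(
            0.9917, abs=2e-4
        )

    def test_sterically_excluded_solute(self, membrane):
        big = dataclasses.replace(lookup("Glucose"), stokes_radius=0.5, name="big")
        assert neutral_real_rejection(big, flux_si(1.35), membrane) == 1.0

    @given(f=st.floats(0.1, 5.0), df=st.floats(0.01, 3.0))
    def test_strictly_increasing_in_flux(self, membrane, f, df):
        x = lookup("Xylose")
        assert neutral_real_rejection(x, flux_si(f + df), membrane) > neutral_real_rejection(
            x, flux_si(f), membrane
        )

    def test_increasing_in_solute_size(self, membrane):
        jv = flux_si(1.35)
        radii = [0.15, 0.2, 0.25, 0.3, 0.35]
        rejections = [
            neutral_real_rejection(dataclasses.replace(lookup("Glucose"), stokes_radius=r, name="x"), jv, membrane)
            for r in radii
        ]
        assert rejections == sorted(rejections)


def na2so4_system(membrane, molarity, flux=2.25e-5):
    na, so4 = lookup("Sodium"), lookup("Sulfate")
    return IonSystem(
        species=[
            ChargedSpecies("Sodium", 1, na.stokes_radius, na.diffusivity, 2 * molarity * 1000),
            ChargedSpecies("Sulfate", -2, so4.stokes_radius, so4.diffusivity, molarity * 1000),
        ],
        charge_density=charge_density(membrane, molarity),
        membrane=membrane,
        permeate_flux=flux,
    )


class TestChargedSolver:
    def test_non_electroneutral_input_rejected(self, membrane):
        na = lookup("Sodium")
        with pytest.raises(ValueError, match="electroneutral"):
            IonSystem(
                species=[ChargedSpecies("Sodium", 1, na.stokes_radius, na.diffusivity, 100.0)],
                charge_density=-10.0,
                membrane=membrane,
                permeate_flux=2e-5,
            )

    def test_zero_charge_reduction_matches_closed_form(self, membrane):
        # z = 0, X_d = 0, dW = 0: each species must reduce to the neutral model
        glu, xyl = lookup("Glucose"), lookup("Xylose")
        system = IonSystem(
            species=[
                ChargedSpecies("Glucose", 0, glu.stokes_radius, glu.diffusivity, 140.0),
                ChargedSpecies("Xylose", 0, xyl.stokes_radius, xyl.diffusivity, 370.0),
            ],
            charge_density=0.0,
            membrane=membrane,
            permeate_flux=2.25e-5,
        )
        res = solve_charged_system(system)
        for name, sol in (("Glucose", glu), ("Xylose", xyl)):
            assert res.rejection_of(name) == pytest.approx(
                neutral_real_rejection(sol, 2.25e-5, membrane), abs=1e-6
            )

    def test_donnan_exclusion_limit(self, no_de_membrane):
        # enormous fixed charge drives the co-ion rejection to 1 even with
        # the dielectric term off
        system = na2so4_system(no_de_membrane, 0.05)
        weak = solve_charged_system(system)
        strong = solve_charged_system(dataclasses.replace(system, charge_density=-5e4))
        assert strong.rejection_of("Sulfate") > 0.999
        assert strong.rejection_of("Sulfate") > weak.rejection_of("Sulfate")

    @pytest.mark.parametrize("molarity", [0.05, 0.5])
    def test_oracle_equivalence_na2so4(self, membrane, molarity):
        system = na2so4_system(membrane, molarity)
        res = solve_charged_system(system)
        oracle = solve_enp_dense(system)
        for name in ("Sodium", "Sulfate"):
            assert res.rejection_of(name) == pytest.approx(oracle[name], abs=5e-3)

    def test_oracle_equivalence_without_dielectric_exclusion(self, no_de_membrane):
        # moderate-rejection regime: the meaty comparison
        system = na2so4_system(no_de_membrane, 0.05)
        res = solve_charged_system(system)
        oracle = solve_enp_dense(system)
        for name in ("Sodium", "Sulfate"):
            assert res.rejection_of(name) == pytest.approx(oracle[name], abs=5e-3)

    def test_oracle_equivalence_three_ion_mixture(self, no_de_membrane):
        ac = lookup("Acetic acid")
        na, so4 = lookup("Sodium"), lookup("Sulfate")
        system = IonSystem(
            species=[
                ChargedSpecies("Acetate", -1, ac.stokes_radius, ac.diffusivity, 2.0),
                ChargedSpecies("Sodium", 1, na.stokes_radius, na.diffusivity, 102.0),
                ChargedSpecies("Sulfate", -2, so4.stokes_radius, so4.diffusivity, 50.0),
            ],
            charge_density=charge_density(no_de_membrane, 0.05),
            membrane=no_de_membrane,
            permeate_flux=2.25e-5,
        )
        res = solve_charged_system(system)
        oracle = solve_enp_dense(system)
        for name in ("Acetate", "Sodium", "Sulfate"):
            assert res.rejection_of(name) == pytest.approx(oracle[name], abs=5e-3)

    @pytest.mark.parametrize("fixture_name", ["membrane", "no_de_membrane"])
    def test_electroneutrality_at_convergence(self, request, fixture_name):
        memb = request.getfixturevalue(fixture_name)
        system = na2so4_system(memb, 0.05)
        res = solve_charged_system(system)
        z = np.array([1.0, -2.0])
        scale = float(np.sum(np.abs(z) * np.abs(res.permeate_concentrations))) + 1e-300
        # permeate electroneutrality
        assert abs(float(z @ res.permeate_concentrations)) <= 1e-8 * scale + 1e-14
        # pore electroneutrality against X_d at every sampled position
        xd = system.charge_density
        net = res.pore_concentrations @ z + xd
        assert np.max(np.abs(net)) <= 1e-6 * abs(xd)

    def test_enp_flux_balance_internal_consistency(self, no_de_membrane):
        # the transport flux evaluated from the converged profile must equal
        # J_v * C_p for each ion (finite-difference check at interior nodes)
        system = na2so4_system(no_de_membrane, 0.05)
        res = solve_charged_system(system)
        memb = no_de_membrane
        z = np.array([1.0, -2.0])
        kd = np.array(
            [hindrance_factors(s.stokes_radius, memb.pore_radius).diffusion_factor for s in system.species]
        )
        kc = np.array(
            [hindrance_factors(s.stokes_radius, memb.pore_radius).convection_factor for s in system.species]
        )
        d = np.array([s.diffusivity for s in system.species])
        x = res.positions * memb.thickness_m
        c = res.pore_concentrations
        rt_over_f = 8.314 * 298.15 / 96487.0
        psi_grad = np.gradient(res.pore_potential / rt_over_f, x)
        jv = system.permeate_flux
        for i in range(2):
            dc = np.gradient(c[:, i], x)
            j = -kd[i] * d[i] * dc - z[i] * c[:, i] * kd[i] * d[i] * psi_grad + kc[i] * c[:, i] * jv
            expected = jv * res.permeate_concentrations[i]
            interior = slice(10, -10)
            scale = max(abs(expected), jv * system.species[i].bulk_concentration * 1e-3)
            assert np.max(np.abs(j[interior] - expected)) <= 5e-3 * scale + 1e-18

    def test_species_order_invariance(self, no_de_membrane):
        system = na2so4_system(no_de_membrane, 0.1)
        flipped = IonSystem(
            species=tuple(reversed(system.species)),
            charge_density=system.charge_density,
            membrane=system.membrane,
            permeate_flux=system.permeate_flux,
        )
        a = solve_charged_system(system)
        b = solve_charged_system(flipped)
        assert a.rejection_of("Sodium") == b.rejection_of("Sodium")
        assert a.rejection_of("Sulfate") == b.rejection_of("Sulfate")


class TestMixtureRejection:
    def test_pure_sugar_feed_matches_closed_form(self, membrane):
        feed = FeedState(volume=3.0, concentrations={"Glucose": 25.0, "Xylose": 55.0}, pH=3.0)
        mix = mixture_rejection(feed, flux_si(1.35), membrane)
        for name in ("Glucose", "Xylose"):
            assert mix.real(name) == pytest.approx(
                neutral_real_rejection(lookup(name), flux_si(1.35), membrane), rel=1e-12
            )
        assert mix.ion_result is None

    def test_acid_far_below_pka_behaves_neutral(self, membrane):
        # at pH 1 acetic acid is ~0.02% dissociated
        feed = FeedState(volume=3.0, concentrations={"Acetic acid": 3.0}, pH=1.0)
        mix = mixture_rejection(feed, flux_si(1.35), membrane)
        assert mix.real("Acetic acid") == pytest.approx(
            neutral_real_rejection(lookup("Acetic acid"), flux_si(1.35), membrane), abs=2e-4
        )

    def test_empty_feed_rejected(self, membrane):
        feed = FeedState(volume=3.0, concentrations={}, pH=3.0)
        with pytest.raises(ValueError, match="empty"):
            mixture_rejection(feed, flux_si(1.35), membrane)

    def test_observed_below_real_for_retained_solutes(self, membrane, model_feed):
        mix = mixture_rejection(model_feed, flux_si(1.35), membrane)
        for name in ("Glucose", "Xylose", "HMF"):
            s = mix.solutes[name]
            assert s.observed_rejection < s.real_rejection

    def test_acid_rejection_blends_subspecies(self, membrane, model_feed):
        mix = mixture_rejection(model_feed, flux_si(1.35), membrane)
        s = mix.solutes["Formic acid"]
        blended = s.neutral_fraction * s.neutral_real_rejection + (
            1 - s.neutral_fraction
        ) * s.anion_real_rejection
        assert s.real_rejection == pytest.approx(blended, rel=1e-12)
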