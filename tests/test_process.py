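"""Concentration/diafiltration mass balance and the performance metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from enp_oracle import concentration_ode, diafiltration_ode
from nfdetox.process import (
    FeedState,
    OperatingPoint,
    average_relative_deviation,
    compute_metrics,
    evaluate_operating_point,
    simulate_concentration,
    simulate_diafiltration,
)

SUGARS = {"Glucose": 12.5, "Xylose": 27.5, "Arabinose": 4.0}


def fixed_feed(**conc):
    return FeedState(volume=3.0, concentrations=conc or dict(SUGARS, **{"HMF": 1.0}), pH=3.0)


class TestFeedState:
    def test_invalid_states_rejected(self):
        with pytest.raises(ValueError):
            FeedState(volume=0.0, concentrations={"Glucose": 1.0})
        with pytest.raises(ValueError):
            FeedState(volume=1.0, concentrations={"Glucose": -1.0})

    def test_mass_accounting(self):
        feed = fixed_feed(Glucose=10.0)
        assert feed.mass("Glucose") == pytest.approx(30.0)


class TestConcentration:
    def run(self, rejections, v_end=3.0):
        feed = FeedState(volume=6.0, concentrations={n: 10.0 for n in rejections}, pH=3.0)
        return simulate_concentration(
            feed, v_end, 1.35, membrane=None, rejection_mode="fixed", rejections=rejections
        )

    def test_full_retention_doubles_concentration(self):
        out = self.run({"Glucose": 1.0})
        assert out.concentrations["Glucose"] == pytest.approx(20.0, rel=1e-12)

    def test_zero_rejection_keeps_concentration_mass_halves(self):
        out = self.run({"HMF": 0.0})
        assert out.concentrations["HMF"] == pytest.approx(10.0, rel=1e-12)
        assert out.volume * out.concentrations["HMF"] == pytest.approx(30.0)

    def test_partial_rejection_closed_form(self):
        out = self.run({"Xylose": 0.95})
        assert out.concentrations["Xylose"] / 10.0 == pytest.approx(2**0.95, rel=1e-12)

    @given(r=st.floats(-1.0, 1.0))
    def test_matches_adaptive_ode_oracle(self, r):
        out = self.run({"X": r})
        oracle = concentration_ode({"X": 10.0}, {"X": r}, 1.35, 0.32, 6.0, 3.0)
        assert out.concentrations["X"] == pytest.approx(oracle["X"], rel=1e-6)

    def test_invalid_target_volumes_rejected(self):
        feed = FeedState(volume=6.0, concentrations={"Glucose": 10.0})
        for bad in (0.0, -1.0, 6.0, 7.0):
            with pytest.raises(ValueError):
                simulate_concentration(feed, bad, 1.35, None, rejection_mode="fixed",
                                       rejections={"Glucose": 1.0})


class TestDiafiltration:
    def simulate(self, rejections, jv=1.10, t=31.0, membrane=None):
        feed = FeedState(volume=3.0, concentrations={n: 10.0 for n in rejections}, pH=3.0)
        point = OperatingPoint(permeate_flux=jv, duration=t)

        class _M:
            area = 0.32

        return simulate_diafiltration(feed, point, membrane or _M(), rejection_mode="fixed",
                                      rejections=rejections), point

    def test_full_retention_is_stationary(self):
        traj, _ = self.simulate({"Glucose": 1.0})
        assert np.allclose(traj.concentrations["Glucose"], 10.0)

    def test_reference_removal_value(self):
        # R = 0.34 at j_v = 1.10, t = 31, A = 0.32, V = 3: G = 1 - e^-2.4006
        traj, _ = self.simulate({"X": 0.34})
        g = 1.0 - traj.concentrations["X"][-1] / 10.0
        assert g == pytest.approx(0.9093, abs=2e-4)

    def test_negative_rejection_washes_out_faster(self):
        fast, _ = self.simulate({"X": -0.5})
        ref, _ = self.simulate({"X": 0.0})
        ratio = np.log(fast.concentrations["X"][-1] / 10.0) / np.log(ref.concentrations["X"][-1] / 10.0)
        assert ratio == pytest.approx(1.5, rel=1e-12)

    @given(
        r=st.lists(st.floats(-1.0, 1.0), min_size=1, max_size=5),
        jv=st.floats(0.1, 2.4),
        t=st.floats(1.0, 40.0),
    )
    def test_matches_adaptive_ode_oracle(self, r, jv, t):
        rejections = {f"s{i}": ri for i, ri in enumerate(r)}
        traj, _ = self.simulate(rejections, jv=jv, t=t)
        oracle, times = diafiltration_ode({n: 10.0 for n in rejections}, rejections, jv, 0.32, 3.0, t)
        for n in rejections:
            assert np.max(np.abs(traj.concentrations[n] - oracle[n])) <= 1e-8 * 10.0

    @given(r=st.floats(-1.0, 1.0))
    def test_tank_plus_permeate_mass_is_conserved(self, r):
        traj, _ = self.simulate({"X": r})
        total = traj.volume * traj.concentrations["X"] + traj.cumulative_permeate_mass("X")
        assert np.allclose(total, 30.0, rtol=1e-12)

    def test_removal_monotone_in_time_and_rejection(self):
        traj_lo, _ = self.simulate({"X": 0.2})
        traj_hi, _ = self.simulate({"X": 0.8})
        g_lo = 1 - traj_lo.concentrations["X"] / 10.0
        assert np.all(np.diff(g_lo) > 0)  # increasing in t
        assert g_lo[-1] > (1 - traj_hi.concentrations["X"][-1] / 10.0)  # decreasing in R


class TestMetrics:
    class _M:
        area = 0.32

    def metrics_for(self, rejections, conc, jv=0.94, t=34.75):
        feed = FeedState(volume=3.0, concentrations=conc, pH=3.0)
        point = OperatingPoint(permeate_flux=jv, duration=t)
        traj = simulate_diafiltration(feed, point, self._M(), rejection_mode="fixed", rejections=rejections)
        return compute_metrics(traj, point, self._M())

    def test_single_inhibitor_worked_example(self):
        # one inhibitor, 12 g initial, removal 0.9 at (0.94, 34.75)
        # choose R so that G = 0.9 exactly
        g = 0.9
        rate = 0.94 * 0.32 * 34.75 / 3.0
        r = 1.0 + np.log(1.0 - g) / rate
        m = self.metrics_for({"HMF": r}, {"HMF": 4.0})
        assert m.water_volume == pytest.approx(10.45, abs=0.01)
        assert m.inhibitor_mass_removed == pytest.approx(10.8, rel=1e-9)
        assert m.water_consumption == pytest.approx(0.968, abs=1e-3)
        assert m.inhibitor_removal_rate == pytest.approx(0.3108, abs=2e-4)

    def test_full_retention_makes_ec_undefined(self):
        with pytest.raises(ValueError, match="EC"):
            self.metrics_for({"HMF": 1.0, "Glucose": 1.0}, {"HMF": 4.0, "Glucose": 25.0})
        m_ok = self.metrics_for({"HMF": 0.5, "Glucose": 1.0}, {"HMF": 4.0, "Glucose": 25.0})
        assert m_ok.sugar_recovery == pytest.approx(1.0)

    def test_no_inhibitors_in_feed_rejected(self):
        with pytest.raises(ValueError, match="inhibitor"):
            self.metrics_for({"Glucose": 0.5}, {"Glucose": 25.0})

    @given(
        jv=st.floats(0.1, 2.4),
        t=st.floats(1.0, 40.0),
        r1=st.floats(-0.5, 0.99),
        r2=st.floats(-0.5, 0.99),
    )
    def test_ec_times_pr_identity(self, jv, t, r1, r2):
        m = self.metrics_for(
            {"HMF": r1, "Acetic acid": r2, "Glucose": 0.99},
            {"HMF": 2.0, "Acetic acid": 2.0, "Glucose": 25.0},
            jv=jv, t=t,
        )
        assert m.water_consumption * m.inhibitor_removal_rate == pytest.approx(jv * 0.32, rel=1e-12)

    def test_class_weights_are_initial_mass_fractions(self):
        m = self.metrics_for(
            {"HMF": 0.5, "Furfural": 0.2, "Glucose": 0.99},
            {"HMF": 3.0, "Furfural": 1.0, "Glucose": 25.0},
        )
        g = m.removal_per_solute
        expected = 0.75 * g["HMF"] + 0.25 * g["Furfural"]
        assert m.total_inhibitor_removal == pytest.approx(expected, rel=1e-12)


class TestARD:
    def test_identical_vectors(self):
        assert average_relative_deviation([0.5, 0.9], [0.5, 0.9]) == 0.0

    def test_single_and_average_values(self):
        assert average_relative_deviation([0.5], [0.45]) == pytest.approx(10.0)
        assert average_relative_deviation([0.9, 0.8], [0.81, 0.88]) == pytest.approx(10.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            average_relative_deviation([], [])
        with pytest.raises(ValueError):
            average_relative_deviation([0.5, 0.2], [0.5])
        with pytest.raises(ValueError):
            average_relative_deviation([0.0], [0.1])
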