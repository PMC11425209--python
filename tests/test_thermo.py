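"""Work chain, Jarzynski estimator, response slope, force and stiffness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wgmdyn.config import SensorConfig
from wgmdyn.constants import CODATA
from wgmdyn.optics import coupling_fraction, intracavity_photons, kappa_from_linewidth
from wgmdyn.thermo import (
    STIFFNESS_SCALE,
    WorkSample,
    apparent_force,
    energy_budget,
    equivalent_diameter,
    fit_work_vs_intensity,
    jarzynski_estimate,
    mechanical_model,
    trap_stiffness,
    work_per_event,
)


def work_via_photon_chain(A: float, cfg: SensorConfig) -> float:
    """Independent oracle: compose the step-by-step energy bookkeeping.

    amplitude -> frequency shift; linewidth -> loss rate; dip depth ->
    coupling fraction -> intracavity photons; then w = N_A * N_in * h * |dnu|.
    """
    dnu = CODATA.c * A / cfg.lambda0**2
    kappa = kappa_from_linewidth(cfg.dlambda_bar, cfg.lambda0)
    a = coupling_fraction(cfg.S_bar)
    state = intracavity_photons(cfg, kappa, a)
    return CODATA.N_A * state.N_in * CODATA.h * abs(dnu)


class TestWorkPerEvent:
    def test_zero_amplitude(self, sensor):
        assert work_per_event(0.0, sensor) == 0.0

    def test_no_coupling_no_work(self):
        assert work_per_event(3e-15, SensorConfig(S_bar=0.0)) == 0.0

    def test_reference_value(self):
        cfg = SensorConfig(P=1e-3, S_bar=0.36, dlambda_bar=100e-15, lambda0=780e-9)
        assert work_per_event(3e-15, cfg) == pytest.approx(2.99e3, rel=2e-3)
        # and it must agree with the independently composed chain
        assert work_per_event(3e-15, cfg) == pytest.approx(
            work_via_photon_chain(3e-15, cfg), rel=1e-12
        )

    def test_equals_photon_chain_over_random_draws(self, rng):
        for _ in range(1000):
            cfg = SensorConfig(
                lambda0=float(rng.uniform(500e-9, 1500e-9)),
                P=float(rng.uniform(1e-6, 1e-2)),
                S_bar=float(rng.uniform(0.01, 0.99)),
                dlambda_bar=float(rng.uniform(1e-14, 1e-12)),
            )
            A = float(rng.uniform(1e-16, 1e-13))
            assert work_per_event(A, cfg) == pytest.approx(
                work_via_photon_chain(A, cfg), rel=1e-10
            )

    @given(st.floats(1e-16, 1e-13), st.floats(0.1, 4.0))
    @settings(deadline=None, derandomize=True)
    def test_exactly_linear_in_amplitude_and_power(self, A, scale):
        cfg = SensorConfig()
        w = work_per_event(A, cfg)
        assert work_per_event(scale * A, cfg) == pytest.approx(scale * w, rel=1e-12)
        cfg2 = cfg.model_copy(update={"P": scale * cfg.P})
        assert work_per_event(A, cfg2) == pytest.approx(scale * w, rel=1e-12)

    def test_monotone_in_coupling(self):
        ws = [work_per_event(3e-15, SensorConfig(S_bar=s)) for s in (0.1, 0.3, 0.6, 0.9)]
        assert all(a < b for a, b in zip(ws, ws[1:]))

    def test_negative_amplitude_gives_positive_work_by_default(self, sensor):
        assert work_per_event(-3e-15, sensor) == work_per_event(3e-15, sensor)
        assert work_per_event(-3e-15, sensor, signed=True) < 0


class TestJarzynski:
    def test_constant_sample_is_exact(self):
        est = jarzynski_estimate(WorkSample(np.full(40, 750.0)), T=298.15)
        assert est.dG == pytest.approx(750.0, rel=1e-12)
        assert est.sigma_dG == pytest.approx(0.0, abs=1e-9)

    def test_single_value(self):
        est = jarzynski_estimate(WorkSample([1234.5]), T=298.15)
        assert est.dG == pytest.approx(1234.5, rel=1e-12)

    def test_two_point_oracle(self):
        # hand evaluation of RT*ln[(e^{w1/RT}+e^{w2/RT})/2]
        RT = CODATA.R * 298.15
        expected = RT * math.log((math.exp(1000.0 / RT) + math.exp(2000.0 / RT)) / 2.0)
        est = jarzynski_estimate(WorkSample([1000.0, 2000.0]), T=298.15)
        assert est.dG == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.55e3, rel=1e-2)
        assert est.dG > 1500.0  # strictly above the arithmetic mean

    @given(
        st.lists(st.floats(0.0, 5000.0), min_size=2, max_size=50).filter(
            lambda w: max(w) - min(w) > 1e-6
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_jensen_bound(self, w):
        est = jarzynski_estimate(WorkSample(w), T=298.15)
        assert float(np.mean(w)) < est.dG <= max(w) + 1e-9

    def test_permutation_invariance(self, rng):
        w = rng.uniform(100.0, 3000.0, 30)
        a = jarzynski_estimate(WorkSample(w), T=298.15).dG
        b = jarzynski_estimate(WorkSample(rng.permutation(w)), T=298.15).dG
        assert a == pytest.approx(b, rel=1e-14)

    def test_no_overflow_for_large_work(self):
        est = jarzynski_estimate(WorkSample([4e5, 5e5]), T=298.15)  # beta*w ~ 200
        assert np.isfinite(est.dG)
        # dominated by the largest value: dG -> max(w) - RT*ln(2)
        RT = CODATA.R * 298.15
        assert est.dG == pytest.approx(5e5 - RT * math.log(2.0), rel=1e-6)

    def test_as_printed_spread_exceeds_variance_spread(self):
        sample = WorkSample([1000.0, 2000.0, 1500.0])
        default = jarzynski_estimate(sample, T=298.15)
        printed = jarzynski_estimate(sample, T=298.15, as_printed=True)
        assert printed.dG == default.dG
        assert printed.sigma_dG > default.sigma_dG

    def test_rejects_bad_temperature(self):
        with pytest.raises(ValueError):
            jarzynski_estimate(WorkSample([1.0]), T=0.0)


class TestWorkIntensityFit:
    def test_exact_two_point_line(self):
        resp = fit_work_vs_intensity(
            [(100.0, WorkSample([225.0])), (200.0, WorkSample([450.0]))]
        )
        assert resp.slope == pytest.approx(2.25)
        assert resp.intercept == pytest.approx(0.0, abs=1e-9)

    def test_single_intensity_is_an_error(self):
        with pytest.raises(ValueError):
            fit_work_vs_intensity([(100.0, WorkSample([225.0]))])
        with pytest.raises(ValueError):
            fit_work_vs_intensity(
                [(100.0, WorkSample([225.0])), (100.0, WorkSample([230.0]))]
            )

    def test_mixed_degenerate_weights_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_work_vs_intensity(
                [
                    (100.0, WorkSample([225.0])),  # zero SE
                    (200.0, WorkSample(rng.normal(450, 5, 50))),
                ]
            )

    def test_weighted_fit_recovers_generating_slope(self, rng):
        slope_true = 2.25
        data = []
        for I in (50, 100, 200, 400):
            w = rng.normal(slope_true * I, 30.0, 150)
            data.append((float(I), WorkSample(w)))
        resp = fit_work_vs_intensity(data)
        assert resp.slope == pytest.approx(slope_true, rel=0.05)
        assert resp.ci95[0] < slope_true < resp.ci95[1]


class TestMechanics:
    def test_unit_sphere_diameter(self):
        assert equivalent_diameter(math.pi / 6.0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "volume,nm", [(5.28e-26, 4.65), (2.78e-26, 3.76)]
    )
    def test_enzyme_diameters(self, volume, nm):
        assert equivalent_diameter(volume) * 1e9 == pytest.approx(nm, abs=0.005)

    @pytest.mark.parametrize(
        "slope,d_nm,mantissa",
        [(2.25, 4.65, 0.802), (1.75, 3.76, 0.774), (1.67, 3.76, 0.737)],
    )
    def test_trap_stiffness_mantissas(self, slope, d_nm, mantissa):
        ts = trap_stiffness(slope, d_nm * 1e-9)
        assert ts / STIFFNESS_SCALE == pytest.approx(mantissa, rel=5e-3)

    def test_zero_slope(self):
        assert trap_stiffness(0.0, 4e-9) == 0.0

    def test_apparent_force_reference(self):
        F = apparent_force(2.25, 100.0, 4.65e-9)
        assert F == pytest.approx(8.0e-14, rel=0.01)  # ~80 fN

    def test_force_linear_in_intensity(self):
        assert apparent_force(2.25, 200.0, 4.65e-9) == pytest.approx(
            2 * apparent_force(2.25, 100.0, 4.65e-9)
        )
        assert apparent_force(2.25, 0.0, 4.65e-9) == 0.0

    def test_mechanical_model_bundles_consistently(self):
        m = mechanical_model(2.25, 5.28e-26)
        assert m.d_E == pytest.approx(4.65e-9, rel=1e-3)
        assert m.force(100.0) == pytest.approx(apparent_force(2.25, 100.0, m.d_E))
        assert m.stiffness_mantissa == pytest.approx(0.803, abs=0.002)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            equivalent_diameter(0.0)
        with pytest.raises(ValueError):
            trap_stiffness(1.0, 0.0)


class TestEnergyBudget:
    def test_reference_sum(self):
        # literature closing energy ~ -4 kJ/mol against a 2.41 kJ/mol penalty
        b = energy_budget(-4000.0, 2410.0)
        assert b.dG_system == pytest.approx(-1590.0)
        assert b.feasible

    def test_zero_penalty(self):
        b = energy_budget(-4000.0, 0.0)
        assert b.dG_system == b.dG_C
        assert b.feasible

    def test_large_penalty_halts_turnover(self):
        assert not energy_budget(-4000.0, 4500.0).feasible

    def test_penalty_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            energy_budget(-4000.0, -1.0)
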