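"""Titration simulation: proton balance, dilution, curve comparison."""

import numpy as np
import pytest

from cuspec import (Component, TitrationProtocol, build_model, bundled_model,
                    compare_curves, design_protocol, simulate_titration,
                    solve_at_ph)
from cuspec.synth import study_design

from .conftest import make_hl_toy, oracle_titration_ph


@pytest.fixture(scope="module")
def cu_tyr_protocol(cu_tyr):
    mmol, prot = study_design("Cu_Tyr")
    return design_protocol(cu_tyr, mmol, prot)


@pytest.fixture(scope="module")
def cu_tyr_curve(cu_tyr, cu_tyr_protocol):
    return simulate_titration(cu_tyr, cu_tyr_protocol)


class TestProtonBalance:
    def test_strong_acid_equivalence_point_at_half_pkw(self):
        """Titrating strong acid alone: at the equivalence volume the
        solution is pure water, pH = pKw/2."""
        m = build_model([Component("H", role="proton")], [])
        # 0.03 mmol HNO3 in 30 mL (1e-3 M), 0.2 M NaOH: equivalence at 0.15 mL
        protocol = TitrationProtocol({}, acid_mmol=0.03, v0_mL=30.0,
                                     titrant_conc_M=0.20, v_max_mL=0.15,
                                     n_points=3)
        curve = simulate_titration(m, protocol)
        assert curve.pH[-1] == pytest.approx(m.pKw / 2, abs=1e-9)
        assert curve.pH[0] == pytest.approx(3.0, abs=0.01)

    def test_half_neutralization_of_monoprotic_ligand(self):
        """pH at half-neutralization of the HL step checked against a
        brute-force proton-balance oracle; close to pKw the textbook
        pH = log K approximation is biased, the oracle is not."""
        m = make_hl_toy(10.28)
        protocol = TitrationProtocol({"L": 0.03}, acid_mmol=0.0,
                                     initial_protonation={"L": 1},
                                     v_max_mL=0.15, n_points=3)
        v_half = 0.075  # half the 0.15 mL equivalence volume
        curve = simulate_titration(m, protocol, np.array([0.0, v_half]))
        expected = oracle_titration_ph(m, protocol, v_half)
        assert curve.pH[-1] == pytest.approx(expected, abs=1e-8)
        # close to, but measurably below, log K = 10.28: hydroxide release
        # at 1e-3 M shifts the half-neutralization point
        assert 9.7 < curve.pH[-1] < 10.28

    @pytest.mark.parametrize("v", [0.0, 0.4, 0.9, 1.4])
    def test_against_bisection_oracle(self, cu_tyr, cu_tyr_protocol, v):
        curve = simulate_titration(cu_tyr, cu_tyr_protocol,
                                   np.array([max(v, 1e-9)]))
        expected = oracle_titration_ph(cu_tyr, cu_tyr_protocol, max(v, 1e-9))
        assert curve.pH[0] == pytest.approx(expected, abs=1e-7)

    def test_designed_protocol_spans_requested_window(self, cu_tyr_curve):
        assert cu_tyr_curve.pH[0] == pytest.approx(2.5, abs=1e-6)
        assert cu_tyr_curve.pH[-1] == pytest.approx(11.0, abs=1e-6)

    def test_ph_monotone_in_added_base(self, cu_tyr_curve):
        assert np.all(np.diff(cu_tyr_curve.pH) > 0)

    def test_consistency_with_fixed_ph_solver(self, cu_tyr, cu_tyr_protocol,
                                              cu_tyr_curve):
        """Re-solving at the simulated pH reproduces the proton balance."""
        k = len(cu_tyr_curve) // 2
        v, ph = cu_tyr_curve.volumes_mL[k], cu_tyr_curve.pH[k]
        state = solve_at_ph(cu_tyr, cu_tyr_protocol.totals_at(v), ph)
        kw = 10.0 ** (-cu_tyr.pKw)
        h = 10.0 ** (-ph)
        bound = sum(cu_tyr.species_by_name(n).coeff("H") * c
                    for n, c in state.species_conc.items())
        t_h = cu_tyr_protocol.proton_total_at(v)
        assert h - kw / h + bound == pytest.approx(t_h, rel=1e-9)

    def test_mass_conservation_along_curve(self, cu_tyr, cu_tyr_protocol,
                                           cu_tyr_curve):
        for k in (0, len(cu_tyr_curve) // 3, len(cu_tyr_curve) - 1):
            v, ph = cu_tyr_curve.volumes_mL[k], cu_tyr_curve.pH[k]
            totals = cu_tyr_protocol.totals_at(v)
            state = solve_at_ph(cu_tyr, totals, ph)
            for comp, total in totals.items():
                bound = sum(cu_tyr.species_by_name(n).coeff(comp) * c
                            for n, c in state.species_conc.items())
                assert state.free[comp] + bound == pytest.approx(total, rel=1e-10)


class TestCurveComparison:
    def test_curve_equals_itself(self, cu_tyr_curve):
        report = compare_curves(cu_tyr_curve, cu_tyr_curve)
        assert report.max_abs_delta == 0.0
        assert report.first_divergence is None

    def test_complexation_onset_above_ph_3(self, cu_tyr, cu_tyr_protocol):
        """The Cu-containing curve departs from the metal-free tyrosine
        curve only once complexes start to form, above pH ~3.  Both
        titrations start at pH 2.5, so the free-ligand protocol gets its
        own acid content, as separate experiments would."""
        tyr_only = build_model(
            [c for c in cu_tyr.components if c.id != "Cu"],
            [s for s in cu_tyr.species if s.coeff("Cu") == 0],
            cu_tyr.pKw)
        mmol = {k: v for k, v in cu_tyr_protocol.component_mmol.items()
                if k != "Cu"}
        protocol_free = design_protocol(
            tyr_only, mmol, dict(cu_tyr_protocol.initial_protonation))
        with_cu = simulate_titration(cu_tyr, cu_tyr_protocol)
        without_cu = simulate_titration(tyr_only, protocol_free)
        report = compare_curves(with_cu, without_cu, threshold=0.05)
        assert report.first_divergence is not None
        v_div, ph_div = report.first_divergence
        assert ph_div > 3.0
        # below the divergence volume the curves agree within the threshold
        before = np.abs(report.delta_pH[report.volumes_mL < v_div])
        assert np.all(before <= 0.05)

    def test_disjoint_ranges_rejected(self, cu_tyr_curve, cu_tyr_protocol):
        from cuspec import TitrationCurve
        other = TitrationCurve(cu_tyr_curve.volumes_mL + 100.0,
                               cu_tyr_curve.pH, cu_tyr_protocol)
        with pytest.raises(ValueError, match="disjoint"):
            compare_curves(cu_tyr_curve, other)

    def test_replicate_noise_bound(self, cu_tyr, cu_tyr_protocol):
        from cuspec import NoiseModel, generate_curve
        sigma = 0.005
        a = generate_curve(cu_tyr, cu_tyr_protocol, NoiseModel(sigma, 11))
        b = generate_curve(cu_tyr, cu_tyr_protocol, NoiseModel(sigma, 12))
        report = compare_curves(a, b)
        # difference of two replicates is N(0, 2 sigma^2); 5 sigma sqrt(2)
        # bounds the max of 250 such draws with large margin
        assert report.max_abs_delta < 5 * sigma * np.sqrt(2)


class TestProtocolValidation:
    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            TitrationProtocol({}, v0_mL=0.0)
        with pytest.raises(ValueError):
            TitrationProtocol({}, n_points=1)
        with pytest.raises(ValueError):
            TitrationProtocol({"Cu": -1.0})

    def test_curves_require_increasing_volumes(self, cu_tyr_protocol):
        from cuspec import TitrationCurve
        with pytest.raises(ValueError, match="strictly increasing"):
            TitrationCurve(np.array([0.0, 0.2, 0.1]),
                           np.array([3.0, 4.0, 5.0]), cu_tyr_protocol)
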