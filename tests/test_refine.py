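"""Constant refinement: recovery, descent, uncertainty and model selection.

Problem sizes here are scaled below the full experimental design (fewer
curves and points) so the whole suite stays quick; the full-size recovery
study lives in the acceptance tests.
"""

import numpy as np
import pytest

from cuspec import (NoiseModel, RefinementSpec, SpeciesDef, bundled_model,
                    generate_study, refine, select_model, simulate_titration)
from cuspec.synth import study_design
from cuspec.titration import TitrationProtocol, design_protocol

from .conftest import make_hl_toy

BINARY_COMPLEXES = ("CuH2(Tyr)", "CuH(Tyr)", "CuH2(Tyr)2", "CuH(Tyr)2")


@pytest.fixture(scope="module")
def hl_truth():
    """Monoprotic toy with a known constant and its exact titration curve."""
    model = make_hl_toy(6.0)
    protocol = design_protocol(model, {"L": 0.03}, {"L": 1},
                               start_pH=3.0, end_pH=10.5, n_points=60)
    curve = simulate_titration(model, protocol)
    return model, curve


@pytest.fixture(scope="module")
def noisy_study():
    return generate_study("Cu_Tyr", 3, NoiseModel(0.005, 21), n_points=100)


class TestRefine:
    def test_noiseless_toy_recovers_truth(self, hl_truth):
        model, curve = hl_truth
        spec = RefinementSpec(model, ("HL",), (curve,))
        result = refine(spec, {"HL": 6.5})
        assert result.converged
        assert result.log_beta_hat["HL"] == pytest.approx(6.0, abs=1e-4)
        assert result.Sigma_stat < 1e-12

    def test_noiseless_correct_model_gives_zero_sigma_stat(self, noisy_study):
        clean = generate_study("Cu_Tyr", 1, NoiseModel(0.0, 1), n_points=60)
        spec = RefinementSpec(clean.truth, BINARY_COMPLEXES, clean.curves)
        result = refine(spec)  # initialized at truth
        assert result.Sigma_stat < 1e-12
        for name in BINARY_COMPLEXES:
            truth = clean.truth.species_by_name(name).log_beta
            assert result.log_beta_hat[name] == pytest.approx(truth, abs=1e-6)

    def test_recovery_from_perturbed_start(self, noisy_study):
        spec = RefinementSpec(noisy_study.truth, BINARY_COMPLEXES,
                              noisy_study.curves)
        initial = {n: noisy_study.truth.species_by_name(n).log_beta + 0.3
                   for n in BINARY_COMPLEXES}
        result = refine(spec, initial)
        for name in BINARY_COMPLEXES:
            truth = noisy_study.truth.species_by_name(name).log_beta
            assert result.log_beta_hat[name] == pytest.approx(truth, abs=0.05)

    def test_empty_free_parameters_is_noop_evaluation(self, noisy_study):
        spec = RefinementSpec(noisy_study.truth, (), noisy_study.curves)
        result = refine(spec)
        assert result.n_iterations == 0
        assert result.log_beta_hat == {}
        assert result.Sigma_stat > 0  # noise leaves residuals

    def test_sigma_stat_not_above_initial_guess(self, noisy_study):
        spec = RefinementSpec(noisy_study.truth, ("CuH(Tyr)",),
                              noisy_study.curves)
        start = {"CuH(Tyr)": 18.54 + 0.2}
        shifted = noisy_study.truth.replace_log_beta(start)
        sigma_at_start = refine(
            RefinementSpec(shifted, (), noisy_study.curves)).Sigma_stat
        result = refine(spec, start)
        assert result.Sigma_stat <= sigma_at_start

    def test_missing_initial_value_rejected(self, noisy_study):
        spec = RefinementSpec(noisy_study.truth, BINARY_COMPLEXES,
                              noisy_study.curves)
        with pytest.raises(ValueError, match="missing"):
            refine(spec, {"CuH(Tyr)": 18.8})

    def test_sigma_weighting(self, noisy_study):
        spec = RefinementSpec(noisy_study.truth, ("CuH(Tyr)",),
                              noisy_study.curves, weighting="sigma_pH")
        result = refine(spec, {"CuH(Tyr)": 18.7})
        # weighted Sigma ~ chi-square with ~n degrees of freedom
        n = sum(len(c) for c in noisy_study.curves)
        assert 0.5 * n < result.Sigma_stat < 2.0 * n

    def test_reported_sigma_tracks_empirical_scatter(self):
        """Over seeded replicates the asymptotic standard deviation is the
        right order: within a factor 3 of the replicate-to-replicate
        scatter of the estimates."""
        estimates = {n: [] for n in BINARY_COMPLEXES}
        sigmas = {n: [] for n in BINARY_COMPLEXES}
        for rep in range(6):
            study = generate_study("Cu_Tyr", 2, NoiseModel(0.005, 100 + 10 * rep),
                                   n_points=80)
            spec = RefinementSpec(study.truth, BINARY_COMPLEXES, study.curves)
            initial = {n: study.truth.species_by_name(n).log_beta + 0.2
                       for n in BINARY_COMPLEXES}
            res = refine(spec, initial)
            for n in BINARY_COMPLEXES:
                estimates[n].append(res.log_beta_hat[n])
                sigmas[n].append(res.sigma[n])
        for n in BINARY_COMPLEXES:
            err = np.abs(np.array(estimates[n])
                         - bundled_model("Cu_Tyr").species_by_name(n).log_beta)
            assert err.mean() < 0.05
            scatter = np.std(estimates[n], ddof=1)
            assert scatter / 3 < np.mean(sigmas[n]) < scatter * 3


class TestEndToEndRecovery:
    @pytest.mark.parametrize("system", ["Cu_Tyr_Ado", "Cu_Tyr_AMP",
                                        "Cu_Tyr_ADP", "Cu_Tyr_ATP"])
    def test_ternary_constants_recovered(self, system):
        """Ternary log beta values are recovered from synthetic curves with
        the binary and protonation constants held fixed, mirroring how
        mixed-ligand systems are refined on top of known binary chemistry."""
        ligand = system.rsplit("_", 1)[1]
        study = generate_study(system, 2, NoiseModel(0.005, 31), n_points=80)
        free = tuple(s.name for s in study.truth.species
                     if s.coeff("Tyr") > 0 and s.coeff(ligand) > 0)
        spec = RefinementSpec(study.truth, free, study.curves)
        initial = {n: study.truth.species_by_name(n).log_beta + 0.2
                   for n in free}
        result = refine(spec, initial)
        for name in free:
            truth = study.truth.species_by_name(name).log_beta
            assert result.log_beta_hat[name] == pytest.approx(truth, abs=0.1)


class TestSelectModel:
    def test_true_model_beats_truncated_model(self, noisy_study):
        truth = noisy_study.truth
        truncated = truth.drop_species(["CuH2(Tyr)2"])
        candidates = [
            RefinementSpec(truth, BINARY_COMPLEXES, noisy_study.curves),
            RefinementSpec(truncated,
                           tuple(n for n in BINARY_COMPLEXES if n != "CuH2(Tyr)2"),
                           noisy_study.curves),
        ]
        ranked = select_model(candidates)
        assert ranked[0][0].model is truth
        assert ranked[0][1].rejected_species == frozenset()

    def test_spurious_species_flagged(self, noisy_study):
        truth = noisy_study.truth
        bloated = type(truth)(
            truth.components,
            truth.species + (SpeciesDef("CuH4(Tyr)2", {"Cu": 1, "Tyr": 2, "H": 4}, 38.0),),
            truth.pKw, truth.temperature_C, truth.ionic_strength_M, "bloated")
        spec = RefinementSpec(bloated, BINARY_COMPLEXES + ("CuH4(Tyr)2",),
                              noisy_study.curves)
        ranked = select_model([spec], sigma_max=0.1)
        assert "CuH4(Tyr)2" in ranked[0][1].rejected_species

    def test_single_candidate(self, noisy_study):
        spec = RefinementSpec(noisy_study.truth, ("CuH(Tyr)",),
                              noisy_study.curves)
        ranked = select_model([spec])
        assert len(ranked) == 1

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_model([])
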