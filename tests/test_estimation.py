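"""Estimation layer: likelihood self-consistency, empirical Bayes shrinkage,
clean-data parameter recovery, goodness of fit."""

import numpy as np
import pandas as pd
import pytest

from gcdcas_pk.datasets import read_dataset
from gcdcas_pk.estimation import (
    FitSpec,
    empirical_bayes,
    fit_population,
    gof,
    individual_nll,
)
from gcdcas_pk.population import PopulationParameters, ResidualSpec
from gcdcas_pk.synthetic import GenerationSpec, generate_study


def _small_sigma_pop(pop, prop=0.01):
    return PopulationParameters(
        fixed=dict(pop.fixed), iiv=dict(pop.iiv),
        residual={
            "biomarker_plasma": ResidualSpec(prop=prop),
            "biomarker_urine": ResidualSpec(prop=prop),
            "rifampicin_plasma": ResidualSpec(prop=prop, add=1e-3, add_fixed=True),
            "probenecid_plasma": ResidualSpec(prop=prop, add=1e-3, add_fixed=True),
        },
        constants=dict(pop.constants))


@pytest.fixture(scope="module")
def clean_study3(tmp_path_factory, pop):
    """Noise-free, IIV-free study #3 dataset (exact identifiability)."""
    truth = PopulationParameters(fixed=dict(pop.fixed), iiv={},
                                 residual=dict(pop.residual),
                                 constants=dict(pop.constants))
    out = tmp_path_factory.mktemp("clean3")
    paths = generate_study(
        GenerationSpec(design="study3", truth=truth, seed=1, with_residual=False), out)
    return read_dataset(paths["dataset"])


@pytest.fixture(scope="module")
def subject_frame(pop, tmp_path_factory):
    """One subject's biomarker data simulated at a known eta, low noise."""
    truth = _small_sigma_pop(pop, prop=0.02)
    out = tmp_path_factory.mktemp("subject")
    paths = generate_study(
        GenerationSpec(design="study3", truth=truth, seed=3, with_residual=True), out)
    df = read_dataset(paths["dataset"])
    return df[df["ID"] == 1].reset_index(drop=True)


class TestCleanRecovery:
    def test_exact_identifiability_without_noise(self, clean_study3, pop):
        """Noise-free data at typical values: the estimator returns the
        generating (ksyn, CLR, Ki, X) to within the solver discretisation."""
        init = _small_sigma_pop(pop)
        spec = FitSpec(estimate_fixed=("ksyn", "CLR", "Ki_u_OAT3", "X"),
                       estimate_iiv=(), estimate_sigma=(),
                       initials={"ksyn": 1.4, "CLR": 0.2, "Ki_u_OAT3": 4.0, "X": 1.3},
                       fix={f"omega_{k}": 0 for k in ("ksyn", "CLR", "Ki_u_OAT3")},
                       dt=0.05)
        res = fit_population(clean_study3, init, spec)
        assert res.estimates.fixed["ksyn"] == pytest.approx(1.0, rel=0.01)
        assert res.estimates.fixed["CLR"] == pytest.approx(0.31, rel=0.01)
        assert res.estimates.fixed["Ki_u_OAT3"] == pytest.approx(2.7, rel=0.02)
        assert res.estimates.fixed["X"] == pytest.approx(1.7, rel=0.02)
        assert res.strategy.startswith("sequential")

    def test_estimation_invariant_to_record_order(self, clean_study3, pop):
        init = _small_sigma_pop(pop)
        spec = FitSpec(estimate_fixed=("ksyn",), estimate_iiv=(), estimate_sigma=(),
                       fix={f"omega_{k}": 0 for k in ("ksyn", "CLR", "Ki_u_OAT3")},
                       dt=0.05)
        res_a = fit_population(clean_study3, init, spec)
        shuffled = clean_study3.sample(frac=1.0, random_state=0)
        shuffled = shuffled.sort_values(["ID", "OCC", "TIME", "EVID"],
                                        ascending=[True, True, True, False],
                                        kind="stable").reset_index(drop=True)
        res_b = fit_population(shuffled, init, spec)
        assert res_a.estimates.fixed["ksyn"] == pytest.approx(
            res_b.estimates.fixed["ksyn"], rel=1e-6)


class TestIndividualLikelihood:
    def test_zero_eta_minimises_clean_typical_data(self, clean_study3, pop):
        sub = clean_study3[clean_study3["ID"] == 1].reset_index(drop=True)
        small = _small_sigma_pop(pop)
        at_zero = individual_nll(sub, {}, small)
        for eta in ({"ksyn": 0.3}, {"ksyn": -0.3}, {"CLR": 0.4}, {"Ki_u_OAT3": 0.5}):
            assert individual_nll(sub, eta, small) > at_zero

    def test_prior_pulls_objective_quadratically(self, clean_study3, pop):
        sub = clean_study3[clean_study3["ID"] == 1].reset_index(drop=True)
        small = _small_sigma_pop(pop)
        base = individual_nll(sub, {}, small)
        up = individual_nll(sub, {"ksyn": 0.61}, small)
        assert up - base > 0.5   # >= the prior cost of a 1-omega excursion


class TestEmpiricalBayes:
    def test_recovers_generating_eta_at_low_noise(self, subject_frame, pop):
        truth = _small_sigma_pop(pop, prop=0.02)
        # the generator draws subject 1's etas first, in iiv insertion order
        rng = np.random.default_rng(3)
        from gcdcas_pk.population import sample_etas
        etas = sample_etas(truth, rng, 12)
        eta_map = empirical_bayes(subject_frame, truth)
        assert eta_map["ksyn"] == pytest.approx(float(etas["ksyn"][0]), abs=0.05)
        assert eta_map["CLR"] == pytest.approx(float(etas["CLR"][0]), abs=0.08)

    def test_empty_subject_returns_prior_mode(self, study3_dataset, pop):
        df = read_dataset(study3_dataset["dataset"])
        sub = df[(df["ID"] == 1) & (df["EVID"] == 1)].reset_index(drop=True)
        assert empirical_bayes(sub, pop) == {}

    def test_shrinkage_toward_zero_with_tight_prior(self, subject_frame, pop):
        loose = _small_sigma_pop(pop, prop=0.02)
        tight = PopulationParameters(
            fixed=dict(loose.fixed),
            iiv={k: 0.01 for k in loose.iiv},
            residual=dict(loose.residual), constants=dict(loose.constants))
        eta_loose = empirical_bayes(subject_frame, loose)
        eta_tight = empirical_bayes(subject_frame, tight)
        assert abs(eta_tight["ksyn"]) < abs(eta_loose["ksyn"])


class TestGOF:
    def test_perfect_data_gives_zero_residuals(self, clean_study3, pop):
        init = _small_sigma_pop(pop)
        spec = FitSpec(estimate_fixed=("ksyn",), estimate_iiv=(), estimate_sigma=(),
                       fix={f"omega_{k}": 0 for k in ("ksyn", "CLR", "Ki_u_OAT3")},
                       dt=0.05)
        res = fit_population(clean_study3, init, spec)
        table = gof(clean_study3, res, dt=0.05)
        assert len(table) == (clean_study3["EVID"] == 0).sum()
        assert np.nanmax(np.abs(table["WRES"])) < 0.2

    def test_weighted_residuals_calibrated_on_noisy_data(self, pop, tmp_path):
        paths = generate_study(GenerationSpec(design="study3", seed=19), tmp_path)
        df = read_dataset(paths["dataset"])
        res = fit_population(df, pop, FitSpec(maxiter=30))
        table = gof(df, res)
        w = table["IWRES"].to_numpy()
        assert np.abs(np.mean(w)) < 0.3
        assert 0.5 < np.std(w) < 1.6
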