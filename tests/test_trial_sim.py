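"""Trial simulation: designs, record bookkeeping, NCA, VPC bands."""

import numpy as np
import pandas as pd
import pytest

from gcdcas_pk.population import PopulationParameters
from gcdcas_pk.trial_sim import builtin_designs, nca, simulate_trial, vpc

BASELINE = 1.0 / 15.31


def _deterministic(pop):
    return PopulationParameters(fixed=dict(pop.fixed), iiv={},
                                residual=dict(pop.residual),
                                constants=dict(pop.constants))


class TestBuiltinDesigns:
    def test_development_study_layout(self, designs):
        s1, s2, s3 = designs["study1"], designs["study2"], designs["study3"]
        assert s1.n_subjects == 6 and len(s1.occasions) == 2
        assert s2.n_subjects == 6 and s2.duration - 13.0 == 168.0
        assert s3.n_subjects == 12
        # probenecid regimen: 2 doses on day 0, then 4 per day
        doses = s2.occasion("probenecid").doses
        times = [d.time for d in doses]
        assert times[:2] == [0.0, 5.0]
        day1 = [t for t in times if 13.0 <= t < 37.0]
        assert len(day1) == 4
        assert all(d.amount == 500.0 for d in doses)

    def test_published_sample_counts(self, designs):
        # per-occasion biomarker plasma record counts match the study tables
        s = designs["study1"]
        assert s.n_subjects * len(s.occasion("control").biomarker_times) == 48
        s3 = designs["study3"]
        assert s3.n_subjects * len(s3.occasion("control").biomarker_times) == 108
        assert s3.n_subjects * len(s3.occasion("control").urine_intervals) == 36

    def test_verification_designs_present(self, designs):
        assert designs["rif300"].occasion("rifampicin").doses[0].amount == 300.0
        assert designs["rif600"].occasion("rifampicin").doses[0].amount == 600.0


class TestSimulateTrial:
    def test_noise_free_control_at_baseline(self, pop, designs, rng):
        det = _deterministic(pop)
        df = simulate_trial(designs["study1"], det, rng, with_residual=False)
        control = df[(df["OCC"] == 1) & (df["OBS"] == "biomarker_plasma")]
        np.testing.assert_allclose(control["DV"], BASELINE, rtol=1e-8)

    def test_record_counts(self, pop, designs, rng):
        df = simulate_trial(designs["study1"], pop, rng)
        assert (df["OBS"] == "biomarker_plasma").sum() == 2 * 48
        assert (df["OBS"] == "rifampicin_plasma").sum() == 6 * 8

    def test_deterministic_when_noise_off(self, pop, designs):
        det = _deterministic(pop)
        a = simulate_trial(designs["study3"], det,
                           np.random.default_rng(0), with_residual=False)
        b = simulate_trial(designs["study3"], det,
                           np.random.default_rng(99), with_residual=False)
        pd.testing.assert_frame_equal(a, b)

    def test_urine_intervals_telescope(self, pop, designs):
        det = _deterministic(pop)
        df = simulate_trial(designs["study3"], det,
                            np.random.default_rng(0), with_residual=False)
        ur = df[(df["ID"] == 1) & (df["OCC"] == 2) & (df["OBS"] == "biomarker_urine")]
        # consecutive interval amounts sum to the total over the full span
        from gcdcas_pk.population import sample_etas
        from gcdcas_pk.trial_sim import simulate_occasion, _individual_arrays
        occ = designs["study3"].occasion("probenecid")
        vals = _individual_arrays(det, {}, 1)
        sim = simulate_occasion(occ, det, vals)
        grid = sim["grid"]
        total = np.interp(occ.urine_intervals[-1][1], grid, sim["urine_cum"][0]) - \
            np.interp(occ.urine_intervals[0][0], grid, sim["urine_cum"][0])
        assert ur["DV"].sum() == pytest.approx(total, rel=1e-9)

    def test_biomarker_rises_then_relaxes_after_rifampicin(self, pop, designs):
        det = _deterministic(pop)
        df = simulate_trial(designs["rif600"], det,
                            np.random.default_rng(0), with_residual=False, n_subjects=1)
        tr = df[(df["OCC"] == 2) & (df["OBS"] == "biomarker_plasma")].sort_values("TIME")
        dv = tr["DV"].to_numpy()
        assert dv.max() > 5 * BASELINE          # clear rise after dosing
        assert dv[-1] < dv.max()                # heading back toward baseline


class TestNCA:
    def _records(self, conc, times, urine=None):
        rows = [{"ID": 1, "OCC": 1, "TIME": t, "OBS": "biomarker_plasma",
                 "DV": c, "USTART": np.nan} for t, c in zip(times, conc)]
        if urine:
            for (a, b), amt in urine:
                rows.append({"ID": 1, "OCC": 1, "TIME": b, "OBS": "biomarker_urine",
                             "DV": amt, "USTART": a})
        return pd.DataFrame(rows)

    def test_constant_concentration_auc(self):
        rec = self._records([0.0653] * 5, [0, 6, 12, 18, 24])
        m = nca(rec, (0, 24))
        assert m.auc == pytest.approx(0.0653 * 24, rel=1e-12)
        assert m.ae is None and not m.clr_defined

    def test_observed_renal_clearance(self):
        rec = self._records([0.0653] * 5, [0, 6, 12, 18, 24],
                            urine=[((0, 12), 0.243), ((12, 24), 0.243)])
        m = nca(rec, (0, 24))
        assert m.clr_obs == pytest.approx(0.486 / (0.0653 * 24), rel=1e-9)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="two plasma points"):
            nca(self._records([0.06], [12.0]), (0, 24))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            nca(self._records([0.06, 0.07], [0.0, 24.0]), (24, 24))


class TestVPC:
    def test_degenerate_bands_coincide_with_typical(self, pop, designs):
        det = _deterministic(pop)
        det = PopulationParameters(
            fixed=dict(det.fixed), iiv={},
            residual={k: type(v)(prop=1e-9, add=0.0) for k, v in det.residual.items()},
            constants=dict(det.constants))
        bands = vpc(designs["study1"], det, 100, np.random.default_rng(0))
        ctrl = bands[(bands["OCC"] == 1) & (bands["OBS"] == "biomarker_plasma")]
        np.testing.assert_allclose(ctrl["p5"], ctrl["p50"], rtol=1e-6)
        np.testing.assert_allclose(ctrl["p50"], BASELINE, rtol=1e-6)

    def test_bands_widen_with_residual_sd(self, pop, designs):
        from gcdcas_pk.population import ResidualSpec
        wide = PopulationParameters(
            fixed=dict(pop.fixed), iiv=dict(pop.iiv),
            residual={**pop.residual, "biomarker_plasma": ResidualSpec(prop=0.90)},
            constants=dict(pop.constants))
        narrow_b = vpc(designs["study1"], pop, 400, np.random.default_rng(1))
        wide_b = vpc(designs["study1"], wide, 400, np.random.default_rng(1))
        sel = (narrow_b["OBS"] == "biomarker_plasma")
        spread_n = (narrow_b[sel]["p95"] - narrow_b[sel]["p5"]).to_numpy()
        spread_w = (wide_b[sel]["p95"] - wide_b[sel]["p5"]).to_numpy()
        assert np.all(spread_w > spread_n)

    def test_minimum_simulation_size_enforced(self, pop, designs, rng):
        with pytest.raises(ValueError):
            vpc(designs["study1"], pop, 50, rng)
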