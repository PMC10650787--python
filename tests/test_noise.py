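"""Noise injection: calibration, determinism, and the recovery-study machinery."""

import numpy as np
import pandas as pd
import pytest

from petkin import (
    FitOptions,
    NoiseModel,
    add_noise,
    fit_compartment_model,
    iqr_coverage,
    run_recovery_study,
    simulate_tissue_tac,
)
from petkin.noise import SimulationStudy

from conftest import params_from_table


class TestNoiseModel:
    def test_zero_level_is_identity(self, wt_thalamus_2fa_tac):
        out = add_noise(wt_thalamus_2fa_tac, NoiseModel(level=0.0), 1)
        assert np.array_equal(out.values, wt_thalamus_2fa_tac.values)

    def test_seed_determinism(self, wt_thalamus_2fa_tac):
        nm = NoiseModel(level=0.2)
        a = add_noise(wt_thalamus_2fa_tac, nm, 42)
        b = add_noise(wt_thalamus_2fa_tac, nm, 42)
        c = add_noise(wt_thalamus_2fa_tac, nm, 43)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_sigma_scaling_with_duration_and_amplitude(self, wt_thalamus_2fa_tac):
        nm = NoiseModel(level=0.2)
        sigma = nm.sigma(wt_thalamus_2fa_tac)
        c = wt_thalamus_2fa_tac.values
        dt = wt_thalamus_2fa_tac.schedule.durations
        # default reading: sigma = level * C_i * (1 min / dt_i)
        assert np.allclose(sigma, 0.2 * c / dt, rtol=1e-12)

    def test_count_statistics_exponents(self, wt_thalamus_2fa_tac):
        nm = NoiseModel(level=0.2, amplitude_exponent=0.5, duration_exponent=0.5)
        sigma = nm.sigma(wt_thalamus_2fa_tac)
        c = wt_thalamus_2fa_tac.values
        cmax = c.max()
        dt = wt_thalamus_2fa_tac.schedule.durations
        assert np.allclose(sigma, 0.2 * cmax * np.sqrt(c / cmax) / np.sqrt(dt),
                           rtol=1e-12)

    def test_monte_carlo_calibration_and_unbiasedness(self, wt_thalamus_2fa_tac):
        nm = NoiseModel(level=0.2)
        sigma = nm.sigma(wt_thalamus_2fa_tac)
        rng = np.random.default_rng(0)
        n_rep = 10_000
        draws = np.stack([
            add_noise(wt_thalamus_2fa_tac, nm, rng).values for _ in range(n_rep)
        ])
        emp_sd = draws.std(axis=0, ddof=1)
        assert np.all(np.abs(emp_sd - sigma) / sigma < 0.03)
        emp_mean = draws.mean(axis=0)
        # unbiased: no clipping, mean converges to the noise-free values
        assert np.all(
            np.abs(emp_mean - wt_thalamus_2fa_tac.values) < 4 * sigma / np.sqrt(n_rep)
        )


def _fake_study(truth, estimates_by_param):
    rows = []
    n = len(next(iter(estimates_by_param.values())))
    for i in range(n):
        row = {"iteration": i, "region": "thalamus", "converged": True, "wss": 1.0}
        for p in ("K1", "k2", "k3", "k4", "vp", "bp_nd"):
            row[p] = estimates_by_param[p][i]
        rows.append(row)
    return SimulationStudy(
        truth={"thalamus": truth}, n_iter=n, seed=0, noise=NoiseModel(),
        estimates=pd.DataFrame(rows),
    )


class TestIqrCoverage:
    def test_truth_outside_and_at_median(self, wt_thalamus_2fa_params):
        import petkin.models as m

        truth = wt_thalamus_2fa_params
        base = {p: np.linspace(1.0, 2.0, 11) for p in ("K1", "k2", "k3", "k4", "vp")}
        base["bp_nd"] = base["k3"] / base["k4"]
        study = _fake_study(truth, base)
        cov = iqr_coverage(study)
        # truth (~0.1 scale) lies below every estimate in [1, 2]
        assert not cov[cov.parameter == "K1"]["covered"].item()

        centred = {
            p: np.linspace(0.9, 1.1, 11) * study.truth_value("thalamus", p)
            for p in ("K1", "k2", "k3", "k4", "vp", "bp_nd")
        }
        cov2 = iqr_coverage(_fake_study(truth, centred))
        assert cov2["covered"].all()


class TestRecoveryStudy:
    def test_zero_noise_collapses_to_truth(self, blood_2fa, sched_2fa):
        truth = params_from_table("2-FA", "WT", "thalamus")
        tac = simulate_tissue_tac(truth, blood_2fa, sched_2fa, region="thalamus")
        opts = FitOptions(seed=0, n_starts=4)
        fitted = fit_compartment_model(tac, blood_2fa, opts).params
        study = run_recovery_study(
            blood_2fa, {"thalamus": tac}, {"thalamus": fitted},
            NoiseModel(level=0.0), n_iter=3, fit_options=opts, seed=0,
        )
        est = study.estimates
        for p in ("K1", "k2", "k3", "k4"):
            assert np.allclose(est[p], getattr(fitted, p), rtol=0.01)
        cov = iqr_coverage(study)
        assert cov["covered"].all()
        # IQR width collapses
        pct = study.percentiles()
        k1 = pct[(pct.parameter == "K1")]
        assert (k1["p75"].item() - k1["p25"].item()) / k1["p50"].item() < 1e-4

    def test_bit_reproducibility_and_estimate_bookkeeping(self, blood_2fa, sched_2fa):
        truth = params_from_table("2-FA", "WT", "thalamus")
        tac = simulate_tissue_tac(truth, blood_2fa, sched_2fa, region="thalamus")
        opts = FitOptions(seed=0, n_starts=3)
        kwargs = dict(
            blood=blood_2fa, region_tacs={"thalamus": tac},
            truth_params={"thalamus": truth}, noise=NoiseModel(level=0.2),
            n_iter=4, fit_options=opts, seed=7,
        )
        s1 = run_recovery_study(**kwargs)
        s2 = run_recovery_study(**kwargs)
        pd.testing.assert_frame_equal(s1.estimates, s2.estimates)
        assert len(s1.estimates) == 4
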