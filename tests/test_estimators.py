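import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from drmmrm import (
    Design,
    Scenario,
    TruthParams,
    fit_dreos,
    fit_drmmrm,
    fit_drmmrm_single,
    fit_mmrm,
    fits_to_frame,
    simulate_trial,
    true_effect,
)
from drmmrm.estimators import ED50_BOUNDS, _drmmrm_design
from drmmrm.simulate import ar1_correlation
from drmmrm.metrics import theoretical_rmse


def _noise_free_trial(ed50=16.0, timecourse="exponential", arm_config="4dose"):
    design = Design(omega=0.0, sigma=1e-7, n_per_arm=4)
    sc = Scenario(ed50_true=ed50, timecourse=timecourse,
                  arm_config=arm_config, n_reps=1, seed=0)
    return simulate_trial(sc, design, 0), design


class TestMmrm:
    def test_noise_free_recovers_truth_everywhere(self):
        trial, _ = _noise_free_trial()
        fit = fit_mmrm(trial)
        params = TruthParams(ed50=16.0, timecourse="exponential")
        for r in fit.estimates.itertuples():
            assert r.estimate == pytest.approx(
                true_effect(params, r.dose, r.week), abs=1e-5
            )

    def test_estimates_are_cell_mean_differences(self, small_trial):
        fit = fit_mmrm(small_trial)
        cells = small_trial.groupby(["dose", "week"])["duacr"].mean()
        for r in fit.estimates.itertuples():
            expected = cells[(r.dose, r.week)] - cells[(0.0, r.week)]
            assert r.estimate == pytest.approx(expected, abs=1e-8)

    def test_last_visit_se_near_theoretical_precision(self, small_trial, design):
        fit = fit_mmrm(small_trial)
        last = fit.estimates[fit.estimates["week"] == 16.0]
        expected = theoretical_rmse(design.omega, design.sigma, design.n_per_arm)
        assert np.allclose(last["se"], expected, rtol=0.15)

    def test_full_shape_and_ci(self, small_trial):
        fit = fit_mmrm(small_trial)
        assert len(fit.estimates) == 4 * 9  # every dose x visit
        assert fit.dose_response is None
        w = fit.estimates["ci_high"] - fit.estimates["ci_low"]
        assert np.allclose(w, 2 * 1.959964 * fit.estimates["se"], rtol=1e-6)


class TestDrEos:
    def test_noise_free_recovers_ed50_and_emax(self):
        trial, _ = _noise_free_trial(ed50=16.0, timecourse="direct")
        fit = fit_dreos(trial)
        assert fit.converged
        assert fit.dose_response.ed50_hat == pytest.approx(16.0, rel=1e-3)
        true_emax = np.log(0.6) * (100 + 16) / 100
        assert fit.dose_response.emax_hat[0] == pytest.approx(true_emax, rel=1e-3)

    def test_only_last_visit_estimates(self, small_trial):
        fit = fit_dreos(small_trial)
        assert set(fit.estimates["week"]) == {16.0}
        assert len(fit.estimates) == 4

    def test_flat_data_gives_zero_effect(self, design):
        sc = Scenario(ed50_true=8, timecourse="direct", n_reps=1, seed=0)
        trial = simulate_trial(sc, design, 0)
        trial = trial.assign(duacr=0.25)
        fit = fit_dreos(trial)
        assert np.allclose(fit.estimates["estimate"], 0.0, atol=1e-8)
        assert abs(fit.dose_response.emax_hat[0] * 100 /
                   (fit.dose_response.ed50_hat + 100)) < 1e-8

    def test_median_ed50_near_truth_over_replicates(self, design):
        sc = Scenario(ed50_true=8, timecourse="direct", n_reps=150, seed=21)
        ed50s = []
        for rep in range(150):
            fit = fit_dreos(simulate_trial(sc, design, rep))
            ed50s.append(fit.dose_response.ed50_hat)
        assert np.median(ed50s) == pytest.approx(8.0, rel=0.45)

    def test_estimates_follow_emax_shape(self, small_trial):
        fit = fit_dreos(small_trial)
        p = fit.dose_response
        for r in fit.estimates.itertuples():
            assert r.estimate == pytest.approx(
                p.emax_hat[0] * r.dose / (p.ed50_hat + r.dose), rel=1e-9
            )


class TestDrMmrmSingle:
    def test_reference_dose_column_collapses_to_unit(self):
        # at d = dose_m the Emax term multiplier is exactly 1
        doses = np.array([0.0, 3.0, 10.0, 30.0, 100.0])
        for i, dm in enumerate(doses[1:], start=1):
            X = _drmmrm_design(doses, 9, ed50=17.3, dose_m=dm)
            assert np.allclose(X[i, :, 9:], np.eye(9), atol=1e-12)
        assert np.allclose(X[0, :, 9:], 0.0)  # placebo has no drug term

    def test_noise_free_recovery(self):
        trial, _ = _noise_free_trial(ed50=16.0, timecourse="linear")
        fit = fit_drmmrm_single(trial, 30.0)
        assert fit.converged
        assert fit.ed50_hat == pytest.approx(16.0, rel=1e-3)
        params = TruthParams(ed50=16.0, timecourse="linear")
        weeks = np.sort(trial["week"].unique())
        for t, w in enumerate(weeks):
            assert fit.e_dose[t] == pytest.approx(
                true_effect(params, 30.0, w), abs=1e-5
            )

    def test_profiled_fit_matches_dense_brute_force(self, tiny_design):
        # brute-force joint maximization over all parameters with an
        # explicitly assembled dense Gaussian likelihood
        sc = Scenario(ed50_true=8.0, timecourse="direct", n_reps=1, seed=13)
        trial = simulate_trial(sc, tiny_design, 0)
        fit = fit_drmmrm_single(trial, 10.0, criterion="ml")

        m = 3
        doses = np.sort(trial["dose"].unique())
        wide = trial.pivot_table(index=["dose", "subject"], columns="week",
                                 values="duacr").sort_index()
        y = wide.to_numpy()
        dose_per_subj = wide.index.get_level_values("dose").to_numpy()

        def neg_dense(theta):
            plc, e_dose = theta[:m], theta[m : 2 * m]
            led50, lsig, z = theta[2 * m], theta[2 * m + 1], theta[2 * m + 2]
            ed50, sig, rho = np.exp(led50), np.exp(lsig), np.tanh(z)
            c = dose_per_subj / (ed50 + dose_per_subj) * (ed50 + 10.0) / 10.0
            mu = plc[None, :] + c[:, None] * e_dose[None, :]
            R = sig**2 * ar1_correlation(rho, m)
            Rinv = np.linalg.inv(R)
            resid = y - mu
            quad = np.einsum("ij,jk,ik->", resid, Rinv, resid)
            _, ld = np.linalg.slogdet(R)
            n = len(y)
            return 0.5 * (n * m * np.log(2 * np.pi) + n * ld + quad)

        x0 = np.concatenate([
            fit.plc, fit.e_dose,
            [np.log(fit.ed50_hat), np.log(fit.sigma_hat),
             np.arctanh(fit.rho_hat)],
        ])
        assert -neg_dense(x0) == pytest.approx(fit.loglik, abs=1e-8)
        res = optimize.minimize(neg_dense, x0 + 0.01, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-11,
                                         "maxiter": 100000, "maxfev": 100000})
        assert fit.loglik >= -res.fun - 1e-6
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-5)


@pytest.fixture(scope="module")
def noisy_fit(small_trial):
    return fit_drmmrm(small_trial)


class TestDrMmrm:
    def test_reparameterization_invariance(self, small_trial):
        # all reference-dose parameterizations share one optimum
        fits = {d: fit_drmmrm_single(small_trial, d) for d in (3.0, 10.0, 30.0, 100.0)}
        lls = [f.loglik for f in fits.values()]
        assert max(lls) - min(lls) < 1e-6
        ed50s = [f.ed50_hat for f in fits.values()]
        assert np.allclose(ed50s, ed50s[0], rtol=1e-4)
        emaxes = [
            f.e_dose[-1] * (f.ed50_hat + f.dose_m) / f.dose_m for f in fits.values()
        ]
        assert np.allclose(emaxes, emaxes[0], rtol=1e-3)

    def test_noise_free_recovery_all_arms(self):
        trial, _ = _noise_free_trial(ed50=32.0, timecourse="exponential")
        fit = fit_drmmrm(trial)
        assert fit.converged
        assert fit.dose_response.ed50_hat == pytest.approx(32.0, rel=1e-3)
        params = TruthParams(ed50=32.0, timecourse="exponential")
        for r in fit.estimates.itertuples():
            assert r.estimate == pytest.approx(
                true_effect(params, r.dose, r.week), abs=1e-4
            )

    def test_estimates_satisfy_emax_shape_across_doses(self, noisy_fit):
        # ratios of fitted effects across arms equal d/(ED50+d) ratios
        ed50 = noisy_fit.dose_response.ed50_hat
        last = noisy_fit.estimates[noisy_fit.estimates["week"] == 16.0]
        frac = last["dose"] / (ed50 + last["dose"])
        ratio = last["estimate"] / frac
        assert np.allclose(ratio, ratio.iloc[0], rtol=1e-3)

    def test_every_dose_and_visit_estimated(self, noisy_fit):
        assert len(noisy_fit.estimates) == 4 * 9
        assert all(noisy_fit.param_converged.values())

    def test_needs_three_active_doses(self, design):
        sc = Scenario(ed50_true=8, timecourse="direct", n_reps=1, seed=0)
        trial = simulate_trial(sc, design, 0)
        with pytest.raises(ValueError):
            fit_drmmrm(trial[trial["dose"].isin([0.0, 10.0])])


@pytest.fixture(scope="module")
def mean_ses(design):
    """Mean last-visit SEs per method per dose over a few replicates."""
    sc = Scenario(ed50_true=32.0, timecourse="linear", n_reps=8, seed=3)
    rows = []
    for rep in range(8):
        trial = simulate_trial(sc, design, rep)
        for fit in (fit_mmrm(trial), fit_dreos(trial), fit_drmmrm(trial)):
            last = fit.estimates[fit.estimates["week"] == 16.0]
            for r in last.itertuples():
                rows.append((fit.method, r.dose, r.se))
    df = pd.DataFrame(rows, columns=["method", "dose", "se"])
    return df.groupby(["method", "dose"])["se"].mean()


class TestPrecisionStructure:
    def test_precision_ordering_lower_doses(self, mean_ses):
        # dose-response sharing buys precision at the lower doses
        for dose in (3.0, 10.0, 30.0):
            assert mean_ses[("DR-MMRM", dose)] <= mean_ses[("DR-EOS", dose)]
            assert mean_ses[("DR-EOS", dose)] <= mean_ses[("MMRM", dose)]

    def test_methods_comparable_at_highest_dose(self, mean_ses):
        ses = [mean_ses[(m, 100.0)] for m in ("MMRM", "DR-EOS", "DR-MMRM")]
        assert max(ses) / min(ses) < 1.3


class TestFitsToFrame:
    def test_tidy_output_columns(self, small_trial):
        frame = fits_to_frame(
            [fit_mmrm(small_trial), fit_dreos(small_trial)],
            scenario="s", rep=2,
        )
        assert {"method", "dose", "week", "estimate", "se", "ci_low",
                "ci_high", "ed50_hat", "emax_hat", "converged", "scenario",
                "rep"} <= set(frame.columns)
        assert set(frame["method"]) == {"MMRM", "DR-EOS"}
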