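"""Dose-response normalization, 4PL/biphasic fitting and significance."""

import numpy as np
import pandas as pd
import pytest

from spherohca.doseresponse import (
    DoseResponseModel,
    fit_biphasic,
    fit_monophasic,
    normalize_to_control,
    select_model,
    simulate_curve,
    stars_for,
)
from spherohca.doseresponse import test_vs_control as welch_vs_control
from spherohca.exceptions import NormalizationError


def _raw_table(control, doses):
    rows = [{"concentration": 0.0, "value": v} for v in control]
    for c, vals in doses.items():
        rows += [{"concentration": c, "value": v} for v in vals]
    return pd.DataFrame(rows)


class TestNormalization:
    def test_simple_halving(self):
        curve = normalize_to_control(_raw_table([100.0], {10.0: [50.0]}))
        assert curve.responses[10.0][0] == pytest.approx(0.5)

    def test_control_mean_from_replicates(self):
        curve = normalize_to_control(_raw_table([90.0, 110.0], {10.0: [100.0]}))
        assert curve.responses[10.0][0] == pytest.approx(1.0)
        assert np.mean(curve.responses[0.0]) == pytest.approx(1.0)

    def test_forty_percent_drop(self):
        curve = normalize_to_control(
            _raw_table([100.0, 100.0], {1000.0: [60.0, 60.0]})
        )
        assert np.mean(curve.responses[1000.0]) == pytest.approx(0.6)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_to_control(_raw_table([0.0], {10.0: [5.0]}))

    def test_missing_vehicle_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_to_control(
                pd.DataFrame({"concentration": [10.0], "value": [1.0]})
            )


class TestMonophasic:
    def test_zero_noise_exact_recovery(self):
        curve = simulate_curve([100.0], hills=1.0, noise_sd=0.0, seed=0)
        res = fit_monophasic(curve)
        assert res.ec50.value == pytest.approx(100.0, rel=1e-6)
        assert res.params["hill"] == pytest.approx(1.0, rel=1e-4)

    def test_flat_curve_censored_no_effect(self):
        curve = simulate_curve([100.0], left=1.0, right=1.0, noise_sd=0.02, seed=1)
        res = fit_monophasic(curve)
        assert res.no_effect
        assert res.ec50.censored == "above_max"
        assert str(res.ec50).startswith(">")

    def test_rescaling_equivariance(self):
        nm = simulate_curve([100.0], noise_sd=0.05, seed=3)
        um = simulate_curve([100.0], noise_sd=0.05, seed=3)
        um.concentrations = nm.concentrations / 1000.0
        um.responses = {c / 1000.0: v for c, v in nm.responses.items()}
        r_nm = fit_monophasic(nm)
        r_um = fit_monophasic(um)
        assert r_um.ec50.value * 1000.0 == pytest.approx(r_nm.ec50.value, rel=1e-3)

    def test_recovery_power_median_log_error(self):
        errs = []
        for i in range(200):
            curve = simulate_curve([100.0], hills=1.0, left=1.0, right=0.25,
                                   noise_sd=0.10, seed=4000 + i)
            res = fit_monophasic(curve, n_starts=4, seed=i)
            errs.append(abs(np.log10(res.ec50.value / 100.0)))
        assert np.median(errs) <= 0.12


class TestBiphasic:
    def test_zero_noise_exact_recovery(self):
        curve = simulate_curve([20.0, 500.0], hills=1.0, fraction=0.5,
                               noise_sd=0.0, seed=0)
        res = fit_biphasic(curve)
        assert res.model == "biphasic_double_hill"
        assert res.ec50s[0].value == pytest.approx(20.0, rel=1e-4)
        assert res.ec50s[1].value == pytest.approx(500.0, rel=1e-4)

    def test_ordered_ec50s(self):
        curve = simulate_curve([20.0, 500.0], hills=2.0, noise_sd=0.05, seed=5)
        res = fit_biphasic(curve)
        if res.model == "biphasic_double_hill":
            assert res.ec50s[0].value < res.ec50s[1].value

    def test_monophasic_data_triggers_fallback(self):
        curve = simulate_curve([100.0], hills=1.5, noise_sd=0.0, seed=0)
        res = fit_biphasic(curve)
        assert res.model == "monophasic_4PL"
        assert res.fell_back

    def test_labels_carry_increments(self):
        curve = simulate_curve([20.0, 500.0], hills=2.0, noise_sd=0.0,
                               parameter="Area", seed=0)
        res = fit_biphasic(curve)
        assert [e.label for e in res.ec50s] == ["Area-1", "Area-2"]


class TestModelSelection:
    def test_monophasic_data_selects_monophasic(self):
        picks = []
        for i in range(100):
            curve = simulate_curve([100.0], hills=1.0, left=1.0, right=0.25,
                                   noise_sd=0.10, seed=2000 + i)
            res = DoseResponseModel(curve).fit("auto", n_starts=4, seed=i)
            picks.append(res.model == "monophasic_4PL")
        assert np.mean(picks) >= 0.90

    def test_biphasic_data_selects_biphasic(self):
        picks = []
        for i in range(100):
            curve = simulate_curve([20.0, 200.0], hills=3.0, fraction=0.5,
                                   left=1.0, right=0.2, noise_sd=0.05,
                                   seed=3000 + i)
            res = DoseResponseModel(curve).fit("auto", n_starts=4, seed=i)
            picks.append(res.model == "biphasic_double_hill")
        assert np.mean(picks) >= 0.80

    def test_tie_goes_to_monophasic(self):
        curve = simulate_curve([100.0], noise_sd=0.05, seed=1)
        mono = fit_monophasic(curve)
        bi = fit_biphasic(curve, seed=1)
        if bi.model == "biphasic_double_hill":
            bi.aicc = mono.aicc  # forced tie
        assert select_model(mono, bi).model == "monophasic_4PL"


class TestSignificance:
    def test_large_effect_three_stars(self):
        curve = simulate_curve([100.0], noise_sd=0.0, seed=0)
        # shift the top dose 5 SD from control with sd ~ 0.02
        rng = np.random.default_rng(0)
        for c in curve.concentrations:
            curve.responses[c] = 1.0 + rng.normal(0, 0.02, 6)
        top = float(curve.concentrations[-1])
        curve.responses[top] = 0.9 + rng.normal(0, 0.02, 6)  # 5 SD away
        sig = welch_vs_control(curve)
        assert sig.stars(top) == "***"

    def test_star_thresholds(self):
        assert stars_for(0.03) == "*"
        assert stars_for(0.009) == "**"
        assert stars_for(0.0009) == "***"
        assert stars_for(0.2) == ""

    def test_single_replicate_gives_na(self):
        curve = simulate_curve([100.0], n_replicates=1, noise_sd=0.05, seed=2)
        sig = welch_vs_control(curve)
        assert sig.table.p_value.isna().all()

    def test_null_distribution_rarely_stars(self):
        rng = np.random.default_rng(9)
        hits = []
        for _ in range(30):
            curve = simulate_curve([100.0], left=1.0, right=1.0,
                                   noise_sd=0.05,
                                   seed=int(rng.integers(2**31)))
            sig = welch_vs_control(curve)
            hits.append((sig.table.p_value < 0.05).mean())
        assert np.mean(hits) < 0.15  # ~alpha, with sampling slack


class TestResultsAPI:
    def test_summary_mentions_model_and_ec50(self):
        curve = simulate_curve([100.0], noise_sd=0.02, seed=4, parameter="ATP")
        res = DoseResponseModel(curve).fit("monophasic")
        text = res.summary()
        assert "monophasic_4PL" in text and "EC50" in text and "ATP" in text

    def test_predict_matches_asymptotes(self):
        curve = simulate_curve([100.0], left=1.0, right=0.25, noise_sd=0.0, seed=0)
        res = fit_monophasic(curve)
        assert res.predict([0.0])[0] == pytest.approx(1.0, abs=0.01)
        assert res.predict([1e7])[0] == pytest.approx(0.25, abs=0.01)
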