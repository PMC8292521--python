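"""Biokinetic model tests: closed-form evaluation, binning against the
published table, constrained fitting, TIAC (closed form vs quadrature), and
the model comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import dmsapk as d
from dmsapk.kinetics import DEFAULT_BIN_WIDTH_H, KidneyUptakeRecord
from dmsapk.projector import LN2


def _record(t, frac):
    return KidneyUptakeRecord("P0", 4.0, 16.0, "female", "retrospective", t, frac)


class TestModelFraction:
    def test_pediatric_model_closed_forms(self):
        m = d.load_model("current_study")
        assert d.model_fraction(m, 0.0) == pytest.approx(0.06)
        assert d.model_fraction(m, 1.1) == pytest.approx(0.21)
        assert m.plateau == pytest.approx(0.36)
        assert d.model_fraction(m, 1e6) == pytest.approx(0.36)

    def test_bounded_by_plateau(self):
        m = d.load_model("current_study")
        t = np.linspace(0, 50, 500)
        f = d.model_fraction(m, t)
        assert ((f >= 0) & (f <= m.plateau + 1e-12)).all()

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            d.BiokineticModel(F_S=0.3, components=((-1.0, 1.0), (0.5, math.inf)))
        with pytest.raises(ValueError):
            d.BiokineticModel(F_S=0.3, components=((1.0, -2.0),))


class TestBinning:
    def test_published_bin_row(self):
        """Nine records reproducing the published 2.50-2.65 h bin: n=9,
        mean 0.335, SD 0.028, CV 8.4%."""
        rng = np.random.default_rng(1)
        target_mean, target_sd, n = 0.335, 0.028, 9
        vals = rng.normal(0, 1, n)
        vals = (vals - vals.mean()) / vals.std(ddof=1) * target_sd + target_mean
        recs = [_record(2.55, v) for v in vals]
        table = d.bin_records(recs)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["t_start_h"] == pytest.approx(2.5)
        assert row["n"] == 9
        assert row["mean_fraction"] == pytest.approx(0.335)
        assert row["sd_fraction"] == pytest.approx(0.028)
        assert round(row["cv_pct"], 1) == 8.4

    def test_single_record_bin_has_no_sd(self):
        table = d.bin_records([_record(0.2, 0.1)])
        assert np.isnan(table.iloc[0]["sd_fraction"])
        assert np.isnan(table.iloc[0]["cv_pct"])

    def test_stats_match_direct_computation(self):
        rng = np.random.default_rng(2)
        recs = [_record(t, f) for t, f in zip(rng.uniform(0, 6, 200),
                                              rng.uniform(0, 0.5, 200))]
        table = d.bin_records(recs)
        assert int(table["n"].sum()) == 200
        for _, row in table.iterrows():
            sel = [r.fraction for r in recs
                   if row["t_start_h"] <= r.time_h < row["t_end_h"]]
            assert row["mean_fraction"] == pytest.approx(np.mean(sel), abs=1e-12)
            if len(sel) >= 2:
                assert row["sd_fraction"] == pytest.approx(np.std(sel, ddof=1),
                                                           abs=1e-12)


class TestFit:
    def test_noise_free_recovery_exact(self):
        truth = d.BiokineticModel(0.25, ((-1.0, 1.4), (1.3, math.inf)))
        t = np.arange(0.25, 6.0, 0.5)
        table = pd.DataFrame({
            "t_mid_h": t,
            "mean_fraction": d.model_fraction(truth, t),
            "n": np.ones_like(t, dtype=int),
            "sd_fraction": np.nan,
        })
        fit = d.fit_biokinetic(table)
        assert fit.params["F_S"] == pytest.approx(0.25, abs=1e-6)
        assert fit.params["T1"] == pytest.approx(1.4, abs=1e-6)
        assert fit.params["a2"] == pytest.approx(1.3, abs=1e-6)

    def test_published_table_fit_within_printed_se(self):
        """The constrained fit to the published binned cohort data lands on
        the published parameters within their published SEs."""
        fit = d.fit_biokinetic(d.load_binned_table())
        assert abs(fit.params["F_S"] - 0.3) <= 0.04
        assert abs(fit.params["T1"] - 1.1) <= 0.4
        assert abs(fit.params["a2"] - 1.2) <= 0.9

    def test_se_shrinks_with_weight_scale(self):
        """Scaling all bin weights up (more patients per bin) shrinks the
        reported parameter SEs."""
        table = d.load_binned_table()
        f1 = d.fit_biokinetic(table, weights=np.ones(len(table)))
        f2 = d.fit_biokinetic(table, weights=np.full(len(table), 16.0))
        # same point estimate, SE scaled by 1/sqrt(16) via residual variance:
        # with relative weights the residual-variance scaling cancels, so
        # compare covariance against explicit per-bin replication instead
        rep = pd.concat([table] * 4, ignore_index=True)
        f3 = d.fit_biokinetic(rep, weights=np.ones(len(rep)))
        assert f3.se["F_S"] < f1.se["F_S"]
        assert f2.params["F_S"] == pytest.approx(f1.params["F_S"], abs=1e-9)

    def test_degenerate_design_rejected(self):
        table = pd.DataFrame({"t_mid_h": [1.0, 1.0, 1.0],
                              "mean_fraction": [0.1, 0.2, 0.3],
                              "n": [1, 1, 1], "sd_fraction": np.nan})
        with pytest.raises(ValueError, match="degenerate"):
            d.fit_biokinetic(table)

    def test_monte_carlo_parameter_recovery(self):
        """100 simulated cohorts at the study size (n=77, 20% measurement
        noise): median absolute F_S error at most 0.05."""
        errs = []
        for s in range(100):
            spec = d.CohortSpec(seed=1000 + s, measurement_cv=0.2,
                                between_patient_cv=0.0, sex_uptake_offset=0.0)
            table = d.bin_records(d.sample_cohort(spec))
            table = table[table["n"] > 0]
            fit = d.fit_biokinetic(table)
            errs.append(abs(fit.params["F_S"] - 0.3))
        assert np.median(errs) <= 0.05


class TestTiac:
    def test_published_model_values(self):
        assert d.tiac(d.load_model("icrp53")).value_h == pytest.approx(3.71, abs=0.005)
        assert d.tiac(d.load_model("current_study")).value_h == pytest.approx(2.7, abs=0.05)

    def test_degenerate_closed_forms(self):
        zero = d.BiokineticModel(0.0, ((1.0, math.inf),))
        assert d.tiac(zero).value_h == 0.0
        single = d.BiokineticModel(0.4, ((1.0, math.inf),))
        assert d.tiac(single).value_h == pytest.approx(0.4 * 6.0 / LN2)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        fs=st.floats(0.05, 0.9),
        t1=st.floats(0.2, 4.0),
        a2=st.floats(1.0, 2.5),
        tphys=st.floats(2.0, 12.0),
    )
    def test_closed_form_matches_quadrature(self, fs, t1, a2, tphys):
        """The closed-form TIAC equals the numerically integrated
        decay-weighted uptake curve."""
        m = d.BiokineticModel(fs, ((-1.0, t1), (a2, math.inf)))
        closed = d.tiac(m, tphys).value_h
        val, _ = quad(lambda t: d.model_fraction(m, t) * d.decay_factor(t, tphys),
                      0, np.inf, limit=200)
        assert closed == pytest.approx(val, rel=1e-6)

    def test_monotone_in_fs_and_half_life(self):
        base = d.load_model("current_study")
        up_fs = d.BiokineticModel(0.35, base.components)
        assert d.tiac(up_fs).value_h > d.tiac(base).value_h
        assert d.tiac(base, 7.0).value_h > d.tiac(base, 6.0).value_h


class TestTiacUncertainty:
    def _fit(self):
        return d.fit_biokinetic(d.load_binned_table())

    def test_zero_covariance_gives_zero_se(self):
        fit = self._fit()
        fit.covariance = np.zeros((3, 3))
        assert d.tiac_uncertainty(fit, n_draws=500, seed=1) == 0.0

    def test_fs_only_variance_is_linear(self):
        """With variance only on F_S the TIAC SE equals
        sigma * TIAC / F_S (TIAC is linear in F_S)."""
        fit = self._fit()
        sigma = 0.01  # small so bound truncation never bites
        fit.covariance = np.diag([sigma**2, 0.0, 0.0])
        se = d.tiac_uncertainty(fit, n_draws=20000, seed=2)
        expected = sigma * d.tiac(fit.model).value_h / fit.params["F_S"]
        assert se == pytest.approx(expected, rel=0.03)

    def test_cohort_fit_se_magnitude(self):
        """SE of the fitted pediatric TIAC is of order 0.4 h."""
        fit = self._fit()
        se = d.tiac_uncertainty(fit, n_draws=4000, seed=3)
        assert 0.1 < se < 1.2

    def test_deterministic_given_seed(self):
        fit = self._fit()
        a = d.tiac_uncertainty(fit, n_draws=1000, seed=7)
        b = d.tiac_uncertainty(fit, n_draws=1000, seed=7)
        assert a == b


class TestCompareModels:
    def test_pediatric_vs_adult_reduction(self):
        models = {"icrp53": d.load_model("icrp53"),
                  "current_study": d.load_model("current_study")}
        df = d.compare_models(models).set_index("model")
        assert df.loc["current_study", "pct_diff_vs_ref"] == -27
        assert df.loc["icrp53", "pct_diff_vs_ref"] == 0

    def test_evans_closed_form_reported(self):
        """The closed form applied to the published Evans parameters gives
        ~1.37 h; the comparison reports the computed value as-is."""
        models = {"icrp53": d.load_model("icrp53"), "evans": d.load_model("evans")}
        df = d.compare_models(models).set_index("model")
        assert df.loc["evans", "tiac_h"] == pytest.approx(1.370, abs=0.005)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            d.compare_models({"a": d.load_model("icrp53"),
                              "b": d.load_model("evans")}, reference="zzz")
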