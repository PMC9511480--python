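"""Melt-curve fitting, Tm shifts, the hit rule, normalization, ITDR."""

import numpy as np
import pandas as pd
import pytest

from maldiscreen import simulate, thermal
from maldiscreen.errors import ConfigError, FitError
from maldiscreen.thermal import (
    DEFAULT_TEMPERATURES,
    MeltFit,
    TPPComparison,
    call_tpp_hits,
    delta_tm,
    fit_itdr,
    fit_melting_curve,
    itdr_model,
    melt_model,
    normalize_tpp,
    params_for_tm,
    tm_from_params,
)

TEMPS = np.asarray(DEFAULT_TEMPERATURES)


class TestMeltModel:
    def test_tm_closed_form_p_zero(self):
        assert tm_from_params(1250.0, 25.0, 0.0) == pytest.approx(50.0)

    def test_tm_is_half_denaturation_point(self):
        # f(Tm) = 0.5 absolute: half of the full 0-to-1 span
        a, b, p = params_for_tm(53.0, 25.0, 0.1)[0], 25.0, 0.1
        tm = tm_from_params(a, b, p)
        assert melt_model(tm, a, b, p) == pytest.approx(0.5)

    @pytest.mark.parametrize("tm_true,b,p", [(46.0, 15.0, 0.0), (52.0, 25.0, 0.05), (60.0, 40.0, 0.2)])
    def test_noiseless_round_trip(self, tm_true, b, p):
        a, _ = params_for_tm(tm_true, b, p)
        y = melt_model(TEMPS, a, b, p)
        fit = fit_melting_curve(TEMPS, y)
        assert fit.converged
        assert fit.tm == pytest.approx(tm_true, abs=0.05)
        assert fit.a == pytest.approx(a, rel=1e-3)
        assert fit.plateau == pytest.approx(p, abs=1e-3)

    def test_monotone_increasing_data_does_not_converge(self):
        y = np.linspace(1.0, 2.0, len(TEMPS))
        fit = fit_melting_curve(TEMPS, y)
        assert not fit.converged
        assert np.isnan(fit.tm)

    def test_too_few_points_rejected(self):
        with pytest.raises(ConfigError):
            fit_melting_curve(TEMPS[:4], np.ones(4))

    def test_celsius_kelvin_consistency(self):
        # the 1/T exponent makes (a, b) unit-dependent, Tm is not
        a, b, p = params_for_tm(52.0, 25.0, 0.02)[0], 25.0, 0.02
        y = melt_model(TEMPS, a, b, p)
        fit_k = fit_melting_curve(TEMPS + 273.15, y)
        assert fit_k.converged
        assert fit_k.tm - 273.15 == pytest.approx(52.0, abs=0.1)


class TestDeltaTm:
    def _fits(self, tms):
        return {
            rep: MeltFit(tm=t, converged=True, a=1.0, b=1.0, plateau=0.0, r_squared=1.0)
            for rep, t in enumerate(tms, start=1)
        }

    def test_constructed_three_degree_shift(self):
        fits1, fits2 = {}, {}
        for rep in range(1, 5):
            a1, b = params_for_tm(50.0, 25.0, 0.02)
            a2, _ = params_for_tm(53.0, 25.0, 0.02)
            y1 = melt_model(TEMPS, a1, b, 0.02)
            y2 = melt_model(TEMPS, a2, b, 0.02)
            fits1[rep] = fit_melting_curve(TEMPS, y1)
            fits2[rep] = fit_melting_curve(TEMPS, y2)
        comp = delta_tm(fits1, fits2)
        assert comp.mean_delta_tm == pytest.approx(3.0, abs=0.01)
        assert comp.sd_delta_tm < 0.01

    def test_antisymmetric_under_condition_swap(self):
        f1, f2 = self._fits([50.0, 50.5, 49.8]), self._fits([53.0, 53.2, 52.7])
        fwd = delta_tm(f1, f2)
        rev = delta_tm(f2, f1)
        assert fwd.mean_delta_tm == pytest.approx(-rev.mean_delta_tm)

    def test_unconverged_replicates_excluded_and_counted(self):
        f1 = self._fits([50.0, 50.1, 50.2, 49.9])
        f2 = self._fits([52.0, 52.1, 52.2, 52.3])
        f2[2] = MeltFit(converged=False)
        comp = delta_tm(f1, f2)
        assert comp.n_usable == 3
        assert comp.n_excluded == 1

    def test_single_usable_pair_flagged_unusable(self):
        comp = delta_tm(self._fits([50.0]), self._fits([52.0]))
        assert not comp.usable


class TestHitRule:
    def _comp(self, deltas):
        arr = np.asarray(deltas, dtype=float)
        return TPPComparison(
            "P", tuple(arr), float(arr.mean()), float(arr.std(ddof=1)),
            len(arr), 0, bool(np.all(arr > 0) or np.all(arr < 0)), True,
        )

    def test_consistent_large_shift_is_hit(self):
        assert call_tpp_hits([self._comp([6, 6, 6, 6])])["hit"].iloc[0]

    def test_sign_inconsistency_blocks(self):
        assert not call_tpp_hits([self._comp([6, -6, 6, 6])])["hit"].iloc[0]

    def test_high_sd_blocks(self):
        comp = self._comp([3, 8, 2, 7])
        assert comp.sd_delta_tm > 2.0
        assert not call_tpp_hits([comp])["hit"].iloc[0]

    def test_ordering_by_absolute_shift(self):
        df = call_tpp_hits([self._comp([2, 2, 2, 2]), self._comp([-5, -5, -5, -5])])
        assert df["mean_delta_tm"].iloc[0] == -5.0

    def test_null_simulations_rarely_called(self):
        # identical-condition simulations: hit rate must stay under 5%
        cfg = simulate.TPPSimConfig(
            proteins=[
                simulate.ProteinMeltSpec(f"P{i}", {"c1": 48.0 + i % 10, "c2": 48.0 + i % 10})
                for i in range(60)
            ],
            seed=17,
        )
        fits = thermal.fit_all_curves(simulate.simulate_tpp(cfg))
        comps = thermal.compare_conditions(fits, "c1", "c2")
        hits = call_tpp_hits(comps)
        assert hits["hit"].mean() < 0.05


class TestParameterRecovery:
    def test_tm_recovered_within_half_degree_at_10pct_noise(self):
        rng = np.random.default_rng(5)
        tms = rng.uniform(44.0, 62.0, 100)
        errs = []
        for i, tm_true in enumerate(tms):
            cfg = simulate.TPPSimConfig(
                proteins=[simulate.ProteinMeltSpec(f"P{i}", {"c": float(tm_true)})],
                replicates=2, tm_jitter_sd=0.0, seed=1000 + i,
            )
            fits = thermal.fit_all_curves(simulate.simulate_tpp(cfg))
            ok = fits[fits.converged]
            errs.extend(np.abs(ok["tm"].values - tm_true))
        assert np.median(errs) < 0.5


class TestNormalization:
    def _table(self, n_proteins=12, scale=None, noise=0.0, seed=0, same_tm=False):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_proteins):
            tm = 50.0 if same_tm else 46.0 + (i % 8)
            a, b = params_for_tm(tm, 25.0, 0.02)
            for cond in ("vehicle", "drug"):
                for rep in (1, 2):
                    y = melt_model(TEMPS, a, b, 0.02)
                    y = y / y[0]
                    if noise:
                        y = y * rng.lognormal(0, noise, len(y))
                    if scale and (cond, rep) in scale:
                        y = y * scale[(cond, rep)]
                    for t, v in zip(TEMPS, y):
                        rows.append(
                            {
                                "protein": f"P{i}", "condition": cond, "replicate": rep,
                                "temperature": t, "rel_abundance": v,
                            }
                        )
        return pd.DataFrame(rows)

    def test_clean_data_yields_unit_factors(self):
        # consistent samples need no correction (median curve is exactly the model)
        out, factors = normalize_tpp(self._table(same_tm=True), reference_condition="vehicle")
        assert np.allclose(factors["factor"].values, 1.0, atol=1e-6)

    def test_mixed_proteins_need_little_correction(self):
        out, factors = normalize_tpp(self._table(), reference_condition="vehicle")
        assert np.allclose(factors["factor"].values, 1.0, atol=0.05)

    def test_global_scaling_recovered(self):
        # a sample scaled 2x beyond the reference point is pulled back
        tab = self._table()
        sel = (tab.condition == "drug") & (tab.replicate == 2) & (tab.temperature > TEMPS[0])
        tab.loc[sel, "rel_abundance"] *= 2.0
        out, factors = normalize_tpp(tab, reference_condition="vehicle")
        f = factors[(factors.condition == "drug") & (factors.replicate == 2)]
        assert np.allclose(f[f.temperature > TEMPS[0]]["factor"].values, 0.5, atol=0.05)

    def test_normalization_preserves_tm(self):
        tab = self._table()
        out, _ = normalize_tpp(tab, reference_condition="vehicle")
        for (prot, cond, rep), grp in out.groupby(["protein", "condition", "replicate"]):
            grp = grp.sort_values("temperature")
            fit = fit_melting_curve(grp.temperature.values, grp.rel_abundance.values)
            raw = tab[(tab.protein == prot) & (tab.condition == cond) & (tab.replicate == rep)]
            raw = raw.sort_values("temperature")
            fit0 = fit_melting_curve(raw.temperature.values, raw.rel_abundance.values)
            if fit.converged and fit0.converged:
                assert fit.tm == pytest.approx(fit0.tm, abs=0.2)


class TestITDR:
    def test_low_concentration_limit_is_baseline(self):
        assert itdr_model(0.0, 0.1, 0.9, 4.6) == pytest.approx(0.1)
        assert itdr_model(1e-9, 0.1, 0.9, 4.6) == pytest.approx(0.1, abs=1e-6)

    def test_noiseless_round_trip(self):
        c = np.array([0.05, 0.2, 1.0, 4.6, 20.0, 100.0])
        y = itdr_model(c, 0.08, 0.92, 4.6, 1.0)
        fit = fit_itdr(c, y)
        assert fit.ec50 == pytest.approx(4.6, rel=0.005)

    def test_hill_fixed_on_five_point_design(self):
        df = simulate.simulate_itdr(noise_cv=0.0)
        fit = fit_itdr(df.concentration, df.soluble_fraction)
        assert fit.hill_fixed and fit.hill == 1.0

    def test_flat_series_rejected(self):
        with pytest.raises(FitError):
            fit_itdr([0.1, 0.5, 1.0, 5.0, 10.0], np.full(5, 0.4))
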