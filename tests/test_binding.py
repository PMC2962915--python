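"""Stage-2 binding fits: saturation, protection, ratios and tables."""

import math

import numpy as np
import pytest

from shprotect import (
    CoenzymeBinding,
    ExperimentDesign,
    NoiseSpec,
    ProtectionConditions,
    ProtectionSeries,
    RateEstimate,
    bootstrap_se_kd,
    build_comparison_table,
    discrimination_ratio,
    fit_kd,
    fit_rate_activity,
    fit_saturation,
    fold_change,
    generate_dtnb_series,
    generate_protection_series,
    round_sig,
)
from shprotect.errors import (
    DegenerateFitError,
    DomainError,
    InsufficientDataError,
    UsageError,
)
from shprotect.units import mM, to_mM, to_uM, uM


def _rates_from_series(courses):
    return [fit_rate_activity(tc) for tc in courses]


def _saturation_fit(params, design, sig, noise, variant="enzyme"):
    courses = generate_dtnb_series(params, design, sig, noise, variant=variant)
    return fit_saturation(_rates_from_series(courses))


class TestSaturationFit:
    @pytest.mark.parametrize("variant", ["wild-type", "D263K", "F238S"])
    def test_noiseless_recovery(self, catalog, design, no_noise, activity_sig, variant):
        rec = catalog[variant]
        fit = _saturation_fit(rec.params, design, activity_sig, no_noise, variant)
        assert fit.j == pytest.approx(rec.params.j, rel=1e-9)
        assert fit.k_dtnb == pytest.approx(rec.params.k_dtnb, rel=1e-9)

    def test_nonlinear_method_agrees_on_noiseless_data(self, catalog, design, no_noise,
                                                       activity_sig):
        rec = catalog["wild-type"]
        courses = generate_dtnb_series(rec.params, design, activity_sig, no_noise,
                                       variant="wild-type")
        rates = _rates_from_series(courses)
        lin = fit_saturation(rates, method="double_reciprocal")
        nl = fit_saturation(rates, method="nonlinear")
        assert nl.j == pytest.approx(lin.j, rel=1e-7)
        assert nl.k_dtnb == pytest.approx(lin.k_dtnb, rel=1e-7)

    def test_constant_rates_flagged_degenerate(self):
        rates = [
            RateEstimate(k=2e-3, se_k=0.0, r_squared=1.0, n_points=10, mode="activity",
                         conditions=ProtectionConditions(dtnb_conc=d * uM))
            for d in (50, 100, 200, 400)
        ]
        fit = fit_saturation(rates)
        assert fit.degenerate
        assert fit.k_dtnb == 0.0
        with pytest.raises(DegenerateFitError):
            fit.params

    def test_too_few_levels_rejected(self):
        rates = [
            RateEstimate(k=k, se_k=0.0, r_squared=1.0, n_points=10, mode="activity",
                         conditions=ProtectionConditions(dtnb_conc=d * uM))
            for d, k in ((100, 1e-3), (200, 1.5e-3))
        ]
        with pytest.raises(InsufficientDataError):
            fit_saturation(rates)


class TestKdFit:
    def _kd_result(self, catalog, variant, coenzyme, design, sig, noise):
        rec = catalog[variant]
        sat = _saturation_fit(rec.params, design, sig, noise, variant)
        courses = generate_protection_series(
            rec.params, rec.bindings[coenzyme], design, sig, noise, variant=variant
        )
        series = ProtectionSeries.from_rates(_rates_from_series(courses))
        return fit_kd(series, sat)

    @pytest.mark.parametrize("variant,coenzyme", [
        ("wild-type", "NAD+"),
        ("F238S", "NADPH"),
        ("P262S", "NADH"),
    ])
    def test_noiseless_recovery(self, catalog, design, no_noise, activity_sig,
                                variant, coenzyme):
        res = self._kd_result(catalog, variant, coenzyme, design, activity_sig, no_noise)
        truth = catalog[variant].bindings[coenzyme].kd
        assert res.kd == pytest.approx(truth, rel=1e-9)
        assert res.consistency_ratio == pytest.approx(1.0, abs=1e-9)

    def test_unprotected_series_yields_non_binding_sentinel(self, catalog, design,
                                                            no_noise, activity_sig):
        rec = catalog["wild-type"]
        sat = _saturation_fit(rec.params, design, activity_sig, no_noise, "wild-type")
        courses = generate_protection_series(
            rec.params, CoenzymeBinding.non_binding("X"), design, activity_sig,
            no_noise, variant="wild-type",
        )
        series = ProtectionSeries.from_rates(_rates_from_series(courses))
        res = fit_kd(series, sat)
        assert res.is_non_binding
        assert math.isinf(res.kd)

    def test_mixed_dtnb_within_series_rejected(self):
        rates = [
            RateEstimate(k=1e-3, se_k=0.0, r_squared=1.0, n_points=10, mode="activity",
                         conditions=ProtectionConditions(dtnb_conc=d * uM,
                                                         co_conc=c * mM, coenzyme="NAD+"))
            for d, c in ((200, 0.0), (200, 0.5), (400, 1.0))
        ]
        with pytest.raises(UsageError):
            ProtectionSeries(variant="x", coenzyme="NAD+", dtnb_conc=200 * uM,
                             rates=tuple(rates))

    def test_variant_mismatch_rejected(self, catalog, design, no_noise, activity_sig):
        rec = catalog["wild-type"]
        sat = _saturation_fit(rec.params, design, activity_sig, no_noise, "wild-type")
        courses = generate_protection_series(
            rec.params, rec.bindings["NAD+"], design, activity_sig, no_noise,
            variant="other",
        )
        series = ProtectionSeries.from_rates(_rates_from_series(courses))
        with pytest.raises(UsageError):
            fit_kd(series, sat)

    def test_delta_method_se_matches_bootstrap(self, catalog, activity_sig):
        """Delta-method SE within a factor of 1.5 of a parametric bootstrap."""
        design = ExperimentDesign()
        noise = NoiseSpec(model="multiplicative_gaussian", sigma=0.02, seed=5)
        rec = catalog["wild-type"]
        sat = _saturation_fit(rec.params, design, activity_sig, noise, "wild-type")
        courses = generate_protection_series(
            rec.params, rec.bindings["NAD+"], design, activity_sig, noise,
            variant="wild-type",
        )
        series = ProtectionSeries.from_rates(_rates_from_series(courses))
        res = fit_kd(series, sat)
        se_boot = bootstrap_se_kd(series, sat, n_boot=500, seed=9)
        assert 1 / 1.5 < res.se_kd / se_boot < 1.5

    def test_noisy_recovery_median_within_five_percent(self, catalog, activity_sig):
        """200 seeded replicates at 2% noise: median Kd error below 5%."""
        design = ExperimentDesign()
        rec = catalog["wild-type"]
        truth = rec.bindings["NAD+"].kd
        kds = []
        for seed in range(200):
            noise = NoiseSpec(model="multiplicative_gaussian", sigma=0.02, seed=seed)
            sat = _saturation_fit(rec.params, design, activity_sig, noise, "wild-type")
            courses = generate_protection_series(
                rec.params, rec.bindings["NAD+"], design, activity_sig, noise,
                variant="wild-type",
            )
            res = fit_kd(ProtectionSeries.from_rates(_rates_from_series(courses)), sat)
            kds.append(res.kd)
        median_err = np.median(np.abs(np.array(kds) / truth - 1.0))
        assert median_err < 0.05


class TestRatios:
    def test_discrimination_ratio_examples(self):
        assert round(discrimination_ratio(0.023, 0.024).value, 2) == 0.96
        assert round(discrimination_ratio(0.375, 0.052).value, 1) == 7.2
        assert discrimination_ratio(0.4, 0.4).value == 1.0

    def test_discrimination_ratio_propagates_se(self):
        r = discrimination_ratio(0.023, 0.024, se_nadph=0.001, se_nadh=0.001)
        expected = (0.023 / 0.024) * math.hypot(0.001 / 0.023, 0.001 / 0.024)
        assert r.se == pytest.approx(expected, rel=1e-12)

    def test_non_binding_input_gives_undefined_ratio(self):
        r = discrimination_ratio(math.inf, 0.024)
        assert not r.defined and math.isnan(r.value)

    def test_fold_change_examples(self):
        assert round_sig(fold_change(2.84, 0.335).value, 2) == 8.5
        assert round_sig(fold_change(0.375, 0.023).value, 2) == 16
        assert fold_change(1.3, 1.3).value == 1.0

    def test_fold_change_rejects_bad_reference(self):
        with pytest.raises(DomainError):
            fold_change(1.0, 0.0)
        with pytest.raises(DomainError):
            fold_change(1.0, math.inf)

    def test_round_sig(self):
        assert round_sig(19.76, 2) == 20
        assert round_sig(0.9583, 2) == 0.96
        assert round_sig(0.0, 2) == 0.0


class TestComparisonTable:
    def _full_results(self, catalog, design, no_noise, activity_sig):
        results = []
        for variant, rec in catalog.items():
            sat = _saturation_fit(rec.params, design, activity_sig, no_noise, variant)
            for coenzyme, binding in rec.bindings.items():
                courses = generate_protection_series(
                    rec.params, binding, design, activity_sig, no_noise, variant=variant
                )
                series = ProtectionSeries.from_rates(_rates_from_series(courses))
                results.append(fit_kd(series, sat))
        return results

    def test_full_study_table(self, catalog, design, no_noise, activity_sig):
        results = self._full_results(catalog, design, no_noise, activity_sig)
        table = build_comparison_table(results, reference="wild-type", sig_figs=None)
        assert table.shape[0] == 5
        # discrimination column reproduces the published values at printed precision
        ratios = table["Kd_NADPH/Kd_NADH"]
        assert round(ratios["wild-type"], 2) == 0.96
        assert round(ratios["F238S"], 1) == 5.6
        assert round(ratios["P262S"], 1) == 7.2
        assert round(ratios["F238S/P262S"], 1) == 2.1
        assert round(ratios["D263K"], 2) == 1.75
        for c in ("NAD+", "NADH", "NADPH"):
            assert table.loc["wild-type", f"fold_{c}"] == pytest.approx(1.0, rel=1e-9)

    def test_single_variant_table(self, catalog, design, no_noise, activity_sig):
        results = [r for r in self._full_results(catalog, design, no_noise, activity_sig)
                   if r.variant == "wild-type"]
        table = build_comparison_table(results, reference="wild-type")
        assert table.shape[0] == 1

    def test_duplicate_entries_rejected(self, catalog, design, no_noise, activity_sig):
        results = [r for r in self._full_results(catalog, design, no_noise, activity_sig)
                   if r.variant == "wild-type"]
        with pytest.raises(UsageError):
            build_comparison_table(results + results[:1], reference="wild-type")

    def test_missing_reference_rejected(self, catalog, design, no_noise, activity_sig):
        results = [r for r in self._full_results(catalog, design, no_noise, activity_sig)
                   if r.variant == "D263K"]
        with pytest.raises(UsageError):
            build_comparison_table(results, reference="wild-type")
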