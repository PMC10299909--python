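import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmsel import synthetic
from pharmsel.binding import (
    SaturationModel,
    TwoSiteCompetitionModel,
    cheng_prusoff,
    eval_saturation,
    eval_two_site,
    fit_competition,
    fit_saturation,
)
from pharmsel.errors import DomainError, FitFailure, ValidationError


class TestEvalSaturation:
    def test_zero_concentration(self):
        m = SaturationModel(b_max=1000.0, p_kd=9.0)
        assert eval_saturation(m, 0.0) == 0.0

    def test_half_saturation_at_kd(self):
        m = SaturationModel(b_max=1000.0, p_kd=9.0)
        assert eval_saturation(m, 1e-9) == pytest.approx(500.0, rel=1e-12)

    def test_hand_substitution(self):
        # Bmax=1000, pKd=9, NS=1e6 signal/M, [A]=1 nM:
        # 1000*1e-9/(2e-9) + 1e6*1e-9 = 500.001
        m = SaturationModel(b_max=1000.0, p_kd=9.0, ns_slope=1e6)
        assert eval_saturation(m, 1e-9) == pytest.approx(500.001, rel=1e-12)

    def test_negative_concentration_rejected(self):
        m = SaturationModel(b_max=1.0, p_kd=9.0)
        with pytest.raises(DomainError):
            eval_saturation(m, -1e-9)


class TestFitSaturation:
    def _make(self, noise_sd=0.0, seed=0):
        return synthetic.generate_binding_curve(
            synthetic.BindingCurveSpec(
                mode="saturation", bmax=900.0, p_kd_radioligand=9.2, ns_slope=2e8,
                conc_grid=tuple(np.linspace(-10.5, -7.5, 8)),
                noise_sd=noise_sd, n_replicates=3, seed=seed,
            )
        )

    def test_noiseless_recovery(self):
        bs = self._make()
        total = bs.data[bs.data["series"] == "total"]
        ns = bs.data[bs.data["series"] == "nonspecific"]
        fit = fit_saturation(total, ns)
        assert fit.model.b_max == pytest.approx(900.0, rel=1e-6)
        assert fit.model.p_kd == pytest.approx(9.2, rel=1e-6)
        assert fit.model.ns_slope == pytest.approx(2e8, rel=1e-6)

    def test_recovery_under_noise(self):
        # noise 2% of Bmax, 8 concentrations, 3 replicates, 200 seeds
        errs = []
        for seed in range(200):
            bs = self._make(noise_sd=18.0, seed=seed)
            total = bs.data[bs.data["series"] == "total"]
            ns = bs.data[bs.data["series"] == "nonspecific"]
            errs.append(fit_saturation(total, ns).model.p_kd - 9.2)
        errs = np.asarray(errs)
        assert np.median(np.abs(errs)) < 0.1
        assert abs(np.median(errs)) < 0.02

    def test_flat_data_fails(self):
        bs = self._make()
        flat = bs.data[bs.data["series"] == "total"].copy()
        flat["signal"] = 500.0
        ns = bs.data[bs.data["series"] == "nonspecific"]
        with pytest.raises(FitFailure, match="dynamic range"):
            fit_saturation(flat, ns)

    def test_too_few_concentrations(self):
        bs = self._make()
        total = bs.data[bs.data["series"] == "total"]
        ns = bs.data[bs.data["series"] == "nonspecific"]
        with pytest.raises(ValidationError, match="4"):
            fit_saturation(total[total["log_conc_m"] < -10], ns)


class TestEvalTwoSite:
    def test_no_competitor_limit(self):
        m = TwoSiteCompetitionModel(
            top=100.0, bottom=10.0, log_ic50_high=-9.0, log_ic50_low=-6.0, fraction_high=0.4
        )
        assert eval_two_site(m, -30.0) == pytest.approx(100.0, rel=1e-12)

    def test_one_site_midpoint(self):
        m = TwoSiteCompetitionModel(
            top=100.0, bottom=20.0, log_ic50_high=-8.0, log_ic50_low=-8.0, fraction_high=1.0
        )
        assert eval_two_site(m, -8.0) == pytest.approx(60.0, rel=1e-12)

    def test_hand_evaluation(self):
        # top=100 bottom=20 lic1=-10 lic2=-7 f1=0.5 at log[B]=-8
        m = TwoSiteCompetitionModel(
            top=100.0, bottom=20.0, log_ic50_high=-10.0, log_ic50_low=-7.0, fraction_high=0.5
        )
        assert eval_two_site(m, -8.0) == pytest.approx(56.759675967596756, rel=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        top=st.floats(10.0, 1000.0),
        span=st.floats(1.0, 500.0),
        lic1=st.floats(-12.0, -5.0),
        dlic=st.floats(0.0, 5.0),
        f1=st.floats(0.0, 1.0),
    )
    def test_monotone_nonincreasing(self, top, span, lic1, dlic, f1):
        m = TwoSiteCompetitionModel(
            top=top, bottom=top - span, log_ic50_high=lic1,
            log_ic50_low=lic1 + dlic, fraction_high=f1,
        )
        grid = np.linspace(-14.0, -2.0, 60)
        y = eval_two_site(m, grid)
        assert (np.diff(y) <= 1e-9 * max(abs(top), 1.0)).all()


class TestFitCompetition:
    def test_noiseless_one_site_exact(self):
        bs = synthetic.generate_binding_curve(
            synthetic.BindingCurveSpec(
                mode="competition_one_site", top=100.0, bottom=5.0, p_ic50_high=8.2,
                conc_grid=tuple(np.linspace(-12.0, -4.0, 10)), noise_sd=0.0, seed=0,
            )
        )
        fit = fit_competition(bs, sites="one")
        assert fit.p_ic50_high == pytest.approx(8.2, abs=1e-6)

    def test_noiseless_two_site_recovery(self, two_site_spec):
        bs = synthetic.generate_binding_curve(two_site_spec)
        fit = fit_competition(bs, sites="two")
        m = fit.model
        assert m.top == pytest.approx(100.0, rel=1e-4)
        assert m.bottom == pytest.approx(0.0, abs=1e-4 * 100)
        assert -m.log_ic50_high == pytest.approx(9.0, rel=1e-4)
        assert -m.log_ic50_low == pytest.approx(6.0, rel=1e-4)
        assert m.fraction_high == pytest.approx(0.6, rel=1e-4)

    def test_auto_selects_one_site_when_sites_unresolvable(self):
        # two true sites only 0.3 log units apart cannot be resolved
        bs = synthetic.generate_binding_curve(
            synthetic.BindingCurveSpec(
                mode="competition_two_site", top=100.0, bottom=0.0,
                p_ic50_high=7.3, p_ic50_low=7.0, fraction_high=0.5,
                conc_grid=tuple(np.linspace(-11.0, -4.0, 12)), noise_sd=1.0, seed=4,
            )
        )
        fit = fit_competition(bs, sites="auto")
        assert fit.model_kind == "one_site"
        assert fit.alternative is not None and fit.alternative.model_kind == "two_site"

    def test_auto_selects_two_site_when_resolvable(self, two_site_spec):
        spec = dataclasses.replace(two_site_spec, noise_sd=1.0)
        fit = fit_competition(synthetic.generate_binding_curve(spec), sites="auto")
        assert fit.model_kind == "two_site"

    def test_round_trip_with_pki_conversion(self, two_site_spec):
        bs = synthetic.generate_binding_curve(two_site_spec)
        fit = fit_competition(bs, sites="two", radioligand_conc=2e-10, radioligand_kd=1e-10)
        expected_hi = cheng_prusoff(10.0**-9.0, 2e-10, 1e-10)
        assert fit.p_ki_high == pytest.approx(expected_hi, abs=1e-3)

    def test_degenerate_two_site_warns_or_collapses(self):
        bs = synthetic.generate_binding_curve(
            synthetic.BindingCurveSpec(
                mode="competition_one_site", top=100.0, bottom=0.0, p_ic50_high=8.0,
                conc_grid=tuple(np.linspace(-12.0, -4.0, 12)), noise_sd=0.0, seed=0,
            )
        )
        fit = fit_competition(bs, sites="two")
        pinned = any("pinned" in w for w in fit.warnings)
        collapsed = abs(fit.model.log_ic50_high - fit.model.log_ic50_low) < 0.05
        assert pinned or collapsed

    def test_too_few_concentrations(self, two_site_spec):
        spec = dataclasses.replace(two_site_spec, conc_grid=tuple(np.linspace(-10, -6, 5)))
        with pytest.raises(ValidationError, match="6"):
            fit_competition(synthetic.generate_binding_curve(spec))

    def test_flat_data_fails(self, two_site_spec):
        bs = synthetic.generate_binding_curve(two_site_spec)
        df = bs.data.copy()
        df["signal"] = 50.0
        with pytest.raises(FitFailure):
            fit_competition(df)


class TestChengPrusoff:
    def test_radioligand_at_kd_halves_ic50(self):
        # Ki = IC50/2
        assert cheng_prusoff(1e-8, 1e-10, 1e-10) == pytest.approx(-np.log10(5e-9), rel=1e-12)

    def test_vanishing_radioligand(self):
        assert cheng_prusoff(1e-8, 1e-16, 1e-10) == pytest.approx(8.0, abs=1e-5)

    def test_hand_arithmetic(self):
        # IC50=10 nM, [A*]=0.2 nM, Kd=0.1 nM -> Ki=10/3 nM
        assert cheng_prusoff(10e-9, 0.2e-9, 0.1e-9) == pytest.approx(8.477121254719663, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        for args in [(0.0, 1e-9, 1e-9), (1e-8, -1e-9, 1e-9), (1e-8, 1e-9, 0.0)]:
            with pytest.raises(DomainError):
                cheng_prusoff(*args)

    @settings(max_examples=50, deadline=None)
    @given(
        ic50=st.floats(1e-10, 1e-5), conc=st.floats(1e-12, 1e-7),
        kd=st.floats(1e-12, 1e-7), scale=st.floats(1e-3, 1e3),
    )
    def test_unit_consistency(self, ic50, conc, kd, scale):
        # rescaling all molar inputs by the same factor shifts pKi by -log10(scale)
        base = cheng_prusoff(ic50, conc, kd)
        scaled = cheng_prusoff(ic50 * scale, conc * scale, kd * scale)
        assert scaled == pytest.approx(base - np.log10(scale), abs=1e-9)
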