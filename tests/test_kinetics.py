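"""Closed-form two-compartment kinetics against independent oracles."""

import numpy as np
import pytest

from voripk.events import DoseEvent, EventDataset, ObservationEvent, SubjectRecord
from voripk.kinetics import (DoseRegimen, concentration, disposition,
                             predict_dataset, steady_state_metrics)
from voripk.params import IndividualParameters

from _oracles import ode_concentration


class TestDisposition:
    def test_micro_constants(self, typical_individual):
        d = disposition(typical_individual)
        assert d.k10 == pytest.approx(3.55 / 33.5, rel=1e-12)
        assert d.k10 == pytest.approx(0.10597, abs=1e-5)
        assert d.k12 == pytest.approx(52.8 / 33.5, rel=1e-12)
        assert d.k21 == pytest.approx(52.8 / 138.0, rel=1e-12)

    def test_hybrid_roots_and_terminal_half_life(self, typical_individual):
        d = disposition(typical_individual)
        assert d.beta == pytest.approx(0.01983, abs=1e-5)
        assert np.log(2) / d.beta == pytest.approx(34.96, abs=0.01)
        # root identities to tight relative tolerance
        assert d.alpha * d.beta == pytest.approx(d.k10 * d.k21, rel=1e-10)
        assert d.alpha + d.beta == pytest.approx(d.k10 + d.k12 + d.k21, rel=1e-10)
        assert d.alpha >= d.beta > 0

    def test_degenerate_q_rejected(self):
        with pytest.raises(ValueError):
            IndividualParameters(cl=3.55, vc=33.5, vp=138.0, q=0.0)


class TestConcentration:
    def test_no_doses_is_zero(self, typical_individual):
        assert concentration(typical_individual, [], 5.0) == 0.0

    def test_closed_form_matches_ode_oracle(self, typical_individual):
        """Mixed IV/oral regimen vs stiff ODE integration at random times."""
        rng = np.random.default_rng(2024)
        doses = [
            DoseEvent(0.0, 400.0, "iv_infusion", 2.0),
            DoseEvent(12.0, 200.0, "oral", None),
            DoseEvent(20.0, 150.0, "nasogastric", None),
            DoseEvent(26.0, 200.0, "iv_infusion", 0.5),
        ]
        ts = np.sort(rng.uniform(0.05, 72.0, size=50))
        cf = concentration(typical_individual, doses, ts)
        oc = ode_concentration(typical_individual, doses, ts)
        assert np.max(np.abs(cf - oc) / np.abs(oc)) < 1e-6

    def test_continuous_at_infusion_stop(self, typical_individual):
        doses = [DoseEvent(0.0, 200.0, "iv_infusion", 1.0)]
        eps = 1e-7
        lo = concentration(typical_individual, doses, 1.0 - eps)
        hi = concentration(typical_individual, doses, 1.0 + eps)
        assert hi == pytest.approx(lo, rel=1e-5)

    def test_single_dose_auc_equals_dose_over_cl(self, typical_individual):
        d = disposition(typical_individual)
        ts = np.linspace(0.0, 10 * np.log(2) / d.beta, 40001)
        c = concentration(typical_individual, [DoseEvent(0, 200, "iv_infusion", 1.0)], ts)
        auc = np.trapezoid(c, ts)
        assert auc == pytest.approx(200.0 / typical_individual.cl, rel=5e-3)

    def test_superposition_linearity(self, typical_individual):
        a = [DoseEvent(0.0, 200.0, "iv_infusion", 1.0),
             DoseEvent(24.0, 200.0, "iv_infusion", 1.0)]
        b = [DoseEvent(12.0, 100.0, "oral", None)]
        ts = np.array([0.5, 3.0, 12.5, 14.0, 25.0, 30.0])
        combined = concentration(typical_individual, a + b, ts)
        assert np.allclose(
            combined,
            concentration(typical_individual, a, ts)
            + concentration(typical_individual, b, ts), rtol=1e-12)

    def test_non_negative_everywhere(self, typical_individual):
        doses = [DoseEvent(0.0, 200.0, "oral", None)]
        ts = np.linspace(0, 48, 200)
        assert np.all(concentration(typical_individual, doses, ts) >= 0)


class TestSteadyState:
    def test_auc24_identity(self, typical_individual):
        met = steady_state_metrics(typical_individual, DoseRegimen(200.0, 12.0))
        assert met["auc24"] == pytest.approx(400.0 / 3.55, rel=1e-12)
        assert met["auc24"] == pytest.approx(112.68, abs=0.01)

    def test_half_life_conventions(self):
        ind = IndividualParameters(cl=3.78, vc=33.5, vp=138.0, q=52.8)
        met = steady_state_metrics(ind, DoseRegimen(200.0, 12.0))
        # monoexponential convention reproduces the per-group summary scale
        assert met["half_life_table3_convention"] == pytest.approx(6.14, abs=0.01)
        # the hybrid terminal half-life is far longer
        assert met["half_life_beta"] > 30.0

    @pytest.mark.parametrize("route", ["iv_infusion", "oral"])
    def test_ss_trough_matches_long_superposition(self, typical_individual, route):
        reg = DoseRegimen(200.0, 12.0, route=route)
        met = steady_state_metrics(typical_individual, reg)
        n = 60  # ~30 days, > 20 terminal half-lives of accumulation
        doses = [DoseEvent(12.0 * i, 200.0, route,
                           1.0 if route == "iv_infusion" else None)
                 for i in range(n)]
        cmin_long = concentration(typical_individual, doses, 12.0 * n)
        assert met["cmin"] == pytest.approx(cmin_long, rel=1e-3)

    def test_oral_auc_scaled_by_bioavailability(self, typical_individual):
        met = steady_state_metrics(typical_individual,
                                   DoseRegimen(200.0, 12.0, route="oral"))
        assert met["auc24"] == pytest.approx(0.835 * 400.0 / 3.55, rel=1e-12)


class TestPredictDataset:
    def _one_subject(self):
        doses = [DoseEvent(0.0, 200.0, "iv_infusion", 1.0),
                 DoseEvent(12.0, 200.0, "iv_infusion", 1.0)]
        obs = [ObservationEvent(t, 1.0) for t in (2.0, 11.5, 14.0)]
        return EventDataset(subjects=[SubjectRecord(
            id="A", doses=doses, observations=obs,
            covariates={0: {"QCRP": 73.6, "CLCR": 71.8, "CRRT": 0,
                            "PLT": 144.0, "PT": 15.0}})])

    def test_zero_etas_match_pointwise_concentration(self, published,
                                                     typical_individual):
        ds = self._one_subject()
        table = predict_dataset(published, ds)
        expect = concentration(typical_individual, ds.subjects[0].doses,
                               table["time"].to_numpy())
        assert np.allclose(table["pred"].to_numpy(), expect, rtol=1e-12)

    def test_empty_dataset_gives_empty_table(self, published):
        table = predict_dataset(published, EventDataset(subjects=[]))
        assert len(table) == 0

    def test_larger_cl_eta_lowers_steady_state_predictions(self, published):
        ds = self._one_subject()
        p1 = predict_dataset(published, ds, etas=np.array([[0.3, 0.0, 0.0]]))
        p2 = predict_dataset(published, ds, etas=np.array([[0.6, 0.0, 0.0]]))
        # troughs fall monotonically as clearance rises
        assert (p2["pred"].to_numpy()[1:] < p1["pred"].to_numpy()[1:]).all()
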