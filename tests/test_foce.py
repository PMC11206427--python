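"""FOCE objective and empirical-Bayes estimation against oracles."""

import math

import numpy as np
import pytest

from voripk.events import DoseEvent, EventDataset, ObservationEvent, SubjectRecord
from voripk.foce import eb_estimate, foce_ofv
from voripk.kinetics import concentration
from voripk.params import (IndividualParameters, OmegaMatrix, PopulationModel,
                           SigmaParams, ThetaVector)

from _oracles import quadrature_ofv

THETA = ThetaVector(cl_tv=3.55, vc=33.5, vp=138.0, q=52.8)
IV_DOSES = [DoseEvent(0.0, 200.0, "iv_infusion", 1.0)]
RICH_TIMES = [1.0, 2.0, 4.0, 6.0, 8.0, 12.0]


def _subject(times, y, sid="1"):
    return SubjectRecord(
        id=sid, doses=list(IV_DOSES),
        observations=[ObservationEvent(t, yy) for t, yy in zip(times, y)],
        covariates={0: {}})


def _individual(eta_cl):
    return IndividualParameters(cl=3.55 * math.exp(eta_cl), vc=33.5,
                                vp=138.0, q=52.8)


def _simulated_subject(eta_cl, noise_sd, seed=3):
    rng = np.random.default_rng(seed)
    y = np.array([concentration(_individual(eta_cl), IV_DOSES, t)
                  for t in RICH_TIMES])
    return _subject(RICH_TIMES, y + rng.normal(0, noise_sd, len(y)))


class TestEmpiricalBayes:
    def test_no_observations_gives_prior_mode(self):
        subj = SubjectRecord(id="1", doses=list(IV_DOSES), observations=[],
                             covariates={0: {}})
        model = PopulationModel(theta=THETA, omega=OmegaMatrix(0.5, 0.5, 0.5),
                                sigma=SigmaParams(0.1, 0.2))
        assert np.allclose(eb_estimate(subj, model), 0.0)

    def test_vanishing_omega_shrinks_eta_to_zero(self):
        subj = _simulated_subject(0.4, 0.05)
        for om, bound in ((0.3, 1.0), (0.01, 2e-3), (1e-4, 1e-6)):
            model = PopulationModel(theta=THETA, omega=OmegaMatrix(cl=om),
                                    sigma=SigmaParams(0.0, 0.2))
            eta = eb_estimate(subj, model)
            assert abs(eta[0]) < bound

    def test_recovers_known_eta_from_rich_noise_free_profile(self):
        subj = _simulated_subject(0.3, 0.0)
        model = PopulationModel(theta=THETA, omega=OmegaMatrix(cl=10.0),
                                sigma=SigmaParams(0.0, 1e-4))
        eta = eb_estimate(subj, model)
        # wide prior + tiny noise: posterior mode ~ generating eta
        assert eta[0] == pytest.approx(0.3, abs=1e-3)
        assert eta[1] == eta[2] == 0.0  # inactive dimensions untouched


class TestFoceOfv:
    def test_matches_quadrature_oracle_on_toy_subject(self):
        """Exact-Hessian Laplace vs adaptive quadrature, 1 eta, additive error."""
        subj = _simulated_subject(0.15, 0.2)
        om, sd = 0.1, 0.2
        model = PopulationModel(theta=THETA, omega=OmegaMatrix(cl=om),
                                sigma=SigmaParams(0.0, sd))
        res = foce_ofv(EventDataset(subjects=[subj]), model, hessian="exact")
        y = [o.concentration for o in subj.observations]
        exact = quadrature_ofv(y, RICH_TIMES, IV_DOSES, _individual, om, sd)
        assert res.ofv == pytest.approx(exact, rel=1e-3)
        # the Gauss-Newton FOCE-I default stays close to the full Laplace
        gn = foce_ofv(EventDataset(subjects=[subj]), model, hessian="gn")
        assert gn.ofv == pytest.approx(res.ofv, abs=0.05)

    def test_zero_omega_equals_exact_gaussian_m2ll(self):
        subj = _simulated_subject(0.0, 0.1)
        sd = 0.2
        model = PopulationModel(theta=THETA, omega=OmegaMatrix(),
                                sigma=SigmaParams(0.0, sd))
        res = foce_ofv(EventDataset(subjects=[subj]), model)
        y = np.array([o.concentration for o in subj.observations])
        pred = np.array([concentration(_individual(0.0), IV_DOSES, t)
                         for t in RICH_TIMES])
        closed = float(np.sum(np.log(2 * np.pi * sd**2) + (y - pred)**2 / sd**2))
        assert res.ofv == pytest.approx(closed, rel=1e-12)

    def test_duplicating_subjects_doubles_ofv(self):
        s1 = _simulated_subject(0.2, 0.1, seed=5)
        s2 = SubjectRecord(id="2", doses=s1.doses,
                           observations=s1.observations, covariates={0: {}})
        model = PopulationModel(theta=THETA, omega=OmegaMatrix(cl=0.4),
                                sigma=SigmaParams(0.089, 0.192))
        one = foce_ofv(EventDataset(subjects=[s1]), model).ofv
        two = foce_ofv(EventDataset(subjects=[s1, s2]), model).ofv
        assert two == pytest.approx(2.0 * one, rel=1e-9)

    def test_invariant_to_subject_order_and_time_origin(self):
        sa = _simulated_subject(0.2, 0.1, seed=5)
        sb = _simulated_subject(-0.3, 0.1, seed=6)
        sb.id = "2"
        model = PopulationModel(theta=THETA, omega=OmegaMatrix(cl=0.4),
                                sigma=SigmaParams(0.089, 0.192))
        o_ab = foce_ofv(EventDataset(subjects=[sa, sb]), model).ofv
        o_ba = foce_ofv(EventDataset(subjects=[sb, sa]), model).ofv
        assert o_ab == pytest.approx(o_ba, rel=1e-12)
        # shift one subject's clock uniformly: likelihood unchanged
        shift = 24.0
        sc = SubjectRecord(
            id="1",
            doses=[DoseEvent(d.time + shift, d.amount, d.route, d.duration)
                   for d in sa.doses],
            observations=[ObservationEvent(o.time + shift, o.concentration)
                          for o in sa.observations],
            covariates={0: {}})
        o_shift = foce_ofv(EventDataset(subjects=[sc]), model).ofv
        o_orig = foce_ofv(EventDataset(subjects=[sa]), model).ofv
        assert o_shift == pytest.approx(o_orig, rel=1e-9)

    def test_ofv_prefers_generating_eta_scale(self):
        """Sanity: OFV at the generating omega beats a far-off omega."""
        subs = [_simulated_subject(e, 0.05, seed=i)
                for i, e in enumerate(np.random.default_rng(0).normal(0, 0.5, 12))]
        for i, s in enumerate(subs):
            s.id = str(i)
        ds = EventDataset(subjects=subs)
        sig = SigmaParams(0.0, 0.05)
        ofv_good = foce_ofv(ds, PopulationModel(
            theta=THETA, omega=OmegaMatrix(cl=0.5), sigma=sig)).ofv
        ofv_bad = foce_ofv(ds, PopulationModel(
            theta=THETA, omega=OmegaMatrix(cl=0.05), sigma=sig)).ofv
        assert ofv_good < ofv_bad
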