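"""Population model fitting: the PopPKModel / PopPKResults pair.

``PopPKModel`` binds an event dataset to a model specification (a
:class:`~voripk.params.PopulationModel` used both as structure and starting
values).  ``fit()`` maximises the FOCE marginal likelihood over an
unconstrained transformed parameter space (log for positive parameters,
logit for bioavailability, raw for signed power exponents) and returns a
``PopPKResults`` carrying estimates, relative standard errors, the OFV,
empirical-Bayes etas and diagnostics hooks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .events import EventDataset
from .foce import FoceResult, eb_estimate_all, foce_ofv
from .kinetics import CompiledDesign, predict_dataset
from .params import (CovariateEffect, OmegaMatrix, PopulationModel,
                     SigmaParams, ThetaVector, published_model)

__all__ = ["PopPKModel", "PopPKResults", "FitResult"]

_log = logging.getLogger(__name__)

_BOUND = 20.0  # clip on the unconstrained scale


def _logit(p):
    return math.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + math.exp(-max(min(x, _BOUND), -_BOUND)))


def _bexp(x):
    return math.exp(max(min(x, _BOUND), -_BOUND))


class ParameterTransform:
    """Maps a PopulationModel to/from an unconstrained parameter vector."""

    def __init__(self, template: PopulationModel, fixed: set[str]):
        self.template = template
        names, kinds = [], []
        for nm in ("cl_tv", "vc", "vp", "q", "ka"):
            names.append(nm); kinds.append("log")
        names.append("f_oral"); kinds.append("logit")
        for eff in template.theta.cov_effects:
            names.append(f"beta_{eff.covariate}")
            kinds.append("logfactor" if eff.form == "factor" else "raw")
        for nm, val in (("omega_cl", template.omega.cl),
                        ("omega_vc", template.omega.vc),
                        ("omega_vp", template.omega.vp)):
            names.append(nm); kinds.append("log")
            if val == 0:
                fixed = fixed | {nm}
        for nm, val in (("sigma_prop", template.sigma.prop_cv),
                        ("sigma_add", template.sigma.add_sd)):
            names.append(nm); kinds.append("log")
            if val == 0:
                fixed = fixed | {nm}
        self.names = names
        self.kinds = dict(zip(names, kinds))
        self.fixed = set(fixed) | {"ka"}
        self.free = [n for n in names if n not in self.fixed]

    # -- natural-scale dict <-> model ------------------------------------
    def to_dict(self, model: PopulationModel) -> dict[str, float]:
        d = {nm: getattr(model.theta, nm)
             for nm in ("cl_tv", "vc", "vp", "q", "ka", "f_oral")}
        for eff in model.theta.cov_effects:
            d[f"beta_{eff.covariate}"] = eff.coefficient
        d.update(omega_cl=model.omega.cl, omega_vc=model.omega.vc,
                 omega_vp=model.omega.vp,
                 sigma_prop=model.sigma.prop_cv, sigma_add=model.sigma.add_sd)
        return d

    def to_model(self, d: dict[str, float]) -> PopulationModel:
        effs = tuple(
            replace(eff, coefficient=d[f"beta_{eff.covariate}"])
            for eff in self.template.theta.cov_effects)
        theta = replace(self.template.theta,
                        cl_tv=d["cl_tv"], vc=d["vc"], vp=d["vp"], q=d["q"],
                        ka=d["ka"], f_oral=d["f_oral"], cov_effects=effs)
        return replace(self.template, theta=theta,
                       omega=OmegaMatrix(d["omega_cl"], d["omega_vc"], d["omega_vp"]),
                       sigma=SigmaParams(d["sigma_prop"], d["sigma_add"]))

    # -- unconstrained vector --------------------------------------------
    def pack(self, model: PopulationModel) -> np.ndarray:
        d = self.to_dict(model)
        x = []
        for nm in self.free:
            v = d[nm]
            k = self.kinds[nm]
            if k in ("log", "logfactor"):
                x.append(math.log(v))
            elif k == "logit":
                x.append(_logit(v))
            else:
                x.append(v)
        return np.asarray(x, dtype=float)

    def unpack(self, x: np.ndarray, base: PopulationModel | None = None
               ) -> PopulationModel:
        d = self.to_dict(base or self.template)
        for nm, xi in zip(self.free, x):
            k = self.kinds[nm]
            if k in ("log", "logfactor"):
                d[nm] = _bexp(xi)
            elif k == "logit":
                d[nm] = _expit(xi)
            else:
                d[nm] = float(np.clip(xi, -_BOUND, _BOUND))
        return self.to_model(d)

    def natural_se(self, d: dict[str, float], se_x: np.ndarray) -> dict[str, float]:
        """Delta-method SEs on the natural scale for the free parameters."""
        out = {}
        for nm, s in zip(self.free, se_x):
            k = self.kinds[nm]
            v = d[nm]
            if k in ("log", "logfactor"):
                out[nm] = abs(v) * s
            elif k == "logit":
                out[nm] = v * (1.0 - v) * s
            else:
                out[nm] = s
        return out


@dataclass
class PopPKResults:
    """Estimation results: estimates, uncertainty, OFV and diagnostics."""

    model: "PopPKModel"
    params: PopulationModel
    ofv: float
    eb_etas: np.ndarray
    converged: bool
    n_function_evals: int
    se: dict[str, float] = field(default_factory=dict)
    rse: dict[str, float] = field(default_factory=dict)
    trace: list = field(default_factory=list)
    message: str = ""

    @property
    def param_dict(self) -> dict[str, float]:
        return self.model.transform.to_dict(self.params)

    @property
    def eb_etas_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.eb_etas, columns=["eta_CL", "eta_VC", "eta_VP"],
                            index=self.model.design.subject_ids)

    def predict(self, individual: bool = False) -> pd.DataFrame:
        """PRED (typical) or IPRED (empirical-Bayes) prediction table."""
        etas = self.eb_etas if individual else None
        return predict_dataset(self.params, self.model.dataset, etas)

    def gof(self) -> pd.DataFrame:
        from .diagnostics import gof_table
        return gof_table(self)

    def cwres(self) -> np.ndarray:
        from .diagnostics import cwres
        return cwres(self)

    def bootstrap(self, n_resamples: int = 1000, seed: int = 0, **fit_kw):
        from .diagnostics import bootstrap
        return bootstrap(self.model.dataset, self.params, n_resamples=n_resamples,
                         seed=seed, fixed=self.model.fixed, **fit_kw)

    def vpc(self, n_sim: int = 1000, bins: int = 8, seed: int = 0):
        from .diagnostics import pcvpc
        return pcvpc(self.model.dataset, self.params, n_sim=n_sim,
                     bins=bins, seed=seed)

    def summary(self) -> str:
        tf = self.model.transform
        d = self.param_dict
        lines = [
            "Population PK fit (two-compartment, FOCE)",
            "=" * 58,
            f"subjects: {self.model.design.n_subjects}"
            f"   observations: {self.model.design.n_obs}"
            f"   OFV: {self.ofv:.3f}",
            f"converged: {self.converged}   function evals: {self.n_function_evals}",
            "-" * 58,
            f"{'parameter':<14}{'estimate':>12}{'RSE%':>10}",
        ]
        display = {
            "cl_tv": "CL (L/h)", "vc": "Vc (L)", "vp": "Vp (L)",
            "q": "Q (L/h)", "ka": "Ka (1/h)", "f_oral": "F",
            "omega_cl": "omega_CL", "omega_vc": "omega_Vc",
            "omega_vp": "omega_Vp", "sigma_prop": "sigma_prop",
            "sigma_add": "sigma_add (mg/L)",
        }
        for nm in tf.names:
            label = display.get(nm, nm)
            fixed = " (fixed)" if nm in tf.fixed else ""
            rse = f"{self.rse[nm]:>9.1f}" if nm in self.rse else "        -"
            val = d[nm]
            if nm.startswith("omega"):
                label += " (%CV)"
                val = 100.0 * val
            lines.append(f"{label:<14}{val:>12.4g}{rse:>10}{fixed}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<PopPKResults OFV={self.ofv:.3f} "
                f"converged={self.converged}>")


#: alias used in prose/tests: a fit result
FitResult = PopPKResults


class PopPKModel:
    """Two-compartment population PK model bound to an event dataset.

    Parameters
    ----------
    dataset : EventDataset
    start : PopulationModel, optional
        Structure (covariate effects, error model) and starting values;
        defaults to the published final model.
    fixed : iterable of parameter names to hold fixed (ka always is).
    """

    def __init__(self, dataset: EventDataset,
                 start: PopulationModel | None = None,
                 fixed=(), include_blq: bool = False):
        if len(dataset) == 0:
            raise ValueError("dataset is empty")
        self.dataset = dataset
        self.start = start or published_model()
        self.fixed = set(fixed) | {"ka"}
        if dataset.iv_only and "f_oral" not in self.fixed:
            _log.warning("IV-only dataset: bioavailability F is not "
                         "identifiable and will be fixed")
            self.fixed.add("f_oral")
        self.design = CompiledDesign(dataset, include_blq=include_blq)
        n_blq = dataset.n_blq
        if n_blq and not include_blq:
            _log.info("excluding %d BLQ observation(s) from estimation", n_blq)
        self.transform = ParameterTransform(self.start, self.fixed)
        self._eta_cache: np.ndarray | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "PopPKModel":
        from .io import read_dataset
        return cls(read_dataset(df), **kw)

    @classmethod
    def from_csv(cls, path, **kw) -> "PopPKModel":
        from .io import read_dataset
        return cls(read_dataset(path), **kw)

    # ------------------------------------------------------------------
    def ofv(self, model: PopulationModel | None = None,
            hessian: str = "gn") -> float:
        """FOCE OFV of the dataset under ``model`` (default: start values)."""
        return foce_ofv(self.design, model or self.start, hessian=hessian).ofv

    def eb_etas(self, model: PopulationModel | None = None) -> np.ndarray:
        etas, _ = eb_estimate_all(self.design, model or self.start)
        return etas

    def _objective(self, counter: list):
        tf = self.transform

        def fun(x: np.ndarray) -> float:
            counter[0] += 1
            try:
                m = tf.unpack(x)
                res = foce_ofv(self.design, m, etas0=self._eta_cache)
            except (ValueError, FloatingPointError, np.linalg.LinAlgError):
                return 1e10
            if not np.isfinite(res.ofv):
                return 1e10
            self._eta_cache = res.etas
            return res.ofv

        return fun

    def fit(self, start: PopulationModel | None = None, method: str = "lbfgs",
            maxiter: int = 200, compute_rse: bool = True,
            verbose: bool = False) -> PopPKResults:
        """Estimate population parameters by FOCE.

        ``method``: ``"lbfgs"`` (finite-difference L-BFGS-B, default),
        ``"powell"`` or ``"neldermead"``.  Convergence is reported when the
        optimiser terminates normally; otherwise the best iterate is
        returned with ``converged=False``.
        """
        tf = self.transform
        start = start or self.start
        x0 = tf.pack(start)
        counter = [0]
        fun = self._objective(counter)
        trace: list[tuple[int, float]] = []
        best = {"x": x0.copy(), "f": fun(x0)}
        trace.append((counter[0], best["f"]))

        def wrapped(x):
            f = fun(x)
            if f < best["f"]:
                best["f"], best["x"] = f, x.copy()
                trace.append((counter[0], f))
                if verbose:
                    print(f"eval {counter[0]:5d}  OFV {f:.4f}")
            return f

        if method == "lbfgs":
            res = optimize.minimize(
                wrapped, x0, method="L-BFGS-B",
                options={"eps": 1e-4, "maxiter": maxiter, "ftol": 1e-10,
                         "gtol": 1e-5, "maxcor": 20})
        elif method == "powell":
            res = optimize.minimize(
                wrapped, x0, method="Powell",
                options={"maxiter": maxiter, "xtol": 1e-6, "ftol": 1e-8})
        elif method == "neldermead":
            res = optimize.minimize(
                wrapped, x0, method="Nelder-Mead",
                options={"maxiter": maxiter * len(x0), "fatol": 1e-6,
                         "xatol": 1e-6, "adaptive": True})
        else:
            raise ValueError(f"unknown method {method!r}")

        x_hat = best["x"] if best["f"] <= res.fun else np.asarray(res.x)
        model_hat = tf.unpack(x_hat)
        final = foce_ofv(self.design, model_hat, etas0=self._eta_cache)
        out = PopPKResults(
            model=self, params=model_hat, ofv=final.ofv,
            eb_etas=final.etas, converged=bool(res.success),
            n_function_evals=counter[0], trace=trace,
            message=str(res.message),
        )
        if compute_rse:
            try:
                se_x = self._se_transformed(fun, x_hat)
                d = tf.to_dict(model_hat)
                out.se = tf.natural_se(d, se_x)
                out.rse = {nm: (100.0 * s / abs(d[nm]) if d[nm] else np.inf)
                           for nm, s in out.se.items()}
            except (np.linalg.LinAlgError, FloatingPointError) as exc:
                _log.warning("RSE computation failed: %s", exc)
        return out

    def _se_transformed(self, fun, x_hat: np.ndarray,
                        step: float = 1e-3) -> np.ndarray:
        """SEs on the unconstrained scale from a central-difference Hessian.

        OFV = -2 log L, so the parameter covariance is 2 * H^-1.
        """
        n = len(x_hat)
        H = np.zeros((n, n))
        f0 = fun(x_hat)
        fp = np.zeros(n); fm = np.zeros(n)
        for i in range(n):
            xp = x_hat.copy(); xp[i] += step
            xm = x_hat.copy(); xm[i] -= step
            fp[i], fm[i] = fun(xp), fun(xm)
            H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / step ** 2
        for i in range(n):
            for j in range(i + 1, n):
                xpp = x_hat.copy(); xpp[[i, j]] += step
                xmm = x_hat.copy(); xmm[[i, j]] -= step
                H[i, j] = H[j, i] = (
                    fun(xpp) - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j]
                    + fun(xmm)) / (2.0 * step ** 2)
        # covariance of the estimates; fall back to pseudo-inverse if the
        # numerical Hessian is not positive definite
        try:
            cov = 2.0 * np.linalg.inv(H)
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError("non-PD Hessian")
        except np.linalg.LinAlgError:
            _log.warning("Hessian not positive definite; using pseudo-inverse")
            cov = 2.0 * np.linalg.pinv(H)
        return np.sqrt(np.abs(np.diag(cov)))
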