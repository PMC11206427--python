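"""Parameter containers for the voriconazole population PK model.

The model is a two-compartment disposition model with linear elimination,
first-order absorption (Ka fixed) for enteral doses, lognormal
inter-individual variability and a combined (proportional + additive)
residual-error model.  Clearance carries a multiplicative covariate model:
power terms for continuous covariates (normalised to a reference value) and
a categorical multiplier for CRRT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import math

import numpy as np

__all__ = [
    "CovariateEffect",
    "ThetaVector",
    "OmegaMatrix",
    "SigmaParams",
    "IndividualParameters",
    "PopulationModel",
    "published_model",
    "individual_clearance",
    "ETA_NAMES",
]

#: order of the random-effect dimensions everywhere in the package
ETA_NAMES = ("CL", "VC", "VP")


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate term on a structural parameter.

    ``power`` form evaluates ``(x / reference) ** coefficient`` and is used
    for continuous covariates; ``factor`` form evaluates
    ``coefficient ** x`` for a 0/1 flag (so the multiplier is ``coefficient``
    when the flag is on and 1 otherwise).  Exponents are stored *signed*:
    a negative exponent means the parameter falls as the covariate rises.
    """

    covariate: str
    form: str  # "power" | "factor"
    coefficient: float
    reference: float | None = None
    parameter: str = "CL"

    def __post_init__(self) -> None:
        if self.form not in ("power", "factor"):
            raise ValueError(f"unknown covariate-effect form {self.form!r}")
        if self.form == "power":
            if self.reference is None or self.reference <= 0:
                raise ValueError(
                    f"power effect on {self.covariate} requires reference > 0"
                )
        else:
            if self.coefficient <= 0:
                raise ValueError(
                    f"factor effect on {self.covariate} requires coefficient > 0"
                )

    def evaluate(self, value):
        """Multiplier contributed by this effect at covariate ``value``.

        Accepts scalars or arrays.  Continuous covariates must be strictly
        positive (they enter through a power of a ratio).
        """
        value = np.asarray(value, dtype=float)
        if self.form == "power":
            if np.any(value <= 0):
                raise ValueError(
                    f"non-positive value for covariate {self.covariate!r}"
                )
            return (value / self.reference) ** self.coefficient
        if np.any((value != 0) & (value != 1)):
            raise ValueError(
                f"categorical covariate {self.covariate!r} must be 0/1"
            )
        return self.coefficient ** value


@dataclass(frozen=True)
class ThetaVector:
    """Typical (population) structural parameters.

    Units: clearances L/h, volumes L, ka 1/h, ``f_oral`` dimensionless.
    ``ka`` is fixed by convention (literature value, not estimated) and
    ``f_oral`` is shared by oral and nasogastric administration.
    """

    cl_tv: float
    vc: float
    vp: float
    q: float
    ka: float = 1.2
    f_oral: float = 1.0
    cov_effects: tuple[CovariateEffect, ...] = ()

    def __post_init__(self) -> None:
        for name in ("cl_tv", "vc", "vp", "q", "ka"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.f_oral <= 1):
            raise ValueError("f_oral must lie in (0, 1]")
        object.__setattr__(self, "cov_effects", tuple(self.cov_effects))

    def covariate_multiplier(self, covs: Mapping[str, float]):
        """Product of all covariate effects on CL for one covariate vector."""
        mult = 1.0
        for eff in self.cov_effects:
            if eff.covariate not in covs:
                raise KeyError(f"covariate {eff.covariate!r} missing")
            mult = mult * eff.evaluate(covs[eff.covariate])
        return mult


def individual_clearance(theta: ThetaVector, covs: Mapping[str, float],
                         eta_cl: float = 0.0) -> float:
    """Individual clearance (L/h): typical value x covariate model x exp(eta)."""
    cl = theta.cl_tv * theta.covariate_multiplier(covs) * math.exp(eta_cl)
    return float(cl)


@dataclass(frozen=True)
class OmegaMatrix:
    """Diagonal inter-individual variance matrix (CL, Vc, Vp).

    Stored as standard deviations ``omega`` (lognormal scale); reported
    externally as %CV = 100 x omega.  The inter-compartmental clearance Q
    carries no random effect.
    """

    cl: float = 0.0
    vc: float = 0.0
    vp: float = 0.0

    def __post_init__(self) -> None:
        if min(self.cl, self.vc, self.vp) < 0:
            raise ValueError("omega standard deviations must be >= 0")

    @property
    def sd(self) -> np.ndarray:
        return np.array([self.cl, self.vc, self.vp], dtype=float)

    @property
    def variances(self) -> np.ndarray:
        return self.sd ** 2

    @property
    def cv_percent(self) -> np.ndarray:
        return 100.0 * self.sd

    @property
    def active(self) -> np.ndarray:
        """Boolean mask of dimensions with non-zero variability."""
        return self.sd > 0


@dataclass(frozen=True)
class SigmaParams:
    """Combined residual-error model  y = f (1 + eps_p) + eps_a.

    ``prop_cv`` is the proportional SD (dimensionless), ``add_sd`` the
    additive SD in mg/L.
    """

    prop_cv: float
    add_sd: float

    def __post_init__(self) -> None:
        if self.prop_cv < 0 or self.add_sd < 0:
            raise ValueError("error SDs must be >= 0")
        if self.prop_cv == 0 and self.add_sd == 0:
            raise ValueError("at least one residual-error component must be > 0")

    def variance(self, c_pred):
        """Residual variance (mg/L)^2 at predicted concentration ``c_pred``."""
        c_pred = np.asarray(c_pred, dtype=float)
        return (c_pred * self.prop_cv) ** 2 + self.add_sd ** 2


@dataclass(frozen=True)
class IndividualParameters:
    """Realised kinetic parameters for one subject (after covariates + etas)."""

    cl: float
    vc: float
    vp: float
    q: float
    ka: float = 1.2
    f: float = 1.0
    eta: tuple[float, ...] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("cl", "vc", "vp", "q", "ka"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class PopulationModel:
    """Full population model: fixed effects, IIV, residual error, fixed masks."""

    theta: ThetaVector
    omega: OmegaMatrix
    sigma: SigmaParams
    #: parameters excluded from estimation (ka always; f when data are IV-only)
    fixed: tuple[str, ...] = ("ka",)

    def individual(self, covs: Mapping[str, float],
                   eta: Sequence[float] = (0.0, 0.0, 0.0),
                   route: str = "iv_infusion") -> IndividualParameters:
        eta = tuple(float(e) for e in eta)
        t = self.theta
        return IndividualParameters(
            cl=individual_clearance(t, covs, eta[0]),
            vc=t.vc * math.exp(eta[1]),
            vp=t.vp * math.exp(eta[2]),
            q=t.q,
            ka=t.ka,
            f=1.0 if route == "iv_infusion" else t.f_oral,
            eta=eta,
        )

    def with_theta(self, **kw) -> "PopulationModel":
        return replace(self, theta=replace(self.theta, **kw))


# Published final-model constants (reference normalisers are the printed
# equation values, which differ slightly from the cohort medians).
REFERENCE_COVARIATES = {
    "QCRP": 73.6,   # mg/L
    "CLCR": 71.8,   # mL/min
    "PLT": 144.0,   # 10^9/L
    "PT": 15.0,     # s
    "CRRT": 0.0,
}


def final_covariate_effects() -> tuple[CovariateEffect, ...]:
    """The published covariate model on clearance (signed exponents)."""
    return (
        CovariateEffect("QCRP", "power", -0.142, 73.6),
        CovariateEffect("CLCR", "power", 0.218, 71.8),
        CovariateEffect("CRRT", "factor", 1.46),
        CovariateEffect("PLT", "power", 0.166, 144.0),
        CovariateEffect("PT", "power", -0.875, 15.0),
    )


def published_model() -> PopulationModel:
    """Final published population model (point estimates).

    IIV %CV values are interpreted directly as 100 x omega (common
    pharmacometric reporting at these magnitudes); the lognormal-exact
    transform sqrt(exp(omega^2)-1) is available via
    :func:`cv_to_omega` for callers who prefer it.
    """
    theta = ThetaVector(
        cl_tv=3.55, vc=33.5, vp=138.0, q=52.8, ka=1.2, f_oral=0.835,
        cov_effects=final_covariate_effects(),
    )
    omega = OmegaMatrix(cl=0.498, vc=0.667, vp=0.817)
    sigma = SigmaParams(prop_cv=0.089, add_sd=0.192)
    return PopulationModel(theta=theta, omega=omega, sigma=sigma)


def cv_to_omega(cv_percent: float, exact: bool = False) -> float:
    """Convert a reported %CV to a lognormal SD omega.

    Default is the direct convention omega = CV/100; ``exact=True`` applies
    the lognormal-exact transform omega = sqrt(log(1 + (CV/100)^2)).
    """
    cv = cv_percent / 100.0
    if exact:
        return math.sqrt(math.log1p(cv * cv))
    return cv
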