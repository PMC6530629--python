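"""Closed-form survival models.

Every model is written on the negative-log-survival scale
(-ln S, "lethal lesions per nucleus") and exponentiated only at the
boundary: mixture survival and targeted x non-targeted products are
accumulated with ``logaddexp`` so that a subpopulation whose survival
underflows in linear space (e.g. -ln S ~ 90 at 10 Gy for a very
radiosensitive bulk) still contributes correctly.

Models
------
linear-quadratic (LQ)    -ln S = alpha*D + beta*D^2
microdosimetric-kinetic  -ln S = (alpha0 + z*beta0)*D + beta0*D^2,
  targeted effect (TE)      z = y_D / (rho * pi * r^2)  [Gy]
two-population mixture   S = (1-f)*S_PC + f*S_CSC
non-targeted effect      -ln S_NT = delta*(1-e^-X)*e^-X
combined                 S = S_T * S_NT
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .params import (
    CombinedModel,
    IMKParameters,
    LQParameters,
    MicrodosimetricSpec,
    MixtureModel,
    NTEParameters,
)

__all__ = [
    "SurvivalPrediction",
    "microdosimetric_factor",
    "lq_log_survival",
    "imk_te_log_survival",
    "mixture_log_survival",
    "mixture_survival",
    "nte_log_survival",
    "combined_te_nte_survival",
    "lethal_lesions_per_dose",
    "model_log_survival",
]

# Unit conversions pinned in one place.
KEV_TO_J = 1.602176634e-16  # exact since SI 2019
UM_TO_M = 1.0e-6
G_CM3_TO_KG_M3 = 1.0e3


@dataclass(frozen=True)
class SurvivalPrediction:
    """Survival at one dose or a dose grid.

    ``surviving_fraction == exp(-neg_log_survival)`` by construction.
    """

    dose: Union[float, np.ndarray]
    surviving_fraction: Union[float, np.ndarray]
    neg_log_survival: Union[float, np.ndarray]

    @classmethod
    def from_neg_log(cls, dose, neg_log_survival) -> "SurvivalPrediction":
        nls = np.asarray(neg_log_survival, dtype=float)
        sf = np.exp(-nls)
        if np.ndim(dose) == 0:
            return cls(float(dose), float(sf), float(nls))
        return cls(np.asarray(dose, dtype=float), sf, nls)


def _as_dose(dose):
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0) or np.any(~np.isfinite(d)):
        raise ValueError("dose must be finite and >= 0 Gy")
    return d


def _maybe_scalar(value, template):
    return float(value) if np.ndim(template) == 0 else value


def microdosimetric_factor(spec: MicrodosimetricSpec) -> float:
    """Specific-energy conversion factor y_D / (rho * pi * r^2) in Gy.

    ``spec.site_diameter_um`` is the site *diameter*; the formula uses the
    radius r = diameter / 2, which is what reproduces the canonical
    0.954 Gy for y_D = 4.68 keV/um in a 1 um water site.
    """
    y_si = spec.y_d * KEV_TO_J / UM_TO_M  # J/m along the track
    radius_m = 0.5 * spec.site_diameter_um * UM_TO_M
    mass_per_length = spec.rho * G_CM3_TO_KG_M3 * math.pi * radius_m**2  # kg/m
    return y_si / mass_per_length  # J/kg = Gy


def lq_log_survival(params: LQParameters, dose):
    """-ln S of the linear-quadratic model: alpha*D + beta*D^2."""
    d = _as_dose(dose)
    return _maybe_scalar(params.alpha * d + params.beta * d**2, dose)


def imk_te_log_survival(params: IMKParameters, spec: MicrodosimetricSpec, dose):
    """-ln S of the microdosimetric-kinetic targeted-effect model.

    (alpha0 + z*beta0)*D + beta0*D^2 with z the specific-energy factor.
    """
    d = _as_dose(dose)
    z = microdosimetric_factor(spec)
    nls = (params.alpha0 + z * params.beta0) * d + params.beta0 * d**2
    return _maybe_scalar(nls, dose)


def mixture_log_survival(model: MixtureModel, spec: MicrodosimetricSpec, dose):
    """ln S of the PC/CSC mixture, computed stably in log space.

    ln S = logaddexp(ln(1-f) + ln S_PC, ln f + ln S_CSC); a weight of zero
    enters as -inf and drops out exactly.
    """
    nls_pc = np.asarray(imk_te_log_survival(model.pc, spec, dose))
    nls_csc = np.asarray(imk_te_log_survival(model.csc, spec, dose))
    with np.errstate(divide="ignore"):
        log_w_pc = np.log(model.f_pc)
        log_w_csc = np.log(model.f_csc)
    # normalising by the log weight sum (= ln 1 up to rounding) makes
    # S(0) = 1 exact instead of off by ~1e-18
    log_s = np.logaddexp(log_w_pc - nls_pc, log_w_csc - nls_csc) - np.logaddexp(
        log_w_pc, log_w_csc
    )
    return _maybe_scalar(log_s, dose)


def mixture_survival(
    model: MixtureModel, spec: MicrodosimetricSpec, dose
) -> SurvivalPrediction:
    """Mixture survival S(D) = (1-f_csc) S_PC(D) + f_csc S_CSC(D)."""
    return SurvivalPrediction.from_neg_log(dose, -np.asarray(mixture_log_survival(model, spec, dose)))


def nte_log_survival(params: NTEParameters, dose):
    """-ln S of the non-targeted (bystander) term.

    X(D) = (alpha_b + gamma*beta_b)*D + beta_b*D^2,
    -ln S_NT = delta * (1 - e^-X) * e^-X.

    Vanishes at D = 0 and as D -> inf, with maximum delta/4 where
    e^-X = 1/2.
    """
    d = _as_dose(dose)
    x = (params.alpha_b + params.gamma * params.beta_b) * d + params.beta_b * d**2
    u = np.exp(-x)
    return _maybe_scalar(params.delta * (1.0 - u) * u, dose)


def combined_te_nte_survival(
    te: Union[IMKParameters, MixtureModel],
    nte: NTEParameters,
    spec: MicrodosimetricSpec,
    dose,
) -> SurvivalPrediction:
    """S = S_T * S_NT: targeted and non-targeted log-survivals add."""
    if isinstance(te, MixtureModel):
        nls_te = -np.asarray(mixture_log_survival(te, spec, dose))
    else:
        nls_te = np.asarray(imk_te_log_survival(te, spec, dose))
    nls = nls_te + np.asarray(nte_log_survival(nte, dose))
    return SurvivalPrediction.from_neg_log(dose, nls)


def lethal_lesions_per_dose(prediction: SurvivalPrediction):
    """(-ln S)/D in Gy^-1, the per-gray effective lethality.

    Natural-log convention.  Undefined at D = 0: raises rather than
    silently returning the limit.
    """
    d = np.asarray(prediction.dose, dtype=float)
    if np.any(d <= 0):
        raise ValueError("lethal lesions per dose is undefined at dose <= 0")
    return _maybe_scalar(np.asarray(prediction.neg_log_survival) / d, prediction.dose)


def model_log_survival(model, spec: MicrodosimetricSpec | None, dose):
    """ln S for any supported parameter object (dispatch helper)."""
    if isinstance(model, LQParameters):
        return -np.asarray(lq_log_survival(model, dose))
    if isinstance(model, MixtureModel):
        if spec is None:
            raise ValueError("mixture model requires a MicrodosimetricSpec")
        return np.asarray(mixture_log_survival(model, spec, dose))
    if isinstance(model, IMKParameters):
        if spec is None:
            raise ValueError("IMK model requires a MicrodosimetricSpec")
        return -np.asarray(imk_te_log_survival(model, spec, dose))
    if isinstance(model, CombinedModel):
        if spec is None:
            raise ValueError("combined model requires a MicrodosimetricSpec")
        pred = combined_te_nte_survival(model.te, model.nte, spec, dose)
        return -np.asarray(pred.neg_log_survival)
    raise TypeError(f"unsupported model object: {type(model).__name__}")
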