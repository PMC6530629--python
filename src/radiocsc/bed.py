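"""Alpha/beta ratios and biologically effective dose (BED).

BED = n*d*(1 + d/(alpha/beta)) compares fractionation regimens on a
common biological scale.  For the microdosimetric-kinetic targeted-
effect model the ratio is alpha0/beta0 + z with z the specific-energy
factor, so it is always at least z.  A zero quadratic coefficient gives
an infinite ratio, represented explicitly as ``math.inf`` (BED then
equals the physical dose n*d).

For the two-population mixture no pooled alpha/beta exists; ratios and
BEDs are reported per subpopulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .core import microdosimetric_factor
from .params import IMKParameters, LQParameters, MicrodosimetricSpec, MixtureModel

__all__ = [
    "FractionationRegimen",
    "BEDResult",
    "alpha_beta_lq",
    "alpha_beta_imk",
    "bed",
    "bed_report",
]


@dataclass(frozen=True)
class FractionationRegimen:
    """n fractions of d Gy each."""

    n_fractions: int
    dose_per_fraction: float

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError(f"n_fractions must be >= 1, got {self.n_fractions!r}")
        if not math.isfinite(self.dose_per_fraction) or self.dose_per_fraction <= 0:
            raise ValueError(
                f"dose_per_fraction must be > 0 Gy, got {self.dose_per_fraction!r}"
            )

    @property
    def total_dose(self) -> float:
        return self.n_fractions * self.dose_per_fraction


@dataclass(frozen=True)
class BEDResult:
    alpha_beta: float  # Gy, may be math.inf
    bed: float  # Gy
    model_tag: str  # "LQ" | "IMK"
    population_tag: str  # "PC" | "CSC" | "single"


def alpha_beta_lq(params: LQParameters) -> float:
    """alpha/beta of the LQ model in Gy; inf when beta = 0."""
    if params.beta == 0:
        return math.inf
    return params.alpha / params.beta


def alpha_beta_imk(params: IMKParameters, spec: MicrodosimetricSpec) -> float:
    """Effective alpha/beta of the targeted-effect model:
    alpha0/beta0 + y_D/(rho*pi*r^2); inf when beta0 = 0."""
    if params.beta0 == 0:
        return math.inf
    return params.alpha0 / params.beta0 + microdosimetric_factor(spec)


def bed(alpha_beta: float, regimen: FractionationRegimen) -> float:
    """BED = n*d*(1 + d/(alpha/beta)) in Gy."""
    if math.isinf(alpha_beta):
        return regimen.total_dose
    if not alpha_beta > 0:
        raise ValueError(f"alpha/beta must be > 0 Gy, got {alpha_beta!r}")
    return regimen.total_dose * (1.0 + regimen.dose_per_fraction / alpha_beta)


def bed_report(
    fit,
    regimen: FractionationRegimen,
    spec: MicrodosimetricSpec,
) -> pd.DataFrame:
    """BED table for a fit result or bare parameter object.

    One row per (model, population): an LQ fit yields a single row; a
    mixture fit yields separate PC and CSC rows (the mixture alpha/beta
    is never pooled).
    """
    theta = getattr(fit, "theta", fit)
    rows: list[BEDResult] = []
    if isinstance(theta, LQParameters):
        ab = alpha_beta_lq(theta)
        rows.append(BEDResult(ab, bed(ab, regimen), "LQ", "single"))
    elif isinstance(theta, MixtureModel):
        for tag, p in (("PC", theta.pc), ("CSC", theta.csc)):
            ab = alpha_beta_imk(p, spec)
            rows.append(BEDResult(ab, bed(ab, regimen), "IMK", tag))
    elif isinstance(theta, IMKParameters):
        ab = alpha_beta_imk(theta, spec)
        rows.append(BEDResult(ab, bed(ab, regimen), "IMK", "single"))
    else:
        raise TypeError(
            f"bed_report needs LQ, IMK or mixture parameters, got {type(theta).__name__}"
        )
    return pd.DataFrame(
        {
            "model": [r.model_tag for r in rows],
            "population": [r.population_tag for r in rows],
            "alpha_beta_gy": [r.alpha_beta for r in rows],
            "bed_gy": [r.bed for r in rows],
        }
    )
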