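"""Parameter containers for the survival models.

All parameter sets are small frozen dataclasses with eager invariant
checking, so an invalid object can never be constructed.  Flat JSON
(de)serialisation uses the conventional field names of the field
(``alpha0_pc``, ``f_csc``, ``y_D`` ...) so parameter files round-trip
between the CLI, the fitting module and external tools.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

__all__ = [
    "LQParameters",
    "IMKParameters",
    "MicrodosimetricSpec",
    "MixtureModel",
    "NTEParameters",
    "CombinedModel",
    "read_params_json",
    "write_params_json",
    "params_to_dict",
    "params_from_dict",
]


def _require_finite_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class LQParameters:
    """Linear-quadratic coefficients: -ln S = alpha*D + beta*D^2.

    alpha : Gy^-1, linear kill coefficient.
    beta  : Gy^-2, quadratic kill coefficient.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        _require_finite_nonneg("alpha", self.alpha)
        _require_finite_nonneg("beta", self.beta)


@dataclass(frozen=True)
class IMKParameters:
    """Intrinsic coefficients of one subpopulation in the microdosimetric-
    kinetic targeted-effect model.

    alpha0 : Gy^-1, intrinsic linear coefficient (before the
             microdosimetric augmentation alpha = alpha0 + z_bar * beta0).
    beta0  : Gy^-2, quadratic coefficient.
    """

    alpha0: float
    beta0: float

    def __post_init__(self) -> None:
        _require_finite_nonneg("alpha0", self.alpha0)
        _require_finite_nonneg("beta0", self.beta0)


@dataclass(frozen=True)
class MicrodosimetricSpec:
    """Microdosimetric site description defining the specific-energy
    conversion factor y_D / (rho * pi * r^2).

    y_d              : dose-mean lineal energy, keV/um.
    rho              : density of the site medium (water), g/cm^3.
    site_diameter_um : diameter of the sensitive site, um.

    Defaults describe the 150 kVp X-ray / 1 um water-site configuration
    (y_D = 4.68 keV/um), for which the factor evaluates to 0.954 Gy.
    """

    y_d: float = 4.68
    rho: float = 1.0
    site_diameter_um: float = 1.0

    def __post_init__(self) -> None:
        for name in ("y_d", "rho", "site_diameter_um"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class MixtureModel:
    """Two-population survival model: radioresistant cancer stem cells
    (CSC) mixed into bulk progeny cells (PC) at number fraction f_csc.

    The radioresistance constraint alpha0_csc <= alpha0_pc and
    beta0_csc <= beta0_pc is enforced at construction; the PC fraction is
    always 1 - f_csc and never stored independently.
    """

    pc: IMKParameters
    csc: IMKParameters
    f_csc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_csc <= 1.0):
            raise ValueError(f"f_csc must lie in [0, 1], got {self.f_csc!r}")
        if self.csc.alpha0 > self.pc.alpha0 or self.csc.beta0 > self.pc.beta0:
            raise ValueError(
                "CSC coefficients must not exceed PC coefficients "
                f"(radioresistance constraint): pc={self.pc}, csc={self.csc}"
            )

    @property
    def f_pc(self) -> float:
        return 1.0 - self.f_csc


@dataclass(frozen=True)
class NTEParameters:
    """Non-targeted-effect (bystander) lethality term
    -ln S_NT = delta * (1 - e^-X) * e^-X with
    X(D) = (alpha_b + gamma*beta_b) * D + beta_b * D^2.

    delta   : maximum lethal lesions per nucleus from the signal (dimensionless).
    alpha_b : signal-activation rate per dose, Gy^-1.
    beta_b  : signal-activation rate per dose squared, Gy^-2.
    gamma   : microdosimetric conversion factor, Gy.  By convention it
              mirrors the targeted-effect augmentation and defaults to the
              specific-energy factor of the accompanying site spec.
    """

    delta: float
    alpha_b: float
    beta_b: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("delta", "alpha_b", "beta_b", "gamma"):
            _require_finite_nonneg(name, getattr(self, name))


@dataclass(frozen=True)
class CombinedModel:
    """Targeted plus non-targeted survival: S = S_T * S_NT."""

    te: Union[IMKParameters, MixtureModel]
    nte: NTEParameters


# ---------------------------------------------------------------------------
# Flat JSON (de)serialisation


def params_to_dict(model, spec: MicrodosimetricSpec | None = None) -> dict:
    """Flatten a parameter object (plus optional site spec) to plain keys."""
    out: dict[str, float] = {}
    if isinstance(model, LQParameters):
        out.update(alpha=model.alpha, beta=model.beta)
    elif isinstance(model, MixtureModel):
        out.update(
            alpha0_pc=model.pc.alpha0,
            beta0_pc=model.pc.beta0,
            alpha0_csc=model.csc.alpha0,
            beta0_csc=model.csc.beta0,
            f_csc=model.f_csc,
        )
    elif isinstance(model, IMKParameters):
        out.update(alpha0=model.alpha0, beta0=model.beta0)
    elif isinstance(model, CombinedModel):
        out.update(params_to_dict(model.te))
        out.update(
            delta=model.nte.delta,
            alpha_b=model.nte.alpha_b,
            beta_b=model.nte.beta_b,
            gamma=model.nte.gamma,
        )
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported parameter object: {type(model).__name__}")
    if spec is not None:
        out.update(y_D=spec.y_d, rho=spec.rho, site_diameter_um=spec.site_diameter_um)
    return out


def params_from_dict(data: dict):
    """Rebuild ``(model, spec)`` from a flat dict; spec may be None."""
    spec = None
    if "y_D" in data:
        spec = MicrodosimetricSpec(
            y_d=float(data["y_D"]),
            rho=float(data.get("rho", 1.0)),
            site_diameter_um=float(data.get("site_diameter_um", 1.0)),
        )
    if "f_csc" in data:
        model: object = MixtureModel(
            pc=IMKParameters(float(data["alpha0_pc"]), float(data["beta0_pc"])),
            csc=IMKParameters(float(data["alpha0_csc"]), float(data["beta0_csc"])),
            f_csc=float(data["f_csc"]),
        )
    elif "delta" in data:
        nte = NTEParameters(
            delta=float(data["delta"]),
            alpha_b=float(data["alpha_b"]),
            beta_b=float(data["beta_b"]),
            gamma=float(data["gamma"]),
        )
        te = IMKParameters(float(data["alpha0"]), float(data["beta0"]))
        model = CombinedModel(te=te, nte=nte)
    elif "alpha0" in data:
        model = IMKParameters(float(data["alpha0"]), float(data["beta0"]))
    elif "alpha" in data:
        model = LQParameters(float(data["alpha"]), float(data["beta"]))
    else:
        raise ValueError(
            "parameter dict does not match any known model: "
            f"keys = {sorted(data)}"
        )
    return model, spec


def write_params_json(path, model, spec: MicrodosimetricSpec | None = None) -> None:
    Path(path).write_text(json.dumps(params_to_dict(model, spec), indent=2) + "\n")


def read_params_json(path):
    return params_from_dict(json.loads(Path(path).read_text()))
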