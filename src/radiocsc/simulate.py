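"""Synthetic clonogenic-survival data with known ground truth.

Emulates colony-formation assays: a dose grid spanning 0-10 Gy, a small
number of replicates per dose, and multiplicative log-normal replicate
noise, S_obs = S_true(D) * exp(eps) with eps ~ Normal(0, sigma_log^2).
Multiplicative noise is used because clonogenic scatter scales with the
survival level and log-survival is the fitting scale.  Observed values
above 1 (possible at low dose) are clamped to 1 and counted.

The generator writes the same CSV dialect the fitting module reads, so
every downstream stage is testable without experimental data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .core import mixture_log_survival, model_log_survival
from .data import SurvivalDataset, SurvivalObservation
from .params import (
    CombinedModel,
    IMKParameters,
    LQParameters,
    MicrodosimetricSpec,
    MixtureModel,
)

__all__ = [
    "SimulationConfig",
    "simulate_survival",
    "sweep_csc_fraction",
    "DEFAULT_DOSES",
    "SWEEP_FRACTIONS",
]

# Dose grid spanning the 0-10 Gy range of kilovoltage X-ray clonogenic
# experiments, denser at low dose where the curve shoulders.
DEFAULT_DOSES = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)

# Canonical CSC-fraction grid for prediction sweeps: 0 to 100%.
SWEEP_FRACTIONS = (0.0, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth plus noise model for one simulated assay.

    truth        : generating parameters (LQ, IMK, mixture or combined).
    spec         : microdosimetric site description.
    doses        : dose grid in Gy.
    n_replicates : replicates per dose (clonogenic assays typically run 3).
    sigma_log    : SD of the log-survival noise; 0 gives exact model values.
    seed         : generator seed; a fixed seed reproduces the dataset
                   byte-identically.
    """

    truth: Union[LQParameters, IMKParameters, MixtureModel, CombinedModel]
    spec: MicrodosimetricSpec = MicrodosimetricSpec()
    doses: Sequence[float] = DEFAULT_DOSES
    n_replicates: int = 3
    sigma_log: float = 0.1
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.doses) == 0:
            raise ValueError("dose list must not be empty")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be >= 0")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_survival(config: SimulationConfig) -> SurvivalDataset:
    """Draw one synthetic dataset from the configured ground truth.

    Per dose, ``n_replicates`` noisy survivals are drawn and summarised
    into one observation carrying their mean and sample SD (SD is NaN
    for a single replicate).
    """
    doses = np.asarray(config.doses, dtype=float)
    log_s_true = np.asarray(model_log_survival(config.truth, config.spec, doses))
    rng = np.random.default_rng(config.seed)
    eps = rng.normal(0.0, config.sigma_log, size=(config.n_replicates, doses.size))
    s_obs = np.exp(log_s_true[None, :] + eps)
    n_clamped = int(np.sum(s_obs > 1.0))
    if n_clamped:
        warnings.warn(
            f"{n_clamped} replicate survival value(s) > 1 clamped to 1",
            stacklevel=2,
        )
        s_obs = np.minimum(s_obs, 1.0)
    mean = s_obs.mean(axis=0)
    sd = (
        s_obs.std(axis=0, ddof=1)
        if config.n_replicates > 1
        else np.full(doses.size, np.nan)
    )
    observations = [
        SurvivalObservation(
            dose=float(d),
            surviving_fraction=float(m),
            sd=float(s),
            n_replicates=config.n_replicates,
        )
        for d, m, s in zip(doses, mean, sd)
    ]
    return SurvivalDataset(label=config.label, observations=observations)


def sweep_csc_fraction(
    base: MixtureModel,
    fractions: Sequence[float] = SWEEP_FRACTIONS,
    spec: MicrodosimetricSpec = MicrodosimetricSpec(),
    doses: Sequence[float] = DEFAULT_DOSES,
) -> pd.DataFrame:
    """Noise-free survival curves over a grid of CSC fractions.

    Returns a long-format table (f_csc, dose_gy, surviving_fraction)
    holding one curve per requested fraction, with the PC and CSC
    component parameters held at ``base``'s values.
    """
    if any(not (0.0 <= f <= 1.0) for f in fractions):
        raise ValueError("all fractions must lie in [0, 1]")
    doses = np.asarray(doses, dtype=float)
    frames = []
    for f in fractions:
        model = MixtureModel(pc=base.pc, csc=base.csc, f_csc=float(f))
        s = np.exp(np.asarray(mixture_log_survival(model, spec, doses)))
        frames.append(
            pd.DataFrame(
                {"f_csc": float(f), "dose_gy": doses, "surviving_fraction": s}
            )
        )
    return pd.concat(frames, ignore_index=True)
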