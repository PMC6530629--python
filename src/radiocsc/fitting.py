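"""Functional fitting surface: least-squares objective, model fits,
chi-square fit quality and bootstrap standard errors.

These are thin wrappers over the estimator classes in
:mod:`radiocsc.estimators`; they exist so scripted analyses can work in
terms of :class:`~radiocsc.data.SurvivalDataset` and parameter
dataclasses without touching the sklearn API.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .core import model_log_survival
from .data import SurvivalDataset, SurvivalObservation
from .estimators import (
    LinearQuadraticSurvival,
    StemCellMixtureSurvival,
    TargetedNontargetedSurvival,
)
from .params import (
    CombinedModel,
    LQParameters,
    MicrodosimetricSpec,
    MixtureModel,
    params_to_dict,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "objective",
    "chi_square",
    "fit_lq",
    "fit_mixture",
    "fit_nte",
    "standard_errors",
]


@dataclass(frozen=True)
class FitConfig:
    """Search settings shared by all fits.

    n_samples : Monte-Carlo draws of the parameter vector.
    seed      : seed of the draw sequence (fits are deterministic in it).
    alpha_max, beta_max, delta_max : upper box bounds of the search.
    polish    : run the bounded least-squares refinement stage.
    polish_starts : number of best draws used as refinement starts.
    n_bootstrap : resamples used by :func:`standard_errors`.
    """

    n_samples: int = 100_000
    seed: int = 0
    alpha_max: float = 10.0
    beta_max: float = 1.0
    delta_max: float = 10.0
    polish: bool = True
    polish_starts: int = 100
    n_bootstrap: int = 200


@dataclass
class FitResult:
    """Outcome of one model fit."""

    theta: Union[LQParameters, MixtureModel, CombinedModel]
    objective: float
    chi_square: Optional[float]
    std_errors: Optional[dict] = None
    n_restarts: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "parameters": params_to_dict(self.theta),
            "objective": self.objective,
            "chi_square": self.chi_square,
            "std_errors": self.std_errors,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
        }


def objective(theta, dataset: SurvivalDataset, spec: MicrodosimetricSpec | None = None) -> float:
    """Sum of squared natural-log survival deviations of ``theta`` on the data."""
    s_exp = dataset.survival
    if np.any(s_exp <= 0):
        raise ValueError("observations with surviving_fraction <= 0 are invalid")
    log_s_model = np.asarray(model_log_survival(theta, spec, dataset.doses))
    return float(np.square(np.log(s_exp) - log_s_model).sum())


def chi_square(model_predictions, dataset: SurvivalDataset) -> float:
    """Reduced chi-square on the linear survival scale:
    (1/N) sum_i (S_exp,i - S_model,i)^2 / sd_i^2.

    Points with sd = 0 or missing sd are excluded with a warning; if no
    point carries a positive sd the statistic is undefined and raises.
    """
    s_model = np.asarray(model_predictions, dtype=float)
    s_exp = dataset.survival
    sd = dataset.sd
    if s_model.shape != s_exp.shape:
        raise ValueError("model_predictions must align with dataset observations")
    usable = np.isfinite(sd) & (sd > 0)
    if not np.any(usable):
        raise ValueError("chi-square undefined: no observation has sd > 0")
    if not np.all(usable):
        warnings.warn(
            f"{int(np.sum(~usable))} observation(s) without positive sd "
            "excluded from chi-square",
            stacklevel=2,
        )
    r = (s_exp[usable] - s_model[usable]) / sd[usable]
    return float(np.mean(r * r))


def _chi_square_or_none(est, dataset: SurvivalDataset) -> Optional[float]:
    sd = dataset.sd
    if not np.any(np.isfinite(sd) & (sd > 0)):
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return chi_square(est.predict(dataset.doses), dataset)


def _result(est, dataset: SurvivalDataset, config: FitConfig) -> FitResult:
    return FitResult(
        theta=est.params_,
        objective=est.objective_,
        chi_square=_chi_square_or_none(est, dataset),
        n_restarts=est.n_samples_,
        seed=config.seed,
    )


def fit_lq(dataset: SurvivalDataset, config: FitConfig | None = None) -> FitResult:
    """Fit the linear-quadratic model (alpha, beta) to one dataset."""
    config = config or FitConfig()
    dataset.validate_for_fit(3)
    est = LinearQuadraticSurvival(
        alpha_max=config.alpha_max,
        beta_max=config.beta_max,
        n_samples=config.n_samples,
        polish=config.polish,
        polish_starts=config.polish_starts,
        random_state=config.seed,
    ).fit(dataset.doses, dataset.survival)
    return _result(est, dataset, config)


def fit_mixture(
    dataset: SurvivalDataset,
    spec: MicrodosimetricSpec,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the five-parameter PC/CSC mixture model to one dataset.

    The microdosimetric spec (y_D etc.) is an input, not fitted.
    """
    config = config or FitConfig()
    dataset.validate_for_fit(6)
    est = StemCellMixtureSurvival(
        spec=spec,
        alpha_max=config.alpha_max,
        beta_max=config.beta_max,
        n_samples=config.n_samples,
        polish=config.polish,
        polish_starts=config.polish_starts,
        random_state=config.seed,
    ).fit(dataset.doses, dataset.survival)
    return _result(est, dataset, config)


def fit_nte(
    dataset: SurvivalDataset,
    spec: MicrodosimetricSpec,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the targeted + non-targeted model
    (alpha0, beta0, delta, alpha_b, beta_b) to one dataset."""
    config = config or FitConfig()
    dataset.validate_for_fit(6)
    est = TargetedNontargetedSurvival(
        spec=spec,
        alpha_max=config.alpha_max,
        beta_max=config.beta_max,
        delta_max=config.delta_max,
        n_samples=config.n_samples,
        polish=config.polish,
        polish_starts=config.polish_starts,
        random_state=config.seed,
    ).fit(dataset.doses, dataset.survival)
    return _result(est, dataset, config)


def _refit(theta_type, dataset, spec, config):
    if theta_type is LQParameters:
        return fit_lq(dataset, config)
    if theta_type is MixtureModel:
        return fit_mixture(dataset, spec, config)
    if theta_type is CombinedModel:
        return fit_nte(dataset, spec, config)
    raise TypeError(f"cannot refit parameters of type {theta_type.__name__}")


def standard_errors(
    fit: FitResult,
    dataset: SurvivalDataset,
    config: FitConfig | None = None,
    spec: MicrodosimetricSpec | None = None,
) -> dict:
    """Nonparametric bootstrap standard errors of the fitted parameters.

    Observations are resampled with replacement ``config.n_bootstrap``
    times; each resample is refitted with the same search settings (a
    per-resample seed drawn from ``config.seed``) and the standard
    deviation of each parameter across resamples is returned, keyed by
    the flat parameter names.  Deterministic in ``config.seed``.
    """
    config = config or FitConfig()
    n_boot = config.n_bootstrap
    if n_boot < 2:
        raise ValueError("n_bootstrap must be >= 2")
    rng = np.random.default_rng(config.seed)
    n = len(dataset)
    rows = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resample = SurvivalDataset(
            label=dataset.label,
            observations=[
                SurvivalObservation(
                    dose=o.dose,
                    surviving_fraction=o.surviving_fraction,
                    sd=o.sd,
                    n_replicates=o.n_replicates,
                )
                for o in (dataset.observations[i] for i in idx)
            ],
        )
        sub_config = FitConfig(
            n_samples=config.n_samples,
            seed=int(rng.integers(0, 2**31 - 1)),
            alpha_max=config.alpha_max,
            beta_max=config.beta_max,
            delta_max=config.delta_max,
            polish=config.polish,
            polish_starts=config.polish_starts,
            n_bootstrap=config.n_bootstrap,
        )
        try:
            res = _refit(type(fit.theta), resample, spec, sub_config)
        except ValueError:
            continue  # degenerate resample (all doses identical)
        rows.append(params_to_dict(res.theta))
    if len(rows) < 2:
        raise RuntimeError("fewer than 2 successful bootstrap refits")
    keys = rows[0].keys()
    return {
        k: float(np.std([r[k] for r in rows], ddof=1)) for k in keys
    }
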