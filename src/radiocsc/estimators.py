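"""Scikit-learn style estimators for clonogenic survival curves.

Each estimator fits its survival model to (dose, surviving fraction)
pairs by least squares on natural-log survival:

    l(theta) = sum_i (ln S_obs,i - ln S_model,i(theta))^2

minimised by Monte-Carlo random search — ``n_samples`` uniform draws of
theta within box bounds (draws violating the CSC radioresistance
constraint are rejected), keeping the best — followed by a bounded
trust-region least-squares polish started from each of the
``polish_starts`` best draws (the multimodal mixture objective has
narrow basins that a single local descent from the single best draw
frequently misses).  The whole procedure is a deterministic function of
(data, parameters, random_state).

Estimators follow the sklearn contract: ``fit(X, y)`` with X the doses
in Gy (1-d or a single column) and y the surviving fractions in (0, 1],
``predict(X)`` returning surviving fractions, fitted attributes with a
trailing underscore, and ``get_params``/``set_params`` for pipeline and
model-selection interoperability.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .core import microdosimetric_factor
from .params import (
    CombinedModel,
    IMKParameters,
    LQParameters,
    MicrodosimetricSpec,
    MixtureModel,
    NTEParameters,
)

__all__ = [
    "LinearQuadraticSurvival",
    "StemCellMixtureSurvival",
    "TargetedNontargetedSurvival",
]

logger = logging.getLogger("radiocsc")

_CHUNK = 10_000  # draws evaluated (and logged) per block


def _as_doses(X) -> np.ndarray:
    X = check_array(X, ensure_2d=False, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("X must be doses: 1-d or a single column")
        X = X[:, 0]
    if np.any(X < 0):
        raise ValueError("doses must be >= 0 Gy")
    return X


class _MonteCarloSurvivalFitter(RegressorMixin, BaseEstimator):
    """Shared MC-search + least-squares-polish machinery (not user-facing)."""

    # subclasses implement: _bounds(), _sample_block(rng, n),
    # _log_survival_batch(thetas, doses), _to_polish(theta),
    # _from_polish(phi), _polish_bounds(), _store_fitted(theta)

    def fit(self, X, y):
        doses = _as_doses(X)
        y = check_array(y, ensure_2d=False, dtype=float)
        if y.shape != doses.shape:
            raise ValueError("X and y must have the same length")
        if np.any(y <= 0) or np.any(~np.isfinite(y)):
            raise ValueError("surviving fractions must be finite and > 0")
        if np.any(y > 1):
            warnings.warn(
                f"{int(np.sum(y > 1))} surviving fraction(s) > 1 clamped to 1",
                stacklevel=2,
            )
            y = np.minimum(y, 1.0)
        self._check_dataset(doses)
        log_s_obs = np.log(y)

        n_total = int(self.n_samples)
        if n_total < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(self.random_state)

        k = max(1, int(self.polish_starts)) if self.polish else 1
        top_obj = np.empty(0)
        top_theta = np.empty((0, 0))
        drawn = 0
        while drawn < n_total:
            block = min(_CHUNK, n_total - drawn)
            thetas = self._sample_block(rng, block)
            drawn += block
            if thetas.shape[0] == 0:
                continue
            log_s = self._log_survival_batch(thetas, doses)
            obj = np.square(log_s_obs[None, :] - log_s).sum(axis=1)
            # running top-k, earlier draws win ties (stable sorts)
            if top_theta.size == 0:
                top_theta = thetas[:0]
            pool_obj = np.concatenate([top_obj, obj])
            pool_theta = np.concatenate([top_theta, thetas])
            keep = np.argsort(pool_obj, kind="stable")[:k]
            top_obj, top_theta = pool_obj[keep], pool_theta[keep]
            logger.info(
                "MC search: %d/%d draws, best objective %.6g",
                drawn,
                n_total,
                float(top_obj[0]),
            )
        if top_obj.size == 0:
            raise RuntimeError(
                "no feasible parameter draw found; increase n_samples"
            )
        best_theta, best_obj = top_theta[0].copy(), float(top_obj[0])

        if self.polish:
            best_theta, best_obj = self._polish(
                top_theta, best_theta, best_obj, doses, log_s_obs
            )

        self._store_fitted(np.asarray(best_theta, dtype=float))
        self.objective_ = best_obj
        self.n_samples_ = n_total
        self.n_features_in_ = 1
        return self

    def _polish(self, starts, theta0, obj0, doses, log_s_obs):
        lower, upper = map(np.asarray, zip(*self._polish_bounds()))
        free = upper > lower  # coordinates with zero-width bounds stay pinned

        def residuals(phi_free, phi_full):
            phi = phi_full.copy()
            phi[free] = phi_free
            theta = self._from_polish(np.clip(phi, lower, upper))
            log_s = self._log_survival_batch(theta[None, :], doses)[0]
            return log_s_obs - log_s

        best_theta, best = np.asarray(theta0, dtype=float), obj0
        for theta_start in starts:
            phi0 = np.clip(self._to_polish(np.asarray(theta_start, dtype=float)), lower, upper)
            res = least_squares(
                residuals,
                phi0[free],
                args=(phi0,),
                bounds=(lower[free], upper[free]),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
            value = float(np.sum(res.fun**2))
            if value < best:
                best = value
                phi = phi0.copy()
                phi[free] = res.x
                best_theta = self._from_polish(np.clip(phi, lower, upper))
            if best < 1e-28:
                break
        logger.info("polish: objective %.6g -> %.6g", obj0, best)
        return best_theta, best

    # -- prediction ----------------------------------------------------

    def predict_neg_log_survival(self, X) -> np.ndarray:
        """-ln S at the given doses for the fitted model."""
        check_is_fitted(self, "theta_")
        doses = _as_doses(X)
        return -self._log_survival_batch(self.theta_[None, :], doses)[0]

    def predict(self, X) -> np.ndarray:
        """Surviving fraction at the given doses."""
        return np.exp(-self.predict_neg_log_survival(X))


class LinearQuadraticSurvival(_MonteCarloSurvivalFitter):
    """Linear-quadratic dose-response fit: -ln S = alpha*D + beta*D^2.

    Parameters
    ----------
    alpha_max, beta_max : upper search bounds for alpha (Gy^-1) and
        beta (Gy^-2); both lower bounds are 0.
    n_samples : number of uniform Monte-Carlo draws.
    polish : run the bounded least-squares refinement stage.
    polish_starts : number of best draws used as refinement starts.
    random_state : seed for the draw sequence.

    Attributes
    ----------
    alpha_, beta_ : fitted coefficients.
    params_ : the fitted :class:`LQParameters`.
    objective_ : minimised sum of squared log-survival deviations.
    """

    _N_MIN_POINTS = 3

    def __init__(
        self,
        alpha_max: float = 10.0,
        beta_max: float = 1.0,
        n_samples: int = 100_000,
        polish: bool = True,
        polish_starts: int = 100,
        random_state=None,
    ):
        self.alpha_max = alpha_max
        self.beta_max = beta_max
        self.n_samples = n_samples
        self.polish = polish
        self.polish_starts = polish_starts
        self.random_state = random_state

    def _check_dataset(self, doses):
        if doses.size < self._N_MIN_POINTS:
            raise ValueError(f"need >= {self._N_MIN_POINTS} dose points")
        if np.all(doses == doses[0]):
            raise ValueError("degenerate dataset: all doses identical")

    def _bounds(self):
        return [(0.0, self.alpha_max), (0.0, self.beta_max)]

    def _sample_block(self, rng, n):
        lo, hi = map(np.asarray, zip(*self._bounds()))
        return rng.uniform(lo, hi, size=(n, 2))

    def _log_survival_batch(self, thetas, doses):
        a, b = thetas[:, 0:1], thetas[:, 1:2]
        d = doses[None, :]
        return -(a * d + b * d * d)

    def _to_polish(self, theta):
        return theta

    def _from_polish(self, phi):
        return np.asarray(phi, dtype=float)

    def _polish_bounds(self):
        return self._bounds()

    def _store_fitted(self, theta):
        self.theta_ = theta
        self.alpha_, self.beta_ = float(theta[0]), float(theta[1])
        self.params_ = LQParameters(self.alpha_, self.beta_)


class StemCellMixtureSurvival(_MonteCarloSurvivalFitter):
    """Two-population microdosimetric-kinetic survival fit.

    The cell population is a mixture of bulk progeny cells (PC) and a
    radioresistant cancer-stem-cell (CSC) fraction f_csc; each component
    follows the targeted-effect model
    -ln S = (alpha0 + z*beta0)*D + beta0*D^2 with z the specific-energy
    factor of ``spec``, and the observable survival is the number-
    fraction-weighted mixture (1-f)*S_PC + f*S_CSC.  The fit enforces
    alpha0_csc <= alpha0_pc and beta0_csc <= beta0_pc: draws violating
    the constraint are rejected, and the polish reparameterises the CSC
    coefficients as fractions u of the PC ones.

    Attributes
    ----------
    alpha0_pc_, beta0_pc_, alpha0_csc_, beta0_csc_, f_csc_ : fitted values.
    params_ : the fitted :class:`MixtureModel`.
    objective_ : minimised sum of squared log-survival deviations.
    """

    _N_MIN_POINTS = 6

    def __init__(
        self,
        spec: MicrodosimetricSpec = MicrodosimetricSpec(),
        alpha_max: float = 10.0,
        beta_max: float = 1.0,
        n_samples: int = 100_000,
        polish: bool = True,
        polish_starts: int = 100,
        random_state=None,
    ):
        self.spec = spec
        self.alpha_max = alpha_max
        self.beta_max = beta_max
        self.n_samples = n_samples
        self.polish = polish
        self.polish_starts = polish_starts
        self.random_state = random_state

    def _check_dataset(self, doses):
        if doses.size < self._N_MIN_POINTS:
            raise ValueError(
                f"need >= {self._N_MIN_POINTS} dose points for the "
                "5-parameter mixture fit"
            )
        if np.all(doses == doses[0]):
            raise ValueError("degenerate dataset: all doses identical")

    def _sample_block(self, rng, n):
        lo = np.zeros(5)
        hi = np.array([self.alpha_max, self.beta_max, self.alpha_max, self.beta_max, 1.0])
        thetas = rng.uniform(lo, hi, size=(n, 5))
        feasible = (thetas[:, 2] <= thetas[:, 0]) & (thetas[:, 3] <= thetas[:, 1])
        return thetas[feasible]

    def _log_survival_batch(self, thetas, doses):
        z = microdosimetric_factor(self.spec)
        a_pc, b_pc = thetas[:, 0:1], thetas[:, 1:2]
        a_csc, b_csc = thetas[:, 2:3], thetas[:, 3:4]
        f = thetas[:, 4:5]
        d = doses[None, :]
        nls_pc = (a_pc + z * b_pc) * d + b_pc * d * d
        nls_csc = (a_csc + z * b_csc) * d + b_csc * d * d
        with np.errstate(divide="ignore"):
            lw_pc = np.log1p(-f)
            lw_csc = np.log(f)
        # weight-sum normalisation keeps S(0) = 1 exact
        return np.logaddexp(lw_pc - nls_pc, lw_csc - nls_csc) - np.logaddexp(lw_pc, lw_csc)

    # polish space: (alpha0_pc, beta0_pc, u_alpha, u_beta, f) with
    # alpha0_csc = u_alpha*alpha0_pc, beta0_csc = u_beta*beta0_pc, so the
    # radioresistance constraint is the box u in [0, 1]^2.
    def _to_polish(self, theta):
        a_pc, b_pc, a_csc, b_csc, f = theta
        u_a = a_csc / a_pc if a_pc > 0 else 1.0
        u_b = b_csc / b_pc if b_pc > 0 else 1.0
        return np.array([a_pc, b_pc, min(u_a, 1.0), min(u_b, 1.0), f])

    def _from_polish(self, phi):
        a_pc, b_pc, u_a, u_b, f = phi
        return np.array([a_pc, b_pc, u_a * a_pc, u_b * b_pc, f])

    def _polish_bounds(self):
        return [
            (0.0, self.alpha_max),
            (0.0, self.beta_max),
            (0.0, 1.0),
            (0.0, 1.0),
            (0.0, 1.0),
        ]

    def _store_fitted(self, theta):
        self.theta_ = theta
        self.alpha0_pc_, self.beta0_pc_ = float(theta[0]), float(theta[1])
        self.alpha0_csc_, self.beta0_csc_ = float(theta[2]), float(theta[3])
        self.f_csc_ = float(theta[4])
        self.params_ = MixtureModel(
            pc=IMKParameters(self.alpha0_pc_, self.beta0_pc_),
            csc=IMKParameters(self.alpha0_csc_, self.beta0_csc_),
            f_csc=self.f_csc_,
        )


class TargetedNontargetedSurvival(_MonteCarloSurvivalFitter):
    """Single-population targeted-effect fit extended with a
    non-targeted (bystander) lethality term.

    -ln S = (alpha0 + z*beta0)*D + beta0*D^2 + delta*(1-e^-X)*e^-X,
    X = (alpha_b + gamma*beta_b)*D + beta_b*D^2.

    ``gamma`` defaults to the specific-energy factor of ``spec``,
    mirroring the targeted-effect augmentation; pass a number to
    override.

    Attributes
    ----------
    alpha0_, beta0_, delta_, alpha_b_, beta_b_ : fitted values.
    params_ : the fitted :class:`CombinedModel`.
    """

    _N_MIN_POINTS = 6

    def __init__(
        self,
        spec: MicrodosimetricSpec = MicrodosimetricSpec(),
        gamma: float | None = None,
        alpha_max: float = 10.0,
        beta_max: float = 1.0,
        delta_max: float = 10.0,
        n_samples: int = 100_000,
        polish: bool = True,
        polish_starts: int = 100,
        random_state=None,
    ):
        self.spec = spec
        self.gamma = gamma
        self.alpha_max = alpha_max
        self.beta_max = beta_max
        self.delta_max = delta_max
        self.n_samples = n_samples
        self.polish = polish
        self.polish_starts = polish_starts
        self.random_state = random_state

    def _gamma(self) -> float:
        return microdosimetric_factor(self.spec) if self.gamma is None else float(self.gamma)

    def _check_dataset(self, doses):
        if doses.size < self._N_MIN_POINTS:
            raise ValueError(
                f"need >= {self._N_MIN_POINTS} dose points for the "
                "5-parameter targeted+non-targeted fit"
            )
        if np.all(doses == doses[0]):
            raise ValueError("degenerate dataset: all doses identical")

    def _bounds(self):
        return [
            (0.0, self.alpha_max),
            (0.0, self.beta_max),
            (0.0, self.delta_max),
            (0.0, self.alpha_max),
            (0.0, self.beta_max),
        ]

    def _sample_block(self, rng, n):
        lo, hi = map(np.asarray, zip(*self._bounds()))
        return rng.uniform(lo, hi, size=(n, 5))

    def _log_survival_batch(self, thetas, doses):
        z = microdosimetric_factor(self.spec)
        g = self._gamma()
        a0, b0 = thetas[:, 0:1], thetas[:, 1:2]
        delta, a_b, b_b = thetas[:, 2:3], thetas[:, 3:4], thetas[:, 4:5]
        d = doses[None, :]
        nls_te = (a0 + z * b0) * d + b0 * d * d
        x = (a_b + g * b_b) * d + b_b * d * d
        u = np.exp(-x)
        return -(nls_te + delta * (1.0 - u) * u)

    def _to_polish(self, theta):
        return theta

    def _from_polish(self, phi):
        return np.asarray(phi, dtype=float)

    def _polish_bounds(self):
        return self._bounds()

    def _store_fitted(self, theta):
        self.theta_ = theta
        self.alpha0_, self.beta0_ = float(theta[0]), float(theta[1])
        self.delta_ = float(theta[2])
        self.alpha_b_, self.beta_b_ = float(theta[3]), float(theta[4])
        self.params_ = CombinedModel(
            te=IMKParameters(self.alpha0_, self.beta0_),
            nte=NTEParameters(
                delta=self.delta_,
                alpha_b=self.alpha_b_,
                beta_b=self.beta_b_,
                gamma=self._gamma(),
            ),
        )
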