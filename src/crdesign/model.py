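"""Four-parameter continuation-ratio (CR) dose-response model.

A patient treated at dose ``d`` has a trinomial outcome ``Z``:

* ``Z = 0`` — no efficacy and no toxicity,
* ``Z = 1`` — efficacy without toxicity,
* ``Z = 2`` — toxicity.

The CR model factorises the outcome distribution into two logistic
regressions: the marginal probability of toxicity

    pT(d) = expit(alpha_tox + beta_tox * d),

and the conditional probability of efficacy given no toxicity

    pE|Tc(d) = expit(alpha_eff + beta_eff * d).

The three outcome probabilities are then

    pi2(d) = pT(d),
    pi1(d) = pE|Tc(d) * (1 - pT(d)),
    pi0(d) = (1 - pE|Tc(d)) * (1 - pT(d)).

Two doses summarise the curve for trial planning: the maximum tolerated
dose (MTD), the dose at which toxicity reaches a target level ``gamma``,
and the optimal biological dose (OBD), the dose maximising the
probability of efficacy without toxicity over the study interval.

Parameter vectors are ordered ``(alpha_tox, beta_tox, alpha_eff,
beta_eff)`` throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit

__all__ = [
    "CRParams",
    "DoseInterval",
    "OutcomeProbabilities",
    "outcome_probabilities",
    "mtd",
    "obd",
    "obd_gradient",
]

#: Canonical parameter order used for every 4-vector and 4x4 matrix.
PARAM_ORDER = ("alpha_tox", "beta_tox", "alpha_eff", "beta_eff")


@dataclass(frozen=True)
class CRParams:
    """CR model parameters.

    ``alpha_tox``/``beta_tox`` are the intercept and slope of the
    toxicity logistic; ``alpha_eff``/``beta_eff`` those of the
    conditional efficacy logistic.  Both slopes must be strictly
    positive so that toxicity and conditional efficacy increase with
    dose.
    """

    alpha_tox: float
    beta_tox: float
    alpha_eff: float
    beta_eff: float

    def __post_init__(self) -> None:
        vals = (self.alpha_tox, self.beta_tox, self.alpha_eff, self.beta_eff)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"CR parameters must be finite, got {vals}")
        if self.beta_tox <= 0 or self.beta_eff <= 0:
            raise ValueError(
                "slopes beta_tox and beta_eff must be strictly positive, "
                f"got beta_tox={self.beta_tox}, beta_eff={self.beta_eff}"
            )

    def to_array(self) -> np.ndarray:
        """Parameters as a 4-vector in canonical order."""
        return np.array(
            [self.alpha_tox, self.beta_tox, self.alpha_eff, self.beta_eff],
            dtype=float,
        )

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "CRParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (4,):
            raise ValueError(f"expected a 4-vector, got shape {theta.shape}")
        return cls(*theta)


@dataclass(frozen=True)
class DoseInterval:
    """Closed dose interval ``[lower, upper]`` available to the study."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("dose interval endpoints must be finite")
        if not self.lower < self.upper:
            raise ValueError(
                f"need lower < upper, got [{self.lower}, {self.upper}]"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, d: float, tol: float = 0.0) -> bool:
        return self.lower - tol <= d <= self.upper + tol


class OutcomeProbabilities(NamedTuple):
    """Trinomial outcome probabilities ``(pi0, pi1, pi2)`` at one dose."""

    p_none: float
    p_eff: float
    p_tox: float


def _ptox(d, params: CRParams):
    return expit(params.alpha_tox + params.beta_tox * np.asarray(d, dtype=float))

def _peff_cond(d, params: CRParams):
    return expit(params.alpha_eff + params.beta_eff * np.asarray(d, dtype=float))


def outcome_probabilities(d: float, params: CRParams) -> OutcomeProbabilities:
    """Evaluate ``(pi0, pi1, pi2)`` at dose ``d``.

    Uses ``scipy.special.expit`` so the result is numerically stable for
    linear predictors far into either tail.
    """
    if not math.isfinite(d):
        raise ValueError(f"dose must be finite, got {d}")
    p_t = float(_ptox(d, params))
    p_e = float(_peff_cond(d, params))
    return OutcomeProbabilities(
        p_none=(1.0 - p_e) * (1.0 - p_t),
        p_eff=p_e * (1.0 - p_t),
        p_tox=p_t,
    )


def mtd(params: CRParams, gamma: float) -> float:
    """Maximum tolerated dose: the ``gamma`` percentile of the toxicity curve.

    Solves ``pT(d) = gamma`` in closed form,
    ``(logit(gamma) - alpha_tox) / beta_tox``.  The result may fall
    outside any particular study interval; callers decide what to do
    then.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"target toxicity level must be in (0, 1), got {gamma}")
    return float((logit(gamma) - params.alpha_tox) / params.beta_tox)


def _p_eff_no_tox(d, theta: np.ndarray):
    """pi1(d) for an unconstrained 4-vector (used for fitted parameters too)."""
    d = np.asarray(d, dtype=float)
    return expit(theta[2] + theta[3] * d) * (1.0 - expit(theta[0] + theta[1] * d))


def _argmax_p_eff_no_tox(
    theta: np.ndarray,
    lower: float,
    upper: float,
    grid_size: int = 1001,
    xatol: float = 1e-6,
) -> float:
    """Maximise pi1 over [lower, upper]: coarse grid then local refinement.

    Works for arbitrary (possibly sign-violating) parameter vectors so
    it can also locate the dose estimate implied by a fitted model.
    """
    grid = np.linspace(lower, upper, grid_size)
    vals = _p_eff_no_tox(grid, theta)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    if lo == hi:
        return float(lo)
    res = minimize_scalar(
        lambda d: -_p_eff_no_tox(d, theta),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol},
    )
    d_star = float(res.x)
    # the bounded search cannot beat an endpoint that is the true argmax
    if _p_eff_no_tox(d_star, theta) < vals[i]:
        d_star = float(grid[i])
    return min(max(d_star, lower), upper)


def obd(params: CRParams, interval: DoseInterval, grid_size: int = 1001) -> float:
    """Optimal biological dose: argmax of pi1 over the interval.

    Deterministic grid search (``grid_size`` points) followed by a
    bounded scalar refinement to an absolute dose tolerance of 1e-6.
    If pi1 is monotone over the interval the appropriate endpoint is
    returned.
    """
    return _argmax_p_eff_no_tox(
        params.to_array(), interval.lower, interval.upper, grid_size=grid_size
    )


def _stationarity_terms(d: float, theta: np.ndarray):
    """The reduced stationarity function h and its partials at dose d.

    pi1'(d) = pE|Tc (1 - pT) * h(d) with
    h(d, theta) = beta_eff (1 - pE|Tc(d)) - beta_tox pT(d);
    the positive prefactor never vanishes, so interior stationary points
    of pi1 are exactly the roots of h.
    """
    a1, b1, a2, b2 = theta
    p_t = float(expit(a1 + b1 * d))
    p_e = float(expit(a2 + b2 * d))
    qt = p_t * (1.0 - p_t)
    qe = p_e * (1.0 - p_e)
    h = b2 * (1.0 - p_e) - b1 * p_t
    dh_dd = -(b2 * b2) * qe - (b1 * b1) * qt
    grad_theta = np.array(
        [
            -b1 * qt,                      # d h / d alpha_tox
            -p_t - b1 * d * qt,            # d h / d beta_tox
            -b2 * qe,                      # d h / d alpha_eff
            (1.0 - p_e) - b2 * d * qe,     # d h / d beta_eff
        ]
    )
    return h, dh_dd, grad_theta


def obd_gradient(
    params: CRParams,
    interval: DoseInterval,
    boundary_tol: float = 1e-5,
) -> np.ndarray:
    """Gradient of the OBD with respect to the four model parameters.

    The OBD satisfies the stationarity condition ``h(OBD, theta) = 0``
    (see :func:`_stationarity_terms`); the implicit function theorem
    then gives component ``j`` of the gradient as
    ``-(dh/dtheta_j) / (dh/dd)`` evaluated at the OBD.  All partials are
    analytic.

    Raises :class:`ValueError` when the OBD sits on an interval boundary
    (the constrained optimum has no two-sided derivative there); the
    c-optimal design search requires an interior OBD.
    """
    theta = params.to_array()
    d_star = obd(params, interval)
    if (
        d_star - interval.lower <= boundary_tol
        or interval.upper - d_star <= boundary_tol
    ):
        raise ValueError(
            "gradient undefined at constrained optimum: OBD "
            f"{d_star:.6g} lies on the boundary of [{interval.lower}, "
            f"{interval.upper}]"
        )
    _, dh_dd, grad_theta = _stationarity_terms(d_star, theta)
    if dh_dd == 0.0:
        raise ValueError("degenerate stationary point: zero curvature at OBD")
    return -grad_theta / dh_dd
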