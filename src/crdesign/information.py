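"""Fisher information and design criteria for the CR model.

A continuous (approximate) design is a probability measure on the dose
interval, written xi = {(d_i, rho_i)}.  Its Fisher information matrix is
the weight-averaged per-dose information M(xi, theta) = sum_i rho_i *
mu(d_i, theta).

Because the trinomial likelihood factorises into a toxicity logistic and
a conditional-efficacy logistic, the single-observation information
mu(d, theta) is block diagonal in the canonical parameter order
(alpha_tox, beta_tox, alpha_eff, beta_eff):

    mu(d) = [ pT(1-pT) v v'            0          ]
            [        0        (1-pT) pE(1-pE) v v']

with v = (1, d)'.  The (1-pT) factor in the efficacy block reflects that
conditional efficacy is only observed in patients without toxicity.

Two criteria are implemented: D-optimality, minimising -ln det M, and
c-optimality, minimising the asymptotic variance c' M^{-1} c of the
estimator of a scalar function of theta (here the OBD, with c its
gradient).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CRParams, _peff_cond, _ptox

__all__ = [
    "ContinuousDesign",
    "InformationMatrix",
    "unit_information",
    "design_information",
    "d_criterion",
    "c_criterion",
    "SINGULAR_SENTINEL",
]

#: Value returned by a criterion when the design cannot estimate the
#: quantity of interest (singular information).  Worse than any finite
#: criterion value, so optimisers treat such designs as maximally bad.
SINGULAR_SENTINEL = np.inf

_DET_TOL = 1e-12


@dataclass(frozen=True)
class ContinuousDesign:
    """A design xi = {(d_i, rho_i)}: support doses with probability weights."""

    doses: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "weights", weights)
        if doses.ndim != 1 or doses.size < 1:
            raise ValueError("need at least one support dose")
        if doses.shape != weights.shape:
            raise ValueError("doses and weights must have equal length")
        if not np.all(np.isfinite(doses)) or not np.all(np.isfinite(weights)):
            raise ValueError("doses and weights must be finite")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("support doses must be strictly increasing")
        if np.any(weights <= 0):
            raise ValueError("weights must be strictly positive")
        if abs(weights.sum() - 1.0) > 1e-10:
            raise ValueError(f"weights must sum to 1, got {weights.sum()!r}")

    @property
    def k(self) -> int:
        """Number of support points."""
        return self.doses.size

    def as_table(self):
        """(dose, weight) rows as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame({"dose": self.doses, "weight": self.weights})


@dataclass(frozen=True)
class InformationMatrix:
    """Symmetric PSD 4x4 Fisher information in canonical parameter order."""

    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
        if not np.allclose(m, m.T, atol=1e-12, rtol=0.0):
            raise ValueError("information matrix must be symmetric")
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ValueError("information matrix must be positive semidefinite")

    def __array__(self, dtype=None, copy=None):
        return np.array(self.matrix, dtype=dtype)


def _moment_blocks(doses, weights, params: CRParams):
    """2x2 toxicity and efficacy blocks of M for (batched) designs.

    ``doses``/``weights`` have shape (..., K); returns two arrays of
    shape (..., 2, 2).  The block structure makes both criteria cheap:
    det M = det A * det B and quadratic forms split across blocks.
    """
    doses = np.asarray(doses, dtype=float)
    weights = np.asarray(weights, dtype=float)
    p_t = _ptox(doses, params)
    p_e = _peff_cond(doses, params)
    w_tox = weights * p_t * (1.0 - p_t)
    w_eff = weights * (1.0 - p_t) * p_e * (1.0 - p_e)

    def block(w):
        s0 = w.sum(axis=-1)
        s1 = (w * doses).sum(axis=-1)
        s2 = (w * doses * doses).sum(axis=-1)
        out = np.empty(s0.shape + (2, 2))
        out[..., 0, 0] = s0
        out[..., 0, 1] = s1
        out[..., 1, 0] = s1
        out[..., 1, 1] = s2
        return out

    return block(w_tox), block(w_eff)


def unit_information(d: float, params: CRParams) -> InformationMatrix:
    """Information mu(d, theta) from a single patient observed at dose ``d``."""
    a, b = _moment_blocks(
        np.array([d], dtype=float), np.array([1.0]), params
    )
    m = np.zeros((4, 4))
    m[:2, :2] = a
    m[2:, 2:] = b
    return InformationMatrix(m)


def design_information(design: ContinuousDesign, params: CRParams) -> InformationMatrix:
    """M(xi, theta): the weight-averaged per-dose information."""
    a, b = _moment_blocks(design.doses, design.weights, params)
    m = np.zeros((4, 4))
    m[:2, :2] = a
    m[2:, 2:] = b
    return InformationMatrix(m)


def d_criterion(design: ContinuousDesign, params: CRParams) -> float:
    """D-optimality objective -ln det M(xi, theta) (smaller is better).

    Returns :data:`SINGULAR_SENTINEL` when M is singular (e.g. fewer
    than two support doses, which cannot identify four parameters).
    """
    m = design_information(design, params).matrix
    det = np.linalg.det(m)
    if det <= _DET_TOL:
        return SINGULAR_SENTINEL
    sign, logdet = np.linalg.slogdet(m)
    return float(-logdet)


def c_criterion(design: ContinuousDesign, params: CRParams, cvec: np.ndarray) -> float:
    """c-optimality objective c' M^{-1} c (smaller is better).

    Computed through a linear solve.  For a singular M the value is the
    asymptotic variance only if c lies in the range of M (pseudoinverse
    solve); otherwise the target is not estimable under the design and
    :data:`SINGULAR_SENTINEL` is returned.
    """
    cvec = np.asarray(cvec, dtype=float)
    if cvec.shape != (4,):
        raise ValueError(f"cvec must be a 4-vector, got shape {cvec.shape}")
    m = design_information(design, params).matrix
    if not np.any(cvec):
        return 0.0
    if np.linalg.det(m) > _DET_TOL:
        x = np.linalg.solve(m, cvec)
        return float(cvec @ x)
    x = np.linalg.pinv(m) @ cvec
    if not np.allclose(m @ x, cvec, atol=1e-8 * max(1.0, np.linalg.norm(cvec))):
        return SINGULAR_SENTINEL
    return float(cvec @ x)


# ---------------------------------------------------------------------------
# Batched criterion kernels used by the design search.  They evaluate the
# same objectives as d_criterion / c_criterion but for many candidate
# designs at once, exploiting the 2x2 block structure.

def _det2(block):
    return (
        block[..., 0, 0] * block[..., 1, 1] - block[..., 0, 1] * block[..., 1, 0]
    )


def _solve2(block, rhs):
    """Solve the 2x2 systems block @ x = rhs (batched); rhs shape (2,)."""
    det = _det2(block)
    x0 = (block[..., 1, 1] * rhs[0] - block[..., 0, 1] * rhs[1]) / det
    x1 = (-block[..., 1, 0] * rhs[0] + block[..., 0, 0] * rhs[1]) / det
    return x0, x1


def batched_d_criterion(doses, weights, params: CRParams) -> np.ndarray:
    """-ln det M for designs given as (..., K) dose/weight arrays."""
    a, b = _moment_blocks(doses, weights, params)
    det_a = _det2(a)
    det_b = _det2(b)
    det = det_a * det_b
    with np.errstate(divide="ignore", invalid="ignore"):
        val = -np.log(det)
    return np.where(det > _DET_TOL, val, SINGULAR_SENTINEL)


def batched_c_criterion(doses, weights, params: CRParams, cvec) -> np.ndarray:
    """c' M^{-1} c for designs given as (..., K) dose/weight arrays."""
    cvec = np.asarray(cvec, dtype=float)
    a, b = _moment_blocks(doses, weights, params)
    det = _det2(a) * _det2(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        xa0, xa1 = _solve2(a, cvec[:2])
        xb0, xb1 = _solve2(b, cvec[2:])
        val = cvec[0] * xa0 + cvec[1] * xa1 + cvec[2] * xb0 + cvec[3] * xb1
    return np.where(det > _DET_TOL, val, SINGULAR_SENTINEL)
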