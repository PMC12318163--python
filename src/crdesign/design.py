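"""Locally optimal designs for the CR model and their optimality certificates.

Four design problems are supported, crossing two criteria with two dose
ranges:

* D-optimal (minimise -ln det M) or c-optimal (minimise the asymptotic
  variance of the OBD estimator, c' M^{-1} c with c the OBD gradient);
* unrestricted (doses anywhere in the study interval D) or restricted
  (doses confined to D* = [dL, MTD], protecting patients from doses
  above the maximum tolerated dose).

Designs are found by PSO over a 2k-dimensional encoding (k candidate
doses plus k weight scores mapped to the simplex) and post-processed by
merging near-duplicate support points.  Local optimality is certified
with the General Equivalence Theorem: the criterion's sensitivity
function must be <= 0 across the dose range, with equality at the
support.  An independent multiplicative-weight algorithm on a fixed
dose grid serves as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .information import (
    ContinuousDesign,
    SINGULAR_SENTINEL,
    batched_c_criterion,
    batched_d_criterion,
    c_criterion,
    d_criterion,
    design_information,
    _moment_blocks,
)
from .model import CRParams, DoseInterval, mtd, obd_gradient
from .pso import PSOConfig, minimize

__all__ = [
    "CriterionSpec",
    "SensitivityProfile",
    "OptimalityReport",
    "design_interval",
    "find_design",
    "collapse_design",
    "sensitivity_function",
    "verify_optimality",
    "grid_oracle",
]


@dataclass(frozen=True)
class CriterionSpec:
    """Which design problem to solve.

    ``kind`` is ``"D"`` or ``"c"``; ``restricted`` truncates the design
    interval at the MTD implied by ``gamma`` (which is also the target
    toxicity level used wherever an MTD is needed).
    """

    kind: str
    restricted: bool = False
    gamma: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in ("D", "c"):
            raise ValueError(f"criterion kind must be 'D' or 'c', got {self.kind!r}")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError(f"gamma must be in (0, 1), got {self.gamma}")


@dataclass(frozen=True)
class SensitivityProfile:
    """Sensitivity function phi(d) sampled over the design interval."""

    grid: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    maximum: float
    argmax: float


@dataclass(frozen=True)
class OptimalityReport:
    """Outcome of the equivalence-theorem check."""

    passed: bool
    maximum: float
    argmax: float
    support_values: np.ndarray
    tol: float

    def __bool__(self) -> bool:
        return self.passed


def design_interval(
    spec: CriterionSpec, params: CRParams, interval: DoseInterval
) -> DoseInterval:
    """Dose range available to the design: D itself, or D* = [dL, MTD]."""
    if not spec.restricted:
        return interval
    upper = min(interval.upper, mtd(params, spec.gamma))
    if upper <= interval.lower:
        raise ValueError(
            f"restricted interval empty: MTD {upper:.6g} <= lower dose "
            f"{interval.lower:.6g}"
        )
    return DoseInterval(interval.lower, upper)


def _criterion_cvec(spec: CriterionSpec, params: CRParams, interval: DoseInterval):
    """The c-vector for a c-criterion problem (None for D)."""
    if spec.kind == "D":
        return None
    # the OBD is defined over the full study interval, also for
    # restricted designs
    return obd_gradient(params, interval)


def collapse_design(
    design: ContinuousDesign,
    dose_tol: float = 0.05,
    weight_tol: float = 1e-3,
) -> ContinuousDesign:
    """Tidy a numerically found design into its true support.

    Repeatedly merges the closest pair of adjacent support points lying
    within ``dose_tol`` of each other (weight-averaged dose, summed
    weight), then drops points carrying weight <= ``weight_tol`` and
    renormalises.
    """
    doses = list(map(float, design.doses))
    weights = list(map(float, design.weights))
    while len(doses) > 1:
        gaps = np.diff(doses)
        j = int(np.argmin(gaps))
        if gaps[j] >= dose_tol:
            break
        w = weights[j] + weights[j + 1]
        d = (doses[j] * weights[j] + doses[j + 1] * weights[j + 1]) / w
        doses[j : j + 2] = [d]
        weights[j : j + 2] = [w]
    keep = [i for i, w in enumerate(weights) if w > weight_tol]
    if not keep:
        raise ValueError("collapse dropped every support point")
    doses = np.array([doses[i] for i in keep])
    weights = np.array([weights[i] for i in keep])
    return ContinuousDesign(doses, weights / weights.sum())


def _decode_particle(x: np.ndarray, k: int) -> ContinuousDesign:
    """Turn a 2k particle vector into a valid (sorted, merged) design."""
    doses = np.asarray(x[:k], dtype=float)
    scores = np.asarray(x[k:], dtype=float)
    total = scores.sum()
    weights = scores / total if total > 0 else np.full(k, 1.0 / k)
    order = np.argsort(doses)
    doses, weights = doses[order], weights[order]
    # merge exact duplicates / zero-weight points so the container validates
    out_d, out_w = [doses[0]], [weights[0]]
    for d, w in zip(doses[1:], weights[1:]):
        if d - out_d[-1] < 1e-12:
            out_w[-1] += w
        else:
            out_d.append(d)
            out_w.append(w)
    d_arr = np.array(out_d)
    w_arr = np.array(out_w)
    pos = w_arr > 0
    if not pos.all():
        if not pos.any():
            pos = np.ones_like(pos)
            w_arr = np.full(w_arr.size, 1.0)
        d_arr, w_arr = d_arr[pos], w_arr[pos]
    return ContinuousDesign(d_arr, w_arr / w_arr.sum())


def _batched_objective(spec, params, cvec, k):
    def objective(x: np.ndarray) -> np.ndarray:
        doses = x[:, :k]
        scores = x[:, k:]
        total = scores.sum(axis=1, keepdims=True)
        uniform = np.full_like(scores, 1.0 / k)
        with np.errstate(invalid="ignore", divide="ignore"):
            weights = np.where(total > 0, scores / np.where(total > 0, total, 1.0), uniform)
        if spec.kind == "D":
            return batched_d_criterion(doses, weights, params)
        return batched_c_criterion(doses, weights, params, cvec)

    return objective


def find_design(
    spec: CriterionSpec,
    params: CRParams,
    interval: DoseInterval,
    k: int = 4,
    config: PSOConfig | None = None,
    dose_tol: float = 0.05,
    weight_tol: float = 1e-3,
) -> tuple[ContinuousDesign, float]:
    """Search for the locally optimal design with PSO.

    A particle is a 2k-vector: k candidate doses in the design interval
    followed by k weight scores in [0, 1] that are normalised onto the
    probability simplex (an all-zero score vector maps to uniform
    weights).  ``k`` defaults to the number of model parameters; support
    points the criterion does not need lose their weight and are removed
    by :func:`collapse_design`.

    Returns the collapsed design and its criterion value.
    """
    if k < 2:
        raise ValueError(f"need at least k=2 candidate support points, got {k}")
    cfg = config or PSOConfig()
    box = design_interval(spec, params, interval)
    cvec = _criterion_cvec(spec, params, interval)
    bounds = [(box.lower, box.upper)] * k + [(0.0, 1.0)] * k
    result = minimize(
        _batched_objective(spec, params, cvec, k),
        bounds,
        cfg,
        vectorized=True,
    )
    design = collapse_design(
        _decode_particle(result.position, k), dose_tol, weight_tol
    )
    if spec.kind == "D":
        value = d_criterion(design, params)
    else:
        value = c_criterion(design, params, cvec)
    return design, float(value)


def _sensitivity_values(spec, design, params, cvec, doses):
    """phi(d) at the given doses for the design's information matrix."""
    m = design_information(design, params).matrix
    if np.linalg.det(m) <= 1e-12:
        raise ValueError("singular information matrix: sensitivity undefined")
    doses = np.asarray(doses, dtype=float)
    a_inv = np.linalg.inv(m[:2, :2])
    b_inv = np.linalg.inv(m[2:, 2:])
    # unit information at each dose, via its 2x2 blocks
    ua, ub = _moment_blocks(doses[:, None], np.ones((doses.size, 1)), params)
    v = np.stack([np.ones_like(doses), doses], axis=-1)  # (n, 2)
    if spec.kind == "D":
        # mu's blocks are q * v v', so tr(A^-1 block) = q * v' A^-1 v
        tr_a = ua[:, 0, 0] * np.einsum("ni,ij,nj->n", v, a_inv, v)
        tr_b = ub[:, 0, 0] * np.einsum("ni,ij,nj->n", v, b_inv, v)
        return tr_a + tr_b - 4.0
    x_a = a_inv @ cvec[:2]
    x_b = b_inv @ cvec[2:]
    denom = float(cvec[:2] @ x_a + cvec[2:] @ x_b)
    num = ua[:, 0, 0] * (v @ x_a) ** 2 + ub[:, 0, 0] * (v @ x_b) ** 2
    return num / denom - 1.0


def sensitivity_function(
    spec: CriterionSpec,
    design: ContinuousDesign,
    params: CRParams,
    interval: DoseInterval,
    grid_size: int = 1001,
) -> SensitivityProfile:
    """Equivalence-theorem sensitivity function over the design interval.

    phi_D(d) = tr(M^{-1} mu(d)) - 4 for the D-criterion and
    phi_c(d) = (c' M^{-1} mu(d) M^{-1} c)/(c' M^{-1} c) - 1 for the
    c-criterion.  At an optimal design phi <= 0 everywhere with equality
    on the support.  The support doses are inserted into the evaluation
    grid so the certificate can check them exactly.
    """
    if grid_size < 11:
        raise ValueError("grid too coarse: need at least 11 points")
    box = design_interval(spec, params, interval)
    cvec = _criterion_cvec(spec, params, interval)
    grid = np.union1d(
        np.linspace(box.lower, box.upper, grid_size), design.doses
    )
    values = _sensitivity_values(spec, design, params, cvec, grid)
    i = int(np.argmax(values))
    return SensitivityProfile(
        grid=grid, values=values, maximum=float(values[i]), argmax=float(grid[i])
    )


def verify_optimality(
    profile: SensitivityProfile,
    design: ContinuousDesign,
    tol: float = 1e-3,
) -> OptimalityReport:
    """Check the equivalence-theorem conditions at tolerance ``tol``.

    Passes iff the profile maximum is <= tol and |phi| <= tol at every
    support dose.
    """
    idx = np.searchsorted(profile.grid, design.doses)
    idx = np.clip(idx, 0, profile.grid.size - 1)
    exact = np.isclose(profile.grid[idx], design.doses, rtol=0, atol=1e-9)
    if not exact.all():
        support_values = np.interp(design.doses, profile.grid, profile.values)
    else:
        support_values = profile.values[idx]
    passed = profile.maximum <= tol and bool(np.all(np.abs(support_values) <= tol))
    return OptimalityReport(
        passed=passed,
        maximum=profile.maximum,
        argmax=profile.argmax,
        support_values=np.asarray(support_values),
        tol=tol,
    )


def grid_oracle(
    spec: CriterionSpec,
    params: CRParams,
    interval: DoseInterval,
    grid_size: int = 1001,
    iterations: int = 5000,
    dose_tol: float = 0.25,
    weight_tol: float = 1e-3,
) -> ContinuousDesign:
    """Optimal design by multiplicative weight updates on a fixed dose grid.

    Deterministic and entirely independent of the PSO search, so it
    serves as a cross-check.  Starting from uniform weights on an
    equally spaced grid, each iteration rescales every weight by the
    criterion's directional quantity at its dose (for D: tr(M^{-1}
    mu(d))/4; for c: the square root of the normalised quadratic form)
    and renormalises — a Fedorov–Wynn/Titterington style ascent whose
    fixed points satisfy the equivalence theorem.  The converged grid
    design is tidied with :func:`collapse_design`; after a finite number
    of iterations the weight mass still straddles a short run of
    adjacent grid points around each true support dose, so the default
    merge tolerance here (0.25) is wider than the one used on PSO
    output.
    """
    box = design_interval(spec, params, interval)
    cvec = _criterion_cvec(spec, params, interval)
    grid = np.linspace(box.lower, box.upper, grid_size)
    weights = np.full(grid_size, 1.0 / grid_size)
    v = np.stack([np.ones_like(grid), grid], axis=-1)
    ua, ub = _moment_blocks(grid[:, None], np.ones((grid_size, 1)), params)
    qa, qb = ua[:, 0, 0], ub[:, 0, 0]

    for _ in range(iterations):
        a, b = _moment_blocks(grid, weights, params)
        a_inv = np.linalg.inv(a)
        b_inv = np.linalg.inv(b)
        if spec.kind == "D":
            psi = qa * np.einsum("ni,ij,nj->n", v, a_inv, v) + qb * np.einsum(
                "ni,ij,nj->n", v, b_inv, v
            )
            weights = weights * psi / 4.0
        else:
            x_a = a_inv @ cvec[:2]
            x_b = b_inv @ cvec[2:]
            denom = float(cvec[:2] @ x_a + cvec[2:] @ x_b)
            phi = (qa * (v @ x_a) ** 2 + qb * (v @ x_b) ** 2) / denom
            weights = weights * np.sqrt(phi)
        weights = np.maximum(weights, 0.0)
        weights = weights / weights.sum()

    support = weights > 1e-9
    design = ContinuousDesign(grid[support], weights[support] / weights[support].sum())
    return collapse_design(design, dose_tol, weight_tol)
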