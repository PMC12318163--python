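"""From continuous designs to n-patient trials and their operating characteristics.

A continuous design allocates *proportions* of patients to doses; a real
trial needs integer counts.  :func:`round_design` performs efficient
(Pukelsheim-style) apportionment, which keeps every count within one
patient of the ideal n*rho_i.

Trials are then simulated under the CR model, the model is refitted to
each simulated data set by maximum likelihood (two logistic fits, one
for toxicity and one for conditional efficacy — the factorised trinomial
likelihood), and the MTD/OBD estimates implied by the fit are compared
with the truth.  Replicates whose MLE is undetermined (separation,
non-convergence, an absurd linear predictor, or a non-positive fitted
toxicity slope, which leaves the MTD formula meaningless) are excluded
from bias/SD/RMSE and reported as Pr(NoMLE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .information import ContinuousDesign
from .model import CRParams, DoseInterval, _argmax_p_eff_no_tox, mtd, obd, outcome_probabilities
from scipy.special import logit

__all__ = [
    "ExactDesign",
    "TrialData",
    "FitResult",
    "OperatingCharacteristics",
    "UndeterminedEstimateError",
    "round_design",
    "simulate_trial",
    "fit_cr_mle",
    "estimate_targets",
    "operating_characteristics",
]


class UndeterminedEstimateError(RuntimeError):
    """Raised when a determined fit still yields no usable MTD estimate."""


@dataclass(frozen=True)
class ExactDesign:
    """Integer patient allocation: ``counts[i]`` patients at ``doses[i]``."""

    doses: np.ndarray
    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "counts", counts)
        if doses.shape != counts.shape:
            raise ValueError("doses and counts must have equal length")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if counts.sum() != self.n:
            raise ValueError(f"counts sum to {counts.sum()}, expected n={self.n}")


@dataclass(frozen=True)
class TrialData:
    """Per-patient records: dose given and trinomial outcome (0, 1 or 2)."""

    doses: np.ndarray
    outcomes: np.ndarray

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        outcomes = np.asarray(self.outcomes, dtype=int)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "outcomes", outcomes)
        if doses.shape != outcomes.shape or doses.ndim != 1:
            raise ValueError("doses and outcomes must be equal-length 1-d arrays")
        if doses.size == 0:
            raise ValueError("trial data must be nonempty")
        if not np.isin(outcomes, (0, 1, 2)).all():
            raise ValueError("outcomes must be coded 0, 1 or 2")

    @property
    def n(self) -> int:
        return self.doses.size

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": np.arange(self.n),
                "dose": self.doses,
                "outcome": self.outcomes,
            }
        )


@dataclass(frozen=True)
class FitResult:
    """MLE of the four CR parameters from one trial.

    ``params_hat`` is a plain 4-vector in canonical order with no sign
    constraints; when ``determined`` is False it must not be used.
    """

    params_hat: np.ndarray = field(repr=False)
    determined: bool
    diagnostics: str = ""


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte Carlo summary of MTD/OBD estimation under one design."""

    mtd_bias: float
    mtd_sd: float
    mtd_rmse: float
    obd_bias: float
    obd_sd: float
    obd_rmse: float
    pr_no_mle: float
    n_reps: int
    n_determined: int

    def as_table(self) -> pd.DataFrame:
        rows = [
            ("MTD_bias", self.mtd_bias),
            ("MTD_sd", self.mtd_sd),
            ("MTD_rmse", self.mtd_rmse),
            ("OBD_bias", self.obd_bias),
            ("OBD_sd", self.obd_sd),
            ("OBD_rmse", self.obd_rmse),
            ("pr_no_mle", self.pr_no_mle),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


def round_design(design: ContinuousDesign, n: int) -> ExactDesign:
    """Efficient apportionment of design weights into n patient counts.

    Starts from ``count_i = ceil((n - K/2) * rho_i)`` and, if the counts
    do not already sum to n, repeatedly decrements the dose with the
    largest ``count_i / rho_i`` (over-represented) or increments the one
    with the smallest (under-represented); ties go to the lower dose.
    Every count stays within one patient of the ideal ``n * rho_i``.
    """
    k = design.k
    if n < k:
        raise ValueError(f"need n >= number of support doses ({k}), got n={n}")
    rho = design.weights
    counts = np.ceil((n - k / 2.0) * rho - 1e-12).astype(int)
    while counts.sum() > n:
        j = int(np.argmax(counts / rho))  # argmax takes the first (lowest dose) tie
        counts[j] -= 1
    while counts.sum() < n:
        j = int(np.argmin(counts / rho))
        counts[j] += 1
    return ExactDesign(design.doses.copy(), counts, n)


def simulate_trial(
    exact: ExactDesign,
    params: CRParams,
    rng_seed: int | np.random.SeedSequence | np.random.Generator,
) -> TrialData:
    """Draw one trial: each patient's outcome is trinomial at their dose."""
    if isinstance(rng_seed, np.random.Generator):
        rng = rng_seed
    else:
        rng = np.random.default_rng(rng_seed)
    doses = np.repeat(exact.doses, exact.counts)
    outcomes = np.empty(doses.size, dtype=int)
    start = 0
    for d, m in zip(exact.doses, exact.counts):
        if m == 0:
            continue
        p = outcome_probabilities(float(d), params)
        u = rng.random(m)
        out = np.where(u < p.p_none, 0, np.where(u < p.p_none + p.p_eff, 1, 2))
        outcomes[start : start + m] = out
        start += m
    return TrialData(doses, outcomes)


_MAX_ABS_PREDICTOR = 30.0


def _fit_logistic(doses, successes, totals):
    """One aggregated binomial logistic fit; returns (params, ok, message)."""
    mask = totals > 0
    doses, successes, totals = doses[mask], successes[mask], totals[mask]
    if doses.size < 2:
        return None, False, "fewer than two dose levels with observations"
    exog = np.column_stack([np.ones_like(doses), doses])
    endog = np.column_stack([successes, totals - successes])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-10
            )
    except Exception as exc:  # separation, singular IRLS step, ...
        return None, False, f"fit failed: {exc}"
    if not res.converged:
        return None, False, "IRLS did not converge in 100 iterations"
    beta = np.asarray(res.params, dtype=float)
    lp = exog @ beta
    if not np.all(np.isfinite(beta)) or np.any(np.abs(lp) > _MAX_ABS_PREDICTOR):
        return None, False, "separation: extreme linear predictor"
    return beta, True, "ok"


def fit_cr_mle(data: TrialData) -> FitResult:
    """Maximum likelihood fit of the CR model.

    The trinomial likelihood factorises, so the MLE is obtained from two
    independent binary logistic regressions: toxicity (Z = 2) against
    dose over all patients, and efficacy (Z = 1) against dose over the
    patients without toxicity.  Observations are aggregated per dose
    level before fitting.

    The fit is flagged undetermined — a value, not an error — when
    either regression separates, fails to converge, or produces a linear
    predictor beyond +/-30 at an observed dose.
    """
    doses = np.unique(data.doses)
    tox = np.array(
        [np.sum(data.outcomes[data.doses == d] == 2) for d in doses], dtype=float
    )
    eff = np.array(
        [np.sum(data.outcomes[data.doses == d] == 1) for d in doses], dtype=float
    )
    total = np.array([np.sum(data.doses == d) for d in doses], dtype=float)

    beta_tox, ok_tox, msg_tox = _fit_logistic(doses, tox, total)
    beta_eff, ok_eff, msg_eff = _fit_logistic(doses, eff, total - tox)
    if not (ok_tox and ok_eff):
        parts = []
        if not ok_tox:
            parts.append(f"toxicity: {msg_tox}")
        if not ok_eff:
            parts.append(f"efficacy: {msg_eff}")
        return FitResult(
            params_hat=np.full(4, np.nan), determined=False, diagnostics="; ".join(parts)
        )
    theta = np.array([beta_tox[0], beta_tox[1], beta_eff[0], beta_eff[1]])
    return FitResult(params_hat=theta, determined=True, diagnostics="ok")


def estimate_targets(
    fit: FitResult, gamma: float, interval: DoseInterval
) -> tuple[float, float]:
    """MTD and OBD implied by a fitted model.

    The MTD estimate applies the closed-form percentile formula to the
    fitted toxicity parameters and is *not* truncated to the study
    interval; a non-positive fitted toxicity slope makes the formula
    meaningless and raises :class:`UndeterminedEstimateError` (callers
    reclassify the replicate as undetermined).  The OBD estimate is the
    interval-constrained argmax of the fitted efficacy-without-toxicity
    curve, hence always inside the interval.
    """
    if not fit.determined:
        raise ValueError("estimate_targets called with an undetermined fit")
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    a1, b1 = fit.params_hat[0], fit.params_hat[1]
    # a numerically-zero slope (|b1| below float resolution of the score
    # equations) has an arbitrary sign; the percentile formula is
    # meaningless either way
    if b1 <= 1e-8:
        raise UndeterminedEstimateError(
            f"fitted toxicity slope {b1:.4g} <= 0: MTD undefined"
        )
    mtd_hat = float((logit(gamma) - a1) / b1)
    obd_hat = _argmax_p_eff_no_tox(fit.params_hat, interval.lower, interval.upper)
    return mtd_hat, obd_hat


def operating_characteristics(
    design: ContinuousDesign,
    params: CRParams,
    gamma: float,
    interval: DoseInterval,
    n: int,
    n_reps: int,
    seed: int,
) -> OperatingCharacteristics:
    """Monte Carlo bias/SD/RMSE of the MTD and OBD estimators.

    Rounds the design to ``n`` patients, simulates ``n_reps``
    independent trials, refits the model on each, and summarises the
    estimation error against the true MTD/OBD at the nominal parameters.
    Replicate ``r`` uses the random substream ``(seed, r)`` so any
    single replicate can be rerun in isolation.  Undetermined replicates
    are excluded from the error summaries and counted in ``pr_no_mle``;
    SD uses the population (ddof=0) convention so that
    RMSE^2 = bias^2 + SD^2 holds exactly.
    """
    if n_reps < 2:
        raise ValueError(f"need n_reps >= 2, got {n_reps}")
    exact = round_design(design, n)
    true_mtd = mtd(params, gamma)
    true_obd = obd(params, interval)

    mtd_hats, obd_hats = [], []
    n_undetermined = 0
    for r in range(n_reps):
        data = simulate_trial(exact, params, np.random.SeedSequence([seed, r]))
        fit = fit_cr_mle(data)
        if not fit.determined:
            n_undetermined += 1
            continue
        try:
            mtd_hat, obd_hat = estimate_targets(fit, gamma, interval)
        except UndeterminedEstimateError:
            n_undetermined += 1
            continue
        mtd_hats.append(mtd_hat)
        obd_hats.append(obd_hat)

    if not mtd_hats:
        raise RuntimeError("no replicate produced a determined MLE")

    def summarise(estimates, truth):
        err = np.asarray(estimates) - truth
        bias = float(err.mean())
        sd = float(err.std(ddof=0))
        rmse = float(np.sqrt(np.mean(err**2)))
        return bias, sd, rmse

    mtd_bias, mtd_sd, mtd_rmse = summarise(mtd_hats, true_mtd)
    obd_bias, obd_sd, obd_rmse = summarise(obd_hats, true_obd)
    return OperatingCharacteristics(
        mtd_bias=mtd_bias,
        mtd_sd=mtd_sd,
        mtd_rmse=mtd_rmse,
        obd_bias=obd_bias,
        obd_sd=obd_sd,
        obd_rmse=obd_rmse,
        pr_no_mle=n_undetermined / n_reps,
        n_reps=n_reps,
        n_determined=len(mtd_hats),
    )
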