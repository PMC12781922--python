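"""Simulate longitudinal cohorts whose assessment times depend on the last observed outcome.

The data-generating process mimics a disease-activity study: each subject has a
latent random intercept/slope, a residual Gaussian process with exponential
correlation, and a recurrent assessment (visit) process whose intensity is

    lambda_i(t) = lambda0 * exp(gamma0 * log(1 + Y_i(T_last))),

i.e. proportional to a transform of the outcome at the most recent visit.
Because the intensity covariate only changes at visits, the intensity is
piecewise constant and visit gaps can be drawn exactly as exponential waiting
times -- no thinning is required.  Subjects whose first gap exceeds the
administrative horizon tau have no follow-up at all; they are retained in the
output, since their omission from downstream fits is exactly the phenomenon
this package studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "OutcomeModelSpec",
    "VisitModelSpec",
    "SubjectPath",
    "default_covariate_map",
    "visit_rate",
    "simulate_visit_gap",
    "sample_outcome_at",
    "simulate_cohort",
    "x1",
    "x2",
    "mean_trajectory",
]

#: Mean-model coefficient triples for the two data-generating mechanisms, on
#: the basis (1, X1(t), X2(t)) with X1(t)=1/(1+t)^2 and X2(t)=log(1+t)/(1+t)^2.
MECHANISM_BETA = {1: (3.3, 4.0, 10.5), 2: (3.3, 0.0, 0.0)}


def x1(t):
    """Time basis function 1/(1+t)^2."""
    t = np.asarray(t, dtype=float)
    return 1.0 / (1.0 + t) ** 2


def x2(t):
    """Time basis function log(1+t)/(1+t)^2."""
    t = np.asarray(t, dtype=float)
    return np.log1p(t) / (1.0 + t) ** 2


def default_covariate_map(y: float) -> float:
    """Intensity covariate log(1 + Y), with Y clamped below at 0.

    The motivating disease-activity score is non-negative; the Gaussian
    simulation can stray below -1 where log(1+Y) is undefined, so the input is
    clamped to preserve the monotone outcome-to-intensity link.
    """
    return math.log1p(max(float(y), 0.0))


@dataclass(frozen=True)
class OutcomeModelSpec:
    """Marginal outcome model plus within-subject covariance components.

    The outcome is Y_i(t) = mu(t) + u_i + v_i t + eps_i(t) with
    (u_i, v_i) bivariate Normal and eps_i a Gaussian process with exponential
    correlation: corr(eps(s), eps(t)) = (1 - nugget) * exp(-|s-t|/corr_range)
    for s != t and 1 at zero lag (the nugget is the proportion of residual
    variance that is uncorrelated across arbitrarily close times).

    Parameters
    ----------
    mechanism : {1, 2}
        1 gives the time-varying mean mu01(t) = 3.3 + 4 X1(t) + 10.5 X2(t);
        2 gives the constant mean mu02 = 3.3.
    beta0 : tuple of 3 floats, optional
        Mean-model coefficients; derived from ``mechanism`` when omitted.
    sigma_u, sigma_v : float
        SDs of the random intercept and slope (defaults 1.6, 1.2).
    rho_uv : float
        Intercept-slope correlation (default -0.7).
    sigma_eps : float
        Residual SD (default 1.5).
    corr_range : float
        Exponential-correlation range, in time units (default 0.5).
    nugget : float in [0, 1)
        Uncorrelated proportion of residual variance (default 0.4).
    """

    mechanism: int = 1
    beta0: tuple[float, float, float] | None = None
    sigma_u: float = 1.6
    sigma_v: float = 1.2
    rho_uv: float = -0.7
    sigma_eps: float = 1.5
    corr_range: float = 0.5
    nugget: float = 0.4

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISM_BETA:
            raise ValueError(f"mechanism must be 1 or 2, got {self.mechanism!r}")
        if self.beta0 is None:
            object.__setattr__(self, "beta0", MECHANISM_BETA[self.mechanism])
        else:
            beta0 = tuple(float(b) for b in self.beta0)
            if len(beta0) != 3:
                raise ValueError("beta0 must have three components")
            if beta0 != MECHANISM_BETA[self.mechanism]:
                raise ValueError(
                    f"beta0 {beta0} inconsistent with mechanism {self.mechanism}"
                )
            object.__setattr__(self, "beta0", beta0)
        for name in ("sigma_u", "sigma_v", "sigma_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not abs(self.rho_uv) < 1:
            raise ValueError("|rho_uv| must be < 1")
        if self.corr_range <= 0:
            raise ValueError("corr_range must be positive")
        if not 0 <= self.nugget < 1:
            raise ValueError("nugget must be in [0, 1)")

    def mean(self, t):
        """Marginal mean mu(t) under this mechanism."""
        b0, b1, b2 = self.beta0
        return b0 + b1 * x1(t) + b2 * x2(t)


def mean_trajectory(spec: OutcomeModelSpec, t):
    """Convenience alias for ``spec.mean(t)``."""
    return spec.mean(t)


@dataclass(frozen=True)
class VisitModelSpec:
    """Proportional assessment-intensity model lambda0 * exp(gamma0 * Z).

    Parameters
    ----------
    lambda0 : float
        Baseline intensity, events per unit time (default 0.5).
    gamma0 : float
        Log intensity ratio per unit of Z (default 0.5).
    tau : float
        Administrative follow-up horizon (default 2.0).
    covariate_map : callable
        Rule mapping the last observed outcome to the intensity covariate Z;
        defaults to log(1 + max(Y, 0)).
    """

    lambda0: float = 0.5
    gamma0: float = 0.5
    tau: float = 2.0
    covariate_map: Callable[[float], float] = field(default=default_covariate_map)

    def __post_init__(self) -> None:
        if self.lambda0 < 0:
            raise ValueError("lambda0 must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class SubjectPath:
    """One subject's simulated (or imported) assessment history.

    The baseline outcome at t=0 is observed for everyone but is *not* a
    follow-up assessment (N_i(0) = 0); it seeds the first intensity covariate.
    ``visit_times`` may be empty: zero-follow-up subjects are first-class.
    """

    subject_id: int | str
    baseline_y: float
    visit_times: np.ndarray
    visit_outcomes: np.ndarray
    u: float = float("nan")
    v: float = float("nan")

    def __post_init__(self) -> None:
        self.visit_times = np.asarray(self.visit_times, dtype=float)
        self.visit_outcomes = np.asarray(self.visit_outcomes, dtype=float)
        if self.visit_times.shape != self.visit_outcomes.shape:
            raise ValueError("visit_times and visit_outcomes must align")
        if self.visit_times.size:
            if np.any(np.diff(self.visit_times) <= 0):
                raise ValueError("visit_times must be strictly increasing")
            if self.visit_times[0] <= 0:
                raise ValueError("visit times must be strictly positive")

    @property
    def n_visits(self) -> int:
        """Number of follow-up assessments N_i(tau)."""
        return int(self.visit_times.size)


def visit_rate(last_outcome: float, visit_spec: VisitModelSpec) -> float:
    """Assessment intensity given the last observed outcome."""
    z = visit_spec.covariate_map(last_outcome)
    return visit_spec.lambda0 * math.exp(visit_spec.gamma0 * z)


def simulate_visit_gap(
    last_outcome: float, visit_spec: VisitModelSpec, rng: np.random.Generator
) -> float:
    """Draw the waiting time to the next assessment.

    The intensity is constant between visits (the covariate only changes at
    visits), so the gap is exactly exponential with the current rate.  A zero
    rate returns +inf: the subject has no further visits.
    """
    rate = visit_rate(last_outcome, visit_spec)
    if rate == 0.0:
        return math.inf
    return rng.exponential(1.0 / rate)


def _conditional_residual(
    t: float,
    times: np.ndarray,
    resids: np.ndarray,
    spec: OutcomeModelSpec,
    rng: np.random.Generator,
) -> float:
    """Draw eps(t) | eps(times) under the exponential-correlation covariance."""
    s2 = spec.sigma_eps**2
    if s2 == 0.0:
        return 0.0
    if times.size == 0:
        return rng.normal(0.0, spec.sigma_eps)
    scale = s2 * (1.0 - spec.nugget)
    dmat = np.abs(times[:, None] - times[None, :])
    cov = scale * np.exp(-dmat / spec.corr_range)
    np.fill_diagonal(cov, s2)
    cvec = scale * np.exp(-np.abs(times - t) / spec.corr_range)
    sol = np.linalg.solve(cov, np.column_stack([resids, cvec]))
    mean = float(cvec @ sol[:, 0])
    var = max(float(s2 - cvec @ sol[:, 1]), 0.0)
    return mean + rng.normal(0.0, math.sqrt(var))


def sample_outcome_at(
    t: float,
    history: list[tuple[float, float]],
    u: float,
    v: float,
    spec: OutcomeModelSpec,
    rng: np.random.Generator,
) -> float:
    """Sample Y(t) = mu(t) + u + v t + eps(t) given the residual history.

    ``history`` is a list of (time, residual) pairs at earlier times; the new
    (t, eps) pair is appended in place so the caller can iterate visit by
    visit.
    """
    if not math.isfinite(t) or t < 0:
        raise ValueError(f"time must be finite and non-negative, got {t}")
    times = np.array([h[0] for h in history], dtype=float)
    if times.size and (np.any(np.diff(times) <= 0) or times[-1] >= t):
        raise ValueError("history times must be strictly increasing and precede t")
    resids = np.array([h[1] for h in history], dtype=float)
    eps = _conditional_residual(t, times, resids, spec, rng)
    history.append((t, eps))
    return float(spec.mean(t) + u + v * t + eps)


def _draw_random_effects(
    spec: OutcomeModelSpec, rng: np.random.Generator
) -> tuple[float, float]:
    su, sv, rho = spec.sigma_u, spec.sigma_v, spec.rho_uv
    z1, z2 = rng.standard_normal(2)
    u = su * z1
    v = sv * (rho * z1 + math.sqrt(1.0 - rho**2) * z2)
    return u, v


def simulate_cohort(
    n: int,
    outcome_spec: OutcomeModelSpec | None = None,
    visit_spec: VisitModelSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[SubjectPath]:
    """Simulate ``n`` subjects, alternating visit-gap and outcome draws.

    One root seed spawns an independent stream per subject, so cohorts are
    reproducible regardless of execution order.  Subjects with zero follow-up
    visits are retained in the output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    outcome_spec = outcome_spec or OutcomeModelSpec()
    visit_spec = visit_spec or VisitModelSpec()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(n)
    tau = visit_spec.tau
    n_clamped = 0
    paths: list[SubjectPath] = []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        u, v = _draw_random_effects(outcome_spec, rng)
        history: list[tuple[float, float]] = []
        y0 = sample_outcome_at(0.0, history, u, v, outcome_spec, rng)
        times: list[float] = []
        outcomes: list[float] = []
        t, y_last = 0.0, y0
        while True:
            if y_last < 0:
                n_clamped += 1
            gap = simulate_visit_gap(y_last, visit_spec, rng)
            t = t + gap
            if not math.isfinite(t) or t > tau:
                break
            y = sample_outcome_at(t, history, u, v, outcome_spec, rng)
            times.append(t)
            outcomes.append(y)
            y_last = y
        paths.append(
            SubjectPath(
                subject_id=i,
                baseline_y=y0,
                visit_times=np.array(times),
                visit_outcomes=np.array(outcomes),
                u=u,
                v=v,
            )
        )
    if n_clamped:
        logger.info(
            "intensity covariate clamped at 0 for %d negative outcomes", n_clamped
        )
    return paths
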