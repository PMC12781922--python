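"""Proportional assessment-intensity model on counting-process data.

The recurrent-event (Andersen-Gill) model lambda(t|Z) = lambda0(t) exp(Z gamma)
is fit by maximizing the Cox partial likelihood with Breslow tie handling.
Data arrive as half-open at-risk intervals (start, stop] with an event
indicator at ``stop``; a subject is at risk at time t on a row iff
start < t <= stop, which prevents double counting at visit times.

Two inclusion schemes are supported:

* ``"EV"`` -- everyone: all rows enter the risk sets (zero-visit subjects
  contribute a single censored row and correct the denominators);
* ``"FU"`` -- follow-up only: every subject with zero events is dropped
  entirely before fitting.  This is the common but biased practice the
  package quantifies.

Inverse-intensity weights for the downstream GEE are exp(-Z gamma_hat); the
baseline hazard cancels out of the weighted estimating equation and is never
needed, though a Breslow cumulative-baseline estimator is provided for
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .simulate import SubjectPath, VisitModelSpec

__all__ = [
    "CORE_COLUMNS",
    "IntensityFit",
    "AndersenGillIntensity",
    "build_counting_process",
    "fit_intensity",
    "compute_weights",
    "breslow_cumulative_hazard",
]

#: Fixed column names of the counting-process table; any further columns are
#: intensity covariates.
CORE_COLUMNS = ("subject_id", "start", "stop", "event")


@dataclass
class IntensityFit:
    """Result of a partial-likelihood fit of the intensity model."""

    gamma_hat: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    scheme: str
    separation: bool = False
    covariates: tuple[str, ...] = ()
    n_subjects: int = 0
    n_events: int = 0


def build_counting_process(
    paths: list[SubjectPath], visit_spec: VisitModelSpec
) -> pd.DataFrame:
    """Expand subject paths into at-risk intervals (start, stop].

    Each subject contributes intervals (0, T1], (T1, T2], ..., (Tk, tau] with
    event=1 on all but the final censored interval; the covariate ``z`` on an
    interval is the intensity covariate evaluated at the outcome observed at
    the interval's left endpoint (the baseline outcome for the first).  A
    zero-visit subject contributes the single censored row (0, tau].
    """
    tau = visit_spec.tau
    zmap = visit_spec.covariate_map
    sid, start, stop, event, zval = [], [], [], [], []
    for p in paths:
        times = np.asarray(p.visit_times, dtype=float)
        if times.size and np.unique(times).size != times.size:
            raise ValueError(f"duplicate visit times for subject {p.subject_id}")
        lefts = np.concatenate([[0.0], times])
        rights = np.concatenate([times, [tau]])
        outcomes = np.concatenate([[p.baseline_y], p.visit_outcomes])
        for j in range(lefts.size):
            is_event = j < times.size
            if not is_event and rights[j] <= lefts[j]:
                continue  # last visit fell exactly at tau: no censored tail
            sid.append(p.subject_id)
            start.append(lefts[j])
            stop.append(rights[j])
            event.append(1 if is_event else 0)
            zval.append(zmap(outcomes[j]))
    return pd.DataFrame(
        {"subject_id": sid, "start": start, "stop": stop, "event": event, "z": zval}
    )


def _validate_rows(rows: pd.DataFrame, covariates: list[str] | None):
    missing = [c for c in CORE_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"counting-process table missing columns {missing}")
    if covariates is None:
        covariates = [c for c in rows.columns if c not in CORE_COLUMNS]
    if not covariates:
        raise ValueError("no intensity covariates found")
    start = rows["start"].to_numpy(float)
    stop = rows["stop"].to_numpy(float)
    if np.any(stop <= start):
        raise ValueError("every interval must satisfy start < stop")
    return covariates, start, stop


class _PartialLikelihood:
    """Breslow partial log-likelihood on (start, stop] data.

    Risk sums at each event time t are computed as prefix-sum differences:
    sum over rows with start < t minus sum over rows with stop < t, after
    sorting rows once by start and by stop.  This keeps every Newton step at
    O((rows + events) log rows) with no per-event Python loop.
    """

    def __init__(self, start, stop, event, Z):
        self.Z = Z
        ev = event.astype(bool)
        self.t_event = stop[ev]
        self.z_event = Z[ev]
        self.order_start = np.argsort(start, kind="stable")
        self.order_stop = np.argsort(stop, kind="stable")
        self.start_sorted = start[self.order_start]
        self.stop_sorted = stop[self.order_stop]
        self.idx_start = np.searchsorted(self.start_sorted, self.t_event, side="left")
        self.idx_stop = np.searchsorted(self.stop_sorted, self.t_event, side="left")

    def _risk_sum(self, values: np.ndarray) -> np.ndarray:
        cs = np.concatenate([[0.0], np.cumsum(values[self.order_start])])
        ce = np.concatenate([[0.0], np.cumsum(values[self.order_stop])])
        return cs[self.idx_start] - ce[self.idx_stop]

    def evaluate(self, gamma: np.ndarray):
        """Return (loglik, score, hessian) at gamma."""
        Z = self.Z
        p = Z.shape[1]
        eta = Z @ gamma
        eta_shift = eta.max()  # guard exp overflow during divergent steps
        w = np.exp(eta - eta_shift)
        s0 = self._risk_sum(w)
        s1 = np.empty((self.t_event.size, p))
        for k in range(p):
            s1[:, k] = self._risk_sum(w * Z[:, k])
        zbar = s1 / s0[:, None]
        loglik = float(np.sum(self.z_event @ gamma) - np.sum(np.log(s0)) - self.t_event.size * eta_shift)
        score = (self.z_event - zbar).sum(axis=0)
        hess = np.zeros((p, p))
        for j in range(p):
            for k in range(j, p):
                s2jk = self._risk_sum(w * Z[:, j] * Z[:, k])
                hjk = -np.sum(s2jk / s0 - zbar[:, j] * zbar[:, k])
                hess[j, k] = hess[k, j] = hjk
        return loglik, score, hess


class AndersenGillIntensity(BaseEstimator):
    """Andersen-Gill recurrent-event intensity model, sklearn style.

    Parameters
    ----------
    scheme : {"EV", "FU"}
        "EV" keeps every subject; "FU" first drops all rows of every subject
        with zero events.
    tol_loglik : float
        Convergence threshold on the relative log-likelihood change.
    tol_score : float
        Convergence threshold on the score sup-norm.
    max_iter : int
        Maximum Newton-Raphson iterations (with step halving on any
        likelihood decrease).

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
        Estimated log intensity ratios gamma_hat.
    cov_ : ndarray of shape (p, p)
        Observed-information (inverse negative Hessian) covariance.
    loglik_ : float
        Maximized partial log-likelihood.
    converged_, separation_ : bool
        Convergence flag, and a flag for monotone-likelihood divergence.
    n_iter_, n_events_, n_subjects_ : int
    covariates_ : tuple of str
    """

    def __init__(self, scheme="EV", tol_loglik=1e-9, tol_score=1e-6, max_iter=50):
        self.scheme = scheme
        self.tol_loglik = tol_loglik
        self.tol_score = tol_score
        self.max_iter = max_iter

    def fit(self, rows: pd.DataFrame, covariates: list[str] | None = None):
        if self.scheme not in ("EV", "FU"):
            raise ValueError(f"scheme must be 'EV' or 'FU', got {self.scheme!r}")
        covariates, start, stop = _validate_rows(rows, covariates)
        event = rows["event"].to_numpy(int)
        subject = rows["subject_id"].to_numpy()
        if self.scheme == "FU":
            with_events = pd.unique(subject[event == 1])
            keep = np.isin(subject, with_events)
            rows_kept = rows.loc[keep]
            start, stop = start[keep], stop[keep]
            event, subject = event[keep], subject[keep]
        else:
            rows_kept = rows
        if event.sum() == 0:
            raise ValueError("empty event set: no assessments after scheme filtering")
        Z = rows_kept[covariates].to_numpy(float)
        pl = _PartialLikelihood(start, stop, event, Z)
        p = Z.shape[1]
        gamma = np.zeros(p)
        loglik, score, hess = pl.evaluate(gamma)
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            try:
                step = np.linalg.solve(hess, -score)
            except np.linalg.LinAlgError as err:
                raise ValueError(
                    "singular information matrix: covariate constant across risk sets"
                ) from err
            new_gamma = gamma + step
            new_loglik, new_score, new_hess = pl.evaluate(new_gamma)
            n_halvings = 0
            # halve only on decreases beyond the loglik's floating-point noise,
            # otherwise the final sub-noise Newton step gets rejected and the
            # score stalls just above tolerance
            noise = 1e-12 * (abs(loglik) + 1.0)
            while new_loglik < loglik - noise and n_halvings < 30:
                step /= 2.0
                new_gamma = gamma + step
                new_loglik, new_score, new_hess = pl.evaluate(new_gamma)
                n_halvings += 1
            rel_change = abs(new_loglik - loglik) / (abs(loglik) + 1.0)
            gamma, loglik, score, hess = new_gamma, new_loglik, new_score, new_hess
            if rel_change < self.tol_loglik and np.max(np.abs(score)) < self.tol_score:
                converged = True
                break
        self.separation_ = bool(not converged and np.max(np.abs(gamma)) > 20.0)
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.coef_ = gamma
        try:
            self.cov_ = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            self.cov_ = np.full((p, p), np.nan)
        self.loglik_ = loglik
        self.covariates_ = tuple(covariates)
        self.n_events_ = int(event.sum())
        self.n_subjects_ = int(pd.unique(subject).size)
        return self

    def result_(self) -> IntensityFit:
        """Package the fitted attributes as an :class:`IntensityFit`."""
        return IntensityFit(
            gamma_hat=self.coef_,
            cov=self.cov_,
            loglik=self.loglik_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            scheme=self.scheme,
            separation=self.separation_,
            covariates=self.covariates_,
            n_subjects=self.n_subjects_,
            n_events=self.n_events_,
        )


def fit_intensity(
    rows: pd.DataFrame,
    scheme: str = "EV",
    tol: float = 1e-6,
    max_iter: int = 50,
    covariates: list[str] | None = None,
) -> IntensityFit:
    """Fit the proportional intensity model and return an :class:`IntensityFit`."""
    est = AndersenGillIntensity(scheme=scheme, tol_score=tol, max_iter=max_iter)
    est.fit(rows, covariates=covariates)
    return est.result_()


def compute_weights(
    fit: IntensityFit | AndersenGillIntensity, event_rows: pd.DataFrame
) -> np.ndarray:
    """Inverse-intensity weights exp(-Z gamma_hat) at the observed assessments.

    The baseline hazard does not appear: the weighted estimating equation
    divides by exp(Z gamma) only, and no stabilization is applied.
    """
    if isinstance(fit, AndersenGillIntensity):
        fit = fit.result_()
    if not fit.converged:
        raise ValueError("intensity fit did not converge; refusing to weight")
    cols = list(fit.covariates)
    missing = [c for c in cols if c not in event_rows.columns]
    if missing:
        raise ValueError(f"missing covariate columns at event times: {missing}")
    Z = event_rows[cols].to_numpy(float)
    if np.any(~np.isfinite(Z)):
        raise ValueError("non-finite covariate at an event time")
    return np.exp(-(Z @ fit.gamma_hat))


def breslow_cumulative_hazard(
    fit: IntensityFit, rows: pd.DataFrame
) -> pd.DataFrame:
    """Breslow estimator of the cumulative baseline intensity (diagnostic only)."""
    cols = list(fit.covariates)
    start = rows["start"].to_numpy(float)
    stop = rows["stop"].to_numpy(float)
    event = rows["event"].to_numpy(int).astype(bool)
    w = np.exp(rows[cols].to_numpy(float) @ fit.gamma_hat)
    t_event = np.sort(stop[event])
    denom = np.empty_like(t_event)
    for i, t in enumerate(t_event):
        denom[i] = w[(start < t) & (t <= stop)].sum()
    return pd.DataFrame({"time": t_event, "cumhaz": np.cumsum(1.0 / denom)})
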