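"""Kalman-filter identification of the time-varying shifting parameters.

The drug-effect coefficient gamma(t) and balancing factor beta(t) are
stacked into the state w = (gamma, beta), modelled as a random walk

    w(n) = w(n-1) + mu(n-1),          E[mu mu'] = Q,

and observed through the scaled first difference of the mean calibrated
shifted fraction,

    delta(n) = (rho_av(n+1) - rho_av(n)) / dt
             = C(n) w(n) + nu(n),     C(n) = [1 - rho_av(n), -rho_av(n)],

with measurement-noise variance R.  The filter below is the standard
predict/update recursion for this model; with Q = 0 and a diffuse prior it
reduces to recursive least squares on the delta/C regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MeasurementSeries",
    "KalmanStep",
    "KalmanTrace",
    "ConvergenceReport",
    "build_measurements",
    "kalman_step",
    "estimate_parameters",
    "convergence_diagnostics",
    "estimate_measurement_noise",
]

DEFAULT_Q = 1e-6  # random-walk drift variance per parameter per step
DEFAULT_R = 1e-6  # fallback when no control series is available
#: Prior variance per parameter: SD 0.05/h, weakly informative on the scale
#: of per-hour shift rates (~0.01/h).  A much wider prior lets the weakly
#: identifiable balancing factor absorb large spurious updates during the
#: drug-onset ramp, which persistently biases the drug-effect coefficient.
DEFAULT_P0 = 0.05**2


@dataclass
class MeasurementSeries:
    """delta(n) and C(n) rows derived from a rho_av series (length T-1)."""

    delta: np.ndarray
    C: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (len(self.delta), 2):
            raise ValueError("C must have shape (len(delta), 2)")

    def __len__(self) -> int:
        return len(self.delta)


def build_measurements(rho_av, dt: float = 1.0) -> MeasurementSeries:
    """Scaled first differences and measurement rows from a rho_av series.

    ``delta[n] = (rho_av[n+1] - rho_av[n]) / dt`` and
    ``C[n] = [1 - rho_av[n], -rho_av[n]]`` (left endpoint of each interval).
    """
    r = np.asarray(rho_av, dtype=float)
    if r.ndim != 1 or len(r) < 2:
        raise ValueError("rho_av must be a 1-d series of length >= 2")
    if dt <= 0:
        raise ValueError("dt must be positive")
    delta = np.diff(r) / dt
    left = r[:-1]
    C = np.column_stack([1.0 - left, -left])
    return MeasurementSeries(delta=delta, C=C, dt=dt)


@dataclass
class KalmanStep:
    w_prior: np.ndarray
    P_prior: np.ndarray
    w_post: np.ndarray
    P_post: np.ndarray
    gain: np.ndarray
    innovation: float
    innovation_var: float


def kalman_step(w_post_prev, P_post_prev, delta_n, C_n, Q, R) -> KalmanStep:
    """One predict/update cycle of the parameter filter.

    Exact recursion:

        w-  = w+(prev)
        P-  = P+(prev) + Q
        S   = C P- C' + R
        K   = P- C' / S
        w+  = w- + K (delta - C w-)
        P+  = P- - K C P-

    Raises when the innovation variance S is not positive.
    """
    w_prior = np.asarray(w_post_prev, dtype=float).reshape(2)
    P_prior = np.asarray(P_post_prev, dtype=float).reshape(2, 2) + np.asarray(
        Q, dtype=float
    ).reshape(2, 2)
    c = np.asarray(C_n, dtype=float).reshape(2)
    S = float(c @ P_prior @ c + R)
    if S <= 0:
        raise ValueError(f"singular innovation variance S = {S}")
    K = (P_prior @ c) / S
    innovation = float(delta_n - c @ w_prior)
    w_post = w_prior + K * innovation
    P_post = P_prior - np.outer(K, c) @ P_prior
    P_post = 0.5 * (P_post + P_post.T)  # guard against round-off asymmetry
    return KalmanStep(
        w_prior=w_prior,
        P_prior=P_prior,
        w_post=w_post,
        P_post=P_post,
        gain=K,
        innovation=innovation,
        innovation_var=S,
    )


@dataclass
class KalmanTrace:
    """Per-step filter history over the T-1 measurement intervals.

    Estimates are indexed to the left endpoint time of each difference
    interval.  ``w_post[:, 0]`` is the posterior gamma series, ``w_post[:, 1]``
    the posterior beta series.
    """

    w_prior: np.ndarray  # (T-1, 2)
    w_post: np.ndarray  # (T-1, 2)
    P_prior: np.ndarray  # (T-1, 2, 2)
    P_post: np.ndarray  # (T-1, 2, 2)
    gain: np.ndarray  # (T-1, 2)
    innovations: np.ndarray  # (T-1,)
    innovation_var: np.ndarray  # (T-1,)
    Q: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    R: float = 0.0
    w0: np.ndarray = field(default_factory=lambda: np.zeros(2))
    P0: np.ndarray = field(default_factory=lambda: np.eye(2))
    dt: float = 1.0
    time_h: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return self.w_post.shape[0]

    @property
    def gamma(self) -> np.ndarray:
        return self.w_post[:, 0]

    @property
    def beta(self) -> np.ndarray:
        return self.w_post[:, 1]

    def to_frame(self, dose_uM: Optional[float] = None):
        import pandas as pd

        t = self.time_h if self.time_h is not None else np.arange(len(self)) * self.dt
        df = pd.DataFrame(
            {
                "time_h": t,
                "gamma_hat": self.w_post[:, 0],
                "beta_hat": self.w_post[:, 1],
                "gamma_prior": self.w_prior[:, 0],
                "beta_prior": self.w_prior[:, 1],
                "P11": self.P_post[:, 0, 0],
                "P12": self.P_post[:, 0, 1],
                "P22": self.P_post[:, 1, 1],
                "innovation": self.innovations,
            }
        )
        if dose_uM is not None:
            df.insert(0, "dose_uM", dose_uM)
        return df


def estimate_parameters(
    rho_av,
    Q=None,
    R: float = DEFAULT_R,
    w0=None,
    P0=None,
    dt: float = 1.0,
    time_h=None,
) -> KalmanTrace:
    """Run the parameter filter over a rho_av series.

    Defaults: Q = 1e-6 I (random-walk drift that lets the filter track
    slowly time-varying parameters), w0 = 0 (no drug effect assumed before
    evidence), P0 = 0.05^2 I (weakly informative on the scale of per-hour
    rates).  R should be set to the
    measurement-noise variance of delta; when control wells are available,
    :func:`estimate_measurement_noise` provides an estimate.
    """
    Q = np.eye(2) * DEFAULT_Q if Q is None else np.asarray(Q, dtype=float)
    if Q.shape != (2, 2):
        raise ValueError("Q must be 2x2")
    if np.linalg.eigvalsh(0.5 * (Q + Q.T)).min() < -1e-12:
        raise ValueError("Q must be positive semidefinite")
    if R <= 0:
        raise ValueError("R must be positive")
    w = np.zeros(2) if w0 is None else np.asarray(w0, dtype=float).reshape(2)
    P = np.eye(2) * DEFAULT_P0 if P0 is None else np.asarray(P0, dtype=float).reshape(2, 2)
    if np.linalg.eigvalsh(0.5 * (P + P.T)).min() < -1e-12:
        raise ValueError("P0 must be positive semidefinite")
    meas = build_measurements(rho_av, dt)
    n = len(meas)
    trace = KalmanTrace(
        w_prior=np.empty((n, 2)),
        w_post=np.empty((n, 2)),
        P_prior=np.empty((n, 2, 2)),
        P_post=np.empty((n, 2, 2)),
        gain=np.empty((n, 2)),
        innovations=np.empty(n),
        innovation_var=np.empty(n),
        Q=Q,
        R=R,
        w0=w.copy(),
        P0=P.copy(),
        dt=dt,
        time_h=None if time_h is None else np.asarray(time_h, dtype=float)[: len(rho_av) - 1],
    )
    for i in range(n):
        step = kalman_step(w, P, meas.delta[i], meas.C[i], Q, R)
        trace.w_prior[i] = step.w_prior
        trace.w_post[i] = step.w_post
        trace.P_prior[i] = step.P_prior
        trace.P_post[i] = step.P_post
        trace.gain[i] = step.gain
        trace.innovations[i] = step.innovation
        trace.innovation_var[i] = step.innovation_var
        w, P = step.w_post, step.P_post
    return trace


@dataclass
class ConvergenceReport:
    """Where (if anywhere) the estimate settled, plus step-wise diagnostics."""

    converged: bool
    step: Optional[int]
    rel_change: np.ndarray
    innovation_var: np.ndarray


def convergence_diagnostics(
    trace: KalmanTrace, tol: float = 1e-3, patience: int = 3
) -> ConvergenceReport:
    """First step at which the relative estimate change stays below ``tol``.

    The relative change at step n is ||w+(n) - w+(n-1)|| / max(||w+(n)||, eps);
    the filter is declared converged at the first n such that the change
    stays below ``tol`` for ``patience`` consecutive steps.  A trace with
    fewer than ``patience + 1`` steps cannot converge by this rule.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if patience < 1:
        raise ValueError("patience must be at least 1")
    if len(trace) == 0:
        raise ValueError("empty trace")
    w = trace.w_post
    dw = np.linalg.norm(np.diff(w, axis=0), axis=1)
    denom = np.maximum(np.linalg.norm(w[1:], axis=1), 1e-12)
    rel = dw / denom
    step: Optional[int] = None
    if len(rel) >= patience:
        ok = rel < tol
        for i in range(len(ok) - patience + 1):
            if ok[i : i + patience].all():
                step = i + 1  # change i corresponds to estimate index i+1
                break
    return ConvergenceReport(
        converged=step is not None,
        step=step,
        rel_change=rel,
        innovation_var=trace.innovation_var.copy(),
    )


def estimate_measurement_noise(
    control_rho: np.ndarray, dt: float = 1.0, n_replicates: int = 1, n_control_wells: int = None
) -> float:
    """Measurement-noise variance R for delta, from control-well series.

    ``control_rho`` holds one shifted-fraction series per control well,
    shape (n_wells, T).  The per-well first-difference variance estimates the
    sampling noise of a single well's increment; the measurement fed to the
    filter averages ``n_replicates`` drug wells and subtracts a pooled
    control aggregate, so the returned variance is

        var_well * (1 / n_replicates + 1 / n_control_wells).
    """
    r = np.atleast_2d(np.asarray(control_rho, dtype=float))
    if r.shape[1] < 2:
        raise ValueError("control series must have at least 2 timepoints")
    deltas = np.diff(r, axis=1) / dt
    var_well = float(deltas.var(ddof=1))
    if n_control_wells is None:
        n_control_wells = r.shape[0]
    R = var_well * (1.0 / max(n_replicates, 1) + 1.0 / max(n_control_wells, 1))
    return max(R, 1e-12)
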