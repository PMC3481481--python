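"""Forward model of the cell-shifting dynamics and its probabilistic basis.

The mean calibrated shifted fraction rho_av(t) is modelled by the linear
time-varying ODE

    d rho_av / dt = (gamma + mu1) (1 - rho_av) - (beta + mu2) rho_av + nu

where gamma(t) is the drug-effect coefficient (rate at which non-shifted
cells shift under drug, 1/h), beta(t) > 0 a balancing factor opposing
further accumulation, mu = (mu1, mu2) zero-mean Gaussian process noise with
covariance Q perturbing the parameters, and nu zero-mean Gaussian
measurement noise with variance R on the observed increment.  The forward
model is discretised by forward Euler on the hourly sampling grid — the same
discretisation the identification stage assumes — so filter and simulator
are mutually consistent.

Also provided: the exact binomial-vs-Gaussian approximation error that
justifies treating the shifted-cell count in a large well as Gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats

__all__ = [
    "ShiftModelParams",
    "simulate_shift_ode",
    "steady_state",
    "binomial_gaussian_distance",
]


def _as_series(x, n_steps: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_steps, float(arr))
    if arr.shape != (n_steps,):
        raise ValueError(f"{name} must be scalar or length-{n_steps}, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _check_psd(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (2, 2):
        raise ValueError("Q must be 2x2")
    if not np.allclose(Q, Q.T):
        raise ValueError("Q must be symmetric")
    eig = np.linalg.eigvalsh(Q)
    if eig.min() < -1e-12:
        raise ValueError("Q must be positive semidefinite")
    return Q


@dataclass
class ShiftModelParams:
    """Parameters driving the cell-shifting ODE.

    gamma and beta may be scalars (time-constant) or per-step arrays; Q is
    the 2x2 process-noise covariance of (mu1, mu2), R the scalar measurement
    noise variance, dt the sampling interval in hours.
    """

    gamma: Union[float, np.ndarray] = 0.01
    beta: Union[float, np.ndarray] = 0.01
    Q: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    R: float = 0.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.Q = _check_psd(self.Q)
        if self.R < 0:
            raise ValueError("R must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def _psd_sqrt(Q: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(Q)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_shift_ode(
    params: ShiftModelParams,
    rho0: float,
    n_steps: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    noiseless: bool = False,
) -> np.ndarray:
    """Forward-Euler trajectory of the cell-shifting ODE.

    Returns an array of length ``n_steps + 1`` starting at ``rho0``.  In the
    noiseless case (``noiseless=True`` or Q = 0 and R = 0) the recursion is
    exactly

        rho[n+1] = rho[n] + dt * (gamma[n] - (gamma[n] + beta[n]) * rho[n])

    which stays in [0, 1] whenever (gamma + beta) * dt <= 1.  In the noisy
    case, mu(n) ~ N(0, Q) perturbs the parameters and nu(n) ~ N(0, R) is
    added to the observed increment, independently across steps; noisy
    trajectories are not clipped (mirroring negative experimental rho).
    """
    if not 0.0 <= rho0 <= 1.0:
        raise ValueError("rho0 must lie in [0, 1]")
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    gamma = _as_series(params.gamma, n_steps, "gamma") if n_steps else np.empty(0)
    beta = _as_series(params.beta, n_steps, "beta") if n_steps else np.empty(0)
    deterministic = noiseless or (np.all(params.Q == 0) and params.R == 0)
    if deterministic and n_steps and np.any((gamma + beta) * params.dt > 1 + 1e-12):
        warnings.warn(
            "(gamma + beta) * dt exceeds 1: noiseless Euler step may leave [0, 1]",
            stacklevel=2,
        )
    if not deterministic and rng is None:
        rng = np.random.default_rng(seed)
    sq = None if deterministic else _psd_sqrt(params.Q)
    traj = np.empty(n_steps + 1)
    traj[0] = rho0
    r = rho0
    for n in range(n_steps):
        g, b = gamma[n], beta[n]
        if not deterministic:
            mu = sq @ rng.standard_normal(2)
            nu = rng.normal(0.0, np.sqrt(params.R)) if params.R > 0 else 0.0
            g, b = g + mu[0], b + mu[1]
            incr = g * (1.0 - r) - b * r + nu
        else:
            incr = g * (1.0 - r) - b * r
        r = r + params.dt * incr
        traj[n + 1] = r
    return traj


def steady_state(gamma: float, beta: float) -> float:
    """Noiseless fixed point of the shifting ODE: gamma / (gamma + beta)."""
    if gamma < 0 or beta < 0:
        raise ValueError("gamma and beta must be non-negative")
    if gamma + beta == 0:
        raise ValueError("steady state undefined for gamma = beta = 0")
    return gamma / (gamma + beta)


def binomial_gaussian_distance(
    N: int, p: float, continuity_correction: bool = False
) -> float:
    """Sup-CDF distance between Binomial(N, p) and its normal approximation.

    Enumerates the exact binomial CDF over the integer support and compares
    it against Normal(Np, Np(1-p)) evaluated at k (or k + 1/2 with the
    continuity correction).  Quantifies how quickly the shifted-cell count in
    an N-cell well becomes Gaussian as N grows.
    """
    if N < 1:
        raise ValueError("N must be a positive integer")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p in (0.0, 1.0):
        warnings.warn("degenerate p: distance 0 by convention", stacklevel=2)
        return 0.0
    k = np.arange(N + 1)
    exact = stats.binom.cdf(k, N, p)
    loc = N * p
    scale = np.sqrt(N * p * (1 - p))
    x = k + 0.5 if continuity_correction else k.astype(float)
    approx = stats.norm.cdf(x, loc=loc, scale=scale)
    return float(np.max(np.abs(exact - approx)))
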