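"""Model/Results interface to the cell-shifting identification.

`CellShiftModel` wraps the Kalman identification of the time-varying
drug-effect coefficient gamma(t) and balancing factor beta(t) from a mean
calibrated shifted-fraction series rho_av(t), in the style of a statsmodels
estimator: construct from data, call ``fit()``, and work with the returned
``CellShiftResults`` (estimates, uncertainties, diagnostics, smoothing,
plateau detection, summary table, plots).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import kalman, smoothing
from .kalman import KalmanTrace

__all__ = ["CellShiftModel", "CellShiftResults"]


class CellShiftModel:
    """Time-varying cell-shifting model for one dose condition.

    Parameters
    ----------
    endog : array-like
        Mean calibrated shifted fraction rho_av(t) on a uniform hourly grid.
    time_h : array-like, optional
        Time grid in hours (default 0, dt, 2·dt, ...).
    dt : float
        Sampling interval in hours.
    dose_uM : float, optional
        Dose label carried into outputs.
    control_rho : array-like, optional
        Control-well shifted-fraction series (n_wells, T) used to estimate
        the measurement-noise variance R when ``fit`` is not given one.
    n_replicates : int
        Number of drug replicate wells averaged into ``endog`` (used by the
        control-based R estimate).
    """

    def __init__(
        self,
        endog,
        time_h=None,
        dt: float = 1.0,
        dose_uM: Optional[float] = None,
        control_rho=None,
        n_replicates: int = 1,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.ndim != 1 or len(self.endog) < 2:
            raise ValueError("endog must be a 1-d series of length >= 2")
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.dt = float(dt)
        if time_h is None:
            time_h = np.arange(len(self.endog)) * self.dt
        self.time_h = np.asarray(time_h, dtype=float)
        if len(self.time_h) != len(self.endog):
            raise ValueError("time_h must match endog length")
        steps = np.diff(self.time_h)
        if len(steps) and not np.allclose(steps, self.dt):
            raise ValueError("time_h must be uniform with spacing dt")
        self.dose_uM = dose_uM
        self.control_rho = None if control_rho is None else np.atleast_2d(control_rho)
        self.n_replicates = int(n_replicates)

    @classmethod
    def from_dataframe(
        cls,
        df,
        value_col: str = "rho_av",
        time_col: str = "time_h",
        dose_uM: Optional[float] = None,
        **kwargs,
    ) -> "CellShiftModel":
        """Build from a tidy frame with time and rho_av columns (one dose)."""
        for col in (value_col, time_col):
            if col not in df.columns:
                raise ValueError(f"dataframe is missing column {col!r}")
        d = df.sort_values(time_col)
        t = d[time_col].to_numpy(dtype=float)
        dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
        return cls(
            d[value_col].to_numpy(dtype=float), time_h=t, dt=dt, dose_uM=dose_uM, **kwargs
        )

    def fit(self, Q=None, R: Optional[float] = None, w0=None, P0=None) -> "CellShiftResults":
        """Run the Kalman identification and return a results object.

        ``R`` defaults to the control-based estimate when control series
        were supplied at construction, otherwise to a small fallback.
        """
        if R is None:
            if self.control_rho is not None:
                R = kalman.estimate_measurement_noise(
                    self.control_rho, dt=self.dt, n_replicates=self.n_replicates
                )
            else:
                R = kalman.DEFAULT_R
        trace = kalman.estimate_parameters(
            self.endog, Q=Q, R=R, w0=w0, P0=P0, dt=self.dt, time_h=self.time_h
        )
        return CellShiftResults(self, trace)


class CellShiftResults:
    """Fitted time-varying parameter traces with uncertainties and tools."""

    def __init__(self, model: CellShiftModel, trace: KalmanTrace) -> None:
        self.model = model
        self.trace = trace
        #: left-endpoint times of the difference intervals
        self.time_h = model.time_h[:-1]

    # --- estimates -------------------------------------------------------
    @property
    def gamma(self) -> np.ndarray:
        """Posterior drug-effect coefficient series (1/h)."""
        return self.trace.w_post[:, 0]

    @property
    def beta(self) -> np.ndarray:
        """Posterior balancing-factor series (1/h)."""
        return self.trace.w_post[:, 1]

    @property
    def gamma_se(self) -> np.ndarray:
        return np.sqrt(self.trace.P_post[:, 0, 0])

    @property
    def beta_se(self) -> np.ndarray:
        return np.sqrt(self.trace.P_post[:, 1, 1])

    @property
    def params(self) -> np.ndarray:
        """Final posterior state (gamma, beta)."""
        return self.trace.w_post[-1]

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Per-step normal confidence bands, shape (T-1, 2, 2)."""
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        se = np.stack([self.gamma_se, self.beta_se], axis=1)
        lo = self.trace.w_post - z * se
        hi = self.trace.w_post + z * se
        return np.stack([lo, hi], axis=2)

    @property
    def innovations(self) -> np.ndarray:
        return self.trace.innovations

    # --- diagnostics and post-processing ---------------------------------
    def convergence(self, tol: float = 1e-3, patience: int = 3):
        return kalman.convergence_diagnostics(self.trace, tol=tol, patience=patience)

    def smoothed(
        self,
        window: int = smoothing.DEFAULT_WINDOW,
        degree: int = smoothing.DEFAULT_DEGREE,
        burn_in_h: float = smoothing.DEFAULT_BURN_IN_H,
        edge: str = "onesided",
    ) -> smoothing.SmoothedTrace:
        """Savitzky–Golay smoothed traces with the burn-in window removed."""
        return smoothing.smooth_parameter_trace(
            self.time_h,
            self.gamma,
            self.beta,
            window=window,
            degree=degree,
            burn_in_h=burn_in_h,
            edge=edge,
            dose_uM=self.model.dose_uM,
        )

    def plateau(
        self, band_frac: float = 0.05, hold_h: float = 8.0, **smooth_kwargs
    ) -> Optional[smoothing.Plateau]:
        """Plateau of the smoothed drug-effect coefficient, if reached."""
        tr = self.smoothed(**smooth_kwargs)
        return smoothing.detect_plateau(tr.time_h, tr.gamma_smooth, band_frac, hold_h)

    def fittedvalues(self) -> np.ndarray:
        """One-step-ahead predicted increments C(n) @ w_prior(n)."""
        meas = kalman.build_measurements(self.model.endog, self.model.dt)
        return np.einsum("ij,ij->i", meas.C, self.trace.w_prior)

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        conv = self.convergence()
        plat = self.plateau()
        lines = [
            "        Cell-shifting model: Kalman identification",
            "=" * 58,
            f"Dose:                {self.model.dose_uM if self.model.dose_uM is not None else '-'} uM",
            f"Observations:        {len(self.model.endog)} (steps: {len(self.trace)})",
            f"Sampling dt:         {self.model.dt} h",
            f"Process noise Q:     diag({self.trace.Q[0, 0]:.3g}, {self.trace.Q[1, 1]:.3g})",
            f"Measurement noise R: {self.trace.R:.3g}",
            "-" * 58,
            f"{'':16s}{'estimate':>12s}{'std err':>12s}",
            f"{'gamma (final)':16s}{self.params[0]:>12.5f}{self.gamma_se[-1]:>12.5f}",
            f"{'beta  (final)':16s}{self.params[1]:>12.5f}{self.beta_se[-1]:>12.5f}",
            "-" * 58,
            f"Converged:           {conv.converged}"
            + (f" (step {conv.step})" if conv.converged else ""),
            "Plateau:             "
            + (
                f"level {plat.level:.4g}, onset {plat.onset_h:g} h"
                if plat is not None
                else "not reached"
            ),
            "=" * 58,
        ]
        return "\n".join(lines)

    # --- plotting ---------------------------------------------------------
    def plot(self, ax=None, show_bands: bool = True):
        """Plot raw and smoothed parameter traces over time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.time_h, self.gamma, color="C0", alpha=0.4, label="gamma (filtered)")
        ax.plot(self.time_h, self.beta, color="C1", alpha=0.4, label="beta (filtered)")
        if show_bands:
            ax.fill_between(
                self.time_h,
                self.gamma - 1.96 * self.gamma_se,
                self.gamma + 1.96 * self.gamma_se,
                color="C0",
                alpha=0.1,
            )
        tr = self.smoothed()
        ax.plot(tr.time_h, tr.gamma_smooth, color="C0", lw=2, label="gamma (smoothed)")
        ax.plot(tr.time_h, tr.beta_smooth, color="C1", lw=2, label="beta (smoothed)")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("rate (1/h)")
        if self.model.dose_uM is not None:
            ax.set_title(f"{self.model.dose_uM:g} uM")
        ax.legend(fontsize=8)
        return ax
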