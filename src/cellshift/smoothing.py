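"""Post-processing of identified parameter traces.

The raw filtered estimates are jittery, especially over the first ~10 hours
while cells commit to a response and noise dominates.  Post-processing
therefore (i) smooths each trace with a Savitzky–Golay moving average —
an unweighted local least-squares fit of a 2nd-degree polynomial over a
5-point span — (ii) discards the burn-in window (first 10 h by default),
(iii) locates the plateau of the smoothed drug-effect coefficient at high
doses, and (iv) tabulates dose comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

__all__ = [
    "SmoothedTrace",
    "Plateau",
    "savgol_smooth",
    "truncate_burn_in",
    "smooth_parameter_trace",
    "detect_plateau",
    "compare_doses",
]

DEFAULT_WINDOW = 5
DEFAULT_DEGREE = 2
DEFAULT_BURN_IN_H = 10.0


def savgol_smooth(
    series, window: int = DEFAULT_WINDOW, degree: int = DEFAULT_DEGREE, edge: str = "onesided"
) -> np.ndarray:
    """Savitzky–Golay smoothing: local least-squares polynomial fit.

    Each interior point is replaced by the centre value of the degree-``degree``
    polynomial fitted (unweighted least squares) to its ``window``-point
    neighbourhood; for window 5, degree 2 the equivalent convolution weights
    are (-3, 12, 17, 12, -3)/35.  Edges:

    - ``edge="onesided"``: the polynomial is fitted to the outermost full
      window and evaluated at the edge points (one-sided fit);
    - ``edge="shrink"``: centred windows shrink near the edges, with the
      degree reduced when the window no longer supports it.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-d")
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    if degree >= window:
        raise ValueError("window must exceed the polynomial degree")
    if len(x) < window:
        raise ValueError(f"series length {len(x)} shorter than window {window}")
    if edge == "onesided":
        return savgol_filter(x, window, degree, mode="interp")
    if edge != "shrink":
        raise ValueError("edge must be 'onesided' or 'shrink'")
    out = savgol_filter(x, window, degree, mode="interp")
    half = window // 2
    for i in list(range(half)) + list(range(len(x) - half, len(x))):
        h = min(i, len(x) - 1 - i)
        if h == 0:
            out[i] = x[i]
            continue
        deg = min(degree, 2 * h)
        sl = x[i - h : i + h + 1]
        coeffs = savgol_coeffs(2 * h + 1, deg)
        out[i] = coeffs @ sl[::-1]
    return out


def truncate_burn_in(time_h, *series, burn_in_h: float = DEFAULT_BURN_IN_H):
    """Drop all points with t <= burn_in_h (strict retention of t > cutoff).

    Returns ``(time, *series)`` truncated; raises if nothing is retained.
    """
    t = np.asarray(time_h, dtype=float)
    mask = t > burn_in_h
    if not mask.any():
        raise ValueError(f"burn-in cutoff {burn_in_h} h leaves no data")
    out = [t[mask]]
    for s in series:
        s = np.asarray(s)
        if s.shape[-1] != len(t):
            raise ValueError("series length does not match time grid")
        out.append(s[..., mask])
    return tuple(out)


@dataclass
class SmoothedTrace:
    """Smoothed, burn-in-truncated parameter traces for one dose."""

    time_h: np.ndarray
    gamma_smooth: np.ndarray
    beta_smooth: np.ndarray
    window: int
    degree: int
    burn_in_h: float
    dose_uM: Optional[float] = None

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < self.degree + 1:
            raise ValueError("window must be odd and >= degree + 1")
        if not (len(self.time_h) == len(self.gamma_smooth) == len(self.beta_smooth)):
            raise ValueError("trace arrays must share length")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "time_h": self.time_h,
                "gamma_smooth": self.gamma_smooth,
                "beta_smooth": self.beta_smooth,
            }
        )
        if self.dose_uM is not None:
            df.insert(0, "dose_uM", self.dose_uM)
        return df


def smooth_parameter_trace(
    time_h,
    gamma,
    beta,
    window: int = DEFAULT_WINDOW,
    degree: int = DEFAULT_DEGREE,
    burn_in_h: float = DEFAULT_BURN_IN_H,
    edge: str = "onesided",
    dose_uM: Optional[float] = None,
) -> SmoothedTrace:
    """Smooth full-length traces, then truncate the burn-in window.

    Smoothing before truncation keeps the filter's edge effects inside the
    discarded burn-in region at the left boundary.
    """
    gs = savgol_smooth(gamma, window, degree, edge)
    bs = savgol_smooth(beta, window, degree, edge)
    t, gs, bs = truncate_burn_in(time_h, gs, bs, burn_in_h=burn_in_h)
    return SmoothedTrace(
        time_h=t,
        gamma_smooth=gs,
        beta_smooth=bs,
        window=window,
        degree=degree,
        burn_in_h=burn_in_h,
        dose_uM=dose_uM,
    )


@dataclass
class Plateau:
    level: float
    onset_h: float


def detect_plateau(
    time_h, series, band_frac: float = 0.05, hold_h: float = 8.0
) -> Optional[Plateau]:
    """Locate the plateau of a smoothed trace, if it has one.

    The plateau level is the mean of the final ``hold_h`` hours; the onset is
    the first time from which the series stays within ±``band_frac``·level of
    that level through the end of the trace.  Returns ``None`` when the trace
    never enters and holds the band (e.g. a strictly rising series whose last
    point still lies outside it).
    """
    t = np.asarray(time_h, dtype=float)
    x = np.asarray(series, dtype=float)
    if len(t) == 0 or len(t) != len(x):
        raise ValueError("time and series must be non-empty and equal length")
    if band_frac <= 0 or hold_h <= 0:
        raise ValueError("band_frac and hold_h must be positive")
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    n_hold = max(1, int(round(hold_h / dt)))
    level = float(x[-n_hold:].mean())
    band = band_frac * abs(level)
    within = np.abs(x - level) <= band + 1e-15
    if not within[-1]:
        return None
    out = np.nonzero(~within)[0]
    onset_idx = 0 if len(out) == 0 else int(out[-1]) + 1
    return Plateau(level=level, onset_h=float(t[onset_idx]))


def _slope_with_se(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    tc = t - t.mean()
    sxx = float(tc @ tc)
    slope = float(tc @ y / sxx)
    resid = y - y.mean() - slope * tc
    dof = max(len(t) - 2, 1)
    se = float(np.sqrt(resid @ resid / dof / sxx))
    return slope, se


def compare_doses(
    smoothed: dict,
    band_frac: float = 0.05,
    hold_h: float = 8.0,
    order_tol: float = 0.0,
):
    """Dose-response summary table across smoothed traces.

    One row per dose (ascending): mean and max smoothed drug-effect
    coefficient, plateau level/onset when present, mean balancing factor and
    its temporal slope (with standard error).  The ``gamma_ordered`` column
    flags whether the mean drug-effect coefficient is non-decreasing along
    the dose ladder (within ``order_tol``) with some strict separation —
    identical traces are not counted as ordered.
    """
    import pandas as pd

    if len(smoothed) < 2:
        raise ValueError("need at least two doses to compare")
    doses = sorted(smoothed)
    grid = smoothed[doses[0]].time_h
    for d in doses[1:]:
        if not np.array_equal(smoothed[d].time_h, grid):
            raise ValueError("smoothed traces are not on a common time grid")
    rows = []
    for d in doses:
        tr = smoothed[d]
        plat = detect_plateau(tr.time_h, tr.gamma_smooth, band_frac, hold_h)
        slope, slope_se = _slope_with_se(tr.time_h, tr.beta_smooth)
        rows.append(
            {
                "dose_uM": d,
                "gamma_mean": float(tr.gamma_smooth.mean()),
                "gamma_max": float(tr.gamma_smooth.max()),
                "plateau_level": plat.level if plat else np.nan,
                "plateau_onset_h": plat.onset_h if plat else np.nan,
                "beta_mean": float(tr.beta_smooth.mean()),
                "beta_slope": slope,
                "beta_slope_se": slope_se,
            }
        )
    df = pd.DataFrame(rows)
    diffs = np.diff(df["gamma_mean"].to_numpy())
    ordered = bool(np.all(diffs >= -order_tol) and np.any(diffs > order_tol))
    df["gamma_ordered"] = ordered
    df.attrs["gamma_ordered"] = ordered
    return df
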