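"""Shifted-cell quantification: thresholding, calibration, replicate pooling.

Converts per-cell log2 intensity series into the measurement the dynamic
model consumes: the calibrated shifted fraction

    rho(t) = rho1(t) - rho1c(t)

where rho1 is the shifted fraction in a drug well and rho1c the fraction in
the pooled drug-free control wells.  Calibration removes environmental
(non-drug) shifting; the result may legitimately be negative, especially in
the first hours before the drug acts, and is never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .simulate import PlateDataset, WellRecord

__all__ = [
    "ShiftSeries",
    "classify_shifted",
    "shift_fraction",
    "control_fraction",
    "calibrate",
    "aggregate_replicates",
    "auto_threshold",
    "quantify_plate",
]

#: Default classification threshold: midpoint between the autofluorescence
#: floor (log2 = 14) and the reporter on-mode (log2 = 18).
DEFAULT_THRESHOLD_LOG2 = 16.0


def classify_shifted(log2_intensity, threshold_log2: float = DEFAULT_THRESHOLD_LOG2):
    """True where a cell's intensity is strictly below the threshold.

    A shifted cell is one whose reporter has switched off, dropping its
    intensity to the autofluorescence floor.  The tie rule is strict
    inequality: a reading exactly at the threshold is *not* shifted.
    """
    x = np.asarray(log2_intensity, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite intensity value")
    if not np.isfinite(threshold_log2):
        raise ValueError("threshold must be finite")
    out = x < threshold_log2
    return bool(out) if out.ndim == 0 else out


def shift_fraction(well: WellRecord, threshold_log2: float = DEFAULT_THRESHOLD_LOG2) -> np.ndarray:
    """Shifted fraction over time for one well: shifted count / n_cells."""
    if well.n_cells == 0:
        raise ValueError(f"well {well.well_id} has no cells")
    return classify_shifted(well.intensities, threshold_log2).mean(axis=0)


def control_fraction(
    control_wells: list, threshold_log2: float = DEFAULT_THRESHOLD_LOG2
) -> tuple[np.ndarray, int]:
    """Cell-weighted pooled shifted fraction across control wells.

    Pools all control wells into one aggregate (total shifted count over
    total cell count per timepoint), maximising control precision.  Returns
    ``(fraction_series, total_cells)``.
    """
    if not control_wells:
        raise ValueError("no control wells to pool")
    shifted = sum(
        classify_shifted(w.intensities, threshold_log2).sum(axis=0) for w in control_wells
    )
    total = sum(w.n_cells for w in control_wells)
    return shifted / total, total


def calibrate(rho1: np.ndarray, rho1c: np.ndarray) -> np.ndarray:
    """Calibrated shifted fraction rho = rho1 - rho1c (elementwise).

    Negative values are preserved: with noise the drug-well fraction can dip
    below the control fraction before the drug takes effect.
    """
    a = np.asarray(rho1, dtype=float)
    b = np.asarray(rho1c, dtype=float)
    if a.shape[-1] != b.shape[-1]:
        raise ValueError(
            f"time-grid mismatch: rho1 has {a.shape[-1]} points, rho1c has {b.shape[-1]}"
        )
    return a - b


def aggregate_replicates(rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error across replicate series.

    ``rho`` has shape (n_replicates, n_timepoints).  The mean is the
    per-timepoint arithmetic mean; the standard error is the sample SD over
    replicates divided by sqrt(n).  With a single replicate the SE is
    undefined and returned as NaN.
    """
    r = np.atleast_2d(np.asarray(rho, dtype=float))
    if r.shape[0] == 0:
        raise ValueError("no replicate series to aggregate")
    mean = r.mean(axis=0)
    if r.shape[0] == 1:
        se = np.full(r.shape[1], np.nan)
    else:
        se = r.std(axis=0, ddof=1) / np.sqrt(r.shape[0])
    return mean, se


def auto_threshold(plate: PlateDataset, n_bins: int = 64) -> float:
    """Minimum-density threshold from the pooled first-timepoint histogram.

    Picks the centre of the least-populated interior bin between the two
    outermost occupied bins.  Only meaningful when the pooled first-timepoint
    distribution is already bimodal; early in an assay (no shifted cells yet)
    the histogram is unimodal and the fixed midpoint default is preferable.
    """
    first = np.concatenate([w.intensities[:, 0] for w in plate.wells])
    counts, edges = np.histogram(first, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = np.nonzero(counts)[0]
    lo, hi = occupied[0], occupied[-1]
    if hi - lo < 2:
        return float(centers[(lo + hi) // 2])
    interior = slice(lo + 1, hi)
    k = int(np.argmin(counts[interior])) + lo + 1
    return float(centers[k])


@dataclass
class ShiftSeries:
    """Per-dose shifted-fraction time series and its calibrated aggregate.

    Attributes
    ----------
    dose : float
        Drug concentration in µM.
    time_grid : ndarray
        Hours, shared by all series.
    rho1 : ndarray, shape (n_replicates, T)
        Raw shifted fraction per drug replicate well.
    rho1c : ndarray, shape (T,)
        Pooled control shifted fraction.
    rho : ndarray, shape (n_replicates, T)
        Calibrated series rho1 - rho1c (may be negative).
    rho_av : ndarray, shape (T,)
        Mean calibrated fraction across replicates — the measurement fed to
        the identification stage.
    rho_se : ndarray, shape (T,)
        Standard error of rho_av across replicates (NaN for one replicate).
    n_cells : ndarray
        Cells per drug replicate well.
    n_control_cells : int
        Total cells pooled into the control aggregate.
    """

    dose: float
    time_grid: np.ndarray
    rho1: np.ndarray
    rho1c: np.ndarray
    rho: np.ndarray
    rho_av: np.ndarray
    rho_se: np.ndarray
    n_cells: np.ndarray
    n_control_cells: int

    @property
    def n_replicates(self) -> int:
        return self.rho1.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "dose_uM": self.dose,
                "time_h": self.time_grid,
                "rho1_mean": self.rho1.mean(axis=0),
                "rho1c": self.rho1c,
                "rho_av": self.rho_av,
                "rho_se": self.rho_se,
                "n_replicates": self.n_replicates,
            }
        )


def quantify_plate(
    plate: PlateDataset,
    threshold_log2: Optional[float] = DEFAULT_THRESHOLD_LOG2,
) -> dict:
    """Quantify every dose on a plate against the pooled control aggregate.

    Passing ``threshold_log2=None`` selects the threshold automatically from
    the pooled first-timepoint histogram (see :func:`auto_threshold`).
    Returns ``{dose_uM: ShiftSeries}``.
    """
    if threshold_log2 is None:
        threshold_log2 = auto_threshold(plate)
    rho1c, n_ctrl = control_fraction(plate.control_wells(), threshold_log2)
    out: dict = {}
    for dose in plate.doses:
        wells = plate.drug_wells(dose)
        rho1 = np.vstack([shift_fraction(w, threshold_log2) for w in wells])
        rho = calibrate(rho1, rho1c)
        rho_av, rho_se = aggregate_replicates(rho)
        out[dose] = ShiftSeries(
            dose=dose,
            time_grid=plate.time_grid,
            rho1=rho1,
            rho1c=rho1c,
            rho=rho,
            rho_av=rho_av,
            rho_se=rho_se,
            n_cells=np.array([w.n_cells for w in wells]),
            n_control_cells=n_ctrl,
        )
    return out
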