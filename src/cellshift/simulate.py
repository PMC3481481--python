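"""Monte Carlo generator of synthetic fluorescent-reporter assay plates.

Emulates a multiwell dosing study on a proliferation-reporter cell line:
each well holds a fixed population of cells imaged hourly; every cell carries
a latent binary state ("shifted" = reporter switched off, intensity at the
autofluorescence floor; "non-shifted" = reporter on).  Per hour, a
non-shifted cell shifts via an independent Bernoulli trial whose probability
is derived from a per-hour hazard rate; shifts are absorbing by default.
Observed log2 intensity is the latent mode plus i.i.d. Gaussian noise.

The dose→hazard map is a Hill saturation in dose multiplied by a logistic
onset in time, so that the drug effect appears after a latency of roughly
ten hours and saturates for high doses — the qualitative behaviour the
analysis downstream is designed to detect and quantify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "HazardParams",
    "SimConfig",
    "WellRecord",
    "PlateDataset",
    "drug_effect_rate",
    "hazard_from_rate",
    "shift_hazard",
    "simulate_plate",
    "simulate_histogram_timecourse",
]


@dataclass(frozen=True)
class HazardParams:
    """Parameters of the latent dose- and time-dependent shift hazard.

    The per-hour shift *rate* for a cell in a well at dose ``d`` (µM) and
    time ``t`` (hours after drug addition) is

        gamma(d, t) = gamma_plateau * d^h / (ec50^h + d^h) * sigmoid((t - onset_h) / onset_width_h)

    i.e. a Hill saturation in dose times a logistic onset in time.  The
    per-hour shift *probability* is ``1 - exp(-gamma * dt)``, which keeps the
    latent rate directly comparable to the drug-effect coefficient recovered
    by the identification stage.

    Parameters
    ----------
    gamma_plateau : float
        Saturating per-hour shift rate at high dose and late time (1/h).
    ec50_uM : float
        Dose at half-maximal rate (µM).
    hill : float
        Hill coefficient of the dose saturation (dimensionless).
    onset_h : float
        Midpoint of the logistic onset in time (hours).
    onset_width_h : float
        Width (scale) of the logistic onset (hours).
    """

    gamma_plateau: float = 0.01
    ec50_uM: float = 4.0
    hill: float = 2.0
    onset_h: float = 8.0
    onset_width_h: float = 1.5

    def __post_init__(self) -> None:
        if self.gamma_plateau < 0:
            raise ValueError("gamma_plateau must be non-negative")
        if self.ec50_uM <= 0:
            raise ValueError("ec50_uM must be positive")
        if self.onset_width_h <= 0:
            raise ValueError("onset_width_h must be positive")

    def plateau_rate(self, dose: float) -> float:
        """Late-time (plateau) per-hour shift rate at ``dose`` µM."""
        d = float(dose)
        if d < 0:
            raise ValueError("dose must be non-negative")
        if d == 0:
            return 0.0
        return float(
            self.gamma_plateau * d**self.hill / (self.ec50_uM**self.hill + d**self.hill)
        )


def drug_effect_rate(dose, t, params: HazardParams):
    """Latent per-hour shift rate gamma(dose, t) (1/h).

    Vectorised over ``dose`` and ``t``.  Raises on negative dose or time.
    """
    d = np.asarray(dose, dtype=float)
    tt = np.asarray(t, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    if np.any(tt < 0):
        raise ValueError("time must be non-negative")
    with np.errstate(divide="ignore"):
        sat = np.where(
            d > 0,
            d**params.hill / (params.ec50_uM**params.hill + d**params.hill),
            0.0,
        )
    onset = expit((tt - params.onset_h) / params.onset_width_h)
    out = params.gamma_plateau * sat * onset
    if out.ndim == 0:
        return float(out)
    return out


def hazard_from_rate(rate, dt: float = 1.0):
    """Convert a per-hour hazard rate into a per-step shift probability.

    ``p = 1 - exp(-rate * dt)``, the survival-law discretisation: constant
    rate gamma over k steps leaves a non-shifted fraction ``exp(-gamma k dt)``.
    """
    r = np.asarray(rate, dtype=float)
    if np.any(r < 0):
        raise ValueError("hazard rate must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = -np.expm1(-r * dt)
    return float(p) if p.ndim == 0 else p


def shift_hazard(dose, t, params: HazardParams, dt: float = 1.0):
    """Per-step shift probability for a non-shifted cell at (dose, t)."""
    return hazard_from_rate(drug_effect_rate(dose, t, params), dt)


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic dosing-study plate.

    Defaults reproduce the study design emulated by this package: 6 lapatinib
    doses from 1 to 32 µM, 6 replicate wells per dose, 36 drug-free control
    wells, 200–400 cells per well, hourly imaging for 48 h, reporter on-mode
    at log2 intensity 18 and autofluorescence floor at 14.
    """

    doses: tuple = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    wells_per_dose: int = 6
    control_wells: int = 36
    cells_per_well_range: tuple = (200, 400)
    n_timepoints: int = 48
    dt_h: float = 1.0
    on_mode_log2: float = 18.0
    floor_log2: float = 14.0
    intensity_sd_log2: float = 0.3
    hazard_params: HazardParams = field(default_factory=HazardParams)
    control_hazard: float = 0.001
    reversion_prob: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.doses) == 0 and self.control_wells == 0:
            raise ValueError("config defines zero wells")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive concentrations (µM)")
        if self.wells_per_dose < 0 or self.control_wells < 0:
            raise ValueError("well counts must be non-negative")
        if len(self.doses) * self.wells_per_dose + self.control_wells == 0:
            raise ValueError("config defines zero wells")
        lo, hi = self.cells_per_well_range
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer))):
            raise ValueError("cells_per_well_range must be integers")
        if lo < 1 or hi < lo:
            raise ValueError("cells_per_well_range must satisfy 1 <= min <= max")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be at least 1")
        if self.dt_h <= 0:
            raise ValueError("dt_h must be positive")
        if not self.floor_log2 < self.on_mode_log2:
            raise ValueError("floor_log2 must be below on_mode_log2")
        if self.intensity_sd_log2 < 0:
            raise ValueError("intensity_sd_log2 must be non-negative")
        if not 0.0 <= self.control_hazard:
            raise ValueError("control_hazard must be non-negative")
        if not 0.0 <= self.reversion_prob <= 1.0:
            raise ValueError("reversion_prob must be in [0, 1]")

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_timepoints, dtype=float) * self.dt_h


@dataclass
class WellRecord:
    """One well: per-cell log2 intensity time series plus metadata.

    ``intensities`` has shape (n_cells, n_timepoints); ``latent_states`` (the
    simulation's ground-truth shifted flags, same shape) is kept for recovery
    tests and is absent for wells read from experimental CSVs.
    """

    well_id: str
    condition: str  # "drug" or "control"
    dose_uM: Optional[float]
    replicate: int
    intensities: np.ndarray
    latent_states: Optional[np.ndarray] = None

    @property
    def n_cells(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.intensities.shape[1]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a (n_cells, n_timepoints) matrix")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"well {self.well_id}: non-finite intensity")
        if self.latent_states is not None:
            self.latent_states = np.asarray(self.latent_states, dtype=bool)
            if self.latent_states.shape != self.intensities.shape:
                raise ValueError("latent_states shape must match intensities")


@dataclass
class PlateDataset:
    """A full plate: wells plus the common (uniform, increasing) time grid."""

    wells: list
    time_grid: np.ndarray
    config: Optional[SimConfig] = None

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if len(self.time_grid) > 1:
            steps = np.diff(self.time_grid)
            if np.any(steps <= 0):
                raise ValueError("time grid must be strictly increasing")
            if not np.allclose(steps, steps[0]):
                raise ValueError("time grid must be uniformly spaced")
        for w in self.wells:
            if w.n_timepoints != len(self.time_grid):
                raise ValueError(
                    f"well {w.well_id}: {w.n_timepoints} timepoints, grid has {len(self.time_grid)}"
                )

    @property
    def doses(self) -> list:
        return sorted({w.dose_uM for w in self.wells if w.condition == "drug"})

    def drug_wells(self, dose: float) -> list:
        return [w for w in self.wells if w.condition == "drug" and w.dose_uM == dose]

    def control_wells(self) -> list:
        return [w for w in self.wells if w.condition == "control"]


def _well_rng(master_seed: int, kind: int, i: int, j: int) -> np.random.Generator:
    # spawn_key keyed by well identity: adding wells/doses never perturbs
    # the stream of an existing well.
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(kind, i, j)))


def _simulate_well(
    rng: np.random.Generator, rates: np.ndarray, cfg: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one well; returns (intensities, latent_states).

    The observation at grid index n reflects the state *before* the n-th
    Bernoulli transition, so under a constant per-step probability p the
    expected non-shifted fraction at hour t is exactly (1 - p)^t.
    """
    lo, hi = cfg.cells_per_well_range
    n_cells = int(rng.integers(lo, hi + 1))
    T = cfg.n_timepoints
    probs = hazard_from_rate(rates, cfg.dt_h)
    latent = np.zeros((n_cells, T), dtype=bool)
    state = np.zeros(n_cells, dtype=bool)
    for n in range(T):
        latent[:, n] = state
        u = rng.random(n_cells)
        state = state | (~state & (u < probs[n]))
        if cfg.reversion_prob > 0:
            rev = latent[:, n] & (rng.random(n_cells) < cfg.reversion_prob)
            state = state & ~rev
    modes = np.where(latent, cfg.floor_log2, cfg.on_mode_log2)
    noise = rng.normal(0.0, cfg.intensity_sd_log2, size=latent.shape)
    return modes + noise, latent


def simulate_plate(config: SimConfig) -> PlateDataset:
    """Simulate a full plate under ``config``.

    One :class:`WellRecord` per configured well.  Drug wells experience the
    control (environmental) baseline hazard *plus* the dose-dependent drug
    hazard, so that subtracting the control shifted fraction downstream
    isolates the drug component.  Identical ``master_seed`` yields a
    bit-identical dataset.
    """
    t = config.time_grid
    wells: list[WellRecord] = []
    for i, dose in enumerate(config.doses):
        rates = config.control_hazard + np.asarray(
            drug_effect_rate(dose, t, config.hazard_params), dtype=float
        )
        for j in range(config.wells_per_dose):
            rng = _well_rng(config.master_seed, 0, i, j)
            intens, latent = _simulate_well(rng, rates, config)
            wells.append(
                WellRecord(
                    well_id=f"D{dose:g}_r{j}",
                    condition="drug",
                    dose_uM=float(dose),
                    replicate=j,
                    intensities=intens,
                    latent_states=latent,
                )
            )
    ctrl_rates = np.full(config.n_timepoints, config.control_hazard, dtype=float)
    for k in range(config.control_wells):
        rng = _well_rng(config.master_seed, 1, 0, k)
        intens, latent = _simulate_well(rng, ctrl_rates, config)
        wells.append(
            WellRecord(
                well_id=f"CTRL_r{k}",
                condition="control",
                dose_uM=None,
                replicate=k,
                intensities=intens,
                latent_states=latent,
            )
        )
    return PlateDataset(wells=wells, time_grid=t, config=config)


def simulate_histogram_timecourse(
    config: SimConfig,
    n_bins: int = 25,
    dose: Optional[float] = None,
    support: Optional[tuple] = None,
):
    """Per-timepoint normalised log2-intensity histograms for one condition.

    Simulates the plate, pools all cells of the requested condition (``dose``
    in µM, ``"control"``, or the first configured dose when omitted) and
    histograms their intensities per timepoint over ``support`` (default:
    floor to one unit above the on-mode, matching the [2^14, 2^19] display
    range of the assay).  Intensities are clipped into the support so every
    histogram sums to exactly 1.

    Returns ``(bin_edges, hist)`` with ``hist`` of shape (n_timepoints, n_bins).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    plate = simulate_plate(config)
    if dose is None:
        if not config.doses:
            raise ValueError("config has no drug doses; pass dose='control'")
        dose = config.doses[0]
    if dose == "control":
        wells = plate.control_wells()
    else:
        wells = plate.drug_wells(float(dose))
    if not wells or sum(w.n_cells for w in wells) == 0:
        raise ValueError(f"no cells found for condition {dose!r}")
    if support is None:
        support = (config.floor_log2, config.on_mode_log2 + 1.0)
    lo, hi = support
    if not lo < hi:
        raise ValueError("support must be an increasing interval")
    pooled = np.vstack([w.intensities for w in wells])  # (cells, T)
    pooled = np.clip(pooled, lo, hi)
    edges = np.linspace(lo, hi, n_bins + 1)
    T = pooled.shape[1]
    hist = np.empty((T, n_bins))
    for n in range(T):
        counts, _ = np.histogram(pooled[:, n], bins=edges)
        hist[n] = counts / counts.sum()
    return edges, hist
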