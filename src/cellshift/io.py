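"""CSV dialects, configuration handling and the end-to-end pipeline.

The long-format plate CSV has columns
``well_id,condition,dose_uM,replicate,cell_id,time_h,log2_intensity``;
conditions are ``drug`` or ``control`` (controls leave ``dose_uM`` empty).
All downstream artifacts (shift series, parameter traces, smoothed traces,
dose summary) are tidy CSVs, and a JSON manifest records the configuration
and seed so that any run can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import kalman
from .model import CellShiftModel
from .quantify import quantify_plate, shift_fraction
from .simulate import HazardParams, PlateDataset, SimConfig, WellRecord, simulate_plate
from .smoothing import compare_doses

__all__ = [
    "PLATE_COLUMNS",
    "read_plate_csv",
    "write_plate_csv",
    "write_latent_csv",
    "write_shift_series_csv",
    "read_shift_series_csv",
    "write_trace_csv",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]

log = logging.getLogger("cellshift")

PLATE_COLUMNS = [
    "well_id",
    "condition",
    "dose_uM",
    "replicate",
    "cell_id",
    "time_h",
    "log2_intensity",
]


def write_plate_csv(plate: PlateDataset, path, latent: bool = False) -> None:
    """Write a plate as long-format CSV (optionally with the latent truth)."""
    frames = []
    T = len(plate.time_grid)
    for w in plate.wells:
        n = w.n_cells
        d = {
            "well_id": np.repeat(w.well_id, n * T),
            "condition": np.repeat(w.condition, n * T),
            "dose_uM": np.repeat(np.nan if w.dose_uM is None else w.dose_uM, n * T),
            "replicate": np.repeat(w.replicate, n * T),
            "cell_id": np.repeat(np.arange(n), T),
            "time_h": np.tile(plate.time_grid, n),
            "log2_intensity": w.intensities.ravel(),
        }
        if latent:
            if w.latent_states is None:
                raise ValueError(f"well {w.well_id} has no latent states to write")
            d["shifted"] = w.latent_states.ravel().astype(int)
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


def write_latent_csv(plate: PlateDataset, path) -> None:
    """Plate CSV including the simulation-truth ``shifted`` column."""
    write_plate_csv(plate, path, latent=True)


def read_plate_csv(path) -> PlateDataset:
    """Read a long-format plate CSV back into a :class:`PlateDataset`.

    Validates required columns, numeric intensities, per-well uniform time
    grids, and uniqueness of (well_id, cell_id, time_h) keys; cell ordering
    within a well is stable (sorted by cell id).
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad = df.index[~np.isfinite(pd.to_numeric(df["log2_intensity"], errors="coerce"))]
    if len(bad):
        raise ValueError(f"{path}: non-numeric log2_intensity at row {bad[0] + 2}")
    dup = df.duplicated(subset=["well_id", "cell_id", "time_h"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (well_id, cell_id, time_h) = "
            f"({row.well_id}, {row.cell_id}, {row.time_h})"
        )
    time_grid = np.sort(df["time_h"].unique()).astype(float)
    if len(time_grid) > 1:
        steps = np.diff(time_grid)
        if not np.allclose(steps, steps[0]):
            raise ValueError(f"{path}: non-uniform time grid {time_grid[:5]}...")
    has_latent = "shifted" in df.columns
    wells = []
    for well_id, g in df.groupby("well_id", sort=True):
        piv = g.pivot(index="cell_id", columns="time_h", values="log2_intensity")
        piv = piv.sort_index().reindex(columns=time_grid)
        if piv.isna().any().any():
            raise ValueError(f"{path}: well {well_id} has a ragged time grid")
        latent = None
        if has_latent:
            lat = g.pivot(index="cell_id", columns="time_h", values="shifted")
            latent = lat.sort_index().reindex(columns=time_grid).to_numpy().astype(bool)
        cond = str(g["condition"].iloc[0])
        dose = g["dose_uM"].iloc[0]
        wells.append(
            WellRecord(
                well_id=str(well_id),
                condition=cond,
                dose_uM=None if pd.isna(dose) else float(dose),
                replicate=int(g["replicate"].iloc[0]),
                intensities=piv.to_numpy(dtype=float),
                latent_states=latent,
            )
        )
    return PlateDataset(wells=wells, time_grid=time_grid)


def write_shift_series_csv(series: dict, path) -> None:
    """Tidy per-dose shifted-fraction CSV (one block per dose)."""
    pd.concat([s.to_frame() for _, s in sorted(series.items())], ignore_index=True).to_csv(
        path, index=False
    )


def read_shift_series_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"dose_uM", "time_h", "rho_av"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def write_trace_csv(traces: dict, path) -> None:
    """Per-dose Kalman trace CSV in the identification dialect."""
    pd.concat(
        [tr.to_frame(dose_uM=d) for d, tr in sorted(traces.items())], ignore_index=True
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class KalmanConfig:
    q_scale: float = kalman.DEFAULT_Q
    r: Optional[float] = None  # None -> estimate from control wells
    w0: tuple = (0.0, 0.0)
    p0_scale: float = kalman.DEFAULT_P0


@dataclass
class SmoothingConfig:
    window: int = 5
    degree: int = 2
    burn_in_h: float = 10.0
    edge: str = "onesided"


@dataclass
class PlateauConfig:
    band_frac: float = 0.05
    hold_h: float = 8.0


@dataclass
class PipelineConfig:
    """Single configuration artifact governing every pipeline stage."""

    sim: SimConfig = field(default_factory=SimConfig)
    input_csv: Optional[str] = None  # when set, simulation is skipped
    outdir: str = "results"
    threshold_log2: Optional[float] = 16.0
    kalman: KalmanConfig = field(default_factory=KalmanConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    plateau: PlateauConfig = field(default_factory=PlateauConfig)
    write_plate: bool = True
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("doses", "cells_per_well_range"):
            d["sim"][key] = list(d["sim"][key])
        d["kalman"]["w0"] = list(d["kalman"]["w0"])
        return d

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        if "hazard_params" in sim:
            sim["hazard_params"] = HazardParams(**sim["hazard_params"])
        if "doses" in sim:
            sim["doses"] = tuple(float(x) for x in sim["doses"])
        if "cells_per_well_range" in sim:
            sim["cells_per_well_range"] = tuple(int(x) for x in sim["cells_per_well_range"])
        kal = dict(d.pop("kalman", {}))
        if "w0" in kal:
            kal["w0"] = tuple(float(x) for x in kal["w0"])
        return cls(
            sim=SimConfig(**sim),
            kalman=KalmanConfig(**kal),
            smoothing=SmoothingConfig(**d.pop("smoothing", {})),
            plateau=PlateauConfig(**d.pop("plateau", {})),
            **d,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    plate: PlateDataset
    series: dict
    results: dict  # dose -> CellShiftResults
    smoothed: dict  # dose -> SmoothedTrace
    summary: pd.DataFrame
    manifest: dict


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute simulate (or load) → quantify → identify → post-process.

    Writes every artifact plus a manifest (config hash and seed) into the
    output directory; identical config and seed reproduce every output
    byte-for-byte.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    stage = "simulate"
    try:
        if config.input_csv:
            stage = "load"
            plate = read_plate_csv(config.input_csv)
            log.info("load: %d wells from %s", len(plate.wells), config.input_csv)
        else:
            plate = simulate_plate(config.sim)
            log.info(
                "simulate: %d wells (%d doses), %d timepoints, seed %d",
                len(plate.wells),
                len(config.sim.doses),
                config.sim.n_timepoints,
                config.sim.master_seed,
            )
            if config.write_plate:
                write_plate_csv(plate, out / "plate.csv")

        stage = "quantify"
        series = quantify_plate(plate, config.threshold_log2)
        write_shift_series_csv(series, out / "shift_series.csv")
        log.info("quantify: %d doses, threshold %s", len(series), config.threshold_log2)

        stage = "identify"
        ctrl = np.vstack(
            [shift_fraction(w, config.threshold_log2 or 16.0) for w in plate.control_wells()]
        ) if plate.control_wells() else None
        Q = np.eye(2) * config.kalman.q_scale
        P0 = np.eye(2) * config.kalman.p0_scale
        results = {}
        for dose, s in series.items():
            m = CellShiftModel(
                s.rho_av,
                time_h=s.time_grid,
                dt=float(np.diff(s.time_grid)[0]) if len(s.time_grid) > 1 else 1.0,
                dose_uM=dose,
                control_rho=ctrl,
                n_replicates=s.n_replicates,
            )
            results[dose] = m.fit(Q=Q, R=config.kalman.r, w0=config.kalman.w0, P0=P0)
        write_trace_csv({d: r.trace for d, r in results.items()}, out / "traces.csv")
        log.info("identify: fitted %d doses", len(results))

        stage = "postprocess"
        smoothed = {
            d: r.smoothed(
                window=config.smoothing.window,
                degree=config.smoothing.degree,
                burn_in_h=config.smoothing.burn_in_h,
                edge=config.smoothing.edge,
            )
            for d, r in results.items()
        }
        pd.concat(
            [tr.to_frame() for _, tr in sorted(smoothed.items())], ignore_index=True
        ).to_csv(out / "smoothed.csv", index=False)
        summary = compare_doses(
            smoothed, band_frac=config.plateau.band_frac, hold_h=config.plateau.hold_h
        )
        summary.to_csv(out / "summary.csv", index=False)
        log.info("postprocess: summary for %d doses in %.1f s", len(summary), time.perf_counter() - t0)
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "master_seed": config.sim.master_seed,
        "outputs": sorted(p.name for p in out.iterdir() if p.suffix == ".csv"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(
        plate=plate,
        series=series,
        results=results,
        smoothed=smoothed,
        summary=summary,
        manifest=manifest,
    )
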