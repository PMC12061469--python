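"""End-to-end orchestration: measurements -> variation -> temperature
correction -> Mantel -> group comparison.

Every stage after measurement is a pure function of the per-call
measurement table plus the individual metadata, so re-running from the
persisted measurement CSV reproduces the downstream tables exactly.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .audio_features import (
    highpass_filter,
    measure_recording,
    measurements_to_frame,
    read_wav,
    select_calls,
)
from .errors import InsufficientDataError, InvalidParameterError
from .geography import haversine_matrix, mantel_table
from .group_comparison import compare_groups, kde_summary
from .synthetic_data import generate_parameter_table, metadata_frame, study_population_config
from .temperature import apply_correction, fit_models, models_to_frame, reference_temperature
from .types import PARAMETER_NAMES, RecordingMetadata, SpectrogramConfig
from .variation import individual_means, to_long, variation_table

logger = logging.getLogger("callvar")

METADATA_COLUMNS = ("individual_id", "locality", "group",
                    "latitude", "longitude", "temperature_c")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    mode: str                              # "audio" | "table" | "simulate"
    output_dir: str
    audio_metadata_csv: str | None = None  # audio mode: has wav_path column
    measurements_csv: str | None = None    # table mode: per-call wide CSV
    metadata_csv: str | None = None        # table mode: per-individual CSV
    highpass_cutoff_hz: float = 500.0
    min_gap_ms: float = 50.0
    threshold_db_above_noise: float = 10.0
    calls_per_individual: int = 5
    cv_thresholds: tuple[float, float] = (5.0, 12.0)
    reference_temperature_c: float | None = None  # None -> auto (mean)
    mantel_permutations: int = 9999
    seed: int = 0
    alpha: float = 0.05
    measure_only: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("audio", "table", "simulate"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        lo, hi = self.cv_thresholds
        if not 0 < lo < hi:
            raise InvalidParameterError("cv_thresholds must satisfy 0 < static < dynamic")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidParameterError("alpha must be in (0, 1)")


@dataclass
class RunResult:
    measurements: pd.DataFrame
    metadata: pd.DataFrame
    variation: pd.DataFrame | None = None
    temperature_models: pd.DataFrame | None = None
    corrected_means: pd.DataFrame | None = None
    mantel: pd.DataFrame | None = None
    comparison: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"{what} missing columns: {missing}")


def _measure_audio(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    meta = pd.read_csv(config.audio_metadata_csv)
    _require_columns(meta, (*METADATA_COLUMNS, "wav_path"), "audio metadata CSV")
    frames: list[pd.DataFrame] = []
    failures: list[str] = []
    for row in meta.itertuples(index=False):
        try:
            rec_meta = RecordingMetadata(
                individual_id=str(row.individual_id), locality=str(row.locality),
                group=str(row.group), temperature_c=float(row.temperature_c),
                latitude=float(row.latitude), longitude=float(row.longitude),
            )
            recording = read_wav(row.wav_path, rec_meta)
            filtered = highpass_filter(recording, config.highpass_cutoff_hz)
            calls = measure_recording(
                filtered, min_gap_ms=config.min_gap_ms,
                threshold_db_above_noise=config.threshold_db_above_noise,
            )
            selected, shortfall = select_calls(calls, config.calls_per_individual)
            if shortfall:
                logger.warning("%s: only %d calls selected",
                               row.individual_id, len(selected))
            frames.append(measurements_to_frame(str(row.individual_id), selected))
        except Exception as exc:  # per-file failures are logged and skipped
            failures.append(f"{row.wav_path}: {exc}")
            logger.error("skipping %s: %s", row.wav_path, exc)
    if failures:
        logger.warning("%d of %d recordings failed", len(failures), len(meta))
    measurements = (pd.concat(frames, ignore_index=True) if frames
                    else pd.DataFrame(columns=["individual_id", "call_index",
                                               *PARAMETER_NAMES, "snr_db"]))
    return measurements, meta[list(METADATA_COLUMNS)].drop_duplicates()


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the configured stages and write all result tables.

    Outputs under ``config.output_dir``: measurements.csv, metadata.csv,
    variation.csv, temperature_models.csv, corrected_means.csv,
    mantel.csv, group_comparison.csv, kde/<parameter>.json, and
    manifest.json.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mode == "simulate":
        pop = study_population_config(seed=config.seed,
                                      calls_per_individual=config.calls_per_individual)
        long_table, _ = generate_parameter_table(pop)
        metadata = metadata_frame(pop)
        measurements = (long_table
                        .pivot_table(index=["individual_id", "call_index"],
                                     columns="parameter", values="value")
                        .reset_index())
        measurements.columns.name = None
    elif config.mode == "table":
        # round_trip parsing so a rerun from persisted CSVs is bit-exact
        measurements = pd.read_csv(config.measurements_csv,
                                   float_precision="round_trip")
        _require_columns(measurements, ("individual_id", "call_index"),
                         "measurement CSV")
        metadata = pd.read_csv(config.metadata_csv,
                               float_precision="round_trip")
        _require_columns(metadata, METADATA_COLUMNS, "metadata CSV")
        long_table = to_long(measurements, metadata)
    else:
        measurements, metadata = _measure_audio(config)
        long_table = (to_long(measurements, metadata)
                      if len(measurements) else None)

    measurements.to_csv(out / "measurements.csv", index=False)
    metadata.to_csv(out / "metadata.csv", index=False)
    result = RunResult(measurements=measurements, metadata=metadata)

    if config.mode == "simulate":
        long_table = to_long(measurements, metadata)

    if not config.measure_only and long_table is not None and len(long_table):
        params = tuple(dict.fromkeys(long_table["parameter"]))
        result.variation = variation_table(long_table, config.cv_thresholds)
        result.variation.to_csv(out / "variation.csv", index=False)

        ind = individual_means(long_table)
        ind = ind.merge(metadata[["individual_id", "latitude", "longitude",
                                  "temperature_c"]], on="individual_id")
        ref = (config.reference_temperature_c
               if config.reference_temperature_c is not None
               else reference_temperature(ind))
        models = fit_models(ind, parameters=params,
                            reference_temperature_c=ref, alpha=config.alpha)
        result.temperature_models = models_to_frame(models)
        result.temperature_models.to_csv(out / "temperature_models.csv", index=False)
        corrected = apply_correction(ind, models)
        result.corrected_means = corrected
        corrected.to_csv(out / "corrected_means.csv", index=False)

        localities = (metadata[["locality", "latitude", "longitude"]]
                      .drop_duplicates("locality"))
        if len(localities) >= 3:
            geo = haversine_matrix(
                list(zip(localities["latitude"], localities["longitude"])),
                labels=localities["locality"],
            )
            loc_means = (corrected.groupby("locality")[list(params)]
                         .mean().loc[list(geo.labels)])
            result.mantel = mantel_table(
                geo, loc_means, n_permutations=config.mantel_permutations,
                seed=config.seed,
            )
            result.mantel.to_csv(out / "mantel.csv", index=False)
        else:
            logger.warning("fewer than 3 localities: Mantel stage skipped")

        groups = corrected["group"].unique()
        if len(groups) == 2:
            try:
                result.comparison = compare_groups(corrected, parameters=params,
                                                   alpha=config.alpha)
            except InsufficientDataError as exc:
                logger.warning("group comparison skipped: %s", exc)
            else:
                result.comparison.to_csv(out / "group_comparison.csv",
                                         index=False)
                kde_dir = out / "kde"
                kde_dir.mkdir(exist_ok=True)
                for parameter in params:
                    if parameter not in corrected.columns:
                        continue
                    payload = {}
                    for group, sub in corrected.groupby("group"):
                        k = kde_summary(sub[parameter])
                        payload[str(group)] = {"grid": k.grid.tolist(),
                                               "density": k.density.tolist(),
                                               "bandwidth": k.bandwidth}
                    (kde_dir / f"{parameter}.json").write_text(
                        json.dumps(payload, indent=1))
        else:
            logger.warning("group comparison needs exactly 2 groups, got %s",
                           list(groups))

    result.manifest = _manifest(config, result)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
    return result


def _manifest(config: RunConfig, result: RunResult) -> dict:
    cfg = asdict(config)
    cfg["cv_thresholds"] = list(config.cv_thresholds)
    blob = json.dumps(cfg, sort_keys=True).encode()
    return {
        "callvar_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "n_calls": int(len(result.measurements)),
        "n_individuals": int(result.measurements["individual_id"].nunique())
        if len(result.measurements) else 0,
    }
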