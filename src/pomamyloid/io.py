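"""CSV schemas and configuration for the analysis pipeline.

All files are plain comma-separated UTF-8 with a mandatory header row
and ``.`` decimal separator; units are encoded in the column names:

* kinetics: ``time_h`` plus one column per well, with a sidecar
  metadata table mapping ``well`` to ``protein_conc_uM``, ``pom_id``,
  ``pom_conc_uM``, ``replicate``;
* titrations: ``conc_uM``, ``signal`` (optional ``probe``);
* quenching: ``Q_M``, ``F``;
* spectra: ``wavelength_nm`` plus ``value`` or one ``rep<i>`` column
  per scan;
* AFM heights: ``height_nm`` (optional ``condition``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .afm_stats import HeightSample
from .fitting import ConfigurationError, KineticTrace, QuenchCurve, TitrationCurve
from .spectra import Spectrum

__all__ = [
    "SchemaError",
    "AnalysisConfig",
    "load_config",
    "read_kinetic_csv",
    "write_kinetic_csv",
    "read_titration_csv",
    "write_titration_csv",
    "read_quench_csv",
    "write_quench_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_heights_csv",
    "write_heights_csv",
]

logger = logging.getLogger("pomamyloid")


class SchemaError(ValueError):
    """A file does not match its expected CSV schema."""


_KINETIC_META_COLS = ("well", "protein_conc_uM", "pom_id", "pom_conc_uM", "replicate")


def read_kinetic_csv(path: str | Path, metadata_path: str | Path) -> list[KineticTrace]:
    """Read a plate-reader kinetics table plus its well-metadata sidecar.

    Rows with non-finite time or signal are dropped per well, with the
    dropped count logged.  A well column missing from the metadata is a
    schema error naming the well.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_h" not in df.columns:
        raise SchemaError("kinetics CSV must contain a 'time_h' column")
    meta = pd.read_csv(metadata_path, float_precision="round_trip")
    missing_cols = set(_KINETIC_META_COLS) - set(meta.columns)
    if missing_cols:
        raise SchemaError(f"metadata CSV missing columns: {sorted(missing_cols)}")
    meta = meta.set_index("well")

    traces = []
    for well in [c for c in df.columns if c != "time_h"]:
        if well not in meta.index:
            raise SchemaError(f"well {well!r} absent from metadata")
        sub = df[["time_h", well]].astype(float)
        finite = np.isfinite(sub["time_h"]) & np.isfinite(sub[well])
        n_dropped = int((~finite).sum())
        if n_dropped:
            logger.warning("well %s: dropped %d non-finite rows", well, n_dropped)
        sub = sub[finite]
        times = sub["time_h"].to_numpy()
        if np.any(np.diff(times) <= 0):
            raise SchemaError(f"well {well!r}: time_h is not strictly increasing")
        row = meta.loc[well]
        traces.append(
            KineticTrace(
                times=times,
                signal=sub[well].to_numpy(),
                protein_conc=float(row["protein_conc_uM"]),
                pom_id=str(row["pom_id"]),
                pom_conc=float(row["pom_conc_uM"]),
                replicate=int(row["replicate"]),
                well=well,
            )
        )
    return traces


def write_kinetic_csv(
    traces: list[KineticTrace], path: str | Path, metadata_path: str | Path
) -> None:
    """Write traces (sharing one time grid) and their metadata sidecar."""
    t0 = traces[0].times
    for tr in traces:
        if not np.array_equal(tr.times, t0):
            raise SchemaError("all traces in one file must share the time grid")
    data = {"time_h": t0}
    meta_rows = []
    for i, tr in enumerate(traces):
        well = tr.well or f"W{i:03d}"
        data[well] = tr.signal
        meta_rows.append(
            {
                "well": well,
                "protein_conc_uM": tr.protein_conc,
                "pom_id": tr.pom_id,
                "pom_conc_uM": tr.pom_conc,
                "replicate": tr.replicate,
            }
        )
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    pd.DataFrame(meta_rows).to_csv(metadata_path, index=False, float_format="%.17g")


def read_titration_csv(path: str | Path) -> TitrationCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"conc_uM", "signal"} <= set(df.columns):
        raise SchemaError("titration CSV must contain 'conc_uM' and 'signal' columns")
    probe = str(df["probe"].iloc[0]) if "probe" in df.columns else "intrinsic-Trp"
    df = df.sort_values("conc_uM")
    return TitrationCurve(
        conc=df["conc_uM"].to_numpy(float), signal=df["signal"].to_numpy(float), probe=probe
    )


def write_titration_csv(curve: TitrationCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"conc_uM": curve.conc, "signal": curve.signal, "probe": curve.probe}
    ).to_csv(path, index=False, float_format="%.17g")


def read_quench_csv(path: str | Path) -> QuenchCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"Q_M", "F"} <= set(df.columns):
        raise SchemaError("quenching CSV must contain 'Q_M' and 'F' columns")
    df = df.sort_values("Q_M")
    return QuenchCurve(Q=df["Q_M"].to_numpy(float), F=df["F"].to_numpy(float))


def write_quench_csv(curve: QuenchCurve, path: str | Path) -> None:
    pd.DataFrame({"Q_M": curve.Q, "F": curve.F}).to_csv(path, index=False, float_format="%.17g")


def read_spectrum_csv(path: str | Path) -> Spectrum:
    df = pd.read_csv(path, float_precision="round_trip")
    if "wavelength_nm" not in df.columns:
        raise SchemaError("spectrum CSV must contain a 'wavelength_nm' column")
    wl = df["wavelength_nm"].to_numpy(float)
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if rep_cols:
        reps = df[rep_cols].to_numpy(float).T
        return Spectrum.from_repeats(wl, reps)
    if "value" not in df.columns:
        raise SchemaError("spectrum CSV must contain 'value' or 'rep<i>' columns")
    return Spectrum(wl, df["value"].to_numpy(float))


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    data = {"wavelength_nm": spectrum.wavelengths}
    if spectrum.repeats is not None:
        for i, rep in enumerate(spectrum.repeats, start=1):
            data[f"rep{i}"] = rep
    else:
        data["value"] = spectrum.values
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_heights_csv(path: str | Path) -> HeightSample:
    df = pd.read_csv(path, float_precision="round_trip")
    if "height_nm" not in df.columns:
        raise SchemaError("heights CSV must contain a 'height_nm' column")
    condition = str(df["condition"].iloc[0]) if "condition" in df.columns else ""
    return HeightSample(heights=df["height_nm"].to_numpy(float), condition=condition)


def write_heights_csv(sample: HeightSample, path: str | Path) -> None:
    pd.DataFrame(
        {"height_nm": sample.heights, "condition": sample.condition}
    ).to_csv(path, index=False, float_format="%.17g")


# --- configuration -------------------------------------------------------

_KNOWN_KEYS = {
    "kinetics_csv",
    "metadata_csv",
    "simulate",
    "protein_conc_uM",
    "ratios",
    "noise_fraction",
    "n_replicates",
    "pom_id",
    "reference_condition",
    "depletion",
    "rate_parameterization",
    "smoothing_window",
    "bootstrap_n",
    "seed",
    "outdir",
}


@dataclass
class AnalysisConfig:
    """Validated options driving :func:`pomamyloid.pipeline.run_pipeline`.

    Either ``kinetics_csv``/``metadata_csv`` point at measured data, or
    ``simulate`` is set and a synthetic panel with the given design is
    generated.  Defaults mirror the aggregation assay design (75 μM
    protein, ratios 1:0.5–1:10, 150 h at 10 min sampling, triplicate).
    """

    kinetics_csv: str | None = None
    metadata_csv: str | None = None
    simulate: bool = False
    protein_conc_uM: float = 75.0
    ratios: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 10.0)
    noise_fraction: float = 0.02
    n_replicates: int = 3
    pom_id: str = "TiNb9"
    reference_condition: str = "none"
    depletion: bool = False
    rate_parameterization: str = "rate"
    smoothing_window: int = 9
    bootstrap_n: int = 0
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.rate_parameterization not in ("rate", "scale"):
            raise ConfigurationError(
                f"unknown rate_parameterization {self.rate_parameterization!r}"
            )
        if not self.simulate:
            for p, label in ((self.kinetics_csv, "kinetics_csv"), (self.metadata_csv, "metadata_csv")):
                if p is None:
                    raise ConfigurationError(f"{label} required unless simulate=true")
                if not Path(p).exists():
                    raise ConfigurationError(f"{label} does not exist: {p}")
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an integer")
        self.ratios = tuple(float(r) for r in self.ratios)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and validate a YAML analysis configuration.

    Unknown keys are rejected before any computation runs.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a YAML mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)
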