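"""Delimited-text readers/writers, unit handling and run manifests.

Units policy: files carry micrometres and nanometres (the units the
instruments print); internal computation uses mm and mm^-1.  Conversions
happen here, driven by column-header unit suffixes, and nowhere else.
Delimiter detection is limited to comma and tab.
"""

from __future__ import annotations

import getpass
import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .km import KMFitResult, TransmittanceDataset
from .mc import FluenceTally
from .ta import BeamProfile, DisplacementProfile, GlobalGaussianFit

__all__ = [
    "SchemaError",
    "ColumnSpec",
    "read_table",
    "read_km_table",
    "read_ta_scan",
    "read_beam_profile",
    "write_report",
    "write_profile_table",
    "save_tally",
    "load_tally",
    "RunManifest",
]


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


@dataclass(frozen=True)
class ColumnSpec:
    """One schema column: canonical name, accepted unit-suffix variants
    mapped to conversion factors into the canonical unit, dtype."""

    canonical: str
    units: dict[str, float] = field(default_factory=dict)  # suffix -> factor
    dtype: type = float
    required: bool = True

    def match(self, header: str) -> float | None:
        """Return the conversion factor if `header` names this column."""
        h = header.strip().lower()
        if h == self.canonical.lower():
            return 1.0
        base = self.canonical.lower().rsplit("_", 1)[0] if self.units else None
        for suffix, factor in self.units.items():
            if h == f"{base}_{suffix}".lower():
                return factor
        return None


def _detect_sep(path: Path) -> str:
    first = path.open().readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_table(path, schema: list[ColumnSpec]) -> pd.DataFrame:
    """Read a comma- or tab-delimited table against a schema.

    Headers are matched case-insensitively; unit-suffix variants are
    converted to the canonical unit (e.g. a pathlength_um column feeds the
    canonical pathlength_mm).  Missing required columns raise SchemaError
    naming the column; unparseable cells raise SchemaError with the line
    number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str,
                     skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    out = {}
    for spec in schema:
        found = None
        for col in df.columns:
            factor = spec.match(col)
            if factor is not None:
                found = (col, factor)
                break
        if found is None:
            if spec.required:
                raise SchemaError(
                    f"{path.name}: missing required column "
                    f"'{spec.canonical}' (or a unit variant)")
            continue
        col, factor = found
        raw = df[col]
        if spec.dtype is float:
            vals = pd.to_numeric(raw, errors="coerce")
            bad = vals.isna() & raw.notna() & (raw.str.strip() != "")
            if bad.any():
                line = int(bad.idxmax()) + 2  # header + 1-based
                raise SchemaError(
                    f"{path.name}:{line}: cannot parse "
                    f"'{raw[bad.idxmax()]}' in column '{col}'")
            out[spec.canonical] = vals.to_numpy() * factor
        else:
            out[spec.canonical] = raw.astype(spec.dtype).to_numpy()
    return pd.DataFrame(out)


KM_SCHEMA = [
    ColumnSpec("sample", dtype=str),
    ColumnSpec("wavelength_nm"),
    ColumnSpec("pathlength_mm", units={"um": 1e-3, "mm": 1.0}),
    ColumnSpec("transmittance"),
]

TA_SCHEMA = [
    ColumnSpec("scan"),
    ColumnSpec("dx_um", units={"um": 1.0, "mm": 1e3}),
    ColumnSpec("dt_ps"),
    ColumnSpec("wavelength_nm"),
    ColumnSpec("dA", required=False),
    ColumnSpec("i_pumped", required=False),
    ColumnSpec("i_unpumped", required=False),
]

BEAM_SCHEMA = [
    ColumnSpec("x_um", units={"um": 1.0, "mm": 1e3}),
    ColumnSpec("intensity"),
]


def read_km_table(path) -> list[TransmittanceDataset]:
    """Read an integrating-sphere table (sample, wavelength_nm,
    pathlength_um, transmittance) into one dataset per sample.
    Transmittances are fractions, not percent."""
    df = read_table(path, KM_SCHEMA)
    datasets = []
    for (sample, wl), grp in df.groupby(["sample", "wavelength_nm"]):
        datasets.append(TransmittanceDataset(
            sample=str(sample),
            wavelength_nm=float(wl),
            pathlengths_mm=grp["pathlength_mm"].to_numpy(),
            transmittance=grp["transmittance"].to_numpy(),
        ))
    return datasets


def read_ta_scan(path) -> pd.DataFrame:
    df = read_table(path, TA_SCHEMA)
    if "dA" not in df.columns and not {"i_pumped", "i_unpumped"} <= set(df.columns):
        raise SchemaError(f"{Path(path).name}: need column 'dA' or the pair "
                          "'i_pumped'/'i_unpumped'")
    return df


def read_beam_profile(path) -> BeamProfile:
    df = read_table(path, BEAM_SCHEMA)
    return BeamProfile(x_um=df["x_um"].to_numpy(),
                       intensity=df["intensity"].to_numpy())


def _reportable(obj):
    if hasattr(obj, "report"):
        return obj.report()
    if isinstance(obj, dict):
        return obj
    raise TypeError(f"cannot serialize {type(obj).__name__} as a report")


def write_report(result, path, manifest: "RunManifest | None" = None) -> None:
    """Write a fit/analysis result as round-trippable JSON at full float
    precision (KMFitResult and GlobalGaussianFit expose .report())."""
    payload = _reportable(result)
    if isinstance(result, KMFitResult):
        payload = {"units": {"S": "mm^-1", "K": "mm^-1"}, **payload}
    if isinstance(result, GlobalGaussianFit):
        payload = {"units": {"widths": "um (FWHM)"}, **payload}
    if manifest is not None:
        payload["manifest"] = manifest.to_dict()
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def write_profile_table(profile: DisplacementProfile, path) -> None:
    profile.table.to_csv(path, index=False)


def save_tally(tally: FluenceTally, prefix) -> None:
    """Persist a fluence tally: npz array container plus a JSON sidecar
    with bin edges, photon count and seed."""
    prefix = Path(prefix)
    np.savez_compressed(prefix.with_suffix(".npz"), fluence=tally.values)
    meta = {
        "x_edges_um": tally.x_edges.tolist(),
        "y_edges_um": tally.y_edges.tolist(),
        "z_edges_um": tally.z_edges.tolist(),
        "n_photons": tally.n_photons,
        "seed": tally.seed,
        "absorbed": tally.absorbed,
        "exited": tally.exited,
        "exited_ballistic": tally.exited_ballistic,
        "roulette_gain": tally.roulette_gain,
        "roulette_loss": tally.roulette_loss,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def load_tally(prefix) -> FluenceTally:
    prefix = Path(prefix)
    values = np.load(prefix.with_suffix(".npz"))["fluence"]
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return FluenceTally(
        values=values,
        x_edges=np.array(meta["x_edges_um"]),
        y_edges=np.array(meta["y_edges_um"]),
        z_edges=np.array(meta["z_edges_um"]),
        n_photons=meta["n_photons"],
        seed=meta["seed"],
        absorbed=meta["absorbed"],
        exited=meta["exited"],
        exited_ballistic=meta["exited_ballistic"],
        roulette_gain=meta["roulette_gain"],
        roulette_loss=meta["roulette_loss"],
    )


@dataclass
class RunManifest:
    """Provenance record attached to every CLI output: command, config
    echo, seed, package version, timestamp, input checksums."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    timestamp: str = ""
    version: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        if not self.version:
            from . import __version__
            self.version = __version__

    @staticmethod
    def checksum(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def add_input(self, path) -> None:
        self.inputs[str(path)] = self.checksum(path)

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "seed": self.seed,
            "config": self.config,
            "inputs": self.inputs,
            "timestamp": self.timestamp,
            "version": self.version,
            "platform": platform.platform(),
        }
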