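"""File formats: surface CSV/TSV, trace CSV, aligned FASTA, YAML metadata,
and deterministic JSON reports.

All writers are byte-deterministic for a given object: JSON keys are
sorted and floats serialized at 12 significant digits, so re-running a
pipeline with the same seed reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synth import PhotocurrentTrace, PumpTrace, TransientAbsorptionSurface

__all__ = [
    "surface_to_csv",
    "surface_from_csv",
    "surface_to_tsv",
    "surface_from_tsv",
    "trace_to_csv",
    "trace_from_csv",
    "read_fasta",
    "write_fasta",
    "dump_json",
    "sha256_of",
]


def _round_sig(x: float, sig: int = 12) -> float:
    return float(f"{x:.{sig}g}")


# -- transient-absorption surfaces -----------------------------------------


def surface_to_csv(surface: TransientAbsorptionSurface, path: str | Path) -> None:
    """Long format: one (wavelength_nm, time_s, delta_A) row per point."""
    wl, t = np.meshgrid(surface.wavelengths, surface.times, indexing="ij")
    df = pd.DataFrame(
        {"wavelength_nm": wl.ravel(), "time_s": t.ravel(), "delta_A": surface.delta_A.ravel()}
    )
    df.to_csv(path, index=False, float_format="%.12g")


def surface_from_csv(path: str | Path) -> TransientAbsorptionSurface:
    df = pd.read_csv(path)
    wl = np.unique(df["wavelength_nm"].to_numpy())
    t = np.unique(df["time_s"].to_numpy())
    pivot = df.pivot(index="wavelength_nm", columns="time_s", values="delta_A")
    return TransientAbsorptionSurface(wl, t, pivot.loc[wl, t].to_numpy())


def surface_to_tsv(surface: TransientAbsorptionSurface, path: str | Path) -> None:
    """Wide matrix: rows = wavelengths, columns = times."""
    df = pd.DataFrame(surface.delta_A, index=surface.wavelengths, columns=surface.times)
    df.index.name = "wavelength_nm"
    df.to_csv(path, sep="\t", float_format="%.12g")


def surface_from_tsv(path: str | Path) -> TransientAbsorptionSurface:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TransientAbsorptionSurface(
        df.index.to_numpy(dtype=float),
        df.columns.to_numpy(dtype=float),
        df.to_numpy(dtype=float),
    )


# -- traces -----------------------------------------------------------------


def trace_to_csv(trace: PhotocurrentTrace | PumpTrace, path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write a trace as (time, value) CSV plus an optional YAML sidecar with
    epochs/window metadata."""
    if isinstance(trace, PhotocurrentTrace):
        df = pd.DataFrame({"time_ms": trace.time, "current_pA": trace.current})
        meta = {
            "kind": "photocurrent",
            "light_epochs_ms": [list(e) for e in trace.light_epochs],
            "holding_potential_mV": trace.holding_potential_mV,
            "irradiance_mW_mm2": trace.irradiance_mW_mm2,
        }
    else:
        df = pd.DataFrame({"time_s": trace.time, "pH": trace.pH})
        meta = {
            "kind": "pump",
            "illumination_window_s": list(trace.illumination_window),
            "cccp_present": trace.cccp_present,
            "nacl_present": trace.nacl_present,
        }
    df.to_csv(path, index=False, float_format="%.12g")
    if meta_path is not None:
        Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=True))


def trace_from_csv(path: str | Path, meta_path: str | Path | None = None):
    """Read a trace CSV (+YAML sidecar).  Returns PhotocurrentTrace or
    PumpTrace if metadata identifies the kind, else a plain (time, value)
    tuple."""
    df = pd.read_csv(path)
    if meta_path is None:
        return df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()
    meta = yaml.safe_load(Path(meta_path).read_text())
    if meta["kind"] == "photocurrent":
        return PhotocurrentTrace(
            df["time_ms"].to_numpy(),
            df["current_pA"].to_numpy(),
            tuple(tuple(e) for e in meta["light_epochs_ms"]),
            holding_potential_mV=meta.get("holding_potential_mV", 0.0),
            irradiance_mW_mm2=meta.get("irradiance_mW_mm2", 0.8),
        )
    if meta["kind"] == "pump":
        return PumpTrace(
            df["time_s"].to_numpy(),
            df["pH"].to_numpy(),
            illumination_window=tuple(meta["illumination_window_s"]),
            cccp_present=meta.get("cccp_present", False),
            nacl_present=meta.get("nacl_present", True),
        )
    raise ValueError(f"unknown trace kind {meta['kind']!r}")


# -- alignments -------------------------------------------------------------


def read_fasta(path: str | Path) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Aligned FASTA → (taxa, sequences)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return tuple(r.id for r in records), tuple(str(r.seq) for r in records)


def write_fasta(taxa, sequences, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=t, description="") for t, s in zip(taxa, sequences)]
    SeqIO.write(records, str(path), "fasta")


# -- reports ----------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _round_sig(float(obj))
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def dump_json(obj, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, floats at 12 significant digits."""
    Path(path).write_text(json.dumps(_jsonable(obj), sort_keys=True, indent=1) + "\n")


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
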