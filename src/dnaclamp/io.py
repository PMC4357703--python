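"""File I/O for traces, curves, titrations, sequences and configuration.

All tabular formats are plain whitespace-delimited text with ``#``
header lines carrying metadata as ``# key: value``; writers emit the
same dialect the loaders read, so write-then-read is an identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .binding import TitrationTable
from .footprint import Fdc, HairpinConstruct
from .kinetics import KineticTrace
from .polymer import ForceExtensionCurve

__all__ = [
    "ParseError",
    "AnalysisConfig",
    "load_config",
    "load_fec",
    "write_fec",
    "load_trace",
    "write_trace",
    "load_fdc",
    "write_fdc",
    "load_titration",
    "write_titration",
    "load_fasta",
    "write_fasta",
]


class ParseError(ValueError):
    """Malformed data file; carries the offending line number."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _read_delimited(path, n_columns):
    """Parse header metadata and a fixed number of float columns."""
    meta = {}
    rows = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != n_columns:
                raise ParseError(path, line_no, f"expected {n_columns} columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ParseError(path, line_no, f"non-numeric value in {parts!r}") from None
    if not rows:
        raise ParseError(path, 0, "empty data file")
    return meta, np.asarray(rows, dtype=float)


def _write_delimited(path, meta, columns, arrays, fmt="%.8g"):
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("# columns: " + " ".join(columns) + "\n")
        np.savetxt(fh, np.column_stack(arrays), fmt=fmt)


def load_fec(path) -> ForceExtensionCurve:
    """Read a force-extension curve (force_pN, extension_nm)."""
    meta, data = _read_delimited(path, 2)
    return ForceExtensionCurve(
        force=data[:, 0],
        extension=data[:, 1],
        direction=meta.pop("direction", "stretch"),
        pulling_speed=float(meta.pop("pulling_speed_nm_s", "nan")),
        metadata=meta,
    )


def write_fec(path, curve: ForceExtensionCurve):
    meta = {"direction": curve.direction, "pulling_speed_nm_s": curve.pulling_speed}
    meta.update(curve.metadata)
    _write_delimited(path, meta, ["force_pN", "extension_nm"], [curve.force, curve.extension])


def load_trace(path) -> KineticTrace:
    """Read a kinetic trace (time_s, force_pN, signal)."""
    meta, data = _read_delimited(path, 3)
    if np.any(np.diff(data[:, 0]) <= 0):
        bad = int(np.where(np.diff(data[:, 0]) <= 0)[0][0]) + 2
        raise ParseError(path, bad, "time values must be strictly increasing")
    return KineticTrace(
        time=data[:, 0],
        force=data[:, 1],
        signal=data[:, 2],
        signal_kind=meta.pop("signal_kind", "extension"),
        metadata=meta,
    )


def write_trace(path, trace: KineticTrace):
    meta = {"signal_kind": trace.signal_kind}
    meta.update({k: v for k, v in trace.metadata.items() if v is not None})
    _write_delimited(
        path, meta, ["time_s", "force_pN", "signal"], [trace.time, trace.force, trace.signal]
    )


def load_fdc(path) -> Fdc:
    """Read a force-distance curve (distance_nm, force_pN)."""
    meta, data = _read_delimited(path, 2)
    return Fdc(
        distance=data[:, 0],
        force=data[:, 1],
        direction=meta.pop("direction", "unzip"),
        metadata=meta,
    )


def write_fdc(path, fdc: Fdc):
    meta = {"direction": fdc.direction}
    meta.update({k: v for k, v in fdc.metadata.items() if not isinstance(v, (list, tuple, dict))})
    _write_delimited(path, meta, ["distance_nm", "force_pN"], [fdc.distance, fdc.force])


def load_titration(path, N_bp=None) -> TitrationTable:
    """Read a titration table (conc_nM, l0_nm, sd_nm, n_molecules)."""
    meta, data = _read_delimited(path, 4)
    if N_bp is None:
        if "N_bp" not in meta:
            raise ParseError(path, 0, "missing '# N_bp:' header and no N_bp argument")
        N_bp = int(meta["N_bp"])
    df = pd.DataFrame(data, columns=["conc_nM", "l0_nm", "sd_nm", "n_molecules"])
    return TitrationTable(data=df, N_bp=N_bp, metadata=meta)


def write_titration(path, table: TitrationTable):
    meta = {"N_bp": table.N_bp}
    meta.update({k: v for k, v in table.metadata.items() if isinstance(v, (str, int, float))})
    df = table.data
    sd = df["sd_nm"] if "sd_nm" in df else np.full(len(df), np.nan)
    nmol = df["n_molecules"] if "n_molecules" in df else np.ones(len(df))
    _write_delimited(
        path,
        meta,
        ["conc_nM", "l0_nm", "sd_nm", "n_molecules"],
        [df["conc_nM"], df["l0_nm"], sd, nmol],
    )


def load_fasta(path):
    """First record of a FASTA file as (id, uppercase sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(path, 0, "no FASTA records found")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def write_fasta(path, name, sequence):
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")


_KNOWN_SECTIONS = {
    "seed",
    "output_dir",
    "elastic",
    "binding",
    "kinetics",
    "footprint",
    "simulate",
    "paths",
}


@dataclass
class AnalysisConfig:
    """Validated analysis configuration (nested key-value blocks)."""

    seed: int = 0
    output_dir: str = "."
    paths: dict = field(default_factory=dict)
    elastic: dict = field(default_factory=dict)
    binding: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    footprint: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    def as_dict(self):
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "paths": self.paths,
            "elastic": self.elastic,
            "binding": self.binding,
            "kinetics": self.kinetics,
            "footprint": self.footprint,
            "simulate": self.simulate,
        }


def load_config(path) -> AnalysisConfig:
    """Load a YAML configuration, rejecting unknown top-level keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = AnalysisConfig()
    for key, val in raw.items():
        setattr(cfg, key, val)
    cfg.output_dir = str(cfg.output_dir)
    Path(cfg.output_dir)  # validate path-like
    return cfg
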