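"""CSV / JSON / YAML input-output for spectra, fits and cohort tables.

Spectrum CSV dialect: a header ``frequency_ghz,eps_real,eps_imag`` (columns
may appear in any order; they are matched by name), one row per frequency
point, optional ``# key=value`` comment lines carrying metadata.  Floats
are written with full round-trip precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .model import CCParameters, Spectrum

__all__ = [
    "ParseError",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_params_json",
    "write_params_json",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_yaml",
    "dump_yaml",
]

_SPECTRUM_COLUMNS = ("frequency_ghz", "eps_real", "eps_imag")


class ParseError(ValueError):
    """A file does not conform to the expected dialect."""


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum, metadata as leading ``# key=value`` comments."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in spectrum.meta.items():
            fh.write(f"# {key}={value}\n")
        fh.write(",".join(_SPECTRUM_COLUMNS) + "\n")
        for f, er, ei in zip(spectrum.frequencies, spectrum.eps_real, spectrum.eps_imag):
            fh.write(f"{float(f)!r},{float(er)!r},{float(ei)!r}\n")
    return path


def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Read and validate a spectrum CSV; errors name the offending line."""
    path = Path(path)
    meta: dict[str, Any] = {}
    header: list[str] | None = None
    cols: dict[str, list[float]] = {c: [] for c in _SPECTRUM_COLUMNS}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = _coerce(value.strip())
                continue
            fields = [f.strip() for f in line.split(",")]
            if header is None:
                header = fields
                missing = set(_SPECTRUM_COLUMNS) - set(header)
                if missing:
                    raise ParseError(
                        f"{path}:{lineno}: header misses columns {sorted(missing)}"
                    )
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            try:
                row = {name: float(v) for name, v in zip(header, fields)}
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            for c in _SPECTRUM_COLUMNS:
                cols[c].append(row[c])
    if header is None:
        raise ParseError(f"{path}: empty file (no header)")
    spectrum = Spectrum(
        frequencies=np.array(cols["frequency_ghz"]),
        eps_real=np.array(cols["eps_real"]),
        eps_imag=np.array(cols["eps_imag"]),
        meta=meta,
    )
    try:
        spectrum.validate()
    except ValueError as exc:
        raise ParseError(f"{path}: invalid spectrum: {exc}") from None
    return spectrum


def _coerce(value: str) -> Any:
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def write_params_json(params: CCParameters, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(params.to_dict(), indent=2) + "\n")
    return path


def read_params_json(path: str | Path) -> CCParameters:
    return CCParameters.from_dict(json.loads(Path(path).read_text())).validate()


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_yaml(path: str | Path) -> dict:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    return data


def dump_yaml(data: dict, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path
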