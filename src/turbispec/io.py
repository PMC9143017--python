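"""CSV/JSON/YAML interchange.

Spectra travel as two-column CSV (``wavelength_nm,value``) with an optional
``# unit:`` comment line; endpoint tables as CSV with columns
``subject_id,group,timepoint,tmre,bodipy,so2,hb``.  Parsers fail loudly and
name the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .spectra import VALID_UNITS, Spectrum

ENDPOINT_COLUMNS = ("subject_id", "group", "timepoint", "tmre", "bodipy", "so2", "hb")


def read_spectrum(path, kind: str = "reflectance") -> Spectrum:
    """Read a ``wavelength_nm,value`` CSV into a :class:`Spectrum`.

    The grid must be free of duplicates (sorted on read); the unit comes from
    a leading ``# unit: <u>`` comment, defaulting to a.u.
    """
    path = Path(path)
    unit = "a.u."
    rows = []
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("unit:"):
                unit = body.split(":", 1)[1].strip()
                if unit not in VALID_UNITS:
                    raise ParseError(f"{path}:{lineno}: unknown unit {unit!r}")
            continue
        if not header_seen:
            cols = [c.strip() for c in line.split(",")]
            if cols[:2] != ["wavelength_nm", "value"]:
                raise ParseError(f"{path}:{lineno}: expected header 'wavelength_nm,value'")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 comma-separated fields")
        try:
            rows.append((float(parts[0]), float(parts[1]), lineno))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric row {line!r}") from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    rows.sort(key=lambda r: r[0])
    for (w1, _, _), (w2, _, ln) in zip(rows, rows[1:]):
        if w1 == w2:
            raise ParseError(f"{path}:{ln}: duplicate wavelength {w2:g} nm")
    grid = np.array([r[0] for r in rows])
    values = np.array([r[1] for r in rows])
    return Spectrum(grid, values, unit=unit, kind=kind)


def write_spectrum(spectrum: Spectrum, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# unit: {spectrum.unit}", "wavelength_nm,value"]
    lines += [f"{w:.10g},{v:.10g}" for w, v in zip(spectrum.grid, spectrum.values)]
    path.write_text("\n".join(lines) + "\n")


def read_endpoint_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in ENDPOINT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df.loc[:, list(ENDPOINT_COLUMNS)]


def write_endpoint_table(table: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.loc[:, list(ENDPOINT_COLUMNS)].to_csv(path, index=False)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_yaml(path) -> dict:
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: expected a mapping document")
    return doc
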