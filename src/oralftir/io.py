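"""File formats the pipeline touches.

Imaging areas are stored as ENVI cubes (raw BSQ array + text ``.hdr`` with
the band wavelengths), spectrum tables as plain CSV (metadata columns first,
then one column per wavenumber), and run metadata / ground truth as JSON.
Readers re-sort ascending wavenumber axes into the canonical descending
order and note that they did via a logged warning.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import REQUIRED_META, SpectrumSet, WavenumberGrid, make_meta

logger = logging.getLogger(__name__)

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float64): 5, np.dtype(np.float32): 4}


class FormatError(ValueError):
    """Raised when a file does not match its declared format."""


# ---------------------------------------------------------------------------
# ENVI cubes
# ---------------------------------------------------------------------------


def write_envi_cube(area: SpectrumSet, path: str | Path) -> Path:
    """Write one imaging area as an ENVI BSQ cube (``path`` + ``path.hdr``).

    Pixels must carry ``row``/``col`` metadata (as generated areas do); the
    cube is written float64 so round trips are lossless.
    """
    path = Path(path)
    meta = area.meta
    if "row" not in meta.columns or "col" not in meta.columns:
        raise ValueError("area metadata must carry row/col pixel coordinates")
    n_rows = int(meta["row"].max()) + 1
    n_cols = int(meta["col"].max()) + 1
    if n_rows * n_cols != area.n_spectra:
        raise ValueError("pixel coordinates do not tile a full rectangle")

    cube = np.empty((len(area.grid), n_rows, n_cols))  # BSQ: band, line, sample
    flat = meta["row"].to_numpy() * n_cols + meta["col"].to_numpy()
    order = np.argsort(flat)
    cube[:] = (
        area.intensities[order].reshape(n_rows, n_cols, -1).transpose(2, 0, 1)
    )
    cube.astype(np.float64).tofile(path)

    sidecar = {
        "sample_id": str(meta["sample_id"].iloc[0]),
        "area_id": str(meta["area_id"].iloc[0]),
        "class_label": str(meta["class_label"].iloc[0]),
        "mode": area.mode,
    }
    header = [
        "ENVI",
        "description = {FTIR imaging area}",
        f"samples = {n_cols}",
        f"lines = {n_rows}",
        f"bands = {len(area.grid)}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 5",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = cm-1",
        "wavelength = {" + ", ".join(f"{w:.6f}" for w in area.grid.values) + "}",
        "; sidecar = " + json.dumps(sidecar),
    ]
    Path(str(path) + ".hdr").write_text("\n".join(header) + "\n")
    return path


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for raw in text.splitlines():
        line = raw.strip()
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_braces = False
            continue
        if line.startswith(";"):
            if "sidecar =" in line:
                fields["sidecar"] = line.split("sidecar =", 1)[1].strip()
            continue
        if "=" not in line:
            continue
        key, value = (part.strip() for part in line.split("=", 1))
        key = key.lower()
        if value.startswith("{") and "}" not in value:
            buf, in_braces = [value], True
        else:
            fields[key] = value
    return fields


def read_envi_cube(path: str | Path) -> SpectrumSet:
    """Read an ENVI cube written by :func:`write_envi_cube` (or compatible).

    The header must declare band wavelengths; a non-square pixel grid is
    accepted with a warning. Rows come back in row-major pixel order.
    """
    path = Path(path)
    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FormatError(f"no ENVI header found next to {path}")
    fields = _parse_envi_header(hdr_path.read_text())

    if "wavelength" not in fields:
        raise FormatError(f"{hdr_path} declares no wavelength field")
    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].strip("{} ").split(",") if tok.strip()]
    )
    n_cols = int(fields["samples"])
    n_rows = int(fields["lines"])
    n_bands = int(fields["bands"])
    if wavelengths.size != n_bands:
        raise FormatError("wavelength list length does not match band count")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise FormatError(f"only BSQ interleave is supported, got {interleave!r}")
    dtype = _ENVI_DTYPES.get(int(fields.get("data type", "5")))
    if dtype is None:
        raise FormatError(f"unsupported ENVI data type {fields.get('data type')}")
    if n_rows != n_cols:
        warnings.warn(f"non-square pixel grid ({n_rows} x {n_cols}) in {path}", stacklevel=2)

    cube = np.fromfile(path, dtype=dtype)
    if cube.size != n_bands * n_rows * n_cols:
        raise FormatError(f"{path} holds {cube.size} values, expected {n_bands * n_rows * n_cols}")
    matrix = cube.reshape(n_bands, n_rows, n_cols).transpose(1, 2, 0).reshape(n_rows * n_cols, n_bands)
    matrix = np.asarray(matrix, dtype=float)

    if np.all(np.diff(wavelengths) > 0):
        logger.info("ascending wavelength axis in %s re-sorted to descending", path)
        wavelengths = wavelengths[::-1]
        matrix = matrix[:, ::-1]

    sidecar = json.loads(fields.get("sidecar", "{}"))
    meta = make_meta(
        sidecar.get("sample_id", path.stem),
        sidecar.get("area_id", path.stem),
        sidecar.get("class_label", "H"),
        role="pixel",
        n=n_rows * n_cols,
        row=np.repeat(np.arange(n_rows), n_cols),
        col=np.tile(np.arange(n_cols), n_rows),
    )
    return SpectrumSet(
        grid=WavenumberGrid(wavelengths),
        intensities=matrix,
        meta=meta,
        mode=sidecar.get("mode", "transmission"),
    )


# ---------------------------------------------------------------------------
# CSV spectrum tables
# ---------------------------------------------------------------------------


def write_csv_spectra(spectra: SpectrumSet, path: str | Path) -> Path:
    """CSV with metadata columns first, then one column per wavenumber.

    Floats are written at full repr precision, so a round trip through
    :func:`read_csv_spectra` is lossless.
    """
    path = Path(path)
    frame = spectra.meta.copy()
    frame.insert(0, "_mode", spectra.mode)
    data = pd.DataFrame(
        spectra.intensities, columns=[f"{w:.6f}" for w in spectra.grid.values]
    )
    pd.concat([frame, data], axis=1).to_csv(path, index=False)
    return path


def read_csv_spectra(path: str | Path) -> SpectrumSet:
    """Read a CSV written by :func:`write_csv_spectra`."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    if frame.empty:
        raise FormatError(f"{path} holds no spectra")

    def _is_wavenumber(name: str) -> bool:
        try:
            float(name)
            return True
        except ValueError:
            return False

    wn_cols = [c for c in frame.columns if _is_wavenumber(c)]
    if len(wn_cols) < 2:
        raise FormatError(f"{path} has no wavenumber columns")
    meta_cols = [c for c in frame.columns if c not in wn_cols and c != "_mode"]
    missing = [c for c in REQUIRED_META if c not in meta_cols]
    if missing:
        raise FormatError(f"{path} is missing metadata columns: {missing}")

    wavelengths = np.array([float(c) for c in wn_cols])
    try:
        matrix = frame[wn_cols].to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric spectral cell in {path}: {exc}") from exc
    if matrix.shape[1] != wavelengths.size or np.isnan(matrix).any():
        raise FormatError(f"ragged or non-numeric spectral rows in {path}")
    if np.all(np.diff(wavelengths) > 0):
        logger.info("ascending wavelength axis in %s re-sorted to descending", path)
        wavelengths = wavelengths[::-1]
        matrix = matrix[:, ::-1]

    mode = str(frame["_mode"].iloc[0]) if "_mode" in frame.columns else "absorbance"
    return SpectrumSet(
        grid=WavenumberGrid(wavelengths),
        intensities=matrix,
        meta=frame[meta_cols].reset_index(drop=True),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# JSON sidecars
# ---------------------------------------------------------------------------


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def _default(value):
        if isinstance(value, (np.integer,)):
            return int(value)
        if isinstance(value, (np.floating,)):
            return float(value)
        if isinstance(value, np.ndarray):
            return value.tolist()
        raise TypeError(f"not JSON-serializable: {type(value)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
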