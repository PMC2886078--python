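"""Containers and I/O for 1-D ¹H NMR spectra and calibration datasets.

A :class:`Spectrum` is one trace (chemical-shift axis in ppm plus
intensities); a :class:`SpectralDataset` is an ``n × p`` intensity matrix of
spectra resampled onto one shared axis, optionally paired with reference
triglyceride values ``y`` (mmol/L) for calibration.

Axis convention: ppm axes are stored strictly **descending**, matching the
left-to-right plotting convention of NMR spectroscopy.  All interval and
region bounds elsewhere in the package are expressed in ppm, never in column
indices.

Supported formats: a plain CSV exchange format (header
``sample_id, <ppm_1>, <ppm_2>, ...`` with optional trailing ``tg_mmol_L``
and ``time_min`` columns) and read-only JCAMP-DX for single spectra.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralDataset",
    "JCAMPFormatError",
    "read_spectrum_jcamp",
    "read_dataset_csv",
    "write_dataset_csv",
    "resample_to_grid",
    "assemble_dataset",
]

#: Name of the reference-value column in the CSV exchange format.
TG_COLUMN = "tg_mmol_L"
#: Optional per-sample metadata columns tolerated in the CSV format.
META_COLUMNS = ("time_min", "subject_id")


class JCAMPFormatError(ValueError):
    """A JCAMP-DX file could not be interpreted as a 1-D spectrum."""


def _validate_axis(ppm: np.ndarray, what: str = "ppm") -> None:
    if ppm.ndim != 1 or ppm.size < 2:
        raise ValueError(f"{what} axis must be 1-D with at least 2 points")
    if not np.all(np.isfinite(ppm)):
        raise ValueError(f"{what} axis contains non-finite values")
    if not np.all(np.diff(ppm) < 0):
        raise ValueError(f"{what} axis must be strictly decreasing")


@dataclass
class Spectrum:
    """One 1-D NMR trace.

    Parameters
    ----------
    ppm
        Chemical-shift axis in ppm, strictly decreasing.
    intensity
        Intensities (arbitrary units), same length as ``ppm``.
    sample_id
        Identifier for the sample, unique within a dataset.
    meta
        Free-form metadata (field strength, time point, ground truth ...).
    """

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        _validate_axis(self.ppm)
        if self.intensity.shape != self.ppm.shape:
            raise ValueError(
                f"intensity length {self.intensity.size} != ppm length {self.ppm.size}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")

    @property
    def n_points(self) -> int:
        return self.ppm.size


@dataclass
class SpectralDataset:
    """Aligned spectra on a shared ppm axis, with optional reference values.

    ``X`` is an ``n × p`` matrix whose rows are spectra on the shared
    (descending) ``ppm`` axis.  ``y`` holds reference chylomicron TG
    concentrations in mmol/L when present.  ``meta`` carries optional
    per-sample metadata (e.g. a ``time_min`` column for time-course runs).
    """

    ppm: np.ndarray
    X: np.ndarray
    sample_ids: list[str]
    y: np.ndarray | None = None
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        _validate_axis(self.ppm)
        if self.X.ndim != 2 or self.X.shape[1] != self.ppm.size:
            raise ValueError(
                f"X must be n×p with p == len(ppm) == {self.ppm.size}, got {self.X.shape}"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.X.shape[0]:
            raise ValueError("number of sample ids does not match rows of X")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (self.X.shape[0],):
                raise ValueError("y length does not match number of samples")
            if not np.all(np.isfinite(self.y)):
                raise ValueError("y contains non-finite values")
            if np.any(self.y < 0):
                raise ValueError("reference TG values must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_points(self) -> int:
        return self.ppm.size

    def spectrum(self, i: int) -> Spectrum:
        """Row ``i`` as a standalone :class:`Spectrum`."""
        meta = {}
        if self.meta is not None:
            meta = dict(self.meta.iloc[i])
        return Spectrum(self.ppm.copy(), self.X[i].copy(), self.sample_ids[i], meta)

    def subset_rows(self, indices) -> "SpectralDataset":
        indices = np.asarray(indices)
        return SpectralDataset(
            ppm=self.ppm.copy(),
            X=self.X[indices].copy(),
            sample_ids=[self.sample_ids[i] for i in indices],
            y=None if self.y is None else self.y[indices].copy(),
            meta=None if self.meta is None else self.meta.iloc[indices].reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# JCAMP-DX reading (1-D, AFFN-encoded XYDATA or single-page NTUPLES)
# ---------------------------------------------------------------------------

_LDR_RE = re.compile(r"^##(?P<label>[^=]*)=(?P<value>.*)$")


def _parse_ldrs(text: str) -> list[tuple[str, str, list[str]]]:
    """Split a JCAMP file into (normalized label, value, data lines) records."""
    records: list[tuple[str, str, list[str]]] = []
    for raw_line in text.splitlines():
        line = raw_line.split("$$")[0].rstrip()  # strip comments
        if not line:
            continue
        m = _LDR_RE.match(line)
        if m:
            label = m.group("label").strip().upper().replace(" ", "").replace("-", "").replace("_", "")
            records.append((label, m.group("value").strip(), []))
        elif records:
            records[-1][2].append(line)
    return records


_AFFN_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def _affn_numbers(line: str, record: str) -> list[float]:
    # JCAMP ASDF compressed forms (SQZ/DIF/DUP) use letters as digit codes;
    # only plain AFFN numbers are supported here.
    if re.search(r"[A-DF-Za-df-z@%]", line):
        raise JCAMPFormatError(
            f"record {record}: compressed (ASDF) data encoding is not supported; "
            "re-export the spectrum with AFFN (plain-number) tables"
        )
    return [float(tok) for tok in _AFFN_NUM.findall(line)]


def _read_xy_table(data_lines: list[str], npoints: int, yfactor: float, record: str) -> np.ndarray:
    """Decode an (X++(Y..Y)) table: each line starts with an X check value."""
    ys: list[float] = []
    for line in data_lines:
        nums = _affn_numbers(line, record)
        if len(nums) < 2:
            raise JCAMPFormatError(f"record {record}: data line with fewer than 2 numbers")
        ys.extend(nums[1:])  # first number is the line's X check value
    if len(ys) != npoints:
        raise JCAMPFormatError(
            f"record {record}: expected {npoints} points, decoded {len(ys)}"
        )
    return np.asarray(ys, dtype=float) * yfactor


def _axis_to_ppm(axis: np.ndarray, xunits: str, observe_mhz: float | None, path: Path) -> np.ndarray:
    xunits = xunits.upper()
    if xunits == "PPM":
        return axis
    if xunits == "HZ":
        if observe_mhz is None or observe_mhz <= 0:
            raise JCAMPFormatError(
                f"{path.name}: Hz axis but no .OBSERVE FREQUENCY record to convert to ppm"
            )
        return axis / observe_mhz
    raise JCAMPFormatError(f"{path.name}: unsupported XUNITS {xunits!r} (need PPM or HZ)")


def read_spectrum_jcamp(path) -> Spectrum:
    """Read a 1-D JCAMP-DX spectrum.

    Handles AFFN-encoded ``##XYDATA=(X++(Y..Y))`` blocks and simple
    single-page ``##NTUPLES`` data tables.  The axis is converted to ppm
    (dividing a Hz axis by the observe frequency in MHz) and returned in
    descending order.  The sample id defaults to the file name stem.

    Raises
    ------
    JCAMPFormatError
        On 2-D data, missing axis metadata, compressed data tables, or a
        point-count mismatch; the message names the offending record.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise JCAMPFormatError(f"cannot read {path}: {exc}") from exc
    records = _parse_ldrs(text)
    if not records:
        raise JCAMPFormatError(f"{path.name}: no JCAMP-DX records found")
    header = {label: value for label, value, _ in records}

    if "TITLE" not in header:
        raise JCAMPFormatError(f"{path.name}: missing ##TITLE record")
    data_type = header.get("DATATYPE", "")
    if "2D" in data_type.upper() or header.get("NUMDIM", "1").strip() not in ("", "1"):
        raise JCAMPFormatError(f"{path.name}: record DATA TYPE: 2-D data is not supported")

    observe_mhz = None
    for key in (".OBSERVEFREQUENCY", "$SFO1"):
        if key in header:
            try:
                observe_mhz = float(_AFFN_NUM.findall(header[key])[0])
            except (IndexError, ValueError):
                raise JCAMPFormatError(f"{path.name}: unparseable observe frequency record")

    for label, value, data_lines in records:
        if label == "XYDATA":
            return _spectrum_from_xydata(header, value, data_lines, observe_mhz, path)
    for label, value, data_lines in records:
        if label == "NTUPLES":
            return _spectrum_from_ntuples(records, observe_mhz, path)
    raise JCAMPFormatError(f"{path.name}: no XYDATA or NTUPLES data record found")


def _require_float(header: dict, key: str, path: Path) -> float:
    if key not in header:
        raise JCAMPFormatError(f"{path.name}: missing ##{key} record")
    try:
        return float(header[key])
    except ValueError:
        raise JCAMPFormatError(f"{path.name}: record {key}: not a number: {header[key]!r}")


def _finalize(ppm: np.ndarray, intensity: np.ndarray, path: Path) -> Spectrum:
    order = np.argsort(ppm)[::-1]  # descending ppm, NMR convention
    return Spectrum(ppm[order], intensity[order], sample_id=path.stem)


def _spectrum_from_xydata(header, form, data_lines, observe_mhz, path) -> Spectrum:
    if "(X++(Y..Y))" not in form.replace(" ", ""):
        raise JCAMPFormatError(
            f"{path.name}: record XYDATA: unsupported table form {form!r}"
        )
    npoints = int(_require_float(header, "NPOINTS", path))
    if npoints < 2:
        raise JCAMPFormatError(f"{path.name}: record NPOINTS: need at least 2 points, got {npoints}")
    firstx = _require_float(header, "FIRSTX", path)
    lastx = _require_float(header, "LASTX", path)
    yfactor = float(header.get("YFACTOR", 1.0))
    xunits = header.get("XUNITS", "")
    if not xunits:
        raise JCAMPFormatError(f"{path.name}: missing ##XUNITS record")
    axis = np.linspace(firstx, lastx, npoints)
    intensity = _read_xy_table(data_lines, npoints, yfactor, "XYDATA")
    return _finalize(_axis_to_ppm(axis, xunits, observe_mhz, path), intensity, path)


def _spectrum_from_ntuples(records, observe_mhz, path) -> Spectrum:
    """Minimal single-page NTUPLES: uses VAR_DIM/FIRST/LAST/FACTOR/UNITS rows."""
    header = {label: value for label, value, _ in records}

    def columns(key):
        return [v.strip() for v in header.get(key, "").split(",")]

    names = [n.upper() for n in columns("VARNAME")]
    if not names or names == [""]:
        raise JCAMPFormatError(f"{path.name}: record NTUPLES: missing ##VAR_NAME")
    try:
        ix = next(i for i, n in enumerate(names) if n in ("X", "FREQUENCY"))
        iy = next(i for i, n in enumerate(names) if n in ("Y", "SPECTRUM", "SPECTRUM/REAL", "R"))
    except StopIteration:
        raise JCAMPFormatError(f"{path.name}: record VAR_NAME: cannot identify X and Y variables")

    def col_float(key, idx, default=None):
        vals = columns(key)
        if idx >= len(vals) or vals[idx] == "":
            if default is not None:
                return default
            raise JCAMPFormatError(f"{path.name}: record {key}: missing value for variable {idx}")
        return float(vals[idx])

    npoints = int(col_float("VARDIM", ix))
    if npoints < 2:
        raise JCAMPFormatError(f"{path.name}: record VAR_DIM: need at least 2 points")
    firstx = col_float("FIRST", ix)
    lastx = col_float("LAST", ix)
    yfactor = col_float("FACTOR", iy, default=1.0)
    xunits = columns("UNITS")[ix] if ix < len(columns("UNITS")) else ""
    if not xunits:
        raise JCAMPFormatError(f"{path.name}: record UNITS: missing X units")

    data_lines = None
    for label, value, lines in records:
        if label == "DATATABLE":
            data_lines = lines
            break
    if data_lines is None:
        raise JCAMPFormatError(f"{path.name}: record NTUPLES: no ##DATA TABLE found")
    axis = np.linspace(firstx, lastx, npoints)
    intensity = _read_xy_table(data_lines, npoints, yfactor, "DATA TABLE")
    return _finalize(_axis_to_ppm(axis, xunits, observe_mhz, path), intensity, path)


# ---------------------------------------------------------------------------
# CSV dataset exchange format
# ---------------------------------------------------------------------------

def read_dataset_csv(path) -> SpectralDataset:
    """Read the CSV exchange format into a :class:`SpectralDataset`.

    The header row is ``sample_id, <ppm_1>, <ppm_2>, ...`` with one row per
    sample.  A ``tg_mmol_L`` column, if present, becomes ``y``; ``time_min``
    and ``subject_id`` columns become per-sample metadata.  The ppm axis is
    re-sorted descending with intensity columns permuted accordingly.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("CSV is missing the 'sample_id' header column")
    sample_ids = df["sample_id"].tolist()
    dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
    if dupes:
        raise ValueError(f"duplicate sample ids: {dupes}")

    special = {"sample_id", TG_COLUMN, *META_COLUMNS}
    ppm_cols = [c for c in df.columns if c not in special]
    try:
        ppm = np.array([float(c) for c in ppm_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric ppm column header: {exc}") from exc

    block = df[ppm_cols]
    bad = block.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"missing or non-numeric cell at row '{sample_ids[r]}', column '{ppm_cols[c]}'"
        )
    X = block.to_numpy(dtype=float)

    order = np.argsort(ppm)[::-1]
    ppm = ppm[order]
    X = X[:, order]

    y = None
    if TG_COLUMN in df.columns:
        if df[TG_COLUMN].isna().any():
            row = sample_ids[int(np.argwhere(df[TG_COLUMN].isna().to_numpy())[0][0])]
            raise ValueError(f"missing {TG_COLUMN} value for sample '{row}'")
        y = df[TG_COLUMN].to_numpy(dtype=float)

    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    meta = df[meta_cols].reset_index(drop=True) if meta_cols else None
    return SpectralDataset(ppm=ppm, X=X, sample_ids=sample_ids, y=y, meta=meta)


def write_dataset_csv(dataset: SpectralDataset, path) -> None:
    """Write a dataset in the CSV exchange format (inverse of
    :func:`read_dataset_csv` up to float formatting)."""
    cols = {"sample_id": dataset.sample_ids}
    for j, p in enumerate(dataset.ppm):
        cols[repr(float(p))] = dataset.X[:, j]
    if dataset.y is not None:
        cols[TG_COLUMN] = dataset.y
    df = pd.DataFrame(cols)
    if dataset.meta is not None:
        for c in dataset.meta.columns:
            df[c] = dataset.meta[c].to_numpy()
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Regridding and dataset assembly
# ---------------------------------------------------------------------------

def resample_to_grid(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a target (descending) ppm grid.

    The grid must lie within the spectrum's ppm range; extrapolation is
    refused.  Linear interpolation is adequate because NMR spectra are
    densely sampled relative to their linewidths, and it is exact on
    piecewise-linear inputs and idempotent on the spectrum's own grid.
    """
    grid = np.asarray(grid, dtype=float)
    _validate_axis(grid, "grid")
    if grid[0] > spectrum.ppm[0] + 1e-12 or grid[-1] < spectrum.ppm[-1] - 1e-12:
        raise ValueError(
            f"grid range [{grid[-1]:g}, {grid[0]:g}] ppm extends beyond the "
            f"spectrum's range [{spectrum.ppm[-1]:g}, {spectrum.ppm[0]:g}] ppm"
        )
    if grid.shape == spectrum.ppm.shape and np.array_equal(grid, spectrum.ppm):
        return Spectrum(grid.copy(), spectrum.intensity.copy(), spectrum.sample_id, dict(spectrum.meta))
    # np.interp wants ascending x
    new_intensity = np.interp(grid[::-1], spectrum.ppm[::-1], spectrum.intensity[::-1])[::-1]
    return Spectrum(grid.copy(), new_intensity, spectrum.sample_id, dict(spectrum.meta))


def assemble_dataset(
    spectra: list[Spectrum],
    grid: np.ndarray,
    references: dict[str, float] | None = None,
) -> SpectralDataset:
    """Resample spectra onto a shared grid and stack them into a dataset.

    Rows follow the input order.  ``references`` maps sample id to reference
    TG (mmol/L); it must cover either all or none of the samples — partial
    coverage is an error, because a silently shrunken calibration set is a
    common source of mistakes.
    """
    if not spectra:
        raise ValueError("no spectra given")
    grid = np.asarray(grid, dtype=float)
    ids = [s.sample_id for s in spectra]
    dupes = sorted({s for s in ids if ids.count(s) > 1})
    if dupes:
        raise ValueError(f"duplicate sample ids: {dupes}")
    X = np.vstack([resample_to_grid(s, grid).intensity for s in spectra])
    y = None
    if references:
        missing = [i for i in ids if i not in references]
        if missing:
            raise ValueError(
                f"references cover only part of the samples; missing: {missing}"
            )
        y = np.array([float(references[i]) for i in ids])
    return SpectralDataset(ppm=grid.copy(), X=X, sample_ids=ids, y=y)
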