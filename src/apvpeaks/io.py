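"""Spectrum and peak-table I/O.

Supported inputs are profile spectra as plain two-column text
(whitespace, comma or tab delimited, ``#`` comments, optional header) and
mzML.  The mzML reader is deliberately minimal: it decodes the m/z and
intensity binary arrays (64/32-bit floats, optionally zlib compressed) of
one selected spectrum and ignores everything else.

Peak tables are CSV files with the fixed header
``summit_mz,height,sigma1,sigma2,beta1,beta2,area,asymmetry,start_mz,end_mz,sse``.
"""

from __future__ import annotations

import base64
import logging
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PEAK_TABLE_COLUMNS",
    "PeakTable",
    "Spectrum",
    "read_peak_table",
    "read_spectrum",
    "write_peak_table",
    "write_spectrum",
]

PEAK_TABLE_COLUMNS = (
    "summit_mz",
    "height",
    "sigma1",
    "sigma2",
    "beta1",
    "beta2",
    "area",
    "asymmetry",
    "start_mz",
    "end_mz",
    "sse",
)


class SpectrumFormatError(ValueError):
    """Raised for unparseable or invariant-violating spectrum input."""


@dataclass
class Spectrum:
    """A profile mass spectrum: paired m/z and intensity arrays.

    m/z values are strictly increasing; processing stages annotate
    ``metadata['stage']`` so downstream steps can warn about missing
    preprocessing.
    """

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumFormatError("mz and intensity must be 1-D")
        if self.mz.size != self.intensity.size:
            raise SpectrumFormatError("mz and intensity length mismatch")
        if self.mz.size < 2:
            raise SpectrumFormatError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.mz) > 0):
            raise SpectrumFormatError("mz must be strictly increasing")

    def __len__(self) -> int:
        return int(self.mz.size)

    def with_intensity(self, intensity: np.ndarray, stage: str | None = None) -> "Spectrum":
        meta = dict(self.metadata)
        if stage is not None:
            meta["stage"] = stage
        return Spectrum(self.mz.copy(), np.asarray(intensity, dtype=float), meta)


@dataclass
class PeakTable:
    """Detected peaks, one row per fitted peak, sorted by summit m/z."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"peak table missing columns: {missing}")
        self.df = self.df.loc[:, list(PEAK_TABLE_COLUMNS)].reset_index(drop=True)
        if len(self.df):
            if not self.df["summit_mz"].is_monotonic_increasing:
                raise ValueError("peak table rows must be sorted by summit_mz")
            if (self.df["asymmetry"] < 1).any():
                raise ValueError("asymmetry must be >= 1")
            bad = (self.df["summit_mz"] < self.df["start_mz"]) | (
                self.df["summit_mz"] > self.df["end_mz"]
            )
            if bad.any():
                raise ValueError("summit_mz outside [start_mz, end_mz]")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "PeakTable":
        df = pd.DataFrame(rows, columns=list(PEAK_TABLE_COLUMNS))
        df = df.sort_values("summit_mz", kind="stable").reset_index(drop=True)
        return cls(df)

    @classmethod
    def empty(cls) -> "PeakTable":
        return cls(pd.DataFrame(columns=list(PEAK_TABLE_COLUMNS)))


def _read_text_spectrum(path: Path) -> tuple[np.ndarray, np.ndarray]:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").replace("\t", " ").split()
            if len(parts) < 2:
                raise SpectrumFormatError(f"{path}:{lineno}: expected two columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1 or (not rows and lineno <= 2):
                    continue  # header line
                raise SpectrumFormatError(
                    f"{path}:{lineno}: non-numeric content {line!r}"
                ) from None
    if len(rows) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data points")
    arr = np.asarray(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary(elem) -> tuple[str | None, np.ndarray]:
    dtype = "d"
    compressed = False
    kind = None
    for cv in elem.iter():
        if not cv.tag.endswith("cvParam"):
            continue
        name = cv.get("name", "")
        if name == "32-bit float":
            dtype = "f"
        elif name == "64-bit float":
            dtype = "d"
        elif name == "zlib compression":
            compressed = True
        elif name == "m/z array":
            kind = "mz"
        elif name == "intensity array":
            kind = "intensity"
    node = elem.find(f"{_NS}binary")
    if node is None:
        node = elem.find("binary")
    raw = base64.b64decode((node.text or "").strip()) if node is not None else b""
    if compressed:
        raw = zlib.decompress(raw)
    width = struct.calcsize(dtype)
    values = np.frombuffer(raw, dtype=np.float32 if dtype == "f" else np.float64)
    if values.size * width != len(raw):
        raise SpectrumFormatError("corrupt binary array in mzML")
    return kind, values.astype(float)


def _read_mzml_spectrum(path: Path, index: int) -> tuple[np.ndarray, np.ndarray]:
    try:
        tree = ElementTree.parse(path)
    except ElementTree.ParseError as exc:
        raise SpectrumFormatError(f"{path}: not valid XML ({exc})") from exc
    spectra = tree.getroot().iter(f"{_NS}spectrum")
    spectra = list(spectra) or list(tree.getroot().iter("spectrum"))
    if not spectra:
        raise SpectrumFormatError(f"{path}: no <spectrum> elements")
    if not (0 <= index < len(spectra)):
        raise SpectrumFormatError(
            f"{path}: spectrum index {index} out of range (n={len(spectra)})"
        )
    mz = inten = None
    for bda in spectra[index].iter(f"{_NS}binaryDataArray"):
        kind, values = _decode_binary(bda)
        if kind == "mz":
            mz = values
        elif kind == "intensity":
            inten = values
    if mz is None or inten is None:
        for bda in spectra[index].iter("binaryDataArray"):
            kind, values = _decode_binary(bda)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
    if mz is None or inten is None:
        raise SpectrumFormatError(f"{path}: missing m/z or intensity array")
    return mz, inten


def read_spectrum(path, format: str = "auto", index: int = 0) -> Spectrum:
    """Read one profile spectrum from ``path``.

    ``format`` is ``"mzml"``, ``"text"`` or ``"auto"`` (sniffed from the
    extension, falling back to content).  Unsorted m/z values are sorted
    with a warning; negative raw intensities are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "mzml" if path.suffix.lower() == ".mzml" else "text"
    if format == "mzml":
        mz, intensity = _read_mzml_spectrum(path, index)
    elif format == "text":
        mz, intensity = _read_text_spectrum(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if np.any(intensity < 0):
        raise SpectrumFormatError(f"{path}: negative raw intensity")
    if not np.all(np.diff(mz) > 0):
        logger.warning("%s: m/z not sorted; sorting", path)
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
    return Spectrum(mz, intensity, metadata={"source": str(path), "stage": "raw"})


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column text at full float precision."""
    arr = np.column_stack([spectrum.mz, spectrum.intensity])
    np.savetxt(path, arr, fmt="%.17g", delimiter="\t", header="mz\tintensity")


def write_peak_table(peaks: PeakTable, path) -> None:
    """Write a peak table as CSV with the canonical column order."""
    peaks.df.to_csv(path, index=False, float_format="%.15g")


def read_peak_table(path) -> PeakTable:
    return PeakTable(pd.read_csv(path))
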