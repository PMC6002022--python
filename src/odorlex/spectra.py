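"""Electron-ionization mass spectra: ingest, m/z windowing, normalization.

Unit-resolution EI spectra are carried as sparse integer-m/z -> intensity
maps and assembled into a dense chemicals x m/z-bin matrix.  The default
window keeps m/z 51..262 inclusive (below ~50 the fragments are dominated
by odorless air constituents; high m/z means low volatility), giving a
212-dimensional input, and the whole dataset is scaled by one global
maximum so values fall in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MZ_LO_DEFAULT = 51
MZ_HI_DEFAULT = 262


class SpectrumError(ValueError):
    """Raised for malformed or invalid mass-spectrum input."""


@dataclass
class RawSpectrum:
    """One chemical's EI spectrum as an integer m/z -> intensity map."""

    chemical_id: str
    peaks: dict[int, float]

    def __post_init__(self) -> None:
        clean: dict[int, float] = {}
        for mz, inten in self.peaks.items():
            mz_int = int(round(float(mz)))
            if abs(float(mz) - mz_int) > 1e-9:
                logger.warning(
                    "spectrum %s: non-integer m/z %s rounded to %d",
                    self.chemical_id, mz, mz_int,
                )
            if mz_int < 1:
                raise SpectrumError(f"spectrum {self.chemical_id}: m/z {mz} < 1")
            if inten < 0:
                raise SpectrumError(
                    f"spectrum {self.chemical_id}: negative intensity {inten} at m/z {mz}"
                )
            clean[mz_int] = clean.get(mz_int, 0.0) + float(inten)
        self.peaks = clean


@dataclass
class SpectrumMatrix:
    """Chemicals x m/z-bin intensity matrix normalized to [0, 1].

    Column ``j`` corresponds to m/z ``mz_lo + j``; after normalization the
    dataset-wide maximum entry is exactly 1.
    """

    chemical_ids: list[str]
    mz_lo: int
    mz_hi: int
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        expected = self.mz_hi - self.mz_lo + 1
        if self.matrix.shape != (len(self.chemical_ids), expected):
            raise SpectrumError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.chemical_ids)} chemicals and window "
                f"[{self.mz_lo}, {self.mz_hi}]"
            )
        if self.matrix.min() < 0 or self.matrix.max() > 1:
            raise SpectrumError("normalized intensities must lie in [0, 1]")

    @property
    def n_dimensions(self) -> int:
        return self.matrix.shape[1]

    @property
    def mz_values(self) -> np.ndarray:
        return np.arange(self.mz_lo, self.mz_hi + 1)


def read_spectra(path, *, format: str = "msp") -> list[RawSpectrum]:
    """Read spectra from NIST-MSP-style text or a wide CSV.

    MSP dialect: records separated by blank lines, each with a ``Name:``
    line, an optional ``Num Peaks:`` line, then whitespace- or
    semicolon-separated ``m/z intensity`` pairs.  Missing m/z bins are
    implicit zeros.  CSV dialect: rows = chemicals (first column id),
    columns = integer m/z.
    """
    if format == "msp":
        return _read_msp(path)
    if format == "csv":
        return _read_csv(path)
    raise SpectrumError(f"unknown spectrum format: {format!r}")


def _read_msp(path) -> list[RawSpectrum]:
    spectra: list[RawSpectrum] = []
    name: str | None = None
    peaks: dict[int, float] = {}

    def flush() -> None:
        nonlocal name, peaks
        if name is not None:
            spectra.append(RawSpectrum(name, peaks))
        name, peaks = None, {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                flush()
                continue
            low = line.lower()
            if low.startswith("name:"):
                flush()
                name = line.split(":", 1)[1].strip()
                continue
            if ":" in line and not line[0].isdigit():
                continue  # other metadata fields (Num Peaks, MW, ...)
            if name is None:
                raise SpectrumError(f"line {lineno}: peak data before any Name: field")
            for pair in line.replace(";", "\n").splitlines():
                pair = pair.strip()
                if not pair:
                    continue
                parts = pair.split()
                if len(parts) != 2:
                    raise SpectrumError(f"line {lineno}: malformed peak line {pair!r}")
                try:
                    mz, inten = float(parts[0]), float(parts[1])
                except ValueError as exc:
                    raise SpectrumError(
                        f"line {lineno}: malformed peak line {pair!r}"
                    ) from exc
                peaks[int(round(mz))] = peaks.get(int(round(mz)), 0.0) + inten
    flush()
    # dataclass validation happens per-record; re-check negatives give context
    return spectra


def _read_csv(path) -> list[RawSpectrum]:
    df = pd.read_csv(path, index_col=0)
    mzs = [int(round(float(c))) for c in df.columns]
    out = []
    for cid, row in zip(df.index, df.to_numpy(dtype=float)):
        peaks = {mz: v for mz, v in zip(mzs, row) if v != 0}
        out.append(RawSpectrum(str(cid), peaks))
    return out


def write_spectra(spectra: list[RawSpectrum], path, *, format: str = "msp") -> None:
    """Write spectra in a dialect :func:`read_spectra` round-trips."""
    if format == "msp":
        with open(path, "w") as fh:
            for sp in spectra:
                fh.write(f"Name: {sp.chemical_id}\n")
                fh.write(f"Num Peaks: {len(sp.peaks)}\n")
                for mz in sorted(sp.peaks):
                    fh.write(f"{mz} {sp.peaks[mz]!r}\n")
                fh.write("\n")
        return
    if format == "csv":
        all_mz = sorted({mz for sp in spectra for mz in sp.peaks})
        mat = np.zeros((len(spectra), len(all_mz)))
        index = {mz: j for j, mz in enumerate(all_mz)}
        for i, sp in enumerate(spectra):
            for mz, v in sp.peaks.items():
                mat[i, index[mz]] = v
        pd.DataFrame(
            mat, index=[sp.chemical_id for sp in spectra], columns=all_mz
        ).rename_axis("chemical_id").to_csv(path)
        return
    raise SpectrumError(f"unknown spectrum format: {format!r}")


def build_spectrum_matrix(
    spectra: list[RawSpectrum],
    mz_lo: int = MZ_LO_DEFAULT,
    mz_hi: int = MZ_HI_DEFAULT,
    *,
    per_spectrum_norm: bool = False,
) -> SpectrumMatrix:
    """Window spectra to [mz_lo, mz_hi] and normalize by the global maximum.

    Every retained intensity is divided by the single maximum over all
    chemicals and all retained bins, so the dataset shares one scale (the
    non-default ``per_spectrum_norm`` divides each row by its own maximum
    instead, for sensitivity studies only).

    Raises
    ------
    SpectrumError
        If the window is empty of signal across the whole dataset.
    """
    if mz_lo > mz_hi:
        raise SpectrumError(f"mz_lo {mz_lo} exceeds mz_hi {mz_hi}")
    n_bins = mz_hi - mz_lo + 1
    mat = np.zeros((len(spectra), n_bins))
    for i, sp in enumerate(spectra):
        for mz, inten in sp.peaks.items():
            if mz_lo <= mz <= mz_hi:
                mat[i, mz - mz_lo] = inten
    if per_spectrum_norm:
        row_max = mat.max(axis=1, keepdims=True)
        if (row_max == 0).any():
            raise SpectrumError("per-spectrum normalization: all-zero window row")
        mat = mat / row_max
    else:
        global_max = mat.max() if mat.size else 0.0
        if global_max <= 0:
            raise SpectrumError(
                f"window [{mz_lo}, {mz_hi}] contains no signal in any spectrum; "
                "normalization undefined"
            )
        mat = mat / global_max
    return SpectrumMatrix([sp.chemical_id for sp in spectra], mz_lo, mz_hi, mat)
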