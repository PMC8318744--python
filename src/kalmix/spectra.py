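"""Reading, writing, and grid alignment of UV-Vis absorption spectra.

A spectrum is a single absorbance trace A(λ) on a strictly increasing
wavelength grid (nm).  All downstream computation assumes every spectrum in
a study sits on one common grid — the instrument scans all solutions with
identical settings — so alignment is an explicit, opt-in step rather than a
silent default.

Files are plain CSV with two numeric columns ``wavelength_nm,absorbance``
(dot decimal, UTF-8, one optional header line).  Negative absorbances are
legal input (baseline noise dips below zero) but are surfaced via
:attr:`Spectrum.has_negative` so report layers can flag them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import GridMismatchError, SpectrumParseError

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "read_spectrum",
    "write_spectrum",
    "align_to_grid",
]

#: two grids are "identical" if they agree element-wise within this (nm)
GRID_ATOL = 1e-9


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace on a wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelengths in nm, length >= 2.
    absorbances
        Absorbance values in AU, same length, all finite.
    label
        Free-text identifier (defaults to the file stem when read from disk).
    """

    wavelengths: np.ndarray
    absorbances: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbances, dtype=float)
        if wl.ndim != 1 or ab.ndim != 1:
            raise ValueError("wavelengths and absorbances must be 1-D")
        if wl.size != ab.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {ab.size} absorbances"
            )
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(ab)):
            raise ValueError("non-finite values in spectrum")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        wl.flags.writeable = False
        ab.flags.writeable = False
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbances", ab)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def has_negative(self) -> bool:
        """True when any absorbance dips below zero (baseline noise)."""
        return bool(np.any(self.absorbances < 0.0))

    def scaled(self, k: float, label: str | None = None) -> "Spectrum":
        """Return a copy with absorbances multiplied by ``k``."""
        return Spectrum(
            self.wavelengths.copy(),
            self.absorbances * float(k),
            label if label is not None else self.label,
        )


@dataclass(frozen=True)
class SpectrumSet:
    """Spectra validated to share one wavelength grid."""

    spectra: tuple[Spectrum, ...]
    grid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        spectra = tuple(self.spectra)
        if not spectra:
            raise ValueError("SpectrumSet needs at least one spectrum")
        grid = self.grid
        if grid is None:
            grid = spectra[0].wavelengths
        grid = np.asarray(grid, dtype=float)
        bad = [
            s.label
            for s in spectra
            if len(s) != grid.size
            or not np.allclose(s.wavelengths, grid, rtol=0.0, atol=GRID_ATOL)
        ]
        if bad:
            raise GridMismatchError(
                "spectra not on the common grid: " + ", ".join(repr(b) for b in bad)
            )
        grid = grid.copy()
        grid.flags.writeable = False
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "grid", grid)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.spectra)

    def matrix(self) -> np.ndarray:
        """Absorbance matrix, shape (n_wavelengths, n_spectra)."""
        return np.column_stack([s.absorbances for s in self.spectra])


def _parse_float(token: str, path: Path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise SpectrumParseError(
            f"{path}: line {lineno}: could not parse {token!r} as a number"
        ) from None


def read_spectrum(
    path: str | Path,
    *,
    delimiter: str = ",",
    label: str | None = None,
) -> Spectrum:
    """Read a two-column wavelength/absorbance CSV file.

    A single leading header line is detected and skipped automatically.
    Rows may appear in any wavelength order; the result is sorted.  Duplicate
    wavelengths are an error — silently averaging them would hide an
    acquisition problem.
    """
    path = Path(path)
    wavelengths: list[float] = []
    absorbances: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = [t.strip() for t in line.split(delimiter)]
            if len(tokens) != 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(tokens)}"
                )
            if lineno == 1 and not wavelengths:
                # optional header: skip iff either token is non-numeric
                try:
                    float(tokens[0])
                    float(tokens[1])
                except ValueError:
                    continue
            wavelengths.append(_parse_float(tokens[0], path, lineno))
            absorbances.append(_parse_float(tokens[1], path, lineno))
    if len(wavelengths) < 2:
        raise SpectrumParseError(
            f"{path}: insufficient data ({len(wavelengths)} rows, need >= 2)"
        )
    wl = np.asarray(wavelengths)
    ab = np.asarray(absorbances)
    order = np.argsort(wl, kind="stable")
    wl, ab = wl[order], ab[order]
    if np.any(np.diff(wl) == 0.0):
        dup = wl[:-1][np.diff(wl) == 0.0][0]
        raise SpectrumParseError(f"{path}: duplicate wavelength {dup} nm")
    return Spectrum(wl, ab, label if label is not None else path.stem)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as ``wavelength_nm,absorbance`` CSV.

    Values are written with ``repr`` precision so a read-back round trip
    reproduces them bit-exactly.
    """
    path = Path(path)
    lines = ["wavelength_nm,absorbance"]
    lines += [
        f"{float(wl)!r},{float(ab)!r}"
        for wl, ab in zip(spectrum.wavelengths, spectrum.absorbances)
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def align_to_grid(
    spectra: Iterable[Spectrum],
    *,
    interpolate: bool = False,
) -> SpectrumSet:
    """Collect spectra onto a common grid.

    Without ``interpolate`` every spectrum must already sit on the first
    spectrum's grid (within :data:`GRID_ATOL`).  With it, spectra are
    linearly interpolated onto the first spectrum's grid; extrapolation
    beyond a source spectrum's range is refused rather than guessed.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra given")
    grid = spectra[0].wavelengths
    if not interpolate:
        return SpectrumSet(tuple(spectra), grid)
    aligned: list[Spectrum] = []
    for s in spectra:
        if len(s) == grid.size and np.allclose(
            s.wavelengths, grid, rtol=0.0, atol=GRID_ATOL
        ):
            aligned.append(s)
            continue
        if grid[0] < s.wavelengths[0] - GRID_ATOL or grid[-1] > s.wavelengths[-1] + GRID_ATOL:
            raise GridMismatchError(
                f"cannot interpolate {s.label!r}: target grid "
                f"[{grid[0]}, {grid[-1]}] nm extends beyond its range "
                f"[{s.wavelengths[0]}, {s.wavelengths[-1]}] nm"
            )
        aligned.append(
            Spectrum(grid.copy(), np.interp(grid, s.wavelengths, s.absorbances), s.label)
        )
    return SpectrumSet(tuple(aligned), grid)
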