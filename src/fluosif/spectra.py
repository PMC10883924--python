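"""Spectral containers shared by every stage of the pipeline.

A :class:`Spectrum` is a wavelength grid (nm, strictly ascending) with values
and a declared quantity/units string, covering the three quantities the
instruments produce: downwelling irradiance (mW m-2 nm-1), upwelling radiance
(mW m-2 nm-1 sr-1) and dark-corrected detector count rates (DN s-1).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import numpy as np

__all__ = ["Spectrum", "PairedObservation"]

# canonical unit strings used in file headers
IRRADIANCE_UNITS = "irradiance mW m-2 nm-1"
RADIANCE_UNITS = "radiance mW m-2 nm-1 sr-1"
DN_RATE_UNITS = "DN s-1"


@dataclass(frozen=True)
class Spectrum:
    """One spectrum on an ascending wavelength grid.

    Parameters
    ----------
    wavelengths : array of float
        Wavelength grid in nm, strictly ascending.
    values : array of float
        Spectral values, same length as ``wavelengths``.
    quantity : str
        Free-form declaration of physical quantity and units
        (e.g. ``"radiance mW m-2 nm-1 sr-1"``).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    quantity: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vv = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vv.shape != wl.shape:
            raise ValueError("wavelengths and values must be 1-D and same length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly ascending")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vv)

    # -- basic algebra -----------------------------------------------------
    def same_grid(self, other: "Spectrum", atol: float = 1e-9) -> bool:
        return (
            self.wavelengths.shape == other.wavelengths.shape
            and np.allclose(self.wavelengths, other.wavelengths, atol=atol, rtol=0.0)
        )

    def with_values(self, values: np.ndarray, quantity: str | None = None) -> "Spectrum":
        return replace(
            self, values=np.asarray(values, dtype=float),
            quantity=self.quantity if quantity is None else quantity,
        )

    def interp(self, wavelength: float | np.ndarray) -> float | np.ndarray:
        """Linear interpolation of the spectrum at ``wavelength`` (nm)."""
        out = np.interp(wavelength, self.wavelengths, self.values)
        return float(out) if np.isscalar(wavelength) else out

    def value_at(self, wavelength: float) -> float:
        """Value at the grid sample nearest to ``wavelength``."""
        return float(self.values[self.index_of(wavelength)])

    def index_of(self, wavelength: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths - wavelength)))

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of samples with lo <= lambda <= hi."""
        return (self.wavelengths >= lo) & (self.wavelengths <= hi)

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi

    # -- I/O ---------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        """Write as two-column delimited text with a one-line units header."""
        header = f"wavelength_nm\t{self.quantity or 'value'}"
        np.savetxt(
            path,
            np.column_stack([self.wavelengths, self.values]),
            delimiter="\t",
            header=header,
            comments="# ",
        )

    @classmethod
    def read(cls, path: str | Path) -> "Spectrum":
        with open(path) as fh:
            first = fh.readline()
            quantity = ""
            if first.startswith("#"):
                parts = first.lstrip("# ").rstrip("\n").split("\t")
                if len(parts) == 2:
                    quantity = parts[1]
                body = fh.read()
            else:
                body = first + fh.read()
        arr = np.loadtxt(io.StringIO(body), delimiter="\t")
        arr = np.atleast_2d(arr)
        return cls(arr[:, 0], arr[:, 1], quantity)


@dataclass
class PairedObservation:
    """Time-stamped bundle of irradiance and radiance for both channels.

    ``e_hr``/``l_hr`` are the high-resolution channel (730-780 nm, for SIF
    retrieval); ``e_bb``/``l_bb`` the broadband channel (350-1100 nm, for
    vegetation indices).  Either channel may be absent (None).
    """

    timestamp: datetime
    e_hr: Spectrum | None = None
    l_hr: Spectrum | None = None
    e_bb: Spectrum | None = None
    l_bb: Spectrum | None = None
    t_int_hr: float = 1.0   # s
    t_int_bb: float = 1.0   # s
    enclosure_temp: float = 25.0  # deg C
    meta: dict = field(default_factory=dict)
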