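"""Spectrum container and plain-text I/O.

Spectra are two-column tables (wavenumber in cm^-1, absorbance) on a
strictly increasing grid inside the measured range [1000, 4000] cm^-1,
with lightweight metadata: KCl concentration (mol/L), a role tag and an
optional protein label.  Files are CSV with ``#``-prefixed metadata
comment lines and the header ``wavenumber_cm-1,absorbance``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

ROLES = ("solution", "reference", "solute_correlated")
MEASURED_RANGE = (1000.0, 4000.0)


@dataclass
class Spectrum:
    """Wavenumber/absorbance pair with metadata."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    concentration: float | None = None  # KCl, mol/L
    role: str = "solution"
    label: str | None = None
    #: simulated spectra (e.g. mapped OH-stretch bands) may extend beyond
    #: the ATR-FTIR measured range; measured spectra may not.
    simulated: bool = False

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumbers and intensities must be equal-length 1D arrays")
        if len(self.wavenumbers) < 2 or np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        lo, hi = MEASURED_RANGE
        if not self.simulated and (
            self.wavenumbers[0] < lo - 1e-9 or self.wavenumbers[-1] > hi + 1e-9
        ):
            raise ValueError(f"wavenumbers must lie within {MEASURED_RANGE} cm^-1")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")

    def same_grid(self, other: "Spectrum") -> bool:
        return len(self.wavenumbers) == len(other.wavenumbers) and np.allclose(
            self.wavenumbers, other.wavenumbers
        )

    def with_intensities(self, y: np.ndarray, role: str | None = None) -> "Spectrum":
        return replace(
            self, intensities=np.asarray(y, dtype=float), role=role or self.role
        )

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.wavenumbers >= lo) & (self.wavenumbers <= hi)

    def band_integral(self, lo: float, hi: float) -> float:
        """Trapezoidal integral of absorbance over [lo, hi] on the native grid."""
        m = self.window_mask(lo, hi)
        if m.sum() < 2:
            raise ValueError(f"band [{lo}, {hi}] contains fewer than 2 grid points")
        return float(np.trapezoid(self.intensities[m], self.wavenumbers[m]))


def resample(spec: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear-interpolation resampling onto an explicit target grid."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < spec.wavenumbers[0] or grid[-1] > spec.wavenumbers[-1]:
        raise ValueError("target grid extends beyond the measured spectrum")
    return replace(
        spec,
        wavenumbers=grid,
        intensities=np.interp(grid, spec.wavenumbers, spec.intensities),
    )


def write_spectrum_csv(spec: Spectrum, path) -> None:
    path = Path(path)
    meta = {
        "concentration": spec.concentration,
        "role": spec.role,
        "label": spec.label,
        "simulated": spec.simulated,
    }
    with path.open("w") as fh:
        fh.write(f"# meta: {json.dumps(meta, sort_keys=True)}\n")
        fh.write("wavenumber_cm-1,absorbance\n")
        for w, a in zip(spec.wavenumbers, spec.intensities):
            fh.write(f"{w:.17g},{a:.17g}\n")


def read_spectrum_csv(path) -> Spectrum:
    path = Path(path)
    meta: dict = {}
    rows: list[tuple[float, float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("meta:"):
                    meta = json.loads(body[len("meta:"):])
                continue
            if line.lower().startswith("wavenumber"):
                continue
            w, a = line.split(",")
            rows.append((float(w), float(a)))
    arr = np.array(rows)
    return Spectrum(
        wavenumbers=arr[:, 0],
        intensities=arr[:, 1],
        concentration=meta.get("concentration"),
        role=meta.get("role", "solution"),
        label=meta.get("label"),
        simulated=bool(meta.get("simulated", False)),
    )
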