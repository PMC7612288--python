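"""Per-spectrum colorimetric transforms.

Cone excitations follow the MacLeod–Boynton convention: the L and M
excitations are luminance-scaled so that L + M is the photopic luminance
signal, hence the chromaticity axes are l = L/(L+M) and s = S/(L+M) with
equal-energy white at (0.7078, 1.000).  CIE 1931 (x, y) chromaticities are
computed from the same working grid by Riemann summation against the
colour-matching functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedChromaticityError
from .spectra import SpectralDistribution, WavelengthGrid
from .standards import KM_LUMENS_PER_WATT, ColorimetricTables, tables_for_grid


@dataclass(frozen=True)
class ConeExcitation:
    """Scaled cone excitations (L+M = luminance signal) of one spectrum."""

    L: float
    M: float
    S: float
    luminance: float
    luminance_unit: str = "relative"


@dataclass(frozen=True)
class ChromaticityPoint:
    """CIE 1931 (x, y) plus MacLeod–Boynton (l, s) with a photometric level."""

    x: float
    y: float
    l_mb: float
    s_mb: float
    photometric_level: float = float("nan")
    level_unit: str = "relative"


_LUMINANCE_UNITS = {"radiance": "cd/m2", "irradiance": "lx"}


def cone_excitations(
    spd: SpectralDistribution, tables: ColorimetricTables | None = None
) -> ConeExcitation:
    """Sum *spd* against the scaled cone fundamentals with the Δλ weight.

    Radiance input yields luminance in cd/m², irradiance yields illuminance
    in lx (both via the 683 lm/W maximum efficacy); any other quantity kind
    yields a relative luminance.
    """
    tables = tables or tables_for_grid(spd.grid)
    tables.check_grid(spd)
    dlam = spd.grid.step_nm
    L, M, S = (spd.values @ tables.cones) * dlam
    lum = L + M
    unit = _LUMINANCE_UNITS.get(spd.kind, "relative")
    if unit != "relative":
        lum *= KM_LUMENS_PER_WATT
    return ConeExcitation(float(L), float(M), float(S), float(lum), unit)


def macleod_boynton(exc: ConeExcitation) -> tuple[float, float]:
    """MacLeod–Boynton (l, s) = (L/(L+M), S/(L+M)) of a cone excitation."""
    denom = exc.L + exc.M
    if denom <= 0:
        raise UndefinedChromaticityError("L + M = 0: MacLeod-Boynton chromaticity undefined")
    return exc.L / denom, exc.S / denom


def tristimulus(
    spd: SpectralDistribution, tables: ColorimetricTables | None = None
) -> tuple[float, float, float]:
    """CIE 1931 tristimulus values X, Y, Z by Riemann summation."""
    tables = tables or tables_for_grid(spd.grid)
    tables.check_grid(spd)
    X, Y, Z = (spd.values @ tables.cmf) * spd.grid.step_nm
    return float(X), float(Y), float(Z)


def xy_chromaticity(
    spd: SpectralDistribution, tables: ColorimetricTables | None = None
) -> ChromaticityPoint:
    """Full chromaticity of a spectrum: (x, y), (l, s) and photometric level."""
    tables = tables or tables_for_grid(spd.grid)
    X, Y, Z = tristimulus(spd, tables)
    total = X + Y + Z
    if total <= 0:
        raise UndefinedChromaticityError("all-zero spectrum has no chromaticity")
    exc = cone_excitations(spd, tables)
    l_mb, s_mb = macleod_boynton(exc)
    return ChromaticityPoint(
        x=X / total, y=Y / total, l_mb=l_mb, s_mb=s_mb,
        photometric_level=exc.luminance, level_unit=exc.luminance_unit,
    )


# Alias emphasising that the point carries every coordinate system we plot.
chromaticity = xy_chromaticity


def spectral_locus(
    tables: ColorimetricTables | None = None, grid: WavelengthGrid | None = None
) -> list[ChromaticityPoint]:
    """Chromaticities of monochromatic spikes at each grid wavelength."""
    if tables is None:
        tables = tables_for_grid(grid or WavelengthGrid.surface())
    pts: list[ChromaticityPoint] = []
    for i in range(tables.grid.n_channels):
        X, Y, Z = tables.cmf[i]
        total = X + Y + Z
        L, M, S = tables.cones[i]
        if total <= 0 or (L + M) <= 0:
            continue  # far-red channels where the tables vanish entirely
        pts.append(
            ChromaticityPoint(
                x=X / total, y=Y / total, l_mb=L / (L + M), s_mb=S / (L + M),
                photometric_level=float(Y * tables.grid.step_nm),
            )
        )
    return pts
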