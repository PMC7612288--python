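"""Standard colorimetric tables on a working grid.

Vendored fixtures (``data/``):

* CIE 1931 2° colour-matching functions x̄,ȳ,z̄ at their native 5 nm
  tabulation, 380–780 nm.
* CIE daylight-model components S0,S1,S2 at their native 10 nm tabulation.

Cone fundamentals in the Stockman–Sharpe (CIE 2006/170-2) convention are
derived at load time from the colour-matching functions through the inverse
of the published cone-fundamental ↔ XYZ 3×3 transform

    x̄ = 1.94735469·l̄ − 1.41445123·m̄ + 0.36476327·s̄
    ȳ = 0.68990272·l̄ + 0.34832189·m̄
    z̄ = 1.93485343·s̄

This construction uses published constants only.  It makes the luminance
identity kL·l̄ + kM·m̄ = ȳ exact, and places equal-energy white at
MacLeod–Boynton (0.7078, 1.000).  Because it is applied to the 1931
observer rather than the 2006 observer's own XYZ tables, the derived
fundamentals are an approximation to the directly tabulated ones, with the
largest relative differences below ~470 nm; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import GridError
from .spectra import SpectralDistribution, WavelengthGrid

# CIE 170-2 cone-fundamental -> XYZ transform (2 degree).
_LMS_TO_XYZ = np.array(
    [
        [1.94735469, -1.41445123, 0.36476327],
        [0.68990272, 0.34832189, 0.0],
        [0.0, 0.0, 1.93485343],
    ]
)

#: Luminance weights of the scaled L and M fundamentals (rows of the ȳ line).
KL = 0.68990272
KM = 0.34832189

#: Maximum luminous efficacy of photopic vision, lm/W.
KM_LUMENS_PER_WATT = 683.0


def _load_table(filename: str) -> pd.DataFrame:
    with resources.files("chromalight.data").joinpath(filename).open() as fh:
        return pd.read_csv(fh)


def _interp_columns(df: pd.DataFrame, columns: list[str], grid: WavelengthGrid) -> np.ndarray:
    """Shape-preserving (monotone cubic) interpolation of smooth standard tables."""
    src_w = df["wavelength_nm"].to_numpy(float)
    if grid.start_nm < src_w[0] - 1e-9 or grid.stop_nm > src_w[-1] + 1e-9:
        raise GridError(
            f"working grid {grid} outside tabulated range {src_w[0]}-{src_w[-1]} nm"
        )
    out = np.empty((grid.n_channels, len(columns)))
    for j, col in enumerate(columns):
        out[:, j] = PchipInterpolator(src_w, df[col].to_numpy(float))(grid.wavelengths)
    return out


@dataclass(frozen=True)
class ColorimetricTables:
    """CMFs, cone fundamentals and MacLeod–Boynton scaling on one grid.

    ``cmf`` and ``cones`` are (n_channels, 3) arrays.  The cone columns are
    already scaled by (kL, kM, kS): summing a spectrum against them with the
    Δλ weight yields cone excitations whose L+M equals the ȳ-based
    luminance, and whose S/(L+M) is 1 for equal-energy white.
    """

    grid: WavelengthGrid
    cmf: np.ndarray
    cones: np.ndarray
    k_l: float
    k_m: float
    k_s: float

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def check_grid(self, spd: SpectralDistribution) -> None:
        if spd.grid != self.grid:
            raise GridError(f"spectrum grid {spd.grid} != tables grid {self.grid}")


@lru_cache(maxsize=8)
def tables_for_grid(grid: WavelengthGrid) -> ColorimetricTables:
    """Build (and cache) the standard tables resampled to *grid*."""
    cmf = _interp_columns(_load_table("cie_1931_2deg_cmf_5nm.csv"), ["xbar", "ybar", "zbar"], grid)
    cmf = np.clip(cmf, 0.0, None)
    raw_lms = cmf @ np.linalg.inv(_LMS_TO_XYZ).T
    # Tiny negative lobes can appear from table rounding at the far red end.
    raw_lms = np.clip(raw_lms, 0.0, None)
    sums = raw_lms.sum(axis=0)
    # s-axis scaling: s(equal-energy white) = 1 exactly on this grid.
    k_s = (KL * sums[0] + KM * sums[1]) / sums[2]
    cones = raw_lms * np.array([KL, KM, k_s])
    return ColorimetricTables(grid=grid, cmf=cmf, cones=cones, k_l=KL, k_m=KM, k_s=k_s)


@lru_cache(maxsize=8)
def daylight_components(grid: WavelengthGrid) -> np.ndarray:
    """CIE daylight-model component spectra S0, S1, S2 on *grid*, shape (n, 3).

    The native tabulation is 10 nm; intermediate values are obtained by
    linear interpolation, the interpolation rule recommended for this table.
    """
    df = _load_table("cie_daylight_components_10nm.csv")
    src_w = df["wavelength_nm"].to_numpy(float)
    if grid.start_nm < src_w[0] - 1e-9 or grid.stop_nm > src_w[-1] + 1e-9:
        raise GridError(f"working grid {grid} outside tabulated range")
    out = np.empty((grid.n_channels, 3))
    for j, col in enumerate(["S0", "S1", "S2"]):
        out[:, j] = np.interp(grid.wavelengths, src_w, df[col].to_numpy(float))
    return out


def equal_energy_white(grid: WavelengthGrid, intensity: float = 1.0) -> SpectralDistribution:
    """Flat spectrum with the given relative intensity at every channel."""
    return SpectralDistribution(
        grid, np.full(grid.n_channels, float(intensity)), "relative", "equal-energy white"
    )
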