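"""Sampled spectral distributions on uniform wavelength grids.

The two canonical grids of the survey design are 380–780 nm at 5 nm
(surface reflectance/transmittance, 81 channels) and 380–780 nm at 1 nm
(daylight radiance/irradiance, 401 channels).  Wavelength values are
channel centres in nm and ranges are inclusive of both endpoints.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, replace

import numpy as np

from .errors import GridError, RangeError, ValidationError

log = logging.getLogger(__name__)

#: Allowed quantity kinds for a spectral distribution.
QUANTITY_KINDS = ("radiance", "irradiance", "reflectance", "transmittance", "relative")


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid, endpoints inclusive, in nm."""

    start_nm: float
    stop_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise ValidationError(f"start_nm ({self.start_nm}) must be < stop_nm ({self.stop_nm})")
        if self.step_nm <= 0:
            raise ValidationError(f"step_nm must be positive, got {self.step_nm}")
        span = self.stop_nm - self.start_nm
        n = span / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                f"grid span {span} nm is not an integer multiple of step {self.step_nm} nm"
            )

    @property
    def n_channels(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_channels)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the channel centred at *wavelength_nm* (must lie on the grid)."""
        pos = (wavelength_nm - self.start_nm) / self.step_nm
        if not (0 <= pos <= self.n_channels - 1) or abs(pos - round(pos)) > 1e-9:
            raise RangeError(f"{wavelength_nm} nm is not a channel of {self}")
        return int(round(pos))

    def covers(self, other: "WavelengthGrid") -> bool:
        return self.start_nm <= other.start_nm and self.stop_nm >= other.stop_nm

    @classmethod
    def surface(cls) -> "WavelengthGrid":
        """Canonical 5 nm surface-measurement grid (81 channels)."""
        return cls(380.0, 780.0, 5.0)

    @classmethod
    def daylight(cls) -> "WavelengthGrid":
        """Canonical 1 nm daylight-measurement grid (401 channels)."""
        return cls(380.0, 780.0, 1.0)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.start_nm:g}-{self.stop_nm:g}nm@{self.step_nm:g}"


@dataclass(frozen=True)
class SpectralDistribution:
    """A sampled function of wavelength: radiance, irradiance, R(λ) or T(λ).

    Units are W·sr⁻¹·m⁻²·nm⁻¹ for radiance, W·m⁻²·nm⁻¹ for irradiance and
    dimensionless for reflectance/transmittance/relative spectra.
    Reflectance and transmittance values above 1 are legal (ratio estimates
    under measurement noise can exceed 1) but are logged, never clipped.
    """

    grid: WavelengthGrid
    values: np.ndarray
    kind: str = "relative"
    name: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.kind not in QUANTITY_KINDS:
            raise ValidationError(f"unknown quantity kind {self.kind!r}")
        if values.ndim != 1 or values.shape[0] != self.grid.n_channels:
            raise ValidationError(
                f"values length {values.shape} does not match grid "
                f"{self.grid} ({self.grid.n_channels} channels)"
            )
        finite = np.isfinite(values)
        if not finite.all():
            # NaN marks explicitly-missing channels awaiting gap filling.
            if np.isinf(values).any():
                raise ValidationError("spectral values must be finite (or NaN for missing)")
        if self.kind in ("reflectance", "transmittance"):
            if np.nanmin(values) < 0:
                raise ValidationError(f"{self.kind} values must be non-negative")
            if np.nanmax(values) > 1:
                log.info(
                    "%s %s has %d channel(s) above 1 (max %.4f); kept un-clipped",
                    self.kind, self.name or "<unnamed>",
                    int(np.sum(values > 1)), float(np.nanmax(values)),
                )

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "SpectralDistribution":
        return replace(self, values=np.asarray(values, float), kind=kind or self.kind)

    def scaled(self, factor: float) -> "SpectralDistribution":
        return self.with_values(self.values * factor)

    def value_at(self, wavelength_nm: float) -> float:
        return float(self.values[self.grid.index_of(wavelength_nm)])


def resample(spd: SpectralDistribution, target: WavelengthGrid) -> SpectralDistribution:
    """Linearly interpolate *spd* onto *target*; extrapolation is refused."""
    src = spd.grid
    if target.start_nm < src.start_nm - 1e-9 or target.stop_nm > src.stop_nm + 1e-9:
        raise RangeError(
            f"target grid {target} extends beyond source range {src}; refusing to extrapolate"
        )
    if target == src:
        return spd
    values = np.interp(target.wavelengths, src.wavelengths, spd.values)
    return SpectralDistribution(target, values, spd.kind, spd.name)


def fill_gap_linear(
    spd: SpectralDistribution, gap_start_nm: float, gap_stop_nm: float
) -> SpectralDistribution:
    """Replace channels in [gap_start, gap_stop] by the line through the flanks.

    The flanking channels are the nearest grid channels strictly outside the
    gap on each side; both must exist, so the gap may not touch the grid
    boundary.  Used e.g. to repair tabulated reflectance banks missing a
    contiguous wavelength block.
    """
    grid = spd.grid
    w = grid.wavelengths
    if gap_start_nm > gap_stop_nm:
        raise ValidationError("gap_start_nm must be <= gap_stop_nm")
    inside = (w >= gap_start_nm - 1e-9) & (w <= gap_stop_nm + 1e-9)
    if not inside.any():
        return spd
    lo = int(np.argmax(inside)) - 1
    hi = int(len(w) - np.argmax(inside[::-1])) # first index after gap
    if lo < 0 or hi > len(w) - 1:
        raise RangeError("gap touches the grid boundary; no flanking channel to interpolate from")
    x0, y0 = w[lo], spd.values[lo]
    x1, y1 = w[hi], spd.values[hi]
    values = spd.values.copy()
    values[inside] = y0 + (y1 - y0) * (w[inside] - x0) / (x1 - x0)
    return spd.with_values(values)


def require_same_grid(a: SpectralDistribution, b: SpectralDistribution) -> None:
    if a.grid != b.grid:
        raise GridError(f"grids differ: {a.grid} vs {b.grid}")


def mix(terms: list[tuple[float, SpectralDistribution]], kind: str = "relative") -> SpectralDistribution:
    """Non-negative linear combination of spectra on a common grid."""
    if not terms:
        raise ValidationError("mix() needs at least one term")
    base = terms[0][1]
    values = np.zeros(base.grid.n_channels)
    for coeff, spd in terms:
        require_same_grid(base, spd)
        values += coeff * spd.values
    return SpectralDistribution(base.grid, values, kind)
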