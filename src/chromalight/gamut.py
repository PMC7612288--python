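"""Optimal colors and the object-color gamut (MacAdam limit).

An optimal color is a 0/1-valued reflectance with at most two spectral
transitions.  Rendered under a given illuminant, the set of all optimal
colors traces the theoretical surface-color gamut: at every chromaticity
the maximum luminance achievable by any physical reflectance (values in
[0, 1]) is attained by one of them.  Transitions live on channel
boundaries of the sampled grid — a band covers the half-open wavelength
interval [λ1, λ2) in channel centres — which removes any ambiguity about
"a transition at a wavelength" on sampled data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import OutsideSupportError, UndefinedChromaticityError, ValidationError
from .spectra import SpectralDistribution
from .standards import ColorimetricTables, tables_for_grid


@dataclass(frozen=True)
class OptimalColor:
    """One two-transition 0/1 reflectance with its rendered color."""

    kind: str  # band_pass | band_stop | all_pass
    lambda1_nm: float
    lambda2_nm: float
    x: float
    y: float
    l_mb: float
    s_mb: float
    luminance: float  # relative to the illuminant (all-pass = 1)


@dataclass
class GamutSurface:
    """All optimal colors under one illuminant, as a tidy table."""

    illuminant: SpectralDistribution
    step_nm: float
    df: pd.DataFrame  # kind, lambda1_nm, lambda2_nm, x, y, l_mb, s_mb, luminance

    @property
    def points(self) -> Iterator[OptimalColor]:
        for row in self.df.itertuples(index=False):
            yield OptimalColor(*row)


def enumerate_optimal_colors(
    illuminant: SpectralDistribution,
    tables: ColorimetricTables | None = None,
    step_nm: float | None = None,
) -> GamutSurface:
    """Enumerate band-pass and band-stop optimal colors under *illuminant*.

    ``step_nm`` sets the transition resolution (a multiple of the grid
    step; default the grid step itself).  The all-pass reflectance is the
    (λ1=start, λ2=end) band-pass and reproduces the illuminant exactly;
    the all-stop reflectance has no chromaticity and is excluded.
    """
    grid = illuminant.grid
    tables = tables or tables_for_grid(grid)
    tables.check_grid(illuminant)
    step_nm = float(step_nm or grid.step_nm)
    mult = step_nm / grid.step_nm
    if abs(mult - round(mult)) > 1e-9 or mult < 1:
        raise ValidationError(f"step_nm={step_nm} is not a multiple of the grid step")
    mult = int(round(mult))

    n = grid.n_channels
    weighted = illuminant.values[:, None] * np.hstack([tables.cmf, tables.cones])
    cum = np.vstack([np.zeros(6), np.cumsum(weighted, axis=0)])  # (n+1, 6)
    total = cum[-1]
    if total[:3].sum() <= 0:
        raise UndefinedChromaticityError("illuminant renders no light; gamut undefined")

    bounds = np.arange(0, n, mult)
    if bounds[-1] != n:
        bounds = np.append(bounds, n)
    ii, jj = np.meshgrid(bounds, bounds, indexing="ij")
    sel = ii < jj
    i_idx, j_idx = ii[sel], jj[sel]

    band = cum[j_idx] - cum[i_idx]           # band-pass responses
    stop = total[None, :] - band             # band-stop complements
    is_all_pass = (i_idx == 0) & (j_idx == n)

    lam = grid.start_nm + grid.step_nm * np.concatenate([i_idx, i_idx])
    lam2 = grid.start_nm + grid.step_nm * np.concatenate([j_idx, j_idx])
    kind = np.concatenate(
        [np.where(is_all_pass, "all_pass", "band_pass"), np.full(len(i_idx), "band_stop")]
    )
    resp = np.vstack([band, stop])

    xyz_sum = resp[:, :3].sum(axis=1)
    lm = resp[:, 3] + resp[:, 4]
    ok = (xyz_sum > 0) & (lm > 0)            # drops all-stop and empty far-red bands
    resp, xyz_sum, lm = resp[ok], xyz_sum[ok], lm[ok]
    lum_total = total[3] + total[4]
    df = pd.DataFrame(
        {
            "kind": kind[ok],
            "lambda1_nm": lam[ok],
            "lambda2_nm": lam2[ok],
            "x": resp[:, 0] / xyz_sum,
            "y": resp[:, 1] / xyz_sum,
            "l_mb": resp[:, 3] / lm,
            "s_mb": resp[:, 5] / lm,
            "luminance": lm / lum_total,
        }
    )
    return GamutSurface(illuminant=illuminant, step_nm=step_nm, df=df)


@dataclass
class GamutEnvelope:
    """Per-chromaticity-bin maximum relative luminance of a gamut surface.

    ``space`` selects the chromaticity plane: "mb" bins (l, s), "xy" bins
    (x, y).  Bins are uniform squares of side ``bin_width``; empty bins are
    simply absent.
    """

    space: str
    bin_width: float
    bins: dict[tuple[int, int], float]

    def _key(self, u: float, v: float) -> tuple[int, int]:
        return (int(np.floor(u / self.bin_width)), int(np.floor(v / self.bin_width)))

    #: lookups farther than this many bin widths from any occupied bin error out
    max_bin_distance: float = 200.0

    def __post_init__(self) -> None:
        keys = np.array(sorted(self.bins), dtype=float)
        self._values = np.array([self.bins[tuple(int(c) for c in k)] for k in keys])
        self._tree = cKDTree(keys)

    def max_luminance(self, u: float, v: float) -> float:
        """Envelope value at chromaticity (u, v) by nearest-occupied-bin lookup.

        The optimal-color cloud is a discrete point set, so bins between
        points can be empty; the lookup finds the nearest occupied bin (in
        bin units).  A query farther than ``max_bin_distance`` bins from
        every occupied bin is outside the envelope support.
        """
        key = self._key(u, v)
        if key in self.bins:
            return self.bins[key]
        dist, idx = self._tree.query([key[0], key[1]])
        if dist > self.max_bin_distance:
            raise OutsideSupportError(
                f"chromaticity ({u:.4f}, {v:.4f}) is outside the gamut envelope support"
            )
        return float(self._values[idx])


def gamut_envelope(
    surface: GamutSurface, bin_width: float = 0.005, space: str = "mb"
) -> GamutEnvelope:
    """Bin the optimal-color cloud and keep the per-bin luminance maximum."""
    if surface.df.empty:
        raise ValidationError("empty gamut surface")
    if space == "mb":
        u, v = surface.df["l_mb"].to_numpy(), surface.df["s_mb"].to_numpy()
    elif space == "xy":
        u, v = surface.df["x"].to_numpy(), surface.df["y"].to_numpy()
    else:
        raise ValidationError(f"unknown chromaticity space {space!r}")
    lum = surface.df["luminance"].to_numpy()
    keys_u = np.floor(u / bin_width).astype(int)
    keys_v = np.floor(v / bin_width).astype(int)
    bins: dict[tuple[int, int], float] = {}
    for ku, kv, lu in zip(keys_u, keys_v, lum):
        k = (int(ku), int(kv))
        if lu > bins.get(k, -np.inf):
            bins[k] = float(lu)
    return GamutEnvelope(space=space, bin_width=bin_width, bins=bins)


def inside_gamut(
    u: float, v: float, luminance: float, envelope: GamutEnvelope, tol: float = 1e-9
) -> bool:
    """True iff the point's relative luminance is under the envelope at its bin."""
    return luminance <= envelope.max_luminance(u, v) + tol
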