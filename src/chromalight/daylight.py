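"""Daylight-specific computation.

Covers the full daylight side of the survey: Planckian radiators and the
CCT estimate (nearest point on the Planckian locus in CIE 1960 (u, v)),
synthesis of CIE daylight-model spectra from a target CCT, the quadratic
daylight-locus fit, the low-photometric-signal filter, sun/shadow pairing
of time-stamped records and one-tailed Welch comparisons between the
paired series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .colorimetry import ChromaticityPoint, xy_chromaticity
from .errors import DomainError, FitError, ValidationError
from .spectra import SpectralDistribution, WavelengthGrid
from .standards import daylight_components, tables_for_grid

log = logging.getLogger(__name__)

SITES = ("rooftop", "A_sports_ground", "B_wood_deck", "C_trees", "D_forest", "E_buildings")
CONDITIONS = ("sun_plus_sky", "shadow_sky", "toward_sun_shielded", "toward_sun_open", "toward_zenith")

#: Radiance-based conditions report luminance (cd/m²); irradiance-based report lux.
CONDITION_UNITS = {
    "sun_plus_sky": "cd/m2",
    "shadow_sky": "cd/m2",
    "toward_sun_shielded": "lx",
    "toward_sun_open": "lx",
    "toward_zenith": "lx",
}

# Second radiation constant, m·K (CODATA value used in colorimetric practice).
C2 = 1.4388e-2


@dataclass
class DaylightRecord:
    """A time-stamped, condition-tagged daylight spectrum."""

    timestamp: datetime
    site: str
    condition: str
    spectrum: SpectralDistribution
    photometric_level: float
    level_unit: str
    cloud_cover_pct: float | None = None
    sun_occluded: bool | None = None

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValidationError(f"unknown site {self.site!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        expected = CONDITION_UNITS[self.condition]
        if self.level_unit != expected:
            raise ValidationError(
                f"condition {self.condition} implies level unit {expected}, got {self.level_unit}"
            )
        if self.photometric_level is None or not np.isfinite(self.photometric_level):
            raise ValidationError(f"record at {self.timestamp} has no valid photometric level")
        if self.photometric_level < 0:
            raise ValidationError("photometric level must be >= 0")


@dataclass(frozen=True)
class CCTResult:
    """Correlated color temperature with its distance from the Planckian locus."""

    cct_K: float
    duv_distance: float
    converged: bool


@dataclass(frozen=True)
class LocusFit:
    """Quadratic chromaticity-locus fit y = a·x² + b·x + c."""

    a: float
    b: float
    c: float
    rms_residual: float
    n_points: int


def planckian_spd(T: float, grid: WavelengthGrid) -> SpectralDistribution:
    """Relative blackbody spectrum B(λ, T) ∝ λ⁻⁵ / (exp(c2/λT) − 1), max 1."""
    if T <= 0:
        raise DomainError(f"blackbody temperature must be positive, got {T}")
    lam = grid.wavelengths * 1e-9
    values = lam ** -5.0 / np.expm1(C2 / (lam * T))
    return SpectralDistribution(grid, values / values.max(), "relative", f"planck_{T:g}K")


def uv_1960(x: float, y: float) -> tuple[float, float]:
    """CIE 1960 (u, v) from CIE 1931 (x, y)."""
    denom = -2.0 * x + 12.0 * y + 3.0
    return 4.0 * x / denom, 6.0 * y / denom


def _planck_uv(T: float, grid: WavelengthGrid) -> tuple[float, float]:
    p = xy_chromaticity(planckian_spd(T, grid))
    return uv_1960(p.x, p.y)


@lru_cache(maxsize=8)
def _planck_locus_table(grid: WavelengthGrid) -> tuple[np.ndarray, np.ndarray]:
    Ts = np.logspace(3.0, 6.0, 256)
    uv = np.array([_planck_uv(T, grid) for T in Ts])
    return Ts, uv


def compute_cct(
    point: ChromaticityPoint | tuple[float, float],
    grid: WavelengthGrid | None = None,
    duv_max: float = 0.05,
) -> CCTResult:
    """CCT as the Planckian-locus temperature nearest to *point* in (u, v).

    A coarse log-spaced temperature sweep over 1000 K – 10⁶ K brackets the
    minimum, then a bounded scalar minimisation refines it.  When the (u,v)
    distance to the locus exceeds ``duv_max`` the chromaticity is too far
    off-locus for the CCT to be meaningful and ``converged`` is False (the
    value is still returned).
    """
    if isinstance(point, ChromaticityPoint):
        x, y = point.x, point.y
    else:
        x, y = point
    grid = grid or WavelengthGrid.daylight()
    u0, v0 = uv_1960(x, y)
    Ts, uv = _planck_locus_table(grid)
    d2 = (uv[:, 0] - u0) ** 2 + (uv[:, 1] - v0) ** 2
    i = int(np.argmin(d2))
    lo, hi = np.log10(Ts[max(i - 1, 0)]), np.log10(Ts[min(i + 1, len(Ts) - 1)])

    def objective(logT: float) -> float:
        uu, vv = _planck_uv(10.0 ** logT, grid)
        return (uu - u0) ** 2 + (vv - v0) ** 2

    res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    cct = 10.0 ** float(res.x)
    duv = float(np.sqrt(res.fun))
    return CCTResult(cct_K=cct, duv_distance=duv, converged=duv <= duv_max)


def daylight_locus_y(x: float | np.ndarray) -> float | np.ndarray:
    """CIE daylight-locus relation y_D = −3.000·x_D² + 2.870·x_D − 0.275."""
    return -3.000 * np.square(x) + 2.870 * np.asarray(x) - 0.275


def daylight_locus_curve():
    """Return the CIE daylight-locus function x ↦ y."""
    return daylight_locus_y


def daylight_target_chromaticity(cct_K: float) -> tuple[float, float]:
    """Target (x_D, y_D) of the CIE daylight model for a CCT in [4000, 25000] K."""
    if not 4000.0 <= cct_K <= 25000.0:
        raise DomainError(f"CIE daylight model is defined for 4000-25000 K, got {cct_K}")
    T = cct_K
    if T <= 7000.0:
        x = -4.6070e9 / T**3 + 2.9678e6 / T**2 + 0.09911e3 / T + 0.244063
    else:
        x = -2.0064e9 / T**3 + 1.9018e6 / T**2 + 0.24748e3 / T + 0.237040
    return x, float(daylight_locus_y(x))


def cie_daylight_spd(cct_K: float, grid: WavelengthGrid) -> SpectralDistribution:
    """Synthesize a CIE daylight spectrum S(λ) = S0 + M1·S1 + M2·S2 at *cct_K*.

    The M1/M2 weights are kept at full precision (no historical rounding to
    three decimals), so the synthesized chromaticity tracks the daylight
    locus as closely as the component tables allow.
    """
    x, y = daylight_target_chromaticity(cct_K)
    denom = 0.0241 + 0.2562 * x - 0.7341 * y
    m1 = (-1.3515 - 1.7703 * x + 5.9114 * y) / denom
    m2 = (0.0300 - 31.4424 * x + 30.0717 * y) / denom
    comps = daylight_components(grid)
    values = comps[:, 0] + m1 * comps[:, 1] + m2 * comps[:, 2]
    values = np.clip(values, 0.0, None)  # guard: far ends can round slightly below 0
    return SpectralDistribution(grid, values, "relative", f"cie_daylight_{cct_K:g}K")


class QuadraticLocusRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares of y on (x², x, 1) for chromaticity loci.

    Fitted attributes: ``coef_`` = (a, b, c), ``rms_residual_``,
    ``n_points_``.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValidationError("x and y must have the same length")
        if np.unique(x).size < 3:
            raise FitError("quadratic locus fit needs at least 3 distinct x values")
        design = np.column_stack([x**2, x, np.ones_like(x)])
        if np.linalg.matrix_rank(design) < 3:
            raise FitError("rank-deficient design: x values do not span a quadratic")
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        self.coef_ = coef
        self.rms_residual_ = float(np.sqrt(np.mean(resid**2)))
        self.n_points_ = int(x.size)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        a, b, c = self.coef_
        return a * x**2 + b * x + c


def fit_quadratic_locus(points) -> LocusFit:
    """Fit y = a·x² + b·x + c to chromaticity points (or (x, y) pairs)."""
    if len(points) and isinstance(points[0], ChromaticityPoint):
        x = np.array([p.x for p in points])
        y = np.array([p.y for p in points])
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    reg = QuadraticLocusRegressor().fit(x, y)
    a, b, c = reg.coef_
    return LocusFit(float(a), float(b), float(c), reg.rms_residual_, reg.n_points_)


def filter_low_signal(
    records: list[DaylightRecord],
    lum_min: float = 10.0,
    illum_min: float = 10.0,
) -> tuple[list[DaylightRecord], list[DaylightRecord]]:
    """Drop records whose level is strictly below the threshold for their unit.

    A record at exactly the threshold is kept ("less than" read strictly).
    """
    kept, removed = [], []
    for rec in records:
        threshold = lum_min if rec.level_unit == "cd/m2" else illum_min
        (removed if rec.photometric_level < threshold else kept).append(rec)
    return kept, removed


def pair_sun_shadow(
    records: list[DaylightRecord], max_gap_minutes: float = 15.0
) -> list[tuple[DaylightRecord, DaylightRecord]]:
    """Greedy nearest-timestamp matching of total-daylight and skylight records.

    Candidate (total, shadow) pairs within the time tolerance are taken in
    order of increasing gap; each record is used at most once.
    """
    total = [r for r in records if r.condition == "sun_plus_sky"]
    sky = [r for r in records if r.condition == "shadow_sky"]
    candidates = []
    for i, rt in enumerate(total):
        for j, rs in enumerate(sky):
            gap = abs((rt.timestamp - rs.timestamp).total_seconds()) / 60.0
            if gap <= max_gap_minutes:
                candidates.append((gap, i, j))
    candidates.sort()
    used_t: set[int] = set()
    used_s: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i not in used_t and j not in used_s:
            used_t.add(i)
            used_s.add(j)
            pairs.append((total[i], sky[j]))
    pairs.sort(key=lambda p: p[0].timestamp)
    return pairs


def welch_t_one_tailed(sample_a, sample_b, direction: str = "greater"):
    """Welch two-sample t statistic with one-tailed p (no equal-variance assumption).

    ``direction="greater"`` tests mean(a) > mean(b); ``"less"`` the reverse.
    Returns (t, df, p) with the Welch–Satterthwaite degrees of freedom.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs n >= 2")
    if direction not in ("greater", "less"):
        raise ValidationError("direction must be 'greater' or 'less'")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            raise ValidationError("both samples constant and equal: p undefined")
        t = np.inf if a.mean() > b.mean() else -np.inf
        df = float(a.size + b.size - 2)
    else:
        se2 = va / a.size + vb / b.size
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / (
            (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
        )
    p = float(stats.t.sf(t, df)) if direction == "greater" else float(stats.t.cdf(t, df))
    return float(t), float(df), p


def diurnal_summary(records: list[DaylightRecord]) -> pd.DataFrame:
    """Per-record CCT and log10 photometric level, preserving record order.

    Records with a zero photometric level cannot appear on a log axis and
    are excluded (logged).  Columns: timestamp, condition, cct_K,
    duv_distance, converged, log10_level, level_unit.
    """
    rows = []
    for rec in records:
        if rec.photometric_level <= 0:
            log.warning("excluding %s record at %s: zero photometric level",
                        rec.condition, rec.timestamp)
            continue
        point = xy_chromaticity(rec.spectrum)
        cct = compute_cct(point, rec.spectrum.grid)
        rows.append(
            {
                "timestamp": rec.timestamp,
                "condition": rec.condition,
                "site": rec.site,
                "cct_K": cct.cct_K,
                "duv_distance": cct.duv_distance,
                "converged": cct.converged,
                "log10_level": np.log10(rec.photometric_level),
                "level_unit": rec.level_unit,
            }
        )
    return pd.DataFrame(rows)
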