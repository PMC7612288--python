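"""Synthetic study generator.

Produces inputs with the statistical structure the survey reports — a
natural-object reflectance bank by category (flowers chromatically widest,
no bright saturated greens), two-peaked leaf transmittances, sunny and
cloudy diurnal daylight series with a total-daylight and a skylight
channel, and five site regimes including canopy-filtered forest light — so
the whole pipeline can run without the measured dataset.  These recipes
are explicitly NOT measured data: they encode only the shapes and moments
the survey describes, and are meant for pattern-recovery testing.

Every generator draws from its own independently seeded stream, so adding
a generator never perturbs the output of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np

from .colorimetry import cone_excitations, xy_chromaticity
from .daylight import DaylightRecord, cie_daylight_spd
from .errors import ValidationError
from .spectra import SpectralDistribution, WavelengthGrid, resample
from .standards import KM_LUMENS_PER_WATT, equal_energy_white, tables_for_grid
from .surfaces import CATEGORY_COUNTS, SurfaceSample


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults mirror the survey design."""

    seed: int = 0
    n_per_category: dict = field(default_factory=lambda: dict(CATEGORY_COUNTS))
    n_near_duplicates: int = 52
    n_transmittance_leaves: int = 75
    #: relative sd of the multiplicative (log-normal) photometric level noise
    noise_sd_rel: float = 0.05
    #: (date, weather, day_length_hours) of the four time-lapse days
    diurnal_days: tuple = (
        (date(2013, 11, 20), "sunny", 10.2),
        (date(2013, 12, 24), "sunny", 9.7),
        (date(2014, 7, 3), "cloudy", 14.4),
        (date(2014, 10, 27), "cloudy", 10.8),
    )
    site_date: date = date(2014, 7, 8)
    #: session start times (hours) of the five-site circuit
    session_hours: tuple = (8.93, 10.40, 13.70, 15.00, 17.12)
    #: open-site vs forest illuminance contrast
    forest_contrast: float = 51.0
    #: exponent applied to the canopy leaf transmittance (density of foliage)
    canopy_power: float = 1.2
    #: fraction of unfiltered daylight reaching the forest floor through gaps
    canopy_gap_fraction: float = 0.10
    #: shadow measurement lags the paired sun measurement by this many minutes
    shadow_offset_min: float = 1.0
    #: distinct samples are kept below this pairwise correlation ...
    distinct_r_max: float = 0.9985
    #: ... while constructed near-duplicates exceed this one
    duplicate_r_min: float = 0.999

    def rng(self, label: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, zlib.crc32(label.encode())])


def _gauss(w: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((w - mu) / sd) ** 2)


def _sigmoid(w: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(w - center) / width))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


# --------------------------------------------------------------------------
# reflectance bank
# --------------------------------------------------------------------------

def _draw_reflectance(category: str, w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if category == "flower":
        if rng.random() < 0.12:  # whitish flowers: high and flat-ish
            r = rng.uniform(0.5, 0.85) + rng.uniform(-0.05, 0.05) * (w - 580) / 200
            r = r + rng.uniform(0.0, 0.08) * _gauss(w, rng.uniform(420, 680), rng.uniform(50, 120))
        else:
            r = rng.uniform(0.03, 0.12) * np.ones_like(w)
            for _ in range(rng.integers(1, 3)):
                r = r + rng.uniform(0.15, 0.8) * _gauss(
                    w, rng.uniform(400, 700), rng.uniform(25, 75)
                )
            if rng.random() < 0.55:  # red/orange edge
                r = r + rng.uniform(0.1, 0.7) * _sigmoid(
                    w, rng.uniform(575, 670), rng.uniform(12, 35)
                )
    elif category == "leaf":
        r = (
            rng.uniform(0.02, 0.06)
            + rng.uniform(0.07, 0.20) * _gauss(w, rng.uniform(540, 565), rng.uniform(22, 38))
            + rng.uniform(0.25, 0.55) * _sigmoid(w, rng.uniform(688, 712), rng.uniform(8, 16))
        )
    elif category == "fruit":
        r = rng.uniform(0.03, 0.10) + rng.uniform(0.3, 0.85) * _sigmoid(
            w, rng.uniform(555, 640), rng.uniform(10, 30)
        )
        if rng.random() < 0.4:
            r = r + rng.uniform(0.05, 0.2) * _gauss(w, rng.uniform(500, 600), rng.uniform(30, 60))
    elif category == "vegetable":
        return _draw_reflectance("leaf" if rng.random() < 0.5 else "fruit", w, rng)
    elif category == "bark":
        ramp = (w - w[0]) / (w[-1] - w[0])
        r = (
            rng.uniform(0.04, 0.12)
            + rng.uniform(0.08, 0.30) * ramp ** rng.uniform(0.5, 2.5)
            + rng.uniform(0.0, 0.12) * _gauss(w, rng.uniform(480, 700), rng.uniform(40, 90))
        )
    elif category == "stone":
        ramp = (w - w[0]) / (w[-1] - w[0])
        r = rng.uniform(0.08, 0.50) + rng.uniform(-0.08, 0.12) * ramp
        for _ in range(2):
            r = r + rng.uniform(-0.04, 0.05) * _gauss(
                w, rng.uniform(420, 720), rng.uniform(40, 110)
            )
    else:  # pragma: no cover
        raise ValidationError(f"unknown category {category!r}")
    return np.clip(r, 0.0, 1.0)


def _largest_remainder(counts: dict[str, int], total: int) -> dict[str, int]:
    """Apportion *total* across categories proportionally to their counts."""
    grand = sum(counts.values())
    quotas = {k: total * v / grand for k, v in counts.items()}
    out = {k: int(np.floor(q)) for k, q in quotas.items()}
    rest = sorted(counts, key=lambda k: quotas[k] - out[k], reverse=True)
    for k in rest[: total - sum(out.values())]:
        out[k] += 1
    return out


def gen_reflectance_bank(cfg: SyntheticConfig) -> list[SurfaceSample]:
    """Synthetic natural-object bank: distinct shapes plus constructed near-copies.

    Per-category recipes give flowers the widest chromatic spread, leaves a
    green bump plus a strong rise beyond 680 nm and stones near-flat
    spectra.  Two rejection rules shape the bank: a candidate too similar
    to an accepted sample (Pearson r above ``distinct_r_max``) is redrawn,
    and so is any candidate that would place a bright saturated green in
    the chromaticity cloud (the survey's reported gap).  The configured
    number of near-duplicates (r > ``duplicate_r_min`` by construction) is
    appended at the end, so a greedy dedup sweep keeps exactly the
    distinct shapes.
    """
    grid = WavelengthGrid.surface()
    w = grid.wavelengths
    tables = tables_for_grid(grid)
    white_lm = float(np.sum(tables.cones[:, 0] + tables.cones[:, 1])) * grid.step_nm

    dup_counts = _largest_remainder(cfg.n_per_category, cfg.n_near_duplicates)
    rng = cfg.rng("reflectance_bank")

    accepted: list[np.ndarray] = []
    centered: list[np.ndarray] = []
    norms: list[float] = []
    samples: list[SurfaceSample] = []

    def too_similar(r: np.ndarray) -> bool:
        if not accepted:
            return False
        c = r - r.mean()
        n = np.linalg.norm(c)
        if n == 0:
            return False
        rr = np.asarray(centered) @ c / (np.asarray(norms) * n)
        return bool(np.max(rr) > cfg.distinct_r_max)

    def bright_green(r: np.ndarray) -> bool:
        L, M, S = (r @ tables.cones) * grid.step_nm
        lum = (L + M) / white_lm
        l_mb = L / (L + M)
        return l_mb < 0.63 and lum > 0.65

    for category, n_total in cfg.n_per_category.items():
        n_distinct = n_total - dup_counts[category]
        for i in range(n_distinct):
            for _ in range(500):
                r = _draw_reflectance(category, w, rng)
                if not too_similar(r) and not bright_green(r):
                    break
            else:  # pragma: no cover - recipe is far from this limit
                raise ValidationError(f"could not draw a distinct {category} sample")
            accepted.append(r)
            centered.append(r - r.mean())
            norms.append(float(np.linalg.norm(centered[-1])))
            samples.append(
                SurfaceSample(
                    sample_id=f"{category}_{i + 1:03d}",
                    category=category,
                    reflectance=SpectralDistribution(grid, r, "reflectance"),
                )
            )

    # near-duplicates go at the end of the bank: the greedy sweep keeps sources
    duplicates: list[SurfaceSample] = []
    by_cat: dict[str, list[SurfaceSample]] = {}
    for s in samples:
        by_cat.setdefault(s.category, []).append(s)
    for category, n_dup in dup_counts.items():
        pool = by_cat.get(category, [])
        for k in range(n_dup):
            src = pool[int(rng.integers(0, len(pool)))]
            for _ in range(100):
                r = np.clip(src.reflectance.values + rng.normal(0.0, 5e-5, w.size), 0.0, 1.0)
                if _pearson(r, src.reflectance.values) > cfg.duplicate_r_min:
                    break
            duplicates.append(
                SurfaceSample(
                    sample_id=f"{src.sample_id}_dup{k + 1}",
                    category=category,
                    reflectance=SpectralDistribution(grid, r, "reflectance"),
                )
            )
    samples.extend(duplicates)

    # attach transmittance pairs to the first distinct leaves
    leaf_pool = by_cat.get("leaf", [])
    n_t = min(cfg.n_transmittance_leaves, len(leaf_pool))
    if n_t:
        for leaf, (front, back) in zip(leaf_pool, gen_leaf_transmittance(cfg, n=n_t)):
            leaf.transmittance_front_up = front
            leaf.transmittance_back_up = back
    return samples


def gen_leaf_transmittance(
    cfg: SyntheticConfig, n: int | None = None
) -> list[tuple[SpectralDistribution, SpectralDistribution]]:
    """Two-peaked leaf transmittances (front-up, back-up), max level <= 0.4.

    Each spectrum has a local maximum near 550 nm (chlorophyll green
    window) and a rising lobe beyond ~700 nm that plateaus at 780 nm.
    Front and back variants differ by a smooth multiplicative factor.
    """
    grid = WavelengthGrid.surface()
    w = grid.wavelengths
    rng = cfg.rng("leaf_transmittance")
    out = []
    for i in range(n or cfg.n_transmittance_leaves):
        t = (
            rng.uniform(0.015, 0.035)
            + rng.uniform(0.07, 0.16) * _gauss(w, rng.uniform(542, 562), rng.uniform(24, 34))
            + rng.uniform(0.20, 0.32) * _sigmoid(w, rng.uniform(712, 728), rng.uniform(14, 20))
            + rng.uniform(0.05, 0.08) * np.clip((w - 740.0) / 40.0, 0.0, 1.0) ** 2
        )
        if t.max() > 0.4:
            t *= 0.4 / t.max()
        factor = rng.uniform(0.75, 0.95) + rng.uniform(-0.08, 0.08) * _sigmoid(w, 620, 60)
        back = np.clip(t * factor, 0.0, 0.4)
        out.append(
            (
                SpectralDistribution(grid, t, "transmittance", f"leaf_T_{i + 1:03d}_front"),
                SpectralDistribution(grid, back, "transmittance", f"leaf_T_{i + 1:03d}_back"),
            )
        )
    return out


# --------------------------------------------------------------------------
# daylight
# --------------------------------------------------------------------------

def _unit_luminance_daylight(cct: float, grid: WavelengthGrid) -> np.ndarray:
    """CIE daylight-model spectrum rescaled to unit luminance signal."""
    spd = cie_daylight_spd(cct, grid)
    exc = cone_excitations(spd)
    return spd.values / (exc.L + exc.M)


def _sample_hours(sunrise: float, sunset: float) -> np.ndarray:
    """Dense sampling near sunrise and sunset, roughly hourly in between."""
    edge = np.array([0.05, 0.15, 0.25, 0.4, 0.6, 0.85])
    hours = np.concatenate(
        [
            sunrise + edge,
            np.arange(np.ceil(sunrise + 1.2), np.floor(sunset - 1.2) + 0.5, 1.0),
            sunset - edge[::-1],
        ]
    )
    return np.unique(hours)


def gen_diurnal_daylight(
    cfg: SyntheticConfig,
    day: date | None = None,
    weather: str = "sunny",
    day_length_hours: float = 10.2,
) -> list[DaylightRecord]:
    """One day of paired rooftop total-daylight and skylight radiance records.

    Total daylight is a luminance-weighted mixture of a low-CCT direct-sun
    daylight spectrum and a high-CCT sky spectrum; the skylight (shadow)
    record is the sky term alone, so its level is below the paired total by
    construction.  On sunny days the sun weight grows with solar elevation,
    making the total-daylight CCT trace a U across the day while the sky
    CCT traces an inverted U; the cloudy regime drives both conditions with
    one overcast profile capped below 10000 K.  A small clock-linear CCT
    drift keeps the extremum unique under symmetric elevation sampling.
    Photometric levels carry multiplicative log-normal noise
    (``noise_sd_rel``); spectral shape is noise-free, as chromaticity noise
    in the measured series is dominated by level, not shape, variation.
    """
    day = day or cfg.diurnal_days[0][0]
    grid = WavelengthGrid.daylight()
    rng = cfg.rng(f"diurnal_{day.isoformat()}_{weather}")
    sunrise = 12.0 - day_length_hours / 2.0
    sunset = 12.0 + day_length_hours / 2.0
    records: list[DaylightRecord] = []
    for t in _sample_hours(sunrise, sunset):
        elev = float(np.sin(np.pi * (t - sunrise) / day_length_hours))
        drift = 25.0 * (t - sunrise)  # K per hour, breaks noon symmetry
        if weather == "sunny":
            w_sun = 0.2 + 0.75 * elev
            cct_sky = 8500.0 + 3000.0 * elev + drift
            sun = _unit_luminance_daylight(5500.0 + drift, grid)
            sky = _unit_luminance_daylight(cct_sky, grid)
            total_shape = w_sun * sun + (1.0 - w_sun) * sky
            shadow_shape = (1.0 - w_sun) * sky
        elif weather == "cloudy":
            cct_c = 9300.0 - 3200.0 * elev + drift
            total_shape = 0.55 * _unit_luminance_daylight(cct_c, grid)
            shadow_shape = 0.5 * 0.55 * _unit_luminance_daylight(min(cct_c + 150.0, 9800.0), grid)
        else:
            raise ValidationError(f"unknown weather {weather!r}")
        amplitude = 9000.0 * elev**1.6 + 0.8  # cd/m² scale with a dawn haze floor
        for condition, shape, offset in (
            ("sun_plus_sky", total_shape, 0.0),
            ("shadow_sky", shadow_shape, cfg.shadow_offset_min),
        ):
            noise = float(np.exp(rng.normal(0.0, cfg.noise_sd_rel)))
            # shapes are unit-(L+M); divide by the luminous efficacy so the
            # stored radiance yields `amplitude` cd/m² (before level noise)
            values = shape * amplitude * noise / KM_LUMENS_PER_WATT
            spd = SpectralDistribution(grid, values, "radiance")
            exc = cone_excitations(spd)
            stamp = datetime(day.year, day.month, day.day) + timedelta(hours=t, minutes=offset)
            records.append(
                DaylightRecord(
                    timestamp=stamp,
                    site="rooftop",
                    condition=condition,
                    spectrum=spd,
                    photometric_level=exc.luminance,
                    level_unit="cd/m2",
                    cloud_cover_pct=5.0 if weather == "sunny" else 90.0,
                    sun_occluded=weather == "cloudy",
                )
            )
    return records


def _forest_shape(
    cct: float, grid: WavelengthGrid, canopy: np.ndarray, gap_fraction: float
) -> np.ndarray:
    """Forest-floor daylight: canopy-transmitted light plus unfiltered gap light."""
    base = _unit_luminance_daylight(cct, grid)
    return (1.0 - gap_fraction) * base * canopy + gap_fraction * base


_SITE_FACTORS = {"A_sports_ground": 1.0, "B_wood_deck": 0.85, "C_trees": 0.68, "E_buildings": 0.5}
_SITE_CCT_OFFSET = {"A_sports_ground": 0.0, "B_wood_deck": 90.0, "C_trees": 160.0, "E_buildings": 260.0}


def gen_site_spectra(cfg: SyntheticConfig) -> list[DaylightRecord]:
    """Five-site irradiance circuit: open sites plus canopy-filtered forest.

    Open sites share a session daylight spectrum with per-site intensity
    factors; the forest site sees the same daylight filtered through a leaf
    transmittance raised to ``canopy_power``, scaled so the open/forest
    illuminance contrast equals ``forest_contrast``.  Each site is visited
    ~10 min after the previous one, and measured both toward the (shielded)
    sun and toward the zenith.
    """
    grid = WavelengthGrid.daylight()
    rng = cfg.rng("site_spectra")
    # the canopy acts as an ensemble of leaves: average many transmittances,
    # which damps the per-leaf green bump relative to the NIR plateau
    leaf_mean = np.mean(
        [f.values for f, _ in gen_leaf_transmittance(cfg, n=12)], axis=0
    )
    canopy = (
        resample(SpectralDistribution(WavelengthGrid.surface(), leaf_mean, "transmittance"), grid)
        .values ** cfg.canopy_power
    )
    base_cct = (5650.0, 5750.0, 5900.0, 5800.0, 5200.0)
    base_lx = (52000.0, 65000.0, 72000.0, 58000.0, 21000.0)
    records: list[DaylightRecord] = []
    d = cfg.site_date
    for s, (hour, cct_s, lx_a) in enumerate(zip(cfg.session_hours, base_cct, base_lx)):
        late = s == len(cfg.session_hours) - 1  # low sun: obstacles shade sites B-E
        for k, site in enumerate(("A_sports_ground", "B_wood_deck", "C_trees", "D_forest", "E_buildings")):
            stamp = datetime(d.year, d.month, d.day) + timedelta(hours=hour, minutes=10.0 * k)
            if site == "D_forest":
                shape = _forest_shape(cct_s, grid, canopy, cfg.canopy_gap_fraction)
                target_lx = lx_a / cfg.forest_contrast
            else:
                shape = _unit_luminance_daylight(cct_s + _SITE_CCT_OFFSET[site], grid)
                factor = _SITE_FACTORS[site] * (0.12 if late and site != "A_sports_ground" else 1.0)
                target_lx = lx_a * factor
            for condition, cct_shift, lvl_factor in (
                ("toward_sun_shielded", 0.0, 1.0),
                ("toward_zenith", 1300.0, 0.28),
            ):
                if site == "D_forest":
                    sh = _forest_shape(cct_s + cct_shift, grid, canopy, cfg.canopy_gap_fraction)
                else:
                    sh = _unit_luminance_daylight(
                        cct_s + _SITE_CCT_OFFSET[site] + cct_shift, grid
                    )
                noise = float(np.exp(rng.normal(0.0, cfg.noise_sd_rel)))
                lx = target_lx * lvl_factor * noise
                spd = SpectralDistribution(grid, sh, "irradiance")
                exc = cone_excitations(spd)
                spd = spd.with_values(sh * lx / exc.luminance)
                records.append(
                    DaylightRecord(
                        timestamp=stamp + timedelta(minutes=2.0 * (condition != "toward_sun_shielded")),
                        site=site,
                        condition=condition,
                        spectrum=spd,
                        photometric_level=lx,
                        level_unit="lx",
                        cloud_cover_pct=30.0,
                    )
                )
    return records


@dataclass
class SyntheticStudy:
    """The complete synthetic survey bundle."""

    bank: list[SurfaceSample]
    diurnal: dict[str, list[DaylightRecord]]
    sites: list[DaylightRecord]

    @property
    def daylight_records(self) -> list[DaylightRecord]:
        out: list[DaylightRecord] = []
        for recs in self.diurnal.values():
            out.extend(recs)
        out.extend(self.sites)
        return out


def gen_study(cfg: SyntheticConfig | None = None) -> SyntheticStudy:
    """Generate the full default study: bank + four diurnal days + site circuit."""
    cfg = cfg or SyntheticConfig()
    diurnal = {
        d.isoformat(): gen_diurnal_daylight(cfg, d, weather, hours)
        for d, weather, hours in cfg.diurnal_days
    }
    return SyntheticStudy(
        bank=gen_reflectance_bank(cfg),
        diurnal=diurnal,
        sites=gen_site_spectra(cfg),
    )
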