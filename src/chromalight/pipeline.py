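"""End-to-end orchestration: simulate → surfaces → gamut → daylight → locus → pca.

``run_pipeline`` executes the whole analysis on either a synthetic study
(generated from the config seed) or on-disk CSV bundles, and produces a
JSON-first report plus CSV side tables (figures, when requested, are
derived artifacts of those tables and never the source of any number).
All results are computed before anything is written, so a failing stage
leaves no partial output behind.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .colorimetry import cone_excitations, xy_chromaticity
from .daylight import (
    compute_cct,
    daylight_locus_y,
    diurnal_summary,
    filter_low_signal,
    fit_quadratic_locus,
    pair_sun_shadow,
    welch_t_one_tailed,
)
from .errors import PipelineError
from .gamut import enumerate_optimal_colors, gamut_envelope, inside_gamut
from .pca import compare_to_basis, normalize_component, pca_spectra
from .spectra import SpectralDistribution
from .standards import daylight_components, equal_energy_white
from .surfaces import dedup_by_correlation
from .synthetic import SyntheticConfig, gen_study

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and options of the full analysis; defaults are the survey's."""

    seed: int = 0
    records_dir: str | None = None  # None -> simulate with the seed
    outdir: str = "chromalight_report"
    r_threshold: float = 0.999
    lum_min_cdm2: float = 10.0
    illum_min_lx: float = 10.0
    pair_gap_min: float = 15.0
    gamut_step_nm: float = 5.0
    envelope_bin: float = 0.005
    n_components: int = 3
    write_figures: bool = False


def _u_shape(series: np.ndarray) -> str:
    """Classify a diurnal series as 'U', 'inverted-U', 'monotone' or 'other'."""
    s = np.sign(np.diff(series))
    s = s[s != 0]
    if len(s) == 0:
        return "flat"
    changes = np.nonzero(np.diff(s) != 0)[0]
    if len(changes) == 0:
        return "monotone"
    if len(changes) == 1:
        return "U" if s[0] < 0 else "inverted-U"
    return "other"


def _record_cct(rec) -> float:
    return compute_cct(xy_chromaticity(rec.spectrum), rec.spectrum.grid).cct_K


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write ``report.json`` (+ CSV tables) to ``outdir``."""
    # the report records the analysis parameters, not where it was written
    report: dict = {"config": {k: v for k, v in asdict(config).items()
                               if k not in ("outdir", "write_figures")}}
    tables: dict[str, pd.DataFrame] = {}
    stage = "inputs"
    try:
        if config.records_dir is None:
            study = gen_study(SyntheticConfig(seed=config.seed))
            bank, daylight = study.bank, study.daylight_records
        else:
            d = Path(config.records_dir)
            bank = cio.read_surface_bank(d / "surfaces")
            daylight = cio.read_daylight_records(d / "daylight")

        stage = "dedup"
        dedup = dedup_by_correlation(bank, config.r_threshold)
        keep = set(dedup.kept_ids)
        kept_bank = [s for s in bank if s.sample_id in keep]
        report["dedup"] = {
            "n_input": len(bank),
            "n_kept": len(dedup.kept_ids),
            "n_removed": len(dedup.removed_ids),
            "removed_ids": dedup.removed_ids,
        }

        stage = "surface_chromaticities"
        rows = []
        for s in kept_bank:
            signals = [("reflectance", s.reflectance)]
            if s.transmittance_front_up is not None:
                signals.append(("transmittance", s.transmittance_front_up))
            for what, spd in signals:
                # under an equal-energy white of unit intensity the surface
                # function itself is the color signal
                p = xy_chromaticity(spd.with_values(spd.values, "relative"))
                rows.append(
                    {
                        "sample_id": s.sample_id, "category": s.category, "signal": what,
                        "x": p.x, "y": p.y, "l_mb": p.l_mb, "s_mb": p.s_mb,
                        "luminance": p.photometric_level,
                    }
                )
        chroma = pd.DataFrame(rows)
        tables["surface_chromaticities"] = chroma
        report["surfaces"] = {
            "n_points": len(chroma),
            "l_mb_range": [float(chroma.l_mb.min()), float(chroma.l_mb.max())],
            "s_mb_range": [float(chroma.s_mb.min()), float(chroma.s_mb.max())],
        }

        stage = "gamut"
        grid = kept_bank[0].reflectance.grid
        eew = equal_energy_white(grid)
        white_lum = cone_excitations(eew).luminance
        surface = enumerate_optimal_colors(eew, step_nm=config.gamut_step_nm)
        env = gamut_envelope(surface, bin_width=config.envelope_bin, space="mb")
        inside = [
            inside_gamut(r.l_mb, r.s_mb, r.luminance / white_lum, env)
            for r in chroma.itertuples(index=False)
        ]
        tables["optimal_colors"] = surface.df
        report["gamut"] = {
            "n_optimal_colors": len(surface.df),
            "peak_luminance": float(surface.df.luminance.max()),
            "fraction_samples_inside": float(np.mean(inside)),
        }

        stage = "daylight_filter"
        kept_daylight, removed_daylight = filter_low_signal(
            daylight, config.lum_min_cdm2, config.illum_min_lx
        )
        report["daylight_filter"] = {
            "n_input": len(daylight),
            "n_kept": len(kept_daylight),
            "n_removed": len(removed_daylight),
        }

        stage = "diurnal"
        rooftop = [r for r in kept_daylight if r.site == "rooftop"]
        frames, per_day, all_pairs = [], [], []
        for day in sorted({r.timestamp.date() for r in rooftop}):
            day_recs = sorted(
                (r for r in rooftop if r.timestamp.date() == day), key=lambda r: r.timestamp
            )
            summary = diurnal_summary(day_recs)
            summary["date"] = day.isoformat()
            frames.append(summary)
            pairs = pair_sun_shadow(day_recs, config.pair_gap_min)
            all_pairs.extend(pairs)
            per_day.append(
                {
                    "date": day.isoformat(),
                    "n_records": len(day_recs),
                    "cct_shape_total": _u_shape(
                        summary[summary.condition == "sun_plus_sky"].cct_K.to_numpy()
                    ),
                    "cct_shape_shadow": _u_shape(
                        summary[summary.condition == "shadow_sky"].cct_K.to_numpy()
                    ),
                    "max_cct_K": float(summary.cct_K.max()),
                    "n_pairs": len(pairs),
                }
            )
        tables["diurnal_summary"] = pd.concat(frames, ignore_index=True)
        report["diurnal"] = per_day

        stage = "pair_tests"
        cct_total = [_record_cct(t) for t, _ in all_pairs]
        cct_sky = [_record_cct(s) for _, s in all_pairs]
        lvl_total = [np.log10(t.photometric_level) for t, _ in all_pairs]
        lvl_sky = [np.log10(s.photometric_level) for _, s in all_pairs]
        t_c, df_c, p_c = welch_t_one_tailed(cct_sky, cct_total, "greater")
        t_l, df_l, p_l = welch_t_one_tailed(lvl_sky, lvl_total, "less")
        report["pair_tests"] = {
            "n_pairs": len(all_pairs),
            "sky_cct_always_higher": bool(np.all(np.array(cct_sky) > np.array(cct_total))),
            "sky_level_always_lower": bool(np.all(np.array(lvl_sky) < np.array(lvl_total))),
            "welch_cct": {"t": t_c, "df": df_c, "p_one_tailed": p_c},
            "welch_log10_level": {"t": t_l, "df": df_l, "p_one_tailed": p_l},
        }

        stage = "locus_fit"
        pts = [xy_chromaticity(r.spectrum) for r in kept_daylight]
        fit = fit_quadratic_locus(pts)
        tables["daylight_chromaticities"] = pd.DataFrame(
            {
                "x": [p.x for p in pts],
                "y": [p.y for p in pts],
                "site": [r.site for r in kept_daylight],
                "condition": [r.condition for r in kept_daylight],
            }
        )
        forest_dev = [
            p.y - float(daylight_locus_y(p.x))
            for p, r in zip(pts, kept_daylight)
            if r.site == "D_forest"
        ]
        report["locus_fit"] = {
            "a": fit.a, "b": fit.b, "c": fit.c,
            "rms_residual": fit.rms_residual, "n_points": fit.n_points,
            "forest_min_y_deviation": float(min(forest_dev)) if forest_dev else None,
        }

        stage = "pca"
        pca_report = {}
        components_table = None
        for label, unit in (("radiance", "cd/m2"), ("irradiance", "lx")):
            ensemble = [r.spectrum for r in kept_daylight if r.level_unit == unit]
            res = pca_spectra(ensemble, n_components=config.n_components, centered=False)
            grid_e = ensemble[0].grid
            s0 = SpectralDistribution(grid_e, daylight_components(grid_e)[:, 0], "relative")
            comparison = compare_to_basis(
                normalize_component(res.components[0]), normalize_component(s0)
            )
            pca_report[label] = {
                "n_spectra": len(ensemble),
                "variance_explained": [float(v) for v in res.variance_explained],
                "first_component_vs_daylight_model": comparison,
            }
            cols = {f"{label}_pc{i + 1}": c.values for i, c in enumerate(res.components)}
            df = pd.DataFrame({"wavelength_nm": grid_e.wavelengths.astype(int), **cols})
            components_table = (
                df if components_table is None
                else components_table.merge(df, on="wavelength_nm", how="outer")
            )
        report["pca"] = pca_report
        tables["pca_components"] = components_table
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - tag the failing stage for the caller
        raise PipelineError(f"stage '{stage}' failed: {e}") from e

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    if config.write_figures:
        _write_figures(outdir, tables, report)
    return report


def _write_figures(outdir: Path, tables: dict[str, pd.DataFrame], report: dict) -> None:
    """Diagnostic figures; every plotted number comes from the CSV tables."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sc = tables["surface_chromaticities"]
    fig, ax = plt.subplots(figsize=(5, 4))
    for signal, marker in (("reflectance", "o"), ("transmittance", "^")):
        sub = sc[sc.signal == signal]
        ax.scatter(sub.l_mb, sub.s_mb, s=6, marker=marker, label=signal, alpha=0.6)
    ax.set_xlabel("L/(L+M)")
    ax.set_ylabel("S/(L+M)")
    ax.legend()
    fig.savefig(outdir / "surface_chromaticities.png", dpi=120)
    plt.close(fig)

    ds = tables["diurnal_summary"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, cond in zip(axes, ("sun_plus_sky", "shadow_sky")):
        for day, sub in ds[ds.condition == cond].groupby("date"):
            hours = pd.to_datetime(sub.timestamp)
            ax.plot(hours.dt.hour + hours.dt.minute / 60, sub.cct_K, ".-", label=day)
        ax.set_title(cond)
        ax.set_xlabel("hour")
    axes[0].set_ylabel("CCT (K)")
    axes[0].legend(fontsize=6)
    fig.savefig(outdir / "diurnal_cct.png", dpi=120)
    plt.close(fig)

    dc = tables["daylight_chromaticities"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(dc.x, dc.y, s=8, c=(dc.site == "D_forest").map({True: "g", False: "k"}), alpha=0.6)
    xs = np.linspace(dc.x.min(), dc.x.max(), 100)
    ax.plot(xs, daylight_locus_y(xs), "b-", lw=1, label="CIE daylight locus")
    lf = report["locus_fit"]
    ax.plot(xs, lf["a"] * xs**2 + lf["b"] * xs + lf["c"], "c--", lw=1, label="fitted locus")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.legend()
    fig.savefig(outdir / "daylight_locus.png", dpi=120)
    plt.close(fig)
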