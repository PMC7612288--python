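"""Readers and writers for the spectral and metadata CSV dialects.

Spectral CSV: first column ``wavelength_nm`` (integer nm, ascending,
uniform step), then one column per sample with a unique sample-ID header.
Empty cells mean *explicitly missing* (awaiting gap filling) and become
NaN.  Metadata sidecars are plain CSVs keyed by ``sample_id``.
"""

from __future__ import annotations


from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .daylight import CONDITION_UNITS, DaylightRecord
from .errors import ParseError
from .spectra import SpectralDistribution, WavelengthGrid
from .surfaces import SurfaceSample


def write_spectra(path, spectra: dict[str, SpectralDistribution]) -> None:
    """Write a dict of same-grid spectra to one spectral CSV."""
    ids = list(spectra)
    if not ids:
        raise ParseError("nothing to write")
    grid = spectra[ids[0]].grid
    data = {"wavelength_nm": grid.wavelengths.astype(int)}
    for sid in ids:
        spd = spectra[sid]
        if spd.grid != grid:
            raise ParseError(f"{sid}: not on the common grid {grid}")
        data[sid] = spd.values
    # %.17g round-trips IEEE doubles exactly and deterministically
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_spectra(path, kind: str = "relative") -> dict[str, SpectralDistribution]:
    """Read a spectral CSV, validating the dialect; returns id -> spectrum."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if not header or header[0] != "wavelength_nm":
        raise ParseError(f"{path}: first column must be 'wavelength_nm', got {header[:1]}")
    ids = header[1:]
    if len(set(ids)) != len(ids):  # pandas would silently mangle these to a.1, a.2 ...
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"{path}: duplicate sample IDs {dupes}")
    df = pd.read_csv(path, float_precision="round_trip")
    w = df["wavelength_nm"].to_numpy()
    if len(w) < 2:
        raise ParseError(f"{path}: needs at least two wavelength rows")
    steps = np.diff(w)
    if (steps <= 0).any():
        row = int(np.argmax(steps <= 0)) + 3  # 1-based + header + offset into diff
        raise ParseError(f"{path}: wavelengths not strictly ascending at line {row}")
    if not np.allclose(steps, steps[0]):
        row = int(np.argmax(~np.isclose(steps, steps[0]))) + 3
        raise ParseError(f"{path}: non-uniform wavelength step at line {row}")
    grid = WavelengthGrid(float(w[0]), float(w[-1]), float(steps[0]))
    out = {}
    for sid in ids:
        col = pd.to_numeric(df[sid], errors="coerce")
        bad = col.isna() & df[sid].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2
            raise ParseError(f"{path}: non-numeric cell for {sid!r} at line {row}")
        out[sid] = SpectralDistribution(grid, col.to_numpy(float), kind, sid)
    return out


# --------------------------------------------------------------------------
# surface bank bundles
# --------------------------------------------------------------------------

def write_surface_bank(directory, samples: list[SurfaceSample]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_spectra(directory / "reflectance.csv", {s.sample_id: s.reflectance for s in samples})
    front = {s.sample_id: s.transmittance_front_up for s in samples if s.transmittance_front_up}
    back = {s.sample_id: s.transmittance_back_up for s in samples if s.transmittance_back_up}
    if front:
        write_spectra(directory / "transmittance_front.csv", front)
    if back:
        write_spectra(directory / "transmittance_back.csv", back)
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "category": [s.category for s in samples],
            "scientific_name": [s.scientific_name or "" for s in samples],
            "has_transmittance": [s.transmittance_front_up is not None for s in samples],
        }
    ).to_csv(directory / "metadata.csv", index=False)


def read_surface_bank(directory) -> list[SurfaceSample]:
    directory = Path(directory)
    refl = read_spectra(directory / "reflectance.csv", "reflectance")
    meta = pd.read_csv(directory / "metadata.csv", keep_default_na=False)
    front, back = {}, {}
    if (directory / "transmittance_front.csv").exists():
        front = read_spectra(directory / "transmittance_front.csv", "transmittance")
    if (directory / "transmittance_back.csv").exists():
        back = read_spectra(directory / "transmittance_back.csv", "transmittance")
    samples = []
    for row in meta.itertuples(index=False):
        if row.sample_id not in refl:
            raise ParseError(f"metadata lists {row.sample_id!r} missing from reflectance.csv")
        samples.append(
            SurfaceSample(
                sample_id=row.sample_id,
                category=row.category,
                reflectance=refl[row.sample_id],
                transmittance_front_up=front.get(row.sample_id),
                transmittance_back_up=back.get(row.sample_id),
                scientific_name=row.scientific_name or None,
            )
        )
    return samples


# --------------------------------------------------------------------------
# daylight record bundles
# --------------------------------------------------------------------------

def write_daylight_records(directory, records: list[DaylightRecord], name: str = "daylight") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = [f"rec_{i + 1:04d}" for i in range(len(records))]
    kind = {"cd/m2": "radiance", "lx": "irradiance"}
    write_spectra(
        directory / f"{name}_spectra.csv",
        {
            rid: r.spectrum.with_values(r.spectrum.values, kind[r.level_unit])
            for rid, r in zip(ids, records)
        },
    )
    pd.DataFrame(
        {
            "sample_id": ids,
            "timestamp": [r.timestamp.isoformat() for r in records],
            "site": [r.site for r in records],
            "condition": [r.condition for r in records],
            "cloud_cover_pct": [r.cloud_cover_pct for r in records],
            "sun_occluded": [r.sun_occluded for r in records],
            "photometric_level": [r.photometric_level for r in records],
            "level_unit": [r.level_unit for r in records],
        }
    ).to_csv(directory / f"{name}_metadata.csv", index=False)


def read_daylight_records(directory, name: str = "daylight") -> list[DaylightRecord]:
    directory = Path(directory)
    meta = pd.read_csv(directory / f"{name}_metadata.csv")
    spectra = read_spectra(directory / f"{name}_spectra.csv")
    records = []
    for row in meta.itertuples(index=False):
        spd = spectra[row.sample_id]
        unit = row.level_unit
        records.append(
            DaylightRecord(
                timestamp=datetime.fromisoformat(row.timestamp),
                site=row.site,
                condition=row.condition,
                spectrum=spd.with_values(
                    spd.values, "radiance" if unit == "cd/m2" else "irradiance"
                ),
                photometric_level=float(row.photometric_level),
                level_unit=unit,
                cloud_cover_pct=None if pd.isna(row.cloud_cover_pct) else float(row.cloud_cover_pct),
                sun_occluded=None if pd.isna(row.sun_occluded) else bool(row.sun_occluded),
            )
        )
    return records
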