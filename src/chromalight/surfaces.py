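"""Reflectance/transmittance estimation and near-duplicate filtering.

Reflectance is estimated as the channelwise ratio of the light reflected
from a sample to the illuminant spectrum measured off a flat white
calibration plate; transmittance analogously from light passed through a
sample versus the bare source.  Banks of reflectances are cleaned with a
Pearson-correlation near-duplicate filter (r > 0.999 across the 81
channels of the 5 nm surface grid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .errors import DivisionGuardError, GridError, ValidationError
from .spectra import SpectralDistribution, require_same_grid

log = logging.getLogger(__name__)

CATEGORIES = ("flower", "leaf", "fruit", "vegetable", "bark", "stone")

#: Object-category composition of a full survey-sized bank.
CATEGORY_COUNTS = {
    "flower": 200, "leaf": 113, "fruit": 23, "vegetable": 6, "bark": 8, "stone": 9,
}


@dataclass
class SurfaceSample:
    """One measured natural object: reflectance plus optional transmittances."""

    sample_id: str
    category: str
    reflectance: SpectralDistribution
    transmittance_front_up: SpectralDistribution | None = None
    transmittance_back_up: SpectralDistribution | None = None
    scientific_name: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        has_t = self.transmittance_front_up is not None or self.transmittance_back_up is not None
        if has_t and self.category != "leaf":
            raise ValidationError(
                f"{self.sample_id}: transmittance measurements are only taken for leaves"
            )


@dataclass
class DedupReport:
    """Outcome of the correlation-based near-duplicate sweep."""

    kept_ids: list[str]
    removed_ids: list[str]
    pair_correlations: list[tuple[str, str, float]]
    degenerate_ids: list[str] = field(default_factory=list)


def _ratio(
    numerator: SpectralDistribution,
    denominator: SpectralDistribution,
    kind: str,
    eps_rel: float = 1e-12,
) -> SpectralDistribution:
    require_same_grid(numerator, denominator)
    den = denominator.values
    guard = eps_rel * float(np.max(den)) if np.max(den) > 0 else 0.0
    bad = den <= guard
    if bad.any():
        ch = denominator.wavelengths[bad][:5]
        raise DivisionGuardError(
            f"illuminant/source is <= {guard:g} at channel(s) {ch.tolist()} nm; "
            "ratio estimate undefined there"
        )
    return SpectralDistribution(numerator.grid, numerator.values / den, kind, numerator.name)


def estimate_reflectance(
    measured: SpectralDistribution,
    illuminant: SpectralDistribution,
    eps_rel: float = 1e-12,
) -> SpectralDistribution:
    """R(λ) = reflected / illuminant, channelwise on a shared grid."""
    return _ratio(measured, illuminant, "reflectance", eps_rel)


def estimate_transmittance(
    transmitted: SpectralDistribution,
    source: SpectralDistribution,
    eps_rel: float = 1e-12,
) -> SpectralDistribution:
    """T(λ) = transmitted / source, channelwise on a shared grid."""
    return _ratio(transmitted, source, "transmittance", eps_rel)


class CorrelationDeduplicator(BaseEstimator):
    """Greedy near-duplicate filter on reflectance spectra.

    A sample is removed when its reflectance has Pearson r > ``r_threshold``
    with any *earlier kept* sample (greedy sweep in input order, so the
    first member of a duplicate group survives).  Constant spectra have an
    undefined correlation; they are kept and reported separately.

    Fitted attributes
    -----------------
    keep_mask_ : boolean array, True for kept rows.
    pairs_ : list of (kept_index, removed_index, r) for every violation.
    """

    def __init__(self, r_threshold: float = 0.999):
        self.r_threshold = r_threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValidationError("X must be a 2-D (n_samples, n_channels) array")
        n = X.shape[0]
        sd = X.std(axis=1)
        centered = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        keep: list[int] = []
        keep_mask = np.zeros(n, dtype=bool)
        pairs: list[tuple[int, int, float]] = []
        degenerate: list[int] = []
        for i in range(n):
            if sd[i] == 0:
                degenerate.append(i)
                keep_mask[i] = True
                keep.append(i)
                continue
            duplicate_of = None
            if keep:
                prev = [j for j in keep if sd[j] > 0]
                if prev:
                    r = centered[prev] @ centered[i] / (norms[prev] * norms[i])
                    hits = np.nonzero(r > self.r_threshold)[0]
                    if hits.size:
                        duplicate_of = [(prev[h], float(r[h])) for h in hits]
            if duplicate_of is None:
                keep_mask[i] = True
                keep.append(i)
            else:
                pairs.extend((j, i, r) for j, r in duplicate_of)
        self.keep_mask_ = keep_mask
        self.pairs_ = pairs
        self.degenerate_ = degenerate
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[0] != self.keep_mask_.shape[0]:
            raise ValidationError("transform() expects the same rows that were fit")
        return X[self.keep_mask_]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def dedup_by_correlation(
    samples: list[SurfaceSample], r_threshold: float = 0.999
) -> DedupReport:
    """Apply the greedy correlation filter to a bank of surface samples."""
    if not samples:
        return DedupReport([], [], [])
    grid = samples[0].reflectance.grid
    for s in samples:
        if s.reflectance.grid != grid:
            raise GridError(f"{s.sample_id}: reflectance not on the common grid {grid}")
    X = np.stack([s.reflectance.values for s in samples])
    dedup = CorrelationDeduplicator(r_threshold=r_threshold).fit(X)
    ids = [s.sample_id for s in samples]
    if dedup.degenerate_:
        log.warning(
            "constant reflectance (undefined correlation) kept as non-duplicate: %s",
            [ids[i] for i in dedup.degenerate_],
        )
    return DedupReport(
        kept_ids=[ids[i] for i in np.nonzero(dedup.keep_mask_)[0]],
        removed_ids=[ids[i] for i in np.nonzero(~dedup.keep_mask_)[0]],
        pair_correlations=[(ids[a], ids[b], r) for a, b, r in dedup.pairs_],
        degenerate_ids=[ids[i] for i in dedup.degenerate_],
    )
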