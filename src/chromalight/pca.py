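"""Characteristic-vector (PCA) decomposition of spectral ensembles.

Daylight ensembles are classically summarised by a handful of
characteristic vectors: an eigen-decomposition of the ensemble
cross-product matrix whose leading components account for nearly all the
spectral variance.  The historical daylight construction works on
*uncentered* data — the first component then plays the role of the mean
daylight spectrum — so ``centered=False`` is the default here, with
conventional mean-centred PCA available.  For uncentered analyses the
"variance explained" fractions are taken about zero (total sum of
squares), which is stated explicitly because the term is ambiguous
without centring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import GridError, NormalizationError, ValidationError
from .spectra import SpectralDistribution

#: Eigenvector signs are arbitrary; pin each component non-negative at this wavelength.
SIGN_PIN_NM = 560.0


@dataclass
class PCAResult:
    """Decomposition result: mean, ordered unit components, variance fractions."""

    mean_spectrum: SpectralDistribution
    components: list[SpectralDistribution]
    variance_explained: np.ndarray
    centered: bool


class SpectralPCA(TransformerMixin, BaseEstimator):
    """PCA over rows of a (n_spectra, n_channels) matrix.

    Parameters
    ----------
    n_components : number of components kept.
    centered : subtract the ensemble mean before decomposition.  False
        reproduces the uncentered characteristic-vector construction.
    sign_pin_index : channel index at which each component is forced
        non-negative (deterministic sign convention); resolved from
        wavelengths when fitting via :func:`pca_spectra`.

    Fitted attributes: ``mean_``, ``components_`` (rows orthonormal),
    ``explained_variance_ratio_``, ``singular_values_``.
    """

    def __init__(self, n_components: int = 3, centered: bool = False,
                 sign_pin_index: int | None = None):
        self.n_components = n_components
        self.centered = centered
        self.sign_pin_index = sign_pin_index

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValidationError("X must be 2-D with at least 2 spectra")
        k = self.n_components
        if not 1 <= k <= min(X.shape):
            raise ValidationError(
                f"n_components={k} must be in [1, min(n_spectra, n_channels)={min(X.shape)}]"
            )
        self.mean_ = X.mean(axis=0)
        work = X - self.mean_ if self.centered else X
        # SVD of the data matrix == eigen-decomposition of the cross-product matrix.
        _, s, vt = np.linalg.svd(work, full_matrices=False)
        total_ss = float(np.sum(work**2))
        comps = vt[:k]
        pin = self.sign_pin_index
        if pin is None:
            pin = X.shape[1] // 2
        flip = np.where(comps[:, pin] < 0, -1.0, 1.0)
        self.components_ = comps * flip[:, None]
        self.singular_values_ = s[:k]
        self.explained_variance_ratio_ = (
            s[:k] ** 2 / total_ss if total_ss > 0 else np.zeros(k)
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        work = X - self.mean_ if self.centered else X
        return work @ self.components_.T

    def inverse_transform(self, scores):
        base = self.mean_ if self.centered else 0.0
        return np.asarray(scores, float) @ self.components_ + base


def pca_spectra(
    spectra: list[SpectralDistribution], n_components: int = 3, centered: bool = False
) -> PCAResult:
    """Characteristic-vector decomposition of a list of spectra on one grid."""
    if len(spectra) < 2:
        raise ValidationError("need at least 2 spectra")
    grid = spectra[0].grid
    for s in spectra:
        if s.grid != grid:
            raise GridError("all spectra must share one grid")
    X = np.stack([s.values for s in spectra])
    w = grid.wavelengths
    pin = int(np.argmin(np.abs(w - SIGN_PIN_NM)))
    est = SpectralPCA(n_components=n_components, centered=centered, sign_pin_index=pin).fit(X)
    return PCAResult(
        mean_spectrum=SpectralDistribution(grid, est.mean_, "relative", "ensemble mean"),
        components=[
            SpectralDistribution(grid, c, "relative", f"component_{i + 1}")
            for i, c in enumerate(est.components_)
        ],
        variance_explained=est.explained_variance_ratio_,
        centered=centered,
    )


def normalize_component(component: SpectralDistribution) -> SpectralDistribution:
    """Shift a spectral vector to min 0, then scale it to 1.0 at 580 nm.

    The standard presentation for comparing characteristic vectors from
    different decompositions on a common footing; invariant to positive
    affine transforms a·v + b of the input.
    """
    v = component.values - component.values.min()
    ref = v[component.grid.index_of(580.0)]
    if ref <= 0:
        raise NormalizationError("component value at 580 nm is 0 after min-shift")
    return component.with_values(v / ref)


def compare_to_basis(
    component: SpectralDistribution,
    reference: SpectralDistribution,
    short_band: tuple[float, float] = (380.0, 480.0),
    long_band: tuple[float, float] = (680.0, 780.0),
) -> dict[str, float]:
    """RMS and band-mean signed differences between two normalized vectors.

    Both inputs should already be on the min-0 / 580-nm-1 normalization.
    Negative band means say the component sits below the reference in that
    wavelength band.
    """
    if component.grid != reference.grid:
        raise GridError("component and reference must share a grid")
    diff = component.values - reference.values
    w = component.grid.wavelengths

    def band_mean(lo: float, hi: float) -> float:
        sel = (w >= lo) & (w <= hi)
        return float(diff[sel].mean())

    return {
        "rms": float(np.sqrt(np.mean(diff**2))),
        "short_band_mean": band_mean(*short_band),
        "long_band_mean": band_mean(*long_band),
    }
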