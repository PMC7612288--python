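"""Reflectance/transmittance estimation and the correlation dedup filter."""

import numpy as np
import pytest

from chromalight.errors import DivisionGuardError, GridError, ValidationError
from chromalight.spectra import SpectralDistribution, WavelengthGrid
from chromalight.surfaces import (
    SurfaceSample,
    dedup_by_correlation,
    estimate_reflectance,
    estimate_transmittance,
)


def spd(grid, values, kind="radiance"):
    return SpectralDistribution(grid, np.asarray(values, float), kind)


def sample(grid, sid, values, category="flower"):
    return SurfaceSample(sid, category, SpectralDistribution(grid, values, "reflectance"))


class TestRatioEstimates:
    def test_self_ratio_is_one(self, surface_grid, rng):
        illum = spd(surface_grid, rng.random(81) + 0.5)
        assert np.allclose(estimate_reflectance(illum, illum).values, 1.0)
        assert np.allclose(estimate_transmittance(illum, illum).values, 1.0)

    def test_zero_numerator_is_zero(self, surface_grid, rng):
        illum = spd(surface_grid, rng.random(81) + 0.5)
        out = estimate_reflectance(spd(surface_grid, np.zeros(81)), illum)
        assert np.allclose(out.values, 0.0)
        assert out.kind == "reflectance"

    def test_recovers_known_reflectance(self, surface_grid, rng):
        """Multiply-then-divide oracle: R = (I*R)/I channel by channel."""
        illum = spd(surface_grid, rng.random(81) + 0.5)
        r_true = rng.random(81)
        measured = spd(surface_grid, illum.values * r_true)
        out = estimate_reflectance(measured, illum)
        assert np.allclose(out.values, r_true, atol=1e-12)

    def test_two_peak_transmittance_recovery(self, surface_grid, rng):
        w = surface_grid.wavelengths
        t_true = 0.1 * np.exp(-0.5 * ((w - 550) / 30) ** 2) + 0.3 / (1 + np.exp(-(w - 700) / 12))
        source = spd(surface_grid, rng.random(81) + 0.5)
        out = estimate_transmittance(spd(surface_grid, source.values * t_true), source)
        assert out.kind == "transmittance"
        assert np.allclose(out.values, t_true, atol=1e-12)

    def test_division_guard_names_channel(self, surface_grid):
        illum_vals = np.ones(81)
        illum_vals[surface_grid.index_of(500)] = 0.0
        with pytest.raises(DivisionGuardError, match="500"):
            estimate_reflectance(spd(surface_grid, np.ones(81)), spd(surface_grid, illum_vals))

    def test_grid_mismatch_rejected(self, surface_grid, daylight_grid):
        with pytest.raises(GridError):
            estimate_reflectance(
                spd(surface_grid, np.ones(81)), spd(daylight_grid, np.ones(401))
            )

    def test_transmittance_sides_stored_independently(self, surface_grid, rng):
        front = SpectralDistribution(surface_grid, rng.random(81) * 0.4, "transmittance")
        back = SpectralDistribution(surface_grid, rng.random(81) * 0.4, "transmittance")
        leaf = SurfaceSample(
            "leaf_x", "leaf",
            SpectralDistribution(surface_grid, rng.random(81), "reflectance"),
            transmittance_front_up=front, transmittance_back_up=back,
        )
        assert not np.allclose(leaf.transmittance_front_up.values,
                               leaf.transmittance_back_up.values)
        with pytest.raises(ValidationError):
            SurfaceSample("stone_x", "stone",
                          SpectralDistribution(surface_grid, rng.random(81), "reflectance"),
                          transmittance_front_up=front)


def greedy_oracle(X, threshold):
    """Plain-loop reference implementation of the greedy dedup sweep."""
    kept = []
    for i in range(len(X)):
        dup = False
        for j in kept:
            if np.std(X[i]) > 0 and np.std(X[j]) > 0:
                if np.corrcoef(X[i], X[j])[0, 1] > threshold:
                    dup = True
                    break
        if not dup:
            kept.append(i)
    return kept


class TestDedup:
    def test_identical_pair_keeps_first(self, surface_grid, rng):
        v = rng.random(81)
        rep = dedup_by_correlation(
            [sample(surface_grid, "a", v), sample(surface_grid, "b", v.copy())]
        )
        assert rep.kept_ids == ["a"] and rep.removed_ids == ["b"]
        assert rep.pair_correlations[0][:2] == ("a", "b")
        assert rep.pair_correlations[0][2] > 0.999

    def test_uncorrelated_pair_kept(self, surface_grid, rng):
        rep = dedup_by_correlation(
            [sample(surface_grid, "a", rng.random(81)), sample(surface_grid, "b", rng.random(81))]
        )
        assert rep.kept_ids == ["a", "b"]

    def test_chain_compares_only_against_kept(self, surface_grid, rng):
        """A~B and B~C above threshold but A~C below: keep A and C, drop B."""
        base = rng.random(81)

        def unit_noise(*orthogonal_to):
            n = rng.normal(0, 1, 81)
            n -= n.mean()
            for v in orthogonal_to:
                vc = v - v.mean()
                n -= (n @ vc) / (vc @ vc) * vc
            return n / n.std()

        # corr(a, a + t*noise*std(a)) = 1/sqrt(1+t^2) for orthogonal noise:
        # t=0.04 puts single steps at r~0.9992 (> 0.999) and the two-step,
        # with mutually orthogonal noises, at r~0.9984 (< 0.999)
        eps = 0.040 * base.std()
        n1 = unit_noise(base)
        n2 = unit_noise(base, n1)
        a = base
        b = base + eps * n1
        c = b + eps * n2
        assert np.corrcoef(a, b)[0, 1] > 0.999
        assert np.corrcoef(b, c)[0, 1] > 0.999
        assert np.corrcoef(a, c)[0, 1] < 0.999
        bank = [
            sample(surface_grid, s, np.clip(v / v.max(), 0, 1))
            for s, v in (("A", a), ("B", b), ("C", c))
        ]
        rep = dedup_by_correlation(bank)
        assert rep.kept_ids == ["A", "C"] and rep.removed_ids == ["B"]

    def test_matches_plain_loop_oracle_on_random_banks(self, surface_grid, rng):
        for trial in range(5):
            base = rng.random((12, 81))
            X = np.vstack([base, base[rng.integers(0, 12, 6)] + rng.normal(0, 1e-5, (6, 81))])
            X = np.clip(X, 0, 1)
            bank = [sample(surface_grid, f"s{i}", X[i]) for i in range(len(X))]
            rep = dedup_by_correlation(bank)
            expected = [f"s{i}" for i in greedy_oracle(X, 0.999)]
            assert rep.kept_ids == expected

    def test_constant_reflectance_kept_and_flagged(self, surface_grid, rng):
        rep = dedup_by_correlation(
            [sample(surface_grid, "flat", np.full(81, 0.3)),
             sample(surface_grid, "flat2", np.full(81, 0.3)),
             sample(surface_grid, "var", rng.random(81))]
        )
        assert set(rep.degenerate_ids) == {"flat", "flat2"}
        assert rep.removed_ids == []

    def test_idempotent_on_kept_set(self, surface_grid, rng):
        base = rng.random((10, 81))
        bank = [sample(surface_grid, f"s{i}", np.clip(v, 0, 1)) for i, v in enumerate(base)]
        bank += [sample(surface_grid, "dup", np.clip(base[0] + 1e-6, 0, 1))]
        rep = dedup_by_correlation(bank)
        kept_bank = [s for s in bank if s.sample_id in rep.kept_ids]
        rep2 = dedup_by_correlation(kept_bank)
        assert rep2.removed_ids == []

    def test_kept_count_monotone_in_threshold(self, surface_grid, rng):
        base = rng.random(81)
        bank = [
            sample(surface_grid, f"s{i}", np.clip(base + sd * rng.normal(0, 1, 81), 0, 1))
            for i, sd in enumerate([0, 1e-4, 1e-3, 1e-2, 0.1])
        ]
        sizes = [
            len(dedup_by_correlation(bank, thr).kept_ids)
            for thr in (0.99999, 0.999, 0.99, 0.9)
        ]
        assert sizes == sorted(sizes, reverse=True)
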