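"""Z-score fields, anterior integrated enrichment, and AP profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from germquant import (
    APProfile,
    aggregate_profiles,
    anterior_integrated_enrichment,
    anterior_region,
    ap_profile,
    zscore_field,
)
from germquant.prep import PixelSet

from conftest import make_sample, random_masked_sample


def brute_force_enrichment(sample, channel, fraction, mode):
    """Independent sort-and-sum oracle: explicit z-formula, explicit pixel
    ranking, math.fsum accumulation."""
    img = sample.channel(channel)
    coords = [(y, x) for y, x in zip(*np.nonzero(sample.mask))]
    vals = [img[y, x] for y, x in coords]
    mu = math.fsum(vals) / len(vals)
    sd = math.sqrt(math.fsum((v - mu) ** 2 for v in vals) / len(vals))
    z = {c: (img[c] - mu) / sd for c in coords}
    if mode == "pixels":
        ranked = sorted(coords, key=lambda c: (c[1], c[0]))
        take = ranked[: int(math.floor(fraction * len(coords) + 0.5))]
    else:
        xs = [x for _, x in coords]
        cut = min(xs) + fraction * (max(xs) - min(xs))
        take = coords if fraction >= 1 else [c for c in coords if c[1] < cut]
    return math.fsum(z[c] for c in take)


class TestZScoreField:
    def test_two_pixel_hand_values(self):
        s = make_sample([[[1.0, 3.0]]])
        zf = zscore_field(s, 0)
        assert zf.mask_mean == 2.0 and zf.mask_sd == 1.0
        np.testing.assert_allclose(zf.values(), [-1.0, 1.0])

    def test_four_pixel_hand_values(self):
        s = make_sample([[[2.0, 4.0, 6.0, 8.0]]])
        zf = zscore_field(s, 0)
        np.testing.assert_allclose(zf.mask_sd, math.sqrt(5), rtol=1e-12)
        np.testing.assert_allclose(
            zf.values(), [-1.3416, -0.4472, 0.4472, 1.3416], atol=5e-5
        )

    def test_constant_channel_raises(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_field(make_sample([np.full((3, 3), 7.0)]), 0)

    def test_zscores_sum_to_zero_over_mask(self, rng):
        for _ in range(10):
            s = random_masked_sample(rng)
            zf = zscore_field(s, 0)
            assert abs(zf.values().sum()) < 1e-6 * s.n_mask_pixels

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0), seed=st.integers(0, 10**6))
    def test_affine_invariance(self, a, b, seed):
        """z-field is unchanged under I -> a*I + b, a > 0."""
        r = np.random.default_rng(seed)
        s = random_masked_sample(r, shape=(16, 16))
        s2 = make_sample([a * s.image[0] + b], mask=s.mask)
        np.testing.assert_allclose(
            zscore_field(s, 0).values(), zscore_field(s2, 0).values(), atol=1e-9
        )


class TestAnteriorEnrichment:
    def test_whole_mask_enrichment_is_zero(self, rng):
        s = random_masked_sample(rng)
        zf = zscore_field(s, 0)
        res = anterior_integrated_enrichment(zf, anterior_region(s, 1.0), fraction=1.0)
        assert abs(res.value) < 1e-6 * s.n_mask_pixels

    def test_ten_pixel_step_profile_hand_value(self):
        # values (10 x5, 0 x5): mu=5, sd=5; anterior 2 pixels each z=+1 -> 2.0
        s = make_sample([[[10.0, 10, 10, 10, 10, 0, 0, 0, 0, 0]]])
        zf = zscore_field(s, 0)
        res = anterior_integrated_enrichment(zf, anterior_region(s, 0.15, "pixels"))
        assert res.value == pytest.approx(2.0, abs=1e-12)
        assert res.n_pixels == 2

    @pytest.mark.parametrize("mode", ["pixels", "length"])
    def test_matches_sort_and_sum_oracle(self, rng, mode):
        for _ in range(50):
            s = random_masked_sample(rng, shape=(32, 32))
            zf = zscore_field(s, 0)
            res = anterior_integrated_enrichment(
                zf, anterior_region(s, 0.15, mode), fraction=0.15, mode=mode
            )
            oracle = brute_force_enrichment(s, 0, 0.15, mode)
            assert res.value == pytest.approx(oracle, abs=1e-9)

    def test_complement_conservation(self, rng):
        """Enrichment over the anterior set equals minus the complement's."""
        s = random_masked_sample(rng)
        zf = zscore_field(s, 0)
        region = anterior_region(s, 0.15)
        ant = anterior_integrated_enrichment(zf, region).value
        all_coords = set(map(tuple, np.argwhere(s.mask)))
        comp = PixelSet(np.array(sorted(all_coords - set(map(tuple, region.coordinates)))))
        post = anterior_integrated_enrichment(zf, comp).value
        assert ant == pytest.approx(-post, abs=1e-6 * s.n_mask_pixels)

    def test_empty_region_raises(self, rng):
        s = random_masked_sample(rng)
        zf = zscore_field(s, 0)
        with pytest.raises(ValueError):
            anterior_integrated_enrichment(zf, PixelSet(np.empty((0, 2))))

    def test_region_outside_mask_raises(self):
        s = make_sample([[[1.0, 2.0], [3.0, 4.0]]], mask=[[True, True], [True, False]])
        zf = zscore_field(s, 0)
        with pytest.raises(ValueError, match="outside"):
            anterior_integrated_enrichment(zf, PixelSet(np.array([[1, 1]])))


class TestAPProfile:
    def test_profile_has_standard_length(self, rng):
        s = random_masked_sample(rng)
        prof = ap_profile(zscore_field(s, 0), s)
        assert prof.n_points == 300
        assert prof.positions[0] == 0.0 and prof.positions[-1] == 1.0

    def test_linear_ramp_gives_strictly_increasing_profile(self):
        ramp = np.tile(np.arange(300.0), (1, 1))
        s = make_sample([ramp])
        prof = ap_profile(zscore_field(s, 0), s)
        assert np.all(np.diff(prof.values) > 0)

    def test_endpoints_equal_boundary_column_means(self, rng):
        s = random_masked_sample(rng)
        zf = zscore_field(s, 0)
        prof = ap_profile(zf, s)
        x_min, x_max = s.ap_bounds
        first = zf.z[:, x_min][s.mask[:, x_min]].mean()
        last = zf.z[:, x_max][s.mask[:, x_max]].mean()
        assert prof.values[0] == pytest.approx(first, rel=1e-12)
        assert prof.values[-1] == pytest.approx(last, rel=1e-12)

    def test_empty_interior_column_is_bridged(self):
        mask = np.ones((1, 5), dtype=bool)
        mask[0, 2] = False  # gap in the middle
        vals = np.array([[0.0, 1.0, 0.0, 3.0, 4.0]])
        s = make_sample([vals], mask=mask)
        prof = ap_profile(zscore_field(s, 0), s, n_points=5)
        # bridged value at x=2 is the midpoint of its neighbours' z-values
        assert prof.values[2] == pytest.approx((prof.values[1] + prof.values[3]) / 2)

    def test_single_column_mask_raises(self):
        s = make_sample([[[1.0], [2.0]]])
        with pytest.raises(ValueError, match="single column"):
            ap_profile(zscore_field(s, 0), s)

    def test_profile_affine_invariant(self, rng):
        s = random_masked_sample(rng)
        s2 = make_sample([3 * s.image[0] + 7], mask=s.mask)
        p1 = ap_profile(zscore_field(s, 0), s)
        p2 = ap_profile(zscore_field(s2, 0), s2)
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-9)


class TestAggregateProfiles:
    def _profile(self, values, n=None):
        values = np.asarray(values, dtype=float)
        return APProfile(positions=np.linspace(0, 1, len(values)), values=values)

    def test_single_profile_zero_width_ci(self, rng):
        v = rng.normal(size=300)
        ens = aggregate_profiles([self._profile(v)])
        np.testing.assert_array_equal(ens.mean, v)
        np.testing.assert_array_equal(ens.ci_low, ens.ci_high)

    def test_profile_and_negation_average_to_zero(self, rng):
        v = rng.normal(size=300)
        ens = aggregate_profiles([self._profile(v), self._profile(-v)])
        np.testing.assert_allclose(ens.mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(ens.ci_low, -ens.ci_high, atol=1e-12)

    def test_matches_direct_recomputation(self, rng):
        mat = rng.normal(size=(10, 300))
        ens = aggregate_profiles([self._profile(row) for row in mat])
        mean = mat.mean(axis=0)
        sem = mat.std(axis=0, ddof=1) / np.sqrt(10)
        np.testing.assert_allclose(ens.mean, mean, rtol=1e-12)
        np.testing.assert_allclose(ens.ci_low, mean - 1.96 * sem, rtol=1e-10)
        np.testing.assert_allclose(ens.ci_high, mean + 1.96 * sem, rtol=1e-10)

    def test_mixed_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="mixed"):
            aggregate_profiles(
                [self._profile(np.zeros(300)), self._profile(np.zeros(200))]
            )

    def test_ci_brackets_mean_pointwise(self, rng):
        mat = rng.normal(size=(5, 50))
        ens = aggregate_profiles([self._profile(row) for row in mat])
        assert np.all(ens.ci_low <= ens.mean) and np.all(ens.mean <= ens.ci_high)
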