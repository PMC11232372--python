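"""Depth binning, normalization, exponential fits, cumulative summaries."""

import numpy as np
import pytest

from slicetox import depthprofile as dp
from slicetox import synthetic
from slicetox.errors import FitError, InputError, ParameterError
from util import detections_from_depths


def profile_from(counts, edges=None):
    counts = np.asarray(counts, dtype=float)
    if edges is None:
        edges = np.arange(0.0, 30.0 * (len(counts) + 1) - 1e-9, 30.0)
    return dp.DepthProfile(bin_edges=edges, counts=counts, kind=dp.KIND_COUNT)


class TestBinByDepth:
    def test_empty_set(self):
        prof = dp.bin_by_depth(detections_from_depths([]))
        assert prof.total == 0 and len(prof.counts) == 10

    def test_half_open_convention(self):
        """z = 0 and 29.9 land in bin 0; z = 30.0 in bin 1."""
        prof = dp.bin_by_depth(detections_from_depths([0.0, 29.9, 30.0]))
        assert prof.counts[0] == 2 and prof.counts[1] == 1

    def test_count_conservation(self, rng):
        z = rng.uniform(0, 300, 500)
        prof = dp.bin_by_depth(detections_from_depths(z))
        assert prof.total == 500

    def test_out_of_range_dropped(self):
        prof = dp.bin_by_depth(detections_from_depths([-5.0, 150.0, 300.0, 400.0]))
        assert prof.total == 1

    def test_unsorted_edges(self):
        with pytest.raises(ParameterError):
            dp.bin_by_depth(detections_from_depths([1.0]), edges=[0.0, 60.0, 30.0])

    def test_bin_masses_match_truncated_exponential(self, rng):
        """Bin counts agree with the analytic truncated-exponential mass within 3 sigma."""
        n, tau = 10_000, 41.0
        z = synthetic.sample_depths(n, tau, 300.0, rng)
        prof = dp.bin_by_depth(detections_from_depths(z))
        edges = prof.bin_edges
        norm = 1.0 - np.exp(-300.0 / tau)
        for b in range(10):
            p = (np.exp(-edges[b] / tau) - np.exp(-edges[b + 1] / tau)) / norm
            expect = n * p
            sd = np.sqrt(n * p * (1 - p))
            assert abs(prof.counts[b] - expect) < max(3 * sd, 1e-9) + 1e-9


class TestNormalizeProfile:
    def test_count_normalization(self):
        prof = dp.normalize_profile(profile_from([8, 2, 0]))
        np.testing.assert_allclose(prof.normalized, [0.8, 0.2, 0.0])
        assert prof.normalized.sum() == pytest.approx(1.0, abs=1e-9)

    def test_intensity_normalization_to_max(self):
        prof = dp.DepthProfile(np.array([0.0, 30.0, 60.0]), np.array([120.0, 200.0]), kind=dp.KIND_INTENSITY)
        out = dp.normalize_profile(prof)
        assert out.normalized.max() == 1.0 and out.normalized[0] == pytest.approx(0.6)

    def test_zero_total_warns(self):
        with pytest.warns(UserWarning):
            out = dp.normalize_profile(profile_from([0, 0, 0]))
        assert not out.normalized.any()


class TestFitExponential:
    def test_noiseless_self_consistency(self):
        """Exact y = 0.5 exp(-z/41) data recovers tau to machine precision, r2 = 1."""
        z = np.arange(15.0, 300.0, 30.0)
        fit = dp.fit_exponential(z, 0.5 * np.exp(-z / 41.0))
        assert fit.converged
        assert fit.tau == pytest.approx(41.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_sampled_depths_recover_tau_within_printed_interval(self, rng):
        """10^4 depths at tau = 41 um: binned fit lands within the 41 +/- 10 um band."""
        z = synthetic.sample_depths(10_000, 41.0, 300.0, rng)
        prof = dp.normalize_profile(dp.bin_by_depth(detections_from_depths(z)))
        fit = dp.fit_exponential(prof)
        assert fit.converged
        assert abs(fit.tau - 41.0) < 10.0

    def test_flat_profile_not_converged(self):
        prof = dp.normalize_profile(profile_from([5, 5, 5, 5, 5]))
        fit = dp.fit_exponential(prof)
        assert not fit.converged

    def test_too_few_nonzero_bins(self):
        with pytest.raises(FitError):
            dp.fit_exponential(profile_from([5, 3, 0, 0, 0]))

    def test_poisson_resampled_within_10pct(self, rng):
        """Poisson noise on an exponential profile perturbs tau by < 10% at n ~ 1e4."""
        z_mid = np.arange(15.0, 300.0, 30.0)
        expected = 10_000 * np.exp(-z_mid / 50.0) / np.exp(-z_mid / 50.0).sum()
        noisy = rng.poisson(expected).astype(float)
        fit = dp.fit_exponential(z_mid, noisy / noisy.sum())
        assert abs(fit.tau - 50.0) / 50.0 < 0.10


class TestCumulativeSummaries:
    def test_fraction_at_last_edge_is_one(self):
        prof = profile_from([3, 1, 2])
        assert dp.fraction_within(prof, 90.0) == 1.0

    def test_linear_interpolation_inside_bin(self):
        """Counts (8, 2) over 0-30/30-60: depth 45 covers half of bin 2 -> 0.9."""
        prof = profile_from([8, 2])
        assert dp.fraction_within(prof, 45.0) == pytest.approx(0.9)

    def test_fraction_at_zero(self):
        assert dp.fraction_within(profile_from([5, 5]), 0.0) == 0.0

    def test_depth_for_fraction_hits_edge(self):
        """Counts (3, 1): cumulative reaches 0.75 exactly at the first edge, 30 um."""
        assert dp.depth_for_fraction(profile_from([3, 1]), 0.75) == pytest.approx(30.0)

    def test_median_of_uniform(self):
        prof = profile_from(np.ones(10))
        assert dp.depth_for_fraction(prof, 0.5) == pytest.approx(150.0)

    def test_round_trip_inverse(self, rng):
        for _ in range(25):
            counts = rng.integers(0, 20, size=10).astype(float)
            if counts.sum() == 0:
                counts[0] = 1
            prof = profile_from(counts)
            for q in (0.1, 0.25, 0.5, 0.75, 0.9):
                d = dp.depth_for_fraction(prof, q)
                assert dp.fraction_within(prof, d) == pytest.approx(q, abs=1e-9)

    def test_fraction_nondecreasing(self, rng):
        prof = profile_from(rng.integers(0, 10, size=10).astype(float) + 0.1)
        vals = [dp.fraction_within(prof, d) for d in np.linspace(0, 300, 61)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_empty_profile_errors(self):
        with pytest.raises(InputError):
            dp.depth_for_fraction(profile_from([0, 0]), 0.5)


class TestMedianNeuropil:
    def test_constant_image_no_masks(self):
        from util import make_projection

        mips = [make_projection(np.full((8, 8), 12.0), z_lo=30.0 * i, z_hi=30.0 * (i + 1)) for i in range(10)]
        prof = dp.median_neuropil_by_depth(mips)
        np.testing.assert_allclose(prof.counts, 12.0)

    def test_recovers_neuropil_tau_noise_free(self):
        """Median intensity per depth step on a noise-free stack refits tau within 5%."""
        cfg = synthetic.SynthStackConfig(
            nx=64, ny=64, n_pi=0, n_filled=0, n_healthy=0, noise_sd=0.0, tau_neuropil=131.0, seed=1
        )
        green, _, _ = synthetic.generate_stack(cfg)
        prof = dp.normalize_profile(dp.median_neuropil_by_depth(green))
        fit = dp.fit_exponential(prof)
        assert fit.converged
        assert abs(fit.tau - 131.0) / 131.0 < 0.05

    def test_masking_somata_never_raises_medians(self):
        """Removing bright soma pixels can only lower (or keep) each bin median."""
        cfg = synthetic.SynthStackConfig(nx=96, ny=96, n_pi=0, n_filled=6, n_healthy=0, noise_sd=0.0, seed=2)
        green, _, truth = synthetic.generate_stack(cfg)
        yy = (np.arange(96) + 0.5) * cfg.pixel_size
        soma = np.zeros((96, 96), dtype=bool)
        for _, row in truth.iterrows():
            soma |= (yy[:, None] - row.y_um) ** 2 + (yy[None, :] - row.x_um) ** 2 <= (2 * cfg.cell_radius) ** 2
        unmasked = dp.median_neuropil_by_depth(green).counts
        masked = dp.median_neuropil_by_depth(green, soma_masks=soma).counts
        ok = np.isfinite(unmasked) & np.isfinite(masked)
        assert np.all(masked[ok] <= unmasked[ok] + 1e-12)
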