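"""Traces, dF/F0, transient metrics, filled classification, grid correlation."""

import numpy as np
import pytest

from slicetox import calcium as ca
from slicetox import synthetic
from slicetox.calcium import Trace
from slicetox.errors import InputError, ParameterError
from util import make_detections, make_projection

FS = 2.67


def trace_from(dff, fs=FS, f0=100.0, roi_id=0):
    dff = np.asarray(dff, dtype=float)
    return Trace(roi_id=roi_id, f=f0 * (1 + dff), frame_rate=fs, f0=f0, dff=dff, median_raw_f=f0)


def gaussian_event(t_peak, sigma, amp, duration=120.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.exp(-((t - t_peak) ** 2) / (2 * sigma**2))


class TestExtractTraces:
    def make_movie(self, frames):
        return synthetic.Movie(frames=np.asarray(frames, dtype=float), frame_rate=FS, pixel_size=1.0)

    def test_soma_equals_annulus_gives_zero(self):
        movie = self.make_movie(np.full((100, 40, 40), 37.0))
        rois = [ca.RoiPair(roi_id=0, x=20.0, y=20.0, radius=5.0)]
        (tr,) = ca.extract_traces(movie, rois)
        np.testing.assert_allclose(tr.f, 0.0)

    def test_constant_soma_and_annulus(self):
        """Soma 100, annulus 20: trace 80 with dF/F0 identically zero."""
        frames = np.full((90, 40, 40), 20.0)
        yy, xx = np.mgrid[:40, :40]
        soma = (yy + 0.5 - 21.0) ** 2 + (xx + 0.5 - 21.0) ** 2 <= 25.0
        frames[:, soma] = 100.0
        movie = self.make_movie(frames)
        (tr,) = ca.extract_traces(movie, [ca.RoiPair(roi_id=0, x=21.0, y=21.0, radius=5.0)])
        np.testing.assert_allclose(tr.f, 80.0)
        np.testing.assert_allclose(tr.dff, 0.0)

    def test_dff_scale_invariance(self):
        """Multiplying the raw movie by a constant leaves dF/F0 unchanged."""
        cfg = synthetic.SynthMovieConfig(n_rois=6, n_filled=0, duration=60.0, noise_sd=0.0, seed=3)
        movie, truth = synthetic.generate_movie(cfg)
        rois = ca.rois_from_table(truth.rois)
        t1 = ca.extract_traces(movie, rois)
        movie2 = synthetic.Movie(frames=movie.frames * 3.0, frame_rate=movie.frame_rate, pixel_size=movie.pixel_size)
        t2 = ca.extract_traces(movie2, rois)
        for a, b in zip(t1, t2):
            if a.dff is not None:
                np.testing.assert_allclose(a.dff, b.dff, atol=1e-9)

    def test_recovered_amplitude_near_truth(self):
        """dF/F0 peaks of isolated synthetic events recover the configured amplitude within 10%."""
        cfg = synthetic.SynthMovieConfig(
            n_rois=5, n_filled=0, duration=240.0, event_rate=0.75, event_amp_dff=1.0, noise_sd=0.5, seed=8
        )
        movie, truth = synthetic.generate_movie(cfg)
        # keep only seeds whose realized events are isolated
        times = truth.event_times
        isolated = [t for t in times if np.all((np.abs(times - t) > 10.0) | (times == t)) and 5 < t < 235]
        assert isolated, "seed produced no isolated events"
        traces = ca.extract_traces(movie, ca.rois_from_table(truth.rois))
        tr = traces[0]
        t = tr.times()
        for te in isolated:
            window = (t > te - 3) & (t < te + 3)
            assert abs(tr.dff[window].max() - 1.0) < 0.10


class TestDetectTransients:
    def test_flat_noisy_trace_no_events(self, rng):
        dff = rng.normal(0, 0.01, size=400)
        m = ca.detect_transients(trace_from(dff))
        assert m.n_events == 0 and m.frequency == 0.0

    def test_gaussian_event_closed_forms(self):
        """A noiseless Gaussian event: amplitude exact, FWHM = 2.3548 sigma within a frame."""
        sigma, amp = 1.5, 2.0
        m = ca.detect_transients(trace_from(gaussian_event(60.0, sigma, amp)))
        assert m.n_events == 1
        assert m.mean_amplitude == pytest.approx(amp, abs=0.01)
        assert abs(m.mean_fwhm - 2 * np.sqrt(2 * np.log(2)) * sigma) < 1.0 / FS

    def test_rectangular_pulse_auc(self):
        """A 4-s unit pulse integrates to ~4 dF/F0*s on the trapezoid grid."""
        t = np.arange(int(120 * FS)) / FS
        dff = ((t >= 50.0) & (t < 54.0)).astype(float)
        m = ca.detect_transients(trace_from(dff))
        assert m.n_events == 1
        assert m.mean_auc == pytest.approx(4.0, abs=2.0 / FS)

    def test_event_times_match_truth_within_one_frame(self):
        """Isolated high-SNR events are localized to within one frame."""
        sigma = 1.5
        truth_times = [30.0, 75.0, 130.0, 200.0]
        dff = sum(gaussian_event(tp, sigma, 1.5, duration=240.0) for tp in truth_times)
        m = ca.detect_transients(trace_from(dff))
        assert m.n_events == len(truth_times)
        for det, tru in zip(m.event_times, truth_times):
            assert abs(det - tru) <= 1.0 / FS + 1e-9

    def test_short_trace_rejected(self):
        with pytest.raises(InputError):
            ca.detect_transients(trace_from(np.zeros(10)))

    def test_frequency_definition(self):
        dff = gaussian_event(30.0, 1.5, 1.0, duration=120.0) + gaussian_event(90.0, 1.5, 1.0, duration=120.0)
        m = ca.detect_transients(trace_from(dff))
        assert m.frequency == pytest.approx(m.n_events / (len(dff) / FS / 60.0))


class TestClassifyFilled:
    def run_movie(self, **kw):
        cfg = synthetic.SynthMovieConfig(**kw)
        movie, truth = synthetic.generate_movie(cfg)
        traces = ca.extract_traces(movie, ca.rois_from_table(truth.rois))
        metrics = [ca.detect_transients(tr) for tr in traces]
        return truth, traces, metrics, ca.classify_filled(traces, metrics)

    def test_exactly_truth_filled_flagged(self):
        truth, _, metrics, flags = self.run_movie(n_rois=40, n_filled=5, duration=300.0, seed=5)
        assert {k for k, v in flags.items() if v} == set(truth.rois[truth.rois.filled].roi_id)
        for m in metrics:
            if flags[m.roi_id]:
                assert m.n_events == 0

    def test_identical_rois_none_flagged(self):
        _, _, _, flags = self.run_movie(n_rois=8, n_filled=0, duration=60.0, event_rate=0.0, noise_sd=0.0, seed=6)
        assert not any(flags.values())

    def test_bright_but_active_not_flagged(self):
        """An ROI with high baseline that still fires transients is not filled."""
        dff_event = gaussian_event(60.0, 1.5, 1.0)
        traces = [trace_from(np.zeros_like(dff_event), f0=100.0, roi_id=i) for i in range(5)]
        bright_active = trace_from(dff_event, f0=1000.0, roi_id=5)
        traces.append(bright_active)
        metrics = [ca.detect_transients(tr) for tr in traces]
        flags = ca.classify_filled(traces, metrics)
        assert not flags[5]

    def test_needs_five_rois(self):
        tr = trace_from(np.zeros(200))
        with pytest.raises(ParameterError):
            ca.classify_filled([tr], [ca.detect_transients(tr)])


class TestGridStats:
    def test_uniform_image_all_excluded(self):
        mip = make_projection(np.full((40, 40), 5.0), pixel_size=1.0)
        cells = ca.grid_stats(mip, make_detections(np.empty((0, 2))))
        assert len(cells) == 16
        assert all(c.excluded for c in cells)
        assert len({c.median_neuropil for c in cells}) == 1

    def test_corner_detection_counted_once(self):
        """A centroid on the shared corner of four tiles is assigned to exactly one."""
        mip = make_projection(np.zeros((40, 40)), pixel_size=1.0)
        dets = make_detections([(20.0, 20.0)])  # exact tile corner in um
        cells = ca.grid_stats(mip, dets)
        assert sum(c.n_pi for c in cells) == 1

    def test_shared_gradient_positive_association(self):
        """PI density and neuropil brightness sharing a gradient correlate positively."""
        rng = np.random.default_rng(3)
        img = np.linspace(1, 10, 40)[:, None] * np.ones((1, 40)) + rng.normal(0, 0.1, (40, 40))
        ys = 40.0 - np.abs(rng.normal(0, 12, size=120)) % 40.0  # denser at high-y (bright) rows
        xs = rng.uniform(0, 40, size=120)
        cells = ca.grid_stats(make_projection(img, pixel_size=1.0), make_detections(np.column_stack([xs, ys])))
        included = [c for c in cells if not c.excluded]
        rho, _ = ca.correlate([c.median_neuropil_norm for c in included], [c.n_pi_norm for c in included])
        assert rho > 0.5


class TestCorrelate:
    def test_perfect_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert ca.correlate(x, x, "spearman")[0] == pytest.approx(1.0)
        assert ca.correlate(x, [-v for v in x], "pearson")[0] == pytest.approx(-1.0)

    def test_rank_example(self):
        """Hand-computed Spearman for one swapped pair of four: rho = 0.8."""
        rho, _ = ca.correlate([1, 2, 3, 4], [1, 3, 2, 4], "spearman")
        assert rho == pytest.approx(0.8)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            rho, p = ca.correlate([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho) and np.isnan(p)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            ca.correlate([1, 2], [1, 2, 3])


class TestFieldOrdering:
    def run_preset(self, name, seed=11):
        movie, truth = synthetic.generate_movie(synthetic.movie_preset(name, seed=seed))
        traces = ca.extract_traces(movie, ca.rois_from_table(truth.rois))
        metrics = [ca.detect_transients(tr) for tr in traces]
        flags = ca.classify_filled(traces, metrics)
        active = [m for m in metrics if not flags[m.roi_id]]
        return (
            float(np.mean([m.frequency for m in active])),
            float(np.mean([m.mean_amplitude for m in active])),
            float(np.mean([m.mean_auc for m in active])),
        )

    def test_deep_exceeds_superficial(self):
        """Deep-tissue preset dominates in frequency, amplitude and AUC."""
        sup = self.run_preset("superficial")
        deep = self.run_preset("deep")
        assert all(d > s for d, s in zip(deep, sup))
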