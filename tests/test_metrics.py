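import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redoximg.metrics import (
    CellTrace,
    compute_orr,
    compute_snr,
    extract_traces,
    orr_image,
    percent_change,
    photobleach_report,
    round_percent,
)
from redoximg.segmentation import LabelMask
from redoximg.simulate import simulate_timelapse
from redoximg.image_io import channel_stack_from_frames
from redoximg.simulate import meta_from_config

from conftest import small_noiseless_config, truth_label_mask

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestComputeOrr:
    @pytest.mark.parametrize(
        "a,b,expected", [(100, 100, 0.5), (100, 0, 1.0), (3, 1, 0.75)]
    )
    def test_worked_examples(self, a, b, expected):
        assert compute_orr(a, b) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_orr(0, 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_orr(-1, 5)

    @settings(max_examples=100, deadline=None)
    @given(a=positive, b=positive)
    def test_bounded_open_interval(self, a, b):
        assert 0.0 < compute_orr(a, b) < 1.0

    @settings(max_examples=100, deadline=None)
    @given(a=positive)
    def test_symmetry_half(self, a):
        assert compute_orr(a, a) == pytest.approx(0.5)

    @settings(max_examples=100, deadline=None)
    @given(a=positive, b=positive, gain=positive)
    def test_gain_invariance(self, a, b, gain):
        assert compute_orr(gain * a, gain * b) == pytest.approx(compute_orr(a, b))

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.floats(min_value=1e-2, max_value=1e4),
        b=st.floats(min_value=1e-2, max_value=1e4),
        bump=st.floats(min_value=1e-2, max_value=1e4),
    )
    def test_monotone_in_451(self, a, b, bump):
        # magnitudes kept comparable so strict monotonicity is resolvable in floats
        assert compute_orr(a + bump, b) > compute_orr(a, b)


class TestOrrImage:
    def test_uniform_images_half(self):
        img = np.full((8, 8), 100.0)
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        assert orr_image(img, img, mask) == pytest.approx(0.5)

    def test_brute_force_pixel_loop_oracle(self, rng):
        img_a = rng.uniform(1, 100, size=(20, 20))
        img_b = rng.uniform(1, 100, size=(20, 20))
        mask = rng.uniform(size=(20, 20)) > 0.5
        total_a = total_b = n = 0.0
        for i in range(20):
            for j in range(20):
                if mask[i, j]:
                    total_a += img_a[i, j]
                    total_b += img_b[i, j]
                    n += 1
        expected = (total_a / n) / (total_a / n + total_b / n)
        assert orr_image(img_a, img_b, mask) == pytest.approx(expected, rel=1e-12)

    def test_two_region_mask_selects_region(self):
        img_a = np.full((10, 10), 30.0)
        img_a[:5] = 70.0
        img_b = np.full((10, 10), 70.0)
        mask = np.zeros((10, 10), bool)
        mask[:5] = True
        assert orr_image(img_a, img_b, mask) == pytest.approx(0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            orr_image(np.ones((4, 4)), np.ones((4, 4)), np.zeros((4, 4), bool))


class TestPercentChange:
    def test_loss_convention_example(self):
        assert percent_change(100, 90, "loss") == pytest.approx(10.0)

    def test_signed_convention_printed_row_low_power(self):
        # printed 451-nm percent change at the lowest assessed power
        assert round_percent(percent_change(53.8, 54.0, "signed")) == 0.4

    def test_signed_convention_printed_row_high_power(self):
        assert round_percent(percent_change(65.0, 53.9, "signed")) == -17.1

    def test_nonpositive_initial_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0, 10)
        with pytest.raises(ValueError):
            percent_change(-5, 10)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            percent_change(10, 5, "relative")

    @settings(max_examples=100, deadline=None)
    @given(initial=positive, final=positive)
    def test_conventions_are_negatives(self, initial, final):
        loss = percent_change(initial, final, "loss")
        signed = percent_change(initial, final, "signed")
        assert signed == pytest.approx(-loss, abs=1e-9)


def _trace(m451, m560, hz=10.0):
    m451 = np.asarray(m451, float)
    return CellTrace(
        cell_id=1,
        mean_451=m451,
        mean_560=np.asarray(m560, float),
        time_s=np.arange(len(m451)) / hz,
        n_pixels=10,
    )


class TestPhotobleachReport:
    def test_constant_traces_zero_percent(self):
        tr = _trace(np.full(30, 80.0), np.full(30, 40.0))
        rep = photobleach_report(tr)
        for metric in ("451", "560", "orr"):
            assert rep.percent_loss[metric][0] == pytest.approx(0.0)
            assert rep.percent_signed[metric][0] == pytest.approx(0.0)

    def test_monoexponential_matches_closed_form(self):
        k, hz, n = 0.08, 10.0, 200
        t = np.arange(n) / hz
        tr = _trace(100 * np.exp(-k * t), np.full(n, 50.0), hz)
        rep = photobleach_report(tr)
        first = np.mean(100 * np.exp(-k * t[:10]))
        last = np.mean(100 * np.exp(-k * t[-10:]))
        expected = (first - last) / first * 100
        assert rep.percent_loss["451"][0] == pytest.approx(expected, rel=1e-12)

    def test_short_trace_rejected_with_required_length(self):
        tr = _trace(np.full(15, 10.0), np.full(15, 10.0))
        with pytest.raises(ValueError, match="20"):
            photobleach_report(tr, n_window=10)

    def test_window_means_are_plain_averages(self):
        vals = np.arange(1.0, 41.0)
        tr = _trace(vals, vals)
        rep = photobleach_report(tr, n_window=10)
        assert rep.initial_window_mean["451"][0] == pytest.approx(vals[:10].mean())
        assert rep.final_window_mean["451"][0] == pytest.approx(vals[-10:].mean())

    @settings(max_examples=50, deadline=None)
    @given(
        start=st.floats(min_value=10, max_value=1e4),
        decay=st.floats(min_value=0.01, max_value=0.5),
    )
    def test_decreasing_trace_positive_loss(self, start, decay):
        t = np.arange(40) / 10.0
        vals = start * np.exp(-decay * t)
        rep = photobleach_report(_trace(vals, np.full(40, start)))
        assert rep.percent_loss["451"][0] > 0

    def test_to_frame_tidy(self):
        tr = _trace(np.full(25, 10.0), np.full(25, 5.0))
        frame = photobleach_report(tr).to_frame()
        assert set(frame["metric"]) == {"451", "560", "orr"}
        assert len(frame) == 3


class TestComputeSnr:
    def _image(self):
        img = np.zeros((10, 10))
        img[:5] = 110.0  # signal
        img[5:] = np.linspace(8, 12, 50).reshape(5, 10)  # background
        signal = np.zeros((10, 10), bool)
        signal[:5] = True
        return img, signal, ~signal

    def test_contrast_definition(self):
        img, sig, bg = self._image()
        rep = compute_snr(img, sig, bg, "contrast")
        expected = (110.0 - img[bg].mean()) / img[bg].std(ddof=1)
        assert rep.snr == pytest.approx(expected)
        assert rep.definition == "contrast"

    def test_offset_invariance_of_contrast(self):
        img, sig, bg = self._image()
        a = compute_snr(img, sig, bg).snr
        b = compute_snr(img + 500.0, sig, bg).snr
        assert a == pytest.approx(b)

    def test_ratio_definition_not_offset_invariant(self):
        img, sig, bg = self._image()
        a = compute_snr(img, sig, bg, "ratio").snr
        assert a == pytest.approx(110.0 / img[bg].std(ddof=1))

    def test_poisson_background_brute_force_oracle(self, rng):
        img = rng.poisson(100.0, size=(40, 40)).astype(float)
        sig = np.zeros((40, 40), bool)
        sig[:10] = True
        img[sig] += 200.0
        bg = ~sig
        rep = compute_snr(img, sig, bg)
        sig_vals = [img[i, j] for i in range(40) for j in range(40) if sig[i, j]]
        bg_vals = np.array(
            [img[i, j] for i in range(40) for j in range(40) if bg[i, j]]
        )
        expected = (np.mean(sig_vals) - bg_vals.mean()) / bg_vals.std(ddof=1)
        assert rep.snr == pytest.approx(expected, rel=1e-12)

    def test_zero_background_variance_rejected(self):
        img = np.ones((6, 6))
        sig = np.zeros((6, 6), bool)
        sig[:3] = True
        with pytest.raises(ValueError, match="variance"):
            compute_snr(img, sig, ~sig)

    def test_overlapping_masks_rejected(self):
        img = np.ones((6, 6))
        m = np.ones((6, 6), bool)
        with pytest.raises(ValueError, match="disjoint"):
            compute_snr(img, m, m)


class TestExtractTraces:
    def test_single_pixel_roi_equals_pixel_series(self, constant_channel_stack):
        cs = constant_channel_stack
        cs.data_451[:, 3, 4] = np.arange(cs.n_frames) + 1.0
        labels = np.zeros(cs.frame_shape, int)
        labels[3, 4] = 1
        traces = extract_traces(cs, LabelMask(labels=labels, provenance={}))
        assert np.array_equal(traces[0].mean_451, cs.data_451[:, 3, 4])
        assert traces[0].n_pixels == 1

    def test_per_frame_loop_oracle(self, rng, meta):
        from redoximg.image_io import ChannelStack

        data_a = rng.uniform(1, 100, size=(6, 12, 12))
        data_b = rng.uniform(1, 100, size=(6, 12, 12))
        labels = np.zeros((12, 12), int)
        labels[2:6, 2:6] = 1
        labels[8:11, 8:11] = 2
        cs = ChannelStack(
            data_451=data_a,
            data_560=data_b,
            time_s=np.arange(6) / meta.frame_rate_hz,
            meta=meta,
        )
        traces = extract_traces(cs, LabelMask(labels=labels, provenance={}))
        for tr in traces:
            for frame in range(6):
                total = count = 0.0
                for i in range(12):
                    for j in range(12):
                        if labels[i, j] == tr.cell_id:
                            total += data_a[frame, i, j]
                            count += 1
                assert tr.mean_451[frame] == pytest.approx(total / count, rel=1e-12)

    def test_noiseless_simulator_equality(self, noiseless_run):
        cfg, stack, truth, cs = noiseless_run
        traces = extract_traces(cs, truth_label_mask(truth))
        for i, tr in enumerate(traces):
            assert np.allclose(tr.mean_451, truth.true_trace_451[i], rtol=1e-9)

    def test_zero_pixel_label_excluded_with_warning(self, constant_channel_stack):
        labels = np.zeros(constant_channel_stack.frame_shape, int)
        labels[1, 1] = 1
        labels[4, 4] = 3  # label 2 has no pixels
        lm = LabelMask(labels=labels, provenance={})
        with pytest.warns(UserWarning, match="label 2"):
            traces = extract_traces(constant_channel_stack, lm)
        assert [t.cell_id for t in traces] == [1, 3]

    def test_noisy_percent_within_monte_carlo_se(self):
        # small-scale repeat-seed check of the windowed percent estimator
        k = 0.05
        base = small_noiseless_config(
            n_cells=2, n_frames=120, frame_rate_hz=20.0, bleach_rate_451=k,
            shot_noise=True, read_noise_sd=2.0, quantize=True,
            fov_shape=(64, 96), cell_radius_px=(8.0, 11.0),
        )
        stack, truth0 = simulate_timelapse(base)
        lm = truth_label_mask(truth0)
        cs = channel_stack_from_frames(stack, meta_from_config(base))
        rep = photobleach_report(extract_traces(cs, lm))
        measured = rep.percent_loss["451"]
        # Monte-Carlo SE via distributionally exact ROI-sum replicates
        reps = []
        rng = np.random.default_rng(99)
        for _ in range(200):
            rep_p = []
            for c in range(2):
                n_px = (truth0.label_mask == c + 1).sum()
                lam = truth0.true_trace_451[c] * n_px
                trace = (
                    rng.poisson(lam) + rng.normal(0, 2.0 * np.sqrt(n_px), size=lam.shape)
                ) / n_px
                first, last = trace[:10].mean(), trace[-10:].mean()
                rep_p.append((first - last) / first * 100)
            reps.append(rep_p)
        reps = np.array(reps)
        se = reps.std(axis=0, ddof=1)
        truth_percent = truth0.true_bleach_percent["451"]
        assert np.all(np.abs(measured - truth_percent) <= 3 * se)
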