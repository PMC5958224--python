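import numpy as np
import pytest

from fluorpheno import imaging
from fluorpheno.fluorparams import extract_basic_signals, fv_fm, npq, phi_psii
from fluorpheno.fluorsim import (
    BANDS,
    DroughtPreset,
    NoiseModel,
    RosetteSpec,
    cohort_manifest,
    control_preset,
    generate_rosette,
    get_preset,
    make_truth,
    simulate_cohort,
    simulate_multicolor,
    simulate_stack,
)

from conftest import model_curves


def _preset(multipliers=None, edge_gradient=0.0, sd=0.0, name="test"):
    m = {k: 1.0 for k in ("fvfm_true", "npq_ss", "phi_ss", "BF", "GF", "RF", "IrF")}
    m.update(multipliers or {})
    return DroughtPreset(name=name, day=0, multipliers=m,
                         edge_gradient=edge_gradient, between_plant_sd=sd)


class TestGenerateRosette:
    def test_zero_leaves_empty_mask(self):
        mask, leaf_id, edge = generate_rosette(RosetteSpec(n_leaves=0))
        assert not mask.any() and not leaf_id.any()

    def test_deterministic(self):
        a = generate_rosette(RosetteSpec(n_leaves=10, seed=1, image_shape=(64, 64)))
        b = generate_rosette(RosetteSpec(n_leaves=10, seed=1, image_shape=(64, 64)))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_single_ellipse_area(self):
        # one leaf with fixed axes: pixel count close to pi*a*b
        spec = RosetteSpec(
            image_shape=(96, 96), n_leaves=1,
            leaf_length_px=(20, 20), leaf_width_px=(10, 10), seed=0,
        )
        mask, _, _ = generate_rosette(spec)
        assert mask.sum() == pytest.approx(np.pi * 20 * 10, rel=0.05)

    def test_leaf_ids_label_pixels(self):
        mask, leaf_id, _ = generate_rosette(RosetteSpec(seed=2))
        assert set(np.unique(leaf_id[mask])) <= set(range(1, 9))
        assert (leaf_id[~mask] == 0).all()

    def test_edge_distance_zero_outside_max_inside(self):
        mask, _, edge = generate_rosette(RosetteSpec(seed=3))
        assert (edge[~mask] == 0).all()
        assert edge[mask].min() >= 1.0  # boundary pixels are 1 px from background

    def test_oversized_leaf_raises(self):
        spec = RosetteSpec(image_shape=(32, 32), n_leaves=4,
                           leaf_length_px=(30, 30), leaf_width_px=(5, 5))
        with pytest.raises(ValueError, match="does not fit"):
            generate_rosette(spec)


class TestMakeTruth:
    def test_control_baseline_uniform(self, square_mask):
        truth = make_truth(square_mask, control_preset(between_plant_sd=0.0), seed=0)
        assert np.allclose(truth.fvfm_true[square_mask], 0.85)
        assert np.allclose(truth.npq_ss[square_mask], 1.2)
        assert np.allclose(truth.phi_ss[square_mask], 0.55)
        assert np.allclose(truth.fm_amp[square_mask], 1000.0)

    def test_multiplier_halves_phi(self, square_mask):
        truth = make_truth(square_mask, _preset({"phi_ss": 0.5}), seed=0)
        assert truth.mean("phi_ss") == pytest.approx(0.55 * 0.5)

    def test_edge_gradient_tip_to_midrib_factor(self):
        mask, _, edge = generate_rosette(RosetteSpec(seed=4, image_shape=(64, 64)))
        truth = make_truth(mask, _preset(edge_gradient=0.3), seed=0)
        vals = truth.npq_ss[mask]
        # edge pixels carry the (1 + g) factor, midrib pixels the baseline
        at_edge = vals[edge[mask] == edge[mask].min()]
        at_midrib = vals[edge[mask] == edge[mask].max()]
        ratio = at_edge.mean() / at_midrib.mean()
        expected = (1 + 0.3 * (1 - edge[mask].min() / edge[mask].max()))
        assert ratio == pytest.approx(expected, rel=1e-9)

    def test_between_plant_sd_varies_plants(self, square_mask):
        p = _preset(sd=0.1)
        t1 = make_truth(square_mask, p, seed=1)
        t2 = make_truth(square_mask, p, seed=2)
        assert t1.mean("phi_ss") != t2.mean("phi_ss")

    def test_maps_nonnegative_and_bounded(self, square_mask):
        truth = make_truth(square_mask, _preset({"fvfm_true": 2.0}, sd=0.3), seed=5)
        assert (truth.fvfm_true >= 0).all() and (truth.fvfm_true < 1).all()
        assert truth.phi0 <= truth.phi_ss[square_mask].min()


class TestSimulateStack:
    def test_fm_flash_peak_equals_fm(self, clean_stack, uniform_truth, protocol):
        ev = protocol.fm_flash
        in_win = (clean_stack.times_s >= ev.time_s) & (clean_stack.times_s < ev.end_s)
        peak = clean_stack.frames[in_win][:, uniform_truth.mask].max()
        assert peak == pytest.approx(1000.0, abs=1e-9)

    def test_ft_le_fmprime_le_fm_in_light(self, clean_stack, uniform_truth, protocol):
        lit = clean_stack.light_state == "actinic"
        vals = clean_stack.frames[lit][:, uniform_truth.mask]
        fm_prime, _ = model_curves(uniform_truth, protocol, clean_stack.times_s[lit])
        assert (vals <= fm_prime[:, None] + 1e-9).all()
        assert (fm_prime <= 1000.0 + 1e-9).all()

    def test_fmprime_converges_to_fm_over_1_plus_npq(self, square_mask, protocol):
        truth = make_truth(square_mask, _preset({"npq_ss": 1.0 / 1.2}), seed=0)
        assert truth.mean("npq_ss") == pytest.approx(1.0)
        stack = simulate_stack(truth, protocol, NoiseModel.none())
        # Fm' at the steady-state flash = Fm / (1 + 1.0) = Fm/2
        s = extract_basic_signals(imaging.extract_trace(stack, square_mask), protocol)
        assert s["Fm_Lss"] == pytest.approx(500.0, rel=1e-6)

    def test_kautsky_peak_shape(self, clean_trace, protocol):
        # Ft rises from Fo to a peak after light onset then declines
        lit = clean_trace.light_state == "actinic"
        t = clean_trace.times_s[lit]
        first_flash = protocol.saturating_flashes("light")[0].time_s
        pre = clean_trace.mean_counts[lit][t < first_flash]
        fo = 150.0
        assert pre.max() > 5 * fo
        assert pre[-1] < pre.max()

    def test_background_is_zero_without_noise(self, clean_stack, uniform_truth):
        assert np.all(clean_stack.frames[:, ~uniform_truth.mask] == 0)

    def test_empty_mask_raises(self, square_mask):
        truth = make_truth(square_mask, control_preset(between_plant_sd=0.0), seed=0)
        truth.mask[:] = False
        with pytest.raises(ValueError, match="empty"):
            simulate_stack(truth)

    def test_noise_deterministic_under_seed(self, uniform_truth, protocol):
        a = simulate_stack(uniform_truth, protocol, NoiseModel(seed=9))
        b = simulate_stack(uniform_truth, protocol, NoiseModel(seed=9))
        assert np.array_equal(a.frames, b.frames)


class TestSimulateMulticolor:
    def test_20_frames_uv(self, clean_multicolor):
        assert len(clean_multicolor) == 20
        assert (clean_multicolor.light_state == "uv").all()
        assert clean_multicolor.meta["bands"].count("BF") == 5

    def test_zero_noise_exposures_identical_to_band_em(self, clean_multicolor, uniform_truth):
        bands = np.asarray(clean_multicolor.meta["bands"])
        for band in BANDS:
            frames = clean_multicolor.frames[bands == band]
            assert np.allclose(frames, uniform_truth.band_em[band][None])

    def test_reproducible(self, uniform_truth):
        a = simulate_multicolor(uniform_truth, NoiseModel(seed=3))
        b = simulate_multicolor(uniform_truth, NoiseModel(seed=3))
        assert np.array_equal(a.frames, b.frames)


class TestSimulateCohort:
    def test_sizes_and_labels(self):
        samples = simulate_cohort(3, 2, "day7", seed=1)
        assert len(samples) == 5
        assert [s.label for s in samples] == [1, 1, 1, 2, 2]

    def test_empty_cohort(self):
        assert simulate_cohort(0, 0, "day7", seed=1) == []

    def test_negative_size_raises(self):
        with pytest.raises(ValueError):
            simulate_cohort(-1, 0, "day7")

    def test_same_seed_identical_manifest(self):
        a = cohort_manifest(simulate_cohort(2, 2, "day3", seed=7))
        b = cohort_manifest(simulate_cohort(2, 2, "day3", seed=7))
        assert a.equals(b)

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="unknown preset"):
            get_preset("day99")

    def test_aliases(self):
        assert get_preset("severe").name == "day7"
        assert get_preset("moderate").name == "day3"


class TestIdentifiabilityInvariants:
    def test_zero_noise_recovery(self, clean_signals, uniform_truth):
        # full extractor on a uniform zero-noise stack recovers the truth
        assert fv_fm(clean_signals) == pytest.approx(0.85, rel=1e-6)
        assert npq(clean_signals, "Lss") == pytest.approx(1.2, rel=1e-6)
        assert phi_psii(clean_signals, "Lss") == pytest.approx(0.55, rel=1e-6)

    def test_phi_multiplier_monotonicity(self, square_mask, protocol):
        extracted = []
        for mult in (1.0, 0.8, 0.6):
            truth = make_truth(square_mask, _preset({"phi_ss": mult}), seed=0)
            stack = simulate_stack(truth, protocol, NoiseModel.none())
            s = extract_basic_signals(imaging.extract_trace(stack, square_mask), protocol)
            extracted.append(phi_psii(s, "Lss"))
        assert extracted[0] > extracted[1] > extracted[2]

    def test_noise_sd_shrinks_with_mask_area(self, protocol):
        # law of large numbers: canopy-mean Fv/Fm varies less on a big ROI
        def sd_for(side, n_rep=6):
            mask = np.zeros((40, 40), dtype=bool)
            mask[2:2 + side, 2:2 + side] = True
            vals = []
            for seed in range(n_rep):
                truth = make_truth(mask, control_preset(between_plant_sd=0.0), seed=0)
                stack = simulate_stack(truth, protocol, NoiseModel(read_sd=8.0, shot_scale=2.0, seed=seed))
                s = extract_basic_signals(imaging.extract_trace(stack, mask), protocol)
                vals.append(fv_fm(s))
            return np.std(vals)

        assert sd_for(30) < sd_for(5)
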