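import dataclasses

import numpy as np
import pytest
from scipy.ndimage import maximum_filter

from cytophase.phase_optics import OpticalParams, phase_to_height
from cytophase.segmentation import SegmentationParams, segment_capture
from cytophase.synthetic_data import (
    ClassMorphology,
    MorphologyParams,
    SceneSpec,
    generate_capture,
    generate_cell_height,
    generate_labeled_dataset,
)

FIXED_SEG = SegmentationParams(threshold_method="fixed", fixed_threshold=0.15)


class TestCellMorphologies:
    def test_apoptotic_cells_taller_than_alive_at_matched_radius(self):
        # same body radius for both classes isolates the height-scale ordering
        morph = MorphologyParams(
            alive=dataclasses.replace(MorphologyParams().alive, body_radius_px=(6.5, 6.5)),
            apoptosis=dataclasses.replace(MorphologyParams().apoptosis, body_radius_px=(6.5, 6.5)),
        )
        taller = 0
        for seed in range(100):
            apo, _ = generate_cell_height("apoptosis", morph, np.random.default_rng(seed))
            alive, _ = generate_cell_height("alive", morph, np.random.default_rng(seed))
            taller += apo.max() > alive.max()
        assert taller == 100

    def test_necroptotic_footprint_larger_than_apoptotic(self):
        larger = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            _, area_necro = generate_cell_height("necroptosis", rng=rng)
            _, area_apo = generate_cell_height("apoptosis", rng=rng)
            larger += area_necro > area_apo
        assert larger == 100

    def test_necroptotic_cells_flatter_than_alive(self):
        flatter = 0
        for seed in range(100):
            necro, _ = generate_cell_height("necroptosis", rng=np.random.default_rng(seed))
            alive, _ = generate_cell_height("alive", rng=np.random.default_rng(seed))
            flatter += necro.max() < alive.max()
        assert flatter >= 95

    def test_zero_blebs_gives_smooth_single_peak(self):
        morph = MorphologyParams(
            apoptosis=dataclasses.replace(MorphologyParams().apoptosis, n_blebs=(0, 0))
        )
        patch, _ = generate_cell_height("apoptosis", morph, np.random.default_rng(4))
        # regional maxima: pixels equal to the 3x3 neighbourhood maximum
        interior = patch > 0
        peaks = (patch == maximum_filter(patch, size=3)) & interior & (patch == patch.max())
        regional = (patch == maximum_filter(patch, size=3)) & interior
        assert regional.sum() == 1

    def test_blebby_apoptotic_cell_has_multiple_peaks(self):
        patch, _ = generate_cell_height("apoptosis", rng=np.random.default_rng(4))
        regional = (patch == maximum_filter(patch, size=3)) & (patch > 0)
        assert regional.sum() >= 2

    def test_scale_factor_ordering_enforced(self):
        with pytest.raises(ValueError, match="order"):
            MorphologyParams(
                necroptosis=dataclasses.replace(
                    MorphologyParams().necroptosis, height_scale_factor=2.0
                )
            )

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            generate_cell_height("pyroptosis", rng=np.random.default_rng(0))


class TestCaptures:
    def test_planted_cell_count_recovered_without_noise(self):
        spec = SceneSpec(
            n_cells=20, noise_sd_rad=0.0, seed=3,
            class_mix={"alive": 0.5, "apoptosis": 0.25, "necroptosis": 0.25},
        )
        capture, annotations = generate_capture(spec, condition="alive")
        assert len(annotations) == 20
        from cytophase.segmentation import detect_cells

        assert len(detect_cells(capture, FIXED_SEG)) == 20

    def test_noise_only_capture_yields_no_crops(self):
        for seed in range(5):
            spec = SceneSpec(n_cells=0, noise_sd_rad=0.02, seed=seed, class_mix={"alive": 1.0})
            capture, annotations = generate_capture(spec, condition="alive")
            assert annotations == []
            assert segment_capture(capture, FIXED_SEG) == []

    def test_same_seed_bit_identical(self):
        spec = SceneSpec(n_cells=8, seed=21, class_mix={"apoptosis": 1.0})
        a, _ = generate_capture(spec, condition="apoptosis")
        b, _ = generate_capture(spec, condition="apoptosis")
        np.testing.assert_array_equal(a.phase, b.phase)

    def test_different_seeds_decorrelated_noise(self):
        specs = [SceneSpec(n_cells=0, noise_sd_rad=0.05, seed=s, class_mix={"alive": 1.0}) for s in (1, 2)]
        fields = [generate_capture(s, condition="alive")[0].phase.ravel() for s in specs]
        corr = np.corrcoef(fields[0], fields[1])[0, 1]
        assert abs(corr) < 0.02

    def test_class_mix_conserved_at_divisible_counts(self):
        spec = SceneSpec(
            n_cells=12, seed=5,
            class_mix={"alive": 0.5, "apoptosis": 0.25, "necroptosis": 0.25},
        )
        _, annotations = generate_capture(spec, condition="alive")
        counts = {c: sum(a.true_class == c for a in annotations) for c in ("alive", "apoptosis", "necroptosis")}
        assert counts == {"alive": 6, "apoptosis": 3, "necroptosis": 3}

    def test_min_separation_respected(self):
        spec = SceneSpec(n_cells=15, seed=9, min_separation_px=50, class_mix={"alive": 1.0})
        _, annotations = generate_capture(spec, condition="alive")
        centers = [a.centroid_rc for a in annotations]
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
                assert d >= 50

    def test_impossible_placement_raises(self):
        spec = SceneSpec(image_shape=(150, 150), n_cells=50, min_separation_px=60, seed=0, class_mix={"alive": 1.0})
        with pytest.raises(RuntimeError, match="place"):
            generate_capture(spec, condition="alive")

    def test_noiseless_capture_recovers_planted_heights(self):
        spec = SceneSpec(n_cells=6, noise_sd_rad=0.0, seed=13, class_mix={"necroptosis": 1.0})
        capture, annotations, canvas = generate_capture(spec, condition="necroptosis", return_height=True)
        recovered = phase_to_height(capture).height_um
        # float32 phase storage bounds the round trip, not the physics
        np.testing.assert_allclose(recovered, canvas, rtol=1e-6, atol=1e-6)


class TestLabeledDataset:
    def test_counts_and_balance(self):
        ds = generate_labeled_dataset(100, seed=1)
        assert len(ds) == 300
        assert ds.class_counts == {"alive": 100, "apoptosis": 100, "necroptosis": 100}
        assert all(c.true_class == c.condition.value for c in ds.crops)

    def test_every_crop_within_area_filter(self):
        ds = generate_labeled_dataset(60, seed=2)
        assert all(80 < c.area_px < 600 for c in ds.crops)

    def test_out_of_filter_morphology_warns(self):
        morph = MorphologyParams(
            apoptosis=dataclasses.replace(
                MorphologyParams().apoptosis, body_radius_px=(4.0, 5.6)
            )
        )
        with pytest.warns(UserWarning, match="area filter"):
            generate_labeled_dataset(40, morph=morph, seed=3)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            generate_labeled_dataset(0)
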