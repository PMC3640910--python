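"""Detection contracts: thresholding, conglomerate rule, reference area."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from agnor.detection import (
    DetectionParams,
    correct_count,
    detect_agnors,
    detect_case,
    estimate_reference_area,
)
from agnor.simulate import ImageScenario, generate_image_set


class TestCorrectCount:
    @pytest.mark.parametrize(
        "area,ref,kappa,expected",
        [
            (1.0, 1.0, 1.5, 1),  # equal to the reference
            (2.2, 1.0, 1.5, 2),  # 2.2x reference rounds to 2
            (0.4, 1.0, 1.5, 1),  # small particles never count as zero
            (1.5, 1.0, 1.5, 1),  # boundary: at kappa*ref still single
            (1.6, 1.0, 1.5, 2),  # just above kappa: floored at 2
            (3.5, 1.0, 1.5, 4),  # half rounds up
            (5.4, 1.0, 1.5, 5),
        ],
    )
    def test_examples(self, area, ref, kappa, expected):
        assert correct_count(area, ref, kappa) == expected

    @pytest.mark.parametrize("area,ref", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_nonpositive_rejected(self, area, ref):
        with pytest.raises(ValueError):
            correct_count(area, ref)

    @given(
        area=st.floats(0.01, 50.0),
        ref=st.floats(0.1, 5.0),
        kappa=st.floats(1.01, 3.0),
    )
    def test_count_at_least_one_and_monotone(self, area, ref, kappa):
        c = correct_count(area, ref, kappa)
        assert c >= 1
        assert correct_count(area * 1.5, ref, kappa) >= c
        if area > kappa * ref:
            assert c >= 2


class TestReferenceArea:
    def test_uniform_areas(self):
        assert estimate_reference_area([2.0, 2.0, 2.0]) == 2.0

    def test_conglomerate_excluded_from_reference(self):
        # {1,1,1,3} with kappa=1.5: the 3 is trimmed before the final median
        assert estimate_reference_area([1.0, 1.0, 1.0, 3.0], kappa=1.5) == 1.0

    def test_single_particle(self):
        assert estimate_reference_area([0.7]) == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_reference_area([])


class TestDetectAgnors:
    def test_two_disjoint_disks(self, circle_nucleus):
        _, mask, paint = circle_nucleus
        img = paint((18, 16, 3.0), (30, 30, 3.0))
        rec = detect_agnors(img, mask)
        assert rec.raw_count == 2
        expected = np.pi * (3 * 0.25) ** 2  # r = 3 px at 0.25 um/px
        for p in rec.particles:
            assert p.area_um2 == pytest.approx(expected, rel=0.15)
            assert not p.is_conglomerate

    def test_no_dark_pixels_gives_empty_list(self, circle_nucleus):
        img, mask, _ = circle_nucleus
        rec = detect_agnors(img, mask)
        assert rec.particles == []
        assert rec.corrected_count == 0

    def test_flat_nucleus_gives_empty_list(self, circle_nucleus):
        img, mask, _ = circle_nucleus
        rec = detect_agnors(np.full_like(img, 150), mask)
        assert rec.particles == []

    def test_merged_disks_flagged_as_conglomerate(self, circle_nucleus):
        # centre spacing 1.2 r -> one connected component whose area exceeds
        # kappa=1.5 times a lone reference disk
        _, mask, paint = circle_nucleus
        r = 3.0
        img = paint((17, 15, r), (17, 15 + 1.2 * r, r), (31, 30, r))
        lone = [p for p in detect_agnors(img, mask).particles]
        lone_area = min(p.area_um2 for p in lone)
        rec = detect_agnors(img, mask, reference_area_um2=lone_area)
        merged = max(rec.particles, key=lambda p: p.area_um2)
        assert rec.raw_count == 2
        assert merged.is_conglomerate
        assert merged.corrected_count == 2

    def test_empty_mask_rejected(self, circle_nucleus):
        img, mask, _ = circle_nucleus
        with pytest.raises(ValueError, match="empty"):
            detect_agnors(img, np.zeros_like(mask))

    def test_shape_mismatch_rejected(self, circle_nucleus):
        img, mask, _ = circle_nucleus
        with pytest.raises(ValueError, match="shape"):
            detect_agnors(img[:-1], mask)

    def test_central_particle_has_zero_d_norm(self, circle_nucleus):
        _, mask, paint = circle_nucleus
        img = paint((24, 24, 3.0))
        rec = detect_agnors(img, mask)
        assert rec.particles[0].d_norm == pytest.approx(0.0, abs=0.05)

    def test_peripheral_particle_has_high_d_norm(self, circle_nucleus):
        _, mask, paint = circle_nucleus
        img = paint((24, 24 + 12, 2.0))  # 12/16 of the radius out
        rec = detect_agnors(img, mask)
        assert rec.particles[0].d_norm == pytest.approx(12 / 16, abs=0.08)


@pytest.fixture(scope="module")
def field(recovery_scenario):
    imgs, masks, gt = generate_image_set(recovery_scenario, seed=3)
    return imgs[0], masks[0], gt


class TestDetectCase:
    def test_noise_free_counts_exact(self, field):
        img, labels, gt = field
        records = detect_case(img, labels)
        detected = {r.nucleus_id: r.corrected_count for r in records}
        assert detected == gt.counts_per_nucleus().to_dict()

    def test_corrected_counts_never_below_components(self, field):
        img, labels, _ = field
        for rec in detect_case(img, labels):
            assert rec.corrected_count >= rec.raw_count

    def test_translation_invariance(self, field):
        img, labels, _ = field
        img2 = np.pad(img, ((7, 0), (11, 0)), constant_values=205)
        lab2 = np.pad(labels, ((7, 0), (11, 0)), constant_values=0)
        a = detect_case(img, labels)
        b = detect_case(img2, lab2)
        for ra, rb in zip(a, b):
            assert ra.raw_count == rb.raw_count
            assert ra.corrected_count == rb.corrected_count
            for pa, pb in zip(ra.particles, rb.particles):
                assert pa.area_um2 == pytest.approx(pb.area_um2)
                assert pa.d_norm == pytest.approx(pb.d_norm, abs=1e-6)

    def test_relabeling_invariance(self, field):
        img, labels, _ = field
        relabeled = np.where(labels > 0, labels + 100, 0).astype(labels.dtype)
        a = detect_case(img, labels)
        b = detect_case(img, relabeled)
        assert [r.corrected_count for r in a] == [r.corrected_count for r in b]
        assert [r.nucleus_id + 100 for r in a] == [r.nucleus_id for r in b]

    def test_no_nuclei_rejected(self, field):
        img, labels, _ = field
        with pytest.raises(ValueError, match="no nuclei"):
            detect_case(img, np.zeros_like(labels))

    def test_noisy_empty_nuclei_stay_empty(self):
        # Otsu on a particle-free nucleus must not carve particles from noise
        sc = ImageScenario(
            n_nuclei=12,
            agnor_count_distribution=("categorical", {0: 1.0}),
            noise_sd=4.0,
        )
        imgs, masks, _ = generate_image_set(sc, seed=8)
        for rec in detect_case(imgs[0], masks[0]):
            assert rec.raw_count == 0


class TestDetectionParams:
    @pytest.mark.parametrize(
        "kw", [dict(kappa=1.0), dict(min_area_px=0), dict(calibration=-1), dict(threshold="mean")]
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            DetectionParams(**kw)

    def test_fixed_threshold(self, circle_nucleus):
        _, mask, paint = circle_nucleus
        img = paint((20, 20, 3.0))
        rec = detect_agnors(img, mask, DetectionParams(threshold=100.0))
        assert rec.raw_count == 1
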