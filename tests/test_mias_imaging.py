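"""PGM I/O, annotation parsing, and the preprocessing chain."""

import numpy as np
import pytest

from qigwo.mias_imaging import (
    AnnotationRecord,
    Mammogram,
    PgmFormatError,
    breast_mask,
    clahe,
    extract_patches,
    extract_roi,
    format_mias_annotations,
    median_filter,
    parse_mias_annotations,
    preprocess_corpus,
    random_normal_roi,
    read_pgm,
    write_pgm,
)
from qigwo.synthetic_data import PhantomSpec, make_phantom


class TestPgmIO:
    def test_minimal_ascii_pgm(self):
        mam = read_pgm(b"P2 2 2 255 0 1 2 3")
        assert mam.pixels.tolist() == [[0, 1], [2, 3]]
        assert mam.maxval == 255

    def test_comments_tolerated(self):
        mam = read_pgm(b"P2\n# a comment\n2 1\n# another\n255\n7 9")
        assert mam.pixels.tolist() == [[7, 9]]

    def test_binary_roundtrip_8bit(self, rng):
        pixels = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        mam = Mammogram(pixels=pixels, id="x", maxval=255)
        back = read_pgm(write_pgm(mam))
        assert np.array_equal(back.pixels, pixels)
        assert write_pgm(back) == write_pgm(mam)

    def test_binary_roundtrip_16bit(self, rng):
        pixels = rng.integers(0, 4096, (8, 8)).astype(np.uint16)
        mam = Mammogram(pixels=pixels, id="x", maxval=4095)
        back = read_pgm(write_pgm(mam))
        assert np.array_equal(back.pixels, pixels)

    def test_ascii_roundtrip(self, rng):
        pixels = rng.integers(0, 256, (4, 6)).astype(np.uint8)
        mam = Mammogram(pixels=pixels, maxval=255)
        back = read_pgm(write_pgm(mam, ascii_format=True))
        assert np.array_equal(back.pixels, pixels)

    def test_bad_magic(self):
        with pytest.raises(PgmFormatError, match="magic"):
            read_pgm(b"P7 2 2 255 0 0 0 0")

    def test_truncated_raster_reports_offset(self):
        data = write_pgm(Mammogram(np.zeros((4, 4), dtype=np.uint8)))
        with pytest.raises(PgmFormatError, match="byte offset"):
            read_pgm(data[:-3])


class TestAnnotations:
    def test_abnormal_record(self):
        recs = parse_mias_annotations("mdb001 G CIRC B 535 425 197\n")
        rec = recs[0]
        assert rec.reference == "mdb001"
        assert rec.tissue == "fatty-glandular"
        assert rec.abnormality == "CIRC"
        assert rec.severity == "benign"
        assert rec.center == (535, 425)
        assert rec.radius == 197

    def test_normal_record_has_no_center(self):
        rec = parse_mias_annotations("mdb003 D NORM\n")[0]
        assert rec.abnormality == "NORM"
        assert rec.center is None and rec.radius is None
        with pytest.raises(ValueError):
            rec.center_rowcol(1024)

    def test_empty_input(self):
        assert parse_mias_annotations("") == []

    def test_unknown_code_with_line_number(self):
        with pytest.raises(ValueError, match="line 2"):
            parse_mias_annotations("mdb001 G NORM\nmdb002 G BLOB B 1 2 3\n")

    def test_roundtrip_through_formatter(self):
        text = "mdb001 G CIRC B 535 425 197\nmdb002 D NORM\n"
        assert format_mias_annotations(parse_mias_annotations(text)) == text

    def test_coordinate_conversion(self):
        rec = AnnotationRecord("r", "fatty", "CIRC", "benign", center=(10, 20), radius=5)
        assert rec.center_rowcol(100) == (79, 10)  # row = 100 - 1 - 20


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((9, 9), 7, dtype=np.uint8)
        assert np.array_equal(median_filter(img, 3), img)

    def test_window_one_is_identity(self, rng):
        img = rng.integers(0, 255, (8, 8)).astype(np.uint8)
        assert np.array_equal(median_filter(img, 1), img)

    def test_impulse_removed(self):
        img = np.zeros((7, 7), dtype=np.uint8)
        img[3, 3] = 255
        assert median_filter(img, 3)[3, 3] == 0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_filter(np.zeros((4, 4)), 2)

    def test_near_idempotent_on_binary_images(self, rng):
        # structured binary image: thresholded smooth random field
        from scipy import ndimage

        field = ndimage.gaussian_filter(rng.random((64, 64)), sigma=2.0)
        img = (field > np.median(field)).astype(np.uint8) * 255
        once = median_filter(median_filter(img, 3), 3)
        twice = median_filter(once, 3)
        assert np.mean(once != twice) < 0.02


class TestClahe:
    def test_constant_maps_to_constant(self):
        img = np.full((64, 64), 120, dtype=np.uint8)
        assert np.array_equal(clahe(img), img)

    def test_two_level_ordering_preserved(self):
        img = np.full((64, 64), 200, dtype=np.uint8)
        img[:32, :32] = 50
        out = clahe(img)
        dark = out[:32, :32].mean()
        bright = out[32:, 32:].mean()
        assert dark < bright

    def test_range_contract(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        out = clahe(img)
        assert out.dtype == np.uint8
        assert out.min() >= 0 and out.max() <= 255

    def test_invalid_clip(self):
        with pytest.raises(ValueError):
            clahe(np.zeros((8, 8), dtype=np.uint8), clip_limit=0.0)


class TestRoiExtraction:
    def test_center_window_symmetric(self):
        img = np.arange(300 * 300).reshape(300, 300)
        roi = extract_roi(img, (150, 150), size=120, origin="rowcol")
        assert roi.pixels.shape == (120, 120)
        assert roi.pixels[60, 60] == img[150, 150]

    def test_corner_center_shifts_window(self):
        img = np.zeros((1024, 1024), dtype=np.uint8)
        roi = extract_roi(img, (10, 10), size=120, origin="rowcol")
        assert roi.pixels.shape == (120, 120)

    def test_bottom_left_origin_conversion(self):
        img = np.zeros((200, 200), dtype=np.uint8)
        img[150, 40] = 255  # y = 200 - 1 - 150 = 49
        roi = extract_roi(img, (40, 49), size=20)
        assert roi.pixels.max() == 255
        assert roi.center == (150, 40)

    def test_outside_center_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            extract_roi(np.zeros((50, 50)), (60, 60), size=20, origin="rowcol")

    def test_patches_are_inside_roi(self, rng):
        roi = extract_roi(
            rng.integers(0, 255, (256, 256)).astype(np.uint8),
            (128, 128), size=120, origin="rowcol", label="normal",
        )
        patches = extract_patches(roi, patch_size=72, count=5, rng=rng)
        assert all(p.pixels.shape == (72, 72) for p in patches)
        assert all(p.label == "normal" for p in patches)


class TestRandomNormalRoi:
    def test_fixed_seed_identical_window(self, tiny_corpus):
        images, _ = tiny_corpus
        img = next(iter(images.values())).pixels
        a = random_normal_roi(img, 120, np.random.default_rng(5))
        b = random_normal_roi(img, 120, np.random.default_rng(5))
        assert np.array_equal(a.pixels, b.pixels)

    def test_windows_inside_bounds(self, tiny_corpus, rng):
        images, _ = tiny_corpus
        img = next(iter(images.values())).pixels
        for _ in range(200):
            roi = random_normal_roi(img, 64, rng)
            assert roi.pixels.shape == (64, 64)

    def test_draws_overlap_breast_mask(self, tiny_corpus, rng):
        images, _ = tiny_corpus
        img = next(iter(images.values())).pixels
        mask = breast_mask(img)
        hits = 0
        n = 200
        for _ in range(n):
            roi = random_normal_roi(img, 64, rng)
            r, c = roi.center
            hits += mask[r, c]
        assert hits / n >= 0.95


class TestPreprocessCorpus:
    def test_counts_and_sizes(self, tiny_corpus):
        from qigwo.mias_imaging import parse_mias_annotations

        images, annotation_text = tiny_corpus
        records = parse_mias_annotations(annotation_text)
        result = preprocess_corpus(images, records, roi_size=120, patch_size=72, seed=0)
        assert result.counts == {"normal": 6, "benign": 3, "malignant": 3}
        assert len(result.rois) == 12
        assert all(r.pixels.shape == (120, 120) for r in result.rois)
        assert all(p.pixels.shape == (72, 72) for p in result.patches)

    def test_abnormal_roi_centered_on_annotation(self, tiny_corpus):
        from qigwo.mias_imaging import parse_mias_annotations

        images, annotation_text = tiny_corpus
        records = [
            r for r in parse_mias_annotations(annotation_text) if r.abnormality != "NORM"
        ]
        result = preprocess_corpus(images, records, seed=0)
        for rec, roi in zip(records, result.rois):
            assert roi.center == rec.center_rowcol(256)
            # the blob is bright: ROI center should exceed the background
            assert roi.pixels[60, 60] > np.median(roi.pixels)

    def test_missing_image_is_corpus_error(self, tiny_corpus):
        images, annotation_text = tiny_corpus
        from qigwo.mias_imaging import parse_mias_annotations

        records = parse_mias_annotations(annotation_text)
        with pytest.raises(KeyError, match="missing image"):
            preprocess_corpus({}, records[:1])

    def test_deterministic_under_seed(self, tiny_corpus):
        from qigwo.mias_imaging import parse_mias_annotations

        images, annotation_text = tiny_corpus
        records = parse_mias_annotations(annotation_text)
        a = preprocess_corpus(images, records, seed=9)
        b = preprocess_corpus(images, records, seed=9)
        for pa, pb in zip(a.patches, b.patches):
            assert np.array_equal(pa.pixels, pb.pixels)
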