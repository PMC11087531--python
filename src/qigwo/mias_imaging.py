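"""Mammogram I/O and the ROI preprocessing chain.

Covers PGM (portable graymap) reading and writing, MIAS-style annotation
parsing, and the preprocessing pipeline used ahead of classification:
median filtering -> contrast-limited adaptive histogram equalization
(CLAHE) -> fixed-size ROI extraction (120 x 120 around the annotated
abnormality center, or a random in-breast window for normal images) ->
random 72 x 72 patch extraction per ROI.

Coordinate convention: MIAS annotation (x, y) pairs use a bottom-left
origin.  Records keep the raw values; the conversion to array (row, col)
indices, ``row = height - 1 - y``, ``col = x``, happens where the image
height is known (see :meth:`AnnotationRecord.center_rowcol`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import exposure, filters, measure

__all__ = [
    "Mammogram",
    "AnnotationRecord",
    "RoiPatch",
    "PgmFormatError",
    "read_pgm",
    "write_pgm",
    "parse_mias_annotations",
    "format_mias_annotations",
    "median_filter",
    "clahe",
    "extract_roi",
    "breast_mask",
    "random_normal_roi",
    "extract_patches",
    "preprocess_corpus",
    "patches_to_feature_table",
]

TISSUE_CODES = {"F": "fatty", "G": "fatty-glandular", "D": "dense-glandular"}
ABNORMALITY_CODES = ("CALC", "CIRC", "SPIC", "MISC", "ARCH", "ASYM", "NORM")
SEVERITY_CODES = {"B": "benign", "M": "malignant"}


@dataclass
class Mammogram:
    """Grayscale image with its reference id and header max value."""

    pixels: np.ndarray
    id: str = ""
    maxval: int = 255

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("mammogram pixels must be a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


class PgmFormatError(ValueError):
    """Malformed PGM data; carries the byte offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (byte offset {offset})")
        self.offset = offset


def _read_header_tokens(data: bytes, count: int, start: int) -> tuple[list[bytes], int]:
    """Read whitespace-separated header tokens, skipping '#' comments."""
    tokens: list[bytes] = []
    pos = start
    n = len(data)
    while len(tokens) < count:
        while pos < n and data[pos : pos + 1].isspace():
            pos += 1
        if pos < n and data[pos : pos + 1] == b"#":
            while pos < n and data[pos : pos + 1] != b"\n":
                pos += 1
            continue
        if pos >= n:
            raise PgmFormatError("truncated header", pos)
        tok_start = pos
        while pos < n and not data[pos : pos + 1].isspace() and data[pos : pos + 1] != b"#":
            pos += 1
        tokens.append(data[tok_start:pos])
    return tokens, pos


def read_pgm(data: bytes, id: str = "") -> Mammogram:
    """Parse P2 (ASCII) or P5 (binary) PGM bytes.

    Comments are tolerated anywhere in the header; 16-bit rasters (maxval >
    255) use big-endian byte order per the format specification.
    """
    if isinstance(data, str):
        data = data.encode("ascii")
    if len(data) < 2:
        raise PgmFormatError("not a PGM stream", 0)
    magic = data[:2]
    if magic not in (b"P2", b"P5"):
        raise PgmFormatError(f"unsupported magic {magic!r}; expected P2 or P5", 0)

    tokens, pos = _read_header_tokens(data, 3, 2)
    try:
        width, height, maxval = (int(t) for t in tokens)
    except ValueError:
        raise PgmFormatError(f"non-integer header field in {tokens!r}", pos) from None
    if width < 1 or height < 1 or not 0 < maxval < 65536:
        raise PgmFormatError(
            f"invalid header values width={width} height={height} maxval={maxval}", pos
        )

    if magic == b"P5":
        pos += 1  # exactly one whitespace byte after maxval
        bytes_per = 2 if maxval > 255 else 1
        expected = width * height * bytes_per
        raster = data[pos : pos + expected]
        if len(raster) < expected:
            raise PgmFormatError(
                f"truncated raster: expected {expected} bytes, got {len(raster)}",
                pos + len(raster),
            )
        dtype = ">u2" if bytes_per == 2 else np.uint8
        pixels = np.frombuffer(raster, dtype=dtype).reshape(height, width)
        pixels = pixels.astype(np.uint16 if bytes_per == 2 else np.uint8)
    else:
        text = data[pos:]
        try:
            values = np.array(text.split(), dtype=int)
        except ValueError:
            raise PgmFormatError("non-integer sample in ASCII raster", pos) from None
        if values.size != width * height:
            raise PgmFormatError(
                f"expected {width * height} samples, got {values.size}", pos
            )
        dtype = np.uint16 if maxval > 255 else np.uint8
        pixels = values.reshape(height, width).astype(dtype)

    if pixels.max(initial=0) > maxval:
        raise PgmFormatError("sample exceeds declared maxval", pos)
    return Mammogram(pixels=pixels, id=id, maxval=maxval)


def write_pgm(image: Mammogram, ascii_format: bool = False) -> bytes:
    """Serialize to P5 (default) or P2; P5 round-trips bit-exactly."""
    h, w = image.shape
    header = f"{'P2' if ascii_format else 'P5'}\n{w} {h}\n{image.maxval}\n".encode("ascii")
    if ascii_format:
        body = "\n".join(" ".join(str(int(v)) for v in row) for row in image.pixels)
        return header + body.encode("ascii") + b"\n"
    dtype = ">u2" if image.maxval > 255 else np.uint8
    return header + np.ascontiguousarray(image.pixels.astype(dtype)).tobytes()


@dataclass(frozen=True)
class AnnotationRecord:
    """One MIAS annotation row.

    ``center`` holds the raw annotation (x, y) in the bottom-left-origin
    convention; NORM records carry neither center nor radius.
    """

    reference: str
    tissue: str
    abnormality: str
    severity: str | None = None
    center: tuple[int, int] | None = None
    radius: int | None = None

    @property
    def label(self) -> str:
        return self.severity if self.severity else "normal"

    def center_rowcol(self, height: int) -> tuple[int, int]:
        """Convert the annotation center to array (row, col) indices."""
        if self.center is None:
            raise ValueError(f"record {self.reference} has no center")
        x, y = self.center
        return height - 1 - y, x


def parse_mias_annotations(text: str) -> list[AnnotationRecord]:
    """Parse MIAS-format annotation text.

    Rows are whitespace-delimited: reference, tissue code (F/G/D),
    abnormality code, then for abnormal rows severity (B/M), x, y, radius.
    """
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected at least 3 fields, got {len(fields)}")
        reference, tissue_code, abnormality = fields[0], fields[1], fields[2]
        if abnormality not in ABNORMALITY_CODES:
            raise ValueError(
                f"line {lineno}: unknown abnormality code {abnormality!r}"
            )
        tissue = TISSUE_CODES.get(tissue_code, tissue_code)
        if abnormality == "NORM":
            records.append(AnnotationRecord(reference, tissue, abnormality))
            continue
        if len(fields) < 7:
            raise ValueError(
                f"line {lineno}: abnormal record needs severity, x, y, radius"
            )
        severity = SEVERITY_CODES.get(fields[3])
        if severity is None:
            raise ValueError(f"line {lineno}: unknown severity code {fields[3]!r}")
        x, y, radius = int(fields[4]), int(fields[5]), int(fields[6])
        records.append(
            AnnotationRecord(reference, tissue, abnormality, severity, (x, y), radius)
        )
    return records


def format_mias_annotations(records: Iterable[AnnotationRecord]) -> str:
    """Inverse of :func:`parse_mias_annotations`."""
    tissue_rev = {v: k for k, v in TISSUE_CODES.items()}
    severity_rev = {v: k for k, v in SEVERITY_CODES.items()}
    lines = []
    for rec in records:
        tissue = tissue_rev.get(rec.tissue, rec.tissue)
        if rec.abnormality == "NORM":
            lines.append(f"{rec.reference} {tissue} NORM")
        else:
            sev = severity_rev[rec.severity]
            x, y = rec.center
            lines.append(
                f"{rec.reference} {tissue} {rec.abnormality} {sev} {x} {y} {rec.radius}"
            )
    return "\n".join(lines) + "\n"


@dataclass
class RoiPatch:
    """Fixed-size grayscale window with its class label and provenance."""

    pixels: np.ndarray
    label: str
    source: str = ""
    center: tuple[int, int] | None = None  # (row, col) in the source image

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def median_filter(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Square median filter with reflective edge handling."""
    if window < 1 or window % 2 == 0:
        raise ValueError("median filter window must be an odd integer >= 1")
    image = np.asarray(image)
    if window == 1:
        return image.copy()
    return ndimage.median_filter(image, size=window, mode="reflect")


def clahe(
    image: np.ndarray,
    clip_limit: float = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
    maxval: int | None = None,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    ``clip_limit`` follows the histogram-clip-factor convention (typical
    values 1-4 relative to a uniform histogram) and is converted internally
    to the fraction expected by scikit-image (clip / 256 bins).  Output is
    rescaled to the input's intensity range and dtype; constant images pass
    through unchanged.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    image = np.asarray(image)
    if maxval is None:
        maxval = 65535 if image.dtype == np.uint16 else 255
    if image.min() == image.max():  # degenerate: histogram is a single bin
        return image.copy()
    rows, cols = tile_grid
    kernel = (max(image.shape[0] // rows, 1), max(image.shape[1] // cols, 1))
    out = exposure.equalize_adapthist(
        image.astype(float) / maxval,
        kernel_size=kernel,
        clip_limit=min(clip_limit / 256.0, 1.0),
    )
    return np.clip(np.round(out * maxval), 0, maxval).astype(image.dtype)


def _clamped_window(center_rc: tuple[int, int], size: int, shape: tuple[int, int]) -> tuple[int, int]:
    """Top-left of a full-size window centered at center_rc, shifted inward
    at borders so the output is always size x size."""
    r0 = int(center_rc[0]) - size // 2
    c0 = int(center_rc[1]) - size // 2
    r0 = min(max(r0, 0), shape[0] - size)
    c0 = min(max(c0, 0), shape[1] - size)
    return r0, c0


def extract_roi(
    image: np.ndarray,
    center: tuple[int, int],
    size: int = 120,
    label: str = "",
    source: str = "",
    origin: str = "bottom-left",
) -> RoiPatch:
    """Square ROI around an annotation center; always full-size.

    ``center`` is the annotation (x, y) pair; with the default bottom-left
    origin it is converted via row = height - 1 - y, col = x.  Pass
    ``origin="rowcol"`` for pre-converted (row, col) indices.  Windows
    within size/2 of a border are shifted, not padded.
    """
    image = np.asarray(image)
    h, w = image.shape
    if origin == "bottom-left":
        x, y = center
        rc = (h - 1 - int(y), int(x))
    elif origin == "rowcol":
        rc = (int(center[0]), int(center[1]))
    else:
        raise ValueError("origin must be 'bottom-left' or 'rowcol'")
    if not (0 <= rc[0] < h and 0 <= rc[1] < w):
        raise ValueError(f"center {rc} (row, col) outside image of shape {image.shape}")
    if size > min(h, w):
        raise ValueError(f"ROI size {size} exceeds image dimensions {image.shape}")
    r0, c0 = _clamped_window(rc, size, image.shape)
    return RoiPatch(
        pixels=image[r0 : r0 + size, c0 : c0 + size].copy(),
        label=label,
        source=source,
        center=rc,
    )


def breast_mask(image: np.ndarray) -> np.ndarray:
    """Foreground (breast) mask: Otsu threshold on the median-filtered
    image, keeping the largest connected component."""
    smoothed = median_filter(np.asarray(image), 3)
    thresh = filters.threshold_otsu(smoothed)
    fg = smoothed > thresh
    if not fg.any():
        return np.ones_like(fg, dtype=bool)
    labeled = measure.label(fg)
    counts = np.bincount(labeled.ravel())
    counts[0] = 0
    return labeled == np.argmax(counts)


def random_normal_roi(
    image: np.ndarray,
    size: int = 120,
    rng: np.random.Generator | None = None,
    label: str = "normal",
    source: str = "",
) -> RoiPatch:
    """Random full-size window centered on a uniformly drawn breast pixel."""
    rng = rng if rng is not None else np.random.default_rng()
    image = np.asarray(image)
    if size > min(image.shape):
        raise ValueError(f"ROI size {size} exceeds image dimensions {image.shape}")
    mask = breast_mask(image)
    candidates = np.flatnonzero(mask)
    pick = int(rng.integers(candidates.size))
    rc = np.unravel_index(candidates[pick], image.shape)
    r0, c0 = _clamped_window((int(rc[0]), int(rc[1])), size, image.shape)
    return RoiPatch(
        pixels=image[r0 : r0 + size, c0 : c0 + size].copy(),
        label=label,
        source=source,
        center=(int(rc[0]), int(rc[1])),
    )


def extract_patches(
    roi: RoiPatch, patch_size: int = 72, count: int = 1, rng: np.random.Generator | None = None
) -> list[RoiPatch]:
    """Randomly placed square patches fully inside the ROI."""
    rng = rng if rng is not None else np.random.default_rng()
    span = roi.pixels.shape[0] - patch_size
    if span < 0:
        raise ValueError(f"patch size {patch_size} exceeds ROI size {roi.pixels.shape[0]}")
    patches = []
    for _ in range(count):
        r0 = int(rng.integers(span + 1))
        c0 = int(rng.integers(span + 1))
        patches.append(
            RoiPatch(
                pixels=roi.pixels[r0 : r0 + patch_size, c0 : c0 + patch_size].copy(),
                label=roi.label,
                source=roi.source,
                center=roi.center,
            )
        )
    return patches


@dataclass
class CorpusResult:
    """Preprocessing output: per-annotation ROIs, patches and class counts."""

    rois: list[RoiPatch]
    patches: list[RoiPatch]
    counts: dict[str, int] = field(default_factory=dict)


def preprocess_corpus(
    images: Mapping[str, Mammogram],
    annotations: Sequence[AnnotationRecord],
    roi_size: int = 120,
    patch_size: int = 72,
    patches_per_roi: int = 1,
    median_window: int = 3,
    clahe_clip: float = 2.0,
    clahe_tiles: tuple[int, int] = (8, 8),
    seed: int = 0,
) -> CorpusResult:
    """Run the full chain over a corpus: median -> CLAHE -> ROI -> patches.

    Abnormal ROIs are centered on their annotation (after coordinate
    conversion); normal ROIs are drawn at a random in-breast center.  One
    ROI per annotation record; missing images are a corpus error.
    """
    rng = np.random.default_rng(seed)
    rois: list[RoiPatch] = []
    patches: list[RoiPatch] = []
    counts: dict[str, int] = {}
    for rec in annotations:
        if rec.reference not in images:
            raise KeyError(f"annotation {rec.reference} references a missing image")
        mam = images[rec.reference]
        enhanced = clahe(
            median_filter(mam.pixels, median_window),
            clip_limit=clahe_clip,
            tile_grid=clahe_tiles,
            maxval=mam.maxval,
        )
        if rec.abnormality == "NORM":
            roi = random_normal_roi(enhanced, roi_size, rng, source=rec.reference)
        else:
            rc = rec.center_rowcol(enhanced.shape[0])
            roi = extract_roi(
                enhanced, rc, roi_size, label=rec.label, source=rec.reference,
                origin="rowcol",
            )
        counts[roi.label] = counts.get(roi.label, 0) + 1
        rois.append(roi)
        patches.extend(extract_patches(roi, patch_size, patches_per_roi, rng))
    return CorpusResult(rois=rois, patches=patches, counts=counts)


def patches_to_feature_table(patches: Sequence[RoiPatch]) -> tuple[np.ndarray, np.ndarray]:
    """Flatten patches into per-patch min-max normalized feature rows."""
    rows = []
    labels = []
    for p in patches:
        v = p.pixels.astype(float).ravel()
        lo, hi = v.min(), v.max()
        rows.append((v - lo) / (hi - lo) if hi > lo else np.zeros_like(v))
        labels.append(p.label)
    return np.asarray(rows), np.asarray(labels)
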