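"""Synthetic mammogram phantoms and feature tables with known structure.

The phantom generator emulates the structure of a MIAS-style screening
corpus -- grayscale PGM-compatible images with an annotation file carrying
reference id, tissue code, abnormality class, severity and, for abnormal
images, the lesion center and radius -- without attempting radiographic
realism.  A phantom is a noisy low-intensity breast disk; benign lesions
add a radially symmetric Gaussian blob (dense, well-demarcated, roughly
spherical masses), while malignant lesions star-deform the same blob with
angular spikes and boundary jitter (irregular, spiculated masses).  The
geometric contrast (high vs. low circularity of the half-maximum contour)
is what downstream shape-sensitive code exercises.

The feature-table generator emits class-conditional Gaussian features with
a known informative subset, supporting selection-recovery experiments.
All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mias_imaging import AnnotationRecord, Mammogram, format_mias_annotations

__all__ = [
    "PhantomSpec",
    "FeatureTableSpec",
    "make_phantom",
    "make_mias_like_corpus",
    "make_feature_table",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom corpus parameters.

    Defaults mirror the MIAS corpus composition (207 normal / 63 benign /
    52 malignant, 1024 x 1024 pixels); tests and examples typically pass
    ``image_size=256`` to stay desk-scale.  ``noise_sigma`` and intensities
    are on the 8-bit [0, 255] scale.
    """

    counts: tuple[int, int, int] = (207, 63, 52)  # normal, benign, malignant
    image_size: int = 1024
    noise_sigma: float = 5.0
    background_level: float = 80.0
    blob_intensity: float = 120.0
    blob_radius_frac: float = 0.06  # lesion radius as a fraction of image size
    spiculation_spikes: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("class counts must be non-negative")
        if self.image_size < 8 * max(int(self.blob_radius_frac * self.image_size), 1):
            raise ValueError("image_size must be at least 8x the blob radius")
        if self.spiculation_spikes < 1:
            raise ValueError("need at least one spiculation spike")


def _breast_disk(size: int) -> tuple[np.ndarray, tuple[float, float], float]:
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    center = (size / 2.0, size / 2.0)
    radius = 0.42 * size
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return mask, center, radius


def make_phantom(
    class_label: str, spec: PhantomSpec, rng: np.random.Generator, reference: str = "syn000"
) -> tuple[Mammogram, AnnotationRecord]:
    """One phantom image plus its annotation record.

    ``class_label`` is normal, benign or malignant.  Abnormal annotations
    record the true lesion center (bottom-left-origin x, y) and the
    half-maximum radius of the blob.
    """
    if class_label not in ("normal", "benign", "malignant"):
        raise ValueError(f"unknown class {class_label!r}")
    size = spec.image_size
    disk, center, disk_radius = _breast_disk(size)

    image = np.full((size, size), 5.0)
    image[disk] = spec.background_level
    image += rng.normal(0.0, spec.noise_sigma, (size, size))

    tissue = ("fatty", "fatty-glandular", "dense-glandular")[int(rng.integers(3))]
    if class_label == "normal":
        pixels = np.clip(np.round(image), 0, 255).astype(np.uint8)
        return (
            Mammogram(pixels=pixels, id=reference, maxval=255),
            AnnotationRecord(reference, tissue, "NORM"),
        )

    blob_radius = spec.blob_radius_frac * size
    sigma_b = blob_radius / 2.0
    # lesion center well inside the breast disk so the blob never leaks out
    angle = rng.uniform(0.0, 2.0 * np.pi)
    dist = rng.uniform(0.0, 0.5 * disk_radius)
    cr = center[0] + dist * np.sin(angle)
    cc_ = center[1] + dist * np.cos(angle)

    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    dr, dc = rr - cr, cc - cc_
    r = np.hypot(dr, dc)

    if class_label == "benign":
        blob = spec.blob_intensity * np.exp(-(r**2) / (2.0 * sigma_b**2))
    else:
        # star-shaped deformation: k angular spikes plus boundary jitter
        phi = np.arctan2(dr, dc)
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        k = spec.spiculation_spikes
        spikes = (0.5 + 0.5 * np.cos(k * (phi - phi0))) ** 3
        jitter = 0.15 * np.sin((2 * k + 1) * phi + rng.uniform(0.0, 2.0 * np.pi))
        scale = 1.0 + 0.9 * spikes + jitter
        blob = spec.blob_intensity * np.exp(-((r / scale) ** 2) / (2.0 * sigma_b**2))

    image += blob
    pixels = np.clip(np.round(image), 0, 255).astype(np.uint8)
    half_max_radius = int(round(sigma_b * np.sqrt(2.0 * np.log(2.0))))
    x = int(round(cc_))
    y = int(size - 1 - round(cr))
    severity = "benign" if class_label == "benign" else "malignant"
    abnormality = "CIRC" if class_label == "benign" else "SPIC"
    return (
        Mammogram(pixels=pixels, id=reference, maxval=255),
        AnnotationRecord(reference, tissue, abnormality, severity, (x, y), half_max_radius),
    )


def make_mias_like_corpus(spec: PhantomSpec) -> tuple[dict[str, Mammogram], str]:
    """Full phantom corpus: images keyed by reference + annotation text.

    The annotation text round-trips through
    :func:`qigwo.mias_imaging.parse_mias_annotations` with exact centers.
    """
    rng = np.random.default_rng(spec.seed)
    images: dict[str, Mammogram] = {}
    records = []
    labels = (
        ["normal"] * spec.counts[0]
        + ["benign"] * spec.counts[1]
        + ["malignant"] * spec.counts[2]
    )
    for i, label in enumerate(labels, start=1):
        ref = f"syn{i:03d}"
        mam, rec = make_phantom(label, spec, rng, reference=ref)
        images[ref] = mam
        records.append(rec)
    return images, format_mias_annotations(records)


@dataclass(frozen=True)
class FeatureTableSpec:
    """Class-conditional Gaussian feature table with a known signal subset.

    Informative features separate the two classes by ``mean_shift *
    noise_sigma``; the rest are identically distributed noise.
    """

    n_samples_per_class: int = 150
    total_features: int = 30
    informative: int = 5
    mean_shift: float = 2.0
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.informative <= self.total_features:
            raise ValueError("informative must be <= total_features")
        if self.n_samples_per_class < 1:
            raise ValueError("need at least one sample per class")


def make_feature_table(
    spec: FeatureTableSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(features, labels, informative_mask) for a two-class problem."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples_per_class, spec.total_features
    X = rng.normal(0.0, spec.noise_sigma, (2 * n, p))
    y = np.repeat([0, 1], n)
    informative = np.zeros(p, dtype=bool)
    informative[: spec.informative] = True
    X[n:, informative] += spec.mean_shift * spec.noise_sigma
    # shuffle rows and feature order so the signal isn't positional
    row_order = rng.permutation(2 * n)
    col_order = rng.permutation(p)
    return X[row_order][:, col_order], y[row_order], informative[col_order]
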