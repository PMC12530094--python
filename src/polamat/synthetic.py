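"""Synthetic polarimetric scene generator.

Renders complete ColoPola-style samples — 36 red-channel-dominant images per
tissue slice, one image per (PSG, PSA) state pair — from known ground-truth
per-pixel Mueller matrix fields. Two sample classes are provided whose
default templates follow the published cohort element statistics: the
cancerous class has lower diagonal-element magnitude (m22, m33), higher
off-diagonal spatial heterogeneity, and consequently higher depolarization
power than the normal class.

The generator exists so that every downstream stage (reading, cropping,
reconstruction, parameter maps, statistics, classification) can be exercised
end-to-end with a known answer, without the multi-gigabyte source dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .polarization import PAIR_CODES, STATE_CODES, forward_intensity_field

__all__ = [
    "SceneSpec",
    "SampleBundle",
    "TABLE_NORMAL_MEAN",
    "TABLE_NORMAL_STD",
    "TABLE_CANCER_MEAN",
    "TABLE_CANCER_STD",
    "DETECTOR_SCALE",
    "make_class_field",
    "render_sample",
    "write_dataset",
    "manifest_from_labels",
]

# Published per-class element means and across-sample standard deviations
# (normalized by m11). Diagonal symmetry m22 ~ m33 holds in both classes;
# the cancer class has markedly lower m22/m33 and m44, i.e. stronger
# depolarization.
TABLE_NORMAL_MEAN = np.array(
    [
        [1.0000, 0.4911, 0.5327, 0.4831],
        [0.4934, 0.2845, 0.3809, 0.4291],
        [0.4618, 0.4812, 0.2818, 0.5786],
        [0.4521, 0.4386, 0.4411, 0.4667],
    ]
)
TABLE_NORMAL_STD = np.array(
    [
        [0.0, 0.0258, 0.0043, 0.0055],
        [0.0027, 0.0087, 0.0062, 0.0043],
        [0.0037, 0.0041, 0.0088, 0.0047],
        [0.0057, 0.0087, 0.0113, 0.0049],
    ]
)
TABLE_CANCER_MEAN = np.array(
    [
        [1.0000, 0.4928, 0.4361, 0.3971],
        [0.4866, 0.1732, 0.3092, 0.5429],
        [0.3677, 0.3461, 0.1743, 0.4181],
        [0.3716, 0.3509, 0.3612, 0.4450],
    ]
)
TABLE_CANCER_STD = np.array(
    [
        [0.0, 0.0350, 0.0166, 0.0375],
        [0.0172, 0.0572, 0.0441, 0.0163],
        [0.0257, 0.0149, 0.0428, 0.0839],
        [0.0512, 0.0098, 0.0135, 0.0177],
    ]
)

#: Counts a fully transmitted beam (identity sample, co-aligned states) maps
#: to. Chosen below the 255 ceiling so additive noise rarely clips.
DETECTOR_SCALE = 200.0

#: Spatial correlation length of the within-sample texture, in pixels.
TEXTURE_CORRELATION_PX = 8.0

# Zero-mean spatial texture amplitude (std of per-pixel deviations). The
# cancer class is given stronger off-diagonal heterogeneity.
TEXTURE_AMP = {
    "normal": {"diag": 0.02, "offdiag": 0.02},
    "cancer": {"diag": 0.03, "offdiag": 0.05},
}


class SceneGenerationError(ValueError):
    """Raised for unphysical templates or invalid scene specifications."""


@dataclass
class SceneSpec:
    """Specification of one synthetic sample.

    ``regions`` is an optional list of ``(mask, matrix)`` pairs whose masks
    must tile the image; when omitted, the per-class default template
    (published means + seeded spatial texture) is used.
    """

    width: int = 128
    height: int = 128
    class_label: str = "normal"
    regions: list | None = None
    noise: tuple = ("none",)
    quantization: str = "float"  # or "uint8"
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in ("normal", "cancer"):
            raise SceneGenerationError(
                f"class_label must be 'normal' or 'cancer', got {self.class_label!r}"
            )
        if self.quantization not in ("float", "uint8"):
            raise SceneGenerationError(f"unknown quantization {self.quantization!r}")
        kind = self.noise[0]
        if kind not in ("none", "gaussian", "poisson"):
            raise SceneGenerationError(f"unknown noise model {kind!r}")


@dataclass
class SampleBundle:
    """One rendered sample: 36 images plus its ground-truth Mueller field."""

    sample_id: str
    class_label: str
    images: dict = field(repr=False)  # code -> (H, W) float or (H, W, 3) uint8
    ground_truth: np.ndarray = field(repr=False)  # (H, W, 4, 4)
    quantization: str = "float"
    detector_scale: float = DETECTOR_SCALE

    def __post_init__(self):
        if set(self.images) != set(PAIR_CODES):
            missing = sorted(set(PAIR_CODES) - set(self.images))
            raise SceneGenerationError(f"bundle missing state images: {missing}")


def _smooth_field(rng: np.random.Generator, shape, corr_px: float) -> np.ndarray:
    """Unit-std smoothed Gaussian random field (zero mean by construction)."""
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=corr_px, mode="reflect")
    sd = sm.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (sm - sm.mean()) / sd


def make_class_field(spec: SceneSpec) -> np.ndarray:
    """Ground-truth per-pixel Mueller field ``(height, width, 4, 4)``.

    With explicit ``regions``, each pixel takes the matrix of its region
    (masks must tile the image exactly). Otherwise the class template is
    used: per-sample element means drawn around the published cohort means
    with the published across-sample spread, plus a seeded, spatially
    smooth zero-mean texture. All elements are clipped to the normalized
    physical range [-1, 1]; m11 is fixed at 1.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    if spec.regions is not None:
        fld = np.zeros((h, w, 4, 4))
        cover = np.zeros((h, w), dtype=int)
        for mask, M in spec.regions:
            M = np.asarray(M, dtype=float)
            if mask is None:
                mask = np.ones((h, w), dtype=bool)
            mask = np.asarray(mask, dtype=bool)
            if M.shape != (4, 4) or not np.all(np.isfinite(M)):
                raise SceneGenerationError("region matrix must be finite 4x4")
            if M[0, 0] <= 0 or np.any(np.abs(M / M[0, 0]) > 1 + 1e-9):
                raise SceneGenerationError(
                    "region matrix unphysical: need m11 > 0 and |m/m11| <= 1"
                )
            fld[mask] = M
            cover += mask
        if not np.all(cover == 1):
            raise SceneGenerationError("region masks must tile the image exactly once")
        return fld

    if spec.class_label == "normal":
        mean, std = TABLE_NORMAL_MEAN, TABLE_NORMAL_STD
    else:
        mean, std = TABLE_CANCER_MEAN, TABLE_CANCER_STD
    amp = TEXTURE_AMP[spec.class_label]

    # sample-level severity: one latent scalar shifts all elements coherently,
    # emulating slice-to-slice variation at the published spread
    z = rng.standard_normal()
    base = mean + z * std
    fld = np.empty((h, w, 4, 4))
    for r in range(4):
        for c in range(4):
            if r == 0 and c == 0:
                fld[:, :, 0, 0] = 1.0
                continue
            a = amp["diag"] if r == c else amp["offdiag"]
            tex = _smooth_field(rng, (h, w), TEXTURE_CORRELATION_PX)
            fld[:, :, r, c] = np.clip(base[r, c] + a * tex, -1.0, 1.0)
    return fld


def render_sample(spec: SceneSpec, sample_id: str | None = None) -> SampleBundle:
    """Render the 36 polarization-state images of one sample.

    Each image is the pixel-wise forward intensity for its (PSG, PSA) pair,
    scaled to detector counts, with optional noise and quantization. In
    ``uint8`` mode the output is RGB with the signal in the red channel,
    the green channel identically zero, and a faint blue floor (<= 4
    counts), matching the source instrument's color statistics.
    """
    fld = make_class_field(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 36]))
    images = {}
    for g in STATE_CODES:
        for a in STATE_CODES:
            counts = forward_intensity_field(fld, g, a) * DETECTOR_SCALE
            kind = spec.noise[0]
            if kind == "gaussian":
                counts = counts + rng.normal(0.0, spec.noise[1], size=counts.shape)
            elif kind == "poisson":
                scale = float(spec.noise[1])
                counts = rng.poisson(np.clip(counts, 0, None) * scale) / scale
            if spec.quantization == "uint8":
                red = np.clip(np.rint(counts), 0, 255).astype(np.uint8)
                rgb = np.zeros(red.shape + (3,), dtype=np.uint8)
                rgb[..., 0] = red
                rgb[..., 2] = rng.integers(0, 5, size=red.shape, dtype=np.uint8)
                images[g + a] = rgb
            else:
                images[g + a] = counts.astype(np.float64)
    sid = sample_id or f"{spec.class_label}_{spec.seed:05d}"
    return SampleBundle(
        sample_id=sid,
        class_label=spec.class_label,
        images=images,
        ground_truth=fld,
        quantization=spec.quantization,
    )


def manifest_from_labels(ids, labels) -> dict:
    """Dataset bookkeeping: per-class sample and image counts (36 per sample)."""
    ids = list(ids)
    labels = list(labels)
    if len(ids) != len(labels):
        raise ValueError("ids and labels must align")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    per_class = {}
    for lab in labels:
        per_class[lab] = per_class.get(lab, 0) + 1
    return {
        "samples": [{"id": i, "class": l} for i, l in zip(ids, labels)],
        "n_samples": len(ids),
        "n_images": 36 * len(ids),
        "images_per_class": {k: 36 * v for k, v in sorted(per_class.items())},
        "samples_per_class": dict(sorted(per_class.items())),
    }


def write_dataset(
    bundles,
    root_path,
    split_fraction: float = 0.8,
    seed: int = 0,
    fmt: str = "tiff",
) -> dict:
    """Write per-sample directories of 36 images plus manifest and split lists.

    Layout: ``<root>/<sample_id>/<PSGPSA>.<ext>`` (e.g. ``HV.tiff``), a
    ``manifest.json``, and ``train.txt`` / ``test.txt`` with one sample id
    per line. The split is seeded and stratified by class.
    """
    import tifffile
    import imageio.v3 as iio

    bundles = list(bundles)
    if len(bundles) < 2:
        raise ValueError("need at least 2 bundles to write a dataset")
    if fmt not in ("tiff", "png"):
        raise ValueError(f"unsupported image format {fmt!r}")
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)

    ids = [b.sample_id for b in bundles]
    labels = [b.class_label for b in bundles]
    manifest = manifest_from_labels(ids, labels)

    ext = "tiff" if fmt == "tiff" else "png"
    for b in bundles:
        d = root / b.sample_id
        d.mkdir(exist_ok=True)
        for code, img in b.images.items():
            path = d / f"{code}.{ext}"
            if fmt == "tiff":
                tifffile.imwrite(path, np.asarray(img))
            else:
                if img.dtype != np.uint8:
                    raise ValueError("PNG output requires uint8 quantization")
                iio.imwrite(path, img)

    # stratified seeded split
    rng = np.random.default_rng(seed)
    train_ids, test_ids = [], []
    for lab in sorted(set(labels)):
        cls = [i for i, l in zip(ids, labels) if l == lab]
        perm = rng.permutation(len(cls))
        n_train = int(round(split_fraction * len(cls)))
        if n_train == 0 or n_train == len(cls):
            raise SceneGenerationError(
                f"stratified split leaves class {lab!r} empty on one side"
            )
        train_ids += [cls[k] for k in perm[:n_train]]
        test_ids += [cls[k] for k in perm[n_train:]]

    manifest["train"] = sorted(train_ids)
    manifest["test"] = sorted(test_ids)
    manifest["format"] = ext
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (root / "train.txt").write_text("\n".join(sorted(train_ids)) + "\n")
    (root / "test.txt").write_text("\n".join(sorted(test_ids)) + "\n")
    return manifest
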