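"""Readers and preprocessing for ColoPola-layout polarimetric samples.

A sample is a directory of 36 images named by a two-letter PSG/PSA code
(``HH`` ... ``LL``). The preprocessing pipeline mirrors the acquisition
study: extract the red channel (the instrument's laser line leaves green
empty and blue nearly so), center-crop to 900x900, rescale to 224x224 with
an anti-aliased bilinear kernel, scale counts to [0, 1], and stack the 36
planes channel-last in canonical PSG-major order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .polarization import PAIR_CODES, STATE_CODES

__all__ = [
    "IntensityStack",
    "ModelInput",
    "DatasetLayoutError",
    "read_sample",
    "stack_from_bundle",
    "center_crop",
    "build_model_input",
    "channel_histogram_report",
    "read_split",
    "CROP_SIZE",
    "MODEL_SIZE",
]

CROP_SIZE = 900
MODEL_SIZE = 224
IMAGE_EXTENSIONS = (".tiff", ".tif", ".png")


class DatasetLayoutError(ValueError):
    """Raised when a sample directory or split file violates the layout."""


@dataclass
class IntensityStack:
    """The 36 scalar state images of one sample.

    ``planes`` has shape ``(36, H, W)`` in canonical order: channel index
    ``6 * index(psg) + index(psa)`` with states ordered H, V, P, M, R, L.
    """

    sample_id: str
    planes: np.ndarray = field(repr=False)
    source_channel: str = "red"

    def __post_init__(self):
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3 or self.planes.shape[0] != 36:
            raise DatasetLayoutError(
                f"expected 36 planes, got array of shape {self.planes.shape}"
            )

    def plane(self, code: str) -> np.ndarray:
        g, a = code[0], code[1]
        return self.planes[6 * STATE_CODES.index(g) + STATE_CODES.index(a)]

    @property
    def shape(self):
        return self.planes.shape[1:]


@dataclass
class ModelInput:
    """A 224x224x36 tensor in [0, 1] plus its class label."""

    tensor: np.ndarray = field(repr=False)
    class_label: str | None = None
    sample_id: str | None = None

    def __post_init__(self):
        t = np.asarray(self.tensor, dtype=float)
        if t.ndim != 3 or t.shape[2] != 36:
            raise DatasetLayoutError(f"model input must be (H, W, 36), got {t.shape}")
        if t.min() < -1e-9 or t.max() > 1 + 1e-9:
            raise DatasetLayoutError("model input values must lie in [0, 1]")
        self.tensor = t


def _red_plane(img: np.ndarray) -> np.ndarray:
    """Red channel of an RGB(A) image; single-channel images pass through."""
    if img.ndim == 2:
        return np.asarray(img, dtype=float)
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return np.asarray(img[..., 0], dtype=float)
    raise DatasetLayoutError(f"unsupported image shape {img.shape}")


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def read_sample(dir_path, channel: str = "red") -> IntensityStack:
    """Read one sample directory into a canonical :class:`IntensityStack`.

    Missing or ambiguous state files are reported by two-letter code; all
    36 planes must share the same dimensions.
    """
    d = Path(dir_path)
    if not d.is_dir():
        raise DatasetLayoutError(f"sample directory not found: {d}")
    files, missing = {}, []
    for code in PAIR_CODES:
        hits = [d / f"{code}{ext}" for ext in IMAGE_EXTENSIONS if (d / f"{code}{ext}").exists()]
        if not hits:
            missing.append(code)
        else:
            files[code] = hits[0]
    if missing:
        raise DatasetLayoutError(f"sample {d.name} missing state images: {missing}")

    planes = []
    for code in PAIR_CODES:
        img = _read_image(files[code])
        planes.append(_red_plane(img) if channel == "red" else np.asarray(img, float))
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise DatasetLayoutError(f"state images of {d.name} disagree in size: {shapes}")
    return IntensityStack(sample_id=d.name, planes=np.stack(planes), source_channel=channel)


def stack_from_bundle(bundle) -> IntensityStack:
    """Canonical stack directly from an in-memory rendered bundle."""
    planes = [ _red_plane(np.asarray(bundle.images[c])) for c in PAIR_CODES ]
    return IntensityStack(sample_id=bundle.sample_id, planes=np.stack(planes))


def center_crop(stack: IntensityStack, size: int = CROP_SIZE) -> IntensityStack:
    """Centered ``size x size`` window from every plane.

    For odd remainders the extra pixel goes to the right/bottom (offsets are
    floor((dim - size) / 2), 0-based, rows = height).
    """
    h, w = stack.shape
    if h < size or w < size:
        raise DatasetLayoutError(f"cannot crop {size}x{size} from {h}x{w} planes")
    r0 = (h - size) // 2
    c0 = (w - size) // 2
    return IntensityStack(
        sample_id=stack.sample_id,
        planes=stack.planes[:, r0 : r0 + size, c0 : c0 + size],
        source_channel=stack.source_channel,
    )


def build_model_input(
    stack: IntensityStack,
    size: int = MODEL_SIZE,
    class_label: str | None = None,
    count_scale: float = 255.0,
) -> ModelInput:
    """Resize each plane to ``size x size`` and scale counts to [0, 1].

    Bilinear resize with anti-aliasing; channels are stacked last in
    canonical order, independent of any file listing order.
    """
    from skimage.transform import resize

    chans = [
        resize(p, (size, size), order=1, anti_aliasing=True, preserve_range=True)
        for p in stack.planes
    ]
    tensor = np.clip(np.stack(chans, axis=-1) / count_scale, 0.0, 1.0)
    return ModelInput(tensor=tensor, class_label=class_label, sample_id=stack.sample_id)


def channel_histogram_report(sample_dir) -> dict:
    """Per-image 256-bin R/G/B histograms plus dynamic-range flags.

    Single-channel images are reported as red-only. The ``flat_red`` list
    names images whose red channel has no dynamic range.
    """
    d = Path(sample_dir)
    report, flat = {}, []
    for code in PAIR_CODES:
        hits = [d / f"{code}{ext}" for ext in IMAGE_EXTENSIONS if (d / f"{code}{ext}").exists()]
        if not hits:
            raise DatasetLayoutError(f"sample {d.name} missing state image {code}")
        img = _read_image(hits[0])
        entry = {}
        if img.ndim == 3 and img.shape[2] >= 3:
            for i, ch in enumerate("RGB"):
                entry[ch] = np.histogram(img[..., i], bins=256, range=(0, 256))[0]
        else:
            entry["R"] = np.histogram(img, bins=256, range=(0, 256))[0]
        if float(np.ptp(np.asarray(img)[..., 0] if img.ndim == 3 else img)) == 0.0:
            flat.append(code)
        report[code] = entry
    return {"histograms": report, "flat_red": flat}


def read_split(train_file, test_file, manifest: dict) -> dict:
    """Validated train/test id sets with per-class counts.

    Ids must exist in the manifest; an id in both files is an overlap error;
    duplicates within one file are deduplicated with a warning.
    """
    known = {s["id"]: s["class"] for s in manifest["samples"]}

    def _read_ids(path):
        lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        seen, out = set(), []
        for ln in lines:
            if ln in seen:
                warnings.warn(f"duplicate id {ln!r} in {path}; deduplicated")
                continue
            seen.add(ln)
            out.append(ln)
        return out

    train = _read_ids(train_file)
    test = _read_ids(test_file)
    overlap = sorted(set(train) & set(test))
    if overlap:
        raise DatasetLayoutError(f"ids present in both train and test: {overlap}")
    unknown = sorted((set(train) | set(test)) - set(known))
    if unknown:
        raise DatasetLayoutError(f"ids absent from manifest: {unknown}")

    def _counts(ids):
        c = {}
        for i in ids:
            c[known[i]] = c.get(known[i], 0) + 1
        return dict(sorted(c.items()))

    return {
        "train": train,
        "test": test,
        "n_train": len(train),
        "n_test": len(test),
        "train_per_class": _counts(train),
        "test_per_class": _counts(test),
    }
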