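"""Reconstruction of the 16 Mueller matrix element images from 36 states.

Each element m_rc is a signed sum of four state images: the generator pair
selected by the column index and the analyzer pair selected by the row index
(index 1 -> H+V sum, 2 -> H-V, 3 -> P-M, 4 -> R-L). With the detector
constant of the forward model, the four-term combination returns exactly
``2 * m_rc``, so elements are recovered up to a global scale that cancels
under m11 normalization.

Two combination tables are provided: the canonical, forward-model-validated
table (default) and an ``as_printed`` table reproducing a published variant
whose m33 cell uses an MH term where the self-consistent term is MP. The
``validate_table`` oracle check flags any such inconsistent cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import IntensityStack
from .polarization import forward_intensity, random_physical_mueller

__all__ = [
    "CombinationTable",
    "ElementImages",
    "canonical_table",
    "as_printed_table",
    "validate_table",
    "reconstruct",
    "normalize",
    "element_summary",
    "ReconstructionError",
]


class ReconstructionError(ValueError):
    pass


# generator/analyzer pair selectors per matrix index (1-based)
_PAIRS = {
    1: (("H", +1), ("V", +1)),
    2: (("H", +1), ("V", -1)),
    3: (("P", +1), ("M", -1)),
    4: (("R", +1), ("L", -1)),
}


@dataclass(frozen=True)
class CombinationTable:
    """Per-element four-term (psg, psa, sign) combination recipes."""

    name: str
    terms: dict  # (r, c) -> tuple of (psg, psa, sign), 1-based indices

    def __post_init__(self):
        if set(self.terms) != {(r, c) for r in range(1, 5) for c in range(1, 5)}:
            raise ReconstructionError("table must define all 16 elements")
        for rc, t in self.terms.items():
            if len(t) != 4:
                raise ReconstructionError(f"element {rc} must have exactly 4 terms")


def canonical_table() -> CombinationTable:
    """The forward-model-consistent 36-state combination table."""
    terms = {}
    for r in range(1, 5):
        for c in range(1, 5):
            terms[(r, c)] = tuple(
                (g, a, sg * sa)
                for g, sg in _PAIRS[c]
                for a, sa in _PAIRS[r]
            )
    return CombinationTable(name="canonical", terms=terms)


def as_printed_table() -> CombinationTable:
    """The published table variant: m33 reads PP - PM - MH + MM."""
    terms = dict(canonical_table().terms)
    terms[(3, 3)] = (("P", "P", +1), ("P", "M", -1), ("M", "H", -1), ("M", "M", +1))
    return CombinationTable(name="as_printed", terms=terms)


def validate_table(
    table: CombinationTable,
    n_trials: int = 20,
    seed: int = 0,
    tol: float = 1e-10,
) -> dict:
    """Oracle check: the table applied to forward intensities of random
    physical matrices must return ``2 * m_rc`` for every element.

    Returns ``{"consistent": bool, "bad_cells": [...], "max_error": float}``.
    """
    rng = np.random.default_rng(seed)
    worst = np.zeros((4, 4))
    for _ in range(n_trials):
        M = random_physical_mueller(rng)
        for (r, c), t in table.terms.items():
            val = sum(s * forward_intensity(M, g, a) for g, a, s in t)
            worst[r - 1, c - 1] = max(worst[r - 1, c - 1], abs(val - 2.0 * M[r - 1, c - 1]))
    bad = [f"m{r}{c}" for r in range(1, 5) for c in range(1, 5) if worst[r - 1, c - 1] > tol]
    return {"consistent": not bad, "bad_cells": bad, "max_error": float(worst.max())}


@dataclass
class ElementImages:
    """The 16 element maps of one sample, with a valid-pixel mask."""

    elements: np.ndarray = field(repr=False)  # (4, 4, H, W)
    normalized: bool = False
    mask: np.ndarray | None = field(default=None, repr=False)  # True = valid
    table_name: str = "canonical"
    sample_id: str | None = None

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=float)
        if self.elements.ndim != 4 or self.elements.shape[:2] != (4, 4):
            raise ReconstructionError(
                f"elements must be (4, 4, H, W), got {self.elements.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.elements.shape[2:], dtype=bool)

    def element(self, r: int, c: int) -> np.ndarray:
        """Element map by 1-based matrix indices (e.g. ``element(2, 2)``)."""
        return self.elements[r - 1, c - 1]


def reconstruct(stack: IntensityStack, table: CombinationTable | None = None) -> ElementImages:
    """Signed four-term sums producing the 16 unnormalized element maps."""
    if table is None:
        table = canonical_table()
    h, w = stack.shape
    out = np.zeros((4, 4, h, w))
    for (r, c), terms in table.terms.items():
        acc = np.zeros((h, w))
        for g, a, s in terms:
            acc += s * stack.plane(g + a)
        out[r - 1, c - 1] = acc
    return ElementImages(
        elements=out, normalized=False, table_name=table.name, sample_id=stack.sample_id
    )


def normalize(
    elems: ElementImages,
    eps_rel: float = 1e-6,
    clip: bool = False,
) -> ElementImages:
    """Divide every element map pixel-wise by m11.

    Pixels with m11 below ``eps_rel * max(m11)`` are masked invalid (not
    NaN) and excluded from all downstream statistics. The m11 map is set to
    1 on valid pixels. With ``clip`` the normalized values are clipped to
    the physical range [-1, 1]; by default out-of-range values are kept.
    """
    if elems.normalized:
        return elems
    m11 = elems.elements[0, 0]
    peak = float(np.max(m11))
    if peak <= 0:
        raise ReconstructionError("degenerate sample: m11 non-positive everywhere")
    valid = m11 > eps_rel * peak
    if not valid.any():
        raise ReconstructionError("degenerate sample: no valid m11 pixels")
    safe = np.where(valid, m11, 1.0)
    out = elems.elements / safe
    out[:, :, ~valid] = 0.0
    out[0, 0][valid] = 1.0
    if clip:
        out = np.clip(out, -1.0, 1.0)
    return ElementImages(
        elements=out,
        normalized=True,
        mask=valid & elems.mask,
        table_name=elems.table_name,
        sample_id=elems.sample_id,
    )


def element_summary(samples, pool_pixels: bool = False):
    """Cohort element statistics in the published table's form.

    Default mode averages each element over a sample's valid pixels, then
    reports mean +- std across samples; ``pool_pixels`` pools every valid
    pixel of the cohort instead. m11 is reported as 1 (normalization).
    Returns a pandas DataFrame with columns element, mean, std, n.
    """
    import pandas as pd

    samples = list(samples)
    if not samples:
        raise ReconstructionError("need at least one sample")
    rows = []
    for r in range(1, 5):
        for c in range(1, 5):
            if r == 1 and c == 1:
                rows.append({"element": "m11", "mean": 1.0, "std": 0.0,
                             "n": len(samples), "note": "normalization"})
                continue
            if pool_pixels:
                vals = np.concatenate(
                    [s.element(r, c)[s.mask] for s in samples]
                )
            else:
                vals = np.array([float(s.element(r, c)[s.mask].mean()) for s in samples])
            rows.append({
                "element": f"m{r}{c}",
                "mean": float(vals.mean()),
                "std": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": len(samples),
                "note": "",
            })
    return pd.DataFrame(rows)
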