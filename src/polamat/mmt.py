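"""Mueller matrix transformation (MMT) parameter maps.

Five scalar descriptors condense the central 2x2 block (and m44) of the
normalized Mueller matrix into rotation-insensitive measures of tissue
microstructure:

* ``b = (m22 + m33) / 2`` — depolarization power factor,
* ``t = sqrt((m22 - m33)^2 + (m23 + m32)^2) / 2`` — anisotropy magnitude,
* ``A`` — normalized anisotropy, ideally in [0, 1],
* ``G`` — degree of anisotropy/isotropy,
* ``Delta = 1 - (|m22| + |m33| + |m44|) / 3`` — depolarization power, in
  [0, 1] for normalized elements.

The published expressions for A and G are typographically corrupted: A as
printed can exceed its own stated [0, 1] range, and G as printed has an
identically zero numerator (so G = 1 wherever defined). Both the as-printed
and corrected forms are therefore exposed, and every result records which
variant produced it. The corrected A equals ``2|b|t / (b^2 + t^2)``, which
respects [0, 1] for all inputs and coincides with the corrected radicand
form wherever ``b >= 0`` (all tissue-like media).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MMTMaps",
    "mmt_b",
    "mmt_t",
    "mmt_A",
    "mmt_G",
    "mmt_delta",
    "compute_mmt",
    "mmt_cohort_stats",
    "A_VARIANTS",
    "G_VARIANTS",
]

A_VARIANTS = ("as_printed", "he2014_corrected")
G_VARIANTS = ("as_printed", "conjectured_corrected")


def mmt_b(m22, m33) -> np.ndarray:
    """Depolarization power factor b = (m22 + m33) / 2."""
    return (np.asarray(m22, float) + np.asarray(m33, float)) / 2.0


def mmt_t(m22, m33, m23, m32) -> np.ndarray:
    """Anisotropy magnitude t = sqrt((m22 - m33)^2 + (m23 + m32)^2) / 2."""
    m22, m33 = np.asarray(m22, float), np.asarray(m33, float)
    m23, m32 = np.asarray(m23, float), np.asarray(m32, float)
    return np.sqrt((m22 - m33) ** 2 + (m23 + m32) ** 2) / 2.0


def mmt_A(m22, m33, m23, m32, variant: str = "he2014_corrected"):
    """Anisotropy A; returns ``(map, valid_mask)``.

    ``as_printed`` evaluates the published expression exactly as typeset
    (radicand ``(m22-m33)^2 + (m22+m33)^2``), which can exceed 1.
    ``he2014_corrected`` uses radicand ``(m22-m33)^2 + (m23+m32)^2`` and a
    magnitude numerator, i.e. ``2|b|t / (b^2 + t^2)``, in [0, 1].
    Pixels with zero denominator are masked.
    """
    if variant not in A_VARIANTS:
        raise ValueError(f"unknown A variant {variant!r}")
    m22, m33 = np.asarray(m22, float), np.asarray(m33, float)
    m23, m32 = np.asarray(m23, float), np.asarray(m32, float)
    denom = (m22 + m33) ** 2 + (m22 - m33) ** 2 + (m23 + m32) ** 2
    valid = denom > 0
    safe = np.where(valid, denom, 1.0)
    if variant == "as_printed":
        num = 2.0 * (m22 + m33) * np.sqrt((m22 - m33) ** 2 + (m22 + m33) ** 2)
    else:
        num = 2.0 * np.abs(m22 + m33) * np.sqrt((m22 - m33) ** 2 + (m23 + m32) ** 2)
    out = np.where(valid, num / safe, 0.0)
    return out, valid


def mmt_G(m22, m33, m23, m32, variant: str = "as_printed"):
    """Degree of anisotropy/isotropy G; returns ``(map, valid_mask)``.

    ``as_printed`` keeps the published numerator ``(m22 m33 - m22 m33)^2``,
    which is identically zero, so G = 1 wherever the denominator is
    nonzero. ``conjectured_corrected`` uses ``(m22 m33 - m23 m32)^2``.
    """
    if variant not in G_VARIANTS:
        raise ValueError(f"unknown G variant {variant!r}")
    m22, m33 = np.asarray(m22, float), np.asarray(m33, float)
    m23, m32 = np.asarray(m23, float), np.asarray(m32, float)
    ssq = m22**2 + m33**2 + m23**2 + m32**2
    denom = 2.0 * ssq**2
    valid = denom > 0
    safe = np.where(valid, denom, 1.0)
    if variant == "as_printed":
        num = 2.0 * (m22 * m33 - m22 * m33) ** 2  # identically zero as typeset
    else:
        num = 2.0 * (m22 * m33 - m23 * m32) ** 2
    out = np.where(valid, np.sqrt(np.clip(1.0 - num / safe, 0.0, None)), 0.0)
    return out, valid


def mmt_delta(m22, m33, m44) -> np.ndarray:
    """Depolarization power Delta = 1 - (|m22| + |m33| + |m44|) / 3."""
    return 1.0 - (
        np.abs(np.asarray(m22, float))
        + np.abs(np.asarray(m33, float))
        + np.abs(np.asarray(m44, float))
    ) / 3.0


@dataclass
class MMTMaps:
    """Per-pixel A, b, t, G, Delta maps plus the shared valid-pixel mask."""

    A: np.ndarray = field(repr=False)
    b: np.ndarray = field(repr=False)
    t: np.ndarray = field(repr=False)
    G: np.ndarray = field(repr=False)
    delta: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    variant_A: str = "he2014_corrected"
    variant_G: str = "as_printed"
    sample_id: str | None = None

    def means(self) -> dict:
        """Valid-pixel means of the five parameters."""
        m = self.mask
        return {
            "A": float(self.A[m].mean()),
            "b": float(self.b[m].mean()),
            "t": float(self.t[m].mean()),
            "G": float(self.G[m].mean()),
            "delta": float(self.delta[m].mean()),
        }


def compute_mmt(
    elems,
    variant_A: str = "he2014_corrected",
    variant_G: str = "as_printed",
) -> MMTMaps:
    """All five parameter maps from normalized :class:`ElementImages`.

    Masked pixels of the input propagate; pixels where A or G are undefined
    are additionally masked.
    """
    if not elems.normalized:
        raise ValueError("MMT parameters require m11-normalized elements")
    m22, m33 = elems.element(2, 2), elems.element(3, 3)
    m23, m32 = elems.element(2, 3), elems.element(3, 2)
    m44 = elems.element(4, 4)
    A, okA = mmt_A(m22, m33, m23, m32, variant=variant_A)
    G, okG = mmt_G(m22, m33, m23, m32, variant=variant_G)
    mask = elems.mask & okA & okG
    return MMTMaps(
        A=A,
        b=mmt_b(m22, m33),
        t=mmt_t(m22, m33, m23, m32),
        G=G,
        delta=mmt_delta(m22, m33, m44),
        mask=mask,
        variant_A=variant_A,
        variant_G=variant_G,
        sample_id=elems.sample_id,
    )


def mmt_cohort_stats(cohort_a, cohort_b, paired: bool = False) -> dict:
    """Per-parameter cohort summaries and two-cohort significance tests.

    Each cohort is a sequence of :class:`MMTMaps`; the per-sample statistic
    is the valid-pixel mean. Requires >= 2 samples per cohort. The
    comparison (Welch t by default, paired t when ``paired``) is delegated
    to :mod:`polamat.stats`.
    """
    from .stats import two_cohort_ttest

    cohort_a, cohort_b = list(cohort_a), list(cohort_b)
    if len(cohort_a) < 2 or len(cohort_b) < 2:
        raise ValueError("need at least 2 samples per cohort")
    out = {}
    for key in ("A", "b", "t", "G", "delta"):
        va = np.array([m.means()[key] for m in cohort_a])
        vb = np.array([m.means()[key] for m in cohort_b])
        res = two_cohort_ttest(va, vb, paired=paired)
        out[key] = {
            "mean_a": float(va.mean()),
            "std_a": float(va.std(ddof=1)),
            "mean_b": float(vb.mean()),
            "std_b": float(vb.std(ddof=1)),
            "t": res.statistic,
            "p": res.pvalue,
            "stars": res.stars,
        }
    return out
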