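"""Cohort statistics and paired classifier-comparison tests.

Covers the analysis battery run on reconstructed element images and trained
classifiers: frequency-distribution histograms (FDHs) of normalized element
intensities, two-cohort t tests with significance star coding, confusion-
matrix metrics (accuracy, precision, recall, F1), McNemar's continuity-
corrected chi-square test, and the exact two-sided binomial (sign) test,
including the rule preferring the binomial test for small disagreement
counts (n01 + n10 <= 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

__all__ = [
    "FDH",
    "ConfusionCounts",
    "PairedComparison",
    "TTestResult",
    "DegenerateComparisonError",
    "compute_fdh",
    "two_cohort_ttest",
    "classification_metrics",
    "mcnemar_test",
    "binomial_test_two_sided",
    "compare_models",
    "type_i_calibration",
    "round_display",
    "p_stars",
]


class DegenerateComparisonError(ValueError):
    """Raised when two classifiers never disagree (n01 + n10 = 0)."""


def round_display(x: float, ndigits: int = 3) -> float:
    """Half-up rounding for display, matching published table formatting."""
    return float(Decimal(repr(float(x))).quantize(Decimal(1).scaleb(-ndigits),
                                                  rounding=ROUND_HALF_UP))


def p_stars(p: float) -> str:
    """Significance star coding (**** for p < 0.0001)."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Frequency distribution histograms
# ---------------------------------------------------------------------------

@dataclass
class FDH:
    """Shared-edge histograms of one element's intensities per cohort."""

    element: str
    edges: np.ndarray
    counts: dict  # cohort name -> counts array
    density: bool = False

    def peak_locations(self) -> dict:
        centers = (self.edges[:-1] + self.edges[1:]) / 2.0
        return {k: float(centers[int(np.argmax(v))]) for k, v in self.counts.items()}


def compute_fdh(
    cohort_maps: dict,
    bins: int = 100,
    value_range: tuple = (-1.0, 1.0),
    density: bool = False,
    element: str = "",
) -> FDH:
    """Histogram the pooled pixels of each cohort on shared bin edges.

    ``cohort_maps`` maps cohort name to a sequence of 2D maps (or
    ``(map, mask)`` pairs); all cohorts share the same edges so their
    distributions are directly comparable.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    edges = np.linspace(value_range[0], value_range[1], bins + 1)
    counts = {}
    for name, maps in cohort_maps.items():
        vals = []
        for m in maps:
            if isinstance(m, tuple):
                arr, mask = m
                vals.append(np.asarray(arr, float)[np.asarray(mask, bool)])
            else:
                vals.append(np.asarray(m, float).ravel())
        if not vals or sum(v.size for v in vals) == 0:
            raise ValueError(f"cohort {name!r} contributes no pixels")
        pooled = np.concatenate(vals)
        counts[name] = np.histogram(pooled, bins=edges, density=density)[0]
    return FDH(element=element, edges=edges, counts=counts, density=density)


# ---------------------------------------------------------------------------
# Two-cohort tests
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    stars: str
    paired: bool


def two_cohort_ttest(values_a, values_b, paired: bool = False) -> TTestResult:
    """Two-sided t test between two cohorts of per-sample values.

    Unpaired mode uses the unequal-variance (Welch) t; paired mode the
    paired t and requires aligned cohorts of equal length >= 2.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired t test requires equal-length cohorts")
        if len(a) < 2:
            raise ValueError("paired t test requires at least 2 pairs")
        if np.allclose(a, b):
            return TTestResult(0.0, 1.0, "ns", True)
        res = sps.ttest_rel(a, b)
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each cohort needs at least 2 values")
        res = sps.ttest_ind(a, b, equal_var=False)
        if np.isnan(res.statistic):  # identical constant cohorts
            return TTestResult(0.0, 1.0, "ns", False)
    p = float(res.pvalue)
    return TTestResult(float(res.statistic), p, p_stars(p), paired)


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with the cancer class as positive."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def classification_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, precision, recall and F1 from confusion counts.

    Ratios with zero denominators are reported as ``None`` (undefined),
    never silently as 0. Values are returned at full precision; use
    :func:`round_display` for table formatting.
    """
    acc = (c.TP + c.TN) / c.n if c.n else None
    prec = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else None
    rec = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else None
    if prec is None or rec is None or (prec + rec) == 0:
        f1 = None
    else:
        f1 = 2.0 * prec * rec / (prec + rec)
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


# ---------------------------------------------------------------------------
# Paired model comparison (McNemar / exact binomial)
# ---------------------------------------------------------------------------

def mcnemar_test(n01: int, n10: int):
    """Continuity-corrected McNemar test on disagreement counts.

    ``chi2 = (max(|n01 - n10| - 1, 0))^2 / (n01 + n10)`` referred to the
    chi-square distribution with 1 degree of freedom (upper tail).
    """
    n01, n10 = int(n01), int(n10)
    if n01 < 0 or n10 < 0:
        raise ValueError("disagreement counts must be nonnegative")
    if n01 + n10 == 0:
        raise DegenerateComparisonError("models never disagree; test undefined")
    chi2 = max(abs(n01 - n10) - 1, 0) ** 2 / (n01 + n10)
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p


def binomial_test_two_sided(n01: int, n10: int) -> float:
    """Exact two-sided sign test at success probability 0.5.

    ``p = min(1, 2 * P(X <= min(n01, n10)))`` for
    ``X ~ Binomial(n01 + n10, 0.5)``.
    """
    n01, n10 = int(n01), int(n10)
    if n01 < 0 or n10 < 0:
        raise ValueError("disagreement counts must be nonnegative")
    n = n01 + n10
    if n == 0:
        raise DegenerateComparisonError("models never disagree; test undefined")
    if abs(n01 - n10) <= 1:
        # doubled smaller tail covers at least half the symmetric mass
        return 1.0
    return float(min(1.0, 2.0 * sps.binom.cdf(min(n01, n10), n, 0.5)))


@dataclass
class PairedComparison:
    """Disagreement counts of two classifiers plus both paired tests.

    ``n01`` counts samples classified normal (0) by model A but cancer (1)
    by model B; ``n10`` the reverse. ``preferred`` names the test used for
    the significance call: the exact binomial when ``n01 + n10 <= 10``,
    McNemar's chi-square otherwise.
    """

    n01: int
    n10: int
    alpha: float
    chi2: float
    p_mcnemar: float
    p_binomial: float
    preferred: str
    significant: bool


def compare_models(predictions_a, predictions_b, labels=None, alpha: float = 0.05) -> PairedComparison:
    """Paired comparison of two classifiers' 0/1 predictions.

    ``labels`` (if given) must align with the prediction vectors; it is not
    used by the tests themselves, which depend only on disagreements.
    """
    a = np.asarray(predictions_a, dtype=int)
    b = np.asarray(predictions_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("prediction vectors must have equal length")
    if labels is not None and np.asarray(labels).shape != a.shape:
        raise ValueError("labels must align with predictions")
    n01 = int(np.sum((a == 0) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    chi2, p_mc = mcnemar_test(n01, n10)
    p_bin = binomial_test_two_sided(n01, n10)
    preferred = "binomial" if (n01 + n10) <= 10 else "mcnemar"
    p_pref = p_bin if preferred == "binomial" else p_mc
    return PairedComparison(
        n01=n01,
        n10=n10,
        alpha=alpha,
        chi2=chi2,
        p_mcnemar=p_mc,
        p_binomial=p_bin,
        preferred=preferred,
        significant=bool(p_pref < alpha),
    )


def type_i_calibration(
    n_sims: int = 2000,
    n_samples: int = 100,
    disagree_rate: float = 0.2,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the preferred paired test.

    Simulates two equal-accuracy classifiers: each sample disagrees with
    probability ``disagree_rate``, the direction of disagreement being a
    fair coin. Returns the fraction of simulations where the preferred
    test rejects at ``alpha``; under the null this should sit near alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    skipped = 0
    for _ in range(n_sims):
        n_dis = rng.binomial(n_samples, disagree_rate)
        if n_dis == 0:
            skipped += 1
            continue
        n01 = rng.binomial(n_dis, 0.5)
        n10 = n_dis - n01
        if (n01 + n10) <= 10:
            p = binomial_test_two_sided(n01, n10)
        else:
            p = mcnemar_test(n01, n10)[1]
        if p < alpha:
            rejections += 1
    return rejections / max(n_sims - skipped, 1)
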