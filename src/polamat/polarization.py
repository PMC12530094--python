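"""Stokes–Mueller algebra.

Canonical polarization states, ideal optical-element Mueller matrices, and
the forward intensity model of a dual-rotating polarimeter: a polarization
state generator (PSG) prepares one of six states, the sample transforms it,
and a polarization state analyzer (PSA) projects onto one of six states,
giving 36 scalar intensity measurements per scene point.

Conventions
-----------
* Stokes vectors are ``(s0, s1, s2, s3)`` with ``s0`` the total intensity.
* Right-circular light carries ``s3 = +RIGHT_CIRCULAR_S3`` (handedness is a
  single module constant; every result downstream of m11 normalization is
  invariant to flipping it consistently).
* Polarizer / wave-plate angles are measured counterclockwise from
  horizontal, in degrees.
* The analyzer projection carries a detector constant of 1/2, so the
  four-term element combinations used in reconstruction return exactly
  ``2 * m_rc``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "STATE_CODES",
    "RIGHT_CIRCULAR_S3",
    "state_index",
    "stokes_of_state",
    "stokes_is_physical",
    "ideal_element",
    "linear_polarizer",
    "quarter_wave_plate",
    "diagonal_depolarizer",
    "rotation_mueller",
    "forward_intensity",
    "forward_intensity_field",
    "random_physical_mueller",
    "PAIR_CODES",
]

#: The six canonical PSG/PSA states, in canonical order.
STATE_CODES = ("H", "V", "P", "M", "R", "L")

#: All 36 two-letter measurement codes, PSG-major (HH, HV, ..., LL).
PAIR_CODES = tuple(g + a for g in STATE_CODES for a in STATE_CODES)

#: Sign of s3 for right-circular light. Flip to -1.0 for the opposite
#: handedness convention; reconstruction round-trips are invariant.
RIGHT_CIRCULAR_S3 = 1.0


class PolarizationStateError(ValueError):
    """Raised for an unknown polarization-state code."""


def state_index(code: str) -> int:
    """Canonical index of a state code (H=0, V=1, P=2, M=3, R=4, L=5)."""
    try:
        return STATE_CODES.index(code)
    except ValueError:
        raise PolarizationStateError(
            f"unknown polarization state {code!r}; expected one of {STATE_CODES}"
        ) from None


def stokes_of_state(code: str) -> np.ndarray:
    """Unit-intensity Stokes vector of a canonical polarization state.

    H/V are horizontal/vertical linear, P/M are +45 deg / 135 deg linear,
    R/L are right/left circular.
    """
    c = RIGHT_CIRCULAR_S3
    table = {
        "H": (1.0, 1.0, 0.0, 0.0),
        "V": (1.0, -1.0, 0.0, 0.0),
        "P": (1.0, 0.0, 1.0, 0.0),
        "M": (1.0, 0.0, -1.0, 0.0),
        "R": (1.0, 0.0, 0.0, c),
        "L": (1.0, 0.0, 0.0, -c),
    }
    if code not in table:
        raise PolarizationStateError(
            f"unknown polarization state {code!r}; expected one of {STATE_CODES}"
        )
    return np.array(table[code], dtype=float)


def stokes_is_physical(s, tol: float = 1e-9) -> bool:
    """True if s0 >= sqrt(s1^2 + s2^2 + s3^2) within tolerance."""
    s = np.asarray(s, dtype=float)
    return bool(s[0] + tol >= np.sqrt(np.sum(s[1:] ** 2)))


def rotation_mueller(theta_deg: float) -> np.ndarray:
    """Mueller rotation matrix for a frame rotation by ``theta_deg``."""
    th = 2.0 * np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c, -s, 0.0],
            [0.0, s, c, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def linear_polarizer(theta_deg: float = 0.0) -> np.ndarray:
    """Ideal linear polarizer with transmission axis at ``theta_deg``."""
    if not np.isfinite(theta_deg):
        raise ValueError("polarizer angle must be finite")
    base = 0.5 * np.array(
        [
            [1.0, 1.0, 0.0, 0.0],
            [1.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    r = rotation_mueller(theta_deg)
    return r @ base @ rotation_mueller(-theta_deg)


def quarter_wave_plate(theta_fast_deg: float = 0.0) -> np.ndarray:
    """Ideal quarter-wave retarder with fast axis at ``theta_fast_deg``."""
    if not np.isfinite(theta_fast_deg):
        raise ValueError("wave-plate angle must be finite")
    # quarter-wave retardance about the horizontal fast axis
    base = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, -1.0],
            [0.0, 0.0, 1.0, 0.0],
        ]
    )
    r = rotation_mueller(theta_fast_deg)
    return r @ base @ rotation_mueller(-theta_fast_deg)


def diagonal_depolarizer(a: float, b: float, c: float) -> np.ndarray:
    """Pure diagonal depolarizer diag(1, a, b, c), factors in [0, 1]."""
    for name, v in (("a", a), ("b", b), ("c", c)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"depolarizer factor {name}={v} outside [0, 1]")
    return np.diag([1.0, float(a), float(b), float(c)])


def ideal_element(kind: str, **params) -> np.ndarray:
    """Textbook Mueller matrix of a named ideal optical element.

    Parameters
    ----------
    kind:
        One of ``identity``, ``linear_polarizer`` (``theta`` in degrees),
        ``quarter_wave_plate`` (``theta_fast`` in degrees),
        ``diagonal_depolarizer`` (``a``, ``b``, ``c`` in [0, 1]).
    """
    if kind == "identity":
        return np.eye(4)
    if kind == "linear_polarizer":
        return linear_polarizer(params.get("theta", 0.0))
    if kind == "quarter_wave_plate":
        return quarter_wave_plate(params.get("theta_fast", 0.0))
    if kind == "diagonal_depolarizer":
        return diagonal_depolarizer(params["a"], params["b"], params["c"])
    raise ValueError(f"unknown element kind {kind!r}")


def forward_intensity(M, psg: str, psa: str) -> float:
    """Detector intensity for one (PSG, PSA) state pair.

    ``I = 1/2 * a^T (M s)`` with ``s`` the generator state and ``a`` the
    analyzer state. May be negative only for unphysical ``M`` (returned
    as-is so callers can flag it).
    """
    M = np.asarray(M, dtype=float)
    s = stokes_of_state(psg)
    a = stokes_of_state(psa)
    return float(0.5 * a @ (M @ s))


def forward_intensity_field(field, psg: str, psa: str) -> np.ndarray:
    """Vectorized :func:`forward_intensity` over a (..., 4, 4) Mueller field."""
    field = np.asarray(field, dtype=float)
    s = stokes_of_state(psg)
    a = stokes_of_state(psa)
    return 0.5 * np.einsum("i,...ij,j->...", a, field, s)


def random_physical_mueller(rng: np.random.Generator) -> np.ndarray:
    """Random genuinely physical Mueller matrix, normalized to m11 = 1.

    Built as a convex mixture of products of ideal elements (rotated
    polarizers, quarter-wave plates, and diagonal depolarizers), each of
    which maps physical Stokes vectors to physical Stokes vectors; the
    mixture therefore does too, so all 36 forward intensities are >= 0.
    """
    n_mix = int(rng.integers(1, 4))
    weights = rng.dirichlet(np.ones(n_mix))
    total = np.zeros((4, 4))
    for w in weights:
        M = np.eye(4)
        for _ in range(int(rng.integers(1, 4))):
            kind = rng.choice(["polarizer", "qwp", "depol"])
            if kind == "polarizer":
                M = linear_polarizer(rng.uniform(0, 180)) @ M
            elif kind == "qwp":
                M = quarter_wave_plate(rng.uniform(0, 180)) @ M
            else:
                M = diagonal_depolarizer(*rng.uniform(0, 1, size=3)) @ M
        total += w * M
    if total[0, 0] <= 1e-12:  # fully absorbing mixture; retry
        return random_physical_mueller(rng)
    return total / total[0, 0]
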