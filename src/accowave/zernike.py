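"""Zernike mode indexing, wavefront evaluation and the RE/LE mirror convention.

Coefficients are carried in micrometres throughout; pupil sizes are
diameters in millimetres.  Polynomials are unit-variance (Noll/ANSI
normalised) over the unit disk, so the RMS wavefront error of a
coefficient vector is the Euclidean norm of its coefficients.  The
single-index ordering is the OSA/ANSI convention, j = (n(n+2) + m) / 2,
with m ascending within each radial order.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, isqrt
from typing import Iterable, NamedTuple, Sequence

import numpy as np


class ZernikeIndex(NamedTuple):
    """Double index of a Zernike mode: radial order n, meridional index m."""

    n: int
    m: int


def _check_index(n: int, m: int) -> None:
    if n < 0 or abs(m) > n or (n - abs(m)) % 2 != 0:
        raise ValueError(f"invalid Zernike index (n={n}, m={m})")


def mode_count(min_order: int, max_order: int) -> int:
    """Number of Zernike modes with min_order <= n <= max_order.

    Each radial order n contributes n + 1 modes; orders 2–6 give 25.
    """
    if min_order < 0 or max_order < min_order:
        raise ValueError(
            f"invalid order range ({min_order}, {max_order}): need 0 <= min <= max"
        )
    return sum(n + 1 for n in range(min_order, max_order + 1))


def single_index(index: ZernikeIndex | tuple[int, int]) -> int:
    """OSA/ANSI single index j = (n(n+2) + m) / 2."""
    n, m = index
    _check_index(n, m)
    return (n * (n + 2) + m) // 2


def double_index(j: int) -> ZernikeIndex:
    """Invert the OSA/ANSI single index."""
    if j < 0:
        raise ValueError(f"single index must be non-negative, got {j}")
    n = (isqrt(8 * j + 1) - 1) // 2
    m = 2 * j - n * (n + 2)
    _check_index(n, m)
    return ZernikeIndex(n, m)


def modes_in_range(min_order: int = 2, max_order: int = 6) -> list[ZernikeIndex]:
    """Modes ordered by the single-index scheme (m ascending within order)."""
    if min_order < 0 or max_order < min_order:
        raise ValueError(f"invalid order range ({min_order}, {max_order})")
    return [
        ZernikeIndex(n, m)
        for n in range(min_order, max_order + 1)
        for m in range(-n, n + 1, 2)
    ]


#: the 25 modes of the accommodation model (orders 2–6), serialization order
MODES: tuple[ZernikeIndex, ...] = tuple(modes_in_range(2, 6))

#: CSV column labels "c_n_m" with signed m, matching MODES
MODE_LABELS: tuple[str, ...] = tuple(f"c_{n}_{m}" for n, m in MODES)

#: demands of the accommodation protocol, dioptres (stimulus magnitude)
DEMANDS: tuple[int, ...] = (0, 1, 2, 3, 4, 5)

#: number of model parameters: 25 modes x 6 demands
N_PARAMETERS: int = len(MODES) * len(DEMANDS)

RIGHT, LEFT = "RE", "LE"
LATERALITIES = (RIGHT, LEFT)


@dataclass
class ZernikeCoefficientVector:
    """Coefficients (µm) over a fixed order range at a given pupil diameter."""

    values: np.ndarray
    pupil_diameter: float
    min_order: int = 2
    max_order: int = 6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = mode_count(self.min_order, self.max_order)
        if self.values.shape != (expected,):
            raise ValueError(
                f"expected {expected} coefficients for orders "
                f"{self.min_order}-{self.max_order}, got shape {self.values.shape}"
            )
        if not self.pupil_diameter > 0:
            raise ValueError(f"pupil diameter must be positive, got {self.pupil_diameter}")

    @property
    def modes(self) -> list[ZernikeIndex]:
        return modes_in_range(self.min_order, self.max_order)


def radial_poly_coefficients(n: int, m_abs: int) -> np.ndarray:
    """Monomial coefficients of the radial polynomial R_n^{|m|}(r).

    Returned array c has degree-k monomial coefficient at c[k]
    (length n + 1); odd powers between n and |m| are zero.
    """
    if m_abs < 0 or m_abs > n or (n - m_abs) % 2:
        raise ValueError(f"invalid radial indices (n={n}, |m|={m_abs})")
    c = np.zeros(n + 1)
    for k in range((n - m_abs) // 2 + 1):
        c[n - 2 * k] = (-1) ** k * comb(n - k, k) * comb(n - 2 * k, (n - m_abs) // 2 - k)
    return c


def normalization(n: int, m: int) -> float:
    """Noll/ANSI factor giving unit variance over the unit disk."""
    return np.sqrt(2.0 * (n + 1) / (1.0 + (m == 0)))


def zernike_value(
    n: int, m: int, rho: np.ndarray | float, theta: np.ndarray | float
) -> np.ndarray | float:
    """Evaluate one normalised Zernike polynomial Z_n^m(rho, theta)."""
    _check_index(n, m)
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho must lie in [0, 1]")
    # np.polyval expects highest degree first
    radial = np.polyval(radial_poly_coefficients(n, abs(m))[::-1], rho)
    if m > 0:
        angular = np.cos(m * np.asarray(theta, dtype=float))
    elif m < 0:
        angular = np.sin(-m * np.asarray(theta, dtype=float))
    else:
        angular = np.ones_like(np.asarray(theta, dtype=float))
    return normalization(n, m) * radial * angular


def evaluate_wavefront(
    coeffs: ZernikeCoefficientVector,
    rho: np.ndarray | float,
    theta: np.ndarray | float,
) -> np.ndarray | float:
    """Wavefront height (µm) at normalised polar pupil coordinates."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho must lie in [0, 1]")
    out = np.zeros(np.broadcast(rho, np.asarray(theta)).shape)
    for (n, m), c in zip(coeffs.modes, coeffs.values):
        if c != 0.0:
            out = out + c * zernike_value(n, m, rho, theta)
    return out if out.shape else float(out)


def rms(
    coeffs: ZernikeCoefficientVector,
    subset: Iterable[ZernikeIndex | tuple[int, int]] | None = None,
) -> float:
    """RMS wavefront error (µm) over all modes or a subset.

    With unit-variance polynomials the RMS equals sqrt(sum of squared
    coefficients).
    """
    if coeffs.values.size == 0:
        raise ValueError("empty coefficient vector")
    if subset is None:
        return float(np.sqrt(np.sum(coeffs.values**2)))
    modes = coeffs.modes
    idx = []
    for pair in subset:
        pair = ZernikeIndex(*pair)
        if pair not in modes:
            raise ValueError(f"mode {pair} not in coefficient vector")
        idx.append(modes.index(pair))
    if not idx:
        raise ValueError("empty mode subset")
    return float(np.sqrt(np.sum(coeffs.values[idx] ** 2)))


def rms_contributions(coeffs: ZernikeCoefficientVector) -> np.ndarray:
    """Relative contribution (%) of each mode to the squared RMS."""
    total = np.sum(coeffs.values**2)
    if total == 0:
        raise ValueError("zero coefficient vector has no RMS contributions")
    return 100.0 * coeffs.values**2 / total


def mirror_sign_flips(modes: Sequence[ZernikeIndex]) -> np.ndarray:
    """Signs (+/-1) applied to LE coefficients to mirror into RE convention.

    Reflection across the vertical meridian flips modes with negative even
    or positive odd meridional index.
    """
    return np.array(
        [-1.0 if ((m < 0 and m % 2 == 0) or (m > 0 and m % 2 == 1)) else 1.0 for _, m in modes]
    )


def mirror_to_right_eye(
    coeffs: ZernikeCoefficientVector, laterality: str
) -> ZernikeCoefficientVector:
    """Map a left-eye coefficient vector to the right-eye convention.

    Right-eye input is returned unchanged; applying the map twice to LE
    data is the identity (the sign rule is an involution).
    """
    if laterality not in LATERALITIES:
        raise ValueError(f"laterality must be one of {LATERALITIES}, got {laterality!r}")
    if laterality == RIGHT:
        return ZernikeCoefficientVector(
            coeffs.values.copy(), coeffs.pupil_diameter, coeffs.min_order, coeffs.max_order
        )
    signs = mirror_sign_flips(coeffs.modes)
    return ZernikeCoefficientVector(
        coeffs.values * signs, coeffs.pupil_diameter, coeffs.min_order, coeffs.max_order
    )
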