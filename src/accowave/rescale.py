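"""Concentric pupil rescaling of Zernike coefficient vectors.

Restricting a wavefront defined on a pupil of diameter D to a concentric
sub-pupil of diameter D' = rho * D (rho <= 1) and re-expanding it in the
Zernike basis of the sub-pupil is a linear map on the coefficients.  The
map is built analytically here: within each meridional family m the
radial polynomials are polynomials in r, so substituting r -> rho*r and
solving the (triangular) change of basis in monomial space gives the
exact re-expansion.  Rescaling never mixes meridional families and a
mode of order n only feeds modes of order <= n, so the matrix is
block-lower-triangular in radial order.

Piston and tilt induced by the restriction are computed internally but
dropped from the output, since the accommodation model's parameter space
starts at order 2.  Upscaling (rho > 1) is refused: it would extrapolate
the wavefront beyond the measured pupil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from accowave.zernike import (
    ZernikeCoefficientVector,
    modes_in_range,
    normalization,
    radial_poly_coefficients,
)


@dataclass
class RescaleMatrix:
    """Linear map from source-pupil to target-pupil coefficients."""

    source_diameter: float
    target_diameter: float
    min_order: int
    max_order: int
    matrix: np.ndarray

    @property
    def ratio(self) -> float:
        return self.target_diameter / self.source_diameter

    def apply(self, values: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(values, dtype=float)


def _radial_family_matrix(m: int, max_order: int, rho: float) -> tuple[list[int], np.ndarray]:
    """Re-expansion matrix for the meridional family m (signed).

    Returns the radial orders of the family (|m|, |m|+2, ..., max_order)
    and the matrix A with c'(n') = sum_n A[n', n] c(n).  The angular part
    is unchanged by a concentric scaling, so the map depends on |m| only.
    """
    orders = list(range(abs(m), max_order + 1, 2))
    deg = max_order + 1
    # columns: normalised radial polynomials in monomial basis (degree-major)
    P = np.zeros((deg, len(orders)))
    Ps = np.zeros((deg, len(orders)))
    for col, n in enumerate(orders):
        coeffs = normalization(n, m) * radial_poly_coefficients(n, abs(m))
        P[: n + 1, col] = coeffs
        # substituting r -> rho*r multiplies the r^k coefficient by rho^k
        Ps[: n + 1, col] = coeffs * rho ** np.arange(n + 1)
    # solve P A = Ps on the family's monomial support (r^{|m|}, r^{|m|+2}, ...)
    rows = [n for n in range(abs(m), max_order + 1, 2)]
    A = np.linalg.solve(P[rows, :], Ps[rows, :])
    return orders, A


def build_rescale_matrix(
    source_diameter: float,
    target_diameter: float,
    min_order: int = 2,
    max_order: int = 6,
) -> RescaleMatrix:
    """Exact coefficient map for a concentric pupil reduction.

    The output rows/columns follow the single-index mode ordering over
    ``min_order..max_order``; induced modes below ``min_order`` (piston,
    tilt) are discarded.
    """
    if not 0 < target_diameter <= source_diameter:
        raise ValueError(
            "target diameter must satisfy 0 < target <= source "
            f"(got source={source_diameter}, target={target_diameter}); "
            "upscaling would extrapolate beyond the measured pupil"
        )
    rho = target_diameter / source_diameter
    modes = modes_in_range(min_order, max_order)
    k = len(modes)
    M = np.zeros((k, k))
    for m in range(-max_order, max_order + 1):
        orders, A = _radial_family_matrix(m, max_order, rho)
        for col_f, n_in in enumerate(orders):
            if n_in < min_order or (n_in, m) not in [(mo.n, mo.m) for mo in modes]:
                continue
            j_in = modes.index((n_in, m))
            for row_f, n_out in enumerate(orders):
                if n_out < min_order:
                    continue  # induced piston/tilt dropped
                j_out = modes.index((n_out, m))
                M[j_out, j_in] = A[row_f, col_f]
    return RescaleMatrix(source_diameter, target_diameter, min_order, max_order, M)


def rescale(
    coeffs: ZernikeCoefficientVector, target_diameter: float
) -> ZernikeCoefficientVector:
    """Rescale a coefficient vector to a smaller concentric pupil."""
    matrix = build_rescale_matrix(
        coeffs.pupil_diameter, target_diameter, coeffs.min_order, coeffs.max_order
    )
    return ZernikeCoefficientVector(
        matrix.apply(coeffs.values), target_diameter, coeffs.min_order, coeffs.max_order
    )
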