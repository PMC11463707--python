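"""Rescaling Zernike coefficients to a smaller standard pupil.

A wavefront measured over a 5.0 mm natural pupil is restricted to the
4.0 mm standard pupil (ratio 0.8).  Defocus shrinks by the ratio squared
and spherical aberration cascades part of its power into defocus.
"""

import numpy as np

from accowave import MODES, ZernikeCoefficientVector, rescale

values = np.zeros(25)
values[MODES.index((2, 0))] = 1.00  # µm defocus
values[MODES.index((4, 0))] = 0.10  # µm spherical aberration
coeffs = ZernikeCoefficientVector(values, pupil_diameter=5.0)

out = rescale(coeffs, target_diameter=4.0)
print("pupil 5.0 mm -> 4.0 mm (ratio 0.8)")
print(f"c(2,0): {values[MODES.index((2, 0))]:.4f} -> {out.values[MODES.index((2, 0))]:.6f} µm")
print(f"c(4,0): {values[MODES.index((4, 0))]:.4f} -> {out.values[MODES.index((4, 0))]:.6f} µm")
# c'(4,0) = 0.8^4 * 0.1 = 0.04096; c'(2,0) = 0.64 + sqrt(15)*0.64*(0.64-1)*0.1
print("analytic check c'(2,0):", 0.64 + np.sqrt(15) * 0.64 * (0.64 - 1) * 0.1)
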