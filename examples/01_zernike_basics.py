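"""Zernike bookkeeping: indexing, RMS and the left-eye mirror convention.

Builds a small aberration vector, reports its RMS error and shows how a
left-eye measurement is mapped into the right-eye convention.
"""

import numpy as np

from accowave import MODES, ZernikeCoefficientVector, mirror_to_right_eye, rms, single_index

values = np.zeros(25)
values[MODES.index((2, 0))] = 1.20   # defocus, µm
values[MODES.index((2, -2))] = 0.15  # oblique astigmatism
values[MODES.index((4, 0))] = 0.04   # primary spherical aberration
coeffs = ZernikeCoefficientVector(values, pupil_diameter=4.66)

print("single indices:", [(nm, single_index(nm)) for nm in [(2, -2), (2, 0), (4, 0)]])
print(f"total RMS wavefront error: {rms(coeffs):.4f} µm")
print(f"defocus-only RMS:          {rms(coeffs, [(2, 0)]):.4f} µm")

mirrored = mirror_to_right_eye(coeffs, "LE")
print("after LE->RE mirroring, c(2,-2) flips sign:",
      coeffs.values[MODES.index((2, -2))], "->", mirrored.values[MODES.index((2, -2))])
# The RMS is unchanged: mirroring only reverses signs of the asymmetric modes.
print(f"mirrored RMS: {rms(mirrored):.4f} µm (identical)")
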