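"""Independent naive filter-bank oracle for the multi-scale features.

Implements the separable periodized 2-D discrete wavelet transform directly
from the published db3 analysis taps (hardcoded literals) with explicit
circular convolution and downsampling, one window at a time — no wavelet
library and none of the package's vectorized kernel machinery.  Used to
cross-check ``extract_feature_image`` coefficient by coefficient.
"""

from __future__ import annotations

import numpy as np

# Daubechies-3 analysis filters (6 taps, orthonormal)
DB3_LO = np.array([
    0.03522629188570953, -0.08544127388202666, -0.13501102001025458,
    0.45987750211849154, 0.8068915093110925, 0.33267055295008263,
])
DB3_HI = np.array([
    -0.33267055295008263, 0.8068915093110925, -0.45987750211849154,
    -0.13501102001025458, 0.08544127388202666, 0.03522629188570953,
])


def periodized_step_1d(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """One circular analysis step along axis 0: y[k] = sum_j f[j] x[2k+3-j]."""
    n = x.shape[0]
    out = np.zeros((n // 2,) + x.shape[1:])
    for k in range(n // 2):
        for j, f in enumerate(filt):
            out[k] += f * x[(2 * k + 3 - j) % n]
    return out


def dwt2_periodized(a: np.ndarray):
    """One separable 2-D level: rows filtered/downsampled, then columns."""
    lo_r = periodized_step_1d(a, DB3_LO)          # low-pass along rows
    hi_r = periodized_step_1d(a, DB3_HI)
    ca = periodized_step_1d(lo_r.T, DB3_LO).T     # then along columns
    cv = periodized_step_1d(lo_r.T, DB3_HI).T
    ch = periodized_step_1d(hi_r.T, DB3_LO).T
    cd = periodized_step_1d(hi_r.T, DB3_HI).T
    return ca, ch, cv, cd


def window_feature(window: np.ndarray, rule: str = "maxabs") -> float:
    """Decompose a 2^M window M levels and fuse the final scalars."""
    a = np.asarray(window, dtype=float)
    m = int(round(np.log2(a.shape[0])))
    for _ in range(m):
        a, ch, cv, cd = dwt2_periodized(a)
    finals = np.array([a.item(), ch.item(), cv.item(), cd.item()])
    if rule == "approx":
        return float(finals[0])
    return float(finals[np.argmax(np.abs(finals))])


def naive_feature_image(
    image: np.ndarray, window_size: int, rule: str = "maxabs"
) -> np.ndarray:
    """Per-pixel loop: reflect-pad, extract each window, decompose, fuse."""
    w = window_size
    padded = np.pad(image, ((w // 2, w // 2 - 1), (w // 2, w // 2 - 1)), "reflect")
    r, c = image.shape
    out = np.empty((r, c))
    for i in range(r):
        for j in range(c):
            out[i, j] = window_feature(padded[i : i + w, j : j + w], rule)
    return out
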