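"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library's own code paths: the SG oracle fits
an explicit polynomial per window with numpy.polynomial and differentiates
it analytically; the AUC oracle enumerates every (positive, negative)
pair.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import polynomial as P


def brute_force_sg(y: np.ndarray, window: int, poly_order: int, deriv_order: int) -> np.ndarray:
    """Interior Savitzky-Golay values by explicit per-window least squares.

    Returns the filtered values at the len(y) - window + 1 positions where
    the full window fits.
    """
    y = np.asarray(y, float)
    half = (window - 1) // 2
    offsets = np.arange(-half, half + 1, dtype=float)
    out = []
    for centre in range(half, y.size - half):
        seg = y[centre - half : centre + half + 1]
        coeffs = P.polyfit(offsets, seg, poly_order)
        deriv = P.polyder(coeffs, deriv_order)
        out.append(P.polyval(0.0, deriv))
    return np.array(out)


def pair_count_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """AUC by exhaustive pair counting: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = scores[positives]
    neg = scores[~positives]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (pos.size * neg.size)


def ols_predict(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares fitted values of centred Y on centred X, plus Y mean."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    return Xc @ B + Y.mean(axis=0)
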