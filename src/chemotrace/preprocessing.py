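"""Savitzky-Golay smoothing/differentiation of spectra.

The filter fits a low-order polynomial by least squares inside a short
moving window and returns the requested derivative of that polynomial at
the window centre.  Because the fit is linear in the data, the whole
operation reduces to a fixed convolution whose weights depend only on the
window size, polynomial order and derivative order.  Applied with a 3-point
window, polynomial order 1 and first derivative (the defaults) it removes
vertical offsets and linear baselines — the multiplicative-scatter nuisance
of TXRF spectra — while preserving peak-shape differences between samples.

The derivative is taken per channel *index* (unit spacing), not per keV:
the window is defined in points, and downstream PLS-DA is unaffected by the
global scale convention once it is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

from .spectra_io import SpectraSet

__all__ = ["SGParams", "sg_coefficients", "sg_filter"]


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay filter settings.

    window
        Odd window length in channels (>= 3).  Default 3.
    poly_order
        Degree of the local polynomial; must be < window.  Default 1.
    deriv_order
        Derivative returned at the window centre; <= poly_order.  Default 1.
    """

    window: int = 3
    poly_order: int = 1
    deriv_order: int = 1

    def validate(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd integer >= 3, got {self.window}")
        if not 0 <= self.poly_order < self.window:
            raise ValueError(
                f"poly_order must satisfy 0 <= poly_order < window, "
                f"got {self.poly_order} with window {self.window}"
            )
        if not 0 <= self.deriv_order <= self.poly_order:
            raise ValueError(
                f"deriv_order must satisfy 0 <= deriv_order <= poly_order, "
                f"got {self.deriv_order} with poly_order {self.poly_order}"
            )

    @property
    def half(self) -> int:
        return (self.window - 1) // 2


def sg_coefficients(params: SGParams) -> np.ndarray:
    """Convolution weights of the least-squares polynomial derivative filter.

    For centred offsets ``x = -h..h`` and Vandermonde matrix
    ``V[j, m] = x_j**m`` the least-squares coefficients of a degree-
    ``poly_order`` polynomial are ``b = pinv(V) @ y``; the ``d``-th
    derivative at the centre is ``d! * b_d``, i.e. a fixed linear
    functional of the window values.  Returned weights ``w`` satisfy
    ``w @ y_window == estimate``.

    With the defaults (window 3, order 1, first derivative) this yields
    the central-difference weights ``(-1/2, 0, +1/2)``.
    """
    params.validate()
    offsets = np.arange(-params.half, params.half + 1, dtype=float)
    vander = offsets[:, None] ** np.arange(params.poly_order + 1)
    pinv = np.linalg.pinv(vander)
    return factorial(params.deriv_order) * pinv[params.deriv_order]


def sg_filter(
    s: SpectraSet,
    params: SGParams = SGParams(),
    edge: str = "replicate",
    force: bool = False,
) -> SpectraSet:
    """Apply the Savitzky-Golay filter to every spectrum of a dataset.

    The convolution is evaluated at every interior channel where the full
    window fits.  Edge channels are handled per ``edge``:

    * ``"replicate"`` (default) — the first and last ``(window-1)/2``
      channels copy the nearest interior result, preserving the channel
      count; no curvature is fabricated at the boundary.
    * ``"drop"`` — edge channels are removed along with their energies.

    The operation is strictly per-sample: no information crosses samples,
    so it may be applied once before cross-validation without leakage.

    Raises
    ------
    ValueError
        If the input is already processed (double-differentiation guard;
        override with ``force=True``) or shorter than the window.
    """
    params.validate()
    if s.processed and not force:
        raise ValueError(
            "input spectra are already processed; pass force=True to filter again"
        )
    if edge not in ("replicate", "drop"):
        raise ValueError(f"unknown edge policy {edge!r}")
    if s.p < params.window:
        raise ValueError(f"spectrum length {s.p} shorter than window {params.window}")

    w = sg_coefficients(params)
    h = params.half
    X = s.intensities
    n_valid = s.p - params.window + 1
    valid = np.zeros((s.n, n_valid))
    for j in range(params.window):
        valid += w[j] * X[:, j : j + n_valid]

    if edge == "drop":
        return SpectraSet(
            sample_ids=s.sample_ids,
            channel_energies=s.channel_energies[h : s.p - h],
            intensities=valid,
            meta=s.meta,
            processed=True,
        )
    out = np.empty_like(X)
    out[:, h : s.p - h] = valid
    out[:, :h] = valid[:, [0]]
    out[:, s.p - h :] = valid[:, [-1]]
    return s.with_intensities(out, processed=True)
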