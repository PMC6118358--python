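"""Integrated 2-D Gaussian pixel model shared by the simulator and localizer.

Each pixel's expected signal is the Gaussian PSF integrated over the pixel
area, expressed per axis as a difference of error functions:

    E(k; c, sigma) = 1/2 [erf((k - c + 1/2)/(sqrt(2) sigma))
                          - erf((k - c - 1/2)/(sqrt(2) sigma))]

where ``k`` is the pixel index and ``c`` the emitter center in pixel units
(coordinate convention: ``c = 3.0`` is the center of pixel 3; 0-based).
The expected pixel value of an emitter with ``N`` photons on background ``b``
photons/pixel is ``mu = N * Ex * Ey + b``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)


def integrated_gaussian_1d(k, center, sigma):
    """Per-pixel integral of a unit 1-D Gaussian centered at ``center``.

    Broadcasts over ``k`` and ``center``.
    """
    k = np.asarray(k, dtype=float)
    up = (k - center + 0.5) / (_SQRT2 * sigma)
    lo = (k - center - 0.5) / (_SQRT2 * sigma)
    return 0.5 * (erf(up) - erf(lo))


def integrated_gaussian_derivs(k, center, sigma):
    """(E, dE/dcenter, d2E/dcenter2) of the 1-D pixel-integrated Gaussian."""
    k = np.asarray(k, dtype=float)
    up = (k - center + 0.5) / (_SQRT2 * sigma)
    lo = (k - center - 0.5) / (_SQRT2 * sigma)
    e_up, e_lo = np.exp(-up**2), np.exp(-lo**2)
    E = 0.5 * (erf(up) - erf(lo))
    dE = (e_lo - e_up) / (_SQRT2PI * sigma)
    d2E = (2.0 / (_SQRT2PI * sigma)) * (lo * e_lo / (_SQRT2 * sigma)
                                        - up * e_up / (_SQRT2 * sigma))
    return E, dE, d2E


def integrated_gaussian_dsigma(k, center, sigma):
    """(dE/dsigma, d2E/dsigma2) of the 1-D pixel-integrated Gaussian."""
    k = np.asarray(k, dtype=float)
    a_up = k - center + 0.5
    a_lo = k - center - 0.5
    up, lo = a_up / (_SQRT2 * sigma), a_lo / (_SQRT2 * sigma)
    e_up, e_lo = np.exp(-up**2), np.exp(-lo**2)
    dE = (a_lo * e_lo - a_up * e_up) / (_SQRT2PI * sigma**2)
    d2E = (
        a_up * e_up * (2.0 / sigma - a_up**2 / sigma**3)
        - a_lo * e_lo * (2.0 / sigma - a_lo**2 / sigma**3)
    ) / _SQRT2PI / sigma**2
    return dE, d2E


def emitter_image(shape, x, y, photons, sigma):
    """Expected photon image of one emitter on a zero background.

    ``shape`` is (rows, cols); ``x`` indexes columns, ``y`` rows.
    """
    rows, cols = shape
    ex = integrated_gaussian_1d(np.arange(cols), x, sigma)
    ey = integrated_gaussian_1d(np.arange(rows), y, sigma)
    return photons * np.outer(ey, ex)


def add_emitters(image, xs, ys, photons, sigma, radius=None):
    """Accumulate emitter PSFs into ``image`` in place (photon units).

    Only a window of ``radius`` pixels around each emitter is touched
    (default 4 sigma + 1), which makes dense multi-frame simulation cheap.
    """
    rows, cols = image.shape
    if radius is None:
        radius = int(np.ceil(4.0 * sigma)) + 1
    for x, y, n in zip(np.atleast_1d(xs), np.atleast_1d(ys), np.atleast_1d(photons)):
        c0, c1 = int(np.floor(x)) - radius, int(np.floor(x)) + radius + 1
        r0, r1 = int(np.floor(y)) - radius, int(np.floor(y)) + radius + 1
        c0, c1 = max(c0, 0), min(c1, cols)
        r0, r1 = max(r0, 0), min(r1, rows)
        if c0 >= c1 or r0 >= r1:
            continue
        ex = integrated_gaussian_1d(np.arange(c0, c1), x, sigma)
        ey = integrated_gaussian_1d(np.arange(r0, r1), y, sigma)
        image[r0:r1, c0:c1] += n * np.outer(ey, ex)
    return image
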