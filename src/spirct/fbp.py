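"""Fan-beam filtered backprojection for a flat equispaced detector.

Standard full-scan (2*pi) flat-detector fan FBP: projections are rescaled
to a virtual detector through the isocenter, cosine weighted, ramp filtered
with the band-limited spatial-domain kernel (optional Hann apodization),
and backprojected with the 1/U^2 distance weight.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import next_fast_len, irfft, rfft

from .projector import Geometry

__all__ = ["ramp_kernel", "fbp_line_integrals"]


def ramp_kernel(n_detector: int, du: float) -> np.ndarray:
    """Band-limited ramp filter, spatial domain, length 2 n - 1.

    h[0] = 1/(4 du^2), h[k] = -1/(pi k du)^2 for odd k, 0 for even k.
    """
    k = np.arange(-(n_detector - 1), n_detector)
    h = np.zeros(k.size)
    h[k == 0] = 1.0 / (4.0 * du**2)
    odd = (k % 2) != 0
    h[odd] = -1.0 / (np.pi * k[odd] * du) ** 2
    return h


def fbp_line_integrals(
    values: np.ndarray,
    geometry: Geometry,
    n_pixels: int,
    pixel_size: float,
    apodization: str | None = None,
) -> np.ndarray:
    """Reconstruct a (n_pixels, n_pixels) image from line-integral projections.

    ``values`` has shape (n_views, n_detector) in (image units) * cm; the
    result is in image units.  ``apodization='hann'`` multiplies the ramp
    response by a Hann window for noise suppression.
    """
    values = np.asarray(values, dtype=float)
    nv, nd = values.shape
    if (nv, nd) != (geometry.n_views, geometry.n_detector):
        raise ValueError("projection shape does not match geometry")
    r_si = geometry.source_to_isocenter
    mag = r_si / geometry.source_to_detector
    u = geometry.detector_offsets * mag  # virtual detector at isocenter
    du = geometry.detector_pitch * mag

    weighted = values * (r_si / np.sqrt(r_si**2 + u**2))
    # ramp filtering by FFT convolution
    kern = ramp_kernel(nd, du)
    nfft = next_fast_len(nd + kern.size - 1)
    kern_f = rfft(kern, nfft)
    if apodization == "hann":
        freq = np.arange(kern_f.size)
        kern_f *= 0.5 * (1.0 + np.cos(np.pi * freq / (kern_f.size - 1)))
    elif apodization is not None:
        raise ValueError(f"unknown apodization {apodization!r}")
    filt = irfft(rfft(weighted, nfft, axis=1) * kern_f, nfft, axis=1)
    filt = filt[:, nd - 1 : 2 * nd - 1] * du

    coords = (np.arange(n_pixels) - (n_pixels - 1) / 2.0) * pixel_size
    x = coords[np.newaxis, :]
    y = coords[:, np.newaxis]
    image = np.zeros((n_pixels, n_pixels))
    # half weight: a full 2*pi fan scan measures every ray twice
    dbeta = np.pi / nv
    for v, beta_deg in enumerate(geometry.view_angles):
        beta = np.deg2rad(beta_deg)
        cb, sb = np.cos(beta), np.sin(beta)
        big_u = r_si - (x * cb + y * sb)  # distance along the central ray
        u_prime = r_si * (-x * sb + y * cb) / big_u
        interp = np.interp(u_prime.ravel(), u, filt[v], left=0.0, right=0.0)
        image += (r_si**2 / big_u**2) * interp.reshape(n_pixels, n_pixels)
    return image * dbeta
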