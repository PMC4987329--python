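"""Complex steerable pyramid: multi-scale, multi-orientation image decomposition.

The pyramid is built in the frequency domain with polar-separable filters:
octave-spaced raised-cosine radial windows and ``cos^(K-1)`` angular windows
(K = number of orientations). Subbands are analytic (complex): the angular
window is restricted to one half of the Fourier plane and doubled in
amplitude, so the magnitude of a coefficient is the local envelope and its
real part is the corresponding real-pyramid coefficient.

Conventions
-----------
* Orientation 1 responds to horizontal structure (energy on the vertical
  frequency axis); successive orientations rotate by ``pi / n_orientations``.
* Each scale halves the linear subband size: the subband at scale ``s`` has
  dimensions ``input / 2**(s-1)``.
* Downsampling is unitary: the lowpass spectrum is cropped and divided by 2
  per scale.  With this convention Parseval holds exactly,

      sum(img**2) == sum(high**2) + sum_k sum(|band_k|**2)/2 + sum(low**2),

  and white noise has (in expectation) equal mean energy at every scale.
  A side effect is that the lowpass residual of a constant image carries
  ``2**n_scales`` times the image mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Dict, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PyramidSpec",
    "PyramidDecomposition",
    "build_pyramid",
    "subband_energy",
    "total_energy",
    "subband_frequency_cpd",
]


@dataclass(frozen=True)
class PyramidSpec:
    """Shape of a steerable pyramid: number of scales and orientations."""

    n_scales: int = 4
    n_orientations: int = 4

    def __post_init__(self) -> None:
        if self.n_scales < 1:
            raise ValueError(f"n_scales must be >= 1, got {self.n_scales}")
        if self.n_orientations < 2:
            raise ValueError(
                f"n_orientations must be >= 2, got {self.n_orientations}"
            )


@dataclass
class PyramidDecomposition:
    """Result of :func:`build_pyramid`.

    ``subbands`` maps ``(scale, orientation)`` (both 1-based) to a complex
    coefficient grid of linear size ``input / 2**(scale-1)``.
    ``lowpass_levels`` holds the real lowpass image at every level
    (index 0 = full-resolution lowpass, index ``n_scales`` = lowpass residual);
    the texture statistics need these intermediates.
    """

    subbands: Dict[Tuple[int, int], np.ndarray]
    highpass_residual: np.ndarray
    lowpass_residual: np.ndarray
    spec: PyramidSpec
    lowpass_levels: list = field(default_factory=list)


def _polar_grids(shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    """Centered radius (rad/sample, Nyquist = pi) and angle grids."""
    h, w = shape
    fy = np.fft.fftshift(np.fft.fftfreq(h))[:, None] * 2.0 * np.pi
    fx = np.fft.fftshift(np.fft.fftfreq(w))[None, :] * 2.0 * np.pi
    r = np.hypot(fy, fx)
    theta = np.arctan2(fy, fx)
    return r, theta


def _hi_mask(r: np.ndarray, cutoff: float) -> np.ndarray:
    """Raised-cosine highpass: 0 below cutoff/2, 1 above cutoff, cos ramp between."""
    with np.errstate(divide="ignore"):
        arg = np.log2(np.maximum(cutoff / np.maximum(r, 1e-30), 1e-30))
    mask = np.cos(0.5 * np.pi * np.clip(arg, 0.0, 1.0))
    mask[r >= cutoff] = 1.0
    mask[r <= cutoff / 2.0] = 0.0
    return mask


def _angular_masks(theta: np.ndarray, n_orientations: int) -> list:
    """Analytic (half-plane, doubled) cos^(K-1) angular windows, tight frame."""
    K = n_orientations
    # sum_k c^2 cos^(2(K-1))(t - pi k/K) == 1 for all t
    c = np.sqrt(4.0 ** (K - 1) / (K * comb(2 * (K - 1), K - 1)))
    masks = []
    for k in range(K):
        # orientation k=0 centered on the vertical frequency axis -> horizontal
        # image structure; increasing k rotates by pi/K
        center = np.pi / 2.0 + np.pi * k / K
        d = np.mod(theta - center + np.pi, 2.0 * np.pi) - np.pi
        m = np.where(np.abs(d) < np.pi / 2.0,
                     2.0 * c * np.cos(d) ** (K - 1), 0.0)
        masks.append(m)
    return masks


def _crop_center_half(spec2d: np.ndarray) -> np.ndarray:
    h, w = spec2d.shape
    return spec2d[h // 4: h // 4 + h // 2, w // 4: w // 4 + w // 2]


def _validate_image(img: np.ndarray, n_scales: int) -> np.ndarray:
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D luminance image, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    factor = 2 ** n_scales
    if a.shape[0] % factor or a.shape[1] % factor:
        raise ValueError(
            f"image dimensions {a.shape} must be divisible by 2**n_scales = {factor}"
        )
    return a


def build_pyramid(img: np.ndarray, spec: PyramidSpec) -> PyramidDecomposition:
    """Decompose a luminance image into oriented complex subbands.

    Parameters
    ----------
    img : 2-D array
        Luminance image; both dimensions must be divisible by
        ``2**spec.n_scales``.
    spec : PyramidSpec

    Returns
    -------
    PyramidDecomposition
    """
    a = _validate_image(img, spec.n_scales)
    dft = np.fft.fftshift(np.fft.fft2(a))
    r, theta = _polar_grids(a.shape)

    hi0 = _hi_mask(r, np.pi)
    lo0 = np.sqrt(np.clip(1.0 - hi0 ** 2, 0.0, 1.0))
    highpass = np.fft.ifft2(np.fft.ifftshift(dft * hi0)).real
    lodft = dft * lo0

    subbands: Dict[Tuple[int, int], np.ndarray] = {}
    lowpass_levels = [np.fft.ifft2(np.fft.ifftshift(lodft)).real]
    for s in range(1, spec.n_scales + 1):
        r, theta = _polar_grids(lodft.shape)
        hi = _hi_mask(r, np.pi / 2.0)
        for k, ang in enumerate(_angular_masks(theta, spec.n_orientations)):
            band = np.fft.ifft2(np.fft.ifftshift(lodft * hi * ang))
            subbands[(s, k + 1)] = band
        lo = np.sqrt(np.clip(1.0 - hi ** 2, 0.0, 1.0))
        lodft = _crop_center_half(lodft * lo) / 2.0  # unitary downsampling
        lowpass_levels.append(np.fft.ifft2(np.fft.ifftshift(lodft)).real)

    lowpass = lowpass_levels[-1]
    return PyramidDecomposition(
        subbands=subbands,
        highpass_residual=highpass,
        lowpass_residual=lowpass,
        spec=spec,
        lowpass_levels=lowpass_levels,
    )


def subband_energy(dec: PyramidDecomposition) -> pd.Series:
    """Mean squared magnitude per (scale, orientation), plus residual energies.

    Ordering is scale-major (fine to coarse), then orientation, then the
    highpass and lowpass residual terms.  For a 6-scale / 12-orientation
    pyramid the vector has exactly 74 entries.
    """
    names, values = [], []
    for s in range(1, dec.spec.n_scales + 1):
        for o in range(1, dec.spec.n_orientations + 1):
            b = dec.subbands[(s, o)]
            names.append(f"energy_s{s}_o{o}")
            values.append(float(np.mean(np.abs(b) ** 2)))
    names.append("energy_highpass")
    values.append(float(np.mean(dec.highpass_residual ** 2)))
    names.append("energy_lowpass")
    values.append(float(np.mean(dec.lowpass_residual ** 2)))
    return pd.Series(values, index=names, dtype=float)


def total_energy(dec: PyramidDecomposition) -> float:
    """Total signal energy reassembled from the decomposition.

    With the unitary downsampling convention this equals ``sum(img**2)``
    up to floating-point error (tight-frame property).  The factor 1/2 on the
    complex subbands converts analytic-band energy to real-band energy.
    """
    tot = float(np.sum(dec.highpass_residual ** 2))
    for b in dec.subbands.values():
        tot += 0.5 * float(np.sum(np.abs(b) ** 2))
    tot += float(np.sum(dec.lowpass_residual ** 2))
    return tot


def subband_frequency_cpd(spec: PyramidSpec, scale: int, px_per_deg: float) -> float:
    """Center frequency of a scale in cycles per degree of visual angle.

    Scale ``s`` peaks at ``pi / 2**s`` rad/sample, i.e. ``2**-(s+1)``
    cycles/pixel; multiplying by the viewing geometry (pixels per degree)
    gives cycles per degree.  Consecutive scales are exactly one octave apart.
    """
    if not 1 <= scale <= spec.n_scales:
        raise ValueError(f"scale must be in 1..{spec.n_scales}, got {scale}")
    if px_per_deg <= 0:
        raise ValueError("px_per_deg must be positive")
    return px_per_deg * 2.0 ** (-(scale + 1))
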