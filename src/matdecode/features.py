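"""Image-statistic families for material photographs.

Three feature families describe each luminance image:

``pixel``
    Six marginal statistics of the gray-level distribution: mean, variance,
    skewness, kurtosis (non-excess; Gaussian = 3), minimum and maximum.

``filter``
    877 texture-model statistics computed from a 4-scale / 4-orientation
    complex steerable pyramid: marginal pixel statistics, skew/kurtosis and
    central autocorrelations of the lowpass images, autocorrelations and
    means of subband magnitudes, cross-orientation and cross-scale magnitude
    correlations, cross-scale relative-phase statistics, and residual
    variances.  ``filter_statistics_breakdown`` itemizes the composition.

``spectral``
    74 subband energies of a 6-scale / 12-orientation pyramid
    (72 oriented bands + highpass + lowpass residual).
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .pyramid import PyramidSpec, build_pyramid, subband_energy

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "rgb_to_luminance",
    "pixel_statistics",
    "filter_statistics",
    "filter_statistics_breakdown",
    "spectral_statistics",
    "extract_features",
    "PixelStatisticsExtractor",
    "FilterStatisticsExtractor",
    "SpectralStatisticsExtractor",
]

#: Rec. 709 relative channel luminances, used when no display calibration is
#: supplied (the display primaries behind a given photo set are usually
#: unpublished).
REC709_WEIGHTS = (0.2126, 0.7152, 0.0722)

FAMILIES = ("pixel", "filter", "spectral")


@dataclass
class FeatureSet:
    """Named feature matrix (images x features) for one statistic family."""

    family: str
    matrix: pd.DataFrame  # index = image_id, columns = feature names

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.matrix.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def image_ids(self) -> List[str]:
        return list(self.matrix.index)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path, index_label="image_id")

    @classmethod
    def from_csv(cls, path, family: str) -> "FeatureSet":
        return cls(family=family, matrix=pd.read_csv(path, index_col="image_id"))


def rgb_to_luminance(rgb: np.ndarray,
                     channel_luminances: Sequence[float] = REC709_WEIGHTS) -> np.ndarray:
    """Convert a linear RGB image to luminance by channel-weighted summation."""
    a = np.asarray(rgb, dtype=float)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {a.shape}")
    w = np.asarray(channel_luminances, dtype=float)
    if w.shape != (3,) or np.any(w < 0):
        raise ValueError("channel_luminances must be 3 nonnegative weights")
    return a @ w


def _moments(x: np.ndarray) -> tuple:
    """(mean, var, skew, kurt) with population (biased) normalization.

    Degenerate (zero-variance) inputs get skew 0 and kurtosis 3 by convention
    so that downstream feature matrices stay complete.
    """
    m = float(np.mean(x))
    v = float(np.var(x))
    if v <= 1e-24 * max(1.0, m * m):
        logger.warning("zero-variance input: skew/kurtosis set to 0/3 by convention")
        return m, v, 0.0, 3.0
    return (m, v,
            float(sps.skew(x, axis=None, bias=True)),
            float(sps.kurtosis(x, axis=None, fisher=False, bias=True)))


def pixel_statistics(img: np.ndarray) -> pd.Series:
    """Marginal statistics of the gray-level distribution (6 values)."""
    a = np.asarray(img, dtype=float)
    if a.size == 0:
        raise ValueError("empty image")
    m, v, sk, ku = _moments(a)
    return pd.Series(
        [m, v, sk, ku, float(a.min()), float(a.max())],
        index=["px_mean", "px_var", "px_skew", "px_kurt", "px_min", "px_max"],
        dtype=float,
    )


def _autocov_central(x: np.ndarray, na: int) -> np.ndarray:
    """Central na x na block of the circular autocovariance, deduplicated.

    The autocovariance is centrally symmetric (``ac(-lag) == ac(lag)``), so
    only the first ``(na**2 + 1) // 2`` entries of the raster-ordered block
    (up to and including the zero-lag center) are kept.  The last kept entry
    is the zero-lag value, i.e. the variance.
    """
    h, w = x.shape
    if na > h or na > w:
        raise ValueError(
            f"autocorrelation neighborhood {na} exceeds grid size {x.shape}; "
            "use a larger image"
        )
    xc = x - x.mean()
    f = np.fft.fft2(xc)
    ac = np.fft.fftshift(np.fft.ifft2(np.abs(f) ** 2).real) / x.size
    cy, cx = h // 2, w // 2
    half = na // 2
    block = ac[cy - half: cy + half + 1, cx - half: cx + half + 1]
    return block.ravel()[: (na * na + 1) // 2]


def _autocov_lag_names(prefix: str, na: int) -> List[str]:
    names = []
    half = na // 2
    n_keep = (na * na + 1) // 2
    k = 0
    for dy in range(-half, half + 1):
        for dx in range(-half, half + 1):
            if k >= n_keep:
                break
            names.append(f"{prefix}_dy{dy}_dx{dx}")
            k += 1
    return names[:n_keep]


def _upsample2(band: np.ndarray) -> np.ndarray:
    """Double both dimensions by centered Fourier zero-padding (amplitude kept)."""
    h, w = band.shape
    f = np.fft.fftshift(np.fft.fft2(band))
    pad = np.zeros((2 * h, 2 * w), dtype=complex)
    pad[h // 2: h // 2 + h, w // 2: w // 2 + w] = f
    return np.fft.ifft2(np.fft.ifftshift(pad)) * 4.0


def filter_statistics_breakdown(spec: PyramidSpec = PyramidSpec(4, 4),
                                na_lowpass: int = 7,
                                na_mag: int = 9) -> "OrderedDict[str, int]":
    """Additive composition of the filter-statistics vector.

    Under the shipped defaults (4 scales, 4 orientations, lowpass
    autocorrelation window 7, magnitude autocorrelation window 9) the blocks
    sum to exactly 877.
    """
    nsc, nor = spec.n_scales, spec.n_orientations
    d_lo = (na_lowpass ** 2 + 1) // 2
    d_mag = (na_mag ** 2 + 1) // 2
    return OrderedDict(
        [
            ("pixel_statistics", 6),
            ("lowpass_skew_kurtosis", 2 * (nsc + 1)),
            (f"lowpass_autocorrelation[{na_lowpass}x{na_lowpass} dedup]",
             (nsc + 1) * d_lo),
            (f"magnitude_autocorrelation[{na_mag}x{na_mag} dedup]",
             nsc * nor * d_mag),
            ("magnitude_means", nsc * nor + 2),
            ("cross_orientation_magnitude_corr", nor * (nor - 1) // 2 * nsc),
            ("cross_scale_magnitude_corr", nor * (nsc - 1)),
            ("cross_scale_phase", 2 * nor * (nsc - 1)),
            ("residual_variances", 2),
        ]
    )


def filter_statistics(img: np.ndarray,
                      spec: PyramidSpec = PyramidSpec(4, 4),
                      na_lowpass: int = 7,
                      na_mag: int = 9) -> pd.Series:
    """Texture-model statistics of one luminance image (877 under defaults).

    Blocks, in order (see :func:`filter_statistics_breakdown`):

    1. pixel statistics of the image (6);
    2. skew and kurtosis of the lowpass image at each pyramid level (10);
    3. central samples of the autocovariance of each lowpass level over an
       ``na_lowpass`` x ``na_lowpass`` neighborhood, symmetry-deduplicated;
    4. the same for each subband's magnitude (``na_mag`` window);
    5. mean magnitude per subband and per residual band;
    6. cross-orientation magnitude covariances within each scale;
    7. cross-scale magnitude covariance with the same-orientation parent
       (parent upsampled to the child grid);
    8. real and imaginary parts of the mean product of each coefficient with
       its phase-doubled parent;
    9. variances of the highpass and lowpass residuals.
    """
    a = np.asarray(img, dtype=float)
    dec = build_pyramid(a, spec)
    nsc, nor = spec.n_scales, spec.n_orientations
    names: List[str] = []
    values: List[float] = []

    def add(nm: Iterable[str], vals: Iterable[float]) -> None:
        names.extend(nm)
        values.extend(float(v) for v in vals)

    # 1. pixel statistics
    px = pixel_statistics(a)
    add(px.index, px.to_numpy())

    # 2. skew/kurtosis of lowpass levels
    for lev, lo in enumerate(dec.lowpass_levels):
        _, _, sk, ku = _moments(lo)
        add([f"lpSkew_l{lev}", f"lpKurt_l{lev}"], [sk, ku])

    # 3. lowpass autocovariances
    for lev, lo in enumerate(dec.lowpass_levels):
        ac = _autocov_central(lo, na_lowpass)
        add(_autocov_lag_names(f"acLow_l{lev}", na_lowpass), ac)

    # magnitudes, centered once for reuse
    mags = {k: np.abs(b) for k, b in dec.subbands.items()}
    mag_means = {k: m.mean() for k, m in mags.items()}
    cmag = {k: m - mag_means[k] for k, m in mags.items()}

    # 4. magnitude autocovariances
    for s in range(1, nsc + 1):
        for o in range(1, nor + 1):
            ac = _autocov_central(mags[(s, o)], na_mag)
            add(_autocov_lag_names(f"acMag_s{s}_o{o}", na_mag), ac)

    # 5. magnitude means (oriented bands + residuals)
    for s in range(1, nsc + 1):
        for o in range(1, nor + 1):
            add([f"magMean_s{s}_o{o}"], [mag_means[(s, o)]])
    add(["magMean_highpass", "magMean_lowpass"],
        [np.abs(dec.highpass_residual).mean(), np.abs(dec.lowpass_residual).mean()])

    # 6. cross-orientation magnitude covariances within scale
    for s in range(1, nsc + 1):
        for i in range(1, nor + 1):
            for j in range(i + 1, nor + 1):
                cov = float(np.mean(cmag[(s, i)] * cmag[(s, j)]))
                add([f"xoriMag_s{s}_o{i}o{j}"], [cov])

    # 7./8. cross-scale statistics against the upsampled parent band
    for s in range(1, nsc):
        for o in range(1, nor + 1):
            parent = _upsample2(dec.subbands[(s + 1, o)])
            pmag = np.abs(parent)
            cov = float(np.mean(cmag[(s, o)] * (pmag - pmag.mean())))
            add([f"xsclMag_s{s}_o{o}"], [cov])
            # phase-doubled parent, magnitude preserved
            pd2 = parent ** 2 / np.maximum(pmag, 1e-30)
            cre = float(np.mean(dec.subbands[(s, o)].real * pd2.real))
            cim = float(np.mean(dec.subbands[(s, o)].real * pd2.imag))
            add([f"phaseRe_s{s}_o{o}", f"phaseIm_s{s}_o{o}"], [cre, cim])

    # 9. residual variances
    add(["varHighpass", "varLowpass"],
        [np.var(dec.highpass_residual), np.var(dec.lowpass_residual)])

    out = pd.Series(values, index=names, dtype=float)
    expected = sum(filter_statistics_breakdown(spec, na_lowpass, na_mag).values())
    assert len(out) == expected, f"internal count mismatch: {len(out)} != {expected}"
    return out


def spectral_statistics(img: np.ndarray,
                        spec: PyramidSpec = PyramidSpec(6, 12)) -> pd.Series:
    """Subband energies of a 6-scale / 12-orientation pyramid (74 values)."""
    return subband_energy(build_pyramid(np.asarray(img, dtype=float), spec))


_FAMILY_FUNCS = {
    "pixel": pixel_statistics,
    "filter": filter_statistics,
    "spectral": spectral_statistics,
}


def extract_features(images: Sequence[np.ndarray],
                     family: str,
                     image_ids: Optional[Sequence[str]] = None,
                     **kwargs) -> FeatureSet:
    """Compute one statistic family for a stack of luminance images."""
    if family not in _FAMILY_FUNCS:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if image_ids is None:
        image_ids = [f"img{i:03d}" for i in range(len(images))]
    if len(image_ids) != len(images):
        raise ValueError("image_ids length does not match images")
    func = _FAMILY_FUNCS[family]
    rows = [func(im, **kwargs) for im in images]
    matrix = pd.DataFrame(rows, index=pd.Index(image_ids, name="image_id"))
    return FeatureSet(family=family, matrix=matrix)


class _FamilyExtractor(TransformerMixin, BaseEstimator):
    """sklearn-style transformer over a list/array of 2-D luminance images."""

    _family: str = ""

    def fit(self, X, y=None):
        self.n_features_in_ = 1  # images, not tabular features
        return self

    def transform(self, X) -> np.ndarray:
        fs = extract_features(list(X), self._family, **self._kwargs())
        self.feature_names_ = list(fs.matrix.columns)
        return fs.values

    def get_feature_names_out(self, input_features=None):
        return np.asarray(getattr(self, "feature_names_", []), dtype=object)

    def _kwargs(self) -> dict:
        return {}


class PixelStatisticsExtractor(_FamilyExtractor):
    _family = "pixel"


class SpectralStatisticsExtractor(_FamilyExtractor):
    _family = "spectral"

    def __init__(self, n_scales: int = 6, n_orientations: int = 12):
        self.n_scales = n_scales
        self.n_orientations = n_orientations

    def _kwargs(self) -> dict:
        return {"spec": PyramidSpec(self.n_scales, self.n_orientations)}


class FilterStatisticsExtractor(_FamilyExtractor):
    _family = "filter"

    def __init__(self, n_scales: int = 4, n_orientations: int = 4,
                 na_lowpass: int = 7, na_mag: int = 9):
        self.n_scales = n_scales
        self.n_orientations = n_orientations
        self.na_lowpass = na_lowpass
        self.na_mag = na_mag

    def _kwargs(self) -> dict:
        return {"spec": PyramidSpec(self.n_scales, self.n_orientations),
                "na_lowpass": self.na_lowpass, "na_mag": self.na_mag}
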