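"""Synthetic surface images, Likert ratings, and beta volumes.

The generator emulates the statistical structure the analysis pipeline
assumes, so every downstream stage can be exercised without any real data:

* **Textures** — filtered Gaussian noise with power spectrum ``f**(-alpha)``
  (slope drawn per image) and mild orientation anisotropy, optionally with
  additive gratings.  Spectral slope controls the balance of fine versus
  coarse structure, the visual correlate of surface roughness.
* **Ratings** — for a coupled property, a rank-monotone map from a driving
  image statistic to a latent 1..7 score, plus per-rater Gaussian noise,
  rounded and clipped (Likert).  A null property ("hardness"-like) draws its
  latent scores independently of every image statistic.
* **Beta volumes** — per participant, a contiguous blob of signal voxels
  inside an ROI carries a random linear readout of the driving image
  statistics (``w . x_i``) plus Gaussian noise; every other gray-matter voxel
  is pure noise.  This is the weakest structure under which linear decoding
  of property groups from voxel patterns can succeed.

All generators are deterministic given ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grouping import PropertyGroups
from .neurodecoding import BetaVolume, VoxelMask

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "generate_textures",
    "generate_ratings",
    "generate_betas",
    "BetaSimulation",
    "image_driving_statistics",
    "default_config",
]

DRIVING_STATISTICS = ("hf_energy", "contrast", "mean_lum")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters for the synthetic dataset.

    Defaults mirror the emulated study: 84 surface photographs, 6 raters,
    15 scanned participants, one beta map per stimulus.  ``coupling`` maps
    each property to the image statistic that drives its ratings (None for
    a property with no visual correlate).
    """

    n_images: int = 84
    image_size: int = 256          # divisible by 2**6 for the spectral pyramid
    n_raters: int = 6
    n_participants: int = 15
    volume_shape: Tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 3.0
    roi_radius: int = 4            # voxels; ROI sphere at gray-matter center
    signal_voxels: int = 30        # contiguous informative voxels inside the ROI
    noise_sd: float = 1.0          # beta noise SD
    signal_amplitude: float = 0.25  # scale of w . x relative to noise
    rating_noise_sd: float = 0.75  # per-rater noise, Likert-scale units
    property_noise_sd: float = 1.5  # image-level component of the latent score
    #   not explained by any image statistic (perceived properties depend on
    #   more than the driving statistic); shared by all raters of an image
    coupling: Tuple[Tuple[str, Optional[str]], ...] = (
        ("roughness", "hf_energy"),
        ("texturedness", "contrast"),
        ("hardness", None),
    )
    alpha_range: Tuple[float, float] = (0.5, 2.5)   # spectral slope f**-alpha
    anisotropy_max: float = 0.6
    grating_fraction: float = 0.0  # fraction of images with an added grating
    beta_signal: str = "statistic"  # "statistic" | "group" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_images", "image_size", "n_raters", "n_participants"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.image_size % 64:
            raise ValueError(
                f"image_size {self.image_size} must be divisible by 2**6 = 64 "
                "(six pyramid scales)"
            )
        if any(d <= 0 for d in self.volume_shape):
            raise ValueError("volume_shape entries must be positive")
        if self.beta_signal not in ("statistic", "group", "none"):
            raise ValueError(f"unknown beta_signal {self.beta_signal!r}")
        for prop, stat in self.coupling:
            if stat is not None and stat not in DRIVING_STATISTICS:
                raise ValueError(
                    f"coupling for {prop!r} names unknown statistic {stat!r}; "
                    f"choose from {DRIVING_STATISTICS}"
                )

    @property
    def coupling_dict(self) -> Dict[str, Optional[str]]:
        return dict(self.coupling)

    @property
    def properties(self) -> List[str]:
        return [p for p, _ in self.coupling]

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    def image_ids(self) -> List[str]:
        return [f"img{i:03d}" for i in range(self.n_images)]


def default_config(**overrides) -> SyntheticConfig:
    return replace(SyntheticConfig(), **overrides) if overrides else SyntheticConfig()


# ------------------------------------------------------------------ textures

def generate_textures(cfg: SyntheticConfig) -> List[np.ndarray]:
    """Noise textures spanning a range of spectral slopes and anisotropies.

    Each image is Gaussian noise shaped to a ``f**(-alpha)`` radial spectrum
    with an orientation gain ``1 + a*cos(2(theta-theta0))``, normalized to
    mean 0.5 / SD 0.15 and clipped to [0, 1] (nonnegative luminance).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.image_size
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    r = np.hypot(fy, fx)
    theta = np.arctan2(fy, fx)
    r[0, 0] = 1.0  # DC handled by normalization

    images = []
    for _ in range(cfg.n_images):
        alpha = rng.uniform(*cfg.alpha_range)
        aniso = rng.uniform(0.0, cfg.anisotropy_max)
        theta0 = rng.uniform(0.0, np.pi)
        gain = np.sqrt(np.maximum(r, 1e-12) ** (-alpha)
                       * (1.0 + aniso * np.cos(2.0 * (theta - theta0))))
        gain[0, 0] = 0.0
        spec = np.fft.fft2(rng.standard_normal((n, n))) * gain
        img = np.fft.ifft2(spec).real
        img = (img - img.mean()) / max(img.std(), 1e-12) * 0.15 + 0.5
        if cfg.grating_fraction > 0 and rng.uniform() < cfg.grating_fraction:
            f = rng.choice([1 / 32, 1 / 16, 1 / 8])
            phi = rng.uniform(0, 2 * np.pi)
            ang = rng.uniform(0, np.pi)
            yy = np.arange(n)[:, None]
            xx = np.arange(n)[None, :]
            img = img + 0.08 * np.sin(
                2 * np.pi * f * (np.cos(ang) * yy + np.sin(ang) * xx) + phi)
        images.append(np.clip(img, 0.0, 1.0))
    return images


def image_driving_statistics(images: Sequence[np.ndarray]) -> pd.DataFrame:
    """Simple FFT-based statistics used to couple ratings and betas to images.

    Deliberately independent of the steerable pyramid so that the generator
    and the analysis pipeline share no code path:

    * ``hf_energy`` — fraction of non-DC spectral power above Nyquist/4;
    * ``contrast`` — pixel standard deviation;
    * ``mean_lum`` — pixel mean.
    """
    rows = []
    for img in images:
        a = np.asarray(img, dtype=float)
        f = np.fft.fft2(a - a.mean())
        p = np.abs(f) ** 2
        fy = np.fft.fftfreq(a.shape[0])[:, None]
        fx = np.fft.fftfreq(a.shape[1])[None, :]
        r = np.hypot(fy, fx)
        total = p.sum()
        hf = p[r > 0.125].sum() / total if total > 0 else 0.0
        rows.append({"hf_energy": float(hf),
                     "contrast": float(a.std()),
                     "mean_lum": float(a.mean())})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- ratings

def generate_ratings(images: Sequence[np.ndarray], cfg: SyntheticConfig
                     ) -> pd.DataFrame:
    """Likert rating table (image_id, property, rater, score).

    Coupled properties: latent score = rank-monotone map of the driving
    statistic onto [1, 7], plus an image-level N(0, property_noise_sd)
    idiosyncrasy shared by all raters (the part of the percept no image
    statistic explains); each rater then adds N(0, rating_noise_sd), rounds
    and clips.  Null properties draw the latent scores independently of
    every image statistic.
    """
    coupling = cfg.coupling_dict
    stats = image_driving_statistics(images)
    if len(stats) != cfg.n_images:
        raise ValueError(
            f"got {len(stats)} images but config specifies {cfg.n_images}")
    ids = cfg.image_ids()
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_images
    rows = []
    for prop in cfg.properties:
        stat = coupling[prop]
        if stat is None:
            latent = rng.uniform(1.0, 7.0, size=n)
        else:
            ranks = rankdata(stats[stat].to_numpy())
            latent = (1.0 + 6.0 * (ranks - 1) / max(n - 1, 1)
                      + rng.normal(0.0, cfg.property_noise_sd, size=n))
        for rater in range(cfg.n_raters):
            noisy = latent + rng.normal(0.0, cfg.rating_noise_sd, size=n)
            scores = np.clip(np.rint(noisy), 1, 7).astype(int)
            rows.extend(
                {"image_id": ids[i], "property": prop,
                 "rater": f"rater{rater}", "score": int(scores[i])}
                for i in range(n))
    return pd.DataFrame(rows, columns=["image_id", "property", "rater", "score"])


# --------------------------------------------------------------------- betas

def _sphere_mask(shape: Tuple[int, int, int], center: np.ndarray,
                 radius: float) -> np.ndarray:
    grid = np.indices(shape)
    d2 = sum((grid[i] - center[i]) ** 2 for i in range(3))
    return d2 <= radius ** 2


def _ellipsoid_mask(shape: Tuple[int, int, int], frac: float = 0.42) -> np.ndarray:
    grid = np.indices(shape).astype(float)
    c = (np.asarray(shape) - 1) / 2.0
    radii = np.maximum(np.asarray(shape) * frac, 1.0)
    d2 = sum(((grid[i] - c[i]) / radii[i]) ** 2 for i in range(3))
    return d2 <= 1.0


class BetaSimulation:
    """Deterministic lazy generator of per-participant beta volumes.

    The full default dataset (15 participants x 84 volumes of 40x48x40
    voxels) is large, so volumes are synthesized on demand; the same
    participant always yields bit-identical data.
    """

    def __init__(self, signal: pd.DataFrame, cfg: SyntheticConfig,
                 groups: Optional[PropertyGroups] = None):
        self.cfg = cfg
        self.image_ids = list(signal.index)
        if len(self.image_ids) != cfg.n_images:
            raise ValueError("signal table does not match config n_images")

        shape = cfg.volume_shape
        self.gm_mask = VoxelMask(_ellipsoid_mask(shape), cfg.affine,
                                 role="gray_matter")
        center = (np.asarray(shape) - 1) // 2
        roi = _sphere_mask(shape, center, cfg.roi_radius) & self.gm_mask.data
        self.roi_mask = VoxelMask(roi, cfg.affine, role="roi")
        roi_coords = np.argwhere(roi)
        if cfg.signal_voxels > len(roi_coords):
            raise ValueError(
                f"signal_voxels={cfg.signal_voxels} exceeds ROI size "
                f"{len(roi_coords)}")
        # contiguous blob: the signal_voxels ROI voxels closest to the center
        d2 = ((roi_coords - center) ** 2).sum(axis=1)
        order = np.lexsort((roi_coords[:, 2], roi_coords[:, 1],
                            roi_coords[:, 0], d2))
        self.signal_coords = roi_coords[order[: cfg.signal_voxels]]
        sig = np.zeros(shape, dtype=bool)
        if cfg.signal_voxels:
            sig[tuple(self.signal_coords.T)] = True
        self.signal_mask = VoxelMask(sig, cfg.affine, role="roi")

        if cfg.beta_signal == "group":
            if groups is None:
                raise ValueError("beta_signal='group' requires groups")
            lab = groups.labels()
            x = np.array([1.0 if lab.get(i) == "high" else 0.0
                          for i in self.image_ids])[:, None]
        elif cfg.beta_signal == "none":
            x = np.zeros((cfg.n_images, 0))
        else:
            x = signal.to_numpy(dtype=float)
        # z-score signal columns (constant columns contribute nothing)
        sd = x.std(axis=0)
        keep = sd > 0
        self._x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]

    @property
    def masks(self) -> Dict[str, VoxelMask]:
        return {"gray_matter": self.gm_mask, "roi": self.roi_mask,
                "signal": self.signal_mask}

    def participant_ids(self) -> List[str]:
        return [f"sub{p:02d}" for p in range(self.cfg.n_participants)]

    def participant_stack(self, participant: int) -> np.ndarray:
        """(n_images, *volume_shape) float32 array for one participant."""
        cfg = self.cfg
        rng = np.random.default_rng([cfg.seed, 7919, participant])
        n_sig, n_feat = len(self.signal_coords), self._x.shape[1]
        w = rng.standard_normal((n_sig, n_feat)) if n_feat else np.zeros((n_sig, 0))
        gm_idx = np.argwhere(self.gm_mask.data)
        n_gm = len(gm_idx)
        noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_images, n_gm))
        stack = np.zeros((cfg.n_images,) + tuple(cfg.volume_shape),
                         dtype=np.float32)
        stack[(slice(None),) + tuple(gm_idx.T)] = noise
        if n_sig and n_feat:
            signal = cfg.signal_amplitude * self._x @ w.T  # (n_images, n_sig)
            stack[(slice(None),) + tuple(self.signal_coords.T)] += \
                signal.astype(np.float32)
        return stack

    def participant_betas(self, participant: int) -> List[BetaVolume]:
        stack = self.participant_stack(participant)
        pid = self.participant_ids()[participant]
        return [BetaVolume(data=stack[i], affine=self.cfg.affine,
                           image_id=img, participant_id=pid)
                for i, img in enumerate(self.image_ids)]


def generate_betas(features, groups: Optional[PropertyGroups],
                   cfg: SyntheticConfig,
                   participants: Optional[Sequence[int]] = None
                   ) -> Tuple[List[BetaVolume], Dict[str, VoxelMask]]:
    """Beta volumes whose signal voxels carry a linear readout of image statistics.

    Parameters
    ----------
    features : DataFrame (images x signal columns) or FeatureSet
        The image statistics driving the voxel signal (z-scored internally).
    groups : PropertyGroups, optional
        Required when ``cfg.beta_signal == 'group'`` (signal = group
        indicator, the perfectly separable case).
    cfg : SyntheticConfig
    participants : indices of participants to synthesize (default: all).

    Returns the flat list of BetaVolume (participant-major) and the masks.
    For memory-friendly per-participant access use :class:`BetaSimulation`.
    """
    matrix = getattr(features, "matrix", features)
    sim = BetaSimulation(matrix, cfg, groups=groups)
    if participants is None:
        participants = range(cfg.n_participants)
    betas: List[BetaVolume] = []
    for p in participants:
        betas.extend(sim.participant_betas(p))
    return betas, sim.masks
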