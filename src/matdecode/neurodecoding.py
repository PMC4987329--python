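"""ROI and searchlight multivoxel pattern analysis on per-stimulus beta maps.

Inputs are one 3-D coefficient volume per stimulus (GLM betas estimated
upstream) plus boolean voxel masks: retinotopic ROIs for region-based
decoding and a gray-matter mask for the whole-volume searchlight.  The
classifier throughout is the pooled-diagonal-covariance linear discriminant
with leave-one-out cross-validation (see :mod:`matdecode.classification`).

Searchlight: a sphere of a given voxel radius is centered on every
gray-matter voxel; the in-mask voxels inside the sphere form the feature
vector and the LOO accuracy is written back to the center voxel.  Sphere
members outside the mask or volume are dropped (not zero-filled).  A
chance-subtracted map (accuracy - 0.5) accompanies each accuracy map, and a
second-level one-sample t-test across participants with 26-connectivity
cluster reporting summarizes the group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .classification import _loo_diag_predict
from .grouping import PropertyGroups

__all__ = [
    "BetaVolume",
    "VoxelMask",
    "SearchlightMap",
    "GroupLevelResult",
    "roi_feature_matrix",
    "sphere_offsets",
    "searchlight",
    "group_level_map",
    "save_volume",
    "load_volume",
    "save_beta_stack",
    "load_beta_stack",
]

CHANCE = 0.5  # balanced two-class designs


@dataclass
class BetaVolume:
    """One 3-D coefficient map for one stimulus of one participant."""

    data: np.ndarray
    affine: np.ndarray
    image_id: str
    participant_id: str = ""


@dataclass
class VoxelMask:
    """Boolean voxel mask with geometry; role is 'roi' or 'gray_matter'."""

    data: np.ndarray
    affine: np.ndarray
    role: str = "roi"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)


@dataclass
class SearchlightMap:
    """Per-participant searchlight accuracy map (NaN outside mask centers)."""

    accuracy: np.ndarray
    chance_subtracted: np.ndarray
    radius: float
    affine: np.ndarray
    participant_id: str = ""


@dataclass
class GroupLevelResult:
    """Second-level t map with suprathreshold clusters."""

    t_map: np.ndarray
    t_critical: float
    df: int
    alpha: float
    clusters: pd.DataFrame
    affine: np.ndarray


def _check_geometry(a_affine: np.ndarray, b_affine: np.ndarray,
                    a_shape, b_shape) -> None:
    if tuple(a_shape) != tuple(b_shape) or not np.allclose(a_affine, b_affine):
        raise ValueError(
            "geometry mismatch:\n"
            f"shapes {tuple(a_shape)} vs {tuple(b_shape)}\n"
            f"affine A:\n{a_affine}\naffine B:\n{b_affine}"
        )


def roi_feature_matrix(betas: Sequence[BetaVolume], mask: VoxelMask
                       ) -> Tuple[np.ndarray, List[str]]:
    """Vectorize each beta volume over the in-mask voxels.

    Returns an (images x voxels) matrix plus the image ids in row order.
    Voxels are ordered by C-order linear index of the mask grid.
    """
    if not np.any(mask.data):
        raise ValueError("mask selects no voxels")
    rows, ids = [], []
    for b in betas:
        _check_geometry(b.affine, mask.affine, b.data.shape, mask.data.shape)
        rows.append(np.asarray(b.data, dtype=float)[mask.data])
        ids.append(b.image_id)
    return np.vstack(rows), ids


def sphere_offsets(radius: float) -> np.ndarray:
    """All integer (dz, dy, dx) offsets with Euclidean norm <= radius."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dz ** 2 + dy ** 2 + dx ** 2 <= radius ** 2
    return np.stack([dz[keep], dy[keep], dx[keep]], axis=1)


def _group_label_vector(image_ids: Sequence[str], groups: PropertyGroups
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Row indices of group members and their 0/1 (low/high) labels."""
    lab = groups.labels()
    idx, y = [], []
    for i, img in enumerate(image_ids):
        if img in lab.index:
            idx.append(i)
            y.append(1 if lab[img] == "high" else 0)
    idx, y = np.asarray(idx, dtype=int), np.asarray(y, dtype=int)
    if (y == 0).sum() < 2 or (y == 1).sum() < 2:
        raise ValueError("need at least 2 images per group in the beta stack")
    return idx, y


def searchlight(betas: Sequence[BetaVolume], gm_mask: VoxelMask,
                groups: PropertyGroups, radius: float = 4,
                radius_mm: bool = False) -> SearchlightMap:
    """Whole-volume searchlight decoding of a property's high/low groups.

    Parameters
    ----------
    betas : beta volumes of ONE participant, one per stimulus.
    gm_mask : gray-matter mask restricting both centers and features.
    groups : high/low image groups for the property being decoded.
    radius : sphere radius in voxel units by default.
    radius_mm : interpret ``radius`` in millimetres using the affine's voxel
        size (isotropic voxel size required).

    Returns
    -------
    SearchlightMap with LOO accuracy at every in-mask center (NaN elsewhere)
    and the chance-subtracted variant (accuracy - 0.5).
    """
    X_all, ids = roi_feature_matrix(betas, gm_mask)
    idx, y = _group_label_vector(ids, groups)
    X_all = X_all[idx]

    if radius_mm:
        vox = np.abs(np.diag(gm_mask.affine)[:3])
        if not np.allclose(vox, vox[0]):
            raise ValueError("radius_mm requires isotropic voxels")
        radius = radius / vox[0]

    shape = gm_mask.data.shape
    col_of = np.full(shape, -1, dtype=np.int64)
    coords = np.argwhere(gm_mask.data)
    col_of[tuple(coords.T)] = np.arange(len(coords))

    offs = sphere_offsets(radius)
    acc = np.full(shape, np.nan)
    dims = np.asarray(shape)
    for c in coords:
        pts = c + offs
        ok = np.all((pts >= 0) & (pts < dims), axis=1)
        cols = col_of[tuple(pts[ok].T)]
        cols = cols[cols >= 0]
        if cols.size == 0:
            continue  # undefined center
        pred, _ = _loo_diag_predict(X_all[:, cols], y)
        acc[tuple(c)] = np.mean(pred == y)

    participant = betas[0].participant_id if betas else ""
    return SearchlightMap(accuracy=acc, chance_subtracted=acc - CHANCE,
                          radius=float(radius), affine=gm_mask.affine,
                          participant_id=participant)


def group_level_map(maps: Sequence[SearchlightMap] | Sequence[np.ndarray],
                    alpha: float = 0.001, cluster_k: int = 5,
                    affine: Optional[np.ndarray] = None) -> GroupLevelResult:
    """Second-level one-sample t-test of chance-subtracted accuracy maps.

    A one-tailed test against 0 (accuracy above chance) with df = n - 1;
    voxels exceeding the critical t at the given alpha are grouped into
    26-connectivity clusters and clusters larger than ``cluster_k`` voxels
    are tabulated with peak voxel/mm coordinates and peak t.
    """
    if len(maps) < 2:
        raise ValueError("need maps from at least 2 participants")
    arrays = []
    for m in maps:
        if isinstance(m, SearchlightMap):
            arrays.append(m.chance_subtracted)
            if affine is None:
                affine = m.affine
        else:
            arrays.append(np.asarray(m, dtype=float))
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError(f"inconsistent grids: {[a.shape for a in arrays]}")
    if affine is None:
        affine = np.eye(4)
    stack = np.stack(arrays)
    defined = np.all(np.isfinite(stack), axis=0)

    n = len(arrays)
    df = n - 1
    t_map = np.full(shape, np.nan)
    vals = stack[:, defined]  # (n, n_defined)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_map[defined] = mean / (sd / np.sqrt(n))

    t_crit = float(sps.t.ppf(1.0 - alpha, df))
    supra = np.where(np.isfinite(t_map), t_map > t_crit, False)
    labels, n_lab = ndimage.label(supra, structure=np.ones((3, 3, 3), dtype=int))
    rows = []
    for lab in range(1, n_lab + 1):
        vox = np.argwhere(labels == lab)
        size = len(vox)
        if size <= cluster_k:
            continue
        tv = t_map[tuple(vox.T)]
        peak = vox[np.argmax(tv)]
        mm = (affine @ np.append(peak, 1.0))[:3]
        rows.append({"cluster": lab, "size": size,
                     "peak_t": float(tv.max()),
                     "x_vox": int(peak[0]), "y_vox": int(peak[1]),
                     "z_vox": int(peak[2]),
                     "x_mm": float(mm[0]), "y_mm": float(mm[1]),
                     "z_mm": float(mm[2])})
    clusters = pd.DataFrame(
        rows, columns=["cluster", "size", "peak_t", "x_vox", "y_vox",
                       "z_vox", "x_mm", "y_mm", "z_mm"])
    return GroupLevelResult(t_map=t_map, t_critical=t_crit, df=df,
                            alpha=alpha, clusters=clusters, affine=affine)


# ---------------------------------------------------------------- NIfTI I/O

def save_volume(path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_volume(path) -> Tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def save_beta_stack(directory, betas: Sequence[BetaVolume]) -> Path:
    """Write one participant's betas as a 4-D NIfTI + JSON sidecar of ids."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.stack([b.data for b in betas], axis=-1).astype(np.float32)
    participant = betas[0].participant_id or "sub"
    nii = directory / f"{participant}_betas.nii.gz"
    nib.save(nib.Nifti1Image(stack, betas[0].affine), str(nii))
    sidecar = {"participant_id": participant,
               "image_ids": [b.image_id for b in betas]}
    with open(directory / f"{participant}_betas.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return nii


def load_beta_stack(nii_path) -> List[BetaVolume]:
    nii_path = Path(nii_path)
    img = nib.load(str(nii_path))
    with open(nii_path.with_name(nii_path.name.replace(".nii.gz", ".json"))) as fh:
        sidecar = json.load(fh)
    data = np.asarray(img.get_fdata(), dtype=float)
    return [BetaVolume(data=data[..., i], affine=img.affine,
                       image_id=img_id,
                       participant_id=sidecar["participant_id"])
            for i, img_id in enumerate(sidecar["image_ids"])]
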