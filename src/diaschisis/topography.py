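"""Cerebellar lesion-topography probability maps.

Given per-dataset binarized lesion masks in a common template space and
the atrophy calls, build for each cerebral lobe the probability map of
lesion location among datasets with atrophy in that lobe, divide it by
the overall stroke-location probability map to correct for where strokes
happen at all, smooth with a Gaussian kernel (FWHM in mm), and combine
the four smoothed ratio maps into a single argmax map: per cerebellar
voxel, the cerebral lobe most likely to show delayed atrophy.

All maps in one analysis share a grid shape and affine.  Voxels where
the overall map is zero have undefined ratios; they are set to 0,
recorded in an undefined-support mask and labelled background in the
combined map.  Argmax ties are broken by the fixed lobe order frontal,
occipital, parietal, temporal and recorded with a tie flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .atlas import LOBES

#: fixed lobe order used for deterministic argmax tie-breaking
COMBINE_ORDER = ("frontal", "occipital", "parietal", "temporal")

#: integer codes of the combined map
BACKGROUND_CODE = 0
LOBE_CODES = {lobe: i + 1 for i, lobe in enumerate(COMBINE_ORDER)}
TIE_FLAG_CODE = 9

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class LesionMask:
    """Binarized lesion on a 3D grid with a voxel→mm affine."""

    grid: np.ndarray
    affine: np.ndarray
    dataset_id: str = ""
    side: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("lesion mask must be a 3D volume")
        if not np.isin(self.grid, (0, 1)).all():
            raise ValueError("lesion mask must be binary {0,1}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("mask affine is not invertible")

    @property
    def voxel_volume_ml(self) -> float:
        return abs(float(np.linalg.det(self.affine[:3, :3]))) / 1000.0

    @property
    def volume_ml(self) -> float:
        return float(self.grid.sum()) * self.voxel_volume_ml


@dataclass
class VoxelMap:
    """Real- or code-valued map sharing the mask geometry."""

    grid: np.ndarray
    affine: np.ndarray
    kind: str = "probability"        # probability | ratio | combined
    group_label: str = ""
    undefined_support: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def _check_geometry(items) -> None:
    ref_shape, ref_affine = items[0].grid.shape, items[0].affine
    for item in items[1:]:
        if item.grid.shape != ref_shape or not np.allclose(
            item.affine, ref_affine, atol=1e-9
        ):
            raise ValueError("masks/maps do not share one shape and affine")


# ---------------------------------------------------------------------------
# group assignment
# ---------------------------------------------------------------------------

def assign_lobe_groups(calls, lobe_mapping: dict[str, str] | None = None):
    """Lobe-wise dataset groups from an atrophy call set.

    A dataset belongs to a lobe group iff it has at least one atrophic
    area in that lobe; membership is non-exclusive, and datasets without
    atrophic areas belong to no group.
    """
    table = calls.calls if hasattr(calls, "calls") else calls
    groups: dict[str, set] = {lobe: set() for lobe in LOBES}
    flagged = table[table["is_atrophic"]]
    for rec in flagged.itertuples(index=False):
        lobe = rec.lobe if lobe_mapping is None else lobe_mapping.get(rec.area_label)
        if lobe not in groups:
            raise ValueError(f"unknown lobe/area for label {rec.area_label!r}")
        groups[lobe].add(rec.dataset_id)
    return groups


# ---------------------------------------------------------------------------
# map construction
# ---------------------------------------------------------------------------

def compile_probability_map(masks: list[LesionMask], group_label: str = "") -> VoxelMap:
    """Voxelwise fraction of masks that contain the voxel."""
    if not masks:
        raise ValueError("cannot compile a probability map from zero masks")
    _check_geometry(masks)
    stack = np.stack([m.grid for m in masks]).astype(float)
    return VoxelMap(
        stack.mean(axis=0),
        masks[0].affine.copy(),
        kind="probability",
        group_label=group_label,
        meta={"n_masks": len(masks)},
    )


def ratio_map(lobe_map: VoxelMap, overall_map: VoxelMap) -> VoxelMap:
    """Lobe-map / overall-map, with zero (and an undefined-support record)
    where the overall stroke-location probability is zero."""
    _check_geometry([lobe_map, overall_map])
    support = overall_map.grid > 0
    out = np.zeros_like(lobe_map.grid, dtype=float)
    np.divide(lobe_map.grid, overall_map.grid, out=out, where=support)
    return VoxelMap(
        out,
        lobe_map.affine.copy(),
        kind="ratio",
        group_label=lobe_map.group_label,
        undefined_support=~support,
    )


def smooth_map(vmap: VoxelMap, fwhm_mm: float) -> VoxelMap:
    """Gaussian smoothing with sigma = FWHM / (2*sqrt(2 ln 2)) per axis,
    converted from mm to voxels via the affine; reflection boundary so
    total mass is preserved."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return VoxelMap(
            vmap.grid.copy(), vmap.affine.copy(), vmap.kind, vmap.group_label,
            None if vmap.undefined_support is None else vmap.undefined_support.copy(),
            dict(vmap.meta),
        )
    voxel_sizes = np.sqrt((vmap.affine[:3, :3] ** 2).sum(axis=0))
    sigma_mm = fwhm_mm * FWHM_TO_SIGMA
    sigma_vox = sigma_mm / voxel_sizes
    smoothed = ndimage.gaussian_filter(
        vmap.grid.astype(float), sigma=sigma_vox, mode="reflect"
    )
    meta = dict(vmap.meta)
    meta.update({"fwhm_mm": fwhm_mm, "sigma_mm": sigma_mm, "boundary": "reflect"})
    return VoxelMap(
        smoothed, vmap.affine.copy(), vmap.kind, vmap.group_label,
        None if vmap.undefined_support is None else vmap.undefined_support.copy(),
        meta,
    )


def combine_maps(
    ratio_maps: dict[str, VoxelMap],
    support: np.ndarray | None = None,
) -> VoxelMap:
    """Argmax map over the four lobe-wise (smoothed) ratio maps.

    Returns an integer-coded map (see ``LOBE_CODES``); voxels outside
    ``support`` (or where every lobe value is zero) are background.  Ties
    take the code of the first lobe in ``COMBINE_ORDER`` and are flagged
    in ``meta["tie_mask"]``.
    """
    missing = [lobe for lobe in COMBINE_ORDER if lobe not in ratio_maps]
    if missing:
        raise ValueError(f"missing lobe maps: {missing}")
    maps = [ratio_maps[lobe] for lobe in COMBINE_ORDER]
    _check_geometry(maps)
    stack = np.stack([m.grid for m in maps])
    best = stack.argmax(axis=0)
    maxval = stack.max(axis=0)
    codes = np.asarray([LOBE_CODES[lobe] for lobe in COMBINE_ORDER])
    out = codes[best]
    background = maxval <= 0
    if support is not None:
        background |= ~support
    out = np.where(background, BACKGROUND_CODE, out)
    tie = (stack == maxval[None]).sum(axis=0) > 1
    tie &= ~background
    return VoxelMap(
        out.astype(np.int16),
        maps[0].affine.copy(),
        kind="combined",
        meta={
            "codes": {**{"background": BACKGROUND_CODE}, **LOBE_CODES},
            "tie_mask": tie,
            "tie_break_order": list(COMBINE_ORDER),
        },
    )


def build_topography_maps(
    masks: list[LesionMask],
    lobe_groups: dict[str, set],
    fwhm_mm: float = 5.0,
) -> dict:
    """Full map stage: overall map, per-lobe probability and smoothed
    ratio maps, and the combined argmax map."""
    by_id = {m.dataset_id: m for m in masks}
    overall = compile_probability_map(masks, group_label="overall")
    lobe_prob, lobe_ratio = {}, {}
    for lobe in COMBINE_ORDER:
        members = sorted(lobe_groups.get(lobe, ()))
        if members:
            group_masks = [by_id[d] for d in members if d in by_id]
            if len(group_masks) != len(members):
                missing = sorted(set(members) - set(by_id))
                raise ValueError(f"masks missing for datasets {missing}")
            prob = compile_probability_map(group_masks, group_label=lobe)
        else:
            prob = VoxelMap(
                np.zeros_like(overall.grid), overall.affine.copy(),
                kind="probability", group_label=lobe, meta={"n_masks": 0},
            )
        lobe_prob[lobe] = prob
        lobe_ratio[lobe] = smooth_map(ratio_map(prob, overall), fwhm_mm)
    combined = combine_maps(lobe_ratio, support=overall.grid > 0)
    return {
        "overall": overall,
        "probability": lobe_prob,
        "ratio": lobe_ratio,
        "combined": combined,
    }


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_mask(path: str | Path, binarize: bool = False,
              dataset_id: str | None = None, side: str = "") -> LesionMask:
    """Read a binarized lesion mask from NIfTI-1.

    Non-binary values are rejected unless ``binarize`` is set, in which
    case the volume is thresholded at 0.5.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: lesion mask must be 3D, got {data.ndim}D")
    if np.isnan(data).any():
        raise ValueError(f"{path}: {int(np.isnan(data).sum())} NaN voxels")
    if not np.isin(data, (0, 1)).all():
        if not binarize:
            raise ValueError(f"{path}: mask is not binary (use binarize)")
        data = (data > 0.5).astype(np.uint8)
    if dataset_id is None:
        dataset_id = Path(path).name.split(".")[0]
    return LesionMask(data.astype(np.uint8), img.affine, dataset_id, side)


def write_mask(mask: LesionMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine), str(path))


def write_map(vmap: VoxelMap, path: str | Path) -> None:
    """Write a map as NIfTI-1; NaNs are rejected with a voxel count."""
    grid = vmap.grid
    if np.issubdtype(grid.dtype, np.floating) and np.isnan(grid).any():
        raise ValueError(f"map contains {int(np.isnan(grid).sum())} NaN voxels")
    dtype = np.int16 if vmap.kind == "combined" else np.float32
    nib.save(nib.Nifti1Image(grid.astype(dtype), vmap.affine), str(path))


def read_map(path: str | Path, kind: str = "probability") -> VoxelMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: map must be 3D")
    if np.issubdtype(data.dtype, np.floating) and np.isnan(data).any():
        raise ValueError(f"{path}: {int(np.isnan(data).sum())} NaN voxels")
    return VoxelMap(data, img.affine, kind=kind)
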