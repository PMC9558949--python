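"""Tumor-bounding options: from a subtractive stack to fixed-size model inputs.

Six options control how much peritumoral parenchyma enters the classifier:

========  ==================================================================
SFB       single fixed-size box, 160x160x80, centered on the lesion centroid
SVB       smallest cubical box around the union of all lesions, resized 64^3
SIB       SVB after resampling the volumes to isotropic voxels
SLVB      one SVB-style cube per lesion (inter-lesion tissue excluded)
SLIB      SLVB after isotropic resampling
2DS       the SVB cube cut into lesion-bearing 2D slices, resized 64x64
========  ==================================================================

All outputs are 4-channel (the four subtractive timepoints), min-max
normalized to [0, 1] per sample over the channels jointly so the relative
wash-in/wash-out intensity ordering between timepoints is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .dce_data import SubtractiveStack

__all__ = [
    "OPTIONS",
    "OPTION_SHAPES",
    "BoundedSample",
    "LesionSet",
    "split_lesions",
    "extract_sfb",
    "extract_svb",
    "resample_isotropic",
    "extract_2ds",
    "resize",
    "normalize01",
    "run_option",
    "write_samples",
]

#: canonical final data shapes per option, channels first
OPTION_SHAPES = {
    "sfb": (4, 160, 160, 80),
    "svb": (4, 64, 64, 64),
    "sib": (4, 64, 64, 64),
    "slvb": (4, 64, 64, 64),
    "slib": (4, 64, 64, 64),
    "2ds": (4, 64, 64),
}
OPTIONS = tuple(OPTION_SHAPES)

SFB_BOX = (160, 160, 80)
VB_SIZE = (64, 64, 64)
SLICE_SIZE = (64, 64)


@dataclass
class BoundedSample:
    """One model input: a cropped, resized, normalized 4-channel array.

    ``lesion_id`` is the 1-based connected-component id for per-lesion
    options and ``"all"`` for whole-tumor options; ``slice_index`` is set
    only for 2D slice samples.
    """

    patient_id: str
    lesion_id: int | str
    option: str
    data: np.ndarray
    label: int
    slice_index: int | None = None

    def __post_init__(self) -> None:
        if self.option not in OPTION_SHAPES:
            raise ValueError(f"unknown bounding option {self.option!r}")


@dataclass
class LesionSet:
    """Connected lesion components of one mask, largest first."""

    lesion_ids: list[int]
    components: list[np.ndarray]
    extents: list[tuple[tuple[int, int], ...]]  # per-axis (min, max) inclusive


# 26-connectivity: faces, edges and corners all connect
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def split_lesions(mask: np.ndarray) -> LesionSet:
    """Split a binary lesion mask into 26-connected components.

    Components are labeled 1, 2, ... in decreasing voxel-count order, so in
    multifocal/multicentric cases lesion 1 is always the largest focus.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("lesion mask is empty")
    labeled, n = ndimage.label(mask, structure=_STRUCT_26)
    counts = np.bincount(labeled.ravel())[1:]
    order = np.argsort(-counts, kind="stable") + 1
    components, extents = [], []
    for lab in order:
        comp = labeled == lab
        components.append(comp)
        extents.append(_bbox(comp))
    return LesionSet(
        lesion_ids=list(range(1, n + 1)), components=components, extents=extents
    )


def _bbox(mask: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Inclusive per-axis (min, max) foreground extents."""
    coords = np.nonzero(mask)
    return tuple((int(c.min()), int(c.max())) for c in coords)


def _crop_padded(vol: np.ndarray, starts, size) -> np.ndarray:
    """Half-open crop ``[start, start+size)`` per axis, zero-padded outside."""
    out = np.zeros(tuple(size), dtype=vol.dtype)
    src, dst = [], []
    for ax, (s0, n) in enumerate(zip(starts, size)):
        lo, hi = max(s0, 0), min(s0 + n, vol.shape[ax])
        if lo >= hi:
            return out  # crop entirely outside the grid
        src.append(slice(lo, hi))
        dst.append(slice(lo - s0, hi - s0))
    out[tuple(dst)] = vol[tuple(src)]
    return out


def _crop_stack(stack: SubtractiveStack, starts, size) -> tuple[np.ndarray, np.ndarray]:
    """Apply one crop identically to the 4 channels and the mask."""
    channels = np.stack(
        [_crop_padded(stack.channels[c], starts, size) for c in range(4)], axis=0
    )
    mask = _crop_padded(stack.mask, starts, size)
    return channels, mask


def extract_sfb(stack: SubtractiveStack, box: tuple[int, int, int] = SFB_BOX):
    """Fixed-size patient-independent crop centered on the tumor centroid.

    The centroid is the voxel mean of the union lesion mask, rounded.  The
    box is identical across the four channels; regions outside the image
    grid are zero-padded.  A tumor larger than the box triggers a warning,
    not an error.
    """
    if not stack.mask.any():
        raise ValueError("lesion mask is empty")
    centroid = np.round(np.mean(np.nonzero(stack.mask), axis=1)).astype(int)
    starts = [int(c) - n // 2 for c, n in zip(centroid, box)]
    ext = _bbox(stack.mask)
    for ax, ((lo, hi), n) in enumerate(zip(ext, box)):
        if hi - lo + 1 > n:
            warnings.warn(
                f"patient {stack.patient_id}: tumor extent {hi - lo + 1} exceeds "
                f"the fixed box size {n} on axis {ax}",
                stacklevel=2,
            )
    return _crop_stack(stack, starts, box)


def extract_svb(stack: SubtractiveStack, target_mask: np.ndarray):
    """Smallest cubical crop containing ``target_mask``.

    The cube side is the maximum per-axis bounding-box extent of the target
    mask; the cube is centered on the (floored) bounding-box center with any
    1-voxel padding asymmetry on the high side, applied identically to the
    four channels, zero-padded where it leaves the grid.
    """
    target_mask = np.asarray(target_mask) > 0
    if not target_mask.any():
        raise ValueError("target mask is empty")
    ext = _bbox(target_mask)
    extents = [hi - lo + 1 for lo, hi in ext]
    side = max(extents)
    starts = [lo - (side - e) // 2 for (lo, _), e in zip(ext, extents)]
    size = (side, side, side)
    channels = np.stack(
        [_crop_padded(stack.channels[c], starts, size) for c in range(4)], axis=0
    )
    mask = _crop_padded(target_mask, starts, size)
    return channels, mask


def resample_isotropic(stack: SubtractiveStack) -> SubtractiveStack:
    """Resample a stack to isotropic voxels at the finest original spacing.

    The target spacing is the minimum of the three spacings (pure
    upsampling, no information discarded); channels use trilinear
    interpolation, the mask nearest-neighbor so it stays binary.  New axis
    length = round(old_length * old_spacing / target_spacing).
    """
    spacing = stack.spacing
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive spacing {spacing}")
    target = min(spacing)
    old_shape = stack.channels.shape[1:]
    new_shape = tuple(
        int(round(n * s / target)) for n, s in zip(old_shape, spacing)
    )
    if new_shape == tuple(old_shape):
        return stack
    channels = np.stack(
        [_resize_volume(stack.channels[c], new_shape, order=1) for c in range(4)],
        axis=0,
    )
    mask = _resize_volume(stack.mask.astype(np.uint8), new_shape, order=0) > 0
    return SubtractiveStack(
        patient_id=stack.patient_id,
        channels=channels,
        source_indices=stack.source_indices,
        spacing=(target, target, target),
        mask=mask,
        label=stack.label,
    )


def _resize_volume(vol: np.ndarray, shape, order: int) -> np.ndarray:
    return _sk_resize(
        vol.astype(np.float32),
        shape,
        order=order,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    ).astype(np.float32)


def _slicing_axis(spacing) -> int:
    """Axis with the coarsest spacing; ties break toward the last axis."""
    sp = np.asarray(spacing, dtype=float)
    return int(len(sp) - 1 - np.argmax(sp[::-1]))


def extract_2ds(stack: SubtractiveStack) -> list[tuple[int, np.ndarray]]:
    """Cut the SVB cube into its lesion-bearing 2D slices.

    The cube is sliced along the axis with the coarsest spacing, so each
    retained plane lies in the finest-resolution projection; only slices
    where the cropped mask has foreground are kept.  Returns
    ``(slice_index, 4-channel 2D image)`` pairs.
    """
    channels, mask = extract_svb(stack, stack.mask)
    axis = _slicing_axis(stack.spacing)
    mask_counts = mask.sum(axis=tuple(a for a in range(3) if a != axis))
    slice_ids = np.nonzero(mask_counts)[0]
    if slice_ids.size == 0:
        raise ValueError("no lesion-bearing slice in the cropped cube")
    out = []
    for k in slice_ids:
        sl = [slice(None)] * 4
        sl[axis + 1] = int(k)  # +1: channel axis first
        out.append((int(k), channels[tuple(sl)]))
    return out


def resize(data: np.ndarray, target_shape) -> np.ndarray:
    """Channel-wise linear resize (trilinear in 3D, bilinear in 2D)."""
    target_shape = tuple(target_shape)
    if any(n < 1 for n in data.shape[1:]):
        raise ValueError(f"degenerate input shape {data.shape}")
    if data.shape[1:] == target_shape:
        return data.astype(np.float32)
    return np.stack(
        [_resize_volume(data[c], target_shape, order=1) for c in range(data.shape[0])],
        axis=0,
    )


def normalize01(data: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1] over all channels jointly.

    A constant sample maps to all zeros.  Joint (not per-channel)
    normalization keeps the intensity ordering between timepoints, i.e. the
    wash-in/wash-out curve shape.
    """
    data = data.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def run_option(stack: SubtractiveStack, option: str) -> list[BoundedSample]:
    """Apply one bounding option to a patient's stack.

    Sample counts: 1 (sfb/svb/sib), one per lesion (slvb/slib), one per
    lesion-bearing slice (2ds).
    """
    option = option.lower()
    if option not in OPTION_SHAPES:
        raise ValueError(f"unknown bounding option {option!r}; valid: {OPTIONS}")
    pid, label = stack.patient_id, stack.label

    if option == "sfb":
        channels, _ = extract_sfb(stack)
        return [BoundedSample(pid, "all", option, normalize01(channels), label)]

    if option in ("sib", "slib"):
        stack = resample_isotropic(stack)

    if option in ("svb", "sib"):
        channels, _ = extract_svb(stack, stack.mask)
        data = normalize01(resize(channels, VB_SIZE))
        return [BoundedSample(pid, "all", option, data, label)]

    if option in ("slvb", "slib"):
        lesions = split_lesions(stack.mask)
        samples = []
        for lid, comp in zip(lesions.lesion_ids, lesions.components):
            channels, _ = extract_svb(stack, comp)
            data = normalize01(resize(channels, VB_SIZE))
            samples.append(BoundedSample(pid, lid, option, data, label))
        return samples

    # 2ds
    samples = []
    for k, img in extract_2ds(stack):
        data = normalize01(resize(img, SLICE_SIZE))
        samples.append(BoundedSample(pid, "all", option, data, label, slice_index=k))
    return samples


def write_samples(samples: list[BoundedSample], out_dir: str | Path) -> pd.DataFrame:
    """Write samples as NIfTI files plus a manifest CSV; returns the manifest."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        tag = f"{s.patient_id}_{s.option}_l{s.lesion_id}"
        if s.slice_index is not None:
            tag += f"_s{s.slice_index:03d}"
        f = out_dir / f"{tag}.nii.gz"
        # channels stored on the last axis for NIfTI convention
        arr = np.moveaxis(s.data, 0, -1).astype(np.float32)
        nib.save(nib.Nifti1Image(arr, np.eye(4)), f)
        rows.append(
            {
                "patient_id": s.patient_id,
                "lesion_id": s.lesion_id,
                "slice_index": -1 if s.slice_index is None else s.slice_index,
                "option": s.option,
                "label": s.label,
                "file": str(f),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "samples.csv", index=False)
    return manifest
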