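"""CT-to-model-input geometry.

Turns a CT volume and its tumor mask into the seven 100 x 100 patches the
base networks consume:

1. stored values -> Hounsfield units (linear rescale slope/intercept);
2. resampling to isotropic 1 mm voxels (cubic spline; nearest for masks);
3. intensity windowing to [-1000, 400] HU, normalized to [0, 255];
4. bicubic in-plane resize to 512 x 512;
5. the central tumor slice (maximum cross-sectional area) anchors five
   axial slices spaced 5 mm (= 5 voxels) apart, plus two multi-scale crops
   (50 and 150 px) of the central slice, both rescaled bicubically to
   100 x 100.

All seven patches share one center of mass, computed from the mask on the
central slice, so they stay co-registered.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

HU_WINDOW = (-1000.0, 400.0)
TARGET_PLANE = 512
PATCH_SIZE = 100
SCALE_SIZES = (50, 100, 150)
SLICE_OFFSETS_MM = (-10, -5, 0, 5, 10)
SLICE_NAMES = ("second_before", "first_before", "medium", "first_after", "second_after")
PATCH_KEYS = SLICE_NAMES + ("scale50", "scale150")


@dataclass
class CTVolume:
    """Stored-value CT grid in (z, y, x) order with rescale metadata."""

    stored: np.ndarray
    spacing_mm: tuple[float, float, float]
    rescale_slope: float
    rescale_intercept: float
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.stored = np.asarray(self.stored)
        if self.stored.ndim != 3 or self.stored.size == 0:
            raise ValueError("stored grid must be a non-empty 3D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")


@dataclass
class TumorMask:
    """Binary mask aligned voxel-for-voxel with its CTVolume."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.mask.any():
            raise ValueError("mask has no foreground voxels")


@dataclass
class PatchSet:
    """Per-patient model inputs: five axial slices and two multi-scale patches,
    each 100 x 100, plus the binary two-year recurrence label."""

    second_before: np.ndarray
    first_before: np.ndarray
    medium: np.ndarray
    first_after: np.ndarray
    second_after: np.ndarray
    scale50: np.ndarray
    scale150: np.ndarray
    label: int
    patient_id: str = ""

    def __post_init__(self) -> None:
        for key in PATCH_KEYS:
            patch = getattr(self, key)
            if patch.shape != (PATCH_SIZE, PATCH_SIZE):
                raise ValueError(f"{key} patch must be {PATCH_SIZE}x{PATCH_SIZE}, "
                                 f"got {patch.shape}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {key: getattr(self, key) for key in PATCH_KEYS}


def to_hounsfield(vol: CTVolume) -> np.ndarray:
    """HU = stored * slope + intercept, as float."""
    if vol.rescale_slope == 0:
        raise ValueError("rescale slope must be non-zero")
    return vol.stored.astype(np.float32) * np.float32(vol.rescale_slope) \
        + np.float32(vol.rescale_intercept)


def _target_shape(shape: tuple[int, ...], spacing: tuple[float, ...]) -> tuple[int, ...]:
    return tuple(int(round(s * sp)) for s, sp in zip(shape, spacing))


def resample_isotropic(grid: np.ndarray, spacing_mm: tuple[float, float, float],
                       order: int = 3) -> np.ndarray:
    """Resample to 1 mm isotropic voxels; output shape = round(shape * spacing).

    ``order=3`` (cubic spline) for intensities; pass ``order=0`` for masks.
    """
    grid = np.asarray(grid)
    if any(s <= 0 for s in spacing_mm):
        raise ValueError("spacing must be strictly positive")
    if any(s == 1 for s in grid.shape):
        raise ValueError("cannot resample a degenerate (single-slice) axis")
    target = _target_shape(grid.shape, spacing_mm)
    zoom = [t / s for t, s in zip(target, grid.shape)]
    out = ndimage.zoom(grid.astype(np.float32), zoom, order=order, mode="nearest",
                       grid_mode=True)
    assert out.shape == target
    return out


def resample_mask(mask: np.ndarray, spacing_mm: tuple[float, float, float]) -> np.ndarray:
    """Nearest-neighbour resampling to 1 mm for binary masks."""
    return resample_isotropic(np.asarray(mask).astype(np.float32),
                              spacing_mm, order=0) > 0.5


def window_normalize(hu: np.ndarray) -> np.ndarray:
    """Clip to [-1000, 400] HU and map linearly onto [0, 255].

    Rounding is half-even so the mapping is bit-reproducible across platforms.
    """
    lo, hi = HU_WINDOW
    v = np.clip(hu, lo, hi)
    return np.rint(255.0 * (v - lo) / (hi - lo)).astype(np.float32)


def resize_plane(plane: np.ndarray, size: int = TARGET_PLANE) -> np.ndarray:
    """Bicubic resize of one axial plane, re-clipped to [0, 255]."""
    if plane.shape == (size, size):
        return plane.astype(np.float32)
    out = _sk_resize(plane.astype(np.float64), (size, size), order=3,
                     mode="edge", anti_aliasing=False, preserve_range=True, clip=False)
    return np.clip(out, 0.0, 255.0).astype(np.float32)


def resize_inplane(vol: np.ndarray, size: int = TARGET_PLANE) -> np.ndarray:
    """Bicubic in-plane resize of every axial plane to ``size`` x ``size``."""
    return np.stack([resize_plane(p, size) for p in np.asarray(vol)])


def central_slice(mask: np.ndarray) -> int:
    """Index of the axial slice with maximum tumor area (ties: smallest z)."""
    mask = np.asarray(mask).astype(bool)
    areas = mask.reshape(mask.shape[0], -1).sum(axis=1)
    if areas.sum() == 0:
        raise ValueError("mask is empty")
    return int(np.argmax(areas))


def slice_indices(center_z: int, depth: int) -> list[int]:
    """Five axial indices at 5-voxel (= 5 mm) spacing around the central slice,
    clamped (with duplication) to the volume bounds."""
    return [int(np.clip(center_z + off, 0, depth - 1)) for off in SLICE_OFFSETS_MM]


def crop_patch(plane: np.ndarray, center: tuple[int, int], size: int) -> np.ndarray:
    """Half-open square window [c - size//2, c + size - size//2) around
    ``center``; regions outside the plane are zero-padded."""
    r, c = int(center[0]), int(center[1])
    h, w = plane.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"center {center} outside plane of shape {plane.shape}")
    half = size // 2
    r0, r1 = r - half, r - half + size
    c0, c1 = c - half, c - half + size
    out = np.zeros((size, size), dtype=np.float32)
    sr0, sr1 = max(r0, 0), min(r1, h)
    sc0, sc1 = max(c0, 0), min(c1, w)
    out[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = plane[sr0:sr1, sc0:sc1]
    return out


def rescale_patch(patch: np.ndarray, size: int = PATCH_SIZE) -> np.ndarray:
    """Bicubic rescale of a square patch to ``size`` x ``size`` (identity if
    already that size), clipped to [0, 255]."""
    patch = np.asarray(patch)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError(f"patch must be square, got {patch.shape}")
    if patch.shape == (size, size):
        return patch.astype(np.float32)
    out = _sk_resize(patch.astype(np.float64), (size, size), order=3,
                     mode="edge", anti_aliasing=False, preserve_range=True, clip=False)
    return np.clip(out, 0.0, 255.0).astype(np.float32)


def _mapped_center(mask_plane: np.ndarray, in_shape: tuple[int, int],
                   out_size: int) -> tuple[int, int]:
    """Center of mass on the 1 mm grid, mapped through the in-plane resize
    (pixel-center convention)."""
    com = ndimage.center_of_mass(mask_plane.astype(np.float32))
    scale = (out_size / in_shape[0], out_size / in_shape[1])
    return (int(round((com[0] + 0.5) * scale[0] - 0.5)),
            int(round((com[1] + 0.5) * scale[1] - 0.5)))


def build_patchset(vol: CTVolume, mask: TumorMask, label: int) -> PatchSet:
    """Run the full geometry pipeline for one patient."""
    if mask.mask.shape != vol.stored.shape:
        raise ValueError("mask and volume shapes differ")
    hu = to_hounsfield(vol)
    iso = resample_isotropic(hu, vol.spacing_mm)
    mask_iso = resample_mask(mask.mask, vol.spacing_mm)
    norm = window_normalize(iso)
    cz = central_slice(mask_iso)
    zs = slice_indices(cz, norm.shape[0])
    center = _mapped_center(mask_iso[cz], norm.shape[1:], TARGET_PLANE)

    planes = {z: resize_plane(norm[z]) for z in set(zs)}
    slices = [crop_patch(planes[z], center, PATCH_SIZE) for z in zs]
    medium_plane = planes[zs[2]]
    scale50 = rescale_patch(crop_patch(medium_plane, center, 50))
    scale150 = rescale_patch(crop_patch(medium_plane, center, 150))
    return PatchSet(*slices, scale50=scale50, scale150=scale150,
                    label=int(label), patient_id=vol.patient_id)


def augment(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal/vertical flip, each independently with probability 1/2.

    Training-time only; a flip is a pixel permutation, so intensities are
    untouched.
    """
    out = patch
    if rng.random() < 0.5:
        out = out[..., ::-1, :]
    if rng.random() < 0.5:
        out = out[..., :, ::-1]
    return np.ascontiguousarray(out)


def augment_flip(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-sample independent random flips for a (N, H, W, C) batch."""
    out = batch.copy()
    flips = rng.random((batch.shape[0], 2)) < 0.5
    for i, (fv, fh) in enumerate(flips):
        if fv:
            out[i] = out[i][::-1, :, :]
        if fh:
            out[i] = out[i][:, ::-1, :]
    return out


def load_ct_nifti(volume_path, mask_path, patient_id: str = "") -> tuple[CTVolume, TumorMask]:
    """Read a stored-value CT volume and its mask from NIfTI-1 files.

    The rescale slope/intercept are taken from the NIfTI scaling header
    (``scl_slope``/``scl_inter``); data arrays are returned unscaled in
    (z, y, x) order.
    """
    import nibabel as nib

    img = nib.load(str(volume_path))
    slope = getattr(img.dataobj, "slope", 1.0)
    inter = getattr(img.dataobj, "inter", 0.0)
    stored = np.asarray(img.dataobj.get_unscaled()).T
    zooms = img.header.get_zooms()[:3]
    vol = CTVolume(stored=stored, spacing_mm=tuple(float(z) for z in zooms[::-1]),
                   rescale_slope=float(slope) if np.isfinite(slope) else 1.0,
                   rescale_intercept=float(inter) if np.isfinite(inter) else 0.0,
                   patient_id=patient_id)
    mimg = nib.load(str(mask_path))
    mask = TumorMask(np.asarray(mimg.dataobj).T > 0.5)
    return vol, mask


def save_patchset(ps: PatchSet, path) -> None:
    """Persist one patient's patches as a compressed array bundle."""
    np.savez_compressed(path, label=ps.label, patient_id=ps.patient_id,
                        **ps.as_dict())


def load_patchset(path) -> PatchSet:
    with np.load(path, allow_pickle=False) as z:
        return PatchSet(**{k: z[k].astype(np.float32) for k in PATCH_KEYS},
                        label=int(z["label"]), patient_id=str(z["patient_id"]))


def _replace(ps: PatchSet, **kw) -> PatchSet:
    return dataclasses.replace(ps, **kw)
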