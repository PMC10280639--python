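"""Synthetic anisotropic CT phantoms with a planted, class-conditional
texture signal.

Each phantom is a lung-like background (Gaussian noise around a low HU mean)
containing one ellipsoidal soft-tissue tumor. The two-year recurrence label
is encoded purely in texture: band-limited Gaussian noise (white noise
smoothed at sigma = 1.5 mm, renormalized to unit variance) is added inside
the tumor and in a peritumoral ring, scaled by a class-conditional amplitude.
The ring carries the full amplitude and the tumor interior a reduced share,
so networks that see more peritumoral context (large-scale patches,
larger-kernel models) have extra signal to exploit — the configuration the
ensemble is designed to detect.

Volumes are emitted as stored values (12-bit clipped) under a rescale
slope/intercept, on an anisotropic grid (thick slices), so the preprocessing
geometry is genuinely exercised.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import CTVolume, TumorMask

STORED_MAX = 4095  # 12-bit CT convention
HALF_PATCH_MARGIN_MM = 75.0  # physical clearance demanded of the largest patch


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for one phantom volume.

    Shapes and spacings are in (z, y, x) order; all physical quantities in mm
    or HU. The default z-spacing of 2.5 mm makes the resampling step
    non-trivial, as in thick-slice clinical CT.
    """

    volume_shape: tuple[int, int, int] = (24, 100, 100)
    spacing_mm: tuple[float, float, float] = (2.5, 2.0, 2.0)
    rescale_slope: float = 1.0
    rescale_intercept: float = -1024.0
    tumor_radii_mm: tuple[float, float, float] = (12.0, 10.0, 10.0)
    background_hu_mean: float = -850.0
    background_hu_sd: float = 20.0
    tumor_hu_mean: float = 30.0
    tumor_hu_sd: float = 15.0
    peritumoral_ring_mm: float = 6.0
    texture_amplitude_pos: float = 80.0
    texture_amplitude_neg: float = 30.0
    texture_sigma_mm: float = 1.5
    intra_tumoral_share: float = 0.6  # tumor interior gets this fraction of the amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if self.peritumoral_ring_mm <= 0:
            raise ValueError("peritumoral ring width must be positive")
        if self.rescale_slope == 0:
            raise ValueError("rescale slope must be non-zero")
        required = self.required_margin_mm()
        extent = self.physical_extent_mm()
        for axis, (need, have) in enumerate(zip(required, extent)):
            if 2 * need > have:
                raise ValueError(
                    f"tumor does not fit: axis {axis} needs a half-extent of "
                    f"{need:.1f} mm (tumor + ring + patch margin) but the volume "
                    f"spans only {have:.1f} mm")

    def physical_extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.volume_shape, self.spacing_mm))

    def required_margin_mm(self) -> tuple[float, float, float]:
        """Half-extent each axis must offer around the tumor center: the tumor
        itself, the ring, plus patch clearance (two 5-mm slices axially, the
        150-px half-patch in plane)."""
        a, b, c = self.tumor_radii_mm
        ring = self.peritumoral_ring_mm
        return (a + ring + 10.0, b + ring + HALF_PATCH_MARGIN_MM,
                c + ring + HALF_PATCH_MARGIN_MM)

    def center_mm(self) -> tuple[float, float, float]:
        return tuple((n - 1) / 2.0 * s for n, s in zip(self.volume_shape, self.spacing_mm))


def _ellipsoid(shape: tuple[int, int, int], spacing: tuple[float, float, float],
               center_mm: tuple[float, float, float],
               radii_mm: tuple[float, float, float]) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)),
                        indexing="ij", sparse=True)
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center_mm, radii_mm))
    return q <= 1.0


def _band_limited_noise(shape: tuple[int, int, int], spacing: tuple[float, float, float],
                        sigma_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Smoothed white noise renormalized to unit standard deviation."""
    white = rng.standard_normal(shape).astype(np.float32)
    sig = [sigma_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sig, mode="wrap")
    sd = smooth.std()
    return smooth / (sd if sd > 0 else 1.0)


def generate_phantom(params: PhantomParams, label: int) -> tuple[CTVolume, TumorMask, int]:
    """Generate one phantom volume, its tumor mask, and echo the label.

    The label selects the texture amplitude (positive class: strong texture);
    stored values satisfy HU = stored * slope + intercept and the whole
    generation is a deterministic function of ``params.seed``.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    rng = np.random.default_rng(params.seed)
    shape, spacing = params.volume_shape, params.spacing_mm
    center = params.center_mm()

    tumor = _ellipsoid(shape, spacing, center, params.tumor_radii_mm)
    ring_outer = _ellipsoid(shape, spacing, center,
                            tuple(r + params.peritumoral_ring_mm
                                  for r in params.tumor_radii_mm))
    ring = ring_outer & ~tumor

    hu = rng.normal(params.background_hu_mean, params.background_hu_sd,
                    shape).astype(np.float32)
    hu[tumor] = rng.normal(params.tumor_hu_mean, params.tumor_hu_sd,
                           int(tumor.sum())).astype(np.float32)

    amplitude = params.texture_amplitude_pos if label == 1 else params.texture_amplitude_neg
    texture = _band_limited_noise(shape, spacing, params.texture_sigma_mm, rng)
    hu[ring] += amplitude * texture[ring]
    hu[tumor] += params.intra_tumoral_share * amplitude * texture[tumor]

    stored = np.rint((hu - params.rescale_intercept) / params.rescale_slope)
    stored = np.clip(stored, 0, STORED_MAX).astype(np.int16)
    vol = CTVolume(stored=stored, spacing_mm=spacing,
                   rescale_slope=params.rescale_slope,
                   rescale_intercept=params.rescale_intercept)
    return vol, TumorMask(tumor), label


def cohort_labels(n: int, class_balance: float) -> np.ndarray:
    """Deterministic label vector with exactly round(n * balance) positives,
    interleaved for stable stratification."""
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    if not 0 < class_balance < 1:
        raise ValueError("class balance must lie strictly between 0 and 1")
    n_pos = round(n * class_balance)
    labels = np.zeros(n, dtype=int)
    if n_pos > 0:
        pos_idx = np.linspace(0, n - 1, n_pos).round().astype(int)
        labels[pos_idx] = 1
    return labels


def _case_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def cohort_cases(n: int, class_balance: float, base_params: PhantomParams,
                 seed: int):
    """Yield (patient_id, CTVolume, TumorMask, label) for an in-memory cohort.

    Per-case seeds are derived deterministically from the master seed, so the
    cohort is reproducible case by case.
    """
    labels = cohort_labels(n, class_balance)
    seeds = _case_seeds(seed, n)
    for i, (lab, case_seed) in enumerate(zip(labels, seeds)):
        pid = f"P{i:04d}"
        params = dataclasses.replace(base_params, seed=case_seed)
        vol, mask, _ = generate_phantom(params, int(lab))
        vol.patient_id = pid
        yield pid, vol, mask, int(lab)


def generate_cohort(n: int, class_balance: float, base_params: PhantomParams,
                    seed: int, out_dir) -> pd.DataFrame:
    """Write NIfTI volume/mask pairs plus a CSV manifest; returns the manifest.

    Manifest columns: patient_id, volume, mask, recurrence (0/1),
    months_to_event (< 24 for recurrences, >= 24 otherwise).
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    time_rng = np.random.default_rng(np.random.SeedSequence([seed, 24]))
    rows = []
    for pid, vol, mask, lab in cohort_cases(n, class_balance, base_params, seed):
        sz, sy, sx = vol.spacing_mm
        affine = np.diag([sx, sy, sz, 1.0])
        vimg = nib.Nifti1Image(vol.stored.T, affine)
        vimg.header.set_slope_inter(vol.rescale_slope, vol.rescale_intercept)
        vpath = out / f"{pid}_ct.nii.gz"
        nib.save(vimg, vpath)
        mpath = out / f"{pid}_mask.nii.gz"
        nib.save(nib.Nifti1Image(mask.mask.T.astype(np.uint8), affine), mpath)
        months = (time_rng.uniform(2.0, 23.0) if lab == 1
                  else time_rng.uniform(25.0, 60.0))
        rows.append({"patient_id": pid, "volume": str(vpath), "mask": str(mpath),
                     "recurrence": lab, "months_to_event": round(float(months), 1)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
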