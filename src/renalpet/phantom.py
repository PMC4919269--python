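"""4D dynamic PET phantoms: rendering, VOI extraction, IDIF, SUV.

Renders a mouse-like digital phantom (ellipsoidal heart and liver,
crescent-shaped renal cortices, spherical bladder) whose labelled voxels
carry per-organ time-activity curves, and re-implements the image side of
the analysis: mean-over-mask TAC extraction, the heart image-derived
input function (average of the first-20-s frames, circular ROIs on the
most intense axial slices), and standard-uptake-value conversion
SUV = concentration [kBq/mL] x body weight [g] / injected dose [kBq].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .cohort import FrameSchedule, SubjectRecord, TimeActivityCurve, ValidationError

__all__ = [
    "PhantomGeometry",
    "DynamicPhantom",
    "VOIMask",
    "ORGAN_LABELS",
    "render_phantom",
    "extract_tac",
    "idif_voi",
    "build_idif",
    "to_suv",
    "write_phantom",
    "read_phantom",
]

#: integer codes in the organ label map
ORGAN_LABELS = {
    "background": 0,
    "heart": 1,
    "liver": 2,
    "kidney_cortex_l": 3,
    "kidney_cortex_r": 4,
    "bladder": 5,
}


@dataclass(frozen=True)
class PhantomGeometry:
    """Voxel grid and organ placement, all lengths in voxels.

    Defaults give a 64x64x96 grid at 0.4 mm isotropic (small-animal
    scanner scale).  Ellipsoids are (center, semi-axes); the kidney
    cortices are crescents: a sphere minus an offset sphere of the same
    radius; the bladder is a sphere.  Image axes are (x, y, z) with z
    axial, 0-indexed.
    """

    shape: tuple[int, int, int] = (64, 64, 96)
    voxel_size_mm: tuple[float, float, float] = (0.4, 0.4, 0.4)
    heart_center: tuple[float, float, float] = (32.0, 32.0, 72.0)
    heart_semiaxes: tuple[float, float, float] = (10.0, 10.0, 11.0)
    liver_center: tuple[float, float, float] = (32.0, 32.0, 48.0)
    liver_semiaxes: tuple[float, float, float] = (14.0, 12.0, 8.0)
    kidney_l_center: tuple[float, float, float] = (14.0, 32.0, 30.0)
    kidney_r_center: tuple[float, float, float] = (50.0, 32.0, 30.0)
    kidney_radius: float = 8.0
    kidney_notch_offset: float = 5.0  # medial shift of the subtracted sphere
    bladder_center: tuple[float, float, float] = (32.0, 32.0, 10.0)
    bladder_radius: float = 7.0


def _ellipsoid(shape: tuple[int, int, int], center, semiaxes) -> np.ndarray:
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((x - center[0]) / semiaxes[0]) ** 2
        + ((y - center[1]) / semiaxes[1]) ** 2
        + ((z - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _crescent(shape, center, radius, notch_offset, medial_sign) -> np.ndarray:
    full = _ellipsoid(shape, center, (radius,) * 3)
    notch_center = (center[0] + medial_sign * notch_offset, center[1], center[2])
    notch = _ellipsoid(shape, notch_center, (radius,) * 3)
    return full & ~notch


def build_label_map(geometry: PhantomGeometry) -> np.ndarray:
    """Render the organ label volume; raises on overlapping organs."""
    shape = geometry.shape
    organs = {
        "heart": _ellipsoid(shape, geometry.heart_center, geometry.heart_semiaxes),
        "liver": _ellipsoid(shape, geometry.liver_center, geometry.liver_semiaxes),
        "kidney_cortex_l": _crescent(
            shape, geometry.kidney_l_center, geometry.kidney_radius,
            geometry.kidney_notch_offset, +1.0,
        ),
        "kidney_cortex_r": _crescent(
            shape, geometry.kidney_r_center, geometry.kidney_radius,
            geometry.kidney_notch_offset, -1.0,
        ),
        "bladder": _ellipsoid(shape, geometry.bladder_center, (geometry.bladder_radius,) * 3),
    }
    labels = np.zeros(shape, dtype=np.uint8)
    for name, mask in organs.items():
        if not mask.any():
            raise ValidationError(f"organ {name!r} has no voxels on this grid")
        if np.any(labels[mask] != 0):
            raise ValidationError(f"organ {name!r} overlaps another organ")
        labels[mask] = ORGAN_LABELS[name]
    return labels


@dataclass(frozen=True)
class DynamicPhantom:
    """4D voxel image [x, y, z, frame] with an organ label map."""

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule
    organ_labels: np.ndarray

    def __post_init__(self) -> None:
        if self.voxels.ndim != 4:
            raise ValidationError("voxels must be a 4-D array [x, y, z, frame]")
        if self.voxels.shape[:3] != self.organ_labels.shape:
            raise ValidationError("spatial dims of voxels and organ_labels must match")
        if self.voxels.shape[3] != self.schedule.count:
            raise ValidationError("frame dimension must match schedule.count")
        if np.any(self.voxels < 0):
            raise ValidationError("voxel values must be >= 0")

    def organ_mask(self, organ: str) -> "VOIMask":
        return VOIMask(self.organ_labels == ORGAN_LABELS[organ], organ)


@dataclass(frozen=True)
class VOIMask:
    mask: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", self.mask.astype(bool))
        if not self.mask.any():
            raise ValidationError("VOI mask must contain at least one voxel")


def render_phantom(
    organ_tacs: Mapping[str, TimeActivityCurve],
    geometry: PhantomGeometry | None = None,
    voxel_noise_scale: float = 0.0,
    seed: int = 0,
) -> DynamicPhantom:
    """Paint per-organ TACs into a labelled 4D volume.

    Every voxel of a labelled organ carries that organ's frame value;
    background stays zero.  Optional voxel-level noise reuses the
    duration-scaled TAC noise model independently per voxel (off by
    default; TAC-level noise is the primary regime).
    """
    geometry = geometry or PhantomGeometry()
    labels = build_label_map(geometry)
    tacs = dict(organ_tacs)
    missing = set(ORGAN_LABELS) - {"background"} - set(tacs)
    if missing:
        raise ValidationError(f"missing TACs for organs: {sorted(missing)}")
    schedule = next(iter(tacs.values())).schedule
    for name, tac in tacs.items():
        if tac.schedule.count != schedule.count or not np.allclose(
            tac.schedule.frame_start_s, schedule.frame_start_s
        ):
            raise ValidationError("all organ TACs must share one schedule")
    voxels = np.zeros(geometry.shape + (schedule.count,), dtype=float)
    rng = np.random.default_rng(seed)
    for name, code in ORGAN_LABELS.items():
        if name == "background":
            continue
        mask = labels == code
        values = tacs[name].values
        if voxel_noise_scale > 0:
            nvox = int(mask.sum())
            sigma = voxel_noise_scale * np.sqrt(
                np.maximum(values, 0.01) / schedule.frame_duration_s
            )
            block = np.maximum(values + rng.normal(size=(nvox, schedule.count)) * sigma, 0.0)
            voxels[mask, :] = block
        else:
            voxels[mask, :] = values
    return DynamicPhantom(voxels, geometry.voxel_size_mm, schedule, labels)


def extract_tac(phantom: DynamicPhantom, voi: VOIMask) -> TimeActivityCurve:
    """Per-frame mean over the masked voxels."""
    if voi.mask.shape != phantom.voxels.shape[:3]:
        raise ValidationError("VOI dimensions must match the phantom")
    values = phantom.voxels[voi.mask, :].mean(axis=0)
    return TimeActivityCurve(phantom.schedule, values, region_label=voi.label)


# --------------------------------------------------------------------------
# image-derived input function
# --------------------------------------------------------------------------

def idif_voi(
    phantom: DynamicPhantom,
    circle_diameter_px: int = 15,
    n_slices: int = 6,
    early_window_s: float = 20.0,
) -> VOIMask:
    """Heart VOI for the image-derived input function.

    (1) duration-weighted average of all frames whose full window lies
    within the first ``early_window_s`` seconds; (2) axial slices ranked
    by mean early intensity, top ``n_slices`` kept; (3) on each, a filled
    circle of ``circle_diameter_px`` pixels centred on the slice's
    intensity-weighted centroid (clipped at the image edge with a
    warning); (4) the union of the circles.
    """
    sched = phantom.schedule
    early = (sched.frame_start_s >= -1e-9) & (sched.frame_end_s <= early_window_s + 1e-9)
    if not early.any():
        raise ValidationError("no frame lies fully inside the early window")
    durations = sched.frame_duration_s[early]
    early_img = np.tensordot(phantom.voxels[..., early], durations, axes=([3], [0]))
    early_img /= durations.sum()
    nx, ny, nz = early_img.shape
    if nz < n_slices:
        raise ValidationError("fewer axial slices than n_slices")
    slice_score = early_img.mean(axis=(0, 1))
    top = np.argsort(-slice_score, kind="stable")[:n_slices]
    radius = circle_diameter_px / 2.0
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    mask = np.zeros(early_img.shape, dtype=bool)
    for z in sorted(int(z) for z in top):
        plane = early_img[:, :, z]
        total = plane.sum()
        if total <= 0:
            cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        else:
            cx = float((xs * plane).sum() / total)
            cy = float((ys * plane).sum() / total)
        circle = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
        if cx - radius < 0 or cx + radius > nx - 1 or cy - radius < 0 or cy + radius > ny - 1:
            warnings.warn(f"IDIF circle clipped at image edge on slice z={z}", stacklevel=2)
        mask[:, :, z] |= circle
    return VOIMask(mask, "idif")


def build_idif(
    phantom: DynamicPhantom,
    circle_diameter_px: int = 15,
    n_slices: int = 6,
    early_window_s: float = 20.0,
) -> TimeActivityCurve:
    """Image-derived input function: extract_tac over the heart VOI."""
    voi = idif_voi(phantom, circle_diameter_px, n_slices, early_window_s)
    return extract_tac(phantom, voi)


# --------------------------------------------------------------------------
# SUV
# --------------------------------------------------------------------------

def to_suv(tac: TimeActivityCurve, subject: SubjectRecord) -> TimeActivityCurve:
    """SUV = concentration [kBq/mL] x body weight [g] / injected dose [kBq]."""
    if tac.units_mode != "concentration":
        raise ValidationError("TAC is already in SUV mode")
    factor = subject.body_weight_g / subject.injected_dose_kBq
    return replace(tac, values=tac.values * factor, units_mode="SUV", subject=subject)


# --------------------------------------------------------------------------
# NIfTI I/O
# --------------------------------------------------------------------------

def write_phantom(phantom: DynamicPhantom, outdir: str | Path, stem: str = "phantom") -> Path:
    """Write the 4D image and label map as NIfTI-1 plus a timing sidecar."""
    import nibabel as nib

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(phantom.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(phantom.voxels.astype(np.float32), affine), out / f"{stem}.nii")
    nib.save(
        nib.Nifti1Image(phantom.organ_labels.astype(np.uint8), affine),
        out / f"{stem}_labels.nii",
    )
    phantom.schedule.to_file(out / f"{stem}_frames.csv")
    return out


def read_phantom(outdir: str | Path, stem: str = "phantom") -> DynamicPhantom:
    import nibabel as nib

    out = Path(outdir)
    img = nib.load(out / f"{stem}.nii")
    labels = nib.load(out / f"{stem}_labels.nii")
    schedule = FrameSchedule.from_file(out / f"{stem}_frames.csv")
    voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
    return DynamicPhantom(
        np.asarray(img.dataobj, dtype=float),
        voxel_size,
        schedule,
        np.asarray(labels.dataobj, dtype=np.uint8),
    )
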