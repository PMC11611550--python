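"""Volume container, NIfTI-1 I/O, and the standard preprocessing chain.

A PET study enters training through a fixed per-volume chain:

1. background stripping (largest connected component over an Otsu threshold,
   holes filled — an automated surrogate for manual skull/background removal);
2. trilinear resampling to the network grid, preserving physical extent;
3. z-scoring of in-mask intensities;
4. an affine map of the volume's [min, max] onto [-1, 1].

Every constant of steps 3-4 is kept in a :class:`PreprocRecord`, so the chain
can be inverted exactly (``mode="exact"``) for round-trip checks, or
approximately (``mode="paper"``: (v+1)/2 times a study scale constant) the way
denoised outputs are rescaled before SUV computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing (mm), origin and orientation."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("Volume requires a 3D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy_with(self, voxels: np.ndarray, **kw) -> "Volume":
        return Volume(voxels, kw.get("spacing_mm", self.spacing_mm),
                      kw.get("origin", self.origin), kw.get("orientation", self.orientation),
                      dict(kw.get("extra", self.extra)))


@dataclass
class PreprocRecord:
    """Everything needed to invert normalisation + rescaling exactly."""

    brain_mask: np.ndarray | None = None
    resample_shape: tuple[int, int, int] | None = None
    norm_mean: float = 0.0
    norm_sd: float = 1.0
    rescale_min: float = 0.0
    rescale_max: float = 1.0
    study_scale_constant: float = 1.0
    steps: list = field(default_factory=list)

    def to_json(self, path: str | Path, mask_path: str | Path | None = None) -> None:
        d = {
            "resample_shape": list(self.resample_shape) if self.resample_shape else None,
            "norm_mean": self.norm_mean,
            "norm_sd": self.norm_sd,
            "rescale_min": self.rescale_min,
            "rescale_max": self.rescale_max,
            "study_scale_constant": self.study_scale_constant,
            "steps": self.steps,
            "mask_path": str(mask_path) if mask_path else None,
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocRecord":
        d = json.loads(Path(path).read_text())
        mask = None
        if d.get("mask_path"):
            mask = read_volume(d["mask_path"]).voxels.astype(bool)
        return cls(
            brain_mask=mask,
            resample_shape=tuple(d["resample_shape"]) if d["resample_shape"] else None,
            norm_mean=d["norm_mean"], norm_sd=d["norm_sd"],
            rescale_min=d["rescale_min"], rescale_max=d["rescale_max"],
            study_scale_constant=d["study_scale_constant"], steps=d.get("steps", []),
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> Volume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
    except Exception as exc:  # noqa: BLE001 - surface path in message
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(data, zooms, origin)


def write_volume(volume: Volume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Preprocessing steps
# ---------------------------------------------------------------------------

def strip_background(volume: Volume) -> tuple[Volume, np.ndarray]:
    """Zero background voxels; the mask is the hole-filled largest connected
    component above an Otsu threshold."""
    v = volume.voxels
    if v.min() < 0:
        raise ValueError("strip_background expects nonnegative intensities")
    finite = v[np.isfinite(v)]
    if finite.max() <= 0:
        raise ValueError("volume has no positive voxels: empty brain mask")
    uniq = np.unique(finite)
    if uniq.size == 1:
        mask = v > 0  # uniform positive volume: keep everything
    else:
        thr = threshold_otsu(finite)
        mask = v > thr
        lab, n = ndimage.label(mask)
        if n == 0:
            raise ValueError("empty brain mask after thresholding")
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
        mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise ValueError("empty brain mask")
    out = volume.copy_with(np.where(mask, v, 0.0))
    return out, mask


def resample(volume: Volume, target_shape: tuple[int, int, int], order: int = 1) -> Volume:
    """Trilinear resampling; spacing rescaled so physical extent is preserved."""
    target_shape = tuple(int(t) for t in target_shape)
    if any(t < 1 for t in target_shape):
        raise ValueError(f"degenerate target shape {target_shape}")
    src = volume.voxels.astype(np.float64)
    factors = [t / s for t, s in zip(target_shape, src.shape)]
    if target_shape == src.shape:
        out = src.copy()
    else:
        out = ndimage.zoom(src, factors, order=order, mode="nearest", grid_mode=True)
        out = out[: target_shape[0], : target_shape[1], : target_shape[2]]
    if volume.voxels.min() >= 0:
        out = np.clip(out, 0.0, None)
    new_spacing = tuple(sp * s / t for sp, s, t in zip(volume.spacing_mm, src.shape, target_shape))
    return Volume(out.astype(np.float32), new_spacing, volume.origin, volume.orientation)


def normalize_and_rescale(volume: Volume, mask: np.ndarray | None = None,
                          study_scale_constant: float | None = None
                          ) -> tuple[Volume, PreprocRecord]:
    """Z-score in-mask intensities, then map the volume's [min, max] to [-1, 1]."""
    v = volume.voxels.astype(np.float64)
    if mask is None:
        mask = v != 0
    if not mask.any():
        raise ValueError("empty mask")
    mu = float(v[mask].mean())
    sd = float(v[mask].std())
    if sd == 0:
        raise ValueError("constant volume: standard deviation is zero")
    z = np.where(mask, (v - mu) / sd, 0.0)
    lo, hi = float(z.min()), float(z.max())
    if hi == lo:
        raise ValueError("degenerate intensity range after z-scoring")
    r = -1.0 + 2.0 * (z - lo) / (hi - lo)
    rec = PreprocRecord(
        brain_mask=mask.copy(), resample_shape=volume.shape,
        norm_mean=mu, norm_sd=sd, rescale_min=lo, rescale_max=hi,
        study_scale_constant=float(v.max() if study_scale_constant is None
                                   else study_scale_constant),
        steps=["normalize", "rescale"],
    )
    return volume.copy_with(r.astype(np.float32)), rec


def invert_rescale(volume: Volume, record: PreprocRecord, mode: str = "exact") -> Volume:
    """Map a [-1, 1] volume back to intensity units.

    ``mode="paper"``: (v + 1) / 2 scaled by the study constant — the
    approximate inversion applied to denoised outputs before SUV computation.
    ``mode="exact"``: full inverse of the recorded affine + z-score chain.
    """
    v = volume.voxels.astype(np.float64)
    if mode == "paper":
        if record.study_scale_constant is None:
            raise ValueError("record lacks study_scale_constant")
        out = (v + 1.0) / 2.0 * record.study_scale_constant
    elif mode == "exact":
        if record.brain_mask is None:
            raise ValueError("exact inversion requires the recorded brain mask")
        z = record.rescale_min + (v + 1.0) * (record.rescale_max - record.rescale_min) / 2.0
        out = np.where(record.brain_mask, record.norm_mean + record.norm_sd * z, 0.0)
    else:
        raise ValueError(f"unknown inversion mode {mode!r}")
    return volume.copy_with(out.astype(np.float32))


def preprocess(volume: Volume, target_shape: tuple[int, int, int] = (128, 128, 128),
               study_scale_constant: float | None = None) -> tuple[Volume, PreprocRecord]:
    """Full chain: strip -> resample -> normalize -> rescale (order is fixed)."""
    stripped, mask = strip_background(volume)
    res = resample(stripped, target_shape)
    mask_res = resample(Volume(mask.astype(np.float32), volume.spacing_mm),
                        target_shape, order=0).voxels > 0.5
    out, rec = normalize_and_rescale(res, mask=mask_res,
                                     study_scale_constant=study_scale_constant)
    rec.steps = ["strip_background", "resample", "normalize", "rescale"]
    return out, rec
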