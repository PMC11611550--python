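"""Synthetic digital brain phantoms with paired standard- and low-count PET.

The phantom is a nested-ellipsoid brain — a CSF (ventricular) core, a white
matter shell and a grey matter rim — with bilateral deep-grey nuclei and
named cortical territories carved out of the rim by geometric predicates.
Default tissue activity contrast is GM:WM:CSF = 4:1:0.3, the textbook FDG
pattern.  Counting statistics follow emission-tomography physics at the image
level: the standard-dose scan draws independent Poisson counts per voxel from
an expected-count map, and the low-dose arm thins each detected event
independently with probability ``thinning_fraction`` (binomial thinning, the
count-statistics analogue of reconstructing 10% of the list-mode frames).
A Gaussian point-spread blur stands in for reconstruction resolution.

Axis convention: axis 0 = left-right (the midsagittal plane is the central
x index), axis 1 = posterior-anterior, axis 2 = inferior-superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume_io import Volume, write_volume

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: integer labels; cortical territories and nuclei are grey matter tissue
TISSUE_LABELS = {"background": 0, "csf": 1, "wm": 2, "gm": 3}
REGION_LABELS = {
    "cerebellum": 10, "occipital": 11, "hippocampus": 12, "temporal": 13,
    "frontal": 14, "parietal": 15, "insula": 16, "caudate": 17,
    "putamen": 18, "thalamus": 19,
}
LESION_LABEL_BASE = 100
#: labels whose tissue class is grey matter
GM_FAMILY = {TISSUE_LABELS["gm"], *REGION_LABELS.values()}


@dataclass
class Lesion:
    center: tuple[int, int, int]
    radius_mm: float
    multiplier: float


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    activity_ratio_gm_wm_csf: tuple[float, float, float] = (4.0, 1.0, 0.3)
    total_counts_standard: int = 20_000_000
    thinning_fraction: float = 0.10
    lesion_list: list[Lesion] = field(default_factory=list)
    psf_fwhm_mm: float = 4.0
    asymmetry: float | None = None  # left-hemisphere activity multiplier
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.thinning_fraction <= 1.0):
            raise ValueError("thinning_fraction must lie in (0, 1]")
        if any(r <= 0 for r in self.activity_ratio_gm_wm_csf):
            raise ValueError("activity ratios must be strictly positive")
        if self.total_counts_standard <= 0:
            raise ValueError("total_counts_standard must be positive")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be nonnegative")
        half_extent = 0.5 * min(n * s for n, s in zip(self.grid_shape, self.voxel_size_mm))
        for i, les in enumerate(self.lesion_list):
            if les.radius_mm >= half_extent:
                raise ValueError(f"lesion {i}: radius exceeds half the grid extent")


@dataclass
class LabelMap:
    labels: np.ndarray
    names: dict[str, int]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.names[name]

    def gm_mask(self) -> np.ndarray:
        return np.isin(self.labels, list(GM_FAMILY))

    def wm_mask(self) -> np.ndarray:
        return self.labels == self.names["wm"]

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def region_names(self) -> list[str]:
        return [n for n in self.names if self.names[n] >= 10]

    @property
    def midsagittal_index(self) -> int:
        return self.labels.shape[0] // 2


def _normalized_coords(shape, spacing):
    """Coordinates scaled to roughly [-1, 1] over the brain-bounding ellipsoid."""
    axes = []
    for n, sp in zip(shape, spacing):
        c = (np.arange(n) - (n - 1) / 2.0) * sp
        axes.append(c)
    x, y, z = np.meshgrid(*axes, indexing="ij")
    semi = [0.44 * n * sp for n, sp in zip(shape, spacing)]
    return x / semi[0], y / semi[1], z / semi[2]


def _ellipsoid(x, y, z, cx, cy, cz, rx, ry, rz):
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def build_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap]:
    """Deterministic activity volume + label map for a phantom specification."""
    shape, spacing = spec.grid_shape, spec.voxel_size_mm
    x, y, z = _normalized_coords(shape, spacing)
    r2 = x**2 + y**2 + z**2

    brain = r2 <= 1.0
    csf = r2 <= 0.25**2  # central ventricular core
    gm_rim = brain & (r2 > 0.72**2)
    wm = brain & ~gm_rim & ~csf

    labels = np.zeros(shape, dtype=np.int16)
    labels[csf] = TISSUE_LABELS["csf"]
    labels[wm] = TISSUE_LABELS["wm"]
    labels[gm_rim] = TISSUE_LABELS["gm"]

    # cortical territories carved from the rim (order sets precedence)
    rim = gm_rim
    sectors = {
        "cerebellum": rim & (y < -0.35) & (z < -0.35),
        "occipital": rim & (y < -0.45) & (z >= -0.35),
        "frontal": rim & (y > 0.45),
        "parietal": rim & (z > 0.5) & (np.abs(y) <= 0.45),
        "temporal": rim & (np.abs(x) > 0.45) & (z < -0.05) & (np.abs(y) <= 0.45) & (y >= -0.35),
        "insula": rim & (np.abs(x) > 0.55) & (np.abs(z) <= 0.3) & (np.abs(y) <= 0.45),
    }
    assigned = np.zeros(shape, dtype=bool)
    for name, m in sectors.items():
        m = m & ~assigned
        labels[m] = REGION_LABELS[name]
        assigned |= m

    # bilateral deep structures (grey matter activity, own labels)
    for name, (cx, cy, cz), rad in [
        ("caudate", (0.28, 0.18, 0.12), (0.12, 0.16, 0.14)),
        ("putamen", (0.42, 0.02, 0.0), (0.13, 0.17, 0.13)),
        ("thalamus", (0.18, -0.15, 0.02), (0.14, 0.16, 0.14)),
        ("hippocampus", (0.38, -0.18, -0.32), (0.12, 0.18, 0.12)),
    ]:
        for sgn in (+1, -1):
            m = _ellipsoid(x, y, z, sgn * cx, cy, cz, *rad) & (labels == TISSUE_LABELS["wm"])
            labels[m] = REGION_LABELS[name]

    gm_a, wm_a, csf_a = spec.activity_ratio_gm_wm_csf
    activity = np.zeros(shape, dtype=np.float64)
    activity[labels == TISSUE_LABELS["csf"]] = csf_a
    activity[labels == TISSUE_LABELS["wm"]] = wm_a
    activity[np.isin(labels, list(GM_FAMILY))] = gm_a

    # lesions multiply the underlying tissue activity
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    for idx, les in enumerate(spec.lesion_list):
        ci, cj, ck = les.center
        d2 = (((ii - ci) * spacing[0]) ** 2 + ((jj - cj) * spacing[1]) ** 2
              + ((kk - ck) * spacing[2]) ** 2)
        sphere = d2 <= les.radius_mm**2
        if not sphere.any() or np.any(sphere & ~brain):
            raise ValueError(f"lesion {idx} at {les.center} extends outside the brain mask")
        activity[sphere] *= les.multiplier
        labels[sphere] = LESION_LABEL_BASE + idx

    if spec.asymmetry is not None:
        left = ii < shape[0] // 2
        activity[left & brain] *= spec.asymmetry

    names = dict(TISSUE_LABELS)
    names.update(REGION_LABELS)
    for idx in range(len(spec.lesion_list)):
        names[f"lesion_{idx}"] = LESION_LABEL_BASE + idx
    vol = Volume(activity, spacing)
    return vol, LabelMap(labels, names, spacing)


def _psf_blur(arr: np.ndarray, fwhm_mm: float, spacing) -> np.ndarray:
    if fwhm_mm <= 0:
        return arr
    sigma = [fwhm_mm * FWHM_TO_SIGMA / sp for sp in spacing]
    return gaussian_filter(arr.astype(np.float64), sigma=sigma, mode="constant")


def simulate_standard_dose(activity: Volume, spec: PhantomSpec,
                           rng: np.random.Generator | None = None) -> Volume:
    """Poisson counts from the activity map, PSF-blurred.

    The raw (pre-blur) integer counts are kept in ``extra["counts"]`` so the
    low-dose arm can thin the actual detected events.
    """
    a = np.asarray(activity.voxels, dtype=np.float64)
    if a.min() < 0:
        raise ValueError("activity must be nonnegative")
    total = a.sum()
    if total <= 0:
        raise ValueError("all-zero activity map")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lam = a * (spec.total_counts_standard / total)
    counts = rng.poisson(lam).astype(np.float64)
    img = _psf_blur(counts, spec.psf_fwhm_mm, activity.spacing_mm)
    out = activity.copy_with(img.astype(np.float32))
    out.extra["counts"] = counts
    return out


def simulate_low_dose(standard: Volume, spec: PhantomSpec,
                      rng: np.random.Generator | None = None) -> Volume:
    """Binomially thin the standard-dose counts, then apply the same PSF blur.

    The blurred image is divided by the thinning fraction so its intensity
    scale matches the standard-dose image (as scaling by frame duration does
    for a short reconstruction); the raw thinned counts stay in
    ``extra["counts"]``.
    """
    p = spec.thinning_fraction
    if not (0.0 < p <= 1.0):
        raise ValueError("thinning_fraction must lie in (0, 1]")
    counts = standard.extra.get("counts")
    if counts is None:
        counts = np.asarray(standard.voxels)
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValueError("standard volume does not carry integer counts")
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    thinned = rng.binomial(np.asarray(counts, dtype=np.int64), p).astype(np.float64)
    img = _psf_blur(thinned, spec.psf_fwhm_mm, standard.spacing_mm) / p
    out = standard.copy_with(img.astype(np.float32))
    out.extra = {"counts": thinned}
    return out


@dataclass
class ScanMeta:
    subject_id: str
    body_weight: float  # kg
    injected_dose: float  # MBq
    seed: int = 0


@dataclass
class ScanPair:
    low: Volume
    standard: Volume
    meta: ScanMeta


@dataclass
class CohortJitter:
    """Per-subject variation ranges for :func:`make_cohort`."""

    scale: float = 0.06            # fractional semi-axis variation
    activity: float = 0.08         # fractional GM/WM/CSF ratio variation
    lesion_probability: float = 0.0
    lesion_multiplier: float = 0.6
    lesion_radius_mm: tuple[float, float] = (8.0, 14.0)
    dose_range_mbq: tuple[float, float] = (150.0, 250.0)
    weight_range_kg: tuple[float, float] = (50.0, 90.0)
    target_brain_suv: float = 5.0  # sets the counts->concentration calibration


def _calibrate_concentration(pair_img: np.ndarray, brain: np.ndarray,
                             dose: float, weight: float, target_suv: float) -> float:
    """Scale factor mapping blurred counts to kBq/mL so mean brain SUV is
    ``target_suv`` (SUV = C x BW / Dose in the g/mL convention)."""
    mean_counts = pair_img[brain].mean()
    return target_suv * dose / (weight * mean_counts)


def make_cohort(n_subjects: int, base_spec: PhantomSpec,
                jitter: CohortJitter | None = None,
                out_dir: str | Path | None = None
                ) -> tuple[list[tuple[ScanPair, LabelMap]], pd.DataFrame]:
    """Generate a cohort of paired low/standard scans with subject variation.

    Volumes are calibrated to activity-concentration units (kBq/mL).  When
    ``out_dir`` is given, NIfTI files and a manifest CSV are written.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    jitter = jitter or CohortJitter()
    master = np.random.default_rng(base_spec.seed)
    subjects: list[tuple[ScanPair, LabelMap]] = []
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for s in range(n_subjects):
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        ratios = tuple(
            r * (1.0 + jitter.activity * float(rng.uniform(-1, 1)))
            for r in base_spec.activity_ratio_gm_wm_csf
        )
        vox = tuple(
            v * (1.0 + jitter.scale * float(rng.uniform(-1, 1)))
            for v in base_spec.voxel_size_mm
        )
        lesions = list(base_spec.lesion_list)
        if rng.uniform() < jitter.lesion_probability:
            shape = base_spec.grid_shape
            # place in the left temporal-ish quadrant, inside the rim
            center = (int(shape[0] * 0.25), int(shape[1] * 0.4), int(shape[2] * 0.35))
            radius = float(rng.uniform(*jitter.lesion_radius_mm))
            lesions.append(Lesion(center, radius, jitter.lesion_multiplier))
        spec = PhantomSpec(
            grid_shape=base_spec.grid_shape, voxel_size_mm=vox,
            activity_ratio_gm_wm_csf=ratios,
            total_counts_standard=base_spec.total_counts_standard,
            thinning_fraction=base_spec.thinning_fraction,
            lesion_list=lesions, psf_fwhm_mm=base_spec.psf_fwhm_mm,
            asymmetry=base_spec.asymmetry, seed=sub_seed,
        )
        activity, labels = build_phantom(spec)
        std = simulate_standard_dose(activity, spec, rng)
        low = simulate_low_dose(std, spec, rng)

        dose = float(rng.uniform(*jitter.dose_range_mbq))
        weight = float(rng.uniform(*jitter.weight_range_kg))
        calib = _calibrate_concentration(std.voxels, labels.brain_mask(), dose, weight,
                                         jitter.target_brain_suv)
        std = std.copy_with((std.voxels * calib).astype(np.float32), extra=std.extra)
        low = low.copy_with((low.voxels * calib).astype(np.float32), extra=low.extra)

        meta = ScanMeta(f"sub-{s:03d}", weight, dose, sub_seed)
        pair = ScanPair(low, std, meta)
        subjects.append((pair, labels))

        row = {"subject_id": meta.subject_id, "dose_MBq": dose, "weight_kg": weight,
               "seed": sub_seed, "path_low": "", "path_standard": "", "path_labels": ""}
        if out_dir is not None:
            row["path_low"] = str(write_volume(low, out_dir / f"{meta.subject_id}_low.nii.gz"))
            row["path_standard"] = str(
                write_volume(std, out_dir / f"{meta.subject_id}_standard.nii.gz"))
            lab_vol = Volume(labels.labels.astype(np.float32), labels.spacing_mm)
            row["path_labels"] = str(
                write_volume(lab_vol, out_dir / f"{meta.subject_id}_labels.nii.gz"))
        rows.append(row)

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return subjects, manifest
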