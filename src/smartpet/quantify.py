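"""PET quantification: SUV maps, SUVr, asymmetry z-maps, ROI statistics.

SUV follows the body-weight convention ``SUV = C x BW / Dose`` with the
activity concentration C in kBq/mL, body weight in kg and net injected dose
in MBq, so a uniform 5 kBq/mL volume at 70 kg / 200 MBq gives SUV 1.75
everywhere (g/mL units).  SUVr divides region mean SUVs by a reference
region's mean (cerebellum for epilepsy analyses, occipital lobe otherwise).

The asymmetry index compares each voxel with its mirror across the
midsagittal plane, ``AI = 200 (I - I_mirror) / (I + I_mirror)``, and is
z-scored against the in-mask AI distribution (zAI).  Hypometabolic ROIs are
connected components of zAI below a z threshold (default -2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import mannwhitneyu

from .phantom import FWHM_TO_SIGMA, LabelMap, ScanMeta
from .volume_io import Volume


def suv_map(volume_activity: Volume, meta: ScanMeta) -> Volume:
    """Voxelwise SUV (g/mL): concentration [kBq/mL] x weight [kg] / dose [MBq]."""
    if meta.body_weight <= 0 or meta.injected_dose <= 0:
        raise ValueError("body weight and injected dose must be positive")
    suv = np.asarray(volume_activity.voxels, dtype=np.float64) \
        * meta.body_weight / meta.injected_dose
    return volume_activity.copy_with(suv.astype(np.float32))


def smooth(volume: Volume, fwhm_mm: float = 2.0) -> Volume:
    """Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)) per axis in
    voxel units.  Boundaries are reflective, so constants are invariant and
    total intensity is conserved for signal supported away from the edge."""
    sigma = [fwhm_mm * FWHM_TO_SIGMA / sp for sp in volume.spacing_mm]
    out = ndimage.gaussian_filter(np.asarray(volume.voxels, dtype=np.float64),
                                  sigma=sigma, mode="reflect")
    return volume.copy_with(out.astype(np.float32))


def suvr(suv: Volume, labels: LabelMap, reference: str = "cerebellum") -> pd.DataFrame:
    """Per-region mean SUV and SUVr (region mean / reference region mean)."""
    ref_mask = labels.mask(reference)
    if not ref_mask.any():
        raise ValueError(f"empty reference region {reference!r}")
    v = np.asarray(suv.voxels, dtype=np.float64)
    ref_mean = float(v[ref_mask].mean())
    if ref_mean == 0:
        raise ValueError("reference region mean is zero")
    rows = []
    for name in labels.region_names():
        m = labels.mask(name)
        if not m.any():
            raise ValueError(f"empty region {name!r}")
        mean_suv = float(v[m].mean())
        rows.append({"region": name, "mean_suv": mean_suv,
                     "suvr": mean_suv / ref_mean, "n_voxels": int(m.sum())})
    return pd.DataFrame(rows)


def zai_map(suv: Volume, brain_mask: np.ndarray) -> Volume:
    """Standardised asymmetry index map (mirror across the midsagittal plane,
    i.e. index reflection of axis 0)."""
    v = np.asarray(suv.voxels, dtype=np.float64)
    mirror = v[::-1, :, :]
    mask = brain_mask & brain_mask[::-1, :, :]
    denom = v + mirror
    valid = mask & (denom > 0)
    ai = np.zeros_like(v)
    ai[valid] = 200.0 * (v[valid] - mirror[valid]) / denom[valid]
    inside = ai[valid]
    if inside.size == 0 or float(inside.std()) == 0.0:
        zai = np.zeros_like(v)  # perfectly symmetric: no asymmetry signal
    else:
        zai = np.zeros_like(v)
        zai[valid] = (inside - inside.mean()) / inside.std()
    return suv.copy_with(zai.astype(np.float32))


@dataclass
class HypoROI:
    label_map: np.ndarray
    volumes_mm3: dict[int, float]


def hypometabolic_roi(zai: Volume, threshold: float = -2.0) -> HypoROI:
    """Connected components of zAI below the threshold, with mm^3 sizes."""
    mask = np.asarray(zai.voxels) < threshold
    lab, n = ndimage.label(mask)
    voxel_mm3 = float(np.prod(zai.spacing_mm))
    sizes = {}
    for comp in range(1, n + 1):
        sizes[comp] = float((lab == comp).sum()) * voxel_mm3
    return HypoROI(lab, sizes)


def compare_cohort(dn_reports: pd.DataFrame, sd_reports: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-region Mann-Whitney U comparison of SUVr between arms, plus the
    absolute percent SUVr deviation per region (paired by subject).

    Inputs are long-form tables with columns subject, region, suvr.
    """
    for df, name in ((dn_reports, "dn"), (sd_reports, "sd")):
        missing = {"subject", "region", "suvr"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns {missing}")
    rows = []
    for region in sorted(sd_reports["region"].unique()):
        x = dn_reports.loc[dn_reports["region"] == region, ["subject", "suvr"]]
        y = sd_reports.loc[sd_reports["region"] == region, ["subject", "suvr"]]
        if len(x) < 3 or len(y) < 3:
            raise ValueError(f"need >= 3 subjects per arm in region {region!r}")
        u, p = mannwhitneyu(x["suvr"], y["suvr"], alternative="two-sided")
        merged = x.merge(y, on="subject", suffixes=("_dn", "_sd"))
        dev = 100.0 * np.abs(merged["suvr_dn"] - merged["suvr_sd"]) / merged["suvr_sd"]
        rows.append({
            "region": region, "U": float(u), "p": float(p),
            "significant": bool(p < alpha),
            "pct_dev_mean": float(dev.mean()), "pct_dev_sd": float(dev.std(ddof=1)),
        })
    return pd.DataFrame(rows)


def cohort_suvr_table(suv_volumes: list[Volume], labels: list[LabelMap],
                      reference: str = "cerebellum") -> pd.DataFrame:
    """Long-form subject x region SUVr table for :func:`compare_cohort`."""
    rows = []
    for i, (vol, lab) in enumerate(zip(suv_volumes, labels)):
        t = suvr(vol, lab, reference)
        t["subject"] = i
        rows.append(t)
    return pd.concat(rows, ignore_index=True)
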