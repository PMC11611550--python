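"""Image-quality metrics comparing denoised volumes against standard-dose.

Six quantities per pair: SSIM, PSNR (dB), NRMSE, FID, and relative SNR/CNR
deviation.  Direction conventions: higher SSIM/PSNR is better; NRMSE, FID and
the SNR/CNR deviation metrics are zero for a perfect match and grow with
degradation.

FID features come from a fixed-architecture, fixed-seed random-projection
convolutional extractor applied to axial slices.  Random projections preserve
distributional geometry well enough for an internally comparable Fréchet
distance; absolute values are not comparable to Inception-feature FIDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .grad import Tensor
from .nn import Conv3d, Module
from .phantom import LabelMap


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def ssim(a: np.ndarray, b: np.ndarray, data_range: float | None = None,
         sigma: float = 1.5, win_size: int = 11,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean local SSIM with a Gaussian window; ``b`` is the reference whose
    intensity range is used unless ``data_range`` is given."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    _check_shapes(a, b)
    if data_range is None:
        data_range = float(b.max() - b.min())
        if data_range == 0:
            raise ValueError("reference volume has zero intensity range")
    return float(structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=sigma,
        win_size=win_size, K1=k1, K2=k2, use_sample_covariance=False))


def psnr(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """10 log10(range(b)^2 / MSE); +inf for identical volumes."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    _check_shapes(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return float("inf")
    if data_range is None:
        data_range = float(b.max() - b.min())
    return float(10.0 * np.log10(data_range**2 / mse))


def nrmse(a: np.ndarray, b: np.ndarray) -> float:
    """RMSE normalised by the reference's root mean square."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    _check_shapes(a, b)
    denom = float(np.sqrt(np.mean(b**2)))
    if denom == 0:
        raise ValueError("zero-energy reference volume")
    return float(np.sqrt(np.mean((a - b) ** 2)) / denom)


# ---------------------------------------------------------------------------
# FID
# ---------------------------------------------------------------------------

class SliceFeatureExtractor(Module):
    """Fixed, seeded random-projection convnet mapping axial slices to
    feature vectors.  Weights are frozen at construction."""

    def __init__(self, feature_dim: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.conv1 = Conv3d(1, 8, (1, 3, 3), stride=(1, 2, 2), padding=(0, 1, 1), rng=rng)
        self.conv2 = Conv3d(8, feature_dim, (1, 3, 3), stride=(1, 2, 2), padding=(0, 1, 1),
                            rng=rng)
        self.feature_dim = feature_dim
        for p in self.parameters():
            p.requires_grad = False

    def forward(self, x: Tensor) -> Tensor:
        """(n_slices, 1, 1, H, W) -> (n_slices, feature_dim)."""
        h = self.conv1(x).leaky_relu(0.2)
        h = self.conv2(h).leaky_relu(0.2)
        return h.mean(axis=(2, 3, 4))

    def features_tensor(self, volume: Tensor) -> Tensor:
        """Differentiable features for one (1, 1, D, H, W) volume tensor:
        every axial (fixed-z) slice becomes one feature vector."""
        d = volume.shape[4]
        x = volume.transpose(0, 4, 1, 2, 3)  # (1, D, 1, X, Y) -> slices on batch
        x = x.reshape(d, 1, 1, volume.shape[2], volume.shape[3])
        return self.forward(x)

    def features(self, volumes: list[np.ndarray]) -> np.ndarray:
        feats = []
        for v in volumes:
            v = np.asarray(v, dtype=np.float32)
            if v.ndim == 3:
                v = v[None, None]
            if v.ndim != 5:
                raise ValueError(f"expected a 3D volume, got shape {v.shape}")
            feats.append(self.features_tensor(Tensor(v)).data)
        return np.concatenate(feats, axis=0)


def frechet_distance(feats_a: np.ndarray, feats_b: np.ndarray) -> float:
    """||mu_a - mu_b||^2 + Tr(Sa + Sb - 2 (Sa Sb)^(1/2)) via a symmetric
    eigendecomposition of Sb^(1/2) Sa Sb^(1/2)."""
    fa = np.atleast_2d(np.asarray(feats_a, dtype=np.float64))
    fb = np.atleast_2d(np.asarray(feats_b, dtype=np.float64))
    if fa.shape[0] < 2 or fb.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors per set")
    mu_a, mu_b = fa.mean(axis=0), fb.mean(axis=0)
    sa = np.atleast_2d(np.cov(fa, rowvar=False))
    sb = np.atleast_2d(np.cov(fb, rowvar=False))
    if not (np.all(np.isfinite(sa)) and np.all(np.isfinite(sb))):
        raise ValueError("non-finite covariance")
    eb, ub = np.linalg.eigh(sb)
    sb_half = (ub * np.sqrt(np.clip(eb, 0.0, None))) @ ub.T
    m = sb_half @ sa @ sb_half
    em = np.linalg.eigvalsh(m)
    tr_sqrt = float(np.sqrt(np.clip(em, 0.0, None)).sum())
    diff = mu_a - mu_b
    val = float(diff @ diff + np.trace(sa) + np.trace(sb) - 2.0 * tr_sqrt)
    return max(val, 0.0)


def fid(set_a: list[np.ndarray], set_b: list[np.ndarray],
        extractor: SliceFeatureExtractor | None = None) -> float:
    extractor = extractor or SliceFeatureExtractor()
    return frechet_distance(extractor.features(set_a), extractor.features(set_b))


# ---------------------------------------------------------------------------
# Region SNR / CNR deviation metrics
# ---------------------------------------------------------------------------

def _snr_cnr(vol: np.ndarray, gm: np.ndarray, wm: np.ndarray) -> tuple[float, float]:
    m_gm = float(vol[gm].mean())
    m_wm = float(vol[wm].mean())
    s_wm = float(vol[wm].std())
    if s_wm == 0:
        raise ValueError("white-matter noise is zero; SNR undefined")
    return m_gm / s_wm, (m_gm - m_wm) / s_wm


def snr_cnr_metrics(dn: np.ndarray, sd: np.ndarray, labels: LabelMap
                    ) -> tuple[float, float]:
    """Relative absolute deviation of GM/WM SNR and CNR between a candidate
    and the reference; 0 means perfect agreement."""
    _check_shapes(np.asarray(dn), np.asarray(sd))
    gm, wm = labels.gm_mask(), labels.wm_mask()
    if not gm.any() or not wm.any():
        raise ValueError("empty GM or WM region")
    snr_dn, cnr_dn = _snr_cnr(np.asarray(dn, dtype=np.float64), gm, wm)
    snr_sd, cnr_sd = _snr_cnr(np.asarray(sd, dtype=np.float64), gm, wm)
    return abs(snr_dn - snr_sd) / abs(snr_sd), abs(cnr_dn - cnr_sd) / abs(cnr_sd)


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    per_pair: pd.DataFrame
    summary: pd.DataFrame


def evaluate_pairs(candidates: list[np.ndarray], references: list[np.ndarray],
                   labels: list[LabelMap] | None = None,
                   extractor: SliceFeatureExtractor | None = None) -> MetricReport:
    """All six metrics for a cohort of (candidate, reference) volume pairs."""
    if len(candidates) != len(references):
        raise ValueError("candidate and reference counts differ")
    extractor = extractor or SliceFeatureExtractor()
    rows = []
    for i, (a, b) in enumerate(zip(candidates, references)):
        row = {
            "pair": i,
            "ssim": ssim(a, b),
            "psnr_db": psnr(a, b),
            "nrmse": nrmse(a, b),
            "fid": fid([a], [b], extractor),
        }
        if labels is not None:
            s, c = snr_cnr_metrics(a, b, labels[i])
            row["snr_metric"], row["cnr_metric"] = s, c
        rows.append(row)
    per_pair = pd.DataFrame(rows)
    cols = [c for c in per_pair.columns if c != "pair"]
    summary = per_pair[cols].agg(["mean", "std"])
    return MetricReport(per_pair, summary)
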