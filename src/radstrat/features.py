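"""Texture feature extraction from masked 2D ROI images.

Four feature families are computed inside the ROI mask of each modality
image:

* first-order histogram statistics of the raw intensities (15 features),
* gray-level co-occurrence matrix (GLCM) features in the Haralick
  tradition, averaged over the four distance-1 directions (20 features),
* gray-level difference matrix (GLDM) features on the distribution of
  absolute quantized-intensity differences, averaged over the same four
  directions (8 features),
* Fourier spectral features of the mean-filled mask bounding box
  (12 features),

for 55 features per modality and 110 per patient (T2W-like block followed
by ADC-like block).  Gray levels are obtained by linear min--max
quantization over the in-mask intensity range: 64 levels for the histogram
entropy/uniformity, 32 levels for GLCM/GLDM (both configurable).

Conventions for degenerate inputs (constant image, zero marginal variance,
zero non-DC spectral power) are fixed here and exercised by the test
suite: statistics that would be 0/0 are defined as 0, except homogeneity
and the inverse-difference family, which are defined at their maximum.

Coordinate convention: offsets and displacements are row-major ``(dy, dx)``
with the origin at the top-left pixel.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import manifest
from .errors import InvalidInputError, InvalidSpecError
from .image import ROIImage

#: Distance-1 offsets at 0, 45, 90 and 135 degrees, row-major (dy, dx).
DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

#: Sentinel gray level for out-of-mask pixels in quantized images.
INVALID = -1


@dataclass(frozen=True)
class FeatureConfig:
    """Quantization settings for the texture families."""

    levels_glcm: int = 32
    levels_hist: int = 64
    offsets: tuple[tuple[int, int], ...] = DIRECTIONS

    def __post_init__(self) -> None:
        if self.levels_glcm < 2 or self.levels_hist < 2:
            raise InvalidSpecError("quantization levels must be >= 2")


DEFAULT_CONFIG = FeatureConfig()


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def quantize(roi: ROIImage, levels: int) -> np.ndarray:
    """Linear min–max quantization of in-mask intensities into ``levels`` bins.

    Returns an integer array of the same shape with codes ``0..levels-1``
    inside the mask and :data:`INVALID` outside.  The in-mask maximum maps
    to ``levels - 1``; a constant image maps entirely to bin 0.
    """
    if levels < 2:
        raise InvalidSpecError(f"levels must be >= 2, got {levels}")
    vals = roi.in_mask
    lo, hi = float(vals.min()), float(vals.max())
    q = np.full(roi.intensities.shape, INVALID, dtype=np.int64)
    if hi > lo:
        codes = np.floor((roi.intensities - lo) / (hi - lo) * levels)
        codes = np.clip(codes, 0, levels - 1)
    else:
        codes = np.zeros_like(roi.intensities)
    q[roi.mask] = codes[roi.mask].astype(np.int64)
    return q


# ---------------------------------------------------------------------------
# first-order histogram features
# ---------------------------------------------------------------------------

def histogram_features(
    roi: ROIImage, levels: int = DEFAULT_CONFIG.levels_hist
) -> dict[str, float]:
    """First-order statistics of the in-mask intensity distribution.

    Skewness and excess kurtosis are defined as 0 for a constant image;
    entropy (base 2) and uniformity are computed on the ``levels``-bin
    min–max quantized histogram.
    """
    vals = roi.in_mask
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if sd > 0:
        skew = float(stats.skew(vals))
        kurt = float(stats.kurtosis(vals))  # excess kurtosis
    else:
        skew = kurt = 0.0
    codes = quantize(roi, levels)[roi.mask]
    p = np.bincount(codes, minlength=levels) / codes.size
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    p10, p25, med, p75, p90 = np.percentile(vals, [10, 25, 50, 75, 90])
    out = {
        "hist_mean": float(vals.mean()),
        "hist_sd": sd,
        "hist_variance": sd * sd,
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_min": float(vals.min()),
        "hist_max": float(vals.max()),
        "hist_range": float(vals.max() - vals.min()),
        "hist_median": float(med),
        "hist_p10": float(p10),
        "hist_p25": float(p25),
        "hist_p75": float(p75),
        "hist_p90": float(p90),
        "hist_entropy": entropy,
        "hist_uniformity": float((p * p).sum()),
    }
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def compute_glcm(qimg: np.ndarray, offset: tuple[int, int], levels: int) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix.

    Counts ordered in-mask pixel pairs ``(p, p + offset)``, adds the
    transpose (so each pair contributes in both directions) and normalizes
    to sum 1.  Out-of-mask pixels (code :data:`INVALID`) never pair.
    """
    dy, dx = offset
    if (dy, dx) == (0, 0):
        raise InvalidInputError("offset must be nonzero")
    a, b = _shifted_pairs(qimg, dy, dx)
    valid = (a != INVALID) & (b != INVALID)
    if not valid.any():
        raise InvalidInputError(f"no valid pixel pair for offset {offset}")
    counts = np.bincount(
        a[valid] * levels + b[valid], minlength=levels * levels
    ).reshape(levels, levels).astype(float)
    counts = counts + counts.T
    return counts / counts.sum()


def _shifted_pairs(qimg: np.ndarray, dy: int, dx: int) -> tuple[np.ndarray, np.ndarray]:
    """Aligned views (origin pixel, offset pixel) for a row-major offset."""
    h, w = qimg.shape
    if abs(dy) >= h or abs(dx) >= w:
        raise InvalidInputError(f"offset ({dy},{dx}) exceeds image extent {qimg.shape}")
    ys = slice(max(0, -dy), min(h, h - dy))
    xs = slice(max(0, -dx), min(w, w - dx))
    ys2 = slice(max(0, dy), min(h, h + dy))
    xs2 = slice(max(0, dx), min(w, w + dx))
    return qimg[ys, xs].ravel(), qimg[ys2, xs2].ravel()


def glcm_features(glcm: np.ndarray) -> dict[str, float]:
    """Haralick-style features of a symmetric normalized GLCM.

    Correlation is defined as 0 when the marginal variance vanishes
    (constant image); homogeneity and the inverse-difference features then
    take their maximum value 1 by construction.
    """
    P = np.asarray(glcm, dtype=float)
    L = P.shape[0]
    i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    pi = P.sum(axis=1)  # marginal (symmetric => both marginals equal)
    mu = float((np.arange(L) * pi).sum())
    var = float(((np.arange(L) - mu) ** 2 * pi).sum())

    diff = np.abs(i - j)
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    contrast = float(((i - j) ** 2 * P).sum())
    autocorr = float((i * j * P).sum())
    correlation = (autocorr - mu * mu) / var if var > 0 else 0.0

    # distributions of the sum i+j and the absolute difference |i-j|
    p_sum = np.bincount((i + j).ravel(), weights=P.ravel(), minlength=2 * L - 1)
    p_diff = np.bincount(diff.ravel(), weights=P.ravel(), minlength=L)
    ks = np.arange(2 * L - 1)
    ds = np.arange(L)
    sum_avg = float((ks * p_sum).sum())
    sum_var = float(((ks - sum_avg) ** 2 * p_sum).sum())
    nz_s = p_sum[p_sum > 0]
    sum_ent = float(-(nz_s * np.log2(nz_s)).sum())
    diff_avg = float((ds * p_diff).sum())
    diff_var = float(((ds - diff_avg) ** 2 * p_diff).sum())
    nz_d = p_diff[p_diff > 0]
    diff_ent = float(-(nz_d * np.log2(nz_d)).sum())

    return {
        "glcm_energy": float((P * P).sum()),
        "glcm_entropy": entropy,
        "glcm_correlation": float(correlation),
        "glcm_contrast": contrast,
        "glcm_homogeneity": float((P / (1.0 + (i - j) ** 2)).sum()),
        "glcm_dissimilarity": float((diff * P).sum()),
        "glcm_cluster_shade": float(((i + j - 2 * mu) ** 3 * P).sum()),
        "glcm_cluster_prominence": float(((i + j - 2 * mu) ** 4 * P).sum()),
        "glcm_max_probability": float(P.max()),
        "glcm_sum_average": sum_avg,
        "glcm_sum_variance": sum_var,
        "glcm_sum_entropy": sum_ent,
        "glcm_difference_average": diff_avg,
        "glcm_difference_variance": diff_var,
        "glcm_difference_entropy": diff_ent,
        "glcm_autocorrelation": autocorr,
        "glcm_joint_mean": mu,
        "glcm_joint_variance": var,
        "glcm_inverse_difference": float((P / (1.0 + diff)).sum()),
        "glcm_inverse_difference_norm": float((P / (1.0 + diff / L)).sum()),
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def compute_gldm(qimg: np.ndarray, displacement: tuple[int, int], levels: int) -> np.ndarray:
    """Normalized distribution of absolute gray-level differences.

    For each in-mask pixel pair ``(p, p + displacement)`` the absolute
    quantized difference ``|g(p) - g(p + d)|`` is tallied; the length-
    ``levels`` histogram is normalized to sum 1.
    """
    dy, dx = displacement
    if (dy, dx) == (0, 0):
        raise InvalidInputError("displacement must be nonzero")
    a, b = _shifted_pairs(qimg, dy, dx)
    valid = (a != INVALID) & (b != INVALID)
    if not valid.any():
        raise InvalidInputError(f"no valid pixel pair for displacement {displacement}")
    d = np.abs(a[valid] - b[valid])
    counts = np.bincount(d, minlength=levels).astype(float)
    return counts / counts.sum()


def gldm_features(gldm: np.ndarray) -> dict[str, float]:
    """Summary statistics of a gray-level difference distribution."""
    p = np.asarray(gldm, dtype=float)
    d = np.arange(p.size)
    mean = float((d * p).sum())
    nz = p[p > 0]
    return {
        "gldm_mean": mean,
        "gldm_variance": float(((d - mean) ** 2 * p).sum()),
        "gldm_entropy": float(-(nz * np.log2(nz)).sum()),
        "gldm_energy": float((p * p).sum()),
        "gldm_contrast": float((d * d * p).sum()),
        "gldm_inverse_difference_moment": float((p / (1.0 + d * d)).sum()),
        "gldm_max_probability": float(p.max()),
        "gldm_zero_fraction": float(p[0]),
    }


# ---------------------------------------------------------------------------
# FFT spectral features
# ---------------------------------------------------------------------------

N_BANDS = 4


def fft_features(roi: ROIImage) -> dict[str, float]:
    """Spectral features of the mean-filled mask bounding box.

    Out-of-mask pixels inside the bounding box are replaced by the in-mask
    mean and the mean is subtracted before the 2D DFT, so the DC component
    is (numerically) zero and mask edges do not dominate the spectrum.
    Radial frequencies are in cycles/pixel.  For a constant image every
    spectral feature is 0 by convention.
    """
    rows = np.any(roi.mask, axis=1)
    cols = np.any(roi.mask, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    box = roi.intensities[r0 : r1 + 1, c0 : c1 + 1].astype(float).copy()
    m = roi.mask[r0 : r1 + 1, c0 : c1 + 1]
    mean = box[m].mean()
    box[~m] = mean
    box -= mean

    names = [f"{n}" for n in manifest.FFT_FEATURES]
    if np.ptp(box) == 0:  # constant image: degenerate spectrum
        return {n: 0.0 for n in names}

    F = np.fft.fft2(box)
    power = np.abs(F) ** 2
    h, w = box.shape
    fy = np.fft.fftfreq(h)
    fx = np.fft.fftfreq(w)
    r = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    nondc = r > 0
    pw = power[nondc]
    total = float(pw.sum())
    if total <= 0:
        return {n: 0.0 for n in names}
    p = pw / total
    rr = r[nondc]

    nz = p[p > 0]
    spec_entropy = float(-(nz * np.log2(nz)).sum())
    r_max = float(rr.max())
    edges = np.linspace(0.0, r_max, N_BANDS + 1)
    band_idx = np.clip(np.digitize(rr, edges[1:-1]), 0, N_BANDS - 1)
    bands = np.bincount(band_idx, weights=p, minlength=N_BANDS)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dominant = float(centers[int(np.argmax(bands))])
    mean_r = float((p * rr).sum())
    sd_r = float(np.sqrt(max((p * rr * rr).sum() - mean_r**2, 0.0)))
    # spectral flatness: geometric / arithmetic mean of the non-DC power
    logs = np.log(np.clip(pw, 1e-300, None))
    flatness = float(np.exp(logs.mean()) / pw.mean())
    # anisotropy: dominant 45-degree sector power over mean sector power
    theta = np.mod(np.arctan2(*np.meshgrid(fy, fx, indexing="ij"))[nondc], np.pi)
    sector = np.clip((theta / (np.pi / 4)).astype(int), 0, 3)
    sector_power = np.bincount(sector, weights=p, minlength=4)
    anisotropy = float(sector_power.max() / sector_power.mean())
    low = float(p[rr <= 0.25].sum())
    high = 1.0 - low
    low_high = low / high if high > 0 else 0.0

    return {
        "fft_total_power": total,
        "fft_spectral_entropy": spec_entropy,
        "fft_band1_fraction": float(bands[0]),
        "fft_band2_fraction": float(bands[1]),
        "fft_band3_fraction": float(bands[2]),
        "fft_band4_fraction": float(bands[3]),
        "fft_dominant_radial_freq": dominant,
        "fft_mean_radial_freq": mean_r,
        "fft_radial_freq_sd": sd_r,
        "fft_spectral_flatness": flatness,
        "fft_anisotropy": anisotropy,
        "fft_low_high_ratio": low_high,
    }


# ---------------------------------------------------------------------------
# per-modality and per-patient extraction
# ---------------------------------------------------------------------------

def extract_modality(
    roi: ROIImage, config: FeatureConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """The 55 texture features of one modality image, in manifest order.

    GLCM features are computed per direction offset and averaged over the
    four offsets; GLDM difference distributions are averaged over the four
    displacements before the summary features are taken.
    """
    out = histogram_features(roi, levels=config.levels_hist)

    q = quantize(roi, config.levels_glcm)
    glcm_acc: dict[str, float] = {}
    n_ok = 0
    for off in config.offsets:
        feats = glcm_features(compute_glcm(q, off, config.levels_glcm))
        for k, v in feats.items():
            glcm_acc[k] = glcm_acc.get(k, 0.0) + v
        n_ok += 1
    out.update({k: v / n_ok for k, v in glcm_acc.items()})

    gldm = np.mean(
        [compute_gldm(q, off, config.levels_glcm) for off in config.offsets], axis=0
    )
    out.update(gldm_features(gldm))
    out.update(fft_features(roi))

    ordered = {name: out[name] for name in manifest.MODALITY_FEATURES}
    assert len(ordered) == manifest.N_FEATURES_PER_MODALITY
    return ordered


def extract_patient(
    t2w: ROIImage, adc: ROIImage, config: FeatureConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """The 110-entry patient feature vector (T2W block then ADC block)."""
    out: dict[str, float] = {}
    for modality, roi in (("t2w", t2w), ("adc", adc)):
        for name, value in extract_modality(roi, config).items():
            out[f"{modality}_{name}"] = value
    assert list(out) == manifest.patient_feature_names()
    return out


def extract_table(
    patients: Iterable,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Feature table for a cohort of patients.

    ``patients`` is an iterable of objects with attributes ``patient_id``,
    ``t2w``, ``adc``, ``label`` and optionally ``pirads`` (the synthetic
    cohort's patient records, or anything shaped like them).  Returns a
    DataFrame with one row per patient: the 110 manifest features plus a
    ``label`` column and, when available, ``pirads``.
    """
    rows = []
    for p in patients:
        row = extract_patient(p.t2w, p.adc, config)
        row["label"] = p.label
        pirads = getattr(p, "pirads", None)
        if pirads is not None:
            row["pirads"] = pirads
        rows.append((p.patient_id, row))
    return pd.DataFrame.from_dict(dict(rows), orient="index")
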