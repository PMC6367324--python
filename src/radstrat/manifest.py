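"""Frozen manifest of the radiomic feature vector.

55 texture features are computed per modality from four families —
first-order histogram statistics (15), gray-level co-occurrence matrix
features (20), gray-level difference matrix features (8) and Fourier
spectral features (12) — and the two modality blocks (T2W-like first,
ADC-like second) are concatenated into the 110-entry patient vector.

The identities and order below are versioned: extraction output is tested
against this list, and trained models refuse feature tables whose columns
deviate from it.
"""

from __future__ import annotations

MANIFEST_VERSION = "1.0"

HISTOGRAM_FEATURES: tuple[str, ...] = (
    "hist_mean",
    "hist_sd",
    "hist_variance",
    "hist_skewness",
    "hist_kurtosis",
    "hist_min",
    "hist_max",
    "hist_range",
    "hist_median",
    "hist_p10",
    "hist_p25",
    "hist_p75",
    "hist_p90",
    "hist_entropy",
    "hist_uniformity",
)

GLCM_FEATURES: tuple[str, ...] = (
    "glcm_energy",
    "glcm_entropy",
    "glcm_correlation",
    "glcm_contrast",
    "glcm_homogeneity",
    "glcm_dissimilarity",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
    "glcm_max_probability",
    "glcm_sum_average",
    "glcm_sum_variance",
    "glcm_sum_entropy",
    "glcm_difference_average",
    "glcm_difference_variance",
    "glcm_difference_entropy",
    "glcm_autocorrelation",
    "glcm_joint_mean",
    "glcm_joint_variance",
    "glcm_inverse_difference",
    "glcm_inverse_difference_norm",
)

GLDM_FEATURES: tuple[str, ...] = (
    "gldm_mean",
    "gldm_variance",
    "gldm_entropy",
    "gldm_energy",
    "gldm_contrast",
    "gldm_inverse_difference_moment",
    "gldm_max_probability",
    "gldm_zero_fraction",
)

FFT_FEATURES: tuple[str, ...] = (
    "fft_total_power",
    "fft_spectral_entropy",
    "fft_band1_fraction",
    "fft_band2_fraction",
    "fft_band3_fraction",
    "fft_band4_fraction",
    "fft_dominant_radial_freq",
    "fft_mean_radial_freq",
    "fft_radial_freq_sd",
    "fft_spectral_flatness",
    "fft_anisotropy",
    "fft_low_high_ratio",
)

#: The 55 per-modality feature names, in canonical extraction order.
MODALITY_FEATURES: tuple[str, ...] = (
    HISTOGRAM_FEATURES + GLCM_FEATURES + GLDM_FEATURES + FFT_FEATURES
)

#: Modalities in concatenation order.
MODALITIES: tuple[str, str] = ("t2w", "adc")


def modality_feature_names(modality: str) -> list[str]:
    """Names of the 55 features of one modality, prefixed by the modality."""
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    return [f"{modality}_{name}" for name in MODALITY_FEATURES]


def patient_feature_names() -> list[str]:
    """The canonical 110 patient-level feature names (T2W block then ADC block)."""
    return [f"{m}_{name}" for m in MODALITIES for name in MODALITY_FEATURES]


N_FEATURES_PER_MODALITY = len(MODALITY_FEATURES)
N_FEATURES_PER_PATIENT = len(MODALITIES) * N_FEATURES_PER_MODALITY

assert N_FEATURES_PER_MODALITY == 55
assert N_FEATURES_PER_PATIENT == 110
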