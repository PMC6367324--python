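"""Synthetic cohorts of paired-modality ROI images with risk labels.

The generator emulates the statistical structure the downstream analysis
assumes: two imbalanced risk classes ("high" vs "lower"), per-patient
pairs of correlated-texture grayscale images (a T2W-like and an ADC-like
modality), and an ordinal 1–5 reader suspicion score correlated with the
risk label.  Texture fields are stationary Gaussian random fields obtained
by frequency-domain filtering of white noise with a Gaussian spectral
envelope, so a single correlation-length knob moves all four feature
families smoothly.

Class differences are parameterized by a dimensionless ``effect_size``
that interpolates between the lower-risk parameters (effect 0: the classes
are generatively identical) and the full class contrast (effect 1): the
ADC-like modality loses mean intensity in the high-risk class, the
T2W-like modality gains correlation length.  Per-patient jitter of the
texture parameters keeps the separation imperfect at realistic levels.

A feature-space shortcut (:func:`generate_feature_table`) draws the
110-dimensional feature vectors directly from a correlated Gaussian model,
so classifier-level code is testable without the image stage, plus an
XOR-structured variant whose classes are separable only through feature
interactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import manifest
from .errors import InvalidInputError, InvalidSpecError
from .image import ROIImage

MANIFEST_COLUMNS = ["patient_id", "t2w_path", "adc_path", "mask_path", "label", "pirads"]

#: Latent ordinal-score class means (high-risk, lower-risk); echo typical
#: reader-score summaries for the two risk groups.
PIRADS_MEANS = {"high": 4.3, "lower": 3.3}


@dataclass(frozen=True)
class TextureParams:
    """Stationary-field parameters of one class/modality combination."""

    mean_intensity: float
    intensity_sd: float
    correlation_length_pixels: float

    def __post_init__(self) -> None:
        if self.correlation_length_pixels <= 0:
            raise InvalidSpecError("correlation_length_pixels must be positive")
        if self.intensity_sd < 0:
            raise InvalidSpecError("intensity_sd must be nonnegative")


#: Default texture parameters at effect_size 1.  The ADC-like modality
#: separates the classes by mean intensity (lower ADC in aggressive
#: disease); the T2W-like modality by correlation length (coarser texture).
DEFAULT_TEXTURE_PARAMS: dict[str, dict[str, TextureParams]] = {
    "t2w": {
        "lower": TextureParams(420.0, 60.0, 2.0),
        "high": TextureParams(420.0, 60.0, 3.0),
    },
    "adc": {
        "lower": TextureParams(1300.0, 150.0, 3.0),
        "high": TextureParams(1180.0, 150.0, 3.0),
    },
}

#: Relative sd of the per-patient jitter applied to mean intensity and
#: (log) correlation length.  Keeps class separation moderate rather than
#: perfect; frozen as a study condition.
PATIENT_JITTER_MEAN = 0.08
PATIENT_JITTER_CORRLEN = 0.15


@dataclass(frozen=True)
class CohortSpec:
    """Specification of one synthetic cohort.

    ``effect_size`` linearly scales the class contrast of
    ``texture_params``: the high-risk parameters actually used are
    ``lower + effect_size * (high - lower)``, so effect 0 makes the
    classes generatively identical and effect 1 reproduces the stated
    high-risk parameters.
    """

    n_high: int
    n_lower: int
    image_size: int = 64
    texture_params: dict[str, dict[str, TextureParams]] = field(
        default_factory=lambda: DEFAULT_TEXTURE_PARAMS
    )
    effect_size: float = 1.0
    reader_noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high < 0 or self.n_lower < 0 or self.n_high + self.n_lower < 1:
            raise InvalidSpecError("need n_high >= 0, n_lower >= 0, total >= 1")
        if self.image_size < 16:
            raise InvalidSpecError("image_size must be >= 16")
        if self.effect_size < 0:
            raise InvalidSpecError("effect_size must be >= 0")
        if self.reader_noise_sd < 0:
            raise InvalidSpecError("reader_noise_sd must be >= 0")

    def class_params(self, modality: str, label: str) -> TextureParams:
        """Effective texture parameters after effect-size interpolation."""
        lo = self.texture_params[modality]["lower"]
        hi = self.texture_params[modality]["high"]
        if label == "lower":
            return lo
        t = self.effect_size
        return TextureParams(
            lo.mean_intensity + t * (hi.mean_intensity - lo.mean_intensity),
            lo.intensity_sd + t * (hi.intensity_sd - lo.intensity_sd),
            lo.correlation_length_pixels
            + t * (hi.correlation_length_pixels - lo.correlation_length_pixels),
        )


@dataclass(frozen=True)
class SyntheticPatient:
    """One synthetic patient record: paired images, risk label, reader score."""

    patient_id: str
    t2w: ROIImage
    adc: ROIImage
    label: str
    pirads: int

    def __post_init__(self) -> None:
        if self.t2w.intensities.shape != self.adc.intensities.shape:
            raise InvalidInputError("modality images must share the grid size")
        if self.label not in ("high", "lower"):
            raise InvalidInputError(f"label must be 'high' or 'lower', got {self.label!r}")
        if self.pirads not in (1, 2, 3, 4, 5):
            raise InvalidInputError(f"pirads must be in 1..5, got {self.pirads!r}")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def synth_texture_image(params: TextureParams, image_size: int, seed) -> ROIImage:
    """A correlated random texture field with an elliptical ROI mask.

    White noise is filtered in the frequency domain with a Gaussian
    spectral envelope of the stated correlation length, affine-scaled to
    the stated mean and sd, clipped to nonnegative values and rounded to
    integer gray values (scanner units are arbitrary; integers make the
    16-bit on-disk representation lossless).  The mask is an axis-aligned
    ellipse with half-axes drawn uniformly from 0.5–0.9 of the half-size.
    """
    if image_size <= 0:
        raise InvalidSpecError("image_size must be positive")
    ell = params.correlation_length_pixels  # validated > 0 by TextureParams
    rng = _as_rng(seed)

    # elliptical mask first so mask geometry is independent of noise draws
    half = image_size / 2.0
    a = rng.uniform(0.5, 0.9) * half
    b = rng.uniform(0.5, 0.9) * half
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    cy = cx = (image_size - 1) / 2.0
    mask = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0

    if params.intensity_sd == 0:
        field_scaled = np.full((image_size, image_size), params.mean_intensity)
    else:
        noise = rng.standard_normal((image_size, image_size))
        fy = np.fft.fftfreq(image_size)
        fx = np.fft.fftfreq(image_size)
        f2 = np.add.outer(fy**2, fx**2)
        envelope = np.exp(-2.0 * (np.pi * ell) ** 2 * f2)
        fld = np.fft.ifft2(np.fft.fft2(noise) * envelope).real
        z = (fld - fld.mean()) / fld.std()
        field_scaled = params.mean_intensity + params.intensity_sd * z
    out = np.clip(np.rint(field_scaled), 0, None)
    return ROIImage(out, mask)


def simulate_pirads(label: str, reader_noise_sd: float, seed) -> int:
    """Ordinal 1–5 reader score: latent class mean + Gaussian noise,
    rounded and clipped to the scale."""
    if reader_noise_sd < 0:
        raise InvalidSpecError("reader_noise_sd must be >= 0")
    rng = _as_rng(seed)
    latent = PIRADS_MEANS[label] + reader_noise_sd * rng.standard_normal()
    return int(np.clip(np.rint(latent), 1, 5))


def _patient_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    """Counter-scheme sub-seeding: patient ``index`` (stream 0..2 for t2w /
    adc / reader score) gets an independent stream regardless of cohort
    size, so extending a cohort never perturbs earlier patients."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index, stream)))


def generate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Exactly ``n_high + n_lower`` patients with deterministic content.

    High-risk patients come first (``P000`` ...), then lower-risk; all
    randomness derives from ``spec.seed`` through the per-patient counter
    scheme.
    """
    labels = ["high"] * spec.n_high + ["lower"] * spec.n_lower
    patients = []
    for i, label in enumerate(labels):
        jit = _patient_rng(spec.seed, i, 3)
        images = {}
        for s, modality in enumerate(("t2w", "adc")):
            p = spec.class_params(modality, label)
            p = TextureParams(
                max(p.mean_intensity * (1 + PATIENT_JITTER_MEAN * jit.standard_normal()), 1.0),
                p.intensity_sd,
                p.correlation_length_pixels
                * math.exp(PATIENT_JITTER_CORRLEN * jit.standard_normal()),
            )
            images[modality] = synth_texture_image(
                p, spec.image_size, _patient_rng(spec.seed, i, s)
            )
        score = simulate_pirads(label, spec.reader_noise_sd, _patient_rng(spec.seed, i, 2))
        patients.append(
            SyntheticPatient(f"P{i:03d}", images["t2w"], images["adc"], label, score)
        )
    return patients


# ---------------------------------------------------------------------------
# feature-space shortcut
# ---------------------------------------------------------------------------

_AR1_RHO = 0.3  # between-feature correlation decays as rho^|i-j|


def _correlated_noise(rng: np.random.Generator, n: int, p: int) -> np.ndarray:
    """Unit-variance Gaussian features with AR(1) cross-correlation."""
    idx = np.arange(p)
    corr = _AR1_RHO ** np.abs(np.subtract.outer(idx, idx))
    chol = np.linalg.cholesky(corr)
    return rng.standard_normal((n, p)) @ chol.T


def _finalize_table(
    spec: CohortSpec, X: np.ndarray, labels: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    table = pd.DataFrame(
        X,
        columns=manifest.patient_feature_names(),
        index=[f"P{i:03d}" for i in range(len(labels))],
    )
    table["label"] = labels
    table["pirads"] = [
        simulate_pirads(lab, spec.reader_noise_sd, rng) for lab in labels
    ]
    return table


def generate_feature_table(spec: CohortSpec, n_informative: int) -> pd.DataFrame:
    """Feature table drawn directly in feature space.

    The first ``n_informative`` manifest features carry a high-risk class
    mean shift of ``spec.effect_size`` within-class standard deviations;
    the remaining columns are pure correlated noise.
    """
    if not 0 <= n_informative <= manifest.N_FEATURES_PER_PATIENT:
        raise InvalidSpecError(
            f"n_informative must be in 0..{manifest.N_FEATURES_PER_PATIENT}"
        )
    rng = np.random.default_rng(spec.seed)
    labels = ["high"] * spec.n_high + ["lower"] * spec.n_lower
    X = _correlated_noise(rng, len(labels), manifest.N_FEATURES_PER_PATIENT)
    X[: spec.n_high, :n_informative] += spec.effect_size
    return _finalize_table(spec, X, labels, rng)


def generate_xor_table(
    spec: CohortSpec, n_pairs: int = 10, rotate: bool = True
) -> pd.DataFrame:
    """Feature table whose signal lives only in feature interactions.

    ``n_pairs`` latent coordinate pairs are planted with an XOR pattern:
    high-risk patients sit in the (+,+)/(−,−) quadrants at radius
    ``effect_size``, lower-risk patients in the mixed quadrants, plus unit
    noise.  Each latent pair is embedded in a random 2D subspace of the
    110-feature space (``rotate=True``, the default), so no single feature
    carries marginal signal and no axis-aligned split is informative:
    linear classifiers are blind to the signal, while polynomial-kernel
    machines — whose kernels depend on dot products only and are therefore
    rotation-invariant — can represent the separating cross-term.  With
    ``rotate=False`` the pairs occupy the leading feature columns directly.
    """
    if not 0 <= 2 * n_pairs <= manifest.N_FEATURES_PER_PATIENT:
        raise InvalidSpecError("too many XOR pairs for the 110-feature manifest")
    rng = np.random.default_rng(spec.seed)
    labels = ["high"] * spec.n_high + ["lower"] * spec.n_lower
    n = len(labels)
    p = manifest.N_FEATURES_PER_PATIENT
    X = rng.standard_normal((n, p))
    delta = spec.effect_size
    same = np.where(np.array(labels) == "high", 1.0, -1.0)
    if rotate:
        basis, _ = np.linalg.qr(rng.standard_normal((p, 2 * n_pairs)))
    for j in range(n_pairs):
        s = rng.choice([-1.0, 1.0], size=n)
        if rotate:
            X += np.outer(s * delta, basis[:, 2 * j])
            X += np.outer(s * same * delta, basis[:, 2 * j + 1])
        else:
            X[:, 2 * j] += s * delta
            X[:, 2 * j + 1] += s * same * delta
    return _finalize_table(spec, X, labels, rng)


# ---------------------------------------------------------------------------
# disk round-trip
# ---------------------------------------------------------------------------

def write_cohort(patients: list[SyntheticPatient], directory) -> Path:
    """Write a cohort to ``directory`` as 16-bit PNGs plus a CSV manifest.

    Per patient: one image per modality, one {0,255} mask PNG (both
    modalities share the mask grid; the T2W mask is written), and one
    manifest row.  Returns the manifest path.  Round-trips losslessly
    through :func:`read_cohort`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patients:
        paths = {}
        for modality in ("t2w", "adc"):
            roi: ROIImage = getattr(p, modality)
            arr = roi.intensities
            if arr.max() > 65535:
                raise InvalidInputError("intensities exceed 16-bit range")
            fname = directory / f"{p.patient_id}_{modality}.png"
            iio.imwrite(fname, np.rint(arr).astype(np.uint16))
            paths[modality] = fname.name
        mask_name = directory / f"{p.patient_id}_mask.png"
        iio.imwrite(mask_name, (p.t2w.mask.astype(np.uint8) * 255))
        rows.append(
            {
                "patient_id": p.patient_id,
                "t2w_path": paths["t2w"],
                "adc_path": paths["adc"],
                "mask_path": mask_name.name,
                "label": p.label,
                "pirads": p.pirads,
            }
        )
    manifest_path = directory / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)
    return manifest_path


def read_cohort(manifest_path) -> list[SyntheticPatient]:
    """Read a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path)
    patients = []
    for row in table.itertuples(index=False):
        mask = np.asarray(iio.imread(base / row.mask_path)) > 0
        t2w = ROIImage(np.asarray(iio.imread(base / row.t2w_path), dtype=float), mask)
        adc = ROIImage(np.asarray(iio.imread(base / row.adc_path), dtype=float), mask)
        patients.append(
            SyntheticPatient(str(row.patient_id), t2w, adc, row.label, int(row.pirads))
        )
    return patients
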