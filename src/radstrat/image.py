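"""Masked 2D region-of-interest images.

An :class:`ROIImage` is the unit of texture analysis: a single-modality 2D
intensity grid (scanner-arbitrary units) together with a same-shape boolean
mask marking the pixels that belong to the tumor region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

MIN_MASK_PIXELS = 16


@dataclass(frozen=True)
class ROIImage:
    """A 2D grayscale image restricted to a region of interest.

    Parameters
    ----------
    intensities
        2D array of finite, nonnegative intensities (arbitrary units).
    mask
        Boolean array of the same shape; True marks in-ROI pixels.
        At least 16 pixels must be in the mask.
    """

    intensities: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensities, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if inten.ndim != 2 or mask.shape != inten.shape:
            raise InvalidInputError(
                f"intensities {inten.shape} and mask {mask.shape} must be "
                "equal-shape 2D arrays"
            )
        n_in = int(mask.sum())
        if n_in < MIN_MASK_PIXELS:
            raise InvalidInputError(
                f"mask has {n_in} in-ROI pixels; at least {MIN_MASK_PIXELS} required"
            )
        vals = inten[mask]
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("in-mask intensities must be finite")
        if np.any(vals < 0):
            raise InvalidInputError("in-mask intensities must be nonnegative")
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "mask", mask)

    @property
    def in_mask(self) -> np.ndarray:
        """1D array of in-ROI intensities (row-major order)."""
        return self.intensities[self.mask]

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())
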