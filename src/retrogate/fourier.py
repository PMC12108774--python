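"""Centered, orthonormal 2-D Fourier transforms.

Convention used throughout the package: the DC component sits at the
matrix center, rows are phase-encode, columns are frequency-encode, and
both directions use orthonormal scaling so that synthesis and
reconstruction are exact inverses and noise standard deviation is
preserved between k-space and image domain.
"""

from __future__ import annotations

import numpy as np

__all__ = ["image_to_kspace", "kspace_to_image"]

_AXES = (-2, -1)


def image_to_kspace(image: np.ndarray) -> np.ndarray:
    """Forward 2-D DFT (image -> k-space), DC at center, orthonormal."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(image, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


def kspace_to_image(kspace: np.ndarray) -> np.ndarray:
    """Inverse 2-D DFT (k-space -> image), DC at center, orthonormal."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(kspace, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )
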