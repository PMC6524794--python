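"""Image formation from Cartesian k-space: centered orthonormal 2D FFTs,
magnitude images and root-sum-of-squares coil combination."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

__all__ = ["ImageVolume", "ifft2_centered", "fft2_centered", "rss_combine",
           "reconstruct", "window_magnitude"]


@dataclass
class ImageVolume:
    """Reconstructed image(s) plus geometry metadata."""

    pixels: np.ndarray                  # (..., n_pe, n_fe)
    pixel_spacing: tuple = (1.0, 1.0)   # (pe, fe) in m
    header: Dict[str, object] = field(default_factory=dict)


def ifft2_centered(kspace: np.ndarray) -> np.ndarray:
    """DC-centered, orthonormal inverse 2D FFT over the last two axes."""
    k = np.asarray(kspace)
    if k.ndim < 2:
        raise ValueError("k-space must be at least 2-D")
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))


def fft2_centered(image: np.ndarray) -> np.ndarray:
    """Inverse of :func:`ifft2_centered`."""
    img = np.asarray(image)
    if img.ndim < 2:
        raise ValueError("image must be at least 2-D")
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))


def rss_combine(per_coil_images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares over the leading (coil) axis."""
    imgs = np.asarray(per_coil_images)
    if imgs.ndim < 3:
        imgs = imgs[None]
    return np.sqrt((np.abs(imgs) ** 2).sum(axis=0))


def reconstruct(kspace_data) -> ImageVolume:
    """Full chain for KSpaceData: per-coil centered iFFT + RSS magnitude.

    Returns magnitude images of shape ``(n_images, n_pe, n_fe)``.
    """
    k = kspace_data.images_matrix()          # (coils, images, pe, fe)
    per_coil = ifft2_centered(k)
    mag = rss_combine(per_coil)              # (images, pe, fe)
    hdr = dict(kspace_data.header)
    dy = hdr.get("fov_pe", 1.0) / k.shape[-2]
    dx = hdr.get("fov_fe", 1.0) / k.shape[-1]
    return ImageVolume(pixels=mag, pixel_spacing=(dy, dx), header=hdr)


def window_magnitude(image: np.ndarray, padding: float = 0.02) -> np.ndarray:
    """Min-max display windowing with fractional range padding."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    span = hi - lo
    lo -= padding * span
    hi += padding * span
    if hi <= lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)
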