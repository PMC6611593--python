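"""Core in-memory containers for dynamic multi-coil phase-contrast MRI data.

Axis convention throughout the package: k-space and image arrays are indexed
``(coil, frame, encoding, ky/y, kx/x)``.  K-space is stored *centered*
(DC at index ``n // 2`` on both spatial axes, fftshift-style layout) and all
Fourier transforms are unitary, so signal energy is identical in every
domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KSpaceSeries",
    "ImageSeries",
    "kspace_to_image",
    "image_to_kspace",
]

_SPATIAL_AXES = (-2, -1)


def image_to_kspace(images: np.ndarray) -> np.ndarray:
    """Unitary centered 2-D FFT over the trailing (y, x) axes."""
    shifted = np.fft.ifftshift(images, axes=_SPATIAL_AXES)
    k = np.fft.fft2(shifted, axes=_SPATIAL_AXES, norm="ortho")
    return np.fft.fftshift(k, axes=_SPATIAL_AXES)


def kspace_to_image(kspace: np.ndarray) -> np.ndarray:
    """Unitary centered 2-D inverse FFT over the trailing (ky, kx) axes."""
    shifted = np.fft.ifftshift(kspace, axes=_SPATIAL_AXES)
    img = np.fft.ifft2(shifted, axes=_SPATIAL_AXES, norm="ortho")
    return np.fft.fftshift(img, axes=_SPATIAL_AXES)


@dataclass
class _Series:
    data: np.ndarray  # complex, (coil, frame, encoding, ky, kx)
    venc: float  # cm/s
    frame_interval: float  # ms
    fov: tuple[float, float] = (50.0, 50.0)  # mm, (y, x)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"expected 5-D (coil, frame, encoding, ky, kx) array, "
                f"got {self.data.ndim}-D"
            )
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_encodings(self) -> int:
        return self.data.shape[2]

    @property
    def n_ky(self) -> int:
        return self.data.shape[3]

    @property
    def n_kx(self) -> int:
        return self.data.shape[4]

    @property
    def pixel_spacing(self) -> tuple[float, float]:
        """(dy, dx) in mm derived from FOV / matrix."""
        return (self.fov[0] / self.n_ky, self.fov[1] / self.n_kx)

    def copy(self):
        return replace(self, data=self.data.copy())


@dataclass
class KSpaceSeries(_Series):
    """Cartesian k-space samples with acquisition metadata.

    Non-acquired entries are exactly zero when the series is paired with a
    sampling mask set.
    """

    def to_images(self) -> "ImageSeries":
        """Zero-filled (direct inverse-FFT) reconstruction."""
        return ImageSeries(
            data=kspace_to_image(self.data),
            venc=self.venc,
            frame_interval=self.frame_interval,
            fov=self.fov,
        )


@dataclass
class ImageSeries(_Series):
    """Complex image-domain counterpart of :class:`KSpaceSeries`."""

    def to_kspace(self) -> KSpaceSeries:
        return KSpaceSeries(
            data=image_to_kspace(self.data),
            venc=self.venc,
            frame_interval=self.frame_interval,
            fov=self.fov,
        )
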