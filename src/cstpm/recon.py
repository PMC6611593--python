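"""Iterative soft-thresholding compressed-sensing reconstruction.

The reconstruction solves, per receiver coil and velocity encoding, the
standard compressed-sensing problem

    min ||T x||_1   subject to   ||R x - k||_2 <= eps

where ``x`` is the complex dynamic image stack, ``T`` a pixelwise temporal
Fourier transform (cardiac cine data are quasi-periodic in time, hence
sparse in temporal frequency), ``R`` the partial Fourier operator implied by
the undersampling mask and ``k`` the measured k-space samples.  The l1 term
is minimised by iterating: inverse 2-D FFT, forward temporal FFT,
soft-thresholding of the real and imaginary coefficient parts, inverse
temporal FFT, forward 2-D FFT, then a data-consistency step that reinserts
the measured samples.  Iteration stops when the change in the residual
``||R x_i - k||_2`` between consecutive iterations falls to at or below
``tol_frac`` (default 1%) of the change between the first two iterations —
but never before ``min_iter`` iterations (guarding against signal loss from
aggressive denoising) and never after ``max_iter``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import ImageSeries, KSpaceSeries, image_to_kspace, kspace_to_image
from .masks import SamplingMaskSet

__all__ = [
    "ReconConfig",
    "ReconReport",
    "soft_threshold",
    "temporal_sparsify",
    "retrospective_undersample",
    "stopping_criterion",
    "cs_reconstruct",
    "select_threshold",
]

_FRAME_AXIS = 1  # (coil, frame, encoding, ky, kx)


@dataclass(frozen=True)
class ReconConfig:
    """Reconstruction tuning parameters.

    ``lam`` is the soft threshold.  By default it is *relative*: the
    absolute threshold applied to each (coil, encoding) channel is
    ``lam * max |temporal coefficient|`` of that channel's zero-filled
    reconstruction, which makes the setting invariant to signal scaling.
    Set ``lam_absolute=True`` to use ``lam`` directly.
    """

    lam: float = 0.01
    max_iter: int = 50
    min_iter: int = 15
    tol_frac: float = 0.01
    lam_absolute: bool = False

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if not (1 <= self.min_iter < self.max_iter):
            raise ValueError("need 1 <= min_iter < max_iter")
        if self.tol_frac < 0:
            raise ValueError("tol_frac must be non-negative")


@dataclass
class ReconReport:
    """Iteration history of one reconstruction run."""

    iterations_run: int
    residuals: list[float]
    converged: bool  # stopping rule met (vs. max_iter safety stop)
    lam_abs: np.ndarray | None = None  # per-(coil, encoding) threshold used

    def __post_init__(self) -> None:
        assert len(self.residuals) == self.iterations_run


def soft_threshold(y, lam):
    """Soft-thresholding shrinkage (the proximal operator of the l1 norm).

    Returns ``y + lam`` for ``y < -lam``, 0 for ``|y| <= lam`` and
    ``y - lam`` for ``y > lam``.  Complex input is thresholded separately
    on its real and imaginary parts.  ``lam`` may be a scalar or an array
    broadcastable against ``y``.
    """
    lam_arr = np.asarray(lam)
    if np.any(lam_arr < 0):
        raise ValueError("threshold must be non-negative")
    y = np.asarray(y)
    if np.iscomplexobj(y):
        return soft_threshold(y.real, lam_arr) + 1j * soft_threshold(y.imag, lam_arr)
    return np.sign(y) * np.maximum(np.abs(y) - lam_arr, 0.0)


def temporal_sparsify(data: np.ndarray, direction: str = "forward") -> np.ndarray:
    """Unitary pixelwise Fourier transform along the frame axis.

    ``direction`` is ``"forward"`` (image frames -> temporal frequencies) or
    ``"inverse"``.  Requires at least two frames.
    """
    data = np.asarray(data)
    if data.shape[_FRAME_AXIS] < 2:
        raise ValueError("temporal transform needs at least 2 frames")
    if direction == "forward":
        return np.fft.fft(data, axis=_FRAME_AXIS, norm="ortho")
    if direction == "inverse":
        return np.fft.ifft(data, axis=_FRAME_AXIS, norm="ortho")
    raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")


def _mask_array(masks: SamplingMaskSet, kspace: KSpaceSeries) -> np.ndarray:
    if (
        masks.n_frames != kspace.n_frames
        or masks.n_encodings != kspace.n_encodings
        or masks.n_ky != kspace.n_ky
    ):
        raise ValueError(
            "mask extents "
            f"(frames={masks.n_frames}, encodings={masks.n_encodings}, "
            f"ky={masks.n_ky}) do not match k-space "
            f"(frames={kspace.n_frames}, encodings={kspace.n_encodings}, "
            f"ky={kspace.n_ky})"
        )
    # broadcast (frame, encoding, ky) -> (coil, frame, encoding, ky, kx)
    return masks.indicator()[None, :, :, :, None].astype(bool)


def retrospective_undersample(
    full_kspace: KSpaceSeries, masks: SamplingMaskSet
) -> KSpaceSeries:
    """Simulate an accelerated acquisition from fully sampled k-space.

    Acquired entries are copied verbatim; every skipped line is set to
    exactly zero.  Idempotent.
    """
    m = _mask_array(masks, full_kspace)
    out = full_kspace.copy()
    out.data = np.where(m, full_kspace.data, 0.0)
    return out


def stopping_criterion(
    residuals: Sequence[float], i: int, config: ReconConfig
) -> bool:
    """Residual-plateau stopping rule.

    ``residuals[j-1]`` holds the residual ``r_j = ||R x_j - k||_2`` after
    iteration ``j``.  Stops when ``|r_i - r_{i-1}| <= tol_frac * |r_1 - r_2|``
    once past ``min_iter`` iterations, or unconditionally at ``max_iter``.
    """
    if i < 2:
        raise ValueError("stopping rule needs at least two iterations")
    if len(residuals) < i:
        raise ValueError("residual history shorter than iteration index")
    if i >= config.max_iter:
        return True
    plateau = abs(residuals[i - 1] - residuals[i - 2]) <= config.tol_frac * abs(
        residuals[0] - residuals[1]
    )
    return plateau and i > config.min_iter


def cs_reconstruct(
    undersampled: KSpaceSeries,
    masks: SamplingMaskSet,
    config: ReconConfig | None = None,
) -> tuple[ImageSeries, ReconReport]:
    """Reconstruct undersampled dynamic k-space by iterative soft-thresholding.

    Coils and velocity encodings are processed independently (the threshold
    is scaled per channel and every operation acts channelwise); the
    iteration loop is shared across channels and the stopping rule is
    evaluated on the aggregate residual norm.  The residual of iteration
    ``i`` is measured on the thresholded estimate *before* the measured
    samples are reinserted — after reinsertion it would be identically zero.

    Returns the reconstructed image series (image-domain transform of the
    final data-consistent k-space) and an iteration report.
    """
    if config is None:
        config = ReconConfig()
    k_meas = np.asarray(undersampled.data, dtype=np.complex128)
    if not np.any(k_meas):
        raise ValueError("all-zero k-space input")
    m = np.broadcast_to(_mask_array(masks, undersampled), k_meas.shape)
    if np.any(k_meas[~m] != 0):
        raise ValueError("k-space has nonzero samples at masked-out locations")

    # per-(coil, encoding) threshold scale from the zero-filled estimate
    coeff0 = temporal_sparsify(kspace_to_image(k_meas), "forward")
    if config.lam_absolute:
        lam_abs = np.full((k_meas.shape[0], 1, k_meas.shape[2], 1, 1), config.lam)
    else:
        scale = np.abs(coeff0).max(axis=(1, 3, 4), keepdims=True)
        lam_abs = config.lam * scale

    k_cur = k_meas.copy()
    # residuals at FFT round-off scale are zero in exact arithmetic (e.g. at
    # full sampling or lam=0); snap them so the plateau rule sees true zeros
    round_off = 1e-12 * float(np.linalg.norm(k_meas))
    residuals: list[float] = []
    converged = False
    i = 0
    for i in range(1, config.max_iter + 1):
        images = kspace_to_image(k_cur)
        coeff = temporal_sparsify(images, "forward")
        coeff = soft_threshold(coeff, lam_abs)
        images = temporal_sparsify(coeff, "inverse")
        k_est = image_to_kspace(images)
        r = float(np.linalg.norm(np.where(m, k_est, 0.0) - k_meas))
        residuals.append(0.0 if r < round_off else r)
        k_cur = np.where(m, k_meas, k_est)
        if i >= 2 and stopping_criterion(residuals, i, config):
            converged = i < config.max_iter or _plateau_at(residuals, i, config)
            break

    out = ImageSeries(
        data=kspace_to_image(k_cur),
        venc=undersampled.venc,
        frame_interval=undersampled.frame_interval,
        fov=undersampled.fov,
    )
    report = ReconReport(
        iterations_run=i,
        residuals=residuals,
        converged=converged,
        lam_abs=np.squeeze(lam_abs),
    )
    return out, report


def _plateau_at(residuals: Sequence[float], i: int, config: ReconConfig) -> bool:
    return (
        abs(residuals[i - 1] - residuals[i - 2])
        <= config.tol_frac * abs(residuals[0] - residuals[1])
        and i > config.min_iter
    )


def select_threshold(
    reference: KSpaceSeries,
    masks: SamplingMaskSet,
    candidates: Sequence[float],
    config: ReconConfig | None = None,
) -> tuple[float, bool, dict[float, ReconReport]]:
    """Choose the soft threshold on a reference undersampled dataset.

    Runs the reconstruction once per candidate and returns the smallest
    candidate whose run satisfies the residual-plateau rule strictly
    between ``min_iter`` and ``max_iter`` iterations.  A run that stops at
    ``min_iter + 1`` plateaued at the first permitted check, i.e. it
    effectively converged before the window opened (the lam = 0 degenerate
    case), and does not qualify.  If no candidate qualifies, the one with
    the lowest final residual is returned with the qualifying flag set to
    False.

    Returns ``(lam, qualifying, reports)``.
    """
    if config is None:
        config = ReconConfig()
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one threshold candidate")
    reports: dict[float, ReconReport] = {}
    for lam in candidates:
        _, reports[lam] = cs_reconstruct(
            reference,
            masks,
            ReconConfig(
                lam=lam,
                max_iter=config.max_iter,
                min_iter=config.min_iter,
                tol_frac=config.tol_frac,
                lam_absolute=config.lam_absolute,
            ),
        )
    qualifying = [
        lam
        for lam in candidates
        if reports[lam].converged
        and config.min_iter + 1 < reports[lam].iterations_run < config.max_iter
    ]
    if qualifying:
        return min(qualifying), True, reports
    fallback = min(candidates, key=lambda lam: reports[lam].residuals[-1])
    return fallback, False, reports


def default_threshold_grid() -> list[float]:
    """Logarithmic candidate grid on the relative-threshold scale."""
    return list(np.logspace(-4, -1, 10))
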