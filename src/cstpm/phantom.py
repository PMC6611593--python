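"""Synthetic contracting-annulus phantom with analytic ground truth.

The phantom emulates a short-axis slice of a contracting myocardial ring.
A material point starting at radius ``rho`` sits at ``rho * s(t)`` with

    s(t) = 1 - a * w(t),        w(t) = sin^2(pi * t / T)

where ``a`` is the fractional radius change at peak systole and ``T`` the
cardiac period; ``w`` is a smooth systole-like pulse with ``w(0) = 0``.
This gives closed forms for everything downstream:

* in-plane velocity at position ``x`` (radius ``r``) and time ``t``:
  ``v = (x - c) * s'(t) / s(t)`` (linear in position inside the ring);
* circumferential strain ``eps(t) = 100 * (s(t) - 1) = -100 * a * w(t)``;
* through-plane (longitudinal) velocity ``v_z = A_long * sin(2 pi t / T)``
  uniform across the ring.

The ring magnitude is a smooth annulus that contracts with ``s(t)``; static
extracardiac blobs are added so background-phase correction has reference
tissue.  Each of the four receiver coils weights the image with a smooth
complex sensitivity.  Per velocity encoding ``e`` the pixel phase is
``phi_0(x) + (pi / venc) * (M_e . v)`` (plus an optional synthetic
eddy-current ramp); images are transformed to centered k-space frame by
frame and seeded complex Gaussian noise is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import KSpaceSeries, image_to_kspace
from .kinematics import Segmentation, midwall_contour, sectorize
from .velocity import EncodingScheme, VelocityField

__all__ = ["PhantomSpec", "PhantomData", "analytic_motion", "render_kspace"]


def _default_scheme() -> EncodingScheme:
    return EncodingScheme.balanced_four_point(venc=13.9)


@dataclass
class PhantomSpec:
    """Study conditions for the synthetic acquisition."""

    matrix: int = 128
    n_frames: int = 24
    fov: float = 50.0  # mm
    r_inner: float = 3.0  # mm
    r_outer: float = 5.5  # mm
    contraction_amplitude: float = 0.15  # peak fractional radius change
    long_velocity_amplitude: float = 2.0  # cm/s
    period: float = 150.0  # ms (rat cardiac cycle)
    venc: float = 13.9  # cm/s
    n_coils: int = 4
    noise_sigma: float = 0.02  # relative complex Gaussian k-space noise
    seed: int = 0
    scheme: EncodingScheme = field(default_factory=_default_scheme)
    eddy_amplitude: float = 0.0  # cm/s spurious velocity ramp amplitude

    def __post_init__(self) -> None:
        if not (0 < self.r_inner < self.r_outer < self.fov / 2):
            raise ValueError("need 0 < r_inner < r_outer < FOV/2")
        if not (0 <= self.contraction_amplitude < 1):
            raise ValueError("contraction amplitude must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.scheme.venc != self.venc:
            self.scheme = EncodingScheme(
                matrix=self.scheme.matrix, venc=self.venc, names=self.scheme.names
            )

    @property
    def frame_interval(self) -> float:
        return self.period / self.n_frames

    @property
    def pixel_spacing(self) -> float:
        return self.fov / self.matrix  # mm, isotropic

    @property
    def r_mid(self) -> float:
        return 0.5 * (self.r_inner + self.r_outer)


def analytic_motion(spec: PhantomSpec, t: float | np.ndarray):
    """Closed-form radius scale, scale rate, strain and longitudinal velocity.

    Returns ``(s, s_dot, strain_pct, v_long)`` at time ``t`` in ms;
    ``s_dot`` is per ms, strain in %strain, ``v_long`` in cm/s.
    """
    t = np.asarray(t, float)
    a = spec.contraction_amplitude
    omega = np.pi / spec.period
    w = np.sin(omega * t) ** 2
    w_dot = 2 * omega * np.sin(omega * t) * np.cos(omega * t)  # per ms
    s = 1.0 - a * w
    s_dot = -a * w_dot
    strain = 100.0 * (s - 1.0)
    v_long = spec.long_velocity_amplitude * np.sin(2 * omega * t)
    return s, s_dot, strain, v_long


def _smooth_band(r: np.ndarray, lo: float, hi: float, width: float) -> np.ndarray:
    """Smooth indicator of lo <= r <= hi with sigmoid edges of given width."""
    from scipy.special import expit

    return expit((r - lo) / width) * expit((hi - r) / width)


def _coil_sensitivities(n_coils: int, n: int) -> np.ndarray:
    """Smooth complex sensitivities, one Gaussian lobe per quadrant."""
    yy, xx = np.mgrid[0:n, 0:n] / (n - 1)  # in [0, 1]
    centres = [(0.15, 0.15), (0.15, 0.85), (0.85, 0.15), (0.85, 0.85)]
    sens = np.empty((n_coils, n, n), complex)
    for c in range(n_coils):
        cy, cx = centres[c % len(centres)]
        g = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 0.45**2)))
        phase = 0.5 * np.pi * (c / max(n_coils, 1)) + 0.3 * (xx - cx) + 0.2 * (yy - cy)
        sens[c] = (0.3 + g) * np.exp(1j * phase)
    return sens


@dataclass
class PhantomData:
    """Rendered phantom plus its exact ground truth."""

    kspace: KSpaceSeries
    truth_velocity: VelocityField  # exact field used in the forward model
    truth_strain: np.ndarray  # %strain per frame (closed form)
    truth_v_long: np.ndarray  # cm/s per frame (closed form)
    myocardial_mask: np.ndarray  # frame-0 ring, (y, x) bool
    static_mask: np.ndarray  # extracardiac static tissue, (y, x) bool
    contour_seeds: np.ndarray  # ordered closed midwall polyline, (n, 2)
    spec: PhantomSpec = None

    def segmentation(self, n_segments: int = 6) -> Segmentation:
        return sectorize(self.myocardial_mask, n_segments=n_segments)


def render_kspace(spec: PhantomSpec) -> PhantomData:
    """Forward-simulate the multi-coil, multi-encoding k-space acquisition."""
    n = spec.matrix
    dx = spec.pixel_spacing  # mm per pixel
    centre = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    ry = (yy - centre) * dx  # mm
    rx = (xx - centre) * dx
    r = np.hypot(ry, rx)

    times = np.arange(spec.n_frames) * spec.frame_interval
    scheme = spec.scheme
    n_enc = scheme.n_encodings
    edge = 0.6 * dx  # mm; sub-pixel edge smoothing

    # static extracardiac blobs (zero velocity) for background correction
    blob_r = 0.32 * spec.fov
    blob_pos = [(blob_r, 0.0), (-blob_r, 0.0), (0.0, blob_r), (0.0, -blob_r)]
    static_mag = np.zeros((n, n))
    for by, bx in blob_pos:
        static_mag += 0.7 * np.exp(-(((ry - by) ** 2 + (rx - bx) ** 2) / (2 * 2.0**2)))
    static_mask = static_mag > 0.35

    phi0 = 0.3 + 0.25 * rx / spec.fov + 0.15 * ry / spec.fov  # background phase
    sens = _coil_sensitivities(spec.n_coils, n)

    images = np.empty((spec.n_coils, spec.n_frames, n_enc, n, n), complex)
    truth_v = np.zeros((spec.n_frames, n, n, 3))
    truth_mag = np.empty((spec.n_frames, n, n))
    band_margin = 1.5 * dx
    for f, t in enumerate(times):
        s, s_dot, _, v_long = analytic_motion(spec, t)
        ring = _smooth_band(r, spec.r_inner * s, spec.r_outer * s, edge)
        support = (r >= spec.r_inner * s - band_margin) & (
            r <= spec.r_outer * s + band_margin
        )
        # v = (x - c) * s'/s, converted mm/ms -> cm/s (factor 100)
        rate = s_dot / s * 100.0  # 1/ms * mm -> cm/s when multiplied by mm
        v = np.zeros((n, n, 3))
        v[..., 0] = np.where(support, rx * rate, 0.0)
        v[..., 1] = np.where(support, ry * rate, 0.0)
        v[..., 2] = np.where(support, v_long, 0.0)
        truth_v[f] = v
        mag = ring + static_mag
        truth_mag[f] = mag
        enc_phase = np.tensordot(v, scheme.matrix.T, axes=([2], [0]))  # (y, x, enc)
        if spec.eddy_amplitude:
            ramp = spec.eddy_amplitude * (0.4 + rx / spec.fov + 0.5 * ry / spec.fov)
            enc_phase = enc_phase + ramp[..., None] * np.ones(3) @ scheme.matrix.T
        peak = np.abs(enc_phase).max() * np.pi / spec.venc
        if peak >= np.pi:
            raise ValueError(
                f"encoded phase {peak:.2f} rad would wrap; reduce velocity or raise venc"
            )
        phase = phi0[..., None] + (np.pi / spec.venc) * enc_phase
        frame_img = mag[..., None] * np.exp(1j * phase)  # (y, x, enc)
        images[:, f] = sens[:, None] * frame_img.transpose(2, 0, 1)[None]

    kdata = image_to_kspace(images)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = spec.noise_sigma * np.sqrt(np.mean(np.abs(kdata) ** 2))
        noise = rng.normal(scale=sigma / np.sqrt(2), size=kdata.shape + (2,))
        kdata = kdata + noise[..., 0] + 1j * noise[..., 1]

    kspace = KSpaceSeries(
        data=kdata,
        venc=spec.venc,
        frame_interval=spec.frame_interval,
        fov=(spec.fov, spec.fov),
    )
    ring0 = _smooth_band(r, spec.r_inner, spec.r_outer, edge)
    myocardial_mask = ring0 > 0.5
    _, _, strain, _ = analytic_motion(spec, times)
    _, _, _, v_long_curve = analytic_motion(spec, times)
    truth_field = VelocityField(
        v=truth_v,
        magnitude=truth_mag,
        venc=spec.venc,
        frame_interval=spec.frame_interval,
        pixel_spacing=(dx, dx),
    )
    seeds = midwall_contour((centre, centre), spec.r_mid / dx, n_points=72)
    return PhantomData(
        kspace=kspace,
        truth_velocity=truth_field,
        truth_strain=strain,
        truth_v_long=v_long_curve,
        myocardial_mask=myocardial_mask,
        static_mask=static_mask,
        contour_seeds=seeds,
        spec=spec,
    )
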