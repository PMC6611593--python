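"""Phase-contrast velocity decoding.

Phase-contrast MRI encodes tissue velocity into the phase of the complex
signal: encoding ``e`` with normalized first-moment direction ``M_e``
produces the pixel phase

    phi_e = phi_0 + (pi / venc) * (M_e . v)

where ``phi_0`` is the velocity-independent background phase and ``venc``
is the velocity mapped to a phase of pi for one encoding difference.
Given at least four encodings whose augmented design matrix ``[1 | M]`` has
full column rank, ``(phi_0, v)`` is recovered per pixel by linear least
squares on the measured phase angles; a two-encoding scheme yields a single
component via ``v = venc * dphi / pi``.

Coil images are combined before decoding by a magnitude-weighted
phase-difference sum against the first (reference) encoding, which cancels
the unknown per-coil phase while preserving the inter-encoding phase
differences that carry the velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ImageSeries

__all__ = [
    "EncodingScheme",
    "VelocityField",
    "combine_coils",
    "decode_velocity",
    "background_phase_correct",
]


@dataclass(frozen=True)
class EncodingScheme:
    """Velocity-encoding design: one normalized first-moment row per encoding."""

    matrix: np.ndarray  # (n_encodings, 3)
    venc: float  # cm/s
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.atleast_2d(np.asarray(self.matrix, float)))
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.matrix.shape[1] != 3:
            raise ValueError("encoding matrix must have 3 columns (x, y, z)")

    @property
    def n_encodings(self) -> int:
        return self.matrix.shape[0]

    def design(self) -> np.ndarray:
        """Augmented design matrix [1 | (pi/venc) M] mapping (phi0, v) to phases."""
        return np.hstack(
            [np.ones((self.n_encodings, 1)), (np.pi / self.venc) * self.matrix]
        )

    def assert_full_rank(self) -> None:
        if np.linalg.matrix_rank(self.design()) < 4:
            raise ValueError("encoding scheme is rank deficient; cannot decode 3 components")

    # -- shipped schemes ---------------------------------------------------

    @classmethod
    def two_point(cls, venc: float, axis: str = "z") -> "EncodingScheme":
        """Reference + one encoded acquisition along a single axis."""
        direction = {"x": [1, 0, 0], "y": [0, 1, 0], "z": [0, 0, 1]}[axis]
        return cls(
            matrix=np.array([[0, 0, 0], direction], float),
            venc=venc,
            names=("ref", f"+{axis}"),
        )

    @classmethod
    def balanced_four_point(cls, venc: float) -> "EncodingScheme":
        """Hadamard-type balanced four-point scheme (tetrahedral corners)."""
        m = np.array(
            [[-1, -1, -1], [1, 1, -1], [1, -1, 1], [-1, 1, 1]], float
        )
        return cls(matrix=m, venc=venc, names=("e1", "e2", "e3", "e4"))

    @classmethod
    def nine_point(cls, venc: float) -> "EncodingScheme":
        """Reference plus the eight symmetric (+-1, +-1, +-1) corners."""
        corners = np.array(
            [
                [s1, s2, s3]
                for s1 in (-1, 1)
                for s2 in (-1, 1)
                for s3 in (-1, 1)
            ],
            float,
        )
        m = np.vstack([np.zeros(3), corners])
        return cls(matrix=m, venc=venc)

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "venc": self.venc,
            "names": list(self.names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingScheme":
        return cls(
            matrix=np.asarray(d["matrix"], float),
            venc=float(d["venc"]),
            names=tuple(d.get("names", ())),
        )


@dataclass
class VelocityField:
    """Per-pixel, per-frame velocity in cm/s.

    ``v`` is indexed ``(frame, y, x, component)`` with components ordered
    (x, y, z); z is the through-plane (longitudinal) direction.
    ``flagged`` marks pixels whose magnitude was zero (velocity set to 0).
    """

    v: np.ndarray  # (frame, y, x, 3) cm/s
    magnitude: np.ndarray  # (frame, y, x)
    venc: float
    frame_interval: float  # ms
    pixel_spacing: tuple[float, float] = (1.0, 1.0)  # mm (dy, dx)
    flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, float)
        if self.v.ndim != 4 or self.v.shape[-1] != 3:
            raise ValueError("v must be (frame, y, x, 3)")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("velocity field contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.v.shape[0]


def combine_coils(per_coil_images: ImageSeries, reference_encoding: int = 0) -> np.ndarray:
    """Magnitude-weighted phase-difference coil combination.

    Returns a complex array of shape (frame, encoding, y, x):
    ``sum_c conj(img[c, :, ref]) * img[c, :, e]``.  The phase of the result
    is the coil-sensitivity-free phase difference against the reference
    encoding, weighted by coil magnitude squared.
    """
    data = per_coil_images.data
    if data.shape[0] < 1:
        raise ValueError("need at least one coil")
    ref = data[:, :, reference_encoding : reference_encoding + 1]
    return np.sum(np.conj(ref) * data, axis=0)


def decode_velocity(
    combined: np.ndarray,
    scheme: EncodingScheme,
    *,
    frame_interval: float = 1.0,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> VelocityField:
    """Decode per-pixel velocities from combined per-encoding complex images.

    ``combined`` has shape (frame, encoding, y, x).  With >= 4 encodings the
    full (phi_0, vx, vy, vz) system is solved by least squares; with exactly
    2 encodings the single phase difference is mapped through
    ``v = venc * dphi / pi`` along the encoded direction.  Pixels with zero
    magnitude across all encodings get velocity 0 and are flagged.
    """
    combined = np.asarray(combined)
    n_frames, n_enc, ny, nx = combined.shape
    if n_enc != scheme.n_encodings:
        raise ValueError(
            f"data has {n_enc} encodings but scheme defines {scheme.n_encodings}"
        )
    magnitude = np.abs(combined).mean(axis=1)
    zero = magnitude == 0

    v = np.zeros((n_frames, ny, nx, 3))
    if n_enc >= 4:
        scheme.assert_full_rank()
        phases = np.angle(combined)  # (frame, enc, y, x)
        a = scheme.design()  # (enc, 4)
        pinv = np.linalg.pinv(a)  # (4, enc)
        # solve for all pixels/frames at once
        flat = phases.transpose(1, 0, 2, 3).reshape(n_enc, -1)
        params = pinv @ flat  # (4, frame*y*x)
        v = params[1:].T.reshape(n_frames, ny, nx, 3)
    elif n_enc == 2:
        direction = scheme.matrix[1] - scheme.matrix[0]
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise ValueError("two-point scheme has identical rows")
        dphi = np.angle(combined[:, 1] * np.conj(combined[:, 0]))
        speed = scheme.venc * dphi / np.pi / norm
        v = speed[..., None] * (direction / norm)
    else:
        raise ValueError("need >= 4 encodings (or exactly 2 for single-component mode)")

    v[zero] = 0.0
    return VelocityField(
        v=v,
        magnitude=magnitude,
        venc=scheme.venc,
        frame_interval=frame_interval,
        pixel_spacing=pixel_spacing,
        flagged=zero,
    )


def background_phase_correct(
    field: VelocityField, static_mask: np.ndarray, order: int = 1
) -> VelocityField:
    """Remove slowly varying background velocity offsets (e.g. eddy currents).

    Fits a 2-D polynomial of the given order (0, 1 or 2) to each velocity
    component over the static-tissue pixels of every frame and subtracts the
    fitted surface from the whole field.  After correction the mean velocity
    over the static region is zero to numerical precision.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    static_mask = np.asarray(static_mask, bool)
    if not static_mask.any():
        raise ValueError("static mask is empty")
    ny, nx = static_mask.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    # normalized coordinates keep the Vandermonde well conditioned
    yn = (yy - ny / 2) / ny
    xn = (xx - nx / 2) / nx
    terms = [np.ones_like(yn)]
    if order >= 1:
        terms += [xn, yn]
    if order >= 2:
        terms += [xn * yn, xn**2, yn**2]
    basis = np.stack(terms, axis=-1)  # (y, x, n_terms)
    a = basis[static_mask]  # (n_static, n_terms)
    if a.shape[0] < a.shape[1]:
        raise ValueError(
            f"{a.shape[0]} static pixels cannot determine {a.shape[1]} coefficients"
        )

    v = field.v.copy()
    flat_basis = basis.reshape(-1, basis.shape[-1])
    for f in range(field.n_frames):
        for comp in range(3):
            b = field.v[f, ..., comp][static_mask]
            coef, *_ = np.linalg.lstsq(a, b, rcond=None)
            v[f, ..., comp] -= (flat_basis @ coef).reshape(ny, nx)
    out = VelocityField(
        v=v,
        magnitude=field.magnitude,
        venc=field.venc,
        frame_interval=field.frame_interval,
        pixel_spacing=field.pixel_spacing,
        flagged=field.flagged,
    )
    return out
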