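"""Centre-weighted random phase-encode undersampling masks.

A Cartesian cine acquisition acquires k-space line by line along the
phase-encode axis (ky).  Acceleration comes from acquiring only a subset of
lines; compressed sensing then requires the aliasing induced by the mask to
be *incoherent* (noise-like) in the sparse domain.  Masks are therefore
drawn with a centre-weighted random generator — the sampling density rises
toward the centre of k-space, and a deterministic centre block holding a
quarter of the acquired lines is always fully sampled to preserve image
contrast — and screened by the sidelobe-to-peak ratio (SPR) of their point
spread function: candidates whose largest PSF sidelobe is too high relative
to the main peak are rejected and redrawn.

Only the phase-encode axis is undersampled; the readout (kx) axis is always
fully sampled, as in a Cartesian gradient-echo sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "MaskQuality",
    "SamplingMaskSet",
    "generate_mask",
    "sidelobe_to_peak",
    "generate_incoherent_mask",
    "make_mask_set",
    "candidate_seed",
]

DEFAULT_SPR_MAX = 0.25
DEFAULT_MAX_ATTEMPTS = 100
DEFAULT_CENTRE_FRACTION = 0.25
DEFAULT_WEIGHT_EXPONENT = 2.0


@dataclass(frozen=True)
class MaskQuality:
    """Incoherence screening outcome for one mask."""

    spr: float
    accepted: bool


def n_acquired_lines(n_ky: int, us_factor: float) -> int:
    """Number of acquired phase-encode lines: ceil(n_ky / us_factor)."""
    return int(math.ceil(n_ky / us_factor))


def centre_block(n_ky: int, n_centre: int) -> np.ndarray:
    """The ``n_centre`` centremost ky indices, symmetric about the DC line.

    DC sits at index ``n_ky // 2`` (centered k-space layout).
    """
    dc = n_ky // 2
    start = dc - n_centre // 2
    return np.arange(start, start + n_centre)


def _validate(n_ky: int, us_factor: float) -> None:
    if n_ky < 4:
        raise ValueError(f"n_ky must be >= 4, got {n_ky}")
    if not (1 <= us_factor <= n_ky):
        raise ValueError(
            f"us_factor must lie in [1, n_ky={n_ky}], got {us_factor}"
        )


def generate_mask(
    n_ky: int,
    us_factor: float,
    seed: int,
    *,
    centre_fraction: float = DEFAULT_CENTRE_FRACTION,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> np.ndarray:
    """Draw one centre-weighted random set of acquired ky indices.

    Exactly ``ceil(n_ky / us_factor)`` lines are returned.  A deterministic
    centre block holding ``round(centre_fraction * n_acq)`` lines around DC
    is always included; the remaining lines are drawn without replacement
    from the periphery with probability weight ``(1 - d / (d_max + 1))**p``
    where ``d`` is the distance from the DC line.  Deterministic given
    ``seed``.

    Returns a sorted integer array of acquired ky indices.
    """
    _validate(n_ky, us_factor)
    n_acq = n_acquired_lines(n_ky, us_factor)
    n_c = int(math.floor(n_acq * centre_fraction + 0.5))
    if n_acq < n_c:
        raise ValueError(
            f"degenerate mask: {n_acq} acquired lines < {n_c} centre lines"
        )
    centre = centre_block(n_ky, n_c)
    n_random = n_acq - n_c
    if n_random == 0:
        return np.sort(centre)

    dc = n_ky // 2
    all_ky = np.arange(n_ky)
    periphery = np.setdiff1d(all_ky, centre, assume_unique=True)
    d = np.abs(periphery - dc).astype(float)
    # +1 keeps the most peripheral line at strictly positive weight so a
    # us_factor of 1 can select every line.
    w = (1.0 - d / (d.max() + 1.0)) ** weight_exponent
    w /= w.sum()
    rng = np.random.default_rng(seed)
    drawn = rng.choice(periphery, size=n_random, replace=False, p=w)
    return np.sort(np.concatenate([centre, drawn]))


def sidelobe_to_peak(lines: np.ndarray, n_ky: int) -> float:
    """Sidelobe-to-peak ratio of a mask's 1-D point spread function.

    The PSF is the modulus of the DFT of the binary acquire/skip indicator
    vector; the ratio of the largest off-peak value to the zero-lag peak
    measures how incoherent (noise-like) the aliasing of the mask is.
    0 for a fully sampled mask, 1 for a single line.
    """
    lines = np.asarray(lines, dtype=int)
    if lines.size == 0:
        raise ValueError("empty mask has no point spread function")
    indicator = np.zeros(n_ky)
    indicator[lines] = 1.0
    psf = np.abs(np.fft.fft(indicator))
    peak = psf[0]  # zero lag: equals the number of acquired lines
    if n_ky == 1:
        return 0.0
    return float(psf[1:].max() / peak)


def candidate_seed(seed: int, attempt: int) -> int:
    """Deterministic sub-seed for retry ``attempt`` of a screened draw."""
    return int(np.random.SeedSequence([seed, attempt]).generate_state(1)[0] % (2**31))


def generate_incoherent_mask(
    n_ky: int,
    us_factor: float,
    seed: int,
    *,
    spr_max: float = DEFAULT_SPR_MAX,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
    centre_fraction: float = DEFAULT_CENTRE_FRACTION,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> tuple[np.ndarray, MaskQuality]:
    """Draw masks until one passes the SPR incoherence screen.

    Candidate ``i`` uses the sub-seed ``candidate_seed(seed, i)``.  If no
    candidate reaches ``spr <= spr_max`` within ``max_attempts``, the
    lowest-SPR candidate is returned flagged ``accepted=False``.
    """
    if not (0 < spr_max <= 1):
        raise ValueError("spr_max must lie in (0, 1]")
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    best_lines: np.ndarray | None = None
    best_spr = np.inf
    for attempt in range(max_attempts):
        lines = generate_mask(
            n_ky,
            us_factor,
            candidate_seed(seed, attempt),
            centre_fraction=centre_fraction,
            weight_exponent=weight_exponent,
        )
        spr = sidelobe_to_peak(lines, n_ky)
        if spr <= spr_max:
            return lines, MaskQuality(spr=spr, accepted=True)
        if spr < best_spr:
            best_spr = spr
            best_lines = lines
    assert best_lines is not None
    return best_lines, MaskQuality(spr=best_spr, accepted=False)


@dataclass
class SamplingMaskSet:
    """One undersampling mask per (frame, velocity encoding).

    ``lines[frame][encoding]`` is the sorted array of acquired ky indices.
    Using a different random mask for every frame and encoding spreads the
    aliasing incoherently along the temporal-frequency axis exploited by
    the reconstruction.
    """

    n_ky: int
    us_factor: float
    lines: list[list[np.ndarray]]
    seed: int
    quality: list[list[MaskQuality]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.lines)

    @property
    def n_encodings(self) -> int:
        return len(self.lines[0])

    @property
    def n_acquired(self) -> int:
        return n_acquired_lines(self.n_ky, self.us_factor)

    def indicator(self) -> np.ndarray:
        """uint8 acquire/skip array of shape (n_frames, n_encodings, n_ky)."""
        out = np.zeros((self.n_frames, self.n_encodings, self.n_ky), dtype=np.uint8)
        for f, per_frame in enumerate(self.lines):
            for e, ky in enumerate(per_frame):
                out[f, e, ky] = 1
        return out

    # -- serialization -----------------------------------------------------

    def to_hdf5(self, group: h5py.Group) -> None:
        group.attrs["n_ky"] = self.n_ky
        group.attrs["us_factor"] = self.us_factor
        group.attrs["seed"] = self.seed
        group.attrs["n_frames"] = self.n_frames
        group.attrs["n_encodings"] = self.n_encodings
        for f in range(self.n_frames):
            for e in range(self.n_encodings):
                indicator = np.zeros(self.n_ky, dtype=np.uint8)
                indicator[self.lines[f][e]] = 1
                ds = group.create_dataset(f"mask_f{f}_e{e}", data=indicator)
                if self.quality:
                    ds.attrs["spr"] = self.quality[f][e].spr
                    ds.attrs["accepted"] = self.quality[f][e].accepted

    @classmethod
    def from_hdf5(cls, group: h5py.Group) -> "SamplingMaskSet":
        n_frames = int(group.attrs["n_frames"])
        n_encodings = int(group.attrs["n_encodings"])
        lines, quality = [], []
        for f in range(n_frames):
            row, qrow = [], []
            for e in range(n_encodings):
                ds = group[f"mask_f{f}_e{e}"]
                row.append(np.flatnonzero(np.asarray(ds[()])))
                spr = float(ds.attrs.get("spr", np.nan))
                qrow.append(MaskQuality(spr=spr, accepted=bool(ds.attrs.get("accepted", True))))
            lines.append(row)
            quality.append(qrow)
        return cls(
            n_ky=int(group.attrs["n_ky"]),
            us_factor=float(group.attrs["us_factor"]),
            lines=lines,
            seed=int(group.attrs["seed"]),
            quality=quality,
        )

    def to_text(self) -> str:
        """One mask per line: ``frame,encoding:ky,ky,...``."""
        rows = []
        for f, per_frame in enumerate(self.lines):
            for e, ky in enumerate(per_frame):
                rows.append(f"{f},{e}:" + ",".join(str(int(i)) for i in ky))
        return "\n".join(rows) + "\n"


def make_mask_set(
    n_ky: int,
    us_factor: float,
    n_frames: int,
    n_encodings: int,
    seed: int,
    *,
    spr_max: float = DEFAULT_SPR_MAX,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
    centre_fraction: float = DEFAULT_CENTRE_FRACTION,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> SamplingMaskSet:
    """Generate an independently screened mask per (frame, encoding).

    Sub-seeds are derived deterministically from ``(seed, frame, encoding)``
    so the same seed always reproduces the same mask set (the set can be
    serialized and reused across datasets).
    """
    if n_frames < 1 or n_encodings < 1:
        raise ValueError("n_frames and n_encodings must be >= 1")
    lines: list[list[np.ndarray]] = []
    quality: list[list[MaskQuality]] = []
    for f in range(n_frames):
        row, qrow = [], []
        for e in range(n_encodings):
            sub = int(
                np.random.SeedSequence([seed, f, e]).generate_state(1)[0] % (2**31)
            )
            ky, q = generate_incoherent_mask(
                n_ky,
                us_factor,
                sub,
                spr_max=spr_max,
                max_attempts=max_attempts,
                centre_fraction=centre_fraction,
                weight_exponent=weight_exponent,
            )
            row.append(ky)
            qrow.append(q)
        lines.append(row)
        quality.append(qrow)
    return SamplingMaskSet(
        n_ky=n_ky, us_factor=us_factor, lines=lines, seed=seed, quality=quality
    )
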