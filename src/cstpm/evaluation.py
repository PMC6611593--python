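"""Retrospective-undersampling validation and agreement statistics.

Myocardial velocity and strain values are not normally distributed, so
agreement between fully sampled and undersampled pipelines is assessed with
a *nonparametric* Bland-Altman analysis: the bias is the median of the
paired differences and the 95% limits of agreement (LOA) are their 2.5th
and 97.5th percentiles (linear-interpolation percentiles).  Group-level
contrasts use the two-sided Wilcoxon rank-sum test with a Bonferroni
correction of the alpha level across the undersampling factors tested.

``retrospective_experiment`` runs the full validation loop: mask the fully
sampled k-space at each undersampling factor, reconstruct with iterative
soft-thresholding, decode velocities, run the kinematic analysis with the
*same* segmentation and contour as the fully sampled reference, and tabulate
bias/LOA per quantity, scope and factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import KSpaceSeries
from .kinematics import KinematicsResult, Segmentation, analyze
from .masks import SamplingMaskSet
from .recon import ReconConfig, cs_reconstruct, retrospective_undersample
from .velocity import EncodingScheme, VelocityField, combine_coils, decode_velocity

__all__ = [
    "BlandAltmanResult",
    "bland_altman",
    "group_compare",
    "retrospective_experiment",
    "magnitude_nrmse",
    "kinematics_from_images",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    """Median bias and 95% percentile limits of agreement."""

    bias: float
    loa_low: float  # 2.5th percentile of differences
    loa_high: float  # 97.5th percentile
    n: int
    units: str = ""

    @property
    def loa_width(self) -> float:
        return self.loa_high - self.loa_low


def bland_altman(a, b, units: str = "") -> BlandAltmanResult:
    """Nonparametric Bland-Altman agreement between paired series.

    Differences are ``a - b``; bias is their median, limits of agreement
    the 2.5th and 97.5th percentiles with linear interpolation between
    order statistics.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    d = a - b
    lo, hi = np.percentile(d, [2.5, 97.5], method="linear")
    return BlandAltmanResult(
        bias=float(np.median(d)),
        loa_low=float(lo),
        loa_high=float(hi),
        n=d.size,
        units=units,
    )


def group_compare(values_a, values_b, n_tests: int, alpha: float = 0.05):
    """Two-sided Wilcoxon rank-sum test with Bonferroni-corrected alpha.

    Uses the exact null distribution when both groups are small and
    tie-free, otherwise the tie-corrected normal approximation.  Returns
    ``(statistic, p, corrected_alpha, significant)``.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "asymptotic" if has_ties or max(a.size, b.size) > 25 else "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    corrected = alpha / n_tests
    return float(res.statistic), p, corrected, p < corrected


def magnitude_nrmse(images: np.ndarray, reference: np.ndarray) -> float:
    """Normalized RMS error between magnitude images (coil sum-of-squares)."""
    mag = np.sqrt(np.sum(np.abs(images) ** 2, axis=0))
    ref = np.sqrt(np.sum(np.abs(reference) ** 2, axis=0))
    return float(np.linalg.norm(mag - ref) / np.linalg.norm(ref))


def kinematics_from_images(
    images, scheme: EncodingScheme, seg: Segmentation, contour_seeds
) -> tuple[KinematicsResult, VelocityField]:
    """Coil combination -> velocity decoding -> kinematic analysis."""
    combined = combine_coils(images)
    field = decode_velocity(
        combined,
        scheme,
        frame_interval=images.frame_interval,
        pixel_spacing=images.pixel_spacing,
    )
    return analyze(field, seg, contour_seeds), field


_QUANTITIES = (
    ("radial velocity", "cm/s"),
    ("longitudinal velocity", "cm/s"),
    ("circumferential strain", "%strain"),
)


def _result_samples(res: KinematicsResult, quantity: str, scope: str) -> np.ndarray:
    key = {
        "radial velocity": ("v_rad_global", "v_rad_seg"),
        "longitudinal velocity": ("v_long_global", "v_long_seg"),
        "circumferential strain": ("strain_circ_global", "strain_circ_seg"),
    }[quantity]
    arr = getattr(res, key[0] if scope == "global" else key[1])
    return np.asarray(arr).ravel()


def retrospective_experiment(
    full_kspace: KSpaceSeries,
    mask_sets: dict[float, SamplingMaskSet],
    segmentation: Segmentation,
    contour_seeds,
    scheme: EncodingScheme,
    config: ReconConfig | None = None,
    slice_label: str = "mid-ventricular",
) -> pd.DataFrame:
    """Bland-Altman agreement table across undersampling factors.

    The fully sampled reference is the direct inverse-FFT reconstruction;
    each undersampled variant is reconstructed by iterative
    soft-thresholding after retrospective masking.  All variants are
    analysed with the same segmentation and contour as the reference, so
    the table isolates the effect of undersampling and reconstruction.

    Returns a tidy DataFrame with one row per (quantity, scope, us factor):
    columns quantity, scope, us, slice, bias, loa_low, loa_high, n, units.
    """
    if not mask_sets:
        raise ValueError("need at least one undersampling factor")
    if config is None:
        config = ReconConfig()
    ref_images = full_kspace.to_images()
    ref_res, _ = kinematics_from_images(ref_images, scheme, segmentation, contour_seeds)

    rows = []
    for us in sorted(mask_sets):
        masks = mask_sets[us]
        undersampled = retrospective_undersample(full_kspace, masks)
        recon_images, _ = cs_reconstruct(undersampled, masks, config)
        res, _ = kinematics_from_images(
            recon_images, scheme, segmentation, contour_seeds
        )
        for quantity, units in _QUANTITIES:
            for scope in ("global", "regional"):
                ba = bland_altman(
                    _result_samples(res, quantity, scope),
                    _result_samples(ref_res, quantity, scope),
                    units=units,
                )
                rows.append(
                    {
                        "quantity": quantity,
                        "scope": scope,
                        "us": us,
                        "slice": slice_label,
                        "bias": ba.bias,
                        "loa_low": ba.loa_low,
                        "loa_high": ba.loa_high,
                        "n": ba.n,
                        "units": units,
                    }
                )
    return pd.DataFrame(rows)
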