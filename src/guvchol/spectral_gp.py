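"""Generalized-polarization analysis of spectral GUV image stacks.

The pipeline mirrors a standard lambda-scan workflow for ratiometric
membrane-order probes: channel registration, maximum-intensity projection,
bright-outlier exclusion, percentile contrast stretch, Otsu segmentation of
the membrane, pixel-wise GP from the two analysis channels,

    GP = (I_B - I_R) / (I_B + I_R),

where I_B and I_R are the photon counts at the shorter (570 nm) and longer
(640 nm) analysis wavelengths, and finally the unweighted mean GP over the
vesicle's masked pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.registration import phase_cross_correlation


def nearest_channel(channel_centers, wavelength_nm: float) -> int:
    """Index of the channel center nearest a wavelength; ties go blue-ward.

    On a 565...695 nm grid both 570 and 640 nm sit exactly between two
    centers; the shorter-wavelength channel is chosen so the analysis bands
    are 565 nm ("blue") and 635 nm ("red").
    """
    centers = np.asarray(channel_centers, dtype=float)
    d = np.abs(centers - wavelength_nm)
    return int(np.argmin(d))  # argmin returns the first (blue-most) minimum on ties


@dataclass
class SpectralStack:
    """Photon-count image cube of one field of view, one page per channel."""

    data: np.ndarray  # (channels, rows, cols), counts
    channel_centers: np.ndarray  # nm, strictly increasing
    pixel_size_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_centers = np.asarray(self.channel_centers, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be (channels, rows, cols)")
        if self.data.shape[0] != self.channel_centers.size:
            raise ValueError("channel_centers length must match the channel axis")
        if self.channel_centers.size < 2:
            raise ValueError("need at least 2 channels")
        if not np.all(np.diff(self.channel_centers) > 0):
            raise ValueError("channel_centers must be strictly increasing")
        if np.any(self.data < 0):
            raise ValueError("photon counts must be nonnegative")

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[0])


@dataclass
class GpImage:
    """Per-pixel GP map; NaN outside the analysis mask."""

    gp: np.ndarray
    mask: np.ndarray
    lambda_blue: float
    lambda_red: float
    n_dropped_low_counts: int = 0

    def defined_values(self) -> np.ndarray:
        return self.gp[self.mask]


@dataclass
class VesicleRecord:
    """One per-GUV readout (mean GP or mean intensity-weighted lifetime)."""

    vesicle_id: str
    condition: str
    modality: str  # "GP" | "lifetime"
    value: float
    n_pixels: int = 0
    n_photons: int = 0
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.modality == "GP" and not -1.0 <= self.value <= 1.0:
            raise ValueError("GP readout must lie in [-1, 1]")
        if self.modality == "lifetime" and self.value <= 0:
            raise ValueError("lifetime readout must be positive")


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def register_stack(
    stack: SpectralStack, max_shift: float = 10.0, upsample_factor: int = 10
) -> tuple[SpectralStack, np.ndarray]:
    """Translate each channel onto the brightest channel by phase correlation.

    Shifts are estimated to subpixel precision but applied rounded to whole
    pixels so photon counts are preserved exactly (pixels shifted in from
    outside the field are zero).  A channel whose estimated shift exceeds
    ``max_shift`` (e.g. pure noise, no structure to register on) is left
    untouched with a warning.  Returns ``(registered_stack, shifts)`` where
    ``shifts`` is (channels, 2) in (row, col) order.
    """
    data = stack.data
    totals = data.sum(axis=(1, 2))
    ref_idx = int(np.argmax(totals))
    ref = data[ref_idx].astype(float)
    out = np.empty_like(data)
    shifts = np.zeros((stack.n_channels, 2))
    for c in range(stack.n_channels):
        ch = data[c]
        if ch.sum() == 0:
            warnings.warn(f"channel {c} is empty; skipping registration", stacklevel=2)
            out[c] = ch
            continue
        if c == ref_idx:
            out[c] = ch
            continue
        shift, _, _ = phase_cross_correlation(
            ref, ch.astype(float), upsample_factor=upsample_factor, normalization=None
        )
        if np.max(np.abs(shift)) > max_shift:
            warnings.warn(
                f"channel {c}: estimated shift {tuple(shift)} exceeds the "
                f"{max_shift} px cap; channel left unshifted",
                stacklevel=2,
            )
            out[c] = ch
            continue
        shifts[c] = shift
        dr, dc = int(round(shift[0])), int(round(shift[1]))
        moved = np.zeros_like(ch)
        src = ch
        r_lo, r_hi = max(0, dr), min(ch.shape[0], ch.shape[0] + dr)
        c_lo, c_hi = max(0, dc), min(ch.shape[1], ch.shape[1] + dc)
        moved[r_lo:r_hi, c_lo:c_hi] = src[r_lo - dr : r_hi - dr, c_lo - dc : c_hi - dc]
        out[c] = moved
    registered = SpectralStack(
        data=out,
        channel_centers=stack.channel_centers,
        pixel_size_um=stack.pixel_size_um,
        meta={**stack.meta, "registration_shifts": shifts.tolist()},
    )
    return registered, shifts


def max_projection(stack: SpectralStack) -> np.ndarray:
    """Pixel-wise maximum across channels (2D overlay image)."""
    return stack.data.max(axis=0)


def exclude_bright_outliers(
    image: np.ndarray, threshold: float = 99.9, mode: str = "quantile"
) -> np.ndarray:
    """Boolean mask of saturated / high-intensity outlier pixels.

    ``mode='quantile'``: flag pixels above the given upper percentile
    (default 99.9).  ``mode='absolute'``: flag pixels above an absolute count.
    """
    image = np.asarray(image)
    if np.any(image < 0):
        raise ValueError("image must be nonnegative")
    if mode == "quantile":
        if not 0 < threshold < 100:
            raise ValueError("quantile threshold must lie in (0, 100)")
        cut = np.percentile(image, threshold)
        excluded = image > cut
    elif mode == "absolute":
        excluded = image > threshold
    else:
        raise ValueError("mode must be 'quantile' or 'absolute'")
    nonzero = np.count_nonzero(image)
    if nonzero and np.count_nonzero(excluded & (image > 0)) > 0.5 * nonzero:
        raise ValueError(
            "outlier threshold excludes more than half of the nonzero pixels; "
            "check the threshold mode/value"
        )
    return excluded


def contrast_stretch(image: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Linear rescale to [0, 1], clamping at the two percentiles."""
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("require 0 <= low_pct < high_pct <= 100")
    image = np.asarray(image, dtype=float)
    lo, hi = np.percentile(image, [low_pct, high_pct])
    if hi == lo:
        warnings.warn("degenerate image (all percentile-equal); contrast stretch is identity",
                      stacklevel=2)
        return image.copy()
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def otsu_mask(
    image: np.ndarray,
    exclusion: np.ndarray | None = None,
    keep_largest: bool = True,
) -> tuple[np.ndarray, dict]:
    """Binary membrane mask by Otsu thresholding on a 256-bin histogram.

    Above-threshold pixels minus the exclusion mask; if ``keep_largest``,
    only the largest connected component is kept (one vesicle per field of
    view) and the number of discarded components is reported in the info
    dict along with the threshold used.
    """
    image = np.asarray(image, dtype=float)
    if np.unique(image).size < 2:
        raise ValueError("cannot Otsu-threshold a single-valued image")
    thr = threshold_otsu(image, nbins=256)
    mask = image > thr
    if exclusion is not None:
        mask &= ~exclusion
    info = {"otsu_threshold": float(thr), "n_components_discarded": 0}
    if keep_largest and mask.any():
        labels = cc_label(mask, connectivity=2)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        keep = int(np.argmax(sizes))
        info["n_components_discarded"] = int((sizes > 0).sum() - 1)
        mask = labels == keep
    return mask, info


def compute_gp(
    stack: SpectralStack,
    mask: np.ndarray,
    lambda_blue: float = 570.0,
    lambda_red: float = 640.0,
    min_counts: int = 10,
) -> GpImage:
    """Pixel-wise GP = (I_B - I_R)/(I_B + I_R) over the masked pixels.

    Pixels whose summed analysis-channel counts fall below ``min_counts`` are
    dropped from the mask (the ratio estimator is too noisy there); the
    number dropped is recorded on the returned image.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    i_b = nearest_channel(stack.channel_centers, lambda_blue)
    i_r = nearest_channel(stack.channel_centers, lambda_red)
    blue = stack.data[i_b].astype(float)
    red = stack.data[i_r].astype(float)
    total = blue + red
    if not np.any(total[mask] > 0):
        raise ValueError("all masked pixels have zero counts in the analysis channels")
    ok = mask & (total >= max(min_counts, 1))
    n_dropped = int(mask.sum() - ok.sum())
    gp = np.full(total.shape, np.nan)
    np.divide(blue - red, total, out=gp, where=ok)
    return GpImage(
        gp=gp,
        mask=ok,
        lambda_blue=float(stack.channel_centers[i_b]),
        lambda_red=float(stack.channel_centers[i_r]),
        n_dropped_low_counts=n_dropped,
    )


def vesicle_mean_gp(
    gp_image: GpImage, vesicle_id: str = "guv", condition: str = ""
) -> VesicleRecord:
    """Unweighted mean of the defined pixel GPs of one vesicle."""
    values = gp_image.defined_values()
    if values.size == 0:
        raise ValueError("no defined GP pixels")
    return VesicleRecord(
        vesicle_id=vesicle_id,
        condition=condition,
        modality="GP",
        value=float(values.mean()),
        n_pixels=int(values.size),
    )


def run_gp_pipeline(
    stack: SpectralStack,
    lambda_blue: float = 570.0,
    lambda_red: float = 640.0,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
    outlier_threshold: float = 99.9,
    outlier_mode: str = "quantile",
    min_counts: int = 10,
    register: bool = True,
    vesicle_id: str = "guv",
    condition: str = "",
) -> tuple[VesicleRecord, GpImage, dict]:
    """Full per-stack GP analysis: register, project, mask, GP, vesicle mean.

    Returns ``(record, gp_image, log)`` where ``log`` collects every
    threshold and parameter actually applied.
    """
    log: dict = {
        "lambda_blue_requested": lambda_blue,
        "lambda_red_requested": lambda_red,
        "low_pct": low_pct,
        "high_pct": high_pct,
        "outlier_threshold": outlier_threshold,
        "outlier_mode": outlier_mode,
        "min_counts": min_counts,
    }
    if register:
        stack, shifts = register_stack(stack)
        log["registration_shifts"] = shifts.tolist()
    projection = max_projection(stack)
    excluded = exclude_bright_outliers(projection, outlier_threshold, outlier_mode)
    log["n_outlier_pixels"] = int(excluded.sum())
    stretched = contrast_stretch(projection, low_pct, high_pct)
    mask, otsu_info = otsu_mask(stretched, exclusion=excluded)
    log.update(otsu_info)
    gp_image = compute_gp(stack, mask, lambda_blue, lambda_red, min_counts)
    log["lambda_blue_used"] = gp_image.lambda_blue
    log["lambda_red_used"] = gp_image.lambda_red
    log["n_dropped_low_counts"] = gp_image.n_dropped_low_counts
    record = vesicle_mean_gp(gp_image, vesicle_id=vesicle_id, condition=condition)
    return record, gp_image, log
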