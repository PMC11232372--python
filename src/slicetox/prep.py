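"""Stack loading and preprocessing.

Reproduces the acquisition-side bookkeeping and image conditioning used
before segmentation: 8-bit conversion, robust background estimation and
subtraction, median smoothing, and grouped maximum-intensity projections
(MIPs) that turn a 0-300 um z-stack into a sequence of 10-15 um-thick
depth sections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.morphology import disk

from .errors import InputError, ParameterError

log = logging.getLogger(__name__)

GREEN = "green"
RED = "red"


@dataclass
class VolumeStack:
    """One channel of a 3-D acquisition, shape (z, y, x), with geometry metadata.

    ``pixel_size`` is the in-plane sampling in um/px, ``z_step`` the plane
    spacing in um, and ``z0`` the depth of the first plane below the cut
    surface (um).
    """

    voxels: np.ndarray
    channel: str
    pixel_size: float
    z_step: float
    z0: float = 0.0

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise InputError("stack must be a non-empty 3-D (z, y, x) array")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        if self.z_step <= 0:
            raise ParameterError("z_step must be > 0")

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]

    def plane_depths(self) -> np.ndarray:
        """Depth (um) of every plane."""
        return self.z0 + np.arange(self.n_planes) * self.z_step


@dataclass
class Projection:
    """A maximum-intensity projection covering the half-open depth span [z_lo, z_hi)."""

    image: np.ndarray
    z_lo: float
    z_hi: float
    mip_index: int
    channel: str
    pixel_size: float = 1.0

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 2 or self.image.size == 0:
            raise InputError("projection image must be non-empty and 2-D")
        if not self.z_hi > self.z_lo:
            raise ParameterError("projection requires z_hi > z_lo")

    @property
    def z_mid(self) -> float:
        """Midpoint depth (um), the depth stamp used for binning."""
        return 0.5 * (self.z_lo + self.z_hi)


@dataclass
class BackgroundStats:
    mean: float
    sd: float


def read_stack(path, channel: str, pixel_size: float, z_step: float, z0: float = 0.0) -> VolumeStack:
    """Read a single-channel multi-page TIFF as a VolumeStack."""
    voxels = tifffile.imread(str(path))
    if voxels.ndim == 2:
        voxels = voxels[None]
    return VolumeStack(voxels=voxels, channel=channel, pixel_size=pixel_size, z_step=z_step, z0=z0)


def write_stack(stack: VolumeStack, path) -> None:
    """Write an ImageJ-compatible multi-page TIFF (z as pages, spacing in um)."""
    vox = stack.voxels
    if vox.dtype not in (np.uint8, np.uint16):
        vox = vox.astype(np.float32)
    tifffile.imwrite(
        str(path),
        vox,
        imagej=True,
        resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
        metadata={"spacing": stack.z_step, "unit": "um", "axes": "ZYX"},
    )


def to_8bit(stack: VolumeStack, lo: float | None = None, hi: float | None = None) -> VolumeStack:
    """Linearly map intensities from [lo, hi] (default: stack min/max) to 0..255.

    A constant stack (degenerate range) maps to all zeros.  Rounding is
    half-up so the map is monotone and endpoints are exact.  ``lo``/``hi``
    allow a shared scale across channels so that cross-channel intensity
    ratios remain meaningful after conversion.
    """
    v = np.asarray(stack.voxels, dtype=np.float64)
    lo = float(v.min()) if lo is None else float(lo)
    hi = float(v.max()) if hi is None else float(hi)
    if hi <= lo:
        out = np.zeros_like(v, dtype=np.uint8)
    else:
        scaled = (v - lo) / (hi - lo) * 255.0
        out = np.floor(np.clip(scaled, 0.0, 255.0) + 0.5).astype(np.uint8)
    return replace(stack, voxels=out)


def to_8bit_joint(green: VolumeStack, red: VolumeStack) -> tuple[VolumeStack, VolumeStack]:
    """8-bit conversion of both channels on one common linear scale."""
    lo = float(min(green.voxels.min(), red.voxels.min()))
    hi = float(max(green.voxels.max(), red.voxels.max()))
    return to_8bit(green, lo, hi), to_8bit(red, lo, hi)


def estimate_background(image: np.ndarray, region: tuple[int, int, int, int] | None = None) -> BackgroundStats:
    """Robust background level and noise estimate for a sparse-signal image.

    Default: median and 1.4826*MAD over all pixels, which ignores bright,
    sparse somata by construction.  ``region=(y0, y1, x0, x1)`` instead uses
    the plain mean/SD of a user-designated signal-free rectangle.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise InputError("cannot estimate background of an empty image")
    if region is not None:
        y0, y1, x0, x1 = region
        patch = image[y0:y1, x0:x1]
        if patch.size == 0:
            raise InputError("background-estimation rectangle is empty")
        return BackgroundStats(mean=float(patch.mean()), sd=float(patch.std()))
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return BackgroundStats(mean=med, sd=1.4826 * mad)


def subtract_background(
    image: np.ndarray, region: tuple[int, int, int, int] | None = None
) -> tuple[np.ndarray, BackgroundStats]:
    """Subtract the estimated background level, clipping at zero.

    Returns the corrected image and the background mean/SD; the SD feeds the
    downstream 5x-SD detection threshold.
    """
    stats = estimate_background(image, region=region)
    corrected = np.clip(np.asarray(image, dtype=np.float64) - stats.mean, 0.0, None)
    return corrected, stats


def median_smooth(image: np.ndarray, radius: int = 2) -> np.ndarray:
    """Median filter with a disk neighborhood; edges handled by reflection."""
    if radius < 0:
        raise ParameterError("median filter radius must be >= 0")
    image = np.asarray(image)
    if radius == 0:
        return image.copy()
    return ndi.median_filter(image, footprint=disk(radius), mode="reflect")


def make_mips(stack: VolumeStack, group_size: int = 5) -> list[Projection]:
    """Reduce consecutive non-overlapping groups of ``group_size`` planes by per-pixel max.

    The final partial group is kept so the depth spans tile the full stack.
    With 2-3 um steps and groups of five, each MIP represents a 10-15 um
    section of tissue.
    """
    if group_size < 1:
        raise ParameterError("group_size must be >= 1")
    n = stack.n_planes
    mips: list[Projection] = []
    for i, k0 in enumerate(range(0, n, group_size)):
        k1 = min(k0 + group_size, n)
        img = stack.voxels[k0:k1].max(axis=0)
        mips.append(
            Projection(
                image=img,
                z_lo=stack.z0 + k0 * stack.z_step,
                z_hi=stack.z0 + k1 * stack.z_step,
                mip_index=i,
                channel=stack.channel,
                pixel_size=stack.pixel_size,
            )
        )
    return mips


def preprocess_channel(
    stack: VolumeStack,
    group_size: int = 5,
    smooth_radius: int = 2,
    eight_bit: bool = True,
    scale: tuple[float, float] | None = None,
    bg_region: tuple[int, int, int, int] | None = None,
) -> tuple[list[Projection], list[BackgroundStats]]:
    """Full preprocessing for one channel: 8-bit, smooth planes, MIP, subtract.

    Returns background-subtracted MIPs and the per-MIP background stats used
    for thresholding.  ``scale`` passes a shared (lo, hi) so both channels of
    a dual acquisition live on one intensity scale.
    """
    if eight_bit:
        stack = to_8bit(stack, *(scale or (None, None)))
    smoothed = np.stack([median_smooth(p, smooth_radius) for p in stack.voxels])
    stack = replace(stack, voxels=smoothed)
    mips = make_mips(stack, group_size)
    stats: list[BackgroundStats] = []
    out: list[Projection] = []
    for mip in mips:
        corrected, st = subtract_background(mip.image, region=bg_region)
        out.append(replace(mip, image=corrected))
        stats.append(st)
    return out, stats


def preprocess_pair(
    green: VolumeStack,
    red: VolumeStack,
    group_size: int = 5,
    smooth_radius: int = 2,
    eight_bit: bool = True,
    joint_scale: bool = True,
    bg_region: tuple[int, int, int, int] | None = None,
):
    """Preprocess a dual-channel acquisition on a common intensity scale.

    Returns ``(green_mips, green_stats), (red_mips, red_stats)``.
    """
    scale = None
    if eight_bit and joint_scale:
        lo = float(min(green.voxels.min(), red.voxels.min()))
        hi = float(max(green.voxels.max(), red.voxels.max()))
        scale = (lo, hi)
    g = preprocess_channel(green, group_size, smooth_radius, eight_bit, scale, bg_region)
    r = preprocess_channel(red, group_size, smooth_radius, eight_bit, scale, bg_region)
    return g, r


def mip_depth_spans(mips: Sequence[Projection]) -> np.ndarray:
    """(n, 2) array of [z_lo, z_hi) spans, for depth bookkeeping checks."""
    return np.array([[m.z_lo, m.z_hi] for m in mips])
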