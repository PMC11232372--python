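"""Depth profiling: 30-um binning, normalization, and single-exponential fits.

Cell counts (or neuropil intensity medians) are tallied into half-open
depth bins [lo, hi) from 0 to 300 um, normalized to the slice total (counts)
or the slice maximum (intensities), and summarized by a single exponential
y = A * exp(-z / tau) fitted at the bin midpoints.  The decay constant tau
is the length scale over which trauma-induced injury falls off below the
cut surface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .detect import DetectionSet
from .errors import FitError, InputError, ParameterError
from .prep import Projection, VolumeStack

log = logging.getLogger(__name__)

KIND_COUNT = "count"
KIND_INTENSITY = "intensity"

DEFAULT_EDGES = np.arange(0.0, 301.0, 30.0)

TAU_BOUNDS = (1.0, 1e4)


@dataclass
class DepthProfile:
    """Binned values vs depth: counts per bin or per-bin intensity medians."""

    bin_edges: np.ndarray
    counts: np.ndarray
    kind: str = KIND_COUNT
    normalized: np.ndarray | None = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ParameterError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise InputError("counts length must equal number of bins")
        if self.kind not in (KIND_COUNT, KIND_INTENSITY):
            raise ParameterError(f"unknown profile kind {self.kind!r}")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        return float(np.nansum(self.counts))


@dataclass
class ExpFit:
    """Result of a single-exponential fit y = A * exp(-z/tau)."""

    amplitude: float
    tau: float
    r2: float
    converged: bool


def bin_by_depth(dets: DetectionSet, edges=DEFAULT_EDGES) -> DepthProfile:
    """Count detections into half-open depth bins [lo, hi).

    Detections outside [first, last) are dropped with a logged count; the
    in-range total is conserved.
    """
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ParameterError("bin edges must be strictly increasing")
    z = dets.df["z_um"].to_numpy(dtype=float)
    in_range = (z >= edges[0]) & (z < edges[-1])
    dropped = int((~in_range).sum())
    if dropped:
        log.info("bin_by_depth: dropped %d detections outside [%g, %g)", dropped, edges[0], edges[-1])
    idx = np.searchsorted(edges, z[in_range], side="right") - 1
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(float)
    return DepthProfile(bin_edges=edges, counts=counts, kind=KIND_COUNT)


def normalize_profile(profile: DepthProfile) -> DepthProfile:
    """Normalize counts to the slice total, or intensities to the slice maximum."""
    vals = profile.counts
    if profile.kind == KIND_COUNT:
        denom = np.nansum(vals)
    else:
        denom = np.nanmax(vals) if np.isfinite(vals).any() else 0.0
    if not denom > 0:
        warnings.warn("profile total/max is zero; normalized profile set to zeros")
        norm = np.zeros_like(vals)
    else:
        norm = vals / denom
    return replace(profile, normalized=norm)


def fit_exponential(profile_or_z, values=None, tau0: float = 50.0) -> ExpFit:
    """Nonlinear least-squares fit of y = A * exp(-z/tau).

    Accepts either a (normalized) DepthProfile — fitted at bin midpoints —
    or explicit (z, y) arrays.  Initialization A = y[0], tau = 50 um; tau is
    bounded to (1, 1e4) um.  ``converged`` is False when the optimizer fails
    or tau pins at a bound (no resolvable decay).
    """
    if isinstance(profile_or_z, DepthProfile):
        p = profile_or_z
        y = p.normalized if p.normalized is not None else p.counts
        z = p.midpoints
    else:
        z = np.asarray(profile_or_z, dtype=float)
        y = np.asarray(values, dtype=float)
    finite = np.isfinite(y) & np.isfinite(z)
    z, y = z[finite], y[finite]
    if int((y != 0).sum()) < 4:
        raise FitError("exponential fit needs >= 4 nonzero points")

    def model(zz, a, tau):
        return a * np.exp(-zz / tau)

    a0 = float(y[0]) if y[0] > 0 else float(max(y.max(), 1e-12))
    converged = True
    try:
        popt, _ = curve_fit(
            model, z, y, p0=(a0, tau0), bounds=([0.0, TAU_BOUNDS[0]], [np.inf, TAU_BOUNDS[1]]), maxfev=10000
        )
        a, tau = float(popt[0]), float(popt[1])
    except RuntimeError:
        a, tau = a0, float("nan")
        converged = False
    if converged and (tau <= TAU_BOUNDS[0] * (1 + 1e-6) or tau >= TAU_BOUNDS[1] * (1 - 1e-6)):
        converged = False
    if np.isfinite(tau):
        resid = y - model(z, a, tau)
        sstot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / sstot if sstot > 0 else float("nan")
    else:
        r2 = float("nan")
    return ExpFit(amplitude=a, tau=tau, r2=r2, converged=converged)


def _cumulative(profile: DepthProfile) -> tuple[np.ndarray, np.ndarray]:
    if profile.kind != KIND_COUNT:
        raise ParameterError("cumulative fractions are defined for count profiles")
    total = profile.total
    if total <= 0:
        raise InputError("empty profile: no counts")
    cum = np.concatenate([[0.0], np.cumsum(profile.counts)]) / total
    return profile.bin_edges, cum


def fraction_within(profile: DepthProfile, depth: float) -> float:
    """Cumulative fraction of counts at depths <= ``depth``.

    Linear interpolation inside a partially covered bin; depths outside the
    binned range are clamped with a warning.
    """
    edges, cum = _cumulative(profile)
    if depth < edges[0] or depth > edges[-1]:
        warnings.warn(f"depth {depth} outside [{edges[0]}, {edges[-1]}]; clamped")
        depth = float(np.clip(depth, edges[0], edges[-1]))
    return float(np.interp(depth, edges, cum))


def depth_for_fraction(profile: DepthProfile, q: float = 0.75) -> float:
    """Smallest depth at which the cumulative fraction reaches ``q`` (inverse of fraction_within)."""
    if not 0.0 < q < 1.0:
        raise ParameterError("q must be in (0, 1)")
    edges, cum = _cumulative(profile)
    # First index where cum >= q; interpolate within the preceding bin.
    i = int(np.searchsorted(cum, q, side="left"))
    if i == 0:
        return float(edges[0])
    if cum[i] == cum[i - 1]:
        return float(edges[i])
    frac = (q - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(edges[i - 1] + frac * (edges[i] - edges[i - 1]))


def median_neuropil_by_depth(
    source: VolumeStack | list[Projection],
    soma_masks=None,
    edges=DEFAULT_EDGES,
) -> DepthProfile:
    """Median green intensity outside soma masks, per 30-um depth step.

    ``source`` is either the (preprocessed) green VolumeStack — pixels are
    pooled over all planes whose depth falls in each bin — or a list of
    MIPs, pooled by midpoint depth.  ``soma_masks`` is an optional boolean
    mask (2-D, shared) or per-plane/MIP sequence marking soma pixels to
    exclude.  A bin whose pixels are all masked yields NaN (flagged).
    """
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ParameterError("bin edges must be strictly increasing")
    if isinstance(source, VolumeStack):
        images = list(source.voxels)
        depths = source.plane_depths()
    else:
        images = [m.image for m in source]
        depths = np.array([m.z_mid for m in source])

    def mask_for(i):
        if soma_masks is None:
            return None
        if isinstance(soma_masks, np.ndarray) and soma_masks.ndim == 2:
            return soma_masks
        return soma_masks[i]

    medians = np.full(len(edges) - 1, np.nan)
    for b in range(len(edges) - 1):
        sel = [i for i, d in enumerate(depths) if edges[b] <= d < edges[b + 1]]
        pixels = []
        for i in sel:
            img = np.asarray(images[i], dtype=float)
            m = mask_for(i)
            pixels.append(img[~m] if m is not None else img.ravel())
        if pixels:
            pooled = np.concatenate(pixels)
            if pooled.size:
                medians[b] = float(np.median(pooled))
            else:
                warnings.warn(f"all pixels masked in depth bin {b}; median flagged NaN")
    return DepthProfile(bin_edges=edges, counts=medians, kind=KIND_INTENSITY)
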