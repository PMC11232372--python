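"""Ratiometric elimination of bleed-through false positives.

At the excitation wavelength used for Ca2+ imaging, roughly half of the
green GCaMP signal leaks into the red (PI) detector, so bright green somata
produce false red detections.  True PI+ cells have more red than green
signal; bleed-through ghosts have red ~ b * green with b < 1.  The
normalized excess ratio (R - G) / G separates the two: it is negative iff
green dominates.  A Gaussian is fitted to the ratio distribution of
(curated) true detections, and everything below mean - 1 SD is eliminated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.optimize import curve_fit

from .detect import DetectionSet
from .errors import FitError, ParameterError

log = logging.getLogger(__name__)

EPS = 1e-6

RATIO_EXCESS = "excess"  # (R - G) / G
RATIO_SYMMETRIC = "symmetric"  # (R - G) / (R + G)


@dataclass
class RatioModel:
    """Gaussian summary of the red/green ratio distribution of true PI+ cells.

    ``threshold`` is always mean - 1 * sd; detections with ratio strictly
    below it are treated as bleed-through ghosts.
    """

    mean: float
    sd: float
    threshold: float
    n_fit: int
    converged: bool = True

    def __post_init__(self):
        if self.sd <= 0:
            raise ParameterError("ratio model sd must be > 0")
        if abs(self.threshold - (self.mean - self.sd)) > 1e-9:
            raise ParameterError("threshold must equal mean - 1*sd")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "mean": float(self.mean),
                    "sd": float(self.sd),
                    "threshold": float(self.threshold),
                    "n_fit": int(self.n_fit),
                    "converged": bool(self.converged),
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "RatioModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


def make_ratio_model(mean: float, sd: float, n_fit: int = 0) -> RatioModel:
    """Build a RatioModel directly from Gaussian parameters (threshold = mean - sd)."""
    return RatioModel(mean=float(mean), sd=float(sd), threshold=float(mean) - float(sd), n_fit=n_fit)


def red_green_ratio(mean_red: float, mean_green: float, convention: str = RATIO_EXCESS) -> float:
    """Normalized red/green ratio of one detection's background-subtracted means.

    Returns +inf (kept as unambiguously red) when green is at the noise
    floor but red is not; raises for a detection dead in both channels.
    """
    r, g = float(mean_red), float(mean_green)
    if g <= EPS and r <= EPS:
        raise ParameterError("ratio undefined: both channels at or below the noise floor")
    if convention == RATIO_EXCESS:
        if g <= EPS:
            return float("inf")
        return (r - g) / g
    if convention == RATIO_SYMMETRIC:
        return (r - g) / (r + g)
    raise ParameterError(f"unknown ratio convention {convention!r}")


def ratios_of(dets: DetectionSet, convention: str = RATIO_EXCESS) -> np.ndarray:
    """Vectorized ratios for a DetectionSet; both-dead detections map to NaN (flagged)."""
    r = dets.df["mean_red"].to_numpy(dtype=float)
    g = dets.df["mean_green"].to_numpy(dtype=float)
    out = np.full(len(r), np.nan)
    dead = (g <= EPS) & (r <= EPS)
    if dead.any():
        log.warning("%d detections dead in both channels; ratio flagged NaN", int(dead.sum()))
    if convention == RATIO_EXCESS:
        ok = (g > EPS) & ~dead
        out[ok] = (r[ok] - g[ok]) / g[ok]
        out[(g <= EPS) & (r > EPS)] = np.inf
    elif convention == RATIO_SYMMETRIC:
        ok = ~dead
        out[ok] = (r[ok] - g[ok]) / (r[ok] + g[ok])
    else:
        raise ParameterError(f"unknown ratio convention {convention!r}")
    return out


def _freedman_diaconis_bins(x: np.ndarray) -> np.ndarray:
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    width = 2.0 * iqr * len(x) ** (-1.0 / 3.0)
    if width <= 0:
        raise FitError("degenerate ratio distribution (zero IQR); cannot histogram")
    n_bins = max(int(np.ceil((x.max() - x.min()) / width)), 4)
    return np.linspace(x.min(), x.max(), n_bins + 1)


def fit_ratio_gaussian(ratios) -> RatioModel:
    """Fit a Gaussian to the frequency distribution of finite ratios.

    Histograms with Freedman-Diaconis bin width, then least-squares fits
    a * exp(-(x - mu)^2 / (2 sigma^2)) to the bin counts.  Falls back to the
    sample mean/SD (with a logged warning) if the curve fit fails.
    """
    x = np.asarray(ratios, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 20:
        raise FitError(f"need >= 20 finite ratios to fit, got {len(x)}")
    if np.ptp(x) <= 0:
        raise FitError("all ratios identical; Gaussian fit undefined")
    edges = _freedman_diaconis_bins(x)
    counts, edges = np.histogram(x, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])

    def gauss(z, a, mu, sigma):
        return a * np.exp(-((z - mu) ** 2) / (2.0 * sigma**2))

    p0 = (counts.max(), float(x.mean()), float(x.std()) or 1.0)
    converged = True
    try:
        popt, _ = curve_fit(gauss, mids, counts, p0=p0, maxfev=10000)
        mu, sigma = float(popt[1]), abs(float(popt[2]))
        if sigma <= 0 or not np.isfinite(mu) or not np.isfinite(sigma):
            raise RuntimeError("non-finite fit")
    except RuntimeError:
        log.warning("Gaussian histogram fit failed; falling back to sample mean/SD")
        mu, sigma = float(x.mean()), float(x.std(ddof=1))
        converged = False
    if sigma <= 0:
        raise FitError("fitted sigma is zero; degenerate ratio distribution")
    return RatioModel(mean=mu, sd=sigma, threshold=mu - sigma, n_fit=len(x), converged=converged)


def apply_ratio_filter(
    dets: DetectionSet, model: RatioModel | float, convention: str = RATIO_EXCESS
) -> tuple[DetectionSet, DetectionSet]:
    """Partition red detections into (kept, eliminated) by the ratio threshold.

    Strictly-below-threshold detections are eliminated, so a detection at
    exactly the printed boundary value survives.  NaN ratios (dead in both
    channels) cannot be judged and are kept.  The partition is exact.
    """
    threshold = model.threshold if isinstance(model, RatioModel) else float(model)
    if dets.empty:
        return DetectionSet(), DetectionSet()
    ratios = ratios_of(dets, convention)
    eliminate = ratios < threshold  # NaN compares False -> kept
    return dets.subset(~eliminate), dets.subset(eliminate)
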