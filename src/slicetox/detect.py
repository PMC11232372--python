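"""Cell detection on depth-sectioned MIPs.

Each background-subtracted MIP is thresholded at five times its background
SD, binarized, and segmented into particles.  Particles are kept if their
area and circularity fall inside the published windows (PI+ cells
10-100 um^2, GCaMP-filled neurons 20-200 um^2, circularity 0.5-1 for both)
and stamped with the MIP's midpoint depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .errors import InputError, ParameterError
from .prep import GREEN, RED, Projection

log = logging.getLogger(__name__)

DETECTION_COLUMNS = [
    "det_id",
    "channel",
    "mip_index",
    "z_um",
    "x_um",
    "y_um",
    "area_um2",
    "circularity",
    "mean_green",
    "mean_red",
]


@dataclass
class FilterSpec:
    """Particle acceptance window: area in um^2, circularity dimensionless."""

    size_min: float
    size_max: float
    circ_min: float = 0.5
    circ_max: float = 1.0

    def __post_init__(self):
        if not self.size_min < self.size_max:
            raise ParameterError("size_min must be < size_max")
        if not 0.0 <= self.circ_min <= self.circ_max <= 1.0:
            raise ParameterError("need 0 <= circ_min <= circ_max <= 1")


# Published windows; sizes are areas (the particle analyzer's size filter).
PI_FILTER = FilterSpec(10.0, 100.0, 0.5, 1.0)
FILLED_FILTER = FilterSpec(20.0, 200.0, 0.5, 1.0)


class DetectionSet:
    """A collection of segmented particles, backed by a DataFrame."""

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=DETECTION_COLUMNS)
        missing = set(DETECTION_COLUMNS) - set(df.columns)
        if missing:
            raise InputError(f"detection table missing columns: {sorted(missing)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"DetectionSet({len(self)} detections)"

    @property
    def empty(self) -> bool:
        return len(self) == 0

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, columns=DETECTION_COLUMNS)

    @classmethod
    def from_csv(cls, path) -> "DetectionSet":
        return cls(pd.read_csv(path))

    def subset(self, mask) -> "DetectionSet":
        return DetectionSet(self.df.loc[mask].reset_index(drop=True))

    def concat(self, other: "DetectionSet") -> "DetectionSet":
        return DetectionSet(pd.concat([self.df, other.df], ignore_index=True))


def threshold_mask(mip: Projection, bg_sd: float, k: float = 5.0) -> np.ndarray:
    """Binary mask of pixels strictly above k times the background SD.

    The MIP is assumed background-subtracted, so the threshold sits at
    ``k * bg_sd`` above zero.
    """
    if k <= 0:
        raise ParameterError("threshold multiplier k must be > 0")
    if bg_sd < 0:
        raise ParameterError("bg_sd must be >= 0")
    return np.asarray(mip.image) > k * bg_sd


def _component_props(mask: np.ndarray, pixel_size: float):
    labels = measure.label(mask, connectivity=2)
    return labels, measure.regionprops(labels)


def segment_particles(
    mask: np.ndarray,
    spec: FilterSpec,
    pixel_size: float,
    intensity_images: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Label 8-connected components and keep those passing the size/circularity filter.

    Area is pixel count times pixel_size^2; the perimeter uses the Crofton
    approximation (as in the particle analyzer this mirrors), and
    circularity 4*pi*A/P^2 is clipped at 1, where discretization can push it
    above.  Centroids are intensity-unweighted, in um.  Bounds are
    inclusive.  ``intensity_images`` maps channel name -> image for in-mask
    mean measurements.
    """
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be > 0")
    mask = np.asarray(mask, dtype=bool)
    labels, props = _component_props(mask, pixel_size)
    rows = []
    for p in props:
        area_px = p.area
        area = float(area_px) * pixel_size**2
        perim = p.perimeter_crofton
        circ = 1.0 if perim <= 0 else min(1.0, 4.0 * np.pi * area_px / perim**2)
        if not (spec.size_min <= area <= spec.size_max):
            continue
        if not (spec.circ_min <= circ <= spec.circ_max):
            continue
        cy, cx = p.centroid  # row, col in pixel index units
        means = {}
        if intensity_images:
            region_mask = labels == p.label
            for name, img in intensity_images.items():
                means[name] = float(np.asarray(img)[region_mask].mean())
        rows.append(
            {
                "x_um": (cx + 0.5) * pixel_size,
                "y_um": (cy + 0.5) * pixel_size,
                "area_um2": area,
                "circularity": circ,
                "mean_green": means.get(GREEN, np.nan),
                "mean_red": means.get(RED, np.nan),
            }
        )
    return pd.DataFrame(rows, columns=["x_um", "y_um", "area_um2", "circularity", "mean_green", "mean_red"])


def detect_channel(
    detect_mips: Sequence[Projection],
    bg_sds: Sequence[float],
    spec: FilterSpec,
    measure_mips: dict[str, Sequence[Projection]],
    channel: str,
    k: float = 5.0,
    dedup_radius: float | None = 10.0,
) -> DetectionSet:
    """Threshold and segment every MIP of one channel.

    ``measure_mips`` supplies the co-registered, preprocessed MIP sequences
    (per channel) on which mean_green / mean_red are measured within each
    particle mask.  Detections are stamped with the MIP midpoint depth.
    ``dedup_radius`` collapses same-cell detections repeated in adjacent
    MIPs (a soma straddling a group boundary) onto the brightest one.
    """
    n = len(detect_mips)
    if len(bg_sds) != n:
        raise InputError("bg_sds length must match number of MIPs")
    for name, seq in measure_mips.items():
        if len(seq) != n:
            raise InputError(f"measurement MIPs for {name!r} do not match detection MIPs")
        for a, b in zip(seq, detect_mips):
            if a.image.shape != b.image.shape:
                raise InputError(f"MIP geometry mismatch between {name!r} and detection channel")

    frames = []
    for i, mip in enumerate(detect_mips):
        mask = threshold_mask(mip, bg_sds[i], k=k)
        imgs = {name: seq[i].image for name, seq in measure_mips.items()}
        df = segment_particles(mask, spec, mip.pixel_size, intensity_images=imgs)
        df["mip_index"] = mip.mip_index
        df["z_um"] = mip.z_mid
        if len(df):
            frames.append(df)
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["x_um", "y_um", "area_um2", "circularity", "mean_green", "mean_red", "mip_index", "z_um"])
    df["channel"] = channel
    df["det_id"] = np.arange(len(df))
    dets = DetectionSet(df[DETECTION_COLUMNS])
    if dedup_radius is not None and len(dets) > 1:
        dets = dedup_adjacent(dets, radius=dedup_radius, max_mip_gap=1)
    return dets


def dedup_adjacent(dets: DetectionSet, radius: float = 10.0, max_mip_gap: int = 1) -> DetectionSet:
    """Collapse detections of the same cell appearing in adjacent MIPs.

    Sorted by in-channel brightness (descending), a detection suppresses any
    later detection within ``radius`` um in-plane and ``max_mip_gap`` MIPs
    in depth.
    """
    df = dets.df
    bright = np.where(df["channel"] == RED, df["mean_red"], df["mean_green"]).astype(float)
    order = np.argsort(-bright, kind="stable")
    keep = np.ones(len(df), dtype=bool)
    xs = df["x_um"].to_numpy()
    ys = df["y_um"].to_numpy()
    mi = df["mip_index"].to_numpy()
    taken: list[int] = []
    for idx in order:
        ok = True
        for j in taken:
            if abs(mi[idx] - mi[j]) <= max_mip_gap and (xs[idx] - xs[j]) ** 2 + (ys[idx] - ys[j]) ** 2 <= radius**2:
                ok = False
                break
        if ok:
            taken.append(idx)
        else:
            keep[idx] = False
    dropped = int((~keep).sum())
    if dropped:
        log.info("deduplicated %d cross-MIP detections", dropped)
    return dets.subset(keep)


def detect_stack(
    green_mips: Sequence[Projection],
    red_mips: Sequence[Projection],
    green_bg_sds: Sequence[float],
    red_bg_sds: Sequence[float],
    specs: dict[str, FilterSpec] | None = None,
    k: float = 5.0,
    dedup_radius: float | None = 10.0,
) -> dict[str, DetectionSet]:
    """Detect GCaMP-filled cells on the green MIPs and PI+ cells on the red MIPs."""
    specs = specs or {GREEN: FILLED_FILTER, RED: PI_FILTER}
    if len(green_mips) != len(red_mips):
        raise InputError("green and red MIP sequences differ in length")
    measure_mips = {GREEN: green_mips, RED: red_mips}
    return {
        GREEN: detect_channel(green_mips, green_bg_sds, specs[GREEN], measure_mips, GREEN, k, dedup_radius),
        RED: detect_channel(red_mips, red_bg_sds, specs[RED], measure_mips, RED, k, dedup_radius),
    }


def match_to_truth(dets: DetectionSet, truth: pd.DataFrame, radius: float) -> dict:
    """Score detections against a ground-truth table by greedy nearest matching.

    Returns a dict with tp/fp/fn counts, precision, recall, and the mean
    planar centroid error of matched pairs (um).
    """
    det_xy = dets.df[["x_um", "y_um"]].to_numpy(dtype=float)
    tru_xy = truth[["x_um", "y_um"]].to_numpy(dtype=float)
    pairs = []
    for i in range(len(det_xy)):
        d = np.hypot(tru_xy[:, 0] - det_xy[i, 0], tru_xy[:, 1] - det_xy[i, 1]) if len(tru_xy) else np.empty(0)
        for j in np.flatnonzero(d <= radius):
            pairs.append((float(d[j]), i, int(j)))
    pairs.sort()
    used_d: set = set()
    used_t: set = set()
    errs = []
    for dist, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        errs.append(dist)
    tp = len(used_d)
    fp = len(det_xy) - tp
    fn = len(tru_xy) - tp
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": tp / len(det_xy) if len(det_xy) else float("nan"),
        "recall": tp / len(tru_xy) if len(tru_xy) else float("nan"),
        "mean_centroid_error_um": float(np.mean(errs)) if errs else float("nan"),
    }
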