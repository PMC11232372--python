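"""Ca2+ time-series analysis.

Somatic fluorescence is measured in circular ROIs, local neuropil in
concentric annuli (excluding all somata), and the neuropil-subtracted trace
is normalized as dF/F0 = (F_t - F0) / F0 with F0 the average baseline
fluorescence.  Transients are detected as peaks above a robust
(median + k * 1.4826*MAD) threshold and summarized per event by amplitude,
trapezoidal AUC, and FWHM.  GCaMP-filled neurons are classified by tonically
high fluorescence together with a complete absence of transients.  A 4x4
grid partition relates local neuropil Ca2+ load to local cell death.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.signal import find_peaks

from .detect import DetectionSet
from .errors import InputError, ParameterError
from .prep import Projection
from .synthetic import Movie

log = logging.getLogger(__name__)


@dataclass
class RoiPair:
    """A somatic disc plus its concentric neuropil annulus (all in um).

    The annulus spans (soma radius + gap, outer_radius) and excludes pixels
    belonging to any soma in the field.
    """

    roi_id: int
    x: float
    y: float
    radius: float
    gap: float = 1.2
    outer_radius: float | None = None

    def __post_init__(self):
        if self.outer_radius is None:
            self.outer_radius = 2.0 * self.radius
        if self.radius <= 0 or self.outer_radius <= self.radius + self.gap:
            raise ParameterError("need 0 < radius and outer_radius > radius + gap")


@dataclass
class Trace:
    """A neuropil-subtracted somatic fluorescence trace and its dF/F0."""

    roi_id: int
    f: np.ndarray
    frame_rate: float
    f0: float
    dff: np.ndarray | None
    median_raw_f: float = float("nan")

    @property
    def duration(self) -> float:
        return len(self.f) / self.frame_rate

    def times(self) -> np.ndarray:
        return np.arange(len(self.f)) / self.frame_rate


@dataclass
class TransientMetrics:
    """Per-ROI (or per-field) Ca2+ transient statistics."""

    roi_id: int
    n_events: int
    frequency: float  # events / min
    mean_amplitude: float  # dF/F0
    mean_auc: float  # dF/F0 * s
    mean_fwhm: float  # s
    event_times: np.ndarray


def rois_from_table(rois: pd.DataFrame, gap: float = 1.2, outer_factor: float = 2.0) -> list[RoiPair]:
    """Build RoiPairs from a table with roi_id, x_um, y_um, radius_um columns."""
    return [
        RoiPair(
            roi_id=int(r.roi_id),
            x=float(r.x_um),
            y=float(r.y_um),
            radius=float(r.radius_um),
            gap=gap,
            outer_radius=outer_factor * float(r.radius_um),
        )
        for r in rois.itertuples()
    ]


def _coordinate_grids(ny: int, nx: int, pixel_size: float):
    yy = (np.arange(ny) + 0.5) * pixel_size
    xx = (np.arange(nx) + 0.5) * pixel_size
    return yy[:, None], xx[None, :]


def extract_traces(
    movie: Movie,
    rois: list[RoiPair],
    baseline: str | tuple[float, float] = "lower_quartile",
) -> list[Trace]:
    """Per-frame soma-minus-annulus traces with dF/F0 normalization.

    ``baseline`` is either "lower_quartile" (F0 = mean of the frames whose
    trace value lies in the lowest quartile) or an explicit (t0, t1) window
    in seconds.  ROIs whose annulus is empty after excluding other somata
    are dropped with a warning.  dF/F0 is left undefined (None) when
    F0 <= 0.
    """
    T, ny, nx = movie.frames.shape
    yy, xx = _coordinate_grids(ny, nx, movie.pixel_size)
    soma_union = np.zeros((ny, nx), dtype=bool)
    soma_masks = {}
    for roi in rois:
        m = (yy - roi.y) ** 2 + (xx - roi.x) ** 2 <= roi.radius**2
        soma_masks[roi.roi_id] = m
        soma_union |= m

    flat = movie.frames.reshape(T, -1)
    traces: list[Trace] = []
    for roi in rois:
        soma = soma_masks[roi.roi_id]
        if not soma.any():
            warnings.warn(f"ROI {roi.roi_id}: empty soma mask; dropped")
            continue
        d2 = (yy - roi.y) ** 2 + (xx - roi.x) ** 2
        annulus = (d2 > (roi.radius + roi.gap) ** 2) & (d2 <= roi.outer_radius**2) & ~soma_union
        if not annulus.any():
            warnings.warn(f"ROI {roi.roi_id}: annulus empty after soma exclusion; dropped")
            continue
        soma_f = flat[:, soma.ravel()].mean(axis=1)
        neuropil_f = flat[:, annulus.ravel()].mean(axis=1)
        f = soma_f - neuropil_f
        if baseline == "lower_quartile":
            q = np.quantile(f, 0.25)
            base = f[f <= q]
        else:
            t0, t1 = baseline
            idx = (np.arange(T) / movie.frame_rate >= t0) & (np.arange(T) / movie.frame_rate < t1)
            if not idx.any():
                raise ParameterError("baseline window contains no frames")
            base = f[idx]
        f0 = float(base.mean())
        dff = (f - f0) / f0 if f0 > 0 else None
        if dff is None:
            warnings.warn(f"ROI {roi.roi_id}: F0 <= 0; dF/F0 undefined")
        traces.append(
            Trace(
                roi_id=roi.roi_id,
                f=f,
                frame_rate=movie.frame_rate,
                f0=f0,
                dff=dff,
                median_raw_f=float(np.median(soma_f)),
            )
        )
    return traces


def _event_bounds(dff: np.ndarray, peak: int, level: float) -> tuple[int, int]:
    """Indices of the first samples at or below ``level`` on each side of ``peak``."""
    left = peak
    while left > 0 and dff[left - 1] > level:
        left -= 1
    right = peak
    n = len(dff)
    while right < n - 1 and dff[right + 1] > level:
        right += 1
    return left, right


def _interp_crossing(t: np.ndarray, y: np.ndarray, i_out: int, i_in: int, level: float) -> float:
    """Linear-interpolated time where y crosses ``level`` between two samples."""
    y0, y1 = y[i_out], y[i_in]
    if y1 == y0:
        return float(t[i_in])
    frac = (level - y0) / (y1 - y0)
    return float(t[i_out] + frac * (t[i_in] - t[i_out]))


def detect_transients(
    trace: Trace, k_sd: float = 3.0, min_sep: float = 2.0, min_amp: float = 0.05
) -> TransientMetrics:
    """Detect Ca2+ transients on a dF/F0 trace and compute per-event metrics.

    Baseline is the trace median; noise is 1.4826 * MAD.  Events are local
    maxima above baseline + max(k_sd * noise, min_amp), separated by at
    least ``min_sep`` seconds; ``min_amp`` (dF/F0) is an absolute amplitude
    floor so that on a quiescent, low-noise trace shot-noise ripple crossing
    its own tiny MAD threshold is not called a transient.  Amplitude is peak
    minus baseline; AUC is the trapezoidal integral of (dF/F0 - baseline)
    between the baseline crossings flanking the peak; FWHM is the width at
    half amplitude, linearly interpolated.
    """
    if trace.frame_rate <= 0:
        raise ParameterError("frame_rate must be > 0")
    if trace.duration < 30.0:
        raise InputError("transient detection requires >= 30 s of data")
    if trace.dff is None:
        raise InputError("trace has no defined dF/F0")
    dff = np.asarray(trace.dff, dtype=float)
    t = trace.times()
    baseline = float(np.median(dff))
    noise = 1.4826 * float(np.median(np.abs(dff - baseline)))
    height = baseline + max(k_sd * noise, min_amp, 1e-12)
    distance = max(1, int(round(min_sep * trace.frame_rate)))
    peaks, _ = find_peaks(dff, height=height, distance=distance)

    amps, aucs, fwhms = [], [], []
    for p in peaks:
        amp = float(dff[p] - baseline)
        l, r = _event_bounds(dff, p, baseline)
        seg = dff[l : r + 1] - baseline
        aucs.append(float(np.trapezoid(seg, dx=1.0 / trace.frame_rate)))
        half = baseline + amp / 2.0
        hl, hr = _event_bounds(dff, p, half)
        t_left = _interp_crossing(t, dff, hl - 1, hl, half) if hl > 0 and dff[hl - 1] <= half else float(t[hl])
        t_right = _interp_crossing(t, dff, hr + 1, hr, half) if hr < len(dff) - 1 and dff[hr + 1] <= half else float(t[hr])
        fwhms.append(t_right - t_left)
        amps.append(amp)

    n = len(peaks)
    duration_min = trace.duration / 60.0
    return TransientMetrics(
        roi_id=trace.roi_id,
        n_events=n,
        frequency=n / duration_min,
        mean_amplitude=float(np.mean(amps)) if n else float("nan"),
        mean_auc=float(np.mean(aucs)) if n else float("nan"),
        mean_fwhm=float(np.mean(fwhms)) if n else float("nan"),
        event_times=t[peaks],
    )


def classify_filled(
    traces: list[Trace], metrics: list[TransientMetrics], f_percentile: float = 90.0
) -> dict[int, bool]:
    """Flag GCaMP-filled neurons: tonically bright AND zero transients.

    The brightness threshold is the ``f_percentile`` of median raw
    fluorescence over the ROIs that do fire transients (the active
    reference population; all ROIs when none fire).  A bright ROI that
    fires events is never flagged.
    """
    if len(traces) < 5:
        raise ParameterError("need >= 5 ROIs for a meaningful percentile")
    by_id = {m.roi_id: m for m in metrics}
    med = {tr.roi_id: tr.median_raw_f for tr in traces}
    active = [med[tr.roi_id] for tr in traces if by_id[tr.roi_id].n_events > 0]
    reference = active if active else list(med.values())
    thr = float(np.percentile(reference, f_percentile))
    return {tr.roi_id: (med[tr.roi_id] > thr and by_id[tr.roi_id].n_events == 0) for tr in traces}


@dataclass
class GridCell:
    """One tile of the 4x4 partition of a MIP."""

    row: int
    col: int
    median_neuropil: float
    n_pi: int
    median_neuropil_norm: float = float("nan")
    n_pi_norm: float = float("nan")
    excluded: bool = False


def grid_stats(
    mip: Projection,
    pi_dets: DetectionSet,
    soma_mask: np.ndarray | None = None,
    n_tiles: int = 4,
) -> list[GridCell]:
    """Per-tile median neuropil intensity and PI+ centroid count on a 4x4 grid.

    Tiles partition the MIP exactly (half-open pixel/um bounds, so a
    centroid on a shared tile boundary is counted exactly once).  Medians
    exclude soma pixels.  Tiles with zero PI+ cells are flagged excluded
    (they are removed from downstream correlations).  Counts are normalized
    to the field total and medians to the field maximum.
    """
    img = np.asarray(mip.image, dtype=float)
    ny, nx = img.shape
    ps = mip.pixel_size
    row_edges = np.linspace(0, ny, n_tiles + 1).astype(int)
    col_edges = np.linspace(0, nx, n_tiles + 1).astype(int)
    x = pi_dets.df["x_um"].to_numpy(dtype=float)
    y = pi_dets.df["y_um"].to_numpy(dtype=float)

    cells = []
    for r in range(n_tiles):
        for c in range(n_tiles):
            r0, r1 = row_edges[r], row_edges[r + 1]
            c0, c1 = col_edges[c], col_edges[c + 1]
            tile = img[r0:r1, c0:c1]
            if soma_mask is not None:
                keep = ~np.asarray(soma_mask, dtype=bool)[r0:r1, c0:c1]
                vals = tile[keep]
            else:
                vals = tile.ravel()
            med = float(np.median(vals)) if vals.size else float("nan")
            in_tile = (y >= r0 * ps) & (y < r1 * ps) & (x >= c0 * ps) & (x < c1 * ps)
            n_pi = int(in_tile.sum())
            cells.append(GridCell(row=r, col=c, median_neuropil=med, n_pi=n_pi, excluded=(n_pi == 0)))

    total = sum(cell.n_pi for cell in cells)
    max_med = max((cell.median_neuropil for cell in cells if np.isfinite(cell.median_neuropil)), default=np.nan)
    for cell in cells:
        cell.n_pi_norm = cell.n_pi / total if total > 0 else float("nan")
        cell.median_neuropil_norm = cell.median_neuropil / max_med if max_med and max_med > 0 else float("nan")
    return cells


def grid_to_frame(cells: list[GridCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.row, c.col, c.median_neuropil_norm, c.n_pi_norm, c.excluded) for c in cells],
        columns=["row", "col", "median_neuropil_norm", "n_pi_norm", "excluded"],
    )


def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    """Spearman (average ranks) or Pearson correlation with a two-sided p value.

    Zero variance in either input is undefined: returns (nan, nan) with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("correlate needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance input; correlation undefined")
        return float("nan"), float("nan")
    if method == "spearman":
        res = sstats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "pearson":
        res = sstats.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)
    raise ParameterError(f"unknown correlation method {method!r}")


def metrics_to_frame(metrics: list[TransientMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (m.roi_id, m.n_events, m.frequency, m.mean_amplitude, m.mean_auc, m.mean_fwhm)
            for m in metrics
        ],
        columns=["roi_id", "n_events", "frequency_per_min", "mean_amplitude", "mean_auc", "mean_fwhm_s"],
    )


def field_trace(traces: list[Trace]) -> Trace:
    """Whole-field trace: mean of the per-ROI dF/F0 traces (for field-level metrics)."""
    usable = [tr for tr in traces if tr.dff is not None]
    if not usable:
        raise InputError("no traces with defined dF/F0")
    n = min(len(tr.dff) for tr in usable)
    dff = np.mean([tr.dff[:n] for tr in usable], axis=0)
    f = np.mean([tr.f[:n] for tr in usable], axis=0)
    return Trace(roi_id=-1, f=f, frame_rate=usable[0].frame_rate, f0=1.0, dff=dff)
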