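"""Synthetic two-photon acquisitions with known ground truth.

Emulates the statistical structure of dual-channel z-stacks of acute
neonatal brain slices: PI+ (dead) cells and GCaMP-filled (Ca2+-overloaded)
neurons rendered as 3-D Gaussian somata whose density decays exponentially
with depth below the cut surface, a diffuse neuropil background with its own
exponential depth decay, green-to-red spectral bleed-through, and additive
Gaussian read noise.  Also generates single-field time-series movies with
synchronous Ca2+ transients and non-participating "filled" ROIs.

Every generated object comes with a ground-truth table so downstream
detection, colocalization and profiling stages can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import GenerationError, ParameterError
from .prep import GREEN, RED, VolumeStack

TRUTH_COLUMNS = ["cell_id", "class", "x_um", "y_um", "z_um", "radius_um", "peak_green", "peak_red"]

CLASS_PI = "pi"
CLASS_FILLED = "filled"
CLASS_COLOC = "coloc"
CLASS_HEALTHY = "healthy"


@dataclass
class SynthStackConfig:
    """Parameters of one synthetic dual-channel z-stack.

    Intensity units are arbitrary; geometry is um.  ``bleedthrough`` is the
    fraction of the green signal added to the red channel before noise
    (default 0.5: at the Ca2+-imaging excitation wavelength roughly half of
    the PI-channel signal is green crosstalk).  ``frac_coloc`` is the
    fraction of GCaMP-filled neurons that are additionally PI+.
    """

    nx: int = 512
    ny: int = 512
    pixel_size: float = 1.2
    z_max: float = 300.0
    z_step: float = 3.0
    n_pi: int = 60
    n_filled: int = 40
    n_healthy: int = 30
    frac_coloc: float = 0.3
    tau_pi: float = 41.0
    tau_filled: float = 65.0
    tau_neuropil: float = 131.0
    cell_radius: float = 5.0
    soma_peak: float = 60.0
    pi_peak: float = 150.0
    filled_peak: float = 180.0
    neuropil_base: float = 40.0
    bleedthrough: float = 0.5
    noise_sd: float = 4.0
    depth_attenuation: float | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pi, self.n_filled, self.n_healthy) < 0:
            raise ParameterError("cell counts must be >= 0")
        if min(self.tau_pi, self.tau_filled, self.tau_neuropil) <= 0:
            raise ParameterError("decay constants tau must be > 0")
        if not 0.0 <= self.frac_coloc <= 1.0:
            raise ParameterError("frac_coloc must be in [0, 1]")
        if not 0.0 <= self.bleedthrough <= 1.0:
            raise ParameterError("bleedthrough must be in [0, 1]")
        if self.pixel_size <= 0 or self.z_step <= 0 or self.z_max <= 0:
            raise ParameterError("pixel_size, z_step and z_max must be > 0")
        n_planes = self.z_max / self.z_step
        if abs(n_planes - round(n_planes)) > 1e-9:
            raise ParameterError("z_max must be an integer multiple of z_step")
        if self.cell_radius <= 0:
            raise ParameterError("cell_radius must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def n_planes(self) -> int:
        return round(self.z_max / self.z_step)

    @property
    def n_coloc(self) -> int:
        return int(np.floor(self.frac_coloc * self.n_filled))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SynthStackConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SynthMovieConfig:
    """Parameters of one synthetic Ca2+-imaging movie.

    Non-filled ROIs share synchronous transients at Poisson event times
    (``event_rate`` per minute), each a Gaussian bump of width
    ``event_sigma`` seconds and amplitude ``event_amp_dff`` in dF/F0 units
    on a baseline of ``baseline_f``.  Filled ROIs sit tonically at
    ``filled_f`` with no events.
    """

    n_rois: int = 40
    duration: float = 300.0
    frame_rate: float = 2.67
    event_rate: float = 2.0
    event_amp_dff: float = 1.0
    event_sigma: float = 1.5
    n_filled: int = 5
    baseline_f: float = 100.0
    filled_f: float = 400.0
    noise_sd: float = 2.0
    seed: int = 0
    nx: int = 160
    ny: int = 160
    pixel_size: float = 1.2
    roi_radius: float = 6.0

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be > 0")
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        if self.duration < 1.0 / self.frame_rate:
            raise ParameterError("duration shorter than one frame")
        if self.n_filled > self.n_rois:
            raise ParameterError("n_filled must be <= n_rois")
        if min(self.n_rois, self.n_filled) < 0:
            raise ParameterError("counts must be >= 0")
        if self.event_rate < 0 or self.event_amp_dff < 0 or self.noise_sd < 0:
            raise ParameterError("rates, amplitudes and noise must be >= 0")
        if self.event_sigma <= 0:
            raise ParameterError("event_sigma must be > 0")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration * self.frame_rate))


@dataclass
class Movie:
    """A single-channel time series, shape (t, y, x)."""

    frames: np.ndarray
    frame_rate: float
    pixel_size: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class MovieTruth:
    """Ground truth of a synthetic movie: ROI geometry, filled flags, event times."""

    rois: pd.DataFrame  # roi_id, x_um, y_um, radius_um, filled
    event_times: np.ndarray  # shared synchronous event times (s)

    def events_for(self, roi_id: int) -> np.ndarray:
        if bool(self.rois.loc[self.rois.roi_id == roi_id, "filled"].iloc[0]):
            return np.empty(0)
        return self.event_times


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_depths(n: int, tau: float, z_max: float, rng) -> np.ndarray:
    """Draw ``n`` depths from the exponential density ~ exp(-z/tau) truncated to [0, z_max].

    Uses inverse-CDF sampling, so results are deterministic given the seed.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    if tau <= 0 or z_max <= 0:
        raise ParameterError("tau and z_max must be > 0")
    rng = _as_rng(rng)
    if n == 0:
        return np.empty(0)
    u = rng.random(n)
    # F(z) = (1 - exp(-z/tau)) / (1 - exp(-z_max/tau)); invert via expm1 for
    # numerical stability at large tau (uniform limit).
    c = -np.expm1(-z_max / tau)
    return -tau * np.log1p(-u * c)


def truncated_exp_mle(depths: np.ndarray, z_max: float, tol: float = 1e-10) -> float:
    """Maximum-likelihood tau for depths from a truncated exponential on [0, z_max].

    Solves the score equation mean(z) = tau - z_max/(exp(z_max/tau) - 1) by
    bisection; independent cross-check for the generator's depth law.
    """
    from scipy.optimize import brentq

    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ParameterError("need at least one depth")
    zbar = float(depths.mean())
    if not 0 < zbar < z_max:
        raise ParameterError("sample mean outside (0, z_max)")

    def score(tau):
        x = z_max / tau
        with np.errstate(over="ignore"):
            return tau - z_max / np.expm1(x) - zbar

    lo, hi = 1e-6, 1e12
    return float(brentq(score, lo, hi, xtol=tol))


def _place_xy(n: int, cfg: SynthStackConfig, rng: np.random.Generator, taken: list, label: str) -> np.ndarray:
    """Rejection-sample xy centers (um) keeping all cells separated and off the border."""
    sigma = cfg.cell_radius / 2.0
    margin = 3.0 * sigma + 2.0 * cfg.pixel_size
    min_sep = max(3.0 * cfg.cell_radius + 2.0, 12.0)
    width = cfg.nx * cfg.pixel_size
    height = cfg.ny * cfg.pixel_size
    if width - 2 * margin <= 0 or height - 2 * margin <= 0:
        raise GenerationError(f"field too small to place {label} cells")
    out = []
    budget = 2000 * max(n, 1)
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > budget:
            raise GenerationError(
                f"could not place {n} {label} cells with separation {min_sep:.1f} um "
                f"in a {width:.0f}x{height:.0f} um field"
            )
        x = margin + rng.random() * (width - 2 * margin)
        y = margin + rng.random() * (height - 2 * margin)
        ok = True
        for (px, py) in taken:
            if (px - x) ** 2 + (py - y) ** 2 < min_sep**2:
                ok = False
                break
        if ok:
            out.append((x, y))
            taken.append((x, y))
    return np.array(out).reshape(n, 2)


def _render_blob(vol: np.ndarray, cfg: SynthStackConfig, x: float, y: float, z: float, peak: float) -> None:
    """Add an isotropic 3-D Gaussian soma (sigma = radius/2, truncated at 3 sigma)."""
    sigma = cfg.cell_radius / 2.0
    cut = 3.0 * sigma
    ps, zs = cfg.pixel_size, cfg.z_step
    # Pixel centers are at (i + 0.5) * pixel_size; planes at k * z_step.
    x0 = max(int(np.floor((x - cut) / ps - 0.5)), 0)
    x1 = min(int(np.ceil((x + cut) / ps - 0.5)) + 1, vol.shape[2])
    y0 = max(int(np.floor((y - cut) / ps - 0.5)), 0)
    y1 = min(int(np.ceil((y + cut) / ps - 0.5)) + 1, vol.shape[1])
    k0 = max(int(np.floor((z - cut) / zs)), 0)
    k1 = min(int(np.ceil((z + cut) / zs)) + 1, vol.shape[0])
    if x1 <= x0 or y1 <= y0 or k1 <= k0:
        return
    xs = (np.arange(x0, x1) + 0.5) * ps - x
    ys = (np.arange(y0, y1) + 0.5) * ps - y
    zs_ = np.arange(k0, k1) * zs - z
    d2 = zs_[:, None, None] ** 2 + ys[None, :, None] ** 2 + xs[None, None, :] ** 2
    blob = peak * np.exp(-d2 / (2.0 * sigma**2))
    blob[d2 > cut**2] = 0.0
    vol[k0:k1, y0:y1, x0:x1] += blob


def generate_stack(config: SynthStackConfig) -> tuple[VolumeStack, VolumeStack, pd.DataFrame]:
    """Render the dual-channel stack and its ground-truth table.

    The red channel receives ``bleedthrough`` times the (noise-free) green
    channel before its own read noise, mimicking spectral crosstalk; it has
    no neuropil source of its own.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_coloc = cfg.n_coloc

    z_pi = sample_depths(cfg.n_pi, cfg.tau_pi, cfg.z_max, rng)
    z_filled = sample_depths(cfg.n_filled, cfg.tau_filled, cfg.z_max, rng)
    z_healthy = rng.random(cfg.n_healthy) * cfg.z_max

    taken: list = []
    xy_pi = _place_xy(cfg.n_pi, cfg, rng, taken, CLASS_PI)
    xy_filled = _place_xy(cfg.n_filled, cfg, rng, taken, CLASS_FILLED)
    xy_healthy = _place_xy(cfg.n_healthy, cfg, rng, taken, CLASS_HEALTHY)

    green = np.zeros((cfg.n_planes, cfg.ny, cfg.nx), dtype=np.float64)
    red = np.zeros_like(green)

    # Diffuse neuropil: green only, exponential depth decay, spatially flat.
    plane_z = np.arange(cfg.n_planes) * cfg.z_step
    green += (cfg.neuropil_base * np.exp(-plane_z / cfg.tau_neuropil))[:, None, None]

    rows = []
    cid = 0
    for i in range(cfg.n_pi):
        _render_blob(red, cfg, xy_pi[i, 0], xy_pi[i, 1], z_pi[i], cfg.pi_peak)
        rows.append((cid, CLASS_PI, xy_pi[i, 0], xy_pi[i, 1], z_pi[i], cfg.cell_radius, 0.0, cfg.pi_peak))
        cid += 1
    for i in range(cfg.n_filled):
        is_coloc = i < n_coloc
        _render_blob(green, cfg, xy_filled[i, 0], xy_filled[i, 1], z_filled[i], cfg.filled_peak)
        peak_red = 0.0
        if is_coloc:
            _render_blob(red, cfg, xy_filled[i, 0], xy_filled[i, 1], z_filled[i], cfg.pi_peak)
            peak_red = cfg.pi_peak
        rows.append(
            (
                cid,
                CLASS_COLOC if is_coloc else CLASS_FILLED,
                xy_filled[i, 0],
                xy_filled[i, 1],
                z_filled[i],
                cfg.cell_radius,
                cfg.filled_peak,
                peak_red,
            )
        )
        cid += 1
    for i in range(cfg.n_healthy):
        _render_blob(green, cfg, xy_healthy[i, 0], xy_healthy[i, 1], z_healthy[i], cfg.soma_peak)
        rows.append(
            (cid, CLASS_HEALTHY, xy_healthy[i, 0], xy_healthy[i, 1], z_healthy[i], cfg.cell_radius, cfg.soma_peak, 0.0)
        )
        cid += 1

    red += cfg.bleedthrough * green

    if cfg.depth_attenuation:
        atten = np.exp(-cfg.depth_attenuation * plane_z)[:, None, None]
        green *= atten
        red *= atten

    if cfg.noise_sd > 0:
        green += rng.normal(0.0, cfg.noise_sd, size=green.shape)
        red += rng.normal(0.0, cfg.noise_sd, size=red.shape)
        np.clip(green, 0.0, None, out=green)
        np.clip(red, 0.0, None, out=red)

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    gstack = VolumeStack(green.astype(np.float32), GREEN, cfg.pixel_size, cfg.z_step)
    rstack = VolumeStack(red.astype(np.float32), RED, cfg.pixel_size, cfg.z_step)
    return gstack, rstack, truth


def generate_movie(config: SynthMovieConfig) -> tuple[Movie, MovieTruth]:
    """Render a time-series movie and its ROI/event ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.n_frames) / cfg.frame_rate

    n_events = rng.poisson(cfg.event_rate * cfg.duration / 60.0)
    event_times = np.sort(rng.random(n_events) * cfg.duration)

    dff = np.zeros_like(t)
    for te in event_times:
        dff += cfg.event_amp_dff * np.exp(-((t - te) ** 2) / (2.0 * cfg.event_sigma**2))

    # ROI centers: rejection-sampled, non-overlapping, away from the border.
    margin = cfg.roi_radius * 2.5 + 2 * cfg.pixel_size
    width, height = cfg.nx * cfg.pixel_size, cfg.ny * cfg.pixel_size
    min_sep = 2.0 * cfg.roi_radius + 4.0  # somata never touch; annuli exclude somata anyway
    centers: list = []
    budget = 5000 * max(cfg.n_rois, 1)
    tries = 0
    while len(centers) < cfg.n_rois:
        tries += 1
        if tries > budget:
            raise GenerationError(f"could not place {cfg.n_rois} ROIs in a {width:.0f}x{height:.0f} um field")
        x = margin + rng.random() * (width - 2 * margin)
        y = margin + rng.random() * (height - 2 * margin)
        if all((px - x) ** 2 + (py - y) ** 2 >= min_sep**2 for px, py in centers):
            centers.append((x, y))

    filled_ids = set(range(cfg.n_filled))  # first n_filled ROIs are filled
    frames = np.zeros((cfg.n_frames, cfg.ny, cfg.nx), dtype=np.float32)
    yy = (np.arange(cfg.ny) + 0.5) * cfg.pixel_size
    xx = (np.arange(cfg.nx) + 0.5) * cfg.pixel_size
    rows = []
    for roi_id, (x, y) in enumerate(centers):
        mask = (yy[:, None] - y) ** 2 + (xx[None, :] - x) ** 2 <= cfg.roi_radius**2
        if roi_id in filled_ids:
            f_t = np.full_like(t, cfg.filled_f)
        else:
            f_t = cfg.baseline_f * (1.0 + dff)
        frames[:, mask] = f_t[:, None]
        rows.append((roi_id, x, y, cfg.roi_radius, roi_id in filled_ids))

    if cfg.noise_sd > 0:
        frames += rng.normal(0.0, cfg.noise_sd, size=frames.shape)

    rois = pd.DataFrame(rows, columns=["roi_id", "x_um", "y_um", "radius_um", "filled"])
    movie = Movie(frames=frames.astype(np.float32), frame_rate=cfg.frame_rate, pixel_size=cfg.pixel_size)
    return movie, MovieTruth(rois=rois, event_times=event_times)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False, columns=TRUTH_COLUMNS)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


# --- Presets -----------------------------------------------------------------
#
# Named parameter regimes for the conditions the analysis is exercised on.
# "fig1" is the baseline acute-slice condition (PI+ decay 41 um, GCaMP-filled
# 65 um, neuropil 131 um).  "fig3-late" emulates prolonged (3-5 h) incubation:
# shallower decays (larger tau) and more cells.  "fig6-mdl" emulates calpain
# inhibition during incubation: fewer PI+ cells and steeper decay.
# Soma radius 3.5 um (7 um diameter, small neonatal somata): with the Gaussian
# soma model this puts detected particle footprints (~90 um^2) inside both
# published size windows (PI+ 10-100 um^2, filled 20-200 um^2).

STACK_PRESETS = {
    "fig1": dict(
        n_pi=60,
        n_filled=40,
        n_healthy=30,
        frac_coloc=0.3,
        tau_pi=41.0,
        tau_filled=65.0,
        tau_neuropil=131.0,
        cell_radius=3.5,
    ),
    "fig3-late": dict(
        n_pi=90,
        n_filled=50,
        n_healthy=30,
        frac_coloc=0.3,
        tau_pi=75.0,
        tau_filled=90.0,
        tau_neuropil=131.0,
        cell_radius=3.5,
    ),
    "fig6-mdl": dict(
        n_pi=30,
        n_filled=25,
        n_healthy=30,
        frac_coloc=0.2,
        tau_pi=22.0,
        tau_filled=35.0,
        tau_neuropil=131.0,
        cell_radius=3.5,
    ),
}

# Movie regimes for the depth comparison of seizure-associated transients:
# deeper tissue shows higher frequency, amplitude and AUC than superficial
# tissue, with unchanged event width.
MOVIE_PRESETS = {
    "superficial": dict(event_rate=2.0, event_amp_dff=0.6, event_sigma=1.5),
    "deep": dict(event_rate=5.0, event_amp_dff=1.2, event_sigma=1.5),
}


def stack_preset(name: str, **overrides) -> SynthStackConfig:
    if name not in STACK_PRESETS:
        raise ParameterError(f"unknown stack preset {name!r}; available: {sorted(STACK_PRESETS)}")
    params = dict(STACK_PRESETS[name])
    params.update(overrides)
    return SynthStackConfig(**params)


def movie_preset(name: str, **overrides) -> SynthMovieConfig:
    if name not in MOVIE_PRESETS:
        raise ParameterError(f"unknown movie preset {name!r}; available: {sorted(MOVIE_PRESETS)}")
    params = dict(MOVIE_PRESETS[name])
    params.update(overrides)
    return SynthMovieConfig(**params)
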