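"""Synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure of an adapting budding-
yeast population: a broad Gaussian distribution of heritable single-cell
growth rates (σ/μ ≈ 0.3 in the adapted phase of the rewired strain, ≈ 0.1
for wild type) with an optional non-grower subpopulation; exponential
microcolony-area trajectories with multiplicative measurement noise; image
stacks of near-circular growing colonies; families of fixed-shape
fluorescence distributions whose variance is a quadratic function of the
mean; selective/rich plate colony counts; and slowly fluctuating
chemostat-like density series.

Every generator is a pure function of its configuration and seed, and emits
the ground truth next to the observable so downstream stages always have a
recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import draw

from ._random import substream
from .assays import PlateCountRecord
from .errors import ConfigurationError, GenerationError
from .growthfit import ColonyTrack
from .scaling import QuadraticLaw, ScalarDistributionSnapshot

LN2 = float(np.log(2.0))

#: Mean division time (hours) of the first adapted-phase growth-rate
#: distribution; sets the default mean rate scale.
DEFAULT_DIVISION_TIME_H = 8.4

#: Pixel area of a single cell under the 10x objective used for the
#: microcolony assay.
SINGLE_CELL_AREA_PX = 45.0

__all__ = [
    "GeneratorConfig",
    "GrowthRateSample",
    "ImageStack",
    "gen_growth_rates",
    "gen_colony_trajectories",
    "gen_microcolony_images",
    "gen_fluorescence_snapshots",
    "gen_plate_counts",
    "gen_density_series",
    "rewired_phase4_config",
    "wild_type_config",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic microcolony experiment.

    ``mean_rate`` is 1/hour (default ln 2 / 8.4 h), ``cv`` the σ/μ of the
    growing subpopulation, ``frac_nongrower`` the designated non-grower
    share, ``noise_cv`` the SD of the multiplicative (log-normal) area
    measurement noise, ``frame_interval`` hours between frames.
    """

    seed: int = 0
    n_cells: int = 500
    mean_rate: float = LN2 / DEFAULT_DIVISION_TIME_H
    cv: float = 0.3
    frac_nongrower: float = 0.0
    noise_cv: float = 0.05
    frame_interval: float = 1.0
    n_frames: int = 13
    image_shape: tuple = (512, 512)
    cell_area_px: float = SINGLE_CELL_AREA_PX

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ConfigurationError("cv must be non-negative")
        if not 0.0 <= self.frac_nongrower <= 1.0:
            raise ConfigurationError("frac_nongrower must be in [0, 1]")
        if self.n_frames < 3:
            raise ConfigurationError("n_frames must be >= 3 (a fit needs >= 3 points)")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be positive")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be non-negative")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if self.cell_area_px <= 0:
            raise ConfigurationError("cell_area_px must be positive")


def rewired_phase4_config(seed: int = 0, n_cells: int = 500, **overrides) -> GeneratorConfig:
    """The adapted-phase rewired-strain fixture: broad rates, σ/μ = 0.3."""
    kw = dict(seed=seed, n_cells=n_cells, mean_rate=LN2 / DEFAULT_DIVISION_TIME_H, cv=0.3)
    kw.update(overrides)
    return GeneratorConfig(**kw)


def wild_type_config(seed: int = 0, n_cells: int = 500, **overrides) -> GeneratorConfig:
    """The wild-type fixture: narrow rates (σ/μ = 0.1).

    The division time (4 h) is set so that the default hourly 12-h movie
    spans the ~3-generation instantaneous-rate window exactly, using all
    frames of the fit; this keeps fit-noise inflation of the measured CV
    below sampling error.
    """
    kw = dict(seed=seed, n_cells=n_cells, mean_rate=LN2 / 4.0, cv=0.1)
    kw.update(overrides)
    return GeneratorConfig(**kw)


@dataclass(frozen=True)
class GrowthRateSample:
    """Per-cell instantaneous growth rates with their ground-truth labels.

    ``nongrower`` marks cells designated non-growers by the generator;
    ``reclassified`` marks cells whose Gaussian draw was ≤ 0 and which were
    therefore reclassified as non-growers (not resampled, preserving the
    Gaussian shape of the growing tail).
    """

    rates: np.ndarray
    nongrower: np.ndarray
    reclassified: np.ndarray
    config: GeneratorConfig

    @property
    def growing_rates(self) -> np.ndarray:
        return self.rates[self.rates > 0]

    @property
    def cv_growing(self) -> float:
        g = self.growing_rates
        return float(g.std(ddof=1) / g.mean())


def gen_growth_rates(config: GeneratorConfig) -> GrowthRateSample:
    """Draw per-cell growth rates: Gaussian growers plus non-growers.

    A ``frac_nongrower`` Bernoulli share is set to exactly 0; the rest are
    Gaussian with mean ``mean_rate`` and SD ``cv * mean_rate``. Non-positive
    Gaussian draws are reclassified as non-growers and flagged.
    """
    rng = substream(config.seed, "growth_rates")
    n = config.n_cells
    designated = rng.random(n) < config.frac_nongrower
    draws = rng.normal(config.mean_rate, config.cv * config.mean_rate, size=n)
    reclassified = ~designated & (draws <= 0)
    rates = np.where(designated | reclassified, 0.0, draws)
    return GrowthRateSample(rates=rates, nongrower=designated, reclassified=reclassified, config=config)


def gen_colony_trajectories(rates: GrowthRateSample, config: GeneratorConfig) -> list:
    """Exponential colony-area trajectories with multiplicative noise.

    area_i(t) = A0 · exp(r_i t) · η_t with η_t i.i.d. mean-one log-normal of
    SD ``noise_cv`` (measurement error scales with colony size). Non-growers
    (r_i = 0) have constant mean area. The generating rate is stored on each
    track (``true_rate``) for recovery tests.
    """
    rng = substream(config.seed, "trajectories")
    t = np.arange(config.n_frames) * config.frame_interval
    a0 = config.cell_area_px
    s = config.noise_cv
    tracks = []
    for i, r in enumerate(rates.rates):
        clean = a0 * np.exp(r * t)
        if s > 0:
            noise = np.exp(s * rng.standard_normal(t.size) - 0.5 * s * s)
        else:
            noise = 1.0
        tracks.append(
            ColonyTrack(colony_id=i, times=t, areas=clean * noise, true_rate=float(r), true_a0=a0)
        )
    return tracks


@dataclass(frozen=True)
class ImageStack:
    """Rendered time-lapse frames with ground-truth labels.

    ``frames``: (n_frames, H, W) float32 intensities; ``labels``: int32
    masks where pixel value k+1 marks colony k; ``centroids``: (n, 2)
    (row, col) positions; ``overlap_ids``: colonies whose disks come closer
    than the proximity threshold (exercises the exclusion rule).
    """

    frames: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    centroids: np.ndarray
    overlap_ids: frozenset
    config: GeneratorConfig


def gen_microcolony_images(
    tracks,
    config: GeneratorConfig,
    *,
    centroids=None,
    background: float = 100.0,
    foreground: float = 200.0,
    pixel_noise_sd: float = 5.0,
    proximity_px: float = 5.0,
) -> ImageStack:
    """Render tracks as filled disks growing in place on a noisy background.

    Colonies are laid out on a grid (or at explicit ``centroids``) with the
    disk area equal to the track area each frame. Colonies whose final
    disks come within ``proximity_px`` of touching are flagged as
    overlapping; overlap is allowed and later frames simply merge. Raises
    :class:`GenerationError` if the footprints cannot fit in
    ``image_shape``.
    """
    tracks = list(tracks)
    h, w = config.image_shape
    n_frames = max((tr.n_frames for tr in tracks), default=config.n_frames)
    rng = substream(config.seed, "images")
    frames = background + pixel_noise_sd * rng.standard_normal((n_frames, h, w))
    labels = np.zeros((n_frames, h, w), dtype=np.int32)
    if not tracks:
        return ImageStack(frames=frames.astype(np.float32), labels=labels,
                          centroids=np.empty((0, 2)), overlap_ids=frozenset(), config=config)

    max_radius = max(float(np.sqrt(tr.areas.max() / np.pi)) for tr in tracks)
    if centroids is None:
        margin = max_radius + 15.0
        pitch = 2 * max_radius + 20.0
        n_cols = max(int((w - 2 * margin) // pitch) + 1, 1)
        n_rows = max(int((h - 2 * margin) // pitch) + 1, 1)
        if n_cols * n_rows < len(tracks):
            raise GenerationError(
                f"{len(tracks)} colonies of max radius {max_radius:.1f} px do not fit in {config.image_shape}"
            )
        centroids = np.array(
            [(margin + (k // n_cols) * pitch, margin + (k % n_cols) * pitch) for k in range(len(tracks))]
        )
    else:
        centroids = np.asarray(centroids, dtype=float)
        if np.any(centroids[:, 0] + max_radius > h) or np.any(centroids[:, 1] + max_radius > w) \
                or np.any(centroids - max_radius < 0):
            raise GenerationError("colony footprints do not fit inside image_shape at the given centroids")

    final_r = np.array([np.sqrt(tr.areas[-1] / np.pi) for tr in tracks])
    overlap = set()
    for i in range(len(tracks)):
        for j in range(i + 1, len(tracks)):
            dist = np.hypot(*(centroids[i] - centroids[j]))
            if dist < final_r[i] + final_r[j] + proximity_px:
                overlap.update((tracks[i].colony_id, tracks[j].colony_id))

    for f in range(n_frames):
        for k, tr in enumerate(tracks):
            if f >= tr.n_frames:
                continue
            radius = np.sqrt(tr.areas[f] / np.pi)
            rr, cc = draw.disk(tuple(centroids[k]), radius, shape=(h, w))
            frames[f, rr, cc] = foreground
            labels[f, rr, cc] = tr.colony_id + 1
    return ImageStack(frames=frames.astype(np.float32), labels=labels, centroids=centroids,
                      overlap_ids=frozenset(overlap), config=config)


def gen_fluorescence_snapshots(
    means,
    variance_law: QuadraticLaw,
    *,
    shape: str = "lognormal",
    shape_param: float = 0.6,
    n_cells: int = 40_000,
    seed: int = 0,
    exact_family: bool = False,
) -> list:
    """A family of same-shape snapshots on a variance–mean law.

    Each requested mean gets a snapshot whose values are an affine
    rescaling of a fixed standardized base shape to that mean and to
    variance = ``variance_law(mean)``; base draws are standardized
    empirically, so the sample moments land exactly on the law and the
    family collapses under standardization. ``shape``: ``"lognormal"``
    (right-skewed, default — the measured distributions are skewed but no
    analytic form is implied) or ``"gaussian"``. With ``exact_family`` all
    snapshots share the same base draws and collapse identically;
    otherwise each snapshot gets fresh draws (two-sample distances then sit
    at the sampling-noise floor).
    """
    rng = substream(seed, "fluorescence")
    means = np.asarray(means, dtype=float)

    def base() -> np.ndarray:
        g = rng.standard_normal(n_cells)
        x = np.exp(shape_param * g) if shape == "lognormal" else g
        if shape not in ("lognormal", "gaussian"):
            raise GenerationError(f"unknown base shape: {shape!r}")
        return (x - x.mean()) / x.std()

    shared = base() if exact_family else None
    out = []
    for i, m in enumerate(means):
        v = float(variance_law(m))
        if v <= 0:
            raise GenerationError(f"variance law is non-positive at mean {m}")
        z = shared if shared is not None else base()
        out.append(ScalarDistributionSnapshot(time_label=f"t{i}", values=m + np.sqrt(v) * z))
    return out


def gen_plate_counts(
    n_plated: int,
    frac_adapted: float,
    *,
    n_glu_plates: int = 3,
    n_ypd_plates: int = 2,
    plating_efficiency=1.0,
    seed: int = 0,
    time_label: str = "t0",
) -> PlateCountRecord:
    """Poisson colony counts on selective (glucose) and rich (YPD) plates.

    ``plating_efficiency`` may be a scalar or a ``(glucose, ypd)`` pair.
    Fractions and efficiencies up to 1.2 are allowed — the downstream
    fraction-adapted estimator is a ratio of plate types and can exceed 1.
    """
    eff = np.broadcast_to(np.asarray(plating_efficiency, dtype=float), (2,))
    if not 0.0 <= frac_adapted <= 1.2:
        raise GenerationError("frac_adapted must be in [0, 1.2]")
    if np.any(eff < 0) or np.any(eff > 1.2):
        raise GenerationError("plating_efficiency must be in [0, 1.2]")
    if n_plated < 1 or n_glu_plates < 1 or n_ypd_plates < 1:
        raise GenerationError("need at least one plate of each type and one plated cell")
    rng = substream(seed, "plates")
    glu = rng.poisson(n_plated * frac_adapted * eff[0], size=n_glu_plates)
    ypd = rng.poisson(n_plated * eff[1], size=n_ypd_plates)
    return PlateCountRecord(
        time_label=time_label,
        glucose_counts=glu,
        ypd_counts=ypd,
        cells_plated=int(n_plated),
    )


def gen_density_series(
    *,
    n_points: int = 500,
    dt: float = 1.0,
    mean: float = 1.0,
    cv: float = 0.05,
    corr_time: float = 0.0,
    seed: int = 0,
):
    """A chemostat-like density series with multiplicative fluctuations.

    Log-density follows a stationary AR(1) (Ornstein–Uhlenbeck) process of
    standard deviation ``cv`` and correlation time ``corr_time``;
    ``corr_time <= 0`` gives white multiplicative noise. Returns
    ``(times, values)``.
    """
    rng = substream(seed, "density")
    if corr_time <= 0:
        x = cv * rng.standard_normal(n_points)
    else:
        phi = np.exp(-dt / corr_time)
        x = np.empty(n_points)
        x[0] = cv * rng.standard_normal()
        innov_sd = cv * np.sqrt(1 - phi * phi)
        for k in range(1, n_points):
            x[k] = phi * x[k - 1] + innov_sd * rng.standard_normal()
    values = mean * np.exp(x - 0.5 * cv * cv)
    return np.arange(n_points) * dt, values
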