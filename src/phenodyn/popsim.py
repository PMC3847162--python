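"""Lineage-selection Monte Carlo of growth-rate phenotypes.

The null model of the study: every founder's growth rate is stably
inherited along its lineage, so between protocol events each lineage grows
as an exact exponential and selection alone reshapes the population.
For Gaussian founder rates the population mean then increases linearly,
⟨r⟩(t) = μ0 + σ0²·t with unchanged SD σ0 (exponential reweighting of a
Gaussian — the Gaussian-tilt closed form, which is also Fisher's
fundamental theorem: d⟨r⟩/dt = Var(r)). The fastest founders take over
monotonically within a few generations; any plateau or decrease of the
population mean requires breaking stable inheritance, which the optional
metastable-switching mode does by re-drawing single-cell rates at
exponentially distributed waiting times.

Three interchangeable representations:

``lineage`` (default)
    Per-founder expected sizes grown as exact exponentials; stochasticity
    enters only at dilution sampling and switching events. Scales to the
    10^9–10^10 cells of a chemostat without per-cell bookkeeping.
``agent``
    Per-cell branching process (Poisson offspring with the matching
    expectation) for cross-validation at small N.
``deterministic``
    The Gaussian continuum evaluated from the closed form; the oracle the
    stochastic modes are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import optimize, stats

from ._random import substream
from .errors import ConfigurationError, ProtocolViolationError

LN2 = float(np.log(2.0))

__all__ = [
    "SerialDilution",
    "Chemostat",
    "SimConfig",
    "PopulationTrajectory",
    "TakeoverResult",
    "simulate",
    "closed_form_gaussian_mean",
    "apply_dilution",
    "takeover_time",
]


@dataclass(frozen=True)
class SerialDilution:
    """Batch propagation: dilute by a random factor every ``interval``.

    The factor is uniform over ``dilution_range`` (default 1:10–1:50) and a
    transfer below ``min_transfer`` cells aborts the run as a protocol
    violation (populations must never pass through a bottleneck).
    """

    interval: float = 12.0
    min_transfer: float = 1e5
    dilution_range: tuple = (10.0, 50.0)


@dataclass(frozen=True)
class Chemostat:
    """Continuous culture at fixed dilution rate (1/hour)."""

    dilution_rate: float = 0.18


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Time is dimensionless by default (rates in inverse simulation time);
    hours apply when a protocol needs them. ``inheritance_mode`` is
    ``stable`` (the null model) or ``switching`` (rates re-drawn at rate
    ``switch_rate`` per cell per unit time, by default from the founder
    distribution; ``redraw="ou"`` instead relaxes class rates along an
    Ornstein–Uhlenbeck path — an extension beyond the null model). Exactly
    one of ``horizon`` (time) or ``horizon_generations`` must be set.
    ``founder_rates``/``founder_sizes`` override the Gaussian draw for
    controlled experiments.
    """

    n_founders: int = 1000
    founder_mean_rate: float = 1.0
    founder_cv: float = 0.3
    inheritance_mode: str = "stable"
    switch_rate: float = 0.0
    redraw: str = "founder"
    ou_relaxation_time: float = 10.0
    protocol: Union[SerialDilution, Chemostat, None] = None
    horizon: Optional[float] = None
    horizon_generations: Optional[float] = None
    seed: int = 0
    checkpoint_interval: float = 0.1
    mode: str = "lineage"
    founder_rates: Optional[np.ndarray] = None
    founder_sizes: Optional[np.ndarray] = None
    record_lineages: bool = True
    max_new_classes_per_step: int = 200

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise ConfigurationError("n_founders must be >= 1")
        if self.founder_cv < 0:
            raise ConfigurationError("founder_cv must be >= 0")
        if self.inheritance_mode not in ("stable", "switching"):
            raise ConfigurationError(f"unknown inheritance_mode {self.inheritance_mode!r}")
        if self.mode not in ("lineage", "agent", "deterministic"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if (self.horizon is None) == (self.horizon_generations is None):
            raise ConfigurationError("set exactly one of horizon or horizon_generations")
        if self.checkpoint_interval <= 0:
            raise ConfigurationError("checkpoint_interval must be positive")
        if isinstance(self.protocol, SerialDilution) and self.protocol.min_transfer < 1:
            raise ConfigurationError("min_transfer must be >= 1")
        if self.inheritance_mode == "switching" and self.switch_rate < 0:
            raise ConfigurationError("switch_rate must be >= 0")


@dataclass
class PopulationTrajectory:
    """Checkpointed population state.

    ``generations`` is log2 of the cumulative gross growth factor (dilution
    losses excluded). ``lineage_freqs`` (checkpoints × founders) attributes
    every cell to its founder; rows sum to 1. ``status`` is ``completed``,
    ``extinct`` or ``protocol_violation`` (truncated trajectories keep the
    checkpoints recorded before the event).
    """

    times: np.ndarray
    sizes: np.ndarray
    mean_rate: np.ndarray
    sd_rate: np.ndarray
    generations: np.ndarray
    frac_growing: np.ndarray
    lineage_freqs: Optional[np.ndarray]
    founder_rates: Optional[np.ndarray]
    status: str
    config: SimConfig
    chemostat_generations: Optional[np.ndarray] = None


@dataclass(frozen=True)
class TakeoverResult:
    """When the fastest founders' descendants first exceed half the population."""

    reached: bool
    time: float
    generations: float


def closed_form_gaussian_mean(mu0: float, sigma0: float, t: float):
    """Mean and SD of r under exponential-growth reweighting of a Gaussian.

    Weighting N(μ0, σ0²) by e^{rt} and renormalizing (complete the square)
    gives N(μ0 + σ0²·t, σ0²): the mean increases linearly at slope σ0², the
    SD is unchanged.
    """
    if sigma0 < 0:
        raise ConfigurationError("sigma0 must be >= 0")
    return mu0 + sigma0 * sigma0 * t, sigma0


def apply_dilution(sizes, factor: float, rng, min_transfer: float = 1.0) -> np.ndarray:
    """Multinomial survival of N/factor cells across lineages.

    Expected lineage frequencies are unchanged by the draw. ``rng`` may be
    a Generator or an integer seed.

    Raises
    ------
    ProtocolViolationError
        If the post-dilution size would fall below ``min_transfer``.
    """
    if factor <= 1:
        raise ConfigurationError("dilution factor must be > 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sizes = np.asarray(sizes, dtype=float)
    total = float(sizes.sum())
    n_surv = int(round(total / factor))
    if n_surv < min_transfer:
        raise ProtocolViolationError(
            f"transfer of {n_surv} cells is below the minimum of {min_transfer:g}"
        )
    return rng.multinomial(n_surv, sizes / total).astype(float)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _founders(config: SimConfig, rng: np.random.Generator):
    if config.founder_rates is not None:
        rates = np.asarray(config.founder_rates, dtype=float).copy()
    else:
        mu = config.founder_mean_rate
        rates = rng.normal(mu, config.founder_cv * mu, size=config.n_founders)
    if config.founder_sizes is not None:
        sizes = np.asarray(config.founder_sizes, dtype=float).copy()
    else:
        sizes = np.ones(rates.size)
    return rates, sizes


def _weighted_stats(rates, sizes):
    total = sizes.sum()
    mean = float((sizes * rates).sum() / total)
    var = float((sizes * (rates - mean) ** 2).sum() / total)
    frac = float(sizes[rates > 0].sum() / total)
    return mean, np.sqrt(max(var, 0.0)), frac


def simulate(config: SimConfig) -> PopulationTrajectory:
    """Run the configured simulation and return its checkpointed trajectory."""
    if config.mode == "deterministic":
        return _simulate_deterministic(config)
    if config.mode == "agent":
        return _simulate_agent(config)
    return _simulate_lineage(config)


def _simulate_deterministic(config: SimConfig) -> PopulationTrajectory:
    """Gaussian continuum: checkpoints evaluated from the closed form."""
    if config.protocol is not None or config.inheritance_mode != "stable":
        raise ConfigurationError("deterministic mode covers the stable, protocol-free model only")
    mu, sig = config.founder_mean_rate, config.founder_cv * config.founder_mean_rate

    def gens(t):
        return (mu * t + 0.5 * sig * sig * t * t) / LN2

    if config.horizon is not None:
        t_end = config.horizon
    else:
        g = config.horizon_generations
        if sig > 0:
            t_end = (-mu + np.sqrt(mu * mu + 2 * sig * sig * g * LN2)) / (sig * sig)
        else:
            t_end = g * LN2 / mu
    times = np.arange(0.0, t_end, config.checkpoint_interval)
    if times.size == 0 or times[-1] < t_end:
        times = np.append(times, t_end)
    mean = mu + sig * sig * times
    sd = np.full_like(times, sig)
    frac = stats.norm.cdf(mean / sig) if sig > 0 else np.full_like(times, float(mu > 0))
    return PopulationTrajectory(
        times=times,
        sizes=config.n_founders * np.exp(mu * times + 0.5 * sig * sig * times * times),
        mean_rate=mean,
        sd_rate=sd,
        generations=gens(times),
        frac_growing=np.atleast_1d(frac).astype(float),
        lineage_freqs=None,
        founder_rates=None,
        status="completed",
        config=config,
    )


def _refine_final_time(rates, sizes, g_now, g_target, dt):
    """Time within the next interval at which the generation counter hits
    the target, assuming fixed rates (no events) over the interval."""
    total = sizes.sum()

    def g_at(tau):
        return g_now + np.log2((sizes * np.exp(rates * tau)).sum() / total)

    if g_at(dt) < g_target:
        return None
    return float(optimize.brentq(lambda tau: g_at(tau) - g_target, 0.0, dt, xtol=1e-10))


def _simulate_lineage(config: SimConfig) -> PopulationTrajectory:
    rng = substream(config.seed, "popsim")
    founder_rates, sizes = _founders(config, rng)
    n_founders = founder_rates.size
    rates = founder_rates.copy()
    founder_of = np.arange(n_founders)

    dil = config.protocol if isinstance(config.protocol, SerialDilution) else None
    chem = config.protocol if isinstance(config.protocol, Chemostat) else None
    D = chem.dilution_rate if chem else 0.0
    switching = config.inheritance_mode == "switching" and config.switch_rate > 0

    dt = config.checkpoint_interval
    t, g = 0.0, 0.0
    next_dilution = dil.interval if dil is not None else np.inf
    status = "completed"
    rows = []

    def record():
        mean, sd, frac = _weighted_stats(rates, sizes)
        freqs = None
        if config.record_lineages:
            freqs = np.bincount(founder_of, weights=sizes, minlength=n_founders) / sizes.sum()
        rows.append((t, sizes.sum(), mean, sd, g, frac, freqs))

    record()
    while True:
        if config.horizon is not None and t >= config.horizon - 1e-12:
            break
        if config.horizon_generations is not None and g >= config.horizon_generations - 1e-12:
            break
        step = dt
        if config.horizon is not None:
            step = min(step, config.horizon - t)
        step = min(step, next_dilution - t) if np.isfinite(next_dilution) else step
        if config.horizon_generations is not None and not switching:
            tau = _refine_final_time(rates, sizes, g, config.horizon_generations, step)
            if tau is not None:
                step = tau
        before = sizes.sum()
        sizes = sizes * np.exp((rates - D) * step)
        g += float(np.log2(sizes.sum() * np.exp(D * step) / before))
        t += step

        if switching:
            lam = config.switch_rate
            if config.redraw == "ou":
                phi = np.exp(-step / config.ou_relaxation_time)
                mu = config.founder_mean_rate
                sig = config.founder_cv * mu
                rates = mu + (rates - mu) * phi + sig * np.sqrt(1 - phi * phi) * rng.standard_normal(rates.size)
            else:
                n_events = np.minimum(rng.poisson(sizes * lam * step), np.floor(sizes)).astype(float)
                total_events = int(n_events.sum())
                if total_events > 0:
                    sizes = sizes - n_events
                    k = min(total_events, config.max_new_classes_per_step)
                    new_rates = rng.normal(config.founder_mean_rate,
                                           config.founder_cv * config.founder_mean_rate, size=k)
                    # attribute switched cells back to founders in proportion
                    src = rng.choice(rates.size, size=k, p=n_events / total_events if total_events else None)
                    new_sizes = np.full(k, total_events / k)
                    rates = np.concatenate([rates, new_rates])
                    sizes = np.concatenate([sizes, new_sizes])
                    founder_of = np.concatenate([founder_of, founder_of[src]])

        if dil is not None and t >= next_dilution - 1e-9:
            next_dilution += dil.interval
            factor = rng.uniform(*dil.dilution_range)
            try:
                sizes = apply_dilution(sizes, factor, rng, min_transfer=dil.min_transfer)
            except ProtocolViolationError:
                status = "protocol_violation"
                record()
                break

        if sizes.sum() < 1.0:
            status = "extinct"
            record()
            break
        record()

    return _assemble(rows, founder_rates, status, config, chem)


def _simulate_agent(config: SimConfig) -> PopulationTrajectory:
    """Per-cell branching process with matching expected growth.

    Over a step Δ each cell with rate r ≥ 0 leaves 1 + Poisson(e^{rΔ}−1)
    descendants (so E[N] grows exactly as e^{rΔ}); cells with r < 0 survive
    with probability e^{rΔ}. Intended for N up to ~10^4 founders as a
    cross-validation of the lineage representation.
    """
    rng = substream(config.seed, "popsim-agent")
    founder_rates, sizes0 = _founders(config, rng)
    if not np.allclose(sizes0, np.round(sizes0)):
        raise ConfigurationError("agent mode needs integer founder sizes")
    reps = np.round(sizes0).astype(int)
    rates = np.repeat(founder_rates, reps)
    founder_of = np.repeat(np.arange(founder_rates.size), reps)
    n_founders = founder_rates.size

    dil = config.protocol if isinstance(config.protocol, SerialDilution) else None
    chem = config.protocol if isinstance(config.protocol, Chemostat) else None
    switching = config.inheritance_mode == "switching" and config.switch_rate > 0

    dt = config.checkpoint_interval
    t, g = 0.0, 0.0
    next_dilution = dil.interval if dil is not None else np.inf
    status = "completed"
    rows = []

    def record():
        mean, sd, frac = _weighted_stats(rates, np.ones(rates.size))
        freqs = None
        if config.record_lineages:
            freqs = np.bincount(founder_of, minlength=n_founders) / rates.size
        rows.append((t, float(rates.size), mean, sd, g, frac, freqs))

    record()
    while True:
        if config.horizon is not None and t >= config.horizon - 1e-12:
            break
        if config.horizon_generations is not None and g >= config.horizon_generations - 1e-12:
            break
        step = dt if config.horizon is None else min(dt, config.horizon - t)
        step = min(step, next_dilution - t) if np.isfinite(next_dilution) else step
        before = rates.size
        growing = rates >= 0
        offspring = np.zeros(rates.size, dtype=np.int64)
        offspring[growing] = rng.poisson(np.expm1(rates[growing] * step))
        survive = np.ones(rates.size, dtype=bool)
        if not growing.all():
            survive[~growing] = rng.random((~growing).sum()) < np.exp(rates[~growing] * step)
        rates = np.concatenate([rates[survive], np.repeat(rates, offspring)])
        founder_of = np.concatenate([founder_of[survive], np.repeat(founder_of, offspring)])
        if rates.size == 0:
            t += step
            status = "extinct"
            record()
            break
        g += float(np.log2(rates.size / before))
        t += step

        if switching:
            p = -np.expm1(-config.switch_rate * step)
            flip = rng.random(rates.size) < p
            if flip.any():
                mu = config.founder_mean_rate
                rates[flip] = rng.normal(mu, config.founder_cv * mu, size=flip.sum())

        if chem is not None:
            keep = rng.random(rates.size) < np.exp(-chem.dilution_rate * step)
            rates, founder_of = rates[keep], founder_of[keep]
        if dil is not None and t >= next_dilution - 1e-9:
            next_dilution += dil.interval
            factor = rng.uniform(*dil.dilution_range)
            n_surv = int(round(rates.size / factor))
            if n_surv < dil.min_transfer:
                status = "protocol_violation"
                record()
                break
            idx = rng.choice(rates.size, size=n_surv, replace=False)
            rates, founder_of = rates[idx], founder_of[idx]
        if rates.size == 0:
            status = "extinct"
            record()
            break
        record()

    return _assemble(rows, founder_rates, status, config, chem)


def _assemble(rows, founder_rates, status, config, chem) -> PopulationTrajectory:
    times = np.array([r[0] for r in rows])
    freqs = None
    if config.record_lineages and rows[0][6] is not None:
        freqs = np.vstack([r[6] for r in rows])
    return PopulationTrajectory(
        times=times,
        sizes=np.array([r[1] for r in rows]),
        mean_rate=np.array([r[2] for r in rows]),
        sd_rate=np.array([r[3] for r in rows]),
        generations=np.array([r[4] for r in rows]),
        frac_growing=np.array([r[5] for r in rows]),
        lineage_freqs=freqs,
        founder_rates=founder_rates,
        status=status,
        config=config,
        chemostat_generations=times * chem.dilution_rate / LN2 if chem else None,
    )


def takeover_time(traj: PopulationTrajectory, top_fraction: float) -> TakeoverResult:
    """First time the top-``top_fraction`` fastest founders' descendants
    exceed 50% of the population.

    The crossing is linearly interpolated between checkpoints, in both time
    and generations. With zero rate variance there is no selection
    differential and takeover never happens (``reached=False``).
    """
    if traj.lineage_freqs is None or traj.founder_rates is None:
        raise ValueError("trajectory carries no lineage frequencies")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    n = traj.founder_rates.size
    k = max(1, int(np.ceil(top_fraction * n)))
    top = np.argsort(-traj.founder_rates)[:k]
    freq = traj.lineage_freqs[:, top].sum(axis=1)
    above = freq > 0.5
    if not above.any():
        return TakeoverResult(reached=False, time=float("nan"), generations=float("nan"))
    i = int(np.argmax(above))
    if i == 0:
        return TakeoverResult(reached=True, time=float(traj.times[0]), generations=float(traj.generations[0]))
    w = (0.5 - freq[i - 1]) / (freq[i] - freq[i - 1])
    t_cross = traj.times[i - 1] + w * (traj.times[i] - traj.times[i - 1])
    g_cross = traj.generations[i - 1] + w * (traj.generations[i] - traj.generations[i - 1])
    return TakeoverResult(reached=True, time=float(t_cross), generations=float(g_cross))
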