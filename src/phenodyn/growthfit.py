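"""Microcolony time-lapse growth-rate pipeline.

Bright-field frames are segmented into colony regions, colonies are tracked
across frames by nearest-centroid matching, each colony's area-versus-time
vector is fitted to y = A·exp(B·x), and fits are gated on goodness of fit
(Rsq > 0.95) plus positional exclusion rules before the accepted
instantaneous growth rates B (1/hour) are summarized into a distribution.

Fits that fail the Rsq gate but are not positionally excluded pass through
an automated review stage (`review_rejected`) that accepts tracks whose
log-area series is consistent with exponential growth plus uncorrelated
noise; every review decision is recorded in a queue for audit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from skimage import filters, measure

from .errors import DegenerateDistributionError

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

ACCEPTED_STATUSES = ("accepted", "accepted_review")

__all__ = [
    "ColonyTrack",
    "Region",
    "FitResult",
    "GrowthRateDistribution",
    "segment_frame",
    "track_colonies",
    "fit_exponential",
    "apply_exclusions",
    "review_rejected",
    "summarize_distribution",
    "fraction_exponential",
    "run_growth_pipeline",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ColonyTrack:
    """Per-colony area-versus-time vector.

    ``times`` are hours (strictly increasing), ``areas`` pixels (positive),
    ``centroids`` optional (row, col) pixel coordinates per frame. ``flags``
    may contain ``edge_proximal``, ``merged`` and ``lost``. Synthetic tracks
    carry their generating rate in ``true_rate`` for recovery tests.
    """

    colony_id: int
    times: np.ndarray
    areas: np.ndarray
    centroids: np.ndarray | None = None
    flags: set = field(default_factory=set)
    true_rate: float | None = None
    true_a0: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.times.shape != self.areas.shape:
            raise ValueError("times and areas must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"colony {self.colony_id}: times must be strictly increasing")
        if np.any(self.areas <= 0):
            raise ValueError(f"colony {self.colony_id}: areas must be positive")

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class Region:
    """A segmented connected region in one frame."""

    label: int
    area: float
    centroid: tuple  # (row, col)
    bbox: tuple  # (min_row, min_col, max_row, max_col)
    boundary: np.ndarray | None = None


@dataclass(frozen=True)
class FitResult:
    """Exponential fit of one colony track.

    ``status`` is one of ``accepted`` (Rsq gate), ``accepted_review``
    (rescued by the automated review of sub-gate fits), ``rejected_rsq``,
    ``rejected_exclusion`` or ``non_growing`` (constant-area track).
    """

    colony_id: int
    A: float
    B: float
    rsq: float
    status: str
    rejection_reason: str = ""
    n_points: int = 0
    window_hours: float = 0.0


@dataclass(frozen=True)
class GrowthRateDistribution:
    """Summary of accepted instantaneous growth rates."""

    rates: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    bin_bootstrap_sd: np.ndarray
    mean: float
    sd: float
    sem: float
    cv: float
    cv_bootstrap_se: float
    mean_bootstrap_se: float
    subsample_sizes: np.ndarray
    subsample_means: np.ndarray

    @property
    def n(self) -> int:
        return self.rates.size

    @property
    def converged(self) -> bool:
        """Mean of random subsets at half the sample size agrees with the
        full mean to within one SEM (the subsample-convergence diagnostic)."""
        if self.n == 0 or self.subsample_means.size < 2:
            return False
        return bool(abs(self.subsample_means[-2] - self.mean) <= max(self.sem, 1e-12))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_frame(
    image,
    *,
    sigma: float = 1.0,
    min_area: float = 20.0,
    min_contrast: float = 10.0,
    threshold: float | None = None,
) -> list:
    """Segment one single-channel frame into labelled colony regions.

    Default backend: Gaussian smoothing, Otsu threshold, connected-component
    labelling, with regions below ``min_area`` pixels dropped. A frame whose
    foreground/background intensity separation is below ``min_contrast`` is
    treated as blank (guards against Otsu splitting pure noise). Boundary
    contours are extracted per region at the half-level of the threshold.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_frame expects a single-channel 2-D image")
    if np.ptp(img) == 0:
        return []
    smooth = filters.gaussian(img, sigma=sigma, preserve_range=True)
    thr = float(filters.threshold_otsu(smooth)) if threshold is None else float(threshold)
    mask = smooth > thr
    if not mask.any() or mask.all():
        return []
    if smooth[mask].mean() - smooth[~mask].mean() < min_contrast:
        return []
    labelled = measure.label(mask)
    regions = []
    for prop in measure.regionprops(labelled):
        if prop.area < min_area:
            continue
        sub = np.pad(prop.image.astype(float), 1)
        contours = measure.find_contours(sub, 0.5)
        boundary = None
        if contours:
            boundary = max(contours, key=len) + np.array(prop.bbox[:2]) - 1.0
        regions.append(
            Region(
                label=prop.label,
                area=float(prop.area),
                centroid=tuple(map(float, prop.centroid)),
                bbox=tuple(prop.bbox),
                boundary=boundary,
            )
        )
    return regions


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


class _OpenTrack:
    __slots__ = ("tid", "frames", "regions", "flags", "active")

    def __init__(self, tid: int, frame: int, region: Region):
        self.tid = tid
        self.frames = [frame]
        self.regions = [region]
        self.flags: set = set()
        self.active = True

    @property
    def last(self) -> Region:
        return self.regions[-1]


def _default_max_displacement(frame_regions) -> float:
    for regs in frame_regions:
        if regs:
            radii = [np.sqrt(r.area / np.pi) for r in regs]
            return max(float(np.mean(radii)), 5.0)
    return 5.0


def track_colonies(
    frame_regions,
    *,
    frame_interval: float = 1.0,
    times=None,
    field_shape: tuple | None = None,
    edge_margin: float = 10.0,
    max_displacement: float | None = None,
) -> list:
    """Link per-frame regions into colony tracks by centroid correlation.

    Greedy nearest-centroid matching under ``max_displacement`` (default:
    one mean colony radius of the first populated frame). Equidistant
    candidates are resolved deterministically by smallest area difference
    (logged). An active track whose nearest region was claimed by another
    track is considered to have merged into it: both carry the ``merged``
    flag. Unmatched regions start new tracks; unmatched tracks are flagged
    ``lost``. Tracks whose colony ever comes within ``edge_margin`` pixels
    of the field border (given ``field_shape``) are flagged
    ``edge_proximal``.
    """
    frame_regions = [list(r) for r in frame_regions]
    if len(frame_regions) < 2:
        raise ValueError("tracking needs at least two frames")
    if times is None:
        times = np.arange(len(frame_regions)) * frame_interval
    times = np.asarray(times, dtype=float)
    max_disp = max_displacement if max_displacement is not None else _default_max_displacement(frame_regions)

    tracks: list[_OpenTrack] = [_OpenTrack(i, 0, reg) for i, reg in enumerate(frame_regions[0])]
    next_id = len(tracks)

    for f in range(1, len(frame_regions)):
        regions = frame_regions[f]
        active = [tr for tr in tracks if tr.active]
        # all candidate pairs within the displacement threshold
        pairs = []
        for tr in active:
            cy, cx = tr.last.centroid
            for j, reg in enumerate(regions):
                d = float(np.hypot(reg.centroid[0] - cy, reg.centroid[1] - cx))
                if d <= max_disp:
                    pairs.append((d, abs(reg.area - tr.last.area), tr.tid, j, tr, reg))
        pairs.sort(key=lambda p: (p[0], p[1], p[2], p[3]))
        for k in range(len(pairs) - 1):
            if abs(pairs[k][0] - pairs[k + 1][0]) < 1e-9 and pairs[k][2] == pairs[k + 1][2]:
                logger.debug(
                    "frame %d: equidistant candidates for track %d resolved by area similarity",
                    f, pairs[k][2],
                )
        taken_tracks: set = set()
        taken_regions: set = set()
        claimed_by: dict = {}
        for d, _, tid, j, tr, reg in pairs:
            if tid in taken_tracks or j in taken_regions:
                continue
            tr.frames.append(f)
            tr.regions.append(reg)
            taken_tracks.add(tid)
            taken_regions.add(j)
            claimed_by[j] = tr
        # merge detection: an unmatched active track whose nearest candidate
        # region was claimed by another track has merged into that region
        for d, _, tid, j, tr, reg in pairs:
            if tid in taken_tracks or j not in claimed_by:
                continue
            tr.flags.add("merged")
            claimed_by[j].flags.add("merged")
            tr.active = False
            taken_tracks.add(tid)
        for tr in active:
            if tr.tid not in taken_tracks:
                tr.flags.add("lost")
                tr.active = False
        for j, reg in enumerate(regions):
            if j not in taken_regions:
                tracks.append(_OpenTrack(next_id, f, reg))
                next_id += 1

    out = []
    for tr in tracks:
        if field_shape is not None:
            h, w = field_shape
            for reg in tr.regions:
                radius = np.sqrt(reg.area / np.pi)
                cy, cx = reg.centroid
                if (
                    cy - radius < edge_margin
                    or cx - radius < edge_margin
                    or cy + radius > h - edge_margin
                    or cx + radius > w - edge_margin
                ):
                    tr.flags.add("edge_proximal")
                    break
        if len(tr.frames) < 2:
            continue
        out.append(
            ColonyTrack(
                colony_id=tr.tid,
                times=times[tr.frames],
                areas=np.array([r.area for r in tr.regions]),
                centroids=np.array([r.centroid for r in tr.regions]),
                flags=tr.flags,
            )
        )
    return out


# ---------------------------------------------------------------------------
# exponential fitting
# ---------------------------------------------------------------------------


def _log_ols(t: np.ndarray, area: np.ndarray):
    slope, intercept = np.polyfit(t, np.log(area), 1)
    return float(np.exp(intercept)), float(slope)


def fit_exponential(
    track: ColonyTrack,
    *,
    rsq_gate: float = 0.95,
    max_generations: float = 3.0,
    method: str = "area",
) -> FitResult:
    """Two-parameter least-squares fit of area = A·exp(B·t).

    The fit is performed on the area scale (``method="area"``, default)
    with a log-linear fit as initializer; ``method="log"`` keeps the
    log-OLS estimate. Rsq = 1 − SS_res/SS_tot is always computed on the
    area scale. Tracks longer than ``max_generations`` doublings of the
    fitted rate are windowed from the start, so B stays an instantaneous
    rate. A constant-area track is classified ``non_growing`` with B = 0
    and undefined Rsq. Gate: Rsq strictly greater than ``rsq_gate``
    accepts; the boundary value rejects.
    """
    if track.n_frames < 3:
        raise ValueError("an exponential fit needs at least 3 frames")
    t_full, a_full = track.times, track.areas
    if np.ptp(a_full) == 0:
        return FitResult(
            colony_id=track.colony_id,
            A=float(a_full[0]),
            B=0.0,
            rsq=float("nan"),
            status="non_growing",
            rejection_reason="constant area",
            n_points=track.n_frames,
            window_hours=float(t_full[-1] - t_full[0]),
        )

    t, a = t_full, a_full
    A, B = _log_ols(t, a)
    for _ in range(3):
        if method == "area":
            try:
                popt, _ = optimize.curve_fit(
                    lambda x, A_, B_: A_ * np.exp(B_ * x), t, a, p0=[A, B], maxfev=10000
                )
                A, B = float(popt[0]), float(popt[1])
            except RuntimeError:
                logger.warning("colony %d: area-scale fit did not converge; using log-OLS", track.colony_id)
        # instantaneous-rate window: cap the fitted span at ~max_generations
        # doublings of the current rate estimate, counted from the start
        if B > 0 and B * (t[-1] - t[0]) > max_generations * LN2 + 1e-12:
            cutoff = t[0] + max_generations * LN2 / B
            keep = t_full <= cutoff + 1e-12
            if keep.sum() < 3:
                keep = np.zeros_like(keep)
                keep[:3] = True
            if keep.sum() == t.size:
                break
            t, a = t_full[keep], a_full[keep]
            A, B = _log_ols(t, a)
        else:
            break

    pred = A * np.exp(B * t)
    ss_res = float(np.sum((a - pred) ** 2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    rsq = 1.0 - ss_res / ss_tot
    status = "accepted" if rsq > rsq_gate else "rejected_rsq"
    reason = "" if status == "accepted" else f"Rsq {rsq:.4f} <= {rsq_gate}"
    return FitResult(
        colony_id=track.colony_id,
        A=A,
        B=B,
        rsq=rsq,
        status=status,
        rejection_reason=reason,
        n_points=int(t.size),
        window_hours=float(t[-1] - t[0]),
    )


def apply_exclusions(fits, tracks, field_bounds: tuple | None = None, *, rsq_gate: float = 0.95) -> list:
    """Final status as a pure function of (Rsq, flags).

    Tracks flagged ``edge_proximal`` or ``merged`` are rejected regardless
    of fit quality. Unflagged fits are re-gated on Rsq. If ``field_bounds``
    (height, width) is given and a track has centroids, edge proximity is
    recomputed for tracks read from tables that carry no flags.
    """
    by_id = {tr.colony_id: tr for tr in tracks}
    out = []
    for fit in fits:
        track = by_id.get(fit.colony_id)
        flags = set(track.flags) if track is not None else set()
        if field_bounds is not None and track is not None and track.centroids is not None:
            h, w = field_bounds
            radii = np.sqrt(track.areas / np.pi)
            cy, cx = track.centroids[:, 0], track.centroids[:, 1]
            if np.any((cy - radii < 10) | (cx - radii < 10) | (cy + radii > h - 10) | (cx + radii > w - 10)):
                flags.add("edge_proximal")
        excl = flags & {"edge_proximal", "merged"}
        if excl:
            out.append(replace(fit, status="rejected_exclusion", rejection_reason=",".join(sorted(excl))))
        elif fit.status == "non_growing":
            out.append(fit)
        elif fit.rsq > rsq_gate:
            out.append(replace(fit, status="accepted", rejection_reason=""))
        else:
            out.append(replace(fit, status="rejected_rsq", rejection_reason=f"Rsq {fit.rsq:.4f} <= {rsq_gate}"))
    return out


def _review_diagnostics(t: np.ndarray, area: np.ndarray, alpha: float):
    """Decide whether a sub-gate track is exponential growth plus noise.

    Log-scale linear fit; accept iff (i) the slope is significantly
    positive, (ii) adding a quadratic term is not significant (no
    systematic curvature away from a single exponential), and (iii) the
    residuals show no significant lag-1 autocorrelation (no unmodelled
    structure). All tests at level ``alpha``.
    """
    n = t.size
    y = np.log(area)
    X = np.column_stack([np.ones(n), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n - 2)
    se_slope = np.sqrt(s2 / np.sum((t - t.mean()) ** 2))
    if se_slope == 0:
        return False, "zero residual variance"
    p_pos = stats.t.sf(beta[1] / se_slope, n - 2)
    if p_pos > alpha:
        return False, f"slope not significantly positive (p={p_pos:.3g})"
    X2 = np.column_stack([np.ones(n), t, t**2])
    b2, *_ = np.linalg.lstsq(X2, y, rcond=None)
    r2 = y - X2 @ b2
    s2q = float(r2 @ r2) / (n - 3)
    cov = s2q * np.linalg.inv(X2.T @ X2)
    t_quad = b2[2] / np.sqrt(cov[2, 2]) if cov[2, 2] > 0 else 0.0
    p_quad = 2 * stats.t.sf(abs(t_quad), n - 3)
    if p_quad < alpha:
        return False, f"significant curvature (p={p_quad:.3g})"
    rr = resid - resid.mean()
    denom = float(rr @ rr)
    ac1 = float(rr[1:] @ rr[:-1]) / denom if denom > 0 else 0.0
    if abs(ac1) > stats.norm.ppf(1 - alpha / 2) / np.sqrt(n):
        return False, f"autocorrelated residuals (r1={ac1:.2f})"
    return True, "consistent with exponential growth plus uncorrelated noise"


def review_rejected(fits, tracks, *, alpha: float = 0.01):
    """Automated review of fits rejected by the Rsq gate.

    Stands in for by-hand assessment of sub-gate fits: a rejected track is
    rescued (status ``accepted_review``) when its log-area series is
    statistically consistent with single-exponential growth — positive
    slope, no curvature, white residuals — so that noisy slow growers are
    not systematically discarded while non-exponential tracks stay out.
    Returns ``(fits, queue)`` where ``queue`` lists every reviewed fit and
    the decision taken, for audit.
    """
    by_id = {tr.colony_id: tr for tr in tracks}
    out, queue = [], []
    for fit in fits:
        if fit.status != "rejected_rsq":
            out.append(fit)
            continue
        track = by_id.get(fit.colony_id)
        if track is None or track.n_frames < 6 or np.any(track.areas <= 0):
            out.append(fit)
            queue.append({"colony_id": fit.colony_id, "rsq": fit.rsq, "decision": "rejected",
                          "reason": "too few points for review"})
            continue
        ok, reason = _review_diagnostics(track.times, track.areas, alpha)
        if ok:
            out.append(replace(fit, status="accepted_review", rejection_reason=""))
        else:
            out.append(replace(fit, rejection_reason=reason))
        queue.append({"colony_id": fit.colony_id, "rsq": fit.rsq,
                      "decision": "accepted_review" if ok else "rejected", "reason": reason})
    return out, queue


# ---------------------------------------------------------------------------
# distribution summary
# ---------------------------------------------------------------------------


def summarize_distribution(
    fits,
    *,
    n_bins: int = 20,
    bootstrap_reps: int = 200,
    seed: int = 0,
    min_colonies: int = 100,
) -> GrowthRateDistribution:
    """Histogram and moments of the accepted growth rates.

    Per-bin error bars are bootstrap SDs over ``bootstrap_reps`` resamples;
    SEM = SD/√n. Measurements with fewer than ``min_colonies`` accepted
    colonies raise a warning (they are reported, not discarded). A
    subsample-convergence diagnostic records the mean of random subsets of
    increasing size; convergence to within the SEM indicates the sample
    represents the distribution.
    """
    rates = np.array([f.B for f in fits if f.status in ACCEPTED_STATUSES], dtype=float)
    if rates.size == 0:
        raise DegenerateDistributionError("no accepted fits to summarize")
    if rates.size < min_colonies:
        warnings.warn(
            f"only {rates.size} accepted colonies (< {min_colonies}); summary may be unreliable",
            stacklevel=2,
        )
    counts, edges = np.histogram(rates, bins=n_bins)
    rng = np.random.default_rng(seed)
    n = rates.size
    boot_counts = np.empty((bootstrap_reps, counts.size))
    boot_mean = np.empty(bootstrap_reps)
    boot_cv = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        sample = rng.choice(rates, size=n, replace=True)
        boot_counts[b] = np.histogram(sample, bins=edges)[0]
        m = sample.mean()
        boot_mean[b] = m
        boot_cv[b] = sample.std(ddof=1) / m if m != 0 else np.nan
    mean = float(rates.mean())
    sd = float(rates.std(ddof=1)) if n > 1 else 0.0
    sizes = np.unique(np.clip([max(n // 16, 5), n // 8, n // 4, n // 2, n], 1, n))
    # average each subset size over 20 random draws so the diagnostic's own
    # noise (~SEM/sqrt(20)) stays well below the SEM it is compared against
    sub_means = np.array(
        [float(np.mean([rng.choice(rates, size=s, replace=False).mean() for _ in range(20)])) for s in sizes]
    )
    return GrowthRateDistribution(
        rates=rates,
        bin_edges=edges,
        counts=counts,
        bin_bootstrap_sd=boot_counts.std(axis=0),
        mean=mean,
        sd=sd,
        sem=sd / np.sqrt(n),
        cv=sd / mean if mean != 0 else float("nan"),
        cv_bootstrap_se=float(np.nanstd(boot_cv)),
        mean_bootstrap_se=float(boot_mean.std()),
        subsample_sizes=sizes,
        subsample_means=sub_means,
    )


def fraction_exponential(fits) -> float:
    """accepted / (accepted + non_growing + rejected_rsq).

    Positionally excluded colonies are removed from the denominator; review
    -rescued fits count as accepted.
    """
    num = sum(1 for f in fits if f.status in ACCEPTED_STATUSES)
    den = num + sum(1 for f in fits if f.status in ("non_growing", "rejected_rsq"))
    if den == 0:
        raise ValueError("no non-excluded fits")
    return num / den


def run_growth_pipeline(
    tracks,
    *,
    rsq_gate: float = 0.95,
    max_generations: float = 3.0,
    review: bool = True,
    review_alpha: float = 0.01,
    field_bounds: tuple | None = None,
    n_bins: int = 20,
    bootstrap_reps: int = 200,
    seed: int = 0,
):
    """Fit, gate, review and summarize a collection of tracks.

    Returns ``(fits, distribution, review_queue)``.
    """
    fits = [fit_exponential(tr, rsq_gate=rsq_gate, max_generations=max_generations) for tr in tracks]
    fits = apply_exclusions(fits, tracks, field_bounds, rsq_gate=rsq_gate)
    queue: list = []
    if review:
        fits, queue = review_rejected(fits, tracks, alpha=review_alpha)
    dist = summarize_distribution(fits, n_bins=n_bins, bootstrap_reps=bootstrap_reps, seed=seed)
    return fits, dist, queue
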