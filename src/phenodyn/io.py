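"""File I/O, run configuration and the pipeline driver.

Tables are CSV with a one-line header and fixed column names; image stacks
are TIFF; summaries are JSON. Every run writes a manifest recording the
fully resolved configuration, the global seed and package versions, and
identical (config, seed) pairs produce byte-identical outputs. All
randomness flows from the single global seed through named per-stage
sub-streams (see :mod:`phenodyn._random`).
"""

from __future__ import annotations

import dataclasses
import glob as globmod
import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage import io as skio

from . import __version__
from ._random import substream_seed
from .errors import FormatError, ParseError
from .growthfit import ColonyTrack

logger = logging.getLogger(__name__)

AREA_COLUMNS = ("colony_id", "time_h", "area_px")
CENTROID_COLUMNS = ("centroid_row", "centroid_col")

__all__ = [
    "RunConfig",
    "read_area_table",
    "write_area_table",
    "read_image_stack",
    "write_image_stack",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# area tables
# ---------------------------------------------------------------------------


def read_area_table(path) -> list:
    """Read colony tracks from a delimited table.

    Expects columns ``colony_id, time_h, area_px`` (centroid columns
    optional). Rows are taken in file order per colony; duplicated
    (colony, time) pairs or non-monotone times raise :class:`ParseError`
    naming the offending line (line numbers include the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: cannot parse table: {exc}") from exc
    missing = [c for c in AREA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    has_centroid = all(c in df.columns for c in CENTROID_COLUMNS)
    tracks = []
    for cid, grp in df.groupby("colony_id", sort=True):
        times = grp["time_h"].to_numpy(float)
        lines = grp.index.to_numpy() + 2  # +1 header, +1 one-based
        bad = np.nonzero(np.diff(times) <= 0)[0]
        if bad.size:
            line = lines[bad[0] + 1]
            if times[bad[0] + 1] == times[bad[0]]:
                raise ParseError(f"{path}: line {line}: duplicated time for colony {cid}")
            raise ParseError(f"{path}: line {line}: non-monotone time for colony {cid}")
        neg = np.nonzero(grp["area_px"].to_numpy(float) <= 0)[0]
        if neg.size:
            raise ParseError(f"{path}: line {lines[neg[0]]}: non-positive area for colony {cid}")
        centroids = grp[list(CENTROID_COLUMNS)].to_numpy(float) if has_centroid else None
        tracks.append(
            ColonyTrack(
                colony_id=int(cid),
                times=times,
                areas=grp["area_px"].to_numpy(float),
                centroids=centroids,
            )
        )
    return tracks


def write_area_table(tracks, path) -> None:
    """Write tracks in the format :func:`read_area_table` reads back."""
    rows = []
    for tr in sorted(tracks, key=lambda t: t.colony_id):
        for k in range(tr.n_frames):
            row = {"colony_id": tr.colony_id, "time_h": tr.times[k], "area_px": tr.areas[k]}
            if tr.centroids is not None:
                row["centroid_row"] = tr.centroids[k][0]
                row["centroid_col"] = tr.centroids[k][1]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

_NUM = re.compile(r"\d+")


def _numeric_key(name: str):
    """Sort key ordering frame2 before frame10: digit runs compare as ints."""
    parts = _NUM.split(name)
    nums = [int(m) for m in _NUM.findall(name)]
    key = []
    for text, num in zip(parts, nums + [None]):
        key.append(text)
        if num is not None:
            key.append(num)
    return tuple(str(k) if isinstance(k, str) else f"{k:020d}" for k in key)


def read_image_stack(path) -> np.ndarray:
    """Read frames from a TIFF stack, a glob pattern, or a directory.

    A file sequence is ordered numerically (``frame2`` precedes
    ``frame10``). All frames must share one shape.
    """
    path = str(path)
    p = Path(path)
    if p.is_file():
        frames = tifffile.imread(p)
        if frames.ndim == 2:
            frames = frames[None]
        return frames
    if p.is_dir():
        files = [str(f) for f in p.iterdir() if f.suffix.lower() in (".tif", ".tiff", ".png")]
    else:
        files = globmod.glob(path)
    if not files:
        raise FormatError(f"no input frames match {path!r}")
    files.sort(key=_numeric_key)
    imgs = [np.asarray(skio.imread(f)) for f in files]
    shapes = {im.shape for im in imgs}
    if len(shapes) > 1:
        raise FormatError(f"mixed frame shapes in {path!r}: {sorted(shapes)}")
    return np.stack(imgs)


def write_image_stack(frames, path) -> None:
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))


# ---------------------------------------------------------------------------
# run configuration and pipeline driver
# ---------------------------------------------------------------------------

_KNOWN_STAGES = ("synth", "simulate", "fit-growth", "scale", "assay")


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one reproducible run.

    Per-stage parameter blocks are plain dicts forwarded to the stage
    entry points; the global ``seed`` is fanned out to named per-stage
    sub-streams so no stage reads ambient randomness.
    """

    stages: list
    outdir: str = "phenodyn_out"
    seed: int = 0
    log_level: str = "INFO"
    synth: dict = dataclasses.field(default_factory=dict)
    simulate: dict = dataclasses.field(default_factory=dict)
    fit: dict = dataclasses.field(default_factory=dict)
    scale: dict = dataclasses.field(default_factory=dict)
    assay: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        expanded = []
        for st in self.stages:
            if st == "all":
                expanded.extend(_KNOWN_STAGES)
            elif st in _KNOWN_STAGES:
                expanded.append(st)
            else:
                raise ValueError(f"unknown stage {st!r}; choose from {_KNOWN_STAGES + ('all',)}")
        self.stages = expanded

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_dump(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _stage_synth(config: RunConfig, outdir: Path) -> dict:
    from . import synthgen

    params = dict(config.synth)
    make_images = params.pop("images", False)
    gconf = synthgen.GeneratorConfig(seed=substream_seed(config.seed, "synth"), **params)
    sample = synthgen.gen_growth_rates(gconf)
    tracks = synthgen.gen_colony_trajectories(sample, gconf)
    write_area_table(tracks, outdir / "areas.csv")
    pd.DataFrame(
        {
            "colony_id": np.arange(gconf.n_cells),
            "true_rate": sample.rates,
            "nongrower": sample.nongrower,
            "reclassified": sample.reclassified,
        }
    ).to_csv(outdir / "truth.csv", index=False)
    out = {"areas": "areas.csv", "truth": "truth.csv", "n_tracks": len(tracks)}
    if make_images:
        stack = synthgen.gen_microcolony_images(tracks, gconf)
        write_image_stack(stack.frames, outdir / "images.tif")
        out["images"] = "images.tif"
    return out


def _stage_simulate(config: RunConfig, outdir: Path) -> dict:
    from . import popsim

    params = dict(config.simulate)
    params.setdefault("horizon_generations", 5.0)
    sconf = popsim.SimConfig(seed=substream_seed(config.seed, "simulate"), record_lineages=False, **params)
    traj = popsim.simulate(sconf)
    pd.DataFrame(
        {
            "time": traj.times,
            "size": traj.sizes,
            "mean_rate": traj.mean_rate,
            "sd_rate": traj.sd_rate,
            "generations": traj.generations,
            "frac_growing": traj.frac_growing,
        }
    ).to_csv(outdir / "trajectory.csv", index=False)
    summary = {
        "status": traj.status,
        "final_generations": float(traj.generations[-1]),
        "initial_mean_rate": float(traj.mean_rate[0]),
        "final_mean_rate": float(traj.mean_rate[-1]),
        "relative_mean_rate_increase": float(traj.mean_rate[-1] / traj.mean_rate[0] - 1.0),
        "rate_units": "1/simulation-time",
    }
    _json_dump(summary, outdir / "sim_summary.json")
    return {"trajectory": "trajectory.csv", "summary": summary}


def _stage_fit(config: RunConfig, outdir: Path) -> dict:
    from . import growthfit

    params = dict(config.fit)
    table = params.pop("input", None) or outdir / "areas.csv"
    tracks = read_area_table(table)
    fits, dist, queue = growthfit.run_growth_pipeline(
        tracks, seed=substream_seed(config.seed, "fit-growth"), **params
    )
    pd.DataFrame(
        [
            {
                "colony_id": f.colony_id,
                "A": f.A,
                "B": f.B,
                "rsq": f.rsq,
                "status": f.status,
                "rejection_reason": f.rejection_reason,
            }
            for f in fits
        ]
    ).to_csv(outdir / "fits.csv", index=False)
    pd.DataFrame(queue).to_csv(outdir / "review_queue.csv", index=False)
    summary = {
        "n_accepted": int(dist.n),
        "mean_rate_per_h": dist.mean,
        "sem": dist.sem,
        "sd": dist.sd,
        "cv": dist.cv,
        "fraction_exponential": growthfit.fraction_exponential(fits),
        "histogram": {
            "bin_edges": dist.bin_edges.tolist(),
            "counts": dist.counts.tolist(),
            "bin_bootstrap_sd": dist.bin_bootstrap_sd.tolist(),
        },
    }
    _json_dump(summary, outdir / "growth_summary.json")
    return {"fits": "fits.csv", "review_queue": "review_queue.csv", "summary": summary}


def _stage_scale(config: RunConfig, outdir: Path) -> dict:
    from . import scaling, synthgen

    params = dict(config.scale)
    law = scaling.QuadraticLaw(*params.pop("variance_law", (0.0, 100.0, 0.5)))
    means = params.pop("means", [200.0, 400.0, 800.0, 1200.0, 1600.0])
    snaps = synthgen.gen_fluorescence_snapshots(
        means, law, seed=substream_seed(config.seed, "scale"), **params
    )
    pd.DataFrame(
        [(s.time_label, v) for s in snaps for v in s.values], columns=["time_label", "value"]
    ).to_csv(outdir / "snapshots.csv", index=False)
    collapse = scaling.collapse_distance(snaps)
    fit = scaling.fit_variance_mean(snaps)
    summary = {
        "collapse_max_distance": collapse.max_distance,
        "variance_mean_law": {"a": fit.law.a, "b": fit.law.b, "c": fit.law.c, "rsq": fit.rsq},
        "snapshot_means": [s.mean for s in snaps],
        "snapshot_variances": [s.variance for s in snaps],
    }
    _json_dump(summary, outdir / "scaling_summary.json")
    return {"snapshots": "snapshots.csv", "summary": summary}


def _stage_assay(config: RunConfig, outdir: Path) -> dict:
    from . import assays, synthgen

    params = dict(config.assay)
    record = synthgen.gen_plate_counts(
        params.pop("n_plated", 200),
        params.pop("frac_adapted", 0.5),
        seed=substream_seed(config.seed, "assay"),
        **params,
    )
    est = assays.fraction_adapted(record)
    summary = {
        "glucose_counts": record.glucose_counts.tolist(),
        "ypd_counts": record.ypd_counts.tolist(),
        "fraction_adapted": est.value,
        "se": est.se,
    }
    _json_dump(summary, outdir / "assay_summary.json")
    return {"summary": summary}


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "simulate": _stage_simulate,
    "fit-growth": _stage_fit,
    "scale": _stage_scale,
    "assay": _stage_assay,
}


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write their outputs plus a manifest.

    Returns a dict of per-stage outputs. Identical (config, seed) pairs
    produce byte-identical files; the manifest deliberately records no
    timestamps.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {}
    for stage in config.stages:
        logger.info("running stage %s", stage)
        outputs[stage] = _STAGE_FUNCS[stage](config, outdir)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "phenodyn": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages_run": list(config.stages),
    }
    _json_dump(manifest, outdir / "manifest.json")
    return outputs
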