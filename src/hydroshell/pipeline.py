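"""Multi-state-point orchestration, tidy output tables, and TMD extraction.

A run takes a set of frame files, each tagged with its state point
(temperature in K, molar density in mol/l), executes the requested
analyses, and writes one tidy TSV per observable plus a JSON manifest
sufficient to reproduce the run.

The temperature of maximum density (TMD) is recovered from an isochoric
pressure series: at fixed volume, the TMD is the temperature minimising
p(T), located here by a quadratic fit through the sampled minimum and its
neighbours.  Pressures are consumed from input tables only — this package
computes structure, not thermodynamics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .frames import BoxedFrame, StatePointSeries, read_frames
from .hbonds import asymmetry, motif_populations
from .neighbors import build_neighbor_table, coordination_number, rdf
from .order import local_structure_index, order_parameters, summarize

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "StatePointInput",
    "run",
    "TMDResult",
    "tmd_from_isochore",
    "series_table",
]


@dataclasses.dataclass
class StatePointInput:
    path: str
    temperature: float
    molar_density: float


@dataclasses.dataclass
class RunConfig:
    """Validated configuration for one analysis run."""

    inputs: list[StatePointInput]
    output_dir: str
    analyses: dict[str, dict[str, Any]] = dataclasses.field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inputs = [StatePointInput(**item) for item in raw["inputs"]]
        return cls(
            inputs=inputs,
            output_dir=raw["output_dir"],
            analyses=raw.get("analyses", {}),
            seed=int(raw.get("seed", 0)),
        )


_KNOWN_ANALYSES = ("rdf", "order", "hbonds", "ranks")


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the configured analyses and write tidy TSV outputs.

    Returns a mapping observable name → written path.  Any stage failure
    aborts with the stage name and state point in the error message.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = set(config.analyses) - set(_KNOWN_ANALYSES)
    if unknown:
        raise ValueError(f"unknown analyses requested: {sorted(unknown)}")

    for item in config.inputs:
        if not Path(item.path).exists():
            raise FileNotFoundError(f"input frame file not found: {item.path}")

    rdf_rows, order_rows, motif_rows, rank_rows = [], [], [], []
    for item in config.inputs:
        frames = read_frames(item.path)
        logger.info(
            "state point (T=%s K, rho=%s mol/l): %d frames, %d molecules",
            item.temperature, item.molar_density, len(frames), frames[0].n_molecules,
        )
        for stage, params in config.analyses.items():
            try:
                if stage == "rdf":
                    res = rdf(
                        frames,
                        bin_width=params.get("bin_width", 0.05),
                        r_max=params.get("r_max"),
                    )
                    for r, g in zip(res.bin_centers, res.g):
                        rdf_rows.append((item.temperature, item.molar_density, r, g))
                elif stage == "order":
                    cutoff = params.get("lsi_cutoff", 3.7)
                    max_rank = params.get("max_rank", 30)
                    per_frame = {"q": [], "lsi": [], "d5": []}
                    for frame in frames:
                        table = build_neighbor_table(frame, max_rank=max_rank)
                        df = order_parameters(frame, table, lsi_cutoff=cutoff)
                        for key in per_frame:
                            per_frame[key].append(df[key].to_numpy())
                    for key, vals in per_frame.items():
                        s = summarize(vals, observable=key,
                                      temperature=item.temperature,
                                      molar_density=item.molar_density)
                        order_rows.append(
                            (item.temperature, item.molar_density, key, s.mean, s.stderr)
                        )
                elif stage == "hbonds":
                    dist = motif_populations(
                        frames,
                        temperature=item.temperature,
                        molar_density=item.molar_density,
                        **{k: v for k, v in params.items()
                           if k in ("roo_max", "angle_max", "angle_convention")},
                    )
                    for label, p in sorted(dist.probabilities.items()):
                        motif_rows.append((item.temperature, item.molar_density, label, p))
                    motif_rows.append(
                        (item.temperature, item.molar_density, "asymmetry", asymmetry(dist))
                    )
                elif stage == "ranks":
                    from .neighbors import rank_distribution

                    k = params.get("k", 5)
                    bins = np.arange(0.0, params.get("r_max", 8.0), params.get("bin_width", 0.05))
                    rd = rank_distribution(frames, k=k, bins=bins)
                    centers = 0.5 * (rd.bin_edges[:-1] + rd.bin_edges[1:])
                    for r, p in zip(centers, rd.probabilities):
                        rank_rows.append((item.temperature, item.molar_density, k, r, p))
            except Exception as exc:
                raise RuntimeError(
                    f"stage '{stage}' failed at state point "
                    f"(T={item.temperature} K, rho={item.molar_density} mol/l): {exc}"
                ) from exc

    written: dict[str, Path] = {}

    def _write(name: str, rows: list, columns: list[str]) -> None:
        if not rows:
            return
        path = outdir / f"{name}.tsv"
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
        written[name] = path

    _write("rdf", rdf_rows, ["temperature", "molar_density", "r", "g"])
    _write("order", order_rows, ["temperature", "molar_density", "observable", "mean", "stderr"])
    _write("motifs", motif_rows, ["temperature", "molar_density", "motif", "probability"])
    _write("ranks", rank_rows, ["temperature", "molar_density", "k", "r", "probability"])

    manifest = {
        "package": "hydroshell",
        "version": __version__,
        "seed": config.seed,
        "inputs": [dataclasses.asdict(i) for i in config.inputs],
        "analyses": config.analyses,
        "outputs": {k: str(v) for k, v in written.items()},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written["manifest"] = manifest_path
    return written


@dataclasses.dataclass
class TMDResult:
    """Temperature of maximum density with its uncertainty (both K)."""

    temperature: float
    uncertainty: float
    window: tuple[int, int]  # index range of the fitted points


def tmd_from_isochore(series: StatePointSeries, window: int = 3) -> TMDResult:
    """Locate the pressure minimum of an isochore by a local quadratic fit.

    The minimum sample must be interior (a minimum at an endpoint is not
    bracketed and raises).  A parabola is fitted through ``window`` points
    centred on the minimum; the vertex is the TMD.  With per-point error
    bars the vertex uncertainty is propagated from the weighted
    least-squares covariance (delta method); without them it falls back to
    half the local temperature spacing.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 points to bracket a minimum")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    t, p = series.temperatures, series.values
    i_min = int(np.argmin(p))
    if i_min == 0 or i_min == len(series) - 1:
        raise ValueError(
            f"minimum not bracketed: lowest pressure at endpoint T={t[i_min]} K"
        )
    half = window // 2
    lo = max(0, i_min - half)
    hi = min(len(series), i_min + half + 1)
    tw, pw = t[lo:hi], p[lo:hi]

    if series.errors is not None:
        ew = series.errors[lo:hi]
        wgt = 1.0 / ew**2
        coeffs, cov = np.polyfit(tw, pw, 2, w=np.sqrt(wgt), cov="unscaled")
    else:
        coeffs = np.polyfit(tw, pw, 2)
        cov = None
    a, b, _ = coeffs
    if a <= 0:
        raise ValueError("fitted parabola is not convex; no interior minimum")
    vertex = -b / (2.0 * a)
    if cov is not None:
        # delta method: T* = -b/2a, grad = (b/2a², -1/2a, 0)
        grad = np.array([b / (2.0 * a**2), -1.0 / (2.0 * a), 0.0])
        sigma = float(np.sqrt(grad @ cov @ grad))
    else:
        sigma = float(0.5 * np.mean(np.diff(tw)))
    return TMDResult(temperature=float(vertex), uncertainty=sigma, window=(lo, hi))


def series_table(observable: str, records: Sequence[dict]) -> pd.DataFrame:
    """Long-format observable table sorted by density then temperature.

    Each record needs ``temperature``, ``molar_density`` and ``value``
    keys (``stderr`` optional).  Duplicate state points are a hard error.
    """
    if not records:
        raise ValueError("records must be non-empty")
    df = pd.DataFrame(list(records))
    for col in ("temperature", "molar_density", "value"):
        if col not in df.columns:
            raise ValueError(f"record missing required key {col!r}")
    if "stderr" not in df.columns:
        df["stderr"] = np.nan
    dup = df.duplicated(subset=["temperature", "molar_density"])
    if dup.any():
        pts = df.loc[dup, ["temperature", "molar_density"]].to_records(index=False)
        raise ValueError(f"duplicate state points: {list(pts)}")
    df.insert(2, "observable", observable)
    return (
        df[["temperature", "molar_density", "observable", "value", "stderr"]]
        .sort_values(["molar_density", "temperature"], kind="stable")
        .reset_index(drop=True)
    )
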