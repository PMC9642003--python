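"""End-to-end cleaning pipeline and its configuration.

The picking stages produce an oversampled table which is aligned in an
external STA package (Dynamo / RELION); the pipeline here consumes the
*aligned* table and runs the cleaning cascade: fold shifts into positions,
remove converged duplicates, normalise CC against latitude and threshold,
then lattice neighbour filtering.  Every stage logs particle counts in/out
and the report is a deterministic JSON document.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ccnorm, dedup, lattice
from .io import (
    read_dynamo_table,
    read_motl,
    read_star,
    write_dynamo_table,
    write_motl,
    write_star,
)
from .particles import ParticleSet

__all__ = ["PipelineConfig", "run_pipeline", "read_table", "write_table"]


@dataclass
class PipelineConfig:
    """Flat configuration for the cleaning pipeline (YAML round-trippable)."""

    input_table: str = ""
    output_prefix: str = "cleaned"
    voxel_size: float = 10.0  # Angstrom / voxel
    min_separation: float = 6.0  # voxels; below expected particle spacing
    cc_degree: int = 3
    cc_min_per_object: int = 50
    cc_low: float = -np.inf
    cc_high: float = np.inf
    cc_use_adjusted: bool = True
    neighbour_box: int = 33  # odd: the grid needs a centre voxel
    neighbour_max_dist: float = 15.0
    neighbour_sigma: float = 0.5
    neighbour_level: float = 0.2
    min_neighbours: int = 2  # calibrated on the synthetic lattice; 1 = keep any supported particle
    seed: int = 0
    formats: list = field(default_factory=lambda: ["tbl"])

    def validate(self) -> None:
        for name in ("voxel_size", "min_separation", "neighbour_max_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cc_low > self.cc_high:
            raise ValueError("cc_low exceeds cc_high")

    def to_file(self, path) -> None:
        d = asdict(self)
        d["cc_low"] = float(d["cc_low"])
        d["cc_high"] = float(d["cc_high"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)


def read_table(path, voxel_size: float = 1.0) -> ParticleSet:
    """Dispatch on extension: .tbl (Dynamo), .em (motive list), .star."""
    suffix = Path(path).suffix.lower()
    if suffix == ".tbl":
        return read_dynamo_table(path, voxel_size)
    if suffix == ".em":
        return read_motl(path, voxel_size)
    if suffix == ".star":
        return read_star(path, voxel_size)
    raise ValueError(f"unrecognised particle table extension: {path}")


def write_table(pset: ParticleSet, path) -> None:
    suffix = Path(path).suffix.lower()
    if suffix == ".tbl":
        write_dynamo_table(pset, path)
    elif suffix == ".em":
        write_motl(pset, path)
    elif suffix == ".star":
        write_star(pset, path)
    else:
        raise ValueError(f"unrecognised particle table extension: {path}")


def run_pipeline(config: PipelineConfig, pset: ParticleSet | None = None) -> dict:
    """Run the cleaning cascade; returns the machine-readable report.

    ``pset`` may be passed directly (e.g. synthetic data); otherwise
    ``config.input_table`` is read.  Outputs ``<prefix>.<fmt>`` for every
    requested format plus ``<prefix>_report.json``.
    """
    config.validate()
    if pset is None:
        if not config.input_table:
            raise ValueError("stage input: no input table configured")
        pset = read_table(config.input_table, config.voxel_size)
    if len(pset) == 0:
        raise ValueError("stage input: empty particle set")

    report: dict = {"config": {k: str(v) for k, v in asdict(config).items()}, "stages": []}

    def stage(name: str, fn, current: ParticleSet, **params) -> ParticleSet:
        try:
            result = fn(current)
        except Exception as exc:
            raise RuntimeError(f"stage {name}: {exc}") from exc
        report["stages"].append(
            {"stage": name, "in": len(current), "out": len(result), "params": params}
        )
        return result

    s = stage("apply_shifts", dedup.apply_shifts, pset)
    s = stage(
        "remove_duplicates",
        lambda p: dedup.remove_duplicates(p, config.min_separation),
        s,
        min_separation=config.min_separation,
    )

    fits = ccnorm.fit_cc_theta(s, config.cc_degree, config.cc_min_per_object)
    s = stage(
        "adjust_cc",
        lambda p: ccnorm.adjust_cc(p, fits),
        s,
        degree=config.cc_degree,
        min_per_object=config.cc_min_per_object,
    )
    s = stage(
        "threshold_cc",
        lambda p: ccnorm.threshold_cc(
            p, config.cc_low, config.cc_high, config.cc_use_adjusted
        ),
        s,
        low=float(config.cc_low),
        high=float(config.cc_high),
        use_adjusted=config.cc_use_adjusted,
    )

    nmap = lattice.compute_neighbour_map(s, config.neighbour_box, config.neighbour_max_dist)
    mask = lattice.binarize_map(nmap, config.neighbour_sigma, config.neighbour_level)
    s = stage(
        "filter_by_neighbours",
        lambda p: lattice.filter_by_neighbours(
            p, mask, config.neighbour_max_dist, config.min_neighbours
        ),
        s,
        box=config.neighbour_box,
        max_dist=config.neighbour_max_dist,
        sigma=config.neighbour_sigma,
        level=config.neighbour_level,
        min_neighbours=config.min_neighbours,
    )

    for fmt in config.formats:
        write_table(s, f"{config.output_prefix}.{fmt}")
    with open(f"{config.output_prefix}_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
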