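"""Chimera marker-set (.cmm) reader.

Tube axes traced with Chimera's volume tracer are saved as XML marker sets
whose coordinates are in physical units (Angstrom); dividing by the target
tomogram's voxel size converts them to voxels.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np

__all__ = ["MarkerTrace", "read_cmm", "write_cmm"]


@dataclass
class MarkerTrace:
    """An ordered polyline of markers (e.g. a traced tube axis)."""

    name: str
    points: np.ndarray  # (N, 3), Angstrom unless units == "voxels"
    radius: float | None = None
    units: str = "angstrom"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 1:
            raise ValueError("a marker trace needs at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("marker coordinates must be finite")

    def in_voxels(self, voxel_size: float) -> "MarkerTrace":
        """Convert physical coordinates (and radius) to voxels."""
        if self.units == "voxels":
            return self
        if voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        return MarkerTrace(
            name=self.name,
            points=self.points / voxel_size,
            radius=None if self.radius is None else self.radius / voxel_size,
            units="voxels",
        )


def read_cmm(path, units: str = "angstrom") -> MarkerTrace:
    """Read a marker set; markers are ordered by their ``id`` attribute."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"{path}: malformed .cmm XML: {exc}") from exc
    marker_set = root if root.tag == "marker_set" else root.find("marker_set")
    if marker_set is None:
        raise ValueError(f"{path}: no marker_set element")
    markers = marker_set.findall("marker")
    if not markers:
        raise ValueError(f"{path}: no marker elements")
    markers.sort(key=lambda m: int(m.get("id", "0")))
    points = np.array(
        [[float(m.get(ax)) for ax in ("x", "y", "z")] for m in markers]
    )
    radii = [float(m.get("radius")) for m in markers if m.get("radius") is not None]
    return MarkerTrace(
        name=marker_set.get("name", "marker_set"),
        points=points,
        radius=float(np.mean(radii)) if radii else None,
        units=units,
    )


def write_cmm(trace: MarkerTrace, path) -> None:
    ms = ET.Element("marker_set", name=trace.name)
    for i, (x, y, z) in enumerate(trace.points, start=1):
        attrs = {"id": str(i), "x": f"{x:.6f}", "y": f"{y:.6f}", "z": f"{z:.6f}"}
        if trace.radius is not None:
            attrs["radius"] = f"{trace.radius:.6f}"
        ET.SubElement(ms, "marker", attrs)
    ET.ElementTree(ms).write(path, xml_declaration=True, encoding="unicode")
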