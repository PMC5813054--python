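"""Polygon contour containers shared by the phantom observer model and morphometry.

Coordinates are patient millimetres in the axial plane (x, y), slices are
0-based indices along the vessel axis. Polygons are implicitly closed: the
last vertex connects back to the first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

LUMEN = "lumen"
OUTER_WALL = "outer_wall"


@dataclass
class Contour:
    """One closed polygon on one slice.

    Parameters
    ----------
    slice_index : 0-based slice number along the vessel axis.
    segment : vessel segment label ("CCA", "ICA" or "ECA").
    vertices : (N, 2) array of (x_mm, y_mm) in-plane coordinates.
    role : "lumen" or "outer_wall".
    """

    slice_index: int
    segment: str
    vertices: np.ndarray
    role: str = LUMEN
    reader_id: str = "auto"
    session_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of (x, y) mm")
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")


@dataclass
class ContourSet:
    """A collection of contours of a single role (lumen or outer wall)."""

    role: str
    contours: list[Contour] = field(default_factory=list)
    reader_id: str = "auto"
    session_id: str = ""

    def add(self, contour: Contour) -> None:
        if contour.role != self.role:
            raise ValueError(f"contour role {contour.role!r} != set role {self.role!r}")
        self.contours.append(contour)

    def get(self, slice_index: int, segment: str) -> Contour:
        for c in self.contours:
            if c.slice_index == slice_index and c.segment == segment:
                return c
        raise KeyError(f"no {self.role} contour for slice {slice_index}, segment {segment}")

    def __iter__(self) -> Iterator[Contour]:
        return iter(self.contours)

    def __len__(self) -> int:
        return len(self.contours)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "role": self.role,
            "reader_id": self.reader_id,
            "session_id": self.session_id,
            "contours": [
                {
                    "slice_index": int(c.slice_index),
                    "segment": c.segment,
                    "vertices_mm": np.asarray(c.vertices).tolist(),
                }
                for c in self.contours
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ContourSet":
        payload = json.loads(Path(path).read_text())
        cs = cls(
            role=payload["role"],
            reader_id=payload.get("reader_id", "auto"),
            session_id=payload.get("session_id", ""),
        )
        for item in payload["contours"]:
            cs.add(
                Contour(
                    slice_index=item["slice_index"],
                    segment=item["segment"],
                    vertices=np.asarray(item["vertices_mm"], dtype=float),
                    role=payload["role"],
                    reader_id=cs.reader_id,
                    session_id=cs.session_id,
                )
            )
        return cs
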