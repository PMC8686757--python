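"""Scene containers: named 3D point sets with optional anchor points.

A :class:`Scene` is an ordered collection of :class:`SceneObject`s — in the
motivating application each object is one chromosome territory modelled as
a bead chain, the anchor being its centromere.  Coordinates are
unit-agnostic; the units label (default micrometres) only decorates chart
axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Scene", "SceneObject"]


@dataclass
class SceneObject:
    """One labelled 3D point set, optionally carrying an anchor point."""

    obj_id: str
    points: np.ndarray  # (n, 3)
    anchor: np.ndarray | None = None  # (3,) e.g. the centromere

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"object {self.obj_id!r}: points must be (n, 3)")
        if self.points.shape[0] < 1:
            raise ValueError(f"object {self.obj_id!r} has no points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"object {self.obj_id!r}: non-finite coordinates")
        if self.anchor is not None:
            self.anchor = np.asarray(self.anchor, dtype=float).reshape(3)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class Scene:
    """An ordered list of scene objects with unique ids.

    ``envelope`` (center, radius) optionally records the bounding sphere of
    the scene — for a modelled nucleus, the nuclear envelope — and sets a
    natural upper distance limit for charts.
    """

    objects: list[SceneObject]
    envelope: tuple[np.ndarray, float] | None = None
    units: str = "um"

    def __post_init__(self):
        ids = [o.obj_id for o in self.objects]
        if len(set(ids)) != len(ids):
            raise ValueError("object ids must be unique")
        if self.envelope is not None:
            center, radius = self.envelope
            self.envelope = (np.asarray(center, dtype=float).reshape(3), float(radius))

    @property
    def object_ids(self) -> list[str]:
        return [o.obj_id for o in self.objects]

    def __getitem__(self, obj_id: str) -> SceneObject:
        for o in self.objects:
            if o.obj_id == obj_id:
                return o
        raise KeyError(f"no object with id {obj_id!r}")

    def __contains__(self, obj_id: str) -> bool:
        return obj_id in self.object_ids

    @property
    def n_points(self) -> int:
        return sum(o.n_points for o in self.objects)

    def all_points(self) -> np.ndarray:
        """All coordinates stacked in object order, shape (N, 3)."""
        return np.vstack([o.points for o in self.objects])

    def point_object_ids(self) -> np.ndarray:
        """Object id of each stacked point, aligned with :meth:`all_points`."""
        return np.concatenate(
            [np.full(o.n_points, o.obj_id, dtype=object) for o in self.objects]
        )

    def translated(self, offset) -> "Scene":
        """A copy of the scene with ``offset`` added to every coordinate."""
        offset = np.asarray(offset, dtype=float).reshape(3)
        objs = [
            SceneObject(
                o.obj_id,
                o.points + offset,
                None if o.anchor is None else o.anchor + offset,
            )
            for o in self.objects
        ]
        env = None
        if self.envelope is not None:
            env = (self.envelope[0] + offset, self.envelope[1])
        return Scene(objs, envelope=env, units=self.units)
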