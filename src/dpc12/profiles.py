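"""Distance profiles and nearest/farthest adjacency summaries.

After full conification every point of every object sits in exactly one
Cone of Sight.  The distance profile condenses this into, per (cone,
object) pair, the minimum and maximum point distance from the anchor (the
coordinate origin after re-centering) and the fraction of the object's
points inside the cone.  These triples are the data behind one DPC12 chart
and behind the nearest/farthest-object rankings used in adjacency
analysis: objects are compared by the *minimum* bar value, i.e. by how
close their closest point comes to the anchor.

Distances are measured from the anchor, not between point sets — this is
why the central object's own bars do not start at zero: its anchor (its
centroid, or its centromere) generally coincides with no point of the
object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conification import CANONICAL_ORDER, ConifiedScene

__all__ = [
    "ProfileEntry",
    "DistanceProfile",
    "compute_profile",
    "nearest_object",
    "farthest_object",
    "profile_to_table",
]


@dataclass(frozen=True)
class ProfileEntry:
    """Min/max anchor distance and object fraction for one (cone, object)."""

    min_dist: float
    max_dist: float
    fraction: float

    def __post_init__(self):
        if not 0.0 <= self.min_dist <= self.max_dist:
            raise ValueError("need 0 <= min_dist <= max_dist")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")


@dataclass
class DistanceProfile:
    """All (cone, object) profile entries for one central object."""

    central_object_id: str
    anchor: np.ndarray
    units: str
    entries: dict[tuple[str, str], ProfileEntry]
    object_order: list[str]
    envelope_radius: float | None = None

    @property
    def cones(self) -> tuple[str, ...]:
        return CANONICAL_ORDER

    def objects_in(self, cone_label: str) -> list[str]:
        """Object ids with at least one point in ``cone_label``, in bar order."""
        return [o for o in self.object_order if (cone_label, o) in self.entries]

    def max_distance(self) -> float:
        """Largest max_dist over all entries (natural chart y-limit)."""
        return max(e.max_dist for e in self.entries.values())


def compute_profile(conified: ConifiedScene) -> DistanceProfile:
    """Compute the distance profile of a fully conified scene.

    For each (cone, object) pair with at least one point: the min and max
    Euclidean norm of the re-centered coordinates, and the object's point
    count in the cone divided by its total point count (so each object's
    fractions sum to 1 across cones).  The central object's own entries are
    included.  Pairs without points get no entry.
    """
    df = conified.to_frame()
    df["dist"] = np.linalg.norm(conified.coords, axis=1)
    totals = df.groupby("obj_id", sort=False)["dist"].size()
    grouped = df.groupby(["cos_id", "obj_id"], sort=False)["dist"].agg(
        ["min", "max", "size"]
    )
    entries: dict[tuple[str, str], ProfileEntry] = {}
    for (cone, obj), row in grouped.iterrows():
        entries[(str(cone), str(obj))] = ProfileEntry(
            min_dist=float(row["min"]),
            max_dist=float(row["max"]),
            fraction=float(row["size"] / totals[obj]),
        )
    env_r = None if conified.envelope is None else float(conified.envelope[1])
    return DistanceProfile(
        central_object_id=conified.central_object_id,
        anchor=np.asarray(conified.anchor, dtype=float),
        units=conified.units,
        entries=entries,
        object_order=list(conified.object_order),
        envelope_radius=env_r,
    )


def _overall_min(profile: DistanceProfile, obj: str) -> tuple[float, str]:
    """(min over cones of min_dist, cone of that minimum) for one object."""
    best, best_cone = np.inf, ""
    for cone in CANONICAL_ORDER:
        e = profile.entries.get((cone, obj))
        if e is not None and e.min_dist < best:
            best, best_cone = e.min_dist, cone
    return best, best_cone


def _ranked(profile: DistanceProfile, descending: bool):
    others = [o for o in profile.object_order if o != profile.central_object_id]
    rows = []
    for rank_pos, obj in enumerate(others):
        d, cone = _overall_min(profile, obj)
        if np.isfinite(d):
            rows.append((d, rank_pos, obj, cone))
    rows.sort(key=lambda r: (-r[0] if descending else r[0], r[1]))
    return [(obj, d, cone) for d, _, obj, cone in rows]


def nearest_object(profile: DistanceProfile) -> list[tuple[str, float, str]]:
    """Non-central objects ranked by ascending minimum anchor distance.

    Returns ``(obj_id, overall_min_dist, cone_of_the_minimum)`` tuples;
    the first entry is the nearest object ("the bar with the lowest min
    value").  Ties keep scene object order.
    """
    return _ranked(profile, descending=False)


def farthest_object(profile: DistanceProfile) -> list[tuple[str, float, str]]:
    """Non-central objects ranked by *descending* minimum anchor distance.

    Objects are compared by their minimum bar value (how close their
    closest point comes), not by their maximum: an object whose nearest
    point is far away is far away as a whole.
    """
    return _ranked(profile, descending=True)


def profile_to_table(profile: DistanceProfile) -> pd.DataFrame:
    """Flatten a profile to rows (central_id, cone, obj_id, min, max, fraction).

    Rows are ordered canonically by cone, then by scene object order, so
    the table is deterministic and round-trips losslessly with the profile
    reader.
    """
    rows = []
    for cone in CANONICAL_ORDER:
        for obj in profile.object_order:
            e = profile.entries.get((cone, obj))
            if e is not None:
                rows.append(
                    {
                        "central_id": profile.central_object_id,
                        "cone": cone,
                        "obj_id": obj,
                        "min": e.min_dist,
                        "max": e.max_dist,
                        "fraction": e.fraction,
                    }
                )
    return pd.DataFrame(
        rows, columns=["central_id", "cone", "obj_id", "min", "max", "fraction"]
    )
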