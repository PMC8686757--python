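"""Readers and writers for the package's delimited-text interchange formats.

* Scene CSV:      header ``obj_id,x,y,z[,is_anchor]``; one point per row,
  object order and point order meaningful, at most one anchor row
  (``is_anchor = 1``) per object — the anchor row is both a point and the
  anchor (e.g. the centromere bead).
* Assignment CSV: header ``x,y,z,obj_id,cos_id`` — the five parameters of
  every conified point, one row per point.
* Profile CSV:    header ``central_id,cone,obj_id,min,max,fraction``; the
  JSON mirror carries the same rows plus the anchor and units.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .conification import ConifiedScene
from .profiles import DistanceProfile, ProfileEntry, profile_to_table
from .scene import Scene, SceneObject

__all__ = [
    "read_scene",
    "write_scene",
    "write_assignments",
    "write_profile",
    "read_profile",
]

_FLOAT_FMT = "%.10g"


def read_scene(path, units: str = "um") -> Scene:
    """Read a scene CSV, preserving object order and point order."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"obj_id", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            line = int(np.flatnonzero(bad | df[col].isna())[0]) + 2  # + header
            raise ValueError(f"{path}: non-numeric {col!r} value at line {line}")
        df[col] = vals
    has_anchor = "is_anchor" in df.columns
    objects = []
    for obj_id in df["obj_id"].astype(str).unique():
        sub = df[df["obj_id"].astype(str) == obj_id]
        anchor = None
        if has_anchor:
            flags = sub["is_anchor"].fillna(0).astype(int)
            idx = np.flatnonzero(flags.to_numpy() == 1)
            if len(idx) > 1:
                line = int(sub.index[idx[1]]) + 2
                raise ValueError(
                    f"{path}: duplicate anchor for object {obj_id!r} at line {line}"
                )
            if len(idx) == 1:
                anchor = sub.iloc[idx[0]][["x", "y", "z"]].to_numpy(float)
        objects.append(
            SceneObject(obj_id, sub[["x", "y", "z"]].to_numpy(float), anchor=anchor)
        )
    return Scene(objects, units=units)


def write_scene(scene: Scene, path) -> None:
    """Write a scene CSV (with ``is_anchor`` column iff any object has one)."""
    any_anchor = any(o.anchor is not None for o in scene.objects)
    rows = []
    for o in scene.objects:
        flags = np.zeros(o.n_points, dtype=int)
        if o.anchor is not None:
            d = np.linalg.norm(o.points - o.anchor, axis=1)
            flags[int(np.argmin(d))] = 1
        for i in range(o.n_points):
            row = {
                "obj_id": o.obj_id,
                "x": o.points[i, 0],
                "y": o.points[i, 1],
                "z": o.points[i, 2],
            }
            if any_anchor:
                row["is_anchor"] = flags[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_assignments(conified: ConifiedScene, path) -> None:
    """Write the five-parameter assignment table, one row per point."""
    conified.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_profile(profile: DistanceProfile, path, format: str = "csv") -> None:
    """Write a distance profile as CSV or as its JSON mirror."""
    table = profile_to_table(profile)
    if format == "csv":
        # 17 significant digits: lossless float round-trip
        table.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        doc = {
            "central_object_id": profile.central_object_id,
            "anchor": [float(v) for v in profile.anchor],
            "units": profile.units,
            "object_order": list(profile.object_order),
            "envelope_radius": profile.envelope_radius,
            "entries": table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown profile format {format!r} (use 'csv' or 'json')")


def read_profile(path, format: str = "csv") -> DistanceProfile:
    """Read a profile back; CSV carries no anchor/units (defaults used)."""
    if format == "csv":
        table = pd.read_csv(path, float_precision="round_trip")
        central = str(table["central_id"].iloc[0]) if len(table) else ""
        anchor = np.zeros(3)
        units = "um"
        order: list[str] = list(dict.fromkeys(table["obj_id"].astype(str)))
        env = None
    elif format == "json":
        with open(path) as fh:
            doc = json.load(fh)
        table = pd.DataFrame(
            doc["entries"],
            columns=["central_id", "cone", "obj_id", "min", "max", "fraction"],
        )
        central = doc["central_object_id"]
        anchor = np.asarray(doc["anchor"], dtype=float)
        units = doc["units"]
        order = list(doc["object_order"])
        env = doc.get("envelope_radius")
    else:
        raise ValueError(f"unknown profile format {format!r}")
    entries = {
        (str(r.cone), str(r.obj_id)): ProfileEntry(
            float(r.min), float(r.max), float(r.fraction)
        )
        for r in table.itertuples()
    }
    return DistanceProfile(
        central_object_id=central,
        anchor=anchor,
        units=units,
        entries=entries,
        object_order=order,
        envelope_radius=env,
    )
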