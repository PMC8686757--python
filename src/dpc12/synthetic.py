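"""Synthetic scene generators and the sphere-packing benchmark.

No public dataset accompanies the method, so everything needed to exercise
it is generated here:

* uniform samples in a ball — the benchmark population for measuring how
  much of space the 12 cones cover;
* the instructional "Mouse 3D Set" (M3DS): three balls — a head and two
  asymmetrically placed ears — whose adjacency readings are known by
  construction;
* a bead-chain nucleus emulating modelled chromosome territories: chains
  of fixed-step beads random-walking inside a spherical envelope, one
  bead per chain flagged as the centromere anchor, plus a nucleolus;
* a Monte-Carlo check that the cubic-close-packing unit cell has packing
  density pi / (3 sqrt 2) ~ 0.74048, the arrangement the 12 cone
  directions are derived from.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scene import Scene, SceneObject

__all__ = [
    "sample_uniform_ball",
    "M3DSParams",
    "make_m3ds",
    "NucleusParams",
    "make_bead_chain_nucleus",
    "fcc_packing_density_mc",
]


def sample_uniform_ball(n: int, radius: float = 1.0, seed: int | None = None) -> np.ndarray:
    """``n`` i.i.d. points uniform in the closed ball of given radius.

    Direct radial method: a uniform unit direction (normalised Gaussian)
    scaled by ``radius * U**(1/3)`` — no rejection involved.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


# Directions of the top-left and top-right cone axes (unit vectors toward
# the published TL / TR generating centers); the ears sit on these rays.
_TL_DIR = np.array([-1.0, -0.68, 1.68]) / np.linalg.norm([-1.0, -0.68, 1.68])
_TR_DIR = np.array([1.0, -0.68, 1.68]) / np.linalg.norm([1.0, -0.68, 1.68])


@dataclass(frozen=True)
class M3DSParams:
    """Parameters of the Mouse 3D Set.

    The head (radius 2) sits at the origin; the ears (radius 1) are
    displaced up-left and up-right along the TL / TR cone axes.  The left
    ear is strictly closer to the head (offset 4.2 vs 4.83, a 15%
    asymmetry), so the set is deliberately not mirror-symmetric and the
    asymmetry is recoverable from the charts alone.  The 4.2 offset keeps
    the head, seen from an ear, inside the opposite cone's half-angle
    (arcsin(2/4.2) < 28.9 deg), so with an ear central the other two
    objects stay in right/bottom-right cones only.
    """

    head_radius: float = 2.0
    ear_radius: float = 1.0
    left_ear_offset: np.ndarray = field(default_factory=lambda: 4.2 * _TL_DIR)
    right_ear_offset: np.ndarray = field(default_factory=lambda: 4.83 * _TR_DIR)
    points_per_object: int = 2000
    seed: int | None = 0

    def __post_init__(self):
        object.__setattr__(
            self, "left_ear_offset", np.asarray(self.left_ear_offset, float).reshape(3)
        )
        object.__setattr__(
            self, "right_ear_offset", np.asarray(self.right_ear_offset, float).reshape(3)
        )
        if not self.ear_radius < self.head_radius:
            raise ValueError("ear_radius must be smaller than head_radius")
        dl = np.linalg.norm(self.left_ear_offset)
        dr = np.linalg.norm(self.right_ear_offset)
        if not dl < dr:
            raise ValueError("left ear must be strictly closer to the head")
        min_sep = self.head_radius + self.ear_radius
        if dl <= min_sep or dr <= min_sep:
            raise ValueError("ear balls overlap the head ball")
        if np.linalg.norm(self.left_ear_offset - self.right_ear_offset) <= 2 * self.ear_radius:
            raise ValueError("ear balls overlap each other")


def make_m3ds(params: M3DSParams | None = None) -> Scene:
    """Build the Mouse 3D Set scene with objects LE, H, RE (in that order).

    Object order follows the left-to-right reading: left ear first, head
    second, right ear third.  Each object is a uniform ball sample.
    """
    if params is None:
        params = M3DSParams()
    rng = np.random.default_rng(params.seed)
    n = params.points_per_object
    seeds = rng.integers(0, 2**31 - 1, size=3)
    le = sample_uniform_ball(n, params.ear_radius, seeds[0]) + params.left_ear_offset
    head = sample_uniform_ball(n, params.head_radius, seeds[1])
    re = sample_uniform_ball(n, params.ear_radius, seeds[2]) + params.right_ear_offset
    return Scene(
        [
            SceneObject("LE", le),
            SceneObject("H", head),
            SceneObject("RE", re),
        ],
        units="au",
    )


@dataclass(frozen=True)
class NucleusParams:
    """Parameters of the bead-chain nucleus.

    Defaults emulate a modelled rice nucleus: a spherical envelope of
    diameter 7.3 um, 24 chromosome-territory chains (12 chromosome pairs),
    each a fixed-step bead chain whose beads stand for ~1 Mb domains, plus
    a central nucleolus.  One bead per chain (the middle one by default)
    is flagged as the centromere anchor.
    """

    envelope_radius: float = 3.65
    nucleolus_radius: float = 0.8
    n_chains: int = 24
    beads_per_chain: int = 30
    step: float = 0.3
    centromere_index: int | None = None  # default: middle bead
    nucleolus_points: int = 300
    seed: int | None = 0

    def __post_init__(self):
        if self.step <= 0 or self.step > self.envelope_radius:
            raise ValueError("step must lie in (0, envelope_radius]")
        if self.n_chains < 1 or self.beads_per_chain < 1:
            raise ValueError("need at least one chain with at least one bead")
        idx = self.centromere_index
        if idx is not None and not 0 <= idx < self.beads_per_chain:
            raise ValueError("centromere_index out of range")


def _chain_labels(n: int) -> list[str]:
    """Chromosome-pair labels 1, 1', 2, 2', ... for the first 2k chains."""
    labels = []
    for i in range(n):
        pair = i // 2 + 1
        labels.append(f"{pair}" if i % 2 == 0 else f"{pair}'")
    return labels


def _reflected_walk(rng, n_beads: int, step: float, radius: float) -> np.ndarray:
    """Fixed-step random walk inside a sphere, bouncing off the boundary.

    A step that would exit is reflected specularly about the tangent plane
    at the current bead (step length preserved); in the rare case the
    reflected step still exits, fresh directions are drawn.
    """
    start_r = (radius - step) * rng.random() ** (1.0 / 3.0)
    d0 = rng.normal(size=3)
    pos = start_r * d0 / np.linalg.norm(d0)
    beads = [pos]
    for _ in range(n_beads - 1):
        d = rng.normal(size=3)
        d = step * d / np.linalg.norm(d)
        nxt = pos + d
        if np.linalg.norm(nxt) > radius:
            nrm = pos / np.linalg.norm(pos)
            d_ref = d - 2.0 * (d @ nrm) * nrm
            nxt = pos + d_ref
            while np.linalg.norm(nxt) > radius:
                d = rng.normal(size=3)
                d = step * d / np.linalg.norm(d)
                nxt = pos + d
        pos = nxt
        beads.append(pos)
    return np.array(beads)


def make_bead_chain_nucleus(params: NucleusParams | None = None) -> Scene:
    """Generate a bead-chain nucleus scene.

    Returns a scene whose envelope is recorded as (origin, envelope
    radius); every chain object carries exactly one anchor (its centromere
    bead) and consecutive beads are exactly ``step`` apart.
    """
    if params is None:
        params = NucleusParams()
    rng = np.random.default_rng(params.seed)
    cen_idx = (
        params.beads_per_chain // 2
        if params.centromere_index is None
        else params.centromere_index
    )
    objects = []
    for label in _chain_labels(params.n_chains):
        beads = _reflected_walk(
            rng, params.beads_per_chain, params.step, params.envelope_radius
        )
        objects.append(SceneObject(label, beads, anchor=beads[cen_idx]))
    nucleolus = sample_uniform_ball(
        params.nucleolus_points,
        params.nucleolus_radius,
        rng.integers(0, 2**31 - 1),
    )
    objects.append(SceneObject("nucleolus", nucleolus))
    return Scene(
        objects,
        envelope=(np.zeros(3), params.envelope_radius),
        units="um",
    )


def fcc_packing_density_mc(n: int, seed: int | None = None, radius: float = 1.0) -> float:
    """Monte-Carlo estimate of the cubic-close-packing density.

    One FCC unit cell is a cube of side ``2 sqrt(2) * r_touch`` with
    spheres at its 8 corners and 6 face centers (``r_touch`` is the
    touching radius; ``radius`` may be smaller for a sparser packing).
    Uniform samples in the cube are tested against all 14 spheres; parts
    of the spheres protruding out of the cell are exactly compensated by
    the neighbouring cells' spheres protruding in, so the hit fraction
    estimates the packing density — pi / (3 sqrt 2) ~ 0.74048 for touching
    spheres, independent of scale.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    r_touch = 1.0
    side = 2.0 * np.sqrt(2.0) * r_touch
    corners = np.array(
        [[i, j, k] for i in (0, side) for j in (0, side) for k in (0, side)]
    )
    h = side / 2.0
    faces = np.array(
        [
            [h, h, 0], [h, h, side],
            [h, 0, h], [h, side, h],
            [0, h, h], [side, h, h],
        ]
    )
    centers = np.vstack([corners, faces])
    rng = np.random.default_rng(seed)
    r = float(radius)  # r_touch = 1 is the touching radius; smaller r is sparser
    hits = 0
    chunk = 200_000
    remaining = n
    while remaining > 0:
        m = min(chunk, remaining)
        pts = rng.random((m, 3)) * side
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        hits += int((d2.min(axis=1) <= r * r).sum())
        remaining -= m
    return hits / n
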