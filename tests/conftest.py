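"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the code paths they check: cap-union solid
angle by latitude-longitude quadrature, point-to-cone distance by
constrained numerical minimisation over an explicit cone parameterisation,
and Hausdorff distance by a dense pairwise-distance matrix.
"""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from dpc12 import build_family12, make_bead_chain_nucleus, make_m3ds
from dpc12.synthetic import M3DSParams, NucleusParams


@pytest.fixture(scope="session")
def family():
    return build_family12()


@pytest.fixture(scope="session")
def m3ds_scene():
    return make_m3ds(M3DSParams(points_per_object=1500, seed=0))


@pytest.fixture(scope="session")
def nucleus_scene():
    return make_bead_chain_nucleus(NucleusParams(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------- oracles


def cap_union_solid_angle(axes, half_angles, n_theta=1200):
    """Fraction of the sphere covered by the union of spherical caps.

    Latitude-longitude quadrature: for each latitude band, the fraction of
    longitudes whose direction falls inside at least one cap, weighted by
    sin(theta).  Independent of the conification code path (works on raw
    axes/angles, uses no cone object).
    """
    axes = np.asarray(axes, dtype=float)
    half_angles = np.asarray(half_angles, dtype=float)
    n_phi = 2 * n_theta
    th = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    ph = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    cos_t = np.cos(half_angles)
    weights = np.sin(th) * (np.pi / n_theta) * (2 * np.pi / n_phi) / (4 * np.pi)
    total = 0.0
    cph, sph = np.cos(ph), np.sin(ph)
    for i in range(n_theta):
        st, ct = np.sin(th[i]), np.cos(th[i])
        u = np.stack([st * cph, st * sph, np.full(n_phi, ct)], axis=1)
        inside = (u @ axes.T >= cos_t).any(axis=1)
        total += weights[i] * inside.sum()
    return total


def cone_distance_numeric(p, axis, half_angle, n_restarts=4):
    """Distance from ``p`` to the solid cone by numerical minimisation.

    The cone is parameterised explicitly as
    ``q(r, phi, psi) = r (cos(phi) axis + sin(phi) (cos(psi) e1 + sin(psi) e2))``
    with ``r >= 0`` and ``0 <= phi <= half_angle``; the squared distance is
    minimised with several restarts.
    """
    p = np.asarray(p, dtype=float)
    axis = np.asarray(axis, dtype=float)
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = helper - (helper @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    r_max = 4.0 * np.linalg.norm(p) + 1.0

    def q(x):
        r, phi, psi = x
        return r * (
            np.cos(phi) * axis + np.sin(phi) * (np.cos(psi) * e1 + np.sin(psi) * e2)
        )

    def obj(x):
        d = p - q(x)
        return d @ d

    psi_p = np.arctan2(p @ e2, p @ e1)
    best = np.inf
    starts = [
        (np.linalg.norm(p), half_angle, psi_p),
        (np.linalg.norm(p), 0.0, psi_p),
        (0.5 * np.linalg.norm(p), half_angle / 2, psi_p),
        (1.0, half_angle, psi_p + np.pi),
    ][:n_restarts]
    for x0 in starts:
        res = minimize(
            obj,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, r_max), (0.0, half_angle), (None, None)],
        )
        best = min(best, res.fun)
    return float(np.sqrt(max(best, 0.0)))


def hausdorff_brute(A, B):
    """Hausdorff distance via the full pairwise distance matrix."""
    D = cdist(np.atleast_2d(A), np.atleast_2d(B))
    return max(D.min(axis=1).max(), D.min(axis=0).max())


def nearest_rank_brute(scene, central_id, anchor):
    """(obj_id, min anchor distance) for non-central objects, ascending."""
    anchor = np.asarray(anchor, dtype=float)
    rows = []
    for o in scene.objects:
        if o.obj_id == central_id:
            continue
        rows.append((o.obj_id, float(np.linalg.norm(o.points - anchor, axis=1).min())))
    rows.sort(key=lambda r: r[1])
    return rows
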