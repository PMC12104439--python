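"""Differentiable geometric primitives over atom coordinate arrays.

All functions accept either plain ndarrays or autodiff :class:`~gmmrefine.autodiff.Var`
nodes and return `Var`s; when the input does not require gradients the tape is
not recorded, so the same code path serves both the differentiable losses and
the plain validation reports.

Angles are returned in degrees to match restraint-table and validation
conventions.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Var, as_var

__all__ = [
    "cross",
    "vdot",
    "vnorm",
    "bond_lengths",
    "bond_angles",
    "dihedrals",
    "rodrigues_apply",
    "nerf_place",
]

_EPS = 1e-12


def cross(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    return Var.op(
        np.cross(a.data, b.data),
        (a, b),
        (lambda g: np.cross(b.data, g), lambda g: np.cross(g, a.data)),
    )


def vdot(a, b) -> Var:
    return (as_var(a) * as_var(b)).sum(axis=-1)


def vnorm(a) -> Var:
    a = as_var(a)
    return ad.sqrt((a * a).sum(axis=-1) + _EPS)


def bond_lengths(coords, pairs: np.ndarray) -> Var:
    """Distances (Å) for each (i, j) row of `pairs`."""
    X = as_var(coords)
    return vnorm(X[pairs[:, 0]] - X[pairs[:, 1]])


def bond_angles(coords, triples: np.ndarray) -> Var:
    """Angle i-j-k in degrees for each row of `triples`."""
    X = as_var(coords)
    a, b, c = X[triples[:, 0]], X[triples[:, 1]], X[triples[:, 2]]
    u, v = a - b, c - b
    # atan2 form is stable near 0 and 180 degrees
    ang = ad.atan2(vnorm(cross(u, v)), vdot(u, v))
    return ang * (180.0 / np.pi)


def dihedrals(coords, quads: np.ndarray) -> Var:
    """Torsion angle in degrees, in (-180, 180], for each (i,j,k,l) row."""
    X = as_var(coords)
    p0, p1, p2, p3 = (X[quads[:, i]] for i in range(4))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 * (1.0 / vnorm(b1)).reshape(-1, 1)
    v = b0 - b1n * vdot(b0, b1n).reshape(-1, 1)
    w = b2 - b1n * vdot(b2, b1n).reshape(-1, 1)
    x = vdot(v, w)
    y = vdot(cross(b1n, v), w)
    return ad.atan2(y, x) * (180.0 / np.pi)


def rodrigues_apply(points, rotvec, center=None) -> Var:
    """Rotate `points` (N,3) by per-point rotation vectors (N,3).

    Uses x' = x + A (r × x) + B (r × (r × x)) with A = sinθ/θ and
    B = (1−cosθ)/θ²; a tiny floor inside the square root keeps the
    small-angle limit exact to machine precision and differentiable.
    """
    x = as_var(points)
    r = as_var(rotvec)
    if center is not None:
        x = x - as_var(center)
    th = ad.sqrt((r * r).sum(axis=-1) + _EPS)
    A = (ad.sin(th) / th).reshape(-1, 1)
    B = ((1.0 - ad.cos(th)) / (th * th)).reshape(-1, 1)
    rx = cross(r, x)
    rrx = cross(r, rx)
    out = x + A * rx + B * rrx
    if center is not None:
        out = out + as_var(center)
    return out


def nerf_place(c, b, a, length, theta_deg, tau_deg) -> Var:
    """Place atoms from internal coordinates (natural extension reference frame).

    Each new atom D is defined relative to three placed atoms A-B-C by a
    bond length |DC|, an angle D-C-B (degrees), and a torsion D-C-B-A
    (degrees). Inputs are (M,3) coordinate arrays and (M,) scalars.
    """
    c, b, a = as_var(c), as_var(b), as_var(a)
    length = as_var(length).reshape(-1, 1)
    th = as_var(theta_deg) * (np.pi / 180.0)
    ta = as_var(tau_deg) * (np.pi / 180.0)
    bc = c - b
    bc = bc * (1.0 / vnorm(bc)).reshape(-1, 1)
    ba = b - a
    n = cross(ba, bc)
    n = n * (1.0 / vnorm(n)).reshape(-1, 1)
    m = cross(n, bc)
    d0 = (-ad.cos(th)).reshape(-1, 1) * length
    d1 = (ad.sin(th) * ad.cos(ta)).reshape(-1, 1) * length
    d2 = (ad.sin(th) * ad.sin(ta)).reshape(-1, 1) * length
    return c + bc * d0 + m * d1 + n * d2
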