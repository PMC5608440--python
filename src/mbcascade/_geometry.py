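"""Vectorized internal-coordinate helpers (distances, angles, dihedrals).

All functions take an (N, 3) coordinate array in Angstrom and integer index
arrays selecting the beads of each term.  Gradients are returned as the
per-term partial derivatives with respect to the participating beads so the
caller can scatter-add them into a full (N, 3) force array.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "pair_distances",
    "bend_angles",
    "dihedral_angles",
    "dihedral_gradients",
    "angle_gradients",
    "wrap_angle",
]


def pair_distances(coords: np.ndarray, i: np.ndarray, j: np.ndarray):
    """Distances r_ij and unit vectors (from i to j) for an index pair list."""
    dvec = coords[j] - coords[i]
    r = np.linalg.norm(dvec, axis=1)
    return r, dvec


def wrap_angle(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi)))


def bend_angles(coords: np.ndarray, i: np.ndarray, j: np.ndarray, k: np.ndarray):
    """Bending angle at j for triples (i, j, k), in [0, pi]."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos = np.einsum("ij,ij->i", u, v) / (nu * nv)
    return np.arccos(np.clip(cos, -1.0, 1.0))


def angle_gradients(coords, i, j, k):
    """d(theta)/d(r_i), d(theta)/d(r_j), d(theta)/d(r_k) for bend angles."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos = np.einsum("ij,ij->i", u, v) / (nu * nv)
    cos = np.clip(cos, -1.0, 1.0)
    sin = np.sqrt(np.maximum(1.0 - cos * cos, 1e-14))
    # d(cos)/du = v/(|u||v|) - cos*u/|u|^2 ; dtheta = -dcos/sin
    du = (v / (nu * nv)[:, None] - (cos / nu**2)[:, None] * u) / (-sin)[:, None]
    dk = (u / (nu * nv)[:, None] - (cos / nv**2)[:, None] * v) / (-sin)[:, None]
    dj = -(du + dk)
    return du, dj, dk


def dihedral_angles(coords: np.ndarray, i, j, k, l):
    """Signed dihedral for quadruples (i, j, k, l), in (-pi, pi].

    Uses the atan2 convention: phi = atan2((n1 x n2).b2hat, n1.n2) with
    b1 = r_j - r_i, b2 = r_k - r_j, b3 = r_l - r_k.
    """
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2) / np.where(b2n > 0, b2n, 1.0)
    x = np.einsum("ij,ij->i", n1, n2)
    return np.arctan2(y, x)


def dihedral_gradients(coords, i, j, k, l, eps: float = 1e-12):
    """Partial derivatives of the dihedral wrt its four beads.

    Returns (dphi_di, dphi_dj, dphi_dk, dphi_dl, defined) where ``defined``
    flags terms whose planes are non-degenerate (collinear triples are
    undefined and should be skipped by the caller).
    """
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    b2n = np.linalg.norm(b2, axis=1)
    defined = (n1sq > eps) & (n2sq > eps) & (b2n > eps)
    safe1 = np.where(defined, n1sq, 1.0)
    safe2 = np.where(defined, n2sq, 1.0)
    safeb = np.where(defined, b2n, 1.0)
    di = (-safeb / safe1)[:, None] * n1
    dl = (safeb / safe2)[:, None] * n2
    f1 = (np.einsum("ij,ij->i", b1, b2) / (safeb**2))[:, None]
    f3 = (np.einsum("ij,ij->i", b3, b2) / (safeb**2))[:, None]
    dj = -di - f1 * di + f3 * dl
    dk = -dl + f1 * di - f3 * dl
    zero = np.zeros_like(di)
    mask = defined[:, None]
    return (
        np.where(mask, di, zero),
        np.where(mask, dj, zero),
        np.where(mask, dk, zero),
        np.where(mask, dl, zero),
        defined,
    )
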