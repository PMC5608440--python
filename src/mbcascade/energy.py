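"""Single-basin structure-based (AICG2+-style) potential and gradients.

All energies in kcal/mol, lengths in Angstrom, angles in radians.  Every
term function returns ``(energy, gradient)`` with the gradient accumulated
into a full (N, 3) array; forces are the negative gradient.  This module is
the readable reference path; the dynamics engine uses an equivalent
compiled kernel that is cross-checked against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _geometry as geom
from .topology import BasinTerms

__all__ = [
    "AICG2PParams",
    "EnergyReport",
    "FlexibleLocalTable",
    "bond_energy",
    "gaussian_local_energy",
    "go_contact_energy",
    "excluded_volume_energy",
    "flexible_local_energy",
    "single_basin_energy",
]

KB_KCAL = 1.987e-3  # Boltzmann constant, kcal/mol/K


@dataclass
class AICG2PParams:
    """Force-field parameter defaults (all configurable, CafeMol-style magnitudes).

    k_b          virtual-bond spring constant (kcal/mol/A^2)
    eps_loc      local Gaussian depth, split equally between the 1-3 and
                 dihedral terms (kcal/mol)
    eps_go       native-contact Go depth (kcal/mol)
    eps_ev, exv_d  excluded-volume strength (kcal/mol) and diameter (A)
    w13, w_phi   Gaussian widths of the 1-3 (A) and dihedral (rad) terms
    contact_cutoff / contact_mode   native-contact criterion (A; allatom,
                 calpha or auto)
    go_cutoff_factor  Go terms truncated (with energy shift) at this multiple
                 of r0; rep_cutoff truncates the repulsion likewise (A)
    """

    k_b: float = 100.0
    eps_loc: float = 0.3
    eps_go: float = 0.3
    eps_ev: float = 0.2
    exv_d: float = 6.5
    w13: float = 0.3
    w_phi: float = 0.3
    contact_cutoff: float = 6.5
    contact_mode: str = "auto"
    go_cutoff_factor: float = 2.5
    rep_cutoff: float = 20.0
    flexible_local: "FlexibleLocalTable | None" = None

    def __post_init__(self):
        for name in ("k_b", "eps_loc", "eps_go", "eps_ev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.exv_d <= 0:
            raise ValueError("exv_d must be positive")


@dataclass
class EnergyReport:
    """Total energy, per-term-class breakdown and full gradient."""

    total: float
    breakdown: dict[str, float]
    gradient: np.ndarray

    def __post_init__(self):
        if not np.isclose(self.total, sum(self.breakdown.values()), atol=1e-9):
            raise ValueError("total does not equal sum of breakdown")
        if not np.all(np.isfinite(self.gradient)):
            raise ValueError("non-finite gradient")


def bond_energy(coords, bond_i, bond_k, bond_b0):
    """Harmonic virtual-bond term sum_i K_b,i (b_i - b_i,0)^2."""
    bond_i = np.asarray(bond_i, dtype=np.int64)
    grad = np.zeros_like(coords)
    if len(bond_i) == 0:
        return 0.0, grad
    r, dvec = geom.pair_distances(coords, bond_i, bond_i + 1)
    if np.any(r == 0):
        raise ValueError("zero-length virtual bond")
    db = r - bond_b0
    e = float(np.sum(bond_k * db * db))
    dEdr = 2.0 * bond_k * db
    per = (dEdr / r)[:, None] * dvec
    np.add.at(grad, bond_i + 1, per)
    np.add.at(grad, bond_i, -per)
    return e, grad


def gaussian_local_energy(coords, g13_i, g13_eps, g13_r0, g13_w,
                          dih_i, dih_eps, dih_phi0, dih_w):
    """Attractive Gaussian wells on 1-3 distances and on dihedrals.

    Each term contributes -eps * exp(-(x - x0)^2 / 2W^2); dihedral deviations
    are wrapped into (-pi, pi].  Terms whose dihedral is undefined (collinear
    triple) are skipped with a warning.
    """
    g13_i = np.asarray(g13_i, dtype=np.int64)
    dih_i = np.asarray(dih_i, dtype=np.int64)
    grad = np.zeros_like(coords)
    e = 0.0
    if len(g13_i):
        r, dvec = geom.pair_distances(coords, g13_i, g13_i + 2)
        gauss = g13_eps * np.exp(-((r - g13_r0) ** 2) / (2.0 * g13_w**2))
        e -= float(np.sum(gauss))
        dEdr = gauss * (r - g13_r0) / g13_w**2
        per = (dEdr / r)[:, None] * dvec
        np.add.at(grad, g13_i + 2, per)
        np.add.at(grad, g13_i, -per)
    if len(dih_i):
        phi = geom.dihedral_angles(coords, dih_i, dih_i + 1, dih_i + 2, dih_i + 3)
        d1, d2, d3, d4, defined = geom.dihedral_gradients(
            coords, dih_i, dih_i + 1, dih_i + 2, dih_i + 3)
        if not defined.all():
            warnings.warn("collinear triple: dihedral term(s) skipped")
        dphi = geom.wrap_angle(phi - dih_phi0)
        gauss = np.where(defined,
                         dih_eps * np.exp(-(dphi**2) / (2.0 * dih_w**2)), 0.0)
        e -= float(np.sum(gauss))
        dEdphi = gauss * dphi / dih_w**2
        for off, d in enumerate((d1, d2, d3, d4)):
            np.add.at(grad, dih_i + off, dEdphi[:, None] * d)
    return e, grad


def go_contact_energy(coords, go_i, go_j, go_eps, go_r0, cutoff_factor=None):
    """12-10 Go attraction eps * [5 (r0/r)^12 - 6 (r0/r)^10] per native pair.

    The minimum is -eps at r = r0.  With ``cutoff_factor`` the term is
    truncated at cutoff_factor * r0 and shifted so it vanishes there.
    """
    go_i = np.asarray(go_i, dtype=np.int64)
    go_j = np.asarray(go_j, dtype=np.int64)
    grad = np.zeros_like(coords)
    if len(go_i) == 0:
        return 0.0, grad
    r, dvec = geom.pair_distances(coords, go_i, go_j)
    if np.any(r == 0):
        raise ValueError("coincident beads in Go contact")
    q = go_r0 / r
    v = go_eps * (5.0 * q**12 - 6.0 * q**10)
    dEdr = (60.0 * go_eps / r) * (q**10 - q**12)
    if cutoff_factor is not None:
        qc = 1.0 / cutoff_factor
        shift = go_eps * (5.0 * qc**12 - 6.0 * qc**10)
        inside = r < cutoff_factor * go_r0
        v = np.where(inside, v - shift, 0.0)
        dEdr = np.where(inside, dEdr, 0.0)
    e = float(np.sum(v))
    per = (dEdr / r)[:, None] * dvec
    np.add.at(grad, go_j, per)
    np.add.at(grad, go_i, -per)
    return e, grad


def excluded_volume_energy(coords, rep_i, rep_j, eps_ev, d, rcut=None):
    """Generic repulsion eps_ev (d/r)^12 over the non-native pair list.

    With ``rcut`` the term is truncated and shifted to zero at r = rcut.
    """
    rep_i = np.asarray(rep_i, dtype=np.int64)
    rep_j = np.asarray(rep_j, dtype=np.int64)
    grad = np.zeros_like(coords)
    if len(rep_i) == 0:
        return 0.0, grad
    r, dvec = geom.pair_distances(coords, rep_i, rep_j)
    if np.any(r == 0):
        raise ValueError("coincident beads in repulsion pair")
    v = eps_ev * (d / r) ** 12
    dEdr = -12.0 * v / r
    if rcut is not None:
        shift = eps_ev * (d / rcut) ** 12
        inside = r < rcut
        v = np.where(inside, v - shift, 0.0)
        dEdr = np.where(inside, dEdr, 0.0)
    e = float(np.sum(v))
    per = (dEdr / r)[:, None] * dvec
    np.add.at(grad, rep_j, per)
    np.add.at(grad, rep_i, -per)
    return e, grad


class FlexibleLocalTable:
    """Tabulated sequence-dependent local potential on bend angles and dihedrals.

    Evaluated by periodic cubic-spline interpolation of an energy table on a
    regular angle grid.  The shipped default is the generic all-zero fallback
    (label "generic"), which contributes nothing; real statistical tables can
    be loaded from a plain-text matrix (one angle grid value and one energy
    per line).
    """

    def __init__(self, angle_grid=None, angle_energy=None,
                 dihedral_grid=None, dihedral_energy=None, label="generic"):
        from scipy.interpolate import CubicSpline

        self.label = label
        self._ang = None
        self._dih = None
        if angle_grid is not None:
            self._ang = CubicSpline(angle_grid, angle_energy, bc_type="natural")
        if dihedral_grid is not None:
            g = np.asarray(dihedral_grid, dtype=float)
            ev = np.asarray(dihedral_energy, dtype=float)
            if not np.isclose(g[-1] - g[0], 2 * np.pi):
                g = np.append(g, g[0] + 2 * np.pi)
                ev = np.append(ev, ev[0])
            self._dih = CubicSpline(g, ev, bc_type="periodic")

    @property
    def is_zero(self):
        return self._ang is None and self._dih is None

    @classmethod
    def from_text(cls, angle_text: str | None = None,
                  dihedral_text: str | None = None, label: str = "custom"):
        def parse(txt):
            rows = np.loadtxt(txt.strip().splitlines())
            return rows[:, 0], rows[:, 1]

        akw = parse(angle_text) if angle_text else (None, None)
        dkw = parse(dihedral_text) if dihedral_text else (None, None)
        return cls(akw[0], akw[1], dkw[0], dkw[1], label=label)

    def angle(self, theta):
        if self._ang is None:
            return np.zeros_like(theta), np.zeros_like(theta)
        return self._ang(theta), self._ang(theta, 1)

    def dihedral(self, phi):
        if self._dih is None:
            return np.zeros_like(phi), np.zeros_like(phi)
        phi = np.mod(phi - self._dih.x[0], 2 * np.pi) + self._dih.x[0]
        return self._dih(phi), self._dih(phi, 1)


def flexible_local_energy(coords, table: FlexibleLocalTable | None):
    """Evaluate the tabulated local potential over all bend angles and dihedrals."""
    grad = np.zeros_like(coords)
    if table is None:
        raise ValueError("no flexible-local table loaded and no fallback enabled")
    if table.is_zero:
        return 0.0, grad
    n = len(coords)
    e = 0.0
    if n >= 3:
        idx = np.arange(n - 2)
        theta = geom.bend_angles(coords, idx, idx + 1, idx + 2)
        v, dv = table.angle(theta)
        e += float(np.sum(v))
        du, dj, dk = geom.angle_gradients(coords, idx, idx + 1, idx + 2)
        for off, d in enumerate((du, dj, dk)):
            np.add.at(grad, idx + off, dv[:, None] * d)
    if n >= 4:
        idx = np.arange(n - 3)
        phi = geom.dihedral_angles(coords, idx, idx + 1, idx + 2, idx + 3)
        v, dv = table.dihedral(phi)
        e += float(np.sum(v))
        d1, d2, d3, d4, defined = geom.dihedral_gradients(
            coords, idx, idx + 1, idx + 2, idx + 3)
        dv = np.where(defined, dv, 0.0)
        for off, d in enumerate((d1, d2, d3, d4)):
            np.add.at(grad, idx + off, dv[:, None] * d)
    return e, grad


def single_basin_energy(coords, terms: BasinTerms, params: AICG2PParams,
                        rep_i=None, rep_j=None,
                        flexible_scope=None) -> EnergyReport:
    """Sum the term classes of one basin's owned term set.

    ``rep_i``/``rep_j`` optionally add the shared excluded-volume pairs
    (whole-molecule evaluations); ``flexible_scope`` optionally evaluates the
    flexible-local table (by default skipped — it is not owned per basin).
    """
    coords = np.asarray(coords, dtype=float)
    breakdown = {}
    grad = np.zeros_like(coords)

    e, g = bond_energy(coords, terms.bond_i, terms.bond_k, terms.bond_b0)
    breakdown["bond"] = e
    grad += g

    e, g = gaussian_local_energy(
        coords, terms.g13_i, terms.g13_eps, terms.g13_r0, terms.g13_w,
        terms.dih_i, terms.dih_eps, terms.dih_phi0, terms.dih_w)
    breakdown["gauss_local"] = e
    grad += g

    e, g = go_contact_energy(coords, terms.go_i, terms.go_j, terms.go_eps,
                             terms.go_r0, cutoff_factor=params.go_cutoff_factor)
    breakdown["go"] = e
    grad += g

    if rep_i is not None and len(rep_i):
        e, g = excluded_volume_energy(coords, rep_i, rep_j, params.eps_ev,
                                      params.exv_d, rcut=params.rep_cutoff)
        breakdown["repulsion"] = e
        grad += g
    else:
        breakdown["repulsion"] = 0.0

    if flexible_scope is not None:
        e, g = flexible_local_energy(coords, params.flexible_local
                                     or FlexibleLocalTable())
        breakdown["flexible_local"] = e
        grad += g
    else:
        breakdown["flexible_local"] = 0.0

    return EnergyReport(sum(breakdown.values()), breakdown, grad)
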