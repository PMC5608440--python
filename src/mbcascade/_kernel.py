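"""Compiled (numba) force/integrator kernels for the multiple-basin surface.

The topology is flattened into per-term arrays concatenated over all
subsystems, each term carrying the index of its owning subsystem.  The
kernel evaluates both basin energies per subsystem, mixes them through the
smaller-eigenvalue closed form and assembles the chain-rule gradient
``w1 grad V1 + w2 grad V2`` in a single pass over the term lists.  A pure
numpy reference path lives in :mod:`mbcascade.multibasin`; the two are
cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

CHI_MAX = 50.0


@njit(cache=True, fastmath=False)
def _dihedral(c, i, j, k, l, dgrad):
    """Dihedral angle of beads (i, j, k, l); gradient into dgrad (4, 3).

    Returns (phi, defined); collinear triples are flagged undefined and
    produce a zero gradient.
    """
    b1x = c[j, 0] - c[i, 0]; b1y = c[j, 1] - c[i, 1]; b1z = c[j, 2] - c[i, 2]
    b2x = c[k, 0] - c[j, 0]; b2y = c[k, 1] - c[j, 1]; b2z = c[k, 2] - c[j, 2]
    b3x = c[l, 0] - c[k, 0]; b3y = c[l, 1] - c[k, 1]; b3z = c[l, 2] - c[k, 2]
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    n1sq = n1x * n1x + n1y * n1y + n1z * n1z
    n2sq = n2x * n2x + n2y * n2y + n2z * n2z
    b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    if n1sq < 1e-12 or n2sq < 1e-12 or b2n < 1e-12:
        for a in range(4):
            for d in range(3):
                dgrad[a, d] = 0.0
        return 0.0, False
    mx = n1y * n2z - n1z * n2y
    my = n1z * n2x - n1x * n2z
    mz = n1x * n2y - n1y * n2x
    y = (mx * b2x + my * b2y + mz * b2z) / b2n
    x = n1x * n2x + n1y * n2y + n1z * n2z
    phi = np.arctan2(y, x)
    f1 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
    f3 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
    dix = -b2n / n1sq * n1x
    diy = -b2n / n1sq * n1y
    diz = -b2n / n1sq * n1z
    dlx = b2n / n2sq * n2x
    dly = b2n / n2sq * n2y
    dlz = b2n / n2sq * n2z
    dgrad[0, 0] = dix; dgrad[0, 1] = diy; dgrad[0, 2] = diz
    dgrad[3, 0] = dlx; dgrad[3, 1] = dly; dgrad[3, 2] = dlz
    dgrad[1, 0] = -dix - f1 * dix + f3 * dlx
    dgrad[1, 1] = -diy - f1 * diy + f3 * dly
    dgrad[1, 2] = -diz - f1 * diz + f3 * dlz
    dgrad[2, 0] = -dlx + f1 * dix - f3 * dlx
    dgrad[2, 1] = -dly + f1 * diy - f3 * dly
    dgrad[2, 2] = -dlz + f1 * diz - f3 * dlz
    return phi, True


@njit(cache=True, fastmath=False)
def energy_force(
    coords,
    bond_i, bond_k, bond_b0_1, bond_b0_2, bond_owner,
    g13_i, g13_eps, g13_r0_1, g13_r0_2, g13_w, g13_owner,
    dih_i, dih_eps, dih_phi0_1, dih_phi0_2, dih_w, dih_owner,
    go1_i, go1_j, go1_eps, go1_r0, go1_owner,
    go2_i, go2_j, go2_eps, go2_r0, go2_owner,
    rep_i, rep_j, eps_ev, exv_d, rep_cutoff, go_cutoff_factor,
    delta, delta_v,
    grad, chi_out,
):
    """Total multiple-basin energy, per-module chi and gradient (in place)."""
    K = delta.shape[0]
    v1 = np.zeros(K)
    v2 = np.zeros(K)
    n = coords.shape[0]
    for a in range(n):
        for d in range(3):
            grad[a, d] = 0.0

    nb = bond_i.shape[0]
    r_bond = np.empty(nb)
    for t in range(nb):
        i = bond_i[t]
        dx = coords[i + 1, 0] - coords[i, 0]
        dy = coords[i + 1, 1] - coords[i, 1]
        dz = coords[i + 1, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        r_bond[t] = r
        o = bond_owner[t]
        v1[o] += bond_k[t] * (r - bond_b0_1[t]) ** 2
        v2[o] += bond_k[t] * (r - bond_b0_2[t]) ** 2

    n13 = g13_i.shape[0]
    r_g13 = np.empty(n13)
    for t in range(n13):
        i = g13_i[t]
        dx = coords[i + 2, 0] - coords[i, 0]
        dy = coords[i + 2, 1] - coords[i, 1]
        dz = coords[i + 2, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        r_g13[t] = r
        o = g13_owner[t]
        w2inv = 1.0 / (g13_w[t] * g13_w[t])
        v1[o] -= g13_eps[t] * np.exp(-0.5 * (r - g13_r0_1[t]) ** 2 * w2inv)
        v2[o] -= g13_eps[t] * np.exp(-0.5 * (r - g13_r0_2[t]) ** 2 * w2inv)

    nd = dih_i.shape[0]
    phi_d = np.empty(nd)
    ok_d = np.empty(nd, dtype=np.bool_)
    dgrad_all = np.empty((nd, 4, 3))
    for t in range(nd):
        i = dih_i[t]
        phi, ok = _dihedral(coords, i, i + 1, i + 2, i + 3, dgrad_all[t])
        phi_d[t] = phi
        ok_d[t] = ok
        if ok:
            o = dih_owner[t]
            w2inv = 1.0 / (dih_w[t] * dih_w[t])
            for basin in range(2):
                phi0 = dih_phi0_1[t] if basin == 0 else dih_phi0_2[t]
                dphi = phi - phi0
                while dphi > np.pi:
                    dphi -= 2 * np.pi
                while dphi <= -np.pi:
                    dphi += 2 * np.pi
                e = -dih_eps[t] * np.exp(-0.5 * dphi * dphi * w2inv)
                if basin == 0:
                    v1[o] += e
                else:
                    v2[o] += e

    ng1 = go1_i.shape[0]
    r_go1 = np.empty(ng1)
    for t in range(ng1):
        i = go1_i[t]; j = go1_j[t]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        r_go1[t] = r
        if r < go_cutoff_factor * go1_r0[t]:
            q = go1_r0[t] / r
            q10 = q ** 10
            qc = 1.0 / go_cutoff_factor
            shift = go1_eps[t] * (5.0 * qc ** 12 - 6.0 * qc ** 10)
            v1[go1_owner[t]] += go1_eps[t] * (5.0 * q10 * q * q - 6.0 * q10) - shift

    ng2 = go2_i.shape[0]
    r_go2 = np.empty(ng2)
    for t in range(ng2):
        i = go2_i[t]; j = go2_j[t]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        r_go2[t] = r
        if r < go_cutoff_factor * go2_r0[t]:
            q = go2_r0[t] / r
            q10 = q ** 10
            qc = 1.0 / go_cutoff_factor
            shift = go2_eps[t] * (5.0 * qc ** 12 - 6.0 * qc ** 10)
            v2[go2_owner[t]] += go2_eps[t] * (5.0 * q10 * q * q - 6.0 * q10) - shift

    # shared repulsion: identical in both basins, added with unit weight
    e_rep = 0.0
    shift_rep = eps_ev * (exv_d / rep_cutoff) ** 12
    for t in range(rep_i.shape[0]):
        i = rep_i[t]; j = rep_j[t]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rep_cutoff * rep_cutoff:
            r = np.sqrt(r2)
            v = eps_ev * (exv_d / r) ** 12
            e_rep += v - shift_rep
            coef = -12.0 * v / r2  # dE/dr / r
            gx = coef * dx; gy = coef * dy; gz = coef * dz
            grad[j, 0] += gx; grad[j, 1] += gy; grad[j, 2] += gz
            grad[i, 0] -= gx; grad[i, 1] -= gy; grad[i, 2] -= gz

    # mixing weights per subsystem
    w1 = np.empty(K)
    w2 = np.empty(K)
    v_total = e_rep
    for o in range(K):
        half_gap = 0.5 * (v1[o] - v2[o] - delta_v[o])
        s = np.sqrt(half_gap * half_gap + delta[o] * delta[o])
        v_mb = 0.5 * (v1[o] + v2[o] + delta_v[o]) - s
        w1[o] = 0.5 - half_gap / (2.0 * s)
        w2[o] = 1.0 - w1[o]
        v_total += v_mb
        ratio = (v1[o] - v_mb) / delta[o]
        if ratio <= np.exp(-CHI_MAX):
            chi_out[o] = -CHI_MAX
        else:
            lr = np.log(ratio)
            if lr > CHI_MAX:
                lr = CHI_MAX
            chi_out[o] = lr

    # gradient pass with basin weights
    for t in range(nb):
        i = bond_i[t]
        o = bond_owner[t]
        r = r_bond[t]
        dEdr = 2.0 * bond_k[t] * (
            w1[o] * (r - bond_b0_1[t]) + w2[o] * (r - bond_b0_2[t]))
        coef = dEdr / r
        dx = coords[i + 1, 0] - coords[i, 0]
        dy = coords[i + 1, 1] - coords[i, 1]
        dz = coords[i + 1, 2] - coords[i, 2]
        gx = coef * dx; gy = coef * dy; gz = coef * dz
        grad[i + 1, 0] += gx; grad[i + 1, 1] += gy; grad[i + 1, 2] += gz
        grad[i, 0] -= gx; grad[i, 1] -= gy; grad[i, 2] -= gz

    for t in range(n13):
        i = g13_i[t]
        o = g13_owner[t]
        r = r_g13[t]
        w2inv = 1.0 / (g13_w[t] * g13_w[t])
        d1 = r - g13_r0_1[t]
        d2 = r - g13_r0_2[t]
        dEdr = g13_eps[t] * w2inv * (
            w1[o] * d1 * np.exp(-0.5 * d1 * d1 * w2inv)
            + w2[o] * d2 * np.exp(-0.5 * d2 * d2 * w2inv))
        coef = dEdr / r
        dx = coords[i + 2, 0] - coords[i, 0]
        dy = coords[i + 2, 1] - coords[i, 1]
        dz = coords[i + 2, 2] - coords[i, 2]
        gx = coef * dx; gy = coef * dy; gz = coef * dz
        grad[i + 2, 0] += gx; grad[i + 2, 1] += gy; grad[i + 2, 2] += gz
        grad[i, 0] -= gx; grad[i, 1] -= gy; grad[i, 2] -= gz

    for t in range(nd):
        if not ok_d[t]:
            continue
        i = dih_i[t]
        o = dih_owner[t]
        w2inv = 1.0 / (dih_w[t] * dih_w[t])
        dEdphi = 0.0
        for basin in range(2):
            phi0 = dih_phi0_1[t] if basin == 0 else dih_phi0_2[t]
            dphi = phi_d[t] - phi0
            while dphi > np.pi:
                dphi -= 2 * np.pi
            while dphi <= -np.pi:
                dphi += 2 * np.pi
            wb = w1[o] if basin == 0 else w2[o]
            dEdphi += wb * dih_eps[t] * dphi * w2inv * np.exp(
                -0.5 * dphi * dphi * w2inv)
        for a in range(4):
            for d in range(3):
                grad[i + a, d] += dEdphi * dgrad_all[t, a, d]

    for t in range(ng1):
        i = go1_i[t]; j = go1_j[t]
        r = r_go1[t]
        if r < go_cutoff_factor * go1_r0[t]:
            q = go1_r0[t] / r
            q10 = q ** 10
            dEdr = (60.0 * go1_eps[t] / r) * (q10 - q10 * q * q)
            coef = w1[go1_owner[t]] * dEdr / r
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            gx = coef * dx; gy = coef * dy; gz = coef * dz
            grad[j, 0] += gx; grad[j, 1] += gy; grad[j, 2] += gz
            grad[i, 0] -= gx; grad[i, 1] -= gy; grad[i, 2] -= gz

    for t in range(ng2):
        i = go2_i[t]; j = go2_j[t]
        r = r_go2[t]
        if r < go_cutoff_factor * go2_r0[t]:
            q = go2_r0[t] / r
            q10 = q ** 10
            dEdr = (60.0 * go2_eps[t] / r) * (q10 - q10 * q * q)
            coef = w2[go2_owner[t]] * dEdr / r
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            gx = coef * dx; gy = coef * dy; gz = coef * dz
            grad[j, 0] += gx; grad[j, 1] += gy; grad[j, 2] += gz
            grad[i, 0] -= gx; grad[i, 1] -= gy; grad[i, 2] -= gz

    return v_total


@njit(cache=True, fastmath=False)
def baoab_chunk(
    coords, vels, grad, noise, dt, gamma, kT, mass,
    bond_i, bond_k, bond_b0_1, bond_b0_2, bond_owner,
    g13_i, g13_eps, g13_r0_1, g13_r0_2, g13_w, g13_owner,
    dih_i, dih_eps, dih_phi0_1, dih_phi0_2, dih_w, dih_owner,
    go1_i, go1_j, go1_eps, go1_r0, go1_owner,
    go2_i, go2_j, go2_eps, go2_r0, go2_owner,
    rep_i, rep_j, eps_ev, exv_d, rep_cutoff, go_cutoff_factor,
    delta, delta_v, chi_out,
):
    """Advance a BAOAB-split underdamped Langevin block of len(noise) steps.

    ``grad`` must hold the gradient at the incoming coordinates and is left
    at the outgoing ones.  With gamma = 0 and T = 0 the O-step is the
    identity and the scheme reduces to velocity Verlet.  Returns the total
    potential energy at the final coordinates; chi_out holds the final
    per-module reaction coordinates.
    """
    n = coords.shape[0]
    nsteps = noise.shape[0]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1) / mass)
    half = 0.5 * dt
    v_total = 0.0
    for step in range(nsteps):
        for a in range(n):
            for d in range(3):
                vels[a, d] -= half * grad[a, d] / mass
                coords[a, d] += half * vels[a, d]
        for a in range(n):
            for d in range(3):
                vels[a, d] = c1 * vels[a, d] + c2 * noise[step, a, d]
                coords[a, d] += half * vels[a, d]
        v_total = energy_force(
            coords,
            bond_i, bond_k, bond_b0_1, bond_b0_2, bond_owner,
            g13_i, g13_eps, g13_r0_1, g13_r0_2, g13_w, g13_owner,
            dih_i, dih_eps, dih_phi0_1, dih_phi0_2, dih_w, dih_owner,
            go1_i, go1_j, go1_eps, go1_r0, go1_owner,
            go2_i, go2_j, go2_eps, go2_r0, go2_owner,
            rep_i, rep_j, eps_ev, exv_d, rep_cutoff, go_cutoff_factor,
            delta, delta_v, grad, chi_out,
        )
        for a in range(n):
            for d in range(3):
                vels[a, d] -= half * grad[a, d] / mass
    return v_total


@dataclass
class CompiledForceField:
    """Flattened term arrays of a SimulationTopology, ready for the kernel."""

    args: tuple
    delta: np.ndarray
    delta_v: np.ndarray
    n_beads: int
    K: int

    def energy_force(self, coords):
        """Total energy, chi vector and gradient at ``coords``."""
        coords = np.ascontiguousarray(coords, dtype=float)
        grad = np.zeros_like(coords)
        chi = np.zeros(self.K)
        v = energy_force(coords, *self.args, self.delta, self.delta_v, grad, chi)
        return float(v), chi, grad


def compile_force_field(topology) -> CompiledForceField:
    """Flatten a SimulationTopology into kernel-ready concatenated arrays.

    Requires the flexible-local potential to be the generic zero fallback
    (the compiled path does not evaluate tables).
    """
    subs = topology.subsystems

    def cat(attr, basin, dtype=float):
        parts = [np.asarray(getattr(getattr(s, basin), attr), dtype=dtype)
                 for s in subs]
        return np.ascontiguousarray(np.concatenate(parts)) if parts else np.empty(0, dtype=dtype)

    def owners(attr, basin):
        parts = [np.full(len(getattr(getattr(s, basin), attr)), k, dtype=np.int64)
                 for k, s in enumerate(subs)]
        return np.ascontiguousarray(np.concatenate(parts))

    # local windows are identical across basins (same owners), only the
    # reference values differ
    args = (
        cat("bond_i", "basin_pre", np.int64), cat("bond_k", "basin_pre"),
        cat("bond_b0", "basin_pre"), cat("bond_b0", "basin_post"),
        owners("bond_i", "basin_pre"),
        cat("g13_i", "basin_pre", np.int64), cat("g13_eps", "basin_pre"),
        cat("g13_r0", "basin_pre"), cat("g13_r0", "basin_post"),
        cat("g13_w", "basin_pre"), owners("g13_i", "basin_pre"),
        cat("dih_i", "basin_pre", np.int64), cat("dih_eps", "basin_pre"),
        cat("dih_phi0", "basin_pre"), cat("dih_phi0", "basin_post"),
        cat("dih_w", "basin_pre"), owners("dih_i", "basin_pre"),
        cat("go_i", "basin_pre", np.int64), cat("go_j", "basin_pre", np.int64),
        cat("go_eps", "basin_pre"), cat("go_r0", "basin_pre"),
        owners("go_i", "basin_pre"),
        cat("go_i", "basin_post", np.int64), cat("go_j", "basin_post", np.int64),
        cat("go_eps", "basin_post"), cat("go_r0", "basin_post"),
        owners("go_i", "basin_post"),
        np.ascontiguousarray(topology.rep_i, dtype=np.int64),
        np.ascontiguousarray(topology.rep_j, dtype=np.int64),
        float(topology.eps_ev), float(topology.exv_d),
        float(topology.rep_cutoff), float(topology.go_cutoff_factor),
    )
    return CompiledForceField(
        args=args,
        delta=np.ascontiguousarray(topology.deltas()),
        delta_v=np.ascontiguousarray(topology.delta_vs()),
        n_beads=topology.n_beads,
        K=topology.K,
    )
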