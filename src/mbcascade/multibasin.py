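"""Multiple-basin mixing: the smoothly connected double-basin surface.

Two single-basin potentials V1 (pre) and V2 (post) are combined into the
smaller eigenvalue of the 2x2 matrix ``[[V1, D], [D, V2 + dV]]``.  The
coupling D (> 0) sets the barrier between the basins; dV shifts the second
basin relative to the first.  The log-ratio of the smaller-eigenvalue
eigenvector components defines the reaction coordinate chi, negative in
basin 1 and positive in basin 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import single_basin_energy, AICG2PParams
from .topology import SimulationTopology, SubsystemSpec

__all__ = ["BasinMixResult", "mix_energies", "subsystem_energy_force",
           "total_energy_force", "CHI_MAX"]

CHI_MAX = 50.0  # clamp for the log-ratio reaction coordinate


@dataclass
class BasinMixResult:
    v_mb: float
    chi: float
    w1: float
    w2: float


def mix_energies(v1: float, v2: float, delta: float, delta_v: float) -> BasinMixResult:
    """Closed-form smaller eigenvalue of the two-basin secular equation.

    V_MB = (V1 + V2')/2 - sqrt(((V1 - V2')/2)^2 + D^2) with V2' = V2 + dV.
    The mixing weights are the squared components of the normalized
    eigenvector, equal to dV_MB/dV1 and dV_MB/dV2; chi = ln|c2/c1| with
    |c2/c1| = (V1 - V_MB)/D, clamped to +-CHI_MAX.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    v2p = v2 + delta_v
    half_gap = 0.5 * (v1 - v2p)
    s = np.hypot(half_gap, delta)
    v_mb = 0.5 * (v1 + v2p) - s
    w1 = 0.5 - half_gap / (2.0 * s)
    w2 = 1.0 - w1
    ratio = (v1 - v_mb) / delta  # = |c2/c1| > 0
    if ratio <= np.exp(-CHI_MAX):
        chi = -CHI_MAX
    else:
        chi = float(np.clip(np.log(ratio), -CHI_MAX, CHI_MAX))
    return BasinMixResult(float(v_mb), chi, float(w1), float(w2))


def subsystem_energy_force(coords, subsystem: SubsystemSpec,
                           params: AICG2PParams):
    """Mixed energy, chi and gradient of one double-basin subsystem.

    The gradient follows from the chain rule on the closed form:
    grad V_MB = w1 grad V1 + w2 grad V2.
    """
    rep1 = single_basin_energy(coords, subsystem.basin_pre, params)
    rep2 = single_basin_energy(coords, subsystem.basin_post, params)
    mix = mix_energies(rep1.total, rep2.total, subsystem.delta, subsystem.delta_v)
    grad = mix.w1 * rep1.gradient + mix.w2 * rep2.gradient
    return mix.v_mb, mix.chi, grad


def total_energy_force(coords, topology: SimulationTopology,
                       params: AICG2PParams | None = None):
    """Sum of all K mixed subsystem energies plus the shared repulsion.

    Returns ``(V_total, chi, gradient)`` with ``chi`` the length-K vector of
    per-module reaction coordinates.  The excluded-volume term is common to
    both basins of every subsystem, so it adds to the total with unit weight
    and leaves every chi unchanged.
    """
    from .energy import excluded_volume_energy

    params = params or AICG2PParams()
    coords = np.asarray(coords, dtype=float)
    v_total = 0.0
    grad = np.zeros_like(coords)
    chis = np.empty(topology.K)
    for k, sub in enumerate(topology.subsystems):
        v, chi, g = subsystem_energy_force(coords, sub, params)
        v_total += v
        chis[k] = chi
        grad += g
    e_rep, g_rep = excluded_volume_energy(
        coords, topology.rep_i, topology.rep_j, topology.eps_ev,
        topology.exv_d, rcut=topology.rep_cutoff)
    v_total += e_rep
    grad += g_rep
    return float(v_total), chis, grad
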