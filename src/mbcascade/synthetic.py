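"""Desk-scale synthetic inputs with the statistical structure the pipeline assumes.

Two generators live here.  ``make_toy_two_state_protein`` builds a K-module
two-state structure pair for the simulator: each module is a short
helix-like C-alpha trace, the post state moves part of each module by a
rigid transform, and adjacent modules share state-specific interface
contacts.  ``simulate_gated_events`` is the kinetic oracle: a
continuous-time model in which each module fires with an exponential clock
whose rate can be suppressed until its gating predecessors have fired —
the ungated case reproduces the independent-exponentials null exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .topology import (ReferenceStructure, ModulePartition, define_partition,
                       build_topology, SimulationTopology, SubsystemSpec,
                       BasinTerms)

__all__ = [
    "RigidTransform",
    "ToyProteinSpec",
    "GatingSpec",
    "make_toy_two_state_protein",
    "simulate_gated_events",
    "make_cascade_benchmark",
    "write_reference_pdb",
]

# helix-like trace constants: 3.8 A virtual bonds from a 2.3 A radius,
# 1.5 A rise, 100 degree twist per residue
HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST = np.deg2rad(100.0)


@dataclass
class RigidTransform:
    """Rotation (axis, angle) about a pivot followed by a translation."""

    axis: tuple = (1.0, 0.0, 0.0)
    angle_deg: float = 0.0
    translation: tuple = (0.0, 0.0, 0.0)
    pivot: tuple | None = None  # default: the module's hinge point

    def matrix(self) -> np.ndarray:
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("rotation axis must be a finite non-zero vector")
        axis = axis / norm
        th = np.deg2rad(self.angle_deg)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)

    def apply(self, coords: np.ndarray, pivot: np.ndarray) -> np.ndarray:
        p = np.asarray(self.pivot if self.pivot is not None else pivot, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("translation must be finite")
        return (coords - p) @ self.matrix().T + p + t


@dataclass
class ToyProteinSpec:
    """Recipe for a K-module two-state toy protein.

    Modules are helix-like traces placed side by side along x at
    ``spacing``; the post state applies each module's rigid transform to
    either the whole module or its C-terminal half (``transform_scope``,
    a hinge motion that gives every module a genuine internal two-state
    change).  The default transforms tilt alternate modules in opposite
    directions so interfaces between mobile halves exist in the pre state
    only.
    """

    n_modules: int = 3
    beads_per_module: int = 12
    spacing: float = 9.0
    transforms: list[RigidTransform] | None = None
    transform_scope: str = "tail_half"
    tilt_deg: float = -120.0
    invert_alternate: bool = True
    min_separation: float = 3.5
    seed: int = 0

    def __post_init__(self):
        if self.n_modules < 1 or self.beads_per_module < 4:
            raise ValueError("need >= 1 module and >= 4 beads per module")
        if self.transform_scope not in ("module", "tail_half"):
            raise ValueError("transform_scope must be 'module' or 'tail_half'")


def _helix(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.stack([
        HELIX_RADIUS * np.cos(i * HELIX_TWIST),
        HELIX_RADIUS * np.sin(i * HELIX_TWIST),
        HELIX_RISE * i,
    ], axis=1)


def _default_transforms(spec: ToyProteinSpec) -> list[RigidTransform]:
    # swing the mobile half about the vertical axis through the hinge bead;
    # with alternate modules inverted, one common swing sense keeps the post
    # state clash-free and breaks every mobile-static interface
    return [
        RigidTransform(axis=(0.0, 0.0, 1.0), angle_deg=spec.tilt_deg)
        for m in range(spec.n_modules)
    ]


def make_toy_two_state_protein(spec: ToyProteinSpec):
    """Build (pre, post, partition) for a toy modular two-state protein.

    Both states share a deterministic construction frame with the pre-state
    centroid at the origin, so builds are bit-reproducible.  Raises if any
    transform brings two beads closer than ``spec.min_separation``.
    """
    n = spec.beads_per_module
    K = spec.n_modules
    transforms = spec.transforms or _default_transforms(spec)
    if len(transforms) != K:
        raise ValueError(f"need {K} transforms, got {len(transforms)}")

    pre_mods, post_mods = [], []
    for m in range(K):
        mod = _helix(n)  # local frame, helix axis along z
        half = n // 2
        # pivot at the first mobile bead: the cross-hinge virtual bond keeps
        # its reference length exactly, so the two basins differ through
        # bounded wells (contacts, 1-3, dihedrals) rather than a bond strain
        hinge_pivot = mod[half].copy()
        post = mod.copy()
        if spec.transform_scope == "module":
            post = transforms[m].apply(post, hinge_pivot)
        else:
            post[half:] = transforms[m].apply(post[half:], hinge_pivot)
        if spec.invert_alternate and m % 2 == 1:
            # rigid 180-degree flip about x through the module center, applied
            # to both states: the mobile (sequence-tail) half of every module
            # then faces the static (sequence-head) half of its successor
            c = mod.mean(axis=0)
            flip = RigidTransform(axis=(1.0, 0.0, 0.0), angle_deg=180.0)
            mod = flip.apply(mod, c)
            post = flip.apply(post, c)
        off = np.array([m * spec.spacing, 0.0, 0.0])
        pre_mods.append(mod + off)
        post_mods.append(post + off)

    pre = np.concatenate(pre_mods)
    post = np.concatenate(post_mods)
    center = pre.mean(axis=0)
    pre = pre - center
    post = post - center

    for label, coords in (("pre", pre), ("post", post)):
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        np.fill_diagonal(d, np.inf)
        d[np.abs(np.subtract.outer(np.arange(len(coords)),
                                   np.arange(len(coords)))) == 1] = np.inf
        if d.min() < spec.min_separation:
            i, j = np.unravel_index(np.argmin(d), d.shape)
            raise ValueError(
                f"{label} structure has a clash: beads {i} and {j} at "
                f"{d[i, j]:.2f} A (< {spec.min_separation} A)")

    ids = [str(i + 1) for i in range(K * n)]
    names = ["ALA"] * (K * n)
    # one chain per module: modules are tethered by interface contacts, not
    # by covalent linkers, so no bonded window spans a module boundary
    chains = np.repeat([chr(ord("A") + m) for m in range(K)], n)
    pre_ref = ReferenceStructure(pre, ids, names, "pre", chain_ids=chains)
    post_ref = ReferenceStructure(post, list(ids), list(names), "post",
                                  chain_ids=chains.copy())
    partition = define_partition(
        [(f"M{m + 1}", [(m * n + 1, (m + 1) * n)]) for m in range(K)], pre_ref)
    return pre_ref, post_ref, partition


def write_reference_pdb(reference: ReferenceStructure, path) -> None:
    """Write a C-alpha-only PDB file for a reference structure."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = reference.n_beads
    atoms = struc.AtomArray(n)
    atoms.coord = reference.coords
    atoms.atom_name = np.array(["CA"] * n)
    atoms.res_name = np.array(reference.residue_names)
    atoms.res_id = reference.residue_numbers
    atoms.chain_id = np.asarray(reference.chain_ids, dtype="U4")
    atoms.element = np.array(["C"] * n)
    f = pdb.PDBFile()
    pdb.set_structure(f, atoms)
    f.write(str(path))


# ---------------------------------------------------------------------------
# Gated continuous-time event oracle
# ---------------------------------------------------------------------------

@dataclass
class GatingSpec:
    """Gated exponential clocks for K modules.

    ``rates`` maps module name to its base rate in 1/10^4 MD steps.  A gate
    (a, b, eps) multiplies b's rate by eps (0 = strict gating, 1 = no
    gating) until a has transited; several gates on b multiply.  The gating
    graph must be acyclic.
    """

    rates: dict[str, float]
    gates: list[tuple[str, str, float]] = field(default_factory=list)
    n_traj: int = 30
    t_end: float = 1e7
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.rates.values()):
            raise ValueError("rates must be positive")
        for a, b, e in self.gates:
            if a not in self.rates or b not in self.rates:
                raise ValueError(f"gate ({a}, {b}) names unknown module")
            if not 0.0 <= e <= 1.0:
                raise ValueError("gate suppression must be in [0, 1]")
        # cycle check by iterated leaf removal
        edges = {(a, b) for a, b, _ in self.gates}
        nodes = set(self.rates)
        while True:
            leaves = {x for x in nodes if not any(b == x for _, b in edges)}
            if not leaves:
                break
            nodes -= leaves
            edges = {(a, b) for a, b in edges if a in nodes and b in nodes}
        if nodes:
            raise ValueError("gating graph has a cycle")


def simulate_gated_events(spec: GatingSpec) -> pd.DataFrame:
    """Simulate first-transition times under gated exponential kinetics.

    Returns an event table (trajectory, module, tau, censored, t_end,
    frame_steps) with tau in MD steps, censored at ``t_end``.  With all
    gates at eps = 1 the module clocks are exactly independent
    exponentials.
    """
    modules = list(spec.rates)
    base = np.array([spec.rates[m] / 1e4 for m in modules])  # per MD step
    gates_on = {m: [(modules.index(a), e) for a, b, e in spec.gates if b == m]
                for m in modules}
    rng = np.random.default_rng(spec.seed)
    rows = []
    for traj in range(spec.n_traj):
        fired = np.zeros(len(modules), dtype=bool)
        tau = np.full(len(modules), np.nan)
        t = 0.0
        while not fired.all():
            rates = np.where(fired, 0.0, base)
            for mi, m in enumerate(modules):
                if fired[mi]:
                    continue
                for ai, e in gates_on[m]:
                    if not fired[ai]:
                        rates[mi] *= e
            total = rates.sum()
            if total == 0.0:
                break
            t += rng.exponential(1.0 / total)
            if t > spec.t_end:
                break
            mi = rng.choice(len(modules), p=rates / total)
            fired[mi] = True
            tau[mi] = t
        for mi, m in enumerate(modules):
            rows.append({
                "trajectory": traj, "module": m,
                "tau": tau[mi] if fired[mi] else np.nan,
                "censored": not fired[mi], "t_end": spec.t_end,
                "frame_steps": 1,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end cascade benchmark
# ---------------------------------------------------------------------------

def make_cascade_benchmark(
    K: int = 3,
    coupling_strength: float = 1.0,
    beads_per_module: int = 12,
    intra_eps: float = 1.0,
    eps_loc: float = 2.0,
    interface_eps: float = 2.0,
    gate_grade: float = 0.5,
    scaffold_eps: float = 1.0,
    delta: float = 1.0,
    delta_v_base: float = -2.0,
    delta_v_step: float = 0.5,
    params=None,
):
    """Toy topology whose designed transition order is module 1, 2, ..., K.

    The pre state packs each module's mobile half against the static half
    of its successor.  Those gate contacts — present in the pre state only,
    owned by the successor — hold the successor's pre basin down until the
    predecessor has swung away, while persistent static-static interface
    contacts (``scaffold_eps``, both basins) keep the assembly tethered.
    The gate depth is ``interface_eps * coupling_strength``, deepened by
    ``gate_grade`` per step down the cascade so later modules are held
    harder, and a graded Delta-V drive (strongest on module 1) starts the
    cascade at the ungated end.  With ``coupling_strength = 0`` the gate
    contacts vanish and the modules transit independently.  Returns
    (topology, expected_order).
    """
    from .energy import AICG2PParams

    if coupling_strength < 0:
        raise ValueError("coupling_strength must be >= 0")
    spec = ToyProteinSpec(n_modules=K, beads_per_module=beads_per_module)
    pre, post, partition = make_toy_two_state_protein(spec)
    params = params or AICG2PParams(eps_go=intra_eps, eps_loc=eps_loc)
    delta_v = {f"M{m + 1}": delta_v_base + m * delta_v_step for m in range(K)}
    # gate contacts break when the predecessor moves, so the successor owns
    # them: its reaction coordinate (and basin weight) is held until then
    ownership = {(f"M{m}", f"M{m + 1}"): f"M{m + 1}" for m in range(1, K)}
    topology = build_topology(pre, post, partition, params=params,
                              delta=delta, delta_v=delta_v,
                              ownership_map=ownership)

    mod = partition.module_of_bead
    pair_sets = {
        attr: {s.name: set(zip(getattr(s, attr).go_i.tolist(),
                               getattr(s, attr).go_j.tolist()))
               for s in topology.subsystems}
        for attr in ("basin_pre", "basin_post")
    }
    subs = []
    for s in topology.subsystems:
        # the gate pairs of pair (m, m+1) are owned by M_{m+1}
        eps_gate = interface_eps * coupling_strength * \
            (1.0 + gate_grade * max(s.index - 1, 0))
        basins = {}
        for attr in ("basin_pre", "basin_post"):
            b = getattr(s, attr)
            other = "basin_post" if attr == "basin_pre" else "basin_pre"
            shared = pair_sets[other][s.name]
            inter = mod[b.go_i] != mod[b.go_j]
            persistent = np.array([(i, j) in shared
                                   for i, j in zip(b.go_i, b.go_j)])
            eps = b.go_eps.copy()
            # persistent inter-module pairs are scaffold; state-specific
            # inter pairs are gates (pre) or dropped (post)
            eps[inter & persistent] = scaffold_eps
            if attr == "basin_pre":
                eps[inter & ~persistent] = eps_gate
            else:
                eps[inter & ~persistent] = 0.0
            keep = eps > 0
            basins[attr] = BasinTerms(
                b.bond_i, b.bond_k, b.bond_b0,
                b.g13_i, b.g13_eps, b.g13_r0, b.g13_w,
                b.dih_i, b.dih_eps, b.dih_phi0, b.dih_w,
                b.go_i[keep], b.go_j[keep], eps[keep], b.go_r0[keep])
        subs.append(SubsystemSpec(s.name, s.index, s.delta, s.delta_v,
                                  basins["basin_pre"], basins["basin_post"]))
    topology = SimulationTopology(
        topology.pre, topology.post, topology.partition, subs,
        topology.rep_i, topology.rep_j, topology.eps_ev, topology.exv_d,
        topology.rep_cutoff, topology.go_cutoff_factor,
        {**topology.metadata, "benchmark": "cascade",
         "coupling_strength": coupling_strength,
         "expected_order": [f"M{m + 1}" for m in range(K)]},
    )
    return topology, [f"M{m + 1}" for m in range(K)]
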