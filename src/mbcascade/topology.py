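"""Two-state topology construction for modular multiple-basin models.

A protein with two reference conformations (``pre`` and ``post``) is
partitioned into K modules.  Each module becomes one double-basin
subsystem owning its intra-module interaction terms plus the inter-module
interface terms assigned to it, so that every term of either
whole-molecule single-basin model lives in exactly one subsystem.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _geometry as geom

__all__ = [
    "ReferenceStructure",
    "ModulePartition",
    "ContactList",
    "LocalGeometry",
    "SubsystemSpec",
    "BasinTerms",
    "SimulationTopology",
    "load_calpha_structure",
    "define_partition",
    "compute_native_contacts",
    "assign_interface_ownership",
    "build_topology",
]


@dataclass
class ReferenceStructure:
    """One bead per residue (C-alpha position) for one conformational state.

    ``residue_ids`` are author residue numbers with insertion codes appended
    (e.g. ``"100"`` or ``"100A"``); ``residue_numbers`` holds the numeric part
    for range lookups.  ``atom_coords`` optionally carries the full heavy-atom
    coordinates of each residue for all-atom contact detection.
    """

    coords: np.ndarray
    residue_ids: list[str]
    residue_names: list[str]
    state_label: str
    residue_numbers: np.ndarray = None
    atom_coords: list[np.ndarray] | None = None
    chain_ids: np.ndarray = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if len(self.coords) < 2:
            raise ValueError("a reference structure needs at least 2 beads")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in reference structure")
        if self.residue_numbers is None:
            nums = []
            for rid in self.residue_ids:
                s = str(rid)
                while s and not (s[-1].isdigit() or s[-1] == "-"):
                    s = s[:-1]
                nums.append(int(s))
            self.residue_numbers = np.asarray(nums, dtype=int)
        else:
            self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if self.chain_ids is None:
            self.chain_ids = np.full(len(self.coords), "A")
        else:
            self.chain_ids = np.asarray(self.chain_ids)

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    def bonded_eligible(self, window: int) -> np.ndarray:
        """Mask of local windows [i, i + window) lying within one chain."""
        n = self.n_beads
        ok = np.ones(n - window + 1, dtype=bool)
        for off in range(1, window):
            ok &= self.chain_ids[off:n - window + 1 + off] == \
                self.chain_ids[: n - window + 1]
        return ok

    def nonlocal_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """All pairs eligible for nonbonded terms: sequence separation > 3
        within a chain, any separation across chains."""
        n = self.n_beads
        ii, jj = np.triu_indices(n, k=1)
        keep = (jj > ii + 3) | (self.chain_ids[ii] != self.chain_ids[jj])
        return ii[keep], jj[keep]


@dataclass
class ModulePartition:
    """Ordered, disjoint, covering assignment of beads to named modules."""

    names: list[str]
    bead_indices: list[np.ndarray]   # per module, sorted bead indices
    module_of_bead: np.ndarray       # (N,) module index per bead

    @property
    def K(self) -> int:
        return len(self.names)

    def segments(self, m: int) -> list[tuple[int, int]]:
        """Contiguous bead-index segments (inclusive) of module m."""
        idx = self.bead_indices[m]
        if len(idx) == 0:
            return []
        breaks = np.where(np.diff(idx) > 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(idx) - 1]])
        return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


@dataclass
class ContactList:
    """Native-contact pairs of one reference state.

    ``owner`` is the index of the subsystem owning each pair (-1 before
    ownership assignment).  ``r0`` is the C-alpha pair distance in the
    reference, ``eps`` the Go well depth (kcal/mol).
    """

    i: np.ndarray
    j: np.ndarray
    r0: np.ndarray
    eps: np.ndarray
    state_label: str
    owner: np.ndarray = None

    def __post_init__(self):
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        self.r0 = np.asarray(self.r0, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        if self.owner is None:
            self.owner = np.full(len(self.i), -1, dtype=np.int64)
        else:
            self.owner = np.asarray(self.owner, dtype=np.int64)
        if len(self.i) and (np.any(self.r0 <= 0) or np.any(self.eps <= 0)):
            raise ValueError("contact r0 and eps must be positive")

    def __len__(self):
        return len(self.i)

    def pair_set(self) -> set[tuple[int, int]]:
        return set(zip(self.i.tolist(), self.j.tolist()))


@dataclass
class LocalGeometry:
    """Reference values of the local (bonded) terms of one state.

    Bond terms live on (i, i+1), 1-3 Gaussians on (i, i+2) and dihedral
    Gaussians on (i .. i+3); windows must lie within one chain.  ``owner``
    arrays assign every window to the module of its first residue.
    """

    bond_idx: np.ndarray     # window start bead indices
    bond_b0: np.ndarray
    bond_k: np.ndarray
    bond_owner: np.ndarray
    g13_idx: np.ndarray
    g13_r0: np.ndarray
    g13_eps: np.ndarray
    g13_w: np.ndarray
    g13_owner: np.ndarray
    dih_idx: np.ndarray
    dih_phi0: np.ndarray
    dih_eps: np.ndarray
    dih_w: np.ndarray
    dih_owner: np.ndarray

    def __post_init__(self):
        for name in ("g13_w", "dih_w"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if np.any(self.bond_k < 0):
            raise ValueError("bond constants must be non-negative")


@dataclass
class BasinTerms:
    """Flat term arrays of one basin of one subsystem (or a whole molecule)."""

    bond_i: np.ndarray
    bond_k: np.ndarray
    bond_b0: np.ndarray
    g13_i: np.ndarray
    g13_eps: np.ndarray
    g13_r0: np.ndarray
    g13_w: np.ndarray
    dih_i: np.ndarray
    dih_eps: np.ndarray
    dih_phi0: np.ndarray
    dih_w: np.ndarray
    go_i: np.ndarray
    go_j: np.ndarray
    go_eps: np.ndarray
    go_r0: np.ndarray


@dataclass
class SubsystemSpec:
    """One double-basin subsystem: a module plus its owned interface terms."""

    name: str
    index: int
    delta: float
    delta_v: float
    basin_pre: BasinTerms
    basin_post: BasinTerms

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError(f"subsystem {self.name}: delta must be > 0")


@dataclass
class SimulationTopology:
    """K double-basin subsystems plus the shared repulsion pair list."""

    pre: ReferenceStructure
    post: ReferenceStructure
    partition: ModulePartition
    subsystems: list[SubsystemSpec]
    rep_i: np.ndarray
    rep_j: np.ndarray
    eps_ev: float
    exv_d: float
    rep_cutoff: float
    go_cutoff_factor: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return self.pre.n_beads

    @property
    def K(self) -> int:
        return len(self.subsystems)

    @property
    def module_names(self) -> list[str]:
        return [s.name for s in self.subsystems]

    def deltas(self) -> np.ndarray:
        return np.array([s.delta for s in self.subsystems])

    def delta_vs(self) -> np.ndarray:
        return np.array([s.delta_v for s in self.subsystems])

    def with_delta_v(self, offsets: dict[str, float]) -> "SimulationTopology":
        """Copy of the topology with per-module Delta-V offsets applied."""
        unknown = set(offsets) - set(self.module_names)
        if unknown:
            raise ValueError(f"unknown modules in delta_v offsets: {sorted(unknown)}")
        subs = []
        for s in self.subsystems:
            dv = s.delta_v + offsets.get(s.name, 0.0)
            subs.append(SubsystemSpec(s.name, s.index, s.delta, dv, s.basin_pre, s.basin_post))
        return SimulationTopology(
            self.pre, self.post, self.partition, subs, self.rep_i, self.rep_j,
            self.eps_ev, self.exv_d, self.rep_cutoff, self.go_cutoff_factor,
            dict(self.metadata),
        )

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        def arr(a):
            return np.asarray(a).tolist()

        doc = {
            "n_beads": self.n_beads,
            "eps_ev": self.eps_ev,
            "exv_d": self.exv_d,
            "rep_cutoff": self.rep_cutoff,
            "go_cutoff_factor": self.go_cutoff_factor,
            "metadata": self.metadata,
            "partition": {
                "names": self.partition.names,
                "bead_indices": [arr(b) for b in self.partition.bead_indices],
            },
            "references": {
                lbl: {
                    "coords": arr(ref.coords),
                    "residue_ids": ref.residue_ids,
                    "residue_names": ref.residue_names,
                    "chain_ids": arr(ref.chain_ids),
                }
                for lbl, ref in (("pre", self.pre), ("post", self.post))
            },
            "rep_pairs": {"i": arr(self.rep_i), "j": arr(self.rep_j)},
            "subsystems": [
                {
                    "name": s.name,
                    "delta": s.delta,
                    "delta_v": s.delta_v,
                    "basins": {
                        lbl: {f: arr(getattr(b, f)) for f in vars(b)}
                        for lbl, b in (("pre", s.basin_pre), ("post", s.basin_post))
                    },
                }
                for s in self.subsystems
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTopology":
        doc = json.loads(text)
        refs = {}
        for lbl, r in doc["references"].items():
            refs[lbl] = ReferenceStructure(
                np.array(r["coords"]), r["residue_ids"], r["residue_names"], lbl,
                chain_ids=np.array(r["chain_ids"]) if "chain_ids" in r else None,
            )
        names = doc["partition"]["names"]
        bead_indices = [np.asarray(b, dtype=np.int64) for b in doc["partition"]["bead_indices"]]
        mod = np.full(doc["n_beads"], -1, dtype=np.int64)
        for m, idx in enumerate(bead_indices):
            mod[idx] = m
        part = ModulePartition(names, bead_indices, mod)
        subs = []
        for k, s in enumerate(doc["subsystems"]):
            basins = {}
            for lbl, b in s["basins"].items():
                kwargs = {}
                for f, v in b.items():
                    dtype = np.int64 if f.endswith("_i") or f.endswith("_j") else float
                    kwargs[f] = np.asarray(v, dtype=dtype)
                basins[lbl] = BasinTerms(**kwargs)
            subs.append(SubsystemSpec(s["name"], k, s["delta"], s["delta_v"],
                                      basins["pre"], basins["post"]))
        return cls(
            refs["pre"], refs["post"], part, subs,
            np.asarray(doc["rep_pairs"]["i"], dtype=np.int64),
            np.asarray(doc["rep_pairs"]["j"], dtype=np.int64),
            doc["eps_ev"], doc["exv_d"], doc["rep_cutoff"], doc["go_cutoff_factor"],
            doc.get("metadata", {}),
        )


# ---------------------------------------------------------------------------
# PDB loading
# ---------------------------------------------------------------------------

def load_calpha_structure(pdb_text: str, state_label: str,
                          keep_all_atoms: bool = True) -> ReferenceStructure:
    """Read a PDB document into a one-bead-per-residue reference structure.

    The bead sits at the C-alpha position.  Alternate locations resolve to
    altloc "A" (or blank); insertion codes are preserved in the residue ids.
    When ``keep_all_atoms`` is true the heavy-atom coordinates of every
    residue are retained for the all-atom contact criterion.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(io.StringIO(pdb_text))
    atoms = pdb.get_structure(pdb_file, model=1, altloc="first",
                              extra_fields=["atom_id"])
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise ValueError("no ATOM records in PDB input")

    coords, rids, rnames, chains, atom_coords = [], [], [], [], []
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for a, b in zip(starts[:-1], starts[1:]):
        res = atoms[a:b]
        ca = res[res.atom_name == "CA"]
        ins = res.ins_code[0] if hasattr(res, "ins_code") else ""
        rid = f"{res.res_id[0]}{ins}".strip()
        if ca.array_length() == 0:
            raise ValueError(f"missing CA at residue {rid}")
        coords.append(ca.coord[0])
        rids.append(rid)
        rnames.append(str(res.res_name[0]))
        chains.append(str(res.chain_id[0]))
        if keep_all_atoms:
            heavy = res[~np.char.startswith(res.element, "H")]
            atom_coords.append(np.array(heavy.coord, dtype=float))
    if len(coords) < 2:
        raise ValueError("fewer than 2 CA records in PDB input")
    return ReferenceStructure(
        np.array(coords, dtype=float), rids, rnames, state_label,
        atom_coords=atom_coords if keep_all_atoms else None,
        chain_ids=np.array(chains),
    )


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def define_partition(spec: list[tuple[str, list[tuple[int, int]]]],
                     structure: ReferenceStructure) -> ModulePartition:
    """Partition beads into named modules from author-numbered residue ranges.

    Each module maps to a list of inclusive ``(first, last)`` residue-number
    ranges; a module may own several disconnected segments.  The ranges must
    be disjoint and together cover every bead.
    """
    n = structure.n_beads
    nums = structure.residue_numbers
    module_of_bead = np.full(n, -1, dtype=np.int64)
    names, bead_indices = [], []
    for m, (name, ranges) in enumerate(spec):
        sel = np.zeros(n, dtype=bool)
        for lo, hi in ranges:
            in_range = (nums >= lo) & (nums <= hi)
            if not in_range.any():
                raise ValueError(
                    f"module {name}: range {lo}-{hi} matches no residue")
            sel |= in_range
        clash = sel & (module_of_bead >= 0)
        if clash.any():
            other = names[module_of_bead[np.where(clash)[0][0]]]
            raise ValueError(f"modules {other} and {name} overlap")
        module_of_bead[sel] = m
        names.append(name)
        bead_indices.append(np.where(sel)[0])
    uncovered = np.where(module_of_bead < 0)[0]
    if len(uncovered):
        missing = [structure.residue_ids[i] for i in uncovered[:10]]
        raise ValueError(f"residues not covered by any module: {missing}")
    return ModulePartition(names, bead_indices, module_of_bead)


# ---------------------------------------------------------------------------
# Native contacts
# ---------------------------------------------------------------------------

def compute_native_contacts(reference: ReferenceStructure, cutoff: float = 6.5,
                            mode: str = "auto", eps_go: float = 0.3) -> ContactList:
    """Native contacts of one reference state.

    A pair (i, j) with sequence separation > 3 is native when its minimum
    inter-residue distance is within ``cutoff``.  In ``allatom`` mode the
    minimum runs over all heavy-atom pairs (the criterion used for real
    structures); in ``calpha`` mode the C-alpha distance is used.  ``auto``
    selects ``allatom`` whenever atom coordinates are available.  ``r0`` is
    always the C-alpha distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if mode == "auto":
        mode = "allatom" if reference.atom_coords is not None else "calpha"
    if mode == "allatom" and reference.atom_coords is None:
        raise ValueError("all-atom contact mode requires atom coordinates")

    coords = reference.coords
    diff = coords[:, None, :] - coords[None, :, :]
    dca = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    # separation > 3 within a chain; any separation across chains
    ii, jj = reference.nonlocal_pairs()

    if mode == "calpha":
        keep = dca[ii, jj] <= cutoff
    else:
        # prefilter on CA distance: two residues cannot have atoms within
        # the cutoff if their CAs are farther apart than cutoff + 2 * rmax
        radii = np.array([
            np.max(np.linalg.norm(ac - c, axis=1)) if len(ac) else 0.0
            for ac, c in zip(reference.atom_coords, coords)
        ])
        keep = np.zeros(len(ii), dtype=bool)
        cand = dca[ii, jj] <= cutoff + radii[ii] + radii[jj]
        for idx in np.where(cand)[0]:
            a = reference.atom_coords[ii[idx]]
            b = reference.atom_coords[jj[idx]]
            d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2)
            keep[idx] = d2.min() <= cutoff**2
    ii, jj = ii[keep], jj[keep]
    return ContactList(
        ii, jj, dca[ii, jj], np.full(len(ii), eps_go), reference.state_label
    )


def assign_interface_ownership(
    partition: ModulePartition,
    contacts_pre: ContactList,
    contacts_post: ContactList,
    ownership_map: dict[tuple[str, str], str] | None = None,
) -> tuple[ContactList, ContactList]:
    """Assign every contact to exactly one owning subsystem.

    Intra-module contacts belong to their module.  An interface pair defaults
    to the module that comes earlier in partition order; ``ownership_map``
    overrides the owner per unordered module-name pair.
    """
    name_to_idx = {n: m for m, n in enumerate(partition.names)}
    overrides = {}
    if ownership_map:
        for pair, owner in ownership_map.items():
            for nm in (*pair, owner):
                if nm not in name_to_idx:
                    raise ValueError(f"ownership map names unknown module {nm!r}")
            overrides[frozenset(pair)] = name_to_idx[owner]

    def fill(contacts: ContactList) -> ContactList:
        mi = partition.module_of_bead[contacts.i]
        mj = partition.module_of_bead[contacts.j]
        owner = np.minimum(mi, mj)  # default: earlier module in partition order
        for k in range(len(contacts)):
            if mi[k] != mj[k]:
                key = frozenset((partition.names[mi[k]], partition.names[mj[k]]))
                if key in overrides:
                    owner[k] = overrides[key]
        return ContactList(contacts.i, contacts.j, contacts.r0, contacts.eps,
                           contacts.state_label, owner)

    return fill(contacts_pre), fill(contacts_post)


# ---------------------------------------------------------------------------
# Local geometry and topology assembly
# ---------------------------------------------------------------------------

def _local_geometry(reference: ReferenceStructure, partition: ModulePartition,
                    params) -> LocalGeometry:
    c = reference.coords
    mod = partition.module_of_bead
    bond_idx = np.where(reference.bonded_eligible(2))[0]
    g13_idx = np.where(reference.bonded_eligible(3))[0]
    dih_idx = np.where(reference.bonded_eligible(4))[0]
    bond_b0 = np.linalg.norm(c[bond_idx + 1] - c[bond_idx], axis=1)
    g13_r0 = np.linalg.norm(c[g13_idx + 2] - c[g13_idx], axis=1)
    dih_phi0 = geom.dihedral_angles(c, dih_idx, dih_idx + 1, dih_idx + 2, dih_idx + 3)
    half = 0.5 * params.eps_loc  # split equally between 1-3 and dihedral terms
    return LocalGeometry(
        bond_idx=bond_idx,
        bond_b0=bond_b0,
        bond_k=np.full(len(bond_idx), params.k_b),
        bond_owner=mod[bond_idx],
        g13_idx=g13_idx,
        g13_r0=g13_r0,
        g13_eps=np.full(len(g13_idx), half),
        g13_w=np.full(len(g13_idx), params.w13),
        g13_owner=mod[g13_idx],
        dih_idx=dih_idx,
        dih_phi0=dih_phi0,
        dih_eps=np.full(len(dih_idx), half),
        dih_w=np.full(len(dih_idx), params.w_phi),
        dih_owner=mod[dih_idx],
    )


def _basin_terms(local: LocalGeometry, contacts: ContactList, owner: int) -> BasinTerms:
    bsel = local.bond_owner == owner
    gsel = local.g13_owner == owner
    dsel = local.dih_owner == owner
    csel = contacts.owner == owner
    bi = local.bond_idx[bsel]
    gi = local.g13_idx[gsel]
    di = local.dih_idx[dsel]
    return BasinTerms(
        bond_i=bi, bond_k=local.bond_k[bsel], bond_b0=local.bond_b0[bsel],
        g13_i=gi, g13_eps=local.g13_eps[gsel], g13_r0=local.g13_r0[gsel],
        g13_w=local.g13_w[gsel],
        dih_i=di, dih_eps=local.dih_eps[dsel], dih_phi0=local.dih_phi0[dsel],
        dih_w=local.dih_w[dsel],
        go_i=contacts.i[csel], go_j=contacts.j[csel],
        go_eps=contacts.eps[csel], go_r0=contacts.r0[csel],
    )


def build_topology(
    pre_ref: ReferenceStructure,
    post_ref: ReferenceStructure,
    partition: ModulePartition,
    params=None,
    delta=5.0,
    delta_v=0.0,
    ownership_map: dict[tuple[str, str], str] | None = None,
    contact_weights: dict | None = None,
) -> SimulationTopology:
    """Assemble the K double-basin subsystems of a two-state modular model.

    ``delta`` and ``delta_v`` may be scalars or ``{module: value}`` dicts
    (kcal/mol).  ``contact_weights`` optionally overrides the uniform Go
    depth per (i, j) bead pair.  Every local and contact term of either
    whole-molecule single-basin model is owned by exactly one subsystem.
    """
    from .energy import AICG2PParams

    params = params or AICG2PParams()
    if pre_ref.n_beads != post_ref.n_beads:
        raise ValueError(
            f"bead count mismatch: pre has {pre_ref.n_beads}, post has {post_ref.n_beads}")

    def per_module(val, what):
        if isinstance(val, dict):
            unknown = set(val) - set(partition.names)
            if unknown:
                raise ValueError(f"unknown modules in {what}: {sorted(unknown)}")
            return [float(val.get(nm, 0.0 if what == "delta_v" else 1.0))
                    for nm in partition.names]
        return [float(val)] * partition.K

    deltas = per_module(delta, "delta")
    dvs = per_module(delta_v, "delta_v")
    for nm, dl in zip(partition.names, deltas):
        if dl <= 0:
            raise ValueError(f"subsystem {nm}: delta must be > 0")

    contacts = {}
    for ref in (pre_ref, post_ref):
        cl = compute_native_contacts(ref, cutoff=params.contact_cutoff,
                                     mode=params.contact_mode, eps_go=params.eps_go)
        if contact_weights:
            eps = cl.eps.copy()
            for k, (i, j) in enumerate(zip(cl.i, cl.j)):
                eps[k] = contact_weights.get((int(i), int(j)), eps[k])
            cl = ContactList(cl.i, cl.j, cl.r0, eps, cl.state_label)
        contacts[ref.state_label] = cl
    c_pre, c_post = assign_interface_ownership(
        partition, contacts["pre"], contacts["post"], ownership_map)

    loc_pre = _local_geometry(pre_ref, partition, params)
    loc_post = _local_geometry(post_ref, partition, params)

    subsystems = []
    for m, name in enumerate(partition.names):
        subsystems.append(SubsystemSpec(
            name=name, index=m, delta=deltas[m], delta_v=dvs[m],
            basin_pre=_basin_terms(loc_pre, c_pre, m),
            basin_post=_basin_terms(loc_post, c_post, m),
        ))

    # shared repulsion: nonlocal pairs that are native in neither state are
    # repulsive everywhere; a pair native in either basin of its owner is
    # exempt so attraction and repulsion never clash mid-transition
    ii, jj = pre_ref.nonlocal_pairs()
    native = c_pre.pair_set() | c_post.pair_set()
    keep = np.array([(a, b) not in native for a, b in zip(ii, jj)], dtype=bool)

    mode = params.contact_mode
    if mode == "auto":
        mode = "allatom" if pre_ref.atom_coords is not None else "calpha"
    return SimulationTopology(
        pre=pre_ref, post=post_ref, partition=partition, subsystems=subsystems,
        rep_i=ii[keep], rep_j=jj[keep],
        eps_ev=params.eps_ev, exv_d=params.exv_d,
        rep_cutoff=params.rep_cutoff, go_cutoff_factor=params.go_cutoff_factor,
        metadata={
            "contact_cutoff": params.contact_cutoff,
            "contact_mode": mode,
            "n_contacts_pre": len(c_pre),
            "n_contacts_post": len(c_post),
            "flexible_local": "generic-zero fallback",
        },
    )


def contact_census(topology: SimulationTopology) -> dict[str, np.ndarray]:
    """Per-state K x K symmetric matrices of contact counts between modules."""
    mod = topology.partition.module_of_bead
    out = {}
    for state, attr in (("pre", "basin_pre"), ("post", "basin_post")):
        census = np.zeros((topology.K, topology.K), dtype=int)
        for s in topology.subsystems:
            b = getattr(s, attr)
            for i, j in zip(b.go_i, b.go_j):
                a, c = mod[i], mod[j]
                census[a, c] += 1
                if a != c:
                    census[c, a] += 1
        out[state] = census
    return out
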