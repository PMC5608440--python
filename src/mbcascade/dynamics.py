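"""Underdamped Langevin dynamics on the multiple-basin surface.

Internal units: energy kcal/mol, length Angstrom, uniform bead mass 1,
k_B = 1.987e-3 kcal/mol/K; the time unit is fixed by these choices and
times are reported in MD steps.  The integrator is a BAOAB splitting of
underdamped Langevin dynamics; with friction 0 and temperature 0 it reduces
to velocity Verlet.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .energy import KB_KCAL
from ._kernel import compile_force_field, baoab_chunk, CompiledForceField
from .topology import SimulationTopology, SubsystemSpec

__all__ = [
    "DynamicsParams",
    "SimulationState",
    "ChiTrajectory",
    "langevin_step",
    "run_trajectory",
    "run_ensemble",
    "parameter_scan",
]


@dataclass
class DynamicsParams:
    """Integration settings.

    dt             time step (internal units); the default keeps the
                   stiffest virtual-bond period above 20 steps
    gamma          friction (1/internal time)
    temperature    thermostat temperature (K)
    n_steps        total MD steps per trajectory
    save_interval  steps between saved chi frames
    mass           uniform bead mass (internal units)
    """

    dt: float = 0.02
    gamma: float = 0.02
    temperature: float = 300.0
    n_steps: int = 10_000_000
    save_interval: int = 1000
    mass: float = 1.0

    def __post_init__(self):
        if self.dt <= 0 or self.n_steps < 1 or self.save_interval < 1:
            raise ValueError("dt, n_steps and save_interval must be positive")
        if self.gamma < 0 or self.temperature < 0:
            raise ValueError("gamma and temperature must be non-negative")

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature


@dataclass
class SimulationState:
    """Coordinates, velocities and cached gradient of a running simulation."""

    coords: np.ndarray
    velocities: np.ndarray
    step: int = 0
    gradient: np.ndarray | None = None


def langevin_step(state: SimulationState, force_field, params: DynamicsParams,
                  rng: np.random.Generator) -> SimulationState:
    """One BAOAB step with a generic ``force_field(coords) -> (V, grad)``.

    This readable per-step path serves small systems and analytic toys; long
    runs use the compiled block integrator, which implements the identical
    scheme.
    """
    x = np.array(state.coords, dtype=float)
    v = np.array(state.velocities, dtype=float)
    m = params.mass
    if state.gradient is None:
        _, grad = force_field(x)
    else:
        grad = state.gradient
    if not np.all(np.isfinite(grad)):
        raise RuntimeError(f"non-finite force at step {state.step}")
    half = 0.5 * params.dt
    v = v - half * grad / m
    x = x + half * v
    c1 = np.exp(-params.gamma * params.dt)
    c2 = np.sqrt(params.kT * (1.0 - c1 * c1) / m)
    v = c1 * v + c2 * rng.standard_normal(v.shape)
    x = x + half * v
    _, grad = force_field(x)
    v = v - half * grad / m
    if not np.all(np.isfinite(x)):
        raise RuntimeError(f"non-finite coordinates at step {state.step + 1}")
    return SimulationState(x, v, state.step + 1, grad)


@dataclass
class ChiTrajectory:
    """Per-module reaction-coordinate time series of one run."""

    steps: np.ndarray            # saved MD step numbers, strictly increasing
    chi: np.ndarray              # (n_saved, K)
    module_names: list[str]
    direction: str               # "power" (pre -> post) or "recovery"
    seed: int
    params: DynamicsParams
    coords_frames: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def t_end(self) -> int:
        return int(self.steps[-1])

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write(f"# direction={self.direction} seed={self.seed} "
                     f"dt={self.params.dt} gamma={self.params.gamma} "
                     f"temperature={self.params.temperature} "
                     f"save_interval={self.params.save_interval}\n")
            cols = "\t".join(f"chi_{m}" for m in self.module_names)
            fh.write(f"step\t{cols}\n")
            for s, row in zip(self.steps, self.chi):
                fh.write(str(int(s)) + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "ChiTrajectory":
        meta = {}
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                meta[k] = v
        df = pd.read_csv(path, sep="\t", comment="#")
        modules = [c[4:] for c in df.columns if c.startswith("chi_")]
        params = DynamicsParams(
            dt=float(meta.get("dt", 0.02)), gamma=float(meta.get("gamma", 0.02)),
            temperature=float(meta.get("temperature", 300.0)),
            n_steps=max(int(df["step"].iloc[-1]), 1),
            save_interval=int(meta.get("save_interval", 1000)),
        )
        return cls(df["step"].to_numpy(), df[[f"chi_{m}" for m in modules]].to_numpy(),
                   modules, meta.get("direction", "power"), int(meta.get("seed", 0)),
                   params)


def _params_hash(topology: SimulationTopology, params: DynamicsParams) -> str:
    h = hashlib.sha256()
    h.update(topology.to_json().encode())
    h.update(repr(params).encode())
    return h.hexdigest()[:12]


def run_trajectory(
    topology: SimulationTopology,
    params: DynamicsParams,
    start_state_label: str = "pre",
    seed: int = 0,
    direction: str | None = None,
    force_field: CompiledForceField | None = None,
    record_coords: bool = False,
) -> ChiTrajectory:
    """Integrate one trajectory and record chi for every module.

    The run starts at the chosen reference structure with Maxwell-Boltzmann
    velocities and is bit-reproducible for a given (seed, params, topology).
    ``direction`` defaults to "power" when starting from pre and "recovery"
    when starting from post.
    """
    if start_state_label not in ("pre", "post"):
        raise ValueError("start_state_label must be 'pre' or 'post'")
    if direction is None:
        direction = "power" if start_state_label == "pre" else "recovery"
    ff = force_field or compile_force_field(topology)
    rng = np.random.default_rng(seed)
    coords = np.array(getattr(topology, start_state_label).coords, dtype=float)
    vels = rng.standard_normal(coords.shape) * np.sqrt(params.kT / params.mass)

    n_chunks = params.n_steps // params.save_interval
    rem = params.n_steps - n_chunks * params.save_interval
    steps = [0]
    _, chi0, grad = ff.energy_force(coords)
    chi_frames = [chi0.copy()]
    frames = [coords.copy()] if record_coords else None
    chi_buf = np.zeros(ff.K)
    n = len(coords)
    for chunk in range(n_chunks + (1 if rem else 0)):
        nsteps = params.save_interval if chunk < n_chunks else rem
        noise = rng.standard_normal((nsteps, n, 3))
        baoab_chunk(coords, vels, grad, noise, params.dt, params.gamma,
                    params.kT, params.mass, *ff.args, ff.delta, ff.delta_v,
                    chi_buf)
        if not np.all(np.isfinite(coords)):
            raise RuntimeError(
                f"non-finite coordinates near step {(chunk + 1) * params.save_interval} "
                f"(seed {seed}); last finite frame at step {steps[-1]}")
        steps.append(steps[-1] + nsteps)
        chi_frames.append(chi_buf.copy())
        if record_coords:
            frames.append(coords.copy())
    return ChiTrajectory(
        steps=np.array(steps), chi=np.array(chi_frames),
        module_names=topology.module_names, direction=direction, seed=seed,
        params=params,
        coords_frames=np.array(frames) if record_coords else None,
        metadata={"params_hash": _params_hash(topology, params),
                  "start_state": start_state_label},
    )


def run_ensemble(
    topology: SimulationTopology,
    params: DynamicsParams,
    n_traj: int,
    base_seed: int = 0,
    start_state_label: str = "pre",
    direction: str | None = None,
) -> list[ChiTrajectory]:
    """Independent trajectories with seeds base_seed + i."""
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    ff = compile_force_field(topology)
    return [
        run_trajectory(topology, params, start_state_label, base_seed + i,
                       direction, force_field=ff)
        for i in range(n_traj)
    ]


def _with_basin_params(topology: SimulationTopology, delta=None, delta_v=None):
    subs = []
    for s in topology.subsystems:
        dl = delta[s.name] if isinstance(delta, dict) else (delta if delta is not None else s.delta)
        dv = delta_v[s.name] if isinstance(delta_v, dict) else (delta_v if delta_v is not None else s.delta_v)
        subs.append(SubsystemSpec(s.name, s.index, float(dl), float(dv),
                                  s.basin_pre, s.basin_post))
    return SimulationTopology(
        topology.pre, topology.post, topology.partition, subs,
        topology.rep_i, topology.rep_j, topology.eps_ev, topology.exv_d,
        topology.rep_cutoff, topology.go_cutoff_factor, dict(topology.metadata))


def parameter_scan(
    topology: SimulationTopology,
    grid: list[dict],
    params: DynamicsParams,
    n_traj: int = 3,
    base_seed: int = 0,
    chi_threshold: float = 1.0,
    persistence: int = 2,
    immediate_fraction: float = 0.02,
) -> pd.DataFrame:
    """Survey (delta, delta_v) cells for usable transition behavior.

    Each grid cell is ``{"label": str, "delta": scalar|dict, "delta_v":
    scalar|dict}``.  Per cell the scan reports the fraction of
    (trajectory, module) pairs with at least one transition, the mean first-
    transition time, and pathology flags: transitions never observed,
    transitions essentially immediate, or basins coalesced into a single
    well around chi = 0.
    """
    from .analysis import detect_transitions

    rows = []
    for cell in grid:
        topo = _with_basin_params(topology, cell.get("delta"), cell.get("delta_v"))
        trajs = run_ensemble(topo, params, n_traj, base_seed)
        events = detect_transitions(trajs, chi_threshold=chi_threshold,
                                    persistence=persistence)
        done = events[~events["censored"]]
        frac = len(done) / len(events)
        mean_tau = float(done["tau"].mean()) if len(done) else np.nan
        chi_all = np.concatenate([t.chi.ravel() for t in trajs])
        coalesced = float(np.mean(np.abs(chi_all) < chi_threshold)) > 0.5
        flags = []
        if frac == 0.0:
            flags.append("no_transition")
        elif len(done) and float(done["tau"].median()) < immediate_fraction * params.n_steps:
            flags.append("immediate_transition")
        if coalesced:
            flags.append("coalesced_basins")
        rows.append({
            "label": cell.get("label", str(len(rows))),
            "fraction_transitioned": frac,
            "mean_first_transition": mean_tau,
            "flags": ",".join(flags),
        })
    return pd.DataFrame(rows)
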