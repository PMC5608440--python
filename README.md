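# mbcascade

Modular multiple-basin coarse-grained dynamics and transition-order
analysis for proteins that switch between two conformational states.

Large motor proteins such as the dynein motor domain change conformation
module by module: the AAA+ ring, the linker and the microtubule-binding
domain each flip between a "pre" and a "post" state, and the *order* of
those flips encodes the allosteric pathway.  `mbcascade` is a toolkit for
studying exactly that question in silico:

* **Topology** — read two reference structures (Cα-level PDB), partition
  the residues into K modules (segments may be disconnected), detect
  state-specific native contacts (6.5 Å rule, all-atom or Cα criterion)
  and assemble K double-basin subsystems.  Every interaction term of
  either whole-molecule structure-based model is owned by exactly one
  subsystem; inter-module interface terms go to a single owner
  (configurable, default: the earlier module).
* **Energy model** — a Cα structure-based (AICG2+-style) potential per
  basin: harmonic virtual bonds, Gaussian wells on 1–3 distances and
  dihedrals, a 12-10 native-contact attraction, generic `(d/r)^12`
  repulsion, and an optional tabulated sequence-dependent local term.
* **Multiple-basin mixing** — each subsystem's two basin potentials V₁
  (pre) and V₂ (post) are coupled into the smaller eigenvalue of

  ```
  | V₁      Δ      | (c₁)      (c₁)
  |                | (  ) = V  (  )
  | Δ   V₂ + ΔV    | (c₂)      (c₂)
  ```

  V_MB = (V₁+V₂+ΔV)/2 − √(((V₁−V₂−ΔV)/2)² + Δ²).  Δ sets the barrier,
  ΔV the relative stability of the post basin.  The reaction coordinate
  χ = ln(c₂/c₁) of the mixing eigenvector is negative in the pre basin
  and positive in the post basin; the total surface is V_total = Σ_I V_MB,I.
* **Dynamics** — underdamped Langevin (BAOAB splitting) on V_total with a
  compiled force kernel, recording per-module χ along each trajectory.
* **Cascade statistics** — first-passage transition times with hysteresis
  detection, the order map P-order(b←a) (fraction of trajectories in
  which module a flips before b), heuristic pair rates
  k(b|a) = ⟨1/Δt_ab⟩ in 1/10⁴ steps with censored waits set to the run
  end, percentile-bootstrap CIs, exact binomial order p-values with
  multiple-testing correction, scaled-time ensemble averages, and a
  one-sample Kolmogorov–Smirnov test of observed Δt against the analytic
  difference-of-two-exponentials null — the "independent pair" versus
  "dependent pair" diagnosis.
* **Synthetic data** — a generator of K-module two-state toy proteins
  (helix-like modules, hinge motions, state-specific interfaces) and a
  gated-exponential continuous-time oracle for validating the statistics
  end to end.

## Worked example: a three-module cascade

The built-in benchmark constructs a K=3 toy whose designed transition
order is M1 → M2 → M3: each module's mobile half packs against the next
module's static half in the pre state, so module m+1's pre basin is held
down until module m has swung away.

```python
from mbcascade import (make_cascade_benchmark, DynamicsParams, run_ensemble,
                       detect_transitions, order_map, pair_rates)

topology, expected = make_cascade_benchmark(K=3, coupling_strength=1.0)
params = DynamicsParams(n_steps=400_000, save_interval=500)
trajs = run_ensemble(topology, params, n_traj=10, base_seed=0)
events = detect_transitions(trajs, chi_threshold=1.0, persistence=2)
om = order_map(events)
rm = pair_rates(events, mask_threshold=7)
print("observed order :", " -> ".join(om.sorted_modules))
print(om.as_frame().round(2))
print("k(M2|M1) =", round(rm.k[0, 1], 3), "per 10^4 steps")
print("corrected p(M1 before M2) =", round(float(om.p_corrected[0, 1]), 5))
```

prints

```
observed order : M1 -> M2 -> M3
     M1   M2   M3
M1  NaN  1.0  1.0
M2  0.0  NaN  1.0
M3  0.0  0.0  NaN
k(M2|M1) = 0.533 per 10^4 steps
corrected p(M1 before M2) = 0.00586
```

Row a, column b holds P-order(b←a): here every one of the ten
trajectories flipped M1 first, then M2, then M3, so the order map is
deterministic; the pair rate says M2 follows M1 within ~2×10⁴ steps on
average, and the exact binomial test (Bonferroni-corrected over the three
tested pairs) rejects a coin-flip order at p ≈ 0.006.

The same pipeline is available from the shell:

```bash
mbcascade build run.toml          # topology.json + contact census
mbcascade simulate run.toml --setup standard --n-traj 10
mbcascade analyze run.toml       # order map, rate map, p-values, CIs
mbcascade scan run.toml          # (Δ, ΔV) usability survey
mbcascade compare run.toml       # perturbed setups vs the standard one
```

Perturbed setups (`[model.setups."M1↑"]`-style tables of per-module ΔV
offsets) reproduce the retard/accelerate experiments used to probe
whether an observed order is mechanically obligatory.

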