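# Methods

This note records the model, the parameter choices and the numerical
decisions behind `mbcascade`, in the spirit of a simulator's methods
appendix.  Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The model

### Single-basin potential

Each basin of each subsystem is a Cα structure-based potential biased
toward one reference conformation **R**₀:

V(R|R₀) = Σᵢ K_b,i (bᵢ − bᵢ,₀)²
        + V_loc^flp
        + Σ_{i} ε_loc,i exp(−(r_{i,i+2} − r⁰_{i,i+2})² / 2W²)
        + Σ_{i} ε_loc,i exp(−(φ_{i..i+3} − φ⁰)² / 2W_φ²)
        + Σ_{native, |i−j|>3} ε_go [5(r⁰/r)¹² − 6(r⁰/r)¹⁰]
        + Σ_{non-native} ε_ev (d/r)¹²

with bonds on consecutive beads, Gaussian wells on 1–3 distances and
backbone dihedrals, a 12-10 attraction on native contacts, and generic
repulsion on all remaining nonlocal pairs.  Local windows never span a
chain break; nonbonded terms require sequence separation > 3 within a
chain and apply at any separation across chains.  A pair that is native
in either basin of its owning subsystem is exempt from repulsion, so
attraction and repulsion never compete on the same pair mid-transition.

`V_loc^flp` is a tabulated bend-angle/dihedral statistical potential
evaluated by periodic cubic splines.  The package ships only the generic
all-zero fallback (labeled `generic-zero fallback` in topology metadata);
the compiled dynamics kernel requires that fallback, while the numpy
reference path evaluates arbitrary tables.

### Parameter defaults

| parameter | default | unit | role |
|---|---|---|---|
| K_b | 100 | kcal/mol/Å² | virtual-bond stiffness |
| ε_loc | 0.3 | kcal/mol | local well depth, split equally between the 1–3 and dihedral terms |
| ε_go | 0.3 | kcal/mol | native-contact depth (uniform; per-contact weights accepted) |
| ε_ev, d | 0.2, 6.5 | kcal/mol, Å | excluded volume |
| W, W_φ | 0.3, 0.3 | Å, rad | Gaussian well widths |
| contact cutoff | 6.5 | Å | minimum inter-residue distance defining a native contact (all-atom when atoms are available, Cα otherwise; recorded in metadata) |
| Δ | per module | kcal/mol | basin coupling (barrier) |
| ΔV | per module | kcal/mol | shift of the post basin relative to pre |

These are conventional coarse-grained magnitudes; the validation suite is
property-based (gradient consistency, eigensolver agreement, statistical
recovery), not tied to particular values.  The atomistically informed
per-term weighting that a full AICG2+ parameterization would provide is
out of scope; uniform depths with an optional per-contact weight table
stand in for it.

### Multiple-basin mixing

Each subsystem's V₁ (pre) and V₂ (post) enter the 2×2 secular equation
with off-diagonal coupling Δ; the surface is the smaller eigenvalue

V_MB = (V₁ + V₂ + ΔV)/2 − √(((V₁ − V₂ − ΔV)/2)² + Δ²),

which is smooth for Δ > 0 and tends to min(V₁, V₂+ΔV) as Δ → 0.  The
force is the chain rule on the closed form, w₁∇V₁ + w₂∇V₂ with
w₁ = ∂V_MB/∂V₁; the weights are exactly the squared components of the
smaller-eigenvalue eigenvector and sum to one.  ΔV is always applied to
basin 2 (post); a reversed (recovery) run keeps the basin roles and uses
its own ΔV table.

The reaction coordinate is χ = ln|c₂/c₁| · sign, computed as
ln((V₁ − V_MB)/Δ).  With a positive off-diagonal coupling the raw
eigenvector ratio is negative; taking the magnitude yields the intended
sign behavior (χ < 0 when the pre basin dominates, χ > 0 when post
dominates, 0 on the seam).  χ is clamped to ±50 for numerical safety.
Because interface terms live in exactly one subsystem, a module's χ
responds to its own internal state *and* to the interfaces it owns —
which is precisely what makes interface ownership a modelling decision
worth exposing (see the cascade benchmark below).

The shared excluded-volume term is identical in both basins of every
subsystem, so it adds to the total with unit weight and cancels from
every χ; the implementation therefore evaluates it once globally.

### Dynamics

Underdamped Langevin dynamics via the BAOAB splitting, with internal
units kcal/mol, Å, unit bead mass and k_B = 1.987×10⁻³ kcal/mol/K.
Defaults: γ = 0.02 (inverse internal time), T = 300 K, dt = 0.02 (the
stiffest bond period ≈ 0.44 internal time units, ≥ 20 dt), velocities
initialized from the Maxwell–Boltzmann distribution, χ saved every 10³
steps.  With γ = 0 and T = 0 the scheme reduces to velocity Verlet (an
exact identity tested per step), so NVE energy conservation checks the
force/energy consistency of the compiled kernel.  The zero-temperature
drift check uses dt = 0.001 so that excluded-volume core bounces are
resolved; with the larger production dt the thermostat absorbs their
integration error.

Times are reported in MD steps and rates in 1/10⁴ steps throughout.

The production force loop is a numba kernel over flattened term arrays
(two passes: basin energies → mixing weights → weighted gradient); a
readable numpy path implements the identical model and the two are
cross-checked to 10⁻⁹ kcal/mol in the tests.  Systems in scope are a few
hundred beads, so full precomputed pair lists are used instead of a
cell-list neighbor search; the Gō term is truncated and shifted at
2.5 r⁰ and the repulsion at 20 Å.

### Transition detection and cascade statistics

A module flips state when χ stays beyond ±χ_c for m consecutive saved
frames (defaults χ_c = 1.0, m = 2; both configurable — a pure sign rule
is m = 1, χ_c = 0).  τ is the first entry into the run's target state;
modules that never arrive are censored at the run end.

* **Order map** — P-order(b←a) counts trajectories with τ_a < τ_b, both
  observed, over the full ensemble size; censored partners and
  frame-resolution ties join neither numerator, so
  P(a first) + P(b first) + P(undecided) = 1 per pair.  Modules are
  ranked by the row sums P_i.  Pair significance is a two-sided exact
  binomial test on the decided trajectories at p = ½, corrected over the
  K(K−1)/2 tested pairs (Bonferroni by default, Holm available).
* **Pair rates** — k(b|a) = ⟨1/Δt_ab⟩ over trajectories where b follows
  a, with a censored b contributing the interval to the run end and Δt
  floored at one saved frame.  The floor matters: for continuous
  exponential waiting times E[1/Δt] diverges, so this estimator is a
  heuristic coupling score, not a rate in the kinetic-theory sense.
  Cells with fewer than 7 contributing trajectories are masked.
  Uncertainty comes from a 2000-resample percentile bootstrap of the
  per-trajectory 1/Δt values.
* **Independence null** — if two modules flip with independent
  exponential clocks k_A, k_B, the time difference Δt = τ_B − τ_A has
  density k_A k_B/(k_A+k_B) · e^{−k_B Δt} (Δt ≥ 0), · e^{+k_A Δt}
  (Δt < 0).  Observed Δt samples are compared with this closed-form CDF
  by a one-sample two-sided KS test; the critical value is the exact
  finite-n quantile (0.2417 at n = 30, α = 0.05).  Clock rates for the
  null are estimated as 1/mean(τ) from uncensored first-passage times.
* **Scaled time** — per trajectory, t ↦ s = (t − τ_first)/(τ_second −
  τ_first) pins two anchor transitions at s = 0 and 1; a third module's χ
  is interpolated onto a common s grid and averaged over trajectories
  with both anchors observed.

## Synthetic data: what it emulates and what it does not

`make_toy_two_state_protein` builds K helix-like modules (2.3 Å radius,
1.5 Å rise, 100°/residue — 3.8 Å virtual bonds) side by side at 9 Å
spacing, one chain per module.  The post state applies a per-module rigid
transform to the whole module or, by default, to its C-terminal half
about a pivot at the first mobile bead — a hinge that preserves the
cross-hinge bond length exactly, so the two basins differ through bounded
wells rather than a harmonic bond strain.  Alternate modules are built
upside down (a rigid 180° flip applied to both states), which lets one
common swing angle (−120° about the vertical) stay clash-free while every
module's mobile half packs against the *static* half of its successor in
the pre state only.  Builds are deterministic and centroid-normalized;
any transform bringing two beads below 3.5 Å is rejected with the
offending pair named.

`make_cascade_benchmark` turns this geometry into a designed cascade
M1 → … → MK: the pre-only "gate" contacts of pair (m, m+1) get depth
interface_eps × coupling_strength (graded +50 % per step down the
cascade) and are owned by the *successor*, so module m+1's pre basin —
and through the mixing weights its mobile half — is held until module m
has swung away; persistent static–static interface contacts (scaffold,
1.0 kcal/mol, both basins) keep the assembly tethered; and a graded ΔV
drive (−2.0, −1.5, −1.0 kcal/mol) starts the cascade at the ungated end.
Benchmark depths (intra ε_go = 1.0, ε_loc = 2.0, interface 2.0, Δ = 1.0)
were chosen by the package's own parameter-scan procedure so that, at
300 K, transitions occur in mid-trajectory (medians ≈ 10⁴–10⁵ steps of a
4×10⁵-step run) rather than immediately or never — the same usability
criterion the `scan` command automates, whose pathological regimes
(never, immediate, coalesced basins) are flagged and tested.  With
coupling_strength = 0 the gate contacts vanish and only the ΔV grading
biases the (then stochastic) order.

`simulate_gated_events` is the kinetic counterpart: exponential clocks
per module, optionally suppressed by a factor ε_gate until the gating
predecessors have fired, censored at t_end.  With ε_gate = 1 it *is* the
independence null, which makes it the oracle for the order/rate/KS
machinery; with ε_gate = 0 it is obligatory gating.  That the energetic
benchmark and the kinetic oracle produce the same qualitative order
statistics is itself part of the test suite.

What the toys do not emulate: realistic protein geometry or sequence,
atomistically derived contact energetics, many-state modules, and any
coupling to nucleotide chemistry.  Passing tests demonstrate that the
machinery recovers known structure from data with the assumed statistical
form — not that a particular real protein follows it.

## Numerical choices and edge cases

* Dihedral gradients use the standard two-normal formulation; collinear
  triples are flagged, skipped and warned about rather than propagating
  NaNs.  Gaussian dihedral deviations are wrapped into (−π, π].
* Alternate locations resolve to altloc "A"/blank; insertion codes are
  preserved in residue ids.
* Contacts present in both states with different r⁰ are two separate
  terms, one per basin, same owner.
* The one-sample KS critical value uses the exact finite-n distribution
  of the two-sided statistic, not the asymptotic formula.
* Trajectories are bit-reproducible given (seed, parameters, topology);
  ensembles use seeds base+i and are independent of scheduling.
* Degenerate inputs raise early with names: overlapping or non-covering
  partitions, missing Cα records, bead-count mismatches, Δ ≤ 0,
  non-positive rates, cyclic gating graphs.

## Known limitations

* The pair-rate estimator's frame floor makes k(b|a) resolution-dependent
  near Δt ≈ 0; treat large values as "fast, strongly coupled", not as
  calibrated rates.
* χ of a module reflects its owned interface terms; ownership choices
  move order-map mass between neighboring modules (the benchmark exploits
  exactly this, and the `ownership` override exists to probe it).
* The compiled kernel supports only the generic (zero) flexible-local
  table; sequence-dependent tables run on the numpy path.
* No cell lists: systems much beyond ~10³ beads will be slow.
* Recovery-stroke runs reuse the power-stroke machinery with swapped
  start state and their own ΔV table; no hysteresis between the two
  directions is modelled.
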