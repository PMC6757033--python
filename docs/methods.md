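# Methods

## Problem and model

A molecule with fixed bond lengths and angles is searched over rotations
about a user-designated set of M rotatable bonds (torsions).  A
conformation is a torsion vector **t** = [t₁, …, t_M] with each tᵢ drawn
from a uniform grid Θ of d angles θ_k = 2πk/d on [0, 2π); the search space
has d^M points.  Removing the torsion bonds partitions the atoms into M+1
rigid bodies; bodies and torsions form a tree (the rigid-body graph), and
every torsion must be a bridge of the bond graph — a torsion on a ring is
rejected, since it cannot rotate freely.

The energy is a pairwise Lennard-Jones 6–12 sum,

    V(α, β) = ε_αβ [ (σ_αβ/r_αβ)¹² − 2 (σ_αβ/r_αβ)⁶ ],

with per-element well depths ε (kcal/mol) and van der Waals distances σ
(Å) from the UFF nonbonded table (H, C, N, O, P, S, Cl shipped; other
elements need a user table), combined by geometric means.  Regrouped by
rigid body, the total splits into rotation-invariant intra-body terms U_a
and cross-body terms U_ab that depend only on the torsions on the tree
path between bodies a and b.  No torsional, bending, or electrostatic
terms are included.

**Nonbonded exclusions.**  Atom pairs separated by one or two bonds are
excluded; 1-4 pairs and beyond are included.  The source method does not
state its exclusion rule; without one, the 1/r¹² terms at bonded distances
dominate everything, so the standard force-field convention is used and
the minimum bond separation is configurable (`EnergyModel(...,
min_separation=...)`).

**Conventions.**  tᵢ = 0 reproduces the reference geometry (angles are
offsets, not absolute dihedrals); rotations are right-handed about the
bond axis oriented from the root-side atom outward; the root body is the
one containing atom 0.  Units are Å and radians internally, degrees at
file/CLI boundaries, kcal/mol throughout for energies.

## Neighbourhoods and the QUBO subproblem

A torsion subset 𝒯_k is *2-torsion dependent* when contracting all other
tree edges yields a star graph; any two contracted super-bodies are then
separated by at most two selected torsions, so with the other torsions
frozen the energy restricted to the subset is exactly quadratic in
per-torsion one-hot indicators.  Maximal such subsets are enumerated by
the boundary characterisation (the 2-torsion-dependent sets are precisely
the edge boundaries δ(C) of connected vertex sets C, with C the star
centre), cross-checked in the tests by a 2^M sweep with the
contract-and-star test.

Each iteration samples a neighbourhood: a subset grown greedily in a
random torsion order φ (lead torsion advances each iteration; φ is
reshuffled after a full cycle), capped at ⌊s/2⌋ members so each torsion
affords at least two angles, plus per-torsion angle menus Θᵢ ⊆ Θ with
budget Σ|Θᵢ| ≤ s, sizes as equal as possible (the equal split maximises
the neighbourhood size Π|Θᵢ|).  The incumbent angle is always kept in its
menu so descent can retain it; the remaining values are drawn uniformly
without replacement.  The exact greedy rule is a documented
reconstruction — the original pseudocode is not available in
machine-readable form.

Pre-evaluated coefficients: U_i(θ) is the centre–leaf-i interaction at
tᵢ = θ and U_ij(θ, θ′) the leaf-i–leaf-j interaction, requiring exactly
Σ_{i<j}|Θᵢ||Θⱼ| + Σᵢ|Θᵢ| energy-term evaluations — fewer than the Π|Θᵢ|
neighbourhood points whenever menus are nontrivial.  The intra-super-body
remainder is computed once per neighbourhood as a *frozen constant* and is
not counted in the evaluation ledger (it does not affect the argmin; the
published counting covers only the U_i/U_ij tables).  Decoded energies are
therefore absolute and comparable across iterations.

The one-hot constraints enter the objective as a quadratic penalty
p·Σᵢ(Σ_k x_ik − 1)² with p = γ·(max − min coefficient), γ = 2, floored at
1 kcal/mol.  No penalty magnitude is published; this choice guarantees
(and the tests verify exhaustively) that the unconstrained optimum is
one-hot feasible.  **Numerical note:** near steric clashes the coefficient
range — and hence p — can exceed 10¹⁰ kcal/mol, so the energy part and the
penalty part of the objective are stored separately and the penalty is
evaluated exactly from integer row sums; folding −p into the linear
coefficients would erase their low-order bits by cancellation.  The folded
flat-QUBO form is still produced for export and for the annealer.

## Solvers

* `solve_exact` enumerates the feasible one-hot product space (Π|Θᵢ|
  points, not 2^n bitstrings — identical optimum, exponentially cheaper);
  ties keep the lexicographically smallest slot tuple.
* `solve_sa` is a single-spin-flip Metropolis annealer over the full
  binary space (geometric β from 0.1 to 50 over 2000 sweeps, 25 reads by
  default), the desk-scale stand-in for quantum-annealing hardware.
  Infeasible samples are discarded, never repaired; if no feasible sample
  is found the iteration keeps the incumbent.  Hardware topics —
  minor embedding, chain strength, bit precision — are out of scope.
* `brute_force_neighbourhood` evaluates the molecular energy at every
  neighbourhood point: the independent oracle the QUBO route is tested
  against.

## Search drivers

**VND** iterates sample → pre-evaluate → solve → decode, accepting only a
strict energy decrease (equal-energy moves are rejected so the
non-improvement counter is well defined).  Stopping: B iterations total, A
consecutive non-improving iterations (counter resets on any improvement),
or best energy within `target_tol` (default 0.1 kcal/mol) of a supplied
reference.  **LS** is steepest-descent over all M·(d−1) single-torsion
moves per sweep, terminating at a single-torsion local optimum.  **LS–VND**
runs LS and hands its output to VND.  **PTMC** runs 8 replicas at
geometric kT from 0.2 to 5 kcal/mol with one sweep (M single-torsion
Metropolis proposals with uniformly random grid angles) between
adjacent-pair exchange attempts; the ladder parameters are reconstructions,
config-exposed, as the originals are not available.  Each full-energy call
and each pre-evaluated coefficient counts one unit in the evaluation
ledger; PTMC's count is its total number of proposals.

Defaults (d = 12, s = 24, A = 10, B = 200) are desk-scale: d = 12 resolves
the anti/gauche alternatives of alkane chains at 30° spacing, and s = 24
lets a two-torsion neighbourhood cover its full 12×12 grid.

## Synthetic molecules

`make_alkane(n)` builds an idealised all-anti n-alkane (C–C 1.54 Å, C–H
1.09 Å, tetrahedral angles); torsions are the internal C–C bonds minus the
two terminal methyl rotors, so M = n − 3 and the rigid-body graph is a
path.  `make_star_molecule(n_arms, arm_length)` builds a hub with straight
carbon arms carrying off-axis hydrogens — a rigid-body graph with a
degree-n_arms hub whose incident edges form one maximal
2-torsion-dependent set, and whose arm–arm hydrogen contacts create the
two-torsion traps that defeat single-torsion search.  `make_two_body_toy(d)`
returns a one-torsion system together with its exact d-point landscape,
used as an oracle.  The published organometallic and ortho-phenylene test
systems are *not* reconstructed (their definitions and metal parameters
are not available); chain and star analogues stand in for the
topology-dependent claims, and the benchmark uses 6-, 8-, and 10-carbon
chains as stand-ins for the published alkane set, whose exact lengths are
likewise unavailable.  Generated geometries are idealised and rigid: no
bond-length/angle relaxation, no ring conformers, no electrostatics — a
green benchmark establishes the search behaviour on this stated landscape,
not chemical accuracy against experimental structures.

## Metrics

Success = final energy within 1 kcal/mol (chemical accuracy) of the
reference energy, boundary inclusive.  Residual = energy gap to the
reference; normalised residual divides by atom count.  References come
from exhaustive d^M enumeration when affordable (≤ 10⁵ points) and
otherwise from pooled multi-seed long PTMC using the same energy model.
Percentiles are nearest-rank.  Wall-clock time is recorded but never used
in acceptance — it is hardware-dependent.  Benchmarks are pure functions
of (config, seeds); per-run generators derive from CRC-32 of the molecule
and method labels plus the run seed.

## Known limitations

* Lennard-Jones-only energies: no torsional barriers, so landscapes are
  sterics-driven and flatter than force-field reality.
* The exhaustive maximal-subset enumeration is limited to 20 torsions
  (the subtree enumeration is exponential on star-like trees); larger
  molecules rely on the neighbourhood sampler.
* The φ-order greedy neighbourhood growth and the PTMC ladder are
  reconstructions; published evaluation-count comparisons can be matched
  only in order of magnitude.
* `solve_sa` models an ideal sampler: no coupler precision limits, noise,
  or embedding overhead.
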