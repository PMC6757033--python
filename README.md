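# vndconf

Conformational search for small molecules by **variable neighbourhood
descent (VND)** with neighbourhood subproblems encoded as **QUBO**
(quadratic unconstrained binary optimization) instances — the formulation
that lets each step be delegated to a binary quadratic optimizer such as a
quantum annealer, here stood in for by an exact enumerator and a simulated
annealer.  Includes single-torsion local search (LS), the LS–VND hybrid,
and a parallel tempering Monte Carlo (PTMC) baseline, plus a synthetic
molecule generator and a benchmark harness, so everything runs
self-contained at desk scale.

## The method in brief

Fix bond lengths and angles and describe a conformation by a torsion
vector **t** ∈ Θ^M, one grid angle per rotatable bond.  The torsions
partition the molecule into M+1 rigid bodies forming a tree G = (ℛ, 𝒯);
the Lennard-Jones energy splits into intra-body constants and cross-body
terms U_ab that depend only on the torsions between bodies a and b.

A torsion subset 𝒯_k ⊆ 𝒯 is *2-torsion dependent* if contracting all
other edges of G leaves a star graph: every pair of super-bodies is then
coupled through at most two selected torsions, so — with the rest of the
molecule frozen — the energy restricted to 𝒯_k is exactly quadratic in
one-hot indicators x_ik (x_ik = 1 ⇔ t_i = θ_k):

    min  Σ_{i≠j} Σ_{k_i,k_j} U_ij(θ_{k_i}, θ_{k_j}) x_ik x_jl
       + Σ_i Σ_k U_i(θ_k) x_ik  +  p Σ_i (Σ_k x_ik − 1)²

with a penalty p enforcing one angle per torsion.  Each VND iteration
samples such a neighbourhood (subset plus per-torsion angle menus Θ_i with
variable budget s = Σ|Θ_i|), pre-evaluates the U_i/U_ij tables — only
Σ_{i<j}|Θ_i||Θ_j| + s energy terms, fewer than the Π|Θ_i| conformations in
the neighbourhood — solves the QUBO, decodes, and accepts on strict
descent.  Runs stop after B iterations, A consecutive non-improving
iterations, or on reaching a reference energy within 0.1 kcal/mol.

See `docs/methods.md` for conventions, defaults, numerical choices, and
limitations.

## Worked example

Generate an octane analogue, inspect its neighbourhood structure, and run
three seeded VND searches:

```sh
$ vndconf generate --kind alkane --n-carbons 8 --out octane
wrote octane.xyz, octane.bonds, octane.torsions (26 atoms, M=5)

$ vndconf neighbourhoods octane.xyz octane.torsions --bonds octane.bonds
{T1, T2}
{T1, T3}
...
{T4, T5}

$ vndconf search octane.xyz octane.torsions --bonds octane.bonds \
      --method vnd --d 12 --s 24 --seed 0 --runs 3
seed 0: best energy 8.607362 kcal/mol, 16 iterations, 2689 energy evaluations
seed 1: best energy 8.607362 kcal/mol, 15 iterations, 2521 energy evaluations
seed 2: best energy 8.607362 kcal/mol, 14 iterations, 2353 energy evaluations
```

Octane's rigid-body graph is a 5-edge path, so the maximal
2-torsion-dependent subsets are exactly the C(5,2) = 10 torsion pairs.
All three runs descend to 8.607362 kcal/mol — the all-anti backbone, which
exhaustive enumeration confirms is the global grid minimum — and the
energy-evaluation counts show what the pre-evaluation economy buys: each
iteration costs 168 coefficient evaluations (12·12 pair terms + 24 linear
terms) instead of the 144-point neighbourhood times full-molecule sums.

The same library surface is available in Python (`vndconf.vnd`,
`vndconf.local_search`, `vndconf.ptmc_search`,
`vndconf.run_benchmark`, ...), and `vndconf benchmark` writes the
method × molecule summary table (success rate, residual percentiles,
evaluation counts) as CSV.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the package's reported quantities from scratch: it builds the
three-torsion chain molecule, partitions it into rigid bodies, enumerates
the inclusion-maximal 2-torsion-dependent subsets via the
contract-and-star test, and writes the resulting count as JSON.
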