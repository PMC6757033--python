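"""One-hot QUBO encoding of a neighbourhood subproblem.

Each selected torsion i gets one binary variable x_ik per candidate angle
θ_k ∈ Θ_i; the neighbourhood energy is quadratic in these variables because
the torsion subset is 2-torsion dependent.  The one-hot constraints
Σ_k x_ik = 1 are moved into the objective with a quadratic penalty p:

    E(x) = Σ_{i<j} Σ_{k,l} U_ij(θ_k, θ_l) x_ik x_jl
         + Σ_i Σ_k U_i(θ_k) x_ik  +  p Σ_i (Σ_k x_ik − 1)².

For any feasible one-hot assignment the penalty vanishes and E(x) plus the
frozen constant is the absolute molecular energy of the decoded vector.

The Lennard-Jones 1/r^12 clash terms make the coefficient range — and
hence p — potentially enormous, so the energy part and the penalty part of
the objective are stored and evaluated separately: folding −p into the
linear coefficients would destroy their low-order bits by cancellation.
The folded (flat-QUBO) form is still available for export and for the
simulated annealer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import NeighbourhoodCoefficients
from .neighbourhoods import NeighbourhoodSpec


class InfeasibleSolutionError(ValueError):
    """A one-hot row summed to something other than one."""


@dataclass
class QuboProblem:
    """Penalised one-hot QUBO over Σ|Θ_i| binary variables.

    ``variables[v]`` is the (torsion, slot) pair of flat index v.
    ``linear[v]`` holds the raw U_i(θ) coefficient and ``quadratic`` the
    symmetric cross-torsion U_ij matrix; the penalty enters the objective
    as p·Σ_i (row_sum_i − 1)², evaluated exactly from integer row sums.
    ``objective + frozen_constant`` is the absolute molecular energy
    (kcal/mol) for feasible assignments.
    """

    variables: list
    linear: np.ndarray
    quadratic: np.ndarray
    penalty: float
    frozen_constant: float
    spec: NeighbourhoodSpec
    index: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {vs: v for v, vs in enumerate(self.variables)}
        if not np.allclose(self.quadratic, self.quadratic.T):
            raise ValueError("quadratic matrix must be symmetric")
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def offset(self) -> float:
        """Constant p·|𝒯_k| produced by expanding the penalty."""
        return self.penalty * len(self.spec.torsions)

    def _row_slices(self):
        pos = 0
        for i in self.spec.torsions:
            sz = len(self.spec.angles[i])
            yield i, slice(pos, pos + sz)
            pos += sz

    def violations(self, x: np.ndarray) -> int:
        """Σ_i (row_sum_i − 1)², an exact small integer."""
        x = np.asarray(x)
        return int(sum((int(np.rint(x[sl].sum())) - 1) ** 2
                       for _, sl in self._row_slices()))

    def objective(self, x: np.ndarray) -> float:
        """QUBO objective of a bitstring, penalty included."""
        x = np.asarray(x, dtype=float)
        energy = float(x @ self.linear + 0.5 * x @ self.quadratic @ x)
        return energy + self.penalty * self.violations(x)

    def absolute_energy(self, x: np.ndarray) -> float:
        """Molecular energy (kcal/mol) of a feasible assignment."""
        if self.violations(x) != 0:
            raise InfeasibleSolutionError("assignment is not one-hot")
        return self.objective(x) + self.frozen_constant

    def folded(self) -> tuple:
        """Flat-QUBO arrays (h, J, offset) with the penalty folded in.

        Expanding p(Σx − 1)² with x² = x adds −p to each linear term,
        +2p to every same-torsion variable pair, and p per torsion to the
        constant offset.  This is the form external QUBO solvers consume.
        """
        h = self.linear - self.penalty
        j = self.quadratic.copy()
        for _, sl in self._row_slices():
            idx = np.arange(sl.start, sl.stop)
            for a in range(idx.size):
                for b in range(a + 1, idx.size):
                    j[idx[a], idx[b]] += 2.0 * self.penalty
                    j[idx[b], idx[a]] += 2.0 * self.penalty
        return h, j, self.offset

    def to_coo_text(self) -> str:
        """Export the folded QUBO as `i j value` coordinate lines."""
        h, j, offset = self.folded()
        lines = [f"# n_variables {self.n_variables}",
                 f"# offset {float(offset)!r}"]
        for v, hv in enumerate(h):
            if hv != 0.0:
                lines.append(f"{v} {v} {float(hv)!r}")
        iu, ju = np.nonzero(np.triu(j, k=1))
        for a, b in zip(iu, ju):
            lines.append(f"{int(a)} {int(b)} {float(j[a, b])!r}")
        return "\n".join(lines) + "\n"


def choose_penalty(coeffs: NeighbourhoodCoefficients, gamma: float = 2.0,
                   floor: float = 1.0) -> float:
    """Penalty p = γ·(max − min coefficient), floored at 1 kcal/mol.

    Any p exceeding the total coefficient range makes every one-hot
    violation cost more than any energy gain, so the unconstrained optimum
    is feasible; γ = 2 leaves margin.
    """
    vals = coeffs.all_values()
    if vals.size == 0:
        raise ValueError("no coefficients")
    return max(floor, gamma * float(vals.max() - vals.min()))


def build_qubo(coeffs: NeighbourhoodCoefficients, p: float) -> QuboProblem:
    """Assemble the penalised QUBO from pre-evaluated coefficient tables."""
    if p <= 0:
        raise ValueError("penalty must be positive")
    spec = coeffs.spec
    variables = []
    for i in spec.torsions:
        for k in range(len(spec.angles[i])):
            variables.append((i, k))
    index = {vs: v for v, vs in enumerate(variables)}
    n = len(variables)

    h = np.zeros(n)
    quad = np.zeros((n, n))
    for i in spec.torsions:
        for k in range(len(spec.angles[i])):
            h[index[(i, k)]] = coeffs.linear[i][k]
    for (i, j), mat in coeffs.quadratic.items():
        for k in range(mat.shape[0]):
            for l in range(mat.shape[1]):
                a, b = index[(i, k)], index[(j, l)]
                quad[a, b] += mat[k, l]
                quad[b, a] += mat[k, l]
    return QuboProblem(variables=variables, linear=h, quadratic=quad,
                       penalty=p, frozen_constant=coeffs.frozen_constant,
                       spec=spec, index=index)


def encode_solution(t: np.ndarray, spec: NeighbourhoodSpec,
                    atol: float = 1e-9) -> np.ndarray:
    """One-hot bitstring of a torsion vector that lies in the neighbourhood."""
    t = np.asarray(t, float)
    bits = []
    for i in spec.torsions:
        menu = spec.angles[i]
        diff = np.abs(np.angle(np.exp(1j * (menu - t[i]))))
        k = int(np.argmin(diff))
        if diff[k] > atol:
            raise ValueError(f"angle of torsion {i} not in its menu")
        row = np.zeros(len(menu), dtype=int)
        row[k] = 1
        bits.append(row)
    return np.concatenate(bits)


def decode_solution(x: np.ndarray, spec: NeighbourhoodSpec,
                    t_incumbent: np.ndarray) -> np.ndarray:
    """Torsion vector of a feasible one-hot bitstring.

    Selected torsions take their one-hot angle; all others keep the
    incumbent value, so the decoded vector is a neighbour of the incumbent
    under N_k.

    Raises
    ------
    InfeasibleSolutionError
        If any one-hot row does not sum to exactly 1.
    """
    x = np.asarray(x)
    t = np.array(t_incumbent, dtype=float)
    pos = 0
    for i in spec.torsions:
        menu = spec.angles[i]
        row = x[pos:pos + len(menu)]
        if row.sum() != 1:
            raise InfeasibleSolutionError(
                f"one-hot row of torsion {i} sums to {int(row.sum())}")
        t[i] = menu[int(np.argmax(row))]
        pos += len(menu)
    if pos != x.size:
        raise ValueError("bitstring length does not match the spec")
    return t
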