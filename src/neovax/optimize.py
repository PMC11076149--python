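"""Budget-constrained vaccine element selection by integer linear programming.

Two objectives over the log no-response coefficients p_ij <= 0:

* **MinSum** — minimize Σ_j Σ_i p_ij x_i: maximize the expected log-likelihood
  of response summed over the whole simulated population ("kill the maximum
  number of cells"). Separable, so it reduces to a knapsack over the
  per-element aggregates Σ_j p_ij.
* **MinMax** — minimize max_j Σ_i p_ij x_i: target the single most resistant
  cell. Linearized with the standard surrogate variable z >= Σ_i p_ij x_i.

Both are solved exactly with HiGHS via :func:`scipy.optimize.milp`. Ties
between equal-objective optima are broken deterministically in favor of the
lexicographically smallest sorted element-id tuple, realized by a
prefix-growing sequence of auxiliary solves capped at the optimal objective.
An exhaustive enumerator (:func:`brute_force_optimum`) serves as an
independent oracle for small instances.
"""

from __future__ import annotations

from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .types import OptimizationProblem, ResponseMatrix, VaccineDesign

_FEAS_TOL = 1e-9

# exact optima required: zero MIP gap, and HiGHS presolve disabled because it
# can return sub-optimal "optimal" solutions on models mixing binary selectors
# with the continuous minimax surrogate variable
_MILP_OPTIONS = {"mip_rel_gap": 0.0, "presolve": False}


def _set_objective(problem: OptimizationProblem, idx: Sequence[int]) -> float:
    """Exact objective of a fixed index set (empty set -> 0)."""
    p = problem.matrix.coefficients
    if problem.objective == "min_sum":
        return float(sum(p[i].sum() for i in idx))
    col = np.zeros(p.shape[1])
    for i in idx:
        col += p[i]
    return float(col.max()) if p.shape[1] else 0.0


def _solve_relaxed(problem: OptimizationProblem,
                   fix_one: Sequence[int] = (), fix_zero: Sequence[int] = (),
                   cap: Optional[float] = None) -> Tuple[Optional[List[int]], Optional[float]]:
    """One MILP solve with some selectors pinned; returns (indices, objective)."""
    p = problem.matrix.coefficients
    n, m = p.shape
    costs = np.asarray(problem.costs, dtype=float)

    lb = np.zeros(n)
    ub = np.ones(n)
    lb[list(fix_one)] = 1.0
    ub[list(fix_zero)] = 0.0

    if problem.objective == "min_sum":
        agg = p.sum(axis=1)
        constraints = [LinearConstraint(costs[None, :], -np.inf, problem.budget)]
        if cap is not None:
            constraints.append(LinearConstraint(agg[None, :], -np.inf, cap))
        res = milp(c=agg, constraints=constraints,
                   integrality=np.ones(n), bounds=Bounds(lb, ub),
                   options=_MILP_OPTIONS)
        if not res.success:
            return None, None
        x = np.round(res.x).astype(int)
        idx = [i for i in range(n) if x[i] == 1]
        return idx, _set_objective(problem, idx)

    # min_max: variables [x_1..x_n, z]
    z_lb = float(np.minimum(p, 0.0).sum()) - 1.0
    z_ub = 0.0 if cap is None else min(0.0, cap)
    c = np.zeros(n + 1)
    c[-1] = 1.0
    # p_.j' x - z <= 0 for every cell j
    a_cells = np.hstack([p.T, -np.ones((m, 1))])
    a_budget = np.hstack([costs[None, :], np.zeros((1, 1))])
    res = milp(c=c,
               constraints=[LinearConstraint(a_cells, -np.inf, np.zeros(m)),
                            LinearConstraint(a_budget, -np.inf, problem.budget)],
               integrality=np.append(np.ones(n), 0.0),
               bounds=Bounds(np.append(lb, z_lb), np.append(ub, z_ub)),
               options=_MILP_OPTIONS)
    if not res.success:
        return None, None
    x = np.round(res.x[:n]).astype(int)
    idx = [i for i in range(n) if x[i] == 1]
    return idx, _set_objective(problem, idx)


def _lex_smallest_optimum(problem: OptimizationProblem, z_star: float) -> List[int]:
    """Among optimal selections, the lexicographically smallest sorted id set.

    Grows a prefix over elements in id order: the prefix terminates as soon
    as it is itself optimal-feasible; otherwise the next member is the
    smallest id whose inclusion (with all smaller non-prefix ids excluded)
    still admits an optimal completion. At most N auxiliary solves.
    """
    ids = problem.matrix.elements
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    tol = _FEAS_TOL * (1.0 + abs(z_star))
    cap = z_star + tol
    costs = problem.costs

    prefix: List[int] = []
    excluded: List[int] = []
    pos = 0
    while True:
        if (_set_objective(problem, prefix) <= cap
                and sum(costs[i] for i in prefix) <= problem.budget + _FEAS_TOL):
            return prefix
        advanced = False
        while pos < len(order):
            e = order[pos]
            pos += 1
            idx, obj = _solve_relaxed(problem, fix_one=prefix + [e],
                                      fix_zero=excluded, cap=cap)
            if idx is not None and obj is not None and obj <= cap:
                prefix.append(e)
                advanced = True
                break
            excluded.append(e)
        if not advanced:  # pragma: no cover - optimum witnessed earlier
            raise RuntimeError("lexicographic refinement failed to reproduce the optimum")


def _finalize(problem: OptimizationProblem, idx: Sequence[int],
              status: str = "optimal") -> VaccineDesign:
    ids = problem.matrix.elements
    return VaccineDesign(
        selected=frozenset(ids[i] for i in idx),
        objective_value=_set_objective(problem, idx),
        objective=problem.objective,
        total_cost=float(sum(problem.costs[i] for i in idx)),
        solver_status=status,  # type: ignore[arg-type]
    )


def _infeasible(problem: OptimizationProblem) -> VaccineDesign:
    return VaccineDesign(selected=frozenset(), objective_value=0.0,
                         objective=problem.objective, total_cost=0.0,
                         solver_status="infeasible")


def solve_min_sum(problem: OptimizationProblem) -> VaccineDesign:
    """Provably optimal MinSum selection under the budget constraint."""
    if problem.objective != "min_sum":
        raise ValueError("problem.objective must be 'min_sum'")
    return _solve(problem)


def solve_min_max(problem: OptimizationProblem) -> VaccineDesign:
    """Provably optimal MinMax selection (surrogate-variable linearization)."""
    if problem.objective != "min_max":
        raise ValueError("problem.objective must be 'min_max'")
    return _solve(problem)


def _solve(problem: OptimizationProblem) -> VaccineDesign:
    if len(problem.costs) == 0:
        return _finalize(problem, [])
    if min(problem.costs) > problem.budget + _FEAS_TOL:
        return _infeasible(problem)
    idx, z_star = _solve_relaxed(problem)
    if idx is None or z_star is None:
        return _infeasible(problem)
    best = _lex_smallest_optimum(problem, z_star)
    return _finalize(problem, best)


def brute_force_optimum(problem: OptimizationProblem,
                        max_elements: int = 20) -> VaccineDesign:
    """Exact optimum by exhaustive subset enumeration (test oracle, N <= 20)."""
    ids = problem.matrix.elements
    n = len(ids)
    if n > max_elements:
        raise ValueError(f"refusing exhaustive enumeration for N={n} > {max_elements}")
    if n and min(problem.costs) > problem.budget + _FEAS_TOL:
        return _infeasible(problem)
    order = sorted(range(n), key=lambda i: ids[i])
    best_idx: List[int] = []
    best_obj = 0.0
    best_key: Tuple[str, ...] = ()
    for r in range(n + 1):
        for combo in combinations(order, r):
            cost = sum(problem.costs[i] for i in combo)
            if cost > problem.budget + _FEAS_TOL:
                continue
            obj = _set_objective(problem, combo)
            key = tuple(sorted(ids[i] for i in combo))
            tol = _FEAS_TOL * (1.0 + abs(best_obj))
            if obj < best_obj - tol or (abs(obj - best_obj) <= tol and key < best_key):
                best_idx, best_obj, best_key = list(combo), obj, key
    return _finalize(problem, best_idx)


def concatenate_matrices(matrices: Sequence[ResponseMatrix]) -> ResponseMatrix:
    """Join replicate matrices along the cell axis for joint optimization.

    All matrices must share the element list and λ (i.e. come from one
    joint-λ build); cells from every replicate become terms/constraints.
    """
    first = matrices[0]
    for m in matrices[1:]:
        if m.elements != first.elements:
            raise ValueError("matrices must share the same element list")
        if not np.isclose(m.lambda_used, first.lambda_used):
            raise ValueError("matrices must share λ; rebuild with a joint λ")
    return ResponseMatrix(
        elements=list(first.elements),
        num_cells=sum(m.num_cells for m in matrices),
        coefficients=np.hstack([m.coefficients for m in matrices]),
        lambda_used=first.lambda_used,
        floor_used=min(m.floor_used for m in matrices),
    )
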