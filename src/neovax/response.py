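"""From simulated populations to the log no-response coefficient matrix.

For a cell *j* and a minimal epitope *p* presented N_jk times (summed over
alleles), the probability that the epitope fails to trigger a T-cell response
is ``max(0, 1 - λ N_jk) ** DFS(p)``, where λ is fixed to the reciprocal of
the maximum presented multiplicity across all supplied cells (so only the
most-presented epitope reaches a certain response) and DFS is a
distance-from-self weight in [0, 1] approximating T-cell recognition.

A vaccine element (mutation) fails in a cell only if all of its epitopes
fail, so its log no-response coefficient is the DFS-weighted sum of the
per-epitope log terms:

    p_ij = Σ_k DFS(p_k) · log max(0, 1 - λ N_jk)

Log-zero events are floored at a configurable finite value so the downstream
integer programs keep finite coefficients while preserving the dominance of
"this element certainly kills this cell".
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .errors import DegenerateModelError
from .types import (
    CellPopulation,
    DfsFunction,
    PatientInput,
    ResponseMatrix,
    SimulatedCell,
)

DEFAULT_FLOOR = -50.0


def compute_lambda(populations: Sequence[CellPopulation]) -> float:
    """λ = 1 / (max presented multiplicity of any epitope in any cell).

    The maximum is taken over every cell of every population supplied, with a
    peptide's multiplicity summed across alleles.
    """
    max_count = 0
    for pop in populations:
        for cell in pop.cells:
            counts = cell.peptide_counts()
            if counts:
                max_count = max(max_count, max(counts.values()))
    if max_count == 0:
        raise DegenerateModelError(
            "no pMHC complex is presented in any simulated cell; "
            "the response model (and any optimization over it) is vacuous")
    return 1.0 / max_count


def epitope_no_response_prob(count: int, lam: float, dfs_value: float) -> float:
    """P(no response | epitope presented ``count`` times) = max(0, 1-λN)^DFS."""
    if count < 0 or lam <= 0 or not (0.0 <= dfs_value <= 1.0):
        raise ValueError("count >= 0, lambda > 0, dfs in [0, 1] required")
    base = max(0.0, 1.0 - lam * count)
    return base ** dfs_value


def element_cell_log_no_response(element_epitopes: Iterable[str],
                                 cell: SimulatedCell, lam: float,
                                 dfs: Optional[DfsFunction] = None,
                                 floor: float = DEFAULT_FLOOR) -> float:
    """p_ij for one element and one cell; 0 if none of its epitopes appear."""
    if floor >= 0:
        raise ValueError("floor must be negative")
    counts = cell.peptide_counts()
    total = 0.0
    for pep in element_epitopes:
        n = counts.get(pep, 0)
        if n == 0:
            continue
        base = max(0.0, 1.0 - lam * n)
        log_term = np.log(base) if base > 0 else -np.inf
        d = 1.0 if dfs is None else float(dfs(pep))
        total += d * max(log_term, floor)
    return max(total, floor)


def build_response_matrix(patient: PatientInput,
                          populations: Sequence[CellPopulation],
                          dfs: Optional[DfsFunction] = None,
                          floor: float = DEFAULT_FLOOR,
                          lam: Optional[float] = None,
                          ) -> List[ResponseMatrix]:
    """One N x M coefficient matrix per supplied population.

    λ is computed once across all populations passed in a single call (pass
    populations one at a time to scope λ per population, as the
    replicate-consensus analysis does). A precomputed ``lam`` may be supplied
    to pin the scale externally.
    """
    if floor >= 0:
        raise ValueError("floor must be negative")
    if lam is None:
        lam = compute_lambda(populations)
    elements = patient.variant_ids
    peptide_of: Dict[str, List[int]] = {}
    for i, vid in enumerate(elements):
        for pep in patient.elements.get(vid, ()):
            peptide_of.setdefault(pep, []).append(i)
    pep_index = {p: r for r, p in enumerate(sorted(peptide_of))}
    n_pep = len(pep_index)
    dfs_w = np.ones(n_pep)
    if dfs is not None:
        for p, r in pep_index.items():
            w = float(dfs(p))
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"DFS({p!r}) = {w} outside [0, 1]")
            dfs_w[r] = w
    # element -> peptide incidence (a peptide may belong to several elements)
    incidence = np.zeros((len(elements), n_pep))
    for pep, owners in peptide_of.items():
        for i in owners:
            incidence[i, pep_index[pep]] = 1.0

    out: List[ResponseMatrix] = []
    for pop in populations:
        m_cells = len(pop)
        counts = np.zeros((n_pep, m_cells))
        for j, cell in enumerate(pop.cells):
            for pep, n in cell.peptide_counts().items():
                r = pep_index.get(pep)
                if r is not None:
                    counts[r, j] = n
        base = np.maximum(0.0, 1.0 - lam * counts)
        with np.errstate(divide="ignore"):
            log_terms = np.log(base)  # -inf where base == 0
        log_terms = np.maximum(log_terms, floor)
        coeffs = np.maximum(incidence @ (dfs_w[:, None] * log_terms), floor)
        # guard tiny positive round-off
        coeffs = np.minimum(coeffs, 0.0)
        out.append(ResponseMatrix(elements=list(elements), num_cells=m_cells,
                                  coefficients=coeffs, lambda_used=lam,
                                  floor_used=floor))
    return out
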