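"""Post-optimization analytics.

Given a design E and the coefficient matrix, each cell's response probability
is ``1 - exp(Σ_{i in E} p_ij)``. From these come the coverage curve (fraction
of cells responding above a probability threshold), the intersection-over-
union consensus of replicate designs, and recall against experimentally
validated immunogenic mutations — including simple threshold/top-N
single-score baselines to compare the optimizer against.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import ReferentialIntegrityError
from .types import EpitopeScore, EvaluationReport, ResponseMatrix, VaccineDesign

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 10))
#: standard binding filters: IC50 <= 500 nM, rank percentile <= 2.0
DEFAULT_AFFINITY_CUTOFF = 500.0
DEFAULT_PERCENTILE_CUTOFF = 2.0


def cell_response_probabilities(matrix: ResponseMatrix,
                                design: VaccineDesign) -> np.ndarray:
    """P(response | E, c_j) = 1 - exp(Σ_{i in E} p_ij) for every cell j."""
    unknown = sorted(design.selected - set(matrix.elements))
    if unknown:
        raise ReferentialIntegrityError(
            f"design references element(s) absent from the matrix: "
            f"{', '.join(unknown)}", offenders=unknown)
    rows = [matrix.elements.index(v) for v in design.selected]
    if not rows:
        return np.zeros(matrix.num_cells)
    log_no_response = matrix.coefficients[rows].sum(axis=0)
    return 1.0 - np.exp(log_no_response)


def coverage_ratio(probs: Sequence[float], threshold: float) -> float:
    """Fraction of cells whose response probability reaches ``threshold``."""
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        return 0.0
    return float(np.mean(probs >= threshold))


def coverage_curve(probs: Sequence[float],
                   thresholds: Iterable[float] = DEFAULT_THRESHOLDS,
                   ) -> List[Tuple[float, float]]:
    return [(float(t), coverage_ratio(probs, t)) for t in thresholds]


def design_iou(designs: Sequence[VaccineDesign],
               mode: str = "all_sets") -> Optional[float]:
    """Consensus of replicate selections; None when every design is empty."""
    if len(designs) < 2:
        raise ValueError("IoU needs at least two designs")
    sets = [set(d.selected) for d in designs]
    if mode == "all_sets":
        union = set.union(*sets)
        if not union:
            return None
        inter = set.intersection(*sets)
        return len(inter) / len(union)
    if mode == "pairwise_mean":
        vals = []
        for a, b in combinations(sets, 2):
            u = a | b
            vals.append(len(a & b) / len(u) if u else None)
        real = [v for v in vals if v is not None]
        return float(np.mean(real)) if real else None
    raise ValueError(f"unknown IoU mode {mode!r}")


def baseline_select(scores: Sequence[EpitopeScore], value_kind: str,
                    top_n: int = 10,
                    affinity_cutoff: float = DEFAULT_AFFINITY_CUTOFF,
                    percentile_cutoff: float = DEFAULT_PERCENTILE_CUTOFF,
                    ) -> Set[str]:
    """Threshold-then-top-N single-score ranking baseline.

    Rows are ranked ascending by binding value (lower = stronger for both
    IC50 and percentile), filtered at the convention's standard cutoff,
    lifted to variants via each variant's best row, and the best ``top_n``
    variants returned.
    """
    if value_kind == "score_nm":
        cutoff = affinity_cutoff
    elif value_kind == "percentile":
        cutoff = percentile_cutoff
    else:
        raise ValueError(f"unknown value_kind {value_kind!r}")
    if top_n < 1:
        raise ValueError("top_n must be positive")
    best: dict = {}
    for s in scores:
        if s.binding_value <= cutoff:
            cur = best.get(s.variant_id)
            if cur is None or s.binding_value < cur:
                best[s.variant_id] = s.binding_value
    ranked = sorted(best, key=lambda v: (best[v], v))
    return set(ranked[:top_n])


def recall_report(selected: Set[str], validated: Set[str],
                  ) -> Tuple[int, int, Optional[float]]:
    """(TP, FN, recall); recall is None when there is nothing to validate."""
    tp = len(set(selected) & set(validated))
    fn = len(set(validated) - set(selected))
    recall = None if tp + fn == 0 else tp / (tp + fn)
    return tp, fn, recall


def evaluate_design(matrix: ResponseMatrix, design: VaccineDesign,
                    thresholds: Iterable[float] = DEFAULT_THRESHOLDS,
                    replicate_designs: Optional[Sequence[VaccineDesign]] = None,
                    validated: Optional[Set[str]] = None,
                    method_name: str = "digital_twin",
                    ) -> EvaluationReport:
    """Bundle the per-cell, coverage, consensus and recall analytics."""
    probs = cell_response_probabilities(matrix, design)
    report = EvaluationReport(response_probs=probs,
                              coverage_curve=coverage_curve(probs, thresholds))
    if replicate_designs is not None and len(replicate_designs) >= 2:
        report.iou = design_iou(replicate_designs)
    if validated is not None:
        tp, fn, rec = recall_report(set(design.selected), validated)
        report.recall_rows.append((method_name, tp, fn, rec))
    return report
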