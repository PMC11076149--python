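"""Domain types shared across the pipeline.

The pipeline moves through four representations:

* :class:`PatientInput` — everything observed about one patient: somatic
  variants with DNA/RNA read counts, per-gene expression moments, HLA class I
  alleles with their expression moments, and per-(variant, epitope, allele)
  predictor scores (cleavage, MHC binding, pMHC stability).
* :class:`SimulatedCell` / :class:`CellPopulation` — the digital twin: each
  simulated cancer cell reduced to the multiset ``S*`` of peptide-MHC
  complexes presented on its surface.
* :class:`ResponseMatrix` — the ``p_ij`` matrix of log no-response
  coefficients linking each candidate vaccine element (a mutation with its
  minimal epitopes) to each simulated cell.
* :class:`VaccineDesign` — a budget-feasible selection of vaccine elements
  with its objective value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, List, Literal, Mapping, Optional, Sequence, Tuple

import numpy as np

BindingMode = Literal["affinity_nm", "percentile"]

#: A distance-from-self surrogate: maps a peptide to a recognition weight in
#: [0, 1] used as the exponent of the per-epitope no-response probability.
DfsFunction = Callable[[str], float]

VALID_BINDING_MODES = ("affinity_nm", "percentile")


@dataclass(frozen=True)
class VariantRecord:
    """One tumor-specific mutation with its sequencing read support."""

    variant_id: str
    gene_id: str
    dna_alt_reads: int
    dna_ref_reads: int
    rna_alt_reads: int
    rna_ref_reads: int

    def __post_init__(self):
        for name in ("dna_alt_reads", "dna_ref_reads", "rna_alt_reads", "rna_ref_reads"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{self.variant_id}: {name} must be non-negative, got {v}")
        if self.dna_alt_reads + self.dna_ref_reads <= 0:
            raise ValueError(
                f"{self.variant_id}: DNA VAF undefined (zero total DNA reads)"
            )

    @property
    def dna_vaf(self) -> float:
        return self.dna_alt_reads / (self.dna_alt_reads + self.dna_ref_reads)

    @property
    def rna_vaf(self) -> float:
        """RNA variant allele frequency; 0 when no RNA reads cover the site."""
        total = self.rna_alt_reads + self.rna_ref_reads
        return 0.0 if total == 0 else self.rna_alt_reads / total


@dataclass(frozen=True)
class GeneExpression:
    """Empirical mean and variance of a gene's expression (e.g. FPKM)."""

    gene_id: str
    mean: float
    variance: float

    def __post_init__(self):
        if self.mean < 0 or self.variance < 0:
            raise ValueError(
                f"{self.gene_id}: expression mean/variance must be non-negative"
            )


@dataclass(frozen=True)
class HlaAllele:
    """An HLA class I allele with the expression moments of its gene."""

    allele_name: str
    expression: GeneExpression

    def __post_init__(self):
        if not self.allele_name:
            raise ValueError("allele_name must be non-empty")


@dataclass(frozen=True)
class EpitopeScore:
    """Predictor scores for one (variant, minimal epitope, allele) triple.

    ``binding_value`` is either an IC50 affinity in nM or a rank percentile
    depending on the patient's ``binding_mode``; lower is stronger for both.
    """

    variant_id: str
    peptide: str
    allele_name: str
    cleavage_score: float
    binding_value: float
    stability_score: float

    def __post_init__(self):
        if not (8 <= len(self.peptide) <= 11):
            raise ValueError(
                f"peptide {self.peptide!r} has length {len(self.peptide)}, "
                "expected a minimal epitope of 8-11 residues"
            )
        if self.cleavage_score < 0:
            raise ValueError(f"{self.peptide}: cleavage_score must be non-negative")
        if self.binding_value <= 0:
            raise ValueError(f"{self.peptide}: binding_value must be positive")
        if self.stability_score < 0:
            raise ValueError(f"{self.peptide}: stability_score must be non-negative")


@dataclass
class PatientInput:
    """Validated per-patient inputs; see :func:`neovax.data_io.load_patient_input`."""

    variants: List[VariantRecord]
    expression: Dict[str, GeneExpression]
    alleles: List[HlaAllele]
    scores: List[EpitopeScore]
    binding_mode: BindingMode = "percentile"
    #: variant_id -> set of its minimal epitopes, derived from ``scores``
    elements: Dict[str, FrozenSet[str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.binding_mode not in VALID_BINDING_MODES:
            raise ValueError(f"unknown binding_mode {self.binding_mode!r}")
        if not self.elements:
            elems: Dict[str, set] = {v.variant_id: set() for v in self.variants}
            for s in self.scores:
                elems.setdefault(s.variant_id, set()).add(s.peptide)
            self.elements = {k: frozenset(v) for k, v in elems.items()}

    @property
    def variant_ids(self) -> List[str]:
        return [v.variant_id for v in self.variants]

    @property
    def allele_names(self) -> List[str]:
        return [a.allele_name for a in self.alleles]


@dataclass(frozen=True)
class SimulationParams:
    """Digital-twin dimensions: M cells per population, K replicate populations."""

    population_size: int
    num_replicates: int = 1
    seed: int = 0
    binding_mode: Optional[BindingMode] = None  # None -> use the patient's

    def __post_init__(self):
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.num_replicates < 1:
            raise ValueError("num_replicates must be >= 1")


@dataclass(frozen=True)
class SimulatedCell:
    """One simulated cancer cell: which variants it carries and its surface
    multiset ``S*`` of presented (peptide, allele) complexes."""

    cell_index: int
    present_variants: FrozenSet[str]
    presented: Mapping[Tuple[str, str], int]

    def peptide_counts(self) -> Dict[str, int]:
        """Presented multiplicity per peptide, summed over alleles (N_jk)."""
        counts: Dict[str, int] = {}
        for (pep, _allele), m in self.presented.items():
            if m > 0:
                counts[pep] = counts.get(pep, 0) + m
        return counts


@dataclass(frozen=True)
class CellPopulation:
    """A population of M simulated cells from one replicate run."""

    cells: Tuple[SimulatedCell, ...]
    replicate_index: int
    seed_used: int

    def __post_init__(self):
        idx = [c.cell_index for c in self.cells]
        if len(set(idx)) != len(idx):
            raise ValueError("cell indices must be unique")

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class ResponseMatrix:
    """The N x M matrix of log no-response coefficients p_ij <= 0."""

    elements: List[str]
    num_cells: int
    coefficients: np.ndarray
    lambda_used: float
    floor_used: float

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        n, m = self.coefficients.shape
        if n != len(self.elements) or m != self.num_cells:
            raise ValueError(
                f"coefficient matrix {self.coefficients.shape} inconsistent with "
                f"{len(self.elements)} elements x {self.num_cells} cells"
            )
        if self.lambda_used <= 0:
            raise ValueError("lambda_used must be positive")
        if self.floor_used >= 0:
            raise ValueError("floor_used must be negative")
        if np.any(self.coefficients > 1e-12):
            raise ValueError("all p_ij must be non-positive")
        if np.any(self.coefficients < self.floor_used - 1e-9):
            raise ValueError("p_ij below the configured floor")

    def row(self, variant_id: str) -> np.ndarray:
        return self.coefficients[self.elements.index(variant_id)]


Objective = Literal["min_sum", "min_max"]


@dataclass(frozen=True)
class OptimizationProblem:
    """A budget-constrained element-selection instance over one ResponseMatrix."""

    matrix: ResponseMatrix
    costs: Tuple[float, ...]
    budget: float
    objective: Objective

    def __post_init__(self):
        if len(self.costs) != len(self.matrix.elements):
            raise ValueError("one cost per element required")
        if any(c <= 0 for c in self.costs):
            raise ValueError("costs must be positive")
        if self.budget <= 0:
            raise ValueError("budget must be positive")
        if self.objective not in ("min_sum", "min_max"):
            raise ValueError(f"unknown objective {self.objective!r}")


SolverStatus = Literal["optimal", "infeasible", "error"]


@dataclass(frozen=True)
class VaccineDesign:
    """A selected element set with its objective value and budget accounting."""

    selected: FrozenSet[str]
    objective_value: float
    objective: Objective
    total_cost: float
    solver_status: SolverStatus = "optimal"


@dataclass
class EvaluationReport:
    """Post-optimization analytics for one design (and optionally replicates)."""

    response_probs: np.ndarray
    coverage_curve: List[Tuple[float, float]]
    iou: Optional[float] = None
    recall_rows: List[Tuple[str, int, int, Optional[float]]] = field(default_factory=list)
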