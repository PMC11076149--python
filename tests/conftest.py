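import numpy as np
import pytest

from neovax.types import (
    CellPopulation,
    EpitopeScore,
    GeneExpression,
    HlaAllele,
    PatientInput,
    ResponseMatrix,
    SimulatedCell,
    VariantRecord,
)

PEPS = {
    "v1": ["ACDEFGHI", "KLMNPQRS", "TVWYACDE", "FGHIKLMN"],
    "v2": ["ACDEFGHK", "KLMNPQRT", "TVWYACDF", "FGHIKLMP"],
    "v3": ["ACDEFGHL", "KLMNPQRV", "TVWYACDG", "FGHIKLMQ"],
    "v4": ["ACDEFGHM", "KLMNPQRW", "TVWYACDH"],
}


@pytest.fixture
def tiny_patient() -> PatientInput:
    """Hand-built patient: 4 variants, 2 alleles, 30 score rows."""
    variants = [
        VariantRecord("v1", "g1", 30, 10, 25, 75),   # DNA VAF 0.75, RNA VAF 0.25
        VariantRecord("v2", "g2", 10, 90, 10, 90),   # subclonal
        VariantRecord("v3", "g3", 50, 50, 40, 40),   # DNA VAF 0.5
        VariantRecord("v4", "g4", 5, 95, 0, 0),      # no RNA coverage
    ]
    expression = {
        "g1": GeneExpression("g1", 60.0, 240.0),
        "g2": GeneExpression("g2", 20.0, 80.0),
        "g3": GeneExpression("g3", 40.0, 30.0),      # under-dispersed
        "g4": GeneExpression("g4", 10.0, 40.0),
    }
    alleles = [
        HlaAllele("HLA-A*01:01", GeneExpression("HLA-A*01:01", 80.0, 320.0)),
        HlaAllele("HLA-B*07:02", GeneExpression("HLA-B*07:02", 60.0, 240.0)),
    ]
    rng = np.random.default_rng(2024)
    scores = []
    for vid, peps in PEPS.items():
        for pep in peps:
            cleavage = float(rng.uniform(0.1, 1.0))
            for allele in ("HLA-A*01:01", "HLA-B*07:02"):
                scores.append(EpitopeScore(
                    variant_id=vid, peptide=pep, allele_name=allele,
                    cleavage_score=cleavage,
                    binding_value=float(rng.uniform(0.1, 10.0)),
                    stability_score=float(rng.uniform(0.1, 1.0))))
    return PatientInput(variants=variants, expression=expression,
                        alleles=alleles, scores=scores,
                        binding_mode="percentile")


def make_cell(index, presented, present=None) -> SimulatedCell:
    present = present if present is not None else {v for (p, a) in presented for v in ()}
    return SimulatedCell(cell_index=index,
                         present_variants=frozenset(present or ()),
                         presented=dict(presented))


def make_population(cells, replicate_index=0, seed=0) -> CellPopulation:
    return CellPopulation(cells=tuple(cells), replicate_index=replicate_index,
                          seed_used=seed)


def make_matrix(coefficients, elements=None, lam=1.0, floor=-50.0) -> ResponseMatrix:
    coefficients = np.asarray(coefficients, dtype=float)
    n = coefficients.shape[0]
    elements = elements or [f"e{i}" for i in range(n)]
    return ResponseMatrix(elements=list(elements),
                          num_cells=coefficients.shape[1],
                          coefficients=coefficients,
                          lambda_used=lam, floor_used=floor)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
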