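"""Per-cell stochastic simulation of the MHC class I presentation pathway.

Each simulated cancer cell runs a five-stage sampling cascade:

1. **Mutation presence** — each variant is present with probability equal to
   its DNA variant allele frequency (Bernoulli).
2. **Protein abundance** — for each present variant, the transcript count of
   its gene is a Gamma-Poisson draw (negative binomial matched to the
   empirical mean/variance; Poisson when under-dispersed), scaled by the RNA
   VAF to the number of mutated protein copies.
3. **Cleavage** — each mutated protein copy is chopped into one of the
   variant's minimal epitopes, multinomially with probabilities proportional
   to the predicted cleavage scores.
4. **MHC binding** — per HLA allele, the number of available MHC molecules is
   a Gamma-Poisson draw from the allele's expression; peptides from the
   pooled cleavage products compete for the min(available MHC, pool size)
   binding slots, multinomially with weights from the binding predictions
   (lower percentile / nM = stronger = more binding events).
5. **Surface presentation** — each distinct bound peptide-MHC complex reaches
   the surface independently with probability proportional to its predicted
   stability, normalized over the cell's bound complexes.

The result per cell is the multiset ``S*`` of presented (peptide, allele)
complexes; a population is M such cells, replicated K times to expose the
simulation's stochasticity.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateModelError, ReferentialIntegrityError
from .types import (
    BindingMode,
    CellPopulation,
    HlaAllele,
    PatientInput,
    SimulatedCell,
    SimulationParams,
    VariantRecord,
)

#: ε guard for the reciprocal binding-propensity transform
PROPENSITY_EPS = 1e-3

PropensityTransform = Callable[[np.ndarray], np.ndarray]


def reciprocal_propensity(values: np.ndarray) -> np.ndarray:
    """Default binding propensity: w = 1 / max(value, ε).

    Both score conventions (IC50 nM and rank percentile) are
    "lower = stronger binder", so the reciprocal preserves the required
    monotonicity: stronger binders draw more binding events.
    """
    return 1.0 / np.maximum(np.asarray(values, dtype=float), PROPENSITY_EPS)


def sample_variant_presence(variant: VariantRecord, rng: np.random.Generator) -> bool:
    """Bernoulli presence of a mutation in one cell, p = DNA VAF."""
    return bool(rng.random() < variant.dna_vaf)


def sample_gamma_poisson(mean: float, variance: float,
                         rng: np.random.Generator) -> int:
    """Gamma-Poisson (negative binomial) count draw matched to (mean, variance).

    When ``variance <= mean`` the mixture degenerates and a Poisson(mean) is
    used; ``mean == 0`` yields 0 deterministically.
    """
    if mean < 0 or variance < 0:
        raise ValueError(f"mean/variance must be non-negative, got ({mean}, {variance})")
    if mean == 0:
        return 0
    if variance <= mean:
        return int(rng.poisson(mean))
    # moment-matched NB: r = m^2/(v-m) successes, p = m/v
    r = mean * mean / (variance - mean)
    p = mean / variance
    return int(rng.negative_binomial(r, p))


def compute_variant_protein_count(transcript_count: int,
                                  variant: VariantRecord) -> int:
    """Mutated protein copies: transcript count x RNA VAF, round-half-to-even."""
    if transcript_count < 0:
        raise ValueError("transcript_count must be non-negative")
    return int(round(transcript_count * variant.rna_vaf))


def sample_cleavage(protein_count: int, peptides: Sequence[str],
                    cleavage_scores: Sequence[float],
                    rng: np.random.Generator) -> Dict[str, int]:
    """Multinomial cleavage of ``protein_count`` protein copies into epitopes.

    Returns the multiset P*_i as peptide -> multiplicity; multiplicities sum
    to ``protein_count`` exactly.
    """
    peptides = list(peptides)
    c = np.asarray(cleavage_scores, dtype=float)
    if len(peptides) != c.size or c.size == 0:
        raise ValueError("need one cleavage score per peptide, at least one peptide")
    total = c.sum()
    if total <= 0:
        raise DegenerateModelError(
            "all-zero cleavage vector: multinomial cleavage undefined")
    if protein_count == 0:
        return {}
    counts = rng.multinomial(protein_count, c / total)
    return {p: int(m) for p, m in zip(peptides, counts) if m > 0}


def sample_binding(pool: Mapping[str, int], allele: HlaAllele, n_mhc: int,
                   scores: Mapping[str, float], binding_mode: BindingMode,
                   rng: np.random.Generator,
                   propensity: Optional[PropensityTransform] = None,
                   ) -> Dict[Tuple[str, str], int]:
    """Competition of pooled peptides for one allele's MHC molecules.

    ``n* = min(n_mhc, |pool|)`` (pool counted with multiplicity) binding
    events are distributed over the distinct pool peptides multinomially with
    weights from the binding-score transform. Returns B*_a as
    (peptide, allele_name) -> multiplicity summing to n*.
    """
    distinct = [p for p, m in pool.items() if m > 0]
    pool_size = sum(pool.values())
    n_star = min(int(n_mhc), pool_size)
    if n_star <= 0 or not distinct:
        return {}
    missing = [p for p in distinct if p not in scores]
    if missing:
        raise ReferentialIntegrityError(
            f"no {binding_mode} binding value for allele {allele.allele_name} "
            f"and peptide(s): {', '.join(sorted(missing))}", offenders=missing)
    transform = propensity or reciprocal_propensity
    w = transform(np.array([scores[p] for p in distinct], dtype=float))
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("binding propensities must be non-negative with positive sum")
    counts = rng.multinomial(n_star, w / w.sum())
    return {(p, allele.allele_name): int(m)
            for p, m in zip(distinct, counts) if m > 0}


def sample_presentation(bound: Mapping[Tuple[str, str], int],
                        stability: Mapping[Tuple[str, str], float],
                        rng: np.random.Generator) -> Dict[Tuple[str, str], int]:
    """Surface presentation of bound complexes.

    Each distinct complex of B* is presented (multiplicity 1) independently
    with probability equal to its stability score normalized over the cell's
    distinct bound complexes. If every bound complex has stability 0, nothing
    is presented.
    """
    distinct = [b for b, m in bound.items() if m > 0]
    if not distinct:
        return {}
    missing = [b for b in distinct if b not in stability]
    if missing:
        raise ReferentialIntegrityError(
            f"no stability score for complex(es): {sorted(missing)}",
            offenders=missing)
    st = np.array([stability[b] for b in distinct], dtype=float)
    if np.any(st < 0):
        raise ValueError("stability scores must be non-negative")
    total = st.sum()
    if total <= 0:
        return {}
    keep = rng.random(len(distinct)) < st / total
    return {b: 1 for b, k in zip(distinct, keep) if k}


class _SimIndex:
    """Precomputed per-patient arrays so the per-cell loop stays cheap."""

    def __init__(self, patient: PatientInput, binding_mode: Optional[BindingMode],
                 propensity: Optional[PropensityTransform]):
        self.binding_mode: BindingMode = binding_mode or patient.binding_mode
        self.propensity = propensity
        self.variants = list(patient.variants)
        self.dna_vaf = np.array([v.dna_vaf for v in self.variants], dtype=float)
        self.gene_mean = np.array(
            [patient.expression[v.gene_id].mean for v in self.variants])
        self.gene_var = np.array(
            [patient.expression[v.gene_id].variance for v in self.variants])
        self.alleles = list(patient.alleles)

        # per variant: ordered peptide list + cleavage vector
        per_variant: Dict[str, Dict[str, float]] = {v.variant_id: {} for v in self.variants}
        self.binding: Dict[str, Dict[str, float]] = {a.allele_name: {} for a in self.alleles}
        self.stability: Dict[Tuple[str, str], float] = {}
        for s in patient.scores:
            if s.variant_id in per_variant:
                per_variant[s.variant_id][s.peptide] = s.cleavage_score
            self.binding[s.allele_name][s.peptide] = s.binding_value
            self.stability[(s.peptide, s.allele_name)] = s.stability_score
        self.peptides: List[List[str]] = []
        self.cleavage: List[np.ndarray] = []
        for v in self.variants:
            peps = sorted(per_variant[v.variant_id])
            self.peptides.append(peps)
            self.cleavage.append(
                np.array([per_variant[v.variant_id][p] for p in peps], dtype=float))


def simulate_cell(patient: PatientInput, cell_index: int,
                  rng: np.random.Generator,
                  _index: Optional[_SimIndex] = None,
                  trace: Optional[dict] = None) -> SimulatedCell:
    """Run the full five-stage cascade for one cell.

    If ``trace`` is a dict it is filled with the intermediate stage outputs
    (protein counts, cleaved multisets, MHC availability, bound multisets) so
    conservation laws can be audited from outside.
    """
    idx = _index or _SimIndex(patient, None, None)

    # stage 1: mutation presence, one Bernoulli per variant
    present_mask = rng.random(len(idx.variants)) < idx.dna_vaf
    present = [v.variant_id for v, m in zip(idx.variants, present_mask) if m]

    # stages 2-3: protein abundance and cleavage, pooled over present variants
    pool: Dict[str, int] = {}
    protein_counts: Dict[str, int] = {}
    cleaved: Dict[str, Dict[str, int]] = {}
    for i, (variant, is_present) in enumerate(zip(idx.variants, present_mask)):
        if not is_present or not idx.peptides[i]:
            continue
        transcripts = sample_gamma_poisson(idx.gene_mean[i], idx.gene_var[i], rng)
        n_prot = compute_variant_protein_count(transcripts, variant)
        cleaved_i = sample_cleavage(n_prot, idx.peptides[i], idx.cleavage[i], rng)
        protein_counts[variant.variant_id] = n_prot
        cleaved[variant.variant_id] = cleaved_i
        for pep, m in cleaved_i.items():
            pool[pep] = pool.get(pep, 0) + m

    # stage 4: per-allele MHC availability and binding competition
    bound: Dict[Tuple[str, str], int] = {}
    mhc_counts: Dict[str, int] = {}
    for allele in idx.alleles:
        n_mhc = sample_gamma_poisson(allele.expression.mean,
                                     allele.expression.variance, rng)
        mhc_counts[allele.allele_name] = n_mhc
        bound.update(sample_binding(pool, allele, n_mhc,
                                    idx.binding[allele.allele_name],
                                    idx.binding_mode, rng, idx.propensity))

    # stage 5: stability-weighted surface presentation
    presented = sample_presentation(bound, idx.stability, rng)
    if trace is not None:
        trace.update(protein_counts=protein_counts, cleaved=cleaved,
                     pool=dict(pool), mhc_counts=mhc_counts, bound=dict(bound))
    return SimulatedCell(cell_index=cell_index,
                         present_variants=frozenset(present),
                         presented=presented)


def cell_rng(seed: int, replicate_index: int, cell_index: int) -> np.random.Generator:
    """Deterministic random substream for one (replicate, cell) pair.

    Population contents therefore do not depend on evaluation order, and any
    cell can be re-simulated in isolation (e.g. to audit its stage-level
    conservation laws) and reproduce the population's cell bit for bit.
    """
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(replicate_index, cell_index))
    return np.random.default_rng(ss)


def simulate_population(patient: PatientInput, params: SimulationParams,
                        replicate_index: int = 0) -> CellPopulation:
    """Simulate one population of M cells (one replicate)."""
    idx = _SimIndex(patient, params.binding_mode, None)
    cells = tuple(
        simulate_cell(patient, j, cell_rng(params.seed, replicate_index, j),
                      _index=idx)
        for j in range(params.population_size)
    )
    return CellPopulation(cells=cells, replicate_index=replicate_index,
                          seed_used=params.seed)


def simulate_replicates(patient: PatientInput,
                        params: SimulationParams) -> List[CellPopulation]:
    """Simulate all K replicate populations for one patient."""
    idx = _SimIndex(patient, params.binding_mode, None)
    out = []
    for k in range(params.num_replicates):
        cells = tuple(
            simulate_cell(patient, j, cell_rng(params.seed, k, j), _index=idx)
            for j in range(params.population_size)
        )
        out.append(CellPopulation(cells=cells, replicate_index=k,
                                  seed_used=params.seed))
    return out
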