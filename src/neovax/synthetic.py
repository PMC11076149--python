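"""Synthetic patient generator with planted ground truth.

Emulates the tabular inputs an upstream pipeline (variant calling, RNA-seq
quantification, HLA typing, epitope prediction) would produce for one
patient, with full control over the features that drive the simulation:

* **clonality** — planted immunogenic variants are clonal (heterozygous
  VAF ~ 0.5), decoys subclonal (VAF in a low range); read counts are drawn
  binomially at realistic WES/RNA-seq depths so empirical VAFs match the
  configured values in expectation;
* **expression dispersion** — per-gene variance tied to the mean through a
  dispersion factor, exercising both the negative-binomial (factor > 1) and
  the Poisson-fallback (factor <= 1) regimes of the simulator;
* **score profiles** — planted variants get strong predictor profiles (low
  binding percentile, high cleavage/stability); decoys get weak ones. A
  configurable fraction of decoys are *traps*: strong binding scores but
  barely expressed genes, so single-score ranking baselines select them
  while the cell simulation exposes that they are rarely presented.

Ground truth (planted variant ids, VAFs, profiles) is returned alongside and
optionally written as ``ground_truth.json``.
"""

from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import data_io
from .types import (
    EpitopeScore,
    GeneExpression,
    HlaAllele,
    PatientInput,
    VariantRecord,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticPatientConfig:
    """Knobs of the generator; defaults describe a moderately heterogeneous
    tumor with a handful of clonal, well-presented immunogenic mutations."""

    num_variants: int = 50
    num_alleles: int = 2
    num_planted: int = 5
    #: planted (clonal) variants: heterozygous VAF
    clonal_vaf: float = 0.5
    #: decoys: subclonal VAF drawn uniformly from this interval
    subclonal_vaf_range: Tuple[float, float] = (0.05, 0.2)
    #: per-gene mean expression (FPKM-like units) drawn from this interval;
    #: planted variants from its upper half
    expression_mean_range: Tuple[float, float] = (1.0, 100.0)
    #: variance = dispersion_factor x mean (>1: negative binomial; <=1: Poisson)
    dispersion_factor: float = 4.0
    #: HLA allele gene expression mean range (class I genes are highly expressed)
    hla_expression_range: Tuple[float, float] = (50.0, 200.0)
    peptides_per_variant: Tuple[int, int] = (4, 12)
    #: fraction of decoys given strong binding scores but negligible
    #: expression — the failure mode of pure-ranking selection
    trap_fraction: float = 0.3
    trap_expression_mean: float = 0.2
    #: binding percentile ranges (lower = stronger)
    strong_percentile_range: Tuple[float, float] = (0.05, 0.5)
    decoy_percentile_range: Tuple[float, float] = (5.0, 50.0)
    strong_cleavage_range: Tuple[float, float] = (0.5, 1.0)
    decoy_cleavage_range: Tuple[float, float] = (0.02, 0.4)
    strong_stability_range: Tuple[float, float] = (0.5, 1.0)
    decoy_stability_range: Tuple[float, float] = (0.02, 0.4)
    dna_depth: int = 200
    rna_depth: int = 80
    seed: int = 0

    def __post_init__(self):
        if self.num_variants < 1 or self.num_alleles < 1:
            raise ValueError("need at least one variant and one allele")
        if not (0 <= self.num_planted <= self.num_variants):
            raise ValueError("num_planted must lie in [0, num_variants]")
        for name in ("subclonal_vaf_range", "expression_mean_range",
                     "hla_expression_range", "peptides_per_variant",
                     "strong_percentile_range", "decoy_percentile_range",
                     "strong_cleavage_range", "decoy_cleavage_range",
                     "strong_stability_range", "decoy_stability_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        lo, hi = self.peptides_per_variant
        if lo < 1 or hi > 24:
            raise ValueError("peptides_per_variant must lie within [1, 24]")
        if not (0.0 <= self.trap_fraction <= 1.0):
            raise ValueError("trap_fraction must lie in [0, 1]")
        if not (0.0 < self.clonal_vaf <= 1.0):
            raise ValueError("clonal_vaf must lie in (0, 1]")
        if self.dispersion_factor <= 0:
            raise ValueError("dispersion_factor must be positive")
        if self.dna_depth < 1 or self.rna_depth < 0:
            raise ValueError("invalid sequencing depths")


def _random_peptide(rng: np.random.Generator, taken: set) -> str:
    while True:
        length = int(rng.integers(8, 12))
        pep = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
        if pep not in taken:
            taken.add(pep)
            return pep


def generate_patient(config: SyntheticPatientConfig,
                     out_dir=None) -> Tuple[PatientInput, Dict]:
    """Build one synthetic patient; optionally write the canonical TSVs,
    a peptide FASTA and ``ground_truth.json`` into ``out_dir``.

    Returns ``(patient, ground_truth)`` where the ground truth records the
    planted immunogenic variants, per-variant true VAFs and score profiles.
    """
    rng = np.random.default_rng(config.seed)
    n = config.num_variants
    planted = set(range(config.num_planted))
    decoys = [i for i in range(n) if i not in planted]
    n_traps = int(round(config.trap_fraction * len(decoys)))
    traps = set(decoys[:n_traps])  # deterministic: first decoys are traps

    variants: List[VariantRecord] = []
    expression: Dict[str, GeneExpression] = {}
    scores: List[EpitopeScore] = []
    taken_peptides: set = set()
    truth_variants = []

    lo_e, hi_e = config.expression_mean_range
    allele_names = [f"HLA-A*{i + 1:02d}:01" for i in range(config.num_alleles)]
    alleles = []
    for name in allele_names:
        mean = float(rng.uniform(*config.hla_expression_range))
        alleles.append(HlaAllele(
            allele_name=name,
            expression=GeneExpression(name, mean,
                                      config.dispersion_factor * mean)))

    for i in range(n):
        vid = f"var{i:03d}"
        gene = f"ENSG{i:08d}"
        is_planted = i in planted
        is_trap = i in traps
        vaf = (config.clonal_vaf if is_planted
               else float(rng.uniform(*config.subclonal_vaf_range)))
        dna_alt = int(rng.binomial(config.dna_depth, vaf))
        dna_alt = min(max(dna_alt, 1), config.dna_depth - 1)  # keep VAF in (0,1)
        rna_alt = int(rng.binomial(config.rna_depth, vaf)) if config.rna_depth else 0
        if config.rna_depth:
            rna_alt = min(max(rna_alt, 1), config.rna_depth)
        variants.append(VariantRecord(
            variant_id=vid, gene_id=gene,
            dna_alt_reads=dna_alt, dna_ref_reads=config.dna_depth - dna_alt,
            rna_alt_reads=rna_alt, rna_ref_reads=config.rna_depth - rna_alt))

        if is_planted:
            mean = float(rng.uniform((lo_e + hi_e) / 2.0, hi_e))
        elif is_trap:
            mean = config.trap_expression_mean
        else:
            mean = float(rng.uniform(lo_e, hi_e))
        expression[gene] = GeneExpression(gene, mean,
                                          config.dispersion_factor * mean)

        strong = is_planted or is_trap
        perc_rng = (config.strong_percentile_range if strong
                    else config.decoy_percentile_range)
        cleav_rng = (config.strong_cleavage_range if strong
                     else config.decoy_cleavage_range)
        stab_rng = (config.strong_stability_range if strong
                    else config.decoy_stability_range)
        n_pep = int(rng.integers(config.peptides_per_variant[0],
                                 config.peptides_per_variant[1] + 1))
        peptides = [_random_peptide(rng, taken_peptides) for _ in range(n_pep)]
        for pep in peptides:
            cleavage = float(rng.uniform(*cleav_rng))
            for allele in allele_names:
                scores.append(EpitopeScore(
                    variant_id=vid, peptide=pep, allele_name=allele,
                    cleavage_score=cleavage,
                    binding_value=float(rng.uniform(*perc_rng)),
                    stability_score=float(rng.uniform(*stab_rng))))
        truth_variants.append({
            "variant_id": vid, "vaf": vaf,
            "profile": ("planted" if is_planted else
                        "trap" if is_trap else "decoy"),
            "expression_mean": mean, "num_peptides": n_pep})

    patient = PatientInput(variants=variants, expression=expression,
                           alleles=alleles, scores=scores,
                           binding_mode="percentile")
    ground_truth = {
        "seed": config.seed,
        "planted_variants": sorted(f"var{i:03d}" for i in planted),
        "trap_variants": sorted(f"var{i:03d}" for i in traps),
        "variants": truth_variants,
        "config": dataclasses.asdict(config),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        data_io.write_patient_input(patient, out_dir)
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(ground_truth, fh, indent=2, sort_keys=True)
        with open(out_dir / "peptides.fasta", "w") as fh:
            seen = set()
            for s in scores:
                if s.peptide not in seen:
                    seen.add(s.peptide)
                    fh.write(f">{s.variant_id}|{s.peptide}\n{s.peptide}\n")

    return patient, ground_truth


def generate_benchmark_suite(seeds: Sequence[int],
                             config: SyntheticPatientConfig,
                             out_dir=None) -> List[Tuple[PatientInput, Dict]]:
    """One synthetic patient per seed (multi-patient comparison scaffolding)."""
    if len(seeds) == 0:
        raise ValueError("need at least one seed")
    out = []
    manifest = []
    for s in seeds:
        cfg = dataclasses.replace(config, seed=int(s))
        patient_dir = None if out_dir is None else Path(out_dir) / f"patient_seed{s}"
        patient, truth = generate_patient(cfg, patient_dir)
        out.append((patient, truth))
        manifest.append({"seed": int(s),
                         "planted_variants": truth["planted_variants"]})
    if out_dir is not None:
        with open(Path(out_dir) / "suite_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return out
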