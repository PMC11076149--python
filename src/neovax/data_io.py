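"""Reading and writing the per-patient tables.

The canonical dialect is TSV with a header row, UTF-8:

* variants:   variant_id  gene_id  dna_alt_reads  dna_ref_reads  rna_alt_reads  rna_ref_reads
* expression: gene_id  mean  variance
* alleles:    allele_name  mean  variance  [gene_id]
* scores:     variant_id  peptide  allele_name  cleavage_score  binding_value  stability_score

A thin adapter (:func:`adapt_pvacbind_scores`) renames the column dialect of
pVACbind-style ``all_epitopes.tsv`` outputs into the canonical score schema,
so the simulator is not tied to one upstream predictor pipeline.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import DuplicateScoreError, ReferentialIntegrityError, SchemaError
from .types import (
    BindingMode,
    EpitopeScore,
    GeneExpression,
    HlaAllele,
    PatientInput,
    ResponseMatrix,
    VaccineDesign,
    VALID_BINDING_MODES,
    VariantRecord,
)

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = [
    "variant_id", "gene_id",
    "dna_alt_reads", "dna_ref_reads", "rna_alt_reads", "rna_ref_reads",
]
EXPRESSION_COLUMNS = ["gene_id", "mean", "variance"]
ALLELE_COLUMNS = ["allele_name", "mean", "variance"]
SCORE_COLUMNS = [
    "variant_id", "peptide", "allele_name",
    "cleavage_score", "binding_value", "stability_score",
]

#: Column mapping for the pVACbind ``all_epitopes.tsv`` dialect (with the
#: NetChop / NetMHCstab columns appended by downstream analysis).
PVACBIND_COLUMN_MAP = {
    "Mutation": "variant_id",
    "MT Epitope Seq": "peptide",
    "HLA Allele": "allele_name",
    "Best Cleavage Score": "cleavage_score",
    "Median MT IC50 Score": "binding_value",
    "Predicted Stability": "stability_score",
}


def _read_table(path, required: List[str], table_name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{table_name} table not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip",
                     dtype={c: str for c in
                            ("variant_id", "gene_id", "allele_name", "peptide")})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{table_name} table {path} is missing column(s): {', '.join(missing)}"
        )
    return df


def adapt_pvacbind_scores(df: pd.DataFrame,
                          column_map: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Rename a pVACbind-dialect epitope table into the canonical score schema.

    Unknown extra columns are dropped; the mapping may be overridden for
    other upstream pipelines.
    """
    cmap = dict(PVACBIND_COLUMN_MAP if column_map is None else column_map)
    out = df.rename(columns=cmap)
    keep = [c for c in SCORE_COLUMNS if c in out.columns]
    return out[keep].copy()


def load_patient_input(variant_path, expression_path, allele_path, score_path,
                       binding_mode: BindingMode = "percentile") -> PatientInput:
    """Load and cross-validate the four patient tables.

    Referential integrity is enforced here so no downstream operation can
    encounter a dangling gene, allele, variant or peptide key.
    """
    if binding_mode not in VALID_BINDING_MODES:
        raise ValueError(f"unknown binding_mode {binding_mode!r}")

    vdf = _read_table(variant_path, VARIANT_COLUMNS, "variant")
    edf = _read_table(expression_path, EXPRESSION_COLUMNS, "expression")
    adf = _read_table(allele_path, ALLELE_COLUMNS, "allele")
    sdf = _read_table(score_path, SCORE_COLUMNS, "score")

    expression = {
        r.gene_id: GeneExpression(r.gene_id, float(r.mean), float(r.variance))
        for r in edf.itertuples()
    }

    variants: List[VariantRecord] = []
    for r in vdf.itertuples():
        variants.append(VariantRecord(
            variant_id=r.variant_id, gene_id=r.gene_id,
            dna_alt_reads=int(r.dna_alt_reads), dna_ref_reads=int(r.dna_ref_reads),
            rna_alt_reads=int(r.rna_alt_reads), rna_ref_reads=int(r.rna_ref_reads),
        ))
        if int(r.rna_alt_reads) + int(r.rna_ref_reads) == 0:
            logger.warning(
                "variant %s has zero RNA coverage; RNA VAF treated as 0 "
                "(no mutated transcript copies)", r.variant_id)

    bad_genes = sorted({v.gene_id for v in variants} - set(expression))
    if bad_genes:
        raise ReferentialIntegrityError(
            f"variant gene_id(s) missing from expression table: {', '.join(bad_genes)}",
            offenders=bad_genes)

    alleles: List[HlaAllele] = []
    for r in adf.itertuples():
        gene_id = getattr(r, "gene_id", None) or r.allele_name
        alleles.append(HlaAllele(
            allele_name=r.allele_name,
            expression=GeneExpression(str(gene_id), float(r.mean), float(r.variance)),
        ))

    known_variants = {v.variant_id for v in variants}
    known_alleles = {a.allele_name for a in alleles}

    dup = sdf.duplicated(subset=["variant_id", "peptide", "allele_name"], keep=False)
    if dup.any():
        keys = sdf.loc[dup, ["variant_id", "peptide", "allele_name"]]
        offenders = sorted({tuple(t) for t in keys.itertuples(index=False)})
        raise DuplicateScoreError(
            f"duplicate score rows for {len(offenders)} (variant, peptide, allele) "
            f"key(s), e.g. {offenders[0]}")

    bad_v = sorted(set(sdf["variant_id"]) - known_variants)
    if bad_v:
        raise ReferentialIntegrityError(
            f"score rows reference unknown variant(s): {', '.join(bad_v)}",
            offenders=bad_v)
    bad_a = sorted(set(sdf["allele_name"]) - known_alleles)
    if bad_a:
        raise ReferentialIntegrityError(
            f"score rows reference unknown allele(s): {', '.join(bad_a)}",
            offenders=bad_a)

    scores = [
        EpitopeScore(
            variant_id=r.variant_id, peptide=r.peptide, allele_name=r.allele_name,
            cleavage_score=float(r.cleavage_score),
            binding_value=float(r.binding_value),
            stability_score=float(r.stability_score),
        )
        for r in sdf.itertuples()
    ]

    # cleavage is a property of (variant, peptide): it must not vary by allele
    cleave: Dict[Tuple[str, str], float] = {}
    bad_c = []
    for s in scores:
        key = (s.variant_id, s.peptide)
        if key in cleave and cleave[key] != s.cleavage_score:
            bad_c.append(key)
        cleave[key] = s.cleavage_score
    if bad_c:
        raise ReferentialIntegrityError(
            f"cleavage_score differs across alleles for: {sorted(set(bad_c))}",
            offenders=sorted(set(bad_c)))

    return PatientInput(variants=variants, expression=expression,
                        alleles=alleles, scores=scores, binding_mode=binding_mode)


def write_patient_input(patient: PatientInput, out_dir) -> Dict[str, Path]:
    """Write the four canonical TSVs into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": out_dir / "variants.tsv",
        "expression": out_dir / "expression.tsv",
        "alleles": out_dir / "alleles.tsv",
        "scores": out_dir / "scores.tsv",
    }
    pd.DataFrame(
        [(v.variant_id, v.gene_id, v.dna_alt_reads, v.dna_ref_reads,
          v.rna_alt_reads, v.rna_ref_reads) for v in patient.variants],
        columns=VARIANT_COLUMNS,
    ).to_csv(paths["variants"], sep="\t", index=False)
    pd.DataFrame(
        [(g.gene_id, g.mean, g.variance) for g in patient.expression.values()],
        columns=EXPRESSION_COLUMNS,
    ).to_csv(paths["expression"], sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(
        [(a.allele_name, a.expression.mean, a.expression.variance,
          a.expression.gene_id) for a in patient.alleles],
        columns=ALLELE_COLUMNS + ["gene_id"],
    ).to_csv(paths["alleles"], sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(
        [(s.variant_id, s.peptide, s.allele_name, s.cleavage_score,
          s.binding_value, s.stability_score) for s in patient.scores],
        columns=SCORE_COLUMNS,
    ).to_csv(paths["scores"], sep="\t", index=False, float_format="%.17g")
    return paths


def write_vaccine_design(design: VaccineDesign, path,
                         costs: Optional[Mapping[str, float]] = None,
                         aggregates: Optional[Mapping[str, float]] = None,
                         budget: Optional[float] = None) -> Path:
    """Persist a design as TSV: metadata header comments + one row per element."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# objective\t{design.objective}\n")
        fh.write(f"# objective_value\t{design.objective_value!r}\n")
        fh.write(f"# total_cost\t{design.total_cost!r}\n")
        fh.write(f"# solver_status\t{design.solver_status}\n")
        fh.write(f"# budget\t{budget!r}\n")
        fh.write("variant_id\tcost\taggregate_p\n")
        for vid in sorted(design.selected):
            c = costs.get(vid, float("nan")) if costs else float("nan")
            p = aggregates.get(vid, float("nan")) if aggregates else float("nan")
            fh.write(f"{vid}\t{c!r}\t{p!r}\n")
    return path


def read_vaccine_design(path) -> Tuple[VaccineDesign, Dict[str, str]]:
    """Inverse of :func:`write_vaccine_design`; returns (design, metadata)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"design file not found: {path}")
    meta: Dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for ln in lines:
        if ln.startswith("#"):
            key, _, val = ln[1:].strip().partition("\t")
            meta[key] = val
        else:
            body.append(ln)
    header, *rows = [ln.rstrip("\n") for ln in body if ln.strip()]
    if header.split("\t") != ["variant_id", "cost", "aggregate_p"]:
        raise SchemaError(f"unexpected design header in {path}: {header!r}")
    selected = frozenset(r.split("\t")[0] for r in rows)
    design = VaccineDesign(
        selected=selected,
        objective_value=float(meta["objective_value"]),
        objective=meta["objective"],  # type: ignore[arg-type]
        total_cost=float(meta["total_cost"]),
        solver_status=meta.get("solver_status", "optimal"),  # type: ignore[arg-type]
    )
    return design, meta


def write_response_matrix(matrix: ResponseMatrix, path) -> Path:
    """Persist an element x cell coefficient matrix as TSV + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(matrix.coefficients, index=matrix.elements,
                      columns=[f"cell_{j}" for j in range(matrix.num_cells)])
    df.index.name = "element"
    df.to_csv(path, sep="\t", float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"lambda": matrix.lambda_used, "floor": matrix.floor_used,
                   "num_cells": matrix.num_cells}, fh)
    return path


def read_response_matrix(path) -> ResponseMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    return ResponseMatrix(
        elements=[str(e) for e in df.index],
        num_cells=int(meta["num_cells"]),
        coefficients=np.minimum(df.to_numpy(dtype=float), 0.0),
        lambda_used=float(meta["lambda"]),
        floor_used=float(meta["floor"]),
    )


def write_population_tsv(population, path) -> Path:
    """One row per presented complex: cell_index, peptide, allele, multiplicity."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for cell in population.cells:
        for (pep, allele), m in sorted(cell.presented.items()):
            if m > 0:
                rows.append((cell.cell_index, pep, allele, m))
    pd.DataFrame(rows, columns=["cell_index", "peptide", "allele", "multiplicity"]
                 ).to_csv(path, sep="\t", index=False)
    return path


def load_peptide_fasta(path) -> Dict[str, List[str]]:
    """Read mutated peptide sequences, keyed by the variant_id prefix of the
    record id (``>variant|anything``)."""
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    out: Dict[str, List[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        vid = rec.id.split("|")[0]
        out.setdefault(vid, []).append(str(rec.seq).upper())
    return out


def check_peptide_provenance(patient: PatientInput, fasta_path) -> None:
    """Verify every scored minimal epitope occurs within one of its variant's
    mutated peptide sequences; raises listing the offenders otherwise."""
    seqs = load_peptide_fasta(fasta_path)
    bad = []
    for s in patient.scores:
        candidates = seqs.get(s.variant_id, [])
        if not any(s.peptide in seq for seq in candidates):
            bad.append((s.variant_id, s.peptide))
    if bad:
        offenders = sorted(set(bad))
        raise ReferentialIntegrityError(
            f"{len(offenders)} scored epitope(s) not found in the mutated "
            f"peptide FASTA, e.g. {offenders[0]}", offenders=offenders)


def load_config(path) -> dict:
    """Load the YAML run configuration (paths, binding_mode, sim/opt params)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"config {path} must be a YAML mapping")
    return cfg
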