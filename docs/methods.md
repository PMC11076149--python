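# Methods

## Model overview

`neovax` treats one patient's tumor as a population of stochastically
differing cells and asks which set of mutations, injected as vaccine
elements, maximizes the chance that every simulated cell is recognized. The
pipeline has three layers: a per-cell sampling cascade over the MHC class I
presentation pathway, a probabilistic response model that turns presented
epitope counts into log no-response coefficients, and exact integer
programming over those coefficients.

## The sampling cascade

Each cell is simulated independently through five stages.

1. **Mutation presence.** A variant is present in a cell with probability
   equal to its DNA variant allele frequency, `d_ALT / (d_ALT + d_REF)`. This
   uses bulk WES read counts as a proxy for the fraction of tumor cells
   carrying the mutation; it deliberately ignores clonal co-occurrence
   structure (each variant is sampled independently).
2. **Transcript and protein abundance.** Transcript counts follow a
   Gamma-Poisson distribution matched to the empirical per-gene mean and
   variance. We parameterize it as a negative binomial with
   `r = m²/(v − m)`, `p = m/v` whenever `v > m`; when `v ≤ m` the mixture is
   degenerate and we fall back to a Poisson with the given mean (a mean of 0
   yields 0 deterministically). Mutated protein copies are the transcript
   count scaled by the RNA VAF — protein abundance is assumed proportional to
   transcript abundance. The product is generally fractional; we round
   half-to-even to obtain an integer multinomial trial count without
   systematic inflation. Zero RNA coverage is interpreted as "no mutated
   transcript" (RNA VAF 0) and flagged with a warning at load time.
3. **Cleavage.** The protein copies of a variant are distributed over its
   8–11-mer minimal epitopes by a multinomial with probabilities proportional
   to predicted cleavage scores. An all-zero cleavage vector is an error, not
   a uniform fallback: silently substituting a uniform distribution would
   change the model. Copy counts are conserved exactly.
4. **MHC binding with competition.** Per HLA allele, the number of available
   MHC class I molecules is a Gamma-Poisson draw from the allele gene's
   expression moments (unitary VAF: HLA genes are not assumed mutated). The
   pooled cleavage products across all present variants compete for
   `n* = min(n_MHC, pool size)` binding slots, multinomially over the
   *distinct* pooled peptides. The weight of a peptide is a transform of its
   predicted binding value; since both supported conventions (IC50 nM, rank
   percentile) are "lower = stronger", the default transform is the
   reciprocal `w = 1/max(value, 10⁻³)`, which preserves the required
   monotonicity for both. The transform is pluggable. Each allele draws from
   the same pool independently, so the total bound copies across alleles may
   exceed a peptide's pooled copy number; this matches the layered
   multiset-union formulation of the model and keeps alleles exchangeable.
5. **Presentation.** Each distinct bound complex reaches the surface
   independently with probability equal to its predicted stability score
   normalized by the summed stability over the cell's distinct bound
   complexes (so a lone bound complex is presented with certainty, and the
   expected number of presented complexes per cell is 1). Presentation
   multiplicity is therefore 0/1 per (peptide, allele); a peptide's presented
   count in a cell, N, sums over alleles. If every bound complex has
   stability exactly 0 the normalizer vanishes and nothing is presented.

**Randomness.** One root seed governs everything. Each (replicate, cell)
pair gets its own `numpy` `SeedSequence` substream with the stage order fixed
inside the cell, so populations are bit-reproducible regardless of
evaluation order, any single cell can be re-simulated in isolation, and
replicates are statistically independent.

## Response model

Let N_jk be the presented multiplicity of epitope k in cell j, summed across
alleles (the model scores peptides, not complexes). The scale parameter λ is
set to the reciprocal of the maximum N_jk over all cells supplied, so exactly
one epitope–cell pair reaches a certain response and nothing saturates. An
epitope fails to elicit a response with probability
`max(0, 1 − λ N_jk)^DFS(k)`, where DFS maps a peptide to [0, 1] and stands
for distance-from-self: a crude hook for T-cell recognition likelihood. The
default DFS is identically 1 (no self-discount); it is pluggable, not
learned. An element fails only if all its epitopes fail, so its coefficient
is the DFS-weighted sum of log terms:

    p_ij = Σ_k DFS(k) · log max(0, 1 − λ N_jk)

Log-zero events are floored at a configurable −50 per term (and the sum at
the same floor) so the integer programs keep finite coefficients while a
"certain kill" still dominates: e^{−50} ≈ 2·10⁻²² is zero for every practical
purpose.

**λ scope.** λ is computed jointly across whatever populations are passed to
`build_response_matrix` in one call. Per-population scaling — what the
replicate-consensus analysis wants, since each replicate is optimized on its
own — is obtained by calling the builder once per population. One rule, no
flag.

## Optimization

All coefficients are ≤ 0, so the empty set is always feasible with objective
0 and any optimum is ≤ 0. Costs default to 1 per element (budget = element
count); length-weighted costs can be passed instead. Two objectives:

- **MinSum** minimizes `Σ_i (Σ_j p_ij) x_i` subject to `Σ k_i x_i ≤ b` — a
  knapsack over per-element aggregates.
- **MinMax** minimizes the worst cell via the standard surrogate variable:
  min z subject to `z ≥ Σ_i p_ij x_i` for every cell j, plus the budget.

Both are solved with HiGHS through `scipy.optimize.milp` at zero MIP gap.
HiGHS presolve is disabled: on models mixing binary selectors with the
continuous minimax surrogate it was observed to return sub-optimal solutions
labeled optimal, and the exhaustive oracle in the test suite catches exactly
this. At the problem sizes involved (tens of elements; the MinSum knapsack is
independent of M) presolve buys nothing.

**Tie-breaking.** Among equal-objective optima the solver returns the
lexicographically smallest sorted element-id tuple. This is enforced exactly,
by growing a prefix in id order with at most N auxiliary capped solves (an
epsilon-perturbation scheme was rejected: geometric weights underflow beyond
~40 elements). Determinism matters because replicate-consensus IoU is a
headline metric; solver-internal tie-breaking would contaminate it.

**A note on MinMax at scale.** In large populations some cells present no
epitope of any candidate (their coefficient column is all zeros), so the
most resistant cell has objective 0 under every selection and the MinMax
optimum is 0 with the empty set as its lexicographic representative. This is
a property of the model, not a solver artifact; MinSum is the objective of
practical interest on large populations.

## Evaluation

Per-cell response probability is `1 − exp(Σ_{i∈E} p_ij)`. The coverage curve
reports the fraction of cells at or above each threshold on a default grid
of 0 to 1 in steps of 0.05. Consensus across replicate designs is
intersection-over-union, either strict (`|∩|/|∪|`, the default) or mean
pairwise; it is undefined (None) when every design is empty. Recall against
validated mutations reports TP, FN and TP/(TP+FN); recall is 0.0 when
nothing validated was selected (0/k is well-defined) and undefined only when
there is nothing to validate. The ranking baseline reproduces standard
practice: rank (variant, peptide, allele) rows ascending by binding value,
filter at IC50 ≤ 500 nM or percentile ≤ 2.0, lift to variants by each
variant's best row, take the top N.

## Synthetic patients

The generator emulates the tabular output of an upstream pipeline with known
ground truth. Defaults describe a moderately heterogeneous tumor:

| parameter | default | rationale |
|---|---|---|
| variants / alleles | 50 / 2 | enough candidates to make selection non-trivial |
| planted immunogenic | 5 | clonal (VAF 0.5), upper-half expression, strong scores |
| decoy VAF | U(0.05, 0.2) | subclonal passengers |
| trap fraction | 30% of decoys | strong binding scores, ~0.2 FPKM expression |
| expression mean | U(1, 100) FPKM | variance = 4 × mean (over-dispersed) |
| HLA expression | U(50, 200) FPKM | class I genes are highly expressed |
| epitopes per variant | 4–12 | plausible count of 8–11-mers per 27-mer construct |
| strong / decoy percentile | U(0.05, 0.5) / U(5, 50) | clear but overlapping-in-rank profiles |
| WES / RNA depth | 200× / 80× | read counts drawn binomially at the true VAF |

The *trap* decoys are the crux of the baseline comparison: a pure
binding-rank baseline cannot distinguish them from planted variants, while
the simulation exposes that they are almost never presented. Dispersion ≤ 1
configs exercise the Poisson branch.

What the generator does **not** emulate: clonal co-occurrence structure,
allele-specific HLA expression, predictor-specific score biases and
correlations, multi-nucleotide or splice variants, and any linkage between
binding and stability beyond the shared profile. Passing tests therefore
demonstrate the correctness and calibration of the machinery on its own
modeling assumptions, not predictive performance on real tumors.

## Problem sizes and numerics

The test suite and the acceptance script run populations of 10–20,000 cells,
10 replicates, 10–30 variants and budgets of 5–10; sampling-distribution
checks use 3-standard-error bands (10% for variances), and exhaustive
ILP-vs-oracle checks use instances up to 12 elements × 6 cells. Floating
comparisons in the optimizer use a relative tolerance of 10⁻⁹; the
probability-space identity `exp(p_ij) = Π_k P(no response)` holds to 10⁻¹²
away from the floor. Degenerate inputs are errors, not silent defaults: an
all-zero cleavage vector, a simulation with no presented complex anywhere
(λ undefined), and a budget below the cheapest element (reported as an
infeasible design) all surface explicitly.

## Known limitations

- Independence assumptions everywhere: across cells, variants within a cell,
  and responses across elements and epitopes.
- The per-allele binding draws share the pool without depleting it;
  cross-allele copy conservation is not enforced.
- The response model is presentation-count based; DFS is a hook, and no
  immunogenicity model is fitted.
- MinMax degenerates on populations containing fully silent cells (see
  above).
- λ couples the response scale to the single most-presented epitope, so a
  single outlier cell rescales all coefficients; flooring bounds the effect.
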