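import math

import numpy as np
import pytest
from scipy import stats

from neovax import simulate
from neovax.errors import DegenerateModelError, ReferentialIntegrityError
from neovax.types import (
    EpitopeScore,
    GeneExpression,
    HlaAllele,
    PatientInput,
    SimulationParams,
    VariantRecord,
)


def variant(dna_alt, dna_ref, rna_alt=1, rna_ref=1, vid="v", gene="g"):
    return VariantRecord(vid, gene, dna_alt, dna_ref, rna_alt, rna_ref)


def allele(mean=50.0, var=200.0, name="HLA-A*02:01"):
    return HlaAllele(name, GeneExpression(name, mean, var))


class TestVariantPresence:
    def test_vaf_zero_never_present(self, rng):
        v = variant(0, 50)
        assert not any(simulate.sample_variant_presence(v, rng) for _ in range(200))

    def test_vaf_one_always_present(self, rng):
        v = variant(40, 0)
        assert all(simulate.sample_variant_presence(v, rng) for _ in range(200))

    def test_frequency_matches_vaf(self, rng):
        # p = 30/40 = 0.75; binomial sampling-distribution oracle at 3 SE
        v = variant(30, 10)
        n = 10_000
        hits = sum(simulate.sample_variant_presence(v, rng) for _ in range(n))
        se = math.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) < 3 * se


class TestGammaPoisson:
    def test_zero_mean_degenerate(self, rng):
        assert all(simulate.sample_gamma_poisson(0.0, 5.0, rng) == 0
                   for _ in range(50))

    def test_negative_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate.sample_gamma_poisson(-1.0, 1.0, rng)
        with pytest.raises(ValueError):
            simulate.sample_gamma_poisson(1.0, -1.0, rng)

    @pytest.mark.parametrize("mean,var", [(50.0, 200.0), (10.0, 5.0)])
    def test_moment_recovery(self, rng, mean, var):
        # overdispersed -> NB matched to (mean, var); var <= mean -> Poisson(mean)
        draws = np.array([simulate.sample_gamma_poisson(mean, var, rng)
                          for _ in range(50_000)])
        target_var = var if var > mean else mean
        se_mean = math.sqrt(target_var / draws.size)
        assert abs(draws.mean() - mean) < 3 * se_mean
        assert abs(draws.var() - target_var) < 0.1 * target_var


class TestProteinCount:
    @pytest.mark.parametrize("transcripts,alt,ref,expected", [
        (100, 25, 75, 25),
        (0, 25, 75, 0),
        (7, 1, 1, 4),    # 3.5 rounds half-to-even to 4
        (5, 1, 1, 2),    # 2.5 rounds half-to-even to 2
        (100, 0, 0, 0),  # no RNA evidence -> no mutated protein
    ])
    def test_rna_vaf_scaling(self, transcripts, alt, ref, expected):
        v = VariantRecord("v", "g", 1, 1, alt, ref)
        assert simulate.compute_variant_protein_count(transcripts, v) == expected


class TestCleavage:
    def test_zero_proteins_empty_multiset(self, rng):
        assert simulate.sample_cleavage(0, ["ACDEFGHI"], [0.4], rng) == {}

    def test_single_category_gets_all_trials(self, rng):
        out = simulate.sample_cleavage(17, ["ACDEFGHI"], [0.01], rng)
        assert out == {"ACDEFGHI": 17}

    def test_conservation_and_proportions(self, rng):
        n = 40_000
        out = simulate.sample_cleavage(n, ["AAAAAAAA", "CCCCCCCC"], [1.0, 3.0], rng)
        assert sum(out.values()) == n
        frac = out["CCCCCCCC"] / n
        se = math.sqrt(0.75 * 0.25 / n)
        assert abs(frac - 0.75) < 3 * se

    def test_all_zero_cleavage_vector_is_degenerate(self, rng):
        with pytest.raises(DegenerateModelError):
            simulate.sample_cleavage(5, ["AAAAAAAA"], [0.0], rng)


class TestBinding:
    def test_empty_pool_or_no_mhc(self, rng):
        a = allele()
        assert simulate.sample_binding({}, a, 100, {}, "percentile", rng) == {}
        assert simulate.sample_binding({"ACDEFGHI": 5}, a, 0,
                                       {"ACDEFGHI": 1.0}, "percentile", rng) == {}

    def test_bound_count_capped_by_pool_and_mhc(self, rng):
        a = allele()
        pool = {"AAAAAAAA": 3, "CCCCCCCC": 4}
        scores = {"AAAAAAAA": 1.0, "CCCCCCCC": 1.0}
        for n_mhc, expected in [(5, 5), (100, 7)]:
            out = simulate.sample_binding(pool, a, n_mhc, scores, "percentile", rng)
            assert sum(out.values()) == expected

    def test_symmetric_propensities_split_evenly(self, rng):
        a = allele()
        pool = {"AAAAAAAA": 20_000, "CCCCCCCC": 20_000}
        scores = {"AAAAAAAA": 2.0, "CCCCCCCC": 2.0}
        out = simulate.sample_binding(pool, a, 10_000, scores, "percentile", rng)
        se = math.sqrt(10_000 * 0.25)
        assert abs(out[("AAAAAAAA", a.allele_name)] - 5000) < 3 * se

    def test_missing_score_names_peptide(self, rng):
        with pytest.raises(ReferentialIntegrityError, match="CCCCCCCC"):
            simulate.sample_binding({"CCCCCCCC": 1}, allele(), 5, {},
                                    "percentile", rng)


class TestPresentation:
    def test_single_complex_always_presented(self, rng):
        key = ("ACDEFGHI", "HLA-A*02:01")
        for _ in range(100):
            assert simulate.sample_presentation({key: 3}, {key: 0.2}, rng) == {key: 1}

    def test_zero_stability_never_presented(self, rng):
        k0 = ("AAAAAAAA", "a")
        k1 = ("CCCCCCCC", "a")
        for _ in range(100):
            out = simulate.sample_presentation({k0: 1, k1: 1},
                                               {k0: 0.0, k1: 0.7}, rng)
            assert k0 not in out

    def test_retention_frequencies_follow_normalized_stability(self, rng):
        k0 = ("AAAAAAAA", "a")
        k1 = ("CCCCCCCC", "a")
        n = 20_000
        hits = np.zeros(2)
        for _ in range(n):
            out = simulate.sample_presentation({k0: 1, k1: 1},
                                               {k0: 1.0, k1: 3.0}, rng)
            hits += [k0 in out, k1 in out]
        for freq, p in zip(hits / n, (0.25, 0.75)):
            assert abs(freq - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_all_zero_stability_presents_nothing(self, rng):
        k0 = ("AAAAAAAA", "a")
        assert simulate.sample_presentation({k0: 2}, {k0: 0.0}, rng) == {}


def single_variant_patient(dna=(40, 0), rna=(1, 1), mean=200.0, var=400.0,
                           peptides=("ACDEFGHI",), percentiles=(1.0,),
                           cleavages=None, stabilities=None, n_alleles=1,
                           allele_mean=100.0):
    cleavages = cleavages or [0.9] * len(peptides)
    stabilities = stabilities or [0.5] * len(peptides)
    alleles = [HlaAllele(f"HLA-A*{i+1:02d}:01",
                         GeneExpression(f"HLA-A*{i+1:02d}:01", allele_mean,
                                        2 * allele_mean))
               for i in range(n_alleles)]
    scores = [EpitopeScore("v1", p, a.allele_name, c, b, s)
              for a in alleles
              for p, c, b, s in zip(peptides, cleavages, percentiles, stabilities)]
    return PatientInput(
        variants=[VariantRecord("v1", "g1", dna[0], dna[1], rna[0], rna[1])],
        expression={"g1": GeneExpression("g1", mean, var)},
        alleles=alleles, scores=scores, binding_mode="percentile")


class TestSimulateCell:
    def test_absent_variants_give_empty_surface(self, rng):
        patient = single_variant_patient(dna=(0, 50))
        for j in range(50):
            cell = simulate.simulate_cell(patient, j, rng)
            assert cell.present_variants == frozenset()
            assert cell.presented == {}

    def test_zero_expression_gives_empty_surface(self, rng):
        patient = single_variant_patient(mean=0.0, var=0.0)
        for j in range(50):
            assert simulate.simulate_cell(patient, j, rng).presented == {}

    def test_surface_support_restricted_to_patient_scores(self, rng):
        patient = single_variant_patient()
        seen = set()
        for j in range(200):
            cell = simulate.simulate_cell(patient, j, rng)
            seen |= set(cell.presented)
        assert seen == {("ACDEFGHI", "HLA-A*01:01")}

    def test_trace_records_conservation(self, rng):
        patient = single_variant_patient(peptides=("ACDEFGHI", "KLMNPQRS"),
                                         percentiles=(1.0, 3.0))
        for j in range(100):
            trace = {}
            cell = simulate.simulate_cell(patient, j, rng, trace=trace)
            for vid, n_prot in trace["protein_counts"].items():
                assert sum(trace["cleaved"][vid].values()) == n_prot
            pool_size = sum(trace["pool"].values())
            for a, n_mhc in trace["mhc_counts"].items():
                bound_a = sum(m for (p, al), m in trace["bound"].items() if al == a)
                assert bound_a == min(n_mhc, pool_size)
            assert set(cell.presented) <= set(trace["bound"])


class TestSimulatePopulation:
    def test_population_size_and_determinism(self, tiny_patient):
        params = SimulationParams(population_size=200, num_replicates=1, seed=11)
        pop1 = simulate.simulate_population(tiny_patient, params)
        pop2 = simulate.simulate_population(tiny_patient, params)
        assert len(pop1) == 200
        for c1, c2 in zip(pop1.cells, pop2.cells):
            assert c1.present_variants == c2.present_variants
            assert c1.presented == c2.presented

    def test_replicates_differ_but_are_reproducible(self, tiny_patient):
        params = SimulationParams(population_size=100, num_replicates=2, seed=5)
        pops = simulate.simulate_replicates(tiny_patient, params)
        assert [p.replicate_index for p in pops] == [0, 1]
        assert any(a.presented != b.presented
                   for a, b in zip(pops[0].cells, pops[1].cells))

    def test_marginal_presence_recovers_dna_vaf(self, tiny_patient):
        m = 4000
        pop = simulate.simulate_population(
            tiny_patient, SimulationParams(population_size=m, seed=21))
        for v in tiny_patient.variants:
            freq = sum(v.variant_id in c.present_variants for c in pop.cells) / m
            se = math.sqrt(max(v.dna_vaf * (1 - v.dna_vaf), 1e-9) / m)
            assert abs(freq - v.dna_vaf) < 3 * se, v.variant_id

    def test_replicates_statistically_independent(self):
        # chi-square on variant-presence co-occurrence across replicate pairs
        patient = single_variant_patient(dna=(50, 50))
        params = SimulationParams(population_size=2000, num_replicates=2, seed=9)
        pops = simulate.simulate_replicates(patient, params)
        x = np.array(["v1" in c.present_variants for c in pops[0].cells])
        y = np.array(["v1" in c.present_variants for c in pops[1].cells])
        table = np.array([[(x & y).sum(), (x & ~y).sum()],
                          [(~x & y).sum(), (~x & ~y).sum()]])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_stronger_binder_presented_more_often(self):
        # equal cleavage/stability, binding propensities 1:9 (percentiles 9:1)
        # under MHC scarcity -> the strong binder dominates the surface
        patient = single_variant_patient(
            peptides=("AAAAAAAA", "CCCCCCCC"), percentiles=(9.0, 1.0),
            cleavages=[0.5, 0.5], stabilities=[0.5, 0.5],
            mean=100.0, var=200.0, allele_mean=5.0)
        pop = simulate.simulate_population(
            patient, SimulationParams(population_size=5000, seed=2))
        weak = np.array([c.presented.get(("AAAAAAAA", "HLA-A*01:01"), 0)
                         for c in pop.cells])
        strong = np.array([c.presented.get(("CCCCCCCC", "HLA-A*01:01"), 0)
                           for c in pop.cells])
        res = stats.ttest_rel(strong, weak, alternative="greater")
        assert res.pvalue < 0.01
        assert strong.mean() > weak.mean()
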