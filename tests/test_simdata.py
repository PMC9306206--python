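"""Synthetic-data generator: engine statistics, dataset shaping, round trips."""

import numpy as np
import pandas as pd
import pytest

from trigene.datatypes import GenotypeMatrix, PopulationMap
from trigene.demography import (
    DemographyModel,
    MigrationWindow,
    SizeEpoch,
    Split,
    star_tree_model,
    two_population_model,
    yunnan_model,
)
from trigene import io as tio
from trigene.popdiff import nucleotide_diversity, wc_fst
from trigene.simdata import (
    add_missingness,
    attach_depth,
    default_popmap,
    emit_dataset,
    genes_from_regions,
    inject_differentiation,
    make_exome_structure,
    simulate_neutral,
)


import functools


@functools.lru_cache(maxsize=1)
def _constant_sim_shared():
    """One 300-region constant-size run shared by the sampling-theory checks."""
    g = simulate_neutral(constant_model(n=200, mu=2e-6), {"P": 10},
                         region_lengths=[20_000] * 300, seed=5, burnin=300)
    return g


def constant_model(n=200, mu=2e-6, rescale=1.0):
    m = DemographyModel(
        populations=["P"], sizes={"P": [SizeEpoch(0, n)]},
        mutation_rate=mu, recombination_rate=0.0, rescale_factor=rescale,
    )
    m.validate()
    return m


class TestEngineContracts:
    def test_zero_mutation_rate_gives_no_variants(self):
        g = simulate_neutral(constant_model(n=100, mu=0.0), {"P": 5},
                             region_length=10_000, seed=1, burnin=20)
        assert g.n_variants == 0

    def test_same_seed_same_model_identical_output(self):
        kw = dict(region_lengths=[5000] * 10, seed=42, burnin=60)
        m = two_population_model(n_anc=100, n_a=100, n_b=100, split_time=30,
                                 mutation_rate=2e-6, rescale_factor=1.0)
        a = simulate_neutral(m, {"A": 6, "B": 6}, **kw)
        b = simulate_neutral(m, {"A": 6, "B": 6}, **kw)
        assert a.equals(b)

    def test_inconsistent_model_rejected(self):
        with pytest.raises(ValueError, match="root"):
            DemographyModel(
                populations=["A", "B"],
                sizes={"A": [SizeEpoch(0, 10)], "B": [SizeEpoch(0, 10)]},
            ).root()

    def test_output_is_valid_and_sorted(self):
        m = constant_model()
        g = simulate_neutral(m, {"P": 8}, region_lengths=[4000] * 5, seed=3, burnin=50)
        g.validate()
        # ancestral allele is REF for simulated data
        assert (g.variants["aa"] == g.variants["ref"]).all()

    def test_watterson_segregating_sites(self):
        """Mean S per region within 3 SE of theta * sum 1/i over 300 regions."""
        n_dip, n_e, mu, L = 10, 200, 2e-6, 20_000
        g = _constant_sim_shared()
        counts = np.zeros(300)
        per = g.variants.groupby("chrom").size()
        for chrom, k in per.items():
            counts[int(chrom) - 1] = k
        expected = 4 * n_e * mu * L * sum(1 / i for i in range(1, 2 * n_dip))
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_pairwise_diversity_matches_theta(self):
        """pi per bp within 3 SE of 4*Ne*mu across 300 replicate regions."""
        n_e, mu, L = 200, 2e-6, 20_000
        g = _constant_sim_shared()
        ac, an = g.allele_counts()
        p = ac / an
        per_site = 2 * p * (1 - p) * an / (an - 1)
        pi_bp = np.zeros(300)
        chrom = g.variants["chrom"].to_numpy().astype(int)
        for r in range(300):
            pi_bp[r] = per_site[chrom == r + 1].sum() / L
        expected = 4 * n_e * mu
        se = pi_bp.std(ddof=1) / np.sqrt(len(pi_bp))
        assert abs(pi_bp.mean() - expected) < 3 * se

    def test_diversity_agrees_with_msprime_oracle(self):
        """The internal engine and an msprime coalescent run of the same
        constant-size model give compatible mean diversity."""
        msprime = pytest.importorskip("msprime")
        n_e, mu, L, reps = 150, 2e-6, 10_000, 120
        g = simulate_neutral(constant_model(n=n_e, mu=mu), {"P": 8},
                             region_lengths=[L] * reps, seed=7, burnin=300)
        ac, an = g.allele_counts()
        pi_engine = (2 * (ac / an) * (1 - ac / an) * an / (an - 1)).sum() / (reps * L)
        pis = []
        for i in range(reps):
            ts = msprime.sim_ancestry(samples=8, population_size=n_e,
                                      sequence_length=L, random_seed=1000 + i)
            ts = msprime.sim_mutations(ts, rate=mu, random_seed=2000 + i)
            pis.append(ts.diversity())
        pi_ms = float(np.mean(pis))
        se = np.std(pis, ddof=1) / np.sqrt(reps)
        assert abs(pi_engine - pi_ms) < 4 * se

    def test_fst_monotone_in_split_time(self):
        """Aggregate WC FST rises with split time across a 3-point grid."""
        values = []
        for tau in (20, 100, 200):
            m = two_population_model(n_anc=200, n_a=200, n_b=200, split_time=tau,
                                     mutation_rate=2e-6, rescale_factor=1.0)
            g = simulate_neutral(m, {"A": 12, "B": 12},
                                 region_lengths=[10_000] * 80, seed=8, burnin=120)
            _, fst = wc_fst(g, default_popmap({"A": 12, "B": 12}), "A", "B")
            values.append(fst)
        assert values[0] < values[1] < values[2]

    def test_migration_limit_recovers_no_migration_fst(self):
        """m -> 0 gives the no-migration FST within sampling error, while
        strong migration pulls FST well below it."""
        def fst_at(mig, seed):
            m = two_population_model(n_anc=150, n_a=150, n_b=150, split_time=150,
                                     migration=mig, mutation_rate=2e-6,
                                     rescale_factor=1.0)
            g = simulate_neutral(m, {"A": 12, "B": 12},
                                 region_lengths=[10_000] * 60, seed=seed, burnin=100)
            return wc_fst(g, default_popmap({"A": 12, "B": 12}), "A", "B")[1]

        f0 = fst_at(0.0, 9)
        f_tiny = fst_at(1e-6, 10)
        f_big = fst_at(0.02, 11)
        assert abs(f_tiny - f0) < 0.3 * f0
        assert f_big < 0.5 * f0

    def test_earliest_diverged_pair_has_largest_fst(self):
        """Serial splits: FST(root-pair) largest in >=95% of 100 replicates."""
        m = star_tree_model(["A", "B", "C"], [120, 30], n=100,
                            mutation_rate=3e-6, rescale_factor=1.0)
        ns = {"A": 10, "B": 10, "C": 10}
        g = simulate_neutral(m, ns, region_lengths=[8000] * (100 * 6),
                             seed=12, burnin=80)
        pm = default_popmap(ns)
        chrom = g.variants["chrom"].to_numpy().astype(int)
        rep = (chrom - 1) // 6
        wins = 0
        for r in range(100):
            sub = g.take_sites(rep == r)
            f_ab = wc_fst(sub, pm, "A", "B")[1]
            f_ac = wc_fst(sub, pm, "A", "C")[1]
            f_bc = wc_fst(sub, pm, "B", "C")[1]
            # B split earliest from the (A,C) lineage
            if f_ab >= f_ac and f_bc >= f_ac:
                wins += 1
        assert wins >= 95

    def test_rescaling_preserves_scaled_diversity(self):
        """theta is invariant under the rescale factor (sizes down, rates up)."""
        pi = {}
        for q in (1.0, 4.0):
            m = DemographyModel(
                populations=["P"], sizes={"P": [SizeEpoch(0, 400)]},
                mutation_rate=5e-7, recombination_rate=0.0, rescale_factor=q,
            )
            m.validate()
            g = simulate_neutral(m, {"P": 10}, region_lengths=[15_000] * 100,
                                 seed=13, burnin=int(500 / q))
            ac, an = g.allele_counts()
            pi[q] = (2 * (ac / an) * (1 - ac / an) * an / (an - 1)).sum()
        assert abs(pi[4.0] - pi[1.0]) / pi[1.0] < 0.2


class TestInjection:
    def test_saturating_shift_fixes_target_genotypes(self, two_pop_dataset):
        geno, pm = two_pop_dataset
        freq = geno.alt_freq()
        loci = np.flatnonzero((freq > 0.05) & (freq < 0.95))[:5]
        out = inject_differentiation(geno, pm, "A", loci, shift=1.0, seed=1)
        cols = pm.indices(geno, "A")
        assert (out.genotypes[np.ix_(loci, cols)] == 2).all()

    def test_zero_shift_is_identity(self, two_pop_dataset):
        geno, pm = two_pop_dataset
        out = inject_differentiation(geno, pm, "A", [0, 1, 2], shift=0.0, seed=1)
        assert out.equals(geno)

    def test_missing_population_named_in_error(self, two_pop_dataset):
        geno, pm = two_pop_dataset
        with pytest.raises(ValueError, match="NOPE"):
            inject_differentiation(geno, pm, "NOPE", [0], shift=0.5)

    def test_injected_loci_exceed_background_fst(self, two_pop_dataset):
        geno, pm = two_pop_dataset
        freq = geno.alt_freq()
        loci = np.flatnonzero((freq > 0.1) & (freq < 0.9))[:50]
        out = inject_differentiation(geno, pm, "A", loci, shift=0.5, seed=2)
        from trigene.popdiff import wc_site_components

        comps = wc_site_components(out, pm.indices(out, "A"), pm.indices(out, "B"))
        with np.errstate(invalid="ignore"):
            per_site = np.where(comps.d != 0, comps.a / comps.d, 0.0)
        others = np.setdiff1d(np.flatnonzero(comps.usable), loci)
        assert per_site[loci].mean() > per_site[others].mean() + 0.1


class TestExomeStructure:
    def test_single_gene(self):
        genes = make_exome_structure(1, 10, seed=1)
        assert len(genes) == 1

    def test_sampler_support_enforced(self):
        with pytest.raises(ValueError, match="1..100"):
            make_exome_structure(5, lambda rng, n: np.full(n, 150), seed=1)

    def test_constant_sampler_realises_counts_on_matrix(self, two_pop_dataset):
        geno, _ = two_pop_dataset
        genes = make_exome_structure(20, 10, seed=2, geno=geno)
        counts = genes.snp_counts(geno)
        assert (counts == 10).all()

    def test_uniform_sampler_mean_near_midpoint(self):
        draws = []

        def sampler(rng, n):
            out = rng.integers(1, 101, size=n)
            draws.append(out)
            return out

        make_exome_structure(400, sampler, seed=3)
        x = np.concatenate(draws)
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert abs(x.mean() - 50.5) < 3 * se

    def test_intervals_non_overlapping(self):
        genes = make_exome_structure(50, 5, seed=4)
        r = genes.records.sort_values(["chrom", "start"])
        assert (r["start"].to_numpy()[1:] >= r["end"].to_numpy()[:-1]).all()


class TestDatasetEmission:
    def test_round_trip_through_files(self, tmp_path, two_pop_dataset):
        geno, pm = two_pop_dataset
        geno = attach_depth(geno, seed=3)
        genes = genes_from_regions(geno)
        paths = emit_dataset(geno, pm, genes, tmp_path)
        back = tio.read_vcf(paths["vcf"])
        back = tio.attach_genetic_map(back, tio.read_plink_map(paths["map"]))
        assert back.equals(geno)
        assert tio.read_popmap(paths["popmap"]).assignments == pm.assignments
        bed = tio.read_bed(paths["bed"])
        assert len(bed) == len(genes)
        assert bed.records["gene_id"].tolist() == genes.records["gene_id"].tolist()

    def test_vcf_parses_with_standard_parser(self, tmp_path, two_pop_dataset):
        from cyvcf2 import VCF

        geno, pm = two_pop_dataset
        paths = emit_dataset(geno, pm, None, tmp_path)
        records = list(VCF(paths["vcf"]))
        assert len(records) == geno.n_variants

    def test_missingness_injection_rate(self, two_pop_dataset, rng):
        geno, _ = two_pop_dataset
        out = add_missingness(geno, rate=0.2, seed=4)
        frac = (out.genotypes == -1).mean()
        assert 0.1 < frac < 0.3
        # original untouched
        assert (geno.genotypes != -1).all()


class TestDemographyModel:
    def test_yunnan_preset_validates_and_rescales(self):
        m = yunnan_model(rescale_factor=50.0)
        r = m.rescaled()
        assert max(e.n for eps in r.sizes.values() for e in eps) <= 1000
        assert r.root() == "TBN"

    def test_split_order_violation_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            DemographyModel(
                populations=["A", "B", "C"],
                sizes={p: [SizeEpoch(0, 10)] for p in "ABC"},
                splits=[Split(10, "B", "A"), Split(20, "C", "B")],
            ).validate()

    def test_migration_row_sum_checked(self):
        with pytest.raises(ValueError, match="sums"):
            DemographyModel(
                populations=["A", "B"],
                sizes={p: [SizeEpoch(0, 10)] for p in "AB"},
                splits=[Split(5, "B", "A")],
                migrations=[
                    MigrationWindow("A", "B", 0.6, 5),
                    MigrationWindow("A", "B", 0.5, 5),
                ],
            ).validate()
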