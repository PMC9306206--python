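"""PBS statistic, SNP-count binned null store and scan logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_matrix
from oracles import brute_pbs

from trigene.datatypes import GeneIntervals, GenotypeMatrix, PopulationMap
from trigene.selection import (
    NullStore,
    PBSRecord,
    bin_key,
    build_null,
    divergent_scan,
    gene_pbs_scan,
    major_variants,
    pbs_pvalues,
    pbs_value,
    shared_signals,
    site_filter_pbs,
    strong_gene_intersection,
)
from trigene.popdiff import wc_fst
from trigene.simdata import default_popmap


def _triple_matrix(rng, n_sites=60, n=8):
    pops = ("TGT", "HAN", "CEU")
    cols = []
    for _ in pops:
        p = rng.beta(0.8, 0.8, size=n_sites)
        cols.append(rng.binomial(2, p[:, None], size=(n_sites, n)))
    g = np.concatenate(cols, axis=1).astype(np.int8)
    samples = [f"{pop}_{j}" for pop in pops for j in range(n)]
    geno = make_matrix(g, samples=samples)
    pm = PopulationMap({s: s.split("_")[0] for s in samples})
    return geno, pm, pops


class TestPbsValue:
    def test_zero_triple_is_zero(self):
        assert pbs_value(0.0, 0.0, 0.0) == 0.0

    def test_symmetric_tenth(self):
        # (-ln 0.9)/2, evaluated independently
        assert pbs_value(0.1, 0.1, 0.1) == pytest.approx(0.05268025782891314, abs=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            pbs_value(float("nan"), 0.1, 0.1)

    def test_negative_fst_clamped_to_zero_branch(self):
        assert pbs_value(-0.5, -0.5, -0.5) == 0.0

    @given(
        st.floats(-0.5, 0.999), st.floats(-0.5, 0.999), st.floats(-0.5, 0.999)
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_branch_additivity_identity(self, f_ab, f_ac, f_bc):
        """PBS_A + PBS_B == T_AB for every FST triple (machine precision)."""
        t_ab = -np.log1p(-np.clip(f_ab, 0, 1 - 1e-8))
        pbs_a = pbs_value(f_ab, f_ac, f_bc)
        pbs_b = pbs_value(f_ab, f_bc, f_ac)
        assert pbs_a + pbs_b == pytest.approx(t_ab, abs=1e-12)

    @given(st.floats(0, 0.99), st.floats(0, 0.99), st.floats(0, 0.99))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_bruteforce_transcription(self, a, b, c):
        assert pbs_value(a, b, c) == pytest.approx(brute_pbs(a, b, c), abs=1e-12)

    def test_monotone_in_target_branches(self):
        base = pbs_value(0.1, 0.1, 0.1)
        assert pbs_value(0.2, 0.1, 0.1) > base
        assert pbs_value(0.1, 0.2, 0.1) > base
        assert pbs_value(0.1, 0.1, 0.2) < base


class TestSiteFilter:
    def test_clean_sites_pass_unchanged(self, rng):
        g = make_matrix(rng.integers(0, 3, size=(10, 6)), depth=100.0)
        out = site_filter_pbs(g)
        assert out.n_variants == 10

    def test_depth_threshold_counts(self, rng):
        depth = np.full(10, 100.0)
        depth[:3] = 40.0
        g = make_matrix(rng.integers(0, 3, size=(10, 6)), depth=depth)
        out = site_filter_pbs(g, min_depth=50)
        assert out.n_variants == 7

    def test_missingness_threshold(self, rng):
        geno = make_matrix(rng.integers(0, 3, size=(4, 20)), depth=100.0)
        geno.genotypes[0, :2] = -1  # 10% missing > 5%
        out = site_filter_pbs(geno)
        assert out.n_variants == 3

    def test_depth_filter_without_depth_field_errors(self, rng):
        g = make_matrix(rng.integers(0, 3, size=(4, 4)))
        with pytest.raises(ValueError, match="depth"):
            site_filter_pbs(g, min_depth=50)


class TestBins:
    def test_single_counts_below_seventy(self):
        assert bin_key(1) == 1
        assert bin_key(69) == 69

    def test_five_wide_bins_from_seventy(self):
        assert bin_key(70) == bin_key(74)
        assert bin_key(69) != bin_key(70)
        assert bin_key(75) == bin_key(79) != bin_key(74)
        assert bin_key(96) == bin_key(100)

    def test_out_of_range_rejected(self):
        for c in (0, 101):
            with pytest.raises(ValueError):
                bin_key(c)


class TestNullStore:
    def _store(self, values, n_sim=None):
        values = np.asarray(values, dtype=float)
        return NullStore(
            bins={5: values}, n_sim=n_sim or len(values),
            triple=("A", "B", "C"), model_id="m", seed=0,
        )

    def test_pseudocount_floor(self):
        store = self._store(np.linspace(0, 1, 999))
        assert store.p_value(5, 2.0) == pytest.approx(1 / 1000)

    def test_below_all_simulations_gives_one(self):
        store = self._store(np.linspace(0.1, 1, 999))
        assert store.p_value(5, -5.0) == pytest.approx(1.0)

    def test_median_observation_near_half(self):
        store = self._store(np.linspace(0, 1, 1001))
        assert store.p_value(5, 0.5) == pytest.approx(0.5, abs=2e-3)

    def test_missing_bin_names_gene(self):
        store = self._store(np.linspace(0, 1, 200))
        records = pd.DataFrame(
            [{"gene_id": "geneX", "n_snps": 9, "pbs": 0.1}]
        )
        with pytest.raises(KeyError, match="geneX"):
            pbs_pvalues(records, store)

    def test_wrong_bin_size_rejected(self):
        with pytest.raises(ValueError, match="n_sim"):
            NullStore(bins={1: np.zeros(5), 2: np.zeros(6)}, n_sim=5,
                      triple=("A", "B", "C"), model_id="m", seed=0)

    def test_json_round_trip(self, tmp_path):
        store = self._store(np.sort(np.random.default_rng(1).normal(size=300)))
        path = tmp_path / "null.json"
        store.to_json(path)
        back = NullStore.from_json(path)
        assert back.n_sim == store.n_sim
        assert np.allclose(back.bins[5], store.bins[5])


class TestGeneScan:
    def test_single_snp_gene_equals_per_snp_pbs(self, rng):
        geno, pm, triple = _triple_matrix(rng, n_sites=12)
        genes = GeneIntervals(pd.DataFrame(
            [{"gene_id": "g1", "chrom": "1",
              "start": int(geno.variants["pos"][3] - 1),
              "end": int(geno.variants["pos"][3])}]
        ))
        table = gene_pbs_scan(geno, pm, genes, triple)
        assert len(table) == 1 and table.iloc[0]["n_snps"] == 1
        sub = geno.take_sites(np.array([3]))
        f_ab = wc_fst(sub, pm, "TGT", "HAN")[1]
        f_ac = wc_fst(sub, pm, "TGT", "CEU")[1]
        f_bc = wc_fst(sub, pm, "HAN", "CEU")[1]
        assert table.iloc[0]["pbs"] == pytest.approx(
            pbs_value(f_ab, f_ac, f_bc), abs=1e-14
        )

    def test_gene_aggregate_is_ratio_of_averages(self, rng):
        geno, pm, triple = _triple_matrix(rng, n_sites=30)
        pos = geno.variants["pos"]
        genes = GeneIntervals(pd.DataFrame(
            [{"gene_id": "g1", "chrom": "1", "start": 0, "end": int(pos.iloc[-1])}]
        ))
        table = gene_pbs_scan(geno, pm, genes, triple)
        f_ab = wc_fst(geno, pm, "TGT", "HAN")[1]
        assert table.iloc[0]["fst_ab"] == pytest.approx(f_ab, abs=1e-12)

    def test_monomorphic_gene_omitted(self):
        g = np.zeros((5, 9), dtype=np.int8)
        g[4, :] = [0, 1, 2, 0, 1, 2, 0, 1, 2]
        samples = [f"{p}_{j}" for p in ("TGT", "HAN", "CEU") for j in range(3)]
        geno = make_matrix(g, samples=samples)
        pm = PopulationMap({s: s.split("_")[0] for s in samples})
        pos = geno.variants["pos"]
        genes = GeneIntervals(pd.DataFrame(
            [
                {"gene_id": "mono", "chrom": "1", "start": 0, "end": int(pos.iloc[3])},
                {"gene_id": "poly", "chrom": "1", "start": int(pos.iloc[3]),
                 "end": int(pos.iloc[4])},
            ]
        ))
        table = gene_pbs_scan(geno, pm, genes, ("TGT", "HAN", "CEU"))
        assert table["gene_id"].tolist() == ["poly"]

    def test_missing_population_errors(self, rng):
        geno, pm, _ = _triple_matrix(rng)
        genes = GeneIntervals(pd.DataFrame(
            [{"gene_id": "g", "chrom": "1", "start": 0, "end": 10_000_000}]
        ))
        with pytest.raises(KeyError, match="YRI"):
            gene_pbs_scan(geno, pm, genes, ("TGT", "HAN", "YRI"))


class TestScanLogic:
    def _tables(self, spec):
        """spec: {pop: {gene: p}} -> tables covering the same gene universe."""
        genes = sorted({g for d in spec.values() for g in d})
        out = {}
        for pop, d in spec.items():
            out[pop] = pd.DataFrame(
                [{"gene_id": g, "n_snps": 5, "pbs": 0.1, "p_value": d.get(g, 0.9)}
                 for g in genes]
            )
        return out

    def test_shared_rule_two_of_four(self):
        tables = self._tables({
            "P1": {"g1": 0.005, "g2": 0.5},
            "P2": {"g1": 0.009, "g2": 0.005},
            "P3": {"g1": 0.5, "g2": 0.5},
            "P4": {"g1": 0.5, "g2": 0.5},
        })
        res = shared_signals(tables)
        assert res["shared"] == {"g1"}
        assert res["all_populations"] == set()

    def test_venn_counts_match_enumeration(self):
        spec = {
            "P1": {"a": 0.001, "b": 0.001, "c": 0.001, "d": 0.5},
            "P2": {"a": 0.001, "b": 0.001, "c": 0.5, "d": 0.001},
            "P3": {"a": 0.001, "b": 0.5, "c": 0.5, "d": 0.5},
            "P4": {"a": 0.001, "b": 0.5, "c": 0.5, "d": 0.5},
        }
        res = shared_signals(self._tables(spec))
        counts = {g: len(p) for g, p in res["per_gene_populations"].items()}
        assert counts == {"a": 4, "b": 2, "c": 1, "d": 1}
        assert res["shared"] == {"a", "b"}
        assert res["all_populations"] == {"a"}

    def test_strong_intersection_strict_all_three(self):
        def t(ps):
            return pd.DataFrame(
                [{"gene_id": g, "p_value": p} for g, p in ps.items()]
            )

        tables = [
            t({"g1": 0.04, "g2": 0.04}),
            t({"g1": 0.04, "g2": 0.01}),
            t({"g1": 0.06, "g2": 0.03}),
        ]
        assert strong_gene_intersection(tables) == {"g2"}
        assert strong_gene_intersection([]) == set()

    def test_major_variants_threshold_strict(self, rng):
        # TGT fixed-different at site 0; equal frequencies at site 1
        g = np.zeros((2, 9), dtype=np.int8)
        g[0, 0:3] = 2  # TGT homozygous alt, HAN/CEU ref
        g[1, :] = [0, 1, 2] * 3
        samples = [f"{p}_{j}" for p in ("TGT", "HAN", "CEU") for j in range(3)]
        geno = make_matrix(g, samples=samples)
        pm = PopulationMap({s: s.split("_")[0] for s in samples})
        pos = geno.variants["pos"]
        genes = GeneIntervals(pd.DataFrame(
            [{"gene_id": "g1", "chrom": "1", "start": 0, "end": int(pos.iloc[-1])}]
        ))
        table = major_variants(geno, pm, genes, ["g1"], ("TGT", "HAN", "CEU"))
        assert table["pos"].tolist() == [int(pos.iloc[0])]
        assert table.iloc[0]["freq_TGT"] == 1.0
        assert (table["pbs"] > 0.1).all()


class TestDivergentScan:
    def _five_pop(self, rng, n_sites=80, n=8):
        pops = ("TGT", "P2", "P3", "P4", "HAN")
        cols = []
        for _ in pops:
            p = rng.beta(0.8, 0.8, size=n_sites)
            cols.append(rng.binomial(2, p[:, None], size=(n_sites, n)))
        g = np.concatenate(cols, axis=1).astype(np.int8)
        samples = [f"{pop}_{j}" for pop in pops for j in range(n)]
        geno = make_matrix(g, samples=samples)
        pm = PopulationMap({s: s.split("_")[0] for s in samples})
        pos = geno.variants["pos"]
        bounds = np.linspace(0, int(pos.iloc[-1]), 9).astype(int)
        genes = GeneIntervals(pd.DataFrame(
            [{"gene_id": f"g{i}", "chrom": "1", "start": int(bounds[i]),
              "end": int(bounds[i + 1])} for i in range(8)]
        ))
        return geno, pm, genes

    def _null_for(self, table):
        bins = {int(c): np.linspace(-0.2, 1.5, 400)
                for c in table["n_snps"].unique()}
        # pad every bin to a common n_sim
        return NullStore(bins={k: v for k, v in bins.items()}, n_sim=400,
                         triple=("TGT", "x", "HAN"), model_id="m", seed=0)

    def test_three_comparisons_and_min_two_rule(self, rng):
        geno, pm, genes = self._five_pop(rng)
        others = ["P2", "P3", "P4"]
        nulls = {}
        for second in others:
            t = gene_pbs_scan(geno, pm, genes, ("TGT", second, "HAN"))
            nulls[second] = self._null_for(t)
        res = divergent_scan(geno, pm, "TGT", others, "HAN", genes, nulls,
                             alpha=0.5, min_comparisons=2)
        assert set(res["tables"]) == set(others)
        counts = {}
        for t in res["tables"].values():
            for gid in t.loc[t["p_value"] < 0.5, "gene_id"]:
                counts[gid] = counts.get(gid, 0) + 1
        assert res["differential"] == {g for g, c in counts.items() if c >= 2}

    def test_overlapping_roles_rejected(self, rng):
        geno, pm, genes = self._five_pop(rng)
        with pytest.raises(ValueError, match="distinct"):
            divergent_scan(geno, pm, "TGT", ["P2", "P3", "TGT"], "HAN",
                           genes, {})


class TestBuildNull:
    def test_structure_and_determinism(self):
        from trigene.demography import pbs_null_model

        model = pbs_null_model(rescale_factor=200.0)
        kw = dict(
            bins=[4, 5], n_sim=150, n_samples={"TGT": 8, "HAN": 8, "CEU": 8},
            burnin=10, gene_length=1500, batch_genes=1500, max_rounds=20,
        )
        a = build_null(model, ("TGT", "HAN", "CEU"), seed=9, **kw)
        b = build_null(model, ("TGT", "HAN", "CEU"), seed=9, **kw)
        assert set(a.bins) == {4, 5}
        for k in a.bins:
            assert len(a.bins[k]) == 150
            assert np.all(np.diff(a.bins[k]) >= 0)
            assert np.array_equal(a.bins[k], b.bins[k])

    def test_n_sim_floor(self):
        from trigene.demography import pbs_null_model

        with pytest.raises(ValueError, match="n_sim"):
            build_null(pbs_null_model(), ("TGT", "HAN", "CEU"), bins=[3],
                       n_sim=50, seed=1)
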