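"""Canned synthetic study designs exercising the full pipeline.

Each function builds a demography, simulates data with the internal engine,
runs the relevant analysis and returns summary quantities.  These designs
back the package's validation suite and the reproduction script; problem
sizes (rescaled effective sizes, region counts, sample sizes) are desk-scale
choices documented in docs/methods.md.

All replicate designs exploit that unlinked regions are independent: one
engine run simulates ``n_rep x regions_per_rep`` regions and the regions are
then grouped into replicates, which is statistically identical to ``n_rep``
separate runs but far cheaper.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PopulationMap
from .demography import (
    DemographyModel,
    MigrationWindow,
    SizeEpoch,
    Split,
    pbs_null_model,
    two_population_model,
    yunnan_model,
)
from . import simdata
from .fstats import d_stat, f3_stat, gene_flow_scan
from .lddemog import binned_r2, divergence_2nefst, ne_trajectory, trajectory_frame
from .popdiff import fst_nj_tree, pairwise_fst_matrix, wc_fst
from .selection import build_null, gene_pbs_scan, pbs_pvalues
from .simdata import default_popmap, genes_from_regions, inject_differentiation, simulate_neutral

__all__ = [
    "dstat_study",
    "f3_ordering_study",
    "pbs_calibration_study",
    "pbs_power_study",
    "ld_ne_study",
    "divergence_study",
    "demo_replicate",
    "DEMO_EDGE_CELLS",
]


def _replicated(geno: GenotypeMatrix, regions_per_rep: int) -> np.ndarray:
    chrom = geno.variants["chrom"].to_numpy().astype(int)
    return (chrom - 1) // regions_per_rep


# ---------------------------------------------------------------------------
# D statistic: type-I calibration and introgression power
# ---------------------------------------------------------------------------

def _dstat_model(migration: float) -> DemographyModel:
    pops = ["O", "Z", "X", "Y"]
    m = DemographyModel(
        populations=pops,
        sizes={p: [SizeEpoch(0, 50)] for p in pops},
        splits=[Split(55, "Z", "O"), Split(35, "X", "Z"), Split(8, "Y", "X")],
        migrations=[MigrationWindow("X", "Z", migration, 6)] if migration > 0 else [],
        mutation_rate=4e-6,
        recombination_rate=0.0,
        rescale_factor=1.0,
    )
    m.validate()
    return m


def dstat_study(
    n_rep: int,
    seed: int,
    migration: float = 0.0,
    regions_per_rep: int = 45,
    region_length: int = 10_000,
    n_per_pop: int = 25,
) -> pd.DataFrame:
    """D(X, Y; Z, O) per replicate under a clean tree (``migration=0``) or
    with a recent Z -> X pulse.  Returns columns d, z, n_snps.

    Replicates are simulated in chunks of 50 to bound peak memory.
    """
    model = _dstat_model(migration)
    ns = {p: n_per_pop for p in ["O", "Z", "X", "Y"]}
    popmap = default_popmap(ns)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rows = []
    remaining = n_rep
    while remaining > 0:
        chunk = min(50, remaining)
        geno = simulate_neutral(
            model, ns, region_lengths=[region_length] * (regions_per_rep * chunk),
            seed=ss.spawn(1)[0], burnin=30,
        )
        rep = _replicated(geno, regions_per_rep)
        for r in range(chunk):
            est = d_stat(geno.take_sites(rep == r), popmap, "X", "Y", "Z", "O")
            rows.append({"d": est.estimate, "z": est.z, "n_snps": est.n_snps})
        remaining -= chunk
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# f3: outgroup-affinity ordering
# ---------------------------------------------------------------------------

def f3_ordering_study(
    n_rep: int,
    seed: int,
    regions_per_rep: int = 20,
    region_length: int = 8_000,
    n_per_pop: int = 20,
) -> pd.DataFrame:
    """Outgroup f3 with a close and a distant partner for X.

    Tree: O outgroup; Y2 splits from X deep, Y1 shallow, so X shares more
    drift with Y1.  Returns f3_close, f3_far per replicate.
    """
    pops = ["O", "X", "Y2", "Y1"]
    model = DemographyModel(
        populations=pops,
        sizes={p: [SizeEpoch(0, 50)] for p in pops},
        splits=[Split(60, "X", "O"), Split(30, "Y2", "X"), Split(10, "Y1", "X")],
        mutation_rate=4e-6,
        recombination_rate=0.0,
        rescale_factor=1.0,
    )
    model.validate()
    ns = {p: n_per_pop for p in pops}
    popmap = default_popmap(ns)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rows = []
    remaining = n_rep
    while remaining > 0:
        chunk = min(50, remaining)
        geno = simulate_neutral(
            model, ns, region_lengths=[region_length] * (regions_per_rep * chunk),
            seed=ss.spawn(1)[0], burnin=30,
        )
        rep = _replicated(geno, regions_per_rep)
        for r in range(chunk):
            sub = geno.take_sites(rep == r)
            close = f3_stat(sub, popmap, "O", "X", "Y1")
            far = f3_stat(sub, popmap, "O", "X", "Y2")
            rows.append({"f3_close": close.estimate, "f3_far": far.estimate})
        remaining -= chunk
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PBS: null calibration and injected-selection power
# ---------------------------------------------------------------------------

PBS_TRIPLE = ("TGT", "HAN", "CEU")
PBS_SAMPLES = {"TGT": 20, "HAN": 20, "CEU": 20}
PBS_BURNIN = 40
PBS_COUNT_RANGE = (3, 10)  # calibrated SNPs-per-gene range at desk scale
_PBS_GENE_LENGTH = 1_800  # targets ~6 usable SNPs per gene


def pbs_model() -> DemographyModel:
    return pbs_null_model(rescale_factor=100.0)


def simulate_scored_genes(
    n_genes: int, seed, model: DemographyModel | None = None
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Neutral gene regions under the PBS null demography (one gene per
    chromosome)."""
    model = model or pbs_model()
    geno = simulate_neutral(
        model, PBS_SAMPLES, region_lengths=[_PBS_GENE_LENGTH] * n_genes,
        seed=seed, burnin=PBS_BURNIN,
    )
    return geno, default_popmap(PBS_SAMPLES)


def pbs_calibration_study(
    seed: int,
    n_obs_genes: int = 3000,
    n_sim: int = 5000,
    count_range: tuple[int, int] = PBS_COUNT_RANGE,
):
    """Score neutral genes against an independently seeded matched null.

    Returns ``(p_values, null_store, observed_table)``; only genes whose
    usable SNP count falls in ``count_range`` are scored (the bins the
    desk-scale null covers).
    """
    model = pbs_model()
    ss = np.random.SeedSequence(seed)
    s_null, s_obs = ss.spawn(2)
    null = build_null(
        model,
        PBS_TRIPLE,
        bins=range(count_range[0], count_range[1] + 1),
        n_sim=n_sim,
        seed=int(s_null.generate_state(1)[0] % (2**31)),
        n_samples=PBS_SAMPLES,
        burnin=PBS_BURNIN,
        gene_length=_PBS_GENE_LENGTH,
        batch_genes=6000,
    )
    geno, popmap = simulate_scored_genes(n_obs_genes, s_obs, model)
    genes = genes_from_regions(geno)
    table = gene_pbs_scan(geno, popmap, genes, PBS_TRIPLE)
    table = table[
        (table["n_snps"] >= count_range[0]) & (table["n_snps"] <= count_range[1])
    ].reset_index(drop=True)
    table = pbs_pvalues(table, null)
    return table["p_value"].to_numpy(), null, table


def pbs_power_study(
    seed: int,
    null,
    n_genes: int = 50,
    shift: float = 0.5,
    count_range: tuple[int, int] = PBS_COUNT_RANGE,
):
    """Inject a target-population frequency shift into ``n_genes`` neutral
    genes and score them (plus ``n_genes`` matched neutral controls) against
    the null.  Returns (injected p-values, control p-values)."""
    model = pbs_model()
    ss = np.random.SeedSequence(seed)
    s_sim, s_inj = ss.spawn(2)
    # simulate extra genes so that n_genes of them land inside the bin range
    geno, popmap = simulate_scored_genes(int(n_genes * 3.5), s_sim, model)
    genes = genes_from_regions(geno)
    idx_by_gene = genes.snp_indices(geno)
    counts = {g: len(i) for g, i in idx_by_gene.items()}
    eligible = [
        g for g, c in counts.items() if count_range[0] <= c <= count_range[1]
    ]
    if len(eligible) < 2 * n_genes:
        raise RuntimeError("too few eligible genes for the power study")
    injected_genes = eligible[:n_genes]
    control_genes = eligible[n_genes : 2 * n_genes]
    freq = geno.alt_freq()
    loci = np.concatenate([idx_by_gene[g] for g in injected_genes])
    loci = loci[(freq[loci] > 0) & (freq[loci] < 1)]
    shifted = inject_differentiation(
        geno, popmap, PBS_TRIPLE[0], loci, shift, seed=s_inj
    )
    table = gene_pbs_scan(shifted, popmap, genes, PBS_TRIPLE)
    table = table[table["n_snps"].between(1, 100)]
    # injection can move a gene's usable count outside the calibrated bins;
    # clamp to the nearest covered bin rather than dropping the gene
    lo, hi = count_range
    table = table.assign(n_snps=table["n_snps"].clip(lo, hi))
    table = pbs_pvalues(table, null)
    by_gene = dict(zip(table["gene_id"], table["p_value"]))
    p_inj = np.array([by_gene[g] for g in injected_genes if g in by_gene])
    p_ctl = np.array([by_gene[g] for g in control_genes if g in by_gene])
    return p_inj, p_ctl


# ---------------------------------------------------------------------------
# LD decay: Ne recovery and split-time recovery
# ---------------------------------------------------------------------------

LD_NE_TRUE = 500


def ld_ne_study(seed: int, total_mb: int = 20, n_samples: int = 50):
    """Constant-size simulation (rescaled Ne=500, 1 cM/Mb); returns the
    trajectory frame and the mean Ne over the 0.05-0.25 cM bins."""
    model = DemographyModel(
        populations=["P"],
        sizes={"P": [SizeEpoch(0, LD_NE_TRUE)]},
        mutation_rate=2.5e-8,
        recombination_rate=1e-8,
        rescale_factor=1.0,
    )
    model.validate()
    n_regions = max(1, total_mb // 5)
    geno = simulate_neutral(
        model, {"P": n_samples}, region_lengths=[5_000_000] * n_regions,
        seed=seed, burnin=2 * LD_NE_TRUE,
    )
    popmap = default_popmap({"P": n_samples})
    df = trajectory_frame(ne_trajectory(binned_r2(geno, popmap, "P")))
    band = df[(df["c_cm"] >= 0.05) & (df["c_cm"] <= 0.25) & df["valid"]]
    return df, float(band["ne"].mean())


def divergence_study(seed: int, split_time: int = 500, n_samples: int = 50):
    """Clean two-population split; returns (estimated T, true split time)."""
    model = two_population_model(
        n_anc=500, n_a=500, n_b=500, split_time=split_time,
        mutation_rate=2.5e-8, recombination_rate=1e-8, rescale_factor=1.0,
    )
    geno = simulate_neutral(
        model, {"A": n_samples, "B": n_samples},
        region_lengths=[5_000_000] * 3, seed=seed, burnin=800,
    )
    popmap = default_popmap({"A": n_samples, "B": n_samples})
    _, fst = wc_fst(geno, popmap, "A", "B")
    traj_a = ne_trajectory(binned_r2(geno, popmap, "A"))
    traj_b = ne_trajectory(binned_r2(geno, popmap, "B"))
    t_hat = divergence_2nefst(traj_a, traj_b, max(fst, 0.0))
    return float(t_hat), float(split_time)


# ---------------------------------------------------------------------------
# end-to-end demo: the six-population Western-Yunnan cartoon
# ---------------------------------------------------------------------------

#: gene-flow-scan cells with their expected outcome under the demo model:
#: (pop1, pop2, donor, expected recipient or "" for no real edge)
DEMO_EDGE_CELLS = [
    ("ACH", "DAI", "TBN", "ACH"),
    ("JIP", "DAI", "TBN", "JIP"),
    ("ACH", "DAI", "HAN", "DAI"),
    ("JIP", "DAI", "HAN", "DAI"),
    ("ACH", "JIP", "HAN", ""),
    ("ACH", "JIP", "TBN", ""),
]

#: unrooted topology of the six study populations in the demo demography
DEMO_TRUE_TOPOLOGY = "((TBN,(ACH,JIP)),(DEA,(DAI,HAN)));"


def topology_matches(newick: str, reference: str = DEMO_TRUE_TOPOLOGY) -> bool:
    """True when the unrooted Robinson-Foulds distance to the reference is 0."""
    import io as _io

    from skbio import TreeNode

    t1 = TreeNode.read(_io.StringIO(newick))
    t2 = TreeNode.read(_io.StringIO(reference))
    return float(t1.compare_rfd(t2)) == 0.0

DEMO_SAMPLES = {p: 15 for p in ["OUT", "TBN", "ACH", "JIP", "DEA", "DAI", "HAN"]}


def demo_replicate(seed, rescale: float = 50.0, n_regions: int = 300,
                   region_length: int = 9_000):
    """One end-to-end run of the six-population demo (plus deep outgroup).

    Returns the pairwise-FST matrix, the NJ Newick string and the
    gene-flow-scan table over :data:`DEMO_EDGE_CELLS`.
    """
    model = yunnan_model(rescale_factor=rescale)
    geno = simulate_neutral(
        model, DEMO_SAMPLES, region_lengths=[region_length] * n_regions,
        seed=seed, burnin=60,
    )
    popmap = default_popmap(DEMO_SAMPLES)
    study = {p: n for p, n in DEMO_SAMPLES.items() if p != "OUT"}
    study_map = PopulationMap(
        {s: p for s, p in popmap.assignments.items() if p != "OUT"}
    )
    fstm = pairwise_fst_matrix(geno, study_map)
    newick = fst_nj_tree(fstm)
    pairs = sorted({(c[0], c[1]) for c in DEMO_EDGE_CELLS})
    donors = sorted({c[2] for c in DEMO_EDGE_CELLS})
    scan = gene_flow_scan(geno, popmap, pairs, donors, outgroup="OUT")
    return fstm, newick, scan
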