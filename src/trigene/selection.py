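"""Population Branch Statistic scans with a simulation-calibrated null.

PBS for a target population A against references B and C is

    PBS_A = (T_AB + T_AC - T_BC) / 2,      T = -log(1 - FST)

computed per gene from ratio-of-averages Weir-Cockerham FST over the gene's
usable SNPs (usable = polymorphic in at least one of the three populations).
Significance comes from an empirical null of neutral gene PBS values
simulated under the study demography and matched on SNPs per gene: one bin
per count 1..69, then 5-wide bins for 70..100.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import GeneIntervals, GenotypeMatrix, PopulationMap
from .demography import DemographyModel
from .popdiff import wc_site_components
from . import simdata

__all__ = [
    "PBSRecord",
    "NullStore",
    "site_filter_pbs",
    "pbs_value",
    "gene_pbs_scan",
    "build_null",
    "pbs_pvalues",
    "shared_signals",
    "divergent_scan",
    "major_variants",
    "strong_gene_intersection",
]

FST_CLAMP_HI = 1.0 - 1e-8
DEPTH_DEFAULT = 50.0
MISSING_DEFAULT = 0.05


# ---------------------------------------------------------------------------
# core statistic
# ---------------------------------------------------------------------------

def _t_branch(fst) -> np.ndarray:
    f = np.clip(np.asarray(fst, dtype=float), 0.0, FST_CLAMP_HI)
    return -np.log1p(-f)


def pbs_value(fst_ab, fst_ac, fst_bc):
    """PBS of population A from the three pairwise FST values.

    FST values are clamped to [0, 1 - 1e-8] before the log transform
    (negative estimates have no drift interpretation; T diverges at 1).
    Scalar in, scalar out; arrays broadcast.
    """
    arrs = [np.asarray(x, dtype=float) for x in (fst_ab, fst_ac, fst_bc)]
    if any(np.isnan(a).any() for a in arrs):
        raise ValueError("NaN FST passed to pbs_value")
    t_ab, t_ac, t_bc = (_t_branch(a) for a in arrs)
    out = (t_ab + t_ac - t_bc) / 2.0
    return float(out) if out.ndim == 0 else out


@dataclass
class PBSRecord:
    gene_id: str
    n_snps: int
    fst_ab: float
    fst_ac: float
    fst_bc: float
    pbs: float = field(init=False)
    t_ab: float = field(init=False)
    t_ac: float = field(init=False)
    t_bc: float = field(init=False)
    p_value: float | None = None

    def __post_init__(self) -> None:
        self.t_ab = float(_t_branch(self.fst_ab))
        self.t_ac = float(_t_branch(self.fst_ac))
        self.t_bc = float(_t_branch(self.fst_bc))
        self.pbs = (self.t_ab + self.t_ac - self.t_bc) / 2.0


# ---------------------------------------------------------------------------
# site filtering
# ---------------------------------------------------------------------------

def site_filter_pbs(
    geno: GenotypeMatrix,
    min_depth: float | None = DEPTH_DEFAULT,
    max_missing: float = MISSING_DEFAULT,
) -> GenotypeMatrix:
    """Retain sites with mean depth above ``min_depth`` and a missing rate
    below ``max_missing`` (defaults 50x and 5%)."""
    keep = np.ones(geno.n_variants, dtype=bool)
    if min_depth is not None:
        depth = geno.variants["depth"].to_numpy(dtype=float)
        if np.isnan(depth).all() and geno.n_variants:
            raise ValueError("depth filter requested but no depth field present")
        keep &= depth > min_depth
    keep &= geno.missing_rate() < max_missing
    return geno.take_sites(keep)


# ---------------------------------------------------------------------------
# gene-level scan
# ---------------------------------------------------------------------------

def _triple_site_components(
    geno: GenotypeMatrix, popmap: PopulationMap, triple: tuple[str, str, str]
):
    """Per-site (a, d) for the three pairs plus the polymorphism mask."""
    a_lab, b_lab, c_lab = triple
    cols = {lab: popmap.indices(geno, lab) for lab in triple}
    comp_ab = wc_site_components(geno, cols[a_lab], cols[b_lab])
    comp_ac = wc_site_components(geno, cols[a_lab], cols[c_lab])
    comp_bc = wc_site_components(geno, cols[b_lab], cols[c_lab])
    poly = np.zeros(geno.n_variants, dtype=bool)
    for lab in triple:
        f = geno.alt_freq(cols[lab])
        poly |= (f > 0) & (f < 1)
    return comp_ab, comp_ac, comp_bc, poly


def _aggregate_pair(comp, idx) -> float:
    use = comp.usable[idx]
    den = comp.d[idx][use].sum()
    if den == 0:
        return 0.0
    return float(comp.a[idx][use].sum() / den)


def gene_pbs_scan(
    geno: GenotypeMatrix,
    popmap: PopulationMap,
    genes: GeneIntervals,
    triple: tuple[str, str, str],
    per_snp_mean: bool = False,
) -> pd.DataFrame:
    """Gene-level PBS for target ``triple[0]`` against ``triple[1:]``.

    Each gene aggregates Weir-Cockerham FST by ratio of averages over its
    usable SNPs, then transforms to PBS; genes with no usable SNP are
    omitted.  ``per_snp_mean=True`` instead averages single-SNP PBS values
    across the gene (the alternative aggregation; off by default).
    """
    for lab in triple:
        if lab not in popmap.populations:
            raise KeyError(f"population {lab!r} missing from population map")
    comp_ab, comp_ac, comp_bc, poly = _triple_site_components(geno, popmap, triple)
    rows = []
    for gene_id, idx in genes.snp_indices(geno).items():
        idx = idx[poly[idx]]
        if idx.size == 0:
            continue
        if per_snp_mean:
            f_ab = _persite_fst(comp_ab, idx)
            f_ac = _persite_fst(comp_ac, idx)
            f_bc = _persite_fst(comp_bc, idx)
            pbs = float(np.mean(pbs_value(f_ab, f_ac, f_bc)))
            rec = PBSRecord(gene_id, int(idx.size), float(np.mean(f_ab)),
                            float(np.mean(f_ac)), float(np.mean(f_bc)))
            rec.pbs = pbs
        else:
            rec = PBSRecord(
                gene_id,
                int(idx.size),
                _aggregate_pair(comp_ab, idx),
                _aggregate_pair(comp_ac, idx),
                _aggregate_pair(comp_bc, idx),
            )
        rows.append(
            {
                "gene_id": rec.gene_id,
                "n_snps": rec.n_snps,
                "fst_ab": rec.fst_ab,
                "fst_ac": rec.fst_ac,
                "fst_bc": rec.fst_bc,
                "t_ab": rec.t_ab,
                "t_ac": rec.t_ac,
                "t_bc": rec.t_bc,
                "pbs": rec.pbs,
            }
        )
    if not rows:
        raise ValueError("no gene with a usable SNP")
    return pd.DataFrame(rows)


def _persite_fst(comp, idx) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(comp.d[idx] != 0, comp.a[idx] / comp.d[idx], 0.0)
    return np.where(comp.usable[idx], f, 0.0)


# ---------------------------------------------------------------------------
# simulated null
# ---------------------------------------------------------------------------

def bin_key(count: int) -> int:
    """SNPs-per-gene bin: one bin per count 1..69, then 5-wide bins
    [70,74], [75,79], ..., [90,94], with the final bin [95,100] absorbing
    the boundary count 100."""
    c = int(count)
    if c < 1 or c > 100:
        raise ValueError(f"SNP count {c} outside 1..100")
    if c < 70:
        return c
    return min(70 + 5 * ((c - 70) // 5), 95)


@dataclass
class NullStore:
    """Sorted neutral gene-PBS values per SNPs-per-gene bin."""

    bins: dict[int, np.ndarray]
    n_sim: int
    triple: tuple[str, str, str]
    model_id: str
    seed: int

    def __post_init__(self) -> None:
        for key, arr in self.bins.items():
            arr = np.sort(np.asarray(arr, dtype=float))
            if arr.size != self.n_sim:
                raise ValueError(
                    f"bin {key} holds {arr.size} values, expected n_sim={self.n_sim}"
                )
            self.bins[key] = arr

    def p_value(self, n_snps: int, pbs: float) -> float:
        """Empirical p with a +1/+1 pseudocount:
        ``(1 + #{simulated >= observed}) / (1 + n_sim)``."""
        key = bin_key(n_snps)
        if key not in self.bins:
            raise KeyError(f"no null bin for SNP count {n_snps} (bin {key})")
        arr = self.bins[key]
        n_ge = arr.size - np.searchsorted(arr, pbs, side="left")
        return float((1 + n_ge) / (1 + self.n_sim))

    # -- serialisation ---------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "n_sim": self.n_sim,
            "triple": list(self.triple),
            "model_id": self.model_id,
            "seed": self.seed,
            "bins": {str(k): v.tolist() for k, v in self.bins.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "NullStore":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            bins={int(k): np.asarray(v) for k, v in payload["bins"].items()},
            n_sim=payload["n_sim"],
            triple=tuple(payload["triple"]),
            model_id=payload["model_id"],
            seed=payload["seed"],
        )


def _model_id(model: DemographyModel) -> str:
    text = repr(model).encode()
    return hashlib.sha1(text).hexdigest()[:12]


def simulate_gene_batch(
    model: DemographyModel,
    triple: tuple[str, str, str],
    lengths: Sequence[int],
    n_samples: Mapping[str, int],
    seed,
    burnin: int | None = None,
) -> pd.DataFrame:
    """Simulate one independent neutral gene per region length and return the
    per-gene usable SNP count and PBS (columns ``n_snps``, ``pbs``).

    Regions are unlinked; with the default exome-scale lengths the engine's
    within-region recombination is negligible and the batch reduces to a set
    of independent gene genealogies under the model.
    """
    geno = simdata.simulate_neutral(
        model,
        dict(n_samples),
        region_lengths=list(lengths),
        seed=seed,
        burnin=burnin,
    )
    if geno.n_variants == 0:
        return pd.DataFrame({"n_snps": [], "pbs": []})
    popmap = simdata.default_popmap(dict(n_samples))
    comp_ab, comp_ac, comp_bc, poly = _triple_site_components(geno, popmap, triple)
    region = geno.variants["chrom"].to_numpy().astype(int) - 1
    rows = {"n_snps": [], "pbs": []}
    order = np.argsort(region, kind="stable")
    region_sorted = region[order]
    boundaries = np.flatnonzero(np.diff(region_sorted)) + 1
    groups = np.split(order, boundaries)
    for idx in groups:
        idx = idx[poly[idx]]
        if idx.size == 0:
            continue
        f_ab = _aggregate_pair(comp_ab, idx)
        f_ac = _aggregate_pair(comp_ac, idx)
        f_bc = _aggregate_pair(comp_bc, idx)
        rows["n_snps"].append(int(idx.size))
        rows["pbs"].append(pbs_value(f_ab, f_ac, f_bc))
    return pd.DataFrame(rows)


def build_null(
    model: DemographyModel,
    triple: tuple[str, str, str],
    bins: Sequence[int],
    n_sim: int,
    seed: int,
    *,
    n_samples: Mapping[str, int] | None = None,
    burnin: int | None = None,
    gene_length: int | None = None,
    batch_genes: int = 4000,
    max_rounds: int = 60,
) -> NullStore:
    """Simulate neutral genes until every requested bin holds ``n_sim`` PBS
    values.

    ``bins`` lists the SNPs-per-gene counts that must be covered (their bin
    keys).  Gene region lengths are targeted at the deficient bins and
    re-calibrated from realised SNP yields each round; genes landing outside
    1..100 SNPs are discarded and re-simulated, with ``max_rounds`` as the
    retry cap.

    When the genes to be scored share one region length, pass it as
    ``gene_length`` so every null gene is simulated at that same length:
    conditioning on the realised SNP count makes the neutral PBS
    distribution length-dependent (count carries information about the
    gene's genealogy given the mutation target size), so a matched length is
    required for exact per-bin calibration.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    needed = sorted({bin_key(int(c)) for c in bins})
    if n_samples is None:
        n_samples = {lab: 20 for lab in triple}
    ss = np.random.SeedSequence(seed)
    pools: dict[int, list[float]] = {k: [] for k in needed}
    # initial SNPs-per-bp guess from Watterson with the union sample size
    resc = model.rescaled()
    n_hap = 2 * sum(n_samples.values())
    root_n = resc.size_at(resc.root(), resc.oldest_event_time() + 1)
    harmonic = float(np.sum(1.0 / np.arange(1, n_hap)))
    density = 4 * root_n * resc.mutation_rate * harmonic  # usable SNPs per bp
    rng = np.random.default_rng(ss.spawn(1)[0])
    for round_i in range(max_rounds):
        deficits = {k: n_sim - len(pools[k]) for k in needed}
        if all(v <= 0 for v in deficits.values()):
            break
        open_keys = [k for k, v in deficits.items() if v > 0]
        if gene_length is not None:
            lengths = np.full(batch_genes, int(gene_length), dtype=np.int64)
        else:
            weights = np.array([deficits[k] for k in open_keys], dtype=float)
            targets = rng.choice(open_keys, size=batch_genes, p=weights / weights.sum())
            # representative count per key: exact for 1..69, bin middle above
            rep = np.where(targets < 70, targets, targets + 2)
            lengths = np.maximum(50, np.round(rep / density)).astype(np.int64)
        batch = simulate_gene_batch(
            model, triple, lengths, n_samples, seed=ss.spawn(1)[0], burnin=burnin
        )
        realized = 0
        for n_snps, pbs in zip(batch["n_snps"], batch["pbs"]):
            realized += n_snps
            if n_snps < 1 or n_snps > 100:
                continue  # outside the modelled range: discard, re-simulate
            key = bin_key(n_snps)
            if key in pools and len(pools[key]) < n_sim * 2:
                pools[key].append(float(pbs))
        total_len = int(lengths.sum())
        if total_len and realized:
            density = 0.5 * density + 0.5 * (realized / total_len)
    shortfall = {k: n_sim - len(pools[k]) for k in needed if len(pools[k]) < n_sim}
    if shortfall:
        raise RuntimeError(
            f"null bins under-filled after {max_rounds} rounds: {shortfall}"
        )
    return NullStore(
        bins={k: np.asarray(v[:n_sim]) for k, v in pools.items()},
        n_sim=n_sim,
        triple=tuple(triple),
        model_id=_model_id(model),
        seed=seed,
    )


def pbs_pvalues(records: pd.DataFrame, null: NullStore) -> pd.DataFrame:
    """Attach the empirical p-value per gene; missing bins raise with the
    offending gene named."""
    out = records.copy()
    ps = []
    for row in out.itertuples(index=False):
        try:
            ps.append(null.p_value(int(row.n_snps), float(row.pbs)))
        except KeyError as exc:
            raise KeyError(f"gene {row.gene_id}: {exc.args[0]}") from None
    out["p_value"] = ps
    return out


# ---------------------------------------------------------------------------
# scan designs
# ---------------------------------------------------------------------------

def shared_signals(
    per_pop_tables: Mapping[str, pd.DataFrame],
    alpha: float = 0.01,
    min_pops: int = 2,
) -> dict:
    """Shared adaptive signals: genes significant (p < alpha) in at least
    ``min_pops`` populations; also reports the all-population intersection."""
    sig_sets = {
        pop: set(t.loc[t["p_value"] < alpha, "gene_id"]) for pop, t in per_pop_tables.items()
    }
    gene_pops: dict[str, set[str]] = {}
    for pop, genes in sig_sets.items():
        for g in genes:
            gene_pops.setdefault(g, set()).add(pop)
    shared = {g for g, pops in gene_pops.items() if len(pops) >= min_pops}
    all_pops = set(per_pop_tables)
    return {
        "per_gene_populations": gene_pops,
        "shared": shared,
        "all_populations": {g for g, pops in gene_pops.items() if pops == all_pops},
        "per_population": sig_sets,
    }


def divergent_scan(
    geno: GenotypeMatrix,
    popmap: PopulationMap,
    target: str,
    others: Sequence[str],
    third: str,
    genes: GeneIntervals,
    null_stores: Mapping[str, NullStore],
    alpha: float = 0.01,
    min_comparisons: int = 2,
) -> dict:
    """Divergent-adaptation scan for one target population.

    Each of the other study populations serves in turn as the second
    population with a fixed third population; a gene significant in at least
    ``min_comparisons`` of the comparisons is a differential adaptive
    signal.
    """
    labels = [target, *others, third]
    if len(set(labels)) != len(labels):
        raise ValueError("target, others and third must be distinct")
    tables: dict[str, pd.DataFrame] = {}
    for second in others:
        t = gene_pbs_scan(geno, popmap, genes, (target, second, third))
        tables[second] = pbs_pvalues(t, null_stores[second])
    counts: dict[str, int] = {}
    for t in tables.values():
        for g in t.loc[t["p_value"] < alpha, "gene_id"]:
            counts[g] = counts.get(g, 0) + 1
    return {
        "tables": tables,
        "differential": {g for g, c in counts.items() if c >= min_comparisons},
    }


def major_variants(
    geno: GenotypeMatrix,
    popmap: PopulationMap,
    genes: GeneIntervals,
    gene_ids: Sequence[str],
    triple: tuple[str, str, str],
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Highly differentiated SNPs inside significant genes: per-SNP PBS
    strictly above ``threshold``, with per-population alternate-allele
    frequencies attached.

    Unlike the gene-level scan, a site fixed for different alleles in
    different populations (monomorphic within each) still counts here — it
    is the most differentiated case a single SNP can show — so usability is
    polymorphism across the union of the three populations.
    """
    comp_ab, comp_ac, comp_bc, _ = _triple_site_components(geno, popmap, triple)
    all_cols = np.concatenate([popmap.indices(geno, lab) for lab in triple])
    f_union = geno.alt_freq(all_cols)
    poly = (f_union > 0) & (f_union < 1)
    wanted = set(gene_ids)
    freqs = {lab: geno.alt_freq(popmap.indices(geno, lab)) for lab in triple}
    rows = []
    for gene_id, idx in genes.snp_indices(geno).items():
        if gene_id not in wanted:
            continue
        idx = idx[poly[idx]]
        if idx.size == 0:
            continue
        pbs = pbs_value(
            _persite_fst(comp_ab, idx), _persite_fst(comp_ac, idx), _persite_fst(comp_bc, idx)
        )
        keep = pbs > threshold
        for j, site in enumerate(idx[keep]):
            v = geno.variants.iloc[site]
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": v["chrom"],
                    "pos": int(v["pos"]),
                    "ref": v["ref"],
                    "alt": v["alt"],
                    "pbs": float(np.atleast_1d(pbs)[keep][j]),
                    **{f"freq_{lab}": float(freqs[lab][site]) for lab in triple},
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "pos", "ref", "alt", "pbs"]
        + [f"freq_{lab}" for lab in triple],
    )


def strong_gene_intersection(
    tables: Sequence[pd.DataFrame], alpha: float = 0.05
) -> set[str]:
    """Genes significant (p < alpha) in ALL provided comparisons: the
    enrichment input set for one target population."""
    sets = [set(t.loc[t["p_value"] < alpha, "gene_id"]) for t in tables]
    if not sets:
        return set()
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out
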