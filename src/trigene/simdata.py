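"""Synthetic multi-population exome-like data under a configurable demography.

The engine is a discrete-generation diploid Wright-Fisher forward simulation
with random mating within populations, migration, splits (realised forward in
time as the ancestral population partitioning at the split generation),
infinite-sites mutation and crossover recombination.  Genomes are collections
of independent regions ("chromosomes"); segregating sites are tracked
sparsely as matrix columns shared across populations.

The ancestral population is initialised at mutation-drift equilibrium by
drawing site counts from the neutral 1/i frequency spectrum, after which a
configurable number of burn-in generations are run before the first
demographic event.  All randomness flows from a single root seed through
numpy ``SeedSequence`` spawning, so every stage is independently
reproducible.
"""

from __future__ import annotations

import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import GeneIntervals, GenotypeMatrix, PopulationMap
from .demography import DemographyModel

__all__ = [
    "simulate_neutral",
    "default_popmap",
    "inject_differentiation",
    "add_missingness",
    "attach_depth",
    "make_exome_structure",
    "genes_from_regions",
    "emit_dataset",
]


def _harmonic(k: int) -> float:
    if k < 100:
        return float(np.sum(1.0 / np.arange(1, k + 1)))
    # Euler-Maclaurin; plenty for k >= 100
    return math.log(k) + 0.5772156649015329 + 1.0 / (2 * k)


class _Engine:
    """One forward simulation run.  Not part of the public API."""

    def __init__(
        self,
        model: DemographyModel,
        region_lengths: np.ndarray,
        rng: np.random.Generator,
        burnin: int | None,
    ):
        model.validate()
        self.model = model.rescaled()
        self.rng = rng
        self.lengths = np.asarray(region_lengths, dtype=np.int64)
        if (self.lengths < 1).any():
            raise ValueError("region lengths must be >= 1")
        self.R = len(self.lengths)
        self.L_tot = int(self.lengths.sum())
        self.mu = self.model.mutation_rate
        self.rbp = self.model.recombination_rate
        self.glen = self.lengths * self.rbp  # Morgans per region
        self.G_tot = float(self.glen.sum())
        self.root = self.model.root()
        t_events = int(math.ceil(self.model.oldest_event_time()))
        if burnin is None:
            burnin = int(round(2 * self.model.size_at(self.root, t_events + 1)))
        self.t_start = t_events + int(burnin)
        if self.t_start < 1:
            self.t_start = 1
        # column state; columns are kept sorted by (region, pos) in a prefix,
        # with freshly arisen mutations in an unsorted tail until the next
        # prune pass folds them in (cheap recombination-mask construction)
        self.region_id = np.empty(0, dtype=np.int32)
        self.pos = np.empty(0, dtype=np.int64)
        self.prefix_counts = np.zeros(self.R, dtype=np.int64)
        self.prefix_len = 0
        self.pops: dict[str, np.ndarray] = {}

    # -- initialisation --------------------------------------------------
    def _init_root(self) -> None:
        m, rng = self.model, self.rng
        n0 = int(m.size_at(self.root, self.t_start))
        h0 = 2 * n0
        theta_bp = 4 * n0 * self.mu
        exp_s = theta_bp * self.L_tot * _harmonic(h0 - 1)
        s0 = int(rng.poisson(exp_s)) if self.mu > 0 else 0
        region = rng.choice(self.R, size=s0, p=self.lengths / self.L_tot) if s0 else np.empty(0, np.int32)
        pos = rng.integers(1, self.lengths[region] + 1) if s0 else np.empty(0, np.int64)
        counts_support = np.arange(1, h0)
        w = 1.0 / counts_support
        counts = rng.choice(counts_support, size=s0, p=w / w.sum()) if s0 else np.empty(0, np.int64)
        region = np.asarray(region, dtype=np.int32)
        pos = np.asarray(pos, dtype=np.int64)
        order = np.lexsort((pos, region))
        region, pos, counts = region[order], pos[order], counts[order] if s0 else counts
        hap = np.zeros((h0, s0), dtype=np.uint8)
        if s0:
            # per column, mark `count` random carriers
            u = rng.random((h0, s0))
            ranks = np.argsort(np.argsort(u, axis=0), axis=0)
            hap = (ranks < counts[None, :]).astype(np.uint8)
        self.region_id = region
        self.pos = pos
        self.prefix_len = s0
        self.prefix_counts = np.bincount(region, minlength=self.R).astype(np.int64)
        self.pops = {self.root: hap}

    # -- one generation ---------------------------------------------------
    def _step(self, t: int) -> None:
        m, rng = self.model, self.rng
        t_child = t - 1
        child_pops = [p for p in m.populations if m.alive(p, t_child)]
        s = len(self.pos)
        new_pops: dict[str, np.ndarray] = {}
        for p in child_pops:
            n_ind = int(m.size_at(p, t_child))
            n_g = 2 * n_ind
            # gamete source populations (migration + split chain)
            src_default = m.ancestor_at(p, t)
            sources = np.zeros(n_g, dtype=np.int32)
            src_names = [src_default]
            mig = m.migration_row(p, t_child)
            if mig:
                u = rng.random(n_g)
                acc = 0.0
                for donor, rate in mig.items():
                    donor_t = m.ancestor_at(donor, t)
                    if donor_t not in src_names:
                        src_names.append(donor_t)
                    sel = (u >= acc) & (u < acc + rate)
                    sources[sel] = src_names.index(donor_t)
                    acc += rate
            # recombination mask: random phase per region, plus crossovers;
            # the sorted prefix lets the mask be built by repeat, not gather
            phase = rng.integers(0, 2, size=(n_g, self.R), dtype=np.uint8)
            k = self.prefix_len
            mask = np.empty((n_g, s), dtype=np.uint8)
            if k:
                mask[:, :k] = np.repeat(phase, self.prefix_counts, axis=1)
            if s > k:
                mask[:, k:] = phase[:, self.region_id[k:]]
            if self.G_tot > 0 and s:
                starts = np.concatenate(([0], np.cumsum(self.prefix_counts)))
                n_x = rng.poisson(self.G_tot, size=n_g)
                total = int(n_x.sum())
                if total:
                    gam = np.repeat(np.arange(n_g), n_x)
                    reg = rng.choice(self.R, size=total, p=self.glen / self.G_tot)
                    bp = rng.integers(1, self.lengths[reg] + 1)
                    tail_reg = self.region_id[k:]
                    tail_pos = self.pos[k:]
                    for g_i, r_i, b_i in zip(gam, reg, bp):
                        lo, hi = starts[r_i], starts[r_i + 1]
                        j = lo + np.searchsorted(self.pos[lo:hi], b_i, side="right")
                        mask[g_i, j:hi] ^= 1
                        if s > k:
                            mask[g_i, k:][(tail_reg == r_i) & (tail_pos > b_i)] ^= 1
            child = np.empty((n_g, s), dtype=np.uint8) if len(src_names) > 1 else None
            for si, name in enumerate(src_names):
                rows = np.arange(n_g) if len(src_names) == 1 else np.flatnonzero(sources == si)
                if rows.size == 0:
                    continue
                pool = self.pops[name]
                n_src = pool.shape[0] // 2
                parent = rng.integers(0, n_src, size=rows.size)
                h1 = pool[2 * parent]
                h2 = pool[2 * parent + 1]
                sub_mask = mask if len(src_names) == 1 else mask[rows]
                # child = h1 where mask==0 else h2, via XOR arithmetic on 0/1
                np.bitwise_xor(h1, h2, out=h2)
                np.bitwise_and(h2, sub_mask, out=h2)
                np.bitwise_xor(h2, h1, out=h2)
                if len(src_names) == 1:
                    child = h2
                else:
                    child[rows] = h2
            new_pops[p] = child
        self.pops = new_pops
        self._mutate_and_prune()

    def _mutate_and_prune(self) -> None:
        m, rng = self.model, self.rng
        pop_names = list(self.pops)
        gam_counts = np.array([self.pops[p].shape[0] for p in pop_names])
        n_g_tot = int(gam_counts.sum())
        n_new = int(rng.poisson(n_g_tot * self.mu * self.L_tot)) if self.mu > 0 else 0
        # column occupancy across the metapopulation
        s = len(self.pos)
        if s:
            tot = np.zeros(s, dtype=np.int64)
            for p in pop_names:
                tot += self.pops[p].sum(axis=0, dtype=np.int64)
            keep = (tot > 0) & (tot < n_g_tot)
        else:
            keep = np.zeros(0, dtype=bool)
        keep_idx = np.flatnonzero(keep)
        order = np.lexsort((self.pos[keep_idx], self.region_id[keep_idx]))
        keep_idx = keep_idx[order]
        if n_new:
            owner = rng.integers(0, n_g_tot, size=n_new)
            reg = rng.choice(self.R, size=n_new, p=self.lengths / self.L_tot)
            bp = rng.integers(1, self.lengths[reg] + 1)
        k = keep_idx.size
        new_region = np.empty(k + n_new, dtype=np.int32)
        new_pos = np.empty(k + n_new, dtype=np.int64)
        new_region[:k] = self.region_id[keep_idx]
        new_pos[:k] = self.pos[keep_idx]
        if n_new:
            new_region[k:] = reg
            new_pos[k:] = bp
        offsets = np.concatenate(([0], np.cumsum(gam_counts)))
        for i, p in enumerate(pop_names):
            old = self.pops[p]
            block = np.zeros((old.shape[0], k + n_new), dtype=np.uint8)
            block[:, :k] = old[:, keep_idx]
            if n_new:
                local = owner - offsets[i]
                mine = (local >= 0) & (local < gam_counts[i])
                block[local[mine], k + np.flatnonzero(mine)] = 1
            self.pops[p] = block
        self.region_id = new_region
        self.pos = new_pos
        self.prefix_len = k
        self.prefix_counts = np.bincount(new_region[:k], minlength=self.R).astype(np.int64)

    # -- run and sample ---------------------------------------------------
    def run(self) -> None:
        self._init_root()
        for t in range(self.t_start, 0, -1):
            self._step(t)

    def sample(
        self, n_samples: Mapping[str, int], keep_monomorphic: bool = False
    ) -> tuple[GenotypeMatrix, PopulationMap]:
        rng = self.rng
        cols: list[np.ndarray] = []
        names: list[str] = []
        assign: dict[str, str] = {}
        for pop, n in n_samples.items():
            if pop not in self.pops:
                raise ValueError(f"population {pop!r} not alive at present")
            pool = self.pops[pop]
            n_ind = pool.shape[0] // 2
            if n > n_ind:
                raise ValueError(
                    f"requested {n} samples from {pop} but only {n_ind} individuals "
                    "exist after rescaling"
                )
            chosen = rng.choice(n_ind, size=n, replace=False)
            geno = (
                pool[2 * chosen].astype(np.int8) + pool[2 * chosen + 1].astype(np.int8)
            )  # (n, S)
            cols.append(geno)
            for j in range(n):
                sid = f"{pop}_{j:03d}"
                names.append(sid)
                assign[sid] = pop
        g = np.concatenate(cols, axis=0).T if cols else np.zeros((len(self.pos), 0), np.int8)
        order = np.lexsort((self.pos, self.region_id))
        region = self.region_id[order]
        pos = self.pos[order]
        g = g[order]
        # infinite-sites bookkeeping: drop duplicate coordinates (rare)
        if len(pos):
            dup = np.concatenate(([False], (np.diff(region) == 0) & (np.diff(pos) == 0)))
            if dup.any():
                sel = ~dup
                region, pos, g = region[sel], pos[sel], g[sel]
        if not keep_monomorphic and g.shape[1] > 0:
            ac = g.sum(axis=1, dtype=np.int64)
            poly = (ac > 0) & (ac < 2 * g.shape[1])
            region, pos, g = region[poly], pos[poly], g[poly]
        cm = pos * self.rbp * 100.0
        variants = pd.DataFrame(
            {
                "chrom": (region + 1).astype(str),
                "pos": pos,
                "ref": "A",
                "alt": "G",
                "aa": "A",
                "cm": cm,
                "depth": np.nan,
            }
        )
        return GenotypeMatrix(variants, names, g), PopulationMap(assign)


def simulate_neutral(
    model: DemographyModel,
    n_samples: Mapping[str, int],
    region_length: int | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    n_regions: int = 1,
    region_lengths: Sequence[int] | None = None,
    burnin: int | None = None,
    keep_monomorphic: bool = False,
) -> GenotypeMatrix:
    """Simulate a neutral multi-population dataset.

    Parameters
    ----------
    model
        Demography in natural units; rescaling is applied internally.
    n_samples
        Diploid sample count per population (present-day populations only).
    region_length
        Length in bases of each simulated region; ``n_regions`` independent
        regions are emitted as separate chromosomes.  ``region_lengths``
        overrides with per-region lengths.
    seed
        Root seed (int) or a pre-spawned ``SeedSequence``.
    burnin
        Generations run before the oldest demographic event, after the
        equilibrium-spectrum initialisation.  Defaults to twice the root
        diploid size (in rescaled units).

    Returns
    -------
    GenotypeMatrix
        Sites monomorphic in the joint sample are dropped unless
        ``keep_monomorphic``; the ancestral allele is always the REF allele.
    """
    for pop, n in n_samples.items():
        if n < 1:
            raise ValueError(f"sample count for {pop} must be >= 1")
    if region_lengths is None:
        if region_length is None or region_length < 1:
            raise ValueError("region_length must be >= 1")
        region_lengths = [int(region_length)] * int(n_regions)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    eng = _Engine(model, np.asarray(region_lengths), rng, burnin)
    eng.run()
    geno, _ = eng.sample(n_samples, keep_monomorphic=keep_monomorphic)
    return geno


def default_popmap(n_samples: Mapping[str, int]) -> PopulationMap:
    """Population map matching the sample IDs ``simulate_neutral`` emits."""
    return PopulationMap(
        {f"{pop}_{j:03d}": pop for pop, n in n_samples.items() for j in range(n)}
    )


# ---------------------------------------------------------------------------
# post-hoc dataset shaping
# ---------------------------------------------------------------------------

def inject_differentiation(
    geno: GenotypeMatrix,
    popmap: PopulationMap,
    target_pop: str,
    loci: Sequence[int],
    shift: float,
    seed: int | np.random.SeedSequence = 0,
) -> GenotypeMatrix:
    """Resample the target population's genotypes at chosen loci from a
    binomial with allele frequency ``min(1, p + shift)``.

    A positive-control generator for the selection scan: other populations are
    untouched, so the shifted loci carry target-specific differentiation.
    ``shift == 0`` is the identity (no resampling at all).
    """
    if not (0 <= shift <= 1):
        raise ValueError("shift must be in [0, 1]")
    if target_pop not in popmap.populations:
        raise ValueError(f"target population {target_pop!r} not in population map")
    loci = np.asarray(loci, dtype=np.intp)
    out = GenotypeMatrix(geno.variants.copy(), list(geno.samples), geno.genotypes.copy())
    if shift == 0 or loci.size == 0:
        return out
    cols = popmap.indices(geno, target_pop)
    freq_all = geno.alt_freq()
    bad = ~((freq_all[loci] > 0) & (freq_all[loci] < 1))
    if bad.any():
        raise ValueError(f"loci not polymorphic: {loci[bad].tolist()}")
    rng = np.random.default_rng(seed)
    p = geno.alt_freq(cols)[loci]
    p = np.where(np.isnan(p), freq_all[loci], p)
    p_new = np.minimum(1.0, p + shift)
    g = out.genotypes
    sub = g[np.ix_(loci, cols)]
    draw = rng.binomial(2, p_new[:, None], size=sub.shape).astype(np.int8)
    draw[sub < 0] = -1  # keep missing calls missing
    g[np.ix_(loci, cols)] = draw
    return out


def add_missingness(
    geno: GenotypeMatrix, rate: float, seed: int | np.random.SeedSequence = 0
) -> GenotypeMatrix:
    """Corrupt called genotypes to missing with the given per-call rate."""
    if not (0 <= rate <= 1):
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = geno.genotypes.copy()
    drop = (rng.random(g.shape) < rate) & (g >= 0)
    g[drop] = -1
    return GenotypeMatrix(geno.variants.copy(), list(geno.samples), g)


def attach_depth(
    geno: GenotypeMatrix,
    mean: float = 100.0,
    sd: float = 25.0,
    seed: int | np.random.SeedSequence = 0,
) -> GenotypeMatrix:
    """Attach a simulated per-site mean depth (truncated normal, floor 1,
    integer-valued so VCF DP round-trips exactly)."""
    rng = np.random.default_rng(seed)
    d = np.maximum(1.0, rng.normal(mean, sd, size=geno.n_variants))
    v = geno.variants.copy()
    v["depth"] = np.round(d)
    return GenotypeMatrix(v, list(geno.samples), geno.genotypes.copy())


# ---------------------------------------------------------------------------
# exome structure
# ---------------------------------------------------------------------------

def _draw_counts(snp_count_sampler, rng: np.random.Generator, n: int) -> np.ndarray:
    if isinstance(snp_count_sampler, (int, np.integer)):
        counts = np.full(n, int(snp_count_sampler))
    elif callable(snp_count_sampler):
        counts = np.asarray(snp_count_sampler(rng, n), dtype=np.int64)
    else:
        raise TypeError("snp_count_sampler must be an int or callable(rng, n)")
    if counts.shape != (n,):
        raise ValueError("sampler must return one count per gene")
    if ((counts < 1) | (counts > 100)).any():
        raise ValueError("SNP counts per gene must lie in 1..100")
    return counts


def make_exome_structure(
    n_genes: int,
    snp_count_sampler,
    spacing: int = 2_000,
    seed: int | np.random.SeedSequence = 0,
    geno: GenotypeMatrix | None = None,
) -> GeneIntervals:
    """Build non-overlapping gene intervals with target SNP counts in 1..100.

    Without a genotype matrix, intervals are laid out on a synthetic
    coordinate system (``spacing`` bases between genes, length scaled to the
    drawn count).  With ``geno``, intervals are carved around consecutive runs
    of that matrix's SNPs so each gene contains exactly its drawn count.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    counts = _draw_counts(snp_count_sampler, rng, n_genes)
    if geno is None:
        rows = []
        cursor = 0
        for i, k in enumerate(counts):
            length = max(200, int(k) * 100)
            rows.append(("gene%05d" % (i + 1), "1", cursor, cursor + length))
            cursor += length + spacing
        return GeneIntervals(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]))
    rows = []
    i_gene = 0
    v = geno.variants
    for chrom, sub in v.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        j = 0
        while i_gene < n_genes and j + counts[i_gene] <= len(pos):
            k = int(counts[i_gene])
            first, last = pos[j], pos[j + k - 1]
            start = first - 1 if j == 0 else (pos[j - 1] + first) // 2
            if j + k < len(pos):
                end = (last + pos[j + k]) // 2
            else:
                end = last
            rows.append(("gene%05d" % (i_gene + 1), str(chrom), int(start), int(end)))
            i_gene += 1
            j += k
        if i_gene >= n_genes:
            break
    if i_gene < n_genes:
        raise ValueError(
            f"matrix has too few SNPs to realise {n_genes} genes (placed {i_gene})"
        )
    return GeneIntervals(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]))


def genes_from_regions(geno: GenotypeMatrix, prefix: str = "gene") -> GeneIntervals:
    """One gene per chromosome spanning all of its SNPs (for simulated
    multi-region datasets where each independent region is one gene)."""
    rows = []
    for i, (chrom, sub) in enumerate(geno.variants.groupby("chrom", sort=False)):
        pos = sub["pos"].to_numpy()
        rows.append((f"{prefix}{i + 1:05d}", str(chrom), int(pos[0] - 1), int(pos[-1])))
    return GeneIntervals(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]))


def emit_dataset(
    geno: GenotypeMatrix,
    popmap: PopulationMap,
    genes: GeneIntervals | None,
    outdir,
) -> dict[str, str]:
    """Write the dataset as VCF + popmap TSV + PLINK .map (+ BED for genes).

    Round-trips losslessly through :mod:`trigene.io` readers.
    """
    from . import io as tio
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(outdir / "dataset.vcf"),
        "popmap": str(outdir / "popmap.tsv"),
        "map": str(outdir / "dataset.map"),
    }
    tio.write_vcf(geno, paths["vcf"])
    tio.write_popmap(popmap, paths["popmap"])
    tio.write_plink_map(geno, paths["map"])
    if genes is not None:
        paths["bed"] = str(outdir / "genes.bed")
        tio.write_bed(genes, paths["bed"])
    return paths
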