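"""Nucleotide diversity and Weir-Cockerham differentiation.

Per-site variance components follow Weir & Cockerham (1984) for two
populations of diploids, including the observed-heterozygosity term.  The
aggregate estimator is the standard ratio of averages, ``sum(a) /
sum(a+b+c)``; sites monomorphic across the pair are excluded from both sums.
Negative aggregates are reported as computed and only clamped downstream
(tree building, the -log(1-FST) transform).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PopulationMap

__all__ = [
    "FstComponents",
    "FstMatrix",
    "nucleotide_diversity",
    "wc_site_components",
    "wc_fst",
    "pairwise_fst_matrix",
    "fst_nj_tree",
]


@dataclass
class FstComponents:
    """Per-site Weir-Cockerham components for one population pair."""

    a: np.ndarray  # among-population component
    d: np.ndarray  # a + b + c
    n_a: np.ndarray  # called diploids, first population
    n_b: np.ndarray  # called diploids, second population
    usable: np.ndarray  # bool: enters the ratio-of-averages aggregation

    def aggregate(self) -> float:
        den = self.d[self.usable].sum()
        if not self.usable.any() or den == 0:
            raise ValueError("no usable sites for FST aggregation")
        return float(self.a[self.usable].sum() / den)


@dataclass
class FstMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    n_sites: np.ndarray  # usable-site counts per pair

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def nucleotide_diversity(
    geno: GenotypeMatrix, popmap: PopulationMap, pop: str
) -> float:
    """Mean pairwise difference per usable site (unbiased pi).

    Per site with ``n`` called allele copies and alternate frequency ``p``,
    the unbiased mean pairwise difference is ``2*p*(1-p)*n/(n-1)``; missing
    genotypes are excluded sitewise and sites with fewer than two called
    alleles are unusable.
    """
    cols = popmap.indices(geno, pop)
    if len(cols) < 2:
        raise ValueError(f"population {pop!r} needs >=2 diploids for pi")
    ac, an = geno.allele_counts(cols)
    usable = an >= 2
    if not usable.any():
        raise ValueError("no usable sites for nucleotide diversity")
    p = ac[usable] / an[usable]
    n = an[usable]
    per_site = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return float(per_site.mean())


def wc_site_components(
    geno: GenotypeMatrix, cols_a: np.ndarray, cols_b: np.ndarray
) -> FstComponents:
    """Vectorised per-site a, b, c components for two diploid samples.

    Sites need at least one called diploid in each population and more than
    one on average (the within-component has an ``n_bar - 1`` divisor);
    sites monomorphic across the pair are flagged unusable.
    """
    ga = geno.genotypes[:, cols_a]
    gb = geno.genotypes[:, cols_b]
    called_a = ga >= 0
    called_b = gb >= 0
    n_a = called_a.sum(axis=1)
    n_b = called_b.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = np.where(called_a, ga, 0).sum(axis=1) / (2.0 * n_a)
        p_b = np.where(called_b, gb, 0).sum(axis=1) / (2.0 * n_b)
        h_a = (ga == 1).sum(axis=1) / n_a
        h_b = (gb == 1).sum(axis=1) / n_b
        r = 2.0
        n_bar = (n_a + n_b) / r
        n_c = r * n_bar - (n_a**2 + n_b**2) / (r * n_bar)  # divided by (r-1)=1
        p_bar = (n_a * p_a + n_b * p_b) / (r * n_bar)
        s2 = (n_a * (p_a - p_bar) ** 2 + n_b * (p_b - p_bar) ** 2) / n_bar  # /(r-1)
        h_bar = (n_a * h_a + n_b * h_b) / (r * n_bar)
        inner = p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2.0
    d = a + b + c
    monomorphic = ((p_a == 0) & (p_b == 0)) | ((p_a == 1) & (p_b == 1))
    usable = (n_a >= 1) & (n_b >= 1) & (n_bar > 1) & ~monomorphic
    a = np.where(usable, a, 0.0)
    d = np.where(usable, d, 0.0)
    return FstComponents(a=a, d=d, n_a=n_a, n_b=n_b, usable=usable)


def wc_fst(
    geno: GenotypeMatrix, popmap: PopulationMap, pop_a: str, pop_b: str
) -> tuple[FstComponents, float]:
    """Weir-Cockerham FST between two populations (components + aggregate)."""
    comps = wc_site_components(
        geno, popmap.indices(geno, pop_a), popmap.indices(geno, pop_b)
    )
    return comps, comps.aggregate()


def pairwise_fst_matrix(geno: GenotypeMatrix, popmap: PopulationMap) -> FstMatrix:
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("need >=2 populations for a pairwise FST matrix")
    k = len(pops)
    vals = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            comps, fst = wc_fst(geno, popmap, pops[i], pops[j])
            vals[i, j] = vals[j, i] = fst
            counts[i, j] = counts[j, i] = int(comps.usable.sum())
    return FstMatrix(labels=list(pops), values=vals, n_sites=counts)


def fst_nj_tree(matrix: FstMatrix) -> str:
    """Neighbor-joining tree (Newick, unrooted) from an FST distance matrix.

    Negative distances are clamped to zero before NJ; negative NJ branch
    lengths are clamped to zero in the output.
    """
    import warnings

    from skbio import DistanceMatrix
    from skbio.tree import nj

    vals = np.asarray(matrix.values, dtype=float)
    if np.isnan(vals).any():
        raise ValueError("NaN in FST matrix")
    if len(matrix.labels) < 3:
        raise ValueError("NJ needs >=3 populations")
    if (vals < 0).any():
        warnings.warn("negative FST entries clamped to 0 for tree building")
        vals = np.clip(vals, 0.0, None)
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2.0
    tree = nj(DistanceMatrix(vals, ids=matrix.labels))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()
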