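"""Patterson-style f3 and D statistics with weighted block-jackknife errors.

Both statistics are computed from population allele frequencies, so
unpolarised VCFs work: D uses the frequency (ABBA-BABA ratio) form with the
outgroup as the fourth population, and f3 carries the standard
sample-size bias correction on the target term.  Standard errors come from a
weighted delete-one block jackknife over contiguous genetic-distance blocks
(Busing et al. 1999), weighted by per-block usable SNP counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PopulationMap

__all__ = [
    "JackknifeEstimate",
    "block_ids",
    "jackknife_ratio",
    "f3_stat",
    "d_stat",
    "gene_flow_scan",
]

DEFAULT_BLOCK_CM = 5.0
Z_THRESHOLD = 3.0


@dataclass
class JackknifeEstimate:
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_snps: int
    weights: np.ndarray  # per-block usable SNP counts
    degenerate: bool = False  # all blocks identical; SE collapsed to 0

    def to_row(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "z": self.z,
            "n_snps": self.n_snps,
            "n_blocks": self.n_blocks,
        }


def block_ids(geno: GenotypeMatrix, block_cm: float = DEFAULT_BLOCK_CM) -> np.ndarray:
    """Contiguous genetic-distance block index per variant.

    Blocks never span chromosomes; within a chromosome they are windows of
    ``block_cm`` centimorgans (sites without genetic positions fall into one
    block per chromosome).
    """
    v = geno.variants
    out = np.zeros(len(v), dtype=np.int64)
    next_id = 0
    for _, sub in v.groupby("chrom", sort=False):
        cm = sub["cm"].to_numpy(dtype=float)
        if np.all(np.isnan(cm)):
            out[sub.index] = next_id
            next_id += 1
            continue
        base = np.nanmin(cm)
        local = np.floor((cm - base) / block_cm).astype(np.int64)
        local[np.isnan(cm)] = 0
        # renumber to consecutive ids
        uniq, inv = np.unique(local, return_inverse=True)
        out[sub.index] = next_id + inv
        next_id += len(uniq)
    return out


def jackknife_ratio(
    num: np.ndarray, den: np.ndarray, blocks: np.ndarray
) -> JackknifeEstimate:
    """Weighted delete-one-block jackknife for a ratio statistic
    ``sum(num)/sum(den)`` with per-block SNP-count weights."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    blocks = np.asarray(blocks)
    uniq, inv = np.unique(blocks, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("need >=2 non-empty blocks for a jackknife SE")
    num_b = np.bincount(inv, weights=num, minlength=g)
    den_b = np.bincount(inv, weights=den, minlength=g)
    m_j = np.bincount(inv, minlength=g).astype(float)
    n = float(m_j.sum())
    tot_num, tot_den = num_b.sum(), den_b.sum()
    if tot_den == 0:
        raise ValueError("zero denominator for ratio statistic")
    theta = tot_num / tot_den
    del_den = tot_den - den_b
    if np.any(del_den == 0):
        raise ValueError("a delete-one block leaves a zero denominator")
    theta_j = (tot_num - num_b) / del_den
    h_j = n / m_j
    theta_jack = g * theta - float(np.sum((1.0 - m_j / n) * theta_j))
    tau = h_j * theta - (h_j - 1.0) * theta_j
    var = float(np.mean((tau - theta_jack) ** 2 / (h_j - 1.0)))
    se = np.sqrt(var)
    degenerate = se == 0 or not np.isfinite(se)
    if degenerate:
        z = 0.0 if theta == 0 else np.sign(theta) * np.inf
    else:
        z = theta / se
    return JackknifeEstimate(
        estimate=float(theta),
        se=float(se),
        z=float(z),
        n_blocks=g,
        n_snps=int(n),
        weights=m_j,
        degenerate=bool(degenerate),
    )


def _pop_freqs(geno: GenotypeMatrix, popmap: PopulationMap, pops: list[str]):
    freqs, ns = [], []
    for p in pops:
        cols = popmap.indices(geno, p)
        ac, an = geno.allele_counts(cols)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs.append(np.where(an > 0, ac / an, np.nan))
        ns.append(an)
    return freqs, ns


def f3_stat(
    geno: GenotypeMatrix,
    popmap: PopulationMap,
    target: str,
    pop_a: str,
    pop_b: str,
    block_cm: float = DEFAULT_BLOCK_CM,
) -> JackknifeEstimate:
    """f3(target; A, B) with target sample-bias correction.

    Per usable site: ``(p_t - p_A)(p_t - p_B) - p_t(1-p_t)/(n_t - 1)`` with
    ``n_t`` the called allele copies in the target.  Outgroup-f3 (target =
    outgroup; larger = closer A,B affinity) and admixture-f3 (significantly
    negative => target admixed) are the same computation.
    """
    if len({target, pop_a, pop_b}) != 3:
        raise ValueError("f3 needs three distinct populations")
    (pt, pa, pb), (nt, _, _) = _pop_freqs(geno, popmap, [target, pop_a, pop_b])
    usable = ~np.isnan(pt) & ~np.isnan(pa) & ~np.isnan(pb) & (nt >= 2)
    if not usable.any():
        raise ValueError("no usable sites for f3")
    val = (pt - pa) * (pt - pb) - pt * (1.0 - pt) / (nt - 1.0)
    num = np.where(usable, val, 0.0)[usable]
    blocks = block_ids(geno, block_cm)[usable]
    return jackknife_ratio(num, np.ones_like(num), blocks)


def d_stat(
    geno: GenotypeMatrix,
    popmap: PopulationMap,
    pop1: str,
    pop2: str,
    pop3: str,
    outgroup: str,
    block_cm: float = DEFAULT_BLOCK_CM,
) -> JackknifeEstimate:
    """ABBA-BABA D for the tree ((pop1, pop2), pop3, outgroup).

    ``D = sum (p1-p2)(p3-p4) / sum (p1+p2-2 p1 p2)(p3+p4-2 p3 p4)``; positive
    D means excess allele sharing between pop1 and pop3.  Sites with an
    undefined frequency in any population are skipped.
    """
    if len({pop1, pop2, pop3, outgroup}) != 4:
        raise ValueError("D needs four distinct populations")
    (p1, p2, p3, p4), _ = _pop_freqs(geno, popmap, [pop1, pop2, pop3, outgroup])
    usable = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(p4))
    num = (p1 - p2) * (p3 - p4)
    den = (p1 + p2 - 2 * p1 * p2) * (p3 + p4 - 2 * p3 * p4)
    informative = usable & (den != 0)
    if not informative.any():
        raise ValueError("no informative sites for D (zero denominator)")
    blocks = block_ids(geno, block_cm)[informative]
    return jackknife_ratio(num[informative], den[informative], blocks)


def gene_flow_scan(
    geno: GenotypeMatrix,
    popmap: PopulationMap,
    pairs: list[tuple[str, str]],
    donors: list[str],
    outgroup: str,
    block_cm: float = DEFAULT_BLOCK_CM,
    z_threshold: float = Z_THRESHOLD,
) -> pd.DataFrame:
    """D statistic for every (pair x donor) cell.

    A cell with ``|Z| > z_threshold`` is flagged; the sign of D points at the
    recipient (positive => excess sharing with pop1, negative => pop2).
    Per-cell failures are recorded and the scan continues.
    """
    rows = []
    for pop1, pop2 in pairs:
        for donor in donors:
            row = {"pop1": pop1, "pop2": pop2, "donor": donor, "outgroup": outgroup}
            try:
                est = d_stat(geno, popmap, pop1, pop2, donor, outgroup, block_cm)
            except (ValueError, KeyError) as exc:
                row.update(
                    {"d": np.nan, "se": np.nan, "z": np.nan, "n_snps": 0,
                     "n_blocks": 0, "flagged": False, "recipient": "", "error": str(exc)}
                )
                rows.append(row)
                continue
            flagged = abs(est.z) > z_threshold and not est.degenerate
            recipient = ""
            if flagged:
                recipient = pop1 if est.estimate > 0 else pop2
            row.update(
                {
                    "d": est.estimate,
                    "se": est.se,
                    "z": est.z,
                    "n_snps": est.n_snps,
                    "n_blocks": est.n_blocks,
                    "flagged": flagged,
                    "recipient": recipient,
                    "error": "",
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)
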