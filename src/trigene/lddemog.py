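"""LD-decay effective population size and divergence-time estimation.

Pairs of SNPs closer than 0.25 cM are binned by genetic distance; the mean
composite (genotype-dosage) r-squared in each bin, corrected by the sample
size as ``r2 - 1/n``, yields an effective size for a past time horizon:

    Ne = [(1 / r2_adj) - 2] * 1 / (4 c)        t = 1 / (2 c) generations

with ``c`` the bin's recombination distance in Morgans, so 0.01-0.25 cM maps
to 5000-200 generations before present.  Divergence time between two
populations is ``2 * Ne * FST`` with Ne the average of the two harmonic-mean
sizes over the distance categories relevant to the divergence window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PopulationMap

__all__ = ["LDBin", "binned_r2", "ne_trajectory", "divergence_2nefst", "ld_prune"]

MAX_CM_DEFAULT = 0.25
BIN_WIDTH_CM_DEFAULT = 0.01
# The Sved-type inversion behind ne_trajectory assumes the r2 expectation of
# common variants; rare-variant pairs have systematically low r2 and inflate
# Ne well beyond its true value (checked against an independent coalescent
# simulator), hence the default MAF floor of 0.10 for LD pairs.
MAF_DEFAULT = 0.10
MAP_GAP_CM = 1.0  # pairs spanning a larger gap between adjacent markers are dropped


@dataclass
class LDBin:
    c: float  # bin-midpoint recombination distance, Morgans
    r2_adj: float  # mean composite r2 minus 1/n
    n_pairs: int
    ne: float = np.nan
    t: float = np.nan  # 1/(2c) generations before present
    valid: bool = False


def binned_r2(
    geno: GenotypeMatrix,
    popmap: PopulationMap,
    pop: str,
    max_cm: float = MAX_CM_DEFAULT,
    bin_width_cm: float = BIN_WIDTH_CM_DEFAULT,
    maf_min: float = MAF_DEFAULT,
) -> list[LDBin]:
    """Mean adjusted composite r2 per genetic-distance bin for one population.

    Composite r2 is the squared Pearson correlation of genotype dosages (no
    phasing required).  Only same-chromosome pairs with distance strictly
    less than ``max_cm`` enter; bins with no pairs are reported with
    ``n_pairs=0``.
    """
    cols = popmap.indices(geno, pop)
    n = len(cols)
    if n < 10:
        raise ValueError(f"population {pop!r} needs >=10 diploids for adjusted r2")
    n_bins = int(np.ceil(max_cm / bin_width_cm))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    freq = geno.alt_freq(cols)
    maf = np.minimum(freq, 1 - freq)
    for _, sub in geno.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        cm = sub["cm"].to_numpy(dtype=float)
        ok = ~np.isnan(cm) & (maf[idx] >= maf_min)
        idx, cm = idx[ok], cm[ok]
        if idx.size < 2:
            continue
        g = geno.genotypes[np.ix_(idx, cols)].astype(float)
        g[g < 0] = np.nan
        mean = np.nanmean(g, axis=1, keepdims=True)
        z = g - mean
        z[np.isnan(z)] = 0.0
        norm = np.sqrt((z**2).sum(axis=1))
        norm[norm == 0] = np.nan
        z /= norm[:, None]
        # map-gap breakpoints: treat long inter-marker gaps as chromosome ends
        gap_break = np.concatenate(([0], np.flatnonzero(np.diff(cm) > MAP_GAP_CM) + 1, [idx.size]))
        for s, e in zip(gap_break[:-1], gap_break[1:]):
            for i in range(s, e - 1):
                hi = np.searchsorted(cm[s:e], cm[i] + max_cm, side="left") + s
                if hi <= i + 1:
                    continue
                r = z[i + 1 : hi] @ z[i]
                d = cm[i + 1 : hi] - cm[i]
                b = np.minimum((d / bin_width_cm).astype(np.int64), n_bins - 1)
                good = ~np.isnan(r)
                np.add.at(sums, b[good], r[good] ** 2)
                np.add.at(counts, b[good], 1)
    out = []
    for k in range(n_bins):
        c = (k + 0.5) * bin_width_cm / 100.0  # Morgans
        if counts[k] == 0:
            out.append(LDBin(c=c, r2_adj=np.nan, n_pairs=0))
        else:
            out.append(LDBin(c=c, r2_adj=sums[k] / counts[k] - 1.0 / n, n_pairs=int(counts[k])))
    return out


def ne_trajectory(bins: list[LDBin]) -> list[LDBin]:
    """Fill in the Ne estimate and time horizon per bin.

    Bins whose adjusted r2 gives a non-positive Ne (or that hold no pairs)
    are flagged invalid and excluded from downstream harmonic means.
    """
    out = []
    for b in bins:
        nb = LDBin(c=b.c, r2_adj=b.r2_adj, n_pairs=b.n_pairs)
        nb.t = 1.0 / (2.0 * b.c)
        if b.n_pairs > 0 and np.isfinite(b.r2_adj) and b.r2_adj > 0:
            ne = (1.0 / b.r2_adj - 2.0) / (4.0 * b.c)
            if ne > 0:
                nb.ne = ne
                nb.valid = True
        out.append(nb)
    return out


def trajectory_frame(bins: list[LDBin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "c_cm": [b.c * 100 for b in bins],
            "t_gen": [b.t for b in bins],
            "n_pairs": [b.n_pairs for b in bins],
            "r2_adj": [b.r2_adj for b in bins],
            "ne": [b.ne for b in bins],
            "valid": [b.valid for b in bins],
        }
    )


def _harmonic_mean_ne(bins: list[LDBin], t_lo: float, t_hi: float) -> float:
    vals = [b.ne for b in bins if b.valid and t_lo <= b.t <= t_hi]
    if not vals:
        raise ValueError(f"no valid Ne bins with t in [{t_lo:g}, {t_hi:g}]")
    inv = np.mean([1.0 / v for v in vals])
    return float(1.0 / inv)


def divergence_2nefst(
    traj_a: list[LDBin],
    traj_b: list[LDBin],
    fst: float,
    t_window: tuple[float, float] | None = None,
    iterate: bool = True,
    tol: float = 0.05,
    max_iter: int = 20,
) -> float:
    """Divergence time ``T = 2 * Ne * FST`` in generations.

    Ne is the arithmetic mean of the two populations' harmonic-mean Ne over
    bins whose time horizon falls inside the window.  With ``iterate`` the
    window is re-centred on the current T ([T/2, 2T]) until T changes by less
    than ``tol`` (relative), so only the distance categories relevant to the
    divergence depth contribute.
    """
    if not (0 <= fst < 1):
        raise ValueError("fst must be in [0, 1)")
    if fst == 0:
        return 0.0
    window = t_window if t_window is not None else (200.0, 5000.0)
    t_est = None
    for _ in range(max_iter):
        ne = 0.5 * (
            _harmonic_mean_ne(traj_a, *window) + _harmonic_mean_ne(traj_b, *window)
        )
        new_t = 2.0 * ne * fst
        if t_est is not None and abs(new_t - t_est) <= tol * t_est:
            return float(new_t)
        t_est = new_t
        if not iterate:
            return float(t_est)
        window = (t_est / 2.0, t_est * 2.0)
        lo = min(b.t for b in traj_a if b.valid)
        hi = max(b.t for b in traj_a if b.valid)
        window = (max(window[0], lo), min(window[1], hi))
        if window[0] >= window[1]:
            window = (lo, hi)
    return float(t_est)


def ld_prune(
    geno: GenotypeMatrix,
    window_bp: int = 1_000,
    step_snps: int = 100,
    r2_max: float = 0.2,
) -> GenotypeMatrix:
    """Greedy LD pruning: windows of ``window_bp`` bases advanced by
    ``step_snps`` SNPs; within a window, every pair with r2 above ``r2_max``
    loses its later-position member (the earlier SNP is kept)."""
    keep = np.ones(geno.n_variants, dtype=bool)
    g_all = geno.genotypes.astype(float)
    g_all[g_all < 0] = np.nan
    for _, sub in geno.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        start = 0
        while start < len(idx):
            hi = np.searchsorted(pos, pos[start] + window_bp, side="left")
            window = idx[start:hi]
            if window.size >= 2:
                g = g_all[window]
                for i in range(len(window)):
                    if not keep[window[i]]:
                        continue
                    for j in range(i + 1, len(window)):
                        if not keep[window[j]]:
                            continue
                        r2 = _pair_r2(g[i], g[j])
                        if r2 > r2_max:
                            keep[window[j]] = False
            start += step_snps
    return geno.take_sites(keep)


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0  # monomorphic column: no LD information
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)
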