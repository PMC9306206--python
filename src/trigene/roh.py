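"""Runs of homozygosity via a two-state HMM with Viterbi decoding.

States are HW (non-autozygous: genotypes follow Hardy-Weinberg at the site's
population allele frequency) and AZ (autozygous: only homozygotes, with
probabilities proportional to allele frequencies).  Observed genotypes are
the true ones passed through a symmetric genotyping-error channel whose rate
is given on the phred scale (the ``-G 30`` convention: error probability
``10**(-30/10) = 1e-3``).  Transition probabilities between consecutive
sites are per-base exponential rates, so sparse regions switch state more
easily.  Maximal AZ runs from first to last AZ site become segments, classed
short (< 1 Mb), medium (1-5 Mb, boundaries inclusive) or long (> 5 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PopulationMap

__all__ = ["ROHSegment", "roh_call", "roh_classify_totals", "classify_length"]

GT_ERROR_PHRED_DEFAULT = 30.0
A_HW_AZ_DEFAULT = 5e-9  # per-bp rate of entering autozygosity
A_AZ_HW_DEFAULT = 5e-8  # per-bp rate of leaving autozygosity
SHORT_MAX = 1_000_000
MEDIUM_MAX = 5_000_000


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_sites: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def cls(self) -> str:
        return classify_length(self.length)


def classify_length(length: int) -> str:
    """Short < 1 Mb; medium 1-5 Mb (both boundaries inclusive); long > 5 Mb."""
    if length < SHORT_MAX:
        return "short"
    if length <= MEDIUM_MAX:
        return "medium"
    return "long"


def _emission_logs(gt: np.ndarray, p: np.ndarray, err: float) -> np.ndarray:
    """log P(observed genotype | state) for states (HW, AZ), shape (2, S).

    The observed genotype equals the true one with probability 1-err, or one
    of the two other genotypes with probability err/2 each.
    """
    q = 1.0 - p
    true_hw = np.stack([q * q, 2 * p * q, p * p])  # genotype 0/1/2 under HW
    true_az = np.stack([q, np.zeros_like(p), p])
    channel = np.full((3, 3), err / 2.0)
    np.fill_diagonal(channel, 1.0 - err)
    obs_hw = channel.T @ true_hw  # (obs, site)
    obs_az = channel.T @ true_az
    s = len(p)
    idx = (gt, np.arange(s))
    out = np.stack([obs_hw[idx], obs_az[idx]])
    return np.log(np.maximum(out, 1e-300))


def _viterbi(
    log_emit: np.ndarray, pos: np.ndarray, a_hw_az: float, a_az_hw: float
) -> np.ndarray:
    """Two-state Viterbi with distance-dependent transitions; returns the
    state path (0 = HW, 1 = AZ)."""
    s = log_emit.shape[1]
    # stationary-ish prior from the rates
    pi_az = a_hw_az / (a_hw_az + a_az_hw)
    delta = np.empty((2, s))
    delta[0, 0] = np.log(1 - pi_az) + log_emit[0, 0]
    delta[1, 0] = np.log(pi_az) + log_emit[1, 0]
    back = np.zeros((2, s), dtype=np.int8)
    d = np.diff(pos).astype(float)
    p_enter = 1.0 - np.exp(-a_hw_az * d)
    p_leave = 1.0 - np.exp(-a_az_hw * d)
    log_t = np.log(
        np.maximum(
            np.stack(
                [
                    np.stack([1 - p_enter, p_enter]),  # from HW: stay, enter
                    np.stack([p_leave, 1 - p_leave]),  # from AZ: leave, stay
                ]
            ),
            1e-300,
        )
    )  # (from, to, step)
    for i in range(1, s):
        for to in (0, 1):
            cand = delta[:, i - 1] + log_t[:, to, i - 1]
            src = int(np.argmax(cand))
            back[to, i] = src
            delta[to, i] = cand[src] + log_emit[to, i]
    path = np.empty(s, dtype=np.int8)
    path[-1] = int(np.argmax(delta[:, -1]))
    for i in range(s - 1, 0, -1):
        path[i - 1] = back[path[i], i]
    return path


def roh_call(
    geno: GenotypeMatrix,
    sample: str,
    allele_freqs: np.ndarray | None = None,
    gt_error_phred: float = GT_ERROR_PHRED_DEFAULT,
    a_hw_az: float = A_HW_AZ_DEFAULT,
    a_az_hw: float = A_AZ_HW_DEFAULT,
) -> list[ROHSegment]:
    """Call ROH segments for one individual.

    ``allele_freqs`` are per-site alternate-allele frequencies; when absent
    they are computed from the full cohort (mirroring a joint-called VCF).
    Chromosomes with fewer than two called sites are skipped.
    """
    if sample not in geno.samples:
        raise KeyError(f"sample {sample!r} not in matrix")
    col = geno.samples.index(sample)
    if allele_freqs is None:
        allele_freqs = geno.alt_freq()
    err = 10.0 ** (-gt_error_phred / 10.0)
    segments: list[ROHSegment] = []
    for chrom, sub in geno.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        gt = geno.genotypes[idx, col]
        called = gt >= 0
        idx, gt = idx[called], gt[called]
        if idx.size < 2:
            continue
        pos = geno.variants["pos"].to_numpy()[idx]
        p = np.clip(np.asarray(allele_freqs)[idx].astype(float), 1e-6, 1 - 1e-6)
        log_emit = _emission_logs(gt.astype(np.intp), p, err)
        path = _viterbi(log_emit, pos, a_hw_az, a_az_hw)
        # maximal AZ runs
        in_run = False
        start_i = 0
        for i, state in enumerate(np.append(path, 0)):
            if state == 1 and not in_run:
                in_run, start_i = True, i
            elif state != 1 and in_run:
                in_run = False
                segments.append(
                    ROHSegment(
                        sample=sample,
                        chrom=str(chrom),
                        start=int(pos[start_i]),
                        end=int(pos[i - 1]),
                        n_sites=i - start_i,
                    )
                )
    return segments


def roh_classify_totals(segments: list[ROHSegment]) -> pd.DataFrame:
    """Per-individual summed ROH length (bp) in each length class."""
    rows: dict[str, dict[str, int]] = {}
    for seg in segments:
        d = rows.setdefault(seg.sample, {"short": 0, "medium": 0, "long": 0})
        d[seg.cls] += seg.length
    out = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    out.index.name = "sample"
    for c in ("short", "medium", "long"):
        if c not in out.columns:
            out[c] = 0
    return out[["short", "medium", "long"]]


def population_roh_summary(
    totals: pd.DataFrame, popmap: PopulationMap
) -> pd.DataFrame:
    """Population-level mean per-individual totals in each class."""
    t = totals.copy()
    t["population"] = [popmap.assignments.get(s, "?") for s in t.index]
    return t.groupby("population")[["short", "medium", "long"]].mean()


def segments_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": s.sample,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "length": s.length,
                "n_sites": s.n_sites,
                "class": s.cls,
            }
            for s in segments
        ],
        columns=["sample", "chrom", "start", "end", "length", "n_sites", "class"],
    )
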