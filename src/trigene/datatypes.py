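"""Core in-memory containers shared by every pipeline stage.

Genotypes are stored as a dense ``(n_variants, n_samples)`` int8 matrix of
alternate-allele counts (0/1/2) with ``-1`` marking a missing diploid call.
Variant metadata (physical and genetic coordinates, alleles, ancestral state,
mean depth) lives in a pandas DataFrame aligned row-for-row with the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: columns every GenotypeMatrix.variants frame carries, in order
VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "aa", "cm", "depth")


@dataclass
class GenotypeMatrix:
    """Biallelic SNV genotypes for a sample cohort.

    Parameters
    ----------
    variants
        DataFrame with columns ``chrom`` (str), ``pos`` (1-based int),
        ``ref``/``alt`` (single bases), ``aa`` (ancestral allele or ``"."``),
        ``cm`` (genetic position in centimorgans, NaN if no map attached) and
        ``depth`` (mean site depth, NaN when unknown).
    samples
        Ordered sample identifiers.
    genotypes
        int8 array, shape ``(len(variants), len(samples))``, values in
        ``{-1, 0, 1, 2}``.
    """

    variants: pd.DataFrame
    samples: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                if col == "aa":
                    self.variants["aa"] = "."
                elif col in ("cm", "depth"):
                    self.variants[col] = np.nan
                else:
                    raise ValueError(f"variants frame lacks required column {col!r}")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )

    # -- basic facts ----------------------------------------------------
    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        g = self.genotypes
        bad = ~np.isin(g, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotypes outside {-1,0,1,2}")
        pos = self.variants["pos"].to_numpy()
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            cm = sub["cm"].to_numpy(dtype=float)
            if not np.all(np.isnan(cm)):
                if np.any(np.diff(cm) < 0):
                    raise ValueError(f"genetic positions decreasing on {chrom}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        _ = pos

    # -- slicing --------------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given variant rows."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            variants=self.variants.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
            genotypes=self.genotypes[index],
        )

    def sample_indices(self, names: Iterable[str]) -> np.ndarray:
        lut = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lut[n] for n in names], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    # -- per-site summaries ---------------------------------------------
    def allele_counts(self, cols: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (alt allele count, called allele count) per site for the
        given sample columns (all samples when None)."""
        g = self.genotypes if cols is None else self.genotypes[:, cols]
        called = g >= 0
        ac = np.where(called, g, 0).sum(axis=1, dtype=np.int64)
        an = 2 * called.sum(axis=1, dtype=np.int64)
        return ac, an

    def alt_freq(self, cols: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per site; NaN where no calls."""
        ac, an = self.allele_counts(cols)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, ac / an, np.nan)

    def missing_rate(self) -> np.ndarray:
        return (self.genotypes < 0).mean(axis=1)

    def variant_keys(self) -> pd.Index:
        v = self.variants
        return pd.Index(
            v["chrom"].astype(str) + ":" + v["pos"].astype(str) + ":" + v["ref"] + ":" + v["alt"]
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        if self.samples != other.samples:
            return False
        if not np.array_equal(self.genotypes, other.genotypes):
            return False
        a = self.variants[list(VARIANT_COLUMNS)]
        b = other.variants[list(VARIANT_COLUMNS)]
        if len(a) != len(b):
            return False
        for col in ("chrom", "pos", "ref", "alt", "aa"):
            if not (a[col].to_numpy() == b[col].to_numpy()).all():
                return False
        for col in ("cm", "depth"):
            x = a[col].to_numpy(dtype=float)
            y = b[col].to_numpy(dtype=float)
            same = np.isclose(x, y, rtol=0, atol=1e-6) | (np.isnan(x) & np.isnan(y))
            if not same.all():
                return False
        return True


@dataclass
class PopulationMap:
    """Assignment of every sample to exactly one population."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("empty population map")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p)
        return list(seen)

    def samples(self, pop: str) -> list[str]:
        out = [s for s, p in self.assignments.items() if p == pop]
        if not out:
            raise KeyError(f"population {pop!r} not present in population map")
        return out

    def indices(self, geno: GenotypeMatrix, pop: str) -> np.ndarray:
        return geno.sample_indices(self.samples(pop))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PopulationMap":
        return cls(dict(pairs))


@dataclass
class GeneIntervals:
    """Gene intervals in BED convention (0-based half-open)."""

    records: pd.DataFrame  # gene_id, chrom, start, end

    def __post_init__(self) -> None:
        r = self.records.reset_index(drop=True)
        required = {"gene_id", "chrom", "start", "end"}
        if not required.issubset(r.columns):
            raise ValueError(f"gene records need columns {sorted(required)}")
        if r["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        if (r["start"] >= r["end"]).any():
            raise ValueError("gene with start >= end")
        self.records = r

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records["gene_id"])

    def snp_indices(self, geno: GenotypeMatrix) -> dict[str, np.ndarray]:
        """Map each gene to the variant-row indices it contains.

        A 1-based variant position ``pos`` falls in BED interval
        ``[start, end)`` when ``start < pos <= end``.
        """
        out: dict[str, np.ndarray] = {}
        v = geno.variants
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in v.groupby("chrom", sort=False):
            by_chrom[str(chrom)] = (sub["pos"].to_numpy(), sub.index.to_numpy())
        for rec in self.records.itertuples(index=False):
            chrom = str(rec.chrom)
            if chrom not in by_chrom:
                out[rec.gene_id] = np.array([], dtype=np.intp)
                continue
            pos, idx = by_chrom[chrom]
            lo = np.searchsorted(pos, rec.start, side="right")  # pos > start
            hi = np.searchsorted(pos, rec.end, side="right")  # pos <= end
            out[rec.gene_id] = idx[lo:hi]
        return out

    def snp_counts(self, geno: GenotypeMatrix) -> pd.Series:
        idx = self.snp_indices(geno)
        return pd.Series({g: len(i) for g, i in idx.items()}, name="snp_count")
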