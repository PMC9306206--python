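"""Novel-variant and loss-of-function classification.

A variant is *novel* when absent from every provided known-variant catalog
(dbSNP/ExAC-style key sets, matched on chrom:pos:ref:alt).  *Singletons* are
variants whose alternate allele count within the stated scope is exactly one
(a single heterozygote; a homozygous carrier has count two and is retained).
*LOF* variants have a HIGH impact classification, or are missense with SIFT
strictly below 0.05 (deleterious) and PolyPhen strictly above 0.446
(damaging); a missing score fails its condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PopulationMap

__all__ = [
    "AnnotationRecord",
    "SIFT_DELETERIOUS",
    "POLYPHEN_DAMAGING",
    "flag_novel",
    "exclude_singletons",
    "classify_lof",
    "classify_lof_table",
    "novelty_counts",
]

SIFT_DELETERIOUS = 0.05  # strict <
POLYPHEN_DAMAGING = 0.446  # strict >

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")


@dataclass(frozen=True)
class AnnotationRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    impact: str
    is_missense: bool
    sift_score: float | None = None
    polyphen_score: float | None = None

    def __post_init__(self) -> None:
        if self.impact not in IMPACTS:
            raise ValueError(f"impact {self.impact!r} not one of {IMPACTS}")
        for name, s in (("sift", self.sift_score), ("polyphen", self.polyphen_score)):
            if s is not None and not (0 <= s <= 1):
                raise ValueError(f"{name} score {s} outside [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def classify_lof(record: AnnotationRecord) -> bool:
    """True when the record is loss-of-function under the impact/score rule."""
    if record.impact == "HIGH":
        return True
    if not record.is_missense:
        return False
    if record.sift_score is None or record.polyphen_score is None:
        return False
    return record.sift_score < SIFT_DELETERIOUS and record.polyphen_score > POLYPHEN_DAMAGING


def classify_lof_table(annotations: pd.DataFrame) -> pd.Series:
    """Vectorised LOF call over an annotation table (io.ANNOTATION_COLUMNS
    schema; missense detected from the ``consequence`` column)."""
    impact_high = annotations["impact"] == "HIGH"
    missense = annotations["consequence"].str.contains("missense", na=False)
    sift = pd.to_numeric(annotations["sift_score"], errors="coerce")
    poly = pd.to_numeric(annotations["polyphen_score"], errors="coerce")
    harmful = (sift < SIFT_DELETERIOUS) & (poly > POLYPHEN_DAMAGING)
    return (impact_high | (missense & harmful)).rename("lof")


def flag_novel(geno: GenotypeMatrix, known_catalogs: list[set[str]]) -> np.ndarray:
    """Boolean per-variant flag: novel iff absent from every catalog."""
    keys = geno.variant_keys()
    novel = np.ones(len(keys), dtype=bool)
    for catalog in known_catalogs:
        novel &= ~keys.isin(catalog)
    return novel


def exclude_singletons(
    geno: GenotypeMatrix,
    popmap: PopulationMap | None = None,
    scope: str = "cohort",
) -> np.ndarray:
    """Boolean keep-mask that drops singletons.

    ``scope='cohort'``: alternate allele count of exactly one across all
    samples.  ``scope='population'``: a variant is dropped when every
    population that carries it does so as a singleton (so population-level
    singletons are masked).
    """
    if scope == "cohort":
        ac, _ = geno.allele_counts()
        return ac != 1
    if scope != "population":
        raise ValueError("scope must be 'population' or 'cohort'")
    if popmap is None:
        raise ValueError("population scope needs a population map")
    keep = np.zeros(geno.n_variants, dtype=bool)
    any_carried = np.zeros(geno.n_variants, dtype=bool)
    for pop in popmap.populations:
        ac, _ = geno.allele_counts(popmap.indices(geno, pop))
        keep |= ac > 1
        any_carried |= ac > 0
    # variants carried nowhere are not singletons; keep them
    return keep | ~any_carried


def novelty_counts(
    geno: GenotypeMatrix,
    popmap: PopulationMap,
    novel_flags: np.ndarray,
    keep_mask: np.ndarray | None = None,
    lof_flags: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Population- and individual-level novel-variant counts.

    Population counts come with and without the singleton mask applied;
    population-specific novel variants are those carried in exactly one
    population.  Individual counts tally novel variants the individual
    carries (genotype > 0).  When ``lof_flags`` is given, LOF subsets are
    reported alongside.
    """
    novel = np.asarray(novel_flags, dtype=bool)
    if keep_mask is None:
        keep_mask = np.ones_like(novel)
    keep_mask = np.asarray(keep_mask, dtype=bool)
    pops = popmap.populations
    carried = {}
    for pop in pops:
        ac, _ = geno.allele_counts(popmap.indices(geno, pop))
        carried[pop] = ac > 0
    n_pops_carrying = np.sum([carried[p] for p in pops], axis=0)
    pop_rows = []
    for pop in pops:
        base = novel & carried[pop]
        specific = base & (n_pops_carrying == 1)
        row = {
            "population": pop,
            "novel": int(base.sum()),
            "novel_no_singletons": int((base & keep_mask).sum()),
            "novel_specific": int(specific.sum()),
            "novel_specific_no_singletons": int((specific & keep_mask).sum()),
        }
        if lof_flags is not None:
            row["novel_lof"] = int((base & lof_flags).sum())
            row["novel_lof_no_singletons"] = int((base & lof_flags & keep_mask).sum())
        pop_rows.append(row)
    ind_rows = []
    g = geno.genotypes
    for j, sample in enumerate(geno.samples):
        carries = g[:, j] > 0
        row = {
            "sample": sample,
            "population": popmap.assignments.get(sample, "?"),
            "novel": int((novel & carries).sum()),
            "novel_no_singletons": int((novel & carries & keep_mask).sum()),
        }
        if lof_flags is not None:
            row["novel_lof"] = int((novel & carries & lof_flags).sum())
        ind_rows.append(row)
    return {
        "population": pd.DataFrame(pop_rows),
        "individual": pd.DataFrame(ind_rows),
    }
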