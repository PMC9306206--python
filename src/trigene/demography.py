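"""Population-history models driving the simulator and the selection null.

A :class:`DemographyModel` is a rooted population tree with piecewise-constant
diploid sizes, reverse-time split events, per-generation migration windows and
temporary bottlenecks.  Times are generations before present; sizes are diploid
effective sizes.  Forward simulation works on a *rescaled* copy of the model
(sizes and times divided, rates multiplied, by ``rescale_factor``), the
standard trick that preserves the scaled parameters ``4*Ne*mu``, ``4*Ne*r``,
``4*Ne*m`` and ``t/Ne`` while keeping desk-scale runtimes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "SizeEpoch",
    "Split",
    "MigrationWindow",
    "Bottleneck",
    "DemographyModel",
    "two_population_model",
    "star_tree_model",
    "pbs_null_model",
    "yunnan_model",
]


@dataclass(frozen=True)
class SizeEpoch:
    """Diploid size ``n`` applying from ``start`` generations ago onward
    (toward the past) until the next epoch, or forever."""

    start: float
    n: float


@dataclass(frozen=True)
class Split:
    """Reverse-time merge: looking backward, ``derived`` joins ``ancestral``
    at ``time`` generations before present.  Forward in time the ancestral
    population partitions at that generation."""

    time: float
    derived: str
    ancestral: str


@dataclass(frozen=True)
class MigrationWindow:
    """During ``[end, start)`` generations ago, a fraction ``rate`` of
    ``recipient``'s gametes per generation are drawn from ``donor``."""

    recipient: str
    donor: str
    rate: float
    start: float
    end: float = 0.0


@dataclass(frozen=True)
class Bottleneck:
    """Temporary diploid size ``n`` for ``pop`` during ``[end, start)``
    generations ago (overrides the epoch schedule)."""

    pop: str
    start: float
    end: float
    n: float


@dataclass
class DemographyModel:
    populations: list[str]
    sizes: dict[str, list[SizeEpoch]]
    splits: list[Split] = field(default_factory=list)
    migrations: list[MigrationWindow] = field(default_factory=list)
    bottlenecks: list[Bottleneck] = field(default_factory=list)
    mutation_rate: float = 1.2e-8
    recombination_rate: float = 1.0e-8
    rescale_factor: float = 1.0

    # -- structure -------------------------------------------------------
    def origin_time(self, pop: str) -> float | None:
        """Split time at which ``pop`` came into existence (None for the root
        lineage)."""
        for s in self.splits:
            if s.derived == pop:
                return s.time
        return None

    def parent(self, pop: str) -> str | None:
        for s in self.splits:
            if s.derived == pop:
                return s.ancestral
        return None

    def alive(self, pop: str, t: float) -> bool:
        origin = self.origin_time(pop)
        return origin is None or t < origin

    def ancestor_at(self, pop: str, t: float) -> str:
        """Walk the split chain until reaching the lineage alive at time t."""
        cur = pop
        while not self.alive(cur, t):
            parent = self.parent(cur)
            if parent is None:  # pragma: no cover - guarded by validate()
                raise ValueError(f"no ancestor of {pop} alive at t={t}")
            cur = parent
        return cur

    def size_at(self, pop: str, t: float) -> float:
        for b in self.bottlenecks:
            if b.pop == pop and b.end <= t < b.start:
                return b.n
        epochs = self.sizes[pop]
        n = epochs[0].n
        for e in epochs:
            if t >= e.start:
                n = e.n
        return n

    def migration_row(self, recipient: str, t: float) -> dict[str, float]:
        """Active donor -> rate entries for gametes produced at time ``t``."""
        row: dict[str, float] = {}
        for m in self.migrations:
            if m.recipient == recipient and m.end <= t < m.start:
                row[m.donor] = row.get(m.donor, 0.0) + m.rate
        return row

    def oldest_event_time(self) -> float:
        t = 0.0
        for s in self.splits:
            t = max(t, s.time)
        for m in self.migrations:
            t = max(t, m.start)
        for b in self.bottlenecks:
            t = max(t, b.start)
        for epochs in self.sizes.values():
            for e in epochs:
                t = max(t, e.start)
        return t

    def root(self) -> str:
        roots = [p for p in self.populations if self.origin_time(p) is None]
        if len(roots) != 1:
            raise ValueError(
                f"model must have exactly one root lineage, found {roots}"
            )
        return roots[0]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.rescale_factor < 1:
            raise ValueError("rescale_factor must be >= 1")
        if set(self.sizes) != set(self.populations):
            missing = set(self.populations) ^ set(self.sizes)
            raise ValueError(f"size schedule mismatch for populations {sorted(missing)}")
        for pop, epochs in self.sizes.items():
            if not epochs or epochs[0].start != 0:
                raise ValueError(f"{pop}: first size epoch must start at time 0")
            starts = [e.start for e in epochs]
            if sorted(starts) != starts or len(set(starts)) != len(starts):
                raise ValueError(f"{pop}: size epochs must have increasing start times")
            for e in epochs:
                if e.n <= 0:
                    raise ValueError(f"{pop}: non-positive size {e.n} at t={e.start}")
        derived_seen = set()
        for s in self.splits:
            if s.derived in derived_seen:
                raise ValueError(f"{s.derived} derived in more than one split")
            derived_seen.add(s.derived)
            if s.derived not in self.populations or s.ancestral not in self.populations:
                raise ValueError(f"split references unknown population: {s}")
            if s.time <= 0:
                raise ValueError(f"split time must be positive: {s}")
            anc_origin = self.origin_time(s.ancestral)
            if anc_origin is not None and anc_origin <= s.time:
                raise ValueError(
                    f"split times not ordered along lineage: {s.derived} splits from "
                    f"{s.ancestral} at {s.time} but {s.ancestral} only exists after "
                    f"{anc_origin}"
                )
        self.root()  # single-root check
        for b in self.bottlenecks:
            if b.pop not in self.populations:
                raise ValueError(f"bottleneck on unknown population {b.pop}")
            if not (b.start > b.end >= 0) or b.n <= 0:
                raise ValueError(f"invalid bottleneck {b}")
        # migration sanity: rates in [0,1), recipient row sums < 1 at window starts
        checkpoints = sorted({m.end for m in self.migrations} | {m.start - 1e-9 for m in self.migrations})
        for m in self.migrations:
            if not (0 <= m.rate < 1):
                raise ValueError(f"migration rate out of range: {m}")
            if m.recipient not in self.populations or m.donor not in self.populations:
                raise ValueError(f"migration references unknown population: {m}")
            if not (m.start > m.end >= 0):
                raise ValueError(f"invalid migration window {m}")
        for t in checkpoints:
            for pop in self.populations:
                total = sum(self.migration_row(pop, t).values())
                if total >= 1:
                    raise ValueError(
                        f"migration into {pop} at t={t} sums to {total} >= 1"
                    )
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be non-negative")

    # -- rescaling -------------------------------------------------------
    def rescaled(self) -> "DemographyModel":
        """Return the model in simulation units (factor applied)."""
        q = self.rescale_factor
        if q == 1:
            out = replace(self)
            out.validate()
            return out

        def t_(t: float) -> float:
            return round(t / q)

        def n_(n: float) -> float:
            return max(2, round(n / q))

        sizes = {
            pop: _dedupe_epochs([SizeEpoch(t_(e.start), n_(e.n)) for e in epochs])
            for pop, epochs in self.sizes.items()
        }
        splits = [Split(max(1, t_(s.time)), s.derived, s.ancestral) for s in self.splits]
        migrations = [
            MigrationWindow(m.recipient, m.donor, min(m.rate * q, 0.45), max(1, t_(m.start)), t_(m.end))
            for m in self.migrations
        ]
        bottlenecks = []
        for b in self.bottlenecks:
            start, end = t_(b.start), t_(b.end)
            if start <= end:
                start = end + 1  # keep at least one rescaled generation
            bottlenecks.append(Bottleneck(b.pop, start, end, n_(b.n)))
        out = DemographyModel(
            populations=list(self.populations),
            sizes=sizes,
            splits=splits,
            migrations=migrations,
            bottlenecks=bottlenecks,
            mutation_rate=self.mutation_rate * q,
            recombination_rate=self.recombination_rate * q,
            rescale_factor=1.0,
        )
        out.validate()
        return out


def _dedupe_epochs(epochs: list[SizeEpoch]) -> list[SizeEpoch]:
    out: list[SizeEpoch] = []
    for e in epochs:
        if out and out[-1].start == e.start:
            out[-1] = e
        else:
            out.append(e)
    return out


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def two_population_model(
    n_anc: float = 10_000,
    n_a: float = 10_000,
    n_b: float = 10_000,
    split_time: float = 2_000,
    migration: float = 0.0,
    mutation_rate: float = 1.2e-8,
    recombination_rate: float = 1.0e-8,
    rescale_factor: float = 1.0,
) -> DemographyModel:
    """Clean two-population split ``(A,B)``, optional symmetric migration."""
    m = DemographyModel(
        populations=["A", "B"],
        sizes={
            "A": [SizeEpoch(0, n_a), SizeEpoch(split_time, n_anc)],
            "B": [SizeEpoch(0, n_b)],
        },
        splits=[Split(split_time, "B", "A")],
        mutation_rate=mutation_rate,
        recombination_rate=recombination_rate,
        rescale_factor=rescale_factor,
    )
    if migration > 0:
        m.migrations = [
            MigrationWindow("A", "B", migration, split_time),
            MigrationWindow("B", "A", migration, split_time),
        ]
    m.validate()
    return m


def star_tree_model(
    labels: list[str],
    split_times: list[float],
    n: float = 10_000,
    mutation_rate: float = 1.2e-8,
    recombination_rate: float = 1.0e-8,
    rescale_factor: float = 1.0,
) -> DemographyModel:
    """Serial splits: ``labels[0]`` is the root lineage; ``labels[i]`` (i>=1)
    splits from it at ``split_times[i-1]`` (strictly decreasing times)."""
    if len(split_times) != len(labels) - 1:
        raise ValueError("need one split time per non-root label")
    sizes = {lab: [SizeEpoch(0, n)] for lab in labels}
    splits = [Split(t, lab, labels[0]) for lab, t in zip(labels[1:], split_times)]
    m = DemographyModel(
        populations=list(labels),
        sizes=sizes,
        splits=splits,
        mutation_rate=mutation_rate,
        recombination_rate=recombination_rate,
        rescale_factor=rescale_factor,
    )
    m.validate()
    return m


def pbs_null_model(
    target: str = "TGT",
    second: str = "HAN",
    third: str = "CEU",
    n_target: float = 8_000,
    n_second: float = 16_000,
    n_third: float = 10_000,
    n_anc: float = 10_000,
    t_target_second: float = 600,
    t_ceu_ea: float = 2_000,
    mutation_rate: float = 1.2e-8,
    recombination_rate: float = 1.0e-8,
    rescale_factor: float = 100.0,
) -> DemographyModel:
    """Three-population null demography for the PBS scan.

    The outermost split (third population, a European-like reference) sits at
    2000 generations, the divergence assumed between Europeans and East
    Asians; the target splits from the East Asian reference more recently.
    """
    m = DemographyModel(
        populations=[third, second, target],
        sizes={
            third: [SizeEpoch(0, n_third), SizeEpoch(t_ceu_ea, n_anc)],
            second: [SizeEpoch(0, n_second)],
            target: [SizeEpoch(0, n_target)],
        },
        splits=[
            Split(t_ceu_ea, second, third),
            Split(t_target_second, target, second),
        ],
        mutation_rate=mutation_rate,
        recombination_rate=recombination_rate,
        rescale_factor=rescale_factor,
    )
    m.validate()
    return m


def yunnan_model(rescale_factor: float = 20.0) -> DemographyModel:
    """Demographic cartoon of the Western-Yunnan study system.

    Seven populations: a deep outgroup OUT; a highland clade with TBN basal to
    the Di-Qiang pair (ACH, JIP); a lowland clade with DEA basal to the
    Bai-Yue/Han pair (DAI, HAN).  Recent gene flow: TBN into ACH and JIP,
    mutual HAN/DAI exchange, and a trickle into DEA from both flanks.  ACH,
    JIP and DEA undergo recent bottlenecks (about 15 generations ago).
    Parameter values are an order-of-magnitude approximation chosen for the
    synthetic-data generator; every number is user-overridable by building a
    DemographyModel directly.
    """
    t_out = 3_000.0
    t_high_low = 1_400.0
    t_tbn = 1_000.0
    t_ach_jip = 400.0
    t_dea = 900.0
    t_dai_han = 600.0
    m = DemographyModel(
        populations=["OUT", "TBN", "ACH", "JIP", "DEA", "DAI", "HAN"],
        sizes={
            "OUT": [SizeEpoch(0, 15_000)],
            # TBN carries the root lineage (ancestral sizes on its older epochs)
            "TBN": [SizeEpoch(0, 8_000), SizeEpoch(t_high_low, 10_000), SizeEpoch(t_out, 12_000)],
            "ACH": [SizeEpoch(0, 5_000)],
            "JIP": [SizeEpoch(0, 5_000)],
            "DEA": [SizeEpoch(0, 6_000)],
            "DAI": [SizeEpoch(0, 15_000)],
            "HAN": [SizeEpoch(0, 20_000)],
        },
        splits=[
            Split(t_out, "OUT", "TBN"),
            Split(t_high_low, "DEA", "TBN"),  # lowland clade branches off
            Split(t_tbn, "ACH", "TBN"),
            Split(t_ach_jip, "JIP", "ACH"),
            Split(t_dai_han, "DAI", "HAN"),
            Split(t_dea, "HAN", "DEA"),
        ],
        migrations=[
            MigrationWindow("ACH", "TBN", 3e-4, 800),
            MigrationWindow("JIP", "TBN", 3e-4, 800),
            MigrationWindow("DAI", "HAN", 3e-4, 600),
            MigrationWindow("HAN", "DAI", 3e-4, 600),
            MigrationWindow("DEA", "JIP", 5e-5, 600),
            MigrationWindow("DEA", "DAI", 5e-5, 600),
        ],
        bottlenecks=[
            Bottleneck("ACH", 15, 0, 800),
            Bottleneck("JIP", 15, 0, 800),
            Bottleneck("DEA", 15, 0, 900),
        ],
        rescale_factor=rescale_factor,
    )
    m.validate()
    return m
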