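"""Forward-time Wright-Fisher reproduction with exact ancestry-segment tracking.

Each chromosome copy is a :class:`SegmentHaplotype`: an ordered mosaic of
half-open intervals ``[start, end)`` tiling ``[0, L)`` in genetic coordinates
(Morgans), each carrying the ancestral-population label and the identifier of
the founding haplotype it descends from.  Crossover is a Poisson process of
rate 1 per Morgan along the chromosome with no end effect and no
interference; chromosomes recombine independently.  Mutation and selection
are not modelled: on the recent time scales of admixture they contribute
negligibly to genome-wide diversity, and their absence is what makes exact
segment bookkeeping cheap.

Reproduction per generation is two-step:

1. build a parent pool of exactly ``N`` individuals — fresh single-ancestry
   founders in the proportions given by the generation's gene-flow column,
   the remainder drawn with replacement from the previous generation;
2. repeat ``N`` times: choose two distinct pool members, pick one haplotype
   of each per chromosome, recombine.  In the default ``"reciprocal"``
   mating mode the two reciprocal crossover products become the offspring's
   chromosome pair; in ``"gamete"`` mode each offspring haplotype is instead
   an independent recombinant of one parent's own two haplotypes.

All randomness flows through a single :class:`numpy.random.Generator`; draw
order is fixed (pool founders, then pool replacement indices; per offspring:
parent indices, then per chromosome haplotype choices, crossover count,
crossover positions, strand coin), so a seed reproduces a run exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .model import SimulationConfig

__all__ = [
    "Segment",
    "SegmentHaplotype",
    "Individual",
    "Population",
    "FounderRegistry",
    "make_founder",
    "build_parent_pool",
    "recombine",
    "make_offspring",
    "advance_generation",
    "simulate",
    "sample_individuals",
]

ADMIXED = 0  # origin tag for individuals born in the admixed population


class Segment(NamedTuple):
    """One ancestral chromosome segment, half-open ``[start, end)`` in Morgans."""

    start: float
    end: float
    ancestry: int
    founder_id: int


class SegmentHaplotype:
    """One chromosome copy as a canonical mosaic of ancestral segments.

    Stored column-wise for speed: ``ends[i]`` is the (exclusive) end of
    segment ``i``, whose start is ``ends[i-1]`` (0 for the first); ``anc[i]``
    and ``fid[i]`` are its ancestry label and founder-haplotype id.  The
    mosaic tiles ``[0, L)`` with no gaps or overlaps, and adjacent segments
    with identical ``(ancestry, founder_id)`` are merged.
    """

    __slots__ = ("ends", "anc", "fid")

    def __init__(self, ends, anc, fid):
        self.ends = np.asarray(ends, dtype=np.float64)
        self.anc = np.asarray(anc, dtype=np.int32)
        self.fid = np.asarray(fid, dtype=np.int64)

    @classmethod
    def single(cls, L: float, ancestry: int, founder_id: int) -> "SegmentHaplotype":
        """A founder haplotype: one segment covering the whole chromosome."""
        return cls(
            np.array([L], dtype=np.float64),
            np.array([ancestry], dtype=np.int32),
            np.array([founder_id], dtype=np.int64),
        )

    @classmethod
    def from_segments(cls, segments: Sequence[Segment]) -> "SegmentHaplotype":
        segs = list(segments)
        return cls(
            [s.end for s in segs],
            [s.ancestry for s in segs],
            [s.founder_id for s in segs],
        )

    @property
    def length(self) -> float:
        return float(self.ends[-1])

    @property
    def starts(self) -> np.ndarray:
        return np.concatenate(([0.0], self.ends[:-1]))

    @property
    def n_segments(self) -> int:
        return self.ends.shape[0]

    def segments(self) -> list[Segment]:
        starts = self.starts
        return [
            Segment(float(starts[i]), float(self.ends[i]), int(self.anc[i]), int(self.fid[i]))
            for i in range(self.n_segments)
        ]

    def copy(self) -> "SegmentHaplotype":
        return SegmentHaplotype(self.ends.copy(), self.anc.copy(), self.fid.copy())

    def check(self, L: Optional[float] = None) -> None:
        """Assert the tiling and canonical-merging invariants; raise otherwise."""
        if self.ends.shape[0] == 0:
            raise AssertionError("empty haplotype")
        starts = self.starts
        if not np.all(self.ends > starts):
            raise AssertionError("non-positive segment length")
        if L is not None and not np.isclose(self.ends[-1], L, rtol=0, atol=0):
            raise AssertionError(f"last end {self.ends[-1]} != L={L}")
        if self.ends.shape[0] > 1:
            same = (self.anc[1:] == self.anc[:-1]) & (self.fid[1:] == self.fid[:-1])
            if same.any():
                raise AssertionError("adjacent mergeable segments (not canonical)")

    def __eq__(self, other) -> bool:
        if not isinstance(other, SegmentHaplotype):
            return NotImplemented
        return (
            np.array_equal(self.ends, other.ends)
            and np.array_equal(self.anc, other.anc)
            and np.array_equal(self.fid, other.fid)
        )

    def __hash__(self):  # pragma: no cover
        return hash((self.ends.tobytes(), self.anc.tobytes(), self.fid.tobytes()))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        parts = ", ".join(
            f"[{s.start:.4g},{s.end:.4g}) a{s.ancestry}/f{s.founder_id}"
            for s in self.segments()
        )
        return f"SegmentHaplotype({parts})"


class Individual:
    """A diploid individual: a pair of haplotypes per chromosome.

    ``origin`` is the ancestral-population label (1..K) for fresh founders
    and ``0`` for individuals born inside the admixed population.
    """

    __slots__ = ("haplotypes", "origin")

    def __init__(self, haplotypes: list, origin: int = ADMIXED):
        self.haplotypes = haplotypes  # list over chromosomes of (hap0, hap1)
        self.origin = origin

    @property
    def n_chrom(self) -> int:
        return len(self.haplotypes)


@dataclass
class Population:
    """All individuals alive at one generation of the admixed population."""

    generation: int
    individuals: list
    founder_registry: Optional["FounderRegistry"] = None

    def __len__(self) -> int:
        return len(self.individuals)


class FounderRegistry:
    """Issues unique founder-haplotype ids and records their provenance.

    Founder haplotypes are the chromosome copies that enter the admixed
    population directly from an ancestral population; every simulated segment
    traces back to one of them.  Ids are consecutive integers from 0 in order
    of creation, so downstream code can index arrays by founder id.
    """

    def __init__(self):
        self.ancestry: list[int] = []
        self.generation: list[int] = []

    def new_ids(self, ancestry: int, generation: int, count: int = 2) -> range:
        start = len(self.ancestry)
        self.ancestry.extend([ancestry] * count)
        self.generation.extend([generation] * count)
        return range(start, start + count)

    def __len__(self) -> int:
        return len(self.ancestry)


def make_founder(
    ancestry: int,
    founder_ids: tuple,
    chrom_lengths: Sequence[float],
) -> Individual:
    """A fresh single-ancestry individual with two distinct founder ids.

    Each of its two haplotypes is a single unbroken segment per chromosome;
    haplotype ``h`` carries ``founder_ids[h]`` on every chromosome.
    """
    if ancestry < 1:
        raise ValueError("ancestry labels are 1-based")
    f0, f1 = founder_ids
    if f0 == f1:
        raise ValueError("a founder's two haplotypes need distinct ids")
    haplotypes = [
        (SegmentHaplotype.single(L, ancestry, f0), SegmentHaplotype.single(L, ancestry, f1))
        for L in chrom_lengths
    ]
    return Individual(haplotypes, origin=ancestry)


def _rounded_founder_counts(column: np.ndarray, N: int, founding: bool) -> np.ndarray:
    """Integer founder counts per ancestral population for one generation.

    ``round(N * m_j)`` with round-half-even; the rounding residual goes to
    the previous-generation share, except at the founding generation where
    there is no previous generation and it goes to the largest-``m``
    population.  If rounding overshoots ``N`` the excess is removed from the
    largest count so the pool size is exactly ``N``.
    """
    counts = np.rint(N * np.asarray(column, dtype=float)).astype(np.int64)
    excess = int(counts.sum()) - N
    if founding:
        counts[int(np.argmax(column))] -= excess
    elif excess > 0:
        counts[int(np.argmax(counts))] -= excess
    if np.any(counts < 0):
        raise RuntimeError("founder-count rounding produced a negative count")
    return counts


def build_parent_pool(
    prev_pop: Optional[Population],
    gene_flow_column: Sequence[float],
    N: int,
    rng: np.random.Generator,
    *,
    chrom_lengths: Sequence[float],
    registry: Optional[FounderRegistry] = None,
    generation: int = 1,
) -> list:
    """Step 1 of reproduction: assemble the pool of N prospective parents.

    ``round(N * m_j)`` fresh founders enter from each ancestral population
    ``j`` (ancestral sources are treated as infinite, so founders are always
    newly created); the remaining slots are filled by sampling uniformly
    *with replacement* from the previous generation.
    """
    column = np.asarray(gene_flow_column, dtype=float)
    counts = _rounded_founder_counts(column, N, founding=prev_pop is None)
    if registry is None:
        registry = FounderRegistry()
    pool: list = []
    for j, c in enumerate(counts, start=1):
        for _ in range(int(c)):
            ids = registry.new_ids(j, generation)
            pool.append(make_founder(j, (ids[0], ids[1]), chrom_lengths))
    n_admixed = N - len(pool)
    if n_admixed < 0:
        raise RuntimeError("pool overflow after rounding reconciliation")
    if n_admixed > 0:
        if prev_pop is None or len(prev_pop) == 0:
            raise ValueError(
                "gene-flow column leaves admixed-population slots but there is "
                "no previous generation to draw from"
            )
        idx = rng.integers(0, len(prev_pop), size=n_admixed)
        prev = prev_pop.individuals
        pool.extend(prev[i] for i in idx)
    if len(pool) != N:
        raise RuntimeError(f"pool size {len(pool)} != N={N}")
    return pool


def _draw_breakpoints(L: float, rng: np.random.Generator) -> np.ndarray:
    """Crossover positions: Poisson(L) count, i.i.d. uniform on (0, L), sorted.

    Coincident breakpoints cancel pairwise (two switches at one point undo
    each other), so only positions with odd multiplicity are kept; with
    continuous draws this is a measure-zero concern handled for robustness.
    """
    x = rng.poisson(L)
    if x == 0:
        return _EMPTY_F8
    bp = rng.uniform(0.0, L, size=x)
    bp = bp[(bp > 0.0) & (bp < L)]
    bp.sort()
    if bp.shape[0] > 1 and np.any(bp[1:] == bp[:-1]):
        vals, counts = np.unique(bp, return_counts=True)
        bp = vals[counts % 2 == 1]
    return bp


_EMPTY_F8 = np.empty(0, dtype=np.float64)


def _refine(ends, anc, fid, bps):
    """Cut a mosaic at the breakpoints; return refined arrays plus, for each
    refined segment, the index of the inter-breakpoint interval it lies in."""
    all_ends = np.concatenate((ends, bps))
    all_ends.sort(kind="stable")
    keep = np.empty(all_ends.shape, dtype=bool)
    keep[0] = True
    np.not_equal(all_ends[1:], all_ends[:-1], out=keep[1:])
    all_ends = all_ends[keep]
    src = np.searchsorted(ends, all_ends, side="left")
    iv = np.searchsorted(bps, all_ends, side="left")
    return all_ends, anc[src], fid[src], iv


def _canonical(ends, anc, fid):
    if ends.shape[0] > 1:
        same = (anc[1:] == anc[:-1]) & (fid[1:] == fid[:-1])
        if same.any():
            keep = np.concatenate((~same, (True,)))
            ends, anc, fid = ends[keep], anc[keep], fid[keep]
    return SegmentHaplotype(ends, anc, fid)


def _combine(eA, aA, fA, eB, aB, fB):
    e = np.concatenate((eA, eB))
    order = np.argsort(e, kind="stable")
    return _canonical(
        e[order],
        np.concatenate((aA, aB))[order],
        np.concatenate((fA, fB))[order],
    )


def recombine(
    hapA: SegmentHaplotype,
    hapB: SegmentHaplotype,
    L: float,
    rng: np.random.Generator,
    *,
    breakpoints: Optional[np.ndarray] = None,
    start_on_a: Optional[bool] = None,
) -> tuple:
    """Cross over two haplotypes; return the two reciprocal products.

    Draws ``X ~ Poisson(L)`` breakpoints uniform on ``(0, L)`` (no end
    effect).  Product 1 starts on ``hapA`` with probability 1/2 and switches
    source at every breakpoint; product 2 is the complementary mosaic.  Both
    outputs are canonical and tile ``[0, L)``.

    ``breakpoints`` and ``start_on_a`` can be injected for testing; when
    supplied they bypass the corresponding random draws.
    """
    if breakpoints is None:
        bps = _draw_breakpoints(L, rng)
    else:
        bps = np.asarray(breakpoints, dtype=np.float64)
    if start_on_a is None:
        start_on_a = bool(rng.integers(0, 2))
    if bps.shape[0] == 0:
        first, second = (hapA, hapB) if start_on_a else (hapB, hapA)
        return first.copy(), second.copy()
    eA, aA, fA, ivA = _refine(hapA.ends, hapA.anc, hapA.fid, bps)
    eB, aB, fB, ivB = _refine(hapB.ends, hapB.anc, hapB.fid, bps)
    evenA = ivA % 2 == 0
    evenB = ivB % 2 == 0
    # the product that starts on A takes A's pieces in even intervals and
    # B's in odd intervals; its reciprocal takes the complement
    p_a = _combine(eA[evenA], aA[evenA], fA[evenA], eB[~evenB], aB[~evenB], fB[~evenB])
    p_b = _combine(eB[evenB], aB[evenB], fB[evenB], eA[~evenA], aA[~evenA], fA[~evenA])
    return (p_a, p_b) if start_on_a else (p_b, p_a)


def make_offspring(
    pool: list,
    chrom_lengths: Sequence[float],
    mating_mode: str,
    rng: np.random.Generator,
) -> Individual:
    """Step 2 of reproduction: one offspring from two distinct pool members."""
    n = len(pool)
    if n < 2:
        raise ValueError("parent pool must contain at least two individuals")
    i = int(rng.integers(0, n))
    j = int(rng.integers(0, n - 1))
    if j >= i:
        j += 1
    p1, p2 = pool[i], pool[j]
    haplotypes = []
    if mating_mode == "reciprocal":
        # literal two-step scheme: pick one haplotype per parent, keep both
        # reciprocal crossover products as the offspring's chromosome pair
        for c, L in enumerate(chrom_lengths):
            h1 = p1.haplotypes[c][int(rng.integers(0, 2))]
            h2 = p2.haplotypes[c][int(rng.integers(0, 2))]
            haplotypes.append(recombine(h1, h2, L, rng))
    elif mating_mode == "gamete":
        # standard Wright-Fisher gametes: each transmitted haplotype is an
        # independent recombinant of its own parent's chromosome pair
        for c, L in enumerate(chrom_lengths):
            g1, _ = recombine(p1.haplotypes[c][0], p1.haplotypes[c][1], L, rng)
            g2, _ = recombine(p2.haplotypes[c][0], p2.haplotypes[c][1], L, rng)
            haplotypes.append((g1, g2))
    else:
        raise ValueError(f"unknown mating mode {mating_mode!r}")
    return Individual(haplotypes, origin=ADMIXED)


def advance_generation(
    prev_pop: Optional[Population],
    gene_flow_column: Sequence[float],
    N: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    registry: Optional[FounderRegistry] = None,
    debug_checks: bool = False,
) -> Population:
    """Advance the admixed population by one generation (pool, then N births)."""
    if N < 2:
        raise ValueError("population size must be at least 2")
    generation = 1 if prev_pop is None else prev_pop.generation + 1
    if registry is None and prev_pop is not None:
        registry = prev_pop.founder_registry
    if registry is None:
        registry = FounderRegistry()
    pool = build_parent_pool(
        prev_pop,
        gene_flow_column,
        N,
        rng,
        chrom_lengths=config.chrom_lengths,
        registry=registry,
        generation=generation,
    )
    individuals = [
        make_offspring(pool, config.chrom_lengths, config.mating_mode, rng)
        for _ in range(N)
    ]
    if debug_checks:
        for ind in individuals:
            for (h0, h1), L in zip(ind.haplotypes, config.chrom_lengths):
                h0.check(L)
                h1.check(L)
    return Population(generation, individuals, founder_registry=registry)


def simulate(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    *,
    debug_checks: bool = False,
    progress=None,
) -> Population:
    """Run the full simulation, generation by generation; return the final
    population (only the current generation is kept in memory).

    ``progress``, if given, is called as ``progress(t, T, N_t)`` after each
    generation.  Deterministic for a fixed config (the seed in ``config`` is
    used unless an explicit generator is supplied).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    registry = FounderRegistry()
    pop: Optional[Population] = None
    T = config.matrix.T
    for t in range(1, T + 1):
        pop = advance_generation(
            pop,
            config.matrix.column(t),
            config.sizes.at(t),
            config,
            rng,
            registry=registry,
            debug_checks=debug_checks,
        )
        if progress is not None:
            progress(t, T, len(pop))
    assert pop is not None
    return pop


def sample_individuals(pop: Population, n: int, rng: np.random.Generator) -> list:
    """Uniform sample of ``n`` individuals without replacement."""
    if n > len(pop):
        raise ValueError(f"cannot sample {n} from population of {len(pop)}")
    if n == 0:
        import warnings

        warnings.warn("sampling zero individuals", stacklevel=2)
        return []
    idx = rng.choice(len(pop), size=n, replace=False)
    return [pop.individuals[i] for i in idx]
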