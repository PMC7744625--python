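import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wfadmix.model import SimulationConfig, SizeTrajectory, preset_hi
from wfadmix.engine import (
    FounderRegistry,
    Population,
    Segment,
    SegmentHaplotype,
    advance_generation,
    build_parent_pool,
    make_founder,
    make_offspring,
    recombine,
    sample_individuals,
    simulate,
)


def oracle_splice(hapA, hapB, breakpoints, start_on_a):
    """Independent brute-force recombination oracle.

    Walks the elementary intervals induced by all boundaries, resolves the
    source haplotype by counting breakpoints left of the interval midpoint,
    looks up the source segment by linear scan, then run-length-encodes.
    Returns both reciprocal products as segment lists.
    """
    bps = list(breakpoints)
    bounds = sorted(set(list(hapA.ends) + list(hapB.ends) + bps))
    products = ([], [])
    prev = 0.0
    for b in bounds:
        mid = (prev + b) / 2.0
        n_left = sum(1 for x in bps if x < mid)
        first_src, second_src = (hapA, hapB) if (n_left % 2 == 0) == start_on_a else (hapB, hapA)
        for out, src in ((products[0], first_src), (products[1], second_src)):
            i = 0
            while src.ends[i] <= mid:  # linear scan for covering segment
                i += 1
            seg = (int(src.anc[i]), int(src.fid[i]))
            if out and out[-1][1] == seg:
                out[-1][0] = b  # extend run
            else:
                out.append([b, seg])
        prev = b
    def to_hap(runs):
        return SegmentHaplotype(
            [r[0] for r in runs], [r[1][0] for r in runs], [r[1][1] for r in runs]
        )
    return to_hap(products[0]), to_hap(products[1])


def random_hap(rng, L, n_seg, n_anc=3, n_fid=6):
    cuts = np.sort(rng.uniform(0, L, size=n_seg - 1)) if n_seg > 1 else np.array([])
    ends = np.concatenate((cuts, [L]))
    anc = rng.integers(1, n_anc + 1, size=n_seg)
    fid = rng.integers(0, n_fid, size=n_seg)
    # canonicalize so the input satisfies the class invariant
    keep = np.concatenate((
        (anc[1:] != anc[:-1]) | (fid[1:] != fid[:-1]), [True]
    )) if n_seg > 1 else np.array([True])
    return SegmentHaplotype(ends[keep], anc[keep], fid[keep])


def assert_tiles(hap, L):
    hap.check(L)


class TestFounders:
    def test_founder_is_single_segment_per_haplotype(self):
        ind = make_founder(1, (0, 1), (1.0,))
        h0, h1 = ind.haplotypes[0]
        assert h0.segments() == [Segment(0.0, 1.0, 1, 0)]
        assert h1.segments() == [Segment(0.0, 1.0, 1, 1)]
        assert ind.origin == 1

    def test_founder_multiple_chromosomes(self):
        ind = make_founder(2, (4, 5), (1.0, 2.0))
        assert ind.n_chrom == 2
        assert ind.haplotypes[1][0].length == 2.0
        assert all(h.n_segments == 1 for pair in ind.haplotypes for h in pair)

    def test_founder_ids_must_differ(self):
        with pytest.raises(ValueError):
            make_founder(1, (3, 3), (1.0,))


class TestParentPool:
    def test_founding_counts_match_proportions(self, rng):
        pool = build_parent_pool(None, [0.25, 0.75], 5000, rng, chrom_lengths=(1.0,))
        origins = np.array([ind.origin for ind in pool])
        assert (origins == 1).sum() == 1250
        assert (origins == 2).sum() == 3750

    def test_zero_gene_flow_draws_only_from_previous(self, rng):
        prev = Population(1, [make_founder(1, (2 * i, 2 * i + 1), (1.0,))
                              for i in range(10)])
        pool = build_parent_pool(prev, [0.0, 0.0], 100, rng, chrom_lengths=(1.0,))
        assert len(pool) == 100
        assert all(ind in prev.individuals for ind in pool)

    def test_rounding_residual_goes_to_admixed_share(self, rng):
        # N*m = 3.3 per population: round-half-even gives 3 + 3 founders,
        # the residual 4 slots come from the previous generation
        prev_inds = []
        for i in range(5):
            ind = make_founder(1, (2 * i, 2 * i + 1), (1.0,))
            ind.origin = 0  # mark as admixed-born for counting
            prev_inds.append(ind)
        prev = Population(1, prev_inds)
        pool = build_parent_pool(prev, [0.33, 0.33], 10, rng, chrom_lengths=(1.0,))
        origins = np.array([ind.origin for ind in pool])
        assert (origins == 1).sum() == 3
        assert (origins == 2).sum() == 3
        assert (origins == 0).sum() == 4
        assert len(pool) == 10

    def test_founding_residual_goes_to_largest_contribution(self, rng):
        # N=3, column (0.5, 0.5): rint gives 2+2 = 4 > 3; largest-m gets the cut
        pool = build_parent_pool(None, [0.5, 0.5], 3, rng, chrom_lengths=(1.0,))
        assert len(pool) == 3

    def test_registry_records_provenance(self, rng):
        reg = FounderRegistry()
        build_parent_pool(None, [0.5, 0.5], 4, rng, chrom_lengths=(1.0,),
                          registry=reg, generation=1)
        assert len(reg) == 8  # two haplotypes per founder
        assert sorted(set(reg.ancestry)) == [1, 2]
        assert set(reg.generation) == {1}


class TestRecombine:
    def test_no_crossover_returns_parents(self, rng):
        a = SegmentHaplotype.single(1.0, 1, 0)
        b = SegmentHaplotype.single(1.0, 2, 1)
        p1, p2 = recombine(a, b, 1.0, rng, breakpoints=[], start_on_a=True)
        assert p1 == a and p2 == b
        p1, p2 = recombine(a, b, 1.0, rng, breakpoints=[], start_on_a=False)
        assert p1 == b and p2 == a

    def test_hand_traced_two_breakpoints(self, rng):
        a = SegmentHaplotype.single(1.0, 1, 0)
        b = SegmentHaplotype.single(1.0, 2, 1)
        p1, p2 = recombine(a, b, 1.0, rng, breakpoints=[0.3, 0.7], start_on_a=True)
        assert p1.segments() == [
            Segment(0.0, 0.3, 1, 0), Segment(0.3, 0.7, 2, 1), Segment(0.7, 1.0, 1, 0)
        ]
        assert p2.segments() == [
            Segment(0.0, 0.3, 2, 1), Segment(0.3, 0.7, 1, 0), Segment(0.7, 1.0, 2, 1)
        ]

    def test_merging_when_sources_share_labels(self, rng):
        a = SegmentHaplotype.single(1.0, 1, 0)
        p1, p2 = recombine(a, a.copy(), 1.0, rng, breakpoints=[0.5], start_on_a=True)
        assert p1.n_segments == 1 and p2.n_segments == 1

    def test_oracle_equivalence_randomized(self):
        """Splice rule agrees exactly with the brute-force interval-walk
        oracle on 1,000 random cases."""
        rng = np.random.default_rng(5150)
        for _ in range(1000):
            L = float(rng.uniform(0.5, 3.0))
            a = random_hap(rng, L, int(rng.integers(1, 8)))
            b = random_hap(rng, L, int(rng.integers(1, 8)))
            bps = np.sort(rng.uniform(0, L, size=rng.poisson(L)))
            bps = np.unique(bps)
            start = bool(rng.integers(0, 2))
            got = recombine(a, b, L, rng, breakpoints=bps, start_on_a=start)
            want = oracle_splice(a, b, bps, start)
            assert got[0] == want[0], (a, b, bps, start)
            assert got[1] == want[1], (a, b, bps, start)

    def test_poisson_crossover_rate(self):
        """Mean crossover count over 1e5 recombinations of a 2-Morgan
        chromosome is 2.0 within 3 standard errors (rate 1 per Morgan)."""
        rng = np.random.default_rng(77)
        a = SegmentHaplotype.single(2.0, 1, 0)
        b = SegmentHaplotype.single(2.0, 2, 1)
        n = 100_000
        counts = np.empty(n)
        for i in range(n):
            p1, _ = recombine(a, b, 2.0, rng)
            counts[i] = p1.n_segments - 1  # distinct labels: segments-1 = switches
        se = np.sqrt(2.0 / n)
        assert abs(counts.mean() - 2.0) <= 3 * se


class TestOffspring:
    @pytest.fixture
    def founder_pool(self):
        return [make_founder(1, (0, 1), (1.0,)), make_founder(2, (2, 3), (1.0,))]

    def test_offspring_heterozygous_without_crossover(self, founder_pool):
        class NoCrossRng:
            """Forces Poisson draws to zero, delegates everything else."""
            def __init__(self):
                self._rng = np.random.default_rng(3)
            def poisson(self, lam):
                return 0
            def __getattr__(self, name):
                return getattr(self._rng, name)

        ind = make_offspring(founder_pool, (1.0,), "reciprocal", NoCrossRng())
        ancs = sorted(int(h.anc[0]) for h in ind.haplotypes[0])
        assert ancs == [1, 2]

    def test_reciprocal_products_cover_parental_material(self, rng):
        """Union of the offspring pair's segments equals the union of the two
        chosen parental haplotypes, position by position."""
        pool = [make_founder(1, (0, 1), (1.0,)), make_founder(2, (2, 3), (1.0,))]
        for _ in range(50):
            ind = make_offspring(pool, (1.0,), "reciprocal", rng)
            h0, h1 = ind.haplotypes[0]
            # at every point, the multiset of (anc) across the pair is {1, 2}
            bounds = np.unique(np.concatenate((h0.ends, h1.ends)))
            mids = (np.concatenate(([0.0], bounds[:-1])) + bounds) / 2
            a0 = h0.anc[np.searchsorted(h0.ends, mids, side="right")]
            a1 = h1.anc[np.searchsorted(h1.ends, mids, side="right")]
            assert np.all(np.sort(np.stack([a0, a1]), axis=0).T == [1, 2])

    @pytest.mark.parametrize("mode", ["reciprocal", "gamete"])
    def test_offspring_tiling_invariant(self, rng, mode):
        pool = [make_founder(j, (4 * j, 4 * j + 1), (1.0, 0.5)) for j in (1, 2, 3)]
        for _ in range(30):
            ind = make_offspring(pool, (1.0, 0.5), mode, rng)
            for pair, L in zip(ind.haplotypes, (1.0, 0.5)):
                pair[0].check(L)
                pair[1].check(L)

    def test_pool_too_small(self, rng):
        with pytest.raises(ValueError):
            make_offspring([make_founder(1, (0, 1), (1.0,))], (1.0,), "reciprocal", rng)


class TestGenerations:
    def _cfg(self, T, N, mode="reciprocal"):
        return SimulationConfig(
            preset_hi([0.25, 0.75], T), SizeTrajectory.constant(N, T),
            (1.0,), min(10, N), 11, mode,
        )

    def test_population_size_follows_trajectory(self, rng):
        cfg = SimulationConfig(
            preset_hi([0.5, 0.5], 3),
            SizeTrajectory(np.array([100, 50, 200])),
            (1.0,), 10, 1,
        )
        pop = simulate(cfg, rng, debug_checks=True)
        assert pop.generation == 3
        assert len(pop) == 200

    def test_generation_index_increments(self, rng):
        cfg = self._cfg(1, 10)
        pop1 = advance_generation(None, [0.25, 0.75], 10, cfg, rng)
        pop2 = advance_generation(pop1, [0.0, 0.0], 10, cfg, rng)
        assert (pop1.generation, pop2.generation) == (1, 2)

    def test_single_ancestry_founding_stays_pure(self, rng):
        cfg = SimulationConfig(
            preset_hi([1.0, 0.0], 1), SizeTrajectory.constant(20, 1), (1.0,), 5, 1,
        )
        pop = simulate(cfg, rng)
        for ind in pop.individuals:
            for h in ind.haplotypes[0]:
                assert np.all(h.anc == 1)

    def test_same_seed_reproduces_identical_segments(self):
        cfg = self._cfg(10, 50)
        pops = [simulate(cfg) for _ in range(2)]
        for i1, i2 in zip(pops[0].individuals, pops[1].individuals):
            for p1, p2 in zip(i1.haplotypes, i2.haplotypes):
                assert p1[0] == p2[0] and p1[1] == p2[1]

    @pytest.mark.parametrize("mode", ["reciprocal", "gamete"])
    def test_tiling_holds_across_whole_run(self, mode):
        cfg = self._cfg(15, 40, mode)
        simulate(cfg, debug_checks=True)  # debug_checks asserts per generation

    def test_segment_count_growth_is_nondecreasing(self):
        """Mean segments per haplotype grows with generations (work per
        generation grows with T, hence total work is quadratic in T)."""
        cfg = self._cfg(25, 200)
        rng = np.random.default_rng(cfg.seed)
        from wfadmix.engine import FounderRegistry

        reg = FounderRegistry()
        pop = None
        means = []
        for t in range(1, 26):
            pop = advance_generation(pop, cfg.matrix.column(t), 200, cfg, rng,
                                     registry=reg)
            means.append(np.mean([
                h.n_segments for ind in pop.individuals
                for h in ind.haplotypes[0]
            ]))
        diffs = np.diff(np.array(means))
        assert means[-1] > means[0]
        assert np.mean(diffs >= 0) > 0.8  # monotone up to sampling noise
        assert means[-1] <= 1 + 25  # bounded by accumulated crossovers + 1


class TestSampling:
    def test_sampling_whole_population_is_permutation(self, rng, small_hi_population):
        _, pop = small_hi_population
        sample = sample_individuals(pop, len(pop), rng)
        assert len(sample) == len(pop)
        assert {id(x) for x in sample} == {id(x) for x in pop.individuals}

    def test_sample_without_replacement(self, rng, small_hi_population):
        _, pop = small_hi_population
        sample = sample_individuals(pop, 50, rng)
        assert len({id(x) for x in sample}) == 50

    def test_oversampling_raises(self, rng, small_hi_population):
        _, pop = small_hi_population
        with pytest.raises(ValueError):
            sample_individuals(pop, len(pop) + 1, rng)

    def test_empty_sample_warns(self, rng, small_hi_population):
        _, pop = small_hi_population
        with pytest.warns(UserWarning):
            assert sample_individuals(pop, 0, rng) == []


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    n_bp=st.integers(0, 6),
    start=st.booleans(),
)
def test_recombination_closure_properties(seed, n_bp, start):
    """Products of arbitrary canonical mosaics are canonical mosaics: tiling,
    merging and total-length preservation hold for any breakpoint set."""
    rng = np.random.default_rng(seed)
    L = float(rng.uniform(0.2, 2.5))
    a = random_hap(rng, L, int(rng.integers(1, 6)))
    b = random_hap(rng, L, int(rng.integers(1, 6)))
    bps = np.unique(rng.uniform(0, L, size=n_bp))
    p1, p2 = recombine(a, b, L, rng, breakpoints=bps, start_on_a=start)
    p1.check(L)
    p2.check(L)
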