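# Methods

## Demographic model

The simulator models a single admixed population of diploid individuals with
discrete, non-overlapping generations. Demography is a `K × T` gene-flow
matrix `M` plus a size trajectory `N(t)`: `m[j][t]` is the fraction of the
generation-`t` population replaced by migrants from ancestral population `j`
(1-based; `t = 1` is the founding event, `t = T` the present). Validity
requires `0 ≤ m[j][t] ≤ 1`, founding column sum exactly 1 (absolute
tolerance 1e-9, so decimal config files round-trip), later column sums ≤ 1,
and `N(t) ≥ 2`. Validation reports *every* violated constraint with a
machine-readable code rather than stopping at the first.

The generation index increases toward the present. One published convention
ambiguity is worth stating: we define the matrix entry by what it means —
gene flow *from ancestral population j* at *generation t* — with rows
indexing populations and columns indexing generations.

### Presets

Neither the gradual-admixture nor the continuous-gene-flow model has a
single canonical parameterisation in the literature, so the presets pin one
down and make it verifiable through the neutral ancestry recursion
`a_t = M[:,t] + (1 − Σ_j m[j][t]) a_{t−1}`:

* **HI**: column 1 = the founding proportions, all later columns zero.
* **GA**: total influx `h_t = 1/t`, split across sources by the target
  proportions. This is the unique constant-final-share choice: solving
  `h_t · Π_{s>t}(1 − h_s) = 1/T` backward gives `h_t = 1/t`, so every
  generation's migrants contribute equally to final ancestry and the
  expected final ancestry equals the input proportions exactly, for any `T`.
* **CGF**: recipient founded pure; donor rate constant at
  `α = 1 − (1−m)^(1/(T−1))` for generations `2..T`, so the expected final
  donor ancestry is exactly the requested `m`.

All presets reduce to HI when `T = 1` (GA) or `α → 0` (CGF).

## Reproduction and recombination

Each generation is built in two steps. First a parent pool of exactly `N`
individuals: `round(N·m[j][t])` *fresh* founders per source population
(round-half-even; the rounding residual is folded into the
previous-generation share, or at founding into the largest contributor, so
the pool is exactly `N`), the remainder drawn uniformly **with replacement**
from the previous generation (the Wright–Fisher choice). Ancestral source
populations are treated as infinite: founders are always new individuals,
each carrying two fresh founder-haplotype ids; when allele panels are
attached, founder ids are mapped to panel rows uniformly with replacement
and the mapping is written to a sidecar table so threading is auditable.

Second, `N` independent births. Two distinct pool members are chosen
uniformly; per chromosome, crossover count `X ~ Poisson(L)` with breakpoints
i.i.d. uniform on `(0, L)` — rate 1 per Morgan, no interference, no end
effect, chromosomes independent. Two mating interpretations are supported:

* **reciprocal** (default): one haplotype is chosen from each parent and the
  two reciprocal crossover products become the offspring's chromosome pair.
  The offspring pair is then complementary — at every position it carries
  exactly the two chosen parental alleles.
* **gamete**: each transmitted haplotype is an independent recombinant of
  one parent's own two haplotypes (the textbook Wright–Fisher gamete).

Both give a per-lineage crossover accumulation of `T` expected breakpoints
per Morgan after `T` generations and both satisfy the exponential
tract-length theory below; the default is the literal two-step reading, the
alternative is one flag away.

Segment lists are stored as structure-of-arrays (ends, ancestry, founder id)
per haplotype; the splice is a vectorised refine/partition/merge on those
arrays, verified segment-for-segment against a brute-force interval-walk
oracle on 1,000 randomised cases. Positions are continuous float64 Morgans,
half-open `[start, end)`, serialised at 8 decimals. Coincident breakpoints
(measure zero) cancel pairwise. All randomness flows through one
`numpy.random.Generator` in a fixed draw order, so a seed reproduces a run
exactly; `simulate` keeps only the current generation in memory.

## Tract statistics

A tract (LACS) is a maximal run of one ancestry label, merging adjacent
segments that differ only in founder id. Under HI the end-free theory says
tracts from a population with contribution `m` are `Exp((1−m)T)`. A finite
chromosome interferes in two ways: tracts touching an end are censored
(length unobservable), and the *interior* tracts that remain follow a
`(L−x)`-tilted version of the exponential — the longer a tract, the fewer
places it fits. `censor_ends=True` (the validation default) excludes
end-touching tracts; both modes are exposed because published comparisons do
not always state which was used.

`ks_against_theory` is a one-sample two-sided Kolmogorov–Smirnov test
against `Exp((1−m)T)` (≥ 30 tracts required). Two caveats define its proper
use, and we state them because they bind in practice:

1. the tilt above is a real, systematic deviation from the end-free theory
   of order `1/((1−m)T·L)` in sup-CDF distance (≈0.005 for rate 75 on a
   1-Morgan chromosome, ≈0.015 for rate 25);
2. tracts from a sampled cohort are not independent — individuals share a
   genealogy, haplotypes share founders, and in reciprocal mode an
   individual's two haplotypes are complementary — so with thousands of
   pooled tracts the nominal p-value is strongly anti-conservative
   (empirically the KS statistic runs about twice the iid expectation).

Consequently the KS test is a useful *shape* diagnostic at moderate tract
counts but will reject the idealised theory at large pooled counts even when
the simulator is exact; the junction-density and moment checks below are the
sharper correctness instruments.

`estimate_T` inverts the exponential mean: `T̂ = 1/((1−m)·mean length)`. It
assumes tracts are short relative to the chromosome; the recovery validation
uses one 3-Morgan chromosome (about the genetic length of the longest human
chromosome), where the end-truncation bias in `T̂` is ≤ 2.3% at `T = 20` and
falls with `T`, comfortably inside the 10% recovery tolerance. On a 1-Morgan
chromosome at `T = 20` truncation alone would bias `T̂` by ≈ +7.5%.

`ancestry_fraction` is exact bookkeeping: summed segment length per ancestry
over both haplotypes of all chromosomes, divided by twice the map length.

## Synthetic panels

`synthesize_panel` draws, per marker, an ancestral frequency
`p ~ U(0.05, 0.95)` and per population `p_j ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`
(Balding–Nichols), then Bernoulli haplotypes; map positions are
uniform-sorted per chromosome. `F` acts like Fst between the sources:
`F = 0.3` gives panels whose first principal component separates the
populations cleanly, mimicking strongly differentiated continental sources;
`F → 0` gives indistinguishable panels. The synthetic panels have no LD
within populations and exchangeable markers — good enough to validate
threading, allele-frequency mixing and PCA-style separation, but not a
substitute for real haplotype reference data when LD structure matters.

## Validation scales and what they show

The test suite validates at the published scenario's own scale where that is
what is being reproduced (ancestry-spread extremes: `N = 5000`, `T = 100`,
3 Morgans, `n = 200`, three seeds with majority agreement; tract-length
theory: same `N, T` on one 1-Morgan chromosome) and at reduced scale where
only the mechanism is under test (conservation: 20 replicates of `N = 1000`,
`T = 50`; time recovery: `N = 2000`). Monte-Carlo assertions use 3-standard-
error bands around the theoretical expectation. Neutral drift means
individual runs scatter: the founding 25% ancestry is conserved in
expectation, with replicate-mean standard deviation of a few percentage
points at `N = 1000`, `T = 50` — passing tests demonstrate unbiasedness, not
that any single run hits 25%.

## Known limitations

No mutation, selection, sex chromosomes, gene conversion or crossover
interference; no migration between ancestral populations; selfing is
excluded only by requiring two distinct parents. Genetic coordinates only —
physical positions in VCF output are a synthetic, documented convention
(`Morgans × 1e6`, collisions bumped), not a recombination map. Memory and
time grow with segment count, i.e. quadratically in `T` at fixed `N·L`.
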