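"""Ancestry-tract statistics and the closed-form tract-length distribution.

Under a hybrid-isolation demography (one founding pulse, no later gene flow),
the genetic length ``x`` of a maximal chromosome run inherited from an
ancestral population with ancestry contribution ``m`` is, ignoring chromosome
ends, exponentially distributed with density

    f(x) = (1 - m) T exp(-(1 - m) T x),

where ``T`` is the number of generations since admixture and lengths are in
Morgans.  This module extracts tract lengths (LACS: length of ancestral
chromosomal segment) from simulated samples, compares them with the theory by
a one-sample Kolmogorov-Smirnov test, computes true per-individual ancestry
fractions from segment lengths, and inverts the mean tract length into a
moment estimate of the admixture time.

A finite chromosome censors the tracts that abut its ends (their full length
is unobservable); ``censor_ends=True`` excludes them, which is the
appropriate mode when testing against the end-free exponential theory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .engine import Individual

__all__ = [
    "LacsSample",
    "collect_lacs",
    "theoretical_lacs_pdf",
    "ks_against_theory",
    "ancestry_fraction",
    "estimate_T",
    "lacs_report",
]


@dataclass(frozen=True)
class LacsSample:
    """Observed ancestry-tract lengths for one ancestral population.

    ``censored[i]`` flags tracts that touch a chromosome end (only present
    when they were not excluded at collection time).
    """

    ancestry: int
    lengths: np.ndarray
    censored: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lengths", np.asarray(self.lengths, dtype=float))
        object.__setattr__(self, "censored", np.asarray(self.censored, dtype=bool))
        if np.any(self.lengths <= 0):
            raise ValueError("tract lengths must be positive")

    @property
    def n(self) -> int:
        return self.lengths.shape[0]


def _hap_tracts(hap) -> tuple:
    """Maximal ancestry runs of one haplotype (founder boundaries merged):
    (start, end, ancestry) arrays."""
    anc = hap.anc
    ends = hap.ends
    if anc.shape[0] > 1:
        last = np.concatenate((anc[1:] != anc[:-1], (True,)))
        run_ends = ends[last]
        run_anc = anc[last]
    else:
        run_ends = ends
        run_anc = anc
    run_starts = np.concatenate(([0.0], run_ends[:-1]))
    return run_starts, run_ends, run_anc


def collect_lacs(
    sample: Sequence[Individual], ancestry: int, censor_ends: bool = False
) -> LacsSample:
    """Tract lengths of ancestry ``ancestry`` over all haplotypes of a sample.

    Tracts are maximal runs of one ancestry label: adjacent segments that
    differ only in founder haplotype are merged first.  With
    ``censor_ends=True``, tracts abutting position 0 or the chromosome end
    are excluded.
    """
    if not sample:
        raise ValueError("empty sample")
    if ancestry < 1:
        raise ValueError(f"unknown ancestry label {ancestry} (labels are 1-based)")
    k_max = 0
    lengths: list[np.ndarray] = []
    flags: list[np.ndarray] = []
    for ind in sample:
        for pair in ind.haplotypes:
            for hap in pair:
                k_max = max(k_max, int(hap.anc.max()))
                starts, ends, anc = _hap_tracts(hap)
                mask = anc == ancestry
                if not mask.any():
                    continue
                s, e = starts[mask], ends[mask]
                touches = (s == 0.0) | (e == ends[-1])
                if censor_ends:
                    s, e, touches = s[~touches], e[~touches], touches[~touches]
                lengths.append(e - s)
                flags.append(touches)
    if ancestry > k_max:
        raise ValueError(
            f"unknown ancestry label {ancestry}: sample carries labels 1..{k_max}"
        )
    if lengths:
        return LacsSample(
            ancestry, np.concatenate(lengths), np.concatenate(flags)
        )
    return LacsSample(ancestry, np.empty(0), np.empty(0, dtype=bool))


def theoretical_lacs_pdf(x, m: float, T: int):
    """Closed-form tract-length density (1-m) T exp(-(1-m) T x).

    ``m`` is the ancestry contribution of the tract's population, ``T`` the
    generations since the founding pulse; an exponential with rate (1-m)T.
    """
    if not 0.0 < m < 1.0:
        raise ValueError("ancestry contribution m must lie strictly in (0, 1)")
    if T < 1:
        raise ValueError("T must be >= 1")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("tract lengths are non-negative")
    rate = (1.0 - m) * T
    out = rate * np.exp(-rate * x)
    return out if out.ndim else float(out)


def ks_against_theory(lacs: LacsSample, m: float, T: int) -> tuple:
    """One-sample two-sided KS test of the tracts against Exp(rate (1-m)T)."""
    if lacs.n < 30:
        raise ValueError(f"need at least 30 tracts for a KS test, have {lacs.n}")
    rate = (1.0 - m) * T
    res = sps.kstest(lacs.lengths, sps.expon(scale=1.0 / rate).cdf)
    return float(res.statistic), float(res.pvalue)


def ancestry_fraction(individual: Individual, K: Optional[int] = None) -> np.ndarray:
    """True ancestry fractions from tracked segment lengths.

    Total segment length per ancestral population across both haplotypes and
    all chromosomes, divided by twice the total map length; sums to one.
    ``K`` fixes the output length (defaults to the largest label present).
    """
    if K is None:
        K = max(
            int(h.anc.max()) for pair in individual.haplotypes for h in pair
        )
    totals = np.zeros(K)
    genome = 0.0
    for pair in individual.haplotypes:
        for hap in pair:
            starts = np.concatenate(([0.0], hap.ends[:-1]))
            lens = hap.ends - starts
            np.add.at(totals, hap.anc - 1, lens)
            genome += hap.length
    return totals / genome


def estimate_T(lacs: LacsSample, m: float) -> float:
    """Moment estimate of the admixture time: T = 1 / ((1-m) * mean length)."""
    if lacs.n < 30:
        raise ValueError(f"need at least 30 tracts to estimate T, have {lacs.n}")
    if not 0.0 < m < 1.0:
        raise ValueError("ancestry contribution m must lie strictly in (0, 1)")
    mean = float(lacs.lengths.mean())
    if mean == 0.0:
        raise ValueError("zero mean tract length")
    return 1.0 / ((1.0 - m) * mean)


def lacs_report(
    sample: Sequence[Individual],
    contributions: Optional[Sequence[float]] = None,
    T: Optional[int] = None,
    censor_ends: bool = True,
    K: Optional[int] = None,
) -> dict:
    """Summary statistics per ancestry for a sampled cohort.

    For each ancestral population: tract count, mean and median length, and
    — when its contribution ``m`` (and ``T`` for the KS test) is supplied —
    the KS comparison against the exponential theory plus the moment estimate
    of the admixture time.
    """
    if K is None:
        K = max(
            int(h.anc.max())
            for ind in sample
            for pair in ind.haplotypes
            for h in pair
        )
    report: dict = {"ancestries": {}, "censor_ends": censor_ends}
    for k in range(1, K + 1):
        lacs = collect_lacs(sample, k, censor_ends=censor_ends)
        entry: dict = {
            "n_tracts": int(lacs.n),
            "mean_length": float(lacs.lengths.mean()) if lacs.n else None,
            "median_length": float(np.median(lacs.lengths)) if lacs.n else None,
        }
        if contributions is not None and lacs.n >= 30:
            m = float(contributions[k - 1])
            if 0.0 < m < 1.0:
                entry["T_hat"] = estimate_T(lacs, m)
                if T is not None:
                    D, p = ks_against_theory(lacs, m, T)
                    entry["ks_D"] = D
                    entry["ks_pvalue"] = p
        report["ancestries"][k] = entry
    fractions = np.array([ancestry_fraction(ind, K) for ind in sample])
    report["mean_ancestry_fraction"] = fractions.mean(axis=0).tolist()
    return report
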