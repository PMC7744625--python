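"""Demographic admixture models: gene-flow matrices, size trajectories, presets.

An admixed population founded ``T`` generations ago by ``K`` ancestral
populations is described by a K x T gene-flow matrix ``M``: ``m[j, t]`` is the
fraction of the admixed population at generation ``t`` that is replaced by
migrants from ancestral population ``j``.  Generation indices are 1-based and
increase toward the present: ``t = 1`` is the founding event ``T`` generations
ago, ``t = T`` is the present.  Ancestral populations are labelled ``1..K``.

Two constraints make a matrix a valid demography:

* every entry lies in ``[0, 1]``;
* the founding column (``t = 1``) sums to one exactly — the first generation
  is drawn entirely from the ancestral populations — while later columns may
  sum to at most one, the remainder coming from the previous admixed
  generation.

Three classic demographies are provided as presets: hybrid isolation (HI, a
single founding pulse followed by isolation), gradual admixture (GA, every
generation's influx contributes equally to the final ancestry), and
continuous gene flow (CGF, a recipient population receiving migrants from one
donor at a constant per-generation rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: absolute tolerance used when checking that a column sums to one, chosen so
#: that user-supplied decimal matrices round-trip through text files.
SUM_TOL = 1e-9

MATING_MODES = ("reciprocal", "gamete")


@dataclass(frozen=True)
class Violation:
    """One violated model constraint: machine-readable code plus location."""

    code: str
    index: tuple
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.code} at {self.index}: {self.message}"


class ModelValidationError(ValueError):
    """Raised by :func:`validate_model`; carries every violated constraint."""

    def __init__(self, violations: Sequence[Violation]):
        self.violations = list(violations)
        super().__init__(
            "invalid admixture model:\n"
            + "\n".join(f"  - {v}" for v in self.violations)
        )

    def codes(self) -> set[str]:
        return {v.code for v in self.violations}


@dataclass(frozen=True)
class GeneFlowMatrix:
    """K x T matrix of gene-flow strengths.

    ``m[j-1, t-1]`` is the fraction of generation ``t`` drawn from ancestral
    population ``j`` (both indices 1-based in the public API).
    """

    m: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.m, dtype=float)
        if arr.ndim != 2:
            raise ValueError("gene-flow matrix must be a 2-D (K x T) array")
        object.__setattr__(self, "m", arr)

    @property
    def K(self) -> int:
        return self.m.shape[0]

    @property
    def T(self) -> int:
        return self.m.shape[1]

    def column(self, t: int) -> np.ndarray:
        """Gene-flow column for generation ``t`` (1-based)."""
        if not 1 <= t <= self.T:
            raise IndexError(f"generation {t} outside 1..{self.T}")
        return self.m[:, t - 1]


@dataclass(frozen=True)
class SizeTrajectory:
    """Admixed population size per generation, ``N[t]`` for ``t = 1..T``."""

    N: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.N, dtype=np.int64)
        if arr.ndim != 1:
            raise ValueError("size trajectory must be a 1-D sequence")
        object.__setattr__(self, "N", arr)

    @classmethod
    def constant(cls, N: int, T: int) -> "SizeTrajectory":
        return cls(np.full(T, int(N), dtype=np.int64))

    @property
    def T(self) -> int:
        return self.N.shape[0]

    def at(self, t: int) -> int:
        return int(self.N[t - 1])


def validate_model(
    matrix: GeneFlowMatrix, sizes: SizeTrajectory
) -> tuple[GeneFlowMatrix, SizeTrajectory]:
    """Check every model invariant; return the model unchanged if valid.

    Raises :class:`ModelValidationError` listing *all* violated constraints,
    each with a code (``BAD_DIMENSIONS``, ``OUT_OF_RANGE``,
    ``NON_STOCHASTIC_FOUNDING``, ``OVERFLOW_COLUMN``, ``BAD_SIZE``) and the
    offending 1-based index.
    """
    v: list[Violation] = []
    K, T = matrix.K, matrix.T
    if K < 2:
        v.append(Violation("BAD_DIMENSIONS", (K,), "need K > 1 ancestral populations"))
    if T < 1:
        v.append(Violation("BAD_DIMENSIONS", (T,), "need T > 0 generations"))
    if sizes.T != T:
        v.append(
            Violation(
                "BAD_DIMENSIONS",
                (sizes.T, T),
                f"size trajectory length {sizes.T} != T={T}",
            )
        )
    bad = np.argwhere((matrix.m < 0.0) | (matrix.m > 1.0))
    for j, t in bad:
        v.append(
            Violation(
                "OUT_OF_RANGE",
                (int(j) + 1, int(t) + 1),
                f"m[{j + 1}][{t + 1}] = {matrix.m[j, t]} outside [0, 1]",
            )
        )
    if T >= 1:
        s0 = float(matrix.m[:, 0].sum())
        if abs(s0 - 1.0) > SUM_TOL:
            v.append(
                Violation(
                    "NON_STOCHASTIC_FOUNDING",
                    (1,),
                    f"founding column sums to {s0!r}, must be 1",
                )
            )
        colsums = matrix.m[:, 1:].sum(axis=0)
        for k in np.flatnonzero(colsums > 1.0 + SUM_TOL):
            v.append(
                Violation(
                    "OVERFLOW_COLUMN",
                    (int(k) + 2,),
                    f"column {k + 2} sums to {colsums[k]} > 1",
                )
            )
    for t in np.flatnonzero(sizes.N < 2):
        v.append(
            Violation(
                "BAD_SIZE", (int(t) + 1), f"N[{t + 1}] = {sizes.N[t]} < 2"
            )
        )
    if v:
        raise ModelValidationError(v)
    return matrix, sizes


def _check_proportions(proportions: Sequence[float]) -> np.ndarray:
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or p.shape[0] < 2:
        raise ValueError("need at least two ancestral proportions")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    if abs(float(p.sum()) - 1.0) > SUM_TOL:
        raise ValueError(f"proportions sum to {p.sum()!r}, must be 1")
    return p


def preset_hi(proportions: Sequence[float], T: int) -> GeneFlowMatrix:
    """Hybrid isolation: one founding pulse, then complete isolation."""
    p = _check_proportions(proportions)
    if T < 1:
        raise ValueError("T must be >= 1")
    m = np.zeros((p.shape[0], T))
    m[:, 0] = p
    return GeneFlowMatrix(m)


def preset_ga(proportions: Sequence[float], T: int) -> GeneFlowMatrix:
    """Gradual admixture: continuous gene flow with total rate 1/t at
    generation t, split across ancestral populations by ``proportions``.

    With h_t = 1/t the influx of every generation contributes exactly 1/T of
    the final ancestry, so the expected final ancestry equals ``proportions``
    for any T, and the founding column sums to one automatically.
    """
    p = _check_proportions(proportions)
    if T < 1:
        raise ValueError("T must be >= 1")
    m = np.empty((p.shape[0], T))
    for t in range(1, T + 1):
        m[:, t - 1] = p / t
    return GeneFlowMatrix(m)


def preset_cgf(recipient: int, donor_fraction: float, T: int) -> GeneFlowMatrix:
    """Continuous gene flow: a two-population model where the recipient is
    founded pure and then receives migrants from the donor every generation
    at the constant rate alpha = 1 - (1-m)^(1/(T-1)), chosen so the expected
    final donor ancestry equals ``donor_fraction`` (= m).

    ``recipient`` is the 1-based label (1 or 2) of the recipient population.
    """
    if recipient not in (1, 2):
        raise ValueError("recipient must be 1 or 2 (K=2 model)")
    if not 0.0 < donor_fraction < 1.0:
        raise ValueError("donor_fraction must lie strictly in (0, 1)")
    if T < 2:
        raise ValueError("CGF needs T >= 2 (founding plus at least one wave)")
    donor = 2 if recipient == 1 else 1
    alpha = 1.0 - (1.0 - donor_fraction) ** (1.0 / (T - 1))
    m = np.zeros((2, T))
    m[recipient - 1, 0] = 1.0
    m[donor - 1, 1:] = alpha
    return GeneFlowMatrix(m)


def expected_final_ancestry(matrix: GeneFlowMatrix) -> np.ndarray:
    """Expected ancestry-fraction vector of the final generation.

    Follows the neutral recursion a_t = M[:, t] + (1 - sum_j m[j, t]) a_{t-1}
    with a_0 = 0; the result is a probability vector for any valid matrix.
    """
    a = np.zeros(matrix.K)
    for t in range(matrix.T):
        col = matrix.m[:, t]
        a = col + (1.0 - float(col.sum())) * a
    return a


@dataclass(frozen=True)
class SimulationConfig:
    """Single source of truth for a simulation run."""

    matrix: GeneFlowMatrix
    sizes: SizeTrajectory
    chrom_lengths: tuple  # genetic lengths in Morgans
    sample_size: int
    seed: int
    mating_mode: str = "reciprocal"

    def __post_init__(self):
        object.__setattr__(
            self, "chrom_lengths", tuple(float(L) for L in self.chrom_lengths)
        )

    def validate(self) -> "SimulationConfig":
        validate_model(self.matrix, self.sizes)
        if not self.chrom_lengths or any(L <= 0 for L in self.chrom_lengths):
            raise ValueError("chromosome lengths must all be positive (Morgans)")
        if not 0 <= self.sample_size <= self.sizes.at(self.sizes.T):
            raise ValueError(
                f"sample_size {self.sample_size} exceeds final population size "
                f"{self.sizes.at(self.sizes.T)}"
            )
        if self.mating_mode not in MATING_MODES:
            raise ValueError(f"mating_mode must be one of {MATING_MODES}")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        """Build a config from a flat mapping (the config-file schema).

        Keys: ``K``, ``T``, ``sizes`` (list, or scalar broadcast to length T),
        ``matrix`` (K rows x T columns, row-major list of lists),
        ``chrom_lengths``, ``sample_size``, ``seed``, ``mating_mode``.
        """
        K, T = int(d["K"]), int(d["T"])
        m = np.asarray(d["matrix"], dtype=float)
        if m.shape != (K, T):
            raise ValueError(f"matrix shape {m.shape} != (K={K}, T={T})")
        sizes = d["sizes"]
        if np.isscalar(sizes):
            traj = SizeTrajectory.constant(int(sizes), T)
        else:
            traj = SizeTrajectory(np.asarray(sizes, dtype=np.int64))
        lengths = d["chrom_lengths"]
        if np.isscalar(lengths):
            lengths = [lengths]
        return cls(
            matrix=GeneFlowMatrix(m),
            sizes=traj,
            chrom_lengths=tuple(float(L) for L in lengths),
            sample_size=int(d["sample_size"]),
            seed=int(d["seed"]),
            mating_mode=str(d.get("mating_mode", "reciprocal")),
        )

    def to_dict(self) -> dict:
        return {
            "K": self.matrix.K,
            "T": self.matrix.T,
            "sizes": self.sizes.N.tolist(),
            "matrix": self.matrix.m.tolist(),
            "chrom_lengths": list(self.chrom_lengths),
            "sample_size": self.sample_size,
            "seed": self.seed,
            "mating_mode": self.mating_mode,
        }


def load_config(path) -> SimulationConfig:
    """Read a YAML config file into a :class:`SimulationConfig`."""
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return SimulationConfig.from_dict(d)
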