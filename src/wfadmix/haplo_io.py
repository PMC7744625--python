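"""Panel I/O, allele threading through segment mosaics, and output writers.

The simulator works purely in genetic coordinates; allele data enter through
*ancestral panels*: phased 0/1 haplotypes with a marker map in Morgans.  The
native text dialect is deliberately minimal:

``.hap``
    one haplotype per line, ``0``/``1`` characters, optionally
    whitespace-separated.
``.map``
    one marker per line: ``id<TAB>position_in_Morgans`` (single chromosome)
    or ``id<TAB>position<TAB>chromosome`` (1-based chromosome index) for
    multi-chromosome maps; positions strictly increasing within a chromosome.

Sampled individuals are written as a segment table (TSV, genetic coordinates,
half-open intervals in Morgans) and, when panels are available, as threaded
allele data in the hap dialect or as a phased VCF for interoperability with
PCA/ancestry-inference tools.  VCF records need integer physical positions,
which a purely genetic simulation does not have; they are synthesised as
``round(position_in_Morgans * 1e6)`` with collisions bumped upward by 1, a
stated convention so outputs are reproducible.

A Balding-Nichols synthesiser generates differentiated panels for fully
self-contained runs: per marker an ancestral frequency ``p ~ U(0.05, 0.95)``
and per population ``p_j ~ Beta(p(1-F)/F, (1-p)(1-F)/F)``, where ``F`` plays
the role of Fst between the ancestral populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import FounderRegistry, Individual, SegmentHaplotype

__all__ = [
    "MarkerMap",
    "AncestralPanel",
    "read_panel",
    "write_panel",
    "synthesize_panel",
    "assign_founders",
    "write_founders",
    "thread_alleles",
    "thread_individual",
    "write_segments",
    "read_segments",
    "write_haplotypes",
]

SEGMENT_COLUMNS = [
    "sample_id",
    "haplotype",
    "chromosome",
    "start",
    "end",
    "ancestry",
    "founder_id",
]


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker ids and genetic positions (Morgans), per chromosome."""

    ids: tuple  # tuple of tuples of str, one per chromosome
    positions: tuple  # tuple of float arrays, one per chromosome

    def __post_init__(self):
        ids = tuple(tuple(i) for i in self.ids)
        pos = tuple(np.asarray(p, dtype=float) for p in self.positions)
        if len(ids) != len(pos):
            raise ValueError("ids and positions disagree on chromosome count")
        for c, (i, p) in enumerate(zip(ids, pos)):
            if len(i) != p.shape[0]:
                raise ValueError(f"chromosome {c + 1}: id/position count mismatch")
            if p.shape[0] and (np.any(np.diff(p) <= 0) or p[0] < 0):
                raise ValueError(
                    f"MONOTONICITY: chromosome {c + 1} positions must be "
                    "non-negative and strictly increasing"
                )
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "positions", pos)

    @property
    def n_chrom(self) -> int:
        return len(self.positions)

    @property
    def n_markers(self) -> int:
        return sum(p.shape[0] for p in self.positions)

    @property
    def offsets(self) -> np.ndarray:
        """Global column index of each chromosome's first marker."""
        counts = [p.shape[0] for p in self.positions]
        return np.concatenate(([0], np.cumsum(counts)[:-1])).astype(int)


@dataclass(frozen=True)
class AncestralPanel:
    """Phased reference haplotypes for one ancestral population (0/1 alleles)."""

    label: int
    haplotypes: np.ndarray  # (n_hap, n_markers) uint8

    def __post_init__(self):
        h = np.asarray(self.haplotypes, dtype=np.uint8)
        if h.ndim != 2 or h.shape[0] == 0:
            raise ValueError("EMPTY_PANEL: need at least one haplotype row")
        if not np.isin(h, (0, 1)).all():
            raise ValueError("NON_BINARY: alleles must be 0/1")
        object.__setattr__(self, "haplotypes", h)

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]


def _parse_map_lines(lines) -> MarkerMap:
    by_chrom: dict[int, list] = {}
    for ln, raw in enumerate(lines, start=1):
        s = raw.strip()
        if not s:
            continue
        parts = s.split()
        if len(parts) == 2:
            mid, pos, chrom = parts[0], float(parts[1]), 1
        elif len(parts) == 3:
            mid, pos, chrom = parts[0], float(parts[1]), int(parts[2])
        else:
            raise ValueError(f"map line {ln}: expected 2 or 3 fields, got {len(parts)}")
        by_chrom.setdefault(chrom, []).append((mid, pos))
    if not by_chrom:
        raise ValueError("empty map file")
    chroms = sorted(by_chrom)
    if chroms != list(range(1, len(chroms) + 1)):
        raise ValueError(f"chromosome indices must be 1..C, got {chroms}")
    ids = [tuple(mid for mid, _ in by_chrom[c]) for c in chroms]
    pos = [np.array([p for _, p in by_chrom[c]]) for c in chroms]
    return MarkerMap(tuple(ids), tuple(pos))


def read_panel(hap_path, map_path, label: int = 1) -> Tuple[AncestralPanel, MarkerMap]:
    """Parse a .hap/.map pair into a panel and its marker map."""
    with open(map_path) as fh:
        marker_map = _parse_map_lines(fh)
    rows = []
    with open(hap_path) as fh:
        for ln, raw in enumerate(fh, start=1):
            s = "".join(raw.split())
            if not s:
                continue
            if set(s) - {"0", "1"}:
                raise ValueError(f"NON_BINARY: hap line {ln} has alleles outside 0/1")
            rows.append(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"))
    if not rows:
        raise ValueError("EMPTY_PANEL: hap file contains no haplotypes")
    widths = {r.shape[0] for r in rows}
    if len(widths) != 1:
        raise ValueError(f"RAGGED_ROWS: haplotype lengths differ ({sorted(widths)})")
    mat = np.vstack(rows)
    if mat.shape[1] != marker_map.n_markers:
        raise ValueError(
            f"hap width {mat.shape[1]} != map marker count {marker_map.n_markers}"
        )
    return AncestralPanel(label, mat), marker_map


def write_panel(panel: AncestralPanel, hap_path) -> None:
    with open(hap_path, "w") as fh:
        for row in panel.haplotypes:
            fh.write("".join("01"[a] for a in row) + "\n")


def write_map(marker_map: MarkerMap, map_path) -> None:
    multi = marker_map.n_chrom > 1
    with open(map_path, "w") as fh:
        for c in range(marker_map.n_chrom):
            for mid, pos in zip(marker_map.ids[c], marker_map.positions[c]):
                if multi:
                    fh.write(f"{mid}\t{pos:.8f}\t{c + 1}\n")
                else:
                    fh.write(f"{mid}\t{pos:.8f}\n")


def synthesize_panel(
    K: int,
    n_hap: int,
    n_markers: int,
    F: float,
    seed: int,
    chrom_lengths: Sequence[float] = (1.0,),
) -> Tuple[Dict[int, AncestralPanel], MarkerMap]:
    """Balding-Nichols synthetic panels for K differentiated populations.

    ``F`` in (0, 1) controls differentiation (Fst-like): as F -> 0 the
    populations share allele frequencies; larger F separates them.  Markers
    are spread across chromosomes proportionally to genetic length, with
    uniform-sorted positions.  Deterministic given the seed.
    """
    if not 0.0 < F < 1.0:
        raise ValueError("differentiation parameter F must lie strictly in (0, 1)")
    if K < 1 or n_hap < 1 or n_markers < 1:
        raise ValueError("K, n_hap and n_markers must be positive")
    rng = np.random.default_rng(seed)
    lengths = np.asarray(chrom_lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("chromosome lengths must be positive")
    # allot markers proportionally to length, at least one per chromosome
    raw = n_markers * lengths / lengths.sum()
    counts = np.maximum(1, np.floor(raw)).astype(int)
    while counts.sum() < n_markers:
        counts[int(np.argmax(raw - counts))] += 1
    while counts.sum() > n_markers:
        counts[int(np.argmax(counts))] -= 1
    ids, positions = [], []
    for c, (L, nc) in enumerate(zip(lengths, counts)):
        pos = np.sort(rng.uniform(0.0, L, size=nc))
        while np.any(np.diff(pos) <= 0):  # enforce strict monotonicity
            pos = np.unique(pos)
            extra = np.sort(rng.uniform(0.0, L, size=nc - pos.shape[0]))
            pos = np.sort(np.concatenate((pos, extra)))
        positions.append(pos)
        ids.append(tuple(f"m{c + 1}_{i + 1}" for i in range(nc)))
    marker_map = MarkerMap(tuple(ids), tuple(positions))
    p = rng.uniform(0.05, 0.95, size=n_markers)
    a, b = p * (1.0 - F) / F, (1.0 - p) * (1.0 - F) / F
    panels: Dict[int, AncestralPanel] = {}
    for j in range(1, K + 1):
        pj = rng.beta(a, b)
        alleles = (rng.random((n_hap, n_markers)) < pj).astype(np.uint8)
        panels[j] = AncestralPanel(j, alleles)
    return panels, marker_map


def assign_founders(
    registry: FounderRegistry,
    panels: Dict[int, AncestralPanel],
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign every founder haplotype a panel row (uniform, with replacement).

    Returns an int array indexed by founder id; entry ``r`` means panel row
    ``r`` of the founder's own ancestral population.
    """
    rows = np.empty(len(registry), dtype=np.int64)
    for fid, anc in enumerate(registry.ancestry):
        panel = panels.get(anc)
        if panel is None:
            raise ValueError(f"no panel supplied for ancestral population {anc}")
        rows[fid] = rng.integers(0, panel.n_hap)
    return rows


def write_founders(registry: FounderRegistry, assignment: np.ndarray, path) -> None:
    """Sidecar table making allele threading auditable."""
    df = pd.DataFrame(
        {
            "founder_id": np.arange(len(registry)),
            "ancestry": registry.ancestry,
            "generation": registry.generation,
            "panel_row": assignment,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def thread_alleles(
    hap: SegmentHaplotype,
    panels: Dict[int, AncestralPanel],
    assignment: np.ndarray,
    marker_map: MarkerMap,
    chrom: int = 0,
) -> np.ndarray:
    """Copy founder alleles through one chromosome's segment mosaic.

    Each marker takes the allele of the founder haplotype whose segment
    contains its position (half-open ``[start, end)``; a marker exactly on a
    breakpoint belongs to the right-hand segment, and the final segment is
    closed at ``L`` so a marker at the chromosome end resolves).
    """
    pos = marker_map.positions[chrom]
    L = hap.length
    if pos.shape[0] and (pos[0] < 0 or pos[-1] > L):
        raise ValueError(f"marker positions outside [0, {L}]")
    idx = np.searchsorted(hap.ends, pos, side="right")
    idx[idx == hap.n_segments] = hap.n_segments - 1  # marker at L
    anc = hap.anc[idx]
    fid = hap.fid[idx]
    if np.any(fid >= assignment.shape[0]):
        raise ValueError("unresolved founder id in haplotype")
    rows = assignment[fid]
    cols = marker_map.offsets[chrom] + np.arange(pos.shape[0])
    out = np.empty(pos.shape[0], dtype=np.uint8)
    for j in np.unique(anc):
        panel = panels.get(int(j))
        if panel is None:
            raise ValueError(f"no panel supplied for ancestral population {j}")
        mask = anc == j
        out[mask] = panel.haplotypes[rows[mask], cols[mask]]
    return out


def thread_individual(
    ind: Individual,
    panels: Dict[int, AncestralPanel],
    assignment: np.ndarray,
    marker_map: MarkerMap,
) -> Tuple[np.ndarray, np.ndarray]:
    """Both phased allele vectors of an individual, all chromosomes concatenated."""
    h0 = [
        thread_alleles(pair[0], panels, assignment, marker_map, c)
        for c, pair in enumerate(ind.haplotypes)
    ]
    h1 = [
        thread_alleles(pair[1], panels, assignment, marker_map, c)
        for c, pair in enumerate(ind.haplotypes)
    ]
    return np.concatenate(h0), np.concatenate(h1)


def write_segments(sample: Sequence[Individual], path, sample_ids=None) -> None:
    """Segment table: one TSV row per segment, positions in Morgans (8 dp).

    Columns: sample_id, haplotype (0/1), chromosome (1-based), start, end,
    ancestry, founder_id; ordered by sample, haplotype, chromosome, start.
    """
    if sample_ids is None:
        sample_ids = [f"ind_{i}" for i in range(len(sample))]
    with open(path, "w") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for sid, ind in zip(sample_ids, sample):
            for h in (0, 1):
                for c, pair in enumerate(ind.haplotypes):
                    hap = pair[h]
                    starts = hap.starts
                    for i in range(hap.n_segments):
                        fh.write(
                            f"{sid}\t{h}\t{c + 1}\t{starts[i]:.8f}\t"
                            f"{hap.ends[i]:.8f}\t{hap.anc[i]}\t{hap.fid[i]}\n"
                        )


def read_segments(path) -> Tuple[list, list]:
    """Rebuild sampled individuals from a segment table.

    Returns ``(individuals, sample_ids)`` in file order.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment file missing columns: {sorted(missing)}")
    individuals, sample_ids = [], []
    for sid, g in df.groupby("sample_id", sort=False):
        n_chrom = int(g["chromosome"].max())
        haplotypes = []
        for c in range(1, n_chrom + 1):
            pair = []
            for h in (0, 1):
                rows = g[(g["haplotype"] == h) & (g["chromosome"] == c)]
                rows = rows.sort_values("start")
                if rows.empty:
                    raise ValueError(
                        f"sample {sid}: missing haplotype {h} on chromosome {c}"
                    )
                pair.append(
                    SegmentHaplotype(
                        rows["end"].to_numpy(float),
                        rows["ancestry"].to_numpy(np.int32),
                        rows["founder_id"].to_numpy(np.int64),
                    )
                )
            haplotypes.append((pair[0], pair[1]))
        individuals.append(Individual(haplotypes))
        sample_ids.append(sid)
    return individuals, sample_ids


def _vcf_positions(marker_map: MarkerMap, chrom: int) -> np.ndarray:
    """Synthetic integer physical positions: Morgans * 1e6, collisions bumped."""
    pos = np.rint(marker_map.positions[chrom] * 1e6).astype(np.int64)
    pos = np.maximum(pos, 1)
    for i in range(1, pos.shape[0]):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos


def write_haplotypes(
    sample: Sequence[Individual],
    panels: Dict[int, AncestralPanel],
    assignment: np.ndarray,
    marker_map: MarkerMap,
    path,
    fmt: str = "hap",
    sample_ids=None,
) -> None:
    """Write the sample's threaded alleles as .hap lines or a phased VCF."""
    if not panels:
        raise ValueError("no panels supplied; cannot emit allele data")
    if sample_ids is None:
        sample_ids = [f"ind_{i}" for i in range(len(sample))]
    threaded = [
        thread_individual(ind, panels, assignment, marker_map) for ind in sample
    ]
    if fmt == "hap":
        with open(path, "w") as fh:
            for h0, h1 in threaded:
                fh.write("".join("01"[a] for a in h0) + "\n")
                fh.write("".join("01"[a] for a in h1) + "\n")
    elif fmt == "vcf":
        _write_vcf(threaded, marker_map, path, sample_ids)
    else:
        raise ValueError(f"unknown haplotype format {fmt!r}")


def _write_vcf(threaded, marker_map: MarkerMap, path, sample_ids) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=wfadmix\n')
        for c in range(marker_map.n_chrom):
            last = _vcf_positions(marker_map, c)[-1] if marker_map.positions[c].size else 1
            fh.write(f"##contig=<ID=chr{c + 1},length={int(last) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for c in range(marker_map.n_chrom):
            phys = _vcf_positions(marker_map, c)
            off = marker_map.offsets[c]
            for i, mid in enumerate(marker_map.ids[c]):
                gts = "\t".join(
                    f"{h0[off + i]}|{h1[off + i]}" for h0, h1 in threaded
                )
                fh.write(
                    f"chr{c + 1}\t{phys[i]}\t{mid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
                )
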