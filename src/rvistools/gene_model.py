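"""Per-gene coding footprints: transcript merging, splice pads, coverage masks.

A gene's footprint is the union of all its transcripts' exons, each exon
widened by a splice pad (default 2 bp) so that splice acceptor/donor sites
fall inside the region. Coverage masking then restricts the footprint to
sites sequenced at adequate mean depth; a gene is "assessable" when a
minimum fraction of its footprint (default 70%) survives the depth filter
(default 10-fold). All coordinates are 0-based half-open internally;
file readers/writers convert at the boundary where a format demands it.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError

DEFAULT_SPLICE_PAD = 2
DEFAULT_MIN_DEPTH = 10.0
DEFAULT_MIN_FRACTION = 0.70


@dataclass(frozen=True)
class TranscriptExon:
    """One exon of one transcript, 0-based half-open."""

    gene_symbol: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise InputError("exon with empty gene symbol")
        if self.start >= self.end:
            raise InputError(
                f"exon {self.gene_symbol}/{self.transcript_id}: "
                f"start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class GeneRegion:
    """Consolidated, splice-padded, optionally coverage-masked footprint.

    ``intervals`` is the sorted disjoint union of padded exons.
    ``covered_intervals`` is the subset of sites passing the depth filter;
    before :func:`apply_coverage` it equals ``intervals`` and
    ``covered_sites``/``assessable`` are unset.
    """

    gene_symbol: str
    chrom: str
    intervals: tuple[tuple[int, int], ...]
    total_sites: int
    covered_intervals: tuple[tuple[int, int], ...] = field(default=())
    covered_sites: int | None = None
    assessable: bool | None = None

    def sites(self) -> np.ndarray:
        """All positions in the footprint, ascending."""
        if not self.intervals:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([np.arange(s, e) for s, e in self.intervals])

    def contains(self, pos: int) -> bool:
        return _intervals_contain(self.intervals, pos)

    def covers(self, pos: int) -> bool:
        """True iff ``pos`` is in the covered-site mask. Before coverage
        masking the whole footprint counts as covered."""
        mask = self.covered_intervals if self.covered_sites is not None else self.intervals
        return _intervals_contain(mask, pos)


def _intervals_contain(intervals: tuple[tuple[int, int], ...], pos: int) -> bool:
    if not intervals:
        return False
    i = bisect_right(intervals, (pos, float("inf"))) - 1
    return i >= 0 and intervals[i][0] <= pos < intervals[i][1]


class CoverageProfile:
    """Piecewise-constant mean depth along the genome.

    Built from (chrom, start, end, depth) intervals; overlapping intervals
    resolve to the maximum depth at each site, and sites absent from the
    profile have depth 0.
    """

    def __init__(self, intervals) -> None:
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, depth in intervals:
            if depth < 0:
                raise InputError(f"negative depth {depth} at {chrom}:{start}-{end}")
            if start >= end:
                raise InputError(f"empty coverage interval {chrom}:{start}-{end}")
            per_chrom.setdefault(str(chrom), []).append((int(start), int(end), float(depth)))
        self._pieces: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivs in per_chrom.items():
            self._pieces[chrom] = _flatten_to_pieces(ivs)

    @classmethod
    def uniform(cls, regions, depth: float) -> "CoverageProfile":
        """Constant depth over every interval of the given regions."""
        ivs = []
        for r in regions:
            for s, e in r.intervals:
                ivs.append((r.chrom, s, e, depth))
        return cls(ivs)

    def depths(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Mean depth at each position (0 where unreported)."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.zeros(len(positions), dtype=float)
        pieces = self._pieces.get(chrom)
        if pieces is None:
            return out
        starts, ends, depth = pieces
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        inside = np.zeros_like(ok)
        inside[ok] = positions[ok] < ends[idx[ok]]
        out[inside] = depth[idx[inside]]
        return out


def _flatten_to_pieces(ivs: list[tuple[int, int, float]]):
    """Resolve possibly-overlapping depth intervals to disjoint pieces
    carrying the per-site maximum depth."""
    bounds = np.unique(
        np.concatenate([[s for s, _, _ in ivs], [e for _, e, _ in ivs]])
    )
    starts, ends = bounds[:-1], bounds[1:]
    depth = np.zeros(len(starts), dtype=float)
    for s, e, d in ivs:
        i = np.searchsorted(bounds, s)
        j = np.searchsorted(bounds, e)
        np.maximum.at(depth, np.arange(i, j), d)
    keep = depth > 0
    return starts[keep], ends[keep], depth[keep]


def merge_transcripts(exons, splice_pad: int = DEFAULT_SPLICE_PAD) -> GeneRegion:
    """Union all exons of one gene into a consolidated footprint.

    Each exon is widened by ``splice_pad`` bases on both sides before the
    union; overlapping or bookended padded exons coalesce into one interval.

    Raises
    ------
    InputError
        on an empty exon set, mixed gene symbols, or mixed chromosomes
        (a symbol mapping to several chromosomes is rejected rather than
        silently merged).
    """
    exons = list(exons)
    if not exons:
        raise InputError("cannot merge an empty exon set")
    if splice_pad < 0:
        raise InputError(f"splice_pad must be >= 0, got {splice_pad}")
    symbols = {e.gene_symbol for e in exons}
    if len(symbols) != 1:
        raise InputError(f"mixed gene symbols in one merge: {sorted(symbols)}")
    chroms = {e.chrom for e in exons}
    if len(chroms) != 1:
        raise InputError(
            f"gene {exons[0].gene_symbol} spans multiple chromosomes: {sorted(chroms)}"
        )
    padded = sorted((e.start - splice_pad, e.end + splice_pad) for e in exons)
    merged: list[list[int]] = []
    for s, e in padded:
        if merged and s <= merged[-1][1]:  # overlap or bookend coalesces
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    intervals = tuple((s, e) for s, e in merged)
    total = sum(e - s for s, e in intervals)
    return GeneRegion(
        gene_symbol=exons[0].gene_symbol,
        chrom=exons[0].chrom,
        intervals=intervals,
        total_sites=total,
        covered_intervals=intervals,
    )


def apply_coverage(
    region: GeneRegion,
    coverage: CoverageProfile,
    min_depth: float = DEFAULT_MIN_DEPTH,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> GeneRegion:
    """Restrict a footprint to sites with mean depth >= ``min_depth``.

    Sets ``covered_sites`` and the ``assessable`` flag
    (covered_sites / total_sites >= ``min_fraction``); the covered-site
    mask is retained so downstream variant filtering can reject variants
    at uncovered sites.
    """
    if not region.intervals:
        raise InputError(f"gene {region.gene_symbol}: empty region")
    if min_depth <= 0:
        raise InputError("min_depth must be > 0")
    if not 0 < min_fraction <= 1:
        raise InputError("min_fraction must be in (0, 1]")
    covered: list[tuple[int, int]] = []
    n_covered = 0
    for s, e in region.intervals:
        pos = np.arange(s, e)
        ok = coverage.depths(region.chrom, pos) >= min_depth
        n_covered += int(ok.sum())
        covered.extend(_runs_to_intervals(pos, ok))
    return replace(
        region,
        covered_intervals=tuple(covered),
        covered_sites=n_covered,
        assessable=n_covered / region.total_sites >= min_fraction,
    )


def _runs_to_intervals(pos: np.ndarray, ok: np.ndarray) -> list[tuple[int, int]]:
    if not ok.any():
        return []
    edge = np.flatnonzero(np.diff(ok.astype(np.int8)))
    starts = [int(pos[0])] if ok[0] else []
    out = []
    for i in edge:
        if ok[i + 1]:
            starts.append(int(pos[i + 1]))
        else:
            out.append((starts.pop(), int(pos[i]) + 1))
    if starts:
        out.append((starts.pop(), int(pos[-1]) + 1))
    return out


def build_gene_regions(
    exons,
    coverage: CoverageProfile | None,
    splice_pad: int = DEFAULT_SPLICE_PAD,
    min_depth: float = DEFAULT_MIN_DEPTH,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> dict[str, GeneRegion]:
    """Group exons by gene symbol, merge, and (optionally) coverage-mask.

    Returns a mapping gene symbol -> GeneRegion. With ``coverage=None``
    regions are returned unmasked (fully covered, assessability unset).
    """
    by_gene: dict[str, list[TranscriptExon]] = {}
    for e in exons:
        by_gene.setdefault(e.gene_symbol, []).append(e)
    regions = {}
    for gene, glist in by_gene.items():
        region = merge_transcripts(glist, splice_pad=splice_pad)
        if coverage is not None:
            region = apply_coverage(region, coverage, min_depth, min_fraction)
        regions[gene] = region
    return regions
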