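"""Conserved syntenic segment (CSS) detection and block statistics.

A CSS is a run of at least ``min_markers`` single-locus orthologous markers
on one (query linkage group, target chromosome) pair in which consecutive
markers — ordered by query map position — are separated by at most a
maximal genetic distance on the query map and a maximal physical distance
on the target genome.  The physical threshold is derived from a gene-count
window (a fixed number of genes scaled by genome size over gene number);
the genetic threshold from a fixed fraction of the total map length.

Chaining is greedy in query-cM order with deterministic tie-breaking; the
pairwise gap rule makes the greedy partition identical to the enumeration
of maximal valid chains.  Target gaps are unsigned, so inversions within a
segment do not break it.  Non-syntenic markers lying inside a block's query
span are counted per block (``n_interspersed``) but do not break chains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import GeneticMapTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntenyThresholds:
    """Parameters of the CSS rule.

    ``max_gap_target_bp`` defaults to 3.2 Mb — a ~200-gene window on a
    475 Mb genome with ~30k genes.  ``max_gap_query_cM`` defaults to 12 cM,
    roughly 1% of a ~1350 cM map; ``map_fraction`` re-derives it for other
    maps (e.g. 14 cM for a 1463 cM map with the default floor rounding).
    ``max_interspersed``, when set, breaks a chain that would skip more
    than that many consecutive foreign markers on the query map.
    """

    min_markers: int = 3
    max_gap_target_bp: float = 3_200_000.0
    max_gap_query_cM: float = 12.0
    map_fraction: float = 0.01
    gene_window: int = 200
    floor_to_int: bool = True
    max_interspersed: int | None = None

    def __post_init__(self) -> None:
        if self.min_markers < 2:
            raise ValueError("min_markers must be >= 2")
        if self.max_gap_target_bp <= 0 or self.max_gap_query_cM <= 0:
            raise ValueError("gap thresholds must be positive")


def derive_physical_threshold(
    genome_size_bp: float, n_genes: int, gene_window: int = 200
) -> float:
    """Physical gap threshold: the span of ``gene_window`` average genes,
    i.e. ``gene_window * genome_size_bp / n_genes`` (bp)."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if genome_size_bp <= 0 or gene_window <= 0:
        raise ValueError("genome size and gene window must be positive")
    return gene_window * genome_size_bp / n_genes


def genes_in_window(window_bp: float, genome_size_bp: float, n_genes: int) -> float:
    """Inverse of :func:`derive_physical_threshold`: how many average genes
    a physical window covers."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    return window_bp * n_genes / genome_size_bp


def derive_genetic_threshold(
    map_length_cM: float, map_fraction: float = 0.01, floor_to_int: bool = False
) -> float:
    """Genetic gap threshold: a fixed fraction of the total map length.

    Returned unrounded by default; ``floor_to_int`` applies the explicit
    floor-to-integer policy (e.g. 14.63 -> 14 cM).
    """
    if map_length_cM <= 0:
        raise ValueError("map length must be positive")
    value = map_fraction * map_length_cM
    return float(math.floor(value)) if floor_to_int else value


@dataclass
class SyntenicBlock:
    """One conserved syntenic segment.

    ``members`` are (marker_id, query position, target position) ordered by
    query position (co-segregating markers ordered by id).  ``target_unit``
    is ``bp`` for map-versus-genome comparisons and ``cM`` for map-versus-
    map comparisons.
    """

    block_id: str
    query_lg: str
    target_chrom: str
    members: list[tuple[str, float, float]]
    n_interspersed: int = 0
    target_unit: str = "bp"

    @property
    def n_syntenic(self) -> int:
        return len(self.members)

    @property
    def query_start(self) -> float:
        return self.members[0][1]

    @property
    def query_end(self) -> float:
        return self.members[-1][1]

    @property
    def span_query(self) -> float:
        return self.query_end - self.query_start

    @property
    def target_start(self) -> float:
        return min(m[2] for m in self.members)

    @property
    def target_end(self) -> float:
        return max(m[2] for m in self.members)

    @property
    def span_target(self) -> float:
        return self.target_end - self.target_start

    def adjacent_gaps(self) -> tuple[list[float], list[float]]:
        """Gaps between consecutive members on (query, target) axes."""
        qs = [m[1] for m in self.members]
        ts = [m[2] for m in self.members]
        return (
            [b - a for a, b in zip(qs, qs[1:])],
            [abs(b - a) for a, b in zip(ts, ts[1:])],
        )


def _chain_indices(
    q: np.ndarray, t: np.ndarray, max_gap_q: float, max_gap_t: float
) -> list[tuple[int, int]]:
    """Split indices 0..n-1 (sorted by q) into maximal runs whose
    consecutive pairs satisfy both gap constraints.  Returns [start, end)
    pairs."""
    runs = []
    start = 0
    for i in range(1, len(q) + 1):
        if i == len(q) or (q[i] - q[i - 1]) > max_gap_q or abs(t[i] - t[i - 1]) > max_gap_t:
            runs.append((start, i))
            start = i
    return runs


# statuses counted as interspersed non-syntenic markers inside a block span:
# mapped markers whose ortholog lies elsewhere, or is absent
_INTERSPERSED_STATUSES = {"single_locus", "absent", "absent_primary_conserved_fallback"}


def detect_css(
    assignments: pd.DataFrame,
    query_map: GeneticMapTable,
    thresholds: SyntenyThresholds | None = None,
) -> list[SyntenicBlock]:
    """Chain single-locus orthologs into conserved syntenic segments.

    For every (query linkage group, target chromosome) pair, markers sorted
    by query cM (ties broken by marker id) are greedily chained; a gap
    larger than either threshold closes the chain.  Chains with at least
    ``min_markers`` members become blocks.  Markers assigned single-locus
    but missing from the query map are skipped with a warning.
    """
    th = thresholds or SyntenyThresholds()
    single = assignments[assignments["status"] == "single_locus"]
    mapdf = query_map.df.rename(columns={"cM": "query_pos"})
    merged = single.merge(mapdf, on="marker", how="left")
    missing = merged[merged["linkage_group"].isna()]
    for m in missing["marker"]:
        logger.warning("marker %s has no query-map placement; skipped", m)
    merged = merged.dropna(subset=["linkage_group"])

    status_by_marker = dict(zip(assignments["marker"], assignments["status"]))
    blocks: list[SyntenicBlock] = []
    for (lg, chrom), grp in sorted(merged.groupby(["linkage_group", "chrom"])):
        grp = grp.sort_values(["query_pos", "marker"], kind="stable")
        q = grp["query_pos"].to_numpy(dtype=float)
        t = grp["pos"].to_numpy(dtype=float)
        markers = grp["marker"].tolist()
        runs = _chain_indices(q, t, th.max_gap_query_cM, th.max_gap_target_bp)
        if th.max_interspersed is not None:
            runs = _split_on_interspersed(
                runs, markers, q, query_map, lg, th.max_interspersed
            )
        k = 0
        for s, e in runs:
            if e - s < th.min_markers:
                continue
            k += 1
            members = [(markers[i], float(q[i]), float(t[i])) for i in range(s, e)]
            block = SyntenicBlock(
                block_id=f"{lg}~{chrom}~{k}",
                query_lg=str(lg),
                target_chrom=str(chrom),
                members=members,
            )
            block.n_interspersed = _count_interspersed(
                block, query_map, status_by_marker
            )
            blocks.append(block)
    return blocks


def _count_interspersed(
    block: SyntenicBlock, query_map: GeneticMapTable, status_by_marker: Mapping[str, str]
) -> int:
    members = {m for m, _q, _t in block.members}
    on_lg = query_map.markers_on(block.query_lg)
    inside = on_lg[
        (on_lg["cM"] >= block.query_start) & (on_lg["cM"] <= block.query_end)
    ]
    n = 0
    for m in inside["marker"]:
        if m in members:
            continue
        if status_by_marker.get(m, "absent") in _INTERSPERSED_STATUSES:
            n += 1
    return n


def _split_on_interspersed(runs, markers, q, query_map, lg, max_interspersed):
    """Optionally break chains across long runs of foreign map markers."""
    on_lg = query_map.markers_on(lg)
    member_set = set(markers)
    out = []
    for s, e in runs:
        start = s
        for i in range(s + 1, e):
            between = on_lg[(on_lg["cM"] > q[i - 1]) & (on_lg["cM"] < q[i])]
            n_foreign = int((~between["marker"].isin(member_set)).sum())
            if n_foreign > max_interspersed:
                out.append((start, i))
                start = i
        out.append((start, e))
    return out


def detect_css_between_maps(
    map_a: GeneticMapTable,
    map_b: GeneticMapTable,
    max_gap_a_cM: float,
    max_gap_b_cM: float,
    min_markers: int = 3,
    pairs: Mapping[str, str] | None = None,
) -> list[SyntenicBlock]:
    """Genetic-versus-genetic CSS detection (two maps, shared markers).

    Each map contributes its own cM gap threshold on its own axis.  By
    default markers are paired by shared id; an explicit ``pairs`` mapping
    (map-A marker -> map-B marker) overrides this.
    """
    a = map_a.df.rename(columns={"linkage_group": "lg_a", "cM": "pos_a"})
    b = map_b.df.rename(columns={"linkage_group": "lg_b", "cM": "pos_b"})
    if pairs is not None:
        a = a.assign(marker_b=[pairs.get(m) for m in a["marker"]]).dropna(
            subset=["marker_b"]
        )
        merged = a.merge(b.rename(columns={"marker": "marker_b"}), on="marker_b")
    else:
        merged = a.merge(b, on="marker")

    blocks: list[SyntenicBlock] = []
    for (lg_a, lg_b), grp in sorted(merged.groupby(["lg_a", "lg_b"])):
        grp = grp.sort_values(["pos_a", "marker"], kind="stable")
        q = grp["pos_a"].to_numpy(dtype=float)
        t = grp["pos_b"].to_numpy(dtype=float)
        markers = grp["marker"].tolist()
        k = 0
        for s, e in _chain_indices(q, t, max_gap_a_cM, max_gap_b_cM):
            if e - s < min_markers:
                continue
            k += 1
            members = [(markers[i], float(q[i]), float(t[i])) for i in range(s, e)]
            block = SyntenicBlock(
                block_id=f"{lg_a}~{lg_b}~{k}",
                query_lg=str(lg_a),
                target_chrom=str(lg_b),
                members=members,
                target_unit="cM",
            )
            on_lg = map_a.markers_on(lg_a)
            inside = on_lg[
                (on_lg["cM"] >= block.query_start) & (on_lg["cM"] <= block.query_end)
            ]
            member_ids = {m for m, _q, _t in block.members}
            block.n_interspersed = int((~inside["marker"].isin(member_ids)).sum())
            blocks.append(block)
    return blocks


@dataclass
class BlockSummary:
    """Table-style statistics over the blocks of one pairwise comparison."""

    n_orthologous_markers: int
    n_css: int
    mean_span_query: float
    max_span_query: float
    mean_span_target: float
    max_span_target: float
    mean_markers_per_css: float
    max_markers_per_css: int
    mean_adjacent_gap_query: float
    mean_adjacent_gap_target: float
    mean_interspersed: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def summarize(
    blocks: Sequence[SyntenicBlock],
    assignments: pd.DataFrame | None = None,
    adjacent: str = "pooled",
) -> BlockSummary:
    """Summarize blocks: spans, markers per block, adjacent-marker gaps.

    Adjacent-marker distances are pooled over all consecutive member pairs
    across blocks (``adjacent="pooled"``); ``adjacent="per_block"`` averages
    per-block means instead.  ``n_orthologous_markers`` is the single-locus
    assignment count when assignments are given, else the chained total.
    """
    if adjacent not in ("pooled", "per_block"):
        raise ValueError("adjacent must be 'pooled' or 'per_block'")
    if assignments is not None:
        n_orth = int((assignments["status"] == "single_locus").sum())
    else:
        n_orth = sum(b.n_syntenic for b in blocks)
    if not blocks:
        return BlockSummary(n_orth, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0, 0.0, 0.0, 0.0)

    spans_q = [b.span_query for b in blocks]
    spans_t = [b.span_target for b in blocks]
    sizes = [b.n_syntenic for b in blocks]
    gq_all, gt_all = [], []
    gq_means, gt_means = [], []
    for b in blocks:
        gq, gt = b.adjacent_gaps()
        gq_all += gq
        gt_all += gt
        if gq:
            gq_means.append(float(np.mean(gq)))
            gt_means.append(float(np.mean(gt)))
    if adjacent == "pooled":
        mean_gq = float(np.mean(gq_all)) if gq_all else 0.0
        mean_gt = float(np.mean(gt_all)) if gt_all else 0.0
    else:
        mean_gq = float(np.mean(gq_means)) if gq_means else 0.0
        mean_gt = float(np.mean(gt_means)) if gt_means else 0.0
    return BlockSummary(
        n_orthologous_markers=n_orth,
        n_css=len(blocks),
        mean_span_query=float(np.mean(spans_q)),
        max_span_query=float(np.max(spans_q)),
        mean_span_target=float(np.mean(spans_t)),
        max_span_target=float(np.max(spans_t)),
        mean_markers_per_css=float(np.mean(sizes)),
        max_markers_per_css=int(np.max(sizes)),
        mean_adjacent_gap_query=mean_gq,
        mean_adjacent_gap_target=mean_gt,
        mean_interspersed=float(np.mean([b.n_interspersed for b in blocks])),
    )


# ---------------------------------------------------------------------------
# three-way triangulation on a shared reference
# ---------------------------------------------------------------------------


def _union_length(intervals: list[tuple[float, float]]) -> float:
    total = 0.0
    last_end = -math.inf
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
        last_end = max(last_end, e)
    return total


def project_multiway(
    blocks_ab: Sequence[SyntenicBlock],
    blocks_cb: Sequence[SyntenicBlock],
    chrom_lengths: Mapping[str, float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Triangulate two pairwise block sets on their shared reference genome.

    Returns (overlaps, coverage): ``overlaps`` reports, for every pair of
    blocks from the two comparisons, the target-interval overlap in bp
    (0 when disjoint or on different chromosomes) and the Jaccard index of
    the two intervals; ``coverage`` gives, per reference chromosome, the
    fraction covered by the union of all block target spans, flagging
    chromosomes no comparison touches.
    """
    rows = []
    for a in blocks_ab:
        for c in blocks_cb:
            if a.target_chrom != c.target_chrom:
                ov, jac = 0.0, 0.0
            else:
                lo = max(a.target_start, c.target_start)
                hi = min(a.target_end, c.target_end)
                ov = max(0.0, hi - lo)
                union = (
                    (a.target_end - a.target_start)
                    + (c.target_end - c.target_start)
                    - ov
                )
                jac = ov / union if union > 0 else 0.0
            rows.append(
                (a.block_id, c.block_id, a.target_chrom, c.target_chrom, ov, jac)
            )
    overlaps = pd.DataFrame(
        rows,
        columns=["block_ab", "block_cb", "chrom_ab", "chrom_cb", "overlap_bp", "jaccard"],
    )

    by_chrom: dict[str, list[tuple[float, float]]] = {c: [] for c in chrom_lengths}
    for b in list(blocks_ab) + list(blocks_cb):
        if b.target_chrom in by_chrom:
            by_chrom[b.target_chrom].append((b.target_start, b.target_end))
    cov_rows = []
    for chrom in sorted(chrom_lengths):
        length = float(chrom_lengths[chrom])
        covered = _union_length(
            [(max(0.0, s), min(length, e)) for s, e in by_chrom[chrom]]
        )
        frac = covered / length if length > 0 else 0.0
        cov_rows.append((chrom, length, covered, frac, covered == 0.0))
    coverage = pd.DataFrame(
        cov_rows, columns=["chrom", "length", "covered_bp", "fraction", "zero_coverage"]
    )
    return overlaps, coverage
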