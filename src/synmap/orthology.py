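"""Single-locus ortholog assignment from BLAST-style hit tables.

Marker sequences queried against a reference genome typically produce
several HSPs per gene; HSPs on the same subject sequence within a merge
window are collapsed into one *locus*.  A query whose hits below the
primary E-value cutoff collapse to exactly one locus is accepted as a
putative single-locus ortholog and carries a target position; queries with
several loci are excluded from synteny as ambiguous (possible lineage-
specific family expansions).  Queries with no primary hit but a hit below
a relaxed fallback cutoff are booked as conserved-by-fallback only — they
never enter the synteny analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STATUSES = (
    "single_locus",
    "multi_locus",
    "chrom_unknown_position",
    "unplaced_contig",
    "absent_primary_conserved_fallback",
    "absent",
)


@dataclass(frozen=True)
class CascadeThresholds:
    """E-value cutoffs of the hit-filter cascade.

    ``e_primary`` is the working cutoff for orthology; ``e_strict`` is the
    stringent cutoff of the initial screen (kept for bookkeeping).  The
    fallback cutoffs are applied, in order, to queries missed at the
    primary cutoff; the loosest of them bounds the conserved-by-fallback
    call.  ``hsp_merge_window`` is the bp distance within which HSPs on one
    subject collapse to a single locus.
    """

    e_strict: float = 1e-10
    e_primary: float = 1e-6
    e_est_fallbacks: tuple[float, ...] = (1e-30, 1e-20, 1e-5)
    hsp_merge_window: float = 50_000.0

    def __post_init__(self) -> None:
        if self.e_strict > self.e_primary:
            raise ValueError("e_strict must be <= e_primary")
        if list(self.e_est_fallbacks) != sorted(self.e_est_fallbacks) or len(
            set(self.e_est_fallbacks)
        ) != len(self.e_est_fallbacks):
            raise ValueError("fallback E-values must be strictly increasing")
        if self.hsp_merge_window < 0:
            raise ValueError("hsp_merge_window must be non-negative")


@dataclass(frozen=True)
class Locus:
    """One merged hit locus: a subject sequence, a point position (midpoint
    of the merged HSP span) and the best E-value among merged HSPs."""

    subject: str
    position: float
    best_e: float
    n_hsps: int


def merge_hsps(hits: pd.DataFrame, hsp_merge_window: float = 50_000.0) -> list[Locus]:
    """Collapse the HSPs of one query into loci.

    HSPs on the same subject whose midpoints lie within
    ``hsp_merge_window`` of the previous HSP (single linkage along the
    subject) form one locus placed at the midpoint of the merged span.
    Returned loci are sorted by best E-value, then subject and position for
    determinism.
    """
    if len(hits) == 0:
        return []
    if hits["query"].nunique() > 1:
        raise ValueError("merge_hsps expects hits of a single query")
    loci: list[Locus] = []
    for subject, sub in hits.groupby("subject"):
        lo = np.minimum(sub["s_start"], sub["s_end"]).to_numpy(dtype=float)
        hi = np.maximum(sub["s_start"], sub["s_end"]).to_numpy(dtype=float)
        mid = (lo + hi) / 2.0
        order = np.argsort(mid, kind="stable")
        e = sub["e_value"].to_numpy(dtype=float)[order]
        lo, hi, mid = lo[order], hi[order], mid[order]
        start = 0
        for i in range(1, len(mid) + 1):
            if i == len(mid) or mid[i] - mid[i - 1] > hsp_merge_window:
                span_lo, span_hi = lo[start:i].min(), hi[start:i].max()
                loci.append(
                    Locus(
                        subject=str(subject),
                        position=float((span_lo + span_hi) / 2.0),
                        best_e=float(e[start:i].min()),
                        n_hsps=i - start,
                    )
                )
                start = i
    loci.sort(key=lambda l: (l.best_e, l.subject, l.position))
    return loci


ASSIGNMENT_COLUMNS = ("marker", "status", "chrom", "pos", "best_e", "n_loci")


def assign(
    hit_table: pd.DataFrame,
    thresholds: CascadeThresholds | None = None,
    unplaced_ids: Iterable[str] = (),
    position_unknown_ids: Iterable[str] = (),
    query_ids: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every query of a hit table (and any hit-less ``query_ids``).

    Returns an assignment table with one row per query — columns ``marker``,
    ``status``, ``chrom``, ``pos`` (target position, set only for
    ``single_locus``), ``best_e`` and ``n_loci`` — plus a tally of counts
    per status.  ``unplaced_ids`` / ``position_unknown_ids`` name subject
    sequences that are unanchored contigs or chromosome-assigned segments
    without a position: single-locus matches landing there are booked but
    excluded from synteny.
    """
    th = thresholds or CascadeThresholds()
    unplaced = set(unplaced_ids)
    pos_unknown = set(position_unknown_ids)
    fallback_max = max(th.e_est_fallbacks) if th.e_est_fallbacks else th.e_primary

    queries = sorted(set(hit_table["query"])) if len(hit_table) else []
    all_queries = sorted(set(queries) | set(query_ids or ()))
    by_query = dict(tuple(hit_table.groupby("query"))) if len(hit_table) else {}

    rows = []
    for q in all_queries:
        hits = by_query.get(q)
        status, chrom, pos, best_e, n_loci = "absent", None, math.nan, math.nan, 0
        if hits is not None and len(hits):
            primary = hits[hits["e_value"] <= th.e_primary]
            if len(primary) == 0:
                if (hits["e_value"] <= fallback_max).any():
                    status = "absent_primary_conserved_fallback"
                    best_e = float(hits["e_value"].min())
            else:
                loci = merge_hsps(primary, th.hsp_merge_window)
                n_loci = len(loci)
                best_e = loci[0].best_e
                if n_loci == 1:
                    top = loci[0]
                    if top.subject in unplaced:
                        status = "unplaced_contig"
                    elif top.subject in pos_unknown:
                        status = "chrom_unknown_position"
                    else:
                        status, chrom, pos = "single_locus", top.subject, top.position
                else:
                    # several loci (incl. equal-E ties on different subjects):
                    # ambiguous, excluded from synteny
                    status = "multi_locus"
        rows.append((q, status, chrom, pos, best_e, n_loci))

    assignments = pd.DataFrame(rows, columns=list(ASSIGNMENT_COLUMNS))
    tally = {s: int((assignments["status"] == s).sum()) for s in STATUSES}
    return assignments, tally


def write_assignments(assignments: pd.DataFrame, path) -> None:
    """Write an assignment table as TSV (stable row order by marker)."""
    out = assignments.sort_values("marker", kind="stable")
    with open(path, "w") as fh:
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for marker, status, chrom, pos, best_e, n_loci in out.itertuples(index=False):
            fh.write(
                f"{marker}\t{status}\t{chrom if chrom is not None else '.'}\t"
                f"{'' if math.isnan(pos) else repr(float(pos))}\t"
                f"{'' if (isinstance(best_e, float) and math.isnan(best_e)) else repr(float(best_e))}\t"
                f"{int(n_loci)}\n"
            )


def read_assignments(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(ASSIGNMENT_COLUMNS):
            raise ValueError(f"{path}: unexpected assignment header")
        for line in fh:
            marker, status, chrom, pos, best_e, n_loci = line.rstrip("\n").split("\t")
            rows.append(
                (
                    marker,
                    status,
                    None if chrom == "." else chrom,
                    float(pos) if pos else math.nan,
                    float(best_e) if best_e else math.nan,
                    int(n_loci),
                )
            )
    return pd.DataFrame(rows, columns=list(ASSIGNMENT_COLUMNS))
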