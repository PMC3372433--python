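"""Ground-truthed synthetic inputs for the comparative-mapping pipeline.

An ancestral marker genome is evolved independently along two (or more)
lineages by large-scale rearrangements — inversions, reciprocal
translocations, fusions and fissions — with optional marker loss and
paralog insertion.  One descendant is observed as a genetic map (linkage
groups, positions in cM), another as a physical genome (pseudo-chromosomes,
positions in bp), together with a noisy BLAST-style hit table linking the
two.  A :class:`TruthSet` records the true orthology and the maximal
ancestral segments conserved between the descendants, so downstream block
detection can be scored against ground truth.

Markers are points; rearrangement breakpoints fall only between markers.
All randomness flows from one integer seed through named
``numpy.random.Generator`` objects — no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import GeneticMapTable, HIT_COLUMNS, PHYSICAL_COLUMNS

DEFAULT_KIND_WEIGHTS = {
    "inversion": 0.4,
    "reciprocal_translocation": 0.4,
    "fusion": 0.1,
    "fission": 0.1,
}

#: Cap on the inter-marker spacing draw, in bp.  Curated comparative-mapping
#: marker panels are chosen for roughly even genome coverage, so the
#: generator avoids marker deserts wider than this.
DEFAULT_MAX_GAP_BP = 2_800_000.0

# lineage index -> chromosome-name prefix (query map, target genome, third)
_LINEAGE_PREFIXES = ("Q", "T", "R")


@dataclass
class Chromosome:
    """One chromosome: ordered markers with orientation and the physical gap
    (bp) preceding each marker."""

    name: str
    entries: list[list]  # [marker_id, orient (+1/-1), gap_bp]

    @property
    def markers(self) -> list[str]:
        return [e[0] for e in self.entries]

    def positions(self) -> np.ndarray:
        """Point position of each marker: cumulative sum of gaps, in bp."""
        return np.cumsum([e[2] for e in self.entries])

    @property
    def length_bp(self) -> float:
        return float(self.positions()[-1]) if self.entries else 0.0


@dataclass
class Genome:
    """An ordered collection of chromosomes holding point markers."""

    name: str
    chromosomes: list[Chromosome]

    def marker_ids(self) -> list[str]:
        return [m for c in self.chromosomes for m in c.markers]

    def locate(self) -> dict[str, tuple[str, int, float, int]]:
        """marker id -> (chromosome name, index on chromosome, bp, orient)."""
        out = {}
        for chrom in self.chromosomes:
            pos = chrom.positions()
            for i, (mid, orient, _gap) in enumerate(chrom.entries):
                out[mid] = (chrom.name, i, float(pos[i]), orient)
        return out


@dataclass
class RearrangementEvent:
    """One large-scale event.  Breakpoints are marker-interval indices: a cut
    at index k falls between the k-th and (k+1)-th marker of a chromosome
    (0 = before the first marker, n = after the last)."""

    kind: str  # inversion | reciprocal_translocation | fusion | fission
    lineage: int
    chrom_indices: tuple[int, ...]
    cuts: tuple[int, ...]


@dataclass
class TruthSet:
    """Simulator ground truth for one descendant pair.

    ``pairs`` maps query marker id to target feature id (one-to-one).
    ``true_blocks`` lists the maximal ancestral segments conserved between
    the two descendants: maximal runs of shared markers that occupy a
    contiguous stretch of shared markers on a single chromosome in *both*
    genomes.  Proximity, not gene order, defines a segment — an inversion
    inside a segment does not split it, matching the downstream block rule.
    """

    pairs: dict[str, str]
    lost_a: list[str]
    lost_b: list[str]
    paralogs_a: list[str]
    paralogs_b: list[str]
    true_blocks: list[list[str]]
    events_a: list[RearrangementEvent] = field(default_factory=list)
    events_b: list[RearrangementEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ancestor
# ---------------------------------------------------------------------------


def _draw_gaps(rng: np.random.Generator, n: int, mean_gap_bp: float, max_gap_bp: float):
    # Gamma(shape=4) spacing: unimodal, CV 0.5, capped to emulate the even
    # coverage of a curated marker panel.
    gaps = rng.gamma(shape=4.0, scale=mean_gap_bp / 4.0, size=n)
    return np.minimum(gaps, max_gap_bp)


def simulate_ancestor(
    n_chromosomes: int = 11,
    markers_per_chromosome: int = 40,
    mean_gap_bp: float = 1_100_000.0,
    seed: int | None = None,
    max_gap_bp: float = DEFAULT_MAX_GAP_BP,
) -> Genome:
    """Build an ancestral marker genome with i.i.d. gamma inter-marker gaps.

    Defaults give 440 markers over ~480 Mb — the scale of a few hundred
    single-copy markers anchored across a mid-sized plant genome.
    """
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise ValueError("counts must be >= 1")
    if mean_gap_bp <= 0:
        raise ValueError("mean_gap_bp must be positive")
    rng = np.random.default_rng(seed)
    chroms = []
    k = 0
    for c in range(n_chromosomes):
        gaps = _draw_gaps(rng, markers_per_chromosome, mean_gap_bp, max_gap_bp)
        entries = []
        for g in gaps:
            k += 1
            entries.append([f"m{k:04d}", 1, float(g)])
        chroms.append(Chromosome(name=f"anc{c + 1:02d}", entries=entries))
    return Genome(name="ancestor", chromosomes=chroms)


# ---------------------------------------------------------------------------
# rearrangement
# ---------------------------------------------------------------------------


def _apply_event(chroms: list[Chromosome], ev: RearrangementEvent) -> None:
    kind = ev.kind
    if kind == "inversion":
        (ci,) = ev.chrom_indices
        i, j = ev.cuts
        seg = chroms[ci].entries[i:j]
        seg = [[m, -o, g] for m, o, g in reversed(seg)]
        # gaps travel with markers; the reversed segment keeps its span
        chroms[ci].entries[i:j] = seg
    elif kind == "reciprocal_translocation":
        ca, cb = ev.chrom_indices
        ka, kb = ev.cuts
        a, b = chroms[ca].entries, chroms[cb].entries
        chroms[ca].entries = a[:ka] + b[kb:]
        chroms[cb].entries = b[:kb] + a[ka:]
    elif kind == "fusion":
        ca, cb = ev.chrom_indices
        chroms[ca].entries = chroms[ca].entries + chroms[cb].entries
        chroms[cb].entries = []
    elif kind == "fission":
        (ci,) = ev.chrom_indices
        (k,) = ev.cuts
        tail = chroms[ci].entries[k:]
        chroms[ci].entries = chroms[ci].entries[:k]
        chroms.append(Chromosome(name=f"{chroms[ci].name}.f", entries=tail))
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    # drop emptied chromosomes
    chroms[:] = [c for c in chroms if c.entries]


def _random_event(
    chroms: list[Chromosome], rng: np.random.Generator, kind_weights: Mapping[str, float], lineage: int
) -> RearrangementEvent | None:
    kinds = sorted(kind_weights)
    probs = np.array([kind_weights[k] for k in kinds], dtype=float)
    probs = probs / probs.sum()
    for _attempt in range(20):
        kind = str(rng.choice(kinds, p=probs))
        n_chroms = len(chroms)
        if kind == "inversion":
            eligible = [i for i, c in enumerate(chroms) if len(c.entries) >= 2]
            if not eligible:
                continue
            ci = int(rng.choice(eligible))
            n = len(chroms[ci].entries)
            i = int(rng.integers(0, n - 1))
            j = int(rng.integers(i + 2, n + 1))
            return RearrangementEvent(kind, lineage, (ci,), (i, j))
        if kind == "reciprocal_translocation":
            if n_chroms < 2:
                continue
            ca, cb = (int(x) for x in rng.choice(n_chroms, size=2, replace=False))
            na, nb = len(chroms[ca].entries), len(chroms[cb].entries)
            if na < 2 or nb < 2:
                continue
            ka, kb = int(rng.integers(1, na)), int(rng.integers(1, nb))
            return RearrangementEvent(kind, lineage, (ca, cb), (ka, kb))
        if kind == "fusion":
            if n_chroms < 2:
                continue
            ca, cb = (int(x) for x in rng.choice(n_chroms, size=2, replace=False))
            return RearrangementEvent(kind, lineage, (ca, cb), ())
        if kind == "fission":
            eligible = [i for i, c in enumerate(chroms) if len(c.entries) >= 2]
            if not eligible:
                continue
            ci = int(rng.choice(eligible))
            k = int(rng.integers(1, len(chroms[ci].entries)))
            return RearrangementEvent(kind, lineage, (ci,), (k,))
    return None


def _evolve_lineage(
    ancestor: Genome,
    lineage: int,
    n_events: int,
    kind_weights: Mapping[str, float],
    marker_loss_rate: float,
    paralog_rate: float,
    rng: np.random.Generator,
    mean_gap_bp: float,
    max_gap_bp: float,
    events: Sequence[RearrangementEvent] | None = None,
) -> tuple[Genome, list[RearrangementEvent], list[str], list[str]]:
    chroms = [
        Chromosome(name=c.name, entries=[list(e) for e in c.entries])
        for c in ancestor.chromosomes
    ]
    applied: list[RearrangementEvent] = []
    if events is not None:
        for ev in events:
            _apply_event(chroms, ev)
            applied.append(ev)
    else:
        for _ in range(n_events):
            ev = _random_event(chroms, rng, kind_weights, lineage)
            if ev is None:
                break
            _apply_event(chroms, ev)
            applied.append(ev)

    lost: list[str] = []
    if marker_loss_rate > 0:
        for chrom in chroms:
            kept = []
            carry = 0.0
            for mid, orient, gap in chrom.entries:
                if rng.random() < marker_loss_rate:
                    lost.append(mid)
                    carry += gap  # preserve physical span across the loss
                else:
                    kept.append([mid, orient, gap + carry])
                    carry = 0.0
            chrom.entries = kept
        chroms = [c for c in chroms if c.entries]

    paralogs: list[str] = []
    if paralog_rate > 0:
        surviving = [m for c in chroms for m in c.markers]
        n_par = int(rng.binomial(len(surviving), paralog_rate))
        for p in range(n_par):
            src = str(rng.choice(surviving))
            new_id = f"{src}_p{p + 1}"
            ci = int(rng.integers(0, len(chroms)))
            pos = int(rng.integers(0, len(chroms[ci].entries) + 1))
            gap = float(_draw_gaps(rng, 1, mean_gap_bp, max_gap_bp)[0])
            orient = int(rng.choice([1, -1]))
            chroms[ci].entries.insert(pos, [new_id, orient, gap])
            paralogs.append(new_id)

    prefix = _LINEAGE_PREFIXES[lineage % len(_LINEAGE_PREFIXES)]
    for i, chrom in enumerate(chroms):
        chrom.name = f"{prefix}{i + 1:02d}"
    genome = Genome(name=f"lineage_{prefix}", chromosomes=chroms)
    return genome, applied, lost, paralogs


def true_blocks(genome_a: Genome, genome_b: Genome, shared: set[str]) -> list[list[str]]:
    """Maximal conserved segments between two descendants.

    Shared markers are grouped by their (chromosome in A, chromosome in B)
    pair; within a group, a segment is the maximal run (in A order) whose
    members occupy consecutive ranks among the *group's* markers in B — a
    common interval of the group-restricted marker orders.  Markers of
    other groups interleaved on either chromosome are ignored: they are
    the interspersed foreign markers that distance-based chaining likewise
    does not break on.  Inversions and within-segment transpositions do not
    split a segment; any rearrangement that tears the group's markers apart
    in either genome does.  The blocks partition the shared markers.
    """
    chrom_of_b: dict[str, str] = {}
    for chrom in genome_b.chromosomes:
        for mid in chrom.markers:
            if mid in shared:
                chrom_of_b[mid] = chrom.name

    # group-restricted A order and B ranks
    order_a: dict[tuple[str, str], list[str]] = {}
    for chrom in genome_a.chromosomes:
        for mid in chrom.markers:
            if mid in shared:
                order_a.setdefault((chrom.name, chrom_of_b[mid]), []).append(mid)
    rank_b: dict[str, int] = {}
    counters: dict[tuple[str, str], int] = {}
    chrom_of_a = {
        mid: chrom.name for chrom in genome_a.chromosomes for mid in chrom.markers
    }
    for chrom in genome_b.chromosomes:
        for mid in chrom.markers:
            if mid in shared:
                key = (chrom_of_a[mid], chrom.name)
                rank_b[mid] = counters.get(key, 0)
                counters[key] = rank_b[mid] + 1

    blocks: list[list[str]] = []
    for key in sorted(order_a):
        run = order_a[key]
        i = 0
        while i < len(run):
            lo = hi = rank_b[run[i]]
            best_j = i
            for j in range(i + 1, len(run)):
                r = rank_b[run[j]]
                lo, hi = min(lo, r), max(hi, r)
                if hi - lo == j - i:  # ranks form a contiguous interval
                    best_j = j
            blocks.append(run[i : best_j + 1])
            i = best_j + 1
    return blocks


def build_truth(
    ancestor: Genome,
    genome_a: Genome,
    genome_b: Genome,
    events_a: Sequence[RearrangementEvent] = (),
    events_b: Sequence[RearrangementEvent] = (),
    paralogs_a: Sequence[str] = (),
    paralogs_b: Sequence[str] = (),
) -> TruthSet:
    """Assemble the ground truth for one descendant pair."""
    anc_ids = set(ancestor.marker_ids())
    ids_a = set(genome_a.marker_ids())
    ids_b = set(genome_b.marker_ids())
    shared = (ids_a & ids_b) & anc_ids
    pairs = {m: m for m in sorted(shared)}
    return TruthSet(
        pairs=pairs,
        lost_a=sorted(anc_ids - ids_a),
        lost_b=sorted(anc_ids - ids_b),
        paralogs_a=sorted(paralogs_a),
        paralogs_b=sorted(paralogs_b),
        true_blocks=true_blocks(genome_a, genome_b, shared),
        events_a=list(events_a),
        events_b=list(events_b),
    )


def evolve(
    ancestor: Genome,
    n_events_per_lineage: int = 8,
    kind_weights: Mapping[str, float] | None = None,
    marker_loss_rate: float = 0.0,
    paralog_rate: float = 0.0,
    seed: int | None = None,
    events_a: Sequence[RearrangementEvent] | None = None,
    events_b: Sequence[RearrangementEvent] | None = None,
    mean_gap_bp: float = 1_100_000.0,
    max_gap_bp: float = DEFAULT_MAX_GAP_BP,
) -> tuple[Genome, Genome, TruthSet]:
    """Evolve two descendants from a common ancestor.

    With zero events and zero loss the descendants are copies of the
    ancestor and the truth holds exactly one block per chromosome.
    Explicit event lists (``events_a``/``events_b``) override the random
    event draw — useful for constructing known scenarios.
    """
    genomes, all_events, all_par = evolve_multi(
        ancestor,
        n_lineages=2,
        n_events_per_lineage=n_events_per_lineage,
        kind_weights=kind_weights,
        marker_loss_rate=marker_loss_rate,
        paralog_rate=paralog_rate,
        seed=seed,
        explicit_events=(events_a, events_b),
        mean_gap_bp=mean_gap_bp,
        max_gap_bp=max_gap_bp,
    )
    truth = build_truth(
        ancestor,
        genomes[0],
        genomes[1],
        events_a=all_events[0],
        events_b=all_events[1],
        paralogs_a=all_par[0],
        paralogs_b=all_par[1],
    )
    return genomes[0], genomes[1], truth


def evolve_multi(
    ancestor: Genome,
    n_lineages: int,
    n_events_per_lineage: int = 8,
    kind_weights: Mapping[str, float] | None = None,
    marker_loss_rate: float = 0.0,
    paralog_rate: float = 0.0,
    seed: int | None = None,
    explicit_events: Sequence[Sequence[RearrangementEvent] | None] | None = None,
    mean_gap_bp: float = 1_100_000.0,
    max_gap_bp: float = DEFAULT_MAX_GAP_BP,
) -> tuple[list[Genome], list[list[RearrangementEvent]], list[list[str]]]:
    """Evolve ``n_lineages`` independent descendants of one ancestor."""
    if not 0.0 <= marker_loss_rate <= 1.0 or not 0.0 <= paralog_rate <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    weights = dict(kind_weights or DEFAULT_KIND_WEIGHTS)
    rng = np.random.default_rng(seed)
    genomes, events, paralogs = [], [], []
    for lin in range(n_lineages):
        forced = explicit_events[lin] if explicit_events else None
        child = np.random.default_rng(int(rng.integers(2**31)))
        g, ev, _lost, par = _evolve_lineage(
            ancestor,
            lin,
            n_events_per_lineage,
            weights,
            marker_loss_rate,
            paralog_rate,
            child,
            mean_gap_bp,
            max_gap_bp,
            events=forced,
        )
        genomes.append(g)
        events.append(ev)
        paralogs.append(par)
    return genomes, events, paralogs


# ---------------------------------------------------------------------------
# observation models: genetic map, physical placements, hit table
# ---------------------------------------------------------------------------


def project_genetic(
    genome: Genome,
    cM_per_Mb_mean: float = 2.8,
    cM_per_Mb_sd: float = 0.4,
    seed: int | None = None,
    map_name: str = "simulated_map",
) -> GeneticMapTable:
    """Project a descendant onto genetic-map coordinates.

    Each inter-marker physical gap is scaled by its own recombination rate
    drawn from a clipped normal (cM/Mb), so map distances jitter around
    linearity but marker order is always preserved (rank-preserving noise).
    """
    if cM_per_Mb_mean <= 0:
        raise ValueError("cM_per_Mb_mean must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in genome.chromosomes:
        gaps = np.array([e[2] for e in chrom.entries])
        rates = rng.normal(cM_per_Mb_mean, cM_per_Mb_sd, size=len(gaps))
        rates = np.clip(rates, 0.5, 4.0)  # recombination never vanishes/explodes
        cm = np.cumsum(gaps / 1e6 * rates)
        for (mid, _o, _g), pos in zip(chrom.entries, cm):
            rows.append((mid, chrom.name, round(float(pos), 3)))
    df = pd.DataFrame(rows, columns=["marker", "linkage_group", "cM"])
    return GeneticMapTable(df, map_name=map_name)


def placements(genome: Genome, feature_length: int = 500) -> pd.DataFrame:
    """Physical placements of a descendant's markers (1-based closed)."""
    rows = []
    for chrom in genome.chromosomes:
        pos = chrom.positions()
        for (mid, orient, _g), p in zip(chrom.entries, pos):
            start = int(p)
            rows.append(
                (mid, chrom.name, start, start + feature_length - 1, "+" if orient > 0 else "-")
            )
    return pd.DataFrame(rows, columns=list(PHYSICAL_COLUMNS))


def emit_hits(
    truth: TruthSet,
    target_placements: pd.DataFrame,
    seed: int | None = None,
    n_spurious_multihit: int = 0,
    n_weak_only: int = 0,
    n_split_hsp: int = 0,
    e_value_log10_range: tuple[float, float] = (-180.0, -30.0),
) -> pd.DataFrame:
    """Emit a BLAST-style hit table from the truth set.

    Every true ortholog pair yields one strong hit (E-value drawn log-
    uniformly from ``e_value_log10_range``, well below a 1e-10 strict
    cutoff).  ``n_spurious_multihit`` markers additionally receive a second
    strong hit at an unrelated position, to exercise the multi-locus
    exclusion.  ``n_weak_only`` markers *without* a true ortholog receive
    only a weak hit (E-value in (1e-6, 1e-5]), emulating sequences detected
    solely by relaxed fallback searches.  ``n_split_hsp`` markers have their
    true hit split into two nearby HSPs, exercising HSP merging.
    """
    rng = np.random.default_rng(seed)
    place = target_placements.set_index("feature")
    chrom_ends = target_placements.groupby("chrom")["end"].max().to_dict()
    chrom_names = sorted(chrom_ends)

    queries = sorted(truth.pairs)
    spurious = set(
        rng.choice(queries, size=min(n_spurious_multihit, len(queries)), replace=False)
    )
    split = set(
        rng.choice(
            sorted(set(queries) - spurious),
            size=min(n_split_hsp, max(0, len(queries) - len(spurious))),
            replace=False,
        )
    )
    weak_candidates = [m for m in truth.lost_b if m not in truth.pairs]
    weak = list(weak_candidates[: min(n_weak_only, len(weak_candidates))])

    rows = []

    def _hit(query, chrom, start, strand, log10_e, length=500):
        e = 10.0 ** log10_e
        s0, s1 = (start, start + length - 1) if strand == "+" else (start + length - 1, start)
        ident = round(float(rng.uniform(82.0, 99.0)), 2)
        mism = int(round(length * (100.0 - ident) / 100.0))
        bit = round(30.0 - 1.8 * log10_e, 1)
        rows.append(
            (query, chrom, ident, length, mism, 0, 1, length, int(s0), int(s1), e, bit)
        )

    lo, hi = e_value_log10_range
    for q in queries:
        feat = place.loc[truth.pairs[q]]
        log_e = float(rng.uniform(lo, hi))
        if q in split:
            # two HSPs of one gene, a few kb apart: must merge to one locus
            _hit(q, feat["chrom"], int(feat["start"]), feat["strand"], log_e, length=240)
            _hit(q, feat["chrom"], int(feat["start"]) + 5_000, feat["strand"], log_e + 1.0, length=240)
        else:
            _hit(q, feat["chrom"], int(feat["start"]), feat["strand"], log_e)
        if q in spurious:
            other = [c for c in chrom_names if c != feat["chrom"]] or chrom_names
            chrom2 = str(rng.choice(other))
            start2 = int(rng.uniform(1, max(2.0, chrom_ends[chrom2] - 500)))
            _hit(q, chrom2, start2, "+", float(rng.uniform(lo, hi)))
    for q in weak:
        chrom2 = str(rng.choice(chrom_names))
        start2 = int(rng.uniform(1, max(2.0, chrom_ends[chrom2] - 500)))
        _hit(q, chrom2, start2, "+", float(rng.uniform(-5.95, -5.0)))

    df = pd.DataFrame(rows, columns=list(HIT_COLUMNS))
    return df.sort_values(["query", "e_value"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def score_recovery(truth: TruthSet, detected_blocks: Sequence) -> dict:
    """Score detected blocks against the truth set.

    ``pair_coverage`` is the fraction of adjacent marker pairs inside true
    blocks whose two members land in the same detected block.  A *false
    merge* is a detected block containing markers from more than one true
    block.
    """
    true_idx: dict[str, int] = {}
    for i, blk in enumerate(truth.true_blocks):
        for m in blk:
            true_idx[m] = i
    det_idx: dict[str, int] = {}
    for j, blk in enumerate(detected_blocks):
        for m, _q, _t in blk.members:
            det_idx[m] = j

    n_pairs = covered = 0
    for blk in truth.true_blocks:
        for a, b in zip(blk, blk[1:]):
            n_pairs += 1
            if a in det_idx and b in det_idx and det_idx[a] == det_idx[b]:
                covered += 1

    false_merges = 0
    for blk in detected_blocks:
        sources = {true_idx[m] for m, _q, _t in blk.members if m in true_idx}
        if len(sources) > 1:
            false_merges += 1

    return {
        "n_true_blocks": len(truth.true_blocks),
        "n_detected_blocks": len(detected_blocks),
        "n_true_pairs": n_pairs,
        "n_covered_pairs": covered,
        "pair_coverage": covered / n_pairs if n_pairs else 1.0,
        "false_merges": false_merges,
    }
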