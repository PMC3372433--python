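"""Gene-order microsynteny between annotated genomic segments.

Input segments are ordered, oriented gene lists with gene-family labels
(family assignment is an input, e.g. from a published ortholog table; a
single-linkage helper over a precomputed similarity matrix is provided for
building fixtures).  The collinear backbone between two segments is a
longest common subsequence (LCS) of family labels over order indices: each
matched pair is *conserved in order*; its orientation relative to the
backbone's consensus reading classifies it as same-order-and-orientation
or inverted.  Unmatched genes whose family is matched elsewhere are tandem
*duplicates*; the rest are lineage-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class Gene:
    gene_id: str
    family: str | None
    strand: str  # '+' or '-'
    order_index: int


@dataclass
class AnnotatedSegment:
    """An ordered, oriented, family-labelled gene list for one segment."""

    segment_id: str
    species: str
    genes: list[Gene]

    def __post_init__(self) -> None:
        idx = [g.order_index for g in self.genes]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"{self.segment_id}: order_index must strictly increase")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.segment_id}: duplicate gene id")

    def window(self, lo: int, hi: int) -> "AnnotatedSegment":
        """Sub-segment restricted to order indices in [lo, hi]."""
        return AnnotatedSegment(
            segment_id=f"{self.segment_id}[{lo}:{hi}]",
            species=self.species,
            genes=[g for g in self.genes if lo <= g.order_index <= hi],
        )


def segment(
    segment_id: str,
    genes: Sequence[tuple[str, str | None, str]],
    species: str | None = None,
) -> AnnotatedSegment:
    """Convenience constructor from (gene_id, family, strand) triples."""
    return AnnotatedSegment(
        segment_id=segment_id,
        species=species or segment_id,
        genes=[Gene(g, f, s, i) for i, (g, f, s) in enumerate(genes)],
    )


def reverse_and_flip(seg: AnnotatedSegment) -> AnnotatedSegment:
    """The segment read from the other end: order reversed, strands flipped."""
    n = len(seg.genes)
    genes = [
        Gene(g.gene_id, g.family, "-" if g.strand == "+" else "+", n - 1 - i)
        for i, g in zip(range(n - 1, -1, -1), reversed(seg.genes))
    ]
    genes.sort(key=lambda g: g.order_index)
    return AnnotatedSegment(
        segment_id=f"{seg.segment_id}.rev", species=seg.species, genes=genes
    )


@dataclass
class MicrosyntenyReport:
    """Classification of every gene of two compared segments.

    ``pairs`` lists matched (gene_a, gene_b, class) with class
    ``same_order_and_orientation`` or ``inverted``;
    ``matched_families = same_order_and_orientation + inverted``.
    ``classes_a`` / ``classes_b`` give each gene's class
    (matched class, ``duplicated`` or ``specific``).
    """

    segment_a: AnnotatedSegment
    segment_b: AnnotatedSegment
    reading: str  # 'forward' or 'reverse'
    allow_reverse_reading: bool
    matched_families: int
    same_order_and_orientation: int
    inverted: int
    duplicated_a: int
    duplicated_b: int
    a_specific: int
    b_specific: int
    pairs: list[tuple[str, str, str]]
    classes_a: dict[str, str]
    classes_b: dict[str, str]

    @property
    def duplicated(self) -> int:
        return self.duplicated_a + self.duplicated_b

    def to_dict(self) -> dict:
        return {
            "segment_a": self.segment_a.segment_id,
            "segment_b": self.segment_b.segment_id,
            "reading": self.reading,
            "matched_families": self.matched_families,
            "same_order_and_orientation": self.same_order_and_orientation,
            "inverted": self.inverted,
            "duplicated": self.duplicated,
            "duplicated_a": self.duplicated_a,
            "duplicated_b": self.duplicated_b,
            "a_specific": self.a_specific,
            "b_specific": self.b_specific,
        }


def _lcs_pairs(fams_a: list[str], fams_b: list[str]) -> list[tuple[int, int]]:
    """Leftmost-in-A LCS backbone over family label sequences."""
    n, m = len(fams_a), len(fams_b)
    # L[i][j] = LCS length of suffixes a[i:], b[j:]
    L = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if fams_a[i] == fams_b[j]:
                L[i][j] = 1 + L[i + 1][j + 1]
            else:
                L[i][j] = max(L[i + 1][j], L[i][j + 1])
    pairs = []
    i = j = 0
    while i < n and j < m:
        if fams_a[i] == fams_b[j] and L[i][j] == 1 + L[i + 1][j + 1]:
            pairs.append((i, j))
            i += 1
            j += 1
        elif L[i + 1][j] >= L[i][j + 1]:
            i += 1
        else:
            j += 1
    return pairs


def _align_oriented(
    seg_a: AnnotatedSegment, seg_b: AnnotatedSegment
) -> tuple[list[tuple[Gene, Gene]], int]:
    a_lab = [(k, g) for k, g in enumerate(seg_a.genes) if g.family is not None]
    b_lab = [(k, g) for k, g in enumerate(seg_b.genes) if g.family is not None]
    idx_pairs = _lcs_pairs([g.family for _k, g in a_lab], [g.family for _k, g in b_lab])
    matched = [(a_lab[i][1], b_lab[j][1]) for i, j in idx_pairs]
    return matched, len(matched)


def align_segments(
    seg_a: AnnotatedSegment,
    seg_b: AnnotatedSegment,
    allow_reverse_reading: bool = False,
) -> MicrosyntenyReport:
    """Collinear family matching and per-gene classification.

    With ``allow_reverse_reading`` segment B is also tried reversed-and-
    flipped and the reading with the larger backbone is reported (forward
    wins ties).  The consensus relative orientation is the majority over
    matched pairs; exact ties default to the same-strand reading.

    When several LCS backbones exist the leftmost one (in the
    lexicographically first segment) is chosen; the comparison is computed
    in that canonical segment order and mirrored, so ``align(A, B)`` and
    ``align(B, A)`` always give mirrored classifications.
    """
    if seg_b.segment_id < seg_a.segment_id:
        return _mirror(align_segments(seg_b, seg_a, allow_reverse_reading), seg_a, seg_b)
    matched_fwd, n_fwd = _align_oriented(seg_a, seg_b)
    reading, seg_b_used, matched = "forward", seg_b, matched_fwd
    if allow_reverse_reading:
        seg_b_rev = reverse_and_flip(seg_b)
        matched_rev, n_rev = _align_oriented(seg_a, seg_b_rev)
        if n_rev > n_fwd:
            reading, seg_b_used, matched = "reverse", seg_b_rev, matched_rev

    n_same_strand = sum(1 for ga, gb in matched if ga.strand == gb.strand)
    n_opp = len(matched) - n_same_strand
    consensus_same = n_same_strand >= n_opp  # tie -> '+/+' reading

    pairs = []
    classes_a: dict[str, str] = {}
    classes_b: dict[str, str] = {}
    for ga, gb in matched:
        same = ga.strand == gb.strand
        cls = (
            "same_order_and_orientation"
            if same == consensus_same
            else "inverted"
        )
        pairs.append((ga.gene_id, gb.gene_id, cls))
        classes_a[ga.gene_id] = cls
        classes_b[gb.gene_id] = cls

    matched_fams = {ga.family for ga, _gb in matched}
    dup_a = dup_b = spec_a = spec_b = 0
    for g in seg_a.genes:
        if g.gene_id in classes_a:
            continue
        if g.family is not None and g.family in matched_fams:
            classes_a[g.gene_id] = "duplicated"
            dup_a += 1
        else:
            classes_a[g.gene_id] = "specific"
            spec_a += 1
    for g in seg_b_used.genes:
        if g.gene_id in classes_b:
            continue
        if g.family is not None and g.family in matched_fams:
            classes_b[g.gene_id] = "duplicated"
            dup_b += 1
        else:
            classes_b[g.gene_id] = "specific"
            spec_b += 1

    n_inverted = sum(1 for _a, _b, c in pairs if c == "inverted")
    return MicrosyntenyReport(
        segment_a=seg_a,
        segment_b=seg_b,
        reading=reading,
        allow_reverse_reading=allow_reverse_reading,
        matched_families=len(matched),
        same_order_and_orientation=len(matched) - n_inverted,
        inverted=n_inverted,
        duplicated_a=dup_a,
        duplicated_b=dup_b,
        a_specific=spec_a,
        b_specific=spec_b,
        pairs=pairs,
        classes_a=classes_a,
        classes_b=classes_b,
    )


def _mirror(
    rep: MicrosyntenyReport, seg_a: AnnotatedSegment, seg_b: AnnotatedSegment
) -> MicrosyntenyReport:
    """Swap the two sides of a report (segments, pairs and per-side counts)."""
    return MicrosyntenyReport(
        segment_a=seg_a,
        segment_b=seg_b,
        reading=rep.reading,
        allow_reverse_reading=rep.allow_reverse_reading,
        matched_families=rep.matched_families,
        same_order_and_orientation=rep.same_order_and_orientation,
        inverted=rep.inverted,
        duplicated_a=rep.duplicated_b,
        duplicated_b=rep.duplicated_a,
        a_specific=rep.b_specific,
        b_specific=rep.a_specific,
        pairs=[(b, a, c) for a, b, c in rep.pairs],
        classes_a=dict(rep.classes_b),
        classes_b=dict(rep.classes_a),
    )


def overlap_window(
    report: MicrosyntenyReport,
    seg_a_bounds: tuple[int, int],
    seg_b_bounds: tuple[int, int],
) -> MicrosyntenyReport:
    """Re-run the comparison restricted to order-index windows of both
    segments (e.g. the region where several species' sequences overlap)."""
    sub_a = report.segment_a.window(*seg_a_bounds)
    sub_b = report.segment_b.window(*seg_b_bounds)
    return align_segments(sub_a, sub_b, report.allow_reverse_reading)


def multi_segment_matrix(
    segments: Sequence[AnnotatedSegment], allow_reverse_reading: bool = False
) -> dict[tuple[str, str], MicrosyntenyReport]:
    """All pairwise reports (including self-identity on the diagonal)."""
    if len(segments) < 2:
        raise ValueError("need at least two segments")
    out: dict[tuple[str, str], MicrosyntenyReport] = {}
    for i, a in enumerate(segments):
        for b in segments[i:]:
            out[(a.segment_id, b.segment_id)] = align_segments(
                a, b, allow_reverse_reading
            )
    return out


def families_from_similarity(
    gene_ids: Sequence[str],
    similarity: Mapping[tuple[str, str], float],
    threshold: float,
    prefix: str = "fam",
) -> dict[str, str]:
    """Single-linkage family grouping from a precomputed similarity matrix.

    Fixture helper only — sequence search is outside this package's scope.
    Genes joined by any similarity >= threshold share a family; families
    are named ``fam1..famN`` in order of their first member.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(gene_ids)
    for (a, b), s in similarity.items():
        if s >= threshold:
            g.add_edge(a, b)
    order = {gid: k for k, gid in enumerate(gene_ids)}
    comps = sorted(nx.connected_components(g), key=lambda c: min(order[x] for x in c))
    out = {}
    for k, comp in enumerate(comps, start=1):
        for gid in comp:
            out[gid] = f"{prefix}{k}"
    return out


def segment_from_gff3(
    path: str | Path,
    segment_id: str | None = None,
    species: str | None = None,
    feature_kind: str = "gene",
    family_attribute: str = "family",
) -> AnnotatedSegment:
    """Load a segment from GFF3; the family label is carried in an attribute
    (default key ``family``); genes without it are lineage-specific."""
    import gffutils

    path = Path(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    feats = sorted(
        db.features_of_type(feature_kind), key=lambda f: (f.seqid, f.start, f.id)
    )
    genes = [
        Gene(
            gene_id=f.attributes.get("ID", [f.id])[0],
            family=(f.attributes.get(family_attribute, [None]) or [None])[0],
            strand=f.strand if f.strand in ("+", "-") else "+",
            order_index=i,
        )
        for i, f in enumerate(feats)
    ]
    return AnnotatedSegment(
        segment_id=segment_id or path.stem, species=species or path.stem, genes=genes
    )


def write_report(reports: Iterable[MicrosyntenyReport], path: str | Path) -> None:
    """Write one or more pairwise reports as a TSV table."""
    rows = [r.to_dict() for r in reports]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
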