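"""Readers and writers for the external table formats the pipeline touches.

Three tabular inputs are supported: genetic maps (marker / linkage group /
centiMorgan TSV), physical placements (BED6 or GFF3 on pseudo-chromosomes)
and similarity hits (BLAST tabular, outfmt 6).  Internally all physical
coordinates are 1-based, closed intervals (the GFF3 convention); BED input
is converted on read and back on write.  Genetic positions are kept as the
decimal centiMorgan values printed in the file, never rescaled.

All writers emit deterministically ordered rows so that identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

GENETIC_MAP_HEADER = ("marker", "linkage_group", "cM")
PHYSICAL_COLUMNS = ("feature", "chrom", "start", "end", "strand")
HIT_COLUMNS = (
    "query",
    "subject",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
)


class FormatError(ValueError):
    """A file violated the expected dialect or an invariant of its table."""


# ---------------------------------------------------------------------------
# genetic maps
# ---------------------------------------------------------------------------


@dataclass
class GeneticMapTable:
    """A genetic map: markers with a linkage group and a position in cM.

    ``df`` has columns ``marker``, ``linkage_group``, ``cM``.  Linkage-group
    order is preserved as given in the source.  Marker ids are case-sensitive
    opaque strings, unique within a map.
    """

    df: pd.DataFrame
    map_name: str = "map"

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in GENETIC_MAP_HEADER if c not in df.columns]
        if missing:
            raise FormatError(f"genetic map missing columns: {missing}")
        if len(df) == 0:
            raise FormatError("no markers")
        dup = df["marker"][df["marker"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate marker id: {dup.iloc[0]!r}")
        pos = df["cM"].to_numpy(dtype=float)
        if not all(math.isfinite(p) for p in pos):
            raise FormatError("non-finite cM position")
        if (pos < 0).any():
            raise FormatError("negative cM position")

    @property
    def linkage_groups(self) -> list[str]:
        """Linkage groups in first-seen order."""
        return list(dict.fromkeys(self.df["linkage_group"]))

    @property
    def lg_lengths(self) -> dict[str, float]:
        """Length of each linkage group, taken as its maximal cM position."""
        return {
            lg: float(self.df.loc[self.df["linkage_group"] == lg, "cM"].max())
            for lg in self.linkage_groups
        }

    @property
    def total_length(self) -> float:
        """Total map length: the sum of linkage-group lengths, in cM."""
        return float(sum(self.lg_lengths.values()))

    def markers_on(self, lg: str) -> pd.DataFrame:
        """Markers of one linkage group, sorted by (cM, marker id)."""
        sub = self.df[self.df["linkage_group"] == lg]
        return sub.sort_values(["cM", "marker"], kind="stable").reset_index(drop=True)


def read_genetic_map(path: str | Path, map_name: str | None = None) -> GeneticMapTable:
    """Read a genetic map from a ``marker<TAB>linkage_group<TAB>cM`` TSV."""
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: no markers") from None
        if [h.strip() for h in header] != list(GENETIC_MAP_HEADER):
            raise FormatError(
                f"{path}: expected header {GENETIC_MAP_HEADER}, got {header}"
            )
        for lineno, rec in enumerate(reader, start=2):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            if len(rec) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(rec)}")
            marker, lg, pos_s = (c.strip() for c in rec)
            try:
                pos = float(pos_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cM position {pos_s!r}"
                ) from None
            rows.append((marker, lg, pos))
    if not rows:
        raise FormatError(f"{path}: no markers")
    df = pd.DataFrame(rows, columns=list(GENETIC_MAP_HEADER))
    return GeneticMapTable(df, map_name=map_name or path.stem)


def write_genetic_map(table: GeneticMapTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(GENETIC_MAP_HEADER) + "\n")
        for marker, lg, pos in table.df[list(GENETIC_MAP_HEADER)].itertuples(index=False):
            fh.write(f"{marker}\t{lg}\t{_fmt(pos)}\n")


# ---------------------------------------------------------------------------
# physical placements
# ---------------------------------------------------------------------------


def _validate_physical(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    if len(df):
        bad = df[df["end"] < df["start"]]
        if len(bad):
            row = bad.iloc[0]
            raise FormatError(
                f"{origin}: feature {row['feature']!r} has end < start"
            )
        if (df["start"] < 0).any():
            raise FormatError(f"{origin}: negative coordinate")
        dup = df["feature"][df["feature"].duplicated()]
        if len(dup):
            raise FormatError(f"{origin}: duplicate feature id: {dup.iloc[0]!r}")
    df["strand"] = [s if s in ("+", "-") else "." for s in df["strand"]]
    return df.reset_index(drop=True)


def read_physical_bed(path: str | Path) -> pd.DataFrame:
    """Read BED (0-based half-open) placements into the 1-based closed
    internal convention.  Columns beyond BED6 are ignored; a missing strand
    column is recorded as unknown (``.``)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: BED needs >= 4 columns")
            chrom, start_s, end_s, name = parts[:4]
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from None
            if end0 < start0:
                raise FormatError(f"{path}:{lineno}: end < start")
            strand = parts[5] if len(parts) >= 6 else "."
            rows.append((name, chrom, start0 + 1, end0, strand))
    df = pd.DataFrame(rows, columns=list(PHYSICAL_COLUMNS))
    return _validate_physical(df, str(path))


def read_physical_gff3(
    path: str | Path, feature_kind: str = "gene", id_attribute: str = "ID"
) -> pd.DataFrame:
    """Read features of one kind from a GFF3 file (1-based closed, as is)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    rows = []
    for feat in db.features_of_type(feature_kind, order_by=("seqid", "start")):
        ids = feat.attributes.get(id_attribute, [feat.id])
        rows.append((ids[0], feat.seqid, feat.start, feat.end, feat.strand or "."))
    df = pd.DataFrame(rows, columns=list(PHYSICAL_COLUMNS))
    return _validate_physical(df, str(path))


def write_physical_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write internal 1-based closed placements back to BED6."""
    with open(path, "w") as fh:
        for feature, chrom, start, end, strand in df[list(PHYSICAL_COLUMNS)].itertuples(
            index=False
        ):
            bed_strand = strand if strand in ("+", "-") else "."
            fh.write(f"{chrom}\t{int(start) - 1}\t{int(end)}\t{feature}\t.\t{bed_strand}\n")


def write_physical_gff3(
    df: pd.DataFrame,
    path: str | Path,
    feature_kind: str = "gene",
    source: str = "synmap",
    extra_attributes: Mapping[str, Mapping[str, str]] | None = None,
) -> None:
    """Write internal placements as GFF3.  ``extra_attributes`` optionally
    maps feature id -> {attribute: value} (used for e.g. family labels)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feature, chrom, start, end, strand in df[list(PHYSICAL_COLUMNS)].itertuples(
            index=False
        ):
            attrs = [f"ID={feature}"]
            if extra_attributes and feature in extra_attributes:
                attrs += [f"{k}={v}" for k, v in extra_attributes[feature].items()]
            fh.write(
                f"{chrom}\t{source}\t{feature_kind}\t{int(start)}\t{int(end)}\t.\t"
                f"{strand if strand in ('+', '-') else '.'}\t.\t{';'.join(attrs)}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular hits
# ---------------------------------------------------------------------------

_HIT_TYPES = (str, str, float, int, int, int, int, int, int, int, float, float)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a 12-column BLAST tabular (outfmt 6) hit file."""
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, rec in enumerate(reader, start=1):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            if rec[0].startswith("#"):
                continue
            if len(rec) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(rec)}"
                )
            try:
                row = tuple(t(v) for t, v in zip(_HIT_TYPES, rec))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed record") from None
            rows.append(row)
    df = pd.DataFrame(rows, columns=list(HIT_COLUMNS))
    if len(df) and (df["e_value"] < 0).any():
        raise FormatError(f"{path}: negative E-value")
    return df


def write_hit_table(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in df[list(HIT_COLUMNS)].itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# block reports and Circos-style links
# ---------------------------------------------------------------------------


def _fmt(value) -> str:
    """Stable text for a scalar: integers bare, floats via repr (round-trips)."""
    if isinstance(value, float):
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return repr(value)
    return str(value)


_BLOCK_REPORT_COLUMNS = (
    "block_id",
    "query_lg",
    "target_chrom",
    "n_syntenic",
    "n_interspersed",
    "query_start",
    "query_end",
    "span_query",
    "target_start",
    "target_end",
    "span_target",
    "target_unit",
    "members",
)


def _sorted_blocks(blocks) -> list:
    return sorted(blocks, key=lambda b: (b.query_lg, b.query_start, b.target_chrom))


def write_block_report(
    blocks: Sequence,
    path: str | Path,
    stats: Mapping | None = None,
    params: Mapping | None = None,
) -> None:
    """Write syntenic blocks as a TSV report, sorted by query linkage group
    then query start.  ``params`` (thresholds) and ``stats`` (summary) are
    recorded as ``# key=value`` header lines for provenance."""
    with open(path, "w") as fh:
        for name, mapping in (("param", params), ("stat", stats)):
            if mapping:
                for key in sorted(mapping):
                    fh.write(f"# {name} {key}={_fmt(mapping[key])}\n")
        fh.write("\t".join(_BLOCK_REPORT_COLUMNS) + "\n")
        for b in _sorted_blocks(blocks):
            members = ";".join(
                f"{m}:{_fmt(q)}:{_fmt(t)}" for m, q, t in b.members
            )
            fh.write(
                "\t".join(
                    (
                        b.block_id,
                        b.query_lg,
                        b.target_chrom,
                        str(b.n_syntenic),
                        str(b.n_interspersed),
                        _fmt(b.query_start),
                        _fmt(b.query_end),
                        _fmt(b.span_query),
                        _fmt(b.target_start),
                        _fmt(b.target_end),
                        _fmt(b.span_target),
                        b.target_unit,
                        members,
                    )
                )
                + "\n"
            )


def read_block_report(path: str | Path) -> list:
    """Read a block report written by :func:`write_block_report`."""
    from .macrosynteny import SyntenicBlock  # local import avoids a cycle

    blocks = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header != list(_BLOCK_REPORT_COLUMNS):
                    raise FormatError(f"{path}: unexpected block report header")
                continue
            rec = dict(zip(header, line.split("\t")))
            members = []
            for item in rec["members"].split(";"):
                marker, q, t = item.rsplit(":", 2)
                members.append((marker, float(q), float(t)))
            blocks.append(
                SyntenicBlock(
                    block_id=rec["block_id"],
                    query_lg=rec["query_lg"],
                    target_chrom=rec["target_chrom"],
                    members=members,
                    n_interspersed=int(rec["n_interspersed"]),
                    target_unit=rec["target_unit"],
                )
            )
    return blocks


def write_links(blocks: Sequence, path: str | Path, cm_scale: float = 1e6) -> None:
    """Write blocks as 6-column Circos-style links.

    The query interval is in cM multiplied by ``cm_scale`` (so genetic and
    physical intervals plot on comparable axes); the target interval is in
    its native unit (bp for map-versus-genome comparisons).
    """
    with open(path, "w") as fh:
        for b in _sorted_blocks(blocks):
            q0 = int(round(b.query_start * cm_scale))
            q1 = int(round(b.query_end * cm_scale))
            fh.write(
                f"{b.query_lg}\t{q0}\t{q1}\t"
                f"{b.target_chrom}\t{int(round(b.target_start))}\t{int(round(b.target_end))}\n"
            )
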