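"""Readers and writers for the standard formats the anchoring pipeline touches.

Dialect decisions made explicit here:

* Internal alignment coordinates are uniformly 0-based half-open on the
  target; AGP output is 1-based inclusive (the AGP v2.1 convention).
* PSL identity is ``matches / (matches + misMatches)`` (repMatches and Ns
  ignored); coverage is ``(qEnd - qStart) / qSize``.
* BLAST tabular ("outfmt 6") lacks the query length, so coverage needs an
  external id -> length table; ``sstart > send`` encodes the '-' strand and
  is normalised on read.
* Readers never filter: identity/coverage thresholding happens downstream
  so the filters are testable in isolation.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A file did not follow the expected layout."""


class AgpError(ValueError):
    """AGP rows are internally inconsistent."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentHit:
    """One query-to-scaffold alignment (filtered or not).

    ``identity`` and ``coverage`` are fractions in [0, 1]; ``target_start``
    and ``target_end`` are 0-based half-open positions on the target.
    """

    query_id: str
    target_id: str
    identity: float
    coverage: float
    target_start: int
    target_end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity out of [0,1]: {self.identity}")
        if not (0.0 <= self.coverage):
            raise ValueError(f"negative coverage: {self.coverage}")
        if self.target_start < 0 or self.target_end <= self.target_start:
            raise ValueError(
                f"bad target interval [{self.target_start}, {self.target_end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class GeneticMapRecord:
    marker_id: str
    linkage_group: str
    cm: float
    source: str  # 'published' or 'new'

    def __post_init__(self) -> None:
        if not np.isfinite(self.cm) or self.cm < 0:
            raise ValueError(f"bad cM position {self.cm} for {self.marker_id}")
        if self.source not in ("published", "new"):
            raise ValueError(f"bad map source {self.source!r}")


@dataclass(frozen=True)
class PhysicalMembership:
    bac_id: str
    contig_id: str | None  # None for singleton BACs (not in any contig)
    singleton: bool = False


@dataclass(frozen=True)
class AgpRow:
    """One AGP v2.1 row; coordinates 1-based inclusive."""

    object_id: str
    object_start: int
    object_end: int
    part_number: int
    component_type: str  # 'W' or 'N'
    # W fields
    component_id: str | None = None
    component_start: int | None = None
    component_end: int | None = None
    orientation: str | None = None  # '+', '-', '?'
    # N fields
    gap_length: int | None = None
    gap_type: str | None = None
    linkage: str | None = None
    evidence: str | None = None


# ---------------------------------------------------------------------------
# alignment formats
# ---------------------------------------------------------------------------

_PSL_NCOL = 21


def read_psl(path: str | Path) -> list[AlignmentHit]:
    """Parse a 21-column PSL file (optional psLayout header) into hits.

    identity = matches/(matches+misMatches); coverage = (qEnd-qStart)/qSize.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        in_header = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            first = fields[0].split()[0] if fields[0].strip() else ""
            if in_header and not _is_int(first):
                # psLayout banner / column-name / dash lines
                continue
            in_header = False
            if len(fields) != _PSL_NCOL:
                raise ParseError(
                    f"{path}: line {lineno}: expected {_PSL_NCOL} PSL columns, "
                    f"got {len(fields)}"
                )
            try:
                matches = int(fields[0])
                mismatches = int(fields[1])
                strand = fields[8][0]
                q_name = fields[9]
                q_size = int(fields[10])
                q_start = int(fields[11])
                q_end = int(fields[12])
                t_name = fields[13]
                t_start = int(fields[15])
                t_end = int(fields[16])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if q_size == 0:
                raise ParseError(f"{path}: line {lineno}: qSize is 0 for {q_name}")
            denom = matches + mismatches
            identity = matches / denom if denom else 0.0
            coverage = (q_end - q_start) / q_size
            hits.append(
                AlignmentHit(
                    query_id=q_name,
                    target_id=t_name,
                    identity=identity,
                    coverage=min(coverage, 1.0),
                    target_start=t_start,
                    target_end=t_end,
                    strand=strand,
                )
            )
    return hits


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def write_psl(rows: Iterable[Mapping[str, object]], path: str | Path) -> None:
    """Write minimal PSL rows from dicts with keys matches, mismatches,
    strand, qname, qsize, qstart, qend, tname, tsize, tstart, tend.

    Repeat/N/insert counts and block columns are zero-filled single blocks.
    """
    with open(path, "w") as fh:
        for r in rows:
            block = int(r["qend"]) - int(r["qstart"])
            fields = [
                r["matches"], r["mismatches"], 0, 0, 0, 0, 0, 0,
                r["strand"], r["qname"], r["qsize"], r["qstart"], r["qend"],
                r["tname"], r["tsize"], r["tstart"], r["tend"],
                1, f"{block},", f"{r['qstart']},", f"{r['tstart']},",
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_blast6(
    path: str | Path, query_lengths: Mapping[str, int]
) -> list[AlignmentHit]:
    """Parse 12-column BLAST tabular output into hits.

    identity = pident/100; coverage = alignment length / query length;
    subject start > end encodes the '-' strand (normalised to forward
    0-based half-open coordinates).
    """
    hits: list[AlignmentHit] = []
    missing: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            qid, sid = fields[0], fields[1]
            if qid not in query_lengths:
                if qid not in missing:
                    missing.append(qid)
                continue
            pident = float(fields[2])
            aln_len = int(fields[3])
            sstart, send = int(fields[8]), int(fields[9])
            if sstart <= send:
                strand, t0, t1 = "+", sstart - 1, send
            else:
                strand, t0, t1 = "-", send - 1, sstart
            qlen = query_lengths[qid]
            if qlen <= 0:
                raise ParseError(f"{path}: non-positive length for query {qid}")
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    target_id=sid,
                    identity=pident / 100.0,
                    coverage=min(aln_len / qlen, 1.0),
                    target_start=t0,
                    target_end=t1,
                    strand=strand,
                )
            )
    if missing:
        raise ParseError(
            f"{path}: query ids absent from the length table: {', '.join(sorted(missing))}"
        )
    return hits


def write_blast6(rows: Iterable[Mapping[str, object]], path: str | Path) -> None:
    """Write 12-column BLAST tabular rows from dicts with keys qseqid,
    sseqid, pident, length, qstart, qend, sstart, send (1-based, sstart >
    send for '-' hits)."""
    with open(path, "w") as fh:
        for r in rows:
            fields = [
                r["qseqid"], r["sseqid"], f"{float(r['pident']):.2f}",
                r["length"], r.get("mismatch", 0), r.get("gapopen", 0),
                r["qstart"], r["qend"], r["sstart"], r["send"],
                r.get("evalue", "1e-50"), r.get("bitscore", "200"),
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> uppercase-sequence mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for {rec.id!r}")
        records[rec.id] = seq
    return records


def write_fasta(
    records: Mapping[str, str], path: str | Path, line_width: int = 60
) -> None:
    seq_records = []
    for rid, seq in records.items():
        if not seq:
            raise ValueError(f"refusing to write empty sequence for {rid!r}")
        seq_records.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# AGP v2.1
# ---------------------------------------------------------------------------


def validate_agp_rows(rows: Sequence[AgpRow]) -> None:
    """Check contiguity, part numbering and span consistency per object."""
    by_object: dict[str, list[AgpRow]] = {}
    for row in rows:
        by_object.setdefault(row.object_id, []).append(row)
    for obj, obj_rows in by_object.items():
        expected_start = 1
        for i, row in enumerate(obj_rows, start=1):
            if row.part_number != i:
                raise AgpError(f"{obj}: part_number {row.part_number} != {i}")
            if row.object_start != expected_start:
                raise AgpError(
                    f"{obj}: part {i} starts at {row.object_start}, "
                    f"expected {expected_start} (overlap or gap)"
                )
            if row.object_end < row.object_start:
                raise AgpError(f"{obj}: part {i} has negative span")
            span = row.object_end - row.object_start + 1
            if row.component_type == "W":
                comp_span = row.component_end - row.component_start + 1
                if comp_span != span:
                    raise AgpError(
                        f"{obj}: part {i}: W span {span} != component span {comp_span}"
                    )
            elif row.component_type == "N":
                if row.gap_length != span:
                    raise AgpError(
                        f"{obj}: part {i}: N span {span} != gap_length {row.gap_length}"
                    )
            else:
                raise AgpError(f"{obj}: part {i}: bad component_type {row.component_type!r}")
            expected_start = row.object_end + 1


def write_agp(pseudomolecules, path: str | Path) -> None:
    """Write AGP v2.1. Accepts objects exposing ``agp_rows()`` (pseudomolecules)
    or an iterable of :class:`AgpRow`. Validates before writing anything."""
    rows: list[AgpRow] = []
    for item in pseudomolecules:
        if hasattr(item, "agp_rows"):
            rows.extend(item.agp_rows())
        else:
            rows.append(item)
    validate_agp_rows(rows)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for r in rows:
            if r.component_type == "W":
                tail = [r.component_id, r.component_start, r.component_end, r.orientation]
            else:
                tail = [r.gap_length, r.gap_type, r.linkage, r.evidence]
            fh.write(
                "\t".join(
                    str(f)
                    for f in [
                        r.object_id, r.object_start, r.object_end,
                        r.part_number, r.component_type, *tail,
                    ]
                )
                + "\n"
            )


def read_agp(path: str | Path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 AGP columns")
            ctype = f[4]
            if ctype == "W":
                rows.append(
                    AgpRow(
                        object_id=f[0], object_start=int(f[1]), object_end=int(f[2]),
                        part_number=int(f[3]), component_type="W",
                        component_id=f[5], component_start=int(f[6]),
                        component_end=int(f[7]), orientation=f[8],
                    )
                )
            elif ctype in ("N", "U"):
                rows.append(
                    AgpRow(
                        object_id=f[0], object_start=int(f[1]), object_end=int(f[2]),
                        part_number=int(f[3]), component_type="N",
                        gap_length=int(f[5]), gap_type=f[6], linkage=f[7],
                        evidence=f[8],
                    )
                )
            else:
                raise ParseError(f"{path}: line {lineno}: bad component type {ctype!r}")
    validate_agp_rows(rows)
    return rows


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

_MAP_COLS = ["marker_id", "linkage_group", "cm", "source"]
_PHYS_COLS = ["bac_id", "contig_id"]
_QLEN_COLS = ["id", "length"]


def _read_tsv(path: str | Path, expected_cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    unknown = [c for c in df.columns if c not in expected_cols]
    if unknown:
        raise ParseError(f"{path}: unknown column(s): {', '.join(unknown)}")
    missing = [c for c in expected_cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s): {', '.join(missing)}")
    return df


def read_genetic_map(path: str | Path) -> list[GeneticMapRecord]:
    df = _read_tsv(path, _MAP_COLS)
    dup = df.duplicated(subset=["marker_id", "source"])
    if dup.any():
        dups = df.loc[dup, "marker_id"].tolist()
        raise ParseError(f"{path}: duplicate (marker_id, source): {dups}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GeneticMapRecord(
                marker_id=row.marker_id,
                linkage_group=row.linkage_group,
                cm=float(row.cm),
                source=row.source,
            )
        )
    return records


def write_genetic_map(records: Iterable[GeneticMapRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_MAP_COLS) + "\n")
        for r in records:
            fh.write(f"{r.marker_id}\t{r.linkage_group}\t{float(r.cm)!r}\t{r.source}\n")


def read_physical_map(path: str | Path) -> list[PhysicalMembership]:
    df = _read_tsv(path, _PHYS_COLS)
    if df["bac_id"].duplicated().any():
        dups = df.loc[df["bac_id"].duplicated(), "bac_id"].tolist()
        raise ParseError(f"{path}: BAC(s) assigned to more than one contig: {dups}")
    out = []
    for row in df.itertuples(index=False):
        contig = row.contig_id if isinstance(row.contig_id, str) and row.contig_id not in ("", "-") else None
        out.append(PhysicalMembership(bac_id=row.bac_id, contig_id=contig, singleton=contig is None))
    return out


def write_physical_map(memberships: Iterable[PhysicalMembership], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PHYS_COLS) + "\n")
        for m in memberships:
            fh.write(f"{m.bac_id}\t{m.contig_id if m.contig_id is not None else '-'}\n")


def read_query_lengths(path: str | Path) -> dict[str, int]:
    df = _read_tsv(path, _QLEN_COLS)
    if df["id"].duplicated().any():
        raise ParseError(f"{path}: duplicate query ids")
    lengths = {}
    for row in df.itertuples(index=False):
        n = int(row.length)
        if n <= 0:
            raise ParseError(f"{path}: non-positive length for {row.id}")
        lengths[row.id] = n
    return lengths


def write_query_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlength\n")
        for qid, n in lengths.items():
            fh.write(f"{qid}\t{n}\n")


def read_depth_matrix(path: str | Path):
    """Read an allele-depth TSV (chrom, pos, ref, alt, then one
    "refDepth,altDepth" column per individual) into a GenotypeMatrix."""
    from .ld import GenotypeMatrix

    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header[:4] != ["chrom", "pos", "ref", "alt"]:
            raise ParseError(f"{path}: expected columns chrom, pos, ref, alt first")
        individuals = header[4:]
        if not individuals:
            raise ParseError(f"{path}: no individual columns")
        sites = []
        ref_rows, alt_rows = [], []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 4 + len(individuals):
                raise ParseError(f"{path}: line {lineno}: wrong column count")
            sites.append((f[0], int(f[1]), f[2], f[3]))
            refs, alts = [], []
            for cell in f[4:]:
                try:
                    r_s, a_s = cell.split(",")
                    r, a = int(r_s), int(a_s)
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: bad depth cell {cell!r}") from exc
                if r < 0 or a < 0:
                    raise ParseError(f"{path}: line {lineno}: negative depth")
                refs.append(r)
                alts.append(a)
            ref_rows.append(refs)
            alt_rows.append(alts)
    sites_df = pd.DataFrame(sites, columns=["chrom", "pos", "ref", "alt"])
    if sites_df.duplicated(subset=["chrom", "pos"]).any():
        raise ParseError(f"{path}: duplicate (chrom, pos) site")
    return GenotypeMatrix(
        sites=sites_df,
        individuals=list(individuals),
        ref_depth=np.asarray(ref_rows, dtype=np.int64).reshape(len(sites), len(individuals)),
        alt_depth=np.asarray(alt_rows, dtype=np.int64).reshape(len(sites), len(individuals)),
    )


def write_depth_matrix(matrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["chrom", "pos", "ref", "alt", *matrix.individuals]) + "\n")
        for i, site in enumerate(matrix.sites.itertuples(index=False)):
            cells = [
                f"{matrix.ref_depth[i, j]},{matrix.alt_depth[i, j]}"
                for j in range(len(matrix.individuals))
            ]
            fh.write(f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.alt}\t" + "\t".join(cells) + "\n")
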