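"""Readers and writers for the formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open ``[start, end)``.  GFF3 is
1-based inclusive and is converted on the way in and out.  Insertion "plot"
files carry one row per genome base (row ``i`` describes base ``i`` in
internal coordinates, i.e. base ``i + 1`` of the 1-based genome) with two
whitespace-separated integer columns: unique-read count for the forward
(alpha) and reverse (beta) transposon orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "GenomeAnnotation",
    "InsertionProfile",
    "FormatError",
    "GFFParseError",
    "REPORT_COLUMNS",
    "read_gff3",
    "write_gff3",
    "read_plot",
    "write_plot",
    "read_site_list",
    "write_site_list",
    "write_gene_report",
    "read_gene_report",
    "read_gene_list",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class GFFParseError(FormatError):
    """A GFF3 line could not be parsed; message names the line number."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated feature as a half-open interval on the genome.

    ``feature_kind`` is one of ``{"CDS", "pseudogene", "other"}``; a CDS is
    the protein coding sequence inclusive of start and stop codons.
    """

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    feature_kind: str = "CDS"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"gene {self.gene_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """A genome length plus an ordered (by start) collection of genes."""

    genome_length: int
    genes: list[GeneRecord] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise FormatError("genome_length must be positive")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        seen: set[str] = set()
        for g in self.genes:
            if g.start < 0 or g.end > self.genome_length:
                raise FormatError(
                    f"gene {g.gene_id!r} interval [{g.start}, {g.end}) outside "
                    f"[0, {self.genome_length})"
                )
            if g.gene_id in seen:
                raise FormatError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class InsertionProfile:
    """Per-base unique-insertion read counts for both transposon orientations."""

    fwd_counts: np.ndarray
    rev_counts: np.ndarray

    def __post_init__(self) -> None:
        self.fwd_counts = np.asarray(self.fwd_counts, dtype=np.int64)
        self.rev_counts = np.asarray(self.rev_counts, dtype=np.int64)
        if self.fwd_counts.shape != self.rev_counts.shape or self.fwd_counts.ndim != 1:
            raise FormatError("forward/reverse count arrays must be equal-length 1-D")
        if (self.fwd_counts < 0).any() or (self.rev_counts < 0).any():
            raise FormatError("insertion counts must be non-negative")

    @property
    def genome_length(self) -> int:
        return int(self.fwd_counts.shape[0])

    @cached_property
    def occupancy(self) -> np.ndarray:
        """Boolean array: True at bases with any insertion evidence."""
        return (self.fwd_counts + self.rev_counts) > 0

    @property
    def unique_sites(self) -> int:
        return int(self.occupancy.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InsertionProfile):
            return NotImplemented
        return bool(
            np.array_equal(self.fwd_counts, other.fwd_counts)
            and np.array_equal(self.rev_counts, other.rev_counts)
        )


# ---------------------------------------------------------------------------
# GFF3


def _feature_kind(gff_type: str) -> str:
    if gff_type == "CDS":
        return "CDS"
    if gff_type == "pseudogene":
        return "pseudogene"
    return "other"


def _attr_id(attrs: str, fallback: str) -> str:
    for key in ("ID", "Name", "locus_tag", "gene"):
        for chunk in attrs.split(";"):
            chunk = chunk.strip()
            if chunk.startswith(key + "="):
                return chunk[len(key) + 1 :]
    return fallback


def read_gff3(
    path: str | Path,
    feature_types: Iterable[str] = ("CDS",),
    genome_length: int | None = None,
    circular: bool = False,
) -> GenomeAnnotation:
    """Read a GFF3 file into a :class:`GenomeAnnotation`.

    Only features whose type column is in ``feature_types`` are retained.
    The genome length is taken from the ``##sequence-region`` directive
    unless ``genome_length`` is supplied explicitly.  Duplicate feature IDs
    are disambiguated with an ordinal suffix and a warning (never dropped).
    """
    wanted = set(feature_types)
    genes: list[GeneRecord] = []
    seen: dict[str, int] = {}
    declared_length = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    try:
                        declared_length = int(parts[3])
                    except ValueError as exc:
                        raise GFFParseError(
                            f"line {lineno}: bad sequence-region length"
                        ) from exc
                continue
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFFParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            ftype = fields[2]
            if ftype not in wanted:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GFFParseError(f"line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise GFFParseError(
                    f"line {lineno}: rejected record, end ({end1}) < start ({start1})"
                )
            strand = fields[6] if fields[6] in {"+", "-"} else "."
            gid = _attr_id(fields[8], fallback=f"feature_{lineno}")
            if gid in seen:
                seen[gid] += 1
                new_gid = f"{gid}_{seen[gid]}"
                warnings.warn(
                    f"duplicate gene_id {gid!r} at line {lineno}; renamed {new_gid!r}",
                    stacklevel=2,
                )
                gid = new_gid
            else:
                seen[gid] = 1
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    start=start1 - 1,  # 1-based inclusive -> 0-based half-open
                    end=end1,
                    strand=strand,
                    feature_kind=_feature_kind(ftype),
                )
            )
    length = genome_length if genome_length is not None else declared_length
    if length is None:
        if not genes:
            raise FormatError(f"{path}: no sequence-region directive and no genes")
        length = max(g.end for g in genes)
    return GenomeAnnotation(genome_length=length, genes=genes, circular=circular)


def write_gff3(annotation: GenomeAnnotation, path: str | Path, seqid: str = "chr") -> None:
    """Write an annotation back out as GFF3 (1-based inclusive coordinates)."""
    kind_to_type = {"CDS": "CDS", "pseudogene": "pseudogene", "other": "gene"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {annotation.genome_length}\n")
        for g in annotation.genes:
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "tradistat",
                        kind_to_type.get(g.feature_kind, "gene"),
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand if g.strand in {"+", "-"} else ".",
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Insertion plot files


def read_plot(path: str | Path, genome_length: int | None = None) -> InsertionProfile:
    """Read a two-column per-base insert-site plot file.

    Row count must equal ``genome_length`` when it is given.
    """
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, names=["fwd", "rev"], dtype=np.int64
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: malformed plot file ({exc})") from exc
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns")
    if genome_length is not None and len(df) != genome_length:
        raise FormatError(
            f"{path}: {len(df)} rows but genome_length is {genome_length}"
        )
    if (df["fwd"] < 0).any() or (df["rev"] < 0).any():
        raise FormatError(f"{path}: negative counts")
    return InsertionProfile(df["fwd"].to_numpy(), df["rev"].to_numpy())


def write_plot(profile: InsertionProfile, path: str | Path) -> None:
    """Write the bit-exact plot dialect: ASCII, one space, newline rows."""
    arr = np.column_stack([profile.fwd_counts, profile.rev_counts])
    pd.DataFrame(arr).to_csv(path, sep=" ", header=False, index=False, lineterminator="\n")


def read_site_list(path: str | Path, genome_length: int) -> InsertionProfile:
    """Read the alternative site-list dialect.

    Tab-separated with header ``position<TAB>orientation<TAB>read_count``;
    position is 1-based, orientation is ``fwd`` or ``rev``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"position", "orientation", "read_count"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: site list needs columns {sorted(required)}")
    bad = set(df["orientation"]) - {"fwd", "rev"}
    if bad:
        raise FormatError(f"{path}: unknown orientation values {sorted(bad)}")
    pos = df["position"].to_numpy(dtype=np.int64) - 1
    if (pos < 0).any() or (pos >= genome_length).any():
        raise FormatError(f"{path}: position outside [1, {genome_length}]")
    fwd = np.zeros(genome_length, dtype=np.int64)
    rev = np.zeros(genome_length, dtype=np.int64)
    is_fwd = (df["orientation"] == "fwd").to_numpy()
    counts = df["read_count"].to_numpy(dtype=np.int64)
    np.add.at(fwd, pos[is_fwd], counts[is_fwd])
    np.add.at(rev, pos[~is_fwd], counts[~is_fwd])
    return InsertionProfile(fwd, rev)


def write_site_list(profile: InsertionProfile, path: str | Path) -> None:
    rows = []
    for name, arr in (("fwd", profile.fwd_counts), ("rev", profile.rev_counts)):
        pos = np.flatnonzero(arr)
        for p in pos:
            rows.append((int(p) + 1, name, int(arr[p])))
    rows.sort()
    pd.DataFrame(rows, columns=["position", "orientation", "read_count"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Gene report / gene lists

REPORT_COLUMNS = [
    "gene_id",
    "start",
    "end",
    "strand",
    "length_bp",
    "unique_insertions",
    "insertion_index",
    "fwd_insertions",
    "rev_insertions",
    "max_ifr_bp",
    "ifr_p_gene",
    "loglik_score",
    "call",
]


def write_gene_report(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-gene report TSV with the fixed 13-column header.

    Rows are emitted in deterministic order (by start, then gene_id).
    """
    missing = [c for c in REPORT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"gene report missing columns: {missing}")
    out = table[REPORT_COLUMNS].sort_values(["start", "gene_id"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gene_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: gene report missing columns: {missing}")
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and ``#`` comments ignored."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def build_gene_table(
    annotation: GenomeAnnotation,
    stats: Sequence,
    calls: Sequence | None = None,
    gene_p: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble the per-gene report table from stats and (optionally) calls."""
    by_id = {g.gene_id: g for g in annotation.genes}
    call_by_id = {c.gene_id: c for c in calls} if calls is not None else {}
    rows = []
    for s in stats:
        g = by_id[s.gene_id]
        c = call_by_id.get(s.gene_id)
        rows.append(
            {
                "gene_id": s.gene_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "length_bp": s.length_bp,
                "unique_insertions": s.unique_insertions,
                "insertion_index": s.insertion_index,
                "fwd_insertions": s.fwd_insertions,
                "rev_insertions": s.rev_insertions,
                "max_ifr_bp": s.max_ifr_bp,
                "ifr_p_gene": (gene_p or {}).get(s.gene_id, np.nan),
                "loglik_score": c.loglik_score if c is not None else np.nan,
                "call": c.call if c is not None else "NA",
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return df.sort_values(["start", "gene_id"], kind="mergesort").reset_index(drop=True)
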