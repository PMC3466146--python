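"""Readers and writers for the on-disk formats the toolkit touches.

Formats: multi-FASTA nucleotide CDS files (via Biopython), tab-separated
genome profile tables (genome id, optional subphylum label, nine ratio
columns in canonical signal order), and BED-like tab-separated gene
coordinate tables on a circular chromosome.  All paths accept a ``.gz``
suffix transparently.  The package ships a 61-genome profile table of
alpha-, beta- and gamma-proteobacteria as `packaged_profile_table`.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterator, Literal

import pandas as pd
from Bio import SeqIO

from .core import SIGNALS, GeneSeq, TSSRVector

logger = logging.getLogger(__name__)

FRAMESHIFT_MARKER = "authentic frameshift"

_RATIO_COLUMNS = [s.replace("@", "_").lower() for s in SIGNALS]


@dataclass(frozen=True)
class GeneLocation:
    """1-based inclusive gene coordinates on a circular chromosome."""

    gene_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    chromosome_length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.chromosome_length < 1:
            raise ValueError("chromosome length must be positive")
        for coord in (self.start, self.end):
            if not 1 <= coord <= self.chromosome_length:
                raise ValueError(
                    f"coordinate {coord} outside 1..{self.chromosome_length}"
                )

    def midpoint(self) -> float:
        """Circular midpoint; genes spanning the origin wrap around."""
        L = self.chromosome_length
        if self.start <= self.end:
            return (self.start + self.end) / 2
        mid = (self.start + self.end + L) / 2
        return mid - L if mid > L else mid


@dataclass(frozen=True)
class ProfileTable:
    """An ordered set of labelled genome TSSR vectors."""

    genome_ids: tuple[str, ...]
    subphyla: tuple[str | None, ...]
    vectors: tuple[TSSRVector, ...]

    def __post_init__(self) -> None:
        if len({*self.genome_ids}) != len(self.genome_ids):
            raise ValueError("genome ids must be unique")
        if not len(self.genome_ids) == len(self.subphyla) == len(self.vectors):
            raise ValueError("column lengths differ")

    def __len__(self) -> int:
        return len(self.genome_ids)

    def vector(self, genome_id: str) -> TSSRVector:
        return self.vectors[self.genome_ids.index(genome_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [v.ratios for v in self.vectors], columns=_RATIO_COLUMNS
        )
        df.insert(0, "subphylum", self.subphyla)
        df.insert(0, "genome_id", self.genome_ids)
        return df


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def read_cds_fasta(
    path: str | Path, exclude_frameshift: bool = False
) -> list[GeneSeq]:
    """Read CDS records from a (possibly gzipped) multi-FASTA file.

    The gene id is the first whitespace-separated header token.  With
    ``exclude_frameshift`` set, records whose header contains the
    case-insensitive substring "authentic frameshift" — genes annotated as
    translated over multiple reading frames — are dropped.  Duplicate ids
    get a numeric suffix rather than raising.
    """
    genes: list[GeneSeq] = []
    seen: dict[str, int] = {}
    dropped = 0
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            header = record.description
            if exclude_frameshift and FRAMESHIFT_MARKER in header.lower():
                dropped += 1
                continue
            gene_id = record.id
            if gene_id in seen:
                seen[gene_id] += 1
                new_id = f"{gene_id}_{seen[gene_id]}"
                logger.warning("duplicate id %s renamed to %s", gene_id, new_id)
                gene_id = new_id
            else:
                seen[gene_id] = 0
            genes.append(GeneSeq(gene_id=gene_id, sequence=str(record.seq)))
    if dropped:
        logger.info("dropped %d authentic-frameshift record(s)", dropped)
    return genes


def write_cds_fasta(genes: list[GeneSeq], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n{g.sequence}\n")


# ---------------------------------------------------------------------------
# profile tables

#: Row sums in published tables are 3-dp rounded and may miss 1 by a few
#: thousandths; anything farther off is treated as a malformed row.
ROW_SUM_TOLERANCE = 0.01


def read_profile_table(path: str | Path) -> ProfileTable:
    """Read a TSV of genome TSSR profiles.

    Expected columns: ``genome_id``, optional ``subphylum``, then the nine
    ratio columns in canonical signal order.  Rows are renormalised to sum
    exactly 1 (rounded published values may sum to 0.996-1.004); a row sum
    farther than 0.01 from 1 is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = list(df.columns)
    if len(cols) == 10:
        has_subphylum = False
    elif len(cols) == 11:
        has_subphylum = True
    else:
        raise ValueError(f"expected 10 or 11 columns, got {len(cols)}")
    ratio_part = df[cols[2 if has_subphylum else 1 :]]
    try:
        ratios = ratio_part.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric ratio cell in {path}: {exc}") from exc
    if ratios.isna().any().any():
        raise ValueError(f"missing ratio cell(s) in {path}")
    ids = tuple(str(x) for x in df[cols[0]])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_id in profile table")
    subphyla: tuple[str | None, ...]
    if has_subphylum:
        subphyla = tuple(
            None if pd.isna(x) else str(x) for x in df[cols[1]]
        )
    else:
        subphyla = tuple(None for _ in ids)
    vectors = []
    for gid, row in zip(ids, ratios.itertuples(index=False)):
        vals = [float(v) for v in row]
        s = sum(vals)
        if abs(s - 1.0) > ROW_SUM_TOLERANCE:
            raise ValueError(f"row {gid!r} sums to {s:.4f}, outside tolerance")
        vectors.append(TSSRVector(tuple(v / s for v in vals)))
    return ProfileTable(ids, subphyla, tuple(vectors))


def write_profile_table(table: ProfileTable, path: str | Path) -> None:
    """Write a profile table as TSV (deterministic, 17 significant digits)."""
    with _open_text(path, "wt") as fh:
        header = ["genome_id", "subphylum", *_RATIO_COLUMNS]
        fh.write("\t".join(header) + "\n")
        for gid, sub, vec in zip(table.genome_ids, table.subphyla, table.vectors):
            cells = [gid, "" if sub is None else sub]
            cells += [repr(v) for v in vec.ratios]
            fh.write("\t".join(cells) + "\n")


def packaged_profile_table() -> ProfileTable:
    """The bundled 61-genome proteobacterial Genomic-TSSR table."""
    ref = resources.files("tssr.data") / "table2_genomic_tssr.tsv"
    with resources.as_file(ref) as path:
        return read_profile_table(path)


# ---------------------------------------------------------------------------
# gene locations


def read_gene_locations(path: str | Path) -> list[GeneLocation]:
    """Read a BED-like TSV of gene coordinates.

    The first line must be ``#chromosome_length<TAB>L``; data rows are
    ``gene_id<TAB>start<TAB>end<TAB>strand`` with 1-based inclusive
    coordinates on a circular chromosome of length ``L``.
    """
    with _open_text(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#chromosome_length"):
            raise ValueError(
                "first line must be '#chromosome_length<TAB>L'"
            )
        length = int(first.split("\t")[1])
        out = []
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"expected 4 fields, got {len(fields)}: {line!r}")
            gene_id, start, end, strand = fields
            out.append(
                GeneLocation(gene_id, int(start), int(end), strand, length)
            )
    return out


def write_gene_locations(locations: list[GeneLocation], path: str | Path) -> None:
    if not locations:
        raise ValueError("no locations to write")
    length = locations[0].chromosome_length
    with _open_text(path, "wt") as fh:
        fh.write(f"#chromosome_length\t{length}\n")
        for loc in locations:
            fh.write(f"{loc.gene_id}\t{loc.start}\t{loc.end}\t{loc.strand}\n")
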