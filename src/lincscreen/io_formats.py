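"""Readers, writers and shared domain types.

All genomic coordinates are 0-based half-open (BED convention) everywhere in
the package; any 1-based dialect must be converted at the boundary of the
reader, never downstream.

Formats handled: FASTA (via Biopython), BED3/BED6, GMT (MSigDB dialect),
chrom.sizes (two-column TSV), expression TSV (gene_id + one column per
sample, optional ``biotype`` column), a Cuffdiff2-like differential table
TSV, per-base coverage TSV and simple count/measurement tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_STRANDS = ("+", "-", ".")

#: mapping chromosome name -> length in bases
ChromSizes = Dict[str, int]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-agnostic >=1 bp overlap on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def tss_of(interval: GenomicInterval) -> int:
    """Transcription start site: ``start`` on '+' (or unstranded), ``end`` on '-'."""
    return interval.end if interval.strand == "-" else interval.start


@dataclass(frozen=True)
class TranscriptRecord:
    """A pre-spliced transcript sequence over {A,C,G,T,N}."""

    id: str
    sequence: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"transcript {self.id!r} contains invalid characters {sorted(bad)}"
            )


@dataclass
class DiffRecord:
    """One gene's record from a Cuffdiff2-like differential-expression table."""

    gene_id: str
    locus: GenomicInterval
    test_statistic: float
    log2fc: float
    p: float
    q: float
    status: str = "OK"

    def __post_init__(self) -> None:
        for name, v in (("p", self.p), ("q", self.q)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1] for gene {self.gene_id}")
        if self.status not in ("OK", "NOTEST"):
            raise ValueError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: Tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.name!r} has zero members")
        if len(set(self.members)) != len(self.members):
            # deduplicate preserving order
            seen: dict = {}
            for m in self.members:
                seen.setdefault(m, None)
            object.__setattr__(self, "members", tuple(seen))


@dataclass
class GeneSetCollection:
    """Named gene sets, preserving file order but addressable by name."""

    sets: Dict[str, GeneSet] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise ValueError(f"duplicate gene set name {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set

    @property
    def names(self) -> List[str]:
        return list(self.sets)


@dataclass
class ExpressionMatrix:
    """FPKM values over genes (rows) x samples (columns).

    ``biotype`` optionally labels each gene as coding / lincRNA / other.
    """

    values: pd.DataFrame
    biotype: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample labels in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative FPKM values in expression matrix")
        if self.biotype is not None:
            self.biotype = self.biotype.reindex(self.values.index)

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)


def log10p1(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Map every FPKM value v to log10(v + 1); monotone, fixes zero."""
    return ExpressionMatrix(values=np.log10(matrix.values + 1.0), biotype=matrix.biotype)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> List[TranscriptRecord]:
    """Read transcripts from FASTA; uppercases and maps U -> T.

    The second whitespace-separated header token, when present, is taken as
    the parent gene id.
    """
    records: List[TranscriptRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate transcript id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence for transcript {rec.id!r} in {path}")
        parts = rec.description.split()
        gene_id = parts[1] if len(parts) > 1 else None
        records.append(TranscriptRecord(id=rec.id, sequence=seq, gene_id=gene_id))
    return records


def write_fasta(records: Sequence[TranscriptRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.gene_id is None else f"{rec.id} {rec.gene_id}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> List[Tuple[GenomicInterval, str]]:
    """Read BED3+ records as (interval, name) pairs, coordinates untouched."""
    out: List[Tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start_s, end_s = cols[0], cols[1], cols[2]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: empty or inverted interval {start}-{end}"
                )
            name = cols[3] if len(cols) > 3 else ""
            strand = cols[5] if len(cols) > 5 else "."
            out.append((GenomicInterval(chrom, start, end, strand), name))
    return out


def write_bed(records: Iterable[Tuple[GenomicInterval, str]], path) -> None:
    """Write BED6 (score column 0); read_bed(write_bed(x)) preserves coordinates."""
    with open(path, "w") as fh:
        for iv, name in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3 or not any(c for c in cols[2:]):
                raise ValueError(f"{path}:{lineno}: gene set with zero members")
            members = tuple(c for c in cols[2:] if c)
            collection.add(GeneSet(name=cols[0], members=members, description=cols[1]))
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# chrom.sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> ChromSizes:
    sizes: ChromSizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            name, length = cols[0], int(cols[1])
            if name in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length for {name!r}")
            sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# differential-expression tables (Cuffdiff2-like TSV dialect)
# ---------------------------------------------------------------------------

_DIFF_REQUIRED = ("gene_id", "locus", "test_stat", "p_value", "q_value")


def _parse_locus(text: str, row: int) -> GenomicInterval:
    try:
        chrom, span = text.split(":")
        start_s, end_s = span.split("-")
        return GenomicInterval(chrom, int(start_s), int(end_s))
    except Exception as exc:  # noqa: BLE001 - re-raise with row context
        raise ValueError(f"unparseable locus {text!r} at row {row}") from exc


def read_diff_table(path) -> List[DiffRecord]:
    """Read the differential table dialect.

    Required columns: gene_id, locus ("chrom:start-end"), test_stat, p_value,
    q_value. Optional: log2fc (default 0, "inf"/"-inf" accepted) and status
    (default OK). Extra columns are ignored; NOTEST rows are retained but
    flagged so significance counts can exclude them.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "locus": str})
    missing = [c for c in _DIFF_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records: List[DiffRecord] = []
    has_fc = "log2fc" in df.columns
    has_status = "status" in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        locus = _parse_locus(getattr(row, "locus"), i)
        log2fc = float(getattr(row, "log2fc")) if has_fc else 0.0
        status = str(getattr(row, "status")) if has_status else "OK"
        records.append(
            DiffRecord(
                gene_id=str(getattr(row, "gene_id")),
                locus=locus,
                test_statistic=float(getattr(row, "test_stat")),
                log2fc=log2fc,
                p=float(getattr(row, "p_value")),
                q=float(getattr(row, "q_value")),
                status=status,
            )
        )
    return records


def write_diff_table(records: Sequence[DiffRecord], path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "locus": f"{r.locus.chrom}:{r.locus.start}-{r.locus.end}",
            "test_stat": r.test_statistic,
            "log2fc": r.log2fc,
            "p_value": r.p,
            "q_value": r.q,
            "status": r.status,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path) -> ExpressionMatrix:
    """Read an FPKM TSV: gene_id column + one column per sample.

    A ``biotype`` column, when present, becomes the per-gene biotype label.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    df = df.set_index("gene_id")
    biotype = None
    if "biotype" in df.columns:
        biotype = df.pop("biotype").astype(str)
    values = df.astype(float)
    if (values.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative FPKM values")
    return ExpressionMatrix(values=values, biotype=biotype)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    if matrix.biotype is not None:
        df.insert(0, "biotype", matrix.biotype)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# per-base coverage tracks (ribosome footprints / total RNA)
# ---------------------------------------------------------------------------

def read_coverage(path) -> Dict[str, np.ndarray]:
    """Read per-base counts keyed by transcript.

    Dialect: header ``transcript_id  position  count`` with 0-based positions
    covering 0..L-1 contiguously for each transcript.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    for col in ("transcript_id", "position", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    tracks: Dict[str, np.ndarray] = {}
    for tid, grp in df.groupby("transcript_id", sort=False):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        if not np.array_equal(pos, np.arange(len(pos))):
            raise ValueError(f"{path}: non-contiguous positions for {tid!r}")
        counts = grp["count"].to_numpy()
        if (counts < 0).any():
            raise ValueError(f"{path}: negative counts for {tid!r}")
        tracks[str(tid)] = counts.astype(np.int64)
    return tracks


def write_coverage(tracks: Dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tposition\tcount\n")
        for tid, counts in tracks.items():
            for i, c in enumerate(np.asarray(counts)):
                fh.write(f"{tid}\t{i}\t{int(c)}\n")


# ---------------------------------------------------------------------------
# small phenotype tables
# ---------------------------------------------------------------------------

def read_cross_counts(path) -> Dict[str, int]:
    """Genotype-class count TSV: columns ``genotype`` and ``count``."""
    df = pd.read_csv(path, sep="\t", dtype={"genotype": str})
    for col in ("genotype", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    counts = {str(g): int(c) for g, c in zip(df["genotype"], df["count"])}
    if any(c < 0 for c in counts.values()):
        raise ValueError(f"{path}: negative genotype count")
    return counts


def read_measurements(path) -> pd.DataFrame:
    """Morphometry TSV: columns ``group`` and ``value``."""
    df = pd.read_csv(path, sep="\t", dtype={"group": str})
    for col in ("group", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df["value"] = df["value"].astype(float)
    if df["value"].isna().any():
        raise ValueError(f"{path}: non-numeric measurement values")
    return df[["group", "value"]]
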