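"""Genomic interval types and BED / minimal-GTF / bedGraph input-output.

Coordinate convention, used everywhere in :mod:`bruwave`: **0-based,
half-open** intervals on the forward genomic axis (BED native).  Strand
enters only through TSS/TES derivation and the distance-from-TSS
transforms applied downstream; stored coordinates are never reflected.

Gene length is the genomic span (``end - start``), introns included —
nascent-RNA reads cover gene bodies uniformly rather than exon-only, so
the intron-inclusive span is the correct normalizer for synthesis-rate
densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("bruwave")

#: sanity bound on a single sequencing-read span (bp)
MAX_READ_LENGTH = 1000

READ_COLUMNS = ("chrom", "start", "end", "strand")


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware genomic gene interval with derived TSS/TES.

    ``start``/``end`` are 0-based half-open genomic coordinates; the
    transcription start site (TSS) is ``start`` on '+' and ``end`` on '-',
    the transcription end site (TES) the opposite boundary.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.start < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: end <= start ({self.end} <= {self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class ReadRecord:
    """One strand-specific aligned nascent-RNA read interval.

    Bulk read sets are carried as :class:`pandas.DataFrame` with columns
    ``chrom, start, end, strand`` (see :func:`read_reads_bed`); this
    dataclass states the per-record contract.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unstranded read at {self.chrom}:{self.start}")
        if self.end <= self.start:
            raise ValueError(f"read end <= start at {self.chrom}:{self.start}")
        if self.end - self.start > MAX_READ_LENGTH:
            raise ValueError(
                f"read longer than {MAX_READ_LENGTH} bp at {self.chrom}:{self.start}"
            )


@dataclass(frozen=True)
class EnhancerInterval:
    """An unstranded enhancer interval; eRNA is treated as bidirectional."""

    id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"enhancer {self.id!r}: end <= start")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# BED input
# ---------------------------------------------------------------------------

def _split_bed_line(line: str, lineno: int, min_fields: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_fields:
        raise ValueError(
            f"malformed BED row at line {lineno}: expected >= {min_fields} "
            f"tab-separated fields, got {len(fields)}"
        )
    return fields


def read_gene_bed(path) -> list[GeneModel]:
    """Read a BED6 gene annotation into validated :class:`GeneModel` rows.

    Rows are returned sorted by ``(chrom, start)``.  Malformed rows,
    duplicate gene ids and strands outside {+,-} raise ``ValueError``
    naming the offending line.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split_bed_line(line, lineno, 6)
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"non-integer coordinate at line {lineno}") from exc
            gene_id, strand = f[3], f[5]
            if strand not in ("+", "-"):
                raise ValueError(f"strand not in {{+,-}} at line {lineno}: {strand!r}")
            if end <= start:
                raise ValueError(f"end <= start at line {lineno}")
            if gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene_id!r} at line {lineno}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id, f[0], start, end, strand))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def read_gene_gtf(path) -> list[GeneModel]:
    """Minimal GTF reader: only ``gene``-type rows, only the gene_id attribute.

    GTF is 1-based inclusive; coordinates are converted to 0-based
    half-open on read.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GTF row at line {lineno}")
            if f[2] != "gene":
                continue
            attrs = f[8]
            gene_id = None
            for token in attrs.split(";"):
                token = token.strip()
                if token.startswith("gene_id"):
                    gene_id = token.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise ValueError(f"gene row without gene_id at line {lineno}")
            if gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene_id!r} at line {lineno}")
            seen.add(gene_id)
            start, end, strand = int(f[3]) - 1, int(f[4]), f[6]
            if strand not in ("+", "-"):
                raise ValueError(f"strand not in {{+,-}} at line {lineno}: {strand!r}")
            if end <= start:
                raise ValueError(f"end <= start at line {lineno}")
            genes.append(GeneModel(gene_id, f[0], start, end, strand))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gene_bed(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_reads_bed(path) -> pd.DataFrame:
    """Read a BED6 file of aligned reads into a ``(chrom,start,end,strand)`` frame.

    The score column is ignored; the row count is logged as the library-size
    candidate.  Unstranded rows ('.'), inverted intervals and reads longer
    than ``MAX_READ_LENGTH`` raise ``ValueError`` naming the line.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2, 5],
            names=["chrom", "start", "end", "strand"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        logger.warning("read BED %s is empty", path)
        return pd.DataFrame(
            {"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64),
             "end": pd.Series(dtype=np.int64), "strand": pd.Series(dtype=str)}
        )

    if df.empty:
        logger.warning("read BED %s is empty", path)
        return df
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"unstranded read at line {int(np.flatnonzero(bad)[0]) + 1}")
    bad = df["end"].to_numpy() <= df["start"].to_numpy()
    if bad.any():
        raise ValueError(f"end <= start at line {int(np.flatnonzero(bad)[0]) + 1}")
    bad = (df["end"] - df["start"]).to_numpy() > MAX_READ_LENGTH
    if bad.any():
        raise ValueError(
            f"read longer than {MAX_READ_LENGTH} bp at line "
            f"{int(np.flatnonzero(bad)[0]) + 1}"
        )
    logger.info("read BED %s: %d reads (library size candidate)", path, len(df))
    return df


def write_reads_bed(reads: pd.DataFrame, path) -> None:
    out = reads.copy()
    out.insert(3, "name", ".")
    out.insert(4, "score", 0)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_enhancer_bed(path) -> list[EnhancerInterval]:
    """Read enhancer intervals from BED3+ (name used as id when present)."""
    out: list[EnhancerInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split_bed_line(line, lineno, 3)
            start, end = int(f[1]), int(f[2])
            if end <= start:
                raise ValueError(f"end <= start at line {lineno}")
            name = f[3] if len(f) > 3 and f[3] not in (".", "") else f"enh_{lineno}"
            out.append(EnhancerInterval(name, f[0], start, end))
    return out


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(
    track: Iterable[tuple[str, int, int, float]],
    path,
    strand: str | None = None,
    suppress_zero: bool = True,
) -> None:
    """Write binned coverage as bedGraph (chrom, start, end, value).

    Bins must be non-overlapping and contiguous per chromosome with a
    fixed width; values must be non-negative.  Zero-valued bins are
    omitted when ``suppress_zero`` is set.  Values are printed with 6
    significant digits so a write→read round trip reproduces them at
    that precision.
    """
    rows = list(track)
    last_end: dict[str, int] = {}
    width: int | None = None
    for chrom, start, end, value in rows:
        if value < 0:
            raise ValueError(f"negative bin value at {chrom}:{start}")
        if end <= start:
            raise ValueError(f"empty bin at {chrom}:{start}")
        if width is None:
            width = end - start
        if chrom in last_end:
            if start < last_end[chrom]:
                raise ValueError(f"overlapping bins at {chrom}:{start}")
        last_end[chrom] = end
    with open(path, "w") as fh:
        if strand is not None:
            fh.write(f'track type=bedGraph name="coverage({strand})"\n')
        for chrom, start, end, value in rows:
            if suppress_zero and value == 0:
                continue
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    out: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    return out


def reads_to_records(reads: pd.DataFrame) -> list[ReadRecord]:
    """Materialize a reads frame as validated :class:`ReadRecord` objects."""
    return [
        ReadRecord(str(c), int(s), int(e), str(st))
        for c, s, e, st in zip(
            reads["chrom"], reads["start"], reads["end"], reads["strand"]
        )
    ]
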