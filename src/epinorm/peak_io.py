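"""Domain types and file I/O for peaks, gene models, signatures and expression.

All genomic coordinates are 0-based, half-open (BED convention).  Peaks are
read from BED3+ files, gene models from a refFlat-like 7-column table, gene
signatures from GMT, and expression matrices from TSV with a sample header.
Gene symbols are upper-cased everywhere set arithmetic is performed, because
signature files and annotations routinely mix cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised on malformed input files; message names the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    """A called ChIP enrichment interval on one chromosome.

    ``read_count`` is the number of ChIP reads attributed to the interval in
    one sample; it may be ``None`` when counts are recomputed later from raw
    read placements.  ``summit`` is the estimated binding position.
    """

    chrom: str
    start: int
    end: int
    summit: int | None = None
    read_count: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside {self.chrom}:{self.start}-{self.end}"
            )
        if self.read_count is not None and self.read_count < 0:
            raise ValueError("read_count must be non-negative")

    @property
    def anchor(self) -> int:
        """Summit when present, else interval midpoint."""
        if self.summit is not None:
            return self.summit
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class PeakSet:
    """An ordered, de-duplicated collection of peaks from one sample."""

    sample_label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int, int], Peak] = {}
        for p in self.peaks:
            seen.setdefault(p.key, p)
        self.peaks = sorted(seen.values(), key=lambda p: p.key)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out


@dataclass(frozen=True)
class GeneModel:
    """A gene with transcript bounds and exon blocks.

    TSS is ``tx_start`` on the + strand and ``tx_end - 1`` on the − strand.
    """

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand must be + or -")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"gene {self.name}: tx_start >= tx_end")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(f"gene {self.name}: exon start/end lists differ in length")
        prev_end = self.tx_start
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s < prev_end or e > self.tx_end or s >= e:
                raise ValueError(f"gene {self.name}: malformed exon blocks")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start


@dataclass
class GeneAnnotation:
    """Collection of gene models; the genome-wide symbol universe.

    Duplicate symbols are collapsed to the longest transcript so every symbol
    has a single deterministic TSS for nearest-gene queries.
    """

    genes: list[GeneModel]
    universe_size: int = 0

    def __post_init__(self) -> None:
        best: dict[str, GeneModel] = {}
        n_dup = 0
        for g in self.genes:
            key = g.name.upper()
            prev = best.get(key)
            if prev is None:
                best[key] = g
            else:
                n_dup += 1
                if g.length > prev.length:
                    best[key] = g
        if n_dup:
            logger.info(
                "annotation: collapsed %d duplicate symbols to longest transcript",
                n_dup,
            )
        self.genes = sorted(best.values(), key=lambda g: (g.chrom, g.tx_start, g.name))
        self.universe_size = len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def symbols(self) -> set[str]:
        return {g.name.upper() for g in self.genes}

    def by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out


@dataclass
class GeneSet:
    """A named signature: a non-empty set of upper-cased gene symbols."""

    name: str
    genes: set[str]

    def __post_init__(self) -> None:
        self.genes = {g.upper() for g in self.genes}
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values: genes x samples with condition labels."""

    values: pd.DataFrame  # rows = gene symbols (upper case), cols = samples
    group: Mapping[str, str]  # sample -> condition label ("wt" / "ko")

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = self.values.index.str.upper()
        missing = [s for s in self.values.columns if s not in self.group]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def condition(self, label: str) -> pd.DataFrame:
        cols = [s for s in self.values.columns if self.group[s] == label]
        return self.values[cols]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_peaks(path: str | Path, sample_label: str) -> PeakSet:
    """Read a BED3+ peak file into a sorted, de-duplicated :class:`PeakSet`.

    Column 4 is the peak name, column 5 the read count (score), column 7 a
    summit offset relative to ``start``.  Missing counts stay ``None``.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
            name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
            count = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    count = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            summit = None
            if len(fields) > 6 and fields[6] not in (".", ""):
                try:
                    summit = start + int(fields[6])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer summit offset") from exc
            try:
                peaks.append(
                    Peak(fields[0], start, end, summit=summit, read_count=count, name=name)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not peaks:
        raise ParseError(f"{path}: no peaks found")
    return PeakSet(sample_label, peaks)


def write_peaks(peakset: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED; score column carries the read count."""
    with open(path, "w") as fh:
        for p in peakset:
            score = "." if p.read_count is None else f"{p.read_count:g}"
            name = p.name or "."
            row = [p.chrom, str(p.start), str(p.end), name, score]
            if p.summit is not None:
                row += [".", str(p.summit - p.start)]
            fh.write("\t".join(row) + "\n")


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read a refFlat-like table: name, chrom, strand, txStart, txEnd,
    exonStarts, exonEnds (comma-separated lists)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(f"{path}:{lineno}: expected 7 columns")
            name, chrom, strand = fields[0], fields[1], fields[2]
            try:
                tx_start, tx_end = int(fields[3]), int(fields[4])
                ex_s = tuple(int(x) for x in fields[5].rstrip(",").split(",") if x)
                ex_e = tuple(int(x) for x in fields[6].rstrip(",").split(",") if x)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            try:
                genes.append(GeneModel(name, chrom, strand, tx_start, tx_end, ex_s, ex_e))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not genes:
        raise ParseError(f"{path}: no genes found")
    return GeneAnnotation(genes)


def write_gene_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in annotation:
            fh.write(
                "\t".join(
                    [
                        g.name,
                        g.chrom,
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        ",".join(map(str, g.exon_starts)) + ",",
                        ",".join(map(str, g.exon_ends)) + ",",
                    ]
                )
                + "\n"
            )


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene signatures from GMT: name, description, then symbols."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=3 fields")
            sets.append(GeneSet(fields[0], {g for g in fields[2:] if g}))
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


def read_expression(
    path: str | Path, group_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Read a log2 expression TSV (first column gene symbol, header samples).

    Rows containing non-numeric or missing values are dropped and counted in
    the log.  Every sample in the header must appear in ``group_map``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    missing = [s for s in df.columns if s not in group_map]
    if missing:
        raise ValueError(f"{path}: samples missing from group map: {missing}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        logger.info("%s: dropped %d rows with missing/non-numeric values", path, int(bad.sum()))
    numeric = numeric[~bad]
    return ExpressionMatrix(numeric, {s: group_map[s] for s in numeric.columns})


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def write_table(df: pd.DataFrame, path: str | Path, params: Mapping[str, object] | None = None) -> None:
    """Write a result table as TSV with '#' comment lines recording parameters."""
    with open(path, "w") as fh:
        for k, v in (params or {}).items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False)
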