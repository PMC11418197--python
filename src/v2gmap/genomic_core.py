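"""Genome-feature types, file I/O, and interval algebra.

All coordinates are 0-based, half-open internally. BED is native; GTF and
summary-statistic positions (1-based) are converted on read and back on
write. A variant is represented as the 1-bp interval ``[pos, pos + 1)``.
"""

from __future__ import annotations

import gzip
import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

#: Activation stages used throughout the pipeline, in temporal order.
TIMEPOINTS = ("unstim", "8h", "24h")

#: Promoter window extent relative to the TSS, in the direction of
#: transcription: 1500 bp upstream, 500 bp downstream.
PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Malformed input file content, reported with line number."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start, end : int
        0-based half-open bounds with ``0 <= start < end``.
    strand : str
        One of ``'+'``, ``'-'``, ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap: at least one shared base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


def point_interval(chrom: str, pos: int) -> GenomicInterval:
    """The 1-bp interval ``[pos, pos + 1)`` representing a variant."""
    return GenomicInterval(chrom, pos, pos + 1)


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcription start sites.

    ``tss_list`` is stored 0-based; annotation inputs (GTF, gene tables)
    are 1-based and converted on read. Multi-TSS support is first-class:
    distances and promoter windows are computed over every TSS.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss_list: tuple[int, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be '+' or '-', got {self.strand!r}")
        if not self.tss_list:
            raise ValueError(f"gene {self.gene_id}: tss_list must be non-empty")
        object.__setattr__(self, "tss_list", tuple(sorted(set(self.tss_list))))


@dataclass(frozen=True)
class PromoterWindow:
    """Promoter interval around one TSS of a gene (-1500/+500 bp)."""

    gene_id: str
    tss: int
    interval: GenomicInterval


@dataclass(frozen=True)
class OCR:
    """Reproducible open-chromatin region with per-timepoint accessibility.

    ``timepoints`` is the set of stages at which the peak is accessible;
    at least one flag must be set. ``n_replicates`` is the number of
    supporting replicates (consensus peaks require >= 2).
    """

    peak_id: str
    interval: GenomicInterval
    timepoints: frozenset[str]
    n_replicates: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints", frozenset(self.timepoints))
        if not self.timepoints:
            raise ValueError(f"OCR {self.peak_id}: at least one timepoint flag required")
        unknown = self.timepoints - set(TIMEPOINTS)
        if unknown:
            raise ValueError(f"OCR {self.peak_id}: unknown timepoints {sorted(unknown)}")
        if self.n_replicates < 1:
            raise ValueError(f"OCR {self.peak_id}: n_replicates must be >= 1")


@dataclass(frozen=True)
class SummaryStatRecord:
    """One GWAS summary-statistic row (position stored 0-based)."""

    variant_id: str
    chrom: str
    pos: int
    p_value: float
    sentinel_id: str
    trait: str
    beta: float | None = None
    se: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(
                f"{self.variant_id}: p-value must be in (0, 1], got {self.p_value}"
            )
        if not self.sentinel_id:
            raise ValueError(f"{self.variant_id}: sentinel_id must be non-empty")
        if self.pos < 0:
            raise ValueError(f"{self.variant_id}: negative position")


@dataclass
class BedRecord:
    """One BED line; ``name``/``score`` kept verbatim for round-tripping."""

    interval: GenomicInterval
    name: str | None = None
    score: str | None = None


# ---------------------------------------------------------------------------
# File I/O (gzip-transparent, tab-delimited, UTF-8)
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def normalize_chrom(chrom: str, chr_prefix: bool | None = None) -> str:
    """Normalize the ``chr`` prefix; ``None`` leaves the name untouched."""
    if chr_prefix is None:
        return chrom
    bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return f"chr{bare}" if chr_prefix else bare


def read_bed(path: str | Path, chr_prefix: bool | None = None) -> list[BedRecord]:
    """Read BED3/BED6 records, preserving coordinates verbatim.

    Raises :class:`ParseError` (with line number) for non-integer bounds
    or ``start >= end``.
    """
    records: list[BedRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = normalize_chrom(fields[0], chr_prefix)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                interval = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            name = fields[3] if len(fields) >= 4 else None
            score = fields[4] if len(fields) >= 5 else None
            records.append(BedRecord(interval, name, score))
    return records


def write_bed(records: Iterable[BedRecord | GenomicInterval], path: str | Path) -> None:
    """Write BED3 (bare intervals) or BED6 (named records)."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            if isinstance(rec, GenomicInterval):
                rec = BedRecord(rec)
            iv = rec.interval
            if rec.name is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = rec.score if rec.score is not None else "0"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.name}\t{score}\t{iv.strand}\n"
                )


def read_ocr_bed(path: str | Path, chr_prefix: bool | None = None) -> list[OCR]:
    """Read OCRs from BED6+2 (col 7 = comma-joined timepoints, col 8 = replicates)."""
    ocrs: list[OCR] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = normalize_chrom(fields[0], chr_prefix)
            try:
                interval = GenomicInterval(chrom, int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            peak_id = fields[3] if len(fields) >= 4 else f"peak{lineno}"
            timepoints = (
                frozenset(fields[6].split(",")) if len(fields) >= 7 else frozenset(TIMEPOINTS)
            )
            n_rep = int(fields[7]) if len(fields) >= 8 else 2
            ocrs.append(OCR(peak_id, interval, timepoints, n_rep))
    return ocrs


def write_ocr_bed(ocrs: Iterable[OCR], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for ocr in ocrs:
            iv = ocr.interval
            tps = ",".join(t for t in TIMEPOINTS if t in ocr.timepoints)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ocr.peak_id}\t0\t.\t{tps}\t{ocr.n_replicates}\n"
            )


_GENE_TABLE_COLUMNS = ["gene_id", "symbol", "chrom", "strand", "tss_csv", "biotype"]


def read_gene_table(path: str | Path, chr_prefix: bool | None = None) -> list[GeneModel]:
    """Read gene models from a headered TSV or a GTF.

    The TSV dialect has columns ``gene_id symbol chrom strand tss_csv
    biotype`` with 1-based TSS positions. GTF transcript records are
    converted to TSS by strand (start for ``+``, end for ``-``); both
    inputs are 1-based and stored 0-based.
    """
    path = Path(path)
    if path.name.endswith((".gtf", ".gtf.gz")):
        return _read_gtf(path, chr_prefix)
    genes: list[GeneModel] = []
    seen: dict[str, GeneModel] = {}
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        missing = [c for c in _GENE_TABLE_COLUMNS if c not in idx]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                tss = tuple(int(x) - 1 for x in fields[idx["tss_csv"]].split(","))
                gene = GeneModel(
                    gene_id=fields[idx["gene_id"]],
                    symbol=fields[idx["symbol"]],
                    chrom=normalize_chrom(fields[idx["chrom"]], chr_prefix),
                    strand=fields[idx["strand"]],
                    tss_list=tss,
                    biotype=fields[idx["biotype"]],
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if gene.gene_id in seen:
                if seen[gene.gene_id].chrom != gene.chrom:
                    raise ParseError(
                        f"{path}:{lineno}: duplicate gene_id {gene.gene_id} with "
                        "conflicting chrom"
                    )
                continue
            seen[gene.gene_id] = gene
            genes.append(gene)
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write the TSV gene-table dialect (TSS emitted 1-based)."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(_GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            tss_csv = ",".join(str(t + 1) for t in g.tss_list)
            fh.write(
                f"{g.gene_id}\t{g.symbol}\t{g.chrom}\t{g.strand}\t{tss_csv}\t{g.biotype}\n"
            )


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _read_gtf(path: Path, chr_prefix: bool | None) -> list[GeneModel]:
    per_gene: dict[str, dict] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "transcript":
                continue
            chrom = normalize_chrom(fields[0], chr_prefix)
            start, end = int(fields[3]), int(fields[4])
            strand = fields[6]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _parse_gtf_attributes(fields[8])
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: transcript without gene_id")
            # GTF is 1-based inclusive; the TSS is the transcript start on
            # '+' and the transcript end on '-', stored 0-based.
            tss = start - 1 if strand == "+" else end - 1
            entry = per_gene.setdefault(
                gene_id,
                {
                    "symbol": attrs.get("gene_name", gene_id),
                    "chrom": chrom,
                    "strand": strand,
                    "tss": set(),
                    "biotype": attrs.get("gene_biotype", attrs.get("gene_type", "protein_coding")),
                },
            )
            if entry["chrom"] != chrom:
                raise ParseError(
                    f"{path}:{lineno}: gene {gene_id} spans multiple chromosomes"
                )
            entry["tss"].add(tss)
    return [
        GeneModel(gid, e["symbol"], e["chrom"], e["strand"], tuple(e["tss"]), e["biotype"])
        for gid, e in per_gene.items()
    ]


_SUMSTAT_COLUMNS = ["variant_id", "chrom", "pos", "p", "sentinel_id", "trait"]


def read_summary_stats(
    path: str | Path, chr_prefix: bool | None = None
) -> list[SummaryStatRecord]:
    """Read summary statistics TSV (1-based positions, stored 0-based)."""
    records: list[SummaryStatRecord] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        missing = [c for c in _SUMSTAT_COLUMNS if c not in idx]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            try:
                records.append(
                    SummaryStatRecord(
                        variant_id=f[idx["variant_id"]],
                        chrom=normalize_chrom(f[idx["chrom"]], chr_prefix),
                        pos=int(f[idx["pos"]]) - 1,
                        p_value=float(f[idx["p"]]),
                        sentinel_id=f[idx["sentinel_id"]],
                        trait=f[idx["trait"]],
                        beta=float(f[idx["beta"]]) if "beta" in idx and f[idx["beta"]] != "" else None,
                        se=float(f[idx["se"]]) if "se" in idx and f[idx["se"]] != "" else None,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_summary_stats(records: Iterable[SummaryStatRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(_SUMSTAT_COLUMNS + ["beta", "se"]) + "\n")
        for r in records:
            beta = "" if r.beta is None else repr(r.beta)
            se = "" if r.se is None else repr(r.se)
            fh.write(
                f"{r.variant_id}\t{r.chrom}\t{r.pos + 1}\t{r.p_value!r}\t"
                f"{r.sentinel_id}\t{r.trait}\t{beta}\t{se}\n"
            )


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def promoter_windows(
    gene: GeneModel,
    chrom_length: int | None = None,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
    strand_aware: bool = True,
) -> list[PromoterWindow]:
    """Promoter windows (one per TSS), -1500/+500 bp around the TSS.

    With ``strand_aware`` (default), "upstream" follows the direction of
    transcription: a '+' TSS t yields ``[t - 1500, t + 500)``, a '-' TSS t
    yields ``[t - 500, t + 1500)``. Windows are clipped at 0 and at
    ``chrom_length`` when given.
    """
    windows = []
    for tss in gene.tss_list:
        if strand_aware and gene.strand == "-":
            start, end = tss - downstream, tss + upstream
        else:
            start, end = tss - upstream, tss + downstream
        # '-' strand: the window must still contain the TSS base itself.
        start = max(0, start)
        end = end + 1 if end <= tss else end
        if chrom_length is not None:
            end = min(end, chrom_length)
        windows.append(PromoterWindow(gene.gene_id, tss, GenomicInterval(gene.chrom, start, end)))
    return windows


def _sort_key(iv: GenomicInterval):
    return (iv.chrom, iv.start, iv.end)


def _is_sorted(ivs: Sequence[GenomicInterval]) -> bool:
    return all(_sort_key(ivs[i]) <= _sort_key(ivs[i + 1]) for i in range(len(ivs) - 1))


def intersect(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    assume_sorted: bool = False,
) -> list[tuple[int, int]]:
    """All index pairs ``(i, j)`` with ``a[i]`` overlapping ``b[j]``.

    Overlap means >= 1 shared base under half-open semantics. Inputs are
    expected sorted by (chrom, start); unsorted inputs are sorted
    internally with a logged warning (returned indices always refer to
    the original ordering). Output is sorted by a-index then b-index.

    Uses a chromosome sweep: both lists are walked in coordinate order
    while a cache of still-open b intervals is maintained, giving
    O((n + m) log(n + m) + k) behaviour for k overlaps.
    """
    order_a = list(range(len(a)))
    order_b = list(range(len(b)))
    if not assume_sorted:
        if not _is_sorted(a):
            logger.warning("intersect: first interval list unsorted; sorting internally")
            order_a.sort(key=lambda i: _sort_key(a[i]))
        if not _is_sorted(b):
            logger.warning("intersect: second interval list unsorted; sorting internally")
            order_b.sort(key=lambda j: _sort_key(b[j]))

    pairs: list[tuple[int, int]] = []
    by_chrom_b: dict[str, list[int]] = {}
    for j in order_b:
        by_chrom_b.setdefault(b[j].chrom, []).append(j)

    by_chrom_a: dict[str, list[int]] = {}
    for i in order_a:
        by_chrom_a.setdefault(a[i].chrom, []).append(i)

    for chrom, a_idx in by_chrom_a.items():
        b_idx = by_chrom_b.get(chrom)
        if not b_idx:
            continue
        cache: list[int] = []  # open b intervals, candidates for future a's
        nxt = 0
        for i in a_idx:
            ai = a[i]
            while nxt < len(b_idx) and b[b_idx[nxt]].start < ai.end:
                cache.append(b_idx[nxt])
                nxt += 1
            # b intervals ending at or before ai.start can never overlap a
            # later a (a starts are non-decreasing): drop them for good.
            cache = [j for j in cache if b[j].end > ai.start]
            pairs.extend((i, j) for j in cache if b[j].start < ai.end)
    pairs.sort()
    return pairs


def distance_to_tss(pos: int, gene: GeneModel, chrom: str | None = None) -> int:
    """Minimum absolute distance from ``pos`` to any TSS of ``gene``."""
    if chrom is not None and chrom != gene.chrom:
        raise ValueError(
            f"position on {chrom} but gene {gene.gene_id} is on {gene.chrom}"
        )
    return min(abs(pos - t) for t in gene.tss_list)


def nearest_gene(
    pos: int,
    chrom: str,
    genes: Iterable[GeneModel],
    biotypes: set[str] | None = None,
) -> GeneModel:
    """Gene minimizing TSS distance; ties broken by smallest gene_id."""
    candidates = [
        g
        for g in genes
        if g.chrom == chrom and (biotypes is None or g.biotype in biotypes)
    ]
    if not candidates:
        raise ValueError(f"no genes on chromosome {chrom}")
    return min(candidates, key=lambda g: (distance_to_tss(pos, g), g.gene_id))


class IntervalSet:
    """Mutable set of merged intervals on one chromosome, for fast
    occupancy checks during fixture construction."""

    def __init__(self) -> None:
        self._starts: list[int] = []
        self._ends: list[int] = []

    def add(self, start: int, end: int) -> None:
        if start >= end:
            raise ValueError("empty interval")
        i = bisect_left(self._starts, start)
        # merge with neighbours
        while i > 0 and self._ends[i - 1] >= start:
            i -= 1
            start = min(start, self._starts[i])
            end = max(end, self._ends[i])
            del self._starts[i], self._ends[i]
        while i < len(self._starts) and self._starts[i] <= end:
            end = max(end, self._ends[i])
            del self._starts[i], self._ends[i]
        self._starts.insert(i, start)
        self._ends.insert(i, end)

    def overlaps(self, start: int, end: int) -> bool:
        i = bisect_left(self._starts, end)
        return i > 0 and self._ends[i - 1] > start
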