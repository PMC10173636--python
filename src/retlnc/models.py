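"""Domain types shared by every stage of the pipeline.

Coordinates are 0-based half-open throughout the package; the GTF reader and
writer in :mod:`retlnc.gtfio` convert to and from GTF's 1-based inclusive
convention at the boundary. Strand is one of ``+``, ``-`` or ``.`` (unknown);
long-read transcripts enter the pipeline strand-unknown and acquire a strand
from stranded short-read evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")
SOURCES = ("annotation", "short_read", "long_read")
POSITIONAL_CLASSES = ("antisense", "divergent", "convergent", "intronic", "intergenic")


class ValidationError(ValueError):
    """An object violates one of the documented invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval requires 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in bp between closest boundaries; 0 when overlapping."""
        if self.chrom != other.chrom:
            raise ValueError("gap_to requires intervals on the same chromosome")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


def _as_source_set(source: str) -> frozenset:
    parts = frozenset(source.split(","))
    if not parts or not parts <= set(SOURCES):
        raise ValidationError(f"source must be a comma-set drawn from {SOURCES}, got {source!r}")
    return parts


def source_string(sources: Iterable[str]) -> str:
    """Canonical comma-joined source tag (annotation < short_read < long_read order)."""
    order = {s: i for i, s in enumerate(SOURCES)}
    return ",".join(sorted(set(sources), key=order.__getitem__))


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered exon chain on a single chromosome and strand.

    ``source`` is one of the three source tags, or a comma-joined combination
    after merging (e.g. ``"annotation,long_read"``).
    """

    transcript_id: str
    gene_id: str
    exons: tuple
    source: str
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if not self.transcript_id or not self.gene_id:
            raise ValidationError("transcript_id and gene_id must be non-empty")
        if len(self.exons) == 0:
            raise ValidationError(f"{self.transcript_id}: transcript needs >= 1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise ValidationError(f"{self.transcript_id}: exons on multiple chromosomes {chroms}")
        if len(strands) > 1:
            raise ValidationError(f"{self.transcript_id}: exons on multiple strands {strands}")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end + 1:
                raise ValidationError(
                    f"{self.transcript_id}: exons must be sorted and separated by >= 1 "
                    f"intronic base, got [{a.start},{a.end}) then [{b.start},{b.end})"
                )
        _as_source_set(self.source)
        if self.biotype not in ("coding", "lncRNA", "unknown"):
            raise ValidationError(f"{self.transcript_id}: bad biotype {self.biotype!r}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    @property
    def introns(self) -> tuple:
        """(start, end) half-open intron coordinates between consecutive exons."""
        return tuple((a.end, b.start) for a, b in zip(self.exons, self.exons[1:]))

    @property
    def intron_chain(self) -> tuple:
        """Hashable key identifying the exon-intron structure up to terminal-exon ends."""
        return (self.chrom, self.strand, self.introns)

    @property
    def source_set(self) -> frozenset:
        return _as_source_set(self.source)

    def with_strand(self, strand: str) -> "TranscriptModel":
        exons = tuple(replace(e, strand=strand) for e in self.exons)
        return replace(self, exons=exons)

    def with_source(self, sources: Iterable[str]) -> "TranscriptModel":
        return replace(self, source=source_string(sources))


@dataclass(frozen=True)
class GeneLocus:
    """A cluster of same-strand, genomically overlapping transcripts."""

    locus_id: str
    transcripts: tuple
    positional_class: str = "unset"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"{self.locus_id}: locus needs >= 1 transcript")
        if len({t.chrom for t in self.transcripts}) > 1:
            raise ValidationError(f"{self.locus_id}: transcripts on multiple chromosomes")
        if len({t.strand for t in self.transcripts}) > 1:
            raise ValidationError(f"{self.locus_id}: transcripts on multiple strands")
        if self.positional_class not in POSITIONAL_CLASSES + ("unset",):
            raise ValidationError(f"{self.locus_id}: bad class {self.positional_class!r}")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def sources(self) -> frozenset:
        out: set = set()
        for t in self.transcripts:
            out |= t.source_set
        return frozenset(out)

    def with_class(self, positional_class: str) -> "GeneLocus":
        return replace(self, positional_class=positional_class)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample metadata.

    ``samples`` is indexed by sample id (matching ``values`` columns) and has
    at least the columns ``condition`` (stage or tissue label) and
    ``replicate`` (integer replicate index within the condition).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "FPKM"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.unit not in ("FPKM", "count"):
            raise ValidationError(f"unit must be FPKM or count, got {self.unit!r}")
        if list(self.values.columns) != list(self.samples.index):
            raise ValidationError("sample metadata must cover every column, in order")
        for col in ("condition", "replicate"):
            if col not in self.samples.columns:
                raise ValidationError(f"sample metadata lacks column {col!r}")
        vals = self.values.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            raise ValidationError("expression matrix contains missing/non-finite cells")
        if vals.size and (vals < 0).any():
            raise ValidationError("expression values must be >= 0")
        if self.unit == "count" and vals.size and not np.array_equal(vals, np.round(vals)):
            raise ValidationError("count matrix must contain integers")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def conditions(self) -> list:
        """Condition labels in order of first appearance."""
        return list(dict.fromkeys(self.samples["condition"]))

    def columns_of(self, condition: str) -> list:
        return list(self.samples.index[self.samples["condition"] == condition])

    def condition_means(self, log2: bool = False) -> pd.DataFrame:
        """Genes x conditions matrix of replicate means (optionally of log2(x+1))."""
        vals = np.log2(self.values + 1.0) if log2 else self.values
        out = {c: vals[self.columns_of(c)].mean(axis=1) for c in self.conditions}
        return pd.DataFrame(out, index=self.values.index)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)].copy(), self.samples, self.unit)


@dataclass
class ScoreTrack:
    """Per-base score track in bedGraph semantics; uncovered bases score 0.

    ``data`` maps chrom -> (starts, ends, scores) sorted, non-overlapping
    numpy arrays.
    """

    data: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, (starts, ends, scores) in self.data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            scores = np.asarray(scores, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, scores = starts[order], ends[order], scores[order]
            if (starts >= ends).any():
                raise ValidationError(f"{chrom}: bedGraph interval with start >= end")
            if (starts[1:] < ends[:-1]).any():
                raise ValidationError(f"{chrom}: overlapping bedGraph intervals")
            if scores.size and ((scores < 0) | (scores > 1)).any():
                raise ValidationError(f"{chrom}: scores must lie in [0, 1]")
            self.data[chrom] = (starts, ends, scores)

    def chrom_extent(self, chrom: str) -> int:
        if chrom not in self.data or self.data[chrom][1].size == 0:
            return 0
        return int(self.data[chrom][1].max())

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base score over [start, end); uncovered bases count as 0."""
        if end <= start:
            raise ValueError("region must be non-empty")
        if chrom not in self.data:
            return 0.0
        starts, ends, scores = self.data[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ov = np.clip(ov, 0, None)
        return float((ov * scores[lo:hi]).sum() / (end - start))
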