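"""Readers and writers for GTF, TSV expression matrices, bedGraph and BED6.

GTF I/O converts between GTF's 1-based inclusive coordinates and the
package-internal 0-based half-open convention. Only ``exon`` features are
consumed; each must carry ``gene_id`` and ``transcript_id`` attributes.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    ExpressionMatrix,
    GeneLocus,
    GenomicInterval,
    ScoreTrack,
    TranscriptModel,
    ValidationError,
)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """A malformed GTF line, reported with its 1-based line number."""


def _parse_attributes(field: str) -> dict:
    return dict(_ATTR_RE.findall(field))


def _merge_overlapping(intervals: list) -> list:
    """Merge book-ended or overlapping exon intervals of one transcript."""
    out: list = []
    for iv in sorted(intervals, key=lambda e: (e.start, e.end)):
        if out and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end, iv.strand)
        else:
            out.append(iv)
    return out


def read_gtf(
    path,
    source_tag: str = "annotation",
    biotype_attr: str = "gene_biotype",
    biotypes: Optional[dict] = None,
) -> list:
    """Read exon features from a GTF file into TranscriptModel objects.

    Parameters
    ----------
    source_tag:
        Source label attached to every transcript (``annotation``,
        ``short_read`` or ``long_read``).
    biotype_attr:
        GTF attribute naming the biotype (values containing ``lncRNA`` or
        equal to ``protein_coding``/``coding`` are recognised).
    biotypes:
        Optional sidecar mapping gene_id -> biotype overriding the attribute.
    """
    exons: dict = {}
    meta: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"{path}: line {lineno}: expected 9 tab fields, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            if start1 < 1 or end1 < start1:
                raise GtfParseError(f"{path}: line {lineno}: bad coordinate range {start1}-{end1}")
            if strand not in ("+", "-", "."):
                raise GtfParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            attrs = _parse_attributes(attr_s)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(f"{path}: line {lineno}: missing gene_id/transcript_id attribute")
            tid = attrs["transcript_id"]
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            exons.setdefault(tid, []).append(iv)
            meta.setdefault(tid, (attrs["gene_id"], attrs.get(biotype_attr)))

    transcripts = []
    for tid, ivs in exons.items():
        gene_id, raw_biotype = meta[tid]
        if len({e.chrom for e in ivs}) > 1 or len({e.strand for e in ivs}) > 1:
            raise ValidationError(f"{path}: transcript {tid} has exons on mixed chroms/strands")
        biotype = "unknown"
        if biotypes is not None and gene_id in biotypes:
            biotype = biotypes[gene_id]
        elif raw_biotype is not None:
            if "lncRNA" in raw_biotype or raw_biotype == "lincRNA":
                biotype = "lncRNA"
            elif raw_biotype in ("protein_coding", "coding"):
                biotype = "coding"
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                exons=tuple(_merge_overlapping(ivs)),
                source=source_tag,
                biotype=biotype,
            )
        )
    transcripts.sort(key=lambda t: (t.chrom, t.span.start, t.span.end, t.transcript_id))
    return transcripts


def _gtf_lines(gene_id: str, t: TranscriptModel, extra: str = "") -> Iterable[str]:
    attrs = f'gene_id "{gene_id}"; transcript_id "{t.transcript_id}";'
    if t.biotype != "unknown":
        bt = "protein_coding" if t.biotype == "coding" else "lncRNA"
        attrs += f' gene_biotype "{bt}";'
    if extra:
        attrs += " " + extra
    span = t.span
    yield "\t".join(
        [span.chrom, t.source, "transcript", str(span.start + 1), str(span.end), ".", t.strand, ".", attrs]
    )
    for e in t.exons:
        yield "\t".join(
            [e.chrom, t.source, "exon", str(e.start + 1), str(e.end), ".", e.strand, ".", attrs]
        )


def write_gtf(items: Sequence, path) -> None:
    """Write GeneLocus or TranscriptModel objects to a GTF file.

    For loci the locus id becomes the emitted gene_id and the positional
    class (when set) is recorded as a ``positional_class`` attribute.
    """
    lines: list = []
    for item in items:
        if isinstance(item, GeneLocus):
            extra = (
                f'positional_class "{item.positional_class}";'
                if item.positional_class != "unset"
                else ""
            )
            for t in item.transcripts:
                lines.extend(_gtf_lines(item.locus_id, t, extra))
        else:
            lines.extend(_gtf_lines(item.gene_id, item))
    Path(path).write_text("".join(line + "\n" for line in lines))


def write_bed6(loci: Sequence, path) -> None:
    """Export locus spans as BED6 (0-based half-open, as BED requires)."""
    with open(path, "w") as fh:
        for locus in loci:
            s = locus.span
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{locus.locus_id}\t0\t{s.strand}\n")


def read_matrix(path, unit: str, metadata_path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a sample-metadata sidecar.

    The sidecar is a TSV with columns ``sample``, ``condition``,
    ``replicate`` covering every matrix column.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    for col in ("sample", "condition", "replicate"):
        if col not in meta.columns:
            raise ValidationError(f"{metadata_path}: metadata lacks column {col!r}")
    meta = meta.set_index("sample")
    missing = [c for c in values.columns if c not in meta.index]
    if missing:
        raise ValidationError(f"{metadata_path}: no metadata for sample column(s) {missing}")
    meta = meta.loc[list(values.columns)]
    return ExpressionMatrix(values=values, samples=meta, unit=unit)


def write_matrix(matrix: ExpressionMatrix, path, metadata_path=None) -> None:
    fmt = "%d" if matrix.unit == "count" else None
    vals = matrix.values
    if matrix.unit == "count":
        vals = vals.astype(np.int64)
    vals.to_csv(path, sep="\t", index_label="gene_id")
    if metadata_path is not None:
        matrix.samples.to_csv(metadata_path, sep="\t", index_label="sample")


def read_bedgraph(path) -> ScoreTrack:
    """Read a bedGraph (chrom, start, end, score) into a ScoreTrack."""
    per_chrom: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise GtfParseError(f"{path}: line {lineno}: expected 4 bedGraph fields")
            chrom, start, end, score = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            per_chrom.setdefault(chrom, []).append((start, end, score))
    data = {}
    for chrom, rows in per_chrom.items():
        arr = np.array(rows, dtype=float)
        data[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    return ScoreTrack(data=data)


def write_bedgraph(track: ScoreTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            starts, ends, scores = track.data[chrom]
            for s, e, sc in zip(starts, ends, scores):
                fh.write(f"{chrom}\t{s}\t{e}\t{sc:g}\n")
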