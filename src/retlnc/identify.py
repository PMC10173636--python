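"""The lncRNA identification cascade.

Four stages turn three raw transcript sets into the final lncRNA gene set:

1. short-read filtering — keep multi-exon, >= 200 nt (mature length),
   noncoding transcripts whose exons never touch a coding exon on either
   strand;
2. long-read strand assignment — a chi-square test of the stranded read
   counts against a 50:50 split, with assignment requiring fold > 2 AND
   p <= 0.05;
3. long-read filtering — keep stranded, multi-exon transcripts sharing no
   intron (exact donor-acceptor coordinates, same strand) with a coding
   transcript;
4. merge — collapse identical intron chains across sources, cluster
   same-strand overlapping transcripts into gene loci, and account for each
   source's contribution; then gate on expression (FPKM >= 1 somewhere).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .models import (
    ExpressionMatrix,
    GeneLocus,
    TranscriptModel,
    ValidationError,
    source_string,
)

_SOURCE_PRIORITY = {"annotation": 0, "long_read": 1, "short_read": 2}


# ---------------------------------------------------------------------------
# exon/intron indices over coding transcripts

class _ExonIndex:
    """Per-chrom sorted exon intervals for strand-blind overlap queries."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        per_chrom: Dict[str, list] = {}
        for t in transcripts:
            for e in t.exons:
                per_chrom.setdefault(e.chrom, []).append((e.start, e.end))
        self._index = {}
        for chrom, ivs in per_chrom.items():
            arr = np.array(sorted(ivs), dtype=np.int64)
            self._index[chrom] = (arr[:, 0], arr[:, 1])

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._index:
            return False
        starts, ends = self._index[chrom]
        i = np.searchsorted(starts, end, side="left")
        return bool((ends[:i] > start).any())


def _coding_intron_keys(coding: Iterable[TranscriptModel]) -> set:
    keys = set()
    for t in coding:
        for s, e in t.introns:
            keys.add((t.chrom, t.strand, s, e))
    return keys


# ---------------------------------------------------------------------------
# stage 1: short-read filter

def filter_short_read_set(
    transcripts: Sequence[TranscriptModel],
    coding: Sequence[TranscriptModel],
    coding_potential: Dict[str, str],
    min_length: int = 200,
    on_missing_potential: str = "drop",
) -> List[TranscriptModel]:
    """Filter assembled short-read transcripts down to lncRNA candidates.

    Keeps transcripts that are multi-exon, have >= ``min_length`` exonic nt,
    share no exonic base with any coding exon (either strand) and are labeled
    ``noncoding`` in the coding-potential table. Transcripts absent from the
    table are dropped with a warning (``on_missing_potential="drop"``) or
    raise (``"error"``).
    """
    exon_index = _ExonIndex(coding)
    kept = []
    for t in transcripts:
        if not t.is_multi_exon:
            continue
        if t.exonic_length < min_length:
            continue
        if any(exon_index.overlaps(e.chrom, e.start, e.end) for e in t.exons):
            continue
        label = coding_potential.get(t.transcript_id)
        if label is None:
            if on_missing_potential == "error":
                raise ValidationError(f"{t.transcript_id}: no coding-potential label")
            warnings.warn(f"{t.transcript_id}: no coding-potential label; dropped", stacklevel=2)
            continue
        if label != "noncoding":
            continue
        kept.append(t)
    return kept


# ---------------------------------------------------------------------------
# stage 2: strand assignment

@dataclass(frozen=True)
class StrandCall:
    """Outcome of the stranded-read vote for one unstranded transcript."""

    transcript_id: str
    plus_reads: int
    minus_reads: int
    fold: float
    chi2: float
    p_value: float
    assigned_strand: str  # "+", "-" or "unassigned"


def assign_strand(
    plus_reads: int,
    minus_reads: int,
    transcript_id: str = "",
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
) -> StrandCall:
    """Chi-square vote of stranded read counts against an equal split.

    The majority strand is assigned iff the majority/minority fold exceeds
    ``fold_threshold`` (strictly) and the chi-square goodness-of-fit p-value
    (df=1, no continuity correction) is <= ``alpha``. With no reads the call
    is unassigned with p = 1.
    """
    if plus_reads < 0 or minus_reads < 0:
        raise ValidationError("read counts must be >= 0")
    n = plus_reads + minus_reads
    if n == 0:
        return StrandCall(transcript_id, 0, 0, 1.0, 0.0, 1.0, "unassigned")
    hi, lo = max(plus_reads, minus_reads), min(plus_reads, minus_reads)
    fold = float("inf") if lo == 0 else hi / lo
    expected = n / 2.0
    chi2 = (plus_reads - expected) ** 2 / expected + (minus_reads - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    if fold > fold_threshold and p <= alpha:
        strand = "+" if plus_reads > minus_reads else "-"
    else:
        strand = "unassigned"
    return StrandCall(transcript_id, plus_reads, minus_reads, fold, chi2, p, strand)


def assign_strands(
    counts: Sequence[Tuple[str, int, int]],
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
) -> Dict[str, StrandCall]:
    """Vectorised convenience wrapper over (transcript_id, plus, minus) rows."""
    return {
        tid: assign_strand(p, m, tid, fold_threshold, alpha) for tid, p, m in counts
    }


# ---------------------------------------------------------------------------
# stage 3: long-read filter

def filter_long_read_set(
    transcripts: Sequence[TranscriptModel],
    strand_calls: Dict[str, StrandCall],
    coding: Sequence[TranscriptModel],
) -> List[TranscriptModel]:
    """Filter full-length long-read transcripts to stranded lncRNA candidates.

    Strand-unknown transcripts take the strand from their StrandCall and are
    dropped when unassigned. Multi-exon transcripts sharing any intron
    (exact coordinates, same strand) with a coding transcript are removed, as
    are single-exon transcripts.
    """
    intron_keys = _coding_intron_keys(coding)
    kept = []
    for t in transcripts:
        if t.strand == ".":
            call = strand_calls.get(t.transcript_id)
            if call is None:
                raise ValidationError(f"{t.transcript_id}: strand-unknown transcript has no StrandCall")
            if call.assigned_strand == "unassigned":
                continue
            t = t.with_strand(call.assigned_strand)
        if not t.is_multi_exon:
            continue
        if any((t.chrom, t.strand, s, e) in intron_keys for s, e in t.introns):
            continue
        kept.append(t)
    return kept


# ---------------------------------------------------------------------------
# stage 4: merge with source accounting

@dataclass
class MergeReport:
    """Source-contribution accounting for the merged gene and transcript sets.

    ``gene_combo_counts``/``transcript_combo_counts`` map a canonical source
    combination string (e.g. ``"annotation,long_read"``) to the number of
    merged loci/transcripts carrying exactly that set of sources, so the
    counts partition the totals (inclusion-exclusion holds by construction
    and is asserted).
    """

    n_loci: int = 0
    n_transcripts: int = 0
    gene_combo_counts: Dict[str, int] = field(default_factory=dict)
    transcript_combo_counts: Dict[str, int] = field(default_factory=dict)
    gene_source_counts: Dict[str, int] = field(default_factory=dict)
    transcript_source_counts: Dict[str, int] = field(default_factory=dict)
    novel_isoforms_by_source: Dict[str, int] = field(default_factory=dict)
    n_annotation_backed_loci: int = 0

    def validate(self) -> None:
        if sum(self.gene_combo_counts.values()) != self.n_loci:
            raise ValidationError("gene combo counts do not partition the locus total")
        if sum(self.transcript_combo_counts.values()) != self.n_transcripts:
            raise ValidationError("transcript combo counts do not partition the transcript total")
        for src, count in self.gene_source_counts.items():
            expect = sum(v for k, v in self.gene_combo_counts.items() if src in k.split(","))
            if count != expect:
                raise ValidationError(f"per-source gene count inconsistent for {src}")


def _collapse_multi_exon(group: List[TranscriptModel]) -> TranscriptModel:
    """Collapse identical-intron-chain transcripts, widening terminal exons."""
    rep = min(group, key=lambda t: (_SOURCE_PRIORITY[sorted(t.source_set)[0]], t.transcript_id))
    start = min(t.span.start for t in group)
    end = max(t.span.end for t in group)
    exons = list(rep.exons)
    chrom, strand = rep.chrom, rep.strand
    first = exons[0]
    exons[0] = type(first)(chrom, start, first.end, strand)
    last = exons[-1]
    exons[-1] = type(last)(chrom, last.start, end, strand)
    sources = set()
    for t in group:
        sources |= t.source_set
    return TranscriptModel(
        transcript_id=rep.transcript_id,
        gene_id=rep.gene_id,
        exons=tuple(exons),
        source=source_string(sources),
        biotype=rep.biotype,
    )


def _collapse_single_exon(group: List[TranscriptModel]) -> TranscriptModel:
    rep = min(group, key=lambda t: (_SOURCE_PRIORITY[sorted(t.source_set)[0]], t.transcript_id))
    chrom, strand = rep.chrom, rep.strand
    start = min(t.span.start for t in group)
    end = max(t.span.end for t in group)
    sources = set()
    for t in group:
        sources |= t.source_set
    iv = type(rep.exons[0])(chrom, start, end, strand)
    return TranscriptModel(rep.transcript_id, rep.gene_id, (iv,), source_string(sources), rep.biotype)


def _cluster_spans(transcripts: List[TranscriptModel]) -> List[List[TranscriptModel]]:
    """Transitive closure of same-strand >= 1 bp span overlap.

    Sorted by start, a transcript joins the open cluster iff it starts before
    the running maximum end — the standard sweep for connected components of
    an interval overlap graph.
    """
    ordered = sorted(
        transcripts,
        key=lambda t: (t.chrom, t.strand, t.span.start, t.span.end, t.transcript_id),
    )
    clusters: List[List[TranscriptModel]] = []
    cur_key = None
    reach = -1
    for t in ordered:
        key = (t.chrom, t.strand)
        if key != cur_key or t.span.start >= reach:
            clusters.append([t])
            cur_key, reach = key, t.span.end
        else:
            clusters[-1].append(t)
            reach = max(reach, t.span.end)
    clusters.sort(key=lambda ms: (ms[0].chrom, ms[0].span.start, ms[0].strand))
    return clusters


def merge_sources(
    annotation_set: Sequence[TranscriptModel],
    sr_set: Sequence[TranscriptModel],
    lr_set: Sequence[TranscriptModel],
    locus_prefix: str = "XLOC",
) -> Tuple[List[GeneLocus], MergeReport]:
    """Merge the three filtered transcript sets into gene loci.

    Multi-exon transcripts with identical intron chains collapse to one
    representative with the union of source tags and the widest terminal
    exons; single-exon transcripts collapse when their spans overlap on the
    same strand. Same-strand transcripts overlapping by >= 1 bp then cluster
    into loci by transitive closure, and loci receive fresh ``XLOC``-style
    ids ordered along the genome.
    """
    pool = list(annotation_set) + list(sr_set) + list(lr_set)
    for t in pool:
        if t.strand == ".":
            raise ValidationError(f"{t.transcript_id}: unstranded transcript reached merge")

    multi: Dict[tuple, List[TranscriptModel]] = {}
    single: List[TranscriptModel] = []
    for t in pool:
        if t.is_multi_exon:
            multi.setdefault(t.intron_chain, []).append(t)
        else:
            single.append(t)
    merged: List[TranscriptModel] = [_collapse_multi_exon(g) for g in multi.values()]
    for cluster in _cluster_spans(single):
        merged.append(_collapse_single_exon(cluster))

    loci: List[GeneLocus] = []
    report = MergeReport()
    clusters = _cluster_spans(merged)
    width = max(6, len(str(len(clusters))))
    annotation_chains = {t.intron_chain for t in annotation_set if t.is_multi_exon}
    for k, members in enumerate(clusters, start=1):
        locus = GeneLocus(locus_id=f"{locus_prefix}_{k:0{width}d}", transcripts=tuple(members))
        loci.append(locus)
        combo = source_string(locus.sources)
        report.gene_combo_counts[combo] = report.gene_combo_counts.get(combo, 0) + 1
        for src in locus.sources:
            report.gene_source_counts[src] = report.gene_source_counts.get(src, 0) + 1
        if "annotation" in locus.sources:
            report.n_annotation_backed_loci += 1
            for t in members:
                srcs = t.source_set
                if "annotation" not in srcs:
                    for src in srcs:
                        report.novel_isoforms_by_source[src] = (
                            report.novel_isoforms_by_source.get(src, 0) + 1
                        )
    report.n_loci = len(loci)
    report.n_transcripts = len(merged)
    for t in merged:
        combo = source_string(t.source_set)
        report.transcript_combo_counts[combo] = report.transcript_combo_counts.get(combo, 0) + 1
        for src in t.source_set:
            report.transcript_source_counts[src] = report.transcript_source_counts.get(src, 0) + 1
    report.validate()
    return loci, report


def expression_gate(
    loci: Sequence[GeneLocus],
    fpkm: ExpressionMatrix,
    threshold: float = 1.0,
    mode: str = "any_sample",
) -> List[GeneLocus]:
    """Remove loci whose expression never reaches ``threshold`` FPKM.

    ``mode="any_sample"`` keeps a locus when FPKM >= threshold in at least
    one sample column; ``mode="stage_replicates"`` requires every replicate
    of at least one stage to reach the threshold.
    """
    if mode not in ("any_sample", "stage_replicates"):
        raise ValueError(f"unknown gate mode {mode!r}")
    kept = []
    for locus in loci:
        if locus.locus_id not in fpkm.values.index:
            raise ValidationError(f"{locus.locus_id}: locus absent from FPKM matrix")
        row = fpkm.values.loc[locus.locus_id]
        if mode == "any_sample":
            ok = bool((row >= threshold).any())
        else:
            ok = any(
                all(row[c] >= threshold for c in fpkm.columns_of(cond))
                for cond in fpkm.conditions
            )
        if ok:
            kept.append(locus)
    return kept
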