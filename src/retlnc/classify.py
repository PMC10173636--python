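"""Positional classification of lncRNA loci and exon conservation scoring.

Each lncRNA locus receives exactly one of five classes relative to the
protein-coding gene complement, decided in precedence order:

1. ``antisense`` — the locus span overlaps an opposite-strand coding gene
   body by at least ``antisense_min_overlap`` bases;
2. ``intronic`` — at least ``intronic_frac`` of the locus's exonic bases lie
   inside same-strand coding introns;
3. ``divergent`` — the nearest coding gene is <= ``window`` bp away and on
   the opposite strand;
4. ``convergent`` — the nearest coding gene is <= ``window`` bp away and on
   the same strand;
5. ``intergenic`` — otherwise (strict lincRNA, > window from any coding gene).

Distances are measured between the closest boundaries of the lncRNA locus
span and the coding gene span; the window boundary is inclusive (a locus at
exactly ``window`` bp is divergent/convergent, one base further intergenic).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .models import GeneLocus, GenomicInterval, ScoreTrack, TranscriptModel


@dataclass(frozen=True)
class ClassificationResult:
    locus_id: str
    positional_class: str
    nearest_coding_gene_id: Optional[str]
    signed_distance: Optional[int]  # >0 coding gene downstream, <0 upstream, 0 overlap
    overlap_bases: int
    intronic_fraction: float


@dataclass(frozen=True)
class _CodingGene:
    gene_id: str
    span: GenomicInterval
    introns: tuple  # (start, end) pairs: gene span minus union of its exons


class CodingIndex:
    """Coding gene bodies and intron sets, grouped by gene_id."""

    def __init__(self, coding_transcripts: Iterable[TranscriptModel]):
        by_gene: Dict[str, List[TranscriptModel]] = {}
        for t in coding_transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        self.genes: List[_CodingGene] = []
        for gene_id in sorted(by_gene):
            ts = by_gene[gene_id]
            chrom, strand = ts[0].chrom, ts[0].strand
            start = min(t.span.start for t in ts)
            end = max(t.span.end for t in ts)
            exon_ivs = sorted((e.start, e.end) for t in ts for e in t.exons)
            merged: List[list] = []
            for s, e in exon_ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            introns = []
            prev = start
            for s, e in merged:
                if s > prev:
                    introns.append((prev, s))
                prev = max(prev, e)
            if end > prev:
                introns.append((prev, end))
            self.genes.append(
                _CodingGene(gene_id, GenomicInterval(chrom, start, end, strand), tuple(introns))
            )

    @classmethod
    def from_loci(cls, coding_loci: Iterable[GeneLocus]) -> "CodingIndex":
        ts = [t for locus in coding_loci for t in locus.transcripts]
        return cls(ts)


def _signed_gap(lnc: GenomicInterval, gene: GenomicInterval) -> int:
    if lnc.overlaps(gene):
        return 0
    if gene.start >= lnc.end:
        return gene.start - lnc.end  # coding gene downstream of the locus
    return -(lnc.start - gene.end)


def classify_locus(
    lnc: GeneLocus,
    coding_index: CodingIndex,
    window: int = 1000,
    intronic_frac: float = 0.5,
    antisense_min_overlap: int = 1,
) -> ClassificationResult:
    """Assign one positional class to a lncRNA locus (see module docstring)."""
    span = lnc.span
    exon_ivs = sorted(
        {(e.start, e.end) for t in lnc.transcripts for e in t.exons}
    )
    merged_exons: List[list] = []
    for s, e in exon_ivs:
        if merged_exons and s <= merged_exons[-1][1]:
            merged_exons[-1][1] = max(merged_exons[-1][1], e)
        else:
            merged_exons.append([s, e])
    exonic_total = sum(e - s for s, e in merged_exons)

    nearest: Optional[_CodingGene] = None
    nearest_dist = None
    antisense_overlap = 0
    same_strand_introns: List[tuple] = []
    for gene in coding_index.genes:
        if gene.span.chrom != span.chrom:
            continue
        ov = span.overlap_length(gene.span)
        if gene.span.strand != span.strand and ov > antisense_overlap:
            antisense_overlap = ov
        if gene.span.strand == span.strand:
            same_strand_introns.extend(
                (s, e) for s, e in gene.introns if s < span.end and e > span.start
            )
        dist = abs(_signed_gap(span, gene.span))
        if nearest_dist is None or (dist, gene.gene_id) < (nearest_dist, nearest.gene_id):
            nearest, nearest_dist = gene, dist

    # union of same-strand coding introns, then intersect with locus exons
    merged_introns: List[list] = []
    for s, e in sorted(same_strand_introns):
        if merged_introns and s <= merged_introns[-1][1]:
            merged_introns[-1][1] = max(merged_introns[-1][1], e)
        else:
            merged_introns.append([s, e])
    intronic_bases = sum(
        max(0, min(e, iend) - max(s, istart))
        for istart, iend in merged_introns
        for s, e in merged_exons
    )
    intronic_fraction = intronic_bases / exonic_total if exonic_total else 0.0

    if nearest is None:
        return ClassificationResult(lnc.locus_id, "intergenic", None, None, 0, intronic_fraction)

    signed = _signed_gap(span, nearest.span)
    overlap_bases = span.overlap_length(nearest.span)
    if antisense_overlap >= antisense_min_overlap:
        cls = "antisense"
    elif intronic_fraction >= intronic_frac:
        cls = "intronic"
    elif nearest_dist <= window:
        cls = "divergent" if nearest.span.strand != span.strand else "convergent"
    else:
        cls = "intergenic"
    return ClassificationResult(
        lnc.locus_id, cls, nearest.gene_id, signed, overlap_bases, intronic_fraction
    )


def classify_all(
    loci: Sequence[GeneLocus],
    coding: Sequence[TranscriptModel],
    window: int = 1000,
    intronic_frac: float = 0.5,
    antisense_min_overlap: int = 1,
) -> Tuple[List[ClassificationResult], Counter]:
    """Classify every locus; returns results plus a per-class count summary."""
    index = CodingIndex(coding)
    results = [
        classify_locus(l, index, window, intronic_frac, antisense_min_overlap) for l in loci
    ]
    summary = Counter(r.positional_class for r in results)
    return results, summary


def exon_conservation(
    loci: Sequence[GeneLocus],
    coding: Sequence[TranscriptModel],
    track: ScoreTrack,
    seed: int,
    n_random: Optional[int] = None,
    max_len: int = 1000,
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> Dict[str, np.ndarray]:
    """Mean per-base conservation of lncRNA exons, coding exons and random regions.

    The random background has the same cardinality as the lncRNA exon set
    (unless ``n_random`` overrides it); lengths are uniform on [1, max_len]
    and placements uniform over the genome (chromosomes weighted by length).
    Bases not covered by the track score 0.
    """
    lnc_exons = [(e.chrom, e.start, e.end) for l in loci for t in l.transcripts for e in t.exons]
    coding_exons = [(e.chrom, e.start, e.end) for t in coding for e in t.exons]
    if chrom_sizes is None:
        chroms = {c for c, _, _ in lnc_exons + coding_exons} | set(track.data)
        chrom_sizes = {
            c: max(
                track.chrom_extent(c),
                max((e for cc, _, e in lnc_exons + coding_exons if cc == c), default=0),
            )
            for c in chroms
        }
    chrom_sizes = {c: n for c, n in chrom_sizes.items() if n > 0}
    if n_random is None:
        n_random = len(lnc_exons)
    rng = np.random.default_rng(seed)
    names = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in names], dtype=float)
    weights /= weights.sum()
    random_regions = []
    for _ in range(n_random):
        chrom = names[rng.choice(len(names), p=weights)]
        length = int(rng.integers(1, max_len + 1))
        length = min(length, chrom_sizes[chrom])
        start = int(rng.integers(0, chrom_sizes[chrom] - length + 1))
        random_regions.append((chrom, start, start + length))
    return {
        "lncRNA_exons": np.array([track.region_mean(*r) for r in lnc_exons]),
        "coding_exons": np.array([track.region_mean(*r) for r in coding_exons]),
        "random": np.array([track.region_mean(*r) for r in random_regions]),
    }
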