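"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator builds a toy single-chromosome genome: non-overlapping
protein-coding genes separated by multi-kb gaps, plus planted lncRNA genes
satisfying exactly one positional-class geometry each (antisense lncRNAs
inside an opposite-strand coding gene body, intronic ones inside a
same-strand intron, divergent/convergent ones within 1 kb of a gene start
on the opposite/same strand, intergenic ones > 1 kb from everything).
Planted lncRNAs are distributed over three "source" transcript sets
(genome annotation, short-read assembly, long-read full-length) with known
overlap, so the merge accounting has exact expected values; decoy
transcripts exercise each filter of the identification cascade (too short,
single-exon, coding-exon overlap, coding potential, shared intron).

Expression generators plant stage-specific genes (true tau = 1),
constitutive genes (true tau = 0), correlated cis pairs and trans
co-expression modules, retina-specific genes, and NB-distributed mutant
counts with known fold changes. Every generator is a pure function of its
parameters and seed.

Default study conditions mirror the emulated design: 15 developmental
stages (E12.5..P28) with 2 replicates, a 15-tissue panel plus retina,
stranded-read depth 200 with strand bias 0.9, replicate noise ~20% CV, and
NB dispersion 0.05 for mutant contrasts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import (
    ExpressionMatrix,
    GenomicInterval,
    TranscriptModel,
    source_string,
)

STAGE_LABELS = [
    "E12.5", "E13.5", "E14.5", "E15.5", "E16.5", "E17.5", "E18.5",
    "P0", "P1", "P3", "P5", "P7", "P14", "P21", "P28",
]
TISSUE_LABELS = [
    "cerebrum", "thymus", "testis", "mammary_gland", "liver", "stomach",
    "large_intestine", "small_intestine", "colon", "kidney", "adrenal",
    "ovary", "lung", "heart", "spleen",
]
CLASSES = ("antisense", "intronic", "divergent", "convergent", "intergenic")

_SOURCE_COMBO_WEIGHTS = {
    "annotation": 0.15,
    "short_read": 0.10,
    "long_read": 0.15,
    "annotation,short_read": 0.10,
    "annotation,long_read": 0.15,
    "short_read,long_read": 0.15,
    "annotation,short_read,long_read": 0.20,
}


class GenerationError(RuntimeError):
    """The requested geometry cannot be placed."""


@dataclass
class SyntheticTruth:
    """Planted ground truth; filled by the genome generator, extended by the
    expression and mutant generators."""

    seed: int
    chrom: str = "chrT"
    chrom_length: int = 0
    coding_genes: Dict[str, dict] = field(default_factory=dict)
    lnc_genes: Dict[str, dict] = field(default_factory=dict)
    unknown_strand: Dict[str, str] = field(default_factory=dict)  # LR tid -> true strand
    class_counts: Dict[str, int] = field(default_factory=dict)  # post-gate classes
    low_expressed: List[str] = field(default_factory=list)
    expected_locus_count: int = 0  # merged loci before the expression gate
    expected_gated_count: int = 0
    expected_transcript_count: int = 0
    expected_gene_combos: Dict[str, int] = field(default_factory=dict)
    expected_transcript_combos: Dict[str, int] = field(default_factory=dict)
    expected_novel_isoforms: Dict[str, int] = field(default_factory=dict)
    stages: List[str] = field(default_factory=list)
    tissues: List[str] = field(default_factory=list)
    stage_specific: Dict[str, str] = field(default_factory=dict)  # gene -> peak stage
    constitutive: List[str] = field(default_factory=list)
    cis_pairs: List[list] = field(default_factory=list)  # [lnc, coding, distance]
    trans_modules: Dict[str, dict] = field(default_factory=dict)
    trans_pairs: List[list] = field(default_factory=list)  # [lnc, coding]
    retina_specific: List[str] = field(default_factory=list)
    de_truth: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class ToyGenome:
    """In-memory toy genome: coding models plus the three lncRNA source sets."""

    coding_transcripts: List[TranscriptModel]
    annotation_set: List[TranscriptModel]  # annotation lncRNAs (incl. single-exon)
    sr_set: List[TranscriptModel]  # raw short-read assembly (with decoys)
    lr_set: List[TranscriptModel]  # raw long-read set (with decoys, some unstranded)
    coding_potential: Dict[str, str]
    truth: SyntheticTruth


def _iv(chrom: str, start: int, end: int, strand: str) -> GenomicInterval:
    return GenomicInterval(chrom, start, end, strand)


def _two_exon_chain(
    chrom: str, start: int, strand: str, rng, e1=(150, 250), gap=(100, 200), e2=(150, 250)
) -> Tuple[GenomicInterval, GenomicInterval]:
    l1 = int(rng.integers(*e1))
    g = int(rng.integers(*gap))
    l2 = int(rng.integers(*e2))
    a = _iv(chrom, start, start + l1, strand)
    b = _iv(chrom, start + l1 + g, start + l1 + g + l2, strand)
    return a, b


def build_toy_genome(
    n_coding: int = 30,
    n_lnc_per_class: int = 5,
    chrom_length: Optional[int] = None,
    seed: int = 0,
    n_single_exon: int = 0,
    n_low_expressed: int = 2,
    lr_unknown_frac: float = 0.5,
    novel_isoform_prob: float = 0.4,
    with_decoys: bool = True,
    chrom: str = "chrT",
) -> ToyGenome:
    """Build the toy genome in memory; see the module docstring for geometry.

    Raises GenerationError when ``n_coding`` provides too few gene bodies and
    gaps for the requested plantings, or when ``chrom_length`` is too small
    to hold the layout.
    """
    rng = np.random.default_rng(seed)
    n_decoy_hosts = 5 if with_decoys else 0
    need_hosts = 2 * n_lnc_per_class + n_decoy_hosts
    need_gaps = 3 * n_lnc_per_class + n_low_expressed + n_single_exon
    if n_coding < need_hosts:
        raise GenerationError(
            f"n_coding={n_coding} too small: need >= {need_hosts} gene bodies to host "
            "antisense/intronic lncRNAs and decoys"
        )
    if n_coding - 1 < need_gaps:
        raise GenerationError(
            f"n_coding={n_coding} too small: need >= {need_gaps + 1} genes for "
            f"{need_gaps} intergenic gap plantings"
        )

    truth = SyntheticTruth(seed=seed, chrom=chrom)

    # --- place coding genes left to right, introns large enough to host lncRNAs
    coding: List[TranscriptModel] = []
    gaps: List[Tuple[int, int]] = []  # (gap_start, gap_end) between consecutive genes
    pos = int(rng.integers(2000, 4000))
    for i in range(n_coding):
        gid = f"PC{i:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(3, 6))
        exons = []
        cursor = pos
        for k in range(n_exons):
            length = int(rng.integers(150, 400))
            exons.append(_iv(chrom, cursor, cursor + length, strand))
            cursor += length
            if k < n_exons - 1:
                cursor += int(rng.integers(1600, 2400))
        coding.append(
            TranscriptModel(f"{gid}.t1", gid, tuple(exons), "annotation", "coding")
        )
        truth.coding_genes[gid] = {"start": pos, "end": cursor, "strand": strand}
        gap = int(rng.integers(4200, 7000))
        gaps.append((cursor, cursor + gap))
        pos = cursor + gap
    total_needed = pos + 2000
    if chrom_length is not None and chrom_length < total_needed:
        raise GenerationError(
            f"chrom_length={chrom_length} too small; layout needs {total_needed} bp"
        )
    truth.chrom_length = chrom_length or total_needed
    gaps = gaps[:-1]  # internal gaps only

    host_order = rng.permutation(n_coding)
    antisense_hosts = host_order[:n_lnc_per_class]
    intronic_hosts = host_order[n_lnc_per_class: 2 * n_lnc_per_class]
    decoy_hosts = host_order[2 * n_lnc_per_class: 2 * n_lnc_per_class + n_decoy_hosts]
    gap_order = rng.permutation(len(gaps))
    div_gaps = gap_order[:n_lnc_per_class]
    conv_gaps = gap_order[n_lnc_per_class: 2 * n_lnc_per_class]
    inter_gaps = gap_order[2 * n_lnc_per_class: 3 * n_lnc_per_class]
    low_gaps = gap_order[3 * n_lnc_per_class: 3 * n_lnc_per_class + n_low_expressed]
    se_gaps = gap_order[
        3 * n_lnc_per_class + n_low_expressed:
        3 * n_lnc_per_class + n_low_expressed + n_single_exon
    ]

    opposite = {"+": "-", "-": "+"}
    lnc_chains: Dict[str, dict] = {}  # gid -> {"exons": tuple, "cls": str, ...}
    gene_counter = 0

    def _register(cls: str, exons: tuple, low: bool = False) -> str:
        nonlocal gene_counter
        gid = f"LNC{gene_counter:03d}"
        gene_counter += 1
        lnc_chains[gid] = {"exons": exons, "cls": cls, "low": low}
        return gid

    for idx in antisense_hosts:
        g = coding[idx]
        start = g.span.start + int(rng.integers(150, 400))
        exons = _two_exon_chain(chrom, start, opposite[g.strand], rng)
        _register("antisense", exons)
    for idx in intronic_hosts:
        g = coding[idx]
        intron = max(g.introns, key=lambda se: se[1] - se[0])
        istart, iend = intron
        span_budget = iend - istart - 200
        if span_budget < 700:
            raise GenerationError(f"intron of {g.gene_id} too small to host a lncRNA")
        start = istart + 100 + int(rng.integers(0, span_budget - 700 + 1))
        exons = _two_exon_chain(chrom, start, g.strand, rng)
        _register("intronic", exons)
    for which, gap_ids in (("divergent", div_gaps), ("convergent", conv_gaps)):
        for gi in gap_ids:
            gap_start, gap_end = gaps[gi]
            right_gene = coding[gi + 1]
            d = int(rng.integers(100, 901))
            exons = _two_exon_chain(chrom, 0, "+", rng)  # template for the span length
            span = exons[1].end - exons[0].start
            start = gap_end - d - span
            if start - gap_start <= 1000 + d:  # nearest must stay the right gene
                raise GenerationError("gap too small for a near-gene lncRNA")
            strand = (
                opposite[right_gene.strand] if which == "divergent" else right_gene.strand
            )
            shifted = tuple(_iv(chrom, e.start + start, e.end + start, strand) for e in exons)
            _register(which, shifted)
    for gap_ids, low in ((inter_gaps, False), (low_gaps, True)):
        for gi in gap_ids:
            gap_start, gap_end = gaps[gi]
            exons = _two_exon_chain(chrom, 0, "+", rng)
            span = exons[1].end - exons[0].start
            lo, hi = gap_start + 1001, gap_end - 1001 - span
            if hi < lo:
                raise GenerationError("gap too small for an intergenic lncRNA")
            start = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            shifted = tuple(_iv(chrom, e.start + start, e.end + start, strand) for e in exons)
            _register("intergenic", shifted, low=low)
    for gi in se_gaps:
        gap_start, gap_end = gaps[gi]
        length = int(rng.integers(400, 800))
        lo, hi = gap_start + 1001, gap_end - 1001 - length
        if hi < lo:
            raise GenerationError("gap too small for a single-exon lncRNA")
        start = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = _register("intergenic", (_iv(chrom, start, start + length, strand),))
        lnc_chains[gid]["single_exon"] = True

    # --- distribute genes over sources and emit transcripts
    combos = list(_SOURCE_COMBO_WEIGHTS)
    weights = np.array([_SOURCE_COMBO_WEIGHTS[c] for c in combos])
    annotation_set: List[TranscriptModel] = []
    sr_set: List[TranscriptModel] = []
    lr_set: List[TranscriptModel] = []
    coding_potential: Dict[str, str] = {}
    abbrev = {"annotation": "an", "short_read": "sr", "long_read": "lr"}

    for gid in sorted(lnc_chains):
        info = lnc_chains[gid]
        exons = info["exons"]
        strand = exons[0].strand
        single = info.get("single_exon", False)
        if single:
            srcs = ["annotation"]
        elif info["cls"] == "antisense":
            # antisense exons may overlap coding exons, so the short-read
            # filter would (correctly) remove them: keep them out of SR
            ok = [c for c in combos if "short_read" not in c]
            w = np.array([_SOURCE_COMBO_WEIGHTS[c] for c in ok])
            srcs = ok[rng.choice(len(ok), p=w / w.sum())].split(",")
        else:
            srcs = combos[rng.choice(len(combos), p=weights / weights.sum())].split(",")
        info["sources"] = sorted(srcs, key=("annotation", "short_read", "long_read").index)
        n_chains = 1
        novel_src = None
        if (
            not single
            and "annotation" in srcs
            and len(srcs) > 1
            and rng.random() < novel_isoform_prob
        ):
            novel_src = [s for s in info["sources"] if s != "annotation"][0]
            n_chains = 2
        info["n_chains"] = n_chains
        info["novel_src"] = novel_src
        for src in info["sources"]:
            tid = f"{gid}.{abbrev[src]}1"
            t_exons = exons
            t_strand = strand
            if src == "long_read" and rng.random() < lr_unknown_frac:
                truth.unknown_strand[tid] = strand
                t_strand = "."
            emitted = TranscriptModel(
                tid,
                gid,
                tuple(_iv(chrom, e.start, e.end, t_strand) for e in t_exons),
                src,
                "lncRNA" if src == "annotation" else "unknown",
            )
            {"annotation": annotation_set, "short_read": sr_set, "long_read": lr_set}[
                src
            ].append(emitted)
            if src != "annotation":
                coding_potential[tid] = "noncoding"
        if novel_src is not None:
            # variant chain: first exon shortened by 40 bp at its 3' boundary
            e0 = exons[0]
            variant = ( _iv(chrom, e0.start, e0.end - 40, strand),) + tuple(
                _iv(chrom, e.start, e.end, strand) for e in exons[1:]
            )
            tid = f"{gid}.{abbrev[novel_src]}2"
            emitted = TranscriptModel(tid, gid, variant, novel_src, "unknown")
            {"short_read": sr_set, "long_read": lr_set}[novel_src].append(emitted)
            coding_potential[tid] = "noncoding"

    # --- decoys for the filter cascade
    if with_decoys:
        def intron_of(idx: int) -> Tuple[TranscriptModel, Tuple[int, int]]:
            g = coding[idx]
            return g, max(g.introns, key=lambda se: se[1] - se[0])

        g, (istart, iend) = intron_of(decoy_hosts[0])  # too short (< 200 nt)
        e = _two_exon_chain(chrom, istart + 100, g.strand, rng, (50, 70), (80, 120), (50, 70))
        sr_set.append(TranscriptModel("DECOY.short", "DECOYG.short", e, "short_read"))
        coding_potential["DECOY.short"] = "noncoding"

        g, (istart, iend) = intron_of(decoy_hosts[1])  # single exon
        sr_set.append(
            TranscriptModel(
                "DECOY.single", "DECOYG.single",
                (_iv(chrom, istart + 100, istart + 600, g.strand),), "short_read",
            )
        )
        coding_potential["DECOY.single"] = "noncoding"

        g = coding[decoy_hosts[2]]  # overlaps a coding exon
        ex = g.exons[1]
        e = _two_exon_chain(chrom, ex.end - 30, g.strand, rng)
        sr_set.append(TranscriptModel("DECOY.exonov", "DECOYG.exonov", e, "short_read"))
        coding_potential["DECOY.exonov"] = "noncoding"

        g, (istart, iend) = intron_of(decoy_hosts[3])  # flagged coding potential
        e = _two_exon_chain(chrom, istart + 100, g.strand, rng)
        sr_set.append(TranscriptModel("DECOY.cp", "DECOYG.cp", e, "short_read"))
        coding_potential["DECOY.cp"] = "coding"

        g = coding[decoy_hosts[4]]  # shares an intron with a coding transcript
        donor, acceptor = g.introns[0]
        e = (
            _iv(chrom, donor - 100, donor, g.strand),
            _iv(chrom, acceptor, acceptor + 100, g.strand),
        )
        lr_set.append(TranscriptModel("DECOY.intron", "DECOYG.intron", e, "long_read"))
        coding_potential["DECOY.intron"] = "noncoding"

    # --- expected merge accounting
    for gid in sorted(lnc_chains):
        info = lnc_chains[gid]
        combo = source_string(info["sources"])
        truth.expected_gene_combos[combo] = truth.expected_gene_combos.get(combo, 0) + 1
        base_combo = combo
        truth.expected_transcript_combos[base_combo] = (
            truth.expected_transcript_combos.get(base_combo, 0) + 1
        )
        truth.expected_transcript_count += info["n_chains"]
        if info["novel_src"] is not None:
            truth.expected_transcript_combos[info["novel_src"]] = (
                truth.expected_transcript_combos.get(info["novel_src"], 0) + 1
            )
            truth.expected_novel_isoforms[info["novel_src"]] = (
                truth.expected_novel_isoforms.get(info["novel_src"], 0) + 1
            )
        truth.lnc_genes[gid] = {
            "start": min(e.start for e in info["exons"]),
            "end": max(e.end for e in info["exons"]),
            "strand": info["exons"][0].strand,
            "cls": info["cls"],
            "sources": info["sources"],
            "low_expressed": info["low"],
            "single_exon": info.get("single_exon", False),
        }
        if info["low"]:
            truth.low_expressed.append(gid)
        else:
            truth.class_counts[info["cls"]] = truth.class_counts.get(info["cls"], 0) + 1
    truth.expected_locus_count = len(lnc_chains)
    truth.expected_gated_count = len(lnc_chains) - len(truth.low_expressed)

    # nearest coding gene and boundary distance for each lncRNA (for cis planting)
    for gid, info in truth.lnc_genes.items():
        best = None
        for cg, cinfo in truth.coding_genes.items():
            if cinfo["start"] >= info["end"]:
                d = cinfo["start"] - info["end"]
            elif cinfo["end"] <= info["start"]:
                d = info["start"] - cinfo["end"]
            else:
                d = 0
            if best is None or (d, cg) < best:
                best = (d, cg)
        info["nearest_coding"], info["nearest_distance"] = best[1], best[0]

    return ToyGenome(
        coding_transcripts=coding,
        annotation_set=annotation_set,
        sr_set=sr_set,
        lr_set=lr_set,
        coding_potential=coding_potential,
        truth=truth,
    )


def make_toy_genome(
    outdir,
    n_coding: int = 30,
    n_lnc_per_class: int = 5,
    chrom_length: Optional[int] = None,
    seed: int = 0,
    **kwargs,
) -> ToyGenome:
    """Build the toy genome and write the three source GTFs plus sidecars.

    Emits ``annotation.gtf`` (coding + annotation lncRNAs), ``short_read.gtf``,
    ``long_read.gtf``, ``coding_potential.tsv`` and ``truth.json`` under
    ``outdir``. Same seed -> byte-identical files.
    """
    from .gtfio import write_gtf

    genome = build_toy_genome(
        n_coding=n_coding,
        n_lnc_per_class=n_lnc_per_class,
        chrom_length=chrom_length,
        seed=seed,
        **kwargs,
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(genome.coding_transcripts + genome.annotation_set, outdir / "annotation.gtf")
    write_gtf(genome.sr_set, outdir / "short_read.gtf")
    write_gtf(genome.lr_set, outdir / "long_read.gtf")
    with open(outdir / "coding_potential.tsv", "w") as fh:
        fh.write("transcript_id\tlabel\n")
        for tid in sorted(genome.coding_potential):
            fh.write(f"{tid}\t{genome.coding_potential[tid]}\n")
    genome.truth.to_json(outdir / "truth.json")
    return genome


def make_stranded_counts(
    truth: SyntheticTruth, depth: int = 200, bias: float = 0.9, seed: int = 0
) -> pd.DataFrame:
    """Stranded read counts for every strand-unknown long-read transcript.

    Each transcript gets ``depth`` reads, drawn binomially onto its true
    strand with success probability ``bias``.
    """
    if not (0.5 <= bias <= 1.0):
        raise ValueError("bias must lie in [0.5, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for tid in sorted(truth.unknown_strand):
        true = truth.unknown_strand[tid]
        on_true = int(rng.binomial(depth, bias))
        plus = on_true if true == "+" else depth - on_true
        rows.append({"transcript_id": tid, "plus_reads": plus, "minus_reads": depth - plus})
    return pd.DataFrame(rows, columns=["transcript_id", "plus_reads", "minus_reads"])


def _pick(rng, pool: List[str], k: int) -> List[str]:
    k = min(k, len(pool))
    chosen = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
    for g in chosen:
        pool.remove(g)
    return chosen


def make_expression(
    truth: SyntheticTruth,
    n_stages: int = 15,
    n_reps: int = 2,
    n_tissues: int = 15,
    seed: int = 0,
    noise_cv: float = 0.2,
    n_stage_specific: int = 6,
    n_constitutive: int = 5,
    n_cis: int = 6,
    n_trans_modules: int = 2,
    trans_codings_per_module: int = 4,
    retina_specific_frac: float = 0.5,
    latent_sd: float = 2.0,
) -> Tuple[ExpressionMatrix, ExpressionMatrix]:
    """Staged FPKM matrix and tissue-panel FPKM matrix with planted structure.

    Plants stage-specific genes (true tau = 1), constitutive genes (tau = 0),
    cis pairs (lncRNA + its nearest coding gene sharing a latent stage
    profile, population correlation >= 0.95 at the default noise), trans
    modules (one lncRNA + several distant coding genes per module) and
    retina-specific genes. Replicate noise is multiplicative log-normal with
    sigma = ``noise_cv``. The truth object is extended in place with the
    planted sets.
    """
    if n_stages < 2 or n_reps < 2:
        raise ValueError("need n_stages >= 2 and n_reps >= 2")
    rng = np.random.default_rng(seed)
    stages = (STAGE_LABELS + [f"S{i}" for i in range(len(STAGE_LABELS), n_stages)])[:n_stages]
    tissues = (TISSUE_LABELS + [f"T{i}" for i in range(len(TISSUE_LABELS), n_tissues)])[:n_tissues]
    truth.stages, truth.tissues = stages, tissues

    lnc_ids = sorted(truth.lnc_genes)
    coding_ids = sorted(truth.coding_genes)
    low = set(truth.low_expressed)
    lnc_pool = [g for g in lnc_ids if g not in low]
    coding_pool = list(coding_ids)

    n_s = len(stages)
    # latent per-stage log2-FPKM profiles
    profiles: Dict[str, np.ndarray] = {}
    for g in lnc_ids + coding_ids:
        level = max(np.log2(2.5), rng.normal(3.0, 0.7))
        profiles[g] = np.full(n_s, level)
    for g in sorted(low):
        profiles[g] = np.log2(np.full(n_s, rng.uniform(0.05, 0.3)))

    specific = _pick(rng, lnc_pool, n_stage_specific)
    for g in specific:
        stage = stages[int(rng.integers(n_s))]
        prof = np.full(n_s, -np.inf)  # expressed in exactly one stage: true tau = 1
        prof[stages.index(stage)] = 5.5
        profiles[g] = prof
        truth.stage_specific[g] = stage
    constitutive = _pick(rng, lnc_pool, n_constitutive)
    truth.constitutive = constitutive

    # cis pairs: lncRNA + its nearest coding gene (must be within 100 kb).
    # Partners must be distinct and unused — several lncRNAs can share one
    # nearest gene, and a coding gene can carry only one latent profile.
    cis_candidates = [
        g for g in lnc_pool if truth.lnc_genes[g]["nearest_distance"] <= 100_000
    ]
    rng.shuffle(cis_candidates)
    n_planted = 0
    for g in cis_candidates:
        if n_planted >= n_cis:
            break
        partner = truth.lnc_genes[g]["nearest_coding"]
        if partner not in coding_pool:
            continue
        coding_pool.remove(partner)
        lnc_pool.remove(g)
        z = rng.normal(3.5, latent_sd, size=n_s)
        profiles[g] = z.copy()
        profiles[partner] = z.copy()
        truth.cis_pairs.append([g, partner, truth.lnc_genes[g]["nearest_distance"]])
        n_planted += 1

    # trans modules: one lncRNA + several coding genes; a module must not
    # contain its own lncRNA's nearest coding gene (keeps cis/trans truth
    # disjoint: within-module correlations are trans edges only)
    for m in range(n_trans_modules):
        if not lnc_pool:
            break
        lnc_members = _pick(rng, lnc_pool, 1)
        own_nearest = {truth.lnc_genes[g]["nearest_coding"] for g in lnc_members}
        eligible = [g for g in coding_pool if g not in own_nearest]
        if len(eligible) < 2:
            break
        coding_members = _pick(rng, eligible, trans_codings_per_module)
        for g in coding_members:
            coding_pool.remove(g)
        z = rng.normal(3.5, latent_sd, size=n_s)
        module_id = f"T{m + 1}"
        for g in lnc_members + coding_members:
            profiles[g] = z.copy()
        truth.trans_modules[module_id] = {
            "lncs": lnc_members,
            "codings": coding_members,
        }
        for l in lnc_members:
            for c in coding_members:
                truth.trans_pairs.append([l, c])

    # staged FPKM with replicate noise
    order = lnc_ids + coding_ids
    cols, col_meta = [], []
    data = np.empty((len(order), n_s * n_reps))
    for si, stage in enumerate(stages):
        for rep in range(1, n_reps + 1):
            cols.append(f"{stage}_r{rep}")
            col_meta.append({"condition": stage, "replicate": rep})
    base = np.array([2.0 ** profiles[g] for g in order])  # genes x stages
    for si in range(n_s):
        for rep in range(n_reps):
            noise = np.exp(rng.normal(0.0, noise_cv, size=len(order)))
            data[:, si * n_reps + rep] = base[:, si] * noise
    staged = ExpressionMatrix(
        values=pd.DataFrame(data, index=order, columns=cols),
        samples=pd.DataFrame(col_meta, index=cols),
        unit="FPKM",
    )

    # tissue panel (one library per tissue, as in typical public panels)
    n_retina_specific = int(round(retina_specific_frac * len([g for g in lnc_ids if g not in low])))
    candidates = [g for g in lnc_ids if g not in low]
    retina_specific = sorted(
        candidates[i] for i in rng.choice(len(candidates), n_retina_specific, replace=False)
    )
    truth.retina_specific = retina_specific
    panel = np.empty((len(order), n_tissues))
    rs = set(retina_specific)
    for gi, g in enumerate(order):
        if g in rs or g in low:
            panel[gi] = rng.uniform(0.02, 0.3, size=n_tissues)
        elif g in truth.coding_genes:
            panel[gi] = 2.0 ** rng.normal(3.0, 0.7, size=n_tissues)
        else:
            k = int(rng.integers(1, 6))
            row = rng.uniform(0.02, 0.3, size=n_tissues)
            idx = rng.choice(n_tissues, size=k, replace=False)
            row[idx] = 2.0 ** rng.normal(2.5, 0.7, size=k) + 1.0
            panel[gi] = row
    tissue_cols = [f"{t}_r1" for t in tissues]
    tissue_matrix = ExpressionMatrix(
        values=pd.DataFrame(panel, index=order, columns=tissue_cols),
        samples=pd.DataFrame(
            [{"condition": t, "replicate": 1} for t in tissues], index=tissue_cols
        ),
        unit="FPKM",
    )
    return staged, tissue_matrix


def make_conservation_track(
    genome: "ToyGenome",
    seed: int = 0,
    coding_score: float = 0.9,
    lnc_score: float = 0.4,
    background_score: float = 0.1,
    jitter: float = 0.05,
    bin_size: int = 200,
) -> "ScoreTrack":
    """Per-base conservation track over the toy chromosome.

    Coding exons score high, lncRNA exons intermediate, everything else low
    — the rank structure expected of a vertebrate conservation track — with
    a little per-bin jitter. Scores stay in [0, 1].
    """
    from .models import ScoreTrack

    rng = np.random.default_rng(seed)
    truth = genome.truth
    length = truth.chrom_length
    base = np.full(length, background_score)
    for t in genome.annotation_set + genome.sr_set + genome.lr_set:
        for e in t.exons:
            base[e.start: e.end] = lnc_score
    for t in genome.coding_transcripts:
        for e in t.exons:
            base[e.start: e.end] = coding_score
    starts = np.arange(0, length, bin_size)
    ends = np.minimum(starts + bin_size, length)
    scores = np.empty(len(starts))
    for i, (s, e) in enumerate(zip(starts, ends)):
        scores[i] = np.clip(base[s:e].mean() + rng.normal(0, jitter), 0.0, 1.0)
    return ScoreTrack(data={truth.chrom: (starts, ends, scores)})


def make_term_map(
    truth: SyntheticTruth,
    target_genes: Sequence[str],
    enriched_term: str = "GO:PLANTED",
    n_background_terms: int = 8,
    term_prob: float = 0.15,
    seed: int = 0,
) -> Dict[str, List[str]]:
    """Gene -> term annotation map with one term enriched in ``target_genes``.

    The planted term annotates ~80% of the targets and ~5% of the rest;
    background terms annotate genes at a uniform rate, so only the planted
    term should test as enriched.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(truth.coding_genes)
    targets = set(target_genes)
    term_map: Dict[str, List[str]] = {}
    for g in genes:
        terms = [
            f"GO:{i:07d}" for i in range(n_background_terms) if rng.random() < term_prob
        ]
        p = 0.8 if g in targets else 0.05
        if rng.random() < p:
            terms.append(enriched_term)
        if terms:
            term_map[g] = terms
    return term_map


def make_mutant_counts(
    truth: Optional[SyntheticTruth],
    n_genes: Optional[int] = None,
    n_reps: int = 3,
    dispersion: float = 0.05,
    lfc_set: Sequence[float] = (),
    seed: int = 0,
    base_mean: Optional[float] = None,
    contrast: str = "mutant",
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, float]]:
    """WT and mutant NB count matrices with planted fold changes.

    With a truth object, genes are the planted lncRNA genes and the DE genes
    are drawn from the intergenic class (the only class tested downstream);
    otherwise ``n_genes`` synthetic genes are created and the first
    ``len(lfc_set)`` of them are DE. ``dispersion=0`` gives Poisson counts.
    Gene-wise WT means are log-normal around 100 unless ``base_mean`` pins
    them. Returns (wt, mut, {gene: true lfc}).
    """
    if n_reps < 2:
        raise ValueError("need n_reps >= 2")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    if truth is not None:
        genes = sorted(g for g in truth.lnc_genes if g not in set(truth.low_expressed))
        intergenic = [
            g for g in genes if truth.lnc_genes[g]["cls"] == "intergenic"
        ]
        de_genes = [
            intergenic[i]
            for i in rng.choice(len(intergenic), min(len(lfc_set), len(intergenic)), replace=False)
        ]
    else:
        if n_genes is None:
            raise ValueError("n_genes required without a truth object")
        genes = [f"G{i:05d}" for i in range(n_genes)]
        de_genes = genes[: len(lfc_set)]
    lfc_map = {g: float(lfc) for g, lfc in zip(de_genes, lfc_set)}

    if base_mean is None:
        means = np.exp(rng.normal(np.log(100.0), 1.0, size=len(genes)))
        means = np.clip(means, 5.0, 5000.0)
    else:
        means = np.full(len(genes), float(base_mean))
    mut_means = means * np.array([2.0 ** lfc_map.get(g, 0.0) for g in genes])

    def draw(mu: np.ndarray) -> np.ndarray:
        lam = np.tile(mu[:, None], (1, n_reps))
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=lam * dispersion)
        return rng.poisson(lam)

    wt = pd.DataFrame(
        draw(means), index=genes, columns=[f"WT_r{i+1}" for i in range(n_reps)]
    )
    mut = pd.DataFrame(
        draw(mut_means), index=genes, columns=[f"{contrast}_r{i+1}" for i in range(n_reps)]
    )
    if truth is not None:
        truth.de_truth[contrast] = lfc_map
    return wt, mut, lfc_map
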