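"""End-to-end workflow wiring: config, stage order, manifest, synthetic demo.

``run_all`` executes the stages in dependency order — identification cascade
(filter / strand / merge / expression gate), positional classification,
expression analytics, cis/trans regulation calling and differential
expression — reading only files named in the config and writing TSV/GTF/JSON
outputs plus a ``manifest.json`` of parameters and per-stage record counts.
Reruns with the same config are byte-identical: every stage is a pure
function of its inputs and the seed, and the manifest carries no timestamps.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import classify as _classify
from . import diffexpr as _diffexpr
from . import expression as _expression
from . import gtfio
from . import identify as _identify
from . import regulation as _regulation
from .models import ExpressionMatrix, GeneLocus, ValidationError


@dataclass
class PipelineConfig:
    """All inputs, outputs and thresholds of the end-to-end run."""

    annotation_gtf: str = ""
    short_read_gtf: str = ""
    long_read_gtf: str = ""
    stranded_counts: str = ""
    coding_potential: str = ""
    fpkm: str = ""
    fpkm_metadata: str = ""
    tissue_fpkm: str = ""
    tissue_metadata: str = ""
    contrasts: Dict[str, Dict[str, str]] = field(default_factory=dict)
    outdir: str = "retlnc_out"
    min_length: int = 200
    fold: float = 2.0
    alpha: float = 0.05
    fpkm_gate: float = 1.0
    gate_mode: str = "any_sample"
    window: int = 1000
    intronic_frac: float = 0.5
    max_dist: int = 100_000
    min_cor: float = 0.9
    cut_height: float = 0.1
    min_module_size: int = 3
    lfc: float = 1.0
    tau_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValidationError("fold must be >= 1")
        for name in ("alpha",):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must lie in (0, 1]")
        for name in ("min_length", "window", "max_dist", "min_module_size"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0 <= self.intronic_frac <= 1):
            raise ValidationError("intronic_frac must lie in [0, 1]")
        if not (0 <= self.min_cor <= 1):
            raise ValidationError("min_cor must lie in [0, 1]")
        if not (0 <= self.tau_threshold <= 1):
            raise ValidationError("tau_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _coding_loci_from(transcripts) -> List[GeneLocus]:
    by_gene: Dict[str, list] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return [
        GeneLocus(locus_id=g, transcripts=tuple(ts)) for g, ts in sorted(by_gene.items())
    ]


def run_all(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the manifest dict (also written)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    # manifest parameters keep file names only, so a rerun of the same
    # workflow rooted elsewhere produces byte-identical outputs
    params = dataclasses.asdict(config)
    for key, val in params.items():
        if key == "contrasts":
            params[key] = {
                name: {k: Path(v).name for k, v in paths.items()}
                for name, paths in val.items()
            }
        elif isinstance(val, str) and val and key != "gate_mode":
            params[key] = Path(val).name
    manifest: dict = {"parameters": params, "counts": {}}
    counts = manifest["counts"]

    # --- inputs
    annotation = gtfio.read_gtf(config.annotation_gtf, "annotation")
    coding = [t for t in annotation if t.biotype == "coding"]
    ann_lnc = [t for t in annotation if t.biotype == "lncRNA"]
    sr_raw = gtfio.read_gtf(config.short_read_gtf, "short_read")
    lr_raw = gtfio.read_gtf(config.long_read_gtf, "long_read")
    cp = pd.read_csv(config.coding_potential, sep="\t")
    coding_potential = dict(zip(cp["transcript_id"], cp["label"]))
    counts["input_annotation_lnc_transcripts"] = len(ann_lnc)
    counts["input_short_read_transcripts"] = len(sr_raw)
    counts["input_long_read_transcripts"] = len(lr_raw)

    # --- identification cascade
    sr_kept = _identify.filter_short_read_set(
        sr_raw, coding, coding_potential, min_length=config.min_length
    )
    stranded = pd.read_csv(config.stranded_counts, sep="\t")
    calls = _identify.assign_strands(
        list(stranded.itertuples(index=False, name=None)),
        fold_threshold=config.fold,
        alpha=config.alpha,
    )
    lr_kept = _identify.filter_long_read_set(lr_raw, calls, coding)
    loci, report = _identify.merge_sources(ann_lnc, sr_kept, lr_kept)
    counts["short_read_kept"] = len(sr_kept)
    counts["long_read_kept"] = len(lr_kept)
    counts["strand_assigned"] = sum(
        1 for c in calls.values() if c.assigned_strand != "unassigned"
    )
    counts["merged_loci"] = report.n_loci
    counts["merged_transcripts"] = report.n_transcripts
    manifest["merge_report"] = {
        "gene_combos": dict(sorted(report.gene_combo_counts.items())),
        "transcript_combos": dict(sorted(report.transcript_combo_counts.items())),
        "novel_isoforms": dict(sorted(report.novel_isoforms_by_source.items())),
        "annotation_backed_loci": report.n_annotation_backed_loci,
    }
    pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "plus_reads": c.plus_reads,
                "minus_reads": c.minus_reads,
                "fold": c.fold,
                "chi2": c.chi2,
                "p_value": c.p_value,
                "assigned_strand": c.assigned_strand,
            }
            for c in calls.values()
        ]
    ).to_csv(out / "strand_calls.tsv", sep="\t", index=False)

    # --- locus-level FPKM (source gene ids -> merged locus ids)
    fpkm_genes = gtfio.read_matrix(config.fpkm, "FPKM", config.fpkm_metadata)
    locus_gene: Dict[str, str] = {}
    for locus in loci:
        gene_ids = sorted({t.gene_id for t in locus.transcripts})
        locus_gene[locus.locus_id] = gene_ids[0]
    missing = [g for g in locus_gene.values() if g not in fpkm_genes.values.index]
    if missing:
        raise ValidationError(f"FPKM matrix lacks locus gene(s) {missing[:5]}")
    lnc_fpkm_vals = fpkm_genes.values.loc[[locus_gene[l.locus_id] for l in loci]]
    lnc_fpkm_vals.index = [l.locus_id for l in loci]
    lnc_fpkm = ExpressionMatrix(lnc_fpkm_vals, fpkm_genes.samples, "FPKM")

    gated = _identify.expression_gate(
        loci, lnc_fpkm, threshold=config.fpkm_gate, mode=config.gate_mode
    )
    counts["gated_loci"] = len(gated)

    # --- classification
    results, summary = _classify.classify_all(
        gated,
        coding,
        window=config.window,
        intronic_frac=config.intronic_frac,
    )
    class_of = {r.locus_id: r.positional_class for r in results}
    gated = [l.with_class(class_of[l.locus_id]) for l in gated]
    gtfio.write_gtf(gated, out / "merged.gtf")
    gtfio.write_bed6(gated, out / "merged.bed")
    pd.DataFrame(
        [
            {
                "locus_id": r.locus_id,
                "class": r.positional_class,
                "nearest_gene": r.nearest_coding_gene_id,
                "distance": r.signed_distance,
                "overlap_bases": r.overlap_bases,
                "intronic_fraction": r.intronic_fraction,
            }
            for r in results
        ]
    ).to_csv(out / "classes.tsv", sep="\t", index=False)
    counts["classes"] = dict(sorted(summary.items()))

    # --- expression analytics over the gated loci
    gated_ids = [l.locus_id for l in gated]
    gfpkm = lnc_fpkm.subset_genes(gated_ids)
    spec = _expression.specificity_table(gfpkm, threshold=config.tau_threshold)
    spec.to_csv(out / "specificity.tsv", sep="\t", index_label="locus_id")
    calls_tbl = _expression.expressed_calls(gfpkm, threshold=config.fpkm_gate)
    sharing = _expression.stage_sharing(calls_tbl)
    sharing.shared_counts.to_csv(out / "stage_shared_counts.tsv", sep="\t")
    pd.DataFrame(
        {
            "expressed": sharing.stage_counts,
            "novel": sharing.cumulative_novel,
            "cumulative": sharing.cumulative_total,
        }
    ).to_csv(out / "stage_accumulation.tsv", sep="\t", index_label="stage")
    structure = _expression.correlation_structure(gfpkm, method="spearman")
    structure.correlation.to_csv(out / "sample_correlation.tsv", sep="\t")
    structure.pca_scores.iloc[:, :2].to_csv(out / "pca_scores.tsv", sep="\t")
    counts["tau_specific"] = int(spec["is_specific"].sum())

    if config.tissue_fpkm:
        panel_genes = gtfio.read_matrix(config.tissue_fpkm, "FPKM", config.tissue_metadata)
        panel_vals = panel_genes.values.reindex(
            [locus_gene[l] for l in gated_ids]
        ).dropna()
        panel_vals.index = [l for l in gated_ids if locus_gene[l] in panel_genes.values.index]
        panel = ExpressionMatrix(panel_vals, panel_genes.samples, "FPKM")
        tissue = _expression.tissue_specificity(gfpkm, panel)
        tissue.to_csv(out / "tissue_specificity.tsv", sep="\t", index_label="locus_id")
        counts["retina_specific"] = int(tissue["retina_specific"].sum())

    # --- cis/trans regulation
    coding_loci = _coding_loci_from(coding)
    coding_ids = [l.locus_id for l in coding_loci]
    combined_vals = pd.concat(
        [gfpkm.values, fpkm_genes.values.loc[[g for g in coding_ids if g in fpkm_genes.values.index]]]
    )
    combined = ExpressionMatrix(combined_vals, fpkm_genes.samples, "FPKM")
    modules = _regulation.detect_modules(
        combined, min_module_size=config.min_module_size, cut_height=config.cut_height
    )
    pd.Series(modules, name="module").sort_index().to_csv(
        out / "modules.tsv", sep="\t", index_label="gene_id"
    )
    cis_calls = _regulation.call_cis(
        gated, coding_loci, combined,
        max_dist=config.max_dist, min_cor=config.min_cor, alpha=config.alpha,
    )
    trans_calls = _regulation.call_trans(
        gated_ids,
        [g for g in coding_ids if g in combined.values.index],
        combined, modules, min_cor=config.min_cor,
    )
    for name, calls_ in (("cis", cis_calls), ("trans", trans_calls)):
        pd.DataFrame(
            [
                {
                    "lnc_id": c.lnc_id,
                    "target": c.target_gene_id,
                    "cor": c.cor,
                    "p_value": c.p_value,
                    "distance": c.distance,
                    "module": c.module_id,
                }
                for c in calls_
            ],
            columns=["lnc_id", "target", "cor", "p_value", "distance", "module"],
        ).to_csv(out / f"regulation_{name}.tsv", sep="\t", index=False)
    counts["cis_calls"] = len(cis_calls)
    counts["trans_calls"] = len(trans_calls)

    # --- differential expression per mutant contrast (intergenic loci only)
    gene_locus = {g: l for l, g in locus_gene.items()}
    contrast_tables: Dict[str, pd.DataFrame] = {}
    for name in sorted(config.contrasts):
        paths = config.contrasts[name]
        wt = pd.read_csv(paths["wt"], sep="\t", index_col=0)
        mut = pd.read_csv(paths["mut"], sep="\t", index_col=0)
        keep = [g for g in wt.index if g in gene_locus]
        wt, mut = wt.loc[keep], mut.loc[keep]
        wt.index = mut.index = [gene_locus[g] for g in keep]
        de = _diffexpr.nb_test(wt, mut, lfc_threshold=config.lfc, alpha=config.alpha)
        de_lincs = _diffexpr.de_intergenic(de, class_of)
        de_lincs.to_csv(out / f"de_{name}.tsv", sep="\t", index_label="locus_id")
        contrast_tables[name] = de_lincs
        counts[f"de_{name}"] = int(de_lincs["is_de"].sum())
    if len(contrast_tables) >= 2:
        summary_tbl = _diffexpr.cross_mutant_summary(
            {k: v[v["is_de"]] for k, v in contrast_tables.items()}
        )
        summary_tbl.to_csv(out / "de_summary.tsv", sep="\t", index_label="locus_id")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def run_demo(outdir, seed: int = 7, n_coding: int = 40, n_lnc_per_class: int = 5) -> dict:
    """Generate a complete synthetic input set, run the pipeline on it, and
    verify the manifest against the planted truth.

    The demo writes inputs under ``outdir/inputs`` and outputs under
    ``outdir/outputs``; the manifest gains a ``truth_comparison`` section
    whose entries are True when the pipeline recovered the planted totals
    (merged loci and transcripts, source combinations, per-class counts,
    strand assignments, expression-gate survivors).
    """
    from . import synthetic

    outdir = Path(outdir)
    inputs = outdir / "inputs"
    genome = synthetic.make_toy_genome(
        inputs, n_coding=n_coding, n_lnc_per_class=n_lnc_per_class,
        seed=seed, n_single_exon=2,
    )
    truth = genome.truth
    stranded = synthetic.make_stranded_counts(truth, depth=200, bias=0.9, seed=seed + 1)
    stranded.to_csv(inputs / "stranded_counts.tsv", sep="\t", index=False)
    staged, panel = synthetic.make_expression(truth, seed=seed + 2)
    gtfio.write_matrix(staged, inputs / "fpkm.tsv", inputs / "fpkm_meta.tsv")
    gtfio.write_matrix(panel, inputs / "tissue_fpkm.tsv", inputs / "tissue_meta.tsv")
    contrasts = {}
    for i, name in enumerate(["mutantA", "mutantB"]):
        wt, mut, _ = synthetic.make_mutant_counts(
            truth, n_reps=3, dispersion=0.05, lfc_set=[2.0, -2.0, 2.0],
            seed=seed + 10 + i, contrast=name,
        )
        wt.to_csv(inputs / f"{name}_wt.tsv", sep="\t", index_label="gene_id")
        mut.to_csv(inputs / f"{name}_mut.tsv", sep="\t", index_label="gene_id")
        contrasts[name] = {
            "wt": str(inputs / f"{name}_wt.tsv"),
            "mut": str(inputs / f"{name}_mut.tsv"),
        }
    truth.to_json(inputs / "truth.json")

    config = PipelineConfig(
        annotation_gtf=str(inputs / "annotation.gtf"),
        short_read_gtf=str(inputs / "short_read.gtf"),
        long_read_gtf=str(inputs / "long_read.gtf"),
        stranded_counts=str(inputs / "stranded_counts.tsv"),
        coding_potential=str(inputs / "coding_potential.tsv"),
        fpkm=str(inputs / "fpkm.tsv"),
        fpkm_metadata=str(inputs / "fpkm_meta.tsv"),
        tissue_fpkm=str(inputs / "tissue_fpkm.tsv"),
        tissue_metadata=str(inputs / "tissue_meta.tsv"),
        contrasts=contrasts,
        outdir=str(outdir / "outputs"),
        seed=seed,
    )
    manifest = run_all(config)

    strand_ok = all(
        row.assigned == truth.unknown_strand[row.Index]
        for row in pd.read_csv(
            Path(config.outdir) / "strand_calls.tsv", sep="\t", index_col=0
        )
        .rename(columns={"assigned_strand": "assigned"})
        .itertuples()
    )
    comparison = {
        "merged_loci": manifest["counts"]["merged_loci"] == truth.expected_locus_count,
        "merged_transcripts": manifest["counts"]["merged_transcripts"]
        == truth.expected_transcript_count,
        "gene_combos": manifest["merge_report"]["gene_combos"]
        == dict(sorted(truth.expected_gene_combos.items())),
        "transcript_combos": manifest["merge_report"]["transcript_combos"]
        == dict(sorted(truth.expected_transcript_combos.items())),
        "novel_isoforms": manifest["merge_report"]["novel_isoforms"]
        == dict(sorted(truth.expected_novel_isoforms.items())),
        "gated_loci": manifest["counts"]["gated_loci"] == truth.expected_gated_count,
        "class_counts": manifest["counts"]["classes"]
        == dict(sorted(truth.class_counts.items())),
        "strand_assignments": strand_ok,
    }
    manifest["truth_comparison"] = comparison
    (Path(config.outdir) / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
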