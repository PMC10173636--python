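"""Cis/trans target calling from co-expression, module detection and term enrichment.

A cis-target is the single nearest coding gene within 100 kb of a lncRNA
locus whose expression correlates strongly with it (Pearson r >= 0.9,
p <= 0.05). A trans-target is any coding gene with r >= 0.9 that falls in
the same co-expression module as the lncRNA; modules come from
average-linkage hierarchical clustering of genes on 1 - |r| distance with a
fixed-height tree cut, the co-membership contract a full weighted-network
pipeline would provide. Correlations are computed on log2(FPKM+1) by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .models import ExpressionMatrix, GeneLocus

BACKGROUND_MODULE = "M0"


@dataclass(frozen=True)
class RegulationCall:
    lnc_id: str
    target_gene_id: str
    mode: str  # "cis" or "trans"
    cor: float
    p_value: float
    distance: Optional[int] = None  # cis only: bp between closest span boundaries
    module_id: Optional[str] = None  # trans only


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson r with the two-sided t-test p-value.

    p is derived from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom. Zero variance in either vector yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson_with_p needs equal-length 1-d vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    xd, yd = x - x.mean(), y - y.mean()
    sx = float(xd @ xd)
    sy = float(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        return float("nan"), float("nan")
    r = float(xd @ yd / np.sqrt(sx * sy))
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p


def _log_values(fpkm: ExpressionMatrix, transform: str) -> pd.DataFrame:
    if transform == "log2":
        return np.log2(fpkm.values + 1.0)
    if transform == "raw":
        return fpkm.values
    raise ValueError(f"unknown transform {transform!r}")


def detect_modules(
    fpkm: ExpressionMatrix,
    min_module_size: int = 3,
    cut_height: float = 0.1,
    transform: str = "log2",
) -> Dict[str, str]:
    """Assign each gene a co-expression module id.

    Genes are clustered by average linkage on 1 - |Pearson r| and the tree is
    cut at ``cut_height``; clusters smaller than ``min_module_size`` fall
    into the background module ``M0``. The default cut of 0.1 mirrors the
    r >= 0.9 correlation threshold of the downstream target calls (module
    co-membership then demands the same strength of co-expression), keeping
    unrelated but moderately correlated gene groups apart. Module ids ``M1, M2, ...`` are ordered
    by decreasing size, then by first member for determinism.
    """
    vals = _log_values(fpkm, transform).to_numpy()
    genes = list(fpkm.values.index)
    if len(genes) < min_module_size or vals.shape[1] < 3:
        return {g: BACKGROUND_MODULE for g in genes}
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(vals)
    r = np.nan_to_num(r, nan=0.0)  # constant genes correlate with nothing
    dist = 1.0 - np.abs(r)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    clusters: Dict[int, List[str]] = {}
    for gene, lab in zip(genes, labels):
        clusters.setdefault(int(lab), []).append(gene)
    keep = [
        members for members in clusters.values() if len(members) >= min_module_size
    ]
    keep.sort(key=lambda ms: (-len(ms), ms[0]))
    assignment = {g: BACKGROUND_MODULE for g in genes}
    for i, members in enumerate(keep, start=1):
        for g in members:
            assignment[g] = f"M{i}"
    return assignment


def nearest_coding_gene(
    lnc_loci: Sequence[GeneLocus], coding_loci: Sequence[GeneLocus]
) -> Dict[str, Tuple[str, int]]:
    """Map each lncRNA locus to (nearest coding locus id, distance in bp).

    Distance is between closest span boundaries, 0 when overlapping; ties go
    to the smaller distance then lexicographic id. Both directions are
    considered; lncRNAs on chromosomes without coding genes are omitted.
    """
    by_chrom: Dict[str, List[GeneLocus]] = {}
    for c in coding_loci:
        by_chrom.setdefault(c.chrom, []).append(c)
    out: Dict[str, Tuple[str, int]] = {}
    for lnc in lnc_loci:
        best: Optional[Tuple[int, str]] = None
        for c in by_chrom.get(lnc.chrom, []):
            d = lnc.span.gap_to(c.span)
            if best is None or (d, c.locus_id) < best:
                best = (d, c.locus_id)
        if best is not None:
            out[lnc.locus_id] = (best[1], best[0])
    return out


def call_cis(
    lnc_loci: Sequence[GeneLocus],
    coding_loci: Sequence[GeneLocus],
    fpkm: ExpressionMatrix,
    max_dist: int = 100_000,
    min_cor: float = 0.9,
    alpha: float = 0.05,
    transform: str = "log2",
) -> List[RegulationCall]:
    """Cis-regulation calls: nearest coding gene within ``max_dist`` whose
    expression satisfies r >= ``min_cor`` and p <= ``alpha``.

    Only the single nearest coding gene per lncRNA is a candidate; p-values
    are raw (no multiple-testing correction), matching the decision rule the
    analysis thresholds.
    """
    vals = _log_values(fpkm, transform)
    calls: List[RegulationCall] = []
    for lnc_id, (gene_id, dist) in nearest_coding_gene(lnc_loci, coding_loci).items():
        if dist > max_dist:
            continue
        if lnc_id not in vals.index or gene_id not in vals.index:
            continue
        r, p = pearson_with_p(vals.loc[lnc_id], vals.loc[gene_id])
        if np.isnan(r):
            continue
        if r >= min_cor and p <= alpha:
            calls.append(RegulationCall(lnc_id, gene_id, "cis", r, p, distance=dist))
    return calls


def call_trans(
    lnc_ids: Sequence[str],
    coding_ids: Sequence[str],
    fpkm: ExpressionMatrix,
    modules: Dict[str, str],
    min_cor: float = 0.90,
    transform: str = "log2",
) -> List[RegulationCall]:
    """Trans-regulation calls: all (lncRNA, coding) pairs with r >= ``min_cor``
    sharing the same non-background module."""
    missing = [g for g in list(lnc_ids) + list(coding_ids) if g not in modules]
    if missing:
        raise ValueError(f"modules must cover every gene; missing {missing[:5]}")
    vals = _log_values(fpkm, transform)
    by_module: Dict[str, Tuple[List[str], List[str]]] = {}
    for g in lnc_ids:
        m = modules[g]
        if m != BACKGROUND_MODULE:
            by_module.setdefault(m, ([], []))[0].append(g)
    for g in coding_ids:
        m = modules[g]
        if m != BACKGROUND_MODULE:
            by_module.setdefault(m, ([], []))[1].append(g)
    calls: List[RegulationCall] = []
    for module_id in sorted(by_module):
        lncs, codings = by_module[module_id]
        for lnc in lncs:
            for gene in codings:
                r, p = pearson_with_p(vals.loc[lnc], vals.loc[gene])
                if not np.isnan(r) and r >= min_cor:
                    calls.append(
                        RegulationCall(lnc, gene, "trans", r, p, module_id=module_id)
                    )
    return calls


def enrich_terms(
    target_set: Sequence[str],
    background: Sequence[str],
    term_map: Dict[str, Sequence[str]],
    bh: bool = False,
) -> pd.DataFrame:
    """Chi-square term enrichment of a target gene set against a background.

    For each term, the 2x2 table (in/out of target x with/without term) gets
    an uncorrected chi-square with df=1; raw p-values are reported, sorted
    ascending, with an optional Benjamini-Hochberg column. Terms only
    annotated outside the background are skipped with a warning.
    """
    background = list(dict.fromkeys(background))
    bg = set(background)
    targets = set(target_set)
    if not targets <= bg:
        raise ValueError("target_set must be a subset of background")
    term_genes: Dict[str, set] = {}
    skipped = set()
    for gene, terms in term_map.items():
        for term in terms:
            if gene in bg:
                term_genes.setdefault(term, set()).add(gene)
            else:
                skipped.add(term)
    for term in sorted(skipped - set(term_genes)):
        warnings.warn(f"term {term!r} only annotates genes outside background; skipped", stacklevel=2)
    n = len(bg)
    n_t = len(targets)
    rows = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        a = len(genes & targets)  # target, with term
        b = n_t - a  # target, without term
        c = len(genes) - a  # non-target, with term
        d = n - n_t - c
        num = n * (a * d - b * c) ** 2
        den = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = num / den if den else 0.0
        p = float(stats.chi2.sf(chi2, df=1)) if den else 1.0
        rows.append(
            {
                "term": term,
                "target_with_term": a,
                "target_without_term": b,
                "background_with_term": c,
                "background_without_term": d,
                "chi2": chi2,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term",
            "target_with_term",
            "target_without_term",
            "background_with_term",
            "background_without_term",
            "chi2",
            "p_value",
        ],
    )
    if len(out):
        out = out.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
        if bh:
            out["p_bh"] = stats.false_discovery_control(out["p_value"], method="bh")
    elif bh:
        out["p_bh"] = pd.Series(dtype=float)
    if not len(targets):
        out = out.iloc[0:0]
    return out
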