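"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive (per-base masks, explicit loops, exact
distributions) and shares no code with the implementation under test.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats


def per_base_classify(
    lnc_span: Tuple[int, int],
    lnc_strand: str,
    lnc_exons: Sequence[Tuple[int, int]],
    coding_genes: Sequence[dict],
    genome_length: int,
    window: int = 1000,
    intronic_frac: float = 0.5,
    antisense_min_overlap: int = 1,
) -> str:
    """Classify one lncRNA locus by brute force over per-base boolean masks.

    ``coding_genes`` entries: {"start", "end", "strand", "exons": [(s, e)]}.
    Mirrors the documented precedence: antisense > intronic > divergent/
    convergent > intergenic, with distances measured between span
    boundaries and an inclusive <= window rule.
    """
    L = genome_length
    lnc_mask = np.zeros(L, dtype=bool)
    lnc_mask[lnc_span[0]: lnc_span[1]] = True
    exon_mask = np.zeros(L, dtype=bool)
    for s, e in lnc_exons:
        exon_mask[s:e] = True

    opp_body = np.zeros(L, dtype=bool)
    same_intron = np.zeros(L, dtype=bool)
    for g in coding_genes:
        body = np.zeros(L, dtype=bool)
        body[g["start"]: g["end"]] = True
        gene_exons = np.zeros(L, dtype=bool)
        for s, e in g["exons"]:
            gene_exons[s:e] = True
        if g["strand"] != lnc_strand:
            opp_body |= body
        else:
            same_intron |= body & ~gene_exons

    if int((lnc_mask & opp_body).sum()) >= antisense_min_overlap:
        return "antisense"
    exonic_total = int(exon_mask.sum())
    if exonic_total and (exon_mask & same_intron).sum() / exonic_total >= intronic_frac:
        return "intronic"

    best: Optional[Tuple[int, str, str]] = None  # (distance, gene_id, strand)
    for g in coding_genes:
        if g["start"] >= lnc_span[1]:
            d = g["start"] - lnc_span[1]
        elif g["end"] <= lnc_span[0]:
            d = lnc_span[0] - g["end"]
        else:
            d = 0
        key = (d, g["gene_id"])
        if best is None or key < (best[0], best[1]):
            best = (d, g["gene_id"], g["strand"])
    if best is None or best[0] > window:
        return "intergenic"
    return "divergent" if best[2] != lnc_strand else "convergent"


def tau_reference(profile: Sequence[float]) -> float:
    """Direct evaluation of Yanai's formula with an explicit loop."""
    xs = list(float(v) for v in profile)
    m = max(xs)
    if m == 0:
        return float("nan")
    total = 0.0
    for v in xs:
        total += 1.0 - v / m
    return total / (len(xs) - 1)


def binomial_strand_p(plus: int, minus: int) -> float:
    """Exact two-sided binomial test of an equal strand split."""
    n = plus + minus
    if n == 0:
        return 1.0
    return float(stats.binomtest(plus, n, 0.5, alternative="two-sided").pvalue)


def median_of_ratios_reference(counts: np.ndarray) -> np.ndarray:
    """Loop implementation of median-of-ratios size factors."""
    n_genes, n_samples = counts.shape
    log_geo = []
    usable = []
    for i in range(n_genes):
        row = counts[i]
        if all(v > 0 for v in row):
            usable.append(i)
            log_geo.append(sum(np.log(v) for v in row) / n_samples)
    factors = np.empty(n_samples)
    for j in range(n_samples):
        ratios = [np.log(counts[i, j]) - lg for i, lg in zip(usable, log_geo)]
        factors[j] = np.exp(np.median(ratios))
    return factors


def sharing_reference(table: np.ndarray) -> dict:
    """Set-algebra stage sharing on a genes x stages boolean matrix."""
    n_stages = table.shape[1]
    sets = [set(np.flatnonzero(table[:, j])) for j in range(n_stages)]
    shared = np.array(
        [[len(sets[i] & sets[j]) for j in range(n_stages)] for i in range(n_stages)]
    )
    novel, total = [], []
    seen: set = set()
    for j in range(n_stages):
        novel.append(len(sets[j] - seen))
        seen |= sets[j]
        total.append(len(seen))
    return {
        "counts": np.array([len(s) for s in sets]),
        "shared": shared,
        "novel": np.array(novel),
        "total": np.array(total),
    }


def chi2_2x2_reference(a: int, b: int, c: int, d: int) -> float:
    """Uncorrected chi-square of a 2x2 table via the closed product formula."""
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / den


def random_toy_instance(rng: np.random.Generator, max_genes: int = 50) -> dict:
    """A random classification instance: coding genes + lncRNA loci that may
    overlap anything, on a small chromosome."""
    length = int(rng.integers(20_000, 60_000))
    n_coding = int(rng.integers(1, max(2, max_genes // 2)))
    genes = []
    for i in range(n_coding):
        start = int(rng.integers(0, length - 3000))
        end = start + int(rng.integers(500, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 4))
        bounds = sorted(rng.choice(np.arange(start, end + 1), 2 * n_ex, replace=False))
        exons = []
        for k in range(n_ex):
            s, e = int(bounds[2 * k]), int(bounds[2 * k + 1])
            if e > s:
                exons.append((s, e))
        if not exons:
            exons = [(start, end)]
        exons[0] = (start, exons[0][1])
        exons[-1] = (exons[-1][0], end)
        genes.append(
            {"gene_id": f"PC{i:03d}", "start": start, "end": end, "strand": strand, "exons": exons}
        )
    n_lnc = int(rng.integers(1, max_genes - n_coding + 1))
    lncs = []
    for i in range(n_lnc):
        start = int(rng.integers(0, length - 2000))
        end = start + int(rng.integers(300, 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        mid_lo = start + (end - start) // 3
        mid_hi = start + 2 * (end - start) // 3
        if mid_hi - mid_lo >= 2 and rng.random() < 0.7:
            exons = [(start, mid_lo), (mid_hi, end)]
        else:
            exons = [(start, end)]
        lncs.append(
            {"lnc_id": f"LNC{i:03d}", "start": start, "end": end, "strand": strand, "exons": exons}
        )
    return {"length": length, "coding": genes, "lnc": lncs}
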