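"""Call cis- and trans-regulated coding targets of lncRNAs from co-expression.

A cis target is the nearest coding gene within 100 kb whose expression
correlates with the lncRNA at r >= 0.9 (p <= 0.05). A trans target is any
coding gene with r >= 0.9 sharing the lncRNA's co-expression module
(average-linkage clustering on 1 - |r|, tree cut 0.1).
"""

from retlnc import build_toy_genome, call_cis, call_trans, detect_modules, make_expression
from retlnc.models import GeneLocus, GenomicInterval, TranscriptModel

genome = build_toy_genome(seed=7, n_coding=60, n_lnc_per_class=10)
truth = genome.truth
staged, _ = make_expression(truth, seed=8, n_cis=10, n_trans_modules=3)


def locus(gid, info, biotype="unknown"):
    iv = GenomicInterval(truth.chrom, info["start"], info["end"], info["strand"])
    return GeneLocus(gid, (TranscriptModel(f"{gid}.t", gid, (iv,), "annotation", biotype),))


lnc_loci = [locus(g, i) for g, i in sorted(truth.lnc_genes.items())]
coding_loci = [locus(g, i, "coding") for g, i in sorted(truth.coding_genes.items())]

cis = call_cis(lnc_loci, coding_loci, staged)
truth_cis = {(a, b) for a, b, _d in truth.cis_pairs}
got = {(c.lnc_id, c.target_gene_id) for c in cis}
print(f"cis calls: {len(cis)} (planted {len(truth_cis)}, "
      f"recovered {len(got & truth_cis)})")
c = cis[0]
print(f"  e.g. {c.lnc_id} -> {c.target_gene_id}: {c.distance} bp apart, "
      f"r = {c.cor:.3f}, p = {c.p_value:.2e}")

modules = detect_modules(staged)
n_modules = len(set(modules.values()) - {"M0"})
print(f"\nco-expression modules detected: {n_modules} "
      f"(planted {len(truth.trans_modules)})")

trans = call_trans(sorted(truth.lnc_genes), sorted(truth.coding_genes), staged, modules)
truth_trans = {(a, b) for a, b in truth.trans_pairs}
got_t = {(c.lnc_id, c.target_gene_id) for c in trans}
print(f"trans calls: {len(trans)} (planted {len(truth_trans)}, "
      f"recovered {len(got_t & truth_trans)})")
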