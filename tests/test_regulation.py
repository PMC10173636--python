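"""Correlation statistics, module detection, cis/trans calling, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retlnc.regulation import (
    call_cis,
    call_trans,
    detect_modules,
    enrich_terms,
    nearest_coding_gene,
    pearson_with_p,
)

from conftest import make_locus, make_matrix
from oracles import chi2_2x2_reference


class TestPearsonWithP:
    def test_affine_identity(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and p == 0.0

    def test_orthogonal_vectors(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0])
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_oracle_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + rng.uniform(-1, 1) * x
            r, p = pearson_with_p(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_flagged(self):
        r, p = pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r) and np.isnan(p)

    def test_rejects_short_or_mismatched(self):
        with pytest.raises(ValueError):
            pearson_with_p([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pearson_with_p([1.0, 2.0, 3.0], [1.0, 2.0])


def block_matrix(rng, n_blocks=2, block_size=5, n_noise=10, n_samples=12, noise=0.05):
    """Genes x samples matrix with planted perfectly-co-expressed blocks."""
    rows, labels, idx = [], {}, 0
    for b in range(n_blocks):
        profile = rng.normal(3.0, 2.0, size=n_samples)
        for _ in range(block_size):
            rows.append(2.0 ** (profile + rng.normal(0, noise, size=n_samples)))
            labels[f"g{idx}"] = f"B{b}"
            idx += 1
    for _ in range(n_noise):
        rows.append(2.0 ** rng.normal(3.0, 0.2, size=n_samples))
        labels[f"g{idx}"] = "noise"
        idx += 1
    em = make_matrix(np.array(rows), index=[f"g{i}" for i in range(idx)])
    return em, labels


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(10)
        em, labels = block_matrix(rng)
        modules = detect_modules(em)
        block_mods = {}
        for g, lab in labels.items():
            if lab.startswith("B"):
                block_mods.setdefault(lab, set()).add(modules[g])
        assert all(len(v) == 1 for v in block_mods.values())
        assert block_mods["B0"] != block_mods["B1"]
        assert "M0" not in {m for v in block_mods.values() for m in v}

    def test_independent_genes_all_background(self):
        rng = np.random.default_rng(11)
        em, labels = block_matrix(rng, n_blocks=0, n_noise=20)
        modules = detect_modules(em)
        assert set(modules.values()) == {"M0"}

    def test_duplicated_rows_share_a_module(self):
        rng = np.random.default_rng(12)
        base = 2.0 ** rng.normal(3, 2, size=10)
        em = make_matrix(np.array([base, base, base]), index=["a", "b", "c"])
        modules = detect_modules(em)
        assert modules["a"] == modules["b"] == modules["c"] != "M0"

    def test_fewer_genes_than_module_size_all_background(self):
        rng = np.random.default_rng(13)
        em = make_matrix(rng.uniform(1, 10, size=(2, 8)), index=["a", "b"])
        assert set(detect_modules(em, min_module_size=3).values()) == {"M0"}


def _regulation_fixture(distance):
    """One lncRNA at a configurable distance from one coding gene, plus a
    decoy coding gene far away."""
    lnc = make_locus("L1", exons=((100_000, 100_500), (100_800, 101_200)))
    near = make_locus("PCnear",
                      exons=((101_200 + distance, 102_300 + distance),),
                      source="annotation", biotype="coding")
    far = make_locus("PCfar", exons=((900_000, 905_000),),
                     source="annotation", biotype="coding")
    return lnc, [near, far]


class TestCallCis:
    def em(self, r_target):
        rng = np.random.default_rng(20)
        x = rng.normal(4, 2, size=12)
        noise_sd = 0.0 if r_target >= 1 else 2.0 * np.sqrt(1 / r_target**2 - 1)
        y = x + rng.normal(0, noise_sd, size=12)
        z = rng.normal(4, 2, size=12)
        return make_matrix(2.0 ** np.array([x, y, z]),
                           index=["L1", "PCnear", "PCfar"])

    def test_near_correlated_pair_called(self):
        lnc, coding = _regulation_fixture(50_000)
        calls = call_cis([lnc], coding, self.em(0.99))
        assert len(calls) == 1
        call = calls[0]
        assert (call.lnc_id, call.target_gene_id) == ("L1", "PCnear")
        assert call.distance == 50_000 and call.cor >= 0.9 and call.p_value <= 0.05

    def test_distance_gate(self):
        lnc, coding = _regulation_fixture(150_000)
        assert call_cis([lnc], coding, self.em(0.99)) == []

    def test_correlation_gate(self):
        lnc, coding = _regulation_fixture(50_000)
        assert call_cis([lnc], coding, self.em(0.5)) == []

    def test_only_nearest_gene_is_candidate(self):
        lnc, coding = _regulation_fixture(50_000)
        nearest = nearest_coding_gene([lnc], coding)
        assert nearest["L1"] == ("PCnear", 50_000)
        # correlate the lncRNA with the FAR gene only: no call
        rng = np.random.default_rng(21)
        x = rng.normal(4, 2, size=12)
        em = make_matrix(2.0 ** np.array([x, rng.normal(4, 2, 12), x]),
                         index=["L1", "PCnear", "PCfar"])
        assert call_cis([lnc], coding, em) == []

    def test_no_lnc_with_two_targets(self, toy_genome, toy_expression):
        from retlnc.models import GeneLocus
        from conftest import make_transcript

        truth = toy_genome.truth
        staged, _ = toy_expression
        lnc_loci = [
            GeneLocus(g, (make_transcript(f"{g}.t", g,
                                          exons=((i["start"], i["end"]),),
                                          strand=i["strand"], source="annotation"),))
            for g, i in sorted(truth.lnc_genes.items())
        ]
        coding_loci = [
            GeneLocus(g, (make_transcript(f"{g}.t", g,
                                          exons=((i["start"], i["end"]),),
                                          strand=i["strand"], source="annotation",
                                          biotype="coding"),))
            for g, i in sorted(truth.coding_genes.items())
        ]
        calls = call_cis(lnc_loci, coding_loci, staged)
        lncs = [c.lnc_id for c in calls]
        assert len(lncs) == len(set(lncs))


class TestCallTrans:
    def test_co_module_pair_called(self):
        rng = np.random.default_rng(30)
        em, labels = block_matrix(rng, n_blocks=1, block_size=4)
        modules = detect_modules(em)
        lncs = ["g0", "g1"]
        codings = ["g2", "g3"]
        calls = call_trans(lncs, codings, em, modules)
        pairs = {(c.lnc_id, c.target_gene_id) for c in calls}
        assert pairs == {("g0", "g2"), ("g0", "g3"), ("g1", "g2"), ("g1", "g3")}
        assert all(c.cor >= 0.9 and c.module_id != "M0" for c in calls)

    def test_different_modules_not_called(self):
        rng = np.random.default_rng(31)
        em, labels = block_matrix(rng, n_blocks=2, block_size=3, n_noise=0)
        modules = detect_modules(em)
        # block 0 lncs vs block 1 codings: never co-module
        calls = call_trans(["g0"], ["g3", "g4", "g5"], em, modules)
        assert calls == []

    def test_modules_must_cover_genes(self):
        rng = np.random.default_rng(32)
        em, _ = block_matrix(rng, n_blocks=1, block_size=3, n_noise=0)
        with pytest.raises(ValueError):
            call_trans(["g0"], ["missing"], em, {"g0": "M1"})


class TestEnrichTerms:
    def test_frozen_chi2_value(self):
        # 2x2 table a=20 b=80 c=10 d=890: chi2 = n(ad-bc)^2 / product of margins
        # = 1000 * 17000^2 / (100*900*30*970) = 110.34746...
        expected = chi2_2x2_reference(20, 80, 10, 890)
        assert expected == pytest.approx(110.34746, abs=1e-4)
        ref = stats.chi2_contingency([[20, 80], [10, 890]], correction=False)
        assert expected == pytest.approx(ref.statistic, abs=1e-9)

        background = [f"g{i}" for i in range(1000)]
        targets = background[:100]
        term_map = {g: ["T"] for g in background[:20] + background[100:110]}
        res = enrich_terms(targets, background, term_map)
        row = res[res["term"] == "T"].iloc[0]
        assert (row.target_with_term, row.target_without_term,
                row.background_with_term, row.background_without_term) == (20, 80, 10, 890)
        assert row.chi2 == pytest.approx(expected, abs=1e-9)
        assert row.p_value < 1e-20

    def test_null_table_not_enriched(self):
        background = [f"g{i}" for i in range(200)]
        targets = background[:50]  # term frequency identical in and out
        term_map = {g: ["T"] for g in background[:10] + background[50:80]}
        res = enrich_terms(targets, background, term_map)
        row = res[res["term"] == "T"].iloc[0]
        assert row.chi2 == pytest.approx(0.0, abs=1e-9)

    def test_empty_target_set(self):
        background = [f"g{i}" for i in range(10)]
        res = enrich_terms([], background, {background[0]: ["T"]})
        assert len(res) == 0

    def test_target_must_be_subset(self):
        with pytest.raises(ValueError):
            enrich_terms(["x"], ["a", "b"], {})

    def test_decision_agrees_with_fisher_on_healthy_tables(self):
        rng = np.random.default_rng(40)
        agree = total = 0
        while total < 200:
            a, b, c, d = rng.integers(5, 120, size=4)
            chi2 = chi2_2x2_reference(a, b, c, d)
            p_chi = stats.chi2.sf(chi2, df=1)
            p_fisher = stats.fisher_exact([[a, b], [c, d]]).pvalue
            total += 1
            agree += (p_chi <= 0.05) == (p_fisher <= 0.05)
        assert agree / total >= 0.95

    def test_bh_column_optional(self):
        background = [f"g{i}" for i in range(100)]
        term_map = {g: ["T1"] for g in background[:30]}
        res = enrich_terms(background[:10], background, term_map, bh=True)
        assert "p_bh" in res.columns

    def test_planted_term_found_in_synthetic_map(self, toy_genome):
        from retlnc import synthetic

        truth = toy_genome.truth
        background = sorted(truth.coding_genes)
        targets = background[:10]
        term_map = synthetic.make_term_map(truth, targets, seed=3)
        res = enrich_terms(targets, background, term_map)
        assert res.iloc[0]["term"] == "GO:PLANTED"
        assert res.iloc[0]["p_value"] <= 0.05
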