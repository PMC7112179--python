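"""Fractional counting, normalization, NB differential expression and
TE categorization."""

import numpy as np
import pytest

from pollentx.annotation import GenomicInterval, TEAnnotation
from pollentx.simulate import SimulationConfig, gen_annotation, gen_counts, gen_placements
from pollentx.te_expression import (
    CountMatrix,
    ReadPlacement,
    categorize_tes,
    family_enrichment,
    fractional_counts,
    nb_differential,
    read_counts_tsv,
    size_factors,
    stage_set_analysis,
    write_counts_tsv,
)

from oracles import hypergeom_tail_enumeration


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def _samples(n_ref=4, n_tgt=4):
    return [
        (f"s{i}", "seedling" if i < n_ref else "pollen", i % 4 + 1, 0)
        for i in range(n_ref + n_tgt)
    ]


def nb_draw(rng, mu, disp, size):
    lam = rng.gamma(1 / disp, np.asarray(mu) * disp, size)
    return rng.poisson(lam)


class TestFractionalCounts:
    def test_four_way_multimapper_quarter_each(self):
        features = [(f"te{k}", iv("chr1", 1000 * k, 1000 * k + 500)) for k in range(1, 5)]
        read = ReadPlacement("r1", tuple(iv("chr1", 1000 * k + 10, 1000 * k + 109) for k in range(1, 5)))
        counts = fractional_counts([read], features)
        assert all(counts[f"te{k}"] == pytest.approx(0.25) for k in range(1, 5))

    def test_unique_read_full_weight(self):
        counts = fractional_counts(
            [ReadPlacement("r1", (iv("chr1", 110, 150),))],
            [("te1", iv("chr1", 100, 600))],
        )
        assert counts["te1"] == 1.0

    def test_mass_conservation_when_all_loci_hit(self, rng):
        features = [(f"te{k}", iv("chr1", 10_000 * k, 10_000 * k + 5000)) for k in range(1, 6)]
        reads = []
        for i in range(10):
            k = int(rng.integers(1, 4))
            loci = []
            for _ in range(k):
                f = features[rng.integers(len(features))][1]
                s = int(rng.integers(f.start, f.end - 100))
                loci.append(iv("chr1", s, s + 99))
            reads.append(ReadPlacement(f"r{i}", tuple(loci)))
        counts = fractional_counts(reads, features)
        assert counts.sum() == pytest.approx(10.0)

    def test_largest_overlap_wins_and_ties_split(self):
        features = [("a", iv("chr1", 100, 180)), ("b", iv("chr1", 150, 400))]
        # read 120-219: 61 bp in a, 70 bp in b -> all weight to b
        counts = fractional_counts([ReadPlacement("r", (iv("chr1", 120, 219),))], features)
        assert counts["b"] == 1.0 and counts["a"] == 0.0
        # symmetric overlap -> split
        features = [("a", iv("chr1", 100, 200)), ("b", iv("chr1", 201, 301))]
        counts = fractional_counts([ReadPlacement("r", (iv("chr1", 151, 250),))], features)
        assert counts["a"] == counts["b"] == pytest.approx(0.5)

    def test_unassigned_locus_contributes_nothing(self):
        counts = fractional_counts(
            [ReadPlacement("r", (iv("chr1", 10, 60), iv("chr2", 10, 60)))],
            [("te1", iv("chr1", 1, 100))],
        )
        assert counts["te1"] == pytest.approx(0.5)

    def test_simulated_placements_conserve_mass(self, small_annotation, small_config):
        placements = gen_placements(small_config, small_annotation)
        features = [(t.te_id, t.interval) for t in small_annotation.tes]
        counts = fractional_counts(placements, features)
        assert counts.sum() <= len(placements) + 1e-9


class TestSizeFactors:
    def test_identical_columns(self):
        cm = CountMatrix(["a", "b"], _samples(1, 1), [[5, 5], [9, 9]])
        np.testing.assert_allclose(size_factors(cm), [1.0, 1.0])

    def test_doubled_column(self):
        cm = CountMatrix(["a", "b", "c"], _samples(1, 1), [[10, 20], [100, 200], [1000, 2000]])
        np.testing.assert_allclose(size_factors(cm), [1 / np.sqrt(2), np.sqrt(2)])

    def test_fallback_warns_without_common_feature(self):
        cm = CountMatrix(["a", "b"], _samples(1, 1), [[5, 0], [0, 10]])
        with pytest.warns(UserWarning):
            sf = size_factors(cm)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_matches_pydeseq2_median_of_ratios(self, rng):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        vals = nb_draw(rng, 50, 0.1, (300, 6)).astype(float) + 1
        cm = CountMatrix([f"f{i}" for i in range(300)], _samples(3, 3), vals)
        _, ref_sf = pydeseq2.deseq2_norm(vals.T)
        ours = size_factors(cm)
        np.testing.assert_allclose(ours / np.exp(np.mean(np.log(ours))),
                                   ref_sf / np.exp(np.mean(np.log(ref_sf))), rtol=1e-10)


class TestNBDifferential:
    def test_constant_feature_is_ns(self):
        vals = np.vstack([np.full(8, 100.0), np.full(8, 7.0)])
        cm = CountMatrix(["flat", "low"], _samples(), vals)
        res = {r.feature_id: r for r in nb_differential(cm, "seedling", "pollen")}
        assert res["flat"].log2_fold_change == 0.0
        assert res["flat"].direction == "ns"

    def test_low_coverage_feature_missing(self):
        vals = np.vstack([np.full(8, 100.0), np.full(8, 0.25)])
        cm = CountMatrix(["hi", "lo"], _samples(), vals)
        res = {r.feature_id: r for r in nb_differential(cm, "seedling", "pollen")}
        assert res["lo"].direction == "missing" and res["lo"].p_value is None

    def test_planted_fold_change_recovered(self, rng):
        n = 800
        mu = np.full(n, 50.0)
        vals = np.column_stack([nb_draw(rng, mu, 0.1, n) for _ in range(8)]).astype(float)
        planted = rng.choice(n, 80, replace=False)
        for j in range(4, 8):
            vals[planted, j] = nb_draw(rng, 4 * mu[planted], 0.1, planted.size)
        cm = CountMatrix([f"f{i}" for i in range(n)], _samples(), vals)
        res = nb_differential(cm, "seedling", "pollen")
        byid = {r.feature_id: r for r in res}
        recovered = np.mean([byid[f"f{i}"].direction == "up" for i in planted])
        assert recovered >= 0.9
        lfc = np.median([byid[f"f{i}"].log2_fold_change for i in planted])
        assert lfc == pytest.approx(2.0, abs=0.3)

    def test_requires_two_replicates(self):
        cm = CountMatrix(["a"], _samples(1, 4), [[1, 2, 3, 4, 5]])
        with pytest.raises(ValueError):
            nb_differential(cm, "seedling", "pollen")


@pytest.fixture(scope="module")
def categorized():
    cfg = SimulationConfig(seed=7, n_genes=150, n_tes=200)
    ann = gen_annotation(cfg)
    _, te_counts, truth = gen_counts(cfg, ann)
    de = {
        t: nb_differential(te_counts, "seedling", t)
        for t in ("microspore", "mature_pollen", "sperm_cell")
    }
    cats = categorize_tes(ann, te_counts, de)
    return ann, te_counts, cats


class TestCategorizeTes:

    def test_partition_is_exhaustive(self, categorized):
        ann, _, cats = categorized
        assert len(cats) == len(ann.tes)
        assert {c.te_id for c in cats} == {t.te_id for t in ann.tes}
        assert {c.category for c in cats} <= {"near_genes", "not_covered", "dynamic", "static"}

    def test_near_gene_precedence(self, categorized):
        from pollentx.annotation import classify_proximity

        ann, _, cats = categorized
        prox, _ = classify_proximity(ann)
        for c in cats:
            if prox[c.te_id] == "near_gene":
                assert c.category == "near_genes"

    def test_low_total_is_not_covered(self, categorized):
        from pollentx.annotation import classify_proximity

        ann, counts, cats = categorized
        prox, _ = classify_proximity(ann)
        totals = dict(zip(counts.feature_ids, counts.values.sum(axis=1)))
        for c in cats:
            if prox[c.te_id] == "distal" and totals[c.te_id] < 10:
                assert c.category == "not_covered"

    def test_dynamic_requires_significant_tissue(self, categorized):
        ann, counts, cats = categorized
        assert any(c.category == "dynamic" for c in cats)
        assert any(c.category == "static" for c in cats)


class TestFamilyEnrichment:
    def test_identity_background(self):
        tes = [TEAnnotation(f"t{i}", iv("chr1", 100 * i + 1, 100 * i + 50), family=f)
               for i, f in enumerate(["RLG"] * 4 + ["DTM"] * 4)]
        res = family_enrichment(tes, tes)
        assert all(r.log2_ratio == pytest.approx(0.0) for r in res)

    def test_double_proportion(self):
        bg = [TEAnnotation(f"b{i}", iv("chr1", 100 * i + 1, 100 * i + 50), family=f)
              for i, f in enumerate(["RLG"] * 2 + ["DTM"] * 6)]
        cat = [t for t in bg if t.family == "RLG"] + [t for t in bg if t.family == "DTM"][:2]
        res = {r.family: r for r in family_enrichment(cat, bg)}
        assert res["RLG"].log2_ratio == pytest.approx(1.0)  # 0.5 / 0.25

    def test_zero_count_is_missing(self):
        bg = [TEAnnotation(f"b{i}", iv("chr1", 100 * i + 1, 100 * i + 50), family=f)
              for i, f in enumerate(["RLG", "RLG", "DTM"])]
        res = {r.family: r for r in family_enrichment([bg[0]], bg)}
        assert res["DTM"].log2_ratio is None


class TestStageSetAnalysis:
    def test_persistence_fraction(self):
        out = stage_set_analysis(
            up_sets={"ms": {"a", "b", "c", "d"}},
            expressed_sets={"ms": {"a", "b", "c", "d"}, "mp": {"a", "b"}},
            universe=set("abcdefgh"),
        )
        assert out["persistence"]["ms"]["mp"] == 0.5

    def test_full_overlap_p_one(self):
        u = set(range(10))
        out = stage_set_analysis({}, {"x": u, "y": u}, u)
        t = out["overlap_tests"][("x", "y")]
        assert t["fraction_of_smaller"] == 1.0
        assert t["p_value"] == pytest.approx(1.0)

    def test_hypergeometric_matches_enumeration(self, rng):
        u = set(range(40))
        for _ in range(10):
            a = set(rng.choice(40, rng.integers(5, 20), replace=False).tolist())
            b = set(rng.choice(40, rng.integers(5, 20), replace=False).tolist())
            out = stage_set_analysis({}, {"a": a, "b": b}, u)
            got = out["overlap_tests"][("a", "b")]["p_value"]
            want = hypergeom_tail_enumeration(len(a & b), 40, len(a), len(b))
            assert got == pytest.approx(want, rel=1e-9)

    def test_exclusive_sets(self):
        out = stage_set_analysis(
            {}, {"a": {1, 2, 3}, "b": {3, 4}}, {1, 2, 3, 4, 5}
        )
        assert out["exclusive"]["a"] == {1, 2}
        assert out["exclusive"]["b"] == {4}

    def test_empty_up_set_missing(self):
        out = stage_set_analysis({"ms": set()}, {"mp": {1}}, {1})
        assert out["persistence"]["ms"]["mp"] is None


def test_counts_tsv_roundtrip(tmp_path, small_counts):
    gene_counts, _, _ = small_counts
    write_counts_tsv(gene_counts, tmp_path / "c.tsv", tmp_path / "m.tsv")
    back = read_counts_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
    assert back.feature_ids == gene_counts.feature_ids
    assert back.samples == gene_counts.samples
    np.testing.assert_allclose(back.values, gene_counts.values)
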