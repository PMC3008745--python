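"""Prioritization cascade: each filter's boundary behaviour and the
brute-force set-operation oracle for stage counts."""

import numpy as np
import pandas as pd
import pytest

from exosnv.cascade import (
    CascadeParams,
    conservation_threshold,
    filter_conserved,
    filter_expressed,
    filter_frequency,
    filter_functional,
    filter_severity,
    flag_categories,
    run_cascade,
)
from exosnv.config import SimulationConfig
from exosnv.simulate import SITE_KEY, AnnotationTables, simulate_annotation_tables, simulate_pair


def _variants(specs):
    """specs: list of (pos, gene, consequence)."""
    return pd.DataFrame(
        [
            {"chrom": "chr1", "pos": p, "ref": "A", "alt": "C", "gene_id": g, "consequence": c}
            for p, g, c in specs
        ]
    )


def _sites(pos_list, **cols):
    df = pd.DataFrame(
        [{"chrom": "chr1", "pos": p, "ref": "A", "alt": "C"} for p in pos_list]
    )
    for k, v in cols.items():
        df[k] = v
    return df


class TestFrequencyFilter:
    table = _sites([1, 2], frequency=[0.02, 0.005])

    def test_common_variant_removed(self):
        out = filter_frequency(_variants([(1, "g", "missense")]), self.table)
        assert out.empty

    def test_absent_variant_kept(self):
        out = filter_frequency(_variants([(7, "g", "missense")]), self.table)
        assert len(out) == 1

    def test_rare_variant_kept(self):
        out = filter_frequency(_variants([(2, "g", "missense")]), self.table)
        assert len(out) == 1


class TestFunctionalFilter:
    flags = _sites([1, 2, 3], predictor_a=[True, False, False], predictor_b=[False, False, True])

    def test_any_mode(self):
        out = filter_functional(_variants([(1, "g", "m"), (2, "g", "m"), (3, "g", "m")]), self.flags)
        assert list(out["pos"]) == [1, 3]

    def test_all_mode(self):
        out = filter_functional(
            _variants([(1, "g", "m"), (3, "g", "m")]), self.flags, mode="all"
        )
        assert out.empty

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            filter_functional(_variants([]), self.flags, mode="either")


class TestConservation:
    def test_quantile_on_uniform_grid(self):
        # order statistics with linear interpolation: 1 + 0.975 * 999
        assert conservation_threshold(np.arange(1, 1001)) == pytest.approx(975.025)

    def test_constant_scores(self):
        assert conservation_threshold([3.3] * 50) == pytest.approx(3.3)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            conservation_threshold([])

    def test_generator_calibrated_to_two(self):
        """With the default conserved fraction (2.5%), the empirical 0.975
        quantile of generated conservation scores sits at 2.0."""
        cfg = SimulationConfig(n_sites=40_000, heterozygosity_rate=0.02, seed=21)
        truth = simulate_pair(cfg)[2]
        tables = simulate_annotation_tables(cfg, truth)
        assert conservation_threshold(tables.conservation["score"]) == pytest.approx(2.0, abs=0.05)

    def test_boundary_inclusive(self, caplog):
        scores = _sites([1, 2, 3], score=[2.0, 1.99, 5.0])
        variants = _variants([(1, "g", "m"), (2, "g", "m"), (3, "g", "m"), (4, "g", "m")])
        with caplog.at_level("WARNING", logger="exosnv.cascade"):
            out = filter_conserved(variants, scores)
        assert list(out["pos"]) == [1, 3]  # 2.0 kept, 1.99 dropped, missing dropped
        assert any("missing conservation" in r.message for r in caplog.records)


class TestExpression:
    matrix = pd.DataFrame(
        {"gene_id": ["g1", "g2", "g3", "g4"], "s1": [1.0, 10, 100, 1000], "s2": [1.0, 10, 100, 1000]}
    )

    def test_quartile_boundary_inclusive(self):
        # Q1 of means {1,10,100,1000} = 7.75; g1 below, others kept
        out = filter_expressed(_variants([(1, "g1", "m"), (2, "g2", "m"), (3, "g4", "m")]), self.matrix)
        assert list(out["pos"]) == [2, 3]

    def test_equal_expression_keeps_all(self):
        flat = pd.DataFrame({"gene_id": ["a", "b"], "s1": [5.0, 5.0], "s2": [5.0, 5.0]})
        out = filter_expressed(_variants([(1, "a", "m"), (2, "b", "m")]), flat)
        assert len(out) == 2

    def test_missing_gene_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="exosnv.cascade"):
            out = filter_expressed(_variants([(1, "nope", "m")]), self.matrix)
        assert out.empty
        assert any("absent from expression" in r.message for r in caplog.records)

    def test_no_sample_columns_rejected(self):
        with pytest.raises(ValueError):
            filter_expressed(_variants([(1, "g1", "m")]), pd.DataFrame({"gene_id": ["g1"]}))


def test_flag_categories_set_oracle():
    genes = [f"g{i}" for i in range(20)]
    rng = np.random.default_rng(3)
    cats = {
        "kinase": set(rng.choice(genes, 6, replace=False)),
        "repair": set(rng.choice(genes, 4, replace=False)),
    }
    variants = _variants([(i + 1, g, "missense") for i, g in enumerate(genes)])
    out = flag_categories(variants, cats)
    for name, members in cats.items():
        assert set(out.loc[out[name], "gene_id"]) == members
    assert len(out) == len(variants)  # never filters


def _fixture_tables():
    freq = _sites([2, 3], frequency=[0.2, 0.001])
    dmg = _sites([1, 3, 4, 5, 6, 7], predictor_a=[True, True, True, False, True, True],
                 predictor_b=[False, True, False, False, True, False])
    cons = _sites(list(range(1, 11)), score=[3.0, 3.0, 1.0, 2.0, 3.0, 3.0, 0.5, 3.0, 3.0, 3.0])
    expr = pd.DataFrame(
        {"gene_id": ["gA", "gB", "gC", "gD"], "s1": [100.0, 50.0, 1.0, 80.0],
         "s2": [100.0, 50.0, 1.0, 80.0]}
    )
    return AnnotationTables(
        frequency=freq, damaging=dmg, conservation=cons, expression=expr,
        categories={"kinase": {"gA"}}, catalogues={"cancer_census": {"gB"}},
    )


def _fixture_variants():
    return _variants(
        [
            (1, "gA", "missense"),   # survives everything
            (2, "gA", "missense"),   # common in population
            (3, "gB", "missense"),   # damaging but score 1.0: dropped at conservation
            (4, "gC", "nonsense"),   # survives to expression, gC not expressed
            (5, "gA", "missense"),   # not damaging
            (6, "gB", "utr3"),       # impact class, damaging, conserved, expressed
            (7, "gA", "synonymous"), # severity gate
            (8, "gA", "intronic"),   # severity gate
            (9, "gD", "missense"),   # no damaging entry: fails closed
            (10, "gA", "intergenic"),
        ]
    )


def test_stage_counts_match_brute_force_sets():
    """Cascade counts equal independent set intersections computed with
    plain python set operations on the same fixture."""
    variants, tables = _fixture_variants(), _fixture_tables()

    impact = {1, 2, 3, 4, 5, 6, 9}
    common = {2}
    damaging = {1, 3, 4, 6}
    conserved_scores = {p: s for p, s in zip(range(1, 11), tables.conservation["score"])}
    expr_means = {"gA": 100.0, "gB": 50.0, "gC": 1.0, "gD": 80.0}
    q1 = np.quantile(list(expr_means.values()), 0.25)
    gene_of = dict(zip(variants["pos"], variants["gene_id"]))

    s_impact = impact
    s_rare = s_impact - common
    s_dmg = s_rare & damaging
    s_cons = {p for p in s_dmg if conserved_scores[p] >= 2.0}
    s_expr = {p for p in s_cons if expr_means[gene_of[p]] >= q1}

    result = run_cascade(variants, tables)
    assert result.stage_counts["input"] == len(variants)
    assert result.stage_counts["impact"] == len(s_impact)
    assert result.stage_counts["rare"] == len(s_rare)
    assert result.stage_counts["damaging"] == len(s_dmg)
    assert result.stage_counts["conserved"] == len(s_cons)
    assert result.stage_counts["expressed"] == len(s_expr)
    assert set(result.final["pos"]) == s_expr
    assert result.categorized_count == len({p for p in s_expr if gene_of[p] == "gA"})


def test_cascade_counts_non_increasing_and_order_invariant():
    variants, tables = _fixture_variants(), _fixture_tables()
    r1 = run_cascade(variants, tables)
    filter_stages = [
        v for k, v in r1.stage_counts.items() if k != "categorized"
    ]
    assert all(a >= b for a, b in zip(filter_stages, filter_stages[1:]))
    shuffled = variants.sample(frac=1, random_state=5).reset_index(drop=True)
    r2 = run_cascade(shuffled, tables)
    assert r1.stage_counts == r2.stage_counts
    pd.testing.assert_frame_equal(r1.final, r2.final)


def test_empty_input_all_zero_counts():
    result = run_cascade(_fixture_variants().iloc[:0], _fixture_tables())
    assert all(v == 0 for v in result.stage_counts.values())
    assert result.final.empty


def test_reporting_only_mode_skips_optional_stages():
    params = CascadeParams(include_conservation_stage=False, include_expression_stage=False)
    result = run_cascade(_fixture_variants(), _fixture_tables(), params)
    assert "conserved" not in result.stage_counts
    assert "expressed" not in result.stage_counts
    assert result.stage_counts["damaging"] == len(result.final)


def test_severity_gate_excludes_silent_classes():
    out = filter_severity(_fixture_variants())
    assert not set(out["consequence"]) & {"synonymous", "intronic", "intergenic"}
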