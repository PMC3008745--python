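"""Synthetic pileup/annotation/CNV generators: determinism, rate
calibration against binomial/Poisson oracles, truth consistency."""

import numpy as np
import pandas as pd
import pytest

from exosnv.config import SimulationConfig, msi_preset, mss_preset
from exosnv.simulate import (
    SITE_KEY,
    simulate_annotation_tables,
    simulate_array_genotypes,
    simulate_cnv_counts,
    simulate_pair,
)


def test_seeded_determinism_byte_identical():
    cfg = SimulationConfig(n_sites=2000, heterozygosity_rate=0.01, somatic_rate=0.005, seed=13)
    out1 = simulate_pair(cfg)
    out2 = simulate_pair(cfg)
    for a, b in zip(out1, out2):
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv(index=False) == b.to_csv(index=False)


def test_zero_somatic_rate_yields_no_somatic_truth():
    cfg = SimulationConfig(n_sites=5000, somatic_rate=0.0, heterozygosity_rate=0.05, seed=1)
    _, _, truth = simulate_pair(cfg)
    assert truth["is_somatic"].sum() == 0


def test_het_site_count_matches_binomial_oracle():
    """Observed heterozygous-site count within 4 SD of Binomial(n, rate)."""
    n, rate = 100_000, 0.001
    cfg = SimulationConfig(n_sites=n, heterozygosity_rate=rate, mean_coverage_normal=20.0, seed=2)
    _, _, truth = simulate_pair(cfg)
    het = int((truth["normal_genotype"] == "het").sum())
    mean, sd = n * rate, np.sqrt(n * rate * (1 - rate))
    assert abs(het - mean) <= 4 * sd


def test_het_allele_fraction_converges_to_half():
    """Pooled variant-read fraction at het sites within the 4 SD binomial
    band around 0.5 (error-free so the oracle is exact)."""
    cfg = SimulationConfig(
        n_sites=20_000, heterozygosity_rate=0.05, error_rate=0.0,
        mean_coverage_normal=40.0, seed=3,
    )
    _, normal, truth = simulate_pair(cfg)
    het = truth["normal_genotype"] == "het"
    sub = normal.loc[het.to_numpy()]
    alt = (sub["alt_fwd"] + sub["alt_rev"]).sum()
    cov = (sub[["ref_fwd", "ref_rev", "alt_fwd", "alt_rev"]].to_numpy().sum())
    assert abs(alt / cov - 0.5) <= 4 * np.sqrt(0.25 / cov)


def test_somatic_never_at_germline_variant_allele():
    cfg = SimulationConfig(n_sites=30_000, heterozygosity_rate=0.05, somatic_rate=0.05, seed=4)
    _, _, truth = simulate_pair(cfg)
    som = truth[truth["is_somatic"]]
    assert (som["normal_genotype"] == "ref_hom").all()
    assert (som["tumor_genotype"] != som["normal_genotype"]).all()


def test_presets_differ_only_in_somatic_rate():
    assert msi_preset().somatic_rate == pytest.approx(8 * mss_preset().somatic_rate)


@pytest.mark.parametrize(
    "field, value",
    [
        ("error_rate", -0.1),
        ("error_rate", 1.5),
        ("heterozygosity_rate", float("nan")),
        ("tumor_purity", 2.0),
        ("n_sites", 0),
        ("bin_count", -5),
    ],
)
def test_invalid_config_rejected(field, value):
    with pytest.raises(ValueError):
        SimulationConfig(**{field: value})


def test_overlapping_planted_segments_rejected():
    with pytest.raises(ValueError, match="overlap"):
        SimulationConfig(planted_segments=[(10, 30, 1.0), (20, 40, -1.0)])


_TABLES_CFG = SimulationConfig(n_sites=20_000, heterozygosity_rate=0.05, somatic_rate=0.01, seed=6)


@pytest.fixture(scope="module")
def truth():
    return simulate_pair(_TABLES_CFG)[2]


@pytest.fixture(scope="module")
def tables(truth):
    return simulate_annotation_tables(_TABLES_CFG, truth)


class TestAnnotationTables:
    cfg = _TABLES_CFG

    def test_frequency_entries_above_threshold_match_truth_flags(self, truth, tables):
        common = tables.frequency[tables.frequency["frequency"] > 0.01]
        got = set(map(tuple, common[SITE_KEY].to_numpy()))
        expected = set(map(tuple, truth.loc[truth["frequent"], SITE_KEY].to_numpy()))
        assert got == expected

    def test_damaging_flags_match_truth(self, truth, tables):
        flagged = tables.damaging[tables.damaging[["predictor_a", "predictor_b"]].any(axis=1)]
        got = set(map(tuple, flagged[SITE_KEY].to_numpy()))
        expected = set(map(tuple, truth.loc[truth["damaging"], SITE_KEY].to_numpy()))
        assert got == expected

    def test_conservation_scores_match_truth_flags(self, truth, tables):
        merged = truth.merge(tables.conservation, on=SITE_KEY)
        assert ((merged["score"] >= 2.0) == merged["conserved"]).all()

    def test_saturated_damaging_fraction(self):
        cfg = SimulationConfig(
            n_sites=3000, heterozygosity_rate=0.02, somatic_rate=0.02,
            damaging_fraction=1.0, seed=8,
        )
        truth = simulate_pair(cfg)[2]
        tables = simulate_annotation_tables(cfg, truth)
        som = truth.loc[truth["is_somatic"], SITE_KEY]
        merged = som.merge(tables.damaging, on=SITE_KEY, how="left")
        assert merged[["predictor_a", "predictor_b"]].any(axis=1).all()

    def test_empty_truth_yields_empty_tables(self):
        truth = simulate_pair(self.cfg)[2].iloc[:0]
        tables = simulate_annotation_tables(self.cfg, truth)
        assert tables.frequency.empty and tables.damaging.empty
        assert tables.conservation.empty and tables.expression.empty
        assert tables.expressed_genes == set()

    def test_duplicate_site_ids_rejected(self, truth):
        dup = pd.concat([truth, truth.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            simulate_annotation_tables(self.cfg, dup)

    def test_expression_matrix_shape_and_quartile_rule(self, tables):
        sample_cols = [c for c in tables.expression.columns if c != "gene_id"]
        assert len(sample_cols) >= 2
        means = tables.expression.set_index("gene_id")[sample_cols].mean(axis=1)
        q1 = np.quantile(means.to_numpy(), 0.25)
        assert tables.expressed_genes == set(means[means >= q1].index)


class TestCnvCounts:
    def test_no_planted_segments_centered_ratios(self):
        """Without planted segments the mean log2 ratio is ~0 within 4 SD
        of the Poisson delta-method error."""
        cfg = SimulationConfig(bin_count=500, cnv_base_rate=500.0, seed=9)
        bins, truth = simulate_cnv_counts(cfg)
        assert truth.empty
        ratio = np.log2(bins["tumor_count"] / bins["normal_count"])
        sd_bin = np.sqrt(2.0 / 500.0) / np.log(2)
        assert abs(ratio.mean()) <= 4 * sd_bin / np.sqrt(500)

    def test_planted_doubling_recovered_in_counts(self):
        cfg = SimulationConfig(
            bin_count=300, cnv_base_rate=500.0, planted_segments=[(100, 119, 1.0)], seed=10
        )
        bins, truth = simulate_cnv_counts(cfg)
        assert truth.iloc[0].tolist() == [100, 119, 1.0]
        inside = bins.iloc[100:120]
        outside = bins.drop(inside.index)
        r_in = inside["tumor_count"].mean() / inside["normal_count"].mean()
        r_out = outside["tumor_count"].mean() / outside["normal_count"].mean()
        assert r_in == pytest.approx(2.0, rel=0.1)
        assert r_out == pytest.approx(1.0, rel=0.05)

    def test_seeded_determinism(self):
        cfg = SimulationConfig(bin_count=100, planted_segments=[(10, 19, 1.0)], seed=11)
        a, _ = simulate_cnv_counts(cfg)
        b, _ = simulate_cnv_counts(cfg)
        pd.testing.assert_frame_equal(a, b)


def test_array_genotypes_track_truth():
    cfg = SimulationConfig(n_sites=1000, heterozygosity_rate=0.1, seed=12)
    _, _, truth = simulate_pair(cfg)
    arr = simulate_array_genotypes(cfg, truth)
    assert (arr["genotype"].to_numpy() == truth["normal_genotype"].to_numpy()).all()
    assert ((arr["quality_p"] >= 0) & (arr["quality_p"] <= 1)).all()
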