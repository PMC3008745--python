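"""Synthetic tumor/normal pileups, annotation side-tables and CNV counts.

The read-sampling model: per-site coverage is Poisson around the
configured mean; reads are drawn from the site's true alleles
binomially (allele fraction 0.5 for heterozygous sites, 1.0 for
homozygous-alternate, scaled by tumor purity for somatic sites);
reference-drawn reads convert to the alternate allele with probability
``error_rate``; strands are assigned per read with probability 0.5.
All generators are deterministic under a fixed config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .genemodels import Genome, homopolymer_lengths, simulate_gene_models

__all__ = [
    "simulate_pair",
    "simulate_annotation_tables",
    "simulate_gene_models",
    "simulate_cnv_counts",
    "simulate_array_genotypes",
    "AnnotationTables",
]

SITE_KEY = ["chrom", "pos", "ref", "alt"]
PILEUP_COLUMNS = SITE_KEY + [
    "ref_fwd",
    "ref_rev",
    "alt_fwd",
    "alt_rev",
    "max_alt_quality",
    "homopolymer_len",
]
TRUTH_COLUMNS = SITE_KEY + [
    "gene_id",
    "normal_genotype",
    "tumor_genotype",
    "is_somatic",
    "consequence",
    "frequent",
    "damaging",
    "conserved",
]

_BASE_ARR = np.array(list("ACGT"))

# per-gene prior probabilities of functional-category / catalogue membership;
# catalogue rates follow the reported overlap of mutated genes with the
# cancer-mutation catalogue (~39%) and an earlier large-scale screen (~13%)
CATEGORY_RATES = {
    "repair": 0.06,
    "kinase": 0.08,
    "receptor": 0.06,
    "transmembrane_receptor": 0.03,
}
CATALOGUE_RATES = {"cancer_census": 0.39, "prior_study": 0.13}


@dataclass
class AnnotationTables:
    """Side tables consumed by the prioritization cascade.

    ``frequency`` lists catalogued population variants (minor allele
    frequency / average heterozygosity); only entries above the 1%
    threshold mark a variant as 'known and common'.  ``damaging`` carries
    two independent predictor flags per tumor-variant site.
    ``conservation`` holds a per-base conservation score for every site;
    the generator calibrates the score distribution so its 0.975 quantile
    sits at 2.0 when ``conserved_fraction`` is 0.025.  ``expression`` is a
    genes x samples matrix; ``expressed_genes`` is the set passing the
    first-quartile rule on genewise means, computed from the realized
    matrix.
    """

    frequency: pd.DataFrame
    damaging: pd.DataFrame
    conservation: pd.DataFrame
    expression: pd.DataFrame
    categories: dict[str, set[str]]
    catalogues: dict[str, set[str]]
    expressed_genes: set[str] = field(default_factory=set)


def _genotype_allele_fraction(gt: np.ndarray) -> np.ndarray:
    af = np.zeros(len(gt))
    af[gt == "het"] = 0.5
    af[gt == "alt_hom"] = 1.0
    return af


def _sample_pileup(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    cov: np.ndarray,
    allele_fraction: np.ndarray,
) -> dict[str, np.ndarray]:
    true_alt = rng.binomial(cov, allele_fraction)
    err = rng.binomial(cov - true_alt, cfg.error_rate)
    alt = true_alt + err
    ref = cov - alt
    alt_fwd = rng.binomial(alt, 0.5)
    ref_fwd = rng.binomial(ref, 0.5)
    # max over alt-read qualities of a two-point (low/high) mixture:
    # the max is low only when every supporting read drew the low value
    p_all_low = np.where(alt > 0, (1.0 - cfg.p_quality_high) ** alt, 1.0)
    qual = np.where(rng.random(len(cov)) < p_all_low, cfg.quality_low, cfg.quality_high)
    qual = np.where(alt > 0, qual, 0)
    return {
        "ref_fwd": ref_fwd,
        "ref_rev": ref - ref_fwd,
        "alt_fwd": alt_fwd,
        "alt_rev": alt - alt_fwd,
        "max_alt_quality": qual,
    }


def simulate_pair(
    config: SimulationConfig, genome: Genome | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate matched tumor and normal pileups plus the truth table.

    Without a genome, sites are consecutive positions on a synthetic
    chromosome with random reference/alternate bases and gene ids
    assigned by position blocks.  With a genome, sites are sampled from
    the reference sequence, the reference base and homopolymer context
    come from it, and the gene id is the covering gene (or '.').
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng([int(cfg.seed), 21])
    n = cfg.n_sites

    if genome is None:
        chrom = "chr1"
        pos = np.arange(1, n + 1)
        ref_idx = rng.integers(0, 4, n)
        hp_hit = rng.random(n) < cfg.homopolymer_fraction
        hp = np.where(hp_hit, rng.integers(5, 9, n), rng.integers(1, 5, n))
        sites_per_gene = -(-n // cfg.n_genes)
        gene_id = np.array([f"G{(p - 1) // sites_per_gene + 1:04d}" for p in pos])
    else:
        chrom = next(iter(genome.reference))
        seq = genome.reference[chrom]
        if n > len(seq):
            raise ValueError(f"n_sites={n} exceeds reference length {len(seq)}")
        p0 = np.sort(rng.choice(len(seq), size=n, replace=False))
        pos = p0 + 1
        seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        ref_idx = np.searchsorted(np.frombuffer(b"ACGT", dtype=np.uint8), seq_arr[p0])
        hp = homopolymer_lengths(seq)[p0]
        gene_id = np.full(n, ".", dtype=object)
        for t in genome.transcripts:
            inside = (p0 >= t.start) & (p0 < t.end)
            gene_id[inside] = t.gene_id

    ref = _BASE_ARR[ref_idx]
    alt = _BASE_ARR[(ref_idx + rng.integers(1, 4, n)) % 4]

    u = rng.random(n)
    normal_gt = np.full(n, "ref_hom", dtype=object)
    het_rate, hom_rate = cfg.heterozygosity_rate, cfg.effective_hom_alt_rate
    normal_gt[u < het_rate] = "het"
    normal_gt[(u >= het_rate) & (u < het_rate + hom_rate)] = "alt_hom"

    is_somatic = (normal_gt == "ref_hom") & (rng.random(n) < cfg.somatic_rate)
    tumor_gt = normal_gt.copy()
    tumor_gt[is_somatic] = "het"

    af_normal = _genotype_allele_fraction(normal_gt)
    af_tumor = af_normal.copy()
    af_tumor[is_somatic] = 0.5 * cfg.tumor_purity

    cov_t = rng.poisson(cfg.mean_coverage_tumor, n)
    cov_n = rng.poisson(cfg.mean_coverage_normal, n)

    base = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})
    tumor = base.assign(**_sample_pileup(rng, cfg, cov_t, af_tumor), homopolymer_len=hp)
    normal = base.assign(**_sample_pileup(rng, cfg, cov_n, af_normal), homopolymer_len=hp)
    tumor = tumor[PILEUP_COLUMNS]
    normal = normal[PILEUP_COLUMNS]

    is_germline_variant = normal_gt != "ref_hom"
    has_tumor_variant = af_tumor > 0
    truth = base.assign(
        gene_id=gene_id,
        normal_genotype=normal_gt,
        tumor_genotype=tumor_gt,
        is_somatic=is_somatic,
        consequence=".",
        frequent=is_germline_variant & (rng.random(n) < cfg.frequent_fraction),
        damaging=has_tumor_variant & (rng.random(n) < cfg.damaging_fraction),
        conserved=rng.random(n) < cfg.conserved_fraction,
    )[TRUTH_COLUMNS]
    return tumor, normal, truth


def simulate_annotation_tables(config: SimulationConfig, truth: pd.DataFrame) -> AnnotationTables:
    """Generate side tables consistent with the truth flags.

    Population-frequent sites get frequencies in [0.05, 0.5]; a fraction
    of the remaining variant sites are catalogued as rare (< 0.01), the
    rest are absent from the table.  Predictor A flags exactly the
    truth-damaging sites; predictor B flags a random subset of them.
    """
    cfg = config
    if truth[SITE_KEY].duplicated().any():
        raise ValueError("duplicate site ids in truth table")
    rng = np.random.default_rng([int(cfg.seed), 31])
    empty = truth.shape[0] == 0

    sites = truth[SITE_KEY]
    frequent = truth["frequent"].to_numpy(bool)
    is_variant = (truth["tumor_genotype"] != "ref_hom") | (truth["normal_genotype"] != "ref_hom")
    rare_known = ~frequent & is_variant.to_numpy() & (rng.random(len(truth)) < 0.3)
    freq_vals = np.where(
        frequent,
        rng.uniform(0.05, 0.5, len(truth)),
        rng.uniform(1e-4, 9e-3, len(truth)),
    )
    frequency = sites[frequent | rare_known].assign(frequency=freq_vals[frequent | rare_known])

    in_tumor = (truth["tumor_genotype"] != "ref_hom").to_numpy()
    damaging_truth = truth["damaging"].to_numpy(bool)
    dmg_sites = sites[in_tumor]
    damaging = dmg_sites.assign(
        predictor_a=damaging_truth[in_tumor],
        predictor_b=damaging_truth[in_tumor] & (rng.random(in_tumor.sum()) < 0.8),
    )

    conserved = truth["conserved"].to_numpy(bool)
    score = np.where(
        conserved,
        2.0 + rng.exponential(0.5, len(truth)),
        2.0 - rng.exponential(1.0, len(truth)),
    )
    conservation = sites.assign(score=score)

    genes = sorted(g for g in truth["gene_id"].unique() if g != ".")
    n_samples = 4
    if genes and not empty:
        high = rng.random(len(genes)) < cfg.expressed_fraction
        gene_mean = np.where(
            high,
            rng.lognormal(np.log(100.0), 0.5, len(genes)),
            rng.lognormal(np.log(2.0), 0.5, len(genes)),
        )
        values = gene_mean[:, None] * rng.lognormal(0.0, 0.2, (len(genes), n_samples))
        expression = pd.DataFrame(
            values, columns=[f"sample_{i + 1}" for i in range(n_samples)]
        ).assign(gene_id=genes)[["gene_id"] + [f"sample_{i + 1}" for i in range(n_samples)]]
        means = expression.drop(columns="gene_id").mean(axis=1).to_numpy()
        q1 = np.quantile(means, 0.25)
        expressed_genes = {g for g, m in zip(genes, means) if m >= q1}
    else:
        expression = pd.DataFrame(
            columns=["gene_id"] + [f"sample_{i + 1}" for i in range(n_samples)]
        )
        expressed_genes = set()

    categories = {
        name: {g for g in genes if rng.random() < rate} for name, rate in CATEGORY_RATES.items()
    }
    catalogues = {
        name: {g for g in genes if rng.random() < rate} for name, rate in CATALOGUE_RATES.items()
    }
    return AnnotationTables(
        frequency=frequency.reset_index(drop=True),
        damaging=damaging.reset_index(drop=True),
        conservation=conservation.reset_index(drop=True),
        expression=expression,
        categories=categories,
        catalogues=catalogues,
        expressed_genes=expressed_genes,
    )


def simulate_cnv_counts(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin tumor/normal read counts with planted copy-number segments.

    Normal counts are Poisson around ``cnv_base_rate``; tumor counts are
    Poisson with the rate multiplied by ``2 ** effect`` inside planted
    segments (bin ranges inclusive of both endpoints).
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng([int(cfg.seed), 41])
    rate = np.full(cfg.bin_count, cfg.cnv_base_rate)
    truth_rows = []
    for start, end, effect in cfg.planted_segments:
        rate[start : end + 1] *= 2.0**effect
        truth_rows.append({"start_bin": start, "end_bin": end, "log2_effect": effect})
    normal = rng.poisson(cfg.cnv_base_rate, cfg.bin_count)
    tumor = rng.poisson(rate)
    bins = pd.DataFrame(
        {
            "chrom": "chr1",
            "bin_start": np.arange(cfg.bin_count) * cfg.bin_size,
            "tumor_count": tumor,
            "normal_count": normal,
        }
    )
    truth = pd.DataFrame(truth_rows, columns=["start_bin", "end_bin", "log2_effect"])
    return bins, truth


def simulate_array_genotypes(config: SimulationConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Array-style genotype table: the truth normal genotype plus a per-
    position quality p-value (Beta(0.5, 10): mostly confident calls, a
    tail above the 0.1 exclusion threshold)."""
    rng = np.random.default_rng([int(config.seed), 51])
    return truth[["chrom", "pos"]].assign(
        genotype=truth["normal_genotype"].to_numpy(),
        quality_p=rng.beta(0.5, 10.0, len(truth)),
    )
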