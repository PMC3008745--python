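"""Sequencing-vs-array genotype concordance.

The array genotypes serve as the reference standard.  Positions enter
the comparison only when the array call is confident (quality p-value
strictly below ``max_array_p``) and the sequencing coverage strictly
exceeds ``min_cov``.  The false-positive rate is the fraction of
array-reference positions where sequencing calls any variant; the
false-negative rate is the fraction of array-variant positions where
sequencing calls reference.  Diploid accuracy is the concordant
fraction over all eligible positions; haploid concordance recodes
heterozygous calls as homozygous non-reference on both sides before
comparing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GENOTYPES

DEFAULT_AF_LOW = 0.15
DEFAULT_AF_HIGH = 0.85


@dataclass
class ConcordanceReport:
    n_compared: int
    false_positive_rate: float
    false_negative_rate: float
    accuracy: float
    haploid_concordance: float
    confusion: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_compared": self.n_compared,
            "false_positive_rate": self.false_positive_rate,
            "false_negative_rate": self.false_negative_rate,
            "accuracy": self.accuracy,
            "haploid_concordance": self.haploid_concordance,
            "confusion": self.confusion,
        }


def call_genotypes(
    pileups: pd.DataFrame, af_low: float = DEFAULT_AF_LOW, af_high: float = DEFAULT_AF_HIGH
) -> pd.DataFrame:
    """Diploid genotypes from pileup allele fractions.

    Alternate-allele fraction below ``af_low`` -> ref_hom, above
    ``af_high`` -> alt_hom, otherwise het.  Zero-coverage sites are
    reported as ref_hom with coverage 0 (they are removed by any
    coverage filter downstream).
    """
    alt = (pileups["alt_fwd"] + pileups["alt_rev"]).to_numpy(float)
    cov = (pileups[["ref_fwd", "ref_rev", "alt_fwd", "alt_rev"]].sum(axis=1)).to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(cov > 0, alt / np.maximum(cov, 1), 0.0)
    gt = np.where(af < af_low, "ref_hom", np.where(af > af_high, "alt_hom", "het"))
    return pileups[["chrom", "pos"]].assign(genotype=gt, coverage=cov.astype(int))


def _validate_coding(df: pd.DataFrame, column: str, who: str) -> None:
    bad = ~df[column].isin(GENOTYPES)
    if bad.any():
        raise ValueError(
            f"{who} genotypes use unknown codes: {sorted(df.loc[bad, column].unique())}"
        )


def compare(
    seq: pd.DataFrame,
    array: pd.DataFrame,
    min_cov: int = 3,
    max_array_p: float = 0.1,
) -> ConcordanceReport:
    """Compare sequencing genotypes (chrom, pos, genotype, coverage) to
    array genotypes (chrom, pos, genotype, quality_p)."""
    _validate_coding(seq, "genotype", "sequencing")
    _validate_coding(array, "genotype", "array")
    merged = seq.merge(array, on=["chrom", "pos"], suffixes=("_seq", "_array"))
    eligible = merged[
        (merged["quality_p"] < max_array_p) & (merged["coverage"] > min_cov)
    ]
    s = eligible["genotype_seq"].to_numpy()
    a = eligible["genotype_array"].to_numpy()
    n = len(eligible)

    array_ref = a == "ref_hom"
    fp = int(np.sum(array_ref & (s != "ref_hom")))
    fn = int(np.sum(~array_ref & (s == "ref_hom")))
    n_ref = int(array_ref.sum())
    n_var = n - n_ref

    s_hap = np.where(s == "het", "alt_hom", s)
    a_hap = np.where(a == "het", "alt_hom", a)

    confusion = {
        ga: {gs: int(np.sum((a == ga) & (s == gs))) for gs in GENOTYPES} for ga in GENOTYPES
    }
    return ConcordanceReport(
        n_compared=n,
        false_positive_rate=fp / n_ref if n_ref else 0.0,
        false_negative_rate=fn / n_var if n_var else 0.0,
        accuracy=float(np.mean(s == a)) if n else 0.0,
        haploid_concordance=float(np.mean(s_hap == a_hap)) if n else 0.0,
        confusion=confusion,
    )


def concordance_vs_coverage(
    seq: pd.DataFrame,
    array: pd.DataFrame,
    coverage_grid: list[int],
    max_array_p: float = 0.1,
) -> pd.DataFrame:
    """One report per minimum-coverage value of a strictly increasing grid."""
    grid = list(coverage_grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("coverage grid must be strictly increasing")
    rows = []
    for c in grid:
        rep = compare(seq, array, min_cov=c, max_array_p=max_array_p)
        rows.append({"min_coverage": c, **{k: v for k, v in rep.to_dict().items() if k != "confusion"}})
    return pd.DataFrame(
        rows,
        columns=[
            "min_coverage",
            "n_compared",
            "false_positive_rate",
            "false_negative_rate",
            "accuracy",
            "haploid_concordance",
        ],
    )
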