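"""High-confidence substitution calling from per-site pileups.

A site is called when its total coverage strictly exceeds the coverage
floor and at least one of two evidence rules fires:

* strand-count rule: >= ``min_variant_reads`` variant reads with at
  least one on each strand;
* quality rule: the best variant-supporting quality strictly exceeds
  the quality threshold (a higher threshold applies when the site sits
  in or adjacent to a homopolymer run of >= 5 bases), with at least
  ``quality_branch_min_reads`` supporting reads.

Each call records which rule fired, the total coverage, the variant
read count and the variant allele fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SITE_KEY

logger = logging.getLogger(__name__)

CALL_COLUMNS = SITE_KEY + ["coverage", "alt_reads", "vaf", "rule"]


@dataclass
class CallerParams:
    min_variant_reads: int = 3
    require_both_strands: bool = True
    quality_threshold: float = 20.0
    homopolymer_quality_threshold: float = 30.0
    homopolymer_min_len: int = 5
    min_coverage: int = 10  # exclusive: a site needs coverage > min_coverage
    quality_branch_min_reads: int = 1

    def __post_init__(self) -> None:
        for name in (
            "min_variant_reads",
            "quality_threshold",
            "homopolymer_quality_threshold",
            "homopolymer_min_len",
            "min_coverage",
            "quality_branch_min_reads",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def validate_pileups(pileups: pd.DataFrame) -> pd.DataFrame:
    """Drop malformed records (negative counts, ref == alt), logging each."""
    counts = pileups[["ref_fwd", "ref_rev", "alt_fwd", "alt_rev"]]
    bad = (counts < 0).any(axis=1) | (pileups["ref"] == pileups["alt"])
    if bad.any():
        for _, row in pileups.loc[bad, SITE_KEY].iterrows():
            logger.warning(
                "rejecting malformed pileup record at %s:%s %s>%s",
                row["chrom"], row["pos"], row["ref"], row["alt"],
            )
    return pileups.loc[~bad]


def call_variants(pileups: pd.DataFrame, params: CallerParams | None = None) -> pd.DataFrame:
    """Apply the high-confidence evidence rules to a pileup table.

    Returns one row per called site, ordered by (chrom, pos), with the
    evidence path in ``rule`` ('strand' or 'quality'; 'strand' wins when
    both fire).
    """
    p = params or CallerParams()
    pileups = validate_pileups(pileups)
    alt_fwd = pileups["alt_fwd"].to_numpy()
    alt_rev = pileups["alt_rev"].to_numpy()
    alt_reads = alt_fwd + alt_rev
    coverage = pileups["ref_fwd"].to_numpy() + pileups["ref_rev"].to_numpy() + alt_reads

    strand_rule = alt_reads >= p.min_variant_reads
    if p.require_both_strands:
        strand_rule &= (alt_fwd >= 1) & (alt_rev >= 1)

    qthresh = np.where(
        pileups["homopolymer_len"].to_numpy() >= p.homopolymer_min_len,
        p.homopolymer_quality_threshold,
        p.quality_threshold,
    )
    quality_rule = (alt_reads >= p.quality_branch_min_reads) & (
        pileups["max_alt_quality"].to_numpy() > qthresh
    )

    called = (coverage > p.min_coverage) & (strand_rule | quality_rule)
    out = pileups.loc[called, SITE_KEY].copy()
    out["coverage"] = coverage[called]
    out["alt_reads"] = alt_reads[called]
    out["vaf"] = np.where(coverage[called] > 0, alt_reads[called] / coverage[called], 0.0)
    out["rule"] = np.where(strand_rule[called], "strand", "quality")
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
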