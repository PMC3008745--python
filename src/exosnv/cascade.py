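"""Multi-stage prioritization of somatic variants.

The cascade narrows labelled-somatic variants to a prioritized set:

1. severity gate — keep consequences with potential functional impact
   (everything except synonymous / intronic / intergenic by default);
2. population-frequency filter — drop variants catalogued with minor
   allele frequency or average heterozygosity above 1%;
3. functional-impairment filter — keep variants flagged damaging by at
   least one of two external predictors (or both, in ``all`` mode);
4. conservation stage — keep sites whose per-base conservation score
   meets the threshold (default 2.0, the 0.975 quantile of all scores);
5. expression stage — keep variants in genes whose mean expression
   across samples reaches the first quartile of genewise means.

Category and catalogue memberships (repair / kinase / receptor /
transmembrane receptor; cancer census, prior study) are attached as
flags; the count of category-flagged survivors is reported but does not
filter the final set.  Missing annotations fail closed (the variant is
dropped by that stage) with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import SEVERITY_ORDER
from .simulate import SITE_KEY, AnnotationTables

logger = logging.getLogger(__name__)

DEFAULT_IMPACT_CLASSES = frozenset(
    c for c in SEVERITY_ORDER if c not in {"synonymous", "intronic", "intergenic"}
)


@dataclass
class CascadeParams:
    impact_classes: frozenset[str] = DEFAULT_IMPACT_CLASSES
    frequency_threshold: float = 0.01
    functional_mode: str = "any"  # 'any' | 'all'
    conservation_threshold: float | None = 2.0  # None => derive 0.975 quantile from the table
    conservation_quantile: float = 0.975
    expression_quantile: float = 0.25
    include_conservation_stage: bool = True
    include_expression_stage: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.frequency_threshold < 1.0):
            raise ValueError("frequency_threshold must be in (0, 1)")
        if self.functional_mode not in ("any", "all"):
            raise ValueError("functional_mode must be 'any' or 'all'")


@dataclass
class CascadeResult:
    stage_counts: dict[str, int]
    final: pd.DataFrame
    per_gene: pd.DataFrame = field(default_factory=pd.DataFrame)
    categorized_count: int = 0


def filter_severity(
    variants: pd.DataFrame, impact_classes: frozenset[str] = DEFAULT_IMPACT_CLASSES
) -> pd.DataFrame:
    return variants.loc[variants["consequence"].isin(impact_classes)]


def filter_frequency(
    variants: pd.DataFrame, frequency: pd.DataFrame, threshold: float = 0.01
) -> pd.DataFrame:
    """Keep variants absent from the population table or rarer than the
    threshold (strict: frequency must be < threshold to survive;
    catalogued variants at or above it are considered known polymorphisms)."""
    merged = variants.merge(frequency[SITE_KEY + ["frequency"]], on=SITE_KEY, how="left")
    keep = merged["frequency"].isna() | (merged["frequency"] < threshold)
    return variants.loc[keep.to_numpy()]


def filter_functional(
    variants: pd.DataFrame, damaging: pd.DataFrame, mode: str = "any"
) -> pd.DataFrame:
    """Keep variants flagged damaging by >=1 predictor (``any``) or by
    both (``all``). Variants absent from the flag table are dropped."""
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    merged = variants.merge(
        damaging[SITE_KEY + ["predictor_a", "predictor_b"]], on=SITE_KEY, how="left"
    )
    a = merged["predictor_a"].notna() & merged["predictor_a"].eq(True)
    b = merged["predictor_b"].notna() & merged["predictor_b"].eq(True)
    missing = merged["predictor_a"].isna()
    if missing.any():
        logger.warning("%d variants missing damaging-prediction flags; dropped", missing.sum())
    keep = (a | b) if mode == "any" else (a & b)
    return variants.loc[keep.to_numpy()]


def conservation_threshold(scores, quantile: float = 0.975) -> float:
    """Empirical quantile of a conservation-score collection (linearly
    interpolated order statistics, numpy's default)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot compute a quantile of an empty score collection")
    return float(np.quantile(scores, quantile))


def filter_conserved(
    variants: pd.DataFrame, conservation: pd.DataFrame, threshold: float = 2.0
) -> pd.DataFrame:
    """Keep variants whose site conservation score is >= threshold
    (inclusive). Missing scores fail closed with a warning."""
    merged = variants.merge(conservation[SITE_KEY + ["score"]], on=SITE_KEY, how="left")
    missing = merged["score"].isna()
    if missing.any():
        logger.warning("%d variants missing conservation scores; dropped", missing.sum())
    keep = merged["score"] >= threshold
    return variants.loc[keep.fillna(False).to_numpy()]


def filter_expressed(
    variants: pd.DataFrame, expression: pd.DataFrame, quantile: float = 0.25
) -> pd.DataFrame:
    """Keep variants whose gene's mean expression across samples reaches
    the given quantile of genewise means (inclusive at the boundary).
    Genes absent from the matrix fail closed with a warning."""
    sample_cols = [c for c in expression.columns if c != "gene_id"]
    if not sample_cols:
        raise ValueError("expression matrix has no sample columns")
    means = expression.set_index("gene_id")[sample_cols].mean(axis=1)
    thr = float(np.quantile(means.to_numpy(), quantile)) if len(means) else np.inf
    gene_mean = variants["gene_id"].map(means)
    missing = gene_mean.isna()
    if missing.any():
        logger.warning("%d variants in genes absent from expression matrix; dropped", missing.sum())
    return variants.loc[(gene_mean >= thr).fillna(False).to_numpy()]


def flag_categories(
    variants: pd.DataFrame,
    categories: dict[str, set[str]],
    catalogues: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Attach boolean gene-category and catalogue membership flags.
    Pure annotation — never filters."""
    out = variants.copy()
    for name, genes in categories.items():
        out[name] = out["gene_id"].isin(genes)
    for name, genes in (catalogues or {}).items():
        out[name] = out["gene_id"].isin(genes)
    return out


def run_cascade(
    variants: pd.DataFrame,
    tables: AnnotationTables,
    params: CascadeParams | None = None,
) -> CascadeResult:
    """Run all stages in order and record surviving counts at each."""
    p = params or CascadeParams()
    variants = variants.sort_values(SITE_KEY, kind="mergesort").reset_index(drop=True)
    counts: dict[str, int] = {"input": len(variants)}

    current = filter_severity(variants, p.impact_classes)
    counts["impact"] = len(current)
    current = filter_frequency(current, tables.frequency, p.frequency_threshold)
    counts["rare"] = len(current)
    current = filter_functional(current, tables.damaging, p.functional_mode)
    counts["damaging"] = len(current)
    if p.include_conservation_stage:
        thr = (
            p.conservation_threshold
            if p.conservation_threshold is not None
            else conservation_threshold(tables.conservation["score"], p.conservation_quantile)
        )
        current = filter_conserved(current, tables.conservation, thr)
        counts["conserved"] = len(current)
    if p.include_expression_stage:
        current = filter_expressed(current, tables.expression, p.expression_quantile)
        counts["expressed"] = len(current)

    final = flag_categories(current, tables.categories, tables.catalogues).reset_index(drop=True)
    category_cols = list(tables.categories)
    categorized = int(final[category_cols].any(axis=1).sum()) if category_cols else 0
    counts["categorized"] = categorized

    if len(final):
        per_gene = (
            final.groupby("gene_id")
            .size()
            .rename("n_variants")
            .reset_index()
            .sort_values(["n_variants", "gene_id"], ascending=[False, True], kind="mergesort")
            .reset_index(drop=True)
        )
    else:
        per_gene = pd.DataFrame(columns=["gene_id", "n_variants"])
    return CascadeResult(
        stage_counts=counts, final=final, per_gene=per_gene, categorized_count=categorized
    )
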