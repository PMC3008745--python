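"""End-to-end orchestration: simulate -> call -> classify -> annotate ->
prioritize -> cnv -> concord -> report.

A run is driven by a YAML config describing a cohort of simulated
patients (each an MSI-like or MSS-like preset with optional parameter
overrides) and writes every stage artifact plus a manifest under the
output directory.  Reruns with the same config and seed are
byte-identical: no timestamps enter any artifact.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import SEVERITY_ORDER, annotate_variants, most_severe
from .calling import CallerParams, call_variants
from .cascade import CascadeParams, run_cascade
from .cnv import SegmentationParams, call_states, compute_ratios, segment_ratios
from .concordance import call_genotypes, compare
from .config import SimulationConfig, msi_preset, mss_preset
from .genemodels import Genome
from .io import (
    write_bed,
    write_fasta,
    write_gff3,
    write_json,
    write_tsv,
    write_vcf,
)
from .simulate import (
    SITE_KEY,
    simulate_annotation_tables,
    simulate_array_genotypes,
    simulate_cnv_counts,
    simulate_gene_models,
    simulate_pair,
)
from .somatic import BimodalParams, classify, filter_tumor_calls

logger = logging.getLogger(__name__)

STAGES = ["simulate", "call", "classify", "annotate", "prioritize", "cnv", "concord", "report"]

PRESETS = {"msi": msi_preset, "mss": mss_preset}


@dataclass
class RunSummary:
    """Cross-patient summary of a cohort run."""

    somatic_counts: dict[str, int]
    nonsynonymous_counts: dict[str, int]
    consequence_fractions: dict[str, dict[str, float]]
    cascade_counts: dict[str, dict[str, int]]
    cnv_segment_counts: dict[str, dict[str, int]]
    fold_ratio_matrix: dict[str, dict[str, float | None]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "somatic_counts": self.somatic_counts,
            "nonsynonymous_counts": self.nonsynonymous_counts,
            "consequence_fractions": self.consequence_fractions,
            "cascade_counts": self.cascade_counts,
            "cnv_segment_counts": self.cnv_segment_counts,
            "fold_ratio_matrix": self.fold_ratio_matrix,
        }


def fold_ratio(count_a: float, count_b: float) -> float:
    """Mutation-burden ratio between two patients."""
    if count_b <= 0:
        raise ValueError("fold_ratio denominator must be positive")
    return count_a / count_b


def fold_ratio_matrix(counts: dict[str, int]) -> dict[str, dict[str, float | None]]:
    """All pairwise burden ratios; None where the denominator is zero."""
    return {
        a: {b: (fold_ratio(ca, cb) if cb > 0 else None) for b, cb in counts.items()}
        for a, ca in counts.items()
    }


def summarize(patient_results: dict[str, dict]) -> RunSummary:
    """Aggregate per-patient stage outputs into a RunSummary.

    ``patient_results`` maps patient id to the dict produced by
    ``run_patient``; missing stage outputs raise ``KeyError`` naming the
    stage.
    """
    required = ("somatic", "consequences", "cascade_counts", "cnv_states")
    for pid, res in patient_results.items():
        for key in required:
            if key not in res:
                raise KeyError(f"patient {pid} is missing stage output {key!r}")

    somatic_counts: dict[str, int] = {}
    nonsyn_counts: dict[str, int] = {}
    fractions: dict[str, dict[str, float]] = {}
    cascade_counts: dict[str, dict[str, int]] = {}
    cnv_counts: dict[str, dict[str, int]] = {}
    nonsyn_classes = {c for c in SEVERITY_ORDER if c not in {"synonymous", "intronic", "intergenic"}}
    for pid, res in patient_results.items():
        cons: pd.Series = res["consequences"]
        somatic_counts[pid] = int(len(cons))
        nonsyn_counts[pid] = int(cons.isin(nonsyn_classes).sum())
        total = len(cons)
        fractions[pid] = (
            {c: float(n) / total for c, n in cons.value_counts().sort_index().items()}
            if total
            else {}
        )
        cascade_counts[pid] = dict(res["cascade_counts"])
        cnv_counts[pid] = dict(res["cnv_states"])
    return RunSummary(
        somatic_counts=somatic_counts,
        nonsynonymous_counts=nonsyn_counts,
        consequence_fractions=fractions,
        cascade_counts=cascade_counts,
        cnv_segment_counts=cnv_counts,
        fold_ratio_matrix=fold_ratio_matrix(nonsyn_counts),
    )


def _fill_truth_consequences(truth: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Annotate the variant sites of the truth table (most severe class)."""
    truth = truth.copy()
    is_var = (truth["tumor_genotype"] != "ref_hom") | (truth["normal_genotype"] != "ref_hom")
    if is_var.any():
        ann = most_severe(annotate_variants(truth.loc[is_var, SITE_KEY], genome))
        cons = truth.loc[is_var, SITE_KEY].merge(ann, on=SITE_KEY, how="left")["consequence"]
        truth.loc[is_var, "consequence"] = cons.to_numpy()
        # truth gene assignment follows the most severe annotation where it names a gene
        gene = truth.loc[is_var, SITE_KEY].merge(ann, on=SITE_KEY, how="left")["gene_id"]
        keep = gene.notna() & (gene != ".")
        truth.loc[truth.index[is_var][keep.to_numpy()], "gene_id"] = gene[keep].to_numpy()
    return truth


def run_patient(
    cfg: SimulationConfig,
    genome: Genome,
    outdir: Path,
    caller_params: CallerParams | None = None,
    bimodal_params: BimodalParams | None = None,
    cascade_params: CascadeParams | None = None,
) -> dict:
    """Run every stage for one simulated patient; returns stage outputs."""
    outdir.mkdir(parents=True, exist_ok=True)

    tumor, normal, truth = simulate_pair(cfg, genome)
    truth = _fill_truth_consequences(truth, genome)
    tables = simulate_annotation_tables(cfg, truth)
    write_tsv(tumor, outdir / "tumor_pileup.tsv")
    write_tsv(normal, outdir / "normal_pileup.tsv")
    write_tsv(truth, outdir / "truth.tsv")
    write_tsv(tables.frequency, outdir / "population_frequency.tsv")
    write_tsv(tables.damaging, outdir / "damaging_flags.tsv")
    write_tsv(tables.conservation, outdir / "conservation.tsv")
    write_tsv(tables.expression, outdir / "expression.tsv")

    calls = call_variants(tumor, caller_params)
    write_tsv(calls, outdir / "calls.tsv")
    write_vcf(calls, outdir / "calls.vcf")

    stringent = filter_tumor_calls(calls, bimodal_params)
    records = classify(stringent, normal, bimodal_params)
    write_tsv(records, outdir / "somatic_records.tsv")
    write_vcf(records, outdir / "somatic_records.vcf")
    somatic = records[records["status"] == "somatic"].reset_index(drop=True)

    annotations = annotate_variants(somatic[SITE_KEY], genome)
    write_tsv(annotations, outdir / "annotations.tsv")
    severe = most_severe(annotations)
    somatic_annotated = somatic.merge(
        severe[SITE_KEY + ["gene_id", "consequence"]], on=SITE_KEY, how="left"
    )

    cascade = run_cascade(somatic_annotated, tables, cascade_params)
    write_tsv(cascade.final, outdir / "prioritized.tsv")
    write_tsv(cascade.per_gene, outdir / "prioritized_per_gene.tsv")
    write_json(cascade.stage_counts, outdir / "cascade_counts.json")

    bins, cnv_truth = simulate_cnv_counts(cfg)
    write_tsv(bins, outdir / "cnv_bins.tsv")
    write_tsv(cnv_truth, outdir / "cnv_truth.tsv")
    profile = compute_ratios(bins)
    segments = segment_ratios(profile, SegmentationParams(seed=cfg.seed))
    segments = call_states(segments, profile)
    write_bed(segments, cfg.bin_size, outdir / "cnv_segments.bed")
    cnv_states = segments["state"].value_counts().to_dict() if len(segments) else {}

    seq_gt = call_genotypes(normal)
    array_gt = simulate_array_genotypes(cfg, truth)
    report = compare(seq_gt, array_gt)
    write_json(report.to_dict(), outdir / "concordance.json")

    return {
        "config": cfg,
        "truth": truth,
        "calls": calls,
        "records": records,
        "somatic": somatic_annotated,
        "consequences": somatic_annotated["consequence"].fillna("intergenic"),
        "cascade_counts": cascade.stage_counts,
        "cascade": cascade,
        "segments": segments,
        "cnv_states": {k: int(v) for k, v in sorted(cnv_states.items())},
        "concordance": report,
    }


def _patient_config(entry: dict, generator: dict, base_seed: int, index: int) -> SimulationConfig:
    preset_name = entry.get("preset", "mss")
    if preset_name not in PRESETS:
        raise ValueError(f"unknown preset {preset_name!r}; expected one of {sorted(PRESETS)}")
    params = dict(generator)
    params.update(entry.get("overrides", {}))
    if "planted_segments" in params:
        params["planted_segments"] = [
            (int(s), int(e), float(x)) for s, e, x in params["planted_segments"]
        ]
    params["seed"] = (int(base_seed) * 1009 + 7 * (index + 1)) % (2**31)
    return PRESETS[preset_name](**params)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: dict | str | Path, outdir: str | Path) -> dict:
    """Execute the full pipeline for every patient in the cohort config.

    ``config`` is a dict (or path to YAML) with keys ``seed``,
    ``generator`` (shared SimulationConfig fields) and ``patients``
    (list of {id, preset, overrides}).  Returns the manifest.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    generator = dict(config.get("generator", {}))
    patients = config.get("patients") or [{"id": "patient_1", "preset": "mss"}]

    genome_cfg = SimulationConfig(
        **{k: v for k, v in generator.items() if k in ("n_genes",)}, seed=seed
    )
    genome = simulate_gene_models(genome_cfg)
    write_fasta(genome.reference, outdir / "reference.fa")
    write_gff3(genome, outdir / "models.gff3")

    results: dict[str, dict] = {}
    for i, entry in enumerate(patients):
        pid = entry.get("id", f"patient_{i + 1}")
        cfg = _patient_config(entry, generator, seed, i)
        logger.info("running patient %s (somatic_rate=%g)", pid, cfg.somatic_rate)
        try:
            results[pid] = run_patient(cfg, genome, outdir / pid)
        except Exception as exc:  # re-raise naming the patient
            raise RuntimeError(f"pipeline failed for patient {pid}: {exc}") from exc

    summary = summarize(results)
    write_json(summary.to_dict(), outdir / "summary.json")

    artifacts = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "tool": "exosnv",
        "version": __version__,
        "seed": seed,
        "stages": STAGES,
        "patients": [entry.get("id", f"patient_{i + 1}") for i, entry in enumerate(patients)],
        "config": {
            "seed": seed,
            "generator": generator,
            "patients": patients,
        },
        "artifacts": {name: _sha256(outdir / name) for name in artifacts},
    }
    write_json(manifest, outdir / "manifest.json")
    return manifest
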