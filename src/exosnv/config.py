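"""Simulation and pipeline configuration.

The synthetic cohort emulates the statistical structure of a matched
tumor/normal exome experiment: per-site read pileups under binomial
sampling, germline heterozygous variants, somatic variants at a
per-patient rate (hypermutated MSI-like tumors vs MSS-like tumors),
sequencing error, annotation side tables, and binned read counts with
planted copy-number segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

GENOTYPES = ("ref_hom", "het", "alt_hom")

#: Somatic per-site rates for the two tumor phenotypes.  The ratio (8:1)
#: mirrors the hypermutation excess of mismatch-repair-deficient (MSI)
#: over MSS tumors; the absolute values are desk-scale so that a cohort
#: of tens of thousands of sites yields usable somatic counts.
MSI_SOMATIC_RATE = 0.008
MSS_SOMATIC_RATE = 0.001


def _check_prob(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and 0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a finite probability in [0, 1], got {value!r}")


def _check_pos(name: str, value: float, strict: bool = True) -> None:
    ok = isinstance(value, (int, float)) and math.isfinite(value)
    if strict:
        ok = ok and value > 0
    else:
        ok = ok and value >= 0
    if not ok:
        raise ValueError(f"{name} must be finite and {'>' if strict else '>='} 0, got {value!r}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic tumor/normal experiment.

    Coverage is drawn per site from a Poisson distribution around the
    configured mean.  ``error_rate`` is the per-read probability that a
    read drawn from the reference allele is recorded as supporting the
    site's alternate allele.  ``heterozygosity_rate`` is the per-site
    probability of a germline heterozygous variant; homozygous alternate
    sites occur at ``hom_alt_rate`` (Hardy-Weinberg-like default
    ``(heterozygosity_rate / 2) ** 2``).  Somatic variants are planted
    only at germline-reference sites, heterozygous in the tumor-cell
    population, so their expected allele fraction is
    ``0.5 * tumor_purity``.
    """

    n_sites: int = 2_000
    mean_coverage_tumor: float = 20.0
    mean_coverage_normal: float = 20.0
    error_rate: float = 1e-3
    heterozygosity_rate: float = 1e-3
    hom_alt_rate: float | None = None
    somatic_rate: float = MSS_SOMATIC_RATE
    tumor_purity: float = 0.8

    # annotation side-table composition
    damaging_fraction: float = 0.4
    conserved_fraction: float = 0.025
    expressed_fraction: float = 0.75
    frequent_fraction: float = 0.8

    # per-read quality: two-point mixture so both quality branches of the
    # caller are exercised
    quality_high: int = 35
    quality_low: int = 15
    p_quality_high: float = 0.9
    homopolymer_fraction: float = 0.05

    # gene-model generator
    n_genes: int = 20

    # CNV generator
    bin_count: int = 300
    bin_size: int = 50_000
    cnv_base_rate: float = 500.0
    planted_segments: list[tuple[int, int, float]] = field(default_factory=list)

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_sites", "n_genes", "bin_count", "bin_size"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        _check_pos("mean_coverage_tumor", self.mean_coverage_tumor)
        _check_pos("mean_coverage_normal", self.mean_coverage_normal)
        _check_pos("cnv_base_rate", self.cnv_base_rate)
        for name in (
            "error_rate",
            "heterozygosity_rate",
            "somatic_rate",
            "tumor_purity",
            "damaging_fraction",
            "conserved_fraction",
            "expressed_fraction",
            "frequent_fraction",
            "p_quality_high",
            "homopolymer_fraction",
        ):
            _check_prob(name, getattr(self, name))
        if self.hom_alt_rate is not None:
            _check_prob("hom_alt_rate", self.hom_alt_rate)
        if self.heterozygosity_rate + self.effective_hom_alt_rate > 1.0:
            raise ValueError("heterozygosity_rate + hom_alt_rate exceeds 1")
        for seg in self.planted_segments:
            start, end, _ = seg
            if not (0 <= start <= end < self.bin_count):
                raise ValueError(f"planted segment {seg} outside [0, {self.bin_count})")
        spans = sorted((int(s), int(e)) for s, e, _ in self.planted_segments)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("planted CNV segments overlap")

    @property
    def effective_hom_alt_rate(self) -> float:
        if self.hom_alt_rate is not None:
            return self.hom_alt_rate
        return (self.heterozygosity_rate / 2.0) ** 2

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["planted_segments"] = [list(map(float, s)) for s in self.planted_segments]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "planted_segments" in d:
            d["planted_segments"] = [
                (int(s), int(e), float(x)) for s, e, x in d["planted_segments"]
            ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def msi_preset(**overrides) -> SimulationConfig:
    """Config for a hypermutated, microsatellite-instable tumor."""
    overrides.setdefault("somatic_rate", MSI_SOMATIC_RATE)
    return SimulationConfig(**overrides)


def mss_preset(**overrides) -> SimulationConfig:
    """Config for a microsatellite-stable tumor (low somatic rate)."""
    overrides.setdefault("somatic_rate", MSS_SOMATIC_RATE)
    return SimulationConfig(**overrides)
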