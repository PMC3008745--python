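"""Synthetic reference sequence and transcript models.

Generates a single-chromosome reference with non-overlapping genes, each
carrying one or more spliced transcripts (5'UTR, CDS, 3'UTR over 1-4
exons), plus a handful of intergenic miRNA intervals.  Every CDS starts
with ATG, ends with a stop codon, has spliced length divisible by three
and no internal stop.  The first gene always carries two transcripts that
disagree at shared bases: transcript 2 uses a planted in-frame internal
ATG, so the region between the two start codons is CDS in transcript 1
but 5'UTR in transcript 2 — the multi-annotation situation the
consequence annotator must handle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = [
    "".join(c) for c in itertools.product(BASES, repeat=3) if "".join(c) not in STOP_CODONS
]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """One spliced transcript. Intervals are 0-based half-open, genomic,
    sorted in ascending genomic order regardless of strand."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if not (s1 < e1 <= s2 < e2):
                    raise ValueError(f"{name} of {self.transcript_id} not sorted/disjoint")
        cds_len = sum(e - s for s, e in self.cds)
        if cds_len % 3 != 0:
            raise ValueError(f"CDS length of {self.transcript_id} not a multiple of 3")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_start(self) -> int:
        return self.cds[0][0]

    @property
    def cds_end(self) -> int:
        return self.cds[-1][1]

    def spliced_cds(self, reference: dict[str, str]) -> str:
        """CDS sequence in translation order (revcomp'd on minus strand)."""
        seq = "".join(reference[self.chrom][s:e] for s, e in self.cds)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class Genome:
    reference: dict[str, str]
    transcripts: list[TranscriptModel]
    mirna: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "name"])
    )

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.transcripts:
            seen.setdefault(t.gene_id, None)
        return list(seen)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, n)])


def _mirror(intervals: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    return sorted((length - e, length - s) for s, e in intervals)


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    strand: str,
    two_transcripts: bool,
) -> tuple[str, list[TranscriptModel]]:
    """Build one gene in local coordinates (sequence starting at 0)."""
    utr5_len = int(rng.integers(15, 61))
    utr3_len = int(rng.integers(15, 61))
    n_codons = int(rng.integers(30, 81))
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    mid = n_codons // 2
    if two_transcripts:
        codons[mid] = "ATG"  # planted in-frame internal start for transcript 2
    cds_mrna = "ATG" + "".join(codons) + STOP_CODONS[rng.integers(0, 3)]
    mrna = _random_seq(rng, utr5_len) + cds_mrna + _random_seq(rng, utr3_len)
    cds_m = (utr5_len, utr5_len + len(cds_mrna))

    # split the mRNA into exons, insert introns
    n_exons = int(rng.integers(1, 5))
    cuts: list[int] = []
    if n_exons > 1:
        candidates = np.arange(10, len(mrna) - 10)
        if len(candidates) >= n_exons - 1:
            cuts = sorted(rng.choice(candidates, size=n_exons - 1, replace=False).tolist())
            cuts = [c for i, c in enumerate(cuts) if i == 0 or c - cuts[i - 1] >= 10]
    bounds = [0, *cuts, len(mrna)]

    seq_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    cursor = 0
    mrna_to_local: list[tuple[int, int, int]] = []  # (mrna_start, mrna_end, local_start)
    for i, (ms, me) in enumerate(zip(bounds, bounds[1:])):
        if i > 0:
            intron = _random_seq(rng, int(rng.integers(30, 82)))
            seq_parts.append(intron)
            cursor += len(intron)
        seq_parts.append(mrna[ms:me])
        exons.append((cursor, cursor + (me - ms)))
        mrna_to_local.append((ms, me, cursor))
        cursor += me - ms
    local_seq = "".join(seq_parts)

    def project(m_start: int, m_end: int) -> list[tuple[int, int]]:
        out = []
        for ms, me, ls in mrna_to_local:
            lo, hi = max(m_start, ms), min(m_end, me)
            if lo < hi:
                out.append((ls + (lo - ms), ls + (hi - ms)))
        return out

    cds_intervals = project(*cds_m)
    tx_specs = [(f"{gene_id}.t1", exons, cds_intervals)]
    if two_transcripts:
        # CDS from the planted internal ATG to the same stop codon
        cds2_m = (cds_m[0] + 3 * (mid + 1), cds_m[1])
        tx_specs.append((f"{gene_id}.t2", exons, project(*cds2_m)))

    length = len(local_seq)
    if strand == "-":
        local_seq = revcomp(local_seq)
    models = []
    for tx_id, ex, cd in tx_specs:
        if strand == "-":
            ex, cd = _mirror(ex, length), _mirror(cd, length)
        models.append(TranscriptModel(gene_id, tx_id, "chr1", strand, list(ex), list(cd)))
    return local_seq, models


def simulate_gene_models(config: SimulationConfig) -> Genome:
    """Generate the reference sequence, transcript models and miRNA intervals."""
    rng = np.random.default_rng([int(config.seed), 11])
    chrom = "chr1"
    parts: list[str] = []
    transcripts: list[TranscriptModel] = []
    cursor = 0
    for g in range(config.n_genes):
        gap = _random_seq(rng, int(rng.integers(60, 201)))
        parts.append(gap)
        cursor += len(gap)
        strand = "+" if (g == 0 or rng.random() < 0.5) else "-"
        gene_id = f"GENE{g + 1:04d}"
        local_seq, models = _build_gene(rng, gene_id, strand, two_transcripts=(g == 0))
        for m in models:
            m.exons = [(s + cursor, e + cursor) for s, e in m.exons]
            m.cds = [(s + cursor, e + cursor) for s, e in m.cds]
        transcripts.extend(models)
        parts.append(local_seq)
        cursor += len(local_seq)

    mirna_rows = []
    for k in range(3):
        gap = _random_seq(rng, int(rng.integers(120, 241)))
        parts.append(gap)
        start = cursor + int(rng.integers(20, 40))
        end = start + int(rng.integers(70, 91))
        mirna_rows.append({"chrom": chrom, "start": start, "end": end, "name": f"mir-{k + 1}"})
        cursor += len(gap)
    parts.append(_random_seq(rng, 100))
    reference = {chrom: "".join(parts)}
    mirna = pd.DataFrame(mirna_rows)
    return Genome(reference=reference, transcripts=transcripts, mirna=mirna)


def homopolymer_lengths(seq: str) -> np.ndarray:
    """For each position, the length of the longest homopolymer run that
    contains the position or is immediately adjacent to it."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    run_len = np.empty(n, dtype=np.int64)
    boundaries = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    for s, e in zip(starts, ends):
        run_len[s:e] = e - s
    out = run_len.copy()
    out[:-1] = np.maximum(out[:-1], run_len[1:])
    out[1:] = np.maximum(out[1:], run_len[:-1])
    return out
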