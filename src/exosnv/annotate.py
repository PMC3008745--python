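"""Consequence annotation of substitutions against transcript models.

Every variant is mapped onto all overlapping transcripts and one record
is emitted per (variant, transcript) — loci covered by several
transcripts deliberately receive several, possibly conflicting,
annotations (e.g. CDS in one transcript, UTR in another).  Interchange
coordinates are 1-based inclusive; internally everything is 0-based
half-open.  Codon extraction is strand-aware: on minus-strand
transcripts the spliced CDS is reverse-complemented and the alternate
base complemented before translation (standard genetic code, via
Biopython).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genemodels import Genome, TranscriptModel, revcomp
from .simulate import SITE_KEY

#: Consequence classes ordered from most to least severe; used to pick a
#: single representative class per variant when transcripts disagree.
SEVERITY_ORDER = [
    "nonsense",
    "start_lost",
    "stop_lost",
    "missense",
    "splice_site",
    "utr5",
    "utr3",
    "mirna",
    "synonymous",
    "intronic",
    "intergenic",
]
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

DEFAULT_SPLICE_WINDOW = 2

ANNOTATION_COLUMNS = SITE_KEY + [
    "gene_id",
    "transcript_id",
    "consequence",
    "ref_codon",
    "alt_codon",
    "ref_aa",
    "alt_aa",
    "protein_pos",
]


@dataclass
class ConsequenceAnnotation:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene_id: str
    transcript_id: str
    consequence: str
    ref_codon: str = "."
    alt_codon: str = "."
    ref_aa: str = "."
    alt_aa: str = "."
    protein_pos: int | None = None


def _classify_codon_change(codon_idx: int, ref_aa: str, alt_aa: str) -> str:
    if ref_aa == alt_aa:
        return "synonymous"
    if codon_idx == 0 and ref_aa == "M":
        return "start_lost"
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == "*":
        return "stop_lost"
    return "missense"


def _annotate_one_transcript(
    chrom: str,
    p0: int,
    ref: str,
    alt: str,
    t: TranscriptModel,
    reference: dict[str, str],
    splice_window: int,
) -> ConsequenceAnnotation:
    ann = ConsequenceAnnotation(chrom, p0 + 1, ref, alt, t.gene_id, t.transcript_id, "intronic")
    in_exon = any(s <= p0 < e for s, e in t.exons)
    if not in_exon:
        near = any(
            (s - splice_window <= p0 < s) or (e <= p0 < e + splice_window) for s, e in t.exons
        )
        ann.consequence = "splice_site" if near else "intronic"
        return ann

    in_cds = any(s <= p0 < e for s, e in t.cds)
    if not in_cds:
        before = p0 < t.cds_start
        if t.strand == "+":
            ann.consequence = "utr5" if before else "utr3"
        else:
            ann.consequence = "utr3" if before else "utr5"
        return ann

    # offset of p0 within the plus-order spliced CDS
    offset_plus = 0
    for s, e in t.cds:
        if p0 < s:
            break
        if p0 < e:
            offset_plus += p0 - s
            break
        offset_plus += e - s
    cds_seq = t.spliced_cds(reference)
    if t.strand == "+":
        offset = offset_plus
        alt_base = alt
    else:
        offset = len(cds_seq) - 1 - offset_plus
        alt_base = revcomp(alt)
    codon_idx, within = divmod(offset, 3)
    ref_codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    ann.consequence = _classify_codon_change(codon_idx, ref_aa, alt_aa)
    ann.ref_codon, ann.alt_codon = ref_codon, alt_codon
    ann.ref_aa, ann.alt_aa = ref_aa, alt_aa
    ann.protein_pos = codon_idx + 1
    return ann


def annotate_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genome: Genome,
    splice_window: int = DEFAULT_SPLICE_WINDOW,
) -> list[ConsequenceAnnotation]:
    """Annotate one substitution against every overlapping transcript.

    Returns one record per overlapping transcript, or a single
    intergenic record if none overlap.  Raises ``ValueError`` if the
    stated reference base disagrees with the reference sequence.
    """
    p0 = pos - 1
    seq = genome.reference.get(chrom)
    if seq is not None and 0 <= p0 < len(seq) and seq[p0] != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: variant says {ref!r}, sequence has {seq[p0]!r}"
        )
    hits = [
        _annotate_one_transcript(chrom, p0, ref, alt, t, genome.reference, splice_window)
        for t in genome.transcripts
        if t.chrom == chrom and t.start <= p0 < t.end
    ]
    if not hits:
        cls = "mirna" if _in_mirna(chrom, p0, genome.mirna) else "intergenic"
        hits = [ConsequenceAnnotation(chrom, pos, ref, alt, ".", ".", cls)]
    return hits


def _in_mirna(chrom: str, p0: int, mirna: pd.DataFrame) -> bool:
    if mirna.empty:
        return False
    m = mirna[mirna["chrom"] == chrom]
    return bool(((m["start"] <= p0) & (p0 < m["end"])).any())


def classify_region(positions: pd.DataFrame, mirna_intervals: pd.DataFrame) -> pd.Series:
    """Flag positions (chrom, pos; 1-based) falling inside miRNA intervals
    (0-based half-open)."""
    flags = np.zeros(len(positions), dtype=bool)
    if not mirna_intervals.empty:
        p0 = positions["pos"].to_numpy() - 1
        for _, iv in mirna_intervals.iterrows():
            flags |= (
                (positions["chrom"].to_numpy() == iv["chrom"])
                & (p0 >= iv["start"])
                & (p0 < iv["end"])
            )
    return pd.Series(flags, index=positions.index, name="mirna")


def annotate_variants(
    variants: pd.DataFrame, genome: Genome, splice_window: int = DEFAULT_SPLICE_WINDOW
) -> pd.DataFrame:
    """Annotate a variant table; one output row per (variant, transcript)."""
    rows = []
    for _, v in variants.iterrows():
        for ann in annotate_variant(
            v["chrom"], int(v["pos"]), v["ref"], v["alt"], genome, splice_window
        ):
            rows.append(ann.__dict__)
    out = pd.DataFrame(rows, columns=[c for c in ConsequenceAnnotation.__annotations__])
    out = out.rename(columns={})
    out["protein_pos"] = out["protein_pos"].astype("Int64") if len(out) else out["protein_pos"]
    return out[ANNOTATION_COLUMNS]


def most_severe(annotations: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-transcript annotations to one row per variant, keeping
    the most severe consequence (ties broken by transcript id)."""
    if annotations.empty:
        return annotations.copy()
    ann = annotations.copy()
    ann["_rank"] = ann["consequence"].map(_SEVERITY_RANK)
    ann = ann.sort_values(SITE_KEY + ["_rank", "transcript_id"], kind="mergesort")
    return ann.drop_duplicates(SITE_KEY, keep="first").drop(columns="_rank").reset_index(drop=True)
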