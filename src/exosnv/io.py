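"""File formats: pileup/annotation TSVs, minimal VCF v4.2, GFF3 subset,
FASTA, BED."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genemodels import Genome, TranscriptModel
from .simulate import PILEUP_COLUMNS

VCF_HEADER = [
    "##fileformat=VCFv4.2",
    "##source=exosnv",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total coverage">',
    '##INFO=<ID=AD,Number=1,Type=Integer,Description="Variant-supporting reads">',
    '##INFO=<ID=RULE,Number=1,Type=String,Description="Evidence rule (strand or quality)">',
    '##INFO=<ID=SS,Number=1,Type=String,Description="Somatic status (SOMATIC, GERMLINE, UNDET)">',
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
]
_SS_CODE = {"somatic": "SOMATIC", "germline": "GERMLINE", "undetermined": "UNDET"}


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup file {path} missing columns: {sorted(missing)}")
    return df[PILEUP_COLUMNS]


def write_vcf(df: pd.DataFrame, path) -> None:
    """Write calls (or classified somatic records) as a minimal VCF v4.2
    subset: CHROM POS ID REF ALT QUAL FILTER INFO with DP/AD/RULE and,
    when present, SS."""
    with open(path, "w") as fh:
        fh.write("\n".join(VCF_HEADER) + "\n")
        for _, r in df.iterrows():
            info = [f"DP={int(r['coverage'])}", f"AD={int(r['alt_reads'])}", f"RULE={r['rule']}"]
            if "status" in df.columns:
                info.append(f"SS={_SS_CODE[r['status']]}")
            fh.write(
                f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\t.\t{';'.join(info)}\n"
            )


def write_fasta(reference: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in reference.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genome: Genome, path) -> None:
    """GFF3 subset: gene / mRNA / exon / CDS (plus miRNA) features,
    1-based inclusive coordinates."""
    lines = ["##gff-version 3"]
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in genome.transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gene_id, txs in by_gene.items():
        chrom = txs[0].chrom
        strand = txs[0].strand
        g_start = min(t.start for t in txs) + 1
        g_end = max(t.end for t in txs)
        lines.append(
            f"{chrom}\texosnv\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\tID={gene_id}"
        )
        for t in txs:
            lines.append(
                f"{chrom}\texosnv\tmRNA\t{t.start + 1}\t{t.end}\t.\t{strand}\t.\t"
                f"ID={t.transcript_id};Parent={gene_id}"
            )
            for i, (s, e) in enumerate(t.exons, 1):
                lines.append(
                    f"{chrom}\texosnv\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"
                )
            for i, (s, e) in enumerate(t.cds, 1):
                lines.append(
                    f"{chrom}\texosnv\tCDS\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}"
                )
    for _, m in genome.mirna.iterrows():
        lines.append(
            f"{m['chrom']}\texosnv\tmiRNA\t{m['start'] + 1}\t{m['end']}\t.\t+\t.\tID={m['name']}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _attrs(field: str) -> dict[str, str]:
    return dict(kv.split("=", 1) for kv in field.split(";") if "=" in kv)


def read_gff3(path, reference: dict[str, str] | None = None) -> Genome:
    """Parse the gene/mRNA/exon/CDS/miRNA subset written by write_gff3."""
    mrna_parent: dict[str, str] = {}
    mrna_meta: dict[str, tuple[str, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    mirna_rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _, ftype, start, end, _, strand, _, attrs = line.split("\t")
        a = _attrs(attrs)
        s0, e0 = int(start) - 1, int(end)
        if ftype == "mRNA":
            mrna_parent[a["ID"]] = a["Parent"]
            mrna_meta[a["ID"]] = (chrom, strand)
        elif ftype == "exon":
            exons.setdefault(a["Parent"], []).append((s0, e0))
        elif ftype == "CDS":
            cds.setdefault(a["Parent"], []).append((s0, e0))
        elif ftype == "miRNA":
            mirna_rows.append({"chrom": chrom, "start": s0, "end": e0, "name": a["ID"]})
    transcripts = [
        TranscriptModel(
            gene_id=mrna_parent[tx],
            transcript_id=tx,
            chrom=mrna_meta[tx][0],
            strand=mrna_meta[tx][1],
            exons=sorted(exons[tx]),
            cds=sorted(cds.get(tx, [])),
        )
        for tx in mrna_parent
    ]
    mirna = pd.DataFrame(mirna_rows, columns=["chrom", "start", "end", "name"])
    return Genome(reference=reference or {}, transcripts=transcripts, mirna=mirna)


def write_bed(segments: pd.DataFrame, bin_size: int, path) -> None:
    """Segments as BED (0-based half-open genomic coordinates) with mean
    ratio and state columns."""
    with open(path, "w") as fh:
        for _, s in segments.iterrows():
            fh.write(
                f"{s['chrom']}\t{int(s['start_bin']) * bin_size}\t{int(s['end_bin']) * bin_size}\t"
                f"{s.get('state', '.')}\t{s['mean_ratio']:.4f}\n"
            )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
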