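"""Readers and writers for the pipeline's on-disk formats.

Counts and sample sheets are plain TSV; transcript models go to GTF
(1-based inclusive) and FASTA; genotypes to VCF v4.2; GWAS loci to BED
(0-based half-open); ground truth to JSON. All writers are deterministic:
the same inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .quantify import CountMatrix
from .seq_features import TranscriptModel


def write_counts_tsv(counts: CountMatrix, path) -> None:
    counts.values.to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(counts_path, samples_path) -> CountMatrix:
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    return CountMatrix(values[list(samples["sample_id"])], samples)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def write_matrix_tsv(matrix: pd.DataFrame, path, index_label: str = "gene") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def write_gtf(models: dict[str, TranscriptModel], path) -> None:
    """GTF with transcript / five_prime_utr / CDS / three_prime_utr rows
    (exon rows for lncRNAs)."""
    lines = []
    for gid in sorted(models):
        m = models[gid]
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; biotype "{m.biotype}";'
        feats = []
        if m.biotype == "coding":
            feats = [("five_prime_utr", m.utr5), ("CDS", m.cds), ("three_prime_utr", m.utr3)]
            span = (m.utr5[0], m.utr3[1])
        else:
            feats = [("exon", m.utr3)]
            span = m.utr3
        lines.append(
            "\t".join(
                [m.chrom, "ribofuse", "transcript", str(span[0]), str(span[1]), ".", m.strand, ".", attrs]
            )
        )
        for feat, iv in feats:
            lines.append(
                "\t".join(
                    [m.chrom, "ribofuse", feat, str(iv[0]), str(iv[1]), ".", m.strand, ".", attrs]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path) -> dict[str, TranscriptModel]:
    """Read transcript models from a GTF written by :func:`write_gtf`.

    Sequences are not stored in GTF; load them separately from FASTA when
    needed.
    """
    models: dict[str, TranscriptModel] = {}
    rows: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _, feat, start, end, _, strand, _, attrs = line.split("\t")
        fields = dict(
            part.strip().split(" ", 1) for part in attrs.strip(";").split(";") if part.strip()
        )
        gid = fields["gene_id"].strip('"')
        rec = rows.setdefault(
            gid,
            {
                "transcript_id": fields["transcript_id"].strip('"'),
                "chrom": chrom,
                "strand": strand,
                "biotype": fields.get("biotype", '"coding"').strip('"'),
            },
        )
        if feat in ("five_prime_utr", "CDS", "three_prime_utr", "exon"):
            rec[feat] = (int(start), int(end))
    for gid, rec in rows.items():
        if rec["biotype"] == "coding":
            models[gid] = TranscriptModel(
                gid, rec["transcript_id"], rec["chrom"], rec["strand"],
                rec["five_prime_utr"], rec["CDS"], rec["three_prime_utr"],
            )
        else:
            m = TranscriptModel(
                gid, rec["transcript_id"], rec["chrom"], rec["strand"],
                None, None, None, biotype="lncRNA",
            )
            m.utr3 = rec["exon"]
            models[gid] = m
    return models


def write_fasta(models: dict[str, TranscriptModel], path, width: int = 70) -> None:
    lines = []
    for gid in sorted(models):
        m = models[gid]
        lines.append(f">{m.transcript_id} gene={m.gene_id} biotype={m.biotype}")
        seq = m.sequence
        lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(lines) + "\n")


def write_vcf(variants: pd.DataFrame, genotypes: pd.DataFrame, path) -> None:
    """Minimal VCF v4.2 with GT fields; dosage 0/1/2 becomes 0/0, 0/1, 1/1
    and -1 becomes ./."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    samples = list(genotypes.columns)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=chrS>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for vid, rec in variants.iterrows():
        gts = "\t".join(gt_map[int(g)] for g in genotypes.loc[vid])
        lines.append(
            f"{rec['chrom']}\t{rec['pos']}\t{rec['variant_id']}\t{rec['ref']}\t{rec['alt']}"
            f"\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(loci: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in loci.columns else [])
    loci[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = ["chrom", "start", "end"] + [f"c{i}" for i in range(3, df.shape[1])]
    if df.shape[1] > 3:
        df = df.rename(columns={"c3": "name"})
    return df


def write_truth_json(truth, path) -> None:
    payload = {
        "true_edges": sorted(map(list, truth.true_edges)),
        "gene_class": truth.gene_class,
        "class_sign": truth.class_sign,
        "true_te": {
            f"{t}|{b}": truth.true_te[(t, b)].round(10).to_dict()
            for (t, b) in truth.true_te.columns
        },
        "causal_variants": truth.causal_variants,
        "tissue_specific_genes": {t: sorted(g) for t, g in truth.tissue_specific_genes.items()},
        "tf_ids": list(truth.tf_ids),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
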