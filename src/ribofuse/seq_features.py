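"""Sequence-feature determinants of translation efficiency.

UTR/CDS length statistics, upstream-AUG counting, TE percentile groups,
ORF category assignment (uORF/dORF/iORF/aORF/lORF), and grouped TE
comparisons against alternative-splicing events and active small-ORF
counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

AS_EVENT_TYPES = {"SE", "MXE", "A3SS", "A5SS", "RI"}

TE_GROUP_LABELS = ["Top1", "Top2", "Top3", "Top4", "Top5"]


@dataclass
class TranscriptModel:
    """Representative transcript of a gene.

    Genomic intervals are 1-based inclusive (GTF convention). For coding
    genes the 5'UTR, CDS and 3'UTR are contiguous and ordered 5'->3';
    lncRNA models carry a single exon and no CDS. Transcript-relative
    coordinates start at 0 at the transcript 5' end.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    utr5: tuple[int, int] | None
    cds: tuple[int, int] | None
    utr3: tuple[int, int] | None
    utr5_seq: str = ""
    cds_seq: str = ""
    utr3_seq: str = ""
    biotype: str = "coding"

    @property
    def utr5_len(self) -> int:
        return len(self.utr5_seq)

    @property
    def cds_len(self) -> int:
        return len(self.cds_seq)

    @property
    def utr3_len(self) -> int:
        return len(self.utr3_seq)

    @property
    def tx_len(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def sequence(self) -> str:
        return self.utr5_seq + self.cds_seq + self.utr3_seq

    @property
    def cds_tx_start(self) -> int:
        """Transcript-relative CDS start (0-based)."""
        return self.utr5_len

    @property
    def cds_tx_end(self) -> int:
        """Transcript-relative CDS end (0-based half-open)."""
        return self.utr5_len + self.cds_len


@dataclass
class ORFRecord:
    """An ORF on a host transcript, in transcript coordinates
    (0-based half-open)."""

    orf_id: str
    transcript_id: str
    start: int
    end: int
    category: str | None = None


def count_uaugs(utr5_sequence: str) -> int:
    """Number of AUG (DNA: ATG) occurrences in a 5'UTR, overlapping scan."""
    seq = utr5_sequence.upper()
    n = 0
    pos = seq.find("ATG")
    while pos != -1:
        n += 1
        pos = seq.find("ATG", pos + 1)
    return n


def te_percentile_groups(te_vector: pd.Series) -> pd.Series:
    """Quintile groups of TE: Top1 = highest 20%, Top5 = lowest 20%.

    Ranks are assigned on (TE, gene id) so ties resolve deterministically;
    quintile sizes differ by at most one gene.
    """
    te_vector = te_vector.dropna()
    n = len(te_vector)
    if n < 5:
        raise ValueError("need at least 5 genes for quintile groups")
    order = sorted(te_vector.index, key=lambda g: (-te_vector[g], g))
    labels = {}
    bounds = [round(i * n / 5) for i in range(6)]
    for q, lab in enumerate(TE_GROUP_LABELS):
        for g in order[bounds[q] : bounds[q + 1]]:
            labels[g] = lab
    return pd.Series(labels, name="te_group").reindex(te_vector.index)


def length_te_correlation(
    models: dict[str, TranscriptModel],
    te: pd.Series,
    min_tpm: float = 0.01,
    tpm: pd.Series | None = None,
) -> pd.DataFrame:
    """Spearman correlation of TE with 5'UTR, CDS and 3'UTR lengths.

    ``models`` maps gene -> representative transcript (callers should pick
    the highest-expressed transcript); genes below ``min_tpm`` are dropped
    when a TPM vector is supplied.
    """
    genes = [g for g in te.dropna().index if g in models and models[g].biotype == "coding"]
    if tpm is not None:
        genes = [g for g in genes if tpm.get(g, 0.0) > min_tpm]
    if len(genes) < 4:
        raise ValueError("need at least 4 genes")
    te_v = te[genes].to_numpy(dtype=float)
    rows = []
    for region, attr in [("utr5", "utr5_len"), ("cds", "cds_len"), ("utr3", "utr3_len")]:
        lengths = np.array([getattr(models[g], attr) for g in genes], dtype=float)
        rho, p = stats.spearmanr(lengths, te_v)
        rows.append({"region": region, "rho": rho, "p": p, "n": len(genes)})
    return pd.DataFrame(rows).set_index("region")


def classify_orf(orf: ORFRecord, model: TranscriptModel) -> str:
    """Assign an ORF to one of aORF / uORF / dORF / iORF / lORF.

    lORF: host is a lncRNA. aORF: overlaps the annotated CDS and shares its
    stop coordinate. uORF / dORF: entirely upstream / downstream of the CDS
    with no overlap. iORF: inside the CDS in a shifted reading frame.
    CDS-overlapping ORFs with a different stop but the annotated frame are
    returned as "unclassified".
    """
    if orf.start < 0 or orf.end > model.tx_len or orf.start >= orf.end:
        raise ValueError(f"ORF {orf.orf_id} outside transcript bounds")
    if model.biotype == "lncRNA":
        return "lORF"
    cds_start, cds_end = model.cds_tx_start, model.cds_tx_end
    overlaps = orf.start < cds_end and orf.end > cds_start
    if overlaps and orf.end == cds_end:
        return "aORF"
    if orf.end <= cds_start:
        return "uORF"
    if orf.start >= cds_end:
        return "dORF"
    inside = orf.start >= cds_start and orf.end <= cds_end
    frame = (orf.start - cds_start) % 3
    if inside and frame != 0:
        return "iORF"
    return "unclassified"


def _count_group(n: int) -> str:
    return "0" if n == 0 else ("1" if n == 1 else "2+")


def orf_te_association(
    active_counts: pd.DataFrame,
    cds_te: pd.Series,
) -> pd.DataFrame:
    """TE distributions grouped by active uORF / dORF counts (0, 1, 2+).

    ``active_counts`` needs columns n_uORF and n_dORF indexed by gene.
    Returns per (orf_type, group) the gene count, median TE, and the
    Mann-Whitney U p-value against the preceding group.
    """
    genes = active_counts.index.intersection(cds_te.dropna().index)
    rows = []
    for orf_type, col in [("uORF", "n_uORF"), ("dORF", "n_dORF")]:
        groups = {
            lab: cds_te[genes[active_counts.loc[genes, col].map(_count_group) == lab]]
            for lab in ["0", "1", "2+"]
        }
        prev = None
        for lab in ["0", "1", "2+"]:
            vals = groups[lab].to_numpy(dtype=float)
            p = np.nan
            if prev is not None and len(vals) >= 2 and len(prev) >= 2:
                p = stats.mannwhitneyu(prev, vals, alternative="two-sided").pvalue
            rows.append(
                {
                    "orf_type": orf_type,
                    "group": lab,
                    "n_genes": len(vals),
                    "median_te": float(np.median(vals)) if len(vals) else np.nan,
                    "p_vs_prev": p,
                }
            )
            prev = vals
    return pd.DataFrame(rows)


def as_te_groups(
    as_events: dict[str, list[str]],
    te: pd.Series,
) -> tuple[pd.Series, pd.DataFrame]:
    """Label genes by alternative-splicing status and compare TE per group.

    "No" = zero events; a single event labels the gene by its type; more
    than one event (any mix, including repeats of one type) = "More".
    Returns (labels, per-group comparison against the "No" group).
    """
    labels = {}
    for gene in te.index:
        events = as_events.get(gene, [])
        for ev in events:
            if ev not in AS_EVENT_TYPES:
                raise ValueError(f"unknown AS event type: {ev}")
        if len(events) == 0:
            labels[gene] = "No"
        elif len(events) == 1:
            labels[gene] = events[0]
        else:
            labels[gene] = "More"
    labels = pd.Series(labels, name="as_group").reindex(te.index)
    ref = te[labels == "No"].dropna().to_numpy(dtype=float)
    rows = []
    for lab in ["No", "More", "SE", "MXE", "A3SS", "A5SS", "RI"]:
        vals = te[labels == lab].dropna().to_numpy(dtype=float)
        p = np.nan
        if lab != "No" and len(vals) >= 2 and len(ref) >= 2:
            p = stats.mannwhitneyu(ref, vals, alternative="two-sided").pvalue
        rows.append(
            {
                "group": lab,
                "n_genes": len(vals),
                "median_te": float(np.median(vals)) if len(vals) else np.nan,
                "p_vs_no": p,
            }
        )
    return labels, pd.DataFrame(rows)
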