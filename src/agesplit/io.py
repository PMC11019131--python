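"""Readers and writers for the pipeline's plain-text interchange formats.

Everything flows through TSV (counts, lengths, sample sheet, result tables)
and FASTA (promoters); PWMs use the TRANSFAC text dialect handled by
:mod:`agesplit.tfbs`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import CountMatrix, ProteinMatrix, PromoterSet


def read_counts(counts_path, lengths_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts = counts.astype(int)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    sheet = pd.read_csv(samples_path, sep="\t", index_col=0)
    return CountMatrix(
        counts=counts,
        gene_lengths=lengths.loc[counts.index],
        groups=sheet["group"].loc[counts.columns],
    )


def write_counts(cm: CountMatrix, counts_path, lengths_path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    cm.gene_lengths.rename("length_bp").rename_axis("gene_id").to_csv(
        lengths_path, sep="\t"
    )


def write_sample_sheet(groups: pd.Series, batch: pd.Series | None, path) -> None:
    sheet = groups.rename("group").rename_axis("sample_id").to_frame()
    if batch is not None:
        sheet["batch"] = batch.reindex(sheet.index)
    sheet.to_csv(path, sep="\t")


def read_proteins(proteins_path, samples_path) -> ProteinMatrix:
    inten = pd.read_csv(proteins_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t", index_col=0)
    cols = [c for c in inten.columns if c in sheet.index]
    if "batch" not in sheet.columns:
        raise ValueError("sample sheet lacks a 'batch' column")
    return ProteinMatrix(
        intensities=inten[cols],
        batch=sheet["batch"].loc[cols],
        groups=sheet["group"].loc[cols],
    )


def write_proteins(pm: ProteinMatrix, path) -> None:
    pm.intensities.rename_axis("protein_id").to_csv(path, sep="\t")


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_promoters(path, role: str = "foreground") -> PromoterSet:
    return PromoterSet(read_fasta(path), role=role)


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)
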