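"""FASTA/FASTQ/TSV/GFF3 input-output, all through Biopython/pandas.

Reads are accepted plain or gzipped. Collapsed unique reads are written in the
conventional ``>seq<i>_x<count>`` FASTA form.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: str | Path) -> str:
    name = Path(path).name.removesuffix(".gz")
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered {id: sequence} mapping."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str]) -> None:
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items())
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def load_reads(path: str | Path, min_mean_quality: float = 20.0) -> tuple[list[str], int]:
    """Load read sequences from FASTA or FASTQ.

    FASTQ reads with mean Phred quality below ``min_mean_quality`` are dropped;
    FASTA input has no quality information so nothing is dropped here. Returns
    (sequences, number dropped as low-quality).
    """
    fmt = _sniff_format(path)
    seqs: list[str] = []
    n_lowq = 0
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            if fmt == "fastq":
                quals = rec.letter_annotations["phred_quality"]
                if quals and sum(quals) / len(quals) < min_mean_quality:
                    n_lowq += 1
                    continue
            seqs.append(str(rec.seq).upper())
    return seqs, n_lowq


def write_collapsed_fasta(path: str | Path, counts: Mapping[str, int]) -> None:
    """Write collapsed unique reads as ``>seq<i>_x<count>`` records."""
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(counts.items(), start=1):
            fh.write(f">seq{i}_x{count}\n{seq}\n")


def read_collapsed_fasta(path: str | Path) -> dict[str, int]:
    """Inverse of :func:`write_collapsed_fasta`; also accepts plain FASTA
    (each record then counts once per occurrence)."""
    counts: dict[str, int] = {}
    for name, seq in read_fasta(path).items():
        n = 1
        if "_x" in name:
            tail = name.rsplit("_x", 1)[1]
            if tail.isdigit():
                n = int(tail)
        counts[seq] = counts.get(seq, 0) + n
    return counts


def read_tag_table(path: str | Path) -> dict[str, int]:
    """Degradome tags as a two-column (sequence, count) TSV without header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["seq", "count"])
    return dict(zip(df["seq"].str.upper(), df["count"].astype(int)))


def write_tsv(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gff3(
    path: str | Path,
    records: Iterable[tuple[str, str, int, int, str, Mapping[str, str]]],
) -> None:
    """Write (seqid, type, start, end, strand, attributes) tuples as GFF3.

    Coordinates are 1-based inclusive, as GFF3 requires.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, ftype, start, end, strand, attrs in records:
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{seqid}\tcuresmir\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attr_s}\n"
            )


def read_gff3(path: str | Path) -> Iterator[tuple[str, str, int, int, str, dict[str, str]]]:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            yield f[0], f[2], int(f[3]), int(f[4]), f[6], attrs
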