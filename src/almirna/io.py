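"""File-format helpers: FASTA/FASTQ via Biopython, GFF3, TSV, collapsed reads.

All sequence I/O normalises RNA ``U`` to DNA ``T`` on input; FASTA output is
written with ``T``.  Collapsed small-RNA reads use the conventional header
dialect ``>tag<serial>_x<count>``.
"""

from __future__ import annotations

import csv
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "normalize_seq",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_fastq_seqs",
    "write_fastq",
    "write_collapsed_fasta",
    "read_collapsed_fasta",
    "write_gff3",
    "write_tsv",
]


def normalize_seq(seq: str) -> str:
    return str(seq).upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return str(Seq(normalize_seq(seq)).reverse_complement())


def read_fasta(path) -> list:
    """Read a FASTA file into a list of (id, sequence) with U->T applied."""
    return [(rec.id, normalize_seq(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, entries: Iterable) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{normalize_seq(seq)}\n")


def read_fastq_seqs(path) -> Iterator[str]:
    """Yield read sequences (U->T normalised) from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield normalize_seq(rec.seq)


def write_fastq(path, reads: Iterable, quality_char: str = "I") -> None:
    """Write (name, sequence) reads with a constant Phred+33 quality line."""
    with open(path, "w") as fh:
        for name, seq in reads:
            seq = normalize_seq(seq)
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_collapsed_fasta(path, tag_counts: Iterable) -> None:
    """Write (sequence, count) pairs as ``>tag<k>_x<count>`` FASTA records."""
    with open(path, "w") as fh:
        for k, (seq, count) in enumerate(tag_counts, start=1):
            fh.write(f">tag{k}_x{int(count)}\n{normalize_seq(seq)}\n")


def read_collapsed_fasta(path) -> list:
    """Read ``>tag<k>_x<count>`` records back into (sequence, count) pairs."""
    out = []
    for name, seq in read_fasta(path):
        try:
            count = int(name.rsplit("_x", 1)[1])
        except (IndexError, ValueError):
            raise ValueError(f"malformed collapsed-read header {name!r}") from None
        out.append((seq, count))
    return out


def write_gff3(path, features: Iterable) -> None:
    """Write features (seqid, source, type, start, end, strand, attributes).

    Coordinates are 1-based inclusive; ``attributes`` is a dict.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, source, ftype, start, end, strand, attrs in features:
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attr_s}\n"
            )


def write_tsv(path, rows: Iterable, header: list) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for row in rows:
            w.writerow(row)
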