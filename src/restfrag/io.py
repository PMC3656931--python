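"""Readers and writers: FASTA/FASTQ (plain or gzip, via Biopython), BED6
fragment intervals, and tab-separated report tables.

BED output is 0-based half-open with name = ``<enzyme>/<ordinal>``, score =
round(1000 x fragment GC) and strand ".".  All tables are tab-delimited
with a header row and "." as the decimal separator.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enzymes import TERMINUS, Fragment
from .errors import ContractError, InputError
from .readqc import ReadRecord


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, uppercased sequence) in file order; ids are taken up to the
    first whitespace.  Plain or gzip.  Sequence data before the first header
    is a malformed record and reported with its line number; an empty file
    yields nothing, with a warning."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise InputError(
                        f"{path}: malformed FASTA, sequence before header at line {lineno}"
                    )
                break
        else:
            warnings.warn(f"{path}: empty FASTA file")
            return
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq).upper()


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records),
            fh,
            "fasta",
        )


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Yield reads with phred qualities; plain or gzip."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield ReadRecord(
                rec.id,
                str(rec.seq),
                tuple(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    def to_seqrecord(read: ReadRecord) -> SeqRecord:
        rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
        quals = read.qualities if read.qualities is not None else (30,) * len(read)
        rec.letter_annotations["phred_quality"] = list(quals)
        return rec

    with _open_text(path, "wt") as fh:
        SeqIO.write((to_seqrecord(r) for r in reads), fh, "fastq")


def _fragment_name(frag: Fragment, ordinal: int) -> str:
    enzyme = next((f for f in frag.flanking if f != TERMINUS), "fragment")
    return f"{enzyme}/{ordinal}"


def write_bed(
    fragments: Sequence[Fragment],
    path: str | Path,
    genome: dict[str, str] | None = None,
) -> None:
    """Write fragments as BED6 (sorted per sequence required).  The score
    column is round(1000 x fragment GC) when the genome is supplied, else 0."""
    prev: Fragment | None = None
    with _open_text(path, "wt") as fh:
        for i, frag in enumerate(fragments):
            if prev is not None and frag.seq_id == prev.seq_id and frag.start < prev.start:
                raise ContractError(
                    f"write_bed requires fragments sorted per sequence; "
                    f"{frag.seq_id}:{frag.start} after {prev.start}"
                )
            score = 0
            if genome is not None:
                sub = genome[frag.seq_id][frag.start:frag.end].upper()
                gc = sub.count("G") + sub.count("C")
                denom = gc + sub.count("A") + sub.count("T")
                score = round(1000 * gc / denom) if denom else 0
            fh.write(
                f"{frag.seq_id}\t{frag.start}\t{frag.end}\t"
                f"{_fragment_name(frag, i)}\t{score}\t.\n"
            )
            prev = frag


def read_bed(path: str | Path) -> list[Fragment]:
    """Read BED back into fragments.  Flanking enzymes are reconstructed from
    the name column's ``enzyme/ordinal`` convention (terminal-fragment
    TERMINUS labels are not representable in BED and come back as the
    enzyme name)."""
    out: list[Fragment] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}: malformed BED line {lineno}")
            seq_id, start, end = fields[0], int(fields[1]), int(fields[2])
            enzyme = "fragment"
            if len(fields) >= 4 and "/" in fields[3]:
                enzyme = fields[3].split("/")[0]
            out.append(Fragment(seq_id, start, end, (enzyme, enzyme)))
    return out


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a report table: tab-separated, header row, full precision."""
    frame.to_csv(path, sep="\t", index=False)
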