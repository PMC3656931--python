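"""Seeded generators for synthetic genomes and protocol-faithful reads.

The genome generator draws i.i.d. bases with a chosen GC fraction — the
null model under which restriction fragments are Poisson-placed — and can
plant motifs (e.g. recognition sites) at uniformly drawn non-overlapping
positions, returning a truth table.  The read simulator replays the
library protocol in silico: first digestion, reduction digestion, overhang
fill-in, barcode + adapter attachment, construct-level size selection, and
optional i.i.d. substitution errors.  Everything is a pure function of its
spec (same seed, same bytes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .barcodes import Barcode
from .design import LibraryDesign, SizeWindow, run_design
from .enzymes import TERMINUS, get_enzyme
from .errors import InputError
from .readqc import ReadRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for one synthetic sequence: length, GC fraction, seed, and
    optional planted motifs given as (pattern, count) pairs."""

    length: int
    gc_fraction: float = 0.5
    seed: int = 0
    motifs: tuple[tuple[str, int], ...] = ()
    name: str = "synth"

    def __post_init__(self):
        if self.length <= 0:
            raise InputError("genome length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise InputError("gc_fraction must lie in [0, 1]")
        object.__setattr__(
            self, "motifs", tuple((p.upper(), int(c)) for p, c in self.motifs)
        )


@dataclass(frozen=True)
class SimulatedGenome:
    """A generated sequence plus the truth table of planted motif positions."""

    name: str
    sequence: str
    planted: tuple[tuple[str, int], ...]  # (pattern, start) pairs

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.planted, columns=["pattern", "start"])


@dataclass(frozen=True)
class ProtocolSpec:
    """Recipe for a pooled barcoded sequencing run of one library design.

    ``barcodes`` pairs each sample barcode with the total length of its
    barcoded adapters; ``selection`` is the electrophoretic window on the
    whole construct (insert + adapters); ``error_rate`` is the per-base
    substitution probability applied to the emitted read.
    """

    design: LibraryDesign
    barcodes: tuple[tuple[Barcode, int], ...]
    selection: SizeWindow
    error_rate: float = 0.0
    seed: int = 0
    quality: int = 30

    def __post_init__(self):
        object.__setattr__(self, "barcodes", tuple(self.barcodes))
        if not self.barcodes:
            raise InputError("protocol needs at least one barcode")
        if not 0.0 <= self.error_rate < 1.0:
            raise InputError("error_rate must lie in [0, 1)")
        for _, adapter_len in self.barcodes:
            if adapter_len < 0 or adapter_len >= self.selection.min_bp:
                raise InputError(
                    f"adapter length {adapter_len} inconsistent with selection "
                    f"{self.selection}"
                )


def simulate_genome(spec: GenomeSpec) -> SimulatedGenome:
    """Generate an i.i.d. genome with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2 and
    overwrite planted motifs at uniformly drawn non-overlapping positions."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=spec.length, p=probs)
    seq = _BASES[idx]

    total_planted = sum(len(p) * c for p, c in spec.motifs)
    if total_planted > spec.length:
        raise InputError("planted motifs do not fit in the genome")
    placed: list[tuple[str, int]] = []
    occupied: list[tuple[int, int]] = []
    for pattern, count in spec.motifs:
        m = len(pattern)
        if m == 0 or count < 0:
            raise InputError("planted motifs need a non-empty pattern and count >= 0")
        for _ in range(count):
            for _attempt in range(1000):
                pos = int(rng.integers(0, spec.length - m + 1))
                if all(pos + m <= a or pos >= b for a, b in occupied):
                    occupied.append((pos, pos + m))
                    placed.append((pattern, pos))
                    seq[pos:pos + m] = np.frombuffer(pattern.encode(), dtype=np.uint8)
                    break
            else:
                raise InputError(
                    f"could not place motif {pattern!r} x{count}: planting density "
                    "infeasible"
                )
    placed.sort(key=lambda t: t[1])
    return SimulatedGenome(spec.name, seq.tobytes().decode(), tuple(placed))


def _filled_insert(seq: str, start: int, end: int, flanking: tuple[str, str]) -> str:
    """Top strand of the filled sequencing insert for a fragment.

    The filled molecule extends past the right-hand cut point by the 5'
    overhang of the right flanking enzyme (those bases are genomic: the
    start of the downstream half-site), so a TaqI-TaqI fragment reads
    CGA...TCG with length (end - start) + 2.
    """
    fill = 0
    right = flanking[1]
    if right != TERMINUS:
        fill = get_enzyme(right).overhang_fill
    return seq[start:min(end + fill, len(seq))]


def simulate_reads(
    genome, protocol: ProtocolSpec
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate a pooled barcoded run: one read per retained fragment per
    barcode, as barcode + filled insert, kept when insert + adapter length
    passes the construct-level selection.

    Returns the reads (constant quality scores) and a truth table mapping
    every read id to its sample and source interval.  If nothing survives
    selection a warning is issued and the outputs are empty.
    """
    from .design import _genome_records  # shared genome normalisation

    records = _genome_records(genome)
    seqs = {sid: seq.upper() for sid, seq in records}
    fragments, _ = run_design(list(seqs.items()), protocol.design)

    rng = np.random.default_rng(protocol.seed)
    reads: list[ReadRecord] = []
    truth_rows = []
    k = 0
    for bc, adapter_len in protocol.barcodes:
        for frag in fragments:
            insert = _filled_insert(seqs[frag.seq_id], frag.start, frag.end, frag.flanking)
            if not protocol.selection.contains(len(insert) + adapter_len):
                continue
            seq = bc.sequence + insert
            if protocol.error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                hit = np.nonzero(rng.random(arr.size) < protocol.error_rate)[0]
                for pos in hit:
                    choices = _BASES[_BASES != arr[pos]]
                    arr[pos] = rng.choice(choices)
                seq = arr.tobytes().decode()
            read_id = f"r{k:06d}"
            k += 1
            reads.append(
                ReadRecord(read_id, seq, (protocol.quality,) * len(seq))
            )
            truth_rows.append(
                {
                    "read_id": read_id,
                    "sample": bc.id,
                    "barcode": bc.sequence,
                    "seq_id": frag.seq_id,
                    "start": frag.start,
                    "end": frag.end,
                    "insert_length": len(insert),
                }
            )
    if not reads:
        import warnings

        warnings.warn("no fragment survived the construct-level size selection")
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id", "sample", "barcode", "seq_id", "start", "end", "insert_length",
        ],
    )
    return reads, truth
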