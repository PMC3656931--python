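"""Demultiplexing and read filtering for restriction-fragment libraries.

Reads from a TaqI library begin with the residual recognition triplet CGA
and — after overhang fill-in — end with TCG, so the QC rules are: require
the prefix, optionally require the suffix, and optionally require the
barcode-trimmed read length to fall inside an insert-size window.  The
insert window is derived from the electrophoretic selection window on the
whole construct by subtracting the barcoded-adapter lengths; with mixed
adapter lengths the pooled window is the intersection of the per-adapter
windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .design import SizeWindow
from .errors import InputError

_RULE_ORDER = ("prefix", "suffix", "length")


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read; qualities (phred integers) are optional but must
    match the sequence length when present."""

    id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.qualities is not None:
            object.__setattr__(self, "qualities", tuple(self.qualities))
            if len(self.qualities) != len(self.sequence):
                raise InputError(
                    f"read {self.id}: {len(self.qualities)} qualities for "
                    f"{len(self.sequence)} bases"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FilterRules:
    """Read-retention rules applied to barcode-trimmed reads, in order:
    required prefix, required suffix (empty string disables), inclusive
    length window (None disables)."""

    required_prefix: str = "CGA"
    required_suffix: str = "TCG"
    length_window: SizeWindow | None = None

    def __post_init__(self):
        for label, s in (("prefix", self.required_prefix), ("suffix", self.required_suffix)):
            if set(s.upper()) - set("ACGT"):
                raise InputError(f"required_{label} must contain only A/C/G/T")
        object.__setattr__(self, "required_prefix", self.required_prefix.upper())
        object.__setattr__(self, "required_suffix", self.required_suffix.upper())


@dataclass
class DemuxResult:
    """Per-sample reads (barcode trimmed), unassigned reads, and counts."""

    assigned: dict[str, list[ReadRecord]]
    unassigned: list[ReadRecord]
    counts: dict[str, int]


def read_length_window(
    selection: SizeWindow, adapter_lengths: Iterable[int]
) -> SizeWindow:
    """Insert-length window implied by a construct-level size selection and a
    set of barcoded-adapter total lengths.

    Returns the intersection of the per-adapter insert windows,
    [selection.min - min(adapters), selection.max - max(adapters)]; e.g.
    selection 240-290 bp with 77/83 bp adapters gives 163-207 bp.
    """
    lengths = sorted(set(int(a) for a in adapter_lengths))
    if not lengths:
        raise InputError("adapter_lengths must be non-empty")
    if any(a < 0 for a in lengths):
        raise InputError("adapter lengths must be >= 0")
    if lengths[-1] >= selection.min_bp:
        raise InputError(
            f"adapter length {lengths[-1]} not smaller than selection minimum "
            f"{selection.min_bp}"
        )
    lo = selection.min_bp - lengths[0]
    hi = selection.max_bp - lengths[-1]
    if lo > hi:
        raise InputError(
            f"empty insert window: intersection of per-adapter windows "
            f"[{selection.min_bp - lengths[0]}, {selection.max_bp - lengths[0]}] and "
            f"[{selection.min_bp - lengths[-1]}, {selection.max_bp - lengths[-1]}] "
            "is empty"
        )
    return SizeWindow(lo, hi)


def _check_prefix_free(barcodes: Sequence[str]) -> None:
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1:]:
            if a.startswith(b) or b.startswith(a):
                raise InputError(
                    f"ambiguous barcode table: {a!r} and {b!r} are prefix-nested"
                )


def demultiplex(
    reads: Iterable[ReadRecord], barcode_table: Mapping[str, str]
) -> DemuxResult:
    """Assign each read to the unique barcode exactly matching its prefix
    (0 mismatches), trimming the barcode from the emitted read.

    ``barcode_table`` maps barcode sequence to sample id and must be
    prefix-free.  Reads matching no barcode go to ``unassigned``.
    """
    table = {bc.upper(): sample for bc, sample in barcode_table.items()}
    if not table:
        raise InputError("barcode table is empty")
    _check_prefix_free(list(table))
    assigned: dict[str, list[ReadRecord]] = {s: [] for s in table.values()}
    unassigned: list[ReadRecord] = []
    for read in reads:
        seq = read.sequence.upper()
        for bc, sample in table.items():
            if seq.startswith(bc):
                k = len(bc)
                quals = read.qualities[k:] if read.qualities is not None else None
                assigned[sample].append(ReadRecord(read.id, read.sequence[k:], quals))
                break
        else:
            unassigned.append(read)
    counts = {s: len(v) for s, v in assigned.items()}
    counts["unassigned"] = len(unassigned)
    return DemuxResult(assigned, unassigned, counts)


def filter_reads(
    reads: Iterable[ReadRecord], rules: FilterRules
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Apply the QC rules to barcode-trimmed reads.

    A read is kept iff it starts with the required prefix, ends with the
    required suffix (when enabled) and its length lies in the window (when
    present).  Rejections are attributed to the first failed rule in the
    order prefix, suffix, length; the kept set itself is order-invariant.
    """
    kept: list[ReadRecord] = []
    rejected = {rule: 0 for rule in _RULE_ORDER}
    for read in reads:
        seq = read.sequence.upper()
        if not seq.startswith(rules.required_prefix):
            rejected["prefix"] += 1
        elif rules.required_suffix and not seq.endswith(rules.required_suffix):
            rejected["suffix"] += 1
        elif rules.length_window is not None and not rules.length_window.contains(len(seq)):
            rejected["length"] += 1
        else:
            kept.append(read)
    return kept, rejected
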