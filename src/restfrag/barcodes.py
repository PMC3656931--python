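"""Barcode screening in adapter/ligation context.

A barcoded adapter must not contain — or form at a junction — a recognition
site of any enzyme used in the protocol, or the reduction digestion would
destroy the adapter-ligated fragment.  The screen therefore scans the full
concatenation ``adapter_5prime + barcode + suffix_3prime``.  The default 3'
suffix is ``CCGA``, the modified TaqI ligation junction (the junction is
engineered so that ligation does not restore the TCGA site), and the
default enzyme set is the nine frequent cutters compatible with one buffer:
TaqI, MseI, MluCI, HaeIII, MspI, HinP1I, MboI, RsaI, Bsh1236I.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .enzymes import RestrictionEnzyme, find_sites, get_enzyme
from .errors import InputError

_DNA_ONLY = re.compile(r"^[ACGT]*$")

DEFAULT_SUFFIX = "CCGA"
DEFAULT_SCREEN_ENZYME_NAMES = (
    "TaqI", "MseI", "MluCI", "HaeIII", "MspI", "HinP1I", "MboI", "RsaI", "Bsh1236I",
)


def default_screen_enzymes() -> tuple[RestrictionEnzyme, ...]:
    return tuple(get_enzyme(n) for n in DEFAULT_SCREEN_ENZYME_NAMES)


def _check_dna(label: str, seq: str, allow_empty: bool = True) -> str:
    s = seq.upper()
    if not allow_empty and not s:
        raise InputError(f"{label} must be non-empty")
    if not _DNA_ONLY.match(s):
        raise InputError(f"{label} must contain only A/C/G/T, got {seq!r}")
    return s


@dataclass(frozen=True)
class Barcode:
    """A sample barcode: id + unambiguous DNA sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(
            self, "sequence", _check_dna(f"barcode {self.id!r}", self.sequence, False)
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScreenContext:
    """Ligation context a barcode is screened in: optional 5' adapter body,
    3' junction suffix, and the enzymes whose sites must be absent."""

    adapter_5prime: str = ""
    suffix_3prime: str = DEFAULT_SUFFIX
    enzymes: tuple[RestrictionEnzyme, ...] = field(default_factory=default_screen_enzymes)

    def __post_init__(self):
        object.__setattr__(
            self, "adapter_5prime", _check_dna("adapter_5prime", self.adapter_5prime)
        )
        object.__setattr__(
            self, "suffix_3prime", _check_dna("suffix_3prime", self.suffix_3prime)
        )
        object.__setattr__(self, "enzymes", tuple(self.enzymes))


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of screening one barcode: pass/fail plus every offending
    (enzyme name, position-in-concatenation) match."""

    barcode_id: str
    passed: bool
    hits: tuple[tuple[str, int], ...]


def screen_barcode(barcode: Barcode, context: ScreenContext | None = None) -> ScreenResult:
    """Fail iff any context enzyme's recognition site occurs anywhere in
    adapter + barcode + suffix (sense strand only: the default enzymes are
    all palindromic, so one strand is complete)."""
    ctx = context or ScreenContext()
    construct = ctx.adapter_5prime + barcode.sequence + ctx.suffix_3prime
    hits: list[tuple[str, int]] = []
    for enz in ctx.enzymes:
        for pos in find_sites(construct, enz.recognition):
            hits.append((enz.name, pos))
    hits.sort(key=lambda h: (h[1], h[0]))
    return ScreenResult(barcode.id, not hits, tuple(hits))


def screen_set(
    barcodes: Sequence[Barcode], context: ScreenContext | None = None
) -> pd.DataFrame:
    """Screen a barcode set; one row per barcode with id, length, pass/fail
    and the offending enzyme hits (``enzyme@position`` list)."""
    barcodes = list(barcodes)
    if not barcodes:
        raise InputError("barcode set must contain at least one barcode")
    ids = [b.id for b in barcodes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate barcode ids: {', '.join(dupes)}")
    rows = []
    for bc in barcodes:
        res = screen_barcode(bc, context)
        rows.append(
            {
                "id": bc.id,
                "length": len(bc),
                "passed": res.passed,
                "reasons": ";".join(f"{name}@{pos}" for name, pos in res.hits),
            }
        )
    return pd.DataFrame(rows)


def load_barcode_tsv(path: str | Path) -> list[Barcode]:
    """Read a barcode TSV with columns id, sequence."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"id", "sequence"} <= set(reader.fieldnames):
            raise InputError(f"barcode table {path}: need columns id, sequence")
        for row in reader:
            out.append(Barcode(row["id"].strip(), row["sequence"].strip()))
    if not out:
        raise InputError(f"barcode table {path} is empty")
    return out
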