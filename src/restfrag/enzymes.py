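"""Restriction-enzyme models, degenerate-site scanning, and digestion of
linear DNA.

Coordinates are 0-based, half-open (BED-compatible) throughout.  A *cut
point* is the position between bases where the top strand is cleaved: TaqI
(T^CGA) matching at position ``i`` cuts at ``i + 1``.  Recognition patterns
use the IUPAC nucleotide alphabet; an ``N`` (or any other ambiguity code) in
the *subject* sequence never matches any pattern symbol, so assembly gaps do
not create phantom sites.  Soft-masked (lowercase) bases are treated as
their uppercase equivalents.

Three counting schemes are supported:

``standard``
    Palindromic frequent cutters (TaqI, MseI, ...).  Digestion of a linear
    sequence with k distinct internal cut points yields k+1 fragments that
    tile the sequence.
``rad_rare``
    RAD-style rare cutters (SbfI): every recognition site yields two
    sequenceable fragments, one on each side; fragment lengths are not
    modelled.
``type_iib``
    Type-IIB enzymes (BsaXI, AlfI) excise one fixed-length fragment per
    recognition site; sites are counted on both strands because the
    patterns need not be palindromic.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import NamedTuple

from .errors import ContractError, InputError

#: Flank label for the outer ends of terminal fragments.
TERMINUS = "TERMINUS"

SCHEMES = ("standard", "rad_rare", "type_iib")

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYWSKMBDHVN", "TGCAYRWSMKVHDBN")
_INVALID_SUBJECT = re.compile(r"[^ACGTRYWSKMBDHVN]")


def reverse_complement(sequence: str) -> str:
    """Reverse complement under IUPAC semantics (R<->Y, K<->M, B<->V, D<->H)."""
    return sequence.upper().translate(_IUPAC_COMPLEMENT)[::-1]


def _prepare_sequence(sequence: str) -> str:
    """Uppercase and validate a subject sequence; report the first bad position."""
    s = sequence.upper()
    m = _INVALID_SUBJECT.search(s)
    if m:
        raise InputError(
            f"non-IUPAC character {m.group()!r} in sequence at position {m.start()}"
        )
    return s


def _validate_pattern(pattern: str) -> str:
    p = pattern.upper()
    if not p:
        raise InputError("recognition pattern must be non-empty")
    for i, ch in enumerate(p):
        if ch not in IUPAC_CODES:
            raise InputError(f"non-IUPAC symbol {ch!r} in pattern at position {i}")
    return p


@lru_cache(maxsize=None)
def _compiled(pattern: str) -> re.Pattern:
    # Lookahead so overlapping occurrences are all reported.  Character
    # classes contain only A/C/G/T: subject ambiguity codes never match.
    parts = []
    for ch in pattern:
        bases = IUPAC_CODES[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("(?=%s)" % "".join(parts))


def find_sites(sequence: str, pattern: str, *, prepared: bool = False) -> list[int]:
    """Start positions of every (possibly overlapping) top-strand occurrence
    of an IUPAC ``pattern`` in ``sequence``, ascending."""
    s = sequence if prepared else _prepare_sequence(sequence)
    p = _validate_pattern(pattern)
    return [m.start() for m in _compiled(p).finditer(s)]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease: recognition pattern, top-strand cut offset
    within the site, and counting scheme.

    For ``scheme="standard"`` the pattern must be its own reverse complement
    (all standard enzymes shipped here are palindromic), so top-strand
    scanning finds every site.  ``iib_fragment_length`` is the fixed excised
    fragment length of a type-IIB enzyme and must exceed the pattern length.
    """

    name: str
    recognition: str
    cut_offset: int
    scheme: str = "standard"
    iib_fragment_length: int | None = None

    def __post_init__(self):
        if not self.name:
            raise InputError("enzyme name must be non-empty")
        object.__setattr__(self, "recognition", _validate_pattern(self.recognition))
        if self.scheme not in SCHEMES:
            raise InputError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise InputError(
                f"cut_offset {self.cut_offset} outside [0, {len(self.recognition)}]"
            )
        if self.scheme == "standard":
            if self.recognition != reverse_complement(self.recognition):
                raise InputError(
                    f"standard enzyme {self.name}: recognition {self.recognition!r} "
                    "is not palindromic under IUPAC semantics"
                )
        if self.scheme == "type_iib":
            if self.iib_fragment_length is None:
                raise InputError(f"type_iib enzyme {self.name} needs iib_fragment_length")
            if self.iib_fragment_length <= len(self.recognition):
                raise InputError(
                    f"{self.name}: iib_fragment_length must exceed the pattern length"
                )
        elif self.iib_fragment_length is not None:
            raise InputError(f"{self.name}: iib_fragment_length only valid for type_iib")

    @property
    def overhang_fill(self) -> int:
        """Bases added per cut end when the 5' overhang is filled in
        (0 for blunt or 3'-overhang cutters)."""
        return max(0, len(self.recognition) - 2 * self.cut_offset)

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == reverse_complement(self.recognition)


@dataclass(frozen=True)
class CutSite:
    """A top-strand cut at ``cut_point`` (between bases) on one sequence."""

    seq_id: str
    cut_point: int
    enzyme_name: str


@dataclass(frozen=True, order=True)
class Fragment:
    """A genomic interval [start, end) produced by digestion.

    ``flanking`` names the enzyme that produced each boundary, outer ends of
    terminal fragments being :data:`TERMINUS`.
    """

    seq_id: str
    start: int
    end: int
    flanking: tuple[str, str] = (TERMINUS, TERMINUS)

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise InputError(f"invalid fragment interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


class SchemeCount(NamedTuple):
    """Fragment count for a non-standard counting scheme, plus the fixed
    fragment length for type-IIB enzymes (``None`` for rad_rare)."""

    count: int
    fragment_length: int | None


def scan_sites(sequence: str, enzyme: RestrictionEnzyme, seq_id: str = "seq") -> list[CutSite]:
    """All top-strand cut sites of a standard (palindromic) enzyme, ascending.

    One :class:`CutSite` per pattern occurrence; overlapping occurrences are
    all reported.  Cuts that would fall at the extreme ends of the sequence
    (cut_point 0 or len) are impossible on a real molecule and dropped.
    """
    if enzyme.scheme != "standard":
        raise ContractError(
            f"scan_sites requires a standard-scheme enzyme, got {enzyme.scheme!r}; "
            "use count_scheme_fragments for rad_rare/type_iib"
        )
    s = _prepare_sequence(sequence)
    n = len(s)
    out = []
    for start in find_sites(s, enzyme.recognition, prepared=True):
        cp = start + enzyme.cut_offset
        if 0 < cp < n:
            out.append(CutSite(seq_id, cp, enzyme.name))
    return out


def digest(sequence: str, enzyme: RestrictionEnzyme, seq_id: str = "seq") -> list[Fragment]:
    """Complete digestion of a linear sequence with one standard enzyme.

    With k distinct internal cut points the result is k+1 fragments tiling
    [0, len) without gaps or overlaps.  Duplicate cut points (from
    overlapping degenerate matches) are deduplicated first.
    """
    if not sequence:
        raise InputError("cannot digest an empty sequence")
    sites = scan_sites(sequence, enzyme, seq_id=seq_id)
    cuts = sorted({s.cut_point for s in sites})
    bounds = [0, *cuts, len(sequence)]
    frags = []
    for i in range(len(bounds) - 1):
        left = TERMINUS if i == 0 else enzyme.name
        right = TERMINUS if i == len(bounds) - 2 else enzyme.name
        frags.append(Fragment(seq_id, bounds[i], bounds[i + 1], (left, right)))
    return frags


def count_scheme_fragments(sequence: str, enzyme: RestrictionEnzyme) -> SchemeCount:
    """Fragment count for RAD rare cutters and type-IIB enzymes.

    rad_rare: each recognition site (top strand; the pattern is palindromic)
    yields two flanking fragments, so count = 2 x sites.  type_iib: sites are
    counted over both strands (distinct start positions on the top-strand
    coordinate system), one fixed-length fragment each.
    """
    if enzyme.scheme == "standard":
        raise ContractError(
            f"{enzyme.name} is a standard-scheme enzyme; use digest() instead"
        )
    s = _prepare_sequence(sequence)
    if enzyme.scheme == "rad_rare":
        n_sites = len(find_sites(s, enzyme.recognition, prepared=True))
        return SchemeCount(2 * n_sites, None)
    starts = set(find_sites(s, enzyme.recognition, prepared=True))
    starts |= set(find_sites(s, reverse_complement(enzyme.recognition), prepared=True))
    return SchemeCount(len(starts), enzyme.iib_fragment_length)


def _builtin_list() -> list[RestrictionEnzyme]:
    std = [
        ("TaqI", "TCGA", 1),
        ("MseI", "TTAA", 1),
        ("TruI", "TTAA", 1),        # MseI isoschizomer
        ("ApoI", "RAATTY", 1),
        ("MluCI", "AATT", 0),
        ("BstUI", "CGCG", 2),
        ("Bsh1236I", "CGCG", 2),    # BstUI isoschizomer
        ("MspI", "CCGG", 1),
        ("HinP1I", "GCGC", 1),
        ("HaeIII", "GGCC", 2),
        ("MboI", "GATC", 0),
        ("RsaI", "GTAC", 2),
    ]
    enzymes = [RestrictionEnzyme(n, r, o) for n, r, o in std]
    enzymes.append(RestrictionEnzyme("SbfI", "CCTGCAGG", 6, scheme="rad_rare"))
    enzymes.append(
        RestrictionEnzyme("BsaXI", "ACNNNNNCTCC", 0, scheme="type_iib",
                          iib_fragment_length=33)
    )
    enzymes.append(
        RestrictionEnzyme("AlfI", "GCANNNNNNTGC", 0, scheme="type_iib",
                          iib_fragment_length=36)
    )
    return enzymes


#: Built-in enzyme table (REBASE conventions), keyed by name.
BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {e.name: e for e in _builtin_list()}

_BY_LOWER = {name.lower(): e for name, e in BUILTIN_ENZYMES.items()}


def get_enzyme(name: str, table: dict[str, RestrictionEnzyme] | None = None) -> RestrictionEnzyme:
    """Look an enzyme up by name (case-insensitive) in ``table`` plus the
    built-in set."""
    if table:
        for key, enz in table.items():
            if key.lower() == name.lower():
                return enz
    enz = _BY_LOWER.get(name.lower())
    if enz is None:
        known = ", ".join(sorted(BUILTIN_ENZYMES))
        raise InputError(f"unknown enzyme {name!r}; built-ins: {known}")
    return enz


def load_enzyme_table(path: str | Path) -> dict[str, RestrictionEnzyme]:
    """Read a user enzyme TSV with columns
    name, recognition, cut_offset, scheme, iib_fragment_length (may be empty)."""
    out: dict[str, RestrictionEnzyme] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "recognition", "cut_offset", "scheme"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise InputError(
                f"enzyme table {path}: need columns name, recognition, cut_offset, "
                "scheme [, iib_fragment_length]"
            )
        for row in reader:
            raw_len = (row.get("iib_fragment_length") or "").strip()
            enz = RestrictionEnzyme(
                name=row["name"].strip(),
                recognition=row["recognition"].strip(),
                cut_offset=int(row["cut_offset"]),
                scheme=row["scheme"].strip() or "standard",
                iib_fragment_length=int(raw_len) if raw_len else None,
            )
            if enz.name in out:
                raise InputError(f"duplicate enzyme name {enz.name!r} in {path}")
            out[enz.name] = enz
    return out
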