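"""Library design engine for restriction-fragment reduced-representation
sequencing.

A library design is: digest the genome with a frequent cutter (restriction
I), discard every fragment containing a site of any enzyme in the reduction
set (restriction II cleaves those after adapter ligation), then keep
fragments whose effective length falls in an inclusive size window.  The
surviving fragments are the sequencing targets; this module also computes
their summary statistics, inter-fragment spacing distributions, a
randomness (Poisson) test of fragment placement, the physical-to-genetic
distance conversion, and multi-design comparison tables.

Two length conventions exist because a restriction fragment has sticky
ends.  ``cutpoint`` measures between top-strand cut points (end - start);
``filled`` adds the filled 5'-overhang bases contributed by each
enzyme-flanked end (+2 per TaqI end; TERMINUS ends add nothing), which is
closer to the length of the sequenced insert.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enzymes import (
    TERMINUS,
    Fragment,
    RestrictionEnzyme,
    SchemeCount,
    _prepare_sequence,
    count_scheme_fragments,
    digest,
    find_sites,
    get_enzyme,
)
from .errors import ContractError, InputError

LENGTH_CONVENTIONS = ("cutpoint", "filled")
DISTANCE_MODES = ("gap", "start_to_start", "midpoint")


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive fragment-size window in bp."""

    min_bp: int
    max_bp: int

    def __post_init__(self):
        if not 0 < self.min_bp <= self.max_bp:
            raise InputError(f"invalid size window [{self.min_bp}, {self.max_bp}]")

    def contains(self, length: int) -> bool:
        return self.min_bp <= length <= self.max_bp

    def __str__(self) -> str:
        return f"{self.min_bp}-{self.max_bp}"


@dataclass(frozen=True)
class LibraryDesign:
    """First enzyme + reduction enzyme set + size window: one library design."""

    enzyme1: RestrictionEnzyme
    reduction_set: tuple[RestrictionEnzyme, ...] = ()
    window: SizeWindow = SizeWindow(1, 10**9)
    length_convention: str = "cutpoint"

    def __post_init__(self):
        object.__setattr__(self, "reduction_set", tuple(self.reduction_set))
        if self.enzyme1.scheme != "standard":
            raise InputError("enzyme1 must be a standard-scheme enzyme")
        for enz in self.reduction_set:
            if enz.scheme != "standard":
                raise InputError("reduction enzymes must be standard-scheme")
            if enz.recognition == self.enzyme1.recognition:
                raise InputError(
                    f"reduction enzyme {enz.name} recognises the same site as "
                    f"enzyme1 {self.enzyme1.name}"
                )
        if self.length_convention not in LENGTH_CONVENTIONS:
            raise InputError(
                f"length_convention must be one of {LENGTH_CONVENTIONS}"
            )

    @property
    def label(self) -> str:
        red = "+".join(e.name for e in self.reduction_set) or "-"
        return f"{self.enzyme1.name}/{red}"


@dataclass(frozen=True)
class FragmentStats:
    """Count, cumulative length and GC of the retained fragments.

    GC is computed over retained fragment bases only; ambiguous bases are
    excluded from numerator and denominator.  ``gc_fraction`` is 0.0 when no
    unambiguous base is retained.
    """

    count: int
    cumulative_bp: int
    gc_fraction: float


@dataclass(frozen=True)
class DistanceStats:
    """Spacing summary: linear-interpolation percentiles plus mean and max."""

    n: int
    mean: float
    median: float
    p5: float
    p25: float
    p75: float
    p95: float
    max: float


@dataclass(frozen=True)
class RandomnessResult:
    """Two placement-randomness diagnostics: a KS test of gap lengths
    against an exponential (rate estimated as gaps / total gap length) and
    an index-of-dispersion chi-square test of binned fragment-start counts
    against Poisson."""

    ks_statistic: float
    ks_p: float
    dispersion_index: float
    dispersion_p: float


def effective_length(
    fragment: Fragment,
    convention: str = "cutpoint",
    enzymes: dict[str, RestrictionEnzyme] | None = None,
) -> int:
    """Fragment length under a convention: cut-point distance, or with the
    filled 5' overhang of each enzyme-flanked end added."""
    L = fragment.end - fragment.start
    if convention == "cutpoint":
        return L
    if convention != "filled":
        raise InputError(f"length convention must be one of {LENGTH_CONVENTIONS}")
    for name in fragment.flanking:
        if name != TERMINUS:
            L += get_enzyme(name, enzymes).overhang_fill
    return L


def reduce_fragments(
    fragments: Sequence[Fragment],
    sequence: str,
    reduction_set: Iterable[RestrictionEnzyme],
) -> list[Fragment]:
    """Keep the fragments whose sequence contains no recognition site of any
    reduction enzyme (an empty reduction set is the identity)."""
    fragments = list(fragments)
    reduction_set = list(reduction_set)
    if not reduction_set:
        return fragments
    s = _prepare_sequence(sequence)
    sites = [
        (np.asarray(find_sites(s, enz.recognition, prepared=True)), len(enz.recognition))
        for enz in reduction_set
    ]
    kept = []
    for frag in fragments:
        hit = False
        for starts, m in sites:
            if starts.size == 0:
                continue
            i = int(np.searchsorted(starts, frag.start))
            # occurrence fully inside [start, end): start position <= end - m
            if i < starts.size and starts[i] <= frag.end - m:
                hit = True
                break
        if not hit:
            kept.append(frag)
    return kept


def size_select(
    fragments: Sequence[Fragment],
    window: SizeWindow,
    convention: str = "cutpoint",
    enzymes: dict[str, RestrictionEnzyme] | None = None,
) -> list[Fragment]:
    """Keep fragments whose effective length lies in the inclusive window."""
    return [
        f for f in fragments if window.contains(effective_length(f, convention, enzymes))
    ]


def _genome_records(genome) -> list[tuple[str, str]]:
    """Normalise a genome argument to a list of (seq_id, sequence) pairs.

    Accepts a FASTA path (plain or gzip), an object with .name/.sequence
    attributes (a simulated genome), or an iterable of (id, seq) pairs.
    """
    if isinstance(genome, (str, os.PathLike)):
        from .io import read_fasta

        records = list(read_fasta(genome))
    elif hasattr(genome, "sequence") and hasattr(genome, "name"):
        records = [(genome.name, genome.sequence)]
    else:
        records = [(sid, seq) for sid, seq in genome]
    if not records:
        raise InputError("empty genome: no sequences to digest")
    return records


def _fragment_stats(records: dict[str, str], fragments: Sequence[Fragment]) -> FragmentStats:
    gc = at = cum = 0
    for f in fragments:
        sub = records[f.seq_id][f.start:f.end]
        gc += sub.count("G") + sub.count("C")
        at += sub.count("A") + sub.count("T")
        cum += f.end - f.start
    denom = gc + at
    return FragmentStats(len(fragments), cum, gc / denom if denom else 0.0)


def run_design(genome, design: LibraryDesign) -> tuple[list[Fragment], FragmentStats]:
    """Digest -> reduce -> size-select each sequence of a genome; return the
    retained fragments in genome order with aggregate statistics."""
    records = _genome_records(genome)
    seqs = {sid: seq.upper() for sid, seq in records}
    retained: list[Fragment] = []
    for sid, _ in records:
        seq = seqs[sid]
        frags = digest(seq, design.enzyme1, seq_id=sid)
        frags = reduce_fragments(frags, seq, design.reduction_set)
        frags = size_select(frags, design.window, design.length_convention)
        retained.extend(frags)
    return retained, _fragment_stats(seqs, retained)


def interfragment_distances(
    fragments: Sequence[Fragment], mode: str = "gap"
) -> list[float]:
    """Distances between consecutive fragments, never across sequences.

    ``gap`` (default): unmarked bases between fragments, start(next) -
    end(prev); ``start_to_start``: difference of starts; ``midpoint``:
    difference of interval midpoints.  n fragments on one sequence yield
    n - 1 distances.
    """
    if mode not in DISTANCE_MODES:
        raise InputError(f"distance mode must be one of {DISTANCE_MODES}")
    out: list[float] = []
    prev: Fragment | None = None
    for frag in fragments:
        if prev is not None and frag.seq_id == prev.seq_id:
            if frag.start < prev.end:
                raise ContractError(
                    f"fragments overlap or are unsorted on {frag.seq_id}: "
                    f"[{prev.start},{prev.end}) then [{frag.start},{frag.end})"
                )
            if mode == "gap":
                out.append(float(frag.start - prev.end))
            elif mode == "start_to_start":
                out.append(float(frag.start - prev.start))
            else:
                out.append(
                    (frag.start + frag.end) / 2.0 - (prev.start + prev.end) / 2.0
                )
        prev = frag
    return out


def distance_summary(distances: Sequence[float]) -> DistanceStats:
    """Summarise a distance sample; percentiles use linear interpolation
    between order statistics."""
    arr = np.asarray(list(distances), dtype=float)
    if arr.size == 0:
        raise InputError("cannot summarise an empty distance list")
    p5, p25, med, p75, p95 = np.percentile(arr, [5, 25, 50, 75, 95])
    return DistanceStats(
        n=int(arr.size),
        mean=float(arr.mean()),
        median=float(med),
        p5=float(p5),
        p25=float(p25),
        p75=float(p75),
        p95=float(p95),
        max=float(arr.max()),
    )


def randomness_test(
    fragments: Sequence[Fragment], sequence_length: int, bins: int = 100
) -> RandomnessResult:
    """Test whether fragment placement is consistent with a homogeneous
    random (Poisson) process on one sequence.

    (a) Kolmogorov-Smirnov of gap distances against an exponential whose
    rate is estimated as n_gaps / total gap length (this estimated-rate KS
    is conservative); (b) index of dispersion of fragment-start counts in
    ``bins`` equal-width bins, with a two-sided chi-square p-value on
    bins - 1 degrees of freedom.  Under-dispersion (periodic placement) and
    over-dispersion (clustering) both reject.
    """
    fragments = list(fragments)
    if len(fragments) < 10:
        raise InputError("randomness test is underpowered below 10 fragments")
    if len({f.seq_id for f in fragments}) != 1:
        raise ContractError("randomness test expects fragments from one sequence")
    last_end = max(f.end for f in fragments)
    if sequence_length < last_end:
        raise ContractError(
            f"sequence_length {sequence_length} smaller than last fragment end {last_end}"
        )
    gaps = np.asarray(interfragment_distances(fragments, "gap"), dtype=float)
    scale = gaps.mean()
    if scale > 0:
        ks = sps.kstest(gaps, "expon", args=(0, scale))
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:  # degenerate: every fragment abuts the next
        ks_stat, ks_p = 1.0, 0.0
    starts = [f.start for f in fragments]
    counts, _ = np.histogram(starts, bins=bins, range=(0, sequence_length))
    mean = counts.mean()
    var = counts.var(ddof=1)
    dispersion = float(var / mean)
    chi = (bins - 1) * dispersion
    p = 2.0 * min(sps.chi2.sf(chi, bins - 1), sps.chi2.cdf(chi, bins - 1))
    return RandomnessResult(ks_stat, ks_p, dispersion, float(min(1.0, p)))


def genetic_distance(physical_kb: float, recomb_rate_cM_per_Mb: float) -> float:
    """Convert a physical distance (kbp) to genetic map distance (cM) given a
    recombination rate in cM/Mb; full precision (round for display)."""
    if physical_kb < 0 or recomb_rate_cM_per_Mb < 0:
        raise InputError("physical distance and recombination rate must be >= 0")
    return physical_kb / 1000.0 * recomb_rate_cM_per_Mb


_DIST_COLUMNS = (
    "n_distances",
    "mean_distance",
    "median_distance",
    "p5",
    "p25",
    "p75",
    "p95",
    "max_distance",
)


def _distance_row(fragments: Sequence[Fragment]) -> dict[str, float]:
    dists = interfragment_distances(fragments, "gap")
    if not dists:
        return {c: (0 if c == "n_distances" else math.nan) for c in _DIST_COLUMNS}
    d = distance_summary(dists)
    return {
        "n_distances": d.n,
        "mean_distance": d.mean,
        "median_distance": d.median,
        "p5": d.p5,
        "p25": d.p25,
        "p75": d.p75,
        "p95": d.p95,
        "max_distance": d.max,
    }


def compare_designs(
    genome,
    designs: Sequence[LibraryDesign | tuple[str, LibraryDesign]],
    scheme_enzymes: Sequence[RestrictionEnzyme] = (),
    windows: Sequence[SizeWindow] | None = None,
) -> pd.DataFrame:
    """Evaluate several library designs (and optionally RAD / type-IIB
    counting schemes) on one genome.

    One row per design x window (``windows`` overrides each design's own
    window when given), with fragment count, cumulative length, GC and a
    gap-distance summary; one row per scheme enzyme counted with
    :func:`count_scheme_fragments`.  Rows keep the given order.
    """
    if not designs and not scheme_enzymes:
        raise InputError("compare_designs needs at least one design")
    records = _genome_records(genome)
    seqs = {sid: seq.upper() for sid, seq in records}
    order = [sid for sid, _ in records]

    rows = []
    cache: dict[tuple, dict[str, list[Fragment]]] = {}
    for item in designs:
        label, design = item if isinstance(item, tuple) else (item.label, item)
        key = (
            design.enzyme1.recognition,
            tuple(sorted(e.recognition for e in design.reduction_set)),
        )
        if key not in cache:
            cache[key] = {
                sid: reduce_fragments(
                    digest(seqs[sid], design.enzyme1, seq_id=sid),
                    seqs[sid],
                    design.reduction_set,
                )
                for sid in order
            }
        reduced = cache[key]
        for window in windows or [design.window]:
            retained: list[Fragment] = []
            for sid in order:
                retained.extend(
                    size_select(reduced[sid], window, design.length_convention)
                )
            st = _fragment_stats(seqs, retained)
            rows.append(
                {
                    "design": label,
                    "min_bp": window.min_bp,
                    "max_bp": window.max_bp,
                    "count": st.count,
                    "cumulative_bp": st.cumulative_bp,
                    "gc_fraction": st.gc_fraction,
                    **_distance_row(retained),
                }
            )
    for item in scheme_enzymes:
        label, enz = item if isinstance(item, tuple) else (item.name, item)
        total = 0
        for sid in order:
            total += count_scheme_fragments(seqs[sid], enz).count
        length = enz.iib_fragment_length
        rows.append(
            {
                "design": label,
                "min_bp": math.nan,
                "max_bp": math.nan,
                "count": total,
                "cumulative_bp": total * length if length else math.nan,
                "gc_fraction": math.nan,
                **{c: (0 if c == "n_distances" else math.nan) for c in _DIST_COLUMNS},
            }
        )
    return pd.DataFrame(rows)
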