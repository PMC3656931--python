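# Methods

## Digestion model

Sequences are linear, scanned case-insensitively on the top strand with
IUPAC degenerate patterns compiled to lookahead regular expressions, so
overlapping occurrences are all reported.  A subject `N` (or any other
ambiguity code in the input) matches no pattern symbol — not even pattern
`N` — because an assembly gap must never create a phantom site.  All
standard-scheme enzymes are required to be palindromic under IUPAC
complement semantics; this makes top-strand scanning complete and is
enforced at construction time.  (A consequence: the occasionally quoted
5-mer spelling of the ApoI site, `RATTY`, is rejected; the package uses
the REBASE 6-mer `RAATTY`.)  Cut points are `match_start + cut_offset`;
cuts that would fall at position 0 or `len` are dropped because the full
site must lie inside the molecule, and duplicate cut points are
deduplicated before fragments are built.  Coordinates are 0-based,
half-open (BED-compatible) throughout, and fragments from one digestion
tile the sequence exactly.

Counting schemes beyond complete digestion: `rad_rare` (SbfI-style RAD)
counts two sequenceable fragments per recognition site without modelling
their lengths; `type_iib` (BsaXI, AlfI) counts distinct site positions
over both strands — the forward pattern plus its reverse complement, with
positions deduplicated so a self-complementary pattern such as AlfI's
`GCANNNNNNTGC` is not double-counted — and assigns each the enzyme's fixed
excised length (33 bp BsaXI, 36 bp AlfI).

## Reduction and size selection

A fragment survives reduction iff no reduction-enzyme site lies fully
inside its interval; the site lists are computed once per sequence and
queried per fragment by binary search, so the cost is one scan per enzyme
per sequence.  Size selection is inclusive on both bounds ("80–100 bp"
keeps 80 and 100).

Two length conventions are offered because a sticky-ended fragment has no
single length.  `cutpoint` (default) is the distance between top-strand
cut points — unambiguous and the natural unit for in silico counting.
`filled` adds, per enzyme-flanked end, that enzyme's filled 5′ overhang
(`len(site) − 2·cut_offset`, clamped at 0): +2 per TaqI end, +4 for an
interior TaqI–TaqI fragment.  The read simulator, by contrast, emits the
physical top strand of the filled molecule, which for a TaqI–TaqI
fragment is `CGA…TCG` and exceeds the cut-point span by one overhang
(+2 bp) in total: the per-end accounting of `filled` is a deliberate
bookkeeping convention (each end contributes its fill to the length used
for selection), not a claim about the blunt molecule's span, and the two
definitions are kept side by side deliberately — selection tooling uses
the convention, read-level tooling uses the physical insert.

## Spacing statistics and the randomness test

Inter-fragment distances never span sequence (scaffold) boundaries.  The
default mode is the gap `start(next) − end(prev)` — the unmarked genome
between adjacent markers; start-to-start and midpoint modes are flags.
Percentiles (5/25/50/75/95) use linear interpolation between order
statistics; the maximum is the sample maximum.

Whether fragment placement is consistent with a homogeneous Poisson
process is assessed two ways, both reported: (a) a Kolmogorov–Smirnov
test of the gaps against an exponential law with rate estimated as
`n_gaps / total_gap_length` — estimating the rate from the same sample
makes this KS conservative, so its p-values are best read as an upper
bound on evidence against randomness; (b) the index of dispersion
(variance/mean, sample variance with one delta degree of freedom) of
fragment-start counts in `B = 100` equal-width bins, with a two-sided
χ² p-value on `B − 1` degrees of freedom, so clustering (index ≫ 1) and
periodicity (index ≈ 0) both reject.  Under fixed-count uniform placement
the dispersion statistic is the classical Pearson χ² and calibrates well;
the test requires ≥ 10 fragments and a declared sequence length no
smaller than the last fragment end.  Degenerate inputs are defined
explicitly: all-abutting fragments (every gap 0) give KS p = 0, and a
perfectly periodic placement gives dispersion 0.

Physical-to-genetic conversion is `cM = kbp/1000 × rate`, full precision
internally, two decimals in summaries (honeybee-scale rates such as
15.7 cM/Mb make typical marker gaps small fractions of a centimorgan).

## Barcode screening and read QC

A barcode is screened by scanning the concatenation
`adapter + barcode + suffix` for every context enzyme; the default suffix
`CCGA` models the modified TaqI ligation junction and the default enzyme
set is the nine-cutter panel (TaqI, MseI, MluCI, HaeIII, MspI, HinP1I,
MboI, RsaI, Bsh1236I).  Only the sense strand is scanned — complete
because all nine are palindromic.  The adapter body is user-supplied
(platform adapters are proprietary); with an empty adapter the screen
still catches sites inside the barcode and across the barcode–suffix
junction (e.g. `AGAT` + `CCGA` forms MboI `GATC`).

Demultiplexing requires a prefix-free barcode table and matches exactly
(0 mismatches); the barcode is trimmed from sequence and qualities.  The
read filters are, in order: prefix `CGA` (the residual TaqI half-site),
suffix `TCG` (the filled far end; disable with an empty string), and an
inclusive length window on the trimmed read.  The kept set is independent
of rule order; only the attribution of rejections follows the order.  The
insert window implied by a pooled construct-level selection `[a, b]` with
adapter lengths `A` is the intersection of per-adapter windows,
`[a − min(A), b − max(A)]` (240–290 bp with 77/83 bp adapters gives
163–207 bp).  The pooled intersection is the default because pooled
libraries are selected together; per-adapter exact windows are what the
demux CLI applies when given the selection bounds, since at that point
each read's adapter is known.  Platform base-quality filtering is out of
scope — reads are assumed pre-filtered.

## Synthetic data

The genome generator draws i.i.d. bases with `P(G) = P(C) = gc/2`, the
null model under which restriction fragments are Poisson-placed, and can
plant motifs at uniformly drawn non-overlapping positions (rejection
sampling, 1000 attempts per copy before the density is declared
infeasible).  Defaults mirror an AT-rich insect-like genome where that
matters (tests use 32 % GC); one integer seed makes every output a pure
function of its spec.  The read simulator replays the protocol: digest,
reduce, fill overhangs (the insert is the genomic top strand extended by
the right-flank overhang, so TaqI–TaqI inserts read `CGA…TCG`), prefix
the barcode, select on insert + adapter length, then apply i.i.d.
substitution errors at rate `e` (default 0) with constant quality scores
(default 30; the platform's error process is not modelled — no
homopolymer indels, no PCR duplicates, no coverage variation, one read
per fragment per barcode).  Consequently, passing pipeline-closure tests
demonstrates the bookkeeping (assignment, trimming, windows, filters) is
exact, not that the filters are robust to real platform noise.

What the i.i.d. genome does not emulate: repeats, isochores/GC
heterogeneity, assembly gaps (except via explicit `N` planting) and
linkage structure.  Analytic expectations used in tests rely on this:
the TaqI site probability per position is `(1/4)^4` at 50 % GC, and the
expected number of digest fragments with cut-point length `L` is
`n·p²·(1−p)^(L−7)` (the exponent discounts the 3 positions on each side
of a site where the non-self-overlapping 4-mer cannot recur).

## Problem sizes and tolerances

The test suite runs on synthetic genomes of 10 kb–3 Mb, sizes at which
every statistic it checks is already stable: scanner equivalence against
a naive per-position matcher on 10 kb for all built-in enzymes;
renewal-expectation and site-count checks within 3 standard errors over
50–100 seeded replicates; dispersion-test calibration over 200 uniform
placements of 500 fragments (acceptance band 1–12 % rejection at
α = 0.05); GC-enrichment direction on a 3 Mb, 32 %-GC genome.  The
62-site RAD-counting fixture plants its SbfI sites on an A/T-only
background so the site count is exact by construction under any seed.
Chromosome-scale FASTA input (tens of Mb) is supported and costs seconds
per enzyme scan, but ships with no bundled data.

## Known limitations

Complete digestion is assumed (no partial digests, star activity or
methylation sensitivity); non-palindromic standard enzymes with two
strand-specific offsets are unsupported; reduction scans the fragment's
genomic spelling only (a site formed across the fragment–adapter junction
is the barcode screen's job, not the reduction model's); annotation
overlap (genes/CDS) and downstream mapping or variant calling are out of
scope.
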