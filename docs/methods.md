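# Methods

This note documents the models, conventions and numerical choices
behind each module, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Genome annotation

**ORF definition.** An ORF is the run from an ATG to the next in-frame
stop, reported once per (strand, frame, stop) region from the *first*
ATG after the previous in-frame stop; alternative (internal) starts are
not reported. This is the convention of standard ORF finders and is the
definition under which the published protein sizes of the
*Caenorhabditis* nodavirus-like segments (a 982-aa polymerase, a 332-aa
RNA2 3′ ORF) are reproducible. Initiator Met is counted, the stop codon
is not. With `allow_partial`, an ATG-initiated run reaching the segment
end with no stop is reported and flagged `partial_3prime`.

**Coordinates.** 0-based half-open on the + strand internally; text
reports use 1-based closed. For − strand calls `start`/`end` are still
+ strand coordinates (ATG at `end`); `frame` is the 0/1/2 offset of the
ORF start on its own reading strand. Input sequences are normalized
(U→T, uppercase); IUPAC ambiguity codes are rejected because exact
matching downstream requires a clean alphabet.

**Organization classification.** With two segments, the segment
carrying the longest + strand ORF is RNA1 (the polymerase segment);
pre-assigned roles are respected. The B2-like search looks for the
longest + strand ORF in frame (RdRP frame + 1) mod 3 intersecting the
final `cterm_window` nt of the RdRP ORF — 300 nt by default, a
configurable stand-in for "the C-terminus", which has no canonical
width. The capsid candidate is the longest ORF starting in the 5′ half
of RNA2; the ORF-δ candidate is the longest other ORF starting 3′ of
the capsid start and ending 3′ of the capsid end (this admits both
non-overlapping downstream ORFs and overlapping ones in another frame).
`rna2_oversize` flags RNA2 exceeding the classical ~1.4 kb convention
by ≥ 500 nt (configurable). `min_aa` defaults to 50, which suppresses
spurious micro-ORFs while retaining every biologically reported
product.

## Small-RNA pipeline

Stage order is demultiplex → trim → size filter → collapse, i.e. the
18–30 nt filter (closed interval) applies *after* A-tail removal, so an
insert trimmed below 18 nt is dropped even if its untrimmed form was in
range. Exclusion rules: any read containing N anywhere ("missing
bases", applied to the whole read since the rule is unqualified), and
any read whose first 4 bases match no configured barcode. The 3′
A-trim is unconditional and therefore also removes genuine terminal
adenosines — a known bias of this processing style, documented here
rather than patched, because the pipeline's value lies in reproducing
the published processing exactly. Collapsing is per barcode (libraries
are distinct samples); `pool=True` merges them. Barcode sequences are
user configuration. Output ordering is deterministic (barcode, then
sequence), so identical input yields byte-identical tables.

## Exact mapper

"Perfect and unambiguous" is implemented in its strictest reproducible
form: a unique insert is informative only when it has **exactly one**
hit — one (record, strand, position) — across the entire host + virus
union. Consequences: a sequence hitting both viral segments once each
is ambiguous; a palindromic sequence matching both strands of one locus
is ambiguous (orientation undefinable); any host hit removes a sequence
from the viral profiles; a sequence hitting host in two places is
ambiguous rather than "host" (this choice cannot affect viral profiles,
only the host/ambiguous split of the denominator-excluded classes).
The categories partition every input: virus_sense, virus_antisense,
host, ambiguous, unmapped.

Matching is k-mer seed (k = 12, below the 18 nt minimum insert length)
plus full verification, so results are exact; the original production
aligner this replaces may have resolved multi-hit sequences
differently, which is why archive-scale reproduction is checked with a
5% band rather than equality.

## viRNA profiles

Counting is in unique sequences (each distinct sequence counts once,
regardless of read depth), matching how virus-derived small-RNA figures
are conventionally drawn; a read-weighted mode exists. Per-position
profiles use full coverage (every reference position covered by the
insert is incremented) by default, with a 5′-end mode (leftmost
position for sense, rightmost for antisense) behind a flag, since
published per-position plots rarely state which was used. First
nucleotides are reported in the RNA alphabet (U for T) and are the 5′
base of the small RNA as sequenced. The summary defines
`viral_fraction` over unambiguously mapped uniques only, and
`flag_22G` = (antisense modal length is 22) ∧ (modal antisense first
base is G). With zero antisense sequences the modal fields are None and
`undefined_antisense_fields` is set instead of raising.

## Phylogeny

Distances are uncorrected p-distances with pairwise gap deletion; a
Poisson correction (−ln(1−p)) is available. The published trees this
mirrors were built by a ClustalW/NJ pipeline whose exact distance
correction is not recoverable, so branch lengths are not reproduction
targets — only topology statements (e.g. a sister pair of two new
taxa) are asserted.

Neighbor joining is the standard Saitou–Nei agglomeration. Determinism:
ties in the Q criterion (within 1e−12) resolve to the pair with the
lowest node-creation indices. NJ can produce negative branch lengths;
they are clamped to zero with the deficit added to the sibling branch,
preserving the path length through the new node (the final three-branch
closed form clamps at zero without redistribution). Bootstrap supports
resample alignment columns with replacement, rebuild the NJ tree per
replicate, and score each internal branch of the full-data tree by the
fraction of replicates containing the same leaf bipartition
(canonicalized as the side not containing the lexicographically first
taxon). The full-data topology is independent of the bootstrap seed.
Newick output writes branch lengths at 12 significant digits and
supports as internal node labels; labels containing metacharacters are
quoted.

## Infection statistics

Worms carry four boolean symptom flags (gut-granule loss, nuclear
degeneration, cytoplasm liquefaction, cell fusion); cohorts are
summarized as the proportion with ≥ k symptoms, k = 1..4 (monotone
non-increasing by construction), and two conditions are compared on the
2×2 table of (≥ 1 symptom) vs none.

The two-sided Fisher p-value sums the hypergeometric probabilities of
all tables with the observed margins whose probability is ≤ that of the
observed table — the convention of the common implementations. Rather
than log-space factorials with tolerance-based tie handling, the
implementation compares exact integer table weights
C(r1,k)·C(r2,c1−k) via `math.comb` and divides once at the end:
for a 2×2 table this is exact at any realistic cohort size, so ties at
the observed probability are decided without any floating-point
ambiguity. Against an independent `Fraction`-based enumeration oracle
and against scipy, agreement is exact / to 1e−9.

**Calibration caveat.** Fisher's exact test is conservative on discrete
data: conditioning on the margins makes the attainable p-values coarse,
so at nominal α = 0.05 with 20 animals per arm the true null rejection
rate is ~0.02–0.025 (computable in closed form by summing binomial
masses over the rejection region), not 0.05. The test suite and the
acceptance script measure this rate by simulation; expecting ≈5%
rejections from an exact test at this sample size is a misreading of
what "exact" guarantees (a rate *at most* α).

## Synthetic data

The generator's defaults are the study conditions the analyses assume:
RNA1 3,600 nt with a 950-aa polymerase surrogate, RNA2 2,650 nt with a
380-aa capsid surrogate and (by default) a planted 300-aa 3′ ORF; a
50 kb uniform-random host stand-in; an infected library of 600 viral
unique inserts (400 antisense + 200 sense) among 29,400 host inserts —
a 2% viral fraction at desk scale; antisense lengths at 22 nt with 0.2
spill probability to 21/23; antisense 5′ G probability 0.5 (giving a
clear modal-G bias over the ~0.25 background); sense lengths uniform
18–30 with no 5′ preference; per-insert read counts geometric(0.5);
A-tails of 1–4 nt appended with probability 0.2; 50 junk reads
exercising the N/barcode exclusion rules. All outputs are pure
functions of the configuration, seed included.

Truth guarantees, and how they are enforced:

* The host stand-in shares no ≥ 18-mer with the viral segments (either
  strand); collisions are patched and re-checked.
* Every insert is unique in its library and has exactly one hit in the
  host + virus union, enforced by rejection against the package's own
  exact-match index at k = 18 — so pipeline classification agrees with
  the truth record for 100% of planted inserts.
* Inserts never end in A, so the unconditional 3′ A-trim removes only
  the planted artifact tails and every insert survives the pipeline
  byte-identically.
* The 5′ G bias is enforced by shifting the sampled window (antisense
  5′ base G ⇔ + strand window ends in C), never by mutating bases, so
  reads remain exact genome substrings. The planted probability is the
  exact marginal: with probability p the window is constrained to yield
  5′ G, otherwise constrained to yield non-G.
* Planted ORFs are detected at exactly their planted coordinates, and
  absent ORFs are never detected: beyond keeping planted reading frames
  stop-free, the generator scrubs the background — it breaks (by
  constrained resampling) any unplanned ATG-initiated run of ≥
  `min_orf_aa` codons that would qualify as a B2-like or ORF-δ
  candidate, and any upstream in-frame ATG that would extend a planted
  ORF 5′ of its true start. Uniform random background would otherwise
  produce such decoy ORFs in a nontrivial fraction of genomes, making
  truth labels wrong.

What the generator does **not** emulate: sequencing errors and quality
variation (qualities are constant), adapter read-through, PCR
duplication structure, the repeat and paralog structure of a real host
genome (which produces far more ambiguous mappings than a random
sequence), codon usage and GC bias of real viral genomes, and any
biological placement structure of viRNA hotspots (windows are sampled
uniformly). Passing tests therefore demonstrate correctness of the
*algorithms* under clean, fully specified conditions — not robustness
to real-library artifacts.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path with tight statistical bands: libraries of 30,000 unique
inserts for the 2% viral-fraction recovery (3 binomial SDs ≈ 0.24
percentage points), 1,000 antisense inserts per planted 5′ G
probability, 1,000 random ≤ 1 kb sequences for the ORF-scanner oracle,
500 queries over 10 kb of reference for the mapper oracle, 100 random
additive trees (4–12 leaves) for NJ consistency, 200 random tables for
the Fisher oracle, and 1,000 simulated cohorts for the null
calibration. Archive-scale reproduction (the deposited GenBank contigs
and GEO libraries against the full host genome build) is wired into the
acceptance tests but requires network access to the archives.
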