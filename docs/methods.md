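# Methods

## Degenerate-primer matching

All matching is positional, over uppercase DNA with IUPAC ambiguity
codes. A primer letter matches a template letter when the two codes'
base sets intersect (`Y` vs `T`: match; `Y` vs `G`: mismatch; `N` on
either side matches anything). This permissive-intersection convention
is the standard one for scanning reference databases, which themselves
contain ambiguity codes; it means a highly ambiguous template region can
never *create* a mismatch. The mismatch count of a primer against a
window is the number of positions with disjoint sets.

Site search scans every window on both strands (the reverse complement
of the primer against the stored strand for `-` sites) and reports
0-based half-open coordinates on the stored sequence. The scan is
vectorised with a 4-bit base encoding (A=1, C=2, G=4, T=8; a code's mask
is the OR of its bases; compatibility is a non-zero AND), and is checked
in the test suite against a naive per-window scan on a thousand random
sequence/primer/mismatch triples.

Mismatches are unweighted: a mismatch at the primer's 3' terminus counts
the same as one in the middle. Position-weighted or thermodynamic
scoring of annealing is out of scope.

## Amplicons

An amplicon pairs a forward-primer site on `+` with a downstream
reverse-primer site on `-` (and symmetrically `-`/`+` for entries
deposited antisense, flagged `antisense`). Its span runs from the start
of the forward site to the end of the reverse site, **primer regions
included**, matching how expected product sizes are quoted for PCR.
Every forward/reverse pairing is emitted; the shortest is flagged
`primary` rather than silently choosing, since degenerate primers can
legitimately hit twice. Records with exactly one site, or sites in
non-amplifiable order, classify as INCOMPLETE — the direct,
deterministic stand-in for similarity-search-based screening of partial
SSU entries; a configurable amplicon-length interval tightens this
completeness criterion.

## Blocking-primer design

The design model assumes the blocking oligo anneals to the amplicon
sense strand in the same orientation as the reverse primer, its 5' end
overlapping the primer's 3' binding region and its 3' end extending into
host-specific sequence, where the Spacer C3 modification (metadata only
here — chemistry has no computational counterpart) prevents elongation.

Procedure, given an annotated database and a target (host) label:

1. restrict both target and off-target pools to records the primer pair
   amplifies at the configured mismatch allowance;
2. take the 3'-terminal window (default **40 nt**) of each target
   amplicon — reverse-primer site plus upstream host sequence — and
   stack the windows right-anchored at the primer site into a per-column
   IUPAC consensus. Right-anchored stacking replaces multiple sequence
   alignment: the windows are positionally homologous by construction
   (each ends at its own reverse-primer site), so a consensus is
   obtained without an aligner, and off-target behaviour is measured by
   direct site search of each candidate instead of cross-alignment. The
   decision quantity — does the candidate hit non-target sequences? — is
   preserved;
3. enumerate one candidate per length in **18–29 nt** (the upper bound
   keeps oligos under 30 bp): the reverse complement of the consensus
   substring whose end sits exactly **10 bp** (the overlap, exact by
   default and configurable) inside the reverse-primer site;
4. compute each candidate's nearest-neighbor Tm and flag those farther
   than **±3 °C** from the primer pair's mean Tm (flagged and excluded
   from selection, but still reported);
5. score every remaining candidate: the fraction of target-pool records
   containing a candidate site (either strand, default **0 mismatches**)
   and likewise for the off-target pool;
6. select by a total lexicographic order: maximal target blocking, then
   minimal off-target blocking, then minimal |ΔTm|, then shorter length,
   then alphabetical sequence — deterministic under input permutation.

The 0-mismatch blocking criterion is deliberately strict — a candidate
"blocks" only records carrying an exactly compatible site — because
partial conservation in related taxa is precisely what the specificity
score must resolve; the threshold is configurable
(`block_max_mismatch`). Whether the overlap must be exactly or at least
10 bp is likewise a design choice; exact overlap is the default because
every extra overlapping base is a base not probing host-specific
sequence.

## Melting temperature

Tm uses the nearest-neighbor model with the SantaLucia & Hicks (2004)
unified parameter set as implemented in Biopython's `Tm_NN`
(`nn_table=DNA_NN4`), at 50 mM monovalent Na+, 250 nM single-strand
oligo, with the entropic salt correction
ΔS += 0.368·(N−1)·ln[Na+]. The constants live in one place
(`blocking_designer.TM_CONDITIONS`). The test suite validates the
implementation against an independent hand-rolled NN sum over the
published table.

Degenerate consensus positions inside a candidate keep their IUPAC codes
for matching but are collapsed to the per-column modal base of the
observed host windows for Tm, since Tm is defined for concrete duplexes.
Note that NN Tm is not monotone under 3' extension: appending a weak
(A/T) stack to a GC-rich oligo can lower the predicted Tm, so candidate
length and Tm rank independently.

A note on Tm-based ranking: among equally specific candidates the oligo
closest to the pair-mean Tm wins, which on the bundled oyster fixture is
the 24-mer prefix of the planted 25-mer motif (|ΔTm| 0.6 °C vs 1.4 °C).
Both block 100% of host and 0% of off-target records; the full ranked
table is always written so the choice is inspectable.

## Specificity profiling

Each record gets exactly one status per primer configuration: NO_SITE
(neither primer found), INCOMPLETE (one site or mis-ordered sites),
AMPLIFIED, or BLOCKED (would amplify, but a blocking-primer site lies
within the amplicon). Removing the blocking primer from a configuration
can therefore only convert BLOCKED to AMPLIFIED. Group tallies at a
chosen taxonomy depth conserve exactly — records annotated more
shallowly than the requested rank fall into an `unresolved` bin instead
of being dropped — and group universes must match before two
configurations are compared.

## Synthetic databases

The generator emulates the *structure* the design procedure relies on,
not rRNA biology: each record is
`pad | forward site | random insert | 3' host region | reverse site | pad`.
A clade conserves the blocking motif with probability `p` — such records
spell the motif's reverse complement across the host region and the
first 10 bp of the reverse site, which automatically carries the
overlap-induced single mismatch against the universal reverse primer
(the host-clade situation) — and is truncated before the reverse site
with probability `q`, yielding INCOMPLETE entries. Planted mismatch
counts are *true* mismatches (substitutions drawn outside the primer's
IUPAC set at non-N positions). Defaults: insert length ~ Normal(150, 20)
nt (V4-like product scale), pads 30–60 nt, background substitution rate
0 so planted truth and classification agree exactly; a non-zero rate
perturbs all positions uniformly and is available for robustness
exploration. Expected profile fractions are analytic — an amplifiable
clade expects a blocked fraction of `p·(1−q)` — and observed fractions
are checked against 99% binomial intervals at n = 500.

Randomness is hierarchical: one global seed plus a stable per-clade
stream derived from a hash of the clade name, so adding a clade never
perturbs the sequences of existing clades.

What the generator does **not** model — secondary structure,
phylogenetically correlated substitution, chimeras, length heterogeneity
of real SSU genes, database annotation errors — bounds what the tests
show: passing planted-truth recovery demonstrates the machinery is
correct, not that any particular database release will yield the same
percentages. Percentages obtained on a real Silva export depend on its
release and taxonomy and should be recomputed with `hostblock profile`.

## Problem sizes and numerics

The bundled fixtures use a 20-record host clade against three 50-record
off-target clades for design recovery, 200 records for coordinate
recovery, and 500 records for the binomial-recovery check — sizes at
which the binomial intervals are already tight (±4.4 percentage points
at 99% for p = 0.82) while the whole suite stays interactive. Tm values
are compared at 1e-6 °C against the independent oracle (identical
formula, so agreement is to rounding); profile fractions are exact
rational counts. Ties in candidate selection are broken by length then
sequence, so selection is reproducible bit-for-bit; CLI reports embed
the effective configuration and its hash in `#` metadata lines.
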