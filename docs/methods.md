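# Methods

## Sequence model and cut geometry

DNA is stored as an uppercase top strand over {A, C, G, T}; ambiguity
codes are rejected rather than expanded, because every toolkit part is a
fully specified sequence.  Coordinates are 0-based half-open on the top
strand; circular molecules reduce positions modulo length, so
recognition sites, cut windows and features may span the origin.
Circular scanning doubles the first `k − 1` bases and deduplicates by
modular position, which an explicit rotate-and-rescan oracle confirms in
the tests.

BsaI is fixed at the standard geometry (GGTCTC, 1-nt spacer, 4-nt 5′
overhang): a plus-strand site at recognition start *p* cuts top at
*p* + 7 and bottom at *p* + 11, mirrored for minus-strand sites.  SwaI
is a blunt mid-palindrome cutter (ATTTAAAT, cut at +4).  Methylation
sensitivity, star activity and partial-digestion kinetics are not
modelled.

Sticky ends are normalized to the top-strand 5′→3′ reading of the
4-nt window between the two cuts.  The two ends created by one cut get
the same normalized string, so "ligatable" collapses to string
equality, and flipping a fragment reverse-complements both of its end
strings.  A fragment's stored sequence includes both windows; ligation
concatenates fragments counting each shared window once, which makes
digestion exactly base-conserving (property-tested).

Digestion refuses overlapping cut windows ("entangled cut") because the
fragment set would be ill-defined.  On linear molecules a site whose
window leaves the ends cannot be cleaved and is skipped; a circular
molecule with no sites is returned intact and flagged uncut.

## Fusion-site grammar

Junction labels 1–11 are numbered left-to-right around the largest
(10-fragment) design; pGGYL1/2 use the prefix of that numbering plus a
single closing backbone junction (5 and 8 respectively; pGGYL3 closes
at 11), so a building block cloned for a slot is reusable in every
backbone that has the slot.  The backbone's marker-side junction is
label 1.  Whether the physical toolkit closes with one label or two is
a figure-level detail; one closing label keeps the 1–11 numbering exact
for 10 fragments + backbone = 11 junctions.

The shipped fusion-site table was chosen once, by deterministic greedy
search, to be *faithful* — no duplicate 4-mers, no reverse-complement
pairs, no self-palindromes — and additionally to contain no
Hamming-distance-1 pair and no 4-mer that occurs inside GGTCTC, GAGACC
or ATTTAAAT.  The last constraint has a structural payoff: any enzyme
site spanning a junction in an assembled product would have to contain
the junction's full 4-mer, which is then impossible; sites overlapping
a junction partially are excluded by scanning every part together with
its flanking fusion windows (for all eleven windows, so slot
relabelling stays safe).  Products are therefore recognition-site-free
by construction, and the whole-product scans in the tests confirm it.

Catalog parts carry first-transcription-unit labels; the registry mints
slot-specific donor plasmids (same insert, the slot's labels) on
demand.  This mirrors the physical library, which stores one part under
several fusion-site pairs, without duplicating catalog rows.

## Assembly simulation

The fragment pool is the BsaI digest of the backbone plus every donor
plasmid (donor vector bodies included — they religate and can chain, as
in the real reaction).  Closures are found by walking a directed graph
whose nodes are normalized 4-mers and whose edges are fragments in both
orientations, each physical fragment used at most once; circles are
canonicalized by anchoring at their lowest-index fragment in forward
orientation, which fixes rotation and reflection.  An independent
permutation-and-orientation brute force is kept as the oracle for pools
of ≤ 6 fragments and must agree exactly (it does, on every seeded pool
tested).

Circles that retain a BsaI site are *transient*: the cyclic
digestion–ligation program re-cuts them.  The simulator therefore takes
the site-free ("stable") closures as end products; under a faithful
table the intended plasmid is the unique stable closure containing the
backbone vector body, and any additional stable backbone closure is
reported as mis-join ambiguity.  All other circles — the blue
stuffer religation, donor religations, re-cuttable chimeras — are
returned as classified side products.  Stoichiometry is ignored (each
fragment exists once) and side-product enumeration is bounded at 12
pieces per circle so the report terminates; linear dead-ends appear
only in failure diagnostics, as the longest extension from the
backbone.  Blunt ends never ligate in this model: the reaction's
ligase-compatible species are the 4-nt sticky ends, and the empty-string
"overhang" of a blunt fragment is not a valid junction.

Colony color is blue iff the lacZ stuffer feature is intact (a product
without the resistance placeholder is "not platable"); a mis-joined
circle without the stuffer is still white, reproducing the false-positive
caveat that motivates junction sequencing.

The ligation-protocol recommendation is a lookup, not a kinetic model:
600 U / 60 cycles up to four fragments, 1,400 U / 120 cycles from five,
with the fixed thermal program (37 °C 3 min / 16 °C 4 min per cycle,
then 50 °C and 80 °C holds).  Wet-lab efficiency percentages and
transformant counts are deliberately out of scope.

## Domestication

Internal BsaI/SwaI sites in coding sequence are removed by synonymous
substitution: for each motif occurrence, every overlapping codon is
tried with every synonymous replacement; a replacement must destroy the
motif and create no new forbidden motif within ±10 nt of the edit
(motifs are ≤ 8 nt, so the window bounds local creation; a final
full-sequence scan guarantees global cleanliness).  Among valid
replacements the fewest-base change wins, ties broken by
lexicographically smallest new codon — determinism without a
codon-usage table, which is the deliberate default; expression-aware
scoring is out of scope.  The loop repeats until clean, so the output
is a fixed point, and every edit touches a single codon.  Non-coding
sequence is only flagged, never auto-edited: promoter or terminator
function could silently change, so those edits stay manual.

## Cassette extraction, PCR, marker recycling

SwaI digestion of a product must find exactly two sites; the fragment
carrying the marker feature is the integration cassette, the other
keeps the resistance and origin placeholders.  In silico PCR is
exact-match only (the verification primers were designed against exact
targets): the forward primer must match one strand and the reverse the
other with 3′ ends convergent, and the shortest spanning product wins,
with circular templates measured both ways.  The default primer pair is
the toolkit's fixed verification pair, embedded in the synthetic
backbones just outside the SwaI sites.

Marker recycling is deterministic: Cre excision removes the region
between the first direct-orientation loxP pair together with one loxP
copy (inverted pairs are rejected, inversion is not modelled), using
the canonical 34-nt loxP sequence, configurable.  The hisG pop-out
requires two identical direct hisG repeats flanking a URA3 feature and
collapses the locus to one repeat; homology-length thresholds are not
modelled because the intended 5-FOA-selected outcome is deterministic.
Both operations error on re-application ("nothing to excise").

## Synthetic toolkit generator

The generator emulates the structure of the physical library — part
counts (8 promoters, 9 terminators, 8 mevalonate-pathway genes plus the
synthase stand-in, 6 markers: five loxP-flanked, one hisG-URA3-hisG),
backbone layout (lacZ stuffer between inward recognitions, kanR/ori
placeholders, two SwaI sites bracketing the assembly region, the
verification-primer landing sites) — with random sequence content.
Length defaults: promoters 300–800 nt, CDSs 600–1,800 nt, terminators
100–300 nt, markers 1,000–2,000 nt, stuffer 500 nt, GC within 30–70 %;
values chosen as typical spans for yeast regulatory and coding
elements.  CDSs are built codon-wise (ATG start, one stop) and cleaned
by the domesticator itself.  Every sequence derives from the seed
through named substreams (crc32 of the component name), so toolkits are
reproducible across processes, and every generated part must pass
registry validation before it is returned.

What the synthetic toolkit does *not* emulate: real promoter/terminator
strengths (the sequences are inert placeholders), codon usage of
*Y. lipolytica*, chromosomal context for integration, and any
wet-lab efficiency observable.  Passing tests therefore demonstrate the
combinatorial and structural correctness of designs — grammar, closure
uniqueness, site freedom, cassette composition, length arithmetic — not
biological activity.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the simulator at the
toolkit's native scale: 200 seeded designs across four toolkits for the
roundtrip/uniqueness checks, 150 random pools of ≤ 6 fragments for the
closure-oracle comparison, and 500 seeded coding sequences with planted
motifs for domestication, sizes at which the whole suite completes in
seconds.  Fold changes are reported to one decimal (snapping to an
integer within 0.05) and percentages to one decimal, or two where the
source ledger carries two; these are reporting conventions only — all
arithmetic is done in double precision.

## Known limitations

Single-copy stoichiometry means concentration effects and multimeric
concatemers are invisible; ligation fidelity is binary (exact 4-mer
match), so near-cognate mis-ligation frequencies are reported only as
Hamming-distance warnings in the table check; uncut (escaped) plasmids
are not carried into the product pool; and the NHEJ integration step
itself — where the cassette lands in the genome — is out of scope, as
are all fermentation observables.
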