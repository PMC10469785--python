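# Methods

## Sequence model

All sequences live on the 15-letter IUPAC nucleotide alphabet
(`ACGT` plus the 11 degeneracy codes), stored uppercase with `U`
normalized to `T`: the 18S target is an rRNA *gene* amplified from DNA,
and oligos are synthesized as DNA, so a single alphabet suffices. Two
codes *match* when their base sets intersect (so `N` matches
everything, `Y` matches `C` and `T`). This set-intersection semantics
is how a degenerate primer behaves at the annealing step and keeps the
packaged degenerate primers (e.g. `1015R`, which contains one `Y` and
therefore expands to exactly two concrete oligos) self-consistent. A
*mismatch* between two equal-length strings is a position whose base
sets are disjoint; this positional count, with no gap model, is the
unit of every rule in the tool. Internally each code is encoded as a
4-bit base-set mask so mismatch counting reduces to a vectorized
bitwise AND; the test suite checks this encoding against plain
set-arithmetic double loops.

Coordinates are 0-based half-open on the template plus strand
everywhere — files (TSV/BED), in-memory types and reports alike.

## In-silico PCR

Primer binding sites are found by exhaustive scanning of every offset
on both strands, degeneracy-aware, using only the gene-specific part of
each oligo (the 5' sequencing-adapter tail, declared per oligo and
stripped by exact prefix match, never anneals). The default allows 0
mismatches at a binding site: no annealing thermodynamics is modelled,
and the degeneracy already encodes the intended wobble. A template's
amplicon is the unique productive pairing of a plus-strand forward site
upstream of a minus-strand reverse site; zero productive pairings is a
"no amplicon" error naming the missing primer, and more than one is an
"ambiguous amplicon" error listing the pairings — blocker placement is
meaningless on a non-unique amplicon, so ambiguity is never silently
resolved to a first hit. The *interior* — the region strictly between
the two footprints — is the hypervariable stretch eligible for blocker
placement. The tool treats the full interior as eligible; a user can
further restrict it by supplying a sub-interval amplicon map.

## Candidate design rules

Candidates are all interior windows with length in
[`min_len` = 20, `max_len` = 30], emitted in both orientations (the
strand a blocker anneals to determines which extension it arrests, and
either can be wanted, so both are enumerated and strand is recorded
explicitly). 20 nt is the published minimum selection length; the 30 nt
cap is a tool default that bounds enumeration at a typical upper length
for synthesized blocking oligos and is configurable. A window passes
when:

* it lies entirely inside the interior and overlaps no primer footprint
  by even 1 nt;
* it occurs exactly once in the host (`require_host_unique`, default
  on), counting distinct plus-strand intervals so a palindromic locus
  is not double-counted;
* its best ungapped alignment against **every** off-target sequence has
  at least `min_offtarget_mismatches` = 3 mismatches.

The off-target screen slides the candidate along each off-target at
every offset on both strands (semi-global, no indels). When an
off-target is shorter than the candidate, all full-overlap diagonals of
the shorter length are scored and uncovered candidate positions count
as mismatches — otherwise a trivially short decoy sequence would pass
any candidate. An empty off-target library yields an explicit
"unscreened" status and the candidate cannot be accepted; it is never a
silent pass.

Accepted candidates are ordered by descending off-target distance, then
GC balance (|GC − 0.5|), then shorter length, then 5'-most start. The
ranking is a tool convention — the selection rules define a pass/fail
set, not an order — and the candidates TSV flags it as such in its
header. GC fraction is advisory metadata only; no melting-temperature
model is applied, since the selection rules specify none. The top-k
accepted windows are emitted as blocking oligos with a C3-spacer
terminator, printed in the conventional `<seq>[SpcC3]` notation.

The validator applies the same rules to any externally supplied
blocking oligo and reports one pass/fail line per rule. An oligo that
does not map to the host is a reported "no host locus" failure, not an
exception; with no host reference given at all (e.g. validating the
packaged *H. illucens* primers without their real 18S reference, which
is recorded by accession only and never fetched), locus-dependent rules
are explicitly marked unevaluated.

## Blocking simulation

Per template, the simulator extracts the amplicon and then searches
each blocking oligo against the template at every offset and strand. A
blocker *binds* iff its best site has at most `t_block` mismatches — a
pure threshold model; any richer annealing model (ΔG, kinetics, partial
suppression across cycles) would be invented biology, so outcomes are
binary per template. A bound blocker *blocks* only when its site lies
entirely inside the amplicon interior: this is elongation arrest, not
anneal inhibition, so sites overlapping a primer footprint are reported
but do not block. The default `t_block = min_offtarget_mismatches − 1
= 2` makes design and simulation mutually consistent: an off-target the
screen kept ≥ 3 mismatches away can never be collaterally blocked at
the default threshold, which the end-to-end tests confirm. Community
summaries report *host suppression* (fraction of host templates blocked
among those with an amplicon) and *collateral blocking* (the same over
non-host templates); ambiguous amplicons propagate as an explicit
outcome reason and are counted separately.

## Synthetic fixtures

The generator emulates the structure of a host marker region — random
background, the `1389F` site, an interior, the reverse-complemented
`1015R` site (its degenerate position concretized by seeded draw), more
background — with defaults of a 400 nt host and a 120 nt interior,
matching the scale of an 18S V9 amplicon. Backgrounds are i.i.d. bases
at a configurable GC content (default 0.5). Hosts are regenerated
(bounded retries) if the background happens to contain a second primer
site, so the amplicon is always unique by construction.

Off-targets copy the host scaffold (so they amplify, and collateral
blocking is measurable) and differ from the host interior at an exact
requested number of positions. The mutated positions are clustered
inside a shared 20 nt *signature* subwindow of the interior, drawn once
per seed. This clustering is what makes the generator a faithful test
bed for the design rules: real hypervariable regions separate taxa
through localized divergent stretches, and a bounded-length blocking
window can only clear the 3-mismatch screen against every off-target if
each off-target's divergence is concentrated within one such stretch.
Were mutations scattered uniformly, no ≤ 30 nt window would cover three
of them per off-target except by vanishing chance, and the design space
the tool exists to search would be empty. Each off-target draw is
re-verified with the specificity screen — the full-interior probe must
score exactly the requested distance, and the signature probe must not
fall below the screen threshold — and redrawn (bounded retries) if a
closer spurious match arose elsewhere. Default distances are
(3, 4, 5, 6, 8, 10): all at or beyond the screen threshold, spanning
near-threshold to clearly-divergent relatives.

Mock communities are a seeded multinomial draw over the host (default
fraction 0.5) and the off-targets (uniform split of the remainder),
default 20 templates. All randomness flows from a single explicit seed
through `numpy` generators (no global state), and FASTA output wraps at
a fixed 70 columns, so identical spec + seed give byte-identical files.

What the fixtures do **not** emulate: phylogenetically realistic rRNA
evolution, indels (the screen is ungapped by design), chimeras, PCR
stochasticity, abundance-weighted efficiencies, or sequencing reads.
Passing tests therefore demonstrate that the rules and searches are
implemented exactly, not that a designed blocker will reach any
particular suppression efficiency on real libraries — that depends on
annealing thermodynamics and template abundances outside this model.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at the
fixture defaults above (400 nt hosts, 6 off-targets, 20-template
communities; ~2100 enumerated candidates per design), with oracle
cross-checks on several hundred random instances up to 2000 nt
templates and 60 nt candidates — sizes at which the brute-force oracles
remain exact and fast. Searches are deterministic with no tolerances:
every comparison is integer mismatch counting. Ties in ranking
preserve input order (stable sort); the validator picks the 5'-most
host locus when an oligo maps more than once. Degenerate candidate
sequences never arise from the generator (interiors are concrete), but
the screen and validator accept them and score them with the same
set-intersection semantics.

## Known limitations

* Ungapped screening only; an off-target differing by an indel inside
  the window is scored by its best ungapped diagonal, which may
  overstate its distance.
* No thermodynamic model: mismatch position (3'-proximal vs 5') does
  not weight binding, although it matters for real annealing.
* One primary host reference per design run; additional host sequences
  are handled by validating against each, not by joint multi-host
  optimization.
* The blocking model ignores competition between blocker and polymerase
  extension timing; suppression is all-or-nothing per template.
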