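# blockprime

Design, validate and in-silico evaluate **elongation-arrest blocking
primers** for host-DNA depletion in amplicon metabarcoding.

## The problem

In marker-gene surveys of host-associated eukaryotic communities (for
example 18S rRNA V9 metabarcoding of an insect gut), the host's own 18S
gene is present in overwhelming copy number and is co-amplified by the
universal primers, drowning out the microbial eukaryotes of interest. A
standard counter-measure is a *blocking primer*: an oligonucleotide that
anneals to the host template **between** the two amplification primers
and carries a 3' C3 spacer, a three-carbon modification that polymerases
cannot extend. Annealed mid-amplicon, it physically arrests elongation
on host templates (elongation-arrest blocking) while templates from
other taxa, which the blocker does not bind, amplify normally.

`blockprime` implements the design procedure for such blockers as a
reusable tool:

* **in-silico PCR** — locate the amplification-primer binding sites on a
  host reference by exhaustive, IUPAC-degeneracy-aware scanning of both
  strands, and extract the amplicon and its hypervariable interior (the
  region eligible for blocker placement);
* **candidate design** — enumerate every interior window of 20–30 nt in
  both orientations and keep those that are unique in the host and at
  least **3 mismatches** away from every sequence in an off-target
  library, under an ungapped semi-global sliding comparison (both
  strands, uncovered positions counted as mismatches). A window must
  never overlap a primer footprint, and 20 nt is the minimum length;
* **validation** — score any externally supplied blocking oligo, such as
  the packaged `BP-F_Hi_V9` / `BP-R_Hi_V9` pair designed against the
  *Hermetia illucens* (Black Soldier Fly) 18S V9 region, against the
  same rules, one pass/fail line per rule;
* **simulation** — predict, for a mock community, which templates
  amplify and which are elongation-arrested, using a mismatch-threshold
  binding model (a blocker binds iff its best match has ≤ `t_block`
  mismatches, default 2), and summarize *host suppression* and
  *collateral blocking* fractions.

A deterministic fixture generator builds synthetic host references,
off-targets at exact mismatch distances and mock communities, so the
whole workflow runs and is tested without any external download. The
packaged oligo table also carries the published 18S V9 pair
(`1389F`/`1015R`) and 16S V3-V4 pair (`341F`/`785R`) with their shared
sequencing adapter tail.

## Worked example

```sh
blockprime fixtures --out bundle --seed 42
blockprime design   --host bundle/host.fasta --offtargets bundle/offtargets.fasta --out design
blockprime simulate --community bundle/community.fasta --host-ids bundle/host_ids.txt \
                    --blockers design/blockers.fasta --out sim
blockprime validate --oligo BP-F_Hi_V9 --oligo BP-R_Hi_V9 --out check
```

`design/candidates.tsv` ranks every screened window (2112 candidates on
the default bundle; the column order below is stable):

```
# ranking keys (tool convention): min_offtarget_mismatches desc, |gc-0.5| asc, length asc, start asc
host_id	start	end	strand	length	seq	gc_fraction	host_copy_count	min_offtarget_mismatches	status	reject_reasons
host_synthetic	202	222	+	20	GCACACTAACCGGTGCTAAA	0.5000	1	3	accepted
host_synthetic	202	222	-	20	TTTAGCACCGGTTAGTGTGC	0.5000	1	3	accepted
```

The top window is unique in the host (`host_copy_count` 1) and at least
3 mismatches from every off-target, so it passes the selection rules;
`design/blockers.fasta` carries the top-k windows in the synthesized
notation, e.g. `GCACACTAACCGGTGCTAAA[SpcC3]`. `sim/summary.json` then
reports

```json
{"host_suppression": 1.0, "collateral_blocking": 0.0, ...}
```

meaning every host template in the mock community is predicted
elongation-arrested while no off-target (all generated ≥ 3 mismatches
away) is collaterally blocked. The `validate` report prints one line
per rule; with no host reference or off-target library given, the
length rule is checked (23 nt and 22 nt, both ≥ 20) and the remaining
rules are explicitly reported as unevaluated — never silently passed.

All subcommands accept a YAML config mirroring the rule names
(`min_len`, `max_len`, `min_offtarget_mismatches`, ...); command-line
flags override the config, which overrides built-in defaults. Outputs
are byte-reproducible for identical config and seed.

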