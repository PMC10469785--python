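"""Blocking-primer candidate enumeration, screening, ranking and validation.

The selection rules implemented here are the published ones for
elongation-arrest blocking primers: a candidate is a window of at least
20 nt (at most ``max_len``) lying entirely inside the hypervariable
interior of the host amplicon, never overlapping an amplification-primer
footprint, unique in the host reference, and at least three mismatches
away from every off-target sequence under an ungapped, degeneracy-aware
sliding comparison on both strands.

The ranking function is a tool convention (the rules define a pass/fail
set, not an order): accepted candidates are sorted by descending
off-target distance, then GC balance, then shorter length, then 5'-most
position.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core_seq import (
    DesignRules,
    NucSequence,
    PrimerOligo,
    encode,
    gc_fraction,
    revcomp,
)
from .insilico_pcr import AmpliconMap, sliding_mismatches

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateWindow",
    "ScreenResult",
    "OfftargetHit",
    "RuleCheck",
    "ValidationReport",
    "enumerate_candidates",
    "host_uniqueness",
    "specificity_screen",
    "screen_candidates",
    "rank_candidates",
    "emit_blocking_primers",
    "validate_blocking_primer",
    "design",
    "write_candidate_tsv",
]

# Rule identifiers used in reject_reasons and validation reports.
RULE_LENGTH = "length"
RULE_IN_INTERIOR = "in_interior"
RULE_NO_FOOTPRINT_OVERLAP = "no_footprint_overlap"
RULE_HOST_UNIQUE = "host_unique"
RULE_OFFTARGET = "offtarget_mismatches"
RULE_UNSCREENED = "specificity_unscreened"


@dataclass(frozen=True)
class OfftargetHit:
    """Best ungapped alignment of a candidate against one off-target.

    ``offset`` is the position of the candidate's first base on the
    off-target's plus strand (negative when a shorter off-target sits
    inside the candidate); uncovered candidate positions count as
    mismatches.
    """

    offtarget_id: str
    mismatches: int
    offset: int
    strand: str


@dataclass(frozen=True)
class ScreenResult:
    candidate_id: str
    hits: tuple[OfftargetHit, ...]
    unscreened: bool = False

    @property
    def min_mismatches(self) -> int | None:
        if self.unscreened or not self.hits:
            return None
        return min(h.mismatches for h in self.hits)


@dataclass
class CandidateWindow:
    """A candidate blocking-primer window on the host plus strand.

    ``strand`` is the orientation of the oligo that would be
    synthesized: '+' means the oligo equals the host plus-strand slice,
    '-' its reverse complement (annealing to the plus strand).
    """

    host_id: str
    start: int
    end: int
    strand: str
    seq: NucSequence
    gc_fraction: float
    host_copy_count: int | None = None
    min_offtarget_mismatches: int | None = None
    screen: ScreenResult | None = None
    status: str = "enumerated"
    reject_reasons: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.host_id}:{self.start}-{self.end}({self.strand})"


def enumerate_candidates(
    amplicon: AmpliconMap, host: NucSequence, rules: DesignRules | None = None
) -> list[CandidateWindow]:
    """Every window of allowed length inside the amplicon interior.

    Windows are emitted in both orientations, ordered by (start, end,
    strand).  By construction no window overlaps a primer footprint.  An
    interior shorter than ``min_len`` yields an empty list (with a
    warning), not an error.
    """
    rules = rules or DesignRules()
    lo, hi = amplicon.interior_start, amplicon.interior_end
    if hi - lo < rules.min_len:
        logger.warning(
            "interior of %s is %d nt, shorter than min_len=%d: no candidates",
            host.id,
            hi - lo,
            rules.min_len,
        )
        return []
    out: list[CandidateWindow] = []
    for s in range(lo, hi - rules.min_len + 1):
        for e in range(s + rules.min_len, min(s + rules.max_len, hi) + 1):
            window = host.seq[s:e]
            for strand in ("+", "-"):
                oligo = window if strand == "+" else str(revcomp(window))
                out.append(
                    CandidateWindow(
                        host_id=host.id,
                        start=s,
                        end=e,
                        strand=strand,
                        seq=NucSequence(f"{host.id}:{s}-{e}({strand})", oligo),
                        gc_fraction=gc_fraction(oligo),
                    )
                )
    return out


def host_uniqueness(candidate: CandidateWindow, host: NucSequence) -> int:
    """Number of distinct host plus-strand intervals matching the candidate.

    Degeneracy-aware exact matching on either strand; plus- and
    minus-strand hits over the same interval (palindromes) count once.
    Always >= 1 for a window cut from the host itself.
    """
    host_enc = encode(host)
    cand = candidate.seq.seq
    intervals: set[tuple[int, int]] = set()
    for query in (cand, str(revcomp(cand))):
        mm = sliding_mismatches(host_enc, encode(query))
        for off in np.flatnonzero(mm == 0):
            intervals.add((int(off), int(off) + len(query)))
    return len(intervals)


def _best_alignment(
    cand_enc: np.ndarray, cand_rc_enc: np.ndarray, subject: NucSequence
) -> tuple[int, int, str]:
    """Minimum-mismatch ungapped alignment of candidate vs one subject.

    Returns (mismatches, offset-on-subject-plus-strand, strand).  When
    the subject is shorter, all full-overlap diagonals of the shorter
    length are scored and uncovered candidate positions count as
    mismatches.
    """
    subj_enc = encode(subject)
    n, m = cand_enc.size, subj_enc.size
    best: tuple[int, int, str] | None = None
    for strand, q in (("+", cand_enc), ("-", cand_rc_enc)):
        if m >= n:
            mm = sliding_mismatches(subj_enc, q)
            off = int(np.argmin(mm))
            score = int(mm[off])
        else:
            # subject slides inside the candidate
            mm = sliding_mismatches(q, subj_enc) + (n - m)
            j = int(np.argmin(mm))
            score, off = int(mm[j]), -j
        if best is None or score < best[0]:
            best = (score, off, strand)
    assert best is not None
    return best


def specificity_screen(
    candidate: CandidateWindow,
    offtargets: Sequence[NucSequence],
    rules: DesignRules | None = None,
) -> ScreenResult:
    """Best ungapped match of the candidate against every off-target.

    The candidate passes when the minimum over all off-targets is at
    least ``rules.min_offtarget_mismatches``.  An empty off-target
    library yields an explicitly unscreened result, never a silent pass.
    """
    if not offtargets:
        return ScreenResult(candidate.id, hits=(), unscreened=True)
    cand_enc = encode(candidate.seq)
    cand_rc_enc = encode(str(revcomp(candidate.seq.seq)))
    hits = []
    for ot in offtargets:
        score, off, strand = _best_alignment(cand_enc, cand_rc_enc, ot)
        hits.append(OfftargetHit(ot.id, score, off, strand))
    return ScreenResult(candidate.id, hits=tuple(hits))


def screen_candidates(
    candidates: Iterable[CandidateWindow],
    host: NucSequence,
    offtargets: Sequence[NucSequence],
    rules: DesignRules | None = None,
) -> list[CandidateWindow]:
    """Apply host-uniqueness and off-target rules, setting status in place."""
    rules = rules or DesignRules()
    out = []
    for cand in candidates:
        cand.host_copy_count = host_uniqueness(cand, host)
        cand.screen = specificity_screen(cand, offtargets, rules)
        cand.min_offtarget_mismatches = cand.screen.min_mismatches
        reasons = []
        if rules.require_host_unique and cand.host_copy_count != 1:
            reasons.append(RULE_HOST_UNIQUE)
        if cand.screen.unscreened:
            reasons.append(RULE_UNSCREENED)
        elif cand.min_offtarget_mismatches < rules.min_offtarget_mismatches:
            reasons.append(RULE_OFFTARGET)
        cand.reject_reasons = reasons
        cand.status = "accepted" if not reasons else "rejected"
        out.append(cand)
    return out


def rank_candidates(candidates: Sequence[CandidateWindow]) -> list[CandidateWindow]:
    """Stable deterministic ordering of screened candidates.

    Keys: descending off-target distance, |GC - 0.5| ascending, shorter
    length, 5'-most start.  Unscreened candidates sort last.
    """
    def key(c: CandidateWindow):
        mm = c.min_offtarget_mismatches if c.min_offtarget_mismatches is not None else -1
        return (-mm, abs(c.gc_fraction - 0.5), c.length, c.start)

    return sorted(candidates, key=key)


def emit_blocking_primers(
    ranked: Sequence[CandidateWindow], k: int
) -> list[PrimerOligo]:
    """Convert the top-k accepted candidates to C3-spacer blocking oligos.

    Fewer than k accepted candidates returns all of them with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    accepted = [c for c in ranked if c.status == "accepted"]
    if len(accepted) < k:
        logger.warning(
            "only %d accepted candidate(s) available, %d requested", len(accepted), k
        )
    return [
        PrimerOligo(
            name=f"BP_{c.host_id}_{c.start}-{c.end}{c.strand}",
            gene_specific=NucSequence(f"BP_{c.host_id}_{c.start}-{c.end}{c.strand}", c.seq.seq),
            role="blocking",
            terminator="C3_spacer",
        )
        for c in accepted[:k]
    ]


# ---------------------------------------------------------------------------
# Validation of externally supplied blocking primers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RuleCheck:
    rule: str
    passed: bool | None  # None = not evaluable (e.g. unscreened, no locus)
    detail: str


@dataclass(frozen=True)
class ValidationReport:
    oligo_name: str
    checks: tuple[RuleCheck, ...]

    @property
    def verdict(self) -> str:
        if any(c.passed is False for c in self.checks):
            return "FAIL"
        if any(c.passed is None for c in self.checks):
            return "PASS (with unevaluated rules)"
        return "PASS"

    @property
    def failed(self) -> bool:
        return any(c.passed is False for c in self.checks)

    def check(self, rule: str) -> RuleCheck:
        for c in self.checks:
            if c.rule == rule:
                return c
        raise KeyError(rule)

    def to_text(self) -> str:
        lines = [f"validation report for {self.oligo_name}"]
        for c in self.checks:
            mark = {True: "PASS", False: "FAIL", None: "----"}[c.passed]
            lines.append(f"  [{mark}] {c.rule}: {c.detail}")
        lines.append(f"  verdict: {self.verdict}")
        return "\n".join(lines)


def validate_blocking_primer(
    oligo: PrimerOligo,
    amplicon: AmpliconMap | None,
    host: NucSequence | None,
    offtargets: Sequence[NucSequence],
    rules: DesignRules | None = None,
) -> ValidationReport:
    """Check a blocking oligo against every design rule, one line per rule.

    An oligo that does not map to the host yields a "no host locus"
    failure (locus-dependent rules become unevaluable), not an
    exception.  With no host reference at all, locus-dependent rules are
    reported as unevaluated.
    """
    if oligo.role != "blocking":
        raise ValueError(f"{oligo.name!r} does not have role blocking")
    rules = rules or DesignRules()
    checks: list[RuleCheck] = []
    seq = oligo.gene_specific
    n = len(seq)

    checks.append(
        RuleCheck(
            RULE_LENGTH,
            n >= rules.min_len,
            f"gene-specific length {n} nt (rule: >= {rules.min_len})",
        )
    )

    if host is None or amplicon is None:
        detail = "no host reference provided"
        checks.append(RuleCheck("host_locus", None, detail))
        checks.append(RuleCheck(RULE_IN_INTERIOR, None, detail))
        checks.append(RuleCheck(RULE_NO_FOOTPRINT_OVERLAP, None, detail))
        checks.append(RuleCheck(RULE_HOST_UNIQUE, None, detail))
        checks.append(_offtarget_check(seq, host, offtargets, rules))
        return ValidationReport(oligo.name, tuple(checks))

    # Map the oligo onto the host (exact degeneracy-aware, either strand).
    host_enc = encode(host)
    loci: list[tuple[int, int, str]] = []
    for strand, q in (("+", seq.seq), ("-", str(revcomp(seq.seq)))):
        mm = sliding_mismatches(host_enc, encode(q))
        for off in np.flatnonzero(mm == 0):
            loci.append((int(off), int(off) + n, strand))
    intervals = sorted({(s, e) for s, e, _ in loci})

    if not loci:
        checks.append(RuleCheck("host_locus", False, "no host locus"))
        checks.append(RuleCheck(RULE_IN_INTERIOR, None, "no host locus"))
        checks.append(RuleCheck(RULE_NO_FOOTPRINT_OVERLAP, None, "no host locus"))
        checks.append(RuleCheck(RULE_HOST_UNIQUE, None, "no host locus"))
    else:
        best = min(loci, key=lambda t: (t[0], t[1], t[2]))
        s, e, strand = best
        checks.append(
            RuleCheck("host_locus", True, f"maps to {host.id}:{s}-{e}({strand})")
        )
        in_interior = amplicon.interior_start <= s and e <= amplicon.interior_end
        checks.append(
            RuleCheck(
                RULE_IN_INTERIOR,
                in_interior,
                f"locus {s}-{e} vs interior "
                f"{amplicon.interior_start}-{amplicon.interior_end}",
            )
        )
        overlap = amplicon.fwd_footprint.overlaps(s, e) or amplicon.rev_footprint.overlaps(s, e)
        checks.append(
            RuleCheck(
                RULE_NO_FOOTPRINT_OVERLAP,
                (not overlap) or rules.footprint_overlap_allowed,
                "overlaps a primer footprint" if overlap else "no footprint overlap",
            )
        )
        copies = len(intervals)
        checks.append(
            RuleCheck(
                RULE_HOST_UNIQUE,
                (copies == 1) if rules.require_host_unique else True,
                f"host copy count {copies}",
            )
        )

    checks.append(_offtarget_check(seq, host, offtargets, rules))
    return ValidationReport(oligo.name, tuple(checks))


def _offtarget_check(
    seq: NucSequence,
    host: NucSequence | None,
    offtargets: Sequence[NucSequence],
    rules: DesignRules,
) -> RuleCheck:
    if not offtargets:
        return RuleCheck(RULE_OFFTARGET, None, "unscreened (empty off-target library)")
    pseudo = CandidateWindow(
        host_id=host.id if host else "?",
        start=0,
        end=len(seq),
        strand="+",
        seq=seq,
        gc_fraction=gc_fraction(seq),
    )
    mm = specificity_screen(pseudo, offtargets, rules).min_mismatches
    return RuleCheck(
        RULE_OFFTARGET,
        mm >= rules.min_offtarget_mismatches,
        f"minimum off-target mismatches {mm} "
        f"(rule: >= {rules.min_offtarget_mismatches})",
    )


# ---------------------------------------------------------------------------
# Orchestration and tabular output
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignResult:
    amplicon: AmpliconMap
    candidates: list[CandidateWindow]  # ranked, screened
    blockers: list[PrimerOligo]

    @property
    def accepted(self) -> list[CandidateWindow]:
        return [c for c in self.candidates if c.status == "accepted"]


def design(
    host: NucSequence,
    fwd: PrimerOligo,
    rev: PrimerOligo,
    offtargets: Sequence[NucSequence],
    rules: DesignRules | None = None,
    k: int = 2,
) -> DesignResult:
    """Full pipeline: amplicon → enumerate → screen → rank → emit top-k."""
    from .insilico_pcr import extract_amplicon

    rules = rules or DesignRules()
    amplicon = extract_amplicon(host, fwd, rev, rules)
    cands = enumerate_candidates(amplicon, host, rules)
    cands = screen_candidates(cands, host, offtargets, rules)
    ranked = rank_candidates(cands)
    blockers = emit_blocking_primers(ranked, k) if ranked else []
    return DesignResult(amplicon=amplicon, candidates=ranked, blockers=blockers)


CANDIDATE_TSV_COLUMNS = [
    "host_id",
    "start",
    "end",
    "strand",
    "length",
    "seq",
    "gc_fraction",
    "host_copy_count",
    "min_offtarget_mismatches",
    "status",
    "reject_reasons",
]


def write_candidate_tsv(candidates: Iterable[CandidateWindow], path: str | Path) -> None:
    """One row per candidate window, in the order given (ranked upstream).

    The leading comment line flags that the ordering is a tool
    convention, not part of the published selection rules.
    """
    with open(path, "w", newline="") as fh:
        fh.write(
            "# ranking keys (tool convention): min_offtarget_mismatches desc, "
            "|gc-0.5| asc, length asc, start asc\n"
        )
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CANDIDATE_TSV_COLUMNS)
        for c in candidates:
            w.writerow(
                [
                    c.host_id,
                    c.start,
                    c.end,
                    c.strand,
                    c.length,
                    c.seq.seq,
                    f"{c.gc_fraction:.4f}",
                    "" if c.host_copy_count is None else c.host_copy_count,
                    ""
                    if c.min_offtarget_mismatches is None
                    else c.min_offtarget_mismatches,
                    c.status,
                    ",".join(c.reject_reasons),
                ]
            )


def write_validation_tsv(reports: Iterable[ValidationReport], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["oligo", "rule", "passed", "detail"])
        for rep in reports:
            for c in rep.checks:
                w.writerow(
                    [
                        rep.oligo_name,
                        c.rule,
                        {True: "pass", False: "fail", None: "NA"}[c.passed],
                        c.detail,
                    ]
                )
            w.writerow([rep.oligo_name, "verdict", rep.verdict, ""])
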