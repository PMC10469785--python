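"""In-silico efficacy evaluation of a blocking-primer set on a community.

The binding model is a pure mismatch-threshold model: a blocking oligo
binds a template wherever its best degeneracy-aware ungapped match has
at most ``t_block`` mismatches.  A bound blocker arrests elongation only
when its site lies entirely inside the amplicon interior (elongation
arrest, not anneal inhibition: sites overlapping a primer footprint are
reported but do not block).  Outcomes are binary per template — no PCR
efficiency, cycle count or partial-suppression modelling.

The default ``t_block`` is ``min_offtarget_mismatches - 1`` (= 2 under
default rules), which makes the design rules and the simulation mutually
consistent: an off-target kept >= 3 mismatches away by the screen can
never be collaterally blocked.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core_seq import DesignRules, NucSequence, PrimerOligo, encode, revcomp
from .insilico_pcr import (
    AmbiguousAmpliconError,
    AmpliconMap,
    NoAmpliconError,
    extract_amplicon,
    sliding_mismatches,
)

__all__ = [
    "BlockingHit",
    "TemplateOutcome",
    "BlockReport",
    "default_t_block",
    "predict_outcome",
    "simulate_community",
    "write_outcome_tsv",
]

OUTCOMES = ("amplified", "blocked", "no_amplicon")


def default_t_block(rules: DesignRules | None = None) -> int:
    rules = rules or DesignRules()
    return max(rules.min_offtarget_mismatches - 1, 0)


@dataclass(frozen=True)
class BlockingHit:
    blocker_name: str
    offset: int
    strand: str
    mismatches: int
    in_interior: bool


@dataclass(frozen=True)
class TemplateOutcome:
    template_id: str
    has_amplicon: bool
    outcome: str
    reason: str
    blocking_hits: tuple[BlockingHit, ...] = ()

    @property
    def best_hit(self) -> BlockingHit | None:
        interior = [h for h in self.blocking_hits if h.in_interior]
        pool = interior or list(self.blocking_hits)
        return min(pool, key=lambda h: h.mismatches) if pool else None


def _blocker_hits(
    template: NucSequence,
    amplicon: AmpliconMap,
    blockers: Sequence[PrimerOligo],
    t_block: int,
) -> list[BlockingHit]:
    tmpl_enc = encode(template)
    hits: list[BlockingHit] = []
    for bl in blockers:
        n = len(bl.gene_specific)
        for strand, q in (
            ("+", bl.gene_specific.seq),
            ("-", str(revcomp(bl.gene_specific.seq))),
        ):
            mm = sliding_mismatches(tmpl_enc, encode(q))
            for off in np.flatnonzero(mm <= t_block):
                s, e = int(off), int(off) + n
                hits.append(
                    BlockingHit(
                        blocker_name=bl.name,
                        offset=s,
                        strand=strand,
                        mismatches=int(mm[off]),
                        in_interior=(
                            amplicon.interior_start <= s and e <= amplicon.interior_end
                        ),
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.blocker_name, h.strand))
    return hits


def predict_outcome(
    template: NucSequence,
    fwd: PrimerOligo,
    rev: PrimerOligo,
    blockers: Sequence[PrimerOligo],
    t_block: int | None = None,
    rules: DesignRules | None = None,
) -> TemplateOutcome:
    """Amplified, blocked, or no_amplicon for one template.

    A template amplifies iff a unique amplicon exists and no blocker
    attains <= t_block mismatches fully inside the amplicon interior.
    An ambiguous amplicon is reported as no_amplicon with an explicit
    reason (counted separately in the community report).
    """
    rules = rules or DesignRules()
    t = default_t_block(rules) if t_block is None else t_block
    if t < 0:
        raise ValueError("t_block must be >= 0")
    for bl in blockers:
        if bl.role != "blocking":
            raise ValueError(f"{bl.name!r} does not have role blocking")
    try:
        amplicon = extract_amplicon(template, fwd, rev, rules)
    except AmbiguousAmpliconError as exc:
        return TemplateOutcome(template.id, False, "no_amplicon", f"ambiguous amplicon: {exc}")
    except NoAmpliconError as exc:
        return TemplateOutcome(template.id, False, "no_amplicon", str(exc))
    hits = _blocker_hits(template, amplicon, blockers, t)
    blocking = [h for h in hits if h.in_interior]
    if blocking:
        best = min(blocking, key=lambda h: h.mismatches)
        return TemplateOutcome(
            template.id,
            True,
            "blocked",
            f"elongation arrest by {best.blocker_name} at offset {best.offset} "
            f"({best.mismatches} mismatches <= t_block={t})",
            tuple(hits),
        )
    return TemplateOutcome(
        template.id, True, "amplified", f"no blocker site within t_block={t} in interior", tuple(hits)
    )


@dataclass(frozen=True)
class BlockReport:
    """Community-level summary of predicted amplification outcomes."""

    outcomes: tuple[TemplateOutcome, ...]
    host_ids: frozenset[str]
    host_suppression: float
    collateral_blocking: float
    counts: dict[str, int]
    ambiguous_count: int

    def to_json_dict(self) -> dict:
        return {
            "community_size": len(self.outcomes),
            "host_templates": sum(1 for o in self.outcomes if o.template_id in self.host_ids),
            "host_suppression": self.host_suppression,
            "collateral_blocking": self.collateral_blocking,
            "counts": dict(self.counts),
            "ambiguous_amplicons": self.ambiguous_count,
        }

    def to_text(self) -> str:
        d = self.to_json_dict()
        lines = [
            f"community size:       {d['community_size']}",
            f"host templates:       {d['host_templates']}",
            f"host suppression:     {self.host_suppression:.4f}",
            f"collateral blocking:  {self.collateral_blocking:.4f}",
            "outcome counts:       "
            + ", ".join(f"{k}={self.counts[k]}" for k in OUTCOMES),
            f"ambiguous amplicons:  {self.ambiguous_count}",
        ]
        return "\n".join(lines)


def simulate_community(
    community: Sequence[NucSequence],
    host_ids: Iterable[str],
    fwd: PrimerOligo,
    rev: PrimerOligo,
    blockers: Sequence[PrimerOligo],
    t_block: int | None = None,
    rules: DesignRules | None = None,
) -> BlockReport:
    """Predict every template's outcome and aggregate suppression fractions.

    host_suppression = blocked host templates / host templates with an
    amplicon; collateral_blocking = the same fraction over non-host
    templates.  Deterministic; an empty community is an error.
    """
    if not community:
        raise ValueError("community is empty")
    host_set = frozenset(host_ids)
    known = {t.id for t in community}
    missing = host_set - known
    if missing:
        raise ValueError(f"host ids not present in community: {sorted(missing)}")

    outcomes = tuple(
        predict_outcome(t, fwd, rev, blockers, t_block, rules) for t in community
    )
    counts = {k: 0 for k in OUTCOMES}
    for o in outcomes:
        counts[o.outcome] += 1
    ambiguous = sum(1 for o in outcomes if o.reason.startswith("ambiguous amplicon"))

    def fraction(ids_pred) -> float:
        with_amp = [o for o in outcomes if ids_pred(o.template_id) and o.has_amplicon]
        if not with_amp:
            return 0.0
        return sum(1 for o in with_amp if o.outcome == "blocked") / len(with_amp)

    return BlockReport(
        outcomes=outcomes,
        host_ids=host_set,
        host_suppression=fraction(lambda i: i in host_set),
        collateral_blocking=fraction(lambda i: i not in host_set),
        counts=counts,
        ambiguous_count=ambiguous,
    )


def write_outcome_tsv(report: BlockReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "template_id",
                "is_host",
                "outcome",
                "best_blocker",
                "best_offset",
                "best_strand",
                "best_mismatches",
                "reason",
            ]
        )
        for o in report.outcomes:
            h = o.best_hit
            w.writerow(
                [
                    o.template_id,
                    "yes" if o.template_id in report.host_ids else "no",
                    o.outcome,
                    h.blocker_name if h else "",
                    h.offset if h else "",
                    h.strand if h else "",
                    h.mismatches if h else "",
                    o.reason,
                ]
            )


def write_summary_json(report: BlockReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
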