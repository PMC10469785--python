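"""In-silico PCR: primer binding-site search and amplicon extraction.

The amplification primers are located on a template by an exhaustive,
degeneracy-aware scan of every offset on both strands (no thermodynamic
annealing model; the degenerate codes already encode intended wobble).
A productive forward/reverse pairing defines the amplicon; the region
strictly between the two primer footprints is the hypervariable interior
in which blocking primers may be placed.

All coordinates are 0-based half-open on the template's plus strand.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .core_seq import DesignRules, NucSequence, PrimerOligo, encode, revcomp

__all__ = [
    "BindingSite",
    "AmpliconMap",
    "NoAmpliconError",
    "AmbiguousAmpliconError",
    "find_binding_sites",
    "extract_amplicon",
    "sliding_mismatches",
    "write_amplicon_tsv",
    "write_amplicon_bed",
]


class NoAmpliconError(ValueError):
    """Forward/reverse sites in productive orientation are absent."""


class AmbiguousAmpliconError(ValueError):
    """More than one productive forward/reverse pairing exists."""

    def __init__(self, message: str, pairings: list[tuple["BindingSite", "BindingSite"]]):
        super().__init__(message)
        self.pairings = pairings


@dataclass(frozen=True)
class BindingSite:
    """A primer footprint on the template plus strand.

    ``strand`` is '+' when the primer sequence matches the plus strand
    directly, '-' when its reverse complement does.
    """

    template_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    primer_name: str

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class AmpliconMap:
    """The amplified interval and its primer-free interior."""

    template_id: str
    amplicon_start: int
    amplicon_end: int
    fwd_footprint: BindingSite
    rev_footprint: BindingSite

    @property
    def interior_start(self) -> int:
        return self.fwd_footprint.end

    @property
    def interior_end(self) -> int:
        return self.rev_footprint.start

    @property
    def interior_length(self) -> int:
        return self.interior_end - self.interior_start

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_end - self.amplicon_start


def sliding_mismatches(template_enc: np.ndarray, query_enc: np.ndarray) -> np.ndarray:
    """Degeneracy-aware mismatch count of ``query`` at every offset.

    Returns an array of length ``len(template) - len(query) + 1`` (empty
    if the query is longer than the template).
    """
    n, k = template_enc.size, query_enc.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(template_enc, k)
    return np.count_nonzero((windows & query_enc) == 0, axis=1)


def find_binding_sites(
    template: NucSequence, primer: PrimerOligo, max_mismatches: int = 0
) -> list[BindingSite]:
    """Exhaustive scan for primer sites on both strands of a template.

    Only the gene-specific part of the oligo is searched (the adapter
    tail never anneals).  Sites are reported in ascending start order,
    plus-strand coordinates, with their mismatch counts.
    """
    if len(template) == 0:
        raise ValueError("template is empty")
    tmpl_enc = encode(template)
    sites: list[BindingSite] = []
    for strand, query in (
        ("+", primer.gene_specific.seq),
        ("-", str(revcomp(primer.gene_specific.seq))),
    ):
        mm = sliding_mismatches(tmpl_enc, encode(query))
        for off in np.flatnonzero(mm <= max_mismatches):
            sites.append(
                BindingSite(
                    template_id=template.id,
                    start=int(off),
                    end=int(off) + len(query),
                    strand=strand,
                    mismatches=int(mm[off]),
                    primer_name=primer.name,
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def extract_amplicon(
    template: NucSequence,
    fwd: PrimerOligo,
    rev: PrimerOligo,
    rules: DesignRules | None = None,
) -> AmpliconMap:
    """Locate the unique productive primer pairing and map the amplicon.

    Productive means the forward primer anneals on the plus strand
    upstream of (and not overlapping) the reverse primer's minus-strand
    site.  Zero productive pairings raise :class:`NoAmpliconError`
    naming the missing primer; several raise
    :class:`AmbiguousAmpliconError` listing all pairings.
    """
    if fwd.role != "amplification_forward":
        raise ValueError(f"{fwd.name!r} does not have role amplification_forward")
    if rev.role != "amplification_reverse":
        raise ValueError(f"{rev.name!r} does not have role amplification_reverse")
    rules = rules or DesignRules()
    max_mm = rules.max_primer_site_mismatches

    fwd_sites = [
        s for s in find_binding_sites(template, fwd, max_mm) if s.strand == "+"
    ]
    rev_sites = [
        s for s in find_binding_sites(template, rev, max_mm) if s.strand == "-"
    ]
    if not fwd_sites and not rev_sites:
        raise NoAmpliconError(
            f"no amplicon on {template.id!r}: no binding site for forward primer "
            f"{fwd.name!r} or reverse primer {rev.name!r}"
        )
    if not fwd_sites:
        raise NoAmpliconError(
            f"no amplicon on {template.id!r}: no plus-strand site for forward "
            f"primer {fwd.name!r}"
        )
    if not rev_sites:
        raise NoAmpliconError(
            f"no amplicon on {template.id!r}: no minus-strand site for reverse "
            f"primer {rev.name!r}"
        )

    pairings = [
        (f, r) for f in fwd_sites for r in rev_sites if f.end <= r.start
    ]
    if not pairings:
        raise NoAmpliconError(
            f"no amplicon on {template.id!r}: sites for {fwd.name!r} and "
            f"{rev.name!r} exist but never in productive orientation"
        )
    if len(pairings) > 1:
        listing = "; ".join(
            f"{f.start}-{f.end} with {r.start}-{r.end}" for f, r in pairings
        )
        raise AmbiguousAmpliconError(
            f"ambiguous amplicon on {template.id!r}: {len(pairings)} productive "
            f"pairings ({listing})",
            pairings,
        )
    f, r = pairings[0]
    return AmpliconMap(
        template_id=template.id,
        amplicon_start=f.start,
        amplicon_end=r.end,
        fwd_footprint=f,
        rev_footprint=r,
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

AMPLICON_TSV_COLUMNS = [
    "template_id",
    "amplicon_start",
    "amplicon_end",
    "interior_start",
    "interior_end",
    "fwd_mismatches",
    "rev_mismatches",
]


def write_amplicon_tsv(maps: Iterable[AmpliconMap], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(AMPLICON_TSV_COLUMNS)
        for m in maps:
            w.writerow(
                [
                    m.template_id,
                    m.amplicon_start,
                    m.amplicon_end,
                    m.interior_start,
                    m.interior_end,
                    m.fwd_footprint.mismatches,
                    m.rev_footprint.mismatches,
                ]
            )


def write_amplicon_bed(maps: Iterable[AmpliconMap], path: str | Path) -> None:
    """BED6 of footprints and interior, 0-based half-open (native convention)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for m in maps:
            fp, rp = m.fwd_footprint, m.rev_footprint
            w.writerow([m.template_id, fp.start, fp.end, fp.primer_name, 0, fp.strand])
            w.writerow(
                [m.template_id, m.interior_start, m.interior_end, "interior", 0, "+"]
            )
            w.writerow([m.template_id, rp.start, rp.end, rp.primer_name, 0, rp.strand])
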