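"""Nucleotide sequences, IUPAC degeneracy algebra, and FASTA I/O.

Everything downstream (binding-site search, specificity screening,
blocking simulation) counts mismatches between possibly-degenerate
oligos and concrete templates.  Two IUPAC codes *match* when the base
sets they denote intersect — this is how a degenerate primer behaves at
the annealing step, and it makes printed primers such as
``CCTTCYGCAGGTTCACCTAC`` (one Y = C/T) self-consistent.

Sequences are stored uppercase with U normalized to T (rRNA genes are
amplified from DNA, and oligos are synthesized as DNA).  Coordinates are
0-based half-open throughout the package.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_complement, ambiguous_dna_values

__all__ = [
    "IUPAC_CODES",
    "NucSequence",
    "PrimerOligo",
    "DesignRules",
    "SequenceError",
    "FastaParseError",
    "iupac_match",
    "revcomp",
    "mismatch_count",
    "degeneracy",
    "encode",
    "read_fasta",
    "write_fasta",
]

FASTA_WIDTH = 70

# ---------------------------------------------------------------------------
# IUPAC algebra
# ---------------------------------------------------------------------------

#: code -> set of concrete bases, from Biopython's IUPAC tables
#: (Biopython's non-standard "X" alias is excluded).
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code in "ACGTRYSWKMBDHVN"
}
IUPAC_CODES: frozenset[str] = frozenset(IUPAC_SETS)

_COMPLEMENT = {c: ambiguous_dna_complement[c] for c in IUPAC_CODES}

# Bitmask encoding: A=1, C=2, G=4, T=8; a degenerate code is the union of
# its bases.  Two codes match iff their masks intersect, which turns
# mismatch counting into a vectorizable bitwise AND.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_MASK = {
    code: np.uint8(sum(_BASE_BIT[b] for b in bases))
    for code, bases in IUPAC_SETS.items()
}
_ENCODE_LUT = np.zeros(256, dtype=np.uint8)
for _code, _mask in _CODE_MASK.items():
    _ENCODE_LUT[ord(_code)] = _mask


class SequenceError(ValueError):
    """Invalid nucleotide content or inconsistent oligo definition."""


class FastaParseError(ValueError):
    """Malformed FASTA input; message carries the offending line number."""


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _validate(seq: str, context: str = "") -> str:
    seq = _normalize(seq)
    for i, ch in enumerate(seq):
        if ch not in IUPAC_CODES:
            where = f" in {context}" if context else ""
            raise SequenceError(
                f"invalid IUPAC nucleotide code {ch!r} at position {i}{where}"
            )
    return seq


def iupac_match(a: str, b: str) -> bool:
    """True iff the base sets denoted by codes ``a`` and ``b`` intersect.

    Symmetric; ``N`` matches everything.  Raises :class:`SequenceError`
    for characters outside the IUPAC alphabet.
    """
    a = _normalize(a)
    b = _normalize(b)
    if a not in IUPAC_CODES:
        raise SequenceError(f"invalid IUPAC nucleotide code {a!r}")
    if b not in IUPAC_CODES:
        raise SequenceError(f"invalid IUPAC nucleotide code {b!r}")
    return bool(_CODE_MASK[a] & _CODE_MASK[b])


@dataclass(frozen=True)
class NucSequence:
    """An identified nucleotide string over the IUPAC alphabet.

    ``seq`` is canonicalized on construction: uppercase, U→T, every
    character validated.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _validate(self.seq, context=repr(self.id)))

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int, id: str | None = None) -> "NucSequence":
        return NucSequence(id or f"{self.id}[{start}:{end}]", self.seq[start:end])


def encode(seq: "NucSequence | str") -> np.ndarray:
    """Encode a validated sequence as a uint8 base-set bitmask array."""
    s = seq.seq if isinstance(seq, NucSequence) else _validate(seq)
    return _ENCODE_LUT[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def revcomp(s: "NucSequence | str") -> "NucSequence | str":
    """Reverse complement, mapping degenerate codes to their complements."""
    if isinstance(s, NucSequence):
        return NucSequence(s.id, str(revcomp(s.seq)))
    seq = _validate(s)
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def mismatch_count(a: "NucSequence | str", b: "NucSequence | str") -> int:
    """Number of positions where the IUPAC base sets do not intersect.

    Both sequences must have equal length; the count is symmetric and
    zero on identical input.
    """
    ea, eb = encode(a), encode(b)
    if ea.size != eb.size:
        raise ValueError(
            f"mismatch_count requires equal lengths ({ea.size} != {eb.size})"
        )
    return int(np.count_nonzero((ea & eb) == 0))


def degeneracy(s: "NucSequence | str") -> int:
    """Number of concrete sequences a degenerate string expands to."""
    seq = s.seq if isinstance(s, NucSequence) else _validate(s)
    return math.prod(len(IUPAC_SETS[c]) for c in seq)


def gc_fraction(s: "NucSequence | str") -> float:
    """Fraction of S-compatible (G/C/S) positions; advisory metadata only."""
    seq = s.seq if isinstance(s, NucSequence) else _validate(s)
    if not seq:
        return 0.0
    return sum(1 for c in seq if c in "GCS") / len(seq)


# ---------------------------------------------------------------------------
# Oligos and design rules
# ---------------------------------------------------------------------------

ROLES = ("amplification_forward", "amplification_reverse", "blocking")
TERMINATORS = ("none", "C3_spacer")


@dataclass(frozen=True)
class PrimerOligo:
    """A 5'→3' oligo: gene-specific part, optional 5' adapter tail, role.

    Blocking oligos carry a 3' C3 spacer terminator (non-extensible by
    polymerase); amplification oligos must not.  The adapter tail is a
    sequencing-platform prefix excluded from all binding-site searches.
    """

    name: str
    gene_specific: NucSequence
    role: str
    adapter_tail: NucSequence | None = None
    terminator: str = "none"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SequenceError(f"unknown oligo role {self.role!r}")
        if self.terminator not in TERMINATORS:
            raise SequenceError(f"unknown terminator {self.terminator!r}")
        if self.role == "blocking" and self.terminator != "C3_spacer":
            raise SequenceError(
                f"blocking oligo {self.name!r} must carry a C3_spacer terminator"
            )
        if self.role != "blocking" and self.terminator != "none":
            raise SequenceError(
                f"amplification oligo {self.name!r} must not carry a terminator"
            )
        if len(self.gene_specific) < 1:
            raise SequenceError(f"oligo {self.name!r} has an empty gene-specific part")

    @property
    def full_sequence(self) -> str:
        """Adapter tail + gene-specific part, as synthesized (5'→3')."""
        tail = self.adapter_tail.seq if self.adapter_tail else ""
        return tail + self.gene_specific.seq

    def display(self) -> str:
        """Oligo in the printed notation, e.g. ``ACGT...[SpcC3]``."""
        suffix = "[SpcC3]" if self.terminator == "C3_spacer" else ""
        return f"{self.full_sequence}{suffix}"


@dataclass(frozen=True)
class DesignRules:
    """Thresholds for candidate selection and in-silico PCR.

    Defaults encode the published selection rules: blocking-primer
    windows of at least 20 nt inside the hypervariable interior, not
    overlapping the amplification-primer footprints, unique in the host,
    and at least 3 mismatches away from every off-target sequence.
    ``max_len`` bounds enumeration (a tool default; typical synthesized
    blocking oligos stay short).
    """

    min_len: int = 20
    max_len: int = 30
    min_offtarget_mismatches: int = 3
    require_host_unique: bool = True
    footprint_overlap_allowed: bool = False
    max_primer_site_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")
        if self.min_offtarget_mismatches < 0:
            raise ValueError("min_offtarget_mismatches must be >= 0")
        if self.max_primer_site_mismatches < 0:
            raise ValueError("max_primer_site_mismatches must be >= 0")

    def with_overrides(self, **kwargs) -> "DesignRules":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------
# A deliberately strict reader: every sequence character is validated at
# load time and malformed records are reported with their line number.
# Both LF and CRLF line endings are accepted; '.gz' paths are transparently
# decompressed.  Output wraps at a fixed width so identical records always
# produce identical bytes.


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t", encoding="ascii", newline="")
    return open(path, mode, encoding="ascii", newline="")


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a (possibly gzipped) multi-record FASTA file strictly.

    Raises :class:`FastaParseError` with a line number for content before
    the first header, empty ids, empty records, or invalid characters.
    """
    records: list[NucSequence] = []
    cur_id: str | None = None
    cur_parts: list[str] = []
    cur_line = 0

    def flush() -> None:
        if cur_id is None:
            return
        if not cur_parts:
            raise FastaParseError(
                f"line {cur_line}: record {cur_id!r} has an empty sequence"
            )
        try:
            records.append(NucSequence(cur_id, "".join(cur_parts)))
        except SequenceError as exc:
            raise FastaParseError(f"record {cur_id!r}: {exc}") from exc

    with _open_text(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0] if line[1:].split() else ""
                if not cur_id:
                    raise FastaParseError(f"line {lineno}: header with empty id")
                cur_parts = []
                cur_line = lineno
            else:
                if cur_id is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                cur_parts.append(line.strip())
        flush()
    return records


def write_fasta(
    records: Iterable[NucSequence],
    path: str | Path,
    descriptions: dict[str, str] | None = None,
) -> None:
    """Write records wrapped at a fixed width; round-trips with read_fasta."""
    with _open_text(path, "w") as fh:
        for rec in records:
            if not rec.seq:
                raise SequenceError(f"cannot write empty record {rec.id!r}")
            desc = (descriptions or {}).get(rec.id, "")
            header = f">{rec.id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), FASTA_WIDTH):
                fh.write(rec.seq[i : i + FASTA_WIDTH] + "\n")
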