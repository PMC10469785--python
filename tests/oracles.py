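"""Independent brute-force oracles used by the test suite.

Deliberately self-contained: IUPAC tables are re-declared here (not
imported from the package) and every search is a plain double loop, so
these stay an independent check on the vectorized implementations.
"""

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


# precomputed pair table (still plain set semantics, just not per call)
_MATCH = {
    (a, b): bool(set(sa) & set(sb))
    for a, sa in IUPAC.items()
    for b, sb in IUPAC.items()
}


def match(a: str, b: str) -> bool:
    return _MATCH[(a, b)]


def revcomp(s: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(s))


def mismatches(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if not match(x, y))


def find_sites(template: str, primer: str, max_mm: int):
    """All (start, end, strand, mismatches) with mm <= max_mm; plus-strand coords."""
    out = []
    k = len(primer)
    for strand, query in (("+", primer), ("-", revcomp(primer))):
        for off in range(len(template) - k + 1):
            mm = mismatches(template[off : off + k], query)
            if mm <= max_mm:
                out.append((off, off + k, strand, mm))
    out.sort()
    return out


def screen_min(candidate: str, subject: str) -> int:
    """Minimum ungapped mismatch count over every offset and strand.

    When the subject is shorter, full-overlap diagonals of the shorter
    length are scored with uncovered candidate positions counted as
    mismatches.
    """
    n, m = len(candidate), len(subject)
    best = None
    for query in (candidate, revcomp(candidate)):
        if m >= n:
            for off in range(m - n + 1):
                mm = mismatches(query, subject[off : off + n])
                best = mm if best is None else min(best, mm)
        else:
            for j in range(n - m + 1):
                mm = mismatches(query[j : j + m], subject) + (n - m)
                best = mm if best is None else min(best, mm)
    return best
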