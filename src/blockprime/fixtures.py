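"""Deterministic synthetic fixtures and the packaged published oligos.

The generator emulates the structure of a host 18S marker region:
random background, the forward-primer binding site, a hypervariable
interior, the reverse-complemented reverse-primer site, more background.
Off-targets share the host's amplicon scaffold but their interior copy
differs at an exact, requested number of positions.  Divergence is
clustered inside a fixed-length "signature" subwindow of the interior —
the divergence hotspot that makes a host-unique blocking window exist,
mirroring how real hypervariable regions separate related taxa.

Everything is driven by a single explicit seed (no global random
state); identical spec + seed produce byte-identical FASTA output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .core_seq import (
    NucSequence,
    PrimerOligo,
    read_fasta,
    revcomp,
    write_fasta,
)
from .insilico_pcr import extract_amplicon, find_binding_sites

__all__ = [
    "FixtureSpec",
    "load_oligos",
    "make_host",
    "make_offtargets",
    "make_community",
    "write_bundle",
    "HOST_REFERENCE_ACCESSION",
    "SIGNATURE_LENGTH",
]

#: NCBI accession of the real host (Hermetia illucens) 18S reference the
#: published blocking primers were designed against.  Recorded as
#: metadata only; nothing here ever fetches it.
HOST_REFERENCE_ACCESSION = "XR_005250514"

#: Version of the packaged oligo table (bumped if the table changes).
OLIGO_TABLE_VERSION = "1"

#: Length of the divergence hotspot shared by all generated off-targets;
#: equals the minimum blocking-primer length so a qualifying window
#: always exists when all requested distances are >= the screen threshold.
SIGNATURE_LENGTH = 20

_MAX_TRIES = 200
_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Packaged oligos
# ---------------------------------------------------------------------------


def load_oligos() -> dict[str, PrimerOligo]:
    """The published oligos (verbatim), keyed by name.

    1389F/1015R (18S V9) and 341F/785R (16S V3-V4) amplification pairs
    with their shared sequencing adapter tail, plus the two Hermetia
    illucens V9 blocking primers BP-F_Hi_V9 and BP-R_Hi_V9 (C3 spacer).
    """
    data = resources.files("blockprime") / "data"
    with resources.as_file(data / "oligos.fasta") as p:
        records = {r.id: r for r in read_fasta(p)}
    oligos: dict[str, PrimerOligo] = {}
    with (data / "oligos.tsv").open("r") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            name = row["name"]
            full = records[name].seq
            tail = row["adapter_tail"].strip()
            if tail:
                if not full.startswith(tail):
                    raise ValueError(
                        f"oligo {name!r}: declared adapter tail is not a prefix"
                    )
                gene_specific = full[len(tail) :]
                adapter = NucSequence(f"{name}_adapter", tail)
            else:
                gene_specific, adapter = full, None
            oligos[name] = PrimerOligo(
                name=name,
                gene_specific=NucSequence(name, gene_specific),
                role=row["role"],
                adapter_tail=adapter,
                terminator=row["terminator"],
            )
    return oligos


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one reproducible fixture bundle."""

    seed: int = 42
    host_length: int = 400
    interior_length: int = 120
    offtarget_count: int = 6
    offtarget_distances: tuple[int, ...] = (3, 4, 5, 6, 8, 10)
    community_size: int = 20
    community_host_fraction: float = 0.5
    background_gc: float = 0.5

    def __post_init__(self) -> None:
        if self.host_length < 1 or self.interior_length < 1:
            raise ValueError("host_length and interior_length must be positive")
        if len(self.offtarget_distances) != self.offtarget_count:
            raise ValueError("offtarget_distances length must equal offtarget_count")
        if any(d < 0 for d in self.offtarget_distances):
            raise ValueError("off-target distances must be >= 0")
        if not 0.0 <= self.community_host_fraction <= 1.0:
            raise ValueError("community_host_fraction must be in [0, 1]")
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError("background_gc must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "host_length": self.host_length,
            "interior_length": self.interior_length,
            "offtarget_count": self.offtarget_count,
            "offtarget_distances": list(self.offtarget_distances),
            "community_size": self.community_size,
            "community_host_fraction": self.community_host_fraction,
            "background_gc": self.background_gc,
        }


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p)) if n else ""


def _concretize(rng: np.random.Generator, seq: str) -> str:
    """Pick one concrete expansion of a degenerate string (seeded)."""
    from .core_seq import IUPAC_SETS

    return "".join(
        c if c in "ACGT" else rng.choice(sorted(IUPAC_SETS[c])) for c in seq
    )


def make_host(spec: FixtureSpec) -> NucSequence:
    """Synthetic host marker region with exactly one productive amplicon.

    Embeds the 1389F and 1015R gene-specific sites (the degenerate 1015R
    position concretized by seeded draw) around an interior of the
    requested length; regenerated (bounded retries) if the random
    background happens to contain a second primer site.
    """
    oligos = load_oligos()
    fwd, rev = oligos["1389F"], oligos["1015R"]
    rng = np.random.default_rng([spec.seed, 0])
    fwd_site = fwd.gene_specific.seq
    rev_site_rc = str(revcomp(_concretize(rng, rev.gene_specific.seq)))
    core = len(fwd_site) + spec.interior_length + len(rev_site_rc)
    flank = spec.host_length - core
    if flank < 2:
        raise ValueError(
            f"host_length {spec.host_length} too short for primer sites plus "
            f"interior_length {spec.interior_length} (need >= {core + 2})"
        )
    left = flank // 2

    for _ in range(_MAX_TRIES):
        interior = _random_bases(rng, spec.interior_length, spec.background_gc)
        bg_l = _random_bases(rng, left, spec.background_gc)
        bg_r = _random_bases(rng, flank - left, spec.background_gc)
        host = NucSequence(
            "host_synthetic", bg_l + fwd_site + interior + rev_site_rc + bg_r
        )
        if len(find_binding_sites(host, fwd, 0)) != 1:
            continue
        if len(find_binding_sites(host, rev, 0)) != 1:
            continue
        amp = extract_amplicon(host, fwd, rev)
        if (
            amp.interior_start == left + len(fwd_site)
            and amp.interior_length == spec.interior_length
        ):
            return host
    raise RuntimeError("could not generate a host with a unique amplicon")


def _signature_window(spec: FixtureSpec, interior_start: int, interior_end: int) -> tuple[int, int]:
    sig_len = min(SIGNATURE_LENGTH, interior_end - interior_start)
    rng = np.random.default_rng([spec.seed, 1])
    start = interior_start + int(
        rng.integers(0, interior_end - interior_start - sig_len + 1)
    )
    return start, start + sig_len


def make_offtargets(host: NucSequence, spec: FixtureSpec) -> list[NucSequence]:
    """Off-targets at exact interior mismatch distances from the host.

    Off-target i copies the host scaffold and mutates exactly
    ``offtarget_distances[i]`` interior positions, clustered in the
    shared signature subwindow first.  Each draw is re-verified with the
    specificity screen (the full-interior probe must score exactly the
    requested distance, and the signature probe must not fall below the
    screen threshold) and redrawn if a closer spurious match exists.
    """
    from .designer import CandidateWindow, specificity_screen
    from .core_seq import gc_fraction

    oligos = load_oligos()
    fwd, rev = oligos["1389F"], oligos["1015R"]
    amp = extract_amplicon(host, fwd, rev)
    i0, i1 = amp.interior_start, amp.interior_end
    if any(d > i1 - i0 for d in spec.offtarget_distances):
        raise ValueError(
            f"requested distance exceeds interior length {i1 - i0}"
        )
    sig_s, sig_e = _signature_window(spec, i0, i1)
    sig_positions = list(range(sig_s, sig_e))
    other_positions = [p for p in range(i0, i1) if not sig_s <= p < sig_e]

    def probe(start: int, end: int) -> CandidateWindow:
        s = host.seq[start:end]
        return CandidateWindow(
            host_id=host.id, start=start, end=end, strand="+",
            seq=NucSequence(f"probe:{start}-{end}", s), gc_fraction=gc_fraction(s),
        )

    interior_probe = probe(i0, i1)
    sig_probe = probe(sig_s, sig_e)
    rng = np.random.default_rng([spec.seed, 2])
    out: list[NucSequence] = []
    for i, d in enumerate(spec.offtarget_distances):
        n_sig = min(d, len(sig_positions))
        for _ in range(_MAX_TRIES):
            pos = list(rng.choice(sig_positions, size=n_sig, replace=False))
            if d > n_sig:
                pos += list(rng.choice(other_positions, size=d - n_sig, replace=False))
            seq = list(host.seq)
            for p in pos:
                choices = [b for b in "ACGT" if b != seq[p]]
                seq[p] = choices[int(rng.integers(0, 3))]
            ot = NucSequence(f"offtarget_{i}_d{d}", "".join(seq))
            # off-target must itself amplify uniquely (primer sites untouched)
            try:
                extract_amplicon(ot, fwd, rev)
            except Exception:
                continue
            if specificity_screen(interior_probe, [ot]).min_mismatches != d:
                continue
            # a window covering the signature must keep >= min(d, 3)
            # mismatches everywhere, so screened designs stay valid
            if specificity_screen(sig_probe, [ot]).min_mismatches < min(n_sig, 3):
                continue
            out.append(ot)
            break
        else:
            raise RuntimeError(
                f"could not place off-target {i} at distance {d} without a "
                f"closer spurious match"
            )
    return out


def make_community(
    host: NucSequence, offtargets: list[NucSequence], spec: FixtureSpec
) -> tuple[list[NucSequence], list[str]]:
    """Seeded multinomial mixture of host and off-target template copies.

    Returns (templates, host_ids); template ids carry a copy index so
    every record in the community FASTA is unique.
    """
    if spec.community_size < 1:
        raise ValueError("community_size must be >= 1")
    rng = np.random.default_rng([spec.seed, 3])
    k = len(offtargets)
    hf = spec.community_host_fraction
    if k == 0:
        probs = [1.0]
    else:
        probs = [hf] + [(1 - hf) / k] * k
    counts = rng.multinomial(spec.community_size, probs)
    templates: list[NucSequence] = []
    host_ids: list[str] = []
    for j in range(counts[0]):
        tid = f"{host.id}_copy{j}"
        templates.append(NucSequence(tid, host.seq))
        host_ids.append(tid)
    for i, ot in enumerate(offtargets):
        for j in range(counts[i + 1] if k else 0):
            templates.append(NucSequence(f"{ot.id}_copy{j}", ot.seq))
    return templates, host_ids


def write_bundle(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write host.fasta, offtargets.fasta, community.fasta, host_ids.txt,
    spec.yaml into ``outdir``; returns the paths keyed by role."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    host = make_host(spec)
    offtargets = make_offtargets(host, spec)
    community, host_ids = make_community(host, offtargets, spec)
    paths = {
        "host": outdir / "host.fasta",
        "offtargets": outdir / "offtargets.fasta",
        "community": outdir / "community.fasta",
        "host_ids": outdir / "host_ids.txt",
        "spec": outdir / "spec.yaml",
    }
    write_fasta([host], paths["host"])
    write_fasta(offtargets, paths["offtargets"])
    write_fasta(community, paths["community"])
    with open(paths["host_ids"], "w") as fh:
        for tid in host_ids:
            fh.write(tid + "\n")
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)
    return paths
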