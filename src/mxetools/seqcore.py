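"""Sequence data model, enzyme definitions and the in-silico digestion engine.

The central observable of a labeled-primer restriction assay is the distance
from a radiolabeled primer 5' end to the first downstream cut on the labeled
strand (denaturing gels resolve single strands, so that distance is the band
position).  Everything in this module serves that computation: IUPAC site
scanning on both strands, digestion of linear and circular molecules, and the
labeled-fragment calculation.

Coordinates are 0-based, half-open internally; human-readable reports convert
to 1-based closed.
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "DnaRecord",
    "RestrictionEnzyme",
    "CutSite",
    "FragmentSet",
    "LabeledFragment",
    "find_sites",
    "digest",
    "labeled_fragment",
    "load_enzyme_table",
    "builtin_enzymes",
    "get_enzymes",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "write_genbank",
    "revcomp",
]

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


class InvalidInputError(ValueError):
    """Raised for structurally invalid sequences, enzymes or coordinates."""


@dataclass
class DnaRecord:
    """A named DNA sequence with linear/circular topology and features.

    Features are ``(name, start, end, strand)`` tuples with 0-based half-open
    coordinates; on a circular molecule a feature may wrap the origin
    (start > end).
    """

    id: str
    seq: str
    topology: str = "linear"
    features: list[tuple[str, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise InvalidInputError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise InvalidInputError(
                f"record {self.id!r}: non-ACGTN characters {sorted(bad)}"
            )
        if self.topology not in ("linear", "circular"):
            raise InvalidInputError(f"bad topology {self.topology!r}")
        n = len(self.seq)
        for name, start, end, strand in self.features:
            if not (0 <= start < n and 0 < end <= n):
                raise InvalidInputError(f"feature {name!r} out of range")
            if start >= end and self.topology == "linear":
                raise InvalidInputError(
                    f"feature {name!r}: start >= end on a linear molecule"
                )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def reverse_complement(self) -> "DnaRecord":
        return DnaRecord(self.id + "_rc", revcomp(self.seq), self.topology)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Recognition site plus top/bottom strand cut offsets.

    Offsets are counted from the recognition-site start on the strand where
    the site reads 5'->3'.  Matching is carried out on both strands, so
    non-palindromic sites cut wherever either strand carries the recognition.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        site = self.recognition.upper()
        object.__setattr__(self, "recognition", site)
        if len(site) < 4:
            raise InvalidInputError(f"{self.name}: recognition shorter than 4 nt")
        bad = set(site) - set(IUPAC)
        if bad:
            raise InvalidInputError(f"{self.name}: bad IUPAC codes {sorted(bad)}")
        lo, hi = -20, len(site) + 20
        for off in (self.cut_top, self.cut_bottom):
            if not (lo <= off <= hi):
                raise InvalidInputError(f"{self.name}: cut offset {off} out of range")

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.recognition) == self.recognition


@dataclass(frozen=True)
class CutSite:
    """A top-strand cut coordinate with its provenance."""

    enzyme: str
    pos: int
    origin: int


@dataclass(frozen=True)
class FragmentSet:
    """Multiset of digestion fragment lengths (nt, top strand)."""

    lengths: tuple[int, ...]
    topology: str
    cut_count: int
    uncut: bool = False

    @property
    def counter(self) -> Counter:
        return Counter(self.lengths)

    def __iter__(self):
        return iter(self.lengths)


@dataclass(frozen=True)
class LabeledFragment:
    """Distance from a labeled 5' nucleotide to the first downstream cut."""

    length: int
    enzyme: str | None
    uncut: bool


# ---------------------------------------------------------------------------
# site scanning

import functools
import re


@functools.lru_cache(maxsize=512)
def _compile(pattern: str) -> "re.Pattern":
    # an N in the molecule never matches any code, so code N maps to [ACGT]
    return re.compile(
        "(?=" + "".join("[" + "".join(sorted(IUPAC[c])) + "]" for c in pattern) + ")"
    )


def _scan_one_strand(seq: str, pattern: str, limit: int) -> list[int]:
    """Start positions < limit where the IUPAC pattern matches (overlaps kept)."""
    rx = _compile(pattern)
    return [m.start() for m in rx.finditer(seq) if m.start() < limit]


def find_sites(record: DnaRecord, enzyme: RestrictionEnzyme) -> list[CutSite]:
    """All top-strand cut coordinates for one enzyme, sorted and deduplicated.

    Both strands are searched; a bottom-strand recognition cuts the top strand
    at ``match_start + (site_length - cut_bottom)``.  Circular molecules are
    scanned on the doubled sequence and coordinates reduced modulo length, so
    origin-spanning sites are found.
    """
    n = len(record)
    site = enzyme.recognition
    m = len(site)
    if record.is_circular:
        scan_seq = record.seq + record.seq[: m - 1]
        limit = n
    else:
        scan_seq = record.seq
        limit = n

    hits: dict[int, CutSite] = {}

    def add(pos: int, origin: int) -> None:
        if record.is_circular:
            pos %= n
        else:
            if not (0 <= pos <= n):
                return
        if pos not in hits:
            hits[pos] = CutSite(enzyme.name, pos, origin % n if record.is_circular else origin)

    for p in _scan_one_strand(scan_seq, site, limit):
        add(p + enzyme.cut_top, p)
    rc = revcomp(site)
    if rc != site:
        for p in _scan_one_strand(scan_seq, rc, limit):
            add(p + (m - enzyme.cut_bottom), p)
    else:
        # palindromic site: bottom-strand recognition coincides with the top
        # one but may cut the top strand at a different offset (e.g. HhaI)
        bottom_off = m - enzyme.cut_bottom
        if bottom_off != enzyme.cut_top:
            for p in _scan_one_strand(scan_seq, site, limit):
                add(p + bottom_off, p)
    return sorted(hits.values(), key=lambda c: c.pos)


def _all_cut_positions(
    record: DnaRecord, enzymes: Iterable[RestrictionEnzyme]
) -> list[CutSite]:
    enzymes = list(enzymes)
    if not enzymes:
        raise InvalidInputError("at least one enzyme required")
    merged: dict[int, CutSite] = {}
    for e in enzymes:
        for c in find_sites(record, e):
            merged.setdefault(c.pos, c)
    return sorted(merged.values(), key=lambda c: c.pos)


def digest(record: DnaRecord, enzymes: Iterable[RestrictionEnzyme]) -> FragmentSet:
    """Complete digest of a linear or circular molecule.

    Linear molecules keep terminal fragments; a circular molecule with k >= 1
    cuts yields k fragments; an uncut circle yields one full-length
    pseudo-fragment flagged ``uncut``.
    """
    n = len(record)
    cuts = [c.pos for c in _all_cut_positions(record, enzymes)]
    if record.is_circular:
        if not cuts:
            return FragmentSet((n,), "circular", 0, uncut=True)
        lengths = [
            (cuts[(i + 1) % len(cuts)] - cuts[i]) % n or n for i in range(len(cuts))
        ]
        # single cut on a circle linearises it into one full-length fragment
        if len(cuts) == 1:
            lengths = [n]
        return FragmentSet(tuple(sorted(lengths)), "circular", len(cuts))
    bounds = [0] + [p for p in cuts if 0 < p < n] + [n]
    lengths = [b - a for a, b in zip(bounds, bounds[1:])]
    return FragmentSet(tuple(sorted(lengths)), "linear", len(bounds) - 2)


def labeled_fragment(
    amplicon: DnaRecord,
    label_pos: int,
    enzymes: Iterable[RestrictionEnzyme],
) -> LabeledFragment:
    """Length of the fragment carrying the 5' label on the top strand.

    Returns the distance from ``label_pos`` to the nearest strictly downstream
    top-strand cut, or to the 3' end (flagged ``uncut``) if no enzyme cuts
    downstream.
    """
    if amplicon.is_circular:
        raise InvalidInputError("labeled-fragment sizing requires a linear amplicon")
    n = len(amplicon)
    if not (0 <= label_pos < n):
        raise InvalidInputError(f"label_pos {label_pos} outside sequence of length {n}")
    downstream = [
        c for c in _all_cut_positions(amplicon, enzymes) if label_pos < c.pos < n
    ]
    if not downstream:
        return LabeledFragment(n - label_pos, None, True)
    first = downstream[0]
    return LabeledFragment(first.pos - label_pos, first.enzyme, False)


# ---------------------------------------------------------------------------
# enzyme tables and sequence I/O

def load_enzyme_table(path: str | Path) -> dict[str, RestrictionEnzyme]:
    """Read a REBASE-style TSV (name, recognition, cut_top, cut_bottom)."""
    table: dict[str, RestrictionEnzyme] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        for req in ("name", "recognition", "cut_top", "cut_bottom"):
            if req not in idx:
                raise InvalidInputError(f"enzyme table missing column {req!r}")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            enz = RestrictionEnzyme(
                f[idx["name"]],
                f[idx["recognition"]],
                int(f[idx["cut_top"]]),
                int(f[idx["cut_bottom"]]),
            )
            table[enz.name] = enz
    return table


def builtin_enzymes() -> dict[str, RestrictionEnzyme]:
    """The enzyme table bundled with the package."""
    ref = importlib.resources.files("mxetools") / "data" / "enzymes.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_enzyme_table(path)


def get_enzymes(
    names: Iterable[str],
    table: dict[str, RestrictionEnzyme] | None = None,
) -> list[RestrictionEnzyme]:
    """Resolve enzyme names against a table (builtin by default)."""
    table = table if table is not None else builtin_enzymes()
    missing = [n for n in names if n not in table]
    if missing:
        raise KeyError(f"unknown enzyme(s): {', '.join(missing)}")
    return [table[n] for n in names]


def _from_bio(rec: _BioSeqRecord, topology: str | None = None) -> DnaRecord:
    topo = topology or rec.annotations.get("topology", "linear")
    feats = []
    for f in rec.features:
        try:
            feats.append(
                (
                    f.type,
                    int(f.location.start),
                    int(f.location.end),
                    f.location.strand or 1,
                )
            )
        except (TypeError, AttributeError):
            continue
    return DnaRecord(rec.id, str(rec.seq), topo, feats)


def read_fasta(path: str | Path, topology: str = "linear") -> list[DnaRecord]:
    """Read FASTA; topology defaults to linear (FASTA carries none)."""
    return [_from_bio(r, topology) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[DnaRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_genbank(path: str | Path) -> list[DnaRecord]:
    """Read GenBank; topology taken from the LOCUS line."""
    return [_from_bio(r) for r in SeqIO.parse(str(path), "genbank")]


def write_genbank(records: Sequence[DnaRecord], path: str | Path) -> None:
    bio = []
    for r in records:
        br = _BioSeqRecord(Seq(r.seq), id=r.id[:16], name=r.id[:16], description="")
        br.annotations["molecule_type"] = "DNA"
        br.annotations["topology"] = r.topology
        bio.append(br)
    SeqIO.write(bio, str(path), "genbank")
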