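"""sgRNA candidate enumeration and ranking for in-vitro Cas9 plasmid scission.

Cas9 with a single-guide RNA cuts double-stranded DNA bluntly 3 bp 5' of an
NGG protospacer-adjacent motif (PAM), and in vitro requires a perfect 20-nt
spacer match.  For cutting plasmids near a target interval the useful
heuristics are simple: low GC at the spacer 5' end, high GC in the
PAM-proximal seed, and a spacer that does not base-pair with the constant
tracrRNA scaffold of the sgRNA (which would disrupt its fold).  This module
enumerates candidates, ranks them by those criteria, reconstructs T7
in-vitro-transcription templates, and predicts linearization fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqcore import DnaRecord, FragmentSet, InvalidInputError, revcomp
from .splicereg import _runs

__all__ = [
    "GuideCandidate",
    "ScaffoldSpec",
    "T7_PROMOTER",
    "SCAFFOLD_ANTISENSE_OLIGO",
    "default_scaffold",
    "enumerate_guides",
    "rank_guides",
    "t7_template",
    "predict_linearization",
    "scaffold_clash",
]

# T7 promoter oligo; the terminal G is the +1 transcribed nucleotide.
T7_PROMOTER = "CCTGGCTAATACGACTCACTATAG"

# Antisense DNA oligo encoding the sgRNA scaffold (tracrRNA-derived constant
# 3' portion); the scaffold RNA is its reverse complement transcribed.
SCAFFOLD_ANTISENSE_OLIGO = (
    "AAAAAAAGCACCGACTCGGTGCCACTTTTTCAAGTTGATAACGGACTAGCCTTATTTTAACTTGCTATTTCTAGCTCTAAAAC"
)


def _rna(dna: str) -> str:
    return dna.replace("T", "U")


def _dna(rna: str) -> str:
    return rna.upper().replace("U", "T")


@dataclass
class ScaffoldSpec:
    """The constant scaffold portion of the sgRNA, as RNA."""

    rna: str
    protected: bool = True  # Cas9-bound sgRNA tolerates extended incubation

    def __post_init__(self) -> None:
        self.rna = self.rna.upper().replace("T", "U")
        if not self.rna:
            raise InvalidInputError("empty scaffold")


def default_scaffold() -> ScaffoldSpec:
    return ScaffoldSpec(_rna(revcomp(SCAFFOLD_ANTISENSE_OLIGO)))


def _gc(s: str) -> float:
    return (s.count("G") + s.count("C")) / len(s) if s else 0.0


def scaffold_clash(spacer: str, scaffold: ScaffoldSpec, allow_GU: bool = True) -> int:
    """Longest contiguous antiparallel complementary run spacer vs scaffold."""
    runs = _runs(spacer, _dna(scaffold.rna), allow_GU)
    return max((L for _, _, L, _ in runs), default=0)


@dataclass
class GuideCandidate:
    """A 20-nt spacer with PAM, predicted cut position and heuristic scores."""

    spacer: str
    pam: str
    strand: int  # +1 top, -1 bottom
    cut_pos: int  # top-strand coordinate of the blunt cut (3 bp 5' of PAM)
    pam_pos: int  # top-strand coordinate of the PAM start
    gc_5prime: float = 0.0  # GC of spacer nt 1-10 (PAM-distal)
    gc_seed: float = 0.0  # GC of spacer nt 11-20 (PAM-proximal)
    clash: int | None = None  # longest complementary run vs scaffold

    def __post_init__(self) -> None:
        self.spacer = self.spacer.upper()
        self.pam = self.pam.upper()
        if len(self.spacer) != 20:
            raise InvalidInputError("spacer must be 20 nt")
        if self.pam[1:] != "GG":
            raise InvalidInputError("PAM must be NGG")
        self.gc_5prime = _gc(self.spacer[:10])
        self.gc_seed = _gc(self.spacer[10:])

    @property
    def t7_ready(self) -> bool:
        return self.spacer.startswith("G")


def enumerate_guides(
    target: DnaRecord,
    interval: tuple[int, int],
    flank: int = 0,
) -> list[GuideCandidate]:
    """All 20-nt spacers (both strands) whose NGG PAM lies in interval +- flank.

    The blunt cut coordinate is 3 bp 5' of the PAM (between spacer positions
    17 and 18).  Circular targets wrap across the origin.
    """
    n = len(target)
    start, end = interval
    if not (0 <= start < end <= n):
        raise InvalidInputError(f"interval {interval} outside sequence of length {n}")
    lo, hi = start - flank, end + flank
    seq = target.seq
    if target.is_circular:
        seq2 = seq + seq  # wrap: spacers/PAMs may span the origin
    else:
        seq2 = seq

    out: list[GuideCandidate] = []
    seen: set[tuple[int, int]] = set()

    def keep(pam_pos: int) -> bool:
        if target.is_circular:
            p = pam_pos % n
            return lo <= p < hi or lo <= p - n < hi
        return lo <= pam_pos < hi

    # top strand: spacer(20) + N G G
    for p in range(len(seq2) - 2):
        if target.is_circular and p >= n:
            break
        if seq2[p + 1 : p + 3] == "GG" and keep(p):
            sp_start = p - 20
            if sp_start < 0:
                if not target.is_circular:
                    continue
                spacer = (seq2 + seq2)[sp_start + n : p + n]
            else:
                spacer = seq2[sp_start:p]
            if len(spacer) == 20 and "N" not in spacer:
                key = (p % n if target.is_circular else p, +1)
                if key not in seen:
                    seen.add(key)
                    cut = (p - 3) % n if target.is_circular else p - 3
                    if cut >= 0:
                        out.append(
                            GuideCandidate(spacer, seq2[p : p + 3], +1, cut, key[0])
                        )
    # bottom strand: top shows C C N + revcomp(spacer)
    for p in range(len(seq2) - 2):
        if target.is_circular and p >= n:
            break
        if seq2[p : p + 2] == "CC":
            pam_top_start = p  # bottom-strand PAM occupies top [p, p+3)
            if not keep(pam_top_start):
                continue
            sp_seg = seq2[p + 3 : p + 23]
            if len(sp_seg) < 20:
                if not target.is_circular:
                    continue
                sp_seg = (seq2 + seq2)[p + 3 : p + 23]
            spacer = revcomp(sp_seg)
            if len(spacer) == 20 and "N" not in spacer:
                key = (p % n if target.is_circular else p, -1)
                if key not in seen:
                    seen.add(key)
                    cut = (p + 6) % n if target.is_circular else p + 6
                    if cut <= n:
                        out.append(
                            GuideCandidate(
                                spacer, revcomp(seq2[p : p + 3]), -1, cut, key[0]
                            )
                        )
    out.sort(key=lambda g: (g.pam_pos, -g.strand))
    return out


def rank_guides(
    cands: list[GuideCandidate],
    scaffold: ScaffoldSpec | None = None,
    clash_threshold: int = 8,
    interval_mid: int | None = None,
) -> tuple[list[GuideCandidate], dict[str, str]]:
    """Rank candidates: low 5'-end GC, high seed GC, no scaffold clash.

    Candidates whose spacer can form a contiguous complementary run of
    >= ``clash_threshold`` nt with the scaffold are excluded (they could
    disrupt the scaffold fold).  Ties are broken by distance of the cut to
    ``interval_mid``.  Returns (ranked, exclusions) where exclusions maps
    spacer -> reason.
    """
    if not cands:
        raise InvalidInputError("no candidates to rank")
    scaffold = scaffold or default_scaffold()
    excl: dict[str, str] = {}
    kept: list[GuideCandidate] = []
    for c in cands:
        c.clash = scaffold_clash(c.spacer, scaffold)
        if c.clash >= clash_threshold:
            excl[c.spacer] = (
                f"scaffold clash: {c.clash}-nt complementary run (threshold "
                f"{clash_threshold})"
            )
        else:
            kept.append(c)

    def key(c: GuideCandidate):
        dist = abs(c.cut_pos - interval_mid) if interval_mid is not None else 0
        return (c.gc_5prime, -c.gc_seed, dist, c.pam_pos, -c.strand)

    kept.sort(key=key)
    return kept, excl


def t7_template(
    spacer: str,
    scaffold: ScaffoldSpec | None = None,
    mode: str = "full_ultramer",
) -> dict:
    """Reconstruct the antisense DNA template(s) for T7 sgRNA transcription.

    T7 transcription yields 5'-(G-prefixed if needed)spacer+scaffold-3'; the
    promoter's terminal G serves as the +1 nucleotide.  ``full_ultramer``
    returns one antisense oligo spanning promoter and entire sgRNA;
    ``two_oligo`` returns a 60-nt sense promoter+partial-sgRNA oligo and the
    constant scaffold antisense oligo, each annealing to the other before
    fill-in.
    """
    spacer = spacer.upper()
    if set(spacer) - set("ACGT"):
        raise InvalidInputError("spacer must be ACGT only")
    scaffold = scaffold or default_scaffold()
    g_spacer = spacer if spacer.startswith("G") else "G" + spacer
    sgrna = _rna(g_spacer) + scaffold.rna
    scaffold_dna = _dna(scaffold.rna)
    # sense template strand; promoter's final G doubles as the sgRNA's first G
    sense = T7_PROMOTER + g_spacer[1:] + scaffold_dna
    ultramer = revcomp(sense)
    result = {
        "sgrna": sgrna,
        "sgrna_length": len(sgrna),
        "g_prepended": not spacer.startswith("G"),
        "sense_template": sense,
    }
    if mode == "full_ultramer":
        result["antisense_ultramer"] = ultramer
        result["promoter_oligo"] = T7_PROMOTER
    elif mode == "two_oligo":
        sense60 = sense[:60]
        scaffold_antisense = revcomp(scaffold_dna)
        # the promoter's terminal G doubles as the sgRNA's first base
        overlap = 60 - (len(T7_PROMOTER) + len(g_spacer) - 1)
        if overlap < 1:
            raise InvalidInputError("spacer too long for the two-oligo design")
        result.update(
            promoter_spacer_oligo=sense60,
            scaffold_antisense_oligo=scaffold_antisense,
            annealing_overlap=overlap,
        )
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")
    return result


def predict_linearization(
    plasmid: DnaRecord, guides: list[GuideCandidate]
) -> FragmentSet:
    """Fragments produced by Cas9 cleavage at 1 or 2 exactly matching guides.

    Each guide's 20-nt spacer followed by its NGG PAM must occur exactly once
    in the plasmid (either strand); single mismatches are not tolerated.  The
    cut is blunt, 3 bp 5' of the PAM.  One guide on a circle linearizes it;
    two guides release the gap and backbone fragments.
    """
    if not 1 <= len(guides) <= 2:
        raise InvalidInputError("predict_linearization takes 1 or 2 guides")
    n = len(plasmid)
    seq = plasmid.seq + (plasmid.seq if plasmid.is_circular else "")
    cuts = []
    for g in guides:
        proto_top = g.spacer + g.pam  # reads on the protospacer strand
        positions = []
        for query, strand in ((proto_top, +1), (revcomp(proto_top), -1)):
            start = 0
            while True:
                p = seq.find(query, start)
                if p == -1 or (plasmid.is_circular and p >= n):
                    break
                # cut 3 bp 5' of PAM on the protospacer strand
                cut = p + 17 if strand == +1 else p + 6
                positions.append(cut % n if plasmid.is_circular else cut)
                start = p + 1
        positions = sorted(set(positions))
        if not positions:
            raise InvalidInputError(
                f"guide {g.spacer}: no exact protospacer+PAM match in {plasmid.id}"
            )
        if len(positions) > 1:
            raise InvalidInputError(
                f"guide {g.spacer}: multiple matches at {positions}"
            )
        cuts.append(positions[0])
    cuts = sorted(set(cuts))
    if plasmid.is_circular:
        if len(cuts) == 1:
            return FragmentSet((n,), "circular", 1)
        lengths = tuple(sorted(((b - a) % n or n) for a, b in
                               zip(cuts, cuts[1:] + [cuts[0]])))
        return FragmentSet(lengths, "circular", len(cuts))
    bounds = [0] + [c for c in cuts if 0 < c < n] + [n]
    lengths = tuple(sorted(b - a for a, b in zip(bounds, bounds[1:])))
    return FragmentSet(lengths, "linear", len(bounds) - 2)
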