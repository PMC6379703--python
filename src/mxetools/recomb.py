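"""Gap-repair recombineering planning.

Two designs are supported.  *Retrieval* pulls a large genomic region into a
vector: the region's two terminal segments serve as homology arms, fused in
the vector so that a unique blunt junction site (e.g. EcoRV) is created
exactly at the fusion point — cutting there exposes arm ends matching the
genome base-for-base, and recombination fills the gap with the region.
*Swap* replaces an interval of a large plasmid: the plasmid is opened with
two cuts (restriction enzymes or Cas9 guides), and an insert consisting of
left arm + replacement + right arm closes the gap; blunt release sites
(e.g. SmaI) flank the insert in its carrier so the released ends match the
destination flanks exactly.

Seam exactness — every engineered cut releasing ends identical to the target
sequence — is the design criterion throughout; validation is exact string
comparison, because recombineering is faithful enough that a single
substitution matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from . import guides as _guides
from . import seqcore
from .seqcore import DnaRecord, InvalidInputError, RestrictionEnzyme, find_sites

__all__ = [
    "ArmSpec",
    "RecombineeringDesign",
    "SeamError",
    "design_retrieval",
    "design_swap",
    "simulate_repair",
    "check_arm",
]


class SeamError(ValueError):
    pass


@dataclass
class ArmSpec:
    """Homology-arm length bounds (nt).

    300-600 nt arms give high recombineering efficiency; 60-299 nt arms work
    at much lower efficiency and are only accepted with ``allow_short`` (a
    warning is emitted).
    """

    min_len: int = 300
    max_len: int = 600
    allow_short: bool = False
    short_min: int = 60

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise InvalidInputError("need 0 < min_len <= max_len")


def check_arm(length: int, arms: ArmSpec, name: str) -> None:
    if length >= arms.min_len:
        return
    if arms.allow_short and length >= arms.short_min:
        warnings.warn(
            f"{name} arm of {length} nt is below {arms.min_len} nt: "
            "expect much lower recombineering efficiency"
        )
        return
    raise InvalidInputError(
        f"{name} arm of {length} nt shorter than minimum {arms.min_len} nt"
    )


@dataclass
class RecombineeringDesign:
    destination: DnaRecord
    gap: tuple[int, int]  # interval opened in the destination (or retrieval gap)
    insert: DnaRecord  # left arm + core + right arm
    left_arm: str
    right_arm: str
    core: str
    engineered_sites: list[tuple[str, int]] = field(default_factory=list)
    seam_ok: bool = True
    seam_mismatches: list[int] = field(default_factory=list)
    construct: DnaRecord | None = None  # retrieval plasmid, when applicable


def _circular_slice(seq: str, start: int, end: int) -> str:
    n = len(seq)
    start %= n
    end %= n
    if start < end:
        return seq[start:end]
    return seq[start:] + seq[:end]


def _compare(a: str, b: str, offset: int) -> list[int]:
    """Coordinates (offset + i) where a and b disagree."""
    return [offset + i for i, (x, y) in enumerate(zip(a, b)) if x != y]


# ---------------------------------------------------------------------------
# retrieval

def design_retrieval(
    source: DnaRecord,
    region: tuple[int, int],
    vector: DnaRecord,
    arms: ArmSpec | None = None,
    junction_enzyme: RestrictionEnzyme | None = None,
    arm_len: int | None = None,
) -> RecombineeringDesign:
    """Plan a retrieval construct: vector + fused terminal arms of the region.

    The circular retrieval plasmid is vector + left arm + right arm with the
    junction between the arms' inner ends.  The junction enzyme's site must
    form exactly at the fusion (from the arms' own terminal bases), cut
    exactly at the fusion coordinate, and occur nowhere else in the plasmid,
    so linearizing it exposes ends matching the genome base-for-base.
    """
    arms = arms or ArmSpec()
    if junction_enzyme is None:
        raise InvalidInputError("a junction enzyme is required")
    start, end = region
    if not (0 <= start < end <= len(source)):
        raise InvalidInputError("region outside source")
    if arm_len is None:
        arm_len = min(arms.max_len, (end - start) // 2)
    check_arm(arm_len, arms, "left")
    check_arm(arm_len, arms, "right")
    if 2 * arm_len > end - start:
        raise InvalidInputError("arms longer than the region itself")

    left_arm = source.seq[start : start + arm_len]
    right_arm = source.seq[end - arm_len : end]
    plasmid_seq = vector.seq + left_arm + right_arm
    plasmid = DnaRecord(f"{vector.id}_retrieval", plasmid_seq, "circular")
    junction = len(vector.seq) + arm_len  # fusion coordinate in the plasmid

    sites = find_sites(plasmid, junction_enzyme)
    if not sites:
        raise SeamError(
            f"{junction_enzyme.name} site not created at the arm fusion"
        )
    if [c.pos for c in sites] != [junction]:
        extra = [c.pos for c in sites if c.pos != junction]
        if extra:
            raise SeamError(
                f"{junction_enzyme.name} is not a unique lineariser: extra "
                f"site(s) cutting at {extra}"
            )
        raise SeamError(
            f"{junction_enzyme.name} cuts at {[c.pos for c in sites]}, not at "
            f"the fusion coordinate {junction}"
        )

    # linearized plasmid: right_arm + vector + left_arm; both termini must
    # match the genome exactly
    mism = _compare(left_arm, source.seq[start : start + arm_len], start)
    mism += _compare(right_arm, source.seq[end - arm_len : end], end - arm_len)
    design = RecombineeringDesign(
        destination=source,
        gap=(start + arm_len, end - arm_len),
        insert=DnaRecord("retrieval_arms", left_arm + right_arm),
        left_arm=left_arm,
        right_arm=right_arm,
        core="",
        engineered_sites=[(junction_enzyme.name, junction)],
        seam_ok=not mism,
        seam_mismatches=mism,
        construct=plasmid,
    )
    return design


def validate_retrieval_seams(
    construct: DnaRecord,
    source: DnaRecord,
    region: tuple[int, int],
    arm_len: int,
    vector_len: int,
) -> tuple[bool, list[int]]:
    """Re-check a (possibly edited) retrieval plasmid's arm sequences.

    Returns (seam_ok, mismatch coordinates in source space).
    """
    start, end = region
    left = construct.seq[vector_len : vector_len + arm_len]
    right = construct.seq[vector_len + arm_len : vector_len + 2 * arm_len]
    mism = _compare(left, source.seq[start : start + arm_len], start)
    mism += _compare(right, source.seq[end - arm_len : end], end - arm_len)
    return (not mism, mism)


# ---------------------------------------------------------------------------
# swaps

def _resolve_cut(destination: DnaRecord, cut) -> int:
    """A cut spec is a restriction enzyme, a guide, or a raw coordinate."""
    if isinstance(cut, int):
        return cut % len(destination)
    if isinstance(cut, RestrictionEnzyme):
        sites = find_sites(destination, cut)
        if len(sites) != 1:
            raise InvalidInputError(
                f"{cut.name}: {len(sites)} sites in {destination.id}; need exactly 1"
            )
        return sites[0].pos
    if isinstance(cut, _guides.GuideCandidate):
        frag = _guides.predict_linearization(destination, [cut])
        # a unique guide cut: recompute its coordinate
        seq2 = destination.seq + (
            destination.seq if destination.is_circular else ""
        )
        proto = cut.spacer + cut.pam
        p = seq2.find(proto)
        if p >= 0:
            return (p + 17) % len(destination)
        p = seq2.find(seqcore.revcomp(proto))
        return (p + 6) % len(destination)
    raise InvalidInputError(f"unsupported cut specification {cut!r}")


def design_swap(
    destination: DnaRecord,
    cut_a,
    cut_b,
    donor: DnaRecord,
    replacement: tuple[int, int],
    arms: ArmSpec | None = None,
    release_enzyme: RestrictionEnzyme | None = None,
    arm_len: int | None = None,
) -> RecombineeringDesign:
    """Plan an insert that swaps the destination interval between two cuts.

    The insert is left_arm + replacement + right_arm with arms copied
    verbatim from the destination flanks; blunt release-enzyme sites are
    formed at the insert ends by the carrier vector contributing the
    PAM-distal half, so the released ends match the destination exactly
    (seam exactness).  The release site must not occur inside the insert.
    """
    arms = arms or ArmSpec()
    pos_a = _resolve_cut(destination, cut_a)
    pos_b = _resolve_cut(destination, cut_b)
    if pos_a == pos_b:
        raise InvalidInputError("cut_a and cut_b coincide")
    if pos_a > pos_b and not destination.is_circular:
        pos_a, pos_b = pos_b, pos_a
    n = len(destination)
    gap_len = (pos_b - pos_a) % n if destination.is_circular else pos_b - pos_a

    if arm_len is None:
        arm_len = arms.max_len
    check_arm(arm_len, arms, "left")
    check_arm(arm_len, arms, "right")
    if destination.is_circular and gap_len + 2 * arm_len > n:
        raise InvalidInputError("arms overlap each other around the circle")
    if not destination.is_circular and (pos_a - arm_len < 0 or pos_b + arm_len > n):
        raise InvalidInputError("arms extend beyond the linear destination")

    left_arm = _circular_slice(destination.seq, pos_a - arm_len, pos_a)
    right_arm = _circular_slice(destination.seq, pos_b, pos_b + arm_len)
    rs, re_ = replacement
    if not (0 <= rs < re_ <= len(donor)):
        raise InvalidInputError("replacement interval outside donor")
    core = donor.seq[rs:re_]
    insert_seq = left_arm + core + right_arm
    insert = DnaRecord("swap_insert", insert_seq)

    engineered: list[tuple[str, int]] = []
    if release_enzyme is not None:
        site = release_enzyme.recognition
        c = release_enzyme.cut_top
        if c != release_enzyme.cut_bottom:
            raise InvalidInputError("release enzyme must cut blunt")
        head, tail = site[c:], site[:c]
        if not _iupac_ok(left_arm[: len(head)], head):
            raise SeamError(
                f"insert does not begin with {head} ({release_enzyme.name} "
                "half-site): released 5' end would not match the destination"
            )
        if not _iupac_ok(right_arm[len(right_arm) - len(tail) :], tail):
            raise SeamError(
                f"insert does not end with {tail} ({release_enzyme.name} "
                "half-site): released 3' end would not match the destination"
            )
        internal = [
            s.pos
            for s in find_sites(insert, release_enzyme)
            if 0 < s.pos < len(insert_seq)
        ]
        if internal:
            raise SeamError(
                f"{release_enzyme.name} cuts inside the insert at {internal}"
            )
        engineered.append((release_enzyme.name, 0))
        engineered.append((release_enzyme.name, len(insert_seq)))

    design = RecombineeringDesign(
        destination=destination,
        gap=(pos_a, pos_b),
        insert=insert,
        left_arm=left_arm,
        right_arm=right_arm,
        core=core,
        engineered_sites=engineered,
        seam_ok=True,
        seam_mismatches=[],
    )
    # verify arms against destination flanks (exact string check)
    mism = _compare(left_arm, _circular_slice(destination.seq, pos_a - arm_len, pos_a), pos_a - arm_len)
    mism += _compare(right_arm, _circular_slice(destination.seq, pos_b, pos_b + arm_len), pos_b)
    design.seam_ok = not mism
    design.seam_mismatches = mism
    return design


def _iupac_ok(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in seqcore.IUPAC[p] for b, p in zip(seq, pattern)
    )


def simulate_repair(design: RecombineeringDesign) -> tuple[DnaRecord, DnaRecord]:
    """Products of gap repair: the intended recombinant and the backbone product.

    The recombinant replaces the gap interval with the insert core; the
    backbone side product arises from recombination of the two arms without
    the core (the gap closed by left arm + right arm alone).  Both are
    returned so their restriction fingerprints can be precomputed.
    """
    if not design.seam_ok:
        raise SeamError(
            f"refusing to simulate a design with seam mismatches at "
            f"{design.seam_mismatches}"
        )
    dest = design.destination
    a, b = design.gap
    if dest.is_circular and a > b:
        # gap wraps the origin: rotate so the retained arc is contiguous
        retained = _circular_slice(dest.seq, b, a)
        recomb_seq = design.core + retained
        backbone_seq = design.left_arm + design.right_arm + retained
    else:
        recomb_seq = dest.seq[:a] + design.core + dest.seq[b:]
        backbone_seq = dest.seq[:a] + design.left_arm + design.right_arm + dest.seq[b:]
    recombinant = DnaRecord(dest.id + "_recombinant", recomb_seq, dest.topology)
    backbone = DnaRecord(dest.id + "_backbone", backbone_seq, dest.topology)
    return recombinant, backbone
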