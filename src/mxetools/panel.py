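"""Enzyme-panel design for same-length variant discrimination.

A cluster of mutually exclusive variable exons produces RT-PCR amplicons of
nearly identical length, indistinguishable on agarose.  A panel of frequent
cutters assigns each variant a unique labeled-fragment length, so that all
variants resolve in one lane of a denaturing gel.  This module verifies and
searches such panels, designs diagnostic digests that distinguish parental
from recombinant plasmids, screens undigested plasmids for concatemers, and
picks variant-specific primer windows from an alignment.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field

from . import seqcore
from .seqcore import (
    DnaRecord,
    FragmentSet,
    InvalidInputError,
    RestrictionEnzyme,
    digest,
    labeled_fragment,
)

__all__ = [
    "Variant",
    "VariantSet",
    "EnzymePanel",
    "GelModel",
    "DiagnosticDigest",
    "PrimerWindow",
    "verify_panel",
    "design_panel",
    "diagnostic_digest",
    "concatemer_check",
    "divergent_window_primers",
    "co_migration_groups",
]

DENATURING_RESOLUTION = 1  # nt, sequencing-type acrylamide
AGAROSE_RESOLUTION = 50  # nt, fingerprint gels


@dataclass(frozen=True)
class Variant:
    id: str
    amplicon: DnaRecord
    label_pos: int = 0


@dataclass
class VariantSet:
    """>=2 same-length variant amplicons sharing primer context."""

    variants: list[Variant]

    def __post_init__(self) -> None:
        if len(self.variants) < 2:
            raise InvalidInputError("a variant set needs at least 2 variants")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("variant ids must be unique")
        for v in self.variants:
            if not (0 <= v.label_pos < len(v.amplicon)):
                raise InvalidInputError(f"variant {v.id}: label_pos out of range")

    def __iter__(self):
        return iter(self.variants)

    def __len__(self):
        return len(self.variants)

    @property
    def ids(self) -> list[str]:
        return [v.id for v in self.variants]


@dataclass
class EnzymePanel:
    """A candidate enzyme set with its per-variant labeled-fragment map."""

    enzymes: tuple[str, ...]
    resolution: int
    assignment: dict[str, int]
    unique: bool
    uncut_variants: tuple[str, ...] = ()
    per_enzyme: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def min_gap(self) -> int:
        lens = sorted(self.assignment.values())
        if len(lens) < 2:
            return 0
        return min(b - a for a, b in zip(lens, lens[1:]))

    @property
    def max_fragment(self) -> int:
        return max(self.assignment.values())


def _unique(lengths: list[int], resolution: int) -> bool:
    s = sorted(lengths)
    return all(b - a >= resolution for a, b in zip(s, s[1:]))


def co_migration_groups(lengths: list[int], resolution: int) -> list[list[int]]:
    """Greedy maximal groups of lengths that co-migrate within resolution."""
    groups: list[list[int]] = []
    for x in sorted(lengths, reverse=True):
        if groups and groups[-1][-1] - x < resolution:
            groups[-1].append(x)
        else:
            groups.append([x])
    return groups


@dataclass
class GelModel:
    """Band list for a simulated lane, sorted by descending length."""

    resolution: int
    bands: list[tuple[int, list[str]]]  # (length, variant ids co-migrating)

    @classmethod
    def from_assignment(cls, assignment: dict[str, int], resolution: int) -> "GelModel":
        by_len = sorted(assignment.items(), key=lambda kv: -kv[1])
        bands: list[tuple[int, list[str]]] = []
        for vid, length in by_len:
            if bands and bands[-1][0] - length < resolution:
                bands[-1][1].append(vid)
            else:
                bands.append((length, [vid]))
        return cls(resolution, bands)


def _resolve(names, table):
    return seqcore.get_enzymes(sorted(names), table)


def verify_panel(
    vs: VariantSet,
    enzymes: set[str] | list[str],
    resolution: int = DENATURING_RESOLUTION,
    table: dict[str, RestrictionEnzyme] | None = None,
) -> EnzymePanel:
    """Check whether an enzyme set gives each variant a unique labeled length.

    Also reports per-single-enzyme assignments (the individual-enzyme lanes
    run next to the combined digest on a real gel).
    """
    enz_objs = _resolve(enzymes, table)
    assignment: dict[str, int] = {}
    uncut: list[str] = []
    for v in vs:
        lf = labeled_fragment(v.amplicon, v.label_pos, enz_objs)
        assignment[v.id] = lf.length
        if lf.uncut:
            uncut.append(v.id)
    per_enzyme = {
        e.name: {
            v.id: labeled_fragment(v.amplicon, v.label_pos, [e]).length for v in vs
        }
        for e in enz_objs
    }
    return EnzymePanel(
        tuple(sorted(e.name for e in enz_objs)),
        resolution,
        assignment,
        _unique(list(assignment.values()), resolution),
        tuple(uncut),
        per_enzyme,
    )


def design_panel(
    vs: VariantSet,
    library: set[str] | list[str],
    resolution: int = DENATURING_RESOLUTION,
    max_enzymes: int = 4,
    table: dict[str, RestrictionEnzyme] | None = None,
) -> list[EnzymePanel]:
    """Search enzyme subsets for minimal panels that discriminate all variants.

    Exhaustive over all subsets of size <= max_enzymes for libraries of up to
    12 enzymes (larger libraries use greedy construction with pairwise
    exchange).  Returns every minimal-cardinality unique panel, ranked by
    (fewer enzymes, larger minimum pairwise gap, shorter maximum fragment).
    An empty result carries a warning plus the best-achievable panel in it.
    """
    library = sorted(set(library))
    if not library or max_enzymes < 1:
        raise InvalidInputError("need a non-empty library and max_enzymes >= 1")
    table = table if table is not None else seqcore.builtin_enzymes()
    seqcore.get_enzymes(library, table)  # raises on unknown names

    if len(library) <= 12:
        winners: list[EnzymePanel] = []
        best: EnzymePanel | None = None
        for k in range(1, max_enzymes + 1):
            for combo in itertools.combinations(library, k):
                p = verify_panel(vs, combo, resolution, table)
                if p.unique:
                    winners.append(p)
                elif best is None or _partition_size(p) > _partition_size(best):
                    best = p
            if winners:
                break
        if not winners:
            warnings.warn("no enzyme subset discriminates all variants")
            return []
        winners.sort(key=lambda p: (len(p.enzymes), -p.min_gap, p.max_fragment))
        return winners

    return _greedy_exchange(vs, library, resolution, max_enzymes, table)


def _partition_size(p: EnzymePanel) -> int:
    """Number of resolution-distinct length classes a panel achieves."""
    return len(co_migration_groups(list(p.assignment.values()), p.resolution))


def _greedy_exchange(vs, library, resolution, max_enzymes, table):
    chosen: list[str] = []
    while len(chosen) < max_enzymes:
        scored = [
            (_partition_size(verify_panel(vs, chosen + [e], resolution, table)), e)
            for e in library
            if e not in chosen
        ]
        best_gain, best_e = max(scored)
        chosen.append(best_e)
        if verify_panel(vs, chosen, resolution, table).unique:
            break
    panel = verify_panel(vs, chosen, resolution, table)
    if panel.unique:
        # try to shrink by single exchanges / removals
        improved = True
        while improved and len(chosen) > 1:
            improved = False
            for e in list(chosen):
                trial = [x for x in chosen if x != e]
                if verify_panel(vs, trial, resolution, table).unique:
                    chosen = trial
                    improved = True
                    break
        return [verify_panel(vs, chosen, resolution, table)]
    warnings.warn("no enzyme subset discriminates all variants (greedy search)")
    return []


@dataclass
class DiagnosticDigest:
    """One enzyme subset's fingerprint comparison of two plasmids."""

    enzymes: tuple[str, ...]
    fragments_a: FragmentSet
    fragments_b: FragmentSet
    distinguishing_a: tuple[int, ...]  # band lengths seen only in a
    distinguishing_b: tuple[int, ...]

    @property
    def n_distinguishing(self) -> int:
        return len(self.distinguishing_a) + len(self.distinguishing_b)

    @property
    def total_fragments(self) -> int:
        return len(self.fragments_a.lengths) + len(self.fragments_b.lengths)


def _merge_bands(lengths: tuple[int, ...], resolution: int) -> Counter:
    """Collapse co-migrating lengths to their group maximum (band caller)."""
    merged: Counter = Counter()
    for grp in co_migration_groups(list(lengths), resolution):
        merged[grp[0]] += len(grp)
    return merged


def diagnostic_digest(
    parental: DnaRecord,
    recombinant: DnaRecord,
    library: set[str] | list[str],
    max_enzymes: int = 2,
    resolution: int = AGAROSE_RESOLUTION,
    table: dict[str, RestrictionEnzyme] | None = None,
) -> list[DiagnosticDigest]:
    """Rank enzyme subsets by how well their fingerprints separate two plasmids.

    Fragment multisets are compared after merging co-migrating bands within
    the gel resolution; subsets are ranked by the number of bands present in
    exactly one of the two digests, then by total band count (more
    distinguishable bands are easier to score on a gel).
    """
    if parental.topology != recombinant.topology:
        raise InvalidInputError("parental and recombinant topology differ")
    library = sorted(set(library))
    table = table if table is not None else seqcore.builtin_enzymes()
    results: list[DiagnosticDigest] = []
    for k in range(1, max_enzymes + 1):
        for combo in itertools.combinations(library, k):
            enz = seqcore.get_enzymes(combo, table)
            fa = digest(parental, enz)
            fb = digest(recombinant, enz)
            ca, cb = _merge_bands(fa.lengths, resolution), _merge_bands(
                fb.lengths, resolution
            )
            only_a = tuple(sorted((ca - cb).elements(), reverse=True))
            only_b = tuple(sorted((cb - ca).elements(), reverse=True))
            if only_a or only_b:
                results.append(DiagnosticDigest(combo, fa, fb, only_a, only_b))
    if not results:
        warnings.warn("no digest distinguishes the two plasmids")
        return []
    results.sort(key=lambda d: (-d.n_distinguishing, -d.total_fragments, d.enzymes))
    return results


def concatemer_check(
    observed_length: float, unit_length: float, tolerance: float = 0.05
) -> int | str:
    """Estimate plasmid copy number from an undigested-gel size.

    Returns the integer multiple k when the observed size is within
    ``tolerance * unit_length`` of ``k * unit_length`` (k >= 1), else
    ``"aberrant"``.  k == 1 is a normal monomer; k >= 2 a concatemer.
    """
    if unit_length <= 0 or observed_length <= 0:
        raise InvalidInputError("lengths must be positive")
    k = max(1, round(observed_length / unit_length))
    if abs(observed_length - k * unit_length) <= tolerance * unit_length:
        return k
    return "aberrant"


@dataclass(frozen=True)
class PrimerWindow:
    variant: str
    start: int  # 0-based alignment column
    divergence: int  # summed per-column mismatches vs all other variants
    terminal_mismatches: int  # mismatches in the window's 3'-most column


def divergent_window_primers(
    alignment: dict[str, str],
    window: int,
    k: int = 3,
) -> dict[str, list[PrimerWindow]]:
    """Pick per-variant primer windows from the most divergent alignment blocks.

    For each variant, windows are scored by the summed per-column count of
    other variants mismatching it; ties prefer more mismatches at the 3'
    terminal column (primer extension specificity), then the leftmost start.
    Identical sequences score zero everywhere and yield an empty ranking with
    a warning.
    """
    ids = list(alignment)
    if len(ids) < 2:
        raise InvalidInputError("need >= 2 aligned variants")
    length = len(next(iter(alignment.values())))
    if any(len(s) != length for s in alignment.values()):
        raise InvalidInputError("alignment rows differ in length")
    if window > length:
        raise InvalidInputError("window longer than alignment")

    out: dict[str, list[PrimerWindow]] = {}
    for vid in ids:
        me = alignment[vid]
        # per-column mismatch counts against all other variants
        col = [
            sum(1 for o in ids if o != vid and alignment[o][c] != me[c])
            for c in range(length)
        ]
        wins = []
        run = sum(col[:window])
        for s in range(length - window + 1):
            if s:
                run += col[s + window - 1] - col[s - 1]
            wins.append(PrimerWindow(vid, s, run, col[s + window - 1]))
        wins.sort(key=lambda w: (-w.divergence, -w.terminal_mismatches, w.start))
        top = [w for w in wins[:k] if w.divergence > 0]
        if not top:
            warnings.warn(f"variant {vid}: no divergence anywhere in the alignment")
        out[vid] = top
    return out
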