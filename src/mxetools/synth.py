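"""Synthetic fixtures with known ground truth.

Every generator emulates one of the toolkit's real input shapes: clusters of
same-length variant amplicons with planted restriction sites (the mutually
exclusive exon situation — variants indistinguishable by size but carrying
discriminating sites), noisy band-intensity tables with known inclusion
proportions (densitometry emulation), and parental/recombinant circular
plasmid pairs where the swap introduces a diagnostic site.  All generators
are deterministic for a fixed seed and return their ground truth, so
downstream tests are closed-loop parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seqcore
from .panel import Variant, VariantSet
from .quantify import BandTable
from .seqcore import DnaRecord, InvalidInputError, RestrictionEnzyme, find_sites

__all__ = [
    "ClusterSpec",
    "BandNoiseSpec",
    "PlasmidPairPlan",
    "make_cluster",
    "make_band_table",
    "make_plasmid_pair",
    "dscam_like_cluster_spec",
    "random_dna",
]

_BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _clean_fill(
    rng: np.random.Generator,
    length: int,
    forbidden: list[RestrictionEnzyme],
    max_rounds: int = 2000,
) -> str:
    """Random sequence free of any site of the forbidden enzymes.

    Offending matches are repaired by point mutation until the scan is clean
    (bounded; raises if the constraint is infeasible).
    """
    seq = list(random_dna(rng, length))
    for _ in range(max_rounds):
        rec = DnaRecord("fill", "".join(seq))
        dirty = False
        for e in forbidden:
            sites = find_sites(rec, e)
            if sites:
                dirty = True
                origin = sites[0].origin
                pos = origin + int(rng.integers(len(e.recognition)))
                pos = min(max(pos, 0), length - 1)
                old = seq[pos]
                seq[pos] = str(rng.choice(_BASES[_BASES != old]))
                break
        if not dirty:
            return "".join(seq)
    raise InvalidInputError("could not generate a clean background sequence")


@dataclass
class ClusterSpec:
    """A cluster of same-length variants with planted restriction sites."""

    n_variants: int
    variant_length: int  # variable-region length, identical across variants
    planted: dict[str, list[tuple[str, int]]]  # variant id -> [(enzyme, pos)]
    flank_left: int = 115  # constant exon + primer context, shared
    flank_right: int = 115
    seed: int = 0
    clean_background: bool = True
    library: tuple[str, ...] = ("MboI", "AluI", "HinP1I", "TaqI")

    def __post_init__(self) -> None:
        table = seqcore.builtin_enzymes()
        for vid, plan in self.planted.items():
            used: set[int] = set()
            for enz, pos in plan:
                L = len(table[enz].recognition)
                if not (0 <= pos <= self.variant_length - L):
                    raise InvalidInputError(
                        f"{vid}: site {enz}@{pos} outside variant body"
                    )
                span = set(range(pos, pos + L))
                if span & used:
                    raise InvalidInputError(f"{vid}: planted sites collide")
                used |= span


def make_cluster(spec: ClusterSpec) -> tuple[VariantSet, dict]:
    """Generate a VariantSet plus a ground-truth sidecar dict.

    Each amplicon is shared-left-flank + variant body + shared-right-flank,
    labeled at position 0 (the forward primer 5' end).  In clean-background
    mode no library enzyme cuts anywhere except at the planted sites, so each
    variant's labeled-fragment length under its planted enzyme is exactly
    ``flank_left + position + cut_offset``.
    """
    rng = np.random.default_rng(spec.seed)
    table = seqcore.builtin_enzymes()
    lib = [table[n] for n in spec.library]
    forbidden = lib if spec.clean_background else []

    left = _clean_fill(rng, spec.flank_left, forbidden)
    right = _clean_fill(rng, spec.flank_right, forbidden)

    variants: list[Variant] = []
    truth: dict = {"variants": {}, "flank_left": spec.flank_left, "seed": spec.seed}
    for i in range(spec.n_variants):
        vid = f"v{i + 1}"
        plan = spec.planted.get(vid, [])
        full = None
        for _attempt in range(20):
            body = list(_clean_fill(rng, spec.variant_length, forbidden))
            for enz, pos in plan:
                site = table[enz].recognition
                if "N" in site:
                    site = site.replace("N", "A")
                body[pos : pos + len(site)] = list(site)
            cand = left + "".join(body) + right
            if not spec.clean_background:
                full = cand
                break
            try:
                # planting and flank/body junctions may create collateral
                # sites; repair by mutating body bases off the planted spans
                full = _repair_collateral(
                    rng, cand, plan, lib, table,
                    body_range=(
                        spec.flank_left,
                        spec.flank_left + spec.variant_length,
                    ),
                )
                break
            except InvalidInputError:
                continue
        if full is None:
            raise InvalidInputError(f"{vid}: could not build a clean variant")
        amplicon = DnaRecord(vid, full)
        variants.append(Variant(vid, amplicon, 0))
        truth["variants"][vid] = {
            "planted": [
                {
                    "enzyme": enz,
                    "position": pos,
                    "labeled_length": spec.flank_left + pos + table[enz].cut_top,
                }
                for enz, pos in plan
            ],
            "length": len(amplicon),
        }
    return VariantSet(variants), truth


def _repair_collateral(rng, full, plan, lib, table, body_range, max_rounds=2000):
    """Mutate body bases until no library enzyme cuts outside planted sites."""
    b0, b1 = body_range
    planted_spans = set()
    planted_origins = set()
    for enz, pos in plan:
        L = len(table[enz].recognition)
        planted_spans |= set(range(b0 + pos, b0 + pos + L))
        planted_origins.add((enz, b0 + pos))
    seq = list(full)
    for _ in range(max_rounds):
        rec = DnaRecord("amplicon", "".join(seq))
        dirty = False
        for e in lib:
            for s in find_sites(rec, e):
                if (e.name, s.origin) in planted_origins:
                    continue
                span = [
                    p
                    for p in range(s.origin, s.origin + len(e.recognition))
                    if b0 <= p < b1 and p not in planted_spans
                ]
                if not span:
                    raise InvalidInputError(
                        "unrepairable collateral site outside the variant body"
                    )
                pos = int(rng.choice(span))
                old = seq[pos]
                seq[pos] = str(rng.choice(_BASES[_BASES != old]))
                dirty = True
                break
            if dirty:
                break
        if not dirty:
            return "".join(seq)
    raise InvalidInputError("could not repair collateral sites")


def dscam_like_cluster_spec(seed: int = 0) -> ClusterSpec:
    """A 12-variant preset shaped like the exon 4 cluster.

    Twelve ~200-nt variable regions with ~115-nt constant flanks; each
    variant carries one planted site from the four-cutter panel at a distinct
    position, so a unique labeled-fragment assignment exists and a 4-enzyme
    panel is discoverable.
    """
    enzymes = ["MboI", "AluI", "HinP1I", "TaqI"]
    planted = {
        f"v{i + 1}": [(enzymes[i % 4], 30 + 12 * i)] for i in range(12)
    }
    return ClusterSpec(
        n_variants=12,
        variant_length=200,
        planted=planted,
        seed=seed,
    )


@dataclass
class BandNoiseSpec:
    """Noisy band-intensity emulation around known inclusion proportions."""

    proportions: np.ndarray  # true per-variant inclusion, sums to 1
    sigma: float = 0.1  # lognormal noise SD (log scale)
    n_samples: int = 3
    seed: int = 0
    loading_range: tuple[float, float] = (0.5, 2.0)  # per-lane loading factor
    group_labels: list[str] | None = None  # one per sample
    group_effects: dict[str, np.ndarray] | None = None  # multiplicative, per variant

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, float)
        if not np.isclose(self.proportions.sum(), 1.0):
            raise InvalidInputError("true proportions must sum to 1")
        if self.sigma < 0:
            raise InvalidInputError("sigma must be >= 0")


def make_band_table(spec: BandNoiseSpec) -> tuple[BandTable, dict]:
    """Intensities = proportion x lognormal(0, sigma) noise x lane loading."""
    rng = np.random.default_rng(spec.seed)
    k = len(spec.proportions)
    cols = {}
    labels = spec.group_labels or [f"s{j + 1}" for j in range(spec.n_samples)]
    names = []
    for j in range(spec.n_samples):
        p = spec.proportions.copy()
        label = labels[j] if spec.group_labels else None
        if spec.group_effects and label in spec.group_effects:
            p = p * spec.group_effects[label]
            p = p / p.sum()
        loading = rng.uniform(*spec.loading_range)
        noise = np.exp(rng.normal(0.0, spec.sigma, size=k))
        name = f"{labels[j]}_{j + 1}" if spec.group_labels else labels[j]
        names.append(name)
        cols[name] = p * noise * loading
    df = pd.DataFrame(cols, index=[f"v{i + 1}" for i in range(k)])
    groups = (
        pd.Series(labels, index=names) if spec.group_labels else None
    )
    truth = {
        "proportions": spec.proportions.tolist(),
        "sigma": spec.sigma,
        "seed": spec.seed,
    }
    return BandTable(df, groups), truth


@dataclass
class PlasmidPairPlan:
    """Parental/recombinant pair; the swap introduces one diagnostic site.

    Defaults reproduce the worked fingerprint: the parental BamHI/EcoRI
    digest contains a 5274-bp fragment; the swapped segment adds an EcoRI
    site splitting it into 3649 + 1625 bp.
    """

    backbone_length: int = 15000
    parental_fragment: int = 5274
    split_at: int = 3649
    frame_enzyme: str = "BamHI"
    diagnostic_enzyme: str = "EcoRI"
    swap_halfwidth: int = 500  # swapped segment extends this far around the new site
    seed: int = 0


def make_plasmid_pair(
    plan: PlasmidPairPlan | None = None,
) -> tuple[DnaRecord, DnaRecord, dict]:
    """Build a circular parental plasmid and its recombinant.

    The parental molecule carries two frame-enzyme sites delimiting a
    fragment of ``parental_fragment`` bp and no diagnostic-enzyme site; the
    recombinant is identical except for a swapped segment that introduces the
    diagnostic site at ``split_at`` into that fragment, so a
    frame+diagnostic double digest shows the parental fragment replaced by
    two fragments summing to it.
    """
    plan = plan or PlasmidPairPlan()
    table = seqcore.builtin_enzymes()
    frame = table[plan.frame_enzyme]
    diag = table[plan.diagnostic_enzyme]
    n = plan.backbone_length
    if plan.parental_fragment >= n:
        raise InvalidInputError("parental fragment larger than the plasmid")
    last_err = None
    for attempt in range(10):
        rng = np.random.default_rng((plan.seed + 1000003 * attempt) % 2**31)
        try:
            return _build_pair(plan, rng, frame, diag, n)
        except InvalidInputError as err:  # collateral site; rebuild
            last_err = err
    raise InvalidInputError(f"could not build a valid plasmid pair: {last_err}")


def _build_pair(plan, rng, frame, diag, n):
    seq = list(_clean_fill(rng, n, [frame, diag]))
    # two frame sites so that the cut-to-cut distance equals parental_fragment
    anchor = 100
    c1 = anchor + frame.cut_top
    for origin in (anchor, anchor + plan.parental_fragment):
        seq[origin : origin + len(frame.recognition)] = list(frame.recognition)
    parental_seq = "".join(seq)
    parental = DnaRecord("parental", parental_seq, "circular")

    # recombinant: swap a segment inside the fragment, adding the diagnostic
    # site so its cut lands split_at downstream of the first frame cut
    diag_origin = c1 + plan.split_at - diag.cut_top
    lo = max(anchor + len(frame.recognition), diag_origin - plan.swap_halfwidth)
    hi = min(anchor + plan.parental_fragment, diag_origin + plan.swap_halfwidth)
    swapped = list(parental_seq[lo:hi])
    swapped[diag_origin - lo : diag_origin - lo + len(diag.recognition)] = list(
        diag.recognition
    )
    recomb_seq = parental_seq[:lo] + "".join(swapped) + parental_seq[hi:]
    recombinant = DnaRecord("recombinant", recomb_seq, "circular")

    # validate that planting created no collateral sites
    frame_cuts = [s.pos for s in find_sites(parental, frame)]
    if frame_cuts != sorted([c1 % n, (c1 + plan.parental_fragment) % n]):
        raise InvalidInputError("collateral frame-enzyme site; rebuild")
    if find_sites(parental, diag):
        raise InvalidInputError("collateral diagnostic site in parental; rebuild")
    diag_cuts = [s.pos for s in find_sites(recombinant, diag)]
    if diag_cuts != [c1 + plan.split_at]:
        raise InvalidInputError("diagnostic site misplaced; rebuild")

    truth = {
        "parental_fragment": plan.parental_fragment,
        "recombinant_fragments": [
            plan.split_at,
            plan.parental_fragment - plan.split_at,
        ],
        "swap_interval": [lo, hi],
        "seed": plan.seed,
    }
    return parental, recombinant, truth


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
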