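# Methods

## Digestion model

Sequences are strings over {A,C,G,T,N}; coordinates are 0-based half-open
internally and converted to 1-based closed in reports. An enzyme is a
recognition site (IUPAC, length ≥ 4) with top- and bottom-strand cut offsets
counted from the recognition start on the strand where the site reads 5′→3′.
Matching runs on both strands: a bottom-strand recognition at top coordinate
*p* cuts the top strand at *p + (site length − cut_bottom)*. An N in the
molecule never matches any code (including N); degenerate codes in the
recognition match by IUPAC set semantics. Overlapping and nested matches
each produce a cut; coincident cut coordinates are merged. Circular
molecules are scanned on the doubled sequence with matches reported once,
reduced modulo length, so origin-spanning sites are found. Digestion is
complete (no partials) — partially digested products, methylation
sensitivity and star activity are outside the model.

Fragment lengths are defined on the **top (labeled) strand** between
successive top-strand cut coordinates. Denaturing gels resolve single
strands, so the labeled-strand length is the observable; the labeled
fragment runs from the label position to the first strictly downstream cut
(or to the 3′ end, flagged `uncut`). A consequence worth noting: for
enzymes leaving overhangs, the two strands of a terminal fragment genuinely
differ in length, so fragment multisets are strand-symmetric only for blunt
cutters (the property tests assert symmetry exactly there). Linear digests
conserve Σ fragments = sequence length with cut_count + 1 fragments; a
circle with k ≥ 1 cuts yields k fragments; an uncut circle is reported as
one full-length pseudo-fragment flagged `uncut`.

Enzyme definitions ship as a REBASE-style TSV (28 common enzymes); user
tables override. A unit test cross-checks every bundled site and offset
against Bio.Restriction, which otherwise plays no role in the engine.

## Panel design

`verify_panel` computes every variant's labeled fragment under the combined
digest and under each single enzyme (the individual lanes run next to the
combined lane on a real gel); a panel is unique when assigned lengths differ
pairwise by at least the gel resolution. Defaults: 1 nt for denaturing
(sequencing-type) gels, 50 nt for agarose fingerprints. `design_panel`
searches subsets exhaustively for libraries of ≤ 12 enzymes (greedy
construction with shrink-by-exchange beyond that) and returns all
minimal-cardinality unique panels ranked by (fewer enzymes, larger minimum
pairwise gap, shorter maximum fragment). The ranking beyond uniqueness is a
package choice: larger gaps are easier to call on a gel, and shorter
fragments migrate into the well-resolved region. Uncut variants participate
with their full amplicon length, so two uncut variants of equal length are
correctly reported as indistinguishable.

Diagnostic digests compare fragment *multisets*, not gel images: bands
co-migrating within the agarose resolution are merged before comparison,
and subsets are ranked by the count of bands present in exactly one digest,
then by total band count (more distinguishable bands per lane). Concatemers
are screened arithmetically from undigested sizes: observed ≈ k × unit
length within a fractional tolerance (default 5%) gives copy number k, else
"aberrant". Variant-specific primer windows are chosen from a supplied
alignment (alignment construction is out of scope) by summed per-column
mismatches against all other variants, with ties broken toward mismatches
at the window's 3′-terminal column — a mismatched primer 3′ end is what
blocks extension — then leftmost position.

## Quantification and outlier statistics

Inclusion is intensity over lane sum; because one labeled molecule yields
exactly one labeled fragment, intensities are molar and need no length
correction. No background subtraction is applied (pre-subtract upstream if
needed). Group contrasts use a two-tailed two-sample t-test (2 groups) or
one-way ANOVA followed by Tukey–Kramer pairwise comparisons
(studentized-range distribution via `scipy.stats.tukey_hsd`, which applies
the Kramer correction for unbalanced groups); significance tiers default to
0.05/0.01 to mirror the one/two-asterisk annotation convention and are
configurable.

Fold change is proportion over the per-variant grand mean across the chosen
individuals. Zero proportions are floored at half the smallest nonzero
proportion in the matrix before log transform (configurable); variants with
zero grand mean are excluded with a warning. Outlier flagging fits a
Gaussian to **log₂ fold changes pooled over all cells** and flags cells
whose two-sided normal tail probability is below α (default 0.05). The log
scale is the package's choice — fold changes are ratio-valued, so symmetric
up/down deviations should count equally — and pooling gives the fit ~120
cells instead of ~10; a per-variant mode is available behind a flag. With
12 × 10 cells the pooled fit yields an empirical type-I rate of ~0.048 at
α = 0.05 and ≥ 95% detection of a planted 4σ cell (both recomputed by the
test suite and the acceptance script). Note that at α = 0.05 roughly 5% of
null cells flag by construction; the procedure controls the per-cell rate,
not family-wise error (no multiplicity correction is applied to the flags).

## Splice-site scoring and duplex scanning

The splice-site scorer is a position-weight-matrix log-odds model:
Σ log₂(weight/background) over the window (donor windows conventionally
3 exonic + 6 intronic positions). Maximum-entropy scores are not
reimplemented — externally computed score tables import directly — because
downstream analysis only consumes scores. Correlation against per-group
mean inclusion reports Pearson and Spearman coefficients with P values and
least-squares trend lines per (group, score kind); zero-variance inputs
yield NaN with a warning rather than an exception.

The docking-site/selector scan finds, for every intron, all maximal
contiguous antiparallel complementary runs against the docking sequence
(Watson–Crick pairs scoring 1, optional G·U wobble 0.5 — the pairing is
RNA-level). Run-length complementarity was chosen over thermodynamic ΔG
because the biological claim under test is presence/absence of
base-pairing-capable sequence, and a run scan has an exact brute-force
oracle. Default minimum run 10 nt (runs below 4 are rejected as
uninformative); RNA secondary-structure folding is out of scope and
externally computed structures can be consulted instead.

## sgRNA design

Candidates are all 20-nt spacers on either strand whose NGG PAM lies in the
target interval ± flank; the blunt cut sits 3 bp 5′ of the PAM (between
spacer positions 17 and 18). "Seed" is interpreted as the 10 PAM-proximal
spacer nucleotides and "5′ end" as the 10 PAM-distal ones (configurable;
the boundary is a convention, not a measurement). Ranking: ascending 5′ GC,
descending seed GC, ties broken by cut distance to the interval midpoint.
Spacers able to form a contiguous complementary run of ≥ 8 nt with the
sgRNA scaffold are excluded — a proxy for disrupting the scaffold fold that
has an exact oracle; stricter checks can use imported structures. The
default scaffold is the 83-nt tracrRNA-derived constant region (stored as
its antisense DNA oligo; the scaffold RNA is its reverse complement).
Cleavage prediction requires a perfect 20-nt protospacer + PAM match,
occurring exactly once — single mismatches are not tolerated, matching
in-vitro Cas9 stringency — and fragments follow from blunt-cut coordinate
arithmetic. No off-target genome scanning or cleavage-efficiency modelling:
the targets are plasmids in vitro.

T7 template reconstruction prepends a G when the spacer lacks one (T7
initiates on G; the promoter oligo's terminal G is the +1 nucleotide) and
returns either one antisense ultramer spanning promoter + sgRNA or the
two-oligo design (60-nt sense promoter + partial sgRNA, annealed to the
constant scaffold antisense oligo, filled in by extension); the two designs
produce byte-identical templates, which the tests assert.

## Recombineering designs

Retrieval: the region's two terminal segments become homology arms, fused
in the vector so that a blunt junction site (e.g. EcoRV) forms *from the
arms' own terminal bases*, cuts exactly at the fusion coordinate, and
occurs nowhere else — linearizing then exposes ends matching the genome
base-for-base. Swap: the destination is opened by two unique cuts
(restriction enzymes or Cas9 guides, interchangeably), and the insert is
left arm + replacement + right arm with blunt release half-sites at the
insert termini (the carrier vector contributes the outer half), so released
ends match the destination exactly. Validation is exact string equality —
no tolerance — because recombineering fidelity is the point of the
workflow; any mismatch is reported with its coordinate. Arm defaults are
300–600 nt (the high-efficiency regime); 60–299 nt arms are accepted only
with an explicit flag and a low-efficiency warning. `simulate_repair`
returns both the intended recombinant (gap replaced by the insert core) and
the backbone side product (gap closed by the arms alone, the most common
aberration), so fingerprints for both can be precomputed; concatemers are
covered by the undigested-size check.

## Synthetic fixtures

`make_cluster` emulates a cluster of same-length variable exons: shared
constant flanks (default 115 nt each, the primer/constant-exon context),
equal-length variant bodies (default 200 nt), and planted restriction sites
at chosen positions. In clean-background mode no library enzyme cuts
anywhere except the planted sites (collateral matches, including
flank/body-junction spans, are repaired by seeded point mutation), so each
variant's labeled length is exactly flank + position + cut offset and every
downstream test is closed-loop parameter recovery. The 12-variant preset
(~430-nt amplicons, one planted four-cutter site per variant at staggered
positions) is sized to the real cluster's amplicon scale and constructed to
be solvable by exactly the four-enzyme panel. `make_band_table` emulates
densitometry: intensity = true proportion × lognormal(0, σ) noise × per-lane
loading factor (σ default 0.1, multiplicative because densitometry noise is
proportional). `make_plasmid_pair` builds a circular parental molecule with
a framed 5274-bp fragment and a recombinant whose swapped segment adds one
diagnostic site splitting it 3649 + 1625; generators validate their own
site inventory and re-derive from the seed if planting collides. What the
fixtures do **not** emulate: PCR amplification bias, RT efficiency,
gel-image artefacts, or sequence homology between variants — so passing
tests demonstrate correctness of the computations, not robustness to those
upstream effects on real data.

## Problem sizes and numerical choices

The test suite runs the digestion-oracle battery on 1,000 seeded random
sequences (20–5,000 nt, both topologies, palindromic/degenerate/
non-palindromic sites), the outlier calibration on 500 null replicates and
detection on 200 planted replicates (12 × 10 matrices), and panel-search
equivalence on 12 variants × 8 enzymes; the acceptance script uses the same
sizes. Ties in every ranking are broken deterministically (lexicographic
enzyme names, leftmost coordinates) so outputs are total orders.
Proportions are validated to 1e-9; t statistics match a closed-form
recomputation to 1e-10.

## Known limitations

- Band intensity vs fragment length on agarose is not modelled; diagnostic
  ranking counts distinguishable bands only.
- The Gaussian outlier fit assumes log-normal fold noise; heavy-tailed
  densitometry errors would inflate the flag rate.
- Primer windows are ranked by divergence only; melting temperature and
  dimer checks are out of scope.
- The scaffold-clash proxy and the duplex run-length score are
  complementarity heuristics, not folding or hybridization energies.
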