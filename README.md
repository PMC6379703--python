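# mxetools

Toolkit for designing and analysing restriction-fingerprint assays that
resolve **same-length mutually exclusive exons**, with companion utilities
for quantifying exon-inclusion levels, planning gap-repair recombineering of
large plasmids, and selecting sgRNAs for in-vitro Cas9 plasmid scission.

## The problem

Clusters of mutually exclusive variable exons — the *Drosophila* Dscam exon
4 cluster, with 12 variants, is the canonical case — produce RT-PCR
amplicons of nearly identical length. Agarose gels cannot tell the variants
apart, yet their sequences diverge enough to carry variant-specific
restriction sites. With a 5′-labeled forward primer, a digest with a small
set of frequent cutters turns each variant into a **labeled fragment** whose
length (the distance from the label to the first downstream cut on the
labeled strand) uniquely identifies it; all variants then resolve in a
single lane of a denaturing acrylamide gel, and band intensities give
inclusion levels.

For variant *v* with first downstream cut at top-strand coordinate *c* and
label at position ℓ, the observable is

    L(v) = c − ℓ          (nt, labeled strand)

A panel *E* of enzymes is *discriminating* at gel resolution *r* when
|L(v) − L(w)| ≥ r for every pair of variants. Inclusion of variant *v* in
sample *s* is its band intensity normalized to the lane sum,
π(v,s) = I(v,s) / Σ_w I(w,s) (one labeled molecule → one labeled fragment,
so no length correction). Individual-level outliers are found by fitting a
Gaussian to pooled log₂ fold changes from the per-variant grand mean and
flagging cells in the two-sided α tails.

## What's in the box

| module | contents |
| --- | --- |
| `seqcore` | sequence model (linear/circular), REBASE-style enzyme tables, IUPAC site scanning, in-silico digestion, labeled-fragment sizing, FASTA/GenBank I/O |
| `panel` | panel verification and minimal-panel search, parental/recombinant diagnostic digests, concatemer detection, divergent primer-window selection |
| `quantify` | inclusion levels, t-test / ANOVA+Tukey–Kramer group contrasts, fold-change matrices, Gaussian outlier flags, heatmap/TSV export |
| `splicereg` | PWM log-odds splice-site scoring (external score import supported), score-vs-inclusion correlation, docking-site/selector duplex scanning |
| `guides` | NGG-PAM sgRNA enumeration, GC/scaffold-clash ranking, T7 transcription-template reconstruction, cleavage/linearization prediction |
| `recomb` | retrieval and swap designs with homology arms, seam-exactness validation, repair-product simulation |
| `synth` | deterministic synthetic fixtures (variant clusters, band tables, plasmid pairs) with ground truth |

## Worked example

```python
from mxetools import panel, synth

# a 12-variant same-length cluster with planted discriminating sites
vs, truth = synth.make_cluster(synth.dscam_like_cluster_spec(seed=1))
p = panel.verify_panel(vs, ["MboI", "AluI", "HinP1I", "TaqI"], resolution=1)
print(p.unique)            # True
print(p.assignment)        # v1: 145, v2: 159, v3: 170, ... v12: 278
```

Every one of the 12 variants (all 430 nt, indistinguishable by size) gets a
distinct labeled-fragment length — 145, 159, 170, 182, 193, 207, 218, 230,
241, 255, 266 and 278 nt — so the combined four-cutter digest resolves the
whole cluster in one lane.

Fingerprinting a recombinant against its parental plasmid:

```python
par, rec, t = synth.make_plasmid_pair(synth.PlasmidPairPlan(seed=1))
d = panel.diagnostic_digest(par, rec, ["BamHI", "EcoRI"], max_enzymes=2)[0]
print(d.enzymes)            # ('BamHI', 'EcoRI')
print(d.distinguishing_a)   # (5274,)       parental-only band
print(d.distinguishing_b)   # (3649, 1625)  recombinant-only bands
```

The swap introduces one EcoRI site, so the 5274-bp parental fragment is
replaced by 3649 + 1625 bp fragments — the two recombinant bands sum exactly
to the parental band, which is the screening signature for a correct clone.

A CLI mirrors the main operations
(`mxetools digest | panel | fingerprint | quantify | outliers | ss-score |
duplex-scan | guides | synth`); run `mxetools --help`.

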