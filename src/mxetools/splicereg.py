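"""Splice-site strength scoring and docking-site duplex scanning.

Inclusion of a variable exon could in principle be set by the strength of its
splice sites or by base-pairing between a conserved docking site and intronic
selector sequences.  This module provides a position-weight-matrix log-odds
scorer for donor/acceptor sites (externally computed scores, e.g. maximum
entropy scores, can be imported instead), correlation of scores against
inclusion levels per sample group, and an exhaustive scan for contiguous
antiparallel complementarity between a docking site and intron sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqcore import DnaRecord, InvalidInputError

__all__ = [
    "SpliceSiteModel",
    "DuplexHit",
    "score_site",
    "read_matrix",
    "read_score_table",
    "correlate_scores_inclusion",
    "duplex_scan",
    "pairs",
]

_BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class SpliceSiteModel:
    """Per-position base probabilities for a donor or acceptor site window."""

    kind: str  # 'donor_5p' or 'acceptor_3p'
    exonic: int  # nt of the window inside the exon
    intronic: int
    weights: np.ndarray  # 4 x window, rows A,C,G,T, columns sum to 1
    background: np.ndarray = None  # length 4, sums to 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, float)
        if self.weights.shape != (4, self.exonic + self.intronic):
            raise InvalidInputError("weight matrix does not match window lengths")
        if not np.allclose(self.background.sum(), 1.0):
            raise InvalidInputError("background must sum to 1")

    @property
    def window(self) -> int:
        return self.exonic + self.intronic

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.weights.argmax(axis=0))

    def max_score(self) -> float:
        return float(
            np.log2(self.weights.max(axis=0) / self.background[self.weights.argmax(axis=0)]).sum()
        )


def score_site(model: SpliceSiteModel, site: str) -> float:
    """Log-odds score (bits) of a site window: sum of log2(weight/background)."""
    site = site.upper().replace("U", "T")
    if len(site) != model.window:
        raise InvalidInputError(
            f"site length {len(site)} != model window {model.window}"
        )
    if any(b not in _IDX for b in site):
        raise InvalidInputError("site contains non-ACGT characters")
    idx = [_IDX[b] for b in site]
    w = model.weights[idx, range(len(site))]
    return float(np.log2(w / model.background[idx]).sum())


def read_matrix(path, kind: str = "donor_5p", exonic: int = 3) -> SpliceSiteModel:
    """Read a whitespace-delimited 4-row (A,C,G,T) probability matrix.

    Rows may carry a leading base label.  ``exonic`` gives the number of
    window positions lying inside the exon (donor sites conventionally 3).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0].upper().rstrip(":") in _BASES:
                parts = parts[1:]
            rows.append([float(x) for x in parts])
    mat = np.asarray(rows, float)
    if mat.shape[0] != 4:
        raise InvalidInputError("matrix must have 4 rows (A,C,G,T)")
    return SpliceSiteModel(kind, exonic, mat.shape[1] - exonic, mat)


def read_score_table(path) -> pd.DataFrame:
    """Import externally computed splice-site scores.

    TSV columns: variant, score_5p, score_3p [, score_combined].  A missing
    combined column is filled with the sum of the 5' and 3' scores.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "score_combined" not in df.columns:
        df["score_combined"] = df["score_5p"] + df["score_3p"]
    return df


def correlate_scores_inclusion(
    scores: pd.DataFrame,
    inclusion: pd.DataFrame,
) -> pd.DataFrame:
    """Correlate splice-site scores with per-group mean inclusion levels.

    ``scores``: variants x {score_5p, score_3p, score_combined};
    ``inclusion``: variants x groups (mean inclusion per group).  Returns a
    tidy table with Pearson and Spearman coefficients, P values and the
    least-squares trend line (slope, intercept) per (group, score kind).
    """
    common = scores.index.intersection(inclusion.index)
    if len(common) < 3:
        raise InvalidInputError("need >= 3 variants with both score and inclusion")
    rows = []
    for group in inclusion.columns:
        y = inclusion.loc[common, group].to_numpy(float)
        for kind in ("score_5p", "score_3p", "score_combined"):
            x = scores.loc[common, kind].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(f"zero variance for {kind}/{group}: correlation undefined")
                rows.append(
                    dict(group=group, score=kind, pearson_r=np.nan, pearson_p=np.nan,
                         spearman_r=np.nan, spearman_p=np.nan, slope=np.nan,
                         intercept=np.nan, n=len(common))
                )
                continue
            pr = stats.pearsonr(x, y)
            sr = stats.spearmanr(x, y)
            fit = stats.linregress(x, y)
            rows.append(
                dict(group=group, score=kind,
                     pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
                     spearman_r=float(sr.statistic), spearman_p=float(sr.pvalue),
                     slope=float(fit.slope), intercept=float(fit.intercept),
                     n=len(common))
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# duplex scanning

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def pairs(a: str, b: str, allow_GU: bool = True) -> float:
    """Pair score for one opposed base pair: 1 WC, 0.5 GU wobble, 0 none.

    Bases are DNA-encoded (U folded onto T), so G.U wobble appears as (G, T).
    """
    if (a, b) in _WC:
        return 1.0
    if allow_GU and (a, b) in _GU:
        return 0.5
    return 0.0


@dataclass(frozen=True)
class DuplexHit:
    """A contiguous antiparallel complementary run between docking and intron."""

    intron: str
    intron_start: int  # 0-based start of the paired block in the intron
    docking_start: int  # 0-based start of the paired block in the docking site
    length: int
    score: float  # +1 per WC pair, +0.5 per GU pair


def _runs(dock: str, target: str, allow_GU: bool) -> list[tuple[int, int, int, float]]:
    """All maximal antiparallel complementary runs (dock_start, tgt_start, len, score).

    dock position i pairs with target position j when the duplex is laid
    antiparallel, and extending the duplex pairs (i+1, j-1).
    """
    n, m = len(dock), len(target)
    run = np.zeros((n + 1, m + 2), dtype=int)
    sc = np.zeros((n + 1, m + 2), dtype=float)
    out = []
    for i in range(n):
        for j in range(m):
            s = pairs(dock[i], target[j], allow_GU)
            if s > 0:
                run[i + 1][j + 1] = run[i][j + 2] + 1
                sc[i + 1][j + 1] = sc[i][j + 2] + s
    for i in range(n):
        for j in range(m):
            L = run[i + 1][j + 1]
            if L == 0:
                continue
            # maximal: cannot be extended by the next antiparallel pair
            if i + 1 < n and j - 1 >= 0 and run[i + 2][j] > L:
                continue
            out.append((i - L + 1, j, L, float(sc[i + 1][j + 1])))
    return out


def duplex_scan(
    docking: str,
    introns: list[DnaRecord],
    min_len: int = 10,
    allow_GU: bool = True,
) -> list[DuplexHit]:
    """Scan introns for selector-like complementarity to a docking site.

    Finds every maximal contiguous antiparallel run of Watson-Crick (and
    optionally G.U wobble) pairs of length >= ``min_len`` between the docking
    sequence and each intron, ranked by run length then pairing score.  A run
    of the full docking length means the intron contains (up to wobble) the
    reverse complement of the docking site.
    """
    if min_len < 4:
        raise InvalidInputError("min_len < 4 is uninformative")
    dock = docking.upper().replace("U", "T")
    if len(dock) < min_len:
        raise InvalidInputError("docking sequence shorter than min_len")
    hits: list[DuplexHit] = []
    for rec in introns:
        for ds, ts, L, score in _runs(dock, rec.seq, allow_GU):
            if L >= min_len:
                hits.append(DuplexHit(rec.id, ts, ds, L, score))
    hits.sort(key=lambda h: (-h.length, -h.score, h.intron, h.intron_start))
    return hits
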