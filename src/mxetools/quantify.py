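"""Band-intensity quantification of variable-exon inclusion.

Each lane of the assay carries one labeled fragment per included variant, so
band intensity is proportional to molar transcript abundance and a variant's
inclusion level is its intensity divided by the lane total.  Group contrasts
use a two-tailed t-test or one-way ANOVA with Tukey-Kramer post-hoc pairs;
individual-level outliers are found by fitting a Gaussian to pooled log2 fold
changes from the per-variant grand mean and flagging cells in the two-sided
tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BandTable",
    "InclusionProfile",
    "FoldChangeMatrix",
    "inclusion_levels",
    "compare_groups",
    "fold_change",
    "gaussian_outliers",
    "export_heatmap",
]


class DegenerateDataError(ValueError):
    pass


@dataclass
class BandTable:
    """Variant x sample intensity matrix with optional group labels."""

    intensities: pd.DataFrame  # rows: variants, columns: samples
    groups: pd.Series | None = None  # sample -> group label

    def __post_init__(self) -> None:
        if (self.intensities.values < 0).any():
            raise ValueError("negative band intensities")
        zero = self.intensities.columns[(self.intensities.sum(axis=0) == 0)]
        if len(zero):
            raise ValueError(f"all-zero sample column(s): {list(zero)}")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.intensities.columns)
            if self.groups.isna().any():
                raise ValueError("group labels missing for some samples")

    @classmethod
    def from_tsv(cls, path, groups_path=None) -> "BandTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        groups = None
        if groups_path is not None:
            g = pd.read_csv(groups_path, sep="\t", index_col=0)
            groups = g.iloc[:, 0]
        return cls(df, groups)


@dataclass
class InclusionProfile:
    """Per-sample inclusion proportions; every column sums to 1."""

    proportions: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        sums = self.proportions.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("inclusion columns must sum to 1")


@dataclass
class FoldChangeMatrix:
    """Per-variant, per-individual fold change from the variant grand mean."""

    fold: pd.DataFrame
    reference: pd.Series  # per-variant grand mean
    excluded: list[str] = field(default_factory=list)


def inclusion_levels(bt: BandTable) -> InclusionProfile:
    """Normalize each sample's intensities by the lane sum.

    One labeled molecule yields exactly one labeled fragment, so intensities
    are treated as molar without fragment-length correction.
    """
    sums = bt.intensities.sum(axis=0)
    return InclusionProfile(bt.intensities.div(sums, axis=1), bt.groups)


def _tiers(p: float, levels=(0.05, 0.01)) -> str:
    if p < levels[1]:
        return "**"
    if p < levels[0]:
        return "*"
    return ""


def compare_groups(
    profile: InclusionProfile,
    method: str = "anova_tukey",
    tier_levels: tuple[float, float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Per-variant group means, SEM and pairwise P values.

    ``t_test``: two-tailed two-sample t-test (exactly 2 groups).
    ``anova_tukey``: one-way ANOVA F-test followed by Tukey-Kramer pairwise
    comparisons (studentized-range distribution; the Kramer correction for
    unbalanced groups is what :func:`scipy.stats.tukey_hsd` implements).

    Returns a tidy table: one row per (variant, group pair) with means, SEM,
    the pairwise P value and a significance tier ('*' and '**' at the two
    ``tier_levels``).
    """
    if profile.groups is None:
        raise ValueError("profile has no group labels")
    df, groups = profile.proportions, profile.groups
    names = list(dict.fromkeys(groups))
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 replicates")
    if method == "t_test" and len(names) != 2:
        raise ValueError("t_test requires exactly 2 groups")
    if method == "anova_tukey" and len(names) < 3:
        raise ValueError("anova_tukey requires >= 3 groups")

    rows = []
    for variant, values in df.iterrows():
        per_group = [values[groups[groups == g].index].to_numpy(float) for g in names]
        means = {g: v.mean() for g, v in zip(names, per_group)}
        sems = {g: stats.sem(v) for g, v in zip(names, per_group)}
        if method == "t_test":
            p = stats.ttest_ind(per_group[0], per_group[1]).pvalue
            pairs = {(names[0], names[1]): float(p)}
            anova_p = float(p)
        else:
            anova_p = float(stats.f_oneway(*per_group).pvalue)
            hsd = stats.tukey_hsd(*per_group)
            pairs = {
                (names[i], names[j]): float(hsd.pvalue[i, j])
                for i in range(len(names))
                for j in range(i + 1, len(names))
            }
        for (ga, gb), p in pairs.items():
            rows.append(
                {
                    "variant": variant,
                    "group_a": ga,
                    "group_b": gb,
                    "mean_a": means[ga],
                    "mean_b": means[gb],
                    "sem_a": sems[ga],
                    "sem_b": sems[gb],
                    "anova_p": anova_p,
                    "p": p,
                    "tier": _tiers(p, tier_levels),
                }
            )
    return pd.DataFrame(rows)


def fold_change(
    profile: InclusionProfile,
    individuals: list[str] | None = None,
    pseudo: float | None = None,
) -> FoldChangeMatrix:
    """Fold change of each individual's inclusion from the variant grand mean.

    Zero proportions are floored at ``pseudo`` (default: half the smallest
    nonzero proportion in the matrix) before division so folds stay positive.
    Variants whose grand mean is zero are excluded with a warning.
    """
    df = profile.proportions
    if individuals is not None:
        df = df[individuals]
    if df.shape[1] < 2:
        raise ValueError("need >= 2 individuals")
    vals = df.to_numpy(float).copy()
    if pseudo is None:
        nz = vals[vals > 0]
        if nz.size == 0:
            raise DegenerateDataError("all proportions are zero")
        pseudo = nz.min() / 2.0
    vals[vals == 0] = pseudo
    ref = vals.mean(axis=1)
    excluded = [v for v, r in zip(df.index, ref) if r <= 0]
    if excluded:
        warnings.warn(f"variant(s) with zero grand mean excluded: {excluded}")
    keep = ref > 0
    fold = pd.DataFrame(
        vals[keep] / ref[keep, None], index=df.index[keep], columns=df.columns
    )
    return FoldChangeMatrix(fold, pd.Series(ref[keep], index=df.index[keep]), excluded)


def gaussian_outliers(
    fc: FoldChangeMatrix,
    alpha: float = 0.05,
    per_variant: bool = False,
) -> pd.DataFrame:
    """Flag (variant, individual) cells in the tails of a fitted Gaussian.

    Log2 fold changes are pooled over all cells (or fitted per variant row
    with ``per_variant=True``); a cell is flagged when its two-sided normal
    tail probability under the fitted mean/SD is below ``alpha``.

    Returns a boolean DataFrame shaped like the fold matrix; the fitted
    parameters are attached as ``.attrs['mu']`` / ``.attrs['sigma']``.
    """
    log2 = np.log2(fc.fold.to_numpy(float))
    if log2.size < 20:
        raise ValueError("need >= 20 cells for a stable Gaussian fit")
    if per_variant:
        mu = log2.mean(axis=1, keepdims=True)
        sd = log2.std(axis=1, ddof=1, keepdims=True)
        if (sd == 0).any():
            raise DegenerateDataError("a variant row has zero variance")
    else:
        mu = log2.mean()
        sd = log2.std(ddof=1)
        if sd == 0:
            raise DegenerateDataError("fold changes have zero variance")
    z = (log2 - mu) / sd
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    flags = pd.DataFrame(
        pvals < alpha, index=fc.fold.index, columns=fc.fold.columns
    )
    flags.attrs["mu"] = np.asarray(mu).ravel().tolist()
    flags.attrs["sigma"] = np.asarray(sd).ravel().tolist()
    return flags


def export_heatmap(
    fc: FoldChangeMatrix,
    flags: pd.DataFrame | None = None,
    tsv_path=None,
    image_path=None,
    cmap: str = "coolwarm",
):
    """Write the fold matrix as TSV and render a heatmap.

    Increased inclusion is drawn warm, decreased cool (log2 scale, symmetric
    limits); flagged cells get a border.  Returns the matplotlib figure when
    an image is rendered, else None.
    """
    if tsv_path is not None:
        fc.fold.to_csv(tsv_path, sep="\t")
    fig = None
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        log2 = np.log2(fc.fold.to_numpy(float))
        lim = max(1e-6, np.abs(log2).max())
        fig, ax = plt.subplots(
            figsize=(1 + 0.45 * fc.fold.shape[1], 1 + 0.3 * fc.fold.shape[0])
        )
        im = ax.imshow(log2, cmap=cmap, vmin=-lim, vmax=lim, aspect="auto")
        ax.set_xticks(range(fc.fold.shape[1]), fc.fold.columns, rotation=90)
        ax.set_yticks(range(fc.fold.shape[0]), fc.fold.index)
        if flags is not None:
            for i in range(flags.shape[0]):
                for j in range(flags.shape[1]):
                    if flags.iloc[i, j]:
                        ax.add_patch(
                            plt.Rectangle(
                                (j - 0.5, i - 0.5), 1, 1,
                                fill=False, edgecolor="purple", lw=2,
                            )
                        )
        fig.colorbar(im, ax=ax, label="log2 fold change from grand mean")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return fig
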