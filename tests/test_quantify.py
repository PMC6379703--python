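"""Inclusion levels, group statistics and fold-change outlier detection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mxetools.quantify import (
    BandTable,
    DegenerateDataError,
    FoldChangeMatrix,
    compare_groups,
    export_heatmap,
    fold_change,
    gaussian_outliers,
    inclusion_levels,
)
from mxetools.synth import BandNoiseSpec, make_band_table


def _table(values, columns=None, groups=None):
    arr = np.asarray(values, float)
    df = pd.DataFrame(
        arr,
        index=[f"v{i+1}" for i in range(arr.shape[0])],
        columns=columns or [f"s{j+1}" for j in range(arr.shape[1])],
    )
    g = pd.Series(groups, index=df.columns) if groups else None
    return BandTable(df, g)


class TestInclusionLevels:
    def test_equal_bands(self):
        prof = inclusion_levels(_table(np.ones((12, 2))))
        assert np.allclose(prof.proportions.values, 1 / 12)

    def test_single_band(self):
        prof = inclusion_levels(_table([[5.0], [0.0], [0.0]]))
        assert list(prof.proportions.iloc[:, 0]) == [1.0, 0.0, 0.0]

    def test_simple_ratios(self):
        prof = inclusion_levels(_table([[2.0], [1.0], [1.0]]))
        assert list(prof.proportions.iloc[:, 0]) == [0.5, 0.25, 0.25]

    def test_columns_sum_to_one(self, rng):
        bt = _table(rng.gamma(2.0, 1.0, size=(12, 8)) + 1e-6)
        prof = inclusion_levels(bt)
        assert np.allclose(prof.proportions.sum(axis=0), 1.0)

    def test_scale_invariance(self, rng):
        vals = rng.gamma(2.0, 1.0, size=(6, 4)) + 1e-6
        scaled = vals * rng.uniform(0.1, 10.0, size=4)
        a = inclusion_levels(_table(vals)).proportions.values
        b = inclusion_levels(_table(scaled)).proportions.values
        assert np.allclose(a, b)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError, match="s2"):
            _table([[1.0, 0.0], [1.0, 0.0]])

    def test_sigma_zero_recovers_truth_exactly(self):
        p = np.array([0.4, 0.3, 0.2, 0.1])
        bt, truth = make_band_table(BandNoiseSpec(p, sigma=0.0, n_samples=4, seed=1))
        prof = inclusion_levels(bt)
        assert np.allclose(prof.proportions.values, p[:, None])


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(3)
        half = np.array([[0.5], [0.3], [0.2]]) * (
            1 + rng.normal(0, 0.02, size=(3, 3))
        )
        # group b replicates are copies of group a's: groups identical
        vals = np.hstack([half, half])
        bt = _table(vals, groups=["a"] * 3 + ["b"] * 3)
        prof = inclusion_levels(bt)
        out = compare_groups(prof, "t_test")
        assert (out["p"] > 0.99).all()
        assert (out["tier"] == "").all()

    def test_t_statistics_match_closed_form(self, rng):
        vals = rng.gamma(2.0, 1.0, size=(5, 6)) + 0.01
        bt = _table(vals, groups=["a"] * 3 + ["b"] * 3)
        prof = inclusion_levels(bt)
        out = compare_groups(prof, "t_test").set_index("variant")
        props = prof.proportions
        for v in props.index:
            x = props.loc[v].iloc[:3].to_numpy()
            y = props.loc[v].iloc[3:].to_numpy()
            nx, ny = 3, 3
            sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
            t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
            p = 2 * stats.t.sf(abs(t), nx + ny - 2)
            assert out.loc[v, "p"] == pytest.approx(p, abs=1e-10)

    def test_shifted_variant_flagged(self):
        rng = np.random.default_rng(5)
        base = np.full((6, 6), 10.0) + rng.normal(0, 0.05, size=(6, 6))
        base[2, 3:] += 5.0  # ~big shift in group b for v3
        bt = _table(base, groups=["a"] * 3 + ["b"] * 3)
        out = compare_groups(inclusion_levels(bt), "t_test").set_index("variant")
        assert out.loc["v3", "tier"] == "**"

    def test_anova_tukey_structure_four_groups(self):
        """Four developmental-stage style groups produce per-variant,
        per-pair Tukey P values and tiers."""
        rng = np.random.default_rng(8)
        groups = ["embryo"] * 3 + ["larva"] * 3 + ["female"] * 3 + ["male"] * 3
        vals = np.abs(rng.normal(10, 0.3, size=(4, 12))) + 0.1
        vals[0, 3:6] *= 2.0  # larva shift in v1
        bt = _table(vals, groups=groups)
        out = compare_groups(inclusion_levels(bt), "anova_tukey")
        assert set(out["variant"]) == {"v1", "v2", "v3", "v4"}
        assert len(out) == 4 * 6  # 4 variants x C(4,2) pairs
        v1 = out[out["variant"] == "v1"].set_index(["group_a", "group_b"])
        # Tukey agrees with scipy recomputation
        props = inclusion_levels(bt).proportions
        samples = [props.loc["v1"].iloc[i:i+3].to_numpy() for i in (0, 3, 6, 9)]
        ref = stats.tukey_hsd(*samples)
        assert v1.loc[("embryo", "larva"), "p"] == pytest.approx(
            ref.pvalue[0, 1], abs=1e-12
        )

    def test_insufficient_replicates(self):
        bt = _table([[1.0, 2.0], [2.0, 1.0]], groups=["a", "b"])
        with pytest.raises(ValueError):
            compare_groups(inclusion_levels(bt), "t_test")

    def test_planted_group_shift_power(self):
        """A 2x inclusion shift with sigma=0.1 noise (3 vs 3) is detected at
        P<0.05 in >=90% of seeded replicates."""
        p = np.full(12, 1 / 12)
        effect = np.ones(12)
        effect[4] = 2.0
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            spec = BandNoiseSpec(
                p,
                sigma=0.1,
                n_samples=6,
                seed=seed,
                group_labels=["ctl"] * 3 + ["shift"] * 3,
                group_effects={"shift": effect},
            )
            bt, _ = make_band_table(spec)
            out = compare_groups(inclusion_levels(bt), "t_test").set_index("variant")
            if out.loc["v5", "p"] < 0.05:
                hits += 1
        assert hits / n_rep >= 0.90


class TestFoldChange:
    def test_identical_individuals_all_one(self):
        vals = np.tile(np.array([[0.5], [0.3], [0.2]]), (1, 5))
        fc = fold_change(inclusion_levels(_table(vals)))
        assert np.allclose(fc.fold.values, 1.0)

    def test_doubled_individual_exact_arithmetic(self):
        # 10 individuals, one with a doubled band for v1:
        # fold(v1, doubled) = 2/(12/10) = 20/12; others = 10/12... computed
        # on proportions, so the lane renormalization shifts all of v-other
        n = 10
        vals = np.ones((3, n))
        vals[0, 0] = 2.0
        prof = inclusion_levels(_table(vals))
        fc = fold_change(prof)
        p = prof.proportions.values
        expect = p / p.mean(axis=1, keepdims=True)
        assert np.allclose(fc.fold.values, expect)
        # lane renormalization damps the raw 20/11 vs 10/11 pattern, but the
        # doubled individual still stands above its peers
        assert fc.fold.values[0, 0] > 1.3 and fc.fold.values[0, 1] < 1.0

    def test_symmetric_perturbation_folds_cancel(self):
        vals = np.ones((12, 6)) * 5
        vals[1, 0] *= 1.1
        vals[1, 1] /= 1.1
        fc = fold_change(inclusion_levels(_table(vals)))
        prod = fc.fold.values[1, 0] * fc.fold.values[1, 1]
        assert prod == pytest.approx(1.0, rel=0.01)

    def test_zero_proportions_floored(self):
        vals = np.ones((3, 4))
        vals[2, :2] = 0.0
        fc = fold_change(inclusion_levels(_table(vals)))
        assert (fc.fold.values > 0).all()

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            fold_change(inclusion_levels(_table([[1.0], [1.0]])))


def _lognormal_fc(rng, n_var=12, n_ind=10, sigma=0.25):
    log2 = rng.normal(0.0, sigma, size=(n_var, n_ind))
    fold = pd.DataFrame(
        2.0 ** log2,
        index=[f"v{i+1}" for i in range(n_var)],
        columns=[chr(ord("A") + j) for j in range(n_ind)],
    )
    return FoldChangeMatrix(fold, pd.Series(1.0, index=fold.index))


class TestGaussianOutliers:
    def test_degenerate_all_ones(self):
        fold = pd.DataFrame(np.ones((5, 5)))
        fc = FoldChangeMatrix(fold, pd.Series(1.0, index=fold.index))
        with pytest.raises(DegenerateDataError):
            gaussian_outliers(fc)

    def test_planted_outlier_detected(self, rng):
        detected = 0
        n_rep = 200
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            fc = _lognormal_fc(r)
            sigma = 0.25
            fc.fold.iloc[3, 4] = 2.0 ** (4 * sigma)  # 4-sigma cell
            flags = gaussian_outliers(fc, alpha=0.05)
            if flags.iloc[3, 4]:
                detected += 1
        assert detected / n_rep >= 0.95

    def test_type_one_calibration(self):
        """On null lognormal data the flag rate is ~alpha."""
        total = flagged = 0
        for seed in range(500):
            r = np.random.default_rng(10_000 + seed)
            fc = _lognormal_fc(r)
            flags = gaussian_outliers(fc, alpha=0.05)
            flagged += flags.values.sum()
            total += flags.size
        rate = flagged / total
        assert abs(rate - 0.05) < 0.01

    def test_variable_variant_concentrates_flags(self, rng):
        """One variant varying across individuals (the rest stable) collects
        the flags on its own row."""
        log2 = rng.normal(0.0, 0.05, size=(12, 10))
        log2[3] = rng.normal(0.0, 1.2, size=10)  # one hyper-variable variant
        fold = pd.DataFrame(2.0 ** log2)
        fc = FoldChangeMatrix(fold, pd.Series(1.0, index=fold.index))
        flags = gaussian_outliers(fc, alpha=0.05)
        per_row = flags.sum(axis=1)
        assert per_row.iloc[3] == per_row.max() and per_row.iloc[3] >= 2

    def test_needs_enough_cells(self):
        fold = pd.DataFrame(np.ones((3, 3)) * 1.1)
        with pytest.raises(ValueError):
            gaussian_outliers(FoldChangeMatrix(fold, pd.Series(1.0, index=fold.index)))


class TestExportHeatmap:
    def test_single_cell_tsv(self, tmp_path):
        fold = pd.DataFrame([[1.5]], index=["v1"], columns=["A"])
        fc = FoldChangeMatrix(fold, pd.Series([1.0], index=["v1"]))
        out = tmp_path / "one.tsv"
        export_heatmap(fc, tsv_path=out)
        assert pd.read_csv(out, sep="\t", index_col=0).shape == (1, 1)

    def test_tsv_roundtrip_lossless(self, rng, tmp_path):
        fc = _lognormal_fc(rng)
        out = tmp_path / "fc.tsv"
        export_heatmap(fc, tsv_path=out)
        back = pd.read_csv(out, sep="\t", index_col=0)
        assert np.allclose(back.values, fc.fold.values)
        assert list(back.index) == list(fc.fold.index)

    def test_image_renders_with_flags(self, rng, tmp_path):
        fc = _lognormal_fc(rng)
        flags = gaussian_outliers(fc, alpha=0.2)
        img = tmp_path / "hm.png"
        export_heatmap(fc, flags, image_path=img)
        assert img.stat().st_size > 0
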