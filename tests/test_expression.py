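"""Preprocessing, statistical tests, BH adjustment, DE calling and qPCR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirarray.config import SimConfig
from mirarray.errors import InputError
from mirarray.expression import (
    DesignTable,
    IntensityMatrix,
    QpcrInput,
    anova_oneway,
    bh_adjust,
    call_de,
    lowess_normalize,
    ma_trend,
    paired_t_test,
    qpcr_relative_expression,
    subtract_background,
)
from mirarray.simulate import (
    _draw_mirnas,
    make_design,
    make_microarray,
)
from oracles import bh_step_up


def _matrix(fg, bg=None, n_mirnas=None):
    probes = [f"m{i}|p{k}" for i in range(fg.shape[0] // 3) for k in (1, 2, 3)]
    fg = pd.DataFrame(fg, index=probes, columns=[f"s{j}" for j in range(fg.shape[1])])
    bgdf = None if bg is None else pd.DataFrame(bg, index=fg.index, columns=fg.columns)
    probe_map = pd.Series([p.split("|")[0] for p in probes], index=probes)
    return IntensityMatrix(foreground=fg, background=bgdf, probe_to_mirna=probe_map)


def _bias_free_fixture(seed=11, planted_de=None, **overrides):
    cfg = SimConfig(rng_seed=seed, **overrides)
    rng = np.random.default_rng(seed)
    mirnas = _draw_mirnas(cfg, rng)
    design = make_design(cfg)
    matrix, truth = make_microarray(cfg, mirnas, design, rng=rng, planted_de=planted_de)
    return cfg, design, matrix, truth


class TestSubtractBackground:
    def test_simple_subtraction(self):
        m = _matrix(np.full((3, 2), 100.0), np.full((3, 2), 30.0))
        assert (subtract_background(m).foreground.values == 70.0).all()

    def test_floor_applied_when_background_exceeds_signal(self):
        m = _matrix(np.full((3, 2), 10.0), np.full((3, 2), 50.0))
        assert (subtract_background(m).foreground.values == 1.0).all()

    def test_zero_background_identity_with_clip(self):
        fg = np.array([[0.5, 200.0]] * 3)
        m = _matrix(fg, np.zeros_like(fg))
        out = subtract_background(m).foreground.values
        assert (out == np.array([[1.0, 200.0]] * 3)).all()

    def test_never_below_floor(self, rng):
        fg = rng.uniform(0, 100, size=(30, 4))
        bg = rng.uniform(0, 100, size=(30, 4))
        out = subtract_background(_matrix(fg, bg)).foreground.values
        assert (out >= 1.0).all()

    def test_shape_mismatch_rejected(self):
        fg = pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=["s0", "s1"])
        bg = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=["s0", "s1", "s2"])
        probe_map = pd.Series(["m"] * 3, index=list("abc"))
        with pytest.raises(InputError):
            IntensityMatrix(foreground=fg, background=bg, probe_to_mirna=probe_map)


class TestLowessNormalize:
    def test_sample_identical_to_reference_is_unchanged(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(10, 1000, size=60)
        vals = np.tile(col[:, None], (1, 4))  # every sample == reference
        m = _matrix(vals)
        out = lowess_normalize(m)
        assert np.abs(out.values - np.log2(vals)).max() < 1e-6

    def test_constant_shift_removed(self):
        rng = np.random.default_rng(1)
        col = rng.uniform(10, 1000, size=90)
        vals = np.tile(col[:, None], (1, 5))
        vals[:, 2] *= 2.0 ** 0.7  # constant M = 0.7 for one sample
        out = lowess_normalize(_matrix(vals))
        assert np.abs(out.values[:, 2] - np.log2(col)).max() < 1e-3

    def test_planted_bias_removed_and_idempotent(self):
        """Amplitude-0.8 intensity-dependent bias: strong before, gone after,
        and renormalization changes nothing."""
        cfg, _design, matrix, _truth = _bias_free_fixture(
            seed=11, n_mirnas=300, bias_amplitude=0.8, noise_sd=0.0, planted_de=[])
        corrected = subtract_background(matrix)
        raw_log2 = pd.DataFrame(np.log2(corrected.foreground.values),
                                index=corrected.foreground.index,
                                columns=corrected.foreground.columns)
        assert ma_trend(raw_log2).max() >= 0.5
        norm = lowess_normalize(corrected)
        assert ma_trend(norm).max() < 0.05
        renorm = lowess_normalize(pd.DataFrame(np.power(2.0, norm.values),
                                               index=norm.index, columns=norm.columns))
        assert np.abs(renorm.values - norm.values).max() < 1e-3

    def test_too_few_probes_refused(self):
        m = _matrix(np.full((9, 2), 50.0))
        with pytest.raises(InputError):
            lowess_normalize(m)


class TestPairedT:
    def test_identical_vectors_give_t_zero(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.degenerate

    def test_hand_computed_example(self):
        # d = (1.1, 0.9, 1.0): t = sqrt(3) * 1.0 / 0.1
        res = paired_t_test([2.1, 1.9, 2.0], [1.0, 1.0, 1.0])
        assert res.t == pytest.approx(np.sqrt(3) / 0.1, rel=1e-12)
        assert res.df == 2
        assert res.p == pytest.approx(2 * stats.t.sf(np.sqrt(3) / 0.1, 2), rel=1e-12)

    def test_agrees_with_scipy_on_random_fixtures(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 12))
            x, y = rng.normal(size=n), rng.normal(size=n)
            res = paired_t_test(x, y)
            ref = stats.ttest_rel(x, y)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_n_below_two_rejected(self):
        with pytest.raises(InputError):
            paired_t_test([1.0], [2.0])


class TestAnova:
    def test_identical_constant_groups_flagged_degenerate(self):
        res = anova_oneway([[5.0, 5.0], [5.0, 5.0]])
        assert res.degenerate and res.F == 0.0

    def test_two_groups_equal_t_squared(self, rng):
        for _ in range(50):
            a, b = rng.normal(size=6), rng.normal(size=5)
            res = anova_oneway([a, b])
            t = stats.ttest_ind(a, b).statistic
            assert res.F == pytest.approx(t ** 2, rel=1e-10)

    def test_hand_computed_sums_of_squares(self):
        res = anova_oneway([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert res.F == pytest.approx(13.5, rel=1e-12)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_agrees_with_scipy_multi_group(self, rng):
        groups = [rng.normal(loc=g, size=4) for g in range(4)]
        res = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)


class TestBHAdjust:
    def test_all_ones_stay_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_hand_worked_example(self):
        adjusted = bh_adjust([0.001, 0.008, 0.039, 0.041])
        assert adjusted == pytest.approx([0.004, 0.016, 0.041, 0.041], abs=1e-12)

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.5]):
            with pytest.raises(InputError):
                bh_adjust(bad)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
    def test_matches_step_up_definition(self, p):
        assert bh_adjust(p) == pytest.approx(bh_step_up(p), abs=1e-12)

    def test_monotone_in_rank(self, rng):
        p = rng.uniform(1e-6, 1, size=200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestCallDe:
    def test_same_group_gives_zero_fold_changes(self):
        cfg, design, matrix, _ = _bias_free_fixture(
            seed=3, n_mirnas=30, noise_sd=0.2, bias_amplitude=0.0, planted_de=[])
        norm = lowess_normalize(subtract_background(matrix))
        res = call_de(norm, DesignTable(design), matrix.probe_to_mirna,
                      ("R-", "cuticle"), ("R-", "cuticle"))
        assert (res["log2_fc"] == 0.0).all()
        assert not res["significant"].any()

    def test_noiseless_planted_effect_read_back_exactly(self):
        planted = [("syn-mir-0005", "R- vs S- / fat_body", "up", 2.0)]
        cfg, design, matrix, _ = _bias_free_fixture(
            seed=5, n_mirnas=30, noise_sd=0.0, bias_amplitude=0.0, planted_de=planted)
        corrected = subtract_background(matrix)
        log2 = pd.DataFrame(np.log2(corrected.foreground.values),
                            index=corrected.foreground.index,
                            columns=corrected.foreground.columns)
        res = call_de(log2, DesignTable(design), matrix.probe_to_mirna,
                      ("R-", "fat_body"), ("S-", "fat_body")).set_index("mirna_name")
        assert res.loc["syn-mir-0005", "log2_fc"] == pytest.approx(2.0, abs=1e-9)
        others = res.drop("syn-mir-0005")
        assert np.abs(others["log2_fc"]).max() < 1e-9

    def test_adjusted_p_never_below_raw(self):
        cfg, design, matrix, _ = _bias_free_fixture(
            seed=6, n_mirnas=60, noise_sd=0.25, bias_amplitude=0.0, planted_de=[])
        norm = lowess_normalize(subtract_background(matrix))
        res = call_de(norm, DesignTable(design), matrix.probe_to_mirna,
                      ("R+", "cuticle"), ("S-", "cuticle"))
        assert (res["p_adj"] >= res["p_raw"] - 1e-15).all()

    def test_unknown_labels_rejected(self):
        cfg, design, matrix, _ = _bias_free_fixture(
            seed=7, n_mirnas=20, planted_de=[])
        norm = lowess_normalize(subtract_background(matrix))
        with pytest.raises(InputError):
            call_de(norm, DesignTable(design), matrix.probe_to_mirna,
                    ("X+", "cuticle"), ("S-", "cuticle"))
        with pytest.raises(InputError):
            call_de(norm, DesignTable(design), matrix.probe_to_mirna,
                    ("R+", "wing"), ("S-", "cuticle"))


class TestQpcr:
    def test_zero_ddct_gives_unit_fold(self):
        q = QpcrInput([20.0] * 3, [15.0] * 3, [20.0] * 3, [15.0] * 3)
        assert qpcr_relative_expression(q).fold_change == pytest.approx(1.0)

    def test_powers_of_two(self):
        # ddCt = -2 -> fold 4
        q = QpcrInput([18.0] * 3, [15.0] * 3, [20.0] * 3, [15.0] * 3)
        assert qpcr_relative_expression(q).fold_change == pytest.approx(4.0)

    def test_fractional_ddct(self):
        # ddCt = +1.5 -> 2^-1.5
        q = QpcrInput([21.5] * 3, [15.0] * 3, [20.0] * 3, [15.0] * 3)
        res = qpcr_relative_expression(q)
        assert res.fold_change == pytest.approx(2.0 ** -1.5)
        assert res.fold_change == pytest.approx(0.35355, abs=1e-4)

    def test_per_replicate_folds_retained(self):
        q = QpcrInput([19.0, 18.0, 17.0], [15.0] * 3, [20.0] * 3, [15.0] * 3)
        res = qpcr_relative_expression(q)
        assert res.per_replicate_fold == pytest.approx((2.0, 4.0, 8.0))

    def test_missing_reference_rejected(self):
        with pytest.raises(InputError):
            QpcrInput([20.0] * 3, [], [20.0] * 3, [15.0] * 3)

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(InputError):
            QpcrInput([20.0, -1.0], [15.0] * 2, [20.0] * 2, [15.0] * 2)
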