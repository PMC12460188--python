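"""Fisher z, outlier removal, rm-ANOVA, BH FDR and post hoc contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import interbrain as ib
from interbrain.stats import rm_anova


def fdr_bh_bruteforce(p, q):
    """Literal step-up definition, independent of the implementation."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_max = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k_max = i
    reject = np.zeros(m, bool)
    reject[order[:k_max]] = True
    return reject


class TestFisherZ:
    @pytest.mark.parametrize(
        "v,expected",
        [(0.0, 0.0), (0.5, 0.5 * np.log(3)), (-0.5, -0.5 * np.log(3))],
    )
    def test_values(self, v, expected):
        assert ib.fisher_z(v) == pytest.approx(expected, abs=1e-12)

    def test_monotone_and_odd(self):
        v = np.linspace(-0.95, 0.95, 41)
        z = ib.fisher_z(v)
        assert (np.diff(z) > 0).all()
        assert np.allclose(z, -ib.fisher_z(-v))

    def test_clipping_keeps_values_finite(self):
        assert np.isfinite(ib.fisher_z(np.array([1.0, -1.0]))).all()


class TestRemoveOutliers:
    def test_identical_values_untouched(self):
        keep, log = ib.remove_outliers(np.full(10, 0.3))
        assert keep.all() and log == []

    def test_gross_outlier_removed_by_iqr_fence(self):
        v = np.array([0.1, 0.11, 0.09, 0.1, 0.12, 5.0])
        keep, log = ib.remove_outliers(v)
        assert not keep[-1]
        assert keep[:-1].all()
        assert log[0]["reason"] == "iqr"

    def test_moment_trimming_rare_under_normality(self):
        rng = np.random.default_rng(0)
        triggered = 0
        for _ in range(100):
            v = rng.standard_normal(30)
            _, log = ib.remove_outliers(v)
            if any(e["reason"] == "moments" for e in log):
                triggered += 1
        assert triggered < 20

    def test_floor_limits_removal(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.standard_normal(14), [50.0] * 6])
        keep, _ = ib.remove_outliers(v)
        assert keep.sum() >= int(np.ceil(0.7 * 20)) - 6  # never below floor
        assert keep.sum() >= 5

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            ib.remove_outliers(np.ones(3))


class TestRmAnova:
    # 5 subjects x 4 conditions; sums of squares checked against an
    # independent by-hand decomposition (means and squared deviations)
    Y = np.array(
        [
            [2.0, 5.0, 3.0, 6.0],
            [4.0, 4.0, 2.0, 5.0],
            [1.0, 6.0, 5.0, 3.0],
            [5.0, 3.0, 4.0, 7.0],
            [3.0, 7.0, 1.0, 4.0],
        ]
    )

    def test_ss_decomposition_by_hand(self):
        y = self.Y
        grand = y.mean()
        ss_cond = 5 * sum((y[:, j].mean() - grand) ** 2 for j in range(4))
        ss_subj = 4 * sum((y[i].mean() - grand) ** 2 for i in range(5))
        ss_tot = ((y - grand) ** 2).sum()
        res = rm_anova(y)
        assert res.ss_condition == pytest.approx(ss_cond)
        assert res.ss_subject == pytest.approx(ss_subj)
        assert res.ss_error == pytest.approx(ss_tot - ss_cond - ss_subj)
        assert res.f_value == pytest.approx(
            (ss_cond / 3) / (res.ss_error / 12)
        )

    def test_against_reference_implementation(self):
        """Cross-check F, epsilon, Mauchly W/chi2 against pingouin."""
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            {
                "s": np.repeat(np.arange(5), 4),
                "c": np.tile(np.arange(4), 5),
                "y": self.Y.ravel(),
            }
        )
        ref = pg.rm_anova(
            dv="y", within="c", subject="s", data=df, correction=True,
            detailed=True,
        )
        res = rm_anova(self.Y)
        assert res.f_value == pytest.approx(ref.loc[0, "F"])
        assert res.p_uncorrected_df == pytest.approx(ref.loc[0, "p_unc"])
        assert res.epsilon == pytest.approx(ref.loc[0, "eps"], abs=1e-9)
        sph = pg.sphericity(df, dv="y", within="c", subject="s")
        assert res.mauchly_w == pytest.approx(sph.W, abs=1e-9)
        assert res.mauchly_chi2 == pytest.approx(sph.chi2, abs=1e-9)

    def test_epsilon_bounds_k4(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            res = rm_anova(rng.standard_normal((12, 4)))
            assert 1.0 / 3.0 - 1e-12 <= res.epsilon <= 1.0 + 1e-12

    def test_power_against_shifted_condition(self):
        rng = np.random.default_rng(3)
        rejections = 0
        for _ in range(100):
            y = rng.standard_normal((30, 4))
            y[:, 0] += 1.0  # one condition shifted by 1 SD
            if rm_anova(y).p_value < 0.05:
                rejections += 1
        assert rejections > 80

    def test_degenerate_zero_error_flagged(self):
        y = np.tile(np.array([[1.0, 2.0, 3.0, 4.0]]), (6, 1))
        y += np.arange(6)[:, None]  # subject offsets only
        res = rm_anova(y)
        assert res.degenerate


class TestFdrBh:
    def test_stepup_example(self):
        q, reject = ib.fdr_bh(np.array([0.001, 0.01, 0.02, 0.04, 0.5]), 0.05)
        assert reject.tolist() == [True, True, True, True, False]

    def test_all_ones_none_rejected(self):
        _, reject = ib.fdr_bh(np.ones(7), 0.05)
        assert not reject.any()

    def test_single_test_reduces_to_threshold(self):
        assert ib.fdr_bh(np.array([0.04]), 0.05)[1][0]
        assert not ib.fdr_bh(np.array([0.06]), 0.05)[1][0]

    def test_adjusted_values_dominate_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=20)
        qv, _ = ib.fdr_bh(p)
        assert (qv >= p - 1e-12).all()

    @settings(derandomize=True, max_examples=300)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=12,
        ),
        st.sampled_from([0.01, 0.05, 0.1, 0.25]),
    )
    def test_matches_exhaustive_stepup(self, p, q):
        _, reject = ib.fdr_bh(np.array(p), q)
        assert reject.tolist() == fdr_bh_bruteforce(p, q).tolist()

    def test_empty_input(self):
        qv, reject = ib.fdr_bh(np.array([]))
        assert qv.size == 0 and reject.size == 0


class TestPosthoc:
    def _cells(self, coop, others):
        cells = {(0, "cooperation"): np.asarray(coop, float)}
        for cond in ("solo", "communication", "competition"):
            cells[(0, cond)] = np.asarray(others, float)
        return cells

    def test_identical_values_give_t0_p1(self):
        v = np.arange(10.0)
        out = ib.posthoc_cooperation_tests(self._cells(v, v), [0])
        assert np.allclose(out["t"], 0.0) and np.allclose(out["p"], 1.0)

    def test_constant_nonzero_difference_is_degenerate_limit(self):
        v = np.arange(10.0)
        out = ib.posthoc_cooperation_tests(self._cells(v + 0.5, v), [0])
        assert (out["p"] == 0.0).all()
        assert np.isinf(out["t"]).all() and (out["direction"] == 1).all()

    def test_only_significant_rois_tested(self):
        v = np.arange(8.0)
        cells = self._cells(v, v)
        out = ib.posthoc_cooperation_tests(cells, [])
        assert out.empty

    def test_too_few_pairs_skipped(self):
        coop = np.array([1.0, 2.0, np.nan, np.nan, np.nan])
        other = np.array([0.5, 1.5, np.nan, np.nan, np.nan])
        cells = {(0, "cooperation"): coop, (0, "solo"): other}
        out = ib.posthoc_cooperation_tests(cells, [0])
        assert out["skipped"].all()


class TestRunGroupStats:
    def test_detects_planted_effect_and_orders_stages(self):
        rng = np.random.default_rng(5)
        rows = []
        for roi in range(4):
            for d in range(24):
                base = rng.standard_normal() * 0.02
                for cond in ib.ANALYSIS_CONDITIONS:
                    v = 0.02 * rng.standard_normal() + base
                    if roi == 2 and cond == "cooperation":
                        v += 0.3
                    rows.append(
                        {
                            "dyad": f"d{d:02d}",
                            "condition": cond,
                            "roi": roi,
                            "value": v,
                            "missing": False,
                        }
                    )
        out = ib.run_group_stats(pd.DataFrame(rows))
        om = out["omnibus"].set_index("roi")
        assert om.loc[2, "significant"]
        assert not om.drop(2)["significant"].any()
        ph = out["posthoc"]
        assert set(ph["roi"]) == {2}
        coop_solo = ph[ph["contrast"] == "cooperation-solo"]
        assert coop_solo["significant"].all()
        assert (coop_solo["direction"] == 1).all()
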