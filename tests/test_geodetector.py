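"""The q statistic against a brute-force variance decomposition, its
significance test, main-factor selection, interactions and risk detection."""

import numpy as np
import pandas as pd
import pytest

from vegeff import geodetector as gd
from vegeff.types import ConstantResponseError, FactorPartition


def make_partition(values, strata, name="f", category="climate"):
    idx = pd.RangeIndex(len(values))
    return FactorPartition(
        name, category, pd.Series(values, index=idx), pd.Series(strata, index=idx)
    )


def brute_force_q(y, strata):
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    ssw = 0.0
    for h in set(strata.tolist()):
        sub = y[strata == h]
        ssw += len(sub) * sub.var()
    return 1.0 - ssw / (len(y) * y.var())


class TestFactorQ:
    def test_hand_variance_decomposition(self):
        y = pd.Series([1.0, 1, 2, 2, 5, 5, 6, 6])
        det = gd.factor_q(y, pd.Series([1, 1, 1, 1, 2, 2, 2, 2]))
        assert det.q == pytest.approx(1 - 2 / 34, abs=1e-12)

    def test_perfect_strata_q_one(self):
        y = pd.Series([1.0, 1, 1, 4, 4, 4])
        det = gd.factor_q(y, pd.Series([1, 1, 1, 2, 2, 2]))
        assert det.q == pytest.approx(1.0)
        assert det.p == 0.0

    def test_identical_distribution_strata_q_zero(self):
        y = pd.Series([1.0, 2, 3, 1, 2, 3])
        det = gd.factor_q(y, pd.Series([1, 1, 1, 2, 2, 2]))
        assert det.q == pytest.approx(0.0, abs=1e-12)

    def test_single_stratum_rejected(self):
        with pytest.raises(ConstantResponseError):
            gd.factor_q(pd.Series([1.0, 2, 3]), pd.Series([1, 1, 1]))

    def test_constant_response_rejected(self):
        with pytest.raises(ConstantResponseError):
            gd.factor_q(pd.Series([2.0, 2, 2, 2]), pd.Series([1, 1, 2, 2]))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(6, 51))
            ell = int(rng.integers(2, min(6, n)))
            y = rng.normal(0, 1, n)
            strata = rng.integers(1, ell + 1, n)
            if len(np.unique(strata)) < 2:
                continue
            strata = np.unique(strata, return_inverse=True)[1] + 1
            det = gd.factor_q(pd.Series(y), pd.Series(strata))
            assert det.q == pytest.approx(brute_force_q(y, strata), abs=1e-12)

    def test_affine_invariance_and_range(self, rng):
        for _ in range(200):
            n = int(rng.integers(8, 40))
            y = rng.normal(0, 3, n)
            strata = np.unique(rng.integers(1, 4, n), return_inverse=True)[1] + 1
            if len(np.unique(strata)) < 2:
                continue
            q1 = gd.factor_q(pd.Series(y), pd.Series(strata)).q
            q2 = gd.factor_q(pd.Series(-2.5 * y + 7), pd.Series(strata)).q
            assert 0.0 <= q1 <= 1.0
            assert q1 == pytest.approx(q2, abs=1e-10)

    def test_empty_strata_dropped_with_warning(self):
        y = pd.Series(np.arange(6, dtype=float))
        part = make_partition(np.arange(6), [1, 1, 1, 5, 5, 5])  # labels 2..4 unused
        with pytest.warns(UserWarning, match="empty strata"):
            det = gd.factor_q(y, part)
        assert len(det.strata) == 2


class TestQSignificance:
    def test_type_one_error_rate_under_null(self, rng):
        n, ell, reps = 120, 5, 1000
        rejections = 0
        for _ in range(reps):
            y = rng.normal(0, 1, n)
            strata = np.unique(rng.integers(1, ell + 1, n), return_inverse=True)[1] + 1
            det = gd.factor_q(pd.Series(y), pd.Series(strata))
            rejections += det.p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_p_monotone_in_q(self):
        # same N and L: larger q must give smaller p
        base = gd.FactorDetection("f", 0.3, n_total=100, sigma2=1.0,
                                  strata=pd.DataFrame({"stratum": [1, 2, 3],
                                                       "N_h": [33, 33, 34],
                                                       "mean": [0, 0, 0],
                                                       "sigma2_h": [1, 1, 1]}))
        stronger = gd.FactorDetection("f", 0.6, n_total=100, sigma2=1.0,
                                      strata=base.strata)
        assert gd.q_significance(stronger) < gd.q_significance(base)

    def test_noncentral_variant_is_conservative(self, rng):
        y = rng.normal(5, 1, 80)
        strata = np.unique(rng.integers(1, 5, 80), return_inverse=True)[1] + 1
        det = gd.factor_q(pd.Series(y), pd.Series(strata))
        assert gd.q_significance(det, "noncentral") >= gd.q_significance(det, "central")


#: Published whole-region ranking: (factor, q); all pass the 95% level.
PUBLISHED_RANKING = [
    ("annual precipitation", 0.75),
    ("gdp", 0.61),
    ("accumulated afforestation intensity", 0.57),
    ("returning farmland to grassland", 0.57),
    ("population density", 0.56),
    ("annual temperature", 0.42),
    ("slope", 0.27),
    ("returning unused land to grassland", 0.26),
    ("maintaining original grassland", 0.22),
    ("altitude", 0.20),
    ("maintaining original forest", 0.19),
    ("soil organic carbon", 0.05),
    ("soil clay", 0.04),
    ("soil moisture", 0.03),
]


class TestSelectMainFactors:
    def test_published_ranking_keeps_top_seven(self):
        detections = [
            gd.FactorDetection(name, q, p=0.01) for name, q in PUBLISHED_RANKING
        ]
        main = gd.select_main_factors(detections)
        assert [d.factor_name for d in main] == [
            "annual precipitation", "gdp", "accumulated afforestation intensity",
            "returning farmland to grassland", "population density",
            "annual temperature", "slope",
        ]

    def test_nothing_significant_empty(self):
        detections = [gd.FactorDetection("a", 0.9, p=0.2), gd.FactorDetection("b", 0.8, p=0.06)]
        assert gd.select_main_factors(detections) == []

    def test_two_factors_top_one(self):
        detections = [gd.FactorDetection("a", 0.4, p=0.01), gd.FactorDetection("b", 0.6, p=0.01)]
        main = gd.select_main_factors(detections)
        assert [d.factor_name for d in main] == ["b"]


class TestInteraction:
    def test_self_interaction_keeps_q(self, rng):
        y = pd.Series(rng.normal(0, 1, 40))
        part = make_partition(rng.normal(size=40), rng.integers(1, 4, 40))
        it = gd.interaction_q(y, part, part)
        assert it.q_ab == pytest.approx(it.q_a, abs=1e-12)

    def test_xor_design_enhances_nonlinearly(self):
        # y determined jointly (XOR-style) while each factor alone explains ~0
        ha = np.array([1, 1, 2, 2] * 10)
        hb = np.array([1, 2, 1, 2] * 10)
        y = pd.Series(((ha == hb).astype(float)))
        pa = make_partition(ha.astype(float), ha, name="A")
        pb = make_partition(hb.astype(float), hb, name="B")
        it = gd.interaction_q(y, pa, pb)
        assert it.q_a == pytest.approx(0.0, abs=1e-12)
        assert it.q_b == pytest.approx(0.0, abs=1e-12)
        assert it.q_ab == pytest.approx(1.0)
        assert it.type == "enhance-nonlinear"

    def test_refinement_never_reduces_q(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 60))
            y = pd.Series(rng.normal(0, 1, n))
            ha = np.unique(rng.integers(1, 5, n), return_inverse=True)[1] + 1
            hb = np.unique(rng.integers(1, 4, n), return_inverse=True)[1] + 1
            pa = make_partition(rng.normal(size=n), ha, name="A")
            pb = make_partition(rng.normal(size=n), hb, name="B")
            try:
                it = gd.interaction_q(y, pa, pb)
            except ConstantResponseError:
                continue
            assert it.q_ab >= max(it.q_a, it.q_b) - 1e-9
            assert it.type in gd.INTERACTION_TYPES


class TestRiskDetect:
    def test_monotone_design_argmax_highest_stratum(self, rng):
        strata = np.repeat([1, 2, 3, 4], 10)
        y = pd.Series(strata * 1.0 + rng.normal(0, 0.1, 40))
        part = make_partition(strata * 10.0 + rng.uniform(0, 1, 40), strata)
        risk = gd.risk_detect(y, part)
        assert risk.argmax_stratum == 4
        top_mean = risk.strata.set_index("stratum").loc[4, "mean"]
        assert top_mean == risk.strata["mean"].max()

    def test_equal_strata_rarely_significant(self, rng):
        strata = np.repeat([1, 2], 50)
        y = pd.Series(rng.normal(0, 1, 100))
        part = make_partition(strata * 1.0, strata)
        risk = gd.risk_detect(y, part)
        assert risk.significance.loc[1, 2] > 0.01  # overwhelmingly the case

    def test_indistinguishable_adjacent_strata_merge_range(self, rng):
        # strata 1..4: means rise then plateau at 3 ~= 4
        strata = np.repeat([1, 2, 3, 4], 15)
        means = {1: 0.0, 2: 1.0, 3: 3.0, 4: 3.02}
        y = pd.Series([means[h] for h in strata] + rng.normal(0, 0.2, 60))
        values = strata * 10.0 + rng.uniform(0, 5, 60)
        part = make_partition(values, strata)
        risk = gd.risk_detect(y, part)
        assert set(risk.optimal_strata) >= {3, 4}
        lo, hi = risk.optimal_range
        assert lo <= values[strata == 3].min() and hi >= values[strata == 4].max()

    def test_singleton_stratum_flagged(self, rng):
        strata = np.array([1] * 10 + [2] * 10 + [3])
        y = pd.Series(rng.normal(0, 1, 21))
        part = make_partition(strata * 1.0, strata)
        with pytest.warns(UserWarning, match="size 1"):
            risk = gd.risk_detect(y, part)
        assert np.isnan(risk.significance.loc[1, 3])
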