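import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from casemap.normative import DegenerateCohortError, NormativeCohort
from casemap.single_case_stats import (
    bh_fdr,
    compare_roi_panel,
    crawford_howell_t,
    z_score,
)
from casemap.synthetic import SimulationConfig, simulate_cohort


def cohort_from(values):
    return NormativeCohort(
        biomarker_key=("r", "volume_mm3"),
        values=[float(v) for v in values],
        control_ids=[f"c{i}" for i in range(len(values))],
        age_window=(30.0, 60.0),
    )


def t_cdf_betainc(t, df):
    """Student-t CDF straight from the regularized incomplete beta."""
    x = df / (df + t * t)
    tail = 0.5 * special.betainc(df / 2.0, 0.5, x)
    return tail if t < 0 else 1.0 - tail


class TestZScore:
    def test_case_at_mean_is_zero(self, small_cohort):
        assert z_score(12.0, small_cohort) == 0.0

    def test_hand_arithmetic(self, small_cohort):
        assert z_score(8.0, small_cohort) == -2.0

    def test_zero_sd_rejected(self):
        with pytest.raises(DegenerateCohortError):
            z_score(5.0, cohort_from([7, 7, 7]))


class TestCrawfordHowell:
    def test_case_at_mean(self, small_cohort):
        t, df, p = crawford_howell_t(12.0, small_cohort)
        assert t == 0.0 and df == 2 and p == 1.0

    def test_worked_example(self, small_cohort):
        # controls {10,12,14}: mean 12, sd 2; case 8 -> t = -4/(2*sqrt(4/3))
        t, df, p = crawford_howell_t(8.0, small_cohort)
        assert t == pytest.approx(-1.7320508, abs=1e-7)
        assert df == 2
        assert p == pytest.approx(2 * t_cdf_betainc(t, 2), abs=1e-12)

    def test_t_approaches_z_for_huge_n(self, rng):
        values = rng.normal(100.0, 10.0, 10**6)
        cohort = cohort_from(values)
        z = z_score(130.0, cohort)
        t, _, _ = crawford_howell_t(130.0, cohort)
        assert abs(t - z) < 1e-5 * abs(z)

    def test_t_strictly_inside_z(self, small_cohort):
        z = z_score(8.0, small_cohort)
        t, _, _ = crawford_howell_t(8.0, small_cohort)
        assert abs(t) < abs(z)
        assert t == pytest.approx(z * math.sqrt(3 / 4))

    def test_one_tailed_variants(self, small_cohort):
        t, df, p_less = crawford_howell_t(8.0, small_cohort, tails="less")
        _, _, p_greater = crawford_howell_t(8.0, small_cohort, tails="greater")
        _, _, p_two = crawford_howell_t(8.0, small_cohort, tails="two")
        assert p_less + p_greater == pytest.approx(1.0)
        assert p_two == pytest.approx(2 * p_less)  # t < 0 here

    def test_p_matches_high_precision_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 40))
            values = rng.normal(rng.uniform(-50, 50), rng.uniform(0.1, 20), n)
            if np.std(values, ddof=1) == 0:
                continue
            x_star = rng.normal(0, 40)
            t, df, p = crawford_howell_t(x_star, cohort_from(values))
            expected = 2 * min(t_cdf_betainc(t, df), 1 - t_cdf_betainc(t, df))
            assert p == pytest.approx(min(expected, 1.0), abs=1e-9)

    @given(
        x_star=st.floats(-100, 100),
        shift=st.floats(0.1, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_p_in_distance_from_mean(self, x_star, shift):
        cohort = cohort_from([10, 12, 14, 11, 13])
        d0 = x_star - cohort.mean
        farther = cohort.mean + (d0 + math.copysign(shift, d0 if d0 else 1.0))
        _, _, p_near = crawford_howell_t(x_star, cohort)
        _, _, p_far = crawford_howell_t(farther, cohort)
        assert p_far <= p_near + 1e-15


def brute_force_bh(p, q=0.05):
    """Step-up BH from the definition: independent oracle."""
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    # largest rank with p_(k) <= q*k/m defines the rejection set
    k_star = 0
    for rank in range(1, m + 1):
        if p[indexed[rank - 1]] <= q * rank / m:
            k_star = rank
    rejected = [False] * m
    for rank in range(k_star):
        rejected[indexed[rank]] = True
    return adj, rejected


class TestBhFdr:
    def test_single_p_identity(self):
        p_adj, rejected = bh_fdr([0.03])
        assert p_adj == [0.03]
        assert rejected == [True]

    def test_uniform_ladder_collapses(self):
        p_adj, rejected = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert p_adj == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert all(rejected)

    def test_all_ones(self):
        p_adj, rejected = bh_fdr([1.0, 1.0, 1.0])
        assert p_adj == [1.0, 1.0, 1.0]
        assert not any(rejected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_brute_force_oracle_including_ties(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 51))
            p = rng.uniform(0, 1, m)
            if rng.random() < 0.5 and m > 2:  # force ties
                p[rng.integers(0, m)] = p[rng.integers(0, m)]
            p = np.round(p, 3)  # more ties
            adj, _ = bh_fdr(p.tolist())
            oracle_adj, _ = brute_force_bh(p.tolist())
            np.testing.assert_allclose(adj, oracle_adj, atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 40)
        adj, _ = bh_fdr(p.tolist())
        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, sm_adj, atol=1e-12)

    def test_ties_share_adjusted_value(self):
        adj, _ = bh_fdr([0.02, 0.02, 0.5])
        assert adj[0] == adj[1]


def _panel_setup(seed, effect=0.0, n_controls=20):
    keys = list(SimulationConfig().roi_panel)[:12]
    config = SimulationConfig(
        seed=seed,
        n_controls=n_controls,
        n_patients=1,
        age_range=(40.0, 60.0),
        implants_roi={("pat000", keys[0]): effect} if effect else {},
    )
    metas, records = simulate_cohort(config)
    subject = [r for r in records if r.subject_id == "pat000"]
    controls = [r for r in records if not r.subject_id.startswith("pat")]
    age = next(m.age for m in metas if m.subject_id == "pat000")
    return subject, controls, metas, keys, age


class TestRoiPanel:
    def test_strong_implant_flagged_below(self):
        subject, controls, metas, keys, age = _panel_setup(seed=7, effect=-6.0)
        results = compare_roi_panel(subject, controls, metas, keys, age)
        by_key = {r.biomarker_key: r for r in results}
        hit = by_key[keys[0]]
        assert hit.significant
        assert hit.direction == "below"
        assert hit.p_adj >= hit.p

    def test_panel_size_one_keeps_raw_p(self):
        subject, controls, metas, keys, age = _panel_setup(seed=3)
        (res,) = compare_roi_panel(subject, controls, metas, keys[:1], age)
        assert res.p_adj == res.p

    def test_missing_panel_key_listed(self):
        subject, controls, metas, keys, age = _panel_setup(seed=3)
        missing = ("Left-Hippocampus", "volume_mm3")
        with pytest.raises(ValueError, match="Left-Hippocampus"):
            compare_roi_panel(subject, controls, metas, [*keys, missing], age)

    def test_sign_consistency_and_padj_floor(self):
        subject, controls, metas, keys, age = _panel_setup(seed=11)
        for r in compare_roi_panel(subject, controls, metas, keys, age):
            assert r.p_adj >= r.p
            if r.control_sd > 0 and r.x_star != r.control_mean:
                assert np.sign(r.z) == np.sign(r.t) == np.sign(r.x_star - r.control_mean)
                assert abs(r.t) < abs(r.z)
            assert r.significant == (r.p_adj < 0.05)

    def test_tiv_normalization_changes_volume_scale(self):
        subject, controls, metas, keys, age = _panel_setup(seed=5)
        res_norm = compare_roi_panel(subject, controls, metas, keys, age, tiv_normalize=True)
        vol = next(r for r in res_norm if r.biomarker_key[1] == "volume_mm3")
        assert vol.x_star < 1.0  # dimensionless proportion after TIV division
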