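"""Welch screening, PCV classification and the LOOCV scoring loop."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from seroprofile import (
    DiscriminationParams,
    SignificantPeak,
    ValidationError,
    loocv_score,
    pcv_classify,
    score_profile,
    select_significant_peaks,
    welch_t_one_tailed,
)

from conftest import make_profile, separated_profiles


class TestWelchOneTailed:
    def test_equal_means_give_half(self):
        assert welch_t_one_tailed((1, 2, 3), (1, 2, 3)) == 0.5

    def test_matches_independent_welch_computation(self):
        """p equals the textbook Welch formula evaluated independently."""
        xs, ys = (10, 11, 12), (1, 2, 3)
        p = welch_t_one_tailed(xs, ys)
        # oracle: scipy's Welch implementation, one-sided in the observed
        # (greater) direction
        oracle = stats.ttest_ind(xs, ys, equal_var=False,
                                 alternative="greater").pvalue
        assert p == pytest.approx(oracle, rel=1e-12)

    @pytest.mark.parametrize("xs,ys", [
        ((3.1, 4.5, 2.2, 6.0), (5.5, 5.9, 4.4)),
        ((0.0, 0.1), (10.0, 9.5, 9.9, 10.4)),
        ((1.0, 1.0, 1.2), (1.1, 1.0, 1.0)),
    ])
    def test_equals_half_two_sided_p(self, xs, ys):
        two_sided = stats.ttest_ind(xs, ys, equal_var=False).pvalue
        assert welch_t_one_tailed(xs, ys) == pytest.approx(two_sided / 2, rel=1e-12)

    def test_degenerate_constant_equal_groups(self):
        assert welch_t_one_tailed((5, 5, 5), (5, 5, 5)) == 1.0

    def test_degenerate_constant_different_groups(self):
        assert welch_t_one_tailed((5, 5, 5), (7, 7, 7)) == 0.0

    def test_single_value_group_rejected(self):
        with pytest.raises(ValidationError):
            welch_t_one_tailed((1,), (1, 2, 3))

    def test_fixed_direction_tail_is_alpha_calibrated(self):
        """With a pre-specified tail the one-tailed Welch p is uniform under
        the null, so P(p < alpha) ~ alpha.  (The data-directed tail used in
        screening rejects at 2*alpha by construction; see the methods note.)"""
        rng = np.random.default_rng(7)
        n_rej = 0
        n_rep = 4000
        for _ in range(n_rep):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0, 1, 10)
            p = stats.ttest_ind(x, y, equal_var=False,
                                alternative="greater").pvalue
            n_rej += p < 0.05
        assert 0.03 < n_rej / n_rep < 0.07


class TestSelectSignificantPeaks:
    def test_single_discriminating_peak(self):
        g1 = [make_profile(f"a{i}", "A", [5, 5, 10 + 0.01 * i, 5]) for i in range(3)]
        g2 = [make_profile(f"b{i}", "B", [5, 5, 0.01 * i, 5]) for i in range(3)]
        ps = select_significant_peaks(g1, g2, DiscriminationParams(
            analysis_range=(400, 403)))
        assert ps.mz_values == [402]
        assert ps.peaks[0].high_group == "A"
        assert 0 < ps.peaks[0].pcv < 10.01

    def test_selection_monotone_in_alpha(self):
        profiles = separated_profiles(n_per_group=5, seed=1)
        g1 = [p for p in profiles if p.group == "disease"]
        g2 = [p for p in profiles if p.group == "control"]
        loose = select_significant_peaks(g1, g2, DiscriminationParams(
            alpha=0.05, analysis_range=(400, 419)))
        strict = select_significant_peaks(g1, g2, DiscriminationParams(
            alpha=0.005, analysis_range=(400, 419)))
        assert set(strict.mz_values) <= set(loose.mz_values)

    def test_matches_brute_force_per_bin_loop(self):
        """Selection on 20-bin data equals an independent per-bin loop
        recomputing the Welch p and the abundance floor from scratch."""
        rng = np.random.default_rng(3)
        n_bins, alpha, frac = 20, 0.05, 0.003
        g1 = [make_profile(f"a{i}", "A", rng.uniform(0, 20, n_bins))
              for i in range(5)]
        g2 = [make_profile(f"b{i}", "B", rng.uniform(0, 20, n_bins))
              for i in range(5)]
        params = DiscriminationParams(alpha=alpha, min_peak_frac=frac,
                                      analysis_range=(400, 419))
        ps = select_significant_peaks(g1, g2, params)
        # independent oracle
        m1 = [np.mean([p.area_by_mz[j] for p in g1]) for j in range(n_bins)]
        m2 = [np.mean([p.area_by_mz[j] for p in g2]) for j in range(n_bins)]
        floor = frac * max(max(a, b) for a, b in zip(m1, m2))
        expected = []
        for j in range(n_bins):
            if max(m1[j], m2[j]) < floor:
                continue
            res = stats.ttest_ind([p.area_by_mz[j] for p in g1],
                                  [p.area_by_mz[j] for p in g2],
                                  equal_var=False)
            if res.pvalue / 2 < alpha and res.statistic != 0:
                expected.append(400 + j)
        assert ps.mz_values == expected
        for p in ps.peaks:
            j = p.mz - 400
            assert p.pcv == pytest.approx((m1[j] + m2[j]) / 2, rel=1e-12)

    def test_empty_selection_returns_empty_set(self):
        g1 = [make_profile(f"a{i}", "A", [5.0, 5.0]) for i in range(3)]
        g2 = [make_profile(f"b{i}", "B", [5.0, 5.0]) for i in range(3)]
        ps = select_significant_peaks(g1, g2, DiscriminationParams(
            analysis_range=(400, 401)))
        assert ps.n_peaks == 0


class TestPcvClassify:
    peak = SignificantPeak(mz=836, p_value=0.01, mean_g1=8, mean_g2=2,
                           pcv=5.0, high_group="CABG", low_group="Control")

    @pytest.mark.parametrize("area,expected", [
        (6.0, "CABG"),       # above the midpoint -> higher-mean group
        (5.0, "Control"),    # at the PCV -> low-mean group ("at or below")
        (4.999, "Control"),
    ])
    def test_midpoint_rule(self, area, expected):
        assert pcv_classify(area, self.peak) == expected

    def test_equals_sign_of_margin(self):
        rng = np.random.default_rng(0)
        for area in rng.uniform(0, 10, 100):
            want = "CABG" if area - self.peak.pcv > 0 else "Control"
            assert pcv_classify(float(area), self.peak) == want


def naive_loocv(profiles, lo, hi, alpha=0.05, frac=0.003):
    """Independent plain-loop reimplementation of the whole LOOCV scorer.

    Same documented conventions (observed-direction tail, per-fold floor on
    group means, midpoint PCV, ties to the low group, strict exclusion of
    the left-out sample) but written with per-bin scalar loops.
    """
    groups = []
    for p in profiles:
        if p.group not in groups:
            groups.append(p.group)
    g1, g2 = groups
    out = []
    for i, left_out in enumerate(profiles):
        left_in = [p for j, p in enumerate(profiles) if j != i]
        a1 = np.vstack([p.restricted(lo, hi) for p in left_in if p.group == g1])
        a2 = np.vstack([p.restricted(lo, hi) for p in left_in if p.group == g2])
        m1 = a1.mean(axis=0)
        m2 = a2.mean(axis=0)
        floor = frac * max(max(u, v) for u, v in zip(m1, m2))
        n_sel = n_g1 = 0
        areas = left_out.restricted(lo, hi)
        for j in range(hi - lo + 1):
            if max(m1[j], m2[j]) < floor:
                continue
            x, y = a1[:, j], a2[:, j]
            v1 = x.var(ddof=1)
            v2 = y.var(ddof=1)
            se2 = v1 / len(x) + v2 / len(y)
            if se2 == 0:
                p = 1.0 if m1[j] == m2[j] else 0.0
            else:
                t = abs(m1[j] - m2[j]) / np.sqrt(se2)
                df = se2 ** 2 / ((v1 / len(x)) ** 2 / (len(x) - 1)
                                 + (v2 / len(y)) ** 2 / (len(y) - 1))
                p = stats.t.sf(t, df)
            if p >= alpha:
                continue
            n_sel += 1
            pcv = (m1[j] + m2[j]) / 2
            high = g1 if m1[j] > m2[j] else g2
            label = high if areas[j] > pcv else (g2 if high == g1 else g1)
            n_g1 += label == g1
        score = 100.0 * n_g1 / n_sel if n_sel else float("nan")
        out.append((left_out.sample_id, score, n_sel))
    return out


class TestLoocvScore:
    def test_complete_separation_scores_0_or_100(self):
        g1 = [make_profile(f"a{i}", "A", [20 + i * 0.1, 5, 30 + i * 0.1])
              for i in range(4)]
        g2 = [make_profile(f"b{i}", "B", [1 + i * 0.1, 5, 2 + i * 0.1])
              for i in range(4)]
        res = loocv_score(g1 + g2, DiscriminationParams(analysis_range=(400, 402)))
        assert all(s.pct_group1 == 100.0 for s in res.scores if s.true_group == "A")
        assert all(s.pct_group1 == 0.0 for s in res.scores if s.true_group == "B")

    def test_single_peak_fold_score_is_0_or_100(self):
        rng = np.random.default_rng(5)
        g1 = [make_profile(f"a{i}", "A", [10 + rng.normal(0, 0.1), 5.0])
              for i in range(4)]
        g2 = [make_profile(f"b{i}", "B", [1 + rng.normal(0, 0.1), 5.0])
              for i in range(4)]
        res = loocv_score(g1 + g2, DiscriminationParams(analysis_range=(400, 401)))
        for s in res.scores:
            assert s.n_peaks_used == 1
            assert s.pct_group1 in (0.0, 100.0)

    def test_score_components_sum_to_100(self, small_cohort, small_params):
        profiles, _, _ = small_cohort
        res = loocv_score(profiles, small_params)
        for s in res.scores:
            if s.defined:
                assert s.pct_group1 + s.pct_group2 == 100.0

    def test_fold_invariant_to_left_out_perturbation(self, tiny_params):
        """Mutating the left-out sample's profile cannot change the peaks
        selected for its fold (strict exclusion)."""
        profiles = separated_profiles(n_per_group=4, seed=2)
        res = loocv_score(profiles, tiny_params)
        target = profiles[0]
        mutated = make_profile(target.sample_id, target.group,
                               np.full(20, 999.0))
        res2 = loocv_score([mutated] + profiles[1:], tiny_params)
        # every *other* fold used sample 0, so only fold 0's selection
        # stayed fixed: its peak count is unchanged
        assert res2.scores[0].n_peaks_used == res.scores[0].n_peaks_used
        for s1, s2 in zip(res.scores[1:], res2.scores[1:]):
            assert s1.sample_id == s2.sample_id

    def test_requires_three_per_group(self):
        g1 = [make_profile(f"a{i}", "A", [1.0, 2.0]) for i in range(2)]
        g2 = [make_profile(f"b{i}", "B", [1.0, 2.0]) for i in range(3)]
        with pytest.raises(ValidationError):
            loocv_score(g1 + g2, DiscriminationParams(analysis_range=(400, 401)))

    def test_matches_naive_reimplementation_bit_for_bit(self):
        """Whole-pipeline oracle: on a 10-sample, 30-bin cohort the scores
        and per-fold peak counts equal an independent plain-loop LOOCV."""
        rng = np.random.default_rng(11)
        profiles = []
        base = rng.uniform(2, 12, 30)
        for g, label in ((0, "A"), (1, "B")):
            for i in range(5):
                areas = np.clip(base + rng.normal(0, 1.5, 30)
                                + (3.0 if g == 0 else 0) * (np.arange(30) % 7 == 0),
                                0, None)
                profiles.append(make_profile(f"{label}{i}", label, areas))
        params = DiscriminationParams(analysis_range=(400, 429))
        res = loocv_score(profiles, params)
        oracle = naive_loocv(profiles, 400, 429)
        assert len(res.scores) == len(oracle)
        for s, (sid, score, n_sel) in zip(res.scores, oracle):
            assert s.sample_id == sid
            assert s.n_peaks_used == n_sel
            if math.isnan(score):
                assert not s.defined
            else:
                assert s.pct_group1 == score  # bit-for-bit

    def test_undefined_fold_warned_and_flagged(self):
        rng = np.random.default_rng(9)
        profiles = [make_profile(f"x{i}", "A" if i < 3 else "B",
                                 rng.uniform(4.9, 5.1, 2))
                    for i in range(6)]
        res = loocv_score(profiles, DiscriminationParams(analysis_range=(400, 401)))
        assert res.n_undefined() == len(res.warnings)


class TestScoreProfile:
    def test_empty_peak_set_is_undefined(self):
        from seroprofile import SignificantPeakSet
        prof = make_profile("s", "A", [1.0, 2.0])
        ps = SignificantPeakSet(left_out_id="s", peaks=[], group_labels=("A", "B"))
        s = score_profile(prof, ps)
        assert not s.defined
        assert s.n_peaks_used == 0
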