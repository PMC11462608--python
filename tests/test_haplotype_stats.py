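import itertools
import math

import numpy as np
import pytest

from sweepscan.genotype_io import Polarity
from sweepscan.haplotype_stats import (
    AlleleClass,
    EHHCurve,
    ScoreStatus,
    Side,
    ehh_curve,
    ihs_scan,
    integrate_ihh,
    nsl_scan,
    scores_to_frame,
    standardize_scores,
)

from conftest import matrix_from_calls, random_matrix


def brute_force_ehh(calls, carriers, core, j_end):
    """Fraction of carrier pairs identical over the span core..j_end inclusive.

    Independent oracle: explicit all-pairs identity count.
    """
    lo, hi = min(core, j_end), max(core, j_end)
    span = calls[np.asarray(carriers)][:, lo : hi + 1]
    c = len(carriers)
    same = sum(
        int(np.array_equal(span[i], span[j]))
        for i, j in itertools.combinations(range(c), 2)
    )
    return same / (c * (c - 1) / 2)


def brute_force_sl(calls, carriers, core, cap):
    """Mean maximal-identity-interval length over carrier pairs (oracle)."""
    n_sites = calls.shape[1]
    lengths = []
    for i, j in itertools.combinations(range(len(carriers)), 2):
        a, b = calls[carriers[i]], calls[carriers[j]]
        left = 0
        k = core - 1
        while k >= 0 and left < cap and a[k] == b[k]:
            left += 1
            k -= 1
        right = 0
        k = core + 1
        while k < n_sites and right < cap and a[k] == b[k]:
            right += 1
            k += 1
        lengths.append(1 + left + right)
    return float(np.mean(lengths))


class TestEhhCurve:
    def test_identical_carriers_stay_at_one(self):
        calls = np.zeros((6, 5), dtype=np.int8)
        calls[:4, 2] = 1  # derived carriers, identical everywhere else
        m = matrix_from_calls(calls)
        curve = ehh_curve(m, 2, AlleleClass.DERIVED, Side.RIGHT)
        assert np.all(curve.ehh == 1.0)
        assert curve.truncated  # never fell below cutoff before data end

    def test_two_two_split(self):
        calls = np.zeros((6, 3), dtype=np.int8)
        calls[:4, 1] = 1
        calls[0, 2] = 1
        calls[1, 2] = 1  # carriers split 2 + 2 at the next SNP
        m = matrix_from_calls(calls)
        curve = ehh_curve(m, 1, AlleleClass.DERIVED, Side.RIGHT)
        assert curve.ehh[1] == pytest.approx((1 + 1) / 6)

    def test_all_distinct_gives_zero_and_ends(self):
        calls = np.zeros((8, 3), dtype=np.int8)
        calls[:4, 1] = 1
        # make the 4 carriers pairwise distinct over sites (0, 2)
        calls[0, 0], calls[1, 2] = 1, 1
        calls[2, 0], calls[2, 2] = 1, 1
        m = matrix_from_calls(calls)
        curve = ehh_curve(m, 1, AlleleClass.DERIVED, Side.RIGHT, cutoff=0.05)
        # 2+2 split right: first step not all-distinct; use left side instead
        left = ehh_curve(m, 1, AlleleClass.DERIVED, Side.LEFT, cutoff=0.05)
        assert left.ehh[-1] < 1.0

    def test_first_point_is_one_and_monotone(self, rng):
        for _ in range(25):
            m = random_matrix(rng, 10, 12)
            core = int(rng.integers(0, m.n_sites))
            for ac in AlleleClass:
                target = 1 if ac is AlleleClass.DERIVED else 0
                if np.sum(m.calls[:, core] == target) < 2:
                    continue
                for side in Side:
                    c = ehh_curve(m, core, ac, side, cutoff=0.0)
                    assert c.ehh[0] == 1.0
                    assert np.all(np.diff(c.ehh) <= 1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 11)) * 2
            m = random_matrix(rng, n, int(rng.integers(4, 41)))
            core = int(rng.integers(0, m.n_sites))
            carriers = np.flatnonzero(m.calls[:, core] == 1)
            if len(carriers) < 2:
                continue
            curve = ehh_curve(m, core, AlleleClass.DERIVED, Side.RIGHT, cutoff=0.0)
            for k in range(1, len(curve.distances)):
                j_end = core + k
                expect = brute_force_ehh(m.calls, carriers, core, j_end)
                assert curve.ehh[k] == pytest.approx(expect, abs=1e-12)

    def test_small_class_rejected(self):
        calls = np.zeros((4, 3), dtype=np.int8)
        calls[0, 1] = 1
        m = matrix_from_calls(calls)
        with pytest.raises(ValueError):
            ehh_curve(m, 1, AlleleClass.DERIVED, Side.RIGHT)

    def test_gap_aborts(self):
        calls = np.zeros((4, 3), dtype=np.int8)
        calls[:2, 1] = 1
        m = matrix_from_calls(calls, positions=[100, 200, 500_000])
        curve = ehh_curve(m, 1, AlleleClass.DERIVED, Side.RIGHT, max_gap_bp=200_000)
        assert curve.gap_aborted


class TestIntegrateIhh:
    def test_single_trapezoid(self):
        c = EHHCurve(0, Side.RIGHT, AlleleClass.DERIVED,
                     np.array([0.0, 1000.0]), np.array([1.0, 0.5]))
        assert integrate_ihh(c) == pytest.approx(750.0)

    def test_constant_one_rectangle(self):
        c = EHHCurve(0, Side.RIGHT, AlleleClass.DERIVED,
                     np.array([0.0, 4000.0, 10_000.0]), np.array([1.0, 1.0, 1.0]))
        assert integrate_ihh(c) == pytest.approx(10_000.0)

    def test_long_gap_scaled(self):
        c = EHHCurve(0, Side.RIGHT, AlleleClass.DERIVED,
                     np.array([0.0, 40_000.0]), np.array([1.0, 1.0]))
        assert integrate_ihh(c, gap_scale_bp=20_000) == pytest.approx(20_000.0)


def mirror_matrix(n_side=4, n_sites=9):
    """Ancestral and derived carrier blocks identical up to relabeling."""
    rng = np.random.default_rng(7)
    block = (rng.random((n_side, n_sites)) < 0.5).astype(np.int8)
    calls = np.vstack([block, block])
    core = n_sites // 2
    calls[:, core] = 0
    calls[n_side:, core] = 1
    return matrix_from_calls(calls)


class TestIhsScan:
    def test_mirror_gives_zero(self):
        m = mirror_matrix()
        scores = ihs_scan(m, maf_min=0.05, cutoff=0.0, trunc_ok=True)
        core = [s for s in scores if s.derived_freq == 0.5]
        assert core
        focal = min(core, key=lambda s: abs(s.pos - m.positions[m.n_sites // 2]))
        assert focal.unstd == pytest.approx(0.0, abs=1e-12)

    def test_sweep_core_negative(self, rng):
        # derived carriers share one long identical haplotype
        n, m_sites = 20, 21
        calls = (rng.random((n, m_sites)) < 0.5).astype(np.int8)
        core = m_sites // 2
        calls[:8, :] = calls[0, :]  # identical sweep haplotypes
        calls[:, core] = 0
        calls[:8, core] = 1
        m = matrix_from_calls(calls)
        scores = ihs_scan(m, maf_min=0.05, trunc_ok=True)
        focal = [s for s in scores if s.core_index == core][0]
        assert focal.status is ScoreStatus.OK
        assert focal.unstd < 0

    def test_maf_filtered_status(self):
        calls = np.zeros((50, 5), dtype=np.int8)
        calls[:2, 2] = 1  # derived freq 0.04
        calls[0, 0] = 1
        calls[1, 4] = 1
        m = matrix_from_calls(calls)
        scores = ihs_scan(m, maf_min=0.05)
        focal = [s for s in scores if s.core_index == 2][0]
        assert focal.status is ScoreStatus.MAF_FILTERED
        assert math.isnan(focal.unstd)

    def test_label_swap_negates_unstd(self, rng):
        m = random_matrix(rng, 12, 15)
        flipped = matrix_from_calls(1 - m.calls, positions=m.positions)
        a = {s.core_index: s for s in ihs_scan(m, maf_min=0.05, cutoff=0.0, trunc_ok=True)}
        b = {s.core_index: s for s in ihs_scan(flipped, maf_min=0.05, cutoff=0.0, trunc_ok=True)}
        checked = 0
        for k in a:
            if a[k].status is ScoreStatus.OK and b[k].status is ScoreStatus.OK:
                assert a[k].unstd == pytest.approx(-b[k].unstd, abs=1e-12)
                checked += 1
        assert checked > 0

    def test_edge_truncated_excluded_by_default(self):
        calls = np.zeros((8, 3), dtype=np.int8)
        calls[:4, 1] = 1  # everything identical away from core: EHH stays 1
        m = matrix_from_calls(calls)
        scores = ihs_scan(m, maf_min=0.05)
        focal = [s for s in scores if s.core_index == 1][0]
        assert focal.status is ScoreStatus.EDGE_TRUNCATED


class TestNslScan:
    def test_mirror_gives_zero(self):
        m = mirror_matrix()
        scores = nsl_scan(m, maf_min=0.05)
        focal = [s for s in scores if s.core_index == m.n_sites // 2][0]
        assert focal.unstd == pytest.approx(0.0, abs=1e-12)

    def test_pair_identical_over_all_snps(self):
        # 2 derived haplotypes identical across all 11 SNPs, core central
        calls = np.zeros((6, 11), dtype=np.int8)
        calls[:2, 5] = 1
        calls[2, 0], calls[3, 1], calls[4, 9] = 1, 1, 1
        m = matrix_from_calls(calls)
        scores = nsl_scan(m, maf_min=0.0, max_extend_snps=100)
        focal = [s for s in scores if s.core_index == 5][0]
        assert focal.der_stat == pytest.approx(11.0)

    def test_pair_differing_adjacent_both_sides(self):
        calls = np.zeros((6, 5), dtype=np.int8)
        calls[:2, 2] = 1
        calls[0, 1] = 1  # mismatch left of core
        calls[0, 3] = 1  # mismatch right of core
        m = matrix_from_calls(calls)
        scores = nsl_scan(m, maf_min=0.0)
        focal = [s for s in scores if s.core_index == 2][0]
        assert focal.der_stat == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9)) * 2
            m = random_matrix(rng, n, int(rng.integers(5, 25)))
            scores = nsl_scan(m, maf_min=0.0, max_extend_snps=7)
            for s in scores:
                if s.status is not ScoreStatus.OK:
                    continue
                der = np.flatnonzero(m.calls[:, s.core_index] == 1)
                anc = np.flatnonzero(m.calls[:, s.core_index] == 0)
                assert s.der_stat == pytest.approx(
                    brute_force_sl(m.calls, der, s.core_index, 7), abs=1e-12)
                assert s.anc_stat == pytest.approx(
                    brute_force_sl(m.calls, anc, s.core_index, 7), abs=1e-12)

    def test_label_swap_negates_unstd(self, rng):
        m = random_matrix(rng, 12, 15)
        flipped = matrix_from_calls(1 - m.calls, positions=m.positions)
        a = {s.core_index: s for s in nsl_scan(m, maf_min=0.05)}
        b = {s.core_index: s for s in nsl_scan(flipped, maf_min=0.05)}
        for k in a:
            if a[k].status is ScoreStatus.OK and b[k].status is ScoreStatus.OK:
                assert a[k].unstd == pytest.approx(-b[k].unstd, abs=1e-12)


def test_neutral_std_ihs_tail_near_gaussian_mass():
    # loose null calibration: fraction of |std| > 2 within +/-50% of the
    # Gaussian tail mass 0.0455, measured on ~5000 neutral scores
    from sweepscan.synthetic_data import NeutralSimConfig, simulate_neutral

    scores = []
    reps = simulate_neutral(
        NeutralSimConfig(n=60, theta=20.0, length_bp=400_000, reps=85, seed=5))
    for m in reps:
        scores.extend(ihs_scan(m, maf_min=0.05, trunc_ok=True, max_gap_bp=10**9))
    std, _ = standardize_scores(scores)
    ok = np.array([s.std for s in std
                   if s.status is ScoreStatus.OK and math.isfinite(s.std)])
    assert len(ok) >= 5000
    frac = float(np.mean(np.abs(ok) > 2))
    assert 0.5 * 0.0455 <= frac <= 1.5 * 0.0455


class TestStandardize:
    def _scores(self, freqs, vals):
        from sweepscan.haplotype_stats import HaplotypeScore

        return [
            HaplotypeScore(core_index=i, variant_id=None, pos=100 * i,
                           derived_freq=f, statistic="ihs", anc_stat=1.0,
                           der_stat=1.0, unstd=v)
            for i, (f, v) in enumerate(zip(freqs, vals))
        ]

    def test_two_scores_one_bin(self):
        out, table = standardize_scores(self._scores([0.5, 0.5], [1.0, 3.0]))
        assert out[0].std == pytest.approx(-1.0)
        assert out[1].std == pytest.approx(1.0)

    def test_single_score_bin_undefined(self):
        out, _ = standardize_scores(self._scores([0.1, 0.9], [1.0, 2.0]))
        assert math.isnan(out[0].std) and math.isnan(out[1].std)

    def test_populated_bins_mean_zero_sd_one(self, rng):
        freqs = rng.uniform(0.05, 0.95, 500)
        vals = rng.normal(size=500)
        out, table = standardize_scores(self._scores(freqs, vals), n_bins=10)
        stds = np.array([s.std for s in out])
        bins = np.minimum((freqs * 10).astype(int), 9)
        for b in range(10):
            sel = stds[bins == b]
            sel = sel[np.isfinite(sel)]
            if len(sel) >= 2:
                assert abs(sel.mean()) < 1e-9
                assert abs(sel.std(ddof=0) - 1) < 1e-9

    def test_frame_columns_follow_statistic(self):
        out, _ = standardize_scores(self._scores([0.5, 0.5], [1.0, 3.0]))
        frame = scores_to_frame(out)
        assert "ihh_a" in frame.columns
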