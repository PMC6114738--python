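import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hairmeth as hm
from hairmeth.dmrcall import (
    differential_sites,
    label_direction,
    merge_dmrs,
    scan_windows,
    smooth,
)
from conftest import matrix_from_counts, matrix_from_levels


def brute_force_merge(pos, sign, max_gap=300, min_sites=3):
    """Independent oracle: enumerate all (i, j) index pairs and keep the
    maximal same-sign, gap-bounded runs with enough sites."""
    n = len(pos)
    out = []
    for i in range(n):
        for j in range(i, n):
            run = range(i, j + 1)
            if len(run) < min_sites:
                continue
            if len({sign[k] for k in run}) != 1:
                continue
            if any(pos[k + 1] - pos[k] > max_gap for k in range(i, j)):
                continue
            left_ok = (i == 0 or sign[i - 1] != sign[i]
                       or pos[i] - pos[i - 1] > max_gap)
            right_ok = (j == n - 1 or sign[j + 1] != sign[j]
                        or pos[j + 1] - pos[j] > max_gap)
            if left_ok and right_ok:
                out.append((int(pos[i]), int(pos[j]) + 1, sign[i],
                            len(run)))
    return out


def flagged_frame(pos, diff, chrom="chr1"):
    return pd.DataFrame({"site_idx": np.arange(len(pos)), "chrom": chrom,
                         "pos": np.asarray(pos),
                         "diff": np.asarray(diff, float),
                         "min_q": 0.01})


class TestSmooth:
    def test_constant_track_preserved(self):
        pos = np.arange(0, 3000, 50)
        n = len(pos)
        m = matrix_from_counts(pos, np.full((n, 6), 5), np.full((n, 6), 10))
        sm = smooth(m)
        assert np.allclose(sm, 0.5)

    def test_isolated_site_keeps_raw_level(self):
        m = matrix_from_counts([100], [[3] * 6], [[10] * 6])
        assert np.allclose(smooth(m), 0.3)

    def test_degree0_matches_brute_force_weighted_mean(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(20_000, size=300, replace=False))
        total = rng.integers(1, 30, size=(300, 6))
        meth = rng.integers(0, total + 1)
        m = matrix_from_counts(pos, meth, total)
        h, min_sites = 500, 10
        sm = smooth(m, half_window=h, min_sites=min_sites, degree=0)
        lvl = meth / total
        for i in rng.choice(300, size=40, replace=False):
            sel = np.abs(pos - pos[i]) <= h
            if sel.sum() < min_sites:
                order = np.argsort(np.abs(pos - pos[i]), kind="stable")
                sel = np.zeros(300, bool)
                sel[order[:min_sites]] = True
                # the implementation widens symmetrically by distance; on
                # ties the result can differ, so skip tie cases
                d = np.sort(np.abs(pos - pos[i]))
                if d[min_sites - 1] == d[min_sites]:
                    continue
            x = np.abs(pos[sel] - pos[i]).astype(float)
            span = max(h, x.max() + 1)
            w = (1 - (x / span) ** 3) ** 3
            expected = ((w[:, None] * total[sel] * lvl[sel]).sum(axis=0)
                        / (w[:, None] * total[sel]).sum(axis=0))
            assert np.allclose(sm[i], expected, atol=1e-10)

    def test_no_smoothing_across_chromosomes(self):
        sites = pd.DataFrame({
            "chrom": ["chr1"] * 3 + ["chr2"] * 3,
            "pos": [0, 50, 100, 0, 50, 100],
            "strand": "+", "context": "CG"})
        meth = np.array([[10] * 6] * 3 + [[0] * 6] * 3)
        total = np.full((6, 6), 10)
        m = hm.MethylomeMatrix(sites, meth, total,
                               [f"anagen_{i}" for i in (1, 2, 3)]
                               + [f"telogen_{i}" for i in (1, 2, 3)],
                               {f"{g}_{i}": g for g in ("anagen", "telogen")
                                for i in (1, 2, 3)})
        sm = smooth(m, half_window=1000, min_sites=2)
        assert np.allclose(sm[:3], 1.0) and np.allclose(sm[3:], 0.0)


class TestScanWindows:
    def test_identical_groups_give_t0_p1(self):
        pos = np.arange(0, 2000, 40)
        n = len(pos)
        m = matrix_from_counts(pos, np.full((n, 6), 4), np.full((n, 6), 10))
        w = scan_windows(m, smooth(m))
        assert np.allclose(w["t_stat"], 0.0)
        assert np.allclose(w["p_value"], 1.0)

    def test_clear_separation_is_significant(self):
        pos = np.arange(0, 3000, 30)
        n = len(pos)
        m = matrix_from_levels(pos, np.full(n, 0.2), np.full(n, 0.8),
                               depth=50, seed=1)
        w = scan_windows(m, smooth(m))
        assert (w["p_value"] < 1e-3).all()
        assert (w["q_value"] < 0.01).all()

    def test_sparse_windows_skipped(self):
        m = matrix_from_counts([0, 5000], np.full((2, 6), 3),
                               np.full((2, 6), 10))
        w = scan_windows(m, smooth(m), min_window_sites=3)
        assert len(w) == 0


class TestDifferentialSites:
    def _matrix(self, diffs):
        pos = np.arange(len(diffs)) * 50
        base = 0.4
        la = np.full(len(diffs), base)
        lt = np.clip(base + np.asarray(diffs), 0.0, 1.0)
        total = np.full((len(diffs), 6), 100)
        meth = np.column_stack(
            [np.round(la * 100)] * 3 + [np.round(lt * 100)] * 3
        ).astype(int)
        return matrix_from_counts(pos, meth, total)

    def _windows(self, q, chrom="chr1", start=0, end=10_000):
        return pd.DataFrame({"chrom": [chrom], "start": [start],
                             "end": [end], "q_value": [q]})

    def test_large_diff_in_significant_window_flagged(self):
        m = self._matrix([0.30])
        f = differential_sites(m, self._windows(0.01))
        assert list(f["pos"]) == [0]
        assert f["diff"].iloc[0] == pytest.approx(0.30)

    def test_no_significant_window_not_flagged(self):
        m = self._matrix([0.30])
        assert len(differential_sites(m, self._windows(0.20))) == 0

    def test_small_diff_not_flagged(self):
        # 0.20 and even exactly 0.25 fail the strict > 0.25 rule
        m = self._matrix([0.20, 0.25, 0.26])
        f = differential_sites(m, self._windows(0.01))
        assert list(f["pos"]) == [100]

    def test_lowering_min_diff_never_shrinks_the_flagged_set(self):
        rng = np.random.default_rng(8)
        m = self._matrix(rng.uniform(-0.5, 0.5, size=40).round(2))
        w = self._windows(0.01)
        strict = set(differential_sites(m, w, min_diff=0.25)["pos"])
        loose = set(differential_sites(m, w, min_diff=0.10)["pos"])
        assert strict <= loose


class TestMergeDmrs:
    def test_three_close_sites_form_one_dmr(self):
        dmrs = merge_dmrs(flagged_frame([100, 200, 300], [0.3, 0.3, 0.3]))
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.start, d.end, d.n_sites, d.direction) == (100, 301, 3,
                                                            "hyper")

    def test_two_sites_are_not_enough(self):
        assert merge_dmrs(flagged_frame([100, 200], [0.3, 0.3])) == []

    def test_large_gap_splits_the_run(self):
        assert merge_dmrs(flagged_frame([100, 200, 600],
                                        [0.3, 0.3, 0.3])) == []

    def test_opposite_signs_never_co_merge(self):
        dmrs = merge_dmrs(flagged_frame([100, 200, 300, 400, 500, 600],
                                        [0.3, 0.3, 0.3, -0.3, -0.3, -0.3]))
        assert [(d.start, d.direction) for d in dmrs] == [
            (100, "hyper"), (400, "hypo")]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 50))
        pos = np.sort(rng.choice(5000, size=n, replace=False))
        sign = rng.choice([-1.0, 1.0], size=n)
        diff = sign * rng.uniform(0.26, 0.6, size=n)
        dmrs = merge_dmrs(flagged_frame(pos, diff))
        got = [(d.start, d.end, 1.0 if d.direction == "hyper" else -1.0,
                d.n_sites) for d in dmrs]
        assert got == brute_force_merge(pos, sign)

    def test_idempotent_on_merged_support(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(4000, size=40, replace=False))
        diff = rng.choice([-1, 1], size=40) * 0.3
        first = merge_dmrs(flagged_frame(pos, diff))
        support = np.concatenate([d.site_indices for d in first]) \
            if first else np.array([], int)
        again = merge_dmrs(flagged_frame(pos[support], diff[support]))
        assert [(d.start, d.end, d.n_sites) for d in again] == \
            [(d.start, d.end, d.n_sites) for d in first]


class TestLabelDirection:
    def test_pooled_difference_sets_direction(self):
        pos = [100, 200, 300]
        total = np.full((3, 6), 10)
        meth = np.column_stack([[4] * 3] * 3 + [[8] * 3] * 3)
        m = matrix_from_counts(pos, meth, total)
        dmrs = merge_dmrs(flagged_frame(pos, [0.4, 0.4, 0.4]))
        (d,) = label_direction(dmrs, m)
        assert d.direction == "hyper"
        assert d.mean_diff == pytest.approx(0.4)

    def test_hypo_direction(self):
        pos = [100, 200, 300]
        total = np.full((3, 6), 10)
        meth = np.column_stack([[5] * 3] * 3 + [[1] * 3] * 3)
        m = matrix_from_counts(pos, meth, total)
        dmrs = merge_dmrs(flagged_frame(pos, [-0.4, -0.4, -0.4]))
        (d,) = label_direction(dmrs, m)
        assert d.direction == "hypo"
        assert d.mean_diff == pytest.approx(-0.4)


class TestPipeline:
    def test_planted_dmrs_recovered_with_direction(self):
        ds = hm.simulate_dataset(hm.preset_config("recovery", 1))
        res = hm.call_dmrs(ds.matrix)
        score = hm.score_dmr_recovery(res.dmrs, ds.truth)
        assert score["sensitivity"] >= 0.9
        assert score["base_precision"] >= 0.8
        assert score["direction_agreement"] == 1.0

    def test_dmr_invariants(self, small_dmr_result):
        for d in small_dmr_result.dmrs:
            assert d.n_sites >= 3
            assert abs(d.mean_diff) > 0
            assert d.direction == ("hyper" if d.mean_diff > 0 else "hypo")
            assert 0 <= d.q_value < 0.05
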