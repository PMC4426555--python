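"""Shuffle test, Benjamini-Hochberg correction, and MCDI arithmetic."""

import numpy as np
import pytest

from mcdi import (
    MCDIAnalysis,
    adjacent_pairs,
    bh_fdr,
    build_protocol,
    make_null_neuron,
    simulate_session,
    shuffle_test_pair,
)
from mcdi.session import Session, TrialRecord


class TestBHFDR:
    def test_step_up_by_hand(self):
        # 0.02 <= 3/4 * 0.05 is the largest passing order statistic
        q, mask = bh_fdr(np.array([0.001, 0.01, 0.02, 0.8]))
        assert q == 0.02
        assert mask.tolist() == [True, True, True, False]

    def test_all_ones_none_significant(self):
        q, mask = bh_fdr(np.ones(40))
        assert q == 0.0 and not mask.any()

    def test_single_p(self):
        q, mask = bh_fdr(np.array([0.04]))
        assert q == 0.04 and mask.all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(25):
            p = rng.random(rng.integers(1, 60)).clip(1e-9, 1.0)
            _, mask = bh_fdr(p)
            reject = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(mask, reject)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([]))
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.0, 0.5]))


class TestAdjacentPairs:
    def test_simple_interleaved(self):
        a = np.array([0.0, 2.0, 10.0])
        b = np.array([1.0, 3.0, 30.0])
        pairs = adjacent_pairs(a, b, max_gap_s=4.0)
        assert pairs == [(0, 0), (1, 1)]  # 10 s trial has no partner within 4 s

    def test_greedy_takes_nearest_free(self):
        a = np.array([0.0, 1.0])
        b = np.array([0.4])
        assert adjacent_pairs(a, b) == [(0, 0)]

    def test_gap_bound_is_respected(self):
        rng = np.random.default_rng(2)
        a = np.sort(rng.uniform(0, 100, 40))
        b = np.sort(rng.uniform(0, 100, 40))
        for ia, ib in adjacent_pairs(a, b, max_gap_s=4.0):
            assert abs(a[ia] - b[ib]) <= 4.0
        # pairing is injective
        ibs = [ib for _, ib in adjacent_pairs(a, b, max_gap_s=4.0)]
        assert len(ibs) == len(set(ibs))


def _two_kind_session(rate_a, rate_b, n_each=64, seed=0, window=None):
    """Alternating A/B trials with piecewise-constant rates (Hz)."""
    rng = np.random.default_rng(seed)
    proto = build_protocol(
        n_examples_per_set=n_each, n_repeats=1, set_kinds=("random", "even"),
        interleave_seed=seed,
    )
    trials = []
    i = 0
    for kind in ["random", "even"] * n_each:
        rate = rate_a if kind == "random" else rate_b
        t = np.arange(0.0, 0.320, 0.001)
        lam = np.full(t.size, rate)
        if window is not None and kind == "even":
            lo, hi = window
            lam = np.where((t * 1000 >= lo) & (t * 1000 < hi), 2 * rate, rate)
        counts = rng.poisson(lam * 0.001)
        spikes = np.sort(
            (np.repeat(np.arange(t.size), counts) + rng.random(counts.sum())) * 0.001
        )
        ex = i // 2
        trials.append(TrialRecord(i, kind, ex, i * 0.32, spikes))
        i += 1
    return Session(protocol=proto, trials=trials)


class TestShuffleTest:
    def test_zero_spikes_all_p_one(self):
        sess = _two_kind_session(0.0, 0.0, n_each=16)
        r = shuffle_test_pair(sess, "random", "even", n_surrogates=100, seed=0)
        assert np.all(r.p_per_bin == 1.0)
        assert not r.discriminates and r.q == 0.0

    def test_symmetry_in_kind_order(self):
        sess = _two_kind_session(20.0, 20.0, n_each=48, seed=3, window=(70, 100))
        ra = shuffle_test_pair(sess, "random", "even", n_surrogates=300, seed=5)
        rb = shuffle_test_pair(sess, "even", "random", n_surrogates=300, seed=5)
        assert np.array_equal(ra.p_per_bin, rb.p_per_bin)
        assert ra.discriminates == rb.discriminates
        assert np.allclose(ra.actual_diff_hz, -rb.actual_diff_hz)

    def test_localized_effect_is_detected_in_window(self):
        """Doubling one kind's rate only during 70-100 ms produces
        significant bins concentrated around that window."""
        sess = _two_kind_session(20.0, 20.0, n_each=512, seed=4, window=(70, 100))
        r = shuffle_test_pair(sess, "random", "even", n_surrogates=500, seed=6)
        assert r.discriminates
        sig_t = r.bin_centers_ms[r.significant_bins]
        assert sig_t.size > 0
        assert np.all((sig_t >= 55) & (sig_t <= 115))

    def test_no_adjacent_pairs_raises(self):
        proto = build_protocol(
            n_examples_per_set=4, n_repeats=1, set_kinds=("random", "even")
        )
        trials = []
        for i, kind in enumerate(["random"] * 4 + ["even"] * 4):
            onset = i * 0.32 + (100.0 if kind == "even" else 0.0)
            trials.append(TrialRecord(i, kind, i % 4, onset, np.array([0.1])))
        sess = Session(protocol=proto, trials=trials)
        with pytest.raises(ValueError, match="adjacency"):
            shuffle_test_pair(sess, "random", "even", n_surrogates=50, seed=0)

    def test_size_under_global_null(self):
        """Two kinds with identical rate processes: the discrimination rate
        stays near the nominal level (tight version runs in acceptance)."""
        hits = 0
        runs = 60
        for k in range(runs):
            sess = _two_kind_session(15.0, 15.0, n_each=32, seed=100 + k)
            r = shuffle_test_pair(sess, "random", "even", n_surrogates=200, seed=k)
            hits += r.discriminates
        se = np.sqrt(0.05 * 0.95 / runs)
        assert hits / runs <= 0.05 + 3 * se


class TestMCDIResults:
    def test_arithmetic_invariants(self, lnln_results):
        res = lnln_results
        assert res.n_pairs == 21
        per_bin = res.mcdi_per_bin
        assert np.all((0 <= per_bin) & (per_bin <= 1))
        assert np.allclose((per_bin * 21) % 1, 0)
        stim = res.stimulus_specific
        assert np.allclose((stim * 6) % 1, 0)
        assert stim.sum() * 6 == 2 * res.n_discriminated
        mat = res.pair_specific
        assert np.array_equal(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 0)
        assert res.overall_mcdi == res.n_discriminated / 21

    def test_summary_mentions_key_quantities(self, lnln_results):
        s = lnln_results.summary()
        assert "overall MCDI" in s and "surrogates" in s

    def test_ground_truth_pattern(self, lnln_results):
        """The LNLN neuron discriminates informative pairs, not the
        random/wye/foot triangle of uninformative ones."""
        mat = lnln_results.pair_specific
        informative = {"even", "odd", "white_triangle", "black_triangle"}
        for a, b in [("random", "wye"), ("random", "foot"), ("wye", "foot")]:
            assert mat.loc[a, b] == 0
        n_inf = sum(
            mat.loc[a, b]
            for a in mat.index
            for b in mat.columns
            if a < b and (a in informative or b in informative)
        )
        assert n_inf >= 10  # strong discrimination of informative correlations

    def test_constructed_counts(self, lnln_results):
        """n/21 and n/6 arithmetic on a hand-built set of pair outcomes."""
        import dataclasses

        res = lnln_results
        sig_pairs = {
            frozenset(p)
            for p in [("even", "odd"), ("even", "random"), ("odd", "wye")]
        }
        tests = {}
        for pair, t in res.pair_tests.items():
            want = frozenset(pair) in sig_pairs
            mask = np.zeros_like(t.significant_bins)
            if want:
                mask = mask.copy()
                mask[5] = True
            tests[pair] = dataclasses.replace(
                t, significant_bins=mask, q=0.01 if want else 0.0
            )
        from mcdi.discrimination import MCDIResults

        fake = MCDIResults(res.model, tests)
        assert fake.n_discriminated == 3
        assert fake.overall_mcdi == pytest.approx(3 / 21)
        assert fake.stimulus_specific["even"] == pytest.approx(2 / 6)
        assert fake.stimulus_specific["odd"] == pytest.approx(2 / 6)
        assert fake.stimulus_specific["foot"] == 0.0
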