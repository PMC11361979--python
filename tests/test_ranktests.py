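"""Kruskal-Wallis, Dunn post-hoc, BH adjustment, candidate regions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from sdrscan.ranktests import (
    bh_adjust,
    call_candidate_regions,
    dunn_posthoc,
    kruskal_wallis,
    run_chrom_tests,
)
from sdrscan.simulate import SimulationConfig, simulate_pools
from sdrscan.sites import scan_sites
from sdrscan.windows import count_in_windows, make_windows


def _midranks(values):
    """Independent midrank computation via sorting (no scipy)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _kw_oracle(groups):
    """Hand-computed tie-corrected H from the rank-sum formula."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    ranks = _midranks(pooled)
    h = 0.0
    i0 = 0
    for g in groups:
        r = sum(ranks[i0 : i0 + len(g)])
        h += r * r / len(g)
        i0 += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    ties = {}
    for x in pooled:
        ties[x] = ties.get(x, 0) + 1
    t_term = sum(t**3 - t for t in ties.values())
    c = 1.0 - t_term / (n**3 - n)
    return h / c if c > 0 else 0.0


def _perm_pvalue(groups):
    """Exact permutation tail probability of H (N <= 8)."""
    sizes = [len(g) for g in groups]
    pooled = [x for g in groups for x in g]
    h_obs = _kw_oracle(groups)
    count = total = 0
    for perm in itertools.permutations(pooled):
        regrouped, i0 = [], 0
        for s in sizes:
            regrouped.append(list(perm[i0 : i0 + s]))
            i0 += s
        total += 1
        if _kw_oracle(regrouped) >= h_obs - 1e-12:
            count += 1
    return count / total


class TestKruskalWallis:
    def test_two_group_hand_example(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27 / 7, abs=1e-9)  # R1=6, R2=15, N=6

    def test_all_equal_defined_as_zero(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert h == 0.0 and p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    def test_matches_rank_formula_oracle_on_small_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n_groups = rng.integers(2, 4)
            sizes = rng.integers(1, 4, size=n_groups)
            while sizes.sum() > 8 or sizes.sum() < n_groups + 1:
                sizes = rng.integers(1, 4, size=n_groups)
            groups = [rng.integers(0, 5, size=s).tolist() for s in sizes]  # ties likely
            if len({x for g in groups for x in g}) == 1:
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(_kw_oracle(groups), abs=1e-9)

    @pytest.mark.parametrize("pooled", [[1, 2, 3, 4, 5, 6], [0, 1, 1, 2, 3, 3], [0, 0, 1, 1, 2, 2]])
    def test_chi_square_p_monotone_with_permutation_p(self, pooled):
        """Within one permutation null (fixed pooled multiset and group
        shape), the chi-square p must order every split of the data the
        same way the exact permutation p does."""
        results = []
        for combo in itertools.combinations(range(6), 3):
            g1 = [pooled[i] for i in combo]
            g2 = [pooled[i] for i in range(6) if i not in combo]
            if len(set(pooled)) == 1:
                continue
            h, p_chi = kruskal_wallis([g1, g2])
            assert h == pytest.approx(_kw_oracle([g1, g2]), abs=1e-9)
            results.append((h, p_chi, _perm_pvalue([g1, g2])))
        for (h1, c1, e1), (h2, c2, e2) in itertools.combinations(results, 2):
            if h1 != h2:
                assert (c1 - c2) * (h1 - h2) <= 0  # chi-square p decreases in H
                assert (e1 - e2) * (h1 - h2) <= 0  # permutation p decreases in H
            if abs(e1 - e2) > 1e-12:
                assert (c1 - c2) * (e1 - e2) >= 0  # hence the two p's agree in order

    @given(st.lists(st.lists(st.floats(-50, 50), min_size=2, max_size=5), min_size=2, max_size=4))
    @settings(max_examples=60, deadline=None)
    def test_invariant_under_monotone_transform(self, groups):
        from hypothesis import assume

        h1, _ = kruskal_wallis(groups)
        for transform in (lambda x: 3.0 * x + 7.0, np.arctan):
            mapped = [[float(transform(x)) for x in g] for g in groups]
            # the transform must stay injective in float64, or it creates ties
            assume(len({x for g in mapped for x in g}) == len({x for g in groups for x in g}))
            h2, _ = kruskal_wallis(mapped)
            assert h1 == pytest.approx(h2, abs=1e-9)


class TestDunn:
    def test_mirrored_groups_give_zero(self):
        d = dunn_posthoc([[1, 4], [2, 3]])
        assert d.loc[0, "z"] == pytest.approx(0.0, abs=1e-12)
        assert d.loc[0, "p_raw"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_pinned_two_group_value(self):
        # mean ranks 2 and 5; se = sqrt(3.5 * (1/3 + 1/3)); z = -3/se
        d = dunn_posthoc([[1, 2, 3], [4, 5, 6]])
        assert d.loc[0, "z"] == pytest.approx(-1.9639610121239315, abs=1e-9)

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(size=6), rng.normal(size=4), rng.normal(size=5)]
        fwd = dunn_posthoc(groups, labels=["a", "b", "c"])
        rev = dunn_posthoc(groups[::-1], labels=["c", "b", "a"])
        z_fwd = {(r.group_i, r.group_j): r.z for r in fwd.itertuples()}
        z_rev = {(r.group_i, r.group_j): r.z for r in rev.itertuples()}
        for (i, j), z in z_fwd.items():
            assert z_rev[(j, i)] == pytest.approx(-z, abs=1e-12)

    def test_tie_correction_applied(self):
        tied = dunn_posthoc([[1, 1, 2], [3, 3, 4]])
        untied = dunn_posthoc([[1.0, 1.1, 2], [3, 3.1, 4]])
        assert abs(tied.loc[0, "z"]) > abs(untied.loc[0, "z"]) - 1e-9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc([[1, 2], []])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.04, 0.01], [0.04, 0.02]),
        ],
    )
    def test_step_up_arithmetic(self, raw, expected):
        assert bh_adjust(raw) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_reference_implementation(self, raw):
        adj = bh_adjust(raw)
        ref = multipletests(raw, method="fdr_bh")[1]
        assert adj == pytest.approx(ref, abs=1e-12)
        assert np.all(adj >= np.asarray(raw) - 1e-15)
        assert np.all((adj >= 0) & (adj <= 1))
        order = np.argsort(raw, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in sorted order


class TestCandidateRegions:
    def _sel(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_xy", "n_zw"])

    def test_adjacent_windows_merge(self):
        sel = self._sel([("c", 27_500_000, 27_600_000, 100, 1), ("c", 27_600_000, 27_700_000, 120, 0)])
        regions = call_candidate_regions(sel, window_size=100_000)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_windows, r.system_call) == (27_500_000, 27_700_000, 2, "XY")
        assert r.peak_window == (27_600_000, 27_700_000)

    def test_gap_larger_than_max_gap_splits(self):
        sel = self._sel([("c", 0, 100_000, 10, 0), ("c", 400_000, 500_000, 9, 0)])
        assert len(call_candidate_regions(sel, window_size=100_000, max_gap=1)) == 2
        assert len(call_candidate_regions(sel, window_size=100_000, max_gap=3)) == 1

    def test_single_sub_threshold_window_bridged(self):
        sel = self._sel([("c", 0, 100_000, 10, 0), ("c", 200_000, 300_000, 9, 0)])
        assert len(call_candidate_regions(sel, window_size=100_000, max_gap=1)) == 1

    def test_system_calls(self):
        sel = self._sel(
            [("a", 0, 100_000, 300, 5), ("b", 0, 100_000, 2, 40), ("c", 0, 100_000, 3, 3)]
        )
        calls = {r.chrom: r.system_call for r in call_candidate_regions(sel, window_size=100_000)}
        assert calls == {"a": "XY", "b": "ZW", "c": "ambiguous"}

    def test_ranked_by_total_count(self):
        sel = self._sel([("a", 0, 100_000, 5, 0), ("b", 0, 100_000, 50, 0)])
        regions = call_candidate_regions(sel, window_size=100_000)
        assert [r.chrom for r in regions] == ["b", "a"]


def test_fully_linked_chromosome_flagged_by_kw_and_dunn():
    """A chromosome whose windows genuinely shift in log2(XY:ZW) must win
    the mean-rank ordering and at least one adjusted Dunn comparison."""
    lengths = {f"LG{i:02d}": 1_000_000 for i in range(1, 13)}
    cfg = SimulationConfig(seed=2, chrom_lengths=lengths, sdr_chrom="LG05",
                           sdr_interval=(0, 1_000_000))
    sites, _ = simulate_pools(cfg)
    win, _ = count_in_windows(make_windows(lengths), scan_sites(sites))
    res = run_chrom_tests(win)
    assert res.p < 0.05 and res.dunn is not None
    means = win.assign(rank=win["log2_ratio"].rank()).groupby("chrom")["rank"].mean()
    assert means.idxmax() == "LG05"
    d = res.dunn
    involving = d[(d["group_i"] == "LG05") | (d["group_j"] == "LG05")]
    assert involving["p_adjusted"].min() < 0.05
    assert np.all(d["p_adjusted"].to_numpy() >= d["p_raw"].to_numpy() - 1e-12)
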