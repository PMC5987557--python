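import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from twindmr.dmr import (
    DMRParams,
    DMW,
    UndefinedStatisticError,
    call_dmrs,
    filter_dmws,
    merge_dmws,
    methylation_distribution,
    methylation_level,
    sample_correlation,
    scan_windows,
    window_sites,
    window_test,
)
from twindmr.simulate import SimulationConfig, simulate_methylome_pair

from conftest import brute_force_ranksum_p, make_sample, regions_overlap


class TestMethylationLevel:
    @pytest.mark.parametrize(
        "meth,unmeth,expected", [(7, 3, 0.7), (0, 12, 0.0), (5, 0, 1.0)]
    )
    def test_values(self, meth, unmeth, expected):
        assert methylation_level(meth, unmeth) == pytest.approx(expected)

    def test_zero_depth_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            methylation_level(0, 0)


class TestWindowTest:
    def test_fully_separated_5v5_exact(self):
        assert window_test([0] * 5, [1] * 5) == pytest.approx(2 / 252)

    def test_identical_lists_give_p_one(self):
        levels = [0.1, 0.4, 0.9]
        assert window_test(levels, levels) == 1.0
        assert window_test(levels, levels, test="signed_rank") == 1.0

    def test_small_shifted_lists_match_enumeration(self):
        x, y = [0.1, 0.2, 0.3], [0.2, 0.3, 0.4]
        assert window_test(x, y) == pytest.approx(brute_force_ranksum_p(x, y))

    def test_empty_input_errors(self):
        with pytest.raises(UndefinedStatisticError):
            window_test([], [0.5])

    @given(
        data=st.data(),
        n1=st.integers(1, 6),
        n2=st.integers(1, 6),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_exact_branch_equals_independent_enumeration(self, data, n1, n2):
        """Tied, discrete level lists: exact p matches a naive oracle."""
        levels = st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0])
        x = data.draw(st.lists(levels, min_size=n1, max_size=n1))
        y = data.draw(st.lists(levels, min_size=n2, max_size=n2))
        assert window_test(x, y) == pytest.approx(brute_force_ranksum_p(x, y))

    def test_large_n_matches_scipy_normal_approximation(self, rng):
        """Tie-free large samples: the asymptotic branch agrees with the
        reference Mann-Whitney implementation's normal method."""
        for _ in range(20):
            x = rng.random(10)
            y = rng.random(10)
            ours = window_test(x, y)
            ref = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_signed_rank_drops_zero_differences(self):
        x = [0.5, 0.5, 0.9, 0.1, 0.8, 0.2, 0.7]
        y = [0.5, 0.5, 0.1, 0.9, 0.2, 0.8, 0.1]
        d = np.array(x) - np.array(y)
        expected = stats.wilcoxon(d[d != 0], alternative="two-sided").pvalue
        assert window_test(x, y, test="signed_rank") == pytest.approx(expected)

    def test_symmetry_under_sample_swap(self, rng):
        for _ in range(20):
            x = list(rng.random(rng.integers(1, 7)))
            y = list(rng.random(rng.integers(1, 7)))
            assert window_test(x, y) == pytest.approx(window_test(y, x))


class TestWindowSites:
    def test_intersection_semantics(self):
        s1 = make_sample("s1", [("chr1", 10, 12, 0), ("chr1", 20, 12, 0), ("chr1", 30, 12, 0), ("chr1", 40, 12, 0)])
        s2 = make_sample("s2", [("chr1", 10, 0, 12), ("chr1", 20, 0, 12), ("chr1", 30, 0, 12), ("chr1", 40, 2, 1)])
        l1, l2 = window_sites(s1, s2, "chr1", 0, 100, min_depth=10)
        assert len(l1) == len(l2) == 3  # site 40 too shallow in s2
        assert l1 == [1.0, 1.0, 1.0] and l2 == [0.0, 0.0, 0.0]

    def test_no_covered_sites_returns_empty_lists(self):
        s1 = make_sample("s1", [("chr1", 10, 12, 0)])
        s2 = make_sample("s2", [("chr2", 10, 12, 0)])
        assert window_sites(s1, s2, "chr1", 0, 100, 10) == ([], [])

    def test_depth_exactly_min_depth_included(self):
        s1 = make_sample("s1", [("chr1", 10, 5, 5)])
        s2 = make_sample("s2", [("chr1", 10, 9, 1)])
        l1, l2 = window_sites(s1, s2, "chr1", 0, 100, min_depth=10)
        assert (l1, l2) == ([0.5], [0.9])


class TestScanWindows:
    def test_grid_property(self):
        """Every window start is on the step grid; width = window_size;
        trailing partial windows are not emitted."""
        sites = [("chr1", p, 10, 10) for p in [5, 60, 110, 170, 230, 245]]
        s1 = make_sample("s1", sites)
        s2 = make_sample("s2", sites)
        params = DMRParams(window_size=100, step=50, min_depth=10)
        dmws = scan_windows(s1, s2, params, {"chr1": 250})
        starts = sorted({w.start for w in dmws})
        assert starts == [0, 50, 100, 150]  # [200,300) would overrun chr end
        assert all(w.end - w.start == 100 for w in dmws)
        assert all(w.start % 50 == 0 for w in dmws)

    def test_identical_samples_give_p_one_everywhere(self, flat_pair):
        s1, _ = flat_pair
        dmws = scan_windows(s1, s1, DMRParams(min_depth=10), {"chr1": 300})
        assert dmws and all(w.p_value == 1.0 for w in dmws)

    def test_swap_symmetry_flips_delta_keeps_p(self, flat_pair):
        s1, s2 = flat_pair
        params = DMRParams(min_depth=10)
        fwd = scan_windows(s1, s2, params, {"chr1": 300})
        rev = scan_windows(s2, s1, params, {"chr1": 300})
        assert len(fwd) == len(rev)
        for a, b in zip(fwd, rev):
            assert (a.chrom, a.start) == (b.chrom, b.start)
            assert a.p_value == pytest.approx(b.p_value)
            assert a.delta == pytest.approx(-b.delta)

    def test_missing_chrom_size_raises(self, flat_pair):
        s1, s2 = flat_pair
        with pytest.raises(ValueError, match="chrom_sizes"):
            scan_windows(s1, s2, DMRParams(), {"chr9": 100})

    def test_planted_block_yields_significant_windows(self):
        positions = list(range(1000, 1100, 10))
        s1 = make_sample("s1", [("chr1", p, 3, 27) for p in positions])
        s2 = make_sample("s2", [("chr1", p, 27, 3) for p in positions])
        dmws = scan_windows(s1, s2, DMRParams(), {"chr1": 2000})
        covering = [w for w in dmws if w.start <= 1000 and w.end >= 1090]
        assert covering and all(w.p_value < 0.01 for w in covering)


class TestFilterDmws:
    def _dmw(self, p, n, delta):
        levels = tuple([0.5] * n)
        return DMW("chr1", 0, 100, tuple(range(n)), levels, levels,
                   0.5 + delta, 0.5, delta, p)

    def test_passing_window_retained(self):
        assert filter_dmws([self._dmw(0.005, 6, 0.25)], DMRParams()) != []

    @pytest.mark.parametrize(
        "p,n,delta",
        [
            (0.005, 6, 0.05),   # effect below 10%
            (0.005, 4, 0.25),   # fewer than 5 CpGs
            (0.02, 6, 0.25),    # p above alpha
        ],
    )
    def test_each_gate_flips_retention(self, p, n, delta):
        assert filter_dmws([self._dmw(p, n, delta)], DMRParams()) == []

    def test_boundary_semantics(self):
        # |delta| exactly at min_delta and n exactly at min_cpgs pass;
        # p exactly at alpha fails (strict inequality).
        assert filter_dmws([self._dmw(0.009, 5, 0.10)], DMRParams()) != []
        assert filter_dmws([self._dmw(0.01, 5, 0.10)], DMRParams()) == []
        assert filter_dmws([self._dmw(0.009, 5, -0.10)], DMRParams()) != []


def _window(chrom, start, end, delta, p=0.005, positions=None):
    positions = positions if positions is not None else tuple(range(start, end, 10))
    n = len(positions)
    l2 = tuple([0.4] * n)
    l1 = tuple([0.4 + delta] * n)
    m1 = 0.4 + delta
    return DMW(chrom, start, end, tuple(positions), l1, l2, m1, 0.4, delta, p)


class TestMergeDmws:
    def test_overlapping_same_direction_unioned(self):
        dmrs = merge_dmws([_window("chr1", 0, 100, 0.3), _window("chr1", 50, 150, 0.3)])
        assert len(dmrs) == 1
        assert (dmrs[0].start, dmrs[0].end, dmrs[0].direction) == (0, 150, "hyper")
        assert dmrs[0].n_windows == 2

    def test_gap_splits(self):
        dmrs = merge_dmws([_window("chr1", 0, 100, 0.3), _window("chr1", 150, 250, 0.3)])
        assert len(dmrs) == 2

    def test_abutting_windows_join(self):
        dmrs = merge_dmws([_window("chr1", 0, 100, 0.3), _window("chr1", 100, 200, 0.3)])
        assert len(dmrs) == 1 and dmrs[0].end == 200

    def test_direction_split(self):
        dmrs = merge_dmws([_window("chr1", 0, 100, 0.3), _window("chr1", 50, 150, -0.3)])
        assert len(dmrs) == 2
        assert {d.direction for d in dmrs} == {"hyper", "hypo"}

    def test_p_value_is_min_and_sites_distinct(self):
        a = _window("chr1", 0, 100, 0.3, p=0.004, positions=(10, 30, 60, 90))
        b = _window("chr1", 50, 150, 0.3, p=0.001, positions=(60, 90, 120))
        (d,) = merge_dmws([a, b])
        assert d.p_value == pytest.approx(0.001)
        assert d.n_cpgs == 5  # 60 and 90 shared

    def test_matches_brute_force_union_oracle(self, rng):
        """Random window sets vs an independent same-direction union oracle."""
        for _ in range(500):
            n = rng.integers(1, 12)
            wins = []
            for _ in range(n):
                start = int(rng.integers(0, 20)) * 50
                chrom = f"chr{rng.integers(1, 3)}"
                delta = float(rng.choice([-0.3, 0.3]))
                wins.append(_window(chrom, start, start + 100, delta))
            got = merge_dmws(wins)
            # oracle: repeated pairwise unions until fixpoint
            items = [
                {"chrom": w.chrom, "start": w.start, "end": w.end,
                 "dir": w.direction, "n": 1}
                for w in wins
            ]
            changed = True
            while changed:
                changed = False
                for i in range(len(items)):
                    for j in range(i + 1, len(items)):
                        a, b = items[i], items[j]
                        if (
                            a["chrom"] == b["chrom"] and a["dir"] == b["dir"]
                            and a["start"] <= b["end"] and b["start"] <= a["end"]
                        ):
                            a["start"] = min(a["start"], b["start"])
                            a["end"] = max(a["end"], b["end"])
                            a["n"] += b["n"]
                            del items[j]
                            changed = True
                            break
                    if changed:
                        break
            expected = sorted(
                (it["chrom"], it["start"], it["end"], it["dir"], it["n"]) for it in items
            )
            observed = sorted(
                (d.chrom, d.start, d.end, d.direction, d.n_windows) for d in got
            )
            assert observed == expected


class TestCallDmrs:
    def test_monotonic_in_thresholds(self):
        cfg = SimulationConfig(seed=5, n_chroms=1, chrom_length=200_000, n_dmrs=8)
        s1, s2, _ = simulate_methylome_pair(cfg)
        sizes = cfg.chrom_sizes
        dmws = scan_windows(s1, s2, DMRParams(), sizes)
        n_sig = [
            len(filter_dmws(dmws, DMRParams(alpha=a))) for a in (0.001, 0.01, 0.05)
        ]
        assert n_sig == sorted(n_sig)
        n_by_delta = [
            len(filter_dmws(dmws, DMRParams(min_delta=d))) for d in (0.05, 0.2, 0.5)
        ]
        assert n_by_delta == sorted(n_by_delta, reverse=True)
        n_by_cpgs = [
            len(filter_dmws(dmws, DMRParams(min_cpgs=k))) for k in (3, 5, 8)
        ]
        assert n_by_cpgs == sorted(n_by_cpgs, reverse=True)

    def test_disjoint_coverage_yields_no_windows(self):
        s1 = make_sample("s1", [("chr1", p, 10, 10) for p in (10, 20, 30)])
        s2 = make_sample("s2", [("chr1", p, 10, 10) for p in (500, 510, 520)])
        dmrs, report = call_dmrs(s1, s2, DMRParams(), {"chr1": 1000})
        assert dmrs == [] and report.windows_tested == 0

    def test_planted_recovery_small(self):
        cfg = SimulationConfig(seed=7, n_chroms=1, chrom_length=300_000, n_dmrs=10)
        s1, s2, truth = simulate_methylome_pair(cfg)
        dmrs, report = call_dmrs(s1, s2, DMRParams(), cfg.chrom_sizes)
        assert report.dmrs == report.n_hyper + report.n_hypo
        recovered = sum(
            any(regions_overlap(d, r) and d.direction == r.direction for d in dmrs)
            for r in truth.regions
        )
        assert recovered >= 9


class TestQcStatistics:
    def test_correlation_of_identical_samples_is_one(self, flat_pair):
        s1, _ = flat_pair
        assert sample_correlation(s1, s1, 10) == pytest.approx(1.0)

    def test_anticorrelated_toy_levels(self):
        s1 = make_sample("s1", [("chr1", 10, 0, 10), ("chr1", 20, 10, 0),
                                 ("chr1", 30, 0, 10), ("chr1", 40, 10, 0)])
        s2 = make_sample("s2", [("chr1", 10, 10, 0), ("chr1", 20, 0, 10),
                                 ("chr1", 30, 10, 0), ("chr1", 40, 0, 10)])
        assert sample_correlation(s1, s2, 10) == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        s = make_sample("s", [("chr1", 10, 10, 0), ("chr1", 20, 10, 0)])
        with pytest.raises(UndefinedStatisticError):
            sample_correlation(s, s, 1)

    def test_replicate_binomial_resampling_highly_correlated(self):
        cfg = SimulationConfig(seed=11, n_chroms=1, chrom_length=200_000, n_dmrs=0)
        s1, s2, _ = simulate_methylome_pair(cfg)
        assert sample_correlation(s1, s2, 10) > 0.95

    def test_distribution_all_zero_levels(self):
        s = make_sample("s", [("chr1", p, 0, 10) for p in (10, 20, 30)])
        counts, _ = methylation_distribution(s, bins=10)
        assert counts[0] == 3 and counts[1:].sum() == 0

    def test_binning_convention_right_closed(self):
        s = make_sample("s", [("chr1", 10, 0, 10), ("chr1", 20, 5, 5), ("chr1", 30, 10, 0)])
        counts, edges = methylation_distribution(s, bins=2)
        assert list(counts) == [2, 1]
        assert edges[0] == 0.0 and edges[-1] == 1.0

    def test_simulated_methylome_is_bimodal(self):
        cfg = SimulationConfig(seed=13, n_chroms=1, chrom_length=150_000, n_dmrs=0)
        s1, _, _ = simulate_methylome_pair(cfg)
        counts, _ = methylation_distribution(s1, bins=10)
        assert counts[0] + counts[-1] > counts.sum() / 2
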