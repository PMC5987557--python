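"""Sliding-window differential methylation calling between two methylomes.

The procedure slides a fixed-width window along each chromosome on a regular
step grid, compares the per-CpG methylation levels of the two samples inside
each window with a Wilcoxon rank-sum test, keeps windows that pass a p-value,
CpG-count and effect-size gate, and merges overlapping-or-abutting
significant windows of the same direction into differentially methylated
regions (DMRs).

"hyper" means sample 1 is more methylated than sample 2 in the region;
"hypo" the reverse.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .io import MethylomeSample

EXACT_ENUMERATION_LIMIT = 12  # exact permutation null up to this combined n


class UndefinedStatisticError(ValueError):
    """A statistic was requested on input where it is not defined."""


@dataclass(frozen=True)
class DMRParams:
    """Tuning knobs of the window scan.

    window_size/step are in bp; min_depth is the per-site read depth
    required in BOTH samples; alpha is the raw two-sided p-value cutoff;
    min_cpgs and min_delta gate window size and effect; test selects the
    rank-sum (independent groups) or signed-rank (paired) Wilcoxon form.
    """

    window_size: int = 100
    step: int = 50
    min_depth: int = 10
    alpha: float = 0.01
    min_cpgs: int = 5
    min_delta: float = 0.10
    test: str = "ranksum"

    def __post_init__(self) -> None:
        if not (self.window_size >= self.step >= 1):
            raise ValueError("need window_size >= step >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 <= self.min_delta <= 1):
            raise ValueError("min_delta must be in [0, 1]")
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")
        if self.test not in ("ranksum", "signed_rank"):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass(frozen=True)
class DMW:
    """One tested window with its per-site levels and statistics."""

    chrom: str
    start: int
    end: int
    positions: tuple[int, ...]
    levels_s1: tuple[float, ...]
    levels_s2: tuple[float, ...]
    mean_s1: float
    mean_s2: float
    delta: float
    p_value: float

    @property
    def n_cpgs(self) -> int:
        return len(self.positions)

    @property
    def direction(self) -> str:
        return "hyper" if self.delta >= 0 else "hypo"


@dataclass(frozen=True)
class DMR:
    """A merged run of same-direction significant windows."""

    chrom: str
    start: int
    end: int
    direction: str
    n_windows: int
    n_cpgs: int
    p_value: float
    mean_s1: float
    mean_s2: float

    @property
    def delta(self) -> float:
        return self.mean_s1 - self.mean_s2


@dataclass
class ScanReport:
    """Counts logged by a full scan."""

    windows_tested: int = 0
    dmws_significant: int = 0
    dmrs: int = 0
    n_hyper: int = 0
    n_hypo: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def methylation_level(meth_count: int, unmeth_count: int) -> float:
    """Fraction of reads supporting methylation; undefined at zero depth."""
    depth = meth_count + unmeth_count
    if depth <= 0:
        raise UndefinedStatisticError("methylation level undefined at zero depth")
    return meth_count / depth


@lru_cache(maxsize=64)
def _combination_matrix(n_total: int, n_pick: int) -> np.ndarray:
    """All C(n_total, n_pick) index subsets as an int array (cached)."""
    combos = list(itertools.combinations(range(n_total), n_pick))
    return np.array(combos, dtype=np.intp)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments.

    Midranks handle ties; the two-sided p is the fraction of assignments
    whose rank-sum deviates from the null mean at least as much as the
    observed one (with a small tolerance so ties in the statistic count).
    """
    n1 = len(x)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r_obs = ranks[:n1].sum()
    mu = n1 * ranks.mean()
    combos = _combination_matrix(len(combined), n1)
    sums = ranks[combos].sum(axis=1)
    hits = np.abs(sums - mu) >= abs(r_obs - mu) - 1e-9
    return float(hits.sum() / len(sums))


def _normal_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    dev = abs(r1 - mu)
    z = max(dev - 0.5, 0.0) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def window_test(levels_s1, levels_s2, test: str = "ranksum") -> float:
    """Two-sided Wilcoxon p-value comparing two per-site level lists.

    ``ranksum`` treats the lists as independent groups: exact permutation
    null when the combined size is <= 12, tie-corrected normal
    approximation above.  ``signed_rank`` pairs the sites positionally and
    drops zero differences.
    """
    x = np.asarray(levels_s1, dtype=float)
    y = np.asarray(levels_s2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise UndefinedStatisticError("window test needs non-empty level lists")
    if test == "ranksum":
        if len(x) + len(y) <= EXACT_ENUMERATION_LIMIT:
            return _exact_ranksum_p(x, y)
        return _normal_ranksum_p(x, y)
    if test == "signed_rank":
        if len(x) != len(y):
            raise UndefinedStatisticError("signed-rank test needs paired lists")
        d = x - y
        d = d[d != 0]
        if len(d) == 0:
            return 1.0
        return float(stats.wilcoxon(d, alternative="two-sided").pvalue)
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# Shared-site extraction
# ---------------------------------------------------------------------------

def shared_site_levels(
    s1: MethylomeSample,
    s2: MethylomeSample,
    min_depth: int,
    chrom: str | None = None,
    context: str = "CG",
) -> pd.DataFrame:
    """Sites covered >= min_depth in BOTH samples, with both levels.

    Returns columns chrom, pos, level_1, level_2 sorted by (chrom, pos);
    sites are matched on (chrom, pos, strand).
    """
    def prep(s: MethylomeSample) -> pd.DataFrame:
        f = s.frame if chrom is None else s.chrom_arrays(chrom)
        depth = f["meth"] + f["unmeth"]
        keep = depth >= max(min_depth, 1)
        if context is not None:
            keep &= f["context"] == context
        f = f.loc[keep, ["chrom", "pos", "strand", "meth"]].copy()
        f["level"] = f["meth"] / depth[keep]
        return f.drop(columns="meth")

    merged = prep(s1).merge(
        prep(s2), on=["chrom", "pos", "strand"], suffixes=("_1", "_2")
    )
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return merged[["chrom", "pos", "level_1", "level_2"]]


def window_sites(
    s1: MethylomeSample,
    s2: MethylomeSample,
    chrom: str,
    start: int,
    end: int,
    min_depth: int,
) -> tuple[list[float], list[float]]:
    """Paired level lists for CpG sites deep enough in both samples in [start, end)."""
    shared = shared_site_levels(s1, s2, min_depth, chrom=chrom)
    in_win = shared[(shared["pos"] >= start) & (shared["pos"] < end)]
    return list(in_win["level_1"]), list(in_win["level_2"])


# ---------------------------------------------------------------------------
# Window scan
# ---------------------------------------------------------------------------

def _window_starts_for_sites(pos: np.ndarray, window_size: int, step: int,
                             chrom_len: int) -> tuple[np.ndarray, np.ndarray]:
    """(window_start, site_index) pairs for every grid window holding a site.

    Window starts are the multiples of ``step``; trailing windows that would
    extend past the chromosome end are not emitted.
    """
    max_k = -(-window_size // step)  # windows that can cover one position
    starts_list, idx_list = [], []
    base = (pos // step) * step
    for k in range(max_k):
        s = base - k * step
        ok = (s >= 0) & (s + window_size <= chrom_len) & (pos >= s) & (pos < s + window_size)
        starts_list.append(s[ok])
        idx_list.append(np.flatnonzero(ok))
    starts = np.concatenate(starts_list)
    idx = np.concatenate(idx_list)
    order = np.lexsort((idx, starts))
    return starts[order], idx[order]


def scan_windows(
    s1: MethylomeSample,
    s2: MethylomeSample,
    params: DMRParams,
    chrom_sizes: dict[str, int],
) -> list[DMW]:
    """Test every grid window holding >= 1 shared deep CpG site.

    Emits a DMW with full statistics for each tested window; significance
    is decided downstream by filter_dmws.
    """
    shared = shared_site_levels(s1, s2, params.min_depth)
    seen_chroms = set(shared["chrom"].unique())
    missing = seen_chroms - set(chrom_sizes)
    if missing:
        raise ValueError(f"chrom_sizes missing chromosomes: {sorted(missing)}")
    out: list[DMW] = []
    for chrom, grp in shared.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        l1 = grp["level_1"].to_numpy()
        l2 = grp["level_2"].to_numpy()
        if len(pos) == 0:
            continue
        starts, idx = _window_starts_for_sites(
            pos, params.window_size, params.step, chrom_sizes[chrom]
        )
        if len(starts) == 0:
            continue
        bounds = np.flatnonzero(starts[1:] != starts[:-1]) + 1
        grp_lo = np.concatenate([[0], bounds])
        grp_hi = np.concatenate([bounds, [len(starts)]])
        for lo, hi in zip(grp_lo, grp_hi):
            w_start = int(starts[lo])
            site_idx = idx[lo:hi]
            wl1, wl2 = l1[site_idx], l2[site_idx]
            m1, m2 = float(wl1.mean()), float(wl2.mean())
            p = window_test(wl1, wl2, params.test)
            out.append(
                DMW(
                    chrom=chrom, start=w_start, end=w_start + params.window_size,
                    positions=tuple(int(p_) for p_ in pos[site_idx]),
                    levels_s1=tuple(float(v) for v in wl1),
                    levels_s2=tuple(float(v) for v in wl2),
                    mean_s1=m1, mean_s2=m2, delta=m1 - m2, p_value=p,
                )
            )
    return out


def filter_dmws(dmws: list[DMW], params: DMRParams) -> list[DMW]:
    """Keep windows with p < alpha, >= min_cpgs sites and |delta| >= min_delta."""
    return [
        w for w in dmws
        if w.p_value < params.alpha
        and w.n_cpgs >= params.min_cpgs
        and abs(w.delta) >= params.min_delta
    ]


def merge_dmws(dmws: list[DMW]) -> list[DMR]:
    """Union maximal runs of overlapping-or-abutting same-direction windows.

    DMR p-value is the minimum constituent p; site counts and means are
    over the distinct CpG sites of the run.  Merging is stratified by
    direction, so an interleaved window of the opposite direction does not
    break a same-direction run.
    """
    out: list[DMR] = []
    for direction in ("hyper", "hypo"):
        out.extend(_merge_one_direction([w for w in dmws if w.direction == direction]))
    return sorted(out, key=lambda d: (d.chrom, d.start, d.end))


def _merge_one_direction(dmws: list[DMW]) -> list[DMR]:
    ordered = sorted(dmws, key=lambda w: (w.chrom, w.start, w.end))
    out: list[DMR] = []
    run: list[DMW] = []

    def flush() -> None:
        if not run:
            return
        sites: dict[int, tuple[float, float]] = {}
        for w in run:
            for p_, a, b in zip(w.positions, w.levels_s1, w.levels_s2):
                sites[p_] = (a, b)
        l1 = [v[0] for v in sites.values()]
        l2 = [v[1] for v in sites.values()]
        out.append(
            DMR(
                chrom=run[0].chrom,
                start=min(w.start for w in run),
                end=max(w.end for w in run),
                direction=run[0].direction,
                n_windows=len(run),
                n_cpgs=len(sites),
                p_value=min(w.p_value for w in run),
                mean_s1=float(np.mean(l1)),
                mean_s2=float(np.mean(l2)),
            )
        )
        run.clear()

    cur_end = None
    for w in ordered:
        if run and (w.chrom != run[0].chrom or w.start > cur_end):
            flush()
        if not run:
            cur_end = w.end
        run.append(w)
        cur_end = max(cur_end, w.end)
    flush()
    return out


def call_dmrs(
    s1: MethylomeSample,
    s2: MethylomeSample,
    params: DMRParams,
    chrom_sizes: dict[str, int],
) -> tuple[list[DMR], ScanReport]:
    """Full scan → filter → merge pipeline with a count report."""
    dmws = scan_windows(s1, s2, params, chrom_sizes)
    significant = filter_dmws(dmws, params)
    dmrs = merge_dmws(significant)
    report = ScanReport(
        windows_tested=len(dmws),
        dmws_significant=len(significant),
        dmrs=len(dmrs),
        n_hyper=sum(1 for d in dmrs if d.direction == "hyper"),
        n_hypo=sum(1 for d in dmrs if d.direction == "hypo"),
    )
    return dmrs, report


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------

def sample_correlation(s1: MethylomeSample, s2: MethylomeSample, min_depth: int) -> float:
    """Pearson r of per-site levels over sites deep enough in both samples."""
    shared = shared_site_levels(s1, s2, min_depth)
    if len(shared) < 2:
        raise UndefinedStatisticError("correlation needs >= 2 shared deep sites")
    a = shared["level_1"].to_numpy()
    b = shared["level_2"].to_numpy()
    if a.std() == 0 or b.std() == 0:
        raise UndefinedStatisticError("correlation undefined with zero variance")
    return float(stats.pearsonr(a, b).statistic)


def methylation_distribution(
    sample: MethylomeSample, bins: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-site methylation levels over covered CpG sites.

    Bins are right-closed on [0, 1] (the first bin includes 0), so a level
    exactly on an edge falls in the lower bin; returns (counts, edges).
    """
    f = sample.frame
    depth = (f["meth"] + f["unmeth"]).to_numpy()
    keep = depth > 0
    if not keep.any():
        raise UndefinedStatisticError("no covered sites to histogram")
    levels = f["meth"].to_numpy()[keep] / depth[keep]
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.searchsorted(edges, levels, side="left") - 1
    idx = np.clip(idx, 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    return counts, edges
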