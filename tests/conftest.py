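import numpy as np
import pandas as pd
import pytest

from twindmr.io import CytosineRecord, MethylomeSample


def make_sample(sample_id, sites):
    """sites: iterable of (chrom, pos0, meth, unmeth[, strand[, context]])."""
    records = []
    for s in sites:
        chrom, pos, meth, unmeth = s[:4]
        strand = s[4] if len(s) > 4 else "+"
        context = s[5] if len(s) > 5 else "CG"
        records.append(CytosineRecord(chrom, pos, strand, meth, unmeth, context))
    return MethylomeSample.from_records(sample_id, records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def flat_pair():
    """Two samples sharing 12 deep CpGs on chr1 with varying level profiles."""
    positions = [10, 20, 30, 40, 110, 120, 130, 140, 210, 220, 230, 240]
    s1 = make_sample(
        "s1", [("chr1", p, 2 + i, 18 - i) for i, p in enumerate(positions)]
    )
    s2 = make_sample(
        "s2", [("chr1", p, 18 - i, 2 + i) for i, p in enumerate(positions)]
    )
    return s1, s2


def brute_force_ranksum_p(x, y):
    """Independent exact two-sided rank-sum oracle by full enumeration.

    Naive midrank computation and deviation counting, written separately
    from the package implementation.
    """
    import itertools

    combined = list(x) + list(y)
    n1, n = len(x), len(combined)
    order = sorted(range(n), key=lambda i: combined[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and combined[order[j + 1]] == combined[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    obs = sum(ranks[:n1])
    mu = n1 * sum(ranks) / n
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        total += 1
        if abs(sum(ranks[i] for i in combo) - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / total


def regions_overlap(dmr, region):
    return (
        dmr.chrom == region.chrom
        and dmr.start < region.end
        and region.start < dmr.end
    )
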