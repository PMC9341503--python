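"""Shared fixtures and independent brute-force oracles.

The oracles operate on explicit per-base boolean/integer arrays over small
toy chromosomes, independently of the sweep-line implementations they check.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pytest

from epitrans import CohortSpec, GenomicInterval, generate_cohort
from epitrans.simulate import NO_NOISE

CHROM = "toy"


def paint(intervals, length: int) -> np.ndarray:
    """Per-base coverage mask of intervals on a single toy chromosome."""
    arr = np.zeros(length, dtype=bool)
    for iv in intervals:
        arr[iv.start : min(iv.end, length)] = True
    return arr


def runs_of(mask: np.ndarray, chrom: str = CHROM):
    """Contiguous True runs of a boolean array as intervals."""
    out = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for lo, hi in idx.reshape(-1, 2):
        out.append(GenomicInterval(chrom, int(lo), int(hi)))
    return out


def oracle_merge(intervals, max_gap: int, length: int):
    """Per-base merge oracle: paint, then fill gaps strictly below max_gap."""
    mask = paint(intervals, length)
    runs = runs_of(mask)
    for a, b in zip(runs[:-1], runs[1:]):
        if b.start - a.end < max_gap:
            mask[a.end : b.start] = True
    # repeated filling is unnecessary: filling never creates new gaps
    return runs_of(mask)


def oracle_support(interval_sets, length: int) -> np.ndarray:
    """Per-base support counts (each set counted at most once per base)."""
    total = np.zeros(length, dtype=int)
    for s in interval_sets:
        total += paint(s, length).astype(int)
    return total


def fisher_two_sided_enum(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, r1)
    kmin, kmax = max(0, r1 - (n - c1)), min(r1, c1)

    def pmf(k):
        return comb(c1, k) * comb(n - c1, r1 - k) / denom

    p_obs = pmf(a)
    return sum(pmf(k) for k in range(kmin, kmax + 1) if pmf(k) <= p_obs * (1 + 1e-9))


def random_intervals(rng, n: int, length: int, max_len: int = 400):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, length - 1))
        end = min(length, start + 1 + int(rng.integers(0, max_len)))
        out.append(GenomicInterval(CHROM, start, end))
    return out


@pytest.fixture(scope="session")
def toy_cohort_clean():
    """Small noiseless toy cohort with sequence, reused across tests."""
    spec = CohortSpec(
        n_healthy=3,
        n_malignant=2,
        scenarios=("u266_like", "z138_like"),
        template="toy",
        noise=NO_NOISE,
        seed=7,
        include_fasta=True,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def igh_cohort_clean():
    """Noiseless cohort on the published-coordinate template."""
    spec = CohortSpec(
        n_healthy=3,
        n_malignant=1,
        scenarios=("u266_like",),
        template="igh_printed",
        noise=NO_NOISE,
        seed=11,
        include_fasta=False,
    )
    return generate_cohort(spec)
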