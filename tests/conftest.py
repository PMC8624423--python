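"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the library code paths they check: ranks by
pairwise counting, the SRD normalization constant by brute force over
permutations, the whole five-step procedure in plain Python loops.
"""

from __future__ import annotations

import itertools
import statistics

import numpy as np
import pytest

from srdkit import PeakRecord, PeakTable, ProcedureLabel


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def naive_ranks(values) -> list[float]:
    """Fractional ranks by counting: 1 + #smaller + (#equal - 1)/2."""
    vals = list(values)
    out = []
    for v in vals:
        less = sum(1 for u in vals if u < v)
        equal = sum(1 for u in vals if u == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def brute_force_max_srd(reference_ranks) -> float:
    """Max footrule distance to the reference over every untied candidate
    ranking (the extreme points of the tie-averaged rank polytope)."""
    ref = list(reference_ranks)
    n = len(ref)
    return max(
        sum(abs(a - b) for a, b in zip(perm, ref))
        for perm in itertools.permutations(range(1, n + 1))
    )


def brute_force_footrule_counts(reference_ranks) -> dict[float, int]:
    """Frequency table of footrule distances over all permutations."""
    ref = list(reference_ranks)
    counts: dict[float, int] = {}
    for perm in itertools.permutations(ref):
        d = round(sum(abs(a - b) for a, b in zip(perm, ref)), 9)
        counts[d] = counts.get(d, 0) + 1
    return counts


def naive_srd_analysis(matrix, mode: str = "max"):
    """Plain-Python five-step SRD: reference, ranks, differences, sum, scale.

    Returns (srd_values, srd_max, scaled) with the normalization constant from
    brute-force permutation search (feasible for <= 8 rows).
    """
    rows = [list(map(float, r)) for r in matrix]
    if mode == "max":
        ref = [max(r) for r in rows]
    elif mode == "min":
        ref = [min(r) for r in rows]
    elif mode == "mean":
        ref = [sum(r) / len(r) for r in rows]
    elif mode == "median":
        ref = [statistics.median(r) for r in rows]
    else:
        raise ValueError(mode)
    ref_ranks = naive_ranks(ref)
    srd = []
    for j in range(len(rows[0])):
        col_ranks = naive_ranks([row[j] for row in rows])
        srd.append(sum(abs(a - b) for a, b in zip(col_ranks, ref_ranks)))
    smax = brute_force_max_srd(ref_ranks)
    scaled = [100.0 * v / smax if smax > 0 else 0.0 for v in srd]
    return srd, smax, scaled


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def build_table(intensities, labels=None, records=None) -> PeakTable:
    """PeakTable from a raw matrix with auto-generated metadata."""
    mat = np.atleast_2d(np.asarray(intensities, dtype=float))
    n, m = mat.shape
    if labels is None:
        labels = [f"A{i + 1}h" for i in range(m)]
    procs = [ProcedureLabel.parse(lab) for lab in labels]
    if records is None:
        records = [
            PeakRecord(retention_time=float(i + 1), name=f"cmpd_{i + 1}")
            for i in range(n)
        ]
    return PeakTable(records=records, procedures=procs, intensities=mat)


@pytest.fixture
def toy_table() -> PeakTable:
    """5 compounds x 3 procedures with a tie in the first column."""
    return build_table(
        [
            [10.0, 3.0, 7.0],
            [10.0, 5.0, 2.0],
            [4.0, 8.0, 9.0],
            [1.0, 1.0, 6.0],
            [6.0, 2.0, 2.0],
        ],
        labels=["A1h", "B1h", "C1h"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210)
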