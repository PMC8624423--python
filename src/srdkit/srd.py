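"""Sum of ranking differences (SRD).

SRD compares candidate columns of a data matrix to a benchmark ("golden
standard") column through rank numbers, in five steps:

1. define the reference column (row-wise max, min, mean, median, or an
   externally supplied standard);
2. rank-transform the reference and every candidate column (ascending,
   fractional/average ranks for ties);
3. take the absolute rank difference per row between each candidate and the
   reference;
4. sum the differences per candidate — the SRD value, a Spearman-footrule
   distance between the candidate's and the reference's rankings;
5. normalize to 0-100 by the maximum SRD attainable against the reference,
   so values are comparable across matrix sizes.

With an untied reference of n rows the normalization constant is the
classical floor(n^2 / 2); with ties it is the rearrangement bound obtained by
pairing the ascending-sorted reference ranks against the reversed untied
ranking n..1. Tie-averaged rank vectors are convex combinations of untied
permutations and the footrule distance is convex, so this bound holds for
every admissible candidate (whatever its tie structure), is exactly
attained by an untied reversal, and reduces to floor(n^2 / 2) when the
reference is untied.

The core computation is exposed as the scikit-learn-style estimator
:class:`SRDRanking` (``fit`` an n_compounds x n_procedures matrix, read the
fitted ``scaled_srd_`` / ``ordering_`` attributes); :func:`srd_analysis`
wraps it for :class:`~srdkit.peak_table.PeakTable` inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .peak_table import PeakTable

__all__ = [
    "rank_with_ties",
    "reference_column",
    "srd_value",
    "max_srd",
    "SRDRanking",
    "SrdResult",
    "srd_analysis",
    "REFERENCE_MODES",
]

REFERENCE_MODES = ("max", "min", "mean", "median", "external")


def rank_with_ties(values) -> np.ndarray:
    """Ascending fractional ranks; tied values share the average rank.

    The rank sum is conserved at n(n+1)/2, which keeps the SRD normalization
    argument valid in the presence of ties.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("cannot rank an empty vector")
    return rankdata(arr, method="average")


def reference_column(matrix, mode: str = "max", external=None) -> np.ndarray:
    """Row-wise benchmark column of an n x m intensity matrix."""
    mat = np.atleast_2d(np.asarray(matrix, dtype=float))
    if mat.shape[0] < 1 or mat.shape[1] < 1:
        raise ValueError("matrix must be at least 1 x 1")
    if mode == "external":
        if external is None:
            raise ValueError("mode='external' requires the external vector")
        ext = np.asarray(external, dtype=float).ravel()
        if ext.shape[0] != mat.shape[0]:
            raise ValueError("external reference length must match row count")
        return ext
    if external is not None:
        raise ValueError("external vector given but mode is not 'external'")
    if mode == "max":
        return mat.max(axis=1)
    if mode == "min":
        return mat.min(axis=1)
    if mode == "mean":
        return mat.mean(axis=1)
    if mode == "median":
        return np.median(mat, axis=1)
    raise ValueError(f"unknown reference mode {mode!r}; use one of {REFERENCE_MODES}")


def srd_value(candidate_ranks, reference_ranks) -> float:
    """Sum of absolute rank differences (Spearman footrule distance)."""
    cand = np.asarray(candidate_ranks, dtype=float).ravel()
    ref = np.asarray(reference_ranks, dtype=float).ravel()
    if cand.shape != ref.shape:
        raise ValueError(
            f"rank vectors differ in length: {cand.shape[0]} vs {ref.shape[0]}"
        )
    return float(np.abs(cand - ref).sum())


def max_srd(reference_ranks) -> float:
    """Maximum SRD attainable against this reference by any candidate ranking.

    Rearrangement bound: ascending-sorted reference ranks paired with the
    reversed untied ranking n..1. Strictly positive for n >= 2 and equal to
    floor(n^2/2) when the reference is untied.
    """
    ref = np.asarray(reference_ranks, dtype=float).ravel()
    n = ref.size
    if n < 2:
        raise ValueError("max_srd needs at least 2 rows")
    asc = np.sort(ref)
    return float(np.abs(asc - np.arange(n, 0, -1)).sum())


class SRDRanking(BaseEstimator):
    """Rank candidate columns by closeness to a benchmark column.

    Parameters
    ----------
    reference : {"max", "min", "mean", "median", "external"}, default "max"
        How the benchmark column is built from the fitted matrix. ``"max"``
        is the convention for sampling optimization: the best achievable
        intensity per compound.
    external : array-like of shape (n_rows,), optional
        The benchmark itself when ``reference="external"``.

    Attributes
    ----------
    reference_ranks_ : ndarray of shape (n_rows,)
        Fractional ranks of the benchmark column.
    srd_values_ : ndarray of shape (n_columns,)
        Raw SRD (footrule distance) of each column vs the benchmark.
    srd_max_ : float
        Normalization constant (maximum attainable SRD).
    scaled_srd_ : ndarray of shape (n_columns,)
        ``100 * srd_values_ / srd_max_``, in [0, 100].
    labels_ : list of str
        Column labels (``col_0`` ... when not supplied to ``fit``).
    ordering_ : list of str
        Labels sorted by scaled SRD ascending (best first), ties broken
        lexicographically.
    """

    def __init__(self, reference: str = "max", external=None):
        self.reference = reference
        self.external = external

    def fit(self, X, y=None, *, labels=None) -> "SRDRanking":
        mat = np.asarray(X, dtype=float)
        if mat.ndim != 2:
            raise ValueError("X must be 2-D (rows x candidate columns)")
        n, m = mat.shape
        if n < 2:
            raise ValueError("SRD needs at least 2 rows; ranking is degenerate")
        if m < 1:
            raise ValueError("X must have at least one candidate column")
        if labels is None:
            labels = [f"col_{j}" for j in range(m)]
        labels = [str(lab) for lab in labels]
        if len(labels) != m:
            raise ValueError("labels length must match the number of columns")

        ref = reference_column(mat, self.reference, self.external)
        ref_ranks = rank_with_ties(ref)
        col_ranks = np.column_stack([rank_with_ties(mat[:, j]) for j in range(m)])
        srd = np.abs(col_ranks - ref_ranks[:, None]).sum(axis=0)
        smax = max_srd(ref_ranks)
        scaled = 100.0 * srd / smax if smax > 0 else np.zeros(m)

        self.n_features_in_ = m
        self.reference_ranks_ = ref_ranks
        self.column_ranks_ = col_ranks
        self.srd_values_ = srd.astype(float)
        self.srd_max_ = smax
        self.scaled_srd_ = scaled
        self.labels_ = labels
        order = sorted(range(m), key=lambda j: (scaled[j], labels[j]))
        self.ordering_ = [labels[j] for j in order]
        return self

    def fit_predict(self, X, y=None, *, labels=None) -> list[str]:
        """Fit and return the column ordering, best (lowest SRD) first."""
        return self.fit(X, y, labels=labels).ordering_


@dataclass(frozen=True)
class SrdResult:
    """Outcome of one SRD run over a peak table's procedure columns."""

    procedure_labels: tuple[str, ...]
    srd_values: tuple[float, ...]
    srd_max: float
    scaled_srd: tuple[float, ...]
    ordering: tuple[str, ...]
    reference_mode: str

    @property
    def n_procedures(self) -> int:
        return len(self.procedure_labels)

    def scaled_of(self, label: str) -> float:
        return self.scaled_srd[self.procedure_labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        """One row per procedure in ordering (best first)."""
        idx = {lab: i for i, lab in enumerate(self.procedure_labels)}
        rows = [
            {
                "procedure": lab,
                "srd": self.srd_values[idx[lab]],
                "scaled_srd": self.scaled_srd[idx[lab]],
            }
            for lab in self.ordering
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "reference_mode": self.reference_mode,
            "srd_max": self.srd_max,
            "procedures": {
                lab: {"srd": s, "scaled_srd": ss}
                for lab, s, ss in zip(
                    self.procedure_labels, self.srd_values, self.scaled_srd
                )
            },
            "ordering": list(self.ordering),
        }


def srd_analysis(
    table: PeakTable, reference_mode: str = "max", external=None
) -> SrdResult:
    """Run the five-step SRD on a peak table's procedure columns."""
    if table.n_compounds < 2:
        raise ValueError("SRD needs at least 2 compounds")
    est = SRDRanking(reference=reference_mode, external=external)
    est.fit(table.intensities, labels=table.procedure_labels)
    return SrdResult(
        procedure_labels=tuple(est.labels_),
        srd_values=tuple(float(v) for v in est.srd_values_),
        srd_max=float(est.srd_max_),
        scaled_srd=tuple(float(v) for v in est.scaled_srd_),
        ordering=tuple(est.ordering_),
        reference_mode=reference_mode,
    )
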