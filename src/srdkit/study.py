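"""Orchestration of the sampling-optimization study.

Three linked experiments over one peak table, each an SRD run with its own
CRRN null (the null depends on the row count):

* the full compound matrix;
* consecutive elution-order groups (volatility bands; 5 groups of 30, the
  last taking the 29-compound remainder, for the 149-compound design);
* top-N highest-intensity subsets (default N = 149, 100, 50, 20) probing how
  far the compound list can be shortened before the procedure ranking moves.

Results are collected in a :class:`StudyReport` with a per-procedure rank
stability table across all sub-analyses, and exported as deterministic
CSV/JSON (plus optional figures: scaled SRD per procedure with the null
frequency curve and its XX1/Med/XX19 levels overlaid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crrn import DEFAULT_PERMUTATIONS, ENUMERATION_LIMIT, CrrnDistribution, crrn_null
from .peak_table import PeakTable
from .srd import SrdResult, rank_with_ties, reference_column, srd_analysis

__all__ = [
    "SubAnalysis",
    "StudyReport",
    "split_by_elution_order",
    "top_n_by_intensity",
    "run_full_study",
    "export_report",
]


def split_by_elution_order(
    table: PeakTable, n_groups: int = 5, block_size: int = 30
) -> list[PeakTable]:
    """Split into consecutive elution-order blocks of ``block_size`` compounds;
    the last group takes all remaining compounds (e.g. 149 -> 30/30/30/30/29)."""
    n = table.n_compounds
    if n_groups < 1 or block_size < 1:
        raise ValueError("n_groups and block_size must be >= 1")
    if (n_groups - 1) * block_size >= n:
        raise ValueError(
            f"cannot cut {n} compounds into {n_groups} groups of {block_size}: "
            "earlier groups would exhaust the table"
        )
    groups = []
    for g in range(n_groups):
        start = g * block_size
        stop = (g + 1) * block_size if g < n_groups - 1 else n
        groups.append(table.subset(range(start, stop)))
    return groups


def top_n_by_intensity(table: PeakTable, n: int, statistic: str = "max") -> PeakTable:
    """Keep the n most intense compounds, by the row-wise ``statistic`` over
    procedures (default: the maximum, consistent with the max reference
    column). Survivors stay in elution order; cutoff ties prefer earlier
    elution; n >= table size returns the whole table."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= table.n_compounds:
        return table.subset(range(table.n_compounds))
    stat = reference_column(table.intensities, statistic)
    # stable sort on -stat keeps earlier elution first among exact ties
    order = np.argsort(-stat, kind="stable")[:n]
    return table.subset(np.sort(order))


@dataclass(frozen=True)
class SubAnalysis:
    """One SRD run (full table, one elution group, or one top-N subset)."""

    name: str
    n_compounds: int
    result: SrdResult | None
    null: CrrnDistribution | None
    index_range: tuple[int, int] | None = None  # elution groups only
    skipped: bool = False
    skip_reason: str | None = None


@dataclass(frozen=True)
class StudyReport:
    full: SubAnalysis
    groups: tuple[SubAnalysis, ...]
    topn: tuple[SubAnalysis, ...]
    rank_stability: pd.DataFrame
    reference_mode: str
    crrn_seed: int
    crrn_permutations: int

    @property
    def analyses(self) -> tuple[SubAnalysis, ...]:
        return (self.full, *self.groups, *self.topn)


def _analyze(
    name: str,
    sub: PeakTable,
    reference_mode: str,
    permutations: int,
    limit: int,
    seed: int,
    index_range: tuple[int, int] | None = None,
) -> SubAnalysis:
    if sub.n_compounds < 2:
        return SubAnalysis(
            name=name,
            n_compounds=sub.n_compounds,
            result=None,
            null=None,
            index_range=index_range,
            skipped=True,
            skip_reason="fewer than 2 compounds; ranking degenerate",
        )
    result = srd_analysis(sub, reference_mode=reference_mode)
    ref_ranks = rank_with_ties(reference_column(sub.intensities, reference_mode))
    null = crrn_null(ref_ranks, limit=limit, n_permutations=permutations, seed=seed)
    return SubAnalysis(
        name=name,
        n_compounds=sub.n_compounds,
        result=result,
        null=null,
        index_range=index_range,
    )


def run_full_study(
    table: PeakTable,
    topn_list: tuple[int, ...] = (149, 100, 50, 20),
    n_groups: int = 5,
    block_size: int = 30,
    reference_mode: str = "max",
    crrn_permutations: int = DEFAULT_PERMUTATIONS,
    crrn_limit: int = ENUMERATION_LIMIT,
    crrn_seed: int = 0,
) -> StudyReport:
    """Run the full-matrix, elution-group and top-N SRD analyses."""
    full = _analyze(
        "full", table, reference_mode, crrn_permutations, crrn_limit, crrn_seed
    )
    groups = []
    for g, sub in enumerate(split_by_elution_order(table, n_groups, block_size)):
        start = g * block_size
        stop = start + sub.n_compounds
        groups.append(
            _analyze(
                f"group_{g + 1}",
                sub,
                reference_mode,
                crrn_permutations,
                crrn_limit,
                crrn_seed,
                index_range=(start, stop),
            )
        )
    topn = [
        _analyze(
            f"top_{n}",
            top_n_by_intensity(table, n),
            reference_mode,
            crrn_permutations,
            crrn_limit,
            crrn_seed,
        )
        for n in topn_list
    ]

    labels = table.procedure_labels
    stability = {}
    for sub in (full, *groups, *topn):
        if sub.skipped or sub.result is None:
            continue
        pos = {lab: i + 1 for i, lab in enumerate(sub.result.ordering)}
        stability[sub.name] = [pos[lab] for lab in labels]
    rank_stability = pd.DataFrame(stability, index=labels)
    rank_stability.index.name = "procedure"

    return StudyReport(
        full=full,
        groups=tuple(groups),
        topn=tuple(topn),
        rank_stability=rank_stability,
        reference_mode=reference_mode,
        crrn_seed=crrn_seed,
        crrn_permutations=crrn_permutations,
    )


def _sub_frame(sub: SubAnalysis) -> pd.DataFrame:
    frame = sub.result.to_frame()
    frame["below_xx1"] = frame["scaled_srd"] < sub.null.xx1
    return frame


def _plot_sub(sub: SubAnalysis, path: Path) -> None:
    # scaled SRD on x and left y (procedures on the diagonal, labelled);
    # null relative frequencies on the right y with XX1/Med/XX19 markers
    from matplotlib.figure import Figure

    fig = Figure(figsize=(7, 4.5))
    ax = fig.add_subplot(111)
    res, null = sub.result, sub.null
    ax.plot(res.scaled_srd, res.scaled_srd, "o", color="tab:blue")
    for lab, ss in zip(res.procedure_labels, res.scaled_srd):
        ax.annotate(lab, (ss, ss), textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set_xlabel("scaled SRD")
    ax.set_ylabel("scaled SRD")
    ax.set_xlim(-2, 102)
    ax.set_ylim(-2, 102)
    ax2 = ax.twinx()
    ax2.plot(null.scaled_support, null.probabilities, "-", color="black", lw=1)
    ax2.set_ylabel("null relative frequency")
    for level, name in ((null.xx1, "XX1"), (null.med, "Med"), (null.xx19, "XX19")):
        ax.axvline(level, color="gray", ls=":", lw=0.8)
        ax.annotate(name, (level, 96), fontsize=7, color="gray")
    ax.set_title(f"{sub.name} (n={sub.n_compounds})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)


def export_report(report: StudyReport, directory, plots: bool = False) -> None:
    """Write per-sub-analysis CSVs, a JSON summary and the rank-stability
    table; byte-identical across re-exports of the same report."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    summary: dict = {
        "reference_mode": report.reference_mode,
        "crrn_seed": report.crrn_seed,
        "crrn_permutations": report.crrn_permutations,
        "analyses": {},
    }
    for sub in report.analyses:
        entry: dict = {"n_compounds": sub.n_compounds, "skipped": sub.skipped}
        if sub.skipped:
            entry["skip_reason"] = sub.skip_reason
        else:
            _sub_frame(sub).to_csv(
                directory / f"{sub.name}.csv", index=False, float_format="%.6f"
            )
            entry["ordering"] = list(sub.result.ordering)
            entry["srd_max"] = sub.result.srd_max
            entry["crrn"] = sub.null.to_dict()
            if sub.index_range is not None:
                entry["index_range"] = list(sub.index_range)
            if plots:
                _plot_sub(sub, directory / f"{sub.name}.png")
        summary["analyses"][sub.name] = entry

    report.rank_stability.to_csv(directory / "rank_stability.csv")
    with open(directory / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
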