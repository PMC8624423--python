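"""Compound-relevance filters for peak tables.

Three filters reduce a found-compound list to the analytically relevant set:

* area fraction — keep compounds whose share of the total integrated area is
  strictly above a threshold (default 0.1%);
* match factor — keep compounds whose library match factor is strictly above
  a threshold (default 80%); unidentified compounds (no match factor) fail;
* delta RI — eliminate compounds whose calculated vs literature retention
  index disagree by more than a threshold (default 10%), unless exempted by a
  high match factor (default > 90%). Compounds without a literature index are
  retained: there is no evidence against them.

``combine_mode`` controls how the area and match-factor filters combine
("all" = conjunction, "any" = disjunction); the delta-RI elimination always
applies. All filters only ever remove rows and are idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peak_table import PeakTable, PeakTableError, delta_ri_percent

__all__ = [
    "FilterConfig",
    "filter_by_area_fraction",
    "filter_by_match_factor",
    "filter_by_delta_ri",
    "apply_filters",
]


@dataclass(frozen=True)
class FilterConfig:
    min_area_percent: float = 0.1
    min_match_factor: float = 80.0
    max_delta_ri_percent: float = 10.0
    delta_ri_exemption_match_factor: float = 90.0
    combine_mode: str = "all"

    def __post_init__(self) -> None:
        for name in (
            "min_area_percent",
            "min_match_factor",
            "max_delta_ri_percent",
            "delta_ri_exemption_match_factor",
        ):
            if getattr(self, name) < 0:
                raise PeakTableError(f"{name} must be >= 0")
        if self.delta_ri_exemption_match_factor < self.min_match_factor:
            raise PeakTableError(
                "delta_ri_exemption_match_factor must be >= min_match_factor"
            )
        if self.combine_mode not in ("all", "any"):
            raise PeakTableError("combine_mode must be 'all' or 'any'")


def _area_shares(table: PeakTable) -> np.ndarray:
    """Per-compound area share in percent.

    Uses the stored ``area_percent`` when present; otherwise the compound's
    summed intensity across procedures as a share of the table total.
    """
    totals = table.intensities.sum(axis=1)
    grand = totals.sum()
    computed = 100.0 * totals / grand if grand > 0 else np.zeros_like(totals)
    stored = np.array(
        [r.area_percent if r.area_percent is not None else np.nan for r in table.records]
    )
    return np.where(np.isnan(stored), computed, stored)


def _area_mask(table: PeakTable, min_area_percent: float) -> np.ndarray:
    return _area_shares(table) > min_area_percent


def _match_factor_mask(table: PeakTable, min_match_factor: float) -> np.ndarray:
    return np.array(
        [
            r.match_factor is not None and r.match_factor > min_match_factor
            for r in table.records
        ]
    )


def _delta_ri_mask(table: PeakTable, max_delta: float, exemption_mf: float) -> np.ndarray:
    keep = np.ones(table.n_compounds, dtype=bool)
    for i, r in enumerate(table.records):
        if r.ri_calculated is None or r.ri_literature is None:
            continue  # no evidence against the identification
        delta = delta_ri_percent(r.ri_calculated, r.ri_literature)
        exempt = r.match_factor is not None and r.match_factor > exemption_mf
        if delta > max_delta and not exempt:
            keep[i] = False
    return keep


def filter_by_area_fraction(table: PeakTable, min_area_percent: float = 0.1) -> PeakTable:
    """Keep compounds with area share strictly above ``min_area_percent``."""
    return table.subset(np.flatnonzero(_area_mask(table, min_area_percent)))


def filter_by_match_factor(table: PeakTable, min_match_factor: float = 80.0) -> PeakTable:
    """Keep compounds with a match factor strictly above ``min_match_factor``."""
    return table.subset(np.flatnonzero(_match_factor_mask(table, min_match_factor)))


def filter_by_delta_ri(
    table: PeakTable,
    max_delta: float = 10.0,
    exemption_mf: float = 90.0,
) -> PeakTable:
    """Eliminate implausible identifications by retention-index disagreement."""
    return table.subset(np.flatnonzero(_delta_ri_mask(table, max_delta, exemption_mf)))


def apply_filters(table: PeakTable, config: FilterConfig | None = None) -> PeakTable:
    """Compose the relevance filters under ``config.combine_mode``."""
    cfg = config if config is not None else FilterConfig()
    area = _area_mask(table, cfg.min_area_percent)
    mf = _match_factor_mask(table, cfg.min_match_factor)
    dri = _delta_ri_mask(
        table, cfg.max_delta_ri_percent, cfg.delta_ri_exemption_match_factor
    )
    if cfg.combine_mode == "all":
        keep = area & mf & dri
    else:
        keep = (area | mf) & dri
    return table.subset(np.flatnonzero(keep))
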