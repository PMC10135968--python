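"""Per-cell efficacy estimation and group summaries.

The estimation chain mirrors how the recordings are analyzed: convert each
cell's measurements to activation probabilities, pick the background
appropriate to the cell's protocol, invert the saturating state function
to get the per-cell efficacy ``c``, convert to stabilization energy dG,
and only then aggregate to group mean +/- SD.  Aggregating per-cell values
(rather than estimating one c from group-mean probabilities) matters
because the inversion is nonlinear in both probabilities.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .cycle import GroupSummary
from .model import (
    DEFAULT_SITE_COUNT,
    SITE_COUNTS,
    ActivationPair,
    EnergyContext,
    efficacy_from_activation,
    free_energy,
)
from .normalize import CellActivationProfile, Protocol, background_pa, modulation_percent

__all__ = ["per_cell_estimates", "group_summary_table", "analyze_profiles"]


def _site_count(compound: str, site_counts: Mapping[str, int]) -> int:
    return int(site_counts.get(compound, DEFAULT_SITE_COUNT))


def per_cell_estimates(
    profiles: pd.DataFrame,
    site_counts: Mapping[str, int] | None = None,
    ctx: EnergyContext | None = None,
) -> pd.DataFrame:
    """Efficacy, energy and modulation percentage for every cell.

    ``profiles`` is a table with columns cell_id, receptor, compound,
    p_constitutive, p_background, p_modulated and optionally protocol /
    correction_flag (rebuilt from p_constitutive when absent).
    """
    if profiles.empty:
        raise ValueError("profile table has no rows")
    site_counts = site_counts if site_counts is not None else SITE_COUNTS
    ctx = ctx or EnergyContext()
    rows = []
    for rec in profiles.itertuples():
        profile = CellActivationProfile(
            cell_id=str(rec.cell_id),
            receptor=str(rec.receptor),
            compound=str(rec.compound),
            p_constitutive=float(rec.p_constitutive),
            p_background=float(rec.p_background),
            p_modulated=float(rec.p_modulated),
            protocol=Protocol(rec.protocol) if hasattr(rec, "protocol") else None,
        )
        N = _site_count(profile.compound, site_counts)
        pair = ActivationPair(
            p_background=background_pa(profile),
            p_modulated=profile.p_modulated,
        )
        c = efficacy_from_activation(pair, N=N)
        rows.append(
            {
                "cell_id": profile.cell_id,
                "receptor": profile.receptor,
                "compound": profile.compound,
                "protocol": profile.protocol.value,
                "modulation_pct": modulation_percent(profile),
                "c": c,
                "dG": free_energy(c, N=N, ctx=ctx),
                "N": N,
                "correction_flag": profile.correction_flag,
            }
        )
    return pd.DataFrame(rows)


def group_summary_table(per_cell: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per receptor x compound, one row per group."""
    grouped = per_cell.groupby(["receptor", "compound"], sort=False)
    out = grouped.agg(
        n=("c", "size"),
        modulation_mean=("modulation_pct", "mean"),
        modulation_sd=("modulation_pct", "std"),
        c_mean=("c", "mean"),
        c_sd=("c", "std"),
        dG_mean=("dG", "mean"),
        dG_sd=("dG", "std"),
        n_flagged=("correction_flag", "sum"),
    ).reset_index()
    return out


def analyze_profiles(
    profiles: pd.DataFrame,
    site_counts: Mapping[str, int] | None = None,
    ctx: EnergyContext | None = None,
) -> tuple[pd.DataFrame, list[GroupSummary]]:
    """Run the per-cell chain and summarize; returns (per-cell, summaries)."""
    per_cell = per_cell_estimates(profiles, site_counts=site_counts, ctx=ctx)
    table = group_summary_table(per_cell)
    summaries = [
        GroupSummary(
            receptor=str(row.receptor),
            compound=str(row.compound),
            mean_dG=float(row.dG_mean),
            sd_dG=float(row.dG_sd),
            n=int(row.n),
        )
        for row in table.itertuples()
    ]
    return per_cell, summaries
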