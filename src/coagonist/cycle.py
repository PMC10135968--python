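"""Mutant-cycle additivity analysis on group stabilization energies.

Each receptor x compound group is summarized by the mean, SD and n of
per-cell stabilization energies dG.  A mutation's effect on a compound is
the coupling energy

    ddG = dG_mutant - dG_wildtype

with standard error from the two group variances,
``se = sqrt(sd_wt^2/n_wt + sd_mut^2/n_mut)``, and a normal-approximation
95% interval ``ddG +/- 1.96 se``.

If binding sites at distinct intersubunit interfaces contribute
independently and additively to the compound's total stabilization energy,
knocking each interface out in turn and summing the losses must recover
the wild-type energy:  dG_wt = -sum(ddG_i).  The additivity verdict tests
whether -dG_wt falls inside the 95% interval of the summed ddG.

Group summaries must be means of per-cell dG values (compute c and dG per
cell, then aggregate) — never energies recomputed from group-mean
activation probabilities, which would be biased by the nonlinearity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "Z_95",
    "GroupSummary",
    "CouplingResult",
    "AdditivityVerdict",
    "ddg",
    "additivity_sum",
    "additivity_test",
    "mutant_cycle_report",
    "read_group_summaries",
    "write_group_summaries",
]

#: Normal 95% two-sided quantile used for all coupling-energy intervals.
Z_95 = 1.96


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SD of per-cell dG for one receptor x compound group."""

    receptor: str
    compound: str
    mean_dG: float
    sd_dG: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.receptor}/{self.compound}: n must be >= 2")
        if self.sd_dG < 0:
            raise ValueError("sd_dG must be >= 0")

    @property
    def var_of_mean(self) -> float:
        return self.sd_dG**2 / self.n


@dataclass(frozen=True)
class CouplingResult:
    """A coupling energy (or sum of them) with its propagated uncertainty."""

    ddG: float
    se: float
    ci_low: float
    ci_high: float
    compound: str
    components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.ddG <= self.ci_high):
            raise ValueError("confidence interval must contain the point estimate")


@dataclass(frozen=True)
class AdditivityVerdict:
    """Outcome of the additivity test for one compound."""

    compound: str
    sum_ddG: CouplingResult
    neg_dG_wt: float
    additive: bool


def ddg(mutant: GroupSummary, wildtype: GroupSummary, z: float = Z_95) -> CouplingResult:
    """Coupling energy of a mutation for one compound, with 95% CI."""
    if mutant.compound != wildtype.compound:
        raise ValueError(
            f"compound mismatch: {mutant.compound!r} vs {wildtype.compound!r}"
        )
    point = mutant.mean_dG - wildtype.mean_dG
    se = math.sqrt(wildtype.var_of_mean + mutant.var_of_mean)
    return CouplingResult(
        ddG=point,
        se=se,
        ci_low=point - z * se,
        ci_high=point + z * se,
        compound=mutant.compound,
        components=(f"{mutant.receptor} - {wildtype.receptor}",),
    )


def additivity_sum(
    results: Sequence[CouplingResult],
    z: float = Z_95,
    wildtype: GroupSummary | None = None,
) -> CouplingResult:
    """Sum of coupling energies with propagated uncertainty.

    By default the component variances are added as if independent, even
    though every ddG shares the wild-type group's sampling error.  That
    convention slightly overstates the summed variance; it is retained as
    the default reporting convention.  Passing the shared ``wildtype``
    summary switches on the covariance-aware propagation
    ``var = sum(var_mut_i) + k^2 * var_wt`` for ``k`` components.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one coupling result to sum")
    compounds = {r.compound for r in results}
    if len(compounds) != 1:
        raise ValueError(f"cannot sum across compounds: {sorted(compounds)}")
    total = sum(r.ddG for r in results)
    if wildtype is None:
        var = sum(r.se**2 for r in results)
    else:
        k = len(results)
        var_wt = wildtype.var_of_mean
        var = sum(r.se**2 - var_wt for r in results) + k**2 * var_wt
    se = math.sqrt(var)
    components = tuple(c for r in results for c in r.components)
    return CouplingResult(
        ddG=total,
        se=se,
        ci_low=total - z * se,
        ci_high=total + z * se,
        compound=compounds.pop(),
        components=components,
    )


def additivity_test(sum_result: CouplingResult, wildtype: GroupSummary) -> AdditivityVerdict:
    """Does the summed coupling energy account for the wild-type energy?

    Additivity holds when ``-dG_wt`` lies inside (boundary-inclusive) the
    95% interval of the summed ddG.
    """
    if wildtype.compound != sum_result.compound:
        raise ValueError(
            f"compound mismatch: {wildtype.compound!r} vs {sum_result.compound!r}"
        )
    target = -wildtype.mean_dG
    additive = sum_result.ci_low <= target <= sum_result.ci_high
    return AdditivityVerdict(
        compound=sum_result.compound,
        sum_ddG=sum_result,
        neg_dG_wt=target,
        additive=bool(additive),
    )


def mutant_cycle_report(
    summaries: Sequence[GroupSummary],
    wildtype_receptor: str,
    z: float = Z_95,
    covariance_aware: bool = False,
) -> tuple[pd.DataFrame, AdditivityVerdict]:
    """Full mutant-cycle analysis for one compound.

    ``summaries`` holds the wild-type group plus one group per mutated
    interface, all for the same compound.  Returns a per-mutation table of
    coupling energies (plus a summary row) and the additivity verdict.
    """
    wt = [s for s in summaries if s.receptor == wildtype_receptor]
    if not wt:
        raise ValueError(f"wild-type receptor {wildtype_receptor!r} not in summaries")
    wildtype = wt[0]
    mutants = [s for s in summaries if s.receptor != wildtype_receptor]
    if not mutants:
        raise ValueError("selection must contain at least one mutant receptor")
    couplings = [ddg(m, wildtype, z=z) for m in mutants]
    total = additivity_sum(
        couplings, z=z, wildtype=wildtype if covariance_aware else None
    )
    verdict = additivity_test(total, wildtype)
    rows = [
        {
            "receptor": m.receptor,
            "compound": m.compound,
            "ddG": r.ddG,
            "se": r.se,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
        }
        for m, r in zip(mutants, couplings)
    ]
    rows.append(
        {
            "receptor": "sum",
            "compound": total.compound,
            "ddG": total.ddG,
            "se": total.se,
            "ci_low": total.ci_low,
            "ci_high": total.ci_high,
        }
    )
    return pd.DataFrame(rows), verdict


_SUMMARY_COLUMNS = ["receptor", "compound", "mean_dG", "sd_dG", "n"]


def read_group_summaries(path: str | Path) -> list[GroupSummary]:
    table = pd.read_csv(path)
    missing = [c for c in _SUMMARY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        GroupSummary(
            receptor=str(row.receptor),
            compound=str(row.compound),
            mean_dG=float(row.mean_dG),
            sd_dG=float(row.sd_dG),
            n=int(row.n),
        )
        for row in table.itertuples()
    ]


def write_group_summaries(summaries: Sequence[GroupSummary], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "receptor": s.receptor,
                "compound": s.compound,
                "mean_dG": s.mean_dG,
                "sd_dG": s.sd_dG,
                "n": s.n,
            }
            for s in summaries
        ],
        columns=_SUMMARY_COLUMNS,
    ).to_csv(path, index=False)
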