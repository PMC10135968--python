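"""Synthetic oocyte experiments with the statistical structure of the assay.

Each simulated cell gets a constitutive activity and a low-agonist
background drawn from truncated normals, a modulated activity computed
from the ground-truth efficacy through the saturating state function, and
multiplicative measurement noise on the observed probabilities.  The
protocol (potentiation vs direct activation) follows from the cell's
constitutive activity exactly as in the real assay, so mutants with high
constitutive activity are automatically analyzed by direct activation.

Measurement noise is multiplicative on probabilities (default CV 5%): the
scatter of per-cell efficacy estimates then scales with the efficacy
itself, matching how group SDs of c grow with c.  Amplitude-level noise is
available through :func:`simulate_amplitudes`, which maps probabilities
back to currents between explicit anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import analyze_profiles
from .cycle import GroupSummary
from .model import (
    DEFAULT_SITE_COUNT,
    EnergyContext,
    efficacy_from_free_energy,
    free_energy,
    saturating_state_function,
)
from .normalize import Protocol, denormalize_probability, select_protocol

__all__ = [
    "SimSpec",
    "SimulatedStudy",
    "simulate_cells",
    "simulate_amplitudes",
    "simulate_study",
    "mutant_efficacy",
    "additive_mutant_efficacies",
]

_TRUNC_LOW, _TRUNC_HIGH = 0.005, 0.95
_MAX_REJECTION_DRAWS = 10_000


@dataclass(frozen=True)
class SimSpec:
    """Ground truth and sampling plan for one receptor x compound group."""

    receptor: str
    compound: str
    n_cells: int
    p_background_mean: float
    p_background_sd: float
    c_true: float
    N: int = DEFAULT_SITE_COUNT
    p_constitutive_mean: float = 0.005
    p_constitutive_sd: float = 0.002
    measurement_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        for name in ("p_background_mean", "p_constitutive_mean"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        for name in ("p_background_sd", "p_constitutive_sd", "measurement_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.c_true > 0:
            raise ValueError("c_true must be > 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")


@dataclass(frozen=True)
class SimulatedStudy:
    """Bundle produced by :func:`simulate_study`."""

    profiles: pd.DataFrame
    per_cell: pd.DataFrame
    summary_table: pd.DataFrame
    group_summaries: list[GroupSummary]


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int,
    low: float = _TRUNC_LOW, high: float = _TRUNC_HIGH,
) -> np.ndarray:
    """Rejection-sampled truncated normal; exact within the window."""
    if sd == 0.0:
        value = min(max(mean, low), high)
        return np.full(size, value)
    out = np.empty(size)
    filled = 0
    for _ in range(_MAX_REJECTION_DRAWS):
        draws = rng.normal(mean, sd, size=size - filled)
        keep = draws[(draws > low) & (draws < high)]
        out[filled : filled + keep.size] = keep
        filled += keep.size
        if filled == size:
            return out
    raise RuntimeError(
        f"truncated-normal rejection cap reached for mean={mean}, sd={sd}"
    )


def _noisy_probability(rng: np.random.Generator, p: np.ndarray, cv: float) -> np.ndarray:
    if cv == 0.0:
        return np.clip(p, 1e-6, 1 - 1e-6)
    noisy = p * rng.normal(1.0, cv, size=p.shape)
    return np.clip(noisy, 1e-6, 1 - 1e-6)


def simulate_cells(spec: SimSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one group of cells; deterministic for a fixed spec seed.

    Returns a profile table (cell_id, receptor, compound, p_constitutive,
    p_background, p_modulated, protocol, correction_flag) consumable by
    the estimation pipeline.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_cells
    p_const = _truncated_normal(rng, spec.p_constitutive_mean, spec.p_constitutive_sd, n)
    p_bg = _truncated_normal(rng, spec.p_background_mean, spec.p_background_sd, n)
    protocols = [select_protocol(p) for p in p_const]
    base = np.where(
        [p is Protocol.DIRECT_ACTIVATION for p in protocols], p_const, p_bg
    )
    p_mod = saturating_state_function(base, spec.c_true, spec.N)
    base_obs = _noisy_probability(rng, base, spec.measurement_cv)
    p_mod_obs = _noisy_probability(rng, np.asarray(p_mod), spec.measurement_cv)
    rows = []
    for i in range(n):
        direct = protocols[i] is Protocol.DIRECT_ACTIVATION
        rows.append(
            {
                "cell_id": f"{spec.receptor}:{spec.compound}:{i + 1:03d}",
                "receptor": spec.receptor,
                "compound": spec.compound,
                "p_constitutive": base_obs[i] if direct else p_const[i],
                "p_background": base_obs[i],
                "p_modulated": p_mod_obs[i],
                "protocol": protocols[i].value,
                "correction_flag": (not direct) and p_const[i] >= 0.01,
            }
        )
    return pd.DataFrame(rows)


def simulate_amplitudes(
    spec: SimSpec,
    full_anchor: float,
    zero_anchor: float = 0.0,
    amplitude_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate raw current amplitudes for one group of cells.

    Probabilities from :func:`simulate_cells` are mapped to currents
    between the two anchors (the inverse of the normalization), with
    optional additive normal noise on every amplitude.  Round-trips
    through the normalization to within that noise.
    """
    if abs(full_anchor - zero_anchor) < 1e-12:
        raise ValueError("degenerate anchors")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    profiles = simulate_cells(spec, rng=rng)
    records = []
    for rec in profiles.itertuples():
        per_condition = {
            "picrotoxin": 0.0,
            "GABA+propofol_max": 1.0,
            "baseline": rec.p_constitutive,
            "background": rec.p_background,
            "modulated": rec.p_modulated,
        }
        for condition, p in per_condition.items():
            amp = denormalize_probability(p, zero_anchor, full_anchor)
            if amplitude_noise_sd > 0 and condition not in (
                "picrotoxin",
                "GABA+propofol_max",
            ):
                amp += rng.normal(0.0, amplitude_noise_sd)
            records.append(
                {
                    "cell_id": rec.cell_id,
                    "receptor": rec.receptor,
                    "condition": condition,
                    "amplitude_nA": amp,
                }
            )
    return pd.DataFrame(records)


def simulate_study(
    specs: Sequence[SimSpec], seed: int | None = None
) -> SimulatedStudy:
    """Simulate several groups and run the full estimation pipeline.

    When ``seed`` is given it streams one RNG across all groups (the
    individual spec seeds are ignored); otherwise each group uses its own
    spec seed.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one SimSpec")
    if seed is not None:
        rng = np.random.default_rng(seed)
        frames = [simulate_cells(s, rng=rng) for s in specs]
    else:
        frames = [simulate_cells(s) for s in specs]
    profiles = pd.concat(frames, ignore_index=True)
    per_cell, summaries = analyze_profiles(profiles)
    from .analysis import group_summary_table

    table = group_summary_table(per_cell)
    return SimulatedStudy(
        profiles=profiles,
        per_cell=per_cell,
        summary_table=table,
        group_summaries=summaries,
    )


def mutant_efficacy(
    c_wildtype: float,
    ddG: float,
    N: int = DEFAULT_SITE_COUNT,
    ctx: EnergyContext | None = None,
) -> float:
    """Efficacy a mutant must have to shift the compound's dG by ``ddG``."""
    ctx = ctx or EnergyContext()
    dG_mut = free_energy(c_wildtype, N=N, ctx=ctx) + ddG
    return efficacy_from_free_energy(dG_mut, N=N, ctx=ctx)


def additive_mutant_efficacies(
    c_wildtype: float,
    n_mutants: int,
    N: int = DEFAULT_SITE_COUNT,
    ctx: EnergyContext | None = None,
) -> list[float]:
    """Mutant efficacies whose coupling energies sum exactly to -dG_wt.

    Splits the wild-type stabilization energy evenly across ``n_mutants``
    interface knockouts — the additive ground truth for power checks.
    """
    ctx = ctx or EnergyContext()
    dG_wt = free_energy(c_wildtype, N=N, ctx=ctx)
    ddg_each = -dG_wt / n_mutants
    return [mutant_efficacy(c_wildtype, ddg_each, N=N, ctx=ctx) for _ in range(n_mutants)]
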