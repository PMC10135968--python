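"""Two-state cyclic co-agonist model of allosteric channel gating.

A receptor equilibrates between a resting (closed) and an active (open)
state.  A modulator binds both states, with dissociation constant ``K_R``
in the resting receptor and ``c * K_R`` in the active receptor.  The
dimensionless efficacy ``c`` is the whole story energetically: ``c < 1``
means the ligand binds the active state more tightly and therefore
stabilizes it (a potentiator/activator), ``c > 1`` destabilizes it (an
inhibitor), and ``c = 1`` is neutral.  With ``N`` equivalent, independent
binding sites the occupancy term enters to the ``N``-th power, and the
total stabilization energy contributed by a saturating ligand is

    dG = N * RT * ln(c)    [kcal/mol]

negative when the ligand stabilizes the active state.

The activity level is summarized as ``P_A``, the probability that the
receptor occupies the active state.  Given a background activity
``P_A,background`` (set by constitutive gating and/or a low agonist
concentration), the modulated activity at ligand concentration ``L`` is
the state function

    P_A,mod = 1 / (1 + ((1 - p_bg)/p_bg) * ((1 + L/K_R)/(1 + L/(K_R*c)))**N)

At saturating ligand the bracket collapses to ``c**N`` and the relation
inverts in closed form, which is how efficacies are estimated from
measured activation-probability pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLAMP_EPSILON",
    "RT_DEFAULT",
    "DEFAULT_SITE_COUNT",
    "SITE_COUNTS",
    "ModulatorParams",
    "ActivationPair",
    "EnergyContext",
    "state_function",
    "saturating_state_function",
    "efficacy_from_activation",
    "free_energy",
    "efficacy_from_free_energy",
    "fold_potentiation_curve",
]

#: Thermal energy R*T in kcal/mol at 298.15 K (R = 1.987e-3 kcal/(mol*K)).
RT_DEFAULT: float = 0.5925

#: Conventional number of imposed binding sites when nothing else is known.
DEFAULT_SITE_COUNT: int = 2

#: Per-compound site-count conventions used throughout the analyses.
#: Propofol is treated as binding four transmembrane intersubunit sites;
#: etomidate and the neurosteroid 3a5bP as binding two.
SITE_COUNTS: dict[str, int] = {
    "NS-1738": 2,
    "PAM-2": 2,
    "propofol": 4,
    "etomidate": 2,
    "3a5bP": 2,
}

#: Probabilities are clamped into [eps, 1-eps] before ratio/log arithmetic
#: so that boundary measurements do not produce infinities.  The epsilon is
#: far below any measurable activation probability so that clamping never
#: alters valid data, and small enough that the closed-form inversion stays
#: exact everywhere the state function's output is representable.
CLAMP_EPSILON: float = 1e-12


def _clamp_probability(p: float, name: str = "probability") -> float:
    """Validate ``p`` in [0, 1] and clamp it strictly inside (0, 1)."""
    p = float(p)
    if not math.isfinite(p) or p < 0.0 or p > 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    return min(max(p, CLAMP_EPSILON), 1.0 - CLAMP_EPSILON)


@dataclass(frozen=True)
class ModulatorParams:
    """Binding/gating parameters of one modulatory compound.

    Parameters
    ----------
    name : str
        Compound label.
    K_R : float
        Equilibrium dissociation constant in the resting receptor (molar).
    c : float
        Gating efficacy: dissociation constant in the active receptor
        divided by ``K_R``.  ``c < 1`` stabilizes the active state.
    N : int
        Number of imposed, equivalent binding sites (>= 1).
    """

    name: str
    K_R: float
    c: float
    N: int = DEFAULT_SITE_COUNT

    def __post_init__(self) -> None:
        if not self.K_R > 0:
            raise ValueError(f"K_R must be > 0, got {self.K_R!r}")
        if not self.c > 0:
            raise ValueError(f"c must be > 0, got {self.c!r}")
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"N must be a positive integer, got {self.N!r}")

    @property
    def stabilizes_active(self) -> bool:
        return self.c < 1.0


@dataclass(frozen=True)
class ActivationPair:
    """Background / modulated activation probabilities for one cell.

    ``saturating`` records the caller's assertion that the compound was
    applied at an effectively saturating concentration (operationally,
    >= 1000x ``K_R``); efficacy estimation is only meaningful then.
    """

    p_background: float
    p_modulated: float
    concentration: float = math.inf
    saturating: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "p_background", _clamp_probability(self.p_background, "p_background")
        )
        object.__setattr__(
            self, "p_modulated", _clamp_probability(self.p_modulated, "p_modulated")
        )
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class EnergyContext:
    """Thermodynamic context: thermal energy and its provenance note."""

    RT: float = RT_DEFAULT
    note: str = "RT = 0.5925 kcal/mol (R = 1.987e-3 kcal/(mol K), T = 298.15 K)"

    def __post_init__(self) -> None:
        if not self.RT > 0:
            raise ValueError(f"RT must be > 0, got {self.RT!r}")


def state_function(
    p_background: float, concentration: float, params: ModulatorParams
) -> float:
    """Modulated activation probability at a given ligand concentration.

    Evaluates the two-state co-agonist state function.  Strictly
    increasing in concentration for ``c < 1``, strictly decreasing for
    ``c > 1``, and constant for ``c = 1``.
    """
    p_bg = _clamp_probability(p_background, "p_background")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    occupancy = (1.0 + concentration / params.K_R) / (
        1.0 + concentration / (params.K_R * params.c)
    )
    gating = ((1.0 - p_bg) / p_bg) * occupancy**params.N
    return 1.0 / (1.0 + gating)


def saturating_state_function(p_background, c: float, N: int = DEFAULT_SITE_COUNT):
    """Modulated activation probability in the saturating-ligand limit.

    The occupancy bracket of the state function tends to ``c`` as the
    concentration grows, leaving ``1 / (1 + ((1-p)/p) * c**N)``.  Accepts
    scalars or numpy arrays for ``p_background``.
    """
    if not c > 0:
        raise ValueError(f"c must be > 0, got {c!r}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N!r}")
    p = np.clip(np.asarray(p_background, dtype=float), CLAMP_EPSILON, 1.0 - CLAMP_EPSILON)
    if np.any(np.asarray(p_background, dtype=float) < 0) or np.any(
        np.asarray(p_background, dtype=float) > 1
    ):
        raise ValueError("p_background must lie in [0, 1]")
    out = 1.0 / (1.0 + ((1.0 - p) / p) * c**N)
    if np.isscalar(p_background) or np.ndim(p_background) == 0:
        return float(out)
    return out


def efficacy_from_activation(pair: ActivationPair, N: int = DEFAULT_SITE_COUNT) -> float:
    """Gating efficacy ``c`` from a saturating activation pair.

    Exact right-inverse of :func:`saturating_state_function`:

        c = [ (1/p_mod - 1) / ((1 - p_bg)/p_bg) ]**(1/N)

    Valid only at saturating compound concentration; callers flag this on
    the :class:`ActivationPair` rather than the function inferring it.
    """
    if not pair.saturating:
        raise ValueError(
            "efficacy estimation requires a saturating concentration; "
            "set ActivationPair.saturating=True to assert it"
        )
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N!r}")
    # (1 - p)/p rather than 1/p - 1: the subtraction is exact for p >= 0.5
    # (Sterbenz), which preserves the inversion near saturation
    numer = (1.0 - pair.p_modulated) / pair.p_modulated
    denom = (1.0 - pair.p_background) / pair.p_background
    return (numer / denom) ** (1.0 / N)


def free_energy(c: float, N: int = DEFAULT_SITE_COUNT, ctx: EnergyContext | None = None) -> float:
    """Stabilization energy dG = N * RT * ln(c), kcal/mol.

    Negative iff ``c < 1``, i.e. iff the compound stabilizes the active
    state.  The nominal value of ``c`` depends on the imposed site count
    ``N``; dG folds that back in and is comparable across compounds.
    """
    if not c > 0:
        raise ValueError(f"c must be > 0, got {c!r}")
    ctx = ctx or EnergyContext()
    return N * ctx.RT * math.log(c)


def efficacy_from_free_energy(
    dG: float, N: int = DEFAULT_SITE_COUNT, ctx: EnergyContext | None = None
) -> float:
    """Inverse of :func:`free_energy`: c = exp(dG / (N * RT))."""
    ctx = ctx or EnergyContext()
    return math.exp(dG / (N * ctx.RT))


def fold_potentiation_curve(
    c: float,
    N: int = DEFAULT_SITE_COUNT,
    p_background_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Apparent fold-potentiation across a grid of background activities.

    For a fixed efficacy the apparent potentiation (modulated/background
    activity at saturation) depends strongly on where on the activation
    curve the measurement is made: a potentiator (``c < 1``) shows the
    largest fold-effect at low background activity and the fold tends to
    one as the background approaches saturation (ceiling effect).  This
    is why ``c`` and dG, not fold-potentiation, are the comparable
    quantities across receptors.

    Returns a DataFrame with columns ``p_background``, ``p_modulated``,
    ``fold``.
    """
    if p_background_grid is None:
        p_background_grid = np.linspace(0.01, 0.99, 99)
    grid = np.asarray(list(p_background_grid), dtype=float)
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("p_background grid values must lie strictly in (0, 1)")
    p_mod = saturating_state_function(grid, c, N)
    p_mod = np.atleast_1d(p_mod)
    return pd.DataFrame(
        {"p_background": grid, "p_modulated": p_mod, "fold": p_mod / grid}
    )
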