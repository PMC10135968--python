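"""Published group summaries used as analysis inputs and simulation presets.

The tables below carry the per-group statistics (modulation percentage,
gating efficacy c and stabilization energy dG, each mean +/- SD with the
number of oocytes) for the wild-type a1b2g2L GABA_A receptor and a panel
of transmembrane intersubunit-interface mutants, for the two a7-nicotinic
PAMs (NS-1738, PAM-2) and for the anesthetics propofol and etomidate and
the neurosteroid 3a5bP.  Receptors measured by direct activation (because
of constitutive activity above 0.02) are marked ``constitutive=True``.

Greek subunit letters are transliterated (a1 = alpha1, b2 = beta2,
g2L = gamma2L).
"""

from __future__ import annotations

import pandas as pd

from .cycle import GroupSummary

__all__ = [
    "WILDTYPE",
    "PAM_GROUPS",
    "ANESTHETIC_GROUPS",
    "STEROID_GROUPS",
    "pam_table",
    "group_summary",
    "mutant_cycle_selection",
    "SIM_PRESETS",
]

WILDTYPE = "a1b2g2L"

# receptor, interface, compound, modulation% (mean, sd), c (mean, sd),
# dG kcal/mol (mean, sd), n, constitutive(direct-activation) flag
_PAM_ROWS = [
    # -- wild type
    (WILDTYPE, "wild-type", "NS-1738", 316, 123, 0.561, 0.106, -0.70, 0.23, 25, False),
    (WILDTYPE, "wild-type", "PAM-2", 189, 36, 0.721, 0.061, -0.39, 0.10, 25, False),
    # -- b+/a- interface
    ("b2(V258M)", "b+/a-", "NS-1738", 720, 140, 0.307, 0.044, -1.40, 0.16, 5, False),
    ("b2(V258M)", "b+/a-", "PAM-2", 301, 87, 0.559, 0.110, -0.70, 0.22, 5, False),
    ("b2(T262V)", "b+/a-", "NS-1738", 126, 12, 0.883, 0.045, -0.15, 0.06, 5, False),
    ("b2(T262V)", "b+/a-", "PAM-2", 121, 9, 0.906, 0.032, -0.12, 0.04, 5, False),
    ("b2(F289T)", "b+/a-", "NS-1738", 21, 14, 2.980, 1.097, 1.22, 0.47, 5, True),
    ("b2(F289T)", "b+/a-", "PAM-2", 98, 29, 1.058, 0.206, 0.05, 0.23, 8, True),
    ("b2(F289A)", "b+/a-", "NS-1738", 74, 55, 1.525, 0.845, 0.37, 0.60, 5, True),
    ("b2(F289A)", "b+/a-", "PAM-2", 87, 20, 1.094, 0.123, 0.10, 0.13, 5, True),
    ("a1(I227W)", "b+/a-", "NS-1738", 207, 56, 0.769, 0.163, -0.33, 0.24, 5, False),
    ("a1(I227W)", "b+/a-", "PAM-2", 135, 18, 0.856, 0.059, -0.19, 0.08, 5, False),
    ("a1(L231C)", "b+/a-", "NS-1738", 349, 133, 0.532, 0.105, -0.76, 0.23, 5, False),
    ("a1(L231C)", "b+/a-", "PAM-2", 197, 19, 0.691, 0.037, -0.44, 0.06, 5, False),
    ("a1(M235W)", "b+/a-", "NS-1738", 196, 46, 0.713, 0.108, -0.41, 0.17, 5, True),
    ("a1(M235W)", "b+/a-", "PAM-2", 174, 20, 0.749, 0.041, -0.34, 0.06, 5, True),
    # -- a+/b- and g+/b- interfaces
    ("b2(L223W)", "a+/b- g+/b-", "NS-1738", 215, 26, 0.635, 0.054, -0.54, 0.10, 5, False),
    ("b2(L223W)", "a+/b- g+/b-", "PAM-2", 48, 10, 1.540, 0.157, 0.50, 0.13, 5, False),
    ("b2(Q224A)", "a+/b- g+/b-", "NS-1738", 389, 182, 0.492, 0.118, -0.87, 0.28, 6, False),
    ("b2(Q224A)", "a+/b- g+/b-", "PAM-2", 169, 26, 0.752, 0.058, -0.34, 0.09, 5, False),
    ("b2(M227C)", "a+/b- g+/b-", "NS-1738", 335, 62, 0.533, 0.055, -0.75, 0.12, 5, False),
    ("b2(M227C)", "a+/b- g+/b-", "PAM-2", 143, 18, 0.833, 0.051, -0.22, 0.07, 5, False),
    # -- g+/b- interface
    ("g2L(L275C)", "g+/b-", "NS-1738", 283, 66, 0.569, 0.082, -0.67, 0.16, 5, False),
    ("g2L(L275C)", "g+/b-", "PAM-2", 251, 21, 0.611, 0.029, -0.58, 0.06, 5, False),
    ("g2L(T277I)", "g+/b-", "NS-1738", 511, 178, 0.375, 0.082, -1.18, 0.26, 5, True),
    ("g2L(T277I)", "g+/b-", "PAM-2", 117, 6, 0.919, 0.025, -0.10, 0.03, 5, True),
    ("g2L(T281I)", "g+/b-", "NS-1738", 262, 61, 0.592, 0.078, -0.63, 0.16, 6, False),
    ("g2L(T281I)", "g+/b-", "PAM-2", 255, 40, 0.687, 0.051, -0.45, 0.09, 5, False),
    ("g2L(F304C)", "g+/b-", "NS-1738", 34, 17, 1.917, 0.449, 0.74, 0.29, 5, True),
    ("g2L(F304C)", "g+/b-", "PAM-2", 40, 17, 1.791, 0.428, 0.66, 0.28, 5, True),
    # -- a+/g- and a+/b- interfaces
    ("a1(T264V)", "a+/g- a+/b-", "NS-1738", 295, 63, 0.530, 0.079, -0.76, 0.17, 5, False),
    ("a1(T264V)", "a+/g- a+/b-", "PAM-2", 240, 51, 0.620, 0.075, -0.57, 0.14, 5, False),
    ("a1(T266M)", "a+/g- a+/b-", "NS-1738", 151, 39, 0.189, 0.107, -0.24, 0.16, 5, False),
    ("a1(T266M)", "a+/g- a+/b-", "PAM-2", 147, 66, 0.855, 0.133, -0.20, 0.21, 6, False),
    ("a1(W287A)", "a+/g- a+/b-", "NS-1738", 292, 81, 0.584, 0.091, -0.65, 0.18, 5, False),
    ("a1(W287A)", "a+/g- a+/b-", "PAM-2", 182, 57, 0.747, 0.092, -0.35, 0.16, 6, False),
    ("a1(A290C)", "a+/g- a+/b-", "NS-1738", 262, 41, 0.596, 0.042, -0.61, 0.08, 5, False),
    ("a1(A290C)", "a+/g- a+/b-", "PAM-2", 215, 45, 0.659, 0.082, -0.50, 0.14, 5, False),
    ("a1(Y293F)", "a+/g- a+/b-", "NS-1738", 311, 140, 0.567, 0.133, -0.70, 0.29, 5, False),
    ("a1(Y293F)", "a+/g- a+/b-", "PAM-2", 184, 56, 0.735, 0.095, -0.37, 0.16, 5, False),
    ("a1(Y293C)", "a+/g- a+/b-", "NS-1738", 62, 14, 1.310, 0.164, 0.31, 0.14, 5, False),
    ("a1(Y293C)", "a+/g- a+/b-", "PAM-2", 122, 7, 0.899, 0.025, -0.13, 0.03, 6, False),
    # -- a+/g- interface
    ("g2L(I242W)", "a+/g-", "NS-1738", 314, 44, 0.541, 0.045, -0.73, 0.10, 5, False),
    ("g2L(I242W)", "a+/g-", "PAM-2", 166, 12, 0.766, 0.030, -0.31, 0.05, 5, False),
    ("g2L(I242S)", "a+/g-", "NS-1738", 376, 106, 0.493, 0.099, -0.85, 0.21, 6, False),
    ("g2L(I242S)", "a+/g-", "PAM-2", 174, 12, 0.744, 0.031, -0.35, 0.05, 5, False),
    ("g2L(L246W)", "a+/g-", "NS-1738", 150, 23, 0.800, 0.081, -0.27, 0.12, 5, True),
    ("g2L(L246W)", "a+/g-", "PAM-2", 115, 5, 0.928, 0.022, -0.09, 0.03, 5, True),
    ("g2L(L246N)", "a+/g-", "NS-1738", 40, 25, 2.161, 1.150, 0.80, 0.55, 5, True),
    ("g2L(L246N)", "a+/g-", "PAM-2", 75, 5, 1.205, 0.047, 0.22, 0.05, 5, True),
]

_ANESTHETIC_ROWS = [
    (WILDTYPE, "wild-type", "propofol", 1677, 1039, 0.302, 0.039, -2.84, 0.33, 6, False),
    (WILDTYPE, "wild-type", "etomidate", 1685, 501, 0.129, 0.030, -2.45, 0.27, 6, False),
    (WILDTYPE, "wild-type", "3a5bP", 715, 271, 0.303, 0.069, -1.45, 0.34, 15, False),
    ("g2L(L246N)", "a+/g-", "propofol", 209, 49, 0.677, 0.122, -0.96, 0.45, 6, True),
    ("g2L(L246N)", "a+/g-", "etomidate", 187, 22, 0.525, 0.184, -0.87, 0.63, 6, True),
    ("g2L(L246N)", "a+/g-", "3a5bP", 181, 9, 0.604, 0.050, -0.60, 0.10, 5, True),
]

_STEROID_ROWS = [
    (WILDTYPE, "wild-type", "3a5bP", 733, 183, 0.330, 0.038, -1.31, 0.14, 15, False),
    ("b2(F289A)", "b+/a-", "3a5bP", 463, 118, 0.453, 0.043, -0.94, 0.12, 5, True),
    ("a1(M235W)", "b+/a-", "3a5bP", 614, 116, 0.304, 0.046, -1.42, 0.19, 6, True),
    ("g2L(T277I)", "g+/b-", "3a5bP", 471, 262, 0.473, 0.110, -0.91, 0.29, 5, True),
    ("g2L(F304C)", "g+/b-", "3a5bP", 255, 31, 0.493, 0.091, -0.86, 0.26, 6, True),
    ("b2(L223W)", "a+/b- g+/b-", "3a5bP", 653, 186, 0.298, 0.057, -1.45, 0.22, 5, True),
    ("a1(Y293C)", "a+/g- a+/b-", "3a5bP", 666, 209, 0.266, 0.055, -1.58, 0.23, 5, False),
    ("g2L(L246N)", "a+/g-", "3a5bP", 181, 9, 0.604, 0.050, -0.60, 0.10, 5, True),
]

_COLUMNS = [
    "receptor",
    "interface",
    "compound",
    "modulation_mean",
    "modulation_sd",
    "c_mean",
    "c_sd",
    "dG_mean",
    "dG_sd",
    "n",
    "constitutive",
]


def _frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=_COLUMNS)


PAM_GROUPS = _frame(_PAM_ROWS)
ANESTHETIC_GROUPS = _frame(_ANESTHETIC_ROWS)
STEROID_GROUPS = _frame(_STEROID_ROWS)


def pam_table() -> pd.DataFrame:
    """Full PAM group-summary table (copy)."""
    return PAM_GROUPS.copy()


def group_summary(receptor: str, compound: str) -> GroupSummary:
    """Look up one receptor x compound group as a :class:`GroupSummary`."""
    for frame in (PAM_GROUPS, ANESTHETIC_GROUPS, STEROID_GROUPS):
        hit = frame[(frame.receptor == receptor) & (frame.compound == compound)]
        if not hit.empty:
            row = hit.iloc[0]
            return GroupSummary(
                receptor=receptor,
                compound=compound,
                mean_dG=float(row.dG_mean),
                sd_dG=float(row.dG_sd),
                n=int(row.n),
            )
    raise KeyError(f"no preset group for {receptor!r} x {compound!r}")


#: Mutations chosen so each class of intersubunit interface is knocked out
#: exactly once: b2(F289T) hits the two b+/a- interfaces, a1(Y293C) the
#: a+/b- and a+/g- interfaces, g2L(F304C) the g+/b- interface.
MUTANT_CYCLE_RECEPTORS = ["b2(F289T)", "a1(Y293C)", "g2L(F304C)"]


def mutant_cycle_selection(compound: str) -> list[GroupSummary]:
    """Wild type plus the three interface-knockout groups for one compound."""
    return [group_summary(WILDTYPE, compound)] + [
        group_summary(r, compound) for r in MUTANT_CYCLE_RECEPTORS
    ]


#: Simulation presets: background / constitutive activation statistics per
#: receptor x compound, matching the per-group recording statistics.  For
#: receptors without a published background P_A the wild-type low-agonist
#: background (0.06 +/- 0.03) is assumed.
SIM_PRESETS: dict[tuple[str, str], dict] = {
    (WILDTYPE, "NS-1738"): dict(
        p_background_mean=0.05, p_background_sd=0.03,
        p_constitutive_mean=0.005, p_constitutive_sd=0.002,
        c_true=0.561, N=2, n_cells=25,
    ),
    (WILDTYPE, "PAM-2"): dict(
        p_background_mean=0.06, p_background_sd=0.03,
        p_constitutive_mean=0.005, p_constitutive_sd=0.002,
        c_true=0.721, N=2, n_cells=25,
    ),
    ("b2(F289T)", "NS-1738"): dict(
        p_background_mean=0.28, p_background_sd=0.05,
        p_constitutive_mean=0.28, p_constitutive_sd=0.05,
        c_true=2.980, N=2, n_cells=5,
    ),
    ("b2(F289T)", "PAM-2"): dict(
        p_background_mean=0.23, p_background_sd=0.06,
        p_constitutive_mean=0.23, p_constitutive_sd=0.06,
        c_true=1.058, N=2, n_cells=8,
    ),
    ("a1(Y293C)", "NS-1738"): dict(
        p_background_mean=0.06, p_background_sd=0.03,
        p_constitutive_mean=0.005, p_constitutive_sd=0.002,
        c_true=1.310, N=2, n_cells=5,
    ),
    ("a1(Y293C)", "PAM-2"): dict(
        p_background_mean=0.06, p_background_sd=0.03,
        p_constitutive_mean=0.005, p_constitutive_sd=0.002,
        c_true=0.899, N=2, n_cells=6,
    ),
    ("g2L(F304C)", "NS-1738"): dict(
        p_background_mean=0.15, p_background_sd=0.07,
        p_constitutive_mean=0.15, p_constitutive_sd=0.07,
        c_true=1.917, N=2, n_cells=5,
    ),
    ("g2L(F304C)", "PAM-2"): dict(
        p_background_mean=0.15, p_background_sd=0.07,
        p_constitutive_mean=0.15, p_constitutive_sd=0.07,
        c_true=1.791, N=2, n_cells=5,
    ),
}
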