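"""Free-ion equilibria of Ca2+/Mg2+/EGTA buffered solutions.

Computes the free divalent-ion concentrations of an ACSF recipe from total
concentrations, pH, temperature and ionic strength, following the scheme of
the classic chelation calculators: absolute metal-ligand association
constants and ligand protonation pK values tabulated at reference
conditions (20 degC, 0.1 M ionic strength), adjusted to the working
temperature by van't Hoff with tabulated reaction enthalpies and to the
working ionic strength with the Davies activity model, then converted to a
pH-dependent apparent constant

    K_app = K_abs / (1 + [H]/Ka1 + [H]^2/(Ka1*Ka2)).

pH is interpreted as hydrogen-ion activity (what a pH meter reports) and
converted to concentration with the Davies single-ion coefficient.  Only
the two basic (amine) protonations of EGTA enter the correction; the
carboxylate pK values (~2.7, 2.0) are irrelevant at physiological pH.

The coupled mass-action / mass-conservation system is solved by scalar
root-finding on the free ligand concentration, which is bisection-safe on
[0, L_total] for 1:1 complexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "SolutionRecipe",
    "ConstantsTable",
    "EGTA_TABLE",
    "apparent_constant",
    "solve_free",
    "sensitivity",
]

_R_KCAL = 1.98720e-3       # kcal / mol / K
_LN10 = math.log(10.0)


@dataclass(frozen=True)
class SolutionRecipe:
    """Total concentrations (mM) plus the solution conditions."""

    metals: dict                     # e.g. {"Ca": 3.0, "Mg": 1.0}, mM
    ligands: dict                    # e.g. {"EGTA": 1.0}, mM
    pH: float = 7.4
    temperature: float = 34.0        # degC
    ionic_strength: float = 0.15     # M

    def __post_init__(self):
        for name, c in {**self.metals, **self.ligands}.items():
            if c < 0:
                raise ValueError(f"total concentration of {name} must be >= 0")
        if not 0.0 < self.pH < 14.0:
            raise ValueError("pH must be in (0, 14)")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")


@dataclass(frozen=True)
class LigandConstants:
    """Reference constants for one ligand and its metal complexes.

    ``log_K`` maps metal name -> (log10 association constant [1/M], Delta-H
    [kcal/mol]); ``pK`` holds the two basic protonation steps as
    (pK, Delta-H) pairs.  ``z_ligand`` is the charge of the fully
    deprotonated ligand (EGTA: -4), used by the Davies adjustment.
    """

    log_K: dict
    pK: tuple
    z_ligand: int = -4
    z_metal: int = 2


@dataclass(frozen=True)
class ConstantsTable:
    """Critical-stability constants at reference conditions."""

    ligands: dict                    # ligand name -> LigandConstants
    ref_temperature: float = 20.0    # degC
    ref_ionic_strength: float = 0.1  # M


# EGTA at 20 degC, I = 0.1 M (critical stability compilations; Delta-H in
# kcal/mol). Ca-EGTA binding is exothermic, Mg-EGTA endothermic -- warming
# from the tabulation temperature weakens Ca binding and strengthens Mg.
EGTA_TABLE = ConstantsTable(ligands={
    "EGTA": LigandConstants(
        log_K={"Ca": (10.97, -8.1), "Mg": (5.21, +5.5)},
        pK=((9.47, -5.6), (8.85, -5.7)),
    ),
})


def _vant_hoff(logK: float, dH: float, T_C: float, Tref_C: float) -> float:
    T = T_C + 273.15
    Tref = Tref_C + 273.15
    return logK + dH * (1.0 / Tref - 1.0 / T) / (_LN10 * _R_KCAL)


def _davies(I: float, A: float = 0.512) -> float:
    """-log10 gamma for a unit charge (Davies equation)."""
    if I <= 0:
        return 0.0
    s = math.sqrt(I)
    return A * (s / (1.0 + s) - 0.3 * I)


def apparent_constant(pair: tuple[str, str], pH: float, temperature: float,
                      ionic_strength: float,
                      table: ConstantsTable = EGTA_TABLE) -> float:
    """pH/temperature/ionic-strength-corrected association constant, 1/mM.

    ``pair`` is (metal, ligand), e.g. ("Ca", "EGTA").
    """
    metal, ligand = pair
    if ligand not in table.ligands:
        raise KeyError(f"unknown ligand {ligand!r}")
    lig = table.ligands[ligand]
    if metal not in lig.log_K:
        raise KeyError(f"no constants for pair {metal}-{ligand}")
    f = _davies(ionic_strength) - _davies(table.ref_ionic_strength)

    zl, zm = lig.z_ligand, lig.z_metal
    # M(2+) + L(4-) -> ML(2-):  sum z^2 reactants - product
    dz2_ml = zm * zm + zl * zl - (zm + zl) ** 2
    logK = _vant_hoff(*lig.log_K[metal], temperature, table.ref_temperature) \
        - dz2_ml * f
    # H+ + L -> HL, H+ + HL -> H2L
    dz2_h1 = 1 + zl * zl - (zl + 1) ** 2
    dz2_h2 = 1 + (zl + 1) ** 2 - (zl + 2) ** 2
    pK1 = _vant_hoff(*lig.pK[0], temperature, table.ref_temperature) - dz2_h1 * f
    pK2 = _vant_hoff(*lig.pK[1], temperature, table.ref_temperature) - dz2_h2 * f

    # pH meter reads activity; convert to concentration for the mass-action
    # quotient written in concentrations
    h_conc = 10.0 ** (-pH) / 10.0 ** (-_davies(ionic_strength))
    alpha = 1.0 + h_conc * 10.0 ** pK1 + h_conc * h_conc * 10.0 ** (pK1 + pK2)
    return 10.0 ** logK / alpha / 1000.0   # 1/M -> 1/mM


@dataclass(frozen=True)
class EquilibriumResult:
    free: dict                       # metal/ligand name -> free mM
    bound: dict                      # (metal, ligand) -> complex mM
    apparent_K: dict                 # (metal, ligand) -> 1/mM
    residual: float                  # worst conservation residual, mM


def solve_free(recipe: SolutionRecipe,
               table: ConstantsTable = EGTA_TABLE,
               tol: float = 1e-12) -> EquilibriumResult:
    """Free and complexed concentrations satisfying mass action + conservation.

    For each ligand L (1:1 complexes): the conservation function
    g(L_free) = L_free * (1 + sum_M K_ML * M_free(L_free)) - L_total is
    strictly increasing on [0, L_total], so the root is bracketed and found
    by Brent's method; with several ligands the scalar solves are iterated
    to joint convergence.
    """
    Ks = {}
    for lig in recipe.ligands:
        for metal in recipe.metals:
            if metal in table.ligands.get(lig, LigandConstants({}, ())).log_K:
                Ks[(metal, lig)] = apparent_constant(
                    (metal, lig), recipe.pH, recipe.temperature,
                    recipe.ionic_strength, table)

    lig_free = {lig: total for lig, total in recipe.ligands.items()}

    def metal_free(metal):
        denom = 1.0 + sum(Ks.get((metal, lig), 0.0) * lf
                          for lig, lf in lig_free.items())
        return recipe.metals[metal] / denom

    for _ in range(200):
        max_move = 0.0
        for lig, L_tot in recipe.ligands.items():
            if L_tot == 0.0:
                lig_free[lig] = 0.0
                continue

            def g(lf):
                lig_free[lig] = lf
                s = sum(Ks.get((m, lig), 0.0) * metal_free(m)
                        for m in recipe.metals)
                return lf * (1.0 + s) - L_tot

            old = lig_free[lig]
            new = brentq(g, 0.0, L_tot, xtol=1e-18, rtol=8.9e-16)
            lig_free[lig] = new
            max_move = max(max_move, abs(new - old))
        if max_move < tol:
            break

    free = {m: metal_free(m) for m in recipe.metals}
    free.update(lig_free)
    bound = {(m, lig): Ks[(m, lig)] * free[m] * lig_free[lig]
             for (m, lig) in Ks}

    # conservation residuals
    resid = 0.0
    for m, tot in recipe.metals.items():
        s = free[m] + sum(b for (mm, _), b in bound.items() if mm == m)
        resid = max(resid, abs(s - tot))
    for lig, tot in recipe.ligands.items():
        # free ligand here means all non-metal-bound ligand (any protonation)
        s = lig_free[lig] + sum(b for (_, ll), b in bound.items() if ll == lig)
        resid = max(resid, abs(s - tot))
    if resid > 1e-9:
        raise RuntimeError(f"equilibrium solver did not converge: residual {resid:.3g} mM")
    return EquilibriumResult(free=free, bound=bound, apparent_K=Ks,
                             residual=resid)


def sensitivity(recipe: SolutionRecipe, species: str,
                dlogK: float = 0.1,
                table: ConstantsTable = EGTA_TABLE) -> tuple[float, float]:
    """Range of the free concentration of ``species`` when every metal-ligand
    log K is shifted by +/- ``dlogK`` (the typical spread between published
    constant sets).  Returns (low, high) in mM."""
    import copy
    results = []
    for shift in (-dlogK, +dlogK):
        ligs = {}
        for name, lc in table.ligands.items():
            ligs[name] = LigandConstants(
                log_K={m: (k + shift, dH) for m, (k, dH) in lc.log_K.items()},
                pK=lc.pK, z_ligand=lc.z_ligand, z_metal=lc.z_metal)
        t2 = ConstantsTable(ligands=ligs, ref_temperature=table.ref_temperature,
                            ref_ionic_strength=table.ref_ionic_strength)
        results.append(solve_free(recipe, t2).free[species])
    return (min(results), max(results))
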