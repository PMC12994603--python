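"""Aqueous mass-balance solver with automatic solid-phase selection.

The solver works at fixed pcH on the log10 concentrations of the master
species (B, H3PO4, Cl-), with the amounts of any imposed solids as
additional linear unknowns constrained by their saturation conditions
(damped Newton, analytic Jacobian).  Sodium is a spectator; the strong
acid/base titrant implied by the imposed pcH is absorbed by a spectator
slack ion, as in pH-ramp practice.  An outer loop rescales all constants
to the current ionic strength until self-consistent.

Phase selection precipitates the candidate solid with the largest positive
saturation index, re-solves, and removes solids whose amounts go negative,
until every saturation index is <= tolerance and all amounts are >= 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .activity_ph import ActivityModel, log_gamma
from .errors import DomainError, InputError, PhaseSelectionError, SolverError
from .model_registry import (
    MediumRecipe,
    ModelConstants,
    default_solids,
    default_species,
)

logger = logging.getLogger("phsolv.speciation")

LN10 = math.log(10.0)
MASTERS = ("B", "P", "Cl")

SI_TOL = 1e-6  # saturation-index tolerance for phase selection
MASS_TOL_REL = 1e-12  # relative mass-balance tolerance
I_TOL = 1e-6  # ionic-strength self-consistency tolerance

__all__ = [
    "ObservationFlag",
    "SolubilityObservation",
    "EquilibriumState",
    "CurvePoint",
    "solve_at_fixed_pcH",
    "select_solid_phases",
    "solve_equilibrium",
    "simulate_logS_curve",
    "saturation_indices",
    "compute_pHmax",
    "henderson_hasselbalch_logS",
]


class ObservationFlag(str, Enum):
    OK = "ok"
    OUTLIER = "outlier_zero_weight"
    DEGRADED = "degraded"
    SUBSATURATED = "subsaturated"


@dataclass(frozen=True)
class SolubilityObservation:
    """One (pcH, log S) point with its assigned SD and weighting flag."""

    pcH: float
    logS: float
    sigma: float = 0.05
    flag: ObservationFlag = ObservationFlag.OK

    def __post_init__(self):
        if self.sigma <= 0:
            raise InputError("observation sigma must be > 0")

    @property
    def weight(self) -> float:
        return 1.0 if self.flag is ObservationFlag.OK else 0.0


@dataclass
class EquilibriumState:
    """Converged free concentrations, solid inventory and bookkeeping."""

    pcH: float
    I: float
    free: dict[str, float]
    derived: dict[str, float]
    solids: dict[str, float]
    totals: dict[str, float]
    c_na: float
    slack_cation: float
    slack_anion: float
    s_dissolved: float
    recipe: MediumRecipe
    activity: ActivityModel
    iterations: int = 0
    mass_residuals: dict[str, float] = field(default_factory=dict)
    _charges: dict[str, int] = field(default_factory=dict)

    def ions(self):
        """Parallel (concentration, charge) arrays over all charged content."""
        names = [n for n, z in self._charges.items() if z != 0]
        c = [self.derived[n] for n in names]
        z = [self._charges[n] for n in names]
        c += [self.free["H+"], self.c_na, self.slack_cation, self.slack_anion]
        z += [1, 1, 1, -1]
        return np.asarray(c), np.asarray(z)

    def charge_imbalance(self) -> float:
        """Net charge including the titrant slack ion (zero by construction)."""
        c, z = self.ions()
        return float(np.sum(c * z))

    @property
    def solids_present(self) -> tuple[str, ...]:
        return tuple(n for n, x in self.solids.items() if x > 0)


@dataclass(frozen=True)
class CurvePoint:
    pcH: float
    logS: float
    solids: tuple[str, ...]
    I: float
    subsaturated: bool


# ---------------------------------------------------------------------------
# scaled mass-action tables


class _Tables:
    """Species/solid mass-action data scaled to one (pcH, I) pair."""

    def __init__(self, model: ModelConstants, activity: ActivityModel,
                 pcH: float, I: float, active: tuple[bool, bool, bool]):
        self.pcH = pcH
        self.I = I
        self.active = active
        self.midx = [i for i, a in enumerate(active) if a]

        def lg(z, I_, salting):
            if z == 0 and not salting:
                return 0.0
            return log_gamma(z, I_, activity)

        species = []
        for sp in default_species(model):
            needs = (True, sp.n_p > 0, sp.n_cl > 0)
            if any(n and not a for n, a in zip(needs[1:], active[1:])):
                continue
            species.append(sp)
        self.species = species
        nsp = len(species)
        comp_full = np.zeros((nsp, 3))
        charge = np.zeros(nsp)
        logbeta = np.zeros(nsp)
        iref = activity.I_ref
        for i, sp in enumerate(species):
            comp_full[i] = (sp.n_b, sp.n_p, sp.n_cl)
            charge[i] = sp.charge
            if activity.is_off:
                logKf = sp.logK_ref
            else:
                def delta(I_):
                    return (lg(sp.charge, I_, sp.salting_out)
                            - sp.n_b * lg(0, I_, True)
                            - sp.n_cl * lg(-1, I_, False)
                            - sp.nu_h * lg(1, I_, False))
                logKf = sp.logK_ref - (delta(I) - delta(iref))
            logbeta[i] = logKf - sp.nu_h * pcH
        self.comp_full = comp_full
        self.comp = comp_full[:, self.midx]
        self.charge = charge
        self.logbeta = logbeta
        self.name_to_idx = {sp.name: i for i, sp in enumerate(species)}

        solids = []
        for so in default_solids(model):
            needs = (so.n_p > 0, so.n_cl > 0)
            if any(n and not a for n, a in zip(needs, active[1:])):
                continue
            solids.append(so)
        self.solids = solids
        self.solid_names = [so.name for so in solids]
        scomp_full = np.zeros((len(solids), 3))
        g0 = np.zeros(len(solids))
        for j, so in enumerate(solids):
            pksp = so.pKsp_ref
            acc = 0.0
            for ion_name, nu in so.iap_definition:
                i = self.name_to_idx[ion_name]
                sp = species[i]
                if not activity.is_off:
                    pksp += nu * (lg(sp.charge, I, sp.salting_out)
                                  - lg(sp.charge, iref, sp.salting_out))
                acc += nu * logbeta[i]
                scomp_full[j] += nu * comp_full[i]
            g0[j] = acc + pksp
        self.scomp_full = scomp_full
        self.scomp = scomp_full[:, self.midx]
        self.g0 = g0

    def concentrations(self, t: np.ndarray) -> np.ndarray:
        expo = np.clip(self.logbeta + self.comp @ t, -300.0, 100.0)
        return 10.0 ** expo


# ---------------------------------------------------------------------------
# Newton core


def _newton(tables: _Tables, totals: np.ndarray, t0: np.ndarray,
            solid_idx: list[int], max_iter: int = 200):
    """Damped Newton on log10 master concentrations + solid amounts."""
    m = len(totals)
    ns = len(solid_idx)
    scomp = tables.scomp[solid_idx] if ns else np.zeros((0, m))
    g0 = tables.g0[solid_idx] if ns else np.zeros(0)
    t = t0.copy()
    x = np.zeros(ns)
    scale = np.maximum(totals, 1e-10)

    def residuals(t_, x_):
        c = tables.concentrations(t_)
        F = tables.comp.T @ c - totals
        if ns:
            F = F + scomp.T @ x_
        G = g0 + scomp @ t_ if ns else np.zeros(0)
        return c, F, G

    def norm(F, G):
        return float(np.max(np.abs(np.concatenate([F / scale, G])))) if (ns or m) else 0.0

    c, F, G = residuals(t, x)
    best = norm(F, G)
    for it in range(max_iter):
        if (np.all(np.abs(F) <= np.maximum(1e-13, MASS_TOL_REL * totals))
                and (ns == 0 or np.max(np.abs(G)) <= 1e-11)):
            return t, x, c, F, it
        J = np.zeros((m + ns, m + ns))
        J[:m, :m] = LN10 * tables.comp.T @ (c[:, None] * tables.comp)
        if ns:
            J[:m, m:] = scomp.T
            J[m:, :m] = scomp
        rhs = -np.concatenate([F, G])
        try:
            delta = np.linalg.solve(J, rhs)
        except np.linalg.LinAlgError:
            delta, *_ = np.linalg.lstsq(J, rhs, rcond=None)
        # cap master steps at one decade to keep the heptamer term tame
        mx = np.max(np.abs(delta[:m])) if m else 0.0
        if mx > 1.0:
            delta = delta / mx
        lam = 1.0
        accepted = False
        for _ in range(40):
            t_new = np.clip(t + lam * delta[:m], -60.0, 3.0)
            x_new = x + lam * delta[m:]
            c_n, F_n, G_n = residuals(t_new, x_new)
            n_new = norm(F_n, G_n)
            if n_new < best or n_new < 1e-14:
                t, x, c, F, G, best = t_new, x_new, c_n, F_n, G_n, n_new
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            break
    if (np.all(np.abs(F) <= np.maximum(1e-13, MASS_TOL_REL * totals))
            and (ns == 0 or np.max(np.abs(G)) <= 1e-11)):
        return t, x, c, F, max_iter
    raise SolverError(
        "mass-balance Newton did not converge",
        diagnostics={"pcH": tables.pcH, "I": tables.I,
                     "residuals": F.tolist(),
                     "saturation": G.tolist() if ns else [],
                     "norm": best})


def _totals_and_masters(recipe: MediumRecipe):
    if recipe.c_b_total <= 0:
        raise InputError("recipe must contain drug (c_b_total > 0)")
    active = (True, recipe.c_p_total > 0, recipe.c_cl_total > 0)
    tot = np.array([recipe.c_b_total, recipe.c_p_total, recipe.c_cl_total])
    return tot[list(i for i, a in enumerate(active) if a)], active


def _solve_phases(recipe: MediumRecipe, model: ModelConstants, pcH: float,
                  activity: ActivityModel, solids_present: tuple[str, ...],
                  warm: EquilibriumState | None = None) -> EquilibriumState:
    """Solve the balances with a fixed set of imposed solids."""
    totals, active = _totals_and_masters(recipe)
    m = len(totals)

    if warm is not None and abs(warm.pcH - pcH) < 2.0:
        I = warm.I
        t0 = np.array([
            math.log10(max(warm.free.get(n, 1e-12), 1e-60))
            for n, a in zip(("B", "H3PO4", "Cl-"), active) if a])
    else:
        I = 0.5 * (recipe.c_na_total + recipe.c_cl_total
                   + recipe.c_strong_acid + recipe.c_strong_base) + 1e-3
        t0 = np.log10(totals) - 2.0

    h = 10.0 ** (-pcH)
    tables = t = x = c = None
    iterations = 0
    for outer in range(60):
        tables = _Tables(model, activity, pcH, I, active)
        sidx = [tables.solid_names.index(n) for n in solids_present]
        attempt_starts = [t0, np.log10(totals) - 4.0, np.log10(totals) - 0.5]
        err = None
        for start in attempt_starts:
            try:
                t, x, c, F, nit = _newton(tables, totals, np.asarray(start, float), sidx)
                err = None
                break
            except SolverError as e:
                err = e
        if err is not None:
            raise err
        iterations += nit
        oh = c[tables.name_to_idx["OH-"]]
        q = float(np.sum(tables.charge * c)) + recipe.c_na_total + h
        slack_an = max(q, 0.0)
        slack_cat = max(-q, 0.0)
        I_new = 0.5 * (float(np.sum(tables.charge ** 2 * c))
                       + recipe.c_na_total + h + slack_an + slack_cat)
        if activity.is_off or abs(I_new - I) < I_TOL:
            I = I_new
            break
        I = I_new if outer < 30 else 0.5 * (I + I_new)
        t0 = t
    else:
        raise SolverError("ionic-strength loop did not converge",
                          diagnostics={"pcH": pcH, "I": I})

    logger.debug("solve pcH=%.3f converged in %d Newton iterations (I=%.4f)",
                 pcH, iterations, I)

    derived = {sp.name: float(ci) for sp, ci in zip(tables.species, c)}
    free = {"H+": h, "OH-": derived["OH-"]}
    for name, a in zip(("B", "H3PO4", "Cl-"), active):
        if a:
            free[name] = derived[name]
    solids = {n: float(xi) for n, xi in zip(solids_present, x)}
    s_dissolved = float(np.sum(tables.comp_full[:, 0] * c))
    resid = {n: float(f) for n, f in zip(
        [nm for nm, a in zip(MASTERS, active) if a], F)}
    charges = {sp.name: int(sp.charge) for sp in tables.species}
    return EquilibriumState(
        pcH=pcH, I=I, free=free, derived=derived, solids=solids,
        totals={"B": recipe.c_b_total, "P": recipe.c_p_total,
                "Cl": recipe.c_cl_total},
        c_na=recipe.c_na_total, slack_cation=slack_cat, slack_anion=slack_an,
        s_dissolved=s_dissolved, recipe=recipe, activity=activity,
        iterations=iterations, mass_residuals=resid, _charges=charges)


# ---------------------------------------------------------------------------
# public API


def solve_at_fixed_pcH(recipe: MediumRecipe, model: ModelConstants, pcH: float,
                       activity: ActivityModel | None = None,
                       warm: EquilibriumState | None = None) -> EquilibriumState:
    """Solve the aqueous balances at fixed pcH with no solids imposed.

    The returned (possibly supersaturated) trial state is the input to
    :func:`select_solid_phases`.
    """
    activity = activity if activity is not None else ActivityModel()
    return _solve_phases(recipe, model, pcH, activity, (), warm)


def saturation_indices(state: EquilibriumState, model: ModelConstants) -> dict[str, float]:
    """SI = log10(IAP/Ksp) for every candidate solid at the state's (pcH, I)."""
    _, active = _totals_and_masters(state.recipe)
    tables = _Tables(model, state.activity, state.pcH, state.I, active)
    t = np.array([math.log10(max(state.free[n], 1e-300))
                  for n, a in zip(("B", "H3PO4", "Cl-"), active) if a])
    return {n: float(g + row @ t)
            for n, g, row in zip(tables.solid_names, tables.g0, tables.scomp)}


def select_solid_phases(state: EquilibriumState, model: ModelConstants,
                        max_cycles: int = 30) -> EquilibriumState:
    """Iterate precipitation/dissolution until all SI <= tol, amounts >= 0.

    Candidate solids are added in order of decreasing saturation index, ties
    broken by the acid-to-base order of :func:`default_solids`; at most two
    drug-bearing solids may coexist (a pHmax point).
    """
    recipe = state.recipe
    present: list[str] = list(state.solids_present)
    history: list[tuple[tuple[str, ...], dict[str, float]]] = []
    st = state
    for _ in range(max_cycles):
        st = _solve_phases(recipe, model, st.pcH, st.activity, tuple(present), warm=st)
        negatives = [n for n, xv in st.solids.items() if xv < -1e-12]
        if negatives:
            worst = min(negatives, key=lambda n: st.solids[n])
            present.remove(worst)
            history.append((tuple(present), {worst: st.solids[worst]}))
            continue
        si = saturation_indices(st, model)
        history.append((tuple(present), si))
        over = [(n, v) for n, v in si.items() if n not in present and v > SI_TOL]
        if not over:
            st.solids = {n: max(xv, 0.0) for n, xv in st.solids.items()}
            return st
        if len(present) >= 2:
            raise PhaseSelectionError(
                "more than two coexisting drug solids requested", history)
        name = max(over, key=lambda nv: (nv[1], -_solid_rank(model, nv[0])))[0]
        present.append(name)
    raise PhaseSelectionError("phase selection did not settle", history)


def _solid_rank(model, name):
    return [s.name for s in default_solids(model)].index(name)


def solve_equilibrium(recipe: MediumRecipe, model: ModelConstants, pcH: float,
                      activity: ActivityModel | None = None,
                      warm: EquilibriumState | None = None) -> EquilibriumState:
    """Trial solve followed by automatic solid-phase selection."""
    activity = activity if activity is not None else ActivityModel()
    initial = warm.solids_present if warm is not None else ()
    try:
        st = _solve_phases(recipe, model, pcH, activity, initial, warm)
        return select_solid_phases(st, model)
    except (SolverError, PhaseSelectionError):
        if initial:  # retry cold
            st = _solve_phases(recipe, model, pcH, activity, ())
            return select_solid_phases(st, model)
        raise


def simulate_logS_curve(recipe: MediumRecipe, model: ModelConstants,
                        grid, activity: ActivityModel | None = None) -> list[CurvePoint]:
    """Forward log S-pcH curve over an ascending pcH grid.

    Where a solid is present, ``S = c_b_total - sum(n_b * solid amounts)``;
    grid points where no solid forms are flagged subsaturated (total drug
    stays dissolved).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise InputError("pcH grid must be 1-D and strictly ascending")
    out: list[CurvePoint] = []
    warm = None
    for pcH in grid:
        try:
            st = solve_equilibrium(recipe, model, float(pcH), activity, warm=warm)
        except (SolverError, PhaseSelectionError) as e:
            raise SolverError(f"curve point pcH={pcH:.4f} failed: {e}",
                              diagnostics=getattr(e, "diagnostics", {})) from e
        warm = st
        sub = not st.solids_present
        logS = math.log10(st.s_dissolved if not sub else recipe.c_b_total)
        out.append(CurvePoint(float(pcH), logS, st.solids_present, st.I, sub))
    return out


def henderson_hasselbalch_logS(pcH, pS0: float, pKa: float):
    """Reference curve for a monoprotic base: -pS0 + log10(1 + 10^(pKa-pcH))."""
    x = np.asarray(pKa - np.asarray(pcH, dtype=float))
    stable = np.maximum(x, 0.0) + np.log10(1.0 + 10.0 ** (-np.abs(x)))
    res = -pS0 + stable
    return float(res) if res.ndim == 0 else res


def compute_pHmax(model: ModelConstants, solid_a: str, solid_b: str,
                  anchors: dict[str, float],
                  activity: ActivityModel | None = None,
                  I: float | None = None,
                  bracket: tuple[float, float] = (0.0, 14.0)) -> float:
    """pcH at which two drug solids are simultaneously saturated.

    ``anchors`` fixes the free concentrations of the counterion species
    (e.g. ``{"Cl-": 1.70}`` or ``{"H2PO4-": 1.5}``).  With activity off and
    the BHCl/B(s) pair this reproduces the closed form
    ``pHmax = pKa + log10(S0 * [Cl-] / Ksp)``.
    """
    if solid_a == solid_b:
        raise DomainError("the two solids must differ")
    activity = activity if activity is not None else ActivityModel.off()
    I_eval = I if I is not None else activity.I_ref
    all_solids = {s.name: s for s in default_solids(model)}
    for name in (solid_a, solid_b):
        if name not in all_solids:
            raise DomainError(f"unknown solid {name!r}")
        if all_solids[name].n_b == 0:
            raise DomainError(f"solid {name!r} does not contain the drug")
    need_p = any(all_solids[n].n_p for n in (solid_a, solid_b))
    need_cl = any(all_solids[n].n_cl for n in (solid_a, solid_b))
    active = (True, need_p, need_cl)

    def si_b(pcH):
        tables = _Tables(model, activity, pcH, I_eval, active)
        t = np.zeros(len(tables.midx))
        known = np.zeros(len(tables.midx), dtype=bool)
        known[0] = True  # B solved from solid A below
        for sp_name, conc in anchors.items():
            if sp_name not in tables.name_to_idx:
                continue
            i = tables.name_to_idx[sp_name]
            row = tables.comp[i]
            (mk,) = np.nonzero(row)
            k = int(mk[0])
            t[k] = (math.log10(conc) - tables.logbeta[i]) / row[k]
            known[k] = True
        if not known.all():
            raise DomainError("anchors do not fix all counterion masters")
        ja = tables.solid_names.index(solid_a)
        jb = tables.solid_names.index(solid_b)
        row_a = tables.scomp[ja]
        t[0] = -(tables.g0[ja] + row_a[1:] @ t[1:]) / row_a[0]
        return tables.g0[jb] + tables.scomp[jb] @ t

    lo, hi = bracket
    flo, fhi = si_b(lo), si_b(hi)
    if flo * fhi > 0:
        raise DomainError(
            f"no coexistence point for {solid_a}/{solid_b} in {bracket}")
    return float(brentq(si_b, lo, hi, xtol=1e-10))
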